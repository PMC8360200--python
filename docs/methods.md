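# Methods

This note records the models, conventions and calibrations behind
`sdrmine`, in the order the pipeline applies them, together with what the
synthetic benchmark does and does not demonstrate.

## Synthetic metagenome

The generator emulates the situation a sequence-directed mining campaign
faces: an assembled environmental library containing a handful of target-
family genes at a wide range of identities to the available seed
sequences, embedded in a large excess of non-family sequence.

* **Contigs** are i.i.d. nucleotide strings at a requested GC content,
  with lengths drawn from a normal distribution truncated at 300 bp
  (defaults 1500 ± 300 bp, GC 0.5). No repeat structure, coverage
  variation or sequencing error is simulated; contig-length statistics of
  real oral-cavity assemblies are not published, so these are free
  parameters chosen once as plausible for short-read assemblies.
* **Seed panel.** Three synthetic 250-residue stand-ins for R-selective
  carbonyl-reductase seeds, generated once from a common ancestor and
  frozen as constants. They share 54–59% mutual identity and carry the
  family hallmarks at canonical positions (glycine motif near the
  N-terminus, catalytic Ser/Tyr/Lys in the C-terminal half, supporting
  Asn upstream). Because they are equal-length by construction, the seed
  set doubles as its own ungapped alignment for profile building.
* **Planted homologs** are made by substitution-only mutation: to hit a
  target identity t, round(L·(1 − t/100)) positions outside the protected
  set are substituted by a uniformly drawn different residue. Length and
  residue coordinates are preserved, so the measured global-alignment
  identity tracks the target within ±2 points for t ≥ 30% (gaps only
  enter at very low identity, where the optimal alignment may shift).
  With motif protection on, the glycine window, the Y-x-x-x-K span, the
  catalytic Ser and the supporting Asn — exactly the positions the motif
  scanners report — are shielded, which is what licenses the benchmark
  requirement that every protected plant passes motif QC. A target below
  100·(protected positions)/L is rejected as infeasible.
* **Decoys** are Fisher–Yates shuffles of a template body (initiator Met
  kept): identical composition, destroyed order. Composition-only
  classifiers cannot reject them; alignment-based search must.
* **Planting** reverse-translates with the most frequent E. coli codon
  per residue (configurable table), appends TAA, and writes an in-frame
  TAA guard immediately upstream of the ATG so that six-frame ORF calling
  recovers exactly the planted protein rather than a fortuitously
  extended upstream variant. Inserts are placed uniformly at random on
  either strand without overlap. The truth table records CDS coordinates
  (stop included), strand, target identity and family status.

Passing the synthetic benchmark therefore shows that the pipeline's
decision machinery separates order-level family signal from composition
at realistic identity ranges; it does not certify performance against
real metagenomes, where gene density, codon usage, fragmentary ORFs and
homologs outside the seeded family all differ.

## ORF discovery

Six reading frames, ATG-only initiation, stop required inside the contig.
Each stop-to-stop segment contributes at most one ORF (its first ATG);
`all_starts=True` exposes every nested variant. The default minimum
protein length is 230 residues — the permissive end of the family's
230–250 band — with an optional maximum for window-style filtering.
Codons containing N translate to X; ORFs over 5% X are dropped.
Coordinates are reported 0-based, half-open, on the forward strand, with
the stop codon inside the interval. Translation uses the
bacterial/plastid genetic code (table 11) by default.

## Alignment engines

Both engines are affine-gap dynamic programming over a named substitution
matrix (default BLOSUM62); a gap of length L costs open + extend·L; X
scores 0 against everything.

* **Local** (candidate scoring): open 11, extend 1, score floor 0,
  traceback from the first row-major maximum with preference
  diagonal > up > left. These tie-breaks make outputs byte-reproducible.
* **Global** (percent identity): open 10, extend 0.5, end gaps penalised.
  Identity = 100 · identical columns / alignment length, gap columns in
  the denominator. This single declared convention is what makes panel
  statistics comparable across runs; the shorter-sequence denominator is
  available by flag because published identity figures rarely state their
  convention. All scores are multiples of 0.5 and exact in doubles, so
  the traceback's equality tests are safe.

Both engines are certified against exhaustive enumeration of alignment
move sequences on short random pairs (tests), not against each other.

## Family search

Two routes, pass on either:

* **Normalised local score** — SW score against the best seed divided by
  that seed's ungapped self-score; 1.0 means seed-identical.
  **Calibration:** a null of 100 shuffled decoys per seed tops out at
  0.037 normalised (99th percentile 0.035), while planted homologs at
  30% identity — the weakest signal the benchmark asks for — score at
  least ≈ 0.086. The default threshold 0.06 sits between, ~1.7× the null
  maximum. It is a calibrated, not canonical, value and is exposed in
  configuration.
* **Profile window** — log2 pseudocounted column frequency over a uniform
  1/20 background (empirical background configurable), columns over 50%
  gaps dropped, slid ungapped over the ORF, best window sum kept. The
  default pass mark is 25% of the profile's self-consensus score; the
  profile route mostly recruits mid-to-high-identity candidates and the
  gapped local aligner covers the rest, which is why full profile-HMM
  machinery is not used. No E-values are computed anywhere.

## Dereplication

Greedy incremental clustering, longest-sequence-first (ties by id): a
sequence joins the first cluster whose representative it matches at or
above the threshold, else founds a new cluster. Representatives are the
longest member (ties by id). The default threshold is 99%: a known family
pair at 98% identity must remain two panel entries, so the collapse point
has to exceed 98. The greedy order and tie-breaks are declared because
published panels rarely state their clustering tool or threshold.

## Comparative view

Distance is 1 − identity/100 — a similarity display, not a rate estimate,
so no Poisson/Kimura correction by default (Poisson available by flag).
Neighbor joining follows Saitou–Nei with the Q-criterion, ties broken by
the smallest index pair; branch lengths from the two-point formulas, with
a negative length clamped to zero and its deficit moved to the sister
branch (standard practice). The result is an unrooted tree with a
trifurcating root; additive inputs are reproduced exactly (path error
below 1e-9 in the acceptance suite). Clades are formed by cutting the
k−1 longest internal branches (leaf branches only as a fallback when k
approaches the leaf count, e.g. k = n); the heat-map leaf order is a
depth-first traversal with children visited smaller-subtree-first, ties
by smallest leaf label.

## Motif QC

The glycine-rich cofactor loop is matched as T-G-x-x-x-G-x-G with the T
inside a configurable N-terminal window (default first 60 residues). The
catalytic constellation anchors on the family's fixed Y-x-x-x-K geometry;
a Ser 10–25 residues upstream of the Tyr completes the triad, and an Asn
20–60 residues upstream of the Ser sets the tetrad flag. The Ser/Asn
windows are configurable because their exact offsets vary across the
family; the missing Asn never rejects a candidate on its own. All
positions are 0-based indices into the input protein.

## Gibson cloning in silico

Primers are adapter + annealing region: adapters are exact vector
sequence flanking the insertion span (default 20 nt per side); annealing
regions grow from 18 nt until the Tm model reaches 60 °C or 30 nt is hit.
Tm is the Wallace rule 2(A+T) + 4(G+C) below 14 nt and
64.9 + 41·(GC − 16.4)/len otherwise — deterministic composition-only
formulas, adequate for relative decisions, not thermodynamic predictions
(no nearest-neighbor model, no salt correction). The reverse annealing
region is taken from the CDS minus its stop codon, which is what lets the
construct read through into the vector tag. Simulated PCR demands unique
exact annealing sites; simulated assembly demands ≥ 15 nt exact junction
homology and then validates the construct: insert ATG at the translation
start, no in-frame stop before the tag, fusion ending …HHHHHH. Junction
failures raise; reading-frame problems are reported as validation issues.
The bundled vector is a synthetic miniature (backbone, MCS span, GSG
linker, His6, TAA) standing in for a C-terminal His-tag expression
vector whose full sequence is not bundled; a real sequence can be
supplied via `VectorSpec`. Primer-dimer/hairpin screening is not applied
by default.

## Assay quantification

Consumed cofactor (mM) = 1000·ΔA₃₄₀ / (ε·path) with ε = 6220 M⁻¹cm⁻¹ for
both NADH and NADPH, endpoint at the final cycle (a minimum-absorbance
endpoint is available for noisy traces), optional blank subtraction, and
clipping to [0, cofactor loading] with a warning — a larger drop implies
recycling or an artefact, neither of which is modelled. Conversion is
reported against **both** the substrate and the cofactor loadings,
because screens with 1 mM cofactor against 5 mM substrate have a 20%
substrate-referenced stoichiometric ceiling and published "conversion"
figures do not always state their reference; the package never guesses.
Path length is a required input (plate-well optical paths depend on fill
volume). Initial rates are least-squares slopes over the first n cycles.
Replicate wells aggregate as mean ± sd; a hit is mean substrate-
referenced conversion ≥ 10% by default. Michaelis–Menten fitting is out
of scope.

## Pipeline and reproducibility

All randomness flows from one integer seed through `numpy.random`
Generators; identical config + inputs give byte-identical artifacts
(report timings aside). Stage artifacts are plain FASTA/TSV/Newick/JSON;
every stage is re-runnable standalone. The run report records counts,
thresholds, seed and per-stage wall time; failures abort with the stage
named and a MANIFEST marking incompleteness.

## Benchmark problem sizes

The acceptance benchmark uses 100 contigs (~1.5 kb), 20 planted homologs
spanning 30–98% identity, and 20 shuffled decoys — large enough that the
score distributions separate or fail visibly, small enough to run in
seconds; the brute-force alignment oracles run at sequence lengths ≤ 8
(global) and ≤ 6 (local), where exhaustive enumeration is tractable, and
the neighbor-joining check uses 5–10 taxa per matrix.

## Known limitations

* The seed panel is synthetic; results on it say nothing about any
  specific natural reductase family beyond the structural assumptions
  encoded (length band, motif geometry, identity spread).
* The search thresholds are calibrated on the synthetic benchmark and
  should be re-calibrated for real seed sets (both are config options).
* Identity control of the mutation model degrades below ~30% targets as
  optimal alignments begin to include gaps.
* The profile search is ungapped; deeply indel-divergent homologs are
  recruited only through the gapped local-alignment route.
* No taxonomic or functional annotation: that requires external databases
  and is deliberately outside the package.
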