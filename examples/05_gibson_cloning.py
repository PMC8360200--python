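"""Design Gibson primers for a gene and verify the construct in silico.

The forward primer carries vector homology upstream of the insertion site;
the reverse primer anneals to the gene's 3' end *excluding* the stop codon
so translation reads through into the vector's His6 tag.
"""

from sdrmine.orfs import revcomp
from sdrmine.primers import design_gibson_primers, make_mock_vector, simulate_gibson, simulate_pcr
from sdrmine.synthetic import SEED_PROTEINS, reverse_translate

vector = make_mock_vector()
protein = SEED_PROTEINS["seedR2"]
gene = reverse_translate(protein) + "TAA"

pair = design_gibson_primers(gene, vector, adapter_len=20, tm_target=60.0)
print(f"gene: {len(gene)} bp (250 aa + stop)")
print(f"forward: {pair.forward}")
print(f"  adapter 20 nt + {pair.anneal_len_f} nt annealing, Tm {pair.tm_f:.1f} C")
print(f"reverse: {pair.reverse}")
print(f"  adapter 20 nt + {pair.anneal_len_r} nt annealing, Tm {pair.tm_r:.1f} C")

site = revcomp(pair.reverse_anneal)
print(f"reverse site ends at {gene.rfind(site) + len(site)} of {len(gene)} "
      "(3 bp short: the stop codon is removed)")

amplicon = simulate_pcr(gene, pair)
assembly = simulate_gibson(vector, amplicon)
print(f"\namplicon: {len(amplicon)} bp; construct valid: {assembly.valid}")
print(f"fusion protein ({len(assembly.fusion_protein)} aa) ends with: "
      f"...{assembly.fusion_protein[-12:]}")
print("\nThe fusion is insert protein + GSG linker + HHHHHH, with the"
      "\ninitiator Met at the translation start and no internal stop.")
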