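"""End-to-end orchestration: simulate/mine -> search -> dereplicate ->
compare -> motif QC -> primer design, with one config and one seed.

Every stage writes its artifact into the output directory and can also be
run standalone through the CLI, so re-screening with new thresholds does
not require re-mining.  The run report (``report.json``) records counts at
every stage, the thresholds used, the seed and per-stage wall time; reruns
with identical config and inputs are byte-identical except for the
timings in the report.  On a stage failure the partial outputs are kept
and ``MANIFEST.txt`` marks where the run stopped.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import assay as assay_mod
from . import derep as derep_mod
from . import motifs as motifs_mod
from . import orfs as orfs_mod
from . import phylo as phylo_mod
from . import primers as primers_mod
from . import search as search_mod
from . import synthetic as synth_mod

log = logging.getLogger("sdrmine")


class ConfigError(ValueError):
    """Invalid pipeline configuration; carries the full error list."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class SimulateConfig:
    n_contigs: int = 100
    length_mean: float = 1500.0
    length_sd: float = 300.0
    gc: float = 0.5
    identities: list[float] = field(default_factory=lambda: [round(30 + 68 * i / 19, 1) for i in range(20)])
    n_decoys: int = 20
    strand_policy: str = "both"


@dataclass
class PipelineConfig:
    out_dir: str = "sdrmine_out"
    contigs: str | None = None  # FASTA path; None => simulate
    seeds: str | None = None  # protein FASTA; None => bundled seed panel
    vector: dict | None = None  # {path, site_start, site_end, his6_frame_offset}
    seed: int = 0
    min_len_aa: int = 230
    max_len_aa: int | None = None
    norm_threshold: float = search_mod.DEFAULT_NORM_THRESHOLD
    profile_fraction: float = search_mod.DEFAULT_PROFILE_FRACTION
    derep_threshold: float = 99.0
    clade_k: int = 3
    adapter_len: int = 20
    tm_target: float = 60.0
    anneal_min: int = 18
    anneal_max: int = 30
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)


def _check_config(cfg: PipelineConfig) -> list[str]:
    errors: list[str] = []
    if cfg.min_len_aa < 1:
        errors.append("min_len_aa must be >= 1")
    if cfg.max_len_aa is not None and cfg.max_len_aa < cfg.min_len_aa:
        errors.append("max_len_aa must be >= min_len_aa")
    if not 0.0 < cfg.derep_threshold <= 100.0:
        errors.append("derep_threshold must lie in (0, 100]")
    if not 0.0 <= cfg.norm_threshold <= 1.5:
        errors.append("norm_threshold must lie in [0, 1.5]")
    if not 0.0 <= cfg.profile_fraction <= 1.0:
        errors.append("profile_fraction must lie in [0, 1]")
    if cfg.clade_k < 1:
        errors.append("clade_k must be >= 1")
    if cfg.anneal_min > cfg.anneal_max:
        errors.append("anneal_min must not exceed anneal_max")
    if cfg.simulate.n_contigs < 1:
        errors.append("simulate.n_contigs must be >= 1")
    if not 0.0 < cfg.simulate.gc < 1.0:
        errors.append("simulate.gc must lie strictly between 0 and 1")
    if cfg.simulate.strand_policy not in ("both", "forward"):
        errors.append("simulate.strand_policy must be 'both' or 'forward'")
    for ident in cfg.simulate.identities:
        if not 10.0 <= ident <= 100.0:
            errors.append(f"simulate identity {ident} outside [10, 100]")
    return errors


KNOWN_KEYS = {
    "out_dir", "contigs", "seeds", "vector", "seed", "min_len_aa", "max_len_aa",
    "norm_threshold", "profile_fraction", "derep_threshold", "clade_k",
    "adapter_len", "tm_target", "anneal_min", "anneal_max", "log_level",
    "simulate",
}


def validate_config(path) -> PipelineConfig:
    """Parse and validate a YAML config, reporting all errors together.

    Unknown keys warn (forward compatibility) rather than fail.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])
    for key in set(raw) - KNOWN_KEYS:
        log.warning("unknown config key ignored: %s", key)
    sim_raw = raw.pop("simulate", {}) or {}
    known_sim = set(SimulateConfig.__dataclass_fields__)
    for key in set(sim_raw) - known_sim:
        log.warning("unknown simulate key ignored: %s", key)
    cfg = PipelineConfig(
        **{k: v for k, v in raw.items() if k in KNOWN_KEYS and k != "simulate"},
        simulate=SimulateConfig(**{k: v for k, v in sim_raw.items() if k in known_sim}),
    )
    errors = _check_config(cfg)
    if errors:
        raise ConfigError(errors)
    return cfg


def _load_seeds(cfg: PipelineConfig) -> dict[str, str]:
    if cfg.seeds is None:
        return dict(synth_mod.SEED_PROTEINS)
    seeds = synth_mod.ContigSet.from_fasta(cfg.seeds).sequences
    if not seeds:
        raise StageError("search", f"no seed sequences in {cfg.seeds}")
    return seeds


def _load_vector(cfg: PipelineConfig) -> primers_mod.VectorSpec:
    if cfg.vector is None:
        return primers_mod.make_mock_vector()
    spec = dict(cfg.vector)
    seq = synth_mod.ContigSet.from_fasta(spec["path"]).sequences
    (sequence,) = seq.values()
    return primers_mod.VectorSpec(
        sequence=sequence,
        site_start=int(spec["site_start"]),
        site_end=int(spec["site_end"]),
        his6_frame_offset=int(spec.get("his6_frame_offset", 3)),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return the run report (also written).

    Raises :class:`StageError` on the first failing stage after writing the
    MANIFEST; earlier artifacts are retained.
    """
    errors = _check_config(config)
    if errors:
        raise ConfigError(errors)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "thresholds": {
            "min_len_aa": config.min_len_aa,
            "max_len_aa": config.max_len_aa,
            "norm_threshold": config.norm_threshold,
            "profile_fraction": config.profile_fraction,
            "derep_threshold": config.derep_threshold,
            "clade_k": config.clade_k,
        },
        "stages": {},
        "counts": {},
    }
    completed: list[str] = []

    def finish_stage(stage: str, t0: float, **counts) -> None:
        report["stages"][stage] = {"wall_s": round(time.perf_counter() - t0, 3)}
        report["counts"].update(counts)
        completed.append(stage)
        log.info("stage %s done: %s", stage, counts)

    def fail(stage: str, message: str) -> StageError:
        (out / "MANIFEST.txt").write_text(
            "incomplete run\ncompleted stages: " + ", ".join(completed)
            + f"\nfailed stage: {stage}\n"
        )
        return StageError(stage, message)

    # stage 1: contigs (load or simulate)
    t0 = time.perf_counter()
    try:
        if config.contigs is not None:
            contigs = synth_mod.ContigSet.from_fasta(config.contigs)
            if not contigs.sequences:
                raise ValueError(f"no contigs parsed from {config.contigs}")
        else:
            sim = config.simulate
            contigs = synth_mod.generate_contigs(
                sim.n_contigs, sim.length_mean, sim.length_sd, sim.gc, seed=config.seed
            )
            contigs, truth = synth_mod.plant_genes(
                contigs,
                synth_mod.default_templates(),
                sim.identities,
                strand_policy=sim.strand_policy,
                seed=config.seed,
                n_decoys=sim.n_decoys,
            )
            contigs.to_fasta(out / "contigs.fna")
            contigs.write_truth_table(out / "truth.tsv")
    except (OSError, ValueError, synth_mod.PlacementError) as exc:
        raise fail("contigs", str(exc)) from exc
    finish_stage("contigs", t0, contigs=len(contigs))

    # stage 2: ORF mining
    t0 = time.perf_counter()
    orfs = orfs_mod.find_orfs_multi(contigs.items(), min_len_aa=config.min_len_aa)
    orfs = orfs_mod.filter_orfs(orfs, config.min_len_aa, config.max_len_aa)
    orfs_mod.write_protein_fasta(orfs, out / "orfs.faa")
    orfs_mod.write_orf_table(orfs, out / "orfs.tsv")
    finish_stage("mine", t0, orfs=len(orfs))

    # stage 3: family search
    t0 = time.perf_counter()
    try:
        seeds = _load_seeds(config)
        profile = None
        if len(seeds) >= 2 and len({len(s) for s in seeds.values()}) == 1:
            # equal-length seed set doubles as its own ungapped alignment
            profile = search_mod.build_profile(seeds)
        hits = search_mod.score_orfs(
            orfs,
            seeds,
            profile,
            norm_threshold=config.norm_threshold,
            profile_fraction=config.profile_fraction,
        )
    except (OSError, ValueError) as exc:
        raise fail("search", str(exc)) from exc
    search_mod.write_hit_table(hits, out / "hits.tsv")
    passed = [h for h in hits if h.passed]
    finish_stage("search", t0, hits=len(hits), passed=len(passed))

    # stage 4: dereplication
    t0 = time.perf_counter()
    orf_by_id = {o.orf_id: o for o in orfs}
    panel = {h.orf_id: orf_by_id[h.orf_id].protein for h in passed}
    lengths = {k: len(v) for k, v in panel.items()}
    if len(panel) >= 2:
        matrix = derep_mod.identity_matrix(panel)
        clusters = derep_mod.cluster_greedy(matrix, config.derep_threshold, lengths)
        matrix.to_tsv(out / "identity_matrix.tsv")
    else:
        matrix = None
        clusters = [
            derep_mod.Cluster((k,), k, config.derep_threshold) for k in panel
        ]
    derep_mod.write_cluster_table(clusters, out / "clusters.tsv")
    representatives = [
        derep_mod.pick_representative(c, lengths) for c in clusters
    ]
    orfs_mod.write_protein_fasta(
        [orf_by_id[r] for r in representatives], out / "representatives.faa"
    )
    finish_stage("derep", t0, clusters=len(clusters), representatives=len(representatives))

    # stage 5: comparative view
    t0 = time.perf_counter()
    if matrix is not None and len(representatives) >= 3:
        rep_matrix = matrix.reorder(representatives)
        tree = phylo_mod.neighbor_joining(phylo_mod.distance_from_identity(rep_matrix))
        (out / "tree.nwk").write_text(phylo_mod.to_newick(tree) + "\n")
        k = min(config.clade_k, len(representatives))
        clades = phylo_mod.assign_clades(tree, k)
        phylo_mod.write_clade_table(clades, out / "clades.tsv")
        order = phylo_mod.heatmap_order(tree)
        rep_matrix.reorder(order).to_tsv(out / "identity_matrix_ordered.tsv")
        n_clades = len(set(clades.values()))
    else:
        log.info("comparative stage skipped: fewer than 3 representatives")
        n_clades = 0
    finish_stage("compare", t0, clades=n_clades)

    # stage 6: motif QC
    t0 = time.perf_counter()
    reports = motifs_mod.qc_table({r: panel[r] for r in representatives})
    motifs_mod.write_qc_table(reports, out / "motif_qc.tsv")
    qc_pass = sum(1 for r in reports if r.gly_pass and r.triad_pass)
    finish_stage("qc", t0, qc_pass=qc_pass)

    # stage 7: Gibson primers (with in-silico cloning verification)
    t0 = time.perf_counter()
    try:
        vector = _load_vector(config)
    except (OSError, KeyError, ValueError) as exc:
        raise fail("primers", f"vector spec invalid: {exc}") from exc
    primer_rows: list[tuple[str, primers_mod.PrimerPair]] = []
    verified = 0
    for rep in representatives:
        rec = orf_by_id[rep]
        dna = contigs.sequences[rec.contig_id][rec.start : rec.end]
        if rec.strand == "-":
            dna = orfs_mod.revcomp(dna)
        try:
            pair = primers_mod.design_gibson_primers(
                dna,
                vector,
                adapter_len=config.adapter_len,
                tm_target=config.tm_target,
                anneal_min=config.anneal_min,
                anneal_max=config.anneal_max,
            )
            amplicon = primers_mod.simulate_pcr(dna, pair)
            assembly = primers_mod.simulate_gibson(vector, amplicon)
        except (ValueError, primers_mod.AmplificationError, primers_mod.AssemblyError) as exc:
            log.warning("primer design failed for %s: %s", rep, exc)
            continue
        primer_rows.append((rep, pair))
        if assembly.valid:
            verified += 1
    primers_mod.write_primer_table(primer_rows, out / "primers.tsv")
    finish_stage("primers", t0, primer_pairs=len(primer_rows), constructs_verified=verified)

    report["artifacts"] = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "report.json"
    )
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    (out / "MANIFEST.txt").write_text(
        "complete run\nstages: " + ", ".join(completed) + "\n"
    )
    return report


def run_assay_stage(traces_path, out_dir, hit_threshold: float = 10.0):
    """Standalone assay stage: trace TSV in, screen table out."""
    traces = assay_mod.read_trace_tsv(traces_path)
    table = assay_mod.screen_matrix(traces, hit_threshold=hit_threshold)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    assay_mod.write_screen_table(table, out / "screen.tsv")
    return table
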