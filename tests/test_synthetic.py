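"""Synthetic metagenome generator: determinism, identity control, planting."""

import numpy as np
import pytest

from sdrmine.derep import global_identity
from sdrmine.orfs import find_orfs_multi
from sdrmine.synthetic import (
    ContigSet,
    GeneTemplate,
    InfeasibleTargetError,
    generate_contigs,
    mutate_protein,
    plant_genes,
    shuffle_decoy,
)

from .oracles import orf_oracle


class TestGenerateContigs:
    def test_zero_sd_forces_exact_length(self):
        cs = generate_contigs(1, length_mean=1000, length_sd=0, gc=0.5, seed=7)
        (seq,) = cs.sequences.values()
        assert len(seq) == 1000

    def test_pooled_gc_concentrates_near_target(self):
        cs = generate_contigs(100, length_mean=1000, length_sd=100, gc=0.40, seed=1)
        pooled = "".join(cs.sequences.values())
        gc = (pooled.count("G") + pooled.count("C")) / len(pooled)
        assert 0.37 <= gc <= 0.43

    def test_seeded_determinism_is_byte_identical(self, tmp_path):
        paths = []
        for run in range(2):
            cs = generate_contigs(10, 800, 150, 0.5, seed=3)
            p = tmp_path / f"run{run}.fna"
            cs.to_fasta(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    @pytest.mark.parametrize("kwargs", [
        dict(n=0), dict(n=5, gc=0.0), dict(n=5, gc=1.2), dict(n=5, length_mean=100),
    ])
    def test_degenerate_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_contigs(**{"length_mean": 1000, "length_sd": 0, "gc": 0.5, "seed": 0, **kwargs})


class TestMutateProtein:
    def test_identity_100_returns_template(self, templates):
        assert mutate_protein(templates[0], 100.0, seed=5) == templates[0].protein

    def test_measured_identity_tracks_target(self, templates):
        mut = mutate_protein(templates[0], 80.0, seed=1)
        assert 78.0 <= global_identity(templates[0].protein, mut) <= 82.0

    def test_identity_control_across_targets(self, templates):
        for target in (30.0, 45.0, 60.0, 75.0, 90.0):
            for s in range(3):
                mut = mutate_protein(templates[1], target, seed=s)
                measured = global_identity(templates[1].protein, mut)
                assert abs(measured - target) <= 2.0

    def test_protected_motifs_survive_mutation(self, templates):
        tpl = templates[0]
        mut = mutate_protein(tpl, 30.0, seed=9)
        for pos in tpl.protected_positions():
            assert mut[pos] == tpl.protein[pos]

    def test_target_below_valid_range_rejected(self, templates):
        with pytest.raises(ValueError):
            mutate_protein(templates[0], 5.0, seed=0)

    def test_infeasible_target_when_protection_dominates(self):
        # short template: 16 protected of 60 residues, so 10% identity would
        # need more substitutions than there are unprotected positions
        protein = (
            "MA" + "TGASRGIG" + "A" * 10 + "N" + "A" * 21 + "S" + "A" * 11
            + "Y" + "AAA" + "K" + "A"
        )
        tpl = GeneTemplate("mini", protein, keep_motifs=True)
        with pytest.raises(InfeasibleTargetError):
            mutate_protein(tpl, 10.0, seed=0)


class TestGeneTemplate:
    def test_motif_free_template_rejected_when_protection_requested(self):
        with pytest.raises(ValueError, match="motif|Ser"):
            GeneTemplate("bad", "M" + "A" * 249, keep_motifs=True)

    def test_non_canonical_residues_rejected(self):
        with pytest.raises(ValueError):
            GeneTemplate("bad", "MABZ", keep_motifs=False)

    def test_decoy_shuffle_preserves_composition_only(self, templates):
        decoy = shuffle_decoy(templates[0], seed=4)
        assert decoy != templates[0].protein
        assert sorted(decoy) == sorted(templates[0].protein)
        assert decoy[0] == "M"


class TestPlantGenes:
    def test_minus_strand_slice_is_a_complete_cds(self, small_metagenome):
        from sdrmine.orfs import revcomp, translate

        contigs, truth = small_metagenome
        minus = [t for t in truth if t.strand == "-"]
        assert minus, "fixture should plant on both strands"
        for t in minus:
            cds = revcomp(contigs.sequences[t.contig_id][t.start : t.end])
            assert cds.startswith("ATG")
            aa = translate(cds)
            assert aa.endswith("*") and "*" not in aa[:-1]

    def test_six_frame_scan_recovers_every_truth_record(self, small_metagenome):
        contigs, truth = small_metagenome
        for t in truth:
            oracle = orf_oracle(contigs.sequences[t.contig_id], 200)
            assert any(
                (s, e, st) == (t.start, t.end, t.strand) for s, e, st, _ in oracle
            ), f"{t.gene_id} not recovered by the six-frame oracle"

    def test_orf_mining_round_trip_has_full_sensitivity(self, small_metagenome):
        contigs, truth = small_metagenome
        orfs = find_orfs_multi(contigs.items(), min_len_aa=230)
        coords = {(o.contig_id, o.start, o.end, o.strand) for o in orfs}
        for t in truth:
            assert (t.contig_id, t.start, t.end, t.strand) in coords

    def test_empty_template_list_is_identity(self):
        cs = generate_contigs(3, 600, 0, 0.5, seed=2)
        out, truth = plant_genes(cs, [], [], seed=2)
        assert truth == []
        assert out.sequences == cs.sequences

    def test_no_two_planted_genes_overlap(self, small_metagenome):
        _, truth = small_metagenome
        by_contig: dict[str, list] = {}
        for t in truth:
            by_contig.setdefault(t.contig_id, []).append((t.start, t.end))
        for spans in by_contig.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_planting_is_seed_deterministic(self, templates):
        runs = []
        for _ in range(2):
            cs = generate_contigs(10, 1500, 100, 0.5, seed=8)
            out, truth = plant_genes(cs, templates, [40.0, 70.0], seed=8, n_decoys=2)
            runs.append((out.sequences, tuple(truth)))
        assert runs[0] == runs[1]

    def test_crowded_contigs_raise_placement_error(self, templates):
        from sdrmine.synthetic import PlacementError

        cs = generate_contigs(1, 300, 0, 0.5, seed=1)  # too short for a 250-aa gene
        with pytest.raises(PlacementError):
            plant_genes(cs, templates, [90.0], seed=1)


def test_fasta_round_trip(tmp_path, small_metagenome):
    contigs, _ = small_metagenome
    p = tmp_path / "contigs.fna"
    contigs.to_fasta(p)
    back = ContigSet.from_fasta(p)
    assert back.sequences == contigs.sequences
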