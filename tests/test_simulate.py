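import numpy as np
import pytest
from Bio.Seq import reverse_complement

from plastdeg import phylo
from plastdeg.genestatus import build_degradation_matrix, gene_inventory
from plastdeg.model import GeneCategory
from plastdeg.quadripartite import detect_inverted_repeats, partition_quadripartite
from plastdeg.simulate import (
    EventSpec,
    GeneSpec,
    SpecError,
    SynthSpec,
    apply_events,
    generate_clade,
    generate_reference,
    toy_spec,
)

from ._random_clades import random_spec

P, T, R = GeneCategory.PROTEIN_CODING, GeneCategory.TRNA, GeneCategory.RRNA


class TestGenerateReference:
    def test_empty_panel_layout_and_detection(self):
        spec = SynthSpec(seed=1, lsc_len=5000, ir_len=2000, ssc_len=1000)
        rec, truth = generate_reference(spec)
        assert len(rec.sequence) == 10_000
        irb, ira = detect_inverted_repeats(rec.sequence, 500)
        assert (irb, ira) == ((5000, 7000), (8000, 10000))

    def test_ira_is_reverse_complement_of_irb(self):
        spec = toy_spec(3)
        rec, _ = generate_reference(spec)
        l, r, s = spec.lsc_len, spec.ir_len, spec.ssc_len
        irb = rec.sequence[l : l + r]
        ira = rec.sequence[l + r + s :]
        assert ira == reverse_complement(irb)

    def test_same_seed_is_byte_identical(self):
        a, _ = generate_reference(toy_spec(7))
        b, _ = generate_reference(toy_spec(7))
        assert a.sequence == b.sequence
        assert a.features == b.features

    def test_different_seed_differs(self):
        a, _ = generate_reference(toy_spec(7))
        b, _ = generate_reference(toy_spec(8))
        assert a.sequence != b.sequence

    def test_gc_targets_hit_within_two_points_on_large_regions(self):
        spec = SynthSpec(
            seed=5, lsc_len=8000, ir_len=5000, ssc_len=5000,
            gc={"LSC": 30.0, "IR": 43.0, "SSC": 31.0},
        )
        rec, _ = generate_reference(spec)
        from plastdeg.quadripartite import gc_percent

        l, r, s = spec.lsc_len, spec.ir_len, spec.ssc_len
        assert gc_percent(rec.sequence[:l]) == pytest.approx(30.0, abs=2.0)
        assert gc_percent(rec.sequence[l : l + r]) == pytest.approx(43.0, abs=2.0)
        assert gc_percent(rec.sequence[l + r : l + r + s]) == pytest.approx(31.0, abs=2.0)

    def test_protein_genes_have_clean_reading_frames(self):
        rec, _ = generate_reference(toy_spec(11))
        stops = {"TAA", "TAG", "TGA"}
        for f in rec.features:
            if f.category is not P:
                continue
            cds = f.spliced(rec.sequence)
            assert cds.startswith("ATG")
            assert cds[-3:] in stops
            internal = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
            assert not any(c in stops for c in internal)

    def test_panel_overflow_rejected(self):
        spec = SynthSpec(
            seed=0, lsc_len=300, ir_len=200, ssc_len=200,
            gene_panel=[GeneSpec("rbcL", P, 600, "LSC", "+")],
        )
        with pytest.raises(SpecError, match="overflow"):
            generate_reference(spec)

    def test_ssc_longer_than_lsc_rejected(self):
        with pytest.raises(SpecError):
            SynthSpec(seed=0, lsc_len=1000, ir_len=500, ssc_len=2000)


class TestApplyEvents:
    def test_no_events_is_identity(self):
        spec = toy_spec(4)
        rec, _ = generate_reference(spec)
        rng = np.random.default_rng(0)
        out, bounds, status = apply_events(
            rec, [], (spec.lsc_len, spec.ir_len, spec.ssc_len), rng
        )
        assert out.sequence == rec.sequence
        assert bounds == (spec.lsc_len, spec.ir_len, spec.ssc_len)
        assert set(status.values()) == {"F"}

    def test_ir_gene_deletion_removes_both_copies(self):
        spec = toy_spec(4)
        rec, _ = generate_reference(spec)
        ndhB = next(f for f in rec.features if f.gene_name == "ndhB")
        rng = np.random.default_rng(0)
        out, (l, r, s), status = apply_events(
            rec, [EventSpec("sp1", "ndhB", "delete")],
            (spec.lsc_len, spec.ir_len, spec.ssc_len), rng,
        )
        assert status["ndhB"] == "D"
        assert len(out.sequence) == len(rec.sequence) - 2 * ndhB.span_length
        assert r == spec.ir_len - ndhB.span_length
        # the repeat pair is still exact and matches the new bookkeeping
        irb = out.sequence[l : l + r]
        ira = out.sequence[l + r + s :]
        assert ira == reverse_complement(irb)
        assert not any(f.gene_name == "ndhB" for f in out.features)

    @pytest.mark.parametrize("indel", ["del", "ins"])
    def test_ir_gene_frameshift_keeps_repeat_symmetry(self, indel):
        spec = toy_spec(4)
        rec, _ = generate_reference(spec)
        rng = np.random.default_rng(1)
        out, (l, r, s), status = apply_events(
            rec, [EventSpec("sp1", "ndhB", "frameshift", offset=40, indel=indel)],
            (spec.lsc_len, spec.ir_len, spec.ssc_len), rng,
        )
        assert status["ndhB"] == "P"
        irb = out.sequence[l : l + r]
        ira = out.sequence[l + r + s :]
        assert ira == reverse_complement(irb)
        assert r == spec.ir_len + (1 if indel == "ins" else -1)

    def test_premature_stop_rewrites_codon(self):
        spec = toy_spec(4)
        rec, _ = generate_reference(spec)
        rng = np.random.default_rng(2)
        out, _, status = apply_events(
            rec, [EventSpec("sp1", "ccsA", "premature_stop", codon=40)],
            (spec.lsc_len, spec.ir_len, spec.ssc_len), rng,
        )
        assert status["ccsA"] == "P"
        feat = next(f for f in out.features if f.gene_name == "ccsA")
        cds = feat.spliced(out.sequence)
        assert cds[120:123] == "TAA"
        assert len(out.sequence) == len(rec.sequence)

    def test_conflicting_events_rejected(self):
        spec = toy_spec(4)
        rec, _ = generate_reference(spec)
        rng = np.random.default_rng(3)
        with pytest.raises(SpecError, match="conflict"):
            apply_events(
                rec,
                [
                    EventSpec("sp1", "ccsA", "frameshift", offset=10),
                    EventSpec("sp1", "ccsA", "premature_stop", codon=5),
                ],
                (spec.lsc_len, spec.ir_len, spec.ssc_len), rng,
            )

    def test_stop_in_rna_gene_rejected(self):
        spec = toy_spec(4)
        rec, _ = generate_reference(spec)
        rng = np.random.default_rng(3)
        with pytest.raises(SpecError, match="frame"):
            apply_events(
                rec, [EventSpec("sp1", "trnL-UAG", "premature_stop", codon=5)],
                (spec.lsc_len, spec.ir_len, spec.ssc_len), rng,
            )


class TestGenerateClade:
    def test_tip_records_and_truth_shapes(self, toy_clade):
        assert set(toy_clade.records) == {"REF", "sp1", "sp2", "sp3", "sp4", "sp5"}
        assert set(toy_clade.truth.status) == set(toy_clade.records)

    def test_event_below_deletion_rejected(self):
        spec = toy_spec(0)
        spec.events = [
            EventSpec("ingroup", "ndhF", "delete"),
            EventSpec("sp2", "ndhF", "frameshift", offset=10),
        ]
        with pytest.raises(SpecError, match="deletion"):
            generate_clade(spec)

    def test_unknown_branch_rejected(self):
        spec = toy_spec(0)
        spec.events = [EventSpec("nope", "ndhF", "delete")]
        with pytest.raises(SpecError, match="nope"):
            generate_clade(spec)

    def test_unknown_gene_rejected(self):
        with pytest.raises(SpecError, match="unknown gene"):
            SynthSpec(
                seed=0, lsc_len=3000, ir_len=800, ssc_len=700,
                gene_panel=[GeneSpec("rbcL", P, 300, "LSC", "+")],
                events=[EventSpec("sp1", "ndhQ", "delete")],
            )

    def test_partition_truth_tracks_deletions(self, toy_clade, small_config):
        for label, rec in toy_clade.records.items():
            l, r, s = toy_clade.truth.region_lengths[label]
            part = partition_quadripartite(
                rec, detect_inverted_repeats(rec.sequence, small_config.min_ir_length)
            )
            assert (part.lsc_length, part.ir_length, part.ssc_length) == (l, r, s)

    def test_ir_duplicated_gene_counted_once_in_inventory(self, toy_clade):
        inv = gene_inventory(toy_clade.reference)
        names = [f.gene_name for f in toy_clade.reference.features]
        assert names.count("ndhB") == 2  # two annotated copies
        assert inv.total_genes == len(set(names))

    def test_determinism_across_full_pipeline(self):
        a = generate_clade(toy_spec(9))
        b = generate_clade(toy_spec(9))
        assert all(
            a.records[k].sequence == b.records[k].sequence for k in a.records
        )
        assert a.truth.branch_events == b.truth.branch_events


class TestEndToEndRecovery:
    """Planted truth is recovered exactly through the full pipeline."""

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_random_clade_recovery(self, seed, small_config):
        spec = random_spec(seed)
        clade = generate_clade(spec)
        targets = [r for k, r in clade.records.items() if k != "REF"]
        matrix = build_degradation_matrix(clade.reference, targets, small_config)
        for sp, genes in clade.truth.status.items():
            for g, st in genes.items():
                assert matrix.table.at[sp, g] == st, (seed, sp, g)
        em = phylo.reconstruct_events(clade.tree, matrix)
        got = {k: sorted(v) for k, v in em.events.items()}
        want = {k: sorted(v) for k, v in clade.truth.branch_events.items()}
        assert got == want, seed
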