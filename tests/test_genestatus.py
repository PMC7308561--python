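import numpy as np
import pytest
from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from plastdeg.config import RunConfig
from plastdeg.genestatus import (
    GeneState,
    build_degradation_matrix,
    call_gene_status,
    gene_inventory,
    locate_gene,
    reference_gene_panel,
    verify_absence,
)
from plastdeg.model import GeneCategory, GeneFeature, PlastomeRecord

from ._oracles import smith_waterman_score

BASES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}


def rand_seq(rng, n):
    return "".join(rng.choice(BASES, size=n))


def rand_cds(rng, n_codons):
    out = ["ATG"]
    while len(out) < n_codons - 1:
        c = rand_seq(rng, 3)
        if c not in STOPS:
            out.append(c)
    out.append("TAA")
    return "".join(out)


def embed(rng, gene, flank=600, strand="+"):
    """A small circular genome containing the gene verbatim."""
    left, right = rand_seq(rng, flank), rand_seq(rng, flank)
    insert = gene if strand == "+" else reverse_complement(gene)
    seq = left + insert + right
    feat = GeneFeature(
        "g", GeneCategory.PROTEIN_CODING, strand, ((flank, flank + len(gene)),)
    )
    return PlastomeRecord(record_id="t", sequence=seq, features=[feat]), feat


@pytest.fixture(scope="module")
def cfg():
    return RunConfig()


class TestCallGeneStatus:
    def test_identical_gene_is_functional(self, cfg):
        rng = np.random.default_rng(0)
        gene = rand_cds(rng, 100)
        rec, feat = embed(rng, gene)
        call = call_gene_status(rec, feat, gene, cfg)
        assert call.state is GeneState.FUNCTIONAL
        assert call.identity_percent == 100.0
        assert call.coverage_fraction == 1.0
        assert call.frameshift_positions == []
        assert call.premature_stop_positions == []

    def test_single_base_deletion_is_frameshift_pseudogene(self, cfg):
        rng = np.random.default_rng(1)
        gene = rand_cds(rng, 100)
        mutated = gene[:150] + gene[151:]  # 1 not divisible by 3
        rec, feat = embed(rng, mutated)
        call = call_gene_status(rec, feat, gene, cfg)
        assert call.state is GeneState.PSEUDOGENE
        assert len(call.frameshift_positions) == 1

    def test_premature_stop_at_codon_10(self, cfg):
        rng = np.random.default_rng(2)
        gene = rand_cds(rng, 100)
        mutated = gene[:30] + "TAA" + gene[33:]
        rec, feat = embed(rng, mutated)
        call = call_gene_status(rec, feat, gene, cfg)
        assert call.state is GeneState.PSEUDOGENE
        assert 10 in call.premature_stop_positions
        assert call.frameshift_positions == []

    def test_compensating_indels_preserve_frame(self, cfg):
        # +1 then -1 further downstream: net 0 (mod 3), frame restored
        rng = np.random.default_rng(3)
        gene = rand_cds(rng, 200)
        mutated = gene[:90] + "A" + gene[90:300] + gene[301:]
        # the +1/-1 window may create transient in-frame stops; only assert
        # the frameshift judgement here
        rec, feat = embed(rng, mutated)
        call = call_gene_status(rec, feat, gene, cfg)
        assert call.state in (GeneState.FUNCTIONAL, GeneState.PSEUDOGENE)
        if call.state is GeneState.PSEUDOGENE:
            # never called a frameshift: only stop evidence may remain
            assert call.premature_stop_positions
        assert len(call.frameshift_positions) in (0, 2)

    def test_absent_gene_is_deleted(self, cfg):
        rng = np.random.default_rng(4)
        gene = rand_cds(rng, 150)
        target = PlastomeRecord(record_id="t", sequence=rand_seq(rng, 20_000))
        feat = GeneFeature("g", GeneCategory.PROTEIN_CODING, "+", ((0, len(gene)),))
        call = call_gene_status(target, feat, gene, cfg)
        assert call.state is GeneState.DELETED
        assert call.coverage_fraction < cfg.del_coverage

    def test_trna_has_no_frame_concept(self, cfg):
        rng = np.random.default_rng(5)
        gene = rand_seq(rng, 75)
        mutated = gene[:30] + gene[31:]  # indel in a tRNA is not a frameshift
        rec, _ = embed(rng, mutated)
        feat = GeneFeature("trnX-ABC", GeneCategory.TRNA, "+", ((0, 75),))
        call = call_gene_status(rec, feat, gene, cfg)
        assert call.state is GeneState.FUNCTIONAL

    def test_minus_strand_gene_found(self, cfg):
        rng = np.random.default_rng(6)
        gene = rand_cds(rng, 80)
        rec, feat = embed(rng, gene, strand="-")
        call = call_gene_status(rec, feat, gene, cfg)
        assert call.state is GeneState.FUNCTIONAL
        assert call.strand == "-"

    def test_strand_symmetry(self, toy_clade, small_config):
        ref = toy_clade.reference
        target = toy_clade.records["sp2"]
        flipped = target.reverse_complemented()
        for feat in reference_gene_panel(ref)[:4]:
            refseq = feat.spliced(ref.sequence)
            a = call_gene_status(target, feat, refseq, small_config)
            b = call_gene_status(flipped, feat, refseq, small_config)
            assert a.state is b.state

    def test_intact_ir_copy_wins_over_degraded_copy(self, cfg):
        # two copies: one intact, one with a premature stop; best local hit
        # is the intact copy, so the gene stays functional
        rng = np.random.default_rng(7)
        gene = rand_cds(rng, 120)
        broken = gene[:60] + "TAA" + gene[63:]
        seq = rand_seq(rng, 400) + gene + rand_seq(rng, 400) + broken + rand_seq(rng, 400)
        rec = PlastomeRecord(record_id="t", sequence=seq)
        feat = GeneFeature("g", GeneCategory.PROTEIN_CODING, "+", ((0, len(gene)),))
        call = call_gene_status(rec, feat, gene, cfg)
        assert call.state is GeneState.FUNCTIONAL

    def test_short_reference_rejected(self, cfg):
        rec = PlastomeRecord(record_id="t", sequence="ACGT" * 100)
        feat = GeneFeature("g", GeneCategory.TRNA, "+", ((0, 8),))
        with pytest.raises(ValueError, match="seed length"):
            call_gene_status(rec, feat, "ACGTACGT", cfg)


class TestVerifyAbsence:
    def test_verbatim_gene_is_present(self, cfg):
        rng = np.random.default_rng(8)
        gene = rand_cds(rng, 100)
        rec, _ = embed(rng, gene)
        present, hit = verify_absence(gene, rec, cfg)
        assert present
        assert hit["coverage_fraction"] == 1.0

    def test_random_gene_vs_independent_genome_is_absent(self, cfg):
        rng = np.random.default_rng(9)
        gene = rand_seq(rng, 1000)
        target = PlastomeRecord(record_id="t", sequence=rand_seq(rng, 100_000))
        present, hit = verify_absence(gene, target, cfg)
        assert not present
        assert hit["coverage_fraction"] < cfg.del_coverage

    def test_truncated_gene_above_coverage_threshold_is_present(self, cfg):
        # 30% of the 3' end deleted: remaining coverage 0.7 >= 0.3
        rng = np.random.default_rng(10)
        gene = rand_cds(rng, 200)
        kept = gene[: int(len(gene) * 0.7)]
        rec, _ = embed(rng, kept)
        present, hit = verify_absence(gene, rec, cfg)
        assert present
        assert 0.65 <= hit["coverage_fraction"] <= 0.75

    def test_deleted_calls_are_confirmed_absent(self, toy_clade, toy_matrix, small_config):
        ref = toy_clade.reference
        panel = {f.gene_name: f for f in reference_gene_panel(ref)}
        for (sp, gene), call in toy_matrix.calls.items():
            if call.state is GeneState.DELETED:
                refseq = panel[gene].spliced(ref.sequence)
                present, _ = verify_absence(refseq, toy_clade.records[sp], small_config)
                assert not present


class TestAlignerAgainstOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_local_score_matches_quadratic_oracle(self, seed, cfg):
        rng = np.random.default_rng(seed)
        q = rand_seq(rng, int(rng.integers(20, 60)))
        t = rand_seq(rng, int(rng.integers(100, 400)))
        if rng.random() < 0.5:  # plant a mutated copy
            pos = int(rng.integers(0, len(t) - len(q)))
            mutated = list(q)
            for _ in range(int(rng.integers(0, 4))):
                mutated[int(rng.integers(len(mutated)))] = str(
                    rng.choice(BASES)
                )
            t = t[:pos] + "".join(mutated) + t[pos + len(q):]
        al = PairwiseAligner()
        al.mode = "local"
        al.match_score = cfg.match
        al.mismatch_score = cfg.mismatch
        al.open_gap_score = cfg.gap_open
        al.extend_gap_score = cfg.gap_extend
        assert al.align(t, q).score == smith_waterman_score(
            q, t, cfg.match, cfg.mismatch, cfg.gap_open, cfg.gap_extend
        )


def make_features(*specs):
    out = []
    for name, cat, start, length, pseudo in specs:
        out.append(
            GeneFeature(name, cat, "+", ((start, start + length),), pseudo_flag=pseudo)
        )
    return out


class TestInventory:
    P, T, R = GeneCategory.PROTEIN_CODING, GeneCategory.TRNA, GeneCategory.RRNA

    def test_empty_record_all_zero(self):
        rec = PlastomeRecord(record_id="r", sequence="ACGT" * 100)
        inv = gene_inventory(rec)
        assert inv.total_genes == inv.functional_genes == inv.pseudogenes == 0

    def test_ir_duplicates_counted_once(self):
        feats = make_features(
            ("rrn16", self.R, 0, 50, False), ("rrn16", self.R, 200, 50, False)
        )
        rec = PlastomeRecord(record_id="r", sequence="ACGT" * 100, features=feats)
        inv = gene_inventory(rec)
        assert inv.total_genes == 1
        assert inv.rRNA == 1

    def test_pseudo_only_if_every_copy_flagged(self):
        feats = make_features(
            ("ndhB", self.P, 0, 60, True), ("ndhB", self.P, 200, 60, False)
        )
        rec = PlastomeRecord(record_id="r", sequence="ACGT" * 100, features=feats)
        inv = gene_inventory(rec)
        assert inv.pseudogenes == 0
        assert inv.protein_coding == 1

    def test_identities_and_deleted_vs_reference_panel(self):
        feats = make_features(
            ("rbcL", self.P, 0, 60, False),
            ("trnV-UAC", self.T, 100, 60, False),
            ("rrn16", self.R, 200, 60, False),
            ("ndhF", self.P, 300, 60, True),
        )
        rec = PlastomeRecord(record_id="r", sequence="ACGT" * 100, features=feats)
        inv = gene_inventory(rec, reference_total=10)
        assert inv.total_genes == 4
        assert inv.functional_genes == 3 == inv.protein_coding + inv.tRNA + inv.rRNA
        assert inv.pseudogenes == 1
        assert inv.deleted == 6
        inv.validate()

    def test_toy_reference_inventory_matches_panel(self, toy_clade):
        inv = gene_inventory(toy_clade.reference)
        assert inv.total_genes == len(toy_clade.truth.gene_panel)
        assert inv.pseudogenes == 0


class TestDegradationMatrix:
    def test_reference_vs_identical_copy_all_functional(self, small_config):
        import plastdeg.simulate as sim

        clade = sim.generate_clade(sim.toy_spec(2))
        twin = sim.replace_record_id(clade.reference, "twin")
        m = build_degradation_matrix(clade.reference, [twin], small_config)
        assert (m.table == "F").all().all()

    def test_toy_clade_matrix_matches_truth(self, toy_clade, toy_matrix):
        for sp, genes in toy_clade.truth.status.items():
            for g, st in genes.items():
                assert toy_matrix.table.at[sp, g] == st, (sp, g)

    def test_duplicate_species_rejected(self, toy_clade, small_config):
        rec = toy_clade.records["sp1"]
        with pytest.raises(ValueError, match="duplicate"):
            build_degradation_matrix(toy_clade.reference, [rec, rec], small_config)

    def test_panel_excludes_pseudo_flagged_reference_genes(self):
        feats = make_features(
            ("rbcL", GeneCategory.PROTEIN_CODING, 0, 60, False),
            ("ndhF", GeneCategory.PROTEIN_CODING, 100, 60, True),
        )
        rec = PlastomeRecord(record_id="r", sequence="ACGT" * 100, features=feats)
        assert [f.gene_name for f in reference_gene_panel(rec)] == ["rbcL"]
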