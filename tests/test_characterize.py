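"""Genomic categories, exon counts, host relations, trimming and Venn
partitions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circdynamics.characterize import (
    cell_specific_sets,
    circ_per_gene,
    classify_genomic_origin,
    classify_host_relation,
    exon_count,
    fraction_single,
    host_representative,
    linear_direction,
    ratio_expression_correlation,
    specific_fractions,
    trim_reads,
)
from circdynamics.core_io import (
    CircCandidate,
    GeneModel,
    GenomeBundle,
    ReadPair,
    Transcript,
)
from circdynamics.simulate import CountSimConfig, simulate_count_tables


def _pc_gene(strand="+"):
    # 4 exons of 100 nt separated by 50 nt introns; CDS confined to the
    # middle two exons so terminal exons are pure UTR
    exons = [(100, 200), (250, 350), (400, 500), (550, 650)]
    tx = Transcript("t1", exons, cds_span=(253, 497))
    return GeneModel("g1", "c1", strand, "protein_coding", [tx])


def _bundle(genes):
    return GenomeBundle({"c1": "A" * 1000}, genes)


class TestGenomicOrigin:
    def test_cds_circle(self):
        b = _bundle([_pc_gene()])
        assert classify_genomic_origin(
            CircCandidate("c1", 250, 500, "+"), b) == "CDS"

    def test_five_prime_utr_plus_strand(self):
        b = _bundle([_pc_gene()])
        assert classify_genomic_origin(
            CircCandidate("c1", 100, 200, "+"), b) == "5UTR"

    def test_three_prime_utr_minus_strand_is_low_coordinate_side(self):
        b = _bundle([_pc_gene(strand="-")])
        assert classify_genomic_origin(
            CircCandidate("c1", 100, 200, "-"), b) == "3UTR"

    def test_lncrna_circle(self):
        g = GeneModel("l1", "c1", "+", "lncRNA",
                      [Transcript("lt1", [(100, 300)])])
        b = _bundle([g])
        assert classify_genomic_origin(
            CircCandidate("c1", 100, 300, "+"), b) == "lncRNA"

    def test_antisense_circle(self):
        b = _bundle([_pc_gene(strand="+")])
        assert classify_genomic_origin(
            CircCandidate("c1", 420, 480, "-"), b) == "antisense"

    def test_intergenic_circle_unannotated(self):
        b = _bundle([_pc_gene()])
        assert classify_genomic_origin(
            CircCandidate("c1", 800, 900, "+"), b) == "unannotated"

    def test_simulated_truth_agreement_and_partition(self, small_sim):
        cfg, bundle, truth, _ = small_sim
        cats = []
        for t in truth.templates:
            c = CircCandidate(t.contig, t.start, t.end, t.strand)
            got = classify_genomic_origin(c, bundle)
            assert got == t.category, t.circ_id
            cats.append(got)
        assert len(cats) == len(truth.templates)  # exactly one category each


class TestExonCount:
    def test_matched_run_counts_exons(self):
        b = _bundle([_pc_gene()])
        assert exon_count(CircCandidate("c1", 250, 500, "+"), b) == 2
        assert exon_count(CircCandidate("c1", 100, 200, "+"), b) == 1

    def test_nonexonic_is_none(self):
        b = _bundle([_pc_gene()])
        assert exon_count(CircCandidate("c1", 800, 900, "+"), b) is None

    def test_simulated_exon_histogram_matches_truth(self, small_sim):
        cfg, bundle, truth, _ = small_sim
        for t in truth.templates:
            if t.gene_id is None:
                continue
            c = CircCandidate(t.contig, t.start, t.end, t.strand)
            assert exon_count(c, bundle) == t.exon_count


class TestCircPerGene:
    def test_histogram_and_fraction_single(self):
        b = _bundle([_pc_gene()])
        circs = [CircCandidate("c1", 250, 500, "+"),
                 CircCandidate("c1", 250, 350, "+")]
        df = circ_per_gene(circs, b)
        assert df.n_circ.tolist() == [2]
        assert fraction_single(df) == 0.0

    def test_empty_set(self):
        df = circ_per_gene([], _bundle([_pc_gene()]))
        assert df.empty and np.isnan(fraction_single(df))

    def test_exact_recovery_on_simulation(self, small_sim):
        cfg, bundle, truth, _ = small_sim
        circs = [CircCandidate(t.contig, t.start, t.end, t.strand)
                 for t in truth.templates]
        df = circ_per_gene(circs, bundle).set_index("gene_id")
        expected = pd.Series([t.gene_id for t in truth.templates
                              if t.gene_id]).value_counts()
        assert df.n_circ.to_dict() == expected.to_dict()


class TestHostRepresentative:
    def _expr(self, norms):
        rows = []
        for cid, per_sample in norms.items():
            for sid, v in per_sample.items():
                rows.append({"feature_id": cid, "feature_kind": "circ",
                             "sample_id": sid, "normalized": v})
        return pd.DataFrame(rows)

    def test_highest_untreated_expression_wins(self):
        expr = self._expr({"a": {"rminus_t0": 30.0},
                           "b": {"rminus_t0": 50.0, "rnaser_t0": 999.0}})
        assert host_representative(["a", "b"], expr) == "b"

    def test_treated_library_is_ignored(self):
        expr = self._expr({"a": {"rminus_t0": 30.0, "rnaser_t0": 999.0},
                           "b": {"rminus_t0": 50.0}})
        assert host_representative(["a", "b"], expr) == "b"

    def test_tie_breaks_to_smallest_id(self):
        expr = self._expr({"b": {"rminus_t0": 50.0},
                           "a": {"rminus_t0": 50.0}})
        assert host_representative(["b", "a"], expr) == "a"

    def test_idempotent_and_order_invariant(self):
        expr = self._expr({"a": {"rminus_t0": 10.0},
                           "b": {"rminus_t24": 20.0},
                           "c": {"rminus_t48": 5.0}})
        r1 = host_representative(["a", "b", "c"], expr)
        r2 = host_representative(["c", "a", "b"], expr)
        assert r1 == r2 == "b"


class TestHostRelation:
    @pytest.mark.parametrize("circ,lin,expected", [
        ("up", "unchanged", "independent"),
        ("down", "unchanged", "independent"),
        ("up", "up", "concordant"),
        ("down", "down", "concordant"),
        ("down", "up", "reciprocal"),
        ("up", "down", "reciprocal"),
        ("unchanged", "up", "both_unchanged"),
        ("unchanged", "unchanged", "both_unchanged"),
    ])
    def test_partition(self, circ, lin, expected):
        assert classify_host_relation(circ, lin) == expected

    def test_linear_direction_two_point_rule(self):
        assert linear_direction(1.6, 1.8) == "up"
        assert linear_direction(0.5, 0.6) == "down"
        assert linear_direction(1.6, 1.2) == "unchanged"

    def test_mostly_independent_on_count_simulation(self):
        """With static host genes, planted circRNA regulation is
        host-independent for the overwhelming majority of circles."""
        cfg = CountSimConfig(seed=19, n_up=30, n_down=30, n_null=40,
                             linear_de=0)
        tabs = simulate_count_tables(cfg)
        lin = tabs["linear"].pivot(index="gene_id", columns="sample_id",
                                   values="linear_reads")
        truth = tabs["truth"].set_index("circ_id")
        relations = []
        for cid, row in truth.iterrows():
            lr = lin.loc[row.gene_id]
            eps = 1.0
            ld = linear_direction(
                (lr.rminus_t24 + eps) / (lr.rminus_t0 + eps),
                (lr.rminus_t48 + eps) / (lr.rminus_t0 + eps))
            relations.append(
                classify_host_relation(row.direction, ld))
        changed = [r for r in relations if r != "both_unchanged"]
        frac_indep = sum(r == "independent" for r in changed) / len(changed)
        assert frac_indep >= 0.9


class TestRatioCorrelation:
    def test_perfectly_inverse_ranks(self):
        host = list(range(1, 21))
        ratios = [1.0 / h for h in host]
        rho, p = ratio_expression_correlation(ratios, host)
        assert rho == pytest.approx(-1.0)

    def test_refuses_small_n(self):
        with pytest.raises(ValueError, match=">= 10"):
            ratio_expression_correlation([1, 2], [3, 4])

    def test_saturating_counts_give_negative_rho(self):
        cfg = CountSimConfig(seed=23, n_up=0, n_down=0, n_null=250,
                             fraction_model="saturating")
        tabs = simulate_count_tables(cfg)
        calls = tabs["calls"].pivot(index="circ_id", columns="sample_id",
                                    values="junction_reads")
        lin = tabs["linear"].pivot(index="gene_id", columns="sample_id",
                                   values="linear_reads")
        gene = tabs["gene"].pivot(index="gene_id", columns="sample_id",
                                  values="gene_reads")
        truth = tabs["truth"]
        # linear coverage is high enough that no pseudocount is needed;
        # a pseudocount would leak a 1/coverage bias into the ratio
        ratios = calls.loc[truth.circ_id, "rminus_t0"].values \
            / lin.loc[truth.gene_id, "rminus_t0"].values
        host = gene.loc[truth.gene_id, "rminus_t0"].values
        rho, _ = ratio_expression_correlation(ratios, host)
        assert rho < -0.3

    def test_constant_fraction_counts_give_null_rho(self):
        cfg = CountSimConfig(seed=23, n_up=0, n_down=0, n_null=250,
                             fraction_model="constant", circ_fraction=0.15)
        tabs = simulate_count_tables(cfg)
        calls = tabs["calls"].pivot(index="circ_id", columns="sample_id",
                                    values="junction_reads")
        lin = tabs["linear"].pivot(index="gene_id", columns="sample_id",
                                   values="linear_reads")
        gene = tabs["gene"].pivot(index="gene_id", columns="sample_id",
                                  values="gene_reads")
        truth = tabs["truth"]
        # linear coverage is high enough that no pseudocount is needed;
        # a pseudocount would leak a 1/coverage bias into the ratio
        ratios = calls.loc[truth.circ_id, "rminus_t0"].values \
            / lin.loc[truth.gene_id, "rminus_t0"].values
        host = gene.loc[truth.gene_id, "rminus_t0"].values
        rho, _ = ratio_expression_correlation(ratios, host)
        assert abs(rho) < 0.1


class TestTrimming:
    def test_three_prime_truncation(self):
        p = ReadPair("r", "A" * 125, "C" * 125, "I" * 125, "J" * 125)
        t = trim_reads([p], 80)[0]
        assert len(t.mate1_seq) == 80 and len(t.mate2_qual) == 80

    def test_identity_at_same_length(self):
        p = ReadPair("r", "A" * 80, "C" * 80, "I" * 80, "I" * 80)
        assert trim_reads([p], 80)[0].mate1_seq == p.mate1_seq

    def test_overlong_target_rejected(self):
        p = ReadPair("r", "A" * 80, "C" * 80, "I" * 80, "I" * 80)
        with pytest.raises(ValueError):
            trim_reads([p], 125)


class TestVenn:
    def test_specific_fraction_example(self):
        sets = {"A": {"c1", "c2", "c3"}, "B": {"c2"}}
        fr = specific_fractions(sets)
        assert fr["A"] == pytest.approx(2 / 3)
        assert fr["B"] == 0.0

    def test_disjoint_sets_fully_specific(self):
        sets = {"A": {"x"}, "B": {"y"}, "C": {"z"}}
        assert all(v == 1.0 for v in specific_fractions(sets).values())

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.dictionaries(st.sampled_from("ABCD"),
                           st.sets(st.integers(0, 30)),
                           min_size=2, max_size=4))
    def test_partition_identity(self, named_sets):
        df = cell_specific_sets(named_sets)
        union = set.union(*named_sets.values())
        assert df["count"].sum() == len(union)
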