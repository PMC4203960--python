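import math

import numpy as np
import pytest

from oracles import (
    fisher_2x2_oracle,
    kendall_tau_b_oracle,
    mann_whitney_exact_p_oracle,
    mann_whitney_u_oracle,
)
from promoscan.reference import reference_table
from promoscan.stats import (
    FrequencyTable,
    compare_frequency_tables,
    correlation_r,
    fisher_exact_2x2,
    fisher_exact_rxc,
    go_enrichment,
    kendall_tau_b,
    mann_whitney_z,
    motif_groups,
    prune_minor_motifs,
)


class TestPrune:
    def _table(self, n, base=100):
        return FrequencyTable.from_counts(
            {f"M{i:02d}": base - i for i in range(n)}
        )

    def test_twenty_motifs_drop_two(self):
        keep, vec, _ = prune_minor_motifs(self._table(20))
        assert len(keep) == 18

    def test_nine_motifs_drop_none(self):
        keep, _, _ = prune_minor_motifs(self._table(9))
        assert len(keep) == 9

    def test_absent_motifs_align_to_zero(self):
        ref = reference_table("chicken_promoter")
        duck = reference_table("duck_promoter")
        keep, rvec, aligned = prune_minor_motifs(ref, {"duck": duck})
        dv = dict(zip(keep, aligned["duck"]))
        assert dv["CG"] == 0       # missing from the duck table
        assert dv["ACGGC"] == 0
        assert dv["AC"] == 433

    def test_tie_break_alphabetical_deterministic(self):
        tab = FrequencyTable.from_counts(
            {"AC": 5, "AT": 5, "AG": 5, "CG": 5, "CCG": 5,
             "AAT": 9, "AAC": 9, "AGG": 9, "AGC": 9, "ACC": 9})
        keep, _, _ = prune_minor_motifs(tab)
        assert len(keep) == 9
        # the alphabetically last count-5 motif is dropped
        assert "CG" not in keep

    def test_empty_reference(self):
        with pytest.raises(ValueError):
            prune_minor_motifs(FrequencyTable.from_counts({}))


class TestKendall:
    def test_identity_and_reversal(self):
        x = [1, 2, 3, 4, 5]
        assert kendall_tau_b(x, x).tau == pytest.approx(1.0)
        assert kendall_tau_b(x, x[::-1]).tau == pytest.approx(-1.0)

    def test_matches_pair_enumeration_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 7))
            x = rng.integers(0, 4, size=n).tolist()
            y = rng.integers(0, 4, size=n).tolist()
            res = kendall_tau_b(x, y)
            expected = kendall_tau_b_oracle(x, y)
            if math.isnan(expected):
                assert math.isnan(res.tau)
            else:
                assert res.tau == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_flagged(self):
        res = kendall_tau_b([1, 1, 1], [1, 2, 3])
        assert math.isnan(res.tau) and math.isnan(res.p_two_sided)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        a = kendall_tau_b(x, y)
        b = kendall_tau_b(np.exp(x), y**3)
        assert a.tau == pytest.approx(b.tau)


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert correlation_r(x, 2 * x) == pytest.approx(1.0)

    def test_independent_samples_near_zero(self, rng):
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        assert abs(correlation_r(x, y)) < 0.05

    def test_spearman_equals_pearson_on_ranks(self, rng):
        x = rng.permutation(50).astype(float)
        y = rng.permutation(50).astype(float)
        from scipy.stats import rankdata

        assert correlation_r(x, y, "spearman") == pytest.approx(
            correlation_r(rankdata(x), rankdata(y), "pearson")
        )

    def test_zero_variance_flagged(self):
        assert math.isnan(correlation_r([1, 1, 1], [1, 2, 3]))


class TestMannWhitney:
    def test_identical_samples(self):
        res = mann_whitney_z([1, 2, 3], [1, 2, 3])
        assert res.z == 0.0

    def test_disjoint_samples_exact_p(self):
        res = mann_whitney_z([1, 2, 3], [4, 5, 6])
        assert res.U == 0.0
        assert res.p_one_sided == pytest.approx(0.05)  # 1 / C(6,3)
        assert res.method == "exact"

    def test_exact_matches_enumeration_with_ties(self, rng):
        for _ in range(30):
            n, m = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            a = rng.integers(0, 5, size=n).tolist()
            b = rng.integers(0, 5, size=m).tolist()
            res = mann_whitney_z(a, b)
            assert res.U == pytest.approx(mann_whitney_u_oracle(a, b))
            p2, p1 = mann_whitney_exact_p_oracle(a, b)
            assert res.p_two_sided == pytest.approx(p2, abs=1e-12)
            assert res.p_one_sided == pytest.approx(p1, abs=1e-12)

    def test_normal_approx_agrees_with_exact_at_n8(self, rng):
        # tie-free samples of size 8: enumeration vs z-approximation
        for _ in range(10):
            pool = rng.permutation(100)[:16].astype(float)
            a, b = pool[:8].tolist(), pool[8:].tolist()
            res = mann_whitney_z(a, b)
            approx = 2 * __import__("scipy.stats", fromlist=["norm"]).norm.sf(
                abs(res.z))
            assert abs(res.p_two_sided - approx) < 0.02

    def test_sign_convention(self):
        res = mann_whitney_z([10, 11, 12, 13, 14, 15, 16, 17, 18],
                             [1, 2, 3, 4, 5, 6, 7, 8, 9])
        assert res.z > 0  # first sample larger -> positive z

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_z([], [1])


class TestFisher2x2:
    def test_diagonal_table(self):
        # [[2,0],[0,2]]: 3 margin-fixed tables, probs {1/6, 4/6, 1/6}
        _, p2 = fisher_exact_2x2([[2, 0], [0, 2]])
        assert p2 == pytest.approx(1 / 3)

    def test_zero_margin_gives_one(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == (1.0, 1.0)

    def test_oracle_agreement_random_tables(self, rng):
        for _ in range(300):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum() == 0:
                continue
            _, p2 = fisher_exact_2x2(t)
            assert p2 == pytest.approx(fisher_2x2_oracle(t), abs=1e-9)


class TestFisherRxC:
    def test_reduces_to_2x2(self, rng):
        for _ in range(20):
            t = rng.integers(1, 10, size=(2, 2))
            res = fisher_exact_rxc(t)
            _, p2 = fisher_exact_2x2(t)
            assert res.p_two_sided == pytest.approx(p2, abs=1e-9)

    def test_degenerate_skipped(self):
        res = fisher_exact_rxc([[0, 0, 0], [1, 2, 3]])
        assert res.method == "skipped"
        assert res.p_two_sided is None

    def test_strong_association_small_p(self):
        t = [[30, 0, 0, 0], [0, 10, 10, 10]]
        res = fisher_exact_rxc(t)
        assert res.p_two_sided < 1e-3

    def test_exact_3x3_against_r_style_small_table(self):
        # independence-ish 3x3: p must be in (0, 1] and exact
        res = fisher_exact_rxc([[3, 2, 1], [2, 3, 2], [1, 2, 3]])
        assert res.method == "exact"
        assert 0 < res.p_two_sided <= 1

    def test_null_p_roughly_uniform(self, rng):
        # multinomial independence 2x4 tables, n = 100
        ps = []
        pr = np.array([0.5, 0.5])
        pc = np.array([0.25, 0.25, 0.25, 0.25])
        cell_p = np.outer(pr, pc).ravel()
        for _ in range(150):
            t = rng.multinomial(100, cell_p).reshape(2, 4)
            res = fisher_exact_rxc(t)
            if res.method == "exact":
                ps.append(res.p_two_sided)
        from scipy.stats import kstest

        stat = kstest(ps, "uniform")
        assert stat.pvalue > 0.01


class TestComparisons:
    def test_reference_species_similarity_ordering(self):
        ref = reference_table("chicken_promoter")
        res_duck = compare_frequency_tables(ref, reference_table("duck_promoter"))
        res_genome = compare_frequency_tables(ref, reference_table("chicken_genome"))
        assert res_duck.r > 0.95
        assert res_duck.r > res_genome.r
        assert res_duck.p_two_sided < 0.001
        assert res_duck.n_motifs_used == 18


class TestEnrichment:
    def _setup(self):
        background = {f"g{i}" for i in range(100)}
        ann = {f"g{i}": {"T1"} for i in range(20)}
        for i in range(100):
            ann.setdefault(f"g{i}", set()).add("T2")
        return background, ann

    def test_group_equals_background_p_one(self):
        background, ann = self._setup()
        groups = {"ALL": set(background)}
        records, _ = go_enrichment(groups, ann, background)
        assert all(r.p == pytest.approx(1.0) for r in records)

    def test_k_zero_p_one(self):
        background, ann = self._setup()
        groups = {"G": {f"g{i}" for i in range(50, 60)}}  # no T1 members
        records, _ = go_enrichment(groups, ann, background)
        rec = next(r for r in records if r.term_id == "T1")
        assert rec.k == 0 and rec.p == 1.0

    def test_enriched_group_flagged(self):
        background, ann = self._setup()
        groups = {"G": {f"g{i}" for i in range(15)}}  # 15/15 have T1
        records, matrix = go_enrichment(groups, ann, background, cutoff=0.01)
        rec = next(r for r in records if r.term_id == "T1")
        assert rec.significant
        # matrix entry is -log10 p
        assert matrix.loc["G", "T1"] == pytest.approx(-math.log10(rec.p))

    def test_one_sided_p_matches_direct_hypergeometric(self):
        from scipy.stats import hypergeom

        background, ann = self._setup()
        groups = {"G": {f"g{i}" for i in range(10, 30)}}
        records, _ = go_enrichment(groups, ann, background)
        rec = next(r for r in records if r.term_id == "T1")
        assert rec.p == pytest.approx(
            hypergeom.sf(rec.k - 1, rec.N, rec.K, rec.n))

    def test_bh_column_present_and_valid(self):
        background, ann = self._setup()
        groups = {"G": {f"g{i}" for i in range(15)}}
        records, _ = go_enrichment(groups, ann, background)
        assert all(r.q_bh is not None and r.q_bh >= r.p - 1e-12 for r in records)

    def test_motif_groups_shape(self):
        g = motif_groups({"a"}, {"b"}, {"c"}, {"d"})
        assert set(g) == {"STR", "PQS", "LCGI", "NCGI"}
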