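"""Mean-expression conservation: transforms, summaries, DE, tau, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import orthoconserve as oc
from orthoconserve.io_formats import KeyingError, ParameterError, ValidationError

from conftest import toy_expression


@pytest.mark.parametrize(
    "tpm,expected", [(0.0, -2.0), (0.75, 0.0), (3.75, 2.0)]
)
def test_log_transform_known_points(tpm, expected):
    assert oc.log_transform(tpm) == pytest.approx(expected)


def test_log_transform_rejects_negative():
    with pytest.raises(ValidationError):
        oc.log_transform(-0.1)


class TestTissueSummary:
    def test_hand_computed_statistics(self):
        em = toy_expression([[1.0, 2.0, 3.0]], ["liver"] * 3)
        s = oc.tissue_summary(em).iloc[0]
        assert s["median_tpm"] == 2.0
        log2 = np.log2(np.array([1, 2, 3]) + 0.25)
        expected_mad = np.median(np.abs(log2 - np.median(log2)))
        assert s["mad_log2"] == pytest.approx(expected_mad)
        assert s["cv"] == pytest.approx(np.std([1, 2, 3], ddof=1) / 2.0)
        assert s["expressed"]

    def test_constant_gene_has_zero_spread(self):
        s = oc.tissue_summary(toy_expression([[2.0, 2.0, 2.0]], ["a"] * 3)).iloc[0]
        assert s["cv"] == 0.0 and s["mad_log2"] == 0.0

    def test_low_median_not_expressed(self):
        s = oc.tissue_summary(toy_expression([[0.05, 0.05]], ["a", "a"])).iloc[0]
        assert not s["expressed"]

    def test_single_sample_tissue_rejected_by_name(self):
        em = toy_expression([[1.0, 2.0, 3.0]], ["a", "a", "lonely"])
        with pytest.raises(ValidationError, match="lonely"):
            oc.tissue_summary(em)


class TestCountExpressed:
    def test_boundary_is_strict(self):
        em = toy_expression([[0.1, 0.1], [0.2, 0.2], [0.0, 0.0]], ["a", "a"])
        s = oc.tissue_summary(em)
        # exactly 0.1 does not count; only the 0.2 gene does
        assert oc.count_expressed(s, "a") == 1

    def test_all_expressed_and_none(self):
        s1 = oc.tissue_summary(toy_expression(np.ones((4, 2)), ["a", "a"]))
        assert oc.count_expressed(s1, "a") == 4
        s0 = oc.tissue_summary(toy_expression(np.zeros((4, 2)), ["a", "a"]))
        assert oc.count_expressed(s0, "a") == 0

    def test_unknown_tissue(self):
        s = oc.tissue_summary(toy_expression(np.ones((2, 2)), ["a", "a"]))
        with pytest.raises(KeyingError):
            oc.count_expressed(s, "b")


class TestSharedWindowFraction:
    def test_identical_rankings_are_fully_shared(self):
        genes = [f"g{i}" for i in range(50)]
        out = oc.shared_window_fraction(genes, genes)
        assert (out["overlap_pct"] == 100.0).all()
        assert out["window_size"].sum() == 50

    def test_reversed_ranking_shares_nothing(self):
        genes = [f"g{i:02d}" for i in range(20)]
        out = oc.shared_window_fraction(genes, genes[::-1])
        assert (out["overlap_pct"] == 0.0).all()

    def test_remainder_genes_dropped(self):
        genes = [f"g{i:02d}" for i in range(23)]
        out = oc.shared_window_fraction(genes, genes)
        assert (out["window_size"] == 2).all()
        assert out["window_size"].sum() == 23 - (23 % 10)

    def test_disjoint_sets_rejected(self):
        with pytest.raises(ValidationError):
            oc.shared_window_fraction(["a", "b"], ["a", "c"])


class TestTau:
    @pytest.mark.parametrize(
        "profile,expected",
        [([5, 5, 5, 5], 0.0), ([7, 0, 0, 0], 1.0), ([1, 0.5], 0.5)],
    )
    def test_known_profiles(self, profile, expected):
        assert oc.tau_score(profile) == pytest.approx(expected)

    def test_all_zero_flagged(self):
        with pytest.raises(ValidationError):
            oc.tau_score([0, 0, 0])

    @settings(deadline=None, max_examples=50)
    @given(
        x=st.lists(st.floats(0, 1e4), min_size=2, max_size=20),
        c=st.floats(1e-3, 1e3),
    )
    def test_bounded_and_scale_invariant(self, x, c):
        arr = np.asarray(x)
        if arr.max() == 0:
            return
        t = oc.tau_score(arr)
        assert 0.0 <= t <= 1.0
        assert oc.tau_score(c * arr) == pytest.approx(t, abs=1e-9)


def _welch_oracle(a, b):
    """Textbook Welch statistic and Satterthwaite df, computed step by step."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / n + vb / m
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / n) ** 2 / (n - 1) + (vb / m) ** 2 / (m - 1))
    return t, 2 * stats.t.sf(abs(t), df)


class TestWelch:
    def test_identical_groups_null(self):
        t, p, deg = oc.welch_ttest(np.array([[4.0, 5.0, 6.0]]), np.array([[4.0, 5.0, 6.0]]))
        assert t[0] == 0.0 and p[0] == pytest.approx(1.0) and not deg[0]

    def test_matches_textbook_oracle(self):
        a = [2.0, 2.1, 1.9, 2.0]
        b = [1.0, 1.1, 0.9, 1.0]
        t, p, _ = oc.welch_ttest(np.array([a]), np.array([b]))
        t0, p0 = _welch_oracle(a, b)
        assert t[0] == pytest.approx(t0)
        assert p[0] == pytest.approx(p0, rel=1e-12)
        # mean difference on this scale is exactly 1 log2 unit
        assert np.mean(a) - np.mean(b) == pytest.approx(1.0)

    def test_degenerate_constant_groups(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, p, deg = oc.welch_ttest(
                np.array([[2.0, 2.0], [1.0, 1.0]]), np.array([[2.0, 2.0], [3.0, 3.0]])
            )
        assert p[0] == 1.0 and t[0] == 0.0
        assert p[1] == np.finfo(float).tiny and np.isinf(t[1])
        assert deg.all()


class TestDifferentialExpression:
    def test_truth_diverged_genes_are_flagged(self, small_bundle):
        expr_a, expr_b, om, truth = small_bundle
        de = oc.differential_expression(
            expr_a.subset_tissue("tissue00"), expr_b.subset_tissue("tissue00"), om
        )
        flagged = de.set_index("gene_a").loc[truth.diverged_gene_ids, "significant"]
        assert flagged.mean() >= 0.9
        # sign of log2fc follows the planted shift direction (A - B scale)
        fc = de.set_index("gene_a")["log2fc"]
        for g, sign in truth.diverged_shift_sign.items():
            assert np.sign(fc[g]) == -np.sign(sign)

    def test_threshold_uses_fold_change_and_fdr(self, small_bundle):
        expr_a, expr_b, om, _ = small_bundle
        de = oc.differential_expression(
            expr_a.subset_tissue("tissue01"), expr_b.subset_tissue("tissue01"), om
        )
        sig = de[de["significant"]]
        assert (sig["fdr"] < 0.05).all()
        assert (sig["log2fc"].abs() > np.log2(1.2)).all()


class TestTissueSpecificDE:
    def test_planted_tissue_specific_gene_detected(self):
        rng = np.random.default_rng(5)
        hits = 0
        for rep in range(10):
            base = rng.normal(2.0, 0.3, size=(30, 40))
            tissues = ["target"] * 10 + ["rest1"] * 15 + ["rest2"] * 15
            base[0, :10] += 4.0  # gene 0 elevated only in target (log2 units)
            em = toy_expression(np.exp2(base) - 0.25, tissues)
            out = oc.tissue_specific_de(em, "target").set_index("gene_id")
            hits += bool(out.loc["g0", "significant"])
            assert not out.loc["g1", "significant"]  # flat gene
        assert hits >= 9  # >= ~95% detection across seeds

    def test_gene_elevated_elsewhere_not_flagged_for_target(self):
        rng = np.random.default_rng(6)
        base = rng.normal(2.0, 0.3, size=(5, 30))
        tissues = ["target"] * 10 + ["other"] * 10 + ["rest"] * 10
        base[0, 10:20] += 4.0  # elevated in 'other', not 'target'
        em = toy_expression(np.exp2(base) - 0.25, tissues)
        out = oc.tissue_specific_de(em, "target").set_index("gene_id")
        assert not out.loc["g0", "significant"]


def _bh_oracle(p):
    """Step-up BH computed literally from the definition."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_known_vectors(self):
        assert oc.bh_fdr([0.05]) == pytest.approx([0.05])
        np.testing.assert_allclose(oc.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_monotone_on_sorted_input(self):
        p = np.sort(np.random.default_rng(0).uniform(size=100))
        assert (np.diff(oc.bh_fdr(p)) >= -1e-12).all()

    def test_agrees_with_step_up_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(oc.bh_fdr(p), _bh_oracle(p), atol=1e-12)

    def test_domain_checked(self):
        with pytest.raises(ValidationError):
            oc.bh_fdr([0.5, 1.2])


def _complete_linkage_oracle(arr, labels):
    """Naive agglomeration on 1 - Pearson distance with complete linkage."""
    d = 1 - np.corrcoef(arr)
    clusters = {i: {i} for i in range(len(labels))}
    merges = []
    nxt = len(labels)
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if i >= j:
                    continue
                h = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        merges.append((frozenset(clusters[i] | clusters[j]), h))
        clusters[nxt] = clusters.pop(i) | clusters.pop(j)
        nxt += 1
    return merges


class TestClusterTissues:
    def test_identical_profiles_merge_first_at_zero(self):
        prof = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]],
            index=["a", "b", "c"],
        )
        linkage, labels = oc.cluster_tissues(prof)
        assert labels == ["a", "b", "c"]
        assert sorted(linkage[0, :2].astype(int).tolist()) == [0, 1]
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_agglomeration(self):
        rng = np.random.default_rng(3)
        prof = pd.DataFrame(rng.normal(size=(4, 30)), index=["t1", "t2", "t3", "t4"])
        linkage, labels = oc.cluster_tissues(prof)
        oracle = _complete_linkage_oracle(prof.sort_index().to_numpy(), labels)
        # compare merge heights and the member sets formed at each step
        members = {i: {i} for i in range(len(labels))}
        for step, (li, lj, h, _) in enumerate(linkage):
            merged = members[int(li)] | members[int(lj)]
            members[len(labels) + step] = merged
            assert frozenset(merged) == oracle[step][0]
            assert h == pytest.approx(oracle[step][1], abs=1e-12)

    def test_constant_profile_rejected_by_name(self):
        prof = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValidationError, match="flat"):
            oc.cluster_tissues(prof)

    def test_two_tissues_minimum(self):
        with pytest.raises(ParameterError):
            oc.cluster_tissues(pd.DataFrame([[1.0, 2.0]], index=["only"]))
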