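"""In-silico ChIP: pseudobulk formula, correlations, binding scores,
markers, hypergeometric enrichment, interval overlap."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import scmultiome as sm
from scmultiome import insilico_chip as ic


class TestPseudobulk:
    def test_formula_on_single_read(self):
        # one read in a cluster of total 1e6 -> ln(2)
        counts = np.zeros((2, 1))
        counts[0, 0] = 1.0
        counts[1, 0] = 1e6 - 1
        prof = ic.pseudobulk(counts, ["c0"], ["a", "b"])
        assert prof.values.loc["a", "c0"] == pytest.approx(np.log(2.0))

    def test_zero_reads_gives_zero(self):
        counts = np.array([[0.0, 0.0], [5.0, 3.0]])
        prof = ic.pseudobulk(counts, ["c0", "c0"], ["a", "b"])
        assert prof.values.loc["a", "c0"] == 0.0

    def test_depth_ratio_invariance(self):
        counts = np.array([[3.0, 1.0], [2.0, 4.0]])
        p1 = ic.pseudobulk(counts, ["u", "v"], ["a", "b"])
        p2 = ic.pseudobulk(counts * 2, ["u", "v"], ["a", "b"])
        assert np.allclose(p1.values, p2.values)

    def test_degenerate_cluster_named_in_error(self):
        counts = np.array([[1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="empty"):
            ic.pseudobulk(counts, ["ok", "empty"], ["x", "y"])

    def test_assignment_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ic.pseudobulk(np.ones((2, 3)), ["a", "a"], ["x", "y"])


def _profiles(expr_rows, acc_rows, clusters=None):
    clusters = clusters or [f"c{i}" for i in range(len(next(iter(expr_rows.values()))))]
    expr = pd.DataFrame(expr_rows, index=clusters).T
    acc = pd.DataFrame(acc_rows, index=clusters).T
    return expr, acc


class TestCorrelation:
    def test_identical_profiles_correlate_one(self):
        expr, acc = _profiles({"tf": [1, 2, 3, 4]}, {"p1": [1, 2, 3, 4]})
        mm = pd.DataFrame({"peak": ["p1"], "tf": ["tf"], "score": [1.0]})
        r = ic.tf_peak_correlation(expr, acc, "tf", mm)
        assert r.loc["p1"] == pytest.approx(1.0)

    def test_negated_profile_correlates_minus_one(self):
        expr, acc = _profiles({"tf": [1, 2, 3, 4]}, {"p1": [9, 8, 7, 6]})
        mm = pd.DataFrame({"peak": ["p1"], "tf": ["tf"], "score": [1.0]})
        assert ic.tf_peak_correlation(expr, acc, "tf", mm).loc["p1"] == pytest.approx(-1.0)

    def test_constant_peak_gives_zero_by_convention(self):
        expr, acc = _profiles({"tf": [1, 2, 3, 4]}, {"p1": [5, 5, 5, 5]})
        mm = pd.DataFrame({"peak": ["p1"], "tf": ["tf"], "score": [1.0]})
        assert ic.tf_peak_correlation(expr, acc, "tf", mm).loc["p1"] == 0.0

    def test_too_few_clusters_rejected(self):
        expr, acc = _profiles({"tf": [1, 2]}, {"p1": [1, 2]})
        mm = pd.DataFrame({"peak": ["p1"], "tf": ["tf"], "score": [1.0]})
        with pytest.raises(ValueError, match="clusters"):
            ic.tf_peak_correlation(expr, acc, "tf", mm)


class TestBindingScores:
    def _fit(self, corr_values, motif_scores, acc_rows, **kw):
        peaks = list(corr_values)
        expr, acc = _profiles({"tf": [1, 2, 3]}, acc_rows)
        corrs = {"tf": pd.Series(corr_values)}
        mm = pd.DataFrame({"peak": peaks, "tf": "tf", "score": [motif_scores[p] for p in peaks]})
        return ic.binding_scores(corrs, mm, acc, **kw)

    def test_maximal_peak_scores_its_correlation(self):
        res = self._fit(
            {"p1": 1.0, "p2": 0.1},
            {"p1": 10.0, "p2": 1.0},
            {"p1": [5, 6, 7], "p2": [1, 1, 2]},
        )
        row = res.table.set_index("peak")
        assert row.loc["p1", "scaled_product"] == 1.0
        assert row.loc["p1", "score"] == pytest.approx(1.0)
        assert row.loc["p1", "bound"]

    def test_zero_correlation_not_bound(self):
        res = self._fit({"p1": 0.0, "p2": 0.5}, {"p1": 5.0, "p2": 1.0},
                        {"p1": [5, 6, 7], "p2": [1, 1, 2]})
        row = res.table.set_index("peak")
        assert row.loc["p1", "score"] == 0.0
        assert not row.loc["p1", "bound"]

    def test_quarter_score_just_above_threshold_is_bound(self):
        # correlation 0.5 and scaled product 0.5 -> 0.25 > 0.2
        res = self._fit(
            {"p1": 0.5, "p2": 1.0, "p3": 0.0},
            {"p1": 5.0, "p2": 10.0, "p3": 0.0},
            {"p1": [5, 5, 5], "p2": [10, 10, 10], "p3": [0.1, 0.1, 0.1]},
        )
        row = res.table.set_index("peak")
        assert row.loc["p1", "scaled_product"] == pytest.approx(0.25, abs=0.2)
        made = row.loc["p1", "correlation"] * row.loc["p1", "scaled_product"]
        assert row.loc["p1", "score"] == pytest.approx(made)

    def test_single_peak_minmax_defaults_to_one(self):
        res = self._fit({"p1": 0.9}, {"p1": 2.0}, {"p1": [1, 2, 3]})
        assert res.table["scaled_product"].iloc[0] == 1.0

    def test_tf_below_min_bound_flagged_excluded(self):
        res = self._fit({"p1": 1.0, "p2": 0.9}, {"p1": 5.0, "p2": 4.0},
                        {"p1": [5, 6, 7], "p2": [4, 5, 6]}, min_bound=40)
        assert not res.tf_summary.loc["tf", "retained"]
        assert res.tf_summary.loc["tf", "bound_peaks"] == int(res.table["bound"].sum())

    def test_score_bounded_by_correlation(self):
        res = self._fit({"p1": -0.7, "p2": 0.4, "p3": 0.9},
                        {"p1": 3.0, "p2": 8.0, "p3": 1.0},
                        {"p1": [5, 1, 7], "p2": [2, 8, 3], "p3": [1, 1, 2]})
        t = res.table
        assert (t["score"].abs() <= t["correlation"].abs() + 1e-12).all()

    def test_whole_matrix_rescaling_leaves_scores_unchanged(self):
        acc = {"p1": [5, 1, 7], "p2": [2, 8, 3]}
        r1 = self._fit({"p1": 0.8, "p2": 0.3}, {"p1": 3.0, "p2": 8.0}, acc)
        acc_scaled = {k: [x * 11.0 for x in v] for k, v in acc.items()}
        r2 = self._fit({"p1": 0.8, "p2": 0.3}, {"p1": 3.0, "p2": 8.0}, acc_scaled)
        assert np.allclose(r1.table["score"], r2.table["score"])

    def test_per_peak_mode_single_peak_rescaling_invariance(self):
        acc = {"p1": [5, 1, 7], "p2": [2, 8, 3]}
        kw = dict(accessibility_mode="per_peak")
        r1 = self._fit({"p1": 0.8, "p2": 0.3}, {"p1": 3.0, "p2": 8.0}, acc, **kw)
        acc2 = {"p1": [x * 9.0 for x in acc["p1"]], "p2": acc["p2"]}
        r2 = self._fit({"p1": 0.8, "p2": 0.3}, {"p1": 3.0, "p2": 8.0}, acc2, **kw)
        assert np.allclose(r1.table["score"], r2.table["score"])


class TestMarkers:
    def test_identical_groups_yield_no_markers(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(5.0, size=(30, 40)).astype(float)
        groups = np.array(["a", "b"] * 20)
        res = ic.marker_features(X, groups)
        assert not res["marker"].any()

    def test_planted_eightfold_peak_detected(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(4.0, size=(50, 200)).astype(float)
        groups = np.array(["a"] * 100 + ["b"] * 100)
        X[7, :100] = rng.poisson(32.0, size=100)
        res = ic.marker_features(X, groups, feature_names=[f"f{i}" for i in range(50)])
        row = res[(res["group"] == "a") & (res["feature"] == "f7")].iloc[0]
        assert row["marker"] and row["log2fc"] > 2.0

    def test_logfc_gate_blocks_small_effects(self):
        rng = np.random.default_rng(2)
        X = rng.normal(100.0, 1.0, size=(5, 400))
        groups = np.array(["a"] * 200 + ["b"] * 200)
        X[0, :200] += 25.0  # log2(126/101) ~ 0.32 < 0.5, but p tiny
        res = ic.marker_features(X, groups)
        row = res[(res["group"] == "a") & (res["feature"] == 0)].iloc[0]
        assert row["fdr"] < 1e-4 and 0 < row["log2fc"] < 0.5
        assert not row["marker"]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            ic.marker_features(np.ones((3, 4)), ["a"] * 4)


def _hypergeom_exact(k, N, K, n) -> float:
    """Upper-tail P(X >= k) by exact rational enumeration of outcomes."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return float(total)


class TestMotifEnrichment:
    def test_marker_equals_background_is_null(self):
        peaks = [f"p{i}" for i in range(10)]
        mm = pd.DataFrame({"peak": peaks[:4], "tf": "tf1", "score": 1.0})
        res = ic.motif_enrichment(peaks, peaks, mm)
        assert res["fold"].iloc[0] == pytest.approx(1.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_perfect_enrichment_matches_closed_form(self):
        """10 markers all motif-positive out of 10 positives in 100 peaks:
        p = 1 / C(100, 10)."""
        background = [f"p{i}" for i in range(100)]
        markers = background[:10]
        mm = pd.DataFrame({"peak": markers, "tf": "tf1", "score": 1.0})
        res = ic.motif_enrichment(markers, background, mm)
        assert res["p"].iloc[0] == pytest.approx(1.0 / comb(100, 10), rel=1e-9)

    def test_absent_motif_in_markers_near_one(self):
        background = [f"p{i}" for i in range(50)]
        mm = pd.DataFrame({"peak": background[40:], "tf": "tf1", "score": 1.0})
        res = ic.motif_enrichment(background[:10], background, mm)
        assert res["p"].iloc[0] > 0.9

    def test_zero_background_hits_yield_null_fold(self):
        background = [f"p{i}" for i in range(10)]
        mm = pd.DataFrame({"peak": ["absent"], "tf": "tf1", "score": 1.0})
        res = ic.motif_enrichment(background[:3], background, mm)
        assert np.isnan(res["fold"].iloc[0]) and res["p"].iloc[0] == 1.0

    def test_marker_outside_background_rejected(self):
        with pytest.raises(ValueError):
            ic.motif_enrichment(["x"], ["y"], pd.DataFrame(columns=["peak", "tf", "score"]))

    @given(st.data())
    def test_matches_exact_enumeration_small_backgrounds(self, data):
        N = data.draw(st.integers(5, 30))
        n = data.draw(st.integers(1, N))
        K = data.draw(st.integers(0, N))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        background = [f"p{i}" for i in range(N)]
        markers = list(rng.choice(background, size=n, replace=False))
        with_motif = list(rng.choice(background, size=K, replace=False))
        mm = pd.DataFrame({"peak": with_motif, "tf": "tf1", "score": 1.0})
        res = ic.motif_enrichment(markers, background, mm)
        if K == 0:
            assert len(res) == 0  # no motif-bearing TF rows at all
            return
        k = len(set(markers) & set(with_motif))
        assert res["p"].iloc[0] == pytest.approx(_hypergeom_exact(k, N, K, n), abs=1e-12)


def _intervals(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _brute_force_overlaps(a, b, min_overlap):
    out = []
    for i, ra in a.iterrows():
        for j, rb in b.iterrows():
            if ra["chrom"] != rb["chrom"]:
                continue
            ov = min(ra["end"], rb["end"]) - max(ra["start"], rb["start"])
            if ov >= min_overlap:
                out.append((i, j, ov))
    return sorted(out)


class TestOverlap:
    def test_exact_100bp_overlap_reported(self):
        a = _intervals([("chr1", 0, 600)])
        b = _intervals([("chr1", 500, 1100)])
        res = ic.overlap_peaks(a, b, min_overlap=100)
        assert len(res) == 1 and res["overlap"].iloc[0] == 100

    def test_99bp_overlap_not_reported(self):
        a = _intervals([("chr1", 0, 600)])
        b = _intervals([("chr1", 501, 1100)])
        assert len(ic.overlap_peaks(a, b, min_overlap=100)) == 0

    def test_identical_peaks_reported(self):
        a = _intervals([("chr2", 1000, 1600)])
        assert len(ic.overlap_peaks(a, a.copy(), min_overlap=100)) == 1

    def test_different_chromosomes_never_overlap(self):
        a = _intervals([("chr1", 0, 600)])
        b = _intervals([("chr2", 0, 600)])
        assert len(ic.overlap_peaks(a, b)) == 0

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            ic.overlap_peaks(_intervals([("chr1", 600, 600)]), _intervals([("chr1", 0, 600)]))

    def test_agrees_with_brute_force_on_random_intervals(self):
        rng = np.random.default_rng(12)
        def random_set(n):
            chrom = rng.choice(["chr1", "chr2"], size=n)
            start = rng.integers(0, 3000, size=n)
            return _intervals(list(zip(chrom, start, start + rng.integers(50, 700, size=n))))
        a, b = random_set(50), random_set(50)
        got = ic.overlap_peaks(a, b, min_overlap=100)
        got_list = sorted(map(tuple, got.to_numpy()))
        assert got_list == _brute_force_overlaps(a, b, 100)


class TestRecoveryOnSimulatedData:
    def test_planted_links_ranked_above_decoys(self, dataset, truth):
        chip = ic.InSilicoChip(
            dataset.rna_counts, dataset.atac_counts, dataset.motif_matches,
            clusters=truth.celltype_per_cell,
            gene_names=dataset.gene_names, peak_names=dataset.peak_names,
        )
        res = chip.fit()
        from sklearn.metrics import roc_auc_score
        labels = np.array([
            (tf, pk) in truth.bound_pairs for tf, pk in zip(res.table["tf"], res.table["peak"])
        ])
        auroc = roc_auc_score(labels, res.table["score"])
        assert auroc >= 0.85  # small instance; the acceptance test uses the full design
        assert (res.table["score"].abs() <= res.table["correlation"].abs() + 1e-12).all()
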