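"""Phenotypic barcodes, Jaccard/Ward clustering, potency correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from planartox import schema as sc
from planartox.barcode_cluster import (ClusterResult, PhenotypicBarcode,
                                       binarize, binary_distance,
                                       endpoint_class_links, filter_barcode,
                                       jaccard_condensed, rank_and_correlate,
                                       spearman_rho, ward_cluster)
from planartox.bmc import BMCResult, ConcentrationResponse


def make_cr(measure, concentrations, per_conc_values, kind="continuous",
            direction="+"):
    return ConcentrationResponse(measure.label, np.asarray(concentrations),
                                 [np.asarray(v, float) for v in per_conc_values],
                                 kind, direction)


class TestBinarize:
    def setup_method(self):
        self.m = sc.OutcomeMeasure("speed_blue1", sc.ADULT, 7, "+")

    def test_exactly_at_bmr_is_inactive(self):
        cr = make_cr(self.m, [1.0, 10.0], [[50.0] * 8, [60.0] * 8])
        bc = binarize({self.m: cr}, {self.m: 50.0}, "x")
        assert not bc.matrix.loc["x@1", self.m.label]
        assert bc.matrix.loc["x@10", self.m.label]

    def test_all_zero_chemical_row_filtered(self):
        cr = make_cr(self.m, [1.0, 10.0], [[0.0] * 8, [0.0] * 8])
        bc = filter_barcode(binarize({self.m: cr}, {self.m: 50.0}, "x"))
        assert bc.matrix.empty

    def test_negative_direction_uses_flipped_median(self):
        m = sc.OutcomeMeasure("speed_blue1", sc.ADULT, 7, "-")
        cr = make_cr(m, [1.0], [[-80.0] * 8], direction="-")
        bc = binarize({m: cr}, {m: 50.0}, "x")
        assert bc.matrix.loc["x@1", m.label]

    def test_designed_pattern_recovered(self):
        m2 = sc.OutcomeMeasure("resting", sc.ADULT, 7, "+")
        crs = {
            self.m: make_cr(self.m, [1.0, 10.0], [[10.0] * 8, [90.0] * 8]),
            m2: make_cr(m2, [1.0, 10.0], [[0.0] * 8, [5.0] * 8]),
        }
        bc = binarize(crs, {self.m: 50.0, m2: 50.0}, "x")
        assert bc.matrix.loc["x@10", self.m.label]
        assert not bc.matrix.loc["x@10", m2.label]

    def test_full_lethality_rows_recorded(self):
        m = sc.OutcomeMeasure("lethality", sc.ADULT, 7, "+")
        cr = make_cr(m, [1.0, 10.0], [[0] * 24, [1] * 24], kind="binary")
        bc = binarize({m: cr}, {m: 10.0}, "x")
        assert bc.lethal_rows == ["x@10"]


class TestFilterBarcode:
    def barcode(self, mat, lethal=()):
        return PhenotypicBarcode(pd.DataFrame(mat).astype(bool), list(lethal))

    def test_all_inactive_row_removed(self):
        mat = pd.DataFrame([[True, False], [False, False]],
                           index=["a", "b"], columns=["c1", "c2"])
        out = filter_barcode(PhenotypicBarcode(mat))
        assert list(out.matrix.index) == ["a"]
        assert list(out.matrix.columns) == ["c1"]

    def test_column_active_only_in_lethal_row_removed(self):
        mat = pd.DataFrame(
            [[True, True], [True, False]],
            index=["dead", "alive"], columns=["c1", "c2"]).astype(bool)
        out = filter_barcode(PhenotypicBarcode(mat, ["dead"]))
        assert list(out.matrix.columns) == ["c1"]
        assert list(out.matrix.index) == ["alive"]

    def test_fully_active_matrix_unchanged_and_idempotent(self):
        mat = pd.DataFrame(np.ones((3, 4), dtype=bool))
        out = filter_barcode(PhenotypicBarcode(mat))
        pd.testing.assert_frame_equal(out.matrix, mat)
        again = filter_barcode(out)
        pd.testing.assert_frame_equal(again.matrix, out.matrix)


class TestBinaryDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ([1, 1, 0], [1, 1, 0], 0.0),
        ([1, 0, 0], [0, 1, 1], 1.0),
        ([1, 1, 0], [1, 0, 1], 2.0 / 3.0),
    ])
    def test_hand_values(self, a, b, expected):
        assert binary_distance(a, b) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 10 - 1), st.integers(0, 2 ** 10 - 1),
           st.integers(0, 2 ** 10 - 1))
    def test_metric_properties(self, ia, ib, ic):
        to_row = lambda i: np.array([(i >> k) & 1 for k in range(10)], bool)
        a, b, c = map(to_row, (ia, ib, ic))
        dab, dba = binary_distance(a, b), binary_distance(b, a)
        assert dab == dba
        assert binary_distance(a, a) == 0.0
        # Jaccard satisfies the triangle inequality on non-empty rows
        if a.any() and b.any() and c.any():
            assert dab <= binary_distance(a, c) + binary_distance(c, b) + 1e-12

    def test_condensed_matches_pairwise(self, rng):
        mat = rng.uniform(size=(8, 12)) > 0.5
        cond = jaccard_condensed(mat)
        k = 0
        for i in range(7):
            for j in range(i + 1, 8):
                assert cond[k] == pytest.approx(binary_distance(mat[i], mat[j]))
                k += 1


def brute_force_ward(dist):
    """Naive Lance-Williams ward.D2 agglomeration (squared distances)."""
    n = dist.shape[0]
    d2 = dist ** 2
    active = {i: [i] for i in range(n)}
    d = {(i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(active) > 1:
        (i, j), _ = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        ni, nj = len(active[i]), len(active[j])
        merges.append((i, j, np.sqrt(d[(i, j)]), ni + nj))
        new = active.pop(i) + active.pop(j)
        for k in list(active):
            nk = len(active[k])
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            dij = d[(i, j)]
            d[(min(k, next_id), max(k, next_id))] = (
                ((ni + nk) * dik + (nj + nk) * djk - nk * dij)
                / (ni + nj + nk))
        del d[(i, j)]
        active[next_id] = new
        next_id += 1
    return merges


class TestWardCluster:
    def planted(self, rng, n_per=5, p_noise=0.0):
        """Two well-separated activity blocks."""
        rows = {}
        for i in range(n_per):
            rows[f"a{i}"] = [True] * 6 + [False] * 6
            rows[f"b{i}"] = [False] * 6 + [True] * 6
        mat = pd.DataFrame(rows).T
        if p_noise:
            flip = rng.uniform(size=mat.shape) < p_noise
            mat = mat ^ flip
        return PhenotypicBarcode(mat.astype(bool))

    def test_singletons_when_k_equals_n(self, rng):
        bc = self.planted(rng, n_per=2)
        res = ward_cluster(bc, k=4)
        assert len(set(res.labels)) == 4

    def test_planted_two_block_recovery(self, rng):
        bc = self.planted(rng)
        res = ward_cluster(bc, k=2)
        groups = {}
        for row, lab in zip(res.row_ids, res.labels):
            groups.setdefault(row[0], set()).add(lab)
        assert groups["a"] != groups["b"]
        assert len(groups["a"]) == len(groups["b"]) == 1

    def test_row_permutation_invariance(self, rng):
        bc = self.planted(rng, n_per=4, p_noise=0.1)
        perm = rng.permutation(len(bc.matrix))
        shuffled = PhenotypicBarcode(bc.matrix.iloc[perm])
        a = ward_cluster(bc, k=2).assignments().sort_index()
        b = ward_cluster(shuffled, k=2).assignments().sort_index()
        # same partition up to label renaming
        pairs = set(zip(a, b))
        assert len(pairs) == len(set(a))

    def test_merge_heights_nondecreasing(self, rng):
        mat = rng.uniform(size=(12, 9)) > 0.5
        bc = PhenotypicBarcode(pd.DataFrame(mat))
        res = ward_cluster(bc, k=3)
        assert np.all(np.diff(res.linkage[:, 2]) >= -1e-12)

    def test_agrees_with_brute_force_oracle(self, rng):
        # generic (tie-free) dissimilarities: Ward merge heights are only
        # well-defined up to tie order, so the oracle comparison uses
        # continuous random distances
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform
        for trial in range(5):
            n = 7
            cond = rng.uniform(0.2, 1.0, n * (n - 1) // 2)
            merges = brute_force_ward(squareform(cond))
            Z = hierarchy.linkage(cond, method="ward")
            assert np.allclose(sorted(m[2] for m in merges),
                               sorted(Z[:, 2]), atol=1e-9)


class TestEndpointClassLinks:
    def result(self, active=True):
        status = "active" if active else "inactive"
        return BMCResult("m", "+", 10, 1.0, 0.5, 2.0, status, 0.0)

    def test_resting_maps_to_motility_only(self):
        m = sc.OutcomeMeasure("resting", sc.ADULT, 7, "+")
        links = endpoint_class_links([self.result()], [m], "x")
        assert links["endpoint_class"].tolist() == ["Motility"]

    def test_no_active_measures_no_links(self):
        m = sc.OutcomeMeasure("resting", sc.ADULT, 7, "+")
        links = endpoint_class_links([self.result(False)], [m], "x")
        assert links.empty

    def test_blue_speed_day7_links_speed_b(self):
        m = sc.OutcomeMeasure("speed_blue1", sc.ADULT, 7, "-")
        links = endpoint_class_links([self.result()], [m], "x")
        assert links["endpoint_class"].tolist() == ["Speed(B)"]

    def test_monotone_adding_activity_never_removes_links(self):
        m1 = sc.OutcomeMeasure("resting", sc.ADULT, 7, "+")
        m2 = sc.OutcomeMeasure("stickiness", sc.ADULT, 7, "+")
        small = endpoint_class_links([self.result()], [m1], "x")
        big = endpoint_class_links([self.result(), self.result()],
                                   [m1, m2], "x")
        assert set(small["endpoint_class"]) <= set(big["endpoint_class"])


class TestRankAndCorrelate:
    def test_identical_rankings(self):
        pot = {f"c{i}": float(i + 1) for i in range(7)}
        out = rank_and_correlate(pot, dict(pot))
        assert out["spearman_rho"] == pytest.approx(1.0)

    def test_reversed_rankings(self):
        a = {f"c{i}": float(i + 1) for i in range(7)}
        b = {f"c{i}": float(7 - i) for i in range(7)}
        out = rank_and_correlate(a, b)
        assert out["spearman_rho"] == pytest.approx(-1.0)

    def test_sum_d2_10_textbook_case(self):
        # rank vectors differing by sum of squared differences 10:
        # rho = 1 - 60/336 = 0.8214...
        a = {c: float(r) for c, r in zip("abcdefg", [1, 2, 3, 4, 5, 6, 7])}
        b = {c: float(r) for c, r in zip("abcdefg", [3, 2, 1, 4, 5, 7, 6])}
        d2 = sum((ra - rb) ** 2 for ra, rb in zip([1, 2, 3, 4, 5, 6, 7],
                                                  [3, 2, 1, 4, 5, 7, 6]))
        assert d2 == 10
        out = rank_and_correlate(a, b)
        assert out["spearman_rho"] == pytest.approx(1 - 6 * 10 / (7 * 48))
        assert out["spearman_rho"] == pytest.approx(0.8214, abs=5e-4)
        assert 0 < out["p_value"] < 0.05

    def test_exact_p_matches_enumeration_sanity(self):
        # perfect agreement at n=4: only reorderings tie or beat |rho|=1
        a = {c: float(i + 1) for i, c in enumerate("abcd")}
        out = rank_and_correlate(a, dict(a))
        assert out["p_value"] == pytest.approx(2 / 24)

    def test_mismatched_chemical_sets_rejected(self):
        with pytest.raises(ValueError):
            rank_and_correlate({"a": 1.0}, {"b": 1.0})

    def test_agrees_with_scipy_on_large_n(self, rng):
        va = rng.uniform(size=20)
        vb = va + rng.normal(0, 0.3, 20)
        a = {f"c{i}": v for i, v in enumerate(va)}
        b = {f"c{i}": v for i, v in enumerate(vb)}
        out = rank_and_correlate(a, b)
        ref = stats.spearmanr(va, vb)
        assert out["spearman_rho"] == pytest.approx(ref.statistic)
        assert out["p_value"] == pytest.approx(ref.pvalue, rel=0.05)
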