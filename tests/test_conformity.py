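import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromaqc.conformity import (
    BATTERY_MEASURES,
    RatioMatrix,
    SSIMParams,
    conformity_report,
    heatmap_export,
    ratio_matrix,
    reference_ratio_vector,
    similarity_battery,
    ssim_score,
)
from chromaqc.io import PeakTable

NAMES3 = ["peak_1.00", "peak_2.00", "peak_3.00"]


class TestRatioVector:
    def test_elementwise_division(self):
        v = reference_ratio_vector(np.array([2.0, 4.0, 8.0]), NAMES3, "peak_1.00")
        np.testing.assert_allclose(v.ratios, [1.0, 2.0, 4.0])

    def test_scale_invariance(self):
        a = np.array([2.0, 4.0, 8.0])
        v1 = reference_ratio_vector(a, NAMES3, "peak_2.00")
        v2 = reference_ratio_vector(7.3 * a, NAMES3, "peak_2.00")
        np.testing.assert_allclose(v1.ratios, v2.ratios)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            reference_ratio_vector(np.array([0.0, 4.0, 8.0]), NAMES3, "peak_1.00")


def _battery_oracle(x, y, ranges=None):
    """Straight-from-formula re-evaluation, independent of the implementation."""
    import math

    x, y = np.asarray(x, float), np.asarray(y, float)
    sxy, sxx, syy = float(x @ y), float(x @ x), float(y @ y)
    cos = sxy / math.sqrt(sxx * syy)
    r = ranges if ranges is not None else np.maximum(x, y)
    out = {
        "ejaccard": sxy / (sxx + syy - sxy),
        "cosine": cos,
        "edice": 2 * sxy / (sxx + syy),
        "correlation": (
            float(
                np.sum((x - x.mean()) * (y - y.mean()))
                / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            )
            if np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2) > 0
            else (1.0 if np.sum((x - x.mean()) ** 2) == np.sum((y - y.mean()) ** 2) else 0.0)
        ),
        "gower": float(np.mean(1.0 - np.abs(x - y) / r)),
    }
    p, q = x / x.sum(), y / y.sum()
    dist = {
        "bray": np.sum(np.abs(x - y)) / np.sum(x + y),
        "canberra": np.sum(np.abs(x - y) / np.abs(x + y)),
        "chord": math.sqrt(2 * (1 - cos)),
        "divergence": np.sum((x - y) ** 2 / (x + y) ** 2),
        "euclidean": math.sqrt(np.sum((x - y) ** 2)),
        "geodesic": math.acos(cos),
        "hellinger": math.sqrt(np.sum((np.sqrt(p) - np.sqrt(q)) ** 2)),
        "kullback": float(np.sum((p - q) * np.log(p / q))),
        "manhattan": np.sum(np.abs(x - y)),
        "podani": float(
            np.mean(
                [
                    (x[i] - x[j]) * (y[i] - y[j]) < 0
                    for i in range(len(x))
                    for j in range(i + 1, len(x))
                ]
            )
        ),
        "soergel": np.sum(np.abs(x - y)) / np.sum(np.maximum(x, y)),
        "supremum": np.max(np.abs(x - y)),
        "whittaker": 0.5 * np.sum(np.abs(p - q)),
        "bhjattacharyya": math.sqrt(np.sum((np.sqrt(x) - np.sqrt(y)) ** 2)),
    }
    for k, d in dist.items():
        out[k] = 1.0 / (1.0 + d)
    return out


class TestBattery:
    def test_nineteen_measures_reported(self):
        s = similarity_battery(np.array([1.0, 2.0]), np.array([2.0, 1.0]))
        assert list(s.index) == list(BATTERY_MEASURES)
        assert len(s) == 19

    def test_identical_vectors_all_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        s = similarity_battery(x, x.copy())
        np.testing.assert_allclose(s.to_numpy(), 1.0)

    def test_formula_oracle_on_fixed_vectors(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0])
        s = similarity_battery(x, y)
        oracle = _battery_oracle(x, y)
        for name in BATTERY_MEASURES:
            assert s[name] == pytest.approx(oracle[name], abs=1e-12), name

    def test_near_orthogonal_geodesic_closed_form(self):
        # cosine -> 0 gives geodesic distance pi/2, reported as 1/(1+pi/2)
        eps = 1e-9
        s = similarity_battery(np.array([1.0, eps]), np.array([eps, 1.0]))
        assert s["cosine"] == pytest.approx(0.0, abs=1e-6)
        assert s["geodesic"] == pytest.approx(1.0 / (1.0 + np.pi / 2), abs=1e-6)

    def test_scale_invariance_via_ratio_vectors(self, rng):
        areas_ref = rng.uniform(1, 5, 6)
        areas_b = areas_ref * rng.uniform(0.8, 1.2, 6)
        names = [f"peak_{i}.00" for i in range(6)]
        v_ref = reference_ratio_vector(areas_ref, names, names[0])
        v_b1 = reference_ratio_vector(areas_b, names, names[0])
        v_b2 = reference_ratio_vector(3.7 * areas_b, names, names[0])
        s1 = similarity_battery(v_ref, v_b1)
        s2 = similarity_battery(v_ref, v_b2)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy())

    @given(st.integers(0, 1000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_all_outputs_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 10, 5)
        y = rng.uniform(0.1, 10, 5)
        s = similarity_battery(x, y)
        no_corr = s.drop("correlation")  # Pearson may go negative by design
        assert (no_corr >= 0).all() and (no_corr <= 1.0 + 1e-12).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            similarity_battery(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]))


class TestRatioMatrix:
    def test_two_peak_example(self):
        m = ratio_matrix(np.array([2.0, 4.0]), ["a", "b"])
        np.testing.assert_allclose(m.M, [[1.0, 0.5], [2.0, 1.0]])

    def test_diagonal_ones(self, rng):
        m = ratio_matrix(rng.uniform(0.5, 5, 7), [f"p{i}" for i in range(7)])
        np.testing.assert_allclose(np.diag(m.M), 1.0)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_reciprocal_identity(self, seed):
        rng = np.random.default_rng(seed)
        m = ratio_matrix(rng.uniform(0.1, 10, 6), [f"p{i}" for i in range(6)])
        np.testing.assert_allclose(m.M * m.M.T, 1.0, rtol=1e-10)

    def test_zero_area_rejected_by_name(self):
        with pytest.raises(ValueError, match="b"):
            ratio_matrix(np.array([1.0, 0.0]), ["a", "b"])


class TestSsim:
    def test_identity_is_exactly_one(self, rng):
        m = ratio_matrix(rng.uniform(0.5, 5, 8), [f"p{i}" for i in range(8)])
        assert ssim_score(m, m) == 1.0

    def test_symmetry_global_mode(self, rng):
        a = rng.uniform(0.5, 2, (6, 6))
        b = rng.uniform(0.5, 2, (6, 6))
        assert ssim_score(a, b) == pytest.approx(ssim_score(b, a), abs=1e-12)

    def test_constant_offset_decreases_monotonically(self, rng):
        A = rng.uniform(1.0, 3.0, (8, 8))
        scores = [ssim_score(A, A + c) for c in (0.0, 0.2, 0.5, 1.0, 2.0)]
        assert scores[0] == 1.0
        assert all(b < a for a, b in zip(scores[:-1], scores[1:]))

    def test_windowed_matches_skimage(self, rng):
        from skimage.metrics import structural_similarity

        A = rng.uniform(0.5, 2.0, (8, 8))
        B = A * rng.uniform(0.9, 1.1, (8, 8))
        lo, hi = min(A.min(), B.min()), max(A.max(), B.max())
        ref = structural_similarity(
            (A - lo) / (hi - lo), (B - lo) / (hi - lo),
            win_size=7, data_range=1.0, gaussian_weights=False,
        )
        assert ssim_score(A, B, SSIMParams(window=7)) == pytest.approx(ref, abs=1e-6)

    def test_global_matches_skimage_full_window(self, rng):
        from skimage.metrics import structural_similarity

        A = rng.uniform(0.5, 2.0, (9, 9))
        B = A + rng.normal(size=(9, 9)) * 0.1
        lo, hi = min(A.min(), B.min()), max(A.max(), B.max())
        ref = structural_similarity(
            (A - lo) / (hi - lo), (B - lo) / (hi - lo),
            win_size=9, data_range=1.0, gaussian_weights=False,
        )
        assert ssim_score(A, B) == pytest.approx(ref, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim_score(np.ones((3, 3)), np.ones((4, 4)))

    def test_concentration_scale_invariance(self, rng):
        areas = rng.uniform(0.5, 5, 6)
        names = [f"p{i}" for i in range(6)]
        m1 = ratio_matrix(areas, names)
        m2 = ratio_matrix(4.2 * areas, names)  # ratios cancel the scale
        assert ssim_score(m1, m2) == 1.0


class TestHeatmapExport:
    def test_deterministic_png_and_text_twin(self, tmp_path, rng):
        m = ratio_matrix(rng.uniform(0.5, 5, 5), [f"p{i}" for i in range(5)])
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        heatmap_export(m, p1)
        heatmap_export(m, p2)
        assert p1.read_bytes() == p2.read_bytes()
        twin = pd.read_csv(tmp_path / "a.txt", index_col=0)
        np.testing.assert_allclose(twin.to_numpy(), np.round(m.M, 3), atol=5e-4)

    def test_degenerate_1x1(self, tmp_path):
        m = ratio_matrix(np.array([2.0]), ["p0"])
        heatmap_export(m, tmp_path / "one.png")
        assert (tmp_path / "one.png").exists()


class TestConformityReport:
    def _table(self, rng):
        names = [f"peak_{i}.00" for i in range(6)]
        base = rng.uniform(1, 5, 6)
        rows = {
            "reference": base,
            "dup": base.copy(),
            "same": base.copy(),
            "shifted": base * rng.uniform(0.9, 1.1, 6),
        }
        return PeakTable(list(rows), names, np.vstack(list(rows.values())))

    def test_reference_duplicate_scores_one_and_conforms(self, rng):
        table = self._table(rng)
        rep = conformity_report(table, "reference", "peak_0.00", ssim_threshold=0.97)
        dup = rep.loc["dup"]
        assert dup[list(BATTERY_MEASURES)].astype(float).min() == pytest.approx(1.0)
        assert dup["ssim"] == 1.0
        assert dup["flag"] == "conforming"

    def test_identical_batches_identical_rows(self, rng):
        table = self._table(rng)
        rep = conformity_report(table, "reference", "peak_0.00")
        pd.testing.assert_series_equal(
            rep.loc["dup"], rep.loc["same"], check_names=False
        )

    def test_missing_reference_rejected(self, rng):
        table = self._table(rng)
        with pytest.raises(ValueError, match="nope"):
            conformity_report(table, "nope", "peak_0.00")
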