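import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fodfsr import metrics, sh

from oracles import transport_cost_bruteforce, quadrature_variance


def make_peaks(dirs, amps):
    dirs = np.asarray(dirs, dtype=float).reshape(-1, 3)
    amps = np.asarray(amps, dtype=float)
    if len(dirs):
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        order = np.argsort(-amps, kind="stable")
        dirs, amps = dirs[order], amps[order]
    return metrics.PeakSet(dirs, amps)


def random_peaks(rng, n):
    return make_peaks(rng.normal(size=(n, 3)), rng.uniform(0.2, 2.0, size=n))


def lobe_coeffs(direction, design, sharpness=8.0):
    """Full SH coefficients of a smooth antipodal lobe around a direction."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    tess = design.tessellation
    samples = np.exp(sharpness * ((tess.directions @ d) ** 2 - 1.0))
    return sh.fit_sh(samples, design)


@pytest.fixture(scope="module")
def lobe_design(quad_design):
    return quad_design


class TestPeakExtraction:
    def test_single_lobe_found_near_truth(self, peak_design, quad_design):
        c = lobe_coeffs([0, 0, 1], quad_design)
        pk = metrics.peaks_from_sh(c, peak_design)
        assert len(pk) == 1
        assert abs(pk.directions[0] @ [0, 0, 1]) > np.cos(np.radians(4))

    def test_relative_threshold_drops_weak_lobe(self, peak_design, quad_design):
        strong = lobe_coeffs([0, 0, 1], quad_design)
        weak = lobe_coeffs([1, 0, 0], quad_design)
        c = strong + 0.4 * weak
        pk = metrics.peaks_from_sh(c, peak_design, rel_thresh=0.5)
        assert len(pk) == 1
        pk_low = metrics.peaks_from_sh(c, peak_design, rel_thresh=0.3)
        assert len(pk_low) == 2

    def test_min_separation_merges_close_maxima(self, peak_design, quad_design):
        a = lobe_coeffs([0, 0, 1], quad_design)
        b = lobe_coeffs([0, np.sin(np.radians(10)), np.cos(np.radians(10))], quad_design)
        pk = metrics.peaks_from_sh(a + b, peak_design, min_sep=25.0)
        assert len(pk) == 1

    def test_scale_invariance(self, peak_design, quad_design):
        c = lobe_coeffs([1, 1, 0], quad_design) + 0.8 * lobe_coeffs([0, 0, 1], quad_design)
        p1 = metrics.peaks_from_sh(c, peak_design)
        p2 = metrics.peaks_from_sh(5.0 * c, peak_design)
        assert len(p1) == len(p2)
        assert np.allclose(p1.directions, p2.directions)
        assert np.allclose(5.0 * p1.amplitudes, p2.amplitudes)

    def test_nonpositive_fodf_gives_empty_set(self, peak_tess):
        pk = metrics.extract_peaks(np.full(len(peak_tess), -1.0), peak_tess)
        assert len(pk) == 0


class TestAngularEMD:
    def test_identity_is_zero(self):
        p = make_peaks([[0, 0, 1], [1, 0, 0]], [1.0, 0.5])
        assert metrics.angular_emd(p, p) == 0.0

    def test_single_pair_equals_angle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            u, v = rng.normal(size=(2, 3))
            p, q = make_peaks(u, [1.0]), make_peaks(v, [2.0])
            ang = np.degrees(np.arccos(min(1.0, abs((u / np.linalg.norm(u)) @ (v / np.linalg.norm(v))))))
            assert metrics.angular_emd(p, q) == pytest.approx(ang, abs=1e-9)

    def test_equal_mass_split_worked_example(self):
        two = make_peaks([[0, 0, 1], [1, 0, 0]], [1.0, 1.0])
        one = make_peaks([[0, 0, 1]], [3.0])
        assert metrics.angular_emd(two, one) == pytest.approx(45.0)

    def test_empty_set_conventions(self):
        empty = metrics.PeakSet(np.empty((0, 3)), np.empty(0))
        one = make_peaks([[0, 0, 1]], [1.0])
        assert metrics.angular_emd(empty, empty) == 0.0
        assert metrics.angular_emd(empty, one) == 90.0

    def test_antipodal_and_permutation_invariance(self):
        rng = np.random.default_rng(1)
        p = random_peaks(rng, 3)
        q = random_peaks(rng, 2)
        base = metrics.angular_emd(p, q)
        flipped = metrics.PeakSet(p.directions * np.array([[-1], [1], [-1]]),
                                  p.amplitudes)
        assert metrics.angular_emd(flipped, q) == pytest.approx(base, abs=1e-9)

    def test_matches_bruteforce_vertex_enumeration(self):
        """Transport cost equals exhaustive basic-solution enumeration."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = random_peaks(rng, int(rng.integers(1, 4)))
            q = random_peaks(rng, int(rng.integers(1, 4)))
            cost = metrics._angle_deg(p.directions, q.directions)
            expected = transport_cost_bruteforce(cost, p.masses, q.masses)
            assert metrics.angular_emd(p, q) == pytest.approx(expected, abs=1e-6)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(1, 4), st.integers(1, 4), st.integers(1, 4),
           st.integers(0, 10_000))
    def test_metric_axioms(self, na, nb, nc, seed):
        """Symmetry, nonnegativity, 90-degree bound, triangle inequality."""
        rng = np.random.default_rng(seed)
        a, b, c = (random_peaks(rng, n) for n in (na, nb, nc))
        dab = metrics.angular_emd(a, b)
        dba = metrics.angular_emd(b, a)
        assert dab == pytest.approx(dba, abs=1e-8)
        assert 0.0 <= dab <= 90.0 + 1e-9
        dac = metrics.angular_emd(a, c)
        dcb = metrics.angular_emd(c, b)
        assert dab <= dac + dcb + 1e-7


class TestErrorMaps:
    @pytest.fixture()
    def peak_grid(self):
        rng = np.random.default_rng(3)
        vol = np.empty((2, 2, 2), dtype=object)
        for idx in np.ndindex(vol.shape):
            vol[idx] = random_peaks(rng, 2)
        return vol

    def test_identical_volumes_give_zero_map(self, peak_grid):
        emd = metrics.emd_error_map(peak_grid, peak_grid)
        # arccos near 1 leaves sub-microdegree float noise
        assert np.nanmax(emd) < 1e-5

    def test_single_perturbed_voxel(self, peak_grid):
        pred = peak_grid.copy()
        pred[1, 1, 0] = make_peaks([[0, 1, 1]], [1.0])
        emd = metrics.emd_error_map(peak_grid, pred)
        assert (emd > 1e-4).sum() == 1
        assert np.nanmax(emd) <= 90.0

    def test_grid_mismatch_rejected(self, peak_grid):
        with pytest.raises(ValueError):
            metrics.emd_error_map(peak_grid, peak_grid[:1])


class TestBestMethodFraction:
    def test_total_tie_gives_both_one(self):
        m = np.ones((2, 2, 2))
        frac = metrics.best_method_fraction({"a": m, "b": m.copy()},
                                            np.ones_like(m, dtype=bool))
        assert frac == {"a": 1.0, "b": 1.0}

    def test_strict_winner(self):
        a = np.zeros((2, 2, 1))
        b = np.ones((2, 2, 1))
        frac = metrics.best_method_fraction({"a": a, "b": b},
                                            np.ones_like(a, dtype=bool))
        assert frac == {"a": 1.0, "b": 0.0}

    def test_partial_tie_hand_count(self):
        a = np.array([1.0, 1.0, 1.0, 5.0]).reshape(4, 1, 1)
        b = np.array([2.0, 3.0, 4.0, 5.0]).reshape(4, 1, 1)
        frac = metrics.best_method_fraction({"a": a, "b": b},
                                            np.ones_like(a, dtype=bool))
        assert frac["a"] == 1.0
        assert frac["b"] == 0.25
        assert frac["a"] + frac["b"] > 1.0  # ties counted for every method

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            metrics.best_method_fraction(
                {"a": np.ones((2, 2, 2)), "b": np.ones((2, 2, 2))},
                np.zeros((2, 2, 2), dtype=bool))


class TestSHSimilarity:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(4)
        gt = rng.normal(size=(6, 6, 6, 3))
        t = metrics.sh_similarity(gt, gt.copy())
        by = t.set_index(["metric", "coef"]).value
        for c in range(3):
            assert by.loc[("mse", c)] == 0.0
            assert by.loc[("mae", c)] == 0.0
            assert by.loc[("correlation", c)] == pytest.approx(1.0)
            assert by.loc[("ssim", c)] == pytest.approx(1.0)

    def test_constant_shift(self):
        rng = np.random.default_rng(5)
        gt = rng.normal(size=(6, 6, 6, 2))
        t = metrics.sh_similarity(gt, gt + 0.3)
        by = t.set_index(["metric", "coef"]).value
        assert by.loc[("mse", 0)] == pytest.approx(0.09)
        assert by.loc[("correlation", 0)] == pytest.approx(1.0)

    def test_mse_matches_direct_computation(self):
        rng = np.random.default_rng(6)
        gt = rng.normal(size=(10, 10, 10, 1))
        pred = rng.normal(size=(10, 10, 10, 1))
        t = metrics.sh_similarity(gt, pred)
        direct = float(np.mean((pred[..., 0] - gt[..., 0]) ** 2))
        assert t.query("metric == 'mse'").value.iloc[0] == pytest.approx(direct)

    def test_constant_map_correlation_missing(self):
        gt = np.zeros((6, 6, 6, 1))
        pred = np.ones((6, 6, 6, 1))
        t = metrics.sh_similarity(gt, pred)
        assert np.isnan(t.query("metric == 'correlation'").value.iloc[0])

    def test_tissue_grouping(self):
        rng = np.random.default_rng(7)
        gt = rng.normal(size=(6, 6, 6, 1))
        labels = np.zeros((6, 6, 6), dtype=int)
        labels[3:] = 1
        t = metrics.sh_similarity(gt, gt + 0.1, labels=labels,
                                  label_names={0: "wm", 1: "csf"})
        assert set(t.tissue) == {"all", "wm", "csf"}


class TestGeneralizedAnisotropy:
    def test_isotropic_voxel_zero(self):
        assert metrics.generalized_anisotropy(np.zeros(44)) == 0.0

    def test_monotone_in_each_coefficient(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=44) * 0.1
        g0 = metrics.generalized_anisotropy(base)
        for k in (0, 10, 43):
            bumped = base.copy()
            bumped[k] *= 1.5
            assert metrics.generalized_anisotropy(bumped) > g0 or bumped[k] == 0

    def test_matches_dense_quadrature_variance(self, quad, quad_design):
        """Analytic V_Y equals the numerically integrated fODF variance."""
        rng = np.random.default_rng(9)
        for _ in range(100):
            norm = rng.normal(size=44) * rng.uniform(0.02, 0.3)
            vals = sh.evaluate_sh(sh.denormalize_fodf(norm), quad_design)
            v_quad = quadrature_variance(vals, quad.weights)
            assert metrics.generalized_anisotropy(norm) == pytest.approx(
                np.tanh(v_quad), abs=1e-4)

    def test_range(self):
        rng = np.random.default_rng(10)
        g = metrics.generalized_anisotropy(rng.normal(size=(50, 44)))
        assert np.all((g >= 0) & (g < 1))


class TestAveragePeakCount:
    def test_uniform_and_mixed_counts(self):
        vol = np.empty((2, 2, 2), dtype=object)
        rng = np.random.default_rng(11)
        for idx in np.ndindex(vol.shape):
            vol[idx] = random_peaks(rng, 1)
        labels = np.zeros((2, 2, 2), dtype=int)
        assert metrics.average_peak_count(vol, labels) == {"0": 1.0}
        for idx in [(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1)]:
            vol[idx] = random_peaks(rng, 3)
        assert metrics.average_peak_count(vol, labels) == {"0": 2.0}

    def test_hand_count_on_toy_volume(self):
        vol = np.empty((2, 2, 2), dtype=object)
        rng = np.random.default_rng(12)
        counts = [1, 1, 2, 2, 3, 3, 4, 5]
        for idx, n in zip(np.ndindex(vol.shape), counts):
            vol[idx] = random_peaks(rng, n)
        labels = np.zeros((2, 2, 2), dtype=int)
        labels[1] = 1
        out = metrics.average_peak_count(vol, labels, label_names={0: "a", 1: "b"})
        assert out["a"] == pytest.approx(np.mean(counts[:4]))
        assert out["b"] == pytest.approx(np.mean(counts[4:]))
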