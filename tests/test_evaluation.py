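import numpy as np
import pandas as pd
import pytest

from hsisynth.evaluation import (EvalConfig, bootstrap_ci_difference,
                                 class_spectrum, dsc, hierarchical_aggregate,
                                 l1_normalize, nsd, records_frame,
                                 rgb_reconstruction, spectral_agreement)
from hsisynth.hsi_io import HsiCube, LabelLegend, SemanticMask
from hsisynth.phantom import PhantomConfig, make_spectral_library, render_scene


def _mask(labels):
    labels = np.asarray(labels)
    legend = LabelLegend(entries={i: f"c{i}" for i in range(int(labels.max()) + 1)},
                         background_id=0)
    return SemanticMask(labels=labels, legend=legend)


from oracles import brute_dsc, brute_nsd  # noqa: E402


class TestDsc:
    def test_hand_example(self):
        g = _mask([[1, 1], [0, 0]])
        p = _mask([[0, 1], [0, 1]])
        assert dsc(p, g, 1) == pytest.approx(0.5)

    def test_identity_and_disjoint(self):
        m = _mask([[1, 0], [0, 0]])
        assert dsc(m, m, 1) == 1.0
        assert dsc(_mask([[0, 1]]), _mask([[1, 0]]), 1) == 0.0

    def test_undefined_when_class_absent_everywhere(self):
        assert np.isnan(dsc(_mask([[0]]), _mask([[0]]), 1))

    def test_symmetry_and_oracle_equality_on_random_masks(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.random((16, 16)) < 0.4
            g = rng.random((16, 16)) < 0.4
            pm, gm = _mask(p.astype(int)), _mask(g.astype(int))
            v = dsc(pm, gm, 1)
            w = dsc(gm, pm, 1)
            o = brute_dsc(p, g)
            assert v == pytest.approx(w)
            assert (np.isnan(v) and np.isnan(o)) or v == pytest.approx(o)


class TestNsd:
    def test_identical_masks_score_one(self):
        m = _mask([[0, 1, 1], [0, 1, 0], [0, 0, 0]])
        for tol in (0.0, 1.0, 3.0):
            assert nsd(m, m, 1, tol) == 1.0

    def test_far_shift_scores_zero(self):
        g = np.zeros((12, 12), int); g[0, 0] = 1
        p = np.zeros((12, 12), int); p[11, 11] = 1
        assert nsd(_mask(p), _mask(g), 1, tolerance=1.0) == 0.0

    def test_row_fixture_matches_oracle(self):
        g = np.zeros((1, 6), int); g[0, [1, 2]] = 1
        p = np.zeros((1, 6), int); p[0, [3, 4]] = 1
        got = nsd(_mask(p), _mask(g), 1, tolerance=1.0)
        assert got == pytest.approx(brute_nsd(p == 1, g == 1, 1.0))

    @pytest.mark.parametrize("tol", [0.0, 1.0, 2.0])
    def test_oracle_equality_on_random_masks(self, tol):
        rng = np.random.default_rng(7 + int(tol))
        for _ in range(66):
            p = rng.random((16, 16)) < 0.35
            g = rng.random((16, 16)) < 0.35
            v = nsd(_mask(p.astype(int)), _mask(g.astype(int)), 1, tol)
            o = brute_nsd(p, g, tol)
            assert (np.isnan(v) and np.isnan(o)) or v == pytest.approx(o)


class TestSpectra:
    def test_l1_normalize_hand_example(self):
        np.testing.assert_allclose(l1_normalize([2, 2, 4]), [0.25, 0.25, 0.5])
        assert l1_normalize([0.0, 0.0]) is None
        v = l1_normalize(np.random.default_rng(0).uniform(0.1, 1, 8))
        assert np.abs(v).sum() == pytest.approx(1.0)

    def test_noise_free_phantom_recovers_library_exactly(self):
        lib = make_spectral_library(4, 20, seed=3)
        cfg = PhantomConfig(H=24, W=24, C=20, n_organ_classes=2,
                            classes_per_image=(2, 2), sigma_m=0, sigma_a=0,
                            illumination_amplitude=0, seed=0)
        cube, mask = render_scene(lib, cfg, "s0", seed=5)
        for cls in np.unique(mask.labels):
            cs = class_spectrum([(cube, mask)], int(cls))
            np.testing.assert_allclose(cs.mean, l1_normalize(lib.spectra[cls]),
                                       atol=1e-6)

    def test_two_subjects_average_by_hand(self):
        wl = np.linspace(500, 600, 4)
        a = np.array([0.4, 0.3, 0.2, 0.1])
        b = np.array([0.1, 0.2, 0.3, 0.4])
        def flat_cube(spec, subject):
            data = np.tile(spec, (2, 2, 1))
            return HsiCube(data=data, wavelengths=wl, subject_id=subject)
        mask = _mask([[1, 1], [1, 1]])
        ds = [(flat_cube(a, "s1"), mask), (flat_cube(b, "s2"), mask)]
        cs = class_spectrum(ds, 1)
        np.testing.assert_allclose(cs.mean, (a + b) / 2, atol=1e-6)

    def test_single_subject_std_is_zero(self):
        wl = np.linspace(500, 600, 4)
        cube = HsiCube(data=np.ones((2, 2, 4)), wavelengths=wl, subject_id="s1")
        cs = class_spectrum([(cube, _mask([[1, 1], [1, 1]]))], 1)
        np.testing.assert_array_equal(cs.std, np.zeros(4))

    def test_agreement_zero_against_self_and_symmetric(self, small_dataset):
        pairs = [(c, m) for c, m, _ in small_dataset]
        assert spectral_agreement(pairs, pairs, 1) == pytest.approx(0.0, abs=1e-12)
        half_a, half_b = pairs[: len(pairs) // 2], pairs[len(pairs) // 2 :]
        d_ab = spectral_agreement(half_a, half_b, 0)
        d_ba = spectral_agreement(half_b, half_a, 0)
        assert d_ab == pytest.approx(d_ba)

    def test_absent_class_is_undefined(self, small_dataset):
        pairs = [(c, m) for c, m, _ in small_dataset]
        assert spectral_agreement(pairs, pairs, 99) is None


class TestAggregation:
    def test_hand_example(self):
        records = pd.DataFrame({
            "image_id": ["i1", "i2", "i3"],
            "subject_id": ["S1", "S1", "S2"],
            "class_id": [1, 1, 1],
            "metric": ["DSC"] * 3,
            "value": [0.8, 0.6, 1.0],
        })
        agg = hierarchical_aggregate(records)
        assert agg["value"].iloc[0] == pytest.approx(0.85)

    def test_constant_values_invariant_to_image_counts(self):
        rows = []
        for subject, n in [("S1", 10), ("S2", 1), ("S3", 4)]:
            rows += [{"image_id": f"{subject}_{i}", "subject_id": subject,
                      "class_id": 1, "metric": "DSC", "value": 0.7}
                     for i in range(n)]
        agg = hierarchical_aggregate(pd.DataFrame(rows))
        assert agg["value"].iloc[0] == pytest.approx(0.7)

    def test_nan_records_are_excluded_not_zeroed(self):
        df = pd.DataFrame({
            "image_id": ["a", "b"], "subject_id": ["S1", "S1"],
            "class_id": [1, 1], "metric": ["DSC", "DSC"],
            "value": [0.5, np.nan],
        })
        assert hierarchical_aggregate(df)["value"].iloc[0] == pytest.approx(0.5)


def _records(values_by_subject, metric="DSC"):
    rows = []
    for subject, vals in values_by_subject.items():
        for i, v in enumerate(vals):
            rows.append({"image_id": f"{subject}_{i}", "subject_id": subject,
                         "class_id": 1, "metric": metric, "value": v})
    return pd.DataFrame(rows)


class TestBootstrap:
    def test_zero_difference_interval_contains_zero(self):
        rng = np.random.default_rng(1)
        rec = _records({f"S{i}": rng.uniform(0.5, 0.9, 3) for i in range(10)})
        ci = bootstrap_ci_difference(rec, rec, EvalConfig(n_bootstrap=200, seed=0))
        assert ci[0] <= 0.0 <= ci[1]
        assert ci[1] - ci[0] < 1e-12

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        a = _records({f"S{i}": rng.uniform(0.4, 1.0, 2) for i in range(8)})
        b = _records({f"S{i}": rng.uniform(0.4, 1.0, 2) for i in range(8)})
        cfg = EvalConfig(n_bootstrap=300, seed=5)
        assert bootstrap_ci_difference(a, b, cfg) == bootstrap_ci_difference(a, b, cfg)

    def test_interval_width_shrinks_with_subjects(self):
        rng = np.random.default_rng(3)
        def make(n):
            a = _records({f"S{i}": [0.7 + rng.normal(0, 0.05)] for i in range(n)})
            b = _records({f"S{i}": [0.6 + rng.normal(0, 0.05)] for i in range(n)})
            return bootstrap_ci_difference(a, b, EvalConfig(n_bootstrap=400, seed=0))
        lo_small, hi_small = make(5)
        lo_big, hi_big = make(40)
        assert (hi_big - lo_big) < (hi_small - lo_small)

    def test_single_subject_returns_none_with_warning(self):
        rec = _records({"S1": [0.5, 0.6]})
        with pytest.warns(UserWarning):
            assert bootstrap_ci_difference(rec, rec, EvalConfig()) is None


class TestRgbReconstruction:
    def _flat_cube(self, value=1.0, c=50):
        wl = np.linspace(500, 1000, c)
        return HsiCube(data=np.full((3, 3, c), value), wavelengths=wl,
                       subject_id="s")

    def test_spectrally_flat_cube_is_gray(self):
        rgb = rgb_reconstruction(self._flat_cube(0.5))
        np.testing.assert_allclose(rgb[..., 0], rgb[..., 1])
        np.testing.assert_allclose(rgb[..., 1], rgb[..., 2])

    def test_constant_one_cube_maps_to_one(self):
        rgb = rgb_reconstruction(self._flat_cube(1.0))
        np.testing.assert_allclose(rgb, 1.0)

    def test_green_band_energy_dominates_green_channel(self):
        wl = np.linspace(500, 1000, 50)
        data = np.zeros((2, 2, 50))
        data[:, :, (wl >= 540) & (wl <= 570)] = 1.0
        cube = HsiCube(data=data, wavelengths=wl, subject_id="s")
        rgb = rgb_reconstruction(cube)
        assert rgb[0, 0, 1] > rgb[0, 0, 0] and rgb[0, 0, 1] > rgb[0, 0, 2]

    def test_window_outside_axis_rejected(self):
        cube = self._flat_cube()
        from hsisynth.errors import ConfigError
        with pytest.raises(ConfigError):
            rgb_reconstruction(cube, windows={"R": (2000, 2100),
                                              "G": (540, 570), "B": (500, 520)})
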