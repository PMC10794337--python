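"""Generators: determinism, internal consistency, analytic oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from macromorph import synthdata
from macromorph._geometry import DESCRIPTOR_COLUMNS, polygon_descriptors
from macromorph.synthdata import (
    ClassSpec,
    Distribution,
    LayoutError,
    MarkerCoupling,
    couple_marker_to_shape,
    make_bead_series,
    make_scene,
    make_tabular_cohort,
)


def two_specs(n0=30, n1=40, sd=0.0):
    return [
        ClassSpec(0, "round", n0, Distribution(400.0, sd), Distribution(1.2, sd and 0.1)),
        ClassSpec(1, "long", n1, Distribution(700.0, sd), Distribution(2.0, sd and 0.2)),
    ]


class TestPolygonGeometry:
    def test_pure_ellipse_matches_analytic_values(self):
        d = polygon_descriptors(20.0, 10.0, eps=0.0, n_vertices=720)
        assert d["area_um2"][0] == pytest.approx(np.pi * 200, rel=1e-4)
        assert d["major_um"][0] == pytest.approx(40.0, rel=1e-3)
        assert d["minor_um"][0] == pytest.approx(20.0, rel=1e-3)
        assert d["aspect_ratio"][0] == pytest.approx(2.0, rel=1e-3)
        assert d["roundness"][0] == pytest.approx(0.5, rel=1e-3)
        assert d["solidity"][0] == pytest.approx(1.0, abs=1e-6)

    def test_panel_invariants_over_random_shapes(self):
        rng = np.random.default_rng(0)
        d = polygon_descriptors(
            rng.uniform(5, 30, 200),
            rng.uniform(3, 20, 200),
            eps=rng.uniform(0, 0.4, 200),
            lobes=rng.integers(3, 9, 200),
            phase=rng.uniform(0, 2 * np.pi, 200),
        )
        # clip at sampling: minor may exceed major input order; panel uses moments
        assert (d["roundness"] <= 1 + 1e-9).all()
        assert (d["solidity"] <= 1 + 1e-9).all()
        assert (d["circularity"] <= 1 + 1e-9).all()
        assert (d["aspect_ratio"] >= 1 - 1e-9).all()
        assert (d["area_um2"] > 0).all()


class TestTabularCohort:
    def test_degenerate_sd_zero_gives_identical_rows_per_class(self):
        specs = [
            ClassSpec(0, "a", 5, Distribution(400.0), Distribution(1.5), lobes=5),
            ClassSpec(1, "b", 5, Distribution(600.0), Distribution(1.2), lobes=5),
        ]
        tab = make_tabular_cohort(specs, seed=3, donor_sd=0.0)
        for cid in (0, 1):
            sub = tab[tab.class_id == cid][DESCRIPTOR_COLUMNS]
            # phase varies but descriptors of the fixed shape are rotation-invariant
            assert sub.round(9).drop_duplicates().shape[0] == 1

    def test_same_seed_bit_identical(self, class_specs_small):
        a = make_tabular_cohort(class_specs_small, seed=5)
        b = make_tabular_cohort(class_specs_small, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_descriptors_internally_consistent(self, cohort_small):
        t = cohort_small
        np.testing.assert_allclose(t.aspect_ratio, t.major_um / t.minor_um, rtol=1e-9)
        assert (t.roundness <= 1 + 1e-9).all()
        assert (t.solidity <= 1 + 1e-9).all()
        assert (t.major_um >= t.minor_um - 1e-12).all()

    def test_sampled_area_matches_spec_distribution(self):
        # areas are sampled directly; class mean within 3 SE of spec mean
        spec = ClassSpec(0, "a", 2000, Distribution(500.0, 100.0, "lognormal"))
        other = ClassSpec(1, "b", 10, Distribution(300.0))
        tab = make_tabular_cohort([spec, other], seed=1, donor_sd=0.0)
        areas = tab[tab.class_id == 0].area_um2
        assert abs(areas.mean() - 500.0) < 3 * 100.0 / np.sqrt(2000)

    def test_rejects_bad_specs(self):
        with pytest.raises(ValueError, match="at least 2"):
            make_tabular_cohort([two_specs()[0]], seed=0)
        dup = two_specs()
        dup[1] = ClassSpec(0, "dup", 5, Distribution(100.0))
        with pytest.raises(ValueError, match="distinct"):
            make_tabular_cohort(dup, seed=0)
        with pytest.raises(ValueError, match="n_cells"):
            ClassSpec(0, "x", 0, Distribution(100.0))


class TestScene:
    def test_single_clean_ellipse_pixel_count(self):
        spec = ClassSpec(0, "e", 1, Distribution(500.0), Distribution(2.0), lobes=5)
        stack, truth = make_scene([spec], seed=4, shape=(256, 256), pixel_size=1.0, noise_sd=0.0)
        row = truth.cells.iloc[0]
        body = stack[1] > 50  # actin foreground
        expected = np.pi * row.a_px * row.b_px
        assert body.sum() == pytest.approx(expected, rel=0.02)

    def test_empty_scene(self):
        stack, truth = make_scene([], seed=0, shape=(64, 64))
        assert truth.cells.empty
        assert stack.shape == (2, 64, 64)  # nucleus + actin only
        assert stack[1].max() < 30  # background only

    def test_fifty_cells_give_fifty_truth_rows_and_nuclei(self, class_specs_small):
        from skimage.measure import label

        stack, truth = make_scene(
            class_specs_small, seed=8, shape=(1400, 1400), n_cells_per_class=10
        )
        assert len(truth.cells) == 60
        nuclei = label(stack[0] > 90)
        assert nuclei.max() == 60

    def test_pixel_identical_for_same_seed(self, class_specs_small):
        s1, _ = make_scene(class_specs_small, seed=2, shape=(512, 512), n_cells_per_class=2)
        s2, _ = make_scene(class_specs_small, seed=2, shape=(512, 512), n_cells_per_class=2)
        np.testing.assert_array_equal(s1, s2)

    def test_layout_failure_raises(self):
        spec = ClassSpec(0, "big", 40, Distribution(2000.0), Distribution(1.0))
        with pytest.raises(LayoutError):
            make_scene([spec], seed=0, shape=(128, 128), retry_budget=5)


class TestBeadSeries:
    def test_noiseless_arithmetic(self):
        t = make_bead_series(100.0, 50.0, [1.0, 2.0], noise_sd=0.0, seed=0, n_beads=1)
        assert t.intensity.tolist() == [150.0, 250.0]

    def test_fewer_than_two_exposures_rejected(self):
        with pytest.raises(ValueError, match="2 distinct"):
            make_bead_series(10.0, 0.0, [5.0], seed=0)

    def test_noisy_fit_within_three_se(self):
        # Monte-Carlo: OLS slope on generated beads lands within 3 SE of truth
        from macromorph.morphometry import fit_bead_curve

        t = make_bead_series(80.0, 20.0, [10, 20, 40, 80], noise_sd=30.0, seed=5, n_beads=50)
        curve = fit_bead_curve(t)
        x = t.exposure_ms.to_numpy()
        resid_se = 30.0 / np.sqrt(((x - x.mean()) ** 2).sum())
        assert abs(curve.slope - 80.0) < 3 * resid_se


class TestMarkerCoupling:
    def test_linear_noiseless_exact(self, cohort_small):
        c = MarkerCoupling("linear", {"area_um2": 2.0}, intercept=5.0)
        out = couple_marker_to_shape(cohort_small, c, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(out.value, 5.0 + 2.0 * cohort_small.area_um2)

    def test_constant_coupling(self, cohort_small):
        out = couple_marker_to_shape(cohort_small, MarkerCoupling("constant", intercept=3.0), seed=0)
        assert (out.value == 3.0).all()

    def test_monotone_coupling_preserves_ranks(self, cohort_small):
        c = MarkerCoupling("loglinear", {"area_um2": 1.0})
        out = couple_marker_to_shape(cohort_small, c, noise_sd=0.0, seed=0)
        rho = stats.spearmanr(out.value, cohort_small.area_um2).statistic
        assert rho == pytest.approx(1.0)

    def test_unknown_descriptor_rejected(self):
        with pytest.raises(ValueError, match="does not compute"):
            MarkerCoupling("linear", {"perimeter_um3": 1.0})
        with pytest.raises(ValueError, match="unknown coupling kind"):
            MarkerCoupling("quadratic", {})

    def test_noise_share_sets_variance_fraction(self, full_cohort):
        # il10 uses a 5% noise share: realized residual variance ~5% of total
        from macromorph.synthdata import _default_marker_couplings

        coup = _default_marker_couplings("m0")["il10"]
        signal = coup.expected(full_cohort)
        resid = full_cohort.il10_norm - signal
        share = resid.var() / full_cohort.il10_norm.var()
        assert 0.02 < share < 0.09
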