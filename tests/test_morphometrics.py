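"""Morphometric panel and parameter-selection filters."""

import numpy as np
import pytest

import colonymorph as cm
from colonymorph.morphometrics import (
    MorphProfile,
    PANEL_FAMILIES,
    PANEL_NAMES,
    compute_profile,
    filter_correlated,
    filter_high_cv,
    apply_filters,
)
from colonymorph.segment import ColonyObject

from conftest import disk_mask, star_mask


def _colony(mask, image_id="img"):
    return ColonyObject(1, mask, int(mask.sum()), (0.0, 0.0), image_id)


def _image_for(mask, seed=0, level=70.0, bg=100.0, sd=5.0):
    rng = np.random.default_rng(seed)
    img = np.full(mask.shape, bg)
    img[mask] = level + sd * rng.standard_normal(int(mask.sum()))
    return np.clip(img, 0, 255).astype(np.uint8)


@pytest.fixture(scope="module")
def disk_profile():
    mask = disk_mask()
    return compute_profile(_colony(mask), _image_for(mask))


class TestPanel:
    def test_panel_has_120_parameters_in_three_families(self, disk_profile):
        assert len(disk_profile.values) == 120
        assert list(disk_profile.values) == list(PANEL_NAMES)
        fams = set(disk_profile.family_of.values())
        assert fams == {"volume", "shape", "frequency"}

    def test_disk_is_circular_solid_and_spectrally_quiet(self, disk_profile):
        v = disk_profile.values
        assert v["circularity"] >= 0.95
        assert v["solidity"] >= 0.98
        assert v["fourier_high_band"] < 0.01
        assert v["fourier_low_band"] < 0.01
        assert v["curvature_mean"] == pytest.approx(1.0, abs=0.05)
        assert v["area_px"] == pytest.approx(np.pi * 150**2, rel=0.01)

    def test_intensity_scaling_only_moves_volume_intensity_parameters(self):
        mask = disk_mask()
        img = _image_for(mask, sd=4.0)
        half = (img.astype(float) / 2).astype(np.uint8)
        p_full = compute_profile(_colony(mask), img)
        p_half = compute_profile(_colony(mask), half)
        for name in PANEL_NAMES:
            if PANEL_FAMILIES[name] in ("shape", "frequency"):
                assert p_full.values[name] == pytest.approx(
                    p_half.values[name], rel=1e-9, abs=1e-9
                ), name
        assert p_half.values["intensity_mean"] == pytest.approx(
            p_full.values["intensity_mean"] / 2, rel=0.03
        )
        assert p_half.values["intensity_total"] == pytest.approx(
            p_full.values["intensity_total"] / 2, rel=0.03
        )

    def test_star_outline_scores_fibrous_and_less_circular_than_disk(self):
        star = star_mask()
        # equal-area disk
        r_eq = np.sqrt(star.sum() / np.pi)
        disk = disk_mask(radius=r_eq)
        p_star = compute_profile(_colony(star), _image_for(star))
        p_disk = compute_profile(_colony(disk), _image_for(disk))
        assert p_star.values["circularity"] < p_disk.values["circularity"]
        assert p_star.values["fourier_high_band"] > p_disk.values["fourier_high_band"]
        assert (
            p_star.values["fibrous_points_t3"] >= 8 > p_disk.values["fibrous_points_t3"]
        )
        assert p_star.values["radius_peaks_p0.05"] == 8

    def test_half_turn_rotation_leaves_all_parameters_unchanged(self):
        mask = star_mask(amp=0.3, spikes=5)
        img = _image_for(mask, seed=4)
        p = compute_profile(_colony(mask), img)
        p_rot = compute_profile(
            _colony(mask[::-1, ::-1].copy()), img[::-1, ::-1].copy()
        )
        for name in PANEL_NAMES:
            assert p.values[name] == pytest.approx(
                p_rot.values[name], rel=1e-9, abs=1e-9
            ), name

    def test_translation_invariance(self):
        mask = star_mask(amp=0.25, spikes=6)
        img = _image_for(mask, seed=5)
        shifted_mask = np.roll(np.roll(mask, 17, axis=0), -23, axis=1)
        shifted_img = np.roll(np.roll(img, 17, axis=0), -23, axis=1)
        p = compute_profile(_colony(mask), img)
        p_shift = compute_profile(_colony(shifted_mask), shifted_img)
        for name in PANEL_NAMES:
            assert p.values[name] == pytest.approx(
                p_shift.values[name], rel=1e-9, abs=1e-9
            ), name

    def test_scale_covariance_of_documented_parameters(self):
        small = disk_mask(shape=(301, 301), center=(150, 150), radius=70)
        large = disk_mask(shape=(601, 601), center=(300, 300), radius=140)
        p_small = compute_profile(_colony(small), _image_for(small))
        p_large = compute_profile(_colony(large), _image_for(large))
        assert p_large.values["area_px"] == pytest.approx(
            4 * p_small.values["area_px"], rel=0.01
        )
        assert p_large.values["perimeter_px"] == pytest.approx(
            2 * p_small.values["perimeter_px"], rel=0.01
        )
        assert p_large.values["circularity"] == pytest.approx(
            p_small.values["circularity"], rel=0.01
        )

    def test_border_colony_is_flagged(self):
        mask = disk_mask(center=(10.0, 200.0))  # clipped at the top edge
        profile = compute_profile(_colony(mask), _image_for(mask))
        assert profile.border


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _profiles_from_matrix(x, names=None):
    n_obs, n_par = x.shape
    names = names or [f"p{j}" for j in range(n_par)]
    return [
        MorphProfile(
            colony_id=f"c{i}",
            values={names[j]: float(x[i, j]) for j in range(n_par)},
            family_of={names[j]: "shape" for j in range(n_par)},
        )
        for i in range(n_obs)
    ]


class TestCorrelationFilter:
    def test_exact_duplicate_column_is_dropped_with_original_kept(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=20)
        x = np.column_stack([a, a.copy(), rng.normal(size=20)])
        report = filter_correlated(_profiles_from_matrix(x))
        assert report.kept == ["p0", "p2"]
        assert report.dropped_correlated[0][0] == "p1"
        assert report.dropped_correlated[0][1] == "p0"
        assert report.dropped_correlated[0][2] == pytest.approx(1.0)

    def test_weakly_correlated_panel_is_untouched(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 6))  # independent columns, |r| << 0.5
        report = filter_correlated(_profiles_from_matrix(x))
        assert report.kept == [f"p{j}" for j in range(6)]
        assert report.dropped_correlated == []

    def test_constructed_four_parameter_case(self):
        # p0~p1 at r = 0.99 (dropped pair -> one representative),
        # p2~p3 at r = 0.97 (both kept).
        rng = np.random.default_rng(2)
        n = 20000
        z = rng.normal(size=n)
        w = rng.normal(size=n)

        def noisy(base, rho):
            return rho * base + np.sqrt(1 - rho**2) * rng.normal(size=n)

        x = np.column_stack([z, noisy(z, 0.99), w, noisy(w, 0.97)])
        emp01 = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
        emp23 = np.corrcoef(x[:, 2], x[:, 3])[0, 1]
        assert emp01 > 0.98 > emp23  # construction sanity
        report = filter_correlated(_profiles_from_matrix(x))
        assert report.kept == ["p0", "p2", "p3"]
        assert [d for d, _, _ in report.dropped_correlated] == ["p1"]

    def test_zero_variance_parameter_never_triggers_the_filter(self):
        rng = np.random.default_rng(3)
        x = np.column_stack([np.full(10, 7.0), rng.normal(size=10)])
        report = filter_correlated(_profiles_from_matrix(x))
        assert report.kept == ["p0", "p1"]

    def test_greedy_rule_matches_exhaustive_oracle_on_small_panels(self):
        rng = np.random.default_rng(4)
        for trial in range(20):
            n_par = int(rng.integers(3, 11))
            x = rng.normal(size=(30, n_par))
            # add some deliberate near-duplicates
            for _ in range(n_par // 3):
                j, k = rng.choice(n_par, 2, replace=False)
                x[:, k] = x[:, j] + 0.01 * rng.normal(size=30)
            report = filter_correlated(_profiles_from_matrix(x))
            # independent re-evaluation of the greedy rule
            corr = np.corrcoef(x.T)
            kept = []
            for j in range(n_par):
                if all(abs(corr[i, j]) <= 0.98 for i in kept):
                    kept.append(j)
            assert report.kept == [f"p{j}" for j in kept], trial


class TestCVFilter:
    def test_constant_parameter_is_kept(self):
        x = np.column_stack([np.full(10, 5.0), np.arange(10, dtype=float)])
        report = filter_high_cv(_profiles_from_matrix(x))
        assert "p0" in report.kept

    def test_constructed_cv_values(self):
        rng = np.random.default_rng(5)
        n = 4000

        def col(mean, sd):
            c = rng.normal(size=n)
            return mean + sd * (c - c.mean()) / c.std(ddof=1)

        x = np.column_stack([col(10, 4), col(10, 2)])  # CV 40 and CV 20
        report = filter_high_cv(_profiles_from_matrix(x))
        assert report.kept == ["p1"]
        name, cv = report.dropped_high_cv[0]
        assert name == "p0" and cv == pytest.approx(40.0, rel=1e-6)

    def test_positive_scaling_never_changes_the_decision(self):
        rng = np.random.default_rng(6)
        x = np.abs(rng.normal(loc=3, size=(50, 4))) + 0.5
        base = filter_high_cv(_profiles_from_matrix(x))
        for scale in (0.01, 7.3, 1e4):
            scaled = filter_high_cv(_profiles_from_matrix(x * scale))
            assert scaled.kept == base.kept

    def test_zero_mean_parameter_is_dropped(self):
        x = np.column_stack([np.array([-1.0, 1.0, -1.0, 1.0]), np.full(4, 2.0)])
        report = filter_high_cv(_profiles_from_matrix(x))
        assert report.kept == ["p1"]
        assert np.isinf(report.dropped_high_cv[0][1])


class TestComposition:
    def test_correlation_then_cv_composition_is_idempotent(self):
        rng = np.random.default_rng(7)
        n = 200
        z = rng.normal(loc=10, scale=1, size=n)
        x = np.column_stack(
            [
                z,
                z + 0.001 * rng.normal(size=n),  # near-duplicate
                np.abs(rng.normal(loc=2, scale=1.5, size=n)),  # high CV
                rng.normal(loc=50, scale=2, size=n),
            ]
        )
        profiles = _profiles_from_matrix(x)
        report = apply_filters(profiles)
        survivors = [
            MorphProfile(
                colony_id=p.colony_id,
                values={k: p.values[k] for k in report.kept},
                family_of={k: "shape" for k in report.kept},
            )
            for p in profiles
        ]
        again = apply_filters(survivors)
        assert again.kept == report.kept
        assert again.dropped_correlated == [] and again.dropped_high_cv == []

    def test_report_partitions_the_panel(self):
        rng = np.random.default_rng(8)
        x = rng.normal(loc=5, size=(60, 8))
        x[:, 5] = x[:, 2] * 1.0000001
        report = apply_filters(_profiles_from_matrix(x))
        assert sorted(report.kept + report.dropped) == [f"p{j}" for j in range(8)]
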