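import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gosmap.graph import AreaGraph, boundary_distances
from gosmap.gos import (PROFILES, CutoffProfile, GosResult, RelativePosition,
                        apply_cutoffs, cohens_kappa, confusion_matrix,
                        consensus, fraction_spatial_variation, kappa_gos,
                        kurtosis_preservation, quantile_categorize,
                        relative_position_casir, roughness,
                        spatial_excess_kurtosis, variogram, variogram_ratio)
from gosmap.models import AreaData
from gosmap.synthetic import make_lattice

from conftest import make_sample


@pytest.fixture
def path_d(path_graph):
    return boundary_distances(path_graph)


class TestVariogram:
    def test_constant_field_is_zero(self, lattice5):
        d = boundary_distances(lattice5)
        v = variogram(np.full(25, 2.5), d, H=4)
        assert np.allclose(v.gamma_mean, 0.0)

    def test_two_adjacent_areas(self):
        g = AreaGraph.from_edges([("A", "B")])
        v = variogram(np.array([0.0, 2.0]), boundary_distances(g), H=1)
        assert np.allclose(v.gamma_area[:, 0], [2.0, 2.0])
        assert np.isclose(v.gamma_mean[0], 2.0)

    def test_path_lag_two_hand_value(self, path_graph, path_d):
        v = variogram(np.array([0.0, 1.0, 2.0]), path_d, H=2)
        # area A at lag 2 sees B and C: (1 + 4) / (2 * 2)
        assert np.isclose(v.gamma_area[0, 1], 1.25)

    def test_pair_counts_nondecreasing_in_lag(self, lattice5, rng):
        d = boundary_distances(lattice5)
        v = variogram(rng.normal(size=25), d, H=6)
        assert np.all(np.diff(v.counts, axis=1) >= 0)

    def test_identical_surfaces_ratio_one(self, lattice5, rng):
        d = boundary_distances(lattice5)
        z = rng.normal(size=25)
        assert np.isclose(variogram_ratio(z, z, d, H=4), 1.0)

    def test_flat_smoothed_surface_ratio_zero(self, lattice5, rng):
        d = boundary_distances(lattice5)
        z = rng.normal(size=25)
        assert variogram_ratio(np.ones(25), z, d, H=4) == 0.0

    def test_half_slope_affine_surface_gives_quarter(self, lattice5, rng):
        d = boundary_distances(lattice5)
        z = rng.normal(size=25)
        assert np.isclose(variogram_ratio(3.0 + 0.5 * z, z, d, H=4), 0.25)

    @settings(derandomize=True, deadline=None, max_examples=20)
    @given(st.floats(0.05, 3.0), st.floats(-5.0, 5.0))
    def test_affine_surface_ratio_is_slope_squared(self, b, a):
        g = make_lattice(4, 4)
        d = boundary_distances(g)
        z = np.sin(np.arange(16) * 1.7)  # fixed non-constant surface
        assert np.isclose(variogram_ratio(a + b * z, z, d, H=3), b**2, rtol=1e-9)

    def test_all_lags_excluded_is_an_error(self, lattice5):
        d = boundary_distances(lattice5)
        with pytest.raises(ValueError, match="excluded"):
            variogram_ratio(np.ones(25), np.ones(25), d, H=3)


class TestKurtosisRoughness:
    def test_two_point_symmetric_deviations(self):
        # checkerboard on a path: deviations alternate +/- a -> kurtosis -2
        g = make_lattice(1, 6)
        z = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        assert np.isclose(spatial_excess_kurtosis(z, g), -2.0)

    def test_gaussian_field_near_zero(self):
        g = make_lattice(40, 40)
        z = np.random.default_rng(4).standard_normal(1600)
        assert abs(spatial_excess_kurtosis(z, g)) < 0.5

    def test_single_extreme_deviation_dominates(self):
        g = make_lattice(6, 6)
        z = np.zeros(36)
        z[14] = 10.0
        assert spatial_excess_kurtosis(z, g) > 5.0

    def test_constant_field_is_error(self, lattice5):
        with pytest.raises(ValueError, match="undefined|constant"):
            spatial_excess_kurtosis(np.ones(25), lattice5)

    def test_roughness_of_constant_is_zero(self, lattice5):
        assert roughness(np.ones(25), lattice5) == 0.0

    def test_checkerboard_roughness_near_two(self, lattice5):
        i, j = np.divmod(np.arange(25), 5)
        z = np.where((i + j) % 2 == 0, 1.0, -1.0)
        assert abs(roughness(z, lattice5) - 2.0) < 0.1

    def test_roughness_homogeneous_in_scale(self, lattice5, rng):
        z = rng.normal(size=25)
        assert np.isclose(roughness(3.5 * z, lattice5), 3.5 * roughness(z, lattice5))

    def test_identity_preserves_kurtosis(self, lattice5, rng):
        z = rng.normal(size=25) ** 3
        ks, kr, _ = kurtosis_preservation(z, z, lattice5)
        assert ks == kr


class TestKappa:
    def test_perfect_agreement(self):
        a = np.array([0] * 9 + [1] * 9)
        assert cohens_kappa(a, a.copy()) == 1.0

    def test_balanced_perfect_disagreement(self):
        a = np.array([0] * 8 + [1] * 8)
        assert cohens_kappa(a, 1 - a) == -1.0

    def test_confusion_2112_gives_one_third(self):
        a = [0, 0, 0, 1, 1, 1]
        b = [0, 0, 1, 1, 1, 0]
        cm = confusion_matrix(a, b)
        assert cm.c.tolist() == [[2, 1], [1, 2]]
        assert np.isclose(cohens_kappa(a, b), 1.0 / 3.0)

    def test_degenerate_marginals_error(self):
        with pytest.raises(ValueError, match="undefined"):
            cohens_kappa([1, 1, 1], [1, 1, 1])

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(st.lists(st.integers(0, 3), min_size=6, max_size=40))
    def test_self_agreement_and_relabel_invariance(self, cats):
        a = np.array(cats)
        if np.unique(a).size < 2:
            return  # degenerate marginals
        assert np.isclose(cohens_kappa(a, a), 1.0)
        relabel = np.array([7, 5, 9, 2])  # consistent bijective relabelling
        assert np.isclose(cohens_kappa(relabel[a], relabel[a]), 1.0)

    def test_kappa_in_unit_interval(self, rng):
        for _ in range(20):
            a = rng.integers(0, 3, 30)
            b = rng.integers(0, 3, 30)
            try:
                k = cohens_kappa(a, b)
            except ValueError:
                continue
            assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12


class TestQuantileCategorize:
    def test_three_categories_sizes(self):
        z = np.arange(100, dtype=float)
        cats = quantile_categorize(z, (0.25, 0.75))
        assert np.bincount(cats).tolist() == [25, 50, 25]

    def test_constant_vector_single_category(self):
        with pytest.warns(UserWarning, match="degenerate"):
            cats = quantile_categorize(np.ones(10))
        assert np.all(cats == 0)

    def test_ties_at_cut_match_half_open_rule(self, rng):
        z = rng.integers(0, 5, 60).astype(float)  # heavy ties
        probs = (0.25, 0.75)
        cats = quantile_categorize(z, probs)
        cuts = np.quantile(z, probs)
        for zi, ci in zip(z, cats):
            expect = sum(1 for q in cuts if zi >= q)  # [q_{k-1}, q_k) rule
            assert ci == expect

    def test_bad_probs_rejected(self):
        for probs in [(0.5, 0.5), (0.0, 0.5), (0.2, 0.9, 0.8)]:
            with pytest.raises(ValueError):
                quantile_categorize(np.arange(10.0), probs)


class TestKappaGos:
    def test_identical_surfaces(self, rng):
        z = rng.normal(size=50)
        assert np.isclose(kappa_gos(z, z.copy(), 3), 1.0)
        assert np.isclose(kappa_gos(z, z.copy(), 5), 1.0)

    def test_monotone_transform_preserves_kappa(self, rng):
        z = rng.normal(size=60)
        assert np.isclose(kappa_gos(np.exp(z), z, 3), 1.0)

    def test_totally_smoothed_surface_gives_zero(self, rng):
        z = rng.normal(size=100)
        with pytest.warns(UserWarning, match="degenerate"):
            k = kappa_gos(np.ones(100), z, 3)
        assert abs(k) < 1e-12

    def test_invalid_category_count(self, rng):
        with pytest.raises(ValueError):
            kappa_gos(rng.normal(size=10), rng.normal(size=10), 4)


class TestFractionSpatialVariation:
    def _sample_with_resid(self, s_star, lam):
        # single-draw sample: residual = lam - y with y = 1, E = 1
        n = len(s_star)
        data = AreaData(y=[1] * n, E=[1.0] * n, X=np.ones((n, 1)))
        sample = make_sample(np.array([s_star]), mu_draws=np.log([lam]))
        return sample, data

    def test_zero_residual_variance_gives_one(self):
        sample, data = self._sample_with_resid([0.0, 1.0, 2.0], [2.0, 2.0, 2.0])
        assert fraction_spatial_variation(sample, data) == 1.0

    def test_constant_field_gives_zero(self):
        sample, data = self._sample_with_resid([1.0, 1.0, 1.0], [1.0, 3.0, 5.0])
        assert fraction_spatial_variation(sample, data) == 0.0

    def test_direct_evaluation(self):
        # s* = (0,1,2), eps* = (0,2,4) -> 1 / (1 + 4)
        sample, data = self._sample_with_resid([0.0, 1.0, 2.0], [1.0, 3.0, 5.0])
        assert np.isclose(fraction_spatial_variation(sample, data), 0.2)

    def test_shift_invariance_and_unit_range(self, rng):
        s = rng.normal(size=(7, 10))
        lam = np.exp(rng.normal(size=(7, 10)))
        data = AreaData(y=rng.poisson(3, 10), E=np.ones(10), X=np.ones((10, 1)))
        base = fraction_spatial_variation(make_sample(s, mu_draws=np.log(lam)), data)
        shifted = fraction_spatial_variation(make_sample(s + 5.0, mu_draws=np.log(lam)), data)
        assert 0.0 <= base <= 1.0
        assert np.isclose(base, shifted)

    def test_double_degeneracy_is_error(self):
        sample, data = self._sample_with_resid([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            fraction_spatial_variation(sample, data)


class TestRelativePosition:
    def _fixture(self):
        # path A-B-C; casir = (1.0, 1.2, 1.2) so m = (1.2, 1.1, 1.2);
        # E tuned so carsir gives positions exactly (0, 0.5, 1)
        g = AreaGraph.from_edges([("A", "B"), ("B", "C")])
        casir = np.array([1.0, 1.2, 1.2])
        carsir = np.array([1.0, 1.2**2 / 1.1, 0.8])
        data = AreaData(y=[1, 1, 1], E=1.0 / carsir, X=np.ones((3, 1)))
        sample = make_sample(np.log([casir]), beta_draws=np.zeros((1, 1)),
                             mu_draws=np.log([casir]))
        return sample, data, g

    def test_endpoints_and_midpoint(self):
        sample, data, g = self._fixture()
        rp = relative_position_casir(sample, data, g)
        assert not rp.excluded.any()
        assert np.allclose(rp.r, [0.0, 0.5, 1.0], atol=1e-12)

    def test_zero_count_area_excluded(self):
        g = AreaGraph.from_edges([("A", "B"), ("B", "C")])
        data = AreaData(y=[0, 2, 3], E=[1.0, 1.0, 1.0], X=np.ones((3, 1)))
        sample = make_sample(np.log([[1.0, 1.5, 2.0]]))
        rp = relative_position_casir(sample, data, g)
        assert rp.excluded[0] and rp.reasons[0] == "zero_count"
        assert np.isnan(rp.r[0])

    def test_narrow_range_excluded(self):
        sample, data, g = self._fixture()
        rp = relative_position_casir(sample, data, g, min_log_range=1.0)
        assert rp.excluded.all()
        assert set(rp.reasons) == {"narrow_range"}

    def test_exclusion_leaves_other_areas_unchanged(self):
        sample, data, g = self._fixture()
        full = relative_position_casir(sample, data, g)
        # exclude area A by zeroing its count; B and C keep their r values
        data2 = AreaData(y=[0, 1, 1], E=data.E, X=data.X)
        part = relative_position_casir(sample, data2, g)
        # carsir for A changes (0), other areas' endpoints are untouched
        assert np.allclose(part.r[1:], full.r[1:], atol=1e-12)

    def test_capping_applied_to_summaries(self):
        g = AreaGraph.from_edges([("A", "B"), ("B", "C")])
        data = AreaData(y=[1, 1, 1], E=[1.0, 1.0, 1.0], X=np.ones((3, 1)))
        # casir far below carsir -> raw position strongly negative
        sample = make_sample(np.log([[0.05, 2.0, 3.0]]))
        rp = relative_position_casir(sample, data, g)
        assert np.nanmin(rp.capped) >= -0.2 and np.nanmax(rp.capped) <= 1.2


def _result(**kw):
    base = dict(variogram_ratio=0.5, kurtosis_smoothed=1.0, kurtosis_raw=0.5,
                roughness=0.2, kappa3=0.5, kappa5=0.5, psi=0.05,
                rel_pos=RelativePosition(r=np.full(4, 0.5), capped=np.full(4, 0.5),
                                         excluded=np.zeros(4, bool),
                                         reasons=np.full(4, "", object)))
    base.update(kw)
    return GosResult(**base)


class TestCutoffsAndConsensus:
    def test_variogram_ratio_pass_under_unbiased(self):
        flags = apply_cutoffs(_result(variogram_ratio=0.5), PROFILES["u"], [_result()])
        assert flags["variogram_ratio"] is True

    def test_kappa_097_fails_unbiased(self):
        flags = apply_cutoffs(_result(kappa3=0.97), PROFILES["u"], [_result()] * 2)
        assert flags["kappa"] is False

    def test_relpos_ninety_percent_in_band_passes_pu(self):
        r = np.concatenate([np.full(9, 0.5), [1.1]])
        rp = RelativePosition(r=r, capped=np.clip(r, -0.2, 1.2),
                              excluded=np.zeros(10, bool),
                              reasons=np.full(10, "", object))
        flags = apply_cutoffs(_result(rel_pos=rp), PROFILES["pu"], [_result()] * 2)
        assert flags["rel_pos"] is True

    def test_pu_profile_has_no_kurtosis_criterion(self):
        flags = apply_cutoffs(_result(), PROFILES["pu"], [_result()] * 2)
        assert "kurtosis" not in flags

    def test_kurtosis_roughness_uses_comparison_minimum(self):
        rough = _result(roughness=0.4)
        smooth = _result(roughness=0.2)
        comp = [rough, smooth]
        assert apply_cutoffs(smooth, PROFILES["u"], comp)["kurtosis"] is True
        assert apply_cutoffs(rough, PROFILES["u"], comp)["kurtosis"] is False

    def test_singleton_comparison_degenerates_to_pass_with_warning(self):
        res = _result()
        with pytest.warns(UserWarning, match="single model"):
            flags = apply_cutoffs(res, PROFILES["u"], [res])
        assert flags["kurtosis"] is True

    def test_consensus_counts(self):
        flags = {
            "all": {"pu": {"variogram_ratio": True, "kappa": True, "rel_pos": True}},
            "one": {"pu": {"variogram_ratio": False, "kappa": True, "rel_pos": False}},
        }
        out = consensus(flags)
        assert out == {"all": 3, "one": 1}
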