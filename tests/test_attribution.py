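import numpy as np
import pytest

from srmd.attribution import (
    compute_contributions,
    contribution_shares,
    fit_noise,
    perturb_factor,
    significance_mask,
    virtual_contribution,
)
from srmd.config import StudyConfig
from srmd.drivers import FACTOR_IDS
from srmd.grid import Grid
from srmd.gwann import train
from srmd.scene import SceneConfig, generate_scene


def _grids(values_by_factor, cell=30.0):
    return {
        fid: Grid(values=np.asarray(v, dtype=float), cell_size_m=cell)
        for fid, v in values_by_factor.items()
    }


class TestPerturbation:
    def test_relative_bias_and_isolation(self, small_scene):
        year = small_scene.mining_years[0]
        stack = small_scene.stacks[year]
        perturbed, bias = perturb_factor(stack, "urban", 0.001)
        x = stack.factors["urban"].values
        nonzero = stack.factors["urban"].mask & (x > 0)
        np.testing.assert_allclose(bias.values[nonzero], 0.001 * x[nonzero])
        np.testing.assert_allclose(
            perturbed.factors["urban"].values[nonzero], 1.001 * x[nonzero]
        )
        for fid in FACTOR_IDS:
            if fid != "urban":
                assert perturbed.factors[fid] is stack.factors[fid]

    def test_zero_cells_receive_absolute_floor(self, small_scene):
        year = small_scene.mining_years[0]
        stack = small_scene.stacks[year]
        zero = stack.factors["mine"].mask & (stack.factors["mine"].values == 0.0)
        assert zero.any()      # per-year min-max normalization guarantees a zero
        _, bias = perturb_factor(stack, "mine", 0.001)
        np.testing.assert_array_equal(bias.values[zero], 1e-6)

    def test_unknown_factor_rejected(self, small_scene):
        stack = small_scene.stacks[small_scene.mining_years[0]]
        with pytest.raises(ValueError, match="unknown factor"):
            perturb_factor(stack, "rainfall", 0.001)


class TestShares:
    def test_equal_derivatives_share_one_fifth(self):
        C = _grids({f: [[1.0]] for f in FACTOR_IDS})
        maps = contribution_shares(C)
        for f in FACTOR_IDS:
            assert maps.W[f].values[0, 0] == pytest.approx(0.2)

    def test_hand_computed_shares(self):
        vals = dict(zip(FACTOR_IDS, [2.0, 1.0, 1.0, 0.0, 0.0]))
        maps = contribution_shares(_grids({f: [[v]] for f, v in vals.items()}))
        expected = dict(zip(FACTOR_IDS, [0.5, 0.25, 0.25, 0.0, 0.0]))
        for f in FACTOR_IDS:
            assert maps.W[f].values[0, 0] == pytest.approx(expected[f])

    @pytest.mark.parametrize("convention", ["signed", "magnitude"])
    def test_shares_sum_to_one_wherever_defined(self, convention):
        rng = np.random.default_rng(0)
        C = _grids({f: rng.normal(0, 1, (8, 8)) for f in FACTOR_IDS})
        maps = contribution_shares(C, convention=convention)
        total = sum(maps.W[f].values for f in FACTOR_IDS)
        defined = maps.W[FACTOR_IDS[0]].mask
        np.testing.assert_allclose(total[defined], 1.0)

    def test_sign_cancelling_denominator_becomes_nodata(self):
        vals = dict(zip(FACTOR_IDS, [1.0, -1.0, 0.5, -0.5, 0.0]))
        maps = contribution_shares(
            _grids({f: [[v]] for f, v in vals.items()}), convention="signed"
        )
        assert not maps.W["mine"].mask[0, 0]

    def test_missing_factor_rejected(self):
        C = _grids({f: [[1.0]] for f in FACTOR_IDS[:-1]})
        with pytest.raises(ValueError, match="mine"):
            contribution_shares(C)


@pytest.fixture(scope="module")
def noiseless_maps():
    scene = generate_scene(
        SceneConfig(seed=33, shape=(30, 30), noise_sd=0.0, mining_amplitude=0.0,
                    no_mining_years=[1992, 1993], mining_years=[2020])
    )
    cfg = StudyConfig(seed=33, max_epochs=800, learning_rate=1.0)
    year = 2020
    model, _ = train({year: scene.stacks[year]}, {year: scene.fvc[year]}, cfg)[year]
    maps = compute_contributions(model, scene.stacks[year], 0.001)
    return scene, maps, model


class TestContributionRecovery:
    """On noiseless linear scenes the derivative maps expose the true coefficients."""

    def test_spatial_factor_ratio_matches_generative_coefficients(self, noiseless_maps):
        # within one year the climate factors are spatially constant and
        # unidentifiable; the spatially varying factors (dem, urban) must
        # expose the generative coefficient ratio
        scene, maps, _ = noiseless_maps
        coeff = scene.truth.coefficients
        c_med = {f: np.median(maps.C[f].valid_values()) for f in ("dem", "urban")}
        ratio = c_med["dem"] / c_med["urban"]
        assert ratio == pytest.approx(coeff["dem"] / coeff["urban"], rel=0.15)
        # signs of the recovered derivatives match the generative signs
        assert c_med["dem"] < 0 and c_med["urban"] < 0

    def test_zero_effect_factor_stays_small(self, noiseless_maps):
        # mining has zero amplitude in this scene, so its derivative is noise
        scene, maps, _ = noiseless_maps
        c_mine = np.median(np.abs(maps.C["mine"].valid_values()))
        largest = max(
            np.median(np.abs(maps.C[f].valid_values())) for f in FACTOR_IDS
        )
        assert c_mine < 0.10 * largest

    def test_step_halving_changes_contributions_below_one_percent(self, noiseless_maps):
        # Richardson-style check: the finite difference is step-size robust
        scene, maps, model = noiseless_maps
        year = 2020
        maps_half = compute_contributions(model, scene.stacks[year], 0.0005)
        for f in ("pre", "urban"):
            a = maps.C[f].valid_values()
            b = maps_half.C[f].valid_values()
            denom = np.maximum(np.abs(a), 1e-3)
            assert np.median(np.abs(a - b) / denom) < 0.01


class TestNoiseModel:
    def test_standard_normal_quantile(self):
        rng = np.random.default_rng(0)
        noise = fit_noise(rng.standard_normal(200_000), alpha=0.05)
        assert noise.critical_value == pytest.approx(1.645, abs=0.02)
        assert noise.mean == pytest.approx(0.0, abs=0.01)
        assert noise.sd == pytest.approx(1.0, abs=0.01)

    def test_gaussian_diagnostic_recovers_histogram_shape(self):
        rng = np.random.default_rng(1)
        noise = fit_noise(rng.normal(0.05, 0.02, 100_000), alpha=0.05)
        _, centre, width = noise.gaussian_fit
        assert centre == pytest.approx(0.05, abs=0.005)
        assert abs(width) == pytest.approx(0.02, rel=0.2)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="100"):
            fit_noise(np.zeros(50))

    def test_virtual_contribution_requires_virtual_stacks(self, small_scene, fast_config):
        year = small_scene.mining_years[0]
        with pytest.raises(ValueError, match="virtual"):
            virtual_contribution(
                {year: small_scene.stacks[year]}, small_scene.fvc, fast_config
            )

    def test_virtual_contribution_year_bookkeeping_and_determinism(
        self, small_scene, fast_config
    ):
        nm = {y: small_scene.stacks[y] for y in small_scene.no_mining_years[:2]}
        cfg = StudyConfig(**{**fast_config.to_dict(), "max_epochs": 30})
        vw1 = virtual_contribution(nm, small_scene.fvc, cfg)
        vw2 = virtual_contribution(nm, small_scene.fvc, cfg)
        assert sorted(vw1) == sorted(nm)
        for y in vw1:
            np.testing.assert_array_equal(vw1[y].values, vw2[y].values)


class TestSignificance:
    def _noise(self, critical=0.085):
        rng = np.random.default_rng(0)
        samples = rng.normal(0.054, 0.017, 10_000)
        noise = fit_noise(samples, alpha=0.05)
        noise.critical_value = critical
        return noise

    def test_flags_only_above_critical_value(self):
        noise = self._noise(0.085)
        w = Grid(values=np.array([[0.09, 0.08], [0.085, 0.2]]), cell_size_m=30.0)
        mask = significance_mask(w, noise)
        np.testing.assert_array_equal(
            mask.values, np.array([[True, False], [False, True]])
        )

    def test_exactly_critical_not_flagged(self):
        noise = self._noise(0.085)
        w = Grid(values=np.array([[0.085]]), cell_size_m=30.0)
        assert significance_mask(w, noise).count() == 0

    def test_null_draws_flag_alpha_fraction(self):
        rng = np.random.default_rng(7)
        samples = rng.normal(0.05, 0.02, 200_000)
        noise = fit_noise(samples, alpha=0.05)
        fresh = rng.normal(0.05, 0.02, (400, 400))
        mask = significance_mask(Grid(values=fresh, cell_size_m=30.0), noise)
        frac = mask.values.mean()
        tol = 2 * np.sqrt(0.05 * 0.95 / fresh.size)
        assert frac == pytest.approx(0.05, abs=tol + 0.002)
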