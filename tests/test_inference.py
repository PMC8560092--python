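"""Distance, priors, calibration and rejection sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkacn.inference import (
    FITS,
    MISFITS,
    PosteriorEnsemble,
    PriorSpec,
    abc_reject,
    calibrate_akar4,
    classify_by_mutant_fit,
    distance_rho,
    kd_landscape,
    normalize_traces,
    sample_prior,
)
from pkacn.network import (
    build_base_network,
    build_extended_network,
    default_parameters,
    extend_parameters,
)
from pkacn.simulate import EmissionTrace, akar4_readout, simulate
from pkacn.synth import GeneratorConfig, gen_akar4_dataset, gen_calibration_dataset


class TestDistance:
    def test_identical_series_zero(self):
        y = np.linspace(0, 1, 50)
        assert distance_rho(y, y) == 0.0

    def test_uniform_offset_is_squared_delta(self):
        y = np.linspace(0, 1, 123)
        assert distance_rho(y, y + 0.1) == pytest.approx(0.01)

    def test_hand_computed_value(self):
        assert distance_rho([0.0, 1.0], [0.0, 0.0]) == pytest.approx(0.5)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            distance_rho([0.0, 1.0], [0.0])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40),
           st.data())
    @settings(max_examples=50, deadline=None)
    def test_premetric_properties(self, ys, data):
        a = np.array(ys)
        b = np.array(data.draw(st.lists(
            st.floats(0, 1), min_size=len(ys), max_size=len(ys))))
        assert distance_rho(a, b) >= 0
        assert distance_rho(a, b) == pytest.approx(distance_rho(b, a))
        if np.all(a == b):
            assert distance_rho(a, b) == 0
        if distance_rho(a, b) == 0:  # underflow-safe converse
            assert np.max(np.abs(a - b)) < 1e-150


def _trace(times, ratio):
    return EmissionTrace(np.asarray(times, float), np.asarray(ratio, float),
                         np.zeros(len(times)))


class TestNormalize:
    def test_range_maps_to_unit_interval(self):
        tr = _trace([0, 5, 10], [1.0, 1.36, 1.72])
        ys, transforms = normalize_traces([tr])
        np.testing.assert_allclose(ys[0], [0.0, 0.5, 1.0])

    def test_unit_series_unchanged(self):
        tr = _trace([0, 5, 10], [0.0, 0.25, 1.0])
        ys, _ = normalize_traces([tr])
        np.testing.assert_allclose(ys[0], [0.0, 0.25, 1.0])

    def test_transform_applies_identically_to_simulations(self):
        tr = _trace([0, 5, 10], [1.0, 1.36, 1.72])
        _, (t,) = normalize_traces([tr])
        np.testing.assert_allclose(t(np.array([1.0, 1.72])), [0.0, 1.0])
        # idempotent on already-normalised values of the same transform
        np.testing.assert_allclose(t(t(np.array([1.0, 1.72])) * (t.hi - t.lo)
                                     + t.lo), [0.0, 1.0])

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_traces([_trace([0, 5], [1.0, 1.0])])


class TestPrior:
    def test_bounds_span_three_decades(self, defaults):
        prior = PriorSpec.from_parameters(defaults)
        draws = sample_prior(prior, 200, seed=0)
        for name in prior.free_names:
            d = defaults[name]
            assert draws[name].between(d * 10 ** -1.5, d * 10 ** 1.5).all()

    def test_log_median_near_default(self, defaults):
        prior = PriorSpec.from_parameters(defaults)
        draws = sample_prior(prior, 4000, seed=1)
        name = "kphos_RIIC"
        logmed = np.median(np.log10(draws[name]))
        # Monte-Carlo error of a median of U(-1.5, 1.5): sd ≈ 1.88/(2√n)
        assert logmed == pytest.approx(np.log10(defaults[name]), abs=0.1)

    def test_seed_reproducibility(self, defaults):
        prior = PriorSpec.from_parameters(defaults)
        a = sample_prior(prior, 50, seed=7)
        b = sample_prior(prior, 50, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_frozen_parameters_fixed(self, defaults):
        prior = PriorSpec.from_parameters(defaults)
        prior.freeze({"kf_AKAR4_C": 0.123})
        draws = sample_prior(prior, 20, seed=0)
        assert (draws["kf_AKAR4_C"] == 0.123).all()

    def test_invalid_bounds_rejected(self, defaults):
        prior = PriorSpec.from_parameters(defaults)
        prior.entries["kphos_RIIC"].low = -1.0
        with pytest.raises(ValueError, match="invalid bounds"):
            sample_prior(prior, 5, seed=0)


class TestCalibration:
    def test_round_trip_recovers_reporter_kinetics(self, base_net):
        """Noiseless traces from perturbed reporter rates are re-fitted to
        reproduce every calibration curve with rho < 0.01."""
        truth = default_parameters()
        truth["kf_AKAR4_C"] = 0.07
        truth["kr_AKAR4_C"] = 0.5
        truth["kcat_AKAR4"] = 0.2
        traces, _ = gen_calibration_dataset(
            akar4_params=truth, config=GeneratorConfig(seed=3, sigma_ratio=0.0))
        frozen = calibrate_akar4(traces)  # starts from package defaults
        fitted = default_parameters()
        fitted.values.update(frozen)
        norms, transforms = normalize_traces(traces[1:])  # drop flat zero-C trace
        for tr, y, t in zip(traces[1:], norms, transforms):
            sim = akar4_readout(simulate(base_net, fitted, tr.condition))
            _, ys = sim.post_injection()
            assert distance_rho(y, t(ys)) < 0.01

    def test_rate_linear_in_c_below_threshold(self, base_net):
        traces, truth = gen_calibration_dataset(
            config=GeneratorConfig(seed=0, sigma_ratio=0.0))
        concs = [tr.condition.totals["C"] for tr in traces]
        rates = [truth["conditions"][tr.condition.label]["initial_rate"]
                 for tr in traces]
        # "close to linear": window-rate saturation bends the curve slightly
        r = np.corrcoef(concs, rates)[0, 1]
        assert r > 0.995
        # and strictly monotone
        assert np.all(np.diff(rates) > 0)

    def test_zero_c_trace_stays_flat(self):
        traces, _ = gen_calibration_dataset(
            config=GeneratorConfig(seed=0, sigma_ratio=0.0))
        flat = traces[0]
        assert flat.condition.totals["C"] == 0.0
        assert np.ptp(flat.ratio) == pytest.approx(0.0, abs=1e-9)

    def test_single_concentration_unidentifiable(self):
        traces, _ = gen_calibration_dataset(
            C_concs=(0.0, 0.2), config=GeneratorConfig(sigma_ratio=0.0))
        with pytest.raises(ValueError, match="distinct"):
            calibrate_akar4(traces)


@pytest.fixture(scope="module")
def small_abc():
    """Reduced rejection run: 2 mixtures × 2 doses, truth injected."""
    net = build_base_network()
    truth = default_parameters()
    cfg = GeneratorConfig(seed=11, sigma_ratio=0.0, doses=(0.2, 1.0),
                          mixtures=("pka", "pka+cn+akap"))
    datasets, _ = gen_akar4_dataset(net, truth, cfg)
    prior = PriorSpec.from_parameters(truth, span_decades=0.5)
    extra = pd.DataFrame([dict(truth.values)])
    ens = abc_reject(datasets, net, prior, 150, threshold=0.01, seed=5,
                     extra_draws=extra)
    return net, truth, datasets, prior, ens


class TestRejection:
    def test_generating_parameters_accepted_with_zero_rho(self, small_abc):
        net, truth, datasets, prior, ens = small_abc
        assert ens.n_accepted >= 1
        # first accepted row is the injected truth with rho == 0 (noiseless)
        first = ens.params.iloc[0]
        for k, v in truth.values.items():
            assert first[k] == pytest.approx(v)
        assert ens.distances.iloc[0].max() < 1e-12

    def test_acceptance_contract(self, small_abc):
        _, _, _, _, ens = small_abc
        assert (ens.distances.to_numpy() < ens.threshold).all()

    def test_threshold_monotonicity(self, small_abc):
        net, truth, datasets, prior, _ = small_abc
        extra = pd.DataFrame([dict(truth.values)])
        tight = abc_reject(datasets, net, prior, 150, threshold=0.002,
                           seed=5, extra_draws=extra)
        loose = abc_reject(datasets, net, prior, 150, threshold=0.01,
                           seed=5, extra_draws=extra)
        tight_rows = {tuple(r) for r in tight.params.to_numpy()}
        loose_rows = {tuple(r) for r in loose.params.to_numpy()}
        assert tight_rows <= loose_rows

    def test_empty_result_warns_not_raises(self, small_abc):
        net, truth, datasets, prior, _ = small_abc
        with pytest.warns(RuntimeWarning, match="no acceptances"):
            ens = abc_reject(datasets, net, prior, 3, threshold=1e-9, seed=2)
        assert ens.n_accepted == 0


@pytest.fixture(scope="module")
def mutant_setup():
    ext = build_extended_network(0.85)
    truth = default_parameters()
    cfg = GeneratorConfig(seed=21, sigma_ratio=0.0, doses=(1.0,),
                          mixtures=("pka+cn+akap",), rii_variant="S98A")
    mut_data, _ = gen_akar4_dataset(ext, extend_parameters(truth), cfg)
    return ext, truth, mut_data


class TestClassification:
    def test_generator_member_fits_and_corrupted_member_misfits(self, mutant_setup):
        ext, truth, mut_data = mutant_setup
        bad = truth.copy()
        bad["kcat_AKAR4"] *= 10 ** 1.5  # dephospho-side distortion of readout
        params = pd.DataFrame([dict(truth.values), dict(bad.values)])
        ens = PosteriorEnsemble(params, pd.DataFrame({"rho_x": [0.0, 0.0]}),
                                0.01, 0, 2)
        out = classify_by_mutant_fit(ens, mut_data, ext)
        assert list(out.labels) == [FITS, MISFITS]

    def test_class_sizes_sum_to_ensemble_size(self, mutant_setup):
        ext, truth, mut_data = mutant_setup
        params = pd.DataFrame([dict(truth.values)] * 3)
        ens = PosteriorEnsemble(params, pd.DataFrame({"rho_x": [0.0] * 3}),
                                0.01, 0, 3)
        out = classify_by_mutant_fit(ens, mut_data, ext)
        assert (out.labels == FITS).sum() + (out.labels == MISFITS).sum() == 3


class TestKdLandscape:
    def _ensemble(self, rows, labels=None):
        params = pd.DataFrame(rows)
        ens = PosteriorEnsemble(params,
                                pd.DataFrame({"rho_x": [0.0] * len(rows)}),
                                0.01, 0, len(rows))
        if labels is not None:
            ens.labels = pd.Series(labels)
        return ens

    def test_identical_members_zero_width(self, defaults):
        ens = self._ensemble([dict(defaults.values)] * 4)
        kd, summary, _ = kd_landscape(ens)
        assert set(kd.columns) >= {"K_D56", "K_D76"}
        assert kd.shape[1] == 9  # 8 K_Ds + class column
        stds = summary.xs("std", axis=1, level=1)
        np.testing.assert_allclose(stds.to_numpy(), 0.0)

    def test_opposed_kd_pair_gives_negative_rank_correlation(self, defaults,
                                                             rng):
        rows = []
        for i in range(20):
            ps = defaults.copy()
            scale = 10 ** rng.uniform(-1, 1)
            ps["kr_RIIC_cAMP"] = defaults["kr_RIIC_cAMP"] * scale      # K_D56 up
            ps["kr_RIIcAMP_C"] = defaults["kr_RIIcAMP_C"] / scale      # K_D76 down
            rows.append(dict(ps.values))
        kd, _, corr = kd_landscape(self._ensemble(rows))
        assert corr["spearman_r"] == pytest.approx(-1.0)
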