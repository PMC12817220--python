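"""Generator tests: Hill amplitude law, kinetics, condition logic, filter."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import signal

from ergdissect.core import AgeClass, ComponentKind, ErgError, Genotype, PerfusionCondition
from ergdissect.presets import NOISE_FREE_CONFIG, base_models, genotype_effect
from ergdissect.synthetic import (
    ComponentModel,
    GenotypeEffect,
    SimConfig,
    acquisition_filter,
    component_waveform,
    hill_amplitude,
    simulate_family,
)

GRID = np.arange(-50, 1050) / 1000.0  # 1 kHz grid, 50 ms pre-flash


@pytest.fixture(params=list(ComponentKind))
def model(request):
    return ComponentModel(request.param, r_max=200.0, k=300.0, n=1.2)


class TestComponentWaveform:
    def test_zero_intensity_gives_zero_waveform(self, model):
        assert np.all(component_waveform(model, 0.0, GRID) == 0.0)

    def test_saturating_intensity_reaches_r_max(self, model):
        wave = component_waveform(model, 1e6 * model.k, GRID)
        assert np.abs(wave).max() == pytest.approx(model.r_max, rel=1e-3)

    def test_half_maximal_at_k(self, model):
        wave = component_waveform(model, model.k, GRID)
        assert np.abs(wave).max() == pytest.approx(model.r_max / 2, rel=1e-12)

    @pytest.mark.parametrize("intensity", [10.0, 300.0, 40000.0])
    def test_peak_magnitude_follows_hill_law(self, model, intensity):
        expected = hill_amplitude(intensity, model.r_max, model.k, model.n)
        wave = component_waveform(model, intensity, GRID)
        assert np.abs(wave).max() == pytest.approx(expected, rel=1e-9)

    def test_polarities(self):
        for kind, sign in [
            (ComponentKind.PHOTORECEPTOR, -1),
            (ComponentKind.ON_BIPOLAR, +1),
            (ComponentKind.MGC, -1),
        ]:
            wave = component_waveform(
                ComponentModel(kind, r_max=100, k=100, n=1), 1000.0, GRID
            )
            extremum = wave[np.abs(wave).argmax()]
            assert np.sign(extremum) == sign

    def test_time_to_extremum_ordering(self):
        times = {}
        for kind in ComponentKind:
            wave = component_waveform(
                ComponentModel(kind, r_max=100, k=100, n=1), 1000.0, GRID
            )
            times[kind] = GRID[np.abs(wave).argmax()]
        assert (
            times[ComponentKind.PHOTORECEPTOR]
            < times[ComponentKind.ON_BIPOLAR]
            < times[ComponentKind.MGC]
        )

    def test_photoreceptor_nose_then_plateau(self):
        wave = component_waveform(
            ComponentModel(ComponentKind.PHOTORECEPTOR, r_max=100, k=100, n=1),
            1e5, GRID,
        )
        trough_t = GRID[wave.argmin()]
        assert trough_t < 0.1  # fast nose
        plateau = wave[(GRID >= 0.4) & (GRID <= 0.6)]
        # partial relaxation: plateau is negative but shallower than the nose
        assert np.all(plateau < 0)
        assert 0.2 * np.abs(wave.min()) < np.abs(plateau.mean()) < 0.8 * np.abs(wave.min())

    def test_negative_intensity_rejected(self, model):
        with pytest.raises(ErgError):
            component_waveform(model, -1.0, GRID)


def _simulate(config, genotype=Genotype.WT, seed=3):
    return simulate_family(
        config,
        base_models(AgeClass.ADULT),
        genotype_effect(genotype, AgeClass.ADULT),
        retina_id="sim",
        age_days=35,
        rng=seed,
    )


class TestConditionLogic:
    def test_noise_free_additivity(self, noise_free_wt):
        family, truth = noise_free_wt.family, noise_free_wt.truth
        for intensity in family.intensities:
            lockes = family.sweeps(PerfusionCondition.LOCKES, intensity)[0].samples
            bacl2 = family.sweeps(PerfusionCondition.BACL2, intensity)[0].samples
            cocktail = family.sweeps(PerfusionCondition.BACL2_LAP4_AA, intensity)[0].samples
            m = truth.component_traces[(ComponentKind.MGC, intensity)]
            b = truth.component_traces[(ComponentKind.ON_BIPOLAR, intensity)]
            p = truth.component_traces[(ComponentKind.PHOTORECEPTOR, intensity)]
            scale = max(np.abs(m).max(), np.abs(b).max(), 1e-9)
            assert np.abs((lockes - bacl2) - m).max() <= 1e-12 * scale
            assert np.abs((bacl2 - cocktail) - b).max() <= 1e-12 * scale
            assert np.array_equal(cocktail, p)

    def test_same_seed_is_bit_identical(self):
        config = replace(NOISE_FREE_CONFIG, noise_sd=2.0, retina_cv_r_max=0.15)
        a = _simulate(config, seed=42)
        b = _simulate(config, seed=42)
        assert all(
            np.array_equal(x.samples, y.samples)
            for x, y in zip(a.family.traces, b.family.traces)
        )

    def test_different_seeds_differ(self):
        config = replace(NOISE_FREE_CONFIG, noise_sd=2.0)
        a, b = _simulate(config, seed=1), _simulate(config, seed=2)
        assert not np.array_equal(a.family.traces[0].samples, b.family.traces[0].samples)

    def test_genotype_scaling_halves_ground_truth_amplitudes(self):
        half = GenotypeEffect(
            Genotype.KO, AgeClass.ADULT,
            {ComponentKind.PHOTORECEPTOR: (0.5, 1.0)},
        )
        wt = _simulate(NOISE_FREE_CONFIG)
        ko = simulate_family(
            NOISE_FREE_CONFIG, base_models(AgeClass.ADULT), half,
            retina_id="ko", age_days=35, rng=3,
        )
        for intensity in wt.family.intensities:
            ratio = (
                ko.truth.amplitude(ComponentKind.PHOTORECEPTOR, intensity)
                / wt.truth.amplitude(ComponentKind.PHOTORECEPTOR, intensity)
            )
            assert ratio == pytest.approx(0.5, rel=1e-12)

    def test_wildtype_effect_must_be_identity(self):
        with pytest.raises(ErgError):
            GenotypeEffect(
                Genotype.WT, AgeClass.ADULT, {ComponentKind.MGC: (0.5, 1.0)}
            )

    def test_mgc_residual_fraction(self):
        config = replace(NOISE_FREE_CONFIG, mgc_residual_fraction=0.25)
        res = _simulate(config)
        intensity = res.family.intensities[-1]
        bacl2 = res.family.sweeps(PerfusionCondition.BACL2, intensity)[0].samples
        lockes = res.family.sweeps(PerfusionCondition.LOCKES, intensity)[0].samples
        m = res.truth.component_traces[(ComponentKind.MGC, intensity)]
        assert np.abs((lockes - bacl2) - 0.75 * m).max() <= 1e-9


class TestAcquisitionFilter:
    def test_constant_trace_unchanged(self):
        from conftest import make_trace

        trace = make_trace(np.full(500, -12.0), sample_rate=10_000.0)
        out = acquisition_filter(trace)
        assert np.allclose(out.samples, -12.0, atol=1e-9)

    def test_zero_trace_stays_zero(self):
        from conftest import make_trace

        trace = make_trace(np.zeros(500), sample_rate=10_000.0)
        assert np.all(acquisition_filter(trace).samples == 0.0)

    def test_high_frequency_attenuation_matches_frequency_response(self):
        from conftest import make_trace

        fs, f_sig = 10_000.0, 3_000.0
        t = np.arange(20_000) / fs
        trace = make_trace(np.sin(2 * np.pi * f_sig * t), sample_rate=fs)
        out = acquisition_filter(trace, cutoff_hz=300.0, poles=8)
        # oracle: magnitude of the designed filter at the probe frequency
        sos = signal.bessel(8, 300.0, btype="low", fs=fs, output="sos")
        _, h = signal.sosfreqz(sos, worN=[f_sig], fs=fs)
        expected = np.abs(h[0])
        measured = np.abs(out.samples[5000:]).max()
        assert measured < 1.0 / 20.0
        assert measured == pytest.approx(expected, rel=0.2)

    def test_cutoff_above_nyquist_rejected(self):
        from conftest import make_trace

        trace = make_trace(np.zeros(500), sample_rate=500.0)
        with pytest.raises(ErgError):
            acquisition_filter(trace, cutoff_hz=300.0)


def test_config_validation():
    with pytest.raises(ErgError):
        SimConfig(sweeps=0)
    with pytest.raises(ErgError):
        SimConfig(intensities=())
    with pytest.raises(ErgError):
        SimConfig(intensities=(1.0,))  # below protocol range
    with pytest.raises(ErgError):
        SimConfig(record_duration=0.05, pre_flash=0.1)
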