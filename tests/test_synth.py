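"""Synthetic spectrum generator: determinism, calibration anchors, recovery."""

import numpy as np
import pytest

from conftest import quiet_noise
from paglucose.grid import DEFAULT_GRID
from paglucose.prep import extract_features
from paglucose.synth import (
    DatasetConfig,
    GlucoseResponseModel,
    NoiseModel,
    carbon_resonator,
    phantom_resonator,
    simulate_calibration,
    simulate_dataset,
    simulate_spectrum,
)

# expected small-sample mean of the population SD of 3 normal draws,
# E[sqrt(chi2_2 / 3)] = sqrt(2/3) * Gamma(3/2) / Gamma(1) * sqrt(2)
SD3_BIAS = np.sqrt(2.0 / 3.0) * 1.2533141373155003 / np.sqrt(2.0)


def _noiseless_spectrum(glucose, shift=0.0):
    return simulate_spectrum(
        DEFAULT_GRID,
        phantom_resonator(),
        GlucoseResponseModel(),
        quiet_noise(),
        glucose_mgdl=glucose,
        shift_bins=shift,
    )


class TestDatasetShape:
    def test_default_campaign_size(self, default_dataset):
        assert len(default_dataset) == 72
        days = {sp.day for sp in default_dataset.spectra}
        classes = {sp.glucose_mgdl for sp in default_dataset.spectra}
        assert days == {1, 2}
        assert len(classes) == 12

    def test_small_campaign(self):
        cfg = DatasetConfig(days=(1,), classes_mgdl=(85.0, 100.0), rounds=1)
        assert len(simulate_dataset(cfg)) == 2

    def test_off_grid_glucose_rejected(self):
        with pytest.raises(ValueError):
            _noiseless_spectrum(90.0)
        with pytest.raises(ValueError):
            _noiseless_spectrum(70.0)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = simulate_dataset(DatasetConfig())
        b = simulate_dataset(DatasetConfig())
        for sa, sb in zip(a.spectra, b.spectra):
            np.testing.assert_array_equal(sa.amplitudes_uv, sb.amplitudes_uv)

    def test_different_seed_differs(self):
        a = simulate_dataset(DatasetConfig())
        cfg = DatasetConfig(noise=NoiseModel(seed=1))
        b = simulate_dataset(cfg)
        assert not np.array_equal(a.spectra[0].amplitudes_uv, b.spectra[0].amplitudes_uv)


class TestResponseModel:
    def test_degenerate_response_identical_spectra(self):
        resp = GlucoseResponseModel(rel_step=0.0)
        ref = None
        for glucose in (85.0, 160.0, 250.0):
            sp = simulate_spectrum(
                DEFAULT_GRID, phantom_resonator(), resp, quiet_noise(),
                glucose_mgdl=glucose, shift_bins=0.0,
            )
            if ref is None:
                ref = sp.amplitudes_uv
            np.testing.assert_array_equal(sp.amplitudes_uv, ref)

    def test_peak_ratio_across_full_range(self):
        """The background-corrected peak grows by exactly (1+rel_step)^11
        from the lowest to the highest class; with the sample-independent
        stray-light background included the raw ratio sits slightly below."""
        bg = phantom_resonator().background_uv
        lo = _noiseless_spectrum(85.0).amplitudes_uv.max()
        hi = _noiseless_spectrum(250.0).amplitudes_uv.max()
        assert (hi - bg) / (lo - bg) == pytest.approx(1.026**11, rel=1e-12)
        assert hi / lo == pytest.approx(1.026**11, rel=0.03)

    def test_rel_step_recovery_from_noiseless_peaks(self):
        """Regressing log background-corrected peak amplitude on class index
        recovers rel_step to machine precision."""
        bg = phantom_resonator().background_uv
        peaks = [
            _noiseless_spectrum(g).amplitudes_uv.max() - bg
            for g in range(85, 251, 15)
        ]
        slopes = np.diff(np.log(peaks))
        np.testing.assert_allclose(np.exp(slopes) - 1.0, 0.026, rtol=1e-12)

    def test_phantom_spectral_anchors(self):
        """Baseline-class spectrum: mean ~14.5 uV and peak ~51.3 uV with the
        noise-floor mean included."""
        sp = _noiseless_spectrum(85.0)
        floor = NoiseModel().floor_uv
        assert sp.amplitudes_uv.mean() + floor == pytest.approx(14.5, abs=0.2)
        assert sp.amplitudes_uv.max() + floor == pytest.approx(51.3, abs=0.2)
        peak_freq = DEFAULT_GRID.values[sp.amplitudes_uv.argmax()]
        assert peak_freq == pytest.approx(23.1)


class TestCalibrationSpectra:
    def test_noise_floor_mean(self):
        sp = simulate_calibration("noise")
        assert sp.amplitudes_uv.mean() == pytest.approx(2.3, abs=0.1)

    def test_carbon_anchor(self):
        sp = simulate_calibration("carbon")
        assert sp.amplitudes_uv.mean() == pytest.approx(306, abs=4)
        assert sp.amplitudes_uv.max() == pytest.approx(724, abs=4)
        peak_freq = sp.grid.values[sp.amplitudes_uv.argmax()]
        assert peak_freq == pytest.approx(21.75)  # nearest grid bin to 21.8

    def test_background_level_and_zero_offset(self):
        sp = simulate_calibration("background")
        assert sp.amplitudes_uv.mean() == pytest.approx(4.5, abs=0.3)
        dark = simulate_calibration(
            "background",
            resonator=phantom_resonator().__class__(
                f1_khz=16.5, f2_khz=23.1, q1=8, q2=14, a1=36.2, a2=43.6,
                background_uv=0.0,
            ),
        )
        np.testing.assert_array_equal(dark.amplitudes_uv, 0.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            simulate_calibration("butter")


class TestParameterRecovery:
    def test_gain_jitter_recovery(self):
        """The SD of the relative peak amplitude over many rounds of one
        class recovers the injected per-round gain jitter (additive noise
        and shifts off to isolate the multiplicative component)."""
        noise = NoiseModel(
            floor_uv=0.0, floor_sd_uv=0.0, round_jitter_rel=0.0101,
            shift_bins_max=0.0, round_shift_sd_bins=0.0, seed=7,
        )
        rng = np.random.default_rng(7)
        peaks = [
            simulate_spectrum(
                DEFAULT_GRID, phantom_resonator(), GlucoseResponseModel(), noise,
                glucose_mgdl=160.0, rng=rng, shift_bins=0.0,
            ).amplitudes_uv.max()
            for _ in range(300)
        ]
        rel_sd = np.std(peaks, ddof=1) / np.mean(peaks)
        assert rel_sd == pytest.approx(0.0101, rel=0.15)

    def test_round_sd_statistic_recovers_day1_jitter(self):
        """Across 20 seeded campaigns, the within-phantom round SD of the
        window integral (after the n=3 population-SD bias factor) recovers
        the day-1 gain jitter within 15%."""
        recovered = []
        for seed in range(20):
            cfg = DatasetConfig(days=(1,), noise=NoiseModel(seed=seed))
            feats = extract_features(simulate_dataset(cfg))
            grouped = feats.groupby("glucose_mgdl")["integral"]
            rel = 100.0 * grouped.std(ddof=0) / grouped.mean()
            recovered.append(rel.mean())
        estimate = np.mean(recovered) / SD3_BIAS
        assert estimate == pytest.approx(1.01, rel=0.15)

    def test_noiseless_window_integrals_strictly_increase(self, noiseless_dataset):
        feats = extract_features(noiseless_dataset)
        for _, df in feats.groupby(["day", "round"]):
            ints = df.sort_values("glucose_mgdl")["integral"].to_numpy()
            assert np.all(np.diff(ints) > 0)
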