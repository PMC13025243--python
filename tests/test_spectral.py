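import numpy as np
import pandas as pd
import pytest

from eegti import (
    BandDefinition,
    PAPER_BANDS,
    Recording,
    band_power_table,
    compute_psd,
    integrate_band,
    log_transform,
    relative_power,
    segment_epochs,
    total_power,
)
from eegti.bands import bands_by_name, check_nonoverlapping
from eegti.exceptions import (
    DomainError,
    ParameterError,
    UndefinedRatioError,
)

BN = bands_by_name(PAPER_BANDS)


def _psd_of(samples, fs=250.0, labels=("Cz",)):
    rec = Recording("s", "c", fs, labels, samples)
    return compute_psd(segment_epochs(rec, 2.0))


class TestComputePsd:
    def test_zero_signal_gives_zero_density(self):
        psd = _psd_of(np.zeros((1, 5000)))
        assert np.all(psd.density == 0)

    def test_frequency_grid_resolution(self):
        psd = _psd_of(np.random.default_rng(0).normal(size=(1, 5000)))
        assert psd.df == pytest.approx(0.5)
        assert psd.freqs[0] == 0 and psd.freqs[-1] == 125.0

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 2.0, (1, 150 * 500))
        psd = _psd_of(x)
        assert total_power(psd)[0] == pytest.approx(4.0, abs=0.2)

    def test_sine_power_closed_form(self, tone_recording):
        rec = tone_recording(freq=15.0, amplitude=2.0, duration_s=300.0)
        psd = compute_psd(segment_epochs(rec, 2.0))
        # A^2/2 = 2.0, concentrated in the 14.5-15.5 Hz bins
        mask = (psd.freqs >= 14.5) & (psd.freqs <= 15.5)
        assert psd.density[0, mask].sum() * psd.df == pytest.approx(2.0, abs=0.04)


class TestIntegrateBand:
    def test_tone_lands_in_its_band_only(self, tone_recording):
        psd = compute_psd(
            segment_epochs(tone_recording(freq=15.0, amplitude=2.0, duration_s=300.0), 2.0)
        )
        assert integrate_band(psd, BN["beta_low"])[0] == pytest.approx(2.0, rel=0.02)
        assert integrate_band(psd, BN["theta"])[0] < 1e-6

    def test_boundary_bin_belongs_to_upper_band(self):
        # half-open convention: all power exactly at 4.0 Hz is theta, not delta
        from eegti.spectral import PSDEstimate

        freqs = np.arange(0, 125.5, 0.5)
        density = np.zeros((1, len(freqs)))
        density[0, freqs == 4.0] = 2.0 / 0.5
        psd = PSDEstimate(freqs, density, ("Cz",), 250.0, 2.0, 1)
        assert integrate_band(psd, BN["theta"])[0] == pytest.approx(2.0)
        assert integrate_band(psd, BN["delta"])[0] == 0.0

    def test_tone_in_band_gap_vanishes_from_both_neighbours(self, tone_recording):
        # a 7.5 Hz tone falls in the [7, 8) gap of the default band set; the
        # window spreads a little energy to the 8.0 Hz bin, nothing more
        psd = compute_psd(
            segment_epochs(tone_recording(freq=7.5, amplitude=2.0, duration_s=300.0), 2.0)
        )
        gap = integrate_band(psd, BandDefinition("gap", 7.0, 8.0))[0]
        assert gap > 1.5  # the bulk of A^2/2 = 2.0 stays in the gap
        assert integrate_band(psd, BN["theta"])[0] < 0.02
        assert integrate_band(psd, BN["alpha_low"])[0] < 0.4

    def test_integration_is_additive(self):
        rng = np.random.default_rng(5)
        psd = _psd_of(rng.normal(0, 3.0, (1, 30 * 500)))
        lo = integrate_band(psd, BandDefinition("a", 4.0, 10.0))
        hi = integrate_band(psd, BandDefinition("b", 10.0, 20.0))
        full = integrate_band(psd, BandDefinition("c", 4.0, 20.0))
        np.testing.assert_allclose(lo + hi, full, rtol=1e-12)

    def test_band_beyond_nyquist_rejected(self):
        psd = _psd_of(np.zeros((1, 5000)))
        with pytest.raises(ParameterError):
            integrate_band(psd, BandDefinition("x", 100.0, 130.0))

    def test_estimator_spread_shrinks_with_epoch_count(self):
        # doubling the epochs should shrink the band-power spread ~1/sqrt(2)
        band = BandDefinition("mid", 10.0, 20.0)
        spreads = []
        for n_epochs in (30, 120):
            estimates = [
                integrate_band(
                    _psd_of(
                        np.random.default_rng(seed).normal(0, 2, (1, n_epochs * 500))
                    ),
                    band,
                )[0]
                for seed in range(40)
            ]
            spreads.append(np.std(estimates))
        assert spreads[1] < 0.75 * spreads[0]


class TestBandPowerTable:
    def test_row_count_and_low_confidence_flag(self):
        psd = _psd_of(np.random.default_rng(1).normal(size=(1, 10 * 500)))
        table = band_power_table({("s01", "prayer"): psd}, PAPER_BANDS)
        assert len(table) == 8
        flagged = table.loc[table["low_confidence"], "band"].tolist()
        assert flagged == ["gamma_high"]  # contains the 50 Hz notch + 70 Hz corner

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ParameterError, match="overlap"):
            check_nonoverlapping(
                [BandDefinition("a", 1.0, 5.0), BandDefinition("b", 4.0, 8.0)]
            )


class TestRelativeAndLogPower:
    def test_single_band_normalises_to_one(self, pseudo_subject_powers):
        out = relative_power(pseudo_subject_powers, ["theta"])
        row = out.loc[out["band"] == "theta"].iloc[0]
        assert row["relative_power"] == 1.0

    def test_equal_powers_split_evenly(self):
        table = pd.DataFrame(
            {
                "subject": ["s"] * 2, "condition": ["c"] * 2,
                "channel": ["Cz"] * 2, "band": ["theta", "alpha_low"],
                "power_uv2": [3.0, 3.0],
            }
        )
        out = relative_power(table, ["theta", "alpha_low"])
        assert out["relative_power"].tolist() == [0.5, 0.5]

    def test_group_mean_relative_theta(self, pseudo_subject_powers):
        # broad-band arithmetic on the study's printed group means:
        # theta / (theta + alpha + beta + delta + gamma) = 0.18644
        broad = pseudo_subject_powers.copy()
        broad.loc[broad["band"] == "alpha_low", "power_uv2"] = 4985.45
        broad.loc[broad["band"] == "beta_low", "power_uv2"] = 1792.57
        broad.loc[broad["band"] == "gamma_low", "power_uv2"] = 693.70
        included = ["delta", "theta", "alpha_low", "beta_low", "gamma_low"]
        out = relative_power(broad, included)
        theta_rp = out.loc[out["band"] == "theta", "relative_power"].iloc[0]
        assert theta_rp == pytest.approx(0.18644, abs=5e-5)
        in_set = out["band"].isin(included)
        assert out.loc[in_set, "relative_power"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_power_names_key(self):
        table = pd.DataFrame(
            {
                "subject": ["s9"], "condition": ["c"], "channel": ["Cz"],
                "band": ["theta"], "power_uv2": [0.0],
            }
        )
        with pytest.raises(UndefinedRatioError, match="s9"):
            relative_power(table, ["theta"])

    @pytest.mark.parametrize(
        "power, base, expected", [(1.0, "e", 0.0), (100.0, "10", 2.0)]
    )
    def test_log_transform_values(self, power, base, expected):
        table = pd.DataFrame(
            {
                "subject": ["s"], "condition": ["c"], "channel": ["Cz"],
                "band": ["theta"], "power_uv2": [power],
            }
        )
        assert log_transform(table, base)["log_power"].iloc[0] == expected

    def test_log_preserves_rank_order(self, pseudo_subject_powers):
        out = log_transform(pseudo_subject_powers)
        assert (
            out["power_uv2"].rank().tolist() == out["log_power"].rank().tolist()
        )

    def test_log_of_nonpositive_power_rejected(self):
        table = pd.DataFrame(
            {
                "subject": ["s"], "condition": ["c"], "channel": ["Cz"],
                "band": ["theta"], "power_uv2": [0.0],
            }
        )
        with pytest.raises(DomainError):
            log_transform(table)
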