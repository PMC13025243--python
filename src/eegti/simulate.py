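"""Synthetic eyes-closed EEG with known band structure, artifacts and effects.

Each channel is a sum of band-limited Gaussian noise processes (one per
canonical band) plus a 1/f^γ background, so that every band's true variance
is known exactly. Between-subject variation is log-normal on each band's
variance, reproducing the right-skewed raw-power distributions typical of
resting EEG. A two-condition study applies a multiplicative ``(1+ε)`` boost
to the theta and alpha-band variances in the first condition, which shifts
the true theta–alpha/beta log-ratio index by exactly ``ln(1+ε)`` — an
analytic identity the pipeline can be checked against.

Default band-variance means keep the *proportions* of group-mean band powers
reported for this kind of portable eyes-closed recording, rescaled to a
physiological ~11 µV RMS total (device power units are arbitrary; a ratio
index is invariant to the overall scale, while amplitude-threshold artifact
screening is not).

Artifacts are injected on demand: 500 µV biphasic 100 ms spikes and 0.5 s
bursts of 40–110 Hz noise at 30 µV RMS, with an exact injection log for
screening-sensitivity checks. Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import signal

from .bands import PAPER_BANDS, TI_DENOMINATOR, TI_NUMERATOR, BandDefinition
from .exceptions import ParameterError
from .io import DEFAULT_MONTAGE, Recording, write_covariates, write_edf

#: Group-mean band variances (µV²): printed group-mean proportions at ~11 µV RMS.
DEFAULT_BAND_MEANS: dict[str, float] = {
    "delta": 9327.87 / 250.0,
    "theta": 3849.94 / 250.0,
    "alpha_low": 5469.42 / 250.0,
    "alpha_high": 4729.73 / 250.0,
    "beta_low": 2109.69 / 250.0,
    "beta_high": 1415.47 / 250.0,
    "gamma_low": 943.36 / 250.0,
    "gamma_high": 478.68 / 250.0,
}

#: Covariate population means/SDs used when planting correlations.
DEFAULT_COVARIATES: dict[str, tuple[float, float]] = {
    "anxiety": (5.59, 4.96),
    "autonomy": (74.28, 12.92),
    "extraversion": (72.26, 12.13),
    "agreeableness": (79.05, 9.08),
    "conscientiousness": (70.41, 10.05),
    "emotional_stability": (64.49, 13.68),
}

SPIKE_AMPLITUDE_UV = 500.0
SPIKE_DURATION_S = 0.1
EMG_RMS_UV = 30.0
EMG_DURATION_S = 0.5
EMG_BAND = (40.0, 110.0)


@dataclass
class StudySimSpec:
    """Parameters of a simulated two-condition eyes-closed study."""

    n_subjects: int = 39
    fs: float = 250.0
    n_channels: int = 8
    block_s: float = 300.0
    band_power_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_MEANS)
    )
    subject_sd_log: float = 0.4
    condition_effect: float = 0.25  # (1+eps) on theta/alpha in conditions[0]
    background_exponent: float = 1.0
    background_fraction: float = 0.10
    artifact_spike_rate: float = 0.0  # expected spike epochs per block
    artifact_emg_rate: float = 0.0
    posterior_alpha_gain: float = 1.0
    conditions: tuple[str, str] = ("prayer", "relaxation")
    epoch_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition_effect <= -1:
            raise ParameterError("condition_effect must exceed -1")
        if any(v <= 0 for v in self.band_power_means.values()):
            raise ParameterError("band power means must be positive")
        if self.artifact_spike_rate < 0 or self.artifact_emg_rate < 0:
            raise ParameterError("artifact rates must be non-negative")

    @property
    def channel_labels(self) -> tuple[str, ...]:
        if self.n_channels == len(DEFAULT_MONTAGE):
            return DEFAULT_MONTAGE
        return tuple(f"ch{i:02d}" for i in range(self.n_channels))

    @property
    def n_epochs(self) -> int:
        return int(self.block_s // self.epoch_s)


def paper_like_artifacts(spec: StudySimSpec) -> StudySimSpec:
    """Preset with a ~10% expected artifact load (half spikes, half EMG)."""
    out = StudySimSpec(**{**spec.__dict__})
    out.artifact_spike_rate = 0.05 * spec.n_epochs
    out.artifact_emg_rate = 0.05 * spec.n_epochs
    return out


def _rng(spec_seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, *keys]))


def make_band_signal(
    band: BandDefinition,
    variance: float,
    duration_s: float,
    fs: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Band-limited Gaussian noise with exact sample variance ``variance``."""
    if variance <= 0:
        raise ParameterError(f"variance must be positive, got {variance}")
    if not (0 < band.f_low < band.f_high < fs / 2):
        raise ParameterError(
            f"band [{band.f_low}, {band.f_high}) outside (0, Nyquist)"
        )
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    sos = signal.butter(4, [band.f_low, band.f_high], btype="bandpass",
                        fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    x = x - x.mean()
    return x * np.sqrt(variance / np.var(x))


def one_over_f_noise(
    exponent: float,
    variance: float,
    duration_s: float,
    fs: float,
    rng: np.random.Generator,
    f_min: float = 0.5,
) -> np.ndarray:
    """Spectrally shaped 1/f^exponent background, exact sample variance."""
    n = int(round(duration_s * fs))
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs >= f_min
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    x = x - x.mean()
    return x * np.sqrt(variance / np.var(x))


def subject_band_variances(
    spec: StudySimSpec, subject_index: int
) -> dict[str, dict[str, float]]:
    """Per-condition true band variances for one subject (channel-mean level).

    Subject effects are log-normal draws shared across conditions; the first
    condition multiplies theta/alpha variances by ``1 + condition_effect``.
    """
    rng = _rng(spec.seed, 1, subject_index)
    base = {
        name: mean * float(np.exp(spec.subject_sd_log * rng.standard_normal()))
        for name, mean in spec.band_power_means.items()
    }
    boosted = set(TI_NUMERATOR)
    out = {}
    for ci, cond in enumerate(spec.conditions):
        gain = 1.0 + spec.condition_effect if ci == 0 else 1.0
        out[cond] = {
            name: v * (gain if name in boosted else 1.0)
            for name, v in base.items()
        }
    return out


def true_ti(variances: dict[str, float], variant: str = "standard") -> float:
    """Ground-truth index from a band→variance map."""
    num = sum(variances[b] for b in TI_NUMERATOR)
    if variant == "delta":
        num += variances["delta"]
    den = sum(variances[b] for b in TI_DENOMINATOR)
    return float(np.log(num / den))


def simulate_recording(
    spec: StudySimSpec, subject_index: int, condition: str
) -> tuple[Recording, pd.DataFrame]:
    """One subject × condition block plus its ground-truth variance table."""
    if condition not in spec.conditions:
        raise ParameterError(f"unknown condition {condition!r}")
    ci = spec.conditions.index(condition)
    per_cond = subject_band_variances(spec, subject_index)
    variances = per_cond[condition]
    bands = {b.name: b for b in PAPER_BANDS if b.name in variances}
    # background is condition-independent: scaled to the unboosted totals so
    # the condition effect stays a clean multiplicative boost on theta/alpha
    base_total = sum(per_cond[spec.conditions[1]].values())
    bg_var = spec.background_fraction * base_total

    labels = spec.channel_labels
    posterior = {"Pz", "PO7", "Oz", "PO8"}
    samples = np.zeros((spec.n_channels, int(round(spec.block_s * spec.fs))))
    truth_rows = []
    for ch_i, lab in enumerate(labels):
        for b_i, (name, var) in enumerate(sorted(variances.items())):
            v = var
            if (
                name in ("alpha_low", "alpha_high")
                and lab in posterior
                and spec.posterior_alpha_gain != 1.0
            ):
                v = var * spec.posterior_alpha_gain
            rng = _rng(spec.seed, 2, subject_index, ci, ch_i, b_i)
            samples[ch_i] += make_band_signal(
                bands[name], v, spec.block_s, spec.fs, rng
            )
            truth_rows.append({
                "subject": f"s{subject_index:02d}", "condition": condition,
                "channel": lab, "band": name, "true_variance": v,
            })
        rng = _rng(spec.seed, 3, subject_index, ci, ch_i)
        samples[ch_i] += one_over_f_noise(
            spec.background_exponent, bg_var, spec.block_s, spec.fs, rng
        )
    rec = Recording(
        subject_id=f"s{subject_index:02d}",
        condition=condition,
        fs=spec.fs,
        channel_labels=labels,
        samples=samples,
        meta={"synthetic": "true", "seed": str(spec.seed)},
    )
    return rec, pd.DataFrame(truth_rows)


def inject_artifacts(
    rec: Recording,
    spike_rate: float,
    emg_rate: float,
    seed: int,
    epoch_s: float = 2.0,
) -> tuple[Recording, pd.DataFrame]:
    """Add spike/EMG artifacts into randomly chosen epochs; return the log.

    Counts are Poisson draws around the expected rates; epochs are chosen
    without replacement, spikes before EMG. The log lists each contaminated
    epoch index and artifact type.
    """
    if spike_rate < 0 or emg_rate < 0:
        raise ParameterError("artifact rates must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    n_ep_samp = int(round(epoch_s * rec.fs))
    n_epochs = rec.n_samples // n_ep_samp
    n_spike = int(rng.poisson(spike_rate))
    n_emg = int(rng.poisson(emg_rate))
    if n_spike + n_emg > n_epochs:
        raise ParameterError(
            f"{n_spike + n_emg} artifact epochs requested, only "
            f"{n_epochs} epochs available"
        )
    order = rng.permutation(n_epochs)
    spike_eps = np.sort(order[:n_spike])
    emg_eps = np.sort(order[n_spike : n_spike + n_emg])

    out = rec.samples.copy()
    log = []

    spike_n = int(round(SPIKE_DURATION_S * rec.fs))
    t = np.arange(spike_n) / rec.fs
    spike_wave = SPIKE_AMPLITUDE_UV * np.sin(2 * np.pi * t / SPIKE_DURATION_S)
    for ep in spike_eps:
        start = ep * n_ep_samp + int(rng.integers(0, n_ep_samp - spike_n))
        out[:, start : start + spike_n] += spike_wave
        log.append({"epoch_index": int(ep), "type": "spike"})

    emg_n = int(round(EMG_DURATION_S * rec.fs))
    f_hi = min(EMG_BAND[1], 0.96 * rec.fs / 2)
    sos = signal.butter(4, [EMG_BAND[0], f_hi], btype="bandpass",
                        fs=rec.fs, output="sos")
    for ep in emg_eps:
        start = ep * n_ep_samp + int(rng.integers(0, n_ep_samp - emg_n))
        burst = signal.sosfiltfilt(
            sos, rng.standard_normal((rec.n_channels, emg_n)), axis=1
        )
        burst *= EMG_RMS_UV / np.sqrt(np.mean(burst**2, axis=1, keepdims=True))
        out[:, start : start + emg_n] += burst
        log.append({"epoch_index": int(ep), "type": "emg"})

    return rec.copy_with(out), pd.DataFrame(
        log, columns=["epoch_index", "type"]
    )


def iter_recordings(
    spec: StudySimSpec,
) -> Iterator[tuple[Recording, pd.DataFrame, pd.DataFrame]]:
    """Yield (recording, ground truth, artifact log) for every block in turn."""
    for s in range(spec.n_subjects):
        for cond in spec.conditions:
            rec, truth = simulate_recording(spec, s, cond)
            if spec.artifact_spike_rate > 0 or spec.artifact_emg_rate > 0:
                art_seed = int(
                    np.random.SeedSequence(
                        [spec.seed, 5, s, spec.conditions.index(cond)]
                    ).generate_state(1)[0] % (2**31)
                )
                rec, log = inject_artifacts(
                    rec, spec.artifact_spike_rate, spec.artifact_emg_rate,
                    art_seed, spec.epoch_s,
                )
            else:
                log = pd.DataFrame(columns=["epoch_index", "type"])
            yield rec, truth, log


def simulate_covariates(
    spec: StudySimSpec,
    planted_rho: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-subject covariate table with chosen true correlations to true TI.

    Each covariate is ``rho·z(TI) + sqrt(1-rho²)·noise`` rescaled to a
    realistic mean/SD; the default plant is the all-null table used for
    type-I checks. The reference TI is the subject's true standard index
    averaged over conditions.
    """
    planted_rho = planted_rho or {}
    ti_true = np.array([
        np.mean([
            true_ti(v) for v in subject_band_variances(spec, s).values()
        ])
        for s in range(spec.n_subjects)
    ])
    z_ti = (ti_true - ti_true.mean()) / ti_true.std(ddof=1)
    rng = _rng(spec.seed, 6)
    rows: dict[str, np.ndarray] = {}
    for name, (mu, sd) in DEFAULT_COVARIATES.items():
        rho = float(planted_rho.get(name, 0.0))
        if not -1 <= rho <= 1:
            raise ParameterError(f"planted correlation for {name!r} outside [-1, 1]")
        noise = rng.standard_normal(spec.n_subjects)
        latent = rho * z_ti + np.sqrt(1 - rho**2) * noise
        rows[name] = mu + sd * latent
    out = pd.DataFrame(rows)
    out.insert(0, "subject", [f"s{i:02d}" for i in range(spec.n_subjects)])
    out["ti_true"] = ti_true
    return out


def simulate_study(
    spec: StudySimSpec,
    out_dir: str | Path,
    planted_rho: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Write a full study to disk: EDF blocks, ground truth, covariates.

    Returns the manifest (subject, condition, path). Deterministic per seed:
    identical spec + seed produce bit-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest, truths, logs = [], [], []
    for rec, truth, log in iter_recordings(spec):
        path = out_dir / f"{rec.subject_id}_{rec.condition}.edf"
        write_edf(rec, path)
        manifest.append({
            "subject": rec.subject_id, "condition": rec.condition,
            "path": str(path),
        })
        truths.append(truth)
        log = log.copy()
        log["subject"], log["condition"] = rec.subject_id, rec.condition
        logs.append(log)
    pd.concat(truths).to_csv(out_dir / "ground_truth.tsv", sep="\t",
                             index=False, lineterminator="\n")
    pd.concat(logs).to_csv(out_dir / "artifact_log.tsv", sep="\t",
                           index=False, lineterminator="\n")
    write_covariates(simulate_covariates(spec, planted_rho),
                     out_dir / "covariates.tsv")
    manifest_df = pd.DataFrame(manifest)
    manifest_df.to_csv(out_dir / "manifest.tsv", sep="\t", index=False,
                       lineterminator="\n")
    return manifest_df
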