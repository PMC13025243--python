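"""Domain containers and file I/O.

The in-memory currency of the pipeline is:

* :class:`Recording` — a labelled multichannel time series in µV;
* a *feature table* — a long-format :class:`pandas.DataFrame` with one row per
  (subject, condition, channel, band), see :data:`FEATURE_COLUMNS`;
* a *covariate table* — one row per subject with named numeric columns,
  missing cells serialized as ``NA``.

EDF/EDF+ files are read through :mod:`mne`; writing uses a minimal EDF encoder
(16-bit, one-second records) sufficient for the synthetic recordings this
package produces. All readers convert samples to µV on ingest so that every
downstream quantity is in µV²; unknown physical dimensions pass through with a
``unit_warning`` entry in :attr:`Recording.meta`.
"""

from __future__ import annotations

import datetime as _dt
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParameterError, ParseError

#: Electrode labels of the 8-channel portable montage used by default.
DEFAULT_MONTAGE = ("Fz", "C3", "Cz", "C4", "Pz", "PO7", "Oz", "PO8")

#: Standard 10-20 / 10-10 scalp labels recognised by montage validation.
TEN_TWENTY_LABELS = frozenset(
    "Fp1 Fp2 Fpz F7 F3 Fz F4 F8 FC5 FC1 FCz FC2 FC6 T7 T3 C3 Cz C4 T8 T4 "
    "CP5 CP1 CPz CP2 CP6 P7 T5 P3 Pz P4 P8 T6 PO7 PO3 POz PO4 PO8 O1 Oz O2 "
    "A1 A2 M1 M2 AFz AF3 AF4 F1 F2 F5 F6 C1 C2 C5 C6 P1 P2 P5 P6".split()
)

FEATURE_COLUMNS = ("subject", "condition", "channel", "band", "power_uv2")
OPTIONAL_FEATURE_COLUMNS = (
    "relative_power",
    "log_power",
    "low_confidence",
    "n_bands_included",
)


@dataclass
class Recording:
    """A multichannel EEG block (channels × samples, µV)."""

    subject_id: str
    condition: str
    fs: float
    channel_labels: tuple[str, ...]
    samples: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ParameterError("samples must be a channels x time matrix")
        self.channel_labels = tuple(self.channel_labels)
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ParameterError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.samples.shape[0]} sample rows"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("recording contains non-finite sample values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, samples: np.ndarray) -> "Recording":
        return Recording(
            subject_id=self.subject_id,
            condition=self.condition,
            fs=self.fs,
            channel_labels=self.channel_labels,
            samples=samples,
            meta=dict(self.meta),
        )


def validate_montage(rec: Recording) -> list[str]:
    """Return advisory warnings for labels outside the 10-20/10-10 scheme.

    Validation never raises: unconventional labels are legal, they just
    forfeit topographic interpretation (e.g. posterior channel subsets).
    """
    return [
        f"channel label {lab!r} is not a recognised 10-20 site"
        for lab in rec.channel_labels
        if lab not in TEN_TWENTY_LABELS
    ]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_HEADER = struct.Struct("<8s80s80s8s8s8s44s8s8s4s")


def _read_edf_header(path: Path) -> dict:
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        parts = _EDF_HEADER.unpack(fixed)
        try:
            n_signals = int(parts[9].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(
                f"{path}: invalid 'number of signals' header field"
            ) from exc
        record_dur = float(parts[8].decode("ascii").strip() or "1")

        def fields(width: int) -> list[str]:
            raw = fh.read(width * n_signals)
            return [
                raw[i * width : (i + 1) * width].decode("ascii", "replace").strip()
                for i in range(n_signals)
            ]

        labels = fields(16)
        fields(80)  # transducer
        dims = fields(8)
        fields(8)  # physical min
        fields(8)  # physical max
        fields(8)  # digital min
        fields(8)  # digital max
        fields(80)  # prefiltering
        ns_per_record = fields(8)
    return {
        "labels": labels,
        "dims": dims,
        "ns_per_record": ns_per_record,
        "record_dur": record_dur,
        "patient": parts[1].decode("ascii", "replace").strip(),
        "recording": parts[2].decode("ascii", "replace").strip(),
    }


def read_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (samples in µV).

    All data signals must share one sampling rate; a mixed-rate file raises
    :class:`FormatError` naming the offending header field. Channels whose
    physical dimension is not a volt unit pass through unscaled with a
    ``unit_warning`` note in ``meta``.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    hdr = _read_edf_header(path)

    data_idx = [i for i, lab in enumerate(hdr["labels"]) if lab != "EDF Annotations"]
    rates = {hdr["ns_per_record"][i] for i in data_idx}
    if len(rates) > 1:
        raise FormatError(
            f"{path}: signals disagree in the 'nr of samples in each data "
            f"record' header field ({sorted(rates)}); a single sampling rate "
            "is required"
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()  # volt-family channels are scaled to volts by mne

    meta: dict = {"source": str(path)}
    volt_units = {"V", "mV", "uV", "µV", "nV"}
    scaled = np.empty_like(data)
    unknown = []
    for i, lab in enumerate(raw.ch_names):
        dim = hdr["dims"][data_idx[i]] if i < len(data_idx) else ""
        if dim in volt_units:
            scaled[i] = data[i] * 1e6  # volts -> µV
        else:
            scaled[i] = data[i]
            unknown.append((lab, dim))
    if unknown:
        meta["unit_warning"] = "; ".join(
            f"channel {lab!r} has physical dimension {dim!r}; passed through "
            "unconverted" for lab, dim in unknown
        )

    subject = hdr["patient"] or "unknown"
    condition = hdr["recording"] or "unknown"
    return Recording(
        subject_id=subject,
        condition=condition,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        samples=scaled,
        meta=meta,
    )


def write_edf(
    rec: Recording,
    path: str | Path,
    physical_range: tuple[float, float] = (-2000.0, 2000.0),
) -> None:
    """Write a recording as 16-bit EDF with one-second data records.

    The sampling rate must be a positive integer and the duration a whole
    number of seconds (both hold for the synthetic blocks this package
    generates). Quantization error is bounded by half an LSB of the declared
    physical range (≈0.03 µV for the ±2000 µV default).
    """
    path = Path(path)
    fs = rec.fs
    if fs != int(fs) or fs <= 0:
        raise ParameterError(f"EDF writer needs an integer sampling rate, got {fs}")
    fs = int(fs)
    if rec.n_samples % fs != 0:
        raise ParameterError(
            "EDF writer needs a whole number of one-second records "
            f"({rec.n_samples} samples at {fs} Hz)"
        )
    pmin, pmax = physical_range
    if not pmin < pmax:
        raise ParameterError("physical_range must be increasing")
    lo, hi = float(np.min(rec.samples)), float(np.max(rec.samples))
    if lo < pmin or hi > pmax:
        raise ParameterError(
            f"samples span [{lo:.1f}, {hi:.1f}] µV, outside the declared "
            f"physical range [{pmin}, {pmax}]"
        )

    n_records = rec.n_samples // fs
    ns = rec.n_channels
    dmin, dmax = -32768, 32767
    now = _dt.datetime(2000, 1, 1)

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii", "replace")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad(rec.subject_id, 80),
            pad(rec.condition, 80),
            pad(now.strftime("%d.%m.%y"), 8),
            pad(now.strftime("%H.%M.%S"), 8),
            pad(str(256 * (ns + 1)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(ns), 4),
        ]
    )

    def per_signal(width: int, values: list[str]) -> bytes:
        return b"".join(pad(v, width) for v in values)

    header += per_signal(16, list(rec.channel_labels))
    header += per_signal(80, [""] * ns)
    header += per_signal(8, ["uV"] * ns)
    header += per_signal(8, [f"{pmin:g}"] * ns)
    header += per_signal(8, [f"{pmax:g}"] * ns)
    header += per_signal(8, [str(dmin)] * ns)
    header += per_signal(8, [str(dmax)] * ns)
    header += per_signal(80, [""] * ns)
    header += per_signal(8, [str(fs)] * ns)
    header += per_signal(32, [""] * ns)

    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((rec.samples - pmin) * gain + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())  # signal-major within each record


# ---------------------------------------------------------------------------
# Delimited text
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_text_recording(
    path: str | Path,
    fs: float,
    unit_scale: float = 1.0,
    subject_id: str = "unknown",
    condition: str = "unknown",
) -> Recording:
    """Read a delimited sample matrix (one column per channel, header row).

    ``unit_scale`` multiplies every sample to reach µV (use ``1e6`` for data
    stored in volts). Malformed rows raise :class:`ParseError` citing the
    offending data row (1-based, excluding the header).
    """
    path = Path(path)
    if fs <= 0:
        raise ParameterError(f"sampling rate must be positive, got {fs}")
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row = int(np.argmax(bad.any(axis=1).to_numpy())) + 1
        col = bad.columns[bad.iloc[row - 1].to_numpy().argmax()]
        raise ParseError(
            f"{path}: non-numeric cell at data row {row}, column {col!r}"
        )
    if numeric.isna().to_numpy().any():
        row = int(np.argmax(numeric.isna().any(axis=1).to_numpy())) + 1
        raise ParseError(f"{path}: missing cell at data row {row}")
    samples = numeric.to_numpy(dtype=float).T * unit_scale
    return Recording(
        subject_id=subject_id,
        condition=condition,
        fs=fs,
        channel_labels=tuple(df.columns),
        samples=samples,
        meta={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# Feature and covariate tables
# ---------------------------------------------------------------------------


def validate_feature_table(table: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"feature table missing column(s): {missing}")
    unknown = [
        c
        for c in table.columns
        if c not in FEATURE_COLUMNS + OPTIONAL_FEATURE_COLUMNS
    ]
    if unknown:
        raise FormatError(f"feature table has unknown column(s): {unknown}")
    if (table["power_uv2"] < 0).any():
        raise FormatError("feature table contains negative power values")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Serialize a feature table as UTF-8 TSV at full float precision."""
    if len(table) == 0:
        raise ParameterError("refusing to write an empty feature table")
    validate_feature_table(table)
    table.to_csv(path, sep="\t", index=False, lineterminator="\n", na_rep="NA")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values="NA", keep_default_na=False)
    for col in ("subject", "condition", "channel", "band"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    validate_feature_table(df)
    return df


def write_covariates(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-subject covariate table; missing cells become ``NA``."""
    if table["subject"].duplicated().any():
        raise ParameterError("covariate table has duplicate subject keys")
    table.to_csv(path, sep="\t", index=False, lineterminator="\n", na_rep="NA")


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(Path(path)), na_values="NA",
                     keep_default_na=False)
    if "subject" not in df.columns:
        raise FormatError(f"{path}: covariate table needs a 'subject' column")
    df["subject"] = df["subject"].astype(str)
    if df["subject"].duplicated().any():
        raise FormatError(f"{path}: duplicate subject keys")
    return df
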