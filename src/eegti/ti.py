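"""The Transcendence Index and its within-subject condition contrast.

The standard index for one subject and condition is the natural log of the
ratio of theta-plus-alpha power to combined beta power,

    TI = ln[ (P_theta + P_alpha_low + P_alpha_high) / (P_beta_low + P_beta_high) ],

and the delta-augmented variant adds delta power to the numerator. Because it
is a ratio of powers from the same spectrum, TI is invariant to global
amplitude scaling of the recording and identical whether absolute or relative
band powers are supplied.

Channel handling: band powers are aggregated across channels *before* the
ratio (default: mean over all channels; a posterior subset Pz/PO7/Oz/PO8 is
available for topographic sensitivity analyses).

The condition contrast is a paired t-test on within-subject TI differences
with the paired-design effect size d = t/√n and the normal-approximation 95%
interval d ± 1.96·√(1/n + d²/2n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bands import (
    PAPER_BANDS,
    TI_DELTA,
    TI_DENOMINATOR,
    TI_NUMERATOR,
    band_set_hash,
)
from .exceptions import (
    AlignmentError,
    DegenerateCaseError,
    DomainError,
    MissingBandError,
    ParameterError,
)

#: Posterior channel subset echoing eyes-closed posterior alpha topography.
POSTERIOR_CHANNELS = ("Pz", "PO7", "Oz", "PO8")

AGGREGATED_CHANNEL = "pooled"


@dataclass(frozen=True)
class PairedContrast:
    """Paired t-test summary for a two-condition within-subject design."""

    n: int
    t: float
    df: int
    p: float
    d: float
    d_ci: tuple[float, float]


def aggregate_channels(
    table: pd.DataFrame,
    method: str = "mean",
    channels: list[str] | None = None,
) -> pd.DataFrame:
    """Reduce per-channel band powers to one value per (subject, condition, band).

    ``method`` is ``"mean"`` or ``"median"``; ``channels`` optionally restricts
    the reduction to a subset (e.g. :data:`POSTERIOR_CHANNELS`). The output
    keeps the feature-table schema with the channel column set to
    ``"pooled"``.
    """
    if method not in ("mean", "median"):
        raise ParameterError(f"unknown aggregation method {method!r}")
    sub = table
    if channels is not None:
        if len(channels) == 0:
            raise ParameterError("empty channel subset")
        sub = table[table["channel"].isin(channels)]
        found = set(sub["channel"])
        missing = set(channels) - found
        if missing:
            raise ParameterError(f"channels not present in table: {sorted(missing)}")
    value_cols = [c for c in ("power_uv2", "relative_power", "log_power")
                  if c in sub.columns]
    agg = (
        sub.groupby(["subject", "condition", "band"], as_index=False)[value_cols]
        .agg(method)
    )
    agg.insert(2, "channel", AGGREGATED_CHANNEL)
    return agg


def compute_ti(
    table: pd.DataFrame,
    variant: str = "standard",
    use_relative: bool = False,
) -> pd.DataFrame:
    """Compute TI per (subject, condition) from an aggregated band-power table.

    ``variant`` is ``"standard"`` or ``"delta"`` (delta-augmented). If the
    table still carries several channels per key they are mean-aggregated
    first. Returns columns ``subject, condition, ti, variant``, the variant
    tag recording formula, log base and a band-set digest.
    """
    if variant not in ("standard", "delta"):
        raise ParameterError(f"unknown TI variant {variant!r}")
    value_col = "relative_power" if use_relative else "power_uv2"
    if value_col not in table.columns:
        raise ParameterError(f"table has no {value_col!r} column")

    if table.groupby(["subject", "condition", "band"])["channel"].nunique().max() > 1:
        table = aggregate_channels(table)

    numerator_bands = list(TI_NUMERATOR)
    if variant == "delta":
        numerator_bands = [TI_DELTA] + numerator_bands
    needed = numerator_bands + list(TI_DENOMINATOR)

    wide = table.pivot_table(
        index=["subject", "condition"], columns="band", values=value_col,
        aggfunc="first",
    )
    missing = [b for b in needed if b not in wide.columns or wide[b].isna().any()]
    if missing:
        raise MissingBandError(
            f"band(s) {missing} required for the {variant} index are missing"
        )
    vals = wide[needed]
    if (vals <= 0).any().any():
        raise DomainError("non-positive band power; the log-ratio is undefined")

    num = wide[numerator_bands].sum(axis=1)
    den = wide[list(TI_DENOMINATOR)].sum(axis=1)
    ti = np.log(num / den)

    tag = (
        f"{variant}|log=e|agg=mean|bands={band_set_hash(PAPER_BANDS)}"
        + ("|relative" if use_relative else "")
    )
    out = ti.rename("ti").reset_index()
    out["variant"] = tag
    return out


def delta_increment(table: pd.DataFrame) -> pd.Series:
    """Exact gap TI_delta − TI_standard = ln(1 + P_delta/(P_theta+P_alpha))."""
    wide = table.pivot_table(
        index=["subject", "condition"], columns="band", values="power_uv2",
        aggfunc="mean",
    )
    num = wide[list(TI_NUMERATOR)].sum(axis=1)
    return np.log1p(wide[TI_DELTA] / num)


def paired_contrast(ti_a: pd.Series, ti_b: pd.Series) -> PairedContrast:
    """Paired t-test of condition A minus condition B on subject-aligned TI.

    Both inputs are indexed by subject id. Effect size is the paired-design
    Cohen's d = t/√n with its normal-approximation 95% CI.
    """
    a = pd.Series(ti_a).astype(float)
    b = pd.Series(ti_b).astype(float)
    if set(a.index) != set(b.index):
        raise AlignmentError(
            "subject sets differ between conditions: "
            f"{sorted(set(a.index) ^ set(b.index))}"
        )
    b = b.reindex(a.index)
    n = len(a)
    if n < 3:
        raise ParameterError(f"need at least 3 paired subjects, got {n}")
    diff = a.to_numpy() - b.to_numpy()
    if np.allclose(diff.std(ddof=1), 0):
        # identical conditions: the no-effect case, not an error
        if np.allclose(diff.mean(), 0):
            se0 = math.sqrt(1.0 / n)
            return PairedContrast(n=n, t=0.0, df=n - 1, p=1.0, d=0.0,
                                  d_ci=(-1.96 * se0, 1.96 * se0))
        raise DegenerateCaseError(
            "constant nonzero differences; t statistic diverges"
        )
    res = sps.ttest_rel(a.to_numpy(), b.to_numpy())
    t = float(res.statistic)
    d = t / math.sqrt(n)
    se = math.sqrt(1.0 / n + d * d / (2.0 * n))
    return PairedContrast(
        n=n, t=t, df=n - 1, p=float(res.pvalue), d=d,
        d_ci=(d - 1.96 * se, d + 1.96 * se),
    )


def contrast_from_ti_table(
    ti_table: pd.DataFrame, condition_a: str, condition_b: str
) -> PairedContrast:
    """Run :func:`paired_contrast` on a long TI table (subject, condition, ti)."""
    pivot = ti_table.pivot_table(index="subject", columns="condition",
                                 values="ti", aggfunc="first")
    for cond in (condition_a, condition_b):
        if cond not in pivot.columns:
            raise AlignmentError(f"condition {cond!r} absent from TI table")
    sub = pivot[[condition_a, condition_b]].dropna()
    return paired_contrast(sub[condition_a], sub[condition_b])
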