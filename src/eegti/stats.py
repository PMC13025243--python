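"""Descriptive and correlational statistics with FDR control.

Conventions follow mainstream social-science reporting: sample (n−1) standard
deviation, small-sample-adjusted Fisher–Pearson skewness G1 and excess
kurtosis G2, two-tailed Pearson correlations with pairwise deletion, and
Benjamini–Hochberg step-up FDR applied within each declared correlation
family (one family per correlation table).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import DomainError, InsufficientDataError
from .ti import PairedContrast


@dataclass(frozen=True)
class Descriptives:
    n: int
    mean: float
    sd: float
    median: float
    minimum: float
    maximum: float
    skewness: float  # NaN when undefined (constant input)
    excess_kurtosis: float
    degenerate: bool = False  # True when sd == 0


@dataclass
class CorrelationReport:
    """Pairwise-complete correlation family with BH-FDR annotation."""

    family_id: str
    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    p_adjusted: pd.DataFrame
    fdr_flags: pd.DataFrame
    q: float


def describe(values) -> Descriptives:
    """Descriptive statistics over the non-missing entries of ``values``."""
    x = pd.Series(values, dtype=float).dropna().to_numpy()
    if len(x) < 2:
        raise InsufficientDataError(
            f"need at least 2 non-missing values, got {len(x)}"
        )
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        skew = kurt = float("nan")
    else:
        skew = float(sps.skew(x, bias=False))
        kurt = float(sps.kurtosis(x, fisher=True, bias=False))
    return Descriptives(
        n=len(x),
        mean=float(np.mean(x)),
        sd=sd,
        median=float(np.median(x)),
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        skewness=skew,
        excess_kurtosis=kurt,
        degenerate=sd == 0,
    )


def describe_table(df: pd.DataFrame) -> pd.DataFrame:
    """Row-per-variable descriptives for every numeric column of ``df``."""
    rows = []
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            continue
        d = describe(df[col])
        rows.append({"variable": col, "n": d.n, "mean": d.mean, "sd": d.sd,
                     "median": d.median, "min": d.minimum, "max": d.maximum,
                     "skewness": d.skewness, "excess_kurtosis": d.excess_kurtosis})
    return pd.DataFrame(rows)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (rejection flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise DomainError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def pearson_matrix(
    df: pd.DataFrame, family_id: str, q: float = 0.05
) -> CorrelationReport:
    """Two-tailed Pearson correlations with pairwise deletion and BH-FDR.

    Every numeric column enters the family. A pair with fewer than 3 complete
    observations is reported as missing (NaN), never fabricated; its cell is
    excluded from the FDR family.
    """
    cols = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i, ci in enumerate(cols):
        n[i, i] = int(df[ci].notna().sum())
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            sub = df[[cols[i], cols[j]]].dropna()
            n[i, j] = n[j, i] = len(sub)
            if len(sub) < 3:
                continue
            res = sps.pearsonr(sub[cols[i]], sub[cols[j]])
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
            pairs.append((i, j))

    p_adj = np.full((k, k), np.nan)
    flags = np.zeros((k, k), dtype=bool)
    if pairs:
        family_p = [p[i, j] for i, j in pairs]
        rej, adj = bh_fdr(family_p, q=q)
        for (i, j), fr, fa in zip(pairs, rej, adj):
            flags[i, j] = flags[j, i] = bool(fr)
            p_adj[i, j] = p_adj[j, i] = fa

    def frame(arr):
        return pd.DataFrame(arr, index=cols, columns=cols)

    return CorrelationReport(
        family_id=family_id,
        variables=cols,
        r=frame(r),
        p=frame(p),
        n=frame(n),
        p_adjusted=frame(p_adj),
        fdr_flags=frame(flags),
        q=q,
    )


def correlation_long(report: CorrelationReport) -> pd.DataFrame:
    """Lower-triangle pairs with r, p, adjusted p and significance markers.

    ``marker`` distinguishes FDR-surviving pairs (``**fdr``) from
    nominal-only ones (``*nominal``).
    """
    rows = []
    cols = report.variables
    for i in range(len(cols)):
        for j in range(i):
            rv = report.r.iloc[i, j]
            pv = report.p.iloc[i, j]
            if np.isnan(rv):
                marker = "unavailable"
            elif report.fdr_flags.iloc[i, j]:
                marker = "**fdr"
            elif pv < 0.05:
                marker = "*nominal"
            else:
                marker = ""
            rows.append({
                "family": report.family_id,
                "var_a": cols[i],
                "var_b": cols[j],
                "n": int(report.n.iloc[i, j]),
                "r": rv,
                "p": pv,
                "p_fdr": report.p_adjusted.iloc[i, j],
                "marker": marker,
            })
    return pd.DataFrame(rows)


def render_report(
    out_dir: str | Path,
    descriptives: pd.DataFrame | None = None,
    correlations: list[CorrelationReport] | None = None,
    contrast: PairedContrast | None = None,
    metadata: dict | None = None,
) -> list[Path]:
    """Write TSV report tables plus a JSON run-metadata block.

    Empty sections are skipped (with a notice recorded in the metadata file)
    rather than written as empty files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    notices: list[str] = []

    if descriptives is not None and len(descriptives):
        f = out_dir / "descriptives.tsv"
        descriptives.to_csv(f, sep="\t", index=False, lineterminator="\n",
                            na_rep="NA")
        written.append(f)
    else:
        notices.append("descriptives section omitted (no data)")

    for rep in correlations or []:
        long = correlation_long(rep)
        if len(long) == 0:
            notices.append(f"correlation family {rep.family_id!r} omitted (empty)")
            continue
        f = out_dir / f"correlations_{rep.family_id}.tsv"
        long.to_csv(f, sep="\t", index=False, lineterminator="\n", na_rep="NA")
        written.append(f)

    if contrast is not None:
        f = out_dir / "contrast.tsv"
        pd.DataFrame([{
            "n": contrast.n, "t": contrast.t, "df": contrast.df,
            "p": contrast.p, "d": contrast.d,
            "d_ci_low": contrast.d_ci[0], "d_ci_high": contrast.d_ci[1],
        }]).to_csv(f, sep="\t", index=False, lineterminator="\n")
        written.append(f)

    meta = dict(metadata or {})
    meta["notices"] = notices
    f = out_dir / "run_metadata.json"
    f.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    written.append(f)
    return written
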