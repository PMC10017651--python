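"""Cohort statistics for longitudinal lung-function and shrinkage data.

Implements the analysis plan of a two-visit fibrosis cohort: a
functional-deterioration rule on percent-predicted lung function
(>= 10 percentage-point FVC% decline or >= 15 percentage-point DLco%
decline between visits), nonparametric two-group comparisons
(Mann-Whitney, Fisher exact), Spearman rank correlations with a banded
interpretation of |r|, and median-(IQR) summary tables.

Conventions stated once: all tests are two-sided at alpha = 0.05;
medians and IQRs use linear-interpolation quantiles; the deterioration
thresholds are inclusive (a decline of exactly 10 / 15 percentage points
classifies as deteriorated); correlation bands are right-open intervals
[0, 0.2), [0.2, 0.4), [0.4, 0.6), [0.6, 0.8), [0.8, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

FVC_DECLINE_THRESHOLD = 10.0  # percentage points of percent-predicted FVC
DLCO_DECLINE_THRESHOLD = 15.0  # percentage points of percent-predicted DLco

_BAND_EDGES = (0.2, 0.4, 0.6, 0.8)
_BAND_NAMES = ("poor", "weak", "moderate", "strong", "very strong")


@dataclass
class PFTRecord:
    """Percent-of-predicted lung function at two visits."""

    patient_id: str
    vc_pct_base: float
    vc_pct_follow: float
    fvc_pct_base: float
    fvc_pct_follow: float
    tlc_pct_base: float
    tlc_pct_follow: float
    dlco_pct_base: float
    dlco_pct_follow: float
    interval_months: float | None = None

    def __post_init__(self):
        for name in (
            "vc_pct_base", "vc_pct_follow", "fvc_pct_base", "fvc_pct_follow",
            "tlc_pct_base", "tlc_pct_follow", "dlco_pct_base", "dlco_pct_follow",
        ):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"PFT field {name!r} is missing for {self.patient_id}")
            if v <= 0:
                raise ValueError(f"PFT field {name!r} must be > 0, got {v}")


def classify_functional(
    rec: PFTRecord,
    fvc_threshold: float = FVC_DECLINE_THRESHOLD,
    dlco_threshold: float = DLCO_DECLINE_THRESHOLD,
    relative: bool = False,
) -> str:
    """'deteriorated' or 'stable' by the two-criterion decline rule.

    Declines are absolute percentage-point drops in percent-predicted
    values (``relative=True`` switches to percent-of-baseline declines,
    an alternative convention some groups use).  Boundary declines equal
    to a threshold classify as deteriorated.
    """
    fvc_drop = rec.fvc_pct_base - rec.fvc_pct_follow
    dlco_drop = rec.dlco_pct_base - rec.dlco_pct_follow
    if relative:
        fvc_drop = 100.0 * fvc_drop / rec.fvc_pct_base
        dlco_drop = 100.0 * dlco_drop / rec.dlco_pct_base
    if fvc_drop >= fvc_threshold or dlco_drop >= dlco_threshold:
        return "deteriorated"
    return "stable"


def classify_cohort(df: pd.DataFrame, **kw) -> pd.Series:
    """Vectorized :func:`classify_functional` over a cohort DataFrame."""
    out = []
    for _, row in df.iterrows():
        rec = PFTRecord(
            patient_id=str(row.get("patient_id", "?")),
            vc_pct_base=row["vc_pct_base"],
            vc_pct_follow=row["vc_pct_follow"],
            fvc_pct_base=row["fvc_pct_base"],
            fvc_pct_follow=row["fvc_pct_follow"],
            tlc_pct_base=row["tlc_pct_base"],
            tlc_pct_follow=row["tlc_pct_follow"],
            dlco_pct_base=row["dlco_pct_base"],
            dlco_pct_follow=row["dlco_pct_follow"],
        )
        out.append(classify_functional(rec, **kw))
    return pd.Series(out, index=df.index, name="functional_group")


# ---------------------------------------------------------------------------
# tests


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact null for small tie-free samples,
    midrank normal approximation with tie correction otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (sum of
    hypergeometric probabilities <= the observed one)."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    r: float
    p: float
    n: int
    band: str

    def __str__(self):
        return (
            f"{self.x_name} vs {self.y_name}: r = {self.r:.3f} "
            f"(p = {self.p:.3g}, n = {self.n}, {self.band})"
        )


def correlation_band(r: float) -> str:
    """Interpretation band of |r|: poor / weak / moderate / strong /
    very strong at cutpoints 0.2, 0.4, 0.6, 0.8 (right-open bins)."""
    a = abs(r)
    for edge, name in zip(_BAND_EDGES, _BAND_NAMES):
        if a < edge:
            return name
    return _BAND_NAMES[-1]


def spearman(
    x: Sequence[float], y: Sequence[float], x_name: str = "x", y_name: str = "y"
) -> CorrelationResult:
    """Spearman rank correlation (Pearson on midranks) with its band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    r, p = sps.spearmanr(x, y)
    return CorrelationResult(x_name, y_name, float(r), float(p), len(x), correlation_band(float(r)))


# ---------------------------------------------------------------------------
# cohort summaries


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation
    return f"{med:.1f} ({q1:.1f} to {q3:.1f})"


def cohort_table(
    df: pd.DataFrame,
    group_col: str,
    continuous: Sequence[str],
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Median (IQR) per group for continuous fields, n (%) for binary
    categorical fields, with two-group p-values (Mann-Whitney / Fisher).

    ``group_col`` must have exactly two levels for p-values; with more
    levels the p column is left blank.
    """
    groups = sorted(df[group_col].dropna().unique())
    rows = []
    two = len(groups) == 2
    for col in continuous:
        x = df[col].astype(float)
        row = {"characteristic": col, "all": _median_iqr(x.to_numpy())}
        for g in groups:
            row[str(g)] = _median_iqr(x[df[group_col] == g].to_numpy())
        if two:
            _, p = mann_whitney(
                x[df[group_col] == groups[0]], x[df[group_col] == groups[1]]
            )
            row["p_value"] = p
        rows.append(row)
    for col in categorical:
        x = df[col].astype(bool)
        row = {
            "characteristic": col,
            "all": f"{int(x.sum())} ({100 * x.mean():.1f})",
        }
        counts = []
        for g in groups:
            sel = x[df[group_col] == g]
            row[str(g)] = f"{int(sel.sum())} ({100 * sel.mean():.1f})"
            counts.append([int(sel.sum()), int((~sel).sum())])
        if two:
            row["p_value"] = fisher_exact(np.array(counts))
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_cohort(
    df: pd.DataFrame,
    target: str = "mean_logjac",
    fields: Sequence[str] | None = None,
) -> list[CorrelationResult]:
    """Spearman correlations of the per-patient mean log-Jacobian against
    lung-function and vessel-change fields."""
    if fields is None:
        fields = [
            c
            for c in df.columns
            if c != target and pd.api.types.is_numeric_dtype(df[c])
        ]
    out = []
    for col in fields:
        sub = df[[target, col]].dropna()
        if len(sub) >= 3 and sub[col].nunique() > 1 and sub[target].nunique() > 1:
            out.append(spearman(sub[target], sub[col], target, col))
    return out


def correlation_report(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x": r.x_name,
                "y": r.y_name,
                "r": r.r,
                "p": r.p,
                "n": r.n,
                "band": r.band,
                "significant": r.p < ALPHA,
            }
            for r in results
        ]
    )
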