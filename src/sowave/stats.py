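"""Group comparison and reporting: Mann-Whitney U, Kolmogorov-Smirnov, cohort tables.

Cohort results are held in a long-format table (animal, group, metric,
value); the report gives mean +/- SEM per group per metric with a two-sided
Mann-Whitney U test (exact null distribution for small tie-free samples,
normal approximation with tie correction otherwise) and significance stars.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["mann_whitney_u", "ks_two_sample", "cohort_table", "cohort_report", "sem"]


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact U null distribution when both samples have n <= 8 and no
    ties, otherwise the normal approximation with tie correction.  Returns
    (U of the first sample, p).  Identical constant samples give p = 1 with
    a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across both samples; p = 1")
        return float(len(a) * len(b) / 2.0), 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test with asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def sem(x) -> float:
    """Standard error of the mean using the sample (n-1) standard deviation."""
    x = np.asarray(x, dtype=float)
    return float(x.std(ddof=1) / np.sqrt(len(x)))


def cohort_table(rows: list[tuple]) -> pd.DataFrame:
    """Long-format cohort table from (animal, group, metric, value) rows."""
    df = pd.DataFrame(rows, columns=["animal", "group", "metric", "value"])
    dup = df.duplicated(["animal", "metric"])
    if dup.any():
        raise ValueError("one value per (animal, metric) required")
    return df


def _stars(p: float) -> str:
    return "**" if p < 0.01 else ("*" if p < 0.05 else "")


def cohort_report(table: pd.DataFrame, group_a: str = "WT",
                  group_b: str = "WBS") -> pd.DataFrame:
    """Per-metric group comparison: mean +/- SEM, Mann-Whitney U p, stars.

    Animals missing a metric are dropped from that metric's comparison with
    a warning.  Output has one row per metric with columns
    mean_a, sem_a, mean_b, sem_b, U, p, stars.
    """
    out = []
    for metric, sub in table.groupby("metric", sort=False):
        va = sub.loc[sub.group == group_a, "value"].dropna().to_numpy()
        vb = sub.loc[sub.group == group_b, "value"].dropna().to_numpy()
        n_dropped = sub["value"].isna().sum()
        if n_dropped:
            warnings.warn(f"{metric}: dropped {n_dropped} animal(s) with missing value")
        if len(va) < 2 or len(vb) < 2:
            warnings.warn(f"{metric}: fewer than 2 animals in a group; skipped")
            continue
        U, p = mann_whitney_u(va, vb)
        out.append({"metric": metric,
                    f"mean_{group_a}": va.mean(), f"sem_{group_a}": sem(va),
                    f"mean_{group_b}": vb.mean(), f"sem_{group_b}": sem(vb),
                    "U": U, "p": p, "stars": _stars(p)})
    return pd.DataFrame(out)


def anterior_posterior_split(values: np.ndarray, positions: np.ndarray,
                             boundary_x: float | None = None) -> dict:
    """Split per-channel values into anterior/posterior means at an x boundary.

    The default boundary is the array midline in x.
    """
    x = positions[:, 0]
    if boundary_x is None:
        boundary_x = 0.5 * (x.min() + x.max())
    return {"anterior": float(np.mean(values[x >= boundary_x])),
            "posterior": float(np.mean(values[x < boundary_x])),
            "boundary_x": float(boundary_x)}
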