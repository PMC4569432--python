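"""Species-level differential abundance and its longitudinal validation.

Per species-level unit: Welch's two-sample t-test on relative abundances
(fixed depth makes counts and proportions equivalent up to scale),
Benjamini-Hochberg adjustment across units, and the case/control log10 fold
change computed with the not-detected convention (a group mean of exactly
zero reads counts as one read so the ratio stays finite).  Units that are
significant cross-sectionally are validated against a longitudinal control
series: the fold change is recomputed against each timepoint's control mean
and its sign compared with the cross-sectional direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mapping import AbundanceTable

ALPHA = 0.05
ND_READS = 1.0


def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's t statistic, Welch-Satterthwaite df and two-sided p.

    Degenerate inputs (zero variance in both groups) yield p = 1 for equal
    means and p = 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(nx + ny - 2), 1.0
        return float(np.inf) * np.sign(x.mean() - y.mean()), float(nx + ny - 2), 0.0
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def log10_fold_change(mean_counts_a: float, mean_counts_b: float,
                      depth: int = 3000, nd_reads: float = ND_READS) -> float:
    """log10(A/B) of group mean read counts with the not-detected rule.

    A group mean of exactly zero is replaced by ``nd_reads`` reads (i.e.
    nd_reads/depth relative abundance) before the ratio, so the fold change
    is always finite.
    """
    if mean_counts_a < 0 or mean_counts_b < 0:
        raise ValueError("mean counts must be non-negative")
    a = mean_counts_a if mean_counts_a > 0 else nd_reads
    b = mean_counts_b if mean_counts_b > 0 else nd_reads
    return float(np.log10(a / b))


def differential_abundance(table: AbundanceTable, case: str = "MS",
                           control: str = "HC", alpha: float = ALPHA,
                           ) -> pd.DataFrame:
    """Per-unit Welch test, BH correction and case/control fold change.

    The significance flag mirrors the raw p < alpha selection; the BH
    q-value is reported alongside for an FDR-controlled reading.
    """
    rel = table.relative
    labels = table.groups
    x_cols = labels.index[labels == case]
    y_cols = labels.index[labels == control]
    if len(x_cols) < 2 or len(y_cols) < 2:
        raise ValueError("each group needs at least two samples")
    rows = []
    for cid in table.counts.index:
        x = rel.loc[cid, x_cols].to_numpy()
        y = rel.loc[cid, y_cols].to_numpy()
        t, df, p = welch_test(x, y)
        fc = log10_fold_change(table.counts.loc[cid, x_cols].mean(),
                               table.counts.loc[cid, y_cols].mean(),
                               depth=table.depth)
        rows.append((cid, x.mean(), y.mean(), fc, t, df, p))
    out = pd.DataFrame(rows, columns=[
        "cluster_id", f"mean_rel_{case}", f"mean_rel_{control}", "log10_fc",
        "t", "df", "p"]).set_index("cluster_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p"] < alpha
    out["significant_q"] = out["q"] < alpha
    return out.sort_values("log10_fc", ascending=False)


@dataclass
class LongitudinalCheck:
    cluster_id: str
    timepoint_fc: pd.Series      # timepoint -> log10 fold change vs case mean
    sign_consistency: float      # fraction matching the cross-sectional sign


def longitudinal_validation(case_mean_counts: pd.Series,
                            cross_fc: pd.Series,
                            long_counts: pd.DataFrame,
                            timepoints: pd.Series,
                            depth: int = 3000,
                            ) -> list[LongitudinalCheck]:
    """Per-timepoint fold changes of the case mean against control means.

    ``case_mean_counts`` holds the cross-sectional case group's mean read
    count per unit, ``cross_fc`` the cross-sectional log10 fold changes whose
    sign is the validation reference, ``long_counts`` the unit x sample
    counts of the longitudinal control series and ``timepoints`` each
    longitudinal sample's timepoint.  Samples with a missing timepoint
    label simply do not contribute to that timepoint's mean.
    """
    timepoints = timepoints.reindex(long_counts.columns)
    checks: list[LongitudinalCheck] = []
    tps = sorted(t for t in timepoints.dropna().unique())
    for cid in cross_fc.index:
        fcs = {}
        for tp in tps:
            cols = timepoints.index[timepoints == tp]
            if len(cols) == 0:
                continue
            hc_mean = long_counts.loc[cid, cols].mean() if cid in long_counts.index else 0.0
            fcs[tp] = log10_fold_change(case_mean_counts[cid], hc_mean,
                                        depth=depth)
        series = pd.Series(fcs, name=cid)
        ref_sign = np.sign(cross_fc[cid])
        agree = float((np.sign(series) == ref_sign).mean()) if len(series) else 0.0
        checks.append(LongitudinalCheck(cid, series, agree))
    return checks


def longitudinal_frame(checks: list[LongitudinalCheck]) -> pd.DataFrame:
    """Long-format (cluster, timepoint, log10_fc) table plus consistency."""
    rows = []
    for c in checks:
        for tp, fc in c.timepoint_fc.items():
            rows.append((c.cluster_id, tp, fc, c.sign_consistency))
    return pd.DataFrame(rows, columns=["cluster_id", "timepoint", "log10_fc",
                                       "sign_consistency"])
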