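"""Per-cell reliability (ICC) and reproducibility (RMSSD) of repeated
standardized BMD maps, with between-setting comparisons.

Reliability is the two-way random-effects intraclass correlation for a
single measurement with absolute agreement, ICC(2,1):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

with n subjects (knees), k repeats, and MSR/MSC/MSE the row, column and
residual mean squares of the two-way ANOVA.  Reproducibility is the
precision error RMSSD: the root mean square over knees of the per-knee
standard deviation across repeats.  Settings are compared per cell with
two-sided Wilcoxon signed-rank tests (normal approximation, zeros
dropped, no continuity correction), Bonferroni-adjusted over the three
pairwise comparisons, with effect size r = |z| / sqrt(N).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RepeatedMeasures",
    "ReliabilityResult",
    "icc_two_way_random",
    "classify_icc",
    "rmssd",
    "compare_settings",
    "evaluate_settings",
]

ICC_CLASSES = ("poor", "moderate", "good", "excellent")


@dataclass
class RepeatedMeasures:
    """BMD values as a cells x knees x repeats array; NaN marks missing.

    The method's evaluation design is 10 knees scanned/segmented twice
    per setting; any n_knees >= 2, n_repeats >= 2 is accepted.
    """

    values: np.ndarray
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise ValueError("values must be cells x knees x repeats")
        if self.values.shape[2] < 2:
            raise ValueError("need at least 2 repeats")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 knees")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.values.shape[0])
        else:
            self.cell_ids = np.asarray(self.cell_ids)
            if len(self.cell_ids) != self.values.shape[0]:
                raise ValueError("cell_ids length mismatch")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


def icc_two_way_random(cell_values: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measurement, on an n_knees x k_repeats matrix without missing
    entries.  Returns NaN when the total variance is zero (degenerate:
    the coefficient is undefined)."""
    x = np.asarray(cell_values, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an (n >= 2) x (k >= 2) matrix")
    if np.isnan(x).any():
        raise ValueError("missing entries must be excluded before ICC")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    if ss_total == 0.0:
        return float("nan")
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        return float("nan")
    return float((msr - mse) / denom)


def classify_icc(icc: float) -> str:
    """Reliability class: poor < 0.5 <= moderate < 0.75 <= good < 0.9,
    excellent above; the 0.9 boundary is assigned to excellent."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite to classify")
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def rmssd(cell_values: np.ndarray) -> float:
    """Precision error: sqrt(mean over knees of the per-knee sample
    variance (ddof=1) across repeats), in the units of the input."""
    x = np.asarray(cell_values, float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 repeats per knee")
    if np.isnan(x).any():
        raise ValueError("missing entries must be excluded before RMSSD")
    sd2 = x.var(axis=1, ddof=1)
    return float(np.sqrt(sd2.mean()))


def compare_settings(
    map_a_cells: np.ndarray,
    map_b_cells: np.ndarray,
    n_comparisons: int = 3,
    exact: bool = False,
):
    """Two-sided Wilcoxon signed-rank test on paired per-cell metrics.

    Returns (z, p_raw, p_adjusted, effect_size) with zeros dropped,
    average ranks for ties, no continuity correction, Bonferroni
    p_adjusted = min(1, n_comparisons * p_raw) and r = |z| / sqrt(N)
    where N counts the non-zero pairs.  ``exact=True`` switches the
    p-value to the exact permutation null (no ties/zeros only).
    """
    a = np.asarray(map_a_cells, float)
    b = np.asarray(map_b_cells, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, 1.0, 0.0
    res = sps.wilcoxon(
        d,
        zero_method="wilcox",
        correction=False,
        alternative="two-sided",
        method="exact" if exact else "approx",
    )
    if exact:
        # z from the normal approximation for the effect size
        za = sps.wilcoxon(
            d, zero_method="wilcox", correction=False,
            alternative="two-sided", method="approx",
        )
        z = float(za.zstatistic)
    else:
        z = float(res.zstatistic)
    p_raw = float(res.pvalue)
    p_adj = min(1.0, n_comparisons * p_raw)
    r = abs(z) / np.sqrt(n)
    return z, p_raw, p_adj, float(r)


@dataclass
class ReliabilityResult:
    """Per-cell and summary reliability/reproducibility of one run.

    per_cell : DataFrame with columns setting, cell_id, icc, icc_class,
        rmssd (NaN icc marks degenerate zero-variance cells).
    summary : DataFrame with per-setting medians/quartiles and the
        fraction of cells in each ICC class.
    comparisons : DataFrame with the pairwise setting tests for both
        metrics (z, p_raw, p_adjusted, effect_size).
    """

    per_cell: pd.DataFrame
    summary: pd.DataFrame
    comparisons: pd.DataFrame


def _per_cell_metrics(rm: RepeatedMeasures) -> pd.DataFrame:
    rows = []
    for c in range(rm.n_cells):
        mat = rm.values[c]
        complete = ~np.isnan(mat).any(axis=1)  # complete-case per cell
        sub = mat[complete]
        if len(sub) < 2:
            rows.append((rm.cell_ids[c], np.nan, None, np.nan, 0))
            continue
        icc = icc_two_way_random(sub)
        cls = classify_icc(icc) if np.isfinite(icc) else None
        rows.append((rm.cell_ids[c], icc, cls, rmssd(sub), len(sub)))
    return pd.DataFrame(
        rows, columns=["cell_id", "icc", "icc_class", "rmssd", "n_knees_used"]
    )


def evaluate_settings(
    measures: dict[str, RepeatedMeasures],
    exact_wilcoxon: bool = False,
) -> ReliabilityResult:
    """Evaluate reliability/reproducibility for each experimental
    setting (e.g. intra-operator/inter-scan, inter-operator/intra-scan,
    inter-operator/inter-scan) and compare the settings pairwise.

    All settings must share the same cell grid (identical cell ids).
    """
    if len(measures) < 1:
        raise ValueError("need at least one setting")
    ids = None
    for name, rm in measures.items():
        if ids is None:
            ids = np.asarray(rm.cell_ids)
        elif rm.values.shape[0] != len(ids) or not np.array_equal(
            np.asarray(rm.cell_ids), ids
        ):
            raise ValueError(f"setting {name!r} is on a different cell grid")

    per_cell_frames = []
    for name, rm in measures.items():
        df = _per_cell_metrics(rm)
        df.insert(0, "setting", name)
        per_cell_frames.append(df)
    per_cell = pd.concat(per_cell_frames, ignore_index=True)

    summaries = []
    for name in measures:
        df = per_cell[per_cell["setting"] == name]
        icc = df["icc"].to_numpy()
        valid = np.isfinite(icc)
        rms = df["rmssd"].to_numpy()
        rms_valid = np.isfinite(rms)
        row = {"setting": name, "n_cells": len(df), "n_degenerate": int((~valid).sum())}
        for label, v in (("icc", icc[valid]), ("rmssd", rms[rms_valid])):
            if len(v):
                q1, med, q3 = np.percentile(v, [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            row.update({f"{label}_median": med, f"{label}_q1": q1, f"{label}_q3": q3})
        row["frac_excellent"] = (
            float(np.mean(icc[valid] > 0.9)) if valid.any() else np.nan
        )
        for cls in ICC_CLASSES:
            row[f"frac_{cls}"] = float((df["icc_class"] == cls).mean())
        summaries.append(row)
    summary = pd.DataFrame(summaries)

    pairs = list(itertools.combinations(measures.keys(), 2))
    comp_rows = []
    for metric in ("icc", "rmssd"):
        for a, b in pairs:
            va = per_cell[per_cell["setting"] == a].set_index("cell_id")[metric]
            vb = per_cell[per_cell["setting"] == b].set_index("cell_id")[metric]
            common = va.index.intersection(vb.index)
            z, p, p_adj, r = compare_settings(
                va.loc[common].to_numpy(),
                vb.loc[common].to_numpy(),
                n_comparisons=max(len(pairs), 1),
                exact=exact_wilcoxon,
            )
            comp_rows.append(
                {
                    "metric": metric,
                    "setting_a": a,
                    "setting_b": b,
                    "z": z,
                    "p_raw": p,
                    "p_adjusted": p_adj,
                    "effect_size": r,
                }
            )
    comparisons = pd.DataFrame(comp_rows)
    return ReliabilityResult(per_cell=per_cell, summary=summary, comparisons=comparisons)
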