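"""Dose-response statistics for repeated measurements across dose levels.

Each CT volume is measured at every dose level, so dose comparisons are
within-subject: a one-way repeated-measures ANOVA over dose levels (with the
Greenhouse–Geisser sphericity correction reported alongside the uncorrected
p), paired two-sided Wilcoxon signed-rank post-hocs with Bonferroni
adjustment, and an ordinary least-squares fit of a metric against the log of
the dose fraction, which captures the empirically logarithmic dose-response
of detection metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .metrics import detection_metrics

__all__ = ["AnovaResult", "DoseResponse", "rm_anova", "paired_wilcoxon",
           "log_fit", "build_tables", "render_tables"]

ALPHA = 0.05


@dataclass
class AnovaResult:
    f_stat: float
    df_num: float
    df_den: float
    p_uncorrected: float
    p_gg: float                # Greenhouse–Geisser corrected
    epsilon: float             # sphericity epsilon
    degenerate: bool = False   # zero error variance

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_gg < ALPHA

    def as_dict(self) -> dict:
        return {"F": self.f_stat, "df_num": self.df_num, "df_den": self.df_den,
                "p_uncorrected": self.p_uncorrected, "p_gg": self.p_gg,
                "epsilon": self.epsilon, "degenerate": self.degenerate,
                "significant": self.significant}


def _as_wide(matrix: pd.DataFrame) -> pd.DataFrame:
    wide = matrix.astype(float)
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 dose levels")
    if wide.isna().any().any():
        raise ValueError("repeated-measures ANOVA requires a complete matrix")
    return wide


def rm_anova(matrix: pd.DataFrame) -> AnovaResult:
    """One-way within-subject ANOVA on a subjects x dose-levels matrix.

    ``F = MS_condition / MS_(condition x subject)``.  With two conditions F
    equals the square of the paired t statistic.  A matrix with zero error
    variance (every subject shows the identical condition pattern) is flagged
    degenerate rather than reported as an infinite F.
    """
    wide = _as_wide(matrix)
    long = wide.reset_index(names="subject").melt(
        id_vars="subject", var_name="condition", value_name="y")
    with np.errstate(invalid="ignore", divide="ignore"):
        table = pg.rm_anova(data=long, dv="y", within="condition",
                            subject="subject", correction=True, detailed=True)
    row = table.iloc[0]
    f = float(row["F"]) if "F" in table.columns else float("nan")
    if not np.isfinite(f):
        return AnovaResult(float("nan"), float(row["DF"]),
                           float(table.iloc[1]["DF"]), float("nan"),
                           float("nan"), float("nan"), degenerate=True)
    eps = float(row.get("eps", 1.0))
    p_unc = float(row["p_unc"])
    gg = row.get("p_GG_corr", np.nan)
    p_gg = float(gg) if np.isfinite(gg) else p_unc
    return AnovaResult(f, float(row["DF"]), float(table.iloc[1]["DF"]),
                       p_unc, p_gg, eps)


def paired_wilcoxon(matrix: pd.DataFrame,
                    pairs: list[tuple] | None = None) -> pd.DataFrame:
    """Two-sided paired Wilcoxon signed-rank tests with Bonferroni adjustment.

    ``pairs`` are column pairs of ``matrix``; the default compares the first
    column (full dose) against every other.  Zero differences are dropped
    (the classic Wilcoxon treatment); the exact null distribution is used for
    n <= 25 pairs, the normal approximation with continuity correction
    otherwise.  All-zero differences give p = 1, flagged degenerate.
    """
    wide = matrix.astype(float)
    if pairs is None:
        cols = list(wide.columns)
        pairs = [(cols[0], c) for c in cols[1:]]
    n_comp = len(pairs)
    rows = []
    for a, b in pairs:
        paired = wide[[a, b]].dropna()
        diff = paired[a].to_numpy() - paired[b].to_numpy()
        nonzero = diff[diff != 0]
        if len(nonzero) == 0:
            raw, stat, degenerate = 1.0, 0.0, True
        else:
            method = "exact" if len(nonzero) <= 25 else "approx"
            res = sps.wilcoxon(diff, zero_method="wilcox", correction=True,
                               alternative="two-sided", method=method)
            raw, stat, degenerate = float(res.pvalue), float(res.statistic), False
        adj = min(1.0, raw * n_comp)
        rows.append({"a": a, "b": b, "n": len(diff), "n_nonzero": len(nonzero),
                     "statistic": stat, "p_raw": raw, "p_bonferroni": adj,
                     "significant": (not degenerate) and adj < ALPHA,
                     "degenerate": degenerate})
    return pd.DataFrame(rows)


@dataclass
class DoseResponse:
    """OLS fit ``metric = intercept + slope * ln(dose fraction)``."""

    doses: np.ndarray
    values: np.ndarray
    intercept: float
    slope: float
    r2: float

    def predict(self, doses) -> np.ndarray:
        return self.intercept + self.slope * np.log(np.asarray(doses, float))

    def as_dict(self) -> dict:
        return {"intercept": self.intercept, "slope": self.slope, "r2": self.r2}


def log_fit(doses, values) -> DoseResponse:
    """Fit a logarithmic dose-response curve by ordinary least squares.

    R-squared is invariant to rescaling dose (fraction vs percent only shifts
    the intercept).  A constant metric has slope 0 and R-squared defined as 0.
    """
    doses = np.asarray(doses, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(np.unique(doses)) < 3:
        raise ValueError("log_fit needs >= 3 distinct dose levels")
    if np.any(doses <= 0):
        raise ValueError("dose fractions must be positive")
    x = np.log(doses)
    slope, intercept = np.polyfit(x, values, 1)
    resid = values - (intercept + slope * x)
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return DoseResponse(doses, values, float(intercept), float(slope), r2)


def build_tables(per_volume: pd.DataFrame,
                 per_node: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-volume/per-node rows into detection and segmentation tables.

    Detection: TP/FP/FN pooled over volumes per (model, dose) with derived
    precision/sensitivity/F1.  Segmentation: mean ± SD of DSC and HD95 per
    (model, dose, size stratum); the "all" stratum is reported both per-volume
    (scores on the union of eligible nodes) and per-node, the size strata
    per-node.  Undefined HD95 values are excluded and counted.
    """
    det_rows = []
    for (model, dose), grp in per_volume.groupby(["model", "dose"], sort=False):
        counts = detection_metrics(int(grp.tp.sum()), int(grp.fp.sum()),
                                   int(grp.fn.sum()))
        det_rows.append({"model": model, "dose": dose, **counts.as_dict()})
    detection = pd.DataFrame(det_rows).sort_values(
        ["model", "dose"], ascending=[True, False], ignore_index=True)

    seg_rows = []

    def _summary(model, dose, stratum, unit, d, h):
        d, h = np.asarray(d, float), np.asarray(h, float)
        hd = h[np.isfinite(h)]
        return {"model": model, "dose": dose, "stratum": stratum, "unit": unit,
                "n": len(d), "dsc_mean": d.mean() if len(d) else np.nan,
                "dsc_sd": d.std(ddof=1) if len(d) > 1 else np.nan,
                "hd95_mean": hd.mean() if len(hd) else np.nan,
                "hd95_sd": hd.std(ddof=1) if len(hd) > 1 else np.nan,
                "hd95_undefined": int(len(h) - len(hd))}

    for (model, dose), grp in per_volume.groupby(["model", "dose"], sort=False):
        seg_rows.append(_summary(model, dose, "all", "per-volume",
                                 grp.volume_dsc, grp.volume_hd95))
    for (model, dose), grp in per_node.groupby(["model", "dose"], sort=False):
        seg_rows.append(_summary(model, dose, "all", "per-node",
                                 grp.dsc, grp.hd95))
        for stratum in ("large", "small"):
            sub = grp[grp.size_class == stratum]
            seg_rows.append(_summary(model, dose, stratum, "per-node",
                                     sub.dsc, sub.hd95))
    segmentation = pd.DataFrame(seg_rows).sort_values(
        ["stratum", "unit", "model", "dose"],
        ascending=[True, True, True, False], ignore_index=True)
    return detection, segmentation


def render_tables(detection: pd.DataFrame, segmentation: pd.DataFrame) -> str:
    """Plain-text rendering with the best model per (dose, metric) starred."""
    lines = ["Detection (lesion-wise, pooled counts)", "=" * 40]
    det = detection.copy()
    for metric in ("precision", "sensitivity", "f1"):
        det[metric + "_best"] = False
        for dose, grp in det.groupby("dose"):
            if grp[metric].notna().any():
                det.loc[grp[metric].idxmax(), metric + "_best"] = True
    for row in det.itertuples():
        def fmt(v, best):
            return "  n/a " if v is None or (isinstance(v, float) and np.isnan(v)) \
                else f"{v:5.1f}" + ("*" if best else " ")
        lines.append(
            f"model={row.model:<10} dose={row.dose:>5.2f}  "
            f"TP={row.tp:>6} FP={row.fp:>6} FN={row.fn:>6}  "
            f"P={fmt(row.precision, row.precision_best)} "
            f"S={fmt(row.sensitivity, row.sensitivity_best)} "
            f"F1={fmt(row.f1, row.f1_best)}")
    lines += ["", "Segmentation (DSC / HD95 mm, mean ± SD)", "=" * 40]
    for row in segmentation.itertuples():
        hd = (f"{row.hd95_mean:5.2f} ± {row.hd95_sd:4.2f}"
              if np.isfinite(row.hd95_mean) and np.isfinite(row.hd95_sd)
              else "  n/a")
        ds = (f"{row.dsc_mean:4.2f} ± {row.dsc_sd:4.2f}"
              if np.isfinite(row.dsc_mean) and np.isfinite(row.dsc_sd)
              else "  n/a")
        lines.append(
            f"model={row.model:<10} dose={row.dose:>5.2f} "
            f"{row.stratum:>5}/{row.unit:<10} n={row.n:>4}  "
            f"DSC {ds}  HD95 {hd}")
    return "\n".join(lines)
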