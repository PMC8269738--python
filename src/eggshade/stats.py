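"""Desk-scale study statistics: reflectance-change summaries, radiation
correlations and day-wise camouflage comparisons.

Mixed-model inference (random-intercept GLMM with post-hoc contrasts) is
routine statistics and is delegated to statsmodels; the reports record the
fitted outputs verbatim rather than re-implementing estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, DomainError
from .radiometry import percent_change

__all__ = [
    "arcsine_sqrt", "pearson", "CorrelationResult",
    "exp1_summary", "exp2_summary", "Exp1Report", "Exp2Report",
]


def arcsine_sqrt(x) -> np.ndarray | float:
    """Arcsine square-root transform (radians), the variance-stabilizer used
    for reflectance proportions.  Values above 1 are clipped with a warning."""
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise DomainError("arcsine_sqrt requires values >= 0")
    if (arr > 1).any():
        warnings.warn("reflectance values above 1 clipped to 1 before "
                      "arcsine-sqrt transform", stacklevel=2)
        arr = np.clip(arr, None, 1.0)
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(x) else out


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with the t-based two-sided p."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise DataError("x and y must be equal-length 1-D vectors")
    if len(xa) < 3:
        raise DataError("Pearson correlation requires n >= 3")
    if xa.std() == 0 or ya.std() == 0:
        raise DataError("zero variance: correlation undefined")
    res = sps.pearsonr(xa, ya)
    return CorrelationResult(r=float(res.statistic), n=len(xa),
                             p=float(res.pvalue))


# --------------------------------------------------------------------------
# experiment 1: reflectance change vs radiation
# --------------------------------------------------------------------------

@dataclass
class Exp1Report:
    """Per-treatment reflectance changes and their radiation correlations."""

    summary: pd.DataFrame                       # treatment x band_set rows
    correlations: dict[str, CorrelationResult | None]
    notes: dict[str, str] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)

    def text(self) -> str:
        lines = ["Reflectance change vs radiation"]
        for _, row in self.summary.iterrows():
            lines.append(
                f"  {row['treatment']:>7s} {row['band_set']}: "
                f"{row['mean_day0']:.3f} -> {row['mean_final']:.3f} "
                f"({row['pct_change']:+.1f}%)")
        for key, res in self.correlations.items():
            if res is None:
                lines.append(f"  r({key}): {self.notes.get(key, 'undefined')}")
            else:
                lines.append(f"  r({key}) = {res.r:.4f} (n={res.n}, p={res.p:.4g})")
        return "\n".join(lines)


def exp1_summary(table: pd.DataFrame, summaries: pd.DataFrame) -> Exp1Report:
    """Summarize the radiation experiment.

    ``table``: tidy per-egg reflectances (columns egg_id, treatment, day,
    band_set, mean_reflectance); ``summaries``: one row per treatment with
    columns irradiance_wm2 and uv_index (daily maxima averaged over the
    recording days).  Per treatment x band the report carries the day-0 and
    final-day means and the percent change computed from unrounded means,
    plus the Pearson correlations of the VIS change against irradiance and
    the UV change against UV index.
    """
    required = {"egg_id", "treatment", "day", "band_set", "mean_reflectance"}
    if not required.issubset(table.columns):
        raise DataError(f"table missing columns {sorted(required - set(table.columns))}")
    days = sorted(table["day"].unique())
    gaps = []
    for tr in table["treatment"].unique():
        for day in days:
            for band in ("VIS", "UV"):
                sub = table.query("treatment == @tr and day == @day and band_set == @band")
                if sub.empty:
                    gaps.append((tr, day, band))
    if gaps:
        raise DataError(f"incomplete table; missing treatment/day/band cells: {gaps}")
    day0, day_final = days[0], days[-1]
    rows = []
    for tr, band in [(t, b) for t in table["treatment"].unique() for b in ("VIS", "UV")]:
        sub = table.query("treatment == @tr and band_set == @band")
        m0 = sub.loc[sub.day == day0, "mean_reflectance"].mean()
        mf = sub.loc[sub.day == day_final, "mean_reflectance"].mean()
        rows.append({"treatment": tr, "band_set": band,
                     "mean_day0": m0, "mean_final": mf,
                     "pct_change": percent_change(m0, mf)})
    summary = pd.DataFrame(rows)
    if "treatment" in summaries.columns:
        summaries = summaries.set_index("treatment")
    summary["irradiance_wm2"] = summary["treatment"].map(summaries["irradiance_wm2"])
    summary["uv_index"] = summary["treatment"].map(summaries["uv_index"])

    correlations: dict[str, CorrelationResult | None] = {}
    notes: dict[str, str] = {}
    pairs = {
        "dVIS_vs_irradiance": ("VIS", "irradiance_wm2"),
        "dUV_vs_uv_index": ("UV", "uv_index"),
    }
    for key, (band, rad_col) in pairs.items():
        sub = summary[summary.band_set == band]
        try:
            correlations[key] = pearson(sub[rad_col].to_numpy(),
                                        sub["pct_change"].to_numpy())
        except DataError as exc:
            correlations[key] = None
            notes[key] = f"not computed: {exc}"
    return Exp1Report(summary=summary, correlations=correlations, notes=notes)


# --------------------------------------------------------------------------
# experiment 2: camouflage over days
# --------------------------------------------------------------------------

@dataclass
class Exp2Report:
    """Day-wise camouflage means and the degradation flag per visual model."""

    daywise: pd.DataFrame          # visual_model, day, mean, se, n
    paired_diffs: pd.DataFrame     # visual_model, nest_id, day, diff_from_day0
    degradation: dict[str, bool]   # model -> mean(final day) > mean(day 0)
    mixed_models: dict[str, str] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.daywise.to_csv(path, index=False)

    def text(self) -> str:
        lines = ["Camouflage (chi-square distance) by day and visual model"]
        for model, grp in self.daywise.groupby("visual_model"):
            cells = ", ".join(
                f"day {int(r.day)}: {r['mean']:.3f} +/- "
                + ("n/a" if np.isnan(r.se) else f"{r.se:.3f}")
                for _, r in grp.iterrows())
            worse = "worsened" if self.degradation[model] else "not worsened"
            lines.append(f"  {model:>8s}: {cells}  -> camouflage {worse}")
        return "\n".join(lines)


def exp2_summary(scores: pd.DataFrame,
                 fit_mixed_models: bool = False) -> Exp2Report:
    """Summarize camouflage scores across nests and days.

    ``scores``: tidy table with columns nest_id, day, visual_model, chi2.
    SE is computed across nests (the nest is the experimental unit).  With
    ``fit_mixed_models`` a random-intercept model chi2 ~ C(day) with nest as
    the grouping factor is fitted per visual model via statsmodels MixedLM
    and its summary recorded verbatim.
    """
    required = {"nest_id", "day", "visual_model", "chi2"}
    if not required.issubset(scores.columns):
        raise DataError(f"scores missing columns {sorted(required - set(scores.columns))}")
    days = sorted(scores["day"].unique())
    if len(days) < 2:
        raise DataError("need scores on at least two days")
    rows, diff_rows = [], []
    degradation = {}
    for model, grp in scores.groupby("visual_model"):
        for day in days:
            vals = grp.loc[grp.day == day, "chi2"].to_numpy()
            n = len(vals)
            se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            rows.append({"visual_model": model, "day": day,
                         "mean": float(vals.mean()), "se": se, "n": n})
        pivot = grp.pivot_table(index="nest_id", columns="day", values="chi2")
        for day in days[1:]:
            if days[0] in pivot.columns and day in pivot.columns:
                d = (pivot[day] - pivot[days[0]]).dropna()
                for nest, v in d.items():
                    diff_rows.append({"visual_model": model, "nest_id": nest,
                                      "day": day, "diff_from_day0": float(v)})
        m0 = grp.loc[grp.day == days[0], "chi2"].mean()
        mf = grp.loc[grp.day == days[-1], "chi2"].mean()
        degradation[model] = bool(mf > m0)
    mixed: dict[str, str] = {}
    if fit_mixed_models:
        import statsmodels.formula.api as smf
        for model, grp in scores.groupby("visual_model"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = smf.mixedlm("chi2 ~ C(day)", grp,
                                      groups=grp["nest_id"]).fit(reml=True)
                mixed[model] = str(fit.summary())
            except Exception as exc:  # singular fits on tiny designs
                mixed[model] = f"mixed model not fitted: {exc}"
    return Exp2Report(daywise=pd.DataFrame(rows),
                      paired_diffs=pd.DataFrame(diff_rows),
                      degradation=degradation, mixed_models=mixed)
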