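"""Method-comparison statistics between paired percent-body-fat series.

Correlation alone overstates agreement between two ways of measuring the
same quantity, so method comparison here follows the standard toolkit:

* a paired t-test on the differences (is the mean difference zero?),
* Bland-Altman limits of agreement, mean difference +/- 1.96 SD,
* a proportional-bias regression of the difference on the pair mean
  (does the disagreement grow with body fat?), and
* Lin's concordance correlation coefficient,

      rho_c = 2 s_ab / (s_a^2 + s_b^2 + (mean_a - mean_b)^2),

  with biased 1/n moments (Lin's 1989 convention), which penalises both
  correlation loss and location/scale shift.

The module is organised statsmodels-style: build :class:`MethodAgreement`
from two paired series, call :meth:`~MethodAgreement.fit`, and read the
statistics off the returned :class:`AgreementResults` (or print
``summary()``).  :func:`run_comparisons` applies the model to the three
study comparisons across combined/male/female strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .densitometry import Condition

#: the three study comparisons: difference = first condition - second condition
COMPARISONS: Dict[int, Tuple[Condition, Condition]] = {
    1: (Condition.HBW_TLC, Condition.HAW_TLC),   # head position only
    2: (Condition.HBW_RV, Condition.HBW_TLC),    # lung volume only
    3: (Condition.HBW_RV, Condition.HAW_TLC),    # both
}

STRATA = ("combined", "male", "female")


def paired_t(a: Sequence[float], b: Sequence[float]) -> Tuple[float, int, float]:
    """Classical paired t-test on d = a - b; returns (t, df, two-sided p).

    Zero-variance differences with a nonzero mean are reported as
    (inf-signed t, df, p=0) with a warning rather than an exception; an
    identically-zero difference vector gives t=0, p=1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired series must be 1-d and equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = a - b
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, df, 1.0
        warnings.warn("zero-variance differences with nonzero mean: degenerate t", stacklevel=2)
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), df, float(res.pvalue)


@dataclass(frozen=True)
class BlandAltman:
    """Per-pair differences/means and the limits of agreement."""

    diffs: np.ndarray
    means: np.ndarray
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    multiplier: float = 1.96


def bland_altman(
    a: Sequence[float], b: Sequence[float], multiplier: float = 1.96
) -> BlandAltman:
    """Bland-Altman summary: diffs a-b, pair means, mean +/- 1.96 SD limits.

    The SD of the differences uses the n-1 denominator.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("Bland-Altman needs paired 1-d series with n >= 3")
    diffs = a - b
    means = (a + b) / 2.0
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    return BlandAltman(
        diffs=diffs,
        means=means,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - multiplier * sd_diff,
        loa_high=mean_diff + multiplier * sd_diff,
        multiplier=multiplier,
    )


def proportional_bias(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float, float]:
    """OLS of the difference on the pair mean: (slope, intercept, slope p).

    A significant slope means the disagreement between the two methods is
    proportional to the measured quantity.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("proportional-bias regression needs paired 1-d series with n >= 3")
    means = (a + b) / 2.0
    if np.var(means) == 0.0:
        raise ValueError("degenerate design: pair means are constant")
    res = stats.linregress(means, a - b)
    p = float(res.pvalue)
    if np.isnan(p) and res.slope == 0.0:
        p = 1.0  # constant difference: zero slope, zero residuals, no evidence of bias
    return float(res.slope), float(res.intercept), p


def lin_ccc(a: Sequence[float], b: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient with 1/n moments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("concordance needs paired 1-d series with n >= 2")
    va = a.var()  # ddof=0: biased moments
    vb = b.var()
    if va == 0.0 and vb == 0.0:
        raise ValueError("Lin's CCC undefined: both series constant")
    sab = np.mean((a - a.mean()) * (b - b.mean()))
    return float(2.0 * sab / (va + vb + (a.mean() - b.mean()) ** 2))


def loo_sensitivity(a: Sequence[float], b: Sequence[float]) -> np.ndarray:
    """Leave-one-out proportional-bias slope p-values, one per pair.

    Re-runs the proportional-bias regression with each pair removed in
    turn; a p-value that crosses the significance threshold when one pair
    is dropped flags that pair as driving the apparent proportional bias.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 4:
        raise ValueError("leave-one-out sensitivity needs n >= 4")
    mask = np.ones(a.size, dtype=bool)
    out = np.empty(a.size)
    for i in range(a.size):
        mask[i] = False
        out[i] = proportional_bias(a[mask], b[mask])[2]
        mask[i] = True
    return out


class MethodAgreement:
    """Agreement model for two paired measurement series.

    Parameters
    ----------
    a, b : array-like
        Paired measurements (e.g. percent body fat under two conditions);
        the analysed difference is ``a - b``.
    ids : sequence, optional
        Participant identifiers carried into exports.
    label : str, optional
        Human-readable name for summaries (e.g. ``"HBW@RV - HBW@TLC"``).
    """

    def __init__(self, a, b, ids=None, label: str = "A - B"):
        self.a = np.asarray(a, dtype=float)
        self.b = np.asarray(b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("a and b must be 1-d and equal length")
        if np.isnan(self.a).any() or np.isnan(self.b).any():
            raise ValueError("paired series must be pairwise complete (no NaN)")
        if self.a.size < 3:
            raise ValueError("agreement analysis needs n >= 3")
        self.ids = np.asarray(ids) if ids is not None else np.arange(self.a.size)
        self.label = label

    def fit(self, loa_multiplier: float = 1.96) -> "AgreementResults":
        """Compute all agreement statistics and return the results object."""
        t, df, p = paired_t(self.a, self.b)
        ba = bland_altman(self.a, self.b, multiplier=loa_multiplier)
        slope, intercept, slope_p = proportional_bias(self.a, self.b)
        ccc = lin_ccc(self.a, self.b)
        return AgreementResults(
            model=self,
            n=self.a.size,
            mean_diff=ba.mean_diff,
            sd_diff=ba.sd_diff,
            loa_low=ba.loa_low,
            loa_high=ba.loa_high,
            loa_multiplier=loa_multiplier,
            t_stat=t,
            df=df,
            p_paired=p,
            slope=slope,
            intercept=intercept,
            slope_p=slope_p,
            lccc=ccc,
            bland_altman=ba,
        )


@dataclass(frozen=True)
class AgreementResults:
    """Fitted agreement statistics for one method pair."""

    model: MethodAgreement
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    loa_multiplier: float
    t_stat: float
    df: int
    p_paired: float
    slope: float
    intercept: float
    slope_p: float
    lccc: float
    bland_altman: BlandAltman

    def loo_slope_p(self) -> np.ndarray:
        """Leave-one-out slope p-values (outlier sensitivity)."""
        return loo_sensitivity(self.model.a, self.model.b)

    def summary(self) -> str:
        """Plain-text summary table in the style of a model results object."""
        lines = [
            f"Method agreement: {self.model.label}",
            "=" * 46,
            f"{'n pairs':<28}{self.n:>18d}",
            f"{'mean difference':<28}{self.mean_diff:>18.4f}",
            f"{'SD of differences':<28}{self.sd_diff:>18.4f}",
            f"{'LoA low  (-%.2f SD)' % self.loa_multiplier:<28}{self.loa_low:>18.4f}",
            f"{'LoA high (+%.2f SD)' % self.loa_multiplier:<28}{self.loa_high:>18.4f}",
            f"{'paired t':<28}{self.t_stat:>18.4f}",
            f"{'df':<28}{self.df:>18d}",
            f"{'p (two-sided)':<28}{self.p_paired:>18.4g}",
            f"{'proportional-bias slope':<28}{self.slope:>18.4f}",
            f"{'slope p':<28}{self.slope_p:>18.4g}",
            f"{'Lin CCC':<28}{self.lccc:>18.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def to_dict(self) -> Dict[str, float]:
        return {
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "t_stat": self.t_stat,
            "df": self.df,
            "p_paired": self.p_paired,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_p": self.slope_p,
            "lccc": self.lccc,
        }

    def plot(self, ax=None):
        """Bland-Altman scatter with mean-difference and LoA lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ba = self.bland_altman
        ax.scatter(ba.means, ba.diffs, s=18)
        ax.axhline(ba.mean_diff, color="k")
        ax.axhline(ba.loa_low, color="k", linestyle=":")
        ax.axhline(ba.loa_high, color="k", linestyle=":")
        ax.set_xlabel("pair mean")
        ax.set_ylabel("difference")
        ax.set_title(self.model.label)
        return ax


def comparison_label(comparison: int) -> str:
    first, second = COMPARISONS[comparison]
    pretty = {
        Condition.HAW_TLC: "HAW@TLC",
        Condition.HBW_TLC: "HBW@TLC",
        Condition.HBW_RV: "HBW@RV",
    }
    return f"{pretty[first]} - {pretty[second]}"


def run_comparisons(
    results: pd.DataFrame,
    loa_multiplier: float = 1.96,
    strict_quality: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Three-comparison, three-stratum agreement report.

    Parameters
    ----------
    results : DataFrame
        Long per-condition results with columns ``participant_id``, ``sex``,
        ``condition``, ``pbf`` (and optionally ``quality``).
    loa_multiplier : float
        Limits-of-agreement multiplier.
    strict_quality : bool
        Drop pair-quality condition estimates before pairing.

    Returns
    -------
    report : DataFrame
        One row per comparison x stratum with the full agreement statistics.
        Strata with fewer than 3 complete pairs are skipped with a warning.
    points : DataFrame
        Per-participant Bland-Altman points (for external plotting).
    """
    required = {"participant_id", "sex", "condition", "pbf"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    df = results.copy()
    if strict_quality and "quality" in df.columns:
        df = df[df["quality"] != "pair"]
    wide = df.pivot_table(
        index=["participant_id", "sex"], columns="condition", values="pbf", aggfunc="first"
    ).reset_index()
    wide = wide.sort_values("participant_id", kind="stable")

    report_rows: List[dict] = []
    point_rows: List[pd.DataFrame] = []
    for comp, (first, second) in COMPARISONS.items():
        cols = [first.value, second.value]
        if any(c not in wide.columns for c in cols):
            warnings.warn(f"comparison {comp}: condition(s) absent from results; skipped", stacklevel=2)
            continue
        complete = wide.dropna(subset=cols)
        for stratum in STRATA:
            sub = complete if stratum == "combined" else complete[complete["sex"] == stratum]
            if len(sub) < 3:
                warnings.warn(
                    f"comparison {comp}, stratum {stratum}: n={len(sub)} < 3, skipped",
                    stacklevel=2,
                )
                continue
            model = MethodAgreement(
                sub[first.value].to_numpy(),
                sub[second.value].to_numpy(),
                ids=sub["participant_id"].to_numpy(),
                label=comparison_label(comp),
            )
            res = model.fit(loa_multiplier=loa_multiplier)
            row = {"comparison": comp, "label": comparison_label(comp), "stratum": stratum}
            row.update(res.to_dict())
            report_rows.append(row)
            point_rows.append(
                pd.DataFrame(
                    {
                        "comparison": comp,
                        "stratum": stratum,
                        "participant_id": sub["participant_id"].to_numpy(),
                        "mean_pbf": res.bland_altman.means,
                        "diff_pbf": res.bland_altman.diffs,
                    }
                )
            )
    report = pd.DataFrame(report_rows)
    points = pd.concat(point_rows, ignore_index=True) if point_rows else pd.DataFrame(
        columns=["comparison", "stratum", "participant_id", "mean_pbf", "diff_pbf"]
    )
    return report, points
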