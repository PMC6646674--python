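"""Temporal analysis of trait series and derived agronomic quantities.

A trait trajectory (green fraction, GPAI, height, MTCI, ...) is by default
modelled as the daily linear interpolant of its observations; parametric
logistic / double-logistic fits are opt-in.  Integrative stress indicators:

* area under the curve (AUC) over a phenological window, e.g. MTCI between
  flowering and maturity as a grain-filling nitrogen indicator;
* curve maxima and their dates;
* divergence onset: the first date a stressed trajectory separates
  persistently from its well-watered reference, locating when a stress
  starts to impact growth.

Also provides the grain-nitrogen arithmetic (Nabs = GY * P / 5.7 with the
unit factor making it kg N/ha for GY in t/ha and P in %), relative yield
loss, and a per-treatment Tukey-HSD summary with compact letter display.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import TraitSeries, TrialDesign, ValidationError

__all__ = [
    "CurveFit",
    "auc",
    "fit_curve",
    "max_value",
    "divergence_onset",
    "nitrogen_grain_quantity",
    "relative_loss",
    "treatment_summary",
]

PROTEIN_TO_N = 5.7  # grain protein mass per unit nitrogen mass


def _to_days(dates) -> np.ndarray:
    """Calendar dates -> float day ordinals (ints pass through)."""
    out = []
    for d in dates:
        if isinstance(d, (_dt.date, _dt.datetime)):
            out.append(_dt.date(d.year, d.month, d.day).toordinal())
        else:
            out.append(float(d))
    return np.asarray(out, dtype=float)


def _series_tv(series: TraitSeries | tuple) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, TraitSeries):
        dates, values = series.dates_values()
    else:
        dates, values = series
    t = _to_days(dates)
    v = np.asarray(values, dtype=float)
    order = np.argsort(t)
    return t[order], v[order]


def auc(series: TraitSeries | tuple, window: tuple) -> float:
    """Trapezoidal area under the linearly interpolated series over a window.

    ``window`` is (start, end) as dates or day numbers; values at the window
    edges are interpolated.  Units: trait-unit x days.  Exactly additive
    over adjacent subwindows.
    """
    t, v = _series_tv(series)
    lo, hi = _to_days(window)
    if hi < lo:
        raise ValueError("window end precedes start")
    if lo < t[0] or hi > t[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] outside series support [{t[0]}, {t[-1]}]"
        )
    inside = (t > lo) & (t < hi)
    knots = np.concatenate([[lo], t[inside], [hi]])
    vals = np.interp(knots, t, v)
    return float(np.trapezoid(vals, knots))


def max_value(series: TraitSeries | tuple) -> tuple[float, float]:
    """(max value, day of max) of the observed series (earliest day on ties)."""
    t, v = _series_tv(series)
    i = int(np.argmax(v))
    return float(v[i]), float(t[i])


def _logistic(t, a, k, t0):
    return a / (1.0 + np.exp(-k * (t - t0)))


def _double_logistic(t, a, kr, tr, kf, tf):
    return a * (1.0 / (1.0 + np.exp(-kr * (t - tr))) - 1.0 / (1.0 + np.exp(-kf * (t - tf))))


_MODELS = {
    "linear-interp": None,
    "logistic": (_logistic, 3),
    "double-logistic": (_double_logistic, 5),
}


@dataclass
class CurveFit:
    """Fitted trait trajectory: evaluable over its support, with residual RMSE."""

    model: str
    parameters: np.ndarray
    rmse: float
    support: tuple[float, float]
    _knots: tuple[np.ndarray, np.ndarray] | None = None

    def __call__(self, t) -> np.ndarray:
        t = _to_days(np.atleast_1d(t))
        if self.model == "linear-interp":
            kt, kv = self._knots
            return np.interp(t, kt, kv)
        fn, _ = _MODELS[self.model]
        return fn(t, *self.parameters)


def fit_curve(series: TraitSeries | tuple, model: str = "linear-interp") -> CurveFit:
    """Least-squares fit of a trajectory model to a trait series.

    ``linear-interp`` reproduces the observations exactly (rmse 0);
    ``logistic`` fits a saturating rise a / (1 + exp(-k (t - t0)));
    ``double-logistic`` a rise-then-fall (green-up and senescence).
    Initialisation is data-driven and deterministic.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; have {sorted(_MODELS)}")
    t, v = _series_tv(series)
    if model == "linear-interp":
        return CurveFit(model, np.array([]), 0.0, (t[0], t[-1]), _knots=(t, v))
    fn, npar = _MODELS[model]
    if len(t) <= npar:
        raise ValidationError(f"{model} needs > {npar} observations, got {len(t)}")
    span = max(t[-1] - t[0], 1.0)
    amp = max(v.max(), 1e-9)
    if model == "logistic":
        # midpoint guess: first crossing of half amplitude
        half = np.argmax(v >= 0.5 * amp)
        p0 = [amp, 4.0 / span, t[half]]
        bounds = ([0, 1e-6, t[0] - span], [10 * amp, np.inf, t[-1] + span])
    else:
        imax = int(np.argmax(v))
        p0 = [amp, 8.0 / span, t[0] + 0.25 * span, 8.0 / span, t[imax] + 0.25 * span]
        bounds = (
            [0, 1e-6, t[0] - span, 1e-6, t[0] - span],
            [10 * amp, np.inf, t[-1] + span, np.inf, t[-1] + span],
        )
    popt, _ = curve_fit(fn, t, v, p0=p0, bounds=bounds, maxfev=20000)
    rmse = float(np.sqrt(np.mean((fn(t, *popt) - v) ** 2)))
    return CurveFit(model, popt, rmse, (t[0], t[-1]))


def divergence_onset(
    a: TraitSeries | tuple,
    b: TraitSeries | tuple,
    delta: float,
    persistence_days: int = 5,
) -> float | None:
    """First day the two trajectories separate persistently.

    Both series are interpolated to a common daily grid over the overlap of
    their supports; the onset is the earliest day where |a - b| exceeds
    ``delta`` and stays above it for at least ``persistence_days``
    consecutive days.  Returns None if they never diverge.  Symmetric in
    (a, b).
    """
    ta, va = _series_tv(a)
    tb, vb = _series_tv(b)
    lo, hi = max(ta[0], tb[0]), min(ta[-1], tb[-1])
    if hi <= lo:
        raise ValueError("series supports do not overlap")
    days = np.arange(np.ceil(lo), np.floor(hi) + 1)
    diff = np.abs(np.interp(days, ta, va) - np.interp(days, tb, vb))
    above = diff > delta
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= persistence_days:
            start = days[i - run + 1]
            # the run must persist to at least persistence_days total; report
            # its first day
            return float(start)
    # tail run reaching the end of the overlap still counts if long enough
    return None


def nitrogen_grain_quantity(gy: float, p: float, literal: bool = False) -> float:
    """Grain nitrogen export Nabs (kg N/ha) from yield and protein content.

    Nabs = GY * P * 10 / 5.7 for GY in t/ha (dry matter) and P in % protein;
    the factor 10 converts t/ha x % to kg/ha.  ``literal=True`` drops the
    unit factor (plain GY*P/5.7).
    """
    if gy < 0 or not 0 <= p <= 100:
        raise ValueError("gy must be >= 0 and p in [0, 100]")
    factor = 1.0 if literal else 10.0
    return gy * p * factor / PROTEIN_TO_N


def relative_loss(reference: float, stressed: float, digits: int | None = None) -> float:
    """Percent decrease from reference to stressed, 100 (ref - stress)/ref.

    ``digits`` rounds for reporting (None keeps full precision).
    """
    if reference <= 0:
        raise ValueError("reference must be > 0")
    loss = 100.0 * (reference - stressed) / reference
    return round(loss, digits) if digits is not None else loss


def _compact_letters(groups: list, nonsig: set[frozenset]) -> dict:
    """Compact letter display: groups sharing a letter are not significantly
    different; significantly different groups never share one."""
    letters: list[list] = []
    for g in groups:
        placed = False
        for members in letters:
            if all(frozenset((g, m)) in nonsig for m in members):
                members.append(g)
                placed = True
        if not placed:
            letters.append([g])
    # coverage: every non-significant pair must share at least one letter
    for pair in nonsig:
        if len(pair) != 2:
            continue
        g1, g2 = sorted(pair, key=groups.index)
        if not any(g1 in m and g2 in m for m in letters):
            members = [g1, g2]
            for g in groups:
                if g in members:
                    continue
                if all(frozenset((g, m)) in nonsig for m in members):
                    members.append(g)
            letters.append(members)
    out = {g: "" for g in groups}
    for li, members in enumerate(letters):
        ch = chr(ord("a") + li)
        for g in members:
            out[g] += ch
    return out


def treatment_summary(
    values: pd.DataFrame,
    design: TrialDesign | None = None,
    value_col: str = "value",
    group_cols: Sequence[str] = ("water_treatment", "nitrogen_treatment"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-treatment means, standard errors, and Tukey-HSD letter groups.

    ``values`` holds one endpoint per plot; treatment columns are taken from
    the frame or merged in from ``design`` on plot_id.  A convenience wrapper
    over one-way ANOVA / Tukey at alpha = 0.05: groups sharing a letter do
    not differ significantly.
    """
    df = values.copy()
    if design is not None and not set(group_cols) <= set(df.columns):
        df = df.merge(design.table, on="plot_id", how="left")
    missing = [c for c in group_cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing grouping columns: {missing}")
    df["_group"] = df[list(group_cols)].astype(str).agg(" ".join, axis=1)
    g = df.groupby("_group")[value_col]
    summary = g.agg(mean="mean", n="size", sd=lambda x: x.std(ddof=1)).reset_index()
    summary["se"] = summary["sd"] / np.sqrt(summary["n"])
    if (summary["n"] < 2).any():
        summary.attrs["warning"] = "single-replicate group: SE undefined"
    groups = list(summary["_group"])
    if len(groups) == 1:
        summary["letters"] = "a"
    else:
        res = pairwise_tukeyhsd(df[value_col].to_numpy(), df["_group"].to_numpy(), alpha=alpha)
        nonsig = {frozenset((g, g)) for g in groups}
        tbl = res.summary().data[1:]
        for row in tbl:
            g1, g2, reject = str(row[0]), str(row[1]), bool(row[-1])
            if not reject:
                nonsig.add(frozenset((g1, g2)))
        # order by descending mean so 'a' marks the top group
        ordered = list(summary.sort_values("mean", ascending=False)["_group"])
        letters = _compact_letters(ordered, nonsig)
        summary["letters"] = summary["_group"].map(letters)
    return summary.rename(columns={"_group": "group"})
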