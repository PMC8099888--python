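"""Anesthetic dose-response analysis.

Normalized response amplitudes A(c) are modelled as pure exponential decay
A(c) = a0 * exp(-c / tau), where tau (the concentration constant) is the
anesthetic increment that reduces the response e-fold. No additive offset is
fitted (A -> 0 as c -> infinity); an offset variant is available behind a
flag for saturation analyses. Group constants are means of per-experiment
fits; confidence intervals use 2.5 x the leave-one-out jackknife SD
(~ p = 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponseSeries",
    "ExpFit",
    "StatResult",
    "normalize_to_control",
    "fit_exponential",
    "concentration_per_drop",
    "retention_at",
    "spearman",
    "pearson",
    "jackknife_ci",
    "dose_report",
]


@dataclass
class DoseResponseSeries:
    anesthetic: str
    unit: str
    concentrations: np.ndarray
    amplitudes: np.ndarray           # normalized; control (c=0) == 1
    component: str = "LS"            # Green|Red|IR|LS|HbO|HbT
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.concentrations.shape != self.amplitudes.shape:
            raise ValueError("concentrations and amplitudes must match")
        if (self.concentrations < 0).any():
            raise ValueError("concentrations must be non-negative")
        if not np.all(np.diff(self.concentrations) > 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass
class ExpFit:
    a0: float
    tau: float
    r2: float
    residuals: np.ndarray = field(repr=False, default=None)
    ci_tau: float = float("nan")

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 must lie in [0, 1]")

    def predict(self, c) -> np.ndarray:
        return self.a0 * np.exp(-np.asarray(c, dtype=float) / self.tau)


@dataclass
class StatResult:
    name: str
    value: float
    p_value: float
    n: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if abs(self.value) > 1 + 1e-12:
            raise ValueError("correlation must lie in [-1, 1]")
        if self.n < 3:
            raise ValueError("need n >= 3")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def normalize_to_control(concentrations: Sequence[float],
                         amplitudes: Sequence[float], anesthetic: str = "",
                         unit: str = "", component: str = "LS",
                         animal_id: str = "") -> DoseResponseSeries:
    """Divide every amplitude by the control (c = 0) amplitude.

    The control is the response recorded before the first anesthetic
    application. Signs are preserved, so a signed LS series normalizes to a
    positive, unit-control series.
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    order = np.argsort(c)
    c, a = c[order], a[order]
    if c[0] != 0.0:
        raise ValueError("control measurement (c = 0) is required")
    if a[0] == 0.0:
        raise ZeroDivisionError("control amplitude is zero; cannot normalize")
    return DoseResponseSeries(anesthetic=anesthetic, unit=unit,
                              concentrations=c, amplitudes=a / a[0],
                              component=component, animal_id=animal_id)


def _fit_once(c, a, tau0, with_offset):
    if with_offset:
        def model(x, a0, tau, b):
            return a0 * np.exp(-x / tau) + b
        p0 = (a[0], tau0, 0.0)
        bounds = ((0.0, 1e-12, -np.inf), (np.inf, np.inf, np.inf))
    else:
        def model(x, a0, tau):
            return a0 * np.exp(-x / tau)
        p0 = (a[0] if a[0] > 0 else 1.0, tau0)
        bounds = ((0.0, 1e-12), (np.inf, np.inf))
    popt, _ = optimize.curve_fit(model, c, a, p0=p0, bounds=bounds, maxfev=20000)
    resid = a - model(c, *popt)
    return popt, float(np.sum(resid ** 2)), resid


def fit_exponential(series: DoseResponseSeries, with_offset: bool = False,
                    tau_grid: np.ndarray = None) -> ExpFit:
    """Deterministic least-squares fit of A(c) = a0 exp(-c/tau).

    Multi-start over a log-spaced tau grid; the best (lowest SS) solution is
    kept, ties broken by the smallest tau. Requires >= 3 distinct
    concentrations and a non-constant series.
    """
    c = series.concentrations
    a = series.amplitudes
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.allclose(a, a[0]):
        raise ValueError("constant series: tau is unidentifiable")
    span = max(c.max() - c.min(), 1e-6)
    if tau_grid is None:
        tau_grid = np.geomspace(span / 50.0, span * 50.0, 13)
    best = None
    errors = []
    for tau0 in tau_grid:
        try:
            popt, ss, resid = _fit_once(c, a, tau0, with_offset)
        except RuntimeError as exc:
            errors.append(str(exc))
            continue
        key = (round(ss, 15), popt[1])
        if best is None or key < best[0]:
            best = (key, popt, resid)
    if best is None:
        raise RuntimeError("exponential fit did not converge; residual trace: "
                           + "; ".join(errors))
    _, popt, resid = best
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return ExpFit(a0=float(popt[0]), tau=float(popt[1]), r2=min(r2, 1.0),
                  residuals=resid)


def retention_at(tau: float, concentration: float) -> float:
    """Predicted fraction of the control response retained at a concentration."""
    return math.exp(-concentration / tau)


def concentration_per_drop(fit_or_tau, level_range: tuple = (0.2, 1.0),
                           drop: float = 0.10) -> float:
    """Mean concentration increment that lowers the response by `drop`.

    Levels step down from the top of `level_range` in absolute steps of
    `drop` (1.0 -> 0.9 -> 0.8 ...); each step costs
    dc = tau * ln(a / (a - drop)). Returns the mean over the steps (the sum
    telescopes to tau * ln(high/low) / n_steps for an exact ladder).
    """
    tau = fit_or_tau.tau if isinstance(fit_or_tau, ExpFit) else float(fit_or_tau)
    if drop <= 0:
        raise ValueError("drop must be > 0")
    low, high = level_range
    if not low < high <= 1.0:
        raise ValueError("level_range must satisfy low < high <= 1")
    if low <= drop:
        raise ValueError(f"lowest level {low} must exceed the drop {drop}")
    steps = []
    a = high
    while a - drop >= low - 1e-12:
        steps.append(tau * math.log(a / (a - drop)))
        a -= drop
    if not steps:
        raise ValueError("level_range shorter than one drop")
    return float(np.mean(steps))


def _corr(fn, name, x, y) -> StatResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined for constant input")
    res = fn(x, y)
    return StatResult(name=name, value=float(res.statistic),
                      p_value=float(res.pvalue), n=x.size)


def spearman(x, y) -> StatResult:
    return _corr(stats.spearmanr, "spearman_rho", x, y)


def pearson(x, y) -> StatResult:
    return _corr(stats.pearsonr, "pearson_r", x, y)


def jackknife_ci(samples: Sequence[float], statistic_fn: Callable = np.mean,
                 multiplier: float = 2.5) -> tuple:
    """(estimate, half_width) via leave-one-out jackknife.

    half_width = multiplier x jackknife SD; the default 2.5 corresponds to
    ~p = 0.05. For the mean the jackknife SD equals sample SD / sqrt(n).
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    estimate = float(statistic_fn(x))
    loo = np.empty(n)
    for i in range(n):
        sub = np.delete(x, i)
        v = statistic_fn(sub)
        if v is None or not np.isfinite(v):
            raise ValueError(f"statistic undefined on leave-one-out subset {i}")
        loo[i] = v
    sd = math.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2))
    return estimate, multiplier * sd


# Experimental concentration ranges: isoflurane MAC 2.21-2.47 %, urethane
# 0.9-1.5 g/kg; "subexperimental" = below those ranges.
DEFAULT_RANGES = {
    "isoflurane": {"experimental": (2.21, 2.47), "subexperimental": (0.0, 2.21)},
    "urethane": {"experimental": (0.9, 1.5), "subexperimental": (0.0, 0.9)},
}


def dose_report(series_collection: Sequence[DoseResponseSeries],
                ranges: dict = None, drop: float = 0.10) -> pd.DataFrame:
    """Group summary per (anesthetic, component).

    Columns: mean tau with jackknife CI, mean r2, mean concentration per
    10%-of-control drop over the sub-experimental and experimental level
    ranges (levels the exponential model predicts inside each concentration
    range), and predicted retention at the range endpoints.
    """
    ranges = ranges or DEFAULT_RANGES
    rows = []
    groups = {}
    for s in series_collection:
        groups.setdefault((s.anesthetic, s.component), []).append(s)
    for (anesthetic, component), group in sorted(groups.items()):
        fits = [fit_exponential(s) for s in group]
        taus = np.array([f.tau for f in fits])
        mean_tau, ci_tau = (float(taus.mean()), float("nan")) if len(taus) < 3 \
            else jackknife_ci(taus)
        row = {
            "anesthetic": anesthetic,
            "component": component,
            "unit": group[0].unit,
            "n_series": len(group),
            "mean_tau": mean_tau,
            "ci_tau_2.5jk": ci_tau,
            "mean_r2": float(np.mean([f.r2 for f in fits])),
        }
        cfg = ranges.get(anesthetic, {})
        for rng_name, (c_lo, c_hi) in cfg.items():
            lo_level = retention_at(mean_tau, c_hi)
            hi_level = min(retention_at(mean_tau, c_lo), 1.0)
            try:
                row[f"dc_per_{int(drop * 100)}pct_{rng_name}"] = concentration_per_drop(
                    mean_tau, level_range=(max(lo_level, drop + 0.01), hi_level), drop=drop)
            except ValueError:
                row[f"dc_per_{int(drop * 100)}pct_{rng_name}"] = float("nan")
            row[f"retention_at_{c_hi:g}"] = retention_at(mean_tau, c_hi)
            row[f"retention_at_{c_lo:g}"] = retention_at(mean_tau, c_lo)
        rows.append(row)
    return pd.DataFrame(rows)
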