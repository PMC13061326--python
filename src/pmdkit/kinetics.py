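"""Methylation decay kinetics under maintenance-methyltransferase loss.

Each domain's methylated fraction m(t) follows dm/dt = -λ·m + ν·(1 - m):
λ is the per-day loss rate from failed maintenance at replication, ν the
per-day de novo gain rate. The closed form is

    m(t) = m∞ + (m0 - m∞)·exp(-(λ+ν)·t),   m∞ = ν / (λ+ν).

With ν = 0 this is pure exponential decay — log m(t) is linear with slope
-λ regardless of the starting level. Positive ν both slows the apparent
loss and raises the plateau, the two signatures used to rank domain classes
by de novo activity. Fitting mirrors the degron time-course analysis:
ordinary least squares of log(weighted mean %) on day over the early,
approximately log-linear window (days 0-6 by default), with the final level
read off at the last time point (day 12).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .domains import wilcoxon_rank_sum

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KineticParams:
    """Forward-model rates: loss λ (/day), de novo gain ν (/day), initial m0."""

    lam: float
    nu: float
    m0: float

    def __post_init__(self) -> None:
        if self.lam < 0 or self.nu < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.m0 <= 1:
            raise ValueError("m0 must be a fraction in [0, 1]")

    @property
    def plateau(self) -> float:
        """Steady state m∞ = ν/(λ+ν); undefined when both rates are zero."""
        if self.lam + self.nu == 0:
            raise ValueError("plateau undefined: λ + ν = 0")
        return self.nu / (self.lam + self.nu)


def decay_model(params: KineticParams, t) -> np.ndarray | float:
    """Methylated fraction m(t) of the maintenance-loss ODE, closed form.

    λ+ν = 0 degenerates to the constant m0 (flagged with a warning).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    rate = params.lam + params.nu
    if rate == 0:
        warnings.warn("λ + ν = 0: methylation is constant", stacklevel=2)
        out = np.full_like(t, params.m0)
        return float(out) if out.ndim == 0 else out
    m_inf = params.plateau
    out = m_inf + (params.m0 - m_inf) * np.exp(-rate * t)
    return float(out) if out.ndim == 0 else out


@dataclass
class KineticsFit:
    """Log-space early-window slope and late plateau level for one domain."""

    slope: float  # d log(m%) / d day over the fit window (natural log)
    intercept: float
    final_level: float  # weighted mean % at final_day (or last available)
    fit_window: tuple[float, float]
    n_points: int


def fit_decay(
    days: Sequence[float],
    values_pct: Sequence[float],
    fit_window: tuple[float, float] = (0.0, 6.0),
    final_day: float = 12.0,
) -> KineticsFit:
    """OLS of log(weighted mean %) on day within the early fit window.

    `values_pct` are weighted mean methylation percentages per time point.
    Requires >= 3 points inside the window, all positive (the log applies);
    a non-positive value excludes the domain (raises, caller logs). The
    final level is the value at `final_day`, or the last available time
    point when that day is absent (logged).
    """
    days = np.asarray(days, dtype=float)
    vals = np.asarray(values_pct, dtype=float)
    if days.shape != vals.shape:
        raise ValueError("days/values length mismatch")
    if np.any(vals <= 0):
        raise ValueError("non-positive methylation value: cannot fit in log space")
    sel = (days >= fit_window[0]) & (days <= fit_window[1])
    if sel.sum() < 3:
        raise ValueError("need >= 3 time points inside the fit window")
    x = days[sel]
    y = np.log(vals[sel])
    slope, intercept = np.polyfit(x, y, 1)
    at_final = np.isclose(days, final_day)
    if at_final.any():
        final = float(vals[at_final][0])
    else:
        last = np.argmax(days)
        log.info("final day %g absent; using day %g", final_day, days[last])
        final = float(vals[last])
    return KineticsFit(
        slope=float(slope),
        intercept=float(intercept),
        final_level=final,
        fit_window=fit_window,
        n_points=int(sel.sum()),
    )


def fit_decay_table(
    table: pd.DataFrame,
    fit_window: tuple[float, float] = (0.0, 6.0),
    final_day: float = 12.0,
) -> pd.DataFrame:
    """Fit every domain in a long-format (domain_id, day, weighted_mean_pct)
    table; domains with non-positive values are excluded and logged."""
    rows = []
    for domain_id, grp in table.groupby("domain_id", sort=False):
        try:
            fit = fit_decay(
                grp["day"].to_numpy(),
                grp["weighted_mean_pct"].to_numpy(),
                fit_window,
                final_day,
            )
        except ValueError as exc:
            log.warning("domain %s excluded from kinetics: %s", domain_id, exc)
            continue
        row = {"domain_id": domain_id, "slope": fit.slope,
               "intercept": fit.intercept, "final_level": fit.final_level,
               "n_points": fit.n_points}
        if "class" in grp.columns:
            row["class"] = grp["class"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def compare_classes(
    fits_by_class: Mapping[str, Sequence[KineticsFit]],
    min_size: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class medians of slope/final level plus pairwise rank-sum tests.

    Classes with fewer than `min_size` fits are skipped with a warning.
    Returns (per-class summary, pairwise test table with p-values for both
    the slope and the final level).
    """
    usable: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, fits in fits_by_class.items():
        if len(fits) < min_size:
            log.warning("class %s has %d fits (< %d): skipped", name, len(fits), min_size)
            continue
        usable[name] = (
            np.array([f.slope for f in fits]),
            np.array([f.final_level for f in fits]),
        )
    if len(usable) < 2:
        raise ValueError("need at least 2 usable classes")
    summary = pd.DataFrame(
        [
            {
                "class": name,
                "n": len(slopes),
                "median_slope": float(np.median(slopes)),
                "median_final": float(np.median(finals)),
            }
            for name, (slopes, finals) in usable.items()
        ]
    )
    names = list(usable)
    rows = []
    for i, x in enumerate(names):
        for y in names[i + 1 :]:
            _, p_slope = wilcoxon_rank_sum(usable[x][0], usable[y][0])
            _, p_final = wilcoxon_rank_sum(usable[x][1], usable[y][1])
            rows.append({"class_a": x, "class_b": y,
                         "p_slope": p_slope, "p_final": p_final})
    return summary, pd.DataFrame(rows)
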