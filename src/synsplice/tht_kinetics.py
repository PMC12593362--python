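"""Ingestion, normalisation and empirical fitting of ThT fluorescence curves.

Thioflavin T fluorescence tracks amyloid fibril mass over time.  Three
quantities are extracted here:

* T50 — the time of the first sample at or above half the maximal
  normalised signal (by the stated rule, no interpolation);
* the scaling exponent γ from T50 = a·[monomer]^γ;
* the empirical rate parameters of the fibril-mass accumulation model

      y(t) = 1 − [1 + λ²/(2κ²θ)·e^{κt}]^{−θ},     0 ≤ θ ≤ 3,

  where λ collects the primary pathway (primary nucleation plus
  elongation), κ the secondary pathway (secondary processes plus
  elongation) and θ is a shape parameter shared across replicates of a
  group.  Only data up to each trace's maximum enter the fit, which
  guards against plateau-phase signal loss (flocculation).

A pelleting-assay helper converts densitometry pairs into the percent
of insoluble (pelletable) material.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

MIN_FIT_POINTS = 10


@dataclass(frozen=True)
class ThTTrace:
    time: np.ndarray                      # hours, strictly increasing
    signal: np.ndarray                    # arbitrary (or normalised) units
    well_id: str = ""
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time, float)
        y = np.asarray(self.signal, float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", y)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("time and signal must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("signal contains non-finite values")


@dataclass
class KineticFit:
    lam: float                  # h^-1
    kap: float                  # h^-1
    theta: float
    residual_ss: float
    n_points: int
    well_id: str = ""
    converged: bool = True
    theta_at_bound: bool = False


@dataclass
class ScalingFit:
    a: float
    gamma: float
    ci95: tuple[float, float]
    loglog_slope: float
    n_points: int


@dataclass
class PelletingResult:
    d_sol: float
    d_whole: float
    pct_pelletable: float


# ------------------------------------------------------------ normalisation


def normalize_trace(trace: ThTTrace, mode: str = "well_max",
                    group_max: float | None = None) -> ThTTrace:
    """Scale a trace to [0, 1] by its own maximum or a dataset maximum.

    ``dataset_max`` (pass ``group_max``) is for wells that never reach a
    plateau, which are normalised to the maximum observed across a named
    trace group instead of their own maximum.
    """
    if mode == "well_max":
        m = float(np.max(trace.signal))
    elif mode == "dataset_max":
        if group_max is None:
            raise ValueError("dataset_max mode needs group_max")
        m = float(group_max)
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    if m <= 0:
        raise ValueError("cannot normalise: maximum signal is not positive")
    return replace(trace, signal=trace.signal / m)


def t50(trace: ThTTrace) -> float | None:
    """Time of the first sample with signal ≥ half the trace maximum.

    Returns None when the threshold is never crossed (e.g. a flat trace).
    """
    y = trace.signal
    m = float(np.max(y))
    if m <= 0:
        return None
    idx = np.flatnonzero(y >= 0.5 * m)
    if idx.size == 0:
        return None
    t = float(trace.time[idx[0]])
    if np.all(y >= 0.5 * m):      # never below threshold: nothing crossed
        return None if np.ptp(y) == 0 else t
    return t


# ------------------------------------------------------------ scaling fit


def fit_scaling(t50s: list[tuple[float, float | None]]) -> ScalingFit:
    """Fit T50 = a·c^γ to (concentration µM, T50 h) pairs.

    Unreached T50s (None) are dropped with a warning.  Reports the
    nonlinear fit with a 95% CI on γ from the covariance, plus the
    log-log linear slope as a cross-check.
    """
    pts = [(c, t) for c, t in t50s if t is not None]
    if len(pts) < len(t50s):
        warnings.warn(f"excluded {len(t50s) - len(pts)} unreached T50 value(s)")
    if len({c for c, _ in pts}) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    x = np.array([c for c, _ in pts], float)
    y = np.array([t for _, t in pts], float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("concentrations and T50s must be positive")
    slope, logc = np.polyfit(np.log(x), np.log(y), 1)
    popt, pcov = curve_fit(lambda c, a, g: a * c**g, x, y,
                           p0=[np.exp(logc), slope], maxfev=10000)
    gerr = float(np.sqrt(pcov[1, 1]))
    return ScalingFit(float(popt[0]), float(popt[1]),
                      (popt[1] - 1.96 * gerr, popt[1] + 1.96 * gerr),
                      float(slope), len(pts))


# ------------------------------------------------------------ empirical fit


def amyloid_curve(t, lam, kap, theta):
    """Normalised fibril mass y(t) = 1 − [1 + λ²/(2κ²θ)·e^{κt}]^{−θ}."""
    t = np.asarray(t, float)
    if theta <= 0:
        raise ValueError("theta must be positive")
    with np.errstate(over="ignore"):   # inf bracket is fine: y -> 1
        bracket = 1.0 + lam**2 / (2.0 * kap**2 * theta) * np.exp(kap * t)
        return 1.0 - bracket ** (-theta)


def _truncate_at_max(trace: ThTTrace) -> ThTTrace:
    """Keep only data up to (and including) the signal maximum."""
    imax = int(np.argmax(trace.signal))
    return replace(trace, time=trace.time[: imax + 1],
                   signal=trace.signal[: imax + 1])


def _kappa_guess(trace: ThTTrace) -> float:
    """κ init from the maximum slope of log-signal in the growth phase."""
    y = np.clip(trace.signal, 1e-6, None)
    slopes = np.diff(np.log(y)) / np.diff(trace.time)
    good = slopes[np.isfinite(slopes) & (slopes > 0)]
    return float(np.max(good)) if good.size else 1.0 / max(trace.time[-1], 1.0)


_LAM_STARTS = (1e-3, 1e-2, 1e-1)
_THETA_MAX = 3.0


def fit_empirical(traces: list[ThTTrace], shared_theta: bool = True
                  ) -> list[KineticFit]:
    """Bound-constrained least-squares fit of the empirical growth model.

    λ and κ are fitted per replicate; θ is shared across the group when
    ``shared_theta`` (one θ per variant/buffer series).  Each trace is
    truncated at its maximum before fitting.  Multistart over λ initial
    values; κ is initialised from the steepest log-signal slope.
    """
    if not traces:
        raise ValueError("no traces to fit")
    truncs = [_truncate_at_max(tr) for tr in traces]
    for tr in truncs:
        if tr.time.size < MIN_FIT_POINTS:
            raise ValueError(f"trace {tr.well_id!r}: fewer than "
                             f"{MIN_FIT_POINTS} points before the maximum")
    if not shared_theta:
        return [f for tr in truncs for f in (_fit_group([tr]),)]
    fits = _fit_group_shared(truncs)
    return fits


def _residuals(params, truncs):
    theta = params[0]
    res = []
    for k, tr in enumerate(truncs):
        lam, kap = params[1 + 2 * k], params[2 + 2 * k]
        res.append(amyloid_curve(tr.time, lam, kap, theta) - tr.signal)
    return np.concatenate(res)


def _fit_group_shared(truncs) -> list[KineticFit]:
    nrep = len(truncs)
    lo = [1e-8] + [0.0, 1e-8] * nrep
    hi = [_THETA_MAX] + [np.inf, np.inf] * nrep
    best = None
    for lam0 in _LAM_STARTS:
        x0 = [1.0]
        for tr in truncs:
            x0 += [lam0, _kappa_guess(tr)]
        try:
            sol = least_squares(_residuals, x0, bounds=(lo, hi),
                                args=(truncs,), method="trf", xtol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return [KineticFit(np.nan, np.nan, np.nan, np.inf, tr.time.size,
                           tr.well_id, converged=False) for tr in truncs]
    theta = float(best.x[0])
    at_bound = theta <= 1e-6 or theta >= _THETA_MAX - 1e-6
    if at_bound:
        warnings.warn(f"theta pinned at bound ({theta:.3g})")
    fits = []
    for k, tr in enumerate(truncs):
        lam, kap = float(best.x[1 + 2 * k]), float(best.x[2 + 2 * k])
        rss = float(np.sum((amyloid_curve(tr.time, lam, kap, theta)
                            - tr.signal) ** 2))
        fits.append(KineticFit(lam, kap, theta, rss, tr.time.size, tr.well_id,
                               converged=bool(best.success),
                               theta_at_bound=at_bound))
    return fits


def _fit_group(truncs) -> KineticFit:
    return _fit_group_shared(truncs)[0]


# ------------------------------------------------------------ pelleting


def pct_pelletable(d_sol: float, d_whole: float) -> float:
    """Percent insoluble material, 100·(1 − Dsol/Dwhole), clipped to [0, 100]."""
    if d_whole <= 0:
        raise ValueError("whole-sample densitometry must be positive")
    pct = 100.0 * (1.0 - d_sol / d_whole)
    if not 0.0 <= pct <= 100.0:
        warnings.warn(f"pelletable percentage {pct:.1f} outside [0, 100]; clipped")
        pct = float(np.clip(pct, 0.0, 100.0))
    return pct


# ------------------------------------------------------------ plate I/O

PLATE_COLUMNS = ["time_h", "signal", "well", "variant", "conc_uM",
                 "nacl_mM", "seeded"]


def read_plate_csv(path: str | Path, sep: str | None = None) -> list[ThTTrace]:
    """Read long-format plate data (columns: time_h, signal, well, variant,
    conc_uM, nacl_mM, seeded) into one trace per well."""
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = set(PLATE_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"plate file lacks columns {sorted(missing)}")
    traces = []
    for well, grp in df.groupby("well", sort=False):
        grp = grp.sort_values("time_h")
        cond = {k: grp[k].iloc[0] for k in PLATE_COLUMNS[3:] if k in grp}
        traces.append(ThTTrace(grp.time_h.to_numpy(float),
                               grp.signal.to_numpy(float), str(well), cond))
    return traces


def fits_table(fits: list[KineticFit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "well": f.well_id, "lambda_per_h": f.lam, "kappa_per_h": f.kap,
        "theta": f.theta, "rss": f.residual_ss, "n": f.n_points,
        "converged": f.converged} for f in fits])
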