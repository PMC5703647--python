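"""Summary statistics over trajectories and per-junction time series.

Conventions: population (divide-by-n) standard deviations throughout;
correlation lags live on the recording grid; deviations are taken from
each junction's own temporal mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .tissue import Tissue

__all__ = [
    "CorrelationCurve",
    "t1_rate",
    "topological_disorder",
    "polygon_fractions",
    "length_cv",
    "snapshot_tension_cv",
    "autocorr",
    "fit_exp_decay",
    "cross_corr",
    "cumulative_t1_curve",
    "fit_saturating",
    "windowed_rate",
    "aligned_t1_profiles",
]


@dataclass
class CorrelationCurve:
    """Junction-averaged correlation values on a lag grid (minutes)."""

    lags: np.ndarray
    values: np.ndarray
    n_junctions: int

    def lag_of_min(self) -> float:
        return float(self.lags[int(np.argmin(self.values))])

    def lag_of_max(self) -> float:
        return float(self.lags[int(np.argmax(self.values))])


# ----------------------------------------------------------------------
# snapshot statistics

def t1_rate(n_events: int, n_junctions_t0: int, duration: float) -> float:
    """Events per minute per junction, normalized to the junction count
    at the start of the observation window."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if n_junctions_t0 <= 0:
        raise ValueError("n_junctions_t0 must be positive")
    return n_events / (n_junctions_t0 * duration)


def topological_disorder(sides) -> float:
    """Population SD of per-cell side counts at one time point."""
    sides = _sides_array(sides)
    if len(sides) < 2:
        raise ValueError("need at least 2 cells")
    return float(np.std(sides))


def polygon_fractions(sides) -> dict[int, float]:
    sides = _sides_array(sides)
    if len(sides) == 0:
        raise ValueError("need at least 1 cell")
    vals, counts = np.unique(sides, return_counts=True)
    return {int(v): float(c) / len(sides) for v, c in zip(vals, counts)}


def _sides_array(sides) -> np.ndarray:
    if isinstance(sides, Tissue):
        return sides.cell_sides()
    return np.asarray(sides)


def length_cv(lengths) -> float:
    """SD/mean of junction lengths across the tissue (CV_L)."""
    if isinstance(lengths, Tissue):
        lengths = lengths.edge_lengths()
    lengths = np.asarray(lengths, dtype=float)
    if len(lengths) < 2:
        raise ValueError("need at least 2 junctions")
    m = lengths.mean()
    if m == 0:
        raise ValueError("mean junction length is zero")
    return float(lengths.std() / m)


def snapshot_tension_cv(values) -> float:
    """SD/mean of instantaneous per-junction tension (or intensity)
    across the tissue at one frame."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 junctions")
    return float(values.std() / values.mean())


# ----------------------------------------------------------------------
# correlation functions

def autocorr(
    series: np.ndarray,
    frame_interval: float,
    max_lag: float = 10.0,
    return_per_junction: bool = False,
):
    """Normalized intensity autocorrelation, junction-averaged.

    Per junction: ``(mean_t[I(t) I(t+dt)] - Ibar^2) / Ibar^2`` with
    ``Ibar`` the junction's temporal mean; constant series contribute a
    zero curve.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    n_j, n_t = series.shape
    n_lags = min(int(round(max_lag / frame_interval)), n_t - 1)
    if n_lags < 1:
        raise ValueError("series too short for the requested max_lag")
    lags = np.arange(n_lags + 1) * frame_interval
    curves = np.zeros((n_j, n_lags + 1))
    for j in range(n_j):
        x = series[j]
        ibar = x.mean()
        if ibar == 0 or np.all(x == x[0]):
            continue
        for k in range(n_lags + 1):
            prod = x[: n_t - k] * x[k:]
            curves[j, k] = (prod.mean() - ibar**2) / ibar**2
    curve = CorrelationCurve(lags=lags, values=curves.mean(axis=0), n_junctions=n_j)
    if return_per_junction:
        return curve, curves
    return curve


def fit_exp_decay(
    curve: CorrelationCurve,
    sigma: np.ndarray | None = None,
    offset: bool = False,
) -> tuple[float, float, float, float]:
    """Least-squares fit of ``y = a exp(-b x)``.

    Returns ``(a, b, decorrelation_time, b_se)`` with ``b`` the
    decay-rate magnitude (1/min), decorrelation_time its inverse and
    ``b_se`` the asymptotic standard error.  The printed convention
    elsewhere may carry the opposite sign on ``b``.

    With ``offset=True`` an additive constant is included to absorb the
    finite-series bias of the mean-subtracted estimator (which depresses
    the whole curve by roughly ``2 tau/T`` times the variance).
    """
    x, y = np.asarray(curve.lags, float), np.asarray(curve.values, float)
    if len(x) < 4:
        raise ValueError("need at least 4 lag points")
    if y[0] <= 0:
        raise ValueError("fit requires a positive value at lag 0")

    half = y < y[0] / 2
    b0 = np.log(2) / (x[np.argmax(half)] if half.any() else x[-1])
    kw = {}
    if sigma is not None:
        kw = {"sigma": np.asarray(sigma, float), "absolute_sigma": True}
    if offset:
        model = lambda x, a, b, c: a * np.exp(-b * x) + c
        p0 = (y[0], b0, 0.0)
    else:
        model = lambda x, a, b: a * np.exp(-b * x)
        p0 = (y[0], b0)
    popt, pcov = curve_fit(model, x, y, p0=p0, maxfev=20_000, **kw)
    a, b = float(popt[0]), abs(float(popt[1]))
    if b == 0:
        raise ValueError("degenerate fit: zero decay rate")
    return a, b, 1.0 / b, float(np.sqrt(pcov[1, 1]))


def cross_corr(
    series_a: np.ndarray,
    series_b: np.ndarray,
    frame_interval: float,
    max_lag: float = 10.0,
) -> CorrelationCurve:
    """Junction-averaged normalized cross-correlation
    ``mean_t[da(t) db(t+dt)] / (sd_a sd_b)``.

    Deviations are from each junction's own temporal mean; junctions
    with zero variance in either series are excluded.  Positive lag
    means ``a`` leads ``b``.
    """
    a = np.atleast_2d(np.asarray(series_a, dtype=float))
    b = np.atleast_2d(np.asarray(series_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("series must be aligned with equal shapes")
    n_j, n_t = a.shape
    n_lags = min(int(round(max_lag / frame_interval)), n_t - 2)
    lags = np.arange(-n_lags, n_lags + 1) * frame_interval
    acc = np.zeros(2 * n_lags + 1)
    used = 0
    for j in range(n_j):
        da = a[j] - a[j].mean()
        db = b[j] - b[j].mean()
        sa, sb = da.std(), db.std()
        if sa == 0 or sb == 0:
            continue
        used += 1
        for i, k in enumerate(range(-n_lags, n_lags + 1)):
            if k >= 0:
                prod = da[: n_t - k] * db[k:]
            else:
                prod = da[-k:] * db[: n_t + k]
            acc[i] += prod.mean() / (sa * sb)
    if used == 0:
        raise ValueError("no junction with nonzero variance in both series")
    return CorrelationCurve(lags=lags, values=acc / used, n_junctions=used)


# ----------------------------------------------------------------------
# cumulative event curves

def cumulative_t1_curve(
    event_times: np.ndarray, n_junctions_t0: int, t0: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-junction cumulative event count as a step curve (t, C(t))."""
    times = np.sort(np.asarray(event_times, dtype=float)) - t0
    counts = np.arange(1, len(times) + 1) / n_junctions_t0
    return times, counts


def fit_saturating(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Fit ``C(t) = a (1 - exp(-b t))`` by nonlinear least squares."""
    t, c = np.asarray(t, float), np.asarray(c, float)
    if len(t) < 2:
        raise ValueError("need at least 2 points to fit")

    def model(t, a, b):
        return a * (1.0 - np.exp(-b * t))

    slope0 = (c[-1] - c[0]) / max(t[-1] - t[0], 1e-12)
    a0 = max(c[-1], 1e-9)
    popt, _ = curve_fit(model, t, c, p0=(a0, max(slope0 / a0, 1e-6)), maxfev=20_000)
    return float(popt[0]), float(popt[1])


def windowed_rate(
    t: np.ndarray, c: np.ndarray, window: float, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Centered-difference rate ``(C(t+w/2) - C(t-w/2)) / w`` of a
    cumulative step curve, evaluated on ``grid``."""
    t, c = np.asarray(t, float), np.asarray(c, float)
    step_t = np.concatenate([[-np.inf], t])
    step_c = np.concatenate([[0.0], c])

    def C(x):
        return step_c[np.searchsorted(step_t, x, side="right") - 1]

    if grid is None:
        grid = np.linspace(t[0] + window / 2, t[-1] - window / 2, 50) if len(t) else np.array([])
    grid = np.asarray(grid, float)
    return grid, (C(grid + window / 2) - C(grid - window / 2)) / window


# ----------------------------------------------------------------------
# event-aligned profiles

def aligned_t1_profiles(
    length_series: dict[int, np.ndarray],
    times: np.ndarray,
    events: list,
    neighbors_of: dict[int, list[int]],
    half_window: float,
    frame_interval: float,
):
    """Mean junction-length profiles aligned to the four-way-vertex time.

    Parameters
    ----------
    length_series : mapping junction id -> full-length time series.
    times : frame times (min).
    events : records with ``edge_id`` and ``time`` attributes.
    neighbors_of : mapping focal junction id -> its four first neighbors
        at the event time.
    half_window : minutes on each side of the event.

    Returns a dict with keys ``rel_times``, ``focal``, ``neighbors``,
    ``total`` (mean over events) plus ``n_used``/``n_excluded``.
    """
    k = int(round(half_window / frame_interval))
    rel = np.arange(-k, k + 1) * frame_interval
    focal_stack, nb_stack, tot_stack = [], [], []
    excluded = 0
    for ev in events:
        i0 = int(np.argmin(np.abs(times - ev.time)))
        if i0 - k < 0 or i0 + k >= len(times):
            excluded += 1
            continue
        nbs = neighbors_of.get(ev.edge_id)
        if nbs is None or len(nbs) != 4 or any(n not in length_series for n in nbs):
            excluded += 1
            continue
        focal = length_series[ev.edge_id][i0 - k : i0 + k + 1]
        nb = np.array([length_series[n][i0 - k : i0 + k + 1] for n in nbs])
        if np.any(np.isnan(focal)) or np.any(np.isnan(nb)):
            excluded += 1
            continue
        focal_stack.append(focal)
        nb_stack.append(nb.mean(axis=0))
        tot_stack.append(focal + nb.sum(axis=0))
    if not focal_stack:
        return {
            "rel_times": rel,
            "focal": np.full_like(rel, np.nan, dtype=float),
            "neighbors": np.full_like(rel, np.nan, dtype=float),
            "total": np.full_like(rel, np.nan, dtype=float),
            "n_used": 0,
            "n_excluded": excluded,
        }
    return {
        "rel_times": rel,
        "focal": np.mean(focal_stack, axis=0),
        "neighbors": np.mean(nb_stack, axis=0),
        "total": np.mean(tot_stack, axis=0),
        "n_used": len(focal_stack),
        "n_excluded": excluded,
    }
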