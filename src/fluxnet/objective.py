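"""Model-data disagreement: two-dimensional point errors, NRMSE, total error.

A data point may miss the model in value *or* in time (e.g. the model
blooms a week late).  The per-point error is therefore the minimum squared
distance in a two-dimensional (concentration, time) space, with the time
axis scaled into concentration units by a first-order rate constant k_ch:

    ES = min_k [ (C_d - C_m,k)^2 + ((t_d - t_m,k) * ave[C_d, C_m,k] * k_ch)^2 ]

taken over all model output points k.  Per-series errors are combined as a
normalized RMSE (sqrt of the mean ES over points, divided by the observed
series mean), then weighted and summed across series into the total error.
All errors are computed in arithmetic space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ObservationSeries",
    "ErrorReport",
    "point_error",
    "series_error",
    "total_error",
]

#: default coupling of the time and value dimensions (1/d): a 10-day offset
#: costs about as much as a full-magnitude concentration error
DEFAULT_K_CH = 0.1


@dataclass
class ObservationSeries:
    """One observed time series (times sorted, values finite)."""

    series_id: str
    t: np.ndarray
    v: np.ndarray
    weight: float = 1.0
    k_ch: float = DEFAULT_K_CH

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.size and np.any(np.diff(self.t) < 0):
            order = np.argsort(self.t)
            self.t, self.v = self.t[order], self.v[order]


@dataclass
class ErrorReport:
    total: float
    per_series: dict[str, float] = field(default_factory=dict)   # NRMSE
    weights: dict[str, float] = field(default_factory=dict)
    per_point: dict[str, np.ndarray] = field(default_factory=dict)  # ES
    argmin: dict[str, np.ndarray] = field(default_factory=dict)


def point_error(t_d: float, C_d: float, t_m: np.ndarray, C_m: np.ndarray,
                k_ch: float = DEFAULT_K_CH) -> tuple[float, int]:
    """Minimum two-dimensional error square of one data point vs a model series.

    Returns (ES, index of the minimizing model point).  The average in the
    time term uses the candidate model point: ave = (C_d + C_m,k)/2.
    """
    t_m = np.asarray(t_m, dtype=float)
    C_m = np.asarray(C_m, dtype=float)
    if t_m.size == 0:
        raise ValueError("model series is empty")
    ave = 0.5 * (C_d + C_m)
    es = (C_d - C_m) ** 2 + ((t_d - t_m) * ave * k_ch) ** 2
    k = int(np.argmin(es))
    return float(es[k]), k


def _es_matrix(t_d, C_d, t_m, C_m, k_ch):
    ave = 0.5 * (C_d[:, None] + C_m[None, :])
    return (C_d[:, None] - C_m[None, :]) ** 2 + \
        ((t_d[:, None] - t_m[None, :]) * ave * k_ch) ** 2


def series_error(obs: ObservationSeries, t_m: np.ndarray, C_m: np.ndarray,
                 normalizer: str = "mean",
                 search_window: float | None = None) -> tuple[float, np.ndarray, np.ndarray]:
    """(NRMSE, per-point ES, per-point argmin) for one series.

    normalizer: "mean" (default) or "range" of the observed values; an
    all-zero normalizer is signaled as a ValueError.  ``search_window``
    (days) optionally restricts the minimum to model points within that
    distance of the data time — a speed path only; the default None is
    the exact global minimum over all model points.
    """
    t_m = np.asarray(t_m, dtype=float)
    C_m = np.asarray(C_m, dtype=float)
    if obs.t.size == 0:
        raise ValueError(f"series {obs.series_id!r} has no observations")
    if search_window is not None and t_m.size > 16:
        lo = np.searchsorted(t_m, obs.t - search_window, side="left")
        hi = np.searchsorted(t_m, obs.t + search_window, side="right")
        width = int((hi - lo).max())
        cols = np.minimum(lo[:, None] + np.arange(width)[None, :], t_m.size - 1)
        tm_w, cm_w = t_m[cols], C_m[cols]
        ave = 0.5 * (obs.v[:, None] + cm_w)
        es = (obs.v[:, None] - cm_w) ** 2 + ((obs.t[:, None] - tm_w) * ave * obs.k_ch) ** 2
        ksub = np.argmin(es, axis=1)
        rows = np.arange(len(obs.t))
        kmin = cols[rows, ksub]
        es_min = es[rows, ksub]
    else:
        es = _es_matrix(obs.t, obs.v, t_m, C_m, obs.k_ch)
        kmin = np.argmin(es, axis=1)
        es_min = es[np.arange(len(obs.t)), kmin]
    if normalizer == "mean":
        norm = float(np.mean(np.abs(obs.v)))
    elif normalizer == "range":
        norm = float(np.ptp(obs.v))
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if norm == 0.0:
        raise ValueError(f"series {obs.series_id!r}: normalizer is zero")
    return float(np.sqrt(np.mean(es_min)) / norm), es_min, kmin


def total_error(observations: list[ObservationSeries],
                modeled: dict[str, tuple[np.ndarray, np.ndarray]],
                normalizer: str = "mean",
                search_window: float | None = None) -> ErrorReport:
    """Weighted sum of per-series NRMSE over all observation series.

    ``modeled`` maps series_id -> (model times, model values).
    """
    rep = ErrorReport(total=0.0)
    for obs in observations:
        t_m, C_m = modeled[obs.series_id]
        nrmse, es, kmin = series_error(obs, t_m, C_m, normalizer=normalizer,
                                       search_window=search_window)
        rep.per_series[obs.series_id] = nrmse
        rep.weights[obs.series_id] = obs.weight
        rep.per_point[obs.series_id] = es
        rep.argmin[obs.series_id] = kmin
        rep.total += obs.weight * nrmse
    return rep
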