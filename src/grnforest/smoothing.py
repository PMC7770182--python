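"""Local linear regression smoothing and derivative estimation.

Noisy time-courses are denoised with a LOESS-style local linear fit: at each
measurement time t_k a weighted straight line is fitted over the nearest
fraction ``span`` of the points, with tricube distance weights. The fitted
intercept at t_k is the smoothed level and the fitted slope is the estimate
of dX/dt at t_k, which feeds the regression targets of the network model.
Steady-state derivatives are zero by definition and are handled by the
training-set builder, not here.

Windows truncate at the series ends (no reflection), and smoothing never
crosses experiment boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datasets import ExpressionDataset
from .exceptions import ValidationError

__all__ = ["SmoothedSeries", "local_linear_smooth", "smooth_dataset", "window_weights"]


@dataclass
class SmoothedSeries:
    times: np.ndarray
    smoothed: np.ndarray
    derivatives: np.ndarray


def window_weights(times: np.ndarray, k: int, span: float, kernel: str):
    """Window membership and kernel weights for the fit at ``times[k]``.

    Returns (indices, weights). The window holds the ``ceil(span * n)``
    nearest points by |t - t_k| (ties resolved toward earlier indices); the
    tricube kernel is applied on distance normalized by the largest distance
    in the window, so the farthest point gets weight zero. Two-point windows
    fall back to uniform weights (a tricube two-point window would leave a
    single effective observation for a two-parameter fit).
    """
    n = len(times)
    r = int(np.ceil(span * n))
    if r < 2:
        raise ValidationError(
            f"span={span} gives a {r}-point window on {n} points; "
            "a local line needs at least 2"
        )
    r = min(r, n)
    d = np.abs(times - times[k])
    order = np.argsort(d, kind="stable")
    idx = order[:r]
    dd = d[idx]
    # bandwidth = distance to the (r+1)-th nearest point so every window
    # member keeps a strictly positive weight (boundary-zero tricube would
    # collapse symmetric windows to a single effective point)
    dmax = dd.max()
    dcut = d[order[r]] if r < n else dmax * 1.05
    dcut = max(dcut, dmax * (1.0 + 1e-9))
    if kernel == "uniform" or r == 2 or dmax == 0:
        w = np.ones(r)
    elif kernel == "tricube":
        u = np.clip(dd / dcut, 0.0, 1.0)
        w = (1 - u**3) ** 3
    else:
        raise ValidationError(f"unknown kernel: {kernel!r}")
    return idx, w


def local_linear_smooth(times, values, span: float = 0.3, kernel: str = "tricube") -> SmoothedSeries:
    """Fit a weighted line around every point; intercept = level, slope = d/dt."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(times)
    if n < 3:
        raise ValidationError("local linear smoothing needs at least 3 points")
    if values.shape[0] != n:
        raise ValidationError("times and values length mismatch")
    if not np.all(np.diff(times) > 0):
        raise ValidationError("times must be strictly increasing")
    smoothed = np.empty(n)
    deriv = np.empty(n)
    for k in range(n):
        idx, w = window_weights(times, k, span, kernel)
        t = times[idx] - times[k]  # center: intercept is the value at t_k
        y = values[idx]
        sw = w.sum()
        st = (w * t).sum()
        stt = (w * t * t).sum()
        sy = (w * y).sum()
        sty = (w * t * y).sum()
        det = sw * stt - st * st
        if det <= 0:
            # degenerate window (all usable mass at one time); flat fit
            smoothed[k] = sy / sw
            deriv[k] = 0.0
            continue
        b = (sw * sty - st * sy) / det
        a = (sy - b * st) / sw
        smoothed[k] = a
        deriv[k] = b
    return SmoothedSeries(times=times, smoothed=smoothed, derivatives=deriv)


def smooth_dataset(dataset: ExpressionDataset, span: float = 0.3, kernel: str = "tricube") -> ExpressionDataset:
    """Attach smoothed levels and derivative estimates to every experiment.

    Gene columns are smoothed per experiment; indicator columns are exact by
    construction, so they pass through unsmoothed with zero derivative.
    """
    new_exps = []
    for exp in dataset.experiments:
        smoothed = exp.values.copy()
        deriv = np.zeros_like(exp.values)
        for m in range(dataset.n_elements):
            if not dataset.is_gene[m]:
                continue
            res = local_linear_smooth(exp.times, exp.values[:, m], span=span, kernel=kernel)
            smoothed[:, m] = res.smoothed
            deriv[:, m] = res.derivatives
        new_exps.append(replace(exp, smoothed=smoothed, derivatives=deriv))
    return ExpressionDataset(
        element_names=list(dataset.element_names),
        experiments=new_exps,
        statics=list(dataset.statics),
        is_gene=dataset.is_gene.copy(),
    )
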