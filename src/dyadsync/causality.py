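"""Bivariate time-domain Granger causality between the two partners'
signals at one channel.

The causality value in the x->y direction is the log ratio of residual
variances of the restricted model (y on its own lags) and the full model
(y on its own lags plus x's lags); the nested-model F statistic tests its
significance.  Lag rows never cross block boundaries, so per-block
detrended task segments can be concatenated safely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as ssig
from scipy import stats as sps

from . import constants
from .errors import StageError, ValidationError
from .stats import one_sample_t, paired_t

__all__ = [
    "VARFit",
    "GCResult",
    "select_order",
    "granger_causality",
    "cohort_gc",
]


@dataclass(frozen=True)
class VARFit:
    order: int
    coefficients: np.ndarray  # (2, 2, p): row = equation, col = source
    residual_cov: np.ndarray  # (2, 2)
    restricted_var: tuple[float, float]  # own-lags-only residual variance per series
    n_effective: int

    @property
    def flagged_short(self) -> bool:
        return self.n_effective <= 10 * self.order


@dataclass(frozen=True)
class GCResult:
    dyad_id: str
    channel: int
    gc_x_to_y: float
    gc_y_to_x: float
    f_x_to_y: float
    f_y_to_x: float
    p_x_to_y: float
    p_y_to_x: float
    order: int


def _blocks_to_list(x: np.ndarray, blocks: Sequence[np.ndarray] | None) -> list[np.ndarray]:
    if blocks is None:
        return [np.asarray(x, dtype=float)]
    return [np.asarray(b, dtype=float) for b in blocks]


def _design(xb: list[np.ndarray], yb: list[np.ndarray], p: int):
    """Stack lagged regressors within blocks only.

    Returns (Y_target_pair, X_own_y, X_own_x, X_full) where X_full holds
    [1, y lags, x lags].
    """
    rows_y, rows_x, lag_y, lag_x = [], [], [], []
    for bx, by in zip(xb, yb):
        if bx.size != by.size:
            raise ValidationError("block length mismatch")
        n = bx.size
        if n <= p:
            continue
        idx = np.arange(p, n)
        rows_y.append(by[idx])
        rows_x.append(bx[idx])
        ly = np.column_stack([by[idx - k] for k in range(1, p + 1)])
        lx = np.column_stack([bx[idx - k] for k in range(1, p + 1)])
        lag_y.append(ly)
        lag_x.append(lx)
    if not rows_y:
        raise ValidationError("series too short for the requested order")
    ty = np.concatenate(rows_y)
    tx = np.concatenate(rows_x)
    LY = np.vstack(lag_y)
    LX = np.vstack(lag_x)
    ones = np.ones((ty.size, 1))
    return ty, tx, np.hstack([ones, LY]), np.hstack([ones, LX]), np.hstack([ones, LY, LX])


def _rss(design: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    beta, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ beta
    return float(resid @ resid), resid


def fit_var(
    x: np.ndarray,
    y: np.ndarray,
    p: int,
    blocks_x: Sequence[np.ndarray] | None = None,
    blocks_y: Sequence[np.ndarray] | None = None,
) -> VARFit:
    """Fit the joint VAR(p) plus the two own-lags-only models."""
    if p < 1:
        raise ValidationError("order must be >= 1")
    xb = _blocks_to_list(x, blocks_x)
    yb = _blocks_to_list(y, blocks_y)
    ty, tx, own_y, own_x, full = _design(xb, yb, p)
    n = ty.size
    rss_y_full, ry = _rss(full, ty)
    rss_x_full, rx = _rss(full, tx)
    rss_y_own, _ = _rss(own_y, ty)
    rss_x_own, _ = _rss(own_x, tx)
    cov = np.cov(np.vstack([rx, ry]))
    beta_y, *_ = np.linalg.lstsq(full, ty, rcond=None)
    beta_x, *_ = np.linalg.lstsq(full, tx, rcond=None)
    # full design columns: [1, y lags (p), x lags (p)]
    coeffs = np.empty((2, 2, p))
    coeffs[1, 1] = beta_y[1 : p + 1]  # y equation, y lags
    coeffs[1, 0] = beta_y[p + 1 : 2 * p + 1]  # y equation, x lags
    coeffs[0, 1] = beta_x[1 : p + 1]  # x equation, y lags
    coeffs[0, 0] = beta_x[p + 1 : 2 * p + 1]  # x equation, x lags
    return VARFit(
        order=p,
        coefficients=coeffs,
        residual_cov=np.atleast_2d(cov),
        restricted_var=(rss_x_own / n, rss_y_own / n),
        n_effective=n,
    )


def select_order(
    x: np.ndarray,
    y: np.ndarray,
    max_order: int = 20,
    criterion: str = "bic",
    blocks_x: Sequence[np.ndarray] | None = None,
    blocks_y: Sequence[np.ndarray] | None = None,
) -> int:
    """BIC (or AIC) minimizing joint VAR order in 1..max_order, evaluated on
    the common effective sample implied by ``max_order``."""
    if criterion not in ("bic", "aic"):
        raise ValidationError("criterion must be 'bic' or 'aic'")
    xb = _blocks_to_list(x, blocks_x)
    yb = _blocks_to_list(y, blocks_y)
    n_total = sum(b.size for b in xb)
    if n_total <= 10 * max_order:
        raise ValidationError("series too short for order selection up to max_order")

    best_p, best_score = 1, np.inf
    for p in range(1, max_order + 1):
        # common sample: drop the first max_order samples of every block
        ty_list, tx_list, full_list = [], [], []
        for bx, by in zip(xb, yb):
            n = bx.size
            if n <= max_order:
                continue
            idx = np.arange(max_order, n)
            ly = np.column_stack([by[idx - k] for k in range(1, p + 1)])
            lx = np.column_stack([bx[idx - k] for k in range(1, p + 1)])
            ty_list.append(by[idx])
            tx_list.append(bx[idx])
            full_list.append(np.hstack([np.ones((idx.size, 1)), ly, lx]))
        ty = np.concatenate(ty_list)
        tx = np.concatenate(tx_list)
        full = np.vstack(full_list)
        n = ty.size
        _, ry = _rss(full, ty)
        _, rx = _rss(full, tx)
        sigma = np.cov(np.vstack([rx, ry]), bias=True)
        det = np.linalg.det(sigma)
        if det <= 0:
            continue
        k_params = 2 * (2 * p + 1)
        penalty = k_params * (np.log(n) if criterion == "bic" else 2.0) / n
        score = float(np.log(det) + penalty)
        if score < best_score:
            best_score, best_p = score, p
    return best_p


def granger_causality(
    x: np.ndarray,
    y: np.ndarray,
    p: int,
    dyad_id: str = "",
    channel: int = 0,
    blocks_x: Sequence[np.ndarray] | None = None,
    blocks_y: Sequence[np.ndarray] | None = None,
) -> GCResult:
    """Granger causality in both directions at order ``p``.

    ``gc_x_to_y = ln(var_restricted(y) / var_full(y))`` clipped at 0, with
    the nested-model F statistic on (p, n - 2p - 1) degrees of freedom.
    """
    xb = _blocks_to_list(x, blocks_x)
    yb = _blocks_to_list(y, blocks_y)
    ty, tx, own_y, own_x, full = _design(xb, yb, p)
    n = ty.size
    df2 = n - (2 * p + 1)
    if df2 < 1:
        raise ValidationError("not enough samples for the full model")

    rss_y_own, _ = _rss(own_y, ty)
    rss_y_full, _ = _rss(full, ty)
    rss_x_own, _ = _rss(own_x, tx)
    rss_x_full, _ = _rss(full, tx)
    if min(rss_y_full, rss_x_full) <= 0:
        raise ValidationError("singular regression (zero residual variance)")

    gc_xy = max(float(np.log(rss_y_own / rss_y_full)), 0.0)
    gc_yx = max(float(np.log(rss_x_own / rss_x_full)), 0.0)
    f_xy = max((rss_y_own - rss_y_full) / p, 0.0) / (rss_y_full / df2)
    f_yx = max((rss_x_own - rss_x_full) / p, 0.0) / (rss_x_full / df2)
    return GCResult(
        dyad_id=dyad_id,
        channel=channel,
        gc_x_to_y=gc_xy,
        gc_y_to_x=gc_yx,
        f_x_to_y=float(f_xy),
        f_y_to_x=float(f_yx),
        p_x_to_y=float(sps.f.sf(f_xy, p, df2)),
        p_y_to_x=float(sps.f.sf(f_yx, p, df2)),
        order=p,
    )


def _task_blocks(recording, channel: int) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-block linearly detrended task-segment oxy-Hb for both partners."""
    times = np.arange(recording.n_times) / recording.fs
    xs, ys = [], []
    for _, row in recording.timeline.iterrows():
        if row["trial_type"] not in constants.TASK_SEGMENTS:
            continue
        on = float(row["onset"])
        off = on + float(row["duration"])
        m = (times >= on) & (times < off)
        xs.append(ssig.detrend(recording.data[0, channel - 1, 0, m]))
        ys.append(ssig.detrend(recording.data[1, channel - 1, 0, m]))
    return xs, ys


def cohort_gc(
    recordings: Sequence,
    channel: int,
    max_order: int = 20,
    order: int | None = None,
) -> tuple[list[GCResult], dict]:
    """Per-dyad Granger causality at one channel plus group-level tests.

    ``recordings`` are hb-stage recordings with aligned timelines.  Signals
    are the per-block detrended task segments; lags never cross block
    boundaries.  Returns per-dyad results and a report with one-sample t
    tests per direction (vs 0, one-tailed) and the paired two-tailed t test
    between directions.
    """
    recs = [r for r in recordings if not (r.bad_channels[:, channel - 1].any())]
    if len(recs) < 3:
        raise ValidationError("need at least 3 dyads with a valid channel")
    results = []
    for rec in recs:
        if rec.stage != "hb":
            raise StageError("cohort_gc requires hb-stage recordings")
        xs, ys = _task_blocks(rec, channel)
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        p = order or select_order(x, y, max_order=max_order, blocks_x=xs, blocks_y=ys)
        results.append(
            granger_causality(
                x, y, p, dyad_id=rec.dyad_id, channel=channel, blocks_x=xs, blocks_y=ys
            )
        )
    gxy = [r.gc_x_to_y for r in results]
    gyx = [r.gc_y_to_x for r in results]
    report = {
        "channel": channel,
        "n_dyads": len(results),
        "mean_gc_1_to_2": float(np.mean(gxy)),
        "mean_gc_2_to_1": float(np.mean(gyx)),
        "t_1_to_2": one_sample_t(gxy, tail="one").as_dict(),
        "t_2_to_1": one_sample_t(gyx, tail="one").as_dict(),
        "paired": paired_t(gxy, gyx, tail="two").as_dict(),
    }
    return results, report
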