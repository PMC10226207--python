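"""Gini index, concentration curves, and the concentration index.

The concentration index C of an outcome H against a living-standard
ranking r is twice the weighted covariance of H with the fractional rank,
scaled by the mean outcome:

    C = 2 cov_w(H, r) / mean_w(H)

equivalently one minus twice the area under the concentration curve.
Negative C means the outcome is concentrated among the poor (curve above
the diagonal).  For a binary outcome with mean H̄ the attainable range is
[H̄ − 1, 1 − H̄].

Covariances here are population-style (divide by total weight, no
finite-sample correction), so with equal weights the covariance form and
the rank-sum form ``(2 / (n H̄)) Σ H_i r_i − 1`` agree exactly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .survey import ConfigError, DataError, RankedOutcome, fractional_rank

__all__ = [
    "CurvePoints",
    "CIResult",
    "gini_index",
    "concentration_curve",
    "concentration_index",
    "ci_standard_error",
]

_NORMALIZATIONS = ("none", "wagstaff", "erreygers")


def _norm_weights(weight, n: int) -> np.ndarray:
    if weight is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(weight, dtype=float)
    total = w.sum()
    if total <= 0:
        raise DataError("total weight must be positive")
    return w / total


def _pop_cov(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Population-style weighted covariance, weights already normalized."""
    mx = float(w @ x)
    my = float(w @ y)
    return float(w @ ((x - mx) * (y - my)))


@dataclass
class CurvePoints:
    """Vertices of a concentration (or Lorenz) curve.

    ``population_share`` is the cumulative population share ranked poorest
    to richest; ``outcome_share`` the matching cumulative share of the
    outcome total.  Both start at 0 and end at 1; plots interpolate
    linearly between vertices.
    """

    population_share: np.ndarray
    outcome_share: np.ndarray
    label: str = ""

    def area(self) -> float:
        """Area under the curve by the trapezoid rule."""
        return float(np.trapezoid(self.outcome_share, self.population_share))


@dataclass
class CIResult:
    """A concentration (or Gini) index with its context.

    ``bounds`` holds the attainable interval (H̄ − 1, 1 − H̄) when the
    outcome is binary, else None.  ``se`` is filled by
    :func:`ci_standard_error` when requested.
    """

    value: float
    weighted: bool
    n: int
    mean_h: float
    se: float | None = None
    bounds: tuple[float, float] | None = None
    normalization: str = "none"

    def __float__(self) -> float:
        return self.value


def gini_index(y, weight=None) -> float:
    """Weighted Gini index of a nonnegative quantity.

    Computed as ``2 cov_w(y, r(y)) / mean_w(y)`` where r(y) are the
    weighted fractional ranks of y itself — i.e. the concentration index
    of y against its own ordering, which equals twice the area between
    the Lorenz curve and the diagonal.
    """
    yv = np.asarray(y, dtype=float)
    if np.any(yv < 0):
        raise DataError("Gini index requires nonnegative values")
    w = _norm_weights(weight, yv.size)
    mean = float(w @ yv)
    if mean <= 0:
        raise DataError("Gini index undefined for zero-mean input")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant y legitimately gives Gini 0
        r = fractional_rank(yv, w)
    return 2.0 * _pop_cov(yv, r, w) / mean


def concentration_curve(ranked, outcome=None, weight=None, label: str = "") -> CurvePoints:
    """Concentration curve of an outcome against a living-standard ranking.

    Parameters
    ----------
    ranked : RankedOutcome or array-like
        Either a :class:`~ineqdecomp.survey.RankedOutcome` or the raw
        ranking score.
    outcome : array-like
        Nonnegative per-unit outcome with positive total.
    weight : array-like, optional
        Sampling weights.

    Returns
    -------
    CurvePoints
        One vertex per distinct rank value, preceded by (0, 0).
    """
    if isinstance(ranked, RankedOutcome):
        ranks = ranked.ranks
    else:
        ranks = fractional_rank(ranked, weight)
    h = np.asarray(outcome, dtype=float)
    if np.any(h < 0) or h.sum() <= 0:
        raise DataError("curve requires a nonnegative outcome with positive total")
    w = _norm_weights(weight, h.size)

    order = np.argsort(ranks, kind="mergesort")
    r_sorted = ranks[order]
    w_sorted = w[order]
    hw_sorted = (h * w)[order]

    # pool tied ranks into single vertices
    boundaries = np.flatnonzero(np.diff(r_sorted)) + 1
    pop = np.add.reduceat(w_sorted, np.concatenate(([0], boundaries)))
    out = np.add.reduceat(hw_sorted, np.concatenate(([0], boundaries)))

    cpop = np.cumsum(pop)
    cout = np.cumsum(out)
    # normalize by the realized cumulative totals so both coordinates end
    # at exactly 1 and stay monotone despite accumulation round-off
    pop_share = np.concatenate(([0.0], cpop / cpop[-1]))
    out_share = np.concatenate(([0.0], cout / cout[-1]))
    return CurvePoints(population_share=pop_share, outcome_share=out_share, label=label)


def concentration_index(outcome, rank_score=None, weight=None, *,
                        ranks=None, weighted: bool = True,
                        normalize: str = "none") -> CIResult:
    """Concentration index of an outcome against a living-standard ranking.

    Parameters
    ----------
    outcome : array-like
        Per-unit outcome H with positive mean.
    rank_score : array-like, optional
        Living-standard score; ignored if precomputed ``ranks`` are given.
    weight : array-like, optional
        Sampling weights.  With ``weighted=False`` the weights are ignored
        entirely: units are re-ranked with equal weights and the
        covariance is unweighted.
    ranks : array-like, optional
        Precomputed fractional ranks (must match the ``weighted`` flag).
    normalize : {"none", "wagstaff", "erreygers"}
        Optional binary-outcome correction: Wagstaff divides by (1 − H̄),
        Erreygers multiplies by 4 H̄.  Default reports the plain index.
    """
    if normalize not in _NORMALIZATIONS:
        raise ConfigError(f"unknown normalization {normalize!r}; "
                          f"choose one of {_NORMALIZATIONS}")
    h = np.asarray(outcome, dtype=float)
    n = h.size
    if not weighted:
        weight = None
    if ranks is None:
        if rank_score is None:
            raise DataError("need rank_score or precomputed ranks")
        r = fractional_rank(rank_score, weight)
    else:
        r = np.asarray(ranks, dtype=float)
    w = _norm_weights(weight, n)
    mean_h = float(w @ h)
    if mean_h <= 0:
        raise DataError("concentration index undefined: mean outcome is zero")
    value = 2.0 * _pop_cov(h, r, w) / mean_h

    is_binary = set(np.unique(h)) <= {0.0, 1.0}
    bounds = (mean_h - 1.0, 1.0 - mean_h) if is_binary else None
    if normalize == "wagstaff":
        if not is_binary:
            raise DataError("Wagstaff normalization applies to binary outcomes")
        value = value / (1.0 - mean_h)
    elif normalize == "erreygers":
        if not is_binary:
            raise DataError("Erreygers correction applies to binary outcomes")
        value = 4.0 * mean_h * value
    return CIResult(value=value, weighted=weighted, n=n, mean_h=mean_h,
                    bounds=bounds, normalization=normalize)


def ci_standard_error(outcome, rank_score=None, weight=None, *,
                      ranks=None, cluster_id=None) -> float:
    """Standard error of the concentration index via convenient regression.

    Regresses ``2 σ_r² (H_i / H̄)`` on the fractional rank with the
    sampling weights; the slope of that weighted least-squares fit equals
    the concentration index and its heteroskedasticity-robust (HC1)
    standard error is returned.  With ``cluster_id`` the variance is
    cluster-robust instead (falling back to HC1, with a warning, when
    fewer than two clusters are present).
    """
    h = np.asarray(outcome, dtype=float)
    n = h.size
    if n < 2:
        raise DataError("need at least 2 units for a standard error")
    if ranks is None:
        if rank_score is None:
            raise DataError("need rank_score or precomputed ranks")
        r = fractional_rank(rank_score, weight)
    else:
        r = np.asarray(ranks, dtype=float)
    w = _norm_weights(weight, n)
    mean_h = float(w @ h)
    if mean_h <= 0:
        raise DataError("standard error undefined: mean outcome is zero")
    if np.ptp(h) == 0:
        warnings.warn("constant outcome: concentration index and its SE are 0",
                      stacklevel=2)
        return 0.0

    var_r = float(w @ (r - float(w @ r)) ** 2)
    lhs = 2.0 * var_r * h / mean_h
    X = sm.add_constant(r)
    if cluster_id is not None:
        groups = np.asarray(cluster_id)
        if np.unique(groups).size < 2:
            warnings.warn("fewer than 2 clusters; using robust (HC1) SE",
                          stacklevel=2)
            cluster_id = None
    model = sm.WLS(lhs, X, weights=w * n)
    if cluster_id is not None:
        res = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(cluster_id)})
    else:
        res = model.fit(cov_type="HC1")
    return float(res.bse[1])
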