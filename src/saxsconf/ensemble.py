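"""Chi-square scoring of calculated profiles against experiment, and
selection of best single-state and minimal multi-state (mixture) models.

Conventions: the scale factor c is the analytic weighted least-squares
minimiser; reduced chi^2 is normalised by N - 1 (one fitted scale).  A
fitted constant background is off by default and available behind a flag.
Calculated profiles are interpolated onto the experimental grid linearly in
q; the calculated grid must cover the experimental range (the overlap is
used otherwise, which the caller should log).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import nnls

from .core_io import ScatteringProfile

__all__ = [
    "FitResult",
    "optimal_scale",
    "chi2",
    "best_single_state",
    "multi_state_fit",
]


@dataclass(frozen=True)
class FitResult:
    member_ids: tuple
    weights: tuple[float, ...]
    scale: float
    chi2: float
    n_points: int
    constant: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if self.chi2 < 0:
            raise ValueError("chi2 must be non-negative")


def _interp_calc(exp: ScatteringProfile, calc: ScatteringProfile) -> np.ndarray:
    """Calculated intensity on the experimental grid (linear in q, overlap only)."""
    lo, hi = calc.q[0], calc.q[-1]
    if exp.q[0] < lo - 1e-9 or exp.q[-1] > hi + 1e-9:
        m = (exp.q >= lo) & (exp.q <= hi)
        if m.sum() < 2:
            raise ValueError("calculated profile does not overlap the experimental grid")
    return np.interp(exp.q, calc.q, calc.intensity)


def optimal_scale(exp: ScatteringProfile, calc: ScatteringProfile) -> float:
    """Analytic minimiser c = sum(I_exp I_calc / s^2) / sum(I_calc^2 / s^2)."""
    s = exp.require_sigma()
    ic = _interp_calc(exp, calc)
    denom = float(np.sum(ic * ic / s**2))
    if denom == 0:
        raise ValueError("zero denominator: calculated intensity vanishes")
    return float(np.sum(exp.intensity * ic / s**2) / denom)


def chi2(
    exp: ScatteringProfile,
    calc: ScatteringProfile,
    fit_constant: bool = False,
) -> float:
    """Reduced chi^2 = 1/(N-1) sum((I_exp - c I_calc - b)/sigma)^2.

    With ``fit_constant`` a flat background b is co-fitted with the scale
    (weighted 2-parameter linear fit, normalisation then N - 2).
    """
    s = exp.require_sigma()
    N = len(exp)
    if N < 2:
        raise ValueError("need at least 2 points")
    ic = _interp_calc(exp, calc)
    if not fit_constant:
        c = optimal_scale(exp, calc)
        resid = (exp.intensity - c * ic) / s
        return float(np.sum(resid**2) / (N - 1))
    A = np.column_stack([ic / s, 1.0 / s])
    coef, *_ = np.linalg.lstsq(A, exp.intensity / s, rcond=None)
    resid = exp.intensity / s - A @ coef
    return float(np.sum(resid**2) / max(N - 2, 1))


def best_single_state(
    exp: ScatteringProfile,
    pool: list[tuple[object, ScatteringProfile]],
    fit_constant: bool = False,
) -> FitResult:
    """Pool member with minimal chi^2; ties broken by lowest id."""
    if not pool:
        raise ValueError("empty pool")
    scored = sorted(
        ((chi2(exp, calc, fit_constant), mid) for mid, calc in pool),
        key=lambda t: (t[0], t[1]),
    )
    best_chi2, best_id = scored[0]
    calc = dict((mid, c) for mid, c in pool)[best_id]
    return FitResult(
        member_ids=(best_id,),
        weights=(1.0,),
        scale=optimal_scale(exp, calc),
        chi2=best_chi2,
        n_points=len(exp),
    )


def _subset_fit(
    exp: ScatteringProfile,
    members: list[tuple[object, np.ndarray]],
) -> tuple[float, tuple[float, ...], float]:
    """Non-negative least squares over a fixed member subset.

    Returns (chi2, normalised weights, overall scale).  The NNLS
    coefficients a_j minimise ||(I_exp - sum a_j I_j)/sigma||; the reported
    weights are a / sum(a) and the scale is sum(a) (the refit of an overall
    scale on the weight-normalised mixture gives back exactly this split).
    """
    s = exp.sigma
    A = np.column_stack([ic / s for _, ic in members])
    a, _ = nnls(A, exp.intensity / s)
    total = a.sum()
    if total <= 0:
        return float("inf"), tuple(0.0 for _ in members), 0.0
    resid = exp.intensity / s - A @ a
    c2 = float(np.sum(resid**2) / max(len(exp) - 1, 1))
    return c2, tuple(a / total), float(total)


def multi_state_fit(
    exp: ScatteringProfile,
    pool: list[tuple[object, ScatteringProfile]],
    k: int = 2,
    prefilter: int | None = None,
) -> FitResult:
    """Best k-state mixture with non-negative weights.

    k <= 2 enumerates all subsets exactly; k > 2 grows greedily from the
    best pair.  ``prefilter`` restricts the pair enumeration to the top-m
    members by single-state chi^2 (useful for large sampled ensembles).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(pool) < k:
        raise ValueError("pool smaller than k")
    exp.require_sigma()
    interp = [(mid, _interp_calc(exp, calc)) for mid, calc in pool]
    if k == 1:
        return best_single_state(exp, pool)
    if prefilter is not None and prefilter < len(interp):
        singles = sorted(
            interp,
            key=lambda m: _subset_fit(exp, [m])[0],
        )
        interp = singles[:prefilter]

    best: tuple[float, list, tuple[float, ...], float] | None = None
    for combo in combinations(range(len(interp)), 2):
        members = [interp[i] for i in combo]
        c2, w, scale = _subset_fit(exp, members)
        if best is None or c2 < best[0]:
            best = (c2, members, w, scale)
    assert best is not None
    c2, members, w, scale = best
    while len(members) < k:
        gain = None
        for cand in interp:
            if any(cand[0] == m[0] for m in members):
                continue
            trial = members + [cand]
            t2, tw, ts = _subset_fit(exp, trial)
            if gain is None or t2 < gain[0]:
                gain = (t2, trial, tw, ts)
        if gain is None:
            break
        c2, members, w, scale = gain
    # drop zero-weight members for reporting, keeping the invariant sum w = 1
    ids = tuple(m[0] for m in members)
    return FitResult(
        member_ids=ids,
        weights=tuple(float(x) for x in w),
        scale=scale,
        chi2=c2,
        n_points=len(exp),
    )
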