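"""Binomial-occupancy correction of the rectification ratio.

A BK channel carries n = 0..4 β2 subunits with Binomial(4, p) probability,
and its rectification ratio grows linearly with n: R_n = R_α + n·Δx.  The
measured ensemble ratio is therefore

    R_measured = Σₙ C(4,n) pⁿ q⁴⁻ⁿ (R_α + n·Δx) = R_α + 4·p·Δx,

from which the per-subunit increment and the full-occupancy ("equivalent")
ratio follow:

    Δx   = (R_measured − R_α) / (4p),
    R_eq = R_α + (R_measured − R_α) / p.

The unbinding probability q = 1 − p is estimated from the non-inactivating
pedestal of the test-pulse fit, q = (C/A)^(1/4), because only channels with
zero bound β2 escape inactivation and their binomial weight is q⁴.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import FitError, LowOccupancyError, UndefinedRatioError
from .synthetic_data import N_SITES, SimulatedPatch
from .trace_fit import (BiexpFit, TailIV, fit_biexponential,
                        measure_instantaneous_tails)

__all__ = [
    "RectificationResult",
    "OccupancyModel",
    "MutantSummary",
    "rectification_ratio",
    "unbinding_probability",
    "equivalent_ratio",
    "ensemble_ratio_forward",
    "analyze_patch",
    "aggregate",
]

P_MIN_DEFAULT = 0.05  # below this occupancy the 1/p correction is unusable


@dataclass(frozen=True)
class RectificationResult:
    """Per-patch outcome of the occupancy-corrected rectification analysis.

    ``q`` and ``p`` are NaN (and the ``alpha-only`` flag set) when the trace
    shows no inactivating component to estimate them from.
    """

    R_measured: float
    q: float
    p: float
    delta_x: float
    R_eq: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class OccupancyModel:
    """Forward binomial-occupancy model of the ensemble ratio."""

    R_alpha: float
    delta_x: float
    p: float
    N_sites: int = N_SITES

    def __post_init__(self) -> None:
        if self.N_sites != N_SITES:
            raise ValueError("the occupancy model has exactly 4 sites")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class MutantSummary:
    """Aggregated cohort statistics for one channel variant."""

    name: str
    req_mean: float
    req_sd: float
    req_n: int
    q_mean: float = float("nan")
    q_sd: float = float("nan")
    q_n: int = 0
    dq_e: int | None = None
    cys_labels: tuple[str, ...] = ()


def rectification_ratio(tails: TailIV) -> float:
    """R = |I(+100)/I(−100)| from the exact ±100 mV grid points."""
    i_pos = tails.at(100.0)
    i_neg = tails.at(-100.0)
    if i_neg == 0.0:
        raise UndefinedRatioError("inward current at −100 mV is zero")
    return abs(i_pos / i_neg)


def unbinding_probability(fit: BiexpFit) -> tuple[float, tuple[str, ...]]:
    """q = (C/A)^(1/4), with the physical clamps flagged.

    A negative fitted pedestal clamps q to 0 (``clamped-pedestal``); a
    pedestal exceeding the amplitude clamps q to 1 (``clamped-q``).
    """
    A = fit.A
    if A <= 0:
        raise FitError("fit amplitude A must be positive to estimate q")
    flags: tuple[str, ...] = ()
    ratio = fit.C / A
    if ratio < 0:
        return 0.0, ("clamped-pedestal",)
    q = ratio ** (1.0 / N_SITES)
    if q > 1.0:
        return 1.0, ("clamped-q",)
    return q, flags


def equivalent_ratio(
    R_measured: float,
    q: float,
    R_alpha: float,
    p_min: float = P_MIN_DEFAULT,
) -> RectificationResult:
    """Correct a measured ratio to full (four-β2) occupancy."""
    if R_measured <= 0:
        raise ValueError("R_measured must be positive")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    p = 1.0 - q
    if p < p_min:
        raise LowOccupancyError(
            f"occupancy p = {p:.3g} below p_min = {p_min}: "
            "the full-occupancy correction is unreliable"
        )
    delta_x = (R_measured - R_alpha) / (N_SITES * p)
    r_eq = R_alpha + (R_measured - R_alpha) / p
    return RectificationResult(R_measured, q, p, delta_x, r_eq)


def ensemble_ratio_forward(model: OccupancyModel) -> float:
    """Ensemble ratio via the explicit 5-term binomial sum.

    The closed form R_α + 4pΔx is evaluated alongside as an internal
    consistency check (they must agree to 1e-12).
    """
    p, q = model.p, 1.0 - model.p
    explicit = sum(
        math.comb(N_SITES, n) * p**n * q ** (N_SITES - n)
        * (model.R_alpha + n * model.delta_x)
        for n in range(N_SITES + 1)
    )
    closed = model.R_alpha + N_SITES * p * model.delta_x
    if abs(explicit - closed) > 1e-12:
        raise AssertionError("binomial sum deviates from its closed form")
    return explicit


def analyze_patch(
    test_pulse_patch: SimulatedPatch,
    tail_patch: SimulatedPatch,
    R_alpha: float = 1.12,
    p_min: float = P_MIN_DEFAULT,
    fit_window_start: float = 0.5,
    pool_min_level: float = 60.0,
) -> RectificationResult:
    """Full per-patch pipeline: tails → R, test-pulse fits → q, then the
    occupancy correction.

    The reference fit (time constants, flags) is the +100 mV trace.  The
    pedestal fraction C/A is the noisiest ingredient, so when the family
    contains further saturated outward steps (V ≥ ``pool_min_level``, well
    above V50) their signed C/A ratios are averaged with the +100 mV one
    before taking the fourth root — the pedestal fraction q⁴ is
    level-independent, so every saturated trace is a repeat measurement.

    A patch with no measurable inactivating component (q within ``p_min``
    of 1, the α-only phenotype) is returned uncorrected with the
    ``alpha-only`` flag and q, p, Δx set to NaN.
    """
    tails = measure_instantaneous_tails(tail_patch)
    r_measured = rectification_ratio(tails)
    end = float(test_pulse_patch.time[-1])

    def fit_level(V: float) -> "BiexpFit":
        return fit_biexponential(test_pulse_patch.time,
                                 test_pulse_patch.currents[V],
                                 window=(fit_window_start, end))

    fit = fit_level(100.0)
    flags = fit.flags
    if not fit.converged:
        flags = flags + ("unconverged-fit",)
    ratios = []
    for V in sorted(test_pulse_patch.currents):
        if V < pool_min_level:
            continue
        f = fit if V == 100.0 else fit_level(V)
        if f.converged and f.A > 0:
            ratios.append(f.C / f.A)
    if not ratios:  # fall back to the reference trace alone
        ratios = [fit.C / fit.A]
    pooled = float(np.mean(ratios))
    q, q_flags = unbinding_probability(
        BiexpFit(A1=fit.A1, tau1=fit.tau1, A2=fit.A2, tau2=fit.tau2,
                 C=pooled * fit.A, rmse=fit.rmse, converged=fit.converged))
    flags = flags + q_flags
    if q > 1.0 - p_min:
        nan = float("nan")
        return RectificationResult(r_measured, nan, nan, nan, r_measured,
                                   flags + ("alpha-only",))
    result = equivalent_ratio(r_measured, q, R_alpha, p_min=p_min)
    return RectificationResult(
        result.R_measured, result.q, result.p, result.delta_x, result.R_eq,
        flags + result.flags,
    )


def aggregate(
    results: list[RectificationResult],
    name: str,
    dq_e: int | None = None,
    cys_labels: tuple[str, ...] = (),
    sem: bool = False,
) -> MutantSummary:
    """Cohort mean ± sd (n) of R_eq and q.

    ``sem`` reports the standard error of the mean instead of the sd
    (useful for band-densitometry-style outputs); the default is sd.
    α-only patches contribute R_eq but not q.
    """
    if len(results) < 2:
        raise ValueError("aggregation needs at least 2 patch results")
    req = np.array([r.R_eq for r in results], dtype=float)
    qs = np.array([r.q for r in results if not math.isnan(r.q)], dtype=float)

    def _spread(x: np.ndarray) -> float:
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")
        return sd / math.sqrt(len(x)) if sem else sd

    return MutantSummary(
        name=name,
        req_mean=float(np.mean(req)), req_sd=_spread(req), req_n=len(req),
        q_mean=float(np.mean(qs)) if len(qs) else float("nan"),
        q_sd=_spread(qs) if len(qs) > 1 else float("nan"),
        q_n=len(qs),
        dq_e=dq_e, cys_labels=cys_labels,
    )
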