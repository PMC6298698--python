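"""Per-trace quantities: bi-exponential inactivation fits, instantaneous
tail amplitudes, and Boltzmann conductance–voltage parameters.

The inactivating macroscopic current is fitted with

    f(t) = A1·exp(−t/τ1) + A2·exp(−t/τ2) + C,

where A1/τ1 describe inactivation, A2/τ2 activation and C the steady-state
non-inactivating pedestal (the "offset").  Components are labelled by the
convention τ1 ≥ τ2 (inactivation slower than activation), and the amplitude
A = max(|A1|, |A2|) plays the role of the Hodgkin–Huxley maximal current.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import FitError
from .synthetic_data import SimulatedPatch

__all__ = [
    "BiexpFit",
    "TailIV",
    "BoltzmannFit",
    "fit_biexponential",
    "measure_instantaneous_tails",
    "fit_boltzmann",
    "gv_from_test_pulse",
]

# multi-start perturbation factors applied to (tau1, tau2) before giving up

def _curve_fit(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        return curve_fit(*args, **kwargs)


_TAU_PERTURBATIONS = (
    (3.0, 1.0), (1 / 3, 1.0), (1.0, 3.0), (1.0, 1 / 3),
    (3.0, 3.0), (1 / 3, 1 / 3), (3.0, 1 / 3), (1 / 3, 3.0),
)


@dataclass(frozen=True)
class BiexpFit:
    """Double-exponential-plus-pedestal fit of one trace.

    Times are referenced to the trace's own time axis (t = 0 at step
    onset), so the amplitudes are onset amplitudes even when the fit
    window starts later.
    """

    A1: float
    tau1: float
    A2: float
    tau2: float
    C: float
    rmse: float
    converged: bool
    flags: tuple[str, ...] = ()

    @property
    def A(self) -> float:
        """Maximal-current amplitude A = max(|A1|, |A2|)."""
        return max(abs(self.A1), abs(self.A2))


@dataclass(frozen=True)
class TailIV:
    """Instantaneous tail amplitude at each repolarization level."""

    levels: tuple[float, ...]
    I_inst: tuple[float, ...]
    method: str

    def __post_init__(self) -> None:
        if list(self.levels) != sorted(self.levels):
            raise ValueError("levels must be strictly increasing")
        if not {-100.0, 100.0} <= set(self.levels):
            raise ValueError("tail I–V must contain the ±100 mV levels")

    def at(self, level: float) -> float:
        return self.I_inst[self.levels.index(level)]


@dataclass(frozen=True)
class BoltzmannFit:
    """G–V fit of G = Gmax·(1 + exp((V − V50)/κ))⁻¹.

    As printed the equation decreases with V for κ > 0, so κ is left
    free-signed and comes out negative for the usual increasing G–V.
    """

    V50: float
    kappa: float
    Gmax: float


def _biexp(t: np.ndarray, A1: float, lt1: float, A2: float, lt2: float,
           C: float) -> np.ndarray:
    # time constants fitted on a log scale so positivity is structural
    return A1 * np.exp(-t / np.exp(lt1)) + A2 * np.exp(-t / np.exp(lt2)) + C


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, ...]:
    """Heuristic start: C from the final 10 %, τ2 from the 1−1/e rise time,
    τ1 from a log-linear regression of the late decay."""
    n = len(t)
    C0 = float(np.mean(y[-max(1, n // 10):]))
    span = float(np.max(y) - np.min(y)) or 1.0
    # rising phase: time to reach 1 − 1/e of the early excursion
    i_peak = int(np.argmax(np.abs(y - y[0])))
    rise = np.abs(y[: i_peak + 1] - y[0])
    thresh = (1 - 1 / math.e) * (rise[-1] if len(rise) else span)
    above = np.nonzero(rise >= thresh)[0]
    tau2 = max(float(t[above[0]] - t[0]), 1e-3) if len(above) else 1.0
    # late decay toward C0, log-linear where the residual keeps one sign
    late = slice(max(i_peak, n // 4), n)
    resid = y[late] - C0
    sign = 1.0 if np.median(resid) >= 0 else -1.0
    good = sign * resid > 1e-3 * span
    if np.count_nonzero(good) >= 5:
        slope = np.polyfit(t[late][good], np.log(sign * resid[good]), 1)[0]
        tau1 = -1.0 / slope if slope < 0 else 10 * tau2
    else:
        tau1 = 10 * tau2
    tau1 = max(tau1, tau2)
    A1 = float(y[i_peak] - C0)
    A2 = -(A1 + C0 - float(y[0]))
    return A1, tau1, A2, tau2, C0


def fit_biexponential(
    time: np.ndarray,
    current: np.ndarray,
    window: tuple[float, float] | None = None,
) -> BiexpFit:
    """Least-squares fit of the bi-exponential-plus-pedestal model.

    ``window`` selects the fitted samples (ms, in trace time); the model is
    still referenced to t = 0.  A constant trace yields a degenerate fit
    (A1 = A2 = 0, C = mean), flagged rather than fabricated.  Non-convergence
    after eight τ multi-starts is reported through ``converged``.
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    if window is not None:
        keep = (time >= window[0]) & (time <= window[1])
        time, current = time[keep], current[keep]
    if len(time) < 50:
        raise FitError("need at least 50 samples inside the fit window")

    scale = float(np.std(current))
    if scale < 1e-12 * max(1.0, abs(float(np.mean(current)))) or scale == 0.0:
        return BiexpFit(0.0, 1.0, 0.0, 1.0, float(np.mean(current)),
                        0.0, False, ("degenerate",))

    A1, tau1, A2, tau2, C0 = _initial_guess(time, current)
    best: tuple[float, np.ndarray] | None = None
    lt_lo, lt_hi = math.log(1e-3), math.log(1e5)  # τ in [1 μs, 100 s]
    bounds = ([-np.inf, lt_lo, -np.inf, lt_lo, -np.inf],
              [np.inf, lt_hi, np.inf, lt_hi, np.inf])

    def _clip(tau: float) -> float:
        return min(max(math.log(tau), lt_lo), lt_hi)

    for f1, f2 in ((1.0, 1.0),) + _TAU_PERTURBATIONS:
        p0 = (A1, _clip(tau1 * f1), A2, _clip(tau2 * f2), C0)
        try:
            popt, _ = _curve_fit(_biexp, time, current, p0=p0,
                                 bounds=bounds, maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        rmse = float(np.sqrt(np.mean((_biexp(time, *popt) - current) ** 2)))
        if best is None or rmse < best[0]:
            best = (rmse, popt)
        if rmse < 0.25 * scale:  # signal clearly captured; stop multistart
            break
    if best is None:
        return BiexpFit(A1, tau1, A2, tau2, C0, float("inf"), False,
                        ("non-convergent",))

    rmse, (a1, lt1, a2, lt2, c) = best
    t1, t2 = math.exp(lt1), math.exp(lt2)
    if t1 < t2:  # labeling convention: τ1 (inactivation) ≥ τ2 (activation)
        a1, t1, a2, t2 = a2, t2, a1, t1
    converged = rmse < 0.5 * scale
    return BiexpFit(float(a1), t1, float(a2), t2, float(c), rmse, converged)


# ---------------------------------------------------------------------------
# instantaneous tails
# ---------------------------------------------------------------------------

def _single_exp(t: np.ndarray, a: float, ltau: float) -> np.ndarray:
    return a * np.exp(-t / np.exp(ltau))


def measure_instantaneous_tails(
    patch: SimulatedPatch,
    method: str = "backextrap",
) -> TailIV:
    """Instantaneous tail amplitude per level.

    ``backextrap`` (default) fits each tail's decay with a single
    exponential and back-extrapolates to the repolarization onset, which is
    independent of any settling window; ``window`` averages the samples in
    [0.15, 0.35] ms after onset.  Near-zero tails (V ≈ 0) fall back to the
    window mean, and the method actually used is recorded.
    """
    if patch.protocol.mode != "tail":
        raise ValueError("patch was not recorded with a tail protocol")
    onset = patch.protocol.prepulse_dur
    post = patch.time > onset + 1e-12
    t_post = patch.time[post] - onset
    win = (t_post >= 0.15) & (t_post <= 0.35)
    levels = sorted(patch.currents)
    amps: list[float] = []
    used_fallback = False
    peak = max(float(np.max(np.abs(tr))) for tr in patch.currents.values())
    for V in levels:
        y = patch.currents[V][post]
        window_mean = float(np.mean(y[win]))
        if method == "window":
            amps.append(window_mean)
            continue
        a0 = float(y[0])
        if abs(a0) < 1e-3 * peak:
            amps.append(window_mean)
            used_fallback = True
            continue
        try:
            popt, _ = _curve_fit(_single_exp, t_post, y,
                                p0=(a0, math.log(2.0)), maxfev=10000)
            amps.append(float(popt[0]))
        except (RuntimeError, ValueError):
            amps.append(window_mean)
            used_fallback = True
    label = method if method == "window" else (
        "backextrap+window-fallback" if used_fallback else "backextrap")
    return TailIV(tuple(float(v) for v in levels), tuple(amps), label)


# ---------------------------------------------------------------------------
# Boltzmann G–V
# ---------------------------------------------------------------------------

def _boltzmann(V: np.ndarray, V50: float, kappa: float,
               Gmax: float) -> np.ndarray:
    return Gmax / (1.0 + np.exp((V - V50) / kappa))


def fit_boltzmann(points: list[tuple[float, float]]) -> BoltzmannFit:
    """Fit G = Gmax·(1 + exp((V − V50)/κ))⁻¹ to (V, G) points."""
    if len(points) < 5:
        raise FitError("need at least 5 G–V points spanning the transition")
    V = np.array([p[0] for p in points], dtype=float)
    G = np.array([p[1] for p in points], dtype=float)
    if float(np.ptp(G)) <= 1e-12 * max(1.0, float(np.max(np.abs(G)))):
        raise FitError("degenerate G–V: all conductances equal")
    gmax0 = float(np.max(G))
    half = np.argmin(np.abs(G - gmax0 / 2))
    v50_0 = float(V[half])
    slope_sign = 1.0 if G[np.argmax(V)] >= G[np.argmin(V)] else -1.0
    kappa0 = -slope_sign * max(float(np.ptp(V)) / 10, 1.0)
    popt, _ = _curve_fit(_boltzmann, V, G, p0=(v50_0, kappa0, gmax0),
                        maxfev=20000)
    return BoltzmannFit(float(popt[0]), float(popt[1]), float(popt[2]))


def gv_from_test_pulse(
    patch: SimulatedPatch,
    R_measured: float,
    fit_window_start: float = 0.5,
) -> list[tuple[float, float]]:
    """Rectification-corrected chord-conductance points from a test-pulse
    family.

    The per-level maximal-current amplitude A (from the bi-exponential fit)
    is divided by the driving force, with the outward limb additionally
    divided by the patch's measured rectification ratio so both limbs share
    one conductance scale.  V = 0 carries no driving force and is skipped.
    """
    if patch.protocol.mode != "test-pulse":
        raise ValueError("patch was not recorded with a test-pulse protocol")
    end = float(patch.time[-1])
    points: list[tuple[float, float]] = []
    for V in sorted(patch.currents):
        if abs(V) < 1e-9:
            continue
        y = patch.currents[V]
        # skip levels whose excursion is buried in noise: the fitted
        # amplitude there would measure noise, not conductance
        noise = float(np.std(np.diff(y))) / math.sqrt(2.0)
        if float(np.ptp(y)) < 6.0 * noise and noise > 0:
            continue
        fit = fit_biexponential(patch.time, y,
                                window=(fit_window_start, end))
        drive = V * (R_measured if V > 0 else 1.0)
        points.append((float(V), fit.A / abs(drive)))
    return points
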