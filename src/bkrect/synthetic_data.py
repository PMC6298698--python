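"""Forward model of macroscopic BK(mSlo1 ± β2) currents.

The BK channel is a tetramer of Slo1 α subunits; up to four auxiliary β2
subunits may associate with one channel.  β2 binding has two macroscopic
signatures that this generator reproduces:

* **outward rectification** of the instantaneous tail current — the ratio
  R = |I(+100 mV)/I(−100 mV)| grows linearly with the number ``n`` of bound
  β2, from ``R_alpha`` (α only) to ``R_alpha + 4·Δx`` (fully occupied);
* **N-type inactivation** — channels with at least one β2 inactivate, so the
  non-inactivating pedestal of a test-pulse current is carried by the
  zero-occupancy fraction, whose binomial weight is ``q⁴`` (``q = 1 − p`` is
  the per-site unbinding probability).

Occupancy is binomial, Binomial(4, p), so the ensemble tail ratio equals the
occupancy-weighted mean of the per-channel ratios: ``R_alpha + 4·p·Δx``.

Two voltage protocols are generated — a depolarizing test-pulse family (for
inactivation fitting) and an instantaneous tail family after a brief
+150 mV prepulse (for rectification measurement) — and written as CSV or
Axon Text File traces with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

N_SITES = 4  # β2 binding sites per BK channel (one per α subunit)

__all__ = [
    "ChannelPreset",
    "VoltageProtocol",
    "SimulatedPatch",
    "make_preset_catalog",
    "occupancy_weights",
    "per_occupancy_iv",
    "simulate_test_pulse_family",
    "simulate_tail_family",
    "test_pulse_protocol",
    "tail_protocol",
    "write_patch",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelPreset:
    """Parameters of one channel variant.

    ``R_eq_full`` is the rectification ratio at full (four-β2) occupancy;
    the per-subunit increment is ``delta_x = (R_eq_full − R_alpha)/4``.
    ``p_bind`` is the per-site binding probability p; kinetics are the
    activation/inactivation time constants in ms, ``V50``/``kappa`` the
    Boltzmann activation parameters (kappa < 0 gives an activation curve
    that increases with voltage), ``g_max`` the maximal chord conductance
    in nS and ``noise_sd`` the additive Gaussian noise as a fraction of
    each trace's peak current.
    """

    name: str
    R_alpha: float = 1.12
    R_eq_full: float = 1.12
    p_bind: float = 0.0
    tau_act: float = 2.0
    tau_inact: float = 20.0
    V50: float = -15.0
    kappa: float = -12.0
    g_max: float = 10.0
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.R_alpha < 1:
            raise ValueError("R_alpha must be >= 1")
        if self.R_eq_full < self.R_alpha:
            raise ValueError("R_eq_full must be >= R_alpha")
        if not 0.0 <= self.p_bind <= 1.0:
            raise ValueError("p_bind must lie in [0, 1]")
        if self.tau_act <= 0 or self.tau_inact <= 0:
            raise ValueError("time constants must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def q_unbind(self) -> float:
        """Per-site unbinding probability q = 1 − p."""
        return 1.0 - self.p_bind

    @property
    def delta_x(self) -> float:
        """Per-subunit rectification increment Δx."""
        return (self.R_eq_full - self.R_alpha) / N_SITES


@dataclass(frozen=True)
class VoltageProtocol:
    """One voltage-clamp protocol: a prepulse followed by a family of steps."""

    holding: float
    prepulse: float
    prepulse_dur: float
    levels: tuple[float, ...]
    level_dur: float
    sample_interval: float = 0.05  # ms; 20 kHz
    mode: str = "test-pulse"

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if not self.levels:
            raise ValueError("levels must be non-empty")
        if self.level_dur <= 0 or self.prepulse_dur < 0:
            raise ValueError("durations must be positive")
        if self.mode not in ("test-pulse", "tail"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.mode == "tail":
            lv = set(self.levels)
            if not {-100.0, 100.0} <= {float(v) for v in lv}:
                raise ValueError("tail protocol must include -100 and +100 mV")


@dataclass
class SimulatedPatch:
    """A simulated patch: one time grid, one current series per level."""

    preset_name: str
    protocol: VoltageProtocol
    time: np.ndarray                      # ms, shared grid
    currents: dict[float, np.ndarray]     # level (mV) -> nA, outward positive
    seed: int | None
    occupancy_weights: np.ndarray         # Binomial(4, p) mass for n = 0..4

    def __post_init__(self) -> None:
        for lvl, series in self.currents.items():
            if len(series) != len(self.time):
                raise ValueError(f"series at {lvl} mV does not match time grid")
        if abs(float(np.sum(self.occupancy_weights)) - 1.0) > 1e-9:
            raise ValueError("occupancy weights must sum to 1")


def test_pulse_protocol(
    levels: tuple[float, ...] = tuple(float(v) for v in range(-140, 141, 20)),
    level_dur: float = 200.0,
    sample_interval: float = 0.05,
) -> VoltageProtocol:
    """Default depolarizing step family, 200 ms steps every 20 mV."""
    return VoltageProtocol(
        holding=-180.0, prepulse=150.0, prepulse_dur=0.0,
        levels=levels, level_dur=level_dur,
        sample_interval=sample_interval, mode="test-pulse",
    )


def tail_protocol(
    levels: tuple[float, ...] = tuple(float(v) for v in range(-150, 151, 10)),
    prepulse_dur: float = 4.0,
    level_dur: float = 20.0,
    sample_interval: float = 0.05,
) -> VoltageProtocol:
    """Default instantaneous-tail family: 4 ms at +150 mV, steps −150..+150."""
    return VoltageProtocol(
        holding=-180.0, prepulse=150.0, prepulse_dur=prepulse_dur,
        levels=levels, level_dur=level_dur,
        sample_interval=sample_interval, mode="tail",
    )


# ---------------------------------------------------------------------------
# preset catalog
# ---------------------------------------------------------------------------

# (name, R_eq_full, q, tau_inact).  Rectification ratios and unbinding
# probabilities are cohort means of the study conditions being emulated;
# conserved-cysteine mutants inactivate with a slower ~25 ms time constant.
_CATALOG_ROWS: tuple[tuple[str, float, float, float], ...] = (
    ("mSlo1",        1.12, 1.00, 20.0),
    ("WT-beta2",     1.85, 0.07, 20.0),
    ("C1S",          1.38, 0.48, 25.0),
    ("C2S",          1.43, 0.09, 20.0),
    ("C3S",          1.47, 0.09, 20.0),
    ("C4S",          1.62, 0.08, 20.0),
    ("C5S",          1.40, 0.66, 25.0),
    ("C6S",          1.43, 0.41, 25.0),
    ("C7S",          1.45, 0.08, 20.0),
    ("C8S",          1.45, 0.38, 25.0),
    ("C1S/C5S",      1.36, 0.55, 25.0),
    ("C3S/C7S",      1.49, 0.10, 20.0),
    ("C6S/C8S",      1.47, 0.45, 25.0),
    ("C1S/C4S",      1.50, 0.40, 25.0),
    ("S173K",        2.13, 0.07, 20.0),
    ("S173D",        1.69, 0.07, 20.0),
    ("S173K/K141A",  1.83, 0.07, 20.0),
    ("S173K/K141D",  1.65, 0.07, 20.0),
    ("Q83K",         1.88, 0.07, 20.0),
    ("L114K",        1.85, 0.07, 20.0),
    ("S100K",        2.13, 0.07, 20.0),
    ("S100D",        1.68, 0.07, 20.0),
    ("S100K/K147D",  1.69, 0.07, 20.0),
    ("S100K/K147A",  1.85, 0.07, 20.0),
    ("N96K",         2.45, 0.07, 20.0),
    ("D104A",        1.71, 0.07, 20.0),
)


def make_preset_catalog(R_alpha: float = 1.12) -> dict[str, ChannelPreset]:
    """Named presets: α only, wild-type β2, the Cys→Ser panel (singles and
    the measured doubles) and the charge-probe mutants.

    The α-only preset has ``p_bind = 0`` so its ``R_eq_full`` equals
    ``R_alpha``; all others share the same α rectification baseline.
    """
    catalog: dict[str, ChannelPreset] = {}
    for name, r_full, q, tau_i in _CATALOG_ROWS:
        p = 0.0 if name == "mSlo1" else round(1.0 - q, 10)
        r_full = R_alpha if name == "mSlo1" else r_full
        catalog[name] = ChannelPreset(
            name=name, R_alpha=R_alpha, R_eq_full=r_full,
            p_bind=p, tau_inact=tau_i,
        )
    return catalog


# ---------------------------------------------------------------------------
# per-occupancy current–voltage relation
# ---------------------------------------------------------------------------

def occupancy_weights(p_bind: float) -> np.ndarray:
    """Binomial(4, p) probabilities of n = 0..4 bound β2."""
    q = 1.0 - p_bind
    return np.array(
        [math.comb(N_SITES, n) * p_bind**n * q ** (N_SITES - n)
         for n in range(N_SITES + 1)]
    )


def per_occupancy_iv(n: int, V: float, preset: ChannelPreset) -> float:
    """Open-channel current (nA) of a channel with ``n`` bound β2 at ``V``.

    Two-limb I–V with a shared linear inward limb: ``g·V`` for V ≤ 0 and
    ``g·V·R_n`` for V > 0 with ``R_n = R_alpha + n·Δx``, so that
    |i_n(+100)/i_n(−100)| = R_n exactly and the ensemble ratio of summed
    currents is the occupancy-weighted mean of the R_n.
    """
    if not 0 <= n <= N_SITES:
        raise ValueError("occupancy n must be in 0..4")
    if not -150.0 <= V <= 150.0:
        raise ValueError(f"voltage {V} mV outside the ±150 mV protocol range")
    g = preset.g_max
    if V <= 0:
        return g * V
    return g * V * (preset.R_alpha + n * preset.delta_x)


def _ensemble_iv(V: float, preset: ChannelPreset) -> float:
    w = occupancy_weights(preset.p_bind)
    return float(sum(w[n] * per_occupancy_iv(n, V, preset)
                     for n in range(N_SITES + 1)))


def _boltzmann_open(V: float, preset: ChannelPreset) -> float:
    # printed Boltzmann form; kappa < 0 makes activation increase with V
    return 1.0 / (1.0 + math.exp((V - preset.V50) / preset.kappa))


# ---------------------------------------------------------------------------
# trace simulation
# ---------------------------------------------------------------------------

def simulate_test_pulse_family(
    preset: ChannelPreset,
    protocol: VoltageProtocol | None = None,
    seed: int | None = None,
) -> SimulatedPatch:
    """Depolarizing family with bi-exponential activation/inactivation.

    At each level the trace is the double-exponential-plus-pedestal form

        I(t) = A1·exp(−t/τ_inact) + A2·exp(−t/τ_act) + C,

    with A1 = P(1 − q⁴), A2 = −P and C = P·q⁴, where P is the peak scale
    (Boltzmann open probability × occupancy-averaged open-channel current)
    and q⁴ is the binomial weight of zero-occupancy channels — the only
    channels that never inactivate, hence the entire pedestal.  I(0) = 0 and
    max(|A1|, |A2|) = P, so the pedestal fraction C/A equals q⁴ exactly.
    """
    protocol = protocol or test_pulse_protocol()
    if protocol.mode != "test-pulse":
        raise ValueError("protocol mode must be 'test-pulse'")
    preset_q4 = preset.q_unbind ** N_SITES
    t = np.arange(0.0, protocol.level_dur + protocol.sample_interval / 2,
                  protocol.sample_interval)
    clean: dict[float, np.ndarray] = {}
    for V in protocol.levels:
        P = _boltzmann_open(V, preset) * _ensemble_iv(V, preset)
        trace = (
            P * (1.0 - preset_q4) * np.exp(-t / preset.tau_inact)
            - P * np.exp(-t / preset.tau_act)
            + P * preset_q4
        )
        clean[float(V)] = trace
    return _add_noise(preset, protocol, t, clean, seed)


def simulate_tail_family(
    preset: ChannelPreset,
    protocol: VoltageProtocol | None = None,
    seed: int | None = None,
) -> SimulatedPatch:
    """Instantaneous tail family after a fully activating +150 mV prepulse.

    During the prepulse the current activates toward the ensemble current at
    +150 mV; at repolarization onset the current jumps instantaneously to
    Σ_n w_n·i_n(V) and then deactivates with a single-exponential time
    constant equal to ``tau_act``.
    """
    protocol = protocol or tail_protocol()
    if protocol.mode != "tail":
        raise ValueError("protocol mode must be 'tail'")
    dt = protocol.sample_interval
    t = np.arange(0.0, protocol.prepulse_dur + protocol.level_dur + dt / 2, dt)
    pre = t <= protocol.prepulse_dur + 1e-12
    t_post = t - protocol.prepulse_dur
    i_pre = _ensemble_iv(protocol.prepulse, preset) * (
        1.0 - np.exp(-t / preset.tau_act)
    )
    clean: dict[float, np.ndarray] = {}
    for V in protocol.levels:
        inst = _ensemble_iv(V, preset)
        trace = np.where(pre, i_pre, inst * np.exp(-t_post / preset.tau_act))
        clean[float(V)] = trace
    return _add_noise(preset, protocol, t, clean, seed)


def _add_noise(
    preset: ChannelPreset,
    protocol: VoltageProtocol,
    t: np.ndarray,
    clean: dict[float, np.ndarray],
    seed: int | None,
) -> SimulatedPatch:
    currents = clean
    if preset.noise_sd > 0 and seed is not None:
        # noise scales with each trace's own peak: gains are adjusted per
        # level, so recording precision is relative, not absolute
        rng = np.random.default_rng(seed)
        currents = {
            V: tr + rng.normal(0.0, preset.noise_sd * float(np.max(np.abs(tr))),
                               tr.shape)
            for V, tr in clean.items()}
    elif preset.noise_sd > 0:
        raise ValueError("noisy simulation requires an explicit seed")
    return SimulatedPatch(
        preset_name=preset.name, protocol=protocol, time=t,
        currents=currents, seed=seed,
        occupancy_weights=occupancy_weights(preset.p_bind),
    )


# ---------------------------------------------------------------------------
# trace output
# ---------------------------------------------------------------------------

def _columns(patch: SimulatedPatch) -> tuple[list[str], np.ndarray]:
    levels = sorted(patch.currents)
    names = ["time_ms"] + [f"V_{_fmt_level(v)}mV" for v in levels]
    data = np.column_stack([patch.time] + [patch.currents[v] for v in levels])
    return names, data


def _fmt_level(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else str(v)


def write_patch(patch: SimulatedPatch, path: str | Path,
                format: str = "csv") -> Path:
    """Write a patch as CSV or Axon Text File, plus a JSON metadata sidecar.

    CSV: header row ``time_ms,V_<level>mV,...`` then one row per sample,
    full double precision (round-trips bit-identically through
    :func:`bkrect.interface.read_traces`).  ATF: ``ATF\\t1.0`` magic, two
    header records (preset, seed), then the same columns.
    """
    path = Path(path)
    names, data = _columns(patch)
    rows = "\n".join(",".join(repr(float(x)) for x in row) for row in data)
    if format == "csv":
        path.write_text(",".join(names) + "\n" + rows + "\n")
    elif format == "atf":
        tab_rows = rows.replace(",", "\t")
        header = (
            "ATF\t1.0\n"
            f"2\t{len(names)}\n"
            f"\"preset={patch.preset_name}\"\n"
            f"\"seed={patch.seed}\"\n"
            + "\t".join(f"\"{n}\"" for n in names) + "\n"
        )
        path.write_text(header + tab_rows + "\n")
    else:
        raise ValueError(f"unknown trace format {format!r}")
    sidecar = {
        "preset": patch.preset_name,
        "seed": patch.seed,
        "format": format,
        "protocol": asdict(patch.protocol),
        "occupancy_weights": [float(w) for w in patch.occupancy_weights],
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path
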