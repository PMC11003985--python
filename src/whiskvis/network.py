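"""Two-population threshold-linear rate model of VISp under cross-modal input.

The model describes the mean firing rates ``A_P`` (pyramidal neurons, PN) and
``A_F`` (fast-spiking interneurons, FS) of mouse primary visual cortex as a
Wilson–Cowan-type recurrent network,

    tau_P dA_P/dt = -A_P + f_P(J_PP A_P - J_PF A_F + I_cm + I_v_P)
    tau_F dA_F/dt = -A_F + f_F(J_FP A_P - J_FF A_F + I_cm + I_v_F)

with threshold-linear transfer ``f_i(h) = G_i * max(h - theta_i, 0)``.  The
tactile (cross-modal) drive from the barrel cortex targets both populations
with equal strength but is capped at ``rho = delta * theta_P`` before entering
the input sum — it can therefore excite the FS population (``theta_F <
theta_P``) but only depolarize the PN population below its own threshold:

    I_cm_eff = max(min(I_cm, rho), 0)

When both populations are above threshold the fixed point is linear and has a
closed form; adding the capped tactile drive then shifts the steady state by

    dA_P* = I_cm_eff * G_P * [1 + G_F (J_FF - J_PF)] / phi
    dA_F* = I_cm_eff * G_F * [1 + G_P (J_FP - J_PP)] / phi

with ``phi = w_FP w_PF - (w_PP - 1)(w_FF + 1)`` and effective weights
``w_ij = G_i J_ij``.  Suppression of both populations (the cross-modal
"simSup" effect) requires an inhibition-stabilized network (``phi > 0``
among other criteria) together with negative numerators above.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from whiskvis.exceptions import (
    DegenerateNetworkError,
    IntegrationInstabilityError,
    InvalidParameterError,
)

Condition = Literal["v", "v+w", "cm-only", "none"]

__all__ = [
    "NetworkParams",
    "StimulusProtocol",
    "Trajectory",
    "SteadyState",
    "Suppression",
    "RegimeReport",
    "cap_crossmodal",
    "response_function",
    "simulate",
    "measure_steady_states",
    "steady_state_analytic",
    "cm_only_steady_state",
    "suppression_analytic",
    "classify_regime",
    "regime_label",
    "sweep",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class NetworkParams:
    """All parameters of the rate model.

    Units: time constants in seconds, gains in Hz per input unit, synaptic
    weights in input units per Hz, thresholds and drives in input units.
    The defaults are the printed reference parameterization of the model.
    """

    tau_P: float = 0.060
    tau_F: float = 0.012
    G_P: float = 1.0
    G_F: float = 5.0
    J_PP: float = 2.0
    J_PF: float = 4.0
    J_FF: float = 0.8
    J_FP: float = 0.4
    theta_P: float = 0.5
    theta_F: float = 0.35
    I_v_P: float = 3.6
    I_v_F: float = 0.6
    I_cm: float = 0.6
    delta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tau_P", "tau_F", "G_P", "G_F",
                     "J_PP", "J_PF", "J_FF", "J_FP"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.delta < 0:
            raise InvalidParameterError("delta must be non-negative")
        if self.theta_P < 0 or self.theta_F < 0:
            raise InvalidParameterError("thresholds must be non-negative")
        for name in ("tau_P", "tau_F", "G_P", "G_F", "J_PP", "J_PF",
                     "J_FF", "J_FP", "theta_P", "theta_F", "I_v_P",
                     "I_v_F", "I_cm", "delta"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")

    # derived quantities -----------------------------------------------------
    @property
    def alpha(self) -> float:
        """I/E weight ratio J_PF / J_PP."""
        return self.J_PF / self.J_PP

    @property
    def rho(self) -> float:
        """Cap on the effective cross-modal drive, rho = delta * theta_P."""
        return self.delta * self.theta_P

    @property
    def k(self) -> float:
        """Time-constant ratio tau_F / tau_P."""
        return self.tau_F / self.tau_P

    # effective weights w_ij = G_i J_ij
    @property
    def w_PP(self) -> float:
        return self.G_P * self.J_PP

    @property
    def w_PF(self) -> float:
        return self.G_P * self.J_PF

    @property
    def w_FF(self) -> float:
        return self.G_F * self.J_FF

    @property
    def w_FP(self) -> float:
        return self.G_F * self.J_FP

    @property
    def I_cm_capped(self) -> float:
        return cap_crossmodal(self.I_cm, self.delta, self.theta_P)

    def with_alpha(self, alpha: float) -> "NetworkParams":
        """Return a copy with J_PF set to alpha * J_PP."""
        return replace(self, J_PF=alpha * self.J_PP)

    def replace(self, **kwargs: float) -> "NetworkParams":
        return replace(self, **kwargs)


@dataclass
class StimulusProtocol:
    """Timing of the visual and cross-modal input windows.

    Default: visual drive on for the full 10 s, cross-modal drive added
    after 5 s and maintained until visual offset; integration step 0.1 ms.
    """

    t_total: float = 10.0
    t_v_on: float = 0.0
    t_v_off: float = 10.0
    t_cm_on: float = 5.0
    t_cm_off: float = 10.0
    dt: float = 0.0001

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if not (0 <= self.t_v_on < self.t_v_off <= self.t_total):
            raise InvalidParameterError(
                "visual window must satisfy 0 <= t_v_on < t_v_off <= t_total")
        if not (0 <= self.t_cm_on < self.t_cm_off <= self.t_total):
            raise InvalidParameterError(
                "cross-modal window must satisfy "
                "0 <= t_cm_on < t_cm_off <= t_total")


@dataclass
class Trajectory:
    """Time course of both population rates (Hz)."""

    times: np.ndarray
    A_P: np.ndarray
    A_F: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.A_P) == len(self.A_F)):
            raise InvalidParameterError("trajectory arrays must share length")


@dataclass
class SteadyState:
    """Active-branch fixed point of the combined linear system."""

    A_P: float
    A_F: float
    condition: Condition
    eps_P: float
    eps_F: float
    active_P: bool
    active_F: bool
    valid: bool


@dataclass
class Suppression:
    """Closed-form steady-state change when cross-modal input is added."""

    dA_P: float
    dA_F: float
    valid: bool


@dataclass
class RegimeReport:
    """ISN criteria, suppression conditions and the quantities behind them."""

    phi: float
    k: float
    isn_I: bool
    isn_II: bool
    isn_III: bool
    supp_P_condition: bool
    supp_F_condition: bool
    valid: bool

    @property
    def is_isn(self) -> bool:
        return self.isn_I and self.isn_II and self.isn_III


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def cap_crossmodal(I_cm: float, delta: float, theta_P: float) -> float:
    """Cap the cross-modal drive at rho = delta * theta_P (and floor at 0).

    Models the intrinsic thresholding of the postsynaptic effect of the
    tactile input: it can depolarize PNs up to, but not beyond, their
    activation threshold.
    """
    if delta < 0 or theta_P < 0:
        raise InvalidParameterError("delta and theta_P must be non-negative")
    return max(min(I_cm, delta * theta_P), 0.0)


def response_function(h, G: float, theta: float):
    """Threshold-linear transfer: 0 for h <= theta, G*(h - theta) above.

    Accepts scalars or arrays; continuous at h = theta.
    """
    if G <= 0:
        raise InvalidParameterError("gain G must be strictly positive")
    return G * np.maximum(np.asarray(h, dtype=float) - theta, 0.0)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(params: NetworkParams,
             protocol: StimulusProtocol | None = None,
             initial: tuple[float, float] = (0.0, 0.0)) -> Trajectory:
    """Integrate the rate equations with forward Euler at ``protocol.dt``.

    The cross-modal drive is capped before entering the input sums; the
    threshold-linear transfer keeps rates non-negative at every step.

    Raises
    ------
    IntegrationInstabilityError
        if a non-finite rate appears, naming the first bad step.
    """
    if protocol is None:
        protocol = StimulusProtocol()
    if initial[0] < 0 or initial[1] < 0:
        raise InvalidParameterError("initial rates must be non-negative")

    n_steps = int(round(protocol.t_total / protocol.dt))
    times = np.arange(n_steps + 1) * protocol.dt
    A_P = np.empty(n_steps + 1)
    A_F = np.empty(n_steps + 1)
    A_P[0], A_F[0] = initial

    icm_eff = cap_crossmodal(params.I_cm, params.delta, params.theta_P)
    v_on = (times >= protocol.t_v_on) & (times < protocol.t_v_off)
    cm_on = (times >= protocol.t_cm_on) & (times < protocol.t_cm_off)
    I_vP = np.where(v_on, params.I_v_P, 0.0)
    I_vF = np.where(v_on, params.I_v_F, 0.0)
    I_cm = np.where(cm_on, icm_eff, 0.0)

    dt_over_tauP = protocol.dt / params.tau_P
    dt_over_tauF = protocol.dt / params.tau_F
    G_P, G_F = params.G_P, params.G_F
    J_PP, J_PF = params.J_PP, params.J_PF
    J_FF, J_FP = params.J_FF, params.J_FP
    th_P, th_F = params.theta_P, params.theta_F

    aP, aF = float(initial[0]), float(initial[1])
    for i in range(n_steps):
        h_P = J_PP * aP - J_PF * aF + I_cm[i] + I_vP[i]
        h_F = J_FP * aP - J_FF * aF + I_cm[i] + I_vF[i]
        f_P = G_P * (h_P - th_P) if h_P > th_P else 0.0
        f_F = G_F * (h_F - th_F) if h_F > th_F else 0.0
        aP += dt_over_tauP * (f_P - aP)
        aF += dt_over_tauF * (f_F - aF)
        if not (math.isfinite(aP) and math.isfinite(aF)):
            raise IntegrationInstabilityError(i + 1, times[i + 1])
        # transfer is rectified, but guard against Euler overshoot below zero
        aP = max(aP, 0.0)
        aF = max(aF, 0.0)
        A_P[i + 1] = aP
        A_F[i + 1] = aF

    return Trajectory(times=times, A_P=A_P, A_F=A_F)


def measure_steady_states(traj: Trajectory,
                          protocol: StimulusProtocol
                          ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Read the pre- and post-cross-modal steady rates off a trajectory.

    Returns ``((A_P, A_F) just before the cross-modal onset,
    (A_P, A_F) just before the visual offset)``.
    """
    i_pre = int(np.searchsorted(traj.times, protocol.t_cm_on)) - 1
    i_post = int(np.searchsorted(traj.times,
                                 min(protocol.t_cm_off, protocol.t_v_off))) - 1
    return ((float(traj.A_P[i_pre]), float(traj.A_F[i_pre])),
            (float(traj.A_P[i_post]), float(traj.A_F[i_post])))


# ---------------------------------------------------------------------------
# analytics
# ---------------------------------------------------------------------------

def _phi(p: NetworkParams) -> float:
    return p.w_FP * p.w_PF - (p.w_PP - 1.0) * (p.w_FF + 1.0)


def steady_state_analytic(params: NetworkParams,
                          condition: Literal["v", "v+w"]) -> SteadyState:
    """Closed-form fixed point assuming both populations are active.

    ``condition="v"`` uses the visual drives only; ``"v+w"`` adds the capped
    cross-modal drive to both populations.  The active-branch assumption is
    verified post hoc: the result is flagged ``valid=False`` when either
    computed rate is non-positive or either summed input falls below its
    population threshold.
    """
    if condition not in ("v", "v+w"):
        raise InvalidParameterError(f"unknown condition {condition!r}")
    icm = params.I_cm_capped if condition == "v+w" else 0.0
    eps_P = params.G_P * (icm + params.I_v_P - params.theta_P)
    eps_F = params.G_F * (icm + params.I_v_F - params.theta_F)

    phi = _phi(params)
    if phi == 0:
        raise DegenerateNetworkError(
            "phi = 0: active-state fixed point undefined")
    A_P = ((1.0 + params.w_FF) * eps_P - params.w_PF * eps_F) / phi
    A_F = (params.w_FP * eps_P - (params.w_PP - 1.0) * eps_F) / phi

    h_P = params.J_PP * A_P - params.J_PF * A_F + icm + params.I_v_P
    h_F = params.J_FP * A_P - params.J_FF * A_F + icm + params.I_v_F
    active_P = h_P > params.theta_P
    active_F = h_F > params.theta_F
    valid = bool(A_P > 0 and A_F > 0 and active_P and active_F)
    return SteadyState(A_P=float(A_P), A_F=float(A_F), condition=condition,
                       eps_P=float(eps_P), eps_F=float(eps_F),
                       active_P=bool(active_P), active_F=bool(active_F),
                       valid=valid)


def cm_only_steady_state(params: NetworkParams) -> SteadyState:
    """Fixed point with cross-modal drive only (no visual input).

    The capped drive stays below the PN threshold, so A_P = 0 and the FS
    population settles at the scalar fixed point
    ``A_F = G_F (I_cm_eff - theta_F) / (1 + G_F J_FF)`` (clipped at zero).
    """
    icm = params.I_cm_capped
    # with A_P = 0 the FS equation is scalar and linear on its active branch
    A_F = max(params.G_F * (icm - params.theta_F), 0.0) / (1.0 + params.w_FF)
    h_P = -params.J_PF * A_F + icm
    if h_P > params.theta_P:  # cap guarantees icm <= theta_P for delta <= 1
        raise InvalidParameterError(
            "cm-only branch assumes the PN population stays below threshold; "
            "increase theta_P or reduce delta")
    return SteadyState(A_P=0.0, A_F=float(A_F), condition="cm-only",
                       eps_P=params.G_P * (icm - params.theta_P),
                       eps_F=params.G_F * (icm - params.theta_F),
                       active_P=False, active_F=A_F > 0, valid=True)


def suppression_analytic(params: NetworkParams) -> Suppression:
    """Steady-state change (v+w minus v) of both rates, in closed form.

    The result is proportional to the capped cross-modal drive and
    independent of the visual-drive magnitudes.  ``valid`` reports whether
    both populations are on the active branch in both conditions (the
    assumption behind the formula); the formula value is returned either way.
    """
    phi = _phi(params)
    if phi == 0:
        raise DegenerateNetworkError("phi = 0: suppression amount undefined")
    icm = params.I_cm_capped
    dA_P = icm * params.G_P * (1.0 + params.G_F * (params.J_FF - params.J_PF)) / phi
    dA_F = icm * params.G_F * (1.0 + params.G_P * (params.J_FP - params.J_PP)) / phi
    valid = (steady_state_analytic(params, "v").valid
             and steady_state_analytic(params, "v+w").valid)
    return Suppression(dA_P=float(dA_P), dA_F=float(dA_F), valid=valid)


def classify_regime(params: NetworkParams) -> RegimeReport:
    """Evaluate the three ISN criteria and the two suppression conditions.

    Criteria: (I) ``G_P J_PP > 1`` (unstable excitatory subnetwork);
    (II) ``G_F J_FF + 1 > k (G_P J_PP - 1)`` with ``k = tau_F / tau_P``
    (inhibition fast enough to stabilize); (III) ``phi > 0`` (stable
    combined fixed point).  Suppression of each population additionally
    needs the corresponding numerator of the closed-form change negative.
    """
    phi = _phi(params)
    k = params.k
    isn_I = params.w_PP > 1.0
    isn_II = params.w_FF + 1.0 > k * (params.w_PP - 1.0)
    isn_III = phi > 0.0
    supp_P = (1.0 + params.G_F * (params.J_FF - params.J_PF)) < 0.0 and phi > 0.0
    supp_F = (1.0 + params.G_P * (params.J_FP - params.J_PP)) < 0.0 and phi > 0.0
    try:
        valid = (steady_state_analytic(params, "v").valid
                 and steady_state_analytic(params, "v+w").valid)
    except DegenerateNetworkError:
        valid = False
    return RegimeReport(phi=float(phi), k=float(k), isn_I=bool(isn_I),
                        isn_II=bool(isn_II), isn_III=bool(isn_III),
                        supp_P_condition=bool(supp_P),
                        supp_F_condition=bool(supp_F), valid=valid)


def regime_label(report: RegimeReport) -> str:
    """Three-way operating-regime label used by the parameter sweeps."""
    if not report.is_isn:
        return "non-ISN"
    if report.supp_P_condition and report.supp_F_condition:
        return "ISN-suppression"
    return "ISN-no-suppression"


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------

_SWEEPABLE = {"I_cm", "theta_P", "alpha", "G_P", "G_F", "delta",
              "J_PP", "J_PF", "J_FF", "J_FP", "theta_F", "I_v_P", "I_v_F"}


def _apply_axis(params: NetworkParams, name: str, value: float) -> NetworkParams:
    if name == "alpha":
        return params.with_alpha(value)
    return params.replace(**{name: value})


def sweep(params: NetworkParams,
          axes: Mapping[str, Sequence[float]],
          check_by_simulation: bool = False,
          protocol: StimulusProtocol | None = None) -> pd.DataFrame:
    """Evaluate suppression and regime over a 1D or 2D parameter grid.

    Parameters
    ----------
    axes
        One or two named grids, e.g. ``{"I_cm": np.linspace(0, 2, 50)}`` or
        ``{"G_P": gp_grid, "G_F": gf_grid}`` (full product grid).  The axis
        name ``alpha`` sets ``J_PF = alpha * J_PP``.
    check_by_simulation
        When true, each grid point is additionally simulated and the
        absolute analytic/numeric steady-state discrepancy recorded.

    Returns a long-format DataFrame with one row per grid point: the axis
    values, ``dA_P``/``dA_F`` (closed form), the v+w steady rates, the
    regime label, and validity flags.  Degenerate grid points (``phi = 0``)
    are kept as NaN rows labelled ``degenerate``.
    """
    if not 1 <= len(axes) <= 2:
        raise InvalidParameterError("sweep takes one or two axes")
    for name in axes:
        if name not in _SWEEPABLE:
            raise InvalidParameterError(f"cannot sweep over {name!r}")
    names = list(axes)
    grids = [np.asarray(axes[n], dtype=float) for n in names]
    for n, g in zip(names, grids):
        if g.ndim != 1 or not np.all(np.isfinite(g)):
            raise InvalidParameterError(f"grid for {n!r} must be finite 1-D")

    rows = []
    for values in itertools.product(*grids):
        p = params
        for n, v in zip(names, values):
            p = _apply_axis(p, n, v)
        row = dict(zip(names, values))
        try:
            sup = suppression_analytic(p)
            ss_vw = steady_state_analytic(p, "v+w")
            rep = classify_regime(p)
            row.update(dA_P=sup.dA_P, dA_F=sup.dA_F,
                       A_P_vw=ss_vw.A_P, A_F_vw=ss_vw.A_F,
                       phi=rep.phi, regime=regime_label(rep),
                       valid=sup.valid)
            if check_by_simulation:
                traj = simulate(p, protocol)
                proto = protocol or StimulusProtocol()
                (_, _), (sP, sF) = measure_steady_states(traj, proto)
                row["sim_discrepancy"] = max(abs(sP - ss_vw.A_P),
                                             abs(sF - ss_vw.A_F))
        except DegenerateNetworkError:
            row.update(dA_P=np.nan, dA_F=np.nan, A_P_vw=np.nan,
                       A_F_vw=np.nan, phi=0.0, regime="degenerate",
                       valid=False)
        rows.append(row)
    return pd.DataFrame(rows)
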