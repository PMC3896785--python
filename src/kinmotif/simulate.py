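"""Step-response simulation and adaptation scoring.

A parameter set is evaluated by (i) finding the stable steady state at the
pre-stimulus input ``I1``, (ii) stepping the input to ``I2`` and following
the transient of the output node C, and (iii) summarising the response by
the pre-stimulus output ``O1``, the transient peak ``Op`` and the
post-stimulus steady state ``O2``.  Two dimensionless scores condense the
response:

* sensitivity  = (|Op - O1| / O1) / (|I2 - I1| / I1)
* precision    = [ (|O2 - O1| / O1) / (|I2 - I1| / I1) ]^-1

A set is a *kinetic solution* (perfect adaptation) when sensitivity > 1
and precision > 10.  Sets whose trajectories are pathological — vanishing
steady states, persistent or weakly damped oscillations, exceedingly long
transients, or numerical breakdown — are classified and excluded from
scoring.

Numerical strategy: steady states come from damped Newton iteration with
the analytic Jacobian (long-horizon integration as fallback); transients
are integrated with LSODA in geometrically growing windows with dense
output for peak detection.  Once a trajectory is demonstrably inside the
linear neighbourhood of a stable post-stimulus equilibrium, its remaining
approach is extrapolated from the dominant Jacobian eigenvalue instead of
integrating out to the full time budget; an unstable spiral equilibrium
with the trajectory bounded away from it signals a limit cycle and is
classified as persistent oscillation without further integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import odeint
from scipy.linalg import eigvals, solve as lin_solve

from .network import NetworkModel

__all__ = [
    "StimulusProtocol",
    "RejectionThresholds",
    "StepResponseSummary",
    "AdaptationScores",
    "OutcomeClass",
    "SteadyStateError",
    "find_steady_state",
    "simulate_step_response",
    "classify_outcome",
    "sensitivity_score",
    "precision_score",
    "is_kinetic_solution",
    "evaluate_parameter_set",
]


class OutcomeClass:
    """Labels for the fate of one simulated parameter set."""

    OK = "OK"
    TINY_STEADY_STATE = "TINY_STEADY_STATE"
    PERSISTENT_OSCILLATION = "PERSISTENT_OSCILLATION"
    WEAKLY_DAMPED_OSCILLATION = "WEAKLY_DAMPED_OSCILLATION"
    LONG_TRANSIENT = "LONG_TRANSIENT"
    NO_CONVERGENCE = "NO_CONVERGENCE"
    NUMERICAL_FAILURE = "NUMERICAL_FAILURE"

    ALL = (
        OK,
        TINY_STEADY_STATE,
        PERSISTENT_OSCILLATION,
        WEAKLY_DAMPED_OSCILLATION,
        LONG_TRANSIENT,
        NO_CONVERGENCE,
        NUMERICAL_FAILURE,
    )


@dataclass(frozen=True)
class StimulusProtocol:
    """Input step: hold at ``I1``, then switch to ``I2`` at t = 0."""

    I1: float = 0.5
    I2: float = 0.6

    def __post_init__(self) -> None:
        if self.I1 <= 0:
            raise ValueError("pre-stimulus input I1 must be positive")
        if self.I2 == self.I1:
            raise ValueError("stimulus step requires I2 != I1")

    @property
    def relative_step(self) -> float:
        return abs(self.I2 - self.I1) / self.I1


@dataclass(frozen=True)
class RejectionThresholds:
    """Configurable filters separating usable responses from pathologies.

    tiny_ss       : steady-state outputs below this are 'extremely small'
    tiny_state    : at the pre-stimulus steady state, the active and the
                    inactive fraction of every regulatory (non-output) node
                    must both exceed this, else the node is pinned at a
                    boundary and its regulation is inoperative
    tol_ss        : inf-norm of derivatives at an accepted steady state
    t_max         : transient time budget (dimensionless time units)
    settle_tol    : all states within this of the final state counts as settled
    osc_floor     : peak-to-peak amplitude above which a tail oscillation
                    is persistent / weakly damped rather than noise
    rtol, atol    : integrator tolerances
    """

    tiny_ss: float = 1e-2
    tiny_state: float = 1e-2
    tol_ss: float = 1e-9
    t_max: float = 1e4
    settle_tol: float = 1e-4
    osc_floor: float = 1e-4
    rtol: float = 1e-8
    atol: float = 1e-10


@dataclass
class StepResponseSummary:
    """Condensed record of one step-response simulation."""

    O1: float
    Op: float
    O2: float
    settle_time: Optional[float]
    times: np.ndarray
    states: np.ndarray          # shape (len(times), n_nodes)
    protocol: StimulusProtocol
    pre_state: Optional[np.ndarray] = None
    failure: Optional[str] = None   # NO_CONVERGENCE / NUMERICAL_FAILURE hint

    @property
    def output(self) -> np.ndarray:
        return self.states[:, -1] if self.states.size else np.empty(0)


@dataclass(frozen=True)
class AdaptationScores:
    sensitivity: float
    precision: float


class SteadyStateError(RuntimeError):
    """Neither root finding nor relaxation produced a stable steady state."""


# ---------------------------------------------------------------------------
# fast scalar closures

def _fast_rhs(model: NetworkModel, input_level: float, params: np.ndarray):
    """Plain-float rate closure (avoids numpy overhead in the ODE callback)."""
    terms = []
    for tgt, sign, kind, ref, ki, Ki in model._edges:
        src_const = input_level if kind == 1 else (ref if kind == 2 else 0.0)
        terms.append((tgt, sign, kind, ref, float(params[ki]), float(params[Ki]), src_const))
    n = model.n_states

    def f(y, t=0.0):
        out = [0.0] * n
        for tgt, sign, kind, ref, k, K, src_const in terms:
            src = y[ref] if kind == 0 else src_const
            x = y[tgt]
            if sign > 0:
                out[tgt] += src * k * (1.0 - x) / ((1.0 - x) + K)
            else:
                out[tgt] -= src * k * x / (x + K)
        return out

    return f


def _fast_jac(model: NetworkModel, input_level: float, params: np.ndarray):
    def jac(y, t=0.0):
        return model.jacobian(y, input_level, params)

    return jac


# ---------------------------------------------------------------------------
# steady states

def _newton_root(model, params, input_level, guess, tol, max_iter=60):
    """Damped Newton for the equilibrium, clipped to the unit box."""
    y = np.clip(np.asarray(guess, dtype=float), 1e-12, 1.0 - 1e-12)
    for _ in range(max_iter):
        r = model.rates(y, input_level, params)
        if not np.all(np.isfinite(r)):
            return None
        if np.max(np.abs(r)) < tol:
            return y
        J = model.jacobian(y, input_level, params)
        try:
            step = lin_solve(J, -r)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(step)):
            return None
        # backtracking line search on the residual norm
        lam = 1.0
        r0 = np.max(np.abs(r))
        for _ in range(30):
            y_new = np.clip(y + lam * step, 0.0, 1.0)
            r_new = model.rates(y_new, input_level, params)
            if np.all(np.isfinite(r_new)) and np.max(np.abs(r_new)) < r0:
                break
            lam *= 0.5
        else:
            return None
        y = y_new
    return y if np.max(np.abs(model.rates(y, input_level, params))) < tol else None


def _is_stable(model, params, input_level, state) -> bool:
    lam = eigvals(model.jacobian(state, input_level, params))
    return bool(np.max(lam.real) < 0)


def find_steady_state(
    model: NetworkModel,
    params: Sequence[float],
    input_level: float,
    initial_guess: Optional[Sequence[float]] = None,
    thresholds: RejectionThresholds = RejectionThresholds(),
) -> tuple[np.ndarray, bool]:
    """Locate a steady state of the network at a constant input level.

    Newton iteration from the guess (default: the box centre) is tried
    first; when it fails or lands on an unstable root, the system is
    relaxed by integration within the time budget and the endpoint is
    polished by Newton.  Returns ``(state, stable)``.

    Raises :class:`SteadyStateError` when nothing settles in time.
    """
    params = np.asarray(params, dtype=float)
    if initial_guess is None:
        initial_guess = np.full(model.n_states, 0.5)
    root = _newton_root(model, params, input_level, initial_guess, thresholds.tol_ss)
    if root is not None and _is_stable(model, params, input_level, root):
        return root, True

    # relaxation fallback: integrate from the guess until derivatives vanish
    f = _fast_rhs(model, input_level, params)
    jac = _fast_jac(model, input_level, params)
    y = np.clip(np.asarray(initial_guess, dtype=float), 0.0, 1.0)
    t0, horizon = 0.0, 50.0
    while t0 < thresholds.t_max:
        horizon = min(horizon, thresholds.t_max - t0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol, info = odeint(
                f, y, [0.0, horizon], Dfun=jac,
                rtol=thresholds.rtol, atol=thresholds.atol, full_output=True,
            )
        if info["message"] != "Integration successful.":
            raise SteadyStateError("integrator breakdown during relaxation")
        y = np.clip(sol[-1], 0.0, 1.0)
        resid = np.max(np.abs(f(y)))
        if resid < 1e-6:
            polished = _newton_root(model, params, input_level, y, thresholds.tol_ss)
            if polished is not None:
                return polished, _is_stable(model, params, input_level, polished)
        if resid < thresholds.tol_ss:
            return y, _is_stable(model, params, input_level, y)
        t0 += horizon
        horizon *= 4.0
    raise SteadyStateError("no steady state within the time budget")


# ---------------------------------------------------------------------------
# trajectory analysis helpers

def _local_extrema(times: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Times and values of interior local extrema of a sampled signal."""
    if len(values) < 3:
        return np.empty(0), np.empty(0)
    d = np.diff(values)
    sign = np.sign(d)
    nz = sign != 0
    # collapse flat runs so plateaus do not spawn spurious extrema
    idx = np.where(nz)[0]
    if len(idx) < 2:
        return np.empty(0), np.empty(0)
    flips = idx[:-1][sign[idx[:-1]] != sign[idx[1:]]] + 1
    return times[flips], values[flips]


def _oscillation_tail(times, output, t_start, floor):
    """Peak-to-peak amplitude sequence of the output after ``t_start``.

    Returns (amplitudes, ext_times); empty when fewer than 3 extrema.
    """
    mask = times >= t_start
    et, ev = _local_extrema(times[mask], output[mask])
    if len(ev) < 3:
        return np.empty(0), et
    amps = np.abs(np.diff(ev))
    return amps, et


def _refine_peak(times, values, i):
    """Parabolic refinement of a sampled extremum at index ``i``."""
    if i == 0 or i == len(values) - 1:
        return values[i]
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return y1
    delta = 0.5 * (y0 - y2) / denom
    if abs(delta) > 1.0:
        return y1
    return y1 - 0.25 * (y0 - y2) * delta


# ---------------------------------------------------------------------------
# step response

_CHUNK_ENDS = (20.0, 100.0, 500.0, 2500.0, 10000.0)


def simulate_step_response(
    model: NetworkModel,
    params: Sequence[float],
    protocol: StimulusProtocol = StimulusProtocol(),
    thresholds: RejectionThresholds = RejectionThresholds(),
) -> StepResponseSummary:
    """Integrate the response of the output node to the input step.

    The returned summary carries O1, the refined transient peak Op, the
    post-stimulus steady state O2 (Newton-polished when the trajectory
    converges to a root), the settle time (first time after which every
    state stays within ``settle_tol`` of the final state; ``None`` when the
    system does not settle inside the budget) and the sampled trajectory.
    """
    params = np.asarray(params, dtype=float)
    empty = lambda fail: StepResponseSummary(
        O1=np.nan, Op=np.nan, O2=np.nan, settle_time=None,
        times=np.empty(0), states=np.empty((0, model.n_states)),
        protocol=protocol, failure=fail,
    )
    try:
        pre, pre_stable = find_steady_state(model, params, protocol.I1, thresholds=thresholds)
    except SteadyStateError:
        return empty(OutcomeClass.NO_CONVERGENCE)
    if not pre_stable:
        return empty(OutcomeClass.NO_CONVERGENCE)
    O1 = float(pre[-1])

    # candidate post-stimulus equilibrium (may be unstable or absent)
    post_root = _newton_root(model, params, protocol.I2, pre, thresholds.tol_ss)
    post_stable = (
        _is_stable(model, params, protocol.I2, post_root) if post_root is not None else False
    )
    post_eigs = (
        eigvals(model.jacobian(post_root, protocol.I2, params))
        if post_root is not None else None
    )

    f = _fast_rhs(model, protocol.I2, params)
    jac = _fast_jac(model, protocol.I2, params)

    chunk_ends = tuple(min(c, thresholds.t_max) for c in _CHUNK_ENDS if c <= thresholds.t_max)
    if not chunk_ends or chunk_ends[-1] < thresholds.t_max:
        chunk_ends = chunk_ends + (thresholds.t_max,)

    all_t = [np.array([0.0])]
    all_y = [pre[None, :]]
    y = pre.copy()
    t_prev = 0.0
    settle_time: Optional[float] = None
    O2: Optional[float] = None
    final_state: Optional[np.ndarray] = None
    early_outcome: Optional[str] = None

    for t_end in chunk_ends:
        n_pts = 241 if t_prev == 0.0 else 161
        tgrid = np.linspace(t_prev, t_end, n_pts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol, info = odeint(
                f, y, tgrid - t_prev, Dfun=jac,
                rtol=thresholds.rtol, atol=thresholds.atol, full_output=True,
            )
        if info["message"] != "Integration successful." or not np.all(np.isfinite(sol)):
            return empty(OutcomeClass.NUMERICAL_FAILURE)
        all_t.append(tgrid[1:])
        all_y.append(sol[1:])
        y = sol[-1]
        t_prev = t_end

        resid = np.max(np.abs(f(y)))
        near_root = post_root is not None and np.max(np.abs(y - post_root)) < thresholds.settle_tol
        if (near_root and post_stable) or resid < thresholds.tol_ss:
            final_state = post_root if (near_root and post_stable) else np.asarray(y)
            polished = _newton_root(model, params, protocol.I2, final_state, thresholds.tol_ss)
            if polished is not None and _is_stable(model, params, protocol.I2, polished):
                final_state = polished
            O2 = float(final_state[-1])
            break

        if post_root is not None and post_stable:
            # inside the linear basin: extrapolate the exponential approach
            dist = np.max(np.abs(y - post_root))
            max_re = float(np.max(post_eigs.real))
            if dist < 0.02 and max_re < 0:
                t_settle_est = t_end + np.log(dist / thresholds.settle_tol) / (-max_re)
                if t_settle_est <= thresholds.t_max:
                    final_state = post_root
                    O2 = float(post_root[-1])
                    settle_time = t_settle_est
                    break
                else:
                    osc = bool(np.max(np.abs(post_eigs.imag)) > 10 * (-max_re))
                    early_outcome = (
                        OutcomeClass.WEAKLY_DAMPED_OSCILLATION
                        if (osc and dist >= thresholds.osc_floor)
                        else OutcomeClass.LONG_TRANSIENT
                    )
                    final_state = post_root
                    O2 = float(post_root[-1])
                    break
        if post_root is not None and not post_stable and t_end >= chunk_ends[min(1, len(chunk_ends) - 1)]:
            # unstable focus with the orbit bounded away from it: limit cycle
            dist = np.max(np.abs(y - post_root))
            times_so_far = np.concatenate(all_t)
            out_so_far = np.concatenate([a[:, -1] for a in all_y])
            amps, _ = _oscillation_tail(times_so_far, out_so_far, t_end * 0.25, thresholds.osc_floor)
            if dist > 10 * thresholds.settle_tol and len(amps) >= 4 and np.max(amps) >= thresholds.osc_floor:
                early_outcome = OutcomeClass.PERSISTENT_OSCILLATION
                final_state = np.asarray(y)
                O2 = float(y[-1])
                break

    times = np.concatenate(all_t)
    states = np.vstack(all_y)
    output = states[:, -1]

    if final_state is None:
        final_state = states[-1]
        O2 = float(final_state[-1])

    # transient peak: global extremum of |C(t) - O1| with parabolic refinement
    dev = np.abs(output - O1)
    ipk = int(np.argmax(dev))
    Op = float(_refine_peak(times, output, ipk)) if ipk > 0 else float(output[ipk])

    if settle_time is None and early_outcome is None:
        within = np.max(np.abs(states - final_state[None, :]), axis=1) <= thresholds.settle_tol
        if within[-1] and O2 is not None and np.max(np.abs(f(final_state))) < 1e-6:
            outside = np.where(~within)[0]
            settle_time = float(times[outside[-1] + 1]) if len(outside) else 0.0

    summary = StepResponseSummary(
        O1=O1, Op=Op, O2=O2, settle_time=settle_time,
        times=times, states=states, protocol=protocol,
        pre_state=pre, failure=early_outcome,
    )
    return summary


def classify_outcome(
    summary: StepResponseSummary,
    thresholds: RejectionThresholds = RejectionThresholds(),
) -> str:
    """Deterministically label one step-response summary.

    Order of precedence: numerical/convergence failures, vanishing steady
    states, settled trajectories (OK), then tail-oscillation analysis on
    the window after twice the time of the initial excursion peak
    (persistent if the peak-to-peak amplitude sits above the oscillation
    floor without decaying, weakly damped if it decays but is still above
    the floor at the end of the budget), and long transients otherwise.
    """
    if summary.failure in (OutcomeClass.NO_CONVERGENCE, OutcomeClass.NUMERICAL_FAILURE):
        return summary.failure
    if summary.O1 < thresholds.tiny_ss or (
        np.isfinite(summary.O2) and summary.O2 < thresholds.tiny_ss
    ):
        return OutcomeClass.TINY_STEADY_STATE
    if summary.pre_state is not None and len(summary.pre_state) > 1:
        regulatory = np.asarray(summary.pre_state[:-1], dtype=float)
        if np.any(regulatory < thresholds.tiny_state) or np.any(
            1.0 - regulatory < thresholds.tiny_state
        ):
            return OutcomeClass.TINY_STEADY_STATE
    if summary.failure in (
        OutcomeClass.PERSISTENT_OSCILLATION,
        OutcomeClass.WEAKLY_DAMPED_OSCILLATION,
        OutcomeClass.LONG_TRANSIENT,
    ):
        return summary.failure
    if summary.settle_time is not None and summary.settle_time <= thresholds.t_max:
        return OutcomeClass.OK

    times, output = summary.times, summary.output
    if len(times) < 8:
        return OutcomeClass.NO_CONVERGENCE
    dev = np.abs(output - summary.O1)
    t_peak = times[int(np.argmax(dev))]
    window_start = min(2.0 * max(t_peak, times[-1] * 0.01), times[-1] * 0.5)
    amps, _ = _oscillation_tail(times, output, window_start, thresholds.osc_floor)
    if len(amps) >= 3 and np.max(amps) >= thresholds.osc_floor:
        half = max(1, len(amps) // 2)
        early_amp = float(np.median(amps[:half]))
        late_amp = float(np.median(amps[half:]))
        if late_amp >= 0.99 * early_amp:
            return OutcomeClass.PERSISTENT_OSCILLATION
        if amps[-1] >= thresholds.osc_floor:
            return OutcomeClass.WEAKLY_DAMPED_OSCILLATION
    return OutcomeClass.LONG_TRANSIENT


# ---------------------------------------------------------------------------
# scores

def sensitivity_score(O1: float, Op: float, protocol: StimulusProtocol = StimulusProtocol()) -> float:
    """Relative peak excursion of the output normalised by the input step."""
    if O1 <= 0:
        raise ValueError("sensitivity undefined for non-positive O1 (tiny steady state)")
    return (abs(Op - O1) / O1) / protocol.relative_step


def precision_score(O1: float, O2: float, protocol: StimulusProtocol = StimulusProtocol()) -> float:
    """Inverse relative steady-state shift normalised by the input step.

    Perfect adaptation (O2 == O1) gives +inf.
    """
    if O1 <= 0:
        raise ValueError("precision undefined for non-positive O1 (tiny steady state)")
    shift = (abs(O2 - O1) / O1) / protocol.relative_step
    return np.inf if shift == 0 else 1.0 / shift


def is_kinetic_solution(scores: AdaptationScores) -> bool:
    """Perfect-adaptation criterion: sensitivity > 1 and precision > 10 (strict)."""
    return bool(scores.sensitivity > 1.0 and scores.precision > 10.0)


def evaluate_parameter_set(
    model: NetworkModel,
    params: Sequence[float],
    protocol: StimulusProtocol = StimulusProtocol(),
    thresholds: RejectionThresholds = RejectionThresholds(),
) -> tuple[str, StepResponseSummary, Optional[AdaptationScores], bool]:
    """Simulate, classify and (for usable trajectories) score one set.

    Returns ``(outcome, summary, scores_or_None, is_solution)``.
    """
    summary = simulate_step_response(model, params, protocol, thresholds)
    outcome = classify_outcome(summary, thresholds)
    if outcome != OutcomeClass.OK:
        return outcome, summary, None, False
    scores = AdaptationScores(
        sensitivity=sensitivity_score(summary.O1, summary.Op, protocol),
        precision=precision_score(summary.O1, summary.O2, protocol),
    )
    return outcome, summary, scores, is_kinetic_solution(scores)
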