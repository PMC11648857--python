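"""Nonlinear dynamics: right-hand side, integration, trajectory summaries.

Integration uses scipy's LSODA (stiff/non-stiff switching) in segments.
After each segment, species that have fallen below an extinction floor are
clamped to zero and — where zero is an absorbing state for them — held
there for the rest of the run.  Predator abundances are multiplicative
(dS_i proportional to S_i) so zero is always absorbing for predators; prey
can be re-seeded by chemostat supply or cross-feeding, so prey are only
clamped when their dynamics are purely multiplicative (logistic growth
without production).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .ensemble import Community

__all__ = ["SimulationControls", "Trajectory", "TrajectorySummary", "rhs", "simulate", "summarize_trajectory"]


@dataclass
class SimulationControls:
    """Tunable integration and summary settings.

    All thresholds are plumbing conventions, recorded in outputs:
    ``extinction_floor_rel`` is relative to the mean fixed-point abundance
    of the corresponding level; the tail window used for fluctuation and
    convergence checks is the trailing ``tail_fraction`` of the horizon;
    fluctuation requires a tail coefficient of variation above
    ``fluctuation_cv``; convergence requires relative drift across the
    tail below ``convergence_drift``.
    """

    t_max: float = 1e4
    rtol: float = 1e-7
    atol: float = 1e-10
    method: str = "LSODA"
    n_segments: int = 25
    n_store: int = 400
    extinction_floor_rel: float = 1e-8
    tail_fraction: float = 0.2
    fluctuation_cv: float = 1e-3
    convergence_drift: float = 1e-6
    early_stop: bool = True
    # stop only once |dx/dt| is this small relative to the abundance scale:
    # stricter than convergence_drift so that slow modes (rate ~ 1/M) have
    # decayed to well below the classifier's return tolerance
    early_stop_drift: float = 1e-9

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class Trajectory:
    times: np.ndarray
    S_path: np.ndarray  # N x T
    R_path: np.ndarray  # M x T
    terminal_flag: str  # "converged" | "max-time" | "failure"
    controls: SimulationControls
    message: str = ""


@dataclass
class TrajectorySummary:
    survivors: np.ndarray  # indices into the stacked (S, R) state
    surviving_predators: np.ndarray
    surviving_prey: np.ndarray
    final_state: np.ndarray  # stacked (S, R), extinct entries exactly 0
    fluctuating: bool
    converged: bool
    thresholds: dict = field(default_factory=dict)


def rhs(community: Community, S: np.ndarray, R: np.ndarray):
    """Time derivatives (dS, dR) of the community dynamics at (S, R)."""
    S = np.asarray(S, dtype=float)
    R = np.asarray(R, dtype=float)
    if S.shape != (community.N,) or R.shape != (community.M,):
        raise ValueError(
            f"state shapes {S.shape}, {R.shape} do not match community ({community.N}, {community.M})"
        )
    growth = (community.C * community.Y) @ R
    if community.H is not None:
        growth = growth + np.einsum("iab,a,b->i", community.H, R, R)
    dS = S * (growth - community.delta - community.epsilon * S)

    if community.supply_model == "logistic":
        h = community.supply_g * R * (community.supply_K - R)
    else:  # chemostat
        h = community.supply_g * (community.supply_K - R)
    dR = h - R * (community.C.T @ S)
    if community.P is not None:
        dR = dR + community.P.T @ S
    return dS, dR


def _prey_absorbing(community: Community) -> bool:
    return community.supply_model == "logistic" and community.P is None


def simulate(
    community: Community,
    initial: tuple[np.ndarray, np.ndarray],
    t_max: Optional[float] = None,
    controls: Optional[SimulationControls] = None,
) -> Trajectory:
    """Integrate the dynamics from ``initial = (S0, R0)`` up to ``t_max``.

    Returns the stored trajectory; integration failures are reported in
    ``terminal_flag`` rather than raised, so ensemble runs never lose a
    community silently.  With ``early_stop`` the run ends as soon as the
    relative time-derivative of every living species is below the
    convergence drift threshold (flag ``"converged"``).
    """
    controls = controls or SimulationControls()
    if t_max is None:
        t_max = controls.t_max
    S0 = np.asarray(initial[0], dtype=float).copy()
    R0 = np.asarray(initial[1], dtype=float).copy()
    if np.any(S0 < 0) or np.any(R0 < 0):
        raise ValueError("initial abundances must be nonnegative")
    N, M = community.N, community.M

    floor_S = controls.extinction_floor_rel * float(np.mean(community.S_star))
    floor_R = controls.extinction_floor_rel * float(np.mean(community.R_star))
    clamp_prey = _prey_absorbing(community)

    alive_S = S0 > floor_S
    alive_R = np.ones(M, dtype=bool)
    S0[~alive_S] = 0.0

    def f(_t, y):
        S = np.maximum(y[:N], 0.0)
        R = np.maximum(y[N:], 0.0)
        S[~alive_S] = 0.0
        if clamp_prey:
            R[~alive_R] = 0.0
        dS, dR = rhs(community, S, R)
        dS[~alive_S] = 0.0
        if clamp_prey:
            dR[~alive_R] = 0.0
        return np.concatenate([dS, dR])

    scale = max(float(np.mean(community.S_star)), float(np.mean(community.R_star)))
    seg_edges = np.linspace(0.0, t_max, controls.n_segments + 1)
    store_per_seg = max(2, controls.n_store // controls.n_segments)

    times = [np.array([0.0])]
    states = [np.concatenate([S0, R0])[:, None]]
    y = np.concatenate([S0, R0])
    flag, message = "max-time", ""

    for k in range(controls.n_segments):
        t0, t1 = seg_edges[k], seg_edges[k + 1]
        t_eval = np.linspace(t0, t1, store_per_seg + 1)[1:]
        sol = solve_ivp(
            f, (t0, t1), y, method=controls.method, t_eval=t_eval,
            rtol=controls.rtol, atol=controls.atol,
        )
        if not sol.success:
            flag, message = "failure", sol.message
            break
        times.append(sol.t)
        states.append(np.maximum(sol.y, 0.0))
        y = np.maximum(sol.y[:, -1], 0.0)
        # extinction clamping: zero is absorbing for predators always,
        # for prey only when their dynamics are purely multiplicative
        newly_dead = alive_S & (y[:N] <= floor_S)
        if np.any(newly_dead):
            alive_S = alive_S & ~newly_dead
            y[:N][~alive_S] = 0.0
        if clamp_prey:
            newly_dead_R = alive_R & (y[N:] <= floor_R)
            if np.any(newly_dead_R):
                alive_R = alive_R & ~newly_dead_R
                y[N:][~alive_R] = 0.0
        if controls.early_stop:
            dy = f(t1, y)
            if np.max(np.abs(dy)) / scale < controls.early_stop_drift:
                flag = "converged"
                break

    t_arr = np.concatenate(times)
    y_arr = np.concatenate(states, axis=1)
    return Trajectory(
        times=t_arr,
        S_path=y_arr[:N],
        R_path=y_arr[N:],
        terminal_flag=flag,
        controls=controls,
        message=message,
    )


def summarize_trajectory(
    trajectory: Trajectory,
    controls: Optional[SimulationControls] = None,
) -> TrajectorySummary:
    """Survivors, final state, and fluctuation/convergence verdicts.

    A species survives if it ends above the extinction floor.  The
    trajectory is *fluctuating* if any surviving species has a coefficient
    of variation above threshold over the tail window (the trailing
    ``tail_fraction`` of stored times), and *converged* if the relative
    drift between the two halves of the tail window is below threshold
    (or the integrator already certified convergence).
    """
    controls = controls or trajectory.controls
    t = trajectory.times
    if t.size < 4:
        raise ValueError("trajectory too short to summarize")
    X = np.vstack([trajectory.S_path, trajectory.R_path])
    N = trajectory.S_path.shape[0]

    tail_start = t[-1] * (1.0 - controls.tail_fraction)
    tail = t >= tail_start
    if tail.sum() < 3:
        tail = np.zeros_like(t, dtype=bool)
        tail[-3:] = True
    Xt = X[:, tail]

    level_scale = np.concatenate([
        np.full(N, np.mean(trajectory.S_path[:, 0]) if N else 1.0),
        np.full(X.shape[0] - N, np.mean(trajectory.R_path[:, 0])),
    ])
    floors = controls.extinction_floor_rel * np.maximum(level_scale, 1e-300)

    final = X[:, -1].copy()
    survivors_mask = final > floors
    final[~survivors_mask] = 0.0

    tail_mean = Xt.mean(axis=1)
    tail_std = Xt.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(tail_mean > floors, tail_std / np.maximum(tail_mean, 1e-300), 0.0)
    if trajectory.terminal_flag == "converged":
        fluctuating = False
        converged = True
    else:
        fluctuating = bool(np.any(cv[survivors_mask] > controls.fluctuation_cv))
        half = Xt.shape[1] // 2
        drift = np.abs(Xt[:, half:].mean(axis=1) - Xt[:, :half].mean(axis=1))
        rel_drift = float(np.max(drift / np.maximum(level_scale, 1e-300)))
        converged = rel_drift < controls.convergence_drift and not fluctuating

    idx = np.nonzero(survivors_mask)[0]
    return TrajectorySummary(
        survivors=idx,
        surviving_predators=idx[idx < N],
        surviving_prey=idx[idx >= N] - N,
        final_state=final,
        fluctuating=fluctuating,
        converged=converged,
        thresholds={
            "extinction_floor_rel": controls.extinction_floor_rel,
            "tail_fraction": controls.tail_fraction,
            "fluctuation_cv": controls.fluctuation_cv,
            "convergence_drift": controls.convergence_drift,
        },
    )
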