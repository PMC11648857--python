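"""Dynamical-behavior classification from multi-initial-condition runs.

Each community is simulated from several independently resampled initial
conditions and labelled with one of four behaviors:

- ``S_f``  — every run returns to the original fixed point with all
  N + M species surviving (globally stable fixed point);
- ``GS_p`` — all runs converge to one and the same reduced community
  (globally stable, but with extinctions);
- ``AS_p`` — runs converge to two or more distinct stable states
  (alternative stable states with partial coexistence);
- ``F``    — at least one run shows persistent fluctuations (limit
  cycles and chaos are not distinguished).

Fluctuation takes precedence: any persistently fluctuating run
demonstrates the loss of global stability of fixed points, whatever the
other runs do.  Final states of converged runs are compared in principal
component space and merged by single linkage below a relative distance
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from ._rng import child_rng
from .dynamics import SimulationControls, simulate, summarize_trajectory
from .ensemble import Community

__all__ = ["ClassifyControls", "BehaviorLabel", "classify_community", "cluster_final_states"]


@dataclass
class ClassifyControls:
    """Conventions for the classifier, all recorded in the output."""

    n_init: int = 10
    return_tol: float = 1e-3  # relative L-inf distance defining "came back"
    pca_variance: float = 0.99
    cluster_rel_threshold: float = 0.05
    sim: SimulationControls = field(default_factory=SimulationControls)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "sim"}
        d["sim"] = self.sim.to_dict()
        return d


@dataclass
class BehaviorLabel:
    label: str  # "S_f" | "GS_p" | "AS_p" | "F"
    n_initial_conditions: int
    n_clusters: int
    survivor_counts: list[int]
    evidence: list[dict]
    controls: dict = field(default_factory=dict)


def cluster_final_states(
    states: Sequence[np.ndarray], controls: Optional[ClassifyControls] = None
) -> int:
    """Number of distinct stable states among converged final states.

    States are projected onto the principal components explaining
    ``pca_variance`` of the variance and merged by single linkage when
    closer than ``cluster_rel_threshold`` times the overall abundance
    scale.  Identical states always collapse to one cluster.
    """
    controls = controls or ClassifyControls()
    X = np.asarray(states, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 states of equal dimension")
    scale = float(np.linalg.norm(X.mean(axis=0)))
    if scale == 0.0:
        scale = float(np.max(np.abs(X))) or 1.0
    threshold = controls.cluster_rel_threshold * scale

    spread = X - X.mean(axis=0)
    if float(np.max(np.abs(spread))) < 1e-12 * scale:
        return 1
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    Z = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    keep = int(np.searchsorted(cum, controls.pca_variance) + 1)
    Z = Z[:, :keep]

    d = pdist(Z)
    if d.size == 0 or float(np.max(d)) <= threshold:
        return 1
    merge = linkage(Z, method="single")
    labels = fcluster(merge, t=threshold, criterion="distance")
    return int(labels.max())


def _sample_initial(community: Community, rng: np.random.Generator):
    # same uniform ranges as fixed-point sampling, centred on the realized
    # fixed-point scale of each level
    s0 = rng.uniform(0.5, 1.5, size=community.N) * float(np.mean(community.S_star))
    r0 = rng.uniform(0.5, 1.5, size=community.M) * float(np.mean(community.R_star))
    return s0, r0


def classify_community(
    community: Community,
    n_init: Optional[int] = None,
    controls: Optional[ClassifyControls] = None,
    rng: np.random.Generator | None = None,
) -> BehaviorLabel:
    """Label a community's post-perturbation behavior.

    Runs ``n_init`` simulations from independently resampled initial
    conditions, summarizes each, and applies the precedence
    F > (GS_p | AS_p) > S_f.  Any integration failure raises — a
    community is never labelled from partial evidence.
    """
    controls = controls or ClassifyControls()
    n_init = n_init or controls.n_init
    if n_init < 2:
        raise ValueError("n_init must be >= 2")
    if rng is None:
        rng = child_rng(0)

    fixed = np.concatenate([community.S_star, community.R_star])
    fixed_scale = float(np.max(np.abs(fixed)))

    evidence: list[dict] = []
    survivor_counts: list[int] = []
    finals: list[np.ndarray] = []
    any_fluct = False
    all_returned = True

    for _ in range(n_init):
        init = _sample_initial(community, rng)
        traj = simulate(community, init, controls=controls.sim)
        if traj.terminal_flag == "failure":
            raise RuntimeError(f"integration failure during classification: {traj.message}")
        summary = summarize_trajectory(traj, controls.sim)
        returned = (
            summary.converged
            and float(np.max(np.abs(summary.final_state - fixed))) / fixed_scale
            <= controls.return_tol
        )
        n_surv = int(summary.survivors.size)
        extinct = n_surv < community.N + community.M
        evidence.append(
            {
                "returned_to_fixed_point": bool(returned),
                "fluctuating": bool(summary.fluctuating),
                "converged": bool(summary.converged),
                "n_extinct": community.N + community.M - n_surv,
            }
        )
        survivor_counts.append(n_surv)
        any_fluct = any_fluct or summary.fluctuating or not summary.converged
        all_returned = all_returned and returned and not extinct
        finals.append(summary.final_state)

    if any_fluct:
        label, n_clusters = "F", 0
    elif all_returned:
        label, n_clusters = "S_f", 1
    else:
        n_clusters = cluster_final_states(finals, controls)
        label = "GS_p" if n_clusters == 1 else "AS_p"

    return BehaviorLabel(
        label=label,
        n_initial_conditions=n_init,
        n_clusters=n_clusters,
        survivor_counts=survivor_counts,
        evidence=evidence,
        controls=controls.to_dict(),
    )
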