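"""Analytic stability criterion from non-Hermitian Marchenko-Pastur theory.

For large communities the reduced interaction matrix Lambda V^T behaves as
a product of correlated rectangular Gaussian matrices, and its eigenvalues
fill an ellipse in the complex plane.  With aligned-element correlation
Corr(Lambda_ia, V_ia) = -rho and the 1/M element-variance normalization,
the ellipse is centred at -rho (1 + N/M) with real semi-axis
sqrt(N/M) (1 + rho^2), so the rightmost eigenvalue crosses zero exactly at
rho = sqrt(N/M).  Together with the dual N > M regime this yields the
universal criterion

    stable  <=>  rho >= min( sqrt(N/M), sqrt(M/N) ):

communities are least stable when the two levels have similar diversity,
and a large diversity *difference* in either direction restores stability
(the reentrant transition).

The correlation itself is estimated from mechanistic moments under equal
abundances (S* = mu_S, R* = mu_R):

    rho_est = 1 / sqrt( (1 + sigma_P^2 / (mu_R^2 sigma_C^2))
                        * (1 + sigma_Y^2/mu_Y^2
                             + sigma_Y^2 mu_C^2 / (sigma_C^2 mu_Y^2)
                             + 2 mu_R^2 sigma_H^2 / (sigma_C^2 mu_Y^2)) )

so yield variation, cross-feeding variation and higher-order regulation
each lower the reciprocity between levels and destabilize.  The May-style
phenomenological interaction strength is sigma = 1 / (rho_est sqrt(M)),
turning the N <= M branch into May's classic sigma sqrt(N) <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .ensemble import EnsembleSpec

__all__ = [
    "CriterionResult",
    "rho_estimate",
    "stability_criterion",
    "stable_diversity_bounds",
    "ellipse_prediction",
    "may_interaction_strength",
    "evaluate_criterion",
]


@dataclass
class CriterionResult:
    rho_est: float
    predicted_stable: bool
    margin: float
    N_upper: float  # stable when N <= M rho^2
    N_lower: float  # stable when N >= M / rho^2
    sigma_may: float
    equal_abundance: bool  # False: rho_est applied beyond its derivation regime

    def to_dict(self) -> dict:
        return asdict(self)


def rho_estimate(spec: EnsembleSpec) -> float:
    """Interlevel correlation implied by the ensemble's moments.

    Exactly 1 when sigma_Y = sigma_P = sigma_H = 0 (pure MacArthur
    reciprocity) and strictly decreasing in each variation.
    """
    if spec.mu_Y <= 0:
        raise ValueError("rho_estimate requires mu_Y > 0")
    if spec.sigma_C <= 0:
        raise ValueError("rho_estimate requires sigma_C > 0")
    vy = (spec.sigma_Y / spec.mu_Y) ** 2
    cross = 1.0 + (spec.sigma_P / (spec.mu_R * spec.sigma_C)) ** 2
    within = (
        1.0
        + vy
        + vy * (spec.mu_C / spec.sigma_C) ** 2
        + 2.0 * (spec.mu_R * spec.sigma_H) ** 2 / (spec.sigma_C * spec.mu_Y) ** 2
    )
    return 1.0 / np.sqrt(cross * within)


def stability_criterion(rho: float, N: int, M: int) -> tuple[bool, float]:
    """Universal criterion: stable iff rho >= min(sqrt(N/M), sqrt(M/N)).

    Returns (predicted_stable, margin) where margin = rho - min(...).
    Symmetric under exchanging N and M.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    threshold = min(np.sqrt(N / M), np.sqrt(M / N))
    margin = float(rho - threshold)
    return margin >= 0.0, margin


def stable_diversity_bounds(rho: float, M: int) -> tuple[float, float]:
    """Predator-diversity window of instability at fixed prey diversity.

    Stability holds for N <= M rho^2 or N >= M / rho^2; the window in
    between is unstable and widens as rho decreases.  rho = 1 closes the
    window entirely (both bounds equal M).
    """
    if rho <= 0:
        raise ValueError("rho must be > 0")
    return float(M * rho**2), float(M / rho**2)


def ellipse_prediction(rho: float, N: int, M: int) -> tuple[float, float, float]:
    """Eigenvalue ellipse of the normalized reduced matrix (N <= M).

    Under the 1/M element-variance normalization of
    :func:`trophicstab.spectra.sample_correlated_pair`, eigenvalues of
    Lambda V^T fill an ellipse centred on the real axis at
    -rho (1 + N/M) with real semi-axis sqrt(N/M) (1 + rho^2).  Returns
    (center, semi_major, rightmost); rightmost = 0 exactly at
    rho = sqrt(N/M).  Arguments are swapped internally when N > M.
    """
    if N > M:
        N, M = M, N
    ratio = N / M
    center = -rho * (1.0 + ratio)
    semi_major = np.sqrt(ratio) * (1.0 + rho**2)
    return float(center), float(semi_major), float(center + semi_major)


def may_interaction_strength(spec: EnsembleSpec) -> float:
    """Effective May interaction strength sigma = 1 / (rho_est sqrt(M)).

    sigma sqrt(N) <= 1 reproduces the N <= M branch of the criterion
    (N <= M rho_est^2) exactly; greater yield variation or fewer prey
    means stronger effective interactions.
    """
    return 1.0 / (rho_estimate(spec) * np.sqrt(spec.M))


def evaluate_criterion(spec: EnsembleSpec) -> CriterionResult:
    """Full analytic prediction for an ensemble specification."""
    rho = float(rho_estimate(spec))
    stable, margin = stability_criterion(rho, spec.N, spec.M)
    n_up, n_lo = stable_diversity_bounds(rho, spec.M)
    return CriterionResult(
        rho_est=rho,
        predicted_stable=stable,
        margin=margin,
        N_upper=n_up,
        N_lower=n_lo,
        sigma_may=float(may_interaction_strength(spec)),
        equal_abundance=spec.fixed_point_mode == "equal",
    )
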