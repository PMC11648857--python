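"""Jacobian assembly, spectra, and the exact block-matrix eigenvalue reduction.

At an interior fixed point the community matrix is the block matrix

    J = [ -D(eps * S*)    Lambda  ]
        [     V^T        -D(b)    ]

where Lambda = D(S*) (C .* Y + R*.H + H.R*) carries how prey affect
predators, V^T = P^T - D(R*) C^T carries how predators affect prey, and
b is the effective prey self-regulation (g_a R*_a for logistic growth,
l_a + sum_i C_ia S*_i for a chemostat) — diagonal and positive for either
supply model.

When predator self-regulation is negligible and the prey block is
approximated by -a_eff I, the characteristic polynomial factorizes:
for N <= M the spectrum is M-N copies of -a_eff plus the 2N roots of
lambda (lambda + a_eff) = lambda_i(Lambda V^T); for N > M it is N-M
zeros plus the 2M roots driven by the eigenvalues of V^T Lambda.
Stability of large communities thus reduces to the reduced interpredator
(Lambda V^T) or interprey (V^T Lambda) interaction matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import Community

__all__ = [
    "JacobianParts",
    "SpectrumReport",
    "build_jacobian",
    "reduced_matrices",
    "quadratic_reduction_spectrum",
    "stability_verdict",
    "sample_correlated_pair",
]

#: Marginality tolerance: eigenvalues within this fraction of the matrix
#: max-norm of the imaginary axis are neither stable nor unstable.
DEFAULT_REL_TOL = 1e-9


@dataclass
class JacobianParts:
    Lambda: np.ndarray  # N x M: prey -> predators
    V: np.ndarray  # N x M; V^T is the lower-left block
    prey_selfreg: np.ndarray  # length M, positive
    pred_selfreg: np.ndarray  # length N, >= 0 (eps_i S*_i)
    a_eff: float  # scalar identity approximation of prey self-regulation


@dataclass
class SpectrumReport:
    eigenvalues: np.ndarray
    spectral_abscissa: float
    n_zero_modes: int
    verdict: str  # "stable" | "unstable" | "marginal"
    margin: float
    tol: float
    source: str = "full"
    meta: dict = field(default_factory=dict)


def build_jacobian(community: Community) -> tuple[np.ndarray, JacobianParts]:
    """Assemble the block Jacobian at the community's fixed point."""
    N, M = community.N, community.M
    S, R = community.S_star, community.R_star

    interaction = community.C * community.Y
    if community.H is not None:
        # (R*.H)_{ib} = sum_a R*_a H_iab ; (H.R*)_{ia} = sum_b H_iab R*_b
        interaction = interaction + np.einsum("a,iab->ib", R, community.H)
        interaction = interaction + np.einsum("iab,b->ia", community.H, R)
    Lambda = S[:, None] * interaction

    V = -(community.C * R[None, :])
    if community.P is not None:
        V = V + community.P

    if community.supply_model == "logistic":
        prey_selfreg = community.supply_g * R
    else:  # chemostat
        prey_selfreg = community.supply_g + community.C.T @ S
    pred_selfreg = community.epsilon * S

    J = np.zeros((N + M, N + M))
    J[:N, :N] = -np.diag(pred_selfreg)
    J[:N, N:] = Lambda
    J[N:, :N] = V.T
    J[N:, N:] = -np.diag(prey_selfreg)

    parts = JacobianParts(
        Lambda=Lambda,
        V=V,
        prey_selfreg=prey_selfreg,
        pred_selfreg=pred_selfreg,
        a_eff=float(np.mean(prey_selfreg)),
    )
    return J, parts


def reduced_matrices(parts: JacobianParts) -> tuple[np.ndarray, np.ndarray]:
    """Reduced interpredator (Lambda V^T, N x N) and interprey (V^T Lambda, M x M) matrices."""
    LVt = parts.Lambda @ parts.V.T
    VtL = parts.V.T @ parts.Lambda
    return LVt, VtL


def quadratic_reduction_spectrum(
    lv_eigs: np.ndarray, a_eff: float, N: int, M: int
) -> np.ndarray:
    """Jacobian spectrum implied by the reduced-matrix eigenvalues.

    ``lv_eigs`` are the eigenvalues of Lambda V^T when N <= M (length N)
    or of V^T Lambda when N > M (length M).  Each contributes the two
    roots of lambda (lambda + a_eff) = lv_eig; the remaining |M - N|
    eigenvalues are the degenerate -a_eff modes (N < M) or structural
    zeros (N > M).
    """
    lv_eigs = np.asarray(lv_eigs, dtype=complex)
    expected = min(N, M)
    if lv_eigs.shape != (expected,):
        raise ValueError(f"expected {expected} reduced eigenvalues, got {lv_eigs.shape}")
    if a_eff <= 0:
        raise ValueError("a_eff must be > 0")
    disc = np.sqrt(a_eff**2 + 4.0 * lv_eigs + 0j)
    roots = np.concatenate([(-a_eff + disc) / 2.0, (-a_eff - disc) / 2.0])
    if N <= M:
        pad = np.full(M - N, -a_eff, dtype=complex)
    else:
        pad = np.zeros(N - M, dtype=complex)
    return np.concatenate([pad, roots])


def stability_verdict(
    report_input: np.ndarray,
    tol: float | None = None,
    *,
    n_structural: int = 0,
    source: str = "full",
) -> SpectrumReport:
    """Classify a matrix or eigenvalue multiset as stable/unstable/marginal.

    Eigenvalues of magnitude <= tol count as zero modes, as do up to
    ``n_structural`` additional smallest-magnitude eigenvalues (exact
    structural zeros of rank-deficient Jacobians, e.g. the N - M
    degenerate modes when predators outnumber prey without
    self-regulation); neither triggers instability.  The verdict follows
    the spectral abscissa of the remaining eigenvalues: unstable above
    +tol, stable below -tol, marginal otherwise.
    """
    arr = np.asarray(report_input)
    if arr.ndim == 2:
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("matrix input must be square")
        scale = float(np.max(np.abs(arr))) if arr.size else 1.0
        eigs = np.linalg.eigvals(arr)
    elif arr.ndim == 1:
        eigs = arr.astype(complex)
        scale = float(np.max(np.abs(eigs))) if eigs.size else 1.0
    else:
        raise ValueError("input must be a square matrix or an eigenvalue multiset")
    if not np.all(np.isfinite(eigs)):
        raise ValueError("non-finite eigenvalues")
    if tol is None:
        tol = DEFAULT_REL_TOL * max(scale, 1.0)

    order = np.argsort(np.abs(eigs))
    eigs_sorted = eigs[order]
    n_zero = int(np.sum(np.abs(eigs_sorted) <= tol))
    n_drop = max(n_zero, min(n_structural, eigs_sorted.size))
    remaining = eigs_sorted[n_drop:]

    abscissa = float(np.max(eigs.real)) if eigs.size else -np.inf
    if remaining.size == 0:
        verdict, margin = "marginal", 0.0
    else:
        rmax = float(np.max(remaining.real))
        margin = rmax
        if rmax > tol:
            verdict = "unstable"
        elif rmax < -tol:
            verdict = "stable"
        else:
            verdict = "marginal"
    return SpectrumReport(
        eigenvalues=eigs,
        spectral_abscissa=abscissa,
        n_zero_modes=n_drop,
        verdict=verdict,
        margin=margin,
        tol=float(tol),
        source=source,
        meta={"n_structural": n_structural},
    )


def sample_correlated_pair(
    N: int, M: int, rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Paired Gaussian N x M matrices with aligned-element correlation -rho.

    Each element has mean 0 and variance 1/M (the normalization under
    which the non-Hermitian Marchenko-Pastur ellipse formulas hold);
    Corr(Lambda_ia, V_jb) = -rho * delta_ij * delta_ab.  rho = 1 returns
    V = -Lambda exactly.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    s = 1.0 / np.sqrt(M)
    A = rng.normal(0.0, s, size=(N, M))
    if rho == 1.0:
        return A, -A
    B = rng.normal(0.0, s, size=(N, M))
    V = -rho * A + np.sqrt(1.0 - rho**2) * B
    return A, V
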