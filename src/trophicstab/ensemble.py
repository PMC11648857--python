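"""Random community ensembles with a prescribed interior fixed point.

A community couples N predators (or consumers) to M prey (or resources):

    dS_i/dt = S_i ( sum_a C_ia Y_ia R_a + sum_ab H_iab R_a R_b - delta_i - eps_i S_i )
    dR_a/dt = h_a(R_a) + sum_i P_ia S_i - R_a sum_i C_ia S_i

with logistic prey growth h_a(R) = g_a R (K_a - R) or chemostat supply
h_a(R) = l_a (kappa_a - R).  Consumption rates C scale as 1/M (per-capita
intake stays bounded as prey diversity grows), cross-feeding production P
as 1/M, and higher-order regulation H as 1/M^{3/2}, so that summed effects
stay of constant order in large communities.

The sampler works backwards from a feasible fixed point: C, Y, H, P and the
abundances (S*, R*) are drawn first, then the mortalities delta_i and the
supply parameters (K_a or kappa_a) are *solved* so that (S*, R*) is an
exact equilibrium.  Draws violating positivity (delta_i <= 0, or K_a <=
R*_a under logistic growth) are rejected and resampled up to a retry
budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from ._rng import child_rng

__all__ = [
    "EnsembleSpec",
    "Community",
    "FeasibilityError",
    "sample_community",
    "solve_consistent_parameters",
    "rescale_yields",
    "save_community",
    "load_community",
]

#: Maximum absolute value of the dynamics' right-hand side at (S*, R*)
#: for a community to count as an exact fixed point.
RESIDUAL_TOL = 1e-10

#: How many times the sampler redraws before declaring the spec infeasible.
DEFAULT_MAX_RETRIES = 100

_CONSUMPTION_MODELS = ("uniform_0_to_1_over_M", "gaussian")
_SUPPLY_MODELS = ("logistic", "chemostat")
_FIXED_POINT_MODES = ("uniform", "equal")

#: Moments of U[0, 1] — implied by the uniform consumption model.
_UNIFORM_MU = 0.5
_UNIFORM_SIGMA = 1.0 / (2.0 * np.sqrt(3.0))


class FeasibilityError(RuntimeError):
    """Raised when no positivity-respecting community is found in the retry budget."""


@dataclass
class EnsembleSpec:
    """Statistical description of a family of random communities.

    Moments are quoted *before* the diversity scaling: elements of C are
    drawn with mean ``mu_C / M`` and SD ``sigma_C / M`` (or uniformly on
    [0, 1/M]), P with mean ``mu_P / M`` and SD ``sigma_P / M``, and H with
    mean 0 and SD ``sigma_H / M^{3/2}``.  Yields Y are unscaled Gaussian
    (mean ``mu_Y``, SD ``sigma_Y``) and may come out negative, modelling
    toxic prey.

    ``fixed_point_mode='uniform'`` draws S* uniformly on
    ``[(1-w) mu_S, (1+w) mu_S]`` with relative half-width ``w =
    fp_rel_halfwidth`` (R* analogously); ``'equal'`` pins S* = mu_S and
    R* = mu_R, the assumption under which the analytic correlation
    estimate is derived.
    """

    N: int
    M: int
    consumption_model: str = "uniform_0_to_1_over_M"
    mu_C: float = _UNIFORM_MU
    sigma_C: float = _UNIFORM_SIGMA
    mu_Y: float = 1.0
    sigma_Y: float = 0.0
    mu_P: float = 0.0
    sigma_P: float = 0.0
    sigma_H: float = 0.0
    epsilon: float = 0.0
    supply_model: str = "logistic"
    supply_base: float = 1.0
    mu_S: float = 1.0
    mu_R: float = 1.0
    fixed_point_mode: str = "uniform"
    fp_rel_halfwidth: float = 0.5
    yield_cap: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1 or self.M < 1:
            raise ValueError("N and M must be positive integers")
        if self.consumption_model not in _CONSUMPTION_MODELS:
            raise ValueError(f"consumption_model must be one of {_CONSUMPTION_MODELS}")
        if self.supply_model not in _SUPPLY_MODELS:
            raise ValueError(f"supply_model must be one of {_SUPPLY_MODELS}")
        if self.fixed_point_mode not in _FIXED_POINT_MODES:
            raise ValueError(f"fixed_point_mode must be one of {_FIXED_POINT_MODES}")
        for name in ("sigma_C", "sigma_Y", "sigma_P", "sigma_H"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mu_S <= 0 or self.mu_R <= 0:
            raise ValueError("mu_S and mu_R must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.supply_base <= 0:
            raise ValueError("supply_base must be > 0")
        if not 0 <= self.fp_rel_halfwidth < 1:
            raise ValueError("fp_rel_halfwidth must be in [0, 1)")
        if self.consumption_model == "uniform_0_to_1_over_M":
            # downstream analytics rely on the implied U[0,1] moments
            self.mu_C = _UNIFORM_MU
            self.sigma_C = _UNIFORM_SIGMA

    def replace(self, **kwargs) -> "EnsembleSpec":
        d = asdict(self)
        d.update(kwargs)
        return EnsembleSpec(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleSpec":
        known = set(cls.__dataclass_fields__)  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown EnsembleSpec keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class Community:
    """One realized parameter set together with its interior fixed point.

    ``supply_g`` holds g_a (logistic) or l_a (chemostat); ``supply_K``
    holds the solved K_a or kappa_a.  H and P are ``None`` when the
    corresponding mechanism is disabled.
    """

    C: np.ndarray
    Y: np.ndarray
    delta: np.ndarray
    epsilon: np.ndarray
    supply_model: str
    supply_g: np.ndarray
    supply_K: np.ndarray
    S_star: np.ndarray
    R_star: np.ndarray
    H: Optional[np.ndarray] = None
    P: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.C.shape[0]

    @property
    def M(self) -> int:
        return self.C.shape[1]


def rescale_yields(Y: np.ndarray, cap: float) -> np.ndarray:
    """Scale all yields by a common positive factor so the maximum is <= cap.

    Multiplying every yield by the same number leaves the dimensionless
    variation sigma_Y / mu_Y — the quantity stability depends on — exactly
    unchanged.  A no-op when the cap already holds.
    """
    if cap <= 0:
        raise ValueError("cap must be > 0")
    ymax = float(np.max(Y))
    if ymax <= cap:
        return np.asarray(Y, dtype=float).copy()
    return np.asarray(Y, dtype=float) * (cap / ymax)


def solve_consistent_parameters(
    C: np.ndarray,
    Y: np.ndarray,
    H: Optional[np.ndarray],
    P: Optional[np.ndarray],
    epsilon: np.ndarray,
    S_star: np.ndarray,
    R_star: np.ndarray,
    supply_model: str,
    supply_base: np.ndarray,
):
    """Solve mortalities and supply parameters that make (S*, R*) exact.

    Predator balance gives, per predator i,

        delta_i = sum_a C_ia Y_ia R*_a + sum_ab H_iab R*_a R*_b - eps_i S*_i

    and the prey balance gives, per prey a with net consumption
    q_a = R*_a sum_i C_ia S*_i - sum_i P_ia S*_i,

        logistic:  K_a     = R*_a + q_a / (g_a R*_a)
        chemostat: kappa_a = R*_a + q_a / l_a.

    Returns ``(delta, supply_K, violations)`` where ``violations`` is a
    dict of boolean masks flagging delta_i <= 0 and (logistic only)
    K_a <= R*_a; the caller decides whether to resample.
    """
    growth = (C * Y) @ R_star
    if H is not None:
        growth = growth + np.einsum("iab,a,b->i", H, R_star, R_star)
    delta = growth - epsilon * S_star

    net_consumption = R_star * (C.T @ S_star)
    if P is not None:
        net_consumption = net_consumption - P.T @ S_star

    if supply_model == "logistic":
        supply_K = R_star + net_consumption / (supply_base * R_star)
        supply_violation = supply_K <= R_star
    elif supply_model == "chemostat":
        supply_K = R_star + net_consumption / supply_base
        # kappa < R* is legitimate when cross-feeding makes net consumption
        # negative; only positive-net-consumption prey require kappa > R*.
        supply_violation = (net_consumption > 0) & (supply_K <= R_star)
    else:  # pragma: no cover - guarded by EnsembleSpec
        raise ValueError(f"unknown supply model {supply_model!r}")

    violations = {"delta_nonpositive": delta <= 0, "supply": supply_violation}
    return delta, supply_K, violations


def _draw_parameters(spec: EnsembleSpec, rng: np.random.Generator):
    N, M = spec.N, spec.M
    if spec.consumption_model == "uniform_0_to_1_over_M":
        C = rng.uniform(0.0, 1.0 / M, size=(N, M))
    else:
        C = rng.normal(spec.mu_C / M, spec.sigma_C / M, size=(N, M))
    Y = rng.normal(spec.mu_Y, spec.sigma_Y, size=(N, M))
    if spec.yield_cap is not None:
        Y = rescale_yields(Y, spec.yield_cap)
    H = None
    if spec.sigma_H > 0:
        H = rng.normal(0.0, spec.sigma_H / M**1.5, size=(N, M, M))
    P = None
    if spec.mu_P > 0 or spec.sigma_P > 0:
        P = rng.normal(spec.mu_P / M, spec.sigma_P / M, size=(N, M))
    return C, Y, H, P


def _draw_fixed_point(spec: EnsembleSpec, rng: np.random.Generator):
    if spec.fixed_point_mode == "equal":
        return np.full(spec.N, spec.mu_S), np.full(spec.M, spec.mu_R)
    w = spec.fp_rel_halfwidth
    S = rng.uniform((1 - w) * spec.mu_S, (1 + w) * spec.mu_S, size=spec.N)
    R = rng.uniform((1 - w) * spec.mu_R, (1 + w) * spec.mu_R, size=spec.M)
    return S, R


def sample_community(
    spec: EnsembleSpec,
    rng: np.random.Generator | None = None,
    *,
    max_retries: int = DEFAULT_MAX_RETRIES,
    allow_negative_delta: bool = False,
) -> Community:
    """Draw one community consistent with ``spec``.

    Mechanistic parameters and the fixed point are sampled; mortalities
    and supply parameters are solved so the fixed point is exact to within
    ``RESIDUAL_TOL``.  Draws violating positivity are rejected and redrawn;
    after ``max_retries`` failures a :class:`FeasibilityError` is raised
    (typical cause: strongly negative mean yields making solved
    mortalities negative).
    """
    if rng is None:
        rng = child_rng(spec.seed)
    supply_base = np.full(spec.M, float(spec.supply_base))
    epsilon = np.full(spec.N, float(spec.epsilon))

    for attempt in range(max_retries):
        C, Y, H, P = _draw_parameters(spec, rng)
        S_star, R_star = _draw_fixed_point(spec, rng)
        delta, supply_K, violations = solve_consistent_parameters(
            C, Y, H, P, epsilon, S_star, R_star, spec.supply_model, supply_base
        )
        bad = bool(np.any(violations["supply"]))
        if not allow_negative_delta:
            bad = bad or bool(np.any(violations["delta_nonpositive"]))
        if bad:
            continue
        community = Community(
            C=C,
            Y=Y,
            delta=delta,
            epsilon=epsilon,
            supply_model=spec.supply_model,
            supply_g=supply_base,
            supply_K=supply_K,
            S_star=S_star,
            R_star=R_star,
            H=H,
            P=P,
            meta={
                "spec": spec.to_dict(),
                "attempts": attempt + 1,
                "residual_tol": RESIDUAL_TOL,
                "max_retries": max_retries,
            },
        )
        _check_residual(community)
        return community

    raise FeasibilityError(
        f"no feasible community within {max_retries} retries for "
        f"N={spec.N}, M={spec.M} (check mean yields / cross-feeding levels)"
    )


def _check_residual(community: Community) -> None:
    from .dynamics import rhs  # local import to avoid a cycle

    dS, dR = rhs(community, community.S_star, community.R_star)
    resid = max(float(np.max(np.abs(dS))), float(np.max(np.abs(dR))))
    community.meta["fixed_point_residual"] = resid
    if resid > RESIDUAL_TOL:
        raise FeasibilityError(f"fixed-point residual {resid:.3e} exceeds {RESIDUAL_TOL}")


# ---------------------------------------------------------------------------
# serialization: JSON metadata + NPZ matrix payload, round-trip exact

_ARRAY_FIELDS = ("C", "Y", "delta", "epsilon", "supply_g", "supply_K", "S_star", "R_star", "H", "P")


def save_community(community: Community, path_prefix: str | Path) -> None:
    """Write ``<prefix>.json`` (scalars/metadata) and ``<prefix>.npz`` (arrays)."""
    prefix = Path(path_prefix)
    arrays = {}
    for name in _ARRAY_FIELDS:
        value = getattr(community, name)
        if value is not None:
            arrays[name] = np.asarray(value)
    np.savez(prefix.with_suffix(".npz"), **arrays)
    doc = {
        "supply_model": community.supply_model,
        "N": community.N,
        "M": community.M,
        "meta": community.meta,
        "arrays": sorted(arrays),
    }
    prefix.with_suffix(".json").write_text(json.dumps(doc, indent=2, sort_keys=True))


def load_community(path_prefix: str | Path) -> Community:
    prefix = Path(path_prefix)
    doc = json.loads(prefix.with_suffix(".json").read_text())
    with np.load(prefix.with_suffix(".npz")) as payload:
        arrays = {name: payload[name] for name in payload.files}
    return Community(
        C=arrays["C"],
        Y=arrays["Y"],
        delta=arrays["delta"],
        epsilon=arrays["epsilon"],
        supply_model=doc["supply_model"],
        supply_g=arrays["supply_g"],
        supply_K=arrays["supply_K"],
        S_star=arrays["S_star"],
        R_star=arrays["R_star"],
        H=arrays.get("H"),
        P=arrays.get("P"),
        meta=doc.get("meta", {}),
    )
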