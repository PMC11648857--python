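"""Batch experiments: diversity and yield-variation phase diagrams.

A sweep samples ``n_per_cell`` communities per grid cell and records the
fraction that are unstable, with binomial standard error.  Two verdict
modes exist: ``jacobian`` reads stability directly off the eigenvalues of
the full community matrix (fast; the default for phase diagrams), while
``classification`` runs the multi-initial-condition classifier and counts
every non-S_f community as unstable (slow; used for validation).

Each cell derives its own seed stream from the root seed, so results are
identical regardless of execution order and any single cell can be
re-generated in isolation.

The three-level experiment is a direct random-Jacobian assembly: a
block-tridiagonal community matrix for M bottom species, N1 middle and N2
top species, with correlated Gaussian interface pairs (correlation -rho at
both interfaces, element variance 1/source-level-size), per-level diagonal
self-regulation, and no direct top-bottom coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .classify import ClassifyControls, classify_community
from .ensemble import EnsembleSpec, FeasibilityError, sample_community
from .spectra import build_jacobian, sample_correlated_pair, stability_verdict

__all__ = [
    "PhaseTable",
    "ThreeLevelSpec",
    "sweep_two_level",
    "sweep_yield_variation",
    "build_three_level",
    "sweep_three_level",
    "plot_phase_table",
]


@dataclass
class PhaseTable:
    """Tidy sweep results: one row per grid cell.

    ``df`` columns always include the axis coordinates, ``fraction_unstable``,
    ``sem`` (binomial standard error sqrt(f (1-f) / n)), ``n``, ``n_failed``
    and ``cell_seed``; ``meta`` records the full configuration.
    """

    df: pd.DataFrame
    axes: tuple[str, ...]
    mode: str
    meta: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class ThreeLevelSpec:
    """Three-level random-Jacobian experiment specification.

    Bottom (M prey/resources), middle (N1 predators), top (N2 apex
    predators); adjacent levels interact through correlated Gaussian
    blocks with interlevel correlation ``rho`` at both interfaces, and the
    top-bottom blocks are structurally zero.  Default self-regulation:
    bottom 1, middle 0 (the consumer-resource convention), top 1.
    """

    M: int
    N1: int
    N2: int
    rho: float = 0.8
    selfreg_bottom: float = 1.0
    selfreg_middle: float = 0.0
    selfreg_top: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1 or self.N1 < 1 or self.N2 < 0:
            raise ValueError("need M >= 1, N1 >= 1, N2 >= 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _binomial_sem(f: float, n: int) -> float:
    return float(np.sqrt(f * (1.0 - f) / n)) if n > 0 else float("nan")


def _cell_unstable_fraction(
    spec: EnsembleSpec,
    n_per_cell: int,
    mode: str,
    root_seed: int,
    cell_index: int,
    classify_controls: Optional[ClassifyControls],
) -> tuple[float, int, int, int]:
    """Returns (fraction_unstable, n_ok, n_failed, cell_seed_key)."""
    n_unstable = 0
    n_ok = 0
    n_failed = 0
    n_structural = max(0, spec.N - spec.M) if spec.epsilon == 0 else 0
    for rep in range(n_per_cell):
        rng = child_rng(root_seed, cell_index, rep)
        try:
            community = sample_community(spec, rng)
        except FeasibilityError:
            n_failed += 1
            continue
        if mode == "jacobian":
            J, _ = build_jacobian(community)
            report = stability_verdict(J, n_structural=n_structural)
            unstable = report.verdict == "unstable"
        elif mode == "classification":
            label = classify_community(
                community, controls=classify_controls, rng=child_rng(root_seed, cell_index, rep, 1)
            )
            unstable = label.label != "S_f"
        else:
            raise ValueError("mode must be 'jacobian' or 'classification'")
        n_ok += 1
        n_unstable += int(unstable)
    frac = n_unstable / n_ok if n_ok else float("nan")
    return frac, n_ok, n_failed, cell_index


def sweep_two_level(
    spec_template: EnsembleSpec,
    N_values: Sequence[int],
    M_values: Sequence[int],
    n_per_cell: int,
    mode: str = "jacobian",
    root_seed: int = 0,
    classify_controls: Optional[ClassifyControls] = None,
) -> PhaseTable:
    """Fraction of unstable communities over an (N, M) grid.

    The same statistical parameters are used in every cell; only the two
    diversities vary.  Plotted against N/M the curves for different M
    collapse onto one reentrant curve.
    """
    if not len(N_values) or not len(M_values):
        raise ValueError("grids must be nonempty")
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    rows = []
    for idx, (M, N) in enumerate((m, n) for m in M_values for n in N_values):
        spec = spec_template.replace(N=int(N), M=int(M))
        frac, n_ok, n_failed, key = _cell_unstable_fraction(
            spec, n_per_cell, mode, root_seed, idx, classify_controls
        )
        rows.append(
            {
                "N": int(N),
                "M": int(M),
                "ratio": N / M,
                "fraction_unstable": frac,
                "sem": _binomial_sem(frac, n_ok),
                "n": n_ok,
                "n_failed": n_failed,
                "cell_seed": f"{root_seed}:{key}",
            }
        )
    df = pd.DataFrame(rows)
    meta = {
        "spec_template": spec_template.to_dict(),
        "root_seed": root_seed,
        "n_per_cell": n_per_cell,
        "mode": mode,
    }
    return PhaseTable(df=df, axes=("N", "M"), mode=mode, meta=meta)


def sweep_yield_variation(
    spec_template: EnsembleSpec,
    sy_over_my_values: Sequence[float],
    N: int,
    M: int,
    n_per_cell: int,
    mode: str = "jacobian",
    root_seed: int = 0,
    classify_controls: Optional[ClassifyControls] = None,
) -> PhaseTable:
    """Fraction unstable as yield variation sigma_Y / mu_Y increases.

    Yield variation lowers the interlevel correlation rho, so the
    unstable fraction rises from 0 through a single transition once rho
    crosses min(sqrt(N/M), sqrt(M/N)).
    """
    if any(v < 0 for v in sy_over_my_values):
        raise ValueError("yield variation values must be >= 0")
    rows = []
    for idx, v in enumerate(sy_over_my_values):
        spec = spec_template.replace(N=int(N), M=int(M), sigma_Y=float(v) * spec_template.mu_Y)
        frac, n_ok, n_failed, key = _cell_unstable_fraction(
            spec, n_per_cell, mode, root_seed, idx, classify_controls
        )
        rows.append(
            {
                "sigma_Y_over_mu_Y": float(v),
                "N": int(N),
                "M": int(M),
                "fraction_unstable": frac,
                "sem": _binomial_sem(frac, n_ok),
                "n": n_ok,
                "n_failed": n_failed,
                "cell_seed": f"{root_seed}:{key}",
            }
        )
    df = pd.DataFrame(rows)
    meta = {
        "spec_template": spec_template.to_dict(),
        "root_seed": root_seed,
        "n_per_cell": n_per_cell,
        "mode": mode,
        "N": N,
        "M": M,
    }
    return PhaseTable(df=df, axes=("sigma_Y_over_mu_Y",), mode=mode, meta=meta)


def build_three_level(spec3: ThreeLevelSpec, rng: np.random.Generator) -> np.ndarray:
    """Assemble one three-level block-tridiagonal community matrix.

    State ordering is [bottom; middle; top].  Interface pairs are drawn
    with :func:`sample_correlated_pair` — bottom-middle blocks sized
    N1 x M (element variance 1/M), middle-top blocks sized N2 x N1
    (element variance 1/N1) — keeping the two-level normalization
    convention per interface.
    """
    M, N1, N2 = spec3.M, spec3.N1, spec3.N2
    L1, V1 = sample_correlated_pair(N1, M, spec3.rho, rng)  # bottom <-> middle
    L2, V2 = sample_correlated_pair(N2, N1, spec3.rho, rng)  # middle <-> top

    n = M + N1 + N2
    J = np.zeros((n, n))
    sl = {
        "b": slice(0, M),
        "m": slice(M, M + N1),
        "t": slice(M + N1, n),
    }
    J[sl["b"], sl["b"]] = -spec3.selfreg_bottom * np.eye(M)
    J[sl["m"], sl["m"]] = -spec3.selfreg_middle * np.eye(N1)
    J[sl["t"], sl["t"]] = -spec3.selfreg_top * np.eye(N2)
    J[sl["b"], sl["m"]] = V1.T  # middle affects bottom
    J[sl["m"], sl["b"]] = L1  # bottom affects middle
    J[sl["m"], sl["t"]] = V2.T  # top affects middle
    J[sl["t"], sl["m"]] = L2  # middle affects top
    # top-bottom blocks stay structurally zero
    return J


def sweep_three_level(
    spec3_template: ThreeLevelSpec,
    M_values: Sequence[int],
    N2_values: Sequence[int],
    n_per_cell: int,
    root_seed: int = 0,
) -> PhaseTable:
    """Unstable fraction over a (M, N2) grid at fixed middle diversity N1.

    Also emits the collapsed coordinate (M + N2) / N1, against which the
    different reentrant transitions collapse; instability peaks where
    M + N2 is closest to N1.
    """
    if not len(M_values) or not len(N2_values):
        raise ValueError("grids must be nonempty")
    N1 = spec3_template.N1
    rows = []
    for idx, (M, N2) in enumerate((m, n2) for m in M_values for n2 in N2_values):
        spec3 = ThreeLevelSpec(
            M=int(M),
            N1=N1,
            N2=int(N2),
            rho=spec3_template.rho,
            selfreg_bottom=spec3_template.selfreg_bottom,
            selfreg_middle=spec3_template.selfreg_middle,
            selfreg_top=spec3_template.selfreg_top,
            seed=root_seed,
        )
        # middle level without self-regulation has N1 - (M + N2) structural
        # zero modes when it outnumbers its neighbours
        n_structural = max(0, N1 - (int(M) + int(N2))) if spec3.selfreg_middle == 0 else 0
        n_unstable = 0
        for rep in range(n_per_cell):
            rng = child_rng(root_seed, idx, rep)
            J3 = build_three_level(spec3, rng)
            report = stability_verdict(J3, n_structural=n_structural)
            n_unstable += int(report.verdict == "unstable")
        frac = n_unstable / n_per_cell
        rows.append(
            {
                "M": int(M),
                "N1": N1,
                "N2": int(N2),
                "collapsed_ratio": (M + N2) / N1,
                "fraction_unstable": frac,
                "sem": _binomial_sem(frac, n_per_cell),
                "n": n_per_cell,
                "n_failed": 0,
                "cell_seed": f"{root_seed}:{idx}",
            }
        )
    df = pd.DataFrame(rows)
    meta = {
        "spec3_template": spec3_template.to_dict(),
        "root_seed": root_seed,
        "n_per_cell": n_per_cell,
    }
    return PhaseTable(df=df, axes=("M", "N2"), mode="jacobian", meta=meta)


def plot_phase_table(table: PhaseTable, path: str | Path, x: str = "ratio") -> None:
    """Render a sweep as a curve (1D) or heatmap (2D grid) to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.df
    fig, ax = plt.subplots(figsize=(5, 4))
    if len(table.axes) == 1 or x in df.columns and df[x].nunique() == len(df):
        xcol = x if x in df.columns else table.axes[0]
        ax.errorbar(df[xcol], df["fraction_unstable"], yerr=df["sem"], fmt="o-")
        ax.set_xlabel(xcol)
        ax.set_ylabel("fraction unstable")
        if xcol == "ratio":
            ax.set_xscale("log")
    else:
        a0, a1 = table.axes[:2]
        pivot = df.pivot_table(index=a1, columns=a0, values="fraction_unstable")
        im = ax.imshow(pivot.to_numpy(), origin="lower", aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(pivot.columns)), pivot.columns)
        ax.set_yticks(range(len(pivot.index)), pivot.index)
        ax.set_xlabel(a0)
        ax.set_ylabel(a1)
        fig.colorbar(im, ax=ax, label="fraction unstable")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
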