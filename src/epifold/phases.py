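"""Phase-diagram scanning in the (U_ns, U_s) plane.

Each parameter point is classified from the stationary solutions of the
self-consistent distance dynamics, reached from a canonical set of
initial conditions (coil, globule, microphase-separated):

* ``multistable`` — several distinct fixed points coexist,
* ``coil``       — mean long-range D stays a sizable fraction of the
  ideal-chain value (extended conformations),
* ``MPS``        — checkerboard contrast between same-type and
  cross-type long-range distances exceeds a threshold (monomers of the
  same chromatin state pack into distinct 3D domains),
* ``globule``    — compact but type-blind,
* ``unresolved`` — a solver run failed to converge.

The numeric thresholds mirror what is classified visually on contact
maps; they are exposed in :class:`ClassifyParams` and calibrated so the
four archetypes are recovered on the (A10B10)6 toy copolymer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import InteractionModel
from .sca import (
    DistanceMatrix,
    SCAParams,
    evolve,
    find_fixed_points,
    init_coil,
    init_globule,
    init_mps,
)
from .sequences import EpigenomicSequence, same_state_indicator

__all__ = [
    "PhasePoint",
    "PhaseDiagram",
    "ClassifyParams",
    "checkerboard_index",
    "classify_point",
    "scan_grid",
]


def checkerboard_index(
    D, seq: EpigenomicSequence, min_separation: int = 10
) -> float:
    """Contrast between cross-type and same-type long-range distances:

    ``(mean cross-type D - mean same-type D) / (mean all-pairs D)``

    over pairs with |m - n| >= min_separation.  Positive values indicate
    same-type compaction (microphase separation); 0 for type-blind D.
    """
    D = D.D if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    if len(set(seq.states)) < 2:
        raise ValueError("checkerboard index needs at least 2 state types")
    n = seq.n
    idx = np.arange(n)
    far = np.abs(idx[:, None] - idx[None, :]) >= min_separation
    same = same_state_indicator(seq).astype(bool) & far
    cross = ~same_state_indicator(seq).astype(bool) & far
    if not same.any() or not cross.any():
        raise ValueError("no same-type or cross-type pairs at this separation")
    return float((D[cross].mean() - D[same].mean()) / D[far].mean())


@dataclass
class ClassifyParams:
    """Classification thresholds (exposed config; see module docstring)."""

    #: coil if mean long-range D > coil_fraction x ideal-chain value
    coil_fraction: float = 0.5
    #: MPS if checkerboard index exceeds this
    checkerboard_threshold: float = 0.1
    #: |m-n| floor for the checkerboard contrast
    checkerboard_min_separation: int = 10
    #: long-range pairs are |m-n| >= long_range_fraction x N
    long_range_fraction: float = 0.25
    #: relative Frobenius distance above which fixed points are distinct
    distinct_tol: float = 1e-2
    #: SCA integration method used for the scan
    method: str = "exponential"
    #: refine each evolved endpoint with a Newton-Krylov root solve
    polish: bool = True


@dataclass
class PhasePoint:
    U_ns: float
    U_s: float
    label: str
    mean_long_range_D: float
    checkerboard: float
    multiplicity: int
    converged: bool


@dataclass
class PhaseDiagram:
    points: list[PhasePoint]
    U_ns_values: tuple[float, ...]
    U_s_values: tuple[float, ...]
    sequence: EpigenomicSequence
    params: SCAParams

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    p.U_ns,
                    p.U_s,
                    p.label,
                    p.mean_long_range_D,
                    p.checkerboard,
                    p.multiplicity,
                    p.converged,
                )
                for p in self.points
            ],
            columns=[
                "U_ns",
                "U_s",
                "label",
                "mean_long_range_D",
                "checkerboard",
                "multiplicity",
                "converged",
            ],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def label_grid(self) -> np.ndarray:
        """Labels as a (len(U_ns_values), len(U_s_values)) object array."""
        grid = np.empty((len(self.U_ns_values), len(self.U_s_values)), dtype=object)
        for k, p in enumerate(self.points):
            i, j = divmod(k, len(self.U_s_values))
            grid[i, j] = p.label
        return grid

    def plot(self, path: str | Path) -> None:
        """Render the label grid as a heat map image."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        order = ["coil", "multistable", "MPS", "globule", "unresolved"]
        codes = np.vectorize(order.index)(self.label_grid())
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(
            codes.T,
            origin="lower",
            aspect="auto",
            cmap="viridis",
            vmin=0,
            vmax=len(order) - 1,
            extent=(
                min(self.U_ns_values), max(self.U_ns_values),
                min(self.U_s_values), max(self.U_s_values),
            ),
        )
        ax.set_xlabel("U_ns (kT)")
        ax.set_ylabel("U_s (kT)")
        cbar = fig.colorbar(im, ticks=range(len(order)))
        cbar.ax.set_yticklabels(order)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _default_inits(
    seq: EpigenomicSequence,
    model: InteractionModel,
    names,
    overrides: dict | None = None,
):
    overrides = overrides or {}
    built = {
        "coil": lambda: init_coil(seq, model),
        "globule": lambda: init_globule(seq, model, plateau=model.chain.l**2),
        "mps": lambda: init_mps(
            seq, model, intra=model.chain.l**2 / 3.0, inter=3.0 * seq.n**0.5
        ),
    }
    return [overrides[name] if name in overrides else built[name]() for name in names]


def classify_point(
    seq: EpigenomicSequence,
    model: InteractionModel,
    params: SCAParams | None = None,
    classify: ClassifyParams | None = None,
    *,
    init_names: tuple[str, ...] = ("coil", "globule", "mps"),
    init_overrides: dict | None = None,
) -> PhasePoint:
    """Classify one (U_ns, U_s) point from its stationary solutions."""
    params = params or SCAParams()
    cls = classify or ClassifyParams()
    init_set = _default_inits(seq, model, init_names, init_overrides)
    fps = find_fixed_points(
        seq,
        model,
        params,
        init_set,
        method=cls.method,
        distinct_tol=cls.distinct_tol,
        polish=cls.polish,
    )
    n = seq.n
    idx = np.arange(n)
    long_range = np.abs(idx[:, None] - idx[None, :]) >= max(
        1, int(cls.long_range_fraction * n)
    )
    coil_lr = float(init_coil(seq, model).D[long_range].mean())

    U_s_diag = float(np.diag(model.U_s_by_type.values).mean())
    if fps.unconverged:
        label = "unresolved"
        mean_lr, cb = np.nan, np.nan
    elif fps.multiplicity >= 2:
        label = "multistable"
        mean_lr = float(
            np.mean([rep.D[long_range].mean() for rep in fps.representatives])
        )
        cb = float(
            np.mean(
                [
                    checkerboard_index(rep, seq, cls.checkerboard_min_separation)
                    for rep in fps.representatives
                ]
            )
        )
    else:
        rep = fps.representatives[0]
        mean_lr = float(rep.D[long_range].mean())
        cb = checkerboard_index(rep, seq, cls.checkerboard_min_separation)
        if mean_lr > cls.coil_fraction * coil_lr:
            label = "coil"
        elif cb > cls.checkerboard_threshold:
            label = "MPS"
        else:
            label = "globule"
    return PhasePoint(
        U_ns=model.U_ns,
        U_s=U_s_diag,
        label=label,
        mean_long_range_D=mean_lr,
        checkerboard=cb,
        multiplicity=fps.multiplicity,
        converged=not fps.unconverged,
    )


def scan_grid(
    seq: EpigenomicSequence,
    U_ns_values,
    U_s_values,
    params: SCAParams | None = None,
    classify: ClassifyParams | None = None,
    *,
    base_model: InteractionModel | None = None,
    init_names: tuple[str, ...] = ("coil", "globule", "mps"),
) -> PhaseDiagram:
    """Classify every node of a rectangular (U_ns, U_s) grid.

    Grid points are evaluated independently (no warm-starting between
    neighbors, which would imprint hysteresis on the labels); a per-point
    failure becomes an ``unresolved`` label without aborting the scan.

    The "coil" member of the init set is the stationary swollen coil of
    the *zero-coupling* chain (excluded volume only), computed once per
    scan: in this model the extended reference state is the
    self-avoiding coil, and starting from the ideal-chain profile would
    just repeat the same slow swelling transient at every weakly coupled
    node.
    """
    U_ns_values = tuple(float(u) for u in U_ns_values)
    U_s_values = tuple(float(u) for u in U_s_values)
    if not U_ns_values or not U_s_values:
        raise ValueError("grid axes must be non-empty")
    params = params or SCAParams()
    cls = classify or ClassifyParams()
    base = base_model or InteractionModel.uniform(0.0, 0.0, seq.alphabet)
    overrides = {}
    if "coil" in init_names:
        model0 = base.with_strengths(0.0, 0.0)
        res0 = evolve(
            init_coil(seq, model0), seq, model0, params, method=cls.method
        )
        overrides["coil"] = res0.distances
    points: list[PhasePoint] = []
    for U_ns in U_ns_values:
        for U_s in U_s_values:
            model = base.with_strengths(U_ns, U_s)
            try:
                points.append(
                    classify_point(
                        seq,
                        model,
                        params,
                        classify,
                        init_names=init_names,
                        init_overrides=overrides,
                    )
                )
            except Exception:
                points.append(
                    PhasePoint(U_ns, U_s, "unresolved", np.nan, np.nan, 0, False)
                )
    return PhaseDiagram(
        points=points,
        U_ns_values=U_ns_values,
        U_s_values=U_s_values,
        sequence=seq,
        params=params,
    )
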