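"""Chain and interaction energetics of the block copolymer.

The Hamiltonian is ``H = H_chain + H_inter``:

* ``H_chain = (3 kT / 2 l^2) sum_n (X_n - X_{n-1})^2 + sum_{n<m} U_hc(r_nm)``
  — harmonic springs between successive beads plus a purely repulsive
  excluded-volume potential (Weeks–Chandler–Andersen form in MD),
* ``H_inter = sum_{n<m} E_nm exp(-r_nm^2 / (2 r0^2))`` — short-range
  Gaussian attractions with ``E_nm = U_ns + U_s[state_m, state_n]``.

The module also provides the closed-form Gaussian-ensemble averages of
the pair potential and of its isotropic Hessian reduction, which are the
building blocks of the self-consistent mean Hessian <J> used by
:mod:`epifold.sca`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sequences import DEFAULT_ALPHABET, EpigenomicSequence


@dataclass
class ChainParams:
    """Bead-spring chain parameters in reduced units (l = kT = 1).

    ``hardcore_md`` is the MD excluded-volume potential: WCA, i.e. a
    Lennard-Jones potential truncated and shifted at ``2^(1/6) sigma`` so
    it is purely repulsive.  ``hardcore_sca`` is the averageable
    excluded-volume surrogate used by the Gaussian self-consistent
    solver: a repulsive Gaussian ``+U_hc0 exp(-r^2/(2 r_hc^2))``.
    """

    l: float = 1.0
    kT: float = 1.0
    #: (form, sigma, epsilon); only the "wca" form is implemented
    hardcore_md: tuple[str, float, float] = ("wca", 1.0, 1.0)
    #: (U_hc0, r_hc) of the repulsive-Gaussian SCA surrogate; defaults
    #: approximately match the WCA second virial (~4.7 l^3) with a range
    #: short enough that repulsion dominates attraction at contact
    hardcore_sca: tuple[float, float] = (10.0, 0.3)

    def __post_init__(self) -> None:
        form, sigma, eps = self.hardcore_md
        u0, rhc = self.hardcore_sca
        if self.l <= 0 or self.kT <= 0:
            raise ValueError("l and kT must be positive")
        if form != "wca":
            raise ValueError(f"unknown MD hard-core form {form!r}")
        if sigma <= 0 or eps < 0:
            raise ValueError("require sigma > 0 and epsilon >= 0")
        if u0 < 0 or rhc <= 0:
            raise ValueError("require U_hc0 >= 0 and r_hc > 0")

    @property
    def spring_k(self) -> float:
        """Scalar spring coefficient 3 kT / l^2 (per component)."""
        return 3.0 * self.kT / self.l**2


@dataclass
class InteractionModel:
    """Pairwise interaction model: E_nm = U_ns + U_s_by_type[s_m, s_n].

    ``U_s_by_type`` is a symmetric label-indexed table of specific
    strengths; its diagonal is the usual uniform ``U_s`` (same-state
    attraction) and its off-diagonal entries default to 0.  Heterogeneous
    tables (e.g. Polycomb–Polycomb stronger than black–black) are
    supported directly.
    """

    U_ns: float = 0.0
    U_s_by_type: pd.DataFrame = field(default_factory=lambda: pd.DataFrame())
    r0: float = 0.5
    chain: ChainParams = field(default_factory=ChainParams)

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.U_s_by_type.empty:
            self.U_s_by_type = pd.DataFrame(
                0.0, index=list(DEFAULT_ALPHABET), columns=list(DEFAULT_ALPHABET)
            )
        t = self.U_s_by_type
        if list(t.index) != list(t.columns) or not np.allclose(
            t.values, t.values.T
        ):
            raise ValueError("U_s_by_type must be symmetric and label-aligned")

    @classmethod
    def uniform(
        cls,
        U_ns: float,
        U_s: float,
        alphabet: tuple[str, ...] = DEFAULT_ALPHABET,
        r0: float = 0.5,
        chain: ChainParams | None = None,
    ) -> "InteractionModel":
        """Model with one specific strength shared by all state types."""
        labels = list(alphabet)
        table = pd.DataFrame(0.0, index=labels, columns=labels)
        np.fill_diagonal(table.values, U_s)
        return cls(
            U_ns=U_ns,
            U_s_by_type=table,
            r0=r0,
            chain=chain if chain is not None else ChainParams(),
        )

    def with_strengths(self, U_ns: float, U_s: float) -> "InteractionModel":
        """Copy of this model with new uniform strengths (same range,
        chain and alphabet)."""
        table = self.U_s_by_type.copy()
        table.loc[:, :] = 0.0
        np.fill_diagonal(table.values, U_s)
        return InteractionModel(
            U_ns=U_ns, U_s_by_type=table, r0=self.r0, chain=self.chain
        )

    # ------------------------------------------------------------ config I/O
    def to_config(self, path: str | Path) -> None:
        """Serialize to a flat key-value YAML config."""
        form, sigma, eps = self.chain.hardcore_md
        u0, rhc = self.chain.hardcore_sca
        cfg = {
            "U_ns": float(self.U_ns),
            "r0": float(self.r0),
            "l": float(self.chain.l),
            "kT": float(self.chain.kT),
            "hardcore.md_form": form,
            "hardcore.md_sigma": float(sigma),
            "hardcore.md_epsilon": float(eps),
            "hardcore.sca_U_hc0": float(u0),
            "hardcore.sca_r_hc": float(rhc),
            "U_s_by_type": {
                f"{a}:{b}": float(self.U_s_by_type.loc[a, b])
                for a in self.U_s_by_type.index
                for b in self.U_s_by_type.columns
                if list(self.U_s_by_type.index).index(a)
                <= list(self.U_s_by_type.columns).index(b)
            },
        }
        Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))

    @classmethod
    def from_config(cls, path: str | Path) -> "InteractionModel":
        cfg = yaml.safe_load(Path(path).read_text())
        labels: list[str] = []
        for key in cfg["U_s_by_type"]:
            for lab in key.split(":"):
                if lab not in labels:
                    labels.append(lab)
        table = pd.DataFrame(0.0, index=labels, columns=labels)
        for key, val in cfg["U_s_by_type"].items():
            a, b = key.split(":")
            table.loc[a, b] = table.loc[b, a] = float(val)
        chain = ChainParams(
            l=float(cfg["l"]),
            kT=float(cfg["kT"]),
            hardcore_md=(
                cfg["hardcore.md_form"],
                float(cfg["hardcore.md_sigma"]),
                float(cfg["hardcore.md_epsilon"]),
            ),
            hardcore_sca=(
                float(cfg["hardcore.sca_U_hc0"]),
                float(cfg["hardcore.sca_r_hc"]),
            ),
        )
        return cls(
            U_ns=float(cfg["U_ns"]), U_s_by_type=table, r0=float(cfg["r0"]), chain=chain
        )


def interaction_matrix(seq: EpigenomicSequence, model: InteractionModel) -> np.ndarray:
    """Pair strength matrix E with E[m, n] = U_ns + U_s_by_type[s_m, s_n].

    Symmetric; the (unused) diagonal is set to 0.
    """
    missing = set(seq.alphabet) - set(model.U_s_by_type.index)
    if missing:
        raise ValueError(f"state labels missing from U_s_by_type: {sorted(missing)}")
    table = model.U_s_by_type.loc[list(seq.alphabet), list(seq.alphabet)].to_numpy()
    codes = seq.codes
    E = model.U_ns + table[np.ix_(codes, codes)]
    np.fill_diagonal(E, 0.0)
    return E


def _wca_energy(r2: np.ndarray, sigma: float, eps: float) -> np.ndarray:
    """WCA pair energy from squared distances (vectorized)."""
    out = np.zeros_like(r2)
    if eps == 0.0:
        return out
    rc2 = 2.0 ** (1.0 / 3.0) * sigma**2  # (2^{1/6} sigma)^2
    inside = r2 < rc2
    if np.any(inside):
        with np.errstate(divide="ignore"):
            s6 = (sigma**2 / r2[inside]) ** 3
        out[inside] = 4.0 * eps * (s6**2 - s6) + eps
    return out


def total_energy(
    positions: np.ndarray, seq: EpigenomicSequence, model: InteractionModel
) -> float:
    """Total Hamiltonian H = H_chain + H_inter of a conformation.

    Spring prefactor 3kT/(2 l^2); Gaussian pair terms
    ``E_mn exp(-r^2/(2 r0^2))`` and the WCA excluded-volume term run over
    all pairs n < m.
    """
    X = np.asarray(positions, dtype=float)
    if X.shape != (seq.n, 3):
        raise ValueError(f"positions must have shape ({seq.n}, 3)")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite coordinates")
    cp = model.chain
    bonds = X[1:] - X[:-1]
    e_spring = 0.5 * cp.spring_k * float((bonds**2).sum())

    iu, ju = np.triu_indices(seq.n, k=1)
    r2 = ((X[iu] - X[ju]) ** 2).sum(axis=1)
    E = interaction_matrix(seq, model)
    e_gauss = float((E[iu, ju] * np.exp(-r2 / (2.0 * model.r0**2))).sum())
    _, sigma, eps = cp.hardcore_md
    e_hc = float(_wca_energy(r2, sigma, eps).sum())
    return e_spring + e_gauss + e_hc


def gaussian_pair_averages(E_pair, a, D):
    """Exact Gaussian-ensemble averages of the pair potential and of its
    isotropic Hessian reduction.

    For ``u(r) = E_pair exp(-r^2/(2 a^2))`` and a centered isotropic
    Gaussian separation with per-component variance ``D``
    (``<(X_m - X_n)^2> = 3 D``):

    * ``<u> = E_pair (a^2 / (a^2 + D))^{3/2}``
    * ``tr<grad grad u>/3 = <lap u>/3 = -E_pair a^3 / (a^2 + D)^{5/2}``

    Both are validated against Monte-Carlo sampling in the test suite.
    Inputs broadcast; returns ``(mean_potential, mean_hessian_scalar)``.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("D must be non-negative")
    a2 = np.asarray(a, dtype=float) ** 2
    denom = a2 + D
    mean_u = E_pair * (a2 / denom) ** 1.5
    mean_h = -E_pair * a2**1.5 / denom**2.5
    return mean_u, mean_h


def _chain_offdiag(n: int, spring_k: float) -> np.ndarray:
    """Off-diagonal part of the harmonic-chain contribution to <J>:
    +spring_k on the first off-diagonals (the diagonal follows from the
    zero-row-sum property of pair terms)."""
    J = np.zeros((n, n))
    idx = np.arange(n - 1)
    J[idx, idx + 1] = spring_k
    J[idx + 1, idx] = spring_k
    return J


def _mean_hessian_fast(
    D: np.ndarray,
    E: np.ndarray,
    spring_k: float,
    r0: float,
    u0: float,
    rhc: float,
) -> np.ndarray:
    """Hot-path <J> assembly from a precomputed pair-strength matrix E
    (avoids re-deriving E from labels at every rhs evaluation)."""
    n = D.shape[0]
    offdiag = ~np.eye(n, dtype=bool)
    J = _chain_offdiag(n, spring_k)
    d = np.maximum(D[offdiag], 0.0)  # guard transient integrator undershoot
    r02 = r0 * r0
    t = r02 + d
    J[offdiag] += -E[offdiag] * r02**1.5 / (t * t * np.sqrt(t))
    if u0 != 0.0:
        rhc2 = rhc * rhc
        t = rhc2 + d
        J[offdiag] += -u0 * rhc2**1.5 / (t * t * np.sqrt(t))
    np.fill_diagonal(J, 0.0)
    np.fill_diagonal(J, -J.sum(axis=1))
    return J


def mean_hessian(
    D: np.ndarray, seq: EpigenomicSequence, model: InteractionModel
) -> np.ndarray:
    """Gaussian-ensemble average <J> = -<d^2 H / dX_m dX_n>, reduced to
    isotropic scalar blocks.

    The harmonic chain contributes exactly ``-(3kT/l^2) L`` with L the
    path-graph Laplacian; each pair (m, n) contributes the closed-form
    Hessian average of its Gaussian attraction (strength E_mn, range r0)
    plus the repulsive SCA hard-core surrogate, both evaluated at D_mn.
    Pair terms depend only on coordinate differences, so every row of J
    sums to zero (translation invariance); the diagonal is built from
    that property.
    """
    D = np.asarray(D, dtype=float)
    n = seq.n
    if D.shape != (n, n):
        raise ValueError(f"D must have shape ({n}, {n})")
    if np.any(D[~np.eye(n, dtype=bool)] < 0):
        raise ValueError("D must be non-negative")
    cp = model.chain
    E = interaction_matrix(seq, model)
    u0, rhc = cp.hardcore_sca
    return _mean_hessian_fast(D, E, cp.spring_k, model.r0, u0, rhc)
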