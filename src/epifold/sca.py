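"""Gaussian self-consistent dynamics of the mean-squared-distance matrix.

The chain's configurational distribution is approximated at every time
by a multivariate Gaussian; its second moments then obey a closed
self-consistent evolution for the per-component separation variances
``D_mn = <(X_m - X_n)^2> / 3``:

    xi dD_mn/dt = 4 kT - sum_k (<J_mk> - <J_nk>) (D_mk - D_nk)

with <J> the Gaussian-averaged (minus) Hessian of the Hamiltonian, a
function of D itself (:func:`epifold.energy.mean_hessian`).  The ideal
(non-interacting) chain profile ``D_mn = |m - n| l^2 / 3`` is an exact
fixed point of this equation — the 4 kT noise term needs no extra
calibration.

Two integrators are provided:

* ``method="rk45"`` — adaptive Dormand–Prince 5(4), the reference
  transient integrator; stability-limited by the stiffest mode of <J>,
  so best for weak-to-moderate couplings.
* ``method="exponential"`` — an adaptive exponential stepper that
  freezes <J> over each step and propagates the covariance exactly
  under the frozen linear dynamics (a Lyapunov-equation update in the
  eigenbasis of <J>).  Unconditionally stable for the frozen part, it
  turns into a rapidly converging self-consistent-field iteration near
  fixed points and is the workhorse for phase-diagram scans.

Stationarity is declared on the dimensionless residual
``max |xi dD/dt| / (4 kT) < steady_tol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .energy import (
    InteractionModel,
    _mean_hessian_fast,
    interaction_matrix,
    mean_hessian,
)
from .sequences import EpigenomicSequence

__all__ = [
    "DistanceMatrix",
    "SCAParams",
    "ConvergenceReport",
    "SCAResult",
    "FixedPoints",
    "sca_rhs",
    "evolve",
    "init_coil",
    "init_globule",
    "init_mps",
    "init_from_contact_map",
    "find_fixed_points",
    "polish_fixed_point",
    "gram_from_distances",
    "distances_from_gram",
    "psd_project",
]


@dataclass
class DistanceMatrix:
    """Per-component separation variances D_mn = <(X_m - X_n)^2>/3 (units l^2)."""

    D: np.ndarray
    bin_size: int | None = None
    l: float = 1.0

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        validate_distance_matrix(self.D)

    @property
    def n(self) -> int:
        return self.D.shape[0]

    # ------------------------------------------------------------------ I/O
    def to_text(self, path: str | Path) -> None:
        """Dense whitespace-delimited text with a one-line header."""
        header = f"N={self.n} bin_size={self.bin_size or 0} l={self.l}"
        np.savetxt(path, self.D, header=header)

    @classmethod
    def from_text(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().lstrip("#").split()
        meta = dict(kv.split("=") for kv in header)
        D = np.loadtxt(path)
        bin_size = int(meta.get("bin_size", 0)) or None
        return cls(D=D, bin_size=bin_size, l=float(meta.get("l", 1.0)))

    def save_npz(self, path: str | Path, times=None, snapshots=None) -> None:
        """Binary container keyed by D / times / snapshots."""
        extras = {}
        if times is not None:
            extras["times"] = np.asarray(times)
        if snapshots is not None:
            extras["snapshots"] = np.asarray(snapshots)
        np.savez_compressed(path, D=self.D, **extras)


def validate_distance_matrix(D: np.ndarray, *, require_positive: bool = False) -> None:
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be a square matrix")
    if not np.all(np.isfinite(D)):
        raise ValueError("D contains non-finite entries")
    if not np.allclose(D, D.T, atol=1e-10 * (1 + np.abs(D).max())):
        raise ValueError("D must be symmetric")
    if np.abs(np.diag(D)).max() > 1e-12 * (1 + np.abs(D).max()):
        raise ValueError("D must have zero diagonal")
    off = D[~np.eye(D.shape[0], dtype=bool)]
    if require_positive and off.size and off.min() <= 0:
        raise ValueError("off-diagonal D entries must be positive")


def _as_D(D) -> np.ndarray:
    return D.D if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)


@dataclass
class SCAParams:
    """Solver parameters (reduced units; time in xi l^2 / kT)."""

    xi: float = 1.0
    rtol: float = 1e-6
    atol: float = 1e-8
    steady_tol: float = 1e-6
    t_max: float = 1e4
    snapshot_times: tuple[float, ...] | None = None
    #: divergence guard: any D entry exceeding this aborts with a flag
    max_D: float = 1e8
    #: exponential stepper: max relative change of D per step
    exp_step_change: float = 0.05
    max_steps: int = 2_000_000
    #: rk45: stop early if the residual has not improved for this many
    #: steps (the explicit method plateaus near rtol x stiffness)
    stall_steps: int = 2000
    #: exponential stepper: relative <J> drift triggering an
    #: eigendecomposition refresh (0 = refresh every step)
    eig_refresh: float = 0.0

    def __post_init__(self) -> None:
        if self.xi <= 0:
            raise ValueError("xi must be positive")
        if min(self.rtol, self.atol, self.steady_tol) <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class ConvergenceReport:
    converged: bool
    t_end: float
    n_steps: int
    residual: float
    diverged: bool = False
    method: str = "rk45"


@dataclass
class SCAResult:
    distances: DistanceMatrix
    snapshots: list[tuple[float, np.ndarray]]
    report: ConvergenceReport


# ---------------------------------------------------------------- embeddings
def gram_from_distances(D: np.ndarray) -> np.ndarray:
    """Centered Gram (covariance) matrix C from D by double-centering -D/2."""
    D = _as_D(D)
    n = D.shape[0]
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * (H @ D @ H)


def distances_from_gram(C: np.ndarray) -> np.ndarray:
    d = np.diag(C)
    D = d[:, None] + d[None, :] - 2.0 * C
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


def psd_project(D: np.ndarray) -> np.ndarray:
    """Nearest valid Gaussian embedding: clip negative Gram eigenvalues
    to zero and rebuild D."""
    C = gram_from_distances(D)
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    return distances_from_gram((V * w) @ V.T)


def is_valid_embedding(D: np.ndarray, tol: float = 1e-8) -> bool:
    w = np.linalg.eigvalsh(gram_from_distances(D))
    return bool(w.min() >= -tol * max(1.0, w.max()))


# -------------------------------------------------------------- right-hand side
def _rhs_from_J(D: np.ndarray, J: np.ndarray, kT: float, xi: float) -> np.ndarray:
    JD = J @ D
    s = np.diag(JD)
    rhs = 4.0 * kT - (s[:, None] + s[None, :] - JD - JD.T)
    np.fill_diagonal(rhs, 0.0)
    return rhs / xi


def sca_rhs(
    D,
    seq: EpigenomicSequence,
    model: InteractionModel,
    params: SCAParams | None = None,
) -> np.ndarray:
    """dD/dt of the self-consistent distance dynamics (symmetric, zero
    diagonal)."""
    D = _as_D(D)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite entries in D")
    params = params or SCAParams()
    J = mean_hessian(D, seq, model)
    return _rhs_from_J(D, J, model.chain.kT, params.xi)


def _scaled_residual(rhs: np.ndarray, kT: float, xi: float) -> float:
    return float(np.abs(rhs).max() * xi / (4.0 * kT))


# ------------------------------------------------------------------- initial D
def init_coil(seq: EpigenomicSequence, model: InteractionModel) -> DistanceMatrix:
    """Ideal-chain profile D_mn = |m - n| l^2 / 3 (a Brownian-bridge-type
    covariance; always a valid embedding)."""
    idx = np.arange(seq.n)
    D = np.abs(idx[:, None] - idx[None, :]) * model.chain.l**2 / 3.0
    return DistanceMatrix(D=D, bin_size=seq.bin_size, l=model.chain.l)


def init_globule(
    seq: EpigenomicSequence, model: InteractionModel, plateau: float
) -> DistanceMatrix:
    """Collapsed initial condition: the coil profile saturated at ``plateau``."""
    if plateau <= 0:
        raise ValueError("plateau must be positive")
    D = np.minimum(init_coil(seq, model).D, plateau)
    D = psd_project(D)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D=D, bin_size=seq.bin_size, l=model.chain.l)


def init_mps(
    seq: EpigenomicSequence,
    model: InteractionModel,
    intra: float = 1.0,
    inter: float = 10.0,
) -> DistanceMatrix:
    """Microphase-separated initial condition: same-type pairs close
    (variance ``intra``), cross-type pairs far (``inter``); short-range
    chain structure kept via an elementwise minimum with the coil
    profile; repaired to a valid embedding by PSD projection."""
    if not 0 < intra < inter:
        raise ValueError("require 0 < intra < inter")
    from .sequences import same_state_indicator

    delta = same_state_indicator(seq).astype(bool)
    D = np.where(delta, intra, inter).astype(float)
    np.fill_diagonal(D, 0.0)
    D = np.minimum(D, init_coil(seq, model).D)
    D = psd_project(D)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D=D, bin_size=seq.bin_size, l=model.chain.l)


def init_from_contact_map(P, contact_params=None) -> DistanceMatrix:
    """Invert the Gaussian contact formula P = A D^{-3/2} to an
    experimental-like initial condition D = (A / P)^{2/3}.

    Zero/missing entries are imputed from the coil profile scaled to the
    median of the inverted entries at the same separation's order of
    magnitude; the result is PSD-projected.
    """
    from .contacts import ContactMap

    if isinstance(P, ContactMap):
        A = P.A if P.A is not None else 1.0
        bin_size = P.bin_size
        P = P.P
    else:
        A = 1.0 if contact_params is None else float(contact_params)
        bin_size = None
        P = np.asarray(P, dtype=float)
    if contact_params is not None:
        A = float(contact_params)
    n = P.shape[0]
    off = ~np.eye(n, dtype=bool)
    pos = off & (P > 0)
    if not pos.any():
        raise ValueError("contact map has no positive off-diagonal entries")
    D = np.zeros_like(P, dtype=float)
    D[pos] = (A / P[pos]) ** (2.0 / 3.0)
    if (off & ~pos).any():
        # impute missing entries from a coil profile matched to the
        # nearest-neighbor scale of the inverted entries
        idx = np.arange(n)
        sep = np.abs(idx[:, None] - idx[None, :])
        nn = pos & (sep == 1)
        scale = np.median(D[nn]) if nn.any() else np.median(D[pos])
        D[off & ~pos] = scale * sep[off & ~pos]
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    D = psd_project(D)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D=D, bin_size=bin_size)


# ------------------------------------------------------------------ integrators
def _snapshot_schedule(params: SCAParams) -> list[float]:
    if not params.snapshot_times:
        return []
    return sorted(t for t in params.snapshot_times if 0.0 < t <= params.t_max)


def _hessian_closure(seq, model):
    """Precompute per-run constants for the hot <J> assembly."""
    E = interaction_matrix(seq, model)
    u0, rhc = model.chain.hardcore_sca
    spring_k, r0 = model.chain.spring_k, model.r0

    def J_of(D: np.ndarray) -> np.ndarray:
        return _mean_hessian_fast(D, E, spring_k, r0, u0, rhc)

    return J_of


def _evolve_rk45(D0, seq, model, params) -> SCAResult:
    from scipy.integrate import RK45

    kT, xi = model.chain.kT, params.xi
    n = seq.n
    iu = np.triu_indices(n, k=1)
    J_of = _hessian_closure(seq, model)

    def unpack(y: np.ndarray) -> np.ndarray:
        D = np.zeros((n, n))
        D[iu] = y
        return D + D.T

    def fun(t: float, y: np.ndarray) -> np.ndarray:
        D = unpack(y)
        return _rhs_from_J(D, J_of(D), kT, xi)[iu]

    y0 = _as_D(D0)[iu].copy()
    solver = RK45(
        fun, 0.0, y0, t_bound=params.t_max, rtol=params.rtol, atol=params.atol
    )
    snapshots: list[tuple[float, np.ndarray]] = []
    pending = _snapshot_schedule(params)
    n_steps = 0
    residual = _scaled_residual(unpack(fun(0.0, y0)), kT, xi)
    converged = residual < params.steady_tol
    diverged = False
    best_residual, best_step = residual, 0
    while not converged and solver.status == "running":
        solver.step()
        n_steps += 1
        while pending and solver.t >= pending[0]:
            t_snap = pending.pop(0)
            snapshots.append((t_snap, unpack(solver.dense_output()(t_snap))))
        if solver.y.max() > params.max_D or not np.all(np.isfinite(solver.y)):
            diverged = True
            break
        residual = _scaled_residual(unpack(fun(solver.t, solver.y)), kT, xi)
        converged = residual < params.steady_tol
        if residual < 0.99 * best_residual:
            best_residual, best_step = residual, n_steps
        elif n_steps - best_step > params.stall_steps and not pending:
            break  # explicit method has hit its accuracy floor
        if n_steps >= params.max_steps:
            break
    D = unpack(solver.y)
    report = ConvergenceReport(
        converged=converged,
        t_end=float(solver.t),
        n_steps=n_steps,
        residual=residual,
        diverged=diverged,
        method="rk45",
    )
    dm = DistanceMatrix(D=D, bin_size=seq.bin_size, l=model.chain.l)
    return SCAResult(distances=dm, snapshots=snapshots, report=report)


def _exp_step(C, w, V, kT, xi, h):
    """Exact covariance propagation under frozen <J> = V diag(w) V^T:
    xi dC/dt = J C + C J + 2 kT H (H = centering projector)."""
    Ct = V.T @ C @ V
    mu = (w[:, None] + w[None, :]) / xi
    growth = np.exp(np.clip(mu * h, -700.0, 700.0))
    # noise is diagonal in any orthonormal basis of the centered subspace;
    # the translation mode (eigenvector ~ 1/sqrt(N), eigenvalue 0) carries
    # none, and C has no weight there because it is centered.
    noise = np.full(len(w), 2.0 * kT)
    ones = np.full(len(w), 1.0 / np.sqrt(len(w)))
    noise -= 2.0 * kT * (V.T @ ones) ** 2  # remove the translation mode
    mu_d = np.diag(mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        integ = np.where(
            np.abs(mu_d) > 1e-12, (np.diag(growth) - 1.0) / (mu_d * xi), h / xi
        )
    Ct = growth * Ct
    Ct[np.diag_indices_from(Ct)] += noise * integ
    C_new = V @ Ct @ V.T
    return 0.5 * (C_new + C_new.T)


def _evolve_exponential(D0, seq, model, params) -> SCAResult:
    kT, xi = model.chain.kT, params.xi
    C = gram_from_distances(_as_D(D0))
    t, h = 0.0, 1e-3
    n_steps = 0
    pending = _snapshot_schedule(params)
    snapshots: list[tuple[float, np.ndarray]] = []
    J_of = _hessian_closure(seq, model)
    D = distances_from_gram(C)
    J = J_of(D)
    residual = _scaled_residual(_rhs_from_J(D, J, kT, xi), kT, xi)
    converged = residual < params.steady_tol
    diverged = False
    scale_floor = model.chain.l**2 / 3.0
    # the eigendecomposition of <J> is refreshed lazily: between
    # refreshes the propagator uses a slightly stale basis, whose error
    # is caught by the residual-based step rejection below
    w, V = np.linalg.eigh(J)
    J_eig = J
    steps_since_refresh = 0
    resid_at_refresh = residual
    while not converged and t < params.t_max and n_steps < params.max_steps:
        h_try = min(h, params.t_max - t)
        if pending:
            h_try = min(h_try, pending[0] - t)
        drift = np.linalg.norm(J - J_eig) / max(np.linalg.norm(J_eig), 1e-300)
        # refresh on <J> drift, or when a stale basis stops making
        # progress (it would otherwise converge to the stale fixed point)
        if drift > params.eig_refresh or (
            J_eig is not J
            and steps_since_refresh >= 8
            and residual > 0.8 * resid_at_refresh
        ):
            w, V = np.linalg.eigh(J)
            J_eig = J
            steps_since_refresh = 0
            resid_at_refresh = residual
        C_new = _exp_step(C, w, V, kT, xi, h_try)
        D_new = distances_from_gram(C_new)
        change = float((np.abs(D_new - D) / (D + scale_floor)).max())
        if change > params.exp_step_change and h_try > 1e-8:
            h = h_try / 2.0
            continue
        if not np.all(np.isfinite(D_new)) or D_new.max() > params.max_D:
            if h_try > 1e-8:
                h = h_try / 2.0
                continue
            diverged = True
            break
        J_new = J_of(D_new)
        residual_new = _scaled_residual(_rhs_from_J(D_new, J_new, kT, xi), kT, xi)
        # reject steps that overshoot the frozen-<J> approximation
        # (undamped self-consistent iterations can flip-flop).  Genuine
        # residual growth — an instability transit, e.g. the fast
        # coil-to-MPS transition — stays within the exponential envelope
        # of the most unstable frozen mode and is not fought.
        envelope = 1.5 * float(
            np.exp(min(2.0 * max(w.max(), 0.0) * h_try / xi, 50.0))
        )
        if residual_new > envelope * residual and h_try > 1e-6:
            h = h_try / 2.0
            continue
        C, D, J, residual = C_new, D_new, J_new, residual_new
        steps_since_refresh += 1
        t += h_try
        n_steps += 1
        if pending and t >= pending[0] - 1e-12:
            snapshots.append((pending.pop(0), D.copy()))
        converged = residual < params.steady_tol
        if change < 0.25 * params.exp_step_change:
            h = min(h_try * 2.0, params.t_max)
        else:
            h = h_try
    report = ConvergenceReport(
        converged=converged,
        t_end=t,
        n_steps=n_steps,
        residual=residual,
        diverged=diverged,
        method="exponential",
    )
    np.fill_diagonal(D, 0.0)
    dm = DistanceMatrix(D=D, bin_size=seq.bin_size, l=model.chain.l)
    return SCAResult(distances=dm, snapshots=snapshots, report=report)


def evolve(
    D0,
    seq: EpigenomicSequence,
    model: InteractionModel,
    params: SCAParams | None = None,
    *,
    method: str = "rk45",
) -> SCAResult:
    """Integrate the self-consistent distance dynamics to stationarity.

    Returns the (approximately) stationary distance matrix, snapshots at
    ``params.snapshot_times``, and a convergence report.  With
    ``params.t_max == 0`` the initial condition is returned unchanged.
    """
    params = params or SCAParams()
    D0_arr = _as_D(D0)
    validate_distance_matrix(D0_arr)
    if params.t_max == 0.0:
        J = mean_hessian(D0_arr, seq, model)
        residual = _scaled_residual(
            _rhs_from_J(D0_arr, J, model.chain.kT, params.xi),
            model.chain.kT,
            params.xi,
        )
        dm = DistanceMatrix(D=D0_arr.copy(), bin_size=seq.bin_size, l=model.chain.l)
        report = ConvergenceReport(
            converged=residual < params.steady_tol,
            t_end=0.0,
            n_steps=0,
            residual=residual,
            method=method,
        )
        return SCAResult(distances=dm, snapshots=[], report=report)
    if method == "rk45":
        return _evolve_rk45(D0_arr, seq, model, params)
    if method == "exponential":
        return _evolve_exponential(D0_arr, seq, model, params)
    raise ValueError(f"unknown method {method!r}")


def polish_fixed_point(
    D,
    seq: EpigenomicSequence,
    model: InteractionModel,
    params: SCAParams | None = None,
    *,
    f_tol_scaled: float = 1e-6,
    max_rel_move: float = 2.0,
):
    """Newton-Krylov refinement of a near-stationary D to a true fixed
    point of the self-consistent dynamics.

    Intended as an endgame accelerator after :func:`evolve` has entered
    a fixed point's basin: the slow terminal drift of the dynamics
    (e.g. coil swelling) is replaced by a direct root solve of the
    stationarity condition.  Returns ``(DistanceMatrix, scaled
    residual)`` or ``None`` if the solve fails or moves further than
    ``max_rel_move`` (relative Frobenius) from the input — a guard
    against jumping into another basin.
    """
    from scipy.optimize import newton_krylov

    params = params or SCAParams()
    D0 = _as_D(D)
    n = D0.shape[0]
    kT, xi = model.chain.kT, params.xi
    iu = np.triu_indices(n, k=1)
    J_of = _hessian_closure(seq, model)

    def unpack(y: np.ndarray) -> np.ndarray:
        M = np.zeros((n, n))
        M[iu] = y
        return M + M.T

    def F(y: np.ndarray) -> np.ndarray:
        M = unpack(y)
        return _rhs_from_J(M, J_of(M), kT, xi)[iu]

    try:
        sol = newton_krylov(
            F, D0[iu], f_tol=f_tol_scaled * 4.0 * kT / xi, maxiter=60
        )
    except Exception:
        return None
    D_new = unpack(np.asarray(sol))
    rel = np.linalg.norm(D_new - D0) / max(np.linalg.norm(D0), 1e-300)
    if rel > max_rel_move or not np.all(np.isfinite(D_new)):
        return None
    residual = _scaled_residual(_rhs_from_J(D_new, J_of(D_new), kT, xi), kT, xi)
    dm = DistanceMatrix(D=D_new, bin_size=seq.bin_size, l=model.chain.l)
    return dm, residual


@dataclass
class FixedPoints:
    """Distinct stationary solutions found from a set of initial conditions."""

    representatives: list[DistanceMatrix]
    members: list[list[int]]  # indices into the init set, per cluster
    reports: list[ConvergenceReport]
    unconverged: list[int] = field(default_factory=list)

    @property
    def multiplicity(self) -> int:
        return len(self.representatives)


def find_fixed_points(
    seq: EpigenomicSequence,
    model: InteractionModel,
    params: SCAParams | None = None,
    init_set: list | None = None,
    *,
    method: str = "rk45",
    distinct_tol: float = 1e-2,
    polish: bool = False,
) -> FixedPoints:
    """Evolve from several initial conditions and cluster the stationary
    solutions by relative Frobenius distance (> ``distinct_tol`` means
    distinct).  Default init set: {coil, globule, MPS}.

    With ``polish=True``, each evolved endpoint is refined by
    :func:`polish_fixed_point`; this lets the integration stop at a
    loose ``steady_tol`` (basin selection) while the root solve supplies
    the exact fixed point.
    """
    params = params or SCAParams()
    if init_set is None:
        init_set = [
            init_coil(seq, model),
            init_globule(seq, model, plateau=model.chain.l**2),
            init_mps(
                seq, model, intra=model.chain.l**2 / 3.0, inter=3.0 * seq.n**0.5
            ),
        ]
    if not init_set:
        raise ValueError("need at least one initial condition")
    results = [evolve(D0, seq, model, params, method=method) for D0 in init_set]
    if polish:
        for res in results:
            out = polish_fixed_point(res.distances, seq, model, params)
            # glassy transits may not be polishable yet: integrate
            # further into the basin and retry
            rounds = 0
            while out is None and rounds < 2 and not res.report.diverged:
                cont = evolve(res.distances, seq, model, params, method=method)
                res.distances = cont.distances
                res.report.t_end += cont.report.t_end
                res.report.n_steps += cont.report.n_steps
                res.report.residual = cont.report.residual
                res.report.converged = cont.report.converged
                out = polish_fixed_point(res.distances, seq, model, params)
                rounds += 1
            if out is not None:
                res.distances, res.report.residual = out
                res.report.converged = True
    reps: list[DistanceMatrix] = []
    members: list[list[int]] = []
    reports: list[ConvergenceReport] = []
    unconverged: list[int] = []
    for i, res in enumerate(results):
        if not res.report.converged:
            unconverged.append(i)
            continue
        D = res.distances.D
        for c, rep in enumerate(reps):
            dist = np.linalg.norm(D - rep.D) / max(np.linalg.norm(rep.D), 1e-300)
            if dist <= distinct_tol:
                members[c].append(i)
                break
        else:
            reps.append(res.distances)
            members.append([i])
            reports.append(res.report)
    return FixedPoints(
        representatives=reps, members=members, reports=reports, unconverged=unconverged
    )
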