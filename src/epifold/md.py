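"""Bead-spring molecular dynamics of the copolymer.

Velocity-Verlet integration with an Andersen thermostat (stochastic
velocity resampling from the Maxwell-Boltzmann distribution at a set
collision frequency).  Forces derive from the same Hamiltonian as
:func:`epifold.energy.total_energy`: harmonic springs, Gaussian pair
attractions and the repulsive WCA excluded volume.  Reduced units
l = mass = kT = 1; the time unit is tau = l sqrt(mass/kT).

The inner loops are numba-compiled; trajectories are bitwise
reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit

from .energy import InteractionModel, interaction_matrix
from .sequences import EpigenomicSequence

__all__ = [
    "Trajectory",
    "simulate",
    "contact_map_from_trajectory",
    "rmsd_same_type",
    "domain_com_distance",
    "sample_pair_statistics",
    "end_to_end_decorrelation_time",
    "export_xyz",
]


@dataclass
class Trajectory:
    """Sampled MD trajectory (times in tau)."""

    times: np.ndarray  # (T,)
    positions: np.ndarray  # (T, N, 3)
    velocities: np.ndarray  # (T, N, 3)
    seed: int
    thermostat_nu: float
    dt: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n(self) -> int:
        return self.positions.shape[1]


@njit(cache=True)
def _forces(X, E, r0, spring_k, sigma, eps, pair_on, F):
    N = X.shape[0]
    F[:] = 0.0
    pe = 0.0
    for n in range(1, N):
        for d in range(3):
            dx = X[n, d] - X[n - 1, d]
            F[n, d] -= spring_k * dx
            F[n - 1, d] += spring_k * dx
            pe += 0.5 * spring_k * dx * dx
    if pair_on:
        rc2 = 2.0 ** (1.0 / 3.0) * sigma * sigma
        inv2r02 = 1.0 / (2.0 * r0 * r0)
        for n in range(N - 1):
            for m in range(n + 1, N):
                dx = X[m, 0] - X[n, 0]
                dy = X[m, 1] - X[n, 1]
                dz = X[m, 2] - X[n, 2]
                r2 = dx * dx + dy * dy + dz * dz
                coeff = 0.0
                e_nm = E[n, m]
                if e_nm != 0.0:
                    g = e_nm * np.exp(-r2 * inv2r02)
                    pe += g
                    coeff += g / (r0 * r0)
                if eps > 0.0 and r2 < rc2:
                    s6 = (sigma * sigma / r2) ** 3
                    pe += 4.0 * eps * (s6 * s6 - s6) + eps
                    coeff += 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
                if coeff != 0.0:
                    F[m, 0] += coeff * dx
                    F[m, 1] += coeff * dy
                    F[m, 2] += coeff * dz
                    F[n, 0] -= coeff * dx
                    F[n, 1] -= coeff * dy
                    F[n, 2] -= coeff * dz
    return pe


@njit(cache=True)
def _run(
    X,
    V,
    n_steps,
    dt,
    nu,
    kT,
    mass,
    E,
    r0,
    spring_k,
    sigma,
    eps,
    pair_on,
    sample_every,
    seed,
    t0,
):
    np.random.seed(seed)
    N = X.shape[0]
    F = np.zeros((N, 3))
    _forces(X, E, r0, spring_k, sigma, eps, pair_on, F)
    n_samples = n_steps // sample_every
    t_out = np.empty(n_samples)
    pos_out = np.empty((n_samples, N, 3))
    vel_out = np.empty((n_samples, N, 3))
    half = 0.5 * dt / mass
    sigma_v = np.sqrt(kT / mass)
    p_coll = nu * dt
    k = 0
    for step in range(1, n_steps + 1):
        for n in range(N):
            for d in range(3):
                V[n, d] += half * F[n, d]
                X[n, d] += dt * V[n, d]
        _forces(X, E, r0, spring_k, sigma, eps, pair_on, F)
        for n in range(N):
            for d in range(3):
                V[n, d] += half * F[n, d]
        if p_coll > 0.0:
            for n in range(N):
                if np.random.random() < p_coll:
                    for d in range(3):
                        V[n, d] = sigma_v * np.random.standard_normal()
        if step % sample_every == 0:
            t_out[k] = t0 + step * dt
            pos_out[k] = X
            vel_out[k] = V
            k += 1
    return t_out, pos_out, vel_out


def _saw_initial_positions(
    n: int, l: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Self-avoiding random walk with bond length l: random directions,
    rejecting steps closer than 0.9 sigma to any previous bead (bounded
    retries, so dense chains still terminate)."""
    X = np.zeros((n, 3))
    min2 = (0.9 * sigma) ** 2
    for i in range(1, n):
        for _ in range(200):
            v = rng.normal(size=3)
            cand = X[i - 1] + l * v / np.linalg.norm(v)
            d2 = ((X[: max(i - 1, 1)] - cand) ** 2).sum(axis=1)
            if d2.min() > min2 or _ == 199:
                X[i] = cand
                break
        else:  # pragma: no cover
            X[i] = cand
    return X


def _model_arrays(seq: EpigenomicSequence, model: InteractionModel):
    E = interaction_matrix(seq, model)
    cp = model.chain
    _, sigma, eps = cp.hardcore_md
    pair_on = bool(np.any(E != 0.0) or eps > 0.0)
    return E, sigma, eps, pair_on


def simulate(
    seq: EpigenomicSequence,
    model: InteractionModel,
    n_steps: int,
    dt: float = 0.005,
    thermostat_nu: float = 1.0,
    seed: int = 0,
    sample_every: int = 100,
    *,
    mass: float = 1.0,
    initial_positions: np.ndarray | None = None,
    initial_velocities: np.ndarray | None = None,
) -> Trajectory:
    """Run velocity-Verlet MD with an Andersen thermostat.

    The initial configuration is a self-avoiding random walk with bond
    length l (unless given); initial velocities are Maxwell-Boltzmann.
    ``thermostat_nu`` is the per-particle collision frequency (0 gives a
    microcanonical NVE run).  Reproducible for a fixed ``seed``.
    """
    if dt <= 0 or n_steps < 1:
        raise ValueError("require dt > 0 and n_steps >= 1")
    cp = model.chain
    E, sigma, eps, pair_on = _model_arrays(seq, model)
    rng = np.random.default_rng(seed)
    X = (
        np.array(initial_positions, dtype=float)
        if initial_positions is not None
        else _saw_initial_positions(seq.n, cp.l, sigma, rng)
    )
    V = (
        np.array(initial_velocities, dtype=float)
        if initial_velocities is not None
        else rng.normal(0.0, np.sqrt(cp.kT / mass), size=(seq.n, 3))
    )
    if initial_velocities is None:
        V -= V.mean(axis=0)  # zero total momentum
    times, pos, vel = _run(
        X,
        V,
        n_steps,
        dt,
        thermostat_nu,
        cp.kT,
        mass,
        E,
        model.r0,
        cp.spring_k,
        sigma,
        eps,
        pair_on,
        sample_every,
        int(seed) % 2**31,
        0.0,
    )
    if not np.all(np.isfinite(pos)):
        raise FloatingPointError(
            "force overflow during integration; reduce dt or soften overlaps"
        )
    return Trajectory(
        times=times,
        positions=pos,
        velocities=vel,
        seed=seed,
        thermostat_nu=thermostat_nu,
        dt=dt,
    )


def end_to_end_decorrelation_time(traj: Trajectory) -> float:
    """Time for the end-to-end vector autocorrelation to decay below 1/e.

    Used as the default equilibration burn-in.
    """
    r = traj.positions[:, -1, :] - traj.positions[:, 0, :]
    r = r - r.mean(axis=0)
    nf = len(r)
    c0 = float((r * r).sum(axis=1).mean())
    if c0 == 0:
        return 0.0
    for lag in range(1, nf):
        c = float((r[:-lag] * r[lag:]).sum(axis=1).mean())
        if c < c0 / np.e:
            return float(traj.times[lag] - traj.times[0])
    return float(traj.times[-1] - traj.times[0])


def _frames_after(traj: Trajectory, burn_in) -> np.ndarray:
    if burn_in == "auto":
        burn_in = end_to_end_decorrelation_time(traj)
    b = float(burn_in)
    frames = traj.positions[traj.times > b] if b > 0 else traj.positions
    if frames.shape[0] == 0:
        raise ValueError("no frames after burn-in")
    return frames


def contact_map_from_trajectory(traj: Trajectory, cutoff: float = 1.5, burn_in=0.0):
    """Time-averaged contact map: P_mn = fraction of post-burn-in frames
    with r_mn < cutoff (diagonal set to 1)."""
    from .contacts import ContactMap

    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frames = _frames_after(traj, burn_in)
    n = frames.shape[1]
    P = np.zeros((n, n))
    cut2 = cutoff * cutoff
    for X in frames:
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        P += d2 < cut2
    P /= len(frames)
    np.fill_diagonal(P, 1.0)
    return ContactMap(P=P, A=None, bin_size=None)


def rmsd_same_type(
    traj: Trajectory,
    seq: EpigenomicSequence,
    type_label: str,
    window: int | None = None,
) -> np.ndarray:
    """Per-frame root mean squared pairwise distance between all monomers
    of one chromatin type (optionally sliding-window smoothed)."""
    idx = seq.type_indices(type_label)
    if idx.size < 2:
        raise ValueError(f"fewer than 2 monomers of type {type_label!r}")
    sub = traj.positions[:, idx, :]
    iu, ju = np.triu_indices(idx.size, k=1)
    d2 = ((sub[:, iu, :] - sub[:, ju, :]) ** 2).sum(axis=2)
    series = np.sqrt(d2.mean(axis=1))
    if window is not None and window > 1:
        kernel = np.full(window, 1.0 / window)
        series = np.convolve(series, kernel, mode="valid")
    return series


def domain_com_distance(
    traj: Trajectory,
    seq: EpigenomicSequence,
    domain_a: tuple[int, int],
    domain_b: tuple[int, int],
) -> np.ndarray:
    """Per-frame distance between the centers of mass of two disjoint
    monomer index ranges [start, stop)."""
    a = np.arange(*domain_a)
    b = np.arange(*domain_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("domains must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("domains must be disjoint")
    com_a = traj.positions[:, a, :].mean(axis=1)
    com_b = traj.positions[:, b, :].mean(axis=1)
    return np.linalg.norm(com_a - com_b, axis=1)


def sample_pair_statistics(
    seq: EpigenomicSequence,
    model: InteractionModel,
    n_steps: int,
    dt: float = 0.01,
    thermostat_nu: float = 0.1,
    seed: int = 0,
    sample_every: int = 100,
    burn_in_steps: int = 0,
    cutoff: float = 0.5,
    *,
    mass: float = 1.0,
    chunk_frames: int = 2000,
):
    """Long-run equilibrium pair statistics without storing the trajectory.

    Runs the MD in chunks, accumulating the mean squared distance matrix
    ``<r_mn^2>`` and the contact frequency at ``cutoff`` over all sampled
    frames after ``burn_in_steps``.  Returns ``(msd, contact_freq,
    n_frames)``.
    """
    cp = model.chain
    E, sigma, eps, pair_on = _model_arrays(seq, model)
    rng = np.random.default_rng(seed)
    X = _saw_initial_positions(seq.n, cp.l, sigma, rng)
    V = rng.normal(0.0, np.sqrt(cp.kT / mass), size=(seq.n, 3))
    V -= V.mean(axis=0)
    n = seq.n
    msd = np.zeros((n, n))
    freq = np.zeros((n, n))
    n_frames = 0
    cut2 = cutoff * cutoff
    done = 0
    chunk = chunk_frames * sample_every
    base_seed = int(seed) % 2**31
    t0 = 0.0
    k = 0
    while done < n_steps:
        this = min(chunk, n_steps - done)
        _, pos, _ = _run(
            X,
            V,
            this,
            dt,
            thermostat_nu,
            cp.kT,
            mass,
            E,
            model.r0,
            cp.spring_k,
            sigma,
            eps,
            pair_on,
            sample_every,
            (base_seed + 9973 * k) % 2**31,
            t0,
        )
        if not np.all(np.isfinite(X)):
            raise FloatingPointError("force overflow; reduce dt")
        for frame_i in range(pos.shape[0]):
            step_of_frame = done + (frame_i + 1) * sample_every
            if step_of_frame <= burn_in_steps:
                continue
            Xf = pos[frame_i]
            d2 = ((Xf[:, None, :] - Xf[None, :, :]) ** 2).sum(axis=2)
            msd += d2
            freq += d2 < cut2
            n_frames += 1
        done += this
        t0 += this * dt
        k += 1
    if n_frames == 0:
        raise ValueError("no frames after burn-in")
    return msd / n_frames, freq / n_frames, n_frames


def export_xyz(
    traj: Trajectory,
    seq: EpigenomicSequence,
    path: str | Path,
    model: InteractionModel | None = None,
) -> None:
    """XYZ export (element column = chromatin-state label) with a JSON
    metadata sidecar recording dt, seed, thermostat and model parameters."""
    path = Path(path)
    with open(path, "w") as fh:
        for t, X in zip(traj.times, traj.positions):
            fh.write(f"{seq.n}\n")
            fh.write(f"t={t}\n")
            for label, (x, y, z) in zip(seq.states, X):
                fh.write(f"{label} {x:.6f} {y:.6f} {z:.6f}\n")
    meta = {
        "dt": traj.dt,
        "seed": traj.seed,
        "thermostat_nu": traj.thermostat_nu,
        "n_frames": traj.n_frames,
        "n_monomers": seq.n,
    }
    if model is not None:
        meta.update(
            {
                "U_ns": model.U_ns,
                "r0": model.r0,
                "l": model.chain.l,
                "kT": model.chain.kT,
            }
        )
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))
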