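"""Contact maps: the Gaussian contact formula, comparisons and I/O.

Under the Gaussian chain ansatz the contact probability between two
monomers follows from the return probability of their separation
vector: ``P_mn ~ A D_mn^{-3/2}`` with A a constant numerical factor.
Comparisons between maps are rank-based by default (Spearman on
log-transformed entries), because experimental maps come in arbitrary
units and normalization states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContactMap",
    "ComparisonReport",
    "contact_probability",
    "compare_maps",
    "read_map",
    "write_map",
]


@dataclass
class ContactMap:
    """Symmetric matrix of contact probabilities / frequencies."""

    P: np.ndarray
    A: float | None = None
    bin_size: int | None = None
    anchor: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError("P must be square")
        if not np.allclose(self.P, self.P.T, atol=1e-10 * (1 + np.abs(self.P).max())):
            raise ValueError("P must be symmetric")
        if self.P.min() < 0:
            raise ValueError("P entries must be non-negative")

    @property
    def n(self) -> int:
        return self.P.shape[0]


def contact_probability(D, A_mode="normalize-nearest-neighbor") -> ContactMap:
    """Contact map from a distance matrix via P_mn = A D_mn^{-3/2}.

    ``A_mode`` is either a fixed numeric A or the string
    ``"normalize-nearest-neighbor"`` (A chosen so the mean
    nearest-neighbor P equals 1, then P clipped to <= 1).  The diagonal
    is set to the maximum off-diagonal value.
    """
    from .sca import DistanceMatrix

    bin_size = None
    anchor = None
    if isinstance(D, DistanceMatrix):
        bin_size = D.bin_size
        D = D.D
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.any(D[off] <= 0):
        raise ValueError("off-diagonal D entries must be positive")
    raw = D[off] ** -1.5
    if isinstance(A_mode, str):
        if A_mode != "normalize-nearest-neighbor":
            raise ValueError(f"unknown A_mode {A_mode!r}")
        idx = np.arange(n)
        nn = np.abs(idx[:, None] - idx[None, :]) == 1
        A = 1.0 / float((D[nn] ** -1.5).mean())
        clip = True
    else:
        A = float(A_mode)
        clip = False
    P = np.zeros_like(D)
    P[off] = A * raw
    if clip:
        P = np.minimum(P, 1.0)
    np.fill_diagonal(P, P[off].max() if n > 1 else 1.0)
    return ContactMap(P=P, A=A, bin_size=bin_size, anchor=anchor)


@dataclass
class ComparisonReport:
    spearman: float
    pearson_log: float
    n_pairs: int
    per_stratum: pd.DataFrame = field(repr=False, default=None)


def _log_with_pseudocount(x: np.ndarray) -> np.ndarray:
    pos = x[x > 0]
    pseudo = pos.min() if pos.size else 1.0
    return np.log(x + np.where(x > 0, 0.0, pseudo))


def compare_maps(
    P_model: ContactMap | np.ndarray,
    P_ref: ContactMap | np.ndarray,
    min_separation: int = 1,
    *,
    strata: tuple[tuple[int, int], ...] | None = None,
) -> ComparisonReport:
    """Rank and log-linear agreement between two maps.

    Spearman and Pearson correlations of log entries with
    ``|m - n| >= min_separation``, over entries positive in both maps;
    plus per-separation-stratum correlations.
    """
    A = P_model.P if isinstance(P_model, ContactMap) else np.asarray(P_model, float)
    B = P_ref.P if isinstance(P_ref, ContactMap) else np.asarray(P_ref, float)
    if A.shape != B.shape:
        raise ValueError("contact maps must have the same shape")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    n = A.shape[0]
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    base = (sep >= min_separation) & (A > 0) & (B > 0) & (idx[:, None] < idx[None, :])
    if base.sum() < 2:
        raise ValueError("fewer than 2 comparable entries")
    la, lb = np.log(A[base]), np.log(B[base])
    rho = float(stats.spearmanr(la, lb).statistic)
    r = float(stats.pearsonr(la, lb).statistic) if la.std() > 0 and lb.std() > 0 else np.nan
    if strata is None:
        edges = np.unique(
            np.geomspace(min_separation, max(n - 1, min_separation + 1), 5).astype(int)
        )
        strata = tuple(zip(edges[:-1], edges[1:]))
    rows = []
    for lo, hi in strata:
        m = base & (sep >= lo) & (sep < hi)
        if m.sum() >= 3 and np.log(A[m]).std() > 0 and np.log(B[m]).std() > 0:
            rows.append(
                (lo, hi, float(stats.spearmanr(np.log(A[m]), np.log(B[m])).statistic))
            )
        else:
            rows.append((lo, hi, np.nan))
    per_stratum = pd.DataFrame(rows, columns=["sep_min", "sep_max", "spearman"])
    return ComparisonReport(
        spearman=rho, pearson_log=r, n_pairs=int(base.sum()), per_stratum=per_stratum
    )


def write_map(cmap: ContactMap, path: str | Path, format: str = "dense") -> None:
    """Write a contact map as dense text (with header) or as 0-based
    (i, j, count) pair triples (upper triangle incl. diagonal)."""
    path = Path(path)
    if format == "dense":
        anchor = f"{cmap.anchor[0]}:{cmap.anchor[1]}" if cmap.anchor else "-"
        header = f"N={cmap.n} bin_size={cmap.bin_size or 0} anchor={anchor}"
        np.savetxt(path, cmap.P, header=header)
    elif format == "pairs":
        iu, ju = np.triu_indices(cmap.n)
        vals = cmap.P[iu, ju]
        keep = vals != 0
        np.savetxt(
            path,
            np.column_stack([iu[keep], ju[keep], vals[keep]]),
            fmt=["%d", "%d", "%.10g"],
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_map(path: str | Path, format: str = "dense") -> ContactMap:
    """Read a contact map; pairs input is symmetrized (both triangles
    filled)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty contact map file: {path}")
    if format == "dense":
        with open(path) as fh:
            first = fh.readline()
        bin_size = None
        anchor = None
        if first.startswith("#"):
            meta = dict(kv.split("=") for kv in first.lstrip("#").split())
            bin_size = int(meta.get("bin_size", 0)) or None
            if meta.get("anchor", "-") != "-":
                chrom, start = meta["anchor"].rsplit(":", 1)
                anchor = (chrom, int(start))
        P = np.loadtxt(path, ndmin=2)
        if P.shape[0] != P.shape[1]:
            raise ValueError("dense map is not square (ragged rows?)")
        return ContactMap(P=P, A=None, bin_size=bin_size, anchor=anchor)
    if format == "pairs":
        data = np.loadtxt(path, ndmin=2)
        if data.shape[1] != 3:
            raise ValueError("pairs map must have 3 columns (i, j, count)")
        if data[:, 2].min() < 0:
            raise ValueError("negative counts in pairs map")
        i = data[:, 0].astype(int)
        j = data[:, 1].astype(int)
        n = int(max(i.max(), j.max())) + 1
        P = np.zeros((n, n))
        P[i, j] = data[:, 2]
        P[j, i] = data[:, 2]
        return ContactMap(P=P, A=None)
    raise ValueError(f"unknown format {format!r}")
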