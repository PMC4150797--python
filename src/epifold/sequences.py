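"""Primary sequences of the copolymer: chromatin-state labels per monomer.

The 1D epigenome — a segmentation of the genome into chromatin-state
domains — defines the block structure of the copolymer.  Each monomer
covers ``bin_size`` bp (10 kb by default) and carries one categorical
state label.  Sequences are built either from BED4 segmentations
(majority-rule binning) or from synthetic block patterns such as
``(A10B10)x6``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_ALPHABET: tuple[str, ...] = ("active", "HP1", "Polycomb", "black")

#: default mapping collapsing the two Filion et al. euchromatic states
#: ("YELLOW" and "RED" in the original five-color nomenclature) into a
#: single active type; keys are matched case-insensitively.
DEFAULT_MERGE_MAP: dict[str, str] = {
    "yellow": "active",
    "red": "active",
    "green": "HP1",
    "blue": "Polycomb",
}


@dataclass
class EpigenomicSequence:
    """Per-monomer chromatin-state labels at a fixed genomic bin size.

    Parameters
    ----------
    states
        One label per monomer, each a member of ``alphabet``.
    alphabet
        Ordered set of allowed state labels.
    bin_size
        Genomic span per monomer, bp.
    anchor
        Optional ``(chromosome, start_bp)`` genomic anchor (0-based).
    """

    states: np.ndarray
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    bin_size: int = 10_000
    anchor: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=object)
        self.alphabet = tuple(self.alphabet)
        if self.states.ndim != 1 or self.states.size < 1:
            raise ValueError("states must be a non-empty 1-D sequence")
        unknown = set(self.states) - set(self.alphabet)
        if unknown:
            raise ValueError(f"state labels not in alphabet: {sorted(unknown)}")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.anchor is not None:
            chrom, start = self.anchor
            if start < 0:
                raise ValueError("anchor start must be >= 0")
            self.anchor = (str(chrom), int(start))

    @property
    def n(self) -> int:
        """Number of monomers N."""
        return self.states.size

    @property
    def codes(self) -> np.ndarray:
        """Integer state codes (index into ``alphabet``), shape (N,)."""
        lookup = {label: i for i, label in enumerate(self.alphabet)}
        return np.array([lookup[s] for s in self.states], dtype=np.int64)

    def type_indices(self, label: str) -> np.ndarray:
        """Monomer indices carrying ``label``."""
        return np.flatnonzero(self.states == label)

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpigenomicSequence):
            return NotImplemented
        return (
            list(self.states) == list(other.states)
            and self.alphabet == other.alphabet
            and self.bin_size == other.bin_size
            and self.anchor == other.anchor
        )

    # ------------------------------------------------------------------ I/O
    def to_bed(self, path: str | Path) -> None:
        """Write as BED4 (chrom, start, end, state), 0-based half-open.

        Consecutive monomers with the same state are merged into one
        interval.  Without an anchor, coordinates start at 0 on a
        placeholder chromosome ``chr``.
        """
        chrom, start0 = self.anchor if self.anchor is not None else ("chr", 0)
        rows = []
        run_start = 0
        for i in range(1, self.n + 1):
            if i == self.n or self.states[i] != self.states[run_start]:
                rows.append(
                    (
                        chrom,
                        start0 + run_start * self.bin_size,
                        start0 + i * self.bin_size,
                        self.states[run_start],
                    )
                )
                run_start = i
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    def to_labels(self, path: str | Path) -> None:
        """Write the sequence as a one-label-per-line text list."""
        Path(path).write_text("\n".join(map(str, self.states)) + "\n")


def _read_bed4(bed_source) -> pd.DataFrame:
    """Read BED4 records from a path, file-like object, or iterable of
    (chrom, start, end, state) tuples."""
    if isinstance(bed_source, pd.DataFrame):
        df = bed_source.iloc[:, :4].copy()
    elif isinstance(bed_source, (str, Path, io.IOBase)):
        df = pd.read_csv(
            bed_source, sep="\t", header=None, usecols=[0, 1, 2, 3], comment="#"
        )
    else:
        df = pd.DataFrame(list(bed_source)).iloc[:, :4]
    df.columns = ["chrom", "start", "end", "state"]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["state"] = df["state"].astype(str)
    return df


def load_segmentation(
    bed_source,
    region: tuple[str, int, int],
    bin_size: int = 10_000,
    *,
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET,
    merge_map: dict[str, str] | None = None,
    default_label: str = "black",
) -> EpigenomicSequence:
    """Coarse-grain a BED-like segmentation to one state per bin.

    The region ``[start, end)`` is tiled with ``ceil((end-start)/bin_size)``
    bins (a partial last bin is allowed).  Each bin takes the label with
    the largest overlap within the bin, ties broken in favor of the label
    appearing first (leftmost) in the bin.  ``merge_map`` renames labels
    before binning (the default merges the two Filion active states into
    one); uncovered bins get ``default_label``, black chromatin being the
    prevalent repressive type.

    Raises
    ------
    ValueError
        If no interval overlaps the region or an unmapped label occurs.
    """
    chrom, start, end = region
    if end <= start:
        raise ValueError("region end must exceed start")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if merge_map is None:
        merge_map = DEFAULT_MERGE_MAP
    merge_lower = {str(k).lower(): v for k, v in merge_map.items()}
    exact_lower = {label.lower(): label for label in alphabet}

    df = _read_bed4(bed_source)
    df = df[(df["chrom"] == chrom) & (df["end"] > start) & (df["start"] < end)]
    if df.empty:
        raise ValueError("no segmentation in region")

    def canonical(label: str) -> str:
        key = label.lower()
        if key in merge_lower:
            label = merge_lower[key]
            key = label.lower()
        if key not in exact_lower:
            raise ValueError(
                f"unknown state label {label!r}: not in merge map or alphabet"
            )
        return exact_lower[key]

    df = df.assign(state=df["state"].map(canonical)).sort_values(
        ["start", "end"], kind="stable"
    )

    n_bins = -(-(end - start) // bin_size)
    states: list[str] = []
    starts = np.asarray(df["start"])
    ends = np.asarray(df["end"])
    labels = list(df["state"])
    for b in range(n_bins):
        lo = start + b * bin_size
        hi = min(lo + bin_size, end)
        overlap: dict[str, int] = {}
        first_pos: dict[str, int] = {}
        for s, e, lab in zip(starts, ends, labels):
            o = min(e, hi) - max(s, lo)
            if o > 0:
                overlap[lab] = overlap.get(lab, 0) + o
                pos = max(s, lo)
                if lab not in first_pos or pos < first_pos[lab]:
                    first_pos[lab] = pos
        if not overlap:
            states.append(default_label)
        else:
            # majority by overlap; ties -> label appearing first in the bin
            best = max(overlap.values())
            tied = [lab for lab, o in overlap.items() if o == best]
            states.append(min(tied, key=lambda lab: first_pos[lab]))
    return EpigenomicSequence(
        states=np.array(states, dtype=object),
        alphabet=alphabet,
        bin_size=bin_size,
        anchor=(chrom, start),
    )


def make_block_sequence(
    pattern: list[tuple[str, int]],
    repeats: int = 1,
    *,
    alphabet: tuple[str, ...] | None = None,
    bin_size: int = 10_000,
) -> EpigenomicSequence:
    """Build a block copolymer sequence from (label, block_length) pairs.

    ``pattern=[("A", 10), ("B", 10)], repeats=6`` gives the 120-monomer
    toy copolymer (A10B10)6 with alternating 10-monomer blocks.
    """
    if not pattern:
        raise ValueError("pattern must not be empty")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    for label, length in pattern:
        if length < 1:
            raise ValueError("block lengths must be >= 1")
    states: list[str] = []
    for _ in range(repeats):
        for label, length in pattern:
            states.extend([label] * length)
    if alphabet is None:
        seen: list[str] = []
        for label, _ in pattern:
            if label not in seen:
                seen.append(label)
        alphabet = tuple(seen)
    return EpigenomicSequence(
        states=np.array(states, dtype=object), alphabet=alphabet, bin_size=bin_size
    )


_PATTERN_RE = re.compile(r"^\(((?:[A-Za-z_]+\d+)+)\)x(\d+)$")
_BLOCK_RE = re.compile(r"([A-Za-z_]+?)(\d+)")


def parse_pattern(text: str) -> tuple[list[tuple[str, int]], int]:
    """Parse a pattern string like ``"(A10B10)x6"``.

    Returns the (label, length) list and the repeat count.
    """
    m = _PATTERN_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed block pattern: {text!r} (expected '(A10B10)x6')")
    body, repeats = m.group(1), int(m.group(2))
    blocks = [(lab, int(n)) for lab, n in _BLOCK_RE.findall(body)]
    consumed = "".join(f"{lab}{n}" for lab, n in blocks)
    if consumed != body or not blocks:
        raise ValueError(f"malformed block pattern: {text!r}")
    return blocks, repeats


def random_block_sequence(
    n_blocks: int,
    block_length_range: tuple[int, int],
    alphabet: tuple[str, ...],
    seed: int,
    *,
    bin_size: int = 10_000,
) -> EpigenomicSequence:
    """Random block sequence with distinct adjacent block labels.

    Reproducible for a fixed ``seed``.  Used as a fixture generator for
    property tests and for sequence-complexity scans.
    """
    lo, hi = block_length_range
    if lo < 1 or hi < lo:
        raise ValueError("block_length_range must satisfy 1 <= min <= max")
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    if len(alphabet) == 1 and n_blocks > 1:
        raise ValueError("cannot make adjacent blocks distinct with one label")
    rng = np.random.default_rng(seed)
    states: list[str] = []
    prev: str | None = None
    for _ in range(n_blocks):
        choices = [a for a in alphabet if a != prev]
        label = choices[rng.integers(len(choices))]
        length = int(rng.integers(lo, hi + 1))
        states.extend([label] * length)
        prev = label
    return EpigenomicSequence(
        states=np.array(states, dtype=object),
        alphabet=tuple(alphabet),
        bin_size=bin_size,
    )


def same_state_indicator(seq: EpigenomicSequence) -> np.ndarray:
    """Binary matrix delta with delta[m, n] = 1 iff monomers m and n share
    their chromatin state (delta[m, m] = 1)."""
    codes = seq.codes
    return (codes[:, None] == codes[None, :]).astype(np.int8)
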