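"""Exhaustive core-sequence spaces and the K-mer graph grid layout.

The assay interrogates every length-``n`` DNA word simultaneously, so the
basic container is the complete, lexicographically ordered space of all
``4**n`` sequences over {A, C, G, T}.  The K-mer graph places each length-k
word in a unique cell of a ``2**k x 2**k`` grid by a recursive quadrant
rule (each base chooses one quadrant of the current block, most significant
base first), so that words sharing a prefix occupy one contiguous square
block -- the x-y plane used by every landscape plot.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_SET = frozenset(BASES)
_RC_TABLE = str.maketrans("ACGT", "TGCA")

#: default base -> (row-bit, col-bit) quadrant assignment
DEFAULT_QUADRANTS: dict[str, tuple[int, int]] = {
    "A": (0, 0),
    "C": (0, 1),
    "G": (1, 0),
    "T": (1, 1),
}

MAX_N = 12  # 4**12 = 16.7M sequences; beyond this the exhaustive model is unusable


def _check_dna(s: str, what: str = "sequence") -> None:
    if not s or not _BASE_SET.issuperset(s):
        raise ValueError(f"{what} must be a nonempty uppercase A/C/G/T string, got {s!r}")


def reverse_complement(s: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T string (involutive)."""
    _check_dna(s)
    return s.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class LibraryDesign:
    """The randomized-library construct: fixed flanks bracketing ``n`` random bases.

    Parameters
    ----------
    left_flank, right_flank
        Fixed sequences 5' and 3' of the randomized region, uppercase A/C/G/T.
    n
        Number of randomized central bases.  The assay was designed for
        4 <= n <= 7; other positive values are allowed with a warning.
    """

    left_flank: str
    right_flank: str
    n: int

    def __post_init__(self) -> None:
        _check_dna(self.left_flank, "left_flank")
        _check_dna(self.right_flank, "right_flank")
        if not isinstance(self.n, int) or self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n!r}")
        if self.n > MAX_N:
            raise ValueError(f"n={self.n} implies a 4**{self.n} space; maximum supported is {MAX_N}")
        if not 4 <= self.n <= 7:
            warnings.warn(f"n={self.n} is outside the 4..7 range the assay was designed for")
        if self.left_flank in self.right_flank or self.right_flank in self.left_flank:
            raise ValueError("left_flank and right_flank must not contain each other")

    @property
    def space_size(self) -> int:
        return 4 ** self.n

    def construct(self, core: str) -> str:
        """Full read-1 sequence of the construct carrying ``core``."""
        if len(core) != self.n:
            raise ValueError(f"core length {len(core)} != design n={self.n}")
        return self.left_flank + core + self.right_flank

    def mirrored(self) -> "LibraryDesign":
        """The design as seen from read 2 (reverse-complement orientation)."""
        return LibraryDesign(
            left_flank=reverse_complement(self.right_flank),
            right_flank=reverse_complement(self.left_flank),
            n=self.n,
        )


@dataclass(frozen=True)
class SequenceSpace:
    """All ``4**n`` length-``n`` sequences, lexicographic (A < C < G < T)."""

    n: int
    sequences: tuple[str, ...]
    _index: dict[str, int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def __contains__(self, s: str) -> bool:
        return s in self._index

    def index(self, s: str) -> int:
        """Ordinal of ``s`` in lexicographic order; KeyError if not length-n ACGT."""
        return self._index[s]


_SPACE_CACHE: dict[int, SequenceSpace] = {}


def enumerate_space(n: int) -> SequenceSpace:
    """Enumerate the full space of ``4**n`` core sequences.

    Results are cached per ``n`` (the space is immutable).
    """
    if not isinstance(n, int) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if n > MAX_N:
        raise ValueError(f"n={n} would enumerate 4**{n} sequences; maximum supported is {MAX_N}")
    if n not in _SPACE_CACHE:
        seqs = tuple("".join(p) for p in itertools.product(BASES, repeat=n))
        _SPACE_CACHE[n] = SequenceSpace(n=n, sequences=seqs, _index={s: i for i, s in enumerate(seqs)})
    return _SPACE_CACHE[n]


def core_mask(space: SequenceSpace, core: str) -> set[str]:
    """Sequences of ``space`` containing ``core`` as a contiguous substring.

    This is the highlight set of the viewer's search function (e.g. core
    ``GAC`` in a 4-mer space selects the eight NGAC/GACN words).
    """
    _check_dna(core, "core")
    if len(core) > space.n:
        warnings.warn(f"core {core!r} is longer than n={space.n}; no sequence can contain it")
        return set()
    return {s for s in space.sequences if core in s}


@dataclass(frozen=True)
class KmerGraphLayout:
    """Bijection from every length-k sequence to a cell of a ``2**k x 2**k`` grid.

    Row/col are 0-based; row 0 is drawn at the top.  ``base_quadrants`` maps
    each base to its (row-bit, col-bit) corner; the most significant base of
    the sequence chooses the coarsest quadrant, so all sequences sharing a
    length-p prefix fill one contiguous ``2**(k-p)`` square block.
    """

    k: int
    base_quadrants: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if set(self.base_quadrants) != _BASE_SET or set(self.base_quadrants.values()) != {
            (0, 0), (0, 1), (1, 0), (1, 1),
        }:
            raise ValueError("base_quadrants must map A,C,G,T bijectively onto the 4 corner bit-pairs")

    @property
    def side(self) -> int:
        return 2 ** self.k

    def cell(self, seq: str) -> tuple[int, int]:
        """(row, col) of ``seq``; raises on wrong length or non-ACGT."""
        if len(seq) != self.k:
            raise ValueError(f"sequence {seq!r} has length {len(seq)}, layout expects {self.k}")
        row = col = 0
        for base in seq:
            try:
                rb, cb = self.base_quadrants[base]
            except KeyError:
                raise ValueError(f"non-ACGT base in {seq!r}") from None
            row = (row << 1) | rb
            col = (col << 1) | cb
        return row, col

    def grid(self, values: dict[str, float] | "pd.Series", fill: float = np.nan) -> np.ndarray:
        """Dense ``2**k x 2**k`` array with ``values`` placed at their cells."""
        out = np.full((self.side, self.side), fill, dtype=float)
        for seq, v in values.items():
            r, c = self.cell(seq)
            out[r, c] = v
        return out

    def to_frame(self) -> pd.DataFrame:
        """Columns sequence,row,col over the whole space, lexicographic order."""
        space = enumerate_space(self.k)
        rows, cols = zip(*(self.cell(s) for s in space))
        return pd.DataFrame({"sequence": space.sequences, "row": rows, "col": cols})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def layout(k: int, base_quadrants: dict[str, tuple[int, int]] | None = None) -> KmerGraphLayout:
    """Build the recursive-quadrant K-mer graph layout of order ``k``."""
    quadrants = dict(DEFAULT_QUADRANTS if base_quadrants is None else base_quadrants)
    return KmerGraphLayout(k=k, base_quadrants=quadrants)
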