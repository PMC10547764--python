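"""Paired-end read processing: flank location, the reverse-complement
pair-consistency filter, and per-pool count tables.

The construct is ``left_flank + core + right_flank`` and its mates are exact
reverse complements across the insert, so the core extracted from read 2
must be the reverse complement of the core extracted from read 1; pairs
violating this are discarded and tallied.  Counting is over the complete
``4**n`` space in read-1 orientation (a type and its reverse complement are
distinct types unless ``collapse_rc`` is requested).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .sequence_space import LibraryDesign, enumerate_space, reverse_complement

# QC failure reasons (values are the keys of the QC tally)
FLANK_NOT_FOUND = "flank_not_found"
WRONG_REGION_LENGTH = "wrong_region_length"
AMBIGUOUS_BASE = "ambiguous_base"
NOT_REVERSE_COMPLEMENT = "not_reverse_complement"
QC_REASONS = (FLANK_NOT_FOUND, WRONG_REGION_LENGTH, AMBIGUOUS_BASE, NOT_REVERSE_COMPLEMENT)

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class ReadPair:
    read1_seq: str
    read1_qual: str
    read2_seq: str
    read2_qual: str
    pair_id: str = ""

    def __post_init__(self) -> None:
        if len(self.read1_seq) != len(self.read1_qual) or len(self.read2_seq) != len(self.read2_qual):
            raise ValueError(f"seq/qual length mismatch in pair {self.pair_id!r}")


@dataclass
class CountTable:
    """Reads per core sequence for one pool, over the full ``4**n`` space.

    ``counts[i]`` belongs to ``enumerate_space(design.n).sequences[i]``;
    absent types are present with count 0.  ``qc`` tallies discarded pairs
    by reason, so kept + discarded equals pairs processed.
    """

    design: LibraryDesign
    pool_label: str
    counts: np.ndarray
    qc: dict[str, int] = field(default_factory=lambda: {r: 0 for r in QC_REASONS})

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.design.space_size,):
            raise ValueError(f"counts must have shape ({self.design.space_size},)")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        for r in QC_REASONS:
            self.qc.setdefault(r, 0)

    @property
    def space(self):
        return enumerate_space(self.design.n)

    @property
    def total_kept(self) -> int:
        return int(self.counts.sum())

    @property
    def total_discarded(self) -> int:
        return sum(self.qc.values())

    def __getitem__(self, seq: str) -> int:
        return int(self.counts[self.space.index(seq)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(self.space.sequences), name="count")


def empty_table(design: LibraryDesign, pool_label: str) -> CountTable:
    return CountTable(design=design, pool_label=pool_label, counts=np.zeros(design.space_size, dtype=np.int64))


def table_from_mapping(design: LibraryDesign, pool_label: str, counts: dict[str, int]) -> CountTable:
    table = empty_table(design, pool_label)
    space = table.space
    for seq, c in counts.items():
        table.counts[space.index(seq)] = c
    return table


def _find_with_mismatches(read: str, pattern: str, start: int, max_mismatch: int) -> int:
    """First index >= start where pattern matches read within max_mismatch (Hamming)."""
    if max_mismatch == 0:
        return read.find(pattern, start)
    m = len(pattern)
    for i in range(start, len(read) - m + 1):
        mism = 0
        for a, b in zip(read[i : i + m], pattern):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return i
    return -1


def extract_region(read: str, design: LibraryDesign, max_mismatch: int = 0) -> tuple[str | None, str | None]:
    """Extract the random core between the fixed flanks of a single read.

    Locates the first occurrence of ``left_flank``, then the first occurrence
    of ``right_flank`` after it (exact match by default).  Returns
    ``(core, None)`` on success or ``(None, reason)`` on failure; failures
    are data, not exceptions.
    """
    if not read:
        raise ValueError("read must be nonempty")
    i = _find_with_mismatches(read, design.left_flank, 0, max_mismatch)
    if i < 0:
        return None, FLANK_NOT_FOUND
    region_start = i + len(design.left_flank)
    j = _find_with_mismatches(read, design.right_flank, region_start, max_mismatch)
    if j < 0:
        return None, FLANK_NOT_FOUND
    region = read[region_start:j]
    if len(region) != design.n:
        return None, WRONG_REGION_LENGTH
    if not _ACGT.issuperset(region):
        return None, AMBIGUOUS_BASE
    return region, None


def extract_pair(pair: ReadPair, design: LibraryDesign, max_mismatch: int = 0) -> tuple[str | None, str | None]:
    """Extract the core from a read pair, enforcing reverse-complement consistency.

    Read 2 is matched against the mirrored design (flanks reverse-complemented
    and swapped); the pair is kept only if both extractions succeed and the
    read-2 core is the reverse complement of the read-1 core.  The kept value
    is the read-1 core (read-1 orientation defines the sequence type).
    """
    region1, reason1 = extract_region(pair.read1_seq, design, max_mismatch)
    if region1 is None:
        return None, reason1
    region2, reason2 = extract_region(pair.read2_seq, design.mirrored(), max_mismatch)
    if region2 is None:
        return None, reason2
    if region2 != reverse_complement(region1):
        return None, NOT_REVERSE_COMPLEMENT
    return region1, None


def count_pool(
    pairs: Iterable[ReadPair],
    design: LibraryDesign,
    pool_label: str,
    max_mismatch: int = 0,
    collapse_rc: bool = False,
) -> CountTable:
    """Tally kept cores over the full sequence space for one pool.

    ``collapse_rc=True`` adds each kept core to both its own type and its
    reverse complement's canonical representative; the default keeps the
    ``4**n`` read-1-orientation types distinct.
    """
    table = empty_table(design, pool_label)
    space = table.space
    n_pairs = 0
    for pair in pairs:
        n_pairs += 1
        core, reason = extract_pair(pair, design, max_mismatch)
        if core is None:
            table.qc[reason] += 1
            continue
        if collapse_rc:
            core = min(core, reverse_complement(core))
        table.counts[space.index(core)] += 1
    if n_pairs == 0:
        warnings.warn(f"empty read stream for pool {pool_label!r}: all-zero count table")
    return table


# ---------------------------------------------------------------------------
# FASTQ input
# ---------------------------------------------------------------------------

def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq_pairs(fastq1, fastq2=None) -> Iterator[ReadPair]:
    """Stream read pairs from two paired FASTQ(.gz) files, or one interleaved file.

    Raises on mismatched mate-stream lengths.
    """
    if fastq2 is None:
        with _open_text(fastq1) as fh:
            records = FastqGeneralIterator(fh)
            for title1, seq1, qual1 in records:
                try:
                    title2, seq2, qual2 = next(records)
                except StopIteration:
                    raise ValueError("interleaved FASTQ has an odd number of records") from None
                yield ReadPair(seq1.upper(), qual1, seq2.upper(), qual2, pair_id=title1.split()[0])
        return
    from itertools import zip_longest

    with _open_text(fastq1) as fh1, _open_text(fastq2) as fh2:
        it1, it2 = FastqGeneralIterator(fh1), FastqGeneralIterator(fh2)
        for rec1, rec2 in zip_longest(it1, it2):
            if rec1 is None or rec2 is None:
                raise ValueError("paired FASTQ files have different numbers of records")
            yield ReadPair(rec1[1].upper(), rec1[2], rec2[1].upper(), rec2[2], pair_id=rec1[0].split()[0])


def count_fastq_pool(fastq1, fastq2, design: LibraryDesign, pool_label: str, **kwargs) -> CountTable:
    """Convenience: FASTQ pair -> CountTable."""
    return count_pool(iter_fastq_pairs(fastq1, fastq2), design, pool_label, **kwargs)


# ---------------------------------------------------------------------------
# TSV output / input
# ---------------------------------------------------------------------------

def write_counts(table: CountTable, path) -> None:
    """Write the count table as TSV (columns sequence,count; lexicographic)."""
    df = pd.DataFrame({"sequence": list(table.space.sequences), "count": table.counts})
    df.to_csv(path, sep="\t", index=False)


def write_qc(table: CountTable, path) -> None:
    """Write the QC tally as a key<TAB>value block."""
    with open(path, "w") as fh:
        fh.write(f"pool_label\t{table.pool_label}\n")
        fh.write(f"kept\t{table.total_kept}\n")
        for reason in QC_REASONS:
            fh.write(f"{reason}\t{table.qc[reason]}\n")
        fh.write(f"processed\t{table.total_kept + table.total_discarded}\n")


def read_counts(path, design: LibraryDesign, pool_label: str) -> CountTable:
    """Read a count-table TSV produced by :func:`write_counts`."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "count": np.int64})
    return table_from_mapping(design, pool_label, dict(zip(df["sequence"], df["count"])))
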