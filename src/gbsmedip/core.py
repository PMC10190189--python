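"""Shared domain types and interval primitives.

All genomic coordinates in memory are 0-based half-open ``[start, end)``.
Conversions to 1-based conventions (GFF3, SAM) happen only at file
boundaries in :mod:`gbsmedip.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _cpg_positions(seq: str) -> np.ndarray:
    """Sorted 0-based start positions of every CG dinucleotide in *seq*."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    is_c = arr[:-1] == ord("C")
    is_g = arr[1:] == ord("G")
    return np.flatnonzero(is_c & is_g).astype(np.int64)


@dataclass
class GenomeRef:
    """A reference genome with a per-chromosome CpG position index."""

    chrom_names: list[str]
    sequences: dict[str, str]
    cpg_index: dict[str, np.ndarray] = field(default_factory=dict)
    #: CpG-island intervals planted by the simulator (empty for real genomes
    #: unless supplied externally).
    islands: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            if not self.sequences.get(name):
                raise ValueError(f"chromosome {name!r} is empty or missing")
            if name not in self.cpg_index:
                self.cpg_index[name] = _cpg_positions(self.sequences[name])

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(self.sequences[c]) for c in self.chrom_names}

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())

    @property
    def total_cpgs(self) -> int:
        return sum(len(v) for v in self.cpg_index.values())

    def cpg_count(self, chrom: str, start: int, end: int) -> int:
        """Number of CpG start positions inside ``[start, end)``."""
        idx = self.cpg_index[chrom]
        return int(np.searchsorted(idx, end) - np.searchsorted(idx, start))

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]


@dataclass(frozen=True)
class GeneModel:
    """One gene/transcript with strand-aware TSS and TTS."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError("tx_start must be < tx_end")
        prev = self.tx_start
        for s, e in self.exons:
            if s < prev or e <= s or e > self.tx_end:
                raise ValueError(
                    f"{self.gene_id}: exons must be sorted, non-overlapping and "
                    "within the transcript"
                )
            prev = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tts(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment; ``selected`` marks the size-selected library."""

    chrom: str
    start: int
    end: int
    cpg_count: int = 0
    selected: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("fragment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignedFragment:
    """A sample-tagged sequenced fragment interval."""

    sample: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("aligned fragment end must exceed start")


@dataclass(frozen=True)
class ROI:
    """A coverage peak retained for differential testing."""

    chrom: str
    start: int
    end: int
    name: str = ""
    p: float = float("nan")
    q: float = float("nan")


class FragmentSet:
    """Per-chromosome sorted interval arrays for one pool of fragments.

    This is the workhorse container for coverage counting: a dict of
    ``chrom -> (starts, ends)`` (both sorted by start) supports
    searchsorted-based overlap counts without materialising per-read objects.
    """

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.intervals = {}
        self._n = 0
        for chrom, (starts, ends) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            self.intervals[chrom] = (starts[order], ends[order])
            self._n += starts.size

    def __len__(self) -> int:
        return self._n

    @classmethod
    def from_aligned(cls, fragments: list[AlignedFragment]) -> "FragmentSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for f in fragments:
            by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
        return cls(
            {
                c: (
                    np.array([iv[0] for iv in ivs], dtype=np.int64),
                    np.array([iv[1] for iv in ivs], dtype=np.int64),
                )
                for c, ivs in by_chrom.items()
            }
        )

    @classmethod
    def from_counts(cls, fragments: list[Fragment], counts: np.ndarray) -> "FragmentSet":
        """Expand multiplicities over a fragment list into an interval pool."""
        counts = np.asarray(counts, dtype=np.int64)
        by_chrom: dict[str, tuple[list, list]] = {}
        for frag, n in zip(fragments, counts):
            if n <= 0:
                continue
            s, e = by_chrom.setdefault(frag.chrom, ([], []))
            s.extend([frag.start] * int(n))
            e.extend([frag.end] * int(n))
        return cls(
            {c: (np.array(s), np.array(e)) for c, (s, e) in by_chrom.items()}
        )

    def count_overlapping(self, chrom: str, starts, ends) -> np.ndarray:
        """Fragments overlapping each query ``[start, end)`` by >= 1 bp."""
        starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
        ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
        if chrom not in self.intervals:
            return np.zeros(starts.size, dtype=np.int64)
        fs, fe = self.intervals[chrom]
        fe_sorted = np.sort(fe)
        n = fs.size
        # overlap  <=>  frag.start < q.end  and  frag.end > q.start
        n_start_ge_end = n - np.searchsorted(fs, ends, side="left")
        n_end_le_start = np.searchsorted(fe_sorted, starts, side="right")
        return n - n_start_ge_end - n_end_le_start


@dataclass
class CountMatrix:
    """ROI x sample read-count matrix with per-sample library sizes."""

    rois: list[ROI]
    samples: list[str]
    counts: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes)
        if self.counts.shape != (len(self.rois), len(self.samples)):
            raise ValueError("counts shape must be (n_rois, n_samples)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        index = [r.name or f"{r.chrom}:{r.start}-{r.end}" for r in self.rois]
        return pd.DataFrame(self.counts, index=index, columns=self.samples)


def merge_intervals(
    intervals: list[tuple[str, int, int]], gap: int = 0
) -> list[tuple[str, int, int]]:
    """Union of half-open intervals; intervals closer than *gap* bp are joined.

    ``gap=0`` joins overlapping or book-ended intervals.
    """
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2] + gap:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            out.append((chrom, start, end))
    return out
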