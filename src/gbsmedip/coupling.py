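"""CpG-density coupling, calibration, relative methylation scores, and the
CpG enrichment score.

MeDIP coverage depends on local CpG density; the coupling value of a region
is simply its CpG count.  A per-sample calibration line fitted to the
ascending low-coupling part of the mean-count-vs-coupling curve converts
raw counts into relative methylation scores (rms).  The enrichment score
compares the CpG density of read-covered territory with the genome-wide
density; values well above 1 indicate methylation-biased capture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FragmentSet, GenomeRef, ROI, merge_intervals


@dataclass
class CouplingSet:
    values: np.ndarray          # per-ROI CpG count
    bin_values: np.ndarray      # distinct coupling values observed
    bin_counts: np.ndarray      # ROIs per bin


@dataclass
class CalibrationFit:
    intercept: float
    slope: float
    c_max_fit: int
    bin_values: np.ndarray
    bin_means: np.ndarray
    residuals: np.ndarray


def compute_coupling(rois: list[ROI], genome: GenomeRef) -> CouplingSet:
    """CpG start positions inside each ROI's ``[start, end)``."""
    values = np.empty(len(rois), dtype=np.int64)
    for i, r in enumerate(rois):
        if r.chrom not in genome.sequences:
            raise ValueError(f"ROI on unknown chromosome {r.chrom!r}")
        if r.end > genome.lengths[r.chrom] or r.start < 0:
            raise ValueError(f"ROI {r.name or i} off chromosome {r.chrom}")
        values[i] = genome.cpg_count(r.chrom, r.start, r.end)
    bins, counts = np.unique(values, return_counts=True)
    return CouplingSet(values=values, bin_values=bins, bin_counts=counts)


def fit_calibration(counts_column: np.ndarray, coupling: CouplingSet) -> CalibrationFit:
    """Least-squares line through per-coupling-bin mean counts.

    ROIs are binned by integer coupling value; the line is fitted only on
    the ascending portion, i.e. bins from 0 up to the bin with the maximum
    mean count (coverage saturates and then falls at high CpG density, which
    the linear model must not be dragged by).
    """
    counts_column = np.asarray(counts_column, dtype=float)
    if counts_column.shape != coupling.values.shape:
        raise ValueError("counts and coupling must align")
    bins = coupling.bin_values
    if bins.size < 2:
        raise ValueError("need >= 2 coupling bins to fit a calibration line")
    means = np.array(
        [counts_column[coupling.values == b].mean() for b in bins]
    )
    top = int(np.argmax(means))
    if top == 0:
        # flat or descending curve: no ascending portion to restrict to
        top = bins.size - 1
    use = slice(0, top + 1)
    slope, intercept = np.polyfit(bins[use].astype(float), means[use], 1)
    fitted = intercept + slope * bins[use]
    return CalibrationFit(
        intercept=float(intercept),
        slope=float(slope),
        c_max_fit=int(bins[top]),
        bin_values=bins[use].copy(),
        bin_means=means[use].copy(),
        residuals=means[use] - fitted,
    )


def rms_transform(
    counts: np.ndarray, coupling: CouplingSet, calibrations: list[CalibrationFit]
) -> np.ndarray:
    """Relative methylation scores ``x / max(a + b*c, floor)`` per sample.

    The floor is the calibration curve at coupling 1, which keeps CpG-free
    regions from dividing by ~0.  rms is a descriptive layer (reporting and
    fold-change display); the differential test runs on raw counts.
    """
    counts = np.asarray(counts, dtype=float)
    out = np.empty_like(counts)
    c = coupling.values.astype(float)
    for j, cal in enumerate(calibrations):
        expected = cal.intercept + cal.slope * c
        floor = cal.intercept + cal.slope * 1.0
        denom = np.maximum(expected, floor)
        if (denom <= 0).any():
            denom = np.maximum(denom, 1e-9)
        out[:, j] = counts[:, j] / denom
    return out


def cpg_enrichment_score(fragments, genome: GenomeRef) -> float:
    """CpG density of read-covered territory relative to the genome.

    relH-style ratio: (CpGs under the union of covered intervals / covered
    bp) divided by (genome CpGs / genome bp).  Uniformly placed coverage
    scores ~1; methylation-biased capture scores > 1.
    """
    if isinstance(fragments, FragmentSet):
        intervals = [
            (chrom, int(s), int(e))
            for chrom, (ss, ee) in fragments.intervals.items()
            for s, e in zip(ss, ee)
        ]
    else:
        intervals = [(f.chrom, f.start, f.end) for f in fragments]
    if not intervals:
        raise ValueError("empty coverage")
    covered = merge_intervals(intervals)
    cov_bp = sum(e - s for _, s, e in covered)
    cov_cpg = sum(genome.cpg_count(c, s, e) for c, s, e in covered)
    genome_density = genome.total_cpgs / genome.total_bp
    return (cov_cpg / cov_bp) / genome_density


def covered_cpg_count(fragments, genome: GenomeRef) -> int:
    """Distinct CpG positions under the union of aligned-fragment intervals."""
    if isinstance(fragments, FragmentSet):
        intervals = [
            (chrom, int(s), int(e))
            for chrom, (ss, ee) in fragments.intervals.items()
            for s, e in zip(ss, ee)
        ]
    else:
        intervals = [(f.chrom, f.start, f.end) for f in fragments]
    covered = merge_intervals(intervals)
    return sum(genome.cpg_count(c, s, e) for c, s, e in covered)
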