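"""Stacked-read filtering, ROI peak calling, and the ROI count matrix.

This is stage 1 of the two-stage differential-methylation method: a
per-sample PCR-stack filter with a Poisson threshold, sliding-window peak
calling on the group-merged fragment pools at FDR <= 0.1, and assembly of
the per-sample ROI read-count matrix that stage 2 tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import AlignedFragment, CountMatrix, FragmentSet, GenomeRef, ROI, merge_intervals
from .dmr import bh_adjust


@dataclass(frozen=True)
class PoissonBackground:
    """Poisson model of per-position read stacking for one sample."""

    lambda_pos: float
    n_star: int
    p_stack: float = 0.001


def estimate_stack_threshold(
    fragments: list[AlignedFragment] | None,
    p_stack: float = 0.001,
    lambda_pos: float | None = None,
) -> PoissonBackground:
    """Smallest stack count ``n`` whose Poisson upper tail is below *p_stack*.

    ``lambda_pos`` (mean reads per covered start position) is estimated as
    total fragments / distinct ``(chrom, start, strand)`` keys, or may be
    given directly.  ``n_star`` satisfies ``P(X >= n_star) < p_stack <=
    P(X >= n_star - 1)`` (or ``n_star = 1`` in the sparse limit).
    """
    if lambda_pos is None:
        if not fragments:
            raise ValueError("no fragments to estimate stacking from")
        keys = {(f.chrom, f.start, f.strand) for f in fragments}
        lambda_pos = len(fragments) / len(keys)
    if lambda_pos <= 0:
        raise ValueError("lambda_pos must be positive")
    n = 1
    while stats.poisson.sf(n - 1, lambda_pos) >= p_stack:
        n += 1
    return PoissonBackground(lambda_pos=float(lambda_pos), n_star=n, p_stack=p_stack)


def filter_stacked_reads(
    fragments: list[AlignedFragment], background: PoissonBackground
) -> tuple[list[AlignedFragment], int]:
    """Cap reads per ``(chrom, start, strand)`` position at ``n_star - 1``.

    At least one read per position is always retained (the threshold marks
    the stack as excessive, not the position as invalid).  Retention is
    deterministic: first by sorted order, then input order.
    """
    cap = max(1, background.n_star - 1)
    order = sorted(
        range(len(fragments)),
        key=lambda i: (fragments[i].chrom, fragments[i].start, fragments[i].strand, i),
    )
    seen: Counter = Counter()
    kept: list[AlignedFragment] = []
    removed = 0
    for i in order:
        f = fragments[i]
        key = (f.chrom, f.start, f.strand)
        if seen[key] < cap:
            seen[key] += 1
            kept.append(f)
        else:
            removed += 1
    return kept, removed


def stack_filter_multiplicities(
    counts: np.ndarray, p_stack: float = 0.001, strands: int = 2
) -> tuple[np.ndarray, int, PoissonBackground]:
    """Stack filter for molecule multiplicities over a fragment universe.

    Restriction fragments are identical intervals by construction, so the
    per-position filter acts as a cap on each fragment's per-strand
    multiplicity.  ``lambda_pos`` is the mean multiplicity per occupied
    (fragment, strand) slot; each fragment is capped at ``strands *
    max(1, n_star - 1)``.
    """
    counts = np.asarray(counts, dtype=np.int64)
    occupied = np.count_nonzero(counts) * strands
    if occupied == 0:
        raise ValueError("no molecules to filter")
    bg = estimate_stack_threshold(None, p_stack, lambda_pos=counts.sum() / occupied)
    cap = strands * max(1, bg.n_star - 1)
    filtered = np.minimum(counts, cap)
    return filtered, int((counts - filtered).sum()), bg


def window_poisson_p(x, lam):
    """Poisson upper tail P(X >= x | lam) used against the background floor."""
    return stats.poisson.sf(np.asarray(x) - 1, lam)


def _window_counts(pool: FragmentSet, chrom: str, length: int, window_bp: int, step_bp: int):
    starts = np.arange(0, max(1, length - window_bp + step_bp), step_bp, dtype=np.int64)
    ends = np.minimum(starts + window_bp, length)
    return starts, ends, pool.count_overlapping(chrom, starts, ends)


def call_rois(
    treatment: FragmentSet | list[AlignedFragment],
    control: FragmentSet | list[AlignedFragment] | None,
    genome: GenomeRef,
    window_bp: int = 300,
    step_bp: int = 100,
    roi_fdr: float = 0.1,
    method: str = "conditional",
) -> list[ROI]:
    """Sliding-window peak calling on merged pools, both directions, union.

    Each group is scored as "treatment" against the other; windows
    significant at BH ``q <= roi_fdr`` in either direction are merged
    (overlapping/adjacent joined) into ROIs carrying their best p and q.

    A window must beat both the scaled control and a global background
    floor ``lambda_floor = N_t * window_bp / genome_bp``.  With
    ``method="conditional"`` (default) the control comparison is the exact
    conditional binomial test of ``x_t`` given ``x_t + x_c`` — the standard
    calibrated comparison of two Poisson counts; ``method="rate"`` instead
    treats the scaled control count as a known Poisson rate
    (``lambda = max(x_c * N_t / N_c, floor)``), which is anticonservative
    because it ignores control sampling noise.  With ``control=None`` only
    the background floor is tested (single-pool peak calling).
    """
    if genome.total_bp <= 0:
        raise ValueError("zero-length genome")
    if isinstance(treatment, list):
        treatment = FragmentSet.from_aligned(treatment)
    if isinstance(control, list):
        control = FragmentSet.from_aligned(control)
    directions = [(treatment, control)]
    if control is not None:
        directions.append((control, treatment))

    selected: list[tuple[str, int, int, float]] = []
    for treat, ctrl in directions:
        n_t = len(treat)
        if n_t == 0:
            raise ValueError("empty treatment pool")
        floor = n_t * window_bp / genome.total_bp
        all_p, meta = [], []
        for chrom in genome.chrom_names:
            length = genome.lengths[chrom]
            w_start, w_end, x_t = _window_counts(treat, chrom, length, window_bp, step_bp)
            p_floor = window_poisson_p(x_t, floor)
            if ctrl is None:
                p = p_floor
            else:
                x_c = ctrl.count_overlapping(chrom, w_start, w_end)
                n_c = len(ctrl)
                if method == "rate":
                    lam = np.maximum(x_c * n_t / n_c, floor)
                    p = window_poisson_p(x_t, lam)
                elif method == "conditional":
                    pi = n_t / (n_t + n_c)
                    p_ctrl = stats.binom.sf(x_t - 1, x_t + x_c, pi)
                    p = np.maximum(p_ctrl, p_floor)
                else:
                    raise ValueError(f"unknown method {method!r}")
            all_p.append(p)
            meta.append((chrom, w_start, w_end))
        p_flat = np.concatenate(all_p)
        q_flat = bh_adjust(p_flat)
        offset = 0
        for (chrom, w_start, w_end), p_arr in zip(meta, all_p):
            n = w_start.size
            q_arr = q_flat[offset : offset + n]
            hit = np.flatnonzero(q_arr <= roi_fdr)
            for i in hit:
                selected.append((chrom, int(w_start[i]), int(w_end[i]), float(p_arr[i])))
            offset += n

    if not selected:
        return []
    merged = merge_intervals([(c, s, e) for c, s, e, _ in selected])
    # best window p inside each merged region; q recomputed over merged ROIs
    best_p = {iv: 1.0 for iv in merged}
    for chrom, s, e, p in selected:
        for iv in merged:
            if iv[0] == chrom and s >= iv[1] and e <= iv[2]:
                best_p[iv] = min(best_p[iv], p)
                break
    ps = np.array([best_p[iv] for iv in merged])
    qs = bh_adjust(ps)
    return [
        ROI(chrom=c, start=s, end=e, name=f"roi{i}", p=float(p), q=float(q))
        for i, ((c, s, e), p, q) in enumerate(zip(merged, ps, qs))
    ]


def rois_from_fragments(fragments) -> list[ROI]:
    """The selected-fragment universe as a region set (one ROI per fragment).

    Used when the unit of testing is the restriction fragment itself, e.g.
    for calibration runs where no differential peaks exist by construction.
    """
    rois = []
    for i, f in enumerate(sorted(fragments, key=lambda f: (f.chrom, f.start))):
        rois.append(ROI(chrom=f.chrom, start=f.start, end=f.end, name=f"frag{i}"))
    return rois


def count_matrix(
    rois: list[ROI],
    sample_pools: dict[str, FragmentSet | list[AlignedFragment]],
) -> CountMatrix:
    """Per-sample counts of fragments overlapping each ROI by >= 1 bp."""
    for a, b in zip(rois[:-1], rois[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError("ROIs must be sorted and non-overlapping")
    samples = list(sample_pools)
    pools = {
        s: (FragmentSet.from_aligned(p) if isinstance(p, list) else p)
        for s, p in sample_pools.items()
    }
    counts = np.zeros((len(rois), len(samples)), dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(rois):
        by_chrom.setdefault(r.chrom, []).append(i)
    for j, s in enumerate(samples):
        pool = pools[s]
        for chrom, idxs in by_chrom.items():
            starts = np.array([rois[i].start for i in idxs])
            ends = np.array([rois[i].end for i in idxs])
            counts[idxs, j] = pool.count_overlapping(chrom, starts, ends)
    lib_sizes = np.array([len(pools[s]) for s in samples])
    return CountMatrix(rois=rois, samples=samples, counts=counts, library_sizes=lib_sizes)
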