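"""Cross-contrast DMR overlap counting and permutation significance.

Venn cells are computed on the connected components of the region-overlap
graph across sets (two regions overlap iff they share >= 1 bp as half-open
intervals); each component is counted once under the signature of the sets
represented in it.  Significance of a pairwise overlap uses a permutation
null that relocates one set's regions uniformly at random,
chromosome-matched and length-preserving, within a placement universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Region = tuple[str, int, int]


@dataclass
class OverlapResult:
    set_sizes: dict[str, int]
    venn_counts: dict[frozenset, int] = field(default_factory=dict)

    def cell(self, *names: str) -> int:
        return self.venn_counts.get(frozenset(names), 0)


def _validate(regions: list[Region]) -> None:
    for chrom, s, e in regions:
        if e <= s:
            raise ValueError(f"malformed interval {chrom}:{s}-{e}")


def find_overlaps(region_sets: dict[str, list[Region]]) -> OverlapResult:
    """Venn cell counts over the connected components of the overlap graph."""
    events = []
    for name, regions in region_sets.items():
        _validate(regions)
        for chrom, s, e in regions:
            events.append((chrom, s, e, name))
    events.sort()
    result = OverlapResult(set_sizes={n: len(r) for n, r in region_sets.items()})
    comp_names: set[str] = set()
    comp_chrom, comp_end = None, -1
    for chrom, s, e, name in events:
        if chrom != comp_chrom or s >= comp_end:
            if comp_names:
                sig = frozenset(comp_names)
                result.venn_counts[sig] = result.venn_counts.get(sig, 0) + 1
            comp_names = {name}
            comp_chrom, comp_end = chrom, e
        else:
            comp_names.add(name)
            comp_end = max(comp_end, e)
    if comp_names:
        sig = frozenset(comp_names)
        result.venn_counts[sig] = result.venn_counts.get(sig, 0) + 1
    return result


@dataclass
class PermutationReport:
    observed: int
    null_mean: float
    null_sd: float
    p: float
    n_perm: int
    seed: int


def _count_a_overlapped(set_a: list[Region], b_by_chrom: dict[str, np.ndarray]) -> int:
    n = 0
    for chrom, s, e in set_a:
        ivs = b_by_chrom.get(chrom)
        if ivs is None or ivs.size == 0:
            continue
        starts, ends = ivs[:, 0], ivs[:, 1]
        if ((starts < e) & (ends > s)).any():
            n += 1
    return n


def permutation_overlap_test(
    set_a: list[Region],
    set_b: list[Region],
    universe: list[Region],
    n_perm: int = 100,
    seed: int = 0,
) -> PermutationReport:
    """Empirical p for the number of set-A regions overlapped by set B.

    Each permutation relocates every set-B region uniformly at random within
    the universe blocks of its own chromosome, preserving its length; the
    statistic is the number of set-A regions overlapped by >= 1 relocated
    region, and ``p = (1 + #{perm >= observed}) / (n_perm + 1)``.
    """
    _validate(set_a)
    _validate(set_b)
    _validate(universe)
    rng = np.random.default_rng(seed)
    uni_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in universe:
        uni_by_chrom.setdefault(chrom, []).append((s, e))

    def _b_arrays(regions: list[Region]) -> dict[str, np.ndarray]:
        by: dict[str, list] = {}
        for chrom, s, e in regions:
            by.setdefault(chrom, []).append((s, e))
        return {c: np.array(sorted(v)) for c, v in by.items()}

    observed = _count_a_overlapped(set_a, _b_arrays(set_b))

    placements: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, blocks in uni_by_chrom.items():
        starts = np.array([b[0] for b in blocks])
        lens = np.array([b[1] - b[0] for b in blocks])
        placements[chrom] = (starts, lens)

    exceed = 0
    stats_null = np.empty(n_perm)
    for it in range(n_perm):
        relocated: dict[str, list] = {}
        for chrom, s, e in set_b:
            length = e - s
            if chrom not in placements:
                raise ValueError(f"no universe blocks on chromosome {chrom}")
            bstarts, blens = placements[chrom]
            slots = blens - length + 1
            ok = slots > 0
            if not ok.any():
                raise ValueError(
                    f"region of {length} bp does not fit in any universe block "
                    f"on {chrom}"
                )
            w = np.where(ok, slots, 0).astype(float)
            bi = rng.choice(bstarts.size, p=w / w.sum())
            off = int(rng.integers(0, slots[bi]))
            ns = int(bstarts[bi]) + off
            relocated.setdefault(chrom, []).append((ns, ns + length))
        b_arr = {c: np.array(sorted(v)) for c, v in relocated.items()}
        stat = _count_a_overlapped(set_a, b_arr)
        stats_null[it] = stat
        if stat >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return PermutationReport(
        observed=observed,
        null_mean=float(stats_null.mean()),
        null_sd=float(stats_null.std(ddof=1)) if n_perm > 1 else 0.0,
        p=float(p),
        n_perm=n_perm,
        seed=seed,
    )


def gene_set_overlap(gene_lists: dict[str, set[str]]) -> dict[frozenset, int]:
    """Exact Venn cells on DMR-related gene id sets (no permutation)."""
    all_genes = set().union(*gene_lists.values()) if gene_lists else set()
    cells: dict[frozenset, int] = {}
    for gene in all_genes:
        sig = frozenset(n for n, s in gene_lists.items() if gene in s)
        cells[sig] = cells.get(sig, 0) + 1
    return cells
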