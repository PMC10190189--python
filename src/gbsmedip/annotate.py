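"""Genomic-feature annotation of DMRs.

Each DMR is classified by its midpoint against strand-aware gene features
with the precedence Promoter > 5'UTR > 3'UTR > Exon > Intron > Downstream >
Distal Intergenic.  The promoter is the 3 kb upstream of the TSS (sub-binned
at 1 kb), the downstream region is the 300 bp after the TTS, and intergenic
DMRs are assigned to the nearest gene by TSS distance.  TSS distances are
signed along the gene's strand (negative = upstream of the TSS) and can be
summarized into leading-digit x power-of-ten magnitude bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .core import GeneModel

PRECEDENCE = [
    "Promoter",
    "5' UTR",
    "3' UTR",
    "Exon",
    "Intron",
    "Downstream",
    "Distal Intergenic",
]

FEATURE_CLASSES = [
    "Promoter (<=1kb)",
    "Promoter (1-2kb)",
    "Promoter (2-3kb)",
    "5' UTR",
    "3' UTR",
    "Exon",
    "Intron",
    "Downstream (<=300bp)",
    "Distal Intergenic",
]


@dataclass(frozen=True)
class AnnotatedDMR:
    chrom: str
    start: int
    end: int
    name: str
    feature: str
    gene_id: str | None
    symbol: str | None
    tss_distance: int | None
    magnitude_bin: str | None


def midpoint(start: int, end: int) -> int:
    return (start + end) // 2


def tss_distance(dmr_start: int, dmr_end: int, gene: GeneModel) -> int:
    """Signed bp from DMR midpoint to the gene's TSS, along the gene strand."""
    mid = midpoint(dmr_start, dmr_end)
    return mid - gene.tss if gene.strand == "+" else gene.tss - mid


def _feature_for_gene(mid: int, d: int, gene: GeneModel, promoter_bp: int, downstream_bp: int):
    """(precedence rank, sub-binned label) of *mid* w.r.t. one gene, or None."""
    if -promoter_bp <= d < 0:
        kb = (-d - 1) // 1000  # 1..1000 -> 0, 1001..2000 -> 1, ...
        labels = ["Promoter (<=1kb)", "Promoter (1-2kb)", "Promoter (2-3kb)"]
        label = labels[min(kb, 2)] if promoter_bp == 3000 else f"Promoter (<={promoter_bp}bp)"
        return 0, label
    for s, e in gene.utr5:
        if s <= mid < e:
            return 1, "5' UTR"
    for s, e in gene.utr3:
        if s <= mid < e:
            return 2, "3' UTR"
    if gene.tx_start <= mid < gene.tx_end:
        for s, e in gene.exons:
            if s <= mid < e:
                return 3, "Exon"
        return 4, "Intron"
    if gene.strand == "+":
        in_down = gene.tx_end <= mid < gene.tx_end + downstream_bp
    else:
        in_down = gene.tx_start - downstream_bp <= mid < gene.tx_start
    if in_down:
        return 5, f"Downstream (<={downstream_bp}bp)"
    return None


def annotate_dmr(
    chrom: str,
    start: int,
    end: int,
    gene_models: list[GeneModel],
    promoter_bp: int = 3000,
    downstream_bp: int = 300,
    name: str = "",
) -> AnnotatedDMR:
    """Classify one DMR and assign its gene.

    Among overlapping candidate genes the highest-precedence feature wins;
    ties break by smaller ``|TSS distance|``, then lexicographic gene id.
    With no gene model on the chromosome the DMR is Distal Intergenic with
    the nearest gene genome-wide on that chromosome, or NA when the gene set
    is empty.
    """
    mid = midpoint(start, end)
    candidates = [g for g in gene_models if g.chrom == chrom]
    if not candidates:
        return AnnotatedDMR(
            chrom, start, end, name, "Distal Intergenic", None, None, None, None
        )
    best = None
    for g in candidates:
        d = tss_distance(start, end, g)
        hit = _feature_for_gene(mid, d, g, promoter_bp, downstream_bp)
        if hit is None:
            continue
        key = (hit[0], abs(d), g.gene_id)
        if best is None or key < best[0]:
            best = (key, hit[1], g, d)
    if best is not None:
        _, label, gene, d = best
        return AnnotatedDMR(
            chrom, start, end, name, label, gene.gene_id, gene.symbol, d,
            magnitude_bin(d),
        )
    gene = min(candidates, key=lambda g: (abs(tss_distance(start, end, g)), g.gene_id))
    d = tss_distance(start, end, gene)
    return AnnotatedDMR(
        chrom, start, end, name, "Distal Intergenic", gene.gene_id, gene.symbol,
        d, magnitude_bin(d),
    )


def magnitude_bin(d: int) -> str:
    """Leading-digit x power-of-ten label of a signed TSS distance.

    ``-2450 -> "-2 Kbps"``, ``+19999 -> "+10 Kbps"``, ``+20000 -> "+20 Kbps"``,
    ``0 -> "0"``.
    """
    if d == 0:
        return "0"
    a = abs(d)
    e = int(math.floor(math.log10(a)))
    digit = a // 10**e
    sign = "+" if d > 0 else "-"
    value = digit * 10**e
    if e >= 6:
        return f"{sign}{value // 10**6} Mbps"
    if e >= 3:
        return f"{sign}{value // 10**3} Kbps"
    return f"{sign}{value} bps"


def annotate_dmrs(
    records,
    gene_models: list[GeneModel],
    promoter_bp: int = 3000,
    downstream_bp: int = 300,
) -> list[AnnotatedDMR]:
    """Annotate an iterable of DMR-like records (need chrom/start/end/name)."""
    out = []
    for r in records:
        name = getattr(r, "roi_name", getattr(r, "name", ""))
        out.append(
            annotate_dmr(
                r.chrom, r.start, r.end, gene_models,
                promoter_bp=promoter_bp, downstream_bp=downstream_bp, name=name,
            )
        )
    return out


def feature_distribution(annotated: list[AnnotatedDMR]) -> pd.DataFrame:
    """Counts and fractions per feature class (fractions sum to 1)."""
    if not annotated:
        raise ValueError("empty annotation set")
    counts = pd.Series([a.feature for a in annotated]).value_counts()
    df = pd.DataFrame({"count": counts, "fraction": counts / counts.sum()})
    df.index.name = "feature"
    return df.sort_index()


def tss_distance_histogram(annotated: list[AnnotatedDMR]) -> pd.DataFrame:
    """Counts of DMRs per signed magnitude bin of TSS distance."""
    bins = [a.magnitude_bin for a in annotated if a.magnitude_bin is not None]
    counts = pd.Series(bins).value_counts()
    df = pd.DataFrame({"count": counts})
    df.index.name = "magnitude_bin"

    def _key(label: str) -> float:
        if label == "0":
            return 0.0
        sign = 1 if label[0] == "+" else -1
        num, unit = label[1:].split(" ")
        mult = {"bps": 1, "Kbps": 1_000, "Mbps": 1_000_000}[unit]
        return sign * int(num) * mult

    return df.sort_index(key=lambda idx: idx.map(_key))
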