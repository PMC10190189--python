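"""Readers/writers for every format the pipeline touches, plus demultiplexing.

Internal coordinates are uniformly 0-based half-open; GFF3 and SAM are
converted at the file boundary.  All writers emit deterministic column and
sort order (chrom, start).
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AlignedFragment, GeneModel, GenomeRef, ROI
from .simulate import PSTI_REMNANT

logger = logging.getLogger(__name__)


def _open_text(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(genome: GenomeRef, path: str) -> None:
    records = [
        SeqRecord(Seq(genome.sequences[c]), id=c, description="")
        for c in genome.chrom_names
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str) -> GenomeRef:
    names, seqs = [], {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            names.append(rec.id)
            seqs[rec.id] = str(rec.seq).upper()
    return GenomeRef(chrom_names=names, sequences=seqs)


# ---------------------------------------------------------------------------
# FASTQ + demultiplexing


def _fastq_records(path: str):
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not seq:
                raise ValueError(f"{path}: truncated FASTQ record at {header!r}")
            yield header.rstrip("\n")[1:], seq, qual


@dataclass
class DemuxStats:
    per_sample: dict[str, int] = field(default_factory=dict)
    n_total: int = 0
    n_rejected: int = 0

    @property
    def n_assigned(self) -> int:
        return self.n_total - self.n_rejected


def demultiplex(
    fastq_r1: str,
    fastq_r2: str,
    barcodes: dict[str, str],
    out_dir: str,
    remnant: str = PSTI_REMNANT,
) -> DemuxStats:
    """Assign read pairs to samples by exact barcode + remnant match on read 1.

    A pair is assigned iff the read-1 prefix equals a barcode and the next
    ``len(remnant)`` bases equal the remnant; assigned pairs are written with
    barcode and remnant trimmed from read 1, everything else goes to a
    reject pair of files.
    """
    if not remnant:
        raise ValueError("remnant must be non-empty")
    bc_lens = {len(b) for b in barcodes.values()}
    if len(bc_lens) != 1:
        raise ValueError("all barcodes must have equal length")
    if len(set(barcodes.values())) != len(barcodes):
        raise ValueError("barcodes must be unique")
    bc_len = bc_lens.pop()
    lookup = {b: s for s, b in barcodes.items()}
    os.makedirs(out_dir, exist_ok=True)
    stats = DemuxStats(per_sample={s: 0 for s in barcodes})
    handles: dict[str, tuple] = {}

    def _get(sample: str):
        if sample not in handles:
            handles[sample] = (
                open(os.path.join(out_dir, f"{sample}_R1.fastq"), "w"),
                open(os.path.join(out_dir, f"{sample}_R2.fastq"), "w"),
            )
        return handles[sample]

    trim = bc_len + len(remnant)
    it1, it2 = _fastq_records(fastq_r1), _fastq_records(fastq_r2)
    try:
        for rec1 in it1:
            rec2 = next(it2, None)
            if rec2 is None:
                raise ValueError("R1 has more records than R2")
            name1, seq1, qual1 = rec1
            stats.n_total += 1
            sample = lookup.get(seq1[:bc_len])
            if sample is not None and seq1[bc_len:trim] == remnant:
                h1, h2 = _get(sample)
                h1.write(f"@{name1}\n{seq1[trim:]}\n+\n{qual1[trim:]}\n")
                h2.write(f"@{rec2[0]}\n{rec2[1]}\n+\n{rec2[2]}\n")
                stats.per_sample[sample] += 1
            else:
                h1, h2 = _get("rejected")
                h1.write(f"@{name1}\n{seq1}\n+\n{qual1}\n")
                h2.write(f"@{rec2[0]}\n{rec2[1]}\n+\n{rec2[2]}\n")
                stats.n_rejected += 1
        if next(it2, None) is not None:
            raise ValueError("R2 has more records than R1")
    finally:
        for h1, h2 in handles.values():
            h1.close()
            h2.close()
    return stats


# ---------------------------------------------------------------------------
# alignments


def load_alignments(
    path: str,
    fmt: str | None = None,
    default_sample: str = "sample0",
    genome: GenomeRef | None = None,
) -> list[AlignedFragment]:
    """Load aligned fragments from BED6 or SAM/BAM, normalized to 0-based.

    BED names of the form ``sample/readid`` (or a bare sample name) carry the
    sample; SAM records use the RG tag when present, else *default_sample*.
    Unmapped/secondary/supplementary SAM records are dropped; proper pairs
    are collapsed to one fragment interval spanning min start to max end.
    """
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {".bed": "bed", ".sam": "sam", ".bam": "bam"}.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer alignment format from {path!r}")
    fmt = fmt.lower()
    if fmt == "bed":
        return _load_bed(path, genome)
    if fmt in ("sam", "bam"):
        return _load_sam(path, default_sample, genome)
    raise ValueError(f"unknown alignment format {fmt!r}")


def _check_chrom(chrom: str, genome: GenomeRef | None, dropped: list) -> bool:
    if genome is not None and chrom not in genome.sequences:
        dropped.append(chrom)
        return False
    return True


def _load_bed(path: str, genome: GenomeRef | None) -> list[AlignedFragment]:
    out: list[AlignedFragment] = []
    dropped: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable BED line") from exc
            name = parts[3] if len(parts) > 3 else "sample0"
            strand = parts[5] if len(parts) > 5 else "+"
            if not _check_chrom(chrom, genome, dropped):
                continue
            out.append(
                AlignedFragment(
                    sample=name.split("/")[0],
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    if dropped:
        logger.warning("dropped %d records on unknown chromosomes", len(dropped))
    return out


def _load_sam(path: str, default_sample: str, genome: GenomeRef | None):
    out: list[AlignedFragment] = []
    dropped: list[str] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_paired:
                if not read.is_read1 or read.template_length <= 0:
                    continue
                start = read.reference_start
                end = start + read.template_length
            else:
                start, end = read.reference_start, read.reference_end
            chrom = read.reference_name
            if not _check_chrom(chrom, genome, dropped):
                continue
            sample = (
                read.get_tag("RG") if read.has_tag("RG") else default_sample
            )
            out.append(
                AlignedFragment(
                    sample=str(sample),
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="-" if read.is_reverse else "+",
                )
            )
    if dropped:
        logger.warning("dropped %d records on unknown chromosomes", len(dropped))
    return out


def write_alignments_bed(fragments: list[AlignedFragment], path: str) -> None:
    rows = sorted(fragments, key=lambda f: (f.chrom, f.start, f.end, f.sample))
    with _open_text(path, "wt") as fh:
        for i, f in enumerate(rows):
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.sample}/{i}\t0\t{f.strand}\n"
            )


def truth_alignments_to_bed(alignments, path: str) -> None:
    """Simulator truth records (sample, chrom, start, end, strand) as BED6."""
    frs = [
        AlignedFragment(sample=s, chrom=c, start=a, end=b, strand=st)
        for s, c, a, b, st in alignments
    ]
    write_alignments_bed(frs, path)


# ---------------------------------------------------------------------------
# gene models


def load_gene_models(path: str, fmt: str | None = None) -> list[GeneModel]:
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {".gff3": "gff3", ".gff": "gff3", ".bed": "bed12", ".bed12": "bed12"}.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer gene-model format from {path!r}")
    return _load_gff3(path) if fmt.lower() == "gff3" else _load_bed12(path)


def _load_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(gene, featuretype="exon")
        )
        tx_start, tx_end = gene.start - 1, gene.end
        if any(s < tx_start or e > tx_end for s, e in exons):
            logger.warning("gene %s: exon outside transcript, record rejected", gene.id)
            continue
        symbol = gene.attributes.get("Name", [gene.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                symbol=symbol,
                chrom=gene.seqid,
                strand=gene.strand,
                tx_start=tx_start,
                tx_end=tx_end,
                exons=tuple(exons) or ((tx_start, tx_end),),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    return genes


def write_gff3(genes: list[GeneModel], path: str) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start)):
            attrs = f"ID={g.gene_id};Name={g.symbol}"
            fh.write(
                f"{g.chrom}\tgbsmedip\tgene\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tgbsmedip\tmRNA\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
                f"{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tgbsmedip\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.e{i};Parent={mrna_id}\n"
                )


def _load_bed12(path: str) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            try:
                chrom, start, end, name = p[0], int(p[1]), int(p[2]), p[3]
                strand = p[5]
                sizes = [int(x) for x in p[10].rstrip(",").split(",")]
                offsets = [int(x) for x in p[11].rstrip(",").split(",")]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable BED12 line") from exc
            exons = tuple(
                (start + o, start + o + s) for o, s in zip(offsets, sizes)
            )
            genes.append(
                GeneModel(
                    gene_id=name,
                    symbol=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    exons=exons,
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    return genes


def write_bed12(genes: list[GeneModel], path: str) -> None:
    with _open_text(path, "wt") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start)):
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.tx_start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.tx_start}\t{g.tx_end}\t0\t{len(g.exons)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# gene sets (GMT) and sample sheets


def load_gene_sets(path: str) -> dict[str, set[str]]:
    """GMT rows (name, description, genes...) as a name -> gene-set mapping."""
    sets: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str, descriptions=None) -> None:
    descriptions = descriptions or {}
    with _open_text(path, "wt") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{descriptions.get(name, 'na')}\t{genes}\n")


def read_sample_sheet(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    if "tissue" not in df.columns:
        df["tissue"] = "A"
    return df


def write_sample_sheet(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ROIs and generic BED


def write_rois_bed(rois: list[ROI], path: str) -> None:
    """ROIs as BED6 with score = -10*log10(q), truncated to integer."""
    with _open_text(path, "wt") as fh:
        for r in sorted(rois, key=lambda r: (r.chrom, r.start)):
            q = r.q if np.isfinite(r.q) and r.q > 0 else 1e-10
            score = int(min(1000, -10 * np.log10(q)))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{score}\t.\n")


def read_rois_bed(path: str) -> list[ROI]:
    rois = []
    with _open_text(path) as fh:
        for line in fh:
            p = line.rstrip("\n").split("\t")
            if len(p) < 3:
                continue
            name = p[3] if len(p) > 3 else ""
            rois.append(ROI(chrom=p[0], start=int(p[1]), end=int(p[2]), name=name))
    return rois
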