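"""Synthetic GBS-MeDIP data with known truth.

The generator emulates the laboratory design of a reduced-representation
methylome library: PstI-digested genomic DNA size-selected to 200-500 bp,
per-sample barcodes followed by the ``CTGCA`` cut-site remnant at the start
of read 1, antibody capture whose probability saturates with the number of
methylated CpGs on a molecule, and paired-end 100 bp reads.  Every emitted
read pair carries a truth alignment and every planted group difference is
recorded, so each downstream stage can be tested without any downloads.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Fragment, GeneModel, GenomeRef, revcomp

PSTI_SITE = "CTGCAG"
PSTI_REMNANT = "CTGCA"
#: cut placed after the remnant within the recognition site
PSTI_CUT_OFFSET = 5

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    n_chrom: int = 2,
    chrom_length_bp: int = 1_000_000,
    gc_fraction: float = 0.42,
    island_density: float = 0.02,
    seed: int = 0,
    island_length_bp: tuple[int, int] = (500, 2000),
    island_cpg_rate: float = 0.6,
    site_spacing_bp: tuple[int, int] | None = None,
) -> GenomeRef:
    """Generate an i.i.d.-background genome with planted CpG islands.

    Background bases are drawn i.i.d. at the given GC fraction.  CpG islands
    are intervals whose sequence is built by emitting a ``CG`` dinucleotide
    with probability *island_cpg_rate* (else one background base), giving a
    CpG density several-fold above background.  *island_density* is the
    approximate fraction of the genome covered by islands.

    When *site_spacing_bp* is given, PstI recognition sites are planted with
    uniform random spacing in that range, so that a desk-scale genome yields
    a realistic number of size-selectable restriction fragments (the
    background frequency of a specific 6-mer would require a genome two
    orders of magnitude larger).
    """
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    if not 0 <= island_density < 1:
        raise ValueError("island_density must be in [0, 1)")
    if n_chrom < 1 or chrom_length_bp < 10_000:
        raise ValueError("need n_chrom >= 1 and chrom_length_bp >= 10,000")
    rng = np.random.default_rng(seed)
    p = np.array(
        [
            (1 - gc_fraction) / 2,
            gc_fraction / 2,
            gc_fraction / 2,
            (1 - gc_fraction) / 2,
        ]
    )
    sequences: dict[str, str] = {}
    islands: dict[str, list[tuple[int, int]]] = {}
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    for name in names:
        arr = _BASES[rng.choice(4, size=chrom_length_bp, p=p)].copy()
        ivs: list[tuple[int, int]] = []
        if island_density > 0:
            mean_len = sum(island_length_bp) / 2
            n_islands = int(round(island_density * chrom_length_bp / mean_len))
            starts = np.sort(rng.integers(0, chrom_length_bp - island_length_bp[1], n_islands))
            prev_end = 0
            for s in starts:
                if s < prev_end:
                    continue
                length = int(rng.integers(island_length_bp[0], island_length_bp[1] + 1))
                end = min(s + length, chrom_length_bp)
                arr[s:end] = _island_block(end - s, rng, p, island_cpg_rate)
                ivs.append((int(s), int(end)))
                prev_end = end
        if site_spacing_bp is not None:
            site = np.frombuffer(PSTI_SITE.encode(), dtype=np.uint8)
            lo, hi = site_spacing_bp
            pos = int(rng.integers(lo, hi))
            while pos + len(site) < chrom_length_bp:
                arr[pos : pos + len(site)] = site
                pos += int(rng.integers(lo, hi))
        sequences[name] = arr.tobytes().decode("ascii")
        islands[name] = ivs
    return GenomeRef(chrom_names=names, sequences=sequences, islands=islands)


def _island_block(length: int, rng, p: np.ndarray, cpg_rate: float) -> np.ndarray:
    out = np.empty(length, dtype=np.uint8)
    i = 0
    while i < length:
        if rng.random() < cpg_rate and i + 1 < length:
            out[i] = ord("C")
            out[i + 1] = ord("G")
            i += 2
        else:
            out[i] = _BASES[rng.choice(4, p=p)]
            i += 1
    return out


# ---------------------------------------------------------------------------
# gene models


def simulate_gene_models(
    genome: GenomeRef,
    n_genes: int,
    exon_count_range: tuple[int, int] = (2, 6),
    seed: int = 0,
    gene_length_bp: tuple[int, int] = (2_000, 10_000),
    max_tries_per_gene: int = 200,
) -> list[GeneModel]:
    """Place non-overlapping transcripts with random strands and exons."""
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    chroms = genome.chrom_names
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneModel] = []
    for i in range(n_genes):
        for _ in range(max_tries_per_gene):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            glen = int(rng.integers(gene_length_bp[0], gene_length_bp[1] + 1))
            if lengths[chrom] <= glen:
                continue
            start = int(rng.integers(0, lengths[chrom] - glen))
            end = start + glen
            if any(start < e and end > s for s, e in placed[chrom]):
                continue
            placed[chrom].append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
            exons = _split_exons(start, end, n_exons, rng)
            genes.append(
                GeneModel(
                    gene_id=f"G{i:04d}",
                    symbol=f"GENE{i}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    exons=exons,
                )
            )
            break
        else:
            raise RuntimeError(
                f"could not place gene {i} without overlap after "
                f"{max_tries_per_gene} tries"
            )
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    return genes


def _split_exons(start: int, end: int, n_exons: int, rng) -> tuple[tuple[int, int], ...]:
    """First exon starts at tx_start, last ends at tx_end, introns >= 1 bp."""
    length = end - start
    n_exons = min(n_exons, max(1, length // 60))
    if n_exons == 1:
        return ((start, end),)
    # 2*n_exons - 1 alternating exon/intron blocks, each >= 30/10 bp
    cuts = np.sort(rng.choice(length - 2, size=2 * n_exons - 2, replace=False) + 1)
    bounds = np.concatenate([[0], cuts, [length]])
    exons = []
    for k in range(n_exons):
        s, e = int(bounds[2 * k]), int(bounds[2 * k + 1])
        if e <= s:
            e = s + 1
        exons.append((start + s, start + e))
    # guard monotonicity after the +1 fix-ups
    fixed = []
    prev = start
    for s, e in exons:
        s = max(s, prev)
        e = max(e, s + 1)
        fixed.append((s, min(e, end)))
        prev = fixed[-1][1] + 1
    if fixed[-1][1] < end:
        fixed[-1] = (fixed[-1][0], end)
    return tuple(fixed)


# ---------------------------------------------------------------------------
# restriction digestion


def digest_genome(
    genome: GenomeRef,
    recognition_site: str = PSTI_SITE,
    cut_offset: int = PSTI_CUT_OFFSET,
    size_min: int = 200,
    size_max: int = 500,
) -> list[Fragment]:
    """In-silico digestion: cut at every exact forward-strand site match.

    Cuts are placed at ``site_start + cut_offset``; fragments are the
    intervals between consecutive cuts plus the chromosome ends, and the
    ``selected`` flag marks fragments inside ``[size_min, size_max]``.
    """
    if set(recognition_site) - set("ACGT"):
        raise ValueError("recognition site must be over {A,C,G,T}")
    if not 0 <= cut_offset <= len(recognition_site):
        raise ValueError("cut_offset out of range")
    fragments: list[Fragment] = []
    for chrom in genome.chrom_names:
        seq = genome.sequences[chrom]
        cuts = [0]
        i = seq.find(recognition_site)
        while i != -1:
            pos = i + cut_offset
            if 0 < pos < len(seq):
                cuts.append(pos)
            i = seq.find(recognition_site, i + 1)
        cuts.append(len(seq))
        for s, e in zip(cuts[:-1], cuts[1:]):
            if e <= s:
                continue
            length = e - s
            fragments.append(
                Fragment(
                    chrom=chrom,
                    start=s,
                    end=e,
                    cpg_count=genome.cpg_count(chrom, s, e),
                    selected=size_min <= length <= size_max,
                )
            )
    return fragments


# ---------------------------------------------------------------------------
# methylome and capture


@dataclass(frozen=True)
class TruthDMR:
    fragment: Fragment
    delta: float
    up_group: str  # the group whose methylation was shifted upward


@dataclass
class MethylomeModel:
    """Per-group CpG methylation probabilities on the genome's CpG index."""

    groups: list[str]
    #: group -> chrom -> probability per CpG of ``genome.cpg_index[chrom]``
    probs: dict[str, dict[str, np.ndarray]]
    kappa: float = 1.0
    eps: float = 0.01
    truth_dmrs: list[TruthDMR] = field(default_factory=list)

    def expected_methylated(self, group: str, frag: Fragment, genome: GenomeRef) -> float:
        idx = genome.cpg_index[frag.chrom]
        lo = np.searchsorted(idx, frag.start)
        hi = np.searchsorted(idx, frag.end)
        return float(self.probs[group][frag.chrom][lo:hi].sum())


@dataclass
class SimTruth:
    truth_dmrs: list[TruthDMR]
    #: (sample, chrom, start, end, strand) per emitted read pair
    alignments: list[tuple[str, str, int, int, str]] = field(default_factory=list)
    barcodes: dict[str, str] = field(default_factory=dict)


def capture_probability(m, kappa: float = 1.0, eps: float = 0.01):
    """MeDIP capture probability of a molecule with *m* methylated CpGs.

    A saturating law ``(1 - eps) * m / (m + kappa) + eps``: enrichment grows
    with methyl-CpG load and plateaus, the qualitative antibody-capture
    behaviour; *eps* is residual background capture of unmethylated DNA.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if not 0 <= eps < 1:
        raise ValueError("eps must be in [0, 1)")
    m = np.asarray(m, dtype=float)
    out = (1 - eps) * m / (m + kappa) + eps
    return float(out) if out.ndim == 0 else out


def plant_methylome(
    genome: GenomeRef,
    fragments: list[Fragment],
    groups: list[str],
    baseline_meth: float = 0.1,
    island_meth: float = 0.7,
    n_dmrs: int = 0,
    delta: float = 0.5,
    seed: int = 0,
    kappa: float = 1.0,
    eps: float = 0.01,
    min_cpgs: int = 3,
) -> tuple[MethylomeModel, SimTruth]:
    """Assign per-CpG methylation probabilities and plant group differences.

    Every group starts from the same landscape (*island_meth* inside planted
    islands, *baseline_meth* elsewhere).  For each of *n_dmrs* randomly
    chosen selected fragments with at least *min_cpgs* CpGs, the CpG
    probabilities of one randomly chosen group are shifted by +-*delta*
    (direction chosen among the feasible signs), and the truth recorded.
    """
    for v in (baseline_meth, island_meth):
        if not 0 <= v <= 1:
            raise ValueError("methylation probabilities must be in [0, 1]")
    if not 0 < delta <= 1:
        raise ValueError("delta must be in (0, 1]")
    rng = np.random.default_rng(seed)
    base: dict[str, np.ndarray] = {}
    for chrom in genome.chrom_names:
        idx = genome.cpg_index[chrom]
        probs = np.full(idx.size, baseline_meth, dtype=float)
        for s, e in genome.islands.get(chrom, []):
            lo, hi = np.searchsorted(idx, [s, e])
            probs[lo:hi] = island_meth
        base[chrom] = probs
    model = MethylomeModel(
        groups=list(groups),
        probs={g: {c: base[c].copy() for c in genome.chrom_names} for g in groups},
        kappa=kappa,
        eps=eps,
    )
    truth: list[TruthDMR] = []
    eligible = [f for f in fragments if f.selected and f.cpg_count >= min_cpgs]
    if n_dmrs > len(eligible):
        raise ValueError(
            f"n_dmrs={n_dmrs} exceeds the {len(eligible)} selected fragments "
            f"with >= {min_cpgs} CpGs"
        )
    if n_dmrs:
        chosen = rng.choice(len(eligible), size=n_dmrs, replace=False)
        for j in chosen:
            frag = eligible[int(j)]
            group = groups[int(rng.integers(len(groups)))]
            idx = genome.cpg_index[frag.chrom]
            lo, hi = np.searchsorted(idx, [frag.start, frag.end])
            seg = model.probs[group][frag.chrom][lo:hi]
            feasible = []
            if (seg + delta <= 1).all():
                feasible.append(+1)
            if (seg - delta >= 0).all():
                feasible.append(-1)
            if not feasible:
                raise ValueError(
                    f"delta={delta} infeasible on fragment "
                    f"{frag.chrom}:{frag.start}-{frag.end}"
                )
            sign = feasible[int(rng.integers(len(feasible)))]
            model.probs[group][frag.chrom][lo:hi] = seg + sign * delta
            if sign > 0:
                up_group = group
            else:
                others = [g for g in groups if g != group]
                up_group = others[0] if others else group
            truth.append(TruthDMR(fragment=frag, delta=delta, up_group=up_group))
    model.truth_dmrs = truth
    return model, SimTruth(truth_dmrs=truth)


# ---------------------------------------------------------------------------
# sampling and reads


def make_sample_sheet(
    group_sizes: dict[str, int],
    tissues: list[str] | None = None,
    barcode_len: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample sheet with unique barcodes (columns sample/barcode/group/tissue)."""
    rng = np.random.default_rng(seed)
    tissues = tissues or ["A"]
    rows = []
    seen: set[str] = set()
    for tissue in tissues:
        for group, n in group_sizes.items():
            for i in range(n):
                while True:
                    bc = "".join("ACGT"[b] for b in rng.integers(0, 4, barcode_len))
                    if bc not in seen:
                        seen.add(bc)
                        break
                rows.append(
                    {
                        "sample": f"{tissue}_{group}{i + 1}",
                        "barcode": bc,
                        "group": group,
                        "tissue": tissue,
                    }
                )
    return pd.DataFrame(rows)


def fragment_weights(
    fragments: list[Fragment], methylome: MethylomeModel, genome: GenomeRef, group: str
) -> np.ndarray:
    """Capture weight per selected fragment for one group.

    The multinomial sampling weight is the capture law evaluated at the
    fragment's expected methylated-CpG count under the group's methylome.
    """
    m = np.array(
        [methylome.expected_methylated(group, f, genome) for f in fragments]
    )
    return capture_probability(m, methylome.kappa, methylome.eps)


def sample_fragment_counts(
    selected: list[Fragment],
    methylome: MethylomeModel,
    sample_sheet: pd.DataFrame,
    genome: GenomeRef,
    mean_fragments_per_sample: float,
    rng,
) -> dict[str, np.ndarray]:
    """Molecule multiplicities per selected fragment for every sample.

    Per-sample depth is Poisson around *mean_fragments_per_sample*; molecules
    are multinomial over selected fragments with capture-probability weights
    (pooled-library sequencing without explicit PCR modelling).
    """
    if not selected:
        raise ValueError("no selected fragments to sample from")
    weights = {
        g: fragment_weights(selected, methylome, genome, g)
        for g in sample_sheet["group"].unique()
    }
    out: dict[str, np.ndarray] = {}
    for row in sample_sheet.itertuples(index=False):
        w = weights[row.group]
        depth = rng.poisson(mean_fragments_per_sample)
        out[row.sample] = rng.multinomial(depth, w / w.sum())
    return out


def _apply_errors(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def simulate_medip_reads(
    genome: GenomeRef,
    fragments: list[Fragment],
    methylome: MethylomeModel,
    sample_sheet: pd.DataFrame,
    mean_fragments_per_sample: float,
    out_prefix: str,
    read_len: int = 100,
    seq_error: float = 0.0,
    seed: int = 0,
    gz: bool = True,
) -> SimTruth:
    """Emit multiplexed paired FASTQ files plus the truth alignments.

    Read 1 is ``barcode + CTGCA + fragment 5' sequence`` (on the sampled
    strand) and read 2 is the reverse complement of the fragment's 3' end,
    both *read_len* bases with fixed Phred "I" qualities; substitution
    errors are injected at *seq_error* after barcode/remnant assembly.
    """
    rng = np.random.default_rng(seed)
    selected = [f for f in fragments if f.selected]
    if not selected:
        raise ValueError("no selected fragments")
    min_len = min(f.length for f in selected)
    if read_len > min_len:
        raise ValueError(
            f"read_len={read_len} exceeds shortest selected fragment ({min_len} bp)"
        )
    barcodes = dict(zip(sample_sheet["sample"], sample_sheet["barcode"]))
    if len(set(barcodes.values())) != len(barcodes):
        raise ValueError("barcodes must be unique per sample")
    bc_lens = {len(b) for b in barcodes.values()}
    if len(bc_lens) != 1:
        raise ValueError("all barcodes must have equal length")
    bc_len = bc_lens.pop()
    genomic_len = read_len - bc_len - len(PSTI_REMNANT)
    if genomic_len <= 0:
        raise ValueError("read_len too short for barcode + remnant")

    counts = sample_fragment_counts(
        selected, methylome, sample_sheet, genome, mean_fragments_per_sample, rng
    )
    truth = SimTruth(truth_dmrs=methylome.truth_dmrs, barcodes=barcodes)
    suffix = ".fastq.gz" if gz else ".fastq"
    r1_path = f"{out_prefix}_R1{suffix}"
    r2_path = f"{out_prefix}_R2{suffix}"
    qual = "I" * read_len
    with _open_det(r1_path, gz) as r1, _open_det(r2_path, gz) as r2:
        read_id = 0
        for sample in sample_sheet["sample"]:
            bc = barcodes[sample]
            mult = counts[sample]
            for frag_i in np.flatnonzero(mult):
                frag = selected[int(frag_i)]
                fseq = genome.fetch(frag.chrom, frag.start, frag.end)
                for _ in range(int(mult[frag_i])):
                    strand = "+" if rng.random() < 0.5 else "-"
                    template = fseq if strand == "+" else revcomp(fseq)
                    s1 = bc + PSTI_REMNANT + template[:genomic_len]
                    s2 = revcomp(template[-read_len:])
                    s1 = _apply_errors(s1, seq_error, rng)
                    s2 = _apply_errors(s2, seq_error, rng)
                    name = f"rp{read_id}"
                    r1.write(f"@{name}/1\n{s1}\n+\n{qual}\n")
                    r2.write(f"@{name}/2\n{s2}\n+\n{qual}\n")
                    truth.alignments.append(
                        (sample, frag.chrom, frag.start, frag.end, strand)
                    )
                    read_id += 1
    return truth


class _open_det:
    """Text writer; gzip output has mtime pinned to 0 for byte determinism."""

    def __init__(self, path: str, gz: bool):
        self.path, self.gz = path, gz

    def __enter__(self):
        if self.gz:
            self._raw = open(self.path, "wb")
            self._gz = gzip.GzipFile(filename="", mode="wb", fileobj=self._raw, mtime=0)
            import io as _io

            self._f = _io.TextIOWrapper(self._gz, encoding="ascii")
        else:
            self._f = open(self.path, "w")
        return self._f

    def __exit__(self, *exc):
        self._f.flush()
        if self.gz:
            self._f.detach().close()
            self._raw.close()
        else:
            self._f.close()
        return False
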