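"""Configuration and end-to-end contrast driver.

Reproduces the study's contrast structure: per tissue, the enriched
environment group (E) is compared against the barren group (B) and its
stereotypy subgroups (BS = stereotypic, BN = non-stereotypic), giving up to
four contrasts {E/B, E/BS, E/BN, BS/BN} per tissue.  Each contrast runs the
full stage-1 (stack filter, peak calling, counting) and stage-2 (exact NB
testing) chain, followed by annotation, cross-contrast overlap statistics
and gene-set over-representation, with a deterministic run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import coupling as cpl
from . import coverage as cov
from . import enrich
from . import io as gio
from . import overlap as ovl
from . import simulate as sim
from .core import FragmentSet, GenomeRef
from .dmr import ContrastSpec, DMRModel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 1
    # stage-1 / stage-2 statistical parameters
    p_stack: float = 0.001
    roi_fdr: float = 0.1
    window_bp: int = 300
    step_bp: int = 100
    min_row_sum: int = 10
    dmr_p: float = 0.05
    dmr_fdr: float = 0.6
    promoter_bp: int = 3000
    downstream_bp: int = 300
    n_perm: int = 100
    ora_fdr: float = 0.1
    # library / simulator parameters
    capture_kappa: float = 1.0
    capture_eps: float = 0.01
    size_min: int = 200
    size_max: int = 500
    read_len: int = 100
    n_chrom: int = 2
    chrom_length_bp: int = 1_000_000
    gc_fraction: float = 0.42
    island_density: float = 0.02
    site_spacing_bp: tuple[int, int] = (150, 900)
    baseline_meth: float = 0.1
    island_meth: float = 0.7
    n_dmrs: int = 20
    delta: float = 0.5
    mean_fragments_per_sample: float = 30_000.0
    n_genes: int = 80
    group_sizes: dict = field(default_factory=lambda: {"E": 9, "BS": 5, "BN": 4})
    tissues: tuple[str, ...] = ("A",)

    def __post_init__(self):
        for name in ("p_stack", "roi_fdr", "dmr_p", "dmr_fdr", "ora_fdr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.window_bp <= 0 or self.step_bp <= 0:
            raise ValueError("window sizes must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("site_spacing_bp", "tissues"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self._canonical(), fh, sort_keys=True)

    def _canonical(self) -> dict:
        d = asdict(self)
        d["site_spacing_bp"] = list(d["site_spacing_bp"])
        d["tissues"] = list(d["tissues"])
        return d

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self._canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def contrasts_from_sheet(sheet: pd.DataFrame) -> list[ContrastSpec]:
    """Auto-generate the {E/B, E/BS, E/BN, BS/BN} x tissue contrast list.

    B is the union of all barren-environment labels (B, BS, BN) present.
    Contrasts with fewer than 2 samples on a side are skipped with a log
    message.
    """
    contrasts = []
    for tissue, sub in sheet.groupby("tissue", sort=True):
        groups = {
            g: tuple(sub.loc[sub["group"] == g, "sample"])
            for g in sub["group"].unique()
        }
        barren = tuple(
            s for g in ("B", "BS", "BN") for s in groups.get(g, ())
        )
        pairs = []
        if "E" in groups and barren:
            pairs.append((f"{tissue}-E/B", groups["E"], barren))
        if "E" in groups and "BS" in groups:
            pairs.append((f"{tissue}-E/BS", groups["E"], groups["BS"]))
        if "E" in groups and "BN" in groups:
            pairs.append((f"{tissue}-E/BN", groups["E"], groups["BN"]))
        if "BS" in groups and "BN" in groups:
            pairs.append((f"{tissue}-BS/BN", groups["BS"], groups["BN"]))
        for name, g1, g2 in pairs:
            if len(g1) < 2 or len(g2) < 2:
                logger.info("skipping %s: fewer than 2 samples per side", name)
                continue
            contrasts.append(
                ContrastSpec(name=name, group1=g1, group2=g2, tissue=str(tissue))
            )
    return contrasts


@dataclass
class SimulatedDataset:
    genome: GenomeRef
    fragments: list
    selected: list
    gene_models: list
    gene_sets: dict
    methylome: sim.MethylomeModel
    truth: sim.SimTruth
    sample_sheet: pd.DataFrame
    #: per-sample molecule multiplicities over ``selected``
    sample_counts: dict[str, np.ndarray]

    def sample_pools(self) -> dict[str, FragmentSet]:
        return {
            s: FragmentSet.from_counts(self.selected, c)
            for s, c in self.sample_counts.items()
        }


def simulate_dataset(config: PipelineConfig) -> SimulatedDataset:
    """Generate the full synthetic study under one seed."""
    rng_seed = np.random.SeedSequence(config.seed)
    seeds = rng_seed.generate_state(5) % (2**31)
    genome = sim.simulate_genome(
        n_chrom=config.n_chrom,
        chrom_length_bp=config.chrom_length_bp,
        gc_fraction=config.gc_fraction,
        island_density=config.island_density,
        seed=int(seeds[0]),
        site_spacing_bp=config.site_spacing_bp,
    )
    fragments = sim.digest_genome(
        genome, size_min=config.size_min, size_max=config.size_max
    )
    selected = [f for f in fragments if f.selected]
    gene_models = sim.simulate_gene_models(genome, config.n_genes, seed=int(seeds[1]))
    sheet = sim.make_sample_sheet(
        config.group_sizes, tissues=list(config.tissues), seed=int(seeds[2])
    )
    groups = list(sheet["group"].unique())
    methylome, truth = sim.plant_methylome(
        genome,
        fragments,
        groups,
        baseline_meth=config.baseline_meth,
        island_meth=config.island_meth,
        n_dmrs=config.n_dmrs,
        delta=config.delta,
        seed=int(seeds[3]),
        kappa=config.capture_kappa,
        eps=config.capture_eps,
    )
    rng = np.random.default_rng(int(seeds[4]))
    counts = sim.sample_fragment_counts(
        selected, methylome, sheet, genome, config.mean_fragments_per_sample, rng
    )
    gene_sets = simulate_gene_sets(gene_models, n_sets=15, rng=rng)
    return SimulatedDataset(
        genome=genome,
        fragments=fragments,
        selected=selected,
        gene_models=gene_models,
        gene_sets=gene_sets,
        methylome=methylome,
        truth=truth,
        sample_sheet=sheet,
        sample_counts=counts,
    )


def simulate_gene_sets(gene_models, n_sets: int, rng, size_range=(5, 25)) -> dict:
    ids = [g.gene_id for g in gene_models]
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], min(size_range[1], len(ids)) + 1))
        members = rng.choice(len(ids), size=size, replace=False)
        sets[f"set{i:02d}"] = {ids[int(j)] for j in members}
    return sets


def run_contrasts(
    config: PipelineConfig,
    dataset: SimulatedDataset,
    out_dir: str,
) -> dict:
    """Execute every contrast end to end and write the output tree.

    Per contrast: ROI BED, count matrix TSV, DMR table, annotation, feature
    fractions, and TSS-distance histogram.  Across contrasts: per-tissue
    Venn cells, permutation overlap reports, and per-contrast ORA tables.
    Returns the (JSON-serialized) run manifest.
    """
    os.makedirs(out_dir, exist_ok=True)
    sheet = dataset.sample_sheet
    contrasts = contrasts_from_sheet(sheet)
    filtered_counts: dict[str, np.ndarray] = {}
    n_removed = 0
    for s, counts in dataset.sample_counts.items():
        filt, removed, _ = cov.stack_filter_multiplicities(counts, config.p_stack)
        filtered_counts[s] = filt
        n_removed += removed
    pools = {
        s: FragmentSet.from_counts(dataset.selected, c)
        for s, c in filtered_counts.items()
    }
    manifest: dict = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "n_samples": len(sheet),
        "n_molecules": int(sum(c.sum() for c in dataset.sample_counts.values())),
        "n_stack_removed": int(n_removed),
        "contrasts": {},
    }
    dmr_regions: dict[str, list] = {}
    dmr_genes: dict[str, set] = {}
    roi_universe_by_contrast: dict[str, list] = {}

    for contrast in contrasts:
        cdir = os.path.join(out_dir, contrast.name.replace("/", "_"))
        os.makedirs(cdir, exist_ok=True)
        pool1 = _merge_pools([pools[s] for s in contrast.group1])
        pool2 = _merge_pools([pools[s] for s in contrast.group2])
        rois = cov.call_rois(
            pool1,
            pool2,
            dataset.genome,
            window_bp=config.window_bp,
            step_bp=config.step_bp,
            roi_fdr=config.roi_fdr,
        )
        gio.write_rois_bed(rois, os.path.join(cdir, "rois.bed"))
        entry = {"n_rois": len(rois)}
        if not rois:
            manifest["contrasts"][contrast.name] = entry | {
                "n_tested": 0,
                "n_dmr_exploratory": 0,
                "n_dmr_top": 0,
            }
            dmr_regions[contrast.name] = []
            dmr_genes[contrast.name] = set()
            continue
        samples = list(contrast.group1) + list(contrast.group2)
        cm = cov.count_matrix(rois, {s: pools[s] for s in samples})
        cm.to_frame().to_csv(os.path.join(cdir, "counts.tsv"), sep="\t")
        coupling = cpl.compute_coupling(rois, dataset.genome)
        cal_rows = []
        calibrations = []
        for j, s in enumerate(cm.samples):
            try:
                cal = cpl.fit_calibration(cm.counts[:, j], coupling)
            except ValueError:
                cal = cpl.CalibrationFit(
                    intercept=float(cm.counts[:, j].mean()),
                    slope=0.0,
                    c_max_fit=0,
                    bin_values=np.array([0]),
                    bin_means=np.array([cm.counts[:, j].mean()]),
                    residuals=np.array([0.0]),
                )
            calibrations.append(cal)
            cal_rows.append(
                {"sample": s, "a": cal.intercept, "b": cal.slope, "c_max_fit": cal.c_max_fit}
            )
        pd.DataFrame(cal_rows).to_csv(
            os.path.join(cdir, "calibration.tsv"), sep="\t", index=False
        )
        rms = cpl.rms_transform(cm.counts, coupling, calibrations)
        pd.DataFrame(rms, index=cm.to_frame().index, columns=cm.samples).to_csv(
            os.path.join(cdir, "rms.tsv"), sep="\t"
        )
        results = DMRModel(cm, contrast).fit(
            min_row_sum=config.min_row_sum,
            p_thr=config.dmr_p,
            fdr_thr=config.dmr_fdr,
        )
        results.to_frame().to_csv(os.path.join(cdir, "dmrs.tsv"), sep="\t", index=False)
        exploratory = results.exploratory
        annotated = ann.annotate_dmrs(
            exploratory,
            dataset.gene_models,
            promoter_bp=config.promoter_bp,
            downstream_bp=config.downstream_bp,
        )
        pd.DataFrame([a.__dict__ for a in annotated]).to_csv(
            os.path.join(cdir, "annotation.tsv"), sep="\t", index=False
        )
        if annotated:
            ann.feature_distribution(annotated).to_csv(
                os.path.join(cdir, "feature_fractions.tsv"), sep="\t"
            )
            ann.tss_distance_histogram(annotated).to_csv(
                os.path.join(cdir, "tss_hist.tsv"), sep="\t"
            )
        entry |= {
            "n_tested": results.n_tested,
            "n_dmr_exploratory": len(exploratory),
            "n_dmr_top": len(results.top),
        }
        manifest["contrasts"][contrast.name] = entry
        dmr_regions[contrast.name] = [
            (r.chrom, r.start, r.end) for r in exploratory
        ]
        dmr_genes[contrast.name] = set(enrich.map_dmrs_to_genes(annotated))
        roi_universe_by_contrast[contrast.name] = [
            (r.chrom, r.start, r.end) for r in rois
        ]
        # ORA against the genes carrying >= 1 tested ROI
        tested_rois = [r for r, rec in zip(rois, results.records)]
        universe_ann = ann.annotate_dmrs(tested_rois, dataset.gene_models)
        universe = enrich.map_dmrs_to_genes(universe_ann)
        if universe and dmr_genes[contrast.name]:
            ora = enrich.ora_test(
                sorted(dmr_genes[contrast.name]), universe, dataset.gene_sets,
                fdr_report=config.ora_fdr,
            )
            enrich.results_to_frame(ora).to_csv(
                os.path.join(cdir, "ora.tsv"), sep="\t", index=False
            )

    # cross-contrast overlap statistics, per tissue
    perm_rows, venn_rows = [], []
    by_tissue: dict[str, list[str]] = {}
    for c in contrasts:
        by_tissue.setdefault(c.tissue, []).append(c.name)
    for tissue, names in sorted(by_tissue.items()):
        sets = {n: dmr_regions[n] for n in names if dmr_regions.get(n)}
        if len(sets) >= 2:
            venn = ovl.find_overlaps(sets)
            for sig, count in sorted(venn.venn_counts.items(), key=lambda kv: sorted(kv[0])):
                venn_rows.append(
                    {"tissue": tissue, "cell": "&".join(sorted(sig)), "count": count}
                )
            names_with = sorted(sets)
            universe = sorted(
                {iv for n in names_with for iv in roi_universe_by_contrast[n]}
            )
            for i in range(len(names_with)):
                for j in range(i + 1, len(names_with)):
                    rep = ovl.permutation_overlap_test(
                        sets[names_with[i]],
                        sets[names_with[j]],
                        universe,
                        n_perm=config.n_perm,
                        seed=config.seed,
                    )
                    perm_rows.append(
                        {
                            "tissue": tissue,
                            "set_a": names_with[i],
                            "set_b": names_with[j],
                            "observed": rep.observed,
                            "null_mean": rep.null_mean,
                            "null_sd": rep.null_sd,
                            "p": rep.p,
                            "n_perm": rep.n_perm,
                        }
                    )
    if venn_rows:
        pd.DataFrame(venn_rows).to_csv(
            os.path.join(out_dir, "venn_cells.tsv"), sep="\t", index=False
        )
    if perm_rows:
        pd.DataFrame(perm_rows).to_csv(
            os.path.join(out_dir, "permutation.tsv"), sep="\t", index=False
        )
    gene_cells = ovl.gene_set_overlap({k: v for k, v in dmr_genes.items() if v})
    manifest["gene_overlap_cells"] = {
        "&".join(sorted(sig)): n for sig, n in sorted(
            gene_cells.items(), key=lambda kv: sorted(kv[0])
        )
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _merge_pools(pools: list[FragmentSet]) -> FragmentSet:
    merged: dict[str, tuple[list, list]] = {}
    for p in pools:
        for chrom, (s, e) in p.intervals.items():
            acc = merged.setdefault(chrom, ([], []))
            acc[0].append(s)
            acc[1].append(e)
    return FragmentSet(
        {c: (np.concatenate(s), np.concatenate(e)) for c, (s, e) in merged.items()}
    )
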