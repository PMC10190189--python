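"""Simulator: genome, digestion, methylome planting, capture, reads."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbsmedip import simulate as sim
from gbsmedip.core import GenomeRef, revcomp


class TestSimulateGenome:
    def test_iid_cpg_density_matches_binomial_expectation(self):
        genome = sim.simulate_genome(1, 200_000, gc_fraction=0.5, island_density=0.0, seed=3)
        n = genome.total_bp - 1
        expected = 1 / 16  # P(C) * P(G) at GC 0.5
        se = np.sqrt(expected * (1 - expected) / n)
        observed = genome.total_cpgs / n
        assert abs(observed - expected) < 3 * se

    def test_same_seed_reproduces_sequence(self):
        a = sim.simulate_genome(1, 10_000, 0.5, 0.01, seed=7)
        b = sim.simulate_genome(1, 10_000, 0.5, 0.01, seed=7)
        assert a.sequences == b.sequences

    def test_island_cpg_density_at_least_5x_background(self):
        genome = sim.simulate_genome(1, 300_000, 0.42, island_density=0.01, seed=5)
        ivs = genome.islands["chr1"]
        assert ivs
        inside_bp = sum(e - s for s, e in ivs)
        inside_cpg = sum(genome.cpg_count("chr1", s, e) for s, e in ivs)
        outside_bp = genome.total_bp - inside_bp
        outside_cpg = genome.total_cpgs - inside_cpg
        assert (inside_cpg / inside_bp) >= 5 * (outside_cpg / outside_bp)

    def test_cpg_index_positions_are_cg(self, small_genome):
        seq = small_genome.sequences["chr1"]
        idx = small_genome.cpg_index["chr1"]
        assert all(seq[p : p + 2] == "CG" for p in idx[:200])

    def test_invalid_gc_fraction_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_genome(1, 10_000, gc_fraction=1.5, island_density=0, seed=0)


class TestGeneModels:
    def test_placed_genes_satisfy_invariants(self, study_genome):
        genes = sim.simulate_gene_models(study_genome, 50, seed=9)
        assert len(genes) == 50
        assert {g.strand for g in genes} == {"+", "-"}
        by_chrom = {}
        for g in genes:
            # dataclass __post_init__ already enforces exon invariants
            assert g.tss == (g.tx_start if g.strand == "+" else g.tx_end - 1)
            assert g.tx_end <= study_genome.lengths[g.chrom]
            by_chrom.setdefault(g.chrom, []).append((g.tx_start, g.tx_end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_same_seed_identical_models(self, small_genome):
        a = sim.simulate_gene_models(small_genome, 8, seed=4, gene_length_bp=(1000, 3000))
        b = sim.simulate_gene_models(small_genome, 8, seed=4, gene_length_bp=(1000, 3000))
        assert a == b


class TestDigestGenome:
    def test_hand_worked_cut_position(self):
        genome = GenomeRef(chrom_names=["c"], sequences={"c": "TTCTGCAGAA" + "A" * 9990})
        frags = sim.digest_genome(genome)
        assert (frags[0].start, frags[0].end) == (0, 7)
        assert frags[1].start == 7

    def test_no_site_yields_whole_chromosome(self):
        genome = GenomeRef(chrom_names=["c"], sequences={"c": "AT" * 5000})
        frags = sim.digest_genome(genome)
        assert len(frags) == 1
        assert (frags[0].start, frags[0].end) == (0, 10_000)
        assert not frags[0].selected  # 10 kb outside 200-500

    def test_constructed_spacing_selects_internal_fragments(self):
        site = sim.PSTI_SITE
        seq = ("A" * (300 - len(site)) + site) * 40 + "A" * 150
        genome = GenomeRef(chrom_names=["c"], sequences={"c": seq})
        frags = sim.digest_genome(genome)
        internal = frags[1:-1]
        assert internal and all(f.selected for f in internal)
        assert all(f.length == 300 for f in internal)
        # terminal fragments selected iff their length is in [200, 500]
        for f in (frags[0], frags[-1]):
            assert f.selected == (200 <= f.length <= 500)

    def test_fragment_cpg_counts_match_substring_scan(self, small_genome, small_fragments):
        for f in small_fragments[:50]:
            expected = small_genome.sequences[f.chrom].count("CG", f.start, f.end)
            # count may include a CG starting at end-1; the index excludes it
            expected = sum(
                1
                for p in range(f.start, f.end)
                if small_genome.sequences[f.chrom][p : p + 2] == "CG"
            )
            assert f.cpg_count == expected


class TestPlantMethylome:
    def test_bookkeeping_of_planted_dmrs(self, small_genome, small_fragments):
        meth, truth = sim.plant_methylome(
            small_genome, small_fragments, ["E", "B"], n_dmrs=10, delta=0.5, seed=2
        )
        assert len(truth.truth_dmrs) == 10
        assert all(t.fragment.selected for t in truth.truth_dmrs)
        assert all(t.fragment.cpg_count >= 3 for t in truth.truth_dmrs)

    def test_island_probabilities_differ_from_baseline(self, small_genome, small_fragments):
        meth, _ = sim.plant_methylome(
            small_genome, small_fragments, ["E"], baseline_meth=0.8,
            island_meth=0.2, n_dmrs=0, seed=2,
        )
        probs = meth.probs["E"]["chr1"]
        idx = small_genome.cpg_index["chr1"]
        in_island = np.zeros(idx.size, dtype=bool)
        for s, e in small_genome.islands["chr1"]:
            lo, hi = np.searchsorted(idx, [s, e])
            in_island[lo:hi] = True
        assert in_island.any() and (~in_island).any()
        assert probs[in_island].mean() < probs[~in_island].mean()

    def test_infeasible_delta_rejected(self, small_genome, small_fragments):
        with pytest.raises(ValueError):
            sim.plant_methylome(
                small_genome, small_fragments, ["E", "B"],
                baseline_meth=0.5, island_meth=0.5, n_dmrs=5, delta=0.9, seed=2,
            )

    def test_probabilities_stay_in_unit_interval(self, small_genome, small_fragments):
        meth, _ = sim.plant_methylome(
            small_genome, small_fragments, ["E", "B"], n_dmrs=15, delta=0.5, seed=3
        )
        for g in meth.groups:
            for arr in meth.probs[g].values():
                assert (arr >= 0).all() and (arr <= 1).all()


class TestCapture:
    def test_half_saturation_point(self):
        assert sim.capture_probability(1, kappa=1.0, eps=0.0) == pytest.approx(0.5)

    def test_zero_methylation_zero_capture(self):
        assert sim.capture_probability(0, kappa=1.0, eps=0.0) == 0.0

    @settings(deadline=None, max_examples=50)
    @given(
        kappa=st.floats(0.1, 50),
        eps=st.floats(0, 0.5),
        m=st.integers(0, 100),
    )
    def test_monotone_in_methylated_count(self, kappa, eps, m):
        lo = sim.capture_probability(m, kappa, eps)
        hi = sim.capture_probability(m + 1, kappa, eps)
        assert hi >= lo


@pytest.fixture(scope="module")
def read_run(tmp_path_factory, small_genome, small_fragments):
    sheet = sim.make_sample_sheet({"E": 2, "B": 2}, seed=5)
    meth, _ = sim.plant_methylome(
        small_genome, small_fragments, ["E", "B"], n_dmrs=0, seed=2
    )
    out = tmp_path_factory.mktemp("reads") / "run"
    truth = sim.simulate_medip_reads(
        small_genome, small_fragments, meth, sheet, 300, str(out),
        seed=42, gz=False,
    )
    return sheet, truth, out


class TestReads:
    def test_reads_match_truth_intervals(self, read_run, small_genome):
        sheet, truth, out = read_run
        with open(f"{out}_R1.fastq") as fh:
            lines = fh.read().splitlines()
        seqs = lines[1::4]
        assert len(seqs) == len(truth.alignments)
        bc_len = len(sheet["barcode"].iloc[0])
        for seq, (sample, chrom, start, end, strand) in zip(seqs[:100], truth.alignments):
            assert seq[:bc_len] == truth.barcodes[sample]
            assert seq[bc_len : bc_len + 5] == sim.PSTI_REMNANT
            frag = small_genome.fetch(chrom, start, end)
            template = frag if strand == "+" else revcomp(frag)
            genomic = seq[bc_len + 5 :]
            assert template.startswith(genomic)

    def test_read2_is_reverse_complement_of_fragment_end(self, read_run, small_genome):
        sheet, truth, out = read_run
        with open(f"{out}_R2.fastq") as fh:
            seqs = fh.read().splitlines()[1::4]
        for seq, (sample, chrom, start, end, strand) in zip(seqs[:50], truth.alignments):
            frag = small_genome.fetch(chrom, start, end)
            template = frag if strand == "+" else revcomp(frag)
            assert seq == revcomp(template[-100:])

    def test_fixed_seed_reproduces_fastq_bytes(
        self, tmp_path, small_genome, small_fragments
    ):
        sheet = sim.make_sample_sheet({"E": 2}, seed=5)
        meth, _ = sim.plant_methylome(small_genome, small_fragments, ["E"], seed=2)
        outs = []
        for tag in ("a", "b"):
            out = tmp_path / tag
            sim.simulate_medip_reads(
                small_genome, small_fragments, meth, sheet, 100, str(out), seed=9
            )
            outs.append((out.parent / f"{tag}_R1.fastq.gz").read_bytes())
        assert outs[0] == outs[1]

    def test_read_longer_than_fragment_rejected(self, small_genome, small_fragments):
        sheet = sim.make_sample_sheet({"E": 2}, seed=5)
        meth, _ = sim.plant_methylome(small_genome, small_fragments, ["E"], seed=2)
        with pytest.raises(ValueError):
            sim.simulate_medip_reads(
                small_genome, small_fragments, meth, sheet, 10, "/tmp/x",
                read_len=5000, seed=1,
            )
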