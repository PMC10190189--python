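"""Stage-2 differential-methylation statistics.

The model: per-sample ROI counts are negative binomial with a common
per-ROI dispersion, sample-specific size factors, and a group effect on the
mean.  Each ROI is tested with a two-sided exact test conditional on its
total count: under equal adjusted group means, the split of the total
between the two groups follows a beta-binomial with shape parameters
``S_g / phi`` (``S_g`` = sum of the group's size factors), which reduces to
a conditional binomial at ``phi = 0``.  The p-value sums the probabilities
of all splits no more probable than the observed one.

The public surface is statsmodels-style: build a :class:`DMRModel` from a
count matrix and a contrast, call :meth:`DMRModel.fit`, and read estimates,
tiers and the summary table off the returned :class:`DMRResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln
from scipy.stats import trim_mean
from statsmodels.stats.multitest import multipletests

_TIE_REL_TOL = 1e-8


@dataclass(frozen=True)
class ContrastSpec:
    """One tissue-specific two-group comparison."""

    name: str
    group1: tuple[str, ...]
    group2: tuple[str, ...]
    tissue: str = ""

    def __post_init__(self):
        if not self.group1 or not self.group2:
            raise ValueError("both groups must be non-empty")
        if set(self.group1) & set(self.group2):
            raise ValueError("groups must be disjoint")


@dataclass
class DispersionModel:
    common: float
    per_roi: np.ndarray
    raw: np.ndarray
    n0: float = 10.0


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def size_factors(counts: np.ndarray, min_positive_rois: int = 10) -> np.ndarray:
    """Median-of-ratios size factors, scaled to geometric mean 1.

    Computed over ROIs with a positive geometric mean; falls back to
    total-count ratios when fewer than *min_positive_rois* such ROIs exist.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("all-zero count matrix")
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    log_geo = log_counts.mean(axis=1)
    ok = np.isfinite(log_geo)
    if ok.sum() >= min_positive_rois:
        ratios = log_counts[ok] - log_geo[ok, None]
        factors = np.exp(np.median(ratios, axis=0))
    else:
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total counts")
        factors = totals / totals.mean()
    return factors / np.exp(np.log(factors).mean())


def estimate_dispersion(
    counts: np.ndarray, group_index: np.ndarray, factors: np.ndarray, n0: float = 10.0
) -> DispersionModel:
    """Method-of-moments NB dispersion with shrinkage toward a common value.

    Per ROI, size-factor-normalized counts are centred within groups (group
    means replaced by the grand mean) and the excess of variance over mean
    gives ``phi_hat = max(0, (s^2 - mu) / mu^2)``.  The common dispersion is
    a 20% trimmed mean of the per-ROI estimates, and each ROI's value is the
    precision-weighted blend ``(d*phi_hat + n0*phi_c) / (d + n0)`` with
    ``d`` the residual degrees of freedom.
    """
    counts = np.asarray(counts, dtype=float)
    group_index = np.asarray(group_index)
    labels = np.unique(group_index)
    if labels.size < 2:
        raise ValueError("need two groups")
    for g in labels:
        if (group_index == g).sum() < 2:
            raise ValueError("each group needs >= 2 samples")
    y = counts / factors[None, :]
    centred = y.copy()
    grand = y.mean(axis=1, keepdims=True)
    for g in labels:
        cols = group_index == g
        centred[:, cols] = y[:, cols] - y[:, cols].mean(axis=1, keepdims=True)
    centred += grand
    n = counts.shape[1]
    d = n - labels.size
    s2 = centred.var(axis=1, ddof=labels.size) * 1.0
    mu = grand[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (s2 - mu) / mu**2, 0.0)
    raw = np.maximum(raw, 0.0)
    common = float(trim_mean(raw, 0.2)) if raw.size else 0.0
    per_roi = (d * raw + n0 * common) / (d + n0)
    return DispersionModel(common=common, per_roi=per_roi, raw=raw, n0=n0)


def _conditional_logpmf(total: int, s1: float, s2: float, phi: float) -> np.ndarray:
    """log P(group-1 sum = k | total) for k = 0..total.

    Beta-binomial with alpha = s1/phi, beta = s2/phi; binomial limit at
    phi = 0 with success probability s1 / (s1 + s2).
    """
    k = np.arange(total + 1)
    if phi <= 0:
        pi = s1 / (s1 + s2)
        return (
            gammaln(total + 1)
            - gammaln(k + 1)
            - gammaln(total - k + 1)
            + k * np.log(pi)
            + (total - k) * np.log1p(-pi)
        )
    a, b = s1 / phi, s2 / phi
    return (
        gammaln(total + 1)
        - gammaln(k + 1)
        - gammaln(total - k + 1)
        + betaln(k + a, total - k + b)
        - betaln(a, b)
    )


def exact_nb_pvalue(k1: int, total: int, s1: float, s2: float, phi: float) -> float:
    """Two-sided exact conditional NB test p-value.

    Sums the probabilities of all splits of *total* between the groups whose
    probability does not exceed (within a small relative tolerance) that of
    the observed group-1 sum *k1*.
    """
    if not 0 <= k1 <= total:
        raise ValueError("observed count outside [0, total]")
    if total == 0:
        return 1.0
    logpmf = _conditional_logpmf(total, s1, s2, phi)
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    obs = pmf[k1]
    return float(min(1.0, pmf[pmf <= obs * (1 + _TIE_REL_TOL)].sum()))


@dataclass(frozen=True)
class DMRRecord:
    roi_name: str
    chrom: str
    start: int
    end: int
    mean1: float
    mean2: float
    log2fc: float
    phi: float
    p: float
    q: float
    tier: str
    hyper_group: str


@dataclass
class DMRResults:
    """Fitted differential-methylation results for one contrast."""

    contrast: ContrastSpec
    records: list[DMRRecord]
    factors: np.ndarray
    dispersion: DispersionModel
    n_input_rois: int
    n_tested: int
    min_row_sum: int
    p_thr: float
    fdr_thr: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    @property
    def exploratory(self) -> list[DMRRecord]:
        return [r for r in self.records if r.p <= self.p_thr]

    @property
    def top(self) -> list[DMRRecord]:
        return [r for r in self.records if r.q <= self.fdr_thr]

    def summary(self) -> str:
        lines = [
            f"Differential methylation: {self.contrast.name}",
            f"  samples: {len(self.contrast.group1)} vs {len(self.contrast.group2)}"
            f" ({', '.join(self.contrast.group1)} | {', '.join(self.contrast.group2)})",
            f"  regions in: {self.n_input_rois}; tested (row sum >= "
            f"{self.min_row_sum}): {self.n_tested}",
            f"  common dispersion: {self.dispersion.common:.4f}",
            f"  exploratory DMRs (p <= {self.p_thr}): {len(self.exploratory)}",
            f"  top DMRs (FDR <= {self.fdr_thr}): {len(self.top)}",
        ]
        head = self.to_frame().sort_values("p").head(10)
        if len(head):
            lines.append(head.to_string(index=False))
        return "\n".join(lines)


class DMRModel:
    """Exact conditional NB model of differential ROI coverage.

    Parameters
    ----------
    count_matrix : CountMatrix
        ROI x sample counts with library sizes (stage-1 output).
    contrast : ContrastSpec
        The two sample groups to compare; all named samples must be columns
        of the count matrix.
    """

    def __init__(self, count_matrix, contrast: ContrastSpec):
        missing = (set(contrast.group1) | set(contrast.group2)) - set(
            count_matrix.samples
        )
        if missing:
            raise ValueError(f"contrast samples absent from matrix: {sorted(missing)}")
        self.count_matrix = count_matrix
        self.contrast = contrast
        cols = list(contrast.group1) + list(contrast.group2)
        col_idx = [count_matrix.samples.index(s) for s in cols]
        self.counts = np.asarray(count_matrix.counts)[:, col_idx]
        self.group_index = np.array(
            [0] * len(contrast.group1) + [1] * len(contrast.group2)
        )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, group1, group2, name="contrast"):
        """Build from a ROI-indexed DataFrame of counts (columns = samples)."""
        from .core import CountMatrix, ROI

        rois = []
        for roi_id in frame.index:
            try:
                chrom, span = str(roi_id).split(":")
                start, end = (int(x) for x in span.split("-"))
            except ValueError:
                chrom, start, end = str(roi_id), 0, 1
            rois.append(ROI(chrom=chrom, start=start, end=end, name=str(roi_id)))
        cm = CountMatrix(
            rois=rois,
            samples=list(frame.columns),
            counts=frame.to_numpy(),
            library_sizes=frame.sum(axis=0).to_numpy(),
        )
        return cls(cm, ContrastSpec(name=name, group1=tuple(group1), group2=tuple(group2)))

    def fit(
        self,
        min_row_sum: int = 10,
        p_thr: float = 0.05,
        fdr_thr: float = 0.6,
        n0: float = 10.0,
        factors: np.ndarray | None = None,
    ) -> DMRResults:
        """Filter, normalize, test every ROI, and BH-adjust.

        ROIs whose total count across the contrast's samples is below
        *min_row_sum* are dropped before testing (and before BH).  Tiers are
        assigned independently: ``exploratory`` at ``p <= p_thr`` and
        ``top`` at ``q <= fdr_thr``.
        """
        counts = self.counts
        keep = counts.sum(axis=1) >= min_row_sum
        tested = counts[keep]
        rois = [r for r, k in zip(self.count_matrix.rois, keep) if k]
        if factors is None:
            factors = size_factors(tested if keep.sum() else counts)
        disp = estimate_dispersion(tested, self.group_index, factors, n0=n0)
        g1 = self.group_index == 0
        s1 = float(factors[g1].sum())
        s2 = float(factors[~g1].sum())
        k1 = tested[:, g1].sum(axis=1)
        totals = tested.sum(axis=1)
        pvals = np.array(
            [
                exact_nb_pvalue(int(k), int(t), s1, s2, float(phi))
                for k, t, phi in zip(k1, totals, disp.per_roi)
            ]
        )
        qvals = bh_adjust(pvals)
        norm = tested / factors[None, :]
        m1 = norm[:, g1].mean(axis=1) if g1.any() else np.zeros(len(tested))
        m2 = norm[:, ~g1].mean(axis=1)
        log2fc = np.log2((m1 + 0.5) / (m2 + 0.5))
        name1 = _group_label(self.contrast.group1)
        name2 = _group_label(self.contrast.group2)
        records = []
        for i, roi in enumerate(rois):
            if pvals[i] <= p_thr and qvals[i] <= fdr_thr:
                tier = "top"
            elif pvals[i] <= p_thr:
                tier = "exploratory"
            elif qvals[i] <= fdr_thr:
                tier = "top"
            else:
                tier = "none"
            hyper = f"{name1}>{name2}" if m1[i] >= m2[i] else f"{name2}>{name1}"
            records.append(
                DMRRecord(
                    roi_name=roi.name,
                    chrom=roi.chrom,
                    start=roi.start,
                    end=roi.end,
                    mean1=float(m1[i]),
                    mean2=float(m2[i]),
                    log2fc=float(log2fc[i]),
                    phi=float(disp.per_roi[i]),
                    p=float(pvals[i]),
                    q=float(qvals[i]),
                    tier=tier,
                    hyper_group=hyper,
                )
            )
        return DMRResults(
            contrast=self.contrast,
            records=records,
            factors=factors,
            dispersion=disp,
            n_input_rois=len(self.count_matrix.rois),
            n_tested=int(keep.sum()),
            min_row_sum=min_row_sum,
            p_thr=p_thr,
            fdr_thr=fdr_thr,
        )


def _group_label(samples) -> str:
    """Common group label of a sample tuple (e.g. 'E' from A_E1, A_E2)."""
    import re

    tags = set()
    for s in samples:
        m = re.match(r".*_([A-Za-z]+)\d*$", s)
        tags.add(m.group(1) if m else s)
    return tags.pop() if len(tags) == 1 else "g1"


def test_dmrs(
    count_matrix,
    contrast: ContrastSpec,
    min_row_sum: int = 10,
    p_thr: float = 0.05,
    fdr_thr: float = 0.6,
    n0: float = 10.0,
) -> DMRResults:
    """Procedural wrapper: fit a :class:`DMRModel` in one call."""
    return DMRModel(count_matrix, contrast).fit(
        min_row_sum=min_row_sum, p_thr=p_thr, fdr_thr=fdr_thr, n0=n0
    )
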