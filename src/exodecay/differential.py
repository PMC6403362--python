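"""Per-interval read counting and the differential-accumulation test.

Counts are modelled as negative binomial (variance = mu + alpha * mu^2).
Samples are normalized by median-of-ratios size factors; per-interval
dispersion is a pooled within-condition method-of-moments estimate floored
at 1e-8; a two-sided Wald test on the log2 fold change (pseudocount 0.5,
delta-method standard error) is Benjamini-Hochberg adjusted. An interval
is called upregulated upon depletion when the fold change is >= 2 and
padj < 0.05 (the padj cut is strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import Bed6Record, GenomicInterval

DISPERSION_FLOOR = 1e-8
LOG2FC_PSEUDOCOUNT = 0.5


@dataclass
class CountTable:
    """Interval x sample matrix of non-negative integer read counts."""

    intervals: list[tuple[str, GenomicInterval]]  # (name, interval)
    samples: list[tuple[str, str]]  # (sample_id, condition)
    counts: np.ndarray  # shape (n_intervals, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.intervals), len(self.samples)):
            raise ValueError("count matrix shape inconsistent with labels")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[name for name, _ in self.intervals],
            columns=[sid for sid, _ in self.samples],
        )

    def condition_columns(self, condition: str) -> np.ndarray:
        return np.array([j for j, (_, c) in enumerate(self.samples) if c == condition])


def count_reads(
    reads_per_sample: dict[str, Sequence[Bed6Record]],
    intervals: Sequence[tuple[str, GenomicInterval]],
    conditions: dict[str, str],
    unique_assignment: bool = False,
) -> CountTable:
    """Count reads overlapping each interval (>=1 bp, strand-agnostic).

    Default policy: a read overlapping k intervals increments all k.
    With ``unique_assignment`` a multi-overlap read counts only toward the
    interval with the largest overlap (ties to the leftmost).
    """
    names = [name for name, _ in intervals]
    samples = sorted(reads_per_sample)
    counts = np.zeros((len(names), len(samples)), dtype=np.int64)
    for j, sid in enumerate(samples):
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in {r.interval.chrom for r in reads_per_sample[sid]}:
            rs = np.array(
                [r.interval.start for r in reads_per_sample[sid] if r.interval.chrom == chrom],
                dtype=np.int64,
            )
            re_ = np.array(
                [r.interval.end for r in reads_per_sample[sid] if r.interval.chrom == chrom],
                dtype=np.int64,
            )
            by_chrom[chrom] = (rs, re_)
        if unique_assignment:
            best_ov = {c: np.zeros(v[0].size, dtype=np.int64) for c, v in by_chrom.items()}
            best_idx = {c: np.full(v[0].size, -1, dtype=np.int64) for c, v in by_chrom.items()}
            order = sorted(range(len(intervals)), key=lambda i: (intervals[i][1].chrom, intervals[i][1].start))
            for idx in order:
                iv = intervals[idx][1]
                if iv.chrom not in by_chrom:
                    continue
                rs, re_ = by_chrom[iv.chrom]
                ov = np.minimum(re_, iv.end) - np.maximum(rs, iv.start)
                better = ov > best_ov[iv.chrom]  # strict: leftmost wins ties
                best_ov[iv.chrom][better] = ov[better]
                best_idx[iv.chrom][better] = idx
            for chrom in by_chrom:
                assigned = best_idx[chrom][best_ov[chrom] > 0]
                for idx, cnt in zip(*np.unique(assigned, return_counts=True)):
                    counts[idx, j] += cnt
        else:
            for idx, (_, iv) in enumerate(intervals):
                if iv.chrom not in by_chrom:
                    continue
                rs, re_ = by_chrom[iv.chrom]
                counts[idx, j] = int(np.sum((rs < iv.end) & (re_ > iv.start)))
    return CountTable(list(intervals), [(sid, conditions[sid]) for sid in samples], counts)


def size_factors(table: CountTable | np.ndarray) -> np.ndarray:
    """Median-of-ratios sample normalization factors.

    For intervals with nonzero counts in all samples, each sample's factor is
    the median of count / per-interval geometric mean. At least one such
    interval must exist.
    """
    counts = table.counts if isinstance(table, CountTable) else np.asarray(table, dtype=float)
    counts = counts.astype(float)
    usable = np.all(counts > 0, axis=1)
    if not np.any(usable):
        raise ValueError(
            "no interval has nonzero counts in every sample; "
            "consider adding a pseudo-reference or filtering samples"
        )
    sub = counts[usable]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    return np.median(ratios, axis=0)


@dataclass(frozen=True)
class DiffResult:
    name: str
    baseMean: float
    log2fc: float
    pvalue: float
    padj: float
    upregulated: bool


def _pooled_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments NB dispersion pooled across conditions, per interval."""
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for cols in groups:
        if cols.size < 2:
            continue
        x = norm[:, cols]
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        # (v - m) = alpha * m^2 summed over conditions -> weighted MoM
        num += v - m
        den += m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return np.maximum(alpha, DISPERSION_FLOOR)


def nb_test(
    table: CountTable,
    control: str = "control",
    depleted: str = "depleted",
    factors: np.ndarray | None = None,
) -> list[DiffResult]:
    """Wald-type NB test of depleted vs control per interval.

    With one sample per condition the dispersion cannot be estimated and
    p-values carry little meaning; a warning is attached via the module
    logger and the floor dispersion is used.
    """
    if factors is None:
        factors = size_factors(table)
    ctl = table.condition_columns(control)
    dep = table.condition_columns(depleted)
    if ctl.size == 0 or dep.size == 0:
        raise ValueError(f"need samples in both conditions {control!r} and {depleted!r}")

    norm = table.counts.astype(float) / factors[None, :]
    alpha = _pooled_dispersion(norm, [ctl, dep])

    m_ctl = norm[:, ctl].mean(axis=1)
    m_dep = norm[:, dep].mean(axis=1)
    base_mean = norm.mean(axis=1)
    log2fc = np.log2((m_dep + LOG2FC_PSEUDOCOUNT) / (m_ctl + LOG2FC_PSEUDOCOUNT))

    # delta method: Var(log2(mean+pc)) ~ Var(mean) / ((mean+pc) ln2)^2,
    # Var(mean) = (mu + alpha mu^2) / n under NB sampling
    ln2 = np.log(2.0)
    var_ctl = (m_ctl + alpha * m_ctl**2) / ctl.size
    var_dep = (m_dep + alpha * m_dep**2) / dep.size
    se = np.sqrt(
        var_ctl / ((m_ctl + LOG2FC_PSEUDOCOUNT) * ln2) ** 2
        + var_dep / ((m_dep + LOG2FC_PSEUDOCOUNT) * ln2) ** 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvals = 2 * stats.norm.sf(np.abs(z))

    degenerate = (table.counts.sum(axis=1) == 0)
    pvals = np.where(degenerate, 1.0, pvals)
    log2fc = np.where(degenerate, 0.0, log2fc)

    padj = benjamini_hochberg(pvals)
    results = []
    for i, (name, _) in enumerate(table.intervals):
        up = bool(log2fc[i] >= 1.0 and padj[i] < 0.05)
        results.append(
            DiffResult(name, float(base_mean[i]), float(log2fc[i]), float(pvals[i]), float(padj[i]), up)
        )
    return results


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def call_upregulated(
    results: Sequence[DiffResult], min_fold: float = 2.0, max_padj: float = 0.05
) -> list[DiffResult]:
    """Intervals with fold >= min_fold and padj strictly < max_padj, by padj."""
    min_log2 = np.log2(min_fold)
    kept = [r for r in results if r.log2fc >= min_log2 and r.padj < max_padj]
    return sorted(kept, key=lambda r: (r.padj, r.name))


def results_frame(results: Sequence[DiffResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "baseMean": r.baseMean,
                "log2fc": r.log2fc,
                "pvalue": r.pvalue,
                "padj": r.padj,
                "upregulated": r.upregulated,
            }
            for r in results
        ]
    )
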