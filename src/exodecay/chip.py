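"""Windowed Poisson peak calling and H3K4me1/me3 enhancer classification.

The genome is tiled into fixed windows; each window's treatment count is
tested against a Poisson expectation taken from the depth-normalized input
control (floored by the genome-wide background rate and an absolute
minimum), p-values are Benjamini-Hochberg adjusted ("q-values"), windows
with q < 0.05 are significant, and adjacent significant windows merge into
peaks. Candidate loci are classified enhancer-like or promoter-like by the
mean per-base log2(H3K4me1 / H3K4me3) ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack
from .differential import benjamini_hochberg
from .intervals import Genome, GenomicInterval

LAMBDA_MIN = 0.1
Q_CUTOFF = 0.05


@dataclass(frozen=True)
class PeakCall:
    interval: GenomicInterval
    treatment_count: float
    expected_lambda: float
    pvalue: float
    qvalue: float
    significant: bool


def poisson_tail(k: float, lam: float) -> float:
    """P(Poisson(lam) >= k) via the survival function."""
    k = int(np.ceil(k))
    if k <= 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def depth_normalize(treatment: CoverageTrack, control: CoverageTrack) -> CoverageTrack:
    """Scale the control to the treatment's sequencing depth."""
    if treatment.library_size <= 0 or control.library_size <= 0:
        raise ValueError("both tracks need known library sizes")
    return control.scaled(treatment.library_size / control.library_size)


def window_scan(
    treatment: CoverageTrack,
    control: CoverageTrack,
    genome: Genome,
    window_bp: int = 200,
    step_bp: int = 200,
    lambda_min: float = LAMBDA_MIN,
) -> pd.DataFrame:
    """Per-window counts, Poisson expectations, p- and q-values.

    ``control`` must already be depth-normalized. The window expectation is
    ``max(control window count, genome-wide control rate x window, lambda_min)``,
    which keeps the test conservative where the local input is sparse.
    """
    total_len = sum(genome.chrom_sizes.values())
    if total_len <= 0:
        raise ValueError("zero-length genome")
    global_rate = control.total() / total_len

    rows = []
    for chrom, size in genome.chrom_sizes.items():
        for start in range(0, size, step_bp):
            end = min(start + window_bp, size)
            k = treatment.window_sum(chrom, start, end, ".")
            local = control.window_sum(chrom, start, end, ".")
            lam = max(local, global_rate * (end - start), lambda_min)
            rows.append((chrom, start, end, k, lam))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "count", "lam"])
    df["pvalue"] = stats.poisson.sf(np.ceil(df["count"]).astype(int) - 1, df["lam"])
    df["qvalue"] = benjamini_hochberg(df["pvalue"].to_numpy())
    df["significant"] = df["qvalue"] < Q_CUTOFF
    return df


def poisson_peaks(
    treatment: CoverageTrack,
    control: CoverageTrack,
    genome: Genome,
    window_bp: int = 200,
    step_bp: int = 200,
    lambda_min: float = LAMBDA_MIN,
) -> list[PeakCall]:
    """Call peaks: significant windows merged when adjacent on one chromosome.

    A merged peak carries the summed treatment count and expectation of its
    windows and the minimum member p/q.
    """
    df = window_scan(treatment, control, genome, window_bp, step_bp, lambda_min)
    peaks: list[PeakCall] = []
    cur = None
    for row in df.itertuples():
        if not row.significant:
            continue
        if cur is not None and row.chrom == cur["chrom"] and row.start <= cur["end"]:
            cur["end"] = max(cur["end"], row.end)
            cur["count"] += row.count
            cur["lam"] += row.lam
            cur["p"] = min(cur["p"], row.pvalue)
            cur["q"] = min(cur["q"], row.qvalue)
        else:
            if cur is not None:
                peaks.append(_finish_peak(cur))
            cur = {"chrom": row.chrom, "start": row.start, "end": row.end,
                   "count": row.count, "lam": row.lam, "p": row.pvalue, "q": row.qvalue}
    if cur is not None:
        peaks.append(_finish_peak(cur))
    return peaks


def _finish_peak(cur: dict) -> PeakCall:
    return PeakCall(
        GenomicInterval(cur["chrom"], int(cur["start"]), int(cur["end"])),
        float(cur["count"]), float(cur["lam"]), float(cur["p"]), float(cur["q"]),
        significant=cur["q"] < Q_CUTOFF,
    )


def log2_ratio(
    me1: CoverageTrack,
    me3: CoverageTrack,
    pseudocount: float = 1.0,
    bin_bp: int = 200,
) -> CoverageTrack:
    """log2((me1 + pc) / (me3 + pc)) comparison track.

    Both tracks should be depth-normalized to a common scale first. With
    ``bin_bp > 1`` the marks are compared as read counts per fixed bin
    (piecewise-constant output), which keeps sparse base-level counts from
    being drowned by the pseudocount; ``bin_bp=1`` compares raw per-base
    values. Regions covered by neither mark get ratio 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if bin_bp <= 1:
        out = me1.binary_op(me3, lambda a, b: np.log2((a + pseudocount) / (b + pseudocount)))
        out.normalization = "log2_ratio"
        return out

    from .coverage import _Runs

    out = CoverageTrack(library_size=me1.library_size, normalization="log2_ratio",
                        stranded=False)
    chroms = {k[0] for k in me1.runs} | {k[0] for k in me3.runs}
    for chrom in chroms:
        extent = 0
        for trk in (me1, me3):
            for (c, _s), r in trk.runs.items():
                if c == chrom and r.ends.size:
                    extent = max(extent, int(r.ends[-1]))
        starts, ends, vals = [], [], []
        for b0 in range(0, extent, bin_bp):
            b1 = min(b0 + bin_bp, extent)
            a = me1.window_sum(chrom, b0, b1, ".")
            b = me3.window_sum(chrom, b0, b1, ".")
            v = float(np.log2((a + pseudocount) / (b + pseudocount)))
            if v != 0:
                starts.append(b0)
                ends.append(b1)
                vals.append(v)
        if starts:
            out.runs[(chrom, ".")] = _Runs(
                np.array(starts, dtype=np.int64),
                np.array(ends, dtype=np.int64),
                np.array(vals, dtype=float),
            )
    return out


def classify_loci(
    loci: list[tuple[str, GenomicInterval]],
    ratio: CoverageTrack,
    min_ratio: float = 1.0,
) -> pd.DataFrame:
    """Label loci enhancer_like / promoter_like / ambiguous by mean log2 ratio.

    Mean per-base ratio >= ``min_ratio`` (me1-high, the enhancer signature)
    -> enhancer_like; <= -``min_ratio`` (me3-high, as at active promoters)
    -> promoter_like; in between -> ambiguous.
    """
    rows = []
    for lid, iv in loci:
        mean = ratio.window_sum(iv.chrom, iv.start, iv.end, ".") / len(iv)
        if mean >= min_ratio:
            label = "enhancer_like"
        elif mean <= -min_ratio:
            label = "promoter_like"
        else:
            label = "ambiguous"
        rows.append({"locus": lid, "mean_log2_ratio": mean, "label": label})
    return pd.DataFrame(rows)
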