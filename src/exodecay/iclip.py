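"""iCLIP crosslink tracks and 3'-extension footprint detection.

Each read contributes one crosslink site at the base immediately 5' of its
5' end in transcription direction (the truncation convention: reverse
transcription stops one nucleotide before the crosslinked base). Tracks
are normalized to reads per million mapped. A ribonuclease "footprint" is
the block of catalytic-mutant crosslink density in the 30-nt window
immediately downstream of a mature RNA 3' end; its enrichment is the
mutant/wild-type RPM ratio over that window, and snoRNA targets are
flagged by any mutant crosslink within 50 nt downstream of their 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .intervals import Bed6Record, GeneModel, Genome, GenomicInterval

ENRICHMENT_PSEUDOCOUNT = 0.1  # RPM


def crosslink_sites(
    reads: Sequence[Bed6Record], convention: str = "truncation"
) -> CoverageTrack:
    """Single-base crosslink-site track from deduplicated read alignments.

    ``truncation`` (default): the site is the base preceding the read 5'
    end in transcription direction — plus-strand read [s, e) -> site s-1,
    minus-strand read [s, e) -> site e. ``five_prime`` uses the read 5' end
    itself. Sites below position 0 are dropped; the library size is the
    total read count.
    """
    if convention not in ("truncation", "five_prime"):
        raise ValueError(f"unknown crosslink convention {convention!r}")
    sites: dict[tuple[str, str], list[int]] = {}
    for r in reads:
        iv = r.interval
        if iv.strand == "-":
            pos = iv.end if convention == "truncation" else iv.end - 1
        else:
            pos = iv.start - 1 if convention == "truncation" else iv.start
        sites.setdefault((iv.chrom, iv.strand), []).append(pos)
    arrays = {k: np.array(v, dtype=np.int64) for k, v in sites.items()}
    return CoverageTrack.from_sites(arrays, library_size=len(reads))


def rpm_normalize(track: CoverageTrack) -> CoverageTrack:
    """Reads-per-million; errors on an empty library or double application."""
    return track.rpm()


def _three_prime_end(feature: GeneModel | GenomicInterval) -> tuple[str, int, str]:
    iv = feature.span if isinstance(feature, GeneModel) else feature
    if iv.strand == "-":
        return iv.chrom, iv.start, "-"  # 3' end is the leftmost base
    return iv.chrom, iv.end - 1, "+"


def downstream_window(
    feature: GeneModel | GenomicInterval, length: int, genome: Genome | None = None
) -> tuple[GenomicInterval, bool]:
    """The ``length``-nt window immediately 3' of a feature, (window, clipped).

    The window starts at the first base after the annotated 3' end (the
    mature end itself is excluded) and runs downstream in transcription
    direction; it is clipped, and flagged, at chromosome bounds.
    """
    chrom, end3, strand = _three_prime_end(feature)
    clipped = False
    if strand == "-":
        start, end = end3 - length, end3
        if start < 0:
            start, clipped = 0, True
    else:
        start, end = end3 + 1, end3 + 1 + length
        if genome is not None and end > genome.length(chrom):
            end, clipped = genome.length(chrom), True
    return GenomicInterval(chrom, start, end, strand), clipped


@dataclass(frozen=True)
class FootprintResult:
    feature_id: str
    feature_3p_end: int
    window: GenomicInterval
    rpm_mut: float
    rpm_wt: float
    enrichment: float
    flagged: bool
    est_width_nt: int | None
    clipped: bool = False


def footprint_score(
    feature: GeneModel | GenomicInterval,
    mut: CoverageTrack,
    wt: CoverageTrack,
    window_nt: int = 30,
    pc: float = ENRICHMENT_PSEUDOCOUNT,
    genome: Genome | None = None,
    feature_id: str | None = None,
) -> FootprintResult:
    """Mutant/WT RPM enrichment over the 3'-downstream footprint window.

    Both tracks must be RPM-normalized. ``enrichment`` is
    ``(rpm_mut + pc) / (rpm_wt + pc)``; with the default pc of 0.1 RPM a
    zero wild-type window stays finite without distorting real signal.
    """
    for name, trk in (("mut", mut), ("wt", wt)):
        if trk.normalization != "RPM":
            raise ValueError(f"{name} track must be RPM-normalized (is {trk.normalization})")
    chrom, end3, strand = _three_prime_end(feature)
    window, clipped = downstream_window(feature, window_nt, genome)
    rpm_mut = mut.window_sum(window.chrom, window.start, window.end, strand)
    rpm_wt = wt.window_sum(window.chrom, window.start, window.end, strand)
    flag_iv, _ = downstream_window(feature, 50, genome)
    flagged = mut.window_sum(flag_iv.chrom, flag_iv.start, flag_iv.end, strand) > 0
    width = footprint_width(feature, mut, genome=genome)
    fid = feature_id or (feature.gene_id if isinstance(feature, GeneModel) else f"{chrom}:{end3}")
    return FootprintResult(
        fid, end3, window, float(rpm_mut), float(rpm_wt),
        float((rpm_mut + pc) / (rpm_wt + pc)), bool(flagged), width, clipped,
    )


def flag_targets(
    features: Sequence[GeneModel],
    mut: CoverageTrack,
    max_dist: int = 50,
) -> list[GeneModel]:
    """snoRNAs with >=1 mutant crosslink site within ``max_dist`` nt downstream.

    Containment is of the crosslink site itself in ``(3'end, 3'end+max_dist]``
    (transcription direction); reads inside the gene body do not count.
    """
    flagged = []
    for f in features:
        iv, _ = downstream_window(f, max_dist)
        if mut.window_sum(iv.chrom, iv.start, iv.end, f.strand) > 0:
            flagged.append(f)
    return flagged


def _downstream_profile(
    feature: GeneModel | GenomicInterval, track: CoverageTrack, max_scan: int
) -> np.ndarray:
    """Per-offset signal at +1..+max_scan downstream of the 3' end."""
    chrom, end3, strand = _three_prime_end(feature)
    if strand == "-":
        vals = track.values(chrom, max(0, end3 - max_scan), end3, strand)
        vals = vals[::-1]
        if vals.size < max_scan:
            vals = np.concatenate([vals, np.zeros(max_scan - vals.size)])
    else:
        vals = track.values(chrom, end3 + 1, end3 + 1 + max_scan, strand)
    return vals


def footprint_width(
    feature: GeneModel | GenomicInterval,
    mut: CoverageTrack,
    max_scan: int = 100,
    mass: float = 0.9,
    genome: Genome | None = None,
) -> int | None:
    """Smallest w whose first w downstream bases hold >= ``mass`` of the signal.

    Signal is the mutant crosslink density within ``max_scan`` nt downstream;
    None when there is none.
    """
    vals = _downstream_profile(feature, mut, max_scan)
    total = vals.sum()
    if total <= 0:
        return None
    cum = np.cumsum(vals)
    return int(np.searchsorted(cum, mass * total - 1e-12) + 1)


def feature_end_metagene(
    features: Sequence[GeneModel],
    track: CoverageTrack,
    flank_nt: int = 100,
) -> pd.DataFrame:
    """Mean RPM at offsets -flank..+flank around feature 5' and 3' ends.

    The offset axis is transcription-oriented (negative = inside/upstream,
    positive = downstream); minus-strand features are reversed. Offset 0 is
    the annotated end base itself.
    """
    n = 2 * flank_nt + 1
    acc5 = np.zeros(n)
    acc3 = np.zeros(n)
    count = 0
    for f in features:
        iv = f.span
        if f.strand == "-":
            p5, p3 = iv.end - 1, iv.start
        else:
            p5, p3 = iv.start, iv.end - 1
        for pos, acc in ((p5, acc5), (p3, acc3)):
            lo, hi = pos - flank_nt, pos + flank_nt + 1
            vals = track.values(iv.chrom, max(0, lo), hi, f.strand)
            if lo < 0:
                vals = np.concatenate([np.zeros(-lo), vals])
            if f.strand == "-":
                vals = vals[::-1]
            acc += vals
        count += 1
    if count == 0:
        raise ValueError("no features")
    offsets = np.arange(-flank_nt, flank_nt + 1)
    return pd.DataFrame({"offset": offsets, "five_prime": acc5 / count, "three_prime": acc3 / count})


def results_frame(results: Iterable[FootprintResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "feature_3p_end": r.feature_3p_end,
                "window_start": r.window.start,
                "window_end": r.window.end,
                "rpm_mut": r.rpm_mut,
                "rpm_wt": r.rpm_wt,
                "enrichment": r.enrichment,
                "flagged": r.flagged,
                "est_width_nt": r.est_width_nt,
                "clipped": r.clipped,
            }
            for r in results
        ]
    )
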