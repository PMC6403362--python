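"""Synthetic genomes, annotations and signal with planted ground truth.

One toy chromosome carries multi-isoform protein-coding genes, intronic
and intergenic snoRNAs and gene-distal enhancer loci, all spaced >= 10 kb
apart. From that layout the generator emits:

* RNA-seq read sets for control and nuclease-depleted conditions —
  negative-binomial counts per locus (variance = mu + alpha mu^2), gene
  bodies constant across conditions, with planted fold increases on
  promoter-upstream (PROMPT) windows (antisense, 8x), enhancer loci
  (bidirectional ~50/50, 8x) and first introns (4x) in the depleted
  condition;
* iCLIP read sets for a wild-type and a catalytic-mutant pull-down — a
  uniform crosslink background over transcribed regions plus, in the
  mutant, a 30-nt footprint block downstream of every snoRNA 3' end whose
  expected RPM ratio over wild type equals the requested enrichment (33x,
  the scale seen for a stalled exonuclease on its trimming substrates);
* ChIP coverage for H3K4me1, H3K4me3 and input — per-base Poisson
  background with H3K4me1 elevated over enhancers and H3K4me3 over
  promoters.

Every planted feature is listed exactly once in :class:`SimTruth`; the
same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .intervals import Bed6Record, GeneModel, Genome, GenomicInterval, TranscriptModel
from .introns import gene_introns

CHROM = "chrS"
READ_LENGTH = 50  # bp, single-end
ICLIP_READ_LENGTH = 30

MIN_SPACING = 10_000


@dataclass
class SimTruth:
    """Planted-feature registry: one record per simulated signal feature."""

    records: pd.DataFrame
    params: dict = field(default_factory=dict)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.records[self.records["kind"] == kind]

    def to_tsv(self, path: str) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def make_annotation(
    n_genes: int = 100,
    n_snornas: int = 20,
    n_enhancers: int = 20,
    chrom_len: int = 2_000_000,
    seed: int = 0,
) -> tuple[Genome, list[GeneModel], SimTruth]:
    """Lay out a toy chromosome and its planted-feature truth table.

    Protein-coding genes have 2-5 exons and 1-3 isoforms; snoRNAs are
    70-200 bp, half placed inside host-gene first-suitable introns and half
    intergenic; enhancer loci are 1 kb and, by the >=10 kb spacing, always
    more than 3 kb from any gene. Raises when the requested features cannot
    fit on ``chrom_len`` with the required spacing.
    """
    rng = _rng(seed, 0)
    genes: list[GeneModel] = []
    truth_rows: list[dict] = []

    n_intergenic_sno = n_snornas // 2
    n_intronic_sno = n_snornas - n_intergenic_sno

    slots = (["gene"] * n_genes + ["sno"] * n_intergenic_sno + ["enh"] * n_enhancers)
    rng.shuffle(slots)

    cursor = 15_000  # room for upstream windows of the first feature
    gene_idx = sno_idx = enh_idx = 0
    enhancers: list[GenomicInterval] = []
    for slot in slots:
        strand = "+" if rng.random() < 0.5 else "-"
        if slot == "gene":
            gene_idx += 1
            gid = f"G{gene_idx:04d}"
            n_exons = int(rng.integers(2, 6))
            exon_lens = rng.integers(150, 501, size=n_exons)
            intron_lens = rng.integers(400, 1201, size=n_exons - 1)
            exons = []
            pos = cursor
            for i, el in enumerate(exon_lens):
                exons.append(GenomicInterval(CHROM, pos, pos + int(el), strand))
                pos += int(el)
                if i < n_exons - 1:
                    pos += int(intron_lens[i])
            span = GenomicInterval(CHROM, cursor, pos, strand)
            transcripts = [TranscriptModel(f"{gid}.t1", gid, strand, exons)]
            n_iso = int(rng.integers(1, 4))
            for j in range(2, n_iso + 1):
                if n_exons > 2:
                    drop = int(rng.integers(1, n_exons - 1))  # internal exon skipped
                    iso_exons = [e for i, e in enumerate(exons) if i != drop]
                else:
                    iso_exons = list(exons)
                transcripts.append(TranscriptModel(f"{gid}.t{j}", gid, strand, iso_exons))
            base_mean = float(np.round(rng.lognormal(np.log(300), 0.8), 3))
            genes.append(GeneModel(gid, "protein_coding", span, transcripts))
            truth_rows.append(
                dict(locus_id=gid, kind="gene", chrom=CHROM, start=span.start,
                     end=span.end, strand=strand, base_mean=base_mean, fold=1.0)
            )
            cursor = pos
        elif slot == "sno":
            sno_idx += 1
            sid = f"SNO{sno_idx:03d}"
            length = int(rng.integers(70, 201))
            iv = GenomicInterval(CHROM, cursor, cursor + length, strand)
            genes.append(
                GeneModel(sid, "snoRNA", iv, [TranscriptModel(f"{sid}.t1", sid, strand, [iv])])
            )
            truth_rows.append(
                dict(locus_id=sid, kind="snoRNA", chrom=CHROM, start=iv.start,
                     end=iv.end, strand=strand, base_mean=float(rng.integers(50, 151)), fold=1.0)
            )
            cursor = iv.end
        else:
            enh_idx += 1
            eid = f"ENH{enh_idx:03d}"
            iv = GenomicInterval(CHROM, cursor, cursor + 1000, ".")
            enhancers.append(iv)
            truth_rows.append(
                dict(locus_id=eid, kind="enhancer", chrom=CHROM, start=iv.start,
                     end=iv.end, strand=".", base_mean=float(np.round(rng.uniform(15, 40), 3)), fold=1.0)
            )
            cursor = iv.end
        cursor += MIN_SPACING + int(rng.integers(0, 1001))

    required = cursor + 15_000
    if required > chrom_len:
        raise ValueError(
            f"features do not fit: need >= {required} bp, chrom_len is {chrom_len}"
        )

    # intronic snoRNAs: drop into the first host intron long enough
    placed = 0
    for g in genes:
        if placed >= n_intronic_sno or g.biotype != "protein_coding":
            continue
        introns = gene_introns(g)
        for intr in introns:
            length = int(rng.integers(70, 201))
            if len(intr.interval) >= length + 60:
                mid = intr.interval.start + (len(intr.interval) - length) // 2
                placed += 1
                sid = f"SNOI{placed:03d}"
                iv = GenomicInterval(CHROM, mid, mid + length, g.strand)
                genes.append(
                    GeneModel(sid, "snoRNA", iv, [TranscriptModel(f"{sid}.t1", sid, g.strand, [iv])])
                )
                truth_rows.append(
                    dict(locus_id=sid, kind="snoRNA", chrom=CHROM, start=iv.start,
                         end=iv.end, strand=g.strand, base_mean=float(rng.integers(50, 151)), fold=1.0)
                )
                break

    # planted unstable RNAs: PROMPT window upstream of every gene (antisense),
    # an eRNA transcript on every enhancer, the first intron of every gene
    for g in [g for g in genes if g.biotype == "protein_coding"]:
        if g.strand == "-":
            iv = GenomicInterval(CHROM, g.span.end + 500, g.span.end + 2500, "+")
        else:
            iv = GenomicInterval(CHROM, g.span.start - 2500, g.span.start - 500, "-")
        truth_rows.append(
            dict(locus_id=f"PROMPT_{g.gene_id}", kind="PROMPT", chrom=CHROM,
                 start=iv.start, end=iv.end, strand=iv.strand,
                 base_mean=float(np.round(rng.uniform(15, 40), 3)), fold=1.0)
        )
        introns = gene_introns(g)
        if introns:
            i1 = introns[0].interval
            truth_rows.append(
                dict(locus_id=f"INTRON1_{g.gene_id}", kind="intron1_PCPA", chrom=CHROM,
                     start=i1.start, end=i1.end, strand=g.strand,
                     base_mean=float(np.round(rng.uniform(10, 30), 3)), fold=1.0)
            )
    for row in [r for r in truth_rows if r["kind"] == "enhancer"]:
        truth_rows.append(
            dict(locus_id=f"eRNA_{row['locus_id']}", kind="eRNA", chrom=CHROM,
                 start=row["start"], end=row["end"], strand=".",
                 base_mean=row["base_mean"], fold=1.0)
        )

    genes.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    truth = SimTruth(
        pd.DataFrame(truth_rows),
        params=dict(seed=seed, n_genes=n_genes, n_snornas=n_snornas,
                    n_enhancers=n_enhancers, chrom_len=chrom_len),
    )
    genome = Genome({CHROM: chrom_len})
    return genome, genes, truth


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """NB with variance = mean + dispersion * mean^2 (Poisson when dispersion=0)."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 0:
        return rng.poisson(mean, size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size)


def _place_reads(
    rng: np.random.Generator, iv_start: int, iv_end: int, n: int, strand: str,
    read_length: int = READ_LENGTH,
) -> list[Bed6Record]:
    lo, hi = iv_start, max(iv_start + 1, iv_end - read_length)
    starts = rng.integers(lo, hi, size=n)
    return [
        Bed6Record(GenomicInterval(CHROM, int(s), int(s) + read_length, strand), ".", 60)
        for s in starts
    ]


def simulate_rnaseq(
    genome: Genome,
    genes: list[GeneModel],
    truth: SimTruth,
    condition: str,
    n_reps: int = 3,
    depth: float = 1.0,
    nb_dispersion: float = 0.05,
    prompt_fold: float = 8.0,
    intron1_fold: float = 4.0,
    erna_fold: float = 8.0,
    seed: int = 0,
) -> dict[str, list[Bed6Record]]:
    """Strand-specific RNA-seq read sets for one condition.

    Gene and snoRNA bodies keep their base mean in both conditions; in the
    ``depleted`` condition PROMPT, eRNA and first-intron loci are scaled by
    their planted folds. Reads are fixed-length, uniformly placed within
    their locus: genes/introns on the gene strand, PROMPTs antisense,
    eRNAs split ~50/50 between strands. The planted folds are recorded in
    the truth table.
    """
    if condition not in ("control", "depleted"):
        raise ValueError(f"condition must be control|depleted, got {condition!r}")
    if min(prompt_fold, intron1_fold, erna_fold) < 1:
        raise ValueError("planted folds must be >= 1")
    folds = {"PROMPT": prompt_fold, "eRNA": erna_fold, "intron1_PCPA": intron1_fold}
    for kind, f in folds.items():
        truth.records.loc[truth.records["kind"] == kind, "fold"] = f
    truth.params.update(
        dict(nb_dispersion=nb_dispersion, depth=depth, n_reps=n_reps, **{f"{k}_fold": v for k, v in folds.items()})
    )

    stream = 1 if condition == "control" else 2
    rng = _rng(seed, stream)
    from .introns import synthetic_transcript

    exons_by_gene = {
        g.gene_id: synthetic_transcript(g) for g in genes
    }
    samples: dict[str, list[Bed6Record]] = {}
    rec = truth.records
    for rep in range(1, n_reps + 1):
        reads: list[Bed6Record] = []
        for row in rec.itertuples():
            if row.kind == "enhancer":
                continue  # signal is carried by the matching eRNA record
            mean = row.base_mean * depth
            if condition == "depleted":
                mean *= folds.get(row.kind, 1.0)
            n = int(_nb_draw(rng, mean, nb_dispersion, 1)[0])
            if n == 0:
                continue
            if row.kind == "eRNA":
                n_plus = int(rng.binomial(n, 0.5))
                reads.extend(_place_reads(rng, row.start, row.end, n_plus, "+"))
                reads.extend(_place_reads(rng, row.start, row.end, n - n_plus, "-"))
            elif row.kind in ("gene", "snoRNA"):
                # mature-RNA reads: placed within the merged exons only
                blocks = exons_by_gene[row.locus_id]
                lens = np.array([len(b) for b in blocks], dtype=float)
                picks = rng.choice(len(blocks), size=n, p=lens / lens.sum())
                for bi, cnt in zip(*np.unique(picks, return_counts=True)):
                    b = blocks[int(bi)]
                    reads.extend(_place_reads(rng, b.start, b.end, int(cnt), row.strand))
            else:
                reads.extend(_place_reads(rng, row.start, row.end, n, row.strand))
        samples[f"{condition}_rep{rep}"] = reads
    return samples


def simulate_iclip(
    genome: Genome,
    genes: list[GeneModel],
    truth: SimTruth,
    sample: str,
    footprint_width: int = 30,
    footprint_enrichment: float = 33.0,
    background_rate: float = 0.5,
    seed: int = 0,
) -> list[Bed6Record]:
    """iCLIP reads for the wild-type (``WT``) or catalytic-mutant (``CAT``) pull-down.

    Background crosslink sites fall uniformly (Poisson per base at
    ``background_rate``) over gene spans, snoRNA bodies and 100 nt of
    3'-downstream readthrough. The mutant sample adds a block of crosslinks
    over the ``footprint_width``-nt window downstream of every snoRNA 3'
    end, sized so the expected windowed mutant/WT RPM ratio equals
    ``footprint_enrichment`` after library-size normalization.
    """
    if sample not in ("WT", "CAT"):
        raise ValueError(f"sample must be WT|CAT, got {sample!r}")
    if footprint_width < 1:
        raise ValueError("footprint width must be >= 1")
    rng = _rng(seed, 3 if sample == "WT" else 4)

    # background regions on each feature's own strand; merged per strand so an
    # intronic snoRNA inside a same-strand host does not double the local rate
    from .intervals import merge_intervals

    raw_regions: dict[str, list[GenomicInterval]] = {"+": [], "-": []}
    snos: list[GeneModel] = []
    for g in genes:
        s, e = g.span.start, g.span.end
        if g.strand == "-":
            iv = GenomicInterval(g.chrom, max(0, s - 100), e, g.strand)
        else:
            iv = GenomicInterval(g.chrom, s, min(genome.length(g.chrom), e + 100), g.strand)
        raw_regions[g.strand].append(iv)
        if g.biotype == "snoRNA":
            snos.append(g)
    regions: list[tuple[int, int, str]] = []
    for strand, ivs in raw_regions.items():
        if ivs:
            regions.extend((m.start, m.end, strand) for m in merge_intervals(ivs))
    regions.sort()

    bg_len = sum(e - s for s, e, _ in regions)
    expected_bg = background_rate * bg_len
    rw = background_rate * footprint_width
    n_sno = len(snos)
    extra_per_sno = 0.0
    if sample == "CAT" and n_sno and background_rate > 0:
        denom = expected_bg - footprint_enrichment * rw * n_sno
        if denom <= 0:
            raise ValueError("background too shallow to plant the requested enrichment")
        # sized so E[(mut_window/mut_lib)/(wt_window/wt_lib)] = enrichment
        extra_per_sno = rw * expected_bg * (footprint_enrichment - 1) / denom
    elif sample == "CAT" and background_rate == 0:
        extra_per_sno = footprint_enrichment * footprint_width  # depth floor when no background

    reads: list[Bed6Record] = []
    for s, e, strand in regions:
        n = int(rng.poisson(background_rate * (e - s)))
        if n == 0:
            continue
        sites = rng.integers(s, e, size=n)
        reads.extend(_reads_from_sites(sites, strand, genome))
    if extra_per_sno > 0:
        for g in snos:
            n = int(rng.poisson(extra_per_sno))
            if n == 0:
                continue
            if g.strand == "-":
                lo, hi = max(0, g.span.start - footprint_width), g.span.start
            else:
                lo = g.span.end
                hi = min(genome.length(g.chrom), g.span.end + footprint_width)
            sites = rng.integers(lo, hi, size=n)
            reads.extend(_reads_from_sites(sites, g.strand, genome))
    return reads


def _reads_from_sites(
    sites: np.ndarray, strand: str, genome: Genome
) -> list[Bed6Record]:
    """Reads whose truncation-convention crosslink site is the given base."""
    out = []
    size = genome.length(CHROM)
    for site in sites:
        site = int(site)
        if strand == "-":
            end = site
            start = max(0, end - ICLIP_READ_LENGTH)
            if end <= 0:
                continue
        else:
            start = site + 1
            end = min(size, start + ICLIP_READ_LENGTH)
            if start >= size:
                continue
        out.append(Bed6Record(GenomicInterval(CHROM, start, end, strand), ".", 60))
    return out


def simulate_chip(
    genome: Genome,
    genes: list[GeneModel],
    truth: SimTruth,
    enhancer_me1_fold: float = 5.0,
    promoter_me3_fold: float = 5.0,
    background_lambda: float = 5.0,
    window_bp: int = 200,
    seed: int = 0,
) -> dict[str, CoverageTrack]:
    """Per-base Poisson ChIP coverage for H3K4me1, H3K4me3 and input.

    ``background_lambda`` is the expected read count per ``window_bp``
    window. H3K4me1 is elevated ``enhancer_me1_fold``-fold over planted
    enhancer loci; H3K4me3 ``promoter_me3_fold``-fold over 1-kb promoter
    windows centred on each protein-coding TSS; input is flat.
    """
    rng = _rng(seed, 5)
    size = genome.length(CHROM)
    base_rate = background_lambda / window_bp

    rate_me1 = np.full(size, base_rate)
    rate_me3 = np.full(size, base_rate)
    for row in truth.of_kind("enhancer").itertuples():
        rate_me1[row.start : row.end] *= enhancer_me1_fold
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        tss = g.tss
        lo, hi = max(0, tss - 500), min(size, tss + 500)
        rate_me3[lo:hi] *= promoter_me3_fold

    tracks = {}
    for name, rate in (("me1", rate_me1), ("me3", rate_me3), ("input", np.full(size, base_rate))):
        arr = rng.poisson(rate).astype(float)
        trk = CoverageTrack.from_array(CHROM, ".", arr, library_size=int(arr.sum()))
        trk.stranded = False
        tracks[name] = trk
    return tracks


def write_reads_bed(reads: list[Bed6Record], path: str) -> None:
    from .intervals import write_bed6

    write_bed6(reads, path)
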