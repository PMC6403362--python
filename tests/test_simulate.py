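"""Simulator layout guarantees, planted statistics and determinism."""

import hashlib

import numpy as np
import pytest
from scipy import stats

from exodecay import simulate
from exodecay.intervals import GenomicInterval, gap_distance


def reads_digest(reads):
    h = hashlib.sha256()
    for r in reads:
        h.update(f"{r.interval.chrom}:{r.interval.start}-{r.interval.end}{r.interval.strand}".encode())
    return h.hexdigest()


class TestMakeAnnotation:
    def test_requested_feature_counts(self, sim_bundle):
        genes, truth = sim_bundle["genes"], sim_bundle["truth"]
        assert sum(1 for g in genes if g.biotype == "protein_coding") == 40
        assert sum(1 for g in genes if g.biotype == "snoRNA") == 10
        assert len(truth.of_kind("enhancer")) == 10
        kinds = truth.records["kind"].value_counts()
        assert kinds["PROMPT"] == 40 and kinds["eRNA"] == 10

    def test_enhancers_are_gene_distal(self, sim_bundle):
        genes = sim_bundle["genes"]
        for r in sim_bundle["truth"].of_kind("enhancer").itertuples():
            enh = GenomicInterval(r.chrom, r.start, r.end)
            assert min(gap_distance(enh, g.span) for g in genes) >= 3_000

    def test_truth_covers_every_planted_feature_once(self, sim_bundle):
        ids = sim_bundle["truth"].records["locus_id"]
        assert ids.is_unique

    def test_seed_determinism(self):
        a = simulate.make_annotation(n_genes=10, n_snornas=4, n_enhancers=3,
                                     chrom_len=400_000, seed=13)
        b = simulate.make_annotation(n_genes=10, n_snornas=4, n_enhancers=3,
                                     chrom_len=400_000, seed=13)
        assert a[2].records.equals(b[2].records)
        assert [(g.gene_id, g.span) for g in a[1]] == [(g.gene_id, g.span) for g in b[1]]

    def test_overflow_raises_with_required_length(self):
        with pytest.raises(ValueError, match="need >="):
            simulate.make_annotation(n_genes=100, chrom_len=100_000, seed=0)


class TestRnaseq:
    def test_seed_determinism(self, sim_bundle):
        again = simulate.simulate_rnaseq(
            sim_bundle["genome"], sim_bundle["genes"], sim_bundle["truth"], "control", seed=5
        )
        assert reads_digest(again["control_rep1"]) == reads_digest(sim_bundle["rnaseq"]["control_rep1"])

    def test_planted_prompt_fold(self, sim_bundle):
        truth, rnaseq = sim_bundle["truth"], sim_bundle["rnaseq"]
        prompts = [
            GenomicInterval(r.chrom, r.start, r.end, r.strand)
            for r in truth.of_kind("PROMPT").itertuples()
        ]

        def total(sample):
            starts = np.array([r.interval.start for r in rnaseq[sample]])
            ends = np.array([r.interval.end for r in rnaseq[sample]])
            return sum(int(np.sum((starts < p.end) & (ends > p.start))) for p in prompts)

        ctl = np.mean([total(f"control_rep{i}") for i in (1, 2, 3)])
        dep = np.mean([total(f"depleted_rep{i}") for i in (1, 2, 3)])
        assert dep / ctl == pytest.approx(8.0, rel=0.15)

    def test_gene_bodies_constant_across_conditions(self, sim_bundle):
        genes = [g for g in sim_bundle["genes"] if g.biotype == "protein_coding"]
        rnaseq = sim_bundle["rnaseq"]

        def exonic_total(sample):
            starts = np.array([r.interval.start for r in rnaseq[sample]])
            ends = np.array([r.interval.end for r in rnaseq[sample]])
            from exodecay.introns import synthetic_transcript

            tot = 0
            for g in genes:
                for e in synthetic_transcript(g):
                    tot += int(np.sum((starts >= e.start) & (ends <= e.end)))
            return tot

        ctl = exonic_total("control_rep1")
        dep = exonic_total("depleted_rep1")
        assert dep / ctl == pytest.approx(1.0, rel=0.1)

    def test_null_conditions_are_exchangeable(self):
        genome, genes, truth = simulate.make_annotation(
            n_genes=20, n_snornas=4, n_enhancers=4, chrom_len=600_000, seed=3
        )
        ctl = simulate.simulate_rnaseq(genome, genes, truth, "control", seed=3)
        dep = simulate.simulate_rnaseq(
            genome, genes, truth, "depleted",
            prompt_fold=1, intron1_fold=1, erna_fold=1, seed=3,
        )

        def per_locus_counts(reads):
            starts = np.array([r.interval.start for r in reads])
            ends = np.array([r.interval.end for r in reads])
            return [
                int(np.sum((starts < r.end) & (ends > r.start)))
                for r in truth.records.itertuples()
            ]

        ks = stats.ks_2samp(
            per_locus_counts(ctl["control_rep1"]), per_locus_counts(dep["depleted_rep1"])
        )
        assert ks.pvalue > 0.01

    def test_erna_reads_are_bidirectional(self, sim_bundle):
        reads = sim_bundle["rnaseq"]["depleted_rep1"]
        truth = sim_bundle["truth"]
        plus = minus = 0
        for r in truth.of_kind("eRNA").itertuples():
            for rd in reads:
                if rd.interval.start < r.end and rd.interval.end > r.start:
                    if rd.interval.strand == "+":
                        plus += 1
                    else:
                        minus += 1
        frac = plus / (plus + minus)
        assert 0.4 < frac < 0.6


class TestIclipSim:
    def test_seed_determinism(self):
        genome, genes, truth = simulate.make_annotation(
            n_genes=15, n_snornas=6, n_enhancers=3, chrom_len=500_000, seed=19
        )
        a = simulate.simulate_iclip(genome, genes, truth, "CAT", seed=19)
        b = simulate.simulate_iclip(genome, genes, truth, "CAT", seed=19)
        assert reads_digest(a) == reads_digest(b)

    def test_zero_background_wt_has_no_reads(self):
        genome, genes, truth = simulate.make_annotation(
            n_genes=15, n_snornas=6, n_enhancers=3, chrom_len=500_000, seed=19
        )
        assert simulate.simulate_iclip(genome, genes, truth, "WT",
                                       background_rate=0.0, seed=19) == []


class TestChipSim:
    def test_background_is_poisson_and_enhancers_enriched(self):
        genome, genes, truth = simulate.make_annotation(
            n_genes=15, n_snornas=6, n_enhancers=5, chrom_len=500_000, seed=23
        )
        tracks = simulate.simulate_chip(genome, genes, truth, seed=23)
        inp = tracks["input"]
        wins = np.array([
            inp.window_sum("chrS", s, s + 200, ".") for s in range(0, 400_000, 200)
        ])
        assert wins.mean() == pytest.approx(5.0, rel=0.05)
        assert wins.var() / wins.mean() == pytest.approx(1.0, abs=0.1)
        # planted enhancers me1-high
        from exodecay.chip import depth_normalize, log2_ratio

        ratio = log2_ratio(tracks["me1"], depth_normalize(tracks["me1"], tracks["me3"]))
        for r in truth.of_kind("enhancer").itertuples():
            mean = ratio.window_sum(r.chrom, r.start, r.end, ".") / (r.end - r.start)
            assert mean > 1.0

    def test_seed_determinism(self):
        genome, genes, truth = simulate.make_annotation(
            n_genes=10, n_snornas=2, n_enhancers=2, chrom_len=350_000, seed=29
        )
        t1 = simulate.simulate_chip(genome, genes, truth, seed=29)
        t2 = simulate.simulate_chip(genome, genes, truth, seed=29)
        assert t1["me1"].total() == t2["me1"].total()
        assert np.array_equal(
            t1["me1"].values("chrS", 0, 350_000), t2["me1"].values("chrS", 0, 350_000)
        )
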