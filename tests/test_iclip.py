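"""Crosslink-site conventions, footprint scoring, snoRNA flagging."""

import numpy as np
import pytest

from exodecay.coverage import CoverageTrack
from exodecay.iclip import (
    crosslink_sites,
    feature_end_metagene,
    flag_targets,
    footprint_score,
    footprint_width,
    rpm_normalize,
)
from exodecay.intervals import Bed6Record, GeneModel, Genome, GenomicInterval, TranscriptModel

C = "chrS"
GENOME = Genome({C: 100_000})


def read(s, e, strand="+"):
    return Bed6Record(GenomicInterval(C, s, e, strand), ".", 60)


def feature(start, end, strand="+", gene_id="SNO1"):
    span = GenomicInterval(C, start, end, strand)
    return GeneModel(gene_id, "snoRNA", span,
                     [TranscriptModel(f"{gene_id}.t", gene_id, strand, [span])])


def site_track(positions, strand="+", library=None):
    """Raw count track with one crosslink per listed position."""
    arrays = {(C, strand): np.array(positions, dtype=np.int64)}
    return CoverageTrack.from_sites(arrays, library_size=library or len(positions))


class TestCrosslinkSites:
    def test_truncation_convention(self):
        trk = crosslink_sites([read(100, 150, "+"), read(100, 150, "-")])
        assert trk.values(C, 99, 100, "+")[0] == 1  # + read -> site s-1
        assert trk.values(C, 150, 151, "-")[0] == 1  # - read -> site e
        assert trk.library_size == 2

    def test_five_prime_convention(self):
        trk = crosslink_sites([read(100, 150, "+"), read(100, 150, "-")], convention="five_prime")
        assert trk.values(C, 100, 101, "+")[0] == 1
        assert trk.values(C, 149, 150, "-")[0] == 1

    def test_site_below_zero_dropped_but_counted_in_library(self):
        trk = crosslink_sites([read(0, 30, "+")])
        assert trk.total() == 0
        assert trk.library_size == 1

    def test_empty_input_errors_on_normalization(self):
        trk = crosslink_sites([])
        with pytest.raises(ValueError, match="library_size"):
            rpm_normalize(trk)


class TestRpmNormalize:
    @pytest.mark.parametrize("library,expected", [(10**6, 1.0), (2 * 10**6, 0.5)])
    def test_scaling(self, library, expected):
        trk = site_track([500], library=library)
        rpm = rpm_normalize(trk)
        assert rpm.values(C, 500, 501, "+")[0] == pytest.approx(expected)


class TestFootprintScore:
    def test_enrichment_arithmetic_at_the_reported_scale(self):
        # 330 reads vs 10 reads per million in the 30-nt window -> ~33x
        feat = feature(1_000, 1_200, "+")
        mut = site_track(list(range(1_200, 1_230)) * 11, library=10**6).rpm()
        wt = site_track(list(range(1_200, 1_210)), library=10**6).rpm()
        res = footprint_score(feat, mut, wt, genome=GENOME)
        assert res.rpm_mut == pytest.approx(330.0)
        assert res.rpm_wt == pytest.approx(10.0)
        assert res.enrichment == pytest.approx(330.1 / 10.1, rel=1e-9)
        assert 32 < res.enrichment < 34

    def test_identical_tracks_give_unit_enrichment(self):
        feat = feature(1_000, 1_200, "+")
        trk = site_track(list(range(1_205, 1_215)), library=10**6).rpm()
        res = footprint_score(feat, trk, trk, genome=GENOME)
        assert res.enrichment == pytest.approx(1.0)

    def test_window_placement_excludes_mature_end(self):
        feat = feature(1_000, 1_200, "+")
        assert (footprint_score(feat, site_track([]).scaled(1, "RPM"),
                                site_track([]).scaled(1, "RPM"), genome=GENOME).window.start
                == 1_200)
        mfeat = feature(2_000, 2_200, "-")
        win = footprint_score(mfeat, site_track([], "-").scaled(1, "RPM"),
                              site_track([], "-").scaled(1, "RPM"), genome=GENOME).window
        assert (win.start, win.end) == (1_970, 2_000)

    def test_strand_mirror_symmetry(self):
        """Mirroring the locus (flip strand + coordinates) preserves results."""
        size = GENOME.length(C)
        feat = feature(1_000, 1_200, "+")
        sites = list(range(1_200, 1_230)) * 5
        mut = site_track(sites, "+", library=10**6).rpm()
        wt = site_track(sites[:30], "+", library=10**6).rpm()
        res = footprint_score(feat, mut, wt, genome=GENOME)

        mirror = lambda p: size - 1 - p
        mfeat = feature(mirror(1_199), mirror(999), "-")
        # site p on + maps to site mirror(p) on -
        msites = [mirror(p) for p in sites]
        mmut = site_track(msites, "-", library=10**6).rpm()
        mwt = site_track(msites[:30], "-", library=10**6).rpm()
        mres = footprint_score(mfeat, mmut, mwt, genome=GENOME)
        assert mres.enrichment == pytest.approx(res.enrichment)
        assert mres.est_width_nt == res.est_width_nt
        assert mres.rpm_mut == pytest.approx(res.rpm_mut)


class TestFlagTargets:
    def test_fifty_nt_rule(self):
        feat = feature(1_000, 1_200, "+")
        assert flag_targets([feat], site_track([1_240])) == [feat]  # +40 ok
        assert flag_targets([feat], site_track([1_260])) == []  # +60 too far
        assert flag_targets([feat], site_track([1_100])) == []  # gene body only

    def test_no_downstream_reads_flags_nothing(self):
        feats = [feature(1_000, 1_200, "+", "A"), feature(3_000, 3_100, "-", "B")]
        body_only = site_track([1_050, 1_199, 3_050])
        assert flag_targets(feats, body_only) == []


class TestFootprintWidth:
    def test_uniform_block_mass_fraction(self):
        feat = feature(1_000, 1_200, "+")
        trk = site_track(list(range(1_200, 1_230)))  # +1..+30 uniform
        assert footprint_width(feat, trk) == 27  # 27/30 = 0.9 exactly

    def test_single_site(self):
        feat = feature(1_000, 1_200, "+")
        assert footprint_width(feat, site_track([1_204])) == 5

    def test_no_downstream_signal_is_undefined(self):
        feat = feature(1_000, 1_200, "+")
        assert footprint_width(feat, site_track([1_100])) is None


class TestEndMetagene:
    def test_planted_block_appears_only_downstream_of_3p(self):
        feats = [feature(1_000, 1_200, "+", "A"), feature(5_000, 5_150, "+", "B")]
        sites = list(range(1_200, 1_230)) + list(range(5_150, 5_180))
        trk = site_track(sites, library=10**6).rpm()
        prof = feature_end_metagene(feats, trk, flank_nt=50)
        three = prof.set_index("offset")["three_prime"]
        assert (three.loc[1:30] > 0).all()
        assert three.loc[31:].sum() == 0
        assert three.loc[:-1].sum() == 0
        assert prof["five_prime"].sum() == 0

    def test_empty_track_gives_zeros(self):
        prof = feature_end_metagene([feature(1_000, 1_200)], site_track([]).scaled(1, "RPM"))
        assert prof["three_prime"].sum() == 0


class TestSimulatedRecovery:
    def test_planted_enrichment_grid_recovered(self):
        from exodecay import simulate

        for target in (10.0, 33.0, 100.0):
            genome, genes, truth = simulate.make_annotation(
                n_genes=30, n_snornas=12, n_enhancers=5, chrom_len=800_000, seed=8
            )
            wt = simulate.simulate_iclip(genome, genes, truth, "WT",
                                         footprint_enrichment=target, seed=8)
            cat = simulate.simulate_iclip(genome, genes, truth, "CAT",
                                          footprint_enrichment=target, seed=8)
            mut, wtt = crosslink_sites(cat).rpm(), crosslink_sites(wt).rpm()
            snos = [g for g in genes if g.biotype == "snoRNA"]
            res = [footprint_score(g, mut, wtt, genome=genome) for g in snos]
            measured = np.mean([r.enrichment for r in res])
            assert abs(measured - target) / target <= 0.20
            if target >= 33:
                # width is a 90%-mass estimate over the mutant track; it is
                # meaningful only where the footprint dominates background
                # readthrough, which a 10x block does not
                widths = [r.est_width_nt for r in res]
                assert all(25 <= w <= 35 for w in widths)
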