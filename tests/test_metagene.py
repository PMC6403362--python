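"""Windowing, overlap discard, binning and profile invariants."""

import numpy as np
import pytest

from exodecay.coverage import CoverageTrack, _Runs
from exodecay.intervals import GeneModel, Genome, GenomicInterval, TranscriptModel
from exodecay.metagene import (
    _binned_means,
    average_profile,
    discard_overlapping,
    extend_window,
    intron_exon_ratio,
    profile,
    prompt_region_profile,
    select_expressed,
)

C = "chr1"
GENOME = Genome({C: 1_000_000})


def gene(gene_id, start, end, strand="+"):
    span = GenomicInterval(C, start, end, strand)
    return GeneModel(gene_id, "protein_coding", span,
                     [TranscriptModel(f"{gene_id}.t", gene_id, strand, [span])])


def flat_track(value=1.0, size=1_000_000):
    trk = CoverageTrack(library_size=1_000_000, normalization="RPKM")
    for strand in ("+", "-"):
        trk.runs[(C, strand)] = _Runs(np.array([0]), np.array([size]), np.array([float(value)]))
    return trk


class TestExpressionFilter:
    def test_strict_boundary(self):
        counts = {"a": 51, "b": 50, "c": 49}
        assert select_expressed(counts) == {"a"}

    def test_empty(self):
        assert select_expressed({}) == set()


class TestExtendWindow:
    def test_plus_strand_extension(self):
        w = extend_window(gene("G", 5_000, 8_000), GENOME)
        assert (w.start, w.end) == (2_000, 15_000)

    def test_minus_strand_rejected_below_zero(self):
        assert extend_window(gene("G", 5_000, 8_000, "-"), GENOME) is None

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_window_length(self, strand):
        w = extend_window(gene("G", 500_000, 503_000, strand), GENOME)
        assert len(w) == 3_000 + 10_000


class TestDiscardOverlapping:
    def _w(self, s, e):
        return GenomicInterval(C, s, e)

    def test_disjoint_kept(self):
        ws = {"a": self._w(0, 100), "b": self._w(200, 300)}
        assert set(discard_overlapping(ws)) == {"a", "b"}

    def test_nested_pair_both_removed(self):
        ws = {"outer": self._w(0, 1000), "inner": self._w(100, 200), "far": self._w(5000, 6000)}
        assert set(discard_overlapping(ws)) == {"far"}

    def test_overlap_chain_removes_all_members(self):
        ws = {"a": self._w(0, 150), "b": self._w(100, 250), "c": self._w(200, 350)}
        assert discard_overlapping(ws) == {}


class TestProfile:
    def test_uniform_signal_is_flat_in_both_modes(self):
        trk = flat_track(1.0)
        regions = [("p", GenomicInterval(C, 50_000, 57_345, "+")),
                   ("m", GenomicInterval(C, 80_000, 84_321, "-"))]
        for mode in ("scale_body", "fixed"):
            m = profile(regions, trk, mode=mode, strand_mode="sense")
            assert np.abs(m.values - 1.0).max() < 1e-9

    def test_binning_matches_per_base_oracle(self):
        rng = np.random.default_rng(9)
        vals = rng.random(600)
        edges = np.linspace(0, 600, 31)
        mine = _binned_means(vals, edges)
        oracle = vals.reshape(30, 20).mean(axis=1)
        assert np.abs(mine - oracle).max() < 1e-9

    def test_mirrored_signal_gives_identical_rows(self):
        size = 2_000
        rng = np.random.default_rng(13)
        fwd = rng.poisson(3, size).astype(float)
        trk = CoverageTrack(library_size=1000, normalization="RPKM")
        trk.runs[(C, "+")] = _Runs(np.arange(size), np.arange(size) + 1, fwd)
        trk.runs[(C, "-")] = _Runs(np.arange(size), np.arange(size) + 1, fwd[::-1].copy())
        regions = [("p", GenomicInterval(C, 0, size, "+")), ("m", GenomicInterval(C, 0, size, "-"))]
        m = profile(regions, trk, mode="fixed", body_bins=40, strand_mode="sense")
        assert np.allclose(m.values[0], m.values[1])

    def test_fixed_mode_conserves_mass(self):
        rng = np.random.default_rng(21)
        arr = rng.poisson(2, 10_000).astype(float)
        trk = CoverageTrack.from_array(C, "+", arr, library_size=1000)
        trk.normalization = "RPKM"
        iv = GenomicInterval(C, 123, 8_888, "+")
        m = profile([("x", iv)], trk, mode="fixed", body_bins=97, strand_mode="sense")
        widths = np.diff(np.linspace(0, len(iv), 98))
        mass = float((m.values[0] * widths).sum())
        expect = arr[iv.start : iv.end].sum()
        assert abs(mass - expect) / expect < 1e-6

    def test_short_region_fractional_weighting(self):
        trk = flat_track(2.0)
        iv = GenomicInterval(C, 1_000, 1_033, "+")  # shorter than body_bins
        m = profile([("s", iv)], trk, up=100, down=100, flank_bin_bp=50,
                    body_bins=100, strand_mode="sense")
        assert np.abs(m.values - 2.0).max() < 1e-9


class TestAverageProfile:
    def test_hand_matrix(self):
        from exodecay.metagene import MetageneMatrix

        mat = MetageneMatrix(["a", "b"], np.array([[1.0, 2.0, 3.0], [3.0, 4.0, 5.0]]),
                             0, 3, 0, 50, "fixed")
        prof = average_profile(mat, median=True)
        assert prof["mean"].tolist() == [2.0, 3.0, 4.0]
        assert prof.attrs["n_regions"] == 2


class TestPromptRegionProfile:
    def test_antisense_only_signal(self):
        g = gene("G", 100_000, 110_000, "+")
        plus = CoverageTrack(library_size=100, normalization="RPM")
        minus = CoverageTrack(library_size=100, normalization="RPM")
        # PROMPT signal: antisense (minus) strand, 2 kb upstream of the TSS
        minus.runs[(C, "-")] = _Runs(np.array([98_000]), np.array([99_500]), np.array([4.0]))
        prof = prompt_region_profile([g], plus, minus)
        assert prof["sense"].max() == 0
        assert prof["antisense"].max() > 0

    def test_unstranded_track_gives_equal_profiles(self):
        g = gene("G", 100_000, 110_000, "+")
        trk = CoverageTrack(library_size=100, normalization="RPM", stranded=False)
        trk.runs[(C, ".")] = _Runs(np.array([97_000]), np.array([100_000]), np.array([1.0]))
        prof = prompt_region_profile([g], trk, trk)
        assert np.allclose(prof["sense"], prof["antisense"])


class TestIntronExonRatio:
    def test_density_arithmetic(self):
        ratios = intron_exon_ratio({"g": (40, 2_000)}, {"g": (10, 1_000)})
        assert ratios["g"] == pytest.approx(2.0)

    def test_zero_exon_gene_omitted(self):
        assert intron_exon_ratio({"g": (40, 2_000)}, {"g": (0, 1_000)}) == {}

    def test_planted_first_intron_effect_recovered(self, sim_bundle):
        from exodecay.differential import count_reads
        from exodecay.introns import first_exon, select_intron

        genes = [g for g in sim_bundle["genes"] if g.biotype == "protein_coding"]
        i1 = select_intron(genes, 1)
        e1 = {g.gene_id: first_exon(g) for g in genes if g.gene_id in i1}

        def ratio_sums(reads):
            ivs = [(f"I_{g}", i1[g]) for g in i1] + [(f"E_{g}", e1[g]) for g in i1]
            tab = count_reads({"s": reads}, ivs, {"s": "x"})
            c = {name: int(tab.counts[k, 0]) for k, (name, _) in enumerate(tab.intervals)}
            icounts = {g: (c[f"I_{g}"], len(i1[g])) for g in i1}
            ecounts = {g: (c[f"E_{g}"], len(e1[g])) for g in i1}
            return intron_exon_ratio(icounts, ecounts)

        rc = ratio_sums(sim_bundle["rnaseq"]["control_rep1"])
        rd = ratio_sums(sim_bundle["rnaseq"]["depleted_rep1"])
        common = [g for g in rc if g in rd and rc[g] > 0]
        fold = np.median([rd[g] / rc[g] for g in common])
        assert 3.0 < fold < 5.0  # planted 4x within NB sampling noise
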