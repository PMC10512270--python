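"""Allele classification thresholds, haplotype matrix, tracks and LOH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ploidypaint as pp
from conftest import make_sites
from ploidypaint.synthetic_data import STATE_FRACTION


def calls_from_freqs(freqs, depth=100):
    alt = [int(round(f * depth)) for f in freqs]
    ref = [depth - a for a in alt]
    t = make_sites("c1", [10 * (i + 1) for i in range(len(freqs))], ref, alt)
    return pp.classify_alleles(t)


class TestClassifyAlleles:
    @pytest.mark.parametrize(
        "freq,expected",
        [
            (0.35, "other"),   # above the 0.2 acceptance threshold
            (0.05, "lupina"),  # below the 0.1 error threshold
            (0.15, "missing"), # conservative middle band
            (0.10, "missing"), # closed endpoints go to missing
            (0.20, "missing"),
        ],
    )
    def test_threshold_partition(self, freq, expected):
        calls = calls_from_freqs([freq])
        assert calls.df["call"].iloc[0] == expected

    @given(freq=st.floats(0, 1))
    @settings(max_examples=100, derandomize=True)
    def test_partition_is_exhaustive_and_exclusive(self, freq):
        call = calls_from_freqs([freq], depth=1000).df["call"].iloc[0]
        f = calls_from_freqs([freq], depth=1000).df["other_freq"].iloc[0]
        if f > 0.2:
            assert call == "other"
        elif f < 0.1:
            assert call == "lupina"
        else:
            assert call == "missing"

    def test_sites_absent_from_reference_calls_become_missing(self):
        calls = pp.classify_alleles(
            make_sites("c1", [10, 20], [50, 50], [50, 50]),
            reference_calls={("c1", 10)},
        )
        assert list(calls.df["call"]) == ["other", "missing"]


class TestUnfoldedAF:
    def test_all_loh_lupina_mass_below_error_threshold(self):
        spec = pp.MosaicSpec({"c1": 100_000}, {"c1": [(0, 100_000, "LOH_lupina")]})
        table, _ = pp.simulate_hybrid_mosaic(spec, seed=1)
        h = pp.unfolded_af(pp.classify_alleles(table))
        assert h.mass(0, 0.1) > 0.999

    def test_balanced_mosaic_bimodal_with_mass_matching_block_proportions(
        self, mosaic_spec, mosaic_sim
    ):
        table, truth = mosaic_sim
        h = pp.unfolded_af(pp.classify_alleles(table))
        p_13 = (truth["state"] == "other_1of3").mean()
        p_23 = (truth["state"] == "other_2of3").mean()
        m_13 = h.mass(1 / 3 - 0.08, 1 / 3 + 0.08)
        m_23 = h.mass(2 / 3 - 0.08, 2 / 3 + 0.08)
        # classified sites only: LOH_lupina sites are in the "lupina" pile
        denom = m_13 + m_23
        assert abs(m_13 / denom - p_13 / (p_13 + p_23)) < 0.1
        assert abs(m_23 / denom - p_23 / (p_13 + p_23)) < 0.1


class TestHaplotypeMatrix:
    def test_incomplete_columns_dropped(self):
        calls = calls_from_freqs([0.4, 0.4, 0.4, 0.4, 0.4])
        hap = make_sites("c1", [10, 20, 30, 50], [100, 100, 100, 100], [0, 0, 0, 0])
        # haploid missing at pos0 40 -> that column is dropped
        m = pp.build_haplotype_matrix(calls, {"h1": hap, "h2": hap, "h3": hap})
        assert m.n_sites() == 4

    def test_needs_at_least_four_haplotypes(self):
        calls = calls_from_freqs([0.4])
        with pytest.raises(ValueError):
            pp.build_haplotype_matrix(calls, {"h1": make_sites("c1", [10], [100], [0])})

    def test_haploid_noise_below_cutoff_keeps_consensus(self):
        calls = calls_from_freqs([0.4, 0.4, 0.4, 0.4])
        noisy = make_sites("c1", [10, 20, 30, 40], [98, 98, 98, 98], [2, 2, 2, 2])
        m = pp.build_haplotype_matrix(calls, {"h1": noisy, "h2": noisy, "h3": noisy})
        assert m.n_sites() == 4
        assert m.alleles.loc["h1"].notna().all()

    def test_haploid_minor_allele_at_cutoff_masks_site(self):
        calls = calls_from_freqs([0.4, 0.4, 0.4, 0.4])
        noisy = make_sites("c1", [10, 20, 30, 40], [95, 98, 98, 98], [5, 2, 2, 2])
        m = pp.build_haplotype_matrix(calls, {"h1": noisy, "h2": noisy, "h3": noisy})
        assert m.n_sites() == 3  # 5% minor allele -> masked -> column dropped

    def test_other_haplotype_recovers_donor_genotype(self, panel):
        calls = pp.classify_alleles(panel.metagenome)
        m = pp.build_haplotype_matrix(calls, panel.haploids)
        other = m.alleles.loc["other"]
        donor = m.alleles.loc[panel.donor]
        truth = panel.truth.set_index("pos0")["state"]
        states = truth.reindex(m.sites["pos0"]).to_numpy()
        in_other_block = np.isin(states, ["other_1of3", "other_2of3"])
        ok = other.notna().to_numpy() & in_other_block
        agree = (other[ok] == donor[ok]).mean()
        assert agree > 0.95


class TestWindowedMedianAndLOH:
    def test_single_site_window_median_is_that_frequency(self):
        calls = calls_from_freqs([0.34])
        track = pp.windowed_median(calls, window_bp=7_500)
        assert np.isclose(track.df["median"].iloc[0], 0.34)

    def test_median_invariant_to_site_order_within_window(self):
        freqs = [0.3, 0.5, 0.4, 0.35, 0.45]
        a = calls_from_freqs(freqs)
        b = calls_from_freqs(freqs[::-1])
        ta = pp.windowed_median(a, 1_000)
        tb = pp.windowed_median(b, 1_000)
        assert np.isclose(ta.df["median"].iloc[0], tb.df["median"].iloc[0])

    def test_windows_tile_from_zero_with_partial_tail(self):
        calls = calls_from_freqs([0.4])
        track = pp.windowed_median(
            calls, 7_500, contigs=pp.ContigIndex({"c1": 20_000})
        )
        assert track.df[["start", "end"]].values.tolist() == [
            [0, 7_500], [7_500, 15_000], [15_000, 20_000]
        ]
        assert track.df["partial"].tolist() == [False, False, True]

    def test_repeat_overlapping_window_is_missing(self):
        calls = calls_from_freqs([0.4])
        repeats = pp.RepeatTrack(
            pd.DataFrame({"contig": ["c1"], "start": [5], "end": [15]})
        )
        track = pp.windowed_median(calls, 7_500, repeats=repeats)
        assert np.isnan(track.df["median"].iloc[0])

    def test_loh_tract_recovery_within_one_window(self):
        blocks = [
            (0, 60_000, "other_1of3"),
            (60_000, 100_000, "LOH_lupina"),
            (100_000, 160_000, "other_2of3"),
        ]
        spec = pp.MosaicSpec({"c1": 160_000}, {"c1": blocks}, het_density=0.01)
        table, _ = pp.simulate_hybrid_mosaic(spec, seed=3)
        track = pp.windowed_median(
            pp.classify_alleles(table), 7_500, contigs=pp.ContigIndex({"c1": 160_000})
        )
        tracts = pp.detect_loh_tracts(track)
        lup = tracts[tracts["direction"] == "lupina"]
        assert len(lup) == 1
        assert abs(lup["start"].iloc[0] - 60_000) <= 7_500
        assert abs(lup["end"].iloc[0] - 100_000) <= 7_500

    def test_loh_other_direction(self):
        blocks = [
            (0, 40_000, "other_1of3"),
            (40_000, 90_000, "LOH_other"),
            (90_000, 130_000, "other_1of3"),
        ]
        spec = pp.MosaicSpec({"c1": 130_000}, {"c1": blocks}, het_density=0.01)
        table, _ = pp.simulate_hybrid_mosaic(spec, seed=4)
        track = pp.windowed_median(
            pp.classify_alleles(table), 7_500, contigs=pp.ContigIndex({"c1": 130_000})
        )
        tracts = pp.detect_loh_tracts(track)
        assert (tracts["direction"] == "other").any()

    def test_no_tracts_when_medians_near_one_third(self):
        spec = pp.MosaicSpec({"c1": 100_000}, {"c1": [(0, 100_000, "other_1of3")]})
        table, _ = pp.simulate_hybrid_mosaic(spec, seed=5)
        track = pp.windowed_median(pp.classify_alleles(table), 7_500)
        assert len(pp.detect_loh_tracts(track)) == 0

    def test_loh_consecutive_windows_in_mosaic(self, mosaic_spec, mosaic_sim):
        """A simulated >=30 kb LOH tract yields >=3 consecutive low windows."""
        table, truth = mosaic_sim
        long_loh = [
            (c, s, e)
            for c, blocks in mosaic_spec.blocks.items()
            for s, e, st_ in blocks
            if st_ == "LOH_lupina" and e - s >= 30_000
        ]
        if not long_loh:
            pytest.skip("random fixture produced no long LOH block")
        contig, s, e = long_loh[0]
        track = pp.windowed_median(
            pp.classify_alleles(table), 7_500,
            contigs=pp.ContigIndex(dict(mosaic_spec.contigs)),
        )
        sub = track.df[
            (track.df["contig"] == contig)
            & (track.df["start"] >= s)
            & (track.df["end"] <= e)
        ]
        assert (sub["median"] < 0.1).sum() >= 3
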