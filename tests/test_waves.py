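"""Leading-edge wave caller: difference tracks, tiling, region calling,
upstream-TSS annotation, rates and processivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polkinetics import waves
from polkinetics.tracks import SignalTrack
from polkinetics.waves import WaveParams, TileVector


def stranded_track(values, chrom="chr1", strand="+"):
    t = SignalTrack({chrom: len(values)})
    t.array(chrom, strand)[:] = values
    return t


class TestDifferenceTrack:
    def test_subtracts_and_censors(self):
        a = stranded_track([5.0, 1.0, 2.0])
        b = stranded_track([2.0, 2.0, 2.0])
        d = waves.difference_track(a, b)
        assert list(d.array("chr1", "+")) == [3.0, 0.0, 0.0]

    def test_self_difference_is_zero(self, rng):
        a = stranded_track(rng.poisson(2.0, 100))
        d = waves.difference_track(a, a)
        assert d.total() == 0

    def test_mismatched_genomes_error(self):
        with pytest.raises(ValueError):
            waves.difference_track(stranded_track([1.0]),
                                   SignalTrack({"chr2": 1}))


def reference_smooth(raw):
    """Independent reference for the one-step running maximum."""
    return np.array([raw[0]] + [max(raw[i - 1], raw[i])
                                for i in range(1, len(raw))])


class TestTileAndSmooth:
    def test_max_rule_example(self):
        raw = np.array([300, 0, 300])
        assert list(waves.smooth_covered(raw)) == [300, 300, 300]

    def test_all_zero_track(self):
        tiles = waves.tile_and_smooth(stranded_track(np.zeros(5000)))
        plus = [tv for tv in tiles if tv.strand == "+"][0]
        assert plus.covered.sum() == 0 and plus.signal_sum.sum() == 0

    def test_covered_and_summed_per_tile(self):
        v = np.zeros(2500)
        v[0:300] = 2.0      # tile 0: 300 covered, sum 600
        v[1100:1150] = 1.0  # tile 1: 50 covered, sum 50
        tiles = waves.tile_and_smooth(stranded_track(v))
        tv = [t for t in tiles if t.strand == "+"][0]
        assert list(tv.covered) == [300, 50, 0]
        assert list(tv.signal_sum) == [600.0, 50.0, 0.0]
        assert list(tv.smoothed_covered) == [300, 300, 50]

    def test_smoothing_matches_reference_on_random_vectors(self, rng):
        for _ in range(1000):
            raw = rng.integers(0, 1000, size=rng.integers(1, 30))
            assert np.array_equal(waves.smooth_covered(raw),
                                  reference_smooth(raw))


def brute_force_regions(retained_tiles, tile, merge_gap, min_len, chrom_size):
    """O(n^2) reference: merge every pair of retained tiles transitively if
    within merge_gap, then length-filter."""
    ivs = [(s, min(s + tile, chrom_size)) for s in retained_tiles]
    merged = []
    for iv in sorted(ivs):
        if merged and iv[0] - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], iv[1]))
        else:
            merged.append(iv)
    return [iv for iv in merged if iv[1] - iv[0] >= min_len]


def tiles_from_flags(flags, tile=1000, signal=10.0, chrom_size=None):
    """TileVector whose retained pattern is exactly ``flags`` (no smoothing
    interference: retained tiles are fully covered with high signal)."""
    n = len(flags)
    covered = np.where(flags, tile, 0)
    sig = np.where(flags, signal, 0.0)
    starts = np.arange(0, n * tile, tile)
    return TileVector("chr1", "+", tile, starts, covered, sig,
                      covered.copy(), chrom_size or n * tile)


class TestCallExpressedRegions:
    def test_three_kb_boundary_region_kept(self):
        tv = tiles_from_flags(np.array([1, 1, 1, 0, 0], dtype=bool))
        out = waves.call_expressed_regions([tv])
        assert len(out) == 1
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (0, 3000)

    def test_short_fragments_dropped(self):
        # two retained 1 kb tiles separated by 5 kb of dropped tiles
        flags = np.zeros(8, dtype=bool)
        flags[[0, 6]] = True
        out = waves.call_expressed_regions([tiles_from_flags(flags)])
        assert len(out) == 0

    def test_four_kb_gap_merged_inclusive(self):
        flags = np.zeros(7, dtype=bool)
        flags[[0, 5]] = True  # gap between tile ends: 4000 bp
        out = waves.call_expressed_regions([tiles_from_flags(flags)])
        assert len(out) == 1 and out.loc[0, "end"] == 6000

    def test_low_signal_tile_removed(self):
        tv = tiles_from_flags(np.ones(4, dtype=bool))
        tv.signal_sum[:] = 0.05  # below the 0.1 normalized-signal threshold
        assert len(waves.call_expressed_regions([tv])) == 0

    def test_smoothed_coverage_is_what_counts(self):
        tv = tiles_from_flags(np.ones(4, dtype=bool))
        tv.covered[:] = 0            # raw fails ...
        tv.smoothed_covered[:] = 250  # ... smoothed passes at exactly 25%
        assert len(waves.call_expressed_regions([tv])) == 1

    @given(st.lists(st.booleans(), min_size=1, max_size=60),
           st.integers(min_value=0, max_value=6))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, flags, gap_tiles):
        params = WaveParams(merge_gap=1000 * gap_tiles + 17)
        flags = np.asarray(flags, dtype=bool)
        tv = tiles_from_flags(flags)
        got = waves.call_expressed_regions([tv], params)
        expected = brute_force_regions(
            list(tv.starts[flags]), 1000, params.merge_gap,
            params.min_region_len, tv.chrom_size)
        assert [(r.start, r.end) for r in got.itertuples()] == expected


def tss_frame(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                     "gene_id"])
    df["tss_id"] = df["gene_id"]
    return df


def region_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


class TestAnnotateUpstreamTss:
    def test_closest_upstream_wins(self):
        tss = tss_frame([("chr1", 8000, 8010, "+", "gA"),
                         ("chr1", 50_000, 50_010, "+", "gB")])
        reg = region_frame([("chr1", 10_000, 20_000, "+")])
        out = waves.annotate_to_upstream_tss(reg, tss)
        assert list(out["gene_id"]) == ["gA"]

    def test_region_upstream_of_all_tss_unassigned(self):
        tss = tss_frame([("chr1", 50_000, 50_010, "+", "gB")])
        reg = region_frame([("chr1", 10_000, 20_000, "+")])
        assert len(waves.annotate_to_upstream_tss(reg, tss)) == 0

    def test_minus_strand_mirror(self):
        tss = tss_frame([("chr1", 30_000, 30_010, "-", "gC")])
        reg = region_frame([("chr1", 10_000, 30_000, "-")])
        out = waves.annotate_to_upstream_tss(reg, tss)
        assert list(out["gene_id"]) == ["gC"]
        assert out.loc[0, "tss_pos"] == 30_010

    def test_empty_tss_errors(self):
        with pytest.raises(ValueError):
            waves.annotate_to_upstream_tss(region_frame([]), tss_frame([]))

    def test_matches_brute_force_scan(self, rng):
        slack = 1000
        tss_rows = [("chr1", int(p), int(p) + 10, s, f"g{i}")
                    for i, (p, s) in enumerate(zip(
                        rng.integers(0, 10**6, 40),
                        rng.choice(["+", "-"], 40)))]
        tss = tss_frame(tss_rows)
        regs = region_frame([
            ("chr1", int(s), int(s) + int(rng.integers(3000, 50_000)), st_)
            for s, st_ in zip(rng.integers(0, 10**6, 500),
                              rng.choice(["+", "-"], 500))])
        got = waves.annotate_to_upstream_tss(regs, tss, slack=slack)
        got_map = {(r.start, r.end, r.strand): r.gene_id
                   for r in got.itertuples()}
        for r in regs.itertuples(index=False):
            cands = []
            for t in tss.itertuples(index=False):
                pos = t.start if t.strand == "+" else t.end
                if t.strand != r.strand:
                    continue
                if r.strand == "+" and pos <= r.start + slack:
                    cands.append((pos, t.gene_id))
                if r.strand == "-" and pos >= r.end - slack:
                    cands.append((-pos, t.gene_id))
            key = (r.start, r.end, r.strand)
            if not cands:
                assert key not in got_map
            else:
                assert got_map[key] == max(cands)[1]


def annotated(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "gene_id", "tss_pos", "condition",
                                       "timepoint"])


class TestElongationRates:
    params = WaveParams(timepoints=(10,))

    def test_rate_arithmetic(self):
        reg = annotated([("chr1", 0, 33_700, "+", "g1", 0, "WT", 10),
                         ("chr1", 0, 26_200, "+", "g2", 0, "WT", 10)])
        rates, medians = waves.elongation_rates(reg, self.params)
        by_gene = rates.set_index("gene_id")["rate_kb_per_min"]
        assert by_gene["g1"] == pytest.approx(3.37)
        assert by_gene["g2"] == pytest.approx(2.62)
        assert medians["median_rate_kb_per_min"].iloc[0] == \
            pytest.approx((3.37 + 2.62) / 2)

    def test_minus_strand_edge_is_region_start(self):
        reg = annotated([("chr1", 66_300, 100_000, "-", "g1", 100_000,
                          "WT", 10)])
        rates, _ = waves.elongation_rates(reg, self.params)
        assert rates.loc[0, "rate_kb_per_min"] == pytest.approx(3.37)

    def test_gene_missing_anywhere_excluded_everywhere(self):
        params = WaveParams(timepoints=(10, 25))
        rows = [("chr1", 0, 30_000, "+", "g1", 0, c, t)
                for c in ("WT", "KO") for t in (10, 25)]
        rows += [("chr1", 0, 30_000, "+", "g2", 0, "WT", 10),
                 ("chr1", 0, 30_000, "+", "g2", 0, "WT", 25),
                 ("chr1", 0, 30_000, "+", "g2", 0, "KO", 10)]  # KO t25 missing
        rates, _ = waves.elongation_rates(annotated(rows), params)
        assert set(rates["gene_id"]) == {"g1"}

    def test_nonpositive_distance_excluded(self):
        reg = annotated([("chr1", 0, 30_000, "+", "g1", 40_000, "WT", 10)])
        rates, _ = waves.elongation_rates(reg, self.params)
        assert len(rates) == 0


class TestProcessivityIndex:
    body = {"chrom": "chr1", "start": 0, "end": 100_000, "strand": "+"}

    def _uniform_track(self, lam, rng):
        t = SignalTrack({"chr1": 100_000})
        t.array("chr1", "+")[:] = rng.poisson(lam, 100_000)
        return t

    def test_equal_windows_give_zero(self):
        t = SignalTrack({"chr1": 100_000})
        t.array("chr1", "+")[:10_000] = 0.01   # proximal 100 reads
        t.array("chr1", "+")[90_000:] = 0.01   # distal 100 reads
        idx, flag = waves.processivity_index(t, self.body)
        assert idx == pytest.approx(0.0) and flag is None

    def test_tenfold_distal_gives_one(self):
        t = SignalTrack({"chr1": 100_000})
        t.array("chr1", "+")[:10_000] = 0.01
        t.array("chr1", "+")[90_000:] = 0.1
        idx, _ = waves.processivity_index(t, self.body)
        assert idx == pytest.approx(1.0)

    def test_uniform_track_index_near_zero(self, rng):
        lam = 0.1  # ~1000 reads per 10 kb window
        t = self._uniform_track(lam, rng)
        idx, flag = waves.processivity_index(t, self.body)
        # 3 SE of log10 ratio of two Poisson(1000) counts
        se = 3 * np.sqrt(2 / 1000) / np.log(10)
        assert flag is None and abs(idx) < se

    def test_zero_proximal_flagged(self):
        t = SignalTrack({"chr1": 100_000})
        t.array("chr1", "+")[90_000:] = 0.1
        idx, flag = waves.processivity_index(t, self.body)
        assert np.isnan(idx) and flag == "zero_proximal"

    def test_invalid_fractions(self):
        with pytest.raises(ValueError):
            waves.processivity_index(SignalTrack({"chr1": 100}), self.body,
                                     proximal_frac=0.6)


class TestWaveParamsValidation:
    def test_rejects_bad_fraction(self):
        with pytest.raises(ValueError):
            WaveParams(min_covered_frac=0.0)

    def test_rejects_nonpositive_tile(self):
        with pytest.raises(ValueError):
            WaveParams(tile=0)
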