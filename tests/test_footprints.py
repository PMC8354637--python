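import numpy as np
import pytest

from seclipkit.footprints import (
    Footprint,
    FootprintCallConfig,
    call_footprints,
    compare_signal,
    count_target_genes,
    enrichment_fc,
    subtract_background,
)
from seclipkit.intervals import GenomicInterval

from .conftest import library_from_sites
from .oracles import brute_force_call, brute_force_subtract

SITE_A = GenomicInterval("chr1", 1000, 1050, "+")
SITE_B = GenomicInterval("chr1", 5000, 5050, "+")


def _call(sites_rep1, sites_rep2, input_sites1=None, input_sites2=None, **cfg_kwargs):
    clip = {
        1: library_from_sites(sites_rep1, "WT_CLIP", 1),
        2: library_from_sites(sites_rep2, "WT_CLIP", 2),
    }
    inputs = {
        1: library_from_sites(input_sites1 or [], "WT_INPUT", 1),
        2: library_from_sites(input_sites2 or [], "WT_INPUT", 2),
    }
    return call_footprints(clip, inputs, FootprintCallConfig(**cfg_kwargs))


def _mk_footprint(start, end, strand="+", sample="WT", rpm=10.0, gene=None):
    return Footprint(
        interval=GenomicInterval("chr1", start, end, strand),
        sample=sample,
        clip_counts={1: 30, 2: 30},
        clip_rpm={1: rpm, 2: rpm},
        input_rpm={1: 1.0, 2: 1.0},
        fold_change={1: 5.0, 2: 5.0},
        passing_replicates=[1, 2],
        gene_id=gene,
    )


class TestEnrichmentFC:
    def test_small_pseudocount_approaches_plain_ratio(self):
        assert enrichment_fc(30, 20, 1e-9) == pytest.approx(1.5)

    def test_equal_signal_gives_one_for_any_pseudocount(self):
        for pc in (0.01, 1.0, 100.0):
            assert enrichment_fc(7.5, 7.5, pc) == 1.0

    def test_zero_input_with_unit_pseudocount(self):
        assert enrichment_fc(10, 0, 1.0) == 11.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            enrichment_fc(10, -1, 1.0)


class TestCallFootprints:
    def test_one_passing_replicate_suffices(self):
        # rep1: 25 reads vs input 5 (FC > 1.5); rep2 present but weak
        fps = _call(
            [(SITE_A, 25)], [(SITE_A, 5)],
            input_sites1=[(SITE_A, 5)], input_sites2=[(SITE_A, 5)],
        )
        assert len(fps) == 1
        assert fps[0].passing_replicates == [1]

    def test_single_replicate_cluster_rejected_despite_strong_signal(self):
        fps = _call([(SITE_A, 100)], [], input_sites1=[(SITE_A, 1)])
        assert fps == []

    def test_threshold_boundaries_inclusive(self):
        # FC is exactly (20+1)/(13+1) = 1.5 with the unit pseudocount
        retained = _call(
            [(SITE_A, 20)], [(SITE_A, 20)],
            input_sites1=[(SITE_A, 13)], input_sites2=[(SITE_A, 13)],
        )
        assert len(retained) == 1
        rejected_reads = _call(
            [(SITE_A, 19)], [(SITE_A, 19)],
            input_sites1=[(SITE_A, 1)], input_sites2=[(SITE_A, 1)],
        )
        assert rejected_reads == []
        # FC exactly (148+1)/(99+1) = 1.49 in both replicates
        rejected_fc = _call(
            [(SITE_A, 148)], [(SITE_A, 148)],
            input_sites1=[(SITE_A, 99)], input_sites2=[(SITE_A, 99)],
        )
        assert rejected_fc == []

    def test_both_replicates_scope(self):
        sites1 = [(SITE_A, 25)]
        sites2 = [(SITE_A, 5)]
        either = _call(sites1, sites2, threshold_scope="either_replicate")
        both = _call(sites1, sites2, threshold_scope="both_replicates")
        assert len(either) == 1 and both == []

    def test_consensus_interval_is_union_of_matched_clusters(self):
        a = GenomicInterval("chr1", 1000, 1040, "+")
        b = GenomicInterval("chr1", 1030, 1080, "+")
        fps = _call([(a, 30)], [(b, 30)])
        assert fps[0].interval == GenomicInterval("chr1", 1000, 1080, "+")

    def test_missing_input_library_errors(self):
        clip = {
            1: library_from_sites([(SITE_A, 30)], "WT_CLIP", 1),
            2: library_from_sites([(SITE_A, 30)], "WT_CLIP", 2),
        }
        with pytest.raises(ValueError, match="INPUT"):
            call_footprints(clip, {1: library_from_sites([], "WT_INPUT", 1)})

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(31)
        sites1, sites2, in1, in2 = [], [], [], []
        for i in range(40):
            iv = GenomicInterval("chr1", 1000 * i, 1000 * i + 50, "+")
            sites1.append((iv, int(rng.integers(0, 60))))
            sites2.append((iv, int(rng.integers(0, 60))))
            in1.append((iv, int(rng.integers(0, 30))))
            in2.append((iv, int(rng.integers(0, 30))))
        base = {f.interval for f in _call(sites1, sites2, in1, in2)}
        stricter_reads = {
            f.interval for f in _call(sites1, sites2, in1, in2, min_reads=30)
        }
        stricter_fc = {f.interval for f in _call(sites1, sites2, in1, in2, min_fc=3.0)}
        assert stricter_reads <= base
        assert stricter_fc <= base

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(37)
        for _ in range(5):
            sites = []
            for i in range(30):
                start = int(rng.integers(0, 5000))
                sites.append(
                    GenomicInterval("chr1", start, start + int(rng.integers(20, 80)),
                                    str(rng.choice(["+", "-"])))
                )
            s1 = [(iv, int(rng.integers(0, 50))) for iv in sites]
            s2 = [(iv, int(rng.integers(0, 50))) for iv in sites]
            i1 = [(iv, int(rng.integers(0, 25))) for iv in sites]
            i2 = [(iv, int(rng.integers(0, 25))) for iv in sites]
            clip = {
                1: library_from_sites(s1, "WT_CLIP", 1),
                2: library_from_sites(s2, "WT_CLIP", 2),
            }
            inputs = {
                1: library_from_sites(i1, "WT_INPUT", 1),
                2: library_from_sites(i2, "WT_INPUT", 2),
            }
            got = sorted(
                (f.interval for f in call_footprints(clip, inputs)),
                key=lambda v: (v.chrom, v.strand, v.start, v.end),
            )
            expected = brute_force_call(clip, inputs)
            assert got == expected


class TestSubtractBackground:
    def test_one_bp_overlap_removes(self):
        fp = _mk_footprint(100, 150)
        bg = _mk_footprint(149, 200, sample="dRRM")
        assert subtract_background([fp], [[bg]]) == []

    def test_non_overlapping_survives_unchanged(self):
        fp = _mk_footprint(100, 150)
        bg = _mk_footprint(150, 200, sample="dRRM")
        out = subtract_background([fp], [[bg]])
        assert out == [fp]

    def test_opposite_strand_background_ignored(self):
        fp = _mk_footprint(100, 150, strand="+")
        bg = _mk_footprint(100, 150, strand="-", sample="dRRM")
        assert subtract_background([fp], [[bg]]) == [fp]

    def test_empty_background_is_identity(self):
        fps = [_mk_footprint(0, 50), _mk_footprint(100, 150)]
        assert subtract_background(fps, [[]]) == fps

    def test_idempotent_and_antimonotone(self):
        rng = np.random.default_rng(41)
        fps = [_mk_footprint(int(s), int(s) + 40) for s in rng.integers(0, 3000, 25)]
        bg1 = [_mk_footprint(int(s), int(s) + 40, sample="dRRM") for s in rng.integers(0, 3000, 8)]
        bg2 = [_mk_footprint(int(s), int(s) + 40, sample="IgG") for s in rng.integers(0, 3000, 8)]
        once = subtract_background(fps, [bg1])
        twice = subtract_background(once, [bg1])
        assert once == twice
        more = subtract_background(fps, [bg1, bg2])
        assert set(f.interval for f in more) <= set(f.interval for f in once)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(43)
        fps = [_mk_footprint(int(s), int(s) + 50) for s in rng.integers(0, 4000, 30)]
        bg = [_mk_footprint(int(s), int(s) + 50, sample="IgG") for s in rng.integers(0, 4000, 10)]
        got = [f.interval for f in subtract_background(fps, [bg])]
        expected = brute_force_subtract([f.interval for f in fps], [b.interval for b in bg])
        assert got == expected


class TestCountTargetGenes:
    def test_simple_tally(self):
        fps = [
            _mk_footprint(0, 50, gene="geneA"),
            _mk_footprint(100, 150, gene="geneA"),
            _mk_footprint(200, 250, gene="geneA"),
            _mk_footprint(300, 350, gene="geneB"),
        ]
        assert count_target_genes(fps) == (4, 2)

    def test_identical_footprints_across_samples_count_once(self):
        wt = _mk_footprint(0, 50, sample="WT", gene="geneA")
        mut = _mk_footprint(0, 50, sample="C130Y", gene="geneA")
        assert count_target_genes([wt, mut]) == (1, 1)

    def test_matches_brute_force_set_union(self):
        rng = np.random.default_rng(47)
        fps = []
        for i in range(200):
            s = int(rng.integers(0, 20000))
            fps.append(
                _mk_footprint(s, s + 40, sample=str(rng.choice(["WT", "C130Y"])),
                              gene=f"gene{int(rng.integers(0, 60)):03d}")
            )
        n_fp, n_genes = count_target_genes(fps)
        # brute-force union of overlapping intervals
        ivs = sorted([f.interval for f in fps], key=lambda v: v.start)
        merged = []
        for iv in ivs:
            if merged and iv.start < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], iv.end)
            else:
                merged.append([iv.start, iv.end])
        assert n_fp == len(merged)
        assert n_genes == len({f.gene_id for f in fps})


class TestCompareSignal:
    def test_identical_sets_sit_on_diagonal(self):
        wt = [_mk_footprint(100 * i, 100 * i + 50, rpm=float(2 + i)) for i in range(5)]
        mut = [
            _mk_footprint(100 * i, 100 * i + 50, sample="C130Y", rpm=float(2 + i))
            for i in range(5)
        ]
        df = compare_signal(wt, mut)
        assert len(df) == 5
        assert (df["log2_rpm_wt"] - df["log2_rpm_c130y"]).abs().max() < 1e-12

    def test_absent_footprint_reports_log2_pseudocount(self):
        wt = [_mk_footprint(0, 50, rpm=8.0)]
        df = compare_signal(wt, [], pseudocount=1.0)
        assert df.loc[0, "log2_rpm_c130y"] == pytest.approx(np.log2(1.0))
        assert df.loc[0, "log2_rpm_wt"] == pytest.approx(np.log2(9.0))

    def test_matches_brute_force_overlap_matching(self):
        rng = np.random.default_rng(53)
        wt = [
            _mk_footprint(int(s), int(s) + 50, rpm=float(rng.uniform(1, 20)))
            for s in rng.integers(0, 5000, 20)
        ]
        mut = [
            _mk_footprint(int(s), int(s) + 50, sample="C130Y", rpm=float(rng.uniform(1, 20)))
            for s in rng.integers(0, 5000, 20)
        ]
        df = compare_signal(wt, mut, pseudocount=1.0)
        # brute force: union-find over pairwise overlaps of all footprints
        from .oracles import _UnionFind, _pairwise_overlap

        allf = wt + mut
        uf = _UnionFind(len(allf))
        for i in range(len(allf)):
            for j in range(i + 1, len(allf)):
                if _pairwise_overlap(allf[i].interval, allf[j].interval):
                    uf.union(i, j)
        groups = {}
        for i, f in enumerate(allf):
            groups.setdefault(uf.find(i), []).append(f)
        expected = set()
        for members in groups.values():
            a = sum(f.mean_rpm for f in members if f.sample == "WT")
            b = sum(f.mean_rpm for f in members if f.sample == "C130Y")
            expected.add((round(np.log2(a + 1), 9), round(np.log2(b + 1), 9)))
        got = {
            (round(x, 9), round(y, 9))
            for x, y in zip(df["log2_rpm_wt"], df["log2_rpm_c130y"])
        }
        assert got == expected
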