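"""Hard filters, coverage/indel filters, mask arithmetic, windows, VCF I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chelonia.core import CallableMask
from chelonia.variantio import (
    VariantRecord,
    coverage_filter,
    filter_records,
    hard_filter,
    indel_proximity_filter,
    intersect_masks,
    make_windows,
    read_bed,
    read_vcf,
    write_bed,
    write_genotype_table_vcf,
    write_vcf,
)


def rec(pos=100, ref="A", alt=("G",), qual=100.0, info=None, scaffold="s"):
    return VariantRecord(
        scaffold=scaffold, pos=pos, ref=ref, alt=tuple(alt), qual=qual, info=info or {}
    )


GOOD_INFO = {"FS": 1.0, "QD": 20.0, "MQ": 60.0, "MQRankSum": 0.0, "ReadPosRankSum": 0.0}


class TestHardFilter:
    def test_clean_biallelic_snp_kept(self):
        keep, reasons = hard_filter(rec(info=dict(GOOD_INFO)))
        assert keep and reasons == []

    @pytest.mark.parametrize(
        "override,expected_reason",
        [
            ({"qual": 59.0}, "QUAL<60"),
            ({"info": {**GOOD_INFO, "FS": 61.0}}, "FS>60"),
            ({"info": {**GOOD_INFO, "QD": 1.5}}, "QD<2"),
            ({"info": {**GOOD_INFO, "MQ": 39.0}}, "MQ<40"),
            ({"info": {**GOOD_INFO, "MQRankSum": -25.0}}, "MQRankSum<-20"),
            ({"info": {**GOOD_INFO, "ReadPosRankSum": -9.0}}, "ReadPosRankSum<-8"),
            ({"alt": ("G", "T")}, "not biallelic SNP"),
            ({"ref": "AT"}, "not biallelic SNP"),
        ],
    )
    def test_each_criterion_fires_with_named_reason(self, override, expected_reason):
        keep, reasons = hard_filter(rec(**override))
        assert not keep and expected_reason in reasons

    def test_absent_info_does_not_fire(self):
        # GATK emits rank-sum annotations only at het sites
        keep, reasons = hard_filter(rec(info={}))
        assert keep and reasons == []

    def test_all_violations_reported_together(self):
        keep, reasons = hard_filter(rec(qual=10, info={"QD": 0.5, "FS": 99.0}))
        assert not keep and set(reasons) == {"QUAL<60", "QD<2", "FS>60"}

    @given(
        qual=st.floats(0, 200),
        qd=st.floats(0, 40),
        fs=st.floats(0, 100),
        mq=st.floats(0, 70),
    )
    @settings(max_examples=50, deadline=None)
    def test_kept_iff_no_criterion_violated(self, qual, qd, fs, mq):
        r = rec(qual=qual, info={"QD": qd, "FS": fs, "MQ": mq})
        keep, reasons = hard_filter(r)
        violated = qual < 60 or qd < 2 or fs > 60 or mq < 40
        assert keep == (not violated)
        assert keep == (len(reasons) == 0)

    def test_annotate_vs_drop_modes_agree(self):
        records = [rec(pos=p, qual=q) for p, q in [(1, 100), (2, 10), (3, 61)]]
        annotated = filter_records([r for r in records], mode="annotate")
        dropped = filter_records([r for r in records], mode="drop")
        assert [r.pos for r in annotated if r.filter == "PASS"] == [r.pos for r in dropped]


class TestCoverageFilter:
    def test_uniform_depth_no_exclusions(self):
        assert coverage_filter(np.full(100, 30.0), 30.0).size == 0

    def test_spike_run_excluded_exactly(self):
        depth = np.full(1000, 30.0)
        depth[200:300] = 150.0  # 5x mean
        iv = coverage_filter(depth, 30.0)
        assert iv.tolist() == [[200, 300]]

    def test_matches_per_base_brute_force(self):
        rng = np.random.default_rng(4)
        depth = rng.poisson(30, size=1000).astype(float)
        depth[[10, 500, 900]] = 300.0
        depth[50:60] = 1.0
        iv = coverage_filter(depth, 30.0, k=4)
        excluded = np.zeros(1000, dtype=bool)
        for s, e in iv:
            excluded[s:e] = True
        brute = (depth > 120.0) | (depth < 7.5)
        assert np.array_equal(excluded, brute)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            coverage_filter(np.array([]), 30.0)


class TestIndelProximity:
    def _records(self, indel_qual):
        return [
            VariantRecord("s", 100, "A", ("AT",), qual=indel_qual),  # indel
            VariantRecord("s", 103, "C", ("T",), qual=100.0),  # 3 bp away
            VariantRecord("s", 106, "C", ("T",), qual=100.0),  # 6 bp away
        ]

    def test_snp_within_radius_of_confident_indel_dropped(self):
        kept = indel_proximity_filter(self._records(70.0))
        assert [r.pos for r in kept] == [106]

    def test_snp_beyond_radius_kept(self):
        kept = indel_proximity_filter(self._records(70.0))
        assert 106 in [r.pos for r in kept]

    def test_low_quality_indel_does_not_trigger(self):
        kept = indel_proximity_filter(self._records(50.0))
        assert [r.pos for r in kept] == [103, 106]

    def test_unsorted_input_rejected(self):
        records = [rec(pos=10), rec(pos=5)]
        with pytest.raises(ValueError, match="sorted"):
            indel_proximity_filter(records)


def mask(d):
    return CallableMask({k: np.array(v, dtype=np.int64).reshape(-1, 2) for k, v in d.items()})


class TestIntersectMasks:
    def test_self_intersection_identity(self):
        m = mask({"s": [[0, 100], [200, 300]]})
        out = intersect_masks([m, m])
        assert np.array_equal(out.intervals["s"], m.intervals["s"])

    def test_simple_overlap(self):
        out = intersect_masks([mask({"s": [[0, 100]]}), mask({"s": [[50, 150]]})])
        assert out.intervals["s"].tolist() == [[50, 100]]

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_matches_bitmap_and_is_commutative(self, data):
        L = 200

        def rand_mask():
            starts = sorted(data.draw(st.lists(st.integers(0, L - 2), min_size=0, max_size=5)))
            iv, last = [], 0
            for s in starts:
                if s < last:
                    continue
                e = data.draw(st.integers(s + 1, L))
                iv.append([s, e])
                last = e
            return mask({"s": iv}) if iv else mask({"s": []})

        ms = [rand_mask() for _ in range(3)]
        out = intersect_masks(ms)
        bitmap = np.ones(L, dtype=bool)
        for m in ms:
            b = np.zeros(L, dtype=bool)
            for s, e in m.intervals.get("s", []):
                b[s:e] = True
            bitmap &= b
        got = np.zeros(L, dtype=bool)
        for s, e in out.intervals.get("s", []):
            got[s:e] = True
        assert np.array_equal(got, bitmap)
        # commutativity
        out2 = intersect_masks(ms[::-1])
        got2 = np.zeros(L, dtype=bool)
        for s, e in out2.intervals.get("s", []):
            got2[s:e] = True
        assert np.array_equal(got, got2)


class TestMakeWindows:
    def test_exact_tiling(self):
        ws = make_windows({"s": 1_000_000}, 100_000)
        assert len(ws) == 10 and not any(w.partial for w in ws)

    def test_short_scaffold_excluded(self):
        assert make_windows({"s": 499_000}, 100_000, min_scaffold=500_000) == []

    def test_trailing_partial_flagged(self):
        ws = make_windows({"s": 1_050_000}, 100_000)
        assert len(ws) == 11
        assert ws[-1].partial and ws[-1].span == 50_000
        assert not any(w.partial for w in ws[:-1])


class TestVcfRoundTrip:
    def test_records_roundtrip_modelled_fields(self, tmp_path):
        records = [
            rec(pos=10, qual=88.5, info={"QD": 12.5, "MQ": 55.0}),
            rec(pos=20, ref="C", alt=("T",), qual=None),
            VariantRecord("s", 30, "G", ("A", "T"), qual=99.0),
        ]
        for r in records:
            r.genotypes = ((0, 1), (1, 1))
            r.depths = (20, 18)
        p = tmp_path / "x.vcf"
        write_vcf(p, records, ["a", "b"], contigs={"s": 1000})
        back, samples = read_vcf(p)
        assert samples == ["a", "b"]
        for orig, rt in zip(records, back):
            assert (rt.scaffold, rt.pos, rt.ref, rt.alt) == (
                orig.scaffold,
                orig.pos,
                orig.ref,
                orig.alt,
            )
            assert rt.qual == (orig.qual if orig.qual is not None else None)
            for k, v in orig.info.items():
                assert rt.info[k] == pytest.approx(v)
            assert rt.genotypes == orig.genotypes
            assert rt.depths == orig.depths

    def test_genotype_table_roundtrip(self, tmp_path, turtle_sim):
        from chelonia.variantio import read_genotype_table

        g = turtle_sim.genotypes
        p = tmp_path / "sim.vcf"
        write_genotype_table_vcf(g, p)
        back = read_genotype_table(p)
        assert back.samples == g.samples
        for name in g.scaffolds:
            assert np.array_equal(back.scaffolds[name].pos, g.scaffolds[name].pos)
            assert np.array_equal(back.scaffolds[name].gt, g.scaffolds[name].gt)
        assert back.scaffold_lengths == g.scaffold_lengths

    def test_bed_roundtrip(self, tmp_path):
        m = mask({"s1": [[0, 100], [250, 300]], "s2": [[10, 20]]})
        p = tmp_path / "m.bed"
        write_bed(m, p)
        back = read_bed(p)
        for k in m.intervals:
            assert np.array_equal(back.intervals[k], m.intervals[k])
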