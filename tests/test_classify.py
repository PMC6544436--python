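"""TE+/TE-/non-enhancer classification and its summaries."""

import numpy as np
import pandas as pd
import pytest

from tescout.annotation import MappabilityScore
from tescout.classify import (
    NON_ENHANCER,
    TE_MINUS,
    TE_PLUS,
    UNCLASSIFIED,
    call_te_minus_enhancers,
    call_te_plus_enhancers,
    mean_methylation_per_element,
    overlap_fraction_matrix,
    select_non_enhancer_tes,
)
from tescout.intervals import GenomicInterval, Peak, PeakSet, TECopy


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def build_peakset(sample="ESC", **assay_intervals):
    ps = PeakSet(sample)
    for assay, intervals in assay_intervals.items():
        assay = assay.replace("TF_", "TF:")
        ps.by_assay[assay] = [Peak(i, assay, 1.0) for i in intervals]
    return ps


class TestTePlus:
    def test_full_signature_far_from_tss_is_called(self):
        copies = [TECopy(iv(10_000, 10_350), "RLTR13D6", "c1")]
        ps = build_peakset(
            ATAC=[iv(10_100, 10_200)],
            H3K27ac=[iv(9_900, 10_500)],
            H3K4me3=[],
            TF_NANOG=[iv(10_150, 10_180)],
        )
        (call,) = call_te_plus_enhancers(copies, ps, [iv(20_000, 20_001)], ["NANOG"])
        assert call.klass == TE_PLUS

    def test_tss_proximity_excludes(self):
        copies = [TECopy(iv(10_000, 10_350), "RLTR13D6", "c1")]
        ps = build_peakset(
            ATAC=[iv(10_100, 10_200)],
            H3K27ac=[iv(9_900, 10_500)],
            H3K4me3=[],
            TF_NANOG=[iv(10_150, 10_180)],
        )
        (call,) = call_te_plus_enhancers(
            copies, ps, [iv(10_650, 10_651)], ["NANOG"]
        )  # 300 bp from element end
        assert call.klass == UNCLASSIFIED
        assert not call.evidence["tss_far"]

    def test_missing_assay_reported(self):
        copies = [TECopy(iv(10_000, 10_350), "RLTR13D6", "c1")]
        ps = build_peakset(ATAC=[], H3K27ac=[], H3K4me3=[])
        with pytest.raises(KeyError, match="TF:NANOG"):
            call_te_plus_enhancers(copies, ps, [iv(0, 1)], ["NANOG"])

    def test_twenty_element_truth_table(self, rng):
        """Exhaustive check of the conjunctive rule against hand enumeration."""
        tss = [iv(200_000, 200_001)]
        copies, ps = [], PeakSet("ESC")
        ps.by_assay = {a: [] for a in ("ATAC", "H3K27ac", "H3K4me3", "TF:OCT4")}
        expected = []
        for i in range(20):
            start = 10_000 + i * 2_000
            copies.append(TECopy(iv(start, start + 350), "RLTR13D6", f"c{i}"))
            has = {a: bool(rng.integers(0, 2)) for a in ps.by_assay}
            for a, flag in has.items():
                if flag:
                    ps.by_assay[a].append(Peak(iv(start + 100, start + 200), a, 1.0))
            expected.append(
                has["ATAC"] and has["H3K27ac"] and has["TF:OCT4"] and not has["H3K4me3"]
            )
        calls = call_te_plus_enhancers(copies, ps, tss, ["OCT4"])
        assert [c.klass == TE_PLUS for c in calls] == expected

    def test_removing_h3k27ac_always_demotes(self):
        copies = [TECopy(iv(10_000, 10_350), "RLTR13D6", "c1")]
        kwargs = dict(
            ATAC=[iv(10_100, 10_200)],
            H3K27ac=[iv(9_900, 10_500)],
            H3K4me3=[],
            TF_NANOG=[iv(10_150, 10_180)],
        )
        tss = [iv(100_000, 100_001)]
        assert call_te_plus_enhancers(copies, build_peakset(**kwargs), tss, ["NANOG"])[0].klass == TE_PLUS
        kwargs["H3K27ac"] = []
        assert call_te_plus_enhancers(copies, build_peakset(**kwargs), tss, ["NANOG"])[0].klass == UNCLASSIFIED


class TestTeMinus:
    def _peakset(self):
        return build_peakset(
            ATAC=[iv(10_000, 10_400), iv(30_000, 30_400)],
            H3K27ac=[iv(9_900, 10_500), iv(29_900, 30_500)],
            H3K4me3=[],
            TF_OCT4=[iv(10_100, 10_200), iv(30_100, 30_200)],
        )

    def test_single_base_repeat_overlap_disqualifies(self):
        ps = self._peakset()
        repeats = [iv(30_399, 30_500)]  # 1 bp overlap with the second peak
        calls = call_te_minus_enhancers(
            ps.by_assay["ATAC"], repeats, ps, [iv(200_000, 200_001)], ["OCT4"]
        )
        assert [c.klass for c in calls] == [TE_MINUS, UNCLASSIFIED]

    def test_repeat_free_peak_with_signature_called(self):
        ps = self._peakset()
        calls = call_te_minus_enhancers(
            ps.by_assay["ATAC"], [], ps, [iv(200_000, 200_001)], ["OCT4"]
        )
        assert all(c.klass == TE_MINUS for c in calls)


class TestNonEnhancerSelection:
    def _setup(self, rng, n=40, n_plus=5):
        copies = [
            TECopy(iv(10_000 + i * 1_000, 10_350 + i * 1_000), "RLTR13D6", f"c{i:02d}")
            for i in range(n)
        ]
        calls = [
            # first n_plus copies are TE+ enhancers
            type("C", (), {})()
            for _ in range(0)
        ]
        from tescout.classify import EnhancerCall

        calls = [
            EnhancerCall(c.copy_id, c.interval, TE_PLUS if i < n_plus else UNCLASSIFIED, family=c.family)
            for i, c in enumerate(copies)
        ]
        scores = [MappabilityScore(c.copy_id, 1.0, 40) for c in copies]
        signal = {c.copy_id: float(rng.random() * 10) for c in copies}
        return copies, calls, scores, signal

    def test_twice_the_te_plus_count(self, rng):
        copies, calls, scores, signal = self._setup(rng)
        out = select_non_enhancer_tes(copies, scores, signal, calls)
        assert sum(c.klass == NON_ENHANCER for c in out) == 10

    def test_unmappable_copy_never_selected(self, rng):
        copies, calls, scores, signal = self._setup(rng)
        scores[20] = MappabilityScore(copies[20].copy_id, 0.4, 40)
        signal[copies[20].copy_id] = 0.0  # lowest signal but unmappable
        out = select_non_enhancer_tes(copies, scores, signal, calls)
        selected = {c.element_id for c in out if c.klass == NON_ENHANCER}
        assert copies[20].copy_id not in selected

    def test_matches_sort_and_slice_oracle(self, rng):
        copies, calls, scores, signal = self._setup(rng)
        out = select_non_enhancer_tes(copies, scores, signal, calls)
        selected = {c.element_id for c in out if c.klass == NON_ENHANCER}
        eligible = sorted(
            (c.copy_id for c in copies[5:]), key=lambda cid: (signal[cid], cid)
        )
        assert selected == set(eligible[:10])

    def test_no_element_is_both_enhancer_and_control(self, rng):
        copies, calls, scores, signal = self._setup(rng)
        out = select_non_enhancer_tes(copies, scores, signal, calls)
        classes = {}
        for c in out:
            assert c.element_id not in classes
            classes[c.element_id] = c.klass
        assert len(classes) == len(copies)

    def test_shortfall_flagged(self, rng):
        copies, calls, scores, signal = self._setup(rng, n=8, n_plus=5)
        out = select_non_enhancer_tes(copies, scores, signal, calls)
        chosen = [c for c in out if c.klass == NON_ENHANCER]
        assert len(chosen) == 3  # only 3 eligible though 10 requested
        assert all(c.warning for c in chosen)


class TestOverlapFractionMatrix:
    def test_fraction_of_replicates(self):
        elements = {"TEplus": [iv(1000, 1400)]}
        samples = {
            "s1": [iv(1100, 1200)],
            "s2": [iv(1150, 1250)],
            "s3": [iv(9000, 9100)],
            "s4": [iv(8000, 8100)],
        }
        grouping = {s: "brain" for s in samples}
        m = overlap_fraction_matrix(elements, samples, grouping, per_element=True)
        assert m.loc["TEplus|chr1:1000-1400", "brain"] == 0.5

    def test_unoverlapped_element_is_zero_everywhere(self):
        elements = {"TEplus": [iv(1000, 1400)]}
        samples = {"s1": [iv(9000, 9100)], "s2": [iv(8000, 8100)]}
        m = overlap_fraction_matrix(elements, samples, {"s1": "a", "s2": "b"}, per_element=True)
        assert (m.loc["TEplus|chr1:1000-1400"] == 0).all()

    def test_per_set_mode_matches_direct_counting(self, rng):
        elements = {
            "setA": [iv(int(s), int(s) + 200) for s in rng.choice(50_000, 25, replace=False)],
            "setB": [iv(int(s), int(s) + 200, "chr2") for s in rng.choice(50_000, 25, replace=False)],
        }
        samples = {
            f"s{k}": [iv(int(s), int(s) + 300, c) for s in rng.choice(50_000, 30) for c in ["chr1", "chr2"]]
            for k in range(3)
        }
        m = overlap_fraction_matrix(elements, samples)
        for label, elems in elements.items():
            for sample, peaks in samples.items():
                direct = np.mean(
                    [
                        any(
                            e.chrom == p.chrom and min(e.end, p.end) > max(e.start, p.start)
                            for p in peaks
                        )
                        for e in elems
                    ]
                )
                assert m.loc[label, sample] == pytest.approx(direct)


class TestMethylation:
    def test_weighted_mean(self):
        cpg = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [1100, 1200], "meth": [4, 0], "total": [4, 4]}
        )
        out = mean_methylation_per_element([iv(1000, 1400)], cpg)
        assert out.iloc[0] == 0.5

    def test_no_cpg_is_missing_not_zero(self):
        cpg = pd.DataFrame({"chrom": ["chr1"], "pos": [99_000], "meth": [1], "total": [2]})
        out = mean_methylation_per_element([iv(1000, 1400)], cpg)
        assert np.isnan(out.iloc[0])

    def test_group_difference_in_planted_direction(self, world):
        from tescout.classify import calls_to_frame

        te_plus = world.te_plus_ids
        lo = [c.interval for c in world.copies if c.copy_id in te_plus]
        hi = [c.interval for c in world.copies if c.copy_id not in te_plus][:60]
        m_lo = mean_methylation_per_element(lo, world.methylation)
        m_hi = mean_methylation_per_element(hi, world.methylation)
        assert m_lo.median() < m_hi.median()
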