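"""Gene linking, normalization, allelic and CRISPRi analyses, simple DE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp
from statsmodels.stats.multitest import multipletests

from tescout.intervals import GenomicInterval, TECopy
from tescout.linking import (
    InteractionMap,
    RestrictionFragment,
    allele_specific_elements,
    allelic_gene_effects,
    crispri_h3k27ac_effect,
    differential_expression_simple,
    exclusive_gene_partition,
    histogram_match_normalize,
    lineage_ratio,
    link_elements_to_genes,
)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def frag(start, end, fid, genes=(), chrom="chr1"):
    return RestrictionFragment(iv(start, end, chrom), fid, bool(genes), tuple(genes))


class TestLinking:
    def test_direct_lookup_through_interaction(self):
        fragments = [frag(0, 5000, "P1", ("GeneA",)), frag(5000, 9000, "F12")]
        inter = InteractionMap([("P1", "F12", 1.0)])
        links = link_elements_to_genes({"e": iv(6000, 6400)}, fragments, inter)
        assert links["e"] == {"GeneA"}

    def test_fragment_without_interactions_gives_empty_set(self):
        fragments = [frag(0, 5000, "P1", ("GeneA",)), frag(5000, 9000, "F12")]
        links = link_elements_to_genes(
            {"e": iv(6000, 6400)}, fragments, InteractionMap([])
        )
        assert links["e"] == frozenset()

    def test_promoter_only_overlap_warns_and_gives_empty(self):
        fragments = [frag(0, 5000, "P1", ("GeneA",))]
        with pytest.warns(UserWarning, match="promoter fragments only"):
            links = link_elements_to_genes(
                {"e": iv(1000, 1400)}, fragments, InteractionMap([])
            )
        assert links["e"] == frozenset()

    def test_forty_element_fixture_matches_hand_join(self, rng):
        fragments, inter_pairs, elements, expected = [], [], {}, {}
        for i in range(40):
            base = i * 10_000
            fragments.append(frag(base, base + 4_000, f"P{i}", (f"G{i}",)))
            fragments.append(frag(base + 4_000, base + 10_000, f"F{i}"))
            elements[f"e{i}"] = iv(base + 5_000, base + 5_400)
            if rng.random() < 0.6:
                j = int(rng.integers(0, 40))
                inter_pairs.append((f"P{j}", f"F{i}", 1.0))
                expected[f"e{i}"] = {f"G{j}"}
            else:
                expected[f"e{i}"] = set()
        links = link_elements_to_genes(elements, fragments, InteractionMap(inter_pairs))
        assert {k: set(v) for k, v in links.items()} == expected


class TestExclusivePartition:
    def test_examples(self):
        plus = {"e1": frozenset({"A", "B"})}
        minus = {"m1": frozenset({"B", "C"})}
        part = exclusive_gene_partition(plus, minus)
        assert part == {
            "TE_plus_only": {"A"},
            "TE_minus_only": {"C"},
            "excluded_both": {"B"},
        }

    @settings(derandomize=True, max_examples=100)
    @given(
        plus=st.lists(st.sets(st.integers(0, 30)), max_size=5),
        minus=st.lists(st.sets(st.integers(0, 30)), max_size=5),
    )
    def test_groups_disjoint_and_exhaustive(self, plus, minus):
        lp = {f"p{i}": frozenset(s) for i, s in enumerate(plus)}
        lm = {f"m{i}": frozenset(s) for i, s in enumerate(minus)}
        part = exclusive_gene_partition(lp, lm)
        groups = list(part.values())
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (groups[i] & groups[j])
        all_genes = set().union(*lp.values(), *lm.values()) if (lp or lm) else set()
        assert set().union(*groups) == all_genes


class TestHistogramMatching:
    def test_identical_sample_unchanged(self, rng):
        x = rng.lognormal(1, 1, 500)
        df = pd.DataFrame({"ref": x, "same": x.copy()})
        out = histogram_match_normalize(df, "ref")
        np.testing.assert_allclose(out["same"], x)

    def test_scaled_sample_maps_exactly_onto_reference(self, rng):
        x = rng.lognormal(1, 1, 500)
        df = pd.DataFrame({"ref": x, "doubled": 2 * x})
        out = histogram_match_normalize(df, "ref")
        np.testing.assert_allclose(np.sort(out["doubled"]), np.sort(x))

    def test_unequal_lengths_reach_small_ks_distance(self, rng):
        n = 10_000
        df = pd.DataFrame(
            {
                "ref": rng.lognormal(1, 1, n),
                "a": np.concatenate([rng.lognormal(3, 0.4, n - 123), [np.nan] * 123]),
            }
        )
        out = histogram_match_normalize(df, "ref")
        ks = ks_2samp(out["a"].dropna(), df["ref"], method="asymp").statistic
        assert ks < 0.01

    def test_idempotent_to_machine_precision(self, rng):
        df = pd.DataFrame(
            {"ref": rng.lognormal(1, 1, 1000), "a": rng.lognormal(0, 2, 1000)}
        )
        once = histogram_match_normalize(df, "ref")
        twice = histogram_match_normalize(once, "ref")
        np.testing.assert_array_equal(once.to_numpy(), twice.to_numpy())

    def test_constant_sample_maps_to_reference_median(self, rng):
        df = pd.DataFrame({"ref": rng.lognormal(1, 1, 101), "flat": np.full(101, 7.0)})
        with pytest.warns(UserWarning, match="constant"):
            out = histogram_match_normalize(df, "ref")
        assert (out["flat"] == np.median(df["ref"])).all()


class TestLineageRatio:
    def test_arithmetic_with_pseudocount(self):
        expr = pd.DataFrame({"ESC_1": [8.0], "TSC_1": [2.0]}, index=["g"])
        r = lineage_ratio(expr, {"ESC_1": "ESC", "TSC_1": "TSC"})
        assert r["g"] == pytest.approx(np.log2(9 / 3))

    def test_silent_gene_excluded(self):
        expr = pd.DataFrame({"ESC_1": [0.0, 5.0], "TSC_1": [0.0, 5.0]}, index=["off", "on"])
        r = lineage_ratio(expr, {"ESC_1": "ESC", "TSC_1": "TSC"})
        assert "off" not in r.index and "on" in r.index

    def test_planted_bias_recovered_on_world(self, world):
        r = lineage_ratio(world.expression, world.sample_tissue)
        truth = world.truth
        esc_genes = truth[
            (truth["label"] == "TE_plus_enhancer") & (truth["lineage"] == "ESC")
        ]["linked_gene"]
        tsc_genes = truth[
            (truth["label"] == "TE_plus_enhancer") & (truth["lineage"] == "TSC")
        ]["linked_gene"]
        assert r[esc_genes].median() > 1
        assert r[tsc_genes].median() < -1


class TestAllelicFilter:
    def _copies(self):
        return [TECopy(iv(100, 400), "RLTR13D6", "c1")]

    def test_skewed_peak_selected(self):
        peaks = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [400], "reads_129": [9], "reads_cast": [1]}
        )
        sel, tes = allele_specific_elements(peaks, self._copies())
        assert len(sel) == 1 and [t.copy_id for t in tes] == ["c1"]

    def test_read_floor_rejects(self):
        peaks = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [400], "reads_129": [2], "reads_cast": [2]}
        )
        sel, tes = allele_specific_elements(peaks, self._copies())
        assert len(sel) == 0

    def test_boundaries_are_strict(self):
        peaks = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [100] * 3,
                "end": [400] * 3,
                # ratio exactly 0.8; max reads exactly 4; passing control
                "reads_129": [8, 4, 9],
                "reads_cast": [2, 0, 1],
            }
        )
        sel, _ = allele_specific_elements(peaks, self._copies())
        assert list(sel.index) == [2]

    def test_symmetric_under_allele_swap(self, rng):
        peaks = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(1000) * 500,
                "end": np.arange(1000) * 500 + 300,
                "reads_129": rng.integers(0, 40, 1000),
                "reads_cast": rng.integers(0, 40, 1000),
            }
        )
        sel, _ = allele_specific_elements(peaks, [])
        swapped = peaks.rename(
            columns={"reads_129": "reads_cast", "reads_cast": "reads_129"}
        )
        sel_sw, _ = allele_specific_elements(swapped, [])
        assert sorted(sel.index) == sorted(sel_sw.index)

    def test_thousand_peaks_match_direct_enumeration(self, world):
        peaks = world.allelic_peaks
        sel, _ = allele_specific_elements(peaks, world.copies)
        total = peaks["reads_129"] + peaks["reads_cast"]
        ratio = peaks["reads_129"] / total
        expected = peaks[
            (total > 0)
            & (peaks[["reads_129", "reads_cast"]].max(axis=1) >= 5)
            & ((ratio > 0.8) | (ratio < 0.2))
        ]
        assert list(sel.index) == list(expected.index)


class TestAllelicGeneEffects:
    def test_distant_gene_not_a_candidate(self):
        tss = {"far": iv(300_000, 300_001), "near": iv(50_000, 50_001)}
        expr = pd.DataFrame(
            {"reads_129": [30, 30], "reads_cast": [10, 30]}, index=["far", "near"]
        )
        out = allelic_gene_effects([iv(100, 400)], tss, expr)
        assert set(out["gene"]) == {"near"}

    def test_fold_flagging(self):
        tss = {"g": iv(50_000, 50_001)}
        expr = pd.DataFrame({"reads_129": [30], "reads_cast": [10]}, index=["g"])
        out = allelic_gene_effects([iv(100, 400)], tss, expr)
        assert bool(out.loc[0, "affected"])

    def test_planted_affected_genes_recovered_on_world(self, world):
        sel, as_tes = allele_specific_elements(world.allelic_peaks, world.copies)
        out = allelic_gene_effects(
            [t.interval for t in as_tes], world.tss, world.allelic_expression
        )
        flagged = set(out.loc[out["affected"], "gene"])
        planted = set(
            world.allelic_expression.index[world.allelic_expression["planted_affected"]]
        )
        assert flagged == planted


class TestCrispriEffect:
    def _copies(self, n=4):
        return [TECopy(iv(i * 1000, i * 1000 + 350), "RLTR13D6", f"c{i}") for i in range(n)]

    def test_strong_loss_requires_peak_overlap(self):
        copies = self._copies(2)
        table, _ = crispri_h3k27ac_effect(
            copies,
            {"c0": 100.0, "c1": 100.0},
            {"c0": 40.0, "c1": 40.0},
            {"c0": 2, "c1": 2},
            {"c0": True, "c1": False},
        )
        assert table.set_index("element_id")["strong_loss"].to_dict() == {
            "c0": True,
            "c1": False,
        }

    def test_identical_signals_not_counted(self):
        copies = self._copies(1)
        table, _ = crispri_h3k27ac_effect(
            copies, {"c0": 80.0}, {"c0": 80.0}, {"c0": 3}, {"c0": True}
        )
        assert not table["strong_loss"].any()
        assert table["log2_effect"].iloc[0] == 0.0

    def test_untargeted_family_summarised_separately(self, world):
        cr = world.crispri.set_index("element_id")
        table, summary = crispri_h3k27ac_effect(
            world.copies,
            cr["signal_control"].to_dict(),
            cr["signal_crispri"].to_dict(),
            cr["hits"].to_dict(),
            cr["peak_overlap"].to_dict(),
        )
        groups = set(summary["group"])
        assert groups == {"targeted", "untargeted_control"}
        ctrl = summary[summary["group"] == "untargeted_control"]
        assert set(ctrl["stratum"]) == {"0"}

    def test_stratum_means_track_planted_effect(self, world):
        cr = world.crispri.set_index("element_id")
        table, _ = crispri_h3k27ac_effect(
            world.copies,
            cr["signal_control"].to_dict(),
            cr["signal_crispri"].to_dict(),
            cr["hits"].to_dict(),
            cr["peak_overlap"].to_dict(),
        )
        by_hits = table.groupby("hits")["log2_effect"].mean()
        assert by_hits.is_monotonic_increasing


class TestDifferentialExpression:
    def test_identical_matrices_nothing_significant(self, rng):
        counts = pd.DataFrame(rng.poisson(50, (100, 3)), index=[f"g{i}" for i in range(100)])
        res = differential_expression_simple(counts, counts.copy())
        assert not res["significant"].any()

    def test_planted_knockdown_detected_with_negative_fold(self, rng):
        genes = [f"g{i}" for i in range(200)]
        base = rng.uniform(100, 400, 200)
        ctrl = pd.DataFrame(
            {f"c{r}": rng.poisson(base) for r in range(3)}, index=genes
        )
        treated_mean = base.copy()
        treated_mean[0] /= 8  # planted 8-fold knockdown in g0
        trt = pd.DataFrame(
            {f"t{r}": rng.poisson(treated_mean) for r in range(3)}, index=genes
        )
        res = differential_expression_simple(ctrl, trt)
        assert bool(res.loc["g0", "significant"])
        assert res.loc["g0", "log2_fold_change"] < -2

    def test_bh_flags_match_manual_computation(self):
        pvec = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.36])
        rej, _, _, _ = multipletests(pvec, alpha=0.05, method="fdr_bh")
        # manual BH: largest i with p_(i) <= i/m * alpha, all smaller ranks flagged
        m = len(pvec)
        order = np.argsort(pvec)
        thresh = (np.arange(1, m + 1) / m) * 0.05
        passing = np.flatnonzero(np.sort(pvec) <= thresh)
        manual = np.zeros(m, bool)
        if passing.size:
            manual[order[: passing.max() + 1]] = True
        assert (rej == manual).all()

    def test_all_zero_gene_excluded(self, rng):
        counts = pd.DataFrame(rng.poisson(30, (10, 3)), index=[f"g{i}" for i in range(10)])
        counts.iloc[4] = 0
        other = counts.copy()
        res = differential_expression_simple(counts, other)
        assert "g4" not in res.index
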