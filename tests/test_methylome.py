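"""Binning, the dual chi-square DMR rule, region summaries and the GLM test."""

import io as _io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from paramethyl import methylome, simulate
from paramethyl.io import CytosineReportError, read_cytosine_report, read_bed, write_cytosine_report
from paramethyl.methylome import (
    bin_counts,
    call_dmrs,
    chisq_2x2,
    classify_dmrs,
    filter_bins,
    region_glm_test,
    sliding_window_profile,
    weighted_level,
    write_dmr_bed,
)


# ---------------------------------------------------------------------------
# cytosine report IO


class TestReportIO:
    def test_empty_file(self):
        assert read_cytosine_report(_io.StringIO("")).empty

    def test_round_trip(self, toy_report):
        buf = _io.StringIO()
        write_cytosine_report(toy_report, buf)
        buf.seek(0)
        back = read_cytosine_report(buf)
        pd.testing.assert_frame_equal(back, toy_report)

    @pytest.mark.parametrize(
        "line, fragment",
        [
            ("2\t10\t+\t3\t7\tCHN\tNNN", "line 2"),
            ("2\t10\t+\t-3\t7\tCG\tNNN", "line 2"),
            ("2\t10\t*\t3\t7\tCG\tNNN", "line 2"),
            ("2\t10\t+\t3\t7", "line 2"),
            ("2\tten\t+\t3\t7\tCG\tNNN", "line 2"),
        ],
    )
    def test_malformed_line_cites_line_number(self, line, fragment):
        text = "2\t5\t+\t1\t1\tCG\tNNN\n" + line + "\n"
        with pytest.raises(CytosineReportError, match=fragment):
            read_cytosine_report(_io.StringIO(text))


# ---------------------------------------------------------------------------
# binning


class TestBinning:
    def test_boundary_arithmetic(self):
        rec = pd.DataFrame(
            {
                "chrom": "2", "pos": [1, 200, 201], "strand": "+",
                "meth": [1, 1, 1], "unmeth": [0, 0, 0], "context": "CG",
            }
        )
        bins = bin_counts(rec)
        assert set(bins["start"]) == {0, 200}
        first = bins.loc[bins["start"] == 0].iloc[0]
        assert first["meth"] == 2  # pos 1 and 200 share bin [0, 200)

    def test_strands_pooled(self, toy_report):
        bins = bin_counts(toy_report)
        cg0 = bins.query("start == 0 and context == 'CG'").iloc[0]
        assert cg0["meth"] == 4 and cg0["total"] == 20  # + and - strand summed

    def test_conservation_per_context(self, random_report):
        bins = bin_counts(random_report)
        for ctx in ("CG", "CHG", "CHH"):
            rec = random_report[random_report["context"] == ctx]
            sub = bins[bins["context"] == ctx]
            assert sub["meth"].sum() == rec["meth"].sum()
            assert sub["total"].sum() == (rec["meth"] + rec["unmeth"]).sum()

    def test_bad_bin_size(self, toy_report):
        with pytest.raises(ValueError):
            bin_counts(toy_report, bin_size=0)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(1, 10_000))
    def test_single_record_lands_in_its_bin(self, pos):
        rec = pd.DataFrame(
            {"chrom": "1", "pos": [pos], "strand": "+", "meth": [2],
             "unmeth": [3], "context": "CG"}
        )
        bins = bin_counts(rec)
        assert bins["start"].item() == ((pos - 1) // 200) * 200
        assert bins["total"].item() == 5


class TestFilter:
    def _aligned(self, totals):
        rows = {"chrom": ["2"], "start": [0], "end": [200], "context": ["CG"]}
        for i, t in enumerate(totals):
            rows[f"meth_s{i}"] = [t // 2]
            rows[f"total_s{i}"] = [t]
        return pd.DataFrame(rows)

    def test_one_low_sample_excludes_bin(self):
        assert filter_bins(self._aligned([9, 50, 50, 50])).empty

    def test_boundary_retained(self):
        assert len(filter_bins(self._aligned([10, 10, 10, 10]))) == 1

    def test_all_zero_excluded(self):
        assert filter_bins(self._aligned([0, 0, 0, 0])).empty

    def test_pooled_scope(self):
        aligned = self._aligned([9, 1, 0, 0])
        assert filter_bins(aligned, scope="pooled").shape[0] == 1
        assert filter_bins(aligned, scope="per_sample").empty


# ---------------------------------------------------------------------------
# chi-square


def brute_force_chisq(a, b, c, d):
    """Sum of (O-E)^2/E over the 2x2 table, coded from the definition."""
    table = [[a, b], [c, d]]
    n = a + b + c + d
    stat = 0.0
    for i in range(2):
        for j in range(2):
            row = sum(table[i])
            col = table[0][j] + table[1][j]
            expected = row * col / n
            stat += (table[i][j] - expected) ** 2 / expected
    return stat


class TestChisq:
    def test_equal_proportions_null(self):
        stat, p = chisq_2x2(10, 90, 20, 180)
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        stat, p = chisq_2x2(10, 90, 50, 50)
        assert stat == pytest.approx(38.095238, abs=1e-6)
        assert p == pytest.approx(6.737e-10, rel=1e-3)

    def test_symmetry(self):
        assert chisq_2x2(10, 90, 50, 50) == chisq_2x2(50, 50, 10, 90)

    def test_degenerate_margins(self):
        assert chisq_2x2(0, 0, 5, 5) == (0.0, 1.0)
        assert chisq_2x2(0, 5, 0, 5) == (0.0, 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            chisq_2x2(-1, 5, 5, 5)

    def test_against_brute_force_on_random_tables(self):
        rng = np.random.default_rng(99)
        tables = rng.integers(1, 500, size=(1000, 4))
        for a, b, c, d in tables:
            stat, _ = chisq_2x2(a, b, c, d)
            assert abs(stat - brute_force_chisq(a, b, c, d)) < 1e-8

    def test_against_scipy_contingency(self):
        rng = np.random.default_rng(7)
        for a, b, c, d in rng.integers(1, 200, size=(50, 4)):
            stat, p = chisq_2x2(a, b, c, d)
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)


# ---------------------------------------------------------------------------
# DMR calling


def _bins_from(counts):
    """counts: list of (start, context, meth, total)."""
    df = pd.DataFrame(counts, columns=["start", "context", "meth", "total"])
    df["chrom"] = "2"
    df["end"] = df["start"] + 200
    return df[["chrom", "start", "end", "context", "meth", "total"]]


class TestCallDmrs:
    def test_max_p_rule_requires_both_pairs(self):
        # pair 1 strongly significant, pair 2 null -> not a DMR
        wt1 = _bins_from([(0, "CG", 10, 100)])
        sulf1 = _bins_from([(0, "CG", 60, 100)])
        wt2 = _bins_from([(0, "CG", 30, 100)])
        sulf2 = _bins_from([(0, "CG", 31, 100)])
        calls = call_dmrs(wt1, sulf1, wt2, sulf2)
        assert calls["p_pair1"].item() < 0.01 < calls["p_pair2"].item()
        assert not calls["is_dmr"].item()

    def test_concordant_hyper_call(self):
        wt1 = _bins_from([(0, "CG", 10, 100)])
        sulf1 = _bins_from([(0, "CG", 60, 100)])
        wt2 = _bins_from([(0, "CG", 12, 100)])
        sulf2 = _bins_from([(0, "CG", 55, 100)])
        calls = call_dmrs(wt1, sulf1, wt2, sulf2)
        row = calls.iloc[0]
        assert row["is_dmr"]
        assert row["direction"] == "hyper_in_sulf"
        assert row["diff"] < 0  # wt - sulf negative: hypermethylation in sulf
        assert row["max_p"] == max(row["p_pair1"], row["p_pair2"])

    def test_discordant_significant_bin_not_directional(self):
        wt1 = _bins_from([(0, "CG", 10, 100)])
        sulf1 = _bins_from([(0, "CG", 60, 100)])
        wt2 = _bins_from([(0, "CG", 60, 100)])
        sulf2 = _bins_from([(0, "CG", 10, 100)])
        calls = call_dmrs(wt1, sulf1, wt2, sulf2)
        assert calls["is_dmr"].item()
        assert calls["direction"].item() == "discordant"
        tally = classify_dmrs(calls)
        cg = tally.set_index("context").loc["CG"]
        assert cg["hyper_in_sulf"] == 0 and cg["discordant"] == 1

    def test_swapping_genotypes_negates_diff_keeps_p(self):
        rng = np.random.default_rng(17)
        def random_bins():
            return _bins_from(
                [(200 * i, "CHG", int(m), 50) for i, m in enumerate(rng.integers(5, 45, 20))]
            )
        wt1, sulf1, wt2, sulf2 = (random_bins() for _ in range(4))
        fwd = call_dmrs(wt1, sulf1, wt2, sulf2)
        rev = call_dmrs(sulf1, wt1, sulf2, wt2)
        np.testing.assert_allclose(fwd["max_p"], rev["max_p"])
        np.testing.assert_allclose(fwd["diff"], -rev["diff"])

    def test_unmatched_bins_skipped(self):
        wt1 = _bins_from([(0, "CG", 10, 100), (200, "CG", 10, 100)])
        other = _bins_from([(0, "CG", 10, 100)])
        calls = call_dmrs(wt1, other, other, other)
        assert len(calls) == 1

    def test_planted_hyper_and_hypo_tallies_recovered(self):
        # 10 hyper + 10 hypo CHG regions at strong effect sizes
        hyper = {"CHG": {"wt": 0.05, "sulf": 0.65}}
        hypo = {"CHG": {"wt": 0.65, "sulf": 0.05}}
        regions = [
            simulate.PlantedRegion(4000 * (i + 1), 4000 * (i + 1) + 400,
                                   hyper if i < 10 else hypo)
            for i in range(20)
        ]
        spec = simulate.MethylomeSimSpec(
            chrom_length=90_000,
            context_density={"CHG": 0.05},
            background_level={"CHG": 0.05},
            planted_regions=regions,
            mean_depth=30.0,
            seed=55,
        )
        samples = simulate.simulate_methylome_experiment(spec, seed=56)
        bins = {k: bin_counts(v) for k, v in samples.items()}
        calls = call_dmrs(bins["wt1"], bins["sulf1"], bins["wt2"], bins["sulf2"])
        hyper_regions = {(r.start, r.end) for r in regions[:10]}
        got_hyper = got_hypo = 0
        for r in regions:
            sub = calls[(calls["start"] >= r.start) & (calls["end"] <= r.end)]
            direction = sub.loc[sub["is_dmr"], "direction"]
            if (r.start, r.end) in hyper_regions:
                got_hyper += (direction == "hyper_in_sulf").any()
            else:
                got_hypo += (direction == "hypo_in_sulf").any()
        assert got_hyper == 10 and got_hypo == 10


# ---------------------------------------------------------------------------
# region summaries


class TestWeightedLevel:
    def test_arithmetic(self):
        rec = pd.DataFrame(
            {"chrom": "2", "pos": [10, 20], "strand": "+",
             "meth": [100, 114], "unmeth": [400, 386], "context": "CG"}
        )
        assert weighted_level(rec, context="CG") == pytest.approx(21.4)

    def test_fully_methylated(self):
        rec = pd.DataFrame(
            {"chrom": "2", "pos": [10], "strand": "+", "meth": [7],
             "unmeth": [0], "context": "CHH"}
        )
        assert weighted_level(rec, context="CHH") == 100.0

    def test_zero_coverage_returns_none_not_zero(self):
        rec = pd.DataFrame(
            {"chrom": "2", "pos": [10], "strand": "+", "meth": [0],
             "unmeth": [0], "context": "CG"}
        )
        assert weighted_level(rec, context="CG") is None
        assert weighted_level(rec, context="CHG") is None  # nothing in context

    def test_region_bounds_are_half_open(self):
        rec = pd.DataFrame(
            {"chrom": "2", "pos": [100, 101], "strand": "+",
             "meth": [5, 0], "unmeth": [0, 5], "context": "CG"}
        )
        # 1-based pos 100 is 0-based 99: outside [100, 200); pos 101 inside
        assert weighted_level(rec, start=100, end=200, context="CG") == 0.0


class TestSlidingWindows:
    def test_window_tiling(self):
        rec = pd.DataFrame(
            {"chrom": "2", "pos": [50, 150, 250, 399], "strand": "+",
             "meth": [1, 1, 1, 1], "unmeth": [1, 1, 1, 1], "context": "CG"}
        )
        prof = sliding_window_profile(rec)
        assert sorted(prof["start"].unique()) == [0, 100, 200, 300]

    def test_uniform_methylation_gives_flat_profile(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(np.arange(1, 2001), size=500, replace=False))
        rec = pd.DataFrame(
            {"chrom": "2", "pos": pos, "strand": "+", "meth": 5,
             "unmeth": 5, "context": "CHG"}
        )
        prof = sliding_window_profile(rec)
        assert (prof["level"] == 50.0).all()

    def test_step_function_transition_localised(self):
        # 0% before 1000, 100% after: profile transitions within one window
        pos = np.arange(1, 2001, 5)
        meth = np.where(pos - 1 >= 1000, 10, 0)
        rec = pd.DataFrame(
            {"chrom": "2", "pos": pos, "strand": "+", "meth": meth,
             "unmeth": 10 - meth, "context": "CG"}
        )
        prof = sliding_window_profile(rec).set_index("start")
        assert (prof.loc[prof.index <= 800, "level"] == 0).all()
        assert (prof.loc[prof.index >= 1000, "level"] == 100).all()

    def test_bad_geometry_rejected(self):
        rec = pd.DataFrame(
            {"chrom": "2", "pos": [1], "strand": "+", "meth": [1],
             "unmeth": [1], "context": "CG"}
        )
        with pytest.raises(ValueError):
            sliding_window_profile(rec, window=100, step=200)


class TestRegionGlm:
    def test_identical_proportions_null(self):
        res = region_glm_test([30, 30, 30, 30], [70, 70, 70, 70],
                              ["wt", "wt", "sulf", "sulf"])
        assert res["statistic"] == pytest.approx(0.0, abs=1e-8)
        assert res["p_value"] == pytest.approx(1.0, abs=1e-6)

    def test_strong_contrast_significant(self):
        # promoter-DMR CHG scale: wt ~4%, sulf ~62%, 300+ calls per sample
        res = region_glm_test([12, 18, 200, 190], [288, 282, 120, 110],
                              ["wt", "wt", "sulf", "sulf"])
        assert res["p_value"] < 1e-10

    def test_matches_closed_form_binomial_lrt(self):
        meth = np.array([12, 18, 200, 190])
        unmeth = np.array([288, 282, 120, 110])
        labels = np.array(["wt", "wt", "sulf", "sulf"])

        def loglik(m, u, p):
            return np.sum(m * np.log(p) + u * np.log1p(-p))

        ll_full = sum(
            loglik(meth[labels == g], unmeth[labels == g],
                   meth[labels == g].sum() / (meth[labels == g] + unmeth[labels == g]).sum())
            for g in ("wt", "sulf")
        )
        ll_null = loglik(meth, unmeth, meth.sum() / (meth.sum() + unmeth.sum()))
        expected = 2 * (ll_full - ll_null)
        res = region_glm_test(meth, unmeth, labels)
        assert res["statistic"] == pytest.approx(expected, abs=1e-6)

    def test_label_swap_symmetry(self):
        a = region_glm_test([10, 50], [90, 50], ["wt", "sulf"])
        b = region_glm_test([10, 50], [90, 50], ["sulf", "wt"])
        assert a["p_value"] == pytest.approx(b["p_value"], rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            region_glm_test([0, 0], [0, 0], ["wt", "sulf"])
        with pytest.raises(ValueError):
            region_glm_test([5, 5], [5, 5], ["wt", "wt"])


# ---------------------------------------------------------------------------
# BED output


class TestBedOutput:
    def test_empty_calls_empty_file(self, tmp_path):
        calls = call_dmrs(*[_bins_from([(0, "CG", 30, 100)])] * 4)
        path = tmp_path / "dmrs.bed"
        write_dmr_bed(calls, path)
        assert read_bed(path).empty

    def test_interval_round_trip(self, tmp_path):
        wt = _bins_from([(200, "CHH", 5, 100)])
        sulf = _bins_from([(200, "CHH", 70, 100)])
        calls = call_dmrs(wt, sulf, wt, sulf)
        path = tmp_path / "dmrs.bed"
        write_dmr_bed(calls, path)
        bed = read_bed(path)
        assert bed.iloc[0]["start"] == 200 and bed.iloc[0]["end"] == 400
        assert bed.iloc[0]["name"] == "CHH:hyper_in_sulf"
        assert 0 <= bed.iloc[0]["score"] <= 1000
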