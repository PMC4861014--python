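"""Binned, context-separated differential-methylation analysis.

The DMR caller follows a replicate-consistent dual chi-square design:
methylated/unmethylated calls from both strands are pooled into
contiguous 200-bp bins separated by cytosine context (CG, CHG, CHH),
bins with insufficient coverage are dropped, each bin is tested with two
independent 2x2 Pearson chi-square tests (wt1 vs sulf1, wt2 vs sulf2),
and a bin is a DMR when the *maximum* of the two p-values falls below
alpha.  Requiring both replicate pairs to reject keeps the genome-wide
false-call rate near alpha^2 without any explicit multiple-testing
correction.

Direction follows the wt - sulf difference: a negative difference means
hypermethylation in sulf.  Region-level methylation is compared across
genotypes with a binomial (logistic) regression on the aggregated raw
counts, one observation per sample, scored by likelihood-ratio test.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")

BIN_KEY = ["chrom", "start", "end", "context"]

HYPER = "hyper_in_sulf"
HYPO = "hypo_in_sulf"
DISCORDANT = "discordant"


# ---------------------------------------------------------------------------
# binning


def bin_counts(records: pd.DataFrame, bin_size: int = 200) -> pd.DataFrame:
    """Pool both strands' calls into contiguous bins, separated by context.

    Parameters
    ----------
    records
        Cytosine report DataFrame (chrom, pos 1-based, strand, meth,
        unmeth, context).
    bin_size
        Bin width in bp; bins are [k*bin_size, (k+1)*bin_size) with
        0-based coordinates, so 1-based position p lands in bin
        floor((p-1)/bin_size).

    Returns
    -------
    DataFrame with columns chrom, start, end, context, meth, total.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if records.empty:
        return pd.DataFrame(columns=BIN_KEY + ["meth", "total"])
    df = pd.DataFrame(
        {
            "chrom": records["chrom"].to_numpy(),
            "start": ((records["pos"].to_numpy() - 1) // bin_size) * bin_size,
            "context": records["context"].to_numpy(),
            "meth": records["meth"].to_numpy(),
            "total": records["meth"].to_numpy() + records["unmeth"].to_numpy(),
        }
    )
    out = (
        df.groupby(["chrom", "start", "context"], sort=True, observed=True)[["meth", "total"]]
        .sum()
        .reset_index()
    )
    out["end"] = out["start"] + bin_size
    return out[BIN_KEY + ["meth", "total"]]


def align_samples(bins_by_sample: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Inner-join per-sample bin tables on (chrom, start, end, context).

    Produces a wide table with meth_<sample> / total_<sample> columns.
    Bins absent from any sample are dropped (logged).
    """
    wide = None
    for name, bins in bins_by_sample.items():
        renamed = bins.rename(columns={"meth": f"meth_{name}", "total": f"total_{name}"})
        wide = renamed if wide is None else wide.merge(renamed, on=BIN_KEY, how="inner")
    if wide is None:
        raise ValueError("no samples given")
    n_union = max(len(b) for b in bins_by_sample.values())
    if len(wide) < n_union:
        logger.info("dropped %d bins not covered in every sample", n_union - len(wide))
    return wide


def filter_bins(
    aligned: pd.DataFrame, min_total: int = 10, scope: str = "per_sample"
) -> pd.DataFrame:
    """Drop low-coverage bins.

    scope='per_sample' (strict, default): keep a bin only if *every*
    sample's total is >= min_total, guaranteeing populated chi-square
    tables.  scope='pooled': keep a bin if the totals summed over samples
    reach min_total.
    """
    total_cols = [c for c in aligned.columns if c.startswith("total_")]
    if scope == "per_sample":
        keep = (aligned[total_cols] >= min_total).all(axis=1)
    elif scope == "pooled":
        keep = aligned[total_cols].sum(axis=1) >= min_total
    else:
        raise ValueError("scope must be 'per_sample' or 'pooled'")
    return aligned.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# chi-square


def _chisq_2x2_arrays(meth_a, unmeth_a, meth_b, unmeth_b):
    """Vectorised Pearson chi-square (1 df, no continuity correction).

    Degenerate tables (an empty row or column) score statistic 0, p 1.
    """
    a = np.asarray(meth_a, dtype=float)
    b = np.asarray(unmeth_a, dtype=float)
    c = np.asarray(meth_b, dtype=float)
    d = np.asarray(unmeth_b, dtype=float)
    if (a < 0).any() or (b < 0).any() or (c < 0).any() or (d < 0).any():
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    valid = denom > 0
    stat = np.zeros_like(n)
    np.divide(n * (a * d - b * c) ** 2, denom, out=stat, where=valid)
    p = np.where(valid, stats.chi2.sf(stat, df=1), 1.0)
    # a zero statistic has p exactly 1
    p = np.where(stat == 0, 1.0, p)
    return stat, p


def chisq_2x2(
    meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int
) -> tuple[float, float]:
    """Pearson chi-square test of two (meth, unmeth) pairs.

    1 df, no Yates correction; returns (statistic, p).  Tables with an
    empty row or column return (0.0, 1.0).
    """
    stat, p = _chisq_2x2_arrays(meth_a, unmeth_a, meth_b, unmeth_b)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# DMR calling


def call_dmrs(
    bins_wt1: pd.DataFrame,
    bins_sulf1: pd.DataFrame,
    bins_wt2: pd.DataFrame,
    bins_sulf2: pd.DataFrame,
    alpha: float = 0.01,
    min_total: int = 10,
    filter_scope: str = "per_sample",
) -> pd.DataFrame:
    """Call DMRs with the dual chi-square maximum-p rule.

    Bins are matched across the four samples, filtered for coverage, then
    tested pairwise (wt1 vs sulf1, wt2 vs sulf2).  A bin is a DMR when
    max(p_pair1, p_pair2) < alpha.  The methylation difference is the mean
    over replicate pairs of (wt level - sulf level) in percentage points;
    negative differences mean hypermethylation in sulf.  Direction is
    assigned only when the two replicate pairs agree in sign, otherwise
    the call is flagged discordant.

    Returns the full tested-bin table with columns: the bin key, per-sample
    levels, p_pair1, p_pair2, max_p, diff, is_dmr, direction.
    """
    aligned = align_samples(
        {"wt1": bins_wt1, "sulf1": bins_sulf1, "wt2": bins_wt2, "sulf2": bins_sulf2}
    )
    aligned = filter_bins(aligned, min_total=min_total, scope=filter_scope)
    out = aligned[BIN_KEY].copy()

    levels = {}
    for s in ("wt1", "sulf1", "wt2", "sulf2"):
        meth = aligned[f"meth_{s}"].to_numpy(dtype=float)
        total = aligned[f"total_{s}"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            levels[s] = np.where(total > 0, 100.0 * meth / total, np.nan)
        out[f"level_{s}"] = levels[s]

    _, p1 = _chisq_2x2_arrays(
        aligned["meth_wt1"], aligned["total_wt1"] - aligned["meth_wt1"],
        aligned["meth_sulf1"], aligned["total_sulf1"] - aligned["meth_sulf1"],
    )
    _, p2 = _chisq_2x2_arrays(
        aligned["meth_wt2"], aligned["total_wt2"] - aligned["meth_wt2"],
        aligned["meth_sulf2"], aligned["total_sulf2"] - aligned["meth_sulf2"],
    )
    d1 = levels["wt1"] - levels["sulf1"]
    d2 = levels["wt2"] - levels["sulf2"]

    out["p_pair1"] = p1
    out["p_pair2"] = p2
    out["max_p"] = np.maximum(p1, p2)
    out["diff"] = (d1 + d2) / 2.0
    out["is_dmr"] = out["max_p"] < alpha
    concordant_neg = (d1 < 0) & (d2 < 0)
    concordant_pos = (d1 > 0) & (d2 > 0)
    direction = np.where(concordant_neg, HYPER, np.where(concordant_pos, HYPO, DISCORDANT))
    out["direction"] = np.where(out["is_dmr"], direction, "")
    return out


def classify_dmrs(calls: pd.DataFrame) -> pd.DataFrame:
    """Tally hyper/hypo (and discordant) DMR calls per context."""
    rows = []
    dmrs = calls.loc[calls["is_dmr"]]
    for ctx in CONTEXTS:
        sub = dmrs.loc[dmrs["context"] == ctx, "direction"]
        rows.append(
            {
                "context": ctx,
                "hyper_in_sulf": int((sub == HYPER).sum()),
                "hypo_in_sulf": int((sub == HYPO).sum()),
                "discordant": int((sub == DISCORDANT).sum()),
            }
        )
    return pd.DataFrame(rows)


def write_dmr_bed(calls: pd.DataFrame, sink) -> None:
    """Write DMR calls as BED6: name=context:direction, score=-10*log10(max_p)."""
    from paramethyl.io import write_bed

    dmrs = calls.loc[calls["is_dmr"]].copy()
    with np.errstate(divide="ignore"):
        score = -10.0 * np.log10(dmrs["max_p"].to_numpy(dtype=float))
    dmrs["score"] = np.minimum(np.nan_to_num(score, posinf=1000.0), 1000.0).round(2)
    dmrs["name"] = dmrs["context"] + ":" + dmrs["direction"]
    dmrs["strand"] = "."
    write_bed(dmrs, sink)


# ---------------------------------------------------------------------------
# region-level summaries


def weighted_level(
    data: pd.DataFrame,
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
    context: str | None = None,
) -> float | None:
    """Weighted methylation percentage over a region.

    100 * sum(meth) / sum(meth + unmeth) over the selected cytosines (or
    bins).  Accepts either a cytosine-report frame (has ``pos``, 1-based)
    or a bin frame (has ``start``/``end``); the region [start, end) is
    0-based half-open and for bins selects bins fully inside it.  Returns
    None when there is no coverage: no data is not 0% methylation.
    """
    df = data
    if chrom is not None and "chrom" in df.columns:
        df = df.loc[df["chrom"] == chrom]
    if context is not None:
        df = df.loc[df["context"] == context]
    if "pos" in df.columns:
        if start is not None:
            df = df.loc[df["pos"] - 1 >= start]
        if end is not None:
            df = df.loc[df["pos"] - 1 < end]
        meth = df["meth"].sum()
        total = meth + df["unmeth"].sum()
    else:
        if start is not None:
            df = df.loc[df["start"] >= start]
        if end is not None:
            df = df.loc[df["end"] <= end]
        meth = df["meth"].sum()
        total = df["total"].sum()
    if total == 0:
        return None
    return 100.0 * float(meth) / float(total)


def sliding_window_profile(
    records: pd.DataFrame, window: int = 200, step: int = 100
) -> pd.DataFrame:
    """Per-context weighted-level profile in sliding windows.

    Windows start at 0 and advance by ``step``; each value is the weighted
    methylation level over [start, start+window).  Windows with no calls
    carry NaN (no data, not 0%).  window must be a multiple of step.
    """
    if step <= 0 or window < step:
        raise ValueError("need window >= step > 0")
    if window % step:
        raise ValueError("window must be a multiple of step")
    if records.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "context", "meth", "total", "level"])
    frames = []
    n_phases = window // step
    pos0 = records["pos"].to_numpy() - 1
    for phase in range(n_phases):
        offset = phase * step
        start = ((pos0 - offset) // window) * window + offset
        keep = pos0 >= offset  # a partial leading window would double-count nothing
        df = pd.DataFrame(
            {
                "chrom": records["chrom"].to_numpy()[keep],
                "start": start[keep],
                "context": records["context"].to_numpy()[keep],
                "meth": records["meth"].to_numpy()[keep],
                "total": (records["meth"] + records["unmeth"]).to_numpy()[keep],
            }
        )
        frames.append(
            df.groupby(["chrom", "start", "context"], observed=True)[["meth", "total"]]
            .sum()
            .reset_index()
        )
    out = pd.concat(frames, ignore_index=True)
    out["end"] = out["start"] + window
    with np.errstate(invalid="ignore", divide="ignore"):
        out["level"] = np.where(out["total"] > 0, 100.0 * out["meth"] / out["total"], np.nan)
    return (
        out.sort_values(["chrom", "context", "start"], kind="stable")
        .reset_index(drop=True)[["chrom", "start", "end", "context", "meth", "total", "level"]]
    )


def region_glm_test(
    meth: Sequence[int],
    unmeth: Sequence[int],
    genotypes: Sequence[str],
) -> dict:
    """Binomial (logistic) regression of region methylation on genotype.

    One binomial observation per sample: aggregated raw methylated and
    unmethylated counts.  The genotype factor is tested against an
    intercept-only model with a likelihood-ratio chi-square test.

    Returns a dict with per-sample weighted levels (%), the LRT statistic,
    its degrees of freedom and the p-value.
    """
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    genotypes = list(genotypes)
    if len(meth) != len(unmeth) or len(meth) != len(genotypes):
        raise ValueError("meth, unmeth and genotypes must have equal length")
    totals = meth + unmeth
    if (totals == 0).all():
        raise ValueError("no coverage in any sample")
    if (totals == 0).any():
        raise ValueError("sample with zero denominator; drop it before testing")
    geno_dummies = pd.get_dummies(pd.Series(genotypes), drop_first=True).to_numpy(dtype=float)
    if geno_dummies.shape[1] == 0:
        raise ValueError("need at least two genotype levels")
    endog = np.column_stack([meth, unmeth])
    exog_full = sm.add_constant(geno_dummies, has_constant="add")
    exog_null = np.ones((len(meth), 1))
    fit_full = sm.GLM(endog, exog_full, family=sm.families.Binomial()).fit()
    fit_null = sm.GLM(endog, exog_null, family=sm.families.Binomial()).fit()
    lrt = max(0.0, 2.0 * (fit_full.llf - fit_null.llf))
    df = geno_dummies.shape[1]
    p = float(stats.chi2.sf(lrt, df)) if lrt > 0 else 1.0
    return {
        "levels": 100.0 * meth / totals,
        "statistic": float(lrt),
        "df": int(df),
        "p_value": p,
    }


def region_test_from_reports(
    reports: Mapping[str, pd.DataFrame],
    genotypes: Mapping[str, str],
    chrom: str,
    start: int,
    end: int,
    context: str,
) -> dict:
    """Aggregate each sample's counts over a region and run region_glm_test."""
    meth, unmeth, labels, samples = [], [], [], []
    for name, rec in reports.items():
        sel = rec.loc[
            (rec["chrom"] == chrom)
            & (rec["context"] == context)
            & (rec["pos"] - 1 >= start)
            & (rec["pos"] - 1 < end)
        ]
        meth.append(int(sel["meth"].sum()))
        unmeth.append(int(sel["unmeth"].sum()))
        labels.append(genotypes[name])
        samples.append(name)
    result = region_glm_test(meth, unmeth, labels)
    result["samples"] = samples
    result["genotypes"] = labels
    return result
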