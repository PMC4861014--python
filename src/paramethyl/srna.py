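"""TMM normalisation and genotype Poisson-regression tests for sRNA loci.

Between-library scaling uses the trimmed mean of M-values (TMM): log
ratios of relative abundance against a reference library are doubly
trimmed (30% on M, 5% on A by default), averaged with inverse
asymptotic-variance precision weights, and the resulting factors are
rescaled to geometric mean 1.  The factors are computed on the subset of
loci detected in every library with at least ``min_total`` total counts.

Differential abundance of a locus across the three genotype levels (wt,
sulf/+, sulf) is scored with a Poisson generalized linear model, log
link, genotype as an unordered factor, against the intercept-only model
by likelihood-ratio test.  The default follows the original analysis
literally (regression on normalised counts rounded to integers); an
offset-based mode on raw counts is exposed as the statistically
preferred alternative.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

GENOTYPES_3 = ("wt", "sulf/+", "sulf")


def normalization_subset(counts: pd.DataFrame, min_total: int = 10) -> pd.Index:
    """Loci usable for TMM: nonzero in every library, row total >= min_total."""
    present = (counts > 0).all(axis=1)
    enough = counts.sum(axis=1) >= min_total
    subset = counts.index[present & enough]
    if len(subset) == 0:
        logger.warning("empty normalization subset; factors fall back to library size only")
    return subset


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_logratio: float,
    trim_absexpr: float,
    weighted: bool,
) -> float:
    """TMM factor of one library against the reference (log2 scale -> 2**f)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    keep = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[keep], abs_e[keep], v[keep]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_logratio) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_absexpr) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_e = stats.rankdata(abs_e)
    trimmed = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not trimmed.any():
        return 1.0
    if weighted:
        f = np.sum(log_r[trimmed] / v[trimmed]) / np.sum(1.0 / v[trimmed])
    else:
        f = np.mean(log_r[trimmed])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    min_total: int = 10,
    trim_logratio: float = 0.30,
    trim_absexpr: float = 0.05,
    weighted: bool = True,
    lib_sizes: Sequence[float] | None = None,
) -> dict:
    """Trimmed-mean-of-M-values scaling factors for a count matrix.

    The reference library is the one whose upper-quartile relative
    abundance is closest to the across-library mean.  Factors are rescaled
    so their geometric mean is exactly 1; multiplied by the raw library
    sizes they give effective library sizes.

    Returns a dict with 'factors' and 'effective_sizes' (pd.Series indexed
    by library) and 'subset' (the locus Index used).
    """
    libs = counts.columns
    sizes = (
        pd.Series(np.asarray(lib_sizes, dtype=float), index=libs)
        if lib_sizes is not None
        else counts.sum(axis=0).astype(float)
    )
    subset = normalization_subset(counts, min_total=min_total)
    factors = pd.Series(1.0, index=libs)
    if len(libs) >= 2 and len(subset) > 0:
        sub = counts.loc[subset]
        rel_uq = sub.div(sizes, axis=1).quantile(0.75, axis=0)
        ref_lib = (rel_uq - rel_uq.mean()).abs().idxmin()
        ref = sub[ref_lib].to_numpy(dtype=float)
        for lib in libs:
            if lib == ref_lib:
                factors[lib] = _tmm_pair(
                    ref, ref, sizes[lib], sizes[ref_lib],
                    trim_logratio, trim_absexpr, weighted,
                )
            else:
                factors[lib] = _tmm_pair(
                    sub[lib].to_numpy(dtype=float), ref, sizes[lib], sizes[ref_lib],
                    trim_logratio, trim_absexpr, weighted,
                )
    # rescale to geometric mean 1 (edgeR convention)
    factors = factors / np.exp(np.mean(np.log(factors)))
    effective = sizes * factors
    return {"factors": factors, "effective_sizes": effective, "subset": subset}


def normalize_counts(counts: pd.DataFrame, normalization: Mapping) -> pd.DataFrame:
    """Scale counts to a common effective library size.

    normalized = raw * (mean effective size / library effective size), so a
    library scaled purely by depth gets its counts mapped back onto the
    common scale.
    """
    eff = normalization["effective_sizes"]
    scale = eff.mean() / eff
    return counts.mul(scale, axis=1)


def poisson_genotype_test(
    counts: Sequence[float],
    genotypes: Sequence[str],
    mode: str = "literal",
    effective_sizes: Sequence[float] | None = None,
) -> dict:
    """Likelihood-ratio Poisson test of one locus's counts on genotype.

    mode='literal' (default): fit the Poisson GLM to the normalised counts
    rounded to the nearest non-negative integer.  mode='offset': fit raw
    counts with log effective-size offsets (requires ``effective_sizes``).

    Returns dict with 'deviance' (the LRT statistic), 'df' and 'p_value'.
    All-zero loci return p 1 with flagged=True.
    """
    y = np.asarray(counts, dtype=float)
    genotypes = list(genotypes)
    if len(y) != len(genotypes):
        raise ValueError("counts and genotypes must have equal length")
    levels = pd.unique(pd.Series(genotypes))
    if len(levels) < 2:
        raise ValueError("need at least two genotype levels")
    if mode == "literal":
        y = np.maximum(np.rint(y), 0.0)
        offset = None
    elif mode == "offset":
        if effective_sizes is None:
            raise ValueError("offset mode requires effective_sizes")
        offset = np.log(np.asarray(effective_sizes, dtype=float))
    else:
        raise ValueError("mode must be 'literal' or 'offset'")
    df = len(levels) - 1
    if y.sum() == 0:
        return {"deviance": 0.0, "df": df, "p_value": 1.0, "flagged": True}
    dummies = pd.get_dummies(pd.Series(genotypes), drop_first=True).to_numpy(dtype=float)
    exog_full = sm.add_constant(dummies, has_constant="add")
    exog_null = np.ones((len(y), 1))
    kw = {} if offset is None else {"offset": offset}
    fit_full = sm.GLM(y, exog_full, family=sm.families.Poisson(), **kw).fit()
    fit_null = sm.GLM(y, exog_null, family=sm.families.Poisson(), **kw).fit()
    lrt = max(0.0, 2.0 * (fit_full.llf - fit_null.llf))
    p = float(stats.chi2.sf(lrt, df)) if lrt > 0 else 1.0
    return {"deviance": float(lrt), "df": int(df), "p_value": p, "flagged": False}


def test_all_loci(
    counts: pd.DataFrame,
    genotype: Mapping[str, str],
    min_total: int = 10,
    mode: str = "literal",
) -> pd.DataFrame:
    """TMM-normalise a count matrix and Poisson-test every locus.

    Returns a DataFrame (locus, deviance, df, p_value, flagged) plus the
    per-library normalisation factors as a ``.attrs['normalization']``
    record.
    """
    labels = [genotype[lib] for lib in counts.columns]
    norm = tmm_factors(counts, min_total=min_total)
    normed = normalize_counts(counts, norm)
    rows = []
    eff = norm["effective_sizes"].to_numpy()
    for locus in counts.index:
        if mode == "offset":
            res = poisson_genotype_test(
                counts.loc[locus].to_numpy(), labels, mode="offset", effective_sizes=eff
            )
        else:
            res = poisson_genotype_test(normed.loc[locus].to_numpy(), labels, mode="literal")
        rows.append({"locus": locus, **res})
    out = pd.DataFrame(rows)
    out.attrs["normalization"] = norm
    return out
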