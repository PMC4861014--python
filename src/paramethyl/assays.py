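"""qPCR-based quantifications: McrBC methylation and relative expression.

McrBC cleaves methylated DNA, so methylated template is lost before
amplification: the fraction of template surviving digestion is
R = E**(Cq_undigested - Cq_digested) at amplification efficiency E
(2 = perfect doubling per cycle), and the methylation proportion is
100 * (1 - R).  A digested sample that fails to amplify (infinite Cq)
means complete digestion: 100% methylation.

Relative expression normalises a target's abundance E**(-Cq) by the
geometric mean of two housekeeping genes, the standard delta-Cq design.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats


def mcrbc_methylation_proportion(
    cq_digested: float, cq_undigested: float, efficiency: float = 2.0
) -> float:
    """Percent methylation from a McrBC-digested / undigested Cq pair.

    ``math.inf`` for ``cq_digested`` encodes "no amplification" (fully
    methylated template).  The result is clamped to [0, 100]: a digested
    sample amplifying *earlier* than the undigested control (R > 1) reads
    as 0% methylation.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must be in (1, 2]")
    for cq in (cq_digested, cq_undigested):
        if not (cq > 0):  # rejects NaN, zero and negatives; inf is allowed
            raise ValueError("Cq values must be positive (or inf for no amplification)")
    if math.isinf(cq_digested):
        return 100.0
    if math.isinf(cq_undigested):
        # no template even without digestion: assay uninformative, treat as 0 survival baseline
        raise ValueError("undigested control failed to amplify")
    surviving = efficiency ** (cq_undigested - cq_digested)
    return float(np.clip(100.0 * (1.0 - surviving), 0.0, 100.0))


def qpcr_relative_expression(
    cq_target: Sequence[float],
    cq_hk1: Sequence[float],
    cq_hk2: Sequence[float],
    efficiency: float = 2.0,
) -> float:
    """Target abundance normalised by the geometric mean of two housekeepers.

    Technical replicates are averaged on the Cq scale.  With E the
    amplification efficiency, abundance = E**(-Cq_target) /
    sqrt(E**(-Cq_hk1) * E**(-Cq_hk2)); shifting every Cq by a constant
    leaves the result unchanged.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must be in (1, 2]")
    groups = []
    for name, cqs in (("target", cq_target), ("hk1", cq_hk1), ("hk2", cq_hk2)):
        arr = np.asarray(cqs, dtype=float)
        if arr.size == 0:
            raise ValueError(f"missing Cq replicates for {name}")
        groups.append(float(arr.mean()))
    t, h1, h2 = groups
    return float(efficiency ** (-t) / math.sqrt(efficiency ** (-h1) * efficiency ** (-h2)))


def fold_change_ttest(
    group_a: Sequence[float], group_b: Sequence[float], log_scale: bool = True
) -> dict:
    """Fold-change of mean abundances with a Welch two-tailed t-test.

    fold = mean(a) / mean(b); the test is run on log2 abundances by
    default (the conventional scale for qPCR ratios) or on the raw values
    with ``log_scale=False``.  Returns {'fold', 'p_value', 't'}.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("abundances must be positive")
    fold = float(a.mean() / b.mean())
    if log_scale:
        t, p = stats.ttest_ind(np.log2(a), np.log2(b), equal_var=False)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(p):  # zero variance in both groups with equal means
        t, p = 0.0, 1.0
    return {"fold": fold, "p_value": float(p), "t": float(t)}
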