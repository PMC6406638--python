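"""Hemisphere- and region-wise information flow, and state comparisons.

Flows are summed NTE weights between electrode groups. The left/right
hemispheres are the odd/even 10-20 electrodes (7 each); the frontal (F),
central-temporal (C) and parieto-occipital (P) region nodes hold 4
electrodes each (AF3/AF4 belong to no region). Statistical comparisons
follow the study design: Welch two-sample t-tests between states and
one-way ANOVA with Tukey-Kramer multiple comparison across the three
states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .channels import LEFT_HEMISPHERE, REGIONS, RIGHT_HEMISPHERE, indices
from .connectivity import NTEMatrix

HEMISPHERE_BLOCKS = ("LH->LH", "LH->RH", "RH->RH", "RH->LH")
REGION_PAIRS = ("F-C", "C-F", "F-P", "P-F", "P-C", "C-P")


def _block(m: np.ndarray, sources: list[int], targets: list[int]) -> np.ndarray:
    """Source-major block: rows = source electrodes, cols = targets."""
    return m[np.ix_(targets, sources)].T


@dataclass
class HemisphereFlows:
    """Four 7x7 source-major sub-matrices and their per-electrode outflows.

    ``blocks[name][r, c]`` is the NTE from the r-th source electrode of
    the originating hemisphere to the c-th target electrode;
    ``outflows[name]`` holds the row sums (total flow from each source
    electrode into the target hemisphere).
    """

    blocks: dict[str, np.ndarray]
    outflows: dict[str, np.ndarray]
    source_labels: dict[str, tuple[str, ...]]


def hemisphere_flows(m: NTEMatrix) -> HemisphereFlows:
    lh, rh = indices(LEFT_HEMISPHERE), indices(RIGHT_HEMISPHERE)
    groups = {"LH": (lh, LEFT_HEMISPHERE), "RH": (rh, RIGHT_HEMISPHERE)}
    blocks, outflows, labels = {}, {}, {}
    for src_name in ("LH", "RH"):
        for tgt_name in ("LH", "RH"):
            key = f"{src_name}->{tgt_name}"
            b = _block(m.values, groups[src_name][0], groups[tgt_name][0])
            blocks[key] = b
            outflows[key] = b.sum(axis=1)
            labels[key] = groups[src_name][1]
    return HemisphereFlows(blocks, outflows, labels)


@dataclass
class RegionFlows:
    """Directed flow totals among the F, C, P region nodes.

    ``matrix[a, b]`` (order F, C, P) sums NTE from every electrode of
    region a to every electrode of region b; the diagonal holds
    within-region flow, which is excluded from the six reported pairs.
    """

    matrix: np.ndarray
    flows: dict[str, float]
    max_pair: str | None
    min_pair: str | None


def region_flows(m: NTEMatrix) -> RegionFlows:
    names = ("F", "C", "P")
    idx = {r: indices(REGIONS[r]) for r in names}
    mat = np.zeros((3, 3))
    for a, ra in enumerate(names):
        for b, rb in enumerate(names):
            block = _block(m.values, idx[ra], idx[rb])
            if a == b:
                np.fill_diagonal(block, 0.0)  # already zero for NTE input
            mat[a, b] = block.sum()
    flows = {}
    for pair in REGION_PAIRS:
        a, b = pair.split("-")
        flows[pair] = float(mat[names.index(a), names.index(b)])
    if any(v != 0 for v in flows.values()):
        max_pair = max(flows, key=flows.get)
        min_pair = min(flows, key=flows.get)
    else:
        max_pair = min_pair = None
    return RegionFlows(mat, flows, max_pair, min_pair)


def mean_information_flow(m: NTEMatrix) -> np.ndarray:
    """Total outgoing NTE of each electrode (source-wise summation of the
    connectivity matrix), one value per channel in canonical order."""
    return m.values.sum(axis=0)


# ---------------------------------------------------------------------------
# Statistics


@dataclass
class StatTestResult:
    """Welch two-sample comparison with 95% CI of the mean difference."""

    mean_difference: float
    ci_low: float
    ci_high: float
    df: float
    t: float
    p: float
    significant: bool
    defined: bool = True


def welch_ttest(a, b, alpha: float = 0.05) -> StatTestResult:
    """Two-sample t-test with unequal variances (Welch-Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    diff = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if diff == 0:
            return StatTestResult(0.0, 0.0, 0.0, float("nan"), float("nan"),
                                  1.0, False, defined=False)
    res = sps.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(1 - alpha)
    p = float(res.pvalue)
    return StatTestResult(diff, float(ci.low), float(ci.high),
                          float(res.df), float(res.statistic), p,
                          p < alpha)


@dataclass
class PairwiseComparison:
    """One Tukey-Kramer pairwise contrast from a one-way ANOVA."""

    group_a: str
    group_b: str
    mean_difference: float
    ci_low: float
    ci_high: float
    p: float
    significant: bool


@dataclass
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    comparisons: list[PairwiseComparison]


def anova_multicompare(groups, labels, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with Tukey-Kramer simultaneous pairwise intervals."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if len(groups) != len(labels):
        raise ValueError("labels must match groups")
    for g, name in zip(groups, labels):
        if len(g) < 2:
            raise ValueError(f"group {name!r} needs at least 2 observations")
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    arrays = [np.asarray(g, dtype=float) for g in groups]
    f, p = sps.f_oneway(*arrays)
    values = np.concatenate(arrays)
    tags = np.concatenate([[name] * len(g)
                           for g, name in zip(arrays, labels)])
    tk = pairwise_tukeyhsd(values, tags, alpha=alpha)
    comparisons = []
    for row, (lo, hi), p_adj, rej in zip(
        tk.summary().data[1:], tk.confint, tk.pvalues, tk.reject
    ):
        comparisons.append(PairwiseComparison(
            str(row[0]), str(row[1]), float(row[2]), float(lo), float(hi),
            float(p_adj), bool(rej),
        ))
    n = len(values)
    return AnovaResult(float(f), float(p), len(groups) - 1, n - len(groups),
                       comparisons)
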