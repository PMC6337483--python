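"""Marker-list robustness by stratified subsampling and pairwise overlap.

The protocol: draw ten sub-datasets, each keeping a random 2/3 of the cases
and 2/3 of the controls (without replacement, stratified), call the
differential genes in each with the same dual threshold, then score every
pair of sub-datasets with an *overlap value* — by default the intersection
size divided by the smaller list size. Ten iterations give C(10, 2) = 45
pairwise values; their median summarizes the stability of the marker list.
The co-discovery profile counts, for each N, the genes appearing in at
least N of the ten lists, as a count and as a fraction of the union.

The 45 pairwise values share sub-samples and are therefore not independent;
:func:`compare_strategies` still offers the conventional Welch t-test (and
Mann-Whitney U) between two strategies' overlap distributions, with that
caveat carried in the report.
"""

from __future__ import annotations

import itertools
import logging
import math
import statistics
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ddipipe._util import child_rng, round_half_up
from ddipipe.integration import IntegratedDataset

logger = logging.getLogger(__name__)

OVERLAP_METHODS = ("intersection_over_min", "jaccard", "mean_containment")


@dataclass
class SubsamplePlan:
    """Index sets of a stratified without-replacement subsampling scheme."""

    n_iterations: int
    fraction: float
    seed: int
    iterations: list[tuple[list[str], list[str]]]  # (case ids, control ids) per iteration

    def sample_ids(self, i: int) -> list[str]:
        cases, controls = self.iterations[i]
        return list(cases) + list(controls)


@dataclass
class RobustnessReport:
    """Per-iteration DEG lists plus overlap and co-discovery summaries."""

    deg_lists: list[set[str]]
    overlap_method: str
    pairwise_overlaps: list[float]
    overlap_median: float
    union_count: int
    per_iteration_counts: list[int]
    co_discovery: dict[int, tuple[int, float]]  # N -> (count, fraction of union)
    dependent_pairs_caveat: bool = True

    def to_dict(self) -> dict:
        return {
            "overlap_method": self.overlap_method,
            "n_iterations": len(self.deg_lists),
            "per_iteration_counts": self.per_iteration_counts,
            "union_count": self.union_count,
            "n_pairwise": len(self.pairwise_overlaps),
            "pairwise_overlaps": self.pairwise_overlaps,
            "overlap_median": self.overlap_median,
            "co_discovery": {
                str(n): {"count": c, "fraction": f} for n, (c, f) in self.co_discovery.items()
            },
            "dependent_pairs_caveat": self.dependent_pairs_caveat,
        }


def draw_subsamples(
    data: IntegratedDataset,
    n_iterations: int = 10,
    fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> SubsamplePlan:
    """Stratified subsample plan: per iteration, floor(fraction * n) of each group.

    Sizes are floored with a minimum of 2 per group; groups smaller than 3
    samples raise. Reproducible for a given seed; strata are sampled
    independently per iteration.
    """
    groups = data.groups
    cases = [s for s, g in groups.items() if g == "case"]
    controls = [s for s, g in groups.items() if g == "control"]
    for name, ids in (("case", cases), ("control", controls)):
        if len(ids) < 3:
            raise ValueError(
                f"{name} group has {len(ids)} samples; need >= 3 for 2/3 subsampling"
            )
    n_case = max(math.floor(fraction * len(cases)), 2)
    n_control = max(math.floor(fraction * len(controls)), 2)
    iterations = []
    for i in range(n_iterations):
        rng = child_rng(seed, f"subsample:{i}")
        iterations.append(
            (
                sorted(rng.choice(cases, size=n_case, replace=False)),
                sorted(rng.choice(controls, size=n_control, replace=False)),
            )
        )
    return SubsamplePlan(
        n_iterations=n_iterations, fraction=fraction, seed=seed, iterations=iterations
    )


def overlap_value(
    a: set[str], b: set[str], method: str = "intersection_over_min"
) -> float:
    """Symmetric similarity of two gene lists, in [0, 1].

    ``intersection_over_min``: |a∩b| / min(|a|, |b|) (0 with a warning when
    either set is empty); ``jaccard``: |a∩b| / |a∪b|; ``mean_containment``:
    the average of the two containment fractions.
    """
    if method not in OVERLAP_METHODS:
        raise ValueError(f"unknown overlap method {method!r}; choose from {OVERLAP_METHODS}")
    a, b = set(a), set(b)
    inter = len(a & b)
    if method == "intersection_over_min":
        if not a or not b:
            logger.warning("overlap_value: empty DEG list, overlap defined as 0")
            return 0.0
        return inter / min(len(a), len(b))
    if method == "jaccard":
        union = len(a | b)
        return inter / union if union else 0.0
    if not a or not b:
        logger.warning("overlap_value: empty DEG list, overlap defined as 0")
        return 0.0
    return 0.5 * (inter / len(a) + inter / len(b))


def robustness_report(
    deg_lists: Sequence[set[str]], method: str = "intersection_over_min"
) -> RobustnessReport:
    """All pairwise overlaps, their median, and the co-discovery profile.

    Co-discovery thresholds run from N = n_iterations down to
    floor(n_iterations/2) + 1 (10, >=9, ..., >=6 for the default ten
    iterations); fractions are count / union size, rounded to 2 decimals
    in the report.
    """
    lists = [set(l) for l in deg_lists]
    if len(lists) < 2:
        raise ValueError("need at least 2 DEG lists")
    pairs = list(itertools.combinations(range(len(lists)), 2))
    overlaps = [overlap_value(lists[i], lists[j], method=method) for i, j in pairs]
    union: set[str] = set().union(*lists)
    counts: dict[str, int] = {}
    for l in lists:
        for g in l:
            counts[g] = counts.get(g, 0) + 1
    co: dict[int, tuple[int, float]] = {}
    for n in range(len(lists), len(lists) // 2, -1):
        c = sum(1 for v in counts.values() if v >= n)
        frac = round_half_up(c / len(union), 2) if union else 0.0
        co[n] = (c, frac)
    return RobustnessReport(
        deg_lists=lists,
        overlap_method=method,
        pairwise_overlaps=overlaps,
        overlap_median=float(statistics.median(overlaps)),
        union_count=len(union),
        per_iteration_counts=[len(l) for l in lists],
        co_discovery=co,
    )


def compare_strategies(
    values_a: Sequence[float], values_b: Sequence[float], test: str = "welch"
) -> float:
    """Two-sided p-value comparing two strategies' overlap-value distributions.

    ``welch`` (default) is the unequal-variance t-test; ``mannwhitney`` the
    rank-sum alternative. Degenerate constant-and-identical inputs return
    p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 overlap values per strategy")
    if a.std() == 0 and b.std() == 0 and a.size and np.all(a[0] == a) and np.all(a[0] == b):
        logger.warning("compare_strategies: identical constant inputs, p defined as 1")
        return 1.0
    if test == "welch":
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    elif test == "mannwhitney":
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    if math.isnan(p):
        logger.warning("compare_strategies: degenerate inputs, p defined as 1")
        return 1.0
    return float(p)
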