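"""Split-half replication, randomized-null runs and overlap statistics.

The validation design for an unbalanced two-morph sample (here 34 vs 62):

* two *balanced split-half* scans, each reusing the full minority group
  against a disjoint half of the majority group, so outliers can be treated
  as hypotheses tested on a partially independent comparison;
* *randomized-null* scans comparing label-blind random groups of equal size,
  giving an empirical false-positive yardstick;
* overlap statistics: the expected shared-outlier count ``n1·n2/L`` under
  independent uniform outlier sets, an exact hypergeometric tail probability
  for the observed overlap, and the probability that the two scans' top loci
  coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .genotype import GenotypeMatrix, filter_loci
from .outlier import MCMCConfig, OutlierResult, bayescan_fit


@dataclass
class GroupDesign:
    """One two-group comparison: disjoint individual sets A and B."""

    run_id: str
    individuals_a: list[str]
    individuals_b: list[str]
    kind: str  # "balanced_split" | "randomized"

    def __post_init__(self) -> None:
        a, b = set(self.individuals_a), set(self.individuals_b)
        if len(a) != len(self.individuals_a) or len(b) != len(self.individuals_b):
            raise ValueError("individuals repeated within a design group")
        if a & b:
            raise ValueError("design groups must be disjoint")


@dataclass
class ReplicationReport:
    """Cross-run outlier comparison plus (optionally) null-run summaries."""

    outliers_per_run: dict[float, tuple[set[str], set[str]]]
    shared_loci: dict[float, set[str]]
    overlap_p: dict[float, float]
    expected_overlap: float
    top_locus_per_run: tuple[str, str]
    top_locus_coincides: bool
    p_top_prespecified: float  # (1/L)^2 — a named locus tops both runs
    p_top_coincidence: float  # 1/L — the two top loci merely coincide
    n_common_loci: int
    null_mean_count: float | None = None
    null_max_count: int | None = None
    null_min_q: float | None = None


def make_designs(
    labels: dict[str, str],
    mode: str,
    n_random_runs: int = 20,
    random_group_size: int = 34,
    seed: int | None = None,
) -> list[GroupDesign]:
    """Build balanced split-half or randomized group designs.

    ``balanced_split``: the full minority class vs each half of a random
    disjoint bipartition of the majority class (two designs).
    ``randomized``: ``n_random_runs`` designs, each two disjoint uniform
    random sets of ``random_group_size`` individuals, ignoring labels.
    """
    rng = np.random.default_rng(seed)
    ids = list(labels)
    if mode == "balanced_split":
        levels = sorted(set(labels.values()))
        if len(levels) != 2:
            raise ValueError("balanced_split requires exactly two label levels")
        by_level = {lev: [i for i in ids if labels[i] == lev] for lev in levels}
        minority, majority = sorted(by_level.values(), key=len)
        if len(minority) < 2:
            raise ValueError("minority class must have at least 2 individuals")
        perm = list(rng.permutation(majority))
        half = len(perm) // 2
        halves = [perm[:half], perm[half:]]
        return [
            GroupDesign(
                run_id=f"balanced_{k + 1}",
                individuals_a=list(minority),
                individuals_b=[str(x) for x in halves[k]],
                kind="balanced_split",
            )
            for k in range(2)
        ]
    if mode == "randomized":
        if 2 * random_group_size > len(ids):
            raise ValueError("2 × random_group_size exceeds the number of individuals")
        designs = []
        for k in range(n_random_runs):
            pick = rng.choice(ids, size=2 * random_group_size, replace=False)
            designs.append(
                GroupDesign(
                    run_id=f"random_{k + 1}",
                    individuals_a=[str(x) for x in pick[:random_group_size]],
                    individuals_b=[str(x) for x in pick[random_group_size:]],
                    kind="randomized",
                )
            )
        return designs
    raise ValueError(f"unknown design mode {mode!r}")


def run_replicated_scan(
    gm: GenotypeMatrix,
    designs: Sequence[GroupDesign],
    cfg: MCMCConfig,
    min_call_rate: float = 0.5,
    min_maf: float = 0.05,
) -> list[OutlierResult]:
    """One Bayesian scan per design on the subsetted matrix.

    Loci are re-checked against the call-rate/MAF thresholds after
    subsetting; loci dropped for a run are recorded on its result.  Each
    run's chain seed is the config seed plus the run index, for full
    reproducibility.
    """
    results = []
    base_seed = cfg.seed if cfg.seed is not None else 0
    for k, design in enumerate(designs):
        ids = design.individuals_a + design.individuals_b
        labels = ["A"] * len(design.individuals_a) + ["B"] * len(design.individuals_b)
        sub = gm.subset_individuals(ids, labels)
        filtered = filter_loci(sub, min_call_rate, min_maf, one_per_tag=False)
        if filtered.n_loci == 0:
            raise ValueError(f"design {design.run_id}: no loci survive re-filtering")
        run_cfg = cfg.with_seed(base_seed + k)
        res = bayescan_fit(filtered, groups=["A", "B"], cfg=run_cfg)
        res.dropped_loci = sorted(set(gm.locus_ids) - set(filtered.locus_ids))
        results.append(res)
    return results


def expected_overlap(n1: int, n2: int, L: int) -> float:
    """Expected shared count of two independent uniform subsets of sizes
    ``n1`` and ``n2`` drawn from ``L`` loci: ``n1 · n2 / L``."""
    if L < 1:
        raise ValueError("L must be at least 1")
    if n1 < 0 or n2 < 0 or n1 > L or n2 > L:
        raise ValueError("subset sizes must lie in [0, L]")
    return n1 * n2 / L


def overlap_report(
    results: Sequence[OutlierResult],
    thresholds: Sequence[float] = (0.2, 0.1, 0.05),
    L: int | None = None,
) -> ReplicationReport:
    """Compare two scans' outlier sets at each q threshold.

    Intersections are taken over the loci retained in both runs.
    ``overlap_p`` is the exact upper-tail hypergeometric probability of at
    least the observed shared count when a size-``n2`` subset is drawn from
    ``L`` loci of which ``n1`` are marked.  Both top-locus probabilities are
    reported: the pre-specified-locus form ``(1/L)²`` and the coincidence
    form ``1/L``.
    """
    if len(results) != 2:
        raise ValueError("overlap_report compares exactly two runs")
    r1, r2 = results
    common = sorted(set(r1.locus_ids) & set(r2.locus_ids))
    if not common:
        raise ValueError("the two runs share no loci")
    L_eff = L if L is not None else len(common)

    outliers: dict[float, tuple[set[str], set[str]]] = {}
    shared: dict[float, set[str]] = {}
    pvals: dict[float, float] = {}
    common_set = set(common)
    for t in thresholds:
        s1 = r1.outlier_set(t) & common_set
        s2 = r2.outlier_set(t) & common_set
        outliers[t] = (s1, s2)
        shared[t] = s1 & s2
        pvals[t] = float(
            hypergeom.sf(len(s1 & s2) - 1, L_eff, len(s1), len(s2))
        )
    t0 = max(thresholds)
    n1, n2 = len(outliers[t0][0]), len(outliers[t0][1])
    top1, top2 = r1.top_locus(), r2.top_locus()
    return ReplicationReport(
        outliers_per_run=outliers,
        shared_loci=shared,
        overlap_p=pvals,
        expected_overlap=expected_overlap(n1, n2, L_eff),
        top_locus_per_run=(top1, top2),
        top_locus_coincides=top1 == top2,
        p_top_prespecified=(1.0 / L_eff) ** 2,
        p_top_coincidence=1.0 / L_eff,
        n_common_loci=len(common),
    )


def null_summary(
    null_results: Sequence[OutlierResult], q_threshold: float = 0.2
) -> tuple[float, int, float]:
    """Summaries of randomized-null scans: (mean outlier count, max outlier
    count, minimum q-value across all runs and loci)."""
    if not null_results:
        raise ValueError("need at least one null run")
    counts = [len(r.outlier_set(q_threshold)) for r in null_results]
    min_q = min(float(r.table["q_value"].min()) for r in null_results)
    return float(np.mean(counts)), int(max(counts)), min_q
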