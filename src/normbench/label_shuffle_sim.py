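"""Cluster-anchored label shuffling: simulate new paired data sets.

New two-group assignments are generated from the benchmark data by
(1) clustering the samples into two clusters on their log2-CPM profiles
(agglomerative, Euclidean distance, Ward linkage), (2) drawing nine anchor
samples per cluster to seed the two new groups, and (3) randomly allocating
the remaining samples to the groups under balanced sizes.  The identical
shuffle applies to the test matrix, so each shuffle yields a new paired
study with a controlled degree of true group separation.  Each pair is
characterized by its DE pattern (proportion of markers called DE in the
shuffled benchmark, and the median absolute group mean difference on the
log2 scale over those markers); a bank of pairs is reproducible from seeds
alone, so nothing but seeds and patterns needs storing.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_io import CountMatrix, GroupAssignment, PairedStudy
from .de_testing import run_de
from .errors import DomainError, InfeasibleAnchorError

logger = logging.getLogger(__name__)

#: labels used for the two shuffled pseudo-groups
GROUP_NAMES = ("G1", "G2")


@dataclass(frozen=True)
class ShuffledAssignment:
    seed: int
    anchors_group1: tuple
    anchors_group2: tuple
    labels: GroupAssignment

    @property
    def anchor_ids(self) -> tuple:
        return self.anchors_group1 + self.anchors_group2


@dataclass(frozen=True)
class PairPattern:
    """DE pattern of one shuffled pair: recomputable from assignment + data."""

    de_proportion: float
    median_mean_diff: float    # NaN if no marker was called DE


def _log2_cpm(cm: CountMatrix) -> np.ndarray:
    d = cm.library_sizes
    return np.log2((cm.counts + 0.5) / (d + 1.0)[np.newaxis, :] * 1e6)


def cluster_samples(cm: CountMatrix) -> dict:
    """Split samples into two clusters (Ward on Euclidean log2-CPM distance).

    The cluster containing the lexicographically smallest sample ID is
    cluster 1, for determinism.
    """
    z = _log2_cpm(cm)
    link = hierarchy.linkage(pdist(z.T, metric="euclidean"), method="ward")
    assign = hierarchy.fcluster(link, t=2, criterion="maxclust")
    ids = np.array(cm.sample_ids)
    first = min(cm.sample_ids)
    c_first = assign[list(cm.sample_ids).index(first)]
    cluster1 = sorted(ids[assign == c_first])
    cluster2 = sorted(ids[assign != c_first])
    return {1: tuple(cluster1), 2: tuple(cluster2)}


def shuffle_labels(study: PairedStudy, seed: int,
                   n_anchors: int = 9, balanced: bool = True) -> ShuffledAssignment:
    """Draw one cluster-anchored shuffled assignment.

    ``n_anchors`` samples per cluster become the anchors of the two new
    groups; the remaining samples are allocated at random, balanced to n/2
    per group by default (``balanced=False`` gives unconstrained Bernoulli(1/2)
    allocation).  Output depends only on (study, seed, n_anchors, balanced).
    """
    clusters = cluster_samples(study.benchmark)
    n = study.benchmark.n_samples
    for c in (1, 2):
        if len(clusters[c]) < n_anchors:
            raise InfeasibleAnchorError(
                f"cluster {c} has {len(clusters[c])} samples, "
                f"fewer than n_anchors={n_anchors}"
            )
    if balanced and 2 * n_anchors > n:
        raise InfeasibleAnchorError("2*n_anchors exceeds the sample count")

    rng = np.random.default_rng(seed)
    anchors1 = tuple(sorted(str(s) for s in
                            rng.choice(clusters[1], size=n_anchors,
                                       replace=False)))
    anchors2 = tuple(sorted(str(s) for s in
                            rng.choice(clusters[2], size=n_anchors,
                                       replace=False)))
    remaining = sorted(set(study.benchmark.sample_ids)
                       - set(anchors1) - set(anchors2))
    if balanced:
        target1 = n // 2 - n_anchors
        if target1 < 0 or target1 > len(remaining):
            raise InfeasibleAnchorError("balanced allocation infeasible")
        perm = rng.permutation(remaining)
        to1 = set(perm[:target1])
    else:
        flips = rng.random(len(remaining)) < 0.5
        to1 = {s for s, f in zip(remaining, flips) if f}

    label_map = {s: GROUP_NAMES[0] for s in anchors1}
    label_map.update({s: GROUP_NAMES[1] for s in anchors2})
    for s in remaining:
        label_map[s] = GROUP_NAMES[0] if s in to1 else GROUP_NAMES[1]

    sample_ids = study.benchmark.sample_ids
    labels = GroupAssignment(sample_ids,
                             tuple(label_map[s] for s in sample_ids))
    return ShuffledAssignment(seed, anchors1, anchors2, labels)


def characterize_pair(study: PairedStudy, assignment: ShuffledAssignment,
                      de_backend: str = "voom",
                      alpha: float = 0.01) -> PairPattern:
    """Run DE on the shuffled benchmark and summarize its DE pattern."""
    de = run_de(study.benchmark, assignment.labels, backend=de_backend)
    called = de.p_values < alpha
    de_prop = float(called.mean())
    if called.any():
        z = _log2_cpm(study.benchmark)
        g = assignment.labels.indicator(study.benchmark.sample_ids).astype(bool)
        diff = np.abs(z[:, g].mean(axis=1) - z[:, ~g].mean(axis=1))
        med = float(np.median(diff[called]))
    else:
        med = float("nan")
    return PairPattern(de_prop, med)


def child_seed(master_seed: int, index: int) -> int:
    """Deterministic counter-based child seed: sha256("master:index") mod 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{index}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2 ** 31)


@dataclass(frozen=True)
class BankEntry:
    index: int
    seed: int
    assignment: ShuffledAssignment
    pattern: PairPattern


def generate_bank(study: PairedStudy, n_pairs: int, seed: int,
                  n_anchors: int = 9, de_backend: str = "voom",
                  alpha: float = 0.01, balanced: bool = True) -> list:
    """Pre-simulate ``n_pairs`` shuffled pairs, each characterized.

    Child seeds are spawned deterministically from the master seed, so every
    pair is reconstructable bit-identically without storing matrices.
    """
    if n_pairs < 1:
        raise DomainError("n_pairs must be >= 1")
    bank = []
    for i in range(n_pairs):
        cs = child_seed(seed, i)
        assignment = shuffle_labels(study, cs, n_anchors=n_anchors,
                                    balanced=balanced)
        pattern = characterize_pair(study, assignment,
                                    de_backend=de_backend, alpha=alpha)
        bank.append(BankEntry(i, cs, assignment, pattern))
    return bank


def extract_by_pattern(bank: Sequence[BankEntry], de_prop_target: float,
                       tolerance: float, diff_target: float,
                       diff_tolerance: float, n: int) -> list:
    """First ``n`` bank entries (bank order) matching the pattern window."""
    if not bank:
        raise DomainError("bank is empty")
    matches = [
        e for e in bank
        if abs(e.pattern.de_proportion - de_prop_target) <= tolerance
        and np.isfinite(e.pattern.median_mean_diff)
        and abs(e.pattern.median_mean_diff - diff_target) <= diff_tolerance
    ]
    if len(matches) < n:
        warnings.warn(
            f"only {len(matches)} of the requested {n} pairs match the "
            "pattern window", RuntimeWarning,
        )
    return matches[:n]


def bank_to_frame(bank: Sequence[BankEntry]) -> pd.DataFrame:
    rows = []
    for e in bank:
        rows.append({
            "index": e.index,
            "child_seed": e.seed,
            "anchors_group1": ";".join(e.assignment.anchors_group1),
            "anchors_group2": ";".join(e.assignment.anchors_group2),
            "labels": ";".join(
                f"{s}={l}" for s, l in zip(e.assignment.labels.sample_ids,
                                           e.assignment.labels.labels)
            ),
            "de_proportion": e.pattern.de_proportion,
            "median_mean_diff": e.pattern.median_mean_diff,
        })
    return pd.DataFrame(rows)


def bank_from_frame(df: pd.DataFrame) -> list:
    """Rebuild bank entries (assignments + patterns) from a serialized table."""
    bank = []
    for _, row in df.iterrows():
        pairs = [kv.split("=") for kv in str(row["labels"]).split(";")]
        labels = GroupAssignment(tuple(s for s, _ in pairs),
                                 tuple(l for _, l in pairs))
        assignment = ShuffledAssignment(
            int(row["child_seed"]),
            tuple(str(row["anchors_group1"]).split(";")),
            tuple(str(row["anchors_group2"]).split(";")),
            labels,
        )
        bank.append(BankEntry(
            int(row["index"]), int(row["child_seed"]), assignment,
            PairPattern(float(row["de_proportion"]),
                        float(row["median_mean_diff"])),
        ))
    return bank
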