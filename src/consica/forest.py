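"""Random survival forests on TC activities for patient stratification.

Each of the (default 1000) trees draws 5 TCs as its candidate classifiers
and recursively partitions the patients by the cutpoint maximizing the
two-sample log-rank statistic, subject to minimum node size and event
counts.  A split must clear a Bonferroni-corrected log-rank significance
threshold (alpha over the number of cutpoints examined at the node), so
trees grown on candidates unrelated to survival usually stay single-node.
No bootstrap resampling is used: every tree sees all patients, so the
summed proximity matrix has diagonal exactly n_trees.

Stratification clusters the summed proximity (converted to the
dissimilarity 1 - proximity/n_trees) with Ward-D2 linkage, and the retained
number of subgroups is the largest k whose k-sample log-rank test is
significant.  A TC's importance score is the fraction of trees, among those
where it was a candidate, in which it classifies (appears in >= 1 split).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import MixingMatrix, SurvivalTable

__all__ = [
    "SurvivalTree",
    "SurvivalForest",
    "ProximityMatrix",
    "logrank_split",
    "grow_tree",
    "build_forest",
    "final_proximity",
    "importance_scores",
    "cluster_proximity",
    "select_max_subgroups",
    "compare_proximity",
]

logger = logging.getLogger(__name__)


@dataclass
class TreeNode:
    samples: np.ndarray  # indices into the tree's sample order
    split_tc: str | None = None
    cutpoint: float | None = None
    statistic: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_terminal(self) -> bool:
        return self.split_tc is None


@dataclass
class SurvivalTree:
    candidate_tcs: list
    root: TreeNode
    terminal_labels: np.ndarray  # per-sample terminal-node id
    used_tcs: set = field(default_factory=set)


@dataclass
class SurvivalForest:
    trees: list
    sample_ids: list
    tc_ids: list
    n_trees: int
    proximity_counts: np.ndarray  # running element-wise sum over trees


def _logrank_scan(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    min_node_size: int,
    min_node_events: int,
):
    """Two-sample log-rank statistic for every candidate cutpoint of x.

    Returns ``(cutpoints, statistics, n_cutpoints_examined)`` over admissible
    splits, or ``None`` when no cutpoint is admissible.  Group 1 is
    ``x <= cut``; the statistic is (O1-E1)^2/V with the hypergeometric
    variance, evaluated for all prefixes of the x-order at once.
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ts = time[order]
    es = event[order].astype(bool)

    # distinct event times and per-time death / at-risk counts
    ev_times, d = np.unique(ts[es], return_counts=True)
    if len(ev_times) == 0:
        return None
    d = d.astype(float)

    # N1[m, j] = members of the first m samples (x-order) at risk at time j
    at_risk = ts[:, None] >= ev_times[None, :]  # (n, J)
    n_at = at_risk.sum(axis=0).astype(float)
    N1 = np.cumsum(at_risk, axis=0).astype(float)
    O1 = np.cumsum(es).astype(float)
    E1 = N1 @ (d / n_at)
    with np.errstate(divide="ignore", invalid="ignore"):
        wvar = np.where(n_at > 1, d * (n_at - d) / ((n_at - 1) * n_at**2), 0.0)
    V = (N1 * (n_at[None, :] - N1)) @ wvar

    m = np.arange(1, n + 1)
    total_events = es.sum()
    boundary = xs[:-1] < xs[1:]  # cannot split between equal values
    admissible = (
        boundary
        & (m[:-1] >= min_node_size)
        & ((n - m[:-1]) >= min_node_size)
        & (O1[:-1] >= min_node_events)
        & ((total_events - O1[:-1]) >= min_node_events)
    )
    idx = np.where(admissible)[0]
    if len(idx) == 0:
        return None
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V[idx] > 0, (O1[idx] - E1[idx]) ** 2 / V[idx], 0.0)
    cuts = 0.5 * (xs[idx] + xs[idx + 1])
    return cuts, chi2, len(idx)


def logrank_split(
    values,
    survival: SurvivalTable,
    min_node_size: int = 15,
    min_node_events: int = 5,
    stat_threshold: float = 0.0,
):
    """Best log-rank cutpoint for one feature, or None if inadmissible.

    ``stat_threshold`` rejects splits whose best statistic falls below it
    (0 accepts any admissible split).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2 * min_node_size:
        return None
    if np.all(x == x[0]):
        return None
    time = survival.data["time"].to_numpy(float)
    event = survival.data["event"].to_numpy(int)
    scan = _logrank_scan(x, time, event, min_node_size, min_node_events)
    if scan is None:
        return None
    cuts, chi2, _ = scan
    best = int(np.argmax(chi2))
    if chi2[best] < stat_threshold or chi2[best] <= 0:
        return None
    return float(cuts[best]), float(chi2[best])


def grow_tree(
    activities: MixingMatrix,
    survival: SurvivalTable,
    candidate_tcs,
    min_node_size: int = 15,
    min_node_events: int = 5,
    split_alpha: float = 0.05,
    seed: int = 0,
) -> SurvivalTree:
    """Recursive log-rank partitioning over the candidate TCs.

    At each node the best (TC, cutpoint) pair is kept only if it clears the
    Bonferroni-corrected chi-square threshold ``split_alpha / n_cutpoints``
    (cutpoints summed over all candidates at that node); otherwise the node
    is terminal.
    """
    candidate_tcs = list(candidate_tcs)
    missing = [c for c in candidate_tcs if c not in activities.component_ids]
    if missing:
        raise ValueError(f"candidate TCs not in mixing matrix: {missing}")
    surv = survival.aligned_to(activities.sample_ids)
    time = surv.data["time"].to_numpy(float)
    event = surv.data["event"].to_numpy(int)
    rowidx = {c: activities.component_ids.index(c) for c in candidate_tcs}
    A = activities.activities
    n = activities.n_samples
    used: set = set()

    def split_node(samples: np.ndarray) -> TreeNode:
        node = TreeNode(samples=samples)
        if len(samples) < 2 * min_node_size:
            return node
        best = None
        total_cuts = 0
        for tc in candidate_tcs:
            x = A[rowidx[tc], samples]
            if np.all(x == x[0]):
                continue
            scan = _logrank_scan(
                x, time[samples], event[samples], min_node_size, min_node_events
            )
            if scan is None:
                continue
            cuts, chi2, n_cuts = scan
            total_cuts += n_cuts
            j = int(np.argmax(chi2))
            if best is None or chi2[j] > best[2]:
                best = (tc, float(cuts[j]), float(chi2[j]))
        if best is None or total_cuts == 0:
            return node
        threshold = stats.chi2.isf(min(split_alpha / total_cuts, 1.0), df=1)
        if best[2] < threshold:
            return node
        tc, cut, stat = best
        mask = A[rowidx[tc], samples] <= cut
        node.split_tc, node.cutpoint, node.statistic = tc, cut, stat
        used.add(tc)
        node.left = split_node(samples[mask])
        node.right = split_node(samples[~mask])
        return node

    root = split_node(np.arange(n))

    labels = np.empty(n, dtype=np.intp)
    counter = [0]

    def assign(node: TreeNode):
        if node.is_terminal:
            labels[node.samples] = counter[0]
            counter[0] += 1
        else:
            assign(node.left)
            assign(node.right)

    assign(root)
    return SurvivalTree(
        candidate_tcs=candidate_tcs, root=root, terminal_labels=labels, used_tcs=used
    )


@dataclass
class _TreeRecord:
    candidate_tcs: list
    used_tcs: set


def build_forest(
    activities: MixingMatrix,
    survival: SurvivalTable,
    n_trees: int = 1000,
    tcs_per_tree: int = 5,
    min_node_size: int = 15,
    min_node_events: int = 5,
    split_alpha: float = 0.05,
    seed: int = 0,
) -> SurvivalForest:
    """Grow the forest, accumulating the element-wise proximity sum.

    Per-tree proximity is the co-terminal-node indicator over all samples;
    trees are summarized to (candidates, used TCs) to keep memory flat.
    """
    k = activities.n_components
    if k < tcs_per_tree:
        raise ValueError(
            f"need at least {tcs_per_tree} TCs, got {k}"
        )
    surv = survival.aligned_to(activities.sample_ids)
    rng = np.random.default_rng(seed)
    n = activities.n_samples
    prox = np.zeros((n, n), dtype=np.int64)
    records = []
    ids = np.array(activities.component_ids)
    for _ in range(n_trees):
        cand = list(ids[rng.choice(k, size=tcs_per_tree, replace=False)])
        tree = grow_tree(
            activities,
            surv,
            cand,
            min_node_size=min_node_size,
            min_node_events=min_node_events,
            split_alpha=split_alpha,
        )
        lab = tree.terminal_labels
        prox += lab[:, None] == lab[None, :]
        records.append(_TreeRecord(candidate_tcs=cand, used_tcs=tree.used_tcs))
    return SurvivalForest(
        trees=records,
        sample_ids=activities.sample_ids,
        tc_ids=list(activities.component_ids),
        n_trees=n_trees,
        proximity_counts=prox,
    )


@dataclass
class ProximityMatrix:
    sample_ids: list
    counts: np.ndarray
    n_trees: int

    def __post_init__(self):
        c = np.asarray(self.counts)
        if not np.array_equal(c, c.T):
            raise ValueError("proximity counts must be symmetric")
        if np.any(c < 0) or np.any(c > self.n_trees):
            raise ValueError("proximity counts must lie in [0, n_trees]")


def final_proximity(forest: SurvivalForest) -> ProximityMatrix:
    """Element-wise summed proximity; diagonal equals n_trees exactly."""
    if forest.n_trees == 0:
        raise ValueError("empty forest")
    return ProximityMatrix(
        sample_ids=forest.sample_ids,
        counts=forest.proximity_counts,
        n_trees=forest.n_trees,
    )


def importance_scores(forest: SurvivalForest) -> pd.Series:
    """Per TC: trees where it classifies / trees where it was a candidate."""
    cand = dict.fromkeys(forest.tc_ids, 0)
    used = dict.fromkeys(forest.tc_ids, 0)
    for rec in forest.trees:
        for tc in rec.candidate_tcs:
            cand[tc] += 1
        for tc in rec.used_tcs:
            used[tc] += 1
    scores = {
        tc: (used[tc] / cand[tc]) if cand[tc] else 0.0 for tc in forest.tc_ids
    }
    return pd.Series(scores, name="importance")


def cluster_proximity(P: ProximityMatrix, k: int) -> np.ndarray:
    """Ward-D2 clustering of d = 1 - proximity/n_trees; labels 1..k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(P.sample_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    if k == 1:
        return np.ones(n, dtype=int)
    D = 1.0 - P.counts / P.n_trees
    np.fill_diagonal(D, 0.0)
    link = linkage(squareform(D, checks=False), method="ward")
    return fcluster(link, t=k, criterion="maxclust")


def select_max_subgroups(
    P: ProximityMatrix,
    survival: SurvivalTable,
    k_max: int = 10,
    alpha: float = 0.05,
) -> tuple[int, np.ndarray, pd.DataFrame]:
    """Largest k in 2..k_max whose k-sample log-rank test is significant.

    Returns (k*, labels, per-k table); (1, all-ones) when nothing reaches
    significance.
    """
    surv = survival.aligned_to(P.sample_ids)
    time = surv.data["time"].to_numpy(float)
    event = surv.data["event"].to_numpy(int)
    rows = []
    best = (1, np.ones(len(P.sample_ids), dtype=int))
    for k in range(2, k_max + 1):
        labels = cluster_proximity(P, k)
        if len(np.unique(labels)) < 2:
            continue
        res = multivariate_logrank_test(time, labels, event)
        p = float(res.p_value)
        rows.append({"k": k, "statistic": float(res.test_statistic), "p_value": p})
        if p < alpha:
            best = (k, labels)
    return best[0], best[1], pd.DataFrame(rows, columns=["k", "statistic", "p_value"])


def compare_proximity(P1: ProximityMatrix, P2: ProximityMatrix) -> float:
    """Pearson r between upper-triangle off-diagonal proximity counts."""
    if list(P1.sample_ids) != list(P2.sample_ids):
        raise ValueError("proximity matrices cover different samples")
    iu = np.triu_indices(len(P1.sample_ids), k=1)
    a, b = P1.counts[iu].astype(float), P2.counts[iu].astype(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate (constant) proximity matrix")
    return float(np.corrcoef(a, b)[0, 1])
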