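"""Consensus independent component analysis of bulk expression.

The decomposition runs FastICA (fixed-point iteration, log-cosh negentropy
contrast) repeatedly from different random initial weight vectors, clusters
components that reappear across runs (|Pearson r| > 0.9 of their gene
weights), averages each cluster into a consensus transcriptional component
(TC), and keeps TCs whose cluster gathered members from at least half the
runs (credibility index >= 0.5).  The number of components is fixed
beforehand as the smallest number of principal components of the
between-sample covariance matrix explaining at least 85% of total variance.

Orientation convention: ICA signs are arbitrary, so each consensus TC is
flipped to have positive gene-weight skewness (ties broken by making the
largest-|weight| gene positive).  This makes the full decomposition
deterministic given the master seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .containers import ExpressionMatrix, MixingMatrix, TCSet

__all__ = [
    "ICARunResult",
    "ComponentCluster",
    "ICAConvergenceError",
    "select_n_components",
    "run_single_ica",
    "cluster_components",
    "build_consensus",
    "estimate_mixing",
    "reconstruct",
    "ReconstructionResult",
    "decompose",
]

logger = logging.getLogger(__name__)


class ICAConvergenceError(RuntimeError):
    pass


@dataclass
class ICARunResult:
    run_seed: int
    components: np.ndarray  # (n_components, n_genes), standardized rows

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


@dataclass
class ComponentCluster:
    #: (run_index, component_index, alignment sign in {+1, -1}) per member
    members: list
    consensus: np.ndarray

    @property
    def size(self) -> int:
        return len(self.members)


def _center_genes(X: ExpressionMatrix) -> np.ndarray:
    V = X.values
    return V - V.mean(axis=1, keepdims=True)


def select_n_components(
    X: ExpressionMatrix, variance_threshold: float = 0.85
) -> int:
    """Minimum number of PCs of the sample-covariance spectrum reaching the
    cumulative explained-variance threshold."""
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    if X.n_samples < 2:
        raise ValueError("need at least 2 samples")
    Xc = _center_genes(X)
    # eigenvalues of the n x n between-sample covariance == squared singular
    # values of the centered matrix (up to the common 1/(p-1) factor)
    s = np.linalg.svd(Xc, compute_uv=False)
    ev = s**2
    total = ev.sum()
    if total <= 0:
        raise ValueError("matrix has zero total variance (constant input)")
    cum = np.cumsum(ev) / total
    return int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)


def run_single_ica(
    X: ExpressionMatrix,
    n_components: int,
    seed: int,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> ICARunResult:
    """One FastICA run in gene space.

    The matrix is fed genes-as-observations so the recovered sources are
    gene-weight vectors; whitening is the PCA step across samples.  Raises
    :class:`ICAConvergenceError` when the fixed-point iteration does not
    converge (e.g. on purely Gaussian data, where ICA is unidentifiable).
    """
    if n_components > min(X.n_genes, X.n_samples):
        raise ValueError("n_components exceeds matrix rank bound")
    Xc = _center_genes(X)
    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        fun="logcosh",
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed) % (2**32),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            S = ica.fit_transform(Xc)  # (genes, k)
        except ConvergenceWarning as exc:
            raise ICAConvergenceError(
                f"FastICA did not converge for run seed {seed}: {exc}"
            ) from exc
    comps = S.T
    comps = (comps - comps.mean(axis=1, keepdims=True)) / comps.std(
        axis=1, keepdims=True
    )
    return ICARunResult(run_seed=seed, components=comps)


def cluster_components(
    runs: list[ICARunResult],
    r_threshold: float = 0.9,
    max_cluster_size: int | None = None,
) -> list[ComponentCluster]:
    """Greedy agglomeration of matching components across ICA runs.

    Edges (|Pearson r| > threshold between standardized gene-weight vectors)
    are processed in descending |r|; a merge is refused when it would exceed
    ``max_cluster_size`` (default: the number of runs) or place two
    components from the same run in one cluster.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 ICA runs to cluster")
    if max_cluster_size is None:
        max_cluster_size = len(runs)
    flat = []  # (run_index, comp_index)
    rows = []
    for ri, run in enumerate(runs):
        for ci in range(run.n_components):
            flat.append((ri, ci))
            rows.append(run.components[ci])
    M = np.asarray(rows)
    p = M.shape[1]
    R = (M @ M.T) / p  # rows standardized -> correlation
    m = len(flat)

    iu, ju = np.triu_indices(m, k=1)
    absr = np.abs(R[iu, ju])
    keep = absr > r_threshold
    order = np.argsort(-absr[keep], kind="stable")
    edges = list(zip(iu[keep][order], ju[keep][order], np.sign(R[iu, ju][keep][order])))

    parent = list(range(m))
    sign = np.ones(m, dtype=int)  # orientation relative to cluster root
    runs_in = [{flat[i][0]} for i in range(m)]
    size = [1] * m

    def find(i):
        root = i
        s = 1
        while parent[root] != root:
            s *= sign[root]
            root = parent[root]
        return root, s

    for i, j, r_sign in edges:
        ri, si = find(i)
        rj, sj = find(j)
        if ri == rj:
            continue
        if size[ri] + size[rj] > max_cluster_size:
            continue
        if runs_in[ri] & runs_in[rj]:
            continue  # one component per run per cluster
        # attach smaller under larger
        if size[ri] < size[rj]:
            ri, rj = rj, ri
            si, sj = sj, si
        # orientation: member j aligns with i via r_sign
        parent[rj] = ri
        sign[rj] = int(si * r_sign * sj)
        size[ri] += size[rj]
        runs_in[ri] |= runs_in[rj]

    clusters: dict[int, list] = {}
    for idx in range(m):
        root, s = find(idx)
        clusters.setdefault(root, []).append((flat[idx][0], flat[idx][1], int(s)))

    out = []
    for root in sorted(clusters, key=lambda r: (-len(clusters[r]), r)):
        members = clusters[root]
        vecs = np.array(
            [s * runs[ri].components[ci] for ri, ci, s in members]
        )
        consensus = vecs.mean(axis=0)
        out.append(ComponentCluster(members=members, consensus=consensus))
    return out


def _canonical_sign(w: np.ndarray) -> int:
    """Positive-skewness orientation; fall back to the largest-|w| gene."""
    z = (w - w.mean()) / w.std()
    skew = float(np.mean(z**3))
    if abs(skew) > 1e-12:
        return 1 if skew > 0 else -1
    return 1 if w[int(np.argmax(np.abs(w)))] >= 0 else -1


def build_consensus(
    clusters: list[ComponentCluster],
    n_runs: int,
    credibility_threshold: float = 0.5,
    gene_ids: list | None = None,
) -> TCSet:
    """Average each cluster, credibility = cluster size / n_runs, keep
    clusters at or above the credibility threshold."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    kept = []
    for cluster in clusters:
        cred = cluster.size / n_runs
        if cred >= credibility_threshold:
            kept.append((cred, cluster))
    if not kept:
        raise ValueError(
            f"no cluster reaches credibility {credibility_threshold} "
            f"({len(clusters)} clusters from {n_runs} runs)"
        )
    # descending credibility, ties by first occurrence in the cluster list
    kept.sort(key=lambda t: -t[0])
    weights, cred = [], []
    for c, cluster in kept:
        w = cluster.consensus
        w = (w - w.mean()) / w.std()
        weights.append(_canonical_sign(w) * w)
        cred.append(c)
    weights = np.asarray(weights)
    p = weights.shape[1]
    return TCSet(
        component_ids=[f"TC{i + 1}" for i in range(len(kept))],
        gene_ids=list(gene_ids) if gene_ids is not None else [f"G{i:05d}" for i in range(p)],
        weights=weights,
        credibility=np.asarray(cred),
    )


def estimate_mixing(X: ExpressionMatrix, tcs: TCSet) -> MixingMatrix:
    """Per-sample least-squares activities against the consensus weights.

    Solves ``min_A ||Xc - S^T A||`` for the gene-centered expression; the
    consensus averaging destroys any exact unmixing inverse, so OLS is the
    natural estimator of the mixing coefficients.
    """
    if list(tcs.gene_ids) != list(X.gene_ids):
        common = [g for g in X.gene_ids if g in set(tcs.gene_ids)]
        if not common:
            raise ValueError("no shared genes between expression and TCSet")
        gx = {g: i for i, g in enumerate(X.gene_ids)}
        gt = {g: i for i, g in enumerate(tcs.gene_ids)}
        Xv = X.values[[gx[g] for g in common]]
        S = tcs.weights[:, [gt[g] for g in common]]
    else:
        Xv = X.values
        S = tcs.weights
    Xc = Xv - Xv.mean(axis=1, keepdims=True)
    G = S @ S.T
    cond = np.linalg.cond(G)
    if cond > 1e10:
        corr = np.corrcoef(S)
        np.fill_diagonal(corr, 0)
        pairs = np.argwhere(np.abs(corr) > 0.999)
        names = sorted(
            {tcs.component_ids[i] for i, j in pairs} | {tcs.component_ids[j] for i, j in pairs}
        )
        raise ValueError(f"weight matrix is rank deficient; collinear components: {names}")
    A = np.linalg.solve(G, S @ Xc)
    # zero-variance samples carry no signal -> exactly zero activities
    zero = Xv.std(axis=0) == 0
    A[:, zero] = 0.0
    return MixingMatrix(tcs.component_ids, X.sample_ids, A)


@dataclass
class ReconstructionResult:
    expression: ExpressionMatrix
    r2_overall: float
    r2_per_sample: np.ndarray


def reconstruct(
    tcs: TCSet, mixing: MixingMatrix, original: ExpressionMatrix | None = None
) -> ReconstructionResult:
    """Inner product of activities and weights, with R^2 bookkeeping.

    R^2 is computed against the gene-centered original when provided
    (reconstruction models centered expression), else reported as NaN.
    """
    if list(tcs.component_ids) != list(mixing.component_ids):
        raise ValueError("component ids of TCSet and MixingMatrix do not match")
    V = tcs.weights.T @ mixing.activities
    Xhat = ExpressionMatrix(tcs.gene_ids, mixing.sample_ids, V)
    if original is None:
        return ReconstructionResult(Xhat, float("nan"), np.full(len(mixing.sample_ids), np.nan))
    if list(original.gene_ids) != list(tcs.gene_ids) or list(
        original.sample_ids
    ) != list(mixing.sample_ids):
        raise ValueError("original matrix dimensions do not match the reconstruction")
    Xc = original.values - original.values.mean(axis=1, keepdims=True)
    resid = Xc - V
    ss_res = (resid**2).sum(axis=0)
    ss_tot = (Xc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2_sample = 1.0 - ss_res / ss_tot
    r2_overall = 1.0 - ss_res.sum() / ss_tot.sum()
    return ReconstructionResult(Xhat, float(r2_overall), r2_sample)


def decompose(
    X: ExpressionMatrix,
    n_runs: int = 25,
    variance_threshold: float = 0.85,
    r_threshold: float = 0.9,
    credibility_threshold: float = 0.5,
    master_seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> tuple[TCSet, MixingMatrix]:
    """Full consensus decomposition: select i -> n_runs x ICA -> cluster ->
    consensus -> mixing estimation.  Run seeds derive deterministically from
    the master seed."""
    i = select_n_components(X, variance_threshold)
    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    logger.info("c-ICA: %d components, %d runs (master seed %d)", i, n_runs, master_seed)
    runs = [run_single_ica(X, i, int(s), max_iter=max_iter, tol=tol) for s in seeds]
    if n_runs == 1:
        clusters = [
            ComponentCluster(members=[(0, ci, 1)], consensus=runs[0].components[ci])
            for ci in range(runs[0].n_components)
        ]
    else:
        clusters = cluster_components(runs, r_threshold=r_threshold)
    logger.info(
        "c-ICA: %d clusters, sizes %s", len(clusters), sorted((c.size for c in clusters), reverse=True)
    )
    tcs = build_consensus(
        clusters, n_runs, credibility_threshold=credibility_threshold, gene_ids=X.gene_ids
    )
    mixing = estimate_mixing(X, tcs)
    return tcs, mixing
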