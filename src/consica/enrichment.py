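"""Gene-set enrichment of TC gene weights and covariate correlation.

Enrichment of a gene set within a TC is the two-sample Welch t statistic
comparing the TC's weights of in-set genes against all out-of-set genes,
converted to a signed standard-normal Z-score via the two-sided p-value so
that sets of different sizes are comparable.  Significance is controlled by
Bonferroni correction over the full (TC x set) table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import GeneSetCollection, MixingMatrix, TCSet

__all__ = [
    "filter_gene_sets",
    "welch_enrichment",
    "enrichment_table",
    "important_genes",
    "activity_covariate_correlation",
]

logger = logging.getLogger(__name__)


def filter_gene_sets(
    collection: GeneSetCollection,
    universe,
    min_size: int = 10,
    max_size: int = 500,
) -> GeneSetCollection:
    """Intersect each set with the profiled universe, then keep sets whose
    post-intersection size lies in [min_size, max_size]."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    kept, dropped = {}, []
    for name, genes in collection:
        members = [g for g in genes if g in universe]
        if min_size <= len(members) <= max_size:
            kept[name] = members
        else:
            dropped.append(name)
    if dropped:
        logger.info("filter_gene_sets: dropped %d/%d sets", len(dropped), len(collection))
    if not kept:
        logger.warning("filter_gene_sets: no sets survive filtering")
    return GeneSetCollection(collection.name, kept)


def _welch_from_stats(m1, v1, n1, m2, v2, n2):
    """Vectorized Welch t and Welch-Satterthwaite df from group moments."""
    se1, se2 = v1 / n1, v2 / n2
    denom = se1 + se2
    t = (m1 - m2) / np.sqrt(denom)
    df = denom**2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    return t, df


def _t_logsf(x, df):
    """log SF of Student t; where the direct computation underflows, the
    incomplete-beta hypergeometric series is evaluated in log space."""
    x, df = np.broadcast_arrays(
        np.asarray(x, dtype=float), np.asarray(df, dtype=float)
    )
    shape = x.shape
    x, df = np.atleast_1d(x).ravel(), np.atleast_1d(df).ravel()
    out = stats.t.logsf(x, df)
    bad = ~np.isfinite(out)
    if np.any(bad):
        # sf(x) = I_z(a, 1/2)/2 with z = df/(df+x^2), a = df/2, evaluated in
        # log space through B_z(a,b) = z^a/a * 2F1(a, 1-b; a+1; z); the
        # hypergeometric series converges geometrically for the z < 1 here
        xb, db = x[bad], df[bad]
        a = db / 2
        z = db / (db + xb**2)
        hyp = np.ones_like(z)  # k = 0 term
        poch = np.ones_like(z)  # (1/2)_k / k!
        for k in range(1, 400):
            poch *= (0.5 + k - 1) / k
            hyp += (a / (a + k)) * poch * z**k
        log_b_z = a * np.log(z) - np.log(a) + np.log(hyp)
        log_beta = (
            special.gammaln(a) + special.gammaln(0.5) - special.gammaln(a + 0.5)
        )
        out[bad] = np.log(0.5) + log_b_z - log_beta
    return out.reshape(shape)


def _z_from_t(t, df):
    """Signed normal quantile of the two-sided p; stable for extreme t.

    z = sign(t) * Phi^{-1}(1 - p/2) with p/2 = SF_t(|t|), computed in log
    space so |t| far beyond 8 still maps to a finite z.
    """
    log_half_p = _t_logsf(np.abs(t), df)
    z = -special.ndtri_exp(log_half_p)
    return np.sign(t) * z


def welch_enrichment(tc_weights, gene_set_mask) -> tuple[float, float, float]:
    """Welch t / Z / two-sided p for one TC and one gene set.

    ``gene_set_mask`` is a boolean array over the TC's genes (True = in set);
    the out-group is every other profiled gene.
    """
    w = np.asarray(tc_weights, dtype=float)
    raw = np.asarray(gene_set_mask)
    if raw.dtype == bool and raw.shape == w.shape:
        mask = raw
    else:  # integer gene indices
        mask = np.zeros(w.shape, dtype=bool)
        mask[raw.astype(int)] = True
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 genes in the set and its complement")
    a, b = w[mask], w[~mask]
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 0.0, 1.0
        raise ValueError("zero variance in both groups: Welch t undefined")
    t, df = _welch_from_stats(
        a.mean(), a.var(ddof=1), n1, b.mean(), b.var(ddof=1), n2
    )
    p = float(2 * stats.t.sf(abs(t), df))
    p = min(p, 1.0)
    z = float(_z_from_t(t, df))
    if t == 0:
        z = 0.0
    return float(t), z, p


def enrichment_table(
    tcs: TCSet, collection: GeneSetCollection, alpha: float = 0.05
) -> pd.DataFrame:
    """Score every (TC, gene set) pair; Bonferroni over the whole table.

    Returns a DataFrame with columns tc_id, set_id, welch_t, z_score,
    p_value, bonferroni_significant, n_in_set, n_out_set, sorted by
    descending |z| within TC.
    """
    gene_index = {g: i for i, g in enumerate(tcs.gene_ids)}
    p_genes = len(tcs.gene_ids)
    set_names, masks = [], []
    for name, genes in collection:
        idx = [gene_index[g] for g in genes if g in gene_index]
        m = np.zeros(p_genes, dtype=bool)
        m[idx] = True
        set_names.append(name)
        masks.append(m)
    if not set_names:
        return pd.DataFrame(
            columns=[
                "tc_id", "set_id", "welch_t", "z_score", "p_value",
                "bonferroni_significant", "n_in_set", "n_out_set",
            ]
        )
    M = np.asarray(masks)  # (n_sets, p)
    n1 = M.sum(axis=1)
    n2 = p_genes - n1
    W = tcs.weights  # (k, p)
    # group moments for all (tc, set) pairs at once
    sum_in = M @ W.T  # (n_sets, k)
    sumsq_in = M @ (W**2).T
    tot = W.sum(axis=1)
    totsq = (W**2).sum(axis=1)
    m1 = sum_in / n1[:, None]
    m2 = (tot[None, :] - sum_in) / n2[:, None]
    v1 = (sumsq_in - n1[:, None] * m1**2) / (n1[:, None] - 1)
    v2 = (totsq[None, :] - sumsq_in - n2[:, None] * m2**2) / (n2[:, None] - 1)
    v1 = np.clip(v1, 0, None)
    v2 = np.clip(v2, 0, None)
    t, df = _welch_from_stats(m1, v1, n1[:, None], m2, v2, n2[:, None])
    z = _z_from_t(t, df)
    logp = _t_logsf(np.abs(t), df) + np.log(2)
    p = np.exp(np.clip(logp, None, 0))
    n_tests = t.size
    sig = p <= alpha / n_tests
    rows = pd.DataFrame(
        {
            "tc_id": np.repeat(tcs.component_ids, len(set_names)),
            "set_id": np.tile(set_names, tcs.n_components),
            "welch_t": t.T.ravel(),
            "z_score": z.T.ravel(),
            "p_value": p.T.ravel(),
            "bonferroni_significant": sig.T.ravel(),
            "n_in_set": np.tile(n1, tcs.n_components),
            "n_out_set": np.tile(n2, tcs.n_components),
        }
    )
    rows["abs_z"] = rows["z_score"].abs()
    rows = (
        rows.sort_values(["tc_id", "abs_z"], ascending=[True, False])
        .drop(columns="abs_z")
        .reset_index(drop=True)
    )
    return rows


def important_genes(
    tcs: TCSet, component_id: str, threshold: float = 3.0
) -> list:
    """Genes with |standardized weight| >= threshold, by descending |weight|."""
    k = tcs.component_ids.index(component_id)
    w = tcs.weights[k]
    idx = np.where(np.abs(w) >= threshold)[0]
    idx = idx[np.argsort(-np.abs(w[idx]), kind="stable")]
    return [tcs.gene_ids[i] for i in idx]


def activity_covariate_correlation(
    mixing: MixingMatrix, covariate
) -> pd.DataFrame:
    """Spearman rank correlation of each TC's activity with a continuous
    covariate; missing covariate values are pairwise-dropped."""
    cov = np.asarray(covariate, dtype=float)
    if cov.shape != (mixing.n_samples,):
        raise ValueError("covariate must have one value per sample")
    ok = np.isfinite(cov)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing paired samples")
    if np.nanstd(cov[ok]) == 0:
        raise ValueError("constant covariate: Spearman correlation undefined")
    out = []
    for k, cid in enumerate(mixing.component_ids):
        rho, p = stats.spearmanr(mixing.activities[k, ok], cov[ok])
        out.append({"tc_id": cid, "rho": float(rho), "p_value": float(p)})
    return pd.DataFrame(out)
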