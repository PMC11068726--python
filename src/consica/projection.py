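"""Projection of consensus TCs onto independent expression profiles.

Cross-dataset activity is the least-squares solution of expression against
the TC weight matrix on the intersected gene space (weights re-standardized
on the intersection).  Because every TC weight vector has zero mean across
genes, the projection is invariant to per-sample additive offsets and a
zero-variance profile maps to exactly zero activity.

Significance of a TC's activity in a spot/cell is assessed against a
permutation null that shuffles the gene labels of that TC's weight vector
and recomputes the projection; the single-cell variant additionally fits a
Johnson SU distribution to the null so activities can be normalized to a
common scale before the p-value computation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, MixingMatrix, SpatialProfile, TCSet

__all__ = [
    "ComponentMatch",
    "project",
    "match_components",
    "permutation_activity_significance",
    "single_cell_activity",
]

logger = logging.getLogger(__name__)


@dataclass
class ComponentMatch:
    primary_id: str
    secondary_id: str
    r: float
    robust: bool


def _intersect(tcs: TCSet, X: ExpressionMatrix, min_overlap: float):
    shared = [g for g in tcs.gene_ids if g in set(X.gene_ids)]
    frac = len(shared) / len(tcs.gene_ids)
    if frac < min_overlap:
        raise ValueError(
            f"gene overlap {len(shared)}/{len(tcs.gene_ids)} "
            f"({frac:.1%}) below required {min_overlap:.0%}"
        )
    gt = {g: i for i, g in enumerate(tcs.gene_ids)}
    gx = {g: i for i, g in enumerate(X.gene_ids)}
    S = tcs.weights[:, [gt[g] for g in shared]]
    S = (S - S.mean(axis=1, keepdims=True)) / S.std(axis=1, keepdims=True)
    V = X.values[[gx[g] for g in shared]]
    logger.info("projection: %d/%d TC genes present (%.1f%%)", len(shared), len(tcs.gene_ids), 100 * frac)
    return S, V


def project(
    tcs: TCSet, X_new: ExpressionMatrix, min_overlap: float = 0.5
) -> MixingMatrix:
    """Least-squares TC activities in a new dataset on shared genes."""
    S, V = _intersect(tcs, X_new, min_overlap)
    G = S @ S.T
    A = np.linalg.solve(G, S @ V)
    zero = V.std(axis=0) == 0
    A[:, zero] = 0.0
    return MixingMatrix(tcs.component_ids, X_new.sample_ids, A)


def match_components(
    primary: TCSet, secondary: TCSet, r_threshold: float = 0.5
) -> list[ComponentMatch]:
    """Greedy one-to-one matching of TCs by |Pearson r| of gene weights.

    Pairs are claimed in descending |r|; matches exceeding the threshold are
    flagged robust.  Unmatched components (when counts differ) are reported
    in the log.
    """
    shared = [g for g in primary.gene_ids if g in set(secondary.gene_ids)]
    if not shared:
        raise ValueError("no shared genes between TC sets")
    gp = {g: i for i, g in enumerate(primary.gene_ids)}
    gs = {g: i for i, g in enumerate(secondary.gene_ids)}
    P = primary.weights[:, [gp[g] for g in shared]]
    S = secondary.weights[:, [gs[g] for g in shared]]
    P = (P - P.mean(axis=1, keepdims=True)) / P.std(axis=1, keepdims=True)
    S = (S - S.mean(axis=1, keepdims=True)) / S.std(axis=1, keepdims=True)
    R = (P @ S.T) / len(shared)
    order = np.dstack(np.unravel_index(np.argsort(-np.abs(R), axis=None), R.shape))[0]
    taken_p: set = set()
    taken_s: set = set()
    matches = []
    for i, j in order:
        if i in taken_p or j in taken_s:
            continue
        taken_p.add(i)
        taken_s.add(j)
        r = float(R[i, j])
        matches.append(
            ComponentMatch(
                primary_id=primary.component_ids[i],
                secondary_id=secondary.component_ids[j],
                r=r,
                robust=abs(r) > r_threshold,
            )
        )
        if len(matches) == min(R.shape):
            break
    unmatched = [
        primary.component_ids[i] for i in range(primary.n_components) if i not in taken_p
    ] + [
        secondary.component_ids[j] for j in range(secondary.n_components) if j not in taken_s
    ]
    if unmatched:
        logger.info("match_components: %d unmatched TCs: %s", len(unmatched), unmatched)
    return matches


def _null_activities(
    S: np.ndarray, V: np.ndarray, tc_index: int, n_perm: int, rng
) -> np.ndarray:
    """Null activities of one TC: permute its weight vector's gene labels,
    re-solve the least-squares projection, keep that TC's row.

    Batched over permutations: only row ``tc_index`` of the Gram matrix and
    of S @ V changes per permutation.
    """
    k, p = S.shape
    n = V.shape[1]
    G0 = S @ S.T
    SV0 = S @ V
    perms = np.array([rng.permutation(p) for _ in range(n_perm)])
    Wp = S[tc_index][perms]  # (B, p)
    cross = Wp @ S.T  # (B, k): permuted row vs all rows
    cross[:, tc_index] = (Wp * Wp).sum(axis=1)
    rhs_row = Wp @ V  # (B, n)
    Gb = np.broadcast_to(G0, (n_perm, k, k)).copy()
    Gb[:, tc_index, :] = cross
    Gb[:, :, tc_index] = cross
    rhs = np.broadcast_to(SV0, (n_perm, k, n)).copy()
    rhs[:, tc_index, :] = rhs_row
    sol = np.linalg.solve(Gb, rhs)  # (B, k, n)
    return sol[:, tc_index, :]  # (B, n)


def permutation_activity_significance(
    tcs: TCSet,
    profile: SpatialProfile | ExpressionMatrix,
    n_perm: int = 5000,
    seed: int = 0,
    min_overlap: float = 0.5,
    batch: int = 1000,
) -> pd.DataFrame:
    """Per-(unit, TC) activity with empirical permutation p and -log10 p.

    The null shuffles the gene labels of the TC's weight vector; the
    two-sided empirical p uses the add-one correction, so the smallest
    achievable p is 1/(n_perm+1).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives very coarse p-values", stacklevel=2)
    if isinstance(profile, SpatialProfile):
        X = profile.expression
        coords = profile.coords.set_index("spot_id")
    else:
        X = profile
        coords = None
    # tolerate all-zero weight rows (no standardization possible)
    sds = tcs.weights.std(axis=1)
    safe = TCSet(
        tcs.component_ids,
        tcs.gene_ids,
        np.where(sds[:, None] > 0, tcs.weights, 0.0),
        tcs.credibility,
    )
    shared = [g for g in safe.gene_ids if g in set(X.gene_ids)]
    frac = len(shared) / len(safe.gene_ids)
    if frac < min_overlap:
        raise ValueError(f"gene overlap {frac:.1%} below required {min_overlap:.0%}")
    gt = {g: i for i, g in enumerate(safe.gene_ids)}
    gx = {g: i for i, g in enumerate(X.gene_ids)}
    S = safe.weights[:, [gt[g] for g in shared]]
    live = S.std(axis=1) > 0
    S[live] = (S[live] - S[live].mean(axis=1, keepdims=True)) / S[live].std(
        axis=1, keepdims=True
    )
    V = X.values[[gx[g] for g in shared]]
    k, n = len(safe.component_ids), X.n_samples

    if live.any():
        Gl = S[live] @ S[live].T
        A = np.zeros((k, n))
        A[live] = np.linalg.solve(Gl, S[live] @ V)
    else:
        A = np.zeros((k, n))

    rng = np.random.default_rng(seed)
    rows = []
    Sl = S[live]
    live_idx = {orig: pos for pos, orig in enumerate(np.where(live)[0])}
    for t, tc in enumerate(safe.component_ids):
        obs = A[t]
        if not live[t]:
            p = np.ones(n)
        else:
            exceed = np.zeros(n)
            done = 0
            while done < n_perm:
                b = min(batch, n_perm - done)
                null = _null_activities(Sl, V, live_idx[t], b, rng)
                exceed += (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)
                done += b
            p = (1 + exceed) / (n_perm + 1)
        for u, unit in enumerate(X.sample_ids):
            row = {
                "unit_id": unit,
                "tc_id": tc,
                "activity": float(obs[u]),
                "p_value": float(p[u]),
                "neg_log10_p": float(-np.log10(p[u])),
            }
            if coords is not None:
                row["row"] = int(coords.loc[unit, "row"])
                row["col"] = int(coords.loc[unit, "col"])
            rows.append(row)
    return pd.DataFrame(rows)


def single_cell_activity(
    tcs: TCSet,
    sc_matrix: ExpressionMatrix,
    cell_labels,
    n_perm: int = 3000,
    subsample_fraction: float = 0.1,
    seed: int = 0,
    min_overlap: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TC activities per (subsampled) cell with Johnson-normalized p-values.

    A Johnson SU distribution is fitted to each TC's permutation null and
    both observed and null activities are mapped through its CDF to a
    standard-normal scale; the reported p is two-sided on that scale.
    Returns ``(per_cell, per_label_summary)``; labels with fewer than 3
    cells after subsampling are excluded with a warning.
    """
    labels = pd.Series(list(cell_labels), index=sc_matrix.sample_ids)
    if labels.isna().any():
        raise ValueError("cell labels must cover all cells")
    rng = np.random.default_rng(seed)
    n_cells = sc_matrix.n_samples
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must lie in (0, 1]")
    if subsample_fraction < 1:
        take = max(1, int(round(subsample_fraction * n_cells)))
        keep = np.sort(rng.choice(n_cells, size=take, replace=False))
        ids = [sc_matrix.sample_ids[i] for i in keep]
        X = ExpressionMatrix(sc_matrix.gene_ids, ids, sc_matrix.values[:, keep])
    else:
        X = sc_matrix
    labels = labels.loc[X.sample_ids]

    S, V = _intersect(tcs, X, min_overlap)
    k, n = S.shape[0], X.n_samples
    A = np.linalg.solve(S @ S.T, S @ V)

    per_cell = []
    for t, tc in enumerate(tcs.component_ids):
        null = _null_activities(S, V, t, n_perm, rng).ravel()
        # Johnson SU normalization of activities against the null
        try:
            params = stats.johnsonsu.fit(null)
            znorm = stats.norm.ppf(
                np.clip(stats.johnsonsu.cdf(A[t], *params), 1e-12, 1 - 1e-12)
            )
        except Exception:  # degenerate null: fall back to z-scoring
            mu, sd = null.mean(), null.std() or 1.0
            znorm = (A[t] - mu) / sd
        p = 2 * stats.norm.sf(np.abs(znorm))
        per_cell.append(
            pd.DataFrame(
                {
                    "cell_id": X.sample_ids,
                    "label": labels.to_numpy(),
                    "tc_id": tc,
                    "activity": A[t],
                    "normalized_activity": znorm,
                    "p_value": np.clip(p, np.finfo(float).tiny, 1.0),
                }
            )
        )
    per_cell = pd.concat(per_cell, ignore_index=True)

    counts = labels.value_counts()
    small = counts[counts < 3].index.tolist()
    if small:
        warnings.warn(f"excluding labels with <3 cells: {small}", stacklevel=2)
        per_cell = per_cell[~per_cell["label"].isin(small)].reset_index(drop=True)
    summary = (
        per_cell.groupby(["tc_id", "label"])["activity"]
        .describe(percentiles=[0.25, 0.5, 0.75])[["25%", "50%", "75%", "count"]]
        .rename(columns={"25%": "q1", "50%": "median", "75%": "q3", "count": "n_cells"})
        .reset_index()
    )
    return per_cell, summary
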