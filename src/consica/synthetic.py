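"""Synthetic ground-truth generators.

The generators invert the linear mixing model the decomposition assumes:
sparse, super-Gaussian gene-weight sources S (components x genes), normal
activities A (components x samples), expression X = A^T S + Gaussian noise.
Survival follows a proportional-hazards model driven by chosen source
activities with independent exponential censoring, and the clinical
covariates are drawn from frequencies matching a typical early colorectal
cancer cohort.  Gene sets are planted inside the sources' active genes so
enrichment has a known positive control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    MixingMatrix,
    SpatialProfile,
    SurvivalTable,
    TCSet,
)

__all__ = [
    "generate_sources",
    "generate_expression",
    "generate_survival",
    "generate_gene_sets",
    "generate_spatial_profile",
    "DEFAULT_COVARIATE_FREQUENCIES",
]

# Frequencies mirroring the clinical mix of a large early-CRC DFS cohort
# (about half the molecular annotations unknown, stage 2/3 dominated).
DEFAULT_COVARIATE_FREQUENCIES = {
    "sex": {"male": 0.53, "female": 0.47},
    "msi": {"msi_high": 0.09, "mss": 0.43, "unknown": 0.48},
    "braf": {"mutated": 0.04, "wildtype": 0.43, "unknown": 0.53},
    "kras": {"mutated": 0.19, "wildtype": 0.32, "unknown": 0.49},
    "location": {"proximal": 0.36, "distal": 0.51, "unknown": 0.13},
    "stage": {"stage_lt2": 0.09, "stage_2": 0.55, "stage_3": 0.35, "unknown": 0.01},
    "adjuvant": {"yes": 0.25, "no": 0.47, "unknown": 0.28},
}

#: Laplace scale for active gene weights; heavy-tailed so that after
#: per-component standardization the active genes dominate the |weight| >= 3
#: tail, as ICA's non-Gaussianity assumption requires.
ACTIVE_WEIGHT_SCALE = 3.0
#: SD of the near-zero background weights of inactive genes.
BACKGROUND_WEIGHT_SD = 0.05


def _gene_ids(p: int) -> list:
    return [f"G{i:05d}" for i in range(p)]


def _sample_ids(n: int, prefix: str = "S") -> list:
    return [f"{prefix}{i:05d}" for i in range(n)]


def generate_sources(
    n_genes: int, n_components: int, active_fraction: float, seed: int
) -> TCSet:
    """Sparse super-Gaussian gene-weight sources, standardized per component.

    Each component has ``round(active_fraction * n_genes)`` active genes with
    Laplace-distributed weights and near-zero Gaussian background elsewhere.
    Active sets are disjoint whenever capacity allows, otherwise overlap is
    minimized by drawing without replacement from a reshuffled pool.
    """
    if n_components >= n_genes:
        raise ValueError("n_components must be smaller than n_genes")
    if not 0 < active_fraction < 1:
        raise ValueError("active_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_active = int(round(active_fraction * n_genes))
    if n_active < 1:
        raise ValueError("active_fraction too small: no active genes")

    pool = list(rng.permutation(n_genes))
    active_sets = []
    for _ in range(n_components):
        if len(pool) < n_active:  # capacity exhausted: refill, minimizing reuse
            pool = list(rng.permutation(n_genes))
        active_sets.append(np.array([pool.pop() for _ in range(n_active)]))

    W = rng.normal(0.0, BACKGROUND_WEIGHT_SD, size=(n_components, n_genes))
    for k, idx in enumerate(active_sets):
        W[k, idx] = rng.laplace(0.0, ACTIVE_WEIGHT_SCALE, size=n_active)
    W = (W - W.mean(axis=1, keepdims=True)) / W.std(axis=1, keepdims=True)
    return TCSet(
        component_ids=[f"TC{k + 1}" for k in range(n_components)],
        gene_ids=_gene_ids(n_genes),
        weights=W,
        credibility=np.ones(n_components),
    )


def generate_expression(
    truth: TCSet,
    n_samples: int,
    activity_sd: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[ExpressionMatrix, MixingMatrix]:
    """Mix sources into expression: X = A^T S + N(0, noise_sd^2).

    Activities are i.i.d. normal(0, activity_sd^2) so that source activity is
    on a z-like scale.  ``noise_sd=0`` reproduces the inner product exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    k = truth.n_components
    if n_samples < 2 * k:
        raise ValueError("need n_samples >= 2 x components")
    rng = np.random.default_rng(seed)
    A = rng.normal(0.0, activity_sd, size=(k, n_samples))
    X = truth.weights.T @ A
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    sample_ids = _sample_ids(n_samples)
    return (
        ExpressionMatrix(truth.gene_ids, sample_ids, X),
        MixingMatrix(truth.component_ids, sample_ids, A),
    )


def generate_survival(
    mixing: MixingMatrix,
    hazard_betas,
    baseline_rate: float = 0.02,
    censor_rate: float = 0.01,
    seed: int = 0,
    covariate_frequencies: dict | None = None,
) -> SurvivalTable:
    """Proportional-hazards DFS times driven by source activities.

    Event time ~ Exp(rate = baseline_rate * exp(beta . activity)); censoring
    time ~ Exp(censor_rate) independently; observed time is the minimum and
    the event flag marks which came first.  Categorical clinical covariates
    are sampled independently from the configured frequencies.
    """
    hazard_betas = np.asarray(hazard_betas, dtype=float)
    if hazard_betas.shape != (mixing.n_components,):
        raise ValueError("hazard_betas length must equal the number of components")
    if baseline_rate <= 0 or censor_rate <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    n = mixing.n_samples
    linpred = hazard_betas @ mixing.activities
    event_t = rng.exponential(1.0, size=n) / (baseline_rate * np.exp(linpred))
    censor_t = rng.exponential(1.0 / censor_rate, size=n)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)

    freqs = covariate_frequencies or DEFAULT_COVARIATE_FREQUENCIES
    cols = {"sample_id": mixing.sample_ids, "time": time, "event": event}
    for name, levels in freqs.items():
        labels = list(levels)
        probs = np.array([levels[lab] for lab in labels], dtype=float)
        probs = probs / probs.sum()
        cols[name] = rng.choice(labels, size=n, p=probs)
    return SurvivalTable(pd.DataFrame(cols))


def generate_gene_sets(
    truth: TCSet,
    n_null_sets: int,
    set_size_range: tuple[int, int] = (10, 100),
    planted_per_component: int = 1,
    seed: int = 0,
) -> GeneSetCollection:
    """Planted (enrichment-positive) and null gene sets within [10, 500].

    Planted sets are *directional*: drawn from one tail of a component's
    active genes (even set index -> positive tail, odd -> negative), since
    the mean-shift enrichment statistic cannot see a two-tailed set whose
    heavy weights cancel.  Sets are padded with random genes up to the
    minimum size; null sets are uniform draws from the gene universe.
    """
    lo, hi = set_size_range
    if not (10 <= lo <= hi <= 500):
        raise ValueError("set_size_range must satisfy 10 <= min <= max <= 500")
    rng = np.random.default_rng(seed)
    genes = np.array(truth.gene_ids)
    p = len(genes)
    sets: dict[str, list] = {}
    for k, cid in enumerate(truth.component_ids):
        w = truth.weights[k]
        for j in range(planted_per_component):
            tail = w if j % 2 == 0 else -w
            # active tail genes of the standardized weights
            active = np.where(tail >= 3.0)[0]
            active = active[np.argsort(-tail[active], kind="stable")]
            members = list(active[:hi])
            while len(members) < lo:
                extra = int(rng.integers(0, p))
                if extra not in members:
                    members.append(extra)
            sets[f"planted_{cid}_{j}"] = list(genes[members])
    for j in range(n_null_sets):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(p, size=size, replace=False)
        sets[f"null_{j}"] = list(genes[idx])
    return GeneSetCollection("synthetic", sets)


def generate_spatial_profile(
    truth: TCSet,
    grid: tuple[int, int],
    region_mask: np.ndarray,
    boosted_component: str,
    boost: float,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SpatialProfile:
    """Grid of spots with one component's activity boosted inside a region.

    The boosted component's activity is ``boost`` inside the mask and 0
    outside; all other components have standard-normal activities per spot.
    """
    rows, cols = grid
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != (rows, cols):
        raise ValueError("region_mask dimensions must match the grid")
    if not region_mask.any():
        raise ValueError("region mask is empty")
    if boosted_component not in truth.component_ids:
        raise ValueError(f"unknown component {boosted_component!r}")
    rng = np.random.default_rng(seed)
    n_spots = rows * cols
    k = truth.n_components
    A = rng.normal(0.0, 1.0, size=(k, n_spots))
    b = truth.component_ids.index(boosted_component)
    A[b] = np.where(region_mask.ravel(), float(boost), 0.0)
    X = truth.weights.T @ A
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    spot_ids = [f"spot_{r}_{c}" for r in range(rows) for c in range(cols)]
    coords = pd.DataFrame(
        {
            "spot_id": spot_ids,
            "row": np.repeat(np.arange(rows), cols),
            "col": np.tile(np.arange(cols), rows),
        }
    )
    return SpatialProfile(ExpressionMatrix(truth.gene_ids, spot_ids, X), coords)
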