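"""In-memory containers shared by every pipeline stage.

All matrices are plain :class:`numpy.ndarray` with explicit identifier lists,
following the gene x sample orientation conventional for bulk expression
data.  Validation happens at construction time so downstream stages can
assume the invariants (unique identifiers, matching dimensions, finite
values) without re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TCSet",
    "MixingMatrix",
    "SurvivalTable",
    "GeneSetCollection",
    "SyntheticTruth",
    "SpatialProfile",
]


def _check_unique(ids, what: str) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} must be unique")
    return ids


@dataclass
class ExpressionMatrix:
    """Log-scale expression values for ``genes x samples``."""

    gene_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.gene_ids = _check_unique(self.gene_ids, "gene_ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample_ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no missing values)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class TCSet:
    """Transcriptional components: per-gene weight vectors.

    Each component's weights are standardized to mean 0 / SD 1 across genes,
    so the |weight| >= 3 "important gene" rule has a z-like reading.  The
    credibility index is the fraction of ICA runs whose components joined the
    consensus cluster.
    """

    component_ids: list
    gene_ids: list
    weights: np.ndarray
    credibility: np.ndarray

    def __post_init__(self):
        self.component_ids = _check_unique(self.component_ids, "component_ids")
        self.gene_ids = _check_unique(self.gene_ids, "gene_ids")
        self.weights = np.asarray(self.weights, dtype=float)
        self.credibility = np.asarray(self.credibility, dtype=float)
        k, p = len(self.component_ids), len(self.gene_ids)
        if self.weights.shape != (k, p):
            raise ValueError(f"weights shape {self.weights.shape} != ({k}, {p})")
        if self.credibility.shape != (k,):
            raise ValueError("credibility must have one entry per component")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if np.any(self.credibility <= 0) or np.any(self.credibility > 1):
            raise ValueError("credibility must lie in (0, 1]")

    @property
    def n_components(self) -> int:
        return len(self.component_ids)

    def standardized(self) -> "TCSet":
        w = self.weights
        mu = w.mean(axis=1, keepdims=True)
        sd = w.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("cannot standardize a constant component")
        return TCSet(self.component_ids, self.gene_ids, (w - mu) / sd, self.credibility)


@dataclass
class MixingMatrix:
    """Component activities per sample (``components x samples``)."""

    component_ids: list
    sample_ids: list
    activities: np.ndarray

    def __post_init__(self):
        self.component_ids = _check_unique(self.component_ids, "component_ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample_ids")
        self.activities = np.asarray(self.activities, dtype=float)
        shape = (len(self.component_ids), len(self.sample_ids))
        if self.activities.shape != shape:
            raise ValueError(f"activities shape {self.activities.shape} != {shape}")
        if not np.all(np.isfinite(self.activities)):
            raise ValueError("activities must be finite")

    @property
    def n_components(self) -> int:
        return len(self.component_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.activities, index=self.component_ids, columns=self.sample_ids
        )


#: categorical clinical covariates carried by a SurvivalTable
CLINICAL_COVARIATES = (
    "sex",
    "msi",
    "braf",
    "kras",
    "location",
    "stage",
    "adjuvant",
)


@dataclass
class SurvivalTable:
    """Disease-free survival outcomes plus clinical covariates.

    ``data`` holds one row per sample with columns ``sample_id``, ``time``
    (months, strictly positive), ``event`` (0/1) and the categorical
    covariates (strings; ``"unknown"`` is a legitimate level).  Additional
    continuous covariates (e.g. microenvironment scores) may be present.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        for col in ("sample_id", "time", "event"):
            if col not in df.columns:
                raise ValueError(f"SurvivalTable missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in SurvivalTable")
        if (df["time"] <= 0).any():
            raise ValueError("survival times must be strictly positive")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return list(self.data["sample_id"])

    def aligned_to(self, sample_ids) -> "SurvivalTable":
        """Reorder rows to ``sample_ids`` (which must all be present)."""
        df = self.data.set_index("sample_id")
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise ValueError(f"samples missing from SurvivalTable: {missing[:5]}")
        return SurvivalTable(df.loc[list(sample_ids)].reset_index())


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique set names, unique members."""

    name: str
    sets: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for set_name, genes in self.sets.items():
            seen: dict = dict.fromkeys(genes)
            clean[str(set_name)] = list(seen)
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    sources: TCSet
    mixing: MixingMatrix
    hazard_betas: np.ndarray
    planted_sets: list
    subgroup_labels: np.ndarray
    seed: int

    def __post_init__(self):
        self.hazard_betas = np.asarray(self.hazard_betas, dtype=float)
        if not np.all(np.isfinite(self.hazard_betas)):
            raise ValueError("hazard betas must be finite")


@dataclass
class SpatialProfile:
    """Expression over grid spots plus their (row, col) coordinates."""

    expression: ExpressionMatrix
    coords: pd.DataFrame  # columns: spot_id, row, col

    def __post_init__(self):
        if list(self.coords["spot_id"]) != self.expression.sample_ids:
            raise ValueError("coords must list the same spots as the expression matrix")
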