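"""Core in-memory containers for the assembly pipeline.

The canonical orientation of a community matrix is samples x taxa
(rows = samples), matching the ecological convention of a "community
data matrix".  Sample and taxon identifiers are opaque, case-sensitive
strings; ASV hashes must survive untouched.

Distance matrices are represented with :class:`skbio.DistanceMatrix`,
which already enforces symmetry, a zero diagonal and id alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SampleMetadata",
    "EnvironmentalMatrix",
    "PairwiseResult",
    "ProcessSummary",
    "PROCESSES",
    "ACCESS_CLASSES",
]

#: The five assembly-process labels of the two-stage classifier.
PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "no_dominant_process",
)

#: Closed four-level set of human-access categories for a lake.
ACCESS_CLASSES = ("no_access", "walking", "private", "public")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class CountTable:
    """Integer abundance matrix, samples x taxa.

    Parameters
    ----------
    sample_ids : list of str
        Row identifiers (one per sample).
    taxon_ids : list of str
        Column identifiers (one per taxon/ASV).
    counts : ndarray of int, shape (n_samples, n_taxa)
        Non-negative read counts.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.taxon_ids)} taxa)"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integer-valued")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")
        self.counts = counts.astype(np.int64, copy=False)

    # -- convenience -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_index(sample_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        keep = list(sample_ids)
        idx = [self.sample_index(s) for s in keep]
        return CountTable(keep, list(self.taxon_ids), self.counts[idx])

    def select_taxa(self, taxon_ids: Iterable[str]) -> "CountTable":
        keep = list(taxon_ids)
        pos = {t: j for j, t in enumerate(self.taxon_ids)}
        idx = [pos[t] for t in keep]
        return CountTable(list(self.sample_ids), keep, self.counts[:, idx])

    def relative_abundance(self) -> np.ndarray:
        """Row-normalised relative abundances (rows with zero total stay zero)."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(totals > 0, self.counts / totals, 0.0)
        return rel


@dataclass
class SampleMetadata:
    """Per-lake metadata: coordinates, human-access class and covariates."""

    sample_id: str
    latitude: float
    longitude: float
    access_class: str
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.access_class not in ACCESS_CLASSES:
            raise ValueError(
                f"access_class {self.access_class!r} not in {ACCESS_CLASSES}"
            )
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass
class EnvironmentalMatrix:
    """Samples x continuous variables, with an explicit missing-value mask.

    ``values`` is float with NaN at missing cells; ``mask`` is True where
    a value is missing.
    """

    sample_ids: list[str]
    variables: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variables = [str(v) for v in self.variables]
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.sample_ids), len(self.variables)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.variables)} variables)"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.variables, "variable")
        self.values = values

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask, True where the value is missing."""
        return np.isnan(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.variables)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EnvironmentalMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def select_variables(self, variables: Iterable[str]) -> "EnvironmentalMatrix":
        keep = list(variables)
        pos = {v: j for j, v in enumerate(self.variables)}
        idx = [pos[v] for v in keep]
        return EnvironmentalMatrix(list(self.sample_ids), keep, self.values[:, idx])


@dataclass
class PairwiseResult:
    """Per lake-pair record of the two-stage assembly classification.

    ``rc_bray`` is None for pairs resolved at the phylogenetic stage
    (|betaNTI| > 2); ``bnti`` is NaN for degenerate null distributions
    (zero standard deviation), in which case the pair falls through to
    the compositional stage.
    """

    sample_a: str
    sample_b: str
    bmntd: float
    bnti: float
    bray_curtis: float
    rc_bray: float | None
    process: str

    def __post_init__(self) -> None:
        if self.process not in PROCESSES:
            raise ValueError(f"unknown process label {self.process!r}")


@dataclass
class ProcessSummary:
    """Component-level percentage of pairs assigned to each process."""

    component: str
    n_pairs: int
    percentages: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(PROCESSES) - set(self.percentages)
        if missing:
            raise ValueError(f"missing process labels in summary: {sorted(missing)}")
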