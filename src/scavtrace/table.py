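"""Sample-by-ASV count tables and the shared presence/absence filters.

The pipeline's unit of observation is an amplicon sequence variant (ASV):
an exact, denoised 16S rRNA fragment.  Counts are raw sequence read counts
per sample; all biomarker logic downstream is presence/absence, where
presence means a count of at least one after filtering.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DayLabel",
    "FRESH_WINDOW",
    "DECAYED_WINDOW",
    "SampleType",
    "AsvTable",
    "remove_control_asvs",
    "filter_singletons",
    "filter_low_depth",
    "total_sum_scale",
]


class DayLabel(str, enum.Enum):
    """Sampling day of the decomposition series.

    Day 0 in the lab and day 0 in the field are distinct control points that
    both precede visible decay; days 2 onward are the decayed phase.
    """

    D0_LAB = "D0_LAB"
    D0_FIELD = "D0_FIELD"
    D1 = "D1"
    D2 = "D2"
    D4 = "D4"
    D7 = "D7"
    D11 = "D11"

    @property
    def order(self) -> int:
        return _DAY_ORDER[self]


_DAY_ORDER = {
    DayLabel.D0_LAB: 0,
    DayLabel.D0_FIELD: 1,
    DayLabel.D1: 2,
    DayLabel.D2: 3,
    DayLabel.D4: 4,
    DayLabel.D7: 5,
    DayLabel.D11: 6,
}

#: Days on which tissue is considered fresh (pre-decay).
FRESH_WINDOW = frozenset({DayLabel.D0_LAB, DayLabel.D0_FIELD, DayLabel.D1})
#: Days on which tissue is considered decayed.
DECAYED_WINDOW = frozenset({DayLabel.D2, DayLabel.D4, DayLabel.D7, DayLabel.D11})


class SampleType(str, enum.Enum):
    CHICKEN_TISSUE = "chicken_tissue"
    RAT_FECES = "rat_feces"
    RAT_STOMACH = "rat_stomach"
    NEGATIVE_CONTROL = "negative_control"


METADATA_COLUMNS = ("sample_type", "site", "day", "is_control")


@dataclass
class AsvTable:
    """A samples x ASVs integer count matrix with per-sample metadata.

    ``counts`` is a DataFrame indexed by sample id with ASV ids as columns.
    ``metadata`` is indexed by the same sample ids and carries at least
    ``sample_type``, ``site``, ``day`` (may be NA) and ``is_control``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.metadata = self.metadata.copy()
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate ASV ids: {dups}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise ValueError("counts must be finite integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            raise ValueError("counts must be non-negative")
        missing = self.counts.index.difference(self.metadata.index)
        if len(missing):
            raise ValueError(f"samples lacking metadata: {missing.tolist()}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        # keep metadata aligned to (and restricted to) the count matrix rows
        self.metadata = self.metadata.loc[self.counts.index]

    # -- accessors -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        """Per-sample read depth (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence view (count >= 1)."""
        return self.counts >= 1

    def day_of(self, sample_id: str) -> DayLabel | None:
        raw = self.metadata.at[sample_id, "day"]
        if pd.isna(raw) or raw == "":
            return None
        return DayLabel(raw) if not isinstance(raw, DayLabel) else raw

    def subset_samples(self, sample_ids) -> "AsvTable":
        sample_ids = list(sample_ids)
        return AsvTable(self.counts.loc[sample_ids], self.metadata.loc[sample_ids])

    def subset_asvs(self, asv_ids) -> "AsvTable":
        asv_ids = list(asv_ids)
        return AsvTable(self.counts.loc[:, asv_ids], self.metadata)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AsvTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.metadata.loc[
            :, list(METADATA_COLUMNS)
        ].equals(other.metadata.loc[:, list(METADATA_COLUMNS)])


# ---------------------------------------------------------------------------
# filters


def remove_control_asvs(table: AsvTable) -> AsvTable:
    """Drop every ASV seen in any negative control, then drop the controls.

    Any ASV with a nonzero count in any negative-control sample is treated
    as a laboratory contaminant and removed from all samples.  This is the
    strictest defensible contaminant rule; it never removes ASVs absent
    from the controls.  With no control samples the table is returned
    unchanged.
    """
    is_control = table.metadata["is_control"].astype(bool)
    if not is_control.any():
        return table
    control_ids = table.metadata.index[is_control]
    contaminants = table.counts.loc[control_ids].sum(axis=0) > 0
    keep_asvs = table.counts.columns[~contaminants]
    keep_samples = table.metadata.index[~is_control]
    return AsvTable(
        table.counts.loc[keep_samples, keep_asvs], table.metadata.loc[keep_samples]
    )


def filter_singletons(table: AsvTable) -> AsvTable:
    """Retain ASVs observed (count >= 1) in at least two samples."""
    prevalence = (table.counts >= 1).sum(axis=0)
    keep = table.counts.columns[prevalence >= 2]
    return AsvTable(table.counts.loc[:, keep], table.metadata)


def filter_low_depth(
    table: AsvTable, min_depth: int
) -> tuple[AsvTable, list[str]]:
    """Drop samples with read depth below ``min_depth``.

    Returns the filtered table and the list of dropped sample ids.  Raises
    if every sample would be removed.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    depths = table.depths
    keep = depths.index[depths >= min_depth]
    dropped = depths.index.difference(keep).tolist()
    if len(keep) == 0:
        raise ValueError(
            f"min_depth={min_depth} removes all {table.n_samples} samples "
            f"(max depth {int(depths.max())})"
        )
    if not dropped:
        return table, []
    return table.subset_samples(keep), dropped


def total_sum_scale(table: AsvTable) -> pd.DataFrame:
    """Convert counts to within-sample proportions (total sum scaling).

    Every row of the result sums to 1; zero counts stay zero.  Zero-depth
    samples are rejected — remove them first with :func:`filter_low_depth`.
    """
    depths = table.depths
    zero = depths.index[depths == 0].tolist()
    if zero:
        raise ValueError(
            f"zero-depth samples {zero}: apply filter_low_depth before scaling"
        )
    return table.counts.div(depths, axis=0)
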