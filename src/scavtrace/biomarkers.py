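"""Fresh- vs decayed-tissue biomarker discovery from a decomposition series.

Tissue samples are pooled by sampling day across replicate sites, and each
ASV's day-occupancy set is compared to two disjoint windows: the fresh
window (day 0 lab, day 0 field, day 1) and the decayed window (days 2, 4,
7, 11).  An ASV confined to one window is a biomarker for that decay
state; an ASV observed in both windows is not a biomarker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .table import DECAYED_WINDOW, FRESH_WINDOW, AsvTable, DayLabel

__all__ = [
    "OccupancyProfile",
    "BiomarkerSet",
    "pool_presence_by_day",
    "classify_biomarkers",
    "biomarker_summary",
]

#: day -> occupancy set, per ASV
OccupancyProfile = dict[str, frozenset[DayLabel]]


@dataclass
class BiomarkerSet:
    """Classified biomarkers and the earliest day each was detected.

    ``first_detection_day`` follows the ordering D0_LAB < D0_FIELD < D1 <
    D2 < D4 < D7 < D11; an ASV detected only in the lab controls reports
    D0_LAB and is flagged in ``lab_only``.
    """

    fresh_ids: frozenset[str]
    decayed_ids: frozenset[str]
    first_detection_day: dict[str, DayLabel] = field(default_factory=dict)
    occupancy: OccupancyProfile = field(default_factory=dict)
    lab_only: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = self.fresh_ids & self.decayed_ids
        if overlap:
            raise ValueError(f"ASVs classified as both fresh and decayed: {overlap}")
        for asv_id in self.fresh_ids:
            occ = self.occupancy.get(asv_id)
            if occ is not None and not occ <= FRESH_WINDOW:
                raise ValueError(f"fresh biomarker {asv_id} occupies {occ}")
        for asv_id in self.decayed_ids:
            occ = self.occupancy.get(asv_id)
            if occ is not None and not occ <= DECAYED_WINDOW:
                raise ValueError(f"decayed biomarker {asv_id} occupies {occ}")

    @property
    def all_ids(self) -> frozenset[str]:
        return self.fresh_ids | self.decayed_ids


def pool_presence_by_day(table: AsvTable) -> OccupancyProfile:
    """Merge samples by day: an ASV occupies a day if present at any site.

    The table should already be restricted to tissue samples, control
    cleaned and singleton filtered.  Samples without a day label are an
    error.  ASVs absent everywhere are not stored.
    """
    presence = table.presence()
    day_members: dict[DayLabel, list[str]] = {}
    for sample_id in table.sample_ids:
        day = table.day_of(sample_id)
        if day is None:
            raise ValueError(f"sample {sample_id!r} has no day label")
        day_members.setdefault(day, []).append(sample_id)
    profile: dict[str, set[DayLabel]] = {}
    for day, members in day_members.items():
        occupied = presence.loc[members].any(axis=0)
        for asv_id in presence.columns[occupied]:
            profile.setdefault(asv_id, set()).add(day)
    return {asv_id: frozenset(days) for asv_id, days in profile.items()}


def classify_biomarkers(profile: OccupancyProfile) -> BiomarkerSet:
    """Split ASVs into fresh biomarkers, decayed biomarkers, and neither.

    fresh  <=> non-empty occupancy within {D0_LAB, D0_FIELD, D1};
    decayed <=> non-empty occupancy within {D2, D4, D7, D11};
    window-spanning ASVs receive no label.
    """
    fresh: set[str] = set()
    decayed: set[str] = set()
    first_day: dict[str, DayLabel] = {}
    lab_only: set[str] = set()
    for asv_id, days in profile.items():
        if not days:
            continue
        if days <= FRESH_WINDOW:
            fresh.add(asv_id)
        elif days <= DECAYED_WINDOW:
            decayed.add(asv_id)
        else:
            continue
        first_day[asv_id] = min(days, key=lambda d: d.order)
        if days == {DayLabel.D0_LAB}:
            lab_only.add(asv_id)
    return BiomarkerSet(
        fresh_ids=frozenset(fresh),
        decayed_ids=frozenset(decayed),
        first_detection_day=first_day,
        occupancy={a: profile[a] for a in fresh | decayed},
        lab_only=frozenset(lab_only),
    )


def biomarker_summary(biomarkers: BiomarkerSet) -> dict[str, int]:
    """Cardinalities of the classified sets."""
    n_fresh = len(biomarkers.fresh_ids)
    n_decayed = len(biomarkers.decayed_ids)
    return {"n_fresh": n_fresh, "n_decayed": n_decayed, "n_total": n_fresh + n_decayed}
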