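"""Carrion-consumption inference: the pipeline's core logic.

A gut ASV that matched a decayed-tissue biomarker is only *informative*
of carrion consumption if it cannot be resident gut flora: it must be
present in at least one rat confirmed (by diet assay) to have eaten bird
and absent from every rat confirmed not to have.  Rats with ambiguous
diet evidence are excluded when building the informative set.

A confirmed bird-consuming rat carrying at least one informative ASV is
called a likely scavenger (``carrion_likely``); a consumer carrying none
may have taken its bird as fresh prey (``predation_or_unknown``).
Non-consumers receive no claim.  As an explicitly exploratory step, an
ambiguous rat carrying at least two informative ASVs is flagged
``suggested_carrion``.
"""

from __future__ import annotations

import enum
import json
import os
from dataclasses import dataclass, field

import pandas as pd

from .biomarkers import (
    BiomarkerSet,
    biomarker_summary,
    classify_biomarkers,
    pool_presence_by_day,
)
from .diet import DietCall, DietStatus, call_diet_table, summarize_diet
from .io import SequenceSet, ensure_dir, write_asv_table, write_fasta
from .matching import MatchResult, match_all, match_counts
from .table import AsvTable, SampleType, filter_singletons, remove_control_asvs
from .simulate import (
    CohortConfig,
    DecompositionConfig,
    TruthLabels,
    generate_decomposition_experiment,
    generate_rat_cohort,
)

__all__ = [
    "InformativeSet",
    "CarrionFlag",
    "ScavengingCall",
    "CohortReport",
    "find_informative",
    "call_scavenging",
    "resolve_ambiguous",
    "summarize_cohort",
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
]


@dataclass
class InformativeSet:
    """Gut ASV -> biomarker matches surviving the resident-flora filter."""

    asv_to_biomarker: dict[str, str]
    identity_pct: dict[str, float] = field(default_factory=dict)
    n_matched_before: int = 0
    n_informative_after: int = 0
    n_biomarkers_hit: int = 0

    def __post_init__(self) -> None:
        self.n_informative_after = len(self.asv_to_biomarker)
        self.n_biomarkers_hit = len(set(self.asv_to_biomarker.values()))
        if self.n_informative_after > self.n_matched_before:
            raise ValueError("informative set cannot exceed the matched set")

    @property
    def asv_ids(self) -> frozenset[str]:
        return frozenset(self.asv_to_biomarker)


class CarrionFlag(str, enum.Enum):
    CARRION_LIKELY = "carrion_likely"
    PREDATION_OR_UNKNOWN = "predation_or_unknown"
    SUGGESTED_CARRION = "suggested_carrion"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class ScavengingCall:
    sample_id: str
    diet_status: DietStatus
    carrion_flag: CarrionFlag
    supporting_asvs: tuple[str, ...] = ()
    exploratory: bool = False

    def __post_init__(self) -> None:
        if self.carrion_flag is CarrionFlag.CARRION_LIKELY and (
            self.diet_status is not DietStatus.CONSUMED or not self.supporting_asvs
        ):
            raise ValueError("carrion_likely requires a consumer with support")
        if self.carrion_flag is CarrionFlag.SUGGESTED_CARRION and (
            self.diet_status is not DietStatus.AMBIGUOUS or len(self.supporting_asvs) < 2
        ):
            raise ValueError("suggested_carrion requires an ambiguous rat with >=2 ASVs")


def find_informative(
    matches: list[MatchResult],
    rat_table: AsvTable,
    calls: list[DietCall],
) -> InformativeSet:
    """Filter biomarker-matched gut ASVs down to the informative subset.

    Retains matched ASVs present (count >= 1) in at least one
    confirmed-consumer rat and absent from every confirmed non-consumer.
    Ambiguous rats take no part in the filter.
    """
    consumed = [c.sample_id for c in calls if c.status is DietStatus.CONSUMED]
    not_consumed = [c.sample_id for c in calls if c.status is DietStatus.NOT_CONSUMED]
    if not consumed and not not_consumed:
        raise ValueError("no unambiguous rats: cannot build an informative set")
    presence = rat_table.presence()
    kept: dict[str, str] = {}
    identity: dict[str, float] = {}
    for match in matches:
        asv = match.query_asv_id
        if asv not in presence.columns:
            continue
        in_consumed = bool(presence.loc[consumed, asv].any()) if consumed else False
        in_not = bool(presence.loc[not_consumed, asv].any()) if not_consumed else False
        if in_consumed and not in_not:
            kept[asv] = match.biomarker_id
            identity[asv] = match.identity_pct
    return InformativeSet(
        asv_to_biomarker=kept,
        identity_pct=identity,
        n_matched_before=len({m.query_asv_id for m in matches}),
    )


def _support(presence: pd.DataFrame, sample_id: str, informative: InformativeSet):
    cols = [a for a in informative.asv_ids if a in presence.columns]
    return tuple(sorted(a for a in cols if presence.at[sample_id, a]))


def call_scavenging(
    calls: list[DietCall],
    informative: InformativeSet,
    rat_table: AsvTable,
) -> list[ScavengingCall]:
    """Classify confirmed consumers as likely scavengers or not.

    Non-consumers and ambiguous rats are returned as ``unresolved`` — the
    method makes no claim about them here (see
    :func:`resolve_ambiguous` for the exploratory ambiguous-rat rule).
    """
    presence = rat_table.presence()
    out = []
    for call in calls:
        if call.status is DietStatus.CONSUMED:
            support = _support(presence, call.sample_id, informative)
            flag = CarrionFlag.CARRION_LIKELY if support else CarrionFlag.PREDATION_OR_UNKNOWN
            out.append(ScavengingCall(call.sample_id, call.status, flag, support))
        else:
            out.append(
                ScavengingCall(call.sample_id, call.status, CarrionFlag.UNRESOLVED)
            )
    return out


def resolve_ambiguous(
    calls: list[DietCall],
    informative: InformativeSet,
    rat_table: AsvTable,
    min_asvs: int = 2,
) -> list[ScavengingCall]:
    """Exploratory rule for ambiguous rats.

    An ambiguous rat whose gut carries at least ``min_asvs`` informative
    ASVs is flagged ``suggested_carrion``; the output is labeled
    exploratory.
    """
    if min_asvs < 1:
        raise ValueError("min_asvs must be >= 1")
    presence = rat_table.presence()
    out = []
    for call in calls:
        if call.status is not DietStatus.AMBIGUOUS:
            continue
        support = _support(presence, call.sample_id, informative)
        if len(support) >= min_asvs:
            flag = CarrionFlag.SUGGESTED_CARRION
        else:
            flag = CarrionFlag.UNRESOLVED
        out.append(
            ScavengingCall(call.sample_id, call.status, flag, support, exploratory=True)
        )
    return out


@dataclass
class CohortReport:
    n_rats: int
    n_consumed: int
    n_not_consumed: int
    n_ambiguous: int
    n_carrion: int
    carrion_by_type: dict[str, int]
    n_suggested_carrion: int
    species_consumed: tuple[str, ...]
    species_with_carrion: tuple[str, ...]
    pct_consumed: int
    pct_carrion: int

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["species_consumed"] = list(self.species_consumed)
        d["species_with_carrion"] = list(self.species_with_carrion)
        return d


def summarize_cohort(
    calls: list[DietCall],
    scav_calls: list[ScavengingCall],
    ambiguous_calls: list[ScavengingCall] | None = None,
) -> CohortReport:
    """Cohort-level counts: diet statuses, carrion rats by sample type,
    species consumed and species with carrion evidence.

    Percentages are rounded to the nearest integer.
    """
    n = len(calls)
    by_id = {c.sample_id: c for c in calls}
    n_consumed = sum(c.status is DietStatus.CONSUMED for c in calls)
    n_not = sum(c.status is DietStatus.NOT_CONSUMED for c in calls)
    n_amb = sum(c.status is DietStatus.AMBIGUOUS for c in calls)

    carrion = [s for s in scav_calls if s.carrion_flag is CarrionFlag.CARRION_LIKELY]
    carrion_by_type: dict[str, int] = {}
    for s in carrion:
        stype = by_id[s.sample_id].sample_type
        carrion_by_type[stype] = carrion_by_type.get(stype, 0) + 1

    suggested = [
        s
        for s in (ambiguous_calls or [])
        if s.carrion_flag is CarrionFlag.SUGGESTED_CARRION
    ]

    species_consumed = sorted(
        {c.species for c in calls if c.species is not None}
    )
    carrion_ids = {s.sample_id for s in carrion}
    species_with_carrion = sorted(
        {
            c.species
            for c in calls
            if c.species is not None and c.sample_id in carrion_ids
        }
    )
    return CohortReport(
        n_rats=n,
        n_consumed=n_consumed,
        n_not_consumed=n_not,
        n_ambiguous=n_amb,
        n_carrion=len(carrion),
        carrion_by_type=carrion_by_type,
        n_suggested_carrion=len(suggested),
        species_consumed=tuple(species_consumed),
        species_with_carrion=tuple(species_with_carrion),
        pct_consumed=round(100 * n_consumed / n) if n else 0,
        pct_carrion=round(100 * len(carrion) / n) if n else 0,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class RunConfig:
    """Configuration for a full simulated pipeline run.

    Thresholds default to the method's published operating points:
    97% matching identity and the >=2-ASV exploratory rule.
    """

    seed: int
    decomposition: DecompositionConfig | None = None
    cohort: CohortConfig | None = None
    identity_threshold: float = 97.0
    min_ambiguous_asvs: int = 2
    out_dir: str | None = None


@dataclass
class PipelineResult:
    chicken_table: AsvTable
    rat_table: AsvTable
    biomarkers: BiomarkerSet
    matches: list[MatchResult]
    diet_calls: list[DietCall]
    informative: InformativeSet
    informative_fresh: InformativeSet
    scav_calls: list[ScavengingCall]
    ambiguous_calls: list[ScavengingCall]
    report: CohortReport
    truth: TruthLabels | None = None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Simulate a decomposition experiment and rat cohort, then run
    biomarker discovery, matching, diet calling, informative filtering
    and scavenging classification end to end.

    Fully deterministic for a given config; derived stage seeds come from
    the top-level seed.  If ``out_dir`` is set every intermediate is
    written as TSV/FASTA.
    """
    decomp_cfg = config.decomposition or DecompositionConfig(seed=config.seed * 2 + 1)
    cohort_cfg = config.cohort or CohortConfig(seed=config.seed * 2 + 2)

    chicken_table, chicken_seqs, decomp_truth = generate_decomposition_experiment(decomp_cfg)
    chicken_table = remove_control_asvs(chicken_table)
    chicken_table = filter_singletons(chicken_table)
    tissue_ids = [
        s
        for s in chicken_table.sample_ids
        if chicken_table.metadata.at[s, "sample_type"] == SampleType.CHICKEN_TISSUE.value
    ]
    profile = pool_presence_by_day(chicken_table.subset_samples(tissue_ids))
    biomarkers = classify_biomarkers(profile)

    decayed_seqs = chicken_seqs.subset(sorted(biomarkers.decayed_ids))
    fresh_seqs = (
        chicken_seqs.subset(sorted(biomarkers.fresh_ids)) if biomarkers.fresh_ids else None
    )

    rat_table, rat_seqs, evidence, cohort_truth = generate_rat_cohort(
        cohort_cfg, decayed_seqs
    )
    diet_calls = call_diet_table(evidence)

    queries = {a: rat_seqs[a] for a in rat_table.asv_ids if a in rat_seqs}
    matches = match_all(queries, decayed_seqs, threshold=config.identity_threshold)
    fresh_matches = (
        match_all(queries, fresh_seqs, threshold=config.identity_threshold)
        if fresh_seqs
        else []
    )

    informative = find_informative(matches, rat_table, diet_calls)
    informative_fresh = (
        find_informative(fresh_matches, rat_table, diet_calls)
        if fresh_matches
        else InformativeSet({}, n_matched_before=0)
    )
    scav_calls = call_scavenging(diet_calls, informative, rat_table)
    ambiguous_calls = resolve_ambiguous(
        diet_calls, informative, rat_table, min_asvs=config.min_ambiguous_asvs
    )
    report = summarize_cohort(diet_calls, scav_calls, ambiguous_calls)

    truth = TruthLabels()
    truth.asv_class = {**decomp_truth.asv_class, **cohort_truth.asv_class}
    truth.windows = decomp_truth.windows
    truth.rat_consumed = cohort_truth.rat_consumed
    truth.rat_scavenged = cohort_truth.rat_scavenged
    truth.rat_ambiguous = cohort_truth.rat_ambiguous
    truth.rat_species = cohort_truth.rat_species
    truth.planted_source = cohort_truth.planted_source

    result = PipelineResult(
        chicken_table=chicken_table,
        rat_table=rat_table,
        biomarkers=biomarkers,
        matches=matches,
        diet_calls=diet_calls,
        informative=informative,
        informative_fresh=informative_fresh,
        scav_calls=scav_calls,
        ambiguous_calls=ambiguous_calls,
        report=report,
        truth=truth,
    )
    if config.out_dir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    out = ensure_dir(config.out_dir)
    write_asv_table(
        result.chicken_table,
        os.path.join(out, "chicken_table.tsv"),
        os.path.join(out, "chicken_meta.tsv"),
    )
    write_asv_table(
        result.rat_table,
        os.path.join(out, "rat_table.tsv"),
        os.path.join(out, "rat_meta.tsv"),
    )
    bm = result.biomarkers
    pd.DataFrame(
        {
            "asv_id": sorted(bm.all_ids),
            "class": [
                "fresh" if a in bm.fresh_ids else "decayed" for a in sorted(bm.all_ids)
            ],
            "first_detection_day": [
                bm.first_detection_day[a].value for a in sorted(bm.all_ids)
            ],
            "occupancy": [
                ",".join(sorted(d.value for d in bm.occupancy[a]))
                for a in sorted(bm.all_ids)
            ],
        }
    ).to_csv(os.path.join(out, "biomarkers.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "query": m.query_asv_id,
                "biomarker": m.biomarker_id,
                "identity_pct": m.identity_pct,
            }
            for m in result.matches
        ]
    ).to_csv(os.path.join(out, "matches.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "sample_type": c.sample_type,
                "status": c.status.value,
                "species": c.species or "",
                "reason": c.reason.value,
            }
            for c in result.diet_calls
        ]
    ).to_csv(os.path.join(out, "diet_calls.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "rat_asv_id": a,
                "biomarker_id": b,
                "identity_pct": result.informative.identity_pct.get(a, ""),
            }
            for a, b in sorted(result.informative.asv_to_biomarker.items())
        ]
    ).to_csv(os.path.join(out, "informative.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "diet_status": s.diet_status.value,
                "carrion_flag": s.carrion_flag.value,
                "supporting_asvs": ",".join(s.supporting_asvs),
                "exploratory": int(s.exploratory),
            }
            for s in result.scav_calls + result.ambiguous_calls
        ]
    ).to_csv(os.path.join(out, "scavenging.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(result.report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    counts = match_counts(result.matches)
    with open(os.path.join(out, "provenance.json"), "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "identity_threshold": config.identity_threshold,
                "min_ambiguous_asvs": config.min_ambiguous_asvs,
                "n_matched_queries": counts["n_matched_queries"],
                "n_biomarkers_hit": counts["n_biomarkers_hit"],
                "biomarker_summary": biomarker_summary(result.biomarkers),
                "diet_summary": summarize_diet(result.diet_calls)
                .astype(int)
                .to_dict(),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
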