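"""Synthetic decomposition experiments, rat cohorts and diet evidence.

The generators emulate the study design the pipeline expects:

* a decomposition series — tissue sampled on seven day labels (day 0 in
  the lab, then days 0, 1, 2, 4, 7, 11 in the field) at replicate sites,
  carrying taxa whose day-occupancy is confined to the fresh window, the
  decayed window, both (spanning), or unconstrained (sporadic);
* a rat cohort (feces and stomach samples) whose bird-scavenging members
  carry gut ASVs that are slightly diverged (substitution-only, at most
  3% of sites by default) copies of decayed-tissue biomarker sequences,
  with "confounder" lookalikes planted in confirmed non-consumers so the
  informative-biomarker filter has real resident signal to remove;
* per-primer diet-assay evidence consistent with each rat's true status,
  with a configurable fraction of rats given ambiguous evidence.

Every generator takes a mandatory seed and is bit-deterministic.  Ground
truth is recorded in :class:`TruthLabels` for parameter-recovery tests.

Counts are negative-binomial (1 + NB so a detected taxon is always
present) with a lognormal per-sample depth factor emulating the roughly
16-fold sequencing-depth spread seen in real runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .diet import BlastHit, PrimerAssayResult, PrimerPair, DEFAULT_ROSTER
from .io import SequenceSet
from .table import DECAYED_WINDOW, FRESH_WINDOW, AsvTable, DayLabel, SampleType

__all__ = [
    "DecompositionConfig",
    "CohortConfig",
    "TruthLabels",
    "generate_16s_fragment",
    "mutate_sequence",
    "generate_decomposition_experiment",
    "generate_rat_cohort",
    "generate_tree",
]

_BASES = np.array(list("ACGT"))

FIELD_DAYS = (
    DayLabel.D0_FIELD,
    DayLabel.D1,
    DayLabel.D2,
    DayLabel.D4,
    DayLabel.D7,
    DayLabel.D11,
)


@dataclass(frozen=True)
class DecompositionConfig:
    """Design of the simulated tissue-decomposition experiment.

    Defaults mirror the study scale: 10 replicate sites, seven sampling
    days, ~70 tissue taxa of which most are decayed-window specialists,
    and sparse early-day communities (freshly sterilized tissue carries
    few microbes, so fresh-window counts are scaled down).
    """

    seed: int
    n_sites: int = 10
    n_fresh_only: int = 2
    n_decayed_only: int = 42
    n_spanning: int = 15
    n_sporadic: int = 11
    fragment_length: int = 425
    detection_prob: float = 0.9
    mean_count: float = 150.0
    fresh_factor: float = 0.15
    nb_dispersion: float = 2.0
    depth_sigma: float = 0.7

    def __post_init__(self) -> None:
        if min(self.n_fresh_only, self.n_decayed_only, self.n_spanning, self.n_sporadic) < 0:
            raise ValueError("taxon class counts must be >= 0")
        if not 0 < self.detection_prob <= 1:
            raise ValueError("detection_prob must be in (0, 1]")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass(frozen=True)
class CohortConfig:
    """Design of the simulated rat cohort.

    Defaults reproduce the study's 51-rat composition: 28 fecal and 23
    stomach samples, 20 confirmed bird consumers, 11 confirmed
    non-consumers (the remainder ambiguous) and 9 true scavengers among
    the consumers.  Planted carrion ASVs diverge from their source
    biomarker by at most ``max_divergence`` of sites (default 3%, the
    complement of the 97% matching threshold).
    """

    seed: int
    n_rats: int = 51
    n_feces: int = 28
    n_kipuka: int = 18
    frac_consumed: float = 20 / 51
    frac_not_consumed: float = 11 / 51
    frac_scavenger: float = 9 / 20  # among consumers
    n_planted_per_scavenger: int = 2
    max_divergence: float = 0.03
    match_threshold: float = 97.0
    n_confounders: int = 5
    n_resident_pool: int = 300
    resident_richness: float = 60.0
    dirichlet_concentration: float = 0.5
    mean_count: float = 80.0
    nb_dispersion: float = 2.0
    depth_sigma: float = 0.7
    ambiguity_from_truth: bool = True

    def __post_init__(self) -> None:
        if self.n_feces > self.n_rats:
            raise ValueError("n_feces cannot exceed n_rats")
        if not 0 <= self.frac_consumed <= 1 or not 0 <= self.frac_not_consumed <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_consumed + self.frac_not_consumed > 1:
            raise ValueError("consumed + not-consumed fractions exceed 1")
        if self.max_divergence > (100.0 - self.match_threshold) / 100.0:
            raise ValueError(
                f"max_divergence {self.max_divergence} exceeds what the "
                f"{self.match_threshold}% matching threshold can accept"
            )

    @property
    def n_consumed(self) -> int:
        return round(self.frac_consumed * self.n_rats)

    @property
    def n_not_consumed(self) -> int:
        return round(self.frac_not_consumed * self.n_rats)

    @property
    def n_ambiguous(self) -> int:
        return self.n_rats - self.n_consumed - self.n_not_consumed

    @property
    def n_scavengers(self) -> int:
        return round(self.frac_scavenger * self.n_consumed)


@dataclass
class TruthLabels:
    """Ground truth recorded by the generators.

    ``asv_class`` maps every generated ASV to exactly one of fresh_only /
    decayed_only / spanning / sporadic / resident / planted_carrion /
    confounder.  ``windows`` stores the configured day window per
    decomposition taxon.  Rat-level truth: consumed, scavenged (implies
    consumed) and whether the generated evidence was made ambiguous.
    ``planted_source`` maps each planted/confounder ASV to the biomarker
    sequence it was mutated from.
    """

    asv_class: dict[str, str] = field(default_factory=dict)
    windows: dict[str, frozenset] = field(default_factory=dict)
    rat_consumed: dict[str, bool] = field(default_factory=dict)
    rat_scavenged: dict[str, bool] = field(default_factory=dict)
    rat_ambiguous: dict[str, bool] = field(default_factory=dict)
    rat_species: dict[str, str] = field(default_factory=dict)
    planted_source: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for rat, scav in self.rat_scavenged.items():
            if scav and not self.rat_consumed.get(rat, False):
                raise ValueError(f"rat {rat} scavenged without consuming")


# ---------------------------------------------------------------------------
# sequence primitives


def generate_16s_fragment(length: int, seed: int) -> str:
    """Uniform-random nucleotide fragment of the given length."""
    if length < 50:
        raise ValueError("fragment length must be >= 50")
    rng = np.random.default_rng(seed)
    return _random_fragment(rng, length)


def _random_fragment(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def mutate_sequence(seq: str, n_subs: int, seed: int) -> str:
    """Substitute exactly ``n_subs`` positions (no indels).

    Positions are drawn without replacement; each replacement base
    differs from the original, so the Hamming distance to the input is
    exactly ``n_subs``.
    """
    rng = np.random.default_rng(seed)
    return _mutate(rng, seq, n_subs)


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    if n_subs < 0 or n_subs > len(seq):
        raise ValueError(f"n_subs must be in [0, {len(seq)}]")
    chars = list(seq)
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# decomposition experiment


def _nb_count(rng: np.random.Generator, mean: float, k: float) -> int:
    # 1 + NB so detection always implies presence
    p = k / (k + mean)
    return 1 + int(rng.negative_binomial(k, p))


def _random_window(rng: np.random.Generator, days: tuple) -> frozenset:
    while True:
        picked = [d for d in days if rng.random() < 0.5]
        if picked:
            return frozenset(picked)


def generate_decomposition_experiment(
    config: DecompositionConfig,
) -> tuple[AsvTable, SequenceSet, TruthLabels]:
    """Simulate the tissue time series: one sample per (site, day) plus a
    lab control per site; taxa honor their configured day windows."""
    rng = np.random.default_rng(config.seed)
    truth = TruthLabels()

    taxa: list[tuple[str, str, frozenset]] = []
    fresh_days = tuple(sorted(FRESH_WINDOW, key=lambda d: d.order))
    decayed_days = tuple(sorted(DECAYED_WINDOW, key=lambda d: d.order))
    all_days = fresh_days + decayed_days
    for i in range(config.n_fresh_only):
        taxa.append((f"fresh{i:03d}", "fresh_only", _random_window(rng, fresh_days)))
    for i in range(config.n_decayed_only):
        taxa.append((f"decay{i:03d}", "decayed_only", _random_window(rng, decayed_days)))
    for i in range(config.n_spanning):
        while True:
            window = _random_window(rng, all_days)
            if window & FRESH_WINDOW and window & DECAYED_WINDOW:
                break
        taxa.append((f"span{i:03d}", "spanning", window))
    for i in range(config.n_sporadic):
        taxa.append((f"spor{i:03d}", "sporadic", _random_window(rng, all_days)))

    sequences = {}
    for asv_id, cls, window in taxa:
        sequences[asv_id] = _random_fragment(rng, config.fragment_length)
        truth.asv_class[asv_id] = cls
        truth.windows[asv_id] = window

    sample_ids = []
    meta_rows = []
    for site in range(1, config.n_sites + 1):
        sample_ids.append(f"lab_s{site:02d}")
        meta_rows.append((SampleType.CHICKEN_TISSUE.value, f"site{site:02d}", DayLabel.D0_LAB.value, False))
        for day in FIELD_DAYS:
            sample_ids.append(f"{day.value.lower()}_s{site:02d}")
            meta_rows.append((SampleType.CHICKEN_TISSUE.value, f"site{site:02d}", day.value, False))

    depth_factor = np.exp(rng.normal(0.0, config.depth_sigma, size=len(sample_ids)))
    counts = np.zeros((len(sample_ids), len(taxa)), dtype=np.int64)
    for j, (asv_id, cls, window) in enumerate(taxa):
        for i, sample_id in enumerate(sample_ids):
            day = DayLabel(meta_rows[i][2])
            if day not in window:
                continue
            if rng.random() >= config.detection_prob:
                continue
            mean = config.mean_count * depth_factor[i]
            if day in FRESH_WINDOW:
                mean *= config.fresh_factor
            counts[i, j] = _nb_count(rng, mean, config.nb_dispersion)

    table = AsvTable(
        pd.DataFrame(counts, index=sample_ids, columns=[t[0] for t in taxa]),
        pd.DataFrame(
            meta_rows,
            index=sample_ids,
            columns=["sample_type", "site", "day", "is_control"],
        ),
    )
    return table, SequenceSet(sequences, length_band=None), truth


# ---------------------------------------------------------------------------
# rat cohort


def generate_rat_cohort(
    config: CohortConfig, biomarkers: SequenceSet
) -> tuple[AsvTable, SequenceSet, list[PrimerAssayResult], TruthLabels]:
    """Simulate the rat cohort, its gut table, sequences and diet evidence.

    Every true scavenger carries at least one planted carrion ASV (a
    slightly diverged copy of a decayed-tissue biomarker); every
    confounder lookalike is planted in at least one confirmed (truth and
    evidence) non-consumer.  Evidence is generated consistent with truth,
    with the configured ambiguous subset.
    """
    if not biomarkers:
        raise ValueError("biomarker sequence set must be non-empty")
    rng = np.random.default_rng(config.seed)
    truth = TruthLabels()

    rat_ids = [f"rat{r:03d}" for r in range(1, config.n_rats + 1)]
    sample_types = [
        SampleType.RAT_FECES.value if r < config.n_feces else SampleType.RAT_STOMACH.value
        for r in range(config.n_rats)
    ]
    kipuka = [f"kipuka{rng.integers(1, config.n_kipuka + 1):02d}" for _ in rat_ids]

    # status assignment: shuffle, then slice
    order = rng.permutation(config.n_rats)
    consumed_idx = set(order[: config.n_consumed].tolist())
    not_idx = set(order[config.n_consumed : config.n_consumed + config.n_not_consumed].tolist())
    ambiguous_idx = set(order[config.n_consumed + config.n_not_consumed :].tolist())
    consumed_list = sorted(consumed_idx)
    scav_pick = rng.permutation(len(consumed_list))[: config.n_scavengers]
    scavenger_idx = {consumed_list[i] for i in scav_pick}

    roster_species = sorted(DEFAULT_ROSTER.species)
    for r, rat in enumerate(rat_ids):
        truth.rat_consumed[rat] = r in consumed_idx
        truth.rat_scavenged[rat] = r in scavenger_idx
        truth.rat_ambiguous[rat] = r in ambiguous_idx
        if r in consumed_idx:
            truth.rat_species[rat] = roster_species[rng.integers(0, len(roster_species))]

    # resident community from a shared Dirichlet pool
    pool_ids = [f"res{i:04d}" for i in range(config.n_resident_pool)]
    sequences = {a: _random_fragment(rng, 425) for a in pool_ids}
    for a in pool_ids:
        truth.asv_class[a] = "resident"
    pool_weights = rng.dirichlet(
        np.full(config.n_resident_pool, config.dirichlet_concentration)
    )

    presence_counts: dict[str, dict[str, int]] = {rat: {} for rat in rat_ids}
    depth_factor = np.exp(rng.normal(0.0, config.depth_sigma, size=config.n_rats))
    for r, rat in enumerate(rat_ids):
        richness = max(5, int(rng.poisson(config.resident_richness)))
        richness = min(richness, config.n_resident_pool)
        members = rng.choice(
            config.n_resident_pool, size=richness, replace=False, p=pool_weights
        )
        for j in members:
            presence_counts[rat][pool_ids[j]] = _nb_count(
                rng, config.mean_count * depth_factor[r], config.nb_dispersion
            )

    # planted carrion ASVs in scavengers
    biomarker_ids = sorted(biomarkers)
    plant_n = 0
    for r in sorted(scavenger_idx):
        rat = rat_ids[r]
        for _ in range(max(1, config.n_planted_per_scavenger)):
            src = biomarker_ids[rng.integers(0, len(biomarker_ids))]
            src_seq = biomarkers[src]
            max_subs = math.floor(config.max_divergence * len(src_seq))
            n_subs = int(rng.integers(0, max_subs + 1))
            asv_id = f"carrion{plant_n:03d}"
            plant_n += 1
            sequences[asv_id] = _mutate(rng, src_seq, n_subs)
            truth.asv_class[asv_id] = "planted_carrion"
            truth.planted_source[asv_id] = src
            presence_counts[rat][asv_id] = _nb_count(
                rng, config.mean_count * depth_factor[r] * 0.2, config.nb_dispersion
            )

    # confounder lookalikes in confirmed non-consumers
    confirmed_not = [r for r in sorted(not_idx)]
    for c in range(config.n_confounders):
        if not confirmed_not:
            break
        src = biomarker_ids[rng.integers(0, len(biomarker_ids))]
        src_seq = biomarkers[src]
        max_subs = math.floor(config.max_divergence * len(src_seq))
        n_subs = int(rng.integers(0, max_subs + 1))
        asv_id = f"confound{c:03d}"
        sequences[asv_id] = _mutate(rng, src_seq, n_subs)
        truth.asv_class[asv_id] = "confounder"
        truth.planted_source[asv_id] = src
        n_hosts = int(rng.integers(1, min(3, len(confirmed_not)) + 1))
        hosts = rng.choice(confirmed_not, size=n_hosts, replace=False)
        for r in hosts:
            rat = rat_ids[r]
            presence_counts[rat][asv_id] = _nb_count(
                rng, config.mean_count * depth_factor[r] * 0.2, config.nb_dispersion
            )

    all_asvs = sorted(sequences)
    counts = np.zeros((config.n_rats, len(all_asvs)), dtype=np.int64)
    col = {a: j for j, a in enumerate(all_asvs)}
    for r, rat in enumerate(rat_ids):
        for asv_id, count in presence_counts[rat].items():
            counts[r, col[asv_id]] = count
    table = AsvTable(
        pd.DataFrame(counts, index=rat_ids, columns=all_asvs),
        pd.DataFrame(
            {
                "sample_type": sample_types,
                "site": kipuka,
                "day": [None] * config.n_rats,
                "is_control": [False] * config.n_rats,
            },
            index=rat_ids,
        ),
    )

    evidence = _generate_evidence(rng, rat_ids, sample_types, truth)
    truth.validate()
    return table, SequenceSet(sequences, length_band=None), evidence, truth


_NON_BIRD_TAXA = ("Lumbricus terrestris", "Amphipsalta zelandica", "Hyposmocoma molluscivora")


def _generate_evidence(
    rng: np.random.Generator,
    rat_ids: list[str],
    sample_types: list[str],
    truth: TruthLabels,
) -> list[PrimerAssayResult]:
    """Two replicates per primer pair per rat, consistent with truth."""
    assays: list[PrimerAssayResult] = []
    pairs = list(PrimerPair)
    for r, rat in enumerate(rat_ids):
        stype = sample_types[r]
        ambiguous = truth.rat_ambiguous.get(rat, False)
        consumed = truth.rat_consumed.get(rat, False)
        positive_pair = pairs[int(rng.integers(0, 2))]
        for pair in pairs:
            for replicate in (1, 2):
                if ambiguous:
                    if pair is positive_pair and replicate == 1:
                        mode = rng.random()
                        if mode < 0.5:  # band, unusable trace
                            assays.append(
                                PrimerAssayResult(rat, stype, pair, replicate, True, 30.0, False, ())
                            )
                        elif mode < 0.75:  # mixed trace
                            assays.append(
                                PrimerAssayResult(rat, stype, pair, replicate, True, 80.0, True, ())
                            )
                        else:  # clean sequence, non-bird taxon
                            taxon = _NON_BIRD_TAXA[rng.integers(0, len(_NON_BIRD_TAXA))]
                            hits = (BlastHit(taxon, 1e-80, 98.0),)
                            assays.append(
                                PrimerAssayResult(rat, stype, pair, replicate, True, 85.0, False, hits)
                            )
                    else:
                        assays.append(
                            PrimerAssayResult(rat, stype, pair, replicate, False)
                        )
                elif consumed:
                    if pair is positive_pair and replicate == 1:
                        species = truth.rat_species[rat]
                        raw = "Lophura nycthemera" if species == "Lophura leucomelanos" else species
                        hits = tuple(
                            BlastHit(raw, 10 ** -float(rng.uniform(60, 120)), float(rng.uniform(96, 100)))
                            for _ in range(int(rng.integers(1, 4)))
                        )
                        quality = float(rng.uniform(80, 99))
                        assays.append(
                            PrimerAssayResult(rat, stype, pair, replicate, True, quality, False, hits)
                        )
                    else:
                        assays.append(
                            PrimerAssayResult(rat, stype, pair, replicate, False)
                        )
                else:
                    assays.append(PrimerAssayResult(rat, stype, pair, replicate, False))
    return assays


# ---------------------------------------------------------------------------
# random tree


def generate_tree(asv_ids, seed: int, mean_branch: float = 0.1) -> skbio.TreeNode:
    """Random binary rooted tree over the given leaf ids.

    Built by repeatedly joining two random subtrees; branch lengths are
    exponential with the given mean.
    """
    ids = list(asv_ids)
    if len(ids) < 2:
        raise ValueError("need at least two leaf ids")
    if len(set(ids)) != len(ids):
        raise ValueError("leaf ids must be unique")
    rng = np.random.default_rng(seed)
    nodes = []
    for name in ids:
        tip = skbio.TreeNode(name=name)
        tip.length = float(rng.exponential(mean_branch))
        nodes.append(tip)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = skbio.TreeNode(children=[left, right])
        parent.length = float(rng.exponential(mean_branch))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root
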