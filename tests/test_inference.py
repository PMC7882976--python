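"""Informative-biomarker filtering and scavenging classification."""

import pytest

from scavtrace import (
    CarrionFlag,
    DietCall,
    DietStatus,
    InformativeSet,
    Reason,
    RunConfig,
    call_scavenging,
    find_informative,
    resolve_ambiguous,
    run_pipeline,
    summarize_cohort,
)
from scavtrace.matching import MatchResult

from conftest import make_table


def diet_call(sample, status, species=None):
    reason = {
        DietStatus.CONSUMED: Reason.CONFIRMED,
        DietStatus.NOT_CONSUMED: Reason.NO_AMPLIFICATION,
        DietStatus.AMBIGUOUS: Reason.LOW_QUALITY,
    }[status]
    return DietCall(sample, "rat_stomach", status, species, reason)


def match(asv, biomarker="bm1", identity=99.0):
    return MatchResult(asv, biomarker, identity, n_identical=420, is_match=True)


@pytest.fixture
def small_cohort():
    # rats: c1, c2 consumed; n1 not consumed; a1 ambiguous
    counts = [
        [5, 0, 2, 1],  # c1
        [0, 3, 0, 1],  # c2
        [0, 0, 4, 0],  # n1
        [2, 3, 0, 0],  # a1
    ]
    table = make_table(
        counts,
        sample_ids=["c1", "c2", "n1", "a1"],
        asv_ids=["gutA", "gutB", "gutC", "gutD"],
        sample_type="rat_stomach",
    )
    calls = [
        diet_call("c1", DietStatus.CONSUMED, "Zosterops japonicus"),
        diet_call("c2", DietStatus.CONSUMED, "Myadestes obscurus"),
        diet_call("n1", DietStatus.NOT_CONSUMED),
        diet_call("a1", DietStatus.AMBIGUOUS),
    ]
    matches = [match("gutA"), match("gutB", "bm2"), match("gutC", "bm1")]
    return table, calls, matches


class TestFindInformative:
    def test_resident_lookalike_excluded(self, small_cohort):
        table, calls, matches = small_cohort
        informative = find_informative(matches, table, calls)
        # gutC is present in the non-consumer n1 -> resident flora
        assert "gutC" not in informative.asv_ids

    def test_consumer_only_asvs_retained(self, small_cohort):
        table, calls, matches = small_cohort
        informative = find_informative(matches, table, calls)
        assert informative.asv_ids == {"gutA", "gutB"}
        assert informative.n_matched_before == 3
        assert informative.n_informative_after == 2
        assert informative.n_biomarkers_hit == 2

    def test_ambiguous_rats_do_not_veto(self):
        # ASV present in a consumer and an ambiguous rat, absent from the
        # non-consumer: still informative (ambiguous rats are excluded)
        table = make_table(
            [[2], [3], [0]],
            sample_ids=["c1", "a1", "n1"],
            asv_ids=["gutA"],
            sample_type="rat_stomach",
        )
        calls = [
            diet_call("c1", DietStatus.CONSUMED, "Zosterops japonicus"),
            diet_call("a1", DietStatus.AMBIGUOUS),
            diet_call("n1", DietStatus.NOT_CONSUMED),
        ]
        informative = find_informative([match("gutA")], table, calls)
        assert informative.asv_ids == {"gutA"}

    def test_no_unambiguous_rats_errors(self):
        table = make_table([[1]], sample_ids=["a1"], asv_ids=["gutA"])
        with pytest.raises(ValueError, match="unambiguous"):
            find_informative([match("gutA")], table, [diet_call("a1", DietStatus.AMBIGUOUS)])

    def test_informative_never_exceeds_matched(self):
        with pytest.raises(ValueError, match="exceed"):
            InformativeSet({"a": "b"}, n_matched_before=0)

    def test_synthetic_recovery(self, noise_free_run):
        """All planted carrion ASVs retained; all confounders excluded."""
        truth = noise_free_run.truth
        informative = noise_free_run.informative
        planted = {a for a, c in truth.asv_class.items() if c == "planted_carrion"}
        confounders = {a for a, c in truth.asv_class.items() if c == "confounder"}
        scav_plants = {
            a
            for a in planted
            if any(
                noise_free_run.rat_table.presence().at[r, a]
                for r, s in truth.rat_scavenged.items()
                if s and not truth.rat_ambiguous[r]
            )
        }
        assert scav_plants <= informative.asv_ids
        assert not (confounders & informative.asv_ids)


class TestScavengingCalls:
    def test_consumer_with_support_is_carrion_likely(self, small_cohort):
        table, calls, matches = small_cohort
        informative = find_informative(matches, table, calls)
        scav = {s.sample_id: s for s in call_scavenging(calls, informative, table)}
        assert scav["c1"].carrion_flag is CarrionFlag.CARRION_LIKELY
        assert scav["c1"].supporting_asvs == ("gutA",)

    def test_consumer_without_support_is_predation_or_unknown(self):
        table = make_table(
            [[0], [2]],
            sample_ids=["c1", "n1"],
            asv_ids=["gutA"],
            sample_type="rat_stomach",
        )
        calls = [
            diet_call("c1", DietStatus.CONSUMED, "Zosterops japonicus"),
            diet_call("n1", DietStatus.NOT_CONSUMED),
        ]
        informative = find_informative([match("gutA")], table, calls)
        scav = {s.sample_id: s for s in call_scavenging(calls, informative, table)}
        assert scav["c1"].carrion_flag is CarrionFlag.PREDATION_OR_UNKNOWN
        assert scav["n1"].carrion_flag is CarrionFlag.UNRESOLVED

    def test_recovers_true_scavengers(self, noise_free_run):
        truth = noise_free_run.truth
        called = {
            s.sample_id
            for s in noise_free_run.scav_calls
            if s.carrion_flag is CarrionFlag.CARRION_LIKELY
        }
        expected = {
            r
            for r, s in truth.rat_scavenged.items()
            if s and not truth.rat_ambiguous[r]
        }
        assert called == expected


class TestResolveAmbiguous:
    def build(self, a1_counts):
        table = make_table(
            [[3, 4], [0, 0], a1_counts],
            sample_ids=["c1", "n1", "a1"],
            asv_ids=["gutA", "gutB"],
            sample_type="rat_stomach",
        )
        calls = [
            diet_call("c1", DietStatus.CONSUMED, "Zosterops japonicus"),
            diet_call("n1", DietStatus.NOT_CONSUMED),
            diet_call("a1", DietStatus.AMBIGUOUS),
        ]
        informative = find_informative(
            [match("gutA"), match("gutB", "bm2")], table, calls
        )
        return table, calls, informative

    def test_two_asvs_suggest_carrion(self):
        table, calls, informative = self.build([1, 1])
        (resolved,) = resolve_ambiguous(calls, informative, table)
        assert resolved.carrion_flag is CarrionFlag.SUGGESTED_CARRION
        assert resolved.exploratory

    def test_one_asv_stays_unresolved(self):
        table, calls, informative = self.build([1, 0])
        (resolved,) = resolve_ambiguous(calls, informative, table)
        assert resolved.carrion_flag is CarrionFlag.UNRESOLVED

    def test_threshold_sweep_is_monotone(self, ambiguous_run):
        table = ambiguous_run.rat_table
        calls = ambiguous_run.diet_calls
        informative = ambiguous_run.informative
        n_suggested = []
        for min_asvs in (1, 2, 3):
            resolved = resolve_ambiguous(calls, informative, table, min_asvs=min_asvs)
            n_suggested.append(
                sum(r.carrion_flag is CarrionFlag.SUGGESTED_CARRION for r in resolved)
            )
        assert n_suggested[0] >= n_suggested[1] >= n_suggested[2]

    def test_min_asvs_below_one_rejected(self, small_cohort):
        table, calls, matches = small_cohort
        informative = find_informative(matches, table, calls)
        with pytest.raises(ValueError):
            resolve_ambiguous(calls, informative, table, min_asvs=0)


class TestSummaryAndPipeline:
    def test_empty_cohort_summary(self):
        report = summarize_cohort([], [], [])
        assert report.n_rats == 0 and report.n_carrion == 0
        assert report.pct_carrion == 0

    def test_conservation_invariants(self, ambiguous_run):
        report = ambiguous_run.report
        informative = ambiguous_run.informative
        assert informative.n_informative_after <= informative.n_matched_before
        carrion = {
            s.sample_id
            for s in ambiguous_run.scav_calls
            if s.carrion_flag is CarrionFlag.CARRION_LIKELY
        }
        consumed = {
            c.sample_id
            for c in ambiguous_run.diet_calls
            if c.status is DietStatus.CONSUMED
        }
        assert carrion <= consumed
        suggested = {
            s.sample_id
            for s in ambiguous_run.ambiguous_calls
            if s.carrion_flag is CarrionFlag.SUGGESTED_CARRION
        }
        ambiguous = {
            c.sample_id
            for c in ambiguous_run.diet_calls
            if c.status is DietStatus.AMBIGUOUS
        }
        assert suggested <= ambiguous
        assert report.n_carrion == len(carrion)

    def test_exclusion_soundness_reassertable(self, ambiguous_run):
        """No informative ASV occurs in any confirmed non-consumer."""
        presence = ambiguous_run.rat_table.presence()
        not_consumed = [
            c.sample_id
            for c in ambiguous_run.diet_calls
            if c.status is DietStatus.NOT_CONSUMED
        ]
        for asv in ambiguous_run.informative.asv_ids:
            assert not presence.loc[not_consumed, asv].any()

    def test_pipeline_is_deterministic(self, tmp_path):
        from conftest import SMALL_COHORT, SMALL_DECOMP
        from scavtrace import CohortConfig, DecompositionConfig

        cfg = lambda out: RunConfig(
            seed=3,
            decomposition=DecompositionConfig(seed=31, **SMALL_DECOMP),
            cohort=CohortConfig(seed=32, **SMALL_COHORT),
            out_dir=str(out),
        )
        r1 = run_pipeline(cfg(tmp_path / "run1"))
        r2 = run_pipeline(cfg(tmp_path / "run2"))
        assert r1.rat_table.counts.equals(r2.rat_table.counts)
        assert r1.report == r2.report
        for name in ("biomarkers.tsv", "matches.tsv", "diet_calls.tsv",
                     "scavenging.tsv", "report.json"):
            assert (tmp_path / "run1" / name).read_text() == (
                tmp_path / "run2" / name
            ).read_text()
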