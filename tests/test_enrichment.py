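"""Phylogenetically weighted scoring, thresholding and DAG refinement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import BP_ROOT, CC_ROOT, MF_ROOT, make_clique
from orthoclique.enrichment import (
    DEFAULT_GROUP_SCORES,
    EnrichmentConfig,
    ScoredAssignment,
    SpeciesGroupConfig,
    candidate_terms,
    enrich_target,
    go_score,
    refine_by_dag,
    score_histogram,
    threshold_filter,
)
from orthoclique.simulate import generate_ontology

GROUPS = SpeciesGroupConfig.default_plants()
FULL = make_clique({sp: f"{sp}_g" for sp in DEFAULT_GROUP_SCORES})
MAX_SCORE = 1 + 1 + 0.5 + 0.5 + 1 / 3 + 0.25 + 0.2 + 0.2 + 1 / 6 + 1 / 6


def annotate(clique, term, species=None):
    """Annotation map carrying `term` on the given species' clique genes."""
    species = set(species if species is not None else [sp for sp, _ in clique.genes])
    return {sp: {g: ({term} if sp in species else set())} for sp, g in clique.genes}


class TestGoScore:
    def test_full_clique_maximum(self):
        ann = annotate(FULL, "GO:0000003")
        s = go_score("GO:0000003", FULL, ann, GROUPS)
        assert s == pytest.approx(4.3166667, abs=1e-6)
        assert round(s, 2) == 4.32

    def test_group2_species_contributes_half(self):
        ann = annotate(FULL, "GO:0000003", species={"HVU"})
        assert go_score("GO:0000003", FULL, ann, GROUPS) == 0.5

    def test_unannotated_term_scores_zero(self):
        ann = annotate(FULL, "GO:0000003", species=set())
        assert go_score("GO:0000003", FULL, ann, GROUPS) == 0.0

    def test_all_but_target_scores_3_32(self):
        others = set(DEFAULT_GROUP_SCORES) - {"TAE"}
        ann = annotate(FULL, "GO:0000003", species=others)
        s = go_score("GO:0000003", FULL, ann, GROUPS)
        assert s == pytest.approx(MAX_SCORE - 1.0, abs=1e-6)
        assert round(s, 2) == 3.32

    def test_additive_one_species_at_a_time(self):
        carried = set()
        prev = 0.0
        for sp in sorted(DEFAULT_GROUP_SCORES):
            carried.add(sp)
            s = go_score("GO:0000003", FULL, annotate(FULL, "GO:0000003", carried), GROUPS)
            assert s == pytest.approx(prev + 1 / DEFAULT_GROUP_SCORES[sp])
            prev = s
        assert prev == pytest.approx(MAX_SCORE)

    def test_missing_species_in_groups_is_error(self):
        clique = make_clique({"TAE": "t", "XXX": "x", "HVU": "h"})
        with pytest.raises(KeyError, match="XXX"):
            go_score("GO:0000003", clique, annotate(clique, "GO:0000003"), GROUPS)


class TestSpeciesGroupConfig:
    def test_target_must_be_group_1(self):
        with pytest.raises(ValueError):
            SpeciesGroupConfig(scores={"TAE": 2}, target_species="TAE")

    def test_target_must_be_listed(self):
        with pytest.raises(ValueError):
            SpeciesGroupConfig(scores={"ATH": 6}, target_species="TAE")


class TestCandidateTerms:
    def test_nontarget_term_becomes_candidate(self):
        clique = make_clique({"TAE": "t", "ATA": "a", "HVU": "h"})
        ann = annotate(clique, "GO:0007568", species={"ATA"})
        out = candidate_terms(clique, ann, GROUPS)
        assert [(a.go_id, a.status) for a in out] == [("GO:0007568", "candidate")]
        assert out[0].gene == "t"

    def test_target_own_terms_are_original(self):
        clique = make_clique({"TAE": "t", "ATA": "a", "HVU": "h"})
        ann = annotate(clique, "GO:0007568", species={"TAE"})
        out = candidate_terms(clique, ann, GROUPS)
        assert [(a.go_id, a.status) for a in out] == [("GO:0007568", "original")]

    def test_clique_without_target_skipped(self):
        clique = make_clique({"ATH": "a", "OSA": "o", "HVU": "h"})
        assert candidate_terms(clique, annotate(clique, "GO:0007568"), GROUPS) == []

    def test_original_scores_at_least_one(self):
        # the target's own +1 contribution puts originals at >= 1
        rng = np.random.default_rng(8)
        clique = FULL
        for _ in range(10):
            carriers = {"TAE"} | {
                sp for sp in DEFAULT_GROUP_SCORES if rng.random() < 0.5
            }
            ann = annotate(clique, "GO:0000003", carriers)
            (rec,) = candidate_terms(clique, ann, GROUPS)
            assert rec.status == "original" and rec.go_score >= 1.0


class TestThresholdFilter:
    def rec(self, score, status="candidate"):
        return ScoredAssignment("t", "GO:0000003", "C1", score, status)

    def test_exactly_half_passes_inclusive_default(self):
        out = threshold_filter([self.rec(0.5)])
        assert out[0].status == "candidate"

    def test_just_below_rejected(self):
        out = threshold_filter([self.rec(0.4999)])
        assert out[0].status == "rejected-below-threshold"

    def test_strict_mode_rejects_exact_threshold(self):
        cfg = EnrichmentConfig(threshold_inclusive=False)
        out = threshold_filter([self.rec(0.5)], cfg)
        assert out[0].status == "rejected-below-threshold"

    def test_originals_always_pass(self):
        out = threshold_filter([self.rec(0.1, "original")])
        assert out[0].status == "original"

    def test_empty(self):
        assert threshold_filter([]) == []


class TestRefineByDag:
    def cand(self, go_id, score=1.0):
        return ScoredAssignment("t", go_id, "C1", score, "candidate")

    def test_deeper_term_accepted(self, toy_dag):
        # original b, candidate c with c is_a b: c is more specific
        (out,) = refine_by_dag("t", [self.cand("GO:0000003")], {"GO:0000002"}, toy_dag)
        assert out.status == "accepted"

    def test_ancestor_of_original_rejected(self, toy_dag):
        # converse: original c, candidate b above it
        (out,) = refine_by_dag("t", [self.cand("GO:0000002")], {"GO:0000003"}, toy_dag)
        assert out.status == "rejected-ancestor-of-original"

    def test_duplicate_rejected(self, toy_dag):
        (out,) = refine_by_dag("t", [self.cand("GO:0000003")], {"GO:0000003"}, toy_dag)
        assert out.status == "rejected-duplicate"

    def test_root_accepted_for_unannotated_gene(self, toy_dag):
        (out,) = refine_by_dag("t", [self.cand(BP_ROOT)], set(), toy_dag)
        assert out.status == "accepted"

    def test_root_accepted_on_different_namespace_path(self, toy_dag):
        # gene annotated only in molecular_function: the bp root is new info
        (out,) = refine_by_dag("t", [self.cand(BP_ROOT)], {"GO:0016887"}, toy_dag)
        assert out.status == "accepted"

    def test_root_rejected_when_namespace_occupied(self, toy_dag):
        (out,) = refine_by_dag("t", [self.cand(BP_ROOT)], {"GO:0000003"}, toy_dag)
        assert out.status == "rejected-ancestor-of-original"

    def test_obsolete_flagged(self, toy_dag):
        (out,) = refine_by_dag("t", [self.cand("GO:0006200")], set(), toy_dag)
        assert out.status == "flagged-obsolete"

    def test_resolve_obsolete_reenters_replacement(self, toy_dag):
        cfg = EnrichmentConfig(resolve_obsolete=True)
        out = refine_by_dag("t", [self.cand("GO:0006200")], set(), toy_dag, cfg)
        statuses = {a.go_id: a.status for a in out}
        assert statuses["GO:0006200"] == "flagged-obsolete"
        assert statuses["GO:0016887"] == "accepted"

    def test_replacement_already_original_rejected_duplicate(self, toy_dag):
        # the obsolete-transfer case that yields no real enrichment: the
        # replacement is already among the originals
        cfg = EnrichmentConfig(resolve_obsolete=True)
        out = refine_by_dag("t", [self.cand("GO:0006200")], {"GO:0016887"}, toy_dag, cfg)
        statuses = {a.go_id: a.status for a in out}
        assert statuses["GO:0016887"] == "rejected-duplicate"

    def test_unknown_id_is_error(self, toy_dag):
        with pytest.raises(KeyError):
            refine_by_dag("t", [self.cand("GO:7777777")], set(), toy_dag)

    def test_order_invariance(self, toy_dag):
        cands = [self.cand(g) for g in ["GO:0000004", "GO:0000002", BP_ROOT, "GO:0000007"]]
        a = refine_by_dag("t", cands, {"GO:0000003"}, toy_dag)
        b = refine_by_dag("t", list(reversed(cands)), {"GO:0000003"}, toy_dag)
        assert a == b

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_never_accepts_ancestor_of_original(self, seed):
        """On random DAGs, no accepted term is an original or a proper
        ancestor of one."""
        dag, _ = generate_ontology(depth=3, branching=2, seed=seed)
        rng = np.random.default_rng(seed)
        live = sorted(t.id for t in dag.live_terms())
        original = set(rng.choice(live, size=3, replace=False).tolist())
        cands = [self.cand(g) for g in rng.choice(live, size=6, replace=False).tolist()]
        out = refine_by_dag("t", cands, original, dag)
        accepted = {a.go_id for a in out if a.status == "accepted"}
        assert accepted.isdisjoint(original)
        for t in original:
            assert accepted.isdisjoint(dag.ancestors(t))


class TestEnrichTarget:
    def fixture(self, toy_dag):
        """Hand-traced: size-3 clique (TAE + two group-2 species); both
        non-target genes carry c (GO:0000003); the target's originals are
        c's parent b plus one molecular_function term."""
        clique = make_clique({"TAE": "t", "ATA": "a", "HVU": "h"})
        ann = {
            "TAE": {"t": {"GO:0000002", "GO:0016887"}},
            "ATA": {"a": {"GO:0000003"}},
            "HVU": {"h": {"GO:0000003"}},
        }
        return clique, ann

    def test_hand_traced_summary(self, toy_dag):
        clique, ann = self.fixture(toy_dag)
        records, summary = enrich_target([clique], ann, toy_dag, GROUPS)
        by_go = {a.go_id: a for a in records}
        # c: 1/2 + 1/2 = 1.0, passes, deeper than b -> accepted
        assert by_go["GO:0000003"].status == "accepted"
        assert by_go["GO:0000003"].go_score == pytest.approx(1.0)
        assert by_go["GO:0000002"].status == "original"
        assert summary.n_genes_enriched == 1
        assert summary.n_genes_newly_annotated == 0
        assert summary.n_accepted == 1
        assert summary.n_original_assignments == 2
        assert summary.pct_increase == pytest.approx(50.0)
        assert summary.mean_accepted_score == pytest.approx(1.0)
        assert dict(summary.accepted_path_lengths) == {2: 1}

    def test_only_ancestor_candidate_nothing_accepted(self, toy_dag):
        clique = make_clique({"TAE": "t", "ATA": "a", "HVU": "h"})
        ann = {
            "TAE": {"t": {"GO:0000003"}},  # child
            "ATA": {"a": {"GO:0000002"}},  # parent only
            "HVU": {"h": {"GO:0000002"}},
        }
        _, summary = enrich_target([clique], ann, toy_dag, GROUPS)
        assert summary.n_accepted == 0
        assert summary.n_genes_enriched == 0

    def test_unannotated_gene_counted_as_newly_annotated(self, toy_dag):
        clique = make_clique({"TAE": "t", "ATA": "a", "HVU": "h"})
        ann = {
            "TAE": {},
            "ATA": {"a": {"GO:0000003"}},
            "HVU": {"h": {"GO:0000003"}},
        }
        _, summary = enrich_target([clique], ann, toy_dag, GROUPS)
        assert summary.n_accepted == 1
        assert summary.n_genes_newly_annotated == 1

    def test_multi_clique_keeps_max_score(self, toy_dag):
        c1 = make_clique({"TAE": "t", "ATA": "a1", "HVU": "h1"}, "C1")
        c2 = make_clique({sp: f"{sp}_g" if sp != "TAE" else "t" for sp in DEFAULT_GROUP_SCORES}, "C2")
        ann = {"TAE": {"t": set()}}
        ann["ATA"] = {"a1": {"GO:0000003"}, "ATA_g": {"GO:0000003"}}
        ann["HVU"] = {"h1": {"GO:0000003"}, "HVU_g": {"GO:0000003"}}
        for sp in set(DEFAULT_GROUP_SCORES) - {"TAE", "ATA", "HVU"}:
            ann[sp] = {f"{sp}_g": {"GO:0000003"}}
        records, _ = enrich_target([c1, c2], ann, toy_dag, GROUPS)
        accepted = [a for a in records if a.status == "accepted"]
        assert len(accepted) == 1
        # the size-10 clique's evidence (3.3166667) beats the size-3 one (1.0)
        assert accepted[0].go_score == pytest.approx(MAX_SCORE - 1.0)
        assert accepted[0].clique_id == "C2"

    def test_determinism(self, toy_dag):
        clique, ann = self.fixture(toy_dag)
        r1, _ = enrich_target([clique], ann, toy_dag, GROUPS)
        r2, _ = enrich_target([clique], ann, toy_dag, GROUPS)
        assert r1 == r2


class TestScoreHistogram:
    BINS = [(0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 4.5)]

    def rec(self, score, status):
        return ScoredAssignment("t", "GO:0000003", "C1", score, status)

    def test_hand_tallied(self):
        recs = [
            self.rec(0.5, "accepted"), self.rec(1.0, "accepted"),
            self.rec(1.5, "original"), self.rec(3.32, "accepted"),
            self.rec(4.32, "original"), self.rec(0.4, "rejected-below-threshold"),
        ]
        t = score_histogram(recs, self.BINS)
        assert t.loc["new", "[0,1]"] == 2  # 0.5 and 1.0 (right-closed)
        assert t.loc["new", "(3,4.5]"] == 1
        assert t.loc["original", "(1,2]"] == 1
        assert t.loc["original", "(3,4.5]"] == 1
        assert int(t.values.sum()) == 5  # rejected records are not binned

    def test_empty(self):
        t = score_histogram([], self.BINS)
        assert t.values.sum() == 0
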