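"""Gene classification: phenotype terms, canonical transcripts, paralogues,
X-inactivation consensus and the 10-subgroup pre-classification."""

import numpy as np
import pytest

from xprio.annotation import (AnnotationError, GeneRecord, ParalogueHit,
                              TranscriptModel, annotate_genes, consensus_xci,
                              flag_close_paralogues, load_phenotype_terms,
                              match_phenotype_terms, preclassify,
                              select_canonical_transcript, SUBGROUP_LABELS)

TERMS = {"intellectual_disability": ["intellectual disability"],
         "seizures": ["seizures"]}


class TestPhenotypeTerms:
    def test_empty_text_all_false(self):
        flags = match_phenotype_terms("", TERMS)
        assert not any(flags.values())

    def test_substring_match_case_insensitive(self):
        flags = match_phenotype_terms("Intellectual disability, severe", TERMS)
        assert flags["intellectual_disability"]
        assert flags["neurologic_any"]
        assert not flags["seizures"]

    def test_no_negation_handling(self):
        # documented limitation: substring matching cannot parse negation
        flags = match_phenotype_terms("no seizures reported", TERMS)
        assert flags["seizures"]

    def test_empty_term_list_rejected(self):
        with pytest.raises(AnnotationError):
            match_phenotype_terms("text", {"seizures": []})

    def test_packaged_term_lists_load(self):
        terms = load_phenotype_terms()
        assert "intellectual_disability" in terms
        assert all(terms.values())


def _tx(tid, mane=False, appris=False, length=500):
    return TranscriptModel(tid, "GENE", mane, appris, length)


class TestCanonicalTranscript:
    def test_mane_beats_longer_appris(self):
        mane = _tx("t1", mane=True, length=500)
        appris = _tx("t2", appris=True, length=900)
        assert select_canonical_transcript([mane, appris]) is mane

    def test_longest_appris(self):
        a, b = _tx("t1", appris=True, length=800), _tx("t2", appris=True, length=1200)
        assert select_canonical_transcript([a, b]) is b

    def test_single_unannotated_transcript_kept(self):
        only = _tx("t1")
        assert select_canonical_transcript([only]) is only

    def test_length_tie_breaks_on_id(self):
        a, b = _tx("tB", appris=True, length=700), _tx("tA", appris=True, length=700)
        assert select_canonical_transcript([a, b]) is b

    def test_permutation_invariance(self, rng):
        txs = [_tx(f"t{i}", appris=(i % 2 == 0), length=100 + 50 * i)
               for i in range(6)]
        picks = {select_canonical_transcript(list(rng.permutation(txs))).transcript_id
                 for _ in range(10)}
        assert len(picks) == 1

    def test_ambiguous_selection_raises(self):
        with pytest.raises(AnnotationError, match="GENE"):
            select_canonical_transcript([_tx("t1"), _tx("t2")])


class TestCloseParalogues:
    def test_empty_hits(self):
        assert flag_close_paralogues([]) == {}

    def test_single_outlier_flagged(self):
        hits = [ParalogueHit(f"g{i}", f"p{i}", 50, 50) for i in range(99)]
        hits.append(ParalogueHit("g_hot", "p_hot", 99.9, 99.9))
        flags = flag_close_paralogues(hits)
        assert flags["g_hot"]
        assert not any(v for k, v in flags.items() if k != "g_hot")

    def test_conjunction_required(self):
        hits = [ParalogueHit(f"g{i}", f"p{i}", float(i), float(99 - i))
                for i in range(100)]
        # g99 has target 99 (> 95th pct) but query 0 (below): not flagged
        assert not flag_close_paralogues(hits)["g99"]

    def test_matches_brute_force(self, rng):
        hits = [ParalogueHit(f"g{i % 40}", f"p{i}",
                             float(rng.uniform(0, 100)), float(rng.uniform(0, 100)))
                for i in range(200)]
        t_thr = np.percentile([h.target_pct for h in hits], 95)
        q_thr = np.percentile([h.query_pct for h in hits], 95)
        expected = {}
        for h in hits:
            expected[h.query] = expected.get(h.query, False) or (
                h.target_pct > t_thr and h.query_pct > q_thr)
        assert flag_close_paralogues(hits) == expected

    def test_percentile_bounds(self):
        with pytest.raises(AnnotationError):
            flag_close_paralogues([ParalogueHit("g", "p", 1, 1)], percentile=0)


class TestConsensusXci:
    @pytest.mark.parametrize("calls,expected", [
        (["escape"] * 6, "high_conf_escape"),
        (["escape"] * 5 + ["non_escape"], "high_conf_escape"),
        (["non_escape"] * 4 + ["escape"] * 2, "low_conf_non_escape"),
        (["escape"] * 3 + ["non_escape"] * 3, "discordant"),
        (["variable"] * 3 + ["escape"] * 2 + ["non_escape"], "variable"),
        (["escape"], "not_available"),
        ([], "not_available"),
    ])
    def test_categories(self, calls, expected):
        assert consensus_xci(calls) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(AnnotationError):
            consensus_xci(["escape", "maybe"])


def _gene(cls="confirmed", brain=True, tol=False):
    return GeneRecord(symbol="G", chromosome="X", tss=100, strand="+",
                      cds_intervals=[(200, 500)], disorder_class=cls,
                      brain_flag=None if cls == "no_disorder" else brain,
                      lof_tolerant=tol)


class TestPreclassify:
    def test_training_classes(self):
        assert preclassify([_gene("confirmed", True, False)])["G"] == "Cbi"
        assert preclassify([_gene("no_disorder", tol=True)])["G"] == "NDt"

    def test_pmt_nonbrain_tolerant(self):
        assert preclassify([_gene("PMT", False, True)])["G"] == "PMTnbt"

    def test_label_lattice_has_ten_labels(self):
        labels = set()
        for cls in ("confirmed", "PMT"):
            for brain in (True, False):
                for tol in (True, False):
                    labels.add(preclassify([_gene(cls, brain, tol)])["G"])
        for tol in (True, False):
            labels.add(preclassify([_gene("no_disorder", tol=tol)])["G"])
        assert labels == set(SUBGROUP_LABELS)
        assert len(labels) == 10

    def test_brain_flag_on_no_disorder_rejected(self):
        with pytest.raises(AnnotationError):
            GeneRecord(symbol="G", chromosome="X", tss=1, strand="+",
                       cds_intervals=[], disorder_class="no_disorder",
                       brain_flag=True, lof_tolerant=True)


class TestAnnotateGenes:
    def test_flags_and_subgroups(self, small_universe):
        ann = annotate_genes(small_universe.genes)
        assert set(ann["subgroup"]) <= set(SUBGROUP_LABELS)
        # no-disorder genes never carry phenotype flags
        nd = ann[ann["disorder_class"] == "no_disorder"]
        assert not nd["neurologic_any"].any()
        # brain-disorder genes with a synopsis match at least one term
        brainy = ann[(ann["clinical_synopsis"].fillna("") != "")]
        assert brainy["neurologic_any"].all()
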