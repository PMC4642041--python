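"""Sieve orchestration: orientation rules, training, pipeline behavior."""

from dataclasses import replace

import pytest

from grnsieve.crf_sieves import (Pipeline, PipelineConfig, orient_event,
                                 orient_interaction, sieve_gold_relations,
                                 train_sieve)
from grnsieve.cleaning import EntityKeyMap
from grnsieve.evaluation import assemble_network
from grnsieve.standoff_io import Relation, read_document, write_a1
from grnsieve.synthetic_corpus import (CorpusSpec, gene_lexicon_for,
                                       generate, gold_network)

SMALL_CFG = PipelineConfig(s_max=2, epochs=4, feature_groups="ABDEG")


@pytest.fixture(scope="module")
def small_pipeline():
    spec = CorpusSpec(n_docs=60, seed=21)
    docs, _ = generate(spec)
    pipe = Pipeline.train(docs[:45], config=SMALL_CFG,
                          gene_lexicon=gene_lexicon_for(spec))
    return pipe, docs[45:]


def _fresh(docs):
    return [read_document(d.text, write_a1(d), None, doc_id=d.doc_id)
            for d in docs]


def test_orient_event_sets_entity_subject(example_doc):
    rel = Relation(id="x", rtype="EVENT", agent="T6", target="T5",
                   directed=False)  # (transcribed, spoVG)
    ev = orient_event(rel, example_doc)
    assert example_doc.mention_by_id(ev.subject).surface == "spoVG"
    assert example_doc.mention_by_id(ev.object).surface == "transcribed"


def test_orient_event_with_levels_action(example_doc):
    rel = Relation(id="x", rtype="EVENT", agent="T3", target="T1",
                   directed=False)  # (levels, spo0H)
    ev = orient_event(rel, example_doc)
    assert example_doc.mention_by_id(ev.subject).surface == "spo0H"
    assert example_doc.mention_by_id(ev.object).surface == "levels"


def test_orient_event_rejects_two_actions(example_doc):
    rel = Relation(id="x", rtype="EVENT", agent="T3", target="T4",
                   directed=False)
    assert orient_event(rel, example_doc) is None


def test_passive_cue_makes_later_mention_the_agent(example_doc):
    # "spoVG, a gene transcribed by E sigma H"
    rel = Relation(id="x", rtype="Interaction.Transcription", agent="T5",
                   target="T7", directed=False)
    oriented = orient_interaction(rel, example_doc)
    assert oriented.directed
    assert example_doc.mention_by_id(oriented.agent).surface == "E sigma H"
    assert example_doc.mention_by_id(oriented.target).surface == "spoVG"


def test_active_clause_keeps_textual_order():
    from conftest import make_doc
    doc = make_doc(["GerE", "cotX"])
    rel = Relation(id="x", rtype="Interaction.Binding", agent="T2",
                   target="T1", directed=False)
    oriented = orient_interaction(rel, doc)
    assert doc.mention_by_id(oriented.agent).surface == "GerE"


def test_already_oriented_relation_unchanged(example_doc):
    rel = Relation(id="x", rtype="Interaction.Binding", agent="T7",
                   target="T1", directed=True)
    assert orient_interaction(rel, example_doc) is rel


def test_training_on_empty_corpus_rejected():
    with pytest.raises(ValueError):
        train_sieve([], "event")
    with pytest.raises(ValueError):
        Pipeline.train([], config=SMALL_CFG)


def test_event_gene_sieve_lifts_event_targets():
    """Event-mediated gold relations become gene-gene training pairs whose
    lifted argument is the event's subject gene."""
    spec = CorpusSpec(n_docs=40, seed=31)
    docs, _ = generate(spec)
    from grnsieve.preprocessing import annotate, mark_bsubtilis_genes
    total = 0
    for doc in docs:
        annotate(doc)
        mark_bsubtilis_genes(doc, gene_lexicon_for(spec), EntityKeyMap())
        ev_subjects = {doc.event_by_id(e.id).subject for e in doc.events}
        for rel in sieve_gold_relations(doc, "event_gene_rel"):
            total += 1
            a = doc.mention_by_id(rel.agent)
            t = doc.mention_by_id(rel.target)
            assert a.is_bsubtilis_gene and t.is_bsubtilis_gene
            assert rel.agent in ev_subjects or rel.target in ev_subjects
    assert total > 0, "corpus contains event-mediated relations"


def test_per_skip_models_are_independent(small_pipeline):
    """Retraining one sieve yields identical per-skip models (deterministic
    backend seed); the model at one skip does not depend on the others."""
    pipe, _held = small_pipeline
    spec = CorpusSpec(n_docs=60, seed=21)
    docs, _ = generate(spec)
    again = Pipeline.train(docs[:45], config=SMALL_CFG,
                           gene_lexicon=gene_lexicon_for(spec))
    for sieve_id, sm in pipe.sieve_models.items():
        other = again.sieve_models[sieve_id]
        for s, handle in sm.models.items():
            assert handle.emission == other.models[s].emission


def test_pipeline_with_no_sieves_changes_nothing(small_pipeline):
    pipe, held = small_pipeline
    empty = replace(pipe, sieve_models={},
                    config=replace(pipe.config, rules_enabled=False,
                                   cleaning=False))
    docs = _fresh(held)
    texts = [(d.doc_id, d.text) for d in docs]
    empty.predict(docs)
    assert all(d.relations == [] and d.events == [] for d in docs)
    assert [(d.doc_id, d.text) for d in docs] == texts


def test_sieves_only_add_relations_before_cleaning(small_pipeline):
    """Monotonicity: with cleaning off, every sieve's relations appear in
    the final set (no sieve deletes another's extractions)."""
    pipe, held = small_pipeline
    no_clean = replace(pipe, config=replace(pipe.config, cleaning=False))
    rules_only = replace(pipe, sieve_models={},
                         config=replace(pipe.config, cleaning=False))
    a, b = _fresh(held), _fresh(held)
    no_clean.predict(a)
    rules_only.predict(b)
    for da, db in zip(a, b):
        full = {(r.rtype, frozenset((r.agent, r.target)))
                for r in da.relations}
        rules = {(r.rtype, frozenset((r.agent, r.target)))
                 for r in db.relations}
        assert rules <= full


def test_sieve_vii_toggle_controls_bundle_and_prediction():
    spec = CorpusSpec(n_docs=40, seed=8)
    docs, _ = generate(spec)
    cfg = replace(SMALL_CFG, include_vii=True)
    pipe = Pipeline.train(docs, config=cfg,
                          gene_lexicon=gene_lexicon_for(spec))
    assert "event_gene_rel" in pipe.sieve_models
    off = Pipeline.train(docs, config=SMALL_CFG,
                         gene_lexicon=gene_lexicon_for(spec))
    assert "event_gene_rel" not in off.sieve_models
    with pytest.raises(ValueError, match="vii"):
        broken = replace(off, config=replace(off.config, include_vii=True))
        broken.predict(_fresh(docs[:2]))


def test_bundle_save_load_round_trip(small_pipeline, tmp_path):
    pipe, held = small_pipeline
    pipe.save(tmp_path / "bundle")
    again = Pipeline.load(tmp_path / "bundle")
    a, b = _fresh(held), _fresh(held)
    pipe.predict(a)
    again.predict(b)
    for da, db in zip(a, b):
        sig = lambda d: sorted((r.rtype, r.agent, r.target)
                               for r in d.relations)
        assert sig(da) == sig(db)


def test_small_end_to_end_recovery(small_pipeline):
    """Even a small training corpus recovers most of the held-out gold
    network (smoke-level sanity; the full check lives in acceptance)."""
    pipe, held = small_pipeline
    gold = gold_network(held)
    docs = _fresh(held)
    pipe.predict(docs)
    pred = assemble_network(docs, pipe.keymap)
    assert len(pred & gold) >= len(gold) * 0.5
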