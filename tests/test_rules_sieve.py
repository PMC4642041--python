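"""The four rule families and the default rule table."""

import random

import pytest

from grnsieve.preprocessing import annotate, mark_bsubtilis_genes
from grnsieve.cleaning import EntityKeyMap
from grnsieve.features import GeneLexicon
from grnsieve.rules_sieve import (RuleSpec, apply_consecutive,
                                  apply_list_consecutive,
                                  apply_mention_triplet, apply_rules,
                                  apply_sentence_consecutive, default_rules,
                                  load_rules, save_rules)
from grnsieve.standoff_io import Document, Mention
from grnsieve.synthetic_corpus import CorpusSpec, generate


def _doc(text, mentions, genes=()):
    doc = Document(doc_id="d", text=text)
    for i, (surface, mtype) in enumerate(mentions, 1):
        start = text.index(surface)
        doc.mentions.append(Mention(id=f"T{i}", mtype=mtype, start=start,
                                    end=start + len(surface),
                                    surface=surface))
    annotate(doc)
    lex = GeneLexicon(names=set(genes) or
                      {s for s, t in mentions if t != "Action"})
    mark_bsubtilis_genes(doc, lex, EntityKeyMap())
    return doc


def test_default_rule_table_has_twenty_rules():
    rules = default_rules()
    assert len(rules) == 20
    assert sum(r.family == "mention_triplet" for r in rules) == 1
    assert sum(r.family == "consecutive" for r in rules) == 13
    assert sum(r.family == "list_consecutive" for r in rules) == 4
    assert sum(r.family == "sentence_consecutive" for r in rules) == 2


def test_mention_triplet_transcription():
    doc = _doc("The rocG gene of Bacillus subtilis, encoding a catabolic "
               "glutamate dehydrogenase, is transcribed by SigL here.",
               [("rocG", "Gene"), ("transcribed", "Action"),
                ("SigL", "Protein")])
    rule = next(r for r in default_rules() if r.family == "mention_triplet")
    rels = apply_mention_triplet(doc, rule)
    assert len(rels) == 1
    rel = rels[0]
    assert rel.rtype == "Interaction.Transcription"
    # passive construction: the sigma factor after "by" acts
    assert doc.mention_by_id(rel.agent).surface == "SigL"
    assert doc.mention_by_id(rel.target).surface == "rocG"


def test_triplet_requires_action_in_the_middle():
    doc = _doc("rocG and cotD and SigL occur.",
               [("rocG", "Gene"), ("cotD", "Gene"), ("SigL", "Protein")])
    rule = next(r for r in default_rules() if r.family == "mention_triplet")
    assert apply_mention_triplet(doc, rule) == []


def test_consecutive_binds_to():
    doc = _doc("GerE binds to a site on one of these promoters, cotX, "
               "that overlaps the site.",
               [("GerE", "Protein"), ("cotX", "Gene")])
    rule = RuleSpec("consecutive", r".*binds.*to.*", "Interaction.Binding")
    rels = apply_consecutive(doc, rule)
    assert len(rels) == 1
    assert doc.mention_by_id(rels[0].agent).surface == "GerE"
    assert doc.mention_by_id(rels[0].target).surface == "cotX"


def test_consecutive_requires_matching_between_text():
    doc = _doc("GerE is unrelated to the gene cotX in this sentence.",
               [("GerE", "Protein"), ("cotX", "Gene")])
    rule = RuleSpec("consecutive", r".*binds to.*", "Interaction.Binding")
    assert apply_consecutive(doc, rule) == []


def test_passive_rule_inverts_agent_and_target():
    doc = _doc("cotD is negatively regulated by gerE in this cell.",
               [("cotD", "Gene"), ("gerE", "Protein")])
    rule = RuleSpec("consecutive", r".*is negatively regulated by.*",
                    "Interaction.Inhibition", passive=True)
    rels = apply_consecutive(doc, rule)
    assert doc.mention_by_id(rels[0].agent).surface == "gerE"
    assert doc.mention_by_id(rels[0].target).surface == "cotD"


def test_list_rule_extracts_two_relations():
    doc = _doc("the cotG promoter is induced under the control of the "
               "sigma K and the DNA-binding protein GerE.",
               [("cotG", "Gene"), ("sigma K", "Protein"),
                ("GerE", "Protein")])
    rule = next(r for r in default_rules()
                if r.family == "list_consecutive" and
                "control" in r.pattern)
    rels = apply_list_consecutive(doc, rule)
    assert len(rels) == 2
    agents = {doc.mention_by_id(r.agent).surface for r in rels}
    targets = {doc.mention_by_id(r.target).surface for r in rels}
    assert agents == {"sigma K", "GerE"} and targets == {"cotG"}


def test_list_rule_cartesian_product():
    doc = _doc("gerE and cotD are governed by sigK, sigE and sigB today.",
               [("gerE", "Gene"), ("cotD", "Gene"), ("sigK", "Gene"),
                ("sigE", "Gene"), ("sigB", "Gene")])
    rule = RuleSpec("list_consecutive", r".*governed by.*",
                    "Interaction.Activation", passive=True)
    rels = apply_list_consecutive(doc, rule)
    assert len(rels) == 6  # 2 targets x 3 agents
    assert {doc.mention_by_id(r.agent).surface for r in rels} == \
        {"sigK", "sigE", "sigB"}


def test_single_mention_sides_degenerate_to_consecutive():
    doc = _doc("cotG is induced under the control of sigK.",
               [("cotG", "Gene"), ("sigK", "Gene")])
    rule = next(r for r in default_rules()
                if r.family == "list_consecutive" and
                "control" in r.pattern)
    assert len(apply_list_consecutive(doc, rule)) == 1


def test_sentence_rule_removes_mention_free_subsentence():
    doc = _doc("The gerE factor turns on many genes, a process typical of "
               "late sporulation, and cotD.",
               [("gerE", "Protein"), ("cotD", "Gene")])
    rule = RuleSpec("sentence_consecutive", r".*turns on.*genes and.*",
                    "Interaction.Activation")
    rels = apply_sentence_consecutive(doc, rule)
    assert len(rels) == 1
    assert doc.mention_by_id(rels[0].agent).surface == "gerE"


def test_sentence_rule_never_removes_text_containing_mentions():
    """Subsentence removal keeps any comma segment that covers a mention
    (property checked on generated corpora)."""
    from grnsieve.rules_sieve import _removable_subsentences
    docs, _ = generate(CorpusSpec(n_docs=40, seed=5))
    for doc in docs:
        annotate(doc)
        for lo, hi in [(0, len(doc.text))]:
            for seg_lo, seg_hi in _removable_subsentences(doc, lo, hi):
                for m in doc.mentions:
                    assert m.end <= seg_lo or m.start >= seg_hi


def test_no_commas_behaves_like_consecutive():
    text = "gerE turns on cotD strongly."
    mentions = [("gerE", "Gene"), ("cotD", "Gene")]
    rule_s = RuleSpec("sentence_consecutive", r".*turns on.*",
                      "Interaction.Activation")
    rule_c = RuleSpec("consecutive", r".*turns on.*",
                      "Interaction.Activation")
    a = apply_sentence_consecutive(_doc(text, mentions), rule_s)
    b = apply_consecutive(_doc(text, mentions), rule_c)
    assert [(r.rtype,) for r in a] == [(r.rtype,) for r in b]
    assert len(a) == 1


def test_rules_do_not_match_across_sentences():
    doc = _doc("gerE turns on many genes. cotD is unrelated.",
               [("gerE", "Gene"), ("cotD", "Gene")])
    rule = RuleSpec("consecutive", r".*turns on.*",
                    "Interaction.Activation")
    assert apply_consecutive(doc, rule) == []


def test_rule_union_is_order_independent():
    docs, _ = generate(CorpusSpec(n_docs=25, seed=11))
    lex = GeneLexicon(names=set())
    from grnsieve.synthetic_corpus import gene_lexicon_for
    lex = gene_lexicon_for(CorpusSpec())
    rules = default_rules()
    rng = random.Random(3)
    for doc in docs:
        annotate(doc)
        mark_bsubtilis_genes(doc, lex, EntityKeyMap())
        ref = {(r.rtype, r.agent, r.target)
               for r in apply_rules(doc, rules)}
        shuffled = rules[:]
        rng.shuffle(shuffled)
        got = {(r.rtype, r.agent, r.target)
               for r in apply_rules(doc, shuffled)}
        assert got == ref


def test_empty_rule_list_is_a_no_op(example_doc):
    assert apply_rules(example_doc, []) == []


def test_malformed_regex_rejected():
    with pytest.raises(ValueError, match="bad regex"):
        RuleSpec("consecutive", r"*broken", "Interaction.Binding")


def test_unknown_family_rejected():
    with pytest.raises(ValueError):
        RuleSpec("nonsense", r".*", "Interaction.Binding")


def test_rule_config_round_trip(tmp_path):
    path = tmp_path / "rules.yaml"
    save_rules(default_rules(), path)
    again = load_rules(path)
    assert [(r.family, r.pattern, r.rtype, r.passive) for r in again] == \
        [(r.family, r.pattern, r.rtype, r.passive) for r in default_rules()]


def test_user_synonym_rule_applies_like_builtins():
    doc = _doc("gerE downmodulates cotD here.",
               [("gerE", "Gene"), ("cotD", "Gene")])
    rule = RuleSpec("consecutive", r".*downmodulates.*",
                    "Interaction.Inhibition")
    rels = apply_consecutive(doc, rule)
    assert len(rels) == 1 and rels[0].rtype == "Interaction.Inhibition"
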