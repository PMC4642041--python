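"""Feature templates, context similarity discretization and vocabulary."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnsieve.features import (Affix, ContextJaccard, GeneLexicon,
                               IsBSubtilisPair, PPITable, compile_templates,
                               extract_features, fit_vocabulary,
                               jaccard_level)
from grnsieve.skip_mention import build_mention_sequence

from conftest import make_doc


def test_prefix_of_mention_surface(example_doc):
    seq = build_mention_sequence(example_doc)
    i = [m.surface for m in seq.mentions].index("E sigma H")
    feats = Affix("prefix", 3, 0)(seq, i, example_doc)
    assert "pre[0,3]=E s" in feats


def test_suffix_of_mention_surface(example_doc):
    seq = build_mention_sequence(example_doc)
    feats = Affix("suffix", 2, 0)(seq, 0, example_doc)
    assert "suf[0,2]=0H" in feats


def test_boundary_marker_at_sequence_start(example_doc):
    seq = build_mention_sequence(example_doc)
    feats = Affix("prefix", 3, -1)(seq, 0, example_doc)
    assert "pre[-1,3]=<B>" in feats  # never an error


def test_feature_extraction_is_deterministic(example_doc):
    seq = build_mention_sequence(example_doc)
    templates = compile_templates("ABCDEFGH")
    a = extract_features(seq, 3, example_doc, templates)
    b = extract_features(seq, 3, example_doc, templates)
    assert a == b


def test_unknown_group_rejected():
    with pytest.raises(ValueError):
        compile_templates("AZ")


def test_group_subset_is_smaller_than_full():
    assert len(compile_templates("A")) < len(compile_templates("ABCDEFGH"))


def test_is_bsubtilis_pair_takes_exactly_one_value(example_doc):
    for m in example_doc.mentions:
        m.is_bsubtilis_gene = m.surface in ("spo0H", "spoVG")
    seq = build_mention_sequence(example_doc)
    template = IsBSubtilisPair()
    for i in range(len(seq)):
        feats = [f for f in template(seq, i, example_doc)]
        assert len(feats) == 1
        assert feats[0].split("=")[1] in ("left", "right", "both", "none")


def test_empty_ppi_table_emits_unknown(example_doc):
    for m in example_doc.mentions:
        m.is_bsubtilis_gene = m.mtype != "Action"
        m.entity_key = m.surface.lower()
    seq = build_mention_sequence(example_doc)
    from grnsieve.features import BSubtilisPPI
    feats = BSubtilisPPI(PPITable())(seq, 1, example_doc)
    assert "ppi=unknown" in feats


def test_ppi_score_thresholds_map_to_levels():
    assert PPITable.level_from_score(100) == "very low"
    assert PPITable.level_from_score(150) == "low"
    assert PPITable.level_from_score(500) == "medium"
    assert PPITable.level_from_score(750) == "high"
    assert PPITable.level_from_score(950) == "very high"


def test_gene_lexicon_is_case_insensitive():
    lex = GeneLexicon(names={"SpoVG", "sigma H"})
    assert lex.contains("spoVG") and lex.contains("SIGMA H")
    assert not lex.contains("rocG")


# -- Jaccard context discretization -----------------------------------------

def test_identical_windows_map_to_top_level():
    s = {"abc", "bcd", "cde"}
    assert jaccard_level(s, s) == 8


def test_disjoint_windows_map_to_bottom_level():
    assert jaccard_level({"abc"}, {"xyz"}) == 1


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.sets(st.text("ab", min_size=3, max_size=3), max_size=12),
       st.sets(st.text("ab", min_size=3, max_size=3), max_size=12),
       st.sets(st.text("ab", min_size=3, max_size=3), max_size=12))
def test_jaccard_level_monotone_in_overlap(a, b, extra):
    """Adding shared n-grams to both sides never lowers the level."""
    level = jaccard_level(a, b)
    assert 1 <= level <= 8
    grown = jaccard_level(a | extra, b | extra)
    if extra and not a and not b:
        assert grown == 8
    if a <= b and b <= a:
        assert level == 8


def test_jaccard_level_monotone_in_coefficient():
    # levels computed from increasing raw coefficients never decrease
    levels = []
    base = {f"g{i}" for i in range(8)}
    for k in range(9):
        other = {f"g{i}" for i in range(k)} | {f"x{i}" for i in range(8 - k)}
        levels.append(jaccard_level(base, other))
    assert levels == sorted(levels)


def test_context_template_emits_single_level(example_doc):
    seq = build_mention_sequence(example_doc)
    for variant in ContextJaccard.VARIANTS:
        feats = list(ContextJaccard(variant)(seq, 2, example_doc))
        assert len(feats) == 1 and feats[0].startswith(f"ctx[{variant}]=")


# -- vocabulary --------------------------------------------------------------

def _sequences(k):
    docs = [make_doc(["gerE", "cotD"], doc_id=f"d{i}") for i in range(k)]
    return [build_mention_sequence(d) for d in docs]


def test_min_count_filtering_boundary():
    templates = compile_templates("A")
    vocab5 = fit_vocabulary(_sequences(5), templates, min_count=5)
    assert "bias" in vocab5.retained  # fired 10 times across 5 docs
    vocab_high = fit_vocabulary(_sequences(4), templates, min_count=5)
    # every feature fired at most 2*4 = 8 times; mention-position features
    # fire exactly 4 times and must be dropped
    assert any("su[cur]" in f for f in vocab5.retained)
    per_position = [f for f in vocab_high.retained if "su2=" in f]
    assert per_position == []


def test_min_count_one_keeps_everything(example_doc):
    templates = compile_templates("AD")
    seq = build_mention_sequence(example_doc)
    vocab = fit_vocabulary([seq], templates, min_count=1)
    observed = set()
    for i in range(len(seq)):
        observed |= extract_features(seq, i, example_doc, templates)
    assert vocab.retained == observed


def test_min_count_below_one_rejected():
    with pytest.raises(ValueError):
        fit_vocabulary([], [], min_count=0)


def test_vocabulary_restricts_extraction(example_doc):
    templates = compile_templates("AD")
    seq = build_mention_sequence(example_doc)
    vocab = fit_vocabulary([seq], templates, min_count=3)
    feats = extract_features(seq, 2, example_doc, templates, vocab)
    assert feats <= vocab.retained
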