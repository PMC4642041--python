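"""Skip-mention construction, labeling and instantiation."""

import random
from dataclasses import replace

import pytest

from grnsieve.skip_mention import (build_mention_sequence, decompose,
                                   default_scheme, event_to_mention,
                                   gold_pairs_from_relations,
                                   instantiate_relations, label_sequences,
                                   merge_extractions)
from grnsieve.standoff_io import Event, Relation

from conftest import make_doc


EXPECTED_ORDER = ["spo0H", "sigma H", "levels", "expression", "spoVG",
                  "transcribed", "E sigma H"]


def test_zero_skip_sequence_of_example_sentence(example_doc):
    seq = build_mention_sequence(example_doc)
    assert [m.surface for m in seq.mentions] == EXPECTED_ORDER
    assert len(seq) == 7 and seq.s == 0


def test_gene_filter_keeps_subsequence(example_doc):
    for m in example_doc.mentions:
        m.is_bsubtilis_gene = m.surface in ("spo0H", "spoVG")
    seq = build_mention_sequence(example_doc, genes_only=True)
    assert [m.surface for m in seq.mentions] == ["spo0H", "spoVG"]


def test_empty_document_gives_empty_sequence():
    doc = make_doc([])
    assert len(build_mention_sequence(doc)) == 0


def test_one_skip_decomposition_matches_figure(example_doc):
    seq = build_mention_sequence(example_doc)
    parts = decompose(seq, 1)
    assert [m.surface for m in parts[0].mentions] == \
        ["spo0H", "levels", "spoVG", "E sigma H"]
    assert [m.surface for m in parts[1].mentions] == \
        ["sigma H", "expression", "transcribed"]


def test_zero_skip_decomposition_is_identity(example_doc):
    seq = build_mention_sequence(example_doc)
    parts = decompose(seq, 0)
    assert len(parts) == 1
    assert parts[0].mentions == seq.mentions


@pytest.mark.parametrize("n", [0, 1, 2, 5, 7, 12])
@pytest.mark.parametrize("s", [0, 1, 2, 3, 5, 10])
def test_decomposition_partitions_and_pair_count(n, s):
    doc = make_doc([f"g{i}" for i in range(n)])
    seq = build_mention_sequence(doc)
    parts = decompose(seq, s)
    assert len(parts) == s + 1
    pooled = sorted(m.id for p in parts for m in p.mentions)
    assert pooled == sorted(m.id for m in seq.mentions)
    pairs = sum(max(0, len(p) - 1) for p in parts)
    assert pairs == max(0, n - (s + 1))


def test_zero_skip_objective_sequence(example_doc):
    """The example sentence labels as [O, O, EVENT, O, EVENT, O,
    TranscriptionBy] at zero skip."""
    seq = build_mention_sequence(example_doc)
    gold = [Relation(id=e.id, rtype="EVENT", agent=e.subject,
                     target=e.object) for e in example_doc.events]
    gold += example_doc.relations
    pairs = gold_pairs_from_relations(seq, gold)
    labeled = label_sequences(decompose(seq, 0), pairs, default_scheme())
    assert labeled[0].labels == \
        ["O", "O", "EVENT", "O", "EVENT", "O", "TranscriptionBy"]


def test_distance_two_relation_labeled_only_at_one_skip(example_doc):
    seq = build_mention_sequence(example_doc)
    pairs = gold_pairs_from_relations(seq, [
        r for r in example_doc.relations
        if r.rtype == "Interaction.Transcription"])
    scheme = default_scheme()
    at0 = label_sequences(decompose(seq, 0), pairs, scheme)
    assert all(l == "O" for sq in at0 for l in sq.labels)
    at1 = label_sequences(decompose(seq, 1), pairs, scheme)
    # residue 0 holds [spo0H, levels, spoVG, E sigma H]
    assert at1[0].labels == ["O", "O", "O", "Interaction.Transcription"]
    assert all(l == "O" for l in at1[1].labels)


def test_no_gold_relations_gives_all_outside(example_doc):
    seq = build_mention_sequence(example_doc)
    labeled = label_sequences(decompose(seq, 2), [], default_scheme())
    assert all(l == "O" for sq in labeled for l in sq.labels)


def test_event_mention_ordering_and_identity(example_doc):
    ev = example_doc.events[1]  # (spoVG, expression)
    em = event_to_mention(ev, example_doc)
    expression = next(m for m in example_doc.mentions
                      if m.surface == "expression")
    assert em.start == expression.start  # ordered at the lowest argument
    assert em.surface == "expression spoVG"
    # two events sharing an action mention yield distinct proxies
    other = Event(id="E9", subject="T1", object="T4")
    example_doc.events.append(other)
    assert event_to_mention(other, example_doc).id != em.id


def test_event_mentions_interleaved_by_lowest_argument(example_doc):
    seq = build_mention_sequence(example_doc, event_mentions=True)
    surfaces = [m.surface for m in seq.mentions]
    assert surfaces.index("levels sigma H") == surfaces.index("sigma H") + 1
    assert surfaces.index("expression spoVG") == \
        surfaces.index("expression") + 1


def test_instantiation_inverts_labeling(example_doc):
    seq = build_mention_sequence(example_doc)
    scheme = default_scheme()
    labeled = label_sequences(
        decompose(seq, 1),
        gold_pairs_from_relations(seq, [example_doc.relations[1]]), scheme)
    rels = instantiate_relations(labeled, scheme)
    assert len(rels) == 1
    assert rels[0].rtype == "Interaction.Transcription"
    assert {rels[0].agent, rels[0].target} == {"T5", "T7"}
    assert not rels[0].directed


def test_all_outside_instantiates_nothing(example_doc):
    seq = build_mention_sequence(example_doc)
    labeled = label_sequences(decompose(seq, 3), [], default_scheme())
    assert instantiate_relations(labeled, default_scheme()) == []


@pytest.mark.parametrize("trial", range(40))
def test_label_instantiate_round_trip_on_random_gold_sets(trial):
    """label -> instantiate recovers exactly the gold pairs with argument
    distance <= s_max + 1, for s_max = 10."""
    rng = random.Random(1000 + trial)
    n = rng.randint(2, 16)
    doc = make_doc([f"g{i}" for i in range(n)])
    seq = build_mention_sequence(doc)
    scheme = default_scheme()
    rtypes = sorted(scheme.inventory() - {"O"})
    pairs = set()
    while len(pairs) < min(n, rng.randint(1, 6)):
        i, j = sorted(rng.sample(range(n), 2))
        pairs.add((i, j))
    gold = [(i, j, rtypes[rng.randrange(len(rtypes))]) for i, j in pairs]
    recovered = set()
    for s in range(11):
        labeled = label_sequences(decompose(seq, s), gold, scheme)
        for rel in instantiate_relations(labeled, scheme):
            a = seq.positions[[m.id for m in seq.mentions].index(rel.agent)]
            b = seq.positions[[m.id for m in seq.mentions].index(rel.target)]
            recovered.add((min(a, b), max(a, b), rel.rtype))
    expected = {(i, j, t) for (i, j, t) in gold if j - i <= 11}
    assert recovered == expected


def test_merge_collapses_duplicates_and_unions_provenance():
    a = Relation(id="1", rtype="Interaction.Binding", agent="T1",
                 target="T2", provenance=("gene_rel",), directed=False)
    b = replace(a, id="2", provenance=("rules.consecutive",))
    c = replace(a, id="3", agent="T2", target="T1")  # same unordered pair
    merged = merge_extractions([a, b, c, a])
    assert len(merged) == 1
    assert set(merged[0].provenance) == {"gene_rel", "rules.consecutive"}


def test_merge_keeps_conflicting_types():
    a = Relation(id="1", rtype="Interaction.Binding", agent="T1",
                 target="T2", directed=False)
    b = replace(a, id="2", rtype="Interaction.Inhibition")
    assert len(merge_extractions([a, b])) == 2


def test_merge_empty_is_empty():
    assert merge_extractions([]) == []
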