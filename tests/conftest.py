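"""Shared fixtures: the classic sporulation example sentence and helpers."""

from __future__ import annotations

import random

import pytest

from grnsieve.preprocessing import annotate
from grnsieve.standoff_io import Document, Event, Mention, Relation

#: A sentence from the sporulation literature with two events and one
#: transcription relation; its mention sequence is
#: [spo0H, sigma H, levels, expression, spoVG, transcribed, E sigma H].
SENTENCE = ("spo0H RNA and sigma H levels during growth are not identical "
            "to each other or to the pattern of expression of spoVG, a gene "
            "transcribed by E sigma H.")

_MENTION_SPECS = (
    ("spo0H", "Gene", "a1"),
    ("sigma H", "Protein", "a1"),
    ("levels", "Action", "a2"),
    ("expression", "Action", "a2"),
    ("spoVG", "Gene", "a1"),
    ("transcribed", "Action", "a2"),
    ("E sigma H", "PolymeraseComplex", "a1"),
)


def build_example_document() -> Document:
    doc = Document(doc_id="PMID-1898930-S9", text=SENTENCE)
    cursor = 0
    for i, (surface, mtype, source) in enumerate(_MENTION_SPECS, start=1):
        start = SENTENCE.index(surface, cursor)
        cursor = start + len(surface)
        doc.mentions.append(Mention(
            id=f"T{i}", mtype=mtype, start=start, end=cursor,
            surface=surface, source=source))
    # sigma H levels ...; the pattern of expression of spoVG
    doc.events.append(Event(id="E1", subject="T2", object="T3"))
    doc.events.append(Event(id="E2", subject="T5", object="T4"))
    # a gene transcribed by E sigma H  (adjacent-mention corpus label)
    doc.relations.append(Relation(id="R1", rtype="TranscriptionBy",
                                  agent="T6", target="T7",
                                  provenance=("gold",)))
    # spoVG ... E sigma H at mention distance 2
    doc.relations.append(Relation(id="R2", rtype="Interaction.Transcription",
                                  agent="T7", target="T5",
                                  provenance=("gold",)))
    doc.validate()
    return doc


@pytest.fixture
def example_doc() -> Document:
    return annotate(build_example_document())


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20130713)


def make_doc(surfaces: list[str], doc_id: str = "doc",
             mtypes: list[str] | None = None) -> Document:
    """Document whose text is the given mention surfaces joined by filler
    words, one mention per surface."""
    doc_text = []
    mentions = []
    pos = 0
    for i, s in enumerate(surfaces):
        if i:
            doc_text.append(" and ")
            pos += 5
        doc_text.append(s)
        mentions.append((pos, pos + len(s), s))
        pos += len(s)
    doc = Document(doc_id=doc_id, text="".join(doc_text))
    for i, (a, b, s) in enumerate(mentions, start=1):
        mtype = mtypes[i - 1] if mtypes else "Gene"
        doc.mentions.append(Mention(id=f"T{i}", mtype=mtype, start=a,
                                    end=b, surface=s))
    doc.validate()
    return annotate(doc)
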