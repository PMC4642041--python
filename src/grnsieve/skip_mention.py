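"""Skip-mention sequence construction, labeling and relation instantiation.

The central data transformation of the system: the ordered mentions of a
document form a *mention sequence*; decomposing it with skip number ``s``
yields ``s+1`` subsequences taking every ``(s+1)``-th mention, so that a
first-order linear sequence model can relate mentions that lie ``s``
mentions apart in the text.  A label at position ``i`` of a sequence encodes
a relation between the mention at ``i`` and its predecessor at ``i-1``;
position 0 is therefore always "O".
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

from .standoff_io import ConsistencyError, Document, Event, Mention, Relation

log = logging.getLogger(__name__)

OUTSIDE = "O"


@dataclass
class LabelScheme:
    """Bijective mapping between relation types and sequence labels.

    The default scheme maps each type to itself and includes both the
    ``Interaction.*`` inventory and the corpus-style spelling
    ``TranscriptionBy`` as distinct labels.
    """

    labels: dict[str, str] = field(default_factory=dict)  # rtype -> label

    def __post_init__(self):
        inv: dict[str, str] = {}
        for rtype, label in self.labels.items():
            if label == OUTSIDE:
                raise ValueError("the outside symbol cannot label a relation")
            if label in inv:
                raise ValueError(f"label {label!r} maps to both "
                                 f"{inv[label]!r} and {rtype!r}")
            inv[label] = rtype
        self._inverse = inv

    def label_of(self, rtype: str) -> str:
        try:
            return self.labels[rtype]
        except KeyError:
            raise KeyError(f"relation type {rtype!r} not in label scheme")

    def rtype_of(self, label: str) -> str:
        try:
            return self._inverse[label]
        except KeyError:
            raise KeyError(f"label {label!r} not in label scheme")

    def inventory(self) -> set[str]:
        return set(self._inverse) | {OUTSIDE}


def default_scheme(extra_rtypes: set[str] | None = None) -> LabelScheme:
    rtypes = {
        "EVENT",
        "Interaction.Regulation", "Interaction.Inhibition",
        "Interaction.Activation", "Interaction.Requirement",
        "Interaction.Binding", "Interaction.Transcription",
        "TranscriptionBy",
    }
    if extra_rtypes:
        rtypes |= extra_rtypes
    return LabelScheme(labels={r: r for r in sorted(rtypes)})


@dataclass
class MentionSequence:
    """Ordered mentions of one document at skip number ``s``.

    ``positions`` holds, for each element, its index in the document's
    zero-skip mention order, so that consecutive elements are exactly
    ``s+1`` apart.
    """

    doc: Document
    s: int
    residue: int
    mentions: list[Mention]
    positions: list[int]
    labels: list[str] | None = None

    @property
    def doc_id(self) -> str:
        return self.doc.doc_id

    def __len__(self) -> int:
        return len(self.mentions)


def _mention_sort_key(m: Mention) -> tuple[int, int, int]:
    # EventMention proxies tie-break after the co-located plain mention
    return (m.start, m.end, 1 if m.mtype == "EventMention" else 0)


def event_to_mention(ev: Event, doc: Document) -> Mention:
    """Map an event to a two-token EventMention proxy.

    The proxy's surface is "<action> <entity>" and its ordering position is
    determined by the lowest (earliest) of the two argument mentions.
    """
    subj = doc.mention_by_id(ev.subject)
    obj = doc.mention_by_id(ev.object)
    start = min(subj.start, obj.start)
    end = max(subj.end, obj.end)
    return Mention(
        id=f"EM_{ev.id}", mtype="EventMention", start=start, end=end,
        surface=f"{obj.surface} {subj.surface}", source="a2",
        token_start=(min(subj.token_start, obj.token_start)
                     if subj.token_start is not None and
                     obj.token_start is not None else None),
        token_end=(max(subj.token_end, obj.token_end)
                   if subj.token_end is not None and
                   obj.token_end is not None else None),
        entity_key=subj.entity_key,
        is_bsubtilis_gene=subj.is_bsubtilis_gene,
        event_id=ev.id)


def build_mention_sequence(doc: Document,
                           include_types: set[str] | None = None,
                           event_mentions: bool = False,
                           genes_only: bool = False) -> MentionSequence:
    """Build the zero-skip mention sequence of a document.

    ``include_types`` filters by mention type; ``genes_only`` keeps only
    mentions flagged as B. subtilis genes; ``event_mentions`` interleaves an
    EventMention proxy for each event at the position of its lowest argument.
    """
    chosen: list[Mention] = []
    for m in doc.mentions:
        if m.mtype == "EventMention":
            continue
        if include_types is not None and m.mtype not in include_types:
            continue
        if genes_only and not m.is_bsubtilis_gene:
            continue
        chosen.append(m)
    if event_mentions:
        for ev in doc.events:
            chosen.append(event_to_mention(ev, doc))
    chosen.sort(key=_mention_sort_key)
    return MentionSequence(doc=doc, s=0, residue=0, mentions=chosen,
                           positions=list(range(len(chosen))))


def decompose(seq: MentionSequence, s: int) -> list[MentionSequence]:
    """Decompose a zero-skip sequence into the ``s+1`` skip-mention sequences.

    Residue ``r`` takes original positions ``r, r+(s+1), r+2(s+1), ...``;
    empty residue sequences are included so the outputs always partition the
    input.
    """
    if seq.s != 0:
        raise ValueError("decompose expects a zero-skip sequence")
    if s < 0:
        raise ValueError("skip number must be non-negative")
    out = []
    step = s + 1
    for r in range(step):
        idx = list(range(r, len(seq), step))
        out.append(MentionSequence(
            doc=seq.doc, s=s, residue=r,
            mentions=[seq.mentions[i] for i in idx],
            positions=[seq.positions[i] for i in idx]))
    return out


GoldPair = tuple[int, int, str]  # (position_i, position_j, rtype) with i < j


def gold_pairs_from_relations(seq: MentionSequence,
                              relations: list[Relation]) -> list[GoldPair]:
    """Resolve gold relations to position pairs in a zero-skip sequence.

    Arguments are matched by mention id; relations whose arguments are not
    both in the sequence's mention universe raise :class:`ConsistencyError`.
    """
    pos_of = {m.id: p for m, p in zip(seq.mentions, seq.positions)}
    pairs: list[GoldPair] = []
    for rel in relations:
        if rel.agent not in pos_of or rel.target not in pos_of:
            raise ConsistencyError(
                f"{seq.doc_id}: relation {rel.id} argument not in the "
                "mention universe")
        i, j = sorted((pos_of[rel.agent], pos_of[rel.target]))
        if i == j:
            raise ConsistencyError(
                f"{seq.doc_id}: relation {rel.id} has coincident arguments")
        pairs.append((i, j, rel.rtype))
    return pairs


def label_sequences(seqs: list[MentionSequence], gold: list[GoldPair],
                    scheme: LabelScheme,
                    rtype_counts: Counter | None = None
                    ) -> list[MentionSequence]:
    """Write gold labels onto the skip-mention sequences of one skip number.

    A gold pair at positions ``i < j`` with ``j - i == s + 1`` labels the
    element holding position ``j`` in the residue-``i mod (s+1)`` sequence;
    pairs at any other distance are ignored at this ``s``.  When two gold
    pairs land on the same slot the relation whose type is rarer in training
    (per ``rtype_counts``) wins and the drop is logged.
    """
    out = []
    for seq in seqs:
        step = seq.s + 1
        labels = [OUTSIDE] * len(seq)
        claimed: dict[int, str] = {}
        for (i, j, rtype) in gold:
            if j - i != step or i % step != seq.residue:
                continue
            slot = (j - seq.residue) // step
            label = scheme.label_of(rtype)
            if slot in claimed and claimed[slot] != rtype:
                if rtype_counts is not None and \
                        rtype_counts[rtype] < rtype_counts[claimed[slot]]:
                    log.info("%s: label conflict at s=%d slot %d: keeping "
                             "rarer %s over %s", seq.doc_id, seq.s, slot,
                             rtype, claimed[slot])
                else:
                    log.info("%s: label conflict at s=%d slot %d: dropping "
                             "%s, keeping %s", seq.doc_id, seq.s, slot,
                             rtype, claimed[slot])
                    continue
            claimed[slot] = rtype
            labels[slot] = label
        if labels and labels[0] != OUTSIDE:
            raise AssertionError("position 0 can never carry a label")
        out.append(replace(seq, labels=labels))
    return out


def instantiate_relations(seqs: list[MentionSequence],
                          scheme: LabelScheme,
                          provenance: str = "crf") -> list[Relation]:
    """Instantiate one undirected candidate relation per non-"O" label,
    between the labeled mention and its predecessor in that sequence."""
    rels: list[Relation] = []
    n = 0
    for seq in seqs:
        if seq.labels is None:
            raise ValueError("sequence has no predicted labels")
        for k, label in enumerate(seq.labels):
            if label == OUTSIDE:
                continue
            rtype = scheme.rtype_of(label)
            if k == 0:
                log.warning("%s: label %s at position 0 ignored",
                            seq.doc_id, label)
                continue
            a, b = seq.mentions[k - 1], seq.mentions[k]
            n += 1
            rels.append(Relation(
                id=f"cand_{seq.s}_{seq.residue}_{n}", rtype=rtype,
                agent=a.event_id or a.id, target=b.event_id or b.id,
                provenance=(provenance,), directed=False))
    return rels


def merge_extractions(cands: list[Relation]) -> list[Relation]:
    """Collapse duplicate candidates (same unordered pair and type), keeping
    the union of their provenances.  Same pair with conflicting types stays:
    both are kept for the downstream direction/cleaning rules."""
    merged: dict[tuple[frozenset[str], str], Relation] = {}
    order: list[tuple[frozenset[str], str]] = []
    for rel in cands:
        key = (rel.arg_pair(), rel.rtype)
        if key in merged:
            old = merged[key]
            prov = tuple(dict.fromkeys(old.provenance + rel.provenance))
            merged[key] = replace(old, provenance=prov)
        else:
            merged[key] = rel
            order.append(key)
    return [merged[k] for k in order]


def distance_histogram(seqs: list[MentionSequence],
                       golds: list[list[GoldPair]]) -> Counter:
    """Histogram of gold-pair mention distances (diagnostic; the shape shows
    which skip numbers are needed to recover the corpus relations)."""
    hist: Counter = Counter()
    for pairs in golds:
        for (i, j, _rtype) in pairs:
            hist[j - i] += 1
    return hist
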