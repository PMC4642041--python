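"""BioNLP-ST-style standoff annotation I/O and the in-memory document model.

A corpus document is a plain-text file (``.txt``) plus two standoff files
that reference it by character offset: ``.a1`` carries the entity mentions
given with the corpus, ``.a2`` carries events and relations (and any
mentions, such as action words, that are part of the annotation rather than
the input).  Character offsets are 0-based half-open, the convention used by
the BioNLP shared tasks.

Line dialect accepted here::

    T1<TAB>Protein 0 5<TAB>spo0H
    E1<TAB>EVENT Subject:T2 Object:T3
    R1<TAB>Interaction.Transcription Agent:T7 Target:E1

Event and relation argument roles are written ``Subject``/``Object`` and
``Agent``/``Target`` respectively; the GRN corpus dialect is not fully
specified anywhere, so the writer documents and sticks to these names.
Discontinuous (multi-fragment) spans are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

#: Entity mention types of the GRN annotation scheme.
ENTITY_TYPES = frozenset({
    "Protein", "GeneFamily", "ProteinFamily", "ProteinComplex",
    "PolymeraseComplex", "Gene", "Operon", "mRNA", "Site", "Regulon",
    "Promoter",
})

#: Types an event subject may take (object is always an Action mention).
EVENT_SUBJECT_TYPES = frozenset({
    "Protein", "GeneFamily", "PolymeraseComplex", "Gene", "Operon", "mRNA",
    "Site", "Regulon", "Promoter",
})

#: Interaction relation types of the gene regulation network task.
INTERACTION_TYPES = frozenset({
    "Interaction.Regulation", "Interaction.Inhibition",
    "Interaction.Activation", "Interaction.Requirement",
    "Interaction.Binding", "Interaction.Transcription",
})


class StandoffError(Exception):
    """Base class for standoff parsing/serialization problems."""


class StandoffParseError(StandoffError):
    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


class SpanError(StandoffError):
    """A mention span falls outside the text or disagrees with it."""


class ConsistencyError(StandoffError):
    """An annotation references an identifier that does not resolve."""


class AlignmentError(StandoffError):
    """A mention boundary falls inside a token after tokenization."""


@dataclass
class Token:
    index: int
    start: int
    end: int
    surface: str
    pos: str | None = None
    lemma: str | None = None


@dataclass
class Mention:
    """A contiguous annotated span that can serve as a relation argument.

    ``source`` records which standoff file the mention belongs to ("a1" for
    corpus-given entities, "a2" for action mentions and other annotation-side
    mentions); EventMention instances are synthesized in memory only and are
    never serialized.
    """

    id: str
    mtype: str
    start: int
    end: int
    surface: str
    source: str = "a1"
    token_start: int | None = None
    token_end: int | None = None  # half-open token-index interval
    is_bsubtilis_gene: bool = False
    entity_key: str | None = None
    event_id: str | None = None   # set on EventMention proxies only

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def starts_upper(self) -> bool:
        return bool(self.surface) and self.surface[0].isupper()


@dataclass
class Event:
    """EVENT link between an entity mention (subject) and an Action mention."""

    id: str
    subject: str  # mention id of the entity
    object: str   # mention id of the Action mention


@dataclass
class Relation:
    """Typed link between two mention-or-event references.

    Until a direction rule runs, ``directed`` is False and agent/target hold
    the two arguments in textual order.
    """

    id: str
    rtype: str
    agent: str
    target: str
    provenance: tuple[str, ...] = ()
    directed: bool = True

    def arg_pair(self) -> frozenset[str]:
        return frozenset((self.agent, self.target))


@dataclass
class Document:
    doc_id: str
    text: str
    tokens: list[Token] = field(default_factory=list)
    sentences: list[tuple[int, int]] = field(default_factory=list)  # token ranges
    mentions: list[Mention] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)
    _id_counter: int = 0

    # -- lookup helpers -----------------------------------------------------
    def mention_by_id(self, mid: str) -> Mention:
        for m in self.mentions:
            if m.id == mid:
                return m
        raise ConsistencyError(f"{self.doc_id}: no mention with id {mid!r}")

    def event_by_id(self, eid: str) -> Event:
        for e in self.events:
            if e.id == eid:
                return e
        raise ConsistencyError(f"{self.doc_id}: no event with id {eid!r}")

    def has_id(self, ref: str) -> bool:
        return any(m.id == ref for m in self.mentions) or \
            any(e.id == ref for e in self.events)

    def fresh_id(self, prefix: str) -> str:
        self._id_counter += 1
        return f"{prefix}{self._id_counter}"

    def sorted_mentions(self) -> list[Mention]:
        return sorted(self.mentions, key=lambda m: (m.start, m.end, m.id))

    def validate(self) -> None:
        """Check the document invariants; raise on violation."""
        seen: set[str] = set()
        for m in self.mentions:
            if m.id in seen:
                raise ConsistencyError(f"duplicate identifier {m.id!r}")
            seen.add(m.id)
            if not (0 <= m.start <= m.end <= len(self.text)):
                raise SpanError(
                    f"mention {m.id} span {m.span} outside text of length "
                    f"{len(self.text)}")
            if self.text[m.start:m.end] != m.surface:
                raise SpanError(
                    f"mention {m.id}: covered text "
                    f"{self.text[m.start:m.end]!r} != surface {m.surface!r}")
        for e in self.events:
            if e.id in seen:
                raise ConsistencyError(f"duplicate identifier {e.id!r}")
            seen.add(e.id)
            subj = self.mention_by_id(e.subject)
            obj = self.mention_by_id(e.object)
            if obj.mtype != "Action":
                raise ConsistencyError(
                    f"event {e.id}: object {obj.id} has type {obj.mtype}, "
                    "expected Action")
            if subj.mtype not in EVENT_SUBJECT_TYPES and subj.mtype != "Action":
                warnings.warn(
                    f"event {e.id}: unusual subject type {subj.mtype}",
                    stacklevel=2)
        for r in self.relations:
            if r.id in seen:
                raise ConsistencyError(f"duplicate identifier {r.id!r}")
            seen.add(r.id)
            if r.agent == r.target:
                raise ConsistencyError(f"relation {r.id}: agent == target")
            for ref in (r.agent, r.target):
                if not self.has_id(ref):
                    raise ConsistencyError(
                        f"relation {r.id} references missing id {ref!r}")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _parse_t_line(fields: list[str], line_no: int, text: str) -> Mention:
    if len(fields) != 3:
        raise StandoffParseError(
            f"expected 3 tab-separated fields, got {len(fields)}", line_no)
    mid, middle, surface = fields
    parts = middle.split(" ")
    if ";" in middle:
        raise StandoffParseError(
            "discontinuous (multi-fragment) spans are not supported", line_no)
    if len(parts) != 3:
        raise StandoffParseError(f"malformed span field {middle!r}", line_no)
    mtype = parts[0]
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError:
        raise StandoffParseError(f"non-integer offsets in {middle!r}", line_no)
    if not (0 <= start < end <= len(text)):
        raise SpanError(
            f"line {line_no}: span {start}:{end} outside text of length "
            f"{len(text)}")
    if text[start:end] != surface:
        raise SpanError(
            f"line {line_no}: text at {start}:{end} is "
            f"{text[start:end]!r}, annotation says {surface!r}")
    if mtype not in ENTITY_TYPES and mtype != "Action":
        warnings.warn(
            f"line {line_no}: unknown mention type {mtype!r} passed through",
            stacklevel=3)
    return Mention(id=mid, mtype=mtype, start=start, end=end, surface=surface)


def _parse_args(spec: list[str], roles: tuple[str, str], line_no: int) -> tuple[str, str]:
    got: dict[str, str] = {}
    for item in spec:
        if ":" not in item:
            raise StandoffParseError(f"malformed argument {item!r}", line_no)
        role, ref = item.split(":", 1)
        got[role] = ref
    for role in roles:
        if role not in got:
            raise StandoffParseError(
                f"missing argument role {role!r} (have {sorted(got)})", line_no)
    return got[roles[0]], got[roles[1]]


def _parse_standoff(content: str, doc: Document, source: str) -> None:
    for line_no, raw in enumerate(content.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        ann_id = fields[0]
        if ann_id.startswith("T"):
            m = _parse_t_line(fields, line_no, doc.text)
            m.source = source
            doc.mentions.append(m)
        elif ann_id.startswith("E"):
            if len(fields) < 2:
                raise StandoffParseError("event line missing body", line_no)
            body = fields[1].split(" ")
            if body[0] != "EVENT":
                raise StandoffParseError(
                    f"expected EVENT type, got {body[0]!r}", line_no)
            subj, obj = _parse_args(body[1:], ("Subject", "Object"), line_no)
            doc.events.append(Event(id=ann_id, subject=subj, object=obj))
        elif ann_id.startswith("R"):
            if len(fields) < 2:
                raise StandoffParseError("relation line missing body", line_no)
            body = fields[1].split(" ")
            rtype = body[0]
            agent, target = _parse_args(body[1:], ("Agent", "Target"), line_no)
            doc.relations.append(Relation(
                id=ann_id, rtype=rtype, agent=agent, target=target,
                provenance=("gold",)))
        else:
            raise StandoffParseError(
                f"unrecognized annotation id {ann_id!r}", line_no)


def read_document(txt: str, a1: str, a2: str | None = None,
                  doc_id: str = "doc") -> Document:
    """Parse a text + standoff triple into a :class:`Document`.

    ``a2`` may be ``None`` or empty, in which case the document carries no
    events or relations.  All annotations are validated against the text;
    mentions are kept sorted by span so parsing is insensitive to line order.
    """
    doc = Document(doc_id=doc_id, text=txt)
    _parse_standoff(a1, doc, source="a1")
    if a2:
        _parse_standoff(a2, doc, source="a2")
    doc.mentions = doc.sorted_mentions()
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _canonical_order(doc: Document):
    """Renumber a2-side annotations in a canonical (span-sorted) order."""
    a2_mentions = [m for m in doc.sorted_mentions()
                   if m.source == "a2" and m.mtype != "EventMention"]
    # "TA" prefix keeps predicted-mention ids disjoint from .a1 ids
    mention_ids = {m.id: f"TA{i}" for i, m in enumerate(a2_mentions, 1)}

    def mention_pos(mid: str) -> tuple[int, int]:
        m = doc.mention_by_id(mid)
        return (m.start, m.end)

    events = sorted(doc.events, key=lambda e: (mention_pos(e.subject),
                                               mention_pos(e.object)))
    event_ids = {e.id: f"E{i}" for i, e in enumerate(events, 1)}

    def ref_pos(ref: str) -> tuple[int, int]:
        if ref in event_ids or any(e.id == ref for e in doc.events):
            e = doc.event_by_id(ref)
            return min(mention_pos(e.subject), mention_pos(e.object))
        return mention_pos(ref)

    relations = sorted(doc.relations,
                       key=lambda r: (ref_pos(r.agent), ref_pos(r.target),
                                      r.rtype))
    return a2_mentions, mention_ids, events, event_ids, relations


def write_predictions(doc: Document) -> str:
    """Serialize the a2-side annotation set (mentions, events, relations).

    Identifiers are renumbered in span order, so ``read ∘ write`` is the
    identity on the annotation multiset (up to ids).  A relation referencing
    an identifier absent from the document raises :class:`ConsistencyError`.
    """
    for r in doc.relations:
        for ref in (r.agent, r.target):
            if not doc.has_id(ref):
                raise ConsistencyError(
                    f"relation {r.id} references missing id {ref!r}")
    a2_mentions, mention_ids, events, event_ids, relations = \
        _canonical_order(doc)

    def rewrite(ref: str) -> str:
        return event_ids.get(ref, mention_ids.get(ref, ref))

    lines: list[str] = []
    for m in a2_mentions:
        lines.append(f"{mention_ids[m.id]}\t{m.mtype} {m.start} {m.end}\t"
                     f"{m.surface}")
    for e in events:
        lines.append(f"{event_ids[e.id]}\tEVENT Subject:{rewrite(e.subject)} "
                     f"Object:{rewrite(e.object)}")
    for i, r in enumerate(relations, 1):
        lines.append(f"R{i}\t{r.rtype} Agent:{rewrite(r.agent)} "
                     f"Target:{rewrite(r.target)}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_a1(doc: Document) -> str:
    """Serialize the corpus-side (entity) mentions as an .a1 file."""
    lines = [f"{m.id}\t{m.mtype} {m.start} {m.end}\t{m.surface}"
             for m in doc.sorted_mentions() if m.source == "a1"]
    return "\n".join(lines) + ("\n" if lines else "")
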