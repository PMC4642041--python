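"""Rule-based relation extraction sieve.

Four rule families operate per sentence, directly on the text with
recognized mentions:

* ``mention_triplet`` — consecutive mention triple (m1, a, m2) whose middle
  element is an Action mention starting with the rule pattern.
* ``consecutive`` — two consecutive B. subtilis gene mentions whose
  in-between text matches the pattern (no other gene mention between them;
  action and non-gene mentions may intervene).
* ``list_consecutive`` — like consecutive, but both sides may be lists of
  gene mentions separated by ",", ", and" or "and"; the cartesian product
  of left x right yields relations.
* ``sentence_consecutive`` — like consecutive after removing comma-delimited
  subsentences that contain no mention.

Each rule carries a target interaction type and a ``passive`` flag; by
default the earlier mention is the agent (active voice) and a passive rule
inverts the roles so the later mention acts.  Matching is case-insensitive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import yaml

from .standoff_io import Document, Mention, Relation

FAMILIES = ("mention_triplet", "consecutive", "list_consecutive",
            "sentence_consecutive")


@dataclass
class RuleSpec:
    family: str
    pattern: str
    rtype: str
    passive: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown rule family {self.family!r}")
        try:
            self.rx = re.compile(self.pattern, re.I | re.S)
        except re.error as exc:
            raise ValueError(
                f"rule ({self.family}, {self.pattern!r}): bad regex: {exc}")


# Default rule table.  Patterns and types follow the published defaults for
# this task; passive=True marks rows whose surface construction is passive,
# so that the agent is always the acting regulator.
DEFAULT_RULES: tuple[tuple[str, str, str, bool], ...] = (
    ("mention_triplet", "transcrib", "Interaction.Transcription", True),
    ("consecutive", r".*directs transcription.*", "Interaction.Transcription", False),
    ("consecutive", r".*inactivate.*", "Interaction.Inhibition", False),
    ("consecutive", r".*inhibits.*", "Interaction.Inhibition", False),
    ("consecutive", r".*repressor to.*", "Interaction.Inhibition", False),
    ("consecutive", r".*is negatively regulated by.*", "Interaction.Inhibition", True),
    ("consecutive", r".*is governed by.*", "Interaction.Activation", True),
    ("consecutive", r".*essential.*activat.*", "Interaction.Activation", True),
    ("consecutive", r".*to.*activat.*", "Interaction.Activation", False),
    ("consecutive", r".*turns on.*", "Interaction.Activation", False),
    ("consecutive", r".*requires.*", "Interaction.Requirement", True),
    ("consecutive", r".*required.*", "Interaction.Requirement", False),
    ("consecutive", r".*binds.*to.*", "Interaction.Binding", False),
    ("consecutive", r"-binding.*", "Interaction.Binding", False),
    ("list_consecutive", r".*under.*control.*of.*", "Interaction.Transcription", True),
    ("list_consecutive", r".*is governed by.*", "Interaction.Activation", True),
    ("list_consecutive", r".*represses.*", "Interaction.Inhibition", False),
    ("list_consecutive", r".*to repress.*", "Interaction.Inhibition", False),
    ("sentence_consecutive", r".*turns on.*", "Interaction.Activation", False),
    ("sentence_consecutive", r".*repressed.*", "Interaction.Inhibition", False),
)


def default_rules() -> list[RuleSpec]:
    return [RuleSpec(*row) for row in DEFAULT_RULES]


def load_rules(path) -> list[RuleSpec]:
    """Read a YAML rule config: a list of {family, pattern, type, passive}."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or []
    rules = []
    for i, row in enumerate(raw):
        try:
            rules.append(RuleSpec(
                family=row["family"], pattern=row["pattern"],
                rtype=row["type"], passive=bool(row.get("passive", False))))
        except (KeyError, TypeError) as exc:
            raise ValueError(f"rule {i}: malformed entry: {exc}")
    return rules


def save_rules(rules: list[RuleSpec], path) -> None:
    rows = [{"family": r.family, "pattern": r.pattern, "type": r.rtype,
             "passive": r.passive} for r in rules]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(rows, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# sentence scaffolding
# ---------------------------------------------------------------------------

def _sentence_char_ranges(doc: Document) -> list[tuple[int, int]]:
    if not doc.sentences or not doc.tokens:
        return [(0, len(doc.text))]
    out = []
    for a, b in doc.sentences:
        out.append((doc.tokens[a].start, doc.tokens[b - 1].end))
    return out


def _mentions_in(doc: Document, lo: int, hi: int,
                 predicate) -> list[Mention]:
    ms = [m for m in doc.mentions
          if m.mtype != "EventMention" and lo <= m.start and m.end <= hi
          and predicate(m)]
    ms.sort(key=lambda m: (m.start, m.end))
    return ms


def _is_entity(m: Mention) -> bool:
    return m.mtype not in ("Action", "EventMention")


def _is_gene(m: Mention) -> bool:
    return _is_entity(m) and m.is_bsubtilis_gene


def _make_relation(doc: Document, rule: RuleSpec, first: Mention,
                   second: Mention, provenance: str) -> Relation:
    agent, target = (second, first) if rule.passive else (first, second)
    return Relation(id=doc.fresh_id("Rrule"), rtype=rule.rtype,
                    agent=agent.id, target=target.id,
                    provenance=(provenance,), directed=True)


# ---------------------------------------------------------------------------
# rule families
# ---------------------------------------------------------------------------

def apply_mention_triplet(doc: Document, rule: RuleSpec) -> list[Relation]:
    """Consecutive mention triples (entity, action, entity) whose action
    surface starts with the rule pattern."""
    rels = []
    for lo, hi in _sentence_char_ranges(doc):
        ms = _mentions_in(doc, lo, hi, lambda m: True)
        for m1, a, m2 in zip(ms, ms[1:], ms[2:]):
            if a.mtype != "Action" or not (_is_entity(m1) and _is_entity(m2)):
                continue
            if rule.rx.match(a.surface):
                rels.append(_make_relation(doc, rule, m1, m2,
                                           "rules.mention_triplet"))
    return rels


def _consecutive_gene_pairs(doc: Document, lo: int, hi: int):
    genes = _mentions_in(doc, lo, hi, _is_gene)
    return list(zip(genes, genes[1:]))


def apply_consecutive(doc: Document, rule: RuleSpec) -> list[Relation]:
    """Consecutive gene-mention pairs whose in-between text matches."""
    rels = []
    for lo, hi in _sentence_char_ranges(doc):
        for a, b in _consecutive_gene_pairs(doc, lo, hi):
            between = doc.text[a.end:b.start]
            if rule.rx.search(between):
                rels.append(_make_relation(doc, rule, a, b,
                                           "rules.consecutive"))
    return rels


# delimiter linking two gene mentions into one list: a comma and/or "and",
# optionally followed by a short descriptor ("and the DNA-binding protein")
_LIST_DELIM = re.compile(
    r"^\s*(?:,|,?\s*and)\s*(?:(?:the|a|an)\s+)?(?:[\w().-]+\s+){0,3}$", re.I)


def _gene_lists(doc: Document, lo: int, hi: int) -> list[list[Mention]]:
    genes = _mentions_in(doc, lo, hi, _is_gene)
    groups: list[list[Mention]] = []
    for g in genes:
        if groups and _LIST_DELIM.match(doc.text[groups[-1][-1].end:g.start]):
            groups[-1].append(g)
        else:
            groups.append([g])
    return groups


def apply_list_consecutive(doc: Document, rule: RuleSpec) -> list[Relation]:
    """Adjacent gene-mention lists whose separating text matches: every
    left x right pair yields a relation."""
    rels = []
    for lo, hi in _sentence_char_ranges(doc):
        groups = _gene_lists(doc, lo, hi)
        for left, right in zip(groups, groups[1:]):
            between = doc.text[left[-1].end:right[0].start]
            if rule.rx.search(between):
                for a in left:
                    for b in right:
                        rels.append(_make_relation(
                            doc, rule, a, b, "rules.list_consecutive"))
    return rels


def _removable_subsentences(doc: Document, lo: int, hi: int
                            ) -> list[tuple[int, int]]:
    """Comma-delimited segments within [lo, hi) that contain no mention.

    Segments are the stretches between two commas; unpaired trailing
    segments are kept, and removal never touches text containing a mention.
    """
    commas = [m.start() for m in re.finditer(",", doc.text[lo:hi])]
    commas = [lo + c for c in commas]
    spans = []
    for a, b in zip(commas, commas[1:]):
        seg_lo, seg_hi = a, b + 1  # include both commas
        if any(m.start < seg_hi and m.end > seg_lo
               for m in doc.mentions if m.mtype != "EventMention"):
            continue
        spans.append((seg_lo, seg_hi))
    return spans


def apply_sentence_consecutive(doc: Document, rule: RuleSpec
                               ) -> list[Relation]:
    """Consecutive-pair matching after removing mention-free subsentences."""
    rels = []
    for lo, hi in _sentence_char_ranges(doc):
        removed = _removable_subsentences(doc, lo, hi)
        for a, b in _consecutive_gene_pairs(doc, lo, hi):
            pieces = []
            pos = a.end
            for seg_lo, seg_hi in removed:
                if seg_lo >= pos and seg_hi <= b.start:
                    pieces.append(doc.text[pos:seg_lo])
                    pos = seg_hi
            pieces.append(doc.text[pos:b.start])
            reduced = "".join(pieces)
            if rule.rx.search(reduced):
                rels.append(_make_relation(doc, rule, a, b,
                                           "rules.sentence_consecutive"))
    return rels


_APPLY = {
    "mention_triplet": apply_mention_triplet,
    "consecutive": apply_consecutive,
    "list_consecutive": apply_list_consecutive,
    "sentence_consecutive": apply_sentence_consecutive,
}


def apply_rules(doc: Document, rules: list[RuleSpec]) -> list[Relation]:
    """Apply every rule to a document; the result set is invariant to rule
    order (relations are deduplicated downstream)."""
    rels: list[Relation] = []
    for rule in rules:
        rels.extend(_APPLY[rule.family](doc, rule))
    return rels
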