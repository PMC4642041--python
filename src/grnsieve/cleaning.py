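"""Data cleaning sieve: remove relation loops and redundant duplicates.

A relation is a *loop* when both arguments refer to the same entity (e.g.,
"spo0H RNA" and "sigma H" both denoting sigH); loops are removed because
they can only contribute insertions.  Duplicate (agent, target, type)
triples are collapsed to one, merging provenances.  Cleaning is idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .standoff_io import Document, Relation

_SIGMA_RE = re.compile(r"^e?\s*sigma[\s(]*([a-z0-9]+)[)]?$")


@dataclass
class EntityKeyMap:
    """Deterministic mention-surface -> canonical gene key mapping.

    A synonym table (surface -> key, case-insensitive) is consulted first;
    sigma-factor conventions ("sigma H", "E sigma H" -> "sigh") are folded
    by rule; any unknown surface maps to itself lower-cased.  Keys are
    all lower-case so that casing variants collapse.
    """

    synonyms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.synonyms = {k.strip().lower(): v for k, v in
                         self.synonyms.items()}

    def canonical(self, surface: str) -> str:
        key = surface.strip().lower()
        if key in self.synonyms:
            return self.synonyms[key]
        m = _SIGMA_RE.match(key)
        if m:
            return "sig" + m.group(1)  # keys are all lower-case
        return key

    @classmethod
    def load(cls, path) -> "EntityKeyMap":
        """Two-column TSV: surface, canonical key."""
        synonyms = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                surface, key = line.split("\t")[:2]
                synonyms[surface] = key
        return cls(synonyms=synonyms)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for surface, key in sorted(self.synonyms.items()):
                fh.write(f"{surface}\t{key}\n")


def argument_key(doc: Document, ref: str, keymap: EntityKeyMap) -> str:
    """Canonical entity key of a relation argument (mention or event; an
    event resolves to its subject entity)."""
    if any(e.id == ref for e in doc.events):
        ev = doc.event_by_id(ref)
        ref = ev.subject
    m = doc.mention_by_id(ref)
    if m.entity_key:
        return m.entity_key
    return keymap.canonical(m.surface)


def remove_loops(rels: list[Relation], doc: Document,
                 keymap: EntityKeyMap) -> list[Relation]:
    """Drop relations whose two arguments share a canonical entity key."""
    kept = []
    for r in rels:
        if argument_key(doc, r.agent, keymap) != \
                argument_key(doc, r.target, keymap):
            kept.append(r)
    return kept


def remove_duplicates(rels: list[Relation], doc: Document,
                      keymap: EntityKeyMap) -> list[Relation]:
    """One relation per (agent key, target key, type); provenances merged.
    The same pair with different types is not a duplicate."""
    seen: dict[tuple[str, str, str], int] = {}
    out: list[Relation] = []
    for r in rels:
        key = (argument_key(doc, r.agent, keymap),
               argument_key(doc, r.target, keymap), r.rtype)
        if key in seen:
            i = seen[key]
            prov = tuple(dict.fromkeys(out[i].provenance + r.provenance))
            out[i] = replace(out[i], provenance=prov)
        else:
            seen[key] = len(out)
            out.append(r)
    return out


def clean(rels: list[Relation], doc: Document,
          keymap: EntityKeyMap) -> list[Relation]:
    return remove_duplicates(remove_loops(rels, doc, keymap), doc, keymap)
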