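"""Gene-network assembly and Slot Error Rate (SER) scoring.

Extracted relations are assembled into a directed, multi-relational gene
network whose nodes are canonical gene keys.  A predicted network is scored
against a reference with

    SER = (S + I + D) / N

where S counts substitutions (right ordered gene pair, wrong interaction
type), I insertions (predicted edges matching nothing), D deletions
(reference edges left unmatched), and N is the reference edge count.  A
prediction matches a reference edge only when the type and both arguments
agree; each reference edge is consumed at most once, exact matches first.
A perfect system scores 0; predicting nothing scores 1 (D = N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, NamedTuple

from .cleaning import EntityKeyMap, argument_key
from .standoff_io import Document, Relation

log = logging.getLogger(__name__)


class NetworkEdge(NamedTuple):
    agent: str
    target: str
    rtype: str


@dataclass
class SERResult:
    S: int
    I: int
    D: int
    M: int
    N: int

    @property
    def ser(self) -> Fraction:
        return ser_value(self.S, self.I, self.D, self.N)

    def __str__(self) -> str:
        return (f"S={self.S} I={self.I} D={self.D} M={self.M} N={self.N} "
                f"SER={float(self.ser):.2f}")


def ser_value(S: int, I: int, D: int, N: int) -> Fraction:
    """(S + I + D) / N as an exact rational."""
    if N <= 0:
        raise ValueError("SER is undefined for an empty reference (N = 0)")
    if min(S, I, D) < 0:
        raise ValueError("SER counters must be non-negative")
    return Fraction(S + I + D, N)


def assemble_network(docs: Iterable[Document],
                     keymap: EntityKeyMap | None = None,
                     relations: dict[str, list[Relation]] | None = None
                     ) -> set[NetworkEdge]:
    """Canonicalize and deduplicate directed relations into an edge set.

    Event arguments are lifted to their subject gene; relations with a
    non-gene argument after lifting are dropped with a log message.  EVENT
    relations themselves never enter the network.
    """
    keymap = keymap or EntityKeyMap()
    edges: set[NetworkEdge] = set()
    for doc in docs:
        rels = (relations or {}).get(doc.doc_id, doc.relations)
        for r in rels:
            if r.rtype == "EVENT":
                continue
            try:
                ok = True
                for ref in (r.agent, r.target):
                    mid = ref
                    if any(e.id == ref for e in doc.events):
                        mid = doc.event_by_id(ref).subject
                    m = doc.mention_by_id(mid)
                    if not m.is_bsubtilis_gene:
                        ok = False
                if not ok:
                    log.info("%s: dropping relation %s with non-gene "
                             "argument", doc.doc_id, r.id)
                    continue
                agent = argument_key(doc, r.agent, keymap)
                target = argument_key(doc, r.target, keymap)
            except Exception as exc:  # dangling reference
                log.warning("%s: dropping relation %s: %s", doc.doc_id,
                            r.id, exc)
                continue
            if agent == target:
                continue
            edges.add(NetworkEdge(agent, target, r.rtype))
    return edges


def score_ser(pred: set[NetworkEdge], ref: set[NetworkEdge],
              reversed_as_substitution: bool = False) -> SERResult:
    """Score a predicted network against a reference.

    Matching is greedy, exact matches first: M = |pred ∩ ref|; a remaining
    prediction whose ordered (agent, target) pair coincides with an
    unmatched reference edge of a different type is a substitution (each
    reference edge consumed once); with ``reversed_as_substitution`` a
    direction-flipped pair also counts as a substitution, otherwise it is
    an insertion.  Whatever remains is I (predictions) and D (references).
    """
    if not ref:
        raise ValueError("SER is undefined for an empty reference network")
    matched = pred & ref
    M = len(matched)
    open_pred = sorted(pred - matched)
    open_ref = set(ref) - matched

    S = 0
    for p in open_pred:
        hit = next((r for r in sorted(open_ref)
                    if (r.agent, r.target) == (p.agent, p.target)), None)
        if hit is None and reversed_as_substitution:
            hit = next((r for r in sorted(open_ref)
                        if (r.agent, r.target) == (p.target, p.agent)), None)
        if hit is not None:
            S += 1
            open_ref.discard(hit)
    I = len(open_pred) - S
    D = len(open_ref)
    return SERResult(S=S, I=I, D=D, M=M, N=len(ref))


# ---------------------------------------------------------------------------
# edge-list TSV I/O
# ---------------------------------------------------------------------------

def write_network(edges: set[NetworkEdge], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("agent\ttarget\ttype\n")
        for e in sorted(edges):
            fh.write(f"{e.agent}\t{e.target}\t{e.rtype}\n")


def read_network(path) -> set[NetworkEdge]:
    edges: set[NetworkEdge] = set()
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[:3] == ["agent", "target", "type"]:
                continue
            if len(parts) < 3:
                raise ValueError(f"line {line_no}: expected 3 columns")
            edges.add(NetworkEdge(parts[0], parts[1], parts[2]))
    return edges
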