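"""Synthetic standoff-annotated corpora with known gold annotations.

The generator emulates the structure of a gene-regulation corpus drawn from
sporulation literature: short sentences containing typed entity mentions,
action mentions (process words such as "expression", "transcribed"), EVENT
links between an entity and an action, and typed, directed interaction
relations between genes — at controllable mention distances.

Sentence templates declare their gold annotations exactly.  The roster
covers active and passive voice, event-mediated constructions and list
constructions ("... under the control of X and Y"), so both the sequence
sieves and every rule family are exercised.  Distances are controlled by
inserting non-gene protein mentions between the relation arguments; the
per-relation mention distance is drawn i.i.d. from the configured profile
(every sampled distance is realized exactly once, so the realized histogram
is a true multinomial sample).

Determinism: the same :class:`CorpusSpec` (including its seed) yields a
byte-identical corpus.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .cleaning import EntityKeyMap
from .evaluation import NetworkEdge
from .features import GeneLexicon
from .standoff_io import Document, Event, Mention, Relation

#: B. subtilis sporulation gene symbols (for realism in generated text).
DEFAULT_GENE_VOCAB = (
    "gerE", "cotD", "spoVG", "sigH", "rocG", "sigL", "cotX", "cotG",
    "sigK", "spoIIID", "sigE", "gerR", "spoIVFA", "spoIVFB", "yvyD", "sigB",
)

#: Non-gene protein names used as distance fillers (never in the lexicon).
FILLER_PROTEINS = ("YqzL", "CmpA", "SafA", "YabP", "KinA", "MedD")

INTERACTION_TYPES = (
    "Interaction.Regulation", "Interaction.Inhibition",
    "Interaction.Activation", "Interaction.Requirement",
    "Interaction.Binding", "Interaction.Transcription",
)

DEFAULT_TYPE_MIX = {
    "Interaction.Regulation": 0.10,
    "Interaction.Inhibition": 0.22,
    "Interaction.Activation": 0.20,
    "Interaction.Requirement": 0.18,
    "Interaction.Binding": 0.10,
    "Interaction.Transcription": 0.20,
}

#: Distances between relation arguments, in mentions (most pairs lie two
#: mentions apart in this kind of corpus).
DEFAULT_DISTANCE_PROFILE = {1: 0.35, 2: 0.40, 3: 0.25}


@dataclass
class CorpusSpec:
    n_docs: int = 100
    gene_vocab: tuple[str, ...] = DEFAULT_GENE_VOCAB
    template_names: tuple[str, ...] | None = None  # None = full roster
    distance_profile: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DISTANCE_PROFILE))
    distractor_rate: float = 0.2
    list_share: float = 0.2
    rare_share: float = 0.03  # total share of rare phrasings; each of the
    # three rare constructions then appears in ~1% of relation sentences,
    # too few for its features to clear the min-count filter — only the
    # rule sieve extracts these reliably
    type_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIX))
    seed: int = 13

    def __post_init__(self):
        if self.template_names is not None and not self.template_names:
            raise ValueError("template list must not be empty")
        total = sum(self.distance_profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("distance_profile must sum to 1")
        if any(d < 1 for d in self.distance_profile):
            raise ValueError("mention distances start at 1")


def gene_lexicon_for(spec: CorpusSpec) -> GeneLexicon:
    """Lexicon covering the vocabulary plus its sigma-factor spellings."""
    names = set(spec.gene_vocab)
    for g in spec.gene_vocab:
        if g.startswith("sig") and len(g) == 4:
            names.add(f"sigma {g[3].upper()}")
    return GeneLexicon(names=names)


# ---------------------------------------------------------------------------
# sentence building
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self):
        self.chunks: list[str] = []
        self.pos = 0
        self.mentions: list[Mention] = []
        self.events: list[tuple[int, int]] = []     # (subject, object) idx
        self.relations: list[tuple[object, object, str]] = []

    def text(self, s: str) -> None:
        self.chunks.append(s)
        self.pos += len(s)

    def mention(self, surface: str, mtype: str = "Gene",
                source: str = "a1") -> int:
        start = self.pos
        self.text(surface)
        self.mentions.append(Mention(
            id=f"tmp{len(self.mentions)}", mtype=mtype, start=start,
            end=self.pos, surface=surface, source=source))
        return len(self.mentions) - 1

    def fill(self, fillers: list[str]) -> None:
        """Insert non-gene protein mentions (distance padding)."""
        if not fillers:
            return
        for k, name in enumerate(fillers):
            # wording deliberately free of rule-pattern substrings
            self.text(", in concert with the " if k == 0 else
                      " and the ")
            self.mention(name, mtype="Protein")
            self.text(" protein" if k == 0 else " subunit")
        self.text(",")

    def event(self, subject: int, obj: int) -> int:
        self.events.append((subject, obj))
        return len(self.events) - 1

    def relation(self, agent, target, rtype: str) -> None:
        # agent/target: mention index or ("E", event index)
        self.relations.append((agent, target, rtype))


@dataclass
class Template:
    name: str
    rtype: str | None
    base_distance: int
    kind: str  # "single" | "list" | "distractor"
    build: object


def _gtype(rng: random.Random) -> str:
    return "Gene" if rng.random() < 0.7 else "Protein"


def _t_regulates(b, rng, genes, fillers):
    a = b.mention(genes[0], _gtype(rng))
    b.fill(fillers)
    b.text(" regulates ")
    t = b.mention(genes[1], _gtype(rng))
    b.text(" during sporulation.")
    b.relation(a, t, "Interaction.Regulation")


def _t_represses(b, rng, genes, fillers):
    a = b.mention(genes[0], _gtype(rng))
    b.fill(fillers)
    b.text(" represses ")
    t = b.mention(genes[1], _gtype(rng))
    b.text(" in the mother cell.")
    b.relation(a, t, "Interaction.Inhibition")


def _t_inhibits(b, rng, genes, fillers):
    a = b.mention(genes[0], _gtype(rng))
    b.fill(fillers)
    b.text(" strongly inhibits ")
    t = b.mention(genes[1], _gtype(rng))
    b.text(".")
    b.relation(a, t, "Interaction.Inhibition")


def _t_negreg(b, rng, genes, fillers):
    t = b.mention(genes[1], _gtype(rng))
    b.fill(fillers)
    b.text(" is negatively regulated by ")
    a = b.mention(genes[0], _gtype(rng))
    b.text(".")
    b.relation(a, t, "Interaction.Inhibition")


def _t_turnson(b, rng, genes, fillers):
    a = b.mention(genes[0], _gtype(rng))
    b.fill(fillers)
    b.text(" turns on ")
    t = b.mention(genes[1], _gtype(rng))
    b.text(" early during development.")
    b.relation(a, t, "Interaction.Activation")


def _t_governed_event(b, rng, genes, fillers):
    b.text("The ")
    act = b.mention("transcription", "Action", source="a2")
    b.text(" of ")
    t = b.mention(genes[1], _gtype(rng))
    b.fill(fillers)
    b.text(" is governed by ")
    a = b.mention(genes[0], _gtype(rng))
    b.text(" in the forespore.")
    e = b.event(t, act)
    b.relation(a, ("E", e), "Interaction.Activation")


def _t_requires_event(b, rng, genes, fillers):
    b.text("The ")
    act = b.mention("expression", "Action", source="a2")
    b.text(" of ")
    t = b.mention(genes[1], _gtype(rng))
    b.fill(fillers)
    b.text(" requires ")
    a = b.mention(genes[0], _gtype(rng))
    b.text(".")
    e = b.event(t, act)
    b.relation(a, ("E", e), "Interaction.Requirement")


def _t_required_event(b, rng, genes, fillers):
    a = b.mention(genes[0], _gtype(rng))
    b.fill(fillers)
    b.text(" is required for normal ")
    act = b.mention("expression", "Action", source="a2")
    b.text(" of ")
    t = b.mention(genes[1], _gtype(rng))
    b.text(".")
    e = b.event(t, act)
    b.relation(a, ("E", e), "Interaction.Requirement")


def _t_binds(b, rng, genes, fillers):
    a = b.mention(genes[0], _gtype(rng))
    b.fill(fillers)
    b.text(" binds directly to the ")
    t = b.mention(genes[1], _gtype(rng))
    b.text(" promoter.")
    b.relation(a, t, "Interaction.Binding")


def _t_directs(b, rng, genes, fillers):
    a = b.mention(genes[0], _gtype(rng))
    b.fill(fillers)
    b.text(" directs transcription of ")
    t = b.mention(genes[1], _gtype(rng))
    b.text(".")
    b.relation(a, t, "Interaction.Transcription")


def _t_transcribed(b, rng, genes, fillers):
    b.text("The ")
    t = b.mention(genes[1], _gtype(rng))
    b.text(" gene")
    b.fill(fillers)
    b.text(" is ")
    act = b.mention("transcribed", "Action", source="a2")
    b.text(" by ")
    a = b.mention(genes[0], _gtype(rng))
    b.text(" during sporulation.")
    b.event(t, act)
    b.relation(a, t, "Interaction.Transcription")


def _t_turnson_sentence(b, rng, genes, fillers):
    b.text("The ")
    a = b.mention(genes[0], _gtype(rng))
    b.text(" factor")
    b.fill(fillers)
    b.text(" turns on many genes, a process typical of late sporulation, "
           "and ")
    t = b.mention(genes[1], _gtype(rng))
    b.text(".")
    b.relation(a, t, "Interaction.Activation")


def _t_under_control_list(b, rng, genes, fillers):
    b.text("The ")
    t = b.mention(genes[2], _gtype(rng))
    b.text(" promoter")
    b.fill(fillers)
    b.text(" is induced under the control of ")
    a1 = b.mention(genes[0], _gtype(rng))
    b.text(" and the ")
    a2 = b.mention(genes[1], _gtype(rng))
    b.text(" protein.")
    b.relation(a1, t, "Interaction.Transcription")
    b.relation(a2, t, "Interaction.Transcription")


def _t_represses_list(b, rng, genes, fillers):
    a = b.mention(genes[0], _gtype(rng))
    b.fill(fillers)
    b.text(" represses both ")
    t1 = b.mention(genes[1], _gtype(rng))
    b.text(" and ")
    t2 = b.mention(genes[2], _gtype(rng))
    b.text(" in the forespore.")
    b.relation(a, t1, "Interaction.Inhibition")
    b.relation(a, t2, "Interaction.Inhibition")


def _t_repressor_to(b, rng, genes, fillers):
    a = b.mention(genes[0], _gtype(rng))
    b.fill(fillers)
    b.text(" acts as a repressor to ")
    t = b.mention(genes[1], _gtype(rng))
    b.text(".")
    b.relation(a, t, "Interaction.Inhibition")


def _t_inactivates(b, rng, genes, fillers):
    a = b.mention(genes[0], _gtype(rng))
    b.fill(fillers)
    b.text(" can inactivate ")
    t = b.mention(genes[1], _gtype(rng))
    b.text(" directly.")
    b.relation(a, t, "Interaction.Inhibition")


def _t_to_activate(b, rng, genes, fillers):
    a = b.mention(genes[0], _gtype(rng))
    b.fill(fillers)
    b.text(" must act to directly activate ")
    t = b.mention(genes[1], _gtype(rng))
    b.text(".")
    b.relation(a, t, "Interaction.Activation")


def _t_distractor_plain(b, rng, genes, fillers):
    b.text("Sporulation of Bacillus subtilis has been studied in detail "
           "for decades.")


def _t_distractor_pair(b, rng, genes, fillers):
    b.text("The chromosome encodes both ")
    b.mention(genes[0], _gtype(rng))
    b.text(" and ")
    b.mention(genes[1], _gtype(rng))
    b.text(".")


def _t_distractor_event(b, rng, genes, fillers):
    act = b.mention("Expression", "Action", source="a2")
    b.text(" of ")
    g = b.mention(genes[0], _gtype(rng))
    b.text(" was monitored throughout development.")
    b.event(g, act)


def _t_distractor_single(b, rng, genes, fillers):
    b.text("Mutant cells lacking ")
    b.mention(genes[0], _gtype(rng))
    b.text(" sporulate poorly.")


def _t_distractor_gap(b, rng, genes, fillers):
    b.mention(genes[0], _gtype(rng))
    b.text(" was characterized several years before ")
    b.mention(genes[1], _gtype(rng))
    b.text(".")


def _t_distractor_gap2(b, rng, genes, fillers):
    b.text("The locus encoding ")
    b.mention(genes[0], _gtype(rng))
    b.text(" maps far from that encoding ")
    b.mention(genes[1], _gtype(rng))
    b.text(".")


TEMPLATES: tuple[Template, ...] = (
    Template("regulates", "Interaction.Regulation", 1, "single",
             _t_regulates),
    Template("represses", "Interaction.Inhibition", 1, "single",
             _t_represses),
    Template("inhibits", "Interaction.Inhibition", 1, "single", _t_inhibits),
    Template("negreg", "Interaction.Inhibition", 1, "single", _t_negreg),
    Template("turnson", "Interaction.Activation", 1, "single", _t_turnson),
    Template("turnson_sentence", "Interaction.Activation", 1, "single",
             _t_turnson_sentence),
    Template("governed_event", "Interaction.Activation", 2, "single",
             _t_governed_event),
    Template("requires_event", "Interaction.Requirement", 2, "single",
             _t_requires_event),
    Template("required_event", "Interaction.Requirement", 1, "single",
             _t_required_event),
    Template("binds", "Interaction.Binding", 1, "single", _t_binds),
    Template("directs", "Interaction.Transcription", 1, "single",
             _t_directs),
    Template("transcribed", "Interaction.Transcription", 2, "single",
             _t_transcribed),
    Template("repressor_to", "Interaction.Inhibition", 1, "rare",
             _t_repressor_to),
    Template("inactivates", "Interaction.Inhibition", 1, "rare",
             _t_inactivates),
    Template("to_activate", "Interaction.Activation", 1, "rare",
             _t_to_activate),
    Template("under_control_list", "Interaction.Transcription", 1, "list",
             _t_under_control_list),
    Template("represses_list", "Interaction.Inhibition", 1, "list",
             _t_represses_list),
    Template("distractor_plain", None, 0, "distractor", _t_distractor_plain),
    Template("distractor_pair", None, 0, "distractor", _t_distractor_pair),
    Template("distractor_event", None, 0, "distractor", _t_distractor_event),
    Template("distractor_single", None, 0, "distractor",
             _t_distractor_single),
    Template("distractor_gap", None, 0, "distractor", _t_distractor_gap),
    Template("distractor_gap2", None, 0, "distractor", _t_distractor_gap2),
)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _weighted_choice(rng: random.Random, weights: dict) -> object:
    items = sorted(weights.items(), key=lambda kv: kv[0])
    r = rng.random() * sum(w for _k, w in items)
    acc = 0.0
    for k, w in items:
        acc += w
        if r < acc:
            return k
    return items[-1][0]


def _render_surface(rng: random.Random, gene: str) -> str:
    if gene.startswith("sig") and len(gene) == 4 and rng.random() < 0.25:
        return f"sigma {gene[3].upper()}"
    return gene


def _finish_document(doc_id: str, b: _Builder) -> Document:
    doc = Document(doc_id=doc_id, text="".join(b.chunks))
    a1_n = a2_n = 0
    for m in b.mentions:
        if m.source == "a1":
            a1_n += 1
            m.id = f"T{a1_n}"
        else:
            a2_n += 1
            m.id = f"TW{a2_n}"
        doc.mentions.append(m)
    for k, (subj, obj) in enumerate(b.events, 1):
        doc.events.append(Event(id=f"E{k}",
                                subject=b.mentions[subj].id,
                                object=b.mentions[obj].id))
    for k, (agent, target, rtype) in enumerate(b.relations, 1):
        def ref(x):
            if isinstance(x, tuple):
                return doc.events[x[1]].id
            return b.mentions[x].id
        doc.relations.append(Relation(id=f"R{k}", rtype=rtype,
                                      agent=ref(agent), target=ref(target),
                                      provenance=("gold",)))
    doc.mentions = doc.sorted_mentions()
    doc.validate()
    return doc


def generate(spec: CorpusSpec) -> tuple[list[Document], set[NetworkEdge]]:
    """Generate a corpus and its canonicalized gold network."""
    rng = random.Random(spec.seed)
    roster = [t for t in TEMPLATES
              if spec.template_names is None or t.name in spec.template_names]
    if not any(t.kind != "distractor" for t in roster):
        raise ValueError("template roster contains no relation templates")
    singles = [t for t in roster if t.kind == "single"]
    lists = [t for t in roster if t.kind == "list"]
    rares = [t for t in roster if t.kind == "rare"]
    distractors = [t for t in roster if t.kind == "distractor"]
    keymap = EntityKeyMap()

    pending: list[int] = []

    def next_d() -> int:
        if pending:
            return pending.pop()
        return _weighted_choice(rng, spec.distance_profile)

    docs: list[Document] = []
    edges: set[NetworkEdge] = set()
    for n in range(spec.n_docs):
        b = _Builder()
        use_distractor = distractors and rng.random() < spec.distractor_rate
        if use_distractor:
            t = distractors[rng.randrange(len(distractors))]
            genes = [_render_surface(rng, g) for g in
                     rng.sample(spec.gene_vocab, 2)]
            t.build(b, rng, genes, [])
        else:
            d1 = next_d()
            template: Template | None = None
            if rares and rng.random() < spec.rare_share:
                cands = [t for t in rares if t.base_distance <= d1]
                if cands:
                    template = cands[rng.randrange(len(cands))]
            if template is None and lists and \
                    rng.random() < spec.list_share:
                d2 = next_d()
                if d2 == d1 + 1:
                    template = lists[rng.randrange(len(lists))]
                else:
                    pending.append(d2)
            if template is None:
                rtype = _weighted_choice(rng, spec.type_mix)
                cands = [t for t in singles
                         if t.rtype == rtype and t.base_distance <= d1]
                if not cands:
                    cands = [t for t in singles if t.base_distance <= d1]
                template = cands[rng.randrange(len(cands))]
            n_fill = d1 - template.base_distance
            fillers = [FILLER_PROTEINS[rng.randrange(len(FILLER_PROTEINS))]
                       for _ in range(n_fill)]
            n_genes = 3 if template.kind == "list" else 2
            genes = [_render_surface(rng, g) for g in
                     rng.sample(spec.gene_vocab, n_genes)]
            template.build(b, rng, genes, fillers)
        doc = _finish_document(f"SYN-{n:04d}", b)
        docs.append(doc)
        for r in doc.relations:
            def key(ref: str) -> str:
                if any(e.id == ref for e in doc.events):
                    ref = doc.event_by_id(ref).subject
                return keymap.canonical(doc.mention_by_id(ref).surface)
            edges.add(NetworkEdge(key(r.agent), key(r.target), r.rtype))
    return docs, edges


def relation_distances(docs: list[Document]) -> list[int]:
    """Mention distances of gold relation argument pairs.

    Distance is measured in the all-mention (entities + actions) order of
    each document; an event argument sits at the position of its lowest
    mention, mirroring the event-to-mention mapping used by the sieves.
    """
    out: list[int] = []
    for doc in docs:
        order = {m.id: i for i, m in enumerate(doc.sorted_mentions())}

        def pos(ref: str) -> int:
            if any(e.id == ref for e in doc.events):
                e = doc.event_by_id(ref)
                return min(order[e.subject], order[e.object])
            return order[ref]

        for r in doc.relations:
            out.append(abs(pos(r.agent) - pos(r.target)))
    return out


def gold_network(docs: list[Document],
                 keymap: EntityKeyMap | None = None) -> set[NetworkEdge]:
    """Canonical gold edge set of already-generated (or parsed) documents."""
    keymap = keymap or EntityKeyMap()
    edges: set[NetworkEdge] = set()
    for doc in docs:
        for r in doc.relations:
            def key(ref: str) -> str:
                if any(e.id == ref for e in doc.events):
                    ref = doc.event_by_id(ref).subject
                return keymap.canonical(doc.mention_by_id(ref).surface)
            edges.add(NetworkEdge(key(r.agent), key(r.target), r.rtype))
    return edges
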