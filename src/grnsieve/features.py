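"""Feature templates evaluated at skip-mention sequence positions.

Each template maps ``(sequence, position, document)`` to a set of feature
strings; templates are deterministic and side-effect free, so identical
inputs always yield identical feature sets.  Templates are organised in
ablation groups A-H, from general to specific:

  A  label prior (bias) and basic surface/type indicators
  B  mention distance and Hearst-style co-occurrence patterns
  C  B. subtilis gene features (lexicon membership, STRING PPI level)
  D  prefix / suffix generators
  E  current-value and consequent-value generators
  F  context character-n-gram (Jaccard) generators
  G  previous/next combinations and left/right/between token values
  H  parse-tree features and split-to-values

A :class:`FeatureVocabulary` retains only features fired at least
``min_count`` times (default 5) on the fitting corpus.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .skip_mention import MentionSequence
from .standoff_io import Document, Mention

BOUNDARY = "<B>"          # emitted when an offset leaves the sequence
UNAVAILABLE = "<na>"      # emitted by templates whose annotator is absent


# ---------------------------------------------------------------------------
# external resources
# ---------------------------------------------------------------------------

PPI_LEVELS = ("very low", "low", "medium", "high", "very high")
#: STRING's conventional combined-score confidence tiers.
PPI_THRESHOLDS = (150, 400, 700, 900)


@dataclass
class PPITable:
    """Symmetric gene-pair -> interaction-score-level lookup."""

    scores: dict[frozenset[str], str] = field(default_factory=dict)

    @staticmethod
    def level_from_score(score: float) -> str:
        level = 0
        for t in PPI_THRESHOLDS:
            if score >= t:
                level += 1
        return PPI_LEVELS[level]

    def lookup(self, a: str, b: str) -> str | None:
        return self.scores.get(frozenset((a.lower(), b.lower())))

    @classmethod
    def load(cls, path) -> "PPITable":
        """Read a TSV of (geneA, geneB, score-or-level) rows."""
        scores: dict[frozenset[str], str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, b, value = line.split("\t")[:3]
                if value in PPI_LEVELS:
                    level = value
                else:
                    level = cls.level_from_score(float(value))
                scores[frozenset((a.lower(), b.lower()))] = level
        return cls(scores=scores)


@dataclass
class GeneLexicon:
    """Case-insensitive B. subtilis gene-name lexicon."""

    names: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.names = {n.lower() for n in self.names}

    def contains(self, surface: str) -> bool:
        return surface.strip().lower() in self.names

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for n in sorted(self.names):
                fh.write(n + "\n")

    @classmethod
    def load(cls, path) -> "GeneLexicon":
        with open(path, encoding="utf-8") as fh:
            return cls(names={l.strip() for l in fh if l.strip()})


# ---------------------------------------------------------------------------
# observable layers
# ---------------------------------------------------------------------------

LAYERS = ("text", "pos", "lemma", "etype", "coref")


def _mention_layer_value(doc: Document, m: Mention, layer: str) -> str:
    if layer == "text":
        return m.surface
    if layer == "etype":
        return m.mtype
    if layer == "coref":
        return UNAVAILABLE  # no coreference layer by default
    if m.token_start is None or m.token_end is None:
        return m.surface.lower() if layer == "lemma" else UNAVAILABLE
    toks = doc.tokens[m.token_start:m.token_end]
    if layer == "lemma":
        return " ".join(t.lemma or t.surface.lower() for t in toks)
    if layer == "pos":
        return " ".join(t.pos or UNAVAILABLE for t in toks)
    raise ValueError(f"unknown layer {layer!r}")


def _at(seq: MentionSequence, i: int) -> Mention | None:
    if 0 <= i < len(seq.mentions):
        return seq.mentions[i]
    return None


def _value(seq: MentionSequence, doc: Document, i: int, layer: str) -> str:
    m = _at(seq, i)
    if m is None:
        return BOUNDARY
    return _mention_layer_value(doc, m, layer)


def _between_text(doc: Document, a: Mention, b: Mention) -> str:
    lo, hi = min(a.end, b.end), max(a.start, b.start)
    if lo >= hi:
        return ""
    return doc.text[lo:hi]


# ---------------------------------------------------------------------------
# feature templates
# ---------------------------------------------------------------------------

class FeatureTemplate:
    """Base class: a named, parameterized, deterministic evaluator."""

    name = "template"
    group = "A"

    def __call__(self, seq: MentionSequence, i: int,
                 doc: Document) -> Iterable[str]:
        raise NotImplementedError


class Bias(FeatureTemplate):
    """Constant feature through which the backend learns the label prior
    (the target-label distribution)."""

    name = "bias"

    def __call__(self, seq, i, doc):
        return ("bias",)


class StartsUpper(FeatureTemplate):
    name = "starts_upper"

    def __init__(self, which: str):  # "cur" | "prev"
        self.which = which

    def __call__(self, seq, i, doc):
        m = _at(seq, i if self.which == "cur" else i - 1)
        if m is None:
            return (f"su[{self.which}]={BOUNDARY}",)
        return (f"su[{self.which}]={int(m.starts_upper())}",)


class StartsUpperTwice(FeatureTemplate):
    name = "starts_upper_twice"

    def __call__(self, seq, i, doc):
        prev, cur = _at(seq, i - 1), _at(seq, i)
        if prev is None or cur is None:
            return (f"su2={BOUNDARY}",)
        return (f"su2={int(prev.starts_upper() and cur.starts_upper())}",)


class MentionType(FeatureTemplate):
    name = "mention_type"

    def __init__(self, which: str):
        self.which = which

    def __call__(self, seq, i, doc):
        m = _at(seq, i if self.which == "cur" else i - 1)
        return (f"mt[{self.which}]={m.mtype if m else BOUNDARY}",)


DEFAULT_HEARST_PATTERNS: tuple[tuple[str, str], ...] = (
    ("such_as", r"\bsuch\s+as\b"),
    ("including", r"\bincluding\b"),
    ("especially", r"\bespecially\b"),
    ("and_other", r"\band\s+other\b"),
    ("or_other", r"\bor\s+other\b"),
    ("is_a", r"\bis\s+an?\b"),
    ("called", r"\bcalled\b"),
)


class Hearst(FeatureTemplate):
    """Does the text between the two mentions follow a co-occurrence
    pattern (e.g., "m_i such as m_j")?"""

    name = "hearst"
    group = "B"

    def __init__(self, patterns=DEFAULT_HEARST_PATTERNS):
        self.patterns = [(n, re.compile(p, re.I)) for n, p in patterns]

    def __call__(self, seq, i, doc):
        prev, cur = _at(seq, i - 1), _at(seq, i)
        if prev is None or cur is None:
            return (f"hearst={BOUNDARY}",)
        between = _between_text(doc, prev, cur)
        hits = [f"hearst={n}" for n, rx in self.patterns
                if rx.search(between)]
        return hits or ("hearst=none",)


class MentionDistance(FeatureTemplate):
    """Distance between the pair in number of mentions (s+1), plus a binned
    token distance."""

    name = "mention_distance"
    group = "B"
    _BINS = (1, 2, 3, 5, 8, 13)

    def __call__(self, seq, i, doc):
        feats = [f"mdist={seq.s + 1}"]
        prev, cur = _at(seq, i - 1), _at(seq, i)
        if prev is not None and cur is not None and \
                prev.token_end is not None and cur.token_start is not None:
            d = max(0, cur.token_start - prev.token_end)
            b = sum(1 for t in self._BINS if d >= t)
            feats.append(f"tokdist={b}")
        return feats


class ParseTreeDepth(FeatureTemplate):
    name = "parse_tree_depth"
    group = "H"

    def __call__(self, seq, i, doc):
        return (f"ptdepth={UNAVAILABLE}",)  # no parser installed


class ParseTreeParent(FeatureTemplate):
    name = "parse_tree_parent"
    group = "H"

    def __init__(self, l: int):
        self.l = l

    def __call__(self, seq, i, doc):
        return (f"ptparent[{self.l}]={UNAVAILABLE}",)


class ParseTreePath(FeatureTemplate):
    name = "parse_tree_path"
    group = "H"

    def __call__(self, seq, i, doc):
        return (f"ptpath={UNAVAILABLE}",)


class BSubtilisPPI(FeatureTemplate):
    """STRING-derived protein-protein interaction level of the pair."""

    name = "bsubtilis_ppi"
    group = "C"

    def __init__(self, ppi: PPITable | None):
        self.ppi = ppi or PPITable()

    def __call__(self, seq, i, doc):
        prev, cur = _at(seq, i - 1), _at(seq, i)
        if prev is None or cur is None:
            return (f"ppi={BOUNDARY}",)
        if not (prev.is_bsubtilis_gene and cur.is_bsubtilis_gene):
            return ("ppi=na",)
        level = self.ppi.lookup(prev.entity_key or prev.surface,
                                cur.entity_key or cur.surface)
        return (f"ppi={level or 'unknown'}",)


class IsBSubtilis(FeatureTemplate):
    name = "is_bsubtilis"
    group = "C"

    def __call__(self, seq, i, doc):
        m = _at(seq, i)
        return (f"isbs={int(bool(m and m.is_bsubtilis_gene))}",)


class IsBSubtilisPair(FeatureTemplate):
    """Which of the two consequent mentions is a B. subtilis gene:
    left, right, both or none (exactly one value per position)."""

    name = "is_bsubtilis_pair"
    group = "C"

    def __call__(self, seq, i, doc):
        prev, cur = _at(seq, i - 1), _at(seq, i)
        left = bool(prev and prev.is_bsubtilis_gene)
        right = bool(cur and cur.is_bsubtilis_gene)
        value = {(True, True): "both", (True, False): "left",
                 (False, True): "right", (False, False): "none"}[(left, right)]
        return (f"bspair={value}",)


class Affix(FeatureTemplate):
    """Prefix/suffix of the mention surface at an offset from position i."""

    group = "D"

    def __init__(self, kind: str, length: int, offset: int):
        self.kind, self.length, self.offset = kind, length, offset
        self.name = f"{kind}_value"

    def __call__(self, seq, i, doc):
        m = _at(seq, i + self.offset)
        if m is None:
            value = BOUNDARY
        elif self.kind == "prefix":
            value = m.surface[:self.length]
        else:
            value = m.surface[-self.length:]
        return (f"{self.kind[:3]}[{self.offset},{self.length}]={value}",)


class CurrentValue(FeatureTemplate):
    name = "current_value"
    group = "E"

    def __init__(self, offset: int, layer: str):
        self.offset, self.layer = offset, layer

    def __call__(self, seq, i, doc):
        v = _value(seq, doc, i + self.offset, self.layer)
        return (f"val[{self.offset},{self.layer}]={v}",)


class ConsequentValue(FeatureTemplate):
    """Combined values of two consequent mentions at an offset."""

    name = "consequent_value"
    group = "E"

    def __init__(self, offset: int, layer: str):
        self.offset, self.layer = offset, layer

    def __call__(self, seq, i, doc):
        a = _value(seq, doc, i + self.offset - 1, self.layer)
        b = _value(seq, doc, i + self.offset, self.layer)
        return (f"cv[{self.offset},{self.layer}]={a}|{b}",)


def _char_ngrams(text: str, n: int = 3) -> set[str]:
    text = re.sub(r"\s+", " ", text.strip().lower())
    if len(text) < n:
        return {text} if text else set()
    return {text[k:k + n] for k in range(len(text) - n + 1)}


def jaccard_level(a: set[str], b: set[str], levels: int = 8) -> int:
    """Discretize the Jaccard coefficient of two n-gram sets into
    ``levels`` equal-width bins (1 = disjoint ... ``levels`` = identical)."""
    if not a and not b:
        return levels
    union = len(a | b)
    j = len(a & b) / union if union else 0.0
    return min(levels, int(j * levels) + 1)


class ContextJaccard(FeatureTemplate):
    """Character-3-gram Jaccard similarity of the context windows of the
    previous and current mentions, for a given window variant."""

    name = "context_value"
    group = "F"
    VARIANTS = ("left", "right", "between", "outside", "union")

    def __init__(self, variant: str, span: int = 5, ngram: int = 3):
        if variant not in self.VARIANTS:
            raise ValueError(f"unknown context variant {variant!r}")
        self.variant, self.span, self.ngram = variant, span, ngram

    def _window(self, doc: Document, m: Mention, other: Mention,
                side: str) -> str:
        if m.token_start is None or m.token_end is None:
            return ""
        if side == "left":
            toks = doc.tokens[max(0, m.token_start - self.span):m.token_start]
        else:
            toks = doc.tokens[m.token_end:m.token_end + self.span]
        return " ".join(t.surface for t in toks)

    def _windows(self, doc, prev: Mention, cur: Mention) -> tuple[str, str]:
        v = self.variant
        if v == "left":
            return (self._window(doc, prev, cur, "left"),
                    self._window(doc, cur, prev, "left"))
        if v == "right":
            return (self._window(doc, prev, cur, "right"),
                    self._window(doc, cur, prev, "right"))
        if v == "between":
            # each mention's half of the in-between text
            between = _between_text(doc, prev, cur)
            mid = len(between) // 2
            return (between[:mid], between[mid:])
        if v == "outside":
            return (self._window(doc, prev, cur, "left"),
                    self._window(doc, cur, prev, "right"))
        # union of all context words around each mention
        return (self._window(doc, prev, cur, "left") + " " +
                self._window(doc, prev, cur, "right"),
                self._window(doc, cur, prev, "left") + " " +
                self._window(doc, cur, prev, "right"))

    def __call__(self, seq, i, doc):
        prev, cur = _at(seq, i - 1), _at(seq, i)
        if prev is None or cur is None:
            return (f"ctx[{self.variant}]={BOUNDARY}",)
        wa, wb = self._windows(doc, prev, cur)
        level = jaccard_level(_char_ngrams(wa, self.ngram),
                              _char_ngrams(wb, self.ngram))
        return (f"ctx[{self.variant}]=L{level}",)


class PrevNextCombo(FeatureTemplate):
    """Combination of the token values at a fixed token distance from the
    current and the previous mentions."""

    name = "prev_next_combo"
    group = "G"

    def __init__(self, distance: int, layer: str):
        self.distance, self.layer = distance, layer

    def _token_value(self, doc: Document, m: Mention | None) -> str:
        if m is None or m.token_start is None or m.token_end is None:
            return BOUNDARY
        if self.distance < 0:
            idx = m.token_start + self.distance
        else:
            idx = m.token_end - 1 + self.distance
        if not (0 <= idx < len(doc.tokens)):
            return BOUNDARY
        t = doc.tokens[idx]
        if self.layer == "text":
            return t.surface
        if self.layer == "lemma":
            return t.lemma or t.surface.lower()
        return t.pos or UNAVAILABLE

    def __call__(self, seq, i, doc):
        a = self._token_value(doc, _at(seq, i - 1))
        b = self._token_value(doc, _at(seq, i))
        return (f"pn[{self.distance},{self.layer}]={a}|{b}",)


class LeftRightBetween(FeatureTemplate):
    """Token values left/right of the two mentions or in between them.

    "left" and "right" are anchored at each of the two mentions; "between"
    indexes the gap tokens from both of its ends, so the tokens adjacent to
    either mention are observed however wide the gap is.
    """

    name = "lrb_value"
    group = "G"

    def __init__(self, side: str, distance: int, layer: str):
        if side not in ("left", "right", "between"):
            raise ValueError(f"unknown side {side!r}")
        self.side, self.distance, self.layer = side, distance, layer

    def _layer_of(self, t) -> str:
        if self.layer == "text":
            return t.surface
        if self.layer == "lemma":
            return t.lemma or t.surface.lower()
        return t.pos or UNAVAILABLE

    def __call__(self, seq, i, doc):
        prev, cur = _at(seq, i - 1), _at(seq, i)
        d, layer = self.distance, self.layer
        if prev is None or cur is None or prev.token_start is None or \
                cur.token_start is None:
            return (f"lrb[{self.side}.a,{d},{layer}]={BOUNDARY}",)
        if self.side == "left":
            anchors = (("a", prev.token_start - d),
                       ("b", cur.token_start - d))
        elif self.side == "right":
            anchors = (("a", prev.token_end - 1 + d),
                       ("b", cur.token_end - 1 + d))
        else:
            gap = range(prev.token_end, cur.token_start)
            anchors = (("a", gap[d - 1] if d <= len(gap) else -1),
                       ("b", gap[-d] if d <= len(gap) else -1))
        feats = []
        for tag, idx in anchors:
            name = f"lrb[{self.side}.{tag},{d},{layer}]"
            if not (0 <= idx < len(doc.tokens)):
                feats.append(f"{name}=<none>")
            else:
                feats.append(f"{name}={self._layer_of(doc.tokens[idx])}")
        return feats


class SplitToValues(FeatureTemplate):
    """Split the current mention by a delimiter class and emit the first N
    parts."""

    name = "split_to_values"
    group = "H"
    DELIMITER = re.compile(r"[-/\s]+")

    def __init__(self, layer: str, n: int = 2):
        self.layer, self.n = layer, n

    def __call__(self, seq, i, doc):
        m = _at(seq, i)
        if m is None:
            return (f"split[{self.layer},0]={BOUNDARY}",)
        value = _mention_layer_value(doc, m, self.layer)
        parts = [p for p in self.DELIMITER.split(value) if p][:self.n]
        return tuple(f"split[{self.layer},{k}]={p}"
                     for k, p in enumerate(parts)) or \
            (f"split[{self.layer},0]=<empty>",)


# ---------------------------------------------------------------------------
# compilation, extraction, vocabulary
# ---------------------------------------------------------------------------

ALL_GROUPS = "ABCDEFGH"


def compile_templates(groups: str = ALL_GROUPS,
                      ppi: PPITable | None = None,
                      gene_lexicon: GeneLexicon | None = None,
                      hearst_patterns=DEFAULT_HEARST_PATTERNS
                      ) -> list[FeatureTemplate]:
    """Instantiate the feature templates of the selected ablation groups
    over their full option grids."""
    unknown = set(groups.upper()) - set(ALL_GROUPS)
    if unknown:
        raise ValueError(f"unknown feature groups: {sorted(unknown)}")
    groups = groups.upper()
    templates: list[FeatureTemplate] = []

    if "A" in groups:
        templates.append(Bias())
        templates.append(StartsUpper("cur"))
        templates.append(StartsUpper("prev"))
        templates.append(StartsUpperTwice())
        templates.append(MentionType("cur"))
        templates.append(MentionType("prev"))
    if "B" in groups:
        templates.append(Hearst(hearst_patterns))
        templates.append(MentionDistance())
    if "C" in groups:
        templates.append(BSubtilisPPI(ppi))
        templates.append(IsBSubtilis())
        templates.append(IsBSubtilisPair())
    if "D" in groups:
        for kind in ("prefix", "suffix"):
            for length in (2, 3):
                for offset in range(-5, 6):
                    templates.append(Affix(kind, length, offset))
    if "E" in groups:
        for offset in range(-4, 5):
            for layer in LAYERS:
                templates.append(CurrentValue(offset, layer))
                templates.append(ConsequentValue(offset, layer))
    if "F" in groups:
        for variant in ContextJaccard.VARIANTS:
            templates.append(ContextJaccard(variant))
    if "G" in groups:
        for distance in (-2, 2):
            for layer in ("text", "pos", "lemma"):
                templates.append(PrevNextCombo(distance, layer))
        for side in ("left", "right", "between"):
            for distance in range(1, 6):
                for layer in ("text", "pos", "lemma"):
                    templates.append(LeftRightBetween(side, distance, layer))
    if "H" in groups:
        templates.append(ParseTreeDepth())
        for l in (1, 2, 3):
            templates.append(ParseTreeParent(l))
        templates.append(ParseTreePath())
        for layer in ("text", "lemma"):
            templates.append(SplitToValues(layer))
    return templates


def extract_features(seq: MentionSequence, i: int, doc: Document,
                     templates: list[FeatureTemplate],
                     vocabulary: "FeatureVocabulary | None" = None
                     ) -> frozenset[str]:
    """Union of all template evaluations at one position, optionally
    restricted to a fitted vocabulary."""
    if not (0 <= i < len(seq)):
        raise IndexError(f"position {i} outside sequence of length {len(seq)}")
    feats: set[str] = set()
    for t in templates:
        feats.update(t(seq, i, doc))
    if vocabulary is not None:
        feats &= vocabulary.retained
    return frozenset(feats)


@dataclass
class FeatureVocabulary:
    retained: frozenset[str]
    min_count: int = 5


def fit_vocabulary(train_seqs: list[MentionSequence],
                   templates: list[FeatureTemplate],
                   min_count: int = 5) -> FeatureVocabulary:
    """Count feature occurrences over all positions of the training
    sequences and retain those fired at least ``min_count`` times."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: Counter = Counter()
    for seq in train_seqs:
        for i in range(len(seq)):
            counts.update(extract_features(seq, i, seq.doc, templates))
    retained = frozenset(f for f, c in counts.items() if c >= min_count)
    return FeatureVocabulary(retained=retained, min_count=min_count)
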