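"""Sentence splitting, tokenization, lemmatization and action-mention detection.

Linguistic annotators are pluggable: an :class:`AnnotatorSet` bundles a
sentence splitter, tokenizer, POS tagger, lemmatizer and constituency
parser, any of which may be absent.  The defaults are lightweight and
model-free — a regex tokenizer that additionally splits at mention
boundaries (so every gold mention aligns to a whole-token range), a
punctuation-based sentence splitter, and a lower-casing lemmatizer.  An
absent parser only disables parse-tree feature templates, never the
pipeline.

Action mentions (process words such as "expression", "transcribed") are not
part of the corpus-given entity set; they are detected by exact matching of
lemmas collected from the training data's gold Action mentions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable

from .standoff_io import AlignmentError, Document, Mention, Token

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")
_SENT_RE = re.compile(r"(?<=[.!?])\s+")


def default_tokenizer(text: str) -> list[tuple[int, int]]:
    """Whitespace/punctuation tokenizer returning character spans."""
    return [(m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def default_sentence_splitter(text: str) -> list[tuple[int, int]]:
    """Split at sentence-final punctuation; returns character ranges."""
    bounds = [0]
    for m in _SENT_RE.finditer(text):
        bounds.append(m.end())
    bounds.append(len(text))
    out = []
    for a, b in zip(bounds, bounds[1:]):
        if text[a:b].strip():
            out.append((a, b))
    return out or [(0, len(text))]


def default_lemmatizer(surface: str) -> str:
    # stand-in lemma: the lower-cased surface form
    return surface.lower()


@dataclass
class AnnotatorSet:
    sentence_splitter: Callable[[str], list[tuple[int, int]]] | None = \
        default_sentence_splitter
    tokenizer: Callable[[str], list[tuple[int, int]]] | None = \
        default_tokenizer
    pos_tagger: Callable[[list[str]], list[str]] | None = None
    lemmatizer: Callable[[str], str] | None = default_lemmatizer
    parser: Callable[[list[str]], object] | None = None


DEFAULT_ANNOTATORS = AnnotatorSet()


def _split_at_boundaries(spans: list[tuple[int, int]],
                         boundaries: set[int]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for start, end in spans:
        cuts = sorted(b for b in boundaries if start < b < end)
        prev = start
        for c in cuts:
            out.append((prev, c))
            prev = c
        out.append((prev, end))
    return out


def annotate(doc: Document, ann: AnnotatorSet | None = None) -> Document:
    """Tokenize, sentence-split and lemmatize a document in place.

    Tokens cover all non-whitespace text and are split at every mention
    boundary so that each mention maps to a whole-token range; a mention
    boundary that still falls inside a token raises :class:`AlignmentError`.
    The operation is a pure function of (text, mention spans) and therefore
    idempotent.
    """
    ann = ann or DEFAULT_ANNOTATORS
    tokenizer = ann.tokenizer or default_tokenizer
    spans = tokenizer(doc.text)
    boundaries = {m.start for m in doc.mentions} | {m.end for m in doc.mentions}
    spans = _split_at_boundaries(spans, boundaries)
    spans = [(a, b) for a, b in spans if doc.text[a:b].strip()]
    spans.sort()

    lemmatize = ann.lemmatizer or default_lemmatizer
    doc.tokens = [
        Token(index=i, start=a, end=b, surface=doc.text[a:b],
              lemma=lemmatize(doc.text[a:b]))
        for i, (a, b) in enumerate(spans)
    ]
    if ann.pos_tagger is not None:
        tags = ann.pos_tagger([t.surface for t in doc.tokens])
        for t, tag in zip(doc.tokens, tags):
            t.pos = tag

    splitter = ann.sentence_splitter or default_sentence_splitter
    char_sents = splitter(doc.text)
    doc.sentences = []
    for a, b in char_sents:
        idx = [t.index for t in doc.tokens if t.start >= a and t.end <= b]
        if idx:
            doc.sentences.append((idx[0], idx[-1] + 1))

    starts = {t.start: t.index for t in doc.tokens}
    ends = {t.end: t.index for t in doc.tokens}
    for m in doc.mentions:
        if m.mtype == "EventMention":
            continue
        if m.start not in starts or m.end not in ends:
            raise AlignmentError(
                f"{doc.doc_id}: mention {m.id} {m.surface!r} does not align "
                "to token boundaries")
        m.token_start = starts[m.start]
        m.token_end = ends[m.end] + 1
    return doc


def sentence_of_token(doc: Document, token_index: int) -> tuple[int, int]:
    for a, b in doc.sentences:
        if a <= token_index < b:
            return (a, b)
    return (0, len(doc.tokens))


# ---------------------------------------------------------------------------
# action lexicon
# ---------------------------------------------------------------------------

@dataclass
class ActionLexicon:
    """Set of action-mention lemma strings (multi-token lemmas are space
    joined and matched against sliding token windows of the same length)."""

    lemmas: set[str] = field(default_factory=set)

    def __contains__(self, lemma: str) -> bool:
        return lemma in self.lemmas

    def __len__(self) -> int:
        return len(self.lemmas)

    def window_lengths(self) -> list[int]:
        return sorted({len(l.split(" ")) for l in self.lemmas}, reverse=True)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for lemma in sorted(self.lemmas):
                fh.write(lemma + "\n")

    @classmethod
    def load(cls, path) -> "ActionLexicon":
        with open(path, encoding="utf-8") as fh:
            lemmas = {line.strip().lower() for line in fh if line.strip()}
        return cls(lemmas=lemmas)


def mention_lemma(doc: Document, m: Mention) -> str:
    if m.token_start is None or m.token_end is None:
        return m.surface.lower()
    return " ".join(t.lemma or t.surface.lower()
                    for t in doc.tokens[m.token_start:m.token_end])


def build_action_lexicon(train_docs: Iterable[Document]) -> ActionLexicon:
    """Collect the lemmas of all gold Action mentions in the training set."""
    lemmas: set[str] = set()
    for doc in train_docs:
        for m in doc.mentions:
            if m.mtype == "Action":
                lemmas.add(mention_lemma(doc, m))
    lex = ActionLexicon(lemmas=lemmas)
    if not lemmas:
        import warnings
        warnings.warn("no Action mentions in training data: empty lexicon",
                      stacklevel=2)
    return lex


def detect_action_mentions(doc: Document, lex: ActionLexicon) -> Document:
    """Add an Action mention over every token window whose lemma string is in
    the lexicon and which does not overlap an existing mention.

    Longer windows are preferred; existing mentions are never altered.
    """
    if not len(lex):
        return doc
    covered = [False] * len(doc.tokens)
    for m in doc.mentions:
        if m.token_start is not None:
            for i in range(m.token_start, m.token_end):
                covered[i] = True
    for length in lex.window_lengths():
        i = 0
        while i + length <= len(doc.tokens):
            window = doc.tokens[i:i + length]
            if any(covered[t.index] for t in window):
                i += 1
                continue
            lemma = " ".join(t.lemma or t.surface.lower() for t in window)
            if lemma in lex:
                mid = doc.fresh_id("TAct")
                doc.mentions.append(Mention(
                    id=mid, mtype="Action", start=window[0].start,
                    end=window[-1].end,
                    surface=doc.text[window[0].start:window[-1].end],
                    source="a2", token_start=window[0].index,
                    token_end=window[-1].index + 1))
                for t in window:
                    covered[t.index] = True
                i += length
            else:
                i += 1
    doc.mentions = doc.sorted_mentions()
    return doc


def mark_bsubtilis_genes(doc: Document, gene_lexicon, keymap=None) -> Document:
    """Flag mentions found in the B. subtilis gene lexicon and record their
    canonical entity key (via ``keymap`` when given)."""
    for m in doc.mentions:
        if m.mtype in ("Action", "EventMention"):
            continue
        m.is_bsubtilis_gene = gene_lexicon.contains(m.surface)
        if keymap is not None:
            m.entity_key = keymap.canonical(m.surface)
        else:
            m.entity_key = m.surface.lower()
    return doc
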