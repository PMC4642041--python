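"""Sequence-model sieves and the end-to-end extraction pipeline.

Five sieves share one mechanism — build a mention sequence, decompose it
into skip-mention sequences for every skip number ``s`` in ``0..s_max``,
train one independent linear-chain model per ``s``, and instantiate
relations from the predicted label sequences:

  event          (iii)  EVENT links between entities and action mentions
  mention_rel    (iv)   relations with only mentions as arguments
  event_rel      (v)    relations with an event argument (events are mapped
                        to two-token EventMention proxies first)
  gene_rel       (vi)   Interaction relations between B. subtilis genes
  event_gene_rel (vii)  gene-gene relations lifted out of event-mediated
                        relations (optional; the default configuration
                        leaves it off)

Predicted relations are undirected; direction is assigned afterwards by
rules (textual order, inverted by passive-voice cues).  The full pipeline
is preprocessing, action-mention detection, the sieves above in order, the
rule-based sieve, and data cleaning.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable

from .backend import AveragedPerceptronBackend, ModelHandle
from .cleaning import EntityKeyMap, clean
from .features import (FeatureVocabulary, GeneLexicon, PPITable,
                       compile_templates, extract_features)
from .preprocessing import (ActionLexicon, annotate, build_action_lexicon,
                            detect_action_mentions, mark_bsubtilis_genes)
from .rules_sieve import RuleSpec, apply_rules, default_rules
from .skip_mention import (GoldPair, LabelScheme, MentionSequence,
                           build_mention_sequence, decompose, default_scheme,
                           gold_pairs_from_relations, instantiate_relations,
                           label_sequences, merge_extractions)
from .standoff_io import Document, Event, Relation

log = logging.getLogger(__name__)

SIEVE_IDS = ("event", "mention_rel", "event_rel", "gene_rel",
             "event_gene_rel")

#: Passive-voice cues between two arguments: the later mention is the agent.
DEFAULT_INVERT_PATTERNS = (
    r"\b\w+(?:ed|en)\s+(?:\w+\s+){0,3}?by\b",
    r"\brequires\b",
    r"\bunder\s+the\s+control\s+of\b",
)


@dataclass
class PipelineConfig:
    """Tunables of the extraction pipeline.

    The defaults are the best-performing configuration: event-based gene
    sieve (vii) off, data cleaning on, skip numbers 0..10, features fired
    at least 5 times retained.
    """

    s_max: int = 10
    min_count: int = 5
    feature_groups: str = "ABCDEFGH"
    include_vii: bool = False
    cleaning: bool = True
    rules_enabled: bool = True
    seed: int = 13
    epochs: int = 10
    invert_patterns: tuple[str, ...] = DEFAULT_INVERT_PATTERNS


@dataclass
class SieveModel:
    sieve_id: str
    models: dict[int, ModelHandle]
    vocabulary: FeatureVocabulary
    scheme: LabelScheme
    s_max: int = 10


# ---------------------------------------------------------------------------
# sieve universes and gold pairs
# ---------------------------------------------------------------------------

def sieve_universe(doc: Document, sieve_id: str) -> MentionSequence:
    if sieve_id in ("event", "mention_rel"):
        return build_mention_sequence(doc)
    if sieve_id == "event_rel":
        return build_mention_sequence(doc, event_mentions=True)
    if sieve_id in ("gene_rel", "event_gene_rel"):
        return build_mention_sequence(doc, genes_only=True)
    raise ValueError(f"unknown sieve {sieve_id!r}")


def _event_ids(doc: Document) -> set[str]:
    return {e.id for e in doc.events}


def sieve_gold_relations(doc: Document, sieve_id: str) -> list[Relation]:
    """Select, and where needed rewrite, the gold links a sieve trains on."""
    ev_ids = _event_ids(doc)
    if sieve_id == "event":
        return [Relation(id=e.id, rtype="EVENT", agent=e.subject,
                         target=e.object, provenance=("gold",))
                for e in doc.events]
    if sieve_id == "mention_rel":
        return [r for r in doc.relations
                if r.agent not in ev_ids and r.target not in ev_ids]
    if sieve_id == "event_rel":
        out = []
        for r in doc.relations:
            if r.agent in ev_ids or r.target in ev_ids:
                agent = f"EM_{r.agent}" if r.agent in ev_ids else r.agent
                target = f"EM_{r.target}" if r.target in ev_ids else r.target
                out.append(replace(r, agent=agent, target=target))
        return out
    if sieve_id == "gene_rel":
        gene_ids = {m.id for m in doc.mentions if m.is_bsubtilis_gene}
        return [r for r in doc.relations
                if r.agent in gene_ids and r.target in gene_ids]
    if sieve_id == "event_gene_rel":
        gene_ids = {m.id for m in doc.mentions if m.is_bsubtilis_gene}
        out = []
        for r in doc.relations:
            refs = (r.agent, r.target)
            ev_ref = next((x for x in refs if x in ev_ids), None)
            other = next((x for x in refs if x not in ev_ids), None)
            if ev_ref is None or other is None or other not in gene_ids:
                continue
            subj = doc.event_by_id(ev_ref).subject
            if subj not in gene_ids or subj == other:
                continue
            lifted = replace(r, agent=other, target=subj) \
                if r.agent == other else replace(r, agent=subj, target=other)
            out.append(lifted)
        return out
    raise ValueError(f"unknown sieve {sieve_id!r}")


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

def train_sieve(docs: list[Document], sieve_id: str,
                backend: AveragedPerceptronBackend | None = None,
                config: PipelineConfig | None = None,
                templates=None, scheme: LabelScheme | None = None
                ) -> SieveModel:
    """Train one model per skip number for a sieve.

    For each ``s`` the document's mention universe is decomposed, labeled
    from the sieve's gold links and featurized through a shared min-count
    vocabulary.  A skip number without any positive label yields a trivial
    (all-"O") model, with a warning.
    """
    if not docs:
        raise ValueError("cannot train a sieve on an empty document list")
    config = config or PipelineConfig()
    backend = backend or AveragedPerceptronBackend(
        epochs=config.epochs, seed=config.seed)
    templates = templates if templates is not None else \
        compile_templates(config.feature_groups)
    scheme = scheme or default_scheme()

    per_doc: list[tuple[MentionSequence, list[GoldPair]]] = []
    rtype_counts: Counter = Counter()
    for doc in docs:
        seq0 = sieve_universe(doc, sieve_id)
        gold = sieve_gold_relations(doc, sieve_id)
        pairs = gold_pairs_from_relations(seq0, gold)
        rtype_counts.update(r for (_i, _j, r) in pairs)
        per_doc.append((seq0, pairs))

    # featurize every labeled skip-mention sequence once, then min-count
    # filter and train per skip number
    staged: dict[int, list[tuple[list[frozenset], list[str]]]] = {}
    counts: Counter = Counter()
    for s in range(config.s_max + 1):
        examples = []
        for seq0, pairs in per_doc:
            for seq in label_sequences(decompose(seq0, s), pairs, scheme,
                                       rtype_counts):
                if len(seq) < 2:
                    continue  # no adjacent pair: nothing to learn
                feats = [extract_features(seq, i, seq.doc, templates)
                         for i in range(len(seq))]
                for fs in feats:
                    counts.update(fs)
                examples.append((feats, seq.labels))
        staged[s] = examples

    vocab = FeatureVocabulary(
        retained=frozenset(f for f, c in counts.items()
                           if c >= config.min_count),
        min_count=config.min_count)

    models: dict[int, ModelHandle] = {}
    for s, examples in staged.items():
        filtered = [([fs & vocab.retained for fs in feats], labels)
                    for feats, labels in examples]
        if not any(l != "O" for _f, labels in filtered for l in labels):
            log.warning("sieve %s: no positive labels at s=%d; trivial "
                        "model", sieve_id, s)
            models[s] = ModelHandle(trivial=True)
            continue
        models[s] = backend.train(filtered)
    return SieveModel(sieve_id=sieve_id, models=models, vocabulary=vocab,
                      scheme=scheme, s_max=config.s_max)


def apply_sieve(model: SieveModel, docs: Iterable[Document],
                backend: AveragedPerceptronBackend | None = None,
                templates=None, feature_groups: str = "ABCDEFGH"
                ) -> dict[str, list[Relation]]:
    """Predict with every per-skip model and instantiate merged, undirected
    candidate relations per document (tagged with the sieve's name)."""
    backend = backend or AveragedPerceptronBackend()
    templates = templates if templates is not None else \
        compile_templates(feature_groups)
    out: dict[str, list[Relation]] = {}
    for doc in docs:
        seq0 = sieve_universe(doc, model.sieve_id)
        cands: list[Relation] = []
        for s in range(model.s_max + 1):
            handle = model.models.get(s)
            if handle is None or handle.trivial:
                continue
            predicted = []
            for seq in decompose(seq0, s):
                if len(seq) < 2:
                    continue
                feats = [extract_features(seq, i, seq.doc, templates,
                                          model.vocabulary)
                         for i in range(len(seq))]
                labels = backend.predict(handle, feats)
                predicted.append(replace(seq, labels=labels))
            cands.extend(instantiate_relations(predicted, model.scheme,
                                               provenance=model.sieve_id))
        out[doc.doc_id] = merge_extractions(cands)
    return out


# ---------------------------------------------------------------------------
# direction rules
# ---------------------------------------------------------------------------

def orient_event(rel: Relation, doc: Document) -> Event | None:
    """Turn an EVENT relation into an Event: the entity becomes the subject
    and the action mention the object.  Dropped (with a log message) unless
    exactly one argument is an Action mention."""
    args = [doc.mention_by_id(rel.agent), doc.mention_by_id(rel.target)]
    actions = [m for m in args if m.mtype == "Action"]
    entities = [m for m in args if m.mtype != "Action"]
    if len(actions) != 1:
        log.info("%s: cannot orient EVENT %s: %d action arguments",
                 doc.doc_id, rel.id, len(actions))
        return None
    return Event(id=doc.fresh_id("Epred"), subject=entities[0].id,
                 object=actions[0].id)


def _ref_span(doc: Document, ref: str) -> tuple[int, int]:
    if any(e.id == ref for e in doc.events):
        e = doc.event_by_id(ref)
        subj, obj = doc.mention_by_id(e.subject), doc.mention_by_id(e.object)
        return (min(subj.start, obj.start), max(subj.end, obj.end))
    m = doc.mention_by_id(ref)
    return (m.start, m.end)


def orient_interaction(rel: Relation, doc: Document,
                       invert_patterns: Iterable[str] =
                       DEFAULT_INVERT_PATTERNS) -> Relation:
    """Assign agent/target of an undirected relation.

    Default rule: textual order (the earlier argument acts), inverted when
    a passive-voice cue appears between the arguments — then the later
    mention is the agent.  Already-directed relations pass through.
    """
    if rel.directed:
        return rel
    a_span = _ref_span(doc, rel.agent)
    b_span = _ref_span(doc, rel.target)
    first, second = (rel.agent, rel.target) if a_span <= b_span else \
        (rel.target, rel.agent)
    lo = min(a_span[1], b_span[1])
    hi = max(a_span[0], b_span[0])
    between = doc.text[lo:hi] if lo < hi else ""
    invert = any(re.search(p, between, re.I) for p in invert_patterns)
    agent, target = (second, first) if invert else (first, second)
    return replace(rel, agent=agent, target=target, directed=True)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class Pipeline:
    """Trained model bundle: sieve models plus the lexicons, rules and
    configuration needed to process raw documents."""

    config: PipelineConfig
    sieve_models: dict[str, SieveModel]
    action_lexicon: ActionLexicon
    gene_lexicon: GeneLexicon
    keymap: EntityKeyMap = field(default_factory=EntityKeyMap)
    rules: list[RuleSpec] = field(default_factory=default_rules)
    ppi: PPITable | None = None

    def _templates(self):
        return compile_templates(self.config.feature_groups, ppi=self.ppi,
                                 gene_lexicon=self.gene_lexicon)

    def _backend(self):
        return AveragedPerceptronBackend(epochs=self.config.epochs,
                                         seed=self.config.seed)

    @classmethod
    def train(cls, docs: list[Document], config: PipelineConfig | None = None,
              gene_lexicon: GeneLexicon | None = None,
              keymap: EntityKeyMap | None = None,
              rules: list[RuleSpec] | None = None,
              ppi: PPITable | None = None) -> "Pipeline":
        """Train every sieve on gold-annotated documents."""
        config = config or PipelineConfig()
        if not docs:
            raise ValueError("empty training corpus")
        gene_lexicon = gene_lexicon or GeneLexicon()
        keymap = keymap or EntityKeyMap()
        for doc in docs:
            annotate(doc)
            mark_bsubtilis_genes(doc, gene_lexicon, keymap)
        action_lexicon = build_action_lexicon(docs)
        templates = compile_templates(config.feature_groups, ppi=ppi,
                                      gene_lexicon=gene_lexicon)
        backend = AveragedPerceptronBackend(epochs=config.epochs,
                                            seed=config.seed)
        sieves = list(SIEVE_IDS) if config.include_vii else \
            [s for s in SIEVE_IDS if s != "event_gene_rel"]
        models = {}
        for sieve_id in sieves:
            log.info("training sieve %s", sieve_id)
            models[sieve_id] = train_sieve(
                docs, sieve_id, backend=backend, config=config,
                templates=templates)
        return cls(config=config, sieve_models=models,
                   action_lexicon=action_lexicon, gene_lexicon=gene_lexicon,
                   keymap=keymap,
                   rules=rules if rules is not None else default_rules(),
                   ppi=ppi)

    def preprocess(self, doc: Document) -> Document:
        annotate(doc)
        mark_bsubtilis_genes(doc, self.gene_lexicon, self.keymap)
        detect_action_mentions(doc, self.action_lexicon)
        annotate(doc)  # re-align token ranges after new mentions
        mark_bsubtilis_genes(doc, self.gene_lexicon, self.keymap)
        return doc

    def predict(self, docs: list[Document],
                preprocessed: bool = False) -> dict[str, Counter]:
        """Run the sieve cascade over documents, appending predicted events
        and relations in place.  Returns per-sieve extraction counts."""
        counts: dict[str, Counter] = {"per_sieve": Counter()}
        if not preprocessed:
            for doc in docs:
                self.preprocess(doc)
        templates = self._templates()
        backend = self._backend()
        cfg = self.config

        # (iii) events
        if "event" in self.sieve_models:
            per_doc = apply_sieve(self.sieve_models["event"], docs,
                                  backend=backend, templates=templates)
            for doc in docs:
                for rel in per_doc.get(doc.doc_id, []):
                    ev = orient_event(rel, doc)
                    if ev is not None:
                        doc.events.append(ev)
                        counts["per_sieve"]["event"] += 1

        # (iv)-(vii) relations
        rel_sieves = ["mention_rel", "event_rel", "gene_rel"]
        if cfg.include_vii:
            rel_sieves.append("event_gene_rel")
        for sieve_id in rel_sieves:
            model = self.sieve_models.get(sieve_id)
            if model is None:
                if sieve_id == "event_gene_rel":
                    raise ValueError(
                        "configuration enables sieve (vii) but the bundle "
                        "has no event_gene_rel model")
                continue
            per_doc = apply_sieve(model, docs, backend=backend,
                                  templates=templates)
            for doc in docs:
                for rel in per_doc.get(doc.doc_id, []):
                    oriented = orient_interaction(rel, doc,
                                                  cfg.invert_patterns)
                    doc.relations.append(oriented)
                    counts["per_sieve"][sieve_id] += 1

        # (viii) rules
        if cfg.rules_enabled and self.rules:
            for doc in docs:
                found = apply_rules(doc, self.rules)
                doc.relations.extend(found)
                counts["per_sieve"]["rules"] += len(found)

        # merge + (ix) cleaning
        for doc in docs:
            before = len(doc.relations)
            doc.relations = merge_extractions(doc.relations)
            if cfg.cleaning:
                doc.relations = clean(doc.relations, doc, self.keymap)
            counts["per_sieve"]["cleaning_removed"] += \
                before - len(doc.relations)
        return counts

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "sieves": sorted(self.sieve_models),
            "rules": [{"family": r.family, "pattern": r.pattern,
                       "type": r.rtype, "passive": r.passive}
                      for r in self.rules],
            "keymap": self.keymap.synonyms,
        }
        (path / "bundle.json").write_text(json.dumps(meta, indent=1))
        self.action_lexicon.save(path / "action_lexicon.txt")
        self.gene_lexicon.save(path / "gene_lexicon.txt")
        for sieve_id, sm in self.sieve_models.items():
            payload = {
                "sieve_id": sieve_id,
                "s_max": sm.s_max,
                "min_count": sm.vocabulary.min_count,
                "vocabulary": sorted(sm.vocabulary.retained),
                "scheme": sm.scheme.labels,
                "models": {str(s): h.to_dict()
                           for s, h in sm.models.items()},
            }
            (path / f"sieve_{sieve_id}.json").write_text(
                json.dumps(payload))

    @classmethod
    def load(cls, path) -> "Pipeline":
        path = Path(path)
        meta = json.loads((path / "bundle.json").read_text())
        raw_cfg = dict(meta["config"])
        raw_cfg["invert_patterns"] = tuple(raw_cfg["invert_patterns"])
        config = PipelineConfig(**raw_cfg)
        models: dict[str, SieveModel] = {}
        for sieve_id in meta["sieves"]:
            payload = json.loads(
                (path / f"sieve_{sieve_id}.json").read_text())
            models[sieve_id] = SieveModel(
                sieve_id=sieve_id,
                models={int(s): ModelHandle.from_dict(h)
                        for s, h in payload["models"].items()},
                vocabulary=FeatureVocabulary(
                    retained=frozenset(payload["vocabulary"]),
                    min_count=payload["min_count"]),
                scheme=LabelScheme(labels=payload["scheme"]),
                s_max=payload["s_max"])
        rules = [RuleSpec(family=r["family"], pattern=r["pattern"],
                          rtype=r["type"], passive=r["passive"])
                 for r in meta["rules"]]
        return cls(config=config, sieve_models=models,
                   action_lexicon=ActionLexicon.load(
                       path / "action_lexicon.txt"),
                   gene_lexicon=GeneLexicon.load(path / "gene_lexicon.txt"),
                   keymap=EntityKeyMap(synonyms=meta["keymap"]),
                   rules=rules)


def run_pipeline(docs: list[Document], pipeline: Pipeline,
                 clean_output: bool | None = None) -> dict[str, Counter]:
    """Convenience wrapper: run the trained cascade over documents."""
    if clean_output is not None:
        pipeline = replace(pipeline, config=replace(
            pipeline.config, cleaning=clean_output))
    return pipeline.predict(docs)
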