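# Methods

## Model

Relation extraction is cast as sequence labeling over mention sequences.
A document's mentions, ordered by character span, form the zero-skip
sequence; for skip number `s`, the `s + 1` skip-mention sequences take
every `(s + 1)`-th mention starting at each residue `r ∈ [0, s]`. A label
`y_i ≠ O` on a sequence encodes a relation between element `i` and its
predecessor, so position 0 is structurally `O`. Labeling at skip `s`
exactly captures argument pairs at mention distance `s + 1`; the
decomposition partitions the mentions for every `s`, and the union over
`s = 0 … s_max` recovers all pairs at distance ≤ `s_max + 1`. These
invariants are property-tested.

One independent linear-chain model is trained per sieve and per skip
number. The backend contract is ranking-only: `train` consumes
(feature-set sequence, label sequence) pairs, `predict` returns the
highest-ranked label sequence of the same length; no normalized
probabilities are required. The shipped backend is an **averaged
structured perceptron** (Viterbi decoding; emission weights on
(feature, label), transition weights on (label, label); weights averaged
over epochs). Training order is shuffled with a seeded RNG, so results are
deterministic given the seed; per-skip models are independent and
retraining reproduces them bit-for-bit. A skip number with no positive
labels yields a trivial all-`O` model with a warning. Sequences with fewer
than two elements carry no adjacent pair and are dropped from training.

## Sieves

1. **Preprocessing** — pluggable annotators. Defaults: regex tokenizer
   (additionally split at mention boundaries, so every mention aligns to a
   whole-token range), punctuation sentence splitter, lower-casing
   lemmatizer. No POS tagger or constituency parser is bundled; an absent
   parser only makes parse-tree feature templates emit a designated
   "unavailable" value.
2. **Action-mention detection** — lemmas of gold Action mentions collected
   from training data; at prediction time, token windows (multi-token
   lemmas supported) matching the lexicon and not overlapping an existing
   mention become Action mentions.
3. **Event sieve** — labels EVENT links between entities and action words;
   oriented afterwards: entity = subject, action = object.
4. **Relation sieves** — (iv) all mentions; (v) mentions plus two-token
   EventMention proxies, each ordered at its event's lowest argument;
   (vi) *B. subtilis* gene mentions only (lexicon-matched); (vii) gene
   pairs lifted from event-mediated relations (a relation between gene G1
   and event E trains the pair (G1, subject(E))). Sieve (vii) is off by
   default — the best-performing configuration excludes it.
5. **Rule sieve** — four families driven by a 20-row regex table
   (mention triplets with a matching action mention; consecutive gene
   mentions with matching in-between text; lists of gene mentions around a
   match, cartesian product; consecutive matching after removing
   comma-delimited subsentences that contain no mention). Matching is
   case-insensitive and per-sentence.
6. **Cleaning** — removes loops (both arguments canonicalize to the same
   entity key) and duplicate (agent, target, type) triples; idempotent.

Direction: sequence sieves predict undirected relations; a rule assigns
the earlier argument as agent unless a passive cue (a participle + "by",
"requires", "under the control of") appears between the arguments, in
which case the later mention acts. The agent is always the acting
regulator, matching the relation representation in which the subject of
"gerE inhibits cotD" is gerE. For the same reason, two rule-table rows
whose surface constructions are passive ("transcrib" mention triplet,
"under the control of" list rule) carry the passive flag alongside the
footnoted passive rows.

## Features

Templates are deterministic functions of (sequence, position, document)
organized in ablation groups A–H (general → specific): A label prior and
surface/type indicators; B mention distance + Hearst-style co-occurrence
patterns; C gene-lexicon flags and STRING-style protein-interaction score
levels (numeric scores bucketed at 150/400/700/900 into five verbal
levels); D prefix/suffix generators (lengths 2–3, offsets −5…5);
E current/consequent value generators (offsets −4…4, over
text/POS/lemma/entity-type/coreference layers — the coreference layer
defaults to a constant); F context similarity — character 3-gram Jaccard
of 5-word windows around the two mentions, discretized into eight
equal-width levels (identical windows map to the top level, disjoint to
the bottom; the level is monotone in the coefficient); G previous/next
token combinations and left/right/between token values, anchored at
*both* mentions and at both ends of the between gap, so the tokens
adjacent to either argument are observed regardless of gap width;
H parse-tree templates (unavailable without a parser) and split-to-values
(mention split on a hyphen/space delimiter class, first two parts).

A vocabulary pass keeps features fired at least `min_count` times
(default 5) on the training data of the sieve.

## Evaluation

Networks are edge sets of canonicalized (agent, target, type) triples.
Canonical keys are lower-cased surfaces with a synonym table and a
sigma-factor folding rule ("sigma H", "E sigma H" → "sigh"). Event
arguments are lifted to the event's subject gene; relations with a
non-gene argument are dropped from the network. The scorer matches
exactly first (M), then counts a remaining prediction with the right
ordered pair but wrong type as a substitution (each reference edge is
consumed once); the rest are insertions and deletions;
`SER = (S + I + D) / N` is kept as an exact rational and printed to two
decimals. Direction-flipped pairs count as insertions by default
(`reversed_as_substitution` switches this). Type-hierarchy credit
(Regulation as a parent of the mechanism types) is not implemented in the
scorer's default path and would be a scoring variant, not a pipeline
change.

## Synthetic corpus

The generator emits one-sentence documents from templates that declare
their gold annotations exactly: active/passive single-relation
constructions, event-mediated constructions ("the expression of X
requires Y"), two lists ("under the control of A1 and A2", "represses
both T1 and T2"), a comma-subsentence construction, three rare phrasings
(~1% each: "acts as a repressor to", "can inactivate", "must act to
directly activate"), and relation-free distractors (including two-gene
sentences with relation-like gaps). Gene names are real sporulation
regulators; sigma factors are sometimes rendered "sigma X" to exercise
canonicalization. Mention distance is controlled by inserting non-gene
protein mentions between the arguments; every distance drawn from the
configured profile (default 1:0.35, 2:0.40, 3:0.25 — most pairs lie about
two mentions apart in corpora of this kind) is realized exactly once, so
the realized histogram is a true multinomial sample. Filler and
distractor wording deliberately avoids rule-pattern substrings.

What the generator does *not* emulate: PubMed's lexical and syntactic
variety, hierarchical (relation-in-relation) annotations, negated
relations, coreference chains, and annotation noise. Passing the recovery
test therefore demonstrates that the machinery — sequence construction,
learning, rules, orientation, assembly, scoring — is correct and that the
sieves complement each other, not that real-corpus accuracy is attained.

The rare phrasings and the two-gene distractors are what give the rule
sieve signal of its own: with ~2–3 training instances per rare phrasing,
their distinguishing features fall below the min-count threshold and
generic signatures are confounded by the distractors, so the statistical
sieves miss some of them while the rules do not — mirroring the
high-precision, recall-boosting role rules play on real text.

## Problem sizes and defaults

The package defaults are `s_max = 10`, `min_count = 5`, feature groups
A–H, sieve (vii) off, cleaning on, seed 13, 10 perceptron epochs. The
end-to-end recovery check trains on 300 generated documents and scores
100 held-out ones with `s_max = 4` (gold distances are ≤ 3, so skips
beyond 4 are vacuous) and 8 epochs; it runs in well under a minute. At
the default seed this yields held-out SER 0.01 with the rule sieve and
0.05 without it; across other seeds SER stays ≤ ~0.13, with rules never
hurting.

## Known limitations

- No bundled biomedical lemmatizer, POS tagger or parser; the lemma layer
  defaults to lower-cased surfaces, so inflection variants ("transcribe"
  vs "transcribed") are distinct lexicon entries unless the user supplies
  a lemmatizer or lexicon rows for both.
- Hierarchical (relation-as-argument) and negated relations are not
  extracted.
- The scorer is this package's reading of slot-error matching
  (exact-pair-first, one-to-one consumption), chosen because it makes the
  published counter arithmetic self-consistent; it is not a byte-for-byte
  reimplementation of the official challenge scorer.
- Rule-table regexes are substring patterns and can interact with
  unforeseen wording (e.g. "to…activat" matching across words); on real
  text the rule config should be curated per corpus.
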