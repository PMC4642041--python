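# grnsieve

Sieve-based extraction of gene regulatory networks from annotated
biomedical text.

Curated resources cannot keep up with the literature on gene regulation;
tools that read abstracts and emit a structured network — *which gene
regulates which, and how* — are how systems biologists bootstrap models of
circuits such as the *Bacillus subtilis* sporulation cascade. `grnsieve`
implements a multi-pass ("sieve") relation-extraction pipeline for
BioNLP-ST-style corpora: plain text plus standoff annotation files marking
entity mentions (genes, proteins, operons, promoters, …), with typed,
directed `Interaction.{Regulation, Inhibition, Activation, Requirement,
Binding, Transcription}` relations as the extraction target.

## The method

A linear-chain sequence model can only relate *adjacent* elements of its
input sequence. The central idea here is to make distant relations local by
a change of representation: collapse a document to its ordered **mention
sequence** `x = [m_1 … m_n]` and label it with a target sequence `y`, where
`y_i ≠ O` asserts a relation between `m_i` and `m_{i-1}`. To reach
arguments `s` mentions apart, the sequence is decomposed into `s + 1`
**skip-mention sequences** (every `(s+1)`-th mention, one sequence per
residue class), and one independent chain model is trained per skip number
`s = 0 … s_max` (default 10). A first-order model over the decomposed
sequences then captures arbitrary bounded-distance relations.

For example, the sentence

> spo0H RNA and sigma H levels during growth are not identical to each
> other or to the pattern of expression of spoVG, a gene transcribed by
> E sigma H.

has the mention sequence `[spo0H, sigma H, levels, expression, spoVG,
transcribed, E sigma H]` and the zero-skip objective sequence
`[O, O, EVENT, O, EVENT, O, TranscriptionBy]`; the distance-2 pair
(spoVG, E sigma H) is labeled in one of the two one-skip sequences
`[spo0H, levels, spoVG, E sigma H]`.

The full pipeline runs nine sieves in order: preprocessing (tokenization,
sentence splitting, lemmatization through pluggable annotators), action-
mention detection by lemma lookup, a sequence-model sieve for EVENT links
(entity + action word, e.g. "expression of spoVG"), four relation sieves
over different mention universes (all mentions; mentions + event proxies;
*B. subtilis* gene mentions; event-lifted gene pairs), a rule-based sieve
(regular-expression patterns over consecutive gene mentions, mention
triplets, list constructions and comma-reduced sentences), and a cleaning
sieve that removes coreferent-argument loops and duplicates. Features are
built from instantiable templates (affixes, mention/context values,
character-n-gram Jaccard context levels, gene-lexicon and
protein-interaction-score lookups) and filtered by a minimum occurrence
count (default 5). Relations are predicted undirected and oriented
afterwards (textual order, inverted on passive-voice cues).

The assembled network is scored against a reference with the **Slot Error
Rate**, `SER = (S + I + D) / N` — substitutions, insertions and deletions
over the number of reference edges; 0 is perfect, 1 is as bad as
predicting nothing.

The sequence-model backend is an averaged structured perceptron with
Viterbi decoding; it satisfies the pipeline's ranking-only backend
contract (train / predict-highest-ranked) and any linear-chain labeler can
be substituted.

## Worked example

A built-in generator emits standoff corpora with known gold annotations
(sporulation-flavored template sentences; see `docs/methods.md`):

```sh
grnsieve generate corpus --n-docs 120 --seed 13
grnsieve train corpus --model-dir model --s-max 4 --epochs 8
grnsieve generate test --n-docs 50 --seed 17
grnsieve predict test --model-dir model --out pred
grnsieve evaluate pred/network.tsv test/gold_network.tsv
```

prints (a2 gold files are ignored at prediction time):

```
S=0 I=10 D=0 M=44 N=44
SER=0.23
  matched Interaction.Activation: 2
  matched Interaction.Binding: 4
  matched Interaction.Inhibition: 13
  ...
```

All 44 held-out reference edges are recovered (M=N, no deletions or
substitutions); ten spurious edges give `SER = 10/44 = 0.23`. Training on
300 documents brings held-out SER to ~0.05 (see the acceptance suite).
`grnsieve stats corpus` prints the mention-distance histogram of the gold
relations — the diagnostic that motivates the skip range.

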