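"""Linear-chain sequence labeling backend.

The sieves only require a ranking contract from their backend: ``train``
takes (feature-set sequence, label sequence) pairs and returns a model
handle; ``predict`` returns the highest-ranked label sequence of the same
length as its input.  Normalized probabilities are never needed.

The default backend is an averaged structured perceptron over a first-order
(linear-chain) factorization: emission weights on (feature, label) pairs and
transition weights on (previous label, label) pairs, decoded with Viterbi.
Training is deterministic given a seed (used only to shuffle the training
order between epochs).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

OUTSIDE = "O"

FeatSeq = list[frozenset]
TrainingExample = tuple[FeatSeq, list[str]]


@dataclass
class ModelHandle:
    labels: list[str] = field(default_factory=lambda: [OUTSIDE])
    emission: dict[str, dict[str, float]] = field(default_factory=dict)
    transition: dict[str, dict[str, float]] = field(default_factory=dict)
    trivial: bool = False

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "emission": self.emission,
            "transition": self.transition,
            "trivial": self.trivial,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelHandle":
        return cls(labels=list(d["labels"]),
                   emission={f: dict(v) for f, v in d["emission"].items()},
                   transition={a: dict(v)
                               for a, v in d["transition"].items()},
                   trivial=bool(d["trivial"]))


START = "<s>"


class AveragedPerceptronBackend:
    """Averaged structured perceptron satisfying the backend contract."""

    def __init__(self, epochs: int = 10, seed: int = 13):
        self.epochs = epochs
        self.seed = seed

    # -- decoding -----------------------------------------------------------
    @staticmethod
    def _viterbi(handle: ModelHandle, feats: FeatSeq) -> list[str]:
        labels = handle.labels
        n = len(feats)
        if n == 0:
            return []
        em = handle.emission
        tr = handle.transition

        def emit_score(i: int) -> dict[str, float]:
            s = {y: 0.0 for y in labels}
            for f in feats[i]:
                w = em.get(f)
                if w:
                    for y, v in w.items():
                        s[y] += v
            return s

        prev_scores = {}
        e0 = emit_score(0)
        t0 = tr.get(START, {})
        for y in labels:
            prev_scores[y] = e0[y] + t0.get(y, 0.0)
        back: list[dict[str, str]] = []
        for i in range(1, n):
            ei = emit_score(i)
            cur: dict[str, float] = {}
            bp: dict[str, str] = {}
            for y in labels:
                best_prev, best_score = None, None
                for yp in labels:
                    sc = prev_scores[yp] + tr.get(yp, {}).get(y, 0.0)
                    if best_score is None or sc > best_score:
                        best_prev, best_score = yp, sc
                cur[y] = best_score + ei[y]
                bp[y] = best_prev
            prev_scores = cur
            back.append(bp)
        # deterministic tie-break: label list order
        last = max(labels, key=lambda y: (prev_scores[y], -labels.index(y)))
        path = [last]
        for bp in reversed(back):
            path.append(bp[path[-1]])
        return list(reversed(path))

    # -- training -----------------------------------------------------------
    def train(self, data: list[TrainingExample]) -> ModelHandle:
        data = [(f, y) for f, y in data if len(f) > 0]
        label_set = sorted({y for _, ys in data for y in ys})
        if not data or label_set in ([], [OUTSIDE]):
            return ModelHandle(trivial=True)
        if OUTSIDE not in label_set:
            label_set.append(OUTSIDE)
        labels = sorted(label_set)

        handle = ModelHandle(labels=labels)
        em = handle.emission
        tr = handle.transition
        # running sums for epoch averaging
        em_sum: dict[str, dict[str, float]] = {}
        tr_sum: dict[str, dict[str, float]] = {}

        def bump(table, key, y, delta):
            row = table.setdefault(key, {})
            row[y] = row.get(y, 0.0) + delta

        rng = random.Random(self.seed)
        order = list(range(len(data)))
        for _epoch in range(self.epochs):
            rng.shuffle(order)
            for k in order:
                feats, gold = data[k]
                pred = self._viterbi(handle, feats)
                if pred == gold:
                    continue
                prev_g = prev_p = START
                for i in range(len(gold)):
                    g, p = gold[i], pred[i]
                    if g != p:
                        for f in feats[i]:
                            bump(em, f, g, 1.0)
                            bump(em, f, p, -1.0)
                    if (prev_g, g) != (prev_p, p):
                        bump(tr, prev_g, g, 1.0)
                        bump(tr, prev_p, p, -1.0)
                    prev_g, prev_p = g, p
            for f, row in em.items():
                dst = em_sum.setdefault(f, {})
                for y, v in row.items():
                    dst[y] = dst.get(y, 0.0) + v
            for a, row in tr.items():
                dst = tr_sum.setdefault(a, {})
                for y, v in row.items():
                    dst[y] = dst.get(y, 0.0) + v

        scale = 1.0 / self.epochs
        handle.emission = {
            f: {y: v * scale for y, v in row.items() if v != 0.0}
            for f, row in em_sum.items()}
        handle.transition = {
            a: {y: v * scale for y, v in row.items() if v != 0.0}
            for a, row in tr_sum.items()}
        handle.emission = {f: r for f, r in handle.emission.items() if r}
        handle.transition = {a: r for a, r in handle.transition.items() if r}
        return handle

    def predict(self, handle: ModelHandle, feats: FeatSeq) -> list[str]:
        if handle.trivial:
            return [OUTSIDE] * len(feats)
        return self._viterbi(handle, feats)
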