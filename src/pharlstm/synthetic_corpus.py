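"""Synthetic DDI corpora with a trigger-token labelling rule.

The generator emits corpora in the same XML dialect the parser reads:
sentences holding two or more drug mentions, all C(n, 2) candidate pairs
annotated.  The gold label of a pair is a deterministic function of the
tokens lying strictly between its two mentions — the first trigger token
found there decides the class; no trigger means NEGATIVE — optionally
flipped to a random other label with probability ``label_noise``.  Because
the label is readable off the between-mention path, the path and
importance filters of the representation carry real signal, and a
noiseless corpus is perfectly separable by construction.

Sentences are template text ("filler trigger filler drug ..."), not natural
prose; lexical realism is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import (
    BINARY, FIVE_CLASS, NEGATIVE, POSITIVE, Corpus, Document, EntityMention,
    PairAnnotation, Sentence, serialize_corpus,
)

__all__ = ["SynthConfig", "generate_corpus", "generate_corpus_xml",
           "DEFAULT_BINARY_TRIGGERS", "DEFAULT_FIVE_CLASS_TRIGGERS"]

# Trigger lexicons: small, disjoint sets of interaction-evoking verbs.
DEFAULT_BINARY_TRIGGERS = {
    POSITIVE: ("increases", "potentiates", "inhibits"),
}
DEFAULT_FIVE_CLASS_TRIGGERS = {
    "ADVICE": ("avoid", "caution", "recommended"),
    "EFFECT": ("increases", "enhances", "potentiates"),
    "MECHANISM": ("inhibits", "metabolism", "absorption"),
    "INT": ("interacts", "interaction", "interfere"),
}

_SYLLABLES = ("ra", "zo", "mi", "tal", "vex", "dor", "lin", "pra", "bu",
              "ket", "fen", "sol")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic corpus.

    Defaults give short template sentences with exactly two drug mentions
    (one candidate pair per sentence), a filler vocabulary of 120 words,
    and a half-negative class balance — negatives dominate real DDI
    corpora, and half/half keeps both tasks learnable at small n.
    """

    n_sentences: int = 500
    task_kind: str = BINARY
    min_drugs: int = 2
    max_drugs: int = 2
    vocabulary_size: int = 120
    triggers: dict[str, tuple[str, ...]] | None = None
    class_priors: dict[str, float] | None = None
    label_noise: float = 0.0
    filler_words: int = 3  # filler tokens on each side of / between drugs
    seed: int = 0

    def resolved_triggers(self) -> dict[str, tuple[str, ...]]:
        if self.triggers is not None:
            return self.triggers
        return (DEFAULT_FIVE_CLASS_TRIGGERS if self.task_kind == FIVE_CLASS
                else DEFAULT_BINARY_TRIGGERS)

    def resolved_priors(self) -> dict[str, float]:
        if self.class_priors is not None:
            return self.class_priors
        positive = list(self.resolved_triggers())
        priors = {NEGATIVE: 0.5}
        for lbl in positive:
            priors[lbl] = 0.5 / len(positive)
        return priors

    def validate(self) -> None:
        if self.min_drugs < 2 or self.max_drugs < self.min_drugs:
            raise ValueError("need min_drugs >= 2 and max_drugs >= min_drugs")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        priors = self.resolved_priors()
        if abs(sum(priors.values()) - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")
        triggers = self.resolved_triggers()
        all_words: list[str] = []
        for words in triggers.values():
            all_words.extend(words)
        if len(set(all_words)) != len(all_words):
            raise ValueError("trigger lexicons must be disjoint")
        for lbl in priors:
            if lbl != NEGATIVE and lbl not in triggers:
                raise ValueError(f"prior given for {lbl!r} but no triggers")


def _drug_name(rng: np.random.Generator) -> str:
    n_syll = rng.integers(2, 4)
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syll)) + "ine"


def _label_between(tokens: list[str], lo: int, hi: int,
                   word_to_class: dict[str, str]) -> str:
    """First-trigger rule: class of the first trigger strictly between."""
    for tok in tokens[lo + 1:hi]:
        if tok in word_to_class:
            return word_to_class[tok]
    return NEGATIVE


def generate_corpus(config: SynthConfig) -> Corpus:
    """Generate a corpus; deterministic for a fixed config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    triggers = config.resolved_triggers()
    priors = config.resolved_priors()
    word_to_class = {w: lbl for lbl, ws in triggers.items() for w in ws}
    fillers = [f"w{idx:03d}" for idx in range(config.vocabulary_size)]
    labels = sorted(priors)
    probs = np.array([priors[lbl] for lbl in labels])
    all_labels = sorted(set(labels) | {NEGATIVE})

    doc = Document(id="synth.d0")
    for s_idx in range(config.n_sentences):
        n_drugs = int(rng.integers(config.min_drugs, config.max_drugs + 1))
        drug_names = []
        while len(drug_names) < n_drugs:
            name = _drug_name(rng)
            if name not in drug_names:
                drug_names.append(name)

        # Build the token stream: filler runs between drugs, each gap
        # seeded (or not) with one trigger drawn from the priors.
        tokens: list[str] = []
        drug_positions: list[int] = []

        def filler_run(k: int) -> list[str]:
            return list(rng.choice(fillers, size=k))

        tokens.extend(filler_run(int(rng.integers(1, config.filler_words + 1))))
        for g in range(n_drugs):
            drug_positions.append(len(tokens))
            tokens.append(drug_names[g])
            if g < n_drugs - 1:
                gap_label = str(rng.choice(labels, p=probs))
                gap = filler_run(int(rng.integers(1, config.filler_words + 1)))
                if gap_label != NEGATIVE:
                    slot = int(rng.integers(0, len(gap) + 1))
                    gap.insert(slot, str(rng.choice(triggers[gap_label])))
                tokens.extend(gap)
        tokens.extend(filler_run(int(rng.integers(1, config.filler_words + 1))))

        text = " ".join(tokens)
        starts = np.cumsum([0] + [len(t) + 1 for t in tokens[:-1]])
        sent = Sentence(id=f"synth.d0.s{s_idx}", text=text)
        for e_idx, pos in enumerate(drug_positions):
            start = int(starts[pos])
            sent.entities.append(EntityMention(
                id=f"{sent.id}.e{e_idx}",
                char_start=start,
                char_end=start + len(tokens[pos]) - 1,
                surface=tokens[pos]))
        for i in range(n_drugs):
            for j in range(i + 1, n_drugs):
                label = _label_between(tokens, drug_positions[i],
                                       drug_positions[j], word_to_class)
                if config.label_noise > 0 and rng.random() < config.label_noise:
                    others = [l for l in all_labels if l != label]
                    label = str(rng.choice(others))
                if config.task_kind == FIVE_CLASS:
                    interacts = label != NEGATIVE
                    ddi_type = label if interacts else None
                else:
                    interacts = label != NEGATIVE
                    ddi_type = None
                sent.pairs.append(PairAnnotation(
                    e1=sent.entities[i].id, e2=sent.entities[j].id,
                    interacts=interacts, ddi_type=ddi_type))
        doc.sentences.append(sent)
    return Corpus(documents=[doc], task_kind=config.task_kind)


def generate_corpus_xml(config: SynthConfig) -> bytes:
    """Generate and serialize in one go (byte-identical under one seed)."""
    return serialize_corpus(generate_corpus(config))
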