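"""Pharmacological representation: token vectors plus target-drug features.

A candidate drug pair is encoded token by token.  Each token contributes a
d-dimensional randomly-encoded word vector and a 4-dimensional vector of
target-drug information computed by four filters:

* target filter     — is the token part of either target mention?
* neighbor filter   — is it directly adjacent to a target mention?
* path filter       — does it lie strictly between the two mentions?
* importance filter — I = 1/(r+1)^2, where r is the token distance to the
  nearest token of the nearest target mention (r=0 on the mention itself).

Target drug surfaces are kept verbatim — no "drug1"/"drug2" blinding — so
the lexical identity of the drugs stays available to the model.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .corpus_io import CandidateInstance

__all__ = [
    "Token", "TokenSequence", "EmbeddingTable", "PharVector",
    "PharRepresentation", "RepresentationError",
    "tokenize", "init_embedding_table", "compute_phar_vector",
    "build_representation", "build_vocabulary",
]

UNK_TOKEN = "<unk>"
_PUNCT = set(string.punctuation)


class RepresentationError(ValueError):
    """A candidate instance cannot be mapped onto the token sequence."""


@dataclass(frozen=True)
class Token:
    text: str
    char_start: int  # 0-based inclusive
    char_end: int    # 0-based inclusive


@dataclass
class TokenSequence:
    tokens: list[Token]

    def __len__(self) -> int:
        return len(self.tokens)

    def texts(self) -> list[str]:
        return [t.text for t in self.tokens]

    def run_for_span(self, char_start: int, char_end: int) -> tuple[int, int]:
        """Token-index run (inclusive) covering the character span."""
        hit = [i for i, tok in enumerate(self.tokens)
               if tok.char_end >= char_start and tok.char_start <= char_end]
        if not hit:
            raise RepresentationError(
                f"no tokens overlap character span {char_start}-{char_end}")
        return hit[0], hit[-1]


def tokenize(text: str, keep_punctuation: bool = False) -> TokenSequence:
    """Split on whitespace, then on punctuation characters.

    Punctuation-only fragments are dropped by default, so the token count n
    satisfies n >= m for m whitespace words while hyphenated compounds like
    "beta-blockers" still split into a contiguous run of word tokens.
    """
    tokens: list[Token] = []
    pos = 0
    for word in text.split():
        start = text.index(word, pos)
        pos = start + len(word)
        frag_start = start
        frag = []
        for offset, ch in enumerate(word):
            if ch in _PUNCT:
                if frag:
                    tokens.append(Token("".join(frag), frag_start,
                                        start + offset - 1))
                    frag = []
                if keep_punctuation:
                    tokens.append(Token(ch, start + offset, start + offset))
                frag_start = start + offset + 1
            else:
                if not frag:
                    frag_start = start + offset
                frag.append(ch)
        if frag:
            tokens.append(Token("".join(frag), frag_start, start + len(word) - 1))
    return TokenSequence(tokens)


@dataclass
class EmbeddingTable:
    """Random-encoding word vectors, one d-vector per vocabulary entry.

    Components are drawn uniformly from [-1/sqrt(d), 1/sqrt(d)]; index 0 is
    reserved for unknown tokens.  The same seed always yields the same
    table.
    """

    vocabulary: dict[str, int]
    vectors: np.ndarray  # (V, d)
    d: int
    seed: int
    unk_index: int = 0

    def index(self, token: str) -> int:
        return self.vocabulary.get(token, self.unk_index)

    def lookup(self, token: str) -> np.ndarray:
        return self.vectors[self.index(token)]


def build_vocabulary(token_lists) -> list[str]:
    """Sorted unique tokens of an iterable of token-text lists."""
    vocab: set[str] = set()
    for toks in token_lists:
        vocab.update(toks)
    return sorted(vocab)


def init_embedding_table(vocabulary: list[str], d: int = 400,
                         seed: int = 0) -> EmbeddingTable:
    if d < 1:
        raise ValueError("embedding dimension must be >= 1")
    rng = np.random.default_rng(seed)
    bound = 1.0 / np.sqrt(d)
    names = [UNK_TOKEN] + [t for t in vocabulary if t != UNK_TOKEN]
    vectors = rng.uniform(-bound, bound, size=(len(names), d))
    vocab = {name: i for i, name in enumerate(names)}
    return EmbeddingTable(vocabulary=vocab, vectors=vectors, d=d, seed=seed)


@dataclass(frozen=True)
class PharVector:
    is_target: int
    is_neighbor: int
    on_path: int
    importance: float

    def as_array(self) -> np.ndarray:
        return np.array([self.is_target, self.is_neighbor,
                         self.on_path, self.importance])


def compute_phar_vector(token_index: int, n_tokens: int,
                        target_runs: tuple[tuple[int, int], tuple[int, int]],
                        neighbor_radius: int = 1) -> PharVector:
    """Evaluate the four target-drug filters for one token position.

    ``target_runs`` are the two (inclusive) token-index runs of the target
    mentions.  Distance r is counted in token positions to the nearest token
    of the nearest run; any token inside a run has r = 0.
    """
    if not (0 <= token_index < n_tokens):
        raise IndexError(
            f"token index {token_index} out of range for {n_tokens} tokens")
    (a_start, a_end), (b_start, b_end) = sorted(target_runs)

    def run_distance(start: int, end: int) -> int:
        if start <= token_index <= end:
            return 0
        return min(abs(token_index - start), abs(token_index - end))

    r = min(run_distance(a_start, a_end), run_distance(b_start, b_end))
    is_target = 1 if r == 0 else 0
    is_neighbor = 1 if 0 < r <= neighbor_radius else 0
    on_path = 1 if a_end < token_index < b_start else 0
    return PharVector(is_target=is_target, is_neighbor=is_neighbor,
                      on_path=on_path, importance=1.0 / (r + 1) ** 2)


@dataclass
class PharRepresentation:
    """Network input for one candidate: token vectors and filter vectors."""

    token_indices: np.ndarray   # (n,) int — rows of the embedding table
    token_vectors: np.ndarray   # (n, d)
    phar_vectors: np.ndarray    # (n, 4)
    label: str

    def __len__(self) -> int:
        return len(self.token_indices)


def build_representation(instance: CandidateInstance, table: EmbeddingTable,
                         neighbor_radius: int = 1,
                         keep_punctuation: bool = False) -> PharRepresentation:
    """Tokenize the sentence and assemble the pharmacological representation."""
    sent = instance.sentence
    seq = tokenize(sent.text, keep_punctuation=keep_punctuation)
    if len(seq) == 0:
        raise RepresentationError(f"sentence {sent.id!r} has no tokens")
    runs = []
    for eid in (instance.target1, instance.target2):
        ent = sent.entity(eid)
        try:
            runs.append(seq.run_for_span(ent.char_start, ent.char_end))
        except RepresentationError as exc:
            raise RepresentationError(
                f"entity {eid!r} in sentence {sent.id!r}: {exc}") from exc
    runs = (runs[0], runs[1])
    n = len(seq)
    indices = np.array([table.index(t) for t in seq.texts()], dtype=np.intp)
    phar = np.stack([
        compute_phar_vector(i, n, runs, neighbor_radius).as_array()
        for i in range(n)
    ])
    return PharRepresentation(
        token_indices=indices,
        token_vectors=table.vectors[indices],
        phar_vectors=phar,
        label=instance.label,
    )
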