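"""Reading and writing DDI-annotated corpora.

The on-disk format is the community XML dialect used by the drug-drug
interaction (DDI) extraction shared tasks: a corpus of documents, each
holding sentences; a sentence carries its raw text, drug-entity mentions
with character offsets, and annotated entity pairs flagged as interacting
or not (with a type for the five-class task).  Character offsets are
0-based with inclusive start and end, matching the corpus files in the
wild.  Discontinuous mentions (semicolon-separated offset lists) keep only
their first span for positioning.

Two task flavours exist:

* ``binary`` — does this drug pair interact? (labels POSITIVE / NEGATIVE)
* ``five_class`` — which kind of interaction? (ADVICE / EFFECT / MECHANISM /
  INT / NEGATIVE)
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

__all__ = [
    "BINARY", "FIVE_CLASS", "BINARY_LABELS", "FIVE_CLASS_LABELS",
    "POSITIVE", "NEGATIVE", "DDI_TYPES",
    "EntityMention", "PairAnnotation", "Sentence", "Document", "Corpus",
    "CandidateInstance", "CorpusValidationError",
    "parse_ddi_corpus", "parse_ddi_corpus_string", "serialize_corpus",
    "generate_candidate_instances", "corpus_candidates",
    "write_candidates_jsonl", "write_predictions_tsv",
]

BINARY = "binary"
FIVE_CLASS = "five_class"

POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"
DDI_TYPES = ("ADVICE", "EFFECT", "MECHANISM", "INT")

BINARY_LABELS = (NEGATIVE, POSITIVE)
FIVE_CLASS_LABELS = (NEGATIVE,) + DDI_TYPES

# Accept the spelling used by the 2013 shared task files alongside ours.
_TYPE_ALIASES = {
    "ADVICE": "ADVICE", "ADVISE": "ADVICE",
    "EFFECT": "EFFECT", "MECHANISM": "MECHANISM", "INT": "INT",
}


class CorpusValidationError(ValueError):
    """An annotation is inconsistent with the sentence it belongs to."""


@dataclass
class EntityMention:
    id: str
    char_start: int  # 0-based, inclusive
    char_end: int    # 0-based, inclusive
    surface: str


@dataclass
class PairAnnotation:
    e1: str
    e2: str
    interacts: bool
    ddi_type: str | None = None


@dataclass
class Sentence:
    id: str
    text: str
    entities: list[EntityMention] = field(default_factory=list)
    pairs: list[PairAnnotation] = field(default_factory=list)

    def entity(self, entity_id: str) -> EntityMention:
        for e in self.entities:
            if e.id == entity_id:
                return e
        raise KeyError(entity_id)


@dataclass
class Document:
    id: str
    sentences: list[Sentence] = field(default_factory=list)


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)
    task_kind: str = BINARY

    @property
    def labels(self) -> tuple[str, ...]:
        return FIVE_CLASS_LABELS if self.task_kind == FIVE_CLASS else BINARY_LABELS

    def sentences(self):
        for doc in self.documents:
            yield from doc.sentences


@dataclass
class CandidateInstance:
    """One target drug pair in one sentence — the unit of classification."""

    sentence: Sentence
    target1: str
    target2: str
    label: str


def _validate_sentence(sent: Sentence, task_kind: str) -> None:
    seen_ids = set()
    for ent in sent.entities:
        if ent.id in seen_ids:
            raise CorpusValidationError(
                f"duplicate entity id {ent.id!r} in sentence {sent.id!r}")
        seen_ids.add(ent.id)
        if not (0 <= ent.char_start <= ent.char_end < len(sent.text)):
            raise CorpusValidationError(
                f"entity {ent.id!r}: offsets {ent.char_start}-{ent.char_end} "
                f"outside sentence {sent.id!r} of length {len(sent.text)}")
        slice_ = sent.text[ent.char_start:ent.char_end + 1]
        if slice_ != ent.surface:
            raise CorpusValidationError(
                f"entity {ent.id!r}: surface {ent.surface!r} does not match "
                f"text slice {slice_!r} at {ent.char_start}-{ent.char_end}")
    for pair in sent.pairs:
        if pair.e1 == pair.e2:
            raise CorpusValidationError(
                f"pair in sentence {sent.id!r} references entity "
                f"{pair.e1!r} twice")
        for eid in (pair.e1, pair.e2):
            if eid not in seen_ids:
                raise CorpusValidationError(
                    f"pair in sentence {sent.id!r} references unknown "
                    f"entity {eid!r}")
        if task_kind == FIVE_CLASS:
            if pair.interacts and pair.ddi_type is None:
                raise CorpusValidationError(
                    f"interacting pair ({pair.e1}, {pair.e2}) in sentence "
                    f"{sent.id!r} lacks a ddi type")
        if pair.ddi_type is not None and pair.ddi_type not in DDI_TYPES:
            raise CorpusValidationError(
                f"unknown ddi type {pair.ddi_type!r} in sentence {sent.id!r}")


def _parse_char_offset(raw: str) -> tuple[int, int]:
    # Discontinuous mentions list several spans ("12-18;25-30"); keep the
    # first span for positioning.
    first = raw.split(";")[0]
    start, end = first.split("-")
    return int(start), int(end)


def _sentence_from_element(el) -> Sentence:
    sent = Sentence(id=el.get("id"), text=el.get("text") or "")
    for ent_el in el.findall("entity"):
        start, end = _parse_char_offset(ent_el.get("charOffset"))
        sent.entities.append(EntityMention(
            id=ent_el.get("id"),
            char_start=start,
            char_end=end,
            surface=ent_el.get("text") or "",
        ))
    for pair_el in el.findall("pair"):
        interacts = (pair_el.get("ddi") or "false").lower() == "true"
        raw_type = pair_el.get("type")
        ddi_type = None
        if raw_type is not None:
            key = raw_type.upper()
            if key not in _TYPE_ALIASES:
                raise CorpusValidationError(
                    f"unknown ddi type {raw_type!r} in sentence {sent.id!r}")
            ddi_type = _TYPE_ALIASES[key]
        sent.pairs.append(PairAnnotation(
            e1=pair_el.get("e1"), e2=pair_el.get("e2"),
            interacts=interacts, ddi_type=ddi_type,
        ))
    return sent


def parse_ddi_corpus(path: str | Path, task_kind: str = BINARY) -> Corpus:
    """Parse a DDI XML corpus file, validating offsets against the text.

    Raises ``lxml.etree.XMLSyntaxError`` (which names the offending line)
    on malformed XML and :class:`CorpusValidationError` on annotations that
    contradict the sentence text.
    """
    tree = etree.parse(str(path))
    return _corpus_from_root(tree.getroot(), task_kind)


def parse_ddi_corpus_string(xml: str | bytes, task_kind: str = BINARY) -> Corpus:
    """Parse a corpus from an in-memory XML string."""
    if isinstance(xml, str):
        xml = xml.encode()
    return _corpus_from_root(etree.fromstring(xml), task_kind)


def _corpus_from_root(root, task_kind: str) -> Corpus:
    if task_kind not in (BINARY, FIVE_CLASS):
        raise ValueError(f"unknown task kind {task_kind!r}")
    doc_elements = [root] if root.tag == "document" else root.findall("document")
    corpus = Corpus(task_kind=task_kind)
    for doc_el in doc_elements:
        doc = Document(id=doc_el.get("id"))
        seen_sids = set()
        for sent_el in doc_el.findall("sentence"):
            sent = _sentence_from_element(sent_el)
            if sent.id in seen_sids:
                raise CorpusValidationError(
                    f"duplicate sentence id {sent.id!r} in document {doc.id!r}")
            seen_sids.add(sent.id)
            _validate_sentence(sent, task_kind)
            doc.sentences.append(sent)
        corpus.documents.append(doc)
    return corpus


def serialize_corpus(corpus: Corpus) -> bytes:
    """Render a corpus back to XML bytes (deterministic attribute order)."""
    root = etree.Element("corpus")
    for doc in corpus.documents:
        doc_el = etree.SubElement(root, "document", id=doc.id)
        for sent in doc.sentences:
            sent_el = etree.SubElement(doc_el, "sentence",
                                       id=sent.id, text=sent.text)
            for ent in sent.entities:
                etree.SubElement(
                    sent_el, "entity", id=ent.id,
                    charOffset=f"{ent.char_start}-{ent.char_end}",
                    type="drug", text=ent.surface)
            for i, pair in enumerate(sent.pairs):
                attrs = {
                    "id": f"{sent.id}.p{i}",
                    "e1": pair.e1, "e2": pair.e2,
                    "ddi": "true" if pair.interacts else "false",
                }
                if pair.ddi_type is not None:
                    attrs["type"] = pair.ddi_type
                etree.SubElement(sent_el, "pair", **attrs)
    return etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8")


def generate_candidate_instances(sentence: Sentence, gold: bool = True,
                                 task_kind: str = BINARY) -> list[CandidateInstance]:
    """Enumerate candidate drug pairs of a sentence.

    With ``gold=True``, one instance per annotated pair carrying its label;
    otherwise all C(n, 2) unordered entity pairs, labelled NEGATIVE.  A
    sentence with n drug mentions therefore yields n(n-1)/2 candidates in
    the un-annotated mode.  Order is deterministic: pairs sorted by the
    character offsets of their two mentions, then entity ids.
    """
    by_id = {e.id: e for e in sentence.entities}

    def sort_key(e1_id: str, e2_id: str):
        a, b = by_id[e1_id], by_id[e2_id]
        if (a.char_start, a.id) > (b.char_start, b.id):
            a, b = b, a
        return (a.char_start, b.char_start, a.id, b.id)

    instances: list[CandidateInstance] = []
    if gold:
        for pair in sentence.pairs:
            if task_kind == FIVE_CLASS:
                label = pair.ddi_type if pair.interacts else NEGATIVE
            else:
                label = POSITIVE if pair.interacts else NEGATIVE
            instances.append(CandidateInstance(
                sentence=sentence, target1=pair.e1, target2=pair.e2,
                label=label))
        instances.sort(key=lambda c: sort_key(c.target1, c.target2))
    else:
        for e1, e2 in itertools.combinations(
                sorted(sentence.entities, key=lambda e: (e.char_start, e.id)), 2):
            instances.append(CandidateInstance(
                sentence=sentence, target1=e1.id, target2=e2.id,
                label=NEGATIVE))
    return instances


def corpus_candidates(corpus: Corpus, gold: bool = True) -> list[CandidateInstance]:
    """All candidate instances of a corpus, in document/sentence order."""
    out: list[CandidateInstance] = []
    for sent in corpus.sentences():
        out.extend(generate_candidate_instances(
            sent, gold=gold, task_kind=corpus.task_kind))
    return out


def write_candidates_jsonl(instances: list[CandidateInstance],
                           path: str | Path) -> None:
    """Debugging mirror: one candidate instance per JSON line."""
    with open(path, "w") as fh:
        for inst in instances:
            fh.write(json.dumps({
                "sentence_id": inst.sentence.id,
                "text": inst.sentence.text,
                "e1": inst.target1,
                "e2": inst.target2,
                "label": inst.label,
            }) + "\n")


def write_predictions_tsv(rows, path: str | Path) -> None:
    """Write predictions: sentence_id, e1, e2, label, probability vector."""
    with open(path, "w") as fh:
        for sentence_id, e1, e2, label, probs in rows:
            prob_str = ",".join(f"{p:.6f}" for p in probs)
            fh.write(f"{sentence_id}\t{e1}\t{e2}\t{label}\t{prob_str}\n")
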