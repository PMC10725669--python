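"""Multi-task model: shared recurrent encoder with per-task softmax heads.

The coarse-grained (binary DDI) and fine-grained (five-type) tasks share
one embedding table and one recurrent cell; each task owns a softmax
classifier over the final hidden state H_n.  Training minimises
cross-entropy plus ridge regularisation on the classifier weights,

    J = mean(-log p(gold)) + (lambda / 2) ||W||^2,

with RMSprop, dropout on the embedding and hidden layers, and two phases:
a pretraining phase that trains the shared parameters under throwaway
heads, then a fine-tuning phase with fresh heads attached and everything
updated jointly.  Mini-batches alternate between tasks in proportion to
corpus size.  All randomness flows from one seed, so a fixed seed gives a
bit-identical training trace.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import RMSprop, Tensor, cross_entropy, gather_rows
from .corpus_io import Corpus, corpus_candidates
from .evaluation import MetricReport, multiclass_report
from .representation import (EmbeddingTable, build_representation,
                             build_vocabulary, init_embedding_table, tokenize)
from .recurrent_core import CellParams, CellState, VariantKind, cell_step

__all__ = ["TrainConfig", "ClassifierParams", "TrainedModel",
           "predict", "loss", "train", "evaluate_model"]


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    dropout: float = 0.2
    batch_size: int = 32
    epochs: int = 200
    ridge: float = 1e-4
    seed: int = 0
    variant: str = "PHAR"
    pretrain_epochs: int = 20
    hidden_size: int = 128
    embed_dim: int = 400
    p_dim: int = 4
    neighbor_radius: int = 1
    keep_punctuation: bool = False
    conventional_gate_roles: bool = False

    def __post_init__(self):
        if not (self.learning_rate > 0 and self.batch_size > 0
                and self.epochs > 0 and self.ridge >= 0):
            raise ValueError("learning_rate/batch_size/epochs must be positive"
                             " and ridge non-negative")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0 <= self.pretrain_epochs <= self.epochs:
            raise ValueError("pretrain_epochs must lie within epochs")
        VariantKind(self.variant)


@dataclass
class ClassifierParams:
    """One softmax head: W (k x hidden) and bias b (k x 1)."""

    W: Tensor
    b: Tensor
    labels: tuple[str, ...]

    @classmethod
    def init(cls, labels, hidden: int,
             rng: np.random.Generator) -> "ClassifierParams":
        k = len(labels)
        if k < 2:
            raise ValueError("a task needs at least two classes")
        s = 1.0 / np.sqrt(hidden)
        return cls(W=Tensor(rng.uniform(-s, s, size=(k, hidden)),
                            requires_grad=True),
                   b=Tensor(np.zeros((k, 1)), requires_grad=True),
                   labels=tuple(labels))

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def predict(h_n: np.ndarray, head: ClassifierParams) -> tuple[str, np.ndarray]:
    """Label and probability vector for one hidden state.

    Probabilities are softmax(W H_n + b); argmax ties break toward the
    lowest class index.
    """
    h = np.asarray(h_n, dtype=float).reshape(-1, 1)
    probs = _softmax(head.W.data @ h + head.b.data).ravel()
    return head.labels[int(np.argmax(probs))], probs


def loss(batch: list[tuple[np.ndarray, str]], head: ClassifierParams,
         ridge: float = 0.0) -> float:
    """Mean cross-entropy of a batch plus (ridge/2) ||W||_F^2."""
    if ridge < 0:
        raise ValueError("ridge weight must be non-negative")
    h = np.stack([np.asarray(hn, dtype=float).ravel()
                  for hn, _ in batch], axis=1)
    gold = np.array([head.labels.index(lbl) for _, lbl in batch])
    logits = Tensor(head.W.data @ h + head.b.data)
    nll = cross_entropy(logits, gold).data.item()
    return nll + 0.5 * ridge * float(np.sum(head.W.data ** 2))


# ---------------------------------------------------------------------------
# Batched sequence encoding
# ---------------------------------------------------------------------------

def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T)
    out._parents = (t,)
    out._backward = lambda g: t._accumulate(g.T)
    return out


def _dropout(t: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    if rate <= 0.0:
        return t
    mask = (rng.random(t.data.shape) >= rate) / (1.0 - rate)
    return t * Tensor(mask)


def _masked_blend(new: Tensor, old: Tensor, mask: np.ndarray) -> Tensor:
    # mask is (1, B) with 1 where the sequence is still active.
    return new * Tensor(mask) + old * Tensor(1.0 - mask)


def _encode_batch(ids: np.ndarray, phar: np.ndarray, lengths: np.ndarray,
                  params: CellParams, embedding: Tensor,
                  conventional_gate_roles: bool,
                  dropout: float = 0.0,
                  rng: np.random.Generator | None = None) -> Tensor:
    """Encode padded sequences; returns H_n of shape (hidden, B).

    ``ids`` is (B, T) embedding-row indices padded with 0, ``phar`` is
    (B, T, 4) padded with zeros.  Finished sequences carry their last state
    forward unchanged via masking, so H_n is the state at each sequence's
    own final token.
    """
    batch, t_max = ids.shape
    variant = params.variant
    state = CellState.zeros(params.hidden, batch=batch, variant=variant)
    for t in range(t_max):
        x_tok = _transpose(gather_rows(embedding, ids[:, t]))  # (d, B)
        if dropout > 0.0:
            x_tok = _dropout(x_tok, dropout, rng)
        x_phar = Tensor(phar[:, t, :].T)  # (4, B)
        new = cell_step(state, x_tok, x_phar, params, variant,
                        conventional_gate_roles=conventional_gate_roles)
        active = (lengths > t).astype(float)[None, :]
        if active.all():
            state = new
        else:
            blended = CellState(C=_masked_blend(new.C, state.C, active),
                                H=_masked_blend(new.H, state.H, active))
            if variant is VariantKind.FGR:
                blended.prev_gates = tuple(
                    _masked_blend(n, o, active)
                    for n, o in zip(new.prev_gates, state.prev_gates))
            state = blended
    return state.H


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class _TaskData:
    labels: tuple[str, ...]
    ids: list[np.ndarray]        # per instance: token-index vector
    phar: list[np.ndarray]       # per instance: (n, 4)
    gold: np.ndarray             # per instance: label index
    meta: list[tuple[str, str, str]]  # sentence id, e1, e2


def _prepare_task(corpus: Corpus, table: EmbeddingTable,
                  config: TrainConfig) -> _TaskData:
    labels = corpus.labels
    ids, phar, gold, meta = [], [], [], []
    for inst in corpus_candidates(corpus, gold=True):
        rep = build_representation(
            inst, table, neighbor_radius=config.neighbor_radius,
            keep_punctuation=config.keep_punctuation)
        ids.append(rep.token_indices)
        phar.append(rep.phar_vectors)
        gold.append(labels.index(rep.label))
        meta.append((inst.sentence.id, inst.target1, inst.target2))
    return _TaskData(labels=labels, ids=ids, phar=phar,
                     gold=np.array(gold, dtype=int), meta=meta)


def _pad_batch(data: _TaskData, idx: np.ndarray):
    lengths = np.array([len(data.ids[i]) for i in idx])
    t_max = int(lengths.max())
    ids = np.zeros((len(idx), t_max), dtype=np.intp)
    phar = np.zeros((len(idx), t_max, 4))
    for row, i in enumerate(idx):
        n = lengths[row]
        ids[row, :n] = data.ids[i]
        phar[row, :n] = data.phar[i]
    return ids, phar, lengths


@dataclass
class TrainedModel:
    table: EmbeddingTable
    cell: CellParams
    heads: dict[str, ClassifierParams]
    config: TrainConfig
    trace: list[dict]  # per epoch: {"loss": {task: v}, "f": {task: v}}

    def encode(self, ids: np.ndarray, phar: np.ndarray,
               lengths: np.ndarray) -> np.ndarray:
        h = _encode_batch(ids, phar, lengths, self.cell,
                          Tensor(self.table.vectors),
                          self.config.conventional_gate_roles)
        return h.data

    def predict_corpus(self, corpus: Corpus):
        """Predictions for every gold candidate of a corpus.

        Returns rows of (sentence_id, e1, e2, predicted_label, probs) plus
        the parallel gold label list.  Dropout is off: evaluation is
        deterministic.
        """
        if corpus.task_kind not in self.heads:
            raise KeyError(f"model has no head for task {corpus.task_kind!r}")
        head = self.heads[corpus.task_kind]
        data = _prepare_task(corpus, self.table, self.config)
        rows, gold_labels = [], []
        for start in range(0, len(data.gold), 256):
            idx = np.arange(start, min(start + 256, len(data.gold)))
            ids, phar, lengths = _pad_batch(data, idx)
            h = self.encode(ids, phar, lengths)
            probs = _softmax(head.W.data @ h + head.b.data)
            pred_idx = probs.argmax(axis=0)
            for col, i in enumerate(idx):
                sid, e1, e2 = data.meta[i]
                rows.append((sid, e1, e2, head.labels[pred_idx[col]],
                             probs[:, col].copy()))
                gold_labels.append(data.labels[data.gold[i]])
        return rows, gold_labels

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        arrays = {"embedding": self.table.vectors}
        for name, w in self.cell.weights.items():
            arrays[f"cell.{name}"] = w.data
        for task, head in self.heads.items():
            arrays[f"head.{task}.W"] = head.W.data
            arrays[f"head.{task}.b"] = head.b.data
        np.savez(out / "weights.npz", **arrays)
        manifest = {
            "config": dataclasses.asdict(self.config),
            "vocabulary": self.table.vocabulary,
            "heads": {t: list(h.labels) for t, h in self.heads.items()},
            "trace": self.trace,
            "versions": {"python": platform.python_version(),
                         "numpy": np.__version__},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, model_dir: str | Path) -> "TrainedModel":
        model_dir = Path(model_dir)
        manifest = json.loads((model_dir / "manifest.json").read_text())
        arrays = np.load(model_dir / "weights.npz")
        config = TrainConfig(**manifest["config"])
        vectors = arrays["embedding"]
        table = EmbeddingTable(vocabulary=manifest["vocabulary"],
                               vectors=vectors, d=vectors.shape[1],
                               seed=config.seed)
        cell = CellParams(variant=VariantKind(config.variant),
                          hidden=config.hidden_size, d=config.embed_dim,
                          p_dim=config.p_dim)
        for key in arrays.files:
            if key.startswith("cell."):
                cell.weights[key[5:]] = Tensor(arrays[key], requires_grad=True)
        heads = {}
        for task, labels in manifest["heads"].items():
            heads[task] = ClassifierParams(
                W=Tensor(arrays[f"head.{task}.W"], requires_grad=True),
                b=Tensor(arrays[f"head.{task}.b"], requires_grad=True),
                labels=tuple(labels))
        return cls(table=table, cell=cell, heads=heads, config=config,
                   trace=manifest["trace"])


def _trace_f(model: TrainedModel, corpus: Corpus) -> float:
    """Scalar F for learning curves: positive-class F for the binary task,
    micro-averaged F (CLA) for the five-class task."""
    rows, gold = model.predict_corpus(corpus)
    pred = [r[3] for r in rows]
    report = multiclass_report(pred, gold, corpus.labels)
    if corpus.task_kind == "binary":
        return report.per_class["POSITIVE"][2]
    return report.cla


def train(corpora: dict[str, Corpus], config: TrainConfig,
          eval_corpora: dict[str, Corpus] | None = None) -> TrainedModel:
    """Train the shared encoder with one softmax head per task.

    ``corpora`` maps a task kind ("binary" / "five_class") to its training
    corpus.  Phase 1 (``pretrain_epochs``) updates the shared embedding and
    cell parameters under throwaway heads; phase 2 attaches fresh heads and
    fine-tunes everything jointly.  If ``eval_corpora`` is given, a scalar
    F-score per task is recorded each epoch into the trace.
    """
    if not corpora or all(not any(True for _ in c.sentences())
                          for c in corpora.values()):
        raise ValueError("at least one task corpus must be non-empty")
    for task, corpus in corpora.items():
        if task != corpus.task_kind:
            raise ValueError(
                f"task key {task!r} does not match corpus kind "
                f"{corpus.task_kind!r}")

    seeds = np.random.SeedSequence(config.seed).spawn(4)
    table_seed = int(seeds[0].generate_state(1)[0] % (2 ** 31))
    param_rng = np.random.default_rng(seeds[1])
    batch_rng = np.random.default_rng(seeds[2])
    dropout_rng = np.random.default_rng(seeds[3])

    # Vocabulary from the training corpora; unseen test tokens map to UNK.
    token_lists = (tokenize(s.text, config.keep_punctuation).texts()
                   for c in corpora.values() for s in c.sentences())
    vocab = build_vocabulary(token_lists)
    table = init_embedding_table(vocab, d=config.embed_dim, seed=table_seed)
    embedding = Tensor(table.vectors, requires_grad=True)
    table.vectors = embedding.data  # shared storage: training updates it

    cell = CellParams.init(config.variant, config.hidden_size,
                           config.embed_dim, config.p_dim, rng=param_rng)
    tasks = {t: _prepare_task(c, table, config) for t, c in corpora.items()}

    model = TrainedModel(table=table, cell=cell, heads={}, config=config,
                         trace=[])

    def run_phase(n_epochs: int, heads: dict[str, ClassifierParams]):
        head_params = [p for h in heads.values() for p in h.parameters()]
        opt = RMSprop([embedding] + cell.parameters() + head_params,
                      lr=config.learning_rate)
        for _ in range(n_epochs):
            schedule = []
            for task, data in tasks.items():
                order = batch_rng.permutation(len(data.gold))
                for start in range(0, len(order), config.batch_size):
                    schedule.append((task, order[start:start + config.batch_size]))
            batch_rng.shuffle(schedule)
            epoch_loss = {task: [] for task in tasks}
            for task, idx in schedule:
                data = tasks[task]
                head = heads[task]
                ids, phar, lengths = _pad_batch(data, idx)
                h = _encode_batch(ids, phar, lengths, cell, embedding,
                                  config.conventional_gate_roles,
                                  dropout=config.dropout, rng=dropout_rng)
                h = _dropout(h, config.dropout, dropout_rng)
                logits = head.W @ h + head.b
                j = cross_entropy(logits, data.gold[idx])
                if config.ridge > 0:
                    j = j + (0.5 * config.ridge) * (head.W * head.W).sum()
                if not np.isfinite(j.data):
                    raise FloatingPointError(
                        f"training diverged at epoch {len(model.trace)}")
                opt.zero_grad()
                j.backward()
                opt.step()
                epoch_loss[task].append(float(j.data))
            entry = {"loss": {t: float(np.mean(v)) if v else float("nan")
                              for t, v in epoch_loss.items()}}
            if eval_corpora:
                model.heads = heads
                entry["f"] = {t: _trace_f(model, c)
                              for t, c in eval_corpora.items()}
            model.trace.append(entry)

    # Phase 1: shared parameters under throwaway heads.
    throwaway = {t: ClassifierParams.init(d.labels, config.hidden_size,
                                          param_rng)
                 for t, d in tasks.items()}
    run_phase(config.pretrain_epochs, throwaway)

    # Phase 2: fresh heads, joint fine-tuning.
    heads = {t: ClassifierParams.init(d.labels, config.hidden_size, param_rng)
             for t, d in tasks.items()}
    run_phase(config.epochs - config.pretrain_epochs, heads)
    model.heads = heads
    return model


def evaluate_model(model: TrainedModel, corpus: Corpus,
                   exclude: set | None = None) -> MetricReport:
    """Score a trained model's head against a gold corpus."""
    rows, gold = model.predict_corpus(corpus)
    pred = [r[3] for r in rows]
    return multiclass_report(pred, gold, corpus.labels, exclude=exclude)
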