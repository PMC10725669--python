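"""The Phar-LSTM recurrent cell and its ten published variants.

The base cell augments an LSTM step with a *pharmacological gate*: the
4-dimensional target-drug filter vector is squashed through its own sigmoid
gate and concatenated with the usual recurrent input

    z_t = (H_{t-1}, x_t^token)
    P_t = (g(W_P x_t^phar + b_P), z_t)
    C_t = g(W_I P_t + b_I) o C_{t-1} + g(W_F P_t + b_F) o h(W_C P_t + b_C)
    O_t = g(W_O P_t + b_O)
    H_t = O_t o h(C_t)

with g the logistic sigmoid, h = tanh, and o pointwise multiplication.

Note the gate arrangement: as published, the gate labelled "input" (W_I)
multiplies the previous cell state and the gate labelled "forget" (W_F)
multiplies the candidate — the reverse of the conventional naming.  The
cell is implemented exactly in this printed form; pass
``conventional_gate_roles=True`` to swap the two gates into the textbook
arrangement for comparison.

Variants (selected by :class:`VariantKind`):

=========  =============================================================
PHAR       the full cell above
NPG        no pharmacological gate — gates read z_t (the vanilla LSTM)
NIG        no input gate — C_{t-1} enters ungated
NIAF       input gate kept but its sigmoid removed
NFG        no forget gate — the candidate enters ungated
NFAF       forget gate kept but its sigmoid removed
NOG        no output gate — H_t = h(C_t)
NOAF       output gate kept but its sigmoid removed
CIFG       coupled gates: forget weight = 1 - input weight
PEEPHOLE   C_{t-1} joins the first two gate inputs, C_t the output gate
FGR        every gate also reads (I_{t-1}, F_{t-1}, O_{t-1}, C_{t-1})
=========  =============================================================
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat, gather_rows
from .representation import PharRepresentation

__all__ = ["VariantKind", "CellParams", "CellState", "cell_step",
           "encode_sequence", "PHAR_DIM"]

PHAR_DIM = 4  # the four target-drug filters


class VariantKind(str, enum.Enum):
    PHAR = "PHAR"
    NPG = "NPG"
    NIG = "NIG"
    NIAF = "NIAF"
    NFG = "NFG"
    NFAF = "NFAF"
    NOG = "NOG"
    NOAF = "NOAF"
    CIFG = "CIFG"
    PEEPHOLE = "PEEPHOLE"
    FGR = "FGR"


def _gate_input_size(variant: VariantKind, hidden: int, d: int,
                     p_dim: int) -> dict[str, int]:
    """Input width of each weight matrix for the given variant."""
    base = hidden + d if variant is VariantKind.NPG else p_dim + hidden + d
    sizes = {"I": base, "F": base, "C": base, "O": base}
    if variant is VariantKind.PEEPHOLE:
        sizes["I"] += hidden
        sizes["F"] += hidden
        sizes["O"] += hidden
    elif variant is VariantKind.FGR:
        for k in ("I", "F", "O"):
            sizes[k] += 4 * hidden
    return sizes


@dataclass
class CellParams:
    """Weights of one recurrent cell, shaped for a particular variant."""

    variant: VariantKind
    hidden: int
    d: int
    p_dim: int
    weights: dict[str, Tensor] = field(default_factory=dict)

    @classmethod
    def init(cls, variant: VariantKind | str, hidden: int, d: int,
             p_dim: int = PHAR_DIM, rng: np.random.Generator | None = None,
             scale: float | None = None) -> "CellParams":
        """Uniform init in [-s, s] with s = 1/sqrt(fan_in) by default."""
        variant = VariantKind(variant)
        rng = rng if rng is not None else np.random.default_rng(0)
        params = cls(variant=variant, hidden=hidden, d=d, p_dim=p_dim)

        def make(name: str, rows: int, cols: int):
            s = scale if scale is not None else 1.0 / np.sqrt(cols)
            params.weights[f"W_{name}"] = Tensor(
                rng.uniform(-s, s, size=(rows, cols)), requires_grad=True)
            params.weights[f"b_{name}"] = Tensor(
                np.zeros((rows, 1)), requires_grad=True)

        if variant is not VariantKind.NPG:
            make("P", p_dim, PHAR_DIM)
        sizes = _gate_input_size(variant, hidden, d, p_dim)
        for gate in ("I", "F", "C", "O"):
            if gate == "I" and variant is VariantKind.NIG:
                continue
            if gate == "F" and variant in (VariantKind.NFG, VariantKind.CIFG):
                continue
            if gate == "O" and variant is VariantKind.NOG:
                continue
            make(gate, hidden, sizes[gate])
        return params

    def parameters(self) -> list[Tensor]:
        return list(self.weights.values())

    def __getitem__(self, key: str) -> Tensor:
        try:
            return self.weights[key]
        except KeyError:
            raise KeyError(
                f"weight {key!r} not present for variant {self.variant.value}")


@dataclass
class CellState:
    """Recurrent state: cell C, hidden H, and (for FGR) the previous gates."""

    C: Tensor
    H: Tensor
    prev_gates: tuple[Tensor, Tensor, Tensor] | None = None
    # Activations of the step that produced this state, for inspection:
    # keys "keep" (gate on C_{t-1}), "write" (gate on the candidate), "out".
    gates: dict[str, Tensor] = field(default_factory=dict)

    @classmethod
    def zeros(cls, hidden: int, batch: int = 1,
              variant: VariantKind = VariantKind.PHAR) -> "CellState":
        z = lambda: Tensor(np.zeros((hidden, batch)))
        state = cls(C=z(), H=z())
        if variant is VariantKind.FGR:
            state.prev_gates = (z(), z(), z())
        return state


def _affine(params: CellParams, gate: str, x: Tensor) -> Tensor:
    w = params[f"W_{gate}"]
    if w.data.shape[1] != x.data.shape[0]:
        raise ValueError(
            f"W_{gate} expects input of size {w.data.shape[1]}, "
            f"got {x.data.shape[0]}")
    return w @ x + params[f"b_{gate}"]


def cell_step(state: CellState, x_token: Tensor | np.ndarray,
              x_phar: Tensor | np.ndarray, params: CellParams,
              variant: VariantKind | str | None = None,
              conventional_gate_roles: bool = False) -> CellState:
    """One recurrent step.  Inputs are column vectors or (dim, B) batches."""
    variant = VariantKind(variant) if variant is not None else params.variant
    x_token = x_token if isinstance(x_token, Tensor) else Tensor(x_token)
    x_phar = x_phar if isinstance(x_phar, Tensor) else Tensor(x_phar)
    if x_token.data.ndim == 1:
        x_token = Tensor(x_token.data[:, None])
    if x_phar.data.ndim == 1:
        x_phar = Tensor(x_phar.data[:, None])

    z_t = concat([state.H, x_token], axis=0)
    if variant is VariantKind.NPG:
        P_t = z_t
    else:
        phar_gate = _affine(params, "P", x_phar).sigmoid()
        P_t = concat([phar_gate, z_t], axis=0)

    if variant is VariantKind.FGR:
        I_prev, F_prev, O_prev = state.prev_gates
        gate_in = concat([P_t, I_prev, F_prev, O_prev, state.C], axis=0)
    elif variant is VariantKind.PEEPHOLE:
        gate_in = concat([P_t, state.C], axis=0)
    else:
        gate_in = P_t

    # Gate on the previous cell state ("input" as printed) and gate on the
    # candidate ("forget" as printed); the conventional flag swaps them.
    keep_name, write_name = ("F", "I") if conventional_gate_roles else ("I", "F")

    candidate = _affine(params, "C", P_t).tanh()

    if variant is VariantKind.CIFG:
        # The coupled gate is always parameterised by the "I" weights.
        a = _affine(params, "I", gate_in).sigmoid()
        coupled = 1.0 - a
        C_t = a * state.C + coupled * candidate
        gate_keep, gate_write = a, coupled
    else:
        if variant is VariantKind.NIG:
            gate_keep = None
            keep_term = state.C
        elif variant is VariantKind.NIAF:
            gate_keep = _affine(params, keep_name, gate_in)
            keep_term = gate_keep * state.C
        else:
            gate_keep = _affine(params, keep_name, gate_in).sigmoid()
            keep_term = gate_keep * state.C
        if variant is VariantKind.NFG:
            gate_write = None
            write_term = candidate
        elif variant is VariantKind.NFAF:
            gate_write = _affine(params, write_name, gate_in)
            write_term = gate_write * candidate
        else:
            gate_write = _affine(params, write_name, gate_in).sigmoid()
            write_term = gate_write * candidate
        C_t = keep_term + write_term

    if variant is VariantKind.NOG:
        O_t = None
        H_t = C_t.tanh()
    else:
        out_in = concat([P_t, C_t], axis=0) \
            if variant is VariantKind.PEEPHOLE else gate_in
        O_t = _affine(params, "O", out_in)
        if variant is not VariantKind.NOAF:
            O_t = O_t.sigmoid()
        H_t = O_t * C_t.tanh()

    if not np.all(np.isfinite(H_t.data)):
        raise FloatingPointError("non-finite hidden state in cell step")

    new_state = CellState(C=C_t, H=H_t)
    for name, gate in (("keep", gate_keep), ("write", gate_write),
                       ("out", O_t)):
        if gate is not None:
            new_state.gates[name] = gate
    if variant is VariantKind.FGR:
        zero = Tensor(np.zeros_like(C_t.data))
        new_state.prev_gates = (
            gate_keep if gate_keep is not None else zero,
            gate_write if gate_write is not None else zero,
            O_t if O_t is not None else zero,
        )
    return new_state


def encode_sequence(rep: PharRepresentation, params: CellParams,
                    variant: VariantKind | str | None = None,
                    conventional_gate_roles: bool = False,
                    embedding: Tensor | None = None) -> Tensor:
    """Run the cell over a representation from a zero state; return H_n.

    The final hidden state is what the classifier consumes.  If
    ``embedding`` (a trainable table tensor) is given, token vectors are
    looked up from it so gradients flow into the table; otherwise the
    frozen vectors stored on the representation are used.
    """
    variant = VariantKind(variant) if variant is not None else params.variant
    n = len(rep)
    if n == 0:
        raise ValueError("cannot encode an empty token sequence")
    state = CellState.zeros(params.hidden, batch=1, variant=variant)
    for t in range(n):
        if embedding is not None:
            x_tok = _as_column(gather_rows(embedding, rep.token_indices[t:t + 1]))
        else:
            x_tok = Tensor(rep.token_vectors[t][:, None])
        x_phar = Tensor(rep.phar_vectors[t][:, None])
        state = cell_step(state, x_tok, x_phar, params, variant,
                          conventional_gate_roles=conventional_gate_roles)
    return state.H


def _as_column(row: Tensor) -> Tensor:
    """Reshape a (1, d) lookup into a (d, 1) column, keeping the graph."""
    out = Tensor(row.data.reshape(-1, 1))
    out._parents = (row,)
    out._backward = lambda g: row._accumulate(g.reshape(row.data.shape))
    return out
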