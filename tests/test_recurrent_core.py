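"""The pharmacological-gate cell and its ten variants.

Each variant's forward pass is pinned by closed-form hand evaluation and
its backward pass by central finite differences; the no-phar-gate variant
is cross-checked against an independently coded textbook LSTM step.
"""

import math

import numpy as np
import pytest
from scipy.special import expit

import pharlstm as ph
from pharlstm._autodiff import Tensor
from pharlstm.recurrent_core import PHAR_DIM, CellParams, CellState, cell_step

ALL_VARIANTS = [v.value for v in ph.VariantKind]


def zero_params(variant, hidden=3, d=4, p_dim=2):
    params = CellParams.init(variant, hidden, d, p_dim,
                             rng=np.random.default_rng(0))
    for w in params.weights.values():
        w.data[:] = 0.0
    return params


def random_step_inputs(rng, d=4, batch=1):
    return rng.normal(size=(d, batch)), rng.normal(size=(PHAR_DIM, batch))


class TestForward:
    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_zero_params_give_zero_state(self, variant, rng):
        """With all-zero weights the candidate is tanh(0)=0, so C_1 = 0 and
        H_1 = 0 regardless of the half-open gates g(0) = 0.5."""
        params = zero_params(variant)
        state = CellState.zeros(3, 1, ph.VariantKind(variant))
        x_tok, x_phar = random_step_inputs(rng)
        out = cell_step(state, x_tok, x_phar, params)
        np.testing.assert_array_equal(out.C.data, 0.0)
        np.testing.assert_array_equal(out.H.data, 0.0)

    def test_scalar_hand_computation(self):
        """hidden = d = p_dim = 1, all weights 1, biases 0, zero inputs and
        state: evaluate the printed recursion by hand."""
        params = CellParams.init("PHAR", hidden=1, d=1, p_dim=1,
                                 rng=np.random.default_rng(0))
        for name, w in params.weights.items():
            w.data[:] = 1.0 if name.startswith("W") else 0.0
        state = CellState.zeros(1, 1)
        out = cell_step(state, np.zeros(1), np.zeros(PHAR_DIM), params)
        # Hand evaluation: phar gate g(0) = 1/2; P_t = (1/2, H_0=0, x=0).
        # Every gate preactivation is W . P_t = 1/2.
        g_half = 1.0 / (1.0 + math.exp(-0.5))
        c1 = g_half * 0.0 + g_half * math.tanh(0.5)
        h1 = g_half * math.tanh(c1)
        assert out.C.data[0, 0] == pytest.approx(c1, abs=1e-10)
        assert out.H.data[0, 0] == pytest.approx(h1, abs=1e-10)

    def test_phar_gate_constant_equals_npg_with_extra_feature(self, rng):
        """Zero W_P with bias b_P makes the phar gate a constant c; the step
        then equals a no-phar-gate cell fed c as an appended input feature."""
        hidden, d, p_dim = 3, 4, 2
        phar = CellParams.init("PHAR", hidden, d, p_dim,
                               rng=np.random.default_rng(1))
        phar["W_P"].data[:] = 0.0
        phar["b_P"].data[:] = 0.7  # constant gate c = g(0.7)
        c = expit(0.7)
        # NPG cell over an input of size d + p_dim with c appended:
        npg = CellParams.init("NPG", hidden, d + p_dim, p_dim,
                              rng=np.random.default_rng(2))
        # P_t orders as (phar-gate, H, x); z_t as (H, x_aug). Rearrange the
        # PHAR weight columns [c-slot | H | x] into [H | x | c-slot].
        for gate in ("I", "F", "C", "O"):
            w = phar[f"W_{gate}"].data
            npg[f"W_{gate}"].data[:] = np.concatenate(
                [w[:, p_dim:], w[:, :p_dim]], axis=1)
            npg[f"b_{gate}"].data[:] = phar[f"b_{gate}"].data
        x_tok, x_phar = random_step_inputs(rng, d=d)
        h0 = rng.normal(size=(hidden, 1))
        state = CellState(C=Tensor(rng.normal(size=(hidden, 1))), H=Tensor(h0))
        out_phar = cell_step(state, x_tok, x_phar, phar)
        x_aug = np.concatenate([x_tok, np.full((p_dim, 1), c)])
        state2 = CellState(C=Tensor(state.C.data.copy()),
                           H=Tensor(h0.copy()))
        out_npg = cell_step(state2, x_aug, x_phar, npg)
        np.testing.assert_allclose(out_phar.H.data, out_npg.H.data,
                                   atol=1e-12)

    def test_conventional_gate_roles_swaps_gates(self, rng):
        params = CellParams.init("PHAR", 3, 4, 2, rng=np.random.default_rng(3))
        x_tok, x_phar = random_step_inputs(rng)
        state = CellState.zeros(3, 1)
        printed = cell_step(state, x_tok, x_phar, params)
        swapped = cell_step(CellState.zeros(3, 1), x_tok, x_phar, params,
                            conventional_gate_roles=True)
        # from a zero state C_{t-1}=0, so only the candidate gate matters;
        # the two arrangements use different weight matrices for it
        assert not np.allclose(printed.C.data, swapped.C.data)

    def test_shape_mismatch_names_weight(self, rng):
        params = CellParams.init("PHAR", 3, 4, 2, rng=np.random.default_rng(0))
        state = CellState.zeros(3, 1)
        with pytest.raises(ValueError):
            cell_step(state, np.zeros((7, 1)), np.zeros((4, 1)), params)

    def test_missing_variant_weight_is_reported(self):
        params = CellParams.init("NOG", 3, 4, 2, rng=np.random.default_rng(0))
        with pytest.raises(KeyError, match="W_O"):
            params["W_O"]


class TestVariantSemantics:
    def test_cifg_gates_sum_to_one_exactly(self, rng):
        params = CellParams.init("CIFG", 4, 5, 2, rng=np.random.default_rng(4))
        x_tok, x_phar = random_step_inputs(rng, d=5)
        state = CellState(C=Tensor(rng.normal(size=(4, 1))),
                          H=Tensor(rng.normal(size=(4, 1))))
        out = cell_step(state, x_tok, x_phar, params)
        total = out.gates["keep"].data + out.gates["write"].data
        assert np.all(total == 1.0)

    @pytest.mark.parametrize("variant", [
        v for v in ALL_VARIANTS if v not in ("NIAF", "NFAF", "NOAF", "NIG",
                                             "NFG", "NOG")])
    def test_sigmoid_gates_stay_in_unit_interval(self, variant, rng):
        params = CellParams.init(variant, 4, 5, 2,
                                 rng=np.random.default_rng(5), scale=3.0)
        x_tok, x_phar = random_step_inputs(rng, d=5)
        state = CellState(C=Tensor(rng.normal(size=(4, 1))),
                          H=Tensor(rng.normal(size=(4, 1))),
                          prev_gates=(Tensor(np.zeros((4, 1))),) * 3)
        out = cell_step(state, x_tok, x_phar, params)
        for gate in out.gates.values():
            assert np.all((gate.data > 0) & (gate.data < 1))
        assert np.all(np.abs(np.tanh(out.C.data)) < 1)

    @pytest.mark.parametrize("variant, gate", [
        ("NIAF", "keep"), ("NFAF", "write"), ("NOAF", "out")])
    def test_unactivated_gates_escape_unit_interval(self, variant, gate, rng):
        """Removing a sigmoid leaves the gate an unbounded affine map."""
        params = CellParams.init(variant, 4, 5, 2,
                                 rng=np.random.default_rng(6), scale=5.0)
        x_tok, x_phar = random_step_inputs(rng, d=5)
        state = CellState(C=Tensor(rng.normal(size=(4, 1))),
                          H=Tensor(rng.normal(size=(4, 1))))
        out = cell_step(state, x_tok, x_phar, params)
        assert np.any(np.abs(out.gates[gate].data) > 1.0)

    def test_nig_drops_gate_on_previous_cell(self, rng):
        """NIG: C_t = C_{t-1} + write o candidate, so with a zero write gate
        region the previous cell state passes through untouched."""
        params = CellParams.init("NIG", 3, 4, 2, rng=np.random.default_rng(7))
        params["W_F"].data[:] = 0.0
        params["b_F"].data[:] = -50.0   # write gate ~ 0
        c0 = rng.normal(size=(3, 1))
        state = CellState(C=Tensor(c0), H=Tensor(np.zeros((3, 1))))
        x_tok, x_phar = random_step_inputs(rng)
        out = cell_step(state, x_tok, x_phar, params)
        np.testing.assert_allclose(out.C.data, c0, atol=1e-12)

    def test_nog_hidden_is_tanh_of_cell(self, rng):
        params = CellParams.init("NOG", 3, 4, 2, rng=np.random.default_rng(8))
        state = CellState.zeros(3, 1)
        x_tok, x_phar = random_step_inputs(rng)
        out = cell_step(state, x_tok, x_phar, params)
        np.testing.assert_allclose(out.H.data, np.tanh(out.C.data))


class TestGradients:
    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_analytic_gradients_match_finite_differences(self, variant):
        """Central-difference check of every parameter through a 3-step
        unrolled sequence, relative error < 1e-4."""
        hidden, d, p_dim, n = 3, 4, 2, 3
        rng = np.random.default_rng(11)
        params = CellParams.init(variant, hidden, d, p_dim,
                                 rng=np.random.default_rng(12))
        xs = [(rng.normal(size=(d, 1)), rng.normal(size=(PHAR_DIM, 1)))
              for _ in range(n)]

        def forward():
            state = CellState.zeros(hidden, 1, ph.VariantKind(variant))
            for x_tok, x_phar in xs:
                state = cell_step(state, x_tok, x_phar, params)
            return (state.H * state.H).sum()

        loss = forward()
        for p in params.parameters():
            p.zero_grad()
        loss.backward()
        eps = 1e-6
        for name, w in params.weights.items():
            analytic = w.grad if w.grad is not None else np.zeros_like(w.data)
            it = np.nditer(w.data, flags=["multi_index"])
            while not it.finished:
                ij = it.multi_index
                orig = w.data[ij]
                w.data[ij] = orig + eps
                fp = forward().data.item()
                w.data[ij] = orig - eps
                fm = forward().data.item()
                w.data[ij] = orig
                fd = (fp - fm) / (2 * eps)
                denom = max(abs(fd), abs(analytic[ij]), 1e-6)
                assert abs(fd - analytic[ij]) / denom < 1e-4, \
                    f"{variant} {name}{ij}: fd={fd} analytic={analytic[ij]}"
                it.iternext()


class TestEncodeSequence:
    def _rep(self, table, n_tokens):
        sent_text = " ".join(["aspirin"] + ["strongly"] * (n_tokens - 2)
                             + ["warfarin"])
        sent = ph.Sentence(id="s", text=sent_text)
        pos = 0
        for i, word in enumerate(sent_text.split()):
            if i in (0, n_tokens - 1):
                sent.entities.append(ph.EntityMention(
                    f"e{i}", pos, pos + len(word) - 1, word))
            pos += len(word) + 1
        inst = ph.CandidateInstance(sent, sent.entities[0].id,
                                    sent.entities[1].id, ph.NEGATIVE)
        return ph.build_representation(inst, table)

    def test_single_token_error(self, small_table):
        rep = self._rep(small_table, 3)
        rep.token_indices = rep.token_indices[:0]
        with pytest.raises(ValueError):
            ph.encode_sequence(rep, CellParams.init(
                "PHAR", 2, small_table.d, 2, rng=np.random.default_rng(0)))

    def test_n1_equals_single_cell_step(self, small_table):
        rep = self._rep(small_table, 2)
        rep.token_indices = rep.token_indices[:1]
        rep.token_vectors = rep.token_vectors[:1]
        rep.phar_vectors = rep.phar_vectors[:1]
        params = CellParams.init("PHAR", 4, small_table.d, 2,
                                 rng=np.random.default_rng(1))
        h = ph.encode_sequence(rep, params)
        manual = cell_step(CellState.zeros(4, 1),
                           rep.token_vectors[0][:, None],
                           rep.phar_vectors[0][:, None], params)
        np.testing.assert_array_equal(h.data, manual.H.data)

    @pytest.mark.parametrize("variant", ["PHAR", "FGR"])
    def test_batched_encoding_equals_instance_loop(self, variant, small_table):
        """Padded/masked batch evaluation reproduces the per-instance loop."""
        from pharlstm.model import _encode_batch
        params = CellParams.init(variant, 4, small_table.d, 2,
                                 rng=np.random.default_rng(2))
        reps = [self._rep(small_table, n) for n in (3, 5, 7)]
        t_max = max(len(r) for r in reps)
        ids = np.zeros((3, t_max), dtype=np.intp)
        phar = np.zeros((3, t_max, 4))
        lengths = np.array([len(r) for r in reps])
        for row, r in enumerate(reps):
            ids[row, :len(r)] = r.token_indices
            phar[row, :len(r)] = r.phar_vectors
        h_batch = _encode_batch(ids, phar, lengths, params,
                                Tensor(small_table.vectors), False)
        for col, r in enumerate(reps):
            h_single = ph.encode_sequence(r, params)
            np.testing.assert_allclose(h_batch.data[:, col:col + 1],
                                       h_single.data, atol=1e-6)

    def test_fgr_threads_previous_gates(self, small_table):
        """Unrolled substitution of the full-gate-recurrence equations."""
        hidden, p_dim = 3, 2
        params = CellParams.init("FGR", hidden, small_table.d, p_dim,
                                 rng=np.random.default_rng(3))
        rep = self._rep(small_table, 3)
        h = ph.encode_sequence(rep, params)

        # Independent unroll with plain numpy.
        W = {k: v.data for k, v in params.weights.items()}
        C = np.zeros((hidden, 1))
        H = np.zeros((hidden, 1))
        I = F = O = np.zeros((hidden, 1))
        for t in range(len(rep)):
            x = rep.token_vectors[t][:, None]
            xp = rep.phar_vectors[t][:, None]
            P = np.concatenate([expit(W["W_P"] @ xp + W["b_P"]),
                                H, x])
            gate_in = np.concatenate([P, I, F, O, C])
            I = expit(W["W_I"] @ gate_in + W["b_I"])
            F = expit(W["W_F"] @ gate_in + W["b_F"])
            O = expit(W["W_O"] @ gate_in + W["b_O"])
            C = I * C + F * np.tanh(W["W_C"] @ P + W["b_C"])
            H = O * np.tanh(C)
        np.testing.assert_allclose(h.data, H, atol=1e-12)


class TestVanillaOracle:
    def test_npg_matches_textbook_lstm(self, rng):
        """The no-phar-gate cell is the vanilla LSTM once the printed gate
        roles are mapped: the weights labelled "I" gate the previous cell
        state (the textbook forget gate) and the weights labelled "F" gate
        the candidate (the textbook input gate)."""
        hidden, d = 5, 6
        params = CellParams.init("NPG", hidden, d,
                                 rng=np.random.default_rng(21))
        x = rng.normal(size=(d, 1))
        h0 = rng.normal(size=(hidden, 1))
        c0 = rng.normal(size=(hidden, 1))
        state = CellState(C=Tensor(c0.copy()), H=Tensor(h0.copy()))
        out = cell_step(state, x, np.zeros((PHAR_DIM, 1)), params)

        # Independent textbook LSTM step, coded directly from the standard
        # equations: f = s(Wf z), i = s(Wi z), c~ = tanh(Wc z),
        # C = f*C0 + i*c~, o = s(Wo z), H = o*tanh(C).
        z = np.concatenate([h0, x])
        W = {k: v.data for k, v in params.weights.items()}
        f_gate = 1.0 / (1.0 + np.exp(-(W["W_I"] @ z + W["b_I"])))
        i_gate = 1.0 / (1.0 + np.exp(-(W["W_F"] @ z + W["b_F"])))
        c_tilde = np.tanh(W["W_C"] @ z + W["b_C"])
        c_new = f_gate * c0 + i_gate * c_tilde
        o_gate = 1.0 / (1.0 + np.exp(-(W["W_O"] @ z + W["b_O"])))
        h_new = o_gate * np.tanh(c_new)
        np.testing.assert_allclose(out.C.data, c_new, atol=1e-6)
        np.testing.assert_allclose(out.H.data, h_new, atol=1e-6)
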