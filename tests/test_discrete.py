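"""Masked discrete diffusion: posterior, loss, path-planning sampler."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duet.discrete import (
    MASK,
    N_AMINO,
    SequenceState,
    alpha_linear,
    inverse_fold_sample,
    mask_forward,
    path_planning_step,
    reverse_posterior,
    round_half_away,
    sample_sequence,
    sample_sequence_batch,
    seq_loss,
)
from duet.synthetic import DiscreteJointSpec, enumerate_discrete_joint


def _log_softmax(a):
    m = a.max(axis=-1, keepdims=True)
    return a - m - np.log(np.exp(a - m).sum(axis=-1, keepdims=True))


class TestForward:
    @pytest.mark.parametrize("t,expected", [(0.0, 1.0), (1.0, 0.0), (0.25, 0.75)])
    def test_alpha_linear(self, t, expected):
        assert alpha_linear(t) == expected

    def test_endpoints(self):
        s0 = SequenceState(np.arange(10) % N_AMINO, 0.0)
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(mask_forward(s0, 0.0, rng).tokens, s0.tokens)
        assert np.all(mask_forward(s0, 1.0, rng).tokens == MASK)

    def test_masked_fraction(self):
        L = 10**4
        s0 = SequenceState(np.zeros(L, dtype=int), 0.0)
        frac = mask_forward(s0, 0.5, np.random.default_rng(1)).masked.mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / L)


class TestReversePosterior:
    def test_unmasked_is_point_mass(self):
        row = reverse_posterior(3, np.full(21, 1 / 21), 0.8, 0.2)
        assert row[3] == 1.0 and row.sum() == 1.0

    def test_substitution_example(self):
        # masked token, alpha_t = 0.5, alpha_s = 0.75, point mass on token 3:
        # fill probability (0.75-0.5)/(1-0.5) = 0.5, stay-mask 0.5
        x0 = np.zeros(21)
        x0[3] = 1.0
        row = reverse_posterior(MASK, x0, 0.75, 0.5)
        assert row[3] == pytest.approx(0.5)
        assert row[MASK] == pytest.approx(0.5)

    @given(st.integers(0, 10**6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_normalization(self, seed):
        rng = np.random.default_rng(seed)
        x0 = rng.dirichlet(np.ones(20))
        full = np.zeros(21)
        full[:20] = x0
        a_t = rng.uniform(0.0, 0.9)
        a_s = rng.uniform(a_t + 1e-6, 1.0)
        row = reverse_posterior(MASK, full, a_s, a_t)
        assert row.sum() == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            reverse_posterior(MASK, full, a_t, a_s)


class TestSeqLoss:
    def test_no_masks_zero(self):
        s = SequenceState(np.zeros(5, dtype=int), 0.0)
        assert seq_loss(np.zeros((5, 21)), s, s, 0.3) == 0.0

    def test_uniform_logits_closed_form(self):
        L = 8
        s0 = SequenceState(np.arange(L) % N_AMINO, 0.0)
        st_ = SequenceState(np.full(L, MASK), 0.25)
        val = seq_loss(np.zeros((L, 21)), s0, st_, 0.25)
        assert val == pytest.approx(0.75 * np.log(20), abs=1e-10)

    def test_perfect_logits_vanish(self):
        L = 6
        s0 = SequenceState(np.arange(L) % N_AMINO, 0.0)
        st_ = SequenceState(np.full(L, MASK), 0.5)
        logits = np.zeros((L, 21))
        logits[np.arange(L), s0.tokens] = 50.0
        assert seq_loss(logits, s0, st_, 0.5) < 1e-10

    def test_invariant_to_unmasked_logits(self):
        rng = np.random.default_rng(4)
        L = 12
        s0 = SequenceState(rng.integers(0, 20, L), 0.0)
        tokens = s0.tokens.copy()
        tokens[::2] = MASK
        st_ = SequenceState(tokens, 0.5)
        logits = rng.standard_normal((L, 21))
        before = seq_loss(logits, s0, st_, 0.5)
        logits[1::2] += rng.standard_normal((L // 2, 21)) * 10
        assert seq_loss(logits, s0, st_, 0.5) == pytest.approx(before, abs=1e-12)


class TestPathPlanning:
    def test_keep_set_size_exhaustive(self):
        rng = np.random.default_rng(5)
        for L in range(1, 65):
            for s_frac in (0.0, 0.1, 0.4, 0.5, 0.77, 0.99):
                s, t = s_frac, 1.0
                if s >= t:
                    continue
                st_ = SequenceState(np.full(L, MASK), t)
                out = path_planning_step(rng.standard_normal((L, 21)), st_, s, t, 0.5,
                                         rng=rng)
                assert (out.tokens == MASK).sum() == round_half_away(s * L)

    def test_s_zero_unmasks_all(self):
        rng = np.random.default_rng(6)
        st_ = SequenceState(np.full(10, MASK), 1.0)
        out = path_planning_step(rng.standard_normal((10, 21)), st_, 0.0, 1.0, 0.5, rng=rng)
        assert not np.any(out.tokens == MASK)

    def test_k_example(self):
        rng = np.random.default_rng(7)
        st_ = SequenceState(np.full(10, MASK), 1.0)
        out = path_planning_step(rng.standard_normal((10, 21)), st_, 0.4, 1.0, 0.5, rng=rng)
        assert (out.tokens != MASK).sum() == 6

    def test_zero_temperature_greedy_oracle(self):
        # zero noise, small gamma: exhaustive ranking oracle over phi
        rng = np.random.default_rng(8)
        L, gamma, s = 12, 1e-3, 0.5
        logits = rng.standard_normal((L, 21))
        st_ = SequenceState(np.full(L, MASK), 1.0)
        out = path_planning_step(logits, st_, s, 1.0, gamma, z=np.zeros((L, 20)))
        phi = _log_softmax(logits[:, :20] / gamma)
        y = phi.argmax(1)
        u = phi.max(1)
        k = L - round_half_away(s * L)
        keep = np.argsort(-u, kind="stable")[:k]
        expected = np.full(L, MASK)
        expected[keep] = y[keep]
        np.testing.assert_array_equal(out.tokens, expected)
        # sampled tokens are the per-position argmax wherever unmasked
        assert np.all(out.tokens[out.tokens != MASK] == logits[:, :20].argmax(1)[out.tokens != MASK])

    def test_remasking_occurs_on_adversarial_logits(self):
        # a previously-unmasked position with terrible confidence leaves the keep-set
        L = 4
        tokens = np.full(L, MASK)
        tokens[0] = 3
        st_ = SequenceState(tokens, 0.8)
        logits = np.zeros((L, 21))
        logits[0, :20] = 0.0          # position 0: low confidence
        logits[1:, 5] = 30.0          # others: near-certain
        out = path_planning_step(logits, st_, 0.25, 0.8, 0.5, mode="cogeneration",
                                 z=np.zeros((L, 20)))
        assert out.tokens[0] == MASK  # re-masked despite being unmasked before
        assert (out.tokens != MASK).sum() == 3

    def test_clamp_never_changes(self):
        rng = np.random.default_rng(9)
        L = 16
        tokens = np.full(L, MASK)
        tokens[[2, 5]] = [7, 11]
        st_ = SequenceState(tokens, 1.0)
        for s in (0.75, 0.5, 0.25):
            out = path_planning_step(rng.standard_normal((L, 21)), st_, s, 1.0, 0.5,
                                     rng=rng, clamp=[2, 5])
            assert out.tokens[2] == 7 and out.tokens[5] == 11


class TestSampleSequence:
    def test_ancestral_matches_enumerable_joint(self):
        spec = DiscreteJointSpec(alphabet=4, length=3, seed=12)
        sequences, probs, posterior = enumerate_discrete_joint(spec)

        # vectorized exact posterior over a batch of partially-masked states
        indicator = np.zeros((len(sequences), 3, 21))
        indicator[np.arange(len(sequences))[:, None], np.arange(3), sequences] = 1.0

        def posterior_batch(tokens):
            consistent = np.ones((tokens.shape[0], len(sequences)), dtype=bool)
            for i in range(3):
                col = tokens[:, i][:, None]
                consistent &= (col == MASK) | (sequences[None, :, i] == col)
            w = consistent * probs[None, :]
            w = w / w.sum(axis=1, keepdims=True)
            return np.einsum("bj,jla->bla", w, indicator)

        n = 10**5
        out = sample_sequence_batch(posterior_batch, 3, 25, n,
                                    rng=np.random.default_rng(2718))
        idx = out[:, 0] * 16 + out[:, 1] * 4 + out[:, 2]
        emp = np.bincount(idx, minlength=64) / n
        tv = 0.5 * np.abs(emp - probs).sum()
        assert tv < 0.05

    def test_single_rollout_ancestral_consistency(self):
        # the scalar API agrees in distribution with the batched sampler on a
        # deterministic joint (point mass -> every rollout returns it)
        spec = DiscreteJointSpec(alphabet=3, length=3, concentration=1e-8, seed=3)
        sequences, probs, posterior = enumerate_discrete_joint(spec)
        top = sequences[probs.argmax()]
        logits_fn = lambda state: np.log(posterior(state.tokens) + 1e-300)
        for seed in range(5):
            out = sample_sequence(logits_fn, 3, 10, mode="ancestral",
                                  rng=np.random.default_rng(seed))
            np.testing.assert_array_equal(out.tokens, top)

    def test_clamp_all_positions(self):
        fixed = np.array([1, 2, 3, 4])
        out = sample_sequence(lambda s: np.zeros((4, 21)), 4, 5,
                              rng=np.random.default_rng(0),
                              clamp=[0, 1, 2, 3], clamp_tokens=fixed)
        np.testing.assert_array_equal(out.tokens, fixed)

    def test_seed_determinism_and_mean_unmask_count(self):
        rng_logits = np.random.default_rng(10)
        table = rng_logits.standard_normal((8, 21))
        model = lambda s: table
        a = sample_sequence(model, 8, 8, rng=np.random.default_rng(3)).tokens
        b = sample_sequence(model, 8, 8, rng=np.random.default_rng(3)).tokens
        np.testing.assert_array_equal(a, b)
        assert not np.any(a == MASK)

    def test_clamp_out_of_range(self):
        with pytest.raises(ValueError):
            sample_sequence(lambda s: np.zeros((4, 21)), 4, 2,
                            rng=np.random.default_rng(0), clamp=[9], clamp_tokens=[1])


class TestInverseFold:
    def test_zero_temperature_argmax(self):
        rng = np.random.default_rng(11)
        table = rng.standard_normal((6, 21))
        out = inverse_fold_sample(lambda s: table, 6, np.random.default_rng(1),
                                  temperature=0.0)
        np.testing.assert_array_equal(out.tokens, table[:, :20].argmax(1))

    def test_single_position_low_temperature(self):
        logits = np.zeros((1, 21))
        logits[0, 4] = 3.0
        out = inverse_fold_sample(lambda s: logits, 1, np.random.default_rng(2),
                                  temperature=0.1)
        assert out.tokens[0] == 4  # 30-logit gap at T=0.1: argmax w.p. ~1
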