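"""Training policies, data sampling, ontology closure, EMA, loss plumbing."""

import numpy as np
import pandas as pd
import pytest

from duet.continuous import SigmaSchedule
from duet.denoiser import DenoiserConfig, build_denoiser
from duet.discrete import MASK
from duet.training import (
    ClusterTable,
    TrainingPolicy,
    combined_loss,
    conditioning_policy,
    ema_update,
    find_roots,
    hierarchical_sample,
    propagate_terms,
    sample_motif_segments,
    sample_noise_levels,
    sequence_loss_tensor,
    structure_loss_tensor,
    train,
)


class TestCombinedLoss:
    @pytest.mark.parametrize("ls,lq,expected", [(1.0, 2.0, 7.0), (0.0, 0.0, 0.0), (3.3, 0.0, 3.3)])
    def test_weighting(self, ls, lq, expected):
        assert combined_loss(ls, lq) == pytest.approx(expected)


class TestNoiseLevels:
    def test_independence_and_uniformity(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        draws = np.array([sample_noise_levels(rng) for _ in range(10**5)])
        rho = np.corrcoef(draws.T)[0, 1]
        assert abs(rho) < 0.01
        for col in range(2):
            assert stats.kstest(draws[:, col], "uniform").pvalue > 0.01

    def test_seeded_reproducibility(self):
        a = sample_noise_levels(np.random.default_rng(5))
        b = sample_noise_levels(np.random.default_rng(5))
        assert a == b


class TestConditioningPolicy:
    def _example(self, terms=None, L=40, seed=0):
        rng = np.random.default_rng(seed)
        return {
            "sequence": rng.integers(0, 20, L),
            "structure": rng.standard_normal((L, 3)),
            "terms": terms,
        }

    def test_no_terms_never_selected(self):
        rng = np.random.default_rng(1)
        ex = self._example(terms=None)
        for _ in range(50):
            assert conditioning_policy(ex, None, TrainingPolicy(), rng).term is None

    def test_attachment_rates(self):
        rng = np.random.default_rng(2)
        ex = self._example(terms=[7])
        n = 10**4
        pol = TrainingPolicy()
        out = [conditioning_policy(ex, None, pol, rng) for _ in range(n)]
        motif_rate = np.mean([c.motif is not None for c in out])
        ds_rate = np.mean([c.drop_sequence for c in out])
        dx_rate = np.mean([c.drop_structure for c in out])
        assert abs(motif_rate - 0.5) < 3 * np.sqrt(0.25 / n)
        se05 = np.sqrt(0.05 * 0.95 / n)
        assert abs(ds_rate - 0.05) < 3 * se05
        assert abs(dx_rate - 0.05) < 3 * se05

    def test_inverse_frequency_selection(self):
        rng = np.random.default_rng(3)
        ex = self._example(terms=[1, 2])
        weights = {1: 10.0, 2: 1000.0}
        n = 2 * 10**4
        pol = TrainingPolicy(term_use_prob=1.0)
        picks = [conditioning_policy(ex, weights, pol, rng).term for _ in range(n)]
        n1 = picks.count(1)
        n2 = picks.count(2)
        # P(term 1) = (1/10) / (1/10 + 1/1000) = 100/101
        p1 = 100 / 101
        assert abs(n1 / n - p1) < 3 * np.sqrt(p1 * (1 - p1) / n)
        assert n1 > 50 * n2

    def test_motif_segments_valid(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            L = int(rng.integers(10, 120))
            idx = sample_motif_segments(L, rng)
            assert len(idx) >= 1
            assert idx.min() >= 0 and idx.max() < L
            assert len(np.unique(idx)) == len(idx)
            assert len(idx) <= max(4, int(0.5 * L) + 4)


class TestHierarchicalSampling:
    def _table(self):
        rows = []
        # outer A: one inner cluster with one protein; outer B: 99 inners
        rows.append(("p0", "A", "A0", 90.0))
        for i in range(99):
            rows.append((f"q{i}", "B", f"B{i}", 90.0))
        return ClusterTable(pd.DataFrame(rows, columns=["id", "outer_cluster", "inner_cluster", "quality"]))

    def test_outer_clusters_equally_likely(self):
        table = self._table()
        rng = np.random.default_rng(5)
        n = 10**4
        hits = sum(hierarchical_sample(table, 80.0, rng)["outer_cluster"] == "A" for _ in range(n))
        assert abs(hits / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_quality_filter_excludes(self):
        df = pd.DataFrame(
            [("a", "X", "X0", 50.0), ("b", "X", "X1", 95.0)],
            columns=["id", "outer_cluster", "inner_cluster", "quality"],
        )
        table = ClusterTable(df)
        rng = np.random.default_rng(6)
        for _ in range(50):
            assert hierarchical_sample(table, 80.0, rng)["id"] == "b"
        with pytest.raises(ValueError):
            hierarchical_sample(table, 99.0, rng)

    def test_single_protein(self):
        df = pd.DataFrame([("only", "O", "O0", 99.0)],
                          columns=["id", "outer_cluster", "inner_cluster", "quality"])
        assert hierarchical_sample(ClusterTable(df), 80.0, np.random.default_rng(7))["id"] == "only"

    def test_inner_cluster_integrity_enforced(self):
        df = pd.DataFrame(
            [("a", "X", "I", 90.0), ("b", "Y", "I", 90.0)],
            columns=["id", "outer_cluster", "inner_cluster", "quality"],
        )
        with pytest.raises(ValueError):
            ClusterTable(df)


class TestOntology:
    ONTO = {
        "a": ["b"], "b": ["c"], "c": [],
        "d": ["c"], "e": ["d", "b"], "f": [], "g": ["f"],
    }

    def test_no_parent_unchanged(self):
        closed = propagate_terms({"p": {"c"}}, self.ONTO)
        assert closed["p"] == frozenset({"c"})

    def test_chain_closure(self):
        closed = propagate_terms({"p": {"a"}}, self.ONTO)
        assert closed["p"] == frozenset({"a", "b", "c"})

    def test_dag_matches_bfs_oracle(self):
        from collections import deque

        closed = propagate_terms({"p": {"e", "g"}}, self.ONTO)
        seen = set()
        dq = deque(["e", "g"])
        while dq:
            t = dq.popleft()
            if t in seen:
                continue
            seen.add(t)
            dq.extend(self.ONTO.get(t, []))
        assert closed["p"] == frozenset(seen)

    def test_roots_flagged(self):
        assert find_roots(self.ONTO) == frozenset({"c", "f"})

    def test_cycle_detected(self):
        with pytest.raises(ValueError):
            propagate_terms({"p": {"x"}}, {"x": ["y"], "y": ["x"]})


class TestEMA:
    def test_one_step_value(self):
        ema = [np.zeros(3)]
        ema_update(ema, [np.ones(3)], 0.999)
        np.testing.assert_allclose(ema[0], 0.001)

    def test_endpoints(self):
        init = [np.full(2, 5.0)]
        params = [np.full(2, -1.0)]
        e0 = [a.copy() for a in init]
        ema_update(e0, params, 0.0)
        np.testing.assert_array_equal(e0[0], params[0])
        e1 = [a.copy() for a in init]
        ema_update(e1, params, 1.0)
        np.testing.assert_array_equal(e1[0], init[0])


class TestLossPlumbing:
    def test_unmasked_positions_carry_no_gradient(self):
        # finite differences on a tiny model: logits at unmasked positions do
        # not influence the masked cross-entropy
        rng = np.random.default_rng(8)
        B, L = 1, 6
        s0 = rng.integers(0, 20, (B, L))
        st = s0.copy()
        st[0, ::2] = MASK
        from duet.nn import Tensor

        raw = rng.standard_normal((B, L, 21))
        logits = Tensor(raw, requires_grad=True)
        loss = sequence_loss_tensor(logits, s0, st, np.array([0.3]))
        loss.backward()
        grad = logits.grad
        assert np.all(grad[0, 1::2] == 0.0)
        assert np.any(grad[0, ::2] != 0.0)

    def test_tensor_losses_match_scalar_formulas(self):
        from duet.continuous import structure_loss
        from duet.discrete import SequenceState, seq_loss
        from duet.nn import Tensor

        rng = np.random.default_rng(9)
        sched = SigmaSchedule()
        L, t = 5, 4.0
        raw = rng.standard_normal((L, 3))
        x0 = rng.standard_normal((L, 3))
        xt = rng.standard_normal((L, 3))
        got = float(structure_loss_tensor(Tensor(raw[None]), x0[None], xt[None],
                                          np.array([t]), sched).data)
        assert got == pytest.approx(structure_loss(raw, x0, xt, t, sched), abs=1e-12)

        s0 = rng.integers(0, 20, L)
        st = s0.copy()
        st[[0, 2]] = MASK
        logits = rng.standard_normal((L, 21))
        got = float(sequence_loss_tensor(Tensor(logits[None]), s0[None], st[None],
                                         np.array([0.25])).data)
        ref = seq_loss(logits, SequenceState(s0, 0.0), SequenceState(st, 0.25), 0.25)
        assert got == pytest.approx(ref, abs=1e-12)

    def test_toy_training_halves_the_loss(self, trained_toy):
        hist = np.asarray(trained_toy.history)
        first = hist[:100].mean()
        last = hist[-100:].mean()
        assert last <= 0.5 * first

    def test_zero_steps_leaves_model_unchanged(self):
        cfg = DenoiserConfig(n_blocks=1, hidden_dim=32, max_length=8)
        model = build_denoiser(cfg, np.random.default_rng(10))
        before = [p.data.copy() for p in model.parameters()]
        model2, ema, hist = train(model, lambda rng: {}, TrainingPolicy(), 0,
                                  np.random.default_rng(0))
        assert hist == []
        for a, b in zip(before, [p.data for p in model2.parameters()]):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(before, ema):
            np.testing.assert_array_equal(a, b)
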