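"""Controller sampling, REINFORCE updates and search-space bookkeeping."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from editnas import (ArchitectureTokens, ControllerState, RewardRecord,
                     SearchConfig, count_model_space, reinforce_update,
                     sample_architecture, sample_random_cohort)
from editnas.exceptions import ConfigError, StalenessError
from editnas import nas as nas_mod


class TestSampling:
    def test_tokens_always_valid(self):
        state = ControllerState(n_layers=4, seed=1)
        rng = np.random.default_rng(2)
        for _ in range(50):
            tokens, ll = sample_architecture(state, rng)
            assert tokens.n_layers == 4
            assert math.isfinite(ll) and ll < 0

    def test_untrained_controller_samples_ops_uniformly(self):
        """Zero-initialised output weights give exactly uniform op marginals."""
        state = ControllerState(n_layers=2, seed=3)
        rng = np.random.default_rng(4)
        counts = np.zeros(7)
        n = 10_000
        for _ in range(n // 2):  # two layers per sample
            tokens, _ = sample_architecture(state, rng)
            for op in tokens.ops:
                counts[op - 1] += 1
        chi2 = ((counts - n / 7) ** 2 / (n / 7)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=6)

    def test_log_likelihood_matches_replay(self):
        state = ControllerState(n_layers=5, seed=5)
        rng = np.random.default_rng(6)
        for _ in range(10):
            tokens, ll = sample_architecture(state, rng)
            replay = float(state.log_prob(tokens).data)
            assert replay == pytest.approx(ll, abs=1e-10)

    def test_replay_requires_exactly_one_mode(self):
        state = ControllerState(n_layers=2, seed=0)
        with pytest.raises(ConfigError):
            state._rollout()


class TestReinforceUpdate:
    def _record(self, state, rng, reward):
        tokens, ll = sample_architecture(state, rng)
        return RewardRecord(tokens=tokens, reward=reward, log_likelihood=ll,
                            step=1)

    def test_positive_advantage_raises_likelihood(self):
        state = ControllerState(n_layers=3, seed=7, lr=0.05)
        state.baseline = 0.0
        rng = np.random.default_rng(8)
        rec = self._record(state, rng, reward=0.8)
        before = float(state.log_prob(rec.tokens).data)
        reinforce_update(state, [rec])
        after = float(state.log_prob(rec.tokens).data)
        assert after > before

    def test_zero_advantage_is_noop(self):
        state = ControllerState(n_layers=3, seed=9)
        state.baseline = 0.37
        rng = np.random.default_rng(10)
        rec = self._record(state, rng, reward=0.37)
        snapshot = {k: v.data.copy() for k, v in state.params.items()}
        reinforce_update(state, [rec])
        for k, v in state.params.items():
            assert np.array_equal(v.data, snapshot[k]), k

    def test_stale_records_rejected(self):
        state = ControllerState(n_layers=3, seed=11, lr=0.1)
        state.baseline = 0.0  # nonzero advantage so the update moves params
        rng = np.random.default_rng(12)
        rec1 = self._record(state, rng, reward=0.5)
        reinforce_update(state, [rec1])  # parameters move
        with pytest.raises(StalenessError):
            reinforce_update(state, [rec1])

    def test_baseline_ema_update(self):
        state = ControllerState(n_layers=2, seed=13, ema_decay=0.9)
        rng = np.random.default_rng(14)
        rec = self._record(state, rng, reward=1.0)
        reinforce_update(state, [rec])
        assert state.baseline == pytest.approx(1.0)  # first batch initialises b
        rec2 = self._record(state, rng, reward=0.0)
        reinforce_update(state, [rec2])
        assert state.baseline == pytest.approx(0.9)  # 0.9*1 + 0.1*0

    def test_analytic_gradient_matches_finite_differences(self):
        """Policy-gradient correctness on a tiny controller, to 1e-4 relative."""
        state = ControllerState(n_layers=2, hidden_size=6, seed=15)
        rng = np.random.default_rng(16)
        tokens, _ = sample_architecture(state, rng)
        for p in state.params.values():
            p.grad = None
        state.log_prob(tokens).backward()
        eps = 1e-5
        for name, p in state.params.items():
            analytic = p.grad if p.grad is not None else np.zeros_like(p.data)
            flat = p.data.ravel()
            idxs = np.random.default_rng(17).choice(
                flat.size, size=min(6, flat.size), replace=False)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + eps
                fp = float(state.log_prob(tokens).data)
                flat[i] = orig - eps
                fm = float(state.log_prob(tokens).data)
                flat[i] = orig
                num = (fp - fm) / (2 * eps)
                a = analytic.ravel()[i]
                denom = max(abs(num), abs(a), 1.0)
                assert abs(a - num) / denom < 1e-4, (name, i, a, num)


class TestRunSearchBookkeeping:
    def test_log_length_and_determinism(self, monkeypatch, small_planted):
        """Search bookkeeping with a stubbed reward (no child training)."""

        def fake_reward(tokens, train_set, validation_set, config, step=0,
                        child_seed=0, log_likelihood=math.nan):
            r = 0.1 * sum(1 for o in tokens.ops if o in (1, 2, 3, 4)) / len(tokens.ops)
            return RewardRecord(tokens=tokens, reward=r,
                                log_likelihood=log_likelihood, step=step)

        monkeypatch.setattr(nas_mod, "compute_reward", fake_reward)
        cfg = SearchConfig(n_layers=3, batch_architectures=3,
                           controller_steps=4, seed=21)
        best1, log1 = nas_mod.run_search(cfg, None, None)
        best2, log2 = nas_mod.run_search(cfg, None, None)
        assert len(log1) == 12
        assert best1 == best2
        assert [r.tokens for r in log1] == [r.tokens for r in log2]
        final = [r for r in log1 if r.step == 4]
        assert best1 == max(final, key=lambda r: r.reward).tokens


class TestGridRefine:
    def _patch(self, monkeypatch, reward_fn):
        def fake(tokens, train_set, validation_set, config, step=0,
                 child_seed=0, log_likelihood=math.nan):
            cfg = config.child_config
            return RewardRecord(tokens=tokens,
                                reward=reward_fn(cfg.width_scale, cfg.dropout),
                                log_likelihood=log_likelihood, step=step)

        monkeypatch.setattr(nas_mod, "compute_reward", fake)

    def test_degenerate_grid_returns_that_pair(self, monkeypatch):
        self._patch(monkeypatch, lambda w, d: 0.5)
        cfg = nas_mod.grid_refine(ArchitectureTokens.all_identity(3), None,
                                  None, [6], [0.4], SearchConfig(n_layers=3))
        assert (cfg.width_scale, cfg.dropout) == (6, 0.4)

    def test_best_pair_selected_from_grid(self, monkeypatch):
        self._patch(monkeypatch,
                    lambda w, d: 0.5 - 0.1 * abs(w - 2) - 0.1 * abs(d - 0.2))
        cfg = nas_mod.grid_refine(ArchitectureTokens.all_identity(3), None,
                                  None, [1, 2, 6], [0.0, 0.2, 0.4],
                                  SearchConfig(n_layers=3))
        assert (cfg.width_scale, cfg.dropout) == (2, 0.2)

    def test_ties_break_toward_smaller_width_then_dropout(self, monkeypatch):
        self._patch(monkeypatch, lambda w, d: 0.5)  # all pairs equal
        cfg = nas_mod.grid_refine(ArchitectureTokens.all_identity(3), None,
                                  None, [6, 1], [0.4, 0.0],
                                  SearchConfig(n_layers=3))
        assert (cfg.width_scale, cfg.dropout) == (1, 0.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            nas_mod.grid_refine(ArchitectureTokens.all_identity(3), None,
                                None, [], [0.4], SearchConfig(n_layers=3))


class TestRandomCohort:
    def test_size_and_validity(self):
        cohort = sample_random_cohort(50, residual_density=0.3, seed=1)
        assert len(cohort) == 50
        for tok in cohort:
            assert tok.n_layers == 8

    def test_zero_density_no_skips(self):
        cohort = sample_random_cohort(20, residual_density=0.0, seed=2)
        assert all(all(b == 0 for row in t.residuals for b in row)
                   for t in cohort)

    def test_uniform_op_frequencies(self):
        cohort = sample_random_cohort(2000, residual_density=0.5, seed=3,
                                      n_layers=8)
        counts = np.zeros(7)
        for tok in cohort:
            for op in tok.ops:
                counts[op - 1] += 1
        n = counts.sum()
        chi2 = ((counts - n / 7) ** 2 / (n / 7)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=6)


class TestCountModelSpace:
    def test_published_space_size(self):
        n = count_model_space(8, 7)
        assert n == 7 ** 8 * 2 ** 28
        assert n / 1e15 == pytest.approx(1.547, abs=0.001)

    def test_no_residual_bits_single_layer(self):
        assert count_model_space(1, 7) == 7

    def test_two_layers(self):
        assert count_model_space(2, 7) == 98

    @pytest.mark.parametrize("T,ops", [(1, 2), (2, 3), (3, 2)])
    def test_matches_bruteforce_enumeration(self, T, ops):
        """Count every valid token assignment explicitly for tiny spaces."""
        n_res_bits = T * (T - 1) // 2
        total = 0
        for op_combo in itertools.product(range(1, ops + 1), repeat=T):
            for bits in itertools.product((0, 1), repeat=n_res_bits):
                # reshape flat bits into ragged rows and validate constructively
                rows, k = [], 0
                for t in range(T):
                    rows.append(tuple(bits[k: k + t]))
                    k += t
                ArchitectureTokens(ops=op_combo, residuals=tuple(rows))
                total += 1
        assert total == count_model_space(T, ops)
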