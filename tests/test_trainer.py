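import numpy as np
import pytest

from rlcausal import (Dataset, EncoderConfig, RewardConfig, TrainingConfig,
                      bic_score, critic_predict, exhaustive_search, is_dag,
                      iter_dags, train)
from rlcausal.nn import Critic


class TestCritic:
    def test_zero_weights_predict_zero(self, rng):
        critic = Critic(8, 4, rng)
        for p in critic.params():
            p.value[...] = 0.0
        assert critic_predict(rng.normal(size=(5, 8)), critic) == 0.0

    def test_scalar_output(self, rng):
        critic = Critic(16, 8, rng)
        out = critic_predict(rng.normal(size=(8, 16)), critic)
        assert isinstance(out, float) and np.isfinite(out)

    def test_invariant_to_row_permutation(self, rng):
        critic = Critic(8, 4, rng)
        enc = rng.normal(size=(6, 8))
        perm = rng.permutation(6)
        assert critic_predict(enc, critic) == pytest.approx(
            critic_predict(enc[perm], critic), rel=1e-12)


class TestDagEnumeration:
    @pytest.mark.parametrize("d,count", [(2, 3), (3, 25), (4, 543)])
    def test_labeled_dag_counts(self, d, count):
        assert sum(len(block) for block in iter_dags(d)) == count

    def test_enumerated_graphs_are_dags(self):
        for block in iter_dags(3):
            for adj in block:
                assert is_dag(adj)

    def test_large_d_refused(self, gauss_data):
        with pytest.raises(ValueError):
            list(iter_dags(6))


class TestExhaustiveSearch:
    def test_independent_noise_prefers_empty_graph(self, rng):
        data = Dataset(rng.normal(size=(500, 2)))
        rec = exhaustive_search(data)
        assert rec.graph.sum() == 0

    def test_record_is_dag_with_zero_h(self, chain3_data):
        rec = exhaustive_search(chain3_data)
        assert rec.is_dag and rec.h == 0.0
        assert rec.reward == -rec.bic

    def test_minimum_over_explicit_enumeration(self, chain3_data):
        rec = exhaustive_search(chain3_data)
        scores = [bic_score(adj, chain3_data)
                  for block in iter_dags(3) for adj in block]
        assert rec.bic == pytest.approx(min(scores), rel=1e-12)


class TestTrain:
    def small_config(self, enc, **kw):
        defaults = dict(iterations=5, graphs_per_iteration=4,
                        learning_rate=1e-3, seed=0, encoder_config=enc)
        defaults.update(kw)
        return TrainingConfig(**defaults)

    def test_single_iteration_single_graph_deterministic(self, chain3_data,
                                                         small_encoder):
        cfg = self.small_config(small_encoder, iterations=1,
                                graphs_per_iteration=1)
        state = train(chain3_data, cfg)
        assert len(state.reward_log) == 1
        assert state.best_record.reward == state.reward_log[0]

    def test_best_record_is_max_of_reward_log(self, chain3_data, small_encoder):
        cfg = self.small_config(small_encoder, iterations=20)
        state = train(chain3_data, cfg)
        assert state.best_record.reward == max(state.reward_log)

    def test_reward_trace_nondecreasing(self, chain3_data, small_encoder):
        state = train(chain3_data, self.small_config(small_encoder, iterations=30))
        trace = state.reward_trace
        assert all(a <= b for a, b in zip(trace, trace[1:]))

    def test_record_invariant(self, chain3_data, small_encoder):
        cfg = self.small_config(small_encoder, iterations=10,
                                reward_config=RewardConfig(2.0, 3.0))
        rec = train(chain3_data, cfg).best_record
        penalty = (0.0 if rec.is_dag else 2.0) + 3.0 * rec.h
        assert rec.reward == pytest.approx(-(rec.bic + penalty), rel=1e-12)

    def test_seeded_runs_bit_reproducible(self, chain3_data, small_encoder):
        cfg = self.small_config(small_encoder, iterations=15, seed=3)
        a = train(chain3_data, cfg)
        b = train(chain3_data, cfg)
        np.testing.assert_array_equal(a.best_record.graph, b.best_record.graph)
        assert a.reward_log == b.reward_log

    def test_large_penalties_force_dag_output(self, chain3_data, small_encoder):
        for seed in (0, 1, 2):
            cfg = self.small_config(
                small_encoder, iterations=200, seed=seed,
                reward_config=RewardConfig(1e3, 1e3))
            assert train(chain3_data, cfg).best_record.is_dag

    def test_training_log_jsonl(self, chain3_data, small_encoder, tmp_path):
        import json
        path = tmp_path / "log.jsonl"
        train(chain3_data, self.small_config(small_encoder, iterations=5),
              log_path=path)
        lines = [json.loads(l) for l in path.read_text().splitlines()]
        assert len(lines) == 5
        assert {"iteration", "best_reward", "mean_reward", "h_best"} <= set(lines[0])

    def test_checkpoint_writes_weights_and_config(self, chain3_data,
                                                  small_encoder, tmp_path):
        import json
        state = train(chain3_data, self.small_config(small_encoder, iterations=2))
        state.save_checkpoint(tmp_path / "ckpt")
        assert (tmp_path / "ckpt" / "policy.npz").exists()
        cfg = json.loads((tmp_path / "ckpt" / "config.json").read_text())
        assert cfg["iterations"] == 2

    def test_n_s_larger_than_m_rejected(self, small_encoder, rng):
        tiny = Dataset(rng.normal(size=(8, 3)))
        cfg = self.small_config(small_encoder)
        with pytest.raises(ValueError, match="n_s"):
            train(tiny, cfg)

    def test_chain_recovery_matches_exhaustive_optimum(self, chain3_data,
                                                       small_encoder):
        opt = exhaustive_search(chain3_data)
        cfg = self.small_config(small_encoder, iterations=150,
                                graphs_per_iteration=32, seed=1)
        state = train(chain3_data, cfg)
        best_bic = bic_score(state.best_record.graph, chain3_data)
        assert abs(best_bic - opt.bic) <= 1e-3 * abs(opt.bic)
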