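"""RL engine: reward rule, lambda schedule, memory penalty, REINFORCE."""

import numpy as np
import pytest

from divmolgen.generator import SampleResult, SmilesGenerator
from divmolgen.rl_engine import (
    DiversityMemory,
    ReinforceOptimizer,
    RewardHistory,
    RewardSpec,
    TrajectoryBatch,
    compute_reward,
    dual_sample,
    logp_oracle,
    memory_diversity_penalty,
    reinforce_loss,
    select_checkpoint,
    select_lambda,
)
from divmolgen.metrics import featurize_ecfp

TAU2 = (0.05, 0.2, 0.1)


class TestComputeReward:
    def test_maximize_rule_exact(self):
        spec = RewardSpec(mode="maximize_pic50")
        assert compute_reward(4.0, spec) == pytest.approx(1.0)
        assert compute_reward(8.0, spec) == pytest.approx(np.e)

    def test_maximize_strictly_increasing(self):
        spec = RewardSpec(mode="maximize_pic50")
        assert compute_reward(6.5, spec) > compute_reward(6.0, spec)

    def test_minimize_rewards_low_affinity(self):
        spec = RewardSpec(mode="minimize_pic50")
        assert compute_reward(2.0, spec) == pytest.approx(1.0)
        assert compute_reward(3.0, spec) < compute_reward(2.0, spec)
        assert compute_reward(3.0, spec) > 0

    def test_logp_range_plateau_and_decay(self):
        spec = RewardSpec(mode="logp_range")
        assert compute_reward(1.0, spec) == compute_reward(2.5, spec) == \
            compute_reward(4.0, spec) == pytest.approx(3.0)
        assert compute_reward(5.0, spec) == pytest.approx(3.0 * np.exp(-1.0))
        assert compute_reward(0.0, spec) == pytest.approx(3.0 * np.exp(-1.0))
        assert compute_reward(-10.0, spec) > 0

    def test_nonfinite_property_rejected(self):
        with pytest.raises(ValueError):
            compute_reward(np.nan, RewardSpec())


class TestLambdaSchedule:
    @pytest.mark.parametrize("means,expected", [
        ([1.0, 1.1, 1.2], 0.05),   # rising -> tau[0]
        ([1.2, 1.1, 1.0], 0.2),    # falling -> tau[1]
        ([1.0, 1.2, 1.1], 0.1),    # mixed -> tau[2]
        ([1.0, 1.1], 0.1),         # too short -> tau[2]
        ([], 0.1),
    ])
    def test_trend_mapping(self, means, expected):
        history = RewardHistory(batch_means=list(means))
        assert select_lambda(history, TAU2) == expected

    def test_always_member_of_tau(self, rng):
        for _ in range(50):
            history = RewardHistory(
                batch_means=list(rng.normal(2, 1, size=rng.integers(0, 20))))
            assert select_lambda(history, TAU2) in TAU2

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            select_lambda(RewardHistory(), (0.1, 0.2))


class TestDiversityMemory:
    def test_fifo_capacity(self):
        memory = DiversityMemory(size=30)
        first = frozenset({0})
        memory.add(first)
        for i in range(1, 31):
            memory.add(frozenset({i}))
        assert len(memory) == 30
        assert first not in memory.entries
        assert frozenset({1}) in memory.entries

    def test_empty_memory_leaves_reward_unchanged(self):
        memory = DiversityMemory()
        adjusted, triggered = memory_diversity_penalty(
            2.0, frozenset({1, 2}), memory)
        assert adjusted == 2.0 and not triggered
        assert len(memory) == 1  # the molecule still enters the memory

    def test_identical_molecules_trigger_15pct_penalty(self):
        memory = DiversityMemory(size=30)
        fp = featurize_ecfp("CCO")
        for _ in range(30):
            memory.add(fp)
        adjusted, triggered = memory_diversity_penalty(
            2.0, fp, memory, kappa=0.75, penalty_fraction=0.15)
        assert triggered
        assert adjusted == pytest.approx(0.85 * 2.0)

    def test_disjoint_fingerprints_do_not_trigger(self):
        memory = DiversityMemory()
        memory.add(frozenset({1, 2, 3}))
        adjusted, triggered = memory_diversity_penalty(
            2.0, frozenset({10, 11}), memory, kappa=0.75)
        assert not triggered and adjusted == 2.0

    def test_adjustment_is_exactly_conservative(self, rng):
        """Adjusted reward is either unchanged or exactly 0.85x."""
        memory = DiversityMemory(size=5)
        for _ in range(40):
            fp = frozenset(rng.integers(0, 20, size=5).tolist())
            reward = float(rng.uniform(0.5, 3))
            adjusted, _ = memory_diversity_penalty(reward, fp, memory)
            assert adjusted in (reward, pytest.approx(0.85 * reward))


class TestDualSampling:
    def test_lambda_zero_all_biased(self, tiny_generator, rng):
        g_u = tiny_generator.clone_model()
        res = dual_sample(tiny_generator, g_u, 0.0, 20, 1.0, rng)
        assert all(f == "G_b" for r in res for f in r.provenance)

    def test_lambda_one_all_unbiased(self, tiny_generator, rng):
        g_u = tiny_generator.clone_model()
        res = dual_sample(tiny_generator, g_u, 1.0, 20, 1.0, rng)
        assert all(f == "G_u" for r in res for f in r.provenance)

    def test_intermediate_lambda_binomial_fraction(self, tiny_generator):
        g_u = tiny_generator.clone_model()
        rng = np.random.default_rng(0)
        flags = []
        while len(flags) < 10_000:
            res = dual_sample(tiny_generator, g_u, 0.3, 400, 1.0, rng)
            flags.extend(f for r in res for f in r.provenance)
        frac = sum(f == "G_u" for f in flags) / len(flags)
        se = np.sqrt(0.3 * 0.7 / len(flags))
        assert abs(frac - 0.3) < 3 * se

    def test_vocabulary_mismatch_rejected(self, tiny_generator):
        other = SmilesGenerator(recurrent_layers=1, recurrent_units=8,
                                max_len=12, epochs=1, random_state=0)
        other.fit(["CCO", "CCN"])
        with pytest.raises(ValueError, match="vocabulary"):
            dual_sample(tiny_generator, other, 0.5, 2, 1.0,
                        np.random.default_rng(0))

    def test_logprobs_recorded_under_biased_policy(self, tiny_generator):
        """Even G_u-emitted tokens carry G_b log-probabilities."""
        g_u = tiny_generator.clone_model()
        key = next(iter(g_u.params_))
        g_u.params_[key] += 0.5  # make the two policies differ
        res = dual_sample(tiny_generator, g_u, 1.0, 1,
                          0.9, np.random.default_rng(3))[0]
        prefix = [tiny_generator.vocab_.start_id]
        for tok, logp in zip(res.token_ids, res.stepwise_logprobs):
            dist = tiny_generator.next_token_distribution(prefix, 0.9)
            assert np.exp(logp) == pytest.approx(dist[tok], rel=1e-9)
            prefix.append(tok)


class TestReinforceLoss:
    def _sample(self, logps):
        return SampleResult(smiles="C", token_ids=[3] * len(logps),
                            stepwise_logprobs=list(logps), terminated=True)

    def test_zero_rewards_give_zero_loss(self):
        batch = TrajectoryBatch(samples=[self._sample([-1.0, -2.0])],
                                rewards=[0.0])
        assert reinforce_loss(batch, gamma=0.9) == 0.0

    def test_hand_evaluated_single_step(self):
        # one molecule, one token, logp -1, R=2, gamma=0.9, j starts at 1
        batch = TrajectoryBatch(samples=[self._sample([-1.0])], rewards=[2.0])
        assert reinforce_loss(batch, gamma=0.9) == pytest.approx(1.8)

    def test_linear_in_rewards(self, rng):
        samples = [self._sample(rng.uniform(-2, -0.1, size=4)) for _ in range(3)]
        rewards = [1.0, 2.0, 0.5]
        base = reinforce_loss(TrajectoryBatch(samples, rewards), gamma=0.97)
        doubled = reinforce_loss(
            TrajectoryBatch(samples, [2 * r for r in rewards]), gamma=0.97)
        assert doubled == pytest.approx(2 * base)

    def test_molecule_indexed_discount_variant(self):
        batch = TrajectoryBatch(
            samples=[self._sample([-1.0]), self._sample([-1.0])],
            rewards=[1.0, 1.0])
        token = reinforce_loss(batch, gamma=0.5, discount_indexing="token")
        molecule = reinforce_loss(batch, gamma=0.5,
                                  discount_indexing="molecule")
        assert token == pytest.approx((0.5 + 0.5) / 2)
        assert molecule == pytest.approx((0.5 + 0.25) / 2)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            reinforce_loss(TrajectoryBatch([], []), gamma=0.9)


class TestBanditConvergence:
    def test_two_token_bandit(self):
        """REINFORCE drives the high-reward token above 0.95 probability."""
        gen = SmilesGenerator(recurrent_layers=1, recurrent_units=8,
                              dropout=0.0, max_len=3, epochs=2,
                              batch_size=4, random_state=0)
        gen.fit(["C", "N", "C", "N"])
        spec = RewardSpec(mode="identity",
                          property_oracle=lambda s: 1.0 if s == "C" else 0.1,
                          invalid_reward=0.1)
        engine = ReinforceOptimizer(objective=spec, iterations=200,
                                    batch_size=10, learning_rate=0.05,
                                    temperature=1.0, tau=(0.0, 0.0, 0.0),
                                    penalty_enabled=False, random_state=1)
        engine.fit(gen)
        g_b = engine.generator_
        dist = g_b.next_token_distribution([g_b.vocab_.start_id], 1.0)
        assert dist[g_b.vocab_.index_of["C"]] > 0.95

    def test_descent_direction_on_favoured_token(self):
        """The gradient pushes probability mass toward rewarded tokens."""
        gen = SmilesGenerator(recurrent_layers=1, recurrent_units=8,
                              dropout=0.0, max_len=3, epochs=2,
                              batch_size=4, random_state=0)
        gen.fit(["C", "N"])
        spec = RewardSpec(mode="identity",
                          property_oracle=lambda s: 1.0 if s == "C" else 0.1,
                          invalid_reward=0.1)
        before = gen.next_token_distribution([gen.vocab_.start_id], 1.0)
        engine = ReinforceOptimizer(objective=spec, iterations=30,
                                    batch_size=10, learning_rate=0.05,
                                    temperature=1.0, tau=(0.0, 0.0, 0.0),
                                    penalty_enabled=False, random_state=1)
        engine.fit(gen)
        after = engine.generator_.next_token_distribution(
            [gen.vocab_.start_id], 1.0)
        c = gen.vocab_.index_of["C"]
        assert after[c] > before[c]


@pytest.fixture(scope="module")
def short_run(tiny_generator):
    spec = RewardSpec(mode="logp_range", property_oracle=logp_oracle)
    engine = ReinforceOptimizer(objective=spec, iterations=8,
                                batch_size=5, random_state=2,
                                eval_every=4, eval_samples=50)
    return engine.fit(tiny_generator)


class TestEngineBookkeeping:
    def test_log_schema_and_lambda_membership(self, short_run):
        assert len(short_run.log_) == 8
        for record in short_run.log_:
            assert record["lambda"] in TAU2
            assert 0.0 <= record["validity_fraction"] <= 1.0
            assert np.isfinite(record["mean_reward"])

    def test_lambda_sequence_replayable_from_history(self, short_run):
        means = short_run.history_.batch_means
        for i, record in enumerate(short_run.log_):
            replayed = select_lambda(RewardHistory(means[:i]), TAU2)
            assert record["lambda"] == replayed

    def test_unbiased_generator_unchanged(self, tiny_generator, short_run):
        # fit() must train a copy, never the pre-trained policy itself
        assert short_run.generator_ is not tiny_generator

    def test_snapshots_recorded(self, short_run):
        assert len(short_run.snapshots_) == 2
        assert {s["iteration"] for s in short_run.snapshots_} == {3, 7}

    def test_missing_objective_rejected(self, tiny_generator):
        with pytest.raises(ValueError):
            ReinforceOptimizer().fit(tiny_generator)


class TestSelectCheckpoint:
    def test_single_snapshot(self):
        snaps = [{"iteration": 4, "pct_desirable": 50.0,
                  "internal_tanimoto": 0.8}]
        assert select_checkpoint(snaps) == 4

    def test_maximizes_product(self):
        snaps = [
            {"iteration": 10, "pct_desirable": 50.0, "internal_tanimoto": 1.0},
            {"iteration": 20, "pct_desirable": 90.0, "internal_tanimoto": 1.0},
            {"iteration": 30, "pct_desirable": 70.0, "internal_tanimoto": 1.0},
        ]
        assert select_checkpoint(snaps) == 20

    def test_tie_goes_to_earliest(self):
        snaps = [
            {"iteration": 10, "pct_desirable": 80.0, "internal_tanimoto": 0.5},
            {"iteration": 20, "pct_desirable": 80.0, "internal_tanimoto": 0.5},
        ]
        assert select_checkpoint(snaps) == 10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_checkpoint([])
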