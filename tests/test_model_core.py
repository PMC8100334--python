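import numpy as np
import pytest

from nemtar import (
    NULL_ATTACHMENT,
    EffectObservations,
    EGeneAttachment,
    NoiseRates,
    PerturbationStates,
    SGeneNetwork,
    attachment_posterior,
    cell_loglik,
    marginal_loglikelihood,
    predict_effects,
    transitive_closure,
)
from nemtar.simulate import sample_observations, sample_states

from conftest import brute_force_marginal, make_instance


class TestTransitiveClosure:
    def test_chain_closure_adds_shortcut(self):
        # S2 -> S3 -> S4 implies S2 -> S4
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 2] = 1
        closed = transitive_closure(adj)
        assert closed[0, 2] == 1
        assert closed.sum() == 3

    def test_empty_graph_unchanged(self):
        adj = np.zeros((4, 4), dtype=int)
        assert transitive_closure(adj).sum() == 0

    def test_four_node_chain_has_six_edges(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1] = adj[1, 2] = adj[2, 3] = 1
        assert transitive_closure(adj).sum() == 6

    def test_idempotent_and_monotone_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            m = rng.integers(2, 7)
            adj = (rng.random((m, m)) < 0.3).astype(int)
            np.fill_diagonal(adj, 0)
            closed = transitive_closure(adj)
            assert np.array_equal(transitive_closure(closed), closed)
            assert (closed >= adj).all()  # monotone: no edge removed
            # adding one edge never removes closure edges
            more = closed.copy()
            zeros = np.argwhere((more == 0) & ~np.eye(m, dtype=bool))
            if len(zeros):
                i, j = zeros[0]
                more[i, j] = 1
                assert (transitive_closure(more) >= closed).all()

    def test_rejects_non_square_and_non_binary(self):
        with pytest.raises(ValueError):
            transitive_closure(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            transitive_closure(np.full((2, 2), 0.5))


class TestSGeneNetwork:
    def test_rejects_unclosed_adjacency(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 2] = 1  # missing 0 -> 2
        with pytest.raises(ValueError, match="closed"):
            SGeneNetwork(["A", "B", "C"], adj)

    def test_rejects_cycles(self):
        adj = np.array([[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="cycle"):
            SGeneNetwork(["A", "B"], adj)

    def test_reach_includes_self(self, chain3):
        assert chain3.reach(0) == {0, 1, 2}
        assert chain3.reach(2) == {2}


class TestPredictEffects:
    def test_upstream_perturbation_reaches_downstream_attachment(self):
        net = SGeneNetwork.from_edges(["S1", "S2"], [("S1", "S2")])
        states = PerturbationStates(["P1"], ["S1", "S2"], [[1, 0]])
        att = EGeneAttachment(["E1"], [1])  # attached to S2
        assert predict_effects(net, states, att)[0, 0] == 1

    def test_null_attachment_predicts_nothing(self, chain3):
        states = PerturbationStates(["P1", "P2"], chain3.names, [[1, 1, 1], [0, 1, 0]])
        att = EGeneAttachment(["E1"], [NULL_ATTACHMENT])
        assert predict_effects(chain3, states, att).sum() == 0

    def test_single_perturbation_design_reduces_to_graph_product(self, chain3):
        # one patient per single S-gene perturbation: expected profile is
        # the subset-structured reach product of the closure and Theta
        states = PerturbationStates(["P1", "P2", "P3"], chain3.names, np.eye(3, dtype=int))
        att = EGeneAttachment(["E1", "E2", "E3"], [0, 1, 2])
        expected = chain3.reach_matrix()[
            np.arange(3)[:, None], att.attach[None, :]
        ]
        assert np.array_equal(predict_effects(chain3, states, att), expected)

    def test_misaligned_sgene_order_rejected(self, chain3):
        states = PerturbationStates(["P1"], ["S3", "S2", "S1"], [[0, 0, 1]])
        with pytest.raises(ValueError, match="order"):
            predict_effects(chain3, states, EGeneAttachment(["E1"], [0]))


class TestCellLoglik:
    @pytest.mark.parametrize(
        "e,expected,rates,value",
        [
            (1, 1, NoiseRates(0.1, 0.2), np.log(0.8)),
            (0, 0, NoiseRates(0.0, 0.2), 0.0),
            (1, 0, NoiseRates(0.07, 0.08), np.log(0.07)),
            (0, 1, NoiseRates(0.07, 0.08), np.log(0.08)),
        ],
    )
    def test_noise_table(self, e, expected, rates, value):
        assert cell_loglik(e, expected, rates) == pytest.approx(value, abs=1e-12)

    def test_zero_rate_gives_neg_inf_on_mismatch(self):
        assert cell_loglik(1, 0, NoiseRates(0.0, 0.1)) == -np.inf

    def test_rates_of_one_rejected(self):
        with pytest.raises(ValueError):
            NoiseRates(1.0, 0.1)
        with pytest.raises(ValueError):
            NoiseRates(0.1, 1.0)


class TestMarginalLoglikelihood:
    def test_single_sgene_hand_enumeration(self):
        # attachments: S1 (effect, prob 1-beta=0.8) or null (prob alpha=0.1)
        net = SGeneNetwork(["S1"], np.zeros((1, 1), dtype=int))
        states = PerturbationStates(["P1"], ["S1"], [[1]])
        obs = EffectObservations(["P1"], ["E1"], [[1]])
        ll = marginal_loglikelihood(net, states, obs, NoiseRates(0.1, 0.2))
        assert ll == pytest.approx(np.log((0.8 + 0.1) / 2), abs=1e-12)

    def test_noiseless_unique_match_gives_uniform_prior_mass(self, chain3):
        states = PerturbationStates(["P1", "P2", "P3"], chain3.names, np.eye(3, dtype=int))
        att = EGeneAttachment(["E1", "E2"], [0, 1])
        data = predict_effects(chain3, states, att)
        obs = EffectObservations(states.patient_ids, att.egene_names, data)
        # each E-gene's noiseless pattern matches exactly one attachment
        ll = marginal_loglikelihood(chain3, states, obs, NoiseRates(0.0, 0.0))
        assert ll == pytest.approx(2 * np.log(1 / 4), abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        net, states, _, obs = make_instance(
            m=3, n_egenes=4, l=5, seed=seed, alpha_sim=0.2, beta_sim=0.1
        )
        rates = NoiseRates(0.15, 0.1)
        fast = marginal_loglikelihood(net, states, obs, rates)
        slow = brute_force_marginal(net, states, obs, rates)
        assert fast == pytest.approx(slow, abs=1e-9)

    def test_invariant_under_egene_permutation(self):
        net, states, _, obs = make_instance(4, 6, 6, seed=3, alpha_sim=0.1, beta_sim=0.1)
        rates = NoiseRates(0.1, 0.1)
        perm = np.random.default_rng(0).permutation(obs.n)
        shuffled = EffectObservations(
            obs.patient_ids, [obs.egene_names[i] for i in perm], obs.data[:, perm]
        )
        assert marginal_loglikelihood(net, states, obs, rates) == pytest.approx(
            marginal_loglikelihood(net, states, shuffled, rates), abs=1e-9
        )

    def test_noise_model_mirror_symmetry(self):
        # with alpha = beta = r, complementing every observation equals
        # swapping the roles of the rates (alpha, beta) -> (1-r, 1-r)
        net, states, _, obs = make_instance(3, 5, 6, seed=9, alpha_sim=0.3, beta_sim=0.3)
        flipped = EffectObservations(obs.patient_ids, obs.egene_names, 1 - obs.data)
        r = 0.3
        assert marginal_loglikelihood(net, states, obs, NoiseRates(r, r)) == pytest.approx(
            marginal_loglikelihood(net, states, flipped, NoiseRates(1 - r, 1 - r)),
            abs=1e-9,
        )

    def test_empty_patient_or_nan_rejected(self, chain3):
        with pytest.raises(ValueError):
            PerturbationStates([], chain3.names, np.zeros((0, 3)))


class TestAttachmentPosterior:
    def test_uninformative_data_gives_uniform_rows(self, chain3):
        states = PerturbationStates(["P1", "P2"], chain3.names, np.zeros((2, 3), dtype=int))
        obs = EffectObservations(["P1", "P2"], ["E1"], [[0], [0]])
        post = attachment_posterior(chain3, states, obs, NoiseRates(0.1, 0.1))
        assert np.allclose(post.posterior, 1 / 4)

    def test_rows_sum_to_one_and_patient_permutation_invariance(self):
        net, states, _, obs = make_instance(4, 8, 10, seed=5, alpha_sim=0.1, beta_sim=0.1)
        rates = NoiseRates(0.1, 0.1)
        post = attachment_posterior(net, states, obs, rates)
        assert np.allclose(post.posterior.sum(axis=1), 1.0, atol=1e-9)
        perm = np.random.default_rng(1).permutation(states.l)
        states_p = PerturbationStates(
            [states.patient_ids[k] for k in perm], states.sgene_names, states.states[perm]
        )
        obs_p = EffectObservations(
            [obs.patient_ids[k] for k in perm], obs.egene_names, obs.data[perm]
        )
        post_p = attachment_posterior(net, states_p, obs_p, rates)
        assert np.allclose(post.posterior, post_p.posterior, atol=1e-12)

    def test_noiseless_matched_data_concentrates_on_truth(self, chain3):
        states = PerturbationStates(
            ["P1", "P2", "P3"], chain3.names, np.eye(3, dtype=int)
        )
        att = EGeneAttachment(["E1"], [2])  # unique pattern: only S3 column
        data = predict_effects(chain3, states, att)
        obs = EffectObservations(states.patient_ids, ["E1"], data)
        post = attachment_posterior(chain3, states, obs, NoiseRates(1e-9, 1e-9))
        assert post.posterior[0, 2] == pytest.approx(1.0, abs=1e-6)

    def test_map_recovers_planted_attachment_under_low_noise(self, chain3):
        rng_states = sample_states(3, 20, (0.2, 0.5), seed=21)
        states = PerturbationStates(rng_states.patient_ids, chain3.names, rng_states.states)
        att = EGeneAttachment(
            [f"E{i}" for i in range(30)], np.repeat([0, 1, 2], 10)
        )
        obs = sample_observations(chain3, states, att, 0.05, 0.05, seed=22)
        post = attachment_posterior(chain3, states, obs, NoiseRates(0.05, 0.05))
        recovered = post.map_attachment()
        assert (recovered == att.attach).mean() >= 0.9

    def test_impossible_row_raises_with_guidance(self):
        net = SGeneNetwork(["S1"], np.zeros((1, 1), dtype=int))
        states = PerturbationStates(["P1", "P2"], ["S1"], [[1], [0]])
        # e=1 while unperturbed (alpha=0 forbids) and e=0 while perturbed
        obs = EffectObservations(["P1", "P2"], ["E1"], [[0], [1]])
        with pytest.raises(ValueError, match="positive noise rates"):
            attachment_posterior(net, states, obs, NoiseRates(0.0, 0.0))
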