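import itertools

import numpy as np
import pytest

from nemtar import (
    EffectObservations,
    EGeneAttachment,
    NoiseRates,
    PerturbationStates,
    SGeneNetwork,
)
from nemtar.simulate import (
    sample_attachment,
    sample_network,
    sample_observations,
    sample_states,
)


@pytest.fixture
def chain3():
    """Closed 3-chain S1 -> S2 -> S3 (closure adds S1 -> S3)."""
    return SGeneNetwork.from_edges(["S1", "S2", "S3"], [("S1", "S2"), ("S2", "S3")])


def make_instance(m, n_egenes, l, seed, alpha_sim=0.0, beta_sim=0.0,
                  edge_prob=0.3, freq_range=(0.2, 0.5)):
    """Small random instance with an exact E-gene count (attachments may
    include the null S-gene when n_egenes is not a multiple of m)."""
    ss = np.random.SeedSequence(seed)
    s1, s2, s3, s4 = (s.generate_state(1)[0] for s in ss.spawn(4))
    net = sample_network(m, edge_prob, s1)
    states = sample_states(m, l, freq_range, s2)
    rng = np.random.default_rng(s3)
    attach = rng.integers(-1, m, size=n_egenes)  # -1 is the null S-gene
    attachment = EGeneAttachment([f"E{i+1}" for i in range(n_egenes)], attach)
    obs = sample_observations(net, states, attachment, alpha_sim, beta_sim, s4)
    return net, states, attachment, obs


def brute_force_marginal(network, states, data, rates):
    """Independent oracle: explicit sum over all (m+1)^n attachment vectors.

    Builds per-(E-gene, attachment) likelihoods cell by cell from the
    noise table, then literally enumerates every attachment vector; no
    shared code with the log-sum-exp implementation.
    """
    m = network.m
    l, n = data.data.shape
    reach = network.reach_matrix()
    # per-patient predicted effect under each candidate attachment
    lik = np.zeros((n, m + 1))
    for i in range(n):
        for j in range(m + 1):
            p = 1.0
            for k in range(l):
                if j < m:
                    expected = int(
                        any(states.states[k, jp] and reach[jp, j] for jp in range(m))
                    )
                else:
                    expected = 0
                e = data.data[k, i]
                if expected:
                    p *= (1.0 - rates.beta) if e else rates.beta
                else:
                    p *= rates.alpha if e else (1.0 - rates.alpha)
            lik[i, j] = p
    total = 0.0
    for vec in itertools.product(range(m + 1), repeat=n):
        prod = 1.0
        for i, j in enumerate(vec):
            prod *= lik[i, j]
        total += prod
    return np.log(total) - n * np.log(m + 1)
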