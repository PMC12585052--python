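"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's pruning/composition code paths:
likelihoods and marginals are computed by exhaustively enumerating
internal-node state combinations, and range composition by enumerating
every subset of the alphabet.  They are exponential in tree size and
only ever run on trees of ~6 tips or fewer.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from bbmrange import AreaAlphabet, Chronogram, F81GParams, f81_transition_matrix


def enum_loglik(chron: Chronogram, presence: dict, params: F81GParams) -> float:
    """Exhaustive-sum log-likelihood of one binary character."""
    total = 0.0
    for rate in params.rates():
        total += _enum_likelihood_terms(chron, presence, params, rate)[0]
    return math.log(total / params.k)


def enum_marginals(chron: Chronogram, presence: dict, params: F81GParams) -> dict:
    """Exhaustive-sum marginal P(state=1) at every internal node."""
    internals = [v for v in range(chron.n_nodes) if not chron.is_tip(v)]
    num = {v: 0.0 for v in internals}
    den = 0.0
    for rate in params.rates():
        like, per_state = _enum_likelihood_terms(chron, presence, params, rate)
        den += like
        for v in internals:
            num[v] += per_state[v]
    return {v: num[v] / den for v in internals}


def _enum_likelihood_terms(chron, presence, params, rate):
    tips = {int(i): presence[chron.labels[i]] for i in chron.tip_ids}
    internals = [v for v in range(chron.n_nodes) if not chron.is_tip(v)]
    pi = [params.pi0, params.pi1]
    P = {
        v: f81_transition_matrix(params, rate, float(chron.lengths[v]))
        for v in range(chron.n_nodes)
        if int(chron.parent[v]) >= 0
    }
    like = 0.0
    per_state_1 = {v: 0.0 for v in internals}
    for combo in itertools.product([0, 1], repeat=len(internals)):
        state = dict(tips)
        state.update(zip(internals, combo))
        pr = pi[state[chron.root]]
        for v in range(chron.n_nodes):
            p = int(chron.parent[v])
            if p >= 0:
                pr *= P[v][state[p], state[v]]
        like += pr
        for v in internals:
            if state[v] == 1:
                per_state_1[v] += pr
    return like, per_state_1


def enum_range_posterior(area_p: dict, max_areas: int, alphabet: AreaAlphabet) -> dict:
    """Range composition by enumerating all 2^A subsets, then masking."""
    letters = list(alphabet.letters)
    weights = {}
    for bits in itertools.product([0, 1], repeat=len(letters)):
        subset = frozenset(l for l, b in zip(letters, bits) if b)
        w = 1.0
        for l, b in zip(letters, bits):
            w *= area_p.get(l, 0.0) if b else 1.0 - area_p.get(l, 0.0)
        weights[subset] = w
    allowed = {s: w for s, w in weights.items() if 0 < len(s) <= max_areas}
    total = sum(allowed.values())
    if total == 0:
        best = max(letters, key=lambda l: area_p.get(l, 0.0))
        return {frozenset([best]): 1.0}
    return {s: w / total for s, w in allowed.items() if w > 0.0}


def random_small_tree(rng: np.random.Generator, max_tips: int = 6) -> Chronogram:
    """Random ultrametric binary tree with 2..max_tips tips (coalescent-style)."""
    from bbmrange import parse_chronogram

    n = int(rng.integers(2, max_tips + 1))
    nodes = [(f"T{i}", 0.0) for i in range(n)]  # (newick, age)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (nwk_j, age_j) = nodes.pop(j)
        (nwk_i, age_i) = nodes.pop(i)
        age = max(age_i, age_j) + float(rng.uniform(0.05, 1.0))
        merged = f"({nwk_i}:{age - age_i:.9f},{nwk_j}:{age - age_j:.9f})"
        nodes.append((merged, age))
    return parse_chronogram(nodes[0][0] + ";")
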