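"""Bayesian binary ancestral range reconstruction (F81 + G).

Presence/absence of a lineage in each geographic area is modelled as an
independent binary character evolving on the chronogram under a
two-state F81 process: the gain rate is proportional to the stationary
presence frequency pi1 and the loss rate to pi0 = 1 - pi1, normalized by
beta = 1 / (2 * pi0 * pi1) so that one unit of branch length produces
one expected change at stationarity.  Among-area rate heterogeneity
("+G") is a discrete-gamma mixture with mean 1 and k equal-probability
categories; each area draws its category independently and the
likelihood marginalizes over categories per area.

A Metropolis-Hastings sampler explores (pi1, alpha) with the product of
per-area pruning likelihoods as the data term.  Per-node presence
posteriors are Rao-Blackwellized averages of the analytic marginal
posterior over the retained MCMC samples; composed range posteriors
truncate at a maximum number of areas, mirroring reconstructions that
cap ancestral ranges (here default 3).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .treedata import AreaAlphabet, Chronogram, CodingError, RegionCoding

__all__ = [
    "F81GParams",
    "BBMConfig",
    "BBMResult",
    "f81_transition_matrix",
    "discrete_gamma_rates",
    "area_log_likelihood",
    "node_area_posterior",
    "compose_range_posterior",
    "map_range",
    "run_bbm_mcmc",
    "run_bbm_mcmc_matrix",
]


@dataclass(frozen=True)
class F81GParams:
    """Binary F81 + discrete-gamma parameters.

    pi1
        Stationary presence frequency, in (0, 1).
    alpha
        Gamma shape of the among-area rate distribution (> 0).
    k
        Number of discrete gamma categories (>= 1, default 4).
    """

    pi1: float
    alpha: float
    k: int = 4

    def __post_init__(self):
        if not 0.0 < self.pi1 < 1.0:
            raise ValueError(f"pi1 must be in (0,1), got {self.pi1}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1

    @property
    def beta(self) -> float:
        """Normalizer giving one expected change per Myr at stationarity."""
        return 1.0 / (2.0 * self.pi0 * self.pi1)

    def rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.k)


@dataclass(frozen=True)
class BBMConfig:
    """MCMC run settings (defaults follow the study design: ten chains of
    100,000 generations, 20,000 burn-in, sampling every 100, ancestral
    ranges capped at three areas)."""

    generations: int = 100_000
    burnin: int = 20_000
    samplefreq: int = 100
    chains: int = 10
    max_areas: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.burnin >= self.generations:
            raise ValueError("burnin must be smaller than generations")
        if self.samplefreq < 1 or self.chains < 1:
            raise ValueError("samplefreq and chains must be positive")
        if self.max_areas < 1:
            raise ValueError("max_areas must be >= 1")

    @property
    def samples_per_chain(self) -> int:
        return (self.generations - self.burnin) // self.samplefreq

    @property
    def total_samples(self) -> int:
        return self.chains * self.samples_per_chain


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean-of-slice discretization of a mean-1 gamma into ``k`` rates.

    The gamma(alpha, rate=alpha) density is cut at its 1/k quantiles and
    each category multiplier is the conditional mean of its slice, so the
    multipliers are strictly increasing with mean exactly 1.
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k == 1:
        return np.ones(1)
    cuts = stats.gamma.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    # E[X ; X <= c] for gamma(a, rate=a) equals regularized gammainc(a+1, a*c)
    upper = special.gammainc(alpha + 1.0, alpha * cuts)
    cdf = np.concatenate(([0.0], upper, [1.0]))
    rates = k * np.diff(cdf)
    return rates / rates.mean()


def f81_transition_matrix(params: F81GParams, rate: float, t: float) -> np.ndarray:
    """2x2 transition matrix P(t) with P_ij = pi_j + (d_ij - pi_j) e^(-beta r t)."""
    if t < 0:
        raise ValueError(f"elapsed time must be >= 0, got {t}")
    if rate < 0:
        raise ValueError(f"rate multiplier must be >= 0, got {rate}")
    e = math.exp(-params.beta * rate * t)
    pi0, pi1 = params.pi0, params.pi1
    return np.array(
        [
            [pi0 + pi1 * e, pi1 * (1.0 - e)],
            [pi0 * (1.0 - e), pi1 + pi0 * e],
        ]
    )


# ---------------------------------------------------------------------------
# pruning engine
# ---------------------------------------------------------------------------


class _PruningPlan:
    """Array layout for level-batched pruning on one chronogram.

    Internal nodes are grouped into topological levels (all children of a
    level's nodes live in lower levels), so one likelihood evaluation is
    a short sequence of vectorized einsum contractions rather than a
    per-node Python loop.
    """

    def __init__(self, chron: Chronogram):
        self.chron = chron
        self.n = chron.n_nodes
        self.root = chron.root
        self.lengths = chron.lengths.copy()
        self.tip_ids = chron.tip_ids
        self.tip_labels = chron.tip_labels
        level = np.zeros(self.n, dtype=np.int64)
        for v in chron.postorder():
            kids = chron.children[v]
            if kids:
                level[v] = 1 + max(level[c] for c in kids)
        self.levels: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for lv in range(1, int(level.max()) + 1):
            nodes = np.flatnonzero(level == lv)
            nodes = nodes[[len(chron.children[v]) == 2 for v in nodes]]
            c1 = np.array([chron.children[v][0] for v in nodes], dtype=np.int64)
            c2 = np.array([chron.children[v][1] for v in nodes], dtype=np.int64)
            self.levels.append((nodes, c1, c2))
        # top-down order for the outside pass
        self.down_levels = list(reversed(self.levels))


def _plan_for(chron: Chronogram) -> _PruningPlan:
    if getattr(chron, "_plan_cache", None) is None:
        chron._plan_cache = _PruningPlan(chron)
    return chron._plan_cache


def _transition_tensor(plan: _PruningPlan, params: F81GParams, rates: np.ndarray) -> np.ndarray:
    """Per-node, per-category 2x2 transition matrices, shape (n, k, 2, 2)."""
    e = np.exp(-params.beta * np.outer(plan.lengths, rates))  # (n, k)
    pi0, pi1 = params.pi0, params.pi1
    P = np.empty((plan.n, len(rates), 2, 2))
    P[..., 0, 0] = pi0 + pi1 * e
    P[..., 0, 1] = pi1 * (1.0 - e)
    P[..., 1, 0] = pi0 * (1.0 - e)
    P[..., 1, 1] = pi1 + pi0 * e
    return P


_TINY = 1e-300


def _up_pass(plan: _PruningPlan, X: np.ndarray, params: F81GParams, rates: np.ndarray):
    """Inside (pruning) pass over all areas and categories at once.

    X : (n_tips, A) 0/1 presence by tip (ordered as plan.tip_ids).
    Returns (L, S, msgs, E, root_ll) where root_ll has shape (A, k) and is
    the log-likelihood per area and category.

    The F81 structure collapses the matrix product: with
    e = exp(-beta*r*t), the message a child sends its parent is
    ``m_i = e * L_i + (1 - e) * (pi0*L_0 + pi1*L_1)`` — no 2x2 matmul
    needed.
    """
    A = X.shape[1]
    k = len(rates)
    E = np.exp(-params.beta * np.outer(plan.lengths, rates))  # (n, k)
    pi = np.array([params.pi0, params.pi1])
    L = np.zeros((plan.n, A, k, 2))
    S = np.zeros((plan.n, A, k))
    msgs = np.zeros((plan.n, A, k, 2))  # message each node sends to its parent
    Xf = X.astype(float)
    L[plan.tip_ids, :, :, 0] = (1.0 - Xf)[:, :, None]
    L[plan.tip_ids, :, :, 1] = Xf[:, :, None]
    for nodes, c1, c2 in plan.levels:
        e1 = E[c1][:, None, :, None]
        e2 = E[c2][:, None, :, None]
        m1 = e1 * L[c1] + (1.0 - e1) * (L[c1] @ pi)[..., None]
        m2 = e2 * L[c2] + (1.0 - e2) * (L[c2] @ pi)[..., None]
        msgs[c1] = m1
        msgs[c2] = m2
        prod = m1 * m2
        mx = np.maximum(prod.max(axis=-1, keepdims=True), _TINY)
        L[nodes] = prod / mx
        S[nodes] = np.log(mx[..., 0]) + S[c1] + S[c2]
    root_ll = np.log(np.maximum(L[plan.root] @ pi, _TINY)) + S[plan.root]
    return L, S, msgs, E, root_ll


def _area_logliks(root_ll: np.ndarray, k: int) -> np.ndarray:
    """Per-area log-likelihood, averaging categories with equal weight."""
    return special.logsumexp(root_ll, axis=1) - math.log(k)


def _loglik_matrix(chron: Chronogram, X: np.ndarray, params: F81GParams) -> np.ndarray:
    plan = _plan_for(chron)
    rates = params.rates()
    _, _, _, _, root_ll = _up_pass(plan, X, params, rates)
    return _area_logliks(root_ll, params.k)


def _marginals_matrix(chron: Chronogram, X: np.ndarray, params: F81GParams) -> np.ndarray:
    """P(present) for every node and area, shape (n_nodes, A).

    Outside-inside pass; categories are mixed with weights proportional
    to each category's data likelihood per area.
    """
    plan = _plan_for(chron)
    rates = params.rates()
    L, S, msgs, E, root_ll = _up_pass(plan, X, params, rates)
    A, k = root_ll.shape
    pi = np.array([params.pi0, params.pi1])
    D = np.zeros((plan.n, A, k, 2))
    D[plan.root, :, :, 0] = params.pi0
    D[plan.root, :, :, 1] = params.pi1
    for nodes, c1, c2 in plan.down_levels:
        out1 = D[nodes] * msgs[c2]
        out2 = D[nodes] * msgs[c1]
        # transposed F81 message: D_j = e*out_j + (1-e)*pi_j*sum(out)
        for child, out in ((c1, out1), (c2, out2)):
            ec = E[child][:, None, :, None]
            D[child] = ec * out + (1.0 - ec) * out.sum(axis=-1)[..., None] * pi
            mx = np.maximum(D[child].max(axis=-1, keepdims=True), _TINY)
            D[child] /= mx
    joint = D * L  # (n, A, k, 2), unnormalized per (node, area, category)
    tot = np.maximum(joint.sum(axis=-1), _TINY)
    p1 = joint[..., 1] / tot
    w = np.exp(root_ll - root_ll.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    return np.einsum("nak,ak->na", p1, w)


def _presence_vector(chron: Chronogram, presence: Mapping[str, int]) -> np.ndarray:
    col = np.empty((chron.n_tips, 1), dtype=np.int8)
    for i, label in enumerate(chron.tip_labels):
        if label not in presence:
            raise CodingError(f"no presence state for taxon {label!r}")
        val = presence[label]
        if val not in (0, 1):
            raise CodingError(f"presence state for {label!r} must be 0 or 1, got {val!r}")
        col[i, 0] = val
    return col


def area_log_likelihood(
    chron: Chronogram, presence: Mapping[str, int], params: F81GParams
) -> float:
    """Felsenstein-pruning log-likelihood of one binary presence character.

    The root is weighted by the stationary distribution (pi0, pi1) and the
    k gamma categories are averaged with equal weights.
    """
    X = _presence_vector(chron, presence)
    return float(_loglik_matrix(chron, X, params)[0])


def node_area_posterior(
    chron: Chronogram, presence: Mapping[str, int], params: F81GParams
) -> dict[int, float]:
    """Marginal posterior P(present) at every node for one area.

    Tips report their observed state; internal values come from the
    outside-inside pass with likelihood-weighted category mixing.
    """
    X = _presence_vector(chron, presence)
    p = _marginals_matrix(chron, X, params)[:, 0]
    return {int(v): float(p[v]) for v in range(chron.n_nodes)}


# ---------------------------------------------------------------------------
# range composition and MAP assignment
# ---------------------------------------------------------------------------


def compose_range_posterior(
    area_p: Mapping[str, float], max_areas: int, alphabet: AreaAlphabet
) -> dict[frozenset, float]:
    """Compose per-area presence posteriors into a range posterior.

    Treats areas as independent: weight(S) = prod_{a in S} p_a *
    prod_{a not in S} (1 - p_a) over all non-empty S with ``|S| <=
    max_areas``, renormalized over that allowed set.  If every allowed
    weight vanishes, falls back to certainty on the single best area.
    """
    if len(alphabet) == 0:
        raise ValueError("empty area alphabet")
    letters = list(alphabet.letters)
    p = np.array([float(area_p.get(a, 0.0)) for a in letters])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("area probabilities must be in [0, 1]")
    weights: dict[frozenset, float] = {}
    total = 0.0
    for size in range(1, min(max_areas, len(letters)) + 1):
        for combo in itertools.combinations(range(len(letters)), size):
            mask = np.zeros(len(letters), dtype=bool)
            mask[list(combo)] = True
            w = float(np.prod(np.where(mask, p, 1.0 - p)))
            rng = frozenset(letters[i] for i in combo)
            weights[rng] = w
            total += w
    if total <= 0.0:
        best = letters[int(np.argmax(p))]
        return {frozenset([best]): 1.0}
    return {rng: w / total for rng, w in weights.items() if w > 0.0}


def map_range(range_post: Mapping[frozenset, float], alphabet: AreaAlphabet) -> frozenset:
    """Highest-posterior range; ties broken by smaller cardinality, then
    lexicographically in alphabet order — fully deterministic."""
    if not range_post:
        raise ValueError("empty range posterior")
    return min(
        range_post,
        key=lambda rng: (-range_post[rng], len(rng), alphabet.range_key(rng)),
    )


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


@dataclass
class BBMResult:
    """Pooled posterior samples plus per-node presence/range posteriors."""

    samples: pd.DataFrame  # columns: chain, generation, pi1, alpha, loglik
    area_posteriors: dict[int, dict[str, float]]
    range_posteriors: dict[int, dict[frozenset, float]]
    acceptance: dict[int, dict[str, float]]
    config: BBMConfig
    alphabet: AreaAlphabet

    def map_ranges(self) -> dict[int, frozenset]:
        return {
            node: map_range(post, self.alphabet)
            for node, post in self.range_posteriors.items()
        }

    def posterior_summary(self) -> pd.DataFrame:
        return self.samples[["pi1", "alpha"]].agg(["mean", "std"])

    def range_posterior_frame(self) -> pd.DataFrame:
        rows = []
        for node in sorted(self.range_posteriors):
            for rng, p in sorted(
                self.range_posteriors[node].items(),
                key=lambda kv: (-kv[1], len(kv[0]), self.alphabet.range_key(kv[0])),
            ):
                rows.append((node, self.alphabet.format_range(rng), p))
        return pd.DataFrame(rows, columns=["node_id", "range", "probability"])


_PI1_WINDOW = 0.1  # half-width of the reflected sliding-window proposal
_ALPHA_SCALE = 0.7  # log-scale width of the multiplier proposal


def _reflect(x: float, lo: float = 0.0, hi: float = 1.0) -> float:
    span = hi - lo
    x = (x - lo) % (2.0 * span)
    return lo + (x if x <= span else 2.0 * span - x)


def _log_prior(pi1: float, alpha: float) -> float:
    # pi1 ~ Uniform(0,1), alpha ~ Exponential(mean 1)
    if not (0.0 < pi1 < 1.0) or alpha <= 0:
        return -np.inf
    return -alpha


def _run_chain(
    chron: Chronogram,
    X: np.ndarray,
    config: BBMConfig,
    k: int,
    rng: np.random.Generator,
    chain_id: int,
):
    pi1 = float(rng.uniform(0.05, 0.95))
    alpha = float(np.exp(rng.uniform(np.log(0.25), np.log(4.0))))

    def loglik(p1, a):
        return float(_loglik_matrix(chron, X, F81GParams(p1, a, k)).sum())

    ll = loglik(pi1, alpha)
    lp = _log_prior(pi1, alpha)
    rows = []
    proposed = {"pi1": 0, "alpha": 0}
    accepted = {"pi1": 0, "alpha": 0}
    for gen in range(1, config.generations + 1):
        if gen % 2 == 1:
            cand = _reflect(pi1 + rng.uniform(-_PI1_WINDOW, _PI1_WINDOW))
            cand = min(max(cand, 1e-9), 1.0 - 1e-9)
            log_hastings = 0.0
            new = (cand, alpha)
            param = "pi1"
        else:
            factor = math.exp(_ALPHA_SCALE * (rng.uniform() - 0.5))
            cand = alpha * factor
            log_hastings = math.log(factor)  # q ratio for a multiplier move
            new = (pi1, cand)
            param = "alpha"
        proposed[param] += 1
        lp_new = _log_prior(*new)
        if np.isfinite(lp_new):
            ll_new = loglik(*new)
            if math.log(rng.uniform() + 1e-300) < (ll_new + lp_new) - (ll + lp) + log_hastings:
                pi1, alpha = new
                ll, lp = ll_new, lp_new
                accepted[param] += 1
        if gen > config.burnin and (gen - config.burnin) % config.samplefreq == 0:
            rows.append((chain_id, gen, pi1, alpha, ll))
    rates = {p: (accepted[p] / proposed[p] if proposed[p] else 0.0) for p in proposed}
    return rows, rates


def run_bbm_mcmc_matrix(
    chron: Chronogram,
    X: np.ndarray,
    config: BBMConfig,
    alphabet: AreaAlphabet,
) -> BBMResult:
    """MCMC over (pi1, alpha) given a 0/1 tip-by-area presence matrix.

    This is the engine behind :func:`run_bbm_mcmc`; it accepts raw
    matrices (including all-absent tips) so simulation studies can feed
    unconditioned data.  Bit-identical results for identical
    (config.seed, inputs).
    """
    X = np.asarray(X)
    if X.shape != (chron.n_tips, len(alphabet)):
        raise ValueError(
            f"presence matrix shape {X.shape} does not match "
            f"({chron.n_tips} tips, {len(alphabet)} areas)"
        )
    col_informative = (X.min(axis=0) != X.max(axis=0)).sum()
    if col_informative == 0 or len(np.unique(X, axis=0)) == 1:
        raise CodingError(
            "degenerate coding: all tips share the same range, no signal for reconstruction"
        )
    k = 4
    streams = np.random.SeedSequence(config.seed).spawn(config.chains)
    all_rows: list[tuple] = []
    acceptance: dict[int, dict[str, float]] = {}
    for chain_id, ss in enumerate(streams):
        rows, rates = _run_chain(chron, X, config, k, np.random.Generator(np.random.PCG64(ss)), chain_id)
        all_rows.extend(rows)
        acceptance[chain_id] = rates
    samples = pd.DataFrame(all_rows, columns=["chain", "generation", "pi1", "alpha", "loglik"])

    # Rao-Blackwellized presence posteriors: average the analytic node
    # marginals over the pooled samples (memoized on the parameter pair,
    # since rejected moves repeat values).
    acc = np.zeros((chron.n_nodes, len(alphabet)))
    memo: dict[tuple[float, float], np.ndarray] = {}
    for p1, a in zip(samples["pi1"], samples["alpha"]):
        key = (p1, a)
        if key not in memo:
            memo[key] = _marginals_matrix(chron, X, F81GParams(p1, a, k))
        acc += memo[key]
    acc /= len(samples)

    letters = list(alphabet.letters)
    area_posteriors = {
        int(v): {letters[a]: float(acc[v, a]) for a in range(len(letters))}
        for v in range(chron.n_nodes)
    }
    range_posteriors = {
        v: compose_range_posterior(post, config.max_areas, alphabet)
        for v, post in area_posteriors.items()
    }
    return BBMResult(samples, area_posteriors, range_posteriors, acceptance, config, alphabet)


def run_bbm_mcmc(
    chron: Chronogram,
    coding: RegionCoding,
    config: BBMConfig,
    alphabet: AreaAlphabet,
) -> BBMResult:
    """Full reconstruction from a taxon->range coding.

    Validates that coding taxa and tree tips coincide and that the data
    carry signal (at least two observed areas, non-identical ranges),
    then delegates to :func:`run_bbm_mcmc_matrix`.
    """
    tips = set(chron.tip_labels)
    coded = coding.taxa()
    if tips != coded:
        missing = sorted(tips - coded)
        extra = sorted(coded - tips)
        raise CodingError(
            f"coding/tree tip mismatch; tips without coding: {missing}; "
            f"coded taxa not in tree: {extra}"
        )
    if len(coding.observed_letters()) < 2:
        raise CodingError("need at least two observed areas for reconstruction")
    X = coding.presence_matrix(chron.tip_labels, alphabet)
    return run_bbm_mcmc_matrix(chron, X, config, alphabet)
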