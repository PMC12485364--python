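"""Expected site-pattern frequencies under the multispecies coalescent with
introgression (MSci) and lineage-specific substitution rates.

The model is a four-taxon asymmetric species tree (((P1,P2),P3),O) with an
optional episodic introgression pulse from P1 into P3, Jukes-Cantor (JC69)
sequence evolution (so homoplasy / multiple hits are allowed), and per-lineage
relative-rate multipliers lambda on the terminal P1, P3 and O populations
(reference rate 1 on P2 and all ancestral populations).  All times are in
expected mutations per site (tau = T*mu) and the population size is
theta = 4*N*mu, assumed equal across populations before rate scaling.

The central quantity is the per-site probability of the three
parsimony-informative patterns ABBA, BABA and BBAA (outgroup state labelled
A).  ``pattern_freqs`` computes them exactly: every coalescent history class
is enumerated (which lineages coalesce in which inter-speciation epoch, and
in what order), the JC69 probability of a pattern given the gene tree is
expanded into a sum of exponentials of branch lengths, and the expectation
over the (truncated-)exponential coalescent waiting times is taken in closed
form.  No Monte Carlo and no quadrature is involved; agreement with the
closed-form ABBA-BABA difference and with simulation is covered by the test
suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MSciParams",
    "GenerationParams",
    "PatternFrequencies",
    "to_mutation_units",
    "abba_baba_diff_closed_form",
    "pattern_freqs",
    "expected_D",
    "tau_for_target_D",
    "limit_D",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MSciParams:
    """MSci model parameters in mutation units.

    tau1, tau2, tau3
        Divergence times of (P1,P2), ((P1,P2),P3) and the root, in expected
        mutations per site; 0 < tau1 < tau2 <= tau3.
    tau_g
        Introgression time (0 <= tau_g < tau1); only meaningful when
        gamma > 0.
    theta
        Scaled population size 4*N*mu, shared by all populations (the P1
        population is scaled to lambda_p1*theta while it hosts the migrant
        lineage, mirroring the branch-length scaling).
    gamma
        Introgression proportion: probability that the P3 lineage traces back
        through the P1 population at tau_g.
    lambda_p1, lambda_p3, lambda_o
        Relative substitution-rate multipliers of the terminal P1, P3 and O
        populations (P2 and all ancestral populations have rate 1).
    """

    tau1: float
    tau2: float
    tau3: float
    theta: float
    gamma: float = 0.0
    tau_g: float = 0.0
    lambda_p1: float = 1.0
    lambda_p3: float = 1.0
    lambda_o: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.tau1 < self.tau2 <= self.tau3):
            raise ValueError(
                f"require 0 < tau1 < tau2 <= tau3, got "
                f"({self.tau1}, {self.tau2}, {self.tau3})"
            )
        if self.theta <= 0.0:
            raise ValueError("theta must be positive")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        if self.gamma > 0.0 and not (0.0 <= self.tau_g < self.tau1):
            raise ValueError("require 0 <= tau_g < tau1 when gamma > 0")
        for name in ("lambda_p1", "lambda_p3", "lambda_o"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class GenerationParams:
    """Branch lengths and demography in generation units (scenario-grid semantics).

    T_S is the divergence time of the sister pair, T_I the internal branch
    length, T_O the outgroup stem length and T_G the introgression time (all
    generations); two_N is the conventional "2N", interpreted as the number of
    haploid gene copies (pairwise coalescence rate 1/2N per generation); mu is
    the mutation rate per site per generation.
    """

    T_S: float
    T_I: float
    T_O: float
    two_N: float
    mu: float
    T_G: float = 0.0

    def __post_init__(self) -> None:
        for name in ("T_S", "T_I", "T_O", "two_N", "mu"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if self.T_G < 0.0 or self.T_G >= self.T_S:
            if self.T_G != 0.0:
                raise ValueError("require 0 <= T_G < T_S")


@dataclass(frozen=True)
class PatternFrequencies:
    """Per-site probabilities of the parsimony-informative patterns."""

    p_abba: float
    p_baba: float
    p_bbaa: float

    def __post_init__(self) -> None:
        s = self.p_abba + self.p_baba + self.p_bbaa
        if min(self.p_abba, self.p_baba, self.p_bbaa) < -1e-15 or s > 1.0 + 1e-12:
            raise ValueError("pattern frequencies must lie in [0,1] and sum to <= 1")


def to_mutation_units(
    gp: GenerationParams,
    rates: tuple[float, float, float] = (1.0, 1.0, 1.0),
    gamma: float = 0.0,
) -> MSciParams:
    """Convert generation-unit parameters to mutation units (tau = T*mu,
    theta = 2*(2N)*mu = 4*N*mu).  ``rates`` is (lambda_p1, lambda_p3, lambda_o)."""
    return MSciParams(
        tau1=gp.T_S * gp.mu,
        tau2=(gp.T_S + gp.T_I) * gp.mu,
        tau3=(gp.T_S + gp.T_I + gp.T_O) * gp.mu,
        theta=2.0 * gp.two_N * gp.mu,
        gamma=gamma,
        tau_g=gp.T_G * gp.mu,
        lambda_p1=rates[0],
        lambda_p3=rates[1],
        lambda_o=rates[2],
    )


# ---------------------------------------------------------------------------
# closed-form ABBA-BABA difference (no introgression, rate shift on P1 only)
# ---------------------------------------------------------------------------


def abba_baba_diff_closed_form(p: MSciParams) -> float:
    """Closed-form P(ABBA) - P(BABA) for gamma = 0 and unit P3/O rates:

        (3/16) * (1 - exp(-(4/3)(lambda-1) tau1)) / (1 + 4 theta/3)
               * (exp(-8 tau2/3) - exp(-8 tau3/3))

    The sign equals sign(lambda_p1 - 1): only rate asymmetry between the
    sister lineages breaks the ABBA/BABA balance maintained by ILS.
    """
    if p.gamma != 0.0:
        raise ValueError("closed form only valid without introgression (gamma=0)")
    if p.lambda_p3 != 1.0 or p.lambda_o != 1.0:
        raise ValueError("closed form only valid for unit P3 and O rates")
    lam = p.lambda_p1
    return (
        (3.0 / 16.0)
        * (-math.expm1(-(4.0 / 3.0) * (lam - 1.0) * p.tau1))
        / (1.0 + 4.0 * p.theta / 3.0)
        * (math.exp(-8.0 * p.tau2 / 3.0) - math.exp(-8.0 * p.tau3 / 3.0))
    )


# ---------------------------------------------------------------------------
# exact pattern frequencies: coalescent-history enumeration
# ---------------------------------------------------------------------------
#
# Lineages are frozensets of tip indices 0..3 = (P1, P2, P3, O).  A "branch"
# of the computation is the introgression indicator: with probability gamma
# the P3 lineage is in the P1 population during [tau_g, tau1].
#
# Time is divided at the breakpoints [0, (tau_g,) tau1, tau2, tau3, inf).
# Within each epoch the lineages present in the single coalescing ("pool")
# population wait with exponential times; the joint density of a history is a
# product of exponentials in the waiting-time variables, and JC69 pattern
# probabilities given the gene tree expand into sums of exponentials of
# branch lengths, which are affine in those variables.  Every term therefore
# integrates in closed form.

_TIP_NAMES = ("P1", "P2", "P3", "O")


def _multiplier(tips: frozenset, interval: int, jump: bool, p: MSciParams) -> float:
    """Mutation-rate multiplier of the population hosting ``tips`` during the
    given breakpoint interval."""
    if jump:
        # intervals: 0=[0,tau_g] 1=[tau_g,tau1] 2=[tau1,tau2] 3=[tau2,tau3] 4=root
        if interval == 0:
            return (p.lambda_p1, 1.0, p.lambda_p3, p.lambda_o)[next(iter(tips))]
        if interval == 1:
            if tips <= {0, 2}:
                return p.lambda_p1
            return 1.0 if tips == {1} else p.lambda_o
        if interval in (2, 3):
            return p.lambda_o if tips == {3} else 1.0
        return 1.0
    # intervals: 0=[0,tau1] 1=[tau1,tau2] 2=[tau2,tau3] 3=root
    if interval == 0:
        return (p.lambda_p1, 1.0, p.lambda_p3, p.lambda_o)[next(iter(tips))]
    if interval == 1:
        if tips <= {0, 1}:
            return 1.0
        return p.lambda_p3 if tips == {2} else p.lambda_o
    if interval == 2:
        return p.lambda_o if tips == {3} else 1.0
    return 1.0


@dataclass(eq=False)
class _Var:
    interval: int
    bounded: bool
    L: float
    pair_rate: float
    k_at_event: int
    earlier_same_epoch: list = field(default_factory=list)
    dens_c: float = 0.0  # density exponent coefficient, filled at epoch end


@dataclass
class _History:
    coef: float
    vars: list
    dens_const: float
    edges: list  # (child_id, parent_id, tips, s_const, s_coefs, s_int, t_const, t_coefs, t_int)


def _enumerate_histories(p: MSciParams, jump: bool) -> list[_History]:
    if jump:
        bps = [0.0, p.tau_g, p.tau1, p.tau2, p.tau3, math.inf]
        pr_first = 2.0 / (p.lambda_p1 * p.theta)
        epochs = [
            (1, pr_first, [frozenset({0}), frozenset({2})]),
            (2, 2.0 / p.theta, [frozenset({1})]),
            (3, 2.0 / p.theta, []),
            (4, 2.0 / p.theta, [frozenset({3})]),
        ]
    else:
        bps = [0.0, p.tau1, p.tau2, p.tau3, math.inf]
        epochs = [
            (1, 2.0 / p.theta, [frozenset({0}), frozenset({1})]),
            (2, 2.0 / p.theta, [frozenset({2})]),
            (3, 2.0 / p.theta, [frozenset({3})]),
        ]

    out: list[_History] = []

    # a lineage is (tips, birth_const, birth_coefs: dict, birth_interval, node_id)
    def tip_lineage(ts: frozenset):
        return (ts, 0.0, {}, 0, next(iter(ts)))

    def run_epoch(ei, pool, vars_, edges, dens_const, coef, next_node):
        interval, pr, entrants = epochs[ei]
        pool = pool + [tip_lineage(t) for t in entrants]
        k0 = len(pool)
        last = ei == len(epochs) - 1
        L = bps[interval + 1] - bps[interval]
        start = bps[interval]
        njs = [k0 - 1] if last else list(range(k0))

        def run_events(cur_pool, nleft, epoch_vars, vars_, edges, coef, next_node):
            if nleft == 0:
                # close the epoch: density contributions
                k_end = len(cur_pool)
                r_end = 0.0 if last else (k_end * (k_end - 1) / 2.0) * pr
                for v in epoch_vars:
                    kk = v.k_at_event
                    v.dens_c = (kk * (kk - 1) / 2.0) * pr - r_end
                if not last:
                    run_epoch(
                        ei + 1, cur_pool, vars_, edges, dens_const + r_end * L,
                        coef, next_node,
                    )
                else:
                    assert len(cur_pool) == 1
                    out.append(_History(coef, list(vars_), dens_const, list(edges)))
                return
            k = len(cur_pool)
            for ia, ib in combinations(range(k), 2):
                var = _Var(interval, not last, L, pr, k)
                var.earlier_same_epoch = [vars_.index(v) for v in epoch_vars]
                nvars = vars_ + [var]
                vid = len(nvars) - 1
                t_coefs = {vars_.index(v): 1.0 for v in epoch_vars}
                t_coefs[vid] = 1.0
                a, b = cur_pool[ia], cur_pool[ib]
                nid = next_node
                nedges = edges + [
                    (a[4], nid, a[0], a[1], a[2], a[3], start, t_coefs, interval),
                    (b[4], nid, b[0], b[1], b[2], b[3], start, t_coefs, interval),
                ]
                merged = (a[0] | b[0], start, dict(t_coefs), interval, nid)
                npool = [x for i, x in enumerate(cur_pool) if i not in (ia, ib)]
                npool.append(merged)
                run_events(
                    npool, nleft - 1, epoch_vars + [var], nvars, nedges, coef * pr, nid + 1
                )

        for j in njs:
            run_events(pool, j, [], vars_, edges, coef, next_node)

    run_epoch(0, [], [], [], 0.0, 1.0, 4)
    return out


def _edge_length_affine(edge, bps, jump, p, m):
    """Mutation length of an edge as (const, coef[m]) in the waiting vars."""
    _, _, tips, s_c, s_co, s_i, t_c, t_co, t_i = edge
    const = 0.0
    coef = np.zeros(m)
    if s_i == t_i:
        mu_ = _multiplier(tips, s_i, jump, p)
        const += mu_ * (t_c - s_c)
        for v, w in t_co.items():
            coef[v] += mu_ * w
        for v, w in s_co.items():
            coef[v] -= mu_ * w
        return const, coef
    mu_s = _multiplier(tips, s_i, jump, p)
    const += mu_s * (bps[s_i + 1] - s_c)
    for v, w in s_co.items():
        coef[v] -= mu_s * w
    for f in range(s_i + 1, t_i):
        const += _multiplier(tips, f, jump, p) * (bps[f + 1] - bps[f])
    mu_t = _multiplier(tips, t_i, jump, p)
    const += mu_t * (t_c - bps[t_i])
    for v, w in t_co.items():
        coef[v] += mu_t * w
    return const, coef


# subset-expansion coefficients of JC69 pattern probabilities ---------------

_STATE_GRID = np.stack(np.meshgrid(*(np.arange(4),) * 3, indexing="ij"), -1).reshape(-1, 3)


def _subset_coefs(edge_nodes: tuple, tipstates: tuple) -> np.ndarray:
    """Coefficients c_S such that P(tips = tipstates | gene tree) equals
    sum_S c_S * prod_{e in S} exp(-(4/3) d_e), with S over subsets of the six
    edges (bit e of S <-> edge e in ``edge_nodes`` order)."""
    states = np.empty((64, 7), dtype=np.int64)
    states[:, :4] = tipstates
    states[:, 4:] = _STATE_GRID
    w = np.empty((64, 6))
    for e, (c, par) in enumerate(edge_nodes):
        same = states[:, c] == states[:, par]
        w[:, e] = np.where(same, 0.75, -0.25)
    prod = np.ones((64, 1))
    for e in range(6):
        prod = np.concatenate([prod, prod * w[:, e : e + 1]], axis=1)
    nbits = np.array([bin(s).count("1") for s in range(64)])
    return 0.25 * (0.25 ** (6 - nbits)) * prod.sum(axis=0)


# ordered representative tip-state assignments; each pattern aggregates 12
# ordered (x, y) nucleotide pairs, all equal under JC69 symmetry
_PATTERN_STATES = {
    "abba": (0, 1, 1, 0),
    "baba": (1, 0, 1, 0),
    "bbaa": (1, 1, 0, 0),
}


def _integrate_history(
    hist: _History, bps, jump, p, coef_rows: np.ndarray
) -> np.ndarray:
    """Expectation over waiting times of the subset-expansion terms.

    coef_rows has shape (64, npat): pattern coefficients per edge subset.
    Returns per-pattern probabilities contributed by this history (without
    the x12 nucleotide-pair factor and without the gamma branch weight).
    """
    m = len(hist.vars)
    d_const = np.empty(6)
    d_coef = np.empty((6, m))
    for e, edge in enumerate(hist.edges):
        d_const[e], d_coef[e] = _edge_length_affine(edge, bps, jump, p, m)
    subs = np.arange(64)
    B = ((subs[:, None] >> np.arange(6)[None, :]) & 1).astype(float)
    K = (4.0 / 3.0) * (B @ d_const) + hist.dens_const
    V = (4.0 / 3.0) * (B @ d_coef)
    for j, v in enumerate(hist.vars):
        V[:, j] += v.dens_c
    C = coef_rows * hist.coef

    cols = list(range(m))
    for x in range(m - 1, -1, -1):
        jx = cols.index(x)
        c = V[:, jx]
        var = hist.vars[x]
        if not var.bounded:
            if np.any(c <= 0.0):
                raise RuntimeError("non-positive exponent on an unbounded epoch")
            C = C / c[:, None]
            V = np.delete(V, jx, axis=1)
            cols.pop(jx)
            continue
        if np.any(np.abs(c) < 1e-12):
            raise RuntimeError(
                "degenerate exponent in closed-form integration; perturb parameters"
            )
        earlier = [cols.index(e) for e in var.earlier_same_epoch]
        C1 = C / c[:, None]
        K2 = K + c * var.L
        V2 = V.copy()
        if earlier:
            V2[:, earlier] -= c[:, None]
        C = np.vstack([C1, -C1])
        V = np.vstack([V, V2])
        K = np.concatenate([K, K2])
        V = np.delete(V, jx, axis=1)
        cols.pop(jx)
    return (C * np.exp(-K)[:, None]).sum(axis=0)


def _branch_pattern_probs(p: MSciParams, jump: bool, patterns) -> np.ndarray:
    bps = (
        [0.0, p.tau_g, p.tau1, p.tau2, p.tau3, math.inf]
        if jump
        else [0.0, p.tau1, p.tau2, p.tau3, math.inf]
    )
    hists = _enumerate_histories(p, jump)
    total = np.zeros(len(patterns))
    cache: dict = {}
    for h in hists:
        edge_nodes = tuple((e[0], e[1]) for e in h.edges)
        key = edge_nodes
        if key not in cache:
            cache[key] = np.stack(
                [_subset_coefs(edge_nodes, _PATTERN_STATES[pt]) for pt in patterns],
                axis=1,
            )
        total += _integrate_history(h, bps, jump, p, cache[key])
    return total


def pattern_freqs(p: MSciParams) -> PatternFrequencies:
    """Exact per-site probabilities of ABBA, BABA and BBAA under the MSci+JC69
    model with lineage rate multipliers.

    Each probability sums the 12 ordered nucleotide assignments (x, y), x != y,
    realising the pattern; JC69 symmetry makes them all equal, so a single
    representative assignment is computed and multiplied by 12.
    """
    patterns = ("abba", "baba", "bbaa")
    probs = np.zeros(3)
    if p.gamma < 1.0:
        probs += (1.0 - p.gamma) * _branch_pattern_probs(p, False, patterns)
    if p.gamma > 0.0:
        probs += p.gamma * _branch_pattern_probs(p, True, patterns)
    probs *= 12.0
    return PatternFrequencies(*probs)


def expected_D(p: MSciParams) -> float:
    """Expected D = (P(ABBA) - P(BABA)) / (P(ABBA) + P(BABA))."""
    f = pattern_freqs(p)
    denom = f.p_abba + f.p_baba
    if denom <= 0.0:
        raise ValueError("P(ABBA) + P(BABA) is zero; D undefined")
    return (f.p_abba - f.p_baba) / denom


def tau_for_target_D(
    theta: float,
    lambda_p1: float,
    target_D: float,
    bracket: tuple[float, float] = (1e-4, 1e-2),
    tol: float = 1e-6,
) -> float:
    """Solve expected_D(tau) = target_D for tau under the depth
    parameterisation tau1 = tau, tau2 = 2 tau, tau3 = 3 tau (gamma = 0).

    Bracketed root-finding (Brent); raises if the bracket does not straddle
    the target or the target is the degenerate D = 0 at lambda = 1.
    """
    if target_D == 0.0 and lambda_p1 == 1.0:
        raise ValueError("target D = 0 with lambda = 1 holds for every tau")

    def f(tau: float) -> float:
        pp = MSciParams(
            tau1=tau, tau2=2 * tau, tau3=3 * tau, theta=theta, lambda_p1=lambda_p1
        )
        return expected_D(pp) - target_D

    fa, fb = f(bracket[0]), f(bracket[1])
    if fa * fb > 0.0:
        raise ValueError(f"no sign change in bracket {bracket}: f={fa:.3g},{fb:.3g}")
    return brentq(f, bracket[0], bracket[1], xtol=tol)


def limit_D(params_seq) -> float:
    """Evaluate expected_D along a parameter sequence approaching the extreme
    regime (tau1, tau2 -> 0 with lambda*tau1, tau3 -> inf and theta -> 0),
    where D -> 1.  Raises if D decreases by more than 1e-3 along the way;
    returns the final D."""
    ds = [expected_D(p) for p in params_seq]
    for a, b in zip(ds, ds[1:]):
        if b < a - 1e-3:
            raise ValueError(f"D sequence not monotone: {a} -> {b}")
    return ds[-1]


# internal cross-check helper (used by the test suite): total density of all
# enumerated histories must be 1 for any valid parameter set
def _total_density(p: MSciParams, jump: bool) -> float:
    bps = (
        [0.0, p.tau_g, p.tau1, p.tau2, p.tau3, math.inf]
        if jump
        else [0.0, p.tau1, p.tau2, p.tau3, math.inf]
    )
    ones = np.zeros((64, 1))
    ones[0, 0] = 1.0  # only the empty subset: integrates the bare density
    tot = 0.0
    for h in _enumerate_histories(p, jump):
        tot += _integrate_history(h, bps, jump, p, ones)[0]
    return tot
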