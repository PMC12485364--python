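"""Coalescent + JC69 genome simulator for the four-taxon MSci scenarios.

Simulates non-recombining loci (default 100 bp) that recombine freely with
one another: for each locus an independent gene tree is drawn under the
multispecies coalescent on (((P1,P2),P3),O) with an optional episodic
P1 -> P3 introgression pulse (backward in time, the P3 lineage jumps into the
P1 population at T_G with probability gamma), then JC69 sequences evolve
along the tree.  Lineage-specific substitution rates are applied by scaling
the mutation length of every gene-tree segment by the rate multiplier of the
population it resides in (direct mode), or equivalently -- for a single
rate-shifted tip and no introgression -- by the sampling-time-shift
construction of ``time_shift_transform``.

Gene-tree sampling is delegated to msprime (haploid samples, population
splits, mass-migration pulse); sequence evolution and site-pattern counting
are vectorised across loci in numpy.  "2N" is the number of haploid gene
copies: a pair of lineages coalesces at rate 1/(2N) per generation, so
theta = 2*(2N)*mu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import msprime
import numpy as np

from .patterns import BlockCounts

__all__ = [
    "ScenarioConfig",
    "SegmentedGeneTree",
    "TreeBatch",
    "SimulatedCounts",
    "sim_gene_tree",
    "sim_gene_trees",
    "scale_to_mutation_lengths",
    "time_shift_transform",
    "sim_locus_alignment",
    "sim_dataset",
]

_POP_ORDER = ("P1", "P2", "P3", "O")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation cell (scenario-grid semantics, generation units).

    T_S, T_I, T_O are the sister divergence time, internal branch length and
    outgroup stem length; two_N is the conventional "2N" (haploid gene copies);
    the lambdas are relative substitution rates of the P1/P3/O terminal
    populations; gamma and T_G parameterise the episodic P1 -> P3
    introgression pulse.  sample_times are non-zero only in scenarios built
    by ``time_shift_transform``.
    """

    T_S: float
    T_I: float
    T_O: float
    two_N: float
    lambda_p1: float = 1.0
    lambda_p3: float = 1.0
    lambda_o: float = 1.0
    gamma: float = 0.0
    T_G: float = 0.0
    genome_size_bp: int = 100_000_000
    locus_length_bp: int = 100
    mu: float = 2e-8
    n_replicates: int = 20
    seed: int | None = None
    sample_times: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("T_S", "T_I", "T_O", "two_N", "mu"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        if self.gamma > 0.0 and not (0.0 <= self.T_G < self.T_S):
            raise ValueError("require 0 <= T_G < T_S when gamma > 0")
        if self.genome_size_bp % self.locus_length_bp:
            raise ValueError("genome size must be divisible by the locus length")
        if any(t != 0.0 for t in self.sample_times) and (
            self.lambda_p1 != 1.0 or self.lambda_p3 != 1.0 or self.lambda_o != 1.0
        ):
            raise ValueError(
                "non-contemporaneous sampling is the uniform-rate representation; "
                "rate multipliers must be 1"
            )

    @property
    def n_loci(self) -> int:
        return self.genome_size_bp // self.locus_length_bp


@dataclass
class TreeBatch:
    """Vectorised gene trees: nodes 0..3 are the P1,P2,P3,O samples, 4..6 the
    coalescences in time order (6 = root).  ``migrant`` flags loci whose P3
    lineage took the introgression pulse."""

    time: np.ndarray  # (n, 7) generations
    parent: np.ndarray  # (n, 7) int, parent[...,6] == -1
    migrant: np.ndarray  # (n,) bool

    def __len__(self) -> int:
        return self.time.shape[0]


@dataclass
class SegmentedGeneTree:
    """A single gene tree with, for every non-root node, the list of
    (population, duration-in-generations) segments of its parent branch."""

    parent: np.ndarray
    time: np.ndarray
    segments: dict[int, list[tuple[str, float]]]
    migrant: bool = False


@dataclass
class SimulatedCounts:
    """Block-partitioned site-pattern counts from one simulated genome."""

    blocks: BlockCounts
    scenario: ScenarioConfig
    seed: int | None

    @property
    def n_abba(self) -> int:
        return int(self.blocks.counts[:, 0].sum())

    @property
    def n_baba(self) -> int:
        return int(self.blocks.counts[:, 1].sum())

    @property
    def n_bbaa(self) -> int:
        return int(self.blocks.counts[:, 2].sum())


# ---------------------------------------------------------------------------
# gene-tree sampling (msprime)
# ---------------------------------------------------------------------------


def _demography(sc: ScenarioConfig, pulse: bool) -> msprime.Demography:
    d = msprime.Demography()
    # ploidy-1 samples: a pair coalesces at rate 1/initial_size per generation
    d.add_population(name="P1", initial_size=sc.two_N * sc.lambda_p1)
    d.add_population(name="P2", initial_size=sc.two_N)
    d.add_population(name="P3", initial_size=sc.two_N)
    d.add_population(name="O", initial_size=sc.two_N)
    d.add_population(name="P12", initial_size=sc.two_N)
    d.add_population(name="P123", initial_size=sc.two_N)
    d.add_population(name="R", initial_size=sc.two_N)
    t1 = sc.T_S
    t2 = sc.T_S + sc.T_I
    t3 = sc.T_S + sc.T_I + sc.T_O
    if pulse:
        d.add_mass_migration(time=sc.T_G, source="P3", dest="P1", proportion=1.0)
    d.add_population_split(time=t1, derived=["P1", "P2"], ancestral="P12")
    d.add_population_split(time=t2, derived=["P12", "P3"], ancestral="P123")
    d.add_population_split(time=t3, derived=["P123", "O"], ancestral="R")
    d.sort_events()
    return d


def _sim_tree_arrays(sc: ScenarioConfig, n: int, pulse: bool, seed: int):
    if n == 0:
        return np.empty((0, 7)), np.empty((0, 7), dtype=np.int8)
    samples = [
        msprime.SampleSet(1, population=p, time=t, ploidy=1)
        for p, t in zip(_POP_ORDER, sc.sample_times)
    ]
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=_demography(sc, pulse),
        ploidy=1,
        num_replicates=n,
        random_seed=seed,
    )
    time = np.empty((n, 7))
    parent = np.empty((n, 7), dtype=np.int8)
    par = np.empty(7, dtype=np.int8)
    for i, ts in enumerate(reps):
        nt = ts.nodes_time
        if nt.shape[0] != 7:
            raise RuntimeError("unexpected gene-tree shape")
        time[i] = nt
        par[6] = -1
        par[ts.edges_child] = ts.edges_parent
        parent[i] = par
    return time, parent


def _sim_trees_msprime(
    sc: ScenarioConfig, n_loci: int, rng: np.random.Generator
) -> TreeBatch:
    migrant = (
        rng.random(n_loci) < sc.gamma
        if sc.gamma > 0.0
        else np.zeros(n_loci, dtype=bool)
    )
    n_mig = int(migrant.sum())
    seed_plain = int(rng.integers(1, 2**31))
    seed_mig = int(rng.integers(1, 2**31))
    t0, p0 = _sim_tree_arrays(sc, n_loci - n_mig, pulse=False, seed=seed_plain)
    t1, p1 = _sim_tree_arrays(sc, n_mig, pulse=True, seed=seed_mig)
    time = np.empty((n_loci, 7))
    parent = np.empty((n_loci, 7), dtype=np.int8)
    time[~migrant], parent[~migrant] = t0, p0
    time[migrant], parent[migrant] = t1, p1
    return TreeBatch(time=time, parent=parent, migrant=migrant)


# --- vectorised multispecies-coalescent sampler ----------------------------
#
# Only four lineages flow through four epochs (P1 during the pulse window,
# P12, P123, root), so the whole backward-in-time process vectorises over
# loci with small per-count groups.  Pair choices are uniform; a specific
# pair coalesces at rate 1/(2N) per generation (1/(lambda_p1*2N) inside P1).

_PAIR_TABLE = {
    k: np.array(
        [(i, j) for i in range(k) for j in range(i + 1, k)], dtype=np.intp
    )
    for k in (2, 3, 4)
}
_REMAIN_TABLE = {
    k: np.array(
        [
            [s for s in range(k) if s not in (i, j)]
            for i in range(k)
            for j in range(i + 1, k)
        ],
        dtype=np.intp,
    ).reshape(len(_PAIR_TABLE[k]), k - 2)
    for k in (2, 3, 4)
}


class _CoalState:
    def __init__(self, n: int, sample_times):
        self.time = np.zeros((n, 7))
        self.time[:, :4] = sample_times
        self.parent = np.full((n, 7), -1, dtype=np.int8)
        self.active = np.full((n, 4), -1, dtype=np.int8)
        self.count = np.zeros(n, dtype=np.int8)
        self.nmerge = np.zeros(n, dtype=np.int8)

    def add(self, idx, node: int) -> None:
        self.active[idx, self.count[idx]] = node
        self.count[idx] += 1

    def merge(self, idx, k: int, pair_choice, tmerge) -> None:
        pt = _PAIR_TABLE[k]
        a = self.active[idx, pt[pair_choice, 0]]
        b = self.active[idx, pt[pair_choice, 1]]
        nid = 4 + self.nmerge[idx]
        self.time[idx, nid] = tmerge
        self.parent[idx, a] = nid
        self.parent[idx, b] = nid
        rem = _REMAIN_TABLE[k][pair_choice]  # (len, k-2)
        kept = self.active[idx[:, None], rem]
        self.active[idx, : k - 2] = kept
        self.active[idx, k - 2] = nid
        self.active[idx, k - 1 :] = -1
        self.count[idx] = k - 1
        self.nmerge[idx] += 1

    def run_epoch(self, mask, t_start, t_end, scale, rng) -> None:
        """Coalesce lineages of ``mask`` loci within [t_start, t_end); a
        specific pair coalesces at rate 1/scale."""
        n = self.count.shape[0]
        ct = np.full(n, t_start)
        live = mask & (self.count >= 2)
        while np.any(live):
            for k in (4, 3, 2):
                idx = np.flatnonzero(live & (self.count == k))
                if idx.size == 0:
                    continue
                npair = k * (k - 1) // 2
                w = rng.exponential(scale / npair, size=idx.size)
                tm = ct[idx] + w
                ok = tm < t_end
                hit = idx[ok]
                if hit.size:
                    choice = rng.integers(0, npair, size=hit.size)
                    self.merge(hit, k, choice, tm[ok])
                    ct[hit] = tm[ok]
                live[idx[~ok]] = False
            live &= self.count >= 2


def _sim_trees_internal(
    sc: ScenarioConfig, n_loci: int, rng: np.random.Generator
) -> TreeBatch:
    t1 = sc.T_S
    t2 = sc.T_S + sc.T_I
    t3 = t2 + sc.T_O
    migrant = (
        rng.random(n_loci) < sc.gamma
        if sc.gamma > 0.0
        else np.zeros(n_loci, dtype=bool)
    )
    st = _CoalState(n_loci, sc.sample_times)

    # pulse window [T_G, T_S): p1 and the migrant p3 lineage inside P1
    mig_idx = np.flatnonzero(migrant)
    if mig_idx.size:
        w = rng.exponential(sc.lambda_p1 * sc.two_N, size=mig_idx.size)
        ok = w < t1 - sc.T_G
        hit = mig_idx[ok]
        if hit.size:
            st.active[hit, 0] = 0
            st.active[hit, 1] = 2
            st.count[hit] = 2
            st.merge(hit, 2, np.zeros(hit.size, dtype=np.intp), sc.T_G + w[ok])
    # assemble the P12 pool: survivors of the pulse window + p1/p2 (+ migrant p3)
    st.count[:] = 0
    no13 = migrant & (st.nmerge == 0)
    st.add(np.flatnonzero(~migrant | no13), 0)
    coal13 = np.flatnonzero(st.nmerge == 1)
    st.add(coal13, 4)
    st.add(np.flatnonzero(no13), 2)
    st.add(np.arange(n_loci), 1)
    st.run_epoch(np.ones(n_loci, dtype=bool), t1, t2, sc.two_N, rng)
    # P123: the non-migrant p3 lineage joins
    st.add(np.flatnonzero(~migrant), 2)
    st.run_epoch(np.ones(n_loci, dtype=bool), t2, t3, sc.two_N, rng)
    # root: the outgroup joins; everything coalesces
    st.add(np.arange(n_loci), 3)
    st.run_epoch(np.ones(n_loci, dtype=bool), t3, math.inf, sc.two_N, rng)
    if not np.all(st.count == 1):
        raise RuntimeError("incomplete coalescence")
    return TreeBatch(time=st.time, parent=st.parent, migrant=migrant)


def sim_gene_trees(
    sc: ScenarioConfig,
    n_loci: int,
    rng: np.random.Generator,
    backend: str = "internal",
) -> TreeBatch:
    """Draw ``n_loci`` independent gene trees under the scenario.

    The default backend is the vectorised internal sampler; ``"msprime"``
    runs the identical demography through msprime (used as an independent
    cross-check in the test suite).
    """
    if backend == "internal":
        return _sim_trees_internal(sc, n_loci, rng)
    if backend == "msprime":
        return _sim_trees_msprime(sc, n_loci, rng)
    raise ValueError(f"unknown backend {backend!r}")


# ---------------------------------------------------------------------------
# rate scaling: generation durations -> expected substitutions per site
# ---------------------------------------------------------------------------


def _clade_masks(parent: np.ndarray) -> np.ndarray:
    """Bitmask of descendant tips per node (bit t set iff tip t below)."""
    n = parent.shape[0]
    mask = np.zeros((n, 7), dtype=np.int8)
    mask[:, :4] = np.array([1, 2, 4, 8], dtype=np.int8)
    ar = np.arange(n)
    for u in range(6):  # children have smaller ids than parents
        mask[ar, parent[:, u]] |= mask[:, u]
    return mask


def _branch_mutation_lengths(batch: TreeBatch, sc: ScenarioConfig) -> np.ndarray:
    """Per-branch lengths in expected substitutions/site, shape (n, 7)
    (column 6, the root, is zero).  Every branch segment resident in a
    terminal population with rate multiplier lambda accrues lambda * mu per
    generation; ancestral populations have rate 1."""
    time, parent, migrant = batch.time, batch.parent, batch.migrant
    n = len(batch)
    ar = np.arange(n)
    tp = time[ar[:, None], np.clip(parent, 0, None)]
    dur = tp - time
    dur[:, 6] = 0.0
    adj = np.zeros_like(dur)
    t1 = sc.T_S
    t2 = sc.T_S + sc.T_I
    t3 = sc.T_S + sc.T_I + sc.T_O
    if sc.lambda_p1 != 1.0:
        d1 = sc.lambda_p1 - 1.0
        adj[:, 0] += d1 * (np.minimum(tp[:, 0], t1) - sc.sample_times[0])
        if migrant.any():
            adj[migrant, 2] += d1 * (np.minimum(tp[migrant, 2], t1) - sc.T_G)
            mask = _clade_masks(parent)
            for v in (4, 5):
                sel = migrant & (mask[:, v] == 5) & (time[:, v] < t1)
                adj[sel, v] += d1 * (t1 - time[sel, v])
    if sc.lambda_p3 != 1.0:
        d3 = sc.lambda_p3 - 1.0
        a3 = np.where(migrant, sc.T_G, np.minimum(tp[:, 2], t2))
        adj[:, 2] += d3 * (a3 - sc.sample_times[2])
    if sc.lambda_o != 1.0:
        adj[:, 3] += (sc.lambda_o - 1.0) * (t3 - sc.sample_times[3])
    return sc.mu * (dur + adj)


# population timelines for the segment representation -----------------------


def _timeline(clade: frozenset, migrant: bool, sc: ScenarioConfig):
    t1, t2 = sc.T_S, sc.T_S + sc.T_I
    t3 = t2 + sc.T_O
    inf = math.inf
    if clade == {0}:
        return [("P1", 0, t1), ("P12", t1, t2), ("P123", t2, t3), ("R", t3, inf)]
    if clade == {1}:
        return [("P2", 0, t1), ("P12", t1, t2), ("P123", t2, t3), ("R", t3, inf)]
    if clade == {2}:
        if migrant:
            return [
                ("P3", 0, sc.T_G),
                ("P1", sc.T_G, t1),
                ("P12", t1, t2),
                ("P123", t2, t3),
                ("R", t3, inf),
            ]
        return [("P3", 0, t2), ("P123", t2, t3), ("R", t3, inf)]
    if clade == {3}:
        return [("O", 0, t3), ("R", t3, inf)]
    if clade == {0, 1}:
        return [("P12", t1, t2), ("P123", t2, t3), ("R", t3, inf)]
    if clade == {0, 2} and migrant:
        return [
            ("P1", sc.T_G, t1),
            ("P12", t1, t2),
            ("P123", t2, t3),
            ("R", t3, inf),
        ]
    if clade <= {0, 1, 2} and migrant:
        # the migrant P3 lineage is already in the P12 ancestral stream
        return [("P12", t1, t2), ("P123", t2, t3), ("R", t3, inf)]
    if clade <= {0, 1, 2}:
        return [("P123", t2, t3), ("R", t3, inf)]
    return [("R", t3, inf)]


def _segments_for_tree(
    time: np.ndarray, parent: np.ndarray, migrant: bool, sc: ScenarioConfig
) -> dict[int, list[tuple[str, float]]]:
    mask = _clade_masks(parent[None, :])[0]
    segs: dict[int, list[tuple[str, float]]] = {}
    for v in range(6):
        clade = frozenset(t for t in range(4) if mask[v] & (1 << t))
        s, e = time[v], time[parent[v]]
        out = []
        for pop, a, b in _timeline(clade, migrant, sc):
            lo, hi = max(a, s), min(b, e)
            if hi > lo:
                out.append((pop, hi - lo))
        segs[v] = out
    return segs


def sim_gene_tree(sc: ScenarioConfig, rng: np.random.Generator) -> SegmentedGeneTree:
    """Sample a single gene tree with per-branch population segments."""
    batch = sim_gene_trees(sc, 1, rng)
    migrant = bool(batch.migrant[0])
    return SegmentedGeneTree(
        parent=batch.parent[0],
        time=batch.time[0],
        segments=_segments_for_tree(batch.time[0], batch.parent[0], migrant, sc),
        migrant=migrant,
    )


def scale_to_mutation_lengths(
    gt: SegmentedGeneTree, sc: ScenarioConfig
) -> dict[int, float]:
    """Branch lengths in expected substitutions/site: each segment of
    duration d in population pop contributes lambda_pop * d * mu."""
    mults = {
        "P1": sc.lambda_p1,
        "P3": sc.lambda_p3,
        "O": sc.lambda_o,
    }
    out = {}
    for v, segs in gt.segments.items():
        out[v] = sc.mu * sum(mults.get(pop, 1.0) * d for pop, d in segs)
    return out


# ---------------------------------------------------------------------------
# the sampling-time-shift construction
# ---------------------------------------------------------------------------


def time_shift_transform(sc: ScenarioConfig) -> ScenarioConfig:
    """Re-express a scenario with a single rate-shifted tip as a uniform-rate
    scenario with non-contemporaneous sampling.

    For an accelerated tip (lambda > 1) every divergence (and introgression)
    time moves into the past by (lambda - 1) * <tip branch duration>, the
    shifted tip is sampled at the present and all other tips at the shift;
    for a decelerated tip the divergence times stay put and the slow tip is
    sampled at (1 - lambda) * <tip branch duration> in the past.  Expected
    pattern frequencies match the rate-scaled scenario when gamma = 0.
    """
    lams = (sc.lambda_p1, sc.lambda_p3, sc.lambda_o)
    shifted = [i for i, l in enumerate(lams) if l != 1.0]
    if len(shifted) == 0:
        return replace(sc, lambda_p1=1.0, lambda_p3=1.0, lambda_o=1.0)
    if len(shifted) > 1:
        raise ValueError(
            "the time-shift construction supports exactly one rate-shifted tip"
        )
    which = shifted[0]
    lam = lams[which]
    tip = (0, 2, 3)[which]  # sample index of P1 / P3 / O
    dur = (sc.T_S, sc.T_S + sc.T_I, sc.T_S + sc.T_I + sc.T_O)[which]
    kwargs = dict(lambda_p1=1.0, lambda_p3=1.0, lambda_o=1.0)
    if lam > 1.0:
        shift = (lam - 1.0) * dur
        times = [shift] * 4
        times[tip] = 0.0
        kwargs.update(
            T_S=sc.T_S + shift,
            sample_times=tuple(times),
        )
        if sc.gamma > 0.0:
            kwargs.update(T_G=sc.T_G + shift)
    else:
        times = [0.0] * 4
        times[tip] = (1.0 - lam) * dur
        kwargs.update(sample_times=tuple(times))
    return replace(sc, **kwargs)


# ---------------------------------------------------------------------------
# JC69 sequence evolution and pattern counting (vectorised over loci)
# ---------------------------------------------------------------------------


def _children_arrays(parent: np.ndarray) -> np.ndarray:
    """children[l, v-4, 0:2] = the two children of internal node v."""
    n = parent.shape[0]
    ch = np.full((n, 3, 2), -1, dtype=np.int8)
    cnt = np.zeros((n, 3), dtype=np.int8)
    ar = np.arange(n)
    for u in range(6):
        p = parent[:, u].astype(np.intp) - 4
        ch[ar, p, cnt[ar, p]] = u
        cnt[ar, p] += 1
    return ch


def _sim_tip_states(
    mutlen: np.ndarray,
    parent: np.ndarray,
    rng: np.random.Generator,
    locus_length: int,
) -> np.ndarray:
    """Simulate JC69 site states for every locus; returns (n, 4, L) uint8
    codes 0..3 for A,C,G,T at the four tips."""
    n = mutlen.shape[0]
    L = locus_length
    ch = _children_arrays(parent)
    states = np.empty((n, 7, L), dtype=np.uint8)
    states[:, 6, :] = rng.integers(0, 4, size=(n, L), dtype=np.uint8)
    ar = np.arange(n)
    cols = np.arange(L)
    for v in (6, 5, 4):
        for s in (0, 1):
            c = ch[:, v - 4, s].astype(np.intp)
            d = mutlen[ar, c]
            p_same = 0.25 + 0.75 * np.exp(-4.0 * d / 3.0)
            stay = rng.random((n, L)) < p_same[:, None]
            shift = rng.integers(1, 4, size=(n, L), dtype=np.uint8)
            par_state = states[:, v, :]
            out = np.where(stay, par_state, (par_state + shift) & 3)
            states[ar[:, None], c[:, None], cols[None, :]] = out
    return states[:, :4, :]


def _pattern_probs_for_trees(mutlen: np.ndarray, parent: np.ndarray) -> np.ndarray:
    """Per-locus JC69 probabilities of (ABBA, BABA, BBAA) given each gene
    tree, by pruning vectorised over loci.  Conditional on the tree, sites
    are iid, so multinomial draws from these probabilities have exactly the
    same distribution as site-by-site simulation."""
    n = mutlen.shape[0]
    ch = _children_arrays(parent)
    ar = np.arange(n)
    z = np.exp(-4.0 / 3.0 * mutlen)  # (n, 7)
    out = np.empty((n, 3))
    for k, tips in enumerate(((0, 1, 1, 0), (1, 0, 1, 0), (1, 1, 0, 0))):
        part = np.zeros((n, 7, 4))
        for t in range(4):
            part[:, t, tips[t]] = 1.0
        for v in (4, 5, 6):
            acc = np.ones((n, 4))
            for s in (0, 1):
                c = ch[:, v - 4, s].astype(np.intp)
                L = part[ar, c]
                zc = z[ar, c][:, None]
                tot = L.sum(axis=1, keepdims=True)
                acc *= 0.25 * tot + zc * (L - 0.25 * tot)
            part[:, v, :] = acc
        # 12 ordered nucleotide pairs x uniform root prior 1/4
        out[:, k] = 3.0 * part[:, 6, :].sum(axis=1)
    return np.clip(out, 0.0, 1.0)


def _count_patterns_states(tips: np.ndarray) -> np.ndarray:
    """Per-locus (n, 3) counts of ABBA, BABA, BBAA from coded tip states."""
    s0, s1, s2, s3 = tips[:, 0], tips[:, 1], tips[:, 2], tips[:, 3]
    abba = (s0 == s3) & (s1 == s2) & (s0 != s1)
    baba = (s0 == s2) & (s1 == s3) & (s0 != s1)
    bbaa = (s0 == s1) & (s2 == s3) & (s0 != s2)
    return np.stack(
        [abba.sum(axis=1), baba.sum(axis=1), bbaa.sum(axis=1)], axis=1
    ).astype(np.int64)


def sim_locus_alignment(
    branch_lengths: dict[int, float] | np.ndarray,
    parent: np.ndarray,
    locus_length: int,
    rng: np.random.Generator,
) -> dict[str, str]:
    """JC69 sequences for one gene tree with branch lengths already in
    expected substitutions/site.  Returns {taxon: sequence}."""
    ml = np.zeros((1, 7))
    if isinstance(branch_lengths, dict):
        for v, d in branch_lengths.items():
            ml[0, v] = d
    else:
        ml[0, : len(branch_lengths)] = branch_lengths
    if np.any(ml < 0.0):
        raise ValueError("negative branch length")
    tips = _sim_tip_states(ml, np.asarray(parent, dtype=np.int8)[None, :], rng, locus_length)
    letters = np.frombuffer(b"ACGT", dtype="S1")
    return {
        name: letters[tips[0, i]].tobytes().decode()
        for i, name in enumerate(_POP_ORDER)
    }


_CHUNK_LOCI = 8192


def sim_dataset(
    sc: ScenarioConfig,
    rng: np.random.Generator | None = None,
    n_blocks: int = 100,
    emit_fasta: str | None = None,
    return_per_locus: bool = False,
    method: str = "per_site",
):
    """Simulate a genome of independent loci and count site patterns.

    With the default ``method="per_site"`` counts are taken directly from
    the simulated site states (the FASTA on ``emit_fasta`` is written from
    those same states, so the two paths agree site for site).
    ``method="multinomial"`` draws each locus's counts from the exact JC69
    pattern probabilities of its gene tree -- the same distribution without
    materialising sites, used for large replicate grids (no FASTA output).
    Loci are assembled into ``n_blocks`` contiguous blocks for jackknife
    resampling.
    """
    if method not in ("per_site", "multinomial"):
        raise ValueError(f"unknown method {method!r}")
    if method == "multinomial" and emit_fasta:
        raise ValueError("FASTA output requires the per-site method")
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    n_loci = sc.n_loci
    L = sc.locus_length_bp
    per_locus = np.empty((n_loci, 3), dtype=np.int64)
    fasta = open(emit_fasta, "wb") if emit_fasta else None
    letters = np.frombuffer(b"ACGT", dtype="S1")
    seq_chunks: list[np.ndarray] = []
    try:
        for lo in range(0, n_loci, _CHUNK_LOCI):
            hi = min(lo + _CHUNK_LOCI, n_loci)
            batch = sim_gene_trees(sc, hi - lo, rng)
            ml = _branch_mutation_lengths(batch, sc)
            if method == "multinomial":
                probs = _pattern_probs_for_trees(ml, batch.parent)
                pvals = np.empty((hi - lo, 4))
                pvals[:, :3] = probs
                pvals[:, 3] = 1.0 - probs.sum(axis=1)
                per_locus[lo:hi] = rng.multinomial(L, pvals)[:, :3]
                continue
            tips = _sim_tip_states(ml, batch.parent, rng, L)
            per_locus[lo:hi] = _count_patterns_states(tips)
            if fasta is not None:
                seq_chunks.append(letters[tips])
        if fasta is not None:
            seqs = np.concatenate(seq_chunks, axis=0)  # (n_loci, 4, L)
            for i, name in enumerate(_POP_ORDER):
                fasta.write(f">{name}\n".encode())
                row = seqs[:, i, :].reshape(-1)
                for s in range(0, row.size, 80):
                    fasta.write(row[s : s + 80].tobytes() + b"\n")
    finally:
        if fasta is not None:
            fasta.close()

    edges = np.linspace(0, n_loci, n_blocks + 1).astype(np.intp)
    counts = np.add.reduceat(per_locus, edges[:-1], axis=0)
    blocks = BlockCounts(
        counts=counts,
        starts=edges[:-1] * L,
        ends=edges[1:] * L,
        total_sites=n_loci * L,
    )
    out = SimulatedCounts(blocks=blocks, scenario=sc, seed=sc.seed)
    if return_per_locus:
        return out, per_locus
    return out
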