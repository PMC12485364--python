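"""Introgression tests on site-pattern counts: the D-statistic and the
HyDe-style comparison of the two least-frequent patterns, both with
block-jackknife standard errors, plus the relative rate test.

The D-statistic is D = (N_ABBA - N_BABA) / (N_ABBA + N_BABA); a significant
positive D is read as P2 <-> P3 introgression and a significant negative D
as P1 <-> P3.  The HyDe-style test ("HyDe_jk") asks whether the two least
frequent of the three parsimony-informative patterns occur at comparable
frequencies; if not, the two ingroup taxa sharing alleles in the smallest
pattern are called parents and the remaining ingroup taxon the hybrid.
Standard errors come from delete-one block jackknife over contiguous genome
blocks; significance from a two-sided normal test (the tail convention is
switchable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .patterns import PATTERNS, BlockCounts

__all__ = [
    "DTestResult",
    "HyDeResult",
    "RelRateResult",
    "d_statistic",
    "block_jackknife",
    "d_test",
    "hyde_jk_test",
    "jc69_distance",
    "relative_rate_test",
]


@dataclass(frozen=True)
class DTestResult:
    d: float
    se: float
    z: float
    p: float
    significant: bool
    inferred_pair: tuple[str, str] | None  # ("P2","P3") if D>0, ("P1","P3") if D<0


@dataclass(frozen=True)
class HyDeResult:
    statistic: float
    se: float
    z: float
    p: float
    significant: bool
    hybrid: str | None
    assignment: str | None  # "Pi-Pj-Pk" with Pj the hybrid
    smallest_patterns: tuple[str, str]
    tie_broken: bool


@dataclass(frozen=True)
class RelRateResult:
    branch_a: float
    branch_b: float
    rate_difference: float
    statistic: float
    p: float


def _as_block_array(blocks) -> np.ndarray:
    if isinstance(blocks, BlockCounts):
        return blocks.counts
    if hasattr(blocks, "blocks"):  # SimulatedCounts
        return blocks.blocks.counts
    arr = np.asarray(blocks, dtype=np.int64)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("blocks must be (n_blocks, 3) counts of ABBA/BABA/BBAA")
    return arr


def d_statistic(n_abba: float, n_baba: float) -> float:
    """(N_ABBA - N_BABA) / (N_ABBA + N_BABA)."""
    denom = n_abba + n_baba
    if denom <= 0:
        raise ValueError("N_ABBA + N_BABA is zero; D undefined")
    return (n_abba - n_baba) / denom


def block_jackknife(blocks, statistic) -> tuple[float, float]:
    """Delete-one-block jackknife estimate and standard error.

    ``statistic`` maps pooled (3,) pattern totals to a scalar.  The leave-one
    -out estimates theta_(i) are computed on the pooled counts of the
    remaining blocks; SE^2 = (B-1)/B * sum_i (theta_(i) - mean)^2.  Blocks on
    which the statistic is undefined are dropped (at least two usable
    leave-one-out subsets are required).
    """
    counts = _as_block_array(blocks)
    B = counts.shape[0]
    if B < 2:
        raise ValueError("need at least two blocks")
    totals = counts.sum(axis=0)
    est = statistic(totals)
    loo = totals[None, :] - counts
    vals = []
    for i in range(B):
        try:
            vals.append(statistic(loo[i]))
        except (ValueError, ZeroDivisionError, FloatingPointError):
            continue
    if len(vals) < 2:
        raise ValueError("fewer than two usable leave-one-out subsets")
    vals = np.asarray(vals, dtype=float)
    b = vals.size
    se = math.sqrt((b - 1) / b * np.sum((vals - vals.mean()) ** 2))
    return float(est), float(se)


def _normal_p(z: float, two_sided: bool) -> float:
    return 2.0 * norm.sf(abs(z)) if two_sided else norm.sf(z)


def d_test(blocks, alpha: float = 0.01, two_sided: bool = True) -> DTestResult:
    """Block-jackknife z-test of D = 0 (default two-sided, alpha = 0.01).

    When significant, the sign convention maps D > 0 to P2 <-> P3
    introgression and D < 0 to P1 <-> P3.
    """
    d, se = block_jackknife(blocks, lambda t: d_statistic(t[0], t[1]))
    if se == 0.0:
        z = 0.0 if d == 0.0 else math.copysign(math.inf, d)
        p = 1.0 if d == 0.0 else 0.0
    else:
        z = d / se
        p = _normal_p(z, two_sided)
    sig = bool(p < alpha)
    pair = None
    if sig and d != 0.0:
        pair = ("P2", "P3") if d > 0 else ("P1", "P3")
    return DTestResult(
        d=d, se=se, z=float(z), p=float(p), significant=sig, inferred_pair=pair
    )


# pattern index -> (parents, hybrid): the two taxa sharing the derived (or
# outgroup) allele in the pattern are the putative parents
_HYDE_MAP = {
    0: (("P2", "P3"), "P1"),  # smallest = ABBA
    1: (("P1", "P3"), "P2"),  # smallest = BABA
    2: (("P1", "P2"), "P3"),  # smallest = BBAA
}


def hyde_jk_test(blocks, alpha: float = 0.01, two_sided: bool = True) -> HyDeResult:
    """Jackknife equality test of the two least-frequent pattern totals.

    The statistic is the normalised difference (N_a - N_b)/(N_a + N_b) of the
    two smallest totals (identified once from the genome totals; ties broken
    in the fixed order BABA, ABBA, BBAA and flagged).  If the difference is
    significant, the ingroup pair sharing alleles in the smallest pattern are
    the parents and the remaining ingroup taxon is the hybrid.
    """
    counts = _as_block_array(blocks)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("all three pattern totals must be positive")
    tie_order = [1, 0, 2]  # BABA before ABBA before BBAA
    order = sorted(range(3), key=lambda i: (totals[i], tie_order.index(i)))
    i_small, i_mid = order[0], order[1]
    tie = bool(
        totals[order[0]] == totals[order[1]] or totals[order[1]] == totals[order[2]]
    )

    def stat(t):
        denom = t[i_small] + t[i_mid]
        if denom <= 0:
            raise ValueError("undefined")
        return (t[i_mid] - t[i_small]) / denom

    est, se = block_jackknife(counts, stat)
    if se == 0.0:
        z = 0.0 if est == 0.0 else math.copysign(math.inf, est)
        p = 1.0 if est == 0.0 else 0.0
    else:
        z = est / se
        p = _normal_p(z, two_sided)
    sig = bool(p < alpha)
    hybrid = assignment = None
    if sig:
        parents, hybrid = _HYDE_MAP[i_small]
        assignment = f"{parents[0]}-{hybrid}-{parents[1]}"
    return HyDeResult(
        statistic=est,
        se=se,
        z=float(z),
        p=float(p),
        significant=sig,
        hybrid=hybrid,
        assignment=assignment,
        smallest_patterns=(PATTERNS[i_small], PATTERNS[i_mid]),
        tie_broken=tie,
    )


# ---------------------------------------------------------------------------
# relative rate test
# ---------------------------------------------------------------------------


def _to_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    return np.asarray(seq, dtype=np.uint8)


def jc69_distance(seq_a, seq_b) -> float:
    """JC69-corrected distance -(3/4) ln(1 - 4 p/3) from the mismatch
    proportion p of two aligned sequences."""
    a, b = _to_codes(seq_a), _to_codes(seq_b)
    if a.size != b.size:
        raise ValueError("sequences must be aligned (equal length)")
    if a.size == 0:
        raise ValueError("empty alignment")
    p = float(np.mean(a != b))
    if p >= 0.75:
        raise ValueError(f"saturated: mismatch proportion {p:.3f} >= 3/4")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def relative_rate_test(seq1, seq2, outgroup) -> RelRateResult:
    """Relative rate test of two ingroup sequences against an outgroup.

    Tip branch lengths come from the JC69-corrected distance triplet:
    a = (d12 + d1O - d2O)/2, b = (d12 + d2O - d1O)/2; the reported rate
    difference is |a - b| / max(a, b) (negative length estimates are clamped
    to zero).  The clock statistic is (d1O - d2O)/SE with a delta-method SE
    using the empirical per-site covariance of the two mismatch indicators
    (they share the outgroup path), and an approximate two-sided normal p.
    """
    s1, s2, so = _to_codes(seq1), _to_codes(seq2), _to_codes(outgroup)
    if not (s1.size == s2.size == so.size):
        raise ValueError("sequences must be aligned (equal length)")
    n = s1.size
    d12 = jc69_distance(s1, s2)
    d1o = jc69_distance(s1, so)
    d2o = jc69_distance(s2, so)
    a = (d12 + d1o - d2o) / 2.0
    b = (d12 + d2o - d1o) / 2.0
    a, b = max(a, 0.0), max(b, 0.0)
    m = max(a, b)
    rate_diff = 0.0 if m == 0.0 else abs(a - b) / m

    x = (s1 != so).astype(float)
    y = (s2 != so).astype(float)
    p1, p2 = x.mean(), y.mean()
    g1 = 1.0 / (1.0 - 4.0 * p1 / 3.0)  # d'(p) of the JC69 correction
    g2 = 1.0 / (1.0 - 4.0 * p2 / 3.0)
    v1 = p1 * (1.0 - p1) / n
    v2 = p2 * (1.0 - p2) / n
    c12 = (np.mean(x * y) - p1 * p2) / n
    var = g1 * g1 * v1 + g2 * g2 * v2 - 2.0 * g1 * g2 * c12
    if var <= 0.0:
        stat = 0.0 if d1o == d2o else math.copysign(math.inf, d1o - d2o)
        p = 1.0 if d1o == d2o else 0.0
    else:
        stat = (d1o - d2o) / math.sqrt(var)
        p = 2.0 * norm.sf(abs(stat))
    return RelRateResult(
        branch_a=float(a),
        branch_b=float(b),
        rate_difference=float(rate_diff),
        statistic=float(stat),
        p=float(p),
    )
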