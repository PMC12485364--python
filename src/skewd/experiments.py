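"""Scenario-grid orchestration: run simulation cells, apply both tests, and
summarise false-positive rates and power.

A "cell" is one parameter combination of the eight simulation scenarios
(phylogenetic depth, population size, rate multipliers, genome size,
introgression settings); each cell is replicated with independent seeds.
False positives are significant calls of an event that was not simulated;
power is the significant detection of the simulated P1 <-> P3 event (for the
hybrid test, a correct call names the recipient P3 as the hybrid).  TSV
tables are the canonical output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from . import theory
from .dstat import d_test, hyde_jk_test
from .simulate import ScenarioConfig, sim_dataset

__all__ = [
    "ReplicateRecord",
    "SummaryRow",
    "theory_expected_d",
    "run_scenario",
    "summarize",
    "expand_scenario_grid",
    "scenario_grid",
]


@dataclass(frozen=True)
class ReplicateRecord:
    scenario_id: str
    replicate: int
    seed: int
    n_abba: int
    n_baba: int
    n_bbaa: int
    d: float | None = None
    se: float | None = None
    z: float | None = None
    p: float | None = None
    d_pair: str | None = None  # "P2-P3" / "P1-P3" when significant
    hyde_stat: float | None = None
    hyde_p: float | None = None
    hyde_hybrid: str | None = None
    error: str | None = None


@dataclass(frozen=True)
class SummaryRow:
    scenario_id: str
    T_S: float
    T_I: float
    T_O: float
    two_N: float
    lambda_p1: float
    lambda_p3: float
    lambda_o: float
    gamma: float
    genome_size_bp: int
    n_replicates: int
    mean_d: float
    min_d: float
    max_d: float
    theory_d: float
    d_fp: float
    d_power: float
    hyde_fp: float
    hyde_power: float


def theory_expected_d(sc: ScenarioConfig) -> float:
    """Analytic expected D for a simulation cell."""
    gp = theory.GenerationParams(
        T_S=sc.T_S, T_I=sc.T_I, T_O=sc.T_O, two_N=sc.two_N, mu=sc.mu, T_G=sc.T_G
    )
    p = theory.to_mutation_units(
        gp, (sc.lambda_p1, sc.lambda_p3, sc.lambda_o), gamma=sc.gamma
    )
    return theory.expected_D(p)


def run_scenario(
    sc: ScenarioConfig,
    scenario_id: str = "cell",
    n_blocks: int = 100,
    alpha: float = 0.01,
    method: str = "per_site",
) -> list[ReplicateRecord]:
    """Simulate ``sc.n_replicates`` independent genomes and apply the D and
    HyDe_jk tests to each.  Fully determined by ``sc.seed`` (per-replicate
    generators are spawned from it); per-replicate failures are recorded in
    the ``error`` field rather than aborting the batch."""
    ss = np.random.SeedSequence(sc.seed)
    out = []
    for rep, child in enumerate(ss.spawn(sc.n_replicates)):
        seed = int(child.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
        rng = np.random.default_rng(seed)
        counts = sim_dataset(sc, rng=rng, n_blocks=n_blocks, method=method)
        base = dict(
            scenario_id=scenario_id,
            replicate=rep,
            seed=seed,
            n_abba=counts.n_abba,
            n_baba=counts.n_baba,
            n_bbaa=counts.n_bbaa,
        )
        try:
            dres = d_test(counts.blocks, alpha=alpha)
            hres = hyde_jk_test(counts.blocks, alpha=alpha)
            out.append(
                ReplicateRecord(
                    **base,
                    d=dres.d,
                    se=dres.se,
                    z=dres.z,
                    p=dres.p,
                    d_pair="-".join(dres.inferred_pair) if dres.inferred_pair else None,
                    hyde_stat=hres.statistic,
                    hyde_p=hres.p,
                    hyde_hybrid=hres.hybrid,
                )
            )
        except ValueError as e:  # degenerate counts (e.g. a zero pattern total)
            out.append(ReplicateRecord(**base, error=str(e)))
    return out


def summarize(
    records: list[ReplicateRecord],
    sc: ScenarioConfig,
    truth: tuple[str, str] | None = None,
    scenario_id: str | None = None,
) -> SummaryRow:
    """Aggregate one cell's replicates into FP/power rates and D summaries.

    ``truth`` is the simulated introgression pair (None when gamma = 0).  A
    significant D call counts as power when its inferred pair equals the
    truth and as a false positive otherwise; a significant hybrid call
    counts as power only when it names the recipient taxon (P3 for the
    P1 -> P3 pulse simulated here).
    """
    if not records:
        raise ValueError("empty record set")
    ok = [r for r in records if r.error is None]
    if not ok:
        raise ValueError("no usable replicates")
    ds = np.array([r.d for r in ok])
    truth_pair = "-".join(truth) if truth else None
    truth_hybrid = "P3" if truth == ("P1", "P3") else None
    n = len(ok)
    d_sig = [r for r in ok if r.d_pair is not None]
    h_sig = [r for r in ok if r.hyde_hybrid is not None]
    return SummaryRow(
        scenario_id=scenario_id or records[0].scenario_id,
        T_S=sc.T_S,
        T_I=sc.T_I,
        T_O=sc.T_O,
        two_N=sc.two_N,
        lambda_p1=sc.lambda_p1,
        lambda_p3=sc.lambda_p3,
        lambda_o=sc.lambda_o,
        gamma=sc.gamma,
        genome_size_bp=sc.genome_size_bp,
        n_replicates=n,
        mean_d=float(ds.mean()),
        min_d=float(ds.min()),
        max_d=float(ds.max()),
        theory_d=theory_expected_d(sc),
        d_fp=sum(r.d_pair != truth_pair for r in d_sig) / n,
        d_power=sum(r.d_pair == truth_pair for r in d_sig) / n if truth else 0.0,
        hyde_fp=sum(r.hyde_hybrid != truth_hybrid for r in h_sig) / n,
        hyde_power=(
            sum(r.hyde_hybrid == truth_hybrid for r in h_sig) / n if truth else 0.0
        ),
    )


# ---------------------------------------------------------------------------
# the eight-scenario simulation grid
# ---------------------------------------------------------------------------

_T_GRID = (1e4, 5e4, 1e5, 5e5, 1e6)
_N_GRID = (1e4, 1e5, 1e6)
_LAM_GRID = (0.2, 0.5, 0.67, 0.83, 1.0, 1.2, 1.5, 2.0, 5.0)


def expand_scenario_grid(
    scenario_ids=(1, 2, 3, 4, 5, 6, 7, 8),
    genome_size_bp: int = 10_000_000,
    n_replicates: int = 20,
    seed: int = 0,
    subset: dict | None = None,
) -> list[tuple[str, ScenarioConfig]]:
    """Expand the scenario rows into (cell_id, ScenarioConfig) pairs.

    The default desk profile uses a 10 Mb genome and 20 replicates; the
    full-scale grid uses 100 Mb (500 Mb / 1 Gb in the genome-size scenario).
    ``subset`` optionally restricts grid values, e.g. {"T": (1e5,),
    "lambda_p1": (1.5,)}.
    """
    sub = subset or {}

    def grid(name, default):
        return sub.get(name, default)

    cells: list[tuple[str, ScenarioConfig]] = []

    def add(sid, label, **kw):
        kw.setdefault("genome_size_bp", genome_size_bp)
        sc = ScenarioConfig(n_replicates=n_replicates, seed=None, **kw)
        cells.append((f"S{sid}:{label}", sc))

    for sid in scenario_ids:
        if sid in (1, 8):
            gamma = 0.05 if sid == 8 else 0.0
            for T in grid("T", _T_GRID):
                for N2 in grid("two_N", _N_GRID):
                    for lam in grid("lambda_p1", _LAM_GRID):
                        add(
                            sid,
                            f"T={T:g},2N={N2:g},lP1={lam:g}",
                            T_S=T,
                            T_I=T,
                            T_O=T,
                            two_N=N2,
                            lambda_p1=lam,
                            gamma=gamma,
                            T_G=0.95 * T if sid == 8 else 0.0,
                        )
        elif sid == 2:
            for T in grid("T", _T_GRID):
                add(sid, f"TS={T:g}", T_S=T, T_I=1e5, T_O=1e5, two_N=1e4, lambda_p1=1.5)
        elif sid == 3:
            for T in grid("T", _T_GRID):
                add(sid, f"TI={T:g}", T_S=1e5, T_I=T, T_O=1e5, two_N=1e4, lambda_p1=1.5)
        elif sid == 4:
            for T in grid("T", _T_GRID):
                add(sid, f"TO={T:g}", T_S=1e5, T_I=1e5, T_O=T, two_N=1e4, lambda_p1=1.5)
        elif sid == 5:
            for l1 in grid("lambda_p1", (1.0, 1.5)):
                for l3 in grid("lambda_p3", (0.5, 0.67, 1.0, 1.5, 2.0)):
                    add(
                        sid,
                        f"lP1={l1:g},lP3={l3:g}",
                        T_S=1e5,
                        T_I=1e5,
                        T_O=1e5,
                        two_N=1e4,
                        lambda_p1=l1,
                        lambda_p3=l3,
                    )
        elif sid == 6:
            for l1 in grid("lambda_p1", (1.0, 1.5)):
                for lo in grid("lambda_o", (0.5, 0.67, 1.0, 1.5, 2.0)):
                    add(
                        sid,
                        f"lP1={l1:g},lO={lo:g}",
                        T_S=1e5,
                        T_I=1e5,
                        T_O=1e5,
                        two_N=1e4,
                        lambda_p1=l1,
                        lambda_o=lo,
                    )
        elif sid == 7:
            for l1 in grid("lambda_p1", (1.2, 1.5)):
                for gs in grid("genome_size_bp", (genome_size_bp,)):
                    add(
                        sid,
                        f"lP1={l1:g},GS={gs}",
                        T_S=1e5,
                        T_I=1e5,
                        T_O=1e5,
                        two_N=1e4,
                        lambda_p1=l1,
                        genome_size_bp=gs,
                    )
        else:
            raise ValueError(f"unknown scenario id {sid}")

    # deterministic per-cell seeds derived from the master seed
    ss = np.random.SeedSequence(seed)
    out = []
    for (label, sc), child in zip(cells, ss.spawn(len(cells))):
        out.append(
            (label, replace(sc, seed=int(child.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)))
        )
    return out


def scenario_grid(
    scenario_ids=(1,),
    genome_size_bp: int = 10_000_000,
    n_replicates: int = 20,
    seed: int = 0,
    subset: dict | None = None,
    n_blocks: int = 100,
    alpha: float = 0.01,
):
    """Run a (subset of the) scenario grid and summarise each cell.

    Returns (replicates DataFrame, summary DataFrame).
    """
    cells = expand_scenario_grid(scenario_ids, genome_size_bp, n_replicates, seed, subset)
    reps_rows, summary_rows = [], []
    for label, sc in cells:
        recs = run_scenario(sc, scenario_id=label, n_blocks=n_blocks, alpha=alpha)
        truth = ("P1", "P3") if sc.gamma > 0 else None
        summary_rows.append(asdict(summarize(recs, sc, truth=truth)))
        reps_rows.extend(asdict(r) for r in recs)
    return pd.DataFrame(reps_rows), pd.DataFrame(summary_rows)
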