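"""Multi-run benchmarking harness with nonparametric comparisons.

Runs each algorithm independently ``runs`` times (per-run seed =
master seed + run index), persists a trace CSV, a best-sequence FASTA and a
summary JSON per run, and aggregates a comparison table (mean/std fitness,
runtime, GC%, Tm, total stacking energy, max homopolymer, RC similarity,
minimum Hamming distance).  Algorithm differences are assessed with the
Friedman test on the per-run fitness matrix plus pairwise Wilcoxon
signed-rank tests (optionally Holm-adjusted).

Runtime is measured and reported but is hardware-dependent and carries no
accept/reject meaning.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import DEFAULT_PARAMS, BaselineConfig, run_baseline
from .codec import NucleotideSequence, benchmark_sequence, write_fasta
from .fitness import ConstraintConfig, FitnessWeights, ThermoTable, dg_sum, load_default_thermo, max_homopolymer
from .optimizer import TCHURConfig, optimize

__all__ = ["ExperimentConfig", "run_experiment", "compare_algorithms"]

log = logging.getLogger("tchur")

ALGORITHMS = ("tchur", "hgs", "run", "pso", "gwo")


@dataclass(frozen=True)
class ExperimentConfig:
    algorithms: tuple[str, ...] = ALGORITHMS
    runs: int = 30
    length: int = 1853
    payload_seed: int = 1
    master_seed: int = 0
    N: int = 50
    Tmax: int = 100
    weights: FitnessWeights = FitnessWeights()
    outdir: str | Path = "results"
    use_payload_archive: bool = True

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if not self.algorithms:
            raise ValueError("need at least one algorithm")
        unknown = set(a.lower() for a in self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms {sorted(unknown)}")


def _constraints_for(payload: NucleotideSequence, use_archive: bool) -> ConstraintConfig:
    if not use_archive:
        return ConstraintConfig()
    # one seeded reference; random-pair expectation of Hamming distance is 0.75 L
    return ConstraintConfig(archive=(payload,), d_min=math.ceil(0.75 * len(payload)))


def _run_one(
    algo: str,
    payload: NucleotideSequence,
    weights: FitnessWeights,
    constraints: ConstraintConfig,
    thermo: ThermoTable,
    N: int,
    Tmax: int,
    seed: int,
):
    if algo == "tchur":
        cfg = TCHURConfig(N=N, Tmax=Tmax, seed=seed)
        return optimize(payload, weights, constraints, cfg, thermo)
    cfg = BaselineConfig(algorithm=algo.upper(), N=N, Tmax=Tmax, seed=seed)
    return run_baseline(cfg, payload, weights, constraints, thermo)


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Execute the full experiment grid and return the comparison table."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thermo = load_default_thermo()
    payload = benchmark_sequence(cfg.length, cfg.payload_seed)
    constraints = _constraints_for(payload, cfg.use_payload_archive)

    rows = []
    fitness_matrix: dict[str, list[float]] = {}
    curves: dict[str, np.ndarray] = {}
    for algo in (a.lower() for a in cfg.algorithms):
        per_run = []
        traces = []
        for r in range(cfg.runs):
            seed = cfg.master_seed + r
            t0 = time.perf_counter()
            try:
                seq, brk, trace = _run_one(
                    algo, payload, cfg.weights, constraints, thermo, cfg.N, cfg.Tmax, seed
                )
            except Exception:
                log.warning("run failed: algo=%s run=%d seed=%d", algo, r, seed, exc_info=True)
                continue
            elapsed = time.perf_counter() - t0
            stem = outdir / f"{algo}_run{r:03d}"
            trace.to_dataframe().to_csv(f"{stem}_trace.csv", index=False)
            write_fasta([(f"{algo}_run{r}", seq)], f"{stem}_best.fasta")
            summary = {
                **brk.to_dict(),
                "algorithm": algo,
                "run": r,
                "seed": seed,
                "runtime_s": elapsed,
                "max_hp": max_homopolymer(seq),
                "dg_sum_kcal_mol": dg_sum(seq, thermo),
            }
            with open(f"{stem}_summary.json", "w") as fh:
                json.dump(summary, fh, indent=2)
            per_run.append(summary)
            traces.append(trace.best_fitness)
        if not per_run:
            log.warning("all runs failed for %s; excluded from the table", algo)
            continue
        fitness_matrix[algo] = [s["total"] for s in per_run]
        curves[algo] = np.stack(traces)
        rows.append(
            {
                "algorithm": algo,
                "mean_fitness": float(np.mean(fitness_matrix[algo])),
                "std_fitness": float(np.std(fitness_matrix[algo], ddof=1)) if len(per_run) > 1 else 0.0,
                "mean_runtime_s": float(np.mean([s["runtime_s"] for s in per_run])),
                "gc_percent": float(np.mean([s["gc_percent"] for s in per_run])),
                "tm_c": float(np.mean([s["tm"] for s in per_run])),
                "dg_sum_kcal_mol": float(np.mean([s["dg_sum_kcal_mol"] for s in per_run])),
                "max_hp": float(np.mean([s["max_hp"] for s in per_run])),
                "rc_percent": float(np.mean([100.0 * s["rc_ratio"] for s in per_run])),
                "min_hamming": float(np.mean([s["min_hamming"] for s in per_run if s["min_hamming"] is not None]))
                if any(s["min_hamming"] is not None for s in per_run) else None,
                "n_runs": len(per_run),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "comparison_table.csv", index=False)
    conv = pd.concat(
        [
            pd.DataFrame(
                {
                    "algorithm": algo,
                    "iteration": np.arange(c.shape[1]),
                    "mean_best_fitness": c.mean(axis=0),
                    "sd_best_fitness": c.std(axis=0, ddof=1) if c.shape[0] > 1 else 0.0,
                }
            )
            for algo, c in curves.items()
        ],
        ignore_index=True,
    )
    conv.to_csv(outdir / "convergence_curves.csv", index=False)
    if len(fitness_matrix) >= 2 and cfg.runs >= 6:
        report = compare_algorithms(pd.DataFrame(fitness_matrix))
        with open(outdir / "stat_tests.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return table


def compare_algorithms(results: pd.DataFrame, holm: bool = False) -> dict:
    """Friedman test plus pairwise Wilcoxon signed-rank p-values.

    ``results`` holds one column per algorithm, one row per run; all columns
    must have equal length.  No multiple-testing correction is applied
    unless ``holm=True``.
    """
    if results.shape[1] < 2:
        raise ValueError("need at least two algorithms to compare")
    if results.isna().any().any():
        raise ValueError("unequal run counts across algorithms")
    cols = list(results.columns)
    arrays = [results[c].to_numpy() for c in cols]
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        friedman = {"statistic": 0.0, "pvalue": 1.0}
    elif len(cols) >= 3:
        st = stats.friedmanchisquare(*arrays)
        friedman = {"statistic": float(st.statistic), "pvalue": float(st.pvalue)}
    else:
        # two algorithms: the classical rank chi-square directly (scipy needs k >= 3)
        mat = np.column_stack(arrays)
        n, k = mat.shape
        ranks = stats.rankdata(mat, axis=1)
        rj = ranks.sum(axis=0)
        chi2 = 12.0 / (n * k * (k + 1)) * float((rj**2).sum()) - 3.0 * n * (k + 1)
        friedman = {"statistic": chi2, "pvalue": float(stats.chi2.sf(chi2, k - 1))}
    pairwise = {}
    for a, b in combinations(cols, 2):
        diff = results[a] - results[b]
        if np.all(diff == 0):
            pairwise[f"{a}_vs_{b}"] = 1.0
        else:
            pairwise[f"{a}_vs_{b}"] = float(stats.wilcoxon(results[a], results[b]).pvalue)
    if holm:
        keys = sorted(pairwise, key=pairwise.get)
        m = len(keys)
        adj = {}
        running = 0.0
        for rank, k in enumerate(keys):
            running = max(running, min(1.0, (m - rank) * pairwise[k]))
            adj[k] = running
        pairwise = adj
    return {"friedman": friedman, "wilcoxon_pairwise": pairwise, "holm_adjusted": holm}
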