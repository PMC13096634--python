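"""Benchmark functions, the five-run repetition protocol and report emission.

The repetition protocol runs the full pipeline once per seed and reports each
metric as mean ± sample standard deviation (n-1 denominator).  Pairwise
comparisons between optimizer arms use a paired t-test on runs paired by
shared seed, with a 95% t-based confidence interval on the mean difference;
no multiple-testing correction is applied (raw p-values are reported, noted
in the report footnote).

``benchmark_suite`` provides classic test functions (sphere, Rosenbrock,
Rastrigin) with known optima for validating the optimizer stack independently
of any CNN training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .space import SearchBounds

__all__ = [
    "BenchmarkFunction",
    "benchmark_suite",
    "RunReport",
    "PairwiseTestResult",
    "repeated_runs",
    "pairwise_test",
    "emit_report",
]

METRIC_COLUMNS = ("accuracy", "precision", "recall", "f1", "objective")


@dataclass(frozen=True)
class BenchmarkFunction:
    """A test function with documented optimum, for optimizer validation."""

    name: str
    dimension: int
    evaluator: Callable[[np.ndarray], float]
    known_optimum_location: np.ndarray
    known_optimum_value: float
    bounds: SearchBounds

    def __call__(self, x: np.ndarray) -> float:
        return float(self.evaluator(np.asarray(x, dtype=float)))


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(x * x))


def _rosenbrock(x: np.ndarray) -> float:
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def _rastrigin(x: np.ndarray) -> float:
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


def benchmark_suite(dimension: int = 5) -> list[BenchmarkFunction]:
    """Sphere, Rosenbrock and Rastrigin in the requested dimension."""
    if dimension < 1:
        raise ValueError("dimension must be >= 1")
    d = dimension
    box = lambda lo, hi: SearchBounds(np.full(d, lo), np.full(d, hi))
    return [
        BenchmarkFunction("sphere", d, _sphere, np.zeros(d), 0.0, box(-5.12, 5.12)),
        BenchmarkFunction("rosenbrock", d, _rosenbrock, np.ones(d), 0.0, box(-2.048, 2.048)),
        BenchmarkFunction("rastrigin", d, _rastrigin, np.zeros(d), 0.0, box(-5.12, 5.12)),
    ]


@dataclass
class RunReport:
    """Per-seed metrics for one optimizer arm, with mean and sample SD."""

    optimizer_name: str
    per_run_metrics: pd.DataFrame      # columns: seed + metric columns
    failed_seeds: list = field(default_factory=list)

    @property
    def means(self) -> pd.Series:
        return self.per_run_metrics.drop(columns=["seed"]).mean()

    @property
    def sds(self) -> pd.Series:
        return self.per_run_metrics.drop(columns=["seed"]).std(ddof=1)

    def metric(self, name: str) -> np.ndarray:
        return self.per_run_metrics[name].to_numpy()


@dataclass(frozen=True)
class PairwiseTestResult:
    metric_name: str
    comparison_label: str
    mean_difference: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean_difference <= self.ci_high):
            raise ValueError("confidence interval must bracket the mean difference")


def repeated_runs(pipeline: Callable[[int], dict], seed_list: Sequence[int],
                  optimizer_name: str = "optimizer") -> RunReport:
    """Run ``pipeline(seed)`` once per seed; failed seeds are excluded with a warning.

    ``pipeline`` returns a metric mapping (e.g. accuracy/precision/recall/f1/
    objective).  The default protocol uses five seeds.
    """
    rows, failed = [], []
    for seed in seed_list:
        try:
            metrics = pipeline(int(seed))
        except Exception as exc:
            warnings.warn(f"run with seed {seed} failed and is excluded: {exc}")
            failed.append(int(seed))
            continue
        rows.append({"seed": int(seed), **{k: float(v) for k, v in metrics.items()}})
    if not rows:
        raise RuntimeError("every run failed; no metrics to report")
    return RunReport(optimizer_name, pd.DataFrame(rows), failed)


def pairwise_test(a: Sequence[float], b: Sequence[float], paired: bool = True,
                  metric_name: str = "metric", comparison_label: str = "a vs. b",
                  confidence: float = 0.95) -> PairwiseTestResult:
    """Two-sided t-test of mean(a) - mean(b) with a t-based confidence interval.

    In paired mode the runs must be paired by shared seed (equal lengths); the
    degenerate zero-variance case (e.g. identical vectors) is reported as
    p = 1.0 for a zero mean difference (CI of zero width at the difference),
    and p = 0.0 for a nonzero constant difference.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and a.shape != b.shape:
        raise ValueError("paired test requires equal-length samples")
    if min(a.size, b.size) < 2:
        raise ValueError("need at least two observations per sample")
    mean_diff = float(a.mean() - b.mean())
    if paired:
        d = a - b
        sd = d.std(ddof=1)
        if sd == 0.0:
            return PairwiseTestResult(metric_name, comparison_label, mean_diff,
                                      mean_diff, mean_diff,
                                      1.0 if mean_diff == 0.0 else 0.0)
        res = stats.ttest_rel(a, b)
        se = sd / np.sqrt(d.size)
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, d.size - 1)
    else:
        if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
            return PairwiseTestResult(metric_name, comparison_label, mean_diff,
                                      mean_diff, mean_diff,
                                      1.0 if mean_diff == 0.0 else 0.0)
        res = stats.ttest_ind(a, b)
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        dof = a.size + b.size - 2
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, dof)
    return PairwiseTestResult(metric_name, comparison_label, mean_diff,
                              mean_diff - float(tcrit * se), mean_diff + float(tcrit * se),
                              float(res.pvalue))


def _format_mean_sd(mean: float, sd: float) -> str:
    return f"{mean:.4f} ± {sd:.4f}"


def emit_report(
    reports: Sequence[RunReport],
    out_dir,
    pairwise: Sequence[PairwiseTestResult] | None = None,
    ablation: dict | None = None,
    histories: dict | None = None,
    confusions: dict | None = None,
    eval_counts: dict | None = None,
    make_plots: bool = True,
) -> dict[str, Path]:
    """Write the CSV tables (and optional plots) for a benchmark campaign.

    Emitted files: point metrics per run, mean ± SD summary, pairwise-test
    table, optional ablation/evaluation-cost tables, per-optimizer convergence
    curves and confusion matrices.  Output is deterministic: re-emitting the
    same results is byte-identical.
    """
    if not reports:
        raise ValueError("at least one RunReport is required")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    point = pd.concat(
        [r.per_run_metrics.assign(optimizer=r.optimizer_name) for r in reports],
        ignore_index=True,
    )
    written["point_metrics"] = out / "point_metrics.csv"
    point.to_csv(written["point_metrics"], index=False)

    rows = []
    for r in reports:
        means, sds = r.means, r.sds
        rows.append({"optimizer": r.optimizer_name,
                     **{m: _format_mean_sd(means[m], sds[m]) for m in means.index}})
    written["mean_sd"] = out / "mean_sd.csv"
    pd.DataFrame(rows).to_csv(written["mean_sd"], index=False)

    if pairwise:
        written["pairwise_tests"] = out / "pairwise_tests.csv"
        pd.DataFrame([{
            "metric": p.metric_name, "comparison": p.comparison_label,
            "mean_difference": p.mean_difference, "ci_low": p.ci_low,
            "ci_high": p.ci_high, "p_value": p.p_value,
        } for p in pairwise]).to_csv(written["pairwise_tests"], index=False)
        (out / "pairwise_tests.footnote.txt").write_text(
            "Raw two-sided paired t-test p-values; no multiple-testing correction applied.\n"
        )

    if ablation:
        written["ablation"] = out / "ablation.csv"
        pd.DataFrame([{"optimizer": k, **v} for k, v in ablation.items()]).to_csv(
            written["ablation"], index=False)

    if eval_counts:
        written["evaluation_costs"] = out / "evaluation_costs.csv"
        pd.DataFrame([{"optimizer": k, **v} for k, v in eval_counts.items()]).to_csv(
            written["evaluation_costs"], index=False)

    if histories:
        for name, history in histories.items():
            path = out / f"convergence_{name}.csv"
            pd.DataFrame(history, columns=["iteration", "phase", "best_objective"]).to_csv(
                path, index=False)
            written[f"convergence_{name}"] = path
        if make_plots:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(6, 4))
            for name, history in histories.items():
                hf = pd.DataFrame(history, columns=["iteration", "phase", "best_objective"])
                ax.plot(hf["iteration"], hf["best_objective"], label=name)
            ax.set_xlabel("iteration")
            ax.set_ylabel("best objective")
            ax.legend()
            fig.tight_layout()
            written["convergence_plot"] = out / "convergence.png"
            fig.savefig(written["convergence_plot"], dpi=120)
            plt.close(fig)

    if confusions:
        for name, matrix in confusions.items():
            path = out / f"confusion_{name}.csv"
            pd.DataFrame(np.asarray(matrix)).to_csv(path, index=True)
            written[f"confusion_{name}"] = path

    return written
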