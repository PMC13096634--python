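"""aohho: hybrid Aquila Optimizer / Harris Hawks Optimization for CNN
hyperparameter tuning on multi-class MRI-like image data."""

from .space import (
    SearchBounds,
    HyperparameterSpace,
    CNNConfig,
    decode,
    encode,
    clip_to_bounds,
    sample_population,
)
from .driver import OptimizerState, MinimizeResult, check_convergence
from .aquila import AOParams, AquilaOptimizer
from .hho import HHOParams, HarrisHawksOptimizer
from .hybrid import HybridAOHHO, HybridConfig, OptimizationResult, optimize, ablate
from .bench import (
    BenchmarkFunction,
    benchmark_suite,
    RunReport,
    PairwiseTestResult,
    repeated_runs,
    pairwise_test,
    emit_report,
)

__version__ = "0.1.0"

__all__ = [
    "SearchBounds", "HyperparameterSpace", "CNNConfig",
    "decode", "encode", "clip_to_bounds", "sample_population",
    "OptimizerState", "MinimizeResult", "check_convergence",
    "AOParams", "AquilaOptimizer", "HHOParams", "HarrisHawksOptimizer",
    "HybridAOHHO", "HybridConfig", "OptimizationResult", "optimize", "ablate",
    "BenchmarkFunction", "benchmark_suite", "RunReport", "PairwiseTestResult",
    "repeated_runs", "pairwise_test", "emit_report",
    "CNNClassifier", "HyperparameterSearch",
]


def __getattr__(name):
    # heavier modules imported lazily
    if name == "CNNClassifier":
        from .cnn import CNNClassifier
        return CNNClassifier
    if name == "HyperparameterSearch":
        from .tuning import HyperparameterSearch
        return HyperparameterSearch
    raise AttributeError(f"module 'aohho' has no attribute {name!r}")
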