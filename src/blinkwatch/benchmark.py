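"""The frozen synthetic feature benchmark for the drowsiness scorer.

The reference corpus for this kind of system — 9964 frames of driver
video — cannot ship with a library, so the operating point is transplanted
onto a frozen synthetic benchmark of the same size: 9964 balanced feature
records around the alert/drowsy centroids, split 70/30, scored by the
three-hidden-layer tansig network after 1000 full-batch epochs.  Dataset
and split use seed 42 as part of the frozen protocol; the weight
initialization seed is the caller's choice.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import mlp, synthetic

BENCHMARK_N = 9964
BENCHMARK_SEED = 42
BENCHMARK_EPOCHS = 1000


@dataclass(frozen=True)
class BenchmarkResult:
    params: mlp.MLPParams
    history: list[float]
    train_report: mlp.EvalReport
    test_report: mlp.EvalReport


def run_benchmark(
    init_seed: int = BENCHMARK_SEED,
    n: int = BENCHMARK_N,
    epochs: int = BENCHMARK_EPOCHS,
    noise_sd: float = synthetic.FEATURE_NOISE_SD,
) -> BenchmarkResult:
    """Generate, split, train and evaluate the benchmark in one call."""
    data = synthetic.generate_feature_dataset(
        n, noise_sd=noise_sd, seed=BENCHMARK_SEED
    )
    train_set, test_set = mlp.split_dataset(
        data, train_fraction=0.7, seed=BENCHMARK_SEED
    )
    config = mlp.TrainConfig(epochs=epochs, seed=init_seed)
    params, history = mlp.train(train_set, config)
    return BenchmarkResult(
        params=params,
        history=history,
        train_report=mlp.evaluate(params, train_set),
        test_report=mlp.evaluate(params, test_set),
    )
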