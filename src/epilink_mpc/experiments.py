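"""Canned experiments: fixed-point accuracy and linkage quality.

These are the two headline quantitative experiments of the package:

* :func:`measure_deviation` — the fixed-point accuracy study: score a
  seeded corpus of random record pairs (half corrupted copies of the same
  person, half unrelated people, so the whole score range is exercised)
  with the double-precision reference and the L-bit fixed-point pipeline,
  and report the maximum absolute score difference as a percentage of the
  [0, 1] range.

* :func:`linkage_quality` — the linkage-quality study: two synthetic
  record sets with configurable size, overlap and per-field error rate
  (defaults: the 10,000-record, 60%-overlap, 10%-error study conditions),
  full cross-linkage with the default configuration, and
  precision/recall against the generator's ground truth.
"""

from __future__ import annotations

from .config_records import LinkageConfig, default_config, records_from_frame
from .fixed_point import score_deviation_experiment
from .linkage_workflow import LinkageMetrics, run_linkage
from .synthetic_data import (
    STUDY_ERROR_RATE,
    STUDY_OVERLAP,
    STUDY_SIZE,
    CorruptionSpec,
    corrupt_frame,
    generate_linkage_problem,
    generate_population,
)

__all__ = ["deviation_pairs", "measure_deviation", "linkage_quality"]


def deviation_pairs(config: LinkageConfig, n_pairs: int, seed: int):
    """Seeded random record pairs covering the whole score range."""
    half = n_pairs // 2
    population = generate_population(n_pairs + half, config, seed=seed)
    originals = records_from_frame(population.iloc[:half], config)
    corrupted = records_from_frame(
        corrupt_frame(
            population.iloc[:half],
            CorruptionSpec(error_rate=STUDY_ERROR_RATE, seed=seed + 1),
        ),
        config,
    )
    others = records_from_frame(
        population.iloc[half : half + (n_pairs - half)], config
    )
    pairs = list(zip(originals, corrupted))
    pairs += list(zip(originals, others))
    return pairs[:n_pairs]


def measure_deviation(
    L: int,
    n_pairs: int = 10_000,
    seed: int = 1,
    config: LinkageConfig | None = None,
) -> float:
    """Max |fixed-point − float| score deviation, in percent of [0, 1]."""
    if config is None:
        config = default_config()
    pairs = deviation_pairs(config, n_pairs, seed)
    return 100.0 * score_deviation_experiment(pairs, config, L)


def linkage_quality(
    size: int = STUDY_SIZE,
    overlap: float = STUDY_OVERLAP,
    error_rate: float = STUDY_ERROR_RATE,
    seed: int = 1,
    config: LinkageConfig | None = None,
) -> LinkageMetrics:
    """Precision/recall of a full size x size cross-linkage."""
    if config is None:
        config = default_config()
    A, B, truth = generate_linkage_problem(
        config,
        size,
        size,
        overlap,
        corruption=CorruptionSpec(error_rate=error_rate, seed=seed + 2),
        seed=seed,
    )
    report = run_linkage(A, B, config, engine="reference")
    return report.evaluated(truth).metrics
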