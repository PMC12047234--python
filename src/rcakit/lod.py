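"""Limit-of-detection simulation for SNV-based tumor detection.

For a given variant panel and sequencing platform (coverage and per-base
error rate), the simulator asks: what is the lowest tumor fraction at
which the MUT-allele count reliably exceeds the background produced by
sequencing errors alone?  Detection is declared when the observed MUT
count reaches a threshold calibrated on TF = 0 simulations to a minimum
true-negative rate; the limit of detection is the smallest grid TF whose
true-positive rate exceeds the required bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .snv import marginal_mut_probability
from .synth import VariantPanel, as_rng

__all__ = [
    "PlatformPreset",
    "PRESETS",
    "LoDResult",
    "expected_admixture_tf",
    "detection_threshold",
    "run_lod",
    "default_tf_grid",
    "lod_experiment_size",
]


@dataclass(frozen=True)
class PlatformPreset:
    """A sequencing technique summarized by coverage and error rate."""

    name: str
    coverage: float
    error_rate: float

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


#: The four simulated techniques: native nanopore reads vs consensus
#: reads, on MinION vs PromethION throughput.
PRESETS: dict[str, PlatformPreset] = {
    p.name: p
    for p in (
        PlatformPreset("raw-minion", coverage=0.25, error_rate=0.00674),
        PlatformPreset("raw-promethion", coverage=3.0, error_rate=0.00674),
        PlatformPreset("consensus-minion", coverage=0.04, error_rate=0.00072),
        PlatformPreset("consensus-promethion", coverage=0.8, error_rate=0.00072),
    )
}


@dataclass(frozen=True)
class LoDResult:
    """Per-preset detection performance across a TF grid.

    ``lowest_detectable_tf`` is ``None`` when no grid TF reaches the
    required true-positive rate.
    """

    preset: PlatformPreset
    tf_grid: np.ndarray
    tpr: np.ndarray
    tnr: float
    threshold: int
    lowest_detectable_tf: float | None
    n_trials: int


def expected_admixture_tf(fraction: float, source_tf: float) -> float:
    """Expected TF of an admixture: ``fraction`` of a source at ``source_tf``
    diluted into a TF-zero background."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if not 0.0 <= source_tf <= 1.0:
        raise ValueError("source_tf must be in [0, 1]")
    return fraction * source_tf


def detection_threshold(null_counts, tnr_min: float = 0.68) -> int:
    """Smallest integer threshold achieving a true-negative rate > ``tnr_min``.

    A sample is called tumor-positive when its MUT count is >= the
    threshold, so the TNR of threshold t is the fraction of TF = 0 trials
    with count < t.  ``tnr_min = 0`` degenerates to threshold 0
    (everything detected).
    """
    if not 0.0 <= tnr_min < 1.0:
        raise ValueError("tnr_min must be in [0, 1)")
    if tnr_min == 0.0:
        return 0
    null = np.asarray(null_counts, dtype=np.int64)
    if null.size < 1000:
        raise ValueError("need >= 1000 null trials to calibrate a threshold")
    for t in range(0, int(null.max()) + 2):
        if np.count_nonzero(null < t) / null.size > tnr_min:
            return t
    raise AssertionError("unreachable: TNR reaches 1 at max(null)+1")


def default_tf_grid() -> np.ndarray:
    """TF 0 plus 50 log-spaced TFs between 0.001 and 1."""
    return np.concatenate([[0.0], np.logspace(-3, 0, 50)])


def run_lod(
    panel: VariantPanel,
    preset: PlatformPreset,
    tf_grid: np.ndarray | None = None,
    n_trials: int = 10_000,
    tnr_min: float = 0.68,
    tpr_min: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> LoDResult:
    """Simulate detection performance over a TF grid for one platform.

    Per trial the number of panel-site observations is
    Poisson(coverage * n_sites) and the MUT count is binomial with the
    marginal per-observation MUT probability at that TF.  The detection
    threshold is calibrated on the TF = 0 trials to ``tnr_min``; the
    limit of detection is the smallest grid TF with TPR > ``tpr_min``.
    """
    rng = as_rng(seed)
    grid = default_tf_grid() if tf_grid is None else np.asarray(tf_grid, dtype=float)
    if grid[0] != 0.0:
        raise ValueError("tf_grid must start at 0 to calibrate the null distribution")
    mean_obs = preset.coverage * panel.n_sites
    counts = np.empty((len(grid), n_trials), dtype=np.int64)
    for i, tf in enumerate(grid):
        n_obs = rng.poisson(mean_obs, size=n_trials)
        p = marginal_mut_probability(panel, float(tf), preset.error_rate)
        counts[i] = rng.binomial(n_obs, p)
    threshold = detection_threshold(counts[0], tnr_min=tnr_min)
    tpr = (counts >= threshold).mean(axis=1)
    tnr = float(1.0 - tpr[0])
    detectable = np.flatnonzero((grid > 0) & (tpr > tpr_min))
    lowest = float(grid[detectable[0]]) if detectable.size else None
    return LoDResult(
        preset=preset,
        tf_grid=grid,
        tpr=tpr,
        tnr=tnr,
        threshold=threshold,
        lowest_detectable_tf=lowest,
        n_trials=n_trials,
    )


def lod_experiment_size(n_trials: int, n_tfs: int, n_techniques: int) -> int:
    """Number of simulated data sets per patient in a full LoD experiment."""
    if min(n_trials, n_tfs, n_techniques) < 1:
        raise ValueError("all factors must be positive integers")
    return n_trials * n_tfs * n_techniques
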