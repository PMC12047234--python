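"""Tumor-informed SNV allele counting and Monte Carlo tumor-fraction inference.

A cfDNA sample is modelled as a mixture of tumor- and healthy-derived
fragments.  A fragment overlapping a tumor-informed variant site i shows
the MUT allele with probability purity * VAF_i if it is tumor-derived,
and essentially never if it is healthy-derived (a sequencing error can
mimic the MUT allele with probability error_rate / 3 under the
uniform-3-alternative substitution model).  The estimator searches a grid
of candidate tumor fractions, simulates the MUT-count distribution at
each, and scores grid points by how often their simulated counts align
with the observed count; the best-aligned TF is the point estimate and
the 2.5% / 97.5% quantiles of the normalized alignment profile give a
95% confidence interval.  Point estimates below 0.05 are refined on a
log-spaced grid over [0, 0.10].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import CALL_ERR, CALL_MUT, CALL_REF, AlleleObservations, VariantPanel, as_rng

__all__ = [
    "AlleleCounts",
    "TFEstimate",
    "count_alleles",
    "cumulative_mut_ratio",
    "fisher_mut_enrichment",
    "mut_probability",
    "marginal_mut_probability",
    "simulate_mut_counts",
    "estimate_tf_snv",
]


@dataclass(frozen=True)
class AlleleCounts:
    """Tally of REF / MUT / ERR calls at tumor-informed sites."""

    n_ref: int
    n_mut: int
    n_err: int

    def __post_init__(self) -> None:
        if min(self.n_ref, self.n_mut, self.n_err) < 0:
            raise ValueError("allele counts must be nonnegative")

    @property
    def n_obs(self) -> int:
        return self.n_ref + self.n_mut + self.n_err


@dataclass(frozen=True)
class TFEstimate:
    """Result of the Monte Carlo grid search.

    ``grid_weights`` is the normalized alignment frequency of each grid
    TF; ``refined`` flags that the estimate comes from the fine log grid
    over [0, 0.10].
    """

    tf_point: float
    ci_low: float
    ci_high: float
    grid: np.ndarray
    grid_weights: np.ndarray
    n_trials: int
    refined: bool

    def __post_init__(self) -> None:
        if not self.ci_low <= self.tf_point <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


def count_alleles(observations: AlleleObservations, panel: VariantPanel) -> AlleleCounts:
    """Tally REF/MUT/ERR calls; observations must reference ``panel``."""
    if observations.n_sites != panel.n_sites:
        raise ValueError("observations were drawn against a different panel")
    return AlleleCounts(
        n_ref=int(np.count_nonzero(observations.call == CALL_REF)),
        n_mut=int(np.count_nonzero(observations.call == CALL_MUT)),
        n_err=int(np.count_nonzero(observations.call == CALL_ERR)),
    )


def cumulative_mut_ratio(
    observations: AlleleObservations,
    bin_minutes: float = 10.0,
    total_minutes: float | None = None,
) -> pd.DataFrame:
    """Real-time cumulative MUT/(MUT+REF) ratio in fixed time bins.

    Returns a DataFrame with columns ``minutes`` (bin end) and
    ``cum_mut_ratio``.  ERR calls are excluded from the ratio.  Bins in
    which no REF or MUT call has yet been seen carry the previous value
    forward (0 before the first observation).
    """
    if bin_minutes <= 0:
        raise ValueError("bin_minutes must be positive")
    ts = observations.timestamp
    horizon = total_minutes if total_minutes is not None else (float(ts.max()) if len(ts) else bin_minutes)
    n_bins = max(1, int(np.ceil(horizon / bin_minutes)))
    edges = bin_minutes * np.arange(1, n_bins + 1)
    is_mut = observations.call == CALL_MUT
    is_ref = observations.call == CALL_REF
    ratios = np.empty(n_bins)
    prev = 0.0
    for k, edge in enumerate(edges):
        seen = ts < edge
        mut = int(np.count_nonzero(seen & is_mut))
        ref = int(np.count_nonzero(seen & is_ref))
        prev = mut / (mut + ref) if mut + ref else prev
        ratios[k] = prev
    return pd.DataFrame({"minutes": edges, "cum_mut_ratio": ratios})


def fisher_mut_enrichment(patient: AlleleCounts, control: AlleleCounts) -> float:
    """One-sided Fisher's exact p-value for MUT enrichment in the patient.

    Tests MUT vs REF counts (ERR excluded) against the control sample;
    the alternative is that the patient's MUT fraction is greater.
    """
    table = [[patient.n_mut, patient.n_ref], [control.n_mut, control.n_ref]]
    if sum(table[0]) + sum(table[1]) == 0:
        warnings.warn("degenerate all-zero table; returning p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(table, alternative="greater")[1])


def mut_probability(purity: float, vaf: float) -> float:
    """Probability that a tumor-derived fragment carries the MUT allele.

    With tumor purity q and biopsy VAF v the probability is q * v: the
    biopsy VAF already folds in local copy number and heterozygosity, and
    the purity corrects for normal-cell contamination of the biopsy.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if not 0.0 < vaf <= 1.0:
        raise ValueError(f"vaf must be in (0, 1], got {vaf}")
    return purity * vaf


def marginal_mut_probability(panel: VariantPanel, tf: float, error_rate: float = 0.0) -> float:
    """MUT probability of one observation at a uniformly random panel site.

    tf * mean_i(purity * VAF_i) + (1 - tf) * error_rate / 3; the error
    term is the chance that a sequencing error in a healthy fragment hits
    the site's specific ALT base.
    """
    if not 0.0 <= tf <= 1.0:
        raise ValueError("tf must be in [0, 1]")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    return tf * float(panel.mut_probabilities().mean()) + (1.0 - tf) * error_rate / 3.0


def simulate_mut_counts(
    panel: VariantPanel,
    n_obs: int,
    tf: float,
    n_trials: int = 10_000,
    error_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate the MUT-allele count of ``n_obs`` observations, ``n_trials`` times.

    Each observation lands on a uniformly random panel site and is MUT
    with probability tf * purity * VAF_i + (1 - tf) * error_rate / 3.
    Because sites are assigned uniformly and independently, the total MUT
    count is distributed exactly Binomial(n_obs, p-bar) with p-bar the
    panel-mean MUT probability, and is sampled as such; this is an exact
    identity, not an approximation, and keeps the grid search fast.
    """
    if n_obs < 0:
        raise ValueError("n_obs must be >= 0")
    rng = as_rng(seed)
    p = marginal_mut_probability(panel, tf, error_rate)
    return rng.binomial(n_obs, p, size=n_trials)


_LINEAR_GRID = np.linspace(0.0, 1.0, 100)
#: Fine grid for low tumor fractions: 0 plus 99 log-spaced points on [1e-4, 0.1].
_LOG_GRID = np.concatenate([[0.0], np.logspace(-4, np.log10(0.10), 99)])


def _weights_on_grid(
    grid: np.ndarray,
    counts: AlleleCounts,
    panel: VariantPanel,
    n_trials: int,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    sims = np.empty((len(grid), n_trials), dtype=np.int64)
    for i, tf in enumerate(grid):
        sims[i] = simulate_mut_counts(panel, counts.n_obs, float(tf), n_trials, error_rate, rng)
    # Alignment = exact MUT-count match; widen symmetrically by the
    # smallest tolerance that leaves any mass (needed for very large n_obs).
    dev = np.abs(sims - counts.n_mut)
    for k in range(0, counts.n_obs + 1):
        w = (dev <= k).mean(axis=1)
        if w.sum() > 0:
            break
    return w / w.sum()


def _point_and_ci(grid: np.ndarray, weights: np.ndarray) -> tuple[float, float, float]:
    # The point estimate is the best-aligned grid TF.  For the interval the
    # alignment profile is integrated over TF, weighting each grid point by
    # its cell width so that linear and log grids imply the same (uniform)
    # prior over TF rather than one proportional to local point density.
    tf_point = float(grid[int(np.argmax(weights))])
    widths = np.empty_like(grid)
    widths[1:-1] = (grid[2:] - grid[:-2]) / 2.0
    widths[0] = (grid[1] - grid[0]) / 2.0
    widths[-1] = (grid[-1] - grid[-2]) / 2.0
    mass = weights * widths
    total = mass.sum()
    cdf = np.cumsum(mass / total) if total > 0 else np.cumsum(weights)
    ci_low = float(grid[int(np.searchsorted(cdf, 0.025, side="left"))])
    ci_high = float(grid[min(int(np.searchsorted(cdf, 0.975, side="left")), len(grid) - 1)])
    return tf_point, min(ci_low, tf_point), max(ci_high, tf_point)


def estimate_tf_snv(
    counts: AlleleCounts,
    panel: VariantPanel,
    n_trials: int = 10_000,
    error_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> TFEstimate:
    """Monte Carlo grid-search estimate of the tumor fraction.

    The TF is varied over 100 linear steps on [0, 1]; at each grid TF,
    ``n_trials`` MUT counts are simulated and the grid point's weight is
    the fraction of trials matching the observed MUT count.  The point
    estimate is the best-aligned TF and the confidence interval spans the
    2.5%-97.5% quantiles of the normalized weight profile.  When the
    point estimate falls below 0.05 the search is repeated on a finer
    grid of 100 steps over [0, 0.10] (log-spaced, with 0 prepended) and
    that refined estimate is returned.
    """
    if counts.n_obs < 1:
        raise ValueError("cannot estimate a tumor fraction from zero observations")
    rng = as_rng(seed)
    grid = _LINEAR_GRID
    weights = _weights_on_grid(grid, counts, panel, n_trials, error_rate, rng)
    tf_point, ci_low, ci_high = _point_and_ci(grid, weights)
    refined = False
    if tf_point < 0.05:
        grid = _LOG_GRID
        weights = _weights_on_grid(grid, counts, panel, n_trials, error_rate, rng)
        tf_point, ci_low, ci_high = _point_and_ci(grid, weights)
        refined = True
    return TFEstimate(
        tf_point=tf_point,
        ci_low=ci_low,
        ci_high=ci_high,
        grid=grid.copy(),
        grid_weights=weights,
        n_trials=n_trials,
        refined=refined,
    )
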