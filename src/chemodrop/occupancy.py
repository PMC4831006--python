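"""Poisson-occupancy statistics for droplet-based single-cell enumeration.

When a dilute cell suspension is segmented into monodisperse droplets, the
number of founder cells per droplet is Poisson distributed with mean
occupancy ``lambda`` (cells/droplet).  After incubation only *presence* of
growth is observed per droplet, so the maximum-likelihood estimator of the
mean occupancy is

    lambda = -ln(1 - f_occ)

where ``f_occ`` is the fraction of growth-positive droplets.  This module
collects everything built on that identity: the pmf, interval estimation of
``lambda`` from droplet tallies, single-cell design probabilities, the
dual-label deconvolution used to quantify a non-labelled species against a
fluorescent reference strain co-encapsulated with it, and the chemotactic
enrichment factor.

Confidence intervals are exact Clopper-Pearson intervals on the occupied
fraction, mapped through the monotone transform ``-ln(1 - p)``; this remains
valid at the ~100-droplet tallies typical of a single tubing run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "OccupancyCount",
    "LambdaEstimate",
    "EnrichmentResult",
    "SaturatedOccupancyError",
    "poisson_pmf",
    "clopper_pearson",
    "estimate_lambda",
    "single_cell_given_growth",
    "empty_fraction",
    "deconvolve_dual_label",
    "enrichment_factor",
    "lambda_from_density",
    "expected_occupancy_curve",
    "round_sig",
]


class SaturatedOccupancyError(ValueError):
    """Every droplet is occupied: the occupancy estimator diverges.

    The assay protocol keeps lambda low by dilution precisely so that this
    does not happen; an all-positive array carries no information about how
    many cells each droplet holds.
    """


def _check_count(name: str, value: int | None, *, required: bool = False) -> int | None:
    if value is None:
        if required:
            raise ValueError(f"{name} is required here but was not recorded")
        return None
    if value != int(value) or value < 0:
        raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
    return int(value)


@dataclass(frozen=True)
class OccupancyCount:
    """Tallies over a droplet array after incubation.

    Parameters
    ----------
    n_total:
        Number of droplets enumerated.
    n_growth:
        Droplets with visible growth (bright-field).
    n_fluor:
        Droplets in which the fluorescent reference strain is present
        (fluorescence channel); optional, dual-label experiments only.
    n_growth_nonfluor:
        Droplets with growth but no fluorescence, i.e. containing only the
        non-labelled species; optional.
    """

    n_total: int
    n_growth: int
    n_fluor: int | None = None
    n_growth_nonfluor: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_total", _check_count("n_total", self.n_total))
        object.__setattr__(self, "n_growth", _check_count("n_growth", self.n_growth))
        object.__setattr__(self, "n_fluor", _check_count("n_fluor", self.n_fluor))
        object.__setattr__(
            self, "n_growth_nonfluor", _check_count("n_growth_nonfluor", self.n_growth_nonfluor)
        )
        if self.n_growth > self.n_total:
            raise ValueError("n_growth cannot exceed n_total")
        if self.n_fluor is not None and self.n_fluor > self.n_total:
            raise ValueError("n_fluor cannot exceed n_total")
        if (
            self.n_growth_nonfluor is not None
            and self.n_growth_nonfluor > self.n_growth
        ):
            raise ValueError("n_growth_nonfluor cannot exceed n_growth")


@dataclass(frozen=True)
class LambdaEstimate:
    """Point estimate of mean occupancy with its exact confidence interval."""

    lambda_hat: float
    ci_low: float
    ci_high: float
    occupied_fraction: float
    n_total: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.lambda_hat <= self.ci_high):
            raise ValueError("confidence interval must bracket the point estimate")

    @property
    def ci_half_width(self) -> float:
        return 0.5 * (self.ci_high - self.ci_low)


@dataclass(frozen=True)
class EnrichmentResult:
    """Target-vs-reference lambda ratios before/after gradient exposure."""

    lambda_target_before: float
    lambda_target_after: float
    lambda_ref_before: float
    lambda_ref_after: float
    ratio_before: float
    ratio_after: float
    enrichment_factor: float


def poisson_pmf(k, lam):
    """Probability of exactly ``k`` founder cells in a droplet at mean occupancy ``lam``.

    Vectorised over ``k`` and ``lam``.  Raises ``ValueError`` on negative or
    non-integer ``k`` and on negative ``lam``.
    """
    k_arr = np.asarray(k)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(k_arr != np.floor(k_arr)) or np.any(k_arr < 0):
        raise ValueError("k must be a non-negative integer")
    if np.any(lam_arr < 0):
        raise ValueError("lam must be non-negative")
    out = stats.poisson.pmf(k_arr, lam_arr)
    if np.isscalar(k) and np.isscalar(lam):
        return float(out)
    return out


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k successes of n."""
    if not 0 < conf < 1:
        raise ValueError("conf must lie in (0, 1)")
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    alpha = 1.0 - conf
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def _lambda_from_fraction(p: float) -> float:
    return float(-math.log1p(-p))


def estimate_lambda(
    counts: OccupancyCount,
    occupied_field: str = "n_growth",
    conf: float = 0.95,
) -> LambdaEstimate:
    """Maximum-likelihood mean occupancy from a presence/absence droplet tally.

    ``occupied_field`` selects which tally counts as "occupied" (``n_growth``
    by default; ``n_fluor`` for the reference-strain channel).  The interval
    is Clopper-Pearson on the occupied fraction mapped through ``-ln(1-p)``,
    which is monotone, so coverage is inherited exactly.
    """
    if counts.n_total <= 0:
        raise ValueError("n_total must be positive")
    n_occ = getattr(counts, occupied_field)
    if n_occ is None:
        raise ValueError(f"tally {occupied_field!r} was not recorded")
    if n_occ > counts.n_total:
        raise ValueError("occupied count exceeds total")
    if n_occ == counts.n_total:
        raise SaturatedOccupancyError(
            "all droplets occupied: lambda is unbounded; dilute the sample"
        )
    p = n_occ / counts.n_total
    lo, hi = clopper_pearson(n_occ, counts.n_total, conf)
    if hi >= 1.0:  # k == n excluded above, so hi < 1 from the beta quantile
        hi = np.nextafter(1.0, 0.0)
    return LambdaEstimate(
        lambda_hat=_lambda_from_fraction(p),
        ci_low=_lambda_from_fraction(lo),
        ci_high=_lambda_from_fraction(hi),
        occupied_fraction=p,
        n_total=counts.n_total,
    )


def single_cell_given_growth(lam: float) -> float:
    """P(exactly one founder | at least one founder) at mean occupancy ``lam``.

    This is the design quantity for single-cell cultivation: at lam = 0.1,
    95% of growth-positive droplets were founded by a single cell.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    return float(lam * math.exp(-lam) / -math.expm1(-lam))


def empty_fraction(lam: float) -> float:
    """Fraction of droplets expected to stay empty, exp(-lam)."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    return float(math.exp(-lam))


def deconvolve_dual_label(
    counts: OccupancyCount, conf: float = 0.95
) -> tuple[LambdaEstimate, LambdaEstimate]:
    """Split total occupancy into labelled-reference and non-labelled parts.

    With independent co-encapsulation of the two species, occupancies add:
    ``lambda_total = lambda_ref + lambda_nonlabelled``.  The reference lambda
    comes from the fluorescent-droplet fraction, the total from the union of
    fluorescent and growth-only-nonfluorescent droplets, and the non-labelled
    lambda by subtraction (clipped at zero, with a warning, if sampling noise
    drives it negative).

    Returns ``(ref, nonlabelled)`` estimates.  The non-labelled interval is a
    conservative difference of the two exact intervals.
    """
    n_fluor = counts.n_fluor
    n_gnf = counts.n_growth_nonfluor
    if n_fluor is None or n_gnf is None:
        raise ValueError("dual-label deconvolution needs n_fluor and n_growth_nonfluor")
    n_union = n_fluor + n_gnf
    if n_union > counts.n_total:
        raise ValueError("inconsistent tallies: fluorescent + growth-only exceed total")
    if n_union == counts.n_total or n_fluor == counts.n_total:
        raise SaturatedOccupancyError("all droplets occupied: dilute the sample")

    ref = estimate_lambda(counts, "n_fluor", conf)
    total = estimate_lambda(
        OccupancyCount(n_total=counts.n_total, n_growth=n_union), "n_growth", conf
    )
    lam_nl = total.lambda_hat - ref.lambda_hat
    if lam_nl < 0:
        warnings.warn(
            "deconvolved non-labelled lambda was negative; clipped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        lam_nl = 0.0
    ci_low = max(0.0, total.ci_low - ref.ci_high)
    ci_high = max(lam_nl, total.ci_high - ref.ci_low)
    nonlabelled = LambdaEstimate(
        lambda_hat=lam_nl,
        ci_low=min(ci_low, lam_nl),
        ci_high=ci_high,
        occupied_fraction=float(-np.expm1(-lam_nl)),
        n_total=counts.n_total,
    )
    return ref, nonlabelled


def enrichment_factor(
    before: tuple[float, float], after: tuple[float, float]
) -> EnrichmentResult:
    """Chemotactic enrichment of the target species against the reference.

    ``before`` and ``after`` are ``(lambda_target, lambda_ref)`` pairs from
    the control run and the gradient-exposed run.  The enrichment factor is
    the ratio of target/reference lambda ratios, after over before.
    """
    (lt_b, lr_b), (lt_a, lr_a) = before, after
    for name, lam in (
        ("lambda_target_before", lt_b),
        ("lambda_ref_before", lr_b),
        ("lambda_target_after", lt_a),
        ("lambda_ref_after", lr_a),
    ):
        if lam < 0:
            raise ValueError(f"{name} must be non-negative, got {lam}")
    if lr_b <= 0 or lr_a <= 0:
        raise ValueError("reference lambda of zero leaves the ratio undefined")
    if lt_b <= 0:
        raise ValueError("target lambda before must be positive for a finite factor")
    ratio_b = lt_b / lr_b
    ratio_a = lt_a / lr_a
    return EnrichmentResult(
        lambda_target_before=lt_b,
        lambda_target_after=lt_a,
        lambda_ref_before=lr_b,
        lambda_ref_after=lr_a,
        ratio_before=ratio_b,
        ratio_after=ratio_a,
        enrichment_factor=ratio_a / ratio_b,
    )


def lambda_from_density(density_cfu_per_ml: float, volume_nl: float) -> float:
    """Mean occupancy implied by a cell density (CFU/mL) and droplet volume (nL)."""
    if density_cfu_per_ml < 0:
        raise ValueError("density must be non-negative")
    if volume_nl <= 0:
        raise ValueError("volume must be positive")
    return float(density_cfu_per_ml * volume_nl * 1e-6)


def expected_occupancy_curve(
    densities_cfu_per_ml: Sequence[float], volume_nl: float
) -> np.ndarray:
    """Expected occupied-droplet fraction 1 - exp(-cV) over a density series."""
    lam = np.array([lambda_from_density(d, volume_nl) for d in densities_cfu_per_ml])
    return -np.expm1(-lam)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention for lambda)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
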