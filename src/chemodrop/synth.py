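"""Synthetic device: chemotactic sorting, Poisson encapsulation, detector traces.

This module generates every input the analysis side consumes, with the
statistical structure the physical device imposes:

* ``simulate_sorting`` — run-and-tumble walkers advected through the solved
  gradient field and split between the collection and waste outlets.  The
  kinematic model is an invention of this package (the device only shows
  *that* cells sort, not a motion law): straight runs at constant speed with
  Poisson-timed tumbles whose rate is suppressed while the cell experiences
  a rising chemoeffector concentration — the classic temporal-sensing bias.
* ``encapsulate`` — independent Poisson founder counts per species at mean
  occupancy ``density x volume``, optional Bernoulli viability thinning,
  growth and fluorescence flags per droplet.
* ``synth_trace`` — the 1D bright-field intensity series of a droplet train
  passing the detection point: an oil baseline, a per-droplet plateau
  (darker when the droplet holds grown cells, by optical absorbance) flanked
  by two narrow meniscus peaks, with jittered durations and Gaussian noise,
  plus a co-registered fluorescence channel and ground-truth segment
  bookkeeping.

All generators take an integer seed and are bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gradient import GradientField
from .occupancy import OccupancyCount

__all__ = [
    "SpeciesParams",
    "DropletRecord",
    "TraceParams",
    "SortingResult",
    "TruthSegment",
    "SyntheticTrace",
    "simulate_sorting",
    "encapsulate",
    "synth_trace",
    "tally_droplets",
]


@dataclass(frozen=True)
class SpeciesParams:
    """Motility and labelling parameters of one species.

    ``chemotactic_sensitivity`` scales the tumble-rate suppression when the
    perceived concentration rises (0 = non-chemotactic, e.g. a cheZ-deletion
    mutant); 1 means tumbling stops entirely at a saturating up-gradient
    signal.
    """

    name: str
    swim_speed: float = 20.0  # um/s
    base_tumble_rate: float = 1.0  # 1/s
    chemotactic_sensitivity: float = 0.0
    labelled: bool = False
    growth_probability: float = 1.0

    def __post_init__(self) -> None:
        if self.swim_speed < 0:
            raise ValueError("swim_speed must be non-negative")
        if self.base_tumble_rate <= 0:
            raise ValueError("base_tumble_rate must be positive")
        if self.chemotactic_sensitivity < 0:
            raise ValueError("chemotactic_sensitivity must be non-negative")
        if not 0 < self.growth_probability <= 1:
            raise ValueError("growth_probability must lie in (0, 1]")


@dataclass(frozen=True)
class DropletRecord:
    """One droplet: latent founder truth plus the two observable flags."""

    droplet_id: int
    volume_nl: float
    founders: tuple[int, ...]  # per-species counts, order of the species list
    growth: bool
    fluorescent: bool


@dataclass(frozen=True)
class SortingResult:
    """Collection-outlet routing outcome for one species."""

    name: str
    n_cells: int
    n_collected: int

    @property
    def fraction(self) -> float:
        return self.n_collected / self.n_cells


@dataclass(frozen=True)
class TruthSegment:
    """Generator-side ground truth for one droplet in the trace."""

    start_idx: int
    end_idx: int  # half-open
    front_peak_idx: int
    back_peak_idx: int
    growth: bool
    fluorescent: bool


@dataclass(frozen=True)
class TraceParams:
    """Shape parameters of the synthetic bright-field / fluorescence trace.

    Intensity units are arbitrary (normalised to the oil baseline ~ 1).  The
    growth plateau sits below the empty plateau because grown cells absorb
    light.  Durations are Gamma-jittered with the given CV to avoid
    metronomic artifacts; the default ``noise_sd`` is the "separable" preset
    (well under half the plateau separation).
    """

    sample_rate: float = 200.0  # Hz
    oil_level: float = 1.0
    empty_plateau_level: float = 0.80
    growth_plateau_level: float = 0.45
    boundary_peak_amplitude: float = 0.6
    boundary_peak_width_ms: float = 40.0
    droplet_duration_ms: float = 1500.0
    gap_duration_ms: float = 500.0
    duration_cv: float = 0.10
    noise_sd: float = 0.02
    fluor_bright_level: float = 1.0
    fluor_dark_level: float = 0.02

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.growth_plateau_level >= self.empty_plateau_level:
            raise ValueError("growth plateau must sit below the empty plateau (absorbance)")
        sep = self.empty_plateau_level - self.growth_plateau_level
        if self.noise_sd >= sep / 2:
            raise ValueError("noise_sd must stay below half the plateau separation")
        if self.duration_cv < 0:
            raise ValueError("duration_cv must be non-negative")


@dataclass
class SyntheticTrace:
    """Bright-field + fluorescence channels with ground-truth segments."""

    bright: "np.ndarray"
    fluor: "np.ndarray"
    sample_rate: float
    truth: list[TruthSegment] = field(default_factory=list)


# ---------------------------------------------------------------------------
# sorting simulator


def _field_lookup(fieldobj: GradientField, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    ix = np.clip((x / fieldobj.dx).astype(np.intp), 0, fieldobj.concentration.shape[0] - 1)
    iy = np.clip((y / fieldobj.dy).astype(np.intp), 0, fieldobj.concentration.shape[1] - 1)
    return fieldobj.concentration[ix, iy]


def simulate_sorting(
    gradient: GradientField,
    species: Sequence[SpeciesParams],
    n_cells: int,
    seed: int,
    dt: float = 0.1,
    release: str = "middle",
    dcdt_scale: float = 0.02,
    rotational_diffusion: float = 0.1,
) -> dict[str, SortingResult]:
    """Route run-and-tumble walkers through the channel and split them at the outlet.

    Cells are released at x = 0 (uniformly within the middle merged stream by
    default, or across the full width with ``release="uniform"``), advected by
    the field's velocity profile while swimming at constant speed, and tumble
    at ``base_tumble_rate * max(0, 1 - sensitivity * clip(dc/dt / dcdt_scale, 0, 1))``.
    A cell leaving at x = length is routed to the collection outlet when its
    transverse position lies beyond the splitting streamline set by the waste
    flow fraction (waste skims the low-y side).

    ``dcdt_scale`` (1/s, on the normalised concentration) sets the perceived
    signal that saturates the tumble suppression; ``rotational_diffusion`` is
    the heading noise in rad^2/s.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if gradient.concentration.ndim != 2:
        raise ValueError("gradient must be a solved 2D field")
    geom, flow = gradient.geometry, gradient.flow
    width, length = geom.width_total, geom.length
    y_split = flow.waste_fraction * width

    fr = flow.inlet_fractions
    mid_lo, mid_hi = fr[0] * width, (fr[0] + fr[1]) * width

    u_of_y = gradient.velocity_profile
    y_grid = gradient.y
    v_mean = float(u_of_y.mean())
    max_steps = int(np.ceil(3 * length / (max(v_mean, 1.0) * dt)))

    results: dict[str, SortingResult] = {}
    root = np.random.default_rng(seed)
    for sp in species:
        rng = np.random.default_rng(root.integers(2**31))
        if release == "middle":
            y = rng.uniform(mid_lo, mid_hi, n_cells)
        elif release == "uniform":
            y = rng.uniform(0.0, width, n_cells)
        else:
            raise ValueError(f"unknown release mode {release!r}")
        x = np.zeros(n_cells)
        theta = rng.uniform(0.0, 2 * np.pi, n_cells)
        c_prev = _field_lookup(gradient, x, y)
        active = np.ones(n_cells, bool)
        exit_y = np.empty(n_cells)
        rot_sd = np.sqrt(2 * rotational_diffusion * dt)
        for _ in range(max_steps):
            if not active.any():
                break
            u = np.interp(y, y_grid, u_of_y)
            x_new = x + (u + sp.swim_speed * np.cos(theta)) * dt * active
            y_new = y + sp.swim_speed * np.sin(theta) * dt * active
            # reflecting walls
            y_new = np.where(y_new < 0, -y_new, y_new)
            y_new = np.where(y_new > width, 2 * width - y_new, y_new)
            c_now = _field_lookup(gradient, np.minimum(x_new, length), y_new)
            dcdt = (c_now - c_prev) / dt
            signal = np.clip(dcdt / dcdt_scale, 0.0, 1.0)
            rate = sp.base_tumble_rate * np.maximum(
                0.0, 1.0 - sp.chemotactic_sensitivity * signal
            )
            tumble = rng.random(n_cells) < rate * dt
            theta = np.where(tumble, rng.uniform(0.0, 2 * np.pi, n_cells), theta)
            theta = theta + rng.normal(0.0, rot_sd, n_cells)
            x, y, c_prev = x_new, y_new, c_now
            done = active & (x >= length)
            exit_y[done] = y[done]
            active &= ~done
        exit_y[active] = y[active]  # stragglers scored at their current position
        n_collected = int(np.count_nonzero(exit_y > y_split))
        results[sp.name] = SortingResult(name=sp.name, n_cells=n_cells, n_collected=n_collected)
    return results


# ---------------------------------------------------------------------------
# encapsulation


def encapsulate(
    species: Sequence[SpeciesParams],
    densities_cfu_per_ml: Sequence[float],
    volume_nl: float,
    n_droplets: int,
    seed: int,
) -> list[DropletRecord]:
    """Poisson-encapsulate a (possibly multi-species) suspension into droplets.

    Per droplet and species the founder count is Poisson with mean
    ``density * volume * 1e-6``; each founder independently survives to grow
    with the species' ``growth_probability``.  ``growth`` flags any surviving
    founder; ``fluorescent`` flags a surviving founder of a labelled species.
    """
    if volume_nl <= 0:
        raise ValueError("volume must be positive")
    if n_droplets <= 0:
        raise ValueError("n_droplets must be positive")
    if len(species) != len(densities_cfu_per_ml):
        raise ValueError("one density per species required")
    if any(d < 0 for d in densities_cfu_per_ml):
        raise ValueError("densities must be non-negative")
    rng = np.random.default_rng(seed)
    lams = np.array([d * volume_nl * 1e-6 for d in densities_cfu_per_ml])
    founders = rng.poisson(lams, size=(n_droplets, len(species)))
    surviving = founders.copy()
    for j, sp in enumerate(species):
        if sp.growth_probability < 1.0:
            surviving[:, j] = rng.binomial(founders[:, j], sp.growth_probability)
    labelled = np.array([sp.labelled for sp in species], bool)
    growth = surviving.sum(axis=1) >= 1
    fluor = (surviving[:, labelled].sum(axis=1) >= 1) if labelled.any() else np.zeros(n_droplets, bool)
    return [
        DropletRecord(
            droplet_id=i,
            volume_nl=volume_nl,
            founders=tuple(int(v) for v in founders[i]),
            growth=bool(growth[i]),
            fluorescent=bool(fluor[i]),
        )
        for i in range(n_droplets)
    ]


def tally_droplets(droplets: Sequence[DropletRecord]) -> OccupancyCount:
    """Tally ground-truth droplet flags into an OccupancyCount."""
    n_growth = sum(d.growth for d in droplets)
    n_fluor = sum(d.fluorescent for d in droplets)
    n_gnf = sum(d.growth and not d.fluorescent for d in droplets)
    return OccupancyCount(
        n_total=len(droplets), n_growth=n_growth, n_fluor=n_fluor, n_growth_nonfluor=n_gnf
    )


# ---------------------------------------------------------------------------
# trace generator


def _jittered(rng: np.random.Generator, mean_ms: float, cv: float) -> float:
    if cv == 0:
        return mean_ms
    shape = 1.0 / (cv * cv)
    return float(rng.gamma(shape, mean_ms / shape))


def synth_trace(
    droplets: Sequence[DropletRecord],
    params: TraceParams | None = None,
    seed: int = 0,
) -> SyntheticTrace:
    """Render a droplet train into bright-field and fluorescence detector traces.

    The train is lead-in oil, then per droplet: a meniscus peak, a plateau at
    the empty or growth level (dark = growth), a second meniscus peak, and an
    oil gap; the fluorescence channel is bright only over droplets holding
    the labelled reference.  Ground-truth boundaries are returned alongside
    for oracle use.
    """
    params = params or TraceParams()
    rng = np.random.default_rng(seed)
    sr = params.sample_rate
    to_n = lambda ms: max(1, int(round(ms / 1000.0 * sr)))

    blocks_b: list[np.ndarray] = []
    blocks_f: list[np.ndarray] = []
    truth: list[TruthSegment] = []
    peak_centers: list[int] = []
    pos = 0

    lead = to_n(_jittered(rng, params.gap_duration_ms, params.duration_cv))
    blocks_b.append(np.full(lead, params.oil_level))
    blocks_f.append(np.full(lead, params.fluor_dark_level))
    pos += lead

    for d in droplets:
        n_drop = to_n(_jittered(rng, params.droplet_duration_ms, params.duration_cv))
        level = params.growth_plateau_level if d.growth else params.empty_plateau_level
        blocks_b.append(np.full(n_drop, level))
        flevel = params.fluor_bright_level if d.fluorescent else params.fluor_dark_level
        blocks_f.append(np.full(n_drop, flevel))
        front, back = pos, pos + n_drop - 1
        peak_centers.extend([front, back])
        truth.append(
            TruthSegment(
                start_idx=front,
                end_idx=pos + n_drop,
                front_peak_idx=front,
                back_peak_idx=back,
                growth=d.growth,
                fluorescent=d.fluorescent,
            )
        )
        pos += n_drop
        n_gap = to_n(_jittered(rng, params.gap_duration_ms, params.duration_cv))
        blocks_b.append(np.full(n_gap, params.oil_level))
        blocks_f.append(np.full(n_gap, params.fluor_dark_level))
        pos += n_gap

    bright = np.concatenate(blocks_b)
    fluor = np.concatenate(blocks_f)

    if peak_centers:
        # meniscus spikes rise above the oil baseline regardless of droplet
        # content; pointwise max keeps each apex exactly on its boundary sample
        sigma = params.boundary_peak_width_ms / 1000.0 * sr / 2.355  # FWHM -> sd, samples
        half = max(1, int(np.ceil(4 * sigma)))
        kernel_x = np.arange(-half, half + 1)
        kernel = params.oil_level + params.boundary_peak_amplitude * np.exp(
            -0.5 * (kernel_x / sigma) ** 2
        )
        for c in peak_centers:
            lo, hi = max(0, c - half), min(len(bright), c + half + 1)
            seg = bright[lo:hi]
            np.maximum(seg, kernel[lo - (c - half) : hi - (c - half)], out=seg)

    if params.noise_sd > 0:
        bright = bright + rng.normal(0.0, params.noise_sd, len(bright))
        fluor = fluor + rng.normal(0.0, params.noise_sd, len(fluor))

    return SyntheticTrace(bright=bright, fluor=fluor, sample_rate=sr, truth=truth)
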