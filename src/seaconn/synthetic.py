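"""Seeded generator of synthetic archipelago datasets.

Produces the full input bundle the analysis pipeline consumes — a
land/water mask forming contiguous island clumps, per-species three-class
habitat-suitability layers biased toward near-shore water, a coastal
disturbance-zone layer, and overlapping MPA polygons of mixed IUCN
categories — all as pure functions of (seed, scenario parameters).

Spatial structure comes from Gaussian-smoothed white-noise random fields
thresholded at quantiles, which yields contiguous patches with a
controllable autocorrelation length; coastal affinity is injected by
adding a distance-to-land decay term to the field before thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Point
from shapely.ops import unary_union

from .core import (DEFAULT_ALPHA, DisturbanceLayer, HabitatLayer, MPAPolygon,
                   MPAStatusLayer, SeascapeGrid, SpeciesProfile,
                   rasterize_mpas)

__all__ = [
    "SeascapeScenario",
    "generate_land_mask",
    "generate_habitat",
    "generate_species",
    "generate_disturbance",
    "generate_mpas",
    "generate_bundle",
]

# substream codes so every layer gets an independent, reproducible stream
_SUB_MASK, _SUB_DISTURBANCE, _SUB_MPA, _SUB_SPECIES = 1, 2, 3, 100


@dataclass(frozen=True)
class SeascapeScenario:
    """Parameters of one synthetic archipelago.

    Defaults give a 100 x 100 grid at 250 m resolution with 25% land,
    4 species with maximum dispersal distances of 1-10 km, coastal
    disturbance on 15% of the water, and an MPA network covering 10.5%
    of the study area of which 27% is strictly protected (echoing a
    coastal network with 2.8% strict protection inside 10.5% total).
    """

    seed: int = 0
    n_rows: int = 100
    n_cols: int = 100
    resolution: float = 250.0
    land_fraction: float = 0.25
    autocorrelation_length: float = 1000.0
    n_species: int = 4
    d_max_range: tuple[float, float] = (1000.0, 10000.0)
    disturbance_intensity: float = 0.15
    mpa_fraction: float = 0.105
    strict_fraction: float = 0.27
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        for name in ("land_fraction", "mpa_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        for name in ("disturbance_intensity", "strict_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.d_max_range[0] <= 0 or self.d_max_range[1] < self.d_max_range[0]:
            raise ValueError("d_max_range must be positive and ordered")


def _rng(scenario: SeascapeScenario, *codes: int) -> np.random.Generator:
    return np.random.default_rng([int(scenario.seed) & 0x7FFFFFFF, *codes])


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma_cells: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    return (f - f.mean()) / (f.std() + 1e-12)


def _coast_bias(water: np.ndarray, resolution: float,
                scale_m: float) -> np.ndarray:
    """exp(-distance_to_land / scale) on water; 0 where there is no land."""
    if water.all():
        return np.zeros(water.shape)
    dist = ndimage.distance_transform_edt(water) * resolution
    return np.exp(-dist / scale_m)


def generate_land_mask(scenario: SeascapeScenario) -> SeascapeGrid:
    """Threshold a smoothed random field into an archipelago land mask.

    The realized land fraction matches ``scenario.land_fraction`` to
    within +/-2 percentage points and the largest connected water body
    holds at least 80% of the water cells; candidate fields failing
    either check are deterministically re-drawn from the substream.
    """
    if scenario.land_fraction >= 1:
        raise ValueError("land_fraction must leave some water")
    shape = (scenario.n_rows, scenario.n_cols)
    sigma = scenario.autocorrelation_length / scenario.resolution
    origin = (0.0, scenario.n_rows * scenario.resolution)
    if scenario.land_fraction == 0:
        return SeascapeGrid(*shape, scenario.resolution, origin,
                            np.ones(shape, dtype=bool))
    for attempt in range(32):
        rng = _rng(scenario, _SUB_MASK, attempt)
        f = _smooth_field(rng, shape, sigma)
        thresh = np.quantile(f, 1.0 - scenario.land_fraction)
        water = f < thresh
        frac_land = 1.0 - water.mean()
        if abs(frac_land - scenario.land_fraction) > 0.02:
            continue
        labels, n_lab = ndimage.label(water)
        if n_lab == 0:
            continue
        largest = np.bincount(labels.ravel())[1:].max()
        if largest >= 0.8 * water.sum():
            return SeascapeGrid(*shape, scenario.resolution, origin, water)
    raise RuntimeError(
        "could not generate an archipelago meeting the land-fraction and "
        "water-connectedness constraints; adjust the scenario"
    )


# water-cell fractions assigned to the two positive habitat classes
_FRAC_VERY_GOOD = 0.05
_FRAC_GOOD = 0.10
# decay scales (m) of the near-shore bias for habitat and disturbance
_HABITAT_COAST_SCALE = 1500.0
_DISTURBANCE_COAST_SCALE = 750.0
# share of disturbed cells per zone 1..5 (non-increasing: higher zones rarer)
_ZONE_SHARES = (0.35, 0.25, 0.18, 0.13, 0.09)


def generate_habitat(scenario: SeascapeScenario, grid: SeascapeGrid,
                     species_index: int) -> HabitatLayer:
    """Three-class habitat layer for one species.

    An independent smoothed random field plus a distance-to-land decay
    (a shallow near-shore analogue) is quantile-thresholded over water
    cells: the top 5% become quality 1.0, the next 10% quality 0.5.
    """
    rng = _rng(scenario, _SUB_SPECIES + species_index)
    sigma = scenario.autocorrelation_length / scenario.resolution
    f = _smooth_field(rng, grid.shape, sigma)
    f = f + 1.5 * _coast_bias(grid.water_mask, grid.resolution,
                              _HABITAT_COAST_SCALE)
    scores = f[grid.water_mask]
    q1 = np.quantile(scores, 1.0 - _FRAC_VERY_GOOD)
    q2 = np.quantile(scores, 1.0 - _FRAC_VERY_GOOD - _FRAC_GOOD)
    quality = np.zeros(grid.shape)
    quality[grid.water_mask & (f >= q2)] = 0.5
    quality[grid.water_mask & (f >= q1)] = 1.0
    return HabitatLayer(grid, quality)


def generate_species(scenario: SeascapeScenario, grid: SeascapeGrid,
                     species_index: int) -> SpeciesProfile:
    """Habitat layer plus a d_max drawn uniformly from ``d_max_range``."""
    habitat = generate_habitat(scenario, grid, species_index)
    rng = _rng(scenario, _SUB_SPECIES + species_index, 1)
    lo, hi = scenario.d_max_range
    d_max = float(rng.uniform(lo, hi))
    return SpeciesProfile(f"species_{species_index}", habitat, d_max,
                          scenario.alpha)


def generate_disturbance(scenario: SeascapeScenario,
                         grid: SeascapeGrid) -> DisturbanceLayer:
    """Coast-clustered disturbance zones 0-5 (piers/marinas analogue).

    Exactly ``round(disturbance_intensity * n_water)`` water cells get a
    nonzero zone; within them, zone frequency decreases from 1 to 5 and
    the most obstructive zones sit closest to shore (highest scores).
    """
    rng = _rng(scenario, _SUB_DISTURBANCE)
    zones = np.zeros(grid.shape, dtype=np.int64)
    n_water = grid.n_water
    n_dist = int(round(scenario.disturbance_intensity * n_water))
    if n_dist == 0:
        return DisturbanceLayer(grid, zones)
    sigma = scenario.autocorrelation_length / scenario.resolution
    f = _smooth_field(rng, grid.shape, sigma)
    f = f + 3.0 * _coast_bias(grid.water_mask, grid.resolution,
                              _DISTURBANCE_COAST_SCALE)
    scores = f[grid.water_mask]
    order = np.argsort(scores)[::-1][:n_dist]  # most coastal first
    counts = [int(np.floor(s * n_dist)) for s in _ZONE_SHARES]
    for i in range(n_dist - sum(counts)):  # leftovers to low zones first
        counts[i % 5] += 1
    zone_seq = np.concatenate([
        np.full(counts[z - 1], z, dtype=np.int64) for z in range(5, 0, -1)
    ])
    water_flat = np.flatnonzero(grid.water_mask.ravel())
    zflat = zones.ravel()
    zflat[water_flat[order]] = zone_seq
    return DisturbanceLayer(grid, zflat.reshape(grid.shape))


def _blob(rng: np.random.Generator, cx: float, cy: float,
          radius: float) -> "Point":
    theta = rng.uniform(0, 2 * np.pi)
    off = 0.6 * radius
    return unary_union([
        Point(cx, cy).buffer(radius, quad_segs=8),
        Point(cx + off * np.cos(theta),
              cy + off * np.sin(theta)).buffer(0.7 * radius, quad_segs=8),
    ])


_STRICT_CATS = ("Ia", "Ib", "II")
_NONSTRICT_CATS = ("IV", "V", None)  # None = category not reported


def generate_mpas(scenario: SeascapeScenario,
                  grid: SeascapeGrid) -> list[MPAPolygon]:
    """Random blob MPAs covering ~``mpa_fraction`` of the water cells.

    Blobs are unions of two overlapping buffered points seeded at random
    water cells; each new blob is strict while the running strict share
    of covered area is below ``strict_fraction``. One deliberately
    overlapping strict/non-strict pair is always included (when any MPA
    exists) to exercise the strictest-designation rule.
    """
    if scenario.mpa_fraction == 0:
        return []
    rng = _rng(scenario, _SUB_MPA)
    n_water = grid.n_water
    target = scenario.mpa_fraction * n_water
    water_flat = np.flatnonzero(grid.water_mask.ravel())
    res = grid.resolution

    mpas: list[MPAPolygon] = []
    covered = np.zeros(grid.shape, dtype=bool)
    strict_covered = 0
    i_strict = i_non = 0
    guard = 0
    while covered[grid.water_mask].sum() < target - 0.005 * n_water \
            and guard < 500:
        guard += 1
        cell = water_flat[rng.integers(water_flat.size)]
        r, c = divmod(cell, grid.n_cols)
        cx, cy = grid.cell_center(np.array(r), np.array(c))
        radius = rng.uniform(2.5, 5.5) * res
        geom = _blob(rng, float(cx), float(cy), radius)
        add_strict = (strict_covered <
                      scenario.strict_fraction * max(covered[grid.water_mask].sum(), 1))
        if add_strict:
            cat = _STRICT_CATS[i_strict % 3]
            i_strict += 1
        else:
            cat = _NONSTRICT_CATS[i_non % 3]
            i_non += 1
        mpa = MPAPolygon(geom, cat)
        new = rasterize_mpas([mpa], grid).status > 0
        newly = new & grid.water_mask & ~covered
        # shrink rather than overshoot the coverage band
        while covered[grid.water_mask].sum() + newly.sum() > target + 0.015 * n_water \
                and radius > 1.5 * res:
            radius *= 0.7
            geom = _blob(rng, float(cx), float(cy), radius)
            mpa = MPAPolygon(geom, cat)
            new = rasterize_mpas([mpa], grid).status > 0
            newly = new & grid.water_mask & ~covered
        mpas.append(mpa)
        covered |= new
        if mpa.is_strict:
            strict_covered += int(newly.sum())
    if mpas:
        # guaranteed strict/non-strict overlap on at least one cell
        host = next((m for m in mpas if m.is_strict), mpas[0])
        cx, cy = host.geometry.centroid.x, host.geometry.centroid.y
        pair_cat = "V" if host.is_strict else "Ia"
        mpas.append(MPAPolygon(Point(cx, cy).buffer(1.2 * res, quad_segs=8),
                               pair_cat))
    return mpas


@dataclass
class ScenarioBundle:
    """Everything one synthetic archipelago provides to the pipeline."""

    scenario: SeascapeScenario
    grid: SeascapeGrid
    species: list[SpeciesProfile]
    disturbance: DisturbanceLayer
    mpas: list[MPAPolygon]
    mpa_status: MPAStatusLayer = field(repr=False, default=None)


def generate_bundle(scenario: SeascapeScenario) -> ScenarioBundle:
    """Generate the full scenario bundle (pure function of the scenario)."""
    grid = generate_land_mask(scenario)
    species = [generate_species(scenario, grid, i)
               for i in range(scenario.n_species)]
    disturbance = generate_disturbance(scenario, grid)
    mpas = generate_mpas(scenario, grid)
    return ScenarioBundle(scenario, grid, species, disturbance, mpas,
                          rasterize_mpas(mpas, grid))
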