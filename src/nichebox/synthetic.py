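"""Virtual-species scene and sequence simulation.

A *scene* is a complete synthetic study system: co-registered climate
rasters (linear spatial gradients plus independent Gaussian noise per
cell), a categorical soil mosaic (seeded Voronoi tessellation of random
centres, giving contiguous patches like a soil map), a small set of
rectangular administrative regions, and occurrence records sampled from
a known true envelope.  Because the truth is known, every downstream
stage — envelope fitting, suitability surfaces, variable importance,
area accounting — can be validated exactly.

Sequence alignments are evolved on a given tree under a two-parameter
substitution process (separate transition and transversion rates) so
that the expected pairwise distance under the matching estimator equals
the path length between leaves.

All randomness flows from explicit seeds; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geo_io import DEFAULT_VARIABLES, RasterGrid, RegionSet, VariableStack
from .phylo import PhyloTree, TreeNode

__all__ = [
    "TrueEnvelope",
    "SceneConfig",
    "Scene",
    "EmptyNicheError",
    "generate_scene",
    "simulate_alignment",
]

#: per-variable (low, high) of the default linear gradients, native units;
#: spans chosen to bracket the envelope ranges reported for temperate-to-
#: subtropical tuber crops (annual mean temperature in deg C, warmest/
#: coldest quarter means in deg C, precipitation in mm, radiation in
#: W m^-2, relative humidity in %)
DEFAULT_GRADIENTS = {
    "T-aver": (-10.0, 30.0),
    "T-warm": (0.0, 36.0),
    "T-cold": (-25.0, 28.0),
    "Precipitation": (0.0, 5000.0),
    "Radiation": (100.0, 230.0),
    "Humidity": (30.0, 85.0),
}

#: default gradient directions (unit-vector angles, degrees from east);
#: staggered so no two variables are perfectly collinear
DEFAULT_DIRECTIONS = {
    "T-aver": 90.0,
    "T-warm": 75.0,
    "T-cold": 105.0,
    "Precipitation": 0.0,
    "Radiation": 30.0,
    "Humidity": 150.0,
}


class EmptyNicheError(ValueError):
    """The requested true envelope matches no cell of the generated scene."""


@dataclass(frozen=True)
class TrueEnvelope:
    """Ground-truth niche: per-variable closed intervals plus allowed soils.

    ``components`` holds one or more per-variable interval mappings; a
    climate vector is inside the envelope when it falls inside any
    component's box on every variable.  Most scenes use one component.
    """

    components: tuple[dict, ...]
    soil_classes: frozenset[int]

    def __post_init__(self):
        if len(self.components) < 1:
            raise ValueError("need at least one niche component")
        if not self.soil_classes:
            raise ValueError("allowed soil-class set must be non-empty")
        for comp in self.components:
            for v, (lo, hi) in comp.items():
                if lo > hi:
                    raise ValueError(f"variable {v!r}: interval low {lo} exceeds high {hi}")
        object.__setattr__(self, "soil_classes", frozenset(int(s) for s in self.soil_classes))

    @classmethod
    def single(cls, intervals: dict, soil_classes) -> "TrueEnvelope":
        return cls(components=(dict(intervals),), soil_classes=frozenset(soil_classes))

    def climate_inside(self, values: np.ndarray, variables) -> np.ndarray:
        """Boolean per row of a (n, n_var) native-unit matrix."""
        values = np.atleast_2d(values)
        inside_any = np.zeros(values.shape[0], dtype=bool)
        for comp in self.components:
            inside = np.ones(values.shape[0], dtype=bool)
            for j, v in enumerate(variables):
                if v in comp:
                    lo, hi = comp[v]
                    inside &= (values[:, j] >= lo) & (values[:, j] <= hi)
            inside_any |= inside
        return inside_any


@dataclass(frozen=True)
class SceneConfig:
    """Knobs of the synthetic scene generator."""

    rows: int = 40
    cols: int = 40
    bounds: tuple[float, float, float, float] = (-20.0, 0.0, 20.0, 40.0)  # W, S, E, N
    variables: tuple[str, ...] = DEFAULT_VARIABLES
    gradient_ranges: dict = field(default_factory=lambda: dict(DEFAULT_GRADIENTS))
    gradient_directions: dict = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    noise_sd: dict = field(default_factory=dict)      # native units per variable; default 0
    n_soil_classes: int = 5
    n_occurrences: int = 200
    detection_noise: float = 0.0                      # fraction mis-georeferenced
    seed: int = 0

    def __post_init__(self):
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.n_occurrences < 1:
            raise ValueError("need at least one occurrence")
        if not 0.0 <= self.detection_noise <= 1.0:
            raise ValueError("detection-noise fraction must be in [0, 1]")
        w, s, e, n = self.bounds
        if not (-180 <= w < e <= 180 and -90 <= s < n <= 90):
            raise ValueError("bounds must be a valid lon/lat box")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise standard deviations must be non-negative")


@dataclass
class Scene:
    """Everything generate_scene produces, plus the truth that made it."""

    stack: VariableStack
    soil: RasterGrid
    regions: RegionSet
    occurrences: pd.DataFrame
    truth: TrueEnvelope
    config: SceneConfig

    def true_mask(self) -> np.ndarray:
        """Boolean grid of cells inside the true envelope with allowed soil."""
        cells = self.stack.cell_matrix(np.ones(self.soil.shape, dtype=bool))
        climate_ok = self.truth.climate_inside(cells, self.stack.variables)
        soil_ok = np.isin(self.soil.data.astype(int), sorted(self.truth.soil_classes))
        return climate_ok.reshape(self.soil.shape) & soil_ok


def _gradient_field(rows, cols, angle_deg, lo, hi):
    """Linear ramp across the grid along the given direction, spanning [lo, hi]."""
    theta = np.deg2rad(angle_deg)
    yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    # projection onto the gradient direction, normalized to [0, 1]
    t = (xx * np.cos(theta) + (rows - 1 - yy) * np.sin(theta))
    t = (t - t.min()) / max(t.max() - t.min(), 1e-12)
    return lo + t * (hi - lo)


def _voronoi_mosaic(rows, cols, n_classes, rng):
    centers = rng.uniform(size=(n_classes, 2)) * [rows, cols]
    yy, xx = np.meshgrid(np.arange(rows) + 0.5, np.arange(cols) + 0.5, indexing="ij")
    d2 = (yy[..., None] - centers[:, 0]) ** 2 + (xx[..., None] - centers[:, 1]) ** 2
    return d2.argmin(axis=-1)


def _quadrant_regions(bounds) -> RegionSet:
    """Two 'continents' split into two 'countries' each, covering the bounds."""
    w, s, e, n = bounds
    xm, ym = (w + e) / 2, (s + n) / 2
    entries = [
        ("West", "continent", None, box(w, s, xm, n)),
        ("East", "continent", None, box(xm, s, e, n)),
        ("Northwest", "country", "West", box(w, ym, xm, n)),
        ("Southwest", "country", "West", box(w, s, xm, ym)),
        ("Northeast", "country", "East", box(xm, ym, e, n)),
        ("Southeast", "country", "East", box(xm, s, e, ym)),
    ]
    return RegionSet(entries)


def generate_scene(config: SceneConfig, truth: TrueEnvelope,
                   species: str = "Virtual species") -> Scene:
    """Build a synthetic scene whose suitable footprint is known exactly.

    Occurrences are placed at the centres of cells drawn uniformly (with
    replacement) from the cells inside *truth*; a ``detection_noise``
    fraction is then re-drawn uniformly over the whole grid, emulating
    mis-georeferenced records.  Generation is a pure function of
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.rows, config.cols
    w, s, e, n = config.bounds
    dx = (e - w) / cols
    dy = (n - s) / rows
    grids = {}
    for v in config.variables:
        lo, hi = config.gradient_ranges[v]
        fieldv = _gradient_field(rows, cols, config.gradient_directions.get(v, 0.0), lo, hi)
        sd = config.noise_sd.get(v, 0.0)
        if sd > 0:
            fieldv = fieldv + rng.normal(0.0, sd, size=fieldv.shape)
        grids[v] = RasterGrid(data=fieldv, west=w, north=n, dx=dx, dy=dy)
    stack = VariableStack(grids)
    soil = RasterGrid(
        data=_voronoi_mosaic(rows, cols, config.n_soil_classes, rng).astype(float),
        west=w, north=n, dx=dx, dy=dy,
    )
    regions = _quadrant_regions(config.bounds)

    cells = stack.cell_matrix(np.ones((rows, cols), dtype=bool))
    climate_ok = truth.climate_inside(cells, config.variables)
    soil_ok = np.isin(soil.data.astype(int).ravel(), sorted(truth.soil_classes))
    suitable = climate_ok & soil_ok
    if not suitable.any():
        per_var_hits = []
        for j, v in enumerate(config.variables):
            hits = 0
            for comp in truth.components:
                if v in comp:
                    lo, hi = comp[v]
                    hits += int(((cells[:, j] >= lo) & (cells[:, j] <= hi)).sum())
                else:
                    hits += cells.shape[0]
            per_var_hits.append((hits, v))
        if not climate_ok.any():
            constraining = min(per_var_hits)[1]
        else:
            constraining = "soil"
        raise EmptyNicheError(
            f"true envelope matches no cell; most constraining factor: {constraining}"
        )

    # cells are drawn by cycling random permutations of the suitable set:
    # marginally uniform, and every suitable cell is sampled once n reaches
    # the suitable-cell count, so a large sample pins the envelope exactly
    flat_idx = np.flatnonzero(suitable)
    reps = -(-config.n_occurrences // len(flat_idx))
    chosen = np.concatenate(
        [rng.permutation(flat_idx) for _ in range(reps)]
    )[: config.n_occurrences]
    n_noisy = int(round(config.detection_noise * config.n_occurrences))
    if n_noisy > 0:
        noisy_pos = rng.choice(config.n_occurrences, size=n_noisy, replace=False)
        chosen[noisy_pos] = rng.integers(0, rows * cols, size=n_noisy)
    r, c = np.unravel_index(chosen, (rows, cols))
    lon, lat = stack.reference.cell_center(r, c)
    occ = pd.DataFrame(
        {
            "species": species,
            "longitude": lon,
            "latitude": lat,
            "source": "synthetic",
        }
    )
    return Scene(stack=stack, soil=soil, regions=regions, occurrences=occ,
                 truth=truth, config=config)


# ---------------------------------------------------------------------------
# sequence simulation under the two-parameter substitution process

_BASES = np.array(list("ACGT"))
#: transition partner of each base index (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1])


def _k2p_probs(d: float, kappa: float) -> np.ndarray:
    """4x4 substitution matrix for branch length *d* (subs/site).

    ``kappa`` is the transition/transversion *rate* ratio alpha/beta;
    rates are scaled so the total substitution rate is 1 per site per
    unit branch length, hence the expected corrected distance between
    the branch ends equals *d*.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * d)                 # transversion decay
    e2 = np.exp(-2.0 * (alpha + beta) * d)       # transition decay
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1                      # each of the two targets
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    for i, j in enumerate(_TRANSITION):
        P[i, j] = p_ts
    return P


def simulate_alignment(tree: PhyloTree, length: int, rate_ratio: float = 2.0,
                       seed: int = 0) -> dict[str, str]:
    """Evolve sequences down *tree* under the two-parameter model.

    Returns ``{leaf name: sequence}`` over the alphabet ACGT.  Branch
    lengths are expected substitutions per site and must be >= 0; the
    root state is uniform over bases.  Same seed, same alignment.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    for node in tree.root.walk():
        if node is not tree.root and node.length is not None and node.length < 0:
            raise ValueError("negative branch length")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}

    def descend(node: TreeNode, states: np.ndarray):
        for child in node.children:
            d = child.length or 0.0
            if d == 0.0:
                child_states = states
            else:
                P = _k2p_probs(d, rate_ratio)
                u = rng.random(length)
                cum = P[states].cumsum(axis=1)
                child_states = (u[:, None] < cum).argmax(axis=1)
            if child.is_leaf():
                seqs[child.name] = "".join(_BASES[child_states])
            else:
                descend(child, child_states)
        if node.is_leaf():  # single-node tree edge case
            seqs[node.name] = "".join(_BASES[states])

    root_states = rng.integers(0, 4, size=length)
    descend(tree.root, root_states)
    return seqs
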