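"""Climate-envelope suitability core.

The model relates occurrence records to climate layers in four steps:

1. *Linear normalization* — every layer is rescaled onto [0, 100] using
   its own valid-cell minimum and maximum,
   ``v' = (v - min_A) / (max_A - min_A) * 100``.
2. *Range-based clustering* — occurrence climate vectors are grouped by
   an alternating assign/update scheme in which a cluster is summarised
   by its *scope* d_i, the per-variable [min, max] hyper-rectangle over
   its members, and a point's distance to a scope is zero inside the
   rectangle and otherwise the Euclidean norm of the per-variable gaps
   to the nearer rectangle edge.  The objective is
   ``E = sum_i sum_{p in D_i} dist(p, d_i)^2``.
3. *Envelope distance surface* — every grid cell's normalized climate
   vector is scored by its smallest distance to any cluster scope.
4. *Soil intersection* — cells whose soil class was never observed at
   an occurrence are unsuitable regardless of climate.

A cell is counted *suitable* when its envelope distance is exactly zero
and its soil class is allowed; the continuous suitability value maps
distance onto (0, 0.999], with 0.999 marking best habitat.

With k = 1 the binary mask reduces to the classic rectangular-envelope
(BIOCLIM-style) inclusion test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo_io import RasterGrid, VariableStack

__all__ = [
    "NormalizationParams",
    "ClusterSet",
    "EnvelopeProfile",
    "SuitabilitySurface",
    "fit_normalization",
    "point_distance",
    "fit_clusters",
    "build_profile",
    "distance_surface",
    "suitability_transform",
    "profile_report",
]

NEW_MIN, NEW_MAX = 0.0, 100.0


@dataclass(frozen=True)
class NormalizationParams:
    """Per-layer min/max used by the linear [0, 100] rescaling."""

    variables: tuple[str, ...]
    min_a: np.ndarray
    max_a: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.min_a, dtype=float)
        hi = np.asarray(self.max_a, dtype=float)
        if np.any(hi <= lo):
            bad = self.variables[int(np.argmax(hi <= lo))]
            raise ValueError(f"constant layer {bad!r}: max_A must exceed min_A")
        object.__setattr__(self, "min_a", lo)
        object.__setattr__(self, "max_a", hi)

    def normalize(self, values, variable: str | None = None):
        """Map native values to normalized units.

        Values outside [min_A, max_A] extrapolate linearly; they are not
        clipped (occurrence values can fall outside layer statistics).
        """
        v = np.asarray(values, dtype=float)
        if variable is not None:
            j = self.variables.index(variable)
            return (v - self.min_a[j]) / (self.max_a[j] - self.min_a[j]) * (NEW_MAX - NEW_MIN)
        return (v - self.min_a) / (self.max_a - self.min_a) * (NEW_MAX - NEW_MIN)

    def denormalize(self, values):
        v = np.asarray(values, dtype=float)
        return v / (NEW_MAX - NEW_MIN) * (self.max_a - self.min_a) + self.min_a

    def subset(self, variables) -> "NormalizationParams":
        idx = [self.variables.index(v) for v in variables]
        return NormalizationParams(tuple(variables), self.min_a[idx], self.max_a[idx])


def fit_normalization(stack: VariableStack) -> NormalizationParams:
    """Layer statistics over valid cells (not over occurrences)."""
    mins, maxs = [], []
    for g in stack.grids.values():
        vals = g.data[g.valid_mask()]
        if vals.size == 0:
            raise ValueError("layer has no valid cells")
        mins.append(vals.min())
        maxs.append(vals.max())
    return NormalizationParams(tuple(stack.variables), np.array(mins), np.array(maxs))


# ---------------------------------------------------------------------------
# range distance and clustering

def _gap_components(points: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Per-variable distance to the nearer scope edge; 0 inside the range."""
    return np.maximum(np.maximum(lo - points, points - hi), 0.0)


def point_distance(p, scope_lo, scope_hi) -> float | np.ndarray:
    """Distance of normalized vector(s) *p* to a cluster scope.

    Per variable the component is 0 when ``lo <= v <= hi`` and otherwise
    ``min(|v - lo|, |v - hi|)``; components aggregate as the Euclidean
    norm.  The squared aggregate is the clustering-objective summand.
    """
    p = np.asarray(p, dtype=float)
    lo = np.asarray(scope_lo, dtype=float)
    hi = np.asarray(scope_hi, dtype=float)
    if p.shape[-1] != lo.shape[-1] or lo.shape != hi.shape:
        raise ValueError("dimension mismatch between point and scope")
    gaps = _gap_components(p, lo, hi)
    return np.sqrt((gaps**2).sum(axis=-1))


@dataclass
class ClusterSet:
    """Result of range-based clustering on normalized climate points."""

    k: int
    labels: np.ndarray            # (n,) cluster index per point
    scopes_lo: np.ndarray         # (k, n_var)
    scopes_hi: np.ndarray         # (k, n_var)
    objective: float              # E on the final partition
    history: tuple = ()           # E after each assign/update sweep

    def member_indices(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.labels == i)


def objective_value(points: np.ndarray, labels: np.ndarray,
                    scopes_lo: np.ndarray, scopes_hi: np.ndarray) -> float:
    """E = sum over clusters of squared member distances to the cluster scope."""
    d = point_distance(points, scopes_lo[labels], scopes_hi[labels])
    return float((d**2).sum())


def scopes_from_labels(points: np.ndarray, labels: np.ndarray, k: int):
    lo = np.empty((k, points.shape[1]))
    hi = np.empty((k, points.shape[1]))
    for i in range(k):
        members = points[labels == i]
        if members.size == 0:
            raise ValueError(f"cluster {i} is empty")
        lo[i] = members.min(axis=0)
        hi[i] = members.max(axis=0)
    return lo, hi


def _distances_to_scopes(points: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """(n, k) matrix of range distances."""
    gaps = _gap_components(points[:, None, :], lo[None], hi[None])
    return np.sqrt((gaps**2).sum(axis=-1))


def _fit_once(points: np.ndarray, k: int, rng: np.random.Generator,
              max_iter: int, tol: float) -> ClusterSet:
    n = points.shape[0]
    seed_idx = rng.choice(n, size=k, replace=False)
    lo = points[seed_idx].copy()
    hi = points[seed_idx].copy()
    labels = np.full(n, -1)
    prev_e = np.inf
    history = []
    for _ in range(max_iter):
        dist = _distances_to_scopes(points, lo, hi)
        new_labels = dist.argmin(axis=1)  # argmin ties -> lowest cluster index
        # re-seed empty clusters from the most remote point
        for i in range(k):
            if not np.any(new_labels == i):
                worst = int(np.argmax(dist[np.arange(n), new_labels]))
                new_labels[worst] = i
        lo, hi = scopes_from_labels(points, new_labels, k)
        e = objective_value(points, new_labels, lo, hi)
        history.append(e)
        stable = np.array_equal(new_labels, labels)
        labels = new_labels
        if stable or prev_e - e < tol:
            prev_e = e
            break
        prev_e = e
    return ClusterSet(k=k, labels=labels, scopes_lo=lo, scopes_hi=hi,
                      objective=prev_e, history=tuple(history))


def fit_clusters(points: np.ndarray, k: int, seed: int = 0,
                 max_iter: int = 100, tol: float = 1e-9,
                 restarts: int = 10) -> ClusterSet:
    """Alternating assign/update clustering under the range distance.

    Runs ``restarts`` seeded initialisations (seeds ``seed .. seed+m-1``)
    and keeps the lowest final objective, first-found on ties.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D matrix")
    n = points.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    if np.isnan(points).any():
        raise ValueError("points contain missing values")
    best = None
    for m in range(max(1, restarts)):
        cs = _fit_once(points, k, np.random.default_rng(seed + m), max_iter, tol)
        if best is None or cs.objective < best.objective - 1e-15:
            best = cs
    return best


# ---------------------------------------------------------------------------
# profiles

@dataclass
class EnvelopeProfile:
    """A species' fitted envelope: native-unit ranges, soil set, clusters."""

    species: str
    variables: tuple[str, ...]
    range_lo: np.ndarray          # native units, per variable
    range_hi: np.ndarray
    soil_classes: frozenset[int]
    clusters: ClusterSet
    params: NormalizationParams

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "variables": list(self.variables),
            "range_lo": self.range_lo.tolist(),
            "range_hi": self.range_hi.tolist(),
            "soil_classes": sorted(self.soil_classes),
            "normalization": {
                "min_a": self.params.min_a.tolist(),
                "max_a": self.params.max_a.tolist(),
            },
            "clusters": {
                "k": self.clusters.k,
                "scopes_lo": self.clusters.scopes_lo.tolist(),
                "scopes_hi": self.clusters.scopes_hi.tolist(),
                "objective": self.clusters.objective,
                "labels": self.clusters.labels.tolist(),
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "EnvelopeProfile":
        with open(path) as fh:
            d = json.load(fh)
        params = NormalizationParams(
            tuple(d["variables"]),
            np.array(d["normalization"]["min_a"]),
            np.array(d["normalization"]["max_a"]),
        )
        cl = d["clusters"]
        clusters = ClusterSet(
            k=cl["k"],
            labels=np.array(cl["labels"], dtype=int),
            scopes_lo=np.array(cl["scopes_lo"]),
            scopes_hi=np.array(cl["scopes_hi"]),
            objective=cl["objective"],
        )
        return cls(
            species=d["species"],
            variables=tuple(d["variables"]),
            range_lo=np.array(d["range_lo"]),
            range_hi=np.array(d["range_hi"]),
            soil_classes=frozenset(d["soil_classes"]),
            clusters=clusters,
            params=params,
        )


def build_profile(climates: np.ndarray, soils, species: str,
                  params: NormalizationParams, k: int = 1, seed: int = 0,
                  restarts: int = 10) -> EnvelopeProfile:
    """Fit a species envelope from occurrence climates and soil classes.

    ``climates`` is a native-unit matrix (one row per valid occurrence,
    columns in ``params.variables`` order); ``soils`` the soil class at
    each occurrence cell.  The native range is the per-variable min/max;
    the allowed soil set the distinct observed classes; the cluster
    structure is fitted on normalized values.
    """
    climates = np.atleast_2d(np.asarray(climates, dtype=float))
    if climates.shape[0] == 0 or np.isnan(climates).all():
        raise ValueError("no valid occurrences to build a profile from")
    keep = ~np.isnan(climates).any(axis=1)
    climates = climates[keep]
    soils = np.asarray(soils)[keep]
    normalized = params.normalize(climates)
    kk = min(k, climates.shape[0])
    clusters = fit_clusters(normalized, kk, seed=seed, restarts=restarts)
    return EnvelopeProfile(
        species=species,
        variables=params.variables,
        range_lo=climates.min(axis=0),
        range_hi=climates.max(axis=0),
        soil_classes=frozenset(int(s) for s in soils),
        clusters=clusters,
        params=params,
    )


# ---------------------------------------------------------------------------
# surfaces

@dataclass
class SuitabilitySurface:
    """Per-cell envelope distance, continuous suitability, and binary mask."""

    distance: RasterGrid
    suitability: RasterGrid | None
    mask: np.ndarray | None       # boolean; nodata cells are False
    species: str
    provenance: dict = field(default_factory=dict)


def distance_surface(stack: VariableStack, profile: EnvelopeProfile) -> SuitabilitySurface:
    """Minimum range distance of every valid cell to any cluster scope."""
    if tuple(stack.variables) != tuple(profile.variables):
        raise ValueError(
            f"variable set mismatch: stack {stack.variables} vs profile {list(profile.variables)}"
        )
    ref = stack.reference
    valid = stack.valid_mask()
    cells = stack.cell_matrix(valid)
    norm = profile.params.normalize(cells)
    dmin = _distances_to_scopes(norm, profile.clusters.scopes_lo,
                                profile.clusters.scopes_hi).min(axis=1)
    out = np.full(ref.shape, ref.nodata, dtype=float)
    out[valid] = dmin
    grid = ref.with_data(out)
    return SuitabilitySurface(distance=grid, suitability=None, mask=None,
                              species=profile.species,
                              provenance={"k": profile.clusters.k})


def suitability_transform(surface: SuitabilitySurface, soil: RasterGrid,
                          profile: EnvelopeProfile) -> SuitabilitySurface:
    """Complete a surface: continuous 0–0.999 suitability and binary mask.

    ``s = 0.999 * exp(-D / sigma)`` with sigma the median of positive
    distances over valid cells (fallback 1 when no positive distance
    exists), then zeroed wherever the soil class is not allowed.  The
    binary mask is ``D == 0`` and soil allowed.
    """
    dist = surface.distance
    valid = dist.valid_mask() & soil.valid_mask()
    d = dist.data
    pos = d[valid & (d > 0)]
    sigma = float(np.median(pos)) if pos.size else 1.0
    s = np.full(dist.shape, dist.nodata, dtype=float)
    s[valid] = 0.999 * np.exp(-d[valid] / sigma)
    allowed = np.isin(soil.data.astype(int), sorted(profile.soil_classes))
    s[valid & ~allowed] = 0.0
    mask = valid & (d == 0) & allowed
    prov = dict(surface.provenance, sigma=sigma, species=profile.species)
    return SuitabilitySurface(distance=dist, suitability=dist.with_data(s),
                              mask=mask, species=profile.species, provenance=prov)


def profile_report(profiles) -> pd.DataFrame:
    """Per-species table of native-unit variable ranges and soil classes."""
    rows = []
    for p in profiles:
        row = {"species": p.species}
        for j, v in enumerate(p.variables):
            row[f"{v}_min"] = p.range_lo[j]
            row[f"{v}_max"] = p.range_hi[j]
        row["soil_classes"] = ";".join(str(s) for s in sorted(p.soil_classes))
        rows.append(row)
    return pd.DataFrame(rows)
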