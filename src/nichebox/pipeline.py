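"""End-to-end orchestration: occurrences + layers -> profiles, surfaces,
area tables, contribution tables, and a checksummed manifest.

Every artifact lands under one run directory; reruns with the same
inputs and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import areas as areas_mod
from . import envelope as env_mod
from . import geo_io
from .importance import SplitSpec, jackknife

logger = logging.getLogger("nichebox")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    occurrences: Path
    climate_dir: Path              # one ASCII grid per variable: <name>.asc
    soil: Path
    regions: Path
    out_dir: Path
    variables: tuple[str, ...] = geo_io.DEFAULT_VARIABLES
    k: int = 1
    restarts: int = 10
    seed: int = 0
    train_fraction: float = 0.75
    run_jackknife: bool = True
    background_cells: int = 5000   # background subsample size for the jackknife

    def __post_init__(self):
        for name in ("occurrences", "climate_dir", "soil", "regions"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        self.out_dir = Path(self.out_dir)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = json.load(fh)
    if "variables" in raw:
        raw["variables"] = tuple(raw["variables"])
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_inputs(config: RunConfig):
    occ = geo_io.read_occurrences(config.occurrences)
    grids = {}
    for v in config.variables:
        p = Path(config.climate_dir) / f"{v}.asc"
        if not p.exists():
            raise FileNotFoundError(f"climate layer missing: {p}")
        grids[v] = geo_io.read_ascii_grid(p)
    stack = geo_io.VariableStack(grids)
    soil = geo_io.read_ascii_grid(config.soil)
    geo_io.align_check(stack, soil, names=["soil"])
    regions = geo_io.read_regions(config.regions)
    return occ, stack, soil, regions


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every species; return the manifest dict."""
    occ, stack, soil, regions = load_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = env_mod.fit_normalization(stack)
    extracted = geo_io.extract_at_points(stack, occ)
    soil_rows, soil_cols = stack.reference.index_of(
        occ["longitude"].to_numpy(), occ["latitude"].to_numpy()
    )
    valid_bg = stack.valid_mask()
    background = stack.cell_matrix(valid_bg)
    rng = np.random.default_rng(config.seed)
    if background.shape[0] > config.background_cells:
        sel = rng.choice(background.shape[0], config.background_cells, replace=False)
        background = background[sel]

    artifacts: list[Path] = []
    profiles = []
    area_tables = []
    for stage, species in (("species-loop", sp) for sp in sorted(occ["species"].unique())):
        sel = (occ["species"] == species).to_numpy() & extracted["valid"].to_numpy()
        if not sel.any():
            raise RuntimeError(f"stage {stage}: no valid occurrences for {species}")
        climates = extracted.loc[sel, list(config.variables)].to_numpy()
        occ_soil = soil.data[soil_rows[sel], soil_cols[sel]].astype(int)
        tag = species.replace(" ", "_")
        try:
            profile = env_mod.build_profile(
                climates, occ_soil, species, params,
                k=config.k, seed=config.seed, restarts=config.restarts,
            )
            profiles.append(profile)
            profile.save(out / f"profile_{tag}.json")
            artifacts.append(out / f"profile_{tag}.json")

            surface = env_mod.distance_surface(stack, profile)
            surface = env_mod.suitability_transform(surface, soil, profile)
            geo_io.write_ascii_grid(surface.suitability, out / f"suitability_{tag}.asc")
            mask_grid = stack.reference.with_data(surface.mask.astype(float))
            geo_io.write_ascii_grid(mask_grid, out / f"mask_{tag}.asc")
            artifacts += [out / f"suitability_{tag}.asc", out / f"mask_{tag}.asc"]

            table = areas_mod.area_by_region(surface.mask, stack.reference,
                                             regions, species=species)
            area_tables.append(table)

            if config.run_jackknife:
                contrib = jackknife(
                    climates, occ_soil, background, params,
                    SplitSpec(config.train_fraction, config.seed),
                    k=config.k, seed=config.seed, species=species,
                )
                contrib.insert(0, "species", species)
                contrib.to_csv(out / f"contributions_{tag}.csv", index=False)
                artifacts.append(out / f"contributions_{tag}.csv")
        except Exception as exc:
            raise RuntimeError(f"stage failed for species {species!r}: {exc}") from exc

    report = env_mod.profile_report(profiles)
    report.to_csv(out / "profile_report.csv", index=False)
    artifacts.append(out / "profile_report.csv")
    combined = pd.concat(area_tables, ignore_index=True)
    combined.to_csv(out / "areas.csv", index=False, float_format="%.6f")
    artifacts.append(out / "areas.csv")

    manifest = {
        "seed": config.seed,
        "k": config.k,
        "species": sorted(occ["species"].unique()),
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return manifest
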