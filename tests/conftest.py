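import numpy as np
import pytest

import nichebox as nb


@pytest.fixture(scope="session")
def truth():
    return nb.TrueEnvelope.single(
        {"T-aver": (5.0, 22.0), "Precipitation": (400.0, 1800.0)},
        soil_classes={0, 1, 2},
    )


@pytest.fixture(scope="session")
def scene(truth):
    """Noise-free 40x40 virtual-species scene with 200 occurrences."""
    return nb.generate_scene(nb.SceneConfig(seed=7), truth)


@pytest.fixture(scope="session")
def scene_data(scene):
    """Extracted occurrence climates, soils, normalization params."""
    params = nb.fit_normalization(scene.stack)
    ext = nb.extract_at_points(scene.stack, scene.occurrences)
    r, c = scene.stack.reference.index_of(
        scene.occurrences["longitude"].to_numpy(),
        scene.occurrences["latitude"].to_numpy(),
    )
    soils = scene.soil.data[r, c].astype(int)
    climates = ext[list(scene.stack.variables)].to_numpy()
    return {"params": params, "climates": climates, "soils": soils,
            "extracted": ext}


@pytest.fixture(scope="session")
def profile(scene, scene_data):
    return nb.build_profile(
        scene_data["climates"], scene_data["soils"], "Virtual species",
        scene_data["params"], k=1, seed=0,
    )


@pytest.fixture(scope="session")
def surface(scene, profile):
    surf = nb.distance_surface(scene.stack, profile)
    return nb.suitability_transform(surf, scene.soil, profile)


@pytest.fixture(scope="session")
def balanced_tree():
    """Five-taxon tree with a long internal branch separating two clades."""
    return nb.PhyloTree.from_newick(
        "((A:0.05,B:0.05):0.15,(C:0.05,D:0.05):0.15,E:0.2);"
    )


def small_grid(data, west=0.0, north=4.0, cell=1.0, nodata=-9999.0):
    return nb.RasterGrid(data=np.asarray(data, float), west=west, north=north,
                         dx=cell, dy=cell, nodata=nodata)
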