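"""Shared fixtures: small meshes, generator datasets, cached geodesics.

Everything is generated programmatically; session scope keeps the expensive
objects (matched surface pairs, geodesic matrices) shared across tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from cortevo import mesh as cmesh
from cortevo import synth
from cortevo.correspondence import MatchConfig, match_surfaces

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def ico2() -> cmesh.SurfaceMesh:
    return cmesh.icosphere(2)


@pytest.fixture(scope="session")
def ico3() -> cmesh.SurfaceMesh:
    return cmesh.icosphere(3)


@pytest.fixture(scope="session")
def ico2_dists(ico2):
    return cmesh.all_pairs_geodesics(ico2)


@pytest.fixture(scope="session")
def ico3_dists(ico3):
    return cmesh.all_pairs_geodesics(ico3)


@pytest.fixture(scope="session")
def rippled_sphere() -> cmesh.SurfaceMesh:
    """Sphere with azimuthal folds: GI > 1, nonzero sulcal depth."""
    base = cmesh.icosphere(3)
    v = base.vertices
    th = np.arctan2(v[:, 1], v[:, 0])
    z = v[:, 2]
    r = 1 + 0.12 * np.sin(8 * th) * np.sin(np.pi * z) * (1 - z ** 2)
    return cmesh.SurfaceMesh(v * r[:, None], base.faces)


@pytest.fixture(scope="session")
def sister_pair_level2():
    """Generator sister pair (level 2) with labels and a full correspondence."""
    tree = synth.simulate_tree(2, 35.0, seed=7)
    gen = synth.GeneratorConfig(n_tips=2, icosphere_level=2)
    truth = synth.simulate_surfaces(tree, gen, seed=8)
    A, B = truth.node_meshes[0], truth.node_meshes[1]
    la = synth.make_label_fields(A, truth.label_seeds)
    lb = synth.make_label_fields(B, truth.label_seeds)
    corr = match_surfaces(A, B, MatchConfig(), labelsA=la, labelsB=lb)
    return {"tree": tree, "truth": truth, "A": A, "B": B,
            "labelsA": la, "labelsB": lb, "corr": corr}


@pytest.fixture(scope="session")
def small_generator_dataset():
    """6-tip level-2 dataset with ecology, no correspondence run."""
    tree = synth.simulate_tree(6, 70.0, seed=5)
    gen = synth.GeneratorConfig(n_tips=6, icosphere_level=2)
    truth = synth.simulate_surfaces(tree, gen, seed=6)
    ecology, info = synth.simulate_ecology(tree, truth, seed=7)
    return {"tree": tree, "truth": truth, "ecology": ecology, "eco_info": info}
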