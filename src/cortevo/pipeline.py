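"""End-to-end orchestration: simulate → match/reconstruct → phylogenetic
modelling → spatial statistics → ecology analysis.

The pipeline is a plain Python function over a validated configuration
object. Every stage writes its artifacts (OFF meshes, Newick trees, CSV
tables, JSON summaries) into a run directory together with a manifest
recording the stage sequence, per-stage seeds (derived from the global seed
by stable hashing of stage names) and a hash of the configuration, so a
re-run from the same configuration reproduces every stochastic stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .ancestral import ShellConfig, reconstruct_tree
from .correspondence import MatchConfig
from .eco import HabitatScale, decode_map, parcel_tests, rmcorr, screen_modes
from .mesh import SurfaceMesh, VertexField, all_pairs_geodesics, icosphere
from .phylo import PhyloTree, TraitMatrix, fit_model, phylo_pca, select_model
from .spatial import empirical_variogram, fit_variogram, surrogate_maps
from .synth import (GeneratorConfig, make_label_fields, simulate_ecology,
                    simulate_modal_maps, simulate_surfaces, simulate_tree)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "stage_seed"]


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic run.

    Unknown keys in a YAML/JSON source are rejected rather than ignored.
    """

    out_dir: str = "cortevo_run"
    seed: int = 0
    n_tips: int = 10
    icosphere_level: int = 3
    depth_myr: float = 70.0
    n_modes: int = 8
    n_surrogates: int = 1000
    n_terms: int = 150
    n_parcels: int = 12
    trait_subsample: int = 162
    modal_target_range: float = 0.4
    generator: dict = field(default_factory=dict)
    match: dict = field(default_factory=dict)
    shell: dict = field(default_factory=dict)
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "reconstruct", "phylo", "variogram", "eco"])

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # a location, not a scientific parameter
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: crc32 of the stage name mixed with the global seed."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2 ** 31)


def _subconfigs(cfg: PipelineConfig) -> tuple[GeneratorConfig, MatchConfig, ShellConfig]:
    gen = GeneratorConfig(n_tips=cfg.n_tips, icosphere_level=cfg.icosphere_level,
                          depth_myr=cfg.depth_myr,
                          modal_target_range=cfg.modal_target_range,
                          **cfg.generator)
    return gen, MatchConfig(**cfg.match), ShellConfig(**cfg.shell)


def run_pipeline(config: PipelineConfig, return_state: bool = False):
    """Execute the configured stages; returns the manifest (also written to disk).

    Stage failure raises with the stage name; artifacts of completed stages
    stay on disk. With ``return_state`` the in-memory objects of every stage
    (ground truth, reconstruction, statistics tables) are returned alongside
    the manifest for programmatic use.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    gen_cfg, match_cfg, shell_cfg = _subconfigs(config)
    manifest: dict = {"config_hash": config.config_hash(), "stages": [],
                      "seeds": {}, "artifacts": {}}
    state: dict = {}
    for stage in config.stages:
        seed = stage_seed(config.seed, stage)
        manifest["seeds"][stage] = seed
        fn = _STAGES.get(stage)
        if fn is None:
            raise ValueError(f"unknown stage '{stage}'")
        try:
            artifacts = fn(config, gen_cfg, match_cfg, shell_cfg, seed, state)
        except Exception as exc:
            _write_manifest(config, manifest)
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages"].append(stage)
        # paths relative to the run directory so re-runs are hash-identical
        manifest["artifacts"][stage] = {
            k: os.path.relpath(v, config.out_dir) if isinstance(v, str) else v
            for k, v in artifacts.items()}
    _write_manifest(config, manifest)
    if return_state:
        return manifest, state
    return manifest


def _write_manifest(config: PipelineConfig, manifest: dict) -> None:
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, gen_cfg, match_cfg, shell_cfg, seed, state) -> dict:
    tree = simulate_tree(gen_cfg.n_tips, gen_cfg.depth_myr, seed)
    truth = simulate_surfaces(tree, gen_cfg, seed + 1)
    ecology, eco_info = simulate_ecology(tree, truth, seed=seed + 2)
    state.update(tree=tree, truth=truth, ecology=ecology, eco_info=eco_info)
    out = cfg.out_dir
    paths = {"tree": os.path.join(out, "tree.nwk"),
             "ecology": os.path.join(out, "ecology.csv"),
             "coefficients": os.path.join(out, "true_coefficients.csv")}
    with open(paths["tree"], "w") as fh:
        fh.write(tree.to_newick() + "\n")
    ecology.to_csv(paths["ecology"])
    pd.DataFrame(truth.coefficients, columns=truth.coefficient_names).to_csv(
        paths["coefficients"], index=False)
    mesh_dir = os.path.join(out, "surfaces")
    os.makedirs(mesh_dir, exist_ok=True)
    for i, label in enumerate(tree.tip_labels):
        cio.write_mesh(truth.node_meshes[i], os.path.join(mesh_dir, f"{label}.off"))
    paths["surfaces"] = mesh_dir
    return paths


def _stage_reconstruct(cfg, gen_cfg, match_cfg, shell_cfg, seed, state) -> dict:
    tree: PhyloTree = state["tree"]
    truth = state["truth"]
    leaf_surfaces = {l: truth.node_meshes[i] for i, l in enumerate(tree.tip_labels)}
    leaf_labels = {l: make_label_fields(leaf_surfaces[l], truth.label_seeds,
                                        gen_cfg.label_bandwidth_frac)
                   for l in tree.tip_labels}
    recon = reconstruct_tree(tree, leaf_surfaces, leaf_labels,
                             shell_cfg=shell_cfg, match_cfg=match_cfg)
    state["recon"] = recon
    out_dir = os.path.join(cfg.out_dir, "ancestors")
    os.makedirs(out_dir, exist_ok=True)
    ages = tree.node_ages()
    rows = []
    for node, res in recon.nodes.items():
        cio.write_mesh(res.mesh, os.path.join(out_dir, f"node{node}.off"))
        rows.append({"node": node, "parent": int(tree.parent[node]),
                     "age_myr": float(ages[node]), "t": res.t,
                     "cortex_area": res.traits.cortex_area,
                     "hull_area": res.traits.hull_area,
                     "gyrification_index": res.traits.gyrification_index})
    table = pd.DataFrame(rows).sort_values("node")
    path = os.path.join(out_dir, "ancestral_traits.csv")
    table.to_csv(path, index=False)
    return {"ancestors": out_dir, "traits": path}


def _stage_phylo(cfg, gen_cfg, match_cfg, shell_cfg, seed, state) -> dict:
    tree: PhyloTree = state["tree"]
    recon = state["recon"]
    # low-resolution shape representation: subsampled common-topology coordinates
    n_common = recon.common_meshes[0].n_vertices
    step = max(1, n_common // max(cfg.trait_subsample, 1))
    idx = np.arange(0, n_common, step)
    coords = np.stack([recon.common_meshes[i].vertices[idx].ravel()
                       for i in range(tree.n_tips)])
    traits = TraitMatrix(coords, list(tree.tip_labels))
    fits = [fit_model(tree, traits, fam, ridge=10.0) for fam in ("BM", "OU", "EB")]
    best = select_model(fits)
    pca = phylo_pca(tree, traits)
    state.update(shape_traits=traits, shape_fits=fits, best_fit=best, pca=pca,
                 trait_vertex_idx=idx)
    path = os.path.join(cfg.out_dir, "phylo_models.json")
    with open(path, "w") as fh:
        json.dump({"families": {f.family: {"loglik": f.loglik, "gic": f.gic_value,
                                           "alpha": f.alpha, "eb_rate": f.eb_rate}
                                for f in fits},
                   "selected": best.family,
                   "ppca_ridge": pca["ridge"],
                   "ppca_eigenvalues": pca["eigenvalues"][: cfg.n_modes].tolist()},
                  fh, indent=2)
    scores_path = os.path.join(cfg.out_dir, "ppca_scores.csv")
    pd.DataFrame(pca["scores"][:, : cfg.n_modes], index=tree.tip_labels,
                 columns=[f"mode{m}" for m in range(cfg.n_modes)]).to_csv(scores_path)
    return {"models": path, "scores": scores_path}


def _stage_variogram(cfg, gen_cfg, match_cfg, shell_cfg, seed, state) -> dict:
    tree: PhyloTree = state["tree"]
    recon = state["recon"]
    ref = SurfaceMesh(recon.common_meshes[0].vertices, recon.reference_faces)
    dists = all_pairs_geodesics(ref)
    rng = np.random.default_rng(seed)
    rows = []
    modal_root = None
    for node in [0, tree.root]:
        mesh = SurfaceMesh(recon.common_meshes[node].vertices, recon.reference_faces)
        nd = all_pairs_geodesics(mesh)
        modal, rec = simulate_modal_maps(mesh, cfg.modal_target_range,
                                         seed=int(rng.integers(2 ** 31)), dists=nd,
                                         strict=False)
        emp = empirical_variogram(mesh, modal, dists=nd, seed=seed)
        fit = fit_variogram(emp, seed=seed)
        rows.append({"node": node, "family": fit.family, "sill": fit.sill,
                     "range": fit.range_, "sse": fit.sse,
                     "target_range": rec["target_range"],
                     "achieved_range": rec["achieved_range"]})
        if node == tree.root:
            modal_root = modal
    state["modal_root"] = modal_root
    state["ref_mesh"] = ref
    state["ref_dists"] = dists
    df = pd.DataFrame(rows)
    path = os.path.join(cfg.out_dir, "variograms.csv")
    df.to_csv(path, index=False)
    return {"variograms": path}


def _voronoi_parcellation(mesh: SurfaceMesh, n_parcels: int) -> np.ndarray:
    """Geodesic Voronoi parcels seeded at well-separated directions."""
    from .mesh import geodesic_distances
    ico = icosphere(0)
    v = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    seeds = [int(np.argmax(v @ d)) for d in ico.vertices[:n_parcels]]
    d = geodesic_distances(mesh, np.array(seeds))
    return np.argmin(d, axis=0)


def _stage_eco(cfg, gen_cfg, match_cfg, shell_cfg, seed, state) -> dict:
    tree: PhyloTree = state["tree"]
    truth = state["truth"]
    ecology: pd.DataFrame = state["ecology"]
    pca = state["pca"]
    recon = state["recon"]
    ref: SurfaceMesh = state.get("ref_mesh") or SurfaceMesh(
        recon.common_meshes[0].vertices, recon.reference_faces)
    rng = np.random.default_rng(seed)

    scores = pca["scores"][:, : cfg.n_modes]
    screen = screen_modes(scores, ecology)

    # shape-space objects live on the subsampled trait vector; expansion maps
    # are evaluated on the full common topology via the mode loadings only if
    # the subsample covers it — here the trait subsample IS the shape vector,
    # so synthesize on the full mesh by re-using per-vertex coordinates
    idx = state["trait_vertex_idx"]
    full = np.stack([recon.common_meshes[i].vertices.ravel() for i in range(tree.n_tips)])
    mean_full = full.mean(axis=0)
    parc = _voronoi_parcellation(ref, cfg.n_parcels)

    def habitat_map(var: str) -> VertexField:
        g = ecology[var].to_numpy().astype(bool)
        if g.sum() == 0 or (~g).sum() == 0:
            raise ValueError(f"habitat '{var}' empty")
        pos = full[g].mean(axis=0).reshape(-1, 3)
        neg = full[~g].mean(axis=0).reshape(-1, 3)
        a_pos = SurfaceMesh(pos, recon.reference_faces).vertex_areas()
        a_neg = SurfaceMesh(neg, recon.reference_faces).vertex_areas()
        e = np.log(a_pos / a_neg)
        # relative expansion: remove the global (allometric) component so
        # region statistics reflect spatial redistribution of area
        return VertexField(e - e.mean(), f"expansion_{var}")

    habitat_maps = {h: habitat_map(h) for h in ("arboreal", "terrestrial", "fossorial")}
    scale = HabitatScale()
    hvals = np.array([scale.arboreal, scale.terrestrial, scale.fossorial])
    region_rm = []
    for r in np.unique(parc):
        mask = parc == r
        Y = np.stack([habitat_maps[h].values[mask]
                      for h in ("arboreal", "terrestrial", "fossorial")], axis=1)
        res = rmcorr(Y, hvals)
        region_rm.append({"region": int(r), "r_rm": res["r"], "p": res["p"],
                          "n_vertices": int(mask.sum())})
    region_rm = pd.DataFrame(region_rm)

    # surrogate-referenced parcel tests on the arboreal expansion map
    emap = habitat_maps["arboreal"]
    dists = state.get("ref_dists")
    if dists is None:
        dists = all_pairs_geodesics(ref)
    surr = surrogate_maps(ref, emap, n=cfg.n_surrogates,
                          seed=int(rng.integers(2 ** 31)), dists=dists)
    min_verts = min(10, max(3, ref.n_vertices // (2 * cfg.n_parcels)))
    ptest = parcel_tests(emap, parc, surr["surrogates"], min_vertices=min_verts)

    # synthetic term library with the planted expansion pattern
    lib: dict[str, np.ndarray] = {}
    dmax = dists.max()
    W = np.exp(-dists ** 2 / (2 * (0.15 * dmax) ** 2))
    W /= W.sum(axis=1, keepdims=True)
    for i in range(cfg.n_terms - 1):
        lib[f"null_term_{i:03d}"] = W @ rng.standard_normal(ref.n_vertices)
    noise = W @ rng.standard_normal(ref.n_vertices)
    planted = emap.values + noise * emap.values.std() / max(noise.std(), 1e-12) / 3.0
    lib["planted_term"] = planted
    decoded = decode_map(emap, lib, keep_fraction=0.01)

    out = cfg.out_dir
    paths = {"screen": os.path.join(out, "mode_screen.csv"),
             "rmcorr": os.path.join(out, "habitat_rmcorr.csv"),
             "parcel": os.path.join(out, "parcel_tests.csv"),
             "decode": os.path.join(out, "decoded_terms.csv")}
    screen.to_csv(paths["screen"], index=False)
    region_rm.to_csv(paths["rmcorr"], index=False)
    ptest["regions"].to_csv(paths["parcel"], index=False)
    decoded.to_csv(paths["decode"], index=False)
    state.update(region_rm=region_rm, parcellation=parc, habitat_maps=habitat_maps,
                 decoded=decoded, screen=screen, parcel_results=ptest)
    return paths


_STAGES = {
    "simulate": _stage_simulate,
    "reconstruct": _stage_reconstruct,
    "phylo": _stage_phylo,
    "variogram": _stage_variogram,
    "eco": _stage_eco,
}


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_inputs(paths: dict) -> list[str]:
    """Report-only validation of a dataset: mesh invariants, tree/table
    agreement, table schemas. Returns a list of violation messages (empty
    when clean)."""
    report: list[str] = []
    tree = None
    if "tree" in paths:
        if not os.path.exists(paths["tree"]):
            report.append(f"tree file missing: {paths['tree']}")
        else:
            try:
                with open(paths["tree"]) as fh:
                    tree = PhyloTree.from_newick(fh.read())
                if not tree.is_binary():
                    report.append("tree is not binary")
                if not tree.is_ultrametric(1e-3):
                    report.append("tree is not ultrametric")
            except Exception as exc:
                report.append(f"tree unreadable: {exc}")
    for name, p in (paths.get("surfaces") if "surfaces" in paths else {}).items():
        if not os.path.exists(p):
            report.append(f"surface missing: {p}")
            continue
        try:
            mesh = cio.read_mesh(p)
            mesh.validate()
        except Exception as exc:
            report.append(f"surface '{name}': {exc}")
    if tree is not None and "surfaces" in paths:
        missing = [l for l in tree.tip_labels if l not in paths["surfaces"]]
        extra = [n for n in paths["surfaces"] if n not in tree.tip_labels]
        if missing:
            report.append(f"tips without surfaces: {missing}")
        if extra:
            report.append(f"surfaces without tree tips: {extra}")
    if "ecology" in paths:
        try:
            eco = pd.read_csv(paths["ecology"], index_col=0)
            bad_cols = [c for c in eco.columns if not set(eco[c].unique()) <= {0, 1}]
            if bad_cols:
                report.append(f"non-binary ecology columns: {bad_cols}")
            if tree is not None:
                unknown = [s for s in eco.index if s not in tree.tip_labels]
                if unknown:
                    report.append(f"ecology species absent from tree: {unknown}")
        except Exception as exc:
            report.append(f"ecology table unreadable: {exc}")
    return report
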