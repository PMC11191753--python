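"""Scenario orchestration: the four cement groups x six load cases,
the cement-free validation model, mesh-convergence studies and the
geometry calibration helper.

Everything is deterministic: a config fully determines all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import anatomy, fem, loads, meshing, postpro
from .errors import InvalidParameterError
from .params import (CementPlan, DiscParams, FacetParams, MeshSettings,
                     PosteriorParams, SegmentParams, VertebraParams)


@dataclass(frozen=True)
class RunConfig:
    """Full experiment configuration."""

    segment: SegmentParams = SegmentParams()
    mesh: MeshSettings = MeshSettings()
    osteoporotic: bool = True
    osteoporotic_cancellous_modulus: float = 34.0
    facet_mode: str = "bonded"
    groups: Tuple[str, ...] = postpro.GROUP_ORDER
    cases: Tuple[str, ...] = loads.CASE_LABELS
    target_cement_volume: float = 6.0       # mL per augmented vertebra
    preload: float = 500.0                  # N
    moment: float = 7.5                     # N*m
    output_dir: str = "out"
    write_fields: bool = False

    def __post_init__(self):
        if not self.groups or not self.cases:
            raise InvalidParameterError(
                "at least one group and one case required")
        if self.facet_mode != "bonded":
            raise InvalidParameterError(
                "only the bonded facet mode is implemented")
        for c in self.cases:
            if c not in loads.CASE_LABELS:
                raise InvalidParameterError(f"unknown case {c!r}")

    def config_hash(self) -> str:
        blob = json.dumps(config_to_dict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    group: str
    case: str
    summary: postpro.SolutionSummary
    provenance: dict


def config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)

    def scrub(o):
        if isinstance(o, dict):
            return {k: scrub(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [scrub(v) for v in o]
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return o

    return scrub(d)


def save_config(config: RunConfig, path: str) -> str:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
    return path


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return config_from_dict(d)


def config_from_dict(d: dict) -> RunConfig:
    seg = d.get("segment", {})
    segment = SegmentParams(
        vertebrae=tuple(VertebraParams(**v) for v in seg["vertebrae"])
        if "vertebrae" in seg else SegmentParams().vertebrae,
        discs=tuple(DiscParams(**x) for x in seg["discs"])
        if "discs" in seg else SegmentParams().discs,
        ligaments=tuple(
            _ligament_from_dict(x) for x in seg["ligaments"])
        if "ligaments" in seg else SegmentParams().ligaments,
        posterior=PosteriorParams(**_tupled(seg["posterior"]))
        if "posterior" in seg else PosteriorParams(),
        facets=FacetParams(**seg["facets"])
        if "facets" in seg else FacetParams(),
    )
    kw = {k: v for k, v in d.items() if k not in ("segment", "mesh")}
    if "groups" in kw:
        kw["groups"] = tuple(kw["groups"])
    if "cases" in kw:
        kw["cases"] = tuple(kw["cases"])
    return RunConfig(segment=segment,
                     mesh=MeshSettings(**d.get("mesh", {})), **kw)


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def _ligament_from_dict(x: dict):
    from .params import LigamentSpec
    x = dict(x)
    x.pop("attachment_pairs", None)
    return LigamentSpec(**x)


# ----------------------------------------------------------------------
# single-model pipeline
# ----------------------------------------------------------------------

class ModelRun:
    """Meshed, assembled and factorised model ready to solve load cases."""

    def __init__(self, geometry: anatomy.SegmentGeometry, config: RunConfig):
        self.geometry = geometry
        self.config = config
        self.mesh = meshing.generate_mesh(geometry, config.mesh)
        self.materials = fem.material_table(
            self.mesh, config.osteoporotic,
            config.osteoporotic_cancellous_modulus)
        self.K = fem.assemble_stiffness(self.mesh, self.materials)
        fixed = loads.fix_base(self.mesh, "L1_inferior")
        self.fixed = fixed
        self.factor = fem.FactorisedSolid(self.K, fixed)
        G, k_ax, signs = fem.truss_system(self.mesh)
        self.solver = fem.WoodburySolver(self.factor, G, k_ax, signs)

    def solve_case(self, case_label: str) -> Tuple[fem.SolutionField,
                                                   loads.LoadCase]:
        case = loads.LoadCase(case_label, preload=self.config.preload,
                              moment=self.config.moment)
        f, fixed = loads.build_case(self.mesh, case)
        sol = fem.solve_model(self.mesh, self.materials, f, fixed,
                              K=self.K, solver=self.solver)
        return sol, case

    def mesh_stats(self) -> dict:
        return {"nodes": int(self.mesh.n_nodes),
                "elements": int(self.mesh.n_elements),
                "trusses": len(self.mesh.trusses),
                "order": self.mesh.order}


def _geometry_for_group(config: RunConfig, group: Optional[str]
                        ) -> anatomy.SegmentGeometry:
    geo = anatomy.build_segment(config.segment)
    if group is None:
        return geo
    plan = CementPlan.for_group(
        group, target_total_volume=config.target_cement_volume)
    return anatomy.place_cement(geo, plan)


def run_matrix(config: RunConfig,
               progress: bool = False) -> List[RunResult]:
    """Run all requested (group x case) combinations.

    Geometry is built and factorised once per group; the six load cases
    reuse the factorisation through the low-rank ligament update.
    """
    results: List[RunResult] = []
    chash = config.config_hash()
    for group in config.groups:
        t0 = time.perf_counter()
        run = ModelRun(_geometry_for_group(config, group), config)
        for case_label in config.cases:
            sol, _case = run.solve_case(case_label)
            summary = postpro.summarize(run.mesh, sol, group, case_label)
            prov = {"config_hash": chash, "mesh": run.mesh_stats(),
                    "active_trusses": int(sol.active_trusses.sum()),
                    "iterations": sol.iterations,
                    "cement_mL": run.geometry.cement_volume_report(),
                    "wall_s": round(time.perf_counter() - t0, 2)}
            results.append(RunResult(group, case_label, summary, prov))
            if config.write_fields:
                from .io import write_vtu
                os.makedirs(config.output_dir, exist_ok=True)
                write_vtu(run.mesh,
                          os.path.join(config.output_dir,
                                       f"{group}_{case_label}.vtu"),
                          point_data={"displacement": sol.displacements},
                          cell_data={"vms": sol.element_vms})
            if progress:
                print(f"[{group} {case_label}] "
                      f"vmsT12={summary.max_vms_T12:.2f} MPa "
                      f"dispT12={summary.max_disp_T12:.3f} mm")
    return results


def run_validation(config: RunConfig, preload: Optional[float] = None,
                   osteoporotic: bool = False) -> pd.DataFrame:
    """ROM of the cement-free model in all six directions vs the published
    corridor (validation stand-in for the original model check).

    The published corridor comes from healthy-spine segment models, so the
    validation model uses normal bone properties by default; the cement
    scenario matrix keeps the osteoporotic condition.  The 500 N preload
    acts together with the moment (``preload=0`` gives the pure-moment
    protocol).
    """
    cfg = replace(config,
                  preload=config.preload if preload is None else preload,
                  osteoporotic=osteoporotic)
    run = ModelRun(_geometry_for_group(cfg, None), cfg)
    rom_by_case: Dict[str, Dict[str, float]] = {}
    for case_label in cfg.cases:
        sol, _ = run.solve_case(case_label)
        axis = loads.CASE_AXES[case_label]
        u = sol.displacements
        rom_by_case[case_label] = {
            "T11-T12": postpro.compute_rom(run.mesh, u, "T11", "T12", axis),
            "T12-L1": postpro.compute_rom(run.mesh, u, "T12", "L1", axis),
            "T11-L1": postpro.compute_rom(run.mesh, u, "T11", "L1", axis),
        }
    return postpro.rom_table(rom_by_case)


def refine_study(geometry: anatomy.SegmentGeometry,
                 settings_list: Sequence[MeshSettings],
                 config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Mesh-convergence table: flexion max T12 VMS and T11-L1 ROM per
    density."""
    config = config or RunConfig()
    rows = []
    for st in settings_list:
        cfg = replace(config, mesh=st)
        run = ModelRun(geometry, cfg)
        sol, _ = run.solve_case("flexion")
        vms, _, _ = postpro.region_max(run.mesh, sol.element_vms,
                                       *postpro.T12_REGIONS)
        rom = postpro.compute_rom(run.mesh, sol.displacements, "T11", "L1",
                                  loads.CASE_AXES["flexion"])
        rows.append({"edge_solid": st.target_edge_solid,
                     "edge_cartilage": st.target_edge_cartilage,
                     "order": st.element_order,
                     "nodes": run.mesh.n_nodes,
                     "elements": run.mesh.n_elements,
                     "max_vms_T12": vms, "rom_T11_L1_flexion": rom})
    return pd.DataFrame(rows)


def calibrate(config: RunConfig,
              disc_heights: Sequence[float],
              nucleus_fractions: Sequence[float] = (0.4,),
              cases: Sequence[str] = ("flexion", "left_rotation"),
              ) -> pd.DataFrame:
    """Coarse grid search of disc geometry against the ROM reference.

    Returns the squared relative ROM error per grid point; the shipped
    defaults were frozen from such a search (see docs/methods.md).
    """
    rows = []
    for h in disc_heights:
        for nf in nucleus_fractions:
            seg = replace(config.segment,
                          discs=tuple(replace(d, height=h,
                                              nucleus_area_fraction=nf)
                                      for d in config.segment.discs))
            cfg = replace(config, segment=seg, cases=tuple(cases))
            rom = run_validation(cfg)
            err = 0.0
            for case in cases:
                ref = postpro.ROM_REFERENCE.loc[case]
                for k in ("T11-T12", "T12-L1", "T11-L1"):
                    err += ((rom.loc[case, k] - ref[k]) / ref[k]) ** 2
            row = {"disc_height": h, "nucleus_fraction": nf,
                   "sq_rel_error": err}
            for case in cases:
                row[f"rom_T11L1_{case}"] = rom.loc[case, "T11-L1"]
            rows.append(row)
    return pd.DataFrame(rows).sort_values("sq_rel_error").reset_index(
        drop=True)


def mirror_node_map(mesh_a: meshing.Mesh, mesh_b: meshing.Mesh
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Node map m with nodes_b[m[i]] == mirror(nodes_a[i]) about y=0.

    Returns (map, unique_mask).  Facet-contact interfaces duplicate node
    coordinates, making the geometric pairing ambiguous there; those nodes
    are excluded from ``unique_mask`` and field comparisons should be
    restricted to it.
    """
    from scipy.spatial import cKDTree
    mirrored = mesh_a.nodes * np.array([1.0, -1.0, 1.0])
    d, idx = cKDTree(mesh_b.nodes).query(mirrored)
    if d.max() > 1e-6:
        raise InvalidParameterError(
            f"meshes are not mirror images (max gap {d.max():.2e} mm)")

    def unique_coord_mask(nodes):
        key = np.round(nodes, 9)
        order = np.lexsort(key.T)
        srt = key[order]
        dup_next = np.zeros(len(nodes), dtype=bool)
        same = np.all(srt[1:] == srt[:-1], axis=1)
        dup_sorted = np.zeros(len(nodes), dtype=bool)
        dup_sorted[1:] |= same
        dup_sorted[:-1] |= same
        mask = np.ones(len(nodes), dtype=bool)
        mask[order] = ~dup_sorted
        return mask

    unique = unique_coord_mask(mesh_a.nodes)
    return idx, unique


def mirror_displacements(u: np.ndarray) -> np.ndarray:
    return u * np.array([1.0, -1.0, 1.0])
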