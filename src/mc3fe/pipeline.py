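"""End-to-end orchestration: segment -> mesh -> material map -> solve -> summarize."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calibration import (
    AsclLaw,
    CalibrationCurve,
    DensityModulusLaw,
    RegionFactors,
)
from .errors import StageError
from .fe import LoadCase, assemble_and_solve, element_moduli, psg_summary
from .image import VoxelImage, label_regions, sclerotic_volume_fraction
from .meshing import LoadPatchSpec, PsgStripSpec, tag_boundary_sets, voxels_to_tets

__all__ = ["PipelineConfig", "run_specimen", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the forward pipeline, serializable to YAML.

    Field groups mirror the pipeline stages: calibration constants,
    segmentation thresholds, mesh edges, load case and strip width, and the
    tuned material laws used when ``tuned`` is requested.
    """

    curve: CalibrationCurve = CalibrationCurve()
    law: DensityModulusLaw = DensityModulusLaw()
    ascl_law: AsclLaw = AsclLaw()
    pooled_dlys: float = 0.65
    threshold_hu: float = 1500.0
    min_lysis_voxels: int = 8
    distal_length_mm: float = 63.5
    fine_edge_mm: float = 0.5
    coarse_edge_mm: float = 1.0
    strip_width_mm: float = 3.0
    load_case: LoadCase = LoadCase()
    nu: float = 0.3
    seed: int = 0

    def to_dict(self) -> dict:
        def sanitize(v):
            if isinstance(v, dict):
                return {k: sanitize(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [sanitize(x) for x in v]
            return v

        return sanitize(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "curve" in d:
            d["curve"] = CalibrationCurve(**d["curve"])
        if "law" in d:
            d["law"] = DensityModulusLaw(**d["law"])
        if "ascl_law" in d:
            d["ascl_law"] = AsclLaw(**{k: v for k, v in d["ascl_law"].items()})
        if "load_case" in d:
            d["load_case"] = LoadCase(**d["load_case"])
        return cls(**d)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {
            "package": "mc3fe",
            "version": __version__,
            "config_hash": self.config_hash(),
            "seed": self.seed,
        }


def run_specimen(
    config: PipelineConfig,
    specimen_id: str,
    image: VoxelImage,
    bone_mask: np.ndarray,
    trabecular_mask: np.ndarray,
    psg_region_mask: np.ndarray,
    condyle_mask: np.ndarray,
    frame,
    psg_strip_spec: PsgStripSpec,
    load_patch_spec: LoadPatchSpec,
    factors: RegionFactors | None = None,
) -> dict:
    """Forward pipeline for one specimen; returns a results bundle.

    When ``factors`` is None the tuned material model is applied:
    ``a_scl = ascl_law(v_scl)`` and, if a lytic region was segmented,
    ``d_lys = pooled_dlys``.  Pass ``RegionFactors(0, 0)`` explicitly for
    the non-tuned model.
    """

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-tagged with stage context
            raise StageError(name, specimen_id, exc) from exc

    labels = _stage(
        "segment",
        label_regions,
        image,
        bone_mask,
        trabecular_mask,
        psg_region_mask,
        threshold_hu=config.threshold_hu,
        min_lysis_voxels=config.min_lysis_voxels,
    )
    v_scl = _stage("segment", sclerotic_volume_fraction, labels, condyle_mask)
    mesh = _stage(
        "mesh",
        voxels_to_tets,
        labels,
        image,
        curve=config.curve,
        law=config.law,
        fine_edge_mm=config.fine_edge_mm,
        coarse_edge_mm=config.coarse_edge_mm,
    )
    _stage(
        "mesh",
        tag_boundary_sets,
        mesh,
        frame,
        psg_strip_spec,
        load_patch_spec,
        strip_width_mm=config.strip_width_mm,
    )
    from .image import Label  # local import to keep module surface tidy

    has_lysis = bool(np.any(mesh.element_region == int(Label.LYS)))
    if factors is None:
        from .calibration import ascl_from_vscl

        factors = RegionFactors(
            float(ascl_from_vscl(v_scl, config.ascl_law)),
            config.pooled_dlys if has_lysis else 0.0,
        )
    youngs = _stage("material", element_moduli, mesh, config.law, factors)
    field_ = _stage(
        "solve", assemble_and_solve, mesh, youngs, frame, config.load_case, nu=config.nu
    )
    summary = _stage("summarize", psg_summary, field_, mesh)
    return {
        "specimen_id": specimen_id,
        "labels": labels,
        "mesh": mesh,
        "youngs": youngs,
        "field": field_,
        "psg_summary": summary,
        "v_scl": v_scl,
        "factors": factors,
        "report": {
            "specimen_id": specimen_id,
            "v_scl": float(v_scl),
            "a_scl": float(factors.a_scl),
            "d_lys": float(factors.d_lys),
            "has_lysis": has_lysis,
            "n_elements": int(mesh.n_tets),
            "n_nodes": int(mesh.n_nodes),
            "psg_mean_max_principal": summary.mean_max_principal,
            "psg_strip_facets": summary.facet_count,
            "psg_strip_area_mm2": summary.area_mm2,
            "provenance": config.provenance(),
        },
    }


def run_pipeline(config: PipelineConfig, specimens, out_dir=None) -> list[dict]:
    """Run the forward pipeline over phantom specimens.

    ``specimens`` is an iterable of ``(specimen_id, CondylePhantom)`` or of
    ``CondylePhantom`` (ids auto-assigned).  When ``out_dir`` is given, a
    JSON report, the label map (NIfTI) and the mesh with its strain field
    (VTK) are written per specimen.  Partial results are preserved: a
    failing specimen is reported in-place with its stage error.
    """
    results = []
    for i, item in enumerate(specimens):
        if isinstance(item, tuple):
            sid, phantom = item
        else:
            sid, phantom = f"specimen-{i}", item
        try:
            res = run_specimen(
                config,
                sid,
                phantom.image,
                phantom.bone_mask,
                phantom.trabecular_mask,
                phantom.psg_region_mask,
                phantom.condyle_mask,
                phantom.frame,
                phantom.psg_strip_spec,
                phantom.load_patch_spec,
            )
        except StageError as err:
            results.append({"specimen_id": sid, "error": str(err), "stage": err.stage})
            continue
        results.append(res)
        if out_dir is not None:
            from .io import save_json, write_label_volume, write_vtk_mesh

            out = Path(out_dir) / sid
            save_json(res["report"], out / "report.json")
            write_label_volume(res["labels"], out / "labels.nii.gz")
            write_vtk_mesh(
                res["mesh"],
                out / "mesh.vtk",
                cell_data={
                    "youngs_mpa": res["youngs"],
                    "max_principal_strain": res["field"].element_principal[:, 0],
                },
            )
    return results
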