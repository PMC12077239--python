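"""Standard-format I/O: NIfTI/MetaImage volumes, VTK/INP meshes, configs.

Volumes are read and written with nibabel (NIfTI) or SimpleITK (MetaImage
and anything else ITK understands).  Axis convention: the in-memory array
axis order is (x, y, z) and world coordinates are origin + index * spacing;
orientation matrices beyond scaling are not interpreted.

Meshes are exported as legacy-ASCII VTK unstructured grids with per-cell
region / density / modulus data, and as a minimal Abaqus-INP-style text
file (nodes, C3D4 elements, one element set per region, node sets).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import yaml

from .errors import InvalidInputError
from .image import Label, LabelVolume, VoxelImage
from .meshing import TetrahedralMesh

__all__ = [
    "read_volume",
    "write_volume",
    "read_label_volume",
    "write_label_volume",
    "write_vtk_mesh",
    "write_inp_mesh",
    "save_yaml",
    "load_yaml",
    "save_json",
]

#: Documented label dictionary for integer label maps on disk.
LABEL_DICTIONARY = {int(l): l.name for l in Label}


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def read_volume(path) -> VoxelImage:
    """Read a volumetric image (NIfTI via nibabel, else SimpleITK)."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"volume not found: {path}")
    if _is_nifti(path):
        img = nib.load(str(path))
        values = np.asarray(img.dataobj, dtype=float)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return VoxelImage(values=values, spacing=spacing, origin=origin)
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).astype(float).transpose(2, 1, 0)  # zyx -> xyz
    return VoxelImage(
        values=values,
        spacing=tuple(float(s) for s in img.GetSpacing()),
        origin=tuple(float(o) for o in img.GetOrigin()),
    )


def write_volume(image: VoxelImage, path, dtype=None) -> Path:
    """Write a volume (format chosen by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = image.values if dtype is None else image.values.astype(dtype)
    if _is_nifti(path):
        affine = np.diag(list(image.spacing) + [1.0])
        affine[:3, 3] = image.origin
        nib.save(nib.Nifti1Image(data, affine), str(path))
    else:
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(image.spacing))
        img.SetOrigin(tuple(image.origin))
        sitk.WriteImage(img, str(path))
    return path


def write_label_volume(labels: LabelVolume, path) -> Path:
    img = VoxelImage(values=labels.labels.astype(float), spacing=labels.spacing, origin=labels.origin)
    return write_volume(img, path, dtype=np.uint8)


def read_label_volume(path) -> LabelVolume:
    img = read_volume(path)
    return LabelVolume(labels=img.values.astype(np.uint8), spacing=img.spacing, origin=img.origin)


def write_vtk_mesh(mesh: TetrahedralMesh, path, cell_data: dict | None = None) -> Path:
    """Write the tet mesh as a legacy-ASCII VTK unstructured grid.

    ``element_region`` and ``element_rho_ash`` are always included as cell
    data; extra per-element arrays can be passed in ``cell_data``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {"region": mesh.element_region.astype(float), "rho_ash_g_cm3": mesh.element_rho_ash}
    if cell_data:
        for name, arr in cell_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (mesh.n_tets,):
                raise InvalidInputError(f"cell data '{name}' must be per-element")
            data[name] = arr
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmc3fe tetrahedral mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.9g")
        fh.write(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}\n")
        cells = np.column_stack([np.full(mesh.n_tets, 4), mesh.tets])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {mesh.n_tets}\n")
        np.savetxt(fh, np.full(mesh.n_tets, 10), fmt="%d")  # VTK_TETRA
        fh.write(f"CELL_DATA {mesh.n_tets}\n")
        for name, arr in data.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%.9g")
    return path


def write_inp_mesh(mesh: TetrahedralMesh, path) -> Path:
    """Minimal Abaqus-INP-style text export (1-based ids, C3D4 elements)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("*HEADING\nmc3fe mesh export\n*NODE\n")
        for i, p in enumerate(mesh.nodes, start=1):
            fh.write(f"{i}, {p[0]:.9g}, {p[1]:.9g}, {p[2]:.9g}\n")
        fh.write("*ELEMENT, TYPE=C3D4\n")
        for i, t in enumerate(mesh.tets, start=1):
            fh.write(f"{i}, {t[0] + 1}, {t[1] + 1}, {t[2] + 1}, {t[3] + 1}\n")
        for lab in np.unique(mesh.element_region):
            name = Label(int(lab)).name
            ids = np.flatnonzero(mesh.element_region == lab) + 1
            fh.write(f"*ELSET, ELSET={name}\n")
            for row in np.array_split(ids, max(1, ids.size // 12)):
                fh.write(", ".join(str(i) for i in row) + "\n")
        for name, nodes in mesh.node_sets.items():
            fh.write(f"*NSET, NSET={name}\n")
            arr = np.asarray(nodes) + 1
            for row in np.array_split(arr, max(1, arr.size // 12)):
                fh.write(", ".join(str(i) for i in row) + "\n")
    return path


def _plain(obj):
    """Recursively convert numpy scalars/arrays and tuples for YAML."""
    if isinstance(obj, dict):
        return {_plain(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    return obj


def save_yaml(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(obj), fh, sort_keys=True)
    return path


def load_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"file not found: {path}")
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
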