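"""File formats and configuration.

Meshes: STL/PLY/OFF via trimesh.  Electrodes: whitespace-delimited text
``label x y z facet_index`` (meters).  Dipoles: CSV ``x y z dx dy dz moment``
(meters, A m).  EEG samples: CSV ``label,voltage_V`` with ``# key: value``
provenance header lines (seed, tolerances, mesh hashes).  Head-model
manifest: JSON/YAML listing surface files outermost-first with compartment
conductivities.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib

import numpy as np
import pandas as pd
import trimesh
import yaml

from .forward import EEGSample
from .geometry import ElectrodeArray, LayeredHeadModel, TriMesh
from .sources import CurrentDipole

__all__ = ["load_mesh", "save_mesh", "load_electrodes", "save_electrodes",
           "load_dipoles", "save_dipoles", "load_eeg_sample", "save_eeg_sample",
           "load_model_manifest", "save_model_manifest", "StudyConfig",
           "load_config", "mesh_hash", "save_refinement_log",
           "save_fit_results", "save_error_map_csv", "save_error_map_ply"]


def load_mesh(path) -> TriMesh:
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mesh file not found: {path}")
    mesh = trimesh.load(str(path), force="mesh")
    return TriMesh.from_trimesh(mesh)


def save_mesh(mesh: TriMesh, path):
    path = pathlib.Path(path)
    mesh.as_trimesh().export(str(path))


def mesh_hash(mesh: TriMesh) -> str:
    h = hashlib.sha256()
    h.update(np.round(mesh.vertices, 12).tobytes())
    h.update(np.asarray(mesh.faces).tobytes())
    return h.hexdigest()[:16]


def save_electrodes(electrodes: ElectrodeArray, path):
    with open(path, "w") as f:
        for label, p, idx in zip(electrodes.labels, electrodes.positions,
                                 electrodes.facet_index):
            f.write(f"{label} {p[0]:.9e} {p[1]:.9e} {p[2]:.9e} {idx}\n")


def load_electrodes(path) -> ElectrodeArray:
    labels, positions, index = [], [], []
    with open(path) as f:
        for line in f:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            labels.append(parts[0])
            positions.append([float(x) for x in parts[1:4]])
            index.append(int(parts[4]))
    return ElectrodeArray(np.asarray(positions), np.asarray(index, dtype=np.int64),
                          labels=tuple(labels))


def save_dipoles(dipoles, path):
    rows = [{"x": d.position[0], "y": d.position[1], "z": d.position[2],
             "dx": d.direction[0], "dy": d.direction[1], "dz": d.direction[2],
             "moment": d.moment} for d in dipoles]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_dipoles(path):
    df = pd.read_csv(path)
    return [CurrentDipole([r.x, r.y, r.z], [r.dx, r.dy, r.dz], r.moment)
            for r in df.itertuples()]


def save_eeg_sample(sample: EEGSample, path, meta=None):
    meta = {**sample.meta, **(meta or {}), "reference": sample.reference}
    with open(path, "w") as f:
        for key in sorted(meta):
            f.write(f"# {key}: {meta[key]}\n")
        f.write("label,voltage_V\n")
        for label, v in zip(sample.labels, sample.voltages):
            f.write(f"{label},{v:.12e}\n")


def load_eeg_sample(path) -> EEGSample:
    meta = {}
    rows = []
    with open(path) as f:
        for line in f:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif line.strip() and not line.startswith("label"):
                label, v = line.strip().split(",")
                rows.append((label, float(v)))
    labels, volts = zip(*rows)
    return EEGSample(np.asarray(volts), tuple(labels),
                     reference=meta.pop("reference", "raw"), meta=meta)


def save_model_manifest(model: LayeredHeadModel, directory, fmt: str = "ply",
                        name: str = "model"):
    """Write surface meshes plus a JSON manifest (outermost-first)."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (surf, label) in enumerate(zip(model.surfaces, model.names)):
        fname = f"{name}_{i}_{label}.{fmt}"
        save_mesh(surf, directory / fname)
        entries.append({"file": fname, "name": label,
                        "conductivity": float(model.conductivities[i]),
                        "hash": mesh_hash(surf)})
    manifest = {
        "surfaces": entries,
        "source_conductivity": float(model.source_conductivity),
        "preset": model.preset,
    }
    path = directory / f"{name}.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_model_manifest(path) -> LayeredHeadModel:
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    if path.suffix in (".yaml", ".yml"):
        manifest = yaml.safe_load(path.read_text())
    else:
        manifest = json.loads(path.read_text())
    surfaces, conductivities, names = [], [], []
    for entry in manifest["surfaces"]:
        surfaces.append(load_mesh(path.parent / entry["file"]))
        conductivities.append(entry["conductivity"])
        names.append(entry.get("name", ""))
    return LayeredHeadModel(surfaces, np.asarray(conductivities),
                            names=tuple(names),
                            source_conductivity=manifest.get("source_conductivity"),
                            preset=manifest.get("preset", ""))


@dataclasses.dataclass
class StudyConfig:
    """Pipeline configuration with the study defaults."""

    radii: tuple = (0.092, 0.086, 0.080)
    preset: str = "SimNIBS3"
    subdivisions: tuple = (3, 4, 4)
    n_electrodes: int = 256
    n_dipoles: int = 10
    gmres_tol: float = 1e-5
    amr_stop: float = 0.01
    amr_fraction: float = 0.01
    amr_max_steps: int = 12
    b_amr_passes: int = 6
    refinement: str = "amr"          # amr | b-amr | none
    fit_strategy: str = "both"
    grid_resolution: float = 0.005
    interpolation_radius: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for field in ("gmres_tol", "amr_stop", "amr_fraction", "grid_resolution",
                      "interpolation_radius"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> StudyConfig:
    path = pathlib.Path(path)
    data = (yaml.safe_load(path.read_text()) if path.suffix in (".yaml", ".yml")
            else json.loads(path.read_text()))
    for key in ("radii", "subdivisions"):
        if key in data:
            data[key] = tuple(data[key])
    return StudyConfig(**data)


def save_refinement_log(log, path):
    pd.DataFrame(log).to_csv(path, index=False,
                             columns=["step", "n_facets", "rel_voltage_change",
                                      "residual", "iterations"])


def save_fit_results(rows, path):
    cols = ["dipole_id", "x", "y", "z", "dx", "dy", "dz", "moment", "rv",
            "n_eval", "strategy"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def save_error_map_csv(error_map, path):
    pd.DataFrame({
        "facet": np.arange(len(error_map.values)),
        "error_mm": error_map.values,
        "n_sources": error_map.n_contributing,
    }).to_csv(path, index=False)


def save_error_map_ply(surface: TriMesh, error_map, path):
    """ASCII PLY with a per-face ``quality`` scalar carrying the error map
    (missing facets written as -1)."""
    vals = np.where(np.isnan(error_map.values), -1.0, error_map.values)
    with open(path, "w") as f:
        f.write("ply\nformat ascii 1.0\n")
        f.write(f"element vertex {len(surface.vertices)}\n")
        f.write("property float x\nproperty float y\nproperty float z\n")
        f.write(f"element face {surface.n_faces}\n")
        f.write("property list uchar int vertex_indices\n")
        f.write("property float quality\nend_header\n")
        for v in surface.vertices:
            f.write(f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
        for face, q in zip(surface.faces, vals):
            f.write(f"3 {face[0]} {face[1]} {face[2]} {q:.6e}\n")
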