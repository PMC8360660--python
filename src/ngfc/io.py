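"""File I/O: SWC morphologies, OBJ meshes, CSV tables, HDF5 maps, JSON.

Formats follow field conventions: morphologies as SWC (axon = structure
type 2) with boutons in a sidecar CSV; meshes as OBJ with face groups
per compartment; amplitude tables as CSV with columns
(condition, trial_index, time_s, amplitude_pA).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import trimesh
import yaml

from .errors import ConfigurationError
from .geometry import MembraneGeometry
from .morphology import AxonMorphology

__all__ = [
    "write_swc",
    "read_swc",
    "write_boutons_csv",
    "read_boutons_csv",
    "write_obj",
    "read_obj",
    "write_amplitudes_csv",
    "read_amplitudes_csv",
    "write_coverage_h5",
    "read_coverage_h5",
    "load_config",
    "write_manifest",
]

SWC_AXON_TYPE = 2
SWC_SOMA_TYPE = 1


def write_swc(morph: AxonMorphology, path, radius: float = 0.2):
    """Write a morphology as SWC (1-based ids; soma then axon nodes)."""
    path = Path(path)
    lines = ["# generated by ngfc", "# id type x y z radius parent"]
    for i in range(morph.n_nodes):
        t = SWC_SOMA_TYPE if i == 0 else SWC_AXON_TYPE
        x, y, z = morph.nodes[i]
        parent = morph.parents[i] + 1 if morph.parents[i] >= 0 else -1
        lines.append(f"{i + 1} {t} {x:.6f} {y:.6f} {z:.6f} {radius:.4f} {parent}")
    path.write_text("\n".join(lines) + "\n")


def read_swc(path) -> AxonMorphology:
    nodes, parents = [], []
    ids = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise ConfigurationError(f"malformed SWC line: {line!r}")
        nid = int(parts[0])
        ids[nid] = len(nodes)
        nodes.append([float(parts[2]), float(parts[3]), float(parts[4])])
        parents.append(int(parts[6]))
    remapped = [ids[p] if p != -1 else -1 for p in parents]
    nodes = np.asarray(nodes)
    return AxonMorphology(soma=nodes[0], nodes=nodes, parents=np.asarray(remapped))


def write_boutons_csv(morph: AxonMorphology, path, cell_id: str = "cell0"):
    df = pd.DataFrame({
        "cell_id": cell_id,
        "x": morph.bouton_xyz[:, 0],
        "y": morph.bouton_xyz[:, 1],
        "z": morph.bouton_xyz[:, 2],
        "path_distance_um": morph.bouton_path_dist,
    })
    df.to_csv(path, index=False)


def read_boutons_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_obj(geometry: MembraneGeometry, path):
    """OBJ export with one face group per compartment label."""
    path = Path(path)
    mesh = geometry.mesh
    out = ["# generated by ngfc"]
    for v in mesh.vertices:
        out.append(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
    order = np.argsort(geometry.face_labels.astype(str), kind="stable")
    current = None
    for fi in order:
        label = geometry.face_labels[fi]
        if label != current:
            out.append(f"g {label}")
            current = label
        a, b, c = mesh.faces[fi] + 1
        out.append(f"f {a} {b} {c}")
    path.write_text("\n".join(out) + "\n")


def read_obj(path) -> MembraneGeometry:
    """Read an OBJ with ``g`` face groups naming compartments."""
    vertices, faces, labels = [], [], []
    current = "shaft"
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            vertices.append([float(x) for x in parts[1:4]])
        elif parts[0] == "g":
            current = parts[1] if len(parts) > 1 else "shaft"
        elif parts[0] == "f":
            idx = [int(p.split("/")[0]) - 1 for p in parts[1:4]]
            faces.append(idx)
            labels.append(current)
    mesh = trimesh.Trimesh(vertices=np.asarray(vertices), faces=np.asarray(faces),
                           process=False)
    return MembraneGeometry(mesh=mesh, face_labels=np.asarray(labels, dtype=object))


def write_amplitudes_csv(dataset, path):
    dataset.to_frame().to_csv(path, index=False)


def read_amplitudes_csv(path):
    from .quantal_bqa import AmplitudeDataset

    return AmplitudeDataset.from_frame(pd.read_csv(path))


def write_coverage_h5(coverage, path):
    with h5py.File(path, "w") as f:
        f.attrs["voxel_size"] = coverage.voxel_size
        f.attrs["radius"] = coverage.radius
        f.attrs["dims"] = coverage.dims
        f.attrs["n_cells"] = coverage.n_cells
        f.attrs["shape"] = coverage.shape
        f.create_dataset("bouton_count", data=coverage.bouton_count, compression="gzip")
        f.create_dataset("source_count", data=coverage.source_count, compression="gzip")
        f.create_dataset("edge_mask", data=coverage.edge_mask, compression="gzip")
        f.create_dataset("pair_voxel", data=coverage.pair_voxel, compression="gzip")
        f.create_dataset("pair_cell", data=coverage.pair_cell, compression="gzip")


def read_coverage_h5(path):
    from .population_coverage import CoverageMap

    with h5py.File(path, "r") as f:
        return CoverageMap(
            voxel_size=float(f.attrs["voxel_size"]),
            radius=float(f.attrs["radius"]),
            shape=tuple(int(s) for s in f.attrs["shape"]),
            dims=tuple(float(d) for d in f.attrs["dims"]),
            bouton_count=f["bouton_count"][...],
            source_count=f["source_count"][...],
            edge_mask=f["edge_mask"][...].astype(bool),
            pair_voxel=f["pair_voxel"][...],
            pair_cell=f["pair_cell"][...],
            n_cells=int(f.attrs["n_cells"]),
        )


def load_config(path, allowed_keys) -> dict:
    """Load a YAML config, rejecting unknown top-level keys."""
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError("config must be a YAML mapping")
    unknown = set(cfg) - set(allowed_keys)
    if unknown:
        raise ConfigurationError(
            f"unknown config keys: {sorted(unknown)}; allowed: {sorted(allowed_keys)}"
        )
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for block in iter(lambda: f.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(out_dir, stage: str, seed, params: dict, outputs):
    """Write a reproducibility manifest next to stage outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "stage": stage,
        "seed": seed,
        "params": params,
        "version": __version__,
        "outputs": {Path(p).name: _sha256(p) for p in outputs},
    }
    with open(out_dir / f"{stage}_manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest
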