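"""HDF5 persistence for voxel volumes and surface photon tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from ..errors import FormatError
from .types import OpticalProperties, SurfaceRecord, VoxelVolume


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Label grid + property table + fluorophore maps in one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("tissue_label", data=volume.tissue_label, compression="gzip")
        f.create_dataset("fluor_yield", data=volume.fluor_yield, compression="gzip")
        f.create_dataset(
            "fluor_lifetime_ns", data=volume.fluor_lifetime_ns, compression="gzip"
        )
        props = np.array(
            [(p.mu_a, p.mu_s_prime, p.g, p.n) for p in volume.properties]
        )
        f.create_dataset("properties", data=props)
        f["properties"].attrs["columns"] = "mu_a,mu_s_prime,g,n"
        f.attrs["voxel_size_mm"] = volume.voxel_size_mm
        f.attrs["n_outside"] = volume.n_outside


def read_volume(path: str | Path) -> VoxelVolume:
    with h5py.File(path, "r") as f:
        for key in ("tissue_label", "properties"):
            if key not in f:
                raise FormatError(f"{path}: missing dataset '{key}'")
        props = [
            OpticalProperties(mu_a=row[0], mu_s_prime=row[1], g=row[2], n=row[3])
            for row in f["properties"][...]
        ]
        return VoxelVolume(
            voxel_size_mm=float(f.attrs["voxel_size_mm"]),
            tissue_label=f["tissue_label"][...],
            properties=props,
            fluor_yield=f["fluor_yield"][...] if "fluor_yield" in f else None,
            fluor_lifetime_ns=(
                f["fluor_lifetime_ns"][...] if "fluor_lifetime_ns" in f else None
            ),
            n_outside=float(f.attrs.get("n_outside", 1.0)),
        )


def write_surface_record(record: SurfaceRecord, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("photons")
        g.create_dataset("x_mm", data=record.x_mm)
        g.create_dataset("y_mm", data=record.y_mm)
        g.create_dataset("t_ps", data=record.t_ps)
        g.create_dataset("weight", data=record.weight)
        g.create_dataset("face", data=record.face)
        if record.launch_x_mm is not None:
            g.create_dataset("launch_x_mm", data=record.launch_x_mm)
        if record.seed is not None:
            f.attrs["seed"] = record.seed


def read_surface_record(path: str | Path) -> SurfaceRecord:
    with h5py.File(path, "r") as f:
        if "photons" not in f:
            raise FormatError(f"{path}: missing group 'photons'")
        g = f["photons"]
        return SurfaceRecord(
            x_mm=g["x_mm"][...],
            y_mm=g["y_mm"][...],
            t_ps=g["t_ps"][...],
            weight=g["weight"][...],
            launch_x_mm=g["launch_x_mm"][...] if "launch_x_mm" in g else None,
            face=g["face"][...],
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )
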