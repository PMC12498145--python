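"""Domain types for the voxelized Monte Carlo fluorescence engine."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ..errors import InvalidConfigError


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of one tissue/medium type.

    ``mu_s`` is derived from the reduced scattering coefficient via the
    similarity relation mu_s = mu_s' / (1 - g).
    """

    mu_a: float
    mu_s_prime: float
    g: float = 0.9
    n: float = 1.37

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_a) or self.mu_a < 0:
            raise InvalidConfigError(f"mu_a must be finite and >= 0, got {self.mu_a}")
        if not np.isfinite(self.mu_s_prime) or self.mu_s_prime < 0:
            raise InvalidConfigError(
                f"mu_s_prime must be finite and >= 0, got {self.mu_s_prime}"
            )
        if not (-1.0 < self.g < 1.0):
            raise InvalidConfigError(f"g must lie in (-1, 1), got {self.g}")

    @property
    def mu_s(self) -> float:
        return self.mu_s_prime / (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        return self.mu_a + self.mu_s


@dataclass
class VoxelVolume:
    """3-D grid of tissue labels plus fluorophore yield/lifetime maps.

    Arrays are indexed ``[ix, iy, iz]`` with z the depth axis (z = 0 at the
    top surface). ``properties`` maps each label value to its optical
    properties; ``em_properties`` optionally holds a separate table for the
    emission wavelength (defaults to the excitation table).
    """

    voxel_size_mm: float
    tissue_label: np.ndarray
    properties: list[OpticalProperties]
    fluor_yield: np.ndarray | None = None
    fluor_lifetime_ns: np.ndarray | None = None
    em_properties: list[OpticalProperties] | None = None
    n_outside: float = 1.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tissue_label = np.ascontiguousarray(self.tissue_label, dtype=np.uint8)
        if self.tissue_label.ndim != 3:
            raise InvalidConfigError("tissue_label must be 3-D (nx, ny, nz)")
        if self.tissue_label.size == 0:
            raise InvalidConfigError("volume has zero extent")
        if self.voxel_size_mm <= 0:
            raise InvalidConfigError("voxel_size_mm must be > 0")
        if self.tissue_label.max() >= len(self.properties):
            raise InvalidConfigError(
                "tissue_label references an undefined properties entry"
            )
        if self.fluor_yield is None:
            self.fluor_yield = np.zeros(self.shape, dtype=np.float32)
        else:
            self.fluor_yield = np.ascontiguousarray(self.fluor_yield, dtype=np.float32)
        if self.fluor_lifetime_ns is None:
            self.fluor_lifetime_ns = np.zeros(self.shape, dtype=np.float32)
        else:
            self.fluor_lifetime_ns = np.ascontiguousarray(
                self.fluor_lifetime_ns, dtype=np.float32
            )
        if self.fluor_yield.shape != self.shape or (
            self.fluor_lifetime_ns.shape != self.shape
        ):
            raise InvalidConfigError("fluorophore maps must match the label grid shape")
        if np.any(self.fluor_yield < 0):
            raise InvalidConfigError("fluor_yield must be >= 0")
        bad = (self.fluor_yield > 0) & (self.fluor_lifetime_ns <= 0)
        if np.any(bad):
            raise InvalidConfigError(
                f"{int(bad.sum())} voxels have fluor_yield > 0 but lifetime <= 0"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tissue_label.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        nx, ny, nz = self.shape
        return nx * self.voxel_size_mm, ny * self.voxel_size_mm, nz * self.voxel_size_mm

    def property_tables(
        self, emission: bool = False
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        """Per-label (mu_a, mu_s, g) arrays and the medium refractive index."""
        props = self.em_properties if (emission and self.em_properties) else self.properties
        mua = np.array([p.mu_a for p in props], dtype=np.float64)
        mus = np.array([p.mu_s for p in props], dtype=np.float64)
        g = np.array([p.g for p in props], dtype=np.float64)
        return mua, mus, g, float(props[0].n)


@dataclass
class TimeResolvedField:
    """Per-voxel, per-time-bin absorbed energy (per launched photon weight)."""

    values: np.ndarray  # (nx, ny, nz, nt) float32
    time_bin_ps: float

    def __post_init__(self) -> None:
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise InvalidConfigError("field values must be finite and non-negative")

    @property
    def n_time_bins(self) -> int:
        return self.values.shape[3]

    def integrated(self) -> np.ndarray:
        return self.values.sum(axis=3)


@dataclass
class Bookkeeping:
    """Weight conservation ledger of one transport run."""

    launched: float
    absorbed: float
    escaped_top: float
    escaped_other: float
    time_killed: float
    roulette_killed: float
    roulette_gain: float

    def imbalance(self) -> float:
        """Relative conservation defect; ~0 for a correct run."""
        sinks = (
            self.absorbed
            + self.escaped_top
            + self.escaped_other
            + self.time_killed
            + self.roulette_killed
        )
        return abs(self.launched + self.roulette_gain - sinks) / max(self.launched, 1e-300)


@dataclass
class SurfaceRecord:
    """Table of photons detected at the volume boundary.

    ``launch_x_mm`` carries the excitation launch x-position of each photon
    (propagated through fluorescence events), enabling synthesis of any
    illumination pattern by reweighting. ``face`` is 0 for the top surface,
    1 for the bottom, 2 for the sides.
    """

    x_mm: np.ndarray
    y_mm: np.ndarray
    t_ps: np.ndarray
    weight: np.ndarray
    launch_x_mm: np.ndarray | None
    face: np.ndarray
    bookkeeping: Bookkeeping | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.x_mm)

    def top(self) -> "SurfaceRecord":
        """Photons that exited through the top (detector) surface."""
        m = self.face == 0
        return SurfaceRecord(
            self.x_mm[m],
            self.y_mm[m],
            self.t_ps[m],
            self.weight[m],
            None if self.launch_x_mm is None else self.launch_x_mm[m],
            self.face[m],
            self.bookkeeping,
            self.seed,
        )


@dataclass
class EmissionSources:
    """Compact per-voxel emission time profiles (energy per time bin)."""

    voxel_index: np.ndarray  # (n, 3) int32
    profiles: np.ndarray     # (n, nt) float64
    time_bin_ps: float
    shape: tuple[int, int, int]

    @property
    def total_energy(self) -> float:
        return float(self.profiles.sum())
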