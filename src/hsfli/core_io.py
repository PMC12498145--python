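"""Containers and file formats for time-gated image stacks and IRFs.

Time is handled in picoseconds internally; constructors accept nanoseconds
for the laser period (sub-nanosecond gate timing makes ps the natural unit).
The native on-disk container is HDF5 with a ``/gates`` dataset and typed
attributes; multi-page TIFF plus a JSON sidecar is supported for
interchange with ImageJ-style tooling.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import tifffile

from .errors import DegenerateIRFError, FormatError, InvalidConfigError

logger = logging.getLogger("hsfli")

#: Vacuum speed of light in mm/ps.
C_MM_PER_PS = 0.299792

_STACK_ATTRS = (
    "gate_width_ps",
    "gate_step_ps",
    "t0_ps",
    "laser_period_ns",
    "pixel_pitch_mm",
)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing and camera settings of a gated acquisition.

    Parameters
    ----------
    n_gates : int
        Number of gate delays acquired.
    gate_width_ps : float
        Integration window of each gate, ps.
    gate_step_ps : float
        Delay increment between successive gates, ps.
    t0_ps : float
        Opening time of the first gate, ps.
    laser_period_ns : float
        Excitation repetition period, ns.
    mcp_voltage : float or None
        Intensifier voltage; free metadata, not interpreted.
    binning : int
        Hardware binning factor; free metadata.
    """

    n_gates: int
    gate_width_ps: float
    gate_step_ps: float
    t0_ps: float = 0.0
    laser_period_ns: float = 12.5
    mcp_voltage: float | None = None
    binning: int = 1

    def __post_init__(self) -> None:
        if self.n_gates < 1:
            raise InvalidConfigError(f"n_gates must be >= 1, got {self.n_gates}")
        if self.gate_width_ps <= 0:
            raise InvalidConfigError(
                f"gate_width_ps must be > 0, got {self.gate_width_ps}"
            )
        if self.gate_step_ps <= 0:
            raise InvalidConfigError(
                f"gate_step_ps must be > 0, got {self.gate_step_ps}"
            )
        if self.laser_period_ns <= 0:
            raise InvalidConfigError(
                f"laser_period_ns must be > 0, got {self.laser_period_ns}"
            )
        if self.span_ps + self.gate_width_ps > self.laser_period_ps + 1e-9:
            raise InvalidConfigError(
                "acquisition window (span + gate width = "
                f"{self.span_ps + self.gate_width_ps} ps) exceeds laser period "
                f"{self.laser_period_ps} ps"
            )

    @property
    def span_ps(self) -> float:
        """Delay between first and last gate opening: (n_gates - 1) * step."""
        return (self.n_gates - 1) * self.gate_step_ps

    @property
    def laser_period_ps(self) -> float:
        return self.laser_period_ns * 1000.0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_config() -> AcquisitionConfig:
    """The 101-gate / 300 ps width / 80 ps step acquisition at 12.5 ns period."""
    return AcquisitionConfig(
        n_gates=101, gate_width_ps=300.0, gate_step_ps=80.0, laser_period_ns=12.5
    )


def make_time_axis(config: AcquisitionConfig) -> np.ndarray:
    """Gate-opening times in ps: ``t_i = t0 + i * gate_step``.

    The axis is strictly increasing with uniform spacing; for the default
    101-gate / 80 ps configuration the span is 8 ns.
    """
    return config.t0_ps + np.arange(config.n_gates) * config.gate_step_ps


@dataclass
class GatedStack:
    """A T x H x W stack of gated camera frames with timing metadata."""

    data: np.ndarray
    config: AcquisitionConfig
    pixel_pitch_mm: float = 1.0
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise InvalidConfigError(
                f"stack data must be 3-D (T, H, W), got ndim={self.data.ndim}"
            )
        if self.data.shape[0] != self.config.n_gates:
            raise InvalidConfigError(
                f"stack has {self.data.shape[0]} gates but config declares "
                f"{self.config.n_gates}"
            )
        if self.pixel_pitch_mm <= 0:
            raise InvalidConfigError("pixel_pitch_mm must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise InvalidConfigError("stack contains non-finite values")
        if np.any(self.data < 0):
            raise InvalidConfigError("stack contains negative counts")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def time_axis(self) -> np.ndarray:
        return make_time_axis(self.config)

    def total_image(self) -> np.ndarray:
        """Sum over gates (H x W)."""
        return self.data.sum(axis=0)


@dataclass
class InstrumentResponse:
    """The system temporal response sampled on the gate time axis.

    ``samples`` is either a 1-D global IRF or a per-pixel T x H x W grid.
    """

    samples: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim not in (1, 3):
            raise InvalidConfigError("IRF must be 1-D or T x H x W")
        if np.any(self.samples < 0) or not np.all(np.isfinite(self.samples)):
            raise InvalidConfigError("IRF samples must be finite and non-negative")


def validate_irf(
    irf: InstrumentResponse, config: AcquisitionConfig | None = None
) -> InstrumentResponse:
    """Check an IRF against a config and return a sum-to-one copy.

    Per-pixel IRFs are normalized pixel-wise along the time axis. An IRF
    with no positive sample (globally, or in any pixel of a per-pixel grid)
    raises :class:`DegenerateIRFError`.
    """
    s = irf.samples
    if config is not None and s.shape[0] != config.n_gates:
        raise InvalidConfigError(
            f"IRF has {s.shape[0]} samples but config declares {config.n_gates} gates"
        )
    if s.ndim == 1:
        total = s.sum()
        if total <= 0:
            raise DegenerateIRFError("IRF has no positive sample")
        return InstrumentResponse(s / total, normalized=True)
    total = s.sum(axis=0, keepdims=True)
    if np.any(total <= 0):
        raise DegenerateIRFError("per-pixel IRF contains all-zero pixels")
    return InstrumentResponse(s / total, normalized=True)


# ---------------------------------------------------------------------------
# HDF5 native container
# ---------------------------------------------------------------------------

def write_stack(stack: GatedStack, path: str | Path) -> None:
    """Write a stack to the native HDF5 layout (dataset ``/gates`` + attrs)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("gates", data=stack.data.astype(np.float32))
        cfg = stack.config
        ds.attrs["n_gates"] = cfg.n_gates
        ds.attrs["gate_width_ps"] = cfg.gate_width_ps
        ds.attrs["gate_step_ps"] = cfg.gate_step_ps
        ds.attrs["t0_ps"] = cfg.t0_ps
        ds.attrs["laser_period_ns"] = cfg.laser_period_ns
        ds.attrs["pixel_pitch_mm"] = stack.pixel_pitch_mm
        if cfg.mcp_voltage is not None:
            ds.attrs["mcp_voltage"] = cfg.mcp_voltage
        ds.attrs["binning"] = cfg.binning
        ds.attrs["provenance_json"] = json.dumps(stack.provenance, default=str)
    logger.info(
        "wrote stack %s shape=%s config_hash=%s",
        path,
        stack.data.shape,
        stack.config.config_hash(),
    )


def read_stack(path: str | Path) -> GatedStack:
    """Read a stack written by :func:`write_stack`.

    Raises :class:`FormatError` naming the first missing attribute.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "gates" not in f:
            raise FormatError(f"{path}: missing dataset 'gates'")
        ds = f["gates"]
        for attr in _STACK_ATTRS:
            if attr not in ds.attrs:
                raise FormatError(f"{path}: missing required attribute '{attr}'")
        data = ds[...]
        cfg = AcquisitionConfig(
            n_gates=int(ds.attrs.get("n_gates", data.shape[0])),
            gate_width_ps=float(ds.attrs["gate_width_ps"]),
            gate_step_ps=float(ds.attrs["gate_step_ps"]),
            t0_ps=float(ds.attrs["t0_ps"]),
            laser_period_ns=float(ds.attrs["laser_period_ns"]),
            mcp_voltage=(
                float(ds.attrs["mcp_voltage"]) if "mcp_voltage" in ds.attrs else None
            ),
            binning=int(ds.attrs.get("binning", 1)),
        )
        provenance = json.loads(ds.attrs.get("provenance_json", "{}"))
        pitch = float(ds.attrs["pixel_pitch_mm"])
    return GatedStack(data=data, config=cfg, pixel_pitch_mm=pitch, provenance=provenance)


# ---------------------------------------------------------------------------
# TIFF + JSON sidecar interchange
# ---------------------------------------------------------------------------

def write_stack_tiff(stack: GatedStack, path: str | Path) -> None:
    """Write a multi-page TIFF (T, Y, X) with a ``.json`` metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32), metadata={"axes": "TYX"})
    meta = dataclasses.asdict(stack.config)
    meta["pixel_pitch_mm"] = stack.pixel_pitch_mm
    meta["provenance"] = stack.provenance
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def read_stack_tiff(path: str | Path) -> GatedStack:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"{path}: missing JSON sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    for key in ("n_gates", "gate_width_ps", "gate_step_ps"):
        if key not in meta:
            raise FormatError(f"{sidecar}: missing required key '{key}'")
    data = tifffile.imread(path)
    cfg = AcquisitionConfig(
        n_gates=int(meta["n_gates"]),
        gate_width_ps=float(meta["gate_width_ps"]),
        gate_step_ps=float(meta["gate_step_ps"]),
        t0_ps=float(meta.get("t0_ps", 0.0)),
        laser_period_ns=float(meta.get("laser_period_ns", 12.5)),
        mcp_voltage=meta.get("mcp_voltage"),
        binning=int(meta.get("binning", 1)),
    )
    return GatedStack(
        data=data,
        config=cfg,
        pixel_pitch_mm=float(meta.get("pixel_pitch_mm", 1.0)),
        provenance=meta.get("provenance", {}),
    )
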