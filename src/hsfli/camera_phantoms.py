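"""Synthetic-data generation: phantom builders, gated-camera model, IRF, noise.

Phantom geometries mirror the validation experiments: a tilted capillary
tube, an 8-tube depth ladder (1 mm capillaries, first tube 0.4 mm below
the surface, 1 mm depth increments), a scattering-free well-plate control,
and a minimal two-layer surface/deep geometry for surface-removal tests.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .core_io import AcquisitionConfig, GatedStack, InstrumentResponse, default_config
from .errors import InvalidConfigError
from .mcfluor import OpticalProperties, VoxelVolume, simulate_two_step
from .structured import (
    PHASES,
    IlluminationPattern,
    make_pattern_triplet,
    source_modulation,
)

logger = logging.getLogger("hsfli")

#: Bulk/dye optical properties used in the simulation phantoms.
BULK_SIM = OpticalProperties(mu_a=0.002, mu_s_prime=1.0, g=0.9, n=1.37)
#: Bulk properties of the experimental depth-ladder phantom.
BULK_LADDER = OpticalProperties(mu_a=0.02, mu_s_prime=1.0, g=0.9, n=1.37)
DYE = OpticalProperties(mu_a=0.04, mu_s_prime=0.09, g=0.9, n=1.37)

#: Mono-exponential lifetime of the AF700-like control dye, ns.
AF700_LIFETIME_NS = 0.9

DEFAULT_PIXEL_PITCH_MM = 0.1875  # 24 mm field on a 128 x 128 grid
DEFAULT_FIELD_MM = 24.0


@dataclass
class PhantomSpec:
    """Parameterization of one synthetic phantom."""

    kind: str  # tilted_tube | depth_ladder | well_plate | two_layer
    field_mm: float = DEFAULT_FIELD_MM
    thickness_mm: float = 10.0
    voxel_mm: float = 0.1
    tube_diameter_mm: float = 1.0
    depths_mm: Sequence[float] = field(
        default_factory=lambda: tuple(0.4 + i * 1.0 for i in range(8))
    )
    tilt_depths_mm: tuple[float, float] = (0.0, 4.0)
    layer_thickness_mm: float = 0.2     # two_layer surface emitter
    layer_yield: float = 1.0
    layer_lifetime_ns: float = 0.5
    well_diameter_mm: float = 8.0
    well_depth_mm: float = 2.0
    bulk: OpticalProperties = field(default_factory=lambda: BULK_SIM)
    inclusion: OpticalProperties = field(default_factory=lambda: DYE)
    fluor_yield: float = 1.0
    fluor_lifetime_ns: float = AF700_LIFETIME_NS
    #: optional amplitude-weighted lifetime mixture [(A_i, tau_i_ns), ...]
    #: for FRET-like two-state donors; overrides fluor_lifetime_ns
    lifetime_components: Sequence[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("tilted_tube", "depth_ladder", "well_plate", "two_layer"):
            raise InvalidConfigError(f"unknown phantom kind {self.kind!r}")
        if any(d < 0 for d in self.depths_mm):
            raise InvalidConfigError("tube depths must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bulk"] = dataclasses.asdict(self.bulk)
        d["inclusion"] = dataclasses.asdict(self.inclusion)
        return d


def _cylinder_mask_y(shape, h, x_c, z_top, radius):
    """Voxels whose centers lie inside a y-axis cylinder (center-in-voxel)."""
    nx, ny, nz = shape
    xs = (np.arange(nx) + 0.5) * h
    zs = (np.arange(nz) + 0.5) * h
    z_c = z_top + radius
    d2 = (xs[:, None] - x_c) ** 2 + (zs[None, :] - z_c) ** 2
    mask2d = d2 <= radius**2
    return np.broadcast_to(mask2d[:, None, :], (nx, ny, nz))


def ladder_tube_x(spec: PhantomSpec, i: int) -> float:
    """x-position (mm) of ladder tube i (0-based), evenly spread."""
    n = len(spec.depths_mm)
    return (i + 0.5) * spec.field_mm / n


def build_phantom(spec: PhantomSpec) -> VoxelVolume:
    """Rasterize a phantom spec into a labeled voxel volume.

    Label 0 is bulk, label 1 the inclusion; fluorophore maps are set
    inside inclusions only (center-in-voxel membership).
    """
    h = spec.voxel_mm
    n_lat = int(round(spec.field_mm / h))
    nz = int(round(spec.thickness_mm / h))
    shape = (n_lat, n_lat, nz)
    label = np.zeros(shape, dtype=np.uint8)
    yld = np.zeros(shape, dtype=np.float32)
    tau = np.zeros(shape, dtype=np.float32)
    r = spec.tube_diameter_mm / 2.0

    if spec.kind == "depth_ladder":
        for i, d in enumerate(spec.depths_mm):
            if d + spec.tube_diameter_mm > spec.thickness_mm:
                raise InvalidConfigError(
                    f"tube {i + 1} at depth {d} mm extends beyond the volume"
                )
            if r > 0:
                m = _cylinder_mask_y(shape, h, ladder_tube_x(spec, i), d, r)
                label[m] = 1
                yld[m] = spec.fluor_yield
                tau[m] = spec.fluor_lifetime_ns
    elif spec.kind == "tilted_tube":
        d0, d1 = spec.tilt_depths_mm
        if max(d0, d1) + spec.tube_diameter_mm > spec.thickness_mm:
            raise InvalidConfigError("tilted tube extends beyond the volume")
        if r > 0:
            # axis along x at y center, top depth linear in x
            nx, ny, nzz = shape
            xs = (np.arange(nx) + 0.5) * h
            ys = (np.arange(ny) + 0.5) * h
            zs = (np.arange(nzz) + 0.5) * h
            z_top = d0 + (d1 - d0) * xs / spec.field_mm
            z_c = z_top + r
            y_c = spec.field_mm / 2.0
            d2 = (ys[None, :, None] - y_c) ** 2 + (
                zs[None, None, :] - z_c[:, None, None]
            ) ** 2
            m = d2 <= r**2
            label[m] = 1
            yld[m] = spec.fluor_yield
            tau[m] = spec.fluor_lifetime_ns
    elif spec.kind == "well_plate":
        # dye disk at the surface of a (near) transparent bulk
        nx, ny, nzz = shape
        xs = (np.arange(nx) + 0.5) * h
        c = spec.field_mm / 2.0
        d2 = (xs[:, None] - c) ** 2 + (xs[None, :] - c) ** 2
        disk = d2 <= (spec.well_diameter_mm / 2.0) ** 2
        ztop = int(round(spec.well_depth_mm / h))
        m = np.zeros(shape, dtype=bool)
        m[:, :, :ztop] = disk[:, :, None]
        label[m] = 1
        yld[m] = spec.fluor_yield
        tau[m] = spec.fluor_lifetime_ns
    elif spec.kind == "two_layer":
        nz_layer = max(1, int(round(spec.layer_thickness_mm / h)))
        m_layer = np.zeros(shape, dtype=bool)
        m_layer[:, :, :nz_layer] = True
        yld[m_layer] = spec.layer_yield
        tau[m_layer] = spec.layer_lifetime_ns
        d = spec.depths_mm[0]
        if d + spec.tube_diameter_mm > spec.thickness_mm:
            raise InvalidConfigError("deep tube extends beyond the volume")
        if r > 0:
            m = _cylinder_mask_y(shape, h, spec.field_mm / 2.0, d, r)
            label[m] = 1
            yld[m] = spec.fluor_yield
            tau[m] = spec.fluor_lifetime_ns

    props = [spec.bulk, spec.inclusion]
    vol = VoxelVolume(
        voxel_size_mm=h,
        tissue_label=label,
        properties=props,
        fluor_yield=yld,
        fluor_lifetime_ns=tau,
        meta={"spec": spec.to_dict()},
    )
    return vol


def tube_roi_masks(
    spec: PhantomSpec,
    image_shape: tuple[int, int],
    pixel_pitch_mm: float,
    n_tubes: int | None = None,
    y_margin_frac: float = 0.1,
) -> dict[str, np.ndarray]:
    """Surface-projection ROI masks of the phantom's inclusions.

    For tube phantoms, each ROI is the geometric projection of the tube
    onto the camera plane (|x - x_tube| <= radius), trimmed at the field
    edges along the tube axis.
    """
    H, W = image_shape
    xs = (np.arange(W) + 0.5) * pixel_pitch_mm
    ys = (np.arange(H) + 0.5) * pixel_pitch_mm
    y_ok = (ys > spec.field_mm * y_margin_frac) & (ys < spec.field_mm * (1 - y_margin_frac))
    r = spec.tube_diameter_mm / 2.0
    masks: dict[str, np.ndarray] = {}
    if spec.kind == "depth_ladder":
        nt = n_tubes or len(spec.depths_mm)
        for i in range(nt):
            x_ok = np.abs(xs - ladder_tube_x(spec, i)) <= r
            masks[f"tube{i + 1}"] = y_ok[:, None] & x_ok[None, :]
    elif spec.kind == "two_layer":
        x_ok = np.abs(xs - spec.field_mm / 2.0) <= r
        masks["tube"] = y_ok[:, None] & x_ok[None, :]
    elif spec.kind == "well_plate":
        c = spec.field_mm / 2.0
        d2 = (ys[:, None] - c) ** 2 + (xs[None, :] - c) ** 2
        masks["well"] = d2 <= (spec.well_diameter_mm / 2.0) ** 2
    elif spec.kind == "tilted_tube":
        x_all = np.ones(W, dtype=bool)
        yc = spec.field_mm / 2.0
        yb = np.abs(ys - yc) <= r
        masks["tube"] = yb[:, None] & x_all[None, :]
    return masks


# ---------------------------------------------------------------------------
# Camera model
# ---------------------------------------------------------------------------

@dataclass
class CameraModel:
    """Gated-intensifier forward model: boxcar gates, gain, noise."""

    config: AcquisitionConfig = field(default_factory=default_config)
    gate_shape: str = "boxcar"  # or "trapezoid"
    gain: float = 1.0
    noise: str = "poisson"  # none | poisson | poisson+gaussian
    read_sigma: float = 0.0
    saturation: float = np.inf
    trapezoid_edge_ps: float = 50.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise InvalidConfigError("gain must be > 0")
        if self.read_sigma < 0:
            raise InvalidConfigError("read_sigma must be >= 0")
        if self.gate_shape not in ("boxcar", "trapezoid"):
            raise InvalidConfigError(f"unknown gate shape {self.gate_shape!r}")
        if self.noise not in ("none", "poisson", "poisson+gaussian"):
            raise InvalidConfigError(f"unknown noise model {self.noise!r}")


def synth_irf(
    fwhm_ps: float, center_ps: float, time_axis: np.ndarray
) -> InstrumentResponse:
    """Normalized Gaussian IRF sampled on a time axis.

    fwhm -> 0 degenerates to a single-bin impulse at the nearest sample.
    """
    if fwhm_ps < 0:
        raise InvalidConfigError("fwhm_ps must be >= 0")
    time_axis = np.asarray(time_axis, dtype=np.float64)
    if center_ps < time_axis[0] or center_ps > time_axis[-1]:
        logger.warning("IRF center %.0f ps lies outside the time axis (truncated)", center_ps)
    if fwhm_ps == 0:
        s = np.zeros_like(time_axis)
        s[int(np.argmin(np.abs(time_axis - center_ps)))] = 1.0
        return InstrumentResponse(s, normalized=True)
    sigma = fwhm_ps / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    s = np.exp(-0.5 * ((time_axis - center_ps) / sigma) ** 2)
    return InstrumentResponse(s / s.sum(), normalized=True)


def _gate_weights(
    camera: CameraModel, fine_bin_ps: float, n_fine: int
) -> np.ndarray:
    """(n_gates, n_fine) matrix of fractional bin weights per gate window."""
    cfg = camera.config
    edges = np.arange(n_fine + 1) * fine_bin_ps
    wmat = np.zeros((cfg.n_gates, n_fine))
    truncated = []
    for gi in range(cfg.n_gates):
        t_open = cfg.t0_ps + gi * cfg.gate_step_ps
        t_close = t_open + cfg.gate_width_ps
        if t_close > n_fine * fine_bin_ps + 1e-9 or t_open < -1e-9:
            truncated.append(gi)
            continue
        lo = np.clip(edges[:-1], t_open, t_close)
        hi = np.clip(edges[1:], t_open, t_close)
        frac = (hi - lo) / fine_bin_ps
        if camera.gate_shape == "trapezoid" and camera.trapezoid_edge_ps > 0:
            centers = (edges[:-1] + edges[1:]) / 2.0
            e = camera.trapezoid_edge_ps
            ramp_in = np.clip((centers - t_open) / e, 0.0, 1.0)
            ramp_out = np.clip((t_close - centers) / e, 0.0, 1.0)
            frac = frac * np.minimum(ramp_in, ramp_out)
        wmat[gi] = frac
    if truncated:
        raise InvalidConfigError(
            f"gate windows exceed the simulated time range for gates {truncated}"
        )
    return wmat


def apply_gating(
    fine_stack: np.ndarray, fine_bin_ps: float, camera: CameraModel,
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM,
    provenance: dict | None = None,
) -> GatedStack:
    """Integrate a fine-binned (nt, H, W) signal into gated camera frames.

    Gate g sums the per-bin signal (fractionally at the window edges) over
    [t_g, t_g + gate_width], times the camera gain. Overlapping gates
    (width > step) are supported. Linear in the input signal.
    """
    fine_stack = np.asarray(fine_stack)
    if fine_stack.ndim == 1:
        fine_stack = fine_stack[:, None, None]
    nt = fine_stack.shape[0]
    wmat = _gate_weights(camera, fine_bin_ps, nt)
    gated = np.tensordot(wmat, fine_stack, axes=(1, 0)) * camera.gain
    return GatedStack(
        data=np.clip(gated, 0.0, None),
        config=camera.config,
        pixel_pitch_mm=pixel_pitch_mm,
        provenance=provenance or {},
    )


def effective_gate_irf(
    irf_fine: np.ndarray, fine_bin_ps: float, camera: CameraModel
) -> InstrumentResponse:
    """The fine-axis IRF as seen through the gate windows, sum-normalized.

    This is the response to fit against gated data: it folds the gate
    integration into the IRF so the decay model can be convolved directly
    on the gate axis.
    """
    wmat = _gate_weights(camera, fine_bin_ps, len(irf_fine))
    g = wmat @ np.asarray(irf_fine, dtype=np.float64)
    if g.sum() <= 0:
        raise InvalidConfigError("IRF has no overlap with the gate windows")
    return InstrumentResponse(g / g.sum(), normalized=True)


def add_noise(stack: GatedStack, camera: CameraModel, seed: int = 0) -> GatedStack:
    """Apply the camera noise model (Poisson shot + optional Gaussian read)."""
    rng = np.random.default_rng(seed)
    data = stack.data.astype(np.float64)
    if camera.noise in ("poisson", "poisson+gaussian"):
        data = rng.poisson(data).astype(np.float64)
    if camera.noise == "poisson+gaussian" and camera.read_sigma > 0:
        data = data + rng.normal(0.0, camera.read_sigma, size=data.shape)
    data = np.clip(data, 0.0, camera.saturation)
    prov = dict(stack.provenance)
    prov["noise"] = camera.noise
    prov["noise_seed"] = seed
    return GatedStack(
        data=data, config=stack.config, pixel_pitch_mm=stack.pixel_pitch_mm,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# End-to-end dataset generation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Sidecar making every fitted quantity checkable against the generator."""

    spec: PhantomSpec
    lifetimes_ns: dict
    roi_masks: dict[str, np.ndarray]
    gate_irf: InstrumentResponse
    m_s: dict[float, float]
    clean_triplets: dict[float, tuple[GatedStack, GatedStack, GatedStack]]
    seed: int


@dataclass
class HsfDataset:
    """Noisy gated triplets per spatial frequency, plus ground truth."""

    triplets: dict[float, tuple[GatedStack, GatedStack, GatedStack]]
    truth: GroundTruth
    patterns: dict[float, list[IlluminationPattern]]


def generate_hsf_dataset(
    spec: PhantomSpec,
    fx_list: Sequence[float],
    camera: CameraModel,
    n_photons: int,
    seed: int = 0,
    *,
    irf_fwhm_ps: float = 300.0,
    irf_center_ps: float = 600.0,
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM,
    time_bin_ps: float = 10.0,
    n_emission: int | None = None,
    target_events: int = 500_000,
    auto_gain_peak: float | None = None,
) -> HsfDataset:
    """Simulate three-phase gated acquisitions for each spatial frequency.

    One coupled two-step MC run per phantom; all (fx, phase) stacks are
    synthesized by launch-position reweighting, convolved with a Gaussian
    IRF on the fine time axis, gate-integrated, and Poisson-noised. The
    ground-truth sidecar always carries the pre-noise stacks, ROI masks,
    true lifetimes, and the gate-axis effective IRF.

    ``auto_gain_peak`` rescales the camera gain so the brightest pre-noise
    gated pixel reads that many counts (emulating exposure tuning).
    """
    if not len(fx_list):
        raise InvalidConfigError("fx_list must be non-empty")
    volume = build_phantom(spec)
    H = W = int(round(spec.field_mm / pixel_pitch_mm))
    patterns = {float(fx): make_pattern_triplet(float(fx), (H, W), pixel_pitch_mm)
                for fx in fx_list}
    all_pats = [p for trip in patterns.values() for p in trip]
    t_max_ps = camera.config.laser_period_ps
    stacks, two = simulate_two_step(
        volume,
        all_pats,
        n_photons,
        seed,
        n_emission=n_emission,
        image_shape=(H, W),
        pixel_pitch_mm=pixel_pitch_mm,
        time_bin_ps=time_bin_ps,
        t_max_ps=t_max_ps,
        lifetime_components=spec.lifetime_components,
        target_events=target_events,
    )
    nt = next(iter(stacks.values())).shape[0]
    fine_axis = (np.arange(nt) + 0.5) * time_bin_ps
    irf_fine = synth_irf(irf_fwhm_ps, irf_center_ps, fine_axis).samples

    # convolve each phase stack with the IRF on the fine axis, then gate
    clean: dict[float, tuple] = {}
    pre_gain_stacks = {}
    peak = 0.0
    for fx in patterns:
        members = []
        for pat in patterns[fx]:
            st = stacks[(pat.fx, pat.phase)]
            conv = fftconvolve(st, irf_fine[:, None, None], axes=0)[:nt]
            members.append(np.clip(conv, 0.0, None))
        pre_gain_stacks[fx] = members
    cam = camera
    if auto_gain_peak is not None:
        tmp_cam = dataclasses.replace(camera, gain=1.0)
        for fx, members in pre_gain_stacks.items():
            for m in members:
                g = apply_gating(m, time_bin_ps, tmp_cam, pixel_pitch_mm)
                peak = max(peak, float(g.data.max()))
        if peak <= 0:
            raise InvalidConfigError("no fluorescence signal; cannot auto-scale gain")
        cam = dataclasses.replace(camera, gain=auto_gain_peak / peak)

    rng_seeds = np.random.SeedSequence(seed).spawn(len(patterns) * 3)
    noisy: dict[float, tuple] = {}
    si = 0
    for fx, members in pre_gain_stacks.items():
        cleans = []
        noisys = []
        for pi, m in enumerate(members):
            prov = {
                "fx_per_mm": fx,
                "phase_index": pi,
                "seed": seed,
                "phantom": spec.kind,
            }
            g = apply_gating(m, time_bin_ps, cam, pixel_pitch_mm, provenance=prov)
            cleans.append(g)
            nseed = int(rng_seeds[si].generate_state(1)[0] % (2**31 - 1))
            si += 1
            noisys.append(add_noise(g, cam, seed=nseed))
        clean[fx] = tuple(cleans)
        noisy[fx] = tuple(noisys)

    gate_axis_irf = effective_gate_irf(irf_fine, time_bin_ps, cam)
    rois = tube_roi_masks(spec, (H, W), pixel_pitch_mm)
    lifetimes = {
        "fluor_lifetime_ns": spec.fluor_lifetime_ns,
        "lifetime_components": spec.lifetime_components,
    }
    if spec.kind == "two_layer":
        lifetimes["layer_lifetime_ns"] = spec.layer_lifetime_ns
    m_s = {
        fx: (source_modulation(trip) if fx > 0 else 1.0)
        for fx, trip in patterns.items()
    }
    truth = GroundTruth(
        spec=spec,
        lifetimes_ns=lifetimes,
        roi_masks=rois,
        gate_irf=gate_axis_irf,
        m_s=m_s,
        clean_triplets=clean,
        seed=seed,
    )
    logger.info(
        "dataset: %s, fx=%s, %d photons, gain=%.3g, seed=%d",
        spec.kind,
        list(patterns),
        n_photons,
        cam.gain,
        seed,
    )
    return HsfDataset(triplets=noisy, truth=truth, patterns=patterns)
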