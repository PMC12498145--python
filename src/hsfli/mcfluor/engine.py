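"""Two-step time-resolved Monte Carlo fluorescence engine.

Step 1 propagates excitation light through the voxel volume and records
where and when it is absorbed; absorption inside fluorescent voxels forms
emission sources (weighted by local quantum yield, delayed by the local
exponential lifetime). Step 2 propagates the emitted photons to the
surface detector.

Every fluorescence photon carries the x-position at which its excitation
photon was launched. Because transport is linear in the source, a single
run under uniform illumination can synthesize the surface signal for any
illumination pattern by reweighting each detected photon with the pattern
value at its launch position (see :func:`reweight_by_pattern`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
from scipy.signal import fftconvolve

from ..errors import HsfliError, InvalidConfigError
from . import _kernels as K
from .types import (
    Bookkeeping,
    EmissionSources,
    OpticalProperties,
    SurfaceRecord,
    TimeResolvedField,
    VoxelVolume,
)

logger = logging.getLogger("hsfli")

C_MM_PER_PS = K.C_MM_PER_PS

_EMPTY_F4 = np.empty(0, dtype=np.float64)
_DUMMY_TR = np.zeros((1, 1, 1, 1), dtype=np.float32)

ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1


def _kernel_seed(rng_or_seed) -> int:
    if isinstance(rng_or_seed, np.random.SeedSequence):
        return int(rng_or_seed.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1)) + 1
    return int(rng_or_seed) % (2**31 - 1) + 1


def sample_scattering_cosine(g: float, rng: np.random.Generator, size=None):
    """Draw scattering cosines from the Henyey-Greenstein phase function.

    The first moment of the distribution equals ``g``.
    """
    if not (-1.0 < g < 1.0):
        raise InvalidConfigError(f"|g| must be < 1, got {g}")
    u = rng.random(size)
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    return np.clip(cost, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Launch specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlanarSource:
    """Collimated, normally incident illumination, uniform over a field."""

    x0: float = 0.0
    x1: float | None = None  # defaults to the volume extent
    y0: float = 0.0
    y1: float | None = None


@dataclass(frozen=True)
class PencilSource:
    """Collimated, normally incident pencil beam at (x, y)."""

    x: float
    y: float


@dataclass(frozen=True)
class PatternSource:
    """Collimated illumination with launch density following a pattern.

    ``pattern`` must expose ``profile01()`` (per-column transmission in
    [0, 1]) and ``pixel_pitch_mm``. Per-photon weight equals the spatial
    mean of the profile so that totals match a uniform run reweighted by
    the same pattern.
    """

    pattern: Any
    y0: float = 0.0
    y1: float | None = None


@dataclass
class ExcitationResult:
    absorbed: np.ndarray                    # (nx, ny, nz) time-integrated deposit
    surface: SurfaceRecord                  # diffuse reflectance record
    bookkeeping: Bookkeeping
    field: TimeResolvedField | None = None  # optional dense time-resolved deposit
    events: "FluorEvents | None" = None


@dataclass
class FluorEvents:
    """Absorption events inside fluorescent voxels (pre-lifetime-delay)."""

    ix: np.ndarray
    iy: np.ndarray
    iz: np.ndarray
    t_ps: np.ndarray
    weight: np.ndarray
    launch_x_mm: np.ndarray

    def __len__(self) -> int:
        return len(self.t_ps)

    @property
    def total_weight(self) -> float:
        return float(self.weight.sum())


def _launch_args(volume: VoxelVolume, source, n_photons: int, rng: np.random.Generator):
    """Translate a source spec into kernel launch arguments."""
    lx, ly, _ = volume.extent_mm
    empty = (_EMPTY_F4,) * 7
    if isinstance(source, PlanarSource):
        x1 = lx if source.x1 is None else source.x1
        y1 = ly if source.y1 is None else source.y1
        return (K.LAUNCH_PLANAR, n_photons, source.x0, x1, source.y0, y1) + empty
    if isinstance(source, PencilSource):
        return (K.LAUNCH_PENCIL, n_photons, source.x, 0.0, source.y, 0.0) + empty
    if isinstance(source, PatternSource):
        prof = np.asarray(source.pattern.profile01(), dtype=np.float64)
        pitch = float(source.pattern.pixel_pitch_mm)
        if prof.sum() <= 0:
            raise InvalidConfigError("pattern source has zero total transmission")
        cols = rng.choice(len(prof), size=n_photons, p=prof / prof.sum())
        src_x = (cols + rng.random(n_photons)) * pitch
        y1 = ly if source.y1 is None else source.y1
        src_y = source.y0 + (y1 - source.y0) * rng.random(n_photons)
        w = np.full(n_photons, prof.mean(), dtype=np.float64)
        zeros = np.zeros(n_photons, dtype=np.float64)
        return (
            K.LAUNCH_TABLE_COLL,
            n_photons,
            0.0,
            0.0,
            0.0,
            0.0,
            src_x,
            src_y,
            zeros,
            zeros,
            w,
            src_x.copy(),
            zeros,
        )
    raise InvalidConfigError(f"unknown source spec {source!r}")


def _run_kernel(
    volume: VoxelVolume,
    launch,
    seed: int,
    *,
    emission: bool = False,
    t_max_ps: float = 25000.0,
    record_tr: bool = False,
    tr_bin_ps: float = 10.0,
    tr_nt: int = 0,
    record_events: bool = False,
    ev_ref_w: float = 0.0,
    event_cap: int = 0,
    record_exits: bool = True,
    exit_cap: int = 0,
    mirror_sides: bool = False,
):
    mua, mus, g, n_med = volume.property_tables(emission=emission)
    if not (np.all(np.isfinite(mua)) and np.all(np.isfinite(mus))):
        raise InvalidConfigError("optical properties contain NaN/inf")
    nx, ny, nz = volume.shape
    absorbed = np.zeros((nx, ny, nz), dtype=np.float64)
    if record_tr:
        if tr_nt <= 0:
            tr_nt = int(math.ceil(t_max_ps / tr_bin_ps))
        if nx * ny * nz * tr_nt > 3e8:
            raise InvalidConfigError(
                "time-resolved field too large; reduce grid or time bins"
            )
        tr_field = np.zeros((nx, ny, nz, tr_nt), dtype=np.float32)
    else:
        tr_field = _DUMMY_TR
    ev_buf = np.zeros((max(event_cap, 1), 6), dtype=np.float32)
    out_buf = np.zeros((max(exit_cap, 1), 6), dtype=np.float32)

    (mode, n_photons, x0, x1, y0, y1, sx, sy, sz, st, sw, stag, stau) = launch

    res = K.run_transport(
        seed,
        volume.tissue_label,
        volume.voxel_size_mm,
        mua,
        mus,
        g,
        n_med,
        volume.n_outside,
        mode,
        n_photons,
        x0,
        x1,
        y0,
        y1,
        np.ascontiguousarray(sx, dtype=np.float64),
        np.ascontiguousarray(sy, dtype=np.float64),
        np.ascontiguousarray(sz, dtype=np.float64),
        np.ascontiguousarray(st, dtype=np.float64),
        np.ascontiguousarray(sw, dtype=np.float64),
        np.ascontiguousarray(stag, dtype=np.float64),
        np.ascontiguousarray(stau, dtype=np.float64),
        t_max_ps,
        absorbed,
        record_tr,
        tr_field,
        tr_bin_ps,
        volume.fluor_yield,
        record_events,
        ev_ref_w,
        ev_buf,
        record_exits,
        out_buf,
        ROULETTE_THRESHOLD,
        ROULETTE_SURVIVAL,
        mirror_sides,
    )
    (
        launched_w,
        absorbed_w,
        top_w,
        other_w,
        tk_w,
        rk_w,
        rg_w,
        n_ev,
        n_out,
        ev_ovf,
        out_ovf,
    ) = res
    book = Bookkeeping(launched_w, absorbed_w, top_w, other_w, tk_w, rk_w, rg_w)
    if record_events and ev_ovf > 0:
        raise HsfliError(
            f"fluorescence event buffer overflowed by {ev_ovf}; "
            "increase event_cap or ev_ref_w"
        )
    if record_exits and out_ovf > 0:
        raise HsfliError(f"exit buffer overflowed by {out_ovf}; increase exit_cap")
    record = SurfaceRecord(
        x_mm=out_buf[:n_out, 0].copy(),
        y_mm=out_buf[:n_out, 1].copy(),
        t_ps=out_buf[:n_out, 2].copy(),
        weight=out_buf[:n_out, 3].copy(),
        launch_x_mm=out_buf[:n_out, 4].copy(),
        face=out_buf[:n_out, 5].astype(np.int8),
        bookkeeping=book,
        seed=seed,
    )
    events = None
    if record_events:
        events = FluorEvents(
            ix=ev_buf[:n_ev, 0].astype(np.int32),
            iy=ev_buf[:n_ev, 1].astype(np.int32),
            iz=ev_buf[:n_ev, 2].astype(np.int32),
            t_ps=ev_buf[:n_ev, 3].astype(np.float64),
            weight=ev_buf[:n_ev, 4].astype(np.float64),
            launch_x_mm=ev_buf[:n_ev, 5].astype(np.float64),
        )
    return absorbed, tr_field if record_tr else None, record, events, book


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def propagate_excitation(
    volume: VoxelVolume,
    source,
    n_photons: int,
    time_bin_ps: float = 10.0,
    seed: int = 0,
    *,
    t_max_ps: float = 25000.0,
    record_time_resolved: bool = True,
    n_time_bins: int | None = None,
    record_exits: bool = True,
    mirror_sides: bool = False,
) -> ExcitationResult:
    """Transport excitation photons; record absorption and boundary exits.

    Returns per-voxel absorbed weight (time-resolved when requested), the
    diffuse-reflectance surface record, and the conservation ledger. Weight
    is conserved to better than 1e-9 relative.
    """
    if n_photons < 1:
        raise InvalidConfigError("n_photons must be >= 1")
    rng = np.random.default_rng(seed)
    launch = _launch_args(volume, source, n_photons, rng)
    nt = n_time_bins or int(math.ceil(t_max_ps / time_bin_ps))
    absorbed, tr, record, _, book = _run_kernel(
        volume,
        launch,
        _kernel_seed(seed),
        t_max_ps=t_max_ps,
        record_tr=record_time_resolved,
        tr_bin_ps=time_bin_ps,
        tr_nt=nt,
        record_exits=record_exits,
        exit_cap=n_photons if record_exits else 0,
        mirror_sides=mirror_sides,
    )
    field = TimeResolvedField(tr, time_bin_ps) if tr is not None else None
    return ExcitationResult(absorbed=absorbed, surface=record, bookkeeping=book, field=field)


def form_emission_sources(
    field: TimeResolvedField, volume: VoxelVolume
) -> EmissionSources:
    """Turn absorbed excitation into per-voxel emission time profiles.

    Spatial density is absorbed energy times the local quantum yield; the
    temporal profile is the local excitation time profile convolved with
    the normalized exponential lifetime kernel. Total emitted energy equals
    sum(absorbed * yield) up to the tail truncated by the time window.
    """
    if field.values.shape[:3] != volume.shape:
        raise InvalidConfigError("field and volume shapes are not congruent")
    yld = volume.fluor_yield
    tau = volume.fluor_lifetime_ns
    idx = np.argwhere((yld > 0) & (field.values.sum(axis=3) > 0))
    nt = field.n_time_bins
    dt = field.time_bin_ps
    if len(idx) == 0:
        return EmissionSources(
            voxel_index=np.zeros((0, 3), dtype=np.int32),
            profiles=np.zeros((0, nt)),
            time_bin_ps=dt,
            shape=volume.shape,
        )
    exc = field.values[idx[:, 0], idx[:, 1], idx[:, 2], :].astype(np.float64)
    exc *= yld[idx[:, 0], idx[:, 1], idx[:, 2], None]
    taus_ps = tau[idx[:, 0], idx[:, 1], idx[:, 2]].astype(np.float64) * 1000.0
    profiles = np.empty_like(exc)
    j = np.arange(nt)
    for tval in np.unique(taus_ps):
        m = taus_ps == tval
        # P(emission in bin j | absorption in bin 0), exact for the
        # exponential integrated over each bin
        kern = np.exp(-j * dt / tval) * (1.0 - np.exp(-dt / tval))
        profiles[m] = fftconvolve(exc[m], kern[None, :], axes=1)[:, :nt]
    profiles = np.clip(profiles, 0.0, None)
    return EmissionSources(
        voxel_index=idx.astype(np.int32),
        profiles=profiles,
        time_bin_ps=dt,
        shape=volume.shape,
    )


def propagate_emission(
    volume: VoxelVolume,
    sources: EmissionSources,
    n_photons: int,
    seed: int = 0,
    *,
    t_max_ps: float = 25000.0,
) -> SurfaceRecord:
    """Transport emission photons sampled from per-voxel time profiles."""
    if sources.total_energy <= 0:
        raise InvalidConfigError("emission sources are empty")
    if sources.profiles.size > 5e7:
        raise InvalidConfigError(
            "dense emission sampling too large; use the coupled two-step path"
        )
    rng = np.random.default_rng(seed)
    p = sources.profiles.ravel() / sources.profiles.sum()
    flat = rng.choice(len(p), size=n_photons, p=p)
    vi, ti = np.divmod(flat, sources.profiles.shape[1])
    h = volume.voxel_size_mm
    pos = (sources.voxel_index[vi] + rng.random((n_photons, 3))) * h
    t0 = (ti + rng.random(n_photons)) * sources.time_bin_ps
    w = np.full(n_photons, sources.total_energy / n_photons)
    launch = (
        K.LAUNCH_TABLE_ISO,
        n_photons,
        0.0,
        0.0,
        0.0,
        0.0,
        pos[:, 0],
        pos[:, 1],
        pos[:, 2],
        t0,
        w,
        np.full(n_photons, np.nan),
        np.zeros(n_photons),
    )
    _, _, record, _, book = _run_kernel(
        volume,
        launch,
        _kernel_seed(seed),
        emission=True,
        t_max_ps=t_max_ps,
        record_exits=True,
        exit_cap=n_photons,
    )
    record.launch_x_mm = None  # dense sources do not carry launch tags
    return record


@dataclass
class TwoStepResult:
    """Fluorescence surface record plus per-step diagnostics."""

    record: SurfaceRecord            # detected fluorescence (with launch tags)
    excitation_book: Bookkeeping
    emission_book: Bookkeeping
    absorbed: np.ndarray
    n_events: int
    event_weight: float
    seed: int


def run_coupled(
    volume: VoxelVolume,
    n_excitation: int,
    n_emission: int,
    seed: int = 0,
    *,
    source=None,
    t_max_ps: float = 25000.0,
    target_events: int = 500_000,
    lifetime_components: Sequence[tuple[float, float]] | None = None,
) -> TwoStepResult:
    """One excitation pass + one emission pass with launch-x tags kept.

    Absorption events in fluorescent voxels are recorded (with online
    thinning towards ``target_events``), each spawning isotropic emission
    launches delayed by an exponential lifetime draw. ``lifetime_components``
    optionally overrides the volume lifetime map with an amplitude-weighted
    mixture [(amplitude, tau_ns), ...] — the forward model of a two-state
    FRET donor.
    """
    if source is None:
        source = PlanarSource()
    ss = np.random.SeedSequence(seed)
    s_pilot, s_main, s_emit, s_np = ss.spawn(4)
    rng = np.random.default_rng(s_np)

    if np.count_nonzero(volume.fluor_yield) == 0:
        empty = np.zeros(0, dtype=np.float32)
        zero_book = Bookkeeping(0, 0, 0, 0, 0, 0, 0)
        rec = SurfaceRecord(empty, empty, empty, empty, empty.copy(), empty.astype(np.int8))
        return TwoStepResult(rec, zero_book, zero_book, np.zeros(volume.shape), 0, 0.0, seed)

    # pilot: estimate fluorescent deposit per launched photon to set the
    # thinning reference weight
    n_pilot = min(n_excitation, max(2000, n_excitation // 100))
    launch = _launch_args(volume, source, n_pilot, rng)
    _, _, _, pilot_ev, _ = _run_kernel(
        volume,
        launch,
        _kernel_seed(s_pilot),
        t_max_ps=t_max_ps,
        record_events=True,
        ev_ref_w=0.0,
        event_cap=max(200_000, 60 * n_pilot),
        record_exits=False,
    )
    per_photon = pilot_ev.total_weight / n_pilot
    expected_total = per_photon * n_excitation
    if expected_total <= 0:
        empty = np.zeros(0, dtype=np.float32)
        zero_book = Bookkeeping(0, 0, 0, 0, 0, 0, 0)
        rec = SurfaceRecord(empty, empty, empty, empty, empty.copy(), empty.astype(np.int8))
        return TwoStepResult(rec, zero_book, zero_book, np.zeros(volume.shape), 0, 0.0, seed)
    ref_w = expected_total / max(target_events, 1)

    launch = _launch_args(volume, source, n_excitation, rng)
    absorbed, _, _, events, exc_book = _run_kernel(
        volume,
        launch,
        _kernel_seed(s_main),
        t_max_ps=t_max_ps,
        record_events=True,
        ev_ref_w=ref_w,
        event_cap=int(3.0 * target_events + 10_000),
        record_exits=False,
    )
    n_ev = len(events)
    if n_ev == 0:
        empty = np.zeros(0, dtype=np.float32)
        rec = SurfaceRecord(empty, empty, empty, empty, empty.copy(), empty.astype(np.int8))
        return TwoStepResult(rec, exc_book, Bookkeeping(0, 0, 0, 0, 0, 0, 0), absorbed, 0, 0.0, seed)

    # expand events into emission launches
    mult = max(1, int(round(n_emission / n_ev)))
    rep_ix = np.repeat(events.ix, mult)
    rep_iy = np.repeat(events.iy, mult)
    rep_iz = np.repeat(events.iz, mult)
    h = volume.voxel_size_mm
    n_launch = len(rep_ix)
    pos = np.stack([rep_ix, rep_iy, rep_iz], axis=1) + rng.random((n_launch, 3))
    pos = pos * h
    t0 = np.repeat(events.t_ps, mult)
    w = np.repeat(events.weight / mult, mult)
    tags = np.repeat(events.launch_x_mm, mult)
    if lifetime_components is not None:
        amps = np.array([a for a, _ in lifetime_components], dtype=np.float64)
        taus = np.array([t for _, t in lifetime_components], dtype=np.float64) * 1000.0
        # (A_i, tau_i) are decay amplitudes; the emitted-photon (energy)
        # share of component i is proportional to A_i * tau_i
        energy = amps * taus
        comp = rng.choice(len(amps), size=n_launch, p=energy / energy.sum())
        tau_ps = taus[comp]
    else:
        tau_ps = (
            volume.fluor_lifetime_ns[rep_ix, rep_iy, rep_iz].astype(np.float64) * 1000.0
        )
    launch = (
        K.LAUNCH_TABLE_ISO,
        n_launch,
        0.0,
        0.0,
        0.0,
        0.0,
        pos[:, 0],
        pos[:, 1],
        pos[:, 2],
        t0,
        w,
        tags,
        tau_ps,
    )
    _, _, record, _, em_book = _run_kernel(
        volume,
        launch,
        _kernel_seed(s_emit),
        emission=True,
        t_max_ps=t_max_ps,
        record_exits=True,
        exit_cap=n_launch,
    )
    logger.info(
        "coupled run: %d excitation photons, %d events, %d emission launches, "
        "%d detected (seed=%d)",
        n_excitation,
        n_ev,
        n_launch,
        len(record),
        seed,
    )
    return TwoStepResult(
        record=record,
        excitation_book=exc_book,
        emission_book=em_book,
        absorbed=absorbed,
        n_events=n_ev,
        event_weight=events.total_weight,
        seed=seed,
    )


def reweight_by_pattern(
    record: SurfaceRecord,
    pattern,
    image_shape: tuple[int, int],
    pixel_pitch_mm: float,
    time_bin_ps: float = 10.0,
    n_time_bins: int | None = None,
    t_max_ps: float = 12500.0,
) -> np.ndarray:
    """Histogram detected photons into a (T, H, W) stack under a pattern.

    Each photon's weight is multiplied by the pattern transmission (0-1)
    at its excitation launch x-position; ``pattern=None`` applies uniform
    weighting. Equal in expectation to a direct simulation whose launch
    density follows the pattern.
    """
    if record.launch_x_mm is None and pattern is not None:
        raise HsfliError("surface record carries no launch-x tags; cannot reweight")
    top = record.top()
    nt = n_time_bins or int(math.ceil(t_max_ps / time_bin_ps))
    H, W = image_shape
    stack = np.zeros(nt * H * W, dtype=np.float64)
    if len(top) == 0:
        return stack.reshape(nt, H, W)
    w = top.weight.astype(np.float64)
    if pattern is not None:
        prof = np.asarray(pattern.profile01(), dtype=np.float64)
        cols = np.clip(
            (top.launch_x_mm / pattern.pixel_pitch_mm).astype(np.int64), 0, len(prof) - 1
        )
        w = w * prof[cols]
    it = (top.t_ps / time_bin_ps).astype(np.int64)
    ixp = (top.x_mm / pixel_pitch_mm).astype(np.int64)
    iyp = (top.y_mm / pixel_pitch_mm).astype(np.int64)
    ok = (it >= 0) & (it < nt) & (ixp >= 0) & (ixp < W) & (iyp >= 0) & (iyp < H)
    flat = (it[ok] * H + iyp[ok]) * W + ixp[ok]
    stack += np.bincount(flat, weights=w[ok], minlength=stack.size)
    return stack.reshape(nt, H, W)


def simulate_two_step(
    volume: VoxelVolume,
    patterns: Sequence,
    n_photons: int,
    seed: int = 0,
    *,
    n_emission: int | None = None,
    image_shape: tuple[int, int] | None = None,
    pixel_pitch_mm: float | None = None,
    time_bin_ps: float = 10.0,
    t_max_ps: float = 12500.0,
    lifetime_components: Sequence[tuple[float, float]] | None = None,
    target_events: int = 500_000,
) -> tuple[dict, TwoStepResult]:
    """Surface fluorescence stacks for each illumination pattern.

    One uniform-illumination coupled MC per volume; all (fx, phase)
    combinations are synthesized by launch-position reweighting. Returns
    ``{(fx, phase): (T, H, W) stack}`` plus the underlying record.
    """
    if pixel_pitch_mm is None:
        pixel_pitch_mm = float(patterns[0].pixel_pitch_mm) if patterns else 0.1875
    if image_shape is None:
        lx, ly, _ = volume.extent_mm
        image_shape = (int(round(ly / pixel_pitch_mm)), int(round(lx / pixel_pitch_mm)))
    two = run_coupled(
        volume,
        n_photons,
        n_emission or n_photons,
        seed,
        t_max_ps=t_max_ps,
        lifetime_components=lifetime_components,
        target_events=target_events,
    )
    stacks = {}
    for pat in patterns:
        key = (float(pat.fx), float(pat.phase))
        stacks[key] = reweight_by_pattern(
            two.record,
            pat,
            image_shape,
            pixel_pitch_mm,
            time_bin_ps=time_bin_ps,
            t_max_ps=t_max_ps,
        )
    return stacks, two
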