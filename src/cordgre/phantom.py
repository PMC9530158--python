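"""Synthetic lumbosacral-cord phantom for multi-echo gradient-echo imaging.

The phantom emulates the lower spinal cord on an axial voxel grid: an
elliptical cord whose cross-sectional area peaks at a designated
lumbosacral-enlargement (LSE) slice and tapers caudally into the conus
medullaris, a butterfly-shaped gray-matter (GM) region present from the
designated conus (CM) slice rostrally, and a cerebrospinal-fluid (CSF)
annulus around the cord.  All shapes are analytic (ellipses and unions of
rotated ellipses), rasterised with sub-voxel occupancy by supersampling, so
areas have closed-form oracles.

Signal is generated with the ideally spoiled gradient-echo steady-state
equation

    S = PD * sin(a) * (1 - exp(-TR/T1)) / (1 - cos(a) * exp(-TR/T1))
           * exp(-TE / T2*)

with per-tissue T1, T2* and relative proton density.  Default tissue values
are literature values for the cord at 3 T: GM T1 994 ms / T2* 41.3 ms /
PD 0.8, WM T1 853 ms / T2* 39.8 ms / PD 0.7 (dorsal-column T1; the
lateral-column value 830 ms can be configured instead), CSF T1 4000 ms /
T2* 2000 ms / PD 1.0.

Noise is thermal: complex Gaussian on two channels yielding a Rician
magnitude, with a Gaussian switch for exact analytic tests.  Bulk motion is
a rigid translation per repetition, applied to the noiseless volume as a
spectral (Fourier) sub-voxel shift before noise is added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import fourier_shift

from .protocol import AcquisitionProtocol, te_ladder

__all__ = [
    "TissueParams",
    "TissueModel",
    "PhantomGeometry",
    "GridSpec",
    "MotionTrace",
    "NoiseSpec",
    "PhantomVolume",
    "GeometryError",
    "build_geometry",
    "spoiled_gre_signal",
    "signal_ladder",
    "simulate_dataset",
    "calibrate_sigma",
]


class GeometryError(ValueError):
    """Raised when phantom geometry parameters are inconsistent."""


@dataclass(frozen=True)
class TissueParams:
    """Relaxation and proton-density parameters of one tissue class."""

    t1_ms: float
    t2star_ms: float
    pd: float

    def __post_init__(self) -> None:
        if self.t1_ms <= 0 or self.t2star_ms <= 0:
            raise ValueError("T1 and T2* must be positive")
        if not 0 < self.pd <= 1:
            raise ValueError("relative proton density must be in (0, 1]")


@dataclass(frozen=True)
class TissueModel:
    """Per-class tissue parameters (background is signal-free)."""

    gm: TissueParams = field(default_factory=lambda: TissueParams(994.0, 41.3, 0.8))
    wm: TissueParams = field(default_factory=lambda: TissueParams(853.0, 39.8, 0.7))
    csf: TissueParams = field(default_factory=lambda: TissueParams(4000.0, 2000.0, 1.0))

    def __getitem__(self, label: str) -> TissueParams:
        try:
            return getattr(self, label.lower())
        except AttributeError:
            raise KeyError(label) from None

    @property
    def labels(self) -> tuple[str, ...]:
        return ("gm", "wm", "csf")


@dataclass(frozen=True)
class GridSpec:
    """Axial voxel grid: in-plane shape/size and slice stack."""

    shape: tuple[int, int] = (128, 128)
    voxel_mm: float = 0.5
    n_slices: int = 12
    slice_thickness_mm: float = 5.0

    def __post_init__(self) -> None:
        if min(self.shape) < 8 or self.n_slices < 1:
            raise ValueError("grid too small")
        if self.voxel_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("voxel dimensions must be positive")

    @property
    def voxel_dims_mm(self) -> tuple[float, float, float]:
        return (self.voxel_mm, self.voxel_mm, self.slice_thickness_mm)

    @property
    def voxel_area_mm2(self) -> float:
        return self.voxel_mm**2

    @classmethod
    def from_protocol(cls, protocol: AcquisitionProtocol) -> "GridSpec":
        return cls(
            shape=protocol.matrix,
            voxel_mm=protocol.in_plane_mm,
            n_slices=protocol.n_slices,
            slice_thickness_mm=protocol.slice_thickness_mm,
        )


# Gray-matter butterfly template at the reference cord size (semi-axes
# 4.8 x 3.6 mm).  Each lobe: (cx, cy, semi_a, semi_b, rotation_deg) in mm,
# anterior = -y, left = -x.  Scaled per slice together with the cord.
_GM_LOBES: tuple[tuple[float, float, float, float, float], ...] = (
    (-1.3, -1.0, 1.00, 1.30, +25.0),  # ventral horn, left
    (+1.3, -1.0, 1.00, 1.30, -25.0),  # ventral horn, right
    (-0.9, +1.2, 0.55, 1.15, -15.0),  # dorsal horn, left
    (+0.9, +1.2, 0.55, 1.15, +15.0),  # dorsal horn, right
    (0.0, 0.0, 1.30, 0.55, 0.0),      # central commissure band
)


@dataclass(frozen=True)
class PhantomGeometry:
    """Parametric cord/GM/CSF geometry of the phantom.

    The cord cross-section is an ellipse whose scale follows an asymmetric
    Gaussian profile of the slice index, peaking (strictly) at ``lse_slice``
    and tapering faster caudally (conus).  The butterfly GM template is
    present for slices >= ``cm_slice``; more caudal slices carry only a small
    central GM blob (the butterfly shape is lost).
    """

    lse_slice: int = 8
    cm_slice: int = 4
    cord_semi_axes_mm: tuple[float, float] = (4.8, 3.6)
    csf_margin_mm: float = 3.0
    gm_scale: float = 1.0
    gm_horn_width_scale: float = 1.0
    rostral_taper_slices: float = 3.0
    caudal_taper_slices: float = 3.5
    supersampling: int = 4

    def __post_init__(self) -> None:
        if self.cord_semi_axes_mm[0] <= 0 or self.cord_semi_axes_mm[1] <= 0:
            raise GeometryError("cord semi-axes must be positive")
        if self.csf_margin_mm <= 0:
            raise GeometryError("CSF margin must be positive")
        if self.gm_scale < 0 or self.gm_horn_width_scale < 0:
            raise GeometryError("GM scales must be non-negative")
        if self.cm_slice >= self.lse_slice:
            raise GeometryError("CM slice must be caudal to (below) the LSE slice")
        self._check_gm_inside_cord()

    def _check_gm_inside_cord(self) -> None:
        # GM and cord scale together per slice, so containment need only be
        # checked once on the template.  Sample each lobe boundary.
        a_c, b_c = self.cord_semi_axes_mm
        t = np.linspace(0.0, 2 * math.pi, 181)
        for cx, cy, sa, sb, deg in _GM_LOBES:
            sa = sa * self.gm_scale * self.gm_horn_width_scale
            sb = sb * self.gm_scale * self.gm_horn_width_scale
            cx, cy = cx * self.gm_scale, cy * self.gm_scale
            th = math.radians(deg)
            x = cx + sa * np.cos(t) * math.cos(th) - sb * np.sin(t) * math.sin(th)
            y = cy + sa * np.cos(t) * math.sin(th) + sb * np.sin(t) * math.cos(th)
            if np.any((x / a_c) ** 2 + (y / b_c) ** 2 > 1.0):
                raise GeometryError(
                    "gray-matter template exceeds the cord outline; reduce gm_scale "
                    "or gm_horn_width_scale"
                )

    @classmethod
    def for_slices(cls, n_slices: int, **overrides) -> "PhantomGeometry":
        """Default geometry with LSE/CM indices placed for ``n_slices`` slices."""
        lse = overrides.pop("lse_slice", round(0.7 * (n_slices - 1)))
        cm = overrides.pop("cm_slice", round(0.35 * (n_slices - 1)))
        return cls(lse_slice=lse, cm_slice=cm, **overrides)

    def cord_scale(self, slice_index: np.ndarray | int) -> np.ndarray:
        """Per-slice cord scale factor; strict unique maximum at the LSE slice."""
        s = np.asarray(slice_index, dtype=float)
        width = np.where(s > self.lse_slice, self.rostral_taper_slices, self.caudal_taper_slices)
        return 0.55 + 0.45 * np.exp(-0.5 * ((s - self.lse_slice) / width) ** 2)


@dataclass(frozen=True)
class MotionTrace:
    """Per-repetition rigid translation (dx, dy, dz) in mm."""

    shifts_mm: np.ndarray

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.shifts_mm, dtype=float))
        if arr.ndim != 2 or arr.shape[1] != 3 or not np.all(np.isfinite(arr)):
            raise ValueError("shifts_mm must be a finite (R, 3) array")
        object.__setattr__(self, "shifts_mm", arr)

    def __len__(self) -> int:
        return self.shifts_mm.shape[0]

    @classmethod
    def zero(cls, n_repetitions: int) -> "MotionTrace":
        return cls(np.zeros((n_repetitions, 3)))

    @classmethod
    def random(
        cls, n_repetitions: int, max_mm: float = 0.6, seed: int | None = None
    ) -> "MotionTrace":
        """Uniform random translations with per-repetition norm <= ``max_mm``."""
        rng = np.random.default_rng(seed)
        vec = rng.normal(size=(n_repetitions, 3))
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        radius = max_mm * rng.uniform(0.0, 1.0, size=(n_repetitions, 1)) ** (1 / 3)
        return cls(vec * radius)


@dataclass(frozen=True)
class NoiseSpec:
    """Thermal-noise model: standard deviation, family, and RNG seed."""

    sigma: float = 0.0
    family: str = "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.family not in ("rician", "gaussian"):
            raise ValueError("family must be 'rician' or 'gaussian'")


@dataclass(frozen=True)
class PhantomVolume:
    """Ground-truth sub-voxel occupancies and slice metadata."""

    occupancy: dict[str, np.ndarray]  # 'gm', 'wm', 'csf' -> (nx, ny, nz)
    grid: GridSpec
    geometry: PhantomGeometry
    cord_area_mm2: np.ndarray          # per-slice, sub-voxel occupancy sum
    analytic_cord_area_mm2: np.ndarray  # per-slice pi*a*b of the cord ellipse

    @property
    def lse_slice(self) -> int:
        return self.geometry.lse_slice

    @property
    def cm_slice(self) -> int:
        return self.geometry.cm_slice

    @property
    def cord(self) -> np.ndarray:
        """Spinal-cord occupancy (GM + WM)."""
        return self.occupancy["gm"] + self.occupancy["wm"]

    def cord_semi_axes(self, slice_index: int) -> tuple[float, float]:
        f = float(self.geometry.cord_scale(slice_index))
        a, b = self.geometry.cord_semi_axes_mm
        return a * f, b * f


def _ellipse_mask(x, y, cx, cy, sa, sb, deg=0.0):
    th = math.radians(deg)
    u = (x - cx) * math.cos(th) + (y - cy) * math.sin(th)
    v = -(x - cx) * math.sin(th) + (y - cy) * math.cos(th)
    return (u / sa) ** 2 + (v / sb) ** 2 <= 1.0


def build_geometry(geometry: PhantomGeometry, grid: GridSpec) -> PhantomVolume:
    """Rasterise the phantom into per-class sub-voxel occupancy maps.

    Each slice is supersampled by ``geometry.supersampling`` in each in-plane
    direction; occupancy is the block mean of the analytic indicator.
    Occupancies of GM, WM and CSF sum to <= 1 per voxel (the remainder is
    signal-free background).
    """
    if geometry.supersampling < 4:
        raise GeometryError("supersampling must be >= 4")
    if not 0 <= geometry.cm_slice < geometry.lse_slice < grid.n_slices:
        raise GeometryError(
            f"need 0 <= cm_slice < lse_slice < n_slices, got "
            f"cm={geometry.cm_slice}, lse={geometry.lse_slice}, n={grid.n_slices}"
        )

    nx, ny = grid.shape
    nz = grid.n_slices
    ss = geometry.supersampling
    # supersample point coordinates (mm), phantom centred on the grid
    xs = (np.arange(nx * ss) + 0.5) * (grid.voxel_mm / ss) - nx * grid.voxel_mm / 2
    ys = (np.arange(ny * ss) + 0.5) * (grid.voxel_mm / ss) - ny * grid.voxel_mm / 2
    x, y = np.meshgrid(xs, ys, indexing="ij")

    a0, b0 = geometry.cord_semi_axes_mm
    occ = {c: np.zeros((nx, ny, nz)) for c in ("gm", "wm", "csf")}
    scales = geometry.cord_scale(np.arange(nz))

    def block_mean(mask):
        return mask.reshape(nx, ss, ny, ss).mean(axis=(1, 3))

    for s in range(nz):
        f = float(scales[s])
        a, b = a0 * f, b0 * f
        cord = _ellipse_mask(x, y, 0.0, 0.0, a, b)
        outer = _ellipse_mask(
            x, y, 0.0, 0.0, a + geometry.csf_margin_mm, b + geometry.csf_margin_mm
        )
        gm = np.zeros_like(cord)
        g = f * geometry.gm_scale
        if g > 0 and geometry.gm_horn_width_scale > 0:
            if s >= geometry.cm_slice:
                lobes = _GM_LOBES
            else:
                # caudal to the conus slice the butterfly is lost; keep a
                # small round central blob only
                lobes = ((0.0, 0.0, 0.9, 0.7, 0.0),)
            w = geometry.gm_horn_width_scale
            for cx, cy, sa, sb, deg in lobes:
                gm |= _ellipse_mask(x, y, cx * g, cy * g, sa * g * w, sb * g * w, deg)
            gm &= cord
        occ["gm"][:, :, s] = block_mean(gm)
        occ["wm"][:, :, s] = block_mean(cord & ~gm)
        occ["csf"][:, :, s] = block_mean(outer & ~cord)

    cord_occ = occ["gm"] + occ["wm"]
    cord_area = cord_occ.sum(axis=(0, 1)) * grid.voxel_area_mm2
    analytic = math.pi * a0 * b0 * scales**2
    # strict unique maximum at the LSE slice is guaranteed by the profile;
    # confirm on the rasterised maps
    if int(np.argmax(cord_area)) != geometry.lse_slice:
        raise GeometryError("rasterised cord area does not peak at the LSE slice")
    return PhantomVolume(
        occupancy=occ,
        grid=grid,
        geometry=geometry,
        cord_area_mm2=cord_area,
        analytic_cord_area_mm2=analytic,
    )


def spoiled_gre_signal(
    tissue: TissueParams,
    protocol: AcquisitionProtocol,
    echo_index: int,
) -> float:
    """Noiseless ideally spoiled GRE steady-state signal at ``echo_index`` (1-based).

    ``S = PD sin(a) (1 - E1) / (1 - cos(a) E1) exp(-TE/T2*)`` with
    ``E1 = exp(-TR/T1)``.  Relative (scale-free) units.
    """
    if not 1 <= echo_index <= protocol.n_echoes:
        raise ValueError(
            f"echo_index must be in 1..{protocol.n_echoes}, got {echo_index}"
        )
    te = te_ladder(protocol)[echo_index - 1]
    e1 = math.exp(-protocol.tr_ms / tissue.t1_ms)
    alpha = protocol.flip_rad
    steady = tissue.pd * math.sin(alpha) * (1 - e1) / (1 - math.cos(alpha) * e1)
    return steady * math.exp(-te / tissue.t2star_ms)


def signal_ladder(tissue: TissueParams, protocol: AcquisitionProtocol) -> np.ndarray:
    """Signal at every echo of the train."""
    return np.array(
        [spoiled_gre_signal(tissue, protocol, e + 1) for e in range(protocol.n_echoes)]
    )


def calibrate_sigma(
    tissue: TissueModel,
    protocol: AcquisitionProtocol,
    target_snr: float = 20.0,
    k_echoes: int = 2,
    nsa: int | None = None,
) -> float:
    """Noise SD such that WM SNR on the ``k_echoes`` RMS combination at
    ``nsa`` averages equals ``target_snr``.

    Uses the delta-method noise propagation of the RMS combination
    (SD -> sigma / sqrt(k)) and the 1/sqrt(NSA) averaging law:
    ``sigma = S_rms(WM, k) * sqrt(k * nsa) / target_snr``.  The default
    target of 20 matches the in-vivo scale of WM SNR on the 2-echo
    combination at 8 averages.
    """
    if nsa is None:
        nsa = protocol.n_repetitions
    s = signal_ladder(tissue.wm, protocol)[:k_echoes]
    s_rms = math.sqrt(float(np.mean(s**2)))
    return s_rms * math.sqrt(k_echoes * nsa) / target_snr


def simulate_dataset(
    phantom: PhantomVolume,
    tissue: TissueModel,
    protocol: AcquisitionProtocol,
    noise: NoiseSpec | None = None,
    motion: MotionTrace | None = None,
):
    """Simulate a multi-echo magnitude acquisition of the phantom.

    Per echo, the noiseless volume is the occupancy-weighted mixture of the
    class signals.  Each repetition applies its rigid translation (spectral
    sub-voxel shift of the whole volume, through-slice included) and then
    adds thermal noise: Rician magnitude (complex Gaussian on two channels)
    or its Gaussian approximation.  Identical seeds give identical data.

    Returns a :class:`cordgre.series.MultiEchoDataset` with axes
    (x, y, slice, echo, repetition).
    """
    from .series import MultiEchoDataset  # local import to avoid a cycle

    noise = noise or NoiseSpec(sigma=0.0)
    R = protocol.n_repetitions
    if motion is None:
        motion = MotionTrace.zero(R)
    if len(motion) != R:
        raise ValueError(
            f"motion trace length {len(motion)} != {R} repetitions"
        )

    clean = np.zeros(phantom.cord.shape + (protocol.n_echoes,))
    for label in tissue.labels:
        s = signal_ladder(tissue[label], protocol)
        clean += phantom.occupancy[label][..., None] * s

    voxel = phantom.grid.voxel_dims_mm
    rng = np.random.default_rng(noise.seed)
    data = np.empty(clean.shape + (R,))
    for r in range(R):
        shift_vox = motion.shifts_mm[r] / np.asarray(voxel)
        if np.any(shift_vox != 0):
            vol = np.empty_like(clean)
            for e in range(protocol.n_echoes):
                spec = fourier_shift(np.fft.fftn(clean[..., e]), shift_vox)
                vol[..., e] = np.fft.ifftn(spec).real
            vol = np.clip(vol, 0.0, None)
        else:
            vol = clean
        if noise.sigma > 0:
            n1 = rng.normal(0.0, noise.sigma, size=vol.shape)
            if noise.family == "rician":
                n2 = rng.normal(0.0, noise.sigma, size=vol.shape)
                data[..., r] = np.hypot(vol + n1, n2)
            else:
                data[..., r] = np.abs(vol + n1)
        else:
            data[..., r] = vol

    meta = {
        "lse_slice": phantom.lse_slice,
        "cm_slice": phantom.cm_slice,
        "noise": noise,
        "motion_mm": motion.shifts_mm,
    }
    return MultiEchoDataset(data=data, voxel_mm=voxel, protocol=protocol, meta=meta)
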