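"""Synthetic contrast-CT phantoms of straight and aneurysmal abdominal aortas.

The phantom emulates the substrate of a contrast-enhanced abdominal CT
angiography at the level of the descending/abdominal aorta: a bright
contrast-filled lumen, a soft-tissue wall ring, perivascular fat in the
adipose Hounsfield window (−190…−30 HU) with a programmable radial
attenuation profile (denser fat near the wall), non-fat background tissue,
and optional additive Gaussian noise.  Every phantom ships with its ground
truth — segmentation mask, anatomic landmarks, and the analytically known
per-band shell statistics — so the downstream distance-shell densitometry
can be validated without any real scan.

Tissue membership is decided per voxel center with no sub-voxel
anti-aliasing: a voxel belongs to the vessel iff its center's radial
distance to the centerline is within the local radius.  Perivascular fat
bands are laid out with the same discrete metric the measurement stage
uses — the anisotropic Euclidean distance from the voxel center to the
nearest vessel-voxel center — which makes the recorded expected shell means
exact rather than merely border-tolerant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import CTVolume

FAT_WINDOW = (-190.0, -30.0)

#: distance bands (mm, half-open) shared with the densitometry defaults
BAND_EDGES = {
    "inner": (0.0, 2.0),
    "close": (2.0, 5.0),
    "gap": (5.0, 10.0),
    "distant": (10.0, 12.0),
}

AAA_LANDMARKS = ("aortic_bifurcation", "coeliac_trunk", "aaa_inferior_end", "aaa_superior_end")
CONTROL_LANDMARKS = ("aortic_bifurcation", "right_renal_junction")


@dataclass(frozen=True)
class StraightCenterline:
    """Vessel axis parallel to the z grid axis at a fixed (x, y) in mm."""

    x_mm: float
    y_mm: float


@dataclass(frozen=True)
class CurvedCenterline:
    """Sinusoidal in-plane deflection: x(z) = x + A sin(2π z / period)."""

    x_mm: float
    y_mm: float
    amplitude_mm: float = 5.0
    period_mm: float = 80.0


@dataclass(frozen=True)
class AneurysmSpec:
    """Fusiform or saccular dilation centred at an arc-length position.

    ``fusiform`` widens the vessel axisymmetrically with a smooth cosine²
    longitudinal profile; ``saccular`` concentrates the same widening on the
    +x side of the wall (an outpouching), falling off with the angular
    distance from that direction.
    """

    center_s_mm: float
    length_mm: float
    max_radius_mm: float
    shape: str = "fusiform"

    def __post_init__(self) -> None:
        if self.shape not in ("fusiform", "saccular"):
            raise ValueError(f"aneurysm shape must be fusiform or saccular, got {self.shape!r}")
        if self.length_mm <= 0:
            raise ValueError("aneurysm length must be positive")


@dataclass(frozen=True)
class FatProfile:
    """Radial HU profile of the perivascular tissue, one value per band.

    ``inner`` covers [0, 2) mm (the zone the densitometry excludes), ``close``
    [2, 5) mm, ``gap`` [5, 10) mm, ``distant`` [10, 12) mm and ``outer``
    everything beyond.  Values inside the adipose window count as fat after
    thresholding; a value placed outside the window makes that band invisible
    to the fat measurement.
    """

    inner: float = -100.0
    close: float = -100.0
    gap: float = -100.0
    distant: float = -100.0
    outer: float = -100.0

    def band_value(self, name: str) -> float:
        return getattr(self, name)


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (57, 57, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    centerline: StraightCenterline | CurvedCenterline | None = None
    lumen_radius_mm: float = 7.0
    wall_thickness_mm: float = 2.0
    aneurysm: AneurysmSpec | None = None
    hu_lumen: float = 300.0
    hu_wall: float = 40.0
    fat_profile: FatProfile = field(default_factory=FatProfile)
    background_hu: float = 30.0
    fat_fraction: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.wall_thickness_mm <= 0:
            raise ValueError("wall thickness must be positive (zero-thickness wall)")
        if self.lumen_radius_mm <= 0:
            raise ValueError("lumen radius must be positive")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError("fat_fraction must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.aneurysm is not None and self.aneurysm.max_radius_mm < self.lumen_radius_mm:
            raise ValueError(
                f"aneurysm max radius {self.aneurysm.max_radius_mm} mm is below the "
                f"lumen radius {self.lumen_radius_mm} mm"
            )

    def resolved_centerline(self) -> StraightCenterline | CurvedCenterline:
        if self.centerline is not None:
            return self.centerline
        cx = (self.grid_shape[0] - 1) * self.spacing[0] / 2.0
        cy = (self.grid_shape[1] - 1) * self.spacing[1] / 2.0
        return StraightCenterline(cx, cy)


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    segmentation: np.ndarray
    landmarks: dict[str, np.ndarray]
    section_intervals: dict[str, tuple[float, float]]
    centerline_points: np.ndarray  # (n, 3) mm, fine sampling
    path_length_mm: float
    expected_shell_means: dict[str, dict[str, float]]  # section -> band -> HU
    expected_shell_volumes: dict[str, dict[str, float]]  # section -> band -> cm³


def _centerline_samples(config: PhantomConfig, step_mm: float = 0.5) -> np.ndarray:
    spec = config.resolved_centerline()
    z_max = (config.grid_shape[2] - 1) * config.spacing[2]
    z = np.arange(0.0, z_max + step_mm / 2, step_mm)
    z = np.clip(z, 0.0, z_max)
    if isinstance(spec, StraightCenterline):
        x = np.full_like(z, spec.x_mm)
    else:
        x = spec.x_mm + spec.amplitude_mm * np.sin(2 * np.pi * z / spec.period_mm)
    y = np.full_like(z, spec.y_mm if isinstance(spec, StraightCenterline) else spec.y_mm)
    return np.column_stack([x, y, z])


def _arc_length(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _bulge(config: PhantomConfig, s: np.ndarray) -> np.ndarray:
    an = config.aneurysm
    if an is None:
        return np.zeros_like(s)
    half = an.length_mm / 2.0
    u = (s - an.center_s_mm) / half
    amp = an.max_radius_mm - config.lumen_radius_mm
    prof = np.where(np.abs(u) < 1.0, np.cos(np.pi * u / 2.0) ** 2, 0.0)
    return amp * prof


def _local_radius(config: PhantomConfig, s: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Lumen radius at arc-length ``s`` toward in-plane direction ``theta``."""
    bulge = _bulge(config, s)
    if config.aneurysm is not None and config.aneurysm.shape == "saccular":
        bulge = bulge * ((1.0 + np.cos(theta)) / 2.0) ** 2
    return config.lumen_radius_mm + bulge


def _check_extent(config: PhantomConfig, cl: np.ndarray, s: np.ndarray) -> None:
    an = config.aneurysm
    if an is None:
        return
    z_max = (config.grid_shape[2] - 1) * config.spacing[2]
    lo, hi = an.center_s_mm - an.length_mm / 2, an.center_s_mm + an.length_mm / 2
    if lo < 0 or hi > z_max:
        raise ValueError(
            f"aneurysm arc extent [{lo:.1f}, {hi:.1f}] mm exceeds the vessel span "
            f"[0, {z_max:.1f}] mm"
        )
    outer = an.max_radius_mm + config.wall_thickness_mm
    for axis in (0, 1):
        extent = (config.grid_shape[axis] - 1) * config.spacing[axis]
        lo_edge = float(np.min(cl[:, axis])) - outer
        hi_edge = float(np.max(cl[:, axis])) + outer
        if lo_edge < 0 or hi_edge > extent:
            raise ValueError(
                f"aneurysm outer radius {outer:.1f} mm reaches [{lo_edge:.1f}, "
                f"{hi_edge:.1f}] mm on axis {axis}, outside the grid extent "
                f"[0, {extent:.1f}] mm"
            )


def _voxel_grid_mm(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ax = [np.arange(n) * sp for n, sp in zip(config.grid_shape, config.spacing)]
    return np.meshgrid(*ax, indexing="ij")


def _nearest_on_path(points_mm: np.ndarray, path: np.ndarray) -> np.ndarray:
    """Index of the nearest path point per query (deterministic KD-tree)."""
    from scipy.spatial import cKDTree

    _, idx = cKDTree(path).query(points_mm)
    return idx


def _section_intervals(config: PhantomConfig, s_total: float) -> tuple[dict, dict]:
    """Landmark arc positions and the section intervals they induce."""
    z_margin = 2.0
    if config.aneurysm is not None:
        an = config.aneurysm
        lm_s = {
            "aortic_bifurcation": 0.0,
            "coeliac_trunk": s_total - z_margin,
            "aaa_inferior_end": an.center_s_mm - an.length_mm / 2,
            "aaa_superior_end": an.center_s_mm + an.length_mm / 2,
        }
        intervals = {
            "aneurysmal": (lm_s["aaa_inferior_end"], lm_s["aaa_superior_end"]),
            "non_aneurysmal_abdominal": (0.0, lm_s["coeliac_trunk"]),
        }
    else:
        lm_s = {
            "aortic_bifurcation": 0.0,
            "right_renal_junction": s_total - z_margin,
        }
        intervals = {"infrarenal": (0.0, lm_s["right_renal_junction"])}
    return lm_s, intervals


def _label_sections(s_vox: np.ndarray, intervals: dict[str, tuple[float, float]]) -> dict[str, np.ndarray]:
    """Boolean selector per section; the aneurysmal interval takes precedence."""
    out: dict[str, np.ndarray] = {}
    aneurysmal = None
    if "aneurysmal" in intervals:
        lo, hi = intervals["aneurysmal"]
        aneurysmal = (s_vox >= lo) & (s_vox <= hi)
        out["aneurysmal"] = aneurysmal
    for name, (lo, hi) in intervals.items():
        if name == "aneurysmal":
            continue
        sel = (s_vox >= lo) & (s_vox <= hi)
        if aneurysmal is not None:
            sel &= ~aneurysmal
        out[name] = sel
    return out


def generate_phantom(config: PhantomConfig) -> tuple[CTVolume, PhantomTruth]:
    """Render one phantom and its ground truth.

    Deterministic: the same ``config`` (including ``seed``) reproduces the
    volume bit-exactly.
    """
    path = _centerline_samples(config)
    s_path = _arc_length(path)
    _check_extent(config, path, s_path)

    gx, gy, gz = _voxel_grid_mm(config)
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    nearest = _nearest_on_path(pts, path)
    near_pts = path[nearest]
    s_vox = s_path[nearest]
    dx = pts[:, 0] - near_pts[:, 0]
    dy = pts[:, 1] - near_pts[:, 1]
    r = np.hypot(dx, dy)  # radial distance in the vessel cross-section plane
    theta = np.arctan2(dy, dx)

    radius = _local_radius(config, s_vox, theta)
    lumen = r <= radius
    vessel = r <= radius + config.wall_thickness_mm
    wall = vessel & ~lumen

    shape = config.grid_shape
    lumen = lumen.reshape(shape)
    wall = wall.reshape(shape)
    vessel = vessel.reshape(shape)
    s_vox = s_vox.reshape(shape)

    # fat bands laid out with the measurement's own discrete distance metric
    dist = ndimage.distance_transform_edt(~vessel, sampling=config.spacing)

    hu = np.full(shape, config.background_hu, dtype=np.float64)
    rng = np.random.default_rng(config.seed)
    fat_field = rng.random(shape) < config.fat_fraction

    band_sel: dict[str, np.ndarray] = {}
    outside = ~vessel
    for name, (lo, hi) in BAND_EDGES.items():
        band_sel[name] = outside & (dist >= lo) & (dist < hi)
    band_sel["outer"] = outside & (dist >= BAND_EDGES["distant"][1])

    for name, sel in band_sel.items():
        hu[sel & fat_field] = config.fat_profile.band_value(name)
    hu[lumen] = config.hu_lumen
    hu[wall] = config.hu_wall
    if config.noise_sigma > 0:
        hu = hu + rng.normal(0.0, config.noise_sigma, size=shape)

    s_total = float(s_path[-1])
    lm_s, intervals = _section_intervals(config, s_total)
    lm_idx = {name: int(np.argmin(np.abs(s_path - s))) for name, s in lm_s.items()}
    landmarks = {name: path[i].copy() for name, i in lm_idx.items()}

    section_sel = _label_sections(s_vox, intervals)
    voxvol = float(np.prod(config.spacing))
    means: dict[str, dict[str, float]] = {}
    vols: dict[str, dict[str, float]] = {}
    for sec, sel in section_sel.items():
        means[sec] = {}
        vols[sec] = {}
        for band in ("close", "distant"):
            value = config.fat_profile.band_value(band)
            n_geom = int(np.count_nonzero(band_sel[band] & sel))
            in_window = FAT_WINDOW[0] <= value <= FAT_WINDOW[1]
            means[sec][band] = value if in_window else math.nan
            vols[sec][band] = (
                config.fat_fraction * n_geom * voxvol / 1000.0 if in_window else 0.0
            )

    truth = PhantomTruth(
        segmentation=vessel,
        landmarks=landmarks,
        section_intervals=intervals,
        centerline_points=path,
        path_length_mm=s_total,
        expected_shell_means=means,
        expected_shell_volumes=vols,
    )
    return CTVolume(data=hu, spacing=config.spacing), truth


@dataclass(frozen=True)
class GroupEffect:
    """Per-patient fat-attenuation distribution for one cohort arm.

    Each patient draws a distant-band HU from N(distant_mean, distant_sd) and
    a close−distant difference from N(delta_mean, delta_sd); the close band is
    their sum.  Draws are clipped to the adipose window so the rendered fat
    stays measurable.
    """

    distant_mean: float = -83.0
    distant_sd: float = 10.0
    delta_mean: float = 8.0
    delta_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.distant_sd < 0 or self.delta_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class PhantomCase:
    patient_id: str
    group: str  # "AAA" | "control"
    config: PhantomConfig
    volume: CTVolume
    truth: PhantomTruth
    drawn_close: float
    drawn_distant: float


DEFAULT_AAA_EFFECT = GroupEffect(distant_mean=-83.9, distant_sd=13.5, delta_mean=8.9, delta_sd=5.1)
DEFAULT_CONTROL_EFFECT = GroupEffect(distant_mean=-83.4, distant_sd=12.5, delta_mean=6.9, delta_sd=4.8)

_DEFAULT_ANEURYSM = AneurysmSpec(center_s_mm=30.0, length_mm=24.0, max_radius_mm=12.0)


def generate_cohort(
    n_aaa: int,
    n_control: int,
    aaa_effect: GroupEffect = DEFAULT_AAA_EFFECT,
    control_effect: GroupEffect = DEFAULT_CONTROL_EFFECT,
    seed: int = 0,
    base_config: PhantomConfig | None = None,
    aneurysm: AneurysmSpec = _DEFAULT_ANEURYSM,
) -> list[PhantomCase]:
    """Simulate a two-arm cohort of phantoms with per-patient fat attenuation.

    Controls are rendered without an aneurysm and carry the control landmark
    set; AAA patients get a dilated segment and AAA landmarks.
    """
    if n_aaa < 1 or n_control < 1:
        raise ValueError("both group sizes must be at least 1")
    base = base_config if base_config is not None else PhantomConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_aaa + n_control)
    cases: list[PhantomCase] = []
    specs = [("AAA", aaa_effect, aneurysm)] * n_aaa + [("control", control_effect, None)] * n_control
    for i, ((group, eff, an), child) in enumerate(zip(specs, children)):
        rng = np.random.default_rng(child)
        distant = float(np.clip(rng.normal(eff.distant_mean, eff.distant_sd), -185.0, -35.0))
        delta = float(rng.normal(eff.delta_mean, eff.delta_sd))
        close = float(np.clip(distant + delta, -189.0, -31.0))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        profile = FatProfile(
            inner=close, close=close, gap=(close + distant) / 2.0, distant=distant, outer=distant
        )
        config = replace(base, aneurysm=an, fat_profile=profile, seed=sub_seed)
        volume, truth = generate_phantom(config)
        cases.append(
            PhantomCase(
                patient_id=f"{group.lower()}_{i:03d}",
                group=group,
                config=config,
                volume=volume,
                truth=truth,
                drawn_close=close,
                drawn_distant=distant,
            )
        )
    return cases
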