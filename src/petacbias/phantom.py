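"""Synthetic 2-D head phantom and arterial input-function generator.

The phantom is a single transaxial slice built from nested ellipses: scalp
soft tissue, a subcutaneous fat ring, a skull ring, a gray-matter shell and a
white-matter core.  It carries everything the downstream pipeline needs —
tissue labels, the true 511 keV μ-map, a CT Hounsfield map, Dixon phase
images, VOI masks and ground-truth kinetic parameters per tissue.

Three VOIs emulate the analysis regions of a brain study: the whole
gray-matter shell (``WBGM``), a cortical ribbon hugging the skull (``SPL``,
the bone-adjacent region) and a deep gray region far from bone (``INS``).
The cortical/deep split is what exposes the bone-distance dependence of
attenuation-correction bias.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.signal import fftconvolve

from .acmaps import DixonImagePair, ct_to_mu
from .kinetics import KineticParams
from .tacs import FrameSchedule


class PhantomConfigError(ValueError):
    """Raised for geometrically or physically inconsistent phantom specs."""


class Tissue(IntEnum):
    AIR = 0
    SOFT = 1
    FAT = 2
    BONE = 3
    GRAY = 4
    WHITE = 5


# Dixon water/fat signal per tissue (arbitrary units). Bone emits ~no signal.
_DIXON_WATER = {Tissue.AIR: 0.0, Tissue.SOFT: 0.90, Tissue.FAT: 0.15,
                Tissue.BONE: 0.02, Tissue.GRAY: 1.00, Tissue.WHITE: 0.95}
_DIXON_FAT = {Tissue.AIR: 0.0, Tissue.SOFT: 0.10, Tissue.FAT: 0.90,
              Tissue.BONE: 0.02, Tissue.GRAY: 0.05, Tissue.WHITE: 0.10}


def _default_kinetics() -> dict[Tissue, KineticParams]:
    # Plausible verapamil-scale rates; gray/white carry the signal of
    # interest, scalp tissues a small background, bone and air none.
    return {
        Tissue.GRAY: KineticParams(K1=0.054, k2=0.077, Vb=0.05, delay_s=3.0),
        Tissue.WHITE: KineticParams(K1=0.035, k2=0.060, Vb=0.05, delay_s=3.0),
        Tissue.SOFT: KineticParams(K1=0.020, k2=0.100, Vb=0.03, delay_s=3.0),
        Tissue.FAT: KineticParams(K1=0.005, k2=0.050, Vb=0.01, delay_s=3.0),
        Tissue.BONE: KineticParams(K1=0.0, k2=1.0, Vb=0.0, delay_s=0.0),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue properties and subject context of one phantom.

    Ellipse parameters are (semi-axis-x, semi-axis-y) in mm about the grid
    centre.  The skull ring spans ``skull_outer``..``skull_inner`` and must
    have nonzero thickness; the ring thickness (12 mm by default, the thick
    end of the adult range) puts the phantom in the regime where bone
    attenuation dominates over soft-tissue class offsets.
    """

    grid_size: int = 128
    pixel_mm: float = 2.0
    scalp: tuple[float, float] = (115.0, 95.0)
    fat_outer: tuple[float, float] = (111.0, 91.0)
    skull_outer: tuple[float, float] = (106.0, 86.0)
    skull_inner: tuple[float, float] = (94.0, 74.0)
    white: tuple[float, float] = (58.0, 42.0)
    skull_hu: float = 1500.0
    fat_hu: float = -100.0
    soft_hu: float = 0.0
    mu_soft: float = 0.096
    mu_fat: float = 0.086
    cortical_voi_max_bone_mm: float = 4.0
    deep_voi_min_bone_mm: float = 20.0
    kinetics: dict[Tissue, KineticParams] = field(default_factory=_default_kinetics)
    injected_dose_mbq: float = 364.0
    body_weight_kg: float = 71.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 64:
            raise PhantomConfigError("grid_size must be >= 64")
        if self.injected_dose_mbq <= 0 or self.body_weight_kg <= 0:
            raise PhantomConfigError("dose and weight must be positive")
        half_mm = self.grid_size * self.pixel_mm / 2.0
        seq = [self.scalp, self.fat_outer, self.skull_outer, self.skull_inner, self.white]
        if max(self.scalp) >= half_mm:
            raise PhantomConfigError("scalp ellipse does not fit inside the grid")
        for outer, inner in zip(seq[:-1], seq[1:]):
            if not (inner[0] < outer[0] and inner[1] < outer[1]):
                raise PhantomConfigError(f"ellipses must be strictly nested: {inner} vs {outer}")

    @property
    def mu_bone(self) -> float:
        """True bone μ, tied to the skull HU via the bilinear CT conversion."""
        return float(ct_to_mu(np.array(self.skull_hu)).mu)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kinetics"] = {
            Tissue(t).name: dataclasses.asdict(p) for t, p in self.kinetics.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "kinetics" in d:
            d["kinetics"] = {
                Tissue[name]: KineticParams(**p) for name, p in d["kinetics"].items()
            }
        for key in ("scalp", "fat_outer", "skull_outer", "skull_inner", "white"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class SubjectPhantom:
    """One synthetic subject: labels, μ truth, HU map, VOIs, kinetics."""

    spec: PhantomSpec
    label_map: np.ndarray
    mu_true: np.ndarray
    hu_map: np.ndarray
    voi_masks: dict[str, np.ndarray]
    kinetics_by_tissue: dict[Tissue, KineticParams]

    @property
    def head_mask(self) -> np.ndarray:
        return self.label_map != Tissue.AIR

    @property
    def brain_mask(self) -> np.ndarray:
        return (self.label_map == Tissue.GRAY) | (self.label_map == Tissue.WHITE)

    def region_label_map(self) -> np.ndarray:
        """Integer VOI map (0 outside, 1 other gray, 2 deep VOI, 3 cortical VOI)."""
        out = np.zeros(self.label_map.shape, dtype=np.int16)
        out[self.voi_masks["WBGM"]] = 1
        out[self.voi_masks["INS"]] = 2
        out[self.voi_masks["SPL"]] = 3
        return out


def _ellipse_mask(n: int, pixel_mm: float, semi_axes: tuple[float, float]) -> np.ndarray:
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n]
    xm = (x - c) * pixel_mm
    ym = (y - c) * pixel_mm
    a, b = semi_axes
    return (xm / a) ** 2 + (ym / b) ** 2 <= 1.0


def build_head_phantom(spec: PhantomSpec) -> SubjectPhantom:
    """Deterministically rasterise the phantom geometry.

    Raises
    ------
    PhantomConfigError
        If the ellipse stack is ill-ordered or a VOI comes out empty.
    """
    n = spec.grid_size
    label = np.full((n, n), int(Tissue.AIR), dtype=np.int16)
    for semi_axes, tissue in [
        (spec.scalp, Tissue.SOFT),
        (spec.fat_outer, Tissue.FAT),
        (spec.skull_outer, Tissue.BONE),
        (spec.skull_inner, Tissue.GRAY),
        (spec.white, Tissue.WHITE),
    ]:
        label[_ellipse_mask(n, spec.pixel_mm, semi_axes)] = int(tissue)

    mu_lut = {Tissue.AIR: 0.0, Tissue.SOFT: spec.mu_soft, Tissue.FAT: spec.mu_fat,
              Tissue.BONE: spec.mu_bone, Tissue.GRAY: spec.mu_soft, Tissue.WHITE: spec.mu_soft}
    hu_lut = {Tissue.AIR: -1000.0, Tissue.SOFT: spec.soft_hu, Tissue.FAT: spec.fat_hu,
              Tissue.BONE: spec.skull_hu, Tissue.GRAY: spec.soft_hu, Tissue.WHITE: spec.soft_hu}
    mu_true = np.zeros((n, n))
    hu_map = np.zeros((n, n))
    for tissue in Tissue:
        sel = label == int(tissue)
        mu_true[sel] = mu_lut[tissue]
        hu_map[sel] = hu_lut[tissue]

    bone = label == int(Tissue.BONE)
    if not bone.any():
        raise PhantomConfigError("skull ring is empty")
    gray = label == int(Tissue.GRAY)
    dist_to_bone_mm = distance_transform_edt(~bone, sampling=spec.pixel_mm)
    vois = {
        "WBGM": gray,
        "SPL": gray & (dist_to_bone_mm <= spec.cortical_voi_max_bone_mm),
        "INS": gray & (dist_to_bone_mm >= spec.deep_voi_min_bone_mm),
    }
    for name, mask in vois.items():
        if not mask.any():
            raise PhantomConfigError(f"VOI {name!r} is empty for this geometry")

    return SubjectPhantom(
        spec=spec,
        label_map=label,
        mu_true=mu_true,
        hu_map=hu_map,
        voi_masks=vois,
        kinetics_by_tissue=dict(spec.kinetics),
    )


def synth_dixon_pair(
    phantom: SubjectPhantom,
    *,
    inverted: bool = False,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DixonImagePair:
    """Simulate an in-phase/opposed-phase Dixon pair for the phantom.

    ``in = W + F`` and ``opp = F − W`` from per-tissue water/fat signals;
    bone emits essentially no signal.  ``inverted`` only sets the vendor
    labeling flag — the phase images themselves are identical either way,
    which is what makes the inversion recoverable downstream.  ``noise_sd``
    is additive Gaussian noise as a fraction of the in-phase maximum.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    label = phantom.label_map
    water = np.zeros(label.shape)
    fat = np.zeros(label.shape)
    for tissue in Tissue:
        sel = label == int(tissue)
        water[sel] = _DIXON_WATER[tissue]
        fat[sel] = _DIXON_FAT[tissue]
    in_phase = water + fat
    opp_phase = fat - water
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        scale = noise_sd * in_phase.max()
        in_phase = in_phase + rng.normal(0.0, scale, size=label.shape)
        opp_phase = opp_phase + rng.normal(0.0, scale, size=label.shape)
    return DixonImagePair(in_phase=in_phase, opp_phase=opp_phase, vendor_inverted=inverted)


@dataclass(frozen=True)
class InputFunctionSet:
    """Arterial curves on a uniform fine time grid (minutes, kBq/mL)."""

    t_min: np.ndarray
    c_plasma_total: np.ndarray
    parent_fraction: np.ndarray
    c_wholeblood: np.ndarray

    @property
    def c_plasma_parent(self) -> np.ndarray:
        return self.c_plasma_total * self.parent_fraction

    def scaled(self, factor: float) -> "InputFunctionSet":
        return replace(
            self,
            c_plasma_total=self.c_plasma_total * factor,
            c_wholeblood=self.c_wholeblood * factor,
        )


@dataclass(frozen=True)
class InputFunctionParams:
    """Tri-exponential (Feng-type) bolus plus metabolite and blood models.

    The parent plasma curve is ``(A1·(t−τ) − A2 − A3)·e^{λ1(t−τ)}
    + A2·e^{λ2(t−τ)} + A3·e^{λ3(t−τ)}`` for t > τ and 0 before, which is
    continuous at the bolus start.  The parent fraction decays smoothly from
    1 toward ``parent_inf``; whole blood is a dispersed, scaled copy of total
    plasma.  Amplitudes are in kBq/mL, rates in min⁻¹.
    """

    tau_min: float = 0.1
    A1: float = 500.0
    A2: float = 20.0
    A3: float = 4.0
    lam1: float = -3.0
    lam2: float = -0.35
    lam3: float = -0.01
    parent_inf: float = 0.6
    parent_tau_min: float = 25.0
    blood_ratio: float = 0.76
    dispersion_min: float = 0.1
    t_end_min: float = 40.0
    dt_s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.lam1 < 0 and self.lam2 < 0 and self.lam3 < 0):
            raise PhantomConfigError("decay rates lam1..lam3 must be negative")
        if self.dt_s > 1.0 + 1e-9:
            raise PhantomConfigError("time grid must resolve the bolus at <= 1 s")
        if not (0 <= self.parent_inf <= 1):
            raise PhantomConfigError("parent_inf must be in [0, 1]")


def synth_input_functions(params: InputFunctionParams | None = None, seed: int = 0) -> InputFunctionSet:
    """Generate the arterial input-function set.

    Deterministic given ``params``; ``seed`` is accepted for interface
    symmetry (subject-level variability is applied by perturbing ``params``).
    """
    p = params or InputFunctionParams()
    dt_min = p.dt_s / 60.0
    t = np.arange(0.0, p.t_end_min + dt_min / 2, dt_min)
    u = t - p.tau_min
    cp = np.where(
        u > 0,
        (p.A1 * u - p.A2 - p.A3) * np.exp(p.lam1 * u)
        + p.A2 * np.exp(p.lam2 * u)
        + p.A3 * np.exp(p.lam3 * u),
        0.0,
    )
    cp = np.clip(cp, 0.0, None)

    frac = p.parent_inf + (1.0 - p.parent_inf) * np.exp(-t / p.parent_tau_min)

    kern = np.exp(-t / p.dispersion_min)
    kern /= kern.sum() * dt_min
    cwb = np.clip(p.blood_ratio * fftconvolve(cp, kern)[: t.size] * dt_min, 0.0, None)

    return InputFunctionSet(t_min=t, c_plasma_total=cp, parent_fraction=frac, c_wholeblood=cwb)


def synth_dynamic_activity(
    phantom: SubjectPhantom,
    inputs: InputFunctionSet,
    schedule: FrameSchedule,
) -> np.ndarray:
    """Ground-truth dynamic activity frames (n_frames, n, n) in kBq/mL.

    Each voxel follows the frame-averaged 1T2K prediction for its tissue's
    ground-truth parameters; air is zero.
    """
    from .kinetics import model_tac

    label = phantom.label_map
    frames = np.zeros((schedule.n_frames,) + label.shape)
    present = set(np.unique(label))
    for tissue in Tissue:
        if tissue == Tissue.AIR or int(tissue) not in present:
            continue
        params = phantom.kinetics_by_tissue.get(tissue)
        if params is None:
            raise KeyError(f"no ground-truth kinetics for tissue {tissue.name}")
        tac = model_tac(params, inputs, schedule)
        frames[:, label == int(tissue)] = tac[:, None]
    return frames
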