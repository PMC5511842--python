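"""Attenuation (μ) map construction for the three AC methods under comparison.

Three μ-map builders mirror routine clinical practice:

* ``segment_tx_mu_map`` — a measured transmission scan segmented into
  air / soft-tissue / bone classes with fixed 511 keV coefficients
  (0.0 / 0.095 / 0.125 cm⁻¹).
* ``dixon_standard_mu`` / ``dixon_correct_inversion`` — MR Dixon fat/water
  separation mapped to fat / soft-tissue / air classes.  Bone gives no MR
  signal and is therefore invisible (assigned air).  A vendor failure mode
  swaps the fat and water labels ("tissue inversion"); the correction
  recomputes fat and water directly from the in-phase and opposed-phase
  images, which are unaffected by the labeling error.
* ``ct_to_mu`` — bilinear conversion of CT Hounsfield units to 511 keV μ
  (120 kVp coefficients).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AttenuationClassTable:
    """Fixed per-class linear attenuation coefficients (cm⁻¹) at 511 keV.

    ``dixon_fat_eq1`` is the fat coefficient used by the two-class
    inversion-correction rule; it differs in the fourth decimal from the
    three-class ``dixon_fat`` and both are kept distinct deliberately.
    """

    tx_bone: float = 0.125
    tx_soft: float = 0.095
    tx_air: float = 0.0
    dixon_soft: float = 0.1
    dixon_fat: float = 0.085
    dixon_fat_eq1: float = 0.0854
    dixon_air: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.tx_bone, self.tx_soft, self.dixon_soft, self.dixon_fat,
                self.dixon_fat_eq1, self.tx_air, self.dixon_air)
        if any(v < 0 for v in vals):
            raise ValueError("attenuation coefficients must be non-negative")
        if not (self.tx_bone > self.tx_soft > self.dixon_fat > self.tx_air):
            raise ValueError("expected ordering bone > soft > fat > air")


DEFAULT_CLASS_TABLE = AttenuationClassTable()


@dataclass(frozen=True)
class MuMap:
    """A μ volume (cm⁻¹) with a provenance tag."""

    mu: np.ndarray
    method: str  # tx_segmented | dixon | dixon_eq1 | ct_bilinear | truth

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "mu", mu)
        if not np.all(np.isfinite(mu)) or np.any(mu < 0):
            raise ValueError("mu must be finite and non-negative")


@dataclass(frozen=True)
class DixonImagePair:
    """In-phase and opposed-phase Dixon images.

    Conventions: ``in = W + F`` and ``opp = F − W`` for water/fat signals W, F,
    so fat and water are recovered as ``F = 0.5 (in + opp)``,
    ``W = 0.5 (in − opp)``.  ``vendor_inverted`` records whether the vendor
    fat/water labeling was swapped at acquisition; the images themselves are
    unaffected by that labeling error.
    """

    in_phase: np.ndarray
    opp_phase: np.ndarray
    vendor_inverted: bool = False

    def __post_init__(self) -> None:
        inp = np.asarray(self.in_phase, dtype=float)
        opp = np.asarray(self.opp_phase, dtype=float)
        object.__setattr__(self, "in_phase", inp)
        object.__setattr__(self, "opp_phase", opp)
        if inp.shape != opp.shape:
            raise ValueError("in-phase and opposed-phase shapes differ")

    def fat_water(self) -> tuple[np.ndarray, np.ndarray]:
        """(F, W) recovered from the phase images, clipped at 0."""
        fat = np.clip(0.5 * (self.in_phase + self.opp_phase), 0.0, None)
        water = np.clip(0.5 * (self.in_phase - self.opp_phase), 0.0, None)
        return fat, water


def segment_tx_mu_map(
    mu_measured: np.ndarray,
    table: AttenuationClassTable = DEFAULT_CLASS_TABLE,
    *,
    air_threshold: float = 0.04,
    bone_threshold: float = 0.11,
) -> MuMap:
    """Segment a measured transmission μ volume into three fixed classes.

    Thresholds (cm⁻¹): μ < ``air_threshold`` → air; below ``bone_threshold``
    → soft tissue; otherwise bone.  Bone in particular is forced to the
    conservative class value 0.125 cm⁻¹ regardless of the measured value —
    for dense skull (true μ ≈ 0.17 cm⁻¹) this underestimates bone attenuation
    by more than 25%.
    """
    mu_measured = np.asarray(mu_measured, dtype=float)
    if np.any(mu_measured < 0):
        raise ValueError("measured mu must be non-negative")
    out = np.full_like(mu_measured, table.tx_air)
    out[(mu_measured >= air_threshold) & (mu_measured < bone_threshold)] = table.tx_soft
    out[mu_measured >= bone_threshold] = table.tx_bone
    return MuMap(mu=out, method="tx_segmented")


def _background_mask(in_phase: np.ndarray, background_fraction: float) -> np.ndarray:
    peak = float(in_phase.max())
    if peak <= 0:
        raise ValueError("all-zero Dixon pair: normalization undefined")
    return in_phase < background_fraction * peak


def dixon_correct_inversion(
    pair: DixonImagePair,
    *,
    background_fraction: float = 0.05,
    table: AttenuationClassTable = DEFAULT_CLASS_TABLE,
) -> MuMap:
    """Two-class μ map recomputed from the phase images (inversion-proof).

    Fat and water are rebuilt as F = 0.5(in+opp), W = 0.5(in−opp), normalised
    each by its own maximum; a voxel is fat (0.0854 cm⁻¹) when the normalised
    fat signal exceeds the normalised water signal, soft tissue (0.1 cm⁻¹)
    otherwise.  Voxels with in-phase signal below ``background_fraction`` of
    the in-phase maximum are air.  Because only ``in`` and ``opp`` enter, the
    output is identical whether or not the vendor labeling was inverted.
    """
    fat, water = pair.fat_water()
    if fat.max() <= 0 or water.max() <= 0:
        raise ValueError("degenerate Dixon pair: fat or water channel is empty")
    fat_norm = fat / fat.max()
    water_norm = water / water.max()
    mu = np.where(fat_norm > water_norm, table.dixon_fat_eq1, table.dixon_soft)
    mu[_background_mask(pair.in_phase, background_fraction)] = table.dixon_air
    return MuMap(mu=mu, method="dixon_eq1")


def dixon_standard_mu(
    pair: DixonImagePair,
    vendor_labels_inverted: bool | None = None,
    *,
    background_fraction: float = 0.05,
    table: AttenuationClassTable = DEFAULT_CLASS_TABLE,
) -> MuMap:
    """Standard three-class Dixon μ map, honoring the vendor fat/water labels.

    Water-dominant voxels get the soft-tissue value and fat-dominant voxels
    the fat value — unless the vendor labeling is inverted, in which case the
    two assignments are swapped, reproducing the tissue-inversion artifact.
    Background (no MR signal, including bone) is air.
    """
    if vendor_labels_inverted is None:
        vendor_labels_inverted = pair.vendor_inverted
    fat, water = pair.fat_water()
    if fat.max() <= 0 or water.max() <= 0:
        raise ValueError("degenerate Dixon pair: fat or water channel is empty")
    fat_dominant = fat / fat.max() > water / water.max()
    if vendor_labels_inverted:
        fat_dominant = ~fat_dominant
    mu = np.where(fat_dominant, table.dixon_fat, table.dixon_soft)
    mu[_background_mask(pair.in_phase, background_fraction)] = table.dixon_air
    return MuMap(mu=mu, method="dixon")


def detect_tissue_inversion(
    pair: DixonImagePair,
    mu_candidate: MuMap,
    *,
    background_fraction: float = 0.05,
    table: AttenuationClassTable = DEFAULT_CLASS_TABLE,
) -> bool:
    """Flag a Dixon μ map as tissue-inverted.

    Inside the head mask (in-phase signal above background) a plausible head
    is mostly water-dominant; the map is declared inverted when the
    fat-assigned volume fraction strictly exceeds 0.5 (an exact 50/50 split
    is, by documented tie-break, not inverted).
    """
    head = ~_background_mask(pair.in_phase, background_fraction)
    if not head.any():
        raise ValueError("empty head mask")
    fat_assigned = np.isclose(mu_candidate.mu, table.dixon_fat) | np.isclose(
        mu_candidate.mu, table.dixon_fat_eq1
    )
    return float(fat_assigned[head].mean()) > 0.5


# 120 kVp bilinear CT->mu coefficients (cm^-1 per HU scale)
_CT_SLOPE_LOW = 9.6e-5
_CT_SLOPE_HIGH = 5.1e-5
_CT_INTERCEPT_HIGH = 4.71e-2
_CT_BREAK_HU = 47.0


def ct_to_mu(hu_map: np.ndarray) -> MuMap:
    """Bilinear conversion of Hounsfield units to 511 keV μ (120 kVp).

    μ = 9.6×10⁻⁵·(HU+1000) below the 47 HU breakpoint and
    μ = 5.1×10⁻⁵·(HU+1000) + 4.71×10⁻² above it.  HU below −1000 are clamped
    with a warning.
    """
    hu = np.asarray(hu_map, dtype=float)
    if np.any(hu < -1000):
        warnings.warn("HU values below -1000 clamped to -1000", stacklevel=2)
        hu = np.clip(hu, -1000.0, None)
    mu_low = _CT_SLOPE_LOW * (hu + 1000.0)
    mu_high = _CT_SLOPE_HIGH * (hu + 1000.0) + _CT_INTERCEPT_HIGH
    mu = np.where(hu <= _CT_BREAK_HU, mu_low, mu_high)
    return MuMap(mu=np.clip(mu, 0.0, None), method="ct_bilinear")


def relative_difference_map(
    test_volume: np.ndarray,
    reference_volume: np.ndarray,
    mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise percent difference (test − ref)/ref × 100 on a mask.

    Returns ``(diff, valid)`` where ``diff`` holds NaN outside the mask and
    at flagged voxels (reference zero inside the mask), and ``valid`` marks
    the voxels where the percent difference is defined.  Flagged voxels are
    never silently zeroed; callers exclude them from region statistics.
    """
    test = np.asarray(test_volume, dtype=float)
    ref = np.asarray(reference_volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not (test.shape == ref.shape == mask.shape):
        raise ValueError("shapes of test, reference and mask must match")
    valid = mask & (ref != 0)
    diff = np.full(test.shape, np.nan)
    diff[valid] = (test[valid] - ref[valid]) / ref[valid] * 100.0
    return diff, valid
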