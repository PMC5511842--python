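"""Parallel-beam emission simulation and OSEM/MLEM reconstruction.

The forward model is a 2-D parallel-beam Radon transform (180 evenly spaced
angles) with attenuation applied in sinogram space: the expected emission
data are ``P(activity) / ACF`` where ``ACF = exp(∫ μ dl)`` per line of
response.  Reconstruction is ordered-subsets MLEM with the attenuation
factors of a chosen μ-map inside the system model — which may deliberately
differ from the μ-map used to generate the data, producing exactly the
attenuation-correction bias the pipeline quantifies.  A Gaussian post-filter
(6 mm FWHM by default) matches resolution across arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import radon, iradon

from .acmaps import MuMap
from .phantom import SubjectPhantom, InputFunctionSet, synth_dynamic_activity
from .tacs import FrameSchedule

MM_PER_CM = 10.0


@dataclass(frozen=True)
class Sinogram:
    """Line-integral data: (radial bin, angle) with geometry metadata."""

    values: np.ndarray
    angles_deg: np.ndarray
    bin_mm: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "angles_deg", np.asarray(self.angles_deg, dtype=float))
        if not np.all(np.isfinite(v)):
            raise ValueError("sinogram values must be finite")
        if v.shape[1] != self.angles_deg.size:
            raise ValueError("angle axis does not match angle list")


@dataclass(frozen=True)
class ReconSettings:
    """Iterative reconstruction settings (2 iterations, 21 subsets, 6 mm filter)."""

    iterations: int = 2
    subsets: int = 21
    post_filter_fwhm_mm: float = 6.0
    n_angles: int = 180

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.subsets < 1 or self.subsets > self.n_angles:
            raise ValueError("subsets must be in [1, n_angles]")
        if self.post_filter_fwhm_mm < 0:
            raise ValueError("post-filter FWHM must be >= 0")


def projection_angles(n_angles: int = 180) -> np.ndarray:
    return np.linspace(0.0, 180.0, n_angles, endpoint=False)


def forward_project(image: np.ndarray, pixel_mm: float, angles_deg: np.ndarray | None = None) -> Sinogram:
    """Line integrals of a square image; lengths in cm.

    Projecting a μ-map (cm⁻¹) therefore yields the dimensionless ∫μ dl.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square")
    if angles_deg is None:
        angles_deg = projection_angles()
    n = image.shape[0]
    yy, xx = np.ogrid[:n, :n]
    fov = (xx - n // 2) ** 2 + (yy - n // 2) ** 2 <= (n // 2) ** 2
    if not np.all(image[~fov] == 0):
        # scanner FOV is the inscribed circle; support outside it is not seen
        image = np.where(fov, image, 0.0)
    sino = radon(image, theta=angles_deg, circle=True) * (pixel_mm / MM_PER_CM)
    return Sinogram(values=sino, angles_deg=angles_deg, bin_mm=pixel_mm)


def attenuation_factors(mu_map: MuMap | np.ndarray, pixel_mm: float, angles_deg: np.ndarray | None = None) -> Sinogram:
    """Attenuation correction factors exp(∫μ dl) per line of response (≥ 1)."""
    mu = mu_map.mu if isinstance(mu_map, MuMap) else np.asarray(mu_map, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mu must be non-negative")
    proj = forward_project(mu, pixel_mm, angles_deg)
    return Sinogram(values=np.exp(proj.values), angles_deg=proj.angles_deg, bin_mm=proj.bin_mm)


def simulate_emission_sinogram(
    activity_image: np.ndarray,
    mu_true: np.ndarray,
    pixel_mm: float,
    *,
    total_counts: float | None = None,
    seed: int = 0,
    angles_deg: np.ndarray | None = None,
    acf_true: Sinogram | None = None,
) -> Sinogram:
    """Attenuated emission data for one frame.

    Expected data are ``P(activity)/ACF(μ_true)``.  With ``total_counts``
    given, the sinogram is scaled to that many expected counts, Poisson noise
    is drawn per bin, and the result is scaled back to concentration units.
    """
    activity_image = np.asarray(activity_image, dtype=float)
    if np.any(activity_image < 0):
        raise ValueError("activity must be non-negative")
    if acf_true is None:
        acf_true = attenuation_factors(mu_true, pixel_mm, angles_deg)
    proj = forward_project(activity_image, pixel_mm, acf_true.angles_deg)
    expected = proj.values / acf_true.values
    if total_counts is not None and expected.sum() > 0:
        rng = np.random.default_rng(seed)
        s = total_counts / expected.sum()
        noisy = rng.poisson(expected * s).astype(float) / s
        expected = noisy
    return Sinogram(values=expected, angles_deg=acf_true.angles_deg, bin_mm=proj.bin_mm)


def _subset_indices(n_angles: int, subsets: int) -> list[np.ndarray]:
    return [np.arange(s, n_angles, subsets) for s in range(subsets)]


@dataclass
class _SystemModel:
    """Cached per-subset projector state for one ACF (reused across frames)."""

    acf: Sinogram
    settings: ReconSettings
    pixel_mm: float
    n: int
    subset_idx: list[np.ndarray] = field(init=False)
    sens: list[np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        self.subset_idx = _subset_indices(self.acf.angles_deg.size, self.settings.subsets)
        self.sens = []
        for idx in self.subset_idx:
            ones = 1.0 / self.acf.values[:, idx]
            self.sens.append(self._backproject(ones, idx))

    def _forward(self, image: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return radon(image, theta=self.acf.angles_deg[idx], circle=True) * (
            self.pixel_mm / MM_PER_CM
        ) / self.acf.values[:, idx]

    def _backproject(self, sino: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return iradon(
            sino,
            theta=self.acf.angles_deg[idx],
            filter_name=None,
            circle=True,
            output_size=self.n,
        )


def mlem_reconstruct(
    data: Sinogram,
    acf: Sinogram,
    settings: ReconSettings = ReconSettings(),
    pixel_mm: float = 2.0,
    *,
    system: _SystemModel | None = None,
    init: str = "fbp",
) -> np.ndarray:
    """Ordered-subsets MLEM with attenuation inside the system model.

    The update is the classical multiplicative EM step per subset; voxels with
    zero subset sensitivity (outside the scanner FOV circle) are excluded.
    The iterations refine a filtered-backprojection estimate of the
    attenuation-corrected data (``init="fbp"``), which converges
    high-frequency structure — thin cortical ribbons in particular — within
    the two clinical iterations; ``init="uniform"`` gives the textbook
    flat start.  A Gaussian post-filter of ``post_filter_fwhm_mm`` finishes
    the reconstruction; output is non-negative.
    """
    y = np.asarray(data.values, dtype=float)
    if np.any(y < 0):
        raise ValueError("emission data must be non-negative")
    if system is None:
        n = y.shape[0]
        system = _SystemModel(acf=acf, settings=settings, pixel_mm=pixel_mm, n=n)
    yy, xx = np.ogrid[: system.n, : system.n]
    fov = (xx - system.n // 2) ** 2 + (yy - system.n // 2) ** 2 <= (system.n // 2) ** 2
    if init == "fbp" and y.max() > 0:
        corrected = y * system.acf.values / (system.pixel_mm / MM_PER_CM)
        x = iradon(corrected, theta=system.acf.angles_deg, filter_name="ramp", circle=True,
                   output_size=system.n)
        x = np.clip(x, 0.0, None)
        # small floor keeps the multiplicative update able to raise any voxel
        x = np.where(fov, np.maximum(x, 0.01 * x.max()), 0.0)
    elif init in ("fbp", "uniform"):
        x = np.where(fov, 1.0, 0.0)
    else:
        raise ValueError(f"unknown init {init!r}")
    eps = 1e-12
    for _ in range(settings.iterations):
        for idx, sens in zip(system.subset_idx, system.sens):
            y_s = y[:, idx]
            yhat = system._forward(x, idx)
            ratio = np.where(yhat > eps, y_s / np.maximum(yhat, eps), 0.0)
            ratio[(yhat <= eps) & (y_s <= eps)] = 1.0
            # adjoint of A = diag(1/ACF)·R is R^T·diag(1/ACF)
            corr = system._backproject(ratio / system.acf.values[:, idx], idx)
            good = sens > eps
            upd = np.zeros_like(x)
            upd[good] = corr[good] / sens[good]
            x = x * upd
    if settings.post_filter_fwhm_mm > 0:
        sigma_px = settings.post_filter_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / pixel_mm
        x = gaussian_filter(x, sigma_px)
    return np.clip(x, 0.0, None)


def build_system_model(acf: Sinogram, settings: ReconSettings, pixel_mm: float, n: int) -> _SystemModel:
    """Precompute subset sensitivities for repeated reconstructions."""
    return _SystemModel(acf=acf, settings=settings, pixel_mm=pixel_mm, n=n)


def simulate_dynamic_study(
    phantom: SubjectPhantom,
    inputs: InputFunctionSet,
    schedule: FrameSchedule,
    mu_test: MuMap,
    settings: ReconSettings = ReconSettings(),
    *,
    total_counts: float | None = None,
    seed: int = 0,
    system: _SystemModel | None = None,
    acf_true: Sinogram | None = None,
) -> np.ndarray:
    """Full dynamic simulation: truth → attenuated data → mismatched recon.

    Every frame is generated from the ground-truth kinetics, attenuated with
    the phantom's true μ-map, and reconstructed with the ACFs of ``mu_test``
    (matched AC when ``mu_test`` equals the truth).  ``total_counts`` is the
    expected count total over the whole study, split across frames in
    proportion to frame duration × mean activity; ``None`` runs noise-free.

    Returns (n_frames, n, n) reconstructed concentration frames.
    """
    pixel_mm = phantom.spec.pixel_mm
    angles = projection_angles(settings.n_angles)
    if acf_true is None:
        acf_true = attenuation_factors(phantom.mu_true, pixel_mm, angles)
    acf_test = attenuation_factors(mu_test, pixel_mm, angles)
    if system is None:
        system = build_system_model(acf_test, settings, pixel_mm, phantom.spec.grid_size)

    activity = synth_dynamic_activity(phantom, inputs, schedule)
    durations = schedule.durations_min
    if total_counts is not None:
        weight = durations * activity.mean(axis=(1, 2))
        frame_counts = total_counts * weight / weight.sum()
    rng = np.random.default_rng(seed)

    frames = np.empty_like(activity)
    for f in range(schedule.n_frames):
        counts = None if total_counts is None else float(frame_counts[f])
        sino = simulate_emission_sinogram(
            activity[f], phantom.mu_true, pixel_mm,
            total_counts=counts, seed=int(rng.integers(2**31 - 1)),
            angles_deg=angles, acf_true=acf_true,
        )
        frames[f] = mlem_reconstruct(sino, acf_test, settings, pixel_mm, system=system)
    return frames
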