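"""Susceptibility-map reconstruction for the simulated phantoms.

A deliberately simple, fully specified pipeline stands behind the
susceptibility maps used in the simulation study: the single-echo phase is
converted to a field map (with FFT-based Laplacian unwrapping when wraps are
expected), inverted with thresholded k-space division (TKD) against the unit
dipole kernel ``D(k) = 1/3 - (k.b)^2/|k|^2``, and the result shifted so the
mean susceptibility outside the dilated vein mask equals the known background
value.  A bypass route feeds exact linear-mixture susceptibility maps built
from the ground-truth partial-volume map straight to the fitting stage,
isolating geometric-fit error from reconstruction error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cylinder_phantom import GAMMA, PhantomBundle
from .icf_core import MaskError

__all__ = [
    "DipoleInversionConfig",
    "laplacian_unwrap",
    "phase_to_fieldmap",
    "dipole_kernel",
    "dipole_invert",
    "normalize_qsm",
    "reconstruct",
    "oracle_qsm",
]


@dataclass(frozen=True)
class DipoleInversionConfig:
    """TKD inversion settings."""

    threshold: float = 0.2
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    TE: float = 7.65  # ms
    B0: float = 7.0   # tesla

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 2.0 / 3.0:
            raise ValueError("threshold must lie in (0, 2/3)")


def _laplacian_multiplier(shape) -> np.ndarray:
    k2 = np.zeros(shape)
    for ax, n in enumerate(shape):
        f = np.fft.fftfreq(n)
        sh = [1] * len(shape)
        sh[ax] = n
        k2 = k2 + (2.0 * math.pi * f.reshape(sh)) ** 2
    return -k2


def laplacian_unwrap(phase: np.ndarray) -> np.ndarray:
    """FFT-based Laplacian phase unwrapping.

    Solves ``lap(psi) = cos(phase) * lap(sin(phase)) - sin(phase) *
    lap(cos(phase))`` for the unwrapped phase ``psi`` with periodic boundary
    conditions; the unobservable constant is chosen so the mean matches the
    wrapped input.  Accurate away from volume boundaries for smooth fields.
    """
    phase = np.asarray(phase, dtype=float)
    lam = _laplacian_multiplier(phase.shape)
    c, s = np.cos(phase), np.sin(phase)

    def lap(x):
        return np.fft.ifftn(lam * np.fft.fftn(x)).real

    rhs = c * lap(s) - s * lap(c)
    lam_inv = np.zeros_like(lam)
    nz = lam != 0
    lam_inv[nz] = 1.0 / lam[nz]
    psi = np.fft.ifftn(lam_inv * np.fft.fftn(rhs)).real
    return psi + (phase.mean() - psi.mean())


def phase_to_fieldmap(
    phase: np.ndarray,
    TE: float,
    B0: float,
    gamma: float = GAMMA,
    unwrap: bool = False,
) -> np.ndarray:
    """Convert single-echo phase (rad) to a field map in ppm of B0.

    Uses ``phase = gamma * B0 * field_ppm * 1e-6 * TE``; ``TE`` in ms.
    """
    phase = np.asarray(phase, dtype=float)
    if unwrap:
        phase = laplacian_unwrap(phase)
    return phase / (gamma * B0 * (TE * 1e-3)) * 1e6


def dipole_kernel(shape, b_dir=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Unit dipole kernel ``1/3 - (k.b)^2/|k|^2`` on the FFT grid (DC = 0)."""
    b = np.asarray(b_dir, dtype=float)
    b = b / np.linalg.norm(b)
    grids = []
    for ax, n in enumerate(shape):
        f = np.fft.fftfreq(n)
        sh = [1] * len(shape)
        sh[ax] = n
        grids.append(f.reshape(sh))
    k2 = sum(g**2 for g in grids)
    kb = sum(g * bi for g, bi in zip(grids, b))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - (kb**2) / k2
    d[tuple([0] * len(shape))] = 0.0
    return d


def dipole_invert(
    fieldmap: np.ndarray,
    b_dir=(0.0, 0.0, 1.0),
    threshold: float = 0.2,
) -> np.ndarray:
    """Thresholded k-space division of a field map (ppm) into susceptibility.

    Kernel values with magnitude below ``threshold`` are replaced by
    ``sign(D) * threshold`` (sign of zero taken positive); the DC component
    is set to zero, an arbitrary reference resolved later by normalization.
    """
    if not 0.0 < threshold < 2.0 / 3.0:
        raise ValueError("threshold must lie in (0, 2/3)")
    fieldmap = np.asarray(fieldmap, dtype=float)
    if not np.all(np.isfinite(fieldmap)):
        raise ValueError("fieldmap must be finite")
    d = dipole_kernel(fieldmap.shape, b_dir)
    sgn = np.where(d >= 0, 1.0, -1.0)
    d_reg = sgn * np.maximum(np.abs(d), threshold)
    f = np.fft.fftn(fieldmap)
    f[tuple([0] * fieldmap.ndim)] = 0.0
    return np.fft.ifftn(f / d_reg).real


def normalize_qsm(
    qsm: np.ndarray, dilated_mask: np.ndarray, chi_bg: float = 0.0
) -> np.ndarray:
    """Shift the map so the mean outside the dilated vein mask equals chi_bg."""
    qsm = np.asarray(qsm, dtype=float)
    outside = ~np.asarray(dilated_mask, dtype=bool)
    if not outside.any():
        raise MaskError("no voxels outside the dilated mask")
    return qsm + (chi_bg - qsm[outside].mean())


def reconstruct(
    bundle: PhantomBundle,
    threshold: float = 0.2,
    unwrap: str | bool = "auto",
) -> np.ndarray:
    """Phase -> field -> TKD susceptibility map for a simulated phantom.

    ``unwrap='auto'`` enables Laplacian unwrapping when the analytic
    intravascular phase could exceed +-pi at the phantom's echo time.
    """
    p = bundle.params
    spec = bundle.spec
    if unwrap == "auto":
        max_phase = (
            p.gamma * p.B0 * 1e-6 * (p.TE * 1e-3)
            * abs(spec.delta_chi) * 0.5  # |3cos^2-1|/6 <= 1/3, margin 1.5x
        )
        unwrap = max_phase > 2.5
    field = phase_to_fieldmap(bundle.phase, p.TE, p.B0, p.gamma, unwrap=bool(unwrap))
    return dipole_invert(field, bundle.truth.b0_dir, threshold)


def oracle_qsm(
    bundle: PhantomBundle, noise_std: float = 0.0, seed: int | None = None
) -> np.ndarray:
    """Exact linear-mixture susceptibility volume from the ground-truth map.

    ``truth_pv * chi_vein + (1 - truth_pv) * chi_background`` plus optional
    i.i.d. Gaussian noise — the reconstruction-free route for isolating the
    fitting error.
    """
    t = bundle.truth
    chi = bundle.truth_pv * t.chi_vein + (1.0 - bundle.truth_pv) * t.chi_background
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        chi = chi + rng.normal(scale=noise_std, size=chi.shape)
    return chi
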