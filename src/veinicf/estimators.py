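"""Vein-susceptibility estimators, OEF conversion and error metrics.

Four estimators of the vein susceptibility are compared throughout the
simulation study:

- **MIV** — maximum intensity voxel within the dilated mask on the
  centermost slice; the classical small-vein readout.
- **NPC** — no partial-volume correction: plain mean over every voxel with
  non-zero true vein fraction.
- **PPC** — perfect partial-volume correction: the linear mixture model
  solved with the ground-truth partial-volume map (oracle upper bound on
  what partial-volume correction can achieve).
- **ICF** — the iterative cylindrical fit (see :mod:`veinicf.icf_core`).

OEF follows ``OEF = (chi_vein - chi_background) / (chi_do * Hct)`` with the
deoxy-oxy susceptibility difference ``chi_do = 4*pi*0.27 ppm`` and a uniform
hematocrit of 0.4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .icf_core import MaskError, estimate_chi_vein

__all__ = [
    "OEFParams",
    "ErrorReport",
    "oef",
    "miv",
    "npc",
    "ppc",
    "cnr",
    "rho_rmse",
    "error_metrics",
]


@dataclass(frozen=True)
class OEFParams:
    """Constants of the susceptibility-to-OEF conversion."""

    chi_do: float = 4.0 * math.pi * 0.27  # ppm, fully deoxy - fully oxy Hb
    hct: float = 0.4

    def __post_init__(self) -> None:
        if self.chi_do <= 0:
            raise ValueError("chi_do must be positive")
        if not 0.0 < self.hct < 1.0:
            raise ValueError("hct must lie in (0, 1)")


def oef(chi_vein: float, chi_bg: float, params: OEFParams = OEFParams()) -> float:
    """Oxygen extraction fraction from a vein/reference susceptibility pair.

    Not clipped: noisy estimates may legitimately fall outside [0, 1] and are
    reported raw.
    """
    return (chi_vein - chi_bg) / (params.chi_do * params.hct)


def miv(pixels: np.ndarray, mask: np.ndarray) -> float:
    """Maximum voxel intensity within the (dilated) mask on one slice."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MaskError("empty mask for MIV")
    return float(np.asarray(pixels)[mask].max())


def npc(pixels: np.ndarray, truth_pv: np.ndarray) -> float:
    """Unweighted mean over voxels with any true vein content."""
    support = np.asarray(truth_pv) > 0
    if not support.any():
        raise MaskError("no voxels with non-zero partial volume")
    return float(np.asarray(pixels)[support].mean())


def ppc(pixels: np.ndarray, truth_pv: np.ndarray, chi_bg: float) -> float:
    """Mixture model solved with the oracle partial-volume map.

    Shares the closed-form least-squares path used by the cylindrical fit,
    so PPC and ICF differ only in where their partial-volume maps come from.
    """
    return estimate_chi_vein(np.asarray(pixels, float), truth_pv, chi_bg)


def cnr(
    qsm: np.ndarray,
    truth_pv: np.ndarray,
    dilated_mask: np.ndarray,
    chi_bg: float,
) -> float:
    """Contrast-to-noise ratio of a susceptibility map.

    Contrast: mean over majority-vein voxels (true rho > 0.5; falls back to
    the highest-rho voxel for sub-voxel veins) minus the background value.
    Noise: standard deviation outside the dilated mask.
    """
    qsm = np.asarray(qsm, dtype=float)
    pv = np.asarray(truth_pv, dtype=float)
    outside = ~np.asarray(dilated_mask, dtype=bool)
    if not outside.any():
        raise MaskError("no background voxels for CNR")
    vein = pv > 0.5
    if vein.any():
        contrast = qsm[vein].mean() - chi_bg
    else:
        contrast = qsm.flat[int(np.argmax(pv))] - chi_bg
    noise = qsm[outside].std()
    return float(contrast / noise) if noise > 0 else float("inf")


def rho_rmse(pv_hat: np.ndarray, pv_true: np.ndarray) -> float:
    """RMS partial-volume error over the union support (symmetric in its args)."""
    a = np.asarray(pv_hat, dtype=float)
    b = np.asarray(pv_true, dtype=float)
    if a.shape != b.shape:
        raise ValueError("partial volume maps differ in shape")
    support = (a > 0) | (b > 0)
    if not support.any():
        raise MaskError("empty support for partial-volume error")
    d = a[support] - b[support]
    return float(np.sqrt((d * d).mean()))


@dataclass(frozen=True)
class ErrorReport:
    """Per-fit error metrics against simulation ground truth.

    ``eps_v`` is the signed OEF error in percentage points; ``eps_p`` the
    Euclidean center error in voxels; ``eps_r`` the relative radius error;
    ``eps_rho`` the RMS partial-volume error; ``cnr`` the map's
    contrast-to-noise ratio.
    """

    eps_v: float
    eps_p: float
    eps_r: float
    eps_rho: float
    cnr: float

    def __post_init__(self) -> None:
        for name in ("eps_p", "eps_r", "eps_rho"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def error_metrics(
    *,
    chi_hat: float,
    chi_bg_hat: float,
    center_hat: tuple[float, float],
    radius_hat: float,
    pv_hat: np.ndarray,
    chi_true: float,
    chi_bg_true: float,
    center_true: tuple[float, float],
    radius_true: float,
    pv_true: np.ndarray,
    qsm: np.ndarray,
    dilated_mask: np.ndarray,
    oef_params: OEFParams = OEFParams(),
) -> ErrorReport:
    """Assemble the full error report for one fitted vein cross-section."""
    ev = (
        oef(chi_hat, chi_bg_hat, oef_params) - oef(chi_true, chi_bg_true, oef_params)
    ) * 100.0
    ep = math.hypot(
        center_hat[0] - center_true[0], center_hat[1] - center_true[1]
    )
    er = abs(radius_hat - radius_true) / radius_true
    erho = rho_rmse(pv_hat, pv_true)
    c = cnr(qsm, pv_true, dilated_mask, chi_bg_true)
    return ErrorReport(eps_v=ev, eps_p=ep, eps_r=er, eps_rho=erho, cnr=c)
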