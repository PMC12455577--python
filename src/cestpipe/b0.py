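"""WASSR B0 field mapping and spectral re-alignment.

Each voxel's water center is located with a maximum-symmetry cost
function (MSCF): the water direct-saturation line is symmetric about its
true center, so the candidate center minimizing the summed squared
mismatch between the spectrum and its mirror image is the B0 shift.  A
coarse grid search is refined by a parabolic fit around the best grid
point.  CEST spectra are then re-sampled at (nominal offset + shift) so
every voxel shares the nominal offset axis; offsets whose source lies
outside the acquired range are marked missing, never extrapolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

logger = logging.getLogger(__name__)

__all__ = ["FieldMap", "QUALITY", "estimate_b0_mscf", "build_field_map", "correct_spectrum"]

QUALITY = {"ok": 0, "edge": 1, "failed": 2}


@dataclass
class FieldMap:
    """Per-voxel B0 shift (ppm) with a quality flag per voxel:
    0 = ok, 1 = edge (estimate at a search/range boundary), 2 = failed.
    Failed voxels carry NaN and are excluded from downstream fitting."""

    shift_ppm: np.ndarray
    quality: np.ndarray

    def ok_mask(self, include_edge: bool = True) -> np.ndarray:
        good = self.quality == QUALITY["ok"]
        if include_edge:
            good |= self.quality == QUALITY["edge"]
        return good


def _interpolator(offsets: np.ndarray, values: np.ndarray, kind: str):
    if kind == "cubic":
        return CubicSpline(offsets, values, extrapolate=False)
    if kind == "linear":
        return interp1d(offsets, values, kind="linear", bounds_error=False,
                        fill_value=np.nan)
    raise ValueError(f"unknown interpolation {kind!r}")


def estimate_b0_mscf(
    wassr_spectrum: np.ndarray,
    offsets: np.ndarray,
    search_bound_ppm: float = 0.5,
    grid_step_ppm: float = 0.01,
    min_pairs: int = 5,
    interp: str = "cubic",
    flat_tol: float = 1e-6,
) -> tuple[float, str]:
    """Estimate one voxel's B0 shift from its WASSR spectrum.

    Minimizes over candidate centers c the mean squared difference
    between the interpolated spectrum at the mirrored offsets ``2c - w``
    and the measured spectrum at ``w``, over offsets whose mirror lies
    inside the acquired range.  Returns ``(shift_ppm, quality)`` with
    quality in {"ok", "edge", "failed"}; failed estimates are NaN.
    """
    z = np.asarray(wassr_spectrum, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    if z.size < 7:
        return np.nan, "failed"
    if search_bound_ppm > (offsets[-1] - offsets[0]) / 2:
        raise ValueError("search bound exceeds half the offset range")
    if np.ptp(z) < flat_tol:
        return np.nan, "failed"
    imin = int(np.argmin(z))
    if imin == 0 or imin == z.size - 1:
        # line minimum not bracketed by the sampled range
        return float(offsets[imin]), "edge"
    spline = _interpolator(offsets, z, interp)
    n_grid = int(round(2 * search_bound_ppm / grid_step_ppm)) + 1
    candidates = np.linspace(-search_bound_ppm, search_bound_ppm, n_grid)
    mirrors = 2.0 * candidates[:, None] - offsets[None, :]  # (n_cand, n_off)
    valid = (mirrors >= offsets[0]) & (mirrors <= offsets[-1])
    if np.any(valid.sum(axis=1) < min_pairs):
        # some candidates unusable; require the *best* candidate be usable below
        pass
    mirrored = spline(np.clip(mirrors, offsets[0], offsets[-1]))
    sq = (mirrored - z[None, :]) ** 2
    sq[~valid] = 0.0
    counts = valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cost = np.where(counts >= min_pairs, sq.sum(axis=1) / counts, np.inf)
    if not np.any(np.isfinite(cost)):
        return np.nan, "failed"
    best = int(np.argmin(cost))
    if best == 0 or best == n_grid - 1:
        return float(candidates[best]), "edge"
    # parabolic refinement through the three points around the minimum
    c0, c1, c2 = cost[best - 1], cost[best], cost[best + 1]
    denom = c0 - 2 * c1 + c2
    if denom <= 0:
        return float(candidates[best]), "ok"
    delta = 0.5 * (c0 - c2) / denom
    shift = candidates[best] + delta * grid_step_ppm
    return float(shift), "ok"


def build_field_map(
    wassr_stack: np.ndarray,
    offsets: np.ndarray,
    mask: np.ndarray,
    search_bound_ppm: float = 0.5,
    grid_step_ppm: float = 0.01,
    min_pairs: int = 5,
    interp: str = "cubic",
) -> FieldMap:
    """Voxelwise MSCF over a WASSR stack.  Raises if more than half the
    masked voxels fail (a sign the WASSR schedule does not cover the
    field's range)."""
    mask = np.asarray(mask, dtype=bool)
    if wassr_stack.shape[:2] != mask.shape:
        raise ValueError("WASSR stack and mask shapes disagree")
    shift = np.full(mask.shape, np.nan)
    quality = np.full(mask.shape, QUALITY["failed"], dtype=np.int8)
    n_failed = 0
    for ij in zip(*np.nonzero(mask)):
        s, q = estimate_b0_mscf(
            wassr_stack[ij], offsets, search_bound_ppm, grid_step_ppm,
            min_pairs=min_pairs, interp=interp,
        )
        shift[ij] = s
        quality[ij] = QUALITY[q]
        n_failed += q == "failed"
    n = int(mask.sum())
    inside = shift[mask & (quality != QUALITY["failed"])]
    if inside.size:
        logger.info(
            "field map: median shift %.4f ppm, IQR %.4f ppm, %.1f%% failed",
            float(np.median(inside)),
            float(np.subtract(*np.percentile(inside, [75, 25]))),
            100.0 * n_failed / max(n, 1),
        )
    if n and n_failed > 0.5 * n:
        raise RuntimeError(
            f"{n_failed}/{n} voxels failed B0 estimation; WASSR schedule likely "
            "does not cover the field's shift range"
        )
    return FieldMap(shift_ppm=shift, quality=quality)


def correct_spectrum(
    cest_spectrum: np.ndarray,
    offsets: np.ndarray,
    shift_ppm: float,
    interp: str = "cubic",
) -> np.ndarray:
    """Re-align one spectrum onto the nominal offset axis.

    A voxel whose water center sits at ``shift_ppm`` has its spectrum
    displaced by that amount, so the aligned value at nominal offset w
    is the acquired spectrum interpolated at ``w + shift``.  Offsets
    whose source lies outside the acquired range come back NaN; a
    non-finite shift returns an all-NaN (unusable) spectrum.
    """
    z = np.asarray(cest_spectrum, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    if not np.isfinite(shift_ppm):
        return np.full_like(z, np.nan)
    if shift_ppm == 0.0:
        return z.copy()
    if abs(shift_ppm) >= (offsets[-1] - offsets[0]) / 2:
        raise ValueError(f"shift {shift_ppm} ppm exceeds half the offset range")
    spline = _interpolator(offsets, z, interp)
    return np.asarray(spline(offsets + shift_ppm), dtype=float)
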