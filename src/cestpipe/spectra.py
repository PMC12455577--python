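"""Core spectral primitives shared across the pipeline.

The offset axis is chemical shift in ppm relative to water at 0 ppm,
positive downfield (standard CEST convention).  Every module in the
package shares this axis and the Lorentzian parameterization defined
here: a pool is a dip of peak depth ``amplitude`` (in normalized-signal
units), full width at half maximum ``fwhm_ppm`` and center
``center_ppm``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SaturationSchedule",
    "PoolSpec",
    "lorentzian_line",
    "default_cest_schedule",
    "default_wassr_schedule",
    "default_pools",
    "POOL_NAMES",
]

POOL_NAMES = ("water", "MT", "CR", "GLU", "NOE")


@dataclass(frozen=True)
class SaturationSchedule:
    """One Z-spectrum acquisition: offset list plus RF saturation parameters.

    Parameters
    ----------
    offsets_ppm
        Strictly increasing saturation offsets in ppm.
    b1_uT
        Continuous-wave saturation amplitude in microtesla.
    t_sat_s
        Saturation duration in seconds.
    """

    offsets_ppm: np.ndarray
    b1_uT: float
    t_sat_s: float

    def __post_init__(self) -> None:
        offsets = np.asarray(self.offsets_ppm, dtype=float)
        if offsets.ndim != 1 or offsets.size < 2:
            raise ValueError("offsets_ppm must be a 1-D array with >= 2 entries")
        if not np.all(np.diff(offsets) > 0):
            raise ValueError("offsets_ppm must be strictly increasing")
        if not self.b1_uT > 0:
            raise ValueError(f"b1_uT must be positive, got {self.b1_uT}")
        if not self.t_sat_s > 0:
            raise ValueError(f"t_sat_s must be positive, got {self.t_sat_s}")
        object.__setattr__(self, "offsets_ppm", offsets)

    @property
    def n_offsets(self) -> int:
        return int(self.offsets_ppm.size)

    def to_dict(self) -> dict:
        return {
            "offsets_ppm": self.offsets_ppm.tolist(),
            "b1_uT": float(self.b1_uT),
            "t_sat_s": float(self.t_sat_s),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SaturationSchedule":
        return cls(
            offsets_ppm=np.asarray(d["offsets_ppm"], dtype=float),
            b1_uT=float(d["b1_uT"]),
            t_sat_s=float(d["t_sat_s"]),
        )


@dataclass(frozen=True)
class PoolSpec:
    """One Lorentzian pool: a dip in the Z-spectrum.

    ``amplitude`` is the peak depth in normalized-signal units (so a
    water pool of amplitude 0.8 pulls Z down to 0.2 at its center),
    ``fwhm_ppm`` the full width at half maximum and ``center_ppm`` the
    resonance offset from water.
    """

    name: str
    center_ppm: float
    amplitude: float
    fwhm_ppm: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"pool {self.name!r}: amplitude must be >= 0")
        if not self.fwhm_ppm > 0:
            raise ValueError(f"pool {self.name!r}: fwhm_ppm must be > 0")

    def scaled(self, factor: float) -> "PoolSpec":
        """Return a copy with the amplitude multiplied by ``factor``."""
        return replace(self, amplitude=self.amplitude * factor)


def lorentzian_line(delta_ppm, pool: PoolSpec):
    """Lorentzian absorption value at offset(s) ``delta_ppm``.

    Computes ``A * (G/2)^2 / ((G/2)^2 + (delta - c)^2)`` for amplitude A,
    FWHM G and center c.  The value peaks at exactly A when
    ``delta == c`` and falls to A/2 at ``delta == c +/- G/2``.

    ``delta_ppm`` is the offset axis already referenced to the voxel's
    B0-corrected water center; scalar or array.
    """
    if not pool.fwhm_ppm > 0:
        raise ValueError(f"pool {pool.name!r}: fwhm_ppm must be > 0")
    delta = np.asarray(delta_ppm, dtype=float)
    hw2 = (pool.fwhm_ppm / 2.0) ** 2
    out = pool.amplitude * hw2 / (hw2 + (delta - pool.center_ppm) ** 2)
    if np.isscalar(delta_ppm):
        return float(out)
    return out


def default_cest_schedule() -> SaturationSchedule:
    """The acquisition schedule: 51 offsets, -5..+5 ppm in 0.2 ppm steps,
    2 uT continuous-wave saturation for 1 s."""
    offsets = np.round(np.linspace(-5.0, 5.0, 51), 10)
    return SaturationSchedule(offsets_ppm=offsets, b1_uT=2.0, t_sat_s=1.0)


def default_wassr_schedule() -> SaturationSchedule:
    """WASSR schedule: low-power, water-only saturation over a narrow
    symmetric range (-1..+1 ppm, 0.02 ppm steps, 0.25 uT)."""
    offsets = np.round(np.linspace(-1.0, 1.0, 101), 10)
    return SaturationSchedule(offsets_ppm=offsets, b1_uT=0.25, t_sat_s=1.0)


def default_pools() -> list[PoolSpec]:
    """Baseline 5-pool parameterization used as phantom ground truth.

    Water at 0 ppm, a broad magnetization-transfer (MT) background at
    -2.5 ppm, creatine (CR) at +2 ppm, glutamate (GLU) at +3 ppm and the
    nuclear Overhauser effect (NOE) at -3.5 ppm.  Amplitudes and widths
    are typical of mouse brain at moderate saturation power.
    """
    return [
        PoolSpec("water", 0.0, 0.80, 1.4),
        PoolSpec("MT", -2.5, 0.08, 25.0),
        PoolSpec("CR", 2.0, 0.025, 0.6),
        PoolSpec("GLU", 3.0, 0.035, 1.0),
        PoolSpec("NOE", -3.5, 0.05, 3.0),
    ]
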