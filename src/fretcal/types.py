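"""Core data containers and exceptions shared across the toolkit.

Conventions
-----------
* Image arrays are indexed ``(z, y, x)``, 0-based, with pixel centers at
  integer coordinates.  This round-trips cleanly with TIFF readers, which
  store planes row-major.
* The three detection channels are always named ``donor`` (GFP emission
  under GFP excitation), ``acceptor`` (mCherry emission under mCherry
  excitation) and ``fret`` (mCherry emission under GFP excitation).
* Lengths are nanometres unless a name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

CHANNELS = ("donor", "acceptor", "fret")

#: Camera pixel size of the reference epifluorescence setup.
DEFAULT_PIXEL_SIZE_NM = 160.0
#: Axial spacing between successive z-planes.
DEFAULT_Z_STEP_NM = 200.0


class FretcalError(Exception):
    """Base class for all toolkit errors."""


class InvalidInputError(FretcalError, ValueError):
    """An argument violates a documented precondition."""


class BoundaryError(FretcalError):
    """A region of interest would clip the image edge."""


class FitFailedError(FretcalError):
    """A least-squares fit did not converge or produced a degenerate model.

    Attributes
    ----------
    diagnostics : dict
        Residual norms / optimizer messages useful for debugging the input.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndefinedRatioError(FretcalError, ZeroDivisionError):
    """A normalization denominator is zero for a named cluster."""


class DomainError(FretcalError, ValueError):
    """A quantity lies outside the mathematical domain of a conversion."""


class SingularFitError(FretcalError):
    """A regression design matrix is singular (e.g. all abscissae equal)."""


class FormatError(FretcalError):
    """An input file does not match the declared layout."""


class ConfigError(FretcalError):
    """A configuration / sidecar file is missing required keys."""


@dataclass(eq=False)
class ChannelStack:
    """One fluorescence channel of a cell as a 3-D intensity grid.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Camera counts; finite and non-negative.
    pixel_size_nm, z_step_nm : float
        Lateral / axial grid calibration.
    channel : str
        One of :data:`CHANNELS`.
    """

    voxels: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    z_step_nm: float = DEFAULT_Z_STEP_NM
    channel: str = "donor"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise InvalidInputError(
                f"stack must be 3-D (z, y, x); got shape {self.voxels.shape}"
            )
        nz, ny, nx = self.voxels.shape
        if nz < 1 or ny < 8 or nx < 8:
            raise InvalidInputError(
                f"stack needs >=1 plane and >=8 pixels in y and x; got {self.voxels.shape}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise InvalidInputError("stack contains non-finite intensities")
        if np.any(self.voxels < 0):
            raise InvalidInputError("stack contains negative intensities")
        if self.channel not in CHANNELS:
            raise InvalidInputError(f"channel must be one of {CHANNELS}; got {self.channel!r}")
        if self.pixel_size_nm <= 0 or self.z_step_nm <= 0:
            raise InvalidInputError("pixel_size_nm and z_step_nm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class RoiSpec:
    """Provenance of the region of interest used to integrate one cluster.

    ``method`` is ``"metaphase_box"`` (6x6 box photometry with a median ring
    background) or ``"anaphase_gaussian"`` (2-D Gaussian fit with an
    elliptical mask).  Exactly one of ``box_origin`` / ``gaussian_params``
    is populated, matching the method.
    """

    method: str
    focus_z: int
    peak_yx: tuple[int, int]
    box_origin: tuple[int, int] | None = None
    gaussian_params: dict[str, float] | None = None
    mask_sigma: float | None = None
    mask_pixel_count: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("metaphase_box", "anaphase_gaussian"):
            raise InvalidInputError(f"unknown ROI method {self.method!r}")
        if self.mask_pixel_count < 1:
            raise InvalidInputError("mask_pixel_count must be >= 1")


@dataclass
class ClusterMeasurement:
    """Background-corrected integrated counts of one cluster in all channels.

    The same :class:`RoiSpec` (focus plane, box placement or Gaussian mask)
    is shared by the three channels, mirroring the acquisition procedure in
    which the donor/acceptor/FRET images are aligned copies of one field.
    """

    cell_id: str
    phase: str
    intensities: dict[str, float]
    roi: RoiSpec
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phase not in ("metaphase", "anaphase"):
            raise InvalidInputError(f"phase must be metaphase|anaphase; got {self.phase!r}")
        missing = [c for c in CHANNELS if c not in self.intensities]
        if missing:
            raise InvalidInputError(f"measurement {self.cell_id!r} missing channels: {missing}")

    def __getitem__(self, channel: str) -> float:
        return self.intensities[channel]
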