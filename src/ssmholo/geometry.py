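"""Input-basis geometry for the holographic sensor.

The retrieval basis is a rectangular set of ``nx × ny`` equally spaced
spatial-frequency modes (low-pass plane waves) spanning a field of view of
``fov_x × fov_y`` millimetres.  The mode counts set both the retrievable
extent and the diffraction-limited spot: ``spot_x = fov_x / nx``.  Rendered
field images sample the FOV on a finer ``grid_nx × grid_ny`` grid so that
the band-limited synthesis is not aliased.

Units: lengths in mm, wavelength in nm, frequencies in cycles/mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidArgumentError


@dataclass(frozen=True)
class BasisGeometry:
    """Geometry of the preset spatial-frequency input basis.

    Parameters
    ----------
    nx, ny
        Mode counts per axis; the coefficient vectors consumed and produced
        by the retrieval pipeline have length ``N = nx * ny``.
    fov_x, fov_y
        Field of view in mm. Defaults match a 66x60-mode sensor with an
        80 x 67 um diffraction-limited spot.
    wavelength_nm
        Illumination wavelength (He-Ne default).
    grid_nx, grid_ny
        Spatial sampling of rendered field images; must be >= the mode
        count per axis. Default: twice the mode count.
    """

    nx: int
    ny: int
    fov_x: float = 5.28
    fov_y: float = 4.00
    wavelength_nm: float = 633.0
    grid_nx: int = field(default=0)
    grid_ny: int = field(default=0)

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise InvalidArgumentError("mode counts nx, ny must be >= 1")
        if self.fov_x <= 0 or self.fov_y <= 0:
            raise InvalidArgumentError("field of view must be positive")
        if self.wavelength_nm <= 0:
            raise InvalidArgumentError("wavelength must be positive")
        if self.grid_nx == 0:
            object.__setattr__(self, "grid_nx", 2 * self.nx)
        if self.grid_ny == 0:
            object.__setattr__(self, "grid_ny", 2 * self.ny)
        if self.grid_nx < self.nx or self.grid_ny < self.ny:
            raise InvalidArgumentError(
                "grid sampling must be >= mode count per axis (band-limited field)"
            )

    @property
    def n_modes(self) -> int:
        return self.nx * self.ny

    @property
    def spot_x(self) -> float:
        """Horizontal diffraction-limited spot size, mm."""
        return self.fov_x / self.nx

    @property
    def spot_y(self) -> float:
        """Vertical diffraction-limited spot size, mm."""
        return self.fov_y / self.ny

    @property
    def pitch_x(self) -> float:
        """Sample pitch of rendered field images, mm."""
        return self.fov_x / self.grid_nx

    @property
    def pitch_y(self) -> float:
        return self.fov_y / self.grid_ny
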