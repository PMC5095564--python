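"""Field rendering on the spatial-frequency basis and angular-spectrum optics.

This module maps coefficient vectors on the preset plane-wave basis to
physical complex field images (and back), propagates field images through
free space with the exact scalar angular-spectrum method, builds focal
stacks, and compounds the amplitudes of independently speckled holograms.

Conventions
-----------
* Modes sit on a centred grid of spatial frequencies; coefficients are
  row-major over ``(f_y, f_x)``.  For even mode counts the extra mode sits
  on the negative-frequency side (the ``fftshift`` centre convention).
* Synthesis/analysis use orthonormal FFTs, so ``coeffs_to_field`` conserves
  energy exactly: ``||field||^2 = ||alpha||^2`` (constant C = 1).
* Lengths are mm, wavelengths nm, spatial frequencies cycles/mm; the grid
  origin is at the array centre (index ``n // 2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import DimensionMismatchError, InvalidArgumentError
from .geometry import BasisGeometry

__all__ = [
    "BasisGeometry",
    "FieldImage",
    "PropagationParams",
    "coeffs_to_field",
    "field_to_coeffs",
    "angular_spectrum_propagate",
    "refocus_stack",
    "angular_compound",
    "sharpness",
    "speckle_contrast",
]


@dataclass
class FieldImage:
    """A 2-D complex field sampled on a regular spatial grid.

    ``values[iy, ix]`` is the field at position
    ``((ix - grid_nx//2) * pitch_x, (iy - grid_ny//2) * pitch_y)`` mm.
    ``z_offset`` records the focal plane relative to the native plane.
    """

    values: np.ndarray
    pitch_x: float
    pitch_y: float
    wavelength_nm: float
    z_offset: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2:
            raise InvalidArgumentError("field values must be a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("field values must be finite")
        if self.pitch_x <= 0 or self.pitch_y <= 0 or self.wavelength_nm <= 0:
            raise InvalidArgumentError("pitch and wavelength must be positive")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)


@dataclass(frozen=True)
class PropagationParams:
    """Signed propagation distance (mm) and evanescent-wave policy."""

    z: float
    evanescent_policy: str = "zero"

    def __post_init__(self) -> None:
        if not np.isfinite(self.z):
            raise InvalidArgumentError("propagation distance must be finite")
        if self.evanescent_policy not in ("zero", "decay"):
            raise InvalidArgumentError(
                f"unknown evanescent policy {self.evanescent_policy!r}"
            )


def _centered_block(n_grid: int, n_modes: int) -> slice:
    # even counts put the extra mode on the negative-frequency side
    c = n_grid // 2
    start = c - n_modes // 2
    return slice(start, start + n_modes)


def coeffs_to_field(x, geometry: BasisGeometry) -> FieldImage:
    """Synthesize the spatial field from mode coefficients.

    ``field(r) = sum_p alpha_p exp(i 2 pi f_p . r)`` over the centred
    ``nx x ny`` frequency grid, rendered by zero-padded inverse FFT on the
    ``grid_nx x grid_ny`` spatial grid.  Unitary: ``||field|| = ||alpha||``.
    """
    coeffs = np.asarray(getattr(x, "coefficients", x), dtype=complex)
    if coeffs.size != geometry.n_modes:
        raise DimensionMismatchError(
            f"coefficient length {coeffs.size} != nx*ny = {geometry.n_modes}"
        )
    spec = np.zeros((geometry.grid_ny, geometry.grid_nx), dtype=complex)
    spec[
        _centered_block(geometry.grid_ny, geometry.ny),
        _centered_block(geometry.grid_nx, geometry.nx),
    ] = coeffs.reshape(geometry.ny, geometry.nx)
    values = np.fft.ifft2(np.fft.ifftshift(spec), norm="ortho")
    return FieldImage(
        values=values,
        pitch_x=geometry.pitch_x,
        pitch_y=geometry.pitch_y,
        wavelength_nm=geometry.wavelength_nm,
    )


def field_to_coeffs(field: FieldImage, geometry: BasisGeometry):
    """Project a field image onto the mode basis (adjoint of synthesis).

    Orthogonal projection: an exact left inverse of :func:`coeffs_to_field`
    and a contraction on arbitrary fields.
    """
    from .forward_model import IncidentField  # local import avoids a cycle

    v = np.asarray(field.values, dtype=complex)
    if v.shape != (geometry.grid_ny, geometry.grid_nx):
        raise DimensionMismatchError(
            f"field grid {v.shape} does not match geometry "
            f"({geometry.grid_ny}, {geometry.grid_nx})"
        )
    spec = np.fft.fftshift(np.fft.fft2(v, norm="ortho"))
    block = spec[
        _centered_block(geometry.grid_ny, geometry.ny),
        _centered_block(geometry.grid_nx, geometry.nx),
    ]
    return IncidentField(
        coefficients=block.ravel(), geometry=geometry, label="projected"
    )


def angular_spectrum_propagate(
    field: FieldImage, params: PropagationParams | float
) -> FieldImage:
    """Propagate a field image by ``z`` mm with the angular-spectrum method.

    The 2-D spectrum is multiplied by ``exp(i 2 pi z sqrt(1/lambda^2 - f^2))``
    for propagating components; evanescent components are zeroed (policy
    ``"zero"``) or damped by ``exp(-2 pi |z| sqrt(f^2 - 1/lambda^2))``
    (policy ``"decay"``).  Unitary on the propagating band.
    """
    if not isinstance(params, PropagationParams):
        params = PropagationParams(z=float(params))
    lam_mm = field.wavelength_nm * 1e-6
    ny, nx = field.values.shape
    fx = np.fft.fftfreq(nx, d=field.pitch_x)
    fy = np.fft.fftfreq(ny, d=field.pitch_y)
    fx2 = fx[np.newaxis, :] ** 2
    fy2 = fy[:, np.newaxis] ** 2
    arg = 1.0 / lam_mm**2 - fx2 - fy2
    transfer = np.zeros((ny, nx), dtype=complex)
    prop = arg > 0
    transfer[prop] = np.exp(2j * np.pi * params.z * np.sqrt(arg[prop]))
    if params.evanescent_policy == "decay":
        ev = ~prop
        transfer[ev] = np.exp(-2 * np.pi * abs(params.z) * np.sqrt(-arg[ev]))
    spec = np.fft.fft2(field.values)
    out = np.fft.ifft2(spec * transfer)
    return FieldImage(
        values=out,
        pitch_x=field.pitch_x,
        pitch_y=field.pitch_y,
        wavelength_nm=field.wavelength_nm,
        z_offset=field.z_offset + params.z,
    )


def refocus_stack(field: FieldImage, z_values) -> list[FieldImage]:
    """Propagate the ORIGINAL field to each z in ``z_values`` (not chained)."""
    z_values = list(z_values)
    if not z_values:
        raise InvalidArgumentError("z_values must be nonempty")
    return [angular_spectrum_propagate(field, float(z)) for z in z_values]


def angular_compound(holograms, z: float = 0.0) -> np.ndarray:
    """Compound hologram amplitudes at a common refocus plane.

    Each hologram is propagated to ``z`` and the pixelwise mean of the
    amplitudes is returned.  With K independent speckle realizations of the
    same object, the speckle contrast of the result drops roughly as
    ``1/sqrt(K)``.
    """
    holograms = list(holograms)
    if not holograms:
        raise InvalidArgumentError("need at least one hologram")
    shape = holograms[0].values.shape
    for h in holograms[1:]:
        if h.values.shape != shape:
            raise DimensionMismatchError(
                f"hologram grids differ: {h.values.shape} vs {shape}"
            )
    amps = [np.abs(angular_spectrum_propagate(h, z).values) for h in holograms]
    return np.mean(amps, axis=0)


def sharpness(amplitude: np.ndarray) -> float:
    """Focus metric: mean gradient magnitude per unit mean amplitude.

    The raw mean gradient of a coherent amplitude image is a total-variation
    measure that keeps GROWING as defocused light spreads fringes over the
    region; dividing by the region's mean amplitude turns it into a spatial
    frequency scale that peaks at the focal plane of sparse smooth objects.
    """
    a = np.asarray(amplitude, dtype=float)
    mean = a.mean()
    if mean == 0:
        raise InvalidArgumentError("zero-amplitude region: sharpness undefined")
    gy, gx = np.gradient(a)
    return float(np.mean(np.hypot(gx, gy)) / mean)


def speckle_contrast(amplitude: np.ndarray, region=None) -> float:
    """Speckle contrast sd/mean of an amplitude image over ``region`` (mask)."""
    a = np.asarray(amplitude, dtype=float)
    if region is not None:
        a = a[region]
    m = a.mean()
    if m == 0:
        raise InvalidArgumentError("zero-mean amplitude: contrast undefined")
    return float(a.std() / m)
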