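"""Synthetic diffusive-layer transport and speckle measurement model.

The diffusive layer is modelled as a random transmission matrix (TM) with
i.i.d. circular complex Gaussian entries: each column ``t_p`` is the
speckle field produced at the camera by the p-th input mode.  Mesoscopic
correlations are neglected (an adequate model for a thin diffuser), and
speckle grains are assumed matched to single camera pixels so that TM rows
are statistically independent.

Columns are normalised to unit mean square modulus, ``(1/M) sum_m
|t_{p,m}|^2 = 1``, so that the spatial correlation ``<t_p* y>`` estimates
the mode coefficient ``alpha_p`` without extra factors.

Detector noise is additive white Gaussian on the intensity with
``sd = mean(I) / SNR``; negative noisy intensities are deliberately kept
(clipping would bias the second moments that the speckle-correlation
scattering matrix is built from).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from ._rng import (
    STAGE_INCIDENT,
    STAGE_INTENSITY_NOISE,
    STAGE_MOMENT,
    STAGE_PHANTOM,
    STAGE_TM,
    STAGE_TM_NOISE,
    substream,
)
from .errors import (
    DimensionMismatchError,
    InvalidArgumentError,
    InvalidDataError,
    ResourceError,
)
from .geometry import BasisGeometry

#: refuse to allocate transmission matrices beyond this many bytes
MAX_TM_BYTES = 4 * 1024**3


@dataclass
class TransmissionMatrix:
    """M x N complex map from input-mode coefficients to the diffused field.

    Column p is ``t_p``, the camera-plane speckle field of input mode k_p.
    """

    entries: np.ndarray
    geometry: BasisGeometry | None = None
    column_normalized: bool = True
    provenance: str = "synthetic"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=complex)
        if self.entries.ndim != 2:
            raise InvalidArgumentError("TM entries must be a 2-D array")
        if not np.all(np.isfinite(self.entries)):
            raise InvalidDataError("TM entries must be finite")
        col_power = np.mean(np.abs(self.entries) ** 2, axis=0)
        if np.any(col_power == 0):
            raise InvalidDataError("TM has an all-zero column")
        if self.column_normalized and np.max(np.abs(col_power - 1.0)) > 1e-9:
            raise InvalidDataError(
                "column_normalized is set but columns are not unit mean-square"
            )

    @property
    def n_pixels(self) -> int:
        return self.entries.shape[0]

    @property
    def n_modes(self) -> int:
        return self.entries.shape[1]

    @property
    def gamma(self) -> float:
        """Sampling ratio M/N."""
        return self.n_pixels / self.n_modes


@dataclass
class IncidentField:
    """Length-N complex coefficient vector on the preset input basis."""

    coefficients: np.ndarray
    geometry: BasisGeometry | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex).ravel()
        if not np.all(np.isfinite(self.coefficients)):
            raise InvalidDataError("incident-field coefficients must be finite")

    @property
    def n_modes(self) -> int:
        return self.coefficients.size


@dataclass
class SpeckleField:
    """Length-M complex diffused field at the camera plane."""

    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex).ravel()
        if not np.all(np.isfinite(self.values)):
            raise InvalidDataError("speckle field values must be finite")


@dataclass
class SpeckleIntensity:
    """Length-M real single-shot camera measurement ``I = |y|^2``.

    With additive detector noise, negative values are possible and are
    preserved unclipped.
    """

    values: np.ndarray
    snr: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise InvalidDataError("intensity values must be finite")


@dataclass
class SimulationConfig:
    """Bookkeeping for one synthetic measurement condition."""

    n_modes: int
    gamma: float
    tm_snr: float | None = None
    intensity_snr: float | None = None
    seed: int = 0
    repetitions: int = 1

    def __post_init__(self) -> None:
        if self.gamma < 1:
            raise InvalidArgumentError("gamma must be >= 1")
        if self.n_modes < 1:
            raise InvalidArgumentError("n_modes must be >= 1")
        if self.repetitions < 1:
            raise InvalidArgumentError("repetitions must be >= 1")
        for s in (self.tm_snr, self.intensity_snr):
            if s is not None and s <= 0:
                raise InvalidArgumentError("snr must be positive or None")

    @property
    def n_pixels(self) -> int:
        return int(round(self.gamma * self.n_modes))


def generate_tm(
    n_modes: int,
    gamma: float,
    seed: int,
    geometry: BasisGeometry | None = None,
    max_bytes: int = MAX_TM_BYTES,
) -> TransmissionMatrix:
    """Draw a synthetic diffusive-layer TM.

    Entries are i.i.d. circular complex Gaussian; each column is then
    rescaled to unit mean square modulus.  ``M = round(gamma * n_modes)``.
    """
    if n_modes < 1:
        raise InvalidArgumentError(f"n_modes must be >= 1, got {n_modes}")
    if gamma < 1:
        raise InvalidArgumentError(f"gamma must be >= 1, got {gamma}")
    m = int(round(gamma * n_modes))
    nbytes = m * n_modes * 16
    if nbytes > max_bytes:
        raise ResourceError(
            f"TM of {m} x {n_modes} needs {nbytes / 1e9:.1f} GB "
            f"(budget {max_bytes / 1e9:.1f} GB)"
        )
    rng = substream(seed, STAGE_TM)
    entries = (
        rng.standard_normal((m, n_modes)) + 1j * rng.standard_normal((m, n_modes))
    ) / np.sqrt(2.0)
    # unit mean-square columns: (1/M) sum |t|^2 = 1
    entries *= np.sqrt(m) / np.linalg.norm(entries, axis=0)
    return TransmissionMatrix(
        entries=entries,
        geometry=geometry,
        column_normalized=True,
        provenance="synthetic",
        seed=seed,
    )


def _phase_phantom_field(geometry: BasisGeometry, rng: np.random.Generator,
                         n_bumps: int, max_phase: float) -> np.ndarray:
    """Unit-amplitude field exp(i phi) with phi a sum of smooth Gaussian bumps."""
    gx = (np.arange(geometry.grid_nx) - geometry.grid_nx // 2) * geometry.pitch_x
    gy = (np.arange(geometry.grid_ny) - geometry.grid_ny // 2) * geometry.pitch_y
    X, Y = np.meshgrid(gx, gy)
    phi = np.zeros_like(X)
    for _ in range(n_bumps):
        cx = rng.uniform(-0.3 * geometry.fov_x, 0.3 * geometry.fov_x)
        cy = rng.uniform(-0.3 * geometry.fov_y, 0.3 * geometry.fov_y)
        # widths a few diffraction-limited spots: smooth, cell-like
        w = rng.uniform(2.0, 6.0) * max(geometry.spot_x, geometry.spot_y)
        a = rng.uniform(0.3, 1.0)
        phi += a * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * w**2))
    peak = np.max(np.abs(phi))
    if peak > 0:
        phi *= max_phase / peak
    return np.exp(1j * phi)


def synthesize_incident(
    geometry: BasisGeometry,
    kind: str,
    seed: int,
    mask: np.ndarray | None = None,
    n_bumps: int = 6,
    max_phase: float = 0.9 * np.pi,
) -> IncidentField:
    """Create a test incident field on the preset basis.

    Kinds
    -----
    ``random``
        i.i.d. circular complex Gaussian mode coefficients (a fully
        developed random wavefront).
    ``binary_mask``
        A {0,1} amplitude pattern on the rendering grid (random rectangles,
        or the explicit ``mask`` array) projected onto the mode basis.
    ``phase_phantom``
        Unit-amplitude smooth phase object ``exp(i phi(r))`` with
        ``max |phi| <= max_phase <= pi`` — a stand-in for transparent
        cell-like specimens — projected onto the mode basis.
    """
    from .optics_propagation import FieldImage, field_to_coeffs

    if max_phase > np.pi or max_phase <= 0:
        raise InvalidArgumentError("max_phase must lie in (0, pi]")
    rng = substream(seed, STAGE_PHANTOM if kind == "phase_phantom" else STAGE_INCIDENT)
    if kind == "random":
        n = geometry.n_modes
        coeffs = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2)
        return IncidentField(coefficients=coeffs, geometry=geometry, label="random")

    if kind == "binary_mask":
        if mask is None:
            mask = np.zeros((geometry.grid_ny, geometry.grid_nx))
            for _ in range(rng.integers(2, 5)):
                h = rng.integers(geometry.grid_ny // 8, geometry.grid_ny // 2)
                w = rng.integers(geometry.grid_nx // 8, geometry.grid_nx // 2)
                r = rng.integers(0, geometry.grid_ny - h)
                c = rng.integers(0, geometry.grid_nx - w)
                mask[r : r + h, c : c + w] = 1.0
        mask = np.asarray(mask, dtype=float)
        if set(np.unique(mask)) - {0.0, 1.0}:
            raise InvalidArgumentError("binary mask must contain only 0 and 1")
        spatial = FieldImage(
            values=mask.astype(complex),
            pitch_x=geometry.pitch_x,
            pitch_y=geometry.pitch_y,
            wavelength_nm=geometry.wavelength_nm,
        )
        out = field_to_coeffs(spatial, geometry)
        out.label = "binary_mask"
        return out

    if kind == "phase_phantom":
        values = _phase_phantom_field(geometry, rng, n_bumps, max_phase)
        spatial = FieldImage(
            values=values,
            pitch_x=geometry.pitch_x,
            pitch_y=geometry.pitch_y,
            wavelength_nm=geometry.wavelength_nm,
        )
        out = field_to_coeffs(spatial, geometry)
        out.label = "phase_phantom"
        return out

    raise InvalidArgumentError(f"unknown incident-field kind {kind!r}")


def forward_propagate(tm: TransmissionMatrix, x: IncidentField) -> SpeckleField:
    """Diffused field ``y = sum_p alpha_p t_p`` (linear in x)."""
    coeffs = np.asarray(getattr(x, "coefficients", x), dtype=complex).ravel()
    if coeffs.size != tm.n_modes:
        raise DimensionMismatchError(
            f"incident field has {coeffs.size} modes, TM expects {tm.n_modes}"
        )
    return SpeckleField(values=tm.entries @ coeffs, source=f"tm:{tm.provenance}")


def capture_intensity(
    y: SpeckleField, snr: float | None = None, seed: int | None = None
) -> SpeckleIntensity:
    """Camera measurement ``I = |y|^2`` with optional additive white noise.

    Noise sd is ``mean(|y|^2) / snr``.  Negative noisy values are kept.
    """
    if snr is not None and snr <= 0:
        raise InvalidArgumentError(f"snr must be positive, got {snr}")
    values = np.abs(np.asarray(getattr(y, "values", y), dtype=complex).ravel()) ** 2
    if snr is not None:
        rng = substream(seed, STAGE_INTENSITY_NOISE)
        values = values + rng.normal(0.0, values.mean() / snr, size=values.size)
    return SpeckleIntensity(values=values, snr=snr, seed=seed)


def add_matrix_noise(
    tm: TransmissionMatrix, snr: float, seed: int | None = None
) -> TransmissionMatrix:
    """Perturb TM entries by i.i.d. complex Gaussian noise.

    Per-entry noise sd (complex magnitude rms) is ``rms(|entries|) / snr``,
    mimicking a noisy calibration.  The input is left unmodified and the
    result is NOT re-normalised (the perturbation must survive).
    """
    if snr is None:
        return TransmissionMatrix(
            entries=tm.entries.copy(),
            geometry=tm.geometry,
            column_normalized=tm.column_normalized,
            provenance=tm.provenance,
            seed=tm.seed,
        )
    if snr <= 0:
        raise InvalidArgumentError(f"snr must be positive, got {snr}")
    rng = substream(seed, STAGE_TM_NOISE)
    rms = np.sqrt(np.mean(np.abs(tm.entries) ** 2))
    sd = rms / snr / np.sqrt(2.0)  # per real component
    noise = rng.normal(0.0, sd, tm.entries.shape) + 1j * rng.normal(
        0.0, sd, tm.entries.shape
    )
    return TransmissionMatrix(
        entries=tm.entries + noise,
        geometry=tm.geometry,
        column_normalized=False,
        provenance=f"{tm.provenance}+noise(snr={snr})",
        seed=tm.seed,
    )


#: fixed complex mixing matrix defining the joint covariance used by
#: moment_identity_check (any full-rank choice works; frozen for determinism)
_MOMENT_MIXER = np.array(
    [
        [1.0 + 0.0j, 0.3 - 0.2j, 0.0, 0.1j],
        [0.3 + 0.1j, 1.0, 0.2, 0.0],
        [0.0, 0.25j, 1.0 - 0.1j, 0.4],
        [0.2, 0.0, 0.3 + 0.3j, 1.0],
    ]
)


def moment_identity_check(n_samples: int, seed: int) -> float:
    """Empirically verify the circular-Gaussian fourth-moment factorisation.

    Draws four jointly circular complex Gaussian fields E_1..E_4 with a
    known covariance and returns the relative error between the empirical
    mixed fourth moment ``<E_1 E_2* E_3 E_4*>`` and its second-moment
    pairing decomposition
    ``<E_1 E_2*><E_3 E_4*> + <E_1 E_4*><E_3 E_2*>``.
    The error shrinks like ``1/sqrt(n_samples)``.
    """
    if n_samples < 100:
        raise InvalidArgumentError("n_samples must be >= 100")
    rng = substream(seed, STAGE_MOMENT)
    g = (
        rng.standard_normal((n_samples, 4)) + 1j * rng.standard_normal((n_samples, 4))
    ) / np.sqrt(2.0)
    e = g @ _MOMENT_MIXER.T
    e1, e2, e3, e4 = e.T
    m4 = np.mean(e1 * np.conj(e2) * e3 * np.conj(e4))
    pairing = np.mean(e1 * np.conj(e2)) * np.mean(e3 * np.conj(e4)) + np.mean(
        e1 * np.conj(e4)
    ) * np.mean(e3 * np.conj(e2))
    return float(np.abs(m4 - pairing) / np.abs(pairing))
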