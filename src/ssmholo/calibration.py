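"""Phase-shifting interferometric calibration of the transmission matrix.

The TM is calibrated one input mode at a time with a three-step
phase-shifting scheme: for mode p, three interferograms of the diffused
field ``t_p`` against a reference beam ``R`` are recorded with global
reference phase delays {0, 2*pi/3, 4*pi/3}, plus one reference-only frame
``|R|^2`` taken with the sample arm blocked — a total of ``3N + 1`` frames.

The closed-form three-step inversion

    t_p . R* = (1/3) * sum_k I_{k,p} * exp(i theta_k)

recovers the product of the unknown field with the conjugate reference
(verified against a brute-force least-squares fit of the interferogram
model).  Dividing by ``|R| = sqrt(reference frame)`` compensates the
reference AMPLITUDE; the reference PHASE is deliberately left in — the
estimate is ``t_p * exp(-i arg R)`` per pixel — because a per-pixel phase
common to every column cancels identically in the speckle-correlation
scattering matrix and therefore in the retrieval.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from ._rng import STAGE_CALIBRATION_NOISE, substream
from .errors import (
    DegenerateReferenceError,
    DimensionMismatchError,
    InvalidArgumentError,
    InvalidDataError,
)
from .forward_model import TransmissionMatrix

#: the standard equally-spaced three-step phase delays (radians); configurable
DEFAULT_DELAYS = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)

#: pixels with |R|^2 below this fraction of the frame maximum are degenerate
REFERENCE_FLOOR = 1e-12


@dataclass
class ReferenceField:
    """Reference beam at the camera pixels; must not vanish anywhere."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex).ravel()
        if not np.all(np.isfinite(self.values)):
            raise InvalidDataError("reference field must be finite")

    @property
    def n_pixels(self) -> int:
        return self.values.size


@dataclass
class CalibrationFrames:
    """The 3N+1 intensity frames of a three-step calibration run.

    ``interferograms[p, k]`` is the length-M frame of mode p at delay
    ``delays[k]``; ``reference_intensity`` is the sample-arm-blocked frame.
    """

    interferograms: np.ndarray  # (N, 3, M)
    reference_intensity: np.ndarray  # (M,)
    delays: tuple = DEFAULT_DELAYS

    def __post_init__(self) -> None:
        self.interferograms = np.asarray(self.interferograms, dtype=float)
        self.reference_intensity = np.asarray(
            self.reference_intensity, dtype=float
        ).ravel()
        if self.interferograms.ndim != 3 or self.interferograms.shape[1] != len(
            self.delays
        ):
            raise InvalidArgumentError(
                "interferograms must have shape (n_modes, n_delays, n_pixels)"
            )
        if self.interferograms.shape[2] != self.reference_intensity.size:
            raise DimensionMismatchError(
                "interferogram and reference pixel counts differ"
            )

    @property
    def n_modes(self) -> int:
        return self.interferograms.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.interferograms.shape[2]

    @property
    def frame_count(self) -> int:
        """Total camera exposures: len(delays) per mode plus the reference."""
        return self.n_modes * len(self.delays) + 1


def simulate_calibration_frames(
    tm_true: TransmissionMatrix,
    reference: ReferenceField,
    noise_snr: float | None = None,
    seed: int | None = None,
    delays: tuple = DEFAULT_DELAYS,
) -> CalibrationFrames:
    """Render the interferogram stack ``|t_p + R e^{i theta_k}|^2``.

    Optional additive white Gaussian noise with a single global sd of
    ``mean(interferograms) / noise_snr`` applied to every frame, the
    reference frame included.
    """
    if reference.n_pixels != tm_true.n_pixels:
        raise DimensionMismatchError(
            f"reference has {reference.n_pixels} pixels, TM has {tm_true.n_pixels}"
        )
    if noise_snr is not None and noise_snr <= 0:
        raise InvalidArgumentError("noise_snr must be positive or None")
    r = reference.values
    # (N, 3, M): t_p broadcast against the delayed reference
    t = tm_true.entries.T[:, np.newaxis, :]  # (N, 1, M)
    shifted = r[np.newaxis, np.newaxis, :] * np.exp(
        1j * np.asarray(delays)[np.newaxis, :, np.newaxis]
    )
    frames = np.abs(t + shifted) ** 2
    ref_frame = np.abs(r) ** 2
    if noise_snr is not None:
        rng = substream(seed, STAGE_CALIBRATION_NOISE)
        sd = frames.mean() / noise_snr
        frames = frames + rng.normal(0.0, sd, frames.shape)
        ref_frame = ref_frame + rng.normal(0.0, sd, ref_frame.shape)
    return CalibrationFrames(
        interferograms=frames, reference_intensity=ref_frame, delays=tuple(delays)
    )


def estimate_tm(
    frames: CalibrationFrames, reference_floor: float = REFERENCE_FLOOR
) -> TransmissionMatrix:
    """Invert three-step calibration frames into a TM estimate.

    Per mode: ``t R* = (1/3) sum_k I_k e^{i theta_k}``; the result is
    divided by ``|R|`` (square root of the reference frame), yielding
    ``t_p e^{-i arg R}`` per pixel.  The residual reference phase is
    common to all columns and cancels downstream.
    """
    delays = np.asarray(frames.delays)
    phasors = np.exp(1j * delays)  # (3,)
    # (N, M): sum over the delay axis
    t_rconj = np.tensordot(frames.interferograms, phasors, axes=([1], [0])) / len(
        delays
    )
    ref = frames.reference_intensity
    floor = reference_floor * ref.max()
    bad = ref <= floor
    if np.any(bad):
        raise DegenerateReferenceError(
            f"reference intensity vanishes on {int(bad.sum())} of {ref.size} pixels; "
            "cannot compensate |R|"
        )
    entries = (t_rconj / np.sqrt(ref)[np.newaxis, :]).T  # (M, N)
    return TransmissionMatrix(
        entries=entries,
        column_normalized=False,
        provenance="calibrated",
        seed=None,
    )


def filter_correlated_modes(
    tm: TransmissionMatrix, threshold: float
) -> TransmissionMatrix:
    """Whiten anomalously correlated directions of the TM singular spectrum.

    An i.i.d. diffusive TM has a Marchenko–Pastur-like singular bulk; mode
    pairs that are physically correlated show up as outlier singular
    values.  Directions whose singular value deviates from the bulk median
    by more than the ``threshold`` factor (above or below) are rescaled to
    the median, preserving the column dimension so that retrieval still
    maps onto the full preset basis.
    """
    if not (0 < threshold <= 1e18):
        raise InvalidArgumentError("threshold must be positive")
    if threshold > 1:
        lo, hi = 1.0 / threshold, threshold
    else:
        # thresholds <=1 express the deviation the other way round
        lo, hi = threshold, 1.0 / threshold
    u, s, vh = np.linalg.svd(tm.entries, full_matrices=False)
    med = np.median(s)
    out = (s > hi * med) | (s < lo * med)
    if not np.any(out):
        return TransmissionMatrix(
            entries=tm.entries.copy(),
            geometry=tm.geometry,
            column_normalized=tm.column_normalized,
            provenance=tm.provenance,
            seed=tm.seed,
        )
    s = s.copy()
    s[out] = med
    entries = (u * s) @ vh
    return TransmissionMatrix(
        entries=entries,
        geometry=tm.geometry,
        column_normalized=False,
        provenance=f"{tm.provenance}+whitened({int(out.sum())} dirs)",
        seed=tm.seed,
    )
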