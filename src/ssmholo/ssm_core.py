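"""The speckle-correlation scattering matrix and eigenvector retrieval.

Given a calibrated TM with columns ``t_p`` and a single speckle intensity
snapshot ``I = |y|^2``, the speckle-correlation scattering matrix is the
N x N Hermitian form

    Z_pq = (1/N_Z) * sum_m  t*_{p,m} I_m t_{q,m},      N_Z = M,

i.e. every pair of TM columns correlated through the measured intensity.
Because the diffused fields are circular complex Gaussian, the mixed
fourth moment factorises into second-moment pairings: in expectation

    Z_pq  ≈  alpha_p alpha_q*  +  delta_pq * mean(I)  +  O(1/sqrt(gamma)),

so after subtracting the self-pairing diagonal ``mean(I) * Id`` the matrix
approaches rank one with the incident coefficient vector as its sole
eigenvector.  The residual shrinks as the sampling ratio gamma = M/N
grows, which is what makes single-shot, reference-free retrieval work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import (
    DegenerateSpectrumError,
    DimensionMismatchError,
    InvalidArgumentError,
    InvalidDataError,
)
from .forward_model import IncidentField, SpeckleIntensity, TransmissionMatrix

logger = logging.getLogger(__name__)

#: above this N the full Hermitian eigendecomposition is replaced by an
#: iterative leading-pair solver
FULL_EIG_MAX_N = 4096


@dataclass
class SSMatrix:
    """N x N Hermitian speckle-correlation scattering matrix."""

    entries: np.ndarray
    normalization_constant: float
    diagonal_corrected: bool
    asymmetry: float = 0.0  # pre-symmetrization relative asymmetry (logged)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=complex)
        if self.entries.ndim != 2 or self.entries.shape[0] != self.entries.shape[1]:
            raise InvalidArgumentError("SSM must be square")
        if self.normalization_constant <= 0:
            raise InvalidArgumentError("normalization constant must be positive")

    @property
    def n_modes(self) -> int:
        return self.entries.shape[0]


@dataclass
class RetrievalResult:
    """Retrieved incident coefficients and eigen-spectrum diagnostics."""

    coefficients: np.ndarray
    eigenvalues: np.ndarray  # descending
    spectral_gap: float  # lambda_1 / lambda_2 confidence diagnostic
    phase_convention: str = "largest coefficient rotated to zero phase"
    method: str = "ssm"


def build_ssm(
    tm: TransmissionMatrix,
    intensity: SpeckleIntensity,
    diagonal_correction: bool = True,
) -> SSMatrix:
    """Correlate all TM column pairs through one intensity snapshot.

    ``Z = T^H diag(I) T / M``, symmetrized as ``(Z + Z^H)/2`` (the
    asymmetry is round-off only and its magnitude is logged).  With
    ``diagonal_correction`` the self-pairing term ``mean(I) * Id`` is
    subtracted so the noiseless Z is numerically rank one; the shift
    cannot change eigenvectors, so retrieval is identical either way.
    """
    i_vals = np.asarray(getattr(intensity, "values", intensity), dtype=float).ravel()
    if not np.all(np.isfinite(i_vals)):
        raise InvalidDataError("intensity contains non-finite values")
    if i_vals.size != tm.n_pixels:
        raise DimensionMismatchError(
            f"intensity has {i_vals.size} pixels, TM has {tm.n_pixels}"
        )
    t = tm.entries
    m = tm.n_pixels
    z = (t.conj().T * i_vals) @ t / m
    norm_z = np.linalg.norm(z)
    asym = float(np.linalg.norm(z - z.conj().T) / norm_z) if norm_z > 0 else 0.0
    logger.debug("SSM pre-symmetrization relative asymmetry: %.3e", asym)
    z = (z + z.conj().T) / 2.0
    if diagonal_correction:
        z -= i_vals.mean() * np.eye(tm.n_modes)
    return SSMatrix(
        entries=z,
        normalization_constant=float(m),
        diagonal_corrected=diagonal_correction,
        asymmetry=asym,
    )


def _leading_spectrum(z: np.ndarray):
    """Descending eigenvalues (full or estimated) and the leading vector."""
    n = z.shape[0]
    if n <= FULL_EIG_MAX_N:
        w, v = np.linalg.eigh(z)
        order = np.argsort(w)[::-1]
        return w[order], v[:, order[0]], None
    from scipy.sparse.linalg import eigsh

    w, v = eigsh(z, k=2, which="LA", tol=1e-10, maxiter=10_000)
    order = np.argsort(w)[::-1]
    # tail median approximated from the trace (full spectrum unavailable)
    tail_shift = (np.trace(z).real - w.sum()) / max(n - 2, 1)
    eigs = np.full(n, tail_shift)
    eigs[:2] = w[order]
    return eigs, v[:, order[0]], tail_shift


def retrieve_field(ssm: SSMatrix) -> RetrievalResult:
    """Retrieve the incident field as the SSM's leading eigenvector.

    The unit eigenvector is scaled by ``sqrt(max(lambda_1 - median(tail), 0))``
    so coefficient amplitudes are physically meaningful (the identity-shift
    self-term inflates all eigenvalues equally; the tail median is its
    robust estimate).  The global phase is fixed by rotating the
    largest-magnitude coefficient to zero phase (ties: lowest index).
    """
    z = ssm.entries
    eigs, vec, tail_shift = _leading_spectrum(z)
    lam1, lam2 = float(eigs[0]), float(eigs[1])
    scale_ref = max(abs(lam1), abs(lam2), np.finfo(float).tiny)
    if abs(lam1 - lam2) <= 1e-9 * scale_ref:
        raise DegenerateSpectrumError(
            f"retrieval ill-posed: leading eigenvalues tied "
            f"(lambda1={lam1:.6g}, lambda2={lam2:.6g})"
        )
    shift = float(np.median(eigs[1:])) if tail_shift is None else tail_shift
    scale = np.sqrt(max(lam1 - shift, 0.0))
    if scale == 0.0:
        scale = np.sqrt(abs(lam1)) if lam1 != 0 else 1.0
    j = int(np.argmax(np.abs(vec)))  # argmax ties break at lowest index
    vec = vec * np.exp(-1j * np.angle(vec[j])) * scale
    gap = lam1 / lam2 if lam2 > 0 else np.inf
    return RetrievalResult(
        coefficients=vec,
        eigenvalues=eigs,
        spectral_gap=float(gap),
    )


def field_correlation(a, b) -> float:
    """Normalized field correlation ``|a^H b| / (||a|| ||b||)`` in [0, 1].

    Invariant to global phase and positive rescaling of either argument.
    """
    av = np.asarray(getattr(a, "coefficients", a), dtype=complex).ravel()
    bv = np.asarray(getattr(b, "coefficients", b), dtype=complex).ravel()
    if av.size != bv.size:
        raise DimensionMismatchError(
            f"field lengths differ: {av.size} vs {bv.size}"
        )
    na, nb = np.linalg.norm(av), np.linalg.norm(bv)
    if na == 0 or nb == 0:
        raise InvalidArgumentError("field correlation undefined for a zero vector")
    return float(min(np.abs(np.vdot(av, bv)) / (na * nb), 1.0))
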