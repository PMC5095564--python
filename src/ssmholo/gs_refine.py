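"""Gerchberg–Saxton error-reduction refinement with the TM as the operator.

The classical GS/error-reduction iteration alternates between an object
domain and a measurement domain linked by a Fourier transform, enforcing a
measured amplitude in the latter.  Here the calibrated transmission matrix
replaces the Fourier operator: starting from the SSM estimate ``x_0``, each
iteration propagates ``y_k = T x_k``, replaces the speckle amplitude with
the measured one while keeping the phase, and back-projects.

Because a TM is not unitary (unlike the Fourier transform), the
back-projection is ambiguous; both readings are provided:

* ``pinv`` (default) — Moore–Penrose least-squares back-projection,
  precomputed once; gives the classical non-increasing speckle-plane
  residual of error reduction.
* ``adjoint`` — ``(1/M) T^H``, a cheap approximation valid for i.i.d. TMs
  where ``T^H T ≈ M Id``; coincides with pinv as gamma grows.

The single measured amplitude is the only constraint: there are no free
parameters beyond the stopping threshold and the iteration cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import DimensionMismatchError, InvalidArgumentError
from .forward_model import IncidentField, SpeckleIntensity, TransmissionMatrix
from .ssm_core import field_correlation

#: successive-iterate correlation above which the iteration is converged
DEFAULT_THRESHOLD = 0.999998
DEFAULT_MAX_ITER = 1000


@dataclass
class GSResult:
    """Refined coefficients plus the convergence trace."""

    coefficients: np.ndarray
    n_iterations: int
    trace: np.ndarray  # successive-correlation per iteration
    terminated_by: str  # "threshold" | "max_iter"
    method: str = "ssm+gs"


def gs_refine(
    tm: TransmissionMatrix,
    intensity: SpeckleIntensity,
    x0: IncidentField,
    threshold: float = DEFAULT_THRESHOLD,
    max_iter: int = DEFAULT_MAX_ITER,
    inverse_mode: str = "pinv",
) -> GSResult:
    """Refine an initial field estimate against the measured speckle amplitude.

    Iterates ``y_k = T x_k``; ``y'_k = sqrt(max(I, 0)) * exp(i arg y_k)``;
    ``x_{k+1} = T^+ y'_k`` (or ``(1/M) T^H y'_k``), stopping when the
    correlation between successive iterates exceeds ``threshold`` or after
    ``max_iter`` iterations (flagged, not raised).  Negative noisy
    intensities are floored at zero only inside the square root — the
    amplitude constraint must be real.
    """
    if inverse_mode not in ("pinv", "adjoint"):
        raise InvalidArgumentError(f"unknown inverse_mode {inverse_mode!r}")
    if not (0 < threshold < 1):
        raise InvalidArgumentError("threshold must lie in (0, 1)")
    if max_iter < 1:
        raise InvalidArgumentError("max_iter must be >= 1")
    i_vals = np.asarray(getattr(intensity, "values", intensity), dtype=float).ravel()
    if i_vals.size != tm.n_pixels:
        raise DimensionMismatchError(
            f"intensity has {i_vals.size} pixels, TM has {tm.n_pixels}"
        )
    x = np.asarray(getattr(x0, "coefficients", x0), dtype=complex).ravel().copy()
    if x.size != tm.n_modes:
        raise DimensionMismatchError(
            f"x0 has {x.size} modes, TM expects {tm.n_modes}"
        )
    if np.linalg.norm(x) == 0:
        raise InvalidArgumentError("x0 must be nonzero")

    amp = np.sqrt(np.clip(i_vals, 0.0, None))
    t = tm.entries
    if inverse_mode == "pinv":
        t_pinv = np.linalg.pinv(t)
        back = lambda yv: t_pinv @ yv
    else:
        back = lambda yv: t.conj().T @ yv / tm.n_pixels

    trace: list[float] = []
    terminated_by = "max_iter"
    for _ in range(max_iter):
        y = t @ x
        y_constrained = amp * np.exp(1j * np.angle(y))
        x_new = back(y_constrained)
        c = field_correlation(x, x_new)
        trace.append(c)
        x = x_new
        if c > threshold:
            terminated_by = "threshold"
            break
    return GSResult(
        coefficients=x,
        n_iterations=len(trace),
        trace=np.asarray(trace),
        terminated_by=terminated_by,
    )


def speckle_residual(tm: TransmissionMatrix, intensity: SpeckleIntensity, x) -> float:
    """Speckle-plane amplitude residual ``||sqrt(max(I,0)) - |T x|||``.

    The quantity error reduction drives down; useful for monitoring.
    """
    i_vals = np.asarray(getattr(intensity, "values", intensity), dtype=float).ravel()
    coeffs = np.asarray(getattr(x, "coefficients", x), dtype=complex).ravel()
    amp = np.sqrt(np.clip(i_vals, 0.0, None))
    return float(np.linalg.norm(amp - np.abs(tm.entries @ coeffs)))
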