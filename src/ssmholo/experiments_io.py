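"""Noise-tolerance sweeps, file containers, and result export.

The gamma x SNR sweep reproduces, at desk scale, the simulation protocol
used to characterise retrieval robustness: for each cell a fresh random
TM and incident field are drawn, white Gaussian noise at the cell's SNR is
applied to both the TM (calibration noise) and the intensity snapshot
(detector noise), and the retrieved field is scored by its correlation
with the ground truth, repeated (default 20x) for error bars.

File containers: TMs and complex fields travel as HDF5 (real/imag pairs
with geometry attributes); intensity snapshots as float TIFF, with 16-bit
PNG export carrying its linear scale in a JSON sidecar (visualization
only); sweep results as tidy CSV plus a [0,1]-scaled heatmap PNG.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from ._rng import STAGE_SWEEP, substream
from .errors import FormatError, InvalidArgumentError, InvalidDataError, ResourceError
from .forward_model import (
    MAX_TM_BYTES,
    IncidentField,
    SpeckleIntensity,
    TransmissionMatrix,
    add_matrix_noise,
    capture_intensity,
    forward_propagate,
    generate_tm,
)
from .geometry import BasisGeometry
from .gs_refine import gs_refine
from .ssm_core import build_ssm, field_correlation, retrieve_field

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# gamma x SNR sweep
# --------------------------------------------------------------------------

@dataclass
class SweepConfig:
    """Protocol of a noise-tolerance sweep.

    ``snr_values`` entries of None (or the string "inf") mean noiseless;
    finite values are applied to BOTH the TM and the intensity.
    Desk-scale default n_modes=256 (the full-scale reference study used
    1,024; Z-build cost scales as M*N^2, so full scale is a config choice).
    """

    gamma_values: list
    snr_values: list
    n_modes: int = 256
    repetitions: int = 20
    with_gs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.gamma_values = [float(g) for g in self.gamma_values]
        self.snr_values = [
            None if s in (None, "inf", np.inf) else float(s) for s in self.snr_values
        ]
        if not self.gamma_values or not self.snr_values:
            raise InvalidArgumentError("gamma and snr lists must be nonempty")
        if any(g < 1 for g in self.gamma_values):
            raise InvalidArgumentError("all gamma values must be >= 1")
        if self.repetitions < 2:
            raise InvalidArgumentError("repetitions must be >= 2 (sd defined)")
        max_m = int(round(max(self.gamma_values) * self.n_modes))
        if max_m * self.n_modes * 16 > MAX_TM_BYTES:
            raise ResourceError(
                f"largest sweep cell needs a {max_m} x {self.n_modes} TM, "
                "over the memory budget"
            )


@dataclass
class SweepResult:
    """Per-repetition correlations and their aggregates."""

    records: pd.DataFrame  # columns: gamma, snr, method, rep, correlation
    config: SweepConfig

    @property
    def summary(self) -> pd.DataFrame:
        """Mean/sd per (gamma, snr, method) cell."""
        g = (
            self.records.groupby(["gamma", "snr", "method"], dropna=False)[
                "correlation"
            ]
            .agg(["mean", "std"])
            .reset_index()
        )
        return g.rename(columns={"std": "sd"})

    def cell_mean(self, gamma: float, snr: float | None, method: str = "ssm") -> float:
        r = self.records
        sel = (r["gamma"] == gamma) & (r["method"] == method)
        sel &= r["snr"].isna() if snr is None else (r["snr"] == snr)
        return float(r.loc[sel, "correlation"].mean())

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def summary_to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)


def run_single_retrieval(
    n_modes: int,
    gamma: float,
    snr: float | None,
    seed: int,
    with_gs: bool = False,
    gs_kwargs: dict | None = None,
):
    """One end-to-end synthetic retrieval; returns (corr_ssm, corr_gs|None).

    Ground-truth propagation uses the clean TM; retrieval uses the noisy
    one, mimicking an imperfect calibration.
    """
    tm = generate_tm(n_modes, gamma, seed=seed)
    rng = substream(seed, STAGE_SWEEP)
    x = IncidentField(
        (rng.standard_normal(n_modes) + 1j * rng.standard_normal(n_modes))
        / np.sqrt(2)
    )
    y = forward_propagate(tm, x)
    intensity = capture_intensity(y, snr=snr, seed=seed)
    tm_meas = add_matrix_noise(tm, snr, seed=seed) if snr is not None else tm
    result = retrieve_field(build_ssm(tm_meas, intensity))
    c_ssm = field_correlation(result.coefficients, x)
    c_gs = None
    if with_gs:
        gs = gs_refine(tm_meas, intensity, result.coefficients, **(gs_kwargs or {}))
        c_gs = field_correlation(gs.coefficients, x)
    return c_ssm, c_gs


def run_gamma_snr_sweep(config: SweepConfig) -> SweepResult:
    """Run the full noise-tolerance grid; reproducible per seed."""
    rows = []
    for gi, gamma in enumerate(config.gamma_values):
        for si, snr in enumerate(config.snr_values):
            for rep in range(config.repetitions):
                cell_seed = int(
                    substream(config.seed, gi, si, rep).integers(0, 2**31 - 1)
                )
                c_ssm, c_gs = run_single_retrieval(
                    config.n_modes, gamma, snr, cell_seed, with_gs=config.with_gs
                )
                rows.append((gamma, snr, "ssm", rep, c_ssm))
                if c_gs is not None:
                    rows.append((gamma, snr, "ssm+gs", rep, c_gs))
            logger.info(
                "sweep cell gamma=%g snr=%s done (%d reps)",
                gamma, snr, config.repetitions,
            )
    records = pd.DataFrame(
        rows, columns=["gamma", "snr", "method", "rep", "correlation"]
    )
    return SweepResult(records=records, config=config)


def plot_sweep_heatmap(result: SweepResult, path, method: str = "ssm") -> None:
    """Correlation heatmap over (gamma, snr); colour scale fixed to [0, 1]."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = result.summary
    sel = summary[summary["method"] == method].copy()
    sel["snr_label"] = sel["snr"].apply(lambda s: "inf" if pd.isna(s) else f"{s:g}")
    pivot = sel.pivot(index="snr_label", columns="gamma", values="mean")
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(pivot.values, vmin=0.0, vmax=1.0, aspect="auto", origin="lower")
    ax.set_xticks(range(len(pivot.columns)), [f"{g:g}" for g in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    ax.set_xlabel("gamma = M/N")
    ax.set_ylabel("SNR")
    ax.set_title(f"field correlation ({method})")
    fig.colorbar(im, ax=ax, label="correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --------------------------------------------------------------------------
# HDF5 containers
# --------------------------------------------------------------------------

def write_tm(path, tm: TransmissionMatrix) -> None:
    """Write a TM to an HDF5 container (datasets tm/real, tm/imag)."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("tm")
        grp.create_dataset("real", data=tm.entries.real, chunks=True)
        grp.create_dataset("imag", data=tm.entries.imag, chunks=True)
        f.attrs["n_modes"] = tm.n_modes
        f.attrs["n_pixels"] = tm.n_pixels
        f.attrs["gamma"] = tm.gamma
        f.attrs["seed"] = -1 if tm.seed is None else tm.seed
        f.attrs["column_normalized"] = tm.column_normalized
        f.attrs["provenance"] = tm.provenance
        if tm.geometry is not None:
            g = tm.geometry
            f.attrs["wavelength_nm"] = g.wavelength_nm
            f.attrs["basis_nx"] = g.nx
            f.attrs["basis_ny"] = g.ny
            f.attrs["fov_mm_x"] = g.fov_x
            f.attrs["fov_mm_y"] = g.fov_y


def read_tm(path) -> TransmissionMatrix:
    """Read a TM container; raises FormatError naming anything missing."""
    with h5py.File(path, "r") as f:
        for ds in ("tm/real", "tm/imag"):
            if ds not in f:
                raise FormatError(f"TM container {path} lacks dataset {ds!r}")
        for attr in ("n_modes", "n_pixels"):
            if attr not in f.attrs:
                raise FormatError(f"TM container {path} lacks attribute {attr!r}")
        entries = f["tm/real"][...] + 1j * f["tm/imag"][...]
        geometry = None
        if "basis_nx" in f.attrs:
            geometry = BasisGeometry(
                nx=int(f.attrs["basis_nx"]),
                ny=int(f.attrs["basis_ny"]),
                fov_x=float(f.attrs.get("fov_mm_x", 5.28)),
                fov_y=float(f.attrs.get("fov_mm_y", 4.00)),
                wavelength_nm=float(f.attrs.get("wavelength_nm", 633.0)),
            )
        if entries.shape != (int(f.attrs["n_pixels"]), int(f.attrs["n_modes"])):
            raise FormatError(
                f"TM container {path}: dataset shape {entries.shape} disagrees "
                f"with attributes (n_pixels, n_modes)"
            )
        seed = int(f.attrs.get("seed", -1))
        return TransmissionMatrix(
            entries=entries,
            geometry=geometry,
            column_normalized=bool(f.attrs.get("column_normalized", False)),
            provenance=str(f.attrs.get("provenance", "file")),
            seed=None if seed < 0 else seed,
        )


def write_incident(path, field: IncidentField) -> None:
    """Write an incident coefficient vector (+ geometry) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("coeff/real", data=field.coefficients.real)
        f.create_dataset("coeff/imag", data=field.coefficients.imag)
        f.attrs["label"] = field.label
        if field.geometry is not None:
            g = field.geometry
            f.attrs.update(
                basis_nx=g.nx, basis_ny=g.ny, fov_mm_x=g.fov_x, fov_mm_y=g.fov_y,
                wavelength_nm=g.wavelength_nm, grid_nx=g.grid_nx, grid_ny=g.grid_ny,
            )


def read_incident(path) -> IncidentField:
    with h5py.File(path, "r") as f:
        for ds in ("coeff/real", "coeff/imag"):
            if ds not in f:
                raise FormatError(f"field container {path} lacks dataset {ds!r}")
        coeffs = f["coeff/real"][...] + 1j * f["coeff/imag"][...]
        geometry = None
        if "basis_nx" in f.attrs:
            geometry = BasisGeometry(
                nx=int(f.attrs["basis_nx"]),
                ny=int(f.attrs["basis_ny"]),
                fov_x=float(f.attrs["fov_mm_x"]),
                fov_y=float(f.attrs["fov_mm_y"]),
                wavelength_nm=float(f.attrs["wavelength_nm"]),
                grid_nx=int(f.attrs["grid_nx"]),
                grid_ny=int(f.attrs["grid_ny"]),
            )
        return IncidentField(
            coefficients=coeffs, geometry=geometry, label=str(f.attrs.get("label", ""))
        )


# --------------------------------------------------------------------------
# intensity images
# --------------------------------------------------------------------------

def write_intensity(path, intensity: SpeckleIntensity, shape: tuple) -> None:
    """Write a snapshot as float32 TIFF on its 2-D camera grid."""
    import tifffile

    values = intensity.values
    if int(np.prod(shape)) != values.size:
        raise InvalidDataError(
            f"camera grid {shape} has {int(np.prod(shape))} pixels, "
            f"intensity has {values.size}"
        )
    tifffile.imwrite(path, values.reshape(shape).astype(np.float32))


def read_intensity(path, expected_pixels: int | None = None) -> SpeckleIntensity:
    """Read a float TIFF snapshot; validates pixel count against the TM."""
    import tifffile

    img = np.asarray(tifffile.imread(path), dtype=float)
    if expected_pixels is not None and img.size != expected_pixels:
        raise InvalidDataError(
            f"intensity image {path} has {img.size} pixels, "
            f"TM expects {expected_pixels}"
        )
    return SpeckleIntensity(values=img.ravel())


def write_intensity_png(path, intensity: SpeckleIntensity, shape: tuple) -> None:
    """16-bit PNG export for visualization; linear scale in a JSON sidecar."""
    import imageio.v3 as iio

    values = intensity.values.reshape(shape)
    vmin, vmax = float(values.min()), float(values.max())
    span = vmax - vmin if vmax > vmin else 1.0
    scaled = np.round((values - vmin) / span * 65535).astype(np.uint16)
    iio.imwrite(path, scaled)
    Path(str(path) + ".json").write_text(
        json.dumps({"vmin": vmin, "vmax": vmax, "scaling": "linear"})
    )


def read_intensity_png(path, expected_pixels: int | None = None) -> SpeckleIntensity:
    """Invert the documented linear PNG scaling using the JSON sidecar."""
    import imageio.v3 as iio

    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise FormatError(f"PNG intensity {path} lacks its scaling sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    img = np.asarray(iio.imread(path), dtype=float)
    if expected_pixels is not None and img.size != expected_pixels:
        raise InvalidDataError(
            f"intensity image {path} has {img.size} pixels, "
            f"TM expects {expected_pixels}"
        )
    values = img / 65535.0 * (meta["vmax"] - meta["vmin"]) + meta["vmin"]
    return SpeckleIntensity(values=values.ravel())


# --------------------------------------------------------------------------
# field images
# --------------------------------------------------------------------------

def write_field(path, field) -> None:
    """Write a FieldImage to HDF5 (field/real, field/imag + optics attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("field/real", data=field.values.real)
        f.create_dataset("field/imag", data=field.values.imag)
        f.attrs["pitch_x"] = field.pitch_x
        f.attrs["pitch_y"] = field.pitch_y
        f.attrs["wavelength_nm"] = field.wavelength_nm
        f.attrs["z_offset"] = field.z_offset


def read_field(path):
    from .optics_propagation import FieldImage

    with h5py.File(path, "r") as f:
        for ds in ("field/real", "field/imag"):
            if ds not in f:
                raise FormatError(f"field container {path} lacks dataset {ds!r}")
        values = f["field/real"][...] + 1j * f["field/imag"][...]
        return FieldImage(
            values=values,
            pitch_x=float(f.attrs["pitch_x"]),
            pitch_y=float(f.attrs["pitch_y"]),
            wavelength_nm=float(f.attrs["wavelength_nm"]),
            z_offset=float(f.attrs.get("z_offset", 0.0)),
        )


def write_focal_stack(path, stack, z_values) -> None:
    """Amplitude focal stack as multi-page float TIFF + z metadata sidecar."""
    import tifffile

    amps = np.stack([np.abs(f.values).astype(np.float32) for f in stack])
    tifffile.imwrite(path, amps, photometric="minisblack")
    Path(str(path) + ".json").write_text(
        json.dumps({"z_mm": [float(z) for z in z_values]})
    )
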