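"""Synthetic nanoporous-gold (NPG) substrate morphologies.

NPG is made by dealloying a Au-Ag alloy; the resulting bicontinuous
pore/ligament structure is morphologically equivalent to a late-stage
spinodal decomposition pattern.  This module generates such patterns by
evolving the Cahn-Hilliard equation

    dc/dt = M * laplacian( f'(c) - kappa * laplacian(c) )

for a conserved gold fraction c(x, y) with the double-well bulk free
energy f(c) = c^2 (1-c)^2, on a periodic square, using the standard
semi-implicit Fourier-spectral scheme (explicit nonlinear term, implicit
biharmonic term).  The dimensionless field is calibrated to a physical
pore size afterwards: the characteristic length of the final pattern is
measured from the radially averaged structure factor and the pixel size
is chosen so that this length equals the requested pore size in nm.
Larger-pore substrates (50-150 nm) are produced by uniformly enlarging
the 20 nm parent field, mirroring how a single dealloyed morphology
coarsens self-similarly under heat treatment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SubstrateField",
    "CahnHilliardParams",
    "evolve_cahn_hilliard",
    "generate_npg_field",
    "rescale_field",
    "make_flat_gold",
    "characteristic_length",
    "binarize",
    "save_field",
    "load_field",
]


class SubstrateError(ValueError):
    """Invalid substrate field or parameters."""


class DegenerateFieldError(SubstrateError):
    """Operation undefined on a structureless (zero-variance) field."""


class ConvergenceError(SubstrateError):
    """Cahn-Hilliard evolution failed to reach the requested state."""


@dataclass(frozen=True)
class SubstrateField:
    """A 2-D gold-concentration field modelling an NPG or flat-gold surface.

    Attributes
    ----------
    concentration
        2-D array of gold fraction per pixel, clipped to [0, 1] at output.
    pixel_size
        Physical size of one pixel in nm.
    nominal_pore_nm
        Declared pore-size label in nm; ``None`` for flat gold.
    kind
        ``"npg"`` or ``"flat"``.
    """

    concentration: np.ndarray
    pixel_size: float = 1.0
    nominal_pore_nm: float | None = None
    kind: str = "npg"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration, dtype=np.float64)
        object.__setattr__(self, "concentration", c)
        if c.ndim != 2:
            raise SubstrateError(f"concentration must be 2-D, got shape {c.shape}")
        if self.pixel_size <= 0:
            raise SubstrateError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.kind not in ("npg", "flat"):
            raise SubstrateError(f"kind must be 'npg' or 'flat', got {self.kind!r}")

    @property
    def extent_nm(self) -> float:
        """Physical side length of the field in nm."""
        return self.concentration.shape[0] * self.pixel_size

    def clipped(self) -> "SubstrateField":
        """Copy with concentration clipped to [0, 1]."""
        return replace(self, concentration=np.clip(self.concentration, 0.0, 1.0))


@dataclass(frozen=True)
class CahnHilliardParams:
    """Dimensionless coefficients of the Cahn-Hilliard evolution.

    ``mean_composition`` is the conserved gold fraction (0.5 by default:
    a symmetric quench yields the bicontinuous morphology in which
    ligament and pore widths track each other, as observed for NPG).
    ``interface_coefficient`` (kappa) sets the diffuse interface width,
    ``dt_ch`` the dimensionless time step of the semi-implicit scheme.
    """

    mean_composition: float = 0.5
    mobility: float = 1.0
    interface_coefficient: float = 1.0
    dt_ch: float = 0.5
    noise_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.mean_composition < 1.0):
            raise SubstrateError(
                f"mean_composition must lie in (0,1), got {self.mean_composition}"
            )
        for name in ("mobility", "interface_coefficient", "dt_ch"):
            if getattr(self, name) <= 0:
                raise SubstrateError(f"{name} must be positive, got {getattr(self, name)}")


def _dfdc(c: np.ndarray) -> np.ndarray:
    # f(c) = c^2 (1-c)^2  ->  f'(c) = 2c(1-c)(1-2c)
    return 2.0 * c * (1.0 - c) * (1.0 - 2.0 * c)


def free_energy(c: np.ndarray, kappa: float) -> float:
    """Discrete Ginzburg-Landau free energy (bulk + gradient), per field."""
    bulk = np.sum(c * c * (1.0 - c) ** 2)
    gx = np.gradient(c, axis=0, edge_order=1)
    gy = np.gradient(c, axis=1, edge_order=1)
    return float(bulk + 0.5 * kappa * np.sum(gx * gx + gy * gy))


def evolve_cahn_hilliard(
    initial_field: SubstrateField, params: CahnHilliardParams, n_steps: int
) -> SubstrateField:
    """Evolve a field by ``n_steps`` of semi-implicit spectral Cahn-Hilliard.

    The spatial mean of c is conserved exactly (the k=0 mode is untouched)
    and the pattern coarsens toward the late-stage bicontinuous morphology.
    Raises :class:`SubstrateError` for non-square or too-small fields, and a
    numerical-stability error naming ``dt_ch`` if the field diverges.
    """
    c = np.array(initial_field.concentration, dtype=np.float64)
    n, m = c.shape
    if n != m or n < 64:
        raise SubstrateError(
            f"field must be square with side >= 64 pixels, got {c.shape}"
        )
    k = 2.0 * np.pi * np.fft.fftfreq(n)  # unit pixel spacing
    k2 = k[:, None] ** 2 + k[None, :] ** 2
    M, kappa, dt = params.mobility, params.interface_coefficient, params.dt_ch
    denom = 1.0 + dt * M * kappa * k2 * k2
    c_hat = np.fft.fft2(c)
    for _ in range(int(n_steps)):
        mu_hat = np.fft.fft2(_dfdc(np.real(np.fft.ifft2(c_hat))))
        c_hat = (c_hat - dt * M * k2 * mu_hat) / denom
    c = np.real(np.fft.ifft2(c_hat))
    if np.any(np.abs(c - 0.5) > 10.0):
        raise SubstrateError(
            f"Cahn-Hilliard evolution diverged; reduce dt_ch (currently {dt})"
        )
    return replace(initial_field, concentration=c)


def characteristic_length(field: SubstrateField) -> float:
    """Dominant pore-scale length of a phase-separated field, in nm.

    Computed as half the dominant wavelength 2*pi/k1 of the pattern, where
    k1 = sum(k S(k)) / sum(S(k)) is the first moment of the radially
    averaged structure factor S(k) = |FFT(c - <c>)|^2.  The half-wavelength
    convention reports the width of one phase domain (one pore or one
    ligament), not the pore+ligament repeat.  Deterministic for a fixed
    field; raises :class:`DegenerateFieldError` on a uniform field.
    """
    c = field.concentration
    dc = c - c.mean()
    if not np.any(np.abs(dc) > 1e-12):
        raise DegenerateFieldError("characteristic length undefined for a uniform field")
    n, m = c.shape
    S = np.abs(np.fft.fft2(dc)) ** 2
    kx = 2.0 * np.pi * np.fft.fftfreq(n)
    ky = 2.0 * np.pi * np.fft.fftfreq(m)
    kmag = np.sqrt(kx[:, None] ** 2 + ky[None, :] ** 2)
    mask = kmag > 0
    k1 = float(np.sum(kmag[mask] * S[mask]) / np.sum(S[mask]))
    wavelength_px = 2.0 * np.pi / k1
    return 0.5 * wavelength_px * field.pixel_size


def binarize(field: SubstrateField, threshold: float = 0.5) -> np.ndarray:
    """Boolean solid-gold mask (c >= threshold); 0.5 suits the symmetric well."""
    return field.concentration >= threshold


def _smooth_binary(mask: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    return np.clip(gaussian_filter(mask.astype(np.float64), sigma, mode="wrap"), 0.0, 1.0)


def generate_npg_field(
    seed: int,
    target_length_nm: float = 20.0,
    params: CahnHilliardParams | None = None,
    size_px: int = 512,
    min_feature_px: float = 8.0,
    max_steps: int = 40_000,
    batch_steps: int = 500,
) -> SubstrateField:
    """Generate an NPG substrate field with a given pore size.

    A random near-uniform field is evolved under Cahn-Hilliard dynamics
    until its characteristic length reaches ``min_feature_px`` pixels (so
    pores are well resolved), then binarized at 0.5, lightly smoothed, and
    calibrated: the pixel size is fixed so the measured characteristic
    length of the output equals ``target_length_nm`` exactly.  Deterministic
    for a fixed seed.
    """
    if target_length_nm <= 0:
        raise SubstrateError(f"target_length_nm must be positive, got {target_length_nm}")
    params = params or CahnHilliardParams()
    rng = np.random.default_rng(seed)
    c0 = params.mean_composition + params.noise_amplitude * (
        rng.random((size_px, size_px)) - 0.5
    )
    fld = SubstrateField(c0, pixel_size=1.0, kind="npg")
    achieved = 0.0
    for _ in range(max(1, max_steps // batch_steps)):
        fld = evolve_cahn_hilliard(fld, params, batch_steps)
        achieved = characteristic_length(fld)
        if achieved >= min_feature_px:
            break
    else:
        raise ConvergenceError(
            f"coarsening stalled at {achieved:.2f} px before reaching "
            f"{min_feature_px} px within {max_steps} steps"
        )
    smooth = _smooth_binary(binarize(fld), sigma=1.0)
    out = SubstrateField(smooth, pixel_size=1.0, kind="npg")
    length_px = characteristic_length(out)
    pixel_size = target_length_nm / length_px
    return SubstrateField(
        smooth, pixel_size=pixel_size, nominal_pore_nm=target_length_nm, kind="npg"
    )


def rescale_field(field: SubstrateField, factor: float) -> SubstrateField:
    """Uniformly enlarge a field by ``factor``: pixel size and nominal pore
    size are multiplied, pixel values are untouched."""
    if factor <= 0:
        raise SubstrateError(f"rescale factor must be positive, got {factor}")
    nominal = None if field.nominal_pore_nm is None else field.nominal_pore_nm * factor
    return replace(
        field, pixel_size=field.pixel_size * factor, nominal_pore_nm=nominal
    )


def make_flat_gold(size_px: int = 100, pixel_size: float = 60.0) -> SubstrateField:
    """Flat-gold control: a uniform field of pure gold (c = 1 everywhere)."""
    if size_px < 1:
        raise SubstrateError(f"size_px must be >= 1, got {size_px}")
    return SubstrateField(
        np.ones((size_px, size_px)), pixel_size=pixel_size, kind="flat"
    )


# ---------------------------------------------------------------------------
# serialization: CSV matrix + JSON sidecar (+ optional 8-bit PNG)

def save_field(field: SubstrateField, out_dir: str | Path, name: str = "substrate",
               png: bool = True) -> dict[str, str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clipped = field.clipped()
    csv_path = out / f"{name}.csv"
    np.savetxt(csv_path, clipped.concentration, delimiter=",", fmt="%.6f")
    meta = {
        "pixel_size_nm": field.pixel_size,
        "nominal_pore_nm": field.nominal_pore_nm,
        "kind": field.kind,
        "shape": list(field.concentration.shape),
    }
    meta_path = out / f"{name}.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    files = {"csv": str(csv_path), "meta": str(meta_path)}
    if png:
        import imageio.v3 as iio

        png_path = out / f"{name}.png"
        iio.imwrite(png_path, (clipped.concentration * 255).astype(np.uint8))
        files["png"] = str(png_path)
    return files


def load_field(out_dir: str | Path, name: str = "substrate") -> SubstrateField:
    out = Path(out_dir)
    conc = np.loadtxt(out / f"{name}.csv", delimiter=",")
    meta = json.loads((out / f"{name}.json").read_text())
    return SubstrateField(
        conc,
        pixel_size=meta["pixel_size_nm"],
        nominal_pore_nm=meta["nominal_pore_nm"],
        kind=meta["kind"],
    )
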