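"""Vector-field propagation through anisotropic, dynamically drifting media.

Two interchangeable realizations of the same linear operator contract:

* ``DenseVTM`` — the vector transmission matrix written out explicitly: four
  complex N x N blocks (N = H*W flattened modes) mapping the two input
  polarization components to the two output components,

      E_out,x = T11 E_in,x + T12 E_in,y
      E_out,y = T21 E_in,x + T22 E_in,y.

  Exact and convenient for small grids; a 256x256 grid would need ~17 GB per
  block, so dense mode is capped (default 48x48) and large grids use the
  layered mode.

* ``LayeredMedium`` — a stack of per-pixel random birefringent Jones screens
  (unitary 2x2 retarders with random fast axis, retardance scaled by the
  anisotropy coupling, and a random scalar phase) separated by unitary
  angular-spectrum free-space propagation.  Linear in the input by
  construction; `effective_vtm` reconstructs its explicit dense matrix on
  small grids, tying the two representations together.

Anisotropy is a single coupling knob ``kappa`` in [0, 1]: kappa = 0 is an
isotropic medium (ground glass) whose cross-polarization blocks vanish and
whose polarization components propagate independently; kappa > 0 couples
them, as in biological tissue.  Temporal drift (tissue deformation, drying)
is an autoregressive sqrt(1-eps)/sqrt(eps) mixture refreshing the random
content of the medium, so repeated steps compound speckle decorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional, Union

import numpy as np
from scipy import ndimage

from ._rng import rng_for, child_seed
from .fields import JonesField

__all__ = [
    "DenseVTM",
    "LayeredMedium",
    "SpeckleRecord",
    "sample_dense_vtm",
    "sample_layered_medium",
    "propagate",
    "effective_vtm",
    "drift_medium",
    "record_speckle",
    "DENSE_GRID_CAP",
    "THICKNESS_LADDER",
]

#: Largest grid side for which the dense matrix is reasonable to hold in RAM.
DENSE_GRID_CAP = 48

#: Four-level difficulty ladder standing in for tissue slices of increasing
#: thickness.  Only the monotone degradation trend is meaningful: thicker
#: means less ballistic light, lower transmissivity, more layers, and a finer
#: speckle grain relative to the camera pixel (speckle_blur, px) — unresolved
#: grain is averaged in the intensity domain, irreversibly reducing contrast.
THICKNESS_LADDER = {
    "0.5mm": dict(ballistic_fraction=0.45, transmissivity=0.90, n_layers=2, speckle_blur=0.0),
    "1.0mm": dict(ballistic_fraction=0.30, transmissivity=0.75, n_layers=4, speckle_blur=0.7),
    "1.5mm": dict(ballistic_fraction=0.12, transmissivity=0.55, n_layers=6, speckle_blur=1.4),
    "2.0mm": dict(ballistic_fraction=0.04, transmissivity=0.40, n_layers=8, speckle_blur=2.1),
}

_BLOCKS = ("xx", "xy", "yx", "yy")


# ---------------------------------------------------------------------------
# dense vector transmission matrix
# ---------------------------------------------------------------------------

@dataclass
class DenseVTM:
    """Explicit 2x2-block transmission operator on flattened grid modes.

    The diffuse content of each block is i.i.d. circular complex Gaussian;
    a ballistic (unscattered) term sqrt(eta*beta) * identity is added to the
    co-polarized blocks.  Cross-polarized blocks are identically zero when
    ``coupling == 0``.
    """

    grid: tuple[int, int]
    coupling: float  # kappa
    ballistic_fraction: float  # beta
    transmissivity: float  # eta
    seed: int
    diffuse: dict  # block name -> (N, N) complex array or None (zero block)
    drift_step: int = 0

    @property
    def n_modes(self) -> int:
        return self.grid[0] * self.grid[1]

    def _block(self, name: str) -> np.ndarray:
        d = self.diffuse[name]
        full = np.zeros((self.n_modes, self.n_modes), dtype=np.complex128) if d is None else d.copy()
        if name in ("xx", "yy"):
            b = np.sqrt(self.transmissivity * self.ballistic_fraction)
            full[np.diag_indices(self.n_modes)] += b
        return full

    @property
    def t11(self) -> np.ndarray:
        return self._block("xx")

    @property
    def t12(self) -> np.ndarray:
        return self._block("xy")

    @property
    def t21(self) -> np.ndarray:
        return self._block("yx")

    @property
    def t22(self) -> np.ndarray:
        return self._block("yy")


def _diffuse_blocks(
    n: int, coupling: float, ballistic_fraction: float, transmissivity: float, seed: int
) -> dict:
    var_co = transmissivity * (1 - coupling) * (1 - ballistic_fraction) / n
    var_cross = transmissivity * coupling * (1 - ballistic_fraction) / n
    out = {}
    for name in _BLOCKS:
        var = var_co if name in ("xx", "yy") else var_cross
        if var == 0.0:
            out[name] = None
            continue
        rng = rng_for(seed, "vtm", name)
        re = rng.standard_normal((n, n))
        im = rng.standard_normal((n, n))
        out[name] = np.sqrt(var / 2) * (re + 1j * im)
    return out


def sample_dense_vtm(
    grid: Union[int, tuple[int, int]],
    coupling: float = 0.5,
    ballistic_fraction: float = 0.3,
    transmissivity: float = 0.9,
    seed: int = 0,
    grid_cap: int = DENSE_GRID_CAP,
) -> DenseVTM:
    """Draw a random dense VTM; deterministic given seed.

    Per-entry variances are chosen so the ensemble-expected output power is
    ``transmissivity`` times the input power, with a fraction
    ``ballistic_fraction`` of the transmitted power passing unscattered and a
    fraction ``coupling`` of the diffuse power routed through the
    cross-polarization blocks.
    """
    H, W = (grid, grid) if isinstance(grid, int) else grid
    if max(H, W) > grid_cap:
        raise ValueError(
            f"grid {H}x{W} exceeds the dense-mode cap ({grid_cap}); use sample_layered_medium"
        )
    for name, v in [("coupling", coupling), ("ballistic_fraction", ballistic_fraction)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if not 0.0 < transmissivity <= 1.0:
        raise ValueError("transmissivity must lie in (0, 1]")
    diffuse = _diffuse_blocks(H * W, coupling, ballistic_fraction, transmissivity, seed)
    return DenseVTM(
        grid=(H, W),
        coupling=coupling,
        ballistic_fraction=ballistic_fraction,
        transmissivity=transmissivity,
        seed=seed,
        diffuse=diffuse,
    )


# ---------------------------------------------------------------------------
# layered Jones-screen medium
# ---------------------------------------------------------------------------

#: Simulation wavelength in pixel units.  Below sqrt(2) px every discrete
#: spatial frequency is propagating, making the angular-spectrum step exactly
#: unitary; larger values activate evanescent clipping.
DEFAULT_WAVELENGTH_PX = 1.4

#: Std-dev of the per-layer scalar phase (radians) and the retardance scale
#: reached at full coupling; correlation length of the screen textures (px).
SCREEN_PHASE_STD = 1.0
SCREEN_RETARDANCE_SCALE = np.pi / 2
SCREEN_CORR_LENGTH = 3.0


@dataclass
class LayeredMedium:
    """Stack of per-pixel unitary Jones screens with free-space gaps.

    Each screen derives from three smoothed standard-normal textures
    (z_phase, z_ret, z_axis): scalar phase ``SCREEN_PHASE_STD * z_phase``,
    retardance ``coupling * SCREEN_RETARDANCE_SCALE * z_ret``, fast-axis angle
    ``pi * z_axis``.  Drift evolves the textures by an Ornstein-Uhlenbeck
    step, preserving their stationary distribution.
    """

    grid: tuple[int, int]
    n_layers: int
    coupling: float
    layer_spacing: float  # gap between screens, pixel units
    seed: int
    textures: list  # per layer: dict(z_phase, z_ret, z_axis) of (H, W) floats
    wavelength: float = DEFAULT_WAVELENGTH_PX
    drift_step: int = 0

    def screen(self, i: int) -> np.ndarray:
        """(H, W, 2, 2) complex unitary Jones matrix of layer i."""
        tx = self.textures[i]
        psi = SCREEN_PHASE_STD * tx["z_phase"]
        phi = self.coupling * SCREEN_RETARDANCE_SCALE * tx["z_ret"]
        theta = np.pi * tx["z_axis"]
        c, s = np.cos(theta), np.sin(theta)
        ep, em = np.exp(1j * phi / 2), np.exp(-1j * phi / 2)
        j = np.empty(self.grid + (2, 2), dtype=np.complex128)
        j[..., 0, 0] = c**2 * ep + s**2 * em
        j[..., 0, 1] = c * s * (ep - em)
        j[..., 1, 0] = j[..., 0, 1]
        j[..., 1, 1] = s**2 * ep + c**2 * em
        return j * np.exp(1j * psi)[..., None, None]


def _smooth_unit_texture(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    z = ndimage.gaussian_filter(rng.standard_normal(shape), SCREEN_CORR_LENGTH, mode="wrap")
    return z / z.std()


def sample_layered_medium(
    grid: Union[int, tuple[int, int]],
    n_layers: int = 4,
    coupling: float = 0.5,
    layer_spacing: float = 8.0,
    seed: int = 0,
    wavelength: float = DEFAULT_WAVELENGTH_PX,
) -> LayeredMedium:
    """Draw a random layered medium; n_layers is the thickness proxy."""
    H, W = (grid, grid) if isinstance(grid, int) else grid
    if n_layers < 0:
        raise ValueError("n_layers must be >= 0")
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    textures = []
    for i in range(n_layers):
        rng = rng_for(seed, "layer", i)
        textures.append(
            {k: _smooth_unit_texture(rng, (H, W)) for k in ("z_phase", "z_ret", "z_axis")}
        )
    return LayeredMedium(
        grid=(H, W),
        n_layers=n_layers,
        coupling=coupling,
        layer_spacing=layer_spacing,
        seed=seed,
        textures=textures,
        wavelength=wavelength,
    )


def _angular_spectrum_step(ex: np.ndarray, ey: np.ndarray, dz: float, wavelength: float):
    """Unitary free-space propagation over dz (px); evanescent modes zeroed."""
    H, W = ex.shape
    fy = np.fft.fftfreq(H)[:, None]
    fx = np.fft.fftfreq(W)[None, :]
    f2 = fx**2 + fy**2
    inv_l2 = 1.0 / wavelength**2
    prop = f2 <= inv_l2
    kz = np.sqrt(np.maximum(inv_l2 - f2, 0.0))
    kernel = np.where(prop, np.exp(2j * np.pi * dz * kz), 0.0)
    out = []
    for comp in (ex, ey):
        out.append(np.fft.ifft2(np.fft.fft2(comp) * kernel))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def propagate(field: JonesField, medium: Union[DenseVTM, LayeredMedium]) -> JonesField:
    """Apply the medium's linear operator to a Jones field."""
    if field.shape != medium.grid:
        raise ValueError(f"field grid {field.shape} does not match medium grid {medium.grid}")
    if isinstance(medium, DenseVTM):
        return _propagate_dense(field, medium)
    return _propagate_layered(field, medium)


def _propagate_dense(field: JonesField, m: DenseVTM) -> JonesField:
    ex = field.ex.ravel()
    ey = field.ey.ravel()
    b = np.sqrt(m.transmissivity * m.ballistic_fraction)
    ox = b * ex
    oy = b * ey
    for name, src, into in (("xx", ex, "x"), ("xy", ey, "x"), ("yx", ex, "y"), ("yy", ey, "y")):
        d = m.diffuse[name]
        if d is None:
            continue
        contrib = d @ src
        if into == "x":
            ox = ox + contrib
        else:
            oy = oy + contrib
    H, W = m.grid
    return JonesField(ox.reshape(H, W), oy.reshape(H, W))


def _propagate_layered(field: JonesField, m: LayeredMedium) -> JonesField:
    ex, ey = field.ex.copy(), field.ey.copy()
    for i in range(m.n_layers):
        j = m.screen(i)
        ex, ey = (
            j[..., 0, 0] * ex + j[..., 0, 1] * ey,
            j[..., 1, 0] * ex + j[..., 1, 1] * ey,
        )
        if m.layer_spacing > 0:
            ex, ey = _angular_spectrum_step(ex, ey, m.layer_spacing, m.wavelength)
    return JonesField(ex, ey)


def effective_vtm(medium: LayeredMedium, grid_cap: int = 24) -> DenseVTM:
    """Explicit dense matrix of a layered medium, built column-by-column.

    Propagates the 2N canonical basis fields; the result reproduces
    `propagate` on arbitrary inputs, which makes it the oracle connecting the
    two medium representations.  Only sensible on small grids.
    """
    H, W = medium.grid
    if max(H, W) > grid_cap:
        raise ValueError(f"grid {H}x{W} too large for dense reconstruction (cap {grid_cap})")
    n = H * W
    blocks = {name: np.zeros((n, n), dtype=np.complex128) for name in _BLOCKS}
    zero = np.zeros((H, W), dtype=np.complex128)
    for k in range(n):
        basis = zero.copy().ravel()
        basis[k] = 1.0
        basis = basis.reshape(H, W)
        out = propagate(JonesField(basis, zero), medium)
        blocks["xx"][:, k] = out.ex.ravel()
        blocks["yx"][:, k] = out.ey.ravel()
        out = propagate(JonesField(zero, basis), medium)
        blocks["xy"][:, k] = out.ex.ravel()
        blocks["yy"][:, k] = out.ey.ravel()
    return DenseVTM(
        grid=(H, W),
        coupling=medium.coupling,
        ballistic_fraction=0.0,
        transmissivity=1.0,
        seed=medium.seed,
        diffuse=blocks,
        drift_step=medium.drift_step,
    )


# ---------------------------------------------------------------------------
# temporal drift
# ---------------------------------------------------------------------------

def drift_medium(
    medium: Union[DenseVTM, LayeredMedium], rate: float, seed: Optional[int] = None
):
    """One autoregressive drift step: M <- sqrt(1-rate) M + sqrt(rate) M_fresh.

    rate = 0 returns the medium unchanged; rate = 1 yields a statistically
    independent medium; intermediate rates compound decorrelation when
    applied repeatedly.  The stationary distribution of the random content is
    preserved exactly.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if rate == 0.0:
        return medium
    step = medium.drift_step + 1
    base = medium.seed if seed is None else seed
    if isinstance(medium, DenseVTM):
        fresh = _diffuse_blocks(
            medium.n_modes,
            medium.coupling,
            medium.ballistic_fraction,
            medium.transmissivity,
            child_seed(base, "drift", step),
        )
        mixed = {
            name: None
            if medium.diffuse[name] is None
            else np.sqrt(1 - rate) * medium.diffuse[name] + np.sqrt(rate) * fresh[name]
            for name in _BLOCKS
        }
        return replace(medium, diffuse=mixed, drift_step=step)
    new_textures = []
    for i, tx in enumerate(medium.textures):
        rng = rng_for(child_seed(base, "drift", step), "layer", i)
        new_textures.append(
            {
                k: np.sqrt(1 - rate) * tx[k]
                + np.sqrt(rate) * _smooth_unit_texture(rng, medium.grid)
                for k in tx
            }
        )
    return replace(medium, textures=new_textures, drift_step=step)


# ---------------------------------------------------------------------------
# camera
# ---------------------------------------------------------------------------

@dataclass
class SpeckleRecord:
    """One camera frame plus the provenance needed to regenerate it."""

    intensity: np.ndarray  # (H, W) float in [0, 1]
    medium_seed: int = 0
    drift_step: int = 0
    encoding_mode: Literal["single", "dual"] = "single"
    polarization: Literal["vector", "scalar"] = "vector"


def record_speckle(
    field: JonesField,
    noise: Optional[float] = None,
    read_noise: float = 0.0,
    speckle_blur: float = 0.0,
    quantize: Optional[int] = None,
    seed: int = 0,
    medium_seed: int = 0,
    drift_step: int = 0,
    encoding_mode: str = "single",
    polarization: str = "vector",
) -> SpeckleRecord:
    """Camera model: total intensity, optional shot/read noise, quantization.

    ``speckle_blur`` is the std-dev (px) of intensity-domain averaging,
    modeling speckle grain finer than the camera pixel: averaging unresolved
    grains reduces contrast incoherently and cannot be undone.  ``noise`` is
    the photon budget — the expected photon count at unit intensity (Poisson
    shot noise; None disables).  ``read_noise`` is the sensor's additive
    noise floor, std-dev in photons at the same scale (only applied when a
    photon budget is set).  Because these act on the *raw* intensity, weakly
    transmitting media yield noisier normalized frames — the mechanism by
    which thicker samples lose information.  ``quantize`` is the ADC bit
    depth (None disables).  The frame is max-normalized to [0, 1] afterwards,
    matching per-image normalization of learning pipelines.
    """
    intensity = field.intensity
    if speckle_blur > 0:
        intensity = ndimage.gaussian_filter(intensity, speckle_blur, mode="wrap")
    if noise is not None:
        if noise <= 0:
            raise ValueError("noise scale must be positive")
        rng = rng_for(seed, "shot", medium_seed, drift_step)
        counts = rng.poisson(np.clip(intensity, 0, None) * noise).astype(np.float64)
        if read_noise > 0:
            counts = counts + read_noise * rng.standard_normal(counts.shape)
        intensity = np.clip(counts, 0, None) / noise
    mx = intensity.max()
    if mx > 0:
        intensity = intensity / mx
    if quantize is not None:
        levels = 2**int(quantize) - 1
        intensity = np.round(intensity * levels) / levels
        mx = intensity.max()
        if mx > 0:
            intensity = intensity / mx
    return SpeckleRecord(
        intensity=intensity,
        medium_seed=medium_seed,
        drift_step=drift_step,
        encoding_mode=encoding_mode,
        polarization=polarization,
    )
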