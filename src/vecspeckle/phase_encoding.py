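"""Phase targets, two-dimensional hologram encoding, and ideal demodulation.

One or two grayscale glyphs are mapped to phase maps ``delta_k = phase_scale *
glyph_k`` (radians) and written onto a two-carrier transmittance hologram

    t(x, y) = 1 + (gamma/2) cos(2 pi f0 x + delta1(x, y))
                + (gamma/2) cos(2 pi f0 y + delta2(x, y)),

with x-, y-carriers at spatial frequency ``f0`` (cycles per grid width).  The
two phase maps ride on orthogonal carriers and can be recovered independently
by selecting the +1 diffraction order on each axis — here modeled as ideal
Fourier filtering (`demodulate_hologram`), the numerical analogue of a
dual-aperture spatial filter in a 4f system.

`synthesize_input_field` turns the recovered phases into a Jones field: in
vector mode the two orthogonal basis components (horizontal/vertical linear,
or left/right circular) carry exp(i*delta1) and exp(i*delta2); in scalar mode
a single polarization carries exp(i*delta1) alone.

Coordinate convention (shared package-wide): pixel-centered lattice, origin at
the top-left pixel, x = column/W, y = row/H; spatial frequencies in cycles per
full grid width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import ndimage

from ._rng import rng_for

__all__ = [
    "PhaseTarget",
    "Hologram",
    "generate_glyph",
    "encode_hologram",
    "demodulate_hologram",
    "synthesize_input_field",
    "load_image",
    "save_image",
]

GLYPH_STYLES = ("digit-like", "blobs", "rings")

#: Default glyph-to-phase scaling (radians per unit gray level).  pi gives
#: maximal interferometric contrast for binary strokes while avoiding the
#: 2*pi == 0 wrap that would erase a binary glyph.
DEFAULT_PHASE_SCALE = np.pi


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PhaseTarget:
    """One or two normalized glyphs and the phase maps they induce.

    ``mode="single"`` means both polarization components carry the same phase
    image (delta1 == delta2 everywhere); ``mode="dual"`` means the components
    carry two independently drawn images.
    """

    glyph1: np.ndarray
    glyph2: Optional[np.ndarray] = None
    phase_scale: float = DEFAULT_PHASE_SCALE
    mode: Literal["single", "dual"] = "single"

    def __post_init__(self) -> None:
        self.glyph1 = np.asarray(self.glyph1, dtype=np.float64)
        if not (0.0 < self.phase_scale <= 2 * np.pi):
            raise ValueError("phase_scale must lie in (0, 2*pi]")
        if self.glyph1.min() < 0 or self.glyph1.max() > 1:
            raise ValueError("glyph1 must be normalized to [0, 1]")
        if self.mode == "dual":
            if self.glyph2 is None:
                raise ValueError("dual mode requires glyph2")
            self.glyph2 = np.asarray(self.glyph2, dtype=np.float64)
            if self.glyph2.shape != self.glyph1.shape:
                raise ValueError("glyph2 shape must match glyph1")
            if self.glyph2.min() < 0 or self.glyph2.max() > 1:
                raise ValueError("glyph2 must be normalized to [0, 1]")
        elif self.mode == "single":
            self.glyph2 = None
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def delta1(self) -> np.ndarray:
        """Phase map on the first (x) polarization component, radians."""
        return self.phase_scale * self.glyph1

    @property
    def delta2(self) -> np.ndarray:
        """Phase map on the second (y) polarization component, radians."""
        g2 = self.glyph1 if self.mode == "single" else self.glyph2
        return self.phase_scale * g2

    @property
    def shape(self) -> tuple[int, int]:
        return self.glyph1.shape

    def labels(self) -> np.ndarray:
        """Training labels: (1, H, W) in single mode, (2, H, W) in dual mode."""
        if self.mode == "single":
            return self.glyph1[None]
        return np.stack([self.glyph1, self.glyph2])


@dataclass
class Hologram:
    """Real transmittance map with its carrier frequency and modulation depth."""

    transmittance: np.ndarray
    carrier_frequency: float  # f0, cycles per grid width
    modulation_depth: float  # gamma

    def __post_init__(self) -> None:
        self.transmittance = np.asarray(self.transmittance, dtype=np.float64)
        g = self.modulation_depth
        t = self.transmittance
        if t.min() < 1 - g - 1e-9 or t.max() > 1 + g + 1e-9:
            raise ValueError("transmittance violates the 1 +/- gamma bounds")


# ---------------------------------------------------------------------------
# glyph generation
# ---------------------------------------------------------------------------

def _paint_points(img: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> None:
    H, W = img.shape
    r = np.clip(np.round(rows).astype(int), 0, H - 1)
    c = np.clip(np.round(cols).astype(int), 0, W - 1)
    np.add.at(img, (r, c), 1.0)


def _stroke_glyph(size: int, rng: np.random.Generator) -> np.ndarray:
    # piecewise-quadratic strokes at 28x28 logical resolution, then upsampled
    base = 28
    img = np.zeros((base, base))
    n_strokes = rng.integers(2, 5)
    for _ in range(n_strokes):
        pts = rng.uniform(4, base - 4, size=(3, 2))
        t = np.linspace(0, 1, 200)[:, None]
        # quadratic Bezier through the three control points
        curve = ((1 - t) ** 2) * pts[0] + 2 * t * (1 - t) * pts[1] + t**2 * pts[2]
        _paint_points(img, curve[:, 0], curve[:, 1])
    img = ndimage.gaussian_filter(img, sigma=0.9)
    img = np.clip(img / (np.quantile(img[img > 0], 0.75) + 1e-12), 0, 1)
    return ndimage.zoom(img, size / base, order=1)


def _blob_glyph(size: int, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal((size, size))
    sm = ndimage.gaussian_filter(noise, sigma=size / 10)
    thr = np.quantile(sm, 0.82)
    binary = (sm > thr).astype(float)
    return ndimage.gaussian_filter(binary, sigma=size / 64 + 0.5)


def _ring_glyph(size: int, rng: np.random.Generator) -> np.ndarray:
    img = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(rng.integers(1, 4)):
        cy, cx = rng.uniform(0.25 * size, 0.75 * size, size=2)
        rad = rng.uniform(0.12 * size, 0.3 * size)
        width = max(1.0, 0.03 * size)
        d = np.hypot(yy - cy, xx - cx)
        img += np.exp(-((d - rad) ** 2) / (2 * width**2))
    return np.clip(img, 0, 1)


_STYLE_FNS = {"digit-like": _stroke_glyph, "blobs": _blob_glyph, "rings": _ring_glyph}


def generate_glyph(style: str, size: int, seed: int) -> np.ndarray:
    """Procedural grayscale glyph in [0, 1], deterministic given seed.

    Emulates preprocessed handwritten-digit targets: stroke-like connected
    structure for ``digit-like``, smooth patches for ``blobs``, annuli for
    ``rings``.  Nonzero support (pixels > 0.1) is guaranteed to cover 5-40 %
    of the grid; out-of-range draws are redrawn from derived sub-seeds.
    """
    if style not in _STYLE_FNS:
        raise ValueError(f"unsupported style {style!r}; choose from {GLYPH_STYLES}")
    if size < 16:
        raise ValueError("size must be >= 16")
    fn = _STYLE_FNS[style]
    for attempt in range(64):
        rng = rng_for(seed, "glyph", style, attempt)
        img = np.clip(fn(size, rng), 0.0, 1.0)
        mx = img.max()
        if mx <= 0:
            continue
        img = img / mx
        frac = float(np.mean(img > 0.1))
        if 0.05 <= frac <= 0.40:
            return img
    raise RuntimeError("could not generate a glyph with in-range support")


# ---------------------------------------------------------------------------
# hologram encode / demodulate
# ---------------------------------------------------------------------------

def _lattice(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    H, W = shape
    x = (np.arange(W) / W)[None, :]
    y = (np.arange(H) / H)[:, None]
    return np.broadcast_to(x, shape), np.broadcast_to(y, shape)


def _glyph_bandwidth(delta: np.ndarray) -> float:
    """Radius (cycles/width) containing 99 % of the spectral energy of exp(i*delta)."""
    H, W = delta.shape
    spec = np.abs(np.fft.fftshift(np.fft.fft2(np.exp(1j * delta)))) ** 2
    fy = np.fft.fftshift(np.fft.fftfreq(H)) * H
    fx = np.fft.fftshift(np.fft.fftfreq(W)) * W
    r = np.hypot(fy[:, None], fx[None, :])
    order = np.argsort(r.ravel())
    cum = np.cumsum(spec.ravel()[order])
    idx = np.searchsorted(cum, 0.99 * cum[-1])
    return float(r.ravel()[order][min(idx, r.size - 1)])


def encode_hologram(target: PhaseTarget, f0: float, gamma: float = 1.0) -> Hologram:
    """Write the target's two phase maps onto orthogonal carriers.

    Raises if the carrier frequency sits below the glyph bandwidth: the
    diffraction orders would then overlap and demodulation is impossible.
    """
    if not (0.0 < gamma <= 1.0):
        raise ValueError("gamma must lie in (0, 1]")
    if f0 < 4:
        raise ValueError("carrier frequency must be >= 4 cycles per grid width")
    d1, d2 = target.delta1, target.delta2
    bw = max(_glyph_bandwidth(d1), _glyph_bandwidth(d2))
    if f0 < bw:
        raise ValueError(
            f"carrier f0={f0} below the glyph bandwidth ({bw:.1f} cycles); "
            "diffraction orders would overlap"
        )
    x, y = _lattice(target.shape)
    t = (
        1.0
        + gamma / 2 * np.cos(2 * np.pi * f0 * x + d1)
        + gamma / 2 * np.cos(2 * np.pi * f0 * y + d2)
    )
    return Hologram(t, carrier_frequency=f0, modulation_depth=gamma)


def _demod_axis(t: np.ndarray, f0: float, axis: str) -> np.ndarray:
    H, W = t.shape
    x, y = _lattice(t.shape)
    carrier = x if axis == "x" else y
    mixed = t * np.exp(-2j * np.pi * f0 * carrier)  # +1 order to baseband
    spec = np.fft.fft2(mixed)
    fy = np.fft.fftfreq(H) * H
    fx = np.fft.fftfreq(W) * W
    r = np.hypot(fy[:, None], fx[None, :])
    # After mixing, every contaminating order (the zero order's carrier delta,
    # the -1 order, both y-carrier orders) lies in the half-plane f_par <= -f0.
    # A Gaussian-edged half-band mask keeps the +1 order's tails on its own
    # side, hard-zeroed well before the neighbors; a radial cap bounds noise.
    f_par = (fx[None, :] if axis == "x" else fy[:, None]) + np.zeros_like(r)
    border, edge = -0.3 * f0, f0 / 8
    mask = np.where(f_par >= border, 1.0, np.exp(-(((f_par - border) / edge) ** 2)))
    mask[f_par <= -0.7 * f0] = 0.0
    cap = 2.0 * f0
    mask *= np.where(r <= cap, 1.0, 0.0)
    analytic = np.fft.ifft2(spec * mask)
    return np.angle(analytic)


def demodulate_hologram(holo: Hologram, refine: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Recover (delta1, delta2) from the +1 orders, each up to a global constant.

    The initial estimate is the idealized dual-aperture spatial-filter model:
    mix each carrier down to baseband, keep a Gaussian-edged half-band mask
    around the +1 order, take the argument of the resulting analytic signal.
    Filtering alone leaves a small bias from the spectral tails that the
    sinusoidal nonlinearity of the transmittance spreads across orders, so
    ``refine`` Gauss-Newton iterations then fit the full transmittance model
    with bandlimited phase updates (update spectrum capped at 0.55 f0);
    ``refine=0`` returns the pure Fourier-filter estimate.
    """
    if holo.modulation_depth <= 0:
        raise ValueError("hologram has zero modulation depth: no orders to select")
    t = holo.transmittance
    f0, gamma = holo.carrier_frequency, holo.modulation_depth
    d1 = _demod_axis(t, f0, "x")
    d2 = _demod_axis(t, f0, "y")
    if refine:
        H, W = t.shape
        x, y = _lattice(t.shape)
        c1, c2 = 2 * np.pi * f0 * x, 2 * np.pi * f0 * y
        fy = np.fft.fftfreq(H) * H
        fx = np.fft.fftfreq(W) * W
        r_grid = np.hypot(fy[:, None], fx[None, :])
        rad = 0.55 * f0
        lp_mask = np.where(r_grid <= rad, 1.0, np.exp(-(((r_grid - rad) / (f0 / 10)) ** 2)))

        def lowpass(u):
            return np.fft.ifft2(np.fft.fft2(u) * lp_mask).real

        for _ in range(refine):
            resid = t - (1 + gamma / 2 * np.cos(c1 + d1) + gamma / 2 * np.cos(c2 + d2))
            d1 = d1 - (4 / gamma) * lowpass(resid * np.sin(c1 + d1))
            resid = t - (1 + gamma / 2 * np.cos(c1 + d1) + gamma / 2 * np.cos(c2 + d2))
            d2 = d2 - (4 / gamma) * lowpass(resid * np.sin(c2 + d2))
    return d1, d2


# ---------------------------------------------------------------------------
# input-field synthesis
# ---------------------------------------------------------------------------

def synthesize_input_field(
    target: PhaseTarget,
    basis: Literal["HV", "circular"] = "HV",
    polarization: Literal["vector", "scalar"] = "vector",
) -> "JonesField":
    """Jones field carrying the target phases on the chosen polarization basis.

    Vector mode superposes unit-amplitude components exp(i*delta1) and
    exp(i*delta2) on the two basis vectors and expresses the result in the
    x/y Jones frame; for the circular basis the change of basis is
    x = (L + R)/sqrt(2), y = (L - R)/(i*sqrt(2)).  Scalar mode puts all power
    into the x component with phase delta1.  Total power is H*W regardless of
    basis, polarization, or target.
    """
    from .fields import JonesField

    d1, d2 = target.delta1, target.delta2
    a1, a2 = np.exp(1j * d1), np.exp(1j * d2)
    if polarization == "scalar":
        return JonesField(a1, np.zeros_like(a1))
    if polarization != "vector":
        raise ValueError(f"unknown polarization {polarization!r}")
    if basis == "HV":
        return JonesField(a1 / np.sqrt(2), a2 / np.sqrt(2))
    if basis == "circular":
        # field = (a1 * Lhat + a2 * Rhat)/sqrt(2), Lhat=(x+iy)/sqrt(2), Rhat=(x-iy)/sqrt(2)
        ex = (a1 + a2) / 2
        ey = 1j * (a1 - a2) / 2
        return JonesField(ex, ey)
    raise ValueError(f"unknown basis {basis!r}")


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def load_image(path) -> np.ndarray:
    """Load a grayscale PNG/TIFF as float in [0, 1] (averaging color channels)."""
    from PIL import Image

    arr = np.asarray(Image.open(path)).astype(np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    lo, hi = arr.min(), arr.max()
    return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)


def save_image(path, img: np.ndarray) -> None:
    """Save a [0, 1] float map as 8-bit grayscale PNG/TIFF."""
    from PIL import Image

    arr = np.clip(np.asarray(img, dtype=np.float64), 0, 1)
    Image.fromarray((arr * 255).round().astype(np.uint8)).save(path)
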