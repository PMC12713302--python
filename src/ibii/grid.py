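"""Synthetic grid-image rendering and grid-method displacement extraction.

The specimen carries a printed periodic pattern of pitch p sampled by the
camera at N pixels per period.  Displacements are encoded in the spatial
phase of the pattern's first harmonic and recovered by a windowed discrete
Fourier transform at the grid frequency (localized spectrum analysis) with a
bi-triangular window of width 2N-1, followed by the fixed-point iteration
that re-evaluates the reference phase at the displaced point.  A triangular
window of width 2N-1 has spectral zeros at every harmonic of the grid
frequency, so the analysis is insensitive to the pattern's higher harmonics.

Rendering inverts the process (synthetic image deformation): the reference
intensity pattern is evaluated at x - u(x), supersampled and box-integrated
over each pixel, then corrupted with Gaussian sensor noise and quantized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import (
    MASK_EXTRAPOLATED,
    MASK_INVALID,
    MASK_VALID,
    FieldSequence,
    GridImageStack,
)

__all__ = [
    "render_grid_images",
    "apply_sensor_noise",
    "extract_displacement",
    "extrapolate_border",
    "GridNoise",
]


@dataclass(frozen=True)
class GridNoise:
    """Additive Gaussian grey-level noise, std as percent of dynamic range."""

    std_pct: float = 0.0
    seed: int = 0


def _reference_pattern(x_px: np.ndarray, y_px: np.ndarray, pxpp: int, amplitude: float, contrast: float, binary: bool) -> np.ndarray:
    """Grey-level pattern at (sub)pixel coordinates given in pixel units."""
    cx = np.cos(2 * np.pi * x_px / pxpp)
    cy = np.cos(2 * np.pi * y_px / pxpp)
    if binary:
        # printed crossed black squares: product of square waves
        pattern = 0.5 * (1.0 + np.sign(cx) * np.sign(cy))
        return amplitude * (1.0 - contrast + contrast * pattern)
    return amplitude * (1.0 + 0.5 * contrast * (cx + cy))


def render_grid_images(
    fields: FieldSequence,
    pitch: float,
    pxpp: int | None = None,
    noise: GridNoise = GridNoise(),
    supersample: int = 3,
    bit_depth: int = 16,
    amplitude_frac: float = 0.45,
    contrast: float = 0.9,
    binary: bool = False,
    quantize: bool = True,
    pad_left_px: int | str = "auto",
) -> GridImageStack:
    """Render a deformed grid-image stack from a displacement sequence.

    Each frame is I(x) = I0(x - u(x)) with I0 the periodic pattern,
    evaluated on a ``supersample`` x ``supersample`` subgrid per pixel and
    box-integrated, mimicking fill-factor-1 sensor integration.  ``pxpp``
    defaults to pitch / pixel_size, which must be (near) integer so the grid
    frequency falls on an analysis bin.

    ``pad_left_px`` widens the image beyond the free edge (displacements
    edge-replicated, exact at a traction-free edge where the axial strain
    vanishes).  A real field of view extends past the specimen, so the
    pattern printed near the free edge stays in frame as the test pushes the
    material that way; without the pad its phase would be unmeasurable in
    the late frames.  ``"auto"`` sizes the pad to the largest leftward
    displacement; the extraction step crops it back off.
    """
    if supersample < 3:
        raise ValueError("supersample must be >= 3")
    px = fields.pixel_size
    if pxpp is None:
        pxpp = pitch / px
        if abs(pxpp - round(pxpp)) > 1e-9:
            warnings.warn(f"non-integer grid sampling {pxpp:.3f}; analysis uses nearest bin")
        pxpp = int(round(pxpp))
    if pxpp < 3:
        raise ValueError("fewer than 3 pixels per grid period: pattern is aliased")
    ux_all, uy_all = fields.ux, fields.uy
    if pad_left_px == "auto":
        pad_left_px = int(np.ceil(max(0.0, -ux_all.min() / px))) + 2 if ux_all.min() < 0 else 0
    if pad_left_px:
        ux_all = np.pad(ux_all, ((0, 0), (0, 0), (pad_left_px, 0)), mode="edge")
        uy_all = np.pad(uy_all, ((0, 0), (0, 0), (pad_left_px, 0)), mode="edge")
    n_frames, n_rows, n_cols = ux_all.shape
    levels = 2**bit_depth - 1
    amp = amplitude_frac * levels

    off = (np.arange(supersample) + 0.5) / supersample - 0.5
    rows = np.arange(n_rows)[:, None] + off[None, :]  # (n_rows, s)
    cols = np.arange(n_cols)[:, None] + off[None, :]
    R = np.repeat(rows.ravel(), n_cols * supersample).reshape(n_rows * supersample, -1)
    C = np.tile(cols.ravel(), (n_rows * supersample, 1))

    images = np.empty((n_frames, n_rows, n_cols))
    rc, cc = np.meshgrid(np.arange(n_rows, dtype=float), np.arange(n_cols, dtype=float), indexing="ij")
    for k in range(n_frames):
        ux_px = ux_all[k] / px
        uy_px = uy_all[k] / px
        if max(np.abs(ux_px).max(), np.abs(uy_px).max()) > 0:
            # The pattern is attached to the material: the deformed intensity
            # at x is the reference intensity at the material point X solving
            # X = x - u(X), with u the displacement at the *material* point.
            # The inverse map is fixed-point iterated at pixel resolution,
            # then evaluated on the supersampled grid.
            dux = np.zeros((n_rows, n_cols))
            duy = np.zeros((n_rows, n_cols))
            for _ in range(3):
                pc = np.stack([(rc - duy).ravel(), (cc - dux).ravel()])
                dux = ndimage.map_coordinates(ux_px, pc, order=3, mode="nearest").reshape(n_rows, n_cols)
                duy = ndimage.map_coordinates(uy_px, pc, order=3, mode="nearest").reshape(n_rows, n_cols)
            coords = np.stack([R.ravel(), C.ravel()])
            sdux = ndimage.map_coordinates(dux, coords, order=3, mode="nearest").reshape(R.shape)
            sduy = ndimage.map_coordinates(duy, coords, order=3, mode="nearest").reshape(R.shape)
        else:
            sdux = sduy = 0.0
        sub = _reference_pattern(C - sdux, R - sduy, pxpp, amp, contrast, binary)
        images[k] = sub.reshape(n_rows, supersample, n_cols, supersample).mean(axis=(1, 3))

    stack = GridImageStack(
        images=images, pitch=pitch, pxpp=pxpp, dt=fields.dt, bit_depth=bit_depth,
        meta=dict(fields.meta) | {"clean": True, "pad_left_px": int(pad_left_px)},
    )
    if not quantize:
        return stack
    return apply_sensor_noise(stack, noise)


def apply_sensor_noise(stack: GridImageStack, noise: GridNoise = GridNoise()) -> GridImageStack:
    """Add seeded Gaussian sensor noise to a clean (float) rendered stack and
    quantize to the sensor bit depth.  Rendering once and re-noising per seed
    makes multi-seed noise studies cheap."""
    levels = 2**stack.bit_depth - 1
    img = stack.images.astype(float)
    if noise.std_pct > 0:
        rng = np.random.default_rng(noise.seed)
        img = img + rng.normal(0.0, noise.std_pct / 100.0 * levels, img.shape)
    img = np.clip(np.round(img), 0, levels)
    meta = dict(stack.meta)
    meta.update({"clean": False, "noise_pct": noise.std_pct, "noise_seed": noise.seed})
    return GridImageStack(
        images=img, pitch=stack.pitch, pxpp=stack.pxpp, dt=stack.dt,
        bit_depth=stack.bit_depth, meta=meta,
    )


# ---------------------------------------------------------------------------
# phase extraction
# ---------------------------------------------------------------------------

def _bitriangular_kernel(pxpp: int) -> tuple[np.ndarray, np.ndarray]:
    """Triangular window of width 2N-1 modulated at the grid frequency."""
    m = np.arange(-(pxpp - 1), pxpp)
    w = (pxpp - np.abs(m)).astype(float)
    w /= w.sum()
    ker = w * np.exp(-2j * np.pi * m / pxpp)
    return ker.real.copy(), ker.imag.copy()


def _windowed_dft(images: np.ndarray, pxpp: int, axis: int) -> np.ndarray:
    """Complex analytic field W at the grid frequency along one axis."""
    kr, ki = _bitriangular_kernel(pxpp)
    real = ndimage.correlate1d(images, kr, axis=axis, mode="reflect")
    imag = ndimage.correlate1d(images, ki, axis=axis, mode="reflect")
    return real + 1j * imag


def _fill_unreachable(frame: np.ndarray, out: np.ndarray) -> None:
    """Replace out-of-reach pixels of one frame by linear extrapolation along
    the rows (then columns for anything left) from the nearest two in-reach
    pixels."""
    n_rows, n_cols = frame.shape
    idx = np.arange(n_cols)
    for r in range(n_rows):
        bad = out[r]
        if not bad.any():
            continue
        good = np.flatnonzero(~bad)
        if len(good) < 2:
            continue
        lo, hi = good[0], good[-1]
        left = idx < lo
        right = idx > hi
        frame[r, left] = frame[r, lo] + (frame[r, lo] - frame[r, lo + 1]) * (lo - idx[left])
        frame[r, right] = frame[r, hi] + (frame[r, hi] - frame[r, hi - 1]) * (idx[right] - hi)
        inner = bad & ~left & ~right
        if inner.any():
            frame[r, inner] = np.interp(idx[inner], good, frame[r, good])


def extract_displacement(
    stack: GridImageStack,
    max_iter: int = 10,
    tol_px: float = 1e-3,
) -> FieldSequence:
    """Recover per-frame displacements from a grid-image stack.

    Frame 0 is the undeformed reference.  Per axis, the windowed DFT at the
    grid frequency gives phase maps whose difference to the reference is
    proportional to displacement, u = -(p/2pi) (phi_def - phi_ref); the phase
    difference is unwrapped along time (displacement increments between
    consecutive frames must stay below half a pitch, easily satisfied at
    5 Mfps) and refined by a fixed-point iteration that re-evaluates the
    reference phase at the displaced point.  A one-pitch border is marked
    invalid because the window uses 2N-1 data points.
    """
    N = stack.pxpp
    imgs = stack.images.astype(float)
    n_frames, n_rows, n_cols = imgs.shape
    Wx = _windowed_dft(imgs, N, axis=2)
    Wy = _windowed_dft(imgs, N, axis=1)

    # initial estimate: temporally unwrapped same-pixel phase difference
    dphx = np.unwrap(np.angle(Wx * np.conj(Wx[0])), axis=0)
    dphy = np.unwrap(np.angle(Wy * np.conj(Wy[0])), axis=0)
    ux = -N / (2 * np.pi) * dphx  # pixels
    uy = -N / (2 * np.pi) * dphy

    # The fixed point solves Phi_def(x + u) = Phi_ref(x), i.e. the deformed
    # phase is re-evaluated at the displaced point, so u is the displacement
    # of the material point at pixel x (directly comparable to a solver
    # field).  The oscillating carrier exp(2i pi x/N) is removed before the
    # bilinear interpolation and restored analytically, which keeps the
    # interpolation error that of the slowly varying modulation only.
    col = np.arange(n_cols)
    row = np.arange(n_rows)
    carrier_x = np.exp(-2j * np.pi * col / N)[None, :]
    carrier_y = np.exp(-2j * np.pi * row / N)[:, None]

    def interp(Zf_re, Zf_im, coords):
        # cubic spline on the prefiltered slowly-varying modulation: bilinear
        # interpolation leaves ~1e-4 px systematic wiggles that double time
        # differentiation would amplify into O(1e6 m/s^2) acceleration bias
        re = ndimage.map_coordinates(Zf_re, coords, order=3, mode="nearest", prefilter=False)
        im = ndimage.map_coordinates(Zf_im, coords, order=3, mode="nearest", prefilter=False)
        return (re + 1j * im).reshape(n_rows, n_cols)

    C, R = np.meshgrid(col, row)
    conj_ref_x = np.conj(Wx[0])
    conj_ref_y = np.conj(Wy[0])
    ever_out = np.zeros((n_rows, n_cols), dtype=bool)
    for k in range(1, n_frames):
        Zxk = Wx[k] * carrier_x
        Zyk = Wy[k] * carrier_y
        Zx_re = ndimage.spline_filter(Zxk.real, order=3, mode="nearest")
        Zx_im = ndimage.spline_filter(Zxk.imag, order=3, mode="nearest")
        Zy_re = ndimage.spline_filter(Zyk.real, order=3, mode="nearest")
        Zy_im = ndimage.spline_filter(Zyk.imag, order=3, mode="nearest")
        for _ in range(max_iter):
            cc = C + ux[k]
            rr = R + uy[k]
            coords = np.stack([rr.ravel(), cc.ravel()])
            def_x = interp(Zx_re, Zx_im, coords) * np.exp(2j * np.pi * cc / N)
            def_y = interp(Zy_re, Zy_im, coords) * np.exp(2j * np.pi * rr / N)
            dux = -N / (2 * np.pi) * np.angle(def_x * conj_ref_x)
            duy = -N / (2 * np.pi) * np.angle(def_y * conj_ref_y)
            ux[k] += dux
            uy[k] += duy
            if max(np.abs(dux).max(), np.abs(duy).max()) < tol_px:
                break
        # Pixels whose displaced evaluation point enters the corrupted
        # one-pitch image border carry no measurement at this frame (the
        # material imaged there at frame 0 has left the analysable window);
        # fill them by per-frame linear extrapolation from in-reach pixels.
        out = (cc < N) | (cc > n_cols - 1 - N) | (rr < N) | (rr > n_rows - 1 - N)
        if out.any():
            ever_out |= out
            for arr in (ux, uy):
                _fill_unreachable(arr[k], out)

    # Temporal unwrapping assumes inter-frame motion below half a pitch; an
    # aliased jump is invisible in the wrapped phases themselves, so flag
    # pixels whose *estimated* increment approaches the half-pitch limit.
    inc = np.maximum(
        np.abs(np.diff(ux, axis=0)).max(axis=0, initial=0.0),
        np.abs(np.diff(uy, axis=0)).max(axis=0, initial=0.0),
    )
    suspect = inc > 0.25 * N
    unwrap_ok = not suspect.any()
    if not unwrap_ok:
        warnings.warn(
            "inter-frame phase jump near the half-pitch limit at "
            f"{int(suspect.sum())} pixels; temporal unwrapping unreliable there"
        )
        # The affected pixels (typically the torn pattern inside an opening
        # crack) carry arbitrarily wrong phase; bridge them per frame from
        # their trackable neighbours so the surface integrals downstream are
        # not polluted, and leave them marked invalid.
        for k in range(1, n_frames):
            _fill_unreachable(ux[k], suspect)
            _fill_unreachable(uy[k], suspect)

    # Crop any render pad beyond the specimen free edge, then mark the
    # one-pitch border of the physical field: at the true specimen edges the
    # reference frame carries no analysable pattern beyond the edge, so one
    # pitch of displacement data is missing there.
    pad = int(stack.meta.get("pad_left_px", 0))
    if pad:
        ux = ux[:, :, pad:]
        uy = uy[:, :, pad:]
        ever_out = ever_out[:, pad:]
        suspect = suspect[:, pad:]
        n_cols -= pad
    mask = np.full((n_rows, n_cols), MASK_VALID, dtype=np.int8)
    mask[ever_out] = MASK_EXTRAPOLATED
    mask[suspect] = MASK_INVALID
    mask[:N, :] = MASK_INVALID
    mask[-N:, :] = MASK_INVALID
    mask[:, :N] = MASK_INVALID
    mask[:, -N:] = MASK_INVALID

    px = stack.pixel_size
    meta = dict(stack.meta)
    meta["unwrap_ok"] = bool(unwrap_ok)
    return FieldSequence(
        pixel_size=px, dt=stack.dt, ux=ux * px, uy=uy * px, mask=mask, meta=meta,
    )


def extrapolate_border(fields: FieldSequence, fit_band_px: int = 12) -> FieldSequence:
    """Fill the invalid border of displacement fields by linear extrapolation.

    Each border pixel is filled along its axis by a straight line fitted by
    least squares to the nearest ``fit_band_px`` valid interior pixels
    (columns first, then rows, so corners extrapolate the already-filled
    columns).  Fitting a band rather than differencing the two nearest
    pixels matters: the extrapolation multiplies the slope by up to a pitch
    of pixels, and a two-point slope carries enough temporally rough phase
    noise to corrupt the accelerations later differentiated from the border.
    The mask records extrapolated provenance.
    """
    out = fields.copy()
    valid = fields.valid  # measured or already-extrapolated pixels carry data
    if valid.all():
        return out
    vcols = np.flatnonzero(valid.any(axis=0))
    vrows = np.flatnonzero(valid.any(axis=1))
    if len(vcols) == 0:
        raise ValueError("no valid pixels to extrapolate from")

    def extrap_axis(arr, lo, hi, axis):
        # fill indices < lo and > hi along axis from a least-squares line
        # through the nearest band of interior lines
        idx = np.arange(arr.shape[axis])
        if hi - lo < 1:
            warnings.warn("fewer than 2 valid lines; filling border with nearest value")
            for j in idx[(idx < lo) | (idx > hi)]:
                sl = [slice(None)] * arr.ndim
                sl[axis] = j
                arr[tuple(sl)] = np.take(arr, lo, axis=axis)
            return arr
        band = min(fit_band_px, hi - lo + 1)

        def line_fit(first, step):
            # mean and LS slope over lines first, first+step, ... (band of them)
            sel = first + step * np.arange(band)
            seg = np.take(arr, sel, axis=axis)
            x = np.arange(band) - (band - 1) / 2.0
            shape = [1] * arr.ndim
            shape[axis] = band
            xb = x.reshape(shape)
            mean = seg.mean(axis=axis, keepdims=True)
            slope = (seg * xb).sum(axis=axis, keepdims=True) / (x**2).sum()
            return mean, slope

        mean, slope = line_fit(lo, +1)
        for j in idx[idx < lo]:
            sl = [slice(None)] * arr.ndim
            sl[axis] = slice(j, j + 1)
            arr[tuple(sl)] = mean + slope * (j - lo - (band - 1) / 2.0)
        mean, slope = line_fit(hi, -1)
        for j in idx[idx > hi]:
            sl = [slice(None)] * arr.ndim
            sl[axis] = slice(j, j + 1)
            arr[tuple(sl)] = mean - slope * (j - hi + (band - 1) / 2.0)
        return arr

    for name in ("ux", "uy"):
        arr = getattr(out, name)
        if arr is None:
            continue
        arr = extrap_axis(arr, vcols[0], vcols[-1], axis=2)
        arr = extrap_axis(arr, vrows[0], vrows[-1], axis=1)
        setattr(out, name, arr)

    new_mask = out.mask.copy()
    new_mask[new_mask == MASK_INVALID] = MASK_EXTRAPOLATED
    out.mask = new_mask
    return out
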