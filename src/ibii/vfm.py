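"""Stiffness identification from kinematic fields via the virtual fields method.

Three identification routes are provided, all exploiting the fact that in an
inertial impact test the acceleration field is a distributed load cell:

* the **stress-gauge** (rigid x-translation virtual field): the mean axial
  stress over the section at x0 equals rho * x0 * (surface-mean axial
  acceleration between the free edge and the section);
* the **shear stress-gauge** (rigid y-translation) and the **linear
  stress-gauge** (adds a rigid rotation), giving a stress estimate linear in
  the height coordinate for local failure-stress work;
* **special optimized virtual fields** on a piecewise bilinear virtual mesh
  with u* = 0 on the impacted edge: per frame, one virtual field per
  stiffness component is found by minimizing a strain-noise sensitivity
  functional subject to speciality constraints that set the internal-virtual-
  work coefficient of that component to one and the others to zero; the
  component then equals minus the acceleration virtual work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import FieldSequence

__all__ = [
    "StressGaugeSeries",
    "VirtualMesh",
    "IdentificationResult",
    "stress_gauge",
    "shear_stress_gauge",
    "linear_stress_gauge",
    "build_stress_gauge_series",
    "fit_stiffness_profile",
    "fit_shear_profile",
    "optimized_vf_identify",
    "select_stable_median",
    "edge_margin_px",
]

#: default assumed Poisson ratios for stress-gauge stress/strain fitting
NU12_DEFAULT = 0.31
NU21_DEFAULT = 0.16


def edge_margin_px(pxpp: int = 6, spatial_radius_px: int = 31) -> int:
    """Pixels to discard at each edge: one grid pitch plus half the spatial
    smoothing kernel (pitch + radius, e.g. 6 + 31 px = 2.08 mm at 56 um/px)."""
    return pxpp + spatial_radius_px


def _columns_for_x0(x0: float, pixel_size: float, n_cols: int) -> int:
    """Number of pixel columns covering [0, x0] by the rectangle method."""
    n = int(round(x0 / pixel_size))
    if n < 1 or n > n_cols:
        raise ValueError("x0 outside the measured field")
    return n


def stress_gauge(ax: np.ndarray, rho: float, x0: float, pixel_size: float) -> np.ndarray:
    """Mean axial stress history at the section x0 from axial acceleration.

    sigma_xx_mean(t) = rho * x0 * mean(ax over [0, x0] x height); x0 is
    snapped to a whole number of pixel columns.
    """
    n = _columns_for_x0(x0, pixel_size, ax.shape[2])
    return rho * (n * pixel_size) * ax[:, :, :n].mean(axis=(1, 2))


def shear_stress_gauge(ay: np.ndarray, rho: float, x0: float, pixel_size: float) -> np.ndarray:
    """Mean shear stress history at x0 from transverse acceleration."""
    n = _columns_for_x0(x0, pixel_size, ay.shape[2])
    return rho * (n * pixel_size) * ay[:, :, :n].mean(axis=(1, 2))


def linear_stress_gauge(
    ax: np.ndarray,
    ay: np.ndarray,
    rho: float,
    x0: float,
    pixel_size: float,
    H: float | None = None,
    y: np.ndarray | None = None,
) -> np.ndarray:
    """Axial stress linear in y at the section x0, from accelerations only.

    sigma_xx(y, t) = rho x0 <ax>^S
                   + (12 rho x0 y / H^2) (<ax y>^S - <ay x>^S + x0 <ay>^S)

    with <.>^S surface averages from the free edge to x0, y measured from the
    section centroid and x from the free edge.  Returns (n_frames, n_rows).
    The height average over y of the result equals the plain stress gauge
    exactly, because the enrichment term is odd in y.
    """
    n_frames, n_rows, n_cols = ax.shape
    if H is None:
        H = n_rows * pixel_size
    if y is None:
        y = (np.arange(n_rows) + 0.5 - n_rows / 2.0) * pixel_size
    if np.any(np.abs(y) > H / 2 + 1e-12):
        raise ValueError("|y| exceeds H/2")
    n = _columns_for_x0(x0, pixel_size, n_cols)
    x0s = n * pixel_size
    x = (np.arange(n) + 0.5) * pixel_size
    ax_s = ax[:, :, :n].mean(axis=(1, 2))
    ay_s = ay[:, :, :n].mean(axis=(1, 2))
    axy_s = (ax[:, :, :n] * y[None, :, None]).mean(axis=(1, 2))
    ayx_s = (ay[:, :, :n] * x[None, None, :]).mean(axis=(1, 2))
    lin = 12.0 * rho * x0s / H**2 * (axy_s - ayx_s + x0s * ay_s)
    return rho * x0s * ax_s[:, None] + lin[:, None] * y[None, :]


# ---------------------------------------------------------------------------
# stress-gauge stress/strain fitting
# ---------------------------------------------------------------------------

@dataclass
class StressGaugeSeries:
    """Per-slice average stress and strain histories along the specimen."""

    x0: np.ndarray                  # (n_slices,) section positions (m)
    cols: np.ndarray                # pixel column index of each slice
    sigma_xx: np.ndarray            # (n_slices, n_frames) stress-gauge stress (Pa)
    sigma_xy: np.ndarray            # shear stress-gauge stress (Pa)
    eps_xx: np.ndarray              # line-average strains at each slice (-)
    eps_yy: np.ndarray
    gamma_xy: np.ndarray
    pixel_size: float
    L: float
    meta: dict = field(default_factory=dict)


def build_stress_gauge_series(
    kin: FieldSequence,
    rho: float | None = None,
    margin_px: int | None = None,
) -> StressGaugeSeries:
    """Evaluate stress-gauge and line-average strain histories at every slice.

    Slices within ``margin_px`` (default: one pitch + half smoothing kernel)
    of either field edge are excluded: the stress there is low and smoothing
    edge effects corrupt the strains.
    """
    if kin.ax is None or kin.eps_xx is None:
        raise ValueError("kinematic fields (accelerations and strains) required")
    if rho is None:
        rho = float(kin.meta["rho"])
    px = kin.pixel_size
    n_frames, n_rows, n_cols = kin.ax.shape
    if margin_px is None:
        margin_px = edge_margin_px(
            int(kin.meta.get("pxpp", 6)), int(kin.meta.get("spatial_radius_px", 31))
        )
    cols = np.arange(margin_px, n_cols - margin_px)
    if len(cols) == 0:
        raise ValueError("edge margin leaves no usable slices")

    # cumulative surface means via running sums over columns
    col_mean_ax = kin.ax.mean(axis=1)      # (n_frames, n_cols)
    col_mean_ay = kin.ay.mean(axis=1)
    cum_ax = np.cumsum(col_mean_ax, axis=1)
    cum_ay = np.cumsum(col_mean_ay, axis=1)
    # sigma(j) = rho * (j+1) px * cum/(j+1) = rho * px * cum
    sigma_xx = (rho * px * cum_ax[:, cols]).T
    sigma_xy = (rho * px * cum_ay[:, cols]).T

    L = float(kin.meta.get("L", n_cols * px))
    return StressGaugeSeries(
        x0=(cols + 1) * px,
        cols=cols,
        sigma_xx=sigma_xx,
        sigma_xy=sigma_xy,
        eps_xx=kin.eps_xx[:, :, cols].mean(axis=1).T,
        eps_yy=kin.eps_yy[:, :, cols].mean(axis=1).T,
        gamma_xy=kin.gamma_xy[:, :, cols].mean(axis=1).T,
        pixel_size=px,
        L=L,
        meta=dict(kin.meta),
    )


def compressive_portion(sigma: np.ndarray, min_frames: int = 5) -> slice | None:
    """Frames from test start until the mean stress first returns to zero
    after its compressive (most negative) extremum."""
    i_min = int(np.argmin(sigma))
    after = np.flatnonzero(sigma[i_min:] >= 0.0)
    end = i_min + int(after[0]) if len(after) else len(sigma)
    if end < min_frames:
        return None
    return slice(0, end)


def _slope_through_origin(x: np.ndarray, y: np.ndarray) -> float:
    denom = float((x * x).sum())
    return float((x * y).sum() / denom) if denom > 0 else np.nan


@dataclass
class StiffnessProfile:
    x0: np.ndarray
    stiffness: np.ndarray      # fitted slope per slice (Pa), NaN where skipped
    average: float             # single value over the averaging window (Pa)
    window: tuple[float, float]
    identifiable: bool = True
    reason: str = ""


def fit_stiffness_profile(
    series: StressGaugeSeries,
    nu_assumed: float = NU21_DEFAULT,
    window: tuple[float, float] = (0.25, 0.75),
) -> StiffnessProfile:
    """Axial stiffness vs position from stress-gauge stress/strain curves.

    Per slice, the stress-gauge stress is regressed (through the origin)
    against eps_xx + nu * eps_yy over the compressive part of the response
    (loading plus unloading, up to the first return of the mean stress to
    zero).  The single reported stiffness is the mean of the slopes over the
    middle of the specimen, x0 in [0.25 L, 0.75 L] by default, where the
    identification is reliable.

    For a longitudinal specimen the slope is Q11 and ``nu_assumed`` is the
    minor Poisson ratio nu21; for a transverse one it is Q22 with nu12.
    """
    n_slices = len(series.x0)
    q = np.full(n_slices, np.nan)
    for i in range(n_slices):
        por = compressive_portion(series.sigma_xx[i])
        if por is None:
            warnings.warn(f"slice x0={series.x0[i]:.4g} m: compressive portion too short; skipped")
            continue
        eps = series.eps_xx[i, por] + nu_assumed * series.eps_yy[i, por]
        q[i] = _slope_through_origin(eps, series.sigma_xx[i, por])
    lo, hi = window[0] * series.L, window[1] * series.L
    sel = (series.x0 >= lo) & (series.x0 <= hi) & np.isfinite(q)
    avg = float(q[sel].mean()) if sel.any() else np.nan
    return StiffnessProfile(series.x0, q, avg, window, identifiable=sel.any())


def fit_shear_profile(
    series: StressGaugeSeries,
    window: tuple[float, float] = (0.5, 0.85),
    min_peak_shear_strain: float = 5e-5,
    frames: slice | None = None,
) -> StiffnessProfile:
    """Shear modulus vs position from shear stress-gauge stress/strain curves.

    The shear wave travels more slowly than the axial one, so the fit is
    averaged closer to the impact edge, x0 in [0.5 L, 0.85 L].  ``frames``
    restricts the fit to an early time window; the pipeline passes the
    first wave cycle (2 L / c + half the pulse), because the reverberating
    late response is distorted differently by the temporal filter on the
    stress (acceleration) and strain paths -- and a real specimen has
    fractured before those frames anyway.  Impacts that happen to be well
    aligned produce no usable shear response; such runs are reported as not
    identifiable rather than returning a noise-driven value.
    """
    if frames is None:
        frames = slice(None)
    lo, hi = window[0] * series.L, window[1] * series.L
    sel = (series.x0 >= lo) & (series.x0 <= hi)
    peak = np.abs(series.gamma_xy[sel][:, frames]).max() if sel.any() else 0.0
    if peak < min_peak_shear_strain:
        return StiffnessProfile(
            series.x0, np.full(len(series.x0), np.nan), np.nan, window,
            identifiable=False,
            reason=f"peak |mean shear strain| {peak:.2e} below threshold {min_peak_shear_strain:.0e}",
        )
    g = np.full(len(series.x0), np.nan)
    for i in np.flatnonzero(sel):
        g[i] = _slope_through_origin(series.gamma_xy[i, frames], series.sigma_xy[i, frames])
    avg = float(np.nanmean(g[sel]))
    return StiffnessProfile(series.x0, g, avg, window)


# ---------------------------------------------------------------------------
# special optimized virtual fields
# ---------------------------------------------------------------------------

@dataclass
class VirtualMesh:
    """Piecewise bilinear virtual mesh with u* = 0 on the impacted edge.

    ``shape`` = (m, n) virtual elements along x and y over the measured
    field; the right-hand node column (impact side) carries no free degrees
    of freedom, which cancels the unknown impact-force virtual work.
    """

    shape: tuple[int, int] = (5, 4)

    @property
    def n_free_nodes(self) -> int:
        m, n = self.shape
        return m * (n + 1)

    @property
    def ndof(self) -> int:
        return 2 * self.n_free_nodes


@dataclass
class IdentificationResult:
    """Per-frame identified stiffnesses and their stable-range medians."""

    times: np.ndarray
    q_traces: np.ndarray          # (n_frames, 4): Q11, Q22, Q12, Q66 (Pa)
    method: str
    stable_range: tuple[int, int] | None = None
    medians: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def components(self) -> tuple[str, ...]:
        return ("Q11", "Q22", "Q12", "Q66")


def _virtual_basis(n_rows: int, n_cols: int, pixel_size: float, mesh: VirtualMesh):
    """Dense (n_pix, ndof) virtual displacement / strain basis matrices.

    DOF ordering: x-displacements of the free nodes, then y-displacements.
    Node (i, j) with column i in [0, m-1] (column m is constrained), row j in
    [0, n].
    """
    m, n = mesh.shape
    W = n_cols * pixel_size
    Hf = n_rows * pixel_size
    ex_w, ey_w = W / m, Hf / n
    x = (np.arange(n_cols) + 0.5) * pixel_size
    y = (np.arange(n_rows) + 0.5) * pixel_size
    X, Y = np.meshgrid(x, y)
    ei = np.minimum((X / ex_w).astype(int), m - 1)
    ej = np.minimum((Y / ey_w).astype(int), n - 1)
    xi = (X - ei * ex_w) / ex_w       # in [0, 1]
    eta = (Y - ej * ey_w) / ey_w

    npix = n_rows * n_cols
    nfree = mesh.n_free_nodes
    Nmat = np.zeros((npix, nfree))
    dNdx = np.zeros((npix, nfree))
    dNdy = np.zeros((npix, nfree))
    flat = lambda a: a.ravel()
    corners = (
        (0, 0, lambda s, t: (1 - s) * (1 - t), lambda s, t: -(1 - t) / ex_w, lambda s, t: -(1 - s) / ey_w),
        (1, 0, lambda s, t: s * (1 - t), lambda s, t: (1 - t) / ex_w, lambda s, t: -s / ey_w),
        (1, 1, lambda s, t: s * t, lambda s, t: t / ex_w, lambda s, t: s / ey_w),
        (0, 1, lambda s, t: (1 - s) * t, lambda s, t: -t / ex_w, lambda s, t: (1 - s) / ey_w),
    )
    pix = np.arange(npix)
    for di, dj, fN, fdx, fdy in corners:
        ni = flat(ei) + di
        nj = flat(ej) + dj
        free = ni < m                      # right-hand node column constrained
        node = ni * (n + 1) + nj           # free-node index
        s, t = flat(xi), flat(eta)
        rows = pix[free]
        cols_ = node[free]
        Nmat[rows, cols_] += fN(s, t)[free]
        dNdx[rows, cols_] += fdx(s, t)[free]
        dNdy[rows, cols_] += fdy(s, t)[free]
    return Nmat, dNdx, dNdy


def optimized_vf_identify(
    kin: FieldSequence,
    rho: float | None = None,
    mesh: VirtualMesh = VirtualMesh(),
    q_weights: tuple[float, float, float, float] | None = None,
    reweight: bool = True,
    constraint_tol: float = 1e-6,
) -> IdentificationResult:
    """Identify Q11, Q22, Q12, Q66 per frame with special optimized virtual fields.

    For each frame and each stiffness component the constrained quadratic
    program

        minimize    Y' H(Q) Y        (strain-noise sensitivity)
        subject to  A(eps) Y = e_i   (speciality + impact-edge u* = 0)

    is solved by a Lagrange-multiplier linear system; the component then
    equals -rho * (acceleration virtual work of its special field).  H uses
    stiffness-weighted virtual strains; with ``reweight`` the identification
    runs once with the initial weights and once more with the identified
    medians re-entering H.  Frames whose constraint system cannot be
    satisfied (not enough strain richness -- e.g. the start of the test, or
    the shear constraint of a perfectly aligned impact) have the affected
    components marked NaN.
    """
    if kin.eps_xx is None or kin.ax is None:
        raise ValueError("strain and acceleration fields required")
    if rho is None:
        rho = float(kin.meta["rho"])
    n_frames, n_rows, n_cols = kin.eps_xx.shape
    px = kin.pixel_size
    w = px * px
    Nmat, dNdx, dNdy = _virtual_basis(n_rows, n_cols, px, mesh)
    nfree = mesh.n_free_nodes
    ndof = 2 * nfree

    # Gram matrices of the virtual strain components over the pixels
    GXX = dNdx.T @ dNdx
    GYY = dNdy.T @ dNdy
    GXY = dNdx.T @ dNdy
    GDX = dNdy.T @ dNdy   # (du*x/dy) gram
    GDC = dNdy.T @ dNdx

    def make_H(qw):
        Q11, Q22, Q12, Q66 = qw
        H = np.zeros((ndof, ndof))
        # eps*_xx lives on x-dofs, eps*_yy on y-dofs, gamma* couples both
        H[:nfree, :nfree] = (Q11**2 + Q12**2) * GXX + Q66**2 * GDX
        H[nfree:, nfree:] = (Q22**2 + Q12**2) * GYY + Q66**2 * GXX
        c = Q12 * (Q11 + Q22)
        H[:nfree, nfree:] += c * GXY + Q66**2 * GDC
        H[nfree:, :nfree] += c * GXY.T + Q66**2 * GDC.T
        return H

    def identify(qw):
        H = make_H(qw)
        traces = np.full((n_frames, 4), np.nan)
        for f in range(n_frames):
            exx = kin.eps_xx[f].ravel()
            eyy = kin.eps_yy[f].ravel()
            gxy = kin.gamma_xy[f].ravel()
            A = np.zeros((4, ndof))
            A[0, :nfree] = w * (exx @ dNdx)
            A[1, nfree:] = w * (eyy @ dNdy)
            A[2, :nfree] = w * (eyy @ dNdx)
            A[2, nfree:] = w * (exx @ dNdy)
            A[3, :nfree] = w * (gxy @ dNdy)
            A[3, nfree:] = w * (gxy @ dNdx)
            b = np.zeros(ndof)
            b[:nfree] = rho * w * (kin.ax[f].ravel() @ Nmat)
            b[nfree:] = rho * w * (kin.ay[f].ravel() @ Nmat)

            K = np.zeros((ndof + 4, ndof + 4))
            K[:ndof, :ndof] = H
            K[:ndof, ndof:] = A.T
            K[ndof:, :ndof] = A
            rhs = np.zeros((ndof + 4, 4))
            rhs[ndof:] = np.eye(4)
            try:
                sol = np.linalg.solve(K, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
            Y = sol[:ndof]
            resid = np.abs(A @ Y - np.eye(4))
            scale = max(np.abs(A).max(), 1e-300)
            for i in range(4):
                if resid[:, i].max() < constraint_tol and np.isfinite(Y[:, i]).all():
                    traces[f, i] = -b @ Y[:, i]
        return traces

    qw = q_weights if q_weights is not None else (20e9, 20e9, 5e9, 5e9)
    traces = identify(qw)
    if reweight:
        med = np.nanmedian(traces, axis=0)
        if np.isfinite(med[:2]).all() and (med[:2] > 0).all():
            qw2 = (
                med[0], med[1],
                med[2] if np.isfinite(med[2]) and abs(med[2]) < np.sqrt(med[0] * med[1]) else 0.2 * med[0],
                med[3] if np.isfinite(med[3]) and med[3] > 0 else 0.25 * med[0],
            )
            traces = identify(qw2)
    return IdentificationResult(
        times=kin.times(), q_traces=traces, method="optimized_vf",
        meta={"mesh": mesh.shape, "rho": rho},
    )


# ---------------------------------------------------------------------------
# stable-range median
# ---------------------------------------------------------------------------

def select_stable_median(
    trace: np.ndarray,
    strategy: str = "auto",
    frame_range: tuple[int, int] | None = None,
    window: int = 5,
    rel_tol: float = 0.10,
    strain_signal: np.ndarray | None = None,
    noise_floor: float = 0.0,
    min_run: int = 5,
) -> tuple[tuple[int, int], float]:
    """Stable temporal range of a per-frame identification and its median.

    Automatic strategy: the first run (or the longest, with
    ``strategy="longest"``) of frames where the sliding-window relative
    variation (window std over |window mean|) stays below ``rel_tol`` and,
    when a strain signal and noise floor are supplied, the mean strain
    magnitude exceeds 5x the static noise floor.  The median is
    robust to the outliers that transient frames produce; a manual
    ``frame_range`` (inclusive start, exclusive stop) overrides the search,
    mirroring how a per-specimen range is picked by eye in practice.
    """
    trace = np.asarray(trace, dtype=float)
    if strategy == "manual" or frame_range is not None:
        if frame_range is None:
            raise ValueError("manual strategy needs frame_range")
        lo, hi = frame_range
        vals = trace[lo:hi]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError("no finite values in the requested range")
        return (lo, hi), float(np.median(vals))
    if strategy not in ("auto", "first", "longest"):
        raise ValueError(f"unknown strategy {strategy!r}")

    n = len(trace)
    ok = np.isfinite(trace)
    half = window // 2
    for f in range(n):
        if not ok[f]:
            continue
        lo, hi = max(0, f - half), min(n, f + half + 1)
        seg = trace[lo:hi]
        seg = seg[np.isfinite(seg)]
        if len(seg) < 2 or abs(seg.mean()) == 0 or seg.std() / abs(seg.mean()) >= rel_tol:
            ok[f] = False
    if strain_signal is not None and noise_floor > 0:
        ok &= np.abs(strain_signal) > 5.0 * noise_floor

    runs = []
    start = None
    for f in range(n + 1):
        if f < n and ok[f]:
            if start is None:
                start = f
        elif start is not None:
            runs.append((start, f))
            start = None
    runs = [r for r in runs if r[1] - r[0] >= min_run]
    if not runs:
        raise ValueError(f"no stable run of >= {min_run} frames found")
    # The identification settles during the first wave traversal and
    # diverges again once reverberations build up, so the default takes the
    # first qualifying plateau; "longest" is available for late-stabilizing
    # traces.
    best = max(runs, key=lambda r: r[1] - r[0]) if strategy == "longest" else runs[0]
    return best, float(np.median(trace[best[0]:best[1]]))
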