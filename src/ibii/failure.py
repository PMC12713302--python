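"""Tensile failure-stress identification from the virtual stress gauge.

After the compressive pulse reflects off the free edge, the resulting
tensile wave fractures the specimen.  The first crack shows up in strain
maps computed from *unsmoothed* displacements as a localized band of
unphysically large tensile strain (really crack opening).  Over a small
virtual gauge area around that location two independent stress measures are
averaged and compared:

* stress reconstructed from the strains and the previously identified
  stiffnesses (meaningless once the material cracks), and
* the linear stress-gauge (LSG) estimate built purely from accelerations.

While the response stays linear elastic the two agree; at fracture the
strain-derived stress shoots up as the "strains" become crack opening, and
the failure stress is read from the *LSG* trace at that separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .containers import FieldSequence
from .kinematics import effective_strain_rate
from .material import MaterialOrientation, OrthotropicPlaneStress, stress_from_strain
from .vfm import linear_stress_gauge

__all__ = ["FractureEvent", "detect_fracture", "gauge_stress_traces", "identify_failure_stress", "analyze_failure"]


@dataclass
class FractureEvent:
    """Detected first fracture and its virtual-gauge failure stress."""

    frame: int
    centroid: tuple[float, float]            # (x, y) in m
    gauge_rows: slice | None = None
    gauge_cols: slice | None = None
    failure_stress: float | None = None      # Pa, from the LSG trace
    strain_rate: float | None = None         # gauge effective strain rate (1/s)
    divergence_frame: int | None = None
    sigma_strain: np.ndarray | None = None   # diagnostic traces (Pa)
    sigma_lsg: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def detect_fracture(
    raw_eps_xx: np.ndarray,
    pixel_size: float,
    valid: np.ndarray | None = None,
    k: float = 3.0,
    min_area_px: int = 10,
) -> tuple[int, tuple[float, float]] | None:
    """First-fracture frame and centroid from raw (unsmoothed) strain maps.

    A crack is the earliest connected blob of at least ``min_area_px``
    pixels whose tensile strain exceeds ``k`` times the 99th percentile of
    the tensile strain seen before the wave reflection (estimated as the
    frame of peak spatial-mean compression).  Returns None when nothing
    qualifies (an uncracked test).  The y coordinate is measured from the
    section centroid, x from the free edge.
    """
    n_frames, n_rows, n_cols = raw_eps_xx.shape
    if valid is None:
        valid = np.ones((n_rows, n_cols), dtype=bool)
    if not valid.any():
        raise ValueError("all pixels masked")
    eps = np.where(valid[None], raw_eps_xx, 0.0)
    mean_exx = eps.sum(axis=(1, 2)) / valid.sum()
    f_reflect = int(np.argmin(mean_exx))
    pre = eps[: f_reflect + 1][:, valid]
    # The legitimate tensile strain after reflection is of the order of the
    # compressive strain before it, so the crack threshold is referenced to
    # the 99th-percentile pre-reflection strain *magnitude*; on noisy data
    # this also absorbs the measured tensile noise floor.
    tensile = pre[pre > 0]
    baseline = float(np.percentile(np.abs(pre), 99)) if pre.size else 0.0
    if tensile.size:
        baseline = max(baseline, float(np.percentile(tensile, 99)))
    if baseline <= 0:
        baseline = 1e-4
    threshold = k * baseline

    for f in range(n_frames):
        blob_map = (raw_eps_xx[f] > threshold) & valid
        if blob_map.sum() < min_area_px:
            continue
        labels = measure.label(blob_map, connectivity=2)
        props = measure.regionprops(labels)
        props = [p for p in props if p.area >= min_area_px]
        if not props:
            continue
        best = max(props, key=lambda p: p.area)
        r, c = best.centroid
        x = (c + 0.5) * pixel_size
        y = (r + 0.5 - n_rows / 2.0) * pixel_size
        return f, (x, y)
    return None


def gauge_stress_traces(
    kin: FieldSequence,
    q: OrthotropicPlaneStress,
    orientation: MaterialOrientation | str,
    rho: float,
    centroid: tuple[float, float],
    gauge_size: tuple[float, float] = (2e-3, 2e-3),
) -> tuple[np.ndarray, np.ndarray, slice, slice]:
    """Average stress-from-strain and LSG stress over the virtual gauge.

    The gauge is a ``gauge_size`` (x, y) box centred on the crack centroid,
    shrunk (with a warning) if it overlaps the excluded field border.
    Returns (sigma_strain(t), sigma_lsg(t), gauge_rows, gauge_cols).
    """
    px = kin.pixel_size
    n_frames, n_rows, n_cols = kin.eps_xx.shape
    vcols = np.flatnonzero(kin.valid.any(axis=0))
    vrows = np.flatnonzero(kin.valid.any(axis=1))
    cx = centroid[0] / px - 0.5
    cy = centroid[1] / px - 0.5 + n_rows / 2.0
    hx = max(1, int(round(gauge_size[0] / px / 2)))
    hy = max(1, int(round(gauge_size[1] / px / 2)))
    c0, c1 = int(round(cx)) - hx, int(round(cx)) + hx + 1
    r0, r1 = int(round(cy)) - hy, int(round(cy)) + hy + 1
    if c0 < vcols[0] or c1 > vcols[-1] + 1 or r0 < vrows[0] or r1 > vrows[-1] + 1:
        warnings.warn("virtual gauge overlaps the excluded border; shrinking")
        c0, c1 = max(c0, vcols[0]), min(c1, vcols[-1] + 1)
        r0, r1 = max(r0, vrows[0]), min(r1, vrows[-1] + 1)
    rows, cols = slice(r0, r1), slice(c0, c1)

    sxx, _, _ = stress_from_strain(
        q, orientation, kin.eps_xx[:, rows, cols], kin.eps_yy[:, rows, cols],
        kin.gamma_xy[:, rows, cols],
    )
    sigma_strain = sxx.mean(axis=(1, 2))

    y = kin.y_coords()
    H = float(kin.meta.get("H", n_rows * px))
    lsg_cols = []
    for j in range(c0, c1):
        prof = linear_stress_gauge(kin.ax, kin.ay, rho, (j + 1) * px, px, H=H, y=y)
        lsg_cols.append(prof[:, rows])
    sigma_lsg = np.stack(lsg_cols, axis=-1).mean(axis=(1, 2))
    return sigma_strain, sigma_lsg, rows, cols


def identify_failure_stress(
    sigma_strain: np.ndarray,
    sigma_lsg: np.ndarray,
    divergence_frac: float = 0.10,
    fracture_frame: int | None = None,
) -> tuple[float, int | None, slice] | None:
    """Failure stress from the divergence of the two gauge stress traces.

    The tensile phase starts at the first frame with positive LSG stress
    after the compressive extremum.  The failure stress is the peak of the
    LSG trace up to (and including) the frame where the strain-derived
    trace first departs from it by more than ``divergence_frac`` of the LSG
    tensile peak.  When the first-fracture frame is known (from the raw
    strain maps) both the compressive extremum and the tensile peak are
    anchored before it, since the post-fracture trace rings unphysically
    around the torn region.  Returns (failure stress, divergence frame,
    tensile-phase frames) or None when the trace never goes tensile.
    """
    n = len(sigma_lsg)
    anchor_end = n if fracture_frame is None else max(int(fracture_frame), 2)
    i_min = int(np.argmin(sigma_lsg[:anchor_end]))
    after = np.flatnonzero(sigma_lsg[i_min:] > 0)
    if len(after) == 0:
        return None
    t0 = i_min + int(after[0])
    tensile = slice(t0, n)
    peak_end = n if fracture_frame is None else min(n, int(fracture_frame) + 3)
    peak_t = float(sigma_lsg[t0:peak_end].max()) if peak_end > t0 else 0.0
    if peak_t <= 0:
        return None
    # fracture signature: the strain-derived stress shoots *up* away from
    # the acceleration-derived one (crack opening masquerading as strain);
    # the signed gap ignores benign transient mismatch of the two metrics
    gap = sigma_strain[tensile] - sigma_lsg[tensile]
    over = np.flatnonzero(gap > divergence_frac * peak_t)
    if len(over):
        f_div = t0 + int(over[0])
        stress = float(sigma_lsg[t0 : f_div + 1].max())
    else:
        f_div = None
        stress = peak_t
    return stress, f_div, tensile


def analyze_failure(
    kin: FieldSequence,
    raw_kin: FieldSequence,
    q: OrthotropicPlaneStress,
    orientation: MaterialOrientation | str,
    rho: float | None = None,
    gauge_size: tuple[float, float] = (2e-3, 2e-3),
    k: float = 3.0,
    min_area_px: int = 10,
    divergence_frac: float = 0.10,
) -> FractureEvent | None:
    """Full failure-stress identification for one processed test.

    ``kin`` carries the smoothed strain and acceleration fields, ``raw_kin``
    the strains from unsmoothed displacements used for crack detection.
    Returns None for an uncracked test.
    """
    if rho is None:
        rho = float(kin.meta["rho"])
    hit = detect_fracture(raw_kin.eps_xx, raw_kin.pixel_size, raw_kin.valid, k=k, min_area_px=min_area_px)
    if hit is None:
        return None
    frame, centroid = hit
    sigma_strain, sigma_lsg, rows, cols = gauge_stress_traces(
        kin, q, orientation, rho, centroid, gauge_size
    )
    res = identify_failure_stress(sigma_strain, sigma_lsg, divergence_frac, fracture_frame=frame)
    event = FractureEvent(
        frame=frame, centroid=centroid, gauge_rows=rows, gauge_cols=cols,
        sigma_strain=sigma_strain, sigma_lsg=sigma_lsg,
    )
    if res is None:
        event.meta["no_tensile_phase"] = True
        return event
    stress, f_div, tensile = res
    event.failure_stress = stress
    event.divergence_frame = f_div
    stop = (f_div + 1) if f_div is not None else len(sigma_lsg)
    region = np.zeros(kin.eps_xx.shape[1:], dtype=bool)
    region[rows, cols] = True
    try:
        event.strain_rate = effective_strain_rate(
            kin.eps_xx, kin.eps_xx_rate, region=region, frames=slice(tensile.start, stop)
        )
    except ValueError:
        event.strain_rate = None
    return event
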