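"""ROI-based PDFF reporting: eight 25-voxel ROIs, lowest-s.d. selection,
iron concentration from R2*, and cross-protocol calibration.

Water-fat swaps corrupt parts of a PDFF map; because liver tissue is
locally homogeneous, corrupted regions show inflated within-ROI standard
deviation, so reporting the mean of the lowest-s.d. ROI dodges them.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Union

import numpy as np

from .types import ROI, IronCalibration, PDFFMap, PDFFReport, ROIStats

__all__ = [
    "place_rois",
    "select_roi",
    "iron_concentration",
    "cross_protocol_calibration",
    "report_pdff",
]


def place_rois(mask: np.ndarray, n_rois: int = 8, roi_shape: tuple = (5, 5)) -> list:
    """Place ``n_rois`` disjoint fully-interior ROIs deterministically.

    The mask bounding box is partitioned into a grid (4 x 2 for eight ROIs,
    oriented along the longer box side); each cell's center is snapped to the
    nearest top-left position whose ROI lies fully inside the mask and does
    not overlap an earlier ROI. Raises ``ValueError`` when fewer than
    ``n_rois`` disjoint placements exist.
    """
    mask = np.asarray(mask, dtype=bool)
    rh, rw = roi_shape
    h, w = mask.shape
    if not mask.any():
        raise ValueError("empty mask")

    # all fully-interior top-left positions, via a sliding-window sum
    ok = np.zeros((h - rh + 1, w - rw + 1), dtype=bool) if h >= rh and w >= rw else np.zeros((0, 0), bool)
    if ok.size:
        csum = np.pad(mask.astype(np.int32), ((1, 0), (1, 0))).cumsum(0).cumsum(1)
        full = rh * rw
        window = (
            csum[rh:, rw:] - csum[:-rh, rw:] - csum[rh:, :-rw] + csum[:-rh, :-rw]
        )
        ok = window == full
    positions = np.argwhere(ok)
    if len(positions) < n_rois:
        raise ValueError(
            f"mask with {int(mask.sum())} voxels admits only {len(positions)} "
            f"interior {rh}x{rw} placements; {n_rois} required"
        )

    rows = np.where(mask.any(axis=1))[0]
    cols = np.where(mask.any(axis=0))[0]
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    box_h, box_w = r1 - r0, c1 - c0

    if n_rois == 8:
        grid = (2, 4) if box_w >= box_h else (4, 2)
    else:  # near-square grid for other counts
        g = int(np.ceil(np.sqrt(n_rois)))
        grid = (g, int(np.ceil(n_rois / g)))
    gr, gc = grid
    centers = []
    for i in range(gr):
        for j in range(gc):
            if len(centers) >= n_rois:
                break
            centers.append(
                (
                    r0 + (i + 0.5) * box_h / gr - rh / 2.0,
                    c0 + (j + 0.5) * box_w / gc - rw / 2.0,
                )
            )

    occupied = np.zeros_like(mask)
    chosen = []
    for cr, cc in centers:
        d2 = (positions[:, 0] - cr) ** 2 + (positions[:, 1] - cc) ** 2
        # deterministic: sort by distance then row-major position
        order = np.lexsort((positions[:, 1], positions[:, 0], d2))
        placed = False
        for k in order:
            pr, pc = positions[k]
            if occupied[pr : pr + rh, pc : pc + rw].any():
                continue
            occupied[pr : pr + rh, pc : pc + rw] = True
            chosen.append(ROI(row=int(pr), col=int(pc), height=rh, width=rw))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could only place {len(chosen)} of {n_rois} disjoint ROIs in a "
                f"mask of {int(mask.sum())} voxels"
            )
    return chosen


def select_roi(pdff_map: Union[PDFFMap, np.ndarray], rois: Sequence[ROI]) -> PDFFReport:
    """Report the mean PDFF (percent) of the lowest-s.d. ROI.

    Per-ROI mean and sample s.d. (n-1 denominator) of the PDFF fraction are
    computed; ROIs containing non-finite voxels are excluded with a warning;
    ties on s.d. resolve to the lowest ROI index. When the map carries an
    R2* image, the iron concentration for the selected ROI's mean R2* is
    attached.
    """
    if isinstance(pdff_map, PDFFMap):
        pdff = pdff_map.pdff
        r2star = pdff_map.r2star
    else:
        pdff = np.asarray(pdff_map, dtype=float)
        r2star = None

    stats = []
    for roi in rois:
        vals = pdff[roi.slices()]
        if vals.size != roi.n_voxels:
            raise ValueError(f"ROI {roi} extends beyond the map")
        finite = np.isfinite(vals).all()
        if not finite:
            warnings.warn(f"ROI at ({roi.row},{roi.col}) contains non-finite voxels; excluded")
            stats.append(ROIStats(roi=roi, mean=np.nan, sd=np.nan, excluded=True))
        else:
            stats.append(
                ROIStats(roi=roi, mean=float(vals.mean()), sd=float(vals.std(ddof=1)))
            )
    usable = [i for i, s in enumerate(stats) if not s.excluded]
    if not usable:
        raise ValueError("all ROIs excluded (non-finite voxels)")
    sds = np.array([stats[i].sd for i in usable])
    sel = usable[int(np.argmin(sds))]  # argmin takes the first minimum: lowest index
    selected = stats[sel]

    iron = None
    if r2star is not None:
        iron = float(iron_concentration(float(np.mean(r2star[selected.roi.slices()]))))
    return PDFFReport(
        rois=stats,
        selected_index=sel + 1,
        reported_pdff=100.0 * selected.mean,
        iron_mg_per_g=iron,
    )


def iron_concentration(
    r2star: Union[float, np.ndarray], cal: IronCalibration = IronCalibration()
) -> Union[float, np.ndarray]:
    """Iron concentration (mg/g) from R2* (1/s): intercept + slope * R2*."""
    arr = np.asarray(r2star, dtype=float)
    if np.any(arr < 0):
        raise ValueError("r2star must be non-negative")
    out = cal.intercept + cal.slope * arr
    return float(out) if np.isscalar(r2star) or arr.ndim == 0 else out


def cross_protocol_calibration(gre_pdff: Sequence[float], ideal_pdff: Optional[Sequence[float]] = None) -> tuple:
    """OLS line of IDEAL-reported PDFF on GRE-reported PDFF (both percent).

    Accepts either two sequences or a single iterable of (gre, ideal) pairs.
    Returns ``(slope, intercept, r_squared)``.
    """
    if ideal_pdff is None:
        pairs = np.asarray(gre_pdff, dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("expected (n, 2) array of (gre, ideal) pairs")
        x, y = pairs[:, 0], pairs[:, 1]
    else:
        x = np.asarray(gre_pdff, dtype=float)
        y = np.asarray(ideal_pdff, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired measurements")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: GRE PDFF has no variance")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def report_pdff(pdff_map: Union[PDFFMap, np.ndarray], mask: Optional[np.ndarray] = None) -> PDFFReport:
    """Convenience wrapper: place the eight ROIs and select the reported one."""
    if mask is None:
        if not isinstance(pdff_map, PDFFMap) or pdff_map.mask is None:
            raise ValueError("a liver mask is required")
        mask = pdff_map.mask
    rois = place_rois(mask)
    return select_roi(pdff_map, rois)
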