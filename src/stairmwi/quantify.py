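"""Voxel-wise apparent myelin water fraction (aMWF) mapping.

With long-T1 water suppressed, the STAIR image is modelled as pure
myelin-water signal and the PD image as total water, so the aMWF is a
scaled voxel-wise ratio:

    aMWF = k * S_STAIR / S_PD,
    k = e^{-TE_pd / T2*_total} /
        [(1 - q_mw e^{-TR/T1_mw} - (1 - q_mw) e^{-TI/T1_mw}) e^{-TE_stair / T2*_mw}]

with the fixed myelin-water constants (T1 = 220 ms, T2* = 10 ms,
q_mw = -0.75) and T2*_total = 60 ms.  The estimate is "apparent" because
residual long-T1 signal and the assumed constants leave a bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from stairmwi.errors import DomainError, GeometryError
from stairmwi.params import QuantConstants, SequenceParams
from stairmwi.phantom import ImageVolume
from stairmwi.signal_model import mw_signal_scale

__all__ = [
    "AMWFMap",
    "ROIStats",
    "amwf_scale_factor",
    "compute_amwf_map",
    "make_mask",
    "extract_roi_stats",
]


@dataclass(frozen=True)
class AMWFMap:
    """An aMWF map with its mask and the assumptions it was computed under."""

    volume: ImageVolume
    mask: np.ndarray
    constants_used: QuantConstants
    seq_stair: SequenceParams
    seq_pd: SequenceParams
    n_clipped_low: int = 0
    n_clipped_high: int = 0

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


@dataclass(frozen=True)
class ROIStats:
    """Summary of one region of interest on one subject's map."""

    roi_name: str
    n_voxels: int
    mean: float | None
    sd: float | None
    subject_id: str = ""


def amwf_scale_factor(
    constants: QuantConstants,
    seq_stair: SequenceParams,
    seq_pd: SequenceParams,
) -> float:
    """Calibration constant k mapping the STAIR/PD ratio to aMWF."""
    mw_scale = mw_signal_scale(constants, seq_stair)
    if mw_scale == 0.0:
        raise DomainError("myelin-water signal scale is zero for these constants")
    pd_scale = float(np.exp(-seq_pd.te_ms / constants.t2s_total_ms))
    return pd_scale / mw_scale


def make_mask(pd: ImageVolume, rel_threshold: float = 0.1) -> np.ndarray:
    """Brain mask: PD above a fraction of its robust maximum.

    The robust maximum is the 99th percentile of positive voxels; the
    largest connected component of the thresholded set is kept.
    """
    if not 0.0 < rel_threshold < 1.0:
        raise DomainError("rel_threshold must be in (0, 1)")
    data = np.abs(pd.data)
    positive = data[data > 0]
    if positive.size == 0:
        raise DomainError("PD volume has no positive voxels; cannot build a mask")
    robust_max = float(np.percentile(positive, 99))
    mask = data > rel_threshold * robust_max
    if not mask.any():
        raise DomainError("mask is empty at this threshold")
    labeled, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
        mask = labeled == (int(np.argmax(sizes)) + 1)
    return mask


def compute_amwf_map(
    stair: ImageVolume,
    pd: ImageVolume,
    constants: QuantConstants = QuantConstants(),
    seq_stair: SequenceParams | None = None,
    seq_pd: SequenceParams | None = None,
    mask: np.ndarray | None = None,
    pd_rel_threshold: float = 0.1,
    clip: bool = True,
) -> AMWFMap:
    """Compute the voxel-wise aMWF map from a STAIR/PD volume pair.

    Voxels where the PD signal falls below ``pd_rel_threshold`` of its
    robust maximum are excluded from the mask rather than divided through.
    Negative ratios are clipped to 0 and values above 1 to 1; the clip
    counts are recorded on the returned map.
    """
    from stairmwi.params import PD_PROTOCOL, STAIR_PROTOCOL

    seq_stair = seq_stair or STAIR_PROTOCOL
    seq_pd = seq_pd or PD_PROTOCOL
    if stair.shape != pd.shape:
        raise GeometryError(
            f"STAIR shape {stair.shape} != PD shape {pd.shape}")
    if not np.allclose(stair.affine, pd.affine, atol=1e-6):
        raise GeometryError("STAIR and PD volume orientations differ")
    if mask is None:
        mask = make_mask(pd, pd_rel_threshold)
    else:
        mask = np.asarray(mask, bool)
        if mask.shape != stair.shape:
            raise GeometryError("mask shape does not match the volumes")
        mask = mask & (np.abs(pd.data)
                       > pd_rel_threshold * float(np.percentile(
                           np.abs(pd.data)[np.abs(pd.data) > 0], 99)))
    if not mask.any():
        raise DomainError("empty mask")

    k = amwf_scale_factor(constants, seq_stair, seq_pd)
    amwf = np.zeros(stair.shape, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = k * stair.data / pd.data
    amwf[mask] = ratio[mask]

    n_lo = n_hi = 0
    if clip:
        n_lo = int(np.count_nonzero(amwf[mask] < 0.0))
        n_hi = int(np.count_nonzero(amwf[mask] > 1.0))
        amwf[mask] = np.clip(amwf[mask], 0.0, 1.0)

    vol = stair.with_data(amwf, kind="amwf", sequence="aMWF")
    return AMWFMap(
        volume=vol, mask=mask, constants_used=constants,
        seq_stair=seq_stair, seq_pd=seq_pd,
        n_clipped_low=n_lo, n_clipped_high=n_hi,
    )


def extract_roi_stats(
    amwf: AMWFMap,
    roi_map: np.ndarray | ImageVolume,
    roi_names: dict[int, str] | list[str],
    subject_id: str = "",
) -> list[ROIStats]:
    """Per-ROI mean and SD of the aMWF over in-mask voxels.

    ``roi_map`` is an integer label volume; ``roi_names`` maps the label
    codes to names (a list is interpreted as codes 1..len).  ROIs with no
    in-mask voxels are reported with ``n_voxels=0`` and absent mean/SD.
    """
    if isinstance(roi_map, ImageVolume):
        roi_map = roi_map.data
    roi_map = np.asarray(roi_map)
    if roi_map.shape != amwf.data.shape:
        raise GeometryError("ROI map shape does not match the aMWF map")
    if isinstance(roi_names, list):
        roi_names = {i + 1: n for i, n in enumerate(roi_names)}
    present = set(np.unique(roi_map[roi_map > 0]).tolist())
    stats: list[ROIStats] = []
    for code, name in roi_names.items():
        if code not in present:
            raise KeyError(f"ROI code {code} ({name}) absent from the ROI map")
        sel = (roi_map == code) & amwf.mask
        n = int(sel.sum())
        if n == 0:
            stats.append(ROIStats(name, 0, None, None, subject_id))
            continue
        vals = amwf.data[sel]
        stats.append(ROIStats(
            roi_name=name, n_voxels=n,
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if n > 1 else 0.0,
            subject_id=subject_id,
        ))
    return stats
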