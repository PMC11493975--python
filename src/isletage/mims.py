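"""MIMS raster quantification and MIMS->EM registration.

Turns multi-isotope count rasters into per-nucleus 15N/14N ratio
measurements and aligns MIMS pixel coordinates to electron-microscopy
coordinates via 32S fiducial landmarks.

The per-nucleus ratio is the ratio of *summed* counts over the ROI, not the
mean of per-pixel ratios: summed counts are the Poisson-optimal estimator
and per-pixel ratios are unstable wherever 14N counts are low.  For the same
reason frames are accumulated (summed element-wise) before taking ratios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

F_NAT = 0.0037

CHANNEL_ORDER = ("15N", "14N", "32S")


@dataclass
class MIMSFrame:
    """One multi-isotope count raster.

    channels maps isotope name ("15N", "14N", "32S") to an integer count
    raster; all channels share shape.  Counts are raw ion counts, so they
    must be non-negative integers.
    """

    channels: dict[str, np.ndarray]
    pixel_size_nm: float = 70.0
    n_frames_accumulated: int = 1

    def __post_init__(self):
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for ch, a in self.channels.items():
            if not np.issubdtype(a.dtype, np.integer):
                raise ValueError(f"channel {ch} must hold integer counts")
            if (a < 0).any():
                raise ValueError(f"channel {ch} contains negative counts")

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class NucleusMeasurement:
    """Summed counts and isotope ratio for one nucleus ROI.

    ratio r = sum15/sum14; atom fraction f = sum15/(sum15 + sum14);
    excess e = f - f_nat.  Excess may be slightly negative from counting
    noise on unlabeled nuclei and is reported as-is.
    """

    label_id: int
    sum15: float
    sum14: float
    ratio: float
    atom_fraction: float
    excess: float
    area_px: int


@dataclass(frozen=True)
class AffineTransform:
    """2D affine map x' = A x + b from MIMS to EM pixel coordinates."""

    linear: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)

    def __post_init__(self):
        if abs(np.linalg.det(self.linear)) <= 1e-12:
            raise ValueError("affine linear part is singular")

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(linear=inv, offset=-inv @ self.offset)


def accumulate(frames: list[MIMSFrame]) -> MIMSFrame:
    """Sum a stack of frames element-wise per channel.

    Pooling counts before ratioing is not the same as averaging per-frame
    ratios; the pooled ratio weights frames by their counts, which is the
    maximum-likelihood combination for Poisson data.
    """
    if not frames:
        raise ValueError("need at least one frame")
    first = frames[0]
    keys = set(first.channels)
    for fr in frames[1:]:
        if set(fr.channels) != keys:
            raise ValueError("frames have mismatched channel sets")
        if fr.shape != first.shape:
            raise ValueError("frames have mismatched shapes")
    summed = {
        ch: np.sum([fr.channels[ch] for fr in frames], axis=0) for ch in keys
    }
    return MIMSFrame(
        channels=summed,
        pixel_size_nm=first.pixel_size_nm,
        n_frames_accumulated=sum(fr.n_frames_accumulated for fr in frames),
    )


def segment_nuclei(
    frame: MIMSFrame,
    min_area_px: int = 50,
    threshold: float | None = None,
    channel: str = "14N",
) -> np.ndarray:
    """Segment nuclei: Otsu threshold + 8-connected components on an
    intensity channel, small objects dropped.

    The default channel is 14N, the usual structure channel when label
    levels are modest.  ``channel="total_n"`` thresholds on 15N + 14N
    instead, which tracks total nitrogen (DNA density) regardless of isotope
    composition and is the robust choice when nuclei may be nearly fully
    labeled (a saturated nucleus is dark in 14N alone).

    Returns an integer label raster (0 = background).  A blank raster yields
    an all-zero mask, not an error.  Callers with ground-truth masks bypass
    this entirely.
    """
    if channel == "total_n":
        if "14N" not in frame.channels or "15N" not in frame.channels:
            raise ValueError("total_n segmentation needs 15N and 14N channels")
        img = frame.channels["15N"] + frame.channels["14N"]
    else:
        if channel not in frame.channels:
            raise ValueError(f"{channel} channel required for segmentation")
        img = frame.channels[channel]
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=np.int32)
    thr = threshold_otsu(img) if threshold is None else threshold
    labeled = cc_label(img > thr, connectivity=2)
    out = np.zeros_like(labeled)
    next_id = 1
    for lab in range(1, labeled.max() + 1):
        mask = labeled == lab
        if mask.sum() >= min_area_px:
            out[mask] = next_id
            next_id += 1
    return out


def measure_nucleus(
    frame: MIMSFrame, mask: np.ndarray, label_id: int, f_nat: float = F_NAT
) -> NucleusMeasurement:
    """Summed-count ratio, atom fraction, and excess for one labeled nucleus."""
    roi = mask == label_id
    if not roi.any():
        raise ValueError(f"label {label_id} absent from mask")
    s15 = float(frame.channels["15N"][roi].sum())
    s14 = float(frame.channels["14N"][roi].sum())
    if s14 == 0:
        raise ValueError(f"nucleus {label_id} has zero 14N counts; unmeasurable")
    f = s15 / (s15 + s14)
    return NucleusMeasurement(
        label_id=label_id,
        sum15=s15,
        sum14=s14,
        ratio=s15 / s14,
        atom_fraction=f,
        excess=f - f_nat,
        area_px=int(roi.sum()),
    )


def measure_all_nuclei(
    frame: MIMSFrame, mask: np.ndarray, f_nat: float = F_NAT
) -> list[NucleusMeasurement]:
    """measure_nucleus for every nonzero label in the mask, ascending."""
    return [
        measure_nucleus(frame, mask, int(lab), f_nat)
        for lab in np.unique(mask)
        if lab != 0
    ]


def measurements_to_frame(measurements: list[NucleusMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label_id": [m.label_id for m in measurements],
            "area_px": [m.area_px for m in measurements],
            "sum15": [m.sum15 for m in measurements],
            "sum14": [m.sum14 for m in measurements],
            "ratio": [m.ratio for m in measurements],
            "atom_fraction": [m.atom_fraction for m in measurements],
            "excess": [m.excess for m in measurements],
        }
    )


# ---------------------------------------------------------------------------
# Fiducial registration
# ---------------------------------------------------------------------------


def fit_fiducial_affine(
    mims_points: np.ndarray, em_points: np.ndarray
) -> tuple[AffineTransform, np.ndarray]:
    """Least-squares affine from MIMS fiducial coordinates to EM coordinates.

    Needs >= 3 non-collinear point pairs.  Returns the transform and the
    per-point residual vectors (n, 2) at the fitted solution.
    """
    P = np.atleast_2d(np.asarray(mims_points, dtype=float))
    Q = np.atleast_2d(np.asarray(em_points, dtype=float))
    if P.shape != Q.shape or P.shape[1] != 2:
        raise ValueError("point sets must be matching (n, 2) arrays")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 fiducial pairs")
    design = np.hstack([P, np.ones((P.shape[0], 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("fiducial points are collinear; affine is degenerate")
    coef, *_ = np.linalg.lstsq(design, Q, rcond=None)
    linear = coef[:2].T
    offset = coef[2]
    transform = AffineTransform(linear=linear, offset=offset)
    residuals = Q - (P @ linear.T + offset)
    return transform, residuals


def apply_transform(t: AffineTransform, points: np.ndarray) -> np.ndarray:
    """Map (n, 2) points with x' = A x + b."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    return P @ t.linear.T + t.offset


def apply_transform_mask(
    t: AffineTransform, mask: np.ndarray, out_shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Map a label mask pixel-wise with nearest-neighbor rounding."""
    out_shape = mask.shape if out_shape is None else out_shape
    out = np.zeros(out_shape, dtype=mask.dtype)
    rows, cols = np.nonzero(mask)
    pts = apply_transform(t, np.column_stack([rows, cols]))
    rr = np.rint(pts[:, 0]).astype(int)
    cc = np.rint(pts[:, 1]).astype(int)
    ok = (rr >= 0) & (rr < out_shape[0]) & (cc >= 0) & (cc < out_shape[1])
    out[rr[ok], cc[ok]] = mask[rows[ok], cols[ok]]
    return out


# ---------------------------------------------------------------------------
# File IO (multi-channel TIFF as written by the synthetic generators)
# ---------------------------------------------------------------------------


def write_frame_tiff(frame: MIMSFrame, path: str | Path) -> None:
    """16-bit multi-channel TIFF, channel order (15N, 14N, 32S), with a
    JSON sidecar carrying pixel geometry."""
    path = Path(path)
    stack = np.stack(
        [frame.channels[ch].astype(np.uint16) for ch in CHANNEL_ORDER if ch in frame.channels]
    )
    tifffile.imwrite(path, stack, photometric="minisblack", planarconfig="separate")
    sidecar = {
        "channels": [ch for ch in CHANNEL_ORDER if ch in frame.channels],
        "pixel_size_nm": frame.pixel_size_nm,
        "n_frames_accumulated": frame.n_frames_accumulated,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_frame_tiff(path: str | Path) -> MIMSFrame:
    path = Path(path)
    stack = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    channels = {
        ch: stack[i].astype(np.int64) for i, ch in enumerate(sidecar["channels"])
    }
    return MIMSFrame(
        channels=channels,
        pixel_size_nm=sidecar["pixel_size_nm"],
        n_frames_accumulated=sidecar["n_frames_accumulated"],
    )
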