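"""Ratiometric quantification of in vivo biosensor imaging data.

Excitation- or emission-ratiometric sensors (ATP/ADP, ATP, pH, redox,
calcium) report their analyte as the ratio of two channel intensities.
The quantification contract implemented here:

1. per-channel background (median of non-ROI voxels) is subtracted;
2. each axon's ratio is the mean over three equal sub-regions along the
   axon of the per-region mean pixel-by-pixel ratio;
3. ratios are normalised to the control-group mean to remove batch
   differences;
4. for FRET sensors the acceptor channel is first corrected for donor
   crosstalk (``cFRET = acceptor - alpha * donor``).

Morphometric and threshold-based readouts (mitochondrial shape factor,
outlier fractions above control mean + k s.d., paired near/far lesion
gradients, marker occupancy within a reference mask, COX-active area) use
the same conventions throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ImageStack:
    """Multi-channel volume plus an ROI label mask.

    ``data`` has shape (channels, z, y, x); ``mask`` has shape (z, y, x)
    with 0 = background and k > 0 = ROI (axon) id.
    """

    data: np.ndarray
    mask: np.ndarray
    voxel_size_um: tuple[float, float, float] | None = None
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.data.ndim != 4:
            raise ValueError("data must be (channels, z, y, x)")
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("mask shape must equal the spatial shape")
        if (self.data < 0).any():
            raise ValueError("negative intensities")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def roi_ids(self) -> np.ndarray:
        ids = np.unique(self.mask)
        return ids[ids > 0]


def subtract_background(stack: ImageStack) -> tuple[ImageStack, np.ndarray]:
    """Subtract the per-channel background (median of non-ROI voxels).

    Corrected voxels are clipped at zero.  Returns the corrected stack and
    the per-channel background estimates.
    """
    bg_voxels = stack.mask == 0
    if not bg_voxels.any():
        raise ValueError("mask contains no background voxels")
    background = np.array(
        [np.median(stack.data[c][bg_voxels]) for c in range(stack.n_channels)]
    )
    corrected = np.clip(stack.data - background[:, None, None, None], 0.0, None)
    out = ImageStack(
        corrected, stack.mask, stack.voxel_size_um, stack.channel_names
    )
    return out, background


def _partition_along_axis(coords: np.ndarray, n_regions: int) -> list[np.ndarray]:
    """Split voxel coordinates into ``n_regions`` equal slabs along the
    principal axis of the point cloud (deterministic region placement)."""
    centered = coords - coords.mean(axis=0)
    # principal direction via SVD of the coordinate cloud
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    order = np.argsort(proj, kind="mergesort")
    return [np.sort(chunk) for chunk in np.array_split(order, n_regions)]


def axon_ratio(
    stack: ImageStack,
    axon_id: int,
    *,
    numerator: int = 0,
    denominator: int = 1,
    n_regions: int = 3,
    convention: Literal["mean_of_ratios", "ratio_of_means"] = "mean_of_ratios",
) -> float:
    """Raw ratio of one axon: mean over ``n_regions`` sub-regions of the
    region-wise channel ratio.

    Regions are equal slabs along the axon's principal axis.  With the
    default convention each region contributes the mean of its pixel-wise
    ratios; ``ratio_of_means`` instead divides the region's channel means.
    Returns NaN (with a warning) when a denominator region mean is <= 0.
    """
    sel = stack.mask == axon_id
    if not sel.any():
        raise ValueError(f"axon id {axon_id} not present in mask")
    coords = np.argwhere(sel)
    if len(coords) < n_regions:
        raise ValueError(
            f"axon {axon_id} has {len(coords)} voxels < {n_regions} regions"
        )
    num = stack.data[numerator][sel]
    den = stack.data[denominator][sel]
    regions = _partition_along_axis(coords.astype(float), n_regions)
    vals = []
    for region in regions:
        n = num[region]
        d = den[region]
        if d.mean() <= 0:
            warnings.warn(f"axon {axon_id}: denominator region mean <= 0; invalid")
            return float("nan")
        if convention == "mean_of_ratios":
            ok = d > 0
            if not ok.any():
                warnings.warn(f"axon {axon_id}: empty denominator; invalid")
                return float("nan")
            vals.append(float(np.mean(n[ok] / d[ok])))
        else:
            vals.append(float(n.mean() / d.mean()))
    return float(np.mean(vals))


def normalize_to_control(
    values: Sequence[float] | pd.Series, control_values: Sequence[float]
) -> np.ndarray | pd.Series:
    """Divide measurements by the control-group mean (batch normalisation).

    After normalisation the control group has mean 1 by construction.
    """
    control = np.asarray(control_values, dtype=float)
    control = control[np.isfinite(control)]
    if control.size == 0:
        raise ValueError("empty control set")
    mean = control.mean()
    if mean <= 0:
        raise ValueError("control mean must be positive")
    if isinstance(values, pd.Series):
        return values / mean
    return np.asarray(values, dtype=float) / mean


def cfret(
    donor: np.ndarray | float, acceptor: np.ndarray | float, alpha: float
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Crosstalk-corrected FRET signal and cFRET:donor ratio.

    ``cFRET = acceptor - alpha * donor`` removes the donor bleed-through
    fraction ``alpha`` from the acceptor channel.  Records with donor <= 0
    are invalid (NaN); negative cFRET is kept but flagged by a warning.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    donor_a = np.asarray(donor, dtype=float)
    acceptor_a = np.asarray(acceptor, dtype=float)
    corrected = acceptor_a - alpha * donor_a
    if np.any(corrected < 0):
        warnings.warn("negative cFRET after crosstalk correction")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(donor_a > 0, corrected / donor_a, np.nan)
    if np.isscalar(donor) or np.ndim(donor) == 0:
        return float(corrected), float(ratio)
    return corrected, ratio


def outlier_fraction(
    values_by_stage: dict[int, Sequence[float]],
    control_values: Sequence[float],
    *,
    k: float = 3.0,
) -> pd.Series:
    """Per-stage fraction of measurements above control mean + k s.d.

    The threshold uses the sample (n-1) standard deviation of the control
    values.  Under a Gaussian null with k=3 the expected fraction is the
    upper tail 1 - Phi(3) ~ 0.00135.
    """
    control = np.asarray(control_values, dtype=float)
    if control.size < 2:
        raise ValueError("need >= 2 control values")
    threshold = control.mean() + k * control.std(ddof=1)
    out = {}
    for stage, vals in values_by_stage.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        out[stage] = float(np.mean(v > threshold)) if v.size else float("nan")
    return pd.Series(out, name="outlier_fraction")


def paired_gradient(axon_table: pd.DataFrame) -> dict[str, float]:
    """Paired near-versus-far analysis of axons traced through a lesion.

    ``axon_table`` needs columns ``axon_id``, ``location`` ('far'/'near')
    and ``value``; axons lacking either location are dropped with a
    warning.  Returns the mean (near - far) difference with a two-sided
    paired t-test; a zero-variance difference is reported as t=0/p=1 when
    the mean difference is 0, and t=+-inf/p=0 otherwise.
    """
    wide = axon_table.pivot_table(
        index="axon_id", columns="location", values="value", aggfunc="mean"
    )
    for col in ("far", "near"):
        if col not in wide.columns:
            raise ValueError(f"no {col!r} measurements present")
    complete = wide.dropna(subset=["far", "near"])
    dropped = len(wide) - len(complete)
    if dropped:
        warnings.warn(f"dropped {dropped} axons without both far and near values")
    if len(complete) < 2:
        raise ValueError("need >= 2 paired axons")
    diff = (complete["near"] - complete["far"]).values
    mean_diff = float(diff.mean())
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.isclose(mean_diff, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(mean_diff)) * np.inf, 0.0
    else:
        t, p = stats.ttest_rel(complete["near"], complete["far"])
    return {"mean_diff": mean_diff, "t": float(t), "p": float(p), "n": len(complete)}


def marker_quantification(
    image: np.ndarray,
    reference_mask: np.ndarray,
    *,
    intensity_cutoff_factor: float = 1.2,
    min_size_px: int = 4,
) -> dict[str, float]:
    """Occupancy, mean fluorescence intensity and integrated density of
    marker-positive puncta within a reference (e.g. neurofilament) mask.

    Puncta are connected components of pixels above
    ``intensity_cutoff_factor x`` the mean intensity inside the reference
    mask, restricted to the mask, and kept only if at least
    ``min_size_px`` pixels.  ``integrated_density = occupancy x MFI``.
    """
    from skimage import measure

    image = np.asarray(image, dtype=float)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if image.shape != reference_mask.shape:
        raise ValueError("image and reference mask shapes differ")
    ref_area = int(reference_mask.sum())
    if ref_area == 0:
        raise ValueError("empty reference mask")
    threshold = intensity_cutoff_factor * image[reference_mask].mean()
    candidate = (image > threshold) & reference_mask
    labels = measure.label(candidate)
    puncta = np.zeros_like(candidate)
    for region in measure.regionprops(labels):
        if region.area >= min_size_px:
            puncta[labels == region.label] = True
    area = int(puncta.sum())
    occupancy = area / ref_area
    if area == 0:
        return {
            "occupancy": 0.0,
            "mfi": 0.0,
            "integrated_density": 0.0,
            "n_puncta": 0,
            "no_puncta": True,
        }
    mfi = float(image[puncta].mean())
    n_puncta = len({r.label for r in measure.regionprops(labels) if r.area >= min_size_px})
    return {
        "occupancy": float(occupancy),
        "mfi": mfi,
        "integrated_density": float(occupancy * mfi),
        "n_puncta": n_puncta,
        "no_puncta": False,
    }


def cox_occupancy(
    axon_mask: np.ndarray,
    cox_positive: np.ndarray,
    *,
    axon_length_um: float | None = None,
    min_length_um: float = 25.0,
) -> float:
    """Percentage of the axonal area occupied by COX-active elements.

    COX (cytochrome c oxidase, respiratory complex IV) histochemistry marks
    enzymatically active mitochondria; occupancy is
    ``100 * |COX+ and axon| / |axon|``.  Axons shorter than
    ``min_length_um`` (when a length is supplied) are rejected.
    """
    axon_mask = np.asarray(axon_mask, dtype=bool)
    cox_positive = np.asarray(cox_positive, dtype=bool)
    if axon_mask.shape != cox_positive.shape:
        raise ValueError("mask shapes differ")
    area = int(axon_mask.sum())
    if area == 0:
        raise ValueError("empty axon mask")
    if axon_length_um is not None and axon_length_um < min_length_um:
        raise ValueError(
            f"axon length {axon_length_um} um below minimum {min_length_um} um"
        )
    return 100.0 * int((cox_positive & axon_mask).sum()) / area


def shape_factor(length: float, width: float) -> float:
    """Mitochondrial shape factor: length divided by width (1 = round)."""
    if width <= 0:
        raise ValueError("width must be positive")
    return length / width
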