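"""Image-derived readouts for stress-granule assays.

Operators mirror a standard high-content workflow: nuclei from a blurred,
thresholded DNA channel; cytoplasmic granules from an unsharp-masked,
thresholded reporter channel with anything touching a nucleus discarded;
and scalar per-field statistics built on top (granules per cell, percent of
cells with >= k granules, nuclear partition, compartment partition
coefficients of a labelled analog).

Conventions: "5-pixel Gaussian blur" is sigma = 5 px; the unsharp filter is
(image - w * blur(image, sigma)) / (1 - w) with w = 0.9, sigma = 10 px.
Fields are 2-D; project z-stacks before input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label

__all__ = [
    "FieldImage",
    "SegmentationResult",
    "segment_nuclei",
    "detect_granules",
    "granules_per_cell",
    "nuclear_partition",
    "pct_cells_with_granules",
    "compartment_partition",
    "quantify_field",
]


@dataclass
class FieldImage:
    """Named 2-D channels of one field of view, sharing a common shape."""

    channels: dict
    pixel_size: float = 1.0  # um per px
    field_id: str = "field_0"

    def __post_init__(self) -> None:
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels disagree in shape: {shapes}")
        for name, arr in self.channels.items():
            a = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(a)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            self.channels[name] = a

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class SegmentationResult:
    nuclei_mask: np.ndarray
    granule_mask: np.ndarray
    compartment_masks: dict = field(default_factory=dict)

    @property
    def n_nuclei(self) -> int:
        return int(self.nuclei_mask.max())

    @property
    def n_granules(self) -> int:
        return int(self.granule_mask.max())


def _threshold(img: np.ndarray, threshold) -> np.ndarray:
    if threshold == "otsu":
        if img.max() == img.min():  # blank field: nothing above threshold
            return np.zeros(img.shape, dtype=bool)
        return img > threshold_otsu(img)
    return img > float(threshold)


def _drop_small(labels: np.ndarray, min_area: int) -> np.ndarray:
    if min_area <= 1 or labels.max() == 0:
        return labels
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return sk_label(keep[labels])


def segment_nuclei(
    dna: np.ndarray,
    blur_sigma_px: float = 5.0,
    threshold="otsu",
    min_area_px: int = 50,
) -> np.ndarray:
    """Label nuclei: Gaussian blur, intensity threshold, connected components.

    Blank images yield zero labels.  ``threshold`` is ``"otsu"`` or a fixed
    intensity value; components below ``min_area_px`` are discarded as noise.
    """
    dna = np.asarray(dna, dtype=float)
    if dna.ndim != 2:
        raise ValueError("expected a 2-D channel")
    smooth = gaussian(dna, sigma=blur_sigma_px, preserve_range=True)
    return _drop_small(sk_label(_threshold(smooth, threshold)), min_area_px)


def unsharp(image: np.ndarray, radius_px: float = 10.0, weight: float = 0.9) -> np.ndarray:
    """Unsharp enhancement (image - w * blur) / (1 - w), preserving range."""
    blur = gaussian(image, sigma=radius_px, preserve_range=True)
    return (image - weight * blur) / (1.0 - weight)


def detect_granules(
    reporter: np.ndarray,
    nuclei: np.ndarray,
    unsharp_radius_px: float = 10.0,
    unsharp_weight: float = 0.9,
    threshold="otsu",
    min_area_px: int = 2,
) -> np.ndarray:
    """Label cytoplasmic granules in the reporter channel.

    Unsharp-mask, threshold, label, then remove every component that
    overlaps the nuclei mask (intranuclear puncta are not cytoplasmic
    granules), so the output mask is disjoint from the nuclei by
    construction.
    """
    reporter = np.asarray(reporter, dtype=float)
    if reporter.shape != np.asarray(nuclei).shape:
        raise ValueError("reporter and nuclei mask must share shape")
    enhanced = unsharp(reporter, unsharp_radius_px, unsharp_weight)
    lab = _drop_small(sk_label(_threshold(enhanced, threshold)), min_area_px)
    if lab.max():
        overlapping = np.unique(lab[(lab > 0) & (np.asarray(nuclei) > 0)])
        if overlapping.size:
            lab[np.isin(lab, overlapping)] = 0
            lab = sk_label(lab > 0)
    return lab


def granules_per_cell(n_granules: int, n_nuclei: int) -> float:
    """Cytoplasmic granules per cell for one field; NaN when no nuclei found."""
    if n_nuclei < 1:
        return float("nan")
    return n_granules / n_nuclei


def nuclear_partition(v_n: float, v_t: float) -> float:
    """Nuclear partition p = a / (1 - a) with a = v_n / v_t per field.

    ``v_n`` is the summed reporter signal inside nuclei, ``v_t`` the summed
    total reporter signal; requires 0 < v_n < v_t.
    """
    if not 0 < v_n < v_t:
        raise ValueError("need 0 < nuclear signal < total signal")
    a = v_n / v_t
    return a / (1.0 - a)


def pct_cells_with_granules(per_cell_counts, k: int = 3) -> float:
    """Percent of cells carrying at least ``k`` granules."""
    counts = np.asarray(per_cell_counts)
    if counts.size == 0:
        raise ValueError("empty count list")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return 100.0 * float(np.mean(counts >= k))


def compartment_partition(analog: np.ndarray, masks: dict) -> dict:
    """Mean-intensity partition coefficient of each compartment vs residual cytoplasm.

    ``masks`` maps compartment names to boolean masks and must contain
    ``"cytoplasm_rest"`` (cytoplasm excluding granules and mitochondria),
    the reference compartment.  Masks must be pairwise disjoint.  An empty
    compartment yields NaN for that compartment.
    """
    analog = np.asarray(analog, dtype=float)
    if "cytoplasm_rest" not in masks:
        raise ValueError("masks must include 'cytoplasm_rest' as reference")
    names = list(masks)
    for i, n1 in enumerate(names):
        for n2 in names[i + 1:]:
            if np.any(np.asarray(masks[n1], bool) & np.asarray(masks[n2], bool)):
                raise ValueError(f"compartment masks {n1!r} and {n2!r} overlap")
    ref_mask = np.asarray(masks["cytoplasm_rest"], bool)
    if not ref_mask.any():
        raise ValueError("cytoplasm_rest mask is empty")
    ref = analog[ref_mask].mean()
    out = {}
    for name, mask in masks.items():
        m = np.asarray(mask, bool)
        out[name] = float(analog[m].mean() / ref) if m.any() else float("nan")
    return out


def quantify_field(
    image: FieldImage,
    dna_channel: str = "dna",
    reporter_channel: str = "reporter",
    **kwargs,
) -> dict:
    """Segment one field and return its scalar statistics.

    Returns n_nuclei, n_granules, granules_per_cell and the nuclear
    partition of the reporter (NaN if degenerate).
    """
    nuclei = segment_nuclei(image[dna_channel], **{
        k: v for k, v in kwargs.items() if k in ("blur_sigma_px", "threshold", "min_area_px")
    })
    granules = detect_granules(image[reporter_channel], nuclei)
    rep = image[reporter_channel]
    v_n, v_t = float(rep[nuclei > 0].sum()), float(rep.sum())
    try:
        p = nuclear_partition(v_n, v_t)
    except ValueError:
        p = float("nan")
    return {
        "field_id": image.field_id,
        "n_nuclei": int(nuclei.max()),
        "n_granules": int(granules.max()),
        "granules_per_cell": granules_per_cell(int(granules.max()), int(nuclei.max())),
        "nuclear_partition": p,
    }
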