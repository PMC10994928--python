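"""Live / apoptotic / dead quantification from three-channel micrographs.

The assay counts all nuclei in a counterstain channel, then scores each
nucleus against an apoptosis-reporter mask and a death-reporter mask:

* death-positive (alone or together with the apoptosis reporter, the
  "yellow" double-positive phenotype) -> dead;
* apoptosis-positive and not death-positive -> apoptotic;
* live = total - apoptotic - dead.

Counts are reported as percentages of the total nucleus count.  Two staining
schemes share this logic: caspase reporter + propidium iodide, and the
NucBlue/NucGreen kit used for channelrhodopsin-expressing cultures.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import local_maxima
from skimage.segmentation import watershed

from .simulate import CellImageSet  # canonical image container

__all__ = [
    "CellCounts",
    "threshold_channel",
    "segment_nuclei",
    "classify_cells",
    "summarize_viability",
    "count_image",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellCounts:
    """Per-image counts; live + apoptotic + dead = total by construction."""

    total: int
    live: int
    apoptotic: int
    dead: int

    def __post_init__(self) -> None:
        if self.live + self.apoptotic + self.dead != self.total:
            raise ValueError("counts must satisfy live + apoptotic + dead = total")
        if min(self.total, self.live, self.apoptotic, self.dead) < 0:
            raise ValueError("counts must be non-negative")

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.total if self.total else 0.0

    @property
    def pct_live(self) -> float:
        return self._pct(self.live)

    @property
    def pct_apoptotic(self) -> float:
        return self._pct(self.apoptotic)

    @property
    def pct_dead(self) -> float:
        return self._pct(self.dead)


def threshold_channel(
    channel: np.ndarray, method: str = "otsu", fixed_value: Optional[float] = None
) -> np.ndarray:
    """Binary foreground mask of one fluorescence channel.

    ``method="otsu"`` uses Otsu's threshold with a robust floor at
    median + 5 scaled MADs of the image, so a channel containing no signal
    (only background noise, where Otsu would split the noise itself) yields
    an essentially empty mask.  ``method="fixed"`` applies ``fixed_value``
    directly, for exact-reproduction workflows.
    """
    img = np.asarray(channel)
    if img.size == 0:
        raise ValueError("empty image")
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed thresholding requires fixed_value")
        thr = float(fixed_value)
    elif method == "otsu":
        if img.max() == img.min():
            warnings.warn("constant image: degenerate threshold, full foreground")
            return np.ones_like(img, dtype=bool) if img.max() > 0 else np.zeros_like(img, dtype=bool)
        med = float(np.median(img))
        mad = float(np.median(np.abs(img.astype(float) - med)))
        floor = med + 5.0 * 1.4826 * mad
        thr = max(float(threshold_otsu(img)), floor)
    else:
        raise ValueError(f"unknown method {method!r}")
    logger.info("threshold_channel: method=%s value=%.6g", method, thr)
    return img > thr


def segment_nuclei(
    mask: np.ndarray,
    nucleus_radius: float = 8.0,
    min_area: Optional[float] = None,
    max_area: Optional[float] = None,
    split_touching: bool = True,
) -> np.ndarray:
    """Label individual nuclei in a binary counterstain mask.

    Connected components are filtered by area (defaults derived from the
    expected nucleus radius); optionally a distance-transform watershed
    splits touching nuclei whose distance maxima are separated.
    Returns a labeled integer image.
    """
    mask = np.asarray(mask, dtype=bool)
    if min_area is None:
        min_area = 0.15 * math.pi * nucleus_radius**2
    if max_area is None:
        max_area = 6.0 * math.pi * nucleus_radius**2
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)

    if split_touching:
        distance = ndi.distance_transform_edt(mask)
        # suppress spurious maxima from boundary roughness
        smoothed = ndi.gaussian_filter(distance, sigma=max(1.0, nucleus_radius / 4.0))
        peaks = local_maxima(smoothed) & (distance > 0.4 * nucleus_radius)
        markers = sk_label(peaks)
        if markers.max() == 0:
            labels = sk_label(mask)
        else:
            labels = watershed(-smoothed, markers, mask=mask)
    else:
        labels = sk_label(mask)

    out = np.zeros(mask.shape, dtype=np.int32)
    next_id = 1
    for region_id in range(1, labels.max() + 1):
        area = int((labels == region_id).sum())
        if min_area <= area <= max_area:
            out[labels == region_id] = next_id
            next_id += 1
    return out


def classify_cells(
    labels: np.ndarray,
    apoptosis_mask: np.ndarray,
    death_mask: np.ndarray,
    assay_variant: str = "caspase_pi",
    overlap_fraction: float = 0.3,
) -> CellCounts:
    """Score each labeled nucleus against the two reporter masks.

    A nucleus is reporter-positive when the reporter mask covers at least
    ``overlap_fraction`` of its area (default 30%, guarding against
    bleed-through).  Death-positive nuclei count as dead regardless of the
    apoptosis reporter; apoptosis-only nuclei count as apoptotic.  Both
    assay variants share this classification.
    """
    labels = np.asarray(labels)
    if labels.shape != np.asarray(apoptosis_mask).shape or labels.shape != np.asarray(death_mask).shape:
        raise ValueError("labels and masks must share one shape")
    if assay_variant not in ("caspase_pi", "nucblue_nucgreen"):
        raise ValueError(f"unknown assay_variant {assay_variant!r}")
    n = int(labels.max())
    if n == 0:
        return CellCounts(0, 0, 0, 0)
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    apo_over = np.bincount(labels.ravel(), weights=np.asarray(apoptosis_mask, bool).ravel(), minlength=n + 1)[1:]
    dead_over = np.bincount(labels.ravel(), weights=np.asarray(death_mask, bool).ravel(), minlength=n + 1)[1:]
    with np.errstate(invalid="ignore"):
        apo_pos = apo_over / areas >= overlap_fraction
        dead_pos = dead_over / areas >= overlap_fraction
    dead = int(dead_pos.sum())
    apoptotic = int((apo_pos & ~dead_pos).sum())
    live = n - apoptotic - dead
    return CellCounts(total=n, live=live, apoptotic=apoptotic, dead=dead)


def count_image(
    images: CellImageSet,
    nucleus_radius: float = 8.0,
    method: str = "otsu",
    overlap_fraction: float = 0.3,
    split_touching: bool = True,
) -> CellCounts:
    """Full per-image pipeline: threshold all channels, segment nuclei,
    classify against the reporter masks."""
    nuc_mask = threshold_channel(images.nuclei_channel, method=method)
    apo_mask = threshold_channel(images.apoptosis_channel, method=method)
    dead_mask = threshold_channel(images.death_channel, method=method)
    labels = segment_nuclei(nuc_mask, nucleus_radius=nucleus_radius, split_touching=split_touching)
    return classify_cells(
        labels, apo_mask, dead_mask, assay_variant=images.assay_variant,
        overlap_fraction=overlap_fraction,
    )


def summarize_viability(
    counts: Sequence[CellCounts], groups: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Mean +/- SEM of per-image percentages within culture groups.

    Returns a table indexed by group with columns
    ``pct_<class>_mean`` / ``pct_<class>_sem`` and ``n_images``; feeds the
    two-group comparison harness (Mann-Whitney between conditions).
    """
    if not counts:
        raise ValueError("need at least one image")
    if groups is None:
        groups = ["all"] * len(counts)
    if len(groups) != len(counts):
        raise ValueError("groups must match counts")
    df = pd.DataFrame(
        {
            "group": list(groups),
            "pct_live": [c.pct_live for c in counts],
            "pct_apoptotic": [c.pct_apoptotic for c in counts],
            "pct_dead": [c.pct_dead for c in counts],
        }
    )
    out = {}
    for g, sub in df.groupby("group", sort=True):
        row = {"n_images": len(sub)}
        for col in ("pct_live", "pct_apoptotic", "pct_dead"):
            x = sub[col].to_numpy()
            row[f"{col}_mean"] = float(np.mean(x))
            row[f"{col}_sem"] = (
                float(np.std(x, ddof=1) / math.sqrt(x.size)) if x.size > 1 else float("nan")
            )
        out[g] = row
    return pd.DataFrame(out).T
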