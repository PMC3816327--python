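"""Patch-of-interest definition from feature-mapping contrasts.

The eye and mouth patches are the voxels exceeding +/- a strict t threshold
(default 3.2) on the eye-minus-mouth checkerboard contrast; the rest-of-V1
patch is the V1 mask minus DILATED versions of those patches (every voxel
exceeding a lowered threshold), intersected with a stimulus-responsive map
(all faces minus baseline, Bonferroni-corrected p < 1e-4 by default).  The
dilation-subtraction keeps a buffer ring between the diagnostic patches and
the rest region.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .glm import TMap

__all__ = [
    "Poi",
    "fdr_threshold",
    "define_feature_pois",
    "rest_of_v1",
    "responsive_voxels",
]


@dataclass
class Poi:
    """A named set of voxel indices with its defining threshold/contrast."""

    name: str
    voxel_indices: np.ndarray
    defining_threshold: float
    contrast: str = ""

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.voxel_indices, dtype=int))
        self.voxel_indices = idx

    @property
    def size(self) -> int:
        return self.voxel_indices.size

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "indices": self.voxel_indices.tolist(),
                "threshold": self.defining_threshold,
                "contrast": self.contrast,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Poi":
        d = json.loads(text)
        return cls(
            name=d["name"],
            voxel_indices=np.asarray(d["indices"], dtype=int),
            defining_threshold=float(d["threshold"]),
            contrast=d.get("contrast", ""),
        )


def fdr_threshold(p_values, q: float = 0.01) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up FDR control.

    Returns the boolean rejection mask and the critical p value (largest
    rejected p, 0 when nothing is rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    crit = float(p[reject].max()) if reject.any() else 0.0
    return reject, crit


def define_feature_pois(tmap: TMap, threshold: float) -> tuple[Poi, Poi]:
    """Eye/mouth patches from a signed eye-minus-mouth t contrast.

    Eye voxels have ``t >= +threshold``, mouth voxels ``t <= -threshold``;
    the two are disjoint by the sign partition.  Empty patches warn rather
    than fail (thresholds are adjusted per subject in practice).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = np.asarray(tmap.t, dtype=float)
    eye = Poi("eye", np.flatnonzero(t >= threshold), threshold, tmap.contrast_label or "eye-minus-mouth")
    mouth = Poi("mouth", np.flatnonzero(t <= -threshold), threshold, tmap.contrast_label or "eye-minus-mouth")
    for p in (eye, mouth):
        if p.size == 0:
            warnings.warn(f"{p.name} POI is empty at threshold {threshold}", stacklevel=2)
    return eye, mouth


def _as_indices(mask_or_indices, n: int) -> np.ndarray:
    arr = np.asarray(mask_or_indices)
    if arr.dtype == bool:
        return np.flatnonzero(arr)
    return np.unique(arr.astype(int))


def rest_of_v1(
    v1_mask,
    tmap: TMap,
    strict_threshold: float,
    lowered_threshold: float,
    responsive_map,
) -> Poi:
    """Rest-of-V1 = (V1 minus dilated eye/mouth patches) intersected with the
    responsive map.

    The dilated patches are all voxels with ``|t| >= lowered_threshold``
    (which must be below the strict patch threshold), so a buffer ring of
    sub-strict but supra-lowered voxels separates the rest region from the
    diagnostic patches.
    """
    if lowered_threshold >= strict_threshold:
        raise ValueError("lowered threshold must be below the strict threshold")
    t = np.asarray(tmap.t, dtype=float)
    v1 = _as_indices(v1_mask, t.size)
    responsive = _as_indices(responsive_map, t.size)
    dilated = np.flatnonzero(np.abs(t) >= lowered_threshold)
    rest = np.setdiff1d(np.setdiff1d(v1, dilated), np.setdiff1d(v1, responsive))
    return Poi("rest_v1", rest, lowered_threshold, "v1-minus-dilated-feature-patches")


def responsive_voxels(
    tmap: TMap,
    p_threshold: float = 1e-4,
    correction: str = "bonferroni",
) -> np.ndarray:
    """Stimulus-responsive voxels from an all-faces-minus-baseline contrast
    (two-sided p below ``p_threshold`` after multiple-comparison correction)."""
    p = tmap.p_values("two-sided")
    if p.size == 0:
        return np.zeros(0, dtype=int)
    if correction == "bonferroni":
        reject = p * p.size < p_threshold
    elif correction == "fdr":
        reject, _ = fdr_threshold(p, q=p_threshold)
    elif correction == "none":
        reject = p < p_threshold
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return np.flatnonzero(reject)
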