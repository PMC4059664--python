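"""Evaluation statistics for combined MP2RAGE images.

Covers the quantities used to judge the robust combination against the
uniform one: background-noise statistics (mean, std, and the fraction of
background voxels spread away from the suppressed level), the per-tissue
bias-ratio map robust/uniform, simple tissue contrast summaries, a
magnitude-threshold masking baseline, and repeat-scan volumetric
reproducibility (mean and worst-case relative volume difference across
segmented structures).
"""

from __future__ import annotations

import warnings
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .combination import CombinedImage

__all__ = [
    "background_stats",
    "bias_ratio",
    "tissue_contrast",
    "volumetric_reproducibility",
    "mask_baseline",
]

VolumetryTable = Union[Mapping[str, float], pd.Series]


def _values(image) -> np.ndarray:
    return image.values if isinstance(image, CombinedImage) else np.asarray(image)


def background_stats(
    image, background_mask: np.ndarray, threshold: float = 0.4
) -> Dict[str, float]:
    """Mean, std and spread fractions of the background.

    ``spread_fraction`` is the fraction of background voxels outside the
    open interval (-threshold, threshold): boundary values count as spread,
    so a perfectly suppressed constant -0.5 background has spread 1.0 but
    ``above_fraction`` (voxels above -threshold, i.e. not suppressed
    towards the dark end) equal to 0 -- the operational "fully suppressed"
    statistic.
    """
    v = _values(image)[np.asarray(background_mask, dtype=bool)]
    if v.size == 0:
        raise ValueError("background mask selects no voxels")
    return {
        "mean": float(v.mean()),
        "std": float(v.std()),
        "spread_fraction": float(np.mean(np.abs(v) >= threshold)),
        "above_fraction": float(np.mean(v > -threshold)),
    }


def bias_ratio(
    robust,
    uniform,
    brain_mask: np.ndarray,
    labels: Optional[np.ndarray] = None,
    label_names: Optional[Mapping[str, int]] = None,
    eps: float = 1e-3,
) -> Tuple[np.ndarray, Dict[str, float]]:
    """Ratio map robust/uniform and per-tissue median ratios.

    The ratio is only defined where |uniform| > eps (the uniform image
    crosses zero inside the brain); elsewhere the map is NaN.  Returns
    ``(ratio_map, summary)`` where the summary holds per-tissue medians if
    ``labels``/``label_names`` are given, else the overall median.
    """
    r = _values(robust)
    u = _values(uniform)
    if r.shape != u.shape:
        raise ValueError("robust and uniform images differ in shape")
    mask = np.asarray(brain_mask, dtype=bool)
    valid = mask & (np.abs(u) > eps)
    ratio = np.full(u.shape, np.nan)
    ratio[valid] = r[valid] / u[valid]
    if not np.any(valid):
        warnings.warn("no valid voxels for bias ratio", stacklevel=2)
        return ratio, {}
    summary: Dict[str, float] = {"median": float(np.median(ratio[valid]))}
    if labels is not None and label_names is not None:
        for name, idx in label_names.items():
            sel = valid & (np.asarray(labels) == idx)
            if np.any(sel):
                summary[name] = float(np.median(ratio[sel]))
    return ratio, summary


def tissue_contrast(image, masks: Mapping[str, np.ndarray]) -> Dict[str, float]:
    """Mean intensity per tissue plus the GM-WM separation.

    ``masks`` must contain boolean masks for at least ``gm``, ``wm`` and
    ``csf``; an empty mask is an error.
    """
    v = _values(image)
    out: Dict[str, float] = {}
    for name in ("gm", "wm", "csf"):
        if name not in masks:
            raise ValueError(f"missing mask {name!r}")
        sel = np.asarray(masks[name], dtype=bool)
        if not np.any(sel):
            raise ValueError(f"mask {name!r} selects no voxels")
        out[f"{name}_mean"] = float(v[sel].mean())
    out["gm_wm_separation"] = out["wm_mean"] - out["gm_mean"]
    return out


def volumetric_reproducibility(
    rep1: VolumetryTable, rep2: VolumetryTable
) -> Dict[str, object]:
    """Repeat-scan volumetric reproducibility across segmented structures.

    Per structure the symmetric relative difference in percent,

        rel_diff = 100 * |V1 - V2| / ((V1 + V2) / 2),

    its mean across structures, and the worst case (the maximum across
    structures of the absolute relative difference).  Symmetric in the two
    repetitions and invariant to a common volume rescaling.
    """
    t1 = pd.Series(rep1, dtype=float)
    t2 = pd.Series(rep2, dtype=float)
    only1 = set(t1.index) - set(t2.index)
    only2 = set(t2.index) - set(t1.index)
    if only1 or only2:
        raise ValueError(
            f"structure sets differ: only in rep1 {sorted(only1)}, "
            f"only in rep2 {sorted(only2)}"
        )
    t2 = t2.reindex(t1.index)
    if np.any(t1 < 0) or np.any(t2 < 0):
        raise ValueError("volumes must be nonnegative")
    mean_vol = (t1 + t2) / 2.0
    if np.any(mean_vol <= 0):
        bad = mean_vol.index[mean_vol <= 0].tolist()
        raise ValueError(f"zero total volume for structure(s) {bad}")
    rel = 100.0 * (t1 - t2).abs() / mean_vol
    return {
        "per_structure": rel.to_dict(),
        "mean": float(rel.mean()),
        "worst_case": float(rel.max()),
    }


def mask_baseline(uniform, m2_volume: np.ndarray, threshold: float) -> np.ndarray:
    """Binary-mask background removal baseline.

    Sets the uniform image to -0.5 wherever the second-inversion magnitude
    is below ``threshold`` -- the simple post-hoc alternative the robust
    combination replaces; provided for comparison only.
    """
    u = _values(uniform)
    m2 = np.asarray(m2_volume, dtype=float)
    if m2.shape != u.shape:
        raise ValueError("magnitude volume shape differs from image shape")
    return np.where(m2 < threshold, -0.5, u)
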