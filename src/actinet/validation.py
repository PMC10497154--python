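"""Scoring extracted skeletons against ground truth, and robustness sweeps.

A predicted skeleton pixel counts as a true positive when a ground-truth
pixel lies within a Chebyshev distance of one (the 8-neighbourhood) —
the single-pixel tolerance appropriate when the pixel size is about half
the optical resolution.  Sensitivity TPR = TP/(TP+FN) measures how much
of the true network was found; precision PPV = TP/(TP+FP) measures the
positional accuracy of what was found.

:func:`run_sweep` drives the four robustness experiments — noise level
(SNR), network density (filament count), threshold percentile, and
numerical aperture — generating synthetic scenes, extracting and scoring
each, and summarising per condition.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .config import ExtractionParams, SceneParams
from .extraction import extract_skeleton
from .synthetic import SyntheticScene, generate_dataset, psf_sigma_from_na

logger = logging.getLogger(__name__)

__all__ = ["MatchResult", "match_skeletons", "score_scene", "run_sweep", "summarise"]


@dataclass
class MatchResult:
    """Pixel-tolerant confusion counts for one predicted/truth pair."""

    tp: int
    fp: int
    fn: int
    tolerance_px: int
    snr: Optional[float] = None
    condition: Optional[str] = None

    @property
    def sensitivity(self) -> float:
        """TPR = TP / (TP + FN); NaN when the truth is empty."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else math.nan

    @property
    def precision(self) -> float:
        """PPV = TP / (TP + FP); NaN when the prediction is empty."""
        denom = self.tp + self.fp
        return self.tp / denom if denom else math.nan


def _within_tolerance(target: np.ndarray, tolerance_px: int) -> np.ndarray:
    if tolerance_px == 0:
        return target
    structure = np.ones((3, 3), dtype=bool)
    return ndi.binary_dilation(target, structure=structure, iterations=tolerance_px)


def match_skeletons(
    predicted: np.ndarray, truth: np.ndarray, tolerance_px: int = 1
) -> MatchResult:
    """Score a predicted skeleton against ground truth with pixel tolerance.

    A predicted pixel is a TP if any truth pixel lies within Chebyshev
    distance ``tolerance_px``, otherwise an FP; a truth pixel with no
    predicted pixel within tolerance is an FN.  Matching is set-based
    (one truth pixel may support several predictions).
    """
    predicted = np.asarray(predicted, bool)
    truth = np.asarray(truth, bool)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth grids must share a shape")
    if tolerance_px < 0:
        raise ValueError("tolerance must be non-negative")
    if not truth.any():
        warnings.warn("empty ground truth: sensitivity undefined", stacklevel=2)
    if not predicted.any():
        warnings.warn("empty prediction: precision undefined", stacklevel=2)
    near_truth = _within_tolerance(truth, tolerance_px)
    near_pred = _within_tolerance(predicted, tolerance_px)
    tp = int((predicted & near_truth).sum())
    fp = int((predicted & ~near_truth).sum())
    fn = int((truth & ~near_pred).sum())
    return MatchResult(tp=tp, fp=fp, fn=fn, tolerance_px=tolerance_px)


def score_scene(
    scene: SyntheticScene,
    extraction_params: Optional[ExtractionParams] = None,
    tolerance_px: int = 1,
) -> MatchResult:
    """Extract a synthetic scene and score it against its ground truth."""
    params = extraction_params or ExtractionParams()
    mask = np.ones(scene.image.shape, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        skeleton = extract_skeleton(scene.image, mask, params)
    result = match_skeletons(skeleton.grid, scene.truth, tolerance_px)
    result.snr = scene.snr
    return result


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------


def run_sweep(
    conditions: dict[str, SceneParams],
    extraction_params: Optional[ExtractionParams | dict[str, ExtractionParams]] = None,
    n_per_condition: int = 100,
    seed: int = 0,
    tolerance_px: int = 1,
) -> pd.DataFrame:
    """Generate, extract and score scenes for each named condition.

    ``conditions`` maps a label to the scene parameters of that condition;
    ``extraction_params`` is either one parameter set for all conditions
    or a per-condition mapping (used by the threshold sweep).  Returns a
    tidy frame with one row per image: condition, seed, snr, tp/fp/fn,
    sensitivity, precision.  Failed images are recorded with NaN metrics
    rather than dropped.
    """
    labels = list(conditions)
    scenes, manifest = generate_dataset(
        [conditions[c] for c in labels], n_per_condition, seed
    )
    rows = []
    for scene, entry in zip(scenes, manifest):
        label = labels[entry["condition"]]
        if isinstance(extraction_params, dict):
            eparams = extraction_params[label]
        else:
            eparams = extraction_params
        try:
            result = score_scene(scene, eparams, tolerance_px)
            rows.append(
                {
                    "condition": label,
                    "seed": entry["seed"],
                    "snr": scene.snr,
                    "tp": result.tp,
                    "fp": result.fp,
                    "fn": result.fn,
                    "sensitivity": result.sensitivity,
                    "precision": result.precision,
                    "error": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 - failures are data here
            logger.exception("scene failed (condition %s)", label)
            rows.append(
                {
                    "condition": label,
                    "seed": entry["seed"],
                    "snr": scene.snr,
                    "tp": 0,
                    "fp": 0,
                    "fn": 0,
                    "sensitivity": math.nan,
                    "precision": math.nan,
                    "error": repr(exc),
                }
            )
    frame = pd.DataFrame(rows)
    frame["condition"] = pd.Categorical(frame["condition"], categories=labels)
    return frame


def summarise(results: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean, SD and quartiles of sensitivity and precision."""
    def _stats(group: pd.DataFrame) -> pd.Series:
        out = {}
        for metric in ("sensitivity", "precision"):
            vals = group[metric].dropna()
            out[f"{metric}_mean"] = vals.mean()
            out[f"{metric}_sd"] = vals.std()
            out[f"{metric}_q25"] = vals.quantile(0.25)
            out[f"{metric}_median"] = vals.quantile(0.5)
            out[f"{metric}_q75"] = vals.quantile(0.75)
        out["snr_mean"] = group["snr"].replace(math.inf, np.nan).mean()
        out["n"] = len(group)
        out["n_failed"] = int((group["error"] != "").sum())
        return pd.Series(out)

    return results.groupby("condition", observed=True).apply(_stats, include_groups=False)


def na_sweep_conditions(
    base: SceneParams, na_values: Sequence[float], wavelength_nm: float = 509.0
) -> dict[str, SceneParams]:
    """Scene conditions for a numerical-aperture sweep (PSF width varies)."""
    return {
        f"NA={na:g}": replace(base, psf_sigma_nm=psf_sigma_from_na(na, wavelength_nm))
        for na in na_values
    }
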