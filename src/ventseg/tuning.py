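"""Coordinate-wise grid search over the evolution parameters.

One parameter is swept at a time against a tuning set of images with known
ground truth: every candidate value is run through the full segmentation,
the mean of the selection metric over the set picks the winner, the winner
is fixed, and the sweep moves to the next parameter.  The per-candidate
means and standard deviations of Dice, Jaccard, sensitivity, specificity
and accuracy are collected into a tuning table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .energies import EvolutionParams
from .metrics import evaluate_masks
from .segment import BoundingBox, run_segmentation

__all__ = ["ParameterGrid", "TuningTable", "select_best", "tune_parameters"]

_METRICS = ("dice", "jaccard", "sensitivity", "specificity", "accuracy")
_TUNABLE = {f.name for f in dc_fields(EvolutionParams) if not f.name.startswith("_")}


@dataclass
class ParameterGrid:
    """Ordered (parameter name, candidate list) pairs plus the selector.

    ``metric`` names the selection measure (default ``accuracy``); ties are
    broken toward the smallest candidate.
    """

    entries: list[tuple[str, list]] = field(default_factory=list)
    metric: str = "accuracy"

    def __post_init__(self):
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}")
        for name, cands in self.entries:
            if name not in _TUNABLE:
                raise ValueError(
                    f"unknown parameter {name!r}; tunable: {sorted(_TUNABLE)}"
                )
            if len(cands) == 0:
                raise ValueError(f"empty candidate list for {name!r}")


@dataclass
class TuningTable:
    """Per-candidate summary (means +/- SDs) and the per-image records."""

    summary: pd.DataFrame
    per_image: pd.DataFrame

    def to_csv(self, path) -> None:
        """Write the summary in a candidate-by-measure layout."""
        self.summary.to_csv(path, index=False)


def select_best(candidates, scores):
    """The candidate with the maximal score; ties go to the smallest candidate.

    ``None``/NaN scores mark failed candidates and are excluded.
    """
    candidates = list(candidates)
    scores = list(scores)
    if len(candidates) != len(scores):
        raise ValueError("candidates and scores must have equal length")
    valid = [
        (c, s)
        for c, s in zip(candidates, scores)
        if s is not None and not (isinstance(s, float) and math.isnan(s))
    ]
    if not valid:
        raise ValueError("all candidates failed; nothing to select")
    best_score = max(s for _, s in valid)
    return min(c for c, s in valid if s == best_score)


def _evaluate_candidate(dataset, params, method, mode):
    """Mean/SD of every measure over the tuning set; None on any failure."""
    rows = []
    for image, truth, box in dataset:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mask, state = run_segmentation(image, box, params, method=method)
            if state.status == "contour_vanished":
                return None, rows
        except (ValueError, FloatingPointError):
            return None, rows
        rows.append(evaluate_masks(mask, truth, mode).to_dict())
    return rows, rows


def tune_parameters(
    dataset: list[tuple[np.ndarray, np.ndarray, BoundingBox]],
    grid: ParameterGrid,
    base: EvolutionParams | None = None,
    method: str = "modified",
    mode: str = "standard",
) -> tuple[EvolutionParams, TuningTable]:
    """Run the coordinate-wise sweep and return (tuned params, table).

    Candidates for which any segmentation fails (divergence, vanished
    contour, invalid parameter combination) are recorded as failed and
    excluded from selection rather than aborting the sweep.
    """
    if not dataset:
        raise ValueError("tuning set is empty")
    if base is None:
        base = EvolutionParams()
    params = base
    summary_rows = []
    per_image_rows = []
    for name, candidates in grid.entries:
        scores = []
        for cand in candidates:
            try:
                trial = params.replace(**{name: cand})
            except ValueError:
                trial = None
            result = None
            if trial is not None:
                result, rows = _evaluate_candidate(dataset, trial, method, mode)
                for i, r in enumerate(rows):
                    per_image_rows.append(
                        dict(parameter=name, candidate=cand, image=i, **r)
                    )
            row = dict(parameter=name, candidate=cand, failed=result is None)
            if result is None:
                scores.append(None)
                for m in _METRICS:
                    row[f"{m}_mean"] = math.nan
                    row[f"{m}_sd"] = math.nan
            else:
                frame = pd.DataFrame(result)
                for m in _METRICS:
                    row[f"{m}_mean"] = float(frame[m].mean())
                    row[f"{m}_sd"] = float(frame[m].std(ddof=0))
                scores.append(row[f"{grid.metric}_mean"])
            summary_rows.append(row)
        best = select_best(candidates, scores)
        params = params.replace(**{name: best})
    table = TuningTable(
        summary=pd.DataFrame(summary_rows), per_image=pd.DataFrame(per_image_rows)
    )
    return params, table
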