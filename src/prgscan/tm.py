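"""Transmembrane-segment prediction by hydropathy sliding windows.

A window (default 19 residues, Kyte-Doolittle scale) whose mean
hydropathy reaches the threshold (default 1.6) marks a candidate TM
region; overlapping windows are unioned and unions separated by fewer
than ``min_gap`` residues are merged.  This hydropathy rule is a
deliberate, documented replacement for a cyclic-topology membrane HMM:
downstream classification consumes only TM presence/absence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List

import numpy as np

from .errors import ModelError
from .seqio import ProteinRecord


@dataclass(frozen=True)
class TmSegment:
    start: int  # 1-based, inclusive
    end: int
    peak_hydropathy: float  # highest window mean inside the segment


@dataclass(frozen=True)
class TmModel:
    hydropathy: Dict[str, float]
    window: int = 19
    threshold: float = 1.6
    min_gap: int = 5

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 1:
            raise ModelError(f"window must be odd and positive, got {self.window}")
        if not np.isfinite(self.threshold):
            raise ModelError("threshold must be finite")

    @classmethod
    def from_json(cls, path: str | Path) -> "TmModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            hydropathy=d["hydropathy"],
            window=d.get("window", 19),
            threshold=d.get("threshold", 1.6),
            min_gap=d.get("min_gap", 5),
        )


def default_tm_model() -> TmModel:
    """The packaged Kyte-Doolittle scale with standard window parameters."""
    with resources.files("prgscan.data").joinpath("kyte_doolittle.json").open() as fh:
        d = json.load(fh)
    return TmModel(
        hydropathy=d["hydropathy"],
        window=d["window"],
        threshold=d["threshold"],
        min_gap=d["min_gap"],
    )


def predict_tm_segments(model: TmModel, protein: ProteinRecord) -> List[TmSegment]:
    """TM segments as unions of above-threshold hydropathy windows."""
    seq = protein.sequence
    L = len(seq)
    W = model.window
    if L < W:
        return []
    values = np.asarray([model.hydropathy.get(c, 0.0) for c in seq])
    cs = np.concatenate([[0.0], np.cumsum(values)])
    means = (cs[W:] - cs[:-W]) / W  # mean per window start
    above = means >= model.threshold
    if not above.any():
        return []
    # union of above-threshold windows as residue intervals, then merge
    intervals: List[List[int]] = []
    for s in np.flatnonzero(above):
        start, end = int(s), int(s) + W - 1  # 0-based inclusive
        if intervals and start <= intervals[-1][1] + model.min_gap:
            intervals[-1][1] = max(intervals[-1][1], end)
        else:
            intervals.append([start, end])
    segments = []
    for start, end in intervals:
        window_starts = [
            s for s in np.flatnonzero(above) if start <= s and s + W - 1 <= end
        ]
        peak = float(means[window_starts].max()) if window_starts else float(means[start])
        segments.append(TmSegment(start + 1, end + 1, round(peak, 3)))
    return segments
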