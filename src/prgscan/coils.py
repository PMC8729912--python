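"""Coiled-coil prediction by heptad-window propensity scoring.

A Lupas-style scorer: a sliding window (default 21 residues) is scored
as the geometric mean of per-residue, per-heptad-position propensities
over all 7 register offsets; the window score is converted to a
probability by comparing two Gaussian score distributions, one for
coiled coils and one for globular sequence,

    P(cc | s) = G_cc(s) / (G_cc(s) + G_glob(s)).

Each residue takes the maximum probability over all windows covering it
and all registers; maximal runs of at least ``min_run`` residues with
probability >= ``p_cutoff`` are reported as CC segments.

The default propensity table and Gaussian parameters ship as a
versioned JSON data file; they are a package-authored Lupas-style table
(hydrophobics favored at heptad positions a/d, charged residues at
e/g), not a digit-for-digit reproduction of any published table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
from scipy.stats import norm

from .errors import ModelError
from .seqio import AA_ALPHABET, ProteinRecord

HEPTAD = "abcdefg"


@dataclass(frozen=True)
class CoilSegment:
    start: int  # 1-based, inclusive
    end: int
    max_probability: float


@dataclass(frozen=True)
class CoilsModel:
    propensities: Dict[str, Tuple[float, ...]]  # residue -> 7 positive weights
    window: int = 21
    gauss_cc: Tuple[float, float] = (1.63, 0.24)  # mean, sd
    gauss_glob: Tuple[float, float] = (0.77, 0.20)
    p_cutoff: float = 0.5
    min_run: int = 14

    def __post_init__(self) -> None:
        for res, row in self.propensities.items():
            if len(row) != 7 or any(p <= 0 for p in row):
                raise ModelError(f"bad propensity row for {res!r}")
        if self.gauss_cc[1] <= 0 or self.gauss_glob[1] <= 0:
            raise ModelError("Gaussian sds must be positive")
        if not (0 < self.p_cutoff < 1):
            raise ModelError("p_cutoff must lie in (0, 1)")

    def log_table(self) -> np.ndarray:
        """(21, 7) log-propensities indexed by residue (X/unknown row = 0)."""
        table = np.zeros((21, 7))
        for i, aa in enumerate(AA_ALPHABET):
            row = self.propensities.get(aa)
            if row is not None:
                table[i] = np.log(row)
        return table

    @classmethod
    def from_json(cls, path: str | Path) -> "CoilsModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            propensities={k: tuple(v) for k, v in d["propensities"].items()},
            window=d.get("window", 21),
            gauss_cc=tuple(d["gauss_cc"]),
            gauss_glob=tuple(d["gauss_glob"]),
            p_cutoff=d.get("p_cutoff", 0.5),
            min_run=d.get("min_run", 14),
        )


def default_coils_model() -> CoilsModel:
    """The packaged default heptad propensity table and score Gaussians."""
    with resources.files("prgscan.data").joinpath("coils_default.json").open() as fh:
        d = json.load(fh)
    return CoilsModel(
        propensities={k: tuple(v) for k, v in d["propensities"].items()},
        window=d["window"],
        gauss_cc=tuple(d["gauss_cc"]),
        gauss_glob=tuple(d["gauss_glob"]),
        p_cutoff=d["p_cutoff"],
        min_run=d["min_run"],
    )


def coils_window_score(model: CoilsModel, window_seq: str, offset: int = 0) -> float:
    """Geometric mean of propensities over one window at one register offset.

    Heptad position of residue i (0-based in the window) is
    ``(i + offset) mod 7``; residues absent from the table (X) score
    propensity 1.
    """
    if len(window_seq) != model.window:
        raise ModelError(
            f"window length {len(window_seq)} != model window {model.window}"
        )
    total = 0.0
    for i, res in enumerate(window_seq):
        row = model.propensities.get(res)
        if row is not None:
            total += np.log(row[(i + offset) % 7])
    return float(np.exp(total / model.window))


def coils_probability(model: CoilsModel, score: float) -> float:
    """Probability that a window score came from the coiled-coil population."""
    g_cc = norm.pdf(score, *model.gauss_cc)
    g_glob = norm.pdf(score, *model.gauss_glob)
    if g_cc + g_glob == 0:  # far tails: decide by distance to the means
        return 1.0 if abs(score - model.gauss_cc[0]) < abs(score - model.gauss_glob[0]) else 0.0
    return float(g_cc / (g_cc + g_glob))


def _per_residue_probability(model: CoilsModel, sequence: str) -> np.ndarray:
    """Max probability over all covering windows and the 7 registers."""
    L = len(sequence)
    W = model.window
    prob = np.zeros(L)
    if L < W:
        return prob
    logt = model.log_table()
    enc = np.asarray(
        [AA_ALPHABET.index(c) if c in AA_ALPHABET else 20 for c in sequence]
    )
    # per-offset per-position log propensity, cumulative for window sums
    best_window = np.full(L - W + 1, -np.inf)
    for off in range(7):
        lp = logt[enc, (np.arange(L) + off) % 7]
        cs = np.concatenate([[0.0], np.cumsum(lp)])
        sums = (cs[W:] - cs[:-W]) / W  # mean log propensity per window start
        best_window = np.maximum(best_window, sums)
    scores = np.exp(best_window)
    pw = np.asarray([coils_probability(model, s) for s in scores])
    for s in range(L - W + 1):
        np.maximum(prob[s : s + W], pw[s], out=prob[s : s + W])
    return prob


def predict_coiled_coils(model: CoilsModel, protein: ProteinRecord) -> List[CoilSegment]:
    """CC segments: maximal runs of >= min_run residues above p_cutoff."""
    prob = _per_residue_probability(model, protein.sequence)
    segments: List[CoilSegment] = []
    start = None
    for i, p in enumerate(prob):
        if p >= model.p_cutoff:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= model.min_run:
                segments.append(
                    CoilSegment(start + 1, i, float(round(prob[start:i].max(), 6)))
                )
            start = None
    if start is not None and len(prob) - start >= model.min_run:
        segments.append(
            CoilSegment(start + 1, len(prob), float(round(prob[start:].max(), 6)))
        )
    return segments
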