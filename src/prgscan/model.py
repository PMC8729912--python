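"""Profile-HMM model container and JSON serialization.

A :class:`ProfileHMM` is a position-specific probabilistic model of a
resistance-domain family with match/insert/delete states.  Layer ``j``
(0-based, ``0 <= j < M``) has a match state ``M_j`` emitting one residue,
an insert state ``I_j`` (between ``M_j`` and ``M_{j+1}``) emitting from
the insert distribution, and a silent delete state ``D_j``.  Transition
vectors are indexed by the source layer:

    mm[j] = P(M_j -> M_{j+1})   mi[j] = P(M_j -> I_j)   md[j] = P(M_j -> D_{j+1})
    im[j] = P(I_j -> M_{j+1})   ii[j] = P(I_j -> I_j)
    dm[j] = P(D_j -> M_{j+1})   dd[j] = P(D_j -> D_{j+1})

The last layer's outgoing probabilities describe termination and are not
used by the alignment recurrences (alignments may start and end at any
match state; see :mod:`prgscan.domain_scan`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .errors import ModelError
from .seqio import AA_ALPHABET

#: Domain vocabulary detected by profile HMMs.
HMM_DOMAIN_LABELS = ("TIR", "NBS", "LRR", "LYSM", "LECM", "KIN")
#: Domains handled by dedicated predictors, never by HMMs.
NON_HMM_DOMAIN_LABELS = ("CC", "TM")
ALL_DOMAIN_LABELS = HMM_DOMAIN_LABELS + NON_HMM_DOMAIN_LABELS

CLASSES = ("CNL", "TNL", "RLK", "RLP", "LYK", "LYP", "LECRK")

TRANSITION_KEYS = ("mm", "mi", "md", "im", "ii", "dm", "dd")

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


@dataclass(frozen=True)
class DomainRegion:
    """A column range of a class MSA annotated with its domain of origin."""

    msa_id: str
    domain_label: str
    col_start: int  # 1-based, inclusive
    col_end: int
    subtype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.domain_label not in ALL_DOMAIN_LABELS:
            raise ModelError(
                f"unknown domain label {self.domain_label!r} in region for "
                f"{self.msa_id!r}"
            )
        if not (1 <= self.col_start <= self.col_end):
            raise ModelError(
                f"bad region columns [{self.col_start}, {self.col_end}] for "
                f"{self.msa_id!r}/{self.domain_label}"
            )


@dataclass(frozen=True)
class ProfileHMM:
    name: str
    class_of_origin: str
    domain_label: str
    match_emissions: np.ndarray  # (M, 20)
    insert_emissions: np.ndarray  # (20,)
    transitions: Dict[str, np.ndarray]  # each (M,)
    background: np.ndarray  # (20,)
    min_blosum_score: Optional[int] = None

    @property
    def length(self) -> int:
        """Number of match states M."""
        return int(self.match_emissions.shape[0])

    @property
    def consensus(self) -> str:
        """Per-match-state argmax residue."""
        idx = np.argmax(self.match_emissions, axis=1)
        return "".join(AA_ALPHABET[i] for i in idx)

    def validate(self) -> None:
        M = self.length
        if M < 1:
            raise ModelError(f"model {self.name!r} has no match states")
        if self.match_emissions.shape != (M, 20):
            raise ModelError(f"model {self.name!r}: bad match_emissions shape")
        vectors = [self.insert_emissions, self.background]
        if any(v.shape != (20,) for v in vectors):
            raise ModelError(f"model {self.name!r}: bad emission vector shape")
        for key in TRANSITION_KEYS:
            if key not in self.transitions or self.transitions[key].shape != (M,):
                raise ModelError(f"model {self.name!r}: bad transition vector {key!r}")
        groups = [self.match_emissions.sum(axis=1), self.insert_emissions.sum(), self.background.sum()]
        t = self.transitions
        groups += [t["mm"] + t["mi"] + t["md"], t["im"] + t["ii"], t["dm"] + t["dd"]]
        for g in groups:
            if not np.allclose(g, 1.0, atol=1e-9):
                raise ModelError(f"model {self.name!r}: probability vectors do not sum to 1")
        allp = np.concatenate(
            [self.match_emissions.ravel(), self.insert_emissions, self.background]
            + [t[k] for k in TRANSITION_KEYS]
        )
        if np.any(allp <= 0):
            raise ModelError(f"model {self.name!r}: zero probabilities (needs pseudocounts)")

    def with_threshold(self, min_blosum_score: int) -> "ProfileHMM":
        return replace(self, min_blosum_score=min_blosum_score)

    # -- serialization (JSON, sorted keys, round-trips bit-identically) ----

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "class_of_origin": self.class_of_origin,
            "domain_label": self.domain_label,
            "length": self.length,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "transitions": {k: self.transitions[k].tolist() for k in TRANSITION_KEYS},
            "background": self.background.tolist(),
            "min_blosum_score": self.min_blosum_score,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileHMM":
        hmm = cls(
            name=d["name"],
            class_of_origin=d["class_of_origin"],
            domain_label=d["domain_label"],
            match_emissions=np.asarray(d["match_emissions"], dtype=float),
            insert_emissions=np.asarray(d["insert_emissions"], dtype=float),
            transitions={k: np.asarray(v, dtype=float) for k, v in d["transitions"].items()},
            background=np.asarray(d["background"], dtype=float),
            min_blosum_score=d.get("min_blosum_score"),
        )
        return hmm

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileHMM":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def encode_sequence(sequence: str) -> np.ndarray:
    """Map residues to indices 0..19; X and anything unknown to 20."""
    return np.asarray([_AA_INDEX.get(c, 20) for c in sequence], dtype=np.int64)
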