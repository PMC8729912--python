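"""Synthetic reference sets, proteomes and truth tables.

Everything downstream of this module is testable without downloads: it
fabricates (a) per-domain generator HMMs and reference MSAs sampled
from them, (b) class reference alignments with a domain-region table,
and (c) proteomes with planted domain architectures plus an exact truth
table recording every planted segment.

The generator's defaults define the study conditions: divergence 0.15
within reference families, 5% substitution noise on planted segments,
seven-class proteomes with linkers drawn from a polar-biased background
composition that is deliberately depleted in hydrophobic runs (so false
TM calls are a property of the method, not of the fixture).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import PrgScanError
from .model import CLASSES, DomainRegion, HMM_DOMAIN_LABELS, ProfileHMM
from .seqio import AA_ALPHABET, Msa, ProteinRecord

log = logging.getLogger(__name__)

#: N-to-C domain order planted for each canonical class.
ARCHITECTURES: Dict[str, Tuple[str, ...]] = {
    "TNL": ("TIR", "NBS", "LRR"),
    "CNL": ("CC", "NBS", "LRR"),
    "RLK": ("LRR", "TM", "KIN"),
    "RLP": ("LRR", "TM"),
    "LYK": ("LYSM", "TM", "KIN"),
    "LYP": ("LYSM", "TM"),
    "LECRK": ("LECM", "TM", "KIN"),
}

#: Domain regions modeled by HMMs in each class reference alignment.
CLASS_HMM_DOMAINS: Dict[str, Tuple[str, ...]] = {
    "TNL": ("TIR", "NBS", "LRR"),
    "CNL": ("NBS", "LRR"),
    "RLK": ("LRR", "KIN"),
    "RLP": ("LRR",),
    "LYK": ("LYSM", "KIN"),
    "LYP": ("LYSM",),
    "LECRK": ("LECM", "KIN"),
}

DEFAULT_DOMAIN_LENGTHS: Dict[str, Tuple[int, int]] = {
    "TIR": (90, 110),
    "NBS": (140, 170),
    "LRR": (100, 130),
    "LYSM": (45, 60),
    "LECM": (90, 110),
    "KIN": (130, 160),
    "CC": (28, 42),
    "TM": (21, 25),
}

#: Polar-biased linker/background composition, depleted in L/I/V/F/M/W/C.
DEFAULT_BACKGROUND: Dict[str, float] = {
    "A": 0.07, "C": 0.01, "D": 0.08, "E": 0.09, "F": 0.015,
    "G": 0.09, "H": 0.03, "I": 0.015, "K": 0.08, "L": 0.02,
    "M": 0.01, "N": 0.07, "P": 0.06, "Q": 0.06, "R": 0.06,
    "S": 0.11, "T": 0.08, "V": 0.02, "W": 0.005, "Y": 0.025,
}

_HEPTAD = "LEELKEK"  # L at a/d, E/K elsewhere: an ideal coiled-coil repeat
_TM_RESIDUES = ("L", "I", "V", "F", "A")
_TM_WEIGHTS = (0.4, 0.25, 0.2, 0.1, 0.05)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic proteome."""

    seed: int = 0
    n_proteins: int = 200
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {c: 1 / 7 for c in CLASSES}
    )
    domain_length: Mapping[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_LENGTHS)
    )
    substitution_noise: float = 0.05
    background_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND)
    )
    linker_length: Tuple[int, int] = (25, 50)
    stochastic_mix: bool = False  # multinomial draw instead of exact counts

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise PrgScanError("class_mix proportions must sum to 1")
        if not (0 <= self.substitution_noise < 0.5):
            raise PrgScanError("substitution_noise must lie in [0, 0.5)")
        for label, (lo, hi) in self.domain_length.items():
            if lo < 1 or hi < lo:
                raise PrgScanError(f"bad length range for {label}: ({lo}, {hi})")
        if self.linker_length[0] < 1 or self.linker_length[1] < self.linker_length[0]:
            raise PrgScanError(f"bad linker length range {self.linker_length}")
        unknown = set(self.class_mix) - set(CLASSES)
        if unknown:
            raise PrgScanError(f"unknown classes in mix: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_proteins": self.n_proteins,
            "class_mix": dict(self.class_mix),
            "domain_length": {k: list(v) for k, v in self.domain_length.items()},
            "substitution_noise": self.substitution_noise,
            "background_composition": dict(self.background_composition),
            "linker_length": list(self.linker_length),
            "stochastic_mix": self.stochastic_mix,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {
            "seed", "n_proteins", "class_mix", "domain_length",
            "substitution_noise", "background_composition", "linker_length",
            "stochastic_mix",
        }
        unknown = set(d) - known
        if unknown:
            raise PrgScanError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "domain_length" in kwargs:
            kwargs["domain_length"] = {
                k: tuple(v) for k, v in kwargs["domain_length"].items()
            }
        if "linker_length" in kwargs:
            kwargs["linker_length"] = tuple(kwargs["linker_length"])
        return cls(**kwargs)


@dataclass(frozen=True)
class TruthEntry:
    protein_id: str
    class_label: str
    segments: Tuple[Tuple[str, int, int], ...]  # (domain_label, start, end), 1-based


@dataclass(frozen=True)
class TruthTable:
    entries: Tuple[TruthEntry, ...]

    def domain_sets(self) -> Dict[str, set]:
        return {
            e.protein_id: {label for label, _, _ in e.segments} for e in self.entries
        }

    def class_of(self) -> Dict[str, str]:
        return {e.protein_id: e.class_label for e in self.entries}


# ----------------------------------------------------------- generators


def _random_consensus(label: str, length: int, rng: np.random.Generator) -> str:
    probs = np.full(20, 1 / 20)
    if label == "LRR":  # leucine-rich flavor
        probs = np.full(20, 0.7 / 19)
        probs[AA_ALPHABET.index("L")] = 0.3
    idx = rng.choice(20, size=length, p=probs)
    return "".join(AA_ALPHABET[i] for i in idx)


def make_generator_hmm(
    domain_label: str,
    length: int,
    divergence: float,
    rng: np.random.Generator,
    name: Optional[str] = None,
) -> ProfileHMM:
    """A generator model concentrated on a random consensus.

    Match states emit the consensus residue with probability
    ``1 - divergence`` (the rest spread uniformly); insertion/deletion
    rates scale with divergence so divergence 0 reproduces the consensus
    exactly.
    """
    consensus = _random_consensus(domain_label, length, rng)
    match = np.full((length, 20), divergence / 19 if divergence > 0 else 0.0)
    for j, res in enumerate(consensus):
        match[j, AA_ALPHABET.index(res)] = 1 - divergence
    background = np.full(20, 1 / 20)
    indel = divergence / 10
    transitions = {
        "mm": np.full(length, 1 - 2 * indel),
        "mi": np.full(length, indel),
        "md": np.full(length, indel),
        "im": np.full(length, 0.7),
        "ii": np.full(length, 0.3),
        "dm": np.full(length, 0.7),
        "dd": np.full(length, 0.3),
    }
    return ProfileHMM(
        name=name or f"gen_{domain_label}",
        class_of_origin="generator",
        domain_label=domain_label,
        match_emissions=match,
        insert_emissions=background.copy(),
        transitions=transitions,
        background=background,
    )


def _sample_path(hmm: ProfileHMM, rng: np.random.Generator):
    """One generative pass; returns (matches, inserts) per layer."""
    M = hmm.length
    t = hmm.transitions
    matches: List[Optional[str]] = [None] * M
    inserts: List[List[str]] = [[] for _ in range(M)]

    def draw(probs: Sequence[float]) -> int:
        return int(rng.choice(len(probs), p=np.asarray(probs) / np.sum(probs)))

    def emit(p: np.ndarray) -> str:
        return AA_ALPHABET[int(rng.choice(20, p=p / p.sum()))]

    j, state = 0, "M"
    while True:
        if state == "M":
            matches[j] = emit(hmm.match_emissions[j])
            if j == M - 1:
                break
            k = draw([t["mm"][j], t["mi"][j], t["md"][j]])
            if k == 0:
                j += 1
            elif k == 1:
                state = "I"
            else:
                j += 1
                state = "D"
        elif state == "I":
            inserts[j].append(emit(hmm.insert_emissions))
            if draw([t["im"][j], t["ii"][j]]) == 0:
                j += 1
                state = "M"
        else:  # D
            if j == M - 1:
                break
            k = draw([t["dm"][j], t["dd"][j]])
            j += 1
            state = "M" if k == 0 else "D"
    return matches, inserts


def sample_from_hmm(hmm: ProfileHMM, seed: int | np.random.Generator) -> str:
    """Emit one sequence from the model (deterministic per seed).

    The pass starts in the first match state and ends after the last
    model layer; flanking inserts are not modeled.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    matches, inserts = _sample_path(hmm, rng)
    out = []
    for j in range(hmm.length):
        if matches[j] is not None:
            out.append(matches[j])
        out.extend(inserts[j])
    return "".join(out)


def _sample_aligned_rows(
    hmm: ProfileHMM, ids: Sequence[str], rng: np.random.Generator
) -> List[Tuple[str, str]]:
    """Sample rows jointly so they share one alignment (inserts padded)."""
    paths = [_sample_path(hmm, rng) for _ in ids]
    M = hmm.length
    ins_width = [max(len(p[1][j]) for p in paths) for j in range(M)]
    rows = []
    for rid, (matches, inserts) in zip(ids, paths):
        parts = []
        for j in range(M):
            parts.append(matches[j] if matches[j] is not None else "-")
            parts.append("".join(inserts[j]).ljust(ins_width[j], "-"))
        rows.append((rid, "".join(parts)))
    return rows


def make_reference_msa(
    domain_label: str,
    n_rows: int,
    divergence: float,
    seed: int,
    length: Optional[int] = None,
) -> Tuple[Msa, ProfileHMM]:
    """A reference MSA sampled from a fresh generator model.

    Rows are aligned by construction (insertions padded with gaps); the
    generator is returned so recovery can be measured against it.
    """
    if n_rows < 2:
        raise PrgScanError(f"need at least 2 rows, got {n_rows}")
    rng = np.random.default_rng(seed)
    lo, hi = DEFAULT_DOMAIN_LENGTHS.get(domain_label, (80, 120))
    length = length or int(rng.integers(lo, hi + 1))
    gen = make_generator_hmm(domain_label, length, divergence, rng)
    ids = [f"{domain_label}_r{i + 1}" for i in range(n_rows)]
    msa = Msa(rows=tuple(_sample_aligned_rows(gen, ids, rng)))
    return msa, gen


@dataclass(frozen=True)
class ReferenceSet:
    """Class reference alignments with regions, plus the domain generators."""

    class_msas: Dict[str, Msa]
    regions: Tuple[DomainRegion, ...]
    generators: Dict[str, ProfileHMM]  # one per HMM-detected domain label


def make_reference_set(
    seed: int, n_rows: int = 8, divergence: float = 0.15
) -> ReferenceSet:
    """Per-class reference MSAs emulating a curated resistance-gene set.

    One generator per domain label is shared across classes; LYSM rows
    for LYK and LYP are sampled in one jointly aligned batch so the
    pooled LYSM model can be built from their concatenation.
    """
    rng = np.random.default_rng(seed)
    generators = {}
    for label in HMM_DOMAIN_LABELS:
        lo, hi = DEFAULT_DOMAIN_LENGTHS[label]
        length = int(rng.integers(lo, hi + 1))
        generators[label] = make_generator_hmm(label, length, divergence, rng)

    lysm_ids = [f"LYK_r{i + 1}" for i in range(n_rows)] + [
        f"LYP_r{i + 1}" for i in range(n_rows)
    ]
    lysm_rows = _sample_aligned_rows(generators["LYSM"], lysm_ids, rng)
    lysm_batches = {"LYK": lysm_rows[:n_rows], "LYP": lysm_rows[n_rows:]}

    bg_letters = sorted(DEFAULT_BACKGROUND)
    bg_probs = np.asarray([DEFAULT_BACKGROUND[a] for a in bg_letters])

    class_msas: Dict[str, Msa] = {}
    regions: List[DomainRegion] = []
    for cls in CLASSES:
        ids = [f"{cls}_r{i + 1}" for i in range(n_rows)]
        blocks: List[List[str]] = [[""] * n_rows]
        col = 0
        for domain in CLASS_HMM_DOMAINS[cls]:
            if domain == "LYSM":
                batch = [(ids[i], lysm_batches[cls][i][1]) for i in range(n_rows)]
            else:
                batch = _sample_aligned_rows(generators[domain], ids, rng)
            width = len(batch[0][1])
            # 5 unconserved linker columns in front of each domain block
            linker = [
                "".join(
                    bg_letters[k]
                    for k in rng.choice(len(bg_letters), size=5, p=bg_probs)
                )
                for _ in range(n_rows)
            ]
            for i in range(n_rows):
                blocks[0][i] += linker[i] + batch[i][1]
            col += 5
            regions.append(
                DomainRegion(
                    msa_id=cls, domain_label=domain,
                    col_start=col + 1, col_end=col + width,
                )
            )
            col += width
        class_msas[cls] = Msa(
            rows=tuple((ids[i], blocks[0][i]) for i in range(n_rows))
        )
    return ReferenceSet(
        class_msas=class_msas, regions=tuple(regions), generators=generators
    )


# ------------------------------------------------------------- proteomes


def largest_remainder_counts(
    n: int, proportions: Mapping[str, float], order: Sequence[str]
) -> Dict[str, int]:
    """Integer counts summing to n, deterministic largest-remainder rounding."""
    raw = {c: n * proportions.get(c, 0.0) for c in order}
    counts = {c: int(np.floor(raw[c])) for c in order}
    short = n - sum(counts.values())
    by_frac = sorted(order, key=lambda c: (-(raw[c] - counts[c]), order.index(c)))
    for c in by_frac[:short]:
        counts[c] += 1
    return counts


def _noisy(seq: str, noise: float, rng: np.random.Generator) -> str:
    if noise == 0:
        return seq
    out = list(seq)
    for i, res in enumerate(out):
        if rng.random() < noise:
            choices = [a for a in AA_ALPHABET if a != res]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _background_stretch(
    length: int, composition: Mapping[str, float], rng: np.random.Generator
) -> str:
    letters = sorted(composition)
    probs = np.asarray([composition[a] for a in letters])
    probs = probs / probs.sum()
    return "".join(letters[k] for k in rng.choice(len(letters), size=length, p=probs))


def make_synthetic_proteome(
    config: SimConfig, generators: Mapping[str, ProfileHMM]
) -> Tuple[List[ProteinRecord], TruthTable]:
    """Assemble a proteome of planted architectures plus its truth table.

    Per protein: the class is drawn from the mix (largest-remainder
    exact counts by default), its architecture is laid out N-to-C with
    background linkers between segments, HMM domains are planted as the
    generator consensus with per-residue substitution noise, CC as an
    ideal heptad repeat and TM as a hydrophobic stretch.
    """
    rng = np.random.default_rng(config.seed)
    active = [c for c in CLASSES if config.class_mix.get(c, 0.0) > 0]
    for cls in active:
        for domain in ARCHITECTURES[cls]:
            if domain in HMM_DOMAIN_LABELS and domain not in generators:
                raise PrgScanError(
                    f"class {cls} needs a generator for domain {domain}"
                )
    if config.stochastic_mix:
        probs = [config.class_mix.get(c, 0.0) for c in CLASSES]
        draw = rng.multinomial(config.n_proteins, probs)
        counts = {c: int(k) for c, k in zip(CLASSES, draw)}
    else:
        counts = largest_remainder_counts(config.n_proteins, config.class_mix, CLASSES)

    records: List[ProteinRecord] = []
    entries: List[TruthEntry] = []
    idx = 0
    for cls in CLASSES:
        for _ in range(counts.get(cls, 0)):
            idx += 1
            pid = f"prot{idx:04d}_{cls}"
            parts: List[str] = []
            segments: List[Tuple[str, int, int]] = []
            pos = 0

            def linker() -> None:
                nonlocal pos
                ll = int(rng.integers(config.linker_length[0], config.linker_length[1] + 1))
                parts.append(
                    _background_stretch(ll, config.background_composition, rng)
                )
                pos += ll

            linker()
            for domain in ARCHITECTURES[cls]:
                if domain == "CC":
                    lo, hi = config.domain_length["CC"]
                    reps = max(4, int(rng.integers(lo, hi + 1)) // 7)
                    seg = _HEPTAD * reps
                elif domain == "TM":
                    lo, hi = config.domain_length["TM"]
                    tl = int(rng.integers(lo, hi + 1))
                    seg = "".join(
                        _TM_RESIDUES[k]
                        for k in rng.choice(
                            len(_TM_RESIDUES), size=tl, p=_TM_WEIGHTS
                        )
                    )
                else:
                    seg = _noisy(
                        generators[domain].consensus, config.substitution_noise, rng
                    )
                parts.append(seg)
                segments.append((domain, pos + 1, pos + len(seg)))
                pos += len(seg)
                linker()
            records.append(ProteinRecord(id=pid, sequence="".join(parts)))
            entries.append(
                TruthEntry(
                    protein_id=pid, class_label=cls, segments=tuple(segments)
                )
            )
    return records, TruthTable(entries=tuple(entries))


# ---------------------------------------------------------------- output

TRUTH_TSV_HEADER = "protein_id\tclass_label\tdomain_label\tstart\tend"


def write_truth_tsv(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(TRUTH_TSV_HEADER + "\n")
        for e in truth.entries:
            for label, start, end in e.segments:
                fh.write(f"{e.protein_id}\t{e.class_label}\t{label}\t{start}\t{end}\n")


def read_truth_tsv(path: str | Path) -> TruthTable:
    per_protein: Dict[str, Tuple[str, List[Tuple[str, int, int]]]] = {}
    order: List[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != TRUTH_TSV_HEADER:
            raise PrgScanError(f"bad truth table header in {path}")
        for line in fh:
            pid, cls, label, start, end = line.rstrip("\n").split("\t")
            if pid not in per_protein:
                per_protein[pid] = (cls, [])
                order.append(pid)
            per_protein[pid][1].append((label, int(start), int(end)))
    return TruthTable(
        entries=tuple(
            TruthEntry(pid, per_protein[pid][0], tuple(per_protein[pid][1]))
            for pid in order
        )
    )
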