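"""Architecture-based classification of pathogen-recognition proteins.

A protein's detected domain set is mapped to one of the seven canonical
classes, in fixed priority order:

    1. TIR + NBS + LRR                      -> TNL
    2. CC + NBS + LRR (no TIR)              -> CNL
    3. LRR + TM + KIN (no NBS)              -> RLK
    4. LRR + TM (no KIN, no NBS)            -> RLP
    5. LYSM + TM + KIN                      -> LYK
    6. LYSM + TM (no KIN)                   -> LYP
    7. LECM + TM + KIN                      -> LECRK

Anything else is NONCANONICAL.  Classification is set-based: the paper
defines classes by domain content, so N-to-C order is kept only in the
display code (CC=C, TIR=T, NBS=N, LRR=L, LYSM=Y, LECM=E, KIN=K, TM=M).
NLRs may carry predicted TMs, so rules 1-2 do not require TM absence,
while rules 3-4 exclude NBS to preserve the surface-receptor (PTI) vs
intracellular-receptor (ETI) split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .coils import CoilsModel, predict_coiled_coils
from .domain_scan import DomainHit, resolve_overlaps, scan_protein
from .errors import PrgScanError
from .model import ALL_DOMAIN_LABELS, ProfileHMM
from .seqio import ProteinRecord
from .tm import TmModel, predict_tm_segments

log = logging.getLogger(__name__)

NONCANONICAL = "NONCANONICAL"

#: Fixed display order of domain codes in the architecture string.
CODE_ORDER: Tuple[Tuple[str, str], ...] = (
    ("CC", "C"), ("TIR", "T"), ("NBS", "N"), ("LRR", "L"),
    ("LYSM", "Y"), ("LECM", "E"), ("KIN", "K"), ("TM", "M"),
)


@dataclass(frozen=True)
class ClassCall:
    protein_id: str
    class_label: str
    code: str
    domains_present: FrozenSet[str]


def architecture_code(domains_present: Set[str]) -> str:
    """Compact architecture string in the fixed display order."""
    return "".join(code for label, code in CODE_ORDER if label in domains_present)


def classify_architecture(domains_present: Iterable[str]) -> Tuple[str, str]:
    """Map a domain set to (class_label, code); total over all subsets."""
    s = set(domains_present)
    unknown = s - set(ALL_DOMAIN_LABELS)
    if unknown:
        raise PrgScanError(f"unknown domain labels: {sorted(unknown)}")
    code = architecture_code(s)
    if {"TIR", "NBS", "LRR"} <= s:
        return "TNL", code
    if {"CC", "NBS", "LRR"} <= s and "TIR" not in s:
        return "CNL", code
    if {"LRR", "TM", "KIN"} <= s and "NBS" not in s:
        return "RLK", code
    if {"LRR", "TM"} <= s and "KIN" not in s and "NBS" not in s:
        return "RLP", code
    if {"LYSM", "TM", "KIN"} <= s:
        return "LYK", code
    if {"LYSM", "TM"} <= s and "KIN" not in s:
        return "LYP", code
    if {"LECM", "TM", "KIN"} <= s:
        return "LECRK", code
    return NONCANONICAL, code


@dataclass(frozen=True)
class ProteinAnnotation:
    """Everything the pipeline knows about one protein."""

    protein_id: str
    hits: Tuple[DomainHit, ...]  # HMM hits plus CC/TM segments, merged
    call: ClassCall


def annotate_protein(
    models: Sequence[ProfileHMM],
    coils_model: CoilsModel,
    tm_model: TmModel,
    protein: ProteinRecord,
) -> ProteinAnnotation:
    """Scan one protein with every model and classify its architecture."""
    hits = resolve_overlaps(scan_protein(models, protein))
    for seg in predict_coiled_coils(coils_model, protein):
        hits.append(
            DomainHit(
                protein_id=protein.id, domain_label="CC",
                start=seg.start, end=seg.end, hmm_name="coils",
                logodds_score=round(seg.max_probability, 3), blosum_score=0,
            )
        )
    for seg in predict_tm_segments(tm_model, protein):
        hits.append(
            DomainHit(
                protein_id=protein.id, domain_label="TM",
                start=seg.start, end=seg.end, hmm_name="hydropathy",
                logodds_score=round(seg.peak_hydropathy, 3), blosum_score=0,
            )
        )
    hits.sort(key=lambda h: (h.start, h.domain_label, h.end))
    present = frozenset(h.domain_label for h in hits)
    label, code = classify_architecture(present)
    call = ClassCall(
        protein_id=protein.id, class_label=label, code=code, domains_present=present
    )
    return ProteinAnnotation(protein_id=protein.id, hits=tuple(hits), call=call)


def annotate_proteome(
    models: Sequence[ProfileHMM],
    coils_model: CoilsModel,
    tm_model: TmModel,
    proteome: Sequence[ProteinRecord],
) -> Tuple[List[ProteinAnnotation], Dict[str, int]]:
    """Annotate every protein; per-protein failures are logged and skipped.

    Returns the annotations (input order) and summary counts per class.
    """
    annotations: List[ProteinAnnotation] = []
    counts: Dict[str, int] = {}
    for protein in proteome:
        try:
            ann = annotate_protein(models, coils_model, tm_model, protein)
        except PrgScanError as exc:
            log.error("skipping %s: %s", protein.id, exc)
            continue
        annotations.append(ann)
        counts[ann.call.class_label] = counts.get(ann.call.class_label, 0) + 1
    return annotations, counts


# ---------------------------------------------------------------- output

CLASS_TSV_HEADER = "protein_id\tclass_label\tcode\tdomains_present\tn_hits"


def write_class_table(annotations: Iterable[ProteinAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(CLASS_TSV_HEADER + "\n")
        for a in annotations:
            doms = ";".join(sorted(a.call.domains_present)) or "none"
            code = a.call.code or "none"
            fh.write(
                f"{a.protein_id}\t{a.call.class_label}\t{code}\t{doms}\t{len(a.hits)}\n"
            )


def write_class_summary(counts: Dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"counts": dict(sorted(counts.items()))}, fh, sort_keys=True, indent=1)
        fh.write("\n")
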