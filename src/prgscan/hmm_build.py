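"""Build, filter and calibrate per-domain profile HMMs from reference MSAs.

One model is built per (class, domain region) from the class reference
alignment restricted to that region.  Candidate models then pass three
retention filters: (i) models for domains that are predicted by
dedicated tools rather than by HMMs (TM, CC) are rejected; (ii) a model
must re-detect every sequence it was built from with a positive
log-odds score; (iii) when a competing legacy model for the same domain
exists, the one with the higher F-score on a labeled benchmark is kept
(ties keep the new model).  Retained models get a minimum BLOSUM62
hit-score threshold: the floored minimum score observed over their
reference positives, so no reference sequence is ever lost to the
threshold.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import CalibrationError, ModelError
from .model import (
    DomainRegion,
    HMM_DOMAIN_LABELS,
    NON_HMM_DOMAIN_LABELS,
    ProfileHMM,
    TRANSITION_KEYS,
)
from .seqio import AA_ALPHABET, GAP, Msa, ProteinRecord

log = logging.getLogger(__name__)

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


def extract_domain_segments(msa: Msa, region: DomainRegion) -> Msa:
    """Sub-MSA restricted to the region's columns.

    Rows that are entirely gaps inside the region are dropped (logged).
    """
    if region.col_end > msa.width:
        raise ModelError(
            f"region {region.domain_label} [{region.col_start}, {region.col_end}] "
            f"exceeds MSA width {msa.width}"
        )
    rows = []
    for rid, row in msa.rows:
        seg = row[region.col_start - 1 : region.col_end]
        if set(seg) == {GAP}:
            log.info(
                "dropping all-gap row %r from %s region %s",
                rid, region.msa_id, region.domain_label,
            )
            continue
        rows.append((rid, seg))
    if len(rows) < 2:
        raise ModelError(
            f"fewer than 2 rows survive in region {region.domain_label} of "
            f"{region.msa_id}"
        )
    return Msa(rows=tuple(rows))


def build_profile_hmm(
    sub_msa: Msa,
    domain_label: str,
    class_of_origin: str,
    name: Optional[str] = None,
    pseudocount: float = 1.0,
) -> ProfileHMM:
    """Estimate a profile HMM from a domain sub-MSA.

    Match states are the columns with gap fraction < 0.5.  Emission and
    transition probabilities are Laplace estimates,
    ``(count + pseudocount) / (total + n_outcomes * pseudocount)``; the
    background is the smoothed residue frequency of the whole sub-MSA.
    """
    n_rows = len(sub_msa)
    width = sub_msa.width
    cols = [[row[c] for _, row in sub_msa.rows] for c in range(width)]
    match_cols = [
        c for c, col in enumerate(cols) if col.count(GAP) / n_rows < 0.5
    ]
    M = len(match_cols)
    if M == 0:
        raise ModelError(
            f"no match columns (all gap-majority) building {domain_label} from "
            f"{class_of_origin}"
        )

    # emissions
    match_counts = np.zeros((M, 20))
    for k, c in enumerate(match_cols):
        for res in cols[c]:
            idx = _AA_INDEX.get(res)
            if idx is not None:
                match_counts[k, idx] += 1
    match_emissions = (match_counts + pseudocount) / (
        match_counts.sum(axis=1, keepdims=True) + 20 * pseudocount
    )

    bg_counts = np.zeros(20)
    for col in cols:
        for res in col:
            idx = _AA_INDEX.get(res)
            if idx is not None:
                bg_counts[idx] += 1
    background = (bg_counts + pseudocount) / (bg_counts.sum() + 20 * pseudocount)
    insert_emissions = background.copy()

    # transitions: walk each row's state path over the layers
    match_set = set(match_cols)
    first_match, last_match = match_cols[0], match_cols[-1]
    tcounts = {k: np.zeros(M) for k in TRANSITION_KEYS}
    layer_of = {c: k for k, c in enumerate(match_cols)}
    for _, row in sub_msa.rows:
        prev = None  # (state, layer)
        for c in range(first_match, last_match + 1):
            if c in match_set:
                state = ("D", layer_of[c]) if row[c] == GAP else ("M", layer_of[c])
            elif row[c] != GAP:
                state = ("I", layer_of[_next_match(match_cols, c)] - 1)
            else:
                continue
            if prev is not None and state != prev:
                _count_transition(tcounts, prev, state)
            elif prev is not None and state[0] == "I" and prev == state:
                tcounts["ii"][state[1]] += 1
            prev = state
        if prev is not None:
            # transition into the end state from the last visited layer
            if prev[0] == "M":
                tcounts["mm"][prev[1]] += 1
            elif prev[0] == "D":
                tcounts["dm"][prev[1]] += 1

    transitions = {}
    m_tot = tcounts["mm"] + tcounts["mi"] + tcounts["md"]
    for k in ("mm", "mi", "md"):
        transitions[k] = (tcounts[k] + pseudocount) / (m_tot + 3 * pseudocount)
    i_tot = tcounts["im"] + tcounts["ii"]
    for k in ("im", "ii"):
        transitions[k] = (tcounts[k] + pseudocount) / (i_tot + 2 * pseudocount)
    d_tot = tcounts["dm"] + tcounts["dd"]
    for k in ("dm", "dd"):
        transitions[k] = (tcounts[k] + pseudocount) / (d_tot + 2 * pseudocount)

    hmm = ProfileHMM(
        name=name or f"{class_of_origin}_{domain_label}_1",
        class_of_origin=class_of_origin,
        domain_label=domain_label,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        transitions=transitions,
        background=background,
    )
    hmm.validate()
    return hmm


def _next_match(match_cols: List[int], c: int) -> int:
    for mc in match_cols:
        if mc > c:
            return mc
    raise AssertionError("insert column beyond last match column")


def _count_transition(tcounts, prev, state) -> None:
    (ps, pj), (ss, sj) = prev, state
    if ps == "M" and ss == "M" and sj == pj + 1:
        tcounts["mm"][pj] += 1
    elif ps == "M" and ss == "I" and sj == pj:
        tcounts["mi"][pj] += 1
    elif ps == "M" and ss == "D" and sj == pj + 1:
        tcounts["md"][pj] += 1
    elif ps == "I" and ss == "M" and sj == pj + 1:
        tcounts["im"][pj] += 1
    elif ps == "D" and ss == "M" and sj == pj + 1:
        tcounts["dm"][pj] += 1
    elif ps == "D" and ss == "D" and sj == pj + 1:
        tcounts["dd"][pj] += 1
    # other (rare) jumps, e.g. I followed by D, are not modeled and ignored


# ------------------------------------------------------------- filtering


@dataclass(frozen=True)
class Rejection:
    hmm_name: str
    criterion: str  # "i", "ii" or "iii"
    reason: str


def _domain_scale_hit(hmm: ProfileHMM, sequence: str):
    """Best local hit, or None unless it is a domain-scale recognition.

    Recognition requires a positive log-odds score AND an alignment
    covering at least half of the model's match states: with free local
    endpoints a one-residue alignment is almost always slightly
    positive, which would make self-recognition vacuous.
    """
    from .domain_scan import viterbi_local

    aln = viterbi_local(hmm, sequence)
    if aln.score <= 0:
        return None
    matched = sum(1 for state, _, _ in aln.path if state == "M")
    if matched < max(1, hmm.length // 2):
        return None
    return aln


def _detects(hmm: ProfileHMM, record: ProteinRecord) -> bool:
    return _domain_scale_hit(hmm, record.sequence) is not None


def _fscore_on_benchmark(
    hmm: ProfileHMM, benchmark: Sequence[Tuple[ProteinRecord, bool]]
) -> float:
    """F-score of 'positive viterbi log-odds' detection on labeled records."""
    tp = fp = fn = 0
    for record, is_positive in benchmark:
        hit = _detects(hmm, record)
        if hit and is_positive:
            tp += 1
        elif hit and not is_positive:
            fp += 1
        elif not hit and is_positive:
            fn += 1
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def filter_hmms(
    candidates: Sequence[ProfileHMM],
    training_seqs: Dict[str, Sequence[ProteinRecord]],
    legacy: Optional[Dict[str, ProfileHMM]] = None,
    benchmark: Optional[Dict[str, Sequence[Tuple[ProteinRecord, bool]]]] = None,
) -> Tuple[List[ProfileHMM], List[Rejection]]:
    """Apply the three retention criteria to candidate models.

    ``training_seqs`` maps model name to the sequences it was built
    from; ``legacy`` maps domain label to a competing older model and
    ``benchmark`` maps domain label to (record, has_domain) pairs used
    for the head-to-head comparison.
    """
    retained: List[ProfileHMM] = []
    rejections: List[Rejection] = []
    legacy = legacy or {}
    benchmark = benchmark or {}
    for hmm in candidates:
        if hmm.domain_label in NON_HMM_DOMAIN_LABELS:
            rejections.append(
                Rejection(hmm.name, "i", f"{hmm.domain_label} domains are predicted "
                          "by a dedicated tool, not by HMMs")
            )
            continue
        train = training_seqs.get(hmm.name)
        if not train:
            raise ModelError(f"candidate {hmm.name!r} has no training sequences")
        missed = [r.id for r in train if not _detects(hmm, r)]
        if missed:
            rejections.append(
                Rejection(hmm.name, "ii",
                          f"fails to re-detect its own training sequences: {missed}")
            )
            continue
        old = legacy.get(hmm.domain_label)
        if old is not None and hmm.domain_label in benchmark:
            bench = benchmark[hmm.domain_label]
            f_new = _fscore_on_benchmark(hmm, bench)
            f_old = _fscore_on_benchmark(old, bench)
            if f_new < f_old:
                rejections.append(
                    Rejection(hmm.name, "iii",
                              f"legacy model outperforms it (F {f_old:.3f} > {f_new:.3f})")
                )
                retained.append(old)
                continue
        retained.append(hmm)
    return retained, rejections


def calibrate_threshold(
    hmm: ProfileHMM, positives: Sequence[ProteinRecord]
) -> ProfileHMM:
    """Set ``min_blosum_score`` to the floored minimum hit score over positives."""
    from .domain_scan import blosum62_hit_score

    if not positives:
        raise CalibrationError(f"no positives supplied for {hmm.name!r}")
    consensus = hmm.consensus
    scores = []
    for rec in positives:
        aln = _domain_scale_hit(hmm, rec.sequence)
        if aln is None:
            raise CalibrationError(
                f"positive {rec.id!r} yields no hit from {hmm.name!r} "
                "(the model should have failed retention criterion ii)"
            )
        scores.append(
            blosum62_hit_score(rec.sequence[aln.start - 1 : aln.end], consensus)
        )
    return hmm.with_threshold(int(math.floor(min(scores))))


# ------------------------------------------------- reference-set assembly


def build_models(
    class_msas: Dict[str, Msa],
    regions: Sequence[DomainRegion],
    pseudocount: float = 1.0,
) -> Tuple[List[ProfileHMM], Dict[str, List[ProteinRecord]]]:
    """Build one candidate model per (class, region), plus pooled models.

    Regions are grouped per (msa_id, domain_label); the i-th region of a
    group yields model ``{class}_{domain}[_{subtype}]_{i}``.  When both
    LYK and LYP carry LYSM regions of equal width, an additional pooled
    model is built from their vertically concatenated sub-MSAs.
    Returns the candidates and the training sequences per model name.
    """
    candidates: List[ProfileHMM] = []
    training: Dict[str, List[ProteinRecord]] = {}
    counters: Dict[Tuple[str, str, Optional[str]], int] = {}
    lysm_parts: List[Msa] = []
    for region in regions:
        if region.msa_id not in class_msas:
            raise ModelError(f"region references unknown MSA {region.msa_id!r}")
        sub = extract_domain_segments(class_msas[region.msa_id], region)
        key = (region.msa_id, region.domain_label, region.subtype)
        counters[key] = counters.get(key, 0) + 1
        parts = [region.msa_id, region.domain_label]
        if region.subtype:
            parts.append(region.subtype)
        name = "_".join(parts + [str(counters[key])])
        hmm = build_profile_hmm(
            sub, region.domain_label, region.msa_id, name=name, pseudocount=pseudocount
        )
        candidates.append(hmm)
        training[name] = sub.ungapped_records()
        if region.domain_label == "LYSM" and region.msa_id in ("LYK", "LYP"):
            lysm_parts.append(sub)
    if len(lysm_parts) >= 2 and len({m.width for m in lysm_parts}) == 1:
        rows = tuple(r for m in lysm_parts for r in m.rows)
        pooled = Msa(rows=rows)
        name = "pooled_LYSM_1"
        hmm = build_profile_hmm(pooled, "LYSM", "pooled", name=name, pseudocount=pseudocount)
        candidates.append(hmm)
        training[name] = pooled.ungapped_records()
    return candidates, training


def build_and_calibrate(
    class_msas: Dict[str, Msa],
    regions: Sequence[DomainRegion],
    legacy: Optional[Dict[str, ProfileHMM]] = None,
    benchmark: Optional[Dict[str, Sequence[Tuple[ProteinRecord, bool]]]] = None,
) -> Tuple[List[ProfileHMM], List[Rejection]]:
    """Full model-construction pipeline: build, filter, calibrate."""
    candidates, training = build_models(class_msas, regions)
    retained, rejections = filter_hmms(candidates, training, legacy, benchmark)
    calibrated = [
        calibrate_threshold(h, training[h.name]) if h.name in training else h
        for h in retained
    ]
    return calibrated, rejections


# ----------------------------------------------------------- persistence


def read_region_table(path: str | Path) -> List[DomainRegion]:
    """TSV with columns msa_id, domain_label, col_start, col_end, subtype."""
    regions = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["msa_id", "domain_label", "col_start", "col_end", "subtype"]
        if header != expected:
            raise ModelError(f"bad region table header in {path}: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            regions.append(
                DomainRegion(
                    msa_id=f[0], domain_label=f[1],
                    col_start=int(f[2]), col_end=int(f[3]),
                    subtype=f[4] or None,
                )
            )
    return regions


def write_region_table(regions: Iterable[DomainRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("msa_id\tdomain_label\tcol_start\tcol_end\tsubtype\n")
        for r in regions:
            fh.write(
                f"{r.msa_id}\t{r.domain_label}\t{r.col_start}\t{r.col_end}\t"
                f"{r.subtype or ''}\n"
            )


def save_model_store(models: Sequence[ProfileHMM], directory: str | Path) -> None:
    """One JSON file per model plus a manifest listing them."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for m in models:
        m.to_json(directory / f"{m.name}.json")
        names.append(m.name)
    with open(directory / "models.json", "w") as fh:
        json.dump({"models": sorted(names)}, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_model_store(directory: str | Path) -> List[ProfileHMM]:
    directory = Path(directory)
    manifest = directory / "models.json"
    if not manifest.exists():
        raise ModelError(f"no model manifest at {manifest}")
    with open(manifest) as fh:
        names = json.load(fh)["models"]
    return [ProfileHMM.from_json(directory / f"{n}.json") for n in names]
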