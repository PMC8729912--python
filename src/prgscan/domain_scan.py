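"""Domain localization and scoring on proteins.

The scanner aligns each profile HMM locally to a protein: alignments may
enter the model at any match state and leave at any match state, with no
charge for the flanking sequence (free endpoints in both the sequence
and the model).  Scores are log-odds in nats: each emitted residue
contributes ``log(emission/background)`` and each transition its log
probability; entry and exit are free.  Multi-domain proteins are handled
by mask-and-rescan: the best hit is reported, its residues are masked,
and the model is realigned until no positive-scoring hit remains (or a
hit cap is reached).

Each located hit is then scored against the model consensus with a
global BLOSUM62 alignment (affine gaps: a gap of length k costs 11 + k,
the NCBI pairing for this matrix); hits below the model's calibrated
minimum BLOSUM62 score are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import SequenceError
from .model import ProfileHMM, encode_sequence
from .seqio import AA_ALPHABET, ProteinRecord

log = logging.getLogger(__name__)

_NEG = -np.inf


@dataclass(frozen=True)
class DomainHit:
    """A located, scored domain occurrence on a protein (1-based, inclusive)."""

    protein_id: str
    domain_label: str
    start: int
    end: int
    hmm_name: str
    logodds_score: float  # nats
    blosum_score: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise SequenceError(
                f"bad hit coordinates {self.start}..{self.end} on {self.protein_id!r}"
            )


@dataclass(frozen=True)
class Alignment:
    """Result of a local model-to-sequence alignment."""

    score: float
    start: int  # 1-based, inclusive
    end: int
    path: Tuple[Tuple[str, int, int], ...]  # (state, layer, seq position), 1-based


def _logodds_tables(hmm: ProfileHMM):
    """Log-odds emission tables with an extra column for X (odds ratio 1)."""
    with np.errstate(divide="ignore"):
        lm = np.log(hmm.match_emissions) - np.log(hmm.background)[None, :]
        li = np.log(hmm.insert_emissions) - np.log(hmm.background)
        lt = {k: np.log(v) for k, v in hmm.transitions.items()}
    lm = np.concatenate([lm, np.zeros((hmm.length, 1))], axis=1)
    li = np.concatenate([li, [0.0]])
    return np.ascontiguousarray(lm), np.ascontiguousarray(li), lt


@njit(cache=True)
def _viterbi_kernel(lm, li, lmm, lmi, lmd, lim, lii, ldm, ldd, enc, masked):
    L = enc.shape[0]
    M = lm.shape[0]
    NEG = -np.inf
    prevM = np.full(M, NEG)
    prevI = np.full(M, NEG)
    prevD = np.full(M, NEG)
    psM = np.zeros(M, np.int64)
    psI = np.zeros(M, np.int64)
    psD = np.zeros(M, np.int64)
    curM = np.empty(M)
    curI = np.empty(M)
    curD = np.empty(M)
    csM = np.zeros(M, np.int64)
    csI = np.zeros(M, np.int64)
    csD = np.zeros(M, np.int64)
    bpM = np.zeros((L, M), np.int8)  # 0 entry, 1 from M, 2 from I, 3 from D
    bpI = np.zeros((L, M), np.int8)  # 0 from M, 1 from I
    bpD = np.zeros((L, M), np.int64)  # origin match layer (same row)
    best = NEG
    best_i = -1
    best_j = -1
    best_s = -1
    for i in range(L):
        x = enc[i]
        if masked[i]:
            for j in range(M):
                curM[j] = NEG
                curI[j] = NEG
                curD[j] = NEG
        else:
            for j in range(M):
                # entry (fresh local start) is free
                sc = 0.0
                ch = np.int8(0)
                st = i
                if j > 0:
                    v = prevM[j - 1] + lmm[j - 1]
                    if v > sc or (v == sc and psM[j - 1] < st):
                        sc = v
                        ch = np.int8(1)
                        st = psM[j - 1]
                    v = prevI[j - 1] + lim[j - 1]
                    if v > sc or (v == sc and psI[j - 1] < st):
                        sc = v
                        ch = np.int8(2)
                        st = psI[j - 1]
                    v = prevD[j - 1] + ldm[j - 1]
                    if v > sc or (v == sc and psD[j - 1] < st):
                        sc = v
                        ch = np.int8(3)
                        st = psD[j - 1]
                curM[j] = lm[j, x] + sc
                bpM[i, j] = ch
                csM[j] = st
                # insert layer j (valid for j < M-1)
                if j < M - 1:
                    a = prevM[j] + lmi[j]
                    b = prevI[j] + lii[j]
                    if b > a or (b == a and psI[j] < psM[j]):
                        curI[j] = li[x] + b
                        bpI[i, j] = 1
                        csI[j] = psI[j]
                    else:
                        curI[j] = li[x] + a
                        bpI[i, j] = 0
                        csI[j] = psM[j]
                else:
                    curI[j] = NEG
                    csI[j] = i
            # delete chain within the row, fed by curM
            curD[0] = NEG
            csD[0] = i
            for j in range(1, M):
                v = curM[j - 1] + lmd[j - 1]
                ch_k = j - 1
                ch_s = csM[j - 1]
                w = curD[j - 1] + ldd[j - 1]
                if w > v or (w == v and csD[j - 1] < ch_s):
                    v = w
                    ch_k = bpD[i, j - 1]
                    ch_s = csD[j - 1]
                curD[j] = v
                bpD[i, j] = ch_k
                csD[j] = ch_s
        for j in range(M):
            s = curM[j]
            if s > best or (
                s == best and (csM[j] < best_s or (csM[j] == best_s and i < best_i))
            ):
                best = s
                best_i = i
                best_j = j
                best_s = csM[j]
        prevM, curM = curM, prevM
        prevI, curI = curI, prevI
        prevD, curD = curD, prevD
        tmp = psM
        psM = csM
        csM = tmp
        tmp = psI
        psI = csI
        csI = tmp
        tmp = psD
        psD = csD
        csD = tmp
    return best, best_i, best_j, bpM, bpI, bpD


@njit(cache=True)
def _forward_kernel(lm, li, lmm, lmi, lmd, lim, lii, ldm, ldd, enc, masked):
    L = enc.shape[0]
    M = lm.shape[0]
    NEG = -np.inf
    prevM = np.full(M, NEG)
    prevI = np.full(M, NEG)
    prevD = np.full(M, NEG)
    curM = np.empty(M)
    curI = np.empty(M)
    curD = np.empty(M)
    total = NEG
    for i in range(L):
        x = enc[i]
        if masked[i]:
            for j in range(M):
                curM[j] = NEG
                curI[j] = NEG
                curD[j] = NEG
        else:
            for j in range(M):
                acc = 0.0  # entry weight exp(0)
                if j > 0:
                    acc = np.logaddexp(acc, prevM[j - 1] + lmm[j - 1])
                    acc = np.logaddexp(acc, prevI[j - 1] + lim[j - 1])
                    acc = np.logaddexp(acc, prevD[j - 1] + ldm[j - 1])
                curM[j] = lm[j, x] + acc
                if j < M - 1:
                    curI[j] = li[x] + np.logaddexp(
                        prevM[j] + lmi[j], prevI[j] + lii[j]
                    )
                else:
                    curI[j] = NEG
            curD[0] = NEG
            for j in range(1, M):
                curD[j] = np.logaddexp(
                    curM[j - 1] + lmd[j - 1], curD[j - 1] + ldd[j - 1]
                )
        for j in range(M):
            total = np.logaddexp(total, curM[j])  # free exit at any match state
        prevM, curM = curM, prevM
        prevI, curI = curI, prevI
        prevD, curD = curD, prevD
    return total


def _traceback(bpM, bpI, bpD, end_i: int, end_j: int):
    """Recover the best path (list of (state, layer, position), 1-based)."""
    path = []
    i, j, state = end_i, end_j, "M"
    while True:
        if state == "M":
            path.append(("M", j + 1, i + 1))
            ch = bpM[i, j]
            if ch == 0:
                break
            i, j = i - 1, j - 1
            state = {1: "M", 2: "I", 3: "D"}[int(ch)]
            if state == "D":
                # expand the silent delete chain on row i
                k = int(bpD[i + 1 - 1, j])  # chain recorded on its own row
                for dj in range(j, k, -1):
                    path.append(("D", dj + 1, i + 1))
                j = k
                state = "M"
        elif state == "I":
            path.append(("I", j + 1, i + 1))
            ch = bpI[i, j]
            i = i - 1
            state = "M" if ch == 0 else "I"
    path.reverse()
    return tuple(path)


def viterbi_local(
    hmm: ProfileHMM, seq: str, mask: Optional[np.ndarray] = None
) -> Alignment:
    """Best local log-odds alignment of ``hmm`` to ``seq``.

    Ties between equal-scoring cells prefer the smaller start position,
    then the smaller end position.
    """
    if not seq:
        raise SequenceError("cannot align an empty sequence")
    enc = encode_sequence(seq)
    masked = np.zeros(len(seq), dtype=np.bool_) if mask is None else np.asarray(mask, dtype=np.bool_)
    lm, li, lt = _logodds_tables(hmm)
    best, bi, bj, bpM, bpI, bpD = _viterbi_kernel(
        lm, li, lt["mm"], lt["mi"], lt["md"], lt["im"], lt["ii"], lt["dm"], lt["dd"],
        enc, masked,
    )
    if not np.isfinite(best):
        return Alignment(score=_NEG, start=1, end=1, path=())
    path = _traceback(bpM, bpI, bpD, bi, bj)
    emitted = [p for s, _, p in path if s in ("M", "I")]
    return Alignment(score=float(best), start=min(emitted), end=max(emitted), path=path)


def forward_local(hmm: ProfileHMM, seq: str, mask: Optional[np.ndarray] = None) -> float:
    """Total log-odds (nats) summed over all local alignments of ``hmm`` to ``seq``."""
    if not seq:
        raise SequenceError("cannot align an empty sequence")
    enc = encode_sequence(seq)
    masked = np.zeros(len(seq), dtype=np.bool_) if mask is None else np.asarray(mask, dtype=np.bool_)
    lm, li, lt = _logodds_tables(hmm)
    return float(
        _forward_kernel(
            lm, li, lt["mm"], lt["mi"], lt["md"], lt["im"], lt["ii"], lt["dm"], lt["dd"],
            enc, masked,
        )
    )


# ---------------------------------------------------------------- BLOSUM62

_aligner: Optional[PairwiseAligner] = None


def _get_aligner() -> PairwiseAligner:
    global _aligner
    if _aligner is None:
        sub = substitution_matrices.load("BLOSUM62")
        xi = sub.alphabet.index("X")
        sub[xi, :] = 0.0
        sub[:, xi] = 0.0
        a = PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = sub
        a.open_gap_score = -12.0  # gap of length k costs 11 + k
        a.extend_gap_score = -1.0
        _aligner = a
    return _aligner


def blosum62_hit_score(hit_seq: str, consensus: str) -> int:
    """Global BLOSUM62 alignment score of a hit against the model consensus.

    Affine gap costs follow the matrix's standard pairing (open 11,
    extend 1 per residue); X scores 0 against every residue.
    """
    if not hit_seq or not consensus:
        raise SequenceError("blosum62_hit_score requires two non-empty sequences")
    return int(round(_get_aligner().score(hit_seq.upper(), consensus.upper())))


# ---------------------------------------------------------------- scanning


def scan_protein(
    models: Sequence[ProfileHMM],
    protein: ProteinRecord,
    max_hits_per_model: int = 10,
) -> List[DomainHit]:
    """Locate all above-threshold domain hits of ``models`` on one protein.

    Per model, the best local hit is found, its residues are masked, and
    the scan repeats while the log-odds score stays positive (up to
    ``max_hits_per_model`` iterations).  Hits are then filtered by the
    model's calibrated minimum BLOSUM62 score and reported sorted by
    (start, domain_label).
    """
    hits: List[DomainHit] = []
    seq = protein.sequence
    for hmm in models:
        consensus = hmm.consensus
        mask = np.zeros(len(seq), dtype=np.bool_)
        for _ in range(max_hits_per_model):
            if mask.all():
                break
            aln = viterbi_local(hmm, seq, mask=mask)
            if aln.score <= 0:
                break
            mask[aln.start - 1 : aln.end] = True
            bl = blosum62_hit_score(seq[aln.start - 1 : aln.end], consensus)
            if hmm.min_blosum_score is not None and bl < hmm.min_blosum_score:
                continue
            hits.append(
                DomainHit(
                    protein_id=protein.id,
                    domain_label=hmm.domain_label,
                    start=aln.start,
                    end=aln.end,
                    hmm_name=hmm.name,
                    logodds_score=round(aln.score, 3),
                    blosum_score=bl,
                )
            )
    hits.sort(key=lambda h: (h.start, h.domain_label, h.end, h.hmm_name))
    return hits


def resolve_overlaps(hits: Iterable[DomainHit]) -> List[DomainHit]:
    """Merge overlapping same-domain hits into their union interval.

    Merged hits keep the maximum of each score and the hmm_name of the
    highest-log-odds member.  Hits with different domain labels are
    never merged.
    """
    by_label: Dict[Tuple[str, str], List[DomainHit]] = {}
    for h in hits:
        by_label.setdefault((h.protein_id, h.domain_label), []).append(h)
    out: List[DomainHit] = []
    for (_, _), group in sorted(by_label.items()):
        group.sort(key=lambda h: (h.start, h.end))
        current = group[0]
        for h in group[1:]:
            if h.start <= current.end:  # >= 1 residue overlap
                best_name = (
                    current.hmm_name
                    if current.logodds_score >= h.logodds_score
                    else h.hmm_name
                )
                current = replace(
                    current,
                    end=max(current.end, h.end),
                    hmm_name=best_name,
                    logodds_score=max(current.logodds_score, h.logodds_score),
                    blosum_score=max(current.blosum_score, h.blosum_score),
                )
            else:
                out.append(current)
                current = h
        out.append(current)
    out.sort(key=lambda h: (h.protein_id, h.start, h.domain_label, h.end))
    return out


# ---------------------------------------------------------------- output

HIT_TSV_HEADER = "protein_id\tdomain_label\tstart\tend\thmm_name\tlogodds_score\tblosum_score"


def write_hits_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(HIT_TSV_HEADER + "\n")
        for h in hits:
            fh.write(
                f"{h.protein_id}\t{h.domain_label}\t{h.start}\t{h.end}\t"
                f"{h.hmm_name}\t{h.logodds_score:.3f}\t{h.blosum_score}\n"
            )


def read_hits_tsv(path: str | Path) -> List[DomainHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != HIT_TSV_HEADER.strip():
            raise SequenceError(f"unrecognized hit table header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hits.append(
                DomainHit(
                    protein_id=f[0], domain_label=f[1], start=int(f[2]), end=int(f[3]),
                    hmm_name=f[4], logodds_score=float(f[5]), blosum_score=int(f[6]),
                )
            )
    return hits


def write_hits_gff3(hits: Iterable[DomainHit], path: str | Path) -> None:
    """One GFF3 feature per hit, protein coordinates, score = blosum_score."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in hits:
            fh.write(
                f"{h.protein_id}\tprgscan\tprotein_match\t{h.start}\t{h.end}\t"
                f"{h.blosum_score}\t.\t.\tName={h.domain_label};Target={h.hmm_name}\n"
            )
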