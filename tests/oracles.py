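"""Independent oracles for the alignment and sampling machinery.

These deliberately share no code with the package's dynamic-programming
kernels: alignments are checked by exhaustive enumeration of every
legal state path, and generative lengths by the closed-form expectation
of the state chain.
"""

from __future__ import annotations

from typing import List

import numpy as np

from prgscan.model import ProfileHMM, encode_sequence


def enumerate_alignment_scores(hmm: ProfileHMM, seq: str) -> np.ndarray:
    """Scores of ALL local alignments (enter/leave at any match state)."""
    enc = encode_sequence(seq)
    M, L = hmm.length, len(seq)
    with np.errstate(divide="ignore"):
        lm = np.log(hmm.match_emissions) - np.log(hmm.background)[None, :]
        lm = np.concatenate([lm, np.zeros((M, 1))], axis=1)
        li = np.concatenate(
            [np.log(hmm.insert_emissions) - np.log(hmm.background), [0.0]]
        )
        lt = {k: np.log(v) for k, v in hmm.transitions.items()}
    out: List[float] = []

    def go(i: int, j: int, state: str, score: float) -> None:
        if state == "M":
            out.append(score)  # any match state is a legal exit
            if j + 1 < M:
                if i + 1 < L:
                    go(i + 1, j + 1, "M", score + lt["mm"][j] + lm[j + 1, enc[i + 1]])
                go(i, j + 1, "D", score + lt["md"][j])
            if j < M - 1 and i + 1 < L:
                go(i + 1, j, "I", score + lt["mi"][j] + li[enc[i + 1]])
        elif state == "I":
            if i + 1 < L:
                go(i + 1, j, "I", score + lt["ii"][j] + li[enc[i + 1]])
                if j + 1 < M:
                    go(i + 1, j + 1, "M", score + lt["im"][j] + lm[j + 1, enc[i + 1]])
        else:  # D (silent)
            if j + 1 < M:
                if i + 1 < L:
                    go(i + 1, j + 1, "M", score + lt["dm"][j] + lm[j + 1, enc[i + 1]])
                go(i, j + 1, "D", score + lt["dd"][j])

    for i in range(L):
        for j in range(M):
            go(i, j, "M", lm[j, enc[i]])
    return np.asarray(out)


def expected_emitted_length(hmm: ProfileHMM) -> float:
    """Closed-form E[emitted length] of a generative pass from match state 1.

    Layer-visit probabilities follow the chain geometry; the number of
    residues emitted per insert-state entry is geometric with mean
    1 / (1 - ii).
    """
    t = hmm.transitions
    M = hmm.length
    p_m = np.zeros(M)
    p_d = np.zeros(M)
    p_m[0] = 1.0
    expected = 0.0
    for j in range(M):
        expected += p_m[j]  # one residue per visited match state
        if j < M - 1:
            enter_i = p_m[j] * t["mi"][j]
            expected += enter_i / (1.0 - t["ii"][j])
            p_m[j + 1] = p_m[j] * (t["mm"][j] + t["mi"][j]) + p_d[j] * t["dm"][j]
            p_d[j + 1] = p_m[j] * t["md"][j] + p_d[j] * t["dd"][j]
    return expected


def random_profile_hmm(rng: np.random.Generator, n_states: int) -> ProfileHMM:
    """A fully random (but valid) model for property tests."""
    me = rng.dirichlet(np.full(20, 0.5), size=n_states)
    mtr = rng.dirichlet(np.full(3, 1.0), size=n_states)
    itr = rng.dirichlet(np.full(2, 1.0), size=n_states)
    dtr = rng.dirichlet(np.full(2, 1.0), size=n_states)
    transitions = {
        "mm": mtr[:, 0].copy(), "mi": mtr[:, 1].copy(), "md": mtr[:, 2].copy(),
        "im": itr[:, 0].copy(), "ii": itr[:, 1].copy(),
        "dm": dtr[:, 0].copy(), "dd": dtr[:, 1].copy(),
    }
    return ProfileHMM(
        name="random",
        class_of_origin="TNL",
        domain_label="NBS",
        match_emissions=me,
        insert_emissions=rng.dirichlet(np.full(20, 5.0)),
        transitions=transitions,
        background=rng.dirichlet(np.full(20, 5.0)),
    )
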