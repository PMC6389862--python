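"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the path
enumerator walks every legal glocal path explicitly, the legality checker
re-derives transition rules from first principles, and the profile builder
oracle recounts emissions by hand.
"""

from __future__ import annotations

import math

import numpy as np

from pirsite.profilehmm import (T_DD, T_DM, T_II, T_IM, T_MD, T_MI, T_MM,
                                ProfileHMM)
from pirsite.rulestore import AMINO_ACIDS

NEG_INF = float("-inf")


def _log2(p: float) -> float:
    return math.log2(p) if p > 0 else NEG_INF


def _logodds_tables(hmm: ProfileHMM):
    bg = hmm.background

    def lo(p, b):
        return _log2(p) - _log2(b) if b > 0 else NEG_INF

    me = [[lo(hmm.match_emissions[k][a], bg[a]) for a in range(20)]
          for k in range(hmm.M + 1)]
    ie = [[lo(hmm.insert_emissions[k][a], bg[a]) for a in range(20)]
          for k in range(hmm.M + 1)]
    t = [[_log2(p) for p in row] for row in hmm.transitions]
    return me, ie, t


def enumerate_best_score(hmm: ProfileHMM, sequence: str) -> float:
    """Max log-odds over all legal glocal paths, by explicit enumeration.

    Glocal grammar: after any free left flank, enter at M1 (emitting) or D1;
    walk nodes 1..M via M/D with optional I_k (1 <= k < M) emissions in
    between; exit from M_M or D_M to E; any free right flank.
    """
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    sym = [aa_index.get(ch, -1) for ch in sequence.upper()]
    L, M = len(sym), hmm.M
    me, ie, t = _logodds_tables(hmm)

    def m_emit(k, i):
        return 0.0 if sym[i] < 0 else me[k][sym[i]]

    def i_emit(k, i):
        return 0.0 if sym[i] < 0 else ie[k][sym[i]]

    best = NEG_INF

    def walk(kind, k, i, score):
        # i = number of residues consumed so far (flank + emitted)
        nonlocal best
        if score == NEG_INF:
            return
        if k == M:
            end = score + (t[M][T_MM] if kind == "M" else t[M][T_DM])
            if end > best:
                best = end
            return
        # to M_{k+1}: emit one residue
        if i < L:
            tr = {"M": t[k][T_MM], "I": t[k][T_IM], "D": t[k][T_DM]}[kind]
            walk("M", k + 1, i + 1, score + tr + m_emit(k + 1, i))
        # to D_{k+1}
        if kind != "I":
            tr = t[k][T_MD] if kind == "M" else t[k][T_DD]
            walk("D", k + 1, i, score + tr)
        # to I_k (only between nodes, and only from M/I)
        if 1 <= k < M and kind in "MI" and i < L:
            tr = t[k][T_MI] if kind == "M" else t[k][T_II]
            walk("I", k, i + 1, score + tr + i_emit(k, i))

    for flank in range(L + 1):
        if flank < L:
            walk("M", 1, flank + 1, t[0][T_MM] + m_emit(1, flank))
        walk("D", 1, flank, t[0][T_MD])
    return best


def path_is_legal(hmm: ProfileHMM, path, sequence: str) -> bool:
    """Transition-by-transition validity check of a glocal state path."""
    if not path:
        return False
    M = hmm.M
    L = len(sequence)
    # entry and exit
    if path[0][:2] not in (("M", 1), ("D", 1)):
        return False
    if path[-1][0] not in "MD" or path[-1][1] != M:
        return False
    allowed = {("M", "M", 1), ("M", "D", 1), ("M", "I", 0),
               ("I", "M", 1), ("I", "I", 0),
               ("D", "M", 1), ("D", "D", 1)}
    prev_pos = None
    for idx, (kind, node, pos) in enumerate(path):
        if kind in "MI":
            if pos is None or not 1 <= pos <= L:
                return False
            if prev_pos is not None and pos != prev_pos + 1:
                return False
            prev_pos = pos
        else:
            if pos is not None:
                return False
        if kind == "I" and not 1 <= node <= M - 1:
            return False
        if idx:
            pk, pn, _ = path[idx - 1]
            if (pk, kind, node - pn) not in allowed:
                return False
            if kind == "I" and node != pn:
                return False
    # every node 1..M visited exactly once by an M or D state
    visited = [n for k, n, _ in path if k in "MD"]
    return visited == list(range(1, M + 1))


def path_score(hmm: ProfileHMM, path, sequence: str) -> float:
    """Independent rescoring of a state path (log-odds, bits)."""
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    sym = [aa_index.get(ch, -1) for ch in sequence.upper()]
    me, ie, t = _logodds_tables(hmm)
    score = 0.0
    prev = ("M", 0)
    for kind, node, pos in path:
        tr = {"MM": T_MM, "MI": T_MI, "MD": T_MD, "IM": T_IM,
              "II": T_II, "DM": T_DM, "DD": T_DD}[prev[0] + kind]
        score += t[prev[1]][tr]
        if kind == "M":
            score += 0.0 if sym[pos - 1] < 0 else me[node][sym[pos - 1]]
        elif kind == "I":
            score += 0.0 if sym[pos - 1] < 0 else ie[node][sym[pos - 1]]
        prev = (kind, node)
    score += t[prev[1]][T_MM] if prev[0] == "M" else t[prev[1]][T_DM]
    return score


def random_reduced_profile(rng, M: int, n_letters: int = 3,
                           concentration: float = 0.6) -> ProfileHMM:
    """Random profile whose emissions live on the first ``n_letters``
    amino acids, with random (valid) transition distributions."""
    me = np.zeros((M + 1, 20))
    ie = np.zeros((M + 1, 20))
    bg = np.zeros(20)
    bg[:n_letters] = rng.dirichlet(np.full(n_letters, 5.0))
    for k in range(M + 1):
        me[k, :n_letters] = rng.dirichlet(np.full(n_letters, concentration))
        ie[k, :n_letters] = rng.dirichlet(np.full(n_letters, 5.0))
    trans = np.zeros((M + 1, 7))
    for k in range(M + 1):
        trans[k, [T_MM, T_MI, T_MD]] = rng.dirichlet([6.0, 1.0, 1.0])
        trans[k, [T_IM, T_II]] = rng.dirichlet([3.0, 1.0])
        trans[k, [T_DM, T_DD]] = rng.dirichlet([3.0, 1.0])
    hmm = ProfileHMM(hmm_id=f"rand{M}", match_emissions=me,
                     insert_emissions=ie, transitions=trans, background=bg)
    hmm.validate()
    return hmm


def all_sequences(alphabet: str, max_len: int):
    from itertools import product

    for n in range(1, max_len + 1):
        for combo in product(alphabet, repeat=n):
            yield "".join(combo)
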