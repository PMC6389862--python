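"""Self-contained Plan7-style profile HMM core for site-specific HMMs (SRHMMs).

An SRHMM is built from the concatenation of conserved alignment blocks
covering the propagatable residues of a protein family, so it is much more
focused on those residues than a full-length family HMM.  This module
provides:

* :func:`extract_site_blocks` — cut and concatenate the conserved windows
  around site columns out of a multiple alignment, keeping the column
  provenance map;
* :func:`build_profile` — estimate a profile HMM from an alignment with
  background-mixture pseudocounts (no sequence or entropy weighting);
* :func:`read_profile` / :func:`write_profile` — HMMER3 ASCII ("HMMER3/f")
  interchange, storing negative natural-log probabilities;
* :func:`viterbi_align` — maximum log-odds alignment in *glocal* mode
  (global across the profile, local along the sequence: the whole conserved
  region must be matched, flanking sequence residues are free);
* :func:`calibrate` / :func:`score_to_evalue` — a Gumbel tail fitted to
  Viterbi bit scores of seeded random background sequences, giving
  per-profile e-values; the prediction gate defaults to 1e-4 downstream.

All probability arithmetic is done in log space; probability zero is
represented as ``-inf``, never as an underflowed float.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rulestore import AMINO_ACIDS

GAP_CHARS = set("-.")
#: Ambiguity codes scored with background probability (log-odds zero);
#: they never satisfy residue conditions downstream.
AMBIGUOUS = set("BZXUOJ")

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# transition column order, matching the HMMER3 node transition line
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)
_TRANS_GROUPS = ((T_MM, T_MI, T_MD), (T_IM, T_II), (T_DM, T_DD))

NEG_INF = float("-inf")


class ProfileError(ValueError):
    pass


class HmmFormatError(ValueError):
    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationParams:
    """Gumbel tail parameters for converting bit scores to e-values.

    ``evalue = Z * exp(-lam * (score - tau))`` clamped to ``[0, Z]``.
    """

    lam: float
    tau: float
    n_calib: int = 0

    def __post_init__(self):
        if not self.lam > 0:
            raise CalibrationError("Gumbel slope lambda must be > 0")


@dataclass
class ProfileHMM:
    """A Plan7-style protein profile.

    Arrays are indexed by node 1..M; row 0 is the begin node (its M row acts
    as B, so ``transitions[0, T_MM]`` is B->M1 and ``transitions[0, T_MD]``
    is B->D1; ``insert_emissions[0]`` is the I0 state).  At node M the M->M
    slot holds M->E and D->M holds D->E, following HMMER3 conventions.
    """

    hmm_id: str
    match_emissions: np.ndarray   # (M+1, 20); row 0 unused
    insert_emissions: np.ndarray  # (M+1, 20)
    transitions: np.ndarray       # (M+1, 7), probabilities
    background: np.ndarray        # (20,)
    calibration: CalibrationParams | None = None
    extra_header: tuple[str, ...] = ()

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0] - 1

    @property
    def consensus(self) -> str:
        idx = np.argmax(self.match_emissions[1:], axis=1)
        return "".join(AMINO_ACIDS[i] for i in idx)

    def validate(self, atol: float = 1e-9) -> None:
        M = self.M
        if M < 1:
            raise ProfileError("profile must have at least one match state")
        if not np.allclose(self.match_emissions[1:].sum(axis=1), 1.0, atol=atol):
            raise ProfileError("match emission rows must sum to 1")
        if not np.allclose(self.insert_emissions.sum(axis=1), 1.0, atol=atol):
            raise ProfileError("insert emission rows must sum to 1")
        if not np.allclose(self.background.sum(), 1.0, atol=atol):
            raise ProfileError("background must sum to 1")
        for lo_hi in _TRANS_GROUPS:
            sums = self.transitions[:, list(lo_hi)].sum(axis=1)
            if not np.allclose(sums, 1.0, atol=atol):
                raise ProfileError("transition groups must sum to 1")


@dataclass
class HmmAlignment:
    """A glocal state path binding sequence positions to profile nodes.

    ``state_path`` lists ``(kind, node, pos)`` with kind in {"M","I","D"},
    node the profile node index (1-based) and pos the 1-based sequence
    position for emitting states (None for deletes).  Flanking residues
    outside the profile are not part of the path.
    """

    sequence_id: str
    state_path: list[tuple[str, int, int | None]]
    bit_score: float
    evalue: float | None = None

    def match_position(self, node: int) -> int | None:
        """Sequence position aligned to match state ``node``, else None."""
        for kind, k, pos in self.state_path:
            if k == node and kind == "M":
                return pos
        return None

    def node_of_position(self, pos: int) -> tuple[str, int] | None:
        """(state kind, node) that emits sequence position ``pos``, else None."""
        for kind, k, p in self.state_path:
            if p == pos:
                return kind, k
        return None


@dataclass
class SiteBlockSpec:
    """Provenance of a concatenated site alignment.

    ``blocks`` are half-open ``(start, stop)`` column intervals of the source
    alignment, non-overlapping and increasing; ``source_columns[j]`` is the
    source column of concatenated column ``j`` (0-based).
    """

    blocks: list[tuple[int, int]]
    source_columns: list[int]


def extract_site_blocks(msa: list[str], site_columns: set[int], flank: int
                        ) -> tuple[list[str], SiteBlockSpec]:
    """Concatenate the windows around each site column into a sub-alignment.

    ``site_columns`` are 0-based column indices of the propagatable residues;
    each contributes the window ``[c - flank, c + flank]`` clipped to the
    alignment, and overlapping windows are merged.
    """
    if not msa:
        raise ProfileError("empty alignment")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ProfileError("alignment rows differ in length")
    if not site_columns:
        raise ProfileError("an SRHMM must cover at least one site column")
    if flank < 0:
        raise ProfileError("flank must be non-negative")
    bad = [c for c in site_columns if not 0 <= c < width]
    if bad:
        raise ProfileError(f"site columns out of range: {sorted(bad)}")

    intervals = sorted((max(0, c - flank), min(width, c + flank + 1))
                       for c in site_columns)
    blocks: list[tuple[int, int]] = []
    for start, stop in intervals:
        if blocks and start <= blocks[-1][1]:
            blocks[-1] = (blocks[-1][0], max(blocks[-1][1], stop))
        else:
            blocks.append((start, stop))
    source_columns = [c for start, stop in blocks for c in range(start, stop)]
    sub = ["".join(row[c] for c in source_columns) for row in msa]
    return sub, SiteBlockSpec(blocks=blocks, source_columns=source_columns)


# --------------------------------------------------------------------------
# construction from an alignment

def _column_states(row: str, match_cols: list[int], is_match: list[bool]
                   ) -> list[tuple[str, int]]:
    # state sequence (kind, node) for one aligned row; inserts attach to the
    # preceding node (node 0 before the first match column)
    col_node = {}
    node = 0
    for j, m in enumerate(is_match):
        if m:
            node += 1
        col_node[j] = node
    states = []
    for j, ch in enumerate(row):
        if is_match[j]:
            if ch in GAP_CHARS:
                states.append(("D", col_node[j]))
            else:
                states.append(("M", col_node[j]))
        elif ch not in GAP_CHARS:
            states.append(("I", col_node[j]))
    return states


def _doctor_path(states: list[tuple[str, int]]) -> list[tuple[str, int]]:
    # Plan7 has no I<->D transitions; merge each adjacent D+I pair into a
    # match state (the inserted residue emitted at the deleted node), as the
    # standard toolchain's trace doctoring does
    out = list(states)
    changed = True
    while changed:
        changed = False
        for i in range(len(out) - 1):
            (k1, n1), (k2, n2) = out[i], out[i + 1]
            if k1 == "I" and k2 == "D":
                out[i:i + 2] = [("M", n2)]
                changed = True
                break
            if k1 == "D" and k2 == "I":
                out[i:i + 2] = [("M", n1)]
                changed = True
                break
    return out


def build_profile(msa, background=None, gap_threshold: float = 0.5,
                  pseudocount_weight: float = 1.0, hmm_id: str = "profile"
                  ) -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Columns whose gap fraction is strictly below ``gap_threshold`` become
    match states.  Emissions are ``(counts + w * background)`` normalized;
    transitions are counted from the observed per-row state paths with the
    same background-mixture pseudocount scheme (uniform prior within each
    transition group).  A transition group never observed and given zero
    pseudocount weight falls back to the deterministic "continue" move
    (M->M, I->M, D->M).

    ``msa`` is a list of equal-length aligned strings (or (id, row) pairs).
    """
    rows = [r[1] if isinstance(r, tuple) else str(r) for r in msa]
    rows = [r.upper() for r in rows]
    if len(rows) < 2:
        raise ProfileError("alignment must have at least 2 rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ProfileError("alignment rows differ in length")
    if background is None:
        background = np.full(20, 1.0 / 20)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or not math.isclose(background.sum(), 1.0,
                                                     abs_tol=1e-9):
        raise ProfileError("background must be 20 frequencies summing to 1")

    n = len(rows)
    gap_frac = [sum(r[j] in GAP_CHARS for r in rows) / n for j in range(width)]
    is_match = [f < gap_threshold for f in gap_frac]
    match_cols = [j for j, m in enumerate(is_match) if m]
    M = len(match_cols)
    if M == 0:
        raise ProfileError("alignment has no match columns at this gap threshold")

    w = float(pseudocount_weight)
    if w < 0:
        raise ProfileError("pseudocount weight must be non-negative")

    me = np.zeros((M + 1, 20))
    ie = np.zeros((M + 1, 20))
    for k, j in enumerate(match_cols, start=1):
        for r in rows:
            ch = r[j]
            if ch in _AA_INDEX:
                me[k, _AA_INDEX[ch]] += 1
    node_of_col = {}
    node = 0
    for j, m in enumerate(is_match):
        if m:
            node += 1
        node_of_col[j] = node
    for j in range(width):
        if is_match[j]:
            continue
        k = node_of_col[j]
        for r in rows:
            ch = r[j]
            if ch in _AA_INDEX:
                ie[k, _AA_INDEX[ch]] += 1

    def _normalize_em(counts):
        out = np.empty_like(counts)
        for k in range(counts.shape[0]):
            total = counts[k].sum()
            if total + w == 0:
                out[k] = background  # unobserved, no pseudocounts: background
            else:
                out[k] = (counts[k] + w * background) / (total + w)
        return out

    match_em = _normalize_em(me)
    match_em[0] = 0.0
    insert_em = _normalize_em(ie)

    tc = np.zeros((M + 1, 7))
    for r in rows:
        states = _doctor_path(_column_states(r, match_cols, is_match))
        prev = ("M", 0)  # begin node acts as M0
        for st in states:
            tc[prev[1], _trans_index(prev[0], st[0])] += 1
            prev = st
        # exit to E, stored in the node-M row (I_M -> E counted as I->M)
        tc[prev[1], _trans_index(prev[0], "M")] += 1

    trans = np.zeros((M + 1, 7))
    for k in range(M + 1):
        for group in _TRANS_GROUPS:
            counts = tc[k, list(group)]
            total = counts.sum()
            prior = w / len(group)
            if total + w == 0:
                probs = np.zeros(len(group))
                probs[0] = 1.0  # deterministic continue (x->M)
            else:
                probs = (counts + prior) / (total + w)
            trans[k, list(group)] = probs
    # begin node: only B->M1 / B->I0 / B->D1 and I0 transitions are real
    trans[0, T_DM], trans[0, T_DD] = 1.0, 0.0

    hmm = ProfileHMM(hmm_id=hmm_id, match_emissions=match_em,
                     insert_emissions=insert_em, transitions=trans,
                     background=background)
    hmm.validate()
    return hmm


def _trans_index(a: str, b: str) -> int:
    return {"MM": T_MM, "MI": T_MI, "MD": T_MD,
            "IM": T_IM, "II": T_II, "DM": T_DM, "DD": T_DD}[a + b]


# --------------------------------------------------------------------------
# HMMER3 ASCII I/O

def _fmt(p: float) -> str:
    if p <= 0.0:
        return "*"
    return f"{-math.log(p):.5f}"


def _parse_logprob(tok: str, line_no: int) -> float:
    if tok == "*":
        return 0.0
    try:
        return math.exp(-float(tok))
    except ValueError:
        raise HmmFormatError(f"bad probability token {tok!r}", line_no)


def write_profile(hmm: ProfileHMM) -> str:
    """Render a profile in HMMER3 ASCII ("HMMER3/f") format.

    Probabilities are stored as negative natural logs, zero as ``*``.  The
    COMPO line carries the model background so read/write round-trips it; a
    ``STATS LOCAL VITERBI`` line carries the calibration (tau, lambda).
    """
    hmm.validate(atol=1e-6)
    M = hmm.M
    lines = ["HMMER3/f [pirsite profile]"]
    lines.append(f"NAME  {hmm.hmm_id}")
    lines.append(f"LENG  {M}")
    lines.append("ALPH  amino")
    lines.extend(hmm.extra_header)
    if hmm.calibration is not None:
        lines.append(
            f"STATS LOCAL VITERBI  {hmm.calibration.tau:.5f}  "
            f"{hmm.calibration.lam:.5f}")
    lines.append("HMM          " + "        ".join(AMINO_ACIDS))
    lines.append("            m->m     m->i     m->d     i->m     i->i"
                 "     d->m     d->d")
    lines.append("  COMPO   " + "  ".join(_fmt(p) for p in hmm.background))
    lines.append("          " + "  ".join(_fmt(p) for p in hmm.insert_emissions[0]))
    lines.append("          " + "  ".join(_fmt(p) for p in hmm.transitions[0]))
    cons = hmm.consensus
    for k in range(1, M + 1):
        lines.append(f"{k:7d}   "
                     + "  ".join(_fmt(p) for p in hmm.match_emissions[k])
                     + f"  {k} {cons[k - 1].lower()} - - -")
        lines.append("          " + "  ".join(_fmt(p) for p in hmm.insert_emissions[k]))
        lines.append("          " + "  ".join(_fmt(p) for p in hmm.transitions[k]))
    lines.append("//")
    return "\n".join(lines) + "\n"


def read_profile(text: str) -> ProfileHMM:
    """Parse a HMMER3 ASCII profile.

    ``STATS LOCAL VITERBI`` lines populate the calibration; unknown header
    lines are preserved on ``extra_header``.  A model with fewer node lines
    than LENG, or missing the final ``//``, raises :class:`HmmFormatError`
    with the offending line number.
    """
    lines = text.splitlines()
    name = "profile"
    leng = None
    calib = None
    extra: list[str] = []
    i = 0
    n_lines = len(lines)
    known = {"NAME", "LENG", "ALPH", "ACC", "DESC", "HMM", "STATS"}
    if not lines or not lines[0].startswith("HMMER3"):
        raise HmmFormatError("not a HMMER3 ASCII profile (missing magic)", 1)
    i = 1
    while i < n_lines and not lines[i].startswith("HMM "):
        tok = lines[i].split(None, 1)
        if tok:
            tag = tok[0]
            if tag == "NAME":
                name = tok[1].strip() if len(tok) > 1 else name
            elif tag == "LENG":
                try:
                    leng = int(tok[1])
                except (IndexError, ValueError):
                    raise HmmFormatError("bad LENG line", i + 1)
            elif tag == "STATS":
                parts = lines[i].split()
                if len(parts) >= 5 and parts[1] == "LOCAL" and parts[2] == "VITERBI":
                    try:
                        calib = CalibrationParams(lam=float(parts[4]),
                                                  tau=float(parts[3]))
                    except (ValueError, CalibrationError):
                        raise HmmFormatError("bad STATS LOCAL VITERBI line", i + 1)
                else:
                    extra.append(lines[i])
            elif tag not in known:
                extra.append(lines[i])
        i += 1
    if i >= n_lines:
        raise HmmFormatError("no HMM section found", n_lines)
    if leng is None:
        raise HmmFormatError("missing LENG header", i + 1)
    i += 1  # skip HMM alphabet line
    if i < n_lines and "m->m" in lines[i]:
        i += 1

    background = np.full(20, 1.0 / 20)
    if i < n_lines and lines[i].split()[:1] == ["COMPO"]:
        toks = lines[i].split()[1:]
        if len(toks) != 20:
            raise HmmFormatError("COMPO line must carry 20 values", i + 1)
        background = np.array([_parse_logprob(t, i + 1) for t in toks])
        i += 1

    def _vals(line_no, expect, skip_leading=0):
        if line_no >= n_lines:
            raise HmmFormatError(
                f"truncated model: expected {leng} nodes", n_lines)
        toks = lines[line_no].split()[skip_leading:]
        if len(toks) < expect:
            raise HmmFormatError(
                f"expected {expect} values, got {len(toks)}", line_no + 1)
        return np.array([_parse_logprob(t, line_no + 1) for t in toks[:expect]])

    insert_em = np.zeros((leng + 1, 20))
    match_em = np.zeros((leng + 1, 20))
    trans = np.zeros((leng + 1, 7))
    insert_em[0] = _vals(i, 20)
    trans[0] = _vals(i + 1, 7)
    i += 2
    for k in range(1, leng + 1):
        if i >= n_lines or lines[i].strip() == "//":
            raise HmmFormatError(
                f"truncated model: {k - 1} of {leng} nodes present", i + 1)
        head = lines[i].split()
        if not head or not head[0].isdigit() or int(head[0]) != k:
            raise HmmFormatError(f"expected node {k} line", i + 1)
        match_em[k] = _vals(i, 20, skip_leading=1)
        insert_em[k] = _vals(i + 1, 20)
        trans[k] = _vals(i + 2, 7)
        i += 3
    while i < n_lines and not lines[i].strip():
        i += 1
    if i >= n_lines or lines[i].strip() != "//":
        raise HmmFormatError("model not terminated by '//'",
                             min(i + 1, n_lines))

    hmm = ProfileHMM(hmm_id=name, match_emissions=match_em,
                     insert_emissions=insert_em, transitions=trans,
                     background=background, calibration=calib,
                     extra_header=tuple(extra))
    hmm.validate(atol=1e-3)
    return hmm


# --------------------------------------------------------------------------
# glocal Viterbi

def _log2(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log2(x)


def _emission_logodds(hmm: ProfileHMM):
    # residues with zero background probability are unalignable: -inf
    bg = hmm.background
    with np.errstate(invalid="ignore"):
        me = np.where(bg[None, :] > 0,
                      _log2(hmm.match_emissions) - _log2(bg)[None, :], NEG_INF)
        ie = np.where(bg[None, :] > 0,
                      _log2(hmm.insert_emissions) - _log2(bg)[None, :], NEG_INF)
    return me, ie


def viterbi_align(hmm: ProfileHMM, sequence: str,
                  sequence_id: str = "seq") -> HmmAlignment:
    """Best glocal alignment of ``sequence`` to the profile.

    The path must traverse every profile node via match or delete states;
    residues flanking the aligned region are unaligned at zero cost.  The
    returned bit score is the path log-odds versus the background model.
    Ties are broken deterministically, preferring match over delete over
    insert predecessors and the leftmost placement.
    """
    seq = sequence.upper()
    if not seq:
        raise ProfileError("cannot align an empty sequence")
    L = len(seq)
    M = hmm.M
    sym = []
    for ch in seq:
        if ch in _AA_INDEX:
            sym.append(_AA_INDEX[ch])
        elif ch in AMBIGUOUS:
            sym.append(-1)
        else:
            raise ProfileError(f"unknown residue {ch!r}")

    me, ie = _emission_logodds(hmm)
    t = _log2(hmm.transitions)

    def m_emit(k, i):  # i is 1-based sequence position
        s = sym[i - 1]
        return 0.0 if s < 0 else me[k, s]

    def i_emit(k, i):
        s = sym[i - 1]
        return 0.0 if s < 0 else ie[k, s]

    VM = np.full((M + 1, L + 1), NEG_INF)
    VI = np.full((M + 1, L + 1), NEG_INF)
    VD = np.full((M + 1, L + 1), NEG_INF)
    # backpointers: 0=M, 1=I, 2=D, 3=begin
    BM = np.zeros((M + 1, L + 1), dtype=np.int8)
    BD = np.zeros((M + 1, L + 1), dtype=np.int8)
    BI = np.zeros((M + 1, L + 1), dtype=np.int8)

    for i in range(0, L + 1):
        VD[1, i] = t[0, T_MD]          # B -> D1 after i free flank residues
        BD[1, i] = 3
        if i >= 1:
            VM[1, i] = t[0, T_MM] + m_emit(1, i)
            BM[1, i] = 3

    for k in range(1, M + 1):
        for i in range(0, L + 1):
            if k >= 2:
                if i >= 1:
                    # candidate order encodes the tie-break: M > D > I
                    cands = (VM[k - 1, i - 1] + t[k - 1, T_MM],
                             VD[k - 1, i - 1] + t[k - 1, T_DM],
                             VI[k - 1, i - 1] + t[k - 1, T_IM])
                    best = max(cands)
                    VM[k, i] = best + m_emit(k, i)
                    BM[k, i] = (0, 2, 1)[cands.index(best)]
                cands = (VM[k - 1, i] + t[k - 1, T_MD],
                         VD[k - 1, i] + t[k - 1, T_DD])
                best = max(cands)
                VD[k, i] = best
                BD[k, i] = (0, 2)[cands.index(best)]
            if k < M and i >= 1:
                cands = (VM[k, i - 1] + t[k, T_MI],
                         VI[k, i - 1] + t[k, T_II])
                best = max(cands)
                VI[k, i] = best + i_emit(k, i)
                BI[k, i] = (0, 1)[cands.index(best)]

    # end: leave node M via M->E (stored T_MM) or D->E (stored T_DM)
    best_score = NEG_INF
    best_end = None  # (kind, i)
    for i in range(0, L + 1):
        for kind, v, tr in (("M", VM[M, i], t[M, T_MM]),
                            ("D", VD[M, i], t[M, T_DM])):
            s = v + tr
            if s > best_score:
                best_score = s
                best_end = (kind, i)
    if best_end is None or best_score == NEG_INF:
        raise ProfileError("no legal glocal path (profile forbids traversal)")

    # traceback
    path: list[tuple[str, int, int | None]] = []
    kind, i = best_end
    k = M
    while True:
        if kind == "M":
            path.append(("M", k, i))
            ptr = BM[k, i]
            i -= 1
            if ptr == 3:
                break
            k -= 1
            kind = {0: "M", 1: "I", 2: "D"}[int(ptr)]
        elif kind == "D":
            path.append(("D", k, None))
            ptr = BD[k, i]
            if ptr == 3:
                break
            k -= 1
            kind = "M" if ptr == 0 else "D"
        else:  # insert stays at node k
            path.append(("I", k, i))
            ptr = BI[k, i]
            i -= 1
            kind = "M" if ptr == 0 else "I"
    path.reverse()
    return HmmAlignment(sequence_id=sequence_id, state_path=path,
                        bit_score=float(best_score))


def score_to_evalue(bit_score: float, calibration: CalibrationParams | None,
                    Z: float = 1.0) -> float:
    """E-value of a Viterbi bit score under the fitted Gumbel tail.

    ``evalue = Z * exp(-lambda * (score - tau))``, clamped to ``[0, Z]``;
    ``Z`` is the search-space size (1 for a per-sequence e-value).
    """
    if calibration is None:
        raise CalibrationError(
            "profile has no calibration; run calibrate() first")
    if Z < 1:
        raise CalibrationError("search-space size Z must be >= 1")
    e = Z * math.exp(-calibration.lam * (bit_score - calibration.tau))
    return min(max(e, 0.0), Z)


def calibrate(hmm: ProfileHMM, n: int = 200, length: int | None = None,
              seed: int = 0) -> CalibrationParams:
    """Fit the Gumbel score tail by maximum likelihood on random sequences.

    Draws ``n`` i.i.d. sequences of ``length`` residues from the profile
    background, scores each with :func:`viterbi_align`, and fits a Gumbel
    distribution to the bit scores (lambda = 1/scale, tau = location).
    Deterministic given ``seed``.
    """
    if n < 50:
        raise CalibrationError("need at least 50 calibration sequences")
    if length is None:
        length = max(30, 2 * hmm.M)
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    p = hmm.background / hmm.background.sum()  # absorb file-format rounding
    scores = np.empty(n)
    for j in range(n):
        seq = "".join(rng.choice(aas, size=length, p=p))
        scores[j] = viterbi_align(hmm, seq).bit_score
    if np.ptp(scores) == 0:
        raise CalibrationError("degenerate score distribution (all equal)")
    loc, scale = stats.gumbel_r.fit(scores)
    if scale <= 0:
        raise CalibrationError("Gumbel fit produced non-positive scale")
    return CalibrationParams(lam=1.0 / scale, tau=loc, n_calib=n)


def read_alignment(handle_or_text, fmt: str = "fasta") -> list[tuple[str, str]]:
    """Read an alignment (aligned FASTA or Stockholm) as (id, row) pairs."""
    import io

    from Bio import AlignIO

    if isinstance(handle_or_text, str):
        handle_or_text = io.StringIO(handle_or_text)
    aln = AlignIO.read(handle_or_text, fmt)
    return [(rec.id, str(rec.seq).upper()) for rec in aln]
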