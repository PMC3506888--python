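"""Local-alignment scoring of protein sequences against profile HMMs.

Scores are log2-odds (bits) of the best (Viterbi) or summed (forward)
local, single-hit path versus the background model. The architecture
follows the Plan7 local convention: an alignment enters at any match state
and any sequence position with uniform probability 1/M, exits from any
match state with probability 1/M, and residues outside the alignment are
emitted at background frequency (their contribution cancels in log-odds,
as do the null model's length terms).

Path probability (odds) of an alignment pi:

    odds(pi) = (1/M) * prod_match e_Mk(x)/f(x) * prod_trans t * (1/M)

Viterbi maximizes log odds(pi); forward sums odds over all paths. Insert
emissions equal the background, so inserts contribute only transition
terms. The dynamic programs run in natural-log space and convert to bits
at the end; numba-compiled kernels are used when available, with an
equivalent pure-Python fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .profile import AA_INDEX, ProfileHMM

_NEG_INF = -math.inf
LN2 = math.log(2.0)


def _py_viterbi_fill(msc, tmm, tmi, tmd, tim, tii, tdm, tdd, entry):
    L, M = msc.shape
    VM = np.full((L, M), _NEG_INF)
    VI = np.full((L, M), _NEG_INF)
    VD = np.full((L, M), _NEG_INF)
    for i in range(L):
        for k in range(M):
            best = entry
            if i > 0 and k > 0:
                v = VM[i - 1, k - 1] + tmm[k - 1]
                if v > best:
                    best = v
                v = VI[i - 1, k - 1] + tim[k - 1]
                if v > best:
                    best = v
                v = VD[i - 1, k - 1] + tdm[k - 1]
                if v > best:
                    best = v
            VM[i, k] = msc[i, k] + best
            if i > 0:
                a = VM[i - 1, k] + tmi[k]
                b = VI[i - 1, k] + tii[k]
                VI[i, k] = a if a >= b else b
            if k > 0:
                a = VM[i, k - 1] + tmd[k - 1]
                b = VD[i, k - 1] + tdd[k - 1]
                VD[i, k] = a if a >= b else b
    return VM, VI, VD


def _py_forward_fill(msc, tmm, tmi, tmd, tim, tii, tdm, tdd, entry):
    L, M = msc.shape
    FM = np.full((L, M), _NEG_INF)
    FI = np.full((L, M), _NEG_INF)
    FD = np.full((L, M), _NEG_INF)
    total = _NEG_INF

    def lse(a, b):
        if a < b:
            a, b = b, a
        if b == _NEG_INF:
            return a
        return a + math.log1p(math.exp(b - a))

    for i in range(L):
        for k in range(M):
            acc = entry
            if i > 0 and k > 0:
                acc = lse(acc, FM[i - 1, k - 1] + tmm[k - 1])
                acc = lse(acc, FI[i - 1, k - 1] + tim[k - 1])
                acc = lse(acc, FD[i - 1, k - 1] + tdm[k - 1])
            FM[i, k] = msc[i, k] + acc
            if i > 0:
                FI[i, k] = lse(FM[i - 1, k] + tmi[k], FI[i - 1, k] + tii[k])
            if k > 0:
                FD[i, k] = lse(FM[i, k - 1] + tmd[k - 1], FD[i, k - 1] + tdd[k - 1])
            total = lse(total, FM[i, k])
    return total


try:  # pragma: no cover - exercised implicitly when numba is present
    from numba import njit

    _viterbi_fill = njit(cache=False)(_py_viterbi_fill)
    _forward_fill = njit(cache=False)(_py_forward_fill)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _viterbi_fill = _py_viterbi_fill
    _forward_fill = _py_forward_fill
    HAVE_NUMBA = False


@dataclass
class ScoreResult:
    """Outcome of scoring one sequence against one profile."""

    sequence_id: str
    bit_score: float
    evalue: Optional[float] = None
    ali_start: Optional[int] = None
    ali_end: Optional[int] = None
    profile_span: Optional[tuple] = None


def encode_sequence(residues: str) -> np.ndarray:
    """Residues to indices 0..19; unknown/ambiguous/stop characters to 20."""
    return np.array([AA_INDEX.get(ch, 20) for ch in residues.upper()], dtype=np.int64)


def _score_arrays(profile: ProfileHMM):
    """Cached natural-log score arrays for a profile."""
    cached = profile.metadata.get("_score_cache")
    if cached is not None:
        return cached
    with np.errstate(divide="ignore"):
        lodm = np.log(profile.match_emissions / profile.null_freqs)
        # row 20: any non-standard residue scores as background (log-odds 0)
        lod_aug = np.vstack([lodm.T, np.zeros(profile.M)])  # (21, M)
        trans = tuple(
            np.log(np.asarray(profile.transitions[n], dtype=float))
            for n in ("MM", "MI", "MD", "IM", "II", "DM", "DD")
        )
    entry = -math.log(profile.M)
    cache = (np.ascontiguousarray(lod_aug), trans, entry)
    profile.metadata["_score_cache"] = cache
    return cache


def _msc(profile: ProfileHMM, idx: np.ndarray) -> np.ndarray:
    lod_aug, _, _ = _score_arrays(profile)
    return np.ascontiguousarray(lod_aug[idx])  # (L, M)


def _residue_indices(seq) -> tuple[str, np.ndarray]:
    if hasattr(seq, "residues"):
        return seq.id, encode_sequence(seq.residues)
    return "", encode_sequence(str(seq))


def viterbi_matrices(profile: ProfileHMM, idx: np.ndarray):
    _, trans, entry = _score_arrays(profile)
    msc = _msc(profile, idx)
    VM, VI, VD = _viterbi_fill(msc, *trans, entry)
    return msc, VM, VI, VD


def viterbi_path(profile: ProfileHMM, idx: np.ndarray):
    """Best local path as (score_nats, [(state, register, seq_pos0)])."""
    _, trans, entry = _score_arrays(profile)
    tmm, tmi, tmd, tim, tii, tdm, tdd = trans
    msc, VM, VI, VD = viterbi_matrices(profile, idx)
    i, k = np.unravel_index(np.argmax(VM), VM.shape)
    score = VM[i, k] + entry  # uniform exit
    path = []
    state = "M"
    eps = 1e-9
    while True:
        path.append((state, k + 1, i))
        if state == "M":
            best = VM[i, k] - msc[i, k]
            if i > 0 and k > 0:
                if abs(VM[i - 1, k - 1] + tmm[k - 1] - best) < eps:
                    i, k, state = i - 1, k - 1, "M"
                    continue
                if abs(VI[i - 1, k - 1] + tim[k - 1] - best) < eps:
                    i, k, state = i - 1, k - 1, "I"
                    continue
                if abs(VD[i - 1, k - 1] + tdm[k - 1] - best) < eps:
                    i, k, state = i - 1, k - 1, "D"
                    continue
            break  # entry point
        if state == "I":
            if abs(VM[i - 1, k] + tmi[k] - VI[i, k]) < eps:
                i, state = i - 1, "M"
            else:
                i, state = i - 1, "I"
            continue
        # state == "D"
        if abs(VM[i, k - 1] + tmd[k - 1] - VD[i, k]) < eps:
            k, state = k - 1, "M"
        else:
            k, state = k - 1, "D"
    path.reverse()
    return score, path


def viterbi_score(profile: ProfileHMM, seq, db_size: Optional[int] = None) -> ScoreResult:
    """Best local single-hit log2-odds score with alignment span."""
    sid, idx = _residue_indices(seq)
    if idx.size == 0:
        raise ValueError(f"cannot score empty sequence {sid!r}")
    score_nats, path = viterbi_path(profile, idx)
    match_cells = [(k, i) for s, k, i in path if s == "M"]
    bits = score_nats / LN2
    res = ScoreResult(
        sequence_id=sid,
        bit_score=bits,
        ali_start=match_cells[0][1] + 1,
        ali_end=match_cells[-1][1] + 1,
        profile_span=(match_cells[0][0], match_cells[-1][0]),
    )
    if db_size is not None and profile.calibrated:
        from .evd import evalue

        res.evalue = evalue(profile, bits, db_size)
    return res


def forward_bits(profile: ProfileHMM, idx: np.ndarray) -> float:
    """Forward log2-odds score from encoded residue indices (hot path)."""
    _, trans, entry = _score_arrays(profile)
    msc = _msc(profile, idx)
    return (_forward_fill(msc, *trans, entry) + entry) / LN2


def forward_score(profile: ProfileHMM, seq, db_size: Optional[int] = None) -> ScoreResult:
    """Summed-path local log2-odds score; span reported from the Viterbi path."""
    sid, idx = _residue_indices(seq)
    if idx.size == 0:
        raise ValueError(f"cannot score empty sequence {sid!r}")
    bits = forward_bits(profile, idx)
    vres = viterbi_score(profile, seq)
    res = ScoreResult(
        sequence_id=sid,
        bit_score=bits,
        ali_start=vres.ali_start,
        ali_end=vres.ali_end,
        profile_span=vres.profile_span,
    )
    if db_size is not None and profile.calibrated:
        from .evd import evalue

        res.evalue = evalue(profile, bits, db_size)
    return res


def profile_coverage(profile: ProfileHMM, seq) -> float:
    """Fraction of match states spanned by the best local alignment."""
    sid, idx = _residue_indices(seq)
    _, path = viterbi_path(profile, idx)
    ks = [k for s, k, _ in path if s == "M"]
    return (ks[-1] - ks[0] + 1) / profile.M
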