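"""Per-family profile HMM construction and serialization.

A profile HMM is built from a multiple sequence alignment of curated
transposases of one IS family (optionally one ORF of a multi-ORF family).
Columns whose gap fraction is below a threshold become match states;
emissions and transitions are estimated with background-weighted additive
pseudocounts. The model is a Plan7-style local, single-hit architecture:
uniform entry into any match state, uniform exit from any match state,
insert states emitting at background frequency, delete states silent.

Scores are log-odds against a fixed background (null) model; see
:mod:`transposcan.scoring`. E-value calibration lives in
:mod:`transposcan.evd`.

Profiles serialize to a versioned ASCII key-value format (header line
``TNPHMM1``) with emissions and transitions in natural-log space; this is
the unit exchanged between the build/calibrate/scan pipeline stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Swiss-Prot-like background amino-acid composition (Robinson & Robinson
# style frequencies), renormalized. Order follows AMINO_ACIDS.
_BG = np.array([
    0.0780, 0.0192, 0.0536, 0.0624, 0.0387, 0.0738, 0.0219, 0.0514,
    0.0574, 0.0901, 0.0224, 0.0448, 0.0520, 0.0426, 0.0512, 0.0712,
    0.0587, 0.0644, 0.0133, 0.0321,
])
BACKGROUND_FREQS = _BG / _BG.sum()

GAP_CHARS = {"-", "."}

TRANSITION_NAMES = ("MM", "MI", "MD", "IM", "II", "DM", "DD")


@dataclass
class Alignment:
    """A protein multiple alignment for one family/ORF.

    ``rows`` is a list of ``(id, aligned_string)`` pairs; gaps are ``-``
    (``.`` is normalized to ``-``).
    """

    family_id: str
    orf_label: str
    rows: list
    ncol: int = 0

    def __post_init__(self) -> None:
        self.rows = [(rid, s.upper().replace(".", "-")) for rid, s in self.rows]
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"alignment rows have unequal lengths {sorted(lengths)}")
        self.ncol = lengths.pop()
        if all(
            all(s[c] in GAP_CHARS for _, s in self.rows) for c in range(self.ncol)
        ):
            raise ValueError("alignment has no non-gap column")

    @property
    def name(self) -> str:
        return f"{self.family_id}/{self.orf_label}"

    @classmethod
    def from_fasta(cls, path, family_id: str, orf_label: str = "ORF1") -> "Alignment":
        from Bio import SeqIO

        rows = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        if not rows:
            raise ValueError(f"no alignment rows in {path}")
        return cls(family_id=family_id, orf_label=orf_label, rows=rows)


@dataclass
class ProfileHMM:
    """A calibratable per-family scoring model.

    Probabilities are stored linearly; ``match_emissions`` is (M, 20),
    transitions are seven length-M arrays indexed by source match position
    (position k holds transitions from state register k to k/k+1). Entry
    and exit are uniform over match states (1/M each) and not stored.
    """

    name: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: dict
    null_freqs: np.ndarray
    evd_mu: Optional[float] = None
    evd_lambda: Optional[float] = None
    cutoff_evalue: Optional[float] = None
    training_lengths: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.null_freqs = np.asarray(self.null_freqs, dtype=float)
        self.validate()

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def family_id(self) -> str:
        return self.name.split("/", 1)[0]

    @property
    def calibrated(self) -> bool:
        return self.evd_mu is not None and self.evd_lambda is not None

    def validate(self) -> None:
        if self.match_emissions.ndim != 2 or self.match_emissions.shape[1] != 20:
            raise ValueError("match_emissions must be (M, 20)")
        if self.M < 1:
            raise ValueError("profile must have M >= 1 match states")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        if not np.allclose(self.insert_emissions.sum(), 1.0, atol=1e-9):
            raise ValueError("insert emissions must sum to 1")
        t = self.transitions
        for group in (("MM", "MI", "MD"), ("IM", "II"), ("DM", "DD")):
            total = sum(np.asarray(t[g], dtype=float) for g in group)
            if not np.allclose(total, 1.0, atol=1e-9):
                raise ValueError(f"transition group {group} must sum to 1")
        if self.evd_lambda is not None and self.evd_lambda <= 0:
            raise ValueError("evd_lambda must be positive")

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Write the documented ASCII profile format (header ``TNPHMM1``)."""

        def _ln(x: float) -> str:
            return repr(math.log(x)) if x > 0 else "-inf"

        def _opt(x) -> str:
            return "NA" if x is None else repr(float(x))

        lines = ["TNPHMM1", f"NAME {self.name}", f"M {self.M}",
                 f"ALPHABET {AMINO_ACIDS}",
                 f"EVD_MU {_opt(self.evd_mu)}",
                 f"EVD_LAMBDA {_opt(self.evd_lambda)}",
                 f"CUTOFF_EVALUE {_opt(self.cutoff_evalue)}",
                 "SEED " + str(self.metadata.get("calibration_seed", "NA")),
                 "TRAINING_LENGTHS "
                 + (",".join(map(str, self.training_lengths)) or "NA"),
                 "NULL " + " ".join(_ln(x) for x in self.null_freqs),
                 "INSERT " + " ".join(_ln(x) for x in self.insert_emissions)]
        for k in range(self.M):
            lines.append(
                f"EMIT {k + 1} "
                + " ".join(_ln(x) for x in self.match_emissions[k])
            )
            lines.append(
                f"TRANS {k + 1} "
                + " ".join(_ln(self.transitions[n][k]) for n in TRANSITION_NAMES)
            )
        lines.append("END")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "ProfileHMM":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if not lines or lines[0] != "TNPHMM1":
            raise ValueError(f"{path}: not a TNPHMM1 profile file")

        def _exp(tok: str) -> float:
            return math.exp(float(tok))

        header: dict = {}
        emits: dict = {}
        trans: dict = {}
        for ln in lines[1:]:
            if ln == "END":
                break
            key, _, rest = ln.partition(" ")
            if key in {"EMIT", "TRANS"}:
                k, _, vals = rest.partition(" ")
                (emits if key == "EMIT" else trans)[int(k)] = [
                    _exp(t) for t in vals.split()
                ]
            else:
                header[key] = rest
        M = int(header["M"])
        match_em = np.array([emits[k] for k in range(1, M + 1)])
        tarr = {n: np.zeros(M) for n in TRANSITION_NAMES}
        for k in range(1, M + 1):
            for j, n in enumerate(TRANSITION_NAMES):
                tarr[n][k - 1] = trans[k][j]

        def _opt(tok: str):
            return None if tok == "NA" else float(tok)

        meta = {}
        if header.get("SEED", "NA") != "NA":
            meta["calibration_seed"] = int(header["SEED"])
        tl = header.get("TRAINING_LENGTHS", "NA")
        training = [] if tl == "NA" else [int(x) for x in tl.split(",")]
        return cls(
            name=header["NAME"],
            match_emissions=match_em,
            insert_emissions=np.array([_exp(t) for t in header["INSERT"].split()]),
            transitions=tarr,
            null_freqs=np.array([_exp(t) for t in header["NULL"].split()]),
            evd_mu=_opt(header["EVD_MU"]),
            evd_lambda=_opt(header["EVD_LAMBDA"]),
            cutoff_evalue=_opt(header["CUTOFF_EVALUE"]),
            training_lengths=training,
            metadata=meta,
        )


# ---------------------------------------------------------------------------
# construction


def assign_match_states(aln: Alignment, gap_threshold: float = 0.5) -> np.ndarray:
    """Boolean mask of match columns: gap fraction strictly below threshold.

    A column whose gap fraction equals the threshold is an insert column
    (strict inequality). Errors if no column qualifies.
    """
    if not (0 < gap_threshold <= 1):
        raise ValueError("gap_threshold must be in (0, 1]")
    n = len(aln.rows)
    gap_frac = np.array(
        [sum(s[c] in GAP_CHARS for _, s in aln.rows) / n for c in range(aln.ncol)]
    )
    mask = gap_frac < gap_threshold
    if not mask.any():
        raise ValueError("no match column survives the gap threshold")
    return mask


def _row_states(aligned: str, mask: np.ndarray):
    """Map one aligned row to its profile state path [('M'|'D'|'I', register)]."""
    states = []
    k = 0
    for c, ch in enumerate(aligned):
        if mask[c]:
            k += 1
            states.append(("M" if ch not in GAP_CHARS else "D", k))
        elif ch not in GAP_CHARS:
            states.append(("I", k))
    return states


def build_profile(
    aln: Alignment,
    mask: Optional[np.ndarray] = None,
    pseudocount: float = 1.0,
    null_freqs: Optional[np.ndarray] = None,
    gap_threshold: float = 0.5,
    name: Optional[str] = None,
) -> ProfileHMM:
    """Estimate a :class:`ProfileHMM` from an alignment.

    Match emission for residue ``a`` at match column ``c``:
    ``(count_a,c + pc * null_a * 20) / (residue_count_c + pc * 20)``
    where ``residue_count_c`` counts unambiguous residues (X excluded, so
    rows stay normalized). Transitions use the same additive scheme on
    observed state-path transition counts. Insert emissions equal the
    background.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    null = BACKGROUND_FREQS if null_freqs is None else np.asarray(null_freqs, float)
    if mask is None:
        mask = assign_match_states(aln, gap_threshold)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (aln.ncol,):
        raise ValueError(
            f"mask length {mask.shape} does not match alignment width {aln.ncol}"
        )
    if not mask.any():
        raise ValueError("mask selects no match column")
    M = int(mask.sum())

    counts = np.zeros((M, 20))
    match_cols = np.flatnonzero(mask)
    for _, s in aln.rows:
        for k, c in enumerate(match_cols):
            idx = AA_INDEX.get(s[c])
            if idx is not None:
                counts[k, idx] += 1
    denom = counts.sum(axis=1, keepdims=True) + pseudocount * 20
    match_em = (counts + pseudocount * null * 20) / denom

    tcounts = {n: np.zeros(M) for n in TRANSITION_NAMES}
    for _, s in aln.rows:
        path = _row_states(s, mask)
        for (s1, k1), (s2, k2) in zip(path, path[1:]):
            key = None
            if s1 == "M" and s2 == "M" and k2 == k1 + 1:
                key = "MM"
            elif s1 == "M" and s2 == "I" and k2 == k1:
                key = "MI"
            elif s1 == "M" and s2 == "D" and k2 == k1 + 1:
                key = "MD"
            elif s1 == "I" and s2 == "M" and k2 == k1 + 1:
                key = "IM"
            elif s1 == "I" and s2 == "I" and k2 == k1:
                key = "II"
            elif s1 == "D" and s2 == "M" and k2 == k1 + 1:
                key = "DM"
            elif s1 == "D" and s2 == "D" and k2 == k1 + 1:
                key = "DD"
            # I<->D adjacencies are not part of the architecture; skipped.
            if key is not None and 1 <= k1 <= M:
                tcounts[key][k1 - 1] += 1

    trans = {n: tcounts[n] + pseudocount for n in TRANSITION_NAMES}
    m_total = trans["MM"] + trans["MI"] + trans["MD"]
    i_total = trans["IM"] + trans["II"]
    d_total = trans["DM"] + trans["DD"]
    for n in ("MM", "MI", "MD"):
        trans[n] = trans[n] / m_total
    for n in ("IM", "II"):
        trans[n] = trans[n] / i_total
    for n in ("DM", "DD"):
        trans[n] = trans[n] / d_total

    lengths = [sum(ch not in GAP_CHARS for ch in s) for _, s in aln.rows]
    return ProfileHMM(
        name=name or aln.name,
        match_emissions=match_em,
        insert_emissions=null.copy(),
        transitions=trans,
        null_freqs=null.copy(),
        training_lengths=lengths,
    )
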