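"""ROC calibration of profile cutoffs and per-family model selection.

Each profile is scored against a known-positives database (curated
transposases) and a known-negatives database (proteins purged of
transposase-related entries by keyword). Sweeping the e-value threshold
yields a ROC curve; the cutoff is the threshold maximizing Youden's
J = sensitivity + selectivity - 1, with ties broken toward the most
stringent (smallest) e-value. "Selectivity" is specificity TN/(TN+FP).

Within a family, candidate profiles (rebuilt here or external, e.g. a
Pfam-derived model) are compared on (sensitivity, selectivity): a
candidate that weakly dominates all others is selected alone; mutually
non-dominating candidates are all selected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .profile import ProfileHMM
from .scoring import forward_bits, encode_sequence
from .evd import evalue
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

#: Description keywords whose bearers are purged from the negatives database.
DEFAULT_NEGATIVE_KEYWORDS = (
    "transposase",
    "insertion sequence",
    "resolvase",
    "recombinase",
    "integrase",
)


def _normalize_keyword(kw: str) -> str:
    kw = kw.strip().lower()
    # singular/plural normalization: a trailing plural 's' is dropped so the
    # singular form substring-matches both ("integrase" matches "integrases")
    if len(kw) > 3 and kw.endswith("s") and not kw.endswith("ss"):
        kw = kw[:-1]
    return kw


def keyword_matches(text: str, keywords: Sequence[str]) -> bool:
    low = text.lower()
    return any(_normalize_keyword(kw) in low for kw in keywords)


# ---------------------------------------------------------------------------
# database construction


def merge_positive_db(a: Sequence[SequenceRecord], b: Sequence[SequenceRecord]):
    """Union of two protein sets with exact-duplicate sequences removed.

    The first id encountered is kept; ids of merged duplicates are recorded
    in the surviving record's description.
    """
    by_seq: dict[str, SequenceRecord] = {}
    for rec in list(a) + list(b):
        kept = by_seq.get(rec.residues)
        if kept is None:
            by_seq[rec.residues] = SequenceRecord(
                id=rec.id, description=rec.description,
                residues=rec.residues, alphabet=rec.alphabet,
            )
        elif rec.id != kept.id:
            kept.description = (kept.description + f" merged:{rec.id}").strip()
    return list(by_seq.values())


def filter_negative_db(
    records: Sequence[SequenceRecord],
    keywords: Sequence[str] = DEFAULT_NEGATIVE_KEYWORDS,
):
    """Drop records whose description matches any keyword (case-insensitive
    substring after singular/plural normalization)."""
    if not keywords:
        raise ValueError("empty keyword list would nullify the negative filter")
    return [r for r in records if not keyword_matches(r.description, keywords)]


@dataclass
class LabeledSet:
    """Positive and negative protein databases for one calibration run."""

    positives: list
    negatives: list

    def __post_init__(self) -> None:
        if not self.positives or not self.negatives:
            raise ValueError("both positive and negative sets must be non-empty")
        pos_seqs = {r.residues for r in self.positives}
        overlap = [r for r in self.negatives if r.residues in pos_seqs]
        if overlap:
            logger.warning(
                "dropping %d negatives whose exact sequence appears in positives",
                len(overlap),
            )
            self.negatives = [r for r in self.negatives if r.residues not in pos_seqs]
        if not self.negatives:
            raise ValueError("no negatives left after cross-set deduplication")


# ---------------------------------------------------------------------------
# scoring and ROC


def score_set(profile: ProfileHMM, records: Sequence[SequenceRecord], db_size: int):
    """One (id, e-value) per record via forward scoring; order preserved."""
    out = []
    for rec in records:
        try:
            bits = forward_bits(profile, encode_sequence(rec.residues))
            out.append((rec.id, evalue(profile, bits, db_size)))
        except Exception as exc:
            raise RuntimeError(f"scoring failed for record {rec.id!r}: {exc}") from exc
    return out


@dataclass
class RocPoint:
    """Confusion counts at one e-value threshold (call positive iff e <= t)."""

    threshold: float
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def selectivity(self) -> float:
        return self.TN / (self.TN + self.FP)


def roc_curve(pos_scores, neg_scores) -> list:
    """ROC points at every observed e-value threshold plus a +inf sentinel."""
    pos = np.sort(np.asarray(list(pos_scores), dtype=float))
    neg = np.sort(np.asarray(list(neg_scores), dtype=float))
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    thresholds = np.unique(np.concatenate([pos, neg, [math.inf]]))
    points = []
    for t in thresholds:
        tp = int(np.searchsorted(pos, t, side="right"))
        fp = int(np.searchsorted(neg, t, side="right"))
        points.append(
            RocPoint(threshold=float(t), TP=tp, FP=fp,
                     TN=neg.size - fp, FN=pos.size - tp)
        )
    return points


def choose_cutoff(roc: Sequence[RocPoint]) -> RocPoint:
    """The ROC point maximizing Youden's J; ties go to the smallest threshold."""
    if not roc:
        raise ValueError("empty ROC curve")
    best = None
    best_j = -math.inf
    for p in sorted(roc, key=lambda p: p.threshold):
        j = p.sensitivity + p.selectivity - 1.0
        if j > best_j + 1e-12:
            best, best_j = p, j
    return best


@dataclass
class CalibrationResult:
    """One calibrated profile: ROC curve, chosen cutoff, sens/sel there."""

    profile_name: str
    roc: list
    cutoff_evalue: float
    sensitivity_at_cutoff: float
    selectivity_at_cutoff: float
    source: str = "rebuilt"


def calibrate_profile(
    profile: ProfileHMM,
    labeled: LabeledSet,
    db_size: int,
    source: str = "rebuilt",
) -> CalibrationResult:
    """Score both sets, sweep thresholds, attach the chosen cutoff."""
    pos = [e for _, e in score_set(profile, labeled.positives, db_size)]
    neg = [e for _, e in score_set(profile, labeled.negatives, db_size)]
    roc = roc_curve(pos, neg)
    point = choose_cutoff(roc)
    profile.cutoff_evalue = point.threshold
    return CalibrationResult(
        profile_name=profile.name,
        roc=roc,
        cutoff_evalue=point.threshold,
        sensitivity_at_cutoff=point.sensitivity,
        selectivity_at_cutoff=point.selectivity,
        source=source,
    )


# ---------------------------------------------------------------------------
# model selection


@dataclass
class FamilyCandidate:
    profile: ProfileHMM
    result: CalibrationResult
    source: str = "rebuilt"


@dataclass
class FamilyModelSet:
    family_id: str
    candidates: list
    selected: list = field(default_factory=list)


def _dominates(a: FamilyCandidate, b: FamilyCandidate) -> bool:
    sa = (a.result.sensitivity_at_cutoff, a.result.selectivity_at_cutoff)
    sb = (b.result.sensitivity_at_cutoff, b.result.selectivity_at_cutoff)
    return sa[0] >= sb[0] and sa[1] >= sb[1] and sa != sb


def select_family_models(fms: FamilyModelSet) -> FamilyModelSet:
    """Fill ``selected`` with the non-dominated candidates.

    A candidate weakly dominating every other one (>= on both sensitivity
    and selectivity, > on at least one) is selected alone; mutually
    non-dominating candidates are all selected. Exact ties on both
    criteria prefer rebuilt models over external ones. Idempotent and
    independent of candidate order.
    """
    cands = [c for c in fms.candidates if c.result is not None]
    if not cands:
        raise ValueError(f"family {fms.family_id}: no calibrated candidate")
    non_dominated = [
        c for c in cands if not any(_dominates(o, c) for o in cands if o is not c)
    ]
    by_score: dict[tuple, list] = {}
    for c in non_dominated:
        key = (c.result.sensitivity_at_cutoff, c.result.selectivity_at_cutoff)
        by_score.setdefault(key, []).append(c)
    selected = []
    for group in by_score.values():
        rebuilt = [c for c in group if c.source == "rebuilt"]
        selected.extend(rebuilt if rebuilt else group)
    selected.sort(key=lambda c: (c.source != "rebuilt", c.profile.name))
    fms.selected = selected
    return fms


# ---------------------------------------------------------------------------
# reports


def format_evalue(e: float) -> str:
    """Display e-values as m.mE±xx (two significant digits)."""
    if e == 0:
        return "0.0E+00"
    exp = math.floor(math.log10(abs(e)))
    mant = e / 10 ** exp
    return f"{mant:.1f}E{exp:+03d}"


def calibration_table(family_sets: Sequence[FamilyModelSet]) -> pd.DataFrame:
    """Per-profile calibration report (family, source, sel%, sens%, cutoff)."""
    rows = []
    for fms in family_sets:
        sel_names = {c.profile.name for c in fms.selected}
        for c in fms.candidates:
            r = c.result
            npos = r.roc[0].TP + r.roc[0].FN
            nneg = r.roc[0].TN + r.roc[0].FP
            cutpt = next(p for p in r.roc if p.threshold == r.cutoff_evalue)
            precision = (
                cutpt.TP / (cutpt.TP + cutpt.FP) if (cutpt.TP + cutpt.FP) else float("nan")
            )
            rows.append(
                {
                    "family": fms.family_id,
                    "profile": c.profile.name,
                    "source": c.source,
                    "selectivity_pct": round(100 * r.selectivity_at_cutoff, 1),
                    "sensitivity_pct": round(100 * r.sensitivity_at_cutoff, 1),
                    "precision_pct": round(100 * precision, 1),
                    "cutoff_display": format_evalue(r.cutoff_evalue),
                    "cutoff_evalue": r.cutoff_evalue,
                    "n_positives": npos,
                    "n_negatives": nneg,
                    "selected": c.profile.name in sel_names,
                }
            )
    return pd.DataFrame(rows)


def write_calibration_report(family_sets, path) -> None:
    calibration_table(family_sets).to_csv(path, sep="\t", index=False)


def write_roc_tsv(result: CalibrationResult, path) -> None:
    pd.DataFrame(
        [
            {
                "threshold": p.threshold,
                "TP": p.TP, "FP": p.FP, "TN": p.TN, "FN": p.FN,
                "sensitivity": p.sensitivity,
                "selectivity": p.selectivity,
            }
            for p in result.roc
        ]
    ).to_csv(path, sep="\t", index=False)
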