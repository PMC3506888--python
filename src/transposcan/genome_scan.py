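"""Whole-genome transposase prediction with calibrated family profiles.

Candidates are (i) every annotated CDS, translated strand-aware, and
(ii) every intergenic ORF of at least ``min_aa`` codons (an ORF
overlapping an annotated CDS span by >= 30 nt is not intergenic). Each
candidate is scored against every selected profile; a hit is accepted iff
its e-value is at or below that profile's calibrated cutoff, and only the
best family per candidate is kept.

Accepted predictions are classified by annotation improvement:

* class ``a`` — the CDS was already annotated as a transposase (product
  matches the transposase keyword list); the prediction adds the family.
* class ``b`` — the CDS had another or no product (e.g. "hypothetical
  protein"); the prediction replaces it with a transposase call.
* class ``c`` — the hit lies in DNA with no annotated gene at all.

Predictions are flagged as fragments (pseudogenes, "molecular fossils")
when the alignment covers less than ``coverage_threshold`` of the
profile's match states or the source CDS translation contains an internal
stop codon.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import pandas as pd

from . import seqio
from .calibration import DEFAULT_NEGATIVE_KEYWORDS, FamilyModelSet, keyword_matches
from .evd import evalue
from .profile import ProfileHMM
from .scoring import encode_sequence, forward_bits, viterbi_path
from .seqio import Feature, GenomeRecord


@dataclass
class Candidate:
    """A protein-coding candidate locus to be scored."""

    id: str
    peptide: str
    start: int
    end: int
    strand: str
    source: str  # 'annotated_cds' | 'intergenic_orf'
    source_feature: Optional[Feature] = None
    pseudo: bool = False  # internal stop codon in the translation

    def __post_init__(self) -> None:
        if self.source == "annotated_cds" and self.source_feature is None:
            raise ValueError(f"candidate {self.id}: annotated_cds requires a feature")
        if self.source == "intergenic_orf" and self.source_feature is not None:
            raise ValueError(f"candidate {self.id}: intergenic_orf carries no feature")


@dataclass
class Prediction:
    """An accepted transposase call (the unit counted in genome summaries)."""

    candidate: Candidate
    family_id: str
    profile_name: str
    evalue: float
    bit_score: float
    profile_coverage: float
    cls: Optional[str] = None
    fragment: bool = False

    @property
    def start(self) -> int:
        return self.candidate.start

    @property
    def end(self) -> int:
        return self.candidate.end

    @property
    def strand(self) -> str:
        return self.candidate.strand


def _overlap_nt(s1: int, e1: int, s2: int, e2: int) -> int:
    return max(0, min(e1, e2) - max(s1, s2) + 1)


def extract_candidates(
    genome: GenomeRecord,
    min_aa: int = 50,
    overlap_nt: int = 30,
    code: int = 11,
) -> list:
    """Annotated-CDS candidates plus intergenic ORF candidates."""
    candidates = []
    cds_feats = [f for f in genome.features if f.type == "CDS"]
    for n, f in enumerate(cds_feats, 1):
        if "translation" in f.qualifiers:
            pep = f.qualifiers["translation"].upper()
        else:
            span = f.span_length()
            dna = genome.subseq(f.start, f.end, f.strand)
            dna = dna[: span - span % 3]
            pep = seqio.translate(dna, code=code, start_context=True)
        pep = pep.rstrip("*")
        if not pep:
            continue
        cid = (
            f.qualifiers.get("locus_tag")
            or f.qualifiers.get("protein_id")
            or f"cds_{n:04d}"
        )
        candidates.append(
            Candidate(
                id=cid, peptide=pep, start=f.start, end=f.end, strand=f.strand,
                source="annotated_cds", source_feature=f, pseudo="*" in pep,
            )
        )
    for orf in seqio.extract_orfs(genome, min_aa=min_aa, code=code):
        if any(
            _overlap_nt(orf.start, orf.end, f.start, f.end) >= overlap_nt
            for f in cds_feats
        ):
            continue
        candidates.append(
            Candidate(
                id=f"orf_{orf.start}_{orf.end}_{'p' if orf.strand == '+' else 'm'}",
                peptide=orf.peptide, start=orf.start, end=orf.end,
                strand=orf.strand, source="intergenic_orf",
            )
        )
    candidates.sort(key=lambda c: (c.start, c.end, c.strand))
    return candidates


def scan(
    candidates: Sequence[Candidate],
    family_sets: Sequence[FamilyModelSet],
    db_size: Optional[int] = None,
    coverage_threshold: float = 0.5,
    keywords: Sequence[str] = DEFAULT_NEGATIVE_KEYWORDS,
) -> list:
    """Score candidates against all selected profiles and keep accepted hits.

    ``db_size`` defaults to the number of candidates scanned. Per
    candidate only the best family is retained (smallest e-value; ties by
    higher bit score, then lexicographic family id). Classification and
    fragment flagging are applied to every accepted prediction.
    """
    selected = []
    for fms in family_sets:
        for cand_model in fms.selected:
            profile = cand_model.profile
            if profile.cutoff_evalue is None or not profile.calibrated:
                raise ValueError(f"profile {profile.name} lacks a calibrated cutoff")
            selected.append((fms.family_id, profile))
    if db_size is None:
        db_size = max(1, len(candidates))
    predictions = []
    for cand in candidates:
        idx = encode_sequence(cand.peptide)
        best = None
        for family_id, profile in selected:
            bits = forward_bits(profile, idx)
            e = evalue(profile, bits, db_size)
            if e <= profile.cutoff_evalue:
                key = (e, -bits, family_id)
                if best is None or key < best[0]:
                    best = (key, family_id, profile, e, bits)
        if best is None:
            continue
        _, family_id, profile, e, bits = best
        _, path = viterbi_path(profile, idx)
        ks = [k for s, k, _ in path if s == "M"]
        coverage = (ks[-1] - ks[0] + 1) / profile.M
        pred = Prediction(
            candidate=cand, family_id=family_id, profile_name=profile.name,
            evalue=e, bit_score=bits, profile_coverage=coverage,
        )
        classify_prediction(pred, keywords=keywords)
        flag_fragment(pred, coverage_threshold=coverage_threshold)
        predictions.append(pred)
    predictions.sort(key=lambda p: (p.start, p.end, p.strand))
    return predictions


def classify_prediction(
    pred: Prediction, keywords: Sequence[str] = DEFAULT_NEGATIVE_KEYWORDS
) -> Prediction:
    """Assign annotation-improvement class a/b/c from candidate provenance."""
    if pred.candidate.source == "intergenic_orf":
        pred.cls = "c"
    else:
        product = pred.candidate.source_feature.qualifiers.get("product", "")
        pred.cls = "a" if keyword_matches(product, keywords) else "b"
    return pred


def flag_fragment(pred: Prediction, coverage_threshold: float = 0.5) -> Prediction:
    """Fragment iff profile coverage below threshold or pseudo (internal stop)."""
    pred.fragment = (
        pred.profile_coverage < coverage_threshold or pred.candidate.pseudo
    )
    return pred


# ---------------------------------------------------------------------------
# comparison against an external annotation


class AnnotationComparison(NamedTuple):
    confirmed: list  # (Prediction, Feature) matched pairs
    tnp_only: list  # predictions with no external match
    external_only: list  # external features not found by the scan


def compare_annotations(
    predictions: Sequence[Prediction],
    external: Sequence[Feature],
    min_reciprocal_overlap: float = 0.5,
) -> AnnotationComparison:
    """Match predictions to external features (same strand, reciprocal
    span overlap >= ``min_reciprocal_overlap``), greedily by overlap."""
    pairs = []
    for i, p in enumerate(predictions):
        for j, f in enumerate(external):
            if p.strand != f.strand:
                continue
            ov = _overlap_nt(p.start, p.end, f.start, f.end)
            if ov == 0:
                continue
            if (
                ov / (p.end - p.start + 1) >= min_reciprocal_overlap
                and ov / (f.end - f.start + 1) >= min_reciprocal_overlap
            ):
                pairs.append((ov, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_f: set[int] = set()
    confirmed = []
    for ov, i, j in pairs:
        if i in used_p or j in used_f:
            continue
        used_p.add(i)
        used_f.add(j)
        confirmed.append((predictions[i], external[j]))
    tnp_only = [p for i, p in enumerate(predictions) if i not in used_p]
    external_only = [f for j, f in enumerate(external) if j not in used_f]
    return AnnotationComparison(confirmed, tnp_only, external_only)


# ---------------------------------------------------------------------------
# summaries


@dataclass
class GenomeSummary:
    """Per-genome accounting of predictions (and optional external comparison)."""

    accession: str
    length_mbp: float
    gc_percent: float
    family_counts: dict
    class_counts: dict
    total: int
    confirmed: Optional[int] = None
    not_found: Optional[int] = None
    union_total: Optional[int] = None

    @property
    def n_families(self) -> int:
        return len(self.family_counts)


def summarize(
    genome: GenomeRecord,
    predictions: Sequence[Prediction],
    external: Optional[Sequence[Feature]] = None,
) -> GenomeSummary:
    """Counts by family and class; optionally confirmed / not-found versus
    an external annotation (union total = predictions + not found)."""
    fam = Counter(p.family_id for p in predictions)
    cls = Counter(p.cls for p in predictions)
    summary = GenomeSummary(
        accession=genome.id,
        length_mbp=round(len(genome) / 1e6, 1),
        gc_percent=seqio.gc_content(genome),
        family_counts=dict(sorted(fam.items())),
        class_counts={c: cls.get(c, 0) for c in "abc"},
        total=len(predictions),
    )
    if external is not None:
        comp = compare_annotations(predictions, external)
        summary.confirmed = len(comp.confirmed)
        summary.not_found = len(comp.external_only)
        summary.union_total = summary.total + summary.not_found
    return summary


def predictions_frame(genome: GenomeRecord, predictions) -> pd.DataFrame:
    """Full per-prediction report (one row per prediction)."""
    return pd.DataFrame(
        [
            {
                "accession": genome.id,
                "candidate_id": p.candidate.id,
                "start": p.start,
                "end": p.end,
                "strand": p.strand,
                "family": p.family_id,
                "profile": p.profile_name,
                "evalue": p.evalue,
                "bit_score": round(p.bit_score, 2),
                "coverage": round(p.profile_coverage, 3),
                "class": p.cls,
                "fragment": p.fragment,
                "source": p.candidate.source,
            }
            for p in predictions
        ],
        columns=[
            "accession", "candidate_id", "start", "end", "strand", "family",
            "profile", "evalue", "bit_score", "coverage", "class",
            "fragment", "source",
        ],
    )


def summary_frame(summary: GenomeSummary) -> pd.DataFrame:
    """Organism-summary table (accession, GC%, length, class/family counts)."""
    rows = [
        ("accession", summary.accession),
        ("gc_percent", summary.gc_percent),
        ("length_mbp", summary.length_mbp),
        ("total_predictions", summary.total),
        ("class_a", summary.class_counts["a"]),
        ("class_b", summary.class_counts["b"]),
        ("class_c", summary.class_counts["c"]),
        ("n_families", summary.n_families),
    ]
    if summary.confirmed is not None:
        rows += [
            ("confirmed_total", summary.confirmed),
            ("not_found", summary.not_found),
            ("union_total", summary.union_total),
        ]
    rows += [(f"family:{f}", n) for f, n in summary.family_counts.items()]
    return pd.DataFrame(rows, columns=["quantity", "value"])


def prediction_features(predictions) -> list:
    """Predictions as GenBank ``misc_feature`` entries."""
    return [
        Feature(
            type="misc_feature",
            start=p.start,
            end=p.end,
            strand=p.strand,
            qualifiers={
                "note": f"transposase family {p.family_id}",
                "family": p.family_id,
                "class": p.cls or "",
                "e_value": f"{p.evalue:.3g}",
                "fragment": "true" if p.fragment else "false",
            },
        )
        for p in predictions
    ]
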