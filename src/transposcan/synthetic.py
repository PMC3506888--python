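"""Seeded synthetic fixtures emulating the pipeline's real-world inputs.

The generators produce, without any downloads: family-structured positive
protein sets sampled from designated truth profiles, composition-preserving
shuffled negatives, and annotated genomes with implanted transposase genes
of every annotation-improvement category (class a/b/c, truncated fragments,
background decoys) together with a ground-truth manifest enabling exact
end-to-end checks.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .profile import (
    AMINO_ACIDS,
    Alignment,
    BACKGROUND_FREQS,
    ProfileHMM,
    build_profile,
)
from .scoring import encode_sequence, viterbi_path
from .seqio import Feature, GenomeRecord, SequenceRecord, reverse_complement

#: TruthProfile is an ordinary ProfileHMM designated as a generative truth model.
TruthProfile = ProfileHMM

MANIFEST_COLUMNS = [
    "gene_id", "family_id", "start", "end", "strand", "category", "truth_profile",
]

CATEGORIES = ("class_a", "class_b", "class_c", "fragment", "decoy")

#: 12-mer carrying stop codons in all three frames on both strands
#: (revcomp-palindromic); placed around implants so ORF boundaries are exact.
STOP_FLANK = "TTAATTAATTAA"


def make_truth_profile(
    family_id: str,
    M: int = 120,
    conservation: float = 0.9,
    seed: int = 0,
    indel: float = 0.02,
) -> TruthProfile:
    """A generative truth model: per position, mass ``conservation`` on one
    random consensus residue, the remainder spread by background."""
    if M < 10:
        raise ValueError("M must be >= 10")
    if not (0 < conservation < 1):
        raise ValueError("conservation must be in the open interval (0, 1)")
    rng = np.random.default_rng(seed)
    cons = rng.integers(0, 20, size=M)
    em = np.tile((1 - conservation) * BACKGROUND_FREQS, (M, 1))
    em[np.arange(M), cons] += conservation
    trans = {
        "MM": np.full(M, 1 - 2 * indel),
        "MI": np.full(M, indel),
        "MD": np.full(M, indel),
        "IM": np.full(M, 0.7),
        "II": np.full(M, 0.3),
        "DM": np.full(M, 0.7),
        "DD": np.full(M, 0.3),
    }
    return ProfileHMM(
        name=f"{family_id}/ORF1",
        match_emissions=em,
        insert_emissions=BACKGROUND_FREQS.copy(),
        transitions=trans,
        null_freqs=BACKGROUND_FREQS.copy(),
        training_lengths=[M],
        metadata={"truth_seed": seed},
    )


def sample_from_profile(tp: TruthProfile, n: int, seed: int = 0) -> list:
    """``n`` sequences by stochastic traversal of the profile states."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    t = tp.transitions
    records = []
    for i in range(n):
        residues = []
        k, state = 1, "M"
        while k <= tp.M:
            if state == "M":
                residues.append(AMINO_ACIDS[rng.choice(20, p=tp.match_emissions[k - 1])])
                nxt = rng.choice(
                    3, p=[t["MM"][k - 1], t["MI"][k - 1], t["MD"][k - 1]]
                )
                if nxt == 1:
                    state = "I"
                else:
                    state = "M" if nxt == 0 else "D"
                    k += 1
            elif state == "I":
                residues.append(AMINO_ACIDS[rng.choice(20, p=tp.insert_emissions)])
                if rng.random() < t["II"][k - 1]:
                    state = "I"
                else:
                    state, k = "M", k + 1
            else:  # D
                if rng.random() < t["DD"][k - 1]:
                    k += 1
                else:
                    state, k = "M", k + 1
        if not residues:  # all-delete traversal; vanishing probability
            residues = [AMINO_ACIDS[rng.choice(20, p=tp.match_emissions[0])]]
        records.append(
            SequenceRecord(
                id=f"{tp.family_id}_{i:04d}",
                description=f"synthetic {tp.family_id} family transposase",
                residues="".join(residues),
            )
        )
    return records


def random_protein(length: int, rng, rec_id: str = "bg") -> SequenceRecord:
    res = "".join(
        AMINO_ACIDS[i] for i in rng.choice(20, size=length, p=BACKGROUND_FREQS)
    )
    return SequenceRecord(
        id=rec_id, description="synthetic background protein", residues=res
    )


def shuffle_negatives(records, seed: int = 0) -> list:
    """Per-record residue shuffles (composition and length preserved) with
    non-keyword descriptions, for use as a known-negatives database."""
    if not records:
        raise ValueError("no records to shuffle")
    rng = np.random.default_rng(seed)
    out = []
    for r in records:
        res = "".join(rng.permutation(list(r.residues)))
        out.append(
            SequenceRecord(
                id=f"{r.id}_shuf",
                description="synthetic background protein",
                residues=res,
                alphabet=r.alphabet,
            )
        )
    return out


def truncate_fragment(record: SequenceRecord, keep_fraction: float, seed: int = 0):
    """A contiguous random-anchor subsequence of the stated fraction."""
    if not (0 < keep_fraction < 1):
        raise ValueError("keep_fraction must be in the open interval (0, 1)")
    rng = np.random.default_rng(seed)
    L = len(record.residues)
    keep = max(1, int(round(L * keep_fraction)))
    anchor = int(rng.integers(0, L - keep + 1))
    return SequenceRecord(
        id=record.id + "_frag",
        description=record.description + " fragment",
        residues=record.residues[anchor : anchor + keep],
        alphabet=record.alphabet,
    )


# ---------------------------------------------------------------------------
# alignment of samples back to a profile (gives consistent training MSAs
# without a multiple aligner: columns are the profile's match states)


def align_to_profile(profile: ProfileHMM, records) -> Alignment:
    """Viterbi-align each record to the profile; one column per match state,
    insert residues dropped (the profile needs only match-column structure)."""
    rows = []
    for r in records:
        score, path = viterbi_path(profile, encode_sequence(r.residues))
        col = ["-"] * profile.M
        for state, k, i in path:
            if state == "M":
                col[k - 1] = r.residues[i]
        rows.append((r.id, "".join(col)))
    return Alignment(family_id=profile.family_id, orf_label="ORF1", rows=rows)


def rebuild_profile_from_samples(
    tp: TruthProfile, n: int = 50, seed: int = 0, pseudocount: float = 1.0
) -> ProfileHMM:
    """Sample ``n`` members, align them back to the truth profile, and
    estimate a fresh profile from that alignment (the pipeline's build step)."""
    samples = sample_from_profile(tp, n, seed=seed)
    aln = align_to_profile(tp, samples)
    return build_profile(aln, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# DNA-level generation


def random_dna(length: int, gc_percent: float, rng, exact: bool = True) -> str:
    """Random DNA at the stated GC; ``exact`` fixes base counts exactly."""
    if exact:
        n_gc = int(round(length * gc_percent / 100.0))
        n_at = length - n_gc
        bases = (
            ["G"] * (n_gc // 2) + ["C"] * (n_gc - n_gc // 2)
            + ["A"] * (n_at // 2) + ["T"] * (n_at - n_at // 2)
        )
        return "".join(rng.permutation(bases))
    p_gc = gc_percent / 200.0
    return "".join(
        rng.choice(["G", "C", "A", "T"], size=length,
                   p=[p_gc, p_gc, 0.5 - p_gc, 0.5 - p_gc])
    )


def _codon_map(code: int = 11) -> dict:
    table = CodonTable.unambiguous_dna_by_id[code]
    aa2codons: dict[str, list] = {}
    for codon, aa in table.forward_table.items():
        aa2codons.setdefault(aa, []).append(codon)
    for aa in aa2codons:
        aa2codons[aa].sort()
    return aa2codons


def reverse_translate(peptide: str, rng, code: int = 11) -> str:
    """Random synonymous codons (uniform choice), bacterial code."""
    aa2codons = _codon_map(code)
    codons = []
    for aa in peptide:
        options = aa2codons.get(aa)
        if options is None:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        codons.append(options[rng.integers(0, len(options))])
    return "".join(codons)


@dataclass
class _Implant:
    gene_id: str
    family_id: str
    category: str
    cds: str  # forward-orientation coding sequence incl. ATG and TAA
    strand: str
    truth_profile: str
    product: str = ""


def build_synthetic_genome(
    families,
    n_per_category: dict,
    length: int = 60000,
    seed: int = 0,
    gc_percent: float = 47.3,
    accession: str = "SYN_000001",
    fragment_keep: float = 0.4,
    decoy_length: int = 150,
):
    """A genome with implanted transposase genes plus its truth manifest.

    Implants are reverse-translated from peptides sampled from the truth
    profiles. ``class_a`` genes get CDS features with a transposase
    product, ``class_b`` CDS with product "hypothetical protein",
    ``class_c`` and ``fragment`` implants get no feature (fragments are
    truncated to ``fragment_keep``), and decoys are background-protein CDS.
    Implants never overlap; each is flanked by all-frame stop codons so
    ORF boundaries match the manifest exactly.
    """
    unknown = set(n_per_category) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    families = list(families)
    implants: list[_Implant] = []
    counter = 0
    for category in CATEGORIES:
        for _ in range(int(n_per_category.get(category, 0))):
            counter += 1
            gid = f"syn{counter:04d}"
            if category == "decoy":
                pep = random_protein(decoy_length, rng, rec_id=gid).residues
                fam, tname, product = "", "", "synthetic background protein"
            else:
                tp = families[counter % len(families)]
                pep = sample_from_profile(
                    tp, 1, seed=int(rng.integers(0, 2**31 - 1))
                )[0].residues
                if category == "fragment":
                    rec = SequenceRecord(id=gid, residues=pep)
                    pep = truncate_fragment(
                        rec, fragment_keep, seed=int(rng.integers(0, 2**31 - 1))
                    ).residues
                fam, tname = tp.family_id, tp.name
                product = (
                    f"{fam} family transposase" if category == "class_a"
                    else "hypothetical protein"
                )
            cds = "ATG" + reverse_translate(pep, rng) + "TAA"
            implants.append(
                _Implant(
                    gene_id=gid, family_id=fam, category=category, cds=cds,
                    strand="+" if rng.random() < 0.5 else "-",
                    truth_profile=tname, product=product,
                )
            )
    rng.shuffle(implants)

    total_implant = sum(len(im.cds) + 2 * len(STOP_FLANK) for im in implants)
    if total_implant >= length / 2:
        raise ValueError(
            f"total implant length {total_implant} exceeds half the genome ({length})"
        )
    n_gaps = len(implants) + 1
    background = length - total_implant
    min_gap = 60
    if background < n_gaps * min_gap:
        raise ValueError("genome length too small for the requested implants")
    extra = rng.multinomial(background - n_gaps * min_gap, np.full(n_gaps, 1 / n_gaps))
    gap_lengths = (extra + min_gap).tolist()

    parts = []
    manifest_rows = []
    features = []
    pos = 0  # 0-based running offset
    for im, gap in zip(implants, gap_lengths):
        bg = random_dna(gap, gc_percent, rng)
        parts.append(bg)
        pos += gap
        parts.append(STOP_FLANK)
        pos += len(STOP_FLANK)
        insert = im.cds if im.strand == "+" else reverse_complement(im.cds)
        start = pos + 1  # 1-based inclusive span of the coding sequence
        end = pos + len(insert)
        parts.append(insert)
        pos = end
        parts.append(STOP_FLANK)
        pos += len(STOP_FLANK)
        manifest_rows.append(
            {
                "gene_id": im.gene_id, "family_id": im.family_id,
                "start": start, "end": end, "strand": im.strand,
                "category": im.category, "truth_profile": im.truth_profile,
            }
        )
        if im.category in {"class_a", "class_b", "decoy"}:
            features.append(
                Feature(
                    type="CDS", start=start, end=end, strand=im.strand,
                    qualifiers={"locus_tag": im.gene_id, "product": im.product},
                )
            )
    parts.append(random_dna(gap_lengths[-1], gc_percent, rng))
    dna = "".join(parts)
    genome = GenomeRecord(id=accession, dna=dna, circular=False, features=features)
    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS).sort_values(
        "start", ignore_index=True
    )
    return genome, manifest


# ---------------------------------------------------------------------------
# calibration set construction


def family_positive_set(
    tp: TruthProfile,
    n: int = 50,
    seed: int = 0,
    n_fragments: int = 0,
    fragment_keep: float = 0.3,
) -> list:
    """Held-out positives for one family; optionally a few truncated members
    emulating the partial entries present in curated transposase databases."""
    records = sample_from_profile(tp, n, seed=seed)
    for j in range(n_fragments):
        records[-(j + 1)] = truncate_fragment(
            records[-(j + 1)], fragment_keep, seed=seed + 1000 + j
        )
    return records
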