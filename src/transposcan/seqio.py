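"""Sequence and annotation I/O.

Reads and writes the formats the pipeline touches (FASTA, GenBank flat
files, GFF3) and provides the sequence utilities the genome scanner needs:
bacterial translation, six-frame ORF extraction and GC content.

Conventions
-----------
* Coordinates are 1-based inclusive everywhere (GenBank convention); the
  GFF3 writer emits the same.
* Strand is ``'+'`` or ``'-'``.
* The bacterial genetic code (NCBI table 11) is the default; GTG and TTG
  are accepted as start codons for ORF extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio.Data import CodonTable

PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
DNA_CHARS = frozenset("ACGTNRYSWKMBDHV")
_UNAMBIGUOUS_DNA = frozenset("ACGT")


@dataclass
class SequenceRecord:
    """A named protein or DNA sequence with free-text description."""

    id: str
    description: str = ""
    residues: str = ""
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = PROTEIN_CHARS if self.alphabet == "protein" else DNA_CHARS
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: residues {sorted(bad)} outside "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Feature:
    """A 1-based, strand-aware annotation feature (CDS, misc_feature, ...)."""

    type: str
    start: int
    end: int
    strand: str = "+"
    qualifiers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"feature {self.type}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature strand must be '+' or '-', got {self.strand!r}")

    def span_length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """A replicon: DNA sequence plus an ordered feature table."""

    id: str
    dna: str
    circular: bool = False
    features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dna = self.dna.upper()
        for f in self.features:
            if f.end > len(self.dna):
                raise ValueError(
                    f"feature {f.type} {f.start}..{f.end} beyond sequence "
                    f"length {len(self.dna)}"
                )

    def __len__(self) -> int:
        return len(self.dna)

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        """1-based inclusive slice, reverse-complemented for '-' strand."""
        s = self.dna[start - 1 : end]
        return reverse_complement(s) if strand == "-" else s


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    The description is the header text after the first whitespace. Errors
    on an empty file, on duplicate ids, and on residues outside the
    declared alphabet (the offending record is named).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id, description=desc, residues=str(rec.seq), alphabet=alphabet
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Write 60-column wrapped FASTA. An empty record list yields an empty file."""
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id} {r.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(r.residues), 60):
                fh.write(r.residues[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# GenBank


def _locus_declared_length(path) -> Optional[int]:
    with open(path) as fh:
        for line in fh:
            if line.startswith("LOCUS"):
                toks = line.split()
                for i, t in enumerate(toks):
                    if t == "bp" and i > 0 and toks[i - 1].isdigit():
                        return int(toks[i - 1])
                return None
    return None


def read_genbank(path) -> GenomeRecord:
    """Read a GenBank flat file into a :class:`GenomeRecord`.

    ``complement()`` locations become strand ``'-'``; ``join()`` spans are
    collapsed to their envelope ``min(start)..max(end)`` with a ``note``
    qualifier recording the original segmentation.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ValueError(
            f"{path}: failed to parse GenBank (missing ORIGIN sequence or "
            f"malformed record): {exc}"
        ) from exc
    try:
        dna = str(rec.seq)
    except Exception as exc:  # undefined sequence => no ORIGIN block
        raise ValueError(f"{path}: GenBank record has no ORIGIN sequence") from exc
    if not dna:
        raise ValueError(f"{path}: GenBank record has no ORIGIN sequence")
    declared = _locus_declared_length(path)
    if declared is not None and declared != len(dna):
        raise ValueError(
            f"{path}: LOCUS length {declared} != sequence length {len(dna)}"
        )
    features = []
    for f in rec.features:
        if f.type == "source":
            continue
        start = int(f.location.start) + 1
        end = int(f.location.end)
        if end > len(dna) or start < 1:
            raise ValueError(
                f"{path}: feature {f.type} coordinates {start}..{end} outside "
                f"sequence of length {len(dna)}"
            )
        strand = "-" if f.location.strand == -1 else "+"
        quals = {k: v[0] if isinstance(v, list) and v else str(v)
                 for k, v in f.qualifiers.items()}
        parts = getattr(f.location, "parts", [f.location])
        if len(parts) > 1:
            segs = ",".join(
                f"{int(p.start) + 1}..{int(p.end)}" for p in parts
            )
            note = quals.get("note", "")
            quals["note"] = (note + "; " if note else "") + f"segments={segs}"
        features.append(Feature(type=f.type, start=start, end=end,
                                strand=strand, qualifiers=quals))
    circular = rec.annotations.get("topology", "linear") == "circular"
    return GenomeRecord(id=rec.id or rec.name, dna=dna, circular=circular,
                        features=features)


def write_genbank(genome: GenomeRecord, path, extra_features: Iterable[Feature] = ()) -> None:
    """Write a GenBank flat file with the genome's feature table.

    ``extra_features`` (e.g. prediction ``misc_feature`` entries) are
    appended after the annotated features.
    """
    rec = SeqRecord(Seq(genome.dna), id=genome.id, name=genome.id[:16].replace("|", "_"),
                    description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.circular else "linear"
    for f in list(genome.features) + list(extra_features):
        loc = FeatureLocation(f.start - 1, f.end, strand=1 if f.strand == "+" else -1)
        quals = {k: [v] for k, v in f.qualifiers.items()}
        rec.features.append(SeqFeature(loc, type=f.type, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# GFF3


def _gff3_escape(value: str) -> str:
    return (
        value.replace("%", "%25").replace(";", "%3B").replace("=", "%3D")
        .replace("&", "%26").replace(",", "%2C")
    )


def write_gff3(genome: GenomeRecord, predictions, path) -> None:
    """Write predictions as GFF3 ``protein_match`` features.

    Attributes carry the assigned IS family, annotation-improvement class,
    e-value and fragment flag. Predictions outside the genome bounds raise.
    """
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {len(genome)}"]
    for i, p in enumerate(predictions, 1):
        if not (1 <= p.start <= p.end <= len(genome)):
            raise ValueError(
                f"prediction {p.start}..{p.end} outside genome {genome.id} "
                f"(length {len(genome)})"
            )
        attrs = ";".join(
            f"{k}={_gff3_escape(str(v))}"
            for k, v in [
                ("ID", f"tnp{i:05d}"),
                ("family", p.family_id),
                ("profile", p.profile_name),
                ("class", p.cls),
                ("e_value", f"{p.evalue:.3g}"),
                ("bit_score", f"{p.bit_score:.2f}"),
                ("coverage", f"{p.profile_coverage:.3f}"),
                ("fragment", "true" if p.fragment else "false"),
            ]
        )
        lines.append(
            "\t".join(
                [genome.id, "transposcan", "protein_match", str(p.start),
                 str(p.end), f"{p.bit_score:.2f}", p.strand, ".", attrs]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Translation / ORFs / GC


def translate(dna: str, code: int = 11, start_context: bool = False) -> str:
    """Translate an in-frame coding sequence.

    Internal stops render ``'*'``; codons unresolved due to ambiguity (N)
    render ``'X'``. With ``start_context=True`` an alternative initiator
    codon (GTG/TTG, bacterial rule) is rendered ``'M'``.
    """
    dna = dna.upper()
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} not divisible by 3")
    if not dna:
        return ""
    pep = str(Seq(dna).translate(table=code))
    if start_context:
        table = CodonTable.ambiguous_dna_by_id[code]
        if dna[:3] in table.start_codons:
            pep = "M" + pep[1:]
    return pep


class Orf(NamedTuple):
    """A maximal start-to-stop open reading frame, forward-strand coordinates."""

    peptide: str
    start: int
    end: int
    strand: str
    frame: int


def _scan_frames(seq: str, min_aa: int, code: int):
    """Yield (start0, end0) half-open 0-based spans of maximal ORFs, stop included."""
    table = CodonTable.unambiguous_dna_by_id[code]
    stops = set(table.stop_codons)
    starts = set(table.start_codons)
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in stops:
                if start is not None and (i - start) // 3 >= min_aa:
                    yield frame, start, i + 3
                start = None
            elif start is None and codon in starts:
                start = i


def extract_orfs(genome, min_aa: int = 50, code: int = 11) -> list[Orf]:
    """All maximal start-to-stop ORFs of >= ``min_aa`` codons in six frames.

    Coordinates are 1-based inclusive on the forward strand; the stop codon
    is included in the span but excluded from the peptide.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = genome.dna if isinstance(genome, GenomeRecord) else str(genome).upper()
    L = len(seq)
    orfs: list[Orf] = []
    for frame, s0, e0 in _scan_frames(seq, min_aa, code):
        pep = translate(seq[s0 : e0 - 3], code=code, start_context=True)
        orfs.append(Orf(pep, s0 + 1, e0, "+", frame + 1))
    rc = reverse_complement(seq)
    for frame, s0, e0 in _scan_frames(rc, min_aa, code):
        pep = translate(rc[s0 : e0 - 3], code=code, start_context=True)
        orfs.append(Orf(pep, L - e0 + 1, L - s0, "-", -(frame + 1)))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def gc_content(genome) -> float:
    """GC percentage 100*(G+C)/(A+C+G+T), ambiguous bases excluded, 1 decimal."""
    seq = genome.dna if isinstance(genome, GenomeRecord) else str(genome).upper()
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains only ambiguous bases")
    return round(100.0 * gc / (gc + at), 1)
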