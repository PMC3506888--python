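"""Candidate extraction, scanning, classification, comparison, summaries."""

import numpy as np
import pytest

from transposcan import genome_scan as gs
from transposcan import seqio, synthetic as syn
from transposcan.genome_scan import (
    Candidate,
    Prediction,
    classify_prediction,
    compare_annotations,
    extract_candidates,
    flag_fragment,
    scan,
    summarize,
)
from transposcan.seqio import Feature, GenomeRecord


def _cds_genome(rng=None, products=("transposase", "hypothetical protein")):
    rng = rng or np.random.default_rng(1)
    peps = ["MKVACDEFGHIKLMNPQRST", "MWYHHRRDDEEKKLLNNPPQ"]
    parts, feats = [], []
    pos = 0
    for pep, product in zip(peps, products):
        gap = syn.random_dna(100, 50.0, rng)
        parts.append(gap)
        pos += 100
        cds = "ATG" + syn.reverse_translate(pep[1:], rng) + "TAA"
        feats.append(
            Feature("CDS", pos + 1, pos + len(cds), "+",
                    {"locus_tag": f"g{len(feats) + 1}", "product": product})
        )
        parts.append(cds)
        pos += len(cds)
    parts.append(syn.random_dna(100, 50.0, rng))
    return GenomeRecord(id="G1", dna="".join(parts), features=feats)


def test_annotated_cds_become_candidates():
    g = _cds_genome()
    cands = extract_candidates(g, min_aa=500)  # min_aa high: no ORF candidates
    assert len(cands) == 2
    assert all(c.source == "annotated_cds" for c in cands)
    assert cands[0].peptide.startswith("M")
    f = cands[0].source_feature
    assert (f.start, f.end) == (cands[0].start, cands[0].end)


def test_unannotated_459nt_orf_is_intergenic_candidate(rng):
    # a 152-codon ORF (459 nt with its stop) in otherwise empty DNA
    pep = "M" + syn.random_protein(151, rng).residues
    cds = "ATG" + syn.reverse_translate(pep[1:], rng) + "TAA"
    assert len(cds) == 459
    dna = (
        syn.random_dna(200, 50.0, rng) + syn.STOP_FLANK + cds + syn.STOP_FLANK
        + syn.random_dna(200, 50.0, rng)
    )
    g = GenomeRecord(id="G2", dna=dna)
    cands = [c for c in extract_candidates(g, min_aa=100) if c.source == "intergenic_orf"]
    spans = [(c.end - c.start + 1) for c in cands]
    assert 459 in spans


def test_orf_overlapping_cds_not_intergenic(rng):
    g = _cds_genome(rng)
    cands = extract_candidates(g, min_aa=5)
    for c in cands:
        if c.source != "intergenic_orf":
            continue
        for f in g.features:
            ov = max(0, min(c.end, f.end) - max(c.start, f.start) + 1)
            assert ov < 30


def test_internal_stop_cds_kept_and_flagged_pseudo(rng):
    pep = "MKVACDEFGH*IKLMNPQRST"  # internal stop: pseudogene remnant
    codons = []
    for aa in pep[1:]:
        codons.append("TAA" if aa == "*" else syn.reverse_translate(aa, rng))
    cds = "ATG" + "".join(codons) + "TAA"
    g = GenomeRecord(
        id="G3", dna=cds,
        features=[Feature("CDS", 1, len(cds), "+", {"locus_tag": "p1"})],
    )
    (cand,) = extract_candidates(g, min_aa=500)
    assert cand.pseudo
    assert "*" in cand.peptide


def test_candidate_count_matches_bruteforce_recount(rng):
    tp = syn.make_truth_profile("FAMY", M=60, seed=11)
    genome, _ = syn.build_synthetic_genome(
        [tp], {"class_a": 2, "class_b": 1, "class_c": 1, "decoy": 1},
        length=20000, seed=12,
    )
    min_aa, ov_nt = 40, 30
    cands = extract_candidates(genome, min_aa=min_aa, overlap_nt=ov_nt)
    cds = [f for f in genome.features if f.type == "CDS"]
    exp_orfs = 0
    for o in seqio.extract_orfs(genome, min_aa=min_aa):
        overlaps = [
            max(0, min(o.end, f.end) - max(o.start, f.start) + 1) for f in cds
        ]
        if all(v < ov_nt for v in overlaps):
            exp_orfs += 1
    assert len(cands) == len(cds) + exp_orfs


# ----------------------------------------------------------- classification


def _pred(cand, coverage=1.0):
    return Prediction(
        candidate=cand, family_id="IS630", profile_name="IS630/ORF1",
        evalue=1e-40, bit_score=120.0, profile_coverage=coverage,
    )


def test_classification_by_provenance():
    f_tnp = Feature("CDS", 10, 30, "+", {"product": "transposase"})
    f_hyp = Feature("CDS", 10, 30, "+", {"product": "hypothetical protein"})
    a = _pred(Candidate("c1", "MKVMKVM", 10, 30, "+", "annotated_cds", f_tnp))
    b = _pred(Candidate("c2", "MKVMKVM", 10, 30, "+", "annotated_cds", f_hyp))
    c = _pred(Candidate("c3", "MKVMKVM", 10, 30, "+", "intergenic_orf"))
    assert classify_prediction(a).cls == "a"
    assert classify_prediction(b).cls == "b"
    assert classify_prediction(c).cls == "c"


def test_cds_without_product_is_class_b():
    f = Feature("CDS", 10, 30, "+", {})
    p = _pred(Candidate("c", "MKVMKVM", 10, 30, "+", "annotated_cds", f))
    assert classify_prediction(p).cls == "b"


def test_fragment_flag_rules():
    cand = Candidate("c", "MKVMKVM", 10, 30, "+", "intergenic_orf")
    assert not flag_fragment(_pred(cand, coverage=1.0)).fragment
    assert flag_fragment(_pred(cand, coverage=0.4)).fragment
    pseudo = Candidate("p", "MKV*KVM", 10, 30, "+", "intergenic_orf", pseudo=True)
    assert flag_fragment(_pred(pseudo, coverage=1.0)).fragment


# ------------------------------------------------------------------- scanning


def test_scan_assigns_true_family_and_rejects_background(
    small_truth, calibrated_family, rng
):
    member = syn.sample_from_profile(small_truth, 1, seed=31)[0]
    bg = syn.random_protein(40, rng)
    cands = [
        Candidate("hit", member.residues, 100, 100 + 3 * len(member) - 1, "+",
                  "intergenic_orf"),
        Candidate("bg", bg.residues, 500, 500 + 3 * len(bg) - 1, "+",
                  "intergenic_orf"),
    ]
    preds = scan(cands, [calibrated_family], db_size=100)
    assert [p.candidate.id for p in preds] == ["hit"]
    assert preds[0].family_id == small_truth.family_id
    assert preds[0].cls == "c"


def test_scan_empty_candidates(calibrated_family):
    assert scan([], [calibrated_family]) == []


def test_scan_requires_calibrated_cutoffs(small_truth):
    from transposcan import calibration as cal

    prof = syn.rebuild_profile_from_samples(small_truth, n=5, seed=1)
    c = cal.FamilyCandidate(prof, result=None)
    fms = cal.FamilyModelSet("ISF9", [c], selected=[c])
    cand = Candidate("x", "MKVMKVMKVM", 1, 30, "+", "intergenic_orf")
    with pytest.raises(ValueError, match="calibrated cutoff"):
        scan([cand], [fms])


def test_scan_invariant_to_candidate_order(small_truth, calibrated_family):
    members = syn.sample_from_profile(small_truth, 3, seed=33)
    cands = [
        Candidate(f"m{i}", m.residues, 100 + 500 * i, 100 + 500 * i + 3 * len(m) - 1,
                  "+", "intergenic_orf")
        for i, m in enumerate(members)
    ]
    a = scan(cands, [calibrated_family], db_size=10)
    b = scan(cands[::-1], [calibrated_family], db_size=10)
    assert [(p.candidate.id, p.evalue) for p in a] == [
        (p.candidate.id, p.evalue) for p in b
    ]


def test_predictions_respect_cutoff(small_truth, calibrated_family):
    members = syn.sample_from_profile(small_truth, 5, seed=34)
    cands = [
        Candidate(f"m{i}", m.residues, 1 + 500 * i, 500 * i + 3 * len(m), "+",
                  "intergenic_orf")
        for i, m in enumerate(members)
    ]
    cutoff = calibrated_family.selected[0].profile.cutoff_evalue
    for p in scan(cands, [calibrated_family], db_size=10):
        assert p.evalue <= cutoff


# ------------------------------------------------------------------ summaries


def test_summarize_empty_predictions():
    g = GenomeRecord(id="E", dna="ACGT" * 2500)
    s = summarize(g, [])
    assert s.total == 0
    assert s.class_counts == {"a": 0, "b": 0, "c": 0}
    assert s.gc_percent == 50.0
    assert s.length_mbp == 0.0


def _random_predictions(rng, n, genome_len=100000):
    preds = []
    for i in range(n):
        start = int(rng.integers(1, genome_len - 400))
        end = start + int(rng.integers(90, 400))
        cand = Candidate(f"c{i}", "MKV" * 10, start, end,
                         "+" if rng.random() < 0.5 else "-", "intergenic_orf")
        p = Prediction(cand, family_id=f"IS{rng.integers(1, 5)}",
                       profile_name="x", evalue=1e-30, bit_score=100.0,
                       profile_coverage=1.0, cls=str(rng.choice(list("abc"))))
        preds.append(p)
    return preds


def test_summary_totals_partition_by_class(rng):
    g = GenomeRecord(id="S", dna="ACGT" * 25000)
    preds = _random_predictions(rng, 25)
    s = summarize(g, preds)
    assert s.total == sum(s.class_counts.values())
    assert s.total == sum(s.family_counts.values())


def test_compare_annotations_matching_rules():
    f = Feature("misc_feature", 100, 400, "+")
    cand = Candidate("c", "MKV" * 30, 100, 400, "+", "intergenic_orf")
    p = Prediction(cand, "IS1", "IS1/ORF1", 1e-30, 90.0, 1.0, cls="c")
    comp = compare_annotations([p], [f])
    assert len(comp.confirmed) == 1 and not comp.tnp_only and not comp.external_only
    # same span, opposite strand: never matched
    f2 = Feature("misc_feature", 100, 400, "-")
    comp2 = compare_annotations([p], [f2])
    assert not comp2.confirmed
    assert len(comp2.tnp_only) == 1 and len(comp2.external_only) == 1


def test_compare_annotations_against_allpairs_oracle(rng):
    preds = _random_predictions(rng, 30)
    ext = [
        Feature("misc_feature", int(s), int(s) + int(rng.integers(90, 400)),
                "+" if rng.random() < 0.5 else "-")
        for s in rng.integers(1, 99000, size=30)
    ]
    comp = compare_annotations(preds, ext)
    # conservation
    assert len(comp.confirmed) + len(comp.tnp_only) == len(preds)
    assert len(comp.confirmed) + len(comp.external_only) == len(ext)
    # every confirmed pair is eligible under the brute-force overlap rule
    for p, f in comp.confirmed:
        ov = max(0, min(p.end, f.end) - max(p.start, f.start) + 1)
        assert p.strand == f.strand
        assert ov / (p.end - p.start + 1) >= 0.5
        assert ov / (f.end - f.start + 1) >= 0.5
    # and no unmatched prediction/feature pair is mutually eligible
    for p in comp.tnp_only:
        for f in comp.external_only:
            ov = max(0, min(p.end, f.end) - max(p.start, f.start) + 1)
            eligible = (
                p.strand == f.strand
                and ov / (p.end - p.start + 1) >= 0.5
                and ov / (f.end - f.start + 1) >= 0.5
            )
            assert not eligible


# --------------------------------------------------------------- file output


def test_gff3_header_only_without_predictions(tmp_path):
    g = GenomeRecord(id="H", dna="ACGT" * 100)
    out = tmp_path / "empty.gff3"
    seqio.write_gff3(g, [], out)
    lines = out.read_text().splitlines()
    assert lines[0] == "##gff-version 3"
    assert all(ln.startswith("#") for ln in lines)


def test_gff3_emits_published_style_coordinates(tmp_path):
    # an unannotated-DNA (class c) call at 5666475..5666933 on the + strand
    g = GenomeRecord(id="CHR", dna="A" * 5667000)
    cand = Candidate("c", "MKV" * 51, 5666475, 5666933, "+", "intergenic_orf")
    p = Prediction(cand, "IS200/IS605", "IS200_IS605/ORF1", 1e-25, 80.0, 1.0,
                   cls="c", fragment=False)
    out = tmp_path / "one.gff3"
    seqio.write_gff3(g, [p], out)
    (line,) = [ln for ln in out.read_text().splitlines() if not ln.startswith("#")]
    cols = line.split("\t")
    assert cols[0] == "CHR"
    assert (cols[3], cols[4], cols[6]) == ("5666475", "5666933", "+")
    assert "class=c" in cols[8]


def test_gff3_output_parses_with_external_validator(tmp_path, rng):
    import gffutils

    g = GenomeRecord(id="V", dna="ACGT" * 5000)
    preds = _random_predictions(rng, 5, genome_len=19000)
    out = tmp_path / "v.gff3"
    seqio.write_gff3(g, preds, out)
    db = gffutils.create_db(str(out), ":memory:", force=True)
    feats = list(db.all_features())
    assert len(feats) == 5
    assert {f.featuretype for f in feats} == {"protein_match"}


def test_gff3_rejects_out_of_bounds_prediction(tmp_path):
    g = GenomeRecord(id="B", dna="ACGT" * 10)
    cand = Candidate("c", "MKV", 30, 99, "+", "intergenic_orf")
    p = Prediction(cand, "IS1", "IS1/ORF1", 1e-10, 10.0, 1.0, cls="c")
    with pytest.raises(ValueError, match="outside genome"):
        seqio.write_gff3(g, [p], tmp_path / "x.gff3")


def test_genbank_misc_features_round_trip(tmp_path):
    g = GenomeRecord(id="RT", dna="ACGT" * 200)
    cand = Candidate("c", "MKV" * 20, 11, 190, "-", "intergenic_orf")
    p = Prediction(cand, "IS5", "IS5/ORF1", 2.5e-33, 77.0, 0.4, cls="c", fragment=True)
    out = tmp_path / "rt.gbk"
    seqio.write_genbank(g, out, extra_features=gs.prediction_features([p]))
    back = seqio.read_genbank(out)
    (f,) = [f for f in back.features if f.type == "misc_feature"]
    assert (f.start, f.end, f.strand) == (11, 190, "-")
    assert f.qualifiers["family"] == "IS5"
    assert f.qualifiers["fragment"] == "true"
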