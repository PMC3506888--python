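# transposcan

Profile-HMM prediction of prokaryotic transposases (Tnps) in whole genomes.

Insertion sequences (ISs) are small mobile DNA elements whose transposase
genes are among the most abundant genes in nature, yet they are routinely
mis-annotated ("hypothetical protein") or missed entirely, and most genomes
are littered with partial IS remnants. `transposcan` addresses this with
per-IS-family profile hidden Markov models: it builds a profile from a
curated multiple alignment of each family's transposases, calibrates a
per-profile e-value acceptance cutoff by ROC analysis against labeled
positive/negative protein databases, and then scans whole genomes —
annotated CDS and intergenic ORFs alike — reporting each hit with its
family, an annotation-improvement class, and a fragment/pseudogene flag.

## The model

Each family profile is a Plan7-style local, single-hit HMM with match,
insert and delete states. Match emissions at column *c* are estimated with
background-weighted additive pseudocounts,

    e_c(a) = (n_c(a) + α·20·f(a)) / (N_c + α·20),

where *f* is a fixed Swiss-Prot-like background composition and α the
pseudocount weight; transitions use the same additive scheme on observed
gap structure. A sequence *x* is scored by the log₂-odds of its best
(Viterbi) or summed (forward) local alignment path versus the background
model; alignments enter and exit the profile uniformly (1/M). Null scores
of each profile follow a Gumbel distribution whose location μ and scale λ
are fitted by maximum likelihood on 5000 random background sequences, so a
hit at bit score *s* in a database of *N* sequences has

    E(s) = N · (1 − exp(−exp(−λ(s − μ)))).

Sweeping the e-value threshold over a known-positives database (curated
transposases) versus a known-negatives database (proteins purged of
transposase/insertion sequence/resolvase/recombinase/integrase entries by
keyword) yields a ROC curve; the cutoff is the threshold maximizing
Youden's J = sensitivity + selectivity − 1 (ties toward the most stringent
e-value). Within a family, candidate profiles are compared on
(sensitivity, selectivity): a profile that dominates on both criteria is
used alone, mutually non-dominating profiles are all used.

Genome predictions are classified by what they add to the annotation:
**class a** — a family assignment for a gene already annotated as a
transposase; **class b** — a transposase call replacing a hypothetical or
other product; **class c** — a call in DNA with no annotated gene.
Predictions covering less than half the profile's match states, or whose
translation contains an internal stop, are flagged as fragments
("molecular fossils").

## Worked example

The package ships a synthetic-data module that emulates every input the
pipeline needs, so the whole workflow runs without downloads:

```bash
transposcan simulate --out demo/sim --seed 7 --n-families 2 \
    --profile-length 80 --genome-length 40000
transposcan build demo/sim/alignments --out demo/profiles --seed 7
transposcan calibrate demo/profiles demo/sim/positives.fasta \
    demo/sim/negatives.fasta --out demo/calibrated --seed 7
transposcan scan demo/sim/genome.gbk demo/calibrated --out demo/scan \
    --seed 7 --min-aa 30
```

`demo/calibrated/calibration_report.tsv` then reads

```
family  profile    source   selectivity_pct  sensitivity_pct  cutoff_display  selected
ISF1    ISF1/ORF1  rebuilt  100.0            100.0            4.0E-31         True
ISF2    ISF2/ORF1  rebuilt  100.0            100.0            2.9E-28         True
```

i.e. both rebuilt profiles separate 50 held-out family members from
shuffled-background negatives perfectly, with acceptance cutoffs of
4.0·10⁻³¹ and 2.9·10⁻²⁸. The scan summary (`demo/scan/summary.tsv`)
reports 12 predictions — 5 class a, 3 class b, 4 class c — matching the
simulated genome's manifest of 5 annotated transposases, 3 transposases
hidden as "hypothetical protein", 2 unannotated transposase loci and 2
featureless 40 %-length fragments; one prediction row looks like

```
candidate_id       start  end    strand family evalue    coverage class fragment source
orf_14773_14871_m  14773  14871  -      ISF2   9.1e-63   0.388    c     True     intergenic_orf
```

a truncated remnant caught below its family cutoff and flagged as a
fragment because the alignment covers only 39 % of the profile. The three
background decoy genes in the simulation draw no prediction.

## Layout

- `src/transposcan/seqio.py` — FASTA/GenBank/GFF3 I/O, translation, ORF
  extraction, GC content
- `src/transposcan/profile.py` — alignment → profile construction and the
  `TNPHMM1` ASCII profile format
- `src/transposcan/scoring.py` — Viterbi/forward local scoring
- `src/transposcan/evd.py` — Gumbel calibration and e-values
- `src/transposcan/calibration.py` — database construction, ROC, cutoffs,
  per-family model selection
- `src/transposcan/genome_scan.py` — candidate extraction, scanning,
  class a/b/c, fragments, summaries, annotation comparison
- `src/transposcan/synthetic.py` — seeded synthetic families, databases
  and genomes with ground-truth manifests
- `src/transposcan/cli.py` — `transposcan` subcommands

See `docs/methods.md` for the modeling choices, defaults and limitations.
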