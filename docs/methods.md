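# Methods

This note documents the models and procedures implemented in
`transposcan`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the package's known limitations.

## Profile architecture and scoring

Profiles are Plan7-style local, single-hit (unihit) models. Transposase
domains occur once per ORF and acceptance cutoffs are per-sequence
e-values, so multihit and glocal modes are deliberately absent. An
alignment path enters the profile at any match state with uniform
probability 1/M and exits from any match state with probability 1/M;
residues outside the local alignment are emitted at background frequency,
so their contribution — and the null model's length terms — cancels in the
log-odds. Insert states emit the background distribution (log-odds 0),
contributing only transition costs. Delete states are silent. I↔D
adjacencies are excluded from the architecture, as is conventional; when a
training alignment implies one, that transition is simply not counted.

Scores are log₂-odds against a fixed background model. The background
composition is a Swiss-Prot-like amino-acid frequency table compiled into
the package. The residue `X` (and `*` from pseudogene translations) emits
at background in every state, so it contributes zero to the log-odds —
ambiguity neither helps nor hurts a hit.

Both dynamic programs (Viterbi maximization and forward summation in
natural-log space) were verified against exhaustive enumeration of all
local paths for every profile shape with M ≤ 4 and sequences of length
≤ 6 at relative tolerance 1e-9; the enumeration oracle in the test suite
shares no code with the DP. The kernels are numba-compiled when numba is
importable and fall back to equivalent pure-Python loops otherwise (the
two are compared directly in a test).

### Estimation

Match columns are alignment columns whose gap fraction is strictly below
`gap_threshold` (default 0.5; a column at exactly the threshold is an
insert column). Emissions and transitions use background-weighted additive
pseudocounts: `(count + α·20·f)/(total + α·20)` with α = 1 by default.
This is simpler than the substitution-matrix (Dirichlet-mixture)
pseudocounts of classic HMM packages and has a testable closed form; for
the well-populated alignments this pipeline targets the difference is
immaterial. Residues outside the 20-letter alphabet (X, *) are excluded
from both the numerator and denominator of emission estimates so that
emission rows remain exactly normalized.

## E-values

Each profile is calibrated by scoring `n_random` = 5000 i.i.d. background
sequences (lengths resampled from the training alignment's row lengths,
so the null length distribution matches the sequences the profile will
meet) and fitting a Gumbel location/scale by maximum likelihood
(`scipy.stats.gumbel_r.fit`). The calibration seed is stored in the
profile file, making profile builds byte-reproducible. E-values are
`db_size` times the fitted upper-tail probability. `db_size` is a
configuration knob (default 10 000 for calibration) rather than a derived
quantity, because published per-family cutoffs span many orders of
magnitude and imply large effective database sizes; at genome-scan time it
defaults to the number of candidates scanned and is recorded in the run
metadata. Forward scores are used for e-values throughout (they are the
quantity the Gumbel fit sees); Viterbi supplies alignment spans and
profile coverage.

## ROC calibration and cutoff choice

"Selectivity" is specificity TN/(TN+FP): the calibration pairs it with
sensitivity in a ROC sweep, and precision is additionally written to the
report TSV for transparency. Thresholds are the observed distinct e-values
plus a +∞ sentinel; a sequence is called positive iff its e-value ≤ t
(the cutoff is the last accepted value). The chosen cutoff maximizes
Youden's J = sensitivity + selectivity − 1 with ties broken toward the
most stringent (smallest) threshold. With well-separated score
distributions this lands on the worst accepted positive: every positive is
admitted at the most stringent threshold that does so.

A consequence worth making explicit: whether truncated transposases
("molecular fossils") in a genome can pass the cutoff depends on the
positive database containing comparably partial entries. Curated
transposase databases do contain partial sequences, and the synthetic
end-to-end workflow mirrors this by including a few truncated members
(keep fraction 0.3) in each family's calibration positives. With
full-length-only positives the Youden cutoff is far too stringent for any
fragment — that configuration is exercised separately by the held-out
recovery tests.

Negatives are purged by case-insensitive substring matching of the keyword
list (transposase, insertion sequence, resolvase, recombinase, integrase)
against description lines, after normalizing keywords to singular form so
plural variants match. An empty keyword list is an error rather than a
silent no-op. Any negative whose exact sequence occurs among the positives
is dropped with a logged warning.

### Model selection

Within a family, candidates (rebuilt here, or external models) are
compared on (sensitivity, selectivity) at their cutoffs. The selected set
is the Pareto-non-dominated set: a candidate at least as good on both
criteria and strictly better on one displaces another; mutually
non-dominating candidates are all kept; exact ties prefer rebuilt models.
The rule is idempotent and order-independent.

## Genome scanning

Candidates are every annotated CDS (translated from its span and strand
with genetic code 11, GTG/TTG rendered as initiator M; the `translation`
qualifier is used when present) plus every maximal start-to-stop intergenic
ORF of ≥ `min_aa` codons in six frames. An ORF overlapping an annotated
CDS span by ≥ 30 nt is not intergenic — this avoids double-counting
frame-shifted readings of annotated genes while tolerating slight boundary
noise. `min_aa` defaults to 50 codons: small enough to catch short
transposase loci and fragments while keeping the candidate count
tractable. A CDS whose translation contains an internal stop is kept and
marked pseudo (it supports fragment detection) rather than discarded.

Each candidate is scored against every selected profile and accepted iff
its e-value is at or below that profile's cutoff; only the best family per
candidate is kept (smallest e-value, then higher bit score, then
lexicographic family id), reflecting one transposase call per locus.
Classification follows provenance exactly: intergenic → class c; annotated
CDS with a transposase-keyword product → class a; any other annotated CDS
→ class b. Fragments are flagged at profile coverage < 0.5 (configurable)
or on the pseudo mark.

Comparison against an external annotation matches a prediction to a
feature iff they share a strand and overlap reciprocally by ≥ 50 % of each
span, greedily by overlap length; the counts satisfy
`union = predictions + not-found` by construction. The matching criterion
is this package's choice — there is no single field convention.

## Synthetic data

Truth profiles concentrate probability `conservation` (default 0.9) on one
random residue per position, remainder spread by background, with small
indel rates (0.02). Sampling traverses the states generatively. Training
alignments are produced by Viterbi-aligning samples back to the truth
profile — one column per match state, insert residues dropped — which
sidesteps implementing a multiple aligner while giving realistic gap
structure. Negatives are per-record residue shuffles: exact composition
and length matches for the positives, destroying only the positional
signal.

Synthetic genomes implant reverse-translated (uniform synonymous codons,
code 11) sampled peptides into exact-composition background DNA (default
GC 47.3 %), each implant flanked by a 12-mer carrying stop codons in all
six frames so that ORF boundaries coincide exactly with the manifest.
Class a implants get CDS features with a transposase product, class b
"hypothetical protein", class c and fragments (truncated to 40 % by
default) no feature at all, and decoys are background-protein CDS.
Implants never overlap. The default end-to-end conditions — three families
of M = 150, a 60 kb genome with 5/3/2/2/3 implants per category, 50
training and 50 held-out positives and 500 shuffled negatives per family —
keep the full pipeline run in the low minutes on one core.

What the generator does not emulate: terminal inverted repeats and target
site duplications, compositional bias and codon usage of real genomes,
sequence redundancy and annotation errors of real databases, and
between-family homology (synthetic families are independent, so
cross-family confusion is easier than for, say, the IS3 subgroups).
Passing the synthetic end-to-end checks therefore demonstrates the
machinery's correctness, not field performance on real genomes; published
per-family performance numbers depend on specific database snapshots and
are not reproducible at desk scale.

## Numerical choices and degenerate inputs

- DP in natural log space; forward uses a numerically safe two-argument
  log-sum-exp; conversions to bits only at the surface.
- Gumbel fits reject zero-variance score sets; calibration requires
  n_random ≥ 100.
- ROC requires both sets non-empty; `choose_cutoff` of an everywhere-flat
  J picks the smallest threshold.
- Viterbi tracebacks resolve exact ties in a fixed order (match, insert,
  delete continuation before entry), making spans deterministic.
- GC content excludes ambiguous bases from numerator and denominator and
  errors on all-ambiguous input; e-values saturate at `db_size` for scores
  far below μ.
- `sample_from_profile` guards the measure-zero all-delete traversal by
  emitting a single match residue.

## Limitations

- The scanner is for prokaryotic, unspliced genes only; no EMBL input; no
  inverted/direct-repeat detection, and therefore no IS element boundary
  calling — predictions are transposase loci.
- Scoring throughput (~10³ sequence-profile pairs/s at M ≈ 150) suits
  single genomes and the synthetic benchmark sizes, not metagenome-scale
  sweeps; there are no acceleration filters.
- Binary profile formats of other HMM packages are not read; profiles are
  exchanged in the documented `TNPHMM1` ASCII format.
- Multi-ORF families are handled as independent profiles per ORF;
  element-level grouping of multiple ORF hits is reported only as a note.
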