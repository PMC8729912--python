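# Methods

## Profile HMMs

Each domain model is a classic match/insert/delete profile HMM
estimated from a reference sub-alignment.  Columns with gap fraction
< 0.5 become match states.  Emissions and transitions are Laplace
(add-one) estimates, `(count + 1) / (total + k)`, where `k` is the
number of outcomes (20 residues; 3 transitions out of a match state, 2
out of insert or delete).  The background distribution is the smoothed
residue frequency of the whole sub-alignment, and insert states emit
the background, so inserts are score-neutral except for their
transition costs.  Laplace was chosen because it is the simplest fully
specified estimator; with the reference-set sizes used here (6–16 rows
per family) informative priors would mostly be prior, and the tests
measure recovery, not likelihood.

Alignment is local in both the sequence and the model: a path may enter
and leave at any match state at no charge, and the score is the
log-odds sum `Σ log(e(x)/bg(x)) + Σ log t` in nats.  `X` has odds ratio
1 everywhere.  Multiple hits per protein are recovered by masking the
best hit's residues and re-aligning; the iteration stops when the best
score is no longer positive or after `max_hits_per_model` (default 10)
rounds.  The cap exists because with free endpoints a one-residue
alignment is almost always marginally positive (add-one smoothing makes
rare residues look enriched relative to the smoothed background), so a
literal "while positive" loop would degenerate into one rescan per
residue; capped and uncapped runs report identical hits on every tested
input because sub-domain fragments are removed by the BLOSUM62
threshold anyway.  The forward companion sums over the same path space
with log-sum-exp and is used as a diagnostic (`forward ≥ viterbi` is
asserted property-wise).

Ties in the Viterbi recurrences are broken deterministically: the
global best cell prefers higher score, then smaller start, then smaller
end; equal-scoring predecessors resolve in a fixed candidate order.
Exact score ties between genuinely different paths essentially do not
occur with continuous emissions; determinism, which the byte-identity
tests rely on, is what the tie-break guarantees.

The dynamic programming kernels are compiled with numba; both are
checked against exhaustive enumeration of every legal state path on
small models (M ≤ 4, |seq| ≤ 6, 200 random cases, 1e-9 nats).

## Hit scoring and thresholds

A located hit is re-scored by a global alignment of the hit subsequence
against the model consensus (per-state argmax residue) under BLOSUM62
with affine gap costs in the NCBI pairing for this matrix: a gap of
length k costs 11 + k.  `X` scores 0 against everything.  The consensus
is the only model-intrinsic second operand for such a comparison, which
is why it is used.

Each retained model's minimum BLOSUM62 score is calibrated as the floor
of the minimum hit score over its reference positives.  This guarantees
zero false negatives on the reference set — the reference genes act as
anchors — at the cost of admitting anything that scores at least as
well as the worst reference member.  Hits must also have positive
log-odds.  Thresholding is applied to the BLOSUM62 score (not the HMM
score) because that is the score the calibration is defined on.

**Recognition** (used by retention criterion ii and by calibration) is
stricter than hit reporting: a model recognizes a sequence only if the
best alignment has positive log-odds *and* covers at least half the
model's match states.  Without the coverage requirement,
self-recognition would be vacuously true for every model (see above on
one-residue alignments) and the "model cannot recognize its own
training sequences" filter could never fire.

## Model retention

Candidates are filtered in order: (i) models whose domain is handled by
a dedicated predictor (TM, CC) are rejected outright; (ii) a model must
recognize every sequence it was built from; (iii) when a competing
legacy model for the same domain is supplied together with a labeled
benchmark, the model with the higher F-score (positive = recognition)
is kept, ties keeping the new model.  Besides per-class models, a
pooled LysM model is built from the vertically concatenated LYK and LYP
sub-alignments (their rows are sampled in one jointly aligned batch so
the widths agree), and lectin-domain regions tagged with a subtype
(legume, bulb) yield one additional model per subtype.  KIN domains are
detected by HMM like the other resistance domains; kinase detection by
profile is standard practice and the classification rules need it.

## Coiled-coil predictor

Lupas-style scoring: a 21-residue window at register offset `o` scores
the geometric mean of per-residue, per-heptad-position propensities,
`exp((1/W) Σ log p[x_i, (i+o) mod 7])`.  The score maps to a
probability by the ratio of two Gaussian densities (coiled-coil mean
1.63, sd 0.24; globular mean 0.77, sd 0.20).  A residue's probability
is the maximum over the 7 registers and all windows covering it;
maximal runs of ≥ 14 residues with probability ≥ 0.5 are segments.  The
propensity table shipped in `prgscan/data/coils_default.json` is a
package-authored table with the canonical structure (hydrophobics
favored at positions a/d, charged residues at e/g, proline strongly
penalized); it is versioned data, not a reproduction of any published
constants, and every load-bearing test uses a synthetic table with
known structure.  Window 21 is the default; 14 or 28 can be configured
but are not exercised by the shipped tests.

## Transmembrane predictor

A 19-residue sliding window over the Kyte–Doolittle scale; windows with
mean hydropathy ≥ 1.6 are unioned, unions closer than 5 residues are
merged, and each segment reports its peak window mean.  This replaces a
cyclic-topology membrane HMM deliberately: classification consumes only
TM presence/absence, which the hydropathy rule provides reliably, and
the module boundary admits a drop-in replacement.  Orientation and
signal peptides are out of scope.

## Classification

Set-based and total: the class is a pure function of the set of
detected domain labels, evaluated against seven rules in fixed priority
order (TNL; CNL requiring no TIR; RLK/RLP requiring no NBS; LYK/LYP;
LECRK), else NONCANONICAL with a compact architecture code in display
order CC→C, TIR→T, NBS→N, LRR→L, LYSM→Y, LECM→E, KIN→K, TM→M.  Rules
1–2 do not require TM absence (real NLRs often carry predicted TMs, and
L-rich LRR regions regularly trigger hydropathy windows); rules 3–4
exclude NBS so an NLR with a spurious TM is never demoted to a surface
receptor.  A lectin domain without a kinase is non-canonical: no
LECRK-minus-kinase class is defined.  N-to-C order is shown in the code
string but never affects the class.

## Validation

Protein-level, presence/absence on the five HMM-detected resistance
domains (TIR, NBS, LRR, LYSM, LECM); CC and TM are excluded because
they come from the dedicated predictors.  Criterion 1 is set equality
with the reference, criterion 2 is superset ("equally or better" — the
only partial order consistent with criterion 1 being the stronger
statement).  Multiplicity is ignored (two LRR hits count as LRR
presence).  Confusion cells are counted per (protein, domain);
undefined ratios (zero denominators) are reported as not-applicable,
never as 0.

## Synthetic data

The generator defines the study conditions.  Reference families are
sampled from per-domain generator HMMs whose match states emit a random
consensus residue with probability `1 − divergence` (rest uniform) and
whose indel rates are `divergence/10`; default divergence is 0.15,
with 8 rows per class.  Domain lengths are scaled-down but
realistic ranges (TIR 90–110, NBS 140–170, LRR 100–130, LysM 45–60,
lectin 90–110, kinase 130–160); the LRR consensus is leucine-enriched.
Proteomes plant each class's architecture N-to-C with background
linkers (25–50 residues) between segments: HMM domains as the generator
consensus with 5% per-residue substitution noise (no indels — planted
segments are verbatim consensus at noise 0), CC as the ideal heptad
`LEELKEK` repeated, TM as a 21–25 residue hydrophobic stretch.  Class
proportions are realized by largest-remainder rounding so counts are
exact (`stochastic_mix` restores multinomial sampling).  The background
composition is polar-biased and depleted in L/I/V/F/M/W/C so
hydrophobic runs — and hence false TM windows in linkers — are rare;
this is a property of the fixture, not a claim about proteomes.

What passing tests show: the pipeline recovers planted domains and
classes essentially perfectly under these conditions (substitution
noise well inside the training divergence, one domain family per
label, no compositional drift).  What they do not show: performance on
real proteomes with divergent subfamilies, repeat-number variation,
domain order violations, fragmented gene models, or compositional
biases that mimic TM/CC signal.  The acceptance run (200 proteins,
seven classes, seed-driven) is a correctness and calibration check, not
a biological benchmark.

## Numerical and interface choices

Scores are nats internally, printed to 3 decimals; coordinates are
1-based inclusive on the protein.  Model JSON serialization sorts keys
and round-trips bit-identically, which together with seed-threaded
randomness makes whole pipeline runs byte-identical — asserted by the
determinism test.  DNA input is translated in all six frames; products
between stop codons shorter than 30 aa are skipped (configurable), and
only N is accepted as a DNA ambiguity code (codons containing N
translate to X).  Same-label hits overlapping by ≥ 1 residue are merged
to their union interval keeping each score's maximum; different labels
never merge.  Problem sizes in the shipped tests (reference sets of 8
rows, proteomes of 10–200 proteins) were chosen to exercise every code
path at desk scale while keeping full-suite runs fast.

## Known limitations

* Single-hit local semantics with mask-and-rescan rather than a
  multi-hit Plan7 architecture; no E-values, no SSV/MSV acceleration.
* The BLOSUM62 threshold calibrated as a reference-set minimum is
  deliberately permissive; on small reference sets one weak member sets
  the bar for the whole family.
* The CC/TM predictors are window rules, not topology models; their
  default constants are package-authored data files.
* Classification precedence between canonical rules (e.g. a protein
  carrying both LRR and LysM with TM and kinase) is a fixed declared
  order, not an empirical claim.
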