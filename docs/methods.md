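# Methods

## Problem setting and model

`repeatrain` quantifies transcription of repeat *types* (families), not
individual genomic copies. The unit of inference is the family because
short reads rarely distinguish diverged copies of the same element, while
the biological question — is this family derepressed? — lives at the type
level. Three modelling commitments follow:

1. **Reference.** Each family is represented by its canonical consensus plus
   all annotated genomic instances, each instance extended by
   `F = floor(L/2)` bases of genomic flank. With `L = 2F`, any read
   overlapping an instance by at least one repeat base lies entirely within
   the extended interval, so instance records capture every read that
   touches annotated repeat sequence, including reads crossing
   satellite-unit junctions. Minus-strand instances are stored
   reverse-complemented (5'→3' in repeat orientation); since reads are
   scored on both strands of every record this choice is observationally
   neutral. Overlapping instances of different families keep their shared
   bases in both families' records; the mask partition excludes bases
   covered by any family.

2. **Assignment.** Alignment quality is the ungapped matching-base count
   (substitution-only; no indels). This makes "equal or better quality" an
   exact integer comparison, so tie semantics — the heart of the uniqueness
   criteria — are unambiguous and oracle-checkable. "Equal or better"
   includes equality, so a tie with another family (criterion 2) or with
   un-annotated genome (criterion 3, optional masking) discards the read.
   Multiple placements within the winning family never discard.

3. **Quantification.** Since assignment is unique-by-type, equivalence
   classes are nearly always singletons and the VBEM essentially returns
   count fractions; the machinery nevertheless resolves residual ambiguity
   (e.g. families sharing most k-mers of a read) exactly as lightweight
   transcript quantifiers do. Both unique assignment and an EM stage are
   retained deliberately rather than guessing which should dominate.

## Seeded search vs exhaustive scoring

Candidate placements are found via shared k-mers and rescored exactly. A
fixed seed of k = 17 on 26-bp reads would be *incomplete*: a placement with
two mismatches can have no exact 17-mer (longest run can be 8). The seed
length is therefore `min(k, min_score // (L − min_score + 1))` — the
pigeonhole guarantee that any placement scoring ≥ `min_score` shares at
least one seed with the target (8 bp at the defaults L = 26,
`min_score` = 24). Scores below `min_score` may be underestimated (they
cannot change any verdict, because a verdict only compares scores against a
best that is itself ≥ `min_score`); the discard label distinguishing
`no_hit` from `below_min_score` is correspondingly approximate, and the two
are one category for validation purposes. Verdicts — assigned family or
discard class — provably equal exhaustive all-offset scoring, which the test
suite checks read-by-read on randomized references.

`min_score` defaults to L − 2 (≈92% identity at L = 26), mirroring
near-exact short-read k-mer mapping; it is a config knob, and the seed
length adapts to it.

## Quantification details

- **k-mers**: k = 17, canonical form = lexicographic min of window and
  reverse complement. The poly-A filter drops windows equal to `A^k` or
  `T^k` *before* canonicalization. Reads whose filtered k-mer set is empty
  are excluded from quantification (logged).
- **Equivalence classes**: a family is compatible with a read when its
  records contain ≥ `ceil(0.8·(L − k + 1))` of the read's filtered k-mers
  (8 of 10 at the defaults). A read compatible with no family at that
  threshold (possible when errors corrupt every 17-mer) keeps its assigned
  family as a singleton class — the assignment stage already established
  its identity at full-read resolution — preserving count conservation.
- **VBEM**: symmetric Dirichlet prior `alpha0 = 0.01` per family;
  responsibilities ∝ `exp(ψ(α_f))/ẽ_f` over the class's family set;
  convergence on `max|Δθ| ≤ 1e−8` (dimension-free and simple), capped at
  1000 iterations with a warning flag on non-convergence. As `alpha0 → 0`
  and counts grow, θ approaches the standard-EM fixed point; at moderate
  counts the `exp(ψ(α)) ≈ α − 0.5` shift keeps them apart by O(1/n), which
  is why the EM-agreement validation uses counts in the thousands.
- **Effective length**: `ẽ = max(l − L + 1, 1)` with `l` the canonical
  consensus length (type-level targets). This is the only length/bias
  correction applied; sequence-composition bias regression is deliberately
  out of scope.
- **TPM**: `(θ_i/ẽ_i)` normalized to 10⁶. Invariant under uniform scaling of
  counts or of effective lengths; sums to 10⁶ whenever any read quantified,
  all-zero input yields all-zero TPM with a warning rather than 0/0.

## Differential testing

Proportions use the *quantified* library size (reads surviving criteria
1–3 and the poly-A filter) as denominator — the compared universes must
match. Consequences: estimates are compositional within the repeat
compartment, so a strong derepression of one family deflates the apparent
proportions of the others (visible in the worked example); keeping the
derepressed family a small share of the compartment keeps the distortion
small.

- **Kal's Z** (unreplicated): pooled-variance two-proportion z; the all-zero
  case returns z = 0, p = 1 by convention.
- **Baggerly-style weighted t** (replicated): per group, iteratively
  reweighted proportion with weights `1/(σ_b² + p̂(1−p̂)/N_s)`, where σ_b² is
  the method-of-moments between-replicate variance floored at 0; variance of
  the estimate is `1/Σw`; Satterthwaite df floored at 1. When both groups
  estimate σ_b² = 0 the statistic reduces to the pooled two-proportion
  z-test with a normal reference — the known-variance regime — rather than a
  t with ~2 df.
- **Fold change**: ratio of mean proportions with pseudo-proportion
  `ε = 0.5/median(N)` (half-count continuity correction).
- **FDR**: Benjamini–Hochberg step-up across all families tested. Families
  with zero counts everywhere are excluded (logged).

Calibration measured by the validation suite: Kal type-I error ≈ 0.05 at
α = 0.05 (5,000 null draws), Baggerly null rejection ≈ 0.05 on
overdispersed 2v2 nulls, null false-discovery proportion ≪ 0.05.

## Synthetic data generator

The generator emulates the data regime the pipeline targets, with defaults
chosen once as the standard study conditions:

- 160 kb genome over three contigs (60/60/40 kb) — large enough for distinct
  repeat compartments and a dominant unique background, small enough for
  desk-scale exactness checks.
- **GSAT-like** major satellite: 234-bp unit, 40-copy tandem array, 2%
  divergence, strand-symmetric (satellite transcription is bidirectional,
  yielding dsRNA); transcripts are read-through concatemers of 1–3 units.
- **SATMIN-like** minor satellite: 120-bp unit, 30 copies, tandem,
  strand-symmetric, baseline weight 0.08 — the minor satellite is a small
  compartment of repeat transcription.
- **LINE1-like**: 1.5-kb consensus, 8 interspersed copies at 10% divergence.
- **SINE-B1-like**: 150-bp consensus, 40 interspersed copies at 8%
  divergence.
- 20 background genes (1 kb), 20% embedding a 100-bp SINE fragment — decoy
  multi-mappers that exercise the masking criterion (their reads match
  un-annotated genome exactly and the SINE family nearly as well).
- Background expression weight 10 vs total repeat weight ≈ 4.2, making
  repeat-derived reads ≈ 30% of the pool.
- 50,000 single-end 26-bp reads per sample, uniform substitution errors at
  0.5%, constant quality, two replicates per condition. Treated samples
  multiply family weights by configured fold changes.

Read length defaults to 26 bp so that the half-read flank is 13 bp; all
half-read quantities are computed as `floor(L/2)`, never hard-coded.
Randomness flows from one master seed through named `SeedSequence` child
streams (genome; one per sample), so identical configurations are
byte-identical and single samples can be regenerated in isolation.

**What the generator does not emulate** — and what passing tests therefore
do not demonstrate about real data: indels and structural variation,
realistic base-quality and PCR-duplicate structure, fragment-length effects,
paired-end reads, splicing, non-uniform background composition
(real genomes are not i.i.d. uniform, so real cross-family and genome ties
are more frequent), and annotation incompleteness beyond the embedded-SINE
decoys. Recovery results on synthetic data bound the method's behaviour in
its own model, not on arbitrary real libraries.

## Validation scale choices

The validation suite runs the full study at 50,000 reads/sample for the
fold-change recovery checks (three pipeline runs plus one null run) and uses
count-level replicate simulation (200 datasets at observed library sizes and
proportions) for false-discovery calibration, where read-level resimulation
would add nothing but runtime. Seeded-vs-exhaustive assignment equality is
checked on 100 randomized small references (~6,000 reads total), the scale
at which exhaustive all-offset scoring is itself cheap to trust.

## Known limitations

- Ungapped scoring: an indel-containing read loses score linearly; real
  aligner behaviour would differ.
- Type-level effective length uses the canonical length even though reads
  also map to flanked instances; for satellites with concatemeric
  transcripts the notion of "transcript length" is intrinsically fuzzy.
- The Baggerly test with 2 replicates/group has few df; its power is modest
  and its variance floor makes it conservative — by design, given the
  replication level.
- Fold-change estimates are compositional (see above); they estimate the
  change in *share of repeat transcription*, which approaches the true
  derepression factor only when the affected family is a minor component.
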