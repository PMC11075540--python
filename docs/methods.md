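# Methods

This note documents the models, decision rules, numerical choices, and
known limitations of the toolkit, and what the synthetic-data generator
does and does not emulate.

## Curation model

A TE consensus library is curated by combining four independent strands of
evidence per sequence.

**Coarse order prediction.** A naive-Bayes classifier over k-mer counts
(default k = 4, additive smoothing 1.0, uniform class prior) predicts one
of three coarse groups: nonLTR, LTR, DNA. Confidence is the normalized
posterior; sequences with no scorable k-mer (e.g. all Ns) are "unknown".
This stands in for external order classifiers; precomputed labels can be
ingested instead, and the decision engine is agnostic to the source. The
three-way label is used only as a gate: curation requires it to agree with
the order implied by the domain evidence (DIRS and PLE count as nonLTR;
Crypton, Helitron, Maverick and DNA/TIR as DNA).

**Domain evidence.** Six-frame ORFs are extracted stop-to-stop (no ATG
requirement, matching getorf's default) with a 200-aa minimum; records
shorter than 3×200 nt cannot qualify and return empty. Domains are modeled
as ungapped per-column log-odds profiles over the 20 amino acids:

    score(col, a) = log2( ((count_a + c·bg_a) / (total + c)) / bg_a )

with pseudocount mass c = 1.0 and a uniform background by default
(configurable). Columns with > 50% gaps are dropped (match-column rule).
Scanning slides the profile along the ORF (or the ORF along the profile
when shorter) and keeps the best window per ORF × profile; a hit requires
≥ 0.5 bits per scored column (configurable). Residues outside the
20-letter alphabet contribute 0 bits. This is deliberately not a full
profile HMM — no insert/delete states, no Forward algorithm, no E-values —
because the curation rules consume only "has a credible domain of order X
with score s". Externally computed hmmsearch domain tables are accepted
through the same ProfileHit interface for users who want the full model.

**Structural evidence.** The TIR search anchors a left arm start within
`edge_window` (default 50) nt of the 5′ terminus and a right arm end
within `edge_window` nt of the 3′ terminus, extends each anchor pair
inward, and keeps the longest arm pair whose mismatch count stays within
`max_mismatch_frac` (default 0.1) of the arm length; ties prefer fewer
mismatches, then outermost placement. The minimum arm length is 8 nt. The
search is exhaustive over anchor pairs, so detection is deterministic and
monotone: lowering the minimum length can only add detections. Size rules
are read inclusively: MITE = TIR ∧ 50–1,000 bp ∧ no transposase;
DNA/TIR candidate = TIR ∧ transposase ∧ 1,000–17,000 bp. A 1,000-bp
record falls in the MITE branch without a transposase and in the DNA/TIR
branch with one; the two calls are mutually exclusive by the transposase
flag.

**Expanded-gene masking.** Host gene families with very high copy number
(Sel1, BTB, Kelch, protein kinase, TPR) produce repeat consensus models
that can carry partial TE insertions. A consensus whose best expanded-gene
profile hit outscores its best TE-domain hit is statused `expanded_gene`
and leaves curation.

**Phylogenetic disambiguation.** When a second domain hit within 25 bits
(configurable) of the best maps to a different order, the consensus'
domain-region protein is placed on a neighbor-joining tree (scikit-bio)
built from uncorrected amino-acid p-distances against labeled reference
sequences (pairwise-complete sites; sequences compared over their common
prefix length, adequate for same-domain regions). The query takes the
label of the reference group with the smallest mean patristic distance; an
exact tie, or fewer than 3 taxa, falls back to the best-scoring hit with
`phylo_resolved = false`. An externally supplied Newick tree (e.g. from a
maximum-likelihood run) overrides the built-in NJ placement.

**Decision cascade.** (1) masked → expanded_gene; (2) no domain: MITE
structure → curated MITE, else relic; (3) order conflict → tree placement;
(4) DNA/TIR: curated only if all four criteria hold (DNA prediction,
domain, TIR, size), else unresolved; (5) all other orders: curated iff the
coarse prediction agrees with the domain's order, else unresolved. Every
input receives exactly one status, so status counts always partition the
library. Curated sequences are renamed `Family#Order/Superfamily`
(RepeatMasker custom-library convention).

## Kimura landscapes

Divergence uses the Kimura 2-parameter closed form
K = −½ ln((1 − 2p − q)√(1 − 2q)) on observed transition/transversion
proportions. Alignment columns with gaps or ambiguity codes are excluded
from the counts; CpG-site exclusion (consensus-strand CpG columns) is
available but off by default. Inputs where a log argument is non-positive
are reported as saturated, excluded from landscapes, and counted.

Landscapes weight each copy by its genomic span in bp (the y-axis is
percent of genome), binned at floor(K% / width) with width 1 over 0–50%.
Copies are assigned to a compartment by the midpoint of their interval —
deterministic for copies straddling a boundary; copies outside every
compartment go to an "unassigned" stratum. Compartments are compared with
a paired t-test over per-bin percentage pairs (two-sided p on n − 1 df),
optionally over a bin subrange such as 10–20; the direction of the mean
difference is reported alongside. All-zero differences short-circuit to
t = 0, p = 1, flagged degenerate.

## Expression links

TPM: rate_i = count_i/(length_i/1000), scaled so each sample sums to 10⁶;
all-zero samples stay zero. Upstream pairing is strand-aware: for a +
gene, TEs whose end lies in [TSS − 1,000, TSS]; mirrored for − genes; a TE
overlapping the TSS counts at distance 0; all qualifying many-to-many
pairs are kept. Coexpression is pair-level Pearson on ln(TPM + 1) of the
mean abundance per feature (natural log, offset 1 — the transform is
configurable since only "log TPM" is conventionally specified). The
p-value comes from t = r√((n−2)/(1−r²)) on n − 2 df; zero-variance inputs
are flagged rather than propagated as NaN surprises. DE summarization uses
the inclusive rule padj ≤ α (default 0.05) with the sign of the log2 fold
change; missing padj is never significant, and UP + DOWN + NO equals the
accepted row count. Group comparisons default to Welch's unequal-variance
t-test (a flag restores Student's); identical zero-variance groups report
t = 0, p = 1 instead of NaN.

## Synthetic-data generator

The generator is first-class, tested code: it defines the study
conditions under which every claim in the test suite is measured.

- **Libraries.** Default 65 families: 12 DNA/TIR (3 kb), 10 MITE (300 bp),
  10 LTR/Gypsy (4 kb), 10 LINE (3.5 kb), 8 Crypton (3 kb), 10 relics
  (1.5 kb), 5 expanded-gene chimeras (2 kb). Domain-bearing families embed
  a stop-flanked ORF back-translated (uniform synonymous codon choice)
  from the domain consensus mutated at 5% on the amino-acid level. The 5%
  planted divergence is applied to the protein rather than the nucleotide
  consensus: nucleotide mutation of a coding region would introduce
  nonsense codons and destroy the ORF whose presence the curation rules
  are testing. Planted TIRs (15 nt) are exact on the consensus — the
  consensus is the family representative, not a diverged copy. Relics are
  1.5 kb (outside the MITE window) so an accidental short inverted repeat
  cannot flip them to MITE. The three coarse order groups get distinct
  background base compositions, which is what makes a k-mer order
  predictor work; real TEs differ by subtler signals, so the generator
  validates the decision logic, not k-mer classification of real repeats.
- **Genomes.** Copies are placed non-overlapping with multinomial random
  gaps on a single 300-kb chromosome split 50/50 into A and B. Each copy
  is mutated to its target K2P divergence by solving the closed form for
  (p, q) at a 2:1 transition/transversion ratio and substituting sites
  independently — the exact inverse of the estimator, so mean recovery is
  unbiased by construction and the `.align` blocks written are exactly the
  planted alignments. The compartment scenario plants 60 young copies
  (0.5–8% divergence) per compartment plus 60 (A) vs 120 (B) aged copies
  (10.5–19.5%), i.e. a 2× aged-bp excess in B.
- **Expression.** Per compartment, 200 gene–TE pairs with log-abundances
  drawn bivariate-normal at ρ_A = 0.2 and ρ_B = 0.85 (mean 3, unit
  variance); TPM = exp(z) − 1 so the analysis transform ln(TPM + 1)
  recovers the planted scale exactly. DE tables plant 40 UP / 10 DOWN /
  50 NO with padj consistent with the labels.
- **Determinism.** All randomness flows from one `numpy` Generator seeded
  by the config; identical configs produce byte-identical files.

The generator is not a biological sequence evolver: no indels, no rate
heterogeneity, no TE nesting, no GC-content gradients, no fragmented
copies. Passing tests therefore demonstrate that the decision rules,
estimators and tests behave correctly under their stated models — not
that the profiles or the k-mer predictor would reach the same accuracy on
real genomic repeats.

## Numerical choices and problem sizes

- Hit threshold 0.5 bits/column; conflict margin 25 bits; both
  configurable and chosen as round defaults in the absence of a stated
  convention.
- NJ trees may contain negative branch lengths (standard NJ behaviour);
  mean patristic distances are used as-is.
- The paired t-test degenerates gracefully (see above); a constant
  non-zero per-bin difference reports infinite t with p = 0.
- Verification sizes: divergence recovery uses 200 copies × 10 kb per
  target K; the compartment comparison uses 100 replicate genomes of
  300 kb; coexpression uses 200 pairs per stratum; the TIR gate uses
  1,000 fixtures built on an A/C-only background (such a background
  cannot base-pair with itself, and a pairing run through the planted arm
  cannot exceed the arm length, so the absence of false accepts is
  structural, not probabilistic).

## Known limitations

- The PSSM scan is ungapped; a domain split by a long insertion in the
  ORF scores as the best contiguous window only.
- p-distances truncate to the common prefix of the two sequences; for
  domain regions of very different lengths an explicit alignment should
  be supplied upstream.
- The `.align` reader supports the block dialect of RepeatMasker 4.1.x
  (query/consensus row pairs, annotation midlines ignored); exotic older
  layouts are not parsed.
- MITE calling is domain-free by rule; a short autonomous element whose
  transposase ORF is missed by the profiles would be called MITE.
- No insertion-age calibration in years: landscapes are left in
  divergence units.
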