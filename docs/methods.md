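# Methods

`hlamotifs` implements an end-to-end pipeline for pooled HLA class I
immunopeptidomics: per-sample motif discovery by mixture-of-PWMs EM,
fully unsupervised mapping of motifs to alleles from genotype
co-occurrence across samples, and a PWM-based ligand / neo-antigen
predictor trained on the deconvoluted peptides. This note records the
models, the parameter choices, and the reasoning behind the design
decisions that were genuinely open.

## Mixture model and EM

Peptides of one length L in one sample are modelled as a mixture of K
position-independent PWMs: a peptide x is generated by choosing motif k
with probability w_k and drawing residue x_i at each position i from
pwm_k[i]. The E-step computes responsibilities
r_ik ∝ w_k · Π_i pwm_k[i][x_i]; the M-step re-estimates PWMs from
responsibility-weighted counts with a Dirichlet smoothing count
γ = 0.1 per residue per position (EM requires strictly positive
emissions; γ is deliberately distinct from the predictor's BLOSUM
pseudocounts, which apply only to final allele models). Convergence is
declared when the relative log-likelihood change drops below 1e-6
(max 500 iterations); the best of `n_restarts` runs (default 5) by
final log-likelihood is kept.

**Initialization.** Component PWMs are seeded from peptides by
farthest-first traversal: a random first seed, then each subsequent
seed is the peptide with the lowest likelihood under the current seed
profiles; each seed PWM is 0.7·uniform + 0.3·one-hot(seed peptide).
Restarts vary the first seed. Two symmetric alternatives fail here:
per-peptide Dirichlet responsibilities average every component onto the
data mean (a saddle point EM cannot leave), and independent random
peptide seeds collide on the same motif with high probability once
K > 3. Farthest-first seeding is the standard remedy and makes the EM
reliably reach the separated optimum. Results are made exactly
invariant to the input peptide order by canonicalizing (sorting) the
list internally and un-sorting the responsibilities.

**Trash component.** Optionally (and by default inside the per-sample
pipeline) the mixture carries one extra component with *fixed* uniform
emissions over the 20 residues and a free weight. Eluted-ligand pools
contain co-purified contaminants that match no allele's anchors; under
an anchored motif such a peptide is several nats less likely than under
the uniform distribution, so the trash component captures contaminants
cleanly while costing a single parameter. Without it, contaminants are
argmax-assigned across the binding motifs and measurably distort the
pooled allele PWMs (anchor entries shift by ~0.04 at 5% contamination;
with the trash class the shift is below 0.01). Peptides whose maximum
responsibility falls on the trash component are excluded from all motif
peptide sets.

**Number of motifs.** Stage 1 fixes K to the number of distinct HLA-A
plus HLA-B alleles (these loci dominate expression); stage 2 selects K
over 1..(genotype size + 1) by BIC with
ν = (K−1) + K·L·19 free parameters (the trash weight adds one). The
BIC penalty per motif component is 171·ln(n)+..., which at desk-scale n
is severe — this interacts with the synthetic-data design below. BIC
minimization is the selection rule throughout; all candidate BICs are
reported on the returned model.

## Motif comparison

Motifs are compared by the length-normalized squared Euclidean distance
D² = (1/L)·Σ_{i,A} (M[i,A] − M'[i,A])², with motifs of different
lengths never compared. Two motifs are "similar" when D² ≤ T with
T = 0.078 (a boundary hit counts as similar; the convention is fixed
for determinism). The BLiC column score is also provided: per position,
the log Bayes factor of a common Dirichlet(α) source (α_j = 1) against
independent sources, plus a common-source-against-background term; the
multinomial coefficients are omitted uniformly in all three terms (they
cancel only pairwise; omitting them everywhere keeps the score a
consistent ranking device, which is how it is used). Euclidean distance
is the working metric of the pipeline; BLiC is used for significance
screening.

Empirical P-values of a motif pair (m_i, m_j) rank their similarity
against the similarities of m_i to every motif of a reference
compendium (the allele m_i is annotated to excluded), with the add-one
estimator P = (1 + #{at least as similar}) / (1 + N_ref) so P is never
zero. With a 107-entry compendium the smallest attainable P is
1/108 ≈ 0.0093.

## Allele annotation from genotype co-occurrence

Each pass applies four rules, with inconsistency elimination after each:

1. **Shared allele.** For an un-annotated allele carried by ≥2 samples,
   search for a selection of exactly one un-annotated motif per sharing
   sample with all pairwise D² ≤ T (a cross-sample clique). Only a
   *unique* clique annotates; two candidate cliques (e.g. two alleles
   that always co-occur) defer. Two alleles with identical sample
   incidence are unidentifiable by co-occurrence in principle; the
   annotation correctly leaves them pending rather than guessing.
2. **All-but-one.** If sample A carries exactly one allele that sample
   B lacks and exactly one of A's motifs has no counterpart within T in
   B, that motif maps to the extra allele.
3. **Last remaining.** A sample with exactly one un-annotated motif and
   one un-annotated allele pairs them.
4. **Propagation.** An allele already annotated elsewhere is recognized
   in further samples when exactly one un-annotated motif is within T
   of *all* of its annotated motifs (the strict all-anchors variant).

Elimination: while two motifs mapped to one allele are farther than T
apart, the motif with the largest mean distance to the others is
returned to the un-annotated pool; exact ties (in particular a mutually
inconsistent pair) drop all tied motifs. Passes repeat until none adds
an annotation; termination is bounded by the total motif count.

The semi-supervised pass seeds annotations from a reference motif
library for alleles supported by more than 20 ligands: in each sample
an un-annotated allele is matched when exactly one un-annotated motif
is within T of its reference PWM; the unsupervised rules then re-run to
exploit the new anchors (this is how an allele absent from the library
can still be resolved by rule 3 afterwards).

Per-allele training pools are the deduplicated union of assigned
peptides over all motifs annotated to the allele, kept separate per
peptide length. No binding-affinity predictor is consulted anywhere in
annotation.

## Ligand predictor

Per allele and length, a PWM is built from the pooled peptides with
substitution pseudocounts: per position, p = (α·f + β·g)/(α + β) with f
the observed frequencies, g = f·ρ, where ρ[B][A] = P(A|B) is derived
from the published BLOSUM62 target (joint) frequency table, α = n − 1
and β = 200. At n = 201 the PWM is exactly (f+g)/2; at n = 1 it is pure
pseudocounts.

The expected MS residue background q is estimated from non-anchor
positions P4–P7 of 9-mer pools, excluding the twelve alleles with known
specificity at those positions, averaged unweighted across alleles;
zero entries are floored at 1e-4 and the vector renormalized (cysteine
under-detection makes exact zeros reachable). A peptide is scored
S = (1/N)·Σ_i ln(p[i][x_i]/q[x_i]) (natural log; rankings are
base-invariant), a sample-level prediction takes the maximum S over the
sample's alleles, and an empirical P-value compares S with the
max-over-allele scores of random proteome peptides (default 100,000;
add-one estimator). Candidate neo-antigens are all 9/10-mer windows
covering a missense site with the alternate residue substituted,
deduplicated across transcripts, ranked by S with lexicographic
tie-breaks; HLA-C models are excluded from ranking by default (low
expression), re-enabled by a flag. Benchmarks report AUC (rank
statistic, ties ½) and PP1%, the fraction of positives among the top
ceil(1%·n) predictions, which at 99-fold decoy excess equals both
precision and recall. A tryptic-signature filter (drop C-terminal R/K,
except for HLA-A03:01 and A31:01) is available for MS training data
hygiene.

## Synthetic data: what it emulates and what it does not

The generator produces per-allele truth PWMs with one anchor residue at
P2 and one at the C-terminal position (anchor probability 0.9),
non-anchor columns drawn from Dirichlet(100 · background) around
human-proteome-like frequencies, peptides sampled from those PWMs with
cysteine detection multiplied by 0.2 (the bias lives in the data, not
the truth), optional uniform-residue contaminants, reference libraries
built the way ligand-derived compendia are (frequency counts plus a
flat count of 1), and random proteomes with missense tables, optionally
with a planted neo-antigen whose mutated window is a draw from a chosen
allele's motif.

Three generator choices deserve their reasoning on record:

* **Distinct anchor residues per position.** Anchor residues are drawn
  without replacement at P2 and (independently) at PΩ, so any two
  alleles differ at both anchors. Shared single anchors (common in
  reality, e.g. among B07/C07 family motifs) make the per-sample
  mixture nearly unidentifiable at desk-scale n under the strict BIC
  above; the preset is designed to test the co-occurrence logic, not
  the hardest limits of model selection. A "confusable pair" option
  generates two alleles within the similarity threshold for tests that
  need ambiguity.
* **Residual non-anchor specificity.** With exactly-background middle
  positions, a K-component mixture differs from a (K−1)-component one
  only at two of nine positions, and the BIC penalty (171·ln n per
  component) exceeds the likelihood gain at realistic sample sizes.
  Real motifs carry weak middle-position preferences (twelve alleles
  are excluded from background estimation for exactly that reason), and
  Dirichlet concentration 100 gives per-column deviations of ~0.02–0.03
  — visible in a logo only on close inspection but informative across
  seven positions.
* **Preset size.** The standard cohort is 10 samples × 3,000 9-mers
  over 15 alleles (6 A, 6 B, 3 C), within the range of real
  immunopeptidomics runs. The genotype table is designed so that all
  15 allele incidence sets are pairwise distinct (co-occurrence cannot
  distinguish alleles that always travel together) and so that the
  shared-allele, all-but-one and last-remaining rules each fire:
  B57:01 occurs only in S4, whose genotype is S3's plus that allele;
  C07:02 occurs only in S10.

What passing on this preset shows: the EM + BIC machinery recovers
well-separated motifs at realistic depth, the co-occurrence rules are
sound (no false annotation across 20 seeded cohorts) and complete on an
identifiable design, and the predictor separates motif-conforming
ligands from proteome decoys. What it does not show: performance on
real spectra (no retention time, detectability or search-engine FDR
effects), on motifs that genuinely share anchors, on strongly imbalanced
allele expression (mixing weights default to uniform; imbalance is a
config away but no quantitative values are emulated), or on 11–14-mers,
which are ingested and grouped but not deconvoluted.

## Validation harness and problem sizes

The scripted experiments run at desk scale: contaminant robustness
injects 5% uniform peptides into the *same* clean lists (so the
comparison isolates contamination from sampling noise); the threshold
sweep re-annotates one fixed catalog over T ∈ 0.01..0.14; sub-sampling
convergence pools motifs over 1/2/4/8 samples across 10 seeds, matching
motifs to alleles with the ground-truth oracle because a single sample
supports no co-occurrence annotation (the experiment measures
estimation error, not annotation reach); leave-one-sample-out retrains
the predictor without the evaluated sample's peptidome and re-ranks a
planted neo-antigen among ~1,800 candidates from 200 mutations (the
planted peptide carries the allele's anchor residues, as a
mass-spectrometry-confirmed neo-antigen must; its held-out rank tracks
the full-cohort rank closely, while the absolute top-1% cutoff retains
some draw-to-draw variability in the planted peptide's non-anchor
residues). Cohort-
scale runs use 3 EM restarts (single-sample operations default to 5).
Empirical P-value backgrounds use 20,000 proteome peptides in the desk-
scale experiments and 100,000 by default in the CLI.

## Numerical choices and degenerate inputs

Log-space throughout EM and scoring, with probabilities floored at
1e-300 before logs; PWM rows validated to sum to 1 within 1e-9 (file
round-trips are exact to 1e-12); assignment and ranking ties break to
the lowest index / lexicographically smallest peptide; K = 1 without a
trash component is computed in closed form (no EM); empty peptide
files, duplicate sample ids, >2 alleles per locus, mixed-length PWM
comparisons and zero-count BLiC columns raise explicit errors rather
than propagating NaNs.

## Known limitations

Only 9- and 10-mers are modelled (no multi-length joint model, no
length-rescaling of scores beyond the shared empirical-P scale);
annotation cannot separate alleles with identical sample incidence or
(in one sample) motifs more similar than T; PP1% against 99-fold decoys
is bounded above by the anchor conformity of the positives — with
anchor probability 0.9, roughly 19% of true ligands lack a canonical
anchor residue and rank below anchor-carrying decoys, capping PP1% near
0.8 regardless of the scorer; the BLiC normalization follows the
documented convention rather than any particular reference
implementation; gene expression is not used in neo-antigen ranking.
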