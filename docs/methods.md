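# Methods

## Substitution classification

The unit of classification is the *unordered* amino-acid pair: pairwise
alignments do not reveal which lineage incurred a mutation, so effects are
pooled over both directions (Ala→Val with Val→Ala). Only pairs that are
direct neighbors in the standard genetic code — some codon of one residue
one nucleotide substitution away from some codon of the other — are
classifiable; there are exactly 75 such pairs. All other pairs raise an
error rather than receiving a guessed label, and codon changes through stop
codons never contribute pairs.

A pair is **non-conservative (NC)** when the fraction of predicted
per-mutation stability changes with ΔΔG < −2 kcal/mol (strict) is at least
20%, and **conservative (C)** otherwise; "less than 20% destabilizing"
defines C, so a fraction of exactly 0.20 is NC. The bundled canonical table
(15 NC, 60 C pairs) was derived from large-scale stability predictions over
the yeast cytosolic proteome and is validated here in two ways: it exactly
partitions the 75 neighbor pairs, and no NC pair has a positive BLOSUM62
score. BLOSUM62 is bundled as a static half-bit table to keep this check
independent of external matrix files; a test cross-checks every entry
against Biopython's copy. `derive_classification` re-derives a
classification from any ΔΔG record table with the same rules; neighbor
pairs with no records are returned as "uncovered", never silently
defaulted.

## Extended count model

Per sense codon, each position contributes a synonymous-site fraction equal
to the share of its single-nucleotide *sense* mutants that are synonymous.
Stop mutants are excluded from both numerator and denominator, so s + n = 3
exactly per codon; the nonsynonymous share splits into C and NC by
classifying each mutant pair, so c + nc = n exactly. Site totals are summed
over valid columns per sequence and averaged across the two sequences
(standard NG86 convention; the alternative of summing differs only by a
factor that cancels in the ratios).

Differences between codons that differ at k positions are averaged over all
k! orderings of the positions. Pathways traversing a stop codon are
discarded; in the rare case that every pathway is blocked (possible only
for 2- and 3-position differences), all pathways are retained but steps
into or out of a stop contribute to no class, which undercounts total
differences for those codon pairs — a documented degenerate fallback.
Counts are exact rationals internally, so the conservation identities hold
exactly, not to tolerance.

Each class rate is Jukes–Cantor corrected independently,
d = −(3/4)·ln(1 − 4p/3), with saturation (p ≥ 3/4) raised as an error
carrying the class label. ω = dN/dS and λ = dNC/dC are flagged undefined
(None) when the denominator rate is zero rather than reported as 0 or
infinity. The count model carries no transition/transversion parameter.

## Extended ML model

A reversible Markov process on the 61 sense codons. For codons differing at
one position, the unscaled rate to codon j is π_j times κ for a transition,
times γ for a nonsynonymous (conservative) change, times an additional λ
for a non-conservative change; multi-position changes have rate 0. Setting
λ = 1 collapses the model onto the standard ω-style codon model with
γ ≡ ω, which `fit_standard_omega` exploits. Q is rescaled so
−Σ π_i q_ii = 1: t is expected substitutions per codon, comparable across
pairs. Detailed balance π_i q_ij = π_j q_ji holds by construction (π_j
target frequencies with symmetric multipliers), so the two sequences can be
modelled at total separation t — equivalent to two branches of t/2 from an
unobserved ancestor — and the likelihood ℓ = Σ n_ij log(π_i p_ij(t)) is
invariant to swapping the sequences. n_ij is not symmetrized (immaterial
under reversibility).

π defaults to F61-style frequencies pooled from the two input sequences
with pseudocount 0.5 per sense codon (guaranteeing positivity); a genome
codon-composition table can be supplied instead, and tables assigning mass
to stop codons are rejected.

Optimization is Nelder–Mead simplex on log-transformed parameters
(unconstrained; log-parameters clipped to [ln 1e-8, ln 1e5] inside the
objective to avoid overflow). Multi-start: the first start is seeded from
count-model estimates (t from total corrected substitutions per codon, γ
from ω, λ from count λ), the rest jittered with a fixed-seed Gaussian
(SD 0.5 in log space). Ties across starts break by highest ℓ, then lowest
t. Parameters ending at bounds (t ≤ 1e-6, ratios outside [1e-4, 1e4]) are
flagged in `notes`; identical sequences legitimately drive t to its floor.
P(t) = expm(Qt) via SciPy's matrix exponential, clipped at 0 from below
before logs. The data-sufficiency screen ℓ_max < −1000 used in large-scale
ortholog studies is available as a post-fit filter, not a hard failure.

## Simulators

`simulate_codon_pair` draws ancestor codons i.i.d. from π and samples
endpoint states exactly from P(t/2) per lineage (`ancestor_split`) or P(t)
for one lineage (`single_branch`); the two modes agree in distribution
under reversibility, which a test checks. No within-branch path is
simulated because the pairwise likelihood only sees endpoints. Default π is
uniform over the 61 sense codons unless supplied. Every generator takes a
mandatory seed and is bit-reproducible given it; replicate seeds in
experiments are drawn from a single seeded stream.

`synthetic_ddg_table` plants a destabilizing fraction per pair:
round(fraction · n) records fall strictly below the −2 kcal/mol cutoff and
the rest at or above it, centred ±2 kcal/mol from the cutoff with Gaussian
jitter (default SD 0.5) and nudged to respect the planted side, so
round-trips through `derive_classification` are exact by construction at
adequate n. Records alternate between the two mutation directions. The real
predictor output this emulates was sampled across a proteome (~10% of all
possible mutations per protein); per-pair record counts stand in for that
sampling and both uniform-per-protein and per-site interpretations collapse
to the same pooled per-pair fractions used downstream.

`synthetic_network_pair` builds two Erdős–Rényi graphs (default 200 nodes,
density 0.04) sharing a one-to-one ortholog core (default 70% of nodes);
planted re-wired nodes (default 5) gain extra edges (default 12) to
species-specific nodes in both networks. Real interactomes are not
Erdős–Rényi (no degree heavy tails, no modules), so these fixtures validate
the *selection machinery* — decile thresholds, consensus intersection —
not biological claims about hubs or bottlenecks.

## Network statistics

Graphs are undirected, unweighted, de-duplicated, self-loops dropped.
Betweenness is Brandes' exact algorithm, unnormalized — only rank deciles
are consumed. Hubs are the top 10% by degree and non-hubs the bottom 10%
(quantile thresholds, ties included on the qualifying side; all-equal
inputs return a degeneracy flag); bottlenecks are the top betweenness
decile minus hubs; non-bottlenecks the bottom betweenness decile; isolated
nodes are retained with degree 0. The re-wired consensus intersects, via
the ortholog map, each network's top decile of non-orthologous-neighbor
counts, with the extra requirement that the count be positive (a node with
no species-specific partners is never re-wired, even when every count is
zero). Alternative percentile cuts (5%, 1%) are parameters, not separate
code paths. SMD is Cohen's d with pooled (n−1) SD; distribution comparisons
use the two-sided Wilcoxon rank-sum test, 2×2 tables Fisher's exact test.

## Validation scope and known limitations

The test suite and `scripts/acceptance.py` validate the machinery on
synthetic data only: oracle equivalence of pathway counting over all
61×61 codon pairs, an independent plain-NG86 reference reproduced to 1e-6,
Markov-model identities to 1e-8, parameter recovery and ML/count λ
concordance (Spearman ≥ 0.99 observed) on simulated panels at
(t=0.3, κ=2, γ=0.3, λ=0.5) with 500-codon pairs, and exact classification
round-trips. Passing these shows the estimators are correct and mutually
consistent under the model's own assumptions; it says nothing about model
misspecification on real genomes (no indels, no among-site rate variation,
single classification for all proteins, F61 frequencies).

One quantitative limit is worth stating: at the simulation conditions above
a 500-codon pair carries only ~15 expected NC substitutions, and the Fisher
information of the pairwise likelihood caps any estimator of λ at a median
relative error of ≈ 28% (Cramér–Rao; computed numerically from the expected
per-column information). The ML estimator attains this floor — λ̂'s
observed median relative error is ≈ 29% with negligible bias — so
single-pair λ estimates at moderate divergence are intrinsically noisy, and
analyses should aggregate over many pairs (or require a minimum NC count,
as the ≥ 3-NC curation screen does). t̂ and κ̂ recover to ≈ 6% and ≈ 11–16%
median relative error under the same conditions. Biopython's NG86
implementation, used as an external cross-check, differs from this
package's site convention in its handling of stop-codon mutants and agrees
with our ω only to within a few percent; the 1e-6 regression check
therefore uses a convention-matched independent reference implementation.
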