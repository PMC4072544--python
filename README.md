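# ncrates

Estimation of the evolutionary rate ratio **λ = dNC/dC** — the relative rate
of *non-conservative* (likely destabilizing) versus *conservative*
amino-acid substitutions — from pairs of aligned orthologous coding
sequences.

## The problem

The classical rate ratio ω = dN/dS lumps every amino-acid change into one
nonsynonymous rate dN, and so cannot distinguish substitutions that barely
perturb a protein (e.g. Leu→Ile) from those likely to destabilize its fold.
`ncrates` splits dN into the rate of conservative substitutions **dC** and
the rate of non-conservative substitutions **dNC**, where the C/NC label of
an amino-acid pair reflects how often mutations between the two residues are
predicted highly destabilizing (ΔΔG < −2 kcal/mol in at least 20% of sampled
sequence contexts). λ = dNC/dC then measures the relative partitioning of
accepted amino-acid changes into more- and less-likely-destabilizing
classes, orthogonally to ω. Only amino-acid pairs that are direct neighbors
in the genetic code (reachable by one nucleotide substitution) carry a
label; the bundled canonical classification covers all 75 such pairs (15 NC,
60 C) and is consistent with BLOSUM62 in that no NC pair has a positive
score.

Two independent estimators are provided:

* an **extended count model** (Nei–Gojobori style): fractional S/N/C/NC site
  opportunities per codon, pathway-averaged difference counts, and per-class
  Jukes–Cantor multiple-hit correction;
* an **extended maximum-likelihood model**: a reversible GY94-style Markov
  process on the 61 sense codons with rate q_ij = π_j · κ^[transition] ·
  γ^[nonsynonymous] · λ^[non-conservative] for single-nucleotide changes,
  fitted by simplex search over (t, κ, γ, λ) on pairs of sequences at total
  separation t.

The package also ships simulators with known ground truth (codon pairs,
predicted-ΔΔG tables, paired interaction networks with planted re-wiring),
alignment curation screens, and the network statistics used to study hubs,
bottlenecks and re-wired proteins (degree, betweenness, non-orthologous
neighbor counts, Wilcoxon/Fisher tests with standardized mean differences).

## Worked example

Simulate a 500-codon ortholog pair under purifying selection against
non-conservative changes (t = 0.3, κ = 2, γ = 0.3, λ = 0.5) and estimate the
rates with both models:

```python
from ncrates import (MLParameters, SimulationSpec, simulate_codon_pair,
                     estimate_rates_count, fit_ml)

params = MLParameters(t=0.3, kappa=2.0, gamma=0.3, lam=0.5)
aln = simulate_codon_pair(SimulationSpec(length=500, params=params, seed=7))

rates = estimate_rates_count(aln)
print(f"count: dS={rates.dS:.4f} dN={rates.dN:.4f} dC={rates.dC:.4f} "
      f"dNC={rates.dNC:.4f} omega={rates.omega:.3f} lambda={rates.lam:.3f}")

fit = fit_ml(aln, n_starts=2, seed=7)
p = fit.params
print(f"ml:    t={p.t:.3f} kappa={p.kappa:.3f} gamma={p.gamma:.3f} "
      f"lambda={p.lam:.3f} loglik={fit.loglik:.1f}")
```

Output:

```
count: dS=0.2397 dN=0.0516 dC=0.0589 dNC=0.0256 omega=0.215 lambda=0.434
ml:    t=0.300 kappa=1.609 gamma=0.266 lambda=0.423 loglik=-2587.5
```

Both estimators see dNC < dC (the planted purifying selection on
destabilizing changes) and agree on λ ≈ 0.43 against a true value of 0.5 —
within the sampling error expected from the ~15 non-conservative
substitutions a pair of this length and divergence contains.

A command-line interface mirrors the library:

```sh
ncrates simulate pair --length 500 --t 0.3 --kappa 2 --gamma 0.3 \
    --lambda 0.5 --seed 7 --out pair.fasta
ncrates estimate --manifest pairs.tsv --classification table1 \
    --method both --out rates.tsv
ncrates classify derive --ddg ddg.tsv --out cls.tsv
ncrates network rewired --edges-a a.tsv --edges-b b.tsv --orthologs orth.tsv
```

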