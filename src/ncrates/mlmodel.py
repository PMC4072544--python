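"""Pairwise maximum-likelihood codon model with conservative/non-conservative
rate splitting.

The model is a reversible 61-state Markov process on sense codons.  For
codons i, j differing at exactly one nucleotide the instantaneous rate is

    q_ij = pi_j                                  synonymous transversion
    q_ij = pi_j * kappa                          synonymous transition
    q_ij = pi_j * gamma                          conservative transversion
    q_ij = pi_j * gamma * kappa                  conservative transition
    q_ij = pi_j * gamma * lam                    non-conservative transversion
    q_ij = pi_j * gamma * lam * kappa            non-conservative transition

and 0 for multi-nucleotide differences.  ``gamma`` is the conservative
nonsynonymous/synonymous rate ratio and ``lam`` the non-conservative /
conservative rate ratio, so at lam = 1 the model collapses onto the standard
omega-style codon model (gamma = omega).  Q is normalized so the expected
number of substitutions per codon per unit time is 1, which fixes the scale
of the divergence time t.

Two sequences are modelled at total separation t under reversibility
(equivalently, two branches of t/2 from an unobserved ancestor), giving the
pairwise log-likelihood  l = sum_ij n_ij log(pi_i p_ij(t))  over the matrix
of aligned codon-pair counts n_ij.  Optimization is a derivative-free
simplex search on log-transformed parameters with multiple starts, the first
seeded from count-model estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
import scipy.linalg
import scipy.optimize

from .classification import (
    GeneticCode,
    SubstitutionClassification,
    is_transition,
    standard_genetic_code,
    table1_classification,
)

__all__ = [
    "CodonFrequencies",
    "MLParameters",
    "RateMatrix",
    "MLFit",
    "estimate_codon_frequencies",
    "build_rate_matrix",
    "transition_matrix",
    "pair_counts",
    "pair_log_likelihood",
    "fit_ml",
    "fit_standard_omega",
]

_LOG_LOWER = math.log(1e-8)
_LOG_UPPER = math.log(1e5)
T_LOWER_BOUND = 1e-6
RATIO_LOWER_BOUND = 1e-4
RATIO_UPPER_BOUND = 1e4


@dataclass(frozen=True)
class CodonFrequencies:
    """Equilibrium frequencies over the 61 sense codons (F61-style)."""

    codons: tuple[str, ...]
    pi: np.ndarray

    def __post_init__(self) -> None:
        if len(self.codons) != len(self.pi):
            raise ValueError("codon list and frequency vector lengths differ")
        if np.any(self.pi <= 0):
            raise ValueError("all codon frequencies must be positive")
        if not math.isclose(float(self.pi.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("codon frequencies must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.codons, map(float, self.pi)))


@dataclass(frozen=True)
class MLParameters:
    """Parameters of the extended pairwise codon model.

    t:      divergence time in expected substitutions per codon (both
            lineages combined).
    kappa:  transition/transversion rate multiplier.
    gamma:  conservative-nonsynonymous/synonymous rate ratio.
    lam:    non-conservative/conservative rate ratio (the parameter of
            interest; 1 collapses to the standard omega model).
    """

    t: float
    kappa: float
    gamma: float
    lam: float

    def __post_init__(self) -> None:
        for name in ("t", "kappa", "gamma", "lam"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")


@dataclass(frozen=True)
class RateMatrix:
    """Scaled instantaneous rate matrix over sense codons."""

    codons: tuple[str, ...]
    q: np.ndarray


@dataclass(frozen=True)
class MLFit:
    """Result of a maximum-likelihood fit."""

    params: MLParameters
    loglik: float
    converged: bool
    n_starts: int
    pi: CodonFrequencies
    notes: tuple[str, ...] = field(default_factory=tuple)
    omega: float | None = None


# --------------------------------------------------------------------------
# Codon frequencies
# --------------------------------------------------------------------------


def estimate_codon_frequencies(
    source: Iterable[str] | Mapping[str, float],
    pseudocount: float = 0.5,
    code: GeneticCode | None = None,
) -> CodonFrequencies:
    """F61-style codon frequencies from sequences or a codon count table.

    ``source`` is either an iterable of coding sequences (strings, length a
    multiple of 3; codon counts are pooled) or a mapping codon -> count or
    frequency (e.g. an average genome codon composition).  Each sense codon
    receives ``pseudocount`` so all frequencies are strictly positive.
    """
    code = code or standard_genetic_code()
    codons = code.sense_codons
    counts = {c: float(pseudocount) for c in codons}
    if isinstance(source, Mapping):
        for codon, weight in source.items():
            codon = codon.upper()
            if codon not in counts:
                if code.is_stop(codon) and weight > 0:
                    raise ValueError(f"codon table assigns mass to stop codon {codon}")
                continue
            counts[codon] += float(weight)
    else:
        for seq in source:
            seq = seq.upper().replace("U", "T")
            for i in range(0, len(seq) - len(seq) % 3, 3):
                codon = seq[i : i + 3]
                if codon in counts:
                    counts[codon] += 1.0
    pi = np.array([counts[c] for c in codons], dtype=float)
    pi /= pi.sum()
    return CodonFrequencies(codons=codons, pi=pi)


# --------------------------------------------------------------------------
# Model structure and rate matrix
# --------------------------------------------------------------------------


@lru_cache(maxsize=16)
def _model_structure(code_key: int, cls_key: int, code: GeneticCode, cls: SubstitutionClassification):
    """Precompute the sparsity structure of Q for a code/classification pair.

    Returns index arrays over all ordered single-nucleotide sense-codon pairs
    plus boolean masks for transition, nonsynonymous and non-conservative
    changes.  Cached on object identity (both inputs are immutable).
    """
    codons = code.sense_codons
    index = {c: k for k, c in enumerate(codons)}
    ii, jj, ts, ns, nc = [], [], [], [], []
    for i, ci in enumerate(codons):
        aa_i = code.translate(ci)
        for pos in range(3):
            for base in "ACGT":
                if base == ci[pos]:
                    continue
                cj = ci[:pos] + base + ci[pos + 1 :]
                j = index.get(cj)
                if j is None:
                    continue
                aa_j = code.translate(cj)
                nonsyn = aa_i != aa_j
                ii.append(i)
                jj.append(j)
                ts.append(is_transition(ci[pos], base))
                ns.append(nonsyn)
                nc.append(nonsyn and cls.is_nc(aa_i, aa_j))
    return (
        codons,
        np.array(ii),
        np.array(jj),
        np.array(ts, dtype=bool),
        np.array(ns, dtype=bool),
        np.array(nc, dtype=bool),
    )


def build_rate_matrix(
    params: MLParameters,
    pi: CodonFrequencies,
    cls: SubstitutionClassification | None = None,
    code: GeneticCode | None = None,
) -> RateMatrix:
    """Build the scaled 61x61 rate matrix Q for the given parameters.

    Rows sum to zero; detailed balance pi_i q_ij = pi_j q_ji holds by
    construction; the matrix is rescaled so -sum_i pi_i q_ii = 1.
    """
    code = code or standard_genetic_code()
    cls = cls or table1_classification()
    codons, ii, jj, ts, ns, nc = _model_structure(id(code), id(cls), code, cls)
    if tuple(pi.codons) != tuple(codons):
        raise ValueError("codon frequency vector does not match the model's codon order")
    n = len(codons)
    rates = pi.pi[jj].copy()
    rates[ts] *= params.kappa
    rates[ns] *= params.gamma
    rates[nc] *= params.lam
    q = np.zeros((n, n))
    q[ii, jj] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -float(np.dot(pi.pi, np.diag(q)))
    if scale <= 0 or not np.isfinite(scale):
        raise ValueError("degenerate rate matrix (non-positive total rate)")
    return RateMatrix(codons=codons, q=q / scale)


def transition_matrix(Q: RateMatrix, t: float) -> np.ndarray:
    """Transition probability matrix P = exp(Q t); rows sum to 1."""
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    if not np.all(np.isfinite(Q.q)):
        raise ValueError("non-finite entries in rate matrix")
    P = scipy.linalg.expm(Q.q * t)
    return np.clip(P, 0.0, None)


# --------------------------------------------------------------------------
# Likelihood
# --------------------------------------------------------------------------


def pair_counts(aln, code: GeneticCode | None = None) -> np.ndarray:
    """61x61 matrix of aligned codon-pair counts n_ij over valid columns."""
    code = code or standard_genetic_code()
    index = {c: k for k, c in enumerate(code.sense_codons)}
    n = np.zeros((len(index), len(index)), dtype=np.int64)
    for a, b in aln.valid_codon_pairs():
        n[index[a], index[b]] += 1
    return n


def pair_log_likelihood(
    n: np.ndarray,
    params: MLParameters,
    pi: CodonFrequencies,
    cls: SubstitutionClassification | None = None,
    code: GeneticCode | None = None,
) -> float:
    """Pairwise log-likelihood  l = sum_ij n_ij log(pi_i p_ij(t))."""
    Q = build_rate_matrix(params, pi, cls=cls, code=code)
    P = transition_matrix(Q, params.t)
    joint = pi.pi[:, None] * P
    mask = n > 0
    with np.errstate(divide="ignore"):
        logs = np.log(joint[mask])
    if np.any(np.isneginf(logs)):
        return -np.inf
    return float(np.sum(n[mask] * logs))


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------


def _count_seeded_start(aln, cls, code) -> tuple[float, float, float, float]:
    """Initial (t, kappa, gamma, lam) from count-model estimates."""
    from .counting import SaturationError, estimate_rates_count

    t0, kappa0, gamma0, lam0 = 0.2, 2.0, 0.3, 0.5
    try:
        rates = estimate_rates_count(aln, code=code, cls=cls)
        sites = rates.sites
        n_codons = float(sites.s_sites + sites.n_sites) / 3.0
        total_subs = rates.dS * float(sites.s_sites) + rates.dN * float(sites.n_sites)
        if n_codons > 0 and total_subs > 0:
            t0 = max(total_subs / n_codons, 2 * T_LOWER_BOUND)
        if rates.omega is not None and rates.omega > 0:
            gamma0 = rates.omega
        if rates.lam is not None and rates.lam > 0:
            lam0 = rates.lam
    except (SaturationError, ValueError):
        pass
    return t0, kappa0, gamma0, lam0


def _maximize(objective, x0_list, tol):
    best = None
    n_converged = 0
    for x0 in x0_list:
        res = scipy.optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": tol**0.5, "fatol": tol, "maxiter": 4000, "maxfev": 6000},
        )
        if res.success:
            n_converged += 1
        # ties across starts: highest loglik, then lowest t (first component)
        key = (-res.fun, -res.x[0])
        if best is None or key > best[0]:
            best = (key, res)
    return best[1], n_converged


def fit_ml(
    aln,
    cls: SubstitutionClassification | None = None,
    code: GeneticCode | None = None,
    pi: CodonFrequencies | None = None,
    n_starts: int = 3,
    tol: float = 1e-8,
    seed: int = 0,
) -> MLFit:
    """Fit (t, kappa, gamma, lam) by maximum likelihood on a codon pair.

    ``pi`` defaults to F61-style frequencies pooled from the two aligned
    sequences with pseudocount 0.5.  The search runs in log-parameter space
    with ``n_starts`` simplex starts: the first seeded from count-model
    estimates, the rest jittered deterministically from ``seed``.  Parameters
    at bounds (t below 1e-6, ratios outside [1e-4, 1e4]) are flagged in
    ``notes``, as is failure of every start to converge.
    """
    code = code or standard_genetic_code()
    cls = cls or table1_classification()
    if pi is None:
        pi = estimate_codon_frequencies(
            ["".join(c for c, _ in aln.valid_codon_pairs()),
             "".join(c for _, c in aln.valid_codon_pairs())],
            code=code,
        )
    n = pair_counts(aln, code=code)
    if n.sum() == 0:
        raise ValueError(f"alignment {aln.id!r} has no valid codon columns")

    def objective(x):
        x = np.clip(x, _LOG_LOWER, _LOG_UPPER)
        t, kappa, gamma, lam = np.exp(x)
        params = MLParameters(t=t, kappa=kappa, gamma=gamma, lam=lam)
        ll = pair_log_likelihood(n, params, pi, cls=cls, code=code)
        return math.inf if ll == -math.inf else -ll

    start = np.log(_count_seeded_start(aln, cls, code))
    rng = np.random.default_rng(seed)
    starts = [start] + [start + rng.normal(0.0, 0.5, size=4) for _ in range(n_starts - 1)]
    res, n_converged = _maximize(objective, starts, tol)
    x = np.clip(res.x, _LOG_LOWER, _LOG_UPPER)
    t, kappa, gamma, lam = map(float, np.exp(x))
    params = MLParameters(t=t, kappa=kappa, gamma=gamma, lam=lam)

    notes = []
    if t <= T_LOWER_BOUND:
        notes.append("t_at_lower_bound")
    for name, value in (("kappa", kappa), ("gamma", gamma), ("lam", lam)):
        if value <= RATIO_LOWER_BOUND:
            notes.append(f"{name}_at_lower_bound")
        elif value >= RATIO_UPPER_BOUND:
            notes.append(f"{name}_at_upper_bound")
    if n_converged == 0:
        notes.append("no_start_converged")

    return MLFit(
        params=params,
        loglik=-float(res.fun),
        converged=n_converged > 0,
        n_starts=len(starts),
        pi=pi,
        notes=tuple(notes),
    )


def fit_standard_omega(
    aln,
    code: GeneticCode | None = None,
    pi: CodonFrequencies | None = None,
    n_starts: int = 3,
    tol: float = 1e-8,
    seed: int = 0,
) -> MLFit:
    """Standard pairwise omega fit: lam fixed to 1, so gamma plays omega's role.

    Uses the same machinery as :func:`fit_ml` with the non-conservative
    multiplier disabled; the fitted gamma is reported as ``omega``.
    """
    code = code or standard_genetic_code()
    cls = table1_classification()  # irrelevant at lam = 1, kept for structure reuse
    if pi is None:
        pi = estimate_codon_frequencies(
            ["".join(c for c, _ in aln.valid_codon_pairs()),
             "".join(c for _, c in aln.valid_codon_pairs())],
            code=code,
        )
    n = pair_counts(aln, code=code)
    if n.sum() == 0:
        raise ValueError(f"alignment {aln.id!r} has no valid codon columns")

    def objective(x):
        x = np.clip(x, _LOG_LOWER, _LOG_UPPER)
        t, kappa, gamma = np.exp(x)
        params = MLParameters(t=t, kappa=kappa, gamma=gamma, lam=1.0)
        ll = pair_log_likelihood(n, params, pi, cls=cls, code=code)
        return math.inf if ll == -math.inf else -ll

    t0, kappa0, gamma0, _ = _count_seeded_start(aln, cls, code)
    start = np.log([t0, kappa0, gamma0])
    rng = np.random.default_rng(seed)
    starts = [start] + [start + rng.normal(0.0, 0.5, size=3) for _ in range(n_starts - 1)]
    res, n_converged = _maximize(objective, starts, tol)
    x = np.clip(res.x, _LOG_LOWER, _LOG_UPPER)
    t, kappa, gamma = map(float, np.exp(x))
    params = MLParameters(t=t, kappa=kappa, gamma=gamma, lam=1.0)

    notes = []
    if t <= T_LOWER_BOUND:
        notes.append("t_at_lower_bound")
    for name, value in (("kappa", kappa), ("omega", gamma)):
        if value <= RATIO_LOWER_BOUND:
            notes.append(f"{name}_at_lower_bound")
        elif value >= RATIO_UPPER_BOUND:
            notes.append(f"{name}_at_upper_bound")
    if n_converged == 0:
        notes.append("no_start_converged")

    return MLFit(
        params=params,
        loglik=-float(res.fun),
        converged=n_converged > 0,
        n_starts=len(starts),
        pi=pi,
        notes=tuple(notes),
        omega=gamma,
    )
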