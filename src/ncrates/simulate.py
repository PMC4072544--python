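"""Synthetic data generators with known ground truth.

Three generators feed the validation harness:

* codon-pair alignments evolved under the extended codon model (ancestor
  drawn from pi, two lineages evolved for t/2 each, or one lineage for t —
  equivalent under reversibility);
* per-mutation predicted-stability (ddG) tables with planted per-pair
  destabilizing fractions, emulating the output of a stability predictor;
* paired protein-interaction networks sharing an ortholog core, with planted
  re-wired nodes that carry extra species-specific interactions.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classification import (
    DdgRecord,
    GeneticCode,
    SubstitutionClassification,
    standard_genetic_code,
    table1_classification,
)
from .mlmodel import (
    CodonFrequencies,
    MLParameters,
    build_rate_matrix,
    transition_matrix,
)
from .seqio import CodonPairAlignment

__all__ = [
    "SimulationSpec",
    "uniform_codon_frequencies",
    "simulate_codon_pair",
    "parameter_recovery_experiment",
    "synthetic_ddg_table",
    "synthetic_network_pair",
]


def uniform_codon_frequencies(code: GeneticCode | None = None) -> CodonFrequencies:
    code = code or standard_genetic_code()
    n = len(code.sense_codons)
    return CodonFrequencies(codons=code.sense_codons, pi=np.full(n, 1.0 / n))


@dataclass(frozen=True)
class SimulationSpec:
    """Specification of one simulated codon pair."""

    length: int
    params: MLParameters
    seed: int
    pi: CodonFrequencies | None = None
    mode: str = "ancestor_split"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1 codon")
        if self.mode not in ("ancestor_split", "single_branch"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _sample_endpoints(ancestors: np.ndarray, P: np.ndarray, rng) -> np.ndarray:
    """Sample one descendant state per ancestor codon from transition matrix P."""
    out = np.empty_like(ancestors)
    # group by ancestral state so each distinct row is sampled in one call
    for state in np.unique(ancestors):
        idx = np.where(ancestors == state)[0]
        row = P[state]
        row = row / row.sum()
        out[idx] = rng.choice(len(row), size=len(idx), p=row)
    return out


def simulate_codon_pair(
    spec: SimulationSpec,
    cls: SubstitutionClassification | None = None,
    code: GeneticCode | None = None,
) -> CodonPairAlignment:
    """Simulate a gap-free aligned codon pair under the extended model.

    Ancestor codons are i.i.d. from pi.  In ``ancestor_split`` mode each
    lineage evolves independently for t/2; in ``single_branch`` mode one
    sequence is the ancestor and the other evolves for the full t.  Endpoint
    states are drawn exactly from the transition matrix (the pairwise
    likelihood only sees endpoints, so no within-branch path is simulated).
    """
    code = code or standard_genetic_code()
    cls = cls or table1_classification()
    pi = spec.pi or uniform_codon_frequencies(code)
    rng = np.random.default_rng(spec.seed)
    codons = pi.codons

    ancestors = rng.choice(len(codons), size=spec.length, p=pi.pi / pi.pi.sum())
    Q = build_rate_matrix(spec.params, pi, cls=cls, code=code)
    if spec.mode == "ancestor_split":
        P = transition_matrix(Q, spec.params.t / 2.0)
        a = _sample_endpoints(ancestors, P, rng)
        b = _sample_endpoints(ancestors, P, rng)
    else:
        P = transition_matrix(Q, spec.params.t)
        a = ancestors
        b = _sample_endpoints(ancestors, P, rng)
    return CodonPairAlignment(
        id=f"sim(seed={spec.seed})",
        codons_a=tuple(codons[k] for k in a),
        codons_b=tuple(codons[k] for k in b),
    )


# --------------------------------------------------------------------------
# Parameter recovery
# --------------------------------------------------------------------------


def parameter_recovery_experiment(
    true_params: MLParameters,
    length: int = 500,
    n_reps: int = 100,
    seed: int = 0,
    estimator: str = "ml",
    pi: CodonFrequencies | None = None,
    cls: SubstitutionClassification | None = None,
    code: GeneticCode | None = None,
    n_starts: int = 2,
):
    """Simulate-and-estimate loop; returns a per-replicate DataFrame
    and a per-parameter summary (bias, RMSE, median relative error).

    Replicate seeds are drawn from one seeded stream so replicates are
    distinct but the whole experiment is reproducible.  Estimator failures
    are recorded (``ok = False``) and excluded from summaries, never fatal.
    """
    import pandas as pd

    from .counting import estimate_rates_count
    from .mlmodel import fit_ml

    if estimator not in ("ml", "count"):
        raise ValueError(f"estimator must be 'ml' or 'count', got {estimator!r}")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    code = code or standard_genetic_code()
    cls = cls or table1_classification()
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)

    rows = []
    for rep, rep_seed in enumerate(rep_seeds):
        spec = SimulationSpec(length=length, params=true_params, seed=int(rep_seed), pi=pi)
        aln = simulate_codon_pair(spec, cls=cls, code=code)
        row: dict = {"rep": rep, "seed": int(rep_seed), "ok": True}
        try:
            if estimator == "ml":
                fit = fit_ml(aln, cls=cls, code=code, n_starts=n_starts, seed=int(rep_seed))
                row.update(
                    t=fit.params.t, kappa=fit.params.kappa,
                    gamma=fit.params.gamma, lam=fit.params.lam,
                    loglik=fit.loglik, converged=fit.converged,
                )
            else:
                rates = estimate_rates_count(aln, code=code, cls=cls)
                row.update(
                    dS=rates.dS, dN=rates.dN, dC=rates.dC, dNC=rates.dNC,
                    omega=rates.omega, lam=rates.lam,
                )
        except Exception as exc:  # noqa: BLE001 - failures are data, not fatal
            row.update(ok=False, error=f"{type(exc).__name__}: {exc}")
        rows.append(row)
    results = pd.DataFrame(rows)

    truth = {"t": true_params.t, "kappa": true_params.kappa,
             "gamma": true_params.gamma, "lam": true_params.lam}
    summary_rows = []
    ok = results[results["ok"]]
    for name, true_value in truth.items():
        if name not in ok.columns:
            continue
        est = ok[name].dropna().to_numpy(dtype=float)
        if len(est) == 0:
            continue
        summary_rows.append({
            "parameter": name,
            "true": true_value,
            "n": len(est),
            "mean": est.mean(),
            "bias": est.mean() - true_value,
            "rmse": float(np.sqrt(np.mean((est - true_value) ** 2))),
            "median_rel_error": float(np.median(np.abs(est - true_value) / true_value)),
        })
    summary = pd.DataFrame(summary_rows)
    return results, summary


# --------------------------------------------------------------------------
# ddG tables
# --------------------------------------------------------------------------


def synthetic_ddg_table(
    planted_fractions: Mapping[frozenset[str], float],
    n_per_pair: int = 200,
    noise_sd: float = 0.5,
    seed: int = 0,
    ddg_cutoff: float = -2.0,
) -> list[DdgRecord]:
    """Generate ddG records with a planted destabilizing fraction per pair.

    For each unordered pair, ``round(fraction * n_per_pair)`` records fall
    strictly below ``ddg_cutoff`` and the rest at or above it; records are
    split across both mutation directions (pooling is bidirectional
    downstream).  Values are centred 2 kcal/mol away from the cutoff on the
    planted side with Gaussian jitter, then nudged to respect the side.
    """
    rng = np.random.default_rng(seed)
    records: list[DdgRecord] = []
    margin = 1e-6
    for pair in sorted(planted_fractions, key=lambda p: tuple(sorted(p))):
        fraction = planted_fractions[pair]
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"fraction for {sorted(pair)} outside [0, 1]: {fraction}")
        aa1, aa2 = sorted(pair)
        n_dest = round(fraction * n_per_pair)
        for k in range(n_per_pair):
            destabilizing = k < n_dest
            centre = ddg_cutoff - 2.0 if destabilizing else ddg_cutoff + 2.0
            ddg = centre + noise_sd * rng.normal()
            if destabilizing:
                ddg = min(ddg, ddg_cutoff - margin)
            else:
                ddg = max(ddg, ddg_cutoff)
            wt, mut = (aa1, aa2) if k % 2 == 0 else (aa2, aa1)
            records.append(DdgRecord(
                protein_id=f"synthP{aa1}{aa2}",
                position=k + 1,
                aa_wt=wt,
                aa_mut=mut,
                ddg=float(ddg),
            ))
    return records


# --------------------------------------------------------------------------
# Paired networks with planted re-wiring
# --------------------------------------------------------------------------


def synthetic_network_pair(
    n_nodes: int = 200,
    edge_density: float = 0.04,
    ortholog_fraction: float = 0.7,
    n_planted_rewired: int = 5,
    extra_nonortholog_edges: int = 12,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], dict[str, str], list[str]]:
    """Two random PPI networks sharing an ortholog core, with planted
    re-wired nodes.

    Each species has ``n_nodes`` proteins; the first
    ``ortholog_fraction * n_nodes`` are one-to-one orthologs (map a_i <-> b_i).
    Background edges are Erdos-Renyi at ``edge_density``.  Each planted node
    (an ortholog) additionally gains ``extra_nonortholog_edges`` edges to
    species-specific partners in *both* networks, mimicking interaction
    re-wiring.  Returns (edges_a, edges_b, ortholog_map a->b, planted a-side
    node names).
    """
    rng = np.random.default_rng(seed)
    n_orth = int(round(ortholog_fraction * n_nodes))
    n_specific = n_nodes - n_orth
    if n_planted_rewired > n_orth:
        raise ValueError("more planted re-wired nodes than orthologs")
    if n_specific == 0 and n_planted_rewired > 0 and extra_nonortholog_edges > 0:
        raise ValueError("no species-specific nodes available for re-wired edges")
    if n_specific > 0 and extra_nonortholog_edges > n_specific:
        raise ValueError("extra_nonortholog_edges exceeds species-specific node count")

    def species_nodes(prefix: str) -> list[str]:
        orth = [f"{prefix}_orth{i:04d}" for i in range(n_orth)]
        specific = [f"{prefix}_spec{i:04d}" for i in range(n_specific)]
        return orth + specific

    nodes_a = species_nodes("a")
    nodes_b = species_nodes("b")
    ortholog_map = {nodes_a[i]: nodes_b[i] for i in range(n_orth)}
    planted_idx = rng.choice(n_orth, size=n_planted_rewired, replace=False) if n_planted_rewired else np.array([], dtype=int)
    planted = [nodes_a[i] for i in sorted(planted_idx)]

    def random_edges(nodes: Sequence[str]) -> set[tuple[str, str]]:
        n = len(nodes)
        iu, ju = np.triu_indices(n, k=1)
        keep = rng.random(len(iu)) < edge_density
        return {(nodes[i], nodes[j]) for i, j in zip(iu[keep], ju[keep])}

    edges_a = random_edges(nodes_a)
    edges_b = random_edges(nodes_b)
    for i in sorted(planted_idx):
        for prefix, edges, nodes in (("a", edges_a, nodes_a), ("b", edges_b, nodes_b)):
            hub = nodes[i]
            partners = rng.choice(n_specific, size=extra_nonortholog_edges, replace=False)
            for p in partners:
                u, v = sorted((hub, nodes[n_orth + p]))
                edges.add((u, v))
    return sorted(edges_a), sorted(edges_b), ortholog_map, planted
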