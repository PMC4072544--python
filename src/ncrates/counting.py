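"""Extended Nei-Gojobori count estimator.

Splits the classical synonymous/nonsynonymous accounting into four classes —
synonymous (S), nonsynonymous (N), conservative (C) and non-conservative
(NC), with C + NC = N — and estimates per-site rates dS, dN, dC, dNC from a
pairwise codon alignment:

* *sites*: for each codon, each position contributes fractional synonymous /
  nonsynonymous opportunity according to the fate of its single-nucleotide
  sense mutants; the nonsynonymous fraction is further partitioned into C and
  NC by classifying each mutant amino-acid pair.  Stop mutants are excluded
  from both numerator and denominator, so s + n = 3 exactly per codon.
* *differences*: codon pairs differing at k positions are resolved by
  averaging over all k! mutational pathways, discarding pathways that pass
  through a stop codon.
* *correction*: per-class Jukes-Cantor multiple-hit correction.

Rate ratios omega = dN/dS and lambda = dNC/dC are reported with explicit
undefined flags when a denominator is zero.  Fractional counts are kept as
exact rationals internally; the conservation identities cd + ncd = nd and
c_sites + nc_sites = n_sites therefore hold exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache

from .classification import (
    GeneticCode,
    SubstitutionClassification,
    standard_genetic_code,
    single_nt_mutants,
    table1_classification,
)

__all__ = [
    "SiteCounts",
    "DifferenceCounts",
    "CountRates",
    "SaturationError",
    "codon_site_opportunities",
    "pair_site_counts",
    "pathway_difference_counts",
    "jukes_cantor_correct",
    "estimate_rates_count",
]


@dataclass(frozen=True)
class SiteCounts:
    """Synonymous/nonsynonymous/C/NC site opportunities, in nucleotide sites."""

    s_sites: Fraction
    n_sites: Fraction
    c_sites: Fraction
    nc_sites: Fraction

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(
            self.s_sites + other.s_sites,
            self.n_sites + other.n_sites,
            self.c_sites + other.c_sites,
            self.nc_sites + other.nc_sites,
        )

    def scale(self, factor: Fraction) -> "SiteCounts":
        return SiteCounts(
            self.s_sites * factor,
            self.n_sites * factor,
            self.c_sites * factor,
            self.nc_sites * factor,
        )


ZERO_SITES = SiteCounts(Fraction(0), Fraction(0), Fraction(0), Fraction(0))


@dataclass(frozen=True)
class DifferenceCounts:
    """Pathway-averaged substitution difference counts."""

    sd: Fraction
    nd: Fraction
    cd: Fraction
    ncd: Fraction

    def __add__(self, other: "DifferenceCounts") -> "DifferenceCounts":
        return DifferenceCounts(
            self.sd + other.sd, self.nd + other.nd, self.cd + other.cd, self.ncd + other.ncd
        )


ZERO_DIFFS = DifferenceCounts(Fraction(0), Fraction(0), Fraction(0), Fraction(0))


@dataclass(frozen=True)
class CountRates:
    """Corrected per-site rates and ratios from the count model.

    ``flags`` records degenerate outcomes: ``omega_undefined`` /
    ``lambda_undefined`` when the respective denominator rate is zero, and
    ``no_X_sites`` when a class has zero site opportunity.
    """

    dS: float
    dN: float
    dC: float
    dNC: float
    omega: float | None
    lam: float | None
    sites: SiteCounts
    diffs: DifferenceCounts
    flags: tuple[str, ...] = field(default_factory=tuple)


class SaturationError(ValueError):
    """Raised when a per-site difference proportion exceeds the Jukes-Cantor domain."""

    def __init__(self, p: float, label: str):
        self.p = p
        self.label = label
        super().__init__(f"substitution class {label!r} saturated: p = {p} >= 3/4")


# --------------------------------------------------------------------------
# Sites
# --------------------------------------------------------------------------


# Cached per (codon, code, cls): the same few immutable code/classification
# instances recur across an analysis, and there are only 61 sense codons.
@lru_cache(maxsize=4096)
def codon_site_opportunities(
    codon: str, code: GeneticCode, cls: SubstitutionClassification
) -> SiteCounts:
    """Fractional S/N/C/NC site opportunities of one sense codon.

    At each position the fraction of single-nucleotide *sense* mutants that
    are synonymous counts toward s; the complement toward n, partitioned into
    c and nc by the mutant amino-acid pair.  Stop mutants are excluded from
    the denominator, so s + n = 1 per position and 3 per codon.
    """
    codon = codon.upper()
    if code.is_stop(codon):
        raise ValueError(f"stop codon has no site opportunities: {codon}")
    aa = code.translate(codon)
    s = c = nc = Fraction(0)
    for pos in range(3):
        mutants = [
            codon[:pos] + base + codon[pos + 1 :]
            for base in "ACGT"
            if base != codon[pos]
        ]
        sense = [m for m in mutants if not code.is_stop(m)]
        if not sense:  # cannot occur in the standard code
            continue
        weight = Fraction(1, len(sense))
        for m in sense:
            aa2 = code.translate(m)
            if aa2 == aa:
                s += weight
            elif cls.is_nc(aa, aa2):
                nc += weight
            else:
                c += weight
    return SiteCounts(s_sites=s, n_sites=3 - s, c_sites=c, nc_sites=nc)


def sequence_site_counts(
    codons: list[str], code: GeneticCode, cls: SubstitutionClassification
) -> SiteCounts:
    total = ZERO_SITES
    for codon in codons:
        total = total + codon_site_opportunities(codon, code, cls)
    return total


def pair_site_counts(aln, code: GeneticCode, cls: SubstitutionClassification) -> SiteCounts:
    """Average the two sequences' summed site opportunities over valid columns.

    ``aln`` is a :class:`~ncrates.seqio.CodonPairAlignment`.
    """
    cols = list(aln.valid_codon_pairs())
    if not cols:
        raise ValueError(f"alignment {aln.id!r} has no valid codon columns")
    total_a = sequence_site_counts([a for a, _ in cols], code, cls)
    total_b = sequence_site_counts([b for _, b in cols], code, cls)
    return (total_a + total_b).scale(Fraction(1, 2))


# --------------------------------------------------------------------------
# Differences
# --------------------------------------------------------------------------


def _step_class(
    codon_from: str, codon_to: str, code: GeneticCode, cls: SubstitutionClassification
) -> str:
    """Class of one single-nucleotide step between sense codons: 'S', 'C' or 'NC'."""
    aa1, aa2 = code.translate(codon_from), code.translate(codon_to)
    if aa1 == aa2:
        return "S"
    return cls.label(aa1, aa2)


@lru_cache(maxsize=8192)
def pathway_difference_counts(
    codon_a: str, codon_b: str, code: GeneticCode, cls: SubstitutionClassification
) -> DifferenceCounts:
    """Pathway-averaged difference counts between two sense codons.

    Enumerates all orderings of the differing positions (1, 2 or 6 pathways);
    pathways traversing a stop codon are discarded and the remainder averaged.
    If every pathway is blocked by a stop (possible only for 2- and 3-position
    differences), all pathways are retained but steps into or out of a stop
    contribute to no class — the per-pathway counts then undercount total
    differences, which is the documented degenerate fallback.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for codon in (codon_a, codon_b):
        if code.is_stop(codon):
            raise ValueError(f"stop codon in difference count: {codon}")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return ZERO_DIFFS

    clean_pathways: list[list[str]] = []  # per-pathway step classes
    blocked_pathways: list[list[str]] = []  # step classes with stop steps dropped
    for order in itertools.permutations(diff_positions):
        current = codon_a
        steps: list[str] = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code.is_stop(current) or code.is_stop(nxt):
                blocked = True
            else:
                steps.append(_step_class(current, nxt, code, cls))
            current = nxt
        (blocked_pathways if blocked else clean_pathways).append(steps)

    pathways = clean_pathways if clean_pathways else blocked_pathways
    weight = Fraction(1, len(pathways))
    sd = nd = cd = ncd = Fraction(0)
    for steps in pathways:
        for lab in steps:
            if lab == "S":
                sd += weight
            else:
                nd += weight
                if lab == "NC":
                    ncd += weight
                else:
                    cd += weight
    return DifferenceCounts(sd=sd, nd=nd, cd=cd, ncd=ncd)


def pair_difference_counts(
    aln, code: GeneticCode, cls: SubstitutionClassification
) -> DifferenceCounts:
    total = ZERO_DIFFS
    for codon_a, codon_b in aln.valid_codon_pairs():
        total = total + pathway_difference_counts(codon_a, codon_b, code, cls)
    return total


# --------------------------------------------------------------------------
# Correction and rates
# --------------------------------------------------------------------------


def jukes_cantor_correct(p: float, label: str = "") -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError(f"negative difference proportion: {p}")
    if p >= 0.75:
        raise SaturationError(p, label)
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def estimate_rates_count(
    aln,
    code: GeneticCode | None = None,
    cls: SubstitutionClassification | None = None,
) -> CountRates:
    """Estimate dS, dN, dC, dNC, omega and lambda from a codon pair alignment.

    Each class rate is the Jukes-Cantor-corrected ratio of pathway-averaged
    differences to site opportunities.  A class with zero sites gets rate 0
    and a ``no_X_sites`` flag; a zero denominator leaves the corresponding
    ratio ``None`` with an ``_undefined`` flag.  Saturation raises
    :class:`SaturationError`.
    """
    code = code or standard_genetic_code()
    cls = cls or table1_classification()
    sites = pair_site_counts(aln, code, cls)
    diffs = pair_difference_counts(aln, code, cls)

    flags: list[str] = []

    def corrected(d: Fraction, s: Fraction, label: str) -> float:
        if s == 0:
            flags.append(f"no_{label}_sites")
            return 0.0
        return jukes_cantor_correct(float(d / s), label)

    dS = corrected(diffs.sd, sites.s_sites, "S")
    dN = corrected(diffs.nd, sites.n_sites, "N")
    dC = corrected(diffs.cd, sites.c_sites, "C")
    dNC = corrected(diffs.ncd, sites.nc_sites, "NC")

    if dS > 0:
        omega: float | None = dN / dS
    else:
        omega = None
        flags.append("omega_undefined")
    if dC > 0:
        lam: float | None = dNC / dC
    else:
        lam = None
        flags.append("lambda_undefined")

    return CountRates(
        dS=dS, dN=dN, dC=dC, dNC=dNC, omega=omega, lam=lam,
        sites=sites, diffs=diffs, flags=tuple(flags),
    )
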