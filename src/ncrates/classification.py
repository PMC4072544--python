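"""Classification of amino-acid substitutions into conservative (C) and
non-conservative (NC) classes.

The classification domain is restricted to amino-acid pairs that are *direct
neighbors in the genetic code*: pairs {a, b} such that some codon of a can be
turned into a codon of b by a single nucleotide substitution.  Only such pairs
are observable as single-step events in a codon substitution model, and only
such pairs carry a C/NC label.

Two classifications are provided:

* :func:`table1_classification` — the canonical classification derived from
  large-scale stability predictions over the yeast cytosolic proteome, in
  which a pair is NC when at least 20% of predicted mutations between the two
  residues are highly destabilizing (ddG < -2 kcal/mol).
* :func:`derive_classification` — re-derives such a classification from a
  user-supplied table of per-mutation predicted stability changes.

The canonical classification is validated against BLOSUM62: no NC pair has a
positive BLOSUM62 score (see :func:`blosum62_positive_nc_count`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "AMINO_ACIDS",
    "STOP",
    "GeneticCode",
    "AminoAcidPair",
    "SubstitutionClassification",
    "DdgRecord",
    "DdgPairSummary",
    "standard_genetic_code",
    "single_nt_neighbor_pairs",
    "table1_classification",
    "classify_pair",
    "derive_classification",
    "summarize_ddg_records",
    "blosum62_score",
    "blosum62_positive_nc_count",
    "read_ddg_table",
    "write_classification",
    "read_classification",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
NUCLEOTIDES = "ACGT"

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(base_a: str, base_b: str) -> bool:
    """True when the nucleotide change is purine<->purine or pyrimidine<->pyrimidine."""
    return (base_a in _PURINES and base_b in _PURINES) or (
        base_a in _PYRIMIDINES and base_b in _PYRIMIDINES
    )


# --------------------------------------------------------------------------
# Genetic code
# --------------------------------------------------------------------------

_STANDARD_CODE_TABLE = """
TTT F  TTC F  TTA L  TTG L  CTT L  CTC L  CTA L  CTG L
ATT I  ATC I  ATA I  ATG M  GTT V  GTC V  GTA V  GTG V
TCT S  TCC S  TCA S  TCG S  CCT P  CCC P  CCA P  CCG P
ACT T  ACC T  ACA T  ACG T  GCT A  GCC A  GCA A  GCG A
TAT Y  TAC Y  TAA *  TAG *  CAT H  CAC H  CAA Q  CAG Q
AAT N  AAC N  AAA K  AAG K  GAT D  GAC D  GAA E  GAG E
TGT C  TGC C  TGA *  TGG W  CGT R  CGC R  CGA R  CGG R
AGT S  AGC S  AGA R  AGG R  GGT G  GGC G  GGA G  GGG G
"""


# eq=False: identity-based hashing (the mapping field is unhashable, and the
# few code instances in play are cached by identity downstream).
@dataclass(frozen=True, eq=False)
class GeneticCode:
    """A codon translation table over the DNA alphabet {A, C, G, T}.

    Attributes
    ----------
    codon_to_aa:
        Mapping from each of the 64 codons to a one-letter amino acid or the
        stop symbol ``*``.
    """

    codon_to_aa: Mapping[str, str]
    sense_codons: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"genetic code must have 64 codons, got {len(self.codon_to_aa)}")
        sense = tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa != STOP))
        object.__setattr__(self, "sense_codons", sense)

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon.upper()]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon.upper()] == STOP

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa == STOP))


def standard_genetic_code() -> GeneticCode:
    """Return the standard nuclear genetic code (stops TAA, TAG, TGA)."""
    fields = _STANDARD_CODE_TABLE.split()
    table = {fields[i]: fields[i + 1] for i in range(0, len(fields), 2)}
    return GeneticCode(codon_to_aa=table)


def single_nt_mutants(codon: str) -> list[str]:
    """All 9 codons differing from ``codon`` at exactly one position."""
    out = []
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base != codon[pos]:
                out.append(codon[:pos] + base + codon[pos + 1 :])
    return out


def single_nt_neighbor_pairs(code: GeneticCode) -> frozenset[frozenset[str]]:
    """Unordered amino-acid pairs reachable by one nucleotide substitution.

    A pair {a, b} is included when some sense codon of a differs from some
    sense codon of b at exactly one position.  Stop codons never contribute.
    """
    pairs: set[frozenset[str]] = set()
    for codon in code.sense_codons:
        aa = code.translate(codon)
        for mut in single_nt_mutants(codon):
            aa2 = code.codon_to_aa[mut]
            if aa2 != STOP and aa2 != aa:
                pairs.add(frozenset((aa, aa2)))
    return frozenset(pairs)


# --------------------------------------------------------------------------
# Classification types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AminoAcidPair:
    """An ordered amino-acid substitution a -> b (a != b)."""

    aa_from: str
    aa_to: str

    def __post_init__(self) -> None:
        for aa in (self.aa_from, self.aa_to):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"not a standard amino acid: {aa!r}")
        if self.aa_from == self.aa_to:
            raise ValueError(f"not a substitution: {self.aa_from} -> {self.aa_to}")

    @property
    def unordered(self) -> frozenset[str]:
        return frozenset((self.aa_from, self.aa_to))


class NotClassifiableError(KeyError):
    """The amino-acid pair is not a single-nucleotide neighbor in the genetic code."""


@dataclass(frozen=True)
class SubstitutionClassification:
    """A partition of single-nucleotide-neighbor amino-acid pairs into C and NC.

    ``nc_pairs`` and ``c_pairs`` are disjoint sets of unordered pairs
    (frozensets of two residues); their union is the classification domain.
    """

    nc_pairs: frozenset[frozenset[str]]
    c_pairs: frozenset[frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        overlap = self.nc_pairs & self.c_pairs
        if overlap:
            raise ValueError(f"pairs labeled both C and NC: {sorted(map(sorted, overlap))}")

    @property
    def domain(self) -> frozenset[frozenset[str]]:
        return self.nc_pairs | self.c_pairs

    def label(self, aa_a: str, aa_b: str) -> str:
        """Return 'C' or 'NC' for the unordered pair {aa_a, aa_b}."""
        return classify_pair(AminoAcidPair(aa_a, aa_b), self)

    def is_nc(self, aa_a: str, aa_b: str) -> bool:
        return self.label(aa_a, aa_b) == "NC"


def classify_pair(pair: AminoAcidPair, cls: SubstitutionClassification) -> str:
    """Classify a substitution as 'C' or 'NC'; direction-independent."""
    key = pair.unordered
    if key in cls.nc_pairs:
        return "NC"
    if key in cls.c_pairs:
        return "C"
    raise NotClassifiableError(
        f"not classifiable (multi-nucleotide amino-acid pair): "
        f"{{{pair.aa_from},{pair.aa_to}}}"
    )


# --------------------------------------------------------------------------
# Canonical classification
# --------------------------------------------------------------------------

# Per-residue C and NC partners.  Symmetric by construction; the unordered
# pairs are assembled below and cross-checked for consistency.
_CANONICAL_ROWS: dict[str, tuple[str, str]] = {
    # residue: (conservative partners, non-conservative partners)
    "A": ("DEGST", "PV"),
    "C": ("GRSWY", "F"),
    "D": ("AEGHNVY", ""),
    "E": ("ADGKQV", ""),
    "F": ("ILY", "CSV"),
    "G": ("ACDER", "SVW"),
    "H": ("DLNPQRY", ""),
    "I": ("FLMNV", "KRST"),
    "K": ("EMNQRT", "I"),
    "L": ("FHIMPQRVW", "S"),
    "M": ("IKLRTV", ""),
    "N": ("DHIKSTY", ""),
    "P": ("HLQRS", "AT"),
    "Q": ("EHKLPR", ""),
    "R": ("CGHKLMPQTW", "IS"),
    "S": ("ACNPTWY", "FGILR"),
    "T": ("AKMNRS", "IP"),
    "V": ("DEILM", "AFG"),
    "W": ("CLRS", "G"),
    "Y": ("CDFHNS", ""),
}


def table1_classification() -> SubstitutionClassification:
    """The canonical stability-based C/NC classification.

    A pair is non-conservative when predicted highly destabilizing
    (ddG < -2 kcal/mol) in at least 20% of sampled mutations between the two
    residues, pooled over both directions; conservative otherwise.  The
    classification covers exactly the single-nucleotide-neighbor pairs of the
    standard genetic code.
    """
    labels: dict[frozenset[str], str] = {}
    for aa, (c_partners, nc_partners) in _CANONICAL_ROWS.items():
        for partner, lab in itertools.chain(
            ((p, "C") for p in c_partners), ((p, "NC") for p in nc_partners)
        ):
            key = frozenset((aa, partner))
            prev = labels.get(key)
            if prev is not None and prev != lab:
                raise AssertionError(
                    f"inconsistent canonical table for pair {sorted(key)}: {prev} vs {lab}"
                )
            labels[key] = lab
    nc = frozenset(k for k, v in labels.items() if v == "NC")
    c = frozenset(k for k, v in labels.items() if v == "C")
    return SubstitutionClassification(nc_pairs=nc, c_pairs=c, source="table1")


def all_conservative_classification(code: GeneticCode | None = None) -> SubstitutionClassification:
    """Degenerate classification with every neighbor pair conservative.

    Collapses the extended model onto the standard synonymous/nonsynonymous
    model (lambda plays no role); used for standard-omega fits and as a
    degenerate limit in tests.
    """
    code = code or standard_genetic_code()
    return SubstitutionClassification(
        nc_pairs=frozenset(),
        c_pairs=single_nt_neighbor_pairs(code),
        source="all_conservative",
    )


# --------------------------------------------------------------------------
# Deriving classifications from predicted-stability tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DdgRecord:
    """One predicted stability change for a point mutation.

    ``ddg`` is in kcal/mol; negative values destabilize.
    """

    protein_id: str
    position: int
    aa_wt: str
    aa_mut: str
    ddg: float

    def __post_init__(self) -> None:
        if self.aa_wt == self.aa_mut:
            raise ValueError("ddG record is not a substitution (wt == mut)")


@dataclass(frozen=True)
class DdgPairSummary:
    """Pooled bidirectional ddG statistics for one unordered amino-acid pair."""

    pair: frozenset[str]
    n_total: int
    n_destabilizing: int

    @property
    def fraction(self) -> float:
        return self.n_destabilizing / self.n_total


def summarize_ddg_records(
    records: Iterable[DdgRecord], ddg_cutoff: float = -2.0
) -> dict[frozenset[str], DdgPairSummary]:
    """Pool records bidirectionally per unordered pair and count highly
    destabilizing ones (strict ddg < ddg_cutoff)."""
    totals: dict[frozenset[str], int] = {}
    dest: dict[frozenset[str], int] = {}
    for rec in records:
        key = frozenset((rec.aa_wt, rec.aa_mut))
        totals[key] = totals.get(key, 0) + 1
        if rec.ddg < ddg_cutoff:
            dest[key] = dest.get(key, 0) + 1
    return {
        key: DdgPairSummary(pair=key, n_total=n, n_destabilizing=dest.get(key, 0))
        for key, n in totals.items()
    }


def derive_classification(
    records: Iterable[DdgRecord],
    ddg_cutoff: float = -2.0,
    fraction_cutoff: float = 0.20,
    code: GeneticCode | None = None,
) -> tuple[SubstitutionClassification, frozenset[frozenset[str]]]:
    """Derive a C/NC classification from per-mutation predicted ddG records.

    Records are pooled over both mutation directions per unordered pair.  A
    pair is NC when the fraction of records with ddg < ``ddg_cutoff`` is at
    least ``fraction_cutoff`` ("less than 20% destabilizing" defines C, so the
    boundary fraction == cutoff is NC).  Output is restricted to
    single-nucleotide-neighbor pairs of ``code``.

    Returns
    -------
    (classification, uncovered)
        ``uncovered`` lists the neighbor pairs with no records; they carry no
        label and are never silently defaulted.
    """
    code = code or standard_genetic_code()
    domain = single_nt_neighbor_pairs(code)
    summaries = summarize_ddg_records(records, ddg_cutoff=ddg_cutoff)
    nc: set[frozenset[str]] = set()
    c: set[frozenset[str]] = set()
    uncovered: set[frozenset[str]] = set()
    for pair in domain:
        summary = summaries.get(pair)
        if summary is None:
            uncovered.add(pair)
        elif summary.fraction >= fraction_cutoff:
            nc.add(pair)
        else:
            c.add(pair)
    cls = SubstitutionClassification(
        nc_pairs=frozenset(nc),
        c_pairs=frozenset(c),
        source=f"derived(ddg_cutoff={ddg_cutoff}, fraction_cutoff={fraction_cutoff})",
    )
    return cls, frozenset(uncovered)


# --------------------------------------------------------------------------
# BLOSUM62 validation
# --------------------------------------------------------------------------

# Standard BLOSUM62 half-bit matrix, bundled as a static table so the
# classification check does not depend on any external matrix file.
_BLOSUM62_ORDER = "ARNDCQEGHILKMFPSTWYV"
_BLOSUM62_ROWS = """
 4 -1 -2 -2  0 -1 -1  0 -2 -1 -1 -1 -1 -2 -1  1  0 -3 -2  0
-1  5  0 -2 -3  1  0 -2  0 -3 -2  2 -1 -3 -2 -1 -1 -3 -2 -3
-2  0  6  1 -3  0  0  0  1 -3 -3  0 -2 -3 -2  1  0 -4 -2 -3
-2 -2  1  6 -3  0  2 -1 -1 -3 -4 -1 -3 -3 -1  0 -1 -4 -3 -3
 0 -3 -3 -3  9 -3 -4 -3 -3 -1 -1 -3 -1 -2 -3 -1 -1 -2 -2 -1
-1  1  0  0 -3  5  2 -2  0 -3 -2  1  0 -3 -1  0 -1 -2 -1 -2
-1  0  0  2 -4  2  5 -2  0 -3 -3  1 -2 -3 -1  0 -1 -3 -2 -2
 0 -2  0 -1 -3 -2 -2  6 -2 -4 -4 -2 -3 -3 -2  0 -2 -2 -3 -3
-2  0  1 -1 -3  0  0 -2  8 -3 -3 -1 -2 -1 -2 -1 -2 -2  2 -3
-1 -3 -3 -3 -1 -3 -3 -4 -3  4  2 -3  1  0 -3 -2 -1 -3 -1  3
-1 -2 -3 -4 -1 -2 -3 -4 -3  2  4 -2  2  0 -3 -2 -1 -2 -1  1
-1  2  0 -1 -3  1  1 -2 -1 -3 -2  5 -1 -3 -1  0 -1 -3 -2 -2
-1 -1 -2 -3 -1  0 -2 -3 -2  1  2 -1  5  0 -2 -1 -1 -1 -1  1
-2 -3 -3 -3 -2 -3 -3 -3 -1  0  0 -3  0  6 -4 -2 -2  1  3 -1
-1 -2 -2 -1 -3 -1 -1 -2 -2 -3 -3 -1 -2 -4  7 -1 -1 -4 -3 -2
 1 -1  1  0 -1  0  0  0 -1 -2 -2  0 -1 -2 -1  4  1 -3 -2 -2
 0 -1  0 -1 -1 -1 -1 -2 -2 -1 -1 -1 -1 -2 -1  1  5 -2 -2  0
-3 -3 -4 -4 -2 -2 -3 -2 -2 -3 -2 -3 -1  1 -4 -3 -2 11  2 -3
-2 -2 -2 -3 -2 -1 -2 -3  2 -1 -1 -2 -1  3 -3 -2 -2  2  7 -1
 0 -3 -3 -3 -1 -2 -2 -3 -3  3  1 -2  1 -1 -2 -2  0 -3 -1  4
"""


def _build_blosum62() -> dict[frozenset[str], int]:
    rows = [r.split() for r in _BLOSUM62_ROWS.strip().splitlines()]
    scores: dict[frozenset[str], int] = {}
    for a, row in zip(_BLOSUM62_ORDER, rows):
        for b, val in zip(_BLOSUM62_ORDER, row):
            scores[frozenset((a, b))] = int(val)
    return scores


_BLOSUM62 = _build_blosum62()


def blosum62_score(aa_a: str, aa_b: str) -> int:
    """BLOSUM62 score for a residue pair (symmetric; diagonal allowed)."""
    return _BLOSUM62[frozenset((aa_a, aa_b))]


def blosum62_positive_nc_count(cls: SubstitutionClassification) -> int:
    """Number of NC pairs with a positive BLOSUM62 score.

    The canonical classification yields 0: every non-conservative pair scores
    zero or negative under BLOSUM62.
    """
    return sum(1 for pair in cls.nc_pairs if _BLOSUM62[pair] > 0)


# --------------------------------------------------------------------------
# TSV serialization
# --------------------------------------------------------------------------


def read_ddg_table(path: str | Path) -> list[DdgRecord]:
    """Read a tab-separated ddG table with header
    protein_id, position, aa_wt, aa_mut, ddg."""
    records: list[DdgRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["protein_id", "position", "aa_wt", "aa_mut", "ddg"]
        if header != expected:
            raise ValueError(f"ddG table header must be {expected}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            pid, pos, wt, mut, ddg = line.rstrip("\n").split("\t")
            records.append(DdgRecord(pid, int(pos), wt, mut, float(ddg)))
    return records


def write_ddg_table(records: Iterable[DdgRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\taa_wt\taa_mut\tddg\n")
        for r in records:
            fh.write(f"{r.protein_id}\t{r.position}\t{r.aa_wt}\t{r.aa_mut}\t{r.ddg:.4f}\n")


def write_classification(cls: SubstitutionClassification, path: str | Path) -> None:
    """Write a classification as TSV: aa1, aa2, label (lexicographic pairs)."""
    rows = [(min(p), max(p), "NC") for p in cls.nc_pairs]
    rows += [(min(p), max(p), "C") for p in cls.c_pairs]
    rows.sort()
    with open(path, "w") as fh:
        fh.write("aa1\taa2\tlabel\n")
        for a, b, lab in rows:
            fh.write(f"{a}\t{b}\t{lab}\n")


def read_classification(path: str | Path, source: str | None = None) -> SubstitutionClassification:
    nc: set[frozenset[str]] = set()
    c: set[frozenset[str]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["aa1", "aa2", "label"]:
            raise ValueError(f"classification header must be aa1/aa2/label, got {header}")
        for line in fh:
            if not line.strip():
                continue
            a, b, lab = line.rstrip("\n").split("\t")
            (nc if lab == "NC" else c).add(frozenset((a, b)))
    return SubstitutionClassification(
        nc_pairs=frozenset(nc), c_pairs=frozenset(c), source=source or str(path)
    )
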