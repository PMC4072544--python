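"""Sequence I/O, codon-alignment construction and curation.

Codon alignments are built by back-translating a supplied protein alignment
onto the underlying coding sequences (the alignment itself is produced by an
external aligner).  Curation applies the screens used for pairwise rate
estimation: a gap-fraction ceiling (fail when *more than* 1/3 of columns are
gapped), an optional minimum count of aligned codons (80 for distant ortholog
pairs), and an optional minimum number of inferred NC substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classification import GeneticCode, standard_genetic_code

__all__ = [
    "CodonPairAlignment",
    "CurationReport",
    "CdsValidationError",
    "read_cds",
    "write_fasta",
    "split_codons",
    "backtranslate",
    "pair_alignment_from_codons",
    "read_codon_pair_fasta",
    "write_codon_pair_fasta",
    "curate",
    "batch_estimate",
]

GAP_CODON = "---"
_UNAMBIGUOUS = frozenset("ACGT")


class CdsValidationError(ValueError):
    """A coding sequence failed validation (length, stops, emptiness)."""


@dataclass(frozen=True)
class CodonPairAlignment:
    """Two gap-aligned codon sequences with per-column validity flags.

    A column is valid when both codons are unambiguous sense codons (no gaps,
    no IUPAC ambiguity, no stops).  Estimators only consume valid columns.
    """

    id: str
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]
    valid_mask: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError(
                f"aligned codon sequences differ in length: "
                f"{len(self.codons_a)} vs {len(self.codons_b)}"
            )
        if not self.valid_mask:
            code = standard_genetic_code()
            mask = tuple(
                _codon_ok(a, code) and _codon_ok(b, code)
                for a, b in zip(self.codons_a, self.codons_b)
            )
            object.__setattr__(self, "valid_mask", mask)
        elif len(self.valid_mask) != len(self.codons_a):
            raise ValueError("valid_mask length does not match alignment length")

    def __len__(self) -> int:
        return len(self.codons_a)

    @property
    def n_valid_codons(self) -> int:
        return sum(self.valid_mask)

    @property
    def gap_fraction(self) -> float:
        """Fraction of columns in which either sequence has a gap codon."""
        if not self.codons_a:
            return 0.0
        gapped = sum(
            1 for a, b in zip(self.codons_a, self.codons_b) if a == GAP_CODON or b == GAP_CODON
        )
        return gapped / len(self.codons_a)

    def valid_codon_pairs(self) -> Iterator[tuple[str, str]]:
        for a, b, ok in zip(self.codons_a, self.codons_b, self.valid_mask):
            if ok:
                yield a, b


def _codon_ok(codon: str, code: GeneticCode) -> bool:
    return (
        len(codon) == 3
        and set(codon) <= _UNAMBIGUOUS
        and not code.is_stop(codon)
    )


# --------------------------------------------------------------------------
# CDS reading and validation
# --------------------------------------------------------------------------


def split_codons(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def read_cds(
    path: str | Path, code: GeneticCode | None = None
) -> dict[str, str]:
    """Read and validate coding sequences from FASTA.

    Sequences are uppercased; length must be divisible by 3; a trailing stop
    codon is stripped; internal stops are errors.  Codons with IUPAC
    ambiguity codes are retained (they are masked out at alignment time).
    """
    code = code or standard_genetic_code()
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        if not seq:
            raise CdsValidationError(f"empty record: {record.id}")
        if len(seq) % 3 != 0:
            raise CdsValidationError(
                f"record {record.id}: length {len(seq)} not divisible by 3"
            )
        codons = split_codons(seq)
        if set(codons[-1]) <= _UNAMBIGUOUS and code.is_stop(codons[-1]):
            codons = codons[:-1]
        for idx, codon in enumerate(codons):
            if set(codon) <= _UNAMBIGUOUS and code.is_stop(codon):
                raise CdsValidationError(
                    f"record {record.id}: internal stop codon {codon} at codon {idx + 1}"
                )
        if not codons:
            raise CdsValidationError(f"record {record.id}: no codons after stop stripping")
        out[record.id] = "".join(codons)
    if not out:
        raise CdsValidationError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# Back-translation
# --------------------------------------------------------------------------


def backtranslate(
    pair_id: str,
    protein_a: str,
    protein_b: str,
    cds_a: str,
    cds_b: str,
    code: GeneticCode | None = None,
) -> CodonPairAlignment:
    """Expand an aligned protein pair to a codon alignment using the CDSs.

    Each residue column maps to its source codon; residue gaps become the gap
    codon ``---``.  Every residue is cross-checked against the translation of
    its codon; ambiguous codons are accepted unchecked (and later masked).
    """
    code = code or standard_genetic_code()
    if len(protein_a) != len(protein_b):
        raise ValueError(f"{pair_id}: aligned proteins differ in length")
    out_a = _expand_one(pair_id + "/a", protein_a, cds_a, code)
    out_b = _expand_one(pair_id + "/b", protein_b, cds_b, code)
    return CodonPairAlignment(id=pair_id, codons_a=tuple(out_a), codons_b=tuple(out_b))


def _expand_one(label: str, protein: str, cds: str, code: GeneticCode) -> list[str]:
    codons = split_codons(cds.upper())
    n_residues = sum(1 for r in protein if r != "-")
    if n_residues != len(codons):
        raise ValueError(
            f"{label}: protein has {n_residues} residues but CDS has {len(codons)} codons"
        )
    out: list[str] = []
    i = 0
    for col, residue in enumerate(protein):
        if residue == "-":
            out.append(GAP_CODON)
            continue
        codon = codons[i]
        i += 1
        if set(codon) <= _UNAMBIGUOUS:
            translated = code.translate(codon)
            if translated != residue.upper():
                raise ValueError(
                    f"{label}: translation mismatch at alignment column {col + 1}: "
                    f"protein says {residue!r} but codon {codon} translates to {translated!r}"
                )
        out.append(codon)
    return out


def pair_alignment_from_codons(
    pair_id: str, codons_a: Iterable[str], codons_b: Iterable[str]
) -> CodonPairAlignment:
    return CodonPairAlignment(id=pair_id, codons_a=tuple(codons_a), codons_b=tuple(codons_b))


def read_codon_pair_fasta(path: str | Path, pair_id: str | None = None) -> CodonPairAlignment:
    """Read a pre-aligned two-record codon FASTA (gap runs of length 3)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 aligned records, got {len(records)}")
    seq_a, seq_b = (str(r.seq).upper() for r in records)
    if len(seq_a) != len(seq_b) or len(seq_a) % 3 != 0:
        raise ValueError(f"{path}: aligned sequences must have equal codon-multiple length")
    return CodonPairAlignment(
        id=pair_id or f"{records[0].id}|{records[1].id}",
        codons_a=tuple(split_codons(seq_a)),
        codons_b=tuple(split_codons(seq_b)),
    )


def write_codon_pair_fasta(
    aln: CodonPairAlignment, path: str | Path, names: tuple[str, str] | None = None
) -> None:
    name_a, name_b = names or (aln.id + "/a", aln.id + "/b")
    write_fasta({name_a: "".join(aln.codons_a), name_b: "".join(aln.codons_b)}, path)


# --------------------------------------------------------------------------
# Curation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CurationReport:
    """Outcome of the curation screens for one alignment."""

    pair_id: str
    gap_fraction: float
    n_valid_codons: int
    nc_substitution_count: float | None
    rules: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.rules.values())

    @property
    def failed_rules(self) -> tuple[str, ...]:
        return tuple(name for name, ok in self.rules.items() if not ok)


def curate(
    aln: CodonPairAlignment,
    max_gap_fraction: float = 1.0 / 3.0,
    min_codons: int | None = None,
    min_nc_subs: float | None = None,
    nc_substitution_count: float | None = None,
) -> CurationReport:
    """Apply curation screens to a codon pair alignment.

    The gap rule fails only when the gap fraction strictly exceeds
    ``max_gap_fraction`` (a fraction of exactly 1/3 passes).  ``min_codons``
    and ``min_nc_subs`` are applied only when given; the NC substitution
    count must be supplied by the caller (from an ML or count estimate).
    """
    gap_fraction = aln.gap_fraction
    rules: dict[str, bool] = {"gap_fraction": gap_fraction <= max_gap_fraction}
    if min_codons is not None:
        rules["min_codons"] = aln.n_valid_codons >= min_codons
    if min_nc_subs is not None:
        if nc_substitution_count is None:
            raise ValueError("min_nc_subs rule requires nc_substitution_count")
        rules["min_nc_subs"] = nc_substitution_count >= min_nc_subs
    return CurationReport(
        pair_id=aln.id,
        gap_fraction=gap_fraction,
        n_valid_codons=aln.n_valid_codons,
        nc_substitution_count=nc_substitution_count,
        rules=rules,
    )


# --------------------------------------------------------------------------
# Batch driver
# --------------------------------------------------------------------------


def load_manifest_pair(
    row: dict[str, str], base_dir: str | Path = "."
) -> CodonPairAlignment:
    """Build the alignment described by one manifest row.

    A row either points to a pre-aligned codon FASTA (column ``codon_aln``)
    or to two CDS FASTAs plus an aligned protein FASTA (columns ``cds_a``,
    ``cds_b``, ``protein_aln``).
    """
    base = Path(base_dir)
    pair_id = row["pair_id"]
    if row.get("codon_aln"):
        return read_codon_pair_fasta(base / row["codon_aln"], pair_id=pair_id)
    cds_a = read_cds(base / row["cds_a"])
    cds_b = read_cds(base / row["cds_b"])
    prots = {
        r.id: str(r.seq) for r in SeqIO.parse(str(base / row["protein_aln"]), "fasta")
    }
    if len(prots) != 2:
        raise ValueError(f"{pair_id}: protein alignment must contain exactly 2 records")
    (pa, pb) = prots.values()
    return backtranslate(pair_id, pa, pb, next(iter(cds_a.values())), next(iter(cds_b.values())))


def batch_estimate(
    manifest_path: str | Path,
    cls,
    method: str = "both",
    code: GeneticCode | None = None,
    max_gap_fraction: float = 1.0 / 3.0,
    min_codons: int | None = None,
    n_starts: int = 3,
    seed: int = 0,
):
    """Run curation and rate estimation over a manifest of alignment pairs.

    Returns a ``pandas.DataFrame`` of per-pair results plus a list of
    (pair_id, reason) skip records.  Per-pair failures are logged, never
    fatal; row order follows the manifest.
    """
    import pandas as pd

    from .counting import estimate_rates_count
    from .mlmodel import fit_ml

    if method not in ("ml", "count", "both"):
        raise ValueError(f"method must be ml/count/both, got {method!r}")
    code = code or standard_genetic_code()
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str).fillna("")
    if "pair_id" not in manifest.columns:
        raise ValueError("manifest must have a pair_id column")

    rows: list[dict] = []
    skipped: list[tuple[str, str]] = []
    base_dir = Path(manifest_path).parent
    for _, row in manifest.iterrows():
        pair_id = row["pair_id"]
        try:
            aln = load_manifest_pair(dict(row), base_dir=base_dir)
            report = curate(aln, max_gap_fraction=max_gap_fraction, min_codons=min_codons)
            if not report.passed:
                skipped.append((pair_id, f"curation failed: {','.join(report.failed_rules)}"))
                continue
            out: dict = {
                "pair_id": pair_id,
                "n_codons": aln.n_valid_codons,
                "gap_fraction": report.gap_fraction,
            }
            if method in ("count", "both"):
                rates = estimate_rates_count(aln, code=code, cls=cls)
                out.update(
                    dS=rates.dS, dN=rates.dN, dC=rates.dC, dNC=rates.dNC,
                    omega_count=rates.omega, lambda_count=rates.lam,
                    count_flags=";".join(rates.flags),
                )
            if method in ("ml", "both"):
                fit = fit_ml(aln, cls=cls, code=code, n_starts=n_starts, seed=seed)
                out.update(
                    t=fit.params.t, kappa=fit.params.kappa, gamma=fit.params.gamma,
                    lambda_ml=fit.params.lam, loglik=fit.loglik,
                    converged=fit.converged, ml_flags=";".join(fit.notes),
                )
            rows.append(out)
        except Exception as exc:  # noqa: BLE001 - batch must not abort
            skipped.append((pair_id, f"{type(exc).__name__}: {exc}"))
    return pd.DataFrame(rows), skipped
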