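"""Registry of TraA/TraB allele sequences and ortholog-screening filters.

Alleles are named ``Prefix_StrainID`` where the prefix encodes taxonomic
origin (e.g. ``Mxx`` for *Myxococcus xanthus*).  The registry parses that
convention from FASTA headers, enforces unique identifiers and a protein
alphabet, collapses byte-identical sequences, and applies the homology-hit
screen (E-value, query coverage, operon-partner presence) used to decide
which hits count as genuine *traAB* orthologs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_RESIDUES = AMINO_ACIDS | {"X"}

CYSTOBACTERINEAE = "Cystobacterineae"
SORANGIINEAE = "Sorangiineae"
NANNOCYSTINEAE = "Nannocystineae"
UNKNOWN = "unknown"

#: Taxonomic prefix vocabulary: prefix -> (species / clade description, suborder).
TAXON_PREFIXES: dict[str, tuple[str, str]] = {
    "Aef": ("Aetherobacter fasciculatus", SORANGIINEAE),
    "Aer": ("Aetherobacter rufus", SORANGIINEAE),
    "AeC": ("Aetherobacter clade", SORANGIINEAE),
    "Ar": ("Archangium gephyra", CYSTOBACTERINEAE),
    "ArC": ("Archangium clade", CYSTOBACTERINEAE),
    "Byc": ("Byssovorax cruenta", SORANGIINEAE),
    "Ccc": ("Corallococcus coralloides", CYSTOBACTERINEAE),
    "CcC": ("Corallococcus clade", CYSTOBACTERINEAE),
    "Cba": ("Cystobacter armeniaca", CYSTOBACTERINEAE),
    "Cbfe": ("Cystobacter ferrugineus", CYSTOBACTERINEAE),
    "Cbfu": ("Cystobacter fuscus", CYSTOBACTERINEAE),
    "Cbv": ("Cystobacter velatus", CYSTOBACTERINEAE),
    "Cbvi": ("Cystobacter violaceus", CYSTOBACTERINEAE),
    "CbC": ("Cystobacter clade", CYSTOBACTERINEAE),
    "Hao": ("Haliangium ochraceum", NANNOCYSTINEAE),
    "Hym": ("Hyalangium minutum", CYSTOBACTERINEAE),
    "HyC": ("Hyalangium clade", CYSTOBACTERINEAE),
    "Meb": ("Melittangium boletus", CYSTOBACTERINEAE),
    "Mir": ("Minicystis rosea", SORANGIINEAE),
    "Mxf": ("Myxococcus fulvus", CYSTOBACTERINEAE),
    "Mxh": ("Myxococcus hansupus", CYSTOBACTERINEAE),
    "Mxm": ("Myxococcus macrosporus", CYSTOBACTERINEAE),
    "Mxst": ("Myxococcus stipitatus", CYSTOBACTERINEAE),
    "Mxv": ("Myxococcus virescens", CYSTOBACTERINEAE),
    "Mxx": ("Myxococcus xanthus", CYSTOBACTERINEAE),
    "MxC": ("Myxococcus clade", CYSTOBACTERINEAE),
    "MyxC": ("Myxococcaceae clade", CYSTOBACTERINEAE),
    "Pxf": ("Pyxidicoccus fallax", CYSTOBACTERINEAE),
    "PxC": ("Pyxidicoccus clade", CYSTOBACTERINEAE),
    "SoS": ("Sorangiineae suborder", SORANGIINEAE),
    "Soce": ("Sorangium cellulosum", SORANGIINEAE),
    "Sga": ("Stigmatella aurantiaca", CYSTOBACTERINEAE),
    "Sge": ("Stigmatella erecta", CYSTOBACTERINEAE),
}


class RegistryError(ValueError):
    """Raised on duplicate identifiers or invalid records."""


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed; carries a line number."""


@dataclass(frozen=True)
class AlleleRecord:
    """One named TraA or TraB protein sequence with taxonomic metadata."""

    allele_id: str
    sequence: str
    taxon_prefix: str = UNKNOWN
    suborder: str = UNKNOWN
    gene: str = "traA"
    species: str = UNKNOWN

    def __post_init__(self) -> None:
        if not self.allele_id:
            raise RegistryError("allele_id must be non-empty")
        if not self.sequence:
            raise RegistryError(f"{self.allele_id}: sequence must be non-empty")
        bad = set(self.sequence.upper()) - ALLOWED_RESIDUES
        if bad:
            raise RegistryError(
                f"{self.allele_id}: non-amino-acid characters {sorted(bad)}"
            )
        if self.gene not in ("traA", "traB"):
            raise RegistryError(f"{self.allele_id}: gene must be traA or traB")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside 1..{len(self.sequence)}")
        return self.sequence[position - 1]


def parse_header(header: str) -> dict[str, str]:
    """Split a ``Prefix_StrainID [gene]`` FASTA header into metadata.

    Unrecognised prefixes are accepted with prefix/suborder ``unknown``; a
    ``traA``/``traB`` token anywhere after the ID sets the gene (default
    ``traA``).
    """
    tokens = header.split()
    allele_id = tokens[0]
    prefix, suborder, species = UNKNOWN, UNKNOWN, UNKNOWN
    if "_" in allele_id:
        cand = allele_id.split("_", 1)[0]
        if cand in TAXON_PREFIXES:
            prefix = cand
            species, suborder = TAXON_PREFIXES[cand]
    gene = "traA"
    for tok in tokens[1:]:
        if tok.lower() in ("traa", "trab"):
            gene = "traA" if tok.lower() == "traa" else "traB"
            break
    return {
        "allele_id": allele_id,
        "taxon_prefix": prefix,
        "suborder": suborder,
        "species": species,
        "gene": gene,
    }


class AlleleRegistry:
    """Ordered collection of :class:`AlleleRecord` with unique IDs."""

    def __init__(self, records: Iterable[AlleleRecord] = ()) -> None:
        self._records: dict[str, AlleleRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: AlleleRecord) -> None:
        if record.allele_id in self._records:
            raise RegistryError(f"duplicate allele ID {record.allele_id!r}")
        self._records[record.allele_id] = record

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[AlleleRecord]:
        return iter(self._records.values())

    def __contains__(self, allele_id: str) -> bool:
        return allele_id in self._records

    def __getitem__(self, allele_id: str) -> AlleleRecord:
        return self._records[allele_id]

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def to_fasta(self, path: str | Path, wrap: int = 60) -> None:
        records = [
            SeqRecord(Seq(r.sequence), id=r.allele_id, description=r.gene)
            for r in self
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
            writer.write_file(records)

    def to_json(self, path: str | Path) -> None:
        payload = [asdict(r) for r in self]
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_alleles(path: str | Path) -> AlleleRegistry:
    """Read a protein FASTA into a registry, parsing taxonomy from headers.

    Raises :class:`FastaParseError` naming the offending line on malformed
    input and :class:`RegistryError` on duplicate IDs.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header '>', "
                        f"got {line.strip()[:30]!r}"
                    )
                break
    registry = AlleleRegistry()
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = parse_header(f"{rec.id} {rec.description.removeprefix(rec.id)}")
        registry.add(AlleleRecord(sequence=str(rec.seq), **meta))
    return registry


def dedupe_alleles(
    registry: AlleleRegistry,
) -> tuple[AlleleRegistry, list[list[str]]]:
    """Collapse byte-identical sequences to one representative each.

    The representative is the lexicographically first allele ID of its
    sequence class.  The report lists every class that collapsed (sorted ID
    lists, length > 1).  Idempotent.
    """
    by_seq: dict[str, list[str]] = {}
    for rec in registry:
        by_seq.setdefault(rec.sequence, []).append(rec.allele_id)
    unique = AlleleRegistry()
    report: list[list[str]] = []
    kept_ids = set()
    for ids in by_seq.values():
        ids_sorted = sorted(ids)
        kept_ids.add(ids_sorted[0])
        if len(ids_sorted) > 1:
            report.append(ids_sorted)
    for rec in registry:  # preserve input order among representatives
        if rec.allele_id in kept_ids:
            unique.add(rec)
    report.sort()
    return unique, report


@dataclass(frozen=True)
class ScreenThresholds:
    """Ortholog-screen cutoffs: strict E-value and query-coverage bounds.

    Defaults retain hits with E-value below 1e-100 and query coverage above
    80%, and require the partner gene of the *traAB* operon to be present at
    the subject locus.
    """

    max_evalue: float = 1e-100
    min_coverage: float = 0.80
    require_operon_partner: bool = True

    def __post_init__(self) -> None:
        if not self.max_evalue > 0:
            raise ValueError("max_evalue must be > 0")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")


@dataclass(frozen=True)
class HitRecord:
    """One homology-search hit with the quantities the screen inspects."""

    query_id: str
    subject_id: str
    evalue: float
    query_coverage: float
    has_partner_locus: bool = True

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.subject_id}: evalue must be >= 0")
        cov = self.query_coverage
        if cov > 1.0:
            # percentage input (0, 100]: rescale to a fraction
            if cov > 100.0:
                raise ValueError(f"{self.subject_id}: coverage {cov} out of range")
            logger.warning(
                "hit %s: coverage %.3g looks like a percentage; rescaling to %.3g",
                self.subject_id, cov, cov / 100.0,
            )
            object.__setattr__(self, "query_coverage", cov / 100.0)
        if self.query_coverage < 0:
            raise ValueError(f"{self.subject_id}: coverage must be >= 0")


@dataclass
class ScreenResult:
    """Partition of hits into kept and dropped, with per-hit reason codes."""

    kept: list[HitRecord] = field(default_factory=list)
    dropped: list[HitRecord] = field(default_factory=list)
    reasons: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for hit in self.kept:
            rows.append((hit.query_id, hit.subject_id, hit.evalue,
                         hit.query_coverage, hit.has_partner_locus, True, ""))
        for hit in self.dropped:
            rows.append((hit.query_id, hit.subject_id, hit.evalue,
                         hit.query_coverage, hit.has_partner_locus, False,
                         self.reasons[(hit.query_id, hit.subject_id)]))
        return pd.DataFrame(
            rows,
            columns=["query", "subject", "evalue", "qcov", "partner", "kept", "reason"],
        )


def screen_orthologs(
    hits: Iterable[HitRecord], thresholds: ScreenThresholds = ScreenThresholds()
) -> ScreenResult:
    """Apply the ortholog screen to homology hits.

    A hit is kept iff ``evalue < max_evalue`` and
    ``query_coverage > min_coverage`` (both strict) and, when required, the
    operon partner locus is present.  The reason code names the first
    failing criterion in that order.
    """
    result = ScreenResult()
    for hit in hits:
        reason = None
        if not hit.evalue < thresholds.max_evalue:
            reason = "evalue"
        elif not hit.query_coverage > thresholds.min_coverage:
            reason = "coverage"
        elif thresholds.require_operon_partner and not hit.has_partner_locus:
            reason = "partner"
        if reason is None:
            result.kept.append(hit)
        else:
            result.dropped.append(hit)
            result.reasons[(hit.query_id, hit.subject_id)] = reason
    return result


def read_hits(path: str | Path) -> list[HitRecord]:
    """Read a TSV hit table with columns query, subject, evalue, qcov, partner."""
    df = pd.read_csv(path, sep="\t")
    required = {"query", "subject", "evalue", "qcov"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    if "partner" not in df.columns:
        df["partner"] = True
    return [
        HitRecord(
            query_id=str(r["query"]),
            subject_id=str(r["subject"]),
            evalue=float(r["evalue"]),
            query_coverage=float(r["qcov"]),
            has_partner_locus=bool(r["partner"]),
        )
        for _, r in df.iterrows()
    ]
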