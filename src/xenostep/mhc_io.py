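"""Reading, writing and naming of MHC allele sequences and genotypes.

MHC nomenclature follows the IPD-IMGT/HLA and IPD-MHC conventions: a name
like ``HLA-DRB1*04:03`` is a species prefix (``HLA``), a gene (``DRB1``)
and colon-separated numeric fields.  Swine (SLA) class I genes are named
``1``, ``2``, ``3`` rather than ``A``, ``B``, ``C``.  Allele *identity*
throughout this package is the two-field name: deeper fields (synonymous
or non-coding variation) are preserved on parse but ignored whenever
alleles are compared or pooled into sets.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: 'X' marks an unknown residue; tolerated on input, skipped by k-mer windows.
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS + "X")

#: Unicode hyphen variants that appear in published genotype strings.
_HYPHENS = {"‐": "-", "‑": "-", "‒": "-", "–": "-", "—": "-"}

#: Reference SLA genotype of a well-characterised xenodonor line, in the
#: compact "locus group"-separated notation used in the xenotransplant
#: literature ("^" separates loci, "+" separates alleles within a locus).
REFERENCE_SLA_GENOTYPE_STRING = (
    "SLA-1*07:02 + SLA-1*13:01 + SLA-1*12:01"
    "^SLA-2*10:01 + SLA-2*02:02"
    "^SLA-3*05:02 + SLA-3*04:02"
    "^SLA-DRB1*10:01 + SLA-DRB1*04:03"
    "^SLA-DQB1*06:01 + SLA-DQB1*03:03"
    "^SLA-DQA*02:04 + SLA-DQA*01:01"
    "^SLA-DRA*02:01 + SLA-DRA*04:01"
)


class MhcParseError(ValueError):
    """Raised for malformed allele names, FASTA records or genotype files."""


def _normalize_hyphens(s: str) -> str:
    for h, repl in _HYPHENS.items():
        s = s.replace(h, repl)
    return s


@dataclass(frozen=True)
class AlleleName:
    """A parsed MHC allele name.

    Equality and hashing use two-field identity: ``HLA-A*01:01:01`` and
    ``HLA-A*01:01`` compare equal.  The full field list is kept in
    ``fields`` and the normalised input in ``raw``.
    """

    raw: str
    species_prefix: str
    gene: str
    fields: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene:
            raise MhcParseError(f"allele name has no gene: {self.raw!r}")

    @property
    def key(self) -> tuple[str, str, tuple[str, ...]]:
        """Two-field identity key used for all set operations."""
        return (self.species_prefix, self.gene, self.fields[:2])

    def two_field(self) -> "AlleleName":
        """Truncate to the first two fields (allele identity resolution)."""
        f2 = self.fields[:2]
        name = AlleleName(raw="", species_prefix=self.species_prefix,
                          gene=self.gene, fields=f2)
        return AlleleName(raw=format_allele_name(name),
                          species_prefix=self.species_prefix,
                          gene=self.gene, fields=f2)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleName):
            return NotImplemented
        return self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __str__(self) -> str:
        return format_allele_name(self)


def parse_allele_name(raw: str) -> AlleleName:
    """Parse ``"SLA-DQA*02:04"`` style names into their components.

    Accepts an optional species prefix before the first ``-``, a gene name,
    and ``*``-introduced colon-separated fields.  A bare gene name (no
    ``*``) parses with an empty field tuple.  Unicode hyphens are
    normalised to ASCII.
    """
    name = _normalize_hyphens(raw).strip()
    if not name:
        raise MhcParseError("empty allele name")
    if "*" in name:
        locus_part, _, field_part = name.partition("*")
        fields = tuple(field_part.split(":"))
        if not field_part or any(f == "" for f in fields):
            raise MhcParseError(f"empty allele field in {raw!r}")
    else:
        locus_part, fields = name, ()
    locus_part = locus_part.strip()
    if "-" in locus_part:
        species, _, gene = locus_part.partition("-")
    else:
        species, gene = "", locus_part
    if not gene:
        raise MhcParseError(f"allele name has no gene: {raw!r}")
    return AlleleName(raw=name, species_prefix=species, gene=gene, fields=fields)


def format_allele_name(name: AlleleName) -> str:
    """Inverse of :func:`parse_allele_name` (up to hyphen normalisation)."""
    locus = f"{name.species_prefix}-{name.gene}" if name.species_prefix else name.gene
    if not name.fields:
        return locus
    return f"{locus}*{':'.join(name.fields)}"


@dataclass(frozen=True)
class AlleleSequence:
    """One named MHC protein sequence."""

    name: AlleleName
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise MhcParseError(f"empty sequence for {self.name}")
        bad = [(i, c) for i, c in enumerate(self.sequence) if c not in ALLOWED_RESIDUES]
        if bad:
            i, c = bad[0]
            raise MhcParseError(
                f"non-amino-acid character {c!r} at position {i} in {self.name}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_allele_fasta(path: str | Path, on_duplicate: str = "error") -> list[AlleleSequence]:
    """Read allele protein sequences from FASTA.

    The allele name is the first whitespace-delimited header token, or the
    second if the first looks like a database accession (IPD-style headers
    ``>HLA00001 HLA-A*01:01:01 365 bp``).  Lowercase residues are
    uppercased.  ``on_duplicate`` is ``"error"`` or ``"dedupe"`` (keep the
    first record with a given two-field name).
    """
    if on_duplicate not in ("error", "dedupe"):
        raise ValueError(f"on_duplicate must be 'error' or 'dedupe', got {on_duplicate!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MhcParseError(f"no FASTA records in {path}")
    out: list[AlleleSequence] = []
    seen: dict[AlleleName, int] = {}
    for rec in records:
        tokens = _normalize_hyphens(rec.description).split()
        token = tokens[0]
        # IPD headers put an accession first; the allele name carries '*'.
        if "*" not in token and len(tokens) > 1 and "*" in tokens[1]:
            token = tokens[1]
        name = parse_allele_name(token)
        seq = str(rec.seq).upper()
        try:
            allele = AlleleSequence(name=name, sequence=seq)
        except MhcParseError as e:
            raise MhcParseError(f"record {rec.id}: {e}") from e
        if name in seen:
            if on_duplicate == "error":
                raise MhcParseError(f"duplicate allele name {name} in {path}")
            continue
        seen[name] = len(out)
        out.append(allele)
    return out


def write_allele_fasta(alleles: Iterable[AlleleSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(a.sequence), id=str(a.name), description="")
        for a in alleles
    ]
    SeqIO.write(records, str(path), "fasta")


class AlleleDB:
    """Lookup table from two-field allele name to sequence."""

    def __init__(self, alleles: Iterable[AlleleSequence]):
        self._by_name: dict[AlleleName, AlleleSequence] = {}
        for a in alleles:
            self._by_name.setdefault(a.name, a)

    def __len__(self) -> int:
        return len(self._by_name)

    def __contains__(self, name: AlleleName) -> bool:
        return name in self._by_name

    def get(self, name: AlleleName) -> AlleleSequence:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"allele {name} not found in sequence database") from None

    def alleles(self) -> list[AlleleSequence]:
        return list(self._by_name.values())


@dataclass
class Genotype:
    """An individual's allele multiset across loci.

    ``presenter_loci`` names the loci whose alleles act as class-II
    presenters when the genotype is a recipient (default: the DRB1-like
    locus).  Loci may carry 1..3 alleles: some reference xenodonor lines
    list three class I alleles per locus, so strict diploidy is not
    enforced.  Duplicate alleles (homozygosity) are retained here and
    collapse naturally wherever sets are formed.
    """

    individual_id: str
    species: str
    loci: dict[str, list[AlleleName]]
    presenter_loci: list[str] = field(default_factory=lambda: ["DRB1"])

    def __post_init__(self) -> None:
        if not any(self.loci.values()):
            raise MhcParseError(f"genotype {self.individual_id!r} has no alleles")

    def all_alleles(self) -> list[AlleleName]:
        return [a for alleles in self.loci.values() for a in alleles]

    def presenter_alleles(self) -> list[AlleleName]:
        """Unique presenter alleles (two-field identity)."""
        out: list[AlleleName] = []
        for locus in self.presenter_loci:
            for a in self.loci.get(locus, []):
                if a not in out:
                    out.append(a)
        return out


def parse_genotype_string(s: str, individual_id: str, species: str = "",
                          presenter_loci: Sequence[str] | None = None) -> Genotype:
    """Parse the compact ``"locus^locus"``/``"allele + allele"`` notation."""
    loci: dict[str, list[AlleleName]] = {}
    for locus_group in _normalize_hyphens(s).split("^"):
        for tok in locus_group.split("+"):
            name = parse_allele_name(tok.strip())
            loci.setdefault(name.gene, []).append(name)
    if not species:
        prefixes = {a.species_prefix for g in loci.values() for a in g}
        species = prefixes.pop() if len(prefixes) == 1 else ""
    return Genotype(individual_id=individual_id, species=species, loci=loci,
                    presenter_loci=list(presenter_loci) if presenter_loci else ["DRB1"])


def reference_sla_genotype() -> Genotype:
    """The bundled reference xenodonor SLA genotype (14 alleles, 7 loci)."""
    return parse_genotype_string(REFERENCE_SLA_GENOTYPE_STRING,
                                 individual_id="reference-xenodonor",
                                 species="SLA")


def read_genotype(path: str | Path) -> Genotype:
    """Read a genotype from JSON or TSV.

    JSON schema: ``{"id": ..., "species": ..., "loci": {"DRB1": [...], ...},
    "presenter_loci": ["DRB1"]}``.  The TSV flattening has one row per
    allele with columns ``locus`` and ``allele`` plus optional header
    comments ``#id=``, ``#species=``, ``#presenter_loci=`` (comma lists).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise MhcParseError(f"empty genotype file {path}")
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        data = json.loads(text)
        loci = {
            locus: [parse_allele_name(a) for a in names]
            for locus, names in data["loci"].items()
        }
        return Genotype(
            individual_id=str(data.get("id", path.stem)),
            species=str(data.get("species", "")),
            loci=loci,
            presenter_loci=list(data.get("presenter_loci", ["DRB1"])),
        )
    ind_id, species, presenter_loci = path.stem, "", ["DRB1"]
    loci: dict[str, list[AlleleName]] = {}
    rows: list[dict[str, str]] = []
    header_lines: list[str] = []
    body_lines: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            header_lines.append(line)
        elif line.strip():
            body_lines.append(line)
    for line in header_lines:
        k, _, v = line.lstrip("#").partition("=")
        k, v = k.strip(), v.strip()
        if k == "id":
            ind_id = v
        elif k == "species":
            species = v
        elif k == "presenter_loci":
            presenter_loci = [x.strip() for x in v.split(",") if x.strip()]
    reader = csv.DictReader(body_lines, delimiter="\t")
    rows = list(reader)
    if not rows or "locus" not in (reader.fieldnames or []):
        raise MhcParseError(f"genotype TSV {path} needs 'locus' and 'allele' columns")
    for row in rows:
        name = parse_allele_name(row["allele"])
        loci.setdefault(row["locus"], []).append(name)
    return Genotype(individual_id=ind_id, species=species, loci=loci,
                    presenter_loci=presenter_loci)


def write_genotype_json(genotype: Genotype, path: str | Path) -> None:
    data = {
        "id": genotype.individual_id,
        "species": genotype.species,
        "loci": {locus: [str(a) for a in alleles]
                 for locus, alleles in genotype.loci.items()},
        "presenter_loci": genotype.presenter_loci,
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")
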