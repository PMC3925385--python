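"""Reference barcode library: Linnean lineages, records, and FASTA/TSV I/O.

A reference library stands in for the remote GenBank/BOLD searches of a
typical barcoding workflow: every reference COI sequence carries a full
six-rank lineage (phylum, class, order, family, genus, species) so that
identification can fall back to higher ranks when no species-level match
exists.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RANKS = ("phylum", "class_", "order", "family", "genus", "species")
#: ranks usable for clade-level identification, most specific first
ASSIGNABLE_RANKS = ("species", "genus", "family", "order")

_VALID_CHARS = set("ACGTN")


class RefDBError(ValueError):
    """Raised on malformed reference libraries or taxonomy tables."""


@dataclass(frozen=True)
class Lineage:
    """Six-rank Linnean lineage, filled top-down.

    ``genus`` and ``species`` may be empty (e.g. a family-level placeholder);
    a filled rank implies all higher ranks are filled.  Subspecies names are
    stored verbatim in ``species``.
    """

    phylum: str
    class_: str
    order: str
    family: str
    genus: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        names = [getattr(self, r) for r in RANKS]
        seen_empty = False
        for rank, name in zip(RANKS, names):
            if name == "":
                seen_empty = True
            elif seen_empty:
                raise RefDBError(
                    f"lineage fills rank {rank!r} below an empty rank: {names}"
                )

    def at(self, rank: str) -> str:
        if rank == "class":
            rank = "class_"
        if rank not in RANKS:
            raise KeyError(rank)
        return getattr(self, rank)

    @property
    def lowest_rank(self) -> str:
        for rank in reversed(RANKS):
            if getattr(self, rank):
                return rank
        raise RefDBError("empty lineage")

    def truncated(self, rank: str) -> "Lineage":
        """Copy of the lineage with ranks below ``rank`` blanked."""
        keep = RANKS[: RANKS.index(rank if rank != "class" else "class_") + 1]
        kwargs = {r: (getattr(self, r) if r in keep else "") for r in RANKS}
        return Lineage(**kwargs)


@dataclass(frozen=True)
class ReferenceRecord:
    """One barcoded reference sequence with a species-level lineage."""

    accession: str
    sequence: str
    lineage: Lineage

    def __post_init__(self) -> None:
        if not self.sequence:
            raise RefDBError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise RefDBError(
                f"{self.accession}: invalid symbols {sorted(bad)}; "
                "only A,C,G,T,N are accepted"
            )
        if not self.lineage.species:
            raise RefDBError(f"{self.accession}: reference lineage lacks species rank")


class ReferenceDB:
    """In-memory reference library with a rank -> name -> accessions index."""

    def __init__(self, records: Iterable[ReferenceRecord]):
        self.records: list[ReferenceRecord] = list(records)
        self.by_accession: dict[str, ReferenceRecord] = {}
        for rec in self.records:
            if rec.accession in self.by_accession:
                raise RefDBError(f"duplicate accession {rec.accession!r}")
            self.by_accession[rec.accession] = rec
        self.index: dict[str, dict[str, list[str]]] = {r: {} for r in RANKS}
        for rec in self.records:
            for rank in RANKS:
                name = getattr(rec.lineage, rank)
                if name:
                    self.index[rank].setdefault(name, []).append(rec.accession)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def lineage_of(self, accession: str) -> Lineage:
        return self.by_accession[accession].lineage

    def names_at(self, rank: str) -> list[str]:
        if rank == "class":
            rank = "class_"
        return sorted(self.index[rank])


def _read_taxonomy(taxonomy_path: str | Path) -> dict[str, Lineage]:
    lineages: dict[str, Lineage] = {}
    with open(taxonomy_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 7:
            raise RefDBError(
                f"taxonomy table must have 7 columns (id + 6 ranks), got {len(header)}"
            )
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise RefDBError(f"{taxonomy_path}:{ln}: expected 7 columns")
            acc = fields[0]
            if acc in lineages:
                raise RefDBError(f"duplicate taxonomy row for {acc!r}")
            lineages[acc] = Lineage(*fields[1:])
    return lineages


def read_reference_fasta(fasta_path: str | Path, taxonomy_path: str | Path) -> ReferenceDB:
    """Load a reference library from a FASTA file plus a 7-column taxonomy TSV.

    Every FASTA record must have a taxonomy row (keyed on the FASTA id);
    records are validated to the {A,C,G,T,N} alphabet and a species-filled
    lineage.  Missing taxonomy or duplicate accessions are hard errors.
    """
    lineages = _read_taxonomy(taxonomy_path)
    records = []
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        acc = seq_rec.id
        if acc not in lineages:
            raise RefDBError(f"FASTA record {acc!r} has no row in {taxonomy_path}")
        records.append(
            ReferenceRecord(acc, str(seq_rec.seq).upper(), lineages[acc])
        )
    return ReferenceDB(records)


def write_reference_fasta(db: ReferenceDB, fasta_path: str | Path,
                          taxonomy_path: str | Path) -> None:
    """Inverse of :func:`read_reference_fasta` (modulo FASTA line wrapping)."""
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in db),
        str(fasta_path), "fasta",
    )
    with open(taxonomy_path, "w") as fh:
        fh.write("accession\tphylum\tclass\torder\tfamily\tgenus\tspecies\n")
        for r in db:
            fh.write(r.accession + "\t" + "\t".join(getattr(r.lineage, k) for k in RANKS) + "\n")


def outgroup_candidates(db: ReferenceDB, lineage: Lineage, n: int) -> list[ReferenceRecord]:
    """Pick up to ``n`` outgroup references from the nearest other families.

    Walks up the query lineage (order, then class, then phylum) and returns
    records that share the current higher rank but belong to a different
    family, in lexicographic accession order.  Returns an empty list when the
    library holds no family other than the query's.
    """
    if len(db) == 0:
        raise RefDBError("empty reference library")
    others = [r for r in db if r.lineage.family != lineage.family]
    for rank in ("order", "class_", "phylum"):
        name = getattr(lineage, rank)
        if not name:
            continue
        pool = [r for r in others if getattr(r.lineage, rank) == name]
        if pool:
            return sorted(pool, key=lambda r: r.accession)[:n]
    return sorted(others, key=lambda r: r.accession)[:n]
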