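"""Alignment and sample-map I/O, region extraction, haplotype collapsing.

The universal input of the pipeline is an :class:`AlignedSequenceSet`: an
aligned multi-FASTA in which every record carries a species label (and an
optional population label) supplied by a tab-separated sample map. Sequences
are stored uppercase over the IUPAC nucleotide alphabet plus the gap
character ``-``.

Coordinates are 0-based half-open internally; every user-facing file and
report uses 1-based inclusive positions, the convention of the barcoding
literature this package serves.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ALPHABET",
    "PURE_BASES",
    "AlignedRecord",
    "AlignedSequenceSet",
    "RegionAnnotation",
    "Haplotype",
    "HaplotypeTable",
    "AlignmentError",
    "AlphabetError",
    "SampleMapError",
    "RegionError",
    "read_alignment",
    "write_alignment",
    "read_sample_map",
    "write_sample_map",
    "extract_region",
    "collapse_haplotypes",
    "write_haplotype_table",
]

#: IUPAC nucleotide codes (incl. U) plus the alignment gap character.
ALPHABET = frozenset("ACGTUNRYSWKMBDHV-")
#: Unambiguous bases; everything else is treated as missing by the distance code.
PURE_BASES = frozenset("ACGT")


class AlignmentError(ValueError):
    """Records do not form a valid alignment (unequal lengths, duplicate ids...)."""


class AlphabetError(ValueError):
    """A residue outside the IUPAC nucleotide alphabet plus gap."""


class SampleMapError(ValueError):
    """Sample map is malformed or does not cover the alignment."""


class RegionError(ValueError):
    """Region annotation outside the alignment or empty."""


@dataclass(frozen=True)
class AlignedRecord:
    """One aligned sequence with its species (and optional population) label."""

    id: str
    species: str
    population: str
    residues: str


@dataclass
class AlignedSequenceSet:
    """Equal-length aligned nucleotide sequences with species/population labels."""

    records: list[AlignedRecord]
    alignment_length: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment must contain at least one record")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"unequal sequence lengths in alignment: {sorted(lengths)}"
            )
        (length,) = lengths
        if self.alignment_length == 0:
            self.alignment_length = length
        elif self.alignment_length != length:
            raise AlignmentError(
                f"declared alignment_length {self.alignment_length} != {length}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = [i for i, c in collections.Counter(ids).items() if c > 1]
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        for r in self.records:
            if not r.species:
                raise SampleMapError(f"record {r.id!r} has an empty species label")
            bad = set(r.residues) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"record {r.id!r} contains non-IUPAC characters {sorted(bad)}"
                )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str, str]]
    ) -> "AlignedSequenceSet":
        """Build from ``(id, species, population, residues)`` tuples (uppercased)."""
        return cls(
            [AlignedRecord(i, sp, pop, res.upper()) for i, sp, pop, res in records]
        )

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def species_map(self) -> dict[str, str]:
        return {r.id: r.species for r in self.records}

    @property
    def population_map(self) -> dict[str, str]:
        return {r.id: r.population for r in self.records}

    @property
    def species(self) -> list[str]:
        """Distinct species labels in first-seen order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species, None)
        return list(seen)

    def members_of(self, species: str) -> list[AlignedRecord]:
        return [r for r in self.records if r.species == species]

    def subset(self, ids: Iterable[str]) -> "AlignedSequenceSet":
        wanted = list(ids)
        by_id = {r.id: r for r in self.records}
        missing = [i for i in wanted if i not in by_id]
        if missing:
            raise SampleMapError(f"unknown sequence ids: {missing}")
        return AlignedSequenceSet([by_id[i] for i in wanted])


@dataclass(frozen=True)
class RegionAnnotation:
    """A column range delimiting a sub-region (e.g. ITS2 within full ITS).

    ``start``/``end`` are 0-based half-open; use :meth:`from_1based` for the
    inclusive coordinates found in annotation files.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise RegionError(f"invalid region [{self.start}, {self.end})")

    @classmethod
    def from_1based(cls, start: int, end: int) -> "RegionAnnotation":
        return cls(start - 1, end)

    def to_1based(self) -> tuple[int, int]:
        return self.start + 1, self.end


@dataclass(frozen=True)
class Haplotype:
    haplotype_id: str
    representative_residues: str
    member_ids: tuple[str, ...]

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


@dataclass
class HaplotypeTable:
    """Partition of sequence ids into identical-sequence classes."""

    haplotypes: list[Haplotype]
    grouping: Literal["global", "per_species"]

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def member_counts(self) -> list[int]:
        return [h.n_members for h in self.haplotypes]

    def haplotype_of(self, seq_id: str) -> str:
        for h in self.haplotypes:
            if seq_id in h.member_ids:
                return h.haplotype_id
        raise KeyError(seq_id)


# ---------------------------------------------------------------------------
# sample map + FASTA I/O
# ---------------------------------------------------------------------------

def read_sample_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a tab-separated sample map ``id<TAB>species<TAB>population``.

    The header row is required; the population column may be empty or absent.
    Returns ``{id: (species, population)}``.
    """
    path = Path(path)
    mapping: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 2 or cols[0] != "id" or cols[1] != "species":
            raise SampleMapError(
                f"{path}: expected header 'id<TAB>species[<TAB>population]', got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise SampleMapError(f"{path}:{lineno}: malformed row {line!r}")
            seq_id = parts[0]
            if seq_id in mapping:
                raise SampleMapError(f"{path}:{lineno}: duplicate id {seq_id!r}")
            population = parts[2] if len(parts) > 2 else ""
            mapping[seq_id] = (parts[1], population)
    return mapping


def write_sample_map(aln: AlignedSequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tspecies\tpopulation\n")
        for r in aln.records:
            fh.write(f"{r.id}\t{r.species}\t{r.population}\n")


def read_alignment(
    fasta_path: str | Path, samplemap_path: str | Path
) -> AlignedSequenceSet:
    """Read an aligned multi-FASTA plus its sample map into a labelled set.

    Every FASTA id must appear in the sample map; records keep file order.
    Residues are uppercased on read.
    """
    mapping = read_sample_map(samplemap_path)
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in mapping:
            raise SampleMapError(
                f"FASTA id {rec.id!r} missing from sample map {samplemap_path}"
            )
        species, population = mapping[rec.id]
        records.append((rec.id, species, population, str(rec.seq)))
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    return AlignedSequenceSet.from_records(records)


def write_alignment(
    aln: AlignedSequenceSet,
    fasta_path: str | Path,
    samplemap_path: str | Path | None = None,
) -> None:
    """Write the FASTA (and, if given, the sample map) for a sequence set."""
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in aln.records
    ]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    if samplemap_path is not None:
        write_sample_map(aln, samplemap_path)


# ---------------------------------------------------------------------------
# region extraction + haplotype collapsing
# ---------------------------------------------------------------------------

def extract_region(
    aln: AlignedSequenceSet, region: RegionAnnotation
) -> AlignedSequenceSet:
    """Return the column slice ``[region.start, region.end)`` with labels kept."""
    if region.end > aln.alignment_length:
        raise RegionError(
            f"region [{region.start}, {region.end}) exceeds alignment length "
            f"{aln.alignment_length}"
        )
    return AlignedSequenceSet(
        [
            AlignedRecord(r.id, r.species, r.population,
                          r.residues[region.start:region.end])
            for r in aln.records
        ]
    )


def _collapse_group(
    records: list[AlignedRecord], gap_policy: str
) -> list[tuple[str, list[str]]]:
    """Group records by sequence identity; returns (representative, member ids)."""
    residues = {r.id: r.residues for r in records}
    if gap_policy == "ignore_gap_only_columns":
        length = len(records[0].residues)
        keep = [
            c for c in range(length)
            if any(r.residues[c] != "-" for r in records)
        ]
        keys = {
            r.id: "".join(r.residues[c] for c in keep) for r in records
        }
    elif gap_policy == "strict":
        keys = {r.id: r.residues for r in records}
    else:
        raise ValueError(f"unknown gap_policy {gap_policy!r}")

    groups: dict[str, list[str]] = {}
    for r in records:
        groups.setdefault(keys[r.id], []).append(r.id)
    # decreasing member count, then first-seen order of the first member
    first_seen = {r.id: i for i, r in enumerate(records)}
    ordered = sorted(
        groups.items(), key=lambda kv: (-len(kv[1]), first_seen[kv[1][0]])
    )
    return [(residues[members[0]], members) for _key, members in ordered]


def collapse_haplotypes(
    aln: AlignedSequenceSet,
    scope: Literal["global", "per_species"] = "global",
    gap_policy: Literal["strict", "ignore_gap_only_columns"] = "strict",
) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes.

    Under the default ``strict`` policy two sequences share a haplotype iff
    their uppercased residue strings are identical, gaps significant and
    ambiguity codes matching only themselves. The ``ignore_gap_only_columns``
    policy first drops columns that are gaps in every member of the scope
    group. Haplotypes are ordered by decreasing member count, ties broken by
    first occurrence; representatives are each group's first-seen sequence.
    """
    haplotypes: list[Haplotype] = []
    if scope == "global":
        for k, (rep, members) in enumerate(
            _collapse_group(aln.records, gap_policy), start=1
        ):
            haplotypes.append(Haplotype(f"Hap_{k}", rep, tuple(members)))
    elif scope == "per_species":
        for sp in aln.species:
            for k, (rep, members) in enumerate(
                _collapse_group(aln.members_of(sp), gap_policy), start=1
            ):
                haplotypes.append(Haplotype(f"{sp}_Hap_{k}", rep, tuple(members)))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return HaplotypeTable(haplotypes, scope)


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("haplotype_id\tn_members\tmember_ids\tsequence\n")
        for h in table.haplotypes:
            fh.write(
                f"{h.haplotype_id}\t{h.n_members}\t{','.join(h.member_ids)}\t"
                f"{h.representative_residues}\n"
            )
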