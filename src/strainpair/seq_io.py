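"""Sequence and report I/O: the :class:`Genome` data model, FASTA reading,
and serialization of strain-specific region reports (TSV / GFF3 / BED).

Internal coordinates throughout the package are 0-based half-open; report
formats use the conventions of their ecosystem (GFF3 and the TSV report are
1-based inclusive, BED is 0-based half-open).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "Genome",
    "RegionRecord",
    "FastaFormatError",
    "read_fasta",
    "write_regions",
    "read_regions",
]

_VALID_BASES = set("ACGTN")


class FastaFormatError(ValueError):
    """Raised when a FASTA record violates the expected format."""


@dataclass
class Genome:
    """A named nucleotide sequence with replicon topology metadata.

    The sequence is uppercase over the alphabet {A, C, G, T, N}; ``N``
    marks assembly gaps and never participates in word matching.
    """

    name: str
    sequence: str
    topology: str = "circular"  # or "linear"

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, topology: str = "circular") -> list[Genome]:
    """Read all records of a FASTA file into :class:`Genome` objects.

    Sequences are uppercased; any character outside {A, C, G, T, N} is
    rejected with an error naming the offending record and character.
    """
    path = Path(path)
    genomes: list[Genome] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} in {path} has an empty sequence")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FastaFormatError(
                f"record {rec.id!r} in {path} contains invalid character(s) "
                f"{sorted(bad)!r}; expected only A,C,G,T,N"
            )
        genomes.append(Genome(rec.id, seq, topology))
    if not genomes:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return genomes


def write_fasta(genomes: Iterable[Genome], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


@dataclass
class RegionRecord:
    """One classified strain-specific region (a row of the region report).

    ``posA``/``posB`` are 1-based inclusive start positions in each genome;
    a length of 0 marks the side where the region is absent (the position
    then points at the first base after the junction).  ``overlap`` is the
    length of a direct repeat at the junction (0 when none); for
    repeat-mediated deletions ``sum`` is the total number of deleted bases
    (core plus one repeat copy).
    """

    region_number: int
    category: str
    posA: int
    lenA: int
    posB: int
    lenB: int
    overlap: int = 0
    sum: int = 0
    location: str = "unknown"  # intergenic | in_gene | in_element | unknown
    description: str = ""
    polarity: str = "unknown"

    def size_class(self) -> str:
        n = max(self.lenA, self.lenB)
        if n < 150:
            return "short"
        if n <= 1500:
            return "medium"
        return "long"


_TSV_COLUMNS = [
    "region_number",
    "category",
    "posA",
    "lenA",
    "posB",
    "lenB",
    "overlap",
    "sum",
    "location",
    "polarity",
    "description",
]
_INT_COLUMNS = {"region_number", "posA", "lenA", "posB", "lenB", "overlap", "sum"}


def _check_sorted(records: Sequence[RegionRecord]) -> None:
    for prev, cur in zip(records, records[1:]):
        if cur.posA < prev.posA:
            raise ValueError(
                f"region records are not sorted by posA "
                f"(region {prev.region_number} at {prev.posA} precedes "
                f"{cur.region_number} at {cur.posA})"
            )


def write_regions(
    records: Sequence[RegionRecord],
    path: str | Path,
    format: str = "tsv",
    name_a: str = "A",
) -> None:
    """Write region records as TSV (all columns), GFF3 or BED.

    GFF3 and BED use the strain-A coordinate frame.  BED intervals are
    0-based half-open; GFF3 and TSV are 1-based inclusive.  Records must be
    sorted by ``posA``.
    """
    _check_sorted(records)
    path = Path(path)
    if format == "tsv":
        with open(path, "w", newline="") as fh:
            fh.write("#" + "\t".join(_TSV_COLUMNS) + "\n")
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for r in records:
                w.writerow([getattr(r, c) for c in _TSV_COLUMNS])
    elif format == "bed":
        with open(path, "w") as fh:
            for r in records:
                start = r.posA - 1
                end = start + r.lenA
                fh.write(
                    f"{name_a}\t{start}\t{end}\t{r.category}:{r.region_number}\t"
                    f"{max(r.lenA, r.lenB)}\t+\n"
                )
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in records:
                start = r.posA
                end = r.posA + max(r.lenA - 1, 0)
                attrs = (
                    f"ID=region{r.region_number};category={r.category};"
                    f"lenA={r.lenA};posB={r.posB};lenB={r.lenB};"
                    f"overlap={r.overlap};sum={r.sum};location={r.location};"
                    f"polarity={r.polarity}"
                )
                fh.write(
                    f"{name_a}\tstrainpair\tsequence_difference\t{start}\t{end}\t.\t+\t.\t{attrs}\n"
                )
    else:
        raise ValueError(f"unknown region format {format!r}")


def read_regions(path: str | Path, format: str = "tsv") -> list[RegionRecord]:
    """Read a region report back; full round trip is supported for TSV,
    and coordinates/categories for GFF3 and BED."""
    path = Path(path)
    records: list[RegionRecord] = []
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().lstrip("#").rstrip("\n").split("\t")
            for line in fh:
                if not line.strip():
                    continue
                vals = line.rstrip("\n").split("\t")
                kwargs = {}
                for col, v in zip(header, vals):
                    kwargs[col] = int(v) if col in _INT_COLUMNS else v
                records.append(RegionRecord(**kwargs))
    elif format == "bed":
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, start, end, name, score, strand = line.split("\t")[:6]
                category, num = name.rsplit(":", 1)
                records.append(
                    RegionRecord(
                        region_number=int(num),
                        category=category,
                        posA=int(start) + 1,
                        lenA=int(end) - int(start),
                        posB=0,
                        lenB=0,
                    )
                )
    elif format == "gff3":
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";"))
                lenA = int(attrs["lenA"])
                records.append(
                    RegionRecord(
                        region_number=int(attrs["ID"].replace("region", "")),
                        category=attrs["category"],
                        posA=int(f[3]),
                        lenA=lenA,
                        posB=int(attrs["posB"]),
                        lenB=int(attrs["lenB"]),
                        overlap=int(attrs["overlap"]),
                        sum=int(attrs["sum"]),
                        location=attrs["location"],
                        polarity=attrs.get("polarity", "unknown"),
                    )
                )
    else:
        raise ValueError(f"unknown region format {format!r}")
    return records
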