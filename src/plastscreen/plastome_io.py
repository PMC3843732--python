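"""Genome, annotation and alignment I/O for plastid marker screening.

All internal coordinates are 0-based half-open intervals; GenBank flat files
use 1-based inclusive coordinates and the conversion happens only at the I/O
boundary. Report output intended for humans is rendered 1-based elsewhere.

Circularity of the plastome is deliberately not modelled: no marker handled
here spans the origin, and features wrapping the origin are rejected.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

FEATURE_KINDS = ("gene", "CDS", "tRNA", "rRNA", "IR", "spacer")

# GenBank feature keys mapped onto our feature kinds
_GENBANK_KEY_TO_KIND = {
    "gene": "gene",
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "repeat_region": "IR",
    "misc_feature": "spacer",
}
_KIND_TO_GENBANK_KEY = {v: k for k, v in _GENBANK_KEY_TO_KIND.items()}

IUPAC_NUCLEOTIDES = frozenset("ACGTUNRYSWKMBDHV")


class PlastomeIOError(ValueError):
    """Raised on malformed genome or alignment input."""


@dataclass(frozen=True)
class Feature:
    """A typed annotation on a plastome.

    ``interval`` is 0-based half-open; ``strand`` is '+' or '-'.
    """

    name: str
    kind: str
    interval: tuple[int, int]
    strand: str = "+"

    def __post_init__(self) -> None:
        start, end = self.interval
        if not self.name:
            raise ValueError("feature name must be non-empty")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if start >= end:
            raise ValueError(f"empty feature interval [{start}, {end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def end(self) -> int:
        return self.interval[1]

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedPlastome:
    """A plastid genome sequence plus typed features."""

    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise PlastomeIOError(f"genome {self.id!r} has an empty sequence")
        bad = set(self.sequence) - IUPAC_NUCLEOTIDES
        if bad:
            raise PlastomeIOError(
                f"genome {self.id!r} contains non-nucleotide characters: "
                f"{sorted(bad)}"
            )
        for feat in self.features:
            if feat.start < 0 or feat.end > len(self.sequence):
                raise PlastomeIOError(
                    f"feature {feat.name!r} interval [{feat.start}, {feat.end}) "
                    f"outside genome of length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]


@dataclass
class Alignment:
    """A rectangular multiple sequence alignment.

    Rows are uppercase strings over nucleotides, IUPAC ambiguity codes and
    '-' gaps. Row order is meaningful only for display; all statistics
    downstream are permutation-invariant.
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise PlastomeIOError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise PlastomeIOError("an alignment needs at least 2 sequences")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise PlastomeIOError(f"duplicate sequence ids: {dupes}")
        self.rows = [r.upper().replace(".", "-").replace("~", "-") for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            ragged = [
                i for i, r in zip(self.ids, self.rows) if len(r) != len(self.rows[0])
            ]
            raise PlastomeIOError(
                f"alignment is ragged; offending records: {ragged}"
            )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> tuple[str, ...]:
        return tuple(row[j] for row in self.rows)

    def slice_columns(self, start: int, end: int) -> "Alignment":
        """Column slice [start, end) as a new alignment."""
        if not (0 <= start < end <= self.n_cols):
            raise PlastomeIOError(
                f"column interval [{start}, {end}) outside alignment "
                f"of width {self.n_cols}"
            )
        return Alignment(list(self.ids), [r[start:end] for r in self.rows])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"no sequence {seq_id!r} in alignment") from None


def _feature_from_biopython(feat: SeqFeature, index: int) -> Feature | None:
    kind = _GENBANK_KEY_TO_KIND.get(feat.type)
    if kind is None:
        return None
    quals = feat.qualifiers
    name = (
        quals.get("gene", [None])[0]
        or quals.get("product", [None])[0]
        or quals.get("note", [None])[0]
        or quals.get("rpt_type", [None])[0]
        or f"{feat.type}_{index}"
    )
    strand = "-" if feat.location.strand == -1 else "+"
    return Feature(
        name=str(name),
        kind=kind,
        interval=(int(feat.location.start), int(feat.location.end)),
        strand=strand,
    )


def read_genbank(path: str | Path) -> AnnotatedPlastome:
    """Read a GenBank flat file into an :class:`AnnotatedPlastome`.

    GenBank 1-based inclusive locations become 0-based half-open intervals;
    ``complement(...)`` locations become strand '-'. ``repeat_region``
    features are imported as IR features.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise PlastomeIOError(f"malformed GenBank file {path}: {exc}") from exc
    seq = str(record.seq)
    if not seq:
        raise PlastomeIOError(f"GenBank record in {path} has an empty sequence")
    features = []
    for i, feat in enumerate(record.features):
        converted = _feature_from_biopython(feat, i)
        if converted is not None:
            features.append(converted)
    return AnnotatedPlastome(id=record.id, sequence=seq, features=features)


def write_genbank(genome: AnnotatedPlastome, path: str | Path) -> None:
    """Write a genome and its features back to a GenBank flat file."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id.split(".")[0][:16],
        description="",
        annotations={"molecule_type": "DNA"},
    )
    for feat in genome.features:
        qualifier = "rpt_type" if feat.kind == "IR" else "gene"
        record.features.append(
            SeqFeature(
                FeatureLocation(
                    feat.start, feat.end, strand=-1 if feat.strand == "-" else 1
                ),
                type=_KIND_TO_GENBANK_KEY[feat.kind],
                qualifiers={qualifier: [feat.name]},
            )
        )
    SeqIO.write([record], str(Path(path)), "genbank")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.

    Rows are uppercased and '.'/'~' gap spellings normalised to '-'.
    Ragged records or duplicate ids raise :class:`PlastomeIOError` naming
    the offending records.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise PlastomeIOError(f"no FASTA records in {path}")
    return Alignment(
        ids=[r.id for r in records], rows=[str(r.seq) for r in records]
    )


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as aligned FASTA (one line per sequence)."""
    with open(path, "w") as fh:
        for seq_id, row in zip(aln.ids, aln.rows):
            fh.write(f">{seq_id}\n{row}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain (unaligned) FASTA as an id → sequence mapping."""
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(Path(path)), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in seqs.items():
            fh.write(f">{seq_id}\n{seq}\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes and gaps."""
    return str(Seq(seq).reverse_complement())


def extract_region(
    genome: AnnotatedPlastome, interval: tuple[int, int], strand: str = "+"
) -> str:
    """Extract a genomic region; minus strand returns the reverse complement.

    The interval is 0-based half-open and must lie within the linearised
    genome — origin-spanning regions are rejected.
    """
    start, end = interval
    if not (0 <= start < end <= genome.length):
        raise PlastomeIOError(
            f"interval [{start}, {end}) out of range for genome "
            f"{genome.id!r} of length {genome.length}"
        )
    region = genome.sequence[start:end]
    if strand == "-":
        return reverse_complement(region)
    if strand != "+":
        raise PlastomeIOError(f"strand must be '+' or '-', got {strand!r}")
    return region


def write_bed(
    regions: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write candidate regions as BED (0-based half-open, like internal
    coordinates): rows of (chrom, start, end, name)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in regions:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def alignment_from_strings(rows: Sequence[str], ids: Sequence[str] | None = None) -> Alignment:
    """Convenience constructor used heavily in tests and examples."""
    if ids is None:
        ids = [f"seq{i + 1}" for i in range(len(rows))]
    return Alignment(ids=list(ids), rows=list(rows))
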