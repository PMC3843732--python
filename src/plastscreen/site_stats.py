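"""Column classification and counting statistics for marker alignments.

A column is *variable* when it carries at least two distinct unambiguous
nucleotide states (A/C/G/T). Gaps and IUPAC ambiguity codes are treated as
missing data for variability: a column whose only heterogeneity involves
gaps or ambiguity codes is not variable (indels are scored separately by
:mod:`plastscreen.indel_coding`).

A column is *parsimony-informative* when at least two unambiguous states are
each present in at least two sequences; this is only defined for alignments
of four or more sequences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable

from .plastome_io import Alignment

UNAMBIGUOUS = frozenset("ACGT")
GAP = "-"

LABELS = (
    "invariant",
    "variable",
    "gap_containing_invariant",
    "gap_only",
    "ambiguous_only",
)


@dataclass
class SiteClassification:
    """Per-column labels and distinct unambiguous state counts."""

    labels: list[str]
    state_counts: list[Counter]

    @property
    def n_cols(self) -> int:
        return len(self.labels)

    def count(self, label: str) -> int:
        if label not in LABELS:
            raise ValueError(f"unknown column label {label!r}")
        return sum(1 for lab in self.labels if lab == label)


def _classify_column(column: Iterable[str]) -> tuple[str, Counter]:
    states = Counter()
    n_gap = 0
    n_other = 0
    for cell in column:
        if cell in UNAMBIGUOUS:
            states[cell] += 1
        elif cell == GAP:
            n_gap += 1
        else:
            n_other += 1
    if len(states) >= 2:
        return "variable", states
    if len(states) == 1:
        return ("gap_containing_invariant" if n_gap else "invariant"), states
    # no unambiguous nucleotide at all
    if n_gap and not n_other:
        return "gap_only", states
    return "ambiguous_only", states


def classify_sites(aln: Alignment) -> SiteClassification:
    """Label every alignment column.

    Ambiguity codes never create nor destroy a variable call; a column is
    variable iff ≥2 distinct A/C/G/T states are each carried by ≥1 sequence.
    """
    labels: list[str] = []
    counts: list[Counter] = []
    for j in range(aln.n_cols):
        label, states = _classify_column(aln.column(j))
        labels.append(label)
        counts.append(states)
    return SiteClassification(labels=labels, state_counts=counts)


def count_variable(aln: Alignment) -> int:
    """Number of variable columns in the alignment."""
    return classify_sites(aln).count("variable")


def count_parsimony_informative(aln: Alignment) -> int:
    """Number of parsimony-informative columns.

    Raises ``ValueError`` for alignments of fewer than four sequences, where
    the statistic is undefined.
    """
    if aln.n_rows < 4:
        raise ValueError(
            "parsimony-informative sites are undefined for alignments "
            f"with fewer than 4 sequences (got {aln.n_rows})"
        )
    n_pi = 0
    for j in range(aln.n_cols):
        states = Counter(c for c in aln.column(j) if c in UNAMBIGUOUS)
        if sum(1 for n in states.values() if n >= 2) >= 2:
            n_pi += 1
    return n_pi


def percent(count: int, total: int) -> float:
    """``100*count/total`` rounded half-up to one decimal place.

    Half-up rounding matches the convention of published screening tables
    (e.g. 56/884 → 6.3).
    """
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    value = Decimal(100 * count) / Decimal(total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class MarkerStats:
    """Per-marker variability tallies, as reported in screening tables.

    ``total_chars`` is the number of alignment columns including gap
    columns — published marker lengths are alignment lengths, not ungapped
    lengths. ``pi_sites`` is None for alignments of fewer than four
    sequences, where parsimony-informative counts are undefined.
    """

    marker: str
    clade: str
    total_chars: int
    variable: int
    indel_chars: int
    pi_sites: int | None = None

    def __post_init__(self) -> None:
        if self.variable > self.total_chars:
            raise ValueError(
                f"{self.marker}: variable ({self.variable}) exceeds "
                f"total characters ({self.total_chars})"
            )
        if self.indel_chars < 0:
            raise ValueError(f"{self.marker}: negative indel character count")

    @property
    def variable_plus_indels(self) -> int:
        return self.variable + self.indel_chars

    @property
    def variable_pct(self) -> float:
        return percent(self.variable, self.total_chars)

    @property
    def variable_plus_indels_pct(self) -> float:
        return percent(self.variable_plus_indels, self.total_chars)


def export_classification_tsv(
    aln: Alignment, path: str | Path, classification: SiteClassification | None = None
) -> None:
    """Write per-column classification as TSV (1-based column index)."""
    cls = classification or classify_sites(aln)
    with open(path, "w") as fh:
        fh.write("column\tlabel\tstates\n")
        for j, (label, states) in enumerate(zip(cls.labels, cls.state_counts), start=1):
            state_str = ",".join(f"{s}:{n}" for s, n in sorted(states.items()))
            fh.write(f"{j}\t{label}\t{state_str}\n")
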