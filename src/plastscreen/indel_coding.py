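"""Simple indel coding of alignment gaps as binary characters.

Gap runs with identical start and end boundaries across sequences are coded
as one presence/absence character each. A sequence whose own (longer) gap
strictly contains a character's interval cannot be scored for that event and
is marked missing ('?'). Terminal gap runs — those touching either alignment
edge — reflect sequencing extent rather than indel events and are excluded:
they found no character, and a sequence whose terminal gap covers a
character's interval is scored missing for it.

Only *variable* coded characters (both presence and absence observed among
scoreable sequences) contribute to the combined variable-plus-indels tally:
an indel shared by every sequence carries no phylogenetic information.
"""

from __future__ import annotations

from dataclasses import dataclass

from .plastome_io import Alignment
from .site_stats import MarkerStats, count_parsimony_informative, count_variable

PRESENT = "1"
ABSENT = "0"
MISSING = "?"


@dataclass(frozen=True)
class GapRun:
    """A maximal run of '-' cells in one alignment row."""

    seq_id: str
    interval: tuple[int, int]
    terminal: bool

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def end(self) -> int:
        return self.interval[1]


@dataclass
class IndelCharacterMatrix:
    """Binary indel characters: one per distinct shared-boundary gap interval.

    ``states[i]`` holds, for character ``i`` (ordered by interval), the
    per-sequence state string over {0, 1, ?} in alignment row order.
    """

    ids: list[str]
    intervals: list[tuple[int, int]]
    states: list[str]

    @property
    def n_characters(self) -> int:
        return len(self.intervals)

    def is_variable(self, i: int) -> bool:
        observed = {s for s in self.states[i] if s != MISSING}
        return PRESENT in observed and ABSENT in observed


def find_gap_runs(aln: Alignment) -> list[GapRun]:
    """All maximal per-row gap runs, flagged terminal at either edge."""
    runs: list[GapRun] = []
    n = aln.n_cols
    for seq_id, row in zip(aln.ids, aln.rows):
        j = 0
        while j < n:
            if row[j] == "-":
                start = j
                while j < n and row[j] == "-":
                    j += 1
                runs.append(
                    GapRun(
                        seq_id=seq_id,
                        interval=(start, j),
                        terminal=(start == 0 or j == n),
                    )
                )
            else:
                j += 1
    return runs


def _score_row(runs_by_row: list[GapRun], interval: tuple[int, int]) -> str:
    start, end = interval
    for run in runs_by_row:
        if run.interval == interval and not run.terminal:
            return PRESENT
        # any longer gap covering the interval makes the event unobservable;
        # a terminal gap covering it is missing data as well
        if run.start <= start and run.end >= end and run.interval != interval:
            return MISSING
        if run.interval == interval and run.terminal:
            return MISSING
    # nucleotides across (at least part of) the interval: the indel is absent
    return ABSENT


def simple_indel_coding(aln: Alignment) -> IndelCharacterMatrix:
    """Code non-terminal gap runs as binary characters.

    Characters are ordered by (start, end) so the coding is deterministic
    and invariant under row permutation.
    """
    runs = find_gap_runs(aln)
    intervals = sorted({r.interval for r in runs if not r.terminal})
    runs_per_row: dict[str, list[GapRun]] = {seq_id: [] for seq_id in aln.ids}
    for run in runs:
        runs_per_row[run.seq_id].append(run)
    states = []
    for interval in intervals:
        states.append(
            "".join(_score_row(runs_per_row[seq_id], interval) for seq_id in aln.ids)
        )
    return IndelCharacterMatrix(ids=list(aln.ids), intervals=intervals, states=states)


def count_indel_characters(matrix: IndelCharacterMatrix) -> int:
    """Number of coded characters that are variable (0 and 1 both observed)."""
    return sum(1 for i in range(matrix.n_characters) if matrix.is_variable(i))


def combined_variability(
    aln: Alignment, marker: str = "region", clade: str = ""
) -> MarkerStats:
    """Variable sites plus variable coded indel characters for one marker."""
    pi = count_parsimony_informative(aln) if aln.n_rows >= 4 else None
    return MarkerStats(
        marker=marker,
        clade=clade,
        total_chars=aln.n_cols,
        variable=count_variable(aln),
        indel_chars=count_indel_characters(simple_indel_coding(aln)),
        pi_sites=pi,
    )


def export_matrix_tsv(matrix: IndelCharacterMatrix, path) -> None:
    """Character matrix as TSV: one column per coded interval (1-based)."""
    with open(path, "w") as fh:
        header = "\t".join(
            f"indel_{start + 1}_{end}" for start, end in matrix.intervals
        )
        fh.write(f"id\t{header}\n")
        for i, seq_id in enumerate(matrix.ids):
            row = "\t".join(matrix.states[k][i] for k in range(matrix.n_characters))
            fh.write(f"{seq_id}\t{row}\n")


def export_matrix_phylip(matrix: IndelCharacterMatrix, path) -> None:
    """Relaxed PHYLIP-style 0/1/? matrix, appendable to an alignment."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.ids)} {matrix.n_characters}\n")
        for i, seq_id in enumerate(matrix.ids):
            chars = "".join(matrix.states[k][i] for k in range(matrix.n_characters))
            fh.write(f"{seq_id}  {chars}\n")
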