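"""Marker ranking within a clade and rank comparison across clades.

Markers are ranked by the absolute number of variable characters including
coded indels — the quantity that drives sequencing cost per informative
character — with a documented deterministic tie-break chain (variable
sites, then combined percentage, then name). Nuclear comparison markers
(ITS, waxy) are reported alongside but never ranked against plastid loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .site_stats import MarkerStats


@dataclass
class RankTable:
    """Ordered plastid markers of one clade with contiguous ranks."""

    clade: str
    entries: list[tuple[MarkerStats, int]]  # (stats, rank), rank 1..n
    key_description: str = (
        "descending variable_plus_indels; ties by variable, "
        "variable_plus_indels_pct, name"
    )

    def rank_of(self, marker: str) -> int:
        for stats, rank in self.entries:
            if stats.marker == marker:
                return rank
        raise KeyError(f"marker {marker!r} not in table for clade {self.clade!r}")

    def top(self, k: int) -> list[str]:
        return [stats.marker for stats, rank in self.entries if rank <= k]

    @property
    def markers(self) -> list[str]:
        return [stats.marker for stats, _ in self.entries]


@dataclass
class CladeComparison:
    """Per-marker rank shifts between two clades and top-k overlaps."""

    clade_a: str
    clade_b: str
    common: list[str]
    delta_rank: dict[str, int]  # rank_a − rank_b
    top3_overlap: set[str] = field(default_factory=set)
    top6_overlap: set[str] = field(default_factory=set)

    @property
    def consistently_top(self) -> set[str]:
        """Markers inside the top six of both clades."""
        return self.top6_overlap


def rank_markers(stats: list[MarkerStats], clade: str | None = None) -> RankTable:
    """Rank markers descending by variable sites plus coded indels."""
    if not stats:
        raise ValueError("cannot rank an empty marker list")
    names = [s.marker for s in stats]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate marker names: {dupes}")
    ordered = sorted(
        stats,
        key=lambda s: (
            -s.variable_plus_indels,
            -s.variable,
            -s.variable_plus_indels_pct,
            s.marker,
        ),
    )
    return RankTable(
        clade=clade or (stats[0].clade if stats[0].clade else ""),
        entries=[(s, i + 1) for i, s in enumerate(ordered)],
    )


def cross_clade_compare(a: RankTable, b: RankTable) -> CladeComparison:
    """Compare marker ranks between two clades over their shared markers."""
    common = [m for m in a.markers if m in set(b.markers)]
    if not common:
        raise ValueError(
            f"no shared markers between clades {a.clade!r} and {b.clade!r}"
        )
    delta = {m: a.rank_of(m) - b.rank_of(m) for m in common}
    return CladeComparison(
        clade_a=a.clade,
        clade_b=b.clade,
        common=common,
        delta_rank=delta,
        top3_overlap=set(a.top(3)) & set(b.top(3)) & set(common),
        top6_overlap=set(a.top(6)) & set(b.top(6)) & set(common),
    )


def _cell(count: int, pct: float) -> str:
    return f"{count} ({pct})"


def render_table(
    a: RankTable,
    b: RankTable,
    nuclear: list[MarkerStats] | None = None,
    fmt: str = "tsv",
) -> str:
    """Side-by-side clade comparison in the count-then-percent convention.

    Each clade contributes Total characters, Variable (%), Variable + indels
    (%), and Rank columns; a marker absent from one clade shows '-'. Nuclear
    rows are appended unranked. Markers in the top six of a clade are
    flagged with ``*`` next to their rank.
    """
    if fmt not in ("tsv", "markdown"):
        raise ValueError(f"unknown format {fmt!r}")
    markers = list(a.markers) + [m for m in b.markers if m not in set(a.markers)]
    header = [
        "marker",
        f"{a.clade}_total", f"{a.clade}_variable", f"{a.clade}_variable_plus_indels",
        f"{a.clade}_rank",
        f"{b.clade}_total", f"{b.clade}_variable", f"{b.clade}_variable_plus_indels",
        f"{b.clade}_rank",
    ]
    lines = [header]
    for marker in markers:
        row = [marker]
        for table in (a, b):
            try:
                rank = table.rank_of(marker)
                stats = next(s for s, _ in table.entries if s.marker == marker)
                flag = "*" if rank <= 6 else ""
                row += [
                    str(stats.total_chars),
                    _cell(stats.variable, stats.variable_pct),
                    _cell(stats.variable_plus_indels, stats.variable_plus_indels_pct),
                    f"{rank}{flag}",
                ]
            except KeyError:
                row += ["-", "-", "-", "-"]
        lines.append(row)
    for stats in nuclear or []:
        row = [stats.marker]
        # nuclear markers are shown for context but never ranked
        shown = [
            str(stats.total_chars),
            _cell(stats.variable, stats.variable_pct),
            _cell(stats.variable_plus_indels, stats.variable_plus_indels_pct),
            "unranked",
        ]
        if stats.clade == a.clade:
            row += shown + ["-", "-", "-", "-"]
        else:
            row += ["-", "-", "-", "-"] + shown
        lines.append(row)
    if fmt == "tsv":
        return "\n".join("\t".join(row) for row in lines) + "\n"
    out = ["| " + " | ".join(lines[0]) + " |"]
    out.append("|" + "---|" * len(lines[0]))
    out += ["| " + " | ".join(row) + " |" for row in lines[1:]]
    return "\n".join(out) + "\n"


def write_table(
    a: RankTable,
    b: RankTable,
    path: str | Path,
    nuclear: list[MarkerStats] | None = None,
    fmt: str = "tsv",
) -> None:
    Path(path).write_text(render_table(a, b, nuclear=nuclear, fmt=fmt))


def read_stats_tsv(path: str | Path) -> list[MarkerStats]:
    """Read a marker-stats TSV with columns marker, clade, total_chars,
    variable, indel_chars [, pi_sites]."""
    stats = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            rec = dict(zip(header, fields))
            pi = rec.get("pi_sites", "")
            stats.append(
                MarkerStats(
                    marker=rec["marker"],
                    clade=rec.get("clade", ""),
                    total_chars=int(rec["total_chars"]),
                    variable=int(rec["variable"]),
                    indel_chars=int(rec["indel_chars"]),
                    pi_sites=int(pi) if pi not in ("", "NA") else None,
                )
            )
    return stats


def write_stats_tsv(stats: list[MarkerStats], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\tclade\ttotal_chars\tvariable\tindel_chars\tpi_sites\n")
        for s in stats:
            pi = "NA" if s.pi_sites is None else str(s.pi_sites)
            fh.write(
                f"{s.marker}\t{s.clade}\t{s.total_chars}\t{s.variable}\t"
                f"{s.indel_chars}\t{pi}\n"
            )
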