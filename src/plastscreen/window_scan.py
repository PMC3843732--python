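"""Sliding-window variability scan over a whole-plastome alignment.

The scan counts variable columns in windows of 1,000 alignment columns
advanced in 100-column steps (the defaults), the scheme commonly used to
shortlist hypervariable ~1 kb regions in plastomes. Windows are
measured in alignment columns *including* gap columns, so every window spans
exactly the same number of columns; an ungapped-window mode instead sizes
each window to cover a fixed number of non-gap positions of a designated
reference row.

Top windows are merged into candidate regions and named from the annotation
of a reference genome ("geneA-geneB" spacers, or the gene itself when the
region mostly covers one gene), then large regions are split into near-equal
parts so their counts stay comparable to ~1 kb markers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .indel_coding import count_indel_characters, simple_indel_coding
from .plastome_io import Alignment, AnnotatedPlastome
from .site_stats import classify_sites, count_variable

DEFAULT_WINDOW = 1000
DEFAULT_STEP = 100


@dataclass
class WindowProfile:
    """Per-window variable-site counts across an alignment."""

    window_starts: list[int]
    window_size: int
    step: int
    values: list[int]
    identity_pct: list[float] | None = None
    truncated_last: bool = False

    def windows(self) -> list[tuple[int, int]]:
        return [(s, s + self.window_size) for s in self.window_starts]


@dataclass
class CandidateRegion:
    """A merged run of top-scoring windows, named from annotation."""

    interval: tuple[int, int]
    name: str
    variable: int = 0
    indel_chars: int = 0
    parts: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def end(self) -> int:
        return self.interval[1]

    def __len__(self) -> int:
        return self.end - self.start


def _variable_mask(aln: Alignment) -> np.ndarray:
    labels = classify_sites(aln).labels
    return np.fromiter((lab == "variable" for lab in labels), dtype=np.int64)


def _identity_track(
    aln: Alignment, reference: str, starts: list[int], window: int
) -> list[float]:
    """Mean pairwise identity (%) of each window vs the reference row,
    over columns where both sequences have a non-gap character."""
    ref = np.frombuffer(aln.row(reference).encode(), dtype=np.uint8)
    gap = ord("-")
    out = []
    others = [r for i, r in zip(aln.ids, aln.rows) if i != reference]
    encoded = [np.frombuffer(r.encode(), dtype=np.uint8) for r in others]
    for s in starts:
        sl = slice(s, s + window)
        ref_w = ref[sl]
        idents = []
        for row in encoded:
            row_w = row[sl]
            both = (ref_w != gap) & (row_w != gap)
            n = int(both.sum())
            idents.append(100.0 * float((ref_w[both] == row_w[both]).sum()) / n if n else 0.0)
        out.append(float(np.mean(idents)) if idents else 0.0)
    return out


def sliding_window_scan(
    aln: Alignment,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    reference: str | None = None,
    keep_truncated: bool = False,
    ungapped_window: bool = False,
) -> WindowProfile:
    """Count variable columns in sliding windows across the alignment.

    With ``ungapped_window`` the window covers ``window`` non-gap positions
    of the ``reference`` row (required then), so alignment-column spans vary
    per window; values are still variable-column counts within the span. By
    default the trailing truncated window is dropped so all values compare
    like for like.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if window > aln.n_cols:
        raise ValueError(
            f"window ({window}) exceeds alignment width ({aln.n_cols})"
        )
    mask = _variable_mask(aln)
    csum = np.concatenate([[0], np.cumsum(mask)])

    if ungapped_window:
        if reference is None:
            raise ValueError("ungapped_window requires a reference row id")
        ref_row = aln.row(reference)
        non_gap_cols = [j for j, c in enumerate(ref_row) if c != "-"]
        starts, values, spans = [], [], []
        for offset in range(0, len(non_gap_cols) - window + 1, step):
            col_start = non_gap_cols[offset]
            col_end = non_gap_cols[offset + window - 1] + 1
            starts.append(col_start)
            spans.append(col_end - col_start)
            values.append(int(csum[col_end] - csum[col_start]))
        profile = WindowProfile(
            window_starts=starts, window_size=window, step=step, values=values
        )
        if reference is not None and starts:
            profile.identity_pct = _identity_track(aln, reference, starts, window)
        return profile

    starts = list(range(0, aln.n_cols - window + 1, step))
    truncated = False
    last_full = starts[-1] if starts else 0
    if keep_truncated and last_full + window < aln.n_cols:
        starts.append(last_full + step)
        truncated = True
    values = [
        int(csum[min(s + window, aln.n_cols)] - csum[s]) for s in starts
    ]
    profile = WindowProfile(
        window_starts=starts,
        window_size=window,
        step=step,
        values=values,
        truncated_last=truncated,
    )
    if reference is not None:
        profile.identity_pct = _identity_track(aln, reference, starts, window)
    return profile


def top_windows(profile: WindowProfile, k: int = 20) -> list[tuple[int, int]]:
    """The ``k`` highest-valued windows; ties broken by lower start offset."""
    if k < 1:
        raise ValueError(f"k must be ≥ 1, got {k}")
    n = len(profile.window_starts)
    if k > n:
        warnings.warn(
            f"requested top {k} windows but profile has only {n}; returning all",
            stacklevel=2,
        )
        k = n
    order = sorted(
        range(n), key=lambda i: (-profile.values[i], profile.window_starts[i])
    )
    chosen = sorted(order[:k], key=lambda i: profile.window_starts[i])
    return [
        (profile.window_starts[i], profile.window_starts[i] + profile.window_size)
        for i in chosen
    ]


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _name_region(
    interval: tuple[int, int], genome: AnnotatedPlastome | None
) -> str:
    start, end = interval
    if genome is None:
        return f"region_{start + 1}_{end}"
    genes = [f for f in genome.features if f.kind in ("gene", "tRNA", "rRNA")]
    if not genes:
        return f"region_{start + 1}_{end}"
    # a region mostly inside one gene is named after that gene
    best = max(genes, key=lambda g: _overlap(interval, g.interval))
    if _overlap(interval, best.interval) >= 0.5 * (end - start):
        return best.name
    # otherwise a spacer named from the nearest flanking genes
    left = [g for g in genes if g.end <= start or (g.start < start < g.end)]
    right = [g for g in genes if g.start >= end or (g.start < end < g.end)]
    left_name = max(left, key=lambda g: g.end).name if left else "start"
    right_name = min(right, key=lambda g: g.start).name if right else "end"
    return f"{left_name}-{right_name}"


def merge_windows_to_regions(
    windows: list[tuple[int, int]],
    genome: AnnotatedPlastome | None = None,
    aln: Alignment | None = None,
    max_gap: int | None = None,
) -> list[CandidateRegion]:
    """Merge overlapping or near-adjacent windows into named regions.

    Windows separated by at most ``max_gap`` columns (default: the scan
    step, approximated as 100 when unknown) are merged. When the alignment
    is supplied, per-region variable-site and coded-indel counts are filled
    in; when a reference genome is supplied, regions are named from its
    annotation, otherwise by 1-based coordinates.
    """
    if not windows:
        return []
    if max_gap is None:
        max_gap = DEFAULT_STEP
    ordered = sorted(windows)
    merged: list[list[int]] = [list(ordered[0])]
    for start, end in ordered[1:]:
        if start <= merged[-1][1] + max_gap:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    regions = []
    for start, end in merged:
        region = CandidateRegion(
            interval=(start, end), name=_name_region((start, end), genome)
        )
        if aln is not None:
            sub = aln.slice_columns(start, min(end, aln.n_cols))
            region.variable = count_variable(sub)
            region.indel_chars = count_indel_characters(simple_indel_coding(sub))
        regions.append(region)
    return regions


def split_region(region: CandidateRegion, max_len: int = 1300) -> list[CandidateRegion]:
    """Split an oversized region into near-equal consecutive parts.

    Regions no longer than 1.4×``max_len`` are returned unsplit; longer
    regions are cut into ⌈length/max_len⌉ parts named "<name> part i".
    """
    if max_len < 500:
        raise ValueError(f"max_len must be ≥ 500, got {max_len}")
    length = len(region)
    if length <= 1.4 * max_len:
        return [region]
    n_parts = math.ceil(length / max_len)
    bounds = [
        region.start + round(i * length / n_parts) for i in range(n_parts + 1)
    ]
    parts = []
    for i in range(n_parts):
        parts.append(
            CandidateRegion(
                interval=(bounds[i], bounds[i + 1]),
                name=f"{region.name} part {i + 1}",
            )
        )
    region.parts = [p.interval for p in parts]
    return parts


def export_profile_tsv(profile: WindowProfile, path) -> None:
    """Profile as TSV with 1-based inclusive window coordinates."""
    with open(path, "w") as fh:
        cols = "start\tend\tvariable_count"
        if profile.identity_pct is not None:
            cols += "\tidentity_pct"
        fh.write(cols + "\n")
        for i, s in enumerate(profile.window_starts):
            line = f"{s + 1}\t{s + profile.window_size}\t{profile.values[i]}"
            if profile.identity_pct is not None:
                line += f"\t{profile.identity_pct[i]:.2f}"
            fh.write(line + "\n")


def export_regions_tsv(regions: list[CandidateRegion], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tstart\tend\tvariable\tindel_chars\n")
        for r in regions:
            fh.write(
                f"{r.name}\t{r.start + 1}\t{r.end}\t{r.variable}\t{r.indel_chars}\n"
            )
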