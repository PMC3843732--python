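"""Plastome-like synthetic data with known ground truth.

Every pipeline stage — site counting, indel coding, window scanning,
Ka/Ks estimation, IR checking — is testable against data whose true
variable columns, indel intervals and substitution classes are known by
construction. Mutations are placed star-wise (each variant assigned
independently to a random proper, non-empty subset of taxa) at distinct
columns, so in this homoplasy-free regime recovered counts must equal the
planted ones exactly. This trades realism (no shared tree structure, no
rate heterogeneity) for exact truth, which is what recovery tests need.

Indels are planted as shared-boundary gap intervals disjoint from planted
variable columns and from each other; each is therefore exactly one variable
coded character under simple indel coding. A nested-gap mode plants one gap
strictly inside a longer gap of another taxon to exercise missing-data
('?') scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .plastome_io import Alignment, AnnotatedPlastome, Feature, reverse_complement
from .selection import (
    STOP_CODONS,
    synonymous_site_fraction,
    translate_codon,
)

BASES = "ACGT"
REGION_KINDS = ("spacer", "CDS", "IR", "gene")


@dataclass
class RegionSpec:
    """One architectural block of the simulated plastome."""

    name: str
    length: int
    kind: str = "spacer"
    rate: float = 0.0  # expected variable sites per column
    n_variants: int | None = None  # exact planted count, overrides rate
    n_indels: int = 0
    indel_len: tuple[int, int] = (3, 9)
    nested_indels: int = 0  # extra nested gaps, exercising '?' scoring
    omega: float | None = None  # CDS only: target Ka/Ks for planted subs
    n_subs: int = 0  # CDS only: planted substitutions when omega is set

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"region {self.name!r}: length must be positive")
        if self.kind not in REGION_KINDS:
            raise ValueError(f"region {self.name!r}: unknown kind {self.kind!r}")
        if not 0 <= self.rate < 1:
            raise ValueError(f"region {self.name!r}: rate must be in [0, 1)")
        if self.kind == "CDS" and self.length % 3:
            raise ValueError(f"CDS region {self.name!r}: length not divisible by 3")
        if self.kind == "IR" and (self.rate or self.n_indels or self.nested_indels):
            raise ValueError(
                f"IR region {self.name!r}: IR copies are mutation-free by "
                "construction (concerted evolution); plant no events there"
            )


@dataclass
class SimulationSpec:
    """A clade-alignment or plastome-trio simulation recipe."""

    n_taxa: int
    regions: list[RegionSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        n_ir = sum(1 for r in self.regions if r.kind == "IR")
        if n_ir not in (0, 2):
            raise ValueError(
                f"IR regions must occur exactly twice (got {n_ir}); the second "
                "copy receives the reverse complement of the first"
            )

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.regions)


@dataclass
class GroundTruth:
    """Planted events, in alignment coordinates."""

    variable_columns: dict[str, list[int]] = field(default_factory=dict)
    indel_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    nested_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    cds_substitutions: dict[str, tuple[int, int]] = field(default_factory=dict)  # (Sd, Nd)
    region_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_variable(self) -> int:
        return sum(len(v) for v in self.variable_columns.values())

    @property
    def n_indel_characters(self) -> int:
        return sum(len(v) for v in self.indel_intervals.values())


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(rng.choice(list(BASES), size=3))
        if codon not in STOP_CODONS:
            return codon


def _ancestral_sequence(region: RegionSpec, rng: np.random.Generator) -> str:
    if region.kind == "CDS":
        return "".join(_random_codon(rng) for _ in range(region.length // 3))
    return "".join(rng.choice(list(BASES), size=region.length))


def _proper_subset(n_taxa: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of a random non-empty proper subset of taxa."""
    while True:
        mask = rng.random(n_taxa) < 0.5
        if 0 < mask.sum() < n_taxa:
            return np.flatnonzero(mask)


def _synonymous_alternatives(codon: str) -> list[tuple[int, str]]:
    aa = translate_codon(codon)
    out = []
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and translate_codon(mutant) == aa:
                out.append((pos, base))
    return out


def _nonsynonymous_alternatives(codon: str) -> list[tuple[int, str]]:
    aa = translate_codon(codon)
    out = []
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and translate_codon(mutant) != aa:
                out.append((pos, base))
    return out


def simulate_codon_pair(
    codons: int, omega: float, subs: int, seed: int
) -> tuple[str, str, tuple[int, int]]:
    """An ancestral codon row and a mutated copy with known (Sd, Nd).

    Substitution events follow the selection model the estimator assumes:
    each event proposes a uniform random single-base change (stop-creating
    proposals are discarded, reflecting lethality) and nonsynonymous
    proposals are accepted with relative probability ω. Multiple hits per
    codon — including reversals — are allowed, which is exactly what the
    Jukes–Cantor correction downstream is there to undo. The realized event
    counts (Sd, Nd) are returned as truth.
    """
    if subs > 3 * codons:
        raise ValueError(f"cannot place {subs} substitutions in {codons} codons")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    rng = np.random.default_rng(seed)
    ancestor = [_random_codon(rng) for _ in range(codons)]
    derived = list(ancestor)
    accept_norm = max(omega, 1.0)
    sd = nd = 0
    placed = 0
    proposals = 0
    max_proposals = 10_000 * max(subs, 1)
    while placed < subs:
        proposals += 1
        if proposals > max_proposals:
            raise ValueError(
                f"omega/subs combination infeasible: placed {placed} of "
                f"{subs} substitutions after {proposals} proposals"
            )
        idx = int(rng.integers(codons))
        pos = int(rng.integers(3))
        base = BASES[rng.integers(4)]
        codon = derived[idx]
        if base == codon[pos]:
            continue
        mutant = codon[:pos] + base + codon[pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        synonymous = translate_codon(mutant) == translate_codon(codon)
        weight = 1.0 if synonymous else omega
        if rng.random() < weight / accept_norm:
            derived[idx] = mutant
            sd += synonymous
            nd += not synonymous
            placed += 1
    return "".join(ancestor), "".join(derived), (sd, nd)


def _plant_region_events(
    region: RegionSpec,
    offset: int,
    columns: np.ndarray,  # (n_taxa, length) uint8-coded characters
    rng: np.random.Generator,
    truth: GroundTruth,
) -> None:
    """Plant substitutions (or codon-aware CDS substitutions) and indels
    into one region of the alignment matrix, recording truth."""
    n_taxa, _ = columns.shape
    length = region.length
    taken = np.zeros(length, dtype=bool)  # columns already used by an event

    # --- indels first: they need runs of free columns -------------------
    intervals: list[tuple[int, int]] = []
    lo, hi = region.indel_len
    for _ in range(region.n_indels):
        size = int(rng.integers(lo, hi + 1))
        for _attempt in range(200):
            start = int(rng.integers(1, max(length - size, 2)))  # non-terminal
            # a one-column buffer keeps runs in the same row from fusing,
            # which would shift character boundaries away from the truth
            pad = taken[max(start - 1, 0) : start + size + 1]
            if not pad.any() and start + size < length:
                break
        else:
            raise ValueError(
                f"region {region.name!r}: cannot place indel of length {size}; "
                "too many events for region length"
            )
        taken[start : start + size] = True
        carriers = _proper_subset(n_taxa, rng)
        for t in carriers:
            columns[t, start : start + size] = ord("-")
        intervals.append((offset + start, offset + start + size))
    if intervals:
        truth.indel_intervals[region.name] = sorted(intervals)

    # nested gaps: a longer gap in one taxon strictly containing a shorter
    # shared gap in others; the contained interval scores '?' for the long row
    nested: list[tuple[int, int]] = []
    for _ in range(region.nested_indels):
        if n_taxa < 3:
            raise ValueError("nested indels need at least 3 taxa")
        size = int(rng.integers(lo, hi + 1))
        outer = size + 4
        for _attempt in range(200):
            start = int(rng.integers(1, max(length - outer, 2)))
            pad = taken[max(start - 1, 0) : start + outer + 1]
            if not pad.any() and start + outer < length:
                break
        else:
            raise ValueError(f"region {region.name!r}: cannot place nested indel")
        taken[start : start + outer] = True
        inner = (start + 2, start + 2 + size)
        taxa = rng.permutation(n_taxa)
        long_taxon, short_taxon = int(taxa[0]), int(taxa[1])
        columns[long_taxon, start : start + outer] = ord("-")
        columns[short_taxon, inner[0] : inner[1]] = ord("-")
        nested.append((offset + inner[0], offset + inner[1]))
    if nested:
        truth.nested_intervals[region.name] = nested

    # --- substitutions ---------------------------------------------------
    if region.kind == "CDS" and region.omega is not None:
        _plant_cds_substitutions(region, offset, columns, taken, rng, truth)
        return
    n_var = (
        region.n_variants
        if region.n_variants is not None
        else round(region.rate * length)
    )
    free = np.flatnonzero(~taken)
    if n_var > free.size:
        raise ValueError(
            f"region {region.name!r}: {n_var} variants requested but only "
            f"{free.size} free columns"
        )
    chosen = rng.choice(free, size=n_var, replace=False) if n_var else np.array([], int)
    var_cols = []
    for col in sorted(int(c) for c in chosen):
        ref = chr(columns[0, col])
        alt = rng.choice([b for b in BASES if b != ref])
        carriers = _proper_subset(n_taxa, rng)
        for t in carriers:
            columns[t, col] = ord(alt)
        var_cols.append(offset + col)
    if var_cols:
        truth.variable_columns[region.name] = var_cols


def _plant_cds_substitutions(
    region: RegionSpec,
    offset: int,
    columns: np.ndarray,
    taken: np.ndarray,
    rng: np.random.Generator,
    truth: GroundTruth,
) -> None:
    n_taxa = columns.shape[0]
    ancestor_row = bytes(columns[0]).decode()
    n_codons = region.length // 3
    s_sites = sum(
        synonymous_site_fraction(ancestor_row[3 * j : 3 * j + 3])
        for j in range(n_codons)
    )
    n_sites = 3 * n_codons - s_sites
    p_syn = 1.0 / (1.0 + region.omega * n_sites / s_sites)
    syn_left = round(region.n_subs * p_syn)
    nonsyn_left = region.n_subs - syn_left
    sd = nd = 0
    var_cols = []
    for cj in rng.permutation(n_codons):
        if syn_left == 0 and nonsyn_left == 0:
            break
        if taken[3 * cj : 3 * cj + 3].any():
            continue
        codon = ancestor_row[3 * cj : 3 * cj + 3]
        want_syn = syn_left > 0 and (
            nonsyn_left == 0 or rng.random() < syn_left / (syn_left + nonsyn_left)
        )
        options = (
            _synonymous_alternatives(codon)
            if want_syn
            else _nonsynonymous_alternatives(codon)
        )
        if not options:
            want_syn = not want_syn
            if (syn_left if want_syn else nonsyn_left) == 0:
                continue
            options = (
                _synonymous_alternatives(codon)
                if want_syn
                else _nonsynonymous_alternatives(codon)
            )
            if not options:
                continue
        pos, base = options[rng.integers(len(options))]
        col = 3 * int(cj) + pos
        taken[3 * cj : 3 * cj + 3] = True
        carriers = _proper_subset(n_taxa, rng)
        for t in carriers:
            columns[t, col] = ord(base)
        if want_syn:
            sd += 1
            syn_left -= 1
        else:
            nd += 1
            nonsyn_left -= 1
        var_cols.append(offset + col)
    if syn_left or nonsyn_left:
        raise ValueError(
            f"CDS region {region.name!r}: only {sd + nd} of {region.n_subs} "
            "substitutions could be placed"
        )
    truth.cds_substitutions[region.name] = (sd, nd)
    if var_cols:
        truth.variable_columns[region.name] = sorted(var_cols)


def simulate_clade_alignment(spec: SimulationSpec) -> tuple[Alignment, GroundTruth]:
    """Simulate a clade alignment with planted, recoverable events.

    Deterministic under a fixed seed: identical specs give byte-identical
    alignments.
    """
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth()
    ancestral_parts: list[str] = []
    ir_content: str | None = None
    offset = 0
    for region in spec.regions:
        if region.kind == "IR":
            if ir_content is None:
                seq = _ancestral_sequence(region, rng)
                ir_content = seq
            else:
                if region.length != len(ir_content):
                    raise ValueError("the two IR regions must have equal length")
                seq = reverse_complement(ir_content)
        else:
            seq = _ancestral_sequence(region, rng)
        truth.region_intervals[region.name] = (offset, offset + region.length)
        ancestral_parts.append(seq)
        offset += region.length
    ancestor = "".join(ancestral_parts)
    matrix = np.tile(
        np.frombuffer(ancestor.encode(), dtype=np.uint8), (spec.n_taxa, 1)
    ).copy()
    offset = 0
    seen_ir = False
    for region in spec.regions:
        if region.kind == "IR" and seen_ir:
            offset += region.length
            continue  # second IR copy stays the untouched reverse complement
        if region.kind == "IR":
            seen_ir = True
        _plant_region_events(
            region, offset, matrix[:, offset : offset + region.length], rng, truth
        )
        offset += region.length
    rows = [bytes(matrix[t]).decode() for t in range(spec.n_taxa)]
    ids = [f"taxon{t + 1}" for t in range(spec.n_taxa)]
    return Alignment(ids=ids, rows=rows), truth


def _trio_features(spec: SimulationSpec) -> list[Feature]:
    features = []
    offset = 0
    for region in spec.regions:
        interval = (offset, offset + region.length)
        if region.kind in ("gene", "CDS"):
            features.append(
                Feature(name=region.name, kind="gene", interval=interval)
            )
            if region.kind == "CDS":
                features.append(
                    Feature(name=region.name, kind="CDS", interval=interval)
                )
        elif region.kind == "IR":
            features.append(Feature(name=region.name, kind="IR", interval=interval))
        offset += region.length
    return features


def simulate_plastome_trio(
    spec: SimulationSpec,
) -> tuple[list[AnnotatedPlastome], Alignment, GroundTruth]:
    """Three aligned, annotated plastome-like genomes.

    Substitution-only (no indels), so each alignment row is also the genome
    sequence and annotation coordinates are shared. The two IR blocks are
    mutation-free reverse complements of each other; regions with elevated
    rates are the expected top windows of a scan.
    """
    if spec.n_taxa != 3:
        spec = SimulationSpec(n_taxa=3, regions=spec.regions, seed=spec.seed)
    for region in spec.regions:
        if region.n_indels or region.nested_indels:
            raise ValueError(
                "plastome trio simulation is substitution-only; plant indels "
                "with simulate_clade_alignment instead"
            )
    aln, truth = simulate_clade_alignment(spec)
    features = _trio_features(spec)
    accessions = ["SYN000001", "SYN000002", "SYN000003"]
    genomes = [
        AnnotatedPlastome(id=acc, sequence=row, features=list(features))
        for acc, row in zip(accessions, aln.rows)
    ]
    aln = Alignment(ids=accessions, rows=list(aln.rows))
    return genomes, aln, truth


def default_trio_spec(seed: int = 0) -> SimulationSpec:
    """A scaled-down quadripartite plastome architecture (~25 kb).

    Hot spacers and the ycf1 CDS carry elevated substitution rates against a
    quiet background, emulating the handful of hypervariable ~1 kb regions
    that stand out of a congeneric plastome comparison; the IR pair is
    mutation-free, as expected under concerted evolution.
    """
    quiet, hot = 0.004, 0.045
    regions = [
        RegionSpec("trnK", 400, "gene", rate=quiet),
        RegionSpec("trnK-rps16 spacer", 1100, "spacer", rate=hot),
        RegionSpec("rps16", 900, "gene", rate=quiet),
        RegionSpec("lsc spacer 1", 2200, "spacer", rate=quiet),
        RegionSpec("clpP", 800, "gene", rate=quiet),
        RegionSpec("clpP-psbB spacer", 1200, "spacer", rate=hot),
        RegionSpec("psbB", 1100, "gene", rate=quiet),
        RegionSpec("lsc spacer 2", 2400, "spacer", rate=quiet),
        RegionSpec("IRa", 3000, "IR"),
        RegionSpec("ndhF", 990, "CDS", omega=0.15, n_subs=18),
        RegionSpec("ndhF-rpl32 spacer", 1000, "spacer", rate=hot),
        # deliberately oversized vs the real gene so the two flanking hot
        # spacers resolve as separate candidate regions at the default step
        RegionSpec("rpl32", 1400, "gene", rate=quiet),
        RegionSpec("rpl32-trnL spacer", 1000, "spacer", rate=hot),
        RegionSpec("trnL", 120, "gene", rate=quiet),
        RegionSpec("ssc spacer 1", 1000, "spacer", rate=quiet),
        RegionSpec("ycf1", 2100, "CDS", omega=0.3, n_subs=95),
        RegionSpec("ssc spacer 2", 900, "spacer", rate=quiet),
        RegionSpec("IRb", 3000, "IR"),
    ]
    return SimulationSpec(n_taxa=3, regions=regions, seed=seed)


def simulate_marker_alignment(
    n_taxa: int,
    total_chars: int,
    n_variable: int,
    n_indels: int,
    seed: int,
    name: str = "marker",
) -> tuple[Alignment, GroundTruth]:
    """Synthetic stand-in for a single marker alignment with exact planted
    counts: ``n_variable`` variable columns and ``n_indels`` shared-boundary
    indel characters over ``total_chars`` alignment columns.

    Used to exercise the measurement pipeline at the per-marker tallies
    reported in published screens when the original alignment files are not
    distributed with the package; the data are synthetic, only the planted
    counts match the published cells.
    """
    spec = SimulationSpec(
        n_taxa=n_taxa,
        regions=[
            RegionSpec(
                name,
                total_chars,
                "spacer",
                n_variants=n_variable,
                n_indels=n_indels,
            )
        ],
        seed=seed,
    )
    return simulate_clade_alignment(spec)


def read_spec_config(path) -> SimulationSpec:
    """Read a simulation spec from a plain key/value + region-lines config.

    Format::

        n_taxa = 12
        seed = 42
        # name kind length rate n_indels [omega n_subs]
        region spacerA spacer 800 0.02 3
        region cds1 CDS 300 0 0 0.1 10
    """
    n_taxa, seed = 2, 0
    regions: list[RegionSpec] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("region"):
                parts = line.split()
                name, kind, length, rate, n_indels = parts[1:6]
                kwargs = {}
                if len(parts) >= 8:
                    kwargs = {"omega": float(parts[6]), "n_subs": int(parts[7])}
                regions.append(
                    RegionSpec(
                        name=name,
                        kind=kind,
                        length=int(length),
                        rate=float(rate),
                        n_indels=int(n_indels),
                        **kwargs,
                    )
                )
            else:
                key, _, value = line.partition("=")
                key = key.strip()
                if key == "n_taxa":
                    n_taxa = int(value)
                elif key == "seed":
                    seed = int(value)
                else:
                    raise ValueError(f"unknown config key {key!r}")
    return SimulationSpec(n_taxa=n_taxa, regions=regions, seed=seed)


def write_truth_tsv(truth: GroundTruth, path) -> None:
    """Ground truth as TSV (1-based inclusive coordinates for display)."""
    with open(path, "w") as fh:
        fh.write("region\tevent\tdetail\n")
        for name, cols in sorted(truth.variable_columns.items()):
            fh.write(f"{name}\tvariable_columns\t{','.join(str(c + 1) for c in cols)}\n")
        for name, ivs in sorted(truth.indel_intervals.items()):
            detail = ",".join(f"{s + 1}-{e}" for s, e in ivs)
            fh.write(f"{name}\tindel_intervals\t{detail}\n")
        for name, (sd, nd) in sorted(truth.cds_substitutions.items()):
            fh.write(f"{name}\tcds_substitutions\tSd={sd},Nd={nd}\n")
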