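"""Pairwise Ka/Ks estimation for coding portions of candidate markers.

Implements the Nei–Gojobori (1986) unweighted pathway method with
Jukes–Cantor distance correction. For each codon, synonymous site content is
the expected fraction of the three possible changes at each position that
preserve the amino acid (changes to stop codons count as nonsynonymous);
observed differences between two codons are partitioned over all minimal
mutational pathways with equal weight, excluding pathways that pass through
a stop codon (unless every pathway does). Proportions are corrected by
d = −(3/4)·ln(1 − (4/3)p), and ω = Ka/Ks.

This simple counting estimator is adequate at the low divergences seen
between congeneric plastomes; likelihood codon models are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from statistics import mean

from Bio.Data.CodonTable import standard_dna_table

from .plastome_io import Alignment, Feature, reverse_complement
from .site_stats import UNAMBIGUOUS

CODON_TABLE = standard_dna_table.forward_table  # plastid CDS use the standard code
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
BASES = "ACGT"


def translate_codon(codon: str) -> str:
    if codon in STOP_CODONS:
        return "*"
    return CODON_TABLE[codon]


@dataclass
class CodonAlignment:
    """Gap-free, in-frame codon rows extracted from a marker alignment."""

    ids: list[str]
    rows: list[str]
    source_interval: tuple[int, int] | None = None

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3

    def codons(self, i: int) -> list[str]:
        row = self.rows[i]
        return [row[3 * j : 3 * j + 3] for j in range(self.n_codons)]


@dataclass
class KaKsResult:
    """Nei–Gojobori substitution-rate estimates for one sequence pair."""

    ka: float
    ks: float
    n_sites: float
    s_sites: float
    nd: float
    sd: float

    @property
    def ratio(self) -> float | None:
        """Ka/Ks, or None when Ks = 0 (ratio undefined)."""
        if self.ks == 0:
            return None
        return self.ka / self.ks


def extract_codon_alignment(aln: Alignment, cds: Feature) -> CodonAlignment:
    """Slice a CDS out of a marker alignment and clean it to whole codons.

    The CDS interval addresses alignment columns. Minus-strand CDS are
    reverse-complemented before framing. Codon columns containing any gap or
    ambiguity code in any row are dropped in all rows; an internal stop in
    any remaining row is an error naming the row and codon.
    """
    start, end = cds.interval
    sub = aln.slice_columns(start, end)
    rows = sub.rows
    if cds.strand == "-":
        rows = [reverse_complement(r) for r in rows]
    width = 3 * (len(rows[0]) // 3)
    rows = [r[:width] for r in rows]
    kept: list[list[str]] = [[] for _ in rows]
    for j in range(width // 3):
        codons = [r[3 * j : 3 * j + 3] for r in rows]
        if all(all(c in UNAMBIGUOUS for c in codon) for codon in codons):
            for store, codon in zip(kept, codons):
                store.append(codon)
    clean = ["".join(cs) for cs in kept]
    if not clean[0]:
        raise ValueError(
            f"CDS {cds.name!r}: no complete gap-free codons in alignment slice"
        )
    n_codons = len(clean[0]) // 3
    for seq_id, row in zip(aln.ids, clean):
        for j in range(n_codons):
            codon = row[3 * j : 3 * j + 3]
            if codon in STOP_CODONS and j < n_codons - 1:
                raise ValueError(
                    f"CDS {cds.name!r}: internal stop codon in {seq_id!r} "
                    f"at codon {j + 1}"
                )
    return CodonAlignment(ids=list(aln.ids), rows=clean, source_interval=cds.interval)


def synonymous_site_fraction(codon: str) -> float:
    """Expected number of synonymous sites in one codon (0–3).

    Each position contributes the fraction of its possible changes that are
    synonymous. Mutations creating stop codons are eliminated from the
    count (numerator and denominator), reflecting their removal by
    lethality rather than charging them as nonsynonymous.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no defined site content")
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            non_stop += 1
            if translate_codon(mutant) == aa:
                syn += 1
        if non_stop:
            s += syn / non_stop
    return s


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts for
    one codon pair, weighting all minimal mutational pathways equally and
    skipping pathways that pass through a stop codon when any stop-free
    pathway exists."""
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff_positions):
        current = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            elif current in STOP_CODONS:
                blocked = True
            else:
                if translate_codon(current) == translate_codon(nxt):
                    sd += 1
                else:
                    nd += 1
            current = nxt
        pathways.append((blocked, sd, nd))
    usable = [(sd, nd) for blocked, sd, nd in pathways if not blocked]
    if not usable:
        # all pathways pass a stop: fall back to counting every step anyway
        usable = []
        for order in permutations(diff_positions):
            current = codon_a
            sd = nd = 0
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                if translate_codon(current) == translate_codon(nxt):
                    sd += 1
                else:
                    nd += 1
                current = nxt
            usable.append((sd, nd))
    return (
        sum(s for s, _ in usable) / len(usable),
        sum(n for _, n in usable) / len(usable),
    )


def jukes_cantor(p: float) -> float:
    """JC69 correction of a proportion of differing sites."""
    if p < 0:
        raise ValueError("proportion cannot be negative")
    if p >= 0.75:
        raise ValueError(
            f"proportion {p:.3f} ≥ 3/4: Jukes–Cantor correction undefined"
        )
    if p == 0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori(row_a: str, row_b: str) -> KaKsResult:
    """Nei–Gojobori Ka/Ks for an equal-length, gap-free codon row pair."""
    if len(row_a) != len(row_b):
        raise ValueError("codon rows differ in length")
    if len(row_a) % 3:
        raise ValueError("codon row length not divisible by 3")
    n_codons = len(row_a) // 3
    if n_codons == 0:
        raise ValueError("empty codon rows")
    s_sites = 0.0
    sd = nd = 0.0
    for j in range(n_codons):
        ca = row_a[3 * j : 3 * j + 3]
        cb = row_b[3 * j : 3 * j + 3]
        s_sites += 0.5 * (synonymous_site_fraction(ca) + synonymous_site_fraction(cb))
        s_j, n_j = _pathway_counts(ca, cb)
        sd += s_j
        nd += n_j
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return KaKsResult(
        ka=jukes_cantor(pn),
        ks=jukes_cantor(ps),
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
    )


def classify_selection(result: KaKsResult, min_differences: int = 5) -> str:
    """Selection regime from a Ka/Ks estimate.

    ω < 0.9 → purifying; 0.9 ≤ ω ≤ 1.1 → near-neutral; ω > 1.1 → positive.
    Undefined ratios (Ks = 0) or fewer than ``min_differences`` observed
    differences give 'undetermined' — too little signal to call a regime.
    """
    ratio = result.ratio
    if ratio is None or (result.nd + result.sd) < min_differences:
        return "undetermined"
    if ratio < 0.9:
        return "purifying"
    if ratio <= 1.1:
        return "near_neutral"
    return "positive"


def region_kaks(codon_aln: CodonAlignment) -> tuple[float | None, list[KaKsResult]]:
    """Mean Ka/Ks over all pairs with defined Ks, plus per-pair results."""
    results = []
    ratios = []
    n = len(codon_aln.rows)
    for i in range(n):
        for j in range(i + 1, n):
            res = nei_gojobori(codon_aln.rows[i], codon_aln.rows[j])
            results.append(res)
            if res.ratio is not None:
                ratios.append(res.ratio)
    return (mean(ratios) if ratios else None), results


def pooled_kaks(results: list[KaKsResult]) -> float | None:
    """One Ka/Ks estimate from summed counts over many pairs/replicates.

    Pooling the observed differences and site counts before forming the
    ratio avoids the strong right skew of averaging per-pair ratios when
    synonymous counts are small. Returns None when the pooled Ks is 0.
    """
    if not results:
        raise ValueError("no results to pool")
    sd = sum(r.sd for r in results)
    nd = sum(r.nd for r in results)
    s_sites = sum(r.s_sites for r in results)
    n_sites = sum(r.n_sites for r in results)
    ks = jukes_cantor(sd / s_sites)
    ka = jukes_cantor(nd / n_sites)
    return None if ks == 0 else ka / ks


def export_kaks_tsv(region: str, codon_aln: CodonAlignment, path) -> None:
    """Per-pair Ka/Ks table for one coding region."""
    with open(path, "w") as fh:
        fh.write(
            "region\tpair\tNd\tSd\tN_sites\tS_sites\tKa\tKs\tratio\tclass\n"
        )
        n = len(codon_aln.rows)
        for i in range(n):
            for j in range(i + 1, n):
                res = nei_gojobori(codon_aln.rows[i], codon_aln.rows[j])
                ratio = "NA" if res.ratio is None else f"{res.ratio:.4f}"
                fh.write(
                    f"{region}\t{codon_aln.ids[i]}|{codon_aln.ids[j]}\t"
                    f"{res.nd:.2f}\t{res.sd:.2f}\t{res.n_sites:.2f}\t"
                    f"{res.s_sites:.2f}\t{res.ka:.4f}\t{res.ks:.4f}\t"
                    f"{ratio}\t{classify_selection(res)}\n"
                )
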