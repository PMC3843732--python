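"""Concerted-evolution check of the two plastid inverted-repeat copies.

The two IR copies of a plastome are homogenised by concerted evolution and
expected to be identical in reverse complement. The check is alignment-free:
copy B is reverse-complemented and compared position by position in copy-A
orientation. Near-identical copies need no realignment; the check validates
identity, not homology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .plastome_io import IUPAC_NUCLEOTIDES, reverse_complement


@dataclass
class IdentityReport:
    """Outcome of comparing two IR copies in reverse complement."""

    compared_length: int
    n_mismatches: int
    mismatch_positions: list[int] = field(default_factory=list)  # 1-based, copy-A orientation
    length_a: int = 0
    length_b: int = 0
    note: str = ""

    @property
    def identical(self) -> bool:
        return self.n_mismatches == 0 and self.length_a == self.length_b


def _validate(seq: str, label: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{label} is empty")
    bad = set(seq) - IUPAC_NUCLEOTIDES
    if bad:
        raise ValueError(f"{label} contains non-nucleotide characters: {sorted(bad)}")
    return seq


def compare_ir_copies(
    copy_a: str, copy_b: str, end_trim: int = 0
) -> IdentityReport:
    """Compare IRa against reverse-complemented IRb.

    Unequal lengths never count as identical; mismatches are still reported
    after end-trimming to the shorter length. ``end_trim`` (≤ 5) additionally
    ignores up to that many positions at each end, tolerating slightly
    different annotated IR boundaries.
    """
    if not 0 <= end_trim <= 5:
        raise ValueError("end_trim must be between 0 and 5")
    a = _validate(copy_a, "copy A")
    b = reverse_complement(_validate(copy_b, "copy B"))
    n = min(len(a), len(b))
    lo, hi = end_trim, n - end_trim
    mism = [i + 1 for i in range(lo, hi) if a[i] != b[i]]
    note = ""
    if len(a) != len(b):
        note = f"lengths differ ({len(a)} vs {len(b)}); compared first {n} bp"
    return IdentityReport(
        compared_length=max(hi - lo, 0),
        n_mismatches=len(mism),
        mismatch_positions=mism,
        length_a=len(a),
        length_b=len(b),
        note=note,
    )


def export_report_tsv(report: IdentityReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("compared_length\tn_mismatches\tidentical\tpositions\tnote\n")
        pos = ",".join(map(str, report.mismatch_positions)) or "-"
        fh.write(
            f"{report.compared_length}\t{report.n_mismatches}\t"
            f"{report.identical}\t{pos}\t{report.note or '-'}\n"
        )
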