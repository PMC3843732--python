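"""Published Solanum screening counts, shipped as reference input data.

The packaged table holds per-marker variable-site and coded-indel counts
for the Potato and Morelloid clades of *Solanum* — the printed results of a
hypervariable plastid-marker screen. They serve as inputs for rank
arithmetic and cross-clade comparison without redoing the underlying
sequencing, and as targets that a re-measurement from the original marker
alignments should reproduce.
"""

from __future__ import annotations

from importlib import resources

from .site_stats import MarkerStats

_DATA = "solanum_screening_counts.tsv"


def load_published_counts(clade: str | None = None, nuclear: bool | None = None) -> list[MarkerStats]:
    """Marker stats from the packaged Solanum screening table.

    ``clade`` filters to 'Potato' or 'Morelloid'; ``nuclear`` selects
    nuclear (True), plastid (False) or all (None) markers.
    """
    text = (resources.files("plastscreen") / "data" / _DATA).read_text()
    out: list[MarkerStats] = []
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        rec = dict(zip(header, fields))
        if clade is not None and rec["clade"] != clade:
            continue
        is_nuclear = rec["nuclear"] == "1"
        if nuclear is not None and is_nuclear != nuclear:
            continue
        out.append(
            MarkerStats(
                marker=rec["marker"],
                clade=rec["clade"],
                total_chars=int(rec["total_chars"]),
                variable=int(rec["variable"]),
                indel_chars=int(rec["indel_chars"]),
            )
        )
    return out
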