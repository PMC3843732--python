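# plastscreen

Screening plastid genomes for hypervariable phylogenetic markers.

## The problem

Non-coding plastid regions (introns and intergenic spacers) are the
workhorse markers of species-level plant phylogenetics, but most of them
carry too little variation to resolve relationships in species-rich groups.
When a few complete plastomes from closely related species are available, a
cheap screen is possible: align the genomes, slide a ~1 kb window across
the alignment, and shortlist the windows with the most variable sites as
candidate markers for Sanger-scale sequencing. The candidates are then
tallied per marker — variable sites, gap-coded indel characters,
parsimony-informative sites — ranked, and compared across clades to see
whether a marker that screens well in one clade stays useful in its
relatives (in *Solanum*, mostly it does not).

`plastscreen` implements that screening pipeline as a library with a thin
CLI:

- **plastome_io** — GenBank / aligned-FASTA / BED I/O, 0-based half-open
  coordinates internally, region extraction with strand handling.
- **site_stats** — column classification; variable sites `v`,
  parsimony-informative sites, and percentages `100·v/L` rounded half-up.
- **indel_coding** — simple indel coding: each non-terminal gap run with
  shared start *and* end becomes one binary character; a sequence whose
  longer gap strictly contains the interval is scored `?`.
- **window_scan** — gap-aware sliding-window scan (default 1,000-column
  windows, 100-column steps), top-*k* window selection, merging into named
  regions ("geneA-geneB"), splitting of oversized regions.
- **selection** — Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction,
  d = −(3/4)·ln(1 − (4/3)p), and selection-regime classification
  (ω < 0.9 purifying, 0.9–1.1 near-neutral, > 1.1 positive).
- **ir_check** — inverted-repeat identity: IRb is reverse-complemented and
  compared position-wise against IRa (concerted evolution predicts zero
  mismatches).
- **ranking** — per-clade marker ranking by variable sites + coded indels,
  cross-clade rank comparison, screening-table rendering.
- **synthetic_data** — plastome-like simulations with exact planted truth
  (variable columns, shared-boundary indels, codon substitutions at a
  target ω, twin IR blocks) so every stage is testable without downloads.
- **published** — packaged per-marker screening counts for the Potato and
  Morelloid clades of *Solanum* as reference inputs for rank arithmetic.

## Worked example

```python
from plastscreen import (default_trio_spec, simulate_plastome_trio,
                         sliding_window_scan, top_windows,
                         merge_windows_to_regions)

genomes, alignment, truth = simulate_plastome_trio(default_trio_spec(seed=42))
profile = sliding_window_scan(alignment, window=1000, step=100)
regions = merge_windows_to_regions(top_windows(profile, k=20),
                                   genome=genomes[0], aln=alignment)
for r in regions:
    print(r.name, r.start + 1, r.end, r.variable)
```

prints

```
trnK-rps16 401 1500 50
clpP-psbB 5401 6600 54
ndhF-rpl32 13901 15100 49
rpl32-trnL 16501 17500 44
ycf1 18701 20800 95
```

— the five hot regions planted by the simulation, recovered by the scan and
named from the reference annotation; the last column is the variable-site
count each candidate would contribute as a marker. The same operations run
from the shell (`plastscreen scan`, `stats`, `rank`, `ir-check`,
`simulate`); the `examples/` directory has one short script per capability,
including ranking the packaged *Solanum* screening counts, where
`clpP-psbB` tops the Potato clade but ranks near the bottom of the
Morelloid clade, and only `ycf1` parts 1 and 3 and `rpl32-trnL` stay in
both top sixes.

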