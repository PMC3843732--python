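import numpy as np
import pytest

from plastscreen import (
    Alignment,
    RegionSpec,
    SimulationSpec,
    alignment_from_strings,
    default_trio_spec,
    simulate_plastome_trio,
)

BASES = "ACGT"


def random_alignment(
    rng: np.random.Generator,
    n_rows: int,
    n_cols: int,
    gap_prob: float = 0.0,
    ambig_prob: float = 0.0,
) -> Alignment:
    """Unstructured random alignment for oracle-agreement tests."""
    alphabet = list(BASES)
    rows = []
    for _ in range(n_rows):
        chars = [alphabet[rng.integers(4)] for _ in range(n_cols)]
        for j in range(n_cols):
            u = rng.random()
            if u < gap_prob:
                chars[j] = "-"
            elif u < gap_prob + ambig_prob:
                chars[j] = "N"
        rows.append("".join(chars))
    return alignment_from_strings(rows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def trio():
    """A simulated annotated plastome trio shared across window/IR tests."""
    return simulate_plastome_trio(default_trio_spec(seed=11))


@pytest.fixture()
def small_spec():
    return SimulationSpec(
        n_taxa=12,
        regions=[RegionSpec("marker", 500, "spacer", rate=0.02, n_indels=3)],
        seed=7,
    )


MINIMAL_GENBANK = """\
LOCUS       TESTPLAST                 60 bp    DNA     linear   PLN 01-JAN-2000
DEFINITION  synthetic minimal record.
ACCESSION   TESTPLAST
VERSION     TESTPLAST.1
FEATURES             Location/Qualifiers
     gene            1..30
                     /gene="trnK"
     CDS             complement(10..60)
                     /gene="ycf1"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""


@pytest.fixture()
def minimal_genbank(tmp_path):
    path = tmp_path / "minimal.gb"
    path.write_text(MINIMAL_GENBANK)
    return path
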