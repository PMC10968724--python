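from __future__ import annotations

import pytest

from plastocaps.fixtures import (
    INSERTION_WINDOW,
    REFERENCE_WINDOW,
    PlastomeSpec,
    make_allele_locus,
    make_toy_plastome,
)


@pytest.fixture(scope="session")
def toy_plastome():
    """500/120/80 quadripartite toy with genes planted at known junction offsets."""
    spec = PlastomeSpec(
        lsc_len=500,
        ir_len=120,
        ssc_len=80,
        seed=7,
        planted_genes=(
            ("rps19", "LSC", 470, 40, "+"),  # straddles LSC/IRb by 10 bp
            ("geneX", "IRb", 60, 60, "+"),  # ends exactly at the IRb/SSC junction
            ("ycf1", "SSC", 55, 50, "+"),  # straddles SSC/IRa by 25 bp
        ),
    )
    return make_toy_plastome(spec)


def clean_allele_locus(flank: int = 100) -> tuple[str, str]:
    """The printed allele pair embedded in flanks free of native MluCI sites.

    The seed is the first one whose random flanks contain no AATT, so any
    digest difference between the alleles must be engineered by a primer
    mismatch interacting with the insertion — the dCAPS scenario proper.
    """
    for seed in range(100):
        ref, alt = make_allele_locus(flank, flank, REFERENCE_WINDOW, INSERTION_WINDOW, seed=seed)
        if "AATT" not in ref and "AATT" not in alt:
            return ref, alt
    raise AssertionError("no AATT-free embedding found in 100 seeds")


@pytest.fixture(scope="session")
def allele_locus_pair():
    return clean_allele_locus()
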