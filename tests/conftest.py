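"""Shared fixtures: small hand-checkable hairpins and synthetic datasets."""

import pytest

from maturescan import PreMiRNA, SynthSpec, align_arms, generate


@pytest.fixture(scope="session")
def perfect_alignment():
    """Perfect 40-bp stem, 6-nt loop, no basal segment (2-nt 3' overhang)."""
    spec = SynthSpec(
        n_precursors=1,
        arm_len=(40, 40),
        loop_len=(6, 6),
        bulge_rate=0.0,
        mismatch_rate=0.0,
        basal_overhang=(0, 0),
        plant_site_determinants=False,
        seed=11,
    )
    ds = generate(spec)
    return align_arms(ds.records[0])


@pytest.fixture(scope="session")
def bulge_alignment():
    """12-mer with a 1x1 internal loop: a 5'-side and a 3'-side bulge.

    Pairs (1-based) 1-12, 2-11, 4-9; expected columns
    (G,C) (C,G) (A,-) (-,U) (G,C).
    """
    return align_arms(PreMiRNA("bulge12", "GCAGAAAACUGC", "((.(....).))"))


@pytest.fixture(scope="session")
def basal_gap_alignment():
    """13-mer whose column 1 is a 3'-arm bulge: (G,C) (-,U) (C,G) (G,C) (G,C)."""
    return align_arms(PreMiRNA("gap13", "GCGGAAAACCGUC", "((((....))).)"))


@pytest.fixture(scope="session")
def flush_alignment():
    """Perfect 6-bp stem flush with both sequence ends (no overhangs)."""
    return align_arms(PreMiRNA("flush16", "GGGGGGAAAACCCCCC", "((((((....))))))"))


@pytest.fixture(scope="session")
def default_dataset():
    """200 precursors under default generator conditions."""
    return generate(SynthSpec(n_precursors=200, seed=42))
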