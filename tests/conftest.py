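"""Shared fixtures: small proteins, design spaces, simulated experiments."""

import pytest

import vampscan as vs


@pytest.fixture(scope="session")
def protein10() -> vs.ProteinSequence:
    return vs.ProteinSequence("p10", "MCDEFGHIKL")


@pytest.fixture(scope="session")
def protein465() -> vs.ProteinSequence:
    # length-matched stand-in for a 465-residue target protein
    return vs.ProteinSequence("p465", ("ACDEFGHIKLMNPQRSTVWY" * 24)[:465])


@pytest.fixture(scope="session")
def design10(protein10) -> vs.DesignSpace:
    return vs.enumerate_design_space(protein10, include_synonymous=True)


@pytest.fixture(scope="session")
def default_experiment(design10) -> vs.SimulatedExperiment:
    """A default-scale simulation shared by recovery tests.

    200 variants, ~10 barcodes/variant, 100 cells/barcode and about
    200 reads per barcode per gate.
    """
    return vs.simulate_experiment(
        design10,
        mean_barcodes_per_variant=10,
        cells_per_barcode=100,
        n_biological=2,
        n_technical=2,
        seed=101,
    )
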