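import numpy as np
import pytest

from glycoflex.synthetic import gen_rees_dataset, gen_toy_structure


@pytest.fixture(scope="session")
def clean_rees_dataset():
    """Noiseless two-component REES dataset with known (CSM0, A, R)."""
    spectra, truth = gen_rees_dataset(seed=11)
    return spectra, truth


@pytest.fixture(scope="session")
def clean_rees_fits(clean_rees_dataset):
    from glycoflex.spectra import fit_spectrum

    spectra, truth = clean_rees_dataset
    return spectra, [fit_spectrum(s) for s in spectra], truth


@pytest.fixture(scope="session")
def toy_helix():
    """15-residue ideal helix with amide hydrogens, no ligand."""
    atoms, truth = gen_toy_structure(seed=0, n_residues=15)
    return atoms, truth


@pytest.fixture(scope="session")
def bridged_helix():
    """Helix whose middle (residues 4-10) is clamped by a rigid HEM-named
    ligand while every backbone H-bond is weak (-1.2 kcal/mol), so rigidity
    at intermediate cutoffs hinges on the ligand and on any artificial
    glycan constraints."""
    n = 15
    energies = {(i + 4, "N", i, "O"): -1.2 for i in range(1, n - 3)}
    atoms, truth = gen_toy_structure(
        seed=0, n_residues=n, with_ligand=True, ligand_span=(4, 10)
    )
    return atoms, energies
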