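"""Shared fixtures: an independently hand-coded mass table and a small
synthetic study generated once per session."""

from pathlib import Path

import pytest

from xlpasef.cli_config import load_config, run_pipeline
from xlpasef.synth_fixtures import SynthConfig, generate_study

# Independent monoisotopic atomic masses (IUPAC), hand-typed — the oracle
# route, deliberately separate from the implementation's mass source.
ATOMIC_MASS = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

# Independent residue monoisotopic masses (unmodified), hand-typed.
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]
PROTON = 1.00727646
CARBAMIDOMETHYL = 57.02146


def oracle_formula_mass(formula_counts: dict) -> float:
    """Hand-sum oracle for element compositions."""
    return sum(ATOMIC_MASS[el] * n for el, n in formula_counts.items())


def oracle_peptide_mass(sequence: str, carbamidomethyl_c: bool = True) -> float:
    """Residue-table summation oracle for neutral peptide mass."""
    total = sum(RESIDUE_MASS[aa] for aa in sequence) + WATER
    if carbamidomethyl_c:
        total += CARBAMIDOMETHYL * sequence.count("C")
    return total


@pytest.fixture(scope="session")
def study(tmp_path_factory) -> tuple:
    """Default-condition synthetic study (seed 7), generated once."""
    out = tmp_path_factory.mktemp("study7")
    truth = generate_study(out, SynthConfig(), seed=7)
    return out, truth


@pytest.fixture(scope="session")
def pipeline_results(study) -> tuple:
    """Full pipeline run on the session study; returns (dir, truth, results dir)."""
    out, truth = study
    cfg = load_config(out / "study.yaml")
    run_pipeline(cfg)
    return out, truth, out / "results"
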