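"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from aquatox import synth
from aquatox.chemdata import MoleculeRecord
from aquatox.textmine import Document


@pytest.fixture(scope="session")
def article() -> Document:
    """A small article with known section offsets and sentence boundaries."""
    text = (
        "Chain length and acute toxicity of amines\n"
        "Abstract\n"
        "We measured acute toxicity for a homologous series.\n"
        "1 Introduction\n"
        "Toxicity increases with chain length. "
        "The fish were fed daily. "
        "LC50 was 0.5 mg/L and related to chain length. "
        "See Fig. 2 for the dose series. "
        "Water temperature was kept constant. "
        "Solubility limits the test range.\n"
        "References\n"
        "[1] Author, A. Some journal, 2001.\n"
    )
    return Document(doc_id="amines", raw_text=text)


# Sentence fixture with exactly two planted relevant sentences (0 and 3).
SIX_SENTENCES = [
    "Toxicity increases with chain length.",          # main "toxicity" + stem "increase"
    "The fish were fed daily.",                        # no main term
    "Toxicity was noted in the report.",               # main term but no connection stem
    "EC50 values depend strongly on logP.",            # main "ec50" + stem "depend"
    "Salinity was held constant throughout.",          # neither
    "Samples were measured in triplicate.",            # neither
]


@pytest.fixture
def six_sentences() -> list[str]:
    return list(SIX_SENTENCES)


@pytest.fixture(scope="session")
def small_records() -> list[MoleculeRecord]:
    smiles_lc50 = [
        ("CCO", 1000.0),
        ("CCCCCC", 50.0),
        ("CCN(C)C", 5.0),
        ("COCCO", 200.0),
        ("CC(C)CC(C)O", 30.0),
        ("NCCCCCC", 8.0),
        ("CCCCCCCCO", 2.0),
        ("CC(=O)NCC", 400.0),
    ]
    return [
        MoleculeRecord.from_lc50(f"M{i}", s, lc)
        for i, (s, lc) in enumerate(smiles_lc50)
    ]


@pytest.fixture(scope="session")
def benchmark() -> synth.Benchmark:
    """Standard synthetic benchmark: n=500, noise_sd=0.3, no contamination."""
    spec = synth.GenSpec(n_molecules=500, seed=7)
    return synth.make_benchmark(spec, test_frac=0.2)


@pytest.fixture(scope="session")
def dataset() -> synth.SyntheticDataset:
    return synth.generate_dataset(synth.GenSpec(n_molecules=500, seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
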