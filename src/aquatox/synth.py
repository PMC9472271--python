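"""Synthetic saturated aliphatic C/H/O/N molecules with trend-true toxicity.

The generator produces the kind of chemistry the screening domain covers —
branched alkyl skeletons decorated with hydroxyl, ether (methoxy), primary
amine and dimethylamino groups — and assigns each molecule a toxicity from
a transparent generative law

    tox = intercept + logp_coef * logP + mw_coef * MW + nNCH3_coef * n_NCH3
          (+ Gaussian noise)

whose three drivers exercise a positive hydrophobicity trend, a positive
size trend and a negative N-methylation trend, i.e. the minimal subset of
the literature rule set with both signs and a scoped fragment rule.  LC50
values follow as exp(-tox), so generated tables feed the standard loading
pipeline unchanged.

An optional *contamination* mimics the known pathology that motivates
MW-based outlier filtering: the highest-MW fraction of molecules has its
noiseless toxicity replaced by a flat value, producing the weak
MW-toxicity correlation regime at the top of the mass range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chemdata import (
    MoleculeRecord,
    ThresholdConfig,
    count_rule_fragments,
    filter_chon_saturated,
    write_dataset,
)
from .descriptors import compute_descriptor

__all__ = [
    "GenSpec",
    "GenModel",
    "SyntheticDataset",
    "Benchmark",
    "generate_molecules",
    "generate_toxicity",
    "generate_dataset",
    "make_benchmark",
    "contamination_indices",
]


@dataclass(frozen=True)
class GenModel:
    """Coefficients of the generative toxicity law."""

    logp_coef: float = 0.9
    mw_coef: float = 0.005
    nNCH3_coef: float = -0.8
    intercept: float = -2.0

    def __post_init__(self) -> None:
        if self.logp_coef <= 0:
            raise ValueError("logp_coef must be > 0")
        if self.mw_coef < 0:
            raise ValueError("mw_coef must be >= 0")
        if self.nNCH3_coef > 0:
            raise ValueError("nNCH3_coef must be <= 0")


@dataclass
class GenSpec:
    """Generation settings: composition, generative law, noise, pathology."""

    n_molecules: int = 500
    seed: int = 0
    chain_length_range: tuple[int, int] = (2, 16)
    group_probs: dict = field(default_factory=lambda: {
        "hydroxyl": 0.4, "ether": 0.3, "primary_amine": 0.3, "tert_amine_NCH3": 0.25,
    })
    gen_model: GenModel = field(default_factory=GenModel)
    noise_sd: float = 0.3
    contamination_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        lo, hi = self.chain_length_range
        if not (2 <= lo <= hi <= 20):
            raise ValueError("chain_length_range must lie within [2, 20]")
        for key, p in self.group_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"group_probs[{key!r}] outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.contamination_frac < 1.0:
            raise ValueError("contamination_frac must be in [0, 1)")


def _random_skeleton(rng: np.random.Generator, n_carbons: int) -> Chem.RWMol:
    mol = Chem.RWMol()
    degrees: list[int] = []
    first = mol.AddAtom(Chem.Atom(6))
    degrees.append(0)
    for _ in range(n_carbons - 1):
        # Prefer extending the most recent atom: mostly chains, some branches.
        candidates = [i for i, d in enumerate(degrees) if d < 4]
        if rng.random() < 0.7 and degrees[candidates[-1]] < 4:
            parent = candidates[-1]
        else:
            parent = int(rng.choice(candidates))
        new = mol.AddAtom(Chem.Atom(6))
        mol.AddBond(parent, new, Chem.BondType.SINGLE)
        degrees[parent] += 1
        degrees.append(1)
    return mol


def _free_carbons(mol: Chem.RWMol) -> list[int]:
    out = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 6 and atom.GetDegree() < 4:
            out.append(atom.GetIdx())
    return out


def _attach(mol: Chem.RWMol, parent: int, atomic_num: int) -> int:
    new = mol.AddAtom(Chem.Atom(atomic_num))
    mol.AddBond(parent, new, Chem.BondType.SINGLE)
    return new


def _decorate(mol: Chem.RWMol, rng: np.random.Generator, group_probs: dict) -> None:
    for group in ("hydroxyl", "ether", "primary_amine", "tert_amine_NCH3"):
        if rng.random() >= group_probs.get(group, 0.0):
            continue
        free = _free_carbons(mol)
        if not free:
            continue
        parent = int(rng.choice(free))
        if group == "hydroxyl":
            _attach(mol, parent, 8)
        elif group == "ether":
            o = _attach(mol, parent, 8)
            _attach(mol, o, 6)  # methoxy: C-O-CH3
        elif group == "primary_amine":
            _attach(mol, parent, 7)
        else:  # dimethylamino: two N-CH3 fragments
            n = _attach(mol, parent, 7)
            _attach(mol, n, 6)
            _attach(mol, n, 6)


def generate_molecules(spec: GenSpec) -> list[str]:
    """Generate ``n_molecules`` canonical SMILES; deterministic per seed.

    Every molecule is a parseable, saturated aliphatic C/H/O/N structure
    (all pass the domain filter).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.chain_length_range
    smiles: list[str] = []
    while len(smiles) < spec.n_molecules:
        n_c = int(rng.integers(lo, hi + 1))
        mol = _random_skeleton(rng, n_c)
        _decorate(mol, rng, spec.group_probs)
        product = mol.GetMol()
        Chem.SanitizeMol(product)
        smiles.append(Chem.MolToSmiles(product))
    return smiles


def contamination_indices(mw: Sequence[float], frac: float) -> np.ndarray:
    """Indices of the ``frac`` highest-MW molecules (deterministic)."""
    mw = np.asarray(mw, dtype=float)
    k = int(np.floor(frac * len(mw)))
    if k == 0:
        return np.array([], dtype=int)
    return np.argsort(mw, kind="stable")[-k:]


def _noiseless_truth(smiles_list: Sequence[str], spec: GenSpec) -> tuple[np.ndarray, np.ndarray]:
    gm = spec.gen_model
    logp = np.array([compute_descriptor(s, "MolLogP") for s in smiles_list])
    mw = np.array([compute_descriptor(s, "MW") for s in smiles_list])
    nch3 = np.array([count_rule_fragments(s)["n_NCH3"] for s in smiles_list], dtype=float)
    truth = gm.intercept + gm.logp_coef * logp + gm.mw_coef * mw + gm.nNCH3_coef * nch3
    return truth, mw


def generate_toxicity(
    smiles_list: Sequence[str], spec: GenSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Assign (LC50 mg/L, noiseless truth) to molecules via the generative law.

    The contaminated fraction (highest MW) gets its truth replaced by the
    median truth before noise is added, flattening the MW-toxicity relation
    at the top of the mass range.  Noise is seeded from ``spec.seed``.
    """
    truth, mw = _noiseless_truth(smiles_list, spec)
    idx = contamination_indices(mw, spec.contamination_frac)
    if idx.size:
        truth = truth.copy()
        truth[idx] = float(np.median(truth))
    rng = np.random.default_rng(spec.seed + 1)
    tox = truth + rng.normal(0.0, spec.noise_sd, size=len(truth))
    lc50 = np.exp(-tox)
    return lc50, truth


@dataclass
class SyntheticDataset:
    """Generated records plus the noiseless truth and contamination mask."""

    records: list[MoleculeRecord]
    truth: np.ndarray
    contaminated: np.ndarray
    spec: GenSpec

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def tox(self) -> np.ndarray:
        return np.array([r.tox for r in self.records])

    def to_csv(self, path: str | Path) -> None:
        write_dataset(self.records, path)


def generate_dataset(
    spec: GenSpec, thresholds: ThresholdConfig | None = None
) -> SyntheticDataset:
    """End-to-end generation: structures, toxicities, validated records."""
    smiles = generate_molecules(spec)
    lc50, truth = generate_toxicity(smiles, spec)
    mw = np.array([compute_descriptor(s, "MW") for s in smiles])
    contaminated = np.zeros(len(smiles), dtype=bool)
    contaminated[contamination_indices(mw, spec.contamination_frac)] = True
    records = [
        MoleculeRecord.from_lc50(f"SYN-{i:05d}", s, float(c), thresholds)
        for i, (s, c) in enumerate(zip(smiles, lc50))
    ]
    kept, rejected = filter_chon_saturated(records)
    assert not rejected, f"generator produced out-of-domain molecules: {rejected[:3]}"
    return SyntheticDataset(records=records, truth=truth, contaminated=contaminated, spec=spec)


@dataclass
class Benchmark:
    """Seeded disjoint train/test split of a synthetic dataset."""

    train: list[MoleculeRecord]
    test: list[MoleculeRecord]
    truth_train: np.ndarray
    truth_test: np.ndarray
    contaminated_train: np.ndarray
    contaminated_test: np.ndarray

    @property
    def train_smiles(self) -> list[str]:
        return [r.smiles for r in self.train]

    @property
    def test_smiles(self) -> list[str]:
        return [r.smiles for r in self.test]

    @property
    def train_tox(self) -> np.ndarray:
        return np.array([r.tox for r in self.train])

    @property
    def test_tox(self) -> np.ndarray:
        return np.array([r.tox for r in self.test])


def make_benchmark(
    spec: GenSpec, test_frac: float = 0.2, seed: int | None = None
) -> Benchmark:
    """Generate a dataset and split it into disjoint train/test parts."""
    if not 0.0 < test_frac < 0.5:
        raise ValueError("test_frac must be in (0, 0.5)")
    ds = generate_dataset(spec)
    n = len(ds.records)
    n_test = int(round(n * test_frac))
    if n_test < 1 or n - n_test < 1:
        raise ValueError(f"n={n} too small for test_frac={test_frac}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    order = rng.permutation(n)
    test_idx = np.sort(order[:n_test])
    train_idx = np.sort(order[n_test:])
    return Benchmark(
        train=[ds.records[i] for i in train_idx],
        test=[ds.records[i] for i in test_idx],
        truth_train=ds.truth[train_idx],
        truth_test=ds.truth[test_idx],
        contaminated_train=ds.contaminated[train_idx],
        contaminated_test=ds.contaminated[test_idx],
    )
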