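"""Molecular descriptor registry with pluggable providers.

The audit and modelling layers only ever see *named numeric columns*; where
those numbers come from is a provider concern.  The default provider mixes
RDKit's physicochemical descriptors (logP, molar refractivity, TPSA, MW,
VSA/Chi/Kappa panels, ...) with native implementations of the
topological-autocorrelation, electrotopological-state and extended
topochemical atom (ETA) descriptor families:

* ``AATSC0p`` — averaged centered Moreau-Broto autocorrelation of lag 0
  weighted by atomic polarizability.
* ``GATS1p`` / ``GATS1i`` — Geary autocorrelation of lag 1 weighted by
  polarizability / first ionization potential.
* ``Mi`` — mean first ionization potential scaled on carbon.
* ``SHBd`` — sum of Kier-Hall E-state indices over hydrogen-bond-donor
  heavy atoms (N/O bearing at least one H).
* ``maxHBint2`` — strongest donor/acceptor E-state pairing at topological
  distance 2 (0 when no such pair exists).
* ``ETA_Alpha`` — sum of ETA alpha (core count) values over heavy atoms.
* ``ETA_dEpsilon_A`` — mean ETA electronegativity measure over heavy atoms
  minus the mean over all atoms; grows with heteroatom content.
* ``ETA_EtaP_B`` — branching measure: excess heavy-atom degree beyond 2,
  normalised by heavy-atom count.

Autocorrelation and Mi sums run over the hydrogen-inclusive graph; E-state
and ETA alpha run on the hydrogen-suppressed graph, following the usual
conventions for those families.  Unknown atomic properties fail loudly
rather than being imputed.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.EState import EStateIndices

from .exceptions import ProviderError

__all__ = [
    "DEFAULT_PANEL",
    "RULE_DESCRIPTORS",
    "ALIASES",
    "resolve_name",
    "available_descriptors",
    "compute_descriptor",
    "register_descriptor",
]

# Atomic properties for the weighted autocorrelations.  Polarizability in
# 10^-24 cm^3, first ionization energy in eV (CRC values).
_POLARIZABILITY: Mapping[int, float] = {
    1: 0.667, 6: 1.76, 7: 1.10, 8: 0.802, 9: 0.557,
    15: 3.63, 16: 2.90, 17: 2.18, 35: 3.05,
}
_IONIZATION: Mapping[int, float] = {
    1: 13.598, 6: 11.260, 7: 14.534, 8: 13.618, 9: 17.423,
    15: 10.487, 16: 10.360, 17: 12.968, 35: 11.814,
}
_CARBON_IONIZATION = _IONIZATION[6]


def _atom_property(atom: Chem.Atom, table: Mapping[int, float], label: str) -> float:
    z = atom.GetAtomicNum()
    try:
        return table[z]
    except KeyError:
        raise ProviderError(
            f"no {label} value for element Z={z} ({atom.GetSymbol()})"
        ) from None


def _with_hs(mol: Chem.Mol) -> Chem.Mol:
    return Chem.AddHs(mol)


def _aatsc0(mol: Chem.Mol, table: Mapping[int, float], label: str) -> float:
    molh = _with_hs(mol)
    w = np.array([_atom_property(a, table, label) for a in molh.GetAtoms()])
    c = w - w.mean()
    return float(np.sum(c * c) / len(w))


def _gats1(mol: Chem.Mol, table: Mapping[int, float], label: str) -> float:
    molh = _with_hs(mol)
    w = np.array([_atom_property(a, table, label) for a in molh.GetAtoms()])
    n = len(w)
    bonds = molh.GetBonds()
    if n < 2 or not bonds:
        return 0.0
    num = sum(
        (w[b.GetBeginAtomIdx()] - w[b.GetEndAtomIdx()]) ** 2 for b in bonds
    ) / (2.0 * len(bonds))
    den = float(np.sum((w - w.mean()) ** 2)) / (n - 1)
    if den == 0.0:
        return 0.0
    return float(num / den)


def _mi(mol: Chem.Mol) -> float:
    molh = _with_hs(mol)
    vals = [
        _atom_property(a, _IONIZATION, "ionization") / _CARBON_IONIZATION
        for a in molh.GetAtoms()
    ]
    return float(np.mean(vals))


def _is_donor(atom: Chem.Atom) -> bool:
    return atom.GetAtomicNum() in (7, 8) and atom.GetTotalNumHs() > 0


def _is_acceptor(atom: Chem.Atom) -> bool:
    return atom.GetAtomicNum() in (7, 8)


def _shbd(mol: Chem.Mol) -> float:
    estates = EStateIndices(mol)
    return float(sum(e for a, e in zip(mol.GetAtoms(), estates) if _is_donor(a)))


def _max_hbint(mol: Chem.Mol, dist: int = 2) -> float:
    estates = EStateIndices(mol)
    n = mol.GetNumAtoms()
    if n < 2:
        return 0.0
    dmat = Chem.GetDistanceMatrix(mol)
    best = 0.0
    found = False
    for i, ai in enumerate(mol.GetAtoms()):
        if not _is_donor(ai):
            continue
        for j, aj in enumerate(mol.GetAtoms()):
            if i == j or not _is_acceptor(aj):
                continue
            if dmat[i, j] == dist:
                found = True
                best = max(best, float(estates[i] + estates[j]))
    return best if found else 0.0


def _eta_alpha_atom(atom: Chem.Atom) -> float:
    z = atom.GetAtomicNum()
    if z == 1:
        return 0.0
    zv = Chem.GetPeriodicTable().GetNOuterElecs(z)
    period = _period(z)
    return ((z - zv) / zv) * (1.0 / (period - 1))


def _period(z: int) -> int:
    for period, upper in ((1, 2), (2, 10), (3, 18), (4, 36), (5, 54)):
        if z <= upper:
            return period
    return 6


def _eta_epsilon_atom(atom: Chem.Atom) -> float:
    zv = Chem.GetPeriodicTable().GetNOuterElecs(atom.GetAtomicNum())
    return -_eta_alpha_atom(atom) + 0.3 * zv


def _eta_alpha(mol: Chem.Mol) -> float:
    return float(sum(_eta_alpha_atom(a) for a in mol.GetAtoms()))


def _eta_d_epsilon_a(mol: Chem.Mol) -> float:
    molh = _with_hs(mol)
    eps_all = [_eta_epsilon_atom(a) for a in molh.GetAtoms()]
    eps_heavy = [
        _eta_epsilon_atom(a) for a in molh.GetAtoms() if a.GetAtomicNum() != 1
    ]
    if not eps_heavy:
        return 0.0
    return float(np.mean(eps_heavy) - np.mean(eps_all))


def _eta_etap_b(mol: Chem.Mol) -> float:
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() != 1]
    if not heavy:
        return 0.0
    excess = sum(max(0, sum(1 for n in a.GetNeighbors() if n.GetAtomicNum() != 1) - 2)
                 for a in heavy)
    return float(excess) / len(heavy)


# --- registry ---------------------------------------------------------------

_REGISTRY: dict[str, Callable[[Chem.Mol], float]] = {}

ALIASES: Mapping[str, str] = {
    "LogP": "MolLogP",
    "MolMR": "MR",
    "MolWt": "MW",
}


def register_descriptor(name: str, func: Callable[[Chem.Mol], float]) -> None:
    """Register (or override) a named descriptor in the default provider."""
    _REGISTRY[name] = func


def resolve_name(name: str) -> str:
    """Map a descriptor alias (LogP, MolWt, ...) to its canonical name."""
    return ALIASES.get(name, name)


def available_descriptors() -> list[str]:
    return sorted(_REGISTRY)


def compute_descriptor(mol: Chem.Mol | str, name: str) -> float:
    """Evaluate one named descriptor on a Mol or SMILES string.

    Unknown names raise :class:`ProviderError`; unparseable SMILES raise
    ``ValueError``.
    """
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES: {mol!r}")
        mol = parsed
    canonical = resolve_name(name)
    try:
        func = _REGISTRY[canonical]
    except KeyError:
        raise ProviderError(f"unknown descriptor {name!r}") from None
    return float(func(mol))


# Table-driven registration of the native family.
register_descriptor("MolLogP", Crippen.MolLogP)
register_descriptor("MR", Crippen.MolMR)
register_descriptor("TPSA", rdMolDescriptors.CalcTPSA)
register_descriptor("MW", Descriptors.MolWt)
register_descriptor("AATSC0p", lambda m: _aatsc0(m, _POLARIZABILITY, "polarizability"))
register_descriptor("GATS1p", lambda m: _gats1(m, _POLARIZABILITY, "polarizability"))
register_descriptor("GATS1i", lambda m: _gats1(m, _IONIZATION, "ionization"))
register_descriptor("Mi", _mi)
register_descriptor("SHBd", _shbd)
register_descriptor("maxHBint2", _max_hbint)
register_descriptor("ETA_Alpha", _eta_alpha)
register_descriptor("ETA_dEpsilon_A", _eta_d_epsilon_a)
register_descriptor("ETA_EtaP_B", _eta_etap_b)

#: Descriptors referenced by the literature-derived rule set.
RULE_DESCRIPTORS: tuple[str, ...] = (
    "MolLogP", "MR", "TPSA", "MW", "AATSC0p", "GATS1p", "GATS1i", "Mi",
    "SHBd", "maxHBint2", "ETA_Alpha", "ETA_dEpsilon_A", "ETA_EtaP_B",
)

# RDKit descriptors filling out the default 93-name panel.
_RDKIT_FILL: tuple[str, ...] = (
    *(f"PEOE_VSA{i}" for i in range(1, 15)),
    *(f"SMR_VSA{i}" for i in range(1, 11)),
    *(f"SlogP_VSA{i}" for i in range(1, 13)),
    *(f"EState_VSA{i}" for i in range(1, 12)),
    "Chi0", "Chi1",
    "Chi0n", "Chi1n", "Chi2n", "Chi3n", "Chi4n",
    "Chi0v", "Chi1v", "Chi2v", "Chi3v", "Chi4v",
    "Kappa1", "Kappa2", "Kappa3", "HallKierAlpha",
    "BalabanJ", "BertzCT", "LabuteASA",
    "HeavyAtomCount", "NumHDonors", "NumHAcceptors", "NumRotatableBonds",
    "RingCount", "FractionCSP3", "NHOHCount", "NOCount", "NumHeteroatoms",
    "NumValenceElectrons",
    "MaxEStateIndex", "MinEStateIndex", "MaxAbsEStateIndex", "MinAbsEStateIndex",
)

for _name in _RDKIT_FILL:
    register_descriptor(_name, getattr(Descriptors, _name))

#: Default descriptor panel: the 13 rule descriptors plus 80 standard RDKit
#: topological/electronic descriptors, 93 names in total.
DEFAULT_PANEL: tuple[str, ...] = RULE_DESCRIPTORS + _RDKIT_FILL

assert len(DEFAULT_PANEL) == 93, len(DEFAULT_PANEL)
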