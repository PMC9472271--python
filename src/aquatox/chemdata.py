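"""Molecule tables, toxicity transform, hazard labels and featurization.

The data model follows the screening workflow for acute aquatic toxicity:
each chemical carries a most-sensitive-species acute L(E)C50 in mg/L, the
modelling target is tox = -ln(LC50), and a three-way screening label
(T / PT / NT) is assigned from the raw mg/L value against the regulatory
cutoffs (<0.01 mg/L Toxic, <0.1 mg/L Potentially Toxic, otherwise Not
Toxic).  The structural domain is saturated aliphatic C/H/O/N chemistry;
``filter_chon_saturated`` enforces it.

Featurization (descriptor panel + circular fingerprints) is exposed both as
plain functions returning a :class:`FeatureSet` and as sklearn transformers
(:class:`DescriptorCalculator`, :class:`FingerprintGenerator`) that map a
sequence of SMILES to a numeric matrix, so models compose into pipelines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

from . import descriptors as desc
from .exceptions import EmptyDatasetError, FeatureError, SchemaError

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.error")

__all__ = [
    "MoleculeRecord",
    "ThresholdConfig",
    "FeatureSet",
    "FingerprintParams",
    "load_dataset",
    "write_dataset",
    "records_from_frame",
    "tox_transform",
    "classify_hazard",
    "filter_chon_saturated",
    "compute_descriptors",
    "compute_fingerprints",
    "count_rule_fragments",
    "DescriptorCalculator",
    "FingerprintGenerator",
    "mol_from_smiles",
    "canonical_smiles",
]

HAZARD_LABELS: tuple[str, ...] = ("T", "PT", "NT")


@dataclass(frozen=True)
class ThresholdConfig:
    """Screening cutoffs in mg/L: T below ``t_cut``, PT below ``pt_cut``."""

    t_cut: float = 0.01
    pt_cut: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.t_cut < self.pt_cut):
            raise ValueError("require 0 < t_cut < pt_cut")


def tox_transform(lc50: float) -> float:
    """Map an LC50 in mg/L onto the modelling scale tox = -ln(LC50)."""
    if lc50 <= 0:
        raise ValueError(f"LC50 must be positive, got {lc50}")
    return -math.log(lc50)


def classify_hazard(lc50: float, cfg: ThresholdConfig | None = None) -> str:
    """Assign the screening label from the raw LC50 (mg/L)."""
    cfg = cfg or ThresholdConfig()
    if lc50 <= 0:
        raise ValueError(f"LC50 must be positive, got {lc50}")
    if lc50 < cfg.t_cut:
        return "T"
    if lc50 < cfg.pt_cut:
        return "PT"
    return "NT"


@dataclass(frozen=True)
class MoleculeRecord:
    """One chemical: structure, acute L(E)C50 and derived quantities."""

    mol_id: str
    smiles: str
    lc50_mg_per_l: float
    tox: float
    hazard: str

    @classmethod
    def from_lc50(
        cls,
        mol_id: str,
        smiles: str,
        lc50_mg_per_l: float,
        thresholds: ThresholdConfig | None = None,
    ) -> "MoleculeRecord":
        return cls(
            mol_id=mol_id,
            smiles=smiles,
            lc50_mg_per_l=float(lc50_mg_per_l),
            tox=tox_transform(lc50_mg_per_l),
            hazard=classify_hazard(lc50_mg_per_l, thresholds),
        )


def mol_from_smiles(smiles: str) -> Chem.Mol | None:
    return Chem.MolFromSmiles(smiles)


def canonical_smiles(smiles: str) -> str:
    mol = mol_from_smiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


DEFAULT_COLUMN_MAP: Mapping[str, str] = {"smiles": "SMILES", "lc50": "LC50_mgL", "id": "CAS"}


def records_from_frame(
    frame: pd.DataFrame,
    column_map: Mapping[str, str] | None = None,
    thresholds: ThresholdConfig | None = None,
) -> list[MoleculeRecord]:
    """Build validated records from a molecule table.

    Rows with unparseable SMILES or nonpositive/missing LC50 are dropped
    with a logged warning; SMILES are canonicalized.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    for key in ("smiles", "lc50"):
        if cmap[key] not in frame.columns:
            raise SchemaError(
                f"required column {cmap[key]!r} (role {key!r}) missing; "
                f"available: {list(frame.columns)}"
            )
    has_id = cmap.get("id") in frame.columns
    records: list[MoleculeRecord] = []
    n_dropped = 0
    for pos, (_, row) in enumerate(frame.iterrows()):
        raw_smiles = row[cmap["smiles"]]
        lc50 = row[cmap["lc50"]]
        mol_id = str(row[cmap["id"]]) if has_id else f"row{pos}"
        mol = mol_from_smiles(str(raw_smiles)) if isinstance(raw_smiles, str) else None
        if mol is None:
            logger.warning("dropping %s: unparseable SMILES %r", mol_id, raw_smiles)
            n_dropped += 1
            continue
        try:
            lc50 = float(lc50)
        except (TypeError, ValueError):
            lc50 = float("nan")
        if not (lc50 > 0):
            logger.warning("dropping %s: nonpositive LC50 %r", mol_id, lc50)
            n_dropped += 1
            continue
        records.append(
            MoleculeRecord.from_lc50(mol_id, Chem.MolToSmiles(mol), lc50, thresholds)
        )
    logger.info("loaded %d records, dropped %d", len(records), n_dropped)
    if not records:
        raise EmptyDatasetError("no valid molecule rows after validation")
    return records


def load_dataset(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    thresholds: ThresholdConfig | None = None,
) -> list[MoleculeRecord]:
    """Read a CSV/XLSX molecule table into validated records."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path)
    return records_from_frame(frame, column_map, thresholds)


def write_dataset(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write records as canonical CSV with tox and hazard columns appended."""
    pd.DataFrame(
        {
            "CAS": [r.mol_id for r in records],
            "SMILES": [r.smiles for r in records],
            "LC50_mgL": [r.lc50_mg_per_l for r in records],
            "tox": [r.tox for r in records],
            "hazard": [r.hazard for r in records],
        }
    ).to_csv(path, index=False)


# --- structural domain filter ----------------------------------------------

_ALLOWED_Z = {1, 6, 7, 8}


def _chon_rejection_reason(mol: Chem.Mol) -> str | None:
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() not in _ALLOWED_Z:
            return f"element:{atom.GetSymbol()}"
    if any(a.GetIsAromatic() for a in mol.GetAtoms()):
        return "aromatic"
    for bond in mol.GetBonds():
        if bond.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE):
            if (bond.GetBeginAtom().GetAtomicNum() == 6
                    and bond.GetEndAtom().GetAtomicNum() == 6):
                return "cc_multiple_bond"
    return None


def filter_chon_saturated(
    records: Sequence[MoleculeRecord],
) -> tuple[list[MoleculeRecord], list[tuple[MoleculeRecord, str]]]:
    """Keep saturated aliphatic C/H/O/N molecules.

    A molecule is kept when its element set is within {C,H,O,N}, it has no
    aromatic atoms, and no carbon-carbon double or triple bonds.  Heteroatom
    multiple bonds (C=O, N=O) are permitted: the saturation criterion is read
    as a carbon-skeleton property, so aliphatic acids, esters and amides stay
    in the domain.  Rejected molecules carry a reason code.
    """
    kept: list[MoleculeRecord] = []
    rejected: list[tuple[MoleculeRecord, str]] = []
    for rec in records:
        mol = mol_from_smiles(rec.smiles)
        if mol is None:
            rejected.append((rec, "unparseable"))
            continue
        reason = _chon_rejection_reason(mol)
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec, reason))
    return kept, rejected


# --- featurization ----------------------------------------------------------

@dataclass(frozen=True)
class FingerprintParams:
    """Circular (Morgan) fingerprint settings."""

    fp_type: str = "morgan"
    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if self.fp_type != "morgan":
            raise ValueError(f"unsupported fingerprint type {self.fp_type!r}")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.n_bits < 64:
            raise ValueError("n_bits must be >= 64")


@dataclass
class FeatureSet:
    """Aligned descriptor matrix and/or fingerprint block for a molecule list."""

    mol_ids: list[str]
    descriptor_names: list[str] = field(default_factory=list)
    descriptors: np.ndarray | None = None
    fingerprints: np.ndarray | None = None
    fp_params: FingerprintParams | None = None
    constant_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.mol_ids)
        if self.descriptors is not None:
            if self.descriptors.shape != (n, len(self.descriptor_names)):
                raise ValueError("descriptor matrix shape mismatch")
            if len(set(self.descriptor_names)) != len(self.descriptor_names):
                raise ValueError("descriptor names must be unique")
        if self.fingerprints is not None and self.fingerprints.shape[0] != n:
            raise ValueError("fingerprint row count mismatch")

    def column(self, name: str) -> np.ndarray:
        """Return one descriptor column by (possibly aliased) name."""
        canonical = desc.resolve_name(name)
        try:
            j = self.descriptor_names.index(canonical)
        except ValueError:
            raise FeatureError(f"descriptor {name!r} not in feature set") from None
        return self.descriptors[:, j]

    def subset(self, names: Sequence[str]) -> "FeatureSet":
        """Column-subset preserving row order; missing names raise."""
        canonical = [desc.resolve_name(n) for n in names]
        missing = [n for n, c in zip(names, canonical) if c not in self.descriptor_names]
        if missing:
            raise FeatureError(f"descriptors not in feature set: {missing}")
        idx = [self.descriptor_names.index(c) for c in canonical]
        return FeatureSet(
            mol_ids=list(self.mol_ids),
            descriptor_names=canonical,
            descriptors=self.descriptors[:, idx],
            constant_columns=[c for c in self.constant_columns if c in canonical],
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.descriptors, columns=self.descriptor_names,
                            index=self.mol_ids)


def _records_to_mols(records: Sequence[MoleculeRecord | str]) -> tuple[list[str], list[Chem.Mol]]:
    ids, mols = [], []
    for i, rec in enumerate(records):
        smiles = rec if isinstance(rec, str) else rec.smiles
        mol_id = f"mol{i}" if isinstance(rec, str) else rec.mol_id
        mol = mol_from_smiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES for {mol_id}: {smiles!r}")
        ids.append(mol_id)
        mols.append(mol)
    return ids, mols


def compute_descriptors(
    records: Sequence[MoleculeRecord | str],
    names: Sequence[str] | None = None,
    provider: str = "default",
) -> FeatureSet:
    """Evaluate the named descriptor panel for every molecule.

    Constant-for-all-molecules columns are flagged (not dropped) in
    ``FeatureSet.constant_columns``; non-finite values raise.
    """
    if provider != "default":
        raise FeatureError(f"unknown descriptor provider {provider!r}")
    names = list(names) if names is not None else list(desc.DEFAULT_PANEL)
    canonical = [desc.resolve_name(n) for n in names]
    ids, mols = _records_to_mols(records)
    matrix = np.empty((len(mols), len(canonical)))
    for i, mol in enumerate(mols):
        for j, name in enumerate(canonical):
            matrix[i, j] = desc.compute_descriptor(mol, name)
    if not np.all(np.isfinite(matrix)):
        bad = [canonical[j] for j in np.where(~np.isfinite(matrix).all(axis=0))[0]]
        raise FeatureError(f"non-finite descriptor values in columns {bad}")
    constant = [
        canonical[j] for j in range(matrix.shape[1])
        if len(mols) > 1 and np.ptp(matrix[:, j]) == 0.0
    ]
    if constant:
        logger.info("constant descriptor columns: %s", constant)
    return FeatureSet(
        mol_ids=ids,
        descriptor_names=canonical,
        descriptors=matrix,
        constant_columns=constant,
    )


def compute_fingerprints(
    records: Sequence[MoleculeRecord | str],
    fp_params: FingerprintParams | None = None,
) -> FeatureSet:
    """Compute fixed-length binary circular fingerprints per molecule."""
    params = fp_params or FingerprintParams()
    ids, mols = _records_to_mols(records)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=params.radius, fpSize=params.n_bits
    )
    fps = np.zeros((len(mols), params.n_bits), dtype=np.uint8)
    for i, mol in enumerate(mols):
        bv = gen.GetFingerprint(mol)
        fps[i, list(bv.GetOnBits())] = 1
    return FeatureSet(mol_ids=ids, fingerprints=fps, fp_params=params)


# --- rule fragments ---------------------------------------------------------

_NCH3_PATTERN = Chem.MolFromSmarts("[CH3][#7]")
_ETHER_PATTERN = Chem.MolFromSmarts("[#6][OX2;!$(O=*)][#6]")


def _is_amine_nitrogen(atom: Chem.Atom) -> bool:
    # Trivalent, non-aromatic N that is not an amide nitrogen; neighbors are
    # carbons and/or it carries hydrogens.
    if atom.GetAtomicNum() != 7 or atom.GetIsAromatic():
        return False
    if atom.GetDegree() > 3 or atom.GetFormalCharge() != 0:
        return False
    heavy = [n for n in atom.GetNeighbors()]
    for nb in heavy:
        if nb.GetAtomicNum() == 6:
            for bond in nb.GetBonds():
                other = bond.GetOtherAtom(nb)
                if (other.GetAtomicNum() == 8
                        and bond.GetBondType() == Chem.BondType.DOUBLE):
                    return False  # amide / carbamate nitrogen
        elif nb.GetAtomicNum() != 1:
            return False  # N bonded to O/N (nitro, hydrazine...) is not a plain amine
    return atom.GetTotalNumHs() >= 1 or all(n.GetAtomicNum() == 6 for n in heavy)


def count_rule_fragments(record: MoleculeRecord | str) -> dict[str, int]:
    """Count the structural features referenced by the trend rules.

    Returns ``nC`` (carbon count), ``n_NCH3`` (methyls bonded to nitrogen),
    ``has_amine``, ``has_methoxy`` (C-O-C ether oxygen) and ``contains_N``
    as 0/1 flags or counts.
    """
    smiles = record if isinstance(record, str) else record.smiles
    mol = mol_from_smiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    n_c = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
    contains_n = any(a.GetAtomicNum() == 7 for a in mol.GetAtoms())
    n_nch3 = len(mol.GetSubstructMatches(_NCH3_PATTERN))
    has_amine = any(_is_amine_nitrogen(a) for a in mol.GetAtoms())
    has_methoxy = mol.HasSubstructMatch(_ETHER_PATTERN)
    return {
        "nC": n_c,
        "n_NCH3": n_nch3,
        "has_amine": int(has_amine),
        "has_methoxy": int(has_methoxy),
        "contains_N": int(contains_n),
    }


# --- sklearn transformers ---------------------------------------------------

class DescriptorCalculator(TransformerMixin, BaseEstimator):
    """Transform a sequence of SMILES into a descriptor matrix.

    Parameters
    ----------
    names : sequence of str or None
        Descriptor panel; ``None`` selects the default 93-name panel.
    """

    def __init__(self, names: Sequence[str] | None = None):
        self.names = names

    def fit(self, X, y=None):
        names = list(self.names) if self.names is not None else list(desc.DEFAULT_PANEL)
        self.feature_names_ = [desc.resolve_name(n) for n in names]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        return compute_descriptors(list(X), self.feature_names_).descriptors

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)


class FingerprintGenerator(TransformerMixin, BaseEstimator):
    """Transform a sequence of SMILES into a binary fingerprint matrix."""

    def __init__(self, radius: int = 2, n_bits: int = 2048):
        self.radius = radius
        self.n_bits = n_bits

    def fit(self, X, y=None):
        self.fp_params_ = FingerprintParams(radius=self.radius, n_bits=self.n_bits)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "fp_params_"):
            self.fit(X)
        return compute_fingerprints(list(X), self.fp_params_).fingerprints
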