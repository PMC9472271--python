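"""Prior-knowledge toxicity model (PKM).

The PKM composes two literature-style components: a linear group-contribution
(GC) fish model — intercept plus coefficients over counted substructure
fragments and, optionally, whole-molecule descriptors — and a linear
interspecies map carrying the fish endpoint onto the more sensitive
*Daphnia magna* endpoint.  Both components and the final prediction live on
*declared* scales (transform of the concentration plus concentration units),
and every composition step checks the declaration chain: silent unit
coercion between mg/L and mmol/L is the dominant failure mode in this
literature, so it is simply forbidden here.

Coefficients are configuration (YAML), not code.  The shipped default is a
baseline-narcosis fish calibration

    -log10(LC50, mmol/L) = 0.85 * logP + 1.39

with an identity interspecies map — a placeholder calibration that keeps the
pipeline runnable; substituting a published GC/interspecies pair is a config
edit.  Conversion between molar and mass concentration units uses the
molecular weight of the query molecule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from rdkit import Chem
from sklearn.base import BaseEstimator, RegressorMixin

from .chemdata import mol_from_smiles, MoleculeRecord
from .descriptors import compute_descriptor
from .exceptions import UnitError

__all__ = [
    "Scale",
    "GcModel",
    "InterspeciesMap",
    "PriorKnowledgeModel",
    "gc_predict",
    "interspecies",
    "pkm_predict",
    "convert_scale",
    "default_pkm",
    "load_pkm_config",
    "save_pkm_config",
    "DATASET_SCALE",
]

_TRANSFORMS = ("linear", "neg_log10", "neg_ln")
_UNITS = {"mg_per_L": None, "mmol_per_L": 1.0, "mol_per_L": 1000.0}


@dataclass(frozen=True)
class Scale:
    """Declaration of what a number means: transform + concentration units.

    ``transform`` is one of ``linear`` (the concentration itself),
    ``neg_log10`` or ``neg_ln`` (of the concentration).  ``units`` is
    ``mg_per_L``, ``mmol_per_L`` or ``mol_per_L``.
    """

    transform: str = "neg_ln"
    units: str = "mg_per_L"

    def __post_init__(self) -> None:
        if self.transform not in _TRANSFORMS:
            raise UnitError(f"unknown transform {self.transform!r}")
        if self.units not in _UNITS:
            raise UnitError(f"unknown units {self.units!r}")

    @property
    def needs_molar_mass(self) -> bool:
        return self.units != "mg_per_L"


#: The data-set toxicity scale: tox = -ln(LC50 in mg/L).
DATASET_SCALE = Scale("neg_ln", "mg_per_L")


def _to_concentration(value: float, transform: str) -> float:
    if transform == "linear":
        return value
    if transform == "neg_log10":
        return 10.0 ** (-value)
    return math.exp(-value)


def _from_concentration(conc: float, transform: str) -> float:
    if transform == "linear":
        return conc
    if conc <= 0:
        raise UnitError(f"nonpositive concentration {conc} cannot be log-transformed")
    if transform == "neg_log10":
        return -math.log10(conc)
    return -math.log(conc)


def convert_scale(
    value: float, src: Scale, dst: Scale, molar_mass: float | None = None
) -> float:
    """Convert a toxicity value between declared scales.

    Crossing between mass and molar units requires ``molar_mass`` in g/mol;
    omitting it raises :class:`UnitError`.  The conversion round-trips to
    high precision.
    """
    if src == dst:
        return value
    conc = _to_concentration(value, src.transform)
    if src.units != dst.units:
        if (src.needs_molar_mass or dst.needs_molar_mass) and molar_mass is None:
            raise UnitError(
                f"molar mass required to convert {src.units} -> {dst.units}"
            )
        # via mg/L
        if src.units != "mg_per_L":
            conc = conc * _UNITS[src.units] * molar_mass
        if dst.units != "mg_per_L":
            conc = conc / (_UNITS[dst.units] * molar_mass)
    return _from_concentration(conc, dst.transform)


@dataclass
class GcModel:
    """Linear group-contribution model on a declared output scale.

    ``fragments`` is a list of (SMARTS, coefficient) pairs; each pattern
    contributes coefficient x (number of substructure matches).
    ``descriptor_terms`` optionally adds coefficient x descriptor-value
    terms for whole-molecule descriptors such as logP, which lets simple
    baseline-narcosis regressions fit the same container.
    """

    fragments: list[tuple[str, float]] = field(default_factory=list)
    descriptor_terms: list[tuple[str, float]] = field(default_factory=list)
    intercept: float = 0.0
    output_scale: Scale = field(default_factory=lambda: Scale("neg_log10", "mmol_per_L"))

    def __post_init__(self) -> None:
        self._patterns = []
        for smarts, coef in self.fragments:
            pattern = Chem.MolFromSmarts(smarts)
            if pattern is None:
                raise ValueError(f"SMARTS pattern failed to compile: {smarts!r}")
            self._patterns.append((smarts, pattern, float(coef)))

    def predict_mol(self, mol: Chem.Mol) -> float:
        value = self.intercept
        for _, pattern, coef in self._patterns:
            value += coef * len(mol.GetSubstructMatches(pattern))
        for name, coef in self.descriptor_terms:
            value += coef * compute_descriptor(mol, name)
        return float(value)


@dataclass(frozen=True)
class InterspeciesMap:
    """Linear map between species endpoints on declared scales."""

    slope: float = 1.0
    intercept: float = 0.0
    input_scale: Scale = field(default_factory=lambda: Scale("neg_log10", "mmol_per_L"))
    output_scale: Scale = field(default_factory=lambda: Scale("neg_log10", "mmol_per_L"))

    def apply(self, fish_value: float) -> float:
        return self.slope * fish_value + self.intercept


def _as_mol(record: MoleculeRecord | str | Chem.Mol) -> Chem.Mol:
    if isinstance(record, Chem.Mol):
        return record
    smiles = record if isinstance(record, str) else record.smiles
    mol = mol_from_smiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def gc_predict(gc: GcModel, record: MoleculeRecord | str | Chem.Mol) -> float:
    """Fish toxicity on ``gc.output_scale`` for one molecule."""
    return gc.predict_mol(_as_mol(record))


def interspecies(mapping: InterspeciesMap, fish_value: float) -> float:
    """Apply the fish -> daphnia linear map."""
    return mapping.apply(fish_value)


class PriorKnowledgeModel(RegressorMixin, BaseEstimator):
    """GC fish model composed with an interspecies map, on the data scale.

    ``predict`` takes a sequence of SMILES (or records) and returns
    toxicity on ``target_scale`` (default -ln(LC50 mg/L), the data-set
    scale).  ``fit`` only validates the declaration chain — the model's
    coefficients are prior knowledge, not fitted to the data.
    """

    def __init__(
        self,
        gc: GcModel | None = None,
        species_map: InterspeciesMap | None = None,
        target_scale: Scale = DATASET_SCALE,
    ):
        self.gc = gc
        self.species_map = species_map
        self.target_scale = target_scale

    def _components(self) -> tuple[GcModel, InterspeciesMap]:
        gc = self.gc if self.gc is not None else _default_gc()
        mapping = self.species_map if self.species_map is not None else InterspeciesMap(
            input_scale=gc.output_scale, output_scale=gc.output_scale
        )
        if gc.output_scale != mapping.input_scale:
            raise UnitError(
                f"GC output scale {gc.output_scale} does not match "
                f"interspecies input scale {mapping.input_scale}"
            )
        return gc, mapping

    def fit(self, X=None, y=None):
        self.gc_, self.map_ = self._components()
        return self

    def predict_one(self, record: MoleculeRecord | str | Chem.Mol) -> float:
        if not hasattr(self, "gc_"):
            self.fit()
        mol = _as_mol(record)
        fish = self.gc_.predict_mol(mol)
        daphnia = self.map_.apply(fish)
        molar_mass = None
        if self.map_.output_scale.needs_molar_mass or self.target_scale.needs_molar_mass:
            molar_mass = compute_descriptor(mol, "MW")
        return convert_scale(daphnia, self.map_.output_scale, self.target_scale, molar_mass)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, (str, Chem.Mol, MoleculeRecord)):
            return np.array([self.predict_one(X)])
        return np.array([self.predict_one(x) for x in X])


def _default_gc() -> GcModel:
    # Placeholder baseline-narcosis calibration (see module docstring).
    return GcModel(
        descriptor_terms=[("MolLogP", 0.85)],
        intercept=1.39,
        output_scale=Scale("neg_log10", "mmol_per_L"),
    )


def default_pkm() -> PriorKnowledgeModel:
    """Shipped default: narcosis fish model + identity interspecies map."""
    gc = _default_gc()
    mapping = InterspeciesMap(
        slope=1.0, intercept=0.0, input_scale=gc.output_scale, output_scale=gc.output_scale
    )
    return PriorKnowledgeModel(gc=gc, species_map=mapping).fit()


def pkm_predict(
    pk: PriorKnowledgeModel, record: MoleculeRecord | str | Chem.Mol
) -> float:
    """Toxicity of one molecule on the data-set scale (-ln LC50 mg/L)."""
    return pk.predict_one(record)


# --- YAML config ------------------------------------------------------------

def _scale_from_dict(d: dict) -> Scale:
    return Scale(transform=d["transform"], units=d["units"])


def _scale_to_dict(s: Scale) -> dict:
    return {"transform": s.transform, "units": s.units}


def load_pkm_config(path: str | Path) -> PriorKnowledgeModel:
    """Build a PKM from a YAML declaration.

    Schema::

        gc:
          intercept: 1.39
          scale: {transform: neg_log10, units: mmol_per_L}
          fragments: [{smarts: "[CH3]", coef: 0.5}, ...]
          descriptors: [{name: MolLogP, coef: 0.85}, ...]
        interspecies:
          slope: 1.0
          intercept: 0.0
          input_scale: {...}
          output_scale: {...}
        target_scale: {transform: neg_ln, units: mg_per_L}
    """
    cfg = yaml.safe_load(Path(path).read_text())
    gc_cfg = cfg["gc"]
    gc = GcModel(
        fragments=[(f["smarts"], float(f["coef"])) for f in gc_cfg.get("fragments", [])],
        descriptor_terms=[(d["name"], float(d["coef"])) for d in gc_cfg.get("descriptors", [])],
        intercept=float(gc_cfg.get("intercept", 0.0)),
        output_scale=_scale_from_dict(gc_cfg["scale"]),
    )
    sp = cfg.get("interspecies")
    if sp is None:
        mapping = InterspeciesMap(input_scale=gc.output_scale, output_scale=gc.output_scale)
    else:
        mapping = InterspeciesMap(
            slope=float(sp.get("slope", 1.0)),
            intercept=float(sp.get("intercept", 0.0)),
            input_scale=_scale_from_dict(sp.get("input_scale", _scale_to_dict(gc.output_scale))),
            output_scale=_scale_from_dict(sp.get("output_scale", _scale_to_dict(gc.output_scale))),
        )
    target = cfg.get("target_scale")
    target_scale = _scale_from_dict(target) if target else DATASET_SCALE
    return PriorKnowledgeModel(gc=gc, species_map=mapping, target_scale=target_scale).fit()


def save_pkm_config(model: PriorKnowledgeModel, path: str | Path) -> None:
    gc, mapping = model._components()
    cfg = {
        "gc": {
            "intercept": gc.intercept,
            "scale": _scale_to_dict(gc.output_scale),
            "fragments": [{"smarts": s, "coef": c} for s, c in gc.fragments],
            "descriptors": [{"name": n, "coef": c} for n, c in gc.descriptor_terms],
        },
        "interspecies": {
            "slope": mapping.slope,
            "intercept": mapping.intercept,
            "input_scale": _scale_to_dict(mapping.input_scale),
            "output_scale": _scale_to_dict(mapping.output_scale),
        },
        "target_scale": _scale_to_dict(model.target_scale),
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
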