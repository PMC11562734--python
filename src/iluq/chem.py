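"""Data model and I/O for ion pairs, measurement conditions and property datasets.

An ionic liquid (IL) is represented as a dot-separated ``cation.anion`` SMILES
pair.  Property datasets are flat tables of (ion pair, conditions, value)
records with optional train/test split labels; they round-trip through CSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Properties supported by the package, mapped to the condition columns their
#: models consume.  Viscosity depends on temperature; CO2 absorption capacity
#: on temperature and pressure; refractive index and log EC50 are treated as
#: condition-free targets evaluated at reference conditions.
PROPERTY_CONDITIONS: dict[str, tuple[str, ...]] = {
    "viscosity": ("temperature_K",),
    "co2_capacity": ("temperature_K", "pressure_kPa"),
    "refractive_index": (),
    "log_ec50": (),
}

PROPERTIES = tuple(PROPERTY_CONDITIONS)

#: Standard ambient conditions used whenever a candidate pool carries none.
STANDARD_TEMPERATURE_K = 298.15
STANDARD_PRESSURE_KPA = 101.325


class ParseError(ValueError):
    """A SMILES string failed to parse."""


class ValidationError(ValueError):
    """A parsed structure violated an ion-pair charge rule."""


class SchemaError(ValueError):
    """A table is missing a mapped column."""


class EmptyDatasetError(ValueError):
    """An operation that requires records received none."""


@dataclass(frozen=True)
class Conditions:
    """Measurement conditions: temperature in kelvin, pressure in kilopascal."""

    temperature_K: float = STANDARD_TEMPERATURE_K
    pressure_kPa: float = STANDARD_PRESSURE_KPA

    def __post_init__(self) -> None:
        if not (self.temperature_K > 0 and math.isfinite(self.temperature_K)):
            raise ValueError(f"temperature must be finite and > 0 K, got {self.temperature_K}")
        if not (self.pressure_kPa > 0 and math.isfinite(self.pressure_kPa)):
            raise ValueError(f"pressure must be finite and > 0 kPa, got {self.pressure_kPa}")


STANDARD_CONDITIONS = Conditions()


@dataclass(frozen=True)
class IonPair:
    """A validated cation/anion SMILES pair — the screening unit.

    ``cation_smiles`` and ``anion_smiles`` are stored in RDKit canonical form.
    ``charge_mode`` records how strictly the pair was validated:

    - ``"strict"``  — cation net charge exactly +1, anion exactly -1
      (the 1:1 pairs the IL datasets consist of);
    - ``"permissive"`` — any (+, -) pair whose charges sum to zero;
    - ``"relaxed"`` — no charge requirement (arbitrary molecule pairs, used
      for deliberately out-of-domain "non-IL" benchmark candidates).
    """

    pair_id: str
    cation_smiles: str
    anion_smiles: str
    charge_mode: str = "strict"

    @property
    def smiles(self) -> str:
        return f"{self.cation_smiles}.{self.anion_smiles}"

    def to_mols(self) -> tuple[Chem.Mol, Chem.Mol]:
        """Return (cation, anion) RDKit molecules; raises if they fail to parse."""
        cat = Chem.MolFromSmiles(self.cation_smiles)
        ani = Chem.MolFromSmiles(self.anion_smiles)
        if cat is None or ani is None:
            raise ParseError(f"stored SMILES no longer parse for pair {self.pair_id!r}")
        return cat, ani

    def combined_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ParseError(f"stored SMILES no longer parse for pair {self.pair_id!r}")
        return mol


def _canonical(smiles: str, what: str, pair_id: str) -> tuple[str, Chem.Mol]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"pair {pair_id!r}: could not parse {what} SMILES {smiles!r}")
    return Chem.MolToSmiles(mol), mol


def parse_ion_pair(text: str, pair_id: str, charge_mode: str = "strict") -> IonPair:
    """Parse a dot-separated ``cation.anion`` SMILES string into an :class:`IonPair`.

    Parameters
    ----------
    text
        A SMILES string with exactly one top-level dot separating the cation
        component from the anion component.
    pair_id
        Identifier attached to the returned pair.
    charge_mode
        ``"strict"`` (default, +1/-1 exactly), ``"permissive"`` (charges sum
        to zero with cation positive) or ``"relaxed"`` (no charge rule).

    Raises
    ------
    ParseError
        If either component fails to parse, or the dot structure is wrong.
    ValidationError
        If the charge rule for ``charge_mode`` is violated.
    """
    if charge_mode not in ("strict", "permissive", "relaxed"):
        raise ValueError(f"unknown charge_mode {charge_mode!r}")
    # Dots inside brackets or ring-bond context do not occur at the top level
    # of component-separated SMILES, so a plain split is safe here.
    parts = text.split(".")
    if len(parts) != 2:
        raise ParseError(
            f"pair {pair_id!r}: expected exactly one component dot in {text!r}, "
            f"found {len(parts) - 1}"
        )
    cat_smiles, cat = _canonical(parts[0], "cation", pair_id)
    ani_smiles, ani = _canonical(parts[1], "anion", pair_id)

    if charge_mode != "relaxed":
        qc = Chem.GetFormalCharge(cat)
        qa = Chem.GetFormalCharge(ani)
        if charge_mode == "strict":
            if qc != 1:
                raise ValidationError(
                    f"pair {pair_id!r}: cation net charge must be +1, got {qc:+d}"
                )
            if qa != -1:
                raise ValidationError(
                    f"pair {pair_id!r}: anion net charge must be -1, got {qa:+d}"
                )
        else:
            if qc <= 0:
                raise ValidationError(
                    f"pair {pair_id!r}: cation net charge must be positive, got {qc:+d}"
                )
            if qa >= 0:
                raise ValidationError(
                    f"pair {pair_id!r}: anion net charge must be negative, got {qa:+d}"
                )
            if qc + qa != 0:
                raise ValidationError(
                    f"pair {pair_id!r}: charges must sum to zero, got {qc:+d}{qa:+d}"
                )
    return IonPair(pair_id=pair_id, cation_smiles=cat_smiles, anion_smiles=ani_smiles,
                   charge_mode=charge_mode)


def _validate_value(property_name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{property_name} value must be finite, got {value}")
    if property_name == "co2_capacity" and not (0.0 <= value <= 1.0):
        raise ValueError(f"co2_capacity is a mole fraction in [0, 1], got {value}")
    if property_name == "refractive_index" and not value > 1.0:
        raise ValueError(f"refractive_index must exceed 1, got {value}")


@dataclass(frozen=True)
class PropertyRecord:
    """One measurement: an ion pair, its conditions, and a property value.

    Values are stored in canonical units: viscosity as log10(mPa·s),
    CO2 capacity as a mole fraction, refractive index dimensionless,
    toxicity as log EC50.
    """

    ion_pair: IonPair
    conditions: Conditions
    property_name: str
    value: float

    def __post_init__(self) -> None:
        if self.property_name not in PROPERTY_CONDITIONS:
            raise ValueError(
                f"unknown property {self.property_name!r}; expected one of {PROPERTIES}"
            )
        _validate_value(self.property_name, self.value)


SPLIT_LABELS = ("train", "test", "unassigned")


@dataclass
class PropertyDataset:
    """An ordered collection of :class:`PropertyRecord` sharing one property.

    ``split_labels[i]`` labels ``records[i]`` as train/test/unassigned.
    Duplicate (pair, conditions) records are retained; :meth:`duplicate_mask`
    flags them and :meth:`deduplicate` drops them explicitly.
    """

    property_name: str
    records: list[PropertyRecord] = field(default_factory=list)
    split_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.split_labels:
            self.split_labels = ["unassigned"] * len(self.records)
        if len(self.split_labels) != len(self.records):
            raise ValueError("split_labels length must match records length")
        for rec in self.records:
            if rec.property_name != self.property_name:
                raise ValueError(
                    f"record property {rec.property_name!r} != dataset "
                    f"property {self.property_name!r}"
                )
        for lab in self.split_labels:
            if lab not in SPLIT_LABELS:
                raise ValueError(f"unknown split label {lab!r}")
        ids = [r.ion_pair.pair_id for r in self.records]
        # pair_id may repeat across conditions; the record identifier is
        # (pair_id, conditions), enforced unique.
        keys = [(r.ion_pair.pair_id, r.conditions) for r in self.records]
        if len(set(ids)) < len(set(keys)):
            pass  # same pair at different conditions is fine
        seen: set = set()
        for k in keys:
            if k in seen:
                logger.warning("duplicate record (pair %s at %s) retained", k[0], k[1])
            seen.add(k)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def pairs(self) -> list[IonPair]:
        return [r.ion_pair for r in self.records]

    @property
    def conditions(self) -> list[Conditions]:
        return [r.conditions for r in self.records]

    @property
    def values(self) -> np.ndarray:
        return np.asarray([r.value for r in self.records], dtype=float)

    def duplicate_mask(self) -> np.ndarray:
        """True for every record whose (pair_id, conditions) already occurred."""
        seen: set = set()
        mask = np.zeros(len(self.records), dtype=bool)
        for i, rec in enumerate(self.records):
            key = (rec.ion_pair.pair_id, rec.conditions)
            mask[i] = key in seen
            seen.add(key)
        return mask

    def deduplicate(self) -> "PropertyDataset":
        keep = ~self.duplicate_mask()
        return self.subset(np.nonzero(keep)[0])

    def subset(self, indices, split_label: str | None = None) -> "PropertyDataset":
        indices = list(indices)
        labels = (
            [split_label] * len(indices)
            if split_label is not None
            else [self.split_labels[i] for i in indices]
        )
        return PropertyDataset(
            property_name=self.property_name,
            records=[self.records[i] for i in indices],
            split_labels=labels,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pair_id": r.ion_pair.pair_id,
                "cation_smiles": r.ion_pair.cation_smiles,
                "anion_smiles": r.ion_pair.anion_smiles,
                "temperature_K": r.conditions.temperature_K,
                "pressure_kPa": r.conditions.pressure_kPa,
                "value": r.value,
                "split": lab,
            }
            for r, lab in zip(self.records, self.split_labels)
        ]
        return pd.DataFrame(rows)


DEFAULT_COLUMNS = {
    "pair_id": "pair_id",
    "cation_smiles": "cation_smiles",
    "anion_smiles": "anion_smiles",
    "temperature_K": "temperature_K",
    "pressure_kPa": "pressure_kPa",
    "value": "value",
    "split": "split",
}


def read_dataset(
    path,
    property_name: str,
    column_map: dict[str, str] | None = None,
    charge_mode: str = "strict",
) -> PropertyDataset:
    """Read a property dataset from CSV.

    Rows whose ion pair fails parsing or charge validation are skipped and
    counted in the log; a file yielding zero valid rows is an error.  Optional
    columns (``pair_id``, conditions, ``split``) fall back to row numbers and
    standard ambient conditions.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("cation_smiles", "anion_smiles", "value"):
        if cols[key] not in df.columns:
            raise SchemaError(f"missing required column {cols[key]!r} in {path}")

    records: list[PropertyRecord] = []
    labels: list[str] = []
    n_skipped = 0
    for i, row in df.iterrows():
        pair_id = str(row[cols["pair_id"]]) if cols["pair_id"] in df.columns else f"row{i}"
        text = f"{row[cols['cation_smiles']]}.{row[cols['anion_smiles']]}"
        try:
            pair = parse_ion_pair(text, pair_id, charge_mode=charge_mode)
            cond = Conditions(
                temperature_K=float(row.get(cols["temperature_K"], STANDARD_TEMPERATURE_K)),
                pressure_kPa=float(row.get(cols["pressure_kPa"], STANDARD_PRESSURE_KPA)),
            )
            rec = PropertyRecord(pair, cond, property_name, float(row[cols["value"]]))
        except (ParseError, ValidationError, ValueError) as exc:
            n_skipped += 1
            logger.warning("skipping row %s: %s", i, exc)
            continue
        records.append(rec)
        labels.append(
            str(row[cols["split"]]) if cols["split"] in df.columns else "unassigned"
        )
    if n_skipped:
        logger.info("read_dataset: skipped %d invalid rows of %d", n_skipped, len(df))
    if not records:
        raise EmptyDatasetError(f"no valid rows in {path}")
    return PropertyDataset(property_name=property_name, records=records, split_labels=labels)


def write_dataset(dataset: PropertyDataset, path) -> None:
    """Write a dataset to CSV so that :func:`read_dataset` round-trips it."""
    if len(dataset) == 0:
        raise EmptyDatasetError("refusing to write an empty dataset")
    # 17 significant digits round-trips IEEE doubles exactly
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")


def split_dataset(
    dataset: PropertyDataset, test_fraction: float, seed: int
) -> tuple[PropertyDataset, PropertyDataset]:
    """Uniform random disjoint train/test partition with a recorded seed.

    ``|test| = round(test_fraction * n)``; the same seed reproduces the split.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    n = len(dataset)
    if n < 5:
        raise ValueError(f"need at least 5 records to split, got {n}")
    n_test = int(round(test_fraction * n))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return (
        dataset.subset(train_idx, split_label="train"),
        dataset.subset(test_idx, split_label="test"),
    )
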