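"""Chemical record curation for CYP substrate data sets.

Parses raw structures (SMILES or SDF blocks), standardizes them with the
ChEMBL-style normalization rules shipped in RDKit's ``rdMolStandardize``
(salt/solvent stripping, neutralization, isotope removal), filters by an
allowed-element whitelist, canonicalizes tautomers (dropping stereochemistry),
and merges duplicate structures under conservative label-consistency rules:
conflicting substrate/non-substrate annotations for the same structure and
isozyme are blanked to MISSING rather than resolved by majority.
"""

from __future__ import annotations

import enum
import json
from collections import OrderedDict
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Elements tolerated in curated structures; anything else is discarded.
ALLOWED_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"]
)


class CypIsozyme(enum.Enum):
    """The nine human CYP isozymes modeled; ordering is fixed for reporting."""

    CYP1A2 = "1A2"
    CYP2A6 = "2A6"
    CYP2B6 = "2B6"
    CYP2C8 = "2C8"
    CYP2C9 = "2C9"
    CYP2C19 = "2C19"
    CYP2D6 = "2D6"
    CYP2E1 = "2E1"
    CYP3A4 = "3A4"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"CYP{self.value}"


CYP_ORDER: tuple[CypIsozyme, ...] = tuple(CypIsozyme)


class ActivityLabel(enum.Enum):
    """Three-state activity annotation; MISSING rows are excluded from training."""

    SUBSTRATE = "substrate"
    NON_SUBSTRATE = "non_substrate"
    MISSING = "missing"


class StandardizationError(ValueError):
    """Raised when a raw structure cannot be parsed or standardized.

    Carries the offending input so callers can keep removal counts.
    """

    def __init__(self, raw_structure: str, reason: str):
        super().__init__(f"{reason}: {raw_structure!r}")
        self.raw_structure = raw_structure
        self.reason = reason


@dataclass
class MoleculeRecord:
    """One standardized, stereochemistry-free structure with provenance."""

    record_id: str
    smiles_canonical: str
    source_tag: str = ""
    labels: dict[CypIsozyme, ActivityLabel] = field(default_factory=dict)

    def label(self, cyp: CypIsozyme) -> ActivityLabel:
        return self.labels.get(cyp, ActivityLabel.MISSING)


@dataclass
class LabeledDataset:
    """Deduplicated molecules with a records x 9-isozyme label matrix."""

    records: list[MoleculeRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.smiles_canonical in seen:
                raise ValueError(
                    f"duplicate structure in dataset: {rec.smiles_canonical}"
                )
            seen.add(rec.smiles_canonical)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def completeness(self) -> float:
        """Fraction of non-MISSING cells in the records x isozymes matrix."""
        if not self.records:
            return 0.0
        defined = sum(
            1
            for rec in self.records
            for cyp in CYP_ORDER
            if rec.label(cyp) is not ActivityLabel.MISSING
        )
        return defined / (len(self.records) * len(CYP_ORDER))

    def subset_for(self, cyp: CypIsozyme) -> "LabeledDataset":
        """Records with a defined (non-MISSING) label for one isozyme."""
        return LabeledDataset(
            [r for r in self.records if r.label(cyp) is not ActivityLabel.MISSING]
        )

    def smiles(self) -> list[str]:
        return [r.smiles_canonical for r in self.records]

    def labels_for(self, cyp: CypIsozyme) -> list[ActivityLabel]:
        return [r.label(cyp) for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {"id": rec.record_id, "smiles": rec.smiles_canonical,
                   "source": rec.source_tag}
            for cyp in CYP_ORDER:
                lab = rec.label(cyp)
                row[f"CYP{cyp.value}"] = (
                    "" if lab is ActivityLabel.MISSING else lab.value
                )
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class ProcessingLog:
    """Per-stage removal counts for a curation run (removal-accounting schema)."""

    initial: int = 0
    missing_structure: int = 0
    unparsable: int = 0
    element_filtered: int = 0
    duplicates_removed: int = 0
    conflicting_label_cells: int = 0
    final: int = 0
    rejected: list[dict] = field(default_factory=list)

    def reject(self, raw: str, reason: str) -> None:
        self.rejected.append({"input": raw, "reason": reason})

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMER_ENUMERATOR = rdMolStandardize.TautomerEnumerator()


def _mol_from_raw(raw_structure: str, dialect: str) -> Chem.Mol | None:
    if dialect == "smiles":
        return Chem.MolFromSmiles(raw_structure)
    if dialect == "sdf-block":
        return Chem.MolFromMolBlock(raw_structure)
    raise ValueError(f"unknown structure dialect: {dialect!r}")


def parse_and_standardize(
    raw_structure: str,
    dialect: str = "smiles",
    record_id: str = "",
    source_tag: str = "",
) -> MoleculeRecord:
    """Parse a raw structure and standardize it to a stereo-free parent.

    Applies normalization of frequent substructure drawing variants,
    salt/solvent stripping to the parent component, neutralization, isotope
    removal, and stereochemistry removal.

    Raises
    ------
    StandardizationError
        If the input is empty, unparsable, or fails standardization.
    """
    if not raw_structure or not raw_structure.strip():
        raise StandardizationError(raw_structure, "empty structure")
    mol = _mol_from_raw(raw_structure, dialect)
    if mol is None:
        raise StandardizationError(raw_structure, "unparsable structure")
    try:
        mol = rdMolStandardize.Cleanup(mol)
        mol = rdMolStandardize.FragmentParent(mol)
        mol = _UNCHARGER.uncharge(mol)
        for atom in mol.GetAtoms():
            atom.SetIsotope(0)
        Chem.RemoveStereochemistry(mol)
        mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    except Exception as exc:  # RDKit raises a zoo of exception types
        raise StandardizationError(raw_structure, f"standardization failed ({exc})")
    if mol is None or mol.GetNumAtoms() == 0:
        raise StandardizationError(raw_structure, "standardization yielded no atoms")
    return MoleculeRecord(
        record_id=record_id or raw_structure,
        smiles_canonical=Chem.MolToSmiles(mol),
        source_tag=source_tag,
    )


def filter_elements(record: MoleculeRecord) -> bool:
    """Keep a record iff every atom's element is in ``ALLOWED_ELEMENTS``."""
    mol = Chem.MolFromSmiles(record.smiles_canonical)
    if mol is None:  # defensive: record invariant guarantees parseability
        return False
    return all(atom.GetSymbol() in ALLOWED_ELEMENTS for atom in mol.GetAtoms())


def canonicalize_tautomer(record: MoleculeRecord) -> MoleculeRecord:
    """Replace the structure with its canonical tautomer, stereo removed.

    Any two tautomeric forms of the same compound map to an identical
    canonical string, which then serves as the duplicate-identity key.
    """
    mol = Chem.MolFromSmiles(record.smiles_canonical)
    if mol is None:
        raise StandardizationError(record.smiles_canonical, "unparsable structure")
    try:
        mol = _TAUTOMER_ENUMERATOR.Canonicalize(mol)
        Chem.RemoveStereochemistry(mol)
    except Exception as exc:
        raise StandardizationError(
            record.smiles_canonical, f"tautomer canonicalization failed ({exc})"
        )
    return MoleculeRecord(
        record_id=record.record_id,
        smiles_canonical=Chem.MolToSmiles(mol),
        source_tag=record.source_tag,
        labels=dict(record.labels),
    )


# ---------------------------------------------------------------------------
# Deduplication and data-set compilation
# ---------------------------------------------------------------------------

def _merge_labels(
    labels: Sequence[ActivityLabel],
) -> tuple[ActivityLabel, bool]:
    """Merge per-isozyme labels of duplicate records.

    Returns the merged label and whether a substrate/non-substrate conflict
    was blanked. Consistent labels are kept; a one-sided MISSING never
    overrides a defined label; a conflict yields MISSING for that isozyme.
    """
    defined = {l for l in labels if l is not ActivityLabel.MISSING}
    if not defined:
        return ActivityLabel.MISSING, False
    if len(defined) == 1:
        return next(iter(defined)), False
    return ActivityLabel.MISSING, True


def merge_duplicates(
    records: Iterable[MoleculeRecord],
) -> tuple[LabeledDataset, ProcessingLog]:
    """Collapse records sharing a canonical structure into one record each.

    The merged record keeps the first-seen record_id, concatenates distinct
    source tags, and merges labels per isozyme under the conflict rule
    (conflict -> MISSING). The log reports the number of removed duplicate
    entries and of blanked conflicting cells.
    """
    groups: "OrderedDict[str, list[MoleculeRecord]]" = OrderedDict()
    n_in = 0
    for rec in records:
        n_in += 1
        groups.setdefault(rec.smiles_canonical, []).append(rec)

    merged: list[MoleculeRecord] = []
    log = ProcessingLog(initial=n_in)
    for smiles, group in groups.items():
        labels: dict[CypIsozyme, ActivityLabel] = {}
        for cyp in CYP_ORDER:
            lab, conflicted = _merge_labels([r.label(cyp) for r in group])
            if conflicted:
                log.conflicting_label_cells += 1
            if lab is not ActivityLabel.MISSING:
                labels[cyp] = lab
        sources = list(dict.fromkeys(r.source_tag for r in group if r.source_tag))
        merged.append(
            MoleculeRecord(
                record_id=group[0].record_id,
                smiles_canonical=smiles,
                source_tag="+".join(sources),
                labels=labels,
            )
        )
    log.duplicates_removed = n_in - len(merged)
    log.final = len(merged)
    return LabeledDataset(merged), log


def curate_records(
    raw_rows: Iterable[tuple[str, str, dict[CypIsozyme, ActivityLabel]]],
    dialect: str = "smiles",
    source_tag: str = "",
) -> tuple[list[MoleculeRecord], ProcessingLog]:
    """Run the full per-record curation chain with removal accounting.

    ``raw_rows`` yields ``(record_id, raw_structure, labels)`` triples.
    Stages: missing-structure check, parse+standardize, element filter,
    tautomer canonicalization. Rejected rows are logged with reason codes,
    never silently dropped.
    """
    log = ProcessingLog()
    out: list[MoleculeRecord] = []
    for record_id, raw, labels in raw_rows:
        log.initial += 1
        if raw is None or not str(raw).strip():
            log.missing_structure += 1
            log.reject(str(raw), "missing structure")
            continue
        try:
            rec = parse_and_standardize(
                str(raw), dialect=dialect, record_id=record_id, source_tag=source_tag
            )
        except StandardizationError as exc:
            log.unparsable += 1
            log.reject(exc.raw_structure, exc.reason)
            continue
        rec.labels = dict(labels)
        if not filter_elements(rec):
            log.element_filtered += 1
            log.reject(rec.smiles_canonical, "disallowed element")
            continue
        try:
            rec = canonicalize_tautomer(rec)
        except StandardizationError as exc:
            log.unparsable += 1
            log.reject(exc.raw_structure, exc.reason)
            continue
        out.append(rec)
    log.final = len(out)
    return out, log


def compile_core_dataset(
    source_a: Sequence[MoleculeRecord],
    source_b: Sequence[MoleculeRecord],
) -> tuple[LabeledDataset, ProcessingLog]:
    """Union two independently curated sources and deduplicate.

    Both sources must already be standardized and tautomer-canonicalized.
    The log carries the duplicate-removal counts of the combined pass.
    """
    union = list(source_a) + list(source_b)
    if not union:
        raise ValueError("cannot compile a core data set from empty sources")
    return merge_duplicates(union)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_LABEL_FROM_TEXT = {
    "substrate": ActivityLabel.SUBSTRATE,
    "non_substrate": ActivityLabel.NON_SUBSTRATE,
    "": ActivityLabel.MISSING,
}


def _labels_from_row(getter) -> dict[CypIsozyme, ActivityLabel]:
    labels: dict[CypIsozyme, ActivityLabel] = {}
    for cyp in CYP_ORDER:
        text = getter(f"CYP{cyp.value}")
        if text is None:
            continue
        text = str(text).strip().lower()
        if text in ("", "nan"):
            continue
        try:
            lab = _LABEL_FROM_TEXT[text]
        except KeyError:
            raise ValueError(f"unrecognized activity label {text!r} for CYP{cyp.value}")
        if lab is not ActivityLabel.MISSING:
            labels[cyp] = lab
    return labels


def read_molecule_csv(path) -> list[tuple[str, str, dict[CypIsozyme, ActivityLabel]]]:
    """Read raw rows from the standard CSV dialect (id, smiles, CYP columns)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "smiles" not in df.columns:
        raise ValueError("CSV must have a 'smiles' column")
    rows = []
    for i, row in df.iterrows():
        rid = str(row["id"]) if "id" in df.columns else f"row{i}"
        rows.append((rid, row["smiles"], _labels_from_row(lambda c: row.get(c))))
    return rows


def read_molecule_sdf(path) -> list[tuple[str, str, dict[CypIsozyme, ActivityLabel]]]:
    """Read raw rows from an SDF; activity labels are taken from SD tags."""
    rows = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            rows.append((f"sdf{i}", "", {}))  # counted as unparsable downstream
            continue
        props = mol.GetPropsAsDict()
        rid = str(props.get("id", mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf{i}"))
        labels = _labels_from_row(lambda c: props.get(c))
        rows.append((rid, Chem.MolToSmiles(mol), labels))
    return rows


def write_dataset_csv(dataset: LabeledDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def write_processing_log(log: ProcessingLog, path) -> None:
    with open(path, "w") as fh:
        fh.write(log.to_json())
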