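"""Molecular descriptor sets for the CYP classifiers.

Four feature families: MACCS structural keys (166 bits), Morgan circular
fingerprints (radius 2, 2048 bits), the full RDKit collection of 2D
physicochemical descriptors, and 300-dimensional continuous substructure
embeddings (mol2vec-style: a molecule is the sum of the vectors of its
radius-0/1 Morgan atom-environment identifiers).
"""

from __future__ import annotations

import enum
import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator, rdMolDescriptors

from .curate import LabeledDataset, MoleculeRecord, StandardizationError

EMBEDDING_DIM = 300
MORGAN_BITS = 2048
MORGAN_RADIUS = 2


class FeatureSet(enum.Enum):
    """The four descriptor families; ordering fixes deterministic tie-breaks."""

    MACCS = "MACCS"
    MORGAN2 = "MORGAN2"
    PHYSCHEM2D = "PHYSCHEM2D"
    EMBED300 = "EMBED300"


#: Binary-valued feature sets (no standardization needed on the SVM path).
BINARY_FEATURE_SETS = frozenset({FeatureSet.MACCS, FeatureSet.MORGAN2})

#: Semantic names for documented MACCS keys (A = any atom, Q = heteroatom,
#: X = halogen, % = aromatic bond), following the public 166-key dictionary.
MACCS_KEY_NAMES = {
    125: "AromaticRing>1",
    162: "Aromatic",
    163: "6MRing",
}


@dataclass
class FeatureMatrix:
    """Named feature columns aligned row-for-row with a LabeledDataset."""

    values: pd.DataFrame
    feature_set: FeatureSet

    @property
    def binary_flag(self) -> bool:
        return self.feature_set in BINARY_FEATURE_SETS

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# feature_set={self.feature_set.value}\n")
            self.values.to_csv(fh, index=True, index_label="record_id")


def _mol(record: MoleculeRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(record.smiles_canonical)
    if mol is None:
        raise StandardizationError(record.smiles_canonical, "unparsable structure")
    return mol


# ---------------------------------------------------------------------------
# MACCS keys
# ---------------------------------------------------------------------------

MACCS_FEATURE_NAMES = [
    MACCS_KEY_NAMES.get(i, f"MACCS_{i:03d}") for i in range(1, 167)
]


def maccs_keys(record: MoleculeRecord) -> np.ndarray:
    """166 binary structural keys (RDKit's public MACCS dialect).

    The "Aromatic" key (166-key index 162) is set iff the molecule contains
    at least one aromatic atom.
    """
    mol = _mol(record)
    try:
        bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
    except Exception as exc:
        raise StandardizationError(record.smiles_canonical, f"MACCS failure ({exc})")
    arr = np.zeros(166, dtype=np.uint8)
    for bit in bv.GetOnBits():
        if bit >= 1:
            arr[bit - 1] = 1
    return arr


# ---------------------------------------------------------------------------
# Morgan fingerprints
# ---------------------------------------------------------------------------

_morgan_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=MORGAN_RADIUS, fpSize=MORGAN_BITS
)


def morgan_fingerprint(
    record: MoleculeRecord, radius: int = MORGAN_RADIUS, n_bits: int = MORGAN_BITS
) -> np.ndarray:
    """Binary circular fingerprint, radius 2 folded to 2048 bits by default."""
    mol = _mol(record)
    if radius == MORGAN_RADIUS and n_bits == MORGAN_BITS:
        gen = _morgan_generator
    else:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in gen.GetFingerprint(mol).GetOnBits():
        arr[bit] = 1
    return arr


# ---------------------------------------------------------------------------
# Physicochemical (2D) descriptors
# ---------------------------------------------------------------------------

PHYSCHEM_FEATURE_NAMES = [name for name, _ in Descriptors._descList]


def physchem_descriptors(record: MoleculeRecord) -> np.ndarray:
    """All RDKit 2D descriptors, with the averaged-information-content Ipc.

    The Ipc descriptor grows super-exponentially with molecule size in its
    raw form; the averaged variant (avg=1) keeps every value finite in
    float32 range.
    """
    mol = _mol(record)
    values = np.empty(len(PHYSCHEM_FEATURE_NAMES), dtype=np.float64)
    for i, (name, fn) in enumerate(Descriptors._descList):
        try:
            if name == "Ipc":
                values[i] = Descriptors.Ipc(mol, avg=1)
            else:
                values[i] = fn(mol)
        except Exception as exc:
            raise StandardizationError(
                record.smiles_canonical, f"descriptor {name} failure ({exc})"
            )
    if not np.all(np.isfinite(values)):
        bad = [PHYSCHEM_FEATURE_NAMES[i] for i in np.flatnonzero(~np.isfinite(values))]
        raise StandardizationError(
            record.smiles_canonical, f"non-finite descriptors: {bad}"
        )
    return values


# ---------------------------------------------------------------------------
# Substructure embeddings
# ---------------------------------------------------------------------------


class EmbeddingTable:
    """Read-only map from Morgan substructure identifiers to 300-dim vectors.

    Identifiers absent from the table map to the unknown-token vector.
    """

    def __init__(
        self, vectors: dict[int, np.ndarray], unknown: np.ndarray | None = None
    ):
        self.dim = EMBEDDING_DIM if not vectors else len(next(iter(vectors.values())))
        for v in vectors.values():
            if len(v) != self.dim:
                raise ValueError("embedding vectors must share one dimension")
        self.vectors = {k: np.asarray(v, dtype=np.float64) for k, v in vectors.items()}
        self.unknown = (
            np.zeros(self.dim) if unknown is None else np.asarray(unknown, dtype=float)
        )
        if len(self.unknown) != self.dim:
            raise ValueError("unknown-token vector has wrong dimension")

    def lookup(self, identifier: int) -> np.ndarray:
        return self.vectors.get(identifier, self.unknown)

    @classmethod
    def load(cls, path) -> "EmbeddingTable":
        """Load a plain-text table: one row = identifier then 300 numbers.

        A row keyed ``UNK`` supplies the unknown-token vector. Gzip input is
        detected by the ``.gz`` suffix.
        """
        opener = gzip.open if str(path).endswith(".gz") else open
        vectors: dict[int, np.ndarray] = {}
        unknown = None
        with opener(path, "rt") as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                vec = np.array([float(x) for x in parts[1:]])
                if parts[0] == "UNK":
                    unknown = vec
                else:
                    vectors[int(parts[0])] = vec
        return cls(vectors, unknown)


class HashedEmbeddingTable(EmbeddingTable):
    """Deterministic pseudo-embeddings from hashed substructure identifiers.

    Each identifier seeds a PRNG that draws its 300-dim vector, so any
    identifier has a reproducible embedding and no token is unknown. This is
    a self-contained stand-in for an externally trained embedding model; the
    geometry of the resulting space is synthetic, not learned.
    """

    def __init__(self, dim: int = EMBEDDING_DIM, seed: int = 0):
        super().__init__({})
        self.dim = dim
        self.seed = seed
        self.unknown = np.zeros(dim)
        self._cache: dict[int, np.ndarray] = {}

    def lookup(self, identifier: int) -> np.ndarray:
        vec = self._cache.get(identifier)
        if vec is None:
            rng = np.random.default_rng((self.seed * 0x9E3779B1 + identifier) % 2**63)
            vec = rng.standard_normal(self.dim) / np.sqrt(self.dim)
            self._cache[identifier] = vec
        return vec


def substructure_identifiers(record: MoleculeRecord) -> list[int]:
    """Radius-0 and radius-1 Morgan atom-environment identifiers, one per
    (atom, radius) occurrence (multiplicity preserved)."""
    mol = _mol(record)
    info: dict[int, tuple] = {}
    rdMolDescriptors.GetMorganFingerprint(mol, 1, bitInfo=info)
    occurrences: list[tuple[int, int, int]] = []  # (atom, radius, identifier)
    for identifier, sites in info.items():
        for atom_idx, radius in sites:
            occurrences.append((atom_idx, radius, identifier))
    occurrences.sort()
    return [identifier for _, _, identifier in occurrences]


def substructure_embedding(
    record: MoleculeRecord, table: EmbeddingTable
) -> np.ndarray:
    """Molecule vector = sum of its substructure-identifier vectors."""
    if table is None:
        raise ValueError("an embedding table is required for EMBED300 features")
    total = np.zeros(table.dim)
    for identifier in substructure_identifiers(record):
        total += table.lookup(identifier)
    return total


# ---------------------------------------------------------------------------
# Data-set featurization
# ---------------------------------------------------------------------------

def featurize_dataset(
    dataset: LabeledDataset,
    feature_set: FeatureSet,
    embedding_table: EmbeddingTable | None = None,
) -> FeatureMatrix:
    """Compute one feature family for every record, preserving row order."""
    if feature_set is FeatureSet.MACCS:
        rows = [maccs_keys(r) for r in dataset.records]
        names = MACCS_FEATURE_NAMES
    elif feature_set is FeatureSet.MORGAN2:
        rows = [morgan_fingerprint(r) for r in dataset.records]
        names = [f"Morgan2_{i}" for i in range(MORGAN_BITS)]
    elif feature_set is FeatureSet.PHYSCHEM2D:
        rows = [physchem_descriptors(r) for r in dataset.records]
        names = PHYSCHEM_FEATURE_NAMES
    elif feature_set is FeatureSet.EMBED300:
        table = embedding_table or HashedEmbeddingTable()
        rows = [substructure_embedding(r, table) for r in dataset.records]
        names = [f"embed_{i}" for i in range(table.dim)]
    else:  # pragma: no cover
        raise ValueError(f"unknown feature set {feature_set}")
    df = pd.DataFrame(
        np.asarray(rows, dtype=np.float64),
        columns=names,
        index=[r.record_id for r in dataset.records],
    )
    return FeatureMatrix(values=df, feature_set=feature_set)
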