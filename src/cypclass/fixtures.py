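"""Synthetic labeled molecule sets for exercising the whole pipeline.

Structures are assembled by template substitution — a fixed scaffold list
crossed with a substituent list — which guarantees chemically valid SMILES
without a validity-checking loop. Labels follow a planted structural rule
(default: substrate iff the molecule contains an aromatic ring and at least
one oxygen atom), optionally flipped by label noise and masked to MISSING,
so that a perfect classifier exists by construction. These fixtures test
machinery, not real CYP structure-activity relationships.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from rdkit import Chem

from .curate import (
    ActivityLabel,
    CYP_ORDER,
    CypIsozyme,
    LabeledDataset,
    MoleculeRecord,
    canonicalize_tautomer,
    filter_elements,
    merge_duplicates,
    parse_and_standardize,
)

#: Two-site scaffold templates; {R1} substitutes as a prefix fragment and
#: {R2} as a parenthesized branch, both positions carrying plain SMILES
#: fragments from SUBSTITUENTS.
SCAFFOLDS: tuple[str, ...] = (
    "{R1}c1ccc({R2})cc1",        # para-disubstituted benzene
    "{R1}c1cccc({R2})c1",        # meta-disubstituted benzene
    "{R1}c1ccc({R2})nc1",        # disubstituted pyridine
    "{R1}c1ccc2cc({R2})ccc2c1",  # disubstituted naphthalene
    "{R1}c1ccc({R2})s1",         # disubstituted thiophene
    "{R1}C1CCC({R2})CC1",        # disubstituted cyclohexane
    "{R1}C1CCC({R2})C1",         # disubstituted cyclopentane
    "{R1}C1CCN({R2})CC1",        # N-substituted piperidine
    "{R1}CCCC{R2}",              # flexible chain
    "{R1}CC(C)C{R2}",            # branched chain
)

#: Substituent fragments, valid both as SMILES prefixes and branches.
#: Roughly half contain oxygen so the default planted rule splits the
#: library into sizeable substrate and non-substrate pools.
SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "CCCC", "CC(C)C", "C(C)C",
    "N", "NC", "NCC", "CN", "F", "Cl", "Br", "CS",
    "O", "OC", "OCC", "CO", "CCO", "C(=O)C", "C(=O)O",
    "CC(=O)O", "OC(C)=O", "C(=O)N",
)


def rule_aromatic_and_oxygen(mol: Chem.Mol) -> bool:
    """Default planted rule: >=1 aromatic atom AND >=1 oxygen atom."""
    has_arom = any(a.GetIsAromatic() for a in mol.GetAtoms())
    has_oxy = any(a.GetSymbol() == "O" for a in mol.GetAtoms())
    return has_arom and has_oxy


@dataclass
class FixtureConfig:
    n_compounds: int = 200
    imbalance_ratio: tuple[int, int] = (1, 4)  # substrates : non-substrates
    planted_rule: Callable[[Chem.Mol], bool] = rule_aromatic_and_oxygen
    label_noise: float = 0.0
    missing_fraction: float = 0.0
    seed: int = 0
    cyps: tuple[CypIsozyme, ...] = CYP_ORDER

    def __post_init__(self):
        a, b = self.imbalance_ratio
        if a <= 0 or b <= 0:
            raise ValueError("imbalance ratio parts must be positive")
        if not (0 <= self.label_noise < 1) or not (0 <= self.missing_fraction < 1):
            raise ValueError("noise and missing fractions must lie in [0, 1)")


_library_cache: list[tuple[str, bool]] | None = None
_LIBRARY_RULE = rule_aromatic_and_oxygen


def _build_library() -> list[tuple[str, bool]]:
    """Curated, deduplicated (smiles, default-rule) pairs in a fixed order."""
    global _library_cache
    if _library_cache is not None:
        return _library_cache
    seen: set[str] = set()
    library: list[tuple[str, bool]] = []
    for scaffold in SCAFFOLDS:
        for r1 in SUBSTITUENTS:
            for r2 in SUBSTITUENTS:
                raw = scaffold.format(R1=r1, R2=r2)
                try:
                    rec = parse_and_standardize(raw)
                    rec = canonicalize_tautomer(rec)
                except Exception:
                    # a few substituents are only valid at one site; the
                    # grammar never emits them into the library
                    continue
                if rec.smiles_canonical in seen or not filter_elements(rec):
                    continue
                seen.add(rec.smiles_canonical)
                mol = Chem.MolFromSmiles(rec.smiles_canonical)
                library.append((rec.smiles_canonical, _LIBRARY_RULE(mol)))
    _library_cache = library
    return library


def generate_labeled_set(config: FixtureConfig) -> LabeledDataset:
    """Build a labeled data set with an exact class ratio by construction.

    Substrates are drawn from the rule-positive pool and non-substrates from
    the rule-negative pool, so with zero noise a rule-based classifier
    reproduces every label. Per-isozyme labels are then independently
    flipped with probability ``label_noise`` and masked MISSING with
    probability ``missing_fraction``. Deterministic per seed.
    """
    a, b = config.imbalance_ratio
    if config.n_compounds * a % (a + b) or config.n_compounds * b % (a + b):
        raise ValueError(
            f"ratio {a}:{b} does not divide n_compounds={config.n_compounds}"
        )
    n_sub = config.n_compounds * a // (a + b)
    n_non = config.n_compounds - n_sub

    rng = np.random.default_rng(config.seed)
    if config.planted_rule is _LIBRARY_RULE:
        library = _build_library()
    else:
        library = [
            (smi, config.planted_rule(Chem.MolFromSmiles(smi)))
            for smi, _ in _build_library()
        ]
    positives = [smi for smi, hit in library if hit]
    negatives = [smi for smi, hit in library if not hit]
    if n_sub > len(positives) or n_non > len(negatives):
        raise ValueError(
            f"library pools too small for {n_sub} substrates / {n_non} "
            f"non-substrates (have {len(positives)} / {len(negatives)})"
        )
    chosen_pos = list(rng.choice(len(positives), size=n_sub, replace=False))
    chosen_neg = list(rng.choice(len(negatives), size=n_non, replace=False))
    entries = [(positives[i], True) for i in chosen_pos] + [
        (negatives[i], False) for i in chosen_neg
    ]
    rng.shuffle(entries)

    records = []
    for idx, (smi, is_substrate) in enumerate(entries):
        labels: dict[CypIsozyme, ActivityLabel] = {}
        for cyp in config.cyps:
            value = is_substrate
            if config.label_noise > 0 and rng.random() < config.label_noise:
                value = not value
            if config.missing_fraction > 0 and rng.random() < config.missing_fraction:
                continue  # MISSING for this isozyme
            labels[cyp] = (
                ActivityLabel.SUBSTRATE if value else ActivityLabel.NON_SUBSTRATE
            )
        records.append(
            MoleculeRecord(
                record_id=f"fix{idx:05d}",
                smiles_canonical=smi,
                source_tag="fixture",
                labels=labels,
            )
        )
    return LabeledDataset(records)


# ---------------------------------------------------------------------------
# Duplicate-merge scenarios
# ---------------------------------------------------------------------------

@dataclass
class DuplicateScenario:
    """Records with planted duplicates plus the expected merge outcome."""

    records: list[MoleculeRecord]
    expected: dict[str, dict[CypIsozyme, ActivityLabel]] = field(
        default_factory=dict
    )


def _expected_merge(
    groups: dict[str, list[MoleculeRecord]]
) -> dict[str, dict[CypIsozyme, ActivityLabel]]:
    """Cell-level oracle for the merge rules, computed per label set."""
    expected = {}
    for smi, group in groups.items():
        cell: dict[CypIsozyme, ActivityLabel] = {}
        for cyp in CYP_ORDER:
            defined = {
                r.label(cyp) for r in group if r.label(cyp) is not ActivityLabel.MISSING
            }
            if len(defined) == 1:
                cell[cyp] = next(iter(defined))
            else:  # none defined, or a substrate/non-substrate conflict
                cell[cyp] = ActivityLabel.MISSING
        expected[smi] = cell
    return expected


def generate_duplicate_scenarios(seed: int = 0) -> DuplicateScenario:
    """Planted duplicate records: at least one consistent pair, one
    conflicting pair, and one one-sided-missing pair, plus randomized
    multi-duplicate groups; carries a machine-readable expected outcome."""
    rng = np.random.default_rng(seed)
    library = _build_library()
    smiles = [smi for smi, _ in library]
    picks = rng.choice(len(smiles), size=8, replace=False)
    s = [smiles[i] for i in picks]
    sub, non, miss = (
        ActivityLabel.SUBSTRATE,
        ActivityLabel.NON_SUBSTRATE,
        ActivityLabel.MISSING,
    )

    def rec(i, smi, **labels):
        return MoleculeRecord(
            record_id=f"dup{i}",
            smiles_canonical=smi,
            source_tag="fixture",
            labels={CypIsozyme(k): v for k, v in labels.items() if v is not miss},
        )

    records = [
        # consistent pair on CYP1A2
        rec(0, s[0], **{"1A2": sub, "3A4": non}),
        rec(1, s[0], **{"1A2": sub}),
        # conflicting pair on CYP1A2
        rec(2, s[1], **{"1A2": sub, "2D6": sub}),
        rec(3, s[1], **{"1A2": non, "2D6": sub}),
        # one-sided-missing pair on CYP2C9
        rec(4, s[2], **{"2C9": sub}),
        rec(5, s[2], **{}),
    ]
    # randomized groups over the remaining structures
    i = 6
    for smi in s[3:]:
        for _ in range(int(rng.integers(1, 4))):
            labels = {}
            for cyp in CYP_ORDER:
                draw = rng.random()
                if draw < 0.3:
                    labels[cyp] = sub
                elif draw < 0.6:
                    labels[cyp] = non
            records.append(
                MoleculeRecord(
                    record_id=f"dup{i}",
                    smiles_canonical=smi,
                    source_tag="fixture",
                    labels=labels,
                )
            )
            i += 1
    groups: dict[str, list[MoleculeRecord]] = {}
    for r in records:
        groups.setdefault(r.smiles_canonical, []).append(r)
    return DuplicateScenario(records=records, expected=_expected_merge(groups))


def verify_merge_against_expected(scenario: DuplicateScenario) -> bool:
    """Run merge_duplicates and compare against the scenario's expected key."""
    dataset, _ = merge_duplicates(scenario.records)
    got = {r.smiles_canonical: r for r in dataset.records}
    if set(got) != set(scenario.expected):
        return False
    for smi, cell in scenario.expected.items():
        for cyp, lab in cell.items():
            if got[smi].label(cyp) is not lab:
                return False
    return True
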