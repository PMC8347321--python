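"""Chemical-space characterization: PCA projections and similarity curves.

Positions a curated data set relative to reference compound collections
(approved drugs, cosmetic ingredients, pesticides) in two ways: a PCA of 44
interpretable 2D physicochemical descriptors (z-scored on the pooled data),
and the curve of the proportion of reference compounds whose nearest core
neighbor exceeds each Tanimoto similarity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

#: 44 interpretable 2D descriptors (subset of the PHYSCHEM2D family) used
#: for chemical-space projection: size, lipophilicity, polarity, flexibility,
#: ring composition, topology, charge extremes, and common functional groups.
PCA_DESCRIPTOR_NAMES: tuple[str, ...] = (
    "MolWt", "HeavyAtomCount", "NumValenceElectrons", "NumHeteroatoms",
    "MolLogP", "MolMR", "TPSA", "LabuteASA",
    "NumHDonors", "NumHAcceptors", "NHOHCount", "NOCount",
    "NumRotatableBonds", "FractionCSP3",
    "RingCount", "NumAromaticRings", "NumAliphaticRings", "NumSaturatedRings",
    "NumAromaticCarbocycles", "NumAromaticHeterocycles",
    "NumAliphaticCarbocycles", "NumAliphaticHeterocycles",
    "NumSaturatedCarbocycles", "NumSaturatedHeterocycles",
    "BalabanJ", "BertzCT", "HallKierAlpha",
    "Chi0", "Chi1", "Chi0v", "Chi1v", "Chi2v",
    "Kappa1", "Kappa2", "Kappa3",
    "MaxPartialCharge", "MinPartialCharge",
    "MaxAbsPartialCharge", "MinAbsPartialCharge",
    "fr_NH0", "fr_NH1", "fr_Al_OH", "fr_Ar_OH", "fr_benzene",
)


@dataclass
class ProjectionResult:
    coordinates: np.ndarray            # n_compounds x k
    explained_variance: np.ndarray     # fractions, non-increasing
    feature_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, columns=cols)


@dataclass
class SimilarityCurve:
    thresholds: np.ndarray
    proportions: np.ndarray  # non-increasing; 1.0 at threshold 0

    def at(self, threshold: float) -> float:
        """Proportion of reference compounds with max similarity >= threshold."""
        i = int(np.argmin(np.abs(self.thresholds - threshold)))
        return float(self.proportions[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "proportion": self.proportions}
        )


def pca_projection(features: pd.DataFrame, k: int) -> ProjectionResult:
    """Project z-scored descriptors onto the top-k principal components.

    Constant columns are dropped before scaling (their z-score is undefined);
    components come out ordered by explained variance.
    """
    X = features.to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if int(keep.sum()) < k:
        raise ValueError(
            f"need at least {k} non-constant columns, have {int(keep.sum())}"
        )
    names = [n for n, m in zip(features.columns, keep) if m]
    Xz = StandardScaler().fit_transform(X[:, keep])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(Xz)
    return ProjectionResult(
        coordinates=coords,
        explained_variance=pca.explained_variance_ratio_,
        feature_names=names,
    )


def similarity_threshold_curve(
    reference_fps: np.ndarray,
    core_fps: np.ndarray,
    thresholds: Sequence[float] | None = None,
) -> SimilarityCurve:
    """For each threshold t, the fraction of reference compounds whose
    nearest core-set neighbor has Tanimoto similarity >= t."""
    ref = np.asarray(reference_fps).astype(bool)
    core = np.asarray(core_fps).astype(bool)
    if ref.size == 0 or core.size == 0:
        raise ValueError("both fingerprint sets must be non-empty")
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.001, 0.05), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    max_sims = np.empty(len(ref))
    core_counts = core.sum(axis=1)
    for i, q in enumerate(ref):
        inter = (core & q).sum(axis=1)
        union = core_counts + int(q.sum()) - inter
        sims = np.where(union == 0, 0.0, inter / np.maximum(union, 1))
        max_sims[i] = sims.max()
    proportions = np.array([(max_sims >= t).mean() for t in thresholds])
    return SimilarityCurve(thresholds=thresholds, proportions=proportions)
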