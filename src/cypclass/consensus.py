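"""Combined (consensus) models over the best single classifiers.

Three voting strategies over 2-4 member classifiers with pairwise-distinct
feature sets: soft voting averages substrate probabilities; hard voting
requires a minimum number of members to agree and abstains otherwise (and
emits no probability); max voting takes the single largest class probability
across members and both classes. The enumeration over the 4 feature sets x
2 algorithms x voting modes yields 72 + 96 + 64 = 232 combined models.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .train import Algorithm, TrainedClassifier
from .featurize import FeatureSet


class VotingMode(enum.Enum):
    SOFT = "soft"
    HARD = "hard"
    MAX = "max"


class ConsensusLabel(enum.Enum):
    SUBSTRATE = "substrate"
    NON_SUBSTRATE = "non_substrate"
    ABSTAIN = "abstain"


@dataclass(frozen=True)
class VotingStrategy:
    mode: VotingMode
    min_consensus: int | None = None  # HARD only

    def validate(self, n_members: int) -> None:
        if self.mode is VotingMode.HARD:
            if self.min_consensus is None:
                raise ValueError("hard voting requires min_consensus")
            if self.min_consensus > n_members:
                raise ValueError("min_consensus cannot exceed the member count")
            allowed = {n_members} | ({n_members - 1} if n_members == 4 else set())
            if self.min_consensus not in allowed:
                raise ValueError(
                    f"min_consensus {self.min_consensus} invalid for "
                    f"{n_members} members (allowed: {sorted(allowed)})"
                )
        elif self.min_consensus is not None:
            raise ValueError("min_consensus applies to hard voting only")


@dataclass(frozen=True)
class CombinedSpec:
    """A combined model: per-feature-set algorithm choices + a strategy."""

    members: tuple[tuple[Algorithm, FeatureSet], ...]
    strategy: VotingStrategy

    def __post_init__(self):
        n = len(self.members)
        if n < 2 or n > 4:
            raise ValueError("combined models have 2-4 members")
        feature_sets = [fs for _, fs in self.members]
        if len(set(feature_sets)) != n:
            raise ValueError("member feature sets must be pairwise distinct")
        self.strategy.validate(n)


@dataclass
class ConsensusPrediction:
    label: ConsensusLabel
    probability: float | None  # absent iff hard voting
    member_votes: tuple = ()   # audit: one vote per member


def enumerate_combined_specs(
    feature_sets: Sequence[FeatureSet] = tuple(FeatureSet),
    algorithms: Sequence[Algorithm] = tuple(Algorithm),
) -> list[CombinedSpec]:
    """All combined-model specifications over the best single classifiers.

    For each subset of 2-4 feature sets, each assignment of an algorithm to
    every chosen feature set, and each voting mode: soft, max, and hard with
    full agreement; four-member committees additionally allow hard voting
    with three of four agreeing.
    """
    specs: list[CombinedSpec] = []
    for k in (2, 3, 4):
        for fs_combo in itertools.combinations(feature_sets, k):
            for alg_assign in itertools.product(algorithms, repeat=k):
                members = tuple(zip(alg_assign, fs_combo))
                strategies = [
                    VotingStrategy(VotingMode.SOFT),
                    VotingStrategy(VotingMode.MAX),
                    VotingStrategy(VotingMode.HARD, min_consensus=k),
                ]
                if k == 4:
                    strategies.append(VotingStrategy(VotingMode.HARD, min_consensus=3))
                for strategy in strategies:
                    specs.append(CombinedSpec(members=members, strategy=strategy))
    return specs


# ---------------------------------------------------------------------------
# Voting rules
# ---------------------------------------------------------------------------

def soft_vote(member_probabilities: Sequence[float]) -> ConsensusPrediction:
    """Average the members' substrate probabilities; substrate iff mean > 0.5.

    The tie at exactly 0.5 resolves to non-substrate (strict inequality).
    """
    if len(member_probabilities) == 0:
        raise ValueError("soft voting requires at least one member probability")
    probs = np.asarray(member_probabilities, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    mean = float(probs.mean())
    label = ConsensusLabel.SUBSTRATE if mean > 0.5 else ConsensusLabel.NON_SUBSTRATE
    return ConsensusPrediction(
        label=label, probability=mean, member_votes=tuple(float(p) for p in probs)
    )


def hard_vote(
    member_labels: Sequence[int], min_consensus: int
) -> ConsensusPrediction:
    """Predict the class reached by at least ``min_consensus`` members,
    abstain otherwise. Hard voting emits no probability."""
    labels = list(member_labels)
    if not labels:
        raise ValueError("hard voting requires at least one member label")
    if min_consensus > len(labels):
        raise ValueError("min_consensus cannot exceed the member count")
    n_sub = sum(1 for l in labels if l == 1)
    n_non = len(labels) - n_sub
    if n_sub >= min_consensus:
        label = ConsensusLabel.SUBSTRATE
    elif n_non >= min_consensus:
        label = ConsensusLabel.NON_SUBSTRATE
    else:
        label = ConsensusLabel.ABSTAIN
    return ConsensusPrediction(
        label=label, probability=None, member_votes=tuple(int(l) for l in labels)
    )


def max_vote(
    member_probability_pairs: Sequence[tuple[float, float]],
    atol: float = 1e-6,
) -> ConsensusPrediction:
    """Adopt the single largest class probability across members and both
    classes; exact cross-member ties resolve in member order (substrate
    probability checked before non-substrate within a member)."""
    pairs = list(member_probability_pairs)
    if not pairs:
        raise ValueError("max voting requires at least one member")
    best_prob = -1.0
    best_label = ConsensusLabel.NON_SUBSTRATE
    for p_sub, p_non in pairs:
        if abs(p_sub + p_non - 1.0) > max(atol, 1e-6):
            raise ValueError("each member's class probabilities must sum to 1")
        for prob, label in (
            (p_sub, ConsensusLabel.SUBSTRATE),
            (p_non, ConsensusLabel.NON_SUBSTRATE),
        ):
            if prob > best_prob:  # strict: earlier members win ties
                best_prob = prob
                best_label = label
    return ConsensusPrediction(
        label=best_label,
        probability=float(best_prob),
        member_votes=tuple((float(a), float(b)) for a, b in pairs),
    )


# ---------------------------------------------------------------------------
# Prediction over trained members
# ---------------------------------------------------------------------------

@dataclass
class ConsensusModel:
    """Trained member classifiers tied to a voting strategy."""

    members: list[TrainedClassifier]
    strategy: VotingStrategy

    def __post_init__(self):
        n = len(self.members)
        if n < 2 or n > 4:
            raise ValueError("combined models have 2-4 members")
        fsets = [m.spec.feature_set for m in self.members]
        if len(set(fsets)) != n:
            raise ValueError("member feature sets must be pairwise distinct")
        self.strategy.validate(n)

    def predict(
        self, features_per_member: Sequence[np.ndarray]
    ) -> list[ConsensusPrediction]:
        """Predict each query row; ``features_per_member`` aligns one raw
        feature matrix (same row order) with each member classifier."""
        if len(features_per_member) != len(self.members):
            raise ValueError("need one feature matrix per member")
        probas = [
            m.predict_proba(X) for m, X in zip(self.members, features_per_member)
        ]
        n_rows = {len(p) for p in probas}
        if len(n_rows) != 1:
            raise ValueError("member feature matrices disagree on row count")
        out: list[ConsensusPrediction] = []
        for i in range(n_rows.pop()):
            member_probs = [float(p[i]) for p in probas]
            if self.strategy.mode is VotingMode.SOFT:
                out.append(soft_vote(member_probs))
            elif self.strategy.mode is VotingMode.MAX:
                out.append(max_vote([(p, 1.0 - p) for p in member_probs]))
            else:
                labels = [1 if p > 0.5 else 0 for p in member_probs]
                out.append(hard_vote(labels, self.strategy.min_consensus))
        return out


def predict_consensus(
    model: ConsensusModel, features_per_member: Sequence[np.ndarray]
) -> list[ConsensusPrediction]:
    """Functional alias for :meth:`ConsensusModel.predict`."""
    return model.predict(features_per_member)
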