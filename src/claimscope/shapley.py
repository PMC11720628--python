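"""Shapley-value attribution of anomaly scores to original features.

An entity's profile row x is explained against a background sample B drawn
from the population's profile matrix. The payoff of a coalition S of feature
groups is the mean detector score over background rows with the columns of S
overwritten by x's values (interventional replacement):

    v(S) = (1/|B|) * sum_{z in B} f(x_S joined with z_{not S})

``exact_shapley`` evaluates the classic Shapley formula by enumerating all
2^g coalitions (feasible for g <= 12 groups); ``monte_carlo_shapley`` is the
unbiased permutation-sampling estimator with per-group standard errors.

Because Shapley values are additive, attributions computed per expanded
column can be summed within each feature group to give the importance of the
original feature; coalitions formed directly at the group level (toggling a
feature's expanded columns together) give the same grouped values for the
exact estimator while cutting enumeration cost — that is the default here.
Per-model attributions are made commensurable by l1 rescaling before the
cross-model mean (the consensus attribution shown to the investigator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import factorial
from typing import Callable, Optional, Sequence

import numpy as np

from .profiles import FeatureGroupMap, ProfileMatrix

MAX_EXACT_GROUPS = 12


@dataclass
class BackgroundSet:
    """Reference sample of (standardized) profile rows for the payoff mean."""

    rows: np.ndarray  # (b, d)

    def __post_init__(self):
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if self.rows.shape[0] < 1:
            raise ValueError("background needs at least one row")

    @classmethod
    def sample(cls, profiles: ProfileMatrix, size: int = 100, seed: int = 0
               ) -> "BackgroundSet":
        rng = np.random.default_rng(seed)
        n = profiles.values.shape[0]
        idx = rng.choice(n, size=min(size, n), replace=False)
        return cls(profiles.values[np.sort(idx)])


@dataclass
class AttributionVector:
    """Additive attribution of one detector's score for one entity.

    ``phi[i]`` is the contribution of attribution unit i (an expanded column,
    or a feature group when computed at group level); ``base_value`` is the
    mean score over the background. For the exact estimator
    sum(phi) + base_value equals the entity's score; the Monte-Carlo
    estimator matches within its reported standard errors.
    """

    entity_id: str
    detector: str
    phi: np.ndarray
    base_value: float
    unit_names: tuple[str, ...]
    standard_errors: Optional[np.ndarray] = None


@dataclass
class GroupedAttribution:
    """Per-original-feature importance for one entity and one detector
    (or the cross-model ``consensus``)."""

    entity_id: str
    detector: str
    importance: dict[str, float]

    def vector(self, features: Sequence[str]) -> np.ndarray:
        return np.array([self.importance[f] for f in features])

    def top_features(self, m: int) -> list[str]:
        return sorted(self.importance, key=lambda f: -abs(self.importance[f]))[:m]


def _group_indices(d: int, groups: Optional[Sequence[Sequence[int]]]):
    if groups is None:
        return [np.array([i]) for i in range(d)]
    return [np.asarray(g, dtype=int) for g in groups]


def _coalition_value(score_fn, x, background, cols: np.ndarray) -> float:
    rows = background.rows.copy()
    if cols.size:
        rows[:, cols] = x[cols]
    return float(np.mean(score_fn(rows)))


def exact_shapley(
    score_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: BackgroundSet,
    groups: Optional[Sequence[Sequence[int]]] = None,
    unit_names: Optional[Sequence[str]] = None,
    entity_id: str = "",
    detector: str = "",
) -> AttributionVector:
    """Exact Shapley values by coalition enumeration over feature groups.

    Refuses more than 12 groups (2^g payoff evaluations); use
    :func:`monte_carlo_shapley` beyond that.
    """
    x = np.asarray(x, dtype=float)
    idx = _group_indices(x.size, groups)
    g = len(idx)
    if g > MAX_EXACT_GROUPS:
        raise ValueError(
            f"{g} groups exceeds the exact-enumeration limit of {MAX_EXACT_GROUPS}; "
            "use monte_carlo_shapley"
        )
    # payoff of every coalition, keyed by bitmask
    values = np.empty(1 << g)
    for mask in range(1 << g):
        cols = np.concatenate([idx[j] for j in range(g) if mask >> j & 1] or [np.array([], int)])
        values[mask] = _coalition_value(score_fn, x, background, cols)
    w = [factorial(s) * factorial(g - s - 1) / factorial(g) for s in range(g)]
    phi = np.zeros(g)
    for j in range(g):
        for mask in range(1 << g):
            if mask >> j & 1:
                continue
            s = bin(mask).count("1")
            phi[j] += w[s] * (values[mask | (1 << j)] - values[mask])
    names = tuple(unit_names) if unit_names else tuple(f"g{j}" for j in range(g))
    return AttributionVector(entity_id, detector, phi, float(values[0]), names)


def monte_carlo_shapley(
    score_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: BackgroundSet,
    n_permutations: int = 2000,
    seed: int = 0,
    groups: Optional[Sequence[Sequence[int]]] = None,
    unit_names: Optional[Sequence[str]] = None,
    entity_id: str = "",
    detector: str = "",
) -> AttributionVector:
    """Permutation-sampling Shapley estimator (unbiased, seeded).

    Each iteration draws a random group ordering and one background row, and
    records every group's marginal contribution when added to its
    predecessors. Per-group standard errors are the sample standard
    deviations of those contributions over sqrt(T).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = np.asarray(x, dtype=float)
    idx = _group_indices(x.size, groups)
    g = len(idx)
    rng = np.random.default_rng(seed)
    b = background.rows.shape[0]
    contrib = np.empty((n_permutations, g))
    base_samples = np.empty(n_permutations)
    # batch all (g+1) partial rows of each permutation into one score call
    for t in range(n_permutations):
        perm = rng.permutation(g)
        z = background.rows[rng.integers(b)]
        rows = np.tile(z, (g + 1, 1))
        for step, j in enumerate(perm, start=1):
            rows[step:, idx[j]] = x[idx[j]]
        scores = np.asarray(score_fn(rows), dtype=float)
        base_samples[t] = scores[0]
        contrib[t, perm] = np.diff(scores)
    phi = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / np.sqrt(n_permutations) if n_permutations > 1 \
        else np.full(g, np.inf)
    names = tuple(unit_names) if unit_names else tuple(f"g{j}" for j in range(g))
    return AttributionVector(entity_id, detector, phi, float(base_samples.mean()),
                             names, standard_errors=se)


def group_attributions(attr: AttributionVector, groups: FeatureGroupMap
                       ) -> GroupedAttribution:
    """Sum expanded-column attributions within each original feature group.

    If the attribution was already computed at group level (one phi per
    group), it is repackaged directly.
    """
    if len(attr.phi) == len(groups) and len(attr.phi) != len(groups.expanded_names):
        importance = {name: float(p) for (name, _), p in zip(groups.groups, attr.phi)}
        return GroupedAttribution(attr.entity_id, attr.detector, importance)
    if len(attr.phi) != len(groups.expanded_names):
        raise ValueError(
            f"phi has {len(attr.phi)} entries but the group map expects "
            f"{len(groups.expanded_names)} expanded columns"
        )
    importance = {
        name: float(np.sum(attr.phi[list(cols)])) for name, cols in groups.groups
    }
    return GroupedAttribution(attr.entity_id, attr.detector, importance)


def consensus_attribution(grouped: Sequence[GroupedAttribution]) -> GroupedAttribution:
    """l1-rescale each model's per-feature importances, then average across
    models, giving one commensurable attribution per entity."""
    if not grouped:
        raise ValueError("need at least one model attribution")
    features = list(grouped[0].importance)
    for ga in grouped:
        if list(ga.importance) != features:
            raise ValueError("attributions must share an identical feature set")
    stacked = np.stack([ga.vector(features) for ga in grouped])
    norms = np.abs(stacked).sum(axis=1, keepdims=True)
    rescaled = np.divide(stacked, norms, out=np.zeros_like(stacked), where=norms > 0)
    mean = rescaled.mean(axis=0)
    return GroupedAttribution(
        grouped[0].entity_id, "consensus",
        {f: float(v) for f, v in zip(features, mean)},
    )


def explain_entity(
    entity_id: str,
    profiles: ProfileMatrix,
    detectors: dict,
    background: BackgroundSet,
    n_permutations: int = 0,
    seed: int = 0,
) -> tuple[dict[str, GroupedAttribution], GroupedAttribution]:
    """Grouped attributions for one entity under every fitted detector, plus
    their consensus. Uses exact enumeration when the feature count allows
    (``n_permutations=0`` forces it), Monte-Carlo otherwise."""
    x = profiles.row(entity_id)
    gmap = profiles.group_map
    group_cols = [list(cols) for _, cols in gmap.groups]
    names = gmap.feature_names
    per_model: dict[str, GroupedAttribution] = {}
    for det_name, det in detectors.items():
        use_exact = len(group_cols) <= MAX_EXACT_GROUPS and n_permutations == 0
        if use_exact:
            attr = exact_shapley(det.score, x, background, groups=group_cols,
                                 unit_names=names, entity_id=entity_id,
                                 detector=det_name)
        else:
            attr = monte_carlo_shapley(det.score, x, background,
                                       n_permutations=max(n_permutations, 200),
                                       seed=seed, groups=group_cols,
                                       unit_names=names, entity_id=entity_id,
                                       detector=det_name)
        per_model[det_name] = group_attributions(attr, gmap)
    return per_model, consensus_attribution(list(per_model.values()))
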