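"""Synthetic claims generator with planted anomalous practitioners.

Emulates the structure of real per-action billing data — many practitioners,
high-cardinality categorical features, heavy class imbalance (~0.3 % anomalous
entities) — so every downstream stage (embedding, profiling, detection,
explanation) can be exercised and benchmarked without restricted data.

Anomaly archetypes perturb *action-level sampling*, not profile-level
features, so planted anomalies must survive the whole aggregation pipeline
to be detected:

``excessive_code``
    multiplies the sampling odds of a few designated billing-code tokens,
    mimicking practitioners known for excessive use of certain codes;
``off_specialty``
    resamples a fraction of an entity's actions from a different specialty
    profile (e.g. a general practitioner whose acts look orthopedic);
``inflated_amount``
    scales a numerical column (billed amount) by a constant factor.

Determinism: one global integer seed; each entity draws from its own
substream keyed by entity index, so enlarging the population never perturbs
existing entities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .schema import ClaimsTable, FeatureSchema


@dataclass(frozen=True)
class SpecialtyProfile:
    """Sampling distributions for one specialty.

    ``categorical``: column → (tokens, probabilities); probabilities sum to 1.
    ``numerical``: column → (mu, sigma) of a log-normal billed-amount model
    (positive and right-skewed, as billing amounts are).

    ``heterogeneity``: column → tau; each entity tilts that column's
    probabilities by i.i.d. log-normal(0, tau) preference weights
    (renormalized), modelling practice-style variation: every practitioner
    has an idiosyncratic repertoire, especially over high-cardinality codes.
    tau = 0 (or absent) means all entities share the column distribution.
    """

    categorical: dict[str, tuple[tuple[str, ...], tuple[float, ...]]]
    numerical: dict[str, tuple[float, float]]
    heterogeneity: dict[str, float] = None

    def __post_init__(self):
        if self.heterogeneity is None:
            object.__setattr__(self, "heterogeneity", {})
        for col, (tokens, probs) in self.categorical.items():
            p = np.asarray(probs, dtype=float)
            if len(tokens) != len(p) or (p < 0).any():
                raise ValueError(f"invalid distribution for column {col!r}")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"probabilities for column {col!r} do not sum to 1")


@dataclass(frozen=True)
class PopulationSpec:
    """Full description of a synthetic practitioner population."""

    n_entities: int
    specialty_profiles: dict[str, SpecialtyProfile]
    specialty_weights: dict[str, float]
    actions_mean: float = 60.0
    actions_dispersion: float = 5.0  # NB size parameter; var = mean + mean^2/size
    seed: int = 0

    def __post_init__(self):
        if self.n_entities < 2:
            raise ValueError("n_entities must be >= 2")
        if set(self.specialty_weights) != set(self.specialty_profiles):
            raise ValueError("specialty_weights keys must match specialty_profiles")
        w = np.asarray(list(self.specialty_weights.values()), dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("specialty weights must be a probability vector")

    def schema(self, entity_id_column: str = "entity_id") -> FeatureSchema:
        any_prof = next(iter(self.specialty_profiles.values()))
        return FeatureSchema(
            entity_id_column=entity_id_column,
            categorical_columns=tuple(any_prof.categorical),
            numerical_columns=tuple(any_prof.numerical),
        )


@dataclass(frozen=True)
class AnomalyArchetype:
    """A parameterized generative perturbation planted into the population."""

    kind: str  # excessive_code | off_specialty | inflated_amount
    strength: float = 10.0
    affected_fraction: float = 0.003
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("excessive_code", "off_specialty", "inflated_amount"):
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if self.strength <= 0:
            raise ValueError("strength must be positive")
        if not (0 < self.affected_fraction < 1):
            raise ValueError("affected_fraction must lie in (0, 1)")


@dataclass
class LabeledClaims:
    """A claims table with ground-truth anomaly labels."""

    table: ClaimsTable
    labels: dict[str, int]
    ground_truth: dict[str, AnomalyArchetype]

    def label_vector(self, entity_ids: list[str]) -> np.ndarray:
        return np.array([self.labels.get(e, 0) for e in entity_ids], dtype=int)


def _entity_rng(seed: int, index: int) -> np.random.Generator:
    # per-entity substream: stable under population growth
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def assign_specialties(spec: PopulationSpec) -> dict[str, str]:
    """Deterministic entity → specialty assignment implied by the spec's seed."""
    names = list(spec.specialty_profiles)
    weights = np.array([spec.specialty_weights[s] for s in names], dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(2**31,)))
    idx = rng.choice(len(names), size=spec.n_entities, p=weights)
    return {_entity_name(i): names[j] for i, j in enumerate(idx)}


def _entity_name(i: int) -> str:
    return f"E{i:05d}"


def _tilt(probs: np.ndarray, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Entity-specific repertoire: log-normal preference reweighting."""
    if tau <= 0:
        return probs
    tilted = probs * rng.lognormal(mean=0.0, sigma=tau, size=len(probs))
    return tilted / tilted.sum()


def _sample_entity_actions(
    profile: SpecialtyProfile, n: int, rng: np.random.Generator,
    tilt: bool = True,
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for col, (tokens, probs) in profile.categorical.items():
        p = np.asarray(probs, dtype=float)
        if tilt:
            p = _tilt(p, profile.heterogeneity.get(col, 0.0), rng)
        out[col] = rng.choice(np.asarray(tokens, dtype=object), size=n, p=p)
    for col, (mu, sigma) in profile.numerical.items():
        out[col] = np.round(rng.lognormal(mean=mu, sigma=sigma, size=n), 2)
    return out


def generate_population(spec: PopulationSpec) -> ClaimsTable:
    """Sample a claims table: i.i.d. actions per entity from its specialty profile."""
    specialties = assign_specialties(spec)
    frames = []
    for i in range(spec.n_entities):
        eid = _entity_name(i)
        rng = _entity_rng(spec.seed, i)
        n = max(1, int(rng.negative_binomial(
            spec.actions_dispersion,
            spec.actions_dispersion / (spec.actions_dispersion + spec.actions_mean),
        )))
        cols = _sample_entity_actions(spec.specialty_profiles[specialties[eid]], n, rng)
        cols["entity_id"] = np.full(n, eid, dtype=object)
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)
    schema = spec.schema()
    return ClaimsTable(df[list(schema.all_columns)], schema)


def _boost_odds(tokens: np.ndarray, probs: np.ndarray, boosted: set, strength: float) -> np.ndarray:
    odds = probs.astype(float).copy()
    mask = np.array([t in boosted for t in tokens])
    odds[mask] *= strength
    return odds / odds.sum()


def inject_anomalies(
    table: ClaimsTable,
    archetypes: list[AnomalyArchetype],
    seed: int,
    spec: Optional[PopulationSpec] = None,
) -> LabeledClaims:
    """Plant anomalous entities by rewriting their action rows.

    Affected entities are drawn without replacement per archetype (disjoint
    across archetypes). ``spec`` is required for the ``excessive_code`` and
    ``off_specialty`` kinds, which resample from specialty profiles.
    """
    if len(table) == 0:
        raise ValueError("cannot inject anomalies into an empty table")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,)))
    entities = table.entities()
    n = len(entities)
    df = table.data.copy()
    labels: dict[str, int] = {}
    ground_truth: dict[str, AnomalyArchetype] = {}
    available = list(entities)

    specialties = assign_specialties(spec) if spec is not None else {}

    for arch in archetypes:
        n_affected = int(round(arch.affected_fraction * n))
        if n_affected < 1:
            warnings.warn(
                f"affected_fraction {arch.affected_fraction} covers <1 of {n} entities; "
                "affecting one entity"
            )
            n_affected = 1
        chosen = rng.choice(len(available), size=min(n_affected, len(available)), replace=False)
        affected = [available[i] for i in sorted(chosen)]
        for eid in affected:
            available.remove(eid)
            labels[eid] = 1
            ground_truth[eid] = arch
            mask = (df[table.schema.entity_id_column] == eid).to_numpy()
            _apply_archetype(df, mask, arch, rng, spec, specialties.get(eid), table.schema)

    for eid in entities:
        labels.setdefault(eid, 0)
    out = ClaimsTable(df, table.schema)
    return LabeledClaims(out, labels, ground_truth)


def _apply_archetype(df, mask, arch, rng, spec, specialty, schema):
    if arch.kind == "inflated_amount":
        col = arch.parameters.get("column", schema.numerical_columns[0])
        df.loc[mask, col] = df.loc[mask, col].to_numpy() * arch.strength
        return
    if spec is None or specialty is None:
        raise ValueError(f"archetype {arch.kind!r} requires the PopulationSpec")
    profile = spec.specialty_profiles[specialty]
    n_rows = int(mask.sum())
    if arch.kind == "excessive_code":
        col = arch.parameters.get("column", schema.categorical_columns[-1])
        tokens, probs = profile.categorical[col]
        tokens = np.asarray(tokens, dtype=object)
        probs = np.asarray(probs, dtype=float)
        boosted = arch.parameters.get("tokens")
        if boosted is None:
            n_tok = int(arch.parameters.get("n_tokens", 3))
            # default pool: the common (top-decile) codes — overconsumption of
            # legitimate, widely used acts; "rare" selects the bottom half
            pool_kind = arch.parameters.get("pool", "common")
            order = np.argsort(probs)[::-1]
            if pool_kind == "common":
                pool = order[: max(n_tok, len(order) // 10)]
            else:
                pool = order[len(order) // 2:]
            boosted = tokens[rng.choice(pool, size=n_tok, replace=False)]
        base = _tilt(probs, profile.heterogeneity.get(col, 0.0), rng)
        odds = _boost_odds(tokens, base, set(boosted), arch.strength)
        df.loc[mask, col] = rng.choice(tokens, size=n_rows, p=odds)
    elif arch.kind == "off_specialty":
        frac = float(arch.parameters.get("fraction", 0.5))
        target = arch.parameters.get("target")
        if target is None:
            others = [s for s in spec.specialty_profiles if s != specialty]
            target = others[int(rng.integers(len(others)))] if others else specialty
        target_profile = spec.specialty_profiles[target]
        idx = np.flatnonzero(mask)
        take = rng.choice(idx, size=max(1, int(round(frac * n_rows))), replace=False)
        resampled = _sample_entity_actions(target_profile, len(take), rng)
        for col, vals in resampled.items():
            df.loc[df.index[take], col] = vals


# ---------------------------------------------------------------------------
# Default desk-scale benchmark mirroring the real data's scale ratios:
# ~2000 entities, ~0.3 % planted anomalies, one categorical column with
# cardinality >= 500, a dominant specialty plus smaller ones.
# ---------------------------------------------------------------------------

def _zipf_probs(n: int, alpha: float = 1.3) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** alpha
    return w / w.sum()


def default_population_spec(seed: int = 0, n_entities: int = 2000) -> PopulationSpec:
    """Benchmark population: 3 specialty profiles over 4 categorical + 1 numerical column.

    The billing-code column pools to cardinality 5000 with Zipf-distributed
    usage (a few workhorse codes, a long tail of rare ones), so the one-hot
    representation of this column alone dwarfs the entity count — the
    high-cardinality regime the embedding is designed for.
    """
    all_codes = [f"C{j:04d}" for j in range(5000)]
    loc_tokens = tuple(f"L{j}" for j in range(5))
    subcat = tuple(f"S{j:02d}" for j in range(20))

    def cat_block(disc, code_slice, loc_probs, sub_alpha):
        codes = tuple(all_codes[code_slice])
        return {
            "discipline": (("gp", "ortho", "derm"), disc),
            "location": (loc_tokens, loc_probs),
            "subcategory": (subcat, tuple(_zipf_probs(20, sub_alpha))),
            "code": (codes, tuple(_zipf_probs(len(codes), 1.0))),
        }

    # practice-style variation: each practitioner has an idiosyncratic
    # repertoire, strongest over the high-cardinality code column
    heterogeneity = {"code": 1.5, "subcategory": 0.4, "location": 0.4}

    profiles = {
        "gp": SpecialtyProfile(
            cat_block((0.9, 0.05, 0.05), slice(0, 3300), (0.6, 0.2, 0.1, 0.07, 0.03), 1.2),
            {"amount": (3.0, 0.5)}, heterogeneity,
        ),
        "ortho": SpecialtyProfile(
            cat_block((0.05, 0.9, 0.05), slice(1700, 5000), (0.1, 0.1, 0.5, 0.2, 0.1), 1.0),
            {"amount": (4.5, 0.6)}, heterogeneity,
        ),
        "derm": SpecialtyProfile(
            cat_block((0.05, 0.05, 0.9), slice(850, 4150), (0.3, 0.4, 0.1, 0.1, 0.1), 1.4),
            {"amount": (3.5, 0.5)}, heterogeneity,
        ),
    }
    return PopulationSpec(
        n_entities=n_entities,
        specialty_profiles=profiles,
        # the benchmark population is a single discipline (as in a per-discipline
        # analysis of general practitioners); the other profiles exist as
        # off-specialty sources for the anomaly archetypes
        specialty_weights={"gp": 1.0, "ortho": 0.0, "derm": 0.0},
        actions_mean=60.0,
        actions_dispersion=5.0,
        seed=seed,
    )


def default_archetypes() -> list[AnomalyArchetype]:
    """Planted anomalies: excessive billing-code use plus off-specialty activity.

    The excessive-code strength is an *odds multiplier* on three common
    billing codes: overconsumption of legitimate, widely used acts rather
    than exotic rare codes. A multiplier of 60 lifts the three codes to an
    expert-visible share (roughly 10-25 %) of the entity's acts.
    """
    return [
        AnomalyArchetype("excessive_code", strength=60.0, affected_fraction=0.0015,
                         parameters={"column": "code", "n_tokens": 3, "pool": "common"}),
        AnomalyArchetype("off_specialty", strength=1.0, affected_fraction=0.0015,
                         parameters={"fraction": 0.5}),
    ]


def default_benchmark(seed: int = 0, n_entities: int = 2000,
                      archetypes: Optional[list[AnomalyArchetype]] = None) -> LabeledClaims:
    """Generate the default labeled benchmark in one call."""
    spec = default_population_spec(seed=seed, n_entities=n_entities)
    table = generate_population(spec)
    if archetypes is None:
        archetypes = default_archetypes()
    return inject_anomalies(table, archetypes, seed=seed, spec=spec)


def write_labels(labeled: LabeledClaims, path) -> None:
    pd.DataFrame(
        {"entity_id": list(labeled.labels), "label": list(labeled.labels.values())}
    ).to_csv(path, index=False)
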