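"""Expert-facing reports: grouped importances plus univariate population comparisons.

For each flagged practitioner the report shows the consensus feature
importances and, for the top features, how the practitioner's own behaviour
compares with the population: categorical features as relative-frequency
distributions (practitioner vs all actions), numerical features as the six
aggregate statistics with z-scores against the population of practitioners.
The billing (nomenclature) code distribution is always included regardless
of importance rank, since it identifies the medical acts themselves.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .profiles import NUM_STATS, ProfileMatrix
from .schema import ClaimsTable
from .shapley import GroupedAttribution


@dataclass
class CategoricalComparison:
    feature: str
    entity_distribution: dict[str, float]  # token -> relative frequency
    population_distribution: dict[str, float]
    top_tokens: list[str]  # by entity frequency


@dataclass
class NumericalComparison:
    feature: str
    entity_stats: dict[str, float]  # stat name -> value
    population_mean: dict[str, float]
    z_scores: dict[str, float]
    degenerate_stats: list[str] = field(default_factory=list)  # population std == 0


@dataclass
class EntityReport:
    entity_id: str
    consensus_count: int
    importance: dict[str, float]  # consensus grouped attribution
    comparisons: list[Union[CategoricalComparison, NumericalComparison]]

    def to_dict(self) -> dict:
        d = {
            "entity_id": self.entity_id,
            "consensus_count": self.consensus_count,
            "importance": self.importance,
            "comparisons": [
                {"type": "categorical" if isinstance(c, CategoricalComparison)
                 else "numerical", **asdict(c)}
                for c in self.comparisons
            ],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EntityReport":
        comps = []
        for c in d["comparisons"]:
            c = dict(c)
            kind = c.pop("type")
            comps.append(CategoricalComparison(**c) if kind == "categorical"
                         else NumericalComparison(**c))
        return cls(d["entity_id"], d["consensus_count"], d["importance"], comps)


def compare_categorical(table: ClaimsTable, entity_id: str, feature: str
                        ) -> CategoricalComparison:
    """Relative token frequencies over the entity's actions vs all actions.

    Population tokens the entity never used are reported with frequency 0.
    """
    if feature not in table.schema.categorical_columns:
        raise KeyError(f"{feature!r} is not a categorical feature")
    sub = table.subset(entity_id)
    if len(sub) == 0:
        raise KeyError(f"unknown entity {entity_id!r}")
    pop = table.data[feature].value_counts(normalize=True)
    ent = sub[feature].value_counts(normalize=True)
    tokens = sorted(pop.index)
    entity_dist = {t: float(ent.get(t, 0.0)) for t in tokens}
    pop_dist = {t: float(pop[t]) for t in tokens}
    top = sorted(entity_dist, key=lambda t: (-entity_dist[t], t))
    return CategoricalComparison(feature, entity_dist, pop_dist,
                                 [t for t in top if entity_dist[t] > 0][:10])


def compare_numerical(profiles: ProfileMatrix, entity_id: str, feature: str
                      ) -> NumericalComparison:
    """The entity's six aggregate statistics against their population
    distribution across entities; z uses the population (ddof=0) std.

    ``profiles`` must be the *unstandardized* matrix so the stats keep their
    original units.
    """
    if profiles.standardization is not None:
        raise ValueError("compare_numerical expects unstandardized profiles")
    cols = profiles.group_map.indices(feature)
    if len(cols) != len(NUM_STATS):
        raise KeyError(f"{feature!r} is not a numerical feature")
    block = profiles.values[:, list(cols)]
    row = profiles.row(entity_id)[list(cols)]
    mean = block.mean(axis=0)
    std = block.std(axis=0, ddof=0)
    degenerate = [s for s, sd in zip(NUM_STATS, std) if sd == 0]
    z = np.where(std > 0, (row - mean) / np.where(std > 0, std, 1.0), 0.0)
    return NumericalComparison(
        feature,
        {s: float(v) for s, v in zip(NUM_STATS, row)},
        {s: float(v) for s, v in zip(NUM_STATS, mean)},
        {s: float(v) for s, v in zip(NUM_STATS, z)},
        degenerate,
    )


def build_entity_report(
    entity_id: str,
    consensus_count: int,
    attribution: GroupedAttribution,
    table: ClaimsTable,
    raw_profiles: ProfileMatrix,
    top_m: int = 5,
    code_feature: Optional[str] = None,
) -> EntityReport:
    """Assemble the report: top-m features by |consensus importance| (the
    code feature appended if not already present), each compared against the
    population."""
    features = attribution.top_features(top_m)
    if code_feature and code_feature not in features:
        features.append(code_feature)
    comparisons = []
    for f in features:
        if f in table.schema.categorical_columns:
            comparisons.append(compare_categorical(table, entity_id, f))
        else:
            comparisons.append(compare_numerical(raw_profiles, entity_id, f))
    importance = {f: attribution.importance[f]
                  for f in sorted(attribution.importance,
                                  key=lambda g: -abs(attribution.importance[g]))}
    return EntityReport(entity_id, consensus_count, importance, comparisons)


def render_report(report: EntityReport, format: str = "json") -> str:
    """Deterministic document in JSON (machine-round-trippable), markdown,
    or HTML (with embedded SVG importance / distribution plots)."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    if format == "markdown":
        return _render_markdown(report)
    if format == "html":
        return _render_html(report)
    raise ValueError(f"unknown format {format!r}")


def parse_report(doc: str) -> EntityReport:
    return EntityReport.from_dict(json.loads(doc))


def _render_markdown(report: EntityReport) -> str:
    lines = [f"# Entity {report.entity_id}",
             f"Consensus count: {report.consensus_count}",
             "", "## Feature importance (consensus)", "",
             "| feature | importance |", "|---|---|"]
    for f, v in report.importance.items():
        lines.append(f"| {f} | {v:.6f} |")
    for comp in report.comparisons:
        lines.append("")
        if isinstance(comp, CategoricalComparison):
            lines += [f"## {comp.feature} (categorical)", "",
                      "| token | entity | population |", "|---|---|---|"]
            for t in comp.top_tokens:
                lines.append(f"| {t} | {comp.entity_distribution[t]:.4f} "
                             f"| {comp.population_distribution[t]:.4f} |")
        else:
            lines += [f"## {comp.feature} (numerical)", "",
                      "| stat | entity | population mean | z |", "|---|---|---|---|"]
            for s in NUM_STATS:
                flag = " (degenerate)" if s in comp.degenerate_stats else ""
                lines.append(f"| {s} | {comp.entity_stats[s]:.4f} "
                             f"| {comp.population_mean[s]:.4f} "
                             f"| {comp.z_scores[s]:.4f}{flag} |")
    return "\n".join(lines) + "\n"


def _importance_svg(report: EntityReport) -> str:
    import matplotlib

    matplotlib.use("svg")
    matplotlib.rcParams["svg.hashsalt"] = "claimscope"  # byte-deterministic ids
    import matplotlib.pyplot as plt

    feats = list(report.importance)[:10][::-1]
    vals = [report.importance[f] for f in feats]
    fig, ax = plt.subplots(figsize=(5, 0.4 * max(len(feats), 3) + 1))
    ax.barh(feats, vals)
    ax.set_xlabel("consensus importance")
    ax.set_title(f"Entity {report.entity_id}")
    fig.tight_layout()
    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    return buf.getvalue()


def _render_html(report: EntityReport) -> str:
    body = _render_markdown(report).replace("\n", "<br/>\n")
    svg = _importance_svg(report)
    return (
        "<html><head><meta charset='utf-8'/></head><body>\n"
        f"{svg}\n<pre>{body}</pre>\n</body></html>\n"
    )
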