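"""End-to-end workflow: filter → embed → aggregate → detect → rank → explain → report.

The workflow is exposed in two equivalent forms:

* a modelling surface — :class:`ClaimsAnomalyModel` is built from a claims
  table and a :class:`RunConfig`; ``fit()`` returns a
  :class:`ClaimsAnomalyResults` carrying scores, the consensus ranking,
  attributions and reports, with a ``summary()`` table;
* :func:`run_pipeline`, which runs the model on a claims file and persists
  every intermediate artifact (profiles, scores, ranking, reports, resolved
  config, log) into a run directory, so any stage can be re-run in isolation.

A single global seed fans out to per-stage seeds by stable hashing of stage
names, making a run fully determined by (input file, config).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import consensus as consensus_mod
from . import detectors as det_mod
from . import embedding as emb_mod
from . import profiles as prof_mod
from . import reporting as rep_mod
from . import shapley as shap_mod
from .schema import ClaimsTable, FeatureSchema, filter_min_actions, read_claims

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) by hashing the stage name."""
    h = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "big") % (2**31)


@dataclass
class RunConfig:
    """Everything that, together with the input file, determines a run."""

    schema: FeatureSchema
    min_actions: int = 50
    per_period: bool = False
    embedding_k: int = 3
    encoding: str = "embeddings"  # embeddings | onehot
    detectors: tuple[str, ...] = ("knn", "hist", "ecdf")
    detector_hyperparameters: dict = field(default_factory=dict)
    consensus_k: int = 50
    background_size: int = 100
    n_permutations: int = 0  # 0 -> exact Shapley when feasible
    top_m_features: int = 5
    max_reports: int = 10
    code_feature: Optional[str] = None
    seed: int = 0

    def detector_specs(self) -> list[det_mod.DetectorSpec]:
        specs = []
        for name in self.detectors:
            specs.append(det_mod.DetectorSpec(
                name=name,
                hyperparameters=self.detector_hyperparameters.get(name, {}),
                seed=stage_seed(self.seed, f"detector:{name}"),
            ))
        return specs

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema"] = self.schema.to_dict()
        d["detectors"] = list(self.detectors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["schema"] = FeatureSchema.from_dict(d["schema"])
        d["detectors"] = tuple(d.get("detectors", ("knn", "hist", "ecdf")))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


class ClaimsAnomalyModel:
    """Unsupervised anomaly-detection model over a claims table.

    Parameters
    ----------
    table : ClaimsTable
        Long-format per-action claims data (already schema-validated).
    config : RunConfig
        Workflow settings; ``config.schema`` must match ``table.schema``.
    """

    def __init__(self, table: ClaimsTable, config: RunConfig):
        self.table = table
        self.config = config

    @classmethod
    def from_csv(cls, path, config: RunConfig, **read_kwargs) -> "ClaimsAnomalyModel":
        return cls(read_claims(path, config.schema, **read_kwargs), config)

    def fit(self) -> "ClaimsAnomalyResults":
        cfg = self.config
        t0 = time.time()
        filtered = filter_min_actions(self.table, cfg.min_actions, cfg.per_period)
        logger.info("filter: %d -> %d actions, %d entities (%.2fs)",
                    len(self.table), len(filtered), len(filtered.entities()),
                    time.time() - t0)
        if len(filtered.entities()) < 2:
            raise RuntimeError("fewer than 2 entities survive the activity filter")

        emb = None
        if cfg.encoding == "embeddings" and filtered.schema.categorical_columns:
            emb = emb_mod.fit_embeddings(filtered, k=cfg.embedding_k)
            raw = prof_mod.build_profiles(filtered, emb)
        elif cfg.encoding == "onehot":
            raw = prof_mod.build_onehot_profiles(filtered)
        else:
            raise ValueError(f"unknown encoding {cfg.encoding!r}")
        std = prof_mod.standardize(raw)
        logger.info("profiles: %d entities x %d features", len(std.entity_ids), std.d)

        scores, fitted = det_mod.run_ensemble(std, cfg.detector_specs())
        k = min(cfg.consensus_k, len(std.entity_ids))
        ranking = consensus_mod.build_consensus(scores, k)
        logger.info("detect+rank: %d detectors, %d entities nominated",
                    len(scores.detector_names), len(ranking))
        return ClaimsAnomalyResults(
            model=self, filtered=filtered, embedding=emb, raw_profiles=raw,
            profiles=std, scores=scores, fitted_detectors=fitted, ranking=ranking,
        )


@dataclass
class ClaimsAnomalyResults:
    """Fitted workflow state: scores, ranking, and on-demand explanations."""

    model: ClaimsAnomalyModel
    filtered: ClaimsTable
    embedding: Optional[emb_mod.EmbeddingTable]
    raw_profiles: prof_mod.ProfileMatrix
    profiles: prof_mod.ProfileMatrix
    scores: det_mod.ScoreMatrix
    fitted_detectors: dict
    ranking: consensus_mod.ConsensusRanking

    def __post_init__(self):
        cfg = self.model.config
        self._background = shap_mod.BackgroundSet.sample(
            self.profiles, size=cfg.background_size,
            seed=stage_seed(cfg.seed, "background"),
        )

    def auroc(self, labels: dict[str, int]) -> dict[str, float]:
        """AUROC of every detector column against entity labels."""
        y = np.array([labels.get(e, 0) for e in self.scores.entity_ids])
        return {
            name: det_mod.evaluate_auroc(self.scores.column(name), y)
            for name in self.scores.detector_names
        }

    def explain(self, entity_id: str) -> shap_mod.GroupedAttribution:
        """Consensus grouped attribution for one entity."""
        cfg = self.model.config
        _, cons = shap_mod.explain_entity(
            entity_id, self.profiles, self.fitted_detectors, self._background,
            n_permutations=cfg.n_permutations,
            seed=stage_seed(cfg.seed, f"explain:{entity_id}"),
        )
        return cons

    def report(self, entity_id: str) -> rep_mod.EntityReport:
        cfg = self.model.config
        count = next((e.consensus_count for e in self.ranking.entries
                      if e.entity_id == entity_id), 0)
        return rep_mod.build_entity_report(
            entity_id, count, self.explain(entity_id), self.filtered,
            self.raw_profiles, top_m=cfg.top_m_features,
            code_feature=cfg.code_feature,
        )

    def top_reports(self) -> list[rep_mod.EntityReport]:
        ids = self.ranking.entity_ids()[: self.model.config.max_reports]
        return [self.report(eid) for eid in ids]

    def summary(self) -> str:
        """Human-readable run summary: shapes, detectors, top entities."""
        cfg = self.model.config
        lines = [
            "Claims anomaly detection results",
            "=" * 40,
            f"entities: {len(self.profiles.entity_ids)}    "
            f"profile dim: {self.profiles.d}",
            f"encoding: {cfg.encoding} (k={cfg.embedding_k})",
            f"detectors: {', '.join(self.scores.detector_names)}",
            f"consensus top-k: {self.ranking.top_k}",
            "",
            f"{'entity':<12}{'consensus':>10}{'mean rank':>12}",
        ]
        for e in self.ranking.entries[:10]:
            lines.append(f"{e.entity_id:<12}{e.consensus_count:>10}{e.mean_rank:>12.1f}")
        return "\n".join(lines)


def run_pipeline(claims_path, config: RunConfig, out_dir,
                 delimiter: str = ",", decimal: str = ".") -> Path:
    """Run the full workflow on a claims file, persisting every artifact.

    Writes ``profiles.csv``, ``scores.csv``, ``ranking.csv``, per-entity
    reports (JSON + markdown), ``config.yaml`` (resolved snapshot),
    ``embedding.json`` and ``run.log`` into ``out_dir``. A stage failure
    aborts with a stage-named error; artifacts written so far are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("claimscope")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "config.yaml")
        stage = "read"
        model = ClaimsAnomalyModel.from_csv(claims_path, config,
                                            delimiter=delimiter, decimal=decimal)
        stage = "fit"
        res = model.fit()
        if res.embedding is not None:
            res.embedding.save(out / "embedding.json")
        res.raw_profiles.write_csv(out / "profiles_raw.csv")
        res.profiles.write_csv(out / "profiles.csv")
        res.scores.write_csv(out / "scores.csv")
        res.ranking.write_csv(out / "ranking.csv")
        stage = "report"
        reports_dir = out / "reports"
        reports_dir.mkdir(exist_ok=True)
        for rep in res.top_reports():
            (reports_dir / f"{rep.entity_id}.json").write_text(
                rep_mod.render_report(rep, "json"))
            (reports_dir / f"{rep.entity_id}.md").write_text(
                rep_mod.render_report(rep, "markdown"))
        (out / "summary.txt").write_text(res.summary() + "\n")
        return out
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
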