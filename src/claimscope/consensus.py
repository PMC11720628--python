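"""Cross-model consensus ranking of anomalous entities.

Each detector nominates its top-k highest-scoring entities; entities are then
ranked by how many detectors nominated them (the consensus count), so the
profiles most anomalous *over all models* surface first for the expert.
Raw score values are never fused across models — counts only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .detectors import ScoreMatrix


@dataclass(frozen=True)
class ConsensusEntry:
    entity_id: str
    consensus_count: int
    mean_rank: float
    ranks: dict[str, int]  # per-detector rank, 1 = most anomalous


@dataclass
class ConsensusRanking:
    """Entities with at least one top-k nomination, ordered by consensus count
    (descending), ties by mean rank (ascending), then entity ID."""

    entries: list[ConsensusEntry]
    top_k: int

    def __len__(self) -> int:
        return len(self.entries)

    def entity_ids(self) -> list[str]:
        return [e.entity_id for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {"entity_id": e.entity_id, "consensus_count": e.consensus_count,
                   "mean_rank": e.mean_rank}
            row.update({f"rank_{d}": r for d, r in e.ranks.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _detector_order(scores: ScoreMatrix, j: int) -> list[int]:
    """Entity indices sorted most-anomalous first; score ties broken by
    lexicographically smaller entity ID (deterministic)."""
    col = scores.scores[:, j]
    ids = scores.entity_ids
    return sorted(range(len(ids)), key=lambda i: (-col[i], ids[i]))


def top_k_sets(scores: ScoreMatrix, k: int) -> dict[str, set[str]]:
    """The k highest-scoring entities per detector (empty sets for k=0)."""
    if k > len(scores.entity_ids):
        raise ValueError("k cannot exceed the number of entities")
    out = {}
    for j, name in enumerate(scores.detector_names):
        order = _detector_order(scores, j)
        out[name] = {scores.entity_ids[i] for i in order[:k]}
    return out

def build_consensus(scores: ScoreMatrix, k: int) -> ConsensusRanking:
    """Count top-k nominations per entity and order the nominated entities."""
    sets = top_k_sets(scores, k)
    rank_of: dict[str, dict[str, int]] = {name: {} for name in scores.detector_names}
    for j, name in enumerate(scores.detector_names):
        for pos, i in enumerate(_detector_order(scores, j), start=1):
            rank_of[name][scores.entity_ids[i]] = pos
    counts: dict[str, int] = {}
    for name, members in sets.items():
        for eid in members:
            counts[eid] = counts.get(eid, 0) + 1
    entries = []
    for eid, count in counts.items():
        ranks = {name: rank_of[name][eid] for name in scores.detector_names}
        entries.append(ConsensusEntry(
            entity_id=eid, consensus_count=count,
            mean_rank=float(np.mean(list(ranks.values()))), ranks=ranks,
        ))
    entries.sort(key=lambda e: (-e.consensus_count, e.mean_rank, e.entity_id))
    return ConsensusRanking(entries, top_k=k)
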