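"""The hybrid screening pipeline: dual fingerprints → Tanimoto profiles →
per-fingerprint K-Means → top-cluster selection → consensus intersection.

The screen ranks clusters of the 1-D Tanimoto distribution and keeps, for
each fingerprint type, the cluster whose *minimum* similarity is highest
(ties: higher maximum, then larger count, then lower id) — the cluster
sitting highest on the similarity axis.  The consensus hit set is the
intersection, by library identifier, of the two selected clusters: a
compound must look like the query both structurally (Morgan) and
pharmacophorically to survive.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .chem_graph import parse_smiles
from .clustering import (
    ClusterSummary,
    KMeansModel,
    cluster_summaries,
    kmeans,
    select_k_elbow,
    silhouette,
    _scan_k,
)
from .similarity import SimilarityTable, similarity_profile

__all__ = [
    "ScreenConfig",
    "FingerprintStageResult",
    "ScreenReport",
    "select_top_cluster",
    "consensus_hits",
    "run_hybrid_screen",
]

logger = logging.getLogger(__name__)

FINGERPRINT_KINDS = ("morgan", "pharmacophore")


@dataclass(frozen=True)
class ScreenConfig:
    """Validated parameters of one hybrid-screen run.

    ``k`` fixes the cluster count for both fingerprint clusterings; when
    ``None`` the count is chosen per fingerprint by the elbow rule over
    ``k_range``.  The seed is mandatory — cluster initialisation is random
    and a run must be reproducible.
    """

    seed: int
    radius: int = 2
    n_bits: int = 2048
    k: int | None = None
    k_range: tuple[int, int] = (1, 20)
    n_restarts: int = 10
    init: str = "random"
    max_iter: int = 300
    tol: float = 1e-6

    def __post_init__(self):
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if not 0 <= self.radius <= 6:
            raise ValueError("radius must be in [0, 6]")
        if self.n_bits <= 0 or self.n_bits & (self.n_bits - 1):
            raise ValueError("n_bits must be a positive power of two")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1 when fixed")
        lo, hi = self.k_range
        if not 1 <= lo <= hi:
            raise ValueError("k_range must satisfy 1 <= lo <= hi")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.init not in ("random", "kmeans++"):
            raise ValueError(f"unknown init {self.init!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenConfig":
        d = dict(d)
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        return cls(**d)


@dataclass
class FingerprintStageResult:
    """Clustering outcome for one fingerprint type."""

    kind: str
    k: int
    auto_k: bool
    wcss: float
    silhouette: float | None
    summaries: list[ClusterSummary]
    selected_cluster: int
    member_ids: list[str]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "k": self.k, "auto_k": self.auto_k,
            "wcss": self.wcss, "silhouette": self.silhouette,
            "summaries": [asdict(s) for s in self.summaries],
            "selected_cluster": self.selected_cluster,
            "member_ids": list(self.member_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FingerprintStageResult":
        return cls(kind=d["kind"], k=d["k"], auto_k=d["auto_k"],
                   wcss=d["wcss"], silhouette=d["silhouette"],
                   summaries=[ClusterSummary(**s) for s in d["summaries"]],
                   selected_cluster=d["selected_cluster"],
                   member_ids=list(d["member_ids"]))


@dataclass
class ScreenReport:
    """Full outcome of a hybrid screen, JSON-serializable.

    ``consensus`` lists (id, smiles, tanimoto_morgan,
    tanimoto_pharmacophore) for compounds in both selected clusters.
    Timings are informational and excluded from determinism comparisons.
    """

    library_size: int
    n_parsed: int
    n_parse_failures: int
    query_id: str
    config: ScreenConfig
    stages: dict[str, FingerprintStageResult]
    consensus: list[tuple[str, str, float, float]]
    timings: dict[str, float] = field(default_factory=dict, compare=False)

    @property
    def consensus_ids(self) -> list[str]:
        return [row[0] for row in self.consensus]

    def to_dict(self) -> dict:
        return {
            "library_size": self.library_size,
            "n_parsed": self.n_parsed,
            "n_parse_failures": self.n_parse_failures,
            "query_id": self.query_id,
            "config": self.config.to_dict(),
            "stages": {k: v.to_dict() for k, v in self.stages.items()},
            "consensus": [list(row) for row in self.consensus],
            "timings": dict(self.timings),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenReport":
        return cls(
            library_size=d["library_size"], n_parsed=d["n_parsed"],
            n_parse_failures=d["n_parse_failures"], query_id=d["query_id"],
            config=ScreenConfig.from_dict(d["config"]),
            stages={k: FingerprintStageResult.from_dict(v)
                    for k, v in d["stages"].items()},
            consensus=[tuple(row) for row in d["consensus"]],
            timings=dict(d.get("timings", {})))

    @classmethod
    def from_json(cls, text: str) -> "ScreenReport":
        return cls.from_dict(json.loads(text))


def select_top_cluster(summaries: list[ClusterSummary]) -> int:
    """Cluster sitting highest on the similarity axis.

    Maximal ``min_value``; ties broken by maximal ``max_value``, then by
    larger count, then by lowest cluster id.
    """
    if not summaries:
        raise ValueError("no cluster summaries")
    best = max(summaries,
               key=lambda s: (s.min_value, s.max_value, s.count,
                              -s.cluster_id))
    return best.cluster_id


def consensus_hits(members_a, members_b) -> set:
    """Identifiers present in both selected clusters (set intersection)."""
    return set(members_a) & set(members_b)


def _cluster_stage(kind: str, values: np.ndarray, ids: list[str],
                   config: ScreenConfig) -> FingerprintStageResult:
    n_distinct = len(np.unique(values))
    auto_k = config.k is None
    if auto_k:
        k_min, k_max = config.k_range
        k_max = min(k_max, n_distinct)
        if k_max - k_min + 1 >= 3:
            curve, models = _scan_k(values, k_min, k_max, config.seed,
                                    config.n_restarts, config.max_iter,
                                    config.tol, config.init)
            k = select_k_elbow(curve)
            model = models[k]
        else:  # too few distinct values for an elbow; use what is possible
            k = min(k_max, max(k_min, 1))
            model = kmeans(values, k, seed=config.seed,
                           n_restarts=config.n_restarts,
                           max_iter=config.max_iter, tol=config.tol,
                           init=config.init)
    else:
        k = min(config.k, n_distinct)
        if k < config.k:
            logger.warning("%s: k reduced from %d to %d distinct values",
                           kind, config.k, k)
        model = kmeans(values, k, seed=config.seed,
                       n_restarts=config.n_restarts,
                       max_iter=config.max_iter, tol=config.tol,
                       init=config.init)
    sil = (silhouette(values, model.assignments, seed=config.seed)
           if model.k >= 2 else None)
    summaries = cluster_summaries(model, values)
    selected = select_top_cluster(summaries)
    member_ids = [ids[i] for i in np.flatnonzero(model.assignments == selected)]
    logger.info("%s: k=%d%s, wcss=%.6g, silhouette=%s, selected cluster %d "
                "with %d members", kind, model.k,
                " (elbow)" if auto_k else "", model.wcss,
                f"{sil:.3f}" if sil is not None else "n/a",
                selected, len(member_ids))
    return FingerprintStageResult(
        kind=kind, k=model.k, auto_k=auto_k, wcss=model.wcss,
        silhouette=sil, summaries=summaries, selected_cluster=selected,
        member_ids=member_ids)


def run_hybrid_screen(library, query, config: ScreenConfig,
                      query_id: str = "query") -> ScreenReport:
    """Run the full hybrid screen of a library against one query.

    ``library`` is an iterable of records with ``id``/``smiles`` (or plain
    pairs); ``query`` a SMILES string or parsed graph.  Deterministic given
    ``config.seed``.
    """
    t0 = time.perf_counter()
    if isinstance(query, str):
        try:
            query = parse_smiles(query)
        except Exception as exc:
            raise ValueError(f"query SMILES failed to parse: {exc}") from exc
    library = list(library)
    profile: SimilarityTable = similarity_profile(
        library, query, query_id=query_id, radius=config.radius,
        n_bits=config.n_bits)
    t1 = time.perf_counter()
    if len(profile) < 2:
        raise ValueError("need at least 2 parseable library compounds")
    ids = profile.frame["id"].tolist()
    logger.info("funnel: %d in library, %d parsed", len(library),
                len(profile))

    stages: dict[str, FingerprintStageResult] = {}
    column = {"morgan": "tanimoto_morgan",
              "pharmacophore": "tanimoto_pharmacophore"}
    for kind in FINGERPRINT_KINDS:
        values = profile.frame[column[kind]].to_numpy()
        stages[kind] = _cluster_stage(kind, values, ids, config)
    t2 = time.perf_counter()

    consensus_set = consensus_hits(stages["morgan"].member_ids,
                                   stages["pharmacophore"].member_ids)
    frame = profile.frame.set_index("id")
    consensus = [
        (cid, frame.at[cid, "smiles"],
         float(frame.at[cid, "tanimoto_morgan"]),
         float(frame.at[cid, "tanimoto_pharmacophore"]))
        for cid in ids if cid in consensus_set]
    logger.info("funnel: %d morgan / %d pharmacophore cluster members, "
                "%d consensus hits",
                len(stages["morgan"].member_ids),
                len(stages["pharmacophore"].member_ids), len(consensus))
    return ScreenReport(
        library_size=len(library), n_parsed=len(profile),
        n_parse_failures=len(profile.failures), query_id=query_id,
        config=config, stages=stages, consensus=consensus,
        timings={"profile_s": t1 - t0, "clustering_s": t2 - t1,
                 "total_s": time.perf_counter() - t0})
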