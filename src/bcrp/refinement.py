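"""Light-chain-informed and publicness-aware cluster refinement.

Heavy-chain clusters are first split by light-chain V-J usage (chain-mixed
members end up in subclusters too small to keep and are unassigned).
Cluster-level publicness — the mean per-sequence publicness score — is
z-standardized across clusters and the top decile flagged as putative
public clusters.  Among flagged clusters, an SHM cutoff (fixed, or derived
from annotated naive/memory clusters by maximizing the Youden index)
separates naive-like pseudo-clonal clusters, which are filtered, from
memory-derived expansions, which are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .clustering import ClonalCluster, cluster_heavy
from .consistency import FrequencyScorer, shm_load
from .records import Repertoire, StateError


@dataclass
class RefinementConfig:
    public_quantile: float = 0.10
    min_subcluster_size: int = 3
    shm_cutoff: object = None  # number, "auto", or None (flag but never filter)
    scorer: Optional[FrequencyScorer] = None
    paired_mode: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.public_quantile < 1.0:
            raise ValueError("public_quantile must be in (0, 1)")


@dataclass
class ClusterFlags:
    publicness_score: float = 0.0
    publicness_z: float = 0.0
    is_public: bool = False
    origin: str = "not_public"  # naive_like | memory_derived | not_public
    retained: bool = True


@dataclass
class RefinementResult:
    clusters: list[ClonalCluster]
    flags: dict[str, ClusterFlags]
    unassigned: list[str] = field(default_factory=list)
    shm_cutoff: Optional[float] = None
    drop_log: list[str] = field(default_factory=list)


def split_by_light_vj(
    cluster: ClonalCluster,
    repertoire: Repertoire,
    min_subcluster_size: int = 3,
) -> tuple[list[ClonalCluster], list[str]]:
    """Subdivide a heavy cluster by light-chain (V, J) usage.

    Returns the surviving subclusters plus the member ids demoted to
    unassigned (subclusters below ``min_subcluster_size``).  Member
    conservation: subcluster members + unassigned = original members.
    """
    by_heavy = repertoire.cell_by_heavy_id()
    missing = [m for m in cluster.members if m not in by_heavy]
    if missing:
        raise StateError(
            f"cluster {cluster.cluster_id}: unpaired member(s) {missing[:5]}"
        )
    groups: dict[tuple[str, str], list[str]] = {}
    for m in cluster.members:
        light = by_heavy[m].light
        groups.setdefault((light.v_call, light.j_call), []).append(m)

    subclusters: list[ClonalCluster] = []
    unassigned: list[str] = []
    for i, key in enumerate(sorted(groups, key=lambda k: (-len(groups[k]), k))):
        members = groups[key]
        if len(members) < min_subcluster_size:
            unassigned.extend(members)
            continue
        suffix = "" if len(groups) == 1 else f".{i}"
        subclusters.append(
            ClonalCluster(
                cluster_id=f"{cluster.cluster_id}{suffix}",
                members=members,
                dominant_v=cluster.dominant_v,
                dominant_j=cluster.dominant_j,
                consensus_score=cluster.consensus_score,
                chain="paired",
                annotations={
                    "parent_cluster": cluster.cluster_id,
                    "light_v": key[0],
                    "light_j": key[1],
                },
            )
        )
    return subclusters, unassigned


def cluster_publicness(
    cluster: ClonalCluster,
    repertoire: Repertoire,
    scorer: FrequencyScorer,
    paired_mode: bool = False,
) -> tuple[float, Optional[float]]:
    """Mean per-sequence publicness over cluster members.

    Returns ``(heavy_mean, light_mean)``; the light mean is None in
    heavy-only mode.  Per-chain means are kept separate so they can be
    standardized independently before combination.
    """
    if not getattr(scorer, "fitted", False):
        raise StateError("publicness scorer is not fitted")
    if paired_mode:
        by_heavy = repertoire.cell_by_heavy_id()
        cells = [by_heavy[m] for m in cluster.members]
        hc = float(np.mean([scorer.score_heavy(c.heavy) for c in cells]))
        lc = float(np.mean([scorer.score_light(c.light) for c in cells]))
        return hc, lc
    if repertoire.paired:
        by_id = {c.heavy.sequence_id: c.heavy for c in repertoire.cells}
    else:
        by_id = {r.sequence_id: r for r in repertoire.chains}
    hc = float(np.mean([scorer.score_heavy(by_id[m]) for m in cluster.members]))
    return hc, None


def _zscores(values: Sequence[float]) -> list[float]:
    arr = np.asarray(values, dtype=float)
    sd = arr.std()
    if sd == 0:
        return [0.0] * len(arr)
    return ((arr - arr.mean()) / sd).tolist()


def flag_public_clusters(
    scores: dict[str, tuple[float, Optional[float]]],
    config: RefinementConfig,
) -> dict[str, tuple[bool, float]]:
    """Flag the top decile of clusters by standardized publicness.

    Heavy (and, in paired mode, light) cluster scores are z-standardized
    across clusters and combined by averaging; exactly
    ``ceil(public_quantile * n)`` top-ranked clusters are flagged (ties
    broken by higher raw score, then cluster id).  With zero variance all
    z-scores are 0 and ranking falls back to the raw scores.
    """
    if len(scores) < 2:
        raise ValueError("flagging requires >= 2 clusters")
    ids = sorted(scores)
    hc_raw = [scores[i][0] for i in ids]
    hc_z = _zscores(hc_raw)
    lc_vals = [scores[i][1] for i in ids]
    if all(v is not None for v in lc_vals):
        lc_z = _zscores([float(v) for v in lc_vals])
        combined = [(h + l) / 2.0 for h, l in zip(hc_z, lc_z)]
        raw = [
            (h + float(l)) / 2.0 for h, l in zip(hc_raw, lc_vals)
        ]
    else:
        combined = hc_z
        raw = hc_raw
    n_flag = math.ceil(config.public_quantile * len(ids))
    order = sorted(
        range(len(ids)), key=lambda i: (-combined[i], -raw[i], ids[i])
    )
    flagged = set(order[:n_flag])
    return {
        ids[i]: (i in flagged, combined[i]) for i in range(len(ids))
    }


def youden_shm_cutoff(
    naive_loads: Sequence[float], memory_loads: Sequence[float]
) -> tuple[float, float]:
    """Optimal SHM threshold separating naive from memory clusters.

    Classification rule: "memory if shm_load >= t".  Candidates are the
    midpoints between consecutive sorted unique pooled values plus the
    +-infinity sentinels; the smallest candidate maximizing the Youden
    index J = sensitivity + specificity - 1 is returned together with J.
    """
    naive = list(naive_loads)
    memory = list(memory_loads)
    if not naive or not memory:
        raise ValueError("both naive and memory loads must be non-empty")
    pooled = sorted(set(naive) | set(memory))
    candidates = [-math.inf]
    candidates += [(a + b) / 2.0 for a, b in zip(pooled, pooled[1:])]
    candidates.append(math.inf)

    best_t, best_j = None, -math.inf
    for t in candidates:
        sens = sum(1 for m in memory if m >= t) / len(memory)
        spec = sum(1 for nv in naive if nv < t) / len(naive)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_t, best_j = t, j
    return float(best_t), float(best_j)


def classify_public_cluster(
    is_public: bool,
    shm: float,
    shm_cutoff: Optional[float],
    publicness_score: float = 0.0,
    publicness_z: float = 0.0,
) -> ClusterFlags:
    """Resolve a cluster's origin and retention from its flags and SHM load.

    Public clusters below the SHM cutoff are naive-like pseudo-clones and
    filtered out; public clusters at or above it are memory-derived
    expansions and retained; non-public clusters are always retained.
    With no cutoff available, public clusters are flagged but kept.
    """
    flags = ClusterFlags(
        publicness_score=publicness_score, publicness_z=publicness_z,
        is_public=is_public,
    )
    if not is_public:
        return flags
    if shm_cutoff is None:
        flags.origin = "memory_derived"
        flags.retained = True
        return flags
    if shm < shm_cutoff:
        flags.origin = "naive_like"
        flags.retained = False
    else:
        flags.origin = "memory_derived"
        flags.retained = True
    return flags


def _auto_cutoff(
    clusters: Sequence[ClonalCluster],
    repertoire: Repertoire,
    paired: bool,
) -> float:
    """Youden cutoff from clusters whose modal cell subtype is naive/memory."""
    by_heavy = repertoire.cell_by_heavy_id() if repertoire.paired else None
    naive, memory = [], []
    for cluster in clusters:
        subtypes = []
        for m in cluster.members:
            rec = by_heavy[m].heavy if by_heavy else None
            if rec is None:
                continue
            subtypes.append(rec.cell_subtype)
        if not subtypes:
            continue
        modal = max(sorted(set(subtypes)), key=subtypes.count)
        load = shm_load(cluster, repertoire, paired=paired)
        if modal == "naive":
            naive.append(load)
        elif modal == "memory":
            memory.append(load)
    if not naive or not memory:
        raise StateError(
            "auto SHM cutoff requires clusters annotated as naive and memory; "
            "pass an explicit --shm-cutoff instead"
        )
    return youden_shm_cutoff(naive, memory)[0]


def run_fastbcr_p(
    repertoire: Repertoire,
    config: RefinementConfig,
    cluster_thre: int = 3,
    overlap_thre: float = 0.1,
    consensus_thre: Optional[float] = None,
) -> RefinementResult:
    """Full refinement pipeline over one repertoire.

    Heavy-chain clustering, then (paired mode) light V-J splitting, then
    publicness flagging and SHM-based classification when a scorer is
    available.  With no paired data and no scorer this reduces to plain
    heavy-chain clustering.
    """
    heavy_records = repertoire.heavy_chains()
    base = cluster_heavy(
        heavy_records,
        cluster_thre=cluster_thre,
        overlap_thre=overlap_thre,
        consensus_thre=consensus_thre,
    )
    drop_log: list[str] = []
    unassigned: list[str] = []

    paired = config.paired_mode and repertoire.paired
    if paired:
        clusters: list[ClonalCluster] = []
        for c in base:
            subs, dropped = split_by_light_vj(
                c, repertoire, min_subcluster_size=config.min_subcluster_size
            )
            clusters.extend(subs)
            unassigned.extend(dropped)
            if dropped:
                drop_log.append(
                    f"{c.cluster_id}: {len(dropped)} member(s) unassigned by LC V-J split"
                )
    else:
        clusters = base

    flags: dict[str, ClusterFlags] = {c.cluster_id: ClusterFlags() for c in clusters}
    cutoff: Optional[float] = None
    if config.scorer is not None and len(clusters) >= 2:
        scores = {
            c.cluster_id: cluster_publicness(
                c, repertoire, config.scorer, paired_mode=paired
            )
            for c in clusters
        }
        flag_map = flag_public_clusters(scores, config)
        if config.shm_cutoff == "auto":
            cutoff = _auto_cutoff(clusters, repertoire, paired)
        elif config.shm_cutoff is not None:
            cutoff = float(config.shm_cutoff)
        for c in clusters:
            is_public, z = flag_map[c.cluster_id]
            raw_h, raw_l = scores[c.cluster_id]
            raw = raw_h if raw_l is None else (raw_h + raw_l) / 2.0
            load = shm_load(c, repertoire, paired=paired)
            flags[c.cluster_id] = classify_public_cluster(
                is_public, load, cutoff, publicness_score=raw, publicness_z=z
            )
            c.annotations["shm_load"] = load
            if not flags[c.cluster_id].retained:
                drop_log.append(
                    f"{c.cluster_id}: filtered as naive-like pseudo-clonal "
                    f"(shm {load:.2f} < cutoff {cutoff:.2f})"
                )
    return RefinementResult(
        clusters=clusters,
        flags=flags,
        unassigned=sorted(unassigned),
        shm_cutoff=cutoff,
        drop_log=drop_log,
    )
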