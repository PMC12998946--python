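"""Heavy-chain clonal family inference via k-mer seed clustering.

Records are partitioned by V gene, J gene, and junction amino-acid length;
within each partition, evenly spaced 5-mer "seeds" are extracted from every
junction, sequences sharing a seed form preliminary seed clusters, and
clusters with sufficient member overlap at compatible offsets are merged
transitively (union-find) into candidate families.  Overlapping candidates
are resolved greedily by consensus score, and clusters below the minimum
size are dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .records import ChainRecord


@dataclass
class VJGroup:
    """All records sharing a V gene, J gene, and junction length."""

    v_gene: str
    j_gene: str
    junction_length: int
    members: list[str] = field(default_factory=list)


@dataclass
class SeedCluster:
    """Sequences sharing one 5-mer at (approximately) one junction offset."""

    seed: str
    seed_offset: int
    members: set[str] = field(default_factory=set)
    junction_length: Optional[int] = None


@dataclass
class ClonalCluster:
    """An inferred clonal family of heavy-chain sequence ids."""

    cluster_id: str
    members: list[str]
    dominant_v: str = ""
    dominant_j: str = ""
    consensus_score: float = 1.0
    chain: str = "heavy"
    annotations: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def partition_vj(records: Sequence[ChainRecord]) -> list[VJGroup]:
    """Exhaustive disjoint partition on (v_call, j_call, junction length).

    Records with an empty junction are excluded (reported via the returned
    groups' complement; callers needing the count can compare sizes).
    """
    groups: dict[tuple[str, str, int], VJGroup] = {}
    for rec in records:
        if not rec.junction_aa:
            continue
        key = (rec.v_call, rec.j_call, len(rec.junction_aa))
        if key not in groups:
            groups[key] = VJGroup(*key)
        groups[key].members.append(rec.sequence_id)
    return list(groups.values())


def extract_seeds(junction_aa: str, k: int = 5, n_seeds: int = 6) -> list[tuple[str, int]]:
    """Evenly spaced k-mer seeds from a junction amino-acid sequence.

    Offsets are round(i*(L-k)/(n_seeds-1)) for i = 0..n_seeds-1 (half-up
    rounding), deduplicated preserving order.  If the junction has fewer
    than n_seeds windows, all windows are returned; junctions shorter than
    k yield no seeds (the sequence is unseedable).
    """
    L = len(junction_aa)
    if L < k:
        return []
    n_windows = L - k + 1
    if n_windows <= n_seeds:
        return [(junction_aa[i : i + k], i) for i in range(n_windows)]
    offsets: list[int] = []
    for i in range(n_seeds):
        off = int((i * (L - k)) / (n_seeds - 1) + 0.5)  # half-up
        if off not in offsets:
            offsets.append(off)
    return [(junction_aa[o : o + k], o) for o in offsets]


def build_seed_clusters(
    junctions: dict[str, str], k: int = 5, n_seeds: int = 6
) -> list[SeedCluster]:
    """Aggregate sequences containing identical seeds at identical offsets.

    ``junctions`` maps sequence_id -> junction amino-acid string (one VJ
    group).  Only clusters with >= 2 members are kept; a sequence may
    appear in several seed clusters.
    """
    buckets: dict[tuple[str, int], set[str]] = {}
    lengths: dict[tuple[str, int], int] = {}
    for sid in sorted(junctions):
        jaa = junctions[sid]
        for seed, off in extract_seeds(jaa, k=k, n_seeds=n_seeds):
            buckets.setdefault((seed, off), set()).add(sid)
            lengths[(seed, off)] = len(jaa)
    return [
        SeedCluster(seed, off, members, junction_length=lengths[(seed, off)])
        for (seed, off), members in sorted(buckets.items())
        if len(members) >= 2
    ]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def merge_seed_clusters(
    clusters: Sequence[SeedCluster],
    overlap_thre: float = 0.1,
    indel_tolerance: int = 1,
) -> list[set[str]]:
    """Integrate seed clusters into candidate families (union-find closure).

    Two routes merge a pair of clusters:

    * member overlap — clusters over junctions of the same length merge
      when |A∩B| / min(|A|,|B|) >= overlap_thre (the six seeds of one
      junction are different windows of the same sequences, so their
      clusters overlap heavily for a real family);
    * indel bridging — clusters whose junction lengths differ by at most
      ``indel_tolerance`` can never share members, so they merge when they
      carry the same seed at offsets differing by at most the tolerance
      (the same junction region shifted by an indel).

    Merging is closed transitively; the result is one member set per
    connected component.
    """
    n = len(clusters)
    uf = _UnionFind(n)

    # route 1: member overlap within a junction length
    by_member: dict[str, list[int]] = {}
    for i, c in enumerate(clusters):
        for m in c.members:
            by_member.setdefault(m, []).append(i)
    checked: set[tuple[int, int]] = set()
    for indices in by_member.values():
        for ai in range(len(indices)):
            for bi in range(ai + 1, len(indices)):
                a, b = indices[ai], indices[bi]
                if (a, b) in checked:
                    continue
                checked.add((a, b))
                ca, cb = clusters[a], clusters[b]
                inter = len(ca.members & cb.members)
                if inter / min(len(ca.members), len(cb.members)) >= overlap_thre:
                    uf.union(a, b)

    # route 2: same seed at near-identical offsets across adjacent lengths
    if indel_tolerance > 0:
        by_seed: dict[str, list[int]] = {}
        for i, c in enumerate(clusters):
            by_seed.setdefault(c.seed, []).append(i)
        for indices in by_seed.values():
            for ai in range(len(indices)):
                for bi in range(ai + 1, len(indices)):
                    a, b = indices[ai], indices[bi]
                    ca, cb = clusters[a], clusters[b]
                    if abs(ca.seed_offset - cb.seed_offset) > indel_tolerance:
                        continue
                    if (
                        ca.junction_length is not None
                        and cb.junction_length is not None
                        and not (
                            0
                            < abs(ca.junction_length - cb.junction_length)
                            <= indel_tolerance
                        )
                    ):
                        continue
                    uf.union(a, b)

    components: dict[int, set[str]] = {}
    for i, c in enumerate(clusters):
        components.setdefault(uf.find(i), set()).update(c.members)
    return [components[r] for r in sorted(components)]


def consensus_score(junctions: Sequence[str]) -> float:
    """Cluster junction homogeneity in [0, 1] (delegates to the consistency scorer)."""
    from .consistency import cdr3_consistency_score

    if len(junctions) == 1:
        return 1.0
    return cdr3_consistency_score(list(junctions))


def cluster_heavy(
    records: Sequence[ChainRecord],
    cluster_thre: int = 3,
    overlap_thre: float = 0.1,
    consensus_thre: Optional[float] = None,
    indel_tolerance: int = 1,
    k: int = 5,
    n_seeds: int = 6,
) -> list[ClonalCluster]:
    """Infer heavy-chain clonal families.

    Per (V, J) stratum (junction lengths within ``indel_tolerance`` are
    co-considered during merging, to account for SHM indels), seed clusters
    are built and merged into candidates.  Candidates are then accepted in
    decreasing consensus-score order (ties: larger cluster, then smallest
    member id) provided at least half their members are still unassigned;
    accepted clusters take only their unassigned members, so the final
    clusters are disjoint.  Clusters smaller than ``cluster_thre`` are
    dropped, as are clusters below ``consensus_thre`` when it is set.
    """
    by_id = {r.sequence_id: r for r in records}
    strata: dict[tuple[str, str], dict[str, str]] = {}
    for rec in records:
        if not rec.junction_aa or len(rec.junction_aa) < k:
            continue
        strata.setdefault((rec.v_call, rec.j_call), {})[rec.sequence_id] = rec.junction_aa

    candidates: list[tuple[float, int, str, list[str]]] = []
    for (v, j) in sorted(strata):
        junctions = strata[(v, j)]
        seed_clusters = build_seed_clusters(junctions, k=k, n_seeds=n_seeds)
        for member_set in merge_seed_clusters(
            seed_clusters, overlap_thre=overlap_thre, indel_tolerance=indel_tolerance
        ):
            members = sorted(member_set)
            score = consensus_score([junctions[m] for m in members])
            candidates.append((score, len(members), members[0], members))

    # greedy resolution: best consensus first, larger cluster, smallest member id
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
    assigned: set[str] = set()
    accepted: list[tuple[list[str], float]] = []
    for score, _, _, members in candidates:
        unassigned = [m for m in members if m not in assigned]
        if not unassigned or len(unassigned) / len(members) < 0.5:
            continue
        if len(unassigned) < len(members):
            score = consensus_score([by_id[m].junction_aa for m in unassigned])
        accepted.append((unassigned, score))
        assigned.update(unassigned)

    out: list[ClonalCluster] = []
    idx = 0
    for members, score in accepted:
        if len(members) < cluster_thre:
            continue
        if consensus_thre is not None and score < consensus_thre:
            continue
        v_counts = Counter(by_id[m].v_call for m in members)
        j_counts = Counter(by_id[m].j_call for m in members)
        out.append(
            ClonalCluster(
                cluster_id=f"C{idx:05d}",
                members=members,
                dominant_v=min(v_counts, key=lambda g: (-v_counts[g], g)),
                dominant_j=min(j_counts, key=lambda g: (-j_counts[g], g)),
                consensus_score=score,
            )
        )
        idx += 1
    return out
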