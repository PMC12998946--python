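"""Cluster-level concordance scoring and the baseline publicness scorer.

Concordance within an inferred clonal family is measured on three axes:
dominant V/J gene usage (fraction of members carrying the modal call),
junction amino-acid homogeneity (agreement with the consensus of a
center-star multiple sequence alignment), and SHM load (mean mutation
count).  Cross-sample sharing counts and a frequency-based publicness
scorer support the detection of convergent "public" sequences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
from Bio import Align

from .records import ChainRecord, PairedCell, Repertoire, StateError

GAP = "-"


def gene_consistency_score(calls: Sequence[str]) -> float:
    """n_max / N: fraction of members carrying the most frequent gene call."""
    if not calls:
        raise ValueError("gene_consistency_score requires >= 1 call")
    counts = Counter(calls)
    return max(counts.values()) / len(calls)


def vj_combination_score(v_calls: Sequence[str], j_calls: Sequence[str]) -> float:
    """Dominance of the modal joint (V, J) pair; <= min of the marginal scores."""
    if len(v_calls) != len(j_calls):
        raise ValueError("v_calls and j_calls must have equal length")
    if not v_calls:
        raise ValueError("vj_combination_score requires >= 1 pair")
    counts = Counter(zip(v_calls, j_calls))
    return max(counts.values()) / len(v_calls)


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def star_center_index(sequences: Sequence[str]) -> int:
    """Index of the sequence minimizing summed edit distance to all others."""
    best_idx, best_sum = 0, None
    for i, seq in enumerate(sequences):
        total = sum(_edit_distance(seq, other) for other in sequences)
        if best_sum is None or total < best_sum:
            best_idx, best_sum = i, total
    return best_idx


def _merge_into_star(
    master_center: str, rows: list[str], c_aln: str, s_aln: str
) -> tuple[str, list[str], str]:
    """Fold one pairwise (center, seq) alignment into the growing star MSA.

    ``master_center`` is the center with gaps accumulated from previous
    merges; ``c_aln``/``s_aln`` is a fresh pairwise alignment of the
    ungapped center against the new sequence.  Gap columns from either
    source are interleaved (master insertions first) so that "once a gap,
    always a gap" holds.
    """
    out_center: list[str] = []
    out_rows: list[list[str]] = [[] for _ in rows]
    out_new: list[str] = []
    i = j = 0
    while i < len(master_center) or j < len(c_aln):
        if i < len(master_center) and master_center[i] == GAP:
            out_center.append(GAP)
            for r, row in enumerate(rows):
                out_rows[r].append(row[i])
            out_new.append(GAP)
            i += 1
        elif j < len(c_aln) and c_aln[j] == GAP:
            out_center.append(GAP)
            for r in range(len(rows)):
                out_rows[r].append(GAP)
            out_new.append(s_aln[j])
            j += 1
        else:  # both carry the same center residue
            out_center.append(master_center[i])
            for r, row in enumerate(rows):
                out_rows[r].append(row[i])
            out_new.append(s_aln[j])
            i += 1
            j += 1
    return (
        "".join(out_center),
        ["".join(r) for r in out_rows],
        "".join(out_new),
    )


def msa_consensus(junction_aas: Sequence[str]) -> tuple[list[str], str]:
    """Center-star MSA of junction sequences plus the column-consensus sequence.

    The center is the sequence with minimal summed edit distance; every
    other sequence is globally aligned to it (match +1, mismatch 0, gap -1)
    and folded into the star.  The consensus takes the most frequent symbol
    per column; ties go to the center's symbol, and a gap never wins
    against a residue (the consensus is always a residue).
    """
    seqs = list(junction_aas)
    if not seqs:
        raise ValueError("msa_consensus requires >= 1 sequence")
    if len(seqs) == 1:
        return [seqs[0]], seqs[0]

    center_idx = star_center_index(seqs)
    center = seqs[center_idx]

    # equal-length inputs need no alignment: columns are positions
    if len({len(s) for s in seqs}) == 1:
        return list(seqs), _column_consensus(list(seqs), center)

    aligner = _aligner()

    master_center = center
    rows: list[str] = []
    order: list[int] = []
    for i, seq in enumerate(seqs):
        if i == center_idx:
            continue
        aln = aligner.align(center, seq)[0]
        c_aln, s_aln = str(aln[0]), str(aln[1])
        master_center, rows, new_row = _merge_into_star(
            master_center, rows, c_aln, s_aln
        )
        rows.append(new_row)
        order.append(i)

    # restore input order, center included
    aligned: list[Optional[str]] = [None] * len(seqs)
    aligned[center_idx] = master_center
    for row, i in zip(rows, order):
        aligned[i] = row
    matrix: list[str] = aligned  # type: ignore[assignment]
    return matrix, _column_consensus(matrix, master_center)


def _column_consensus(matrix: list[str], aligned_center: str) -> str:
    consensus_chars: list[str] = []
    for col in range(len(aligned_center)):
        counts = Counter(row[col] for row in matrix)
        center_sym = aligned_center[col]
        residues = {s: c for s, c in counts.items() if s != GAP}
        if not residues:
            continue  # all-gap column (cannot arise from star merging)
        best = max(residues.values())
        top = sorted(s for s, c in residues.items() if c == best)
        if center_sym in top:
            consensus_chars.append(center_sym)
        else:
            consensus_chars.append(top[0])
    return "".join(consensus_chars)


def cdr3_consistency_score(junction_aas: Sequence[str]) -> float:
    """Mean per-column agreement of all members with the MSA consensus.

    A gap counts as disagreement with the (always-residue) consensus
    symbol.  1.0 iff all junctions are identical; permutation invariant up
    to alignment ties.
    """
    seqs = list(junction_aas)
    if not seqs:
        raise ValueError("cdr3_consistency_score requires >= 1 sequence")
    if len(seqs) == 1:
        return 1.0
    matrix, consensus = msa_consensus(seqs)
    n_cols = len(matrix[0])
    if n_cols == 0:
        return 1.0
    total = 0.0
    ci = 0
    for col in range(n_cols):
        column = [row[col] for row in matrix]
        if all(sym == GAP for sym in column):
            continue
        total += sum(1 for sym in column if sym == consensus[ci]) / len(column)
        ci += 1
    return total / ci if ci else 1.0


@dataclass
class ConsistencyReport:
    """Per-cluster concordance summary for one chain side."""

    v_score: float
    j_score: float
    vj_score: float
    cdr3_score: float
    N: int
    n_max_v: int
    n_max_j: int


def cluster_report(cluster, repertoire: Repertoire, chain: str = "heavy") -> ConsistencyReport:
    """Concordance report for the requested chain side of a cluster.

    Cluster members are heavy-chain sequence ids; ``chain="light"``
    requires paired data and scores the linked light chains.
    """
    recs = _chain_records(cluster, repertoire, chain)
    v_calls = [r.v_call for r in recs]
    j_calls = [r.j_call for r in recs]
    junctions = [r.junction_aa for r in recs]
    v_counts = Counter(v_calls)
    j_counts = Counter(j_calls)
    return ConsistencyReport(
        v_score=gene_consistency_score(v_calls),
        j_score=gene_consistency_score(j_calls),
        vj_score=vj_combination_score(v_calls, j_calls),
        cdr3_score=cdr3_consistency_score(junctions),
        N=len(recs),
        n_max_v=max(v_counts.values()),
        n_max_j=max(j_counts.values()),
    )


def _chain_records(cluster, repertoire: Repertoire, chain: str) -> list[ChainRecord]:
    members = cluster.members if hasattr(cluster, "members") else list(cluster)
    if chain == "heavy" and not repertoire.paired:
        by_id = {r.sequence_id: r for r in repertoire.chains}
        try:
            return [by_id[m] for m in members]
        except KeyError as exc:
            raise KeyError(f"cluster member {exc} not found in repertoire") from exc
    if not repertoire.paired:
        cid = getattr(cluster, "cluster_id", "?")
        raise StateError(
            f"cluster {cid}: chain={chain!r} scoring requires paired data"
        )
    by_heavy = repertoire.cell_by_heavy_id()
    missing = [m for m in members if m not in by_heavy]
    if missing:
        cid = getattr(cluster, "cluster_id", "?")
        raise StateError(f"cluster {cid}: members without pairing: {missing[:5]}")
    cells = [by_heavy[m] for m in members]
    return [c.heavy for c in cells] if chain == "heavy" else [c.light for c in cells]


def shm_load(cluster, repertoire: Repertoire, paired: bool = False) -> float:
    """Mean SHM count over cluster members.

    In paired mode each cell contributes the mean of its heavy and light
    shm_count.  Falls back to v_identity-derived counts when shm_count is
    absent but an AIRR ``v_identity`` extra column is present.
    """
    heavies = _chain_records(cluster, repertoire, "heavy")
    if paired:
        lights = _chain_records(cluster, repertoire, "light")
        values = [
            (_shm_of(h) + _shm_of(l)) / 2.0 for h, l in zip(heavies, lights)
        ]
    else:
        values = [_shm_of(h) for h in heavies]
    return float(sum(values) / len(values))


def _shm_of(rec: ChainRecord) -> float:
    if rec.shm_count is not None:
        return float(rec.shm_count)
    v_identity = rec.extra.get("v_identity")
    if v_identity not in (None, ""):
        length = rec.v_sequence_end or (len(rec.sequence_nt or "") or 0)
        return round((1.0 - float(v_identity)) * length)
    raise StateError(
        f"record {rec.sequence_id!r} has no SHM information; provide "
        "shm_count or a v_identity column"
    )


def _sharing_key(rec: ChainRecord) -> tuple:
    return (rec.locus, rec.v_call, rec.junction_aa)


def sharing_counts(
    records: Sequence, corpus: Sequence[Repertoire], key: str = "heavy"
) -> list[int]:
    """For each record (or paired cell), the number of distinct corpus samples
    containing an identical V-gene + CDR3 key (both chains for key="paired")."""
    sample_keys: dict[tuple, set[str]] = {}
    for rep in corpus:
        if key == "paired":
            for cell in rep.cells:
                k = _sharing_key(cell.heavy) + _sharing_key(cell.light)
                sample_keys.setdefault(k, set()).add(rep.sample_id)
        else:
            want = "IGH" if key == "heavy" else None
            for rec in rep.all_chains():
                if want and rec.locus != want:
                    continue
                if key == "light" and rec.locus == "IGH":
                    continue
                sample_keys.setdefault(_sharing_key(rec), set()).add(rep.sample_id)
    counts = []
    for item in records:
        if key == "paired":
            k = _sharing_key(item.heavy) + _sharing_key(item.light)
        else:
            k = _sharing_key(item)
        counts.append(len(sample_keys.get(k, set())))
    return counts


class FrequencyScorer:
    """Occurrence-frequency publicness scorer (pluggable baseline).

    A sequence key is its V gene plus CDR pattern (CDR1/CDR2 when present,
    CDR3 always).  Heavy chains seen in >= 10 samples are maximally public
    (probability 1); light-chain publicness is the raw cross-sample count,
    mirroring a classification (heavy) vs regression (light) split.
    Unseen keys score as a single occurrence.
    """

    hc_public_threshold = 10
    lc_public_threshold = 5

    def __init__(self) -> None:
        self.hc_counts: dict[tuple, int] = {}
        self.lc_counts: dict[tuple, int] = {}
        self.fitted = False

    @staticmethod
    def _key(rec: ChainRecord) -> tuple:
        return (rec.v_call, rec.cdr1_aa or "", rec.cdr2_aa or "", rec.junction_aa)

    def fit(self, corpus: Sequence[Repertoire]) -> "FrequencyScorer":
        if not corpus:
            raise ValueError("corpus must contain >= 1 repertoire")
        hc_samples: dict[tuple, set[str]] = {}
        lc_samples: dict[tuple, set[str]] = {}
        for rep in corpus:
            for rec in rep.all_chains():
                table = hc_samples if rec.locus == "IGH" else lc_samples
                table.setdefault(self._key(rec), set()).add(rep.sample_id)
        self.hc_counts = {k: len(v) for k, v in hc_samples.items()}
        self.lc_counts = {k: len(v) for k, v in lc_samples.items()}
        self.fitted = True
        return self

    def _check(self) -> None:
        if not self.fitted:
            raise StateError("scorer must be fitted before scoring")

    def score_heavy(self, rec: ChainRecord) -> float:
        self._check()
        count = self.hc_counts.get(self._key(rec), 1)
        return min(1.0, count / self.hc_public_threshold)

    def score_light(self, rec: ChainRecord) -> float:
        self._check()
        return float(self.lc_counts.get(self._key(rec), 1))


# convenience wrapper mirroring the functional surface
def fit_frequency_scorer(corpus: Sequence[Repertoire]) -> FrequencyScorer:
    return FrequencyScorer().fit(corpus)
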