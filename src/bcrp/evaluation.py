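"""Ground-truth clustering evaluation.

Compares an inferred partition of sequences against the simulated truth
with four metric families: the adjusted Rand index (pair-counting,
chance-corrected); pairwise precision/recall/F (over all unordered
sequence pairs); closeness precision/recall/F (best-correspondence between
inferred clusters and truth families via modal labels); and the
true-inferred-cluster (TIC) suite — the fraction of inferred clusters that
reconstruct at least 80% of some family, their purity, and the overall
retention of family members inside them.

Noise/singleton sequences carry the reserved label "noise": they form no
true pairs and, for the ARI, are expanded to per-sequence singleton labels
(alternatively excluded via ``noise_mode="exclude"``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Optional, Sequence

from .records import NOISE_LABEL


@dataclass
class LabeledPartition:
    """A full labeling of sequence ids; ``noise_label`` marks noise/singletons."""

    assignment: dict[str, str]
    noise_label: str = NOISE_LABEL

    @classmethod
    def from_clusters(
        cls, clusters: Sequence, all_ids: Sequence[str], noise_label: str = NOISE_LABEL
    ) -> "LabeledPartition":
        """Build a partition from inferred clusters; unclustered ids get the noise label."""
        assignment = {i: noise_label for i in all_ids}
        for c in clusters:
            label = getattr(c, "cluster_id", None)
            members = getattr(c, "members", c)
            if label is None:
                label = f"cluster{id(c)}"
            for m in members:
                assignment[m] = label
        return cls(assignment, noise_label)

    def clusters(self) -> dict[str, list[str]]:
        """Non-noise label -> member ids."""
        out: dict[str, list[str]] = {}
        for sid, label in self.assignment.items():
            if label != self.noise_label:
                out.setdefault(label, []).append(sid)
        return out

    def expanded(self) -> dict[str, str]:
        """Assignment with each noise id as its own singleton label."""
        return {
            sid: (f"__singleton__{sid}" if label == self.noise_label else label)
            for sid, label in self.assignment.items()
        }


def _check_ids(truth: LabeledPartition, inferred: LabeledPartition) -> None:
    t, i = set(truth.assignment), set(inferred.assignment)
    if t != i:
        diff = sorted(t.symmetric_difference(i))
        raise ValueError(f"partitions cover different ids: {diff[:10]}")


def adjusted_rand_index(
    truth: LabeledPartition,
    inferred: LabeledPartition,
    noise_mode: str = "singleton",
) -> float:
    """Pair-counting ARI between the two partitions.

    ``noise_mode="singleton"`` treats each noise id as its own cluster in
    both partitions (the pair-counting formula assumes a full partition);
    ``"exclude"`` drops truth-noise ids from both sides first.
    """
    _check_ids(truth, inferred)
    t_map = truth.expanded()
    i_map = inferred.expanded()
    ids = list(t_map)
    if noise_mode == "exclude":
        ids = [s for s in ids if truth.assignment[s] != truth.noise_label]
    elif noise_mode != "singleton":
        raise ValueError("noise_mode must be singleton|exclude")
    if not ids:
        raise ValueError("no ids left to evaluate")

    contingency: Counter = Counter((t_map[s], i_map[s]) for s in ids)
    a: Counter = Counter(t_map[s] for s in ids)
    b: Counter = Counter(i_map[s] for s in ids)
    n = len(ids)

    sum_nij = sum(comb(c, 2) for c in contingency.values())
    sum_a = sum(comb(c, 2) for c in a.values())
    sum_b = sum(comb(c, 2) for c in b.values())
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total else 0.0
    maximum = (sum_a + sum_b) / 2.0
    if maximum == expected:
        return 1.0  # both partitions trivial (all singletons or one block)
    return (sum_nij - expected) / (maximum - expected)


def _harmonic(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def pairwise_metrics(
    truth: LabeledPartition, inferred: LabeledPartition
) -> tuple[float, float, float]:
    """Precision, recall and F over all unordered sequence pairs.

    A pair is TP if co-clustered in both partitions, FP if co-clustered
    only in the inference (noise-noise pairs included), FN if only in the
    truth.  Noise ids form no true pairs.
    """
    _check_ids(truth, inferred)
    t_ass, i_ass = truth.assignment, inferred.assignment
    tn, inl = truth.noise_label, inferred.noise_label

    contingency: Counter = Counter()
    a: Counter = Counter()  # inferred cluster sizes
    b: Counter = Counter()  # truth family sizes
    for sid, il in i_ass.items():
        tl = t_ass[sid]
        if il != inl:
            a[il] += 1
            if tl != tn:
                contingency[(tl, il)] += 1
        if tl != tn:
            b[tl] += 1

    tp = sum(comb(c, 2) for c in contingency.values())
    inferred_pairs = sum(comb(c, 2) for c in a.values())
    true_pairs = sum(comb(c, 2) for c in b.values())
    fp = inferred_pairs - tp
    fn = true_pairs - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall, _harmonic(precision, recall)


def _modal_label(members: Sequence[str], t_ass: Mapping[str, str]) -> str:
    counts = Counter(t_ass[m] for m in members)
    best = max(counts.values())
    return sorted(l for l, c in counts.items() if c == best)[0]


def closeness_metrics(
    truth: LabeledPartition, inferred: LabeledPartition
) -> tuple[float, float, float]:
    """Best-correspondence precision, recall and F.

    Each inferred cluster is labeled by its modal truth label; its TP count
    is its intersection with the matching family, FP the remainder of the
    cluster, FN the remainder of the family.  Clusters whose modal label is
    noise have no corresponding family (TP 0, FP = cluster size, FN 0).
    """
    _check_ids(truth, inferred)
    t_ass = truth.assignment
    families = truth.clusters()
    tp = fp = fn = 0
    for members in inferred.clusters().values():
        label = _modal_label(members, t_ass)
        if label == truth.noise_label:
            fp += len(members)
            continue
        inter = sum(1 for m in members if t_ass[m] == label)
        tp += inter
        fp += len(members) - inter
        fn += len(families[label]) - inter
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall, _harmonic(precision, recall)


def tic_metrics(
    truth: LabeledPartition,
    inferred: LabeledPartition,
    reconstruction_threshold: float = 0.8,
) -> tuple[float, float, float, int, dict[str, str]]:
    """True-inferred-cluster (TIC) fraction, purity and retention.

    A family's TIC is the inferred cluster holding its largest member
    share, provided that cluster covers at least 80% of the family; each
    inferred cluster serves at most one family (largest share wins, ties to
    the smaller family label).  Remaining clusters are classed "noise"
    (only noise members) or "mix".  Fraction = N*/M over the M inferred
    clusters; purity and retention pool member counts over all TICs.
    """
    _check_ids(truth, inferred)
    t_ass = truth.assignment
    families = truth.clusters()
    if not families:
        raise ValueError("truth contains no non-noise family")
    inferred_clusters = inferred.clusters()
    M = len(inferred_clusters)

    # family -> (best cluster, intersection size)
    overlap: dict[str, Counter] = {f: Counter() for f in families}
    for cid, members in inferred_clusters.items():
        for m in members:
            tl = t_ass[m]
            if tl != truth.noise_label:
                overlap[tl][cid] += 1

    claims: dict[str, tuple[str, int]] = {}  # cluster -> (family, intersection)
    for fam in sorted(families):
        counts = overlap[fam]
        if not counts:
            continue
        best = max(counts.values())
        cid = sorted(c for c, n in counts.items() if n == best)[0]
        if best < reconstruction_threshold * len(families[fam]):
            continue
        held = claims.get(cid)
        if held is None or best > held[1] or (best == held[1] and fam < held[0]):
            claims[cid] = (fam, best)

    classes: dict[str, str] = {}
    tic_member_total = 0
    tic_correct_total = 0
    for cid, members in inferred_clusters.items():
        if cid in claims:
            classes[cid] = "tic"
            fam, inter = claims[cid]
            tic_member_total += len(members)
            tic_correct_total += inter
        elif all(t_ass[m] == truth.noise_label for m in members):
            classes[cid] = "noise"
        else:
            classes[cid] = "mix"

    n_tic = len(claims)
    fraction = n_tic / M if M else 0.0
    purity = tic_correct_total / tic_member_total if tic_member_total else 0.0
    family_total = sum(len(v) for v in families.values())
    retention = tic_correct_total / family_total if family_total else 0.0
    return fraction, purity, retention, n_tic, classes


@dataclass
class EvaluationReport:
    ari: float
    pairwise_precision: float
    pairwise_recall: float
    pairwise_fm: float
    closeness_precision: float
    closeness_recall: float
    closeness_fm: float
    tic_fraction: float
    tic_purity: float
    tic_retention: float
    n_tic: int
    n_noise_clusters: int
    n_mix_clusters: int
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extra"}
        d.update(self.extra)
        return d


def evaluate(
    truth: LabeledPartition,
    inferred: LabeledPartition,
    noise_mode: str = "singleton",
    reconstruction_threshold: float = 0.8,
) -> EvaluationReport:
    """All metrics in one pass; deterministic for fixed inputs."""
    ari = adjusted_rand_index(truth, inferred, noise_mode=noise_mode)
    pp, pr, pf = pairwise_metrics(truth, inferred)
    cp, cr, cf = closeness_metrics(truth, inferred)
    frac, pur, ret, n_tic, classes = tic_metrics(
        truth, inferred, reconstruction_threshold=reconstruction_threshold
    )
    counts = Counter(classes.values())
    return EvaluationReport(
        ari=ari,
        pairwise_precision=pp, pairwise_recall=pr, pairwise_fm=pf,
        closeness_precision=cp, closeness_recall=cr, closeness_fm=cf,
        tic_fraction=frac, tic_purity=pur, tic_retention=ret,
        n_tic=n_tic,
        n_noise_clusters=counts.get("noise", 0),
        n_mix_clusters=counts.get("mix", 0),
    )


_NORMALIZED_METRICS = (
    "ari", "pairwise_precision", "pairwise_recall", "pairwise_fm",
    "closeness_precision", "closeness_recall", "closeness_fm",
    "tic_fraction", "tic_purity", "tic_retention",
)


def normalize_reports(reports: Mapping[str, EvaluationReport]):
    """Min-max scale each metric across compared methods (radar-plot-ready).

    With a single method, or a metric constant across methods, the
    normalized value is 1.
    """
    import pandas as pd

    rows = {}
    for name, rep in reports.items():
        rows[name] = {m: getattr(rep, m) for m in _NORMALIZED_METRICS}
    df = pd.DataFrame(rows).T
    lo, hi = df.min(), df.max()
    span = hi - lo
    normalized = df.copy()
    for col in df.columns:
        if span[col] == 0:
            normalized[col] = 1.0
        else:
            normalized[col] = (df[col] - lo[col]) / span[col]
    return normalized


def truth_from_records(records: Sequence, noise_label: str = NOISE_LABEL) -> LabeledPartition:
    """Truth partition from ChainRecords carrying ``true_clone_id``."""
    assignment = {}
    for rec in records:
        assignment[rec.sequence_id] = rec.true_clone_id or noise_label
    return LabeledPartition(assignment, noise_label)
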