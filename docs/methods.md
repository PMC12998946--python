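# Methods

## The simulator

The simulator produces paired heavy/light repertoires with known clonal
structure. It deliberately models the *clustering-relevant* features of
affinity maturation — junctional diversity, CDR3-concentrated SHM, clonal
expansion with attrition — and nothing else.

**Germline set.** A bundled synthetic set (`data/germline_synthetic.fasta`)
provides 20 V / 10 D / 6 J segments for IGH and 15 V / 5 J for each light
locus. Sequences are random but fixed; every V ends with a TGT (Cys) codon
and every J begins with TGG (Trp), so assembled junctions carry the
conserved CDR3 anchors. D segments are 28–36 nt, placing heavy CDR3s in
the human-typical 12–15 aa range — long enough that a single amino-acid
change cannot erase all 5-mer windows at once, which is also true of real
heavy chains. Users may substitute any IMGT-style FASTA per locus.

**Ancestor assembly.** Heavy ancestors concatenate random V, D, J
segments with 1–3 single-nucleotide indels at each of the V-D and D-J
junctions; light ancestors draw the kappa locus with probability 0.60 and
join V to J with 0–2 indels. Deletions trim the D segment (heavy) or the
J 5' end (light), so `v_sequence_end` and `j_sequence_start` (1-based,
inclusive, AIRR convention) remain exact. The CDR3 span of a synthetic
record is the region strictly between the V end and J start extended one
codon into each flank; the junction amino-acid string is its in-frame
translation (trailing partial codons dropped). A consequence worth noting:
light-chain junctions are short (the V-J join plus two anchor codons),
unlike real light CDR3s which draw most of their length from the V 3'
region. This does not affect clustering (heavy-chain based) but makes the
light CDR3 consistency score coarse on simulated data.

**Somatic hypermutation.** Each round, every position within the CDR3
window (+-15 nt for heavy, +-10 nt for light) mutates independently with
probability mu = 0.01 (light chains use mu times a multiplier, default
0.5). Mutation types are drawn at insertion:deletion:substitution =
0.8:1:100; substitution targets follow a per-base matrix whose G row is
A 0.70 / T 0.15 / C 0.15 (the documented transition bias) and whose other
rows are uniform — the source only specifies the G row, so uniformity is
the least-informative completion, and the matrix is configurable.
Positions outside the window never mutate. Indels shift the recorded
V/J coordinates; junctions are re-derived after every round, so
`shm_count` counts mutation events accumulated down a lineage.

**Expansion and selection.** A family starts as 5 founder copies of the
ancestor. Each of 6 rounds, every living member spawns 2 mutated
offspring, then exactly `round(0.40 * n_new)` of the round's new variants
are discarded uniformly at random (deterministic count, random identity;
a per-variant Bernoulli mode exists behind `apoptosis_mode` for users who
prefer it — the deterministic form gives tighter test tolerances). The
per-round offspring count is not dictated by the biology being emulated;
2 was fixed once so that default families reach several hundred members,
matching the benchmark scale of thousands of family sequences in ten
families. The ancestor itself is emitted as a family member (configurable).

**Noise.** Two artifact generators:

* *junction-randomized noise* copies a family member's V/J calls and
  flanking sequence but rewrites the junction interior (per-position
  substitution probability 0.6, plus 0–3 indels) and pairs it with a
  freshly rearranged light chain carrying elevated point mutations (rate
  0.03 across the whole chain). These emulate unrelated singletons that
  share V/J annotation with families.
* *chain-mixed noise* copies a family member's heavy chain nearly intact
  (0–2 junction substitutions) but pairs it with a fresh light chain —
  the canonical chain-mixing artifact, invisible to heavy-only methods.

* the *public fixture* builder emits multi-sample repertoires in which a
  designated low-SHM clone (members differ by at most one substitution)
  recurs across a configurable number of samples, emulating convergent
  recombination rather than expansion.

**Benchmark assembly** concatenates families and noise, then collapses
cells with identical translated heavy+light amino-acid sequences to one
representative (mirroring standard repertoire preprocessing; the
deduplication key is the full pair, with a heavy-only option). Truth
labels map heavy-chain sequence ids to family labels or "noise".

## Heavy-chain clustering

Within each (V gene, J gene) stratum, junctions shorter than 5 aa are
unseedable and left unclustered. Six 5-mer seeds are taken per junction at
offsets `round(i*(L-5)/5)` (half-up rounding, deduplicated; all windows if
fewer than six exist). Sequences sharing a seed at the same offset form
seed clusters (size >= 2). Seed clusters are merged transitively by two
routes: same-junction-length clusters merge when shared members reach 10%
of the smaller cluster (different windows of one family overlap heavily);
clusters whose junction lengths differ by exactly the indel tolerance
(default 1) merge when they carry the same seed at offsets within that
tolerance — such clusters can never share members, so seed identity is
the only available bridge across an SHM indel. Candidates are then
accepted greedily in decreasing consensus-score order (ties: larger
cluster, then smallest member id), each claiming only members not already
assigned, and only when at least half its members are still free; this
replaces the original method's unspecified dynamic-programming
integration with a deterministic rule whose output is validated against a
brute-force single-linkage oracle on well-separated instances. Clusters
below `cluster_thre = 3` members are dropped; no consensus-score filter is
applied unless `consensus_thre` is set.

## Consistency scores

* V (or J) gene consistency = `n_max / N`, the fraction of members
  carrying the modal call; the joint V–J score uses the modal (V, J) pair
  and is never above either marginal.
* CDR3 consistency aligns the junctions (center-star: the center is the
  sequence with minimal summed edit distance; others are globally aligned
  to it with match +1, mismatch 0, gap -1; equal-length inputs reduce to
  positional stacking), takes the column-wise consensus (most frequent
  symbol, ties to the center's symbol, a gap never beats a residue), and
  averages over columns the fraction of members matching the consensus,
  gaps counting as mismatches. All members are counted in the agreement
  fraction, including the one contributing the consensus symbol — the
  alternative (excluding it) rescales the score without changing its
  ordering, and counting all members keeps the score exactly 1 for
  identical inputs.
* SHM load is the arithmetic mean of member `shm_count` (paired mode:
  mean of heavy and light per cell). When `shm_count` is absent but an
  AIRR `v_identity` column is present, `round((1 - v_identity) * v length)`
  is used.
* The frequency publicness scorer counts, per (V gene, CDR1, CDR2, CDR3)
  key, the number of distinct samples containing the key. Heavy-chain
  publicness is `min(1, count/10)` (>=10 occurrences = fully public, a
  classification-style probability); light-chain publicness is the raw
  count (a regression-style target, light chains being far more often
  shared); unseen keys count as 1. The scorer is a pluggable interface:
  any object with fitted/score_heavy/score_light can replace it, e.g. a
  learned sequence model.

## Refinement

Heavy clusters are split by exact light (V, J) usage; subclusters below
`min_subcluster_size` (default = `cluster_thre`) are demoted to
unassigned rather than kept as undersized clusters. Cluster publicness is
the mean member score per chain; per-chain values are z-standardized
across clusters and combined by averaging the two z-scores (how the two
standardized chains are combined is an open design point; the mean is
symmetric and scale-free). Exactly `ceil(0.10 * n_clusters)` top-ranked
clusters are flagged — an explicit count rather than a score threshold,
so the "top 10%" is exact and deterministic; ties break by raw score then
cluster id, and zero-variance score sets fall back to raw ranking.

Flagged clusters are classified by SHM: below the cutoff they are
naive-like pseudo-clones (`retained = False`), at or above it
memory-derived expansions (retained). The cutoff may be given explicitly
or derived by ROC analysis from clusters whose modal cell subtype is
naive or memory: candidate thresholds are midpoints between consecutive
pooled unique SHM loads plus +-infinity sentinels, the rule is "memory if
load >= t", and the smallest candidate maximizing the Youden index
(sensitivity + specificity - 1) is chosen. When neither is available,
public clusters are flagged but nothing is filtered (safe default).
Filtered clusters remain in the output with `retained = False` so
downstream users decide whether to drop them.

## Evaluation

Truth and inference are full labelings with a reserved noise label.

* **ARI** uses the pair-counting formula on contingency counts; noise ids
  become per-id singleton labels (the formula assumes a full partition),
  with an exclude-noise mode behind a flag.
* **Pairwise** precision/recall/F count unordered pairs: TP co-clustered
  in both, FP co-clustered only in the inference (noise-noise pairs
  included), FN only in the truth.
* **Closeness** labels each inferred cluster by its modal truth label
  (ties: lexicographically smallest; a noise-modal cluster contributes
  only false positives) and accumulates TP/FP/FN against the matching
  family.
* **TIC** metrics: a family's TIC is the inferred cluster holding its
  largest member share, if that cluster covers >= 80% of the family; each
  cluster serves at most one family (largest share wins, ties to the
  smaller family label). Fraction = TIC count over all inferred clusters;
  purity and retention pool member counts over TICs (micro-average),
  matching the set-cardinality definitions; the retention formula is
  already in [0, 1], so no further normalization is applied. Remaining
  clusters are classed noise (only noise members) or mix.

All four families of metrics are tested for exact agreement with
independent brute-force implementations (explicit pair enumeration,
literal set arithmetic, an external ARI implementation) on hundreds of
random partitions, and the Youden cutoff against an exhaustive threshold
sweep.

## Problem sizes and determinism

The default benchmark (10 families, 3,500 junction-randomized noise
cells) yields roughly 6,000 cells after deduplication — thousands of
family members and thousands of noise cells, the scale the method is
meant for — and runs end to end in seconds; the test suite's refinement
comparison injects 300 chain-mixed cells on top. Every stochastic
component takes an explicit `numpy` Generator; pipeline stages derive
independent substreams from one global seed keyed by stage name, so
adding a stage never perturbs earlier stages' draws and identical
configurations reproduce byte-identical outputs.

## Known limitations

* SHM is position-independent within the window: no hotspot motifs
  (WRC/GYW), no codon-context model, no selection on affinity.
* Heavy/light rearrangements are sampled independently; real pairing has
  weak biases the simulator ignores (it models pairing artifacts, not
  pairing preferences).
* Light-chain junctions are shorter than real light CDR3s (see above).
* The publicness baseline is frequency lookup; it cannot generalize to
  unseen sequences the way a learned model can, and scores them as
  singletons. Passing tests therefore demonstrate the refinement
  machinery, not publicness prediction on held-out sequences.
* Isotype switching, lineage trees within families, and per-position
  SHM analyses are out of scope.
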