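"""Ground-truth simulator for paired-chain clonal families.

Each clonal family starts from one ancestral cell: a heavy chain assembled
from random IGH V/D/J segments (with junctional indels) paired with a light
chain from IGK or IGL V/J segments.  The family then grows through rounds
of clonal expansion with somatic hypermutation (SHM) concentrated in and
around the CDR3, followed by random apoptosis of a fixed fraction of new
variants — a coarse model of germinal-center selection.

Noise generators emulate the two artifact classes that plague heavy-chain-
only clustering: junction-randomized singletons that share V/J annotations
with real families, and chain-mixed cells whose heavy chain resembles a
family member while the light chain is freshly rearranged.  A public-clone
fixture builder emits low-SHM, near-identical pseudo-clones recurring
across samples (convergent recombination, not clonal expansion).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import (
    ChainRecord,
    ConfigurationError,
    GermlineSet,
    NOISE_LABEL,
    PairedCell,
    Repertoire,
)

BASES = ("A", "C", "G", "T")
MUTATION_KINDS = ("insertion", "deletion", "substitution")

#: substitution target distribution per original base; the G row reflects the
#: strong G->A transition bias, the remaining rows are uniform
DEFAULT_SUBSTITUTION_MATRIX = {
    "G": {"A": 0.70, "T": 0.15, "C": 0.15},
    "A": {"C": 1 / 3, "G": 1 / 3, "T": 1 / 3},
    "C": {"A": 1 / 3, "G": 1 / 3, "T": 1 / 3},
    "T": {"A": 1 / 3, "C": 1 / 3, "G": 1 / 3},
}

_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def translate_nt(seq: str) -> str:
    """Translate in frame 0, truncating a trailing partial codon."""
    table = _codon_table()
    n = len(seq) - len(seq) % 3
    return "".join(table.get(seq[i : i + 3], "X") for i in range(0, n, 3))


@dataclass
class SimulationConfig:
    """All simulator rates and counts.

    Defaults encode the study conditions: 60% kappa light chains, 1-3
    junctional indels per heavy junction (0-2 for light), SHM rate 0.01 per
    eligible position per round with insertion:deletion:substitution drawn
    at 0.8:1:100, mutation windows of +-15 nt (heavy) / +-10 nt (light)
    around CDR3, five founder cells, 40% apoptosis, six rounds.
    """

    n_families: int = 10
    kappa_probability: float = 0.60
    hc_junction_indels: tuple[int, int] = (1, 3)
    lc_junction_indels: tuple[int, int] = (0, 2)
    mutation_rate: float = 0.01
    mutation_type_weights: tuple[float, float, float] = (0.8, 1.0, 100.0)
    hc_window: int = 15
    lc_window: int = 10
    initial_cells: int = 5
    apoptosis_fraction: float = 0.40
    n_rounds: int = 6
    expansion_factor: int = 2
    substitution_matrix: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_SUBSTITUTION_MATRIX)
    )
    n_noise: int = 3500
    n_chain_mixed: int = 0
    lc_rate_multiplier: float = 0.5
    apoptosis_mode: str = "deterministic"  # or "bernoulli"
    emit_ancestor: bool = True
    noise_junction_sub_rate: float = 0.6
    noise_lc_mut_rate: float = 0.03
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("kappa_probability", "apoptosis_fraction", "lc_rate_multiplier",
                     "noise_junction_sub_rate", "noise_lc_mut_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.mutation_rate < 1.0:
            raise ConfigurationError("mutation_rate must be in (0, 1)")
        if any(w <= 0 for w in self.mutation_type_weights):
            raise ConfigurationError("mutation_type_weights must be positive")
        for name in ("hc_junction_indels", "lc_junction_indels"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ConfigurationError(f"{name} must be a non-negative range")
        if self.initial_cells < 1:
            raise ConfigurationError("initial_cells must be >= 1")
        if self.n_rounds < 0:
            raise ConfigurationError("n_rounds must be >= 0")
        if self.n_noise < 0 or self.n_chain_mixed < 0:
            raise ConfigurationError("noise counts must be >= 0")
        if self.hc_window < 0 or self.lc_window < 0:
            raise ConfigurationError("mutation windows must be >= 0")
        if self.apoptosis_mode not in ("deterministic", "bernoulli"):
            raise ConfigurationError("apoptosis_mode must be deterministic|bernoulli")
        for base, row in self.substitution_matrix.items():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"substitution row for {base} must sum to 1")
            if base in row:
                raise ConfigurationError(f"substitution row for {base} maps to itself")

    @property
    def mutation_type_probs(self) -> np.ndarray:
        w = np.asarray(self.mutation_type_weights, dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class MutationEvent:
    """One SHM event at a 0-based offset in the pre-mutation sequence."""

    kind: str
    position: int
    detail: object  # inserted base / deleted base / (from, to)


def derive_rng(seed: int, stage: str) -> np.random.Generator:
    """Stage-keyed substream of a single global seed.

    Adding a pipeline stage never perturbs the draws of earlier stages.
    """
    import zlib

    return np.random.default_rng([int(seed), zlib.crc32(stage.encode("utf-8"))])


# ---------------------------------------------------------------------------
# ancestor assembly


def _draw_indel_count(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    lo, hi = bounds
    return int(rng.integers(lo, hi + 1))


def cdr3_span_nt(record: ChainRecord) -> tuple[int, int]:
    """CDR3 span as a 0-based half-open nt interval.

    Defined as the region strictly between the V end and the J start,
    extended one codon into each flank (so the junction carries the
    conserved V-end Cys and J-start Trp codons when present).
    """
    v_end0 = record.v_sequence_end - 1
    j_start0 = record.j_sequence_start - 1
    return max(0, v_end0 - 2), min(len(record.sequence_nt), j_start0 + 3)


def _set_junction(record: ChainRecord) -> None:
    start, end = cdr3_span_nt(record)
    record.junction_nt = record.sequence_nt[start:end]
    record.junction_aa = translate_nt(record.junction_nt)


def assemble_heavy_ancestor(
    germline: GermlineSet, config: SimulationConfig, rng: np.random.Generator
) -> ChainRecord:
    """Assemble a heavy-chain ancestor: random V+D+J with junctional indels.

    1-3 single-nucleotide indels are introduced independently at the V-D
    and D-J junctions; deletions trim the D segment so the V 3' and J 5'
    anchors (and hence v_sequence_end / j_sequence_start) stay intact.
    """
    v = germline.get("IGH", "V")[rng.integers(len(germline.get("IGH", "V")))]
    d = germline.get("IGH", "D")[rng.integers(len(germline.get("IGH", "D")))]
    j = germline.get("IGH", "J")[rng.integers(len(germline.get("IGH", "J")))]

    d_seq = d.nt_sequence
    n_vd = _draw_indel_count(rng, config.hc_junction_indels)
    insert_vd = ""
    for _ in range(n_vd):
        if rng.random() < 0.5 or not d_seq:
            insert_vd += BASES[rng.integers(4)]
        else:
            d_seq = d_seq[1:]
    n_dj = _draw_indel_count(rng, config.hc_junction_indels)
    insert_dj = ""
    for _ in range(n_dj):
        if rng.random() < 0.5 or not d_seq:
            insert_dj += BASES[rng.integers(4)]
        else:
            d_seq = d_seq[:-1]

    mid = insert_vd + d_seq + insert_dj
    seq = v.nt_sequence + mid + j.nt_sequence
    rec = ChainRecord(
        sequence_id="ancestor",
        locus="IGH",
        v_call=v.name,
        d_call=d.name,
        j_call=j.name,
        junction_aa="",
        sequence_nt=seq,
        shm_count=0,
        v_sequence_end=len(v.nt_sequence),
        j_sequence_start=len(v.nt_sequence) + len(mid) + 1,
        extra={"vd_indels": n_vd, "dj_indels": n_dj},
    )
    _set_junction(rec)
    return rec


def assemble_light_ancestor(
    germline: GermlineSet, config: SimulationConfig, rng: np.random.Generator
) -> ChainRecord:
    """Assemble a light-chain ancestor: kappa with probability 0.60, else lambda."""
    locus = "IGK" if rng.random() < config.kappa_probability else "IGL"
    v = germline.get(locus, "V")[rng.integers(len(germline.get(locus, "V")))]
    j = germline.get(locus, "J")[rng.integers(len(germline.get(locus, "J")))]

    j_seq = j.nt_sequence
    n = _draw_indel_count(rng, config.lc_junction_indels)
    mid = ""
    for _ in range(n):
        if rng.random() < 0.5 or len(j_seq) <= 1:
            mid += BASES[rng.integers(4)]
        else:
            j_seq = j_seq[1:]

    seq = v.nt_sequence + mid + j_seq
    rec = ChainRecord(
        sequence_id="ancestor",
        locus=locus,
        v_call=v.name,
        j_call=j.name,
        junction_aa="",
        sequence_nt=seq,
        shm_count=0,
        v_sequence_end=len(v.nt_sequence),
        j_sequence_start=len(v.nt_sequence) + len(mid) + 1,
        extra={"vj_indels": n},
    )
    _set_junction(rec)
    return rec


# ---------------------------------------------------------------------------
# somatic hypermutation


def draw_mutation_types(
    n: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw n mutation-kind indices (0=insertion, 1=deletion, 2=substitution)."""
    return rng.choice(3, size=n, p=config.mutation_type_probs)


def mutate_once(
    sequence_nt: str,
    cdr3_span: tuple[int, int],
    window: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    rate: Optional[float] = None,
) -> tuple[str, list[MutationEvent]]:
    """One SHM round over the CDR3 window of a sequence.

    Every position inside ``[cdr3_start - window, cdr3_end + window)``
    mutates independently with probability ``rate`` (default the configured
    mutation rate); positions outside the window never mutate.  Events are
    returned in position order with pre-mutation coordinates.
    """
    mu = config.mutation_rate if rate is None else rate
    if not 0.0 <= mu < 1.0:
        raise ConfigurationError(f"mutation rate must be in [0, 1), got {mu}")
    start, end = cdr3_span
    lo = max(0, start - window)
    hi = min(len(sequence_nt), end + window)
    if mu == 0.0 or hi <= lo:
        return sequence_nt, []

    hits = np.flatnonzero(rng.random(hi - lo) < mu) + lo
    if hits.size == 0:
        return sequence_nt, []
    kinds = draw_mutation_types(hits.size, config, rng)

    events: list[MutationEvent] = []
    pieces: list[str] = []
    prev = 0
    for pos, kind_idx in zip(hits.tolist(), kinds.tolist()):
        kind = MUTATION_KINDS[kind_idx]
        pieces.append(sequence_nt[prev:pos])
        base = sequence_nt[pos]
        if kind == "substitution":
            row = config.substitution_matrix.get(base)
            if row is None:  # non-ACGT position: leave unchanged
                pieces.append(base)
                prev = pos + 1
                continue
            targets = sorted(row)
            new = rng.choice(targets, p=[row[t] for t in targets])
            pieces.append(str(new))
            events.append(MutationEvent("substitution", pos, (base, str(new))))
            prev = pos + 1
        elif kind == "deletion":
            events.append(MutationEvent("deletion", pos, base))
            prev = pos + 1
        else:  # insertion before this position
            ins = BASES[rng.integers(4)]
            pieces.append(ins)
            events.append(MutationEvent("insertion", pos, ins))
            prev = pos
    pieces.append(sequence_nt[prev:])
    return "".join(pieces), events


def _shift_coords(
    events: Sequence[MutationEvent], v_end0: int, j_start0: int
) -> tuple[int, int]:
    """Map V-end / J-start 0-based coordinates through a set of SHM events."""
    dv = dj = 0
    for ev in events:
        if ev.kind == "insertion":
            if ev.position <= v_end0:
                dv += 1
            if ev.position <= j_start0:
                dj += 1
        elif ev.kind == "deletion":
            if ev.position <= v_end0:
                dv -= 1
            if ev.position < j_start0:
                dj -= 1
    v_new = v_end0 + dv
    j_new = max(j_start0 + dj, v_new + 1)
    return v_new, j_new


def _mutate_chain(
    rec: ChainRecord,
    window: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    rate: Optional[float] = None,
) -> ChainRecord:
    new = copy.copy(rec)
    new.extra = dict(rec.extra)
    span = cdr3_span_nt(rec)
    seq, events = mutate_once(rec.sequence_nt, span, window, config, rng, rate=rate)
    if events:
        v_end0, j_start0 = _shift_coords(
            events, rec.v_sequence_end - 1, rec.j_sequence_start - 1
        )
        v_end0 = max(v_end0, 2)
        j_start0 = min(max(j_start0, v_end0 + 1), len(seq) - 1)
        new.sequence_nt = seq
        new.v_sequence_end = v_end0 + 1
        new.j_sequence_start = j_start0 + 1
        _set_junction(new)
        new.shm_count = (rec.shm_count or 0) + len(events)
    return new


# ---------------------------------------------------------------------------
# clonal expansion


def _copy_cell(
    cell: PairedCell, cell_id: str, clone_id: Optional[str], sample_id: str = ""
) -> PairedCell:
    heavy = copy.copy(cell.heavy)
    light = copy.copy(cell.light)
    heavy.extra = dict(cell.heavy.extra)
    light.extra = dict(cell.light.extra)
    for rec, suffix in ((heavy, "H"), (light, "L")):
        rec.sequence_id = f"{cell_id}_{suffix}"
        rec.cell_id = cell_id
        rec.true_clone_id = clone_id
        if sample_id:
            rec.sample_id = sample_id
    return PairedCell(cell_id, heavy, light)


def expand_family(
    ancestor_pair: PairedCell,
    config: SimulationConfig,
    rng: np.random.Generator,
    stats_out: Optional[list] = None,
) -> list[PairedCell]:
    """Grow one clonal family from an ancestral paired cell.

    Generation 1 is ``initial_cells`` unmutated copies of the ancestor.
    Each round, every surviving member spawns ``expansion_factor`` offspring
    whose heavy and light chains are mutated independently (light chains
    with the smaller window and the reduced rate), then a fraction
    ``apoptosis_fraction`` of the new variants is discarded uniformly at
    random.  The returned family is the ancestor plus all survivors; each
    member's shm_count accumulates down its lineage.

    ``stats_out``, when given, receives one ``(n_new, n_discarded)`` tuple
    per round.
    """
    clone = ancestor_pair.heavy.true_clone_id or "clone"
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{clone}_s{counter}"

    population = [
        _copy_cell(ancestor_pair, next_id(), clone) for _ in range(config.initial_cells)
    ]
    lc_rate = config.mutation_rate * config.lc_rate_multiplier

    for _ in range(config.n_rounds):
        new: list[PairedCell] = []
        for parent in population:
            for _ in range(config.expansion_factor):
                cid = next_id()
                heavy = _mutate_chain(parent.heavy, config.hc_window, config, rng)
                light = _mutate_chain(
                    parent.light, config.lc_window, config, rng, rate=lc_rate
                )
                heavy.sequence_id, heavy.cell_id, heavy.true_clone_id = (
                    f"{cid}_H", cid, clone)
                light.sequence_id, light.cell_id, light.true_clone_id = (
                    f"{cid}_L", cid, clone)
                new.append(PairedCell(cid, heavy, light))
        if config.apoptosis_mode == "deterministic":
            n_discard = round(config.apoptosis_fraction * len(new))
            discard = set(rng.choice(len(new), size=n_discard, replace=False).tolist())
        else:
            mask = rng.random(len(new)) < config.apoptosis_fraction
            discard = set(np.flatnonzero(mask).tolist())
            n_discard = len(discard)
        if stats_out is not None:
            stats_out.append((len(new), n_discard))
        population.extend(c for i, c in enumerate(new) if i not in discard)

    members = []
    if config.emit_ancestor:
        members.append(_copy_cell(ancestor_pair, f"{clone}_s0", clone))
    members.extend(population)
    return members


# ---------------------------------------------------------------------------
# noise and fixtures


def _randomize_mid(mid: str, config: SimulationConfig, rng: np.random.Generator) -> str:
    chars = list(mid)
    for i, base in enumerate(chars):
        if rng.random() < config.noise_junction_sub_rate:
            alternatives = [b for b in BASES if b != base]
            chars[i] = alternatives[rng.integers(3)]
    for _ in range(int(rng.integers(0, 4))):  # 0-3 indels
        if rng.random() < 0.5 or not chars:
            chars.insert(int(rng.integers(0, len(chars) + 1)), BASES[rng.integers(4)])
        else:
            chars.pop(int(rng.integers(0, len(chars))))
    return "".join(chars)


def generate_noise(
    families: Sequence[PairedCell],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[PairedCell]:
    """Junction-randomized noise cells sharing V/J annotations with families.

    Each noise heavy chain copies a random family member's V/J calls and
    flanking regions but carries a heavily randomized junction; each noise
    light chain is a fresh V-J rearrangement with elevated point mutation
    across the whole chain.  All noise cells are labeled "noise".
    """
    if config.n_noise and not families:
        raise ConfigurationError("noise generation requires >=1 template family")
    germline = None
    out: list[PairedCell] = []
    for i in range(config.n_noise):
        template = families[rng.integers(len(families))]
        th = template.heavy
        v_end0 = th.v_sequence_end - 1
        j_start0 = th.j_sequence_start - 1
        mid = _randomize_mid(th.sequence_nt[v_end0 + 1 : j_start0], config, rng)
        seq = th.sequence_nt[: v_end0 + 1] + mid + th.sequence_nt[j_start0:]
        heavy = ChainRecord(
            sequence_id=f"noise{i}_H",
            locus="IGH",
            v_call=th.v_call,
            d_call=th.d_call,
            j_call=th.j_call,
            junction_aa="",
            sequence_nt=seq,
            shm_count=0,
            v_sequence_end=v_end0 + 1,
            j_sequence_start=v_end0 + 1 + len(mid) + 1,
            sample_id=th.sample_id,
            true_clone_id=NOISE_LABEL,
            extra={"template": template.cell_id,
                   "template_junction_aa": th.junction_aa},
        )
        _set_junction(heavy)

        if germline is None:
            from .io import load_default_germline

            germline = generate_noise.germline or load_default_germline()
        light = assemble_light_ancestor(germline, config, rng)
        light, _ = _noisify_light(light, config, rng)
        light.sequence_id = f"noise{i}_L"
        light.sample_id = th.sample_id
        light.true_clone_id = NOISE_LABEL

        cid = f"noise{i}"
        heavy.cell_id = light.cell_id = cid
        out.append(PairedCell(cid, heavy, light))
    return out


generate_noise.germline = None  # injection point for custom germline sets


def _noisify_light(
    light: ChainRecord, config: SimulationConfig, rng: np.random.Generator
) -> tuple[ChainRecord, int]:
    """Elevated point mutations across the whole light chain (V and J)."""
    noisy = _mutate_chain(
        light, window=len(light.sequence_nt), config=config, rng=rng,
        rate=config.noise_lc_mut_rate,
    )
    return noisy, (noisy.shm_count or 0)


def generate_chain_mixed(
    families: Sequence[PairedCell],
    n: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    germline: Optional[GermlineSet] = None,
) -> list[PairedCell]:
    """Chain-mixed noise: near-copy heavy chains paired with fresh light chains.

    These emulate the chain-mixing artifact — similar heavy chains that do
    not descend from the family's ancestor, revealed only by their divergent
    light chains.  Labeled "noise" in the ground truth.
    """
    if n and not families:
        raise ConfigurationError("chain-mixed generation requires >=1 template family")
    if germline is None and n:
        from .io import load_default_germline

        germline = load_default_germline()
    out: list[PairedCell] = []
    for i in range(n):
        template = families[rng.integers(len(families))]
        heavy = copy.copy(template.heavy)
        heavy.extra = dict(template.heavy.extra)
        v_end0 = heavy.v_sequence_end - 1
        j_start0 = heavy.j_sequence_start - 1
        chars = list(heavy.sequence_nt[v_end0 + 1 : j_start0])
        for _ in range(int(rng.integers(0, 3))):  # 0-2 junction substitutions
            if not chars:
                break
            pos = int(rng.integers(len(chars)))
            alternatives = [b for b in BASES if b != chars[pos]]
            chars[pos] = alternatives[rng.integers(3)]
        heavy.sequence_nt = (
            heavy.sequence_nt[: v_end0 + 1] + "".join(chars) + heavy.sequence_nt[j_start0:]
        )
        _set_junction(heavy)
        heavy.shm_count = 0
        heavy.true_clone_id = NOISE_LABEL
        heavy.extra["noise_kind"] = "chain_mixed"

        light = assemble_light_ancestor(germline, config, rng)
        light.true_clone_id = NOISE_LABEL
        light.sample_id = heavy.sample_id

        cid = f"mix{i}"
        heavy.sequence_id, light.sequence_id = f"{cid}_H", f"{cid}_L"
        heavy.cell_id = light.cell_id = cid
        out.append(PairedCell(cid, heavy, light))
    return out


def generate_public_fixture(
    n_samples: int,
    n_public_clones: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    germline: Optional[GermlineSet] = None,
    members_per_sample: int = 5,
    n_shared_samples: Optional[int] = None,
    background_families: int = 1,
) -> list[Repertoire]:
    """Multi-sample repertoires seeded with low-SHM public pseudo-clones.

    Each public clone is one ancestral pair replicated (shm_count <= 1)
    across ``n_shared_samples`` samples — convergent, near-identical heavy
    and light chains that recur across individuals.  Background clonal
    families are simulated independently per sample.
    """
    if n_samples < 2:
        raise ConfigurationError("public fixture requires n_samples >= 2")
    if germline is None:
        from .io import load_default_germline

        germline = load_default_germline()
    shared = n_shared_samples if n_shared_samples is not None else n_samples
    shared = min(shared, n_samples)

    public_pairs = []
    for p in range(n_public_clones):
        heavy = assemble_heavy_ancestor(germline, config, rng)
        light = assemble_light_ancestor(germline, config, rng)
        heavy.cell_id = light.cell_id = f"pubanc{p}"
        heavy.true_clone_id = light.true_clone_id = f"public{p}"
        public_pairs.append(PairedCell(f"pubanc{p}", heavy, light))

    reps: list[Repertoire] = []
    for s in range(n_samples):
        sample = f"S{s}"
        cells: list[PairedCell] = []
        for f in range(background_families):
            heavy = assemble_heavy_ancestor(germline, config, rng)
            light = assemble_light_ancestor(germline, config, rng)
            cid = f"{sample}_fam{f}_anc"
            heavy.cell_id = light.cell_id = cid
            heavy.true_clone_id = light.true_clone_id = f"{sample}_fam{f}"
            family = expand_family(PairedCell(cid, heavy, light), config, rng)
            for cell in family:
                cell.heavy.sample_id = cell.light.sample_id = sample
            cells.extend(family)
        for p, pub in enumerate(public_pairs):
            if s >= shared:
                continue
            for m in range(members_per_sample):
                cell = _copy_cell(pub, f"{sample}_pub{p}_{m}", f"public{p}", sample)
                n_sub = int(rng.integers(0, 2))  # 0 or 1 point mutation
                if n_sub:
                    cell = PairedCell(
                        cell.cell_id,
                        _mutate_single_substitution(cell.heavy, rng),
                        cell.light,
                    )
                cells.append(cell)
        reps.append(
            Repertoire(
                sample,
                cells=cells,
                metadata={
                    "public_fixture": True,
                    "public_clone_ids": [f"public{p}" for p in range(n_public_clones)],
                    "n_shared_samples": shared,
                },
            )
        )
    return reps


def _mutate_single_substitution(
    rec: ChainRecord, rng: np.random.Generator
) -> ChainRecord:
    new = copy.copy(rec)
    new.extra = dict(rec.extra)
    start, end = cdr3_span_nt(rec)
    pos = int(rng.integers(start, end))
    base = rec.sequence_nt[pos]
    alternatives = [b for b in BASES if b != base]
    new.sequence_nt = (
        rec.sequence_nt[:pos] + alternatives[rng.integers(3)] + rec.sequence_nt[pos + 1 :]
    )
    _set_junction(new)
    new.shm_count = (rec.shm_count or 0) + 1
    return new


# ---------------------------------------------------------------------------
# benchmark assembly


def _pair_aa(cell: PairedCell) -> tuple[str, str]:
    return translate_nt(cell.heavy.sequence_nt), translate_nt(cell.light.sequence_nt)


def simulate_benchmark(
    config: SimulationConfig,
    germline: Optional[GermlineSet] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Repertoire, dict[str, str]]:
    """Simulate a full labeled benchmark: clonal families plus noise.

    Families are expanded from independent ancestors, junction-randomized
    noise and (optionally) chain-mixed cells are appended, and identical
    amino-acid heavy/light pairs within the sample are collapsed to one
    representative.  Returns the paired repertoire and the ground-truth
    labels keyed by heavy-chain sequence_id ("noise" for non-family cells).
    """
    if germline is None:
        from .io import load_default_germline

        germline = load_default_germline()
    germline.validate_for_simulation()
    if rng is None:
        rng = derive_rng(config.rng_seed, "benchmark")

    cells: list[PairedCell] = []
    for f in range(config.n_families):
        heavy = assemble_heavy_ancestor(germline, config, rng)
        light = assemble_light_ancestor(germline, config, rng)
        cid = f"fam{f}_anc"
        heavy.cell_id = light.cell_id = cid
        heavy.true_clone_id = light.true_clone_id = f"fam{f}"
        cells.extend(expand_family(PairedCell(cid, heavy, light), config, rng))

    family_cells = list(cells)
    old_germline = generate_noise.germline
    generate_noise.germline = germline
    try:
        cells.extend(generate_noise(family_cells, config, rng))
    finally:
        generate_noise.germline = old_germline
    cells.extend(
        generate_chain_mixed(family_cells, config.n_chain_mixed, config, rng, germline)
    )

    seen: set[tuple[str, str]] = set()
    kept: list[PairedCell] = []
    for cell in cells:
        key = _pair_aa(cell)
        if key in seen:
            continue
        seen.add(key)
        cell.heavy.sample_id = cell.light.sample_id = "sim"
        kept.append(cell)

    repertoire = Repertoire(
        "sim",
        cells=kept,
        metadata={"n_families": config.n_families,
                  "n_collapsed": len(cells) - len(kept)},
    )
    truth = {cell.heavy.sequence_id: cell.heavy.true_clone_id for cell in kept}
    return repertoire, truth
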