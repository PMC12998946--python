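"""Domain types for paired-chain B-cell receptor repertoires.

A repertoire is a collection of annotated immunoglobulin chains.  Heavy
chains come from the IGH locus (V-D-J rearrangement); light chains from
IGK (kappa) or IGL (lambda) (V-J rearrangement).  In paired (single-cell)
data a heavy and a light chain are linked through a shared ``cell_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)
from typing import Iterator, Optional

LOCI = ("IGH", "IGK", "IGL")
SEGMENT_CLASSES = ("V", "D", "J")
CELL_SUBTYPES = ("naive", "memory", "plasma", "unsorted", "unknown")
NOISE_LABEL = "noise"


class FormatError(ValueError):
    """Malformed input file or record."""


class ConfigurationError(ValueError):
    """Invalid configuration value."""


class StateError(RuntimeError):
    """Operation called in an invalid state (e.g. scoring before fitting)."""


def strip_allele(call: str) -> str:
    """Drop the allele designation from a gene call (IGHV3-23*04 -> IGHV3-23).

    Idempotent: stripping an already-stripped call is a no-op.
    """
    if not call:
        return ""
    return call.split("*", 1)[0].strip()


@dataclass(frozen=True)
class GermlineSegment:
    """One germline gene segment (major allele only)."""

    name: str
    locus: str
    segment_class: str
    nt_sequence: str

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise ConfigurationError(f"unknown locus {self.locus!r}")
        if self.segment_class not in SEGMENT_CLASSES:
            raise ConfigurationError(f"unknown segment class {self.segment_class!r}")
        if self.segment_class == "D" and self.locus != "IGH":
            raise ConfigurationError("D segments exist only for locus IGH")
        if not self.nt_sequence:
            raise ConfigurationError(f"segment {self.name!r} has empty sequence")
        bad = set(self.nt_sequence) - set("ACGT")
        if bad:
            raise ConfigurationError(
                f"segment {self.name!r} contains non-ACGT characters {sorted(bad)}"
            )


class GermlineSet:
    """Germline segments indexed by (locus, segment_class)."""

    #: (locus, class) pairs the simulator draws from
    REQUIRED = (
        ("IGH", "V"), ("IGH", "D"), ("IGH", "J"),
        ("IGK", "V"), ("IGK", "J"),
        ("IGL", "V"), ("IGL", "J"),
    )

    def __init__(self, segments: Optional[list[GermlineSegment]] = None) -> None:
        self._index: dict[tuple[str, str], list[GermlineSegment]] = {}
        self._names: set[tuple[str, str, str]] = set()
        for seg in segments or []:
            self.add(seg)

    def add(self, segment: GermlineSegment) -> None:
        key = (segment.locus, segment.segment_class, segment.name)
        if key in self._names:
            raise ConfigurationError(
                f"duplicate segment name {segment.name!r} for "
                f"{segment.locus}/{segment.segment_class}"
            )
        self._names.add(key)
        self._index.setdefault((segment.locus, segment.segment_class), []).append(segment)

    def get(self, locus: str, segment_class: str) -> list[GermlineSegment]:
        segs = self._index.get((locus, segment_class), [])
        if not segs:
            raise ConfigurationError(
                f"germline set has no {locus} {segment_class} segments"
            )
        return segs

    def validate_for_simulation(self) -> None:
        for locus, cls in self.REQUIRED:
            self.get(locus, cls)

    def __len__(self) -> int:
        return sum(len(v) for v in self._index.values())


@dataclass
class ChainRecord:
    """One annotated heavy or light chain.

    Coordinates ``v_sequence_end`` / ``j_sequence_start`` are 1-based
    inclusive positions into ``sequence_nt`` (AIRR convention).
    """

    sequence_id: str
    locus: str
    v_call: str
    j_call: str
    junction_aa: str
    d_call: str = ""
    junction_nt: str = ""
    sequence_nt: Optional[str] = None
    cdr1_aa: Optional[str] = None
    cdr2_aa: Optional[str] = None
    shm_count: Optional[int] = None
    v_sequence_end: Optional[int] = None
    j_sequence_start: Optional[int] = None
    sample_id: str = ""
    donor_id: str = ""
    cell_id: str = ""
    cell_subtype: str = "unknown"
    true_clone_id: Optional[str] = None
    clone_id: Optional[str] = None  # inferred cluster label, filled downstream
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise FormatError(
                f"record {self.sequence_id!r}: unknown locus {self.locus!r}"
            )
        if self.v_call and not self.v_call.startswith(self.locus):
            raise FormatError(
                f"record {self.sequence_id!r}: v_call {self.v_call!r} "
                f"inconsistent with locus {self.locus}"
            )
        if (
            self.v_sequence_end is not None
            and self.j_sequence_start is not None
            and not self.v_sequence_end < self.j_sequence_start
        ):
            raise FormatError(
                f"record {self.sequence_id!r}: v_sequence_end must precede "
                "j_sequence_start"
            )
        if self.shm_count is not None and self.shm_count < 0:
            raise FormatError(f"record {self.sequence_id!r}: negative shm_count")

    @property
    def is_heavy(self) -> bool:
        return self.locus == "IGH"


@dataclass
class PairedCell:
    """A heavy chain linked to a light chain through a cell identifier."""

    cell_id: str
    heavy: ChainRecord
    light: ChainRecord

    def __post_init__(self) -> None:
        if self.heavy.locus != "IGH":
            raise FormatError(f"cell {self.cell_id!r}: heavy slot holds {self.heavy.locus}")
        if self.light.locus not in ("IGK", "IGL"):
            raise FormatError(f"cell {self.cell_id!r}: light slot holds {self.light.locus}")
        if not (self.heavy.cell_id == self.light.cell_id == self.cell_id):
            raise FormatError(f"cell {self.cell_id!r}: member cell_id mismatch")


class Repertoire:
    """A sample's worth of records, in paired or single-chain mode."""

    def __init__(
        self,
        sample_id: str,
        cells: Optional[list[PairedCell]] = None,
        chains: Optional[list[ChainRecord]] = None,
        metadata: Optional[dict] = None,
    ) -> None:
        if (cells is None) == (chains is None):
            raise ConfigurationError("provide exactly one of cells= or chains=")
        self.sample_id = sample_id
        self.cells = cells
        self.chains = chains
        self.metadata = metadata or {}
        ids = [r.sequence_id for r in self.all_chains()]
        if len(ids) != len(set(ids)):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise FormatError(f"duplicate sequence_id values: {sorted(dups)[:5]}")

    @property
    def paired(self) -> bool:
        return self.cells is not None

    def all_chains(self) -> Iterator[ChainRecord]:
        if self.paired:
            for cell in self.cells:
                yield cell.heavy
                yield cell.light
        else:
            yield from self.chains

    def heavy_chains(self) -> list[ChainRecord]:
        if self.paired:
            return [c.heavy for c in self.cells]
        return [r for r in self.chains if r.is_heavy]

    def cell_by_heavy_id(self) -> dict[str, PairedCell]:
        if not self.paired:
            raise StateError("repertoire is not in paired mode")
        return {c.heavy.sequence_id: c for c in self.cells}

    def __len__(self) -> int:
        return len(self.cells) if self.paired else len(self.chains)
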