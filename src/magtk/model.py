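"""Core domain types.

The toolkit is organised around a handful of small records:

* :class:`ContigRecord` — an assembled contig, optionally with sequence and
  parent bin.
* :class:`SampleMeta` — one sequencing sample: its layer role (active layer
  ``AL`` or permafrost layer ``PL``), depth below surface, and the total
  number of reads mapped in that sample (the denominator of the per-million
  scaling factor).
* :class:`GeneAnnotation` — one predicted gene and its (optional) KEGG
  Orthology assignment.
* :class:`ModuleDefinition` — a KEGG Module treated as a plain set of KOs.
* :class:`MagRecord` — a named contig set (a bin / MAG).
* :class:`CoverageMatrix` — contig × sample coverage values with an explicit
  raw/normalized state so the per-million scaling cannot be applied twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, StateError

#: Taxonomic ranks handled by the toolkit, highest first.  Kaiju's domain
#: level is dropped at read time; species is terminal.
RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus", "species")

#: One-letter rank identifiers used when synthesizing NA labels and when
#: naming per-rank FASTA subsets.
RANK_LETTERS: dict[str, str] = {
    "phylum": "P",
    "class": "C",
    "order": "O",
    "family": "F",
    "genus": "G",
    "species": "S",
}

NA_TOKEN = "NA"


@dataclass
class ContigRecord:
    contig_id: str
    length_bp: int
    sequence: str | None = None
    bin_id: str | None = None

    def __post_init__(self) -> None:
        if not self.contig_id or any(c.isspace() for c in self.contig_id):
            raise InputError(f"invalid contig id {self.contig_id!r}")
        if self.length_bp <= 0:
            raise InputError(f"contig {self.contig_id}: non-positive length")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise InputError(
                f"contig {self.contig_id}: length_bp={self.length_bp} does not "
                f"match sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    role: str  # "AL" or "PL"
    depth_cm: float
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.role not in ("AL", "PL"):
            raise InputError(
                f"sample {self.sample_id}: role must be AL or PL, got {self.role!r}"
            )
        if self.depth_cm < 0:
            raise InputError(f"sample {self.sample_id}: negative depth")
        if self.total_mapped_reads <= 0:
            raise InputError(
                f"sample {self.sample_id}: total_mapped_reads must be positive"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    contig_id: str
    ko_id: str | None = None


@dataclass(frozen=True)
class ModuleDefinition:
    module_id: str
    ko_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.ko_ids:
            raise InputError(f"module {self.module_id}: zero KOs")

    @property
    def size(self) -> int:
        return len(self.ko_ids)


@dataclass
class MagRecord:
    mag_id: str
    contig_ids: set[str]
    taxonomy: tuple[str, ...] | None = None


@dataclass
class CoverageMatrix:
    """Contig × sample coverage table with a raw/normalized state machine.

    ``values`` is a pandas DataFrame indexed by contig id with one column per
    sample id.  The only permitted state transition is raw → normalized (see
    :func:`magtk.coverage.normalize`).
    """

    values: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in ("raw", "normalized"):
            raise StateError(f"unknown coverage state {self.state!r}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (np.isnan(arr).any() or (arr < 0).any()):
            raise InputError("coverage values must be finite and non-negative")

    @property
    def contig_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def order_samples(samples: list[SampleMeta]) -> tuple[SampleMeta, list[SampleMeta]]:
    """Split metadata into the single AL sample and PL samples by depth.

    The grouping scheme assumes one active-layer sample and at least two
    permafrost samples; PL samples are ordered by increasing depth so that
    the index ``i`` of ``PL_Pi`` is stable.
    """
    al = [s for s in samples if s.role == "AL"]
    pl = sorted((s for s in samples if s.role == "PL"), key=lambda s: (s.depth_cm, s.sample_id))
    if len(al) != 1:
        raise InputError(f"exactly one AL sample required, found {len(al)}")
    if len(pl) < 2:
        raise InputError(f"at least two PL samples required, found {len(pl)}")
    return al[0], pl
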