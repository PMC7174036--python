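"""Taxonomy-guided bin decontamination.

Contig classifiers such as Kaiju return ``NA`` for ranks they cannot
resolve, which flattens the taxonomic hierarchy exactly where contamination
must be judged.  The remedy implemented here synthesizes hierarchical
placeholder labels: an ``NA`` at a sub-phylum rank becomes the label of the
rank above joined with ``_NA_`` and the rank letter, and an ``NA`` at phylum
becomes ``P_NA``.  For example,

    Proteobacteria; Alphaproteobacteria; Rhizobiales; NA; NA; Unknown species

propagates to

    Proteobacteria; Alphaproteobacteria; Rhizobiales; Rhizobiales_NA_F;
    Rhizobiales_NA_F_NA_G; Unknown species

so that every contig carries a concrete label at every rank.  Per-bin label
compositions are then computed rank by rank, and any label whose fraction of
the bin exceeds a user-defined threshold (default 0.5) is emitted as a
candidate refined subset.  Completeness/contamination of the candidates is
supplied externally (e.g. by CheckM); :func:`score_refinement` ranks them.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import InputError
from .model import NA_TOKEN, RANK_LETTERS, RANKS, ContigRecord
from . import io as mio


@dataclass(frozen=True)
class BinSubset:
    """One per-rank candidate subset of a bin: the contigs carrying one label."""

    source_bin: str
    rank: str
    label: str
    contig_ids: frozenset[str]
    fraction: float


@dataclass(frozen=True)
class QualityRecord:
    """Externally supplied genome-quality numbers for one candidate subset."""

    subset_name: str
    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        for field_name, v in (("completeness", self.completeness),
                              ("contamination", self.contamination)):
            if not 0.0 <= v <= 100.0:
                raise InputError(
                    f"{self.subset_name}: {field_name} {v} outside [0, 100]"
                )


def propagate_na_labels(raw_lineage: Sequence[str]) -> tuple[str, ...]:
    """Convert a raw lineage with ``NA`` tokens into hierarchical labels.

    Scanning phylum → species, a non-``NA`` entry is kept verbatim; ``NA`` at
    phylum becomes ``P_NA``; ``NA`` at a lower rank becomes the (already
    propagated) label one rank up, joined with ``_NA_`` and that rank's
    letter.  Deterministic, and the identity on NA-free lineages.
    """
    if len(raw_lineage) != len(RANKS):
        raise InputError(
            f"lineage must have {len(RANKS)} ranks, got {len(raw_lineage)}"
        )
    out: list[str] = []
    for i, (rank, value) in enumerate(zip(RANKS, raw_lineage)):
        if value != NA_TOKEN:
            out.append(value)
        elif i == 0:
            out.append(f"{RANK_LETTERS[rank]}_NA")
        else:
            out.append(f"{out[i - 1]}_NA_{RANK_LETTERS[rank]}")
    return tuple(out)


def _label_at(
    contig_id: str,
    lineages: Mapping[str, Sequence[str]],
    rank_index: int,
) -> str:
    try:
        return lineages[contig_id][rank_index]
    except KeyError:
        raise InputError(f"contig {contig_id!r} has no lineage") from None


def rank_composition(
    bin_contigs: Sequence[str],
    lineages: Mapping[str, Sequence[str]],
    rank: str,
    lengths: Mapping[str, int] | None = None,
) -> dict[str, float]:
    """Fraction of the bin carried by each label at one rank.

    By default fractions are per contig count; pass per-contig ``lengths``
    for the optional length-weighted mode.  ``lineages`` must already be
    NA-propagated.
    """
    if rank not in RANKS:
        raise InputError(f"unknown rank {rank!r}")
    if not bin_contigs:
        raise InputError("empty bin")
    idx = RANKS.index(rank)
    if lengths is None:
        counts = Counter(_label_at(c, lineages, idx) for c in bin_contigs)
        total = float(len(bin_contigs))
    else:
        counts: Counter[str] = Counter()
        for c in bin_contigs:
            counts[_label_at(c, lineages, idx)] += lengths[c]
        total = float(sum(counts.values()))
    return {label: n / total for label, n in counts.items()}


def subset_bin(
    bin_contigs: Sequence[str],
    lineages: Mapping[str, Sequence[str]],
    rank: str,
    min_fraction: float = 0.5,
    source_bin: str = "bin",
    lengths: Mapping[str, int] | None = None,
) -> list[BinSubset]:
    """Emit one subset per label whose fraction is strictly above threshold.

    With ``min_fraction == 0`` the subsets partition the bin.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise InputError(f"min_fraction {min_fraction} outside [0, 1]")
    comp = rank_composition(bin_contigs, lineages, rank, lengths=lengths)
    idx = RANKS.index(rank)
    subsets = []
    for label in sorted(comp):
        if comp[label] > min_fraction:
            members = frozenset(
                c for c in bin_contigs if _label_at(c, lineages, idx) == label
            )
            subsets.append(
                BinSubset(
                    source_bin=source_bin,
                    rank=rank,
                    label=label,
                    contig_ids=members,
                    fraction=comp[label],
                )
            )
    return subsets


def refine_across_ranks(
    bin_contigs: Sequence[str],
    lineages: Mapping[str, Sequence[str]],
    min_fraction: float = 0.5,
    source_bin: str = "bin",
    lengths: Mapping[str, int] | None = None,
) -> dict[str, list[BinSubset]]:
    """Apply :func:`subset_bin` at every rank, phylum through species."""
    return {
        rank: subset_bin(
            bin_contigs, lineages, rank, min_fraction,
            source_bin=source_bin, lengths=lengths,
        )
        for rank in RANKS
    }


def sanitize_label(label: str) -> str:
    """Make a taxon label safe for file names: non-alphanumerics become '_'."""
    return re.sub(r"[^A-Za-z0-9]+", "_", label).strip("_") or "label"


def write_subsets(
    subsets_by_rank: Mapping[str, Iterable[BinSubset]],
    contigs: Mapping[str, ContigRecord],
    out_dir: str | Path,
) -> list[Path]:
    """Emit each subset as ``<bin>.<rankLetter>.<sanitized label>.fasta``.

    Name collisions after sanitization are resolved with a numeric suffix.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    used: set[str] = set()
    for rank in RANKS:
        for subset in subsets_by_rank.get(rank, []):
            stem = f"{subset.source_bin}.{RANK_LETTERS[rank]}.{sanitize_label(subset.label)}"
            name, k = stem, 1
            while name in used:
                k += 1
                name = f"{stem}.{k}"
            used.add(name)
            records = [contigs[c] for c in sorted(subset.contig_ids)]
            if any(r.sequence is None for r in records):
                continue  # tables-only workflow: nothing to emit
            path = out_dir / f"{name}.fasta"
            try:
                mio.write_fasta(records, path)
            except OSError as exc:
                raise InputError(f"cannot write {path}: {exc}") from exc
            written.append(path)
    return written


def score_refinement(
    quality_records: Sequence[QualityRecord], weight: float = 5.0
) -> list[tuple[QualityRecord, float]]:
    """Rank candidate subsets by completeness − weight × contamination.

    Ties break toward higher completeness, then lexicographic subset name.
    The quality numbers themselves come from an external assessor; this
    toolkit never computes completeness or contamination.
    """
    scored = [
        (rec, rec.completeness - weight * rec.contamination)
        for rec in quality_records
    ]
    scored.sort(key=lambda t: (-t[1], -t[0].completeness, t[0].subset_name))
    return scored
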