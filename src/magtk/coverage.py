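"""TPM-like coverage normalization and MAG relative abundance.

Coverage of a contig is the number of reads mapped to it divided by its
length.  Analogous to TPM normalization of RNA-seq counts, each sample's
coverage column is divided by that sample's "per-million" scaling factor
(total mapped reads / 1e6), making columns comparable across samples of
different sequencing depth.  A sample with 9,171,534 mapped reads has
scaling factor 9.171534.

Relative abundance of a MAG in a sample is the sum of the mapping ratios of
its member contigs (fractions of the sample's read pool).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .errors import InputError, StateError
from .model import CoverageMatrix, SampleMeta

PER_MILLION = 1_000_000.0


def scaling_factor(total_mapped_reads: int) -> float:
    """Per-million scale factor: total mapped reads divided by one million."""
    if total_mapped_reads <= 0:
        raise InputError(
            f"total_mapped_reads must be positive, got {total_mapped_reads}"
        )
    return total_mapped_reads / PER_MILLION


def coverage_from_counts(mapped_reads: int, length_bp: int) -> float:
    """Raw coverage of a contig: mapped reads divided by contig length."""
    if length_bp <= 0:
        raise InputError(f"contig length must be positive, got {length_bp}")
    if mapped_reads < 0:
        raise InputError(f"mapped read count must be non-negative, got {mapped_reads}")
    return mapped_reads / length_bp


def normalize(
    matrix: CoverageMatrix, samples: Sequence[SampleMeta], per_kb: bool = False
) -> CoverageMatrix:
    """Divide each sample column by its per-million scaling factor.

    Only a raw matrix may be normalized (the state machine rejects double
    scaling).  ``per_kb=True`` additionally multiplies by 1000 for users
    whose coverage tables are reads per kilobase rather than reads per base.
    """
    if matrix.state != "raw":
        raise StateError("matrix is already normalized")
    meta = {s.sample_id: s for s in samples}
    missing = [s for s in matrix.sample_ids if s not in meta]
    if missing:
        raise InputError(f"no metadata for sample(s) {missing}")
    factors = pd.Series(
        {s: scaling_factor(meta[s].total_mapped_reads) for s in matrix.sample_ids}
    )
    values = matrix.values.div(factors, axis="columns")
    if per_kb:
        values = values * 1000.0
    return CoverageMatrix(values=values, state="normalized")


def mag_relative_abundance(
    contig_mapping_ratios: pd.DataFrame,
    mag_membership: Mapping[str, str],
) -> pd.DataFrame:
    """Aggregate per-contig mapping ratios into per-MAG relative abundance.

    ``contig_mapping_ratios`` is a contig × sample DataFrame of fractions in
    [0, 1]; ``mag_membership`` maps contig id → MAG id (contigs without a
    MAG are ignored).  Returns a MAG × sample DataFrame; a MAG whose summed
    ratio exceeds 1 signals inconsistent input and raises.
    """
    arr = contig_mapping_ratios.to_numpy(dtype=float)
    if arr.size and ((arr < 0).any() or (arr > 1 + 1e-9).any()):
        raise InputError("mapping ratios must lie in [0, 1]")
    mags = sorted(set(mag_membership.values()))
    out = pd.DataFrame(
        0.0, index=mags, columns=contig_mapping_ratios.columns
    )
    grouped = [
        (mag, [c for c in contig_mapping_ratios.index if mag_membership.get(c) == mag])
        for mag in mags
    ]
    for mag, members in grouped:
        if members:
            out.loc[mag] = contig_mapping_ratios.loc[members].sum(axis=0)
    if (out.to_numpy() > 1 + 1e-9).any():
        bad = out.index[(out > 1 + 1e-9).any(axis=1)][0]
        raise InputError(f"MAG {bad!r}: summed mapping ratio exceeds 1")
    out.index.name = "mag_id"
    return out
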