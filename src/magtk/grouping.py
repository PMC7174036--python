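"""Coverage-pattern group assignment and depth-trend tagging.

Each contig's normalized coverage profile over the single active-layer (AL)
sample and the n ≥ 2 permafrost-layer (PL) samples is binarized against a
global threshold TH — the median of all contig × sample normalized
coverages — with a value counted *present* iff it is ≥ TH.  The presence
pattern then determines exactly one primary group:

======  ==========================================================
LO      absent everywhere (low coverage, filtered)
AL      present in AL only
BO      present in AL and in every PL sample (ubiquitous, "both")
PL_Pi   absent in AL, present in exactly one PL sample (the i-th by depth)
PL_SUB  absent in AL, present in 2..n−1 PL samples
PL_ALL  absent in AL, present in every PL sample
UN      present in AL and in a strict, non-empty subset of PL samples
======  ==========================================================

This seven-way classification is a total partition of presence patterns.
Contigs in PL_ALL or PL_SUB additionally get a depth-trend tag when their
PL coverages correlate with sample depth at Pearson |r| ≥ 0.9: KI
(increasing with depth, r ≥ 0.9) or KD (decreasing, r ≤ −0.9).  A constant
PL profile has undefined correlation and is never tagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError
from .model import CoverageMatrix, SampleMeta, order_samples

PRIMARY_GROUPS = ("AL", "BO", "LO", "PL_SUB", "PL_ALL", "UN")  # plus PL_P1..PL_Pn
TREND_TAGS = ("KI", "KD")
DEFAULT_CORR_THRESHOLD = 0.9


def global_threshold(matrix: CoverageMatrix) -> float:
    """Median over all contig × sample normalized coverage entries."""
    if matrix.state != "normalized":
        raise InputError("global threshold is defined on normalized coverage")
    arr = matrix.values.to_numpy(dtype=float).ravel()
    if arr.size == 0:
        raise InputError("empty coverage matrix")
    return float(np.median(arr))


def assign_primary_group(
    al_value: float, pl_values: np.ndarray | list[float], threshold: float
) -> str:
    """Classify one contig's (AL, PL...) profile into its primary group."""
    pl = np.asarray(pl_values, dtype=float)
    if pl.size < 2:
        raise InputError(f"need at least 2 PL values, got {pl.size}")
    al_present = al_value >= threshold
    pl_present = pl >= threshold
    k = int(pl_present.sum())
    n = pl.size
    if not al_present and k == 0:
        return "LO"
    if al_present and k == 0:
        return "AL"
    if al_present and k == n:
        return "BO"
    if not al_present:
        if k == n:
            return "PL_ALL"
        if k == 1:
            return f"PL_P{int(np.flatnonzero(pl_present)[0]) + 1}"
        return "PL_SUB"
    return "UN"


def pearson(x: np.ndarray | list[float], y: np.ndarray | list[float]) -> float:
    """Product-moment correlation; NaN when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("pearson needs two equal-length vectors of length ≥ 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def assign_trend(
    primary: str,
    pl_values: np.ndarray | list[float],
    depths_cm: np.ndarray | list[float],
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
) -> tuple[str, float]:
    """Depth-trend tag for one contig: KI, KD or '' (with the r used).

    Only PL_ALL / PL_SUB contigs are eligible.  All PL values enter the
    correlation, including sub-threshold ones.  Undefined r (zero variance)
    yields no tag.
    """
    if primary not in ("PL_ALL", "PL_SUB"):
        return "", float("nan")
    r = pearson(pl_values, depths_cm)
    if np.isnan(r):
        return "", r
    if r >= corr_threshold:
        return "KI", r
    if r <= -corr_threshold:
        return "KD", r
    return "", r


def assign_groups(
    matrix: CoverageMatrix,
    samples: list[SampleMeta],
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Assign every contig a primary group and (where eligible) a trend tag.

    Returns a DataFrame indexed by contig id with columns ``primary``,
    ``trend``, ``r``, ``threshold`` and one boolean ``present_<sample>``
    column per sample.  ``threshold`` defaults to the global median of the
    normalized matrix.
    """
    if matrix.state != "normalized":
        raise InputError("group assignment requires a normalized matrix")
    al, pl = order_samples(samples)
    needed = [al.sample_id] + [s.sample_id for s in pl]
    missing = [s for s in needed if s not in matrix.sample_ids]
    if missing:
        raise InputError(f"coverage matrix lacks sample column(s) {missing}")
    th = global_threshold(matrix) if threshold is None else float(threshold)
    depths = np.array([s.depth_cm for s in pl], dtype=float)

    rows = []
    for contig_id, row in matrix.values.iterrows():
        al_value = float(row[al.sample_id])
        pl_values = row[[s.sample_id for s in pl]].to_numpy(dtype=float)
        primary = assign_primary_group(al_value, pl_values, th)
        trend, r = assign_trend(primary, pl_values, depths, corr_threshold)
        rec = {
            "contig_id": contig_id,
            "primary": primary,
            "trend": trend,
            "r": r,
            "threshold": th,
            f"present_{al.sample_id}": al_value >= th,
        }
        for s, v in zip(pl, pl_values):
            rec[f"present_{s.sample_id}"] = v >= th
        rows.append(rec)
    return pd.DataFrame(rows).set_index("contig_id")


def group_summary(assignments: pd.DataFrame) -> pd.DataFrame:
    """Contig counts and fractions per primary group, with KI/KD overlays.

    Primary-group fractions sum to 1 over all classified contigs; the trend
    tags are reported as overlay rows (their contigs are already counted in
    PL_ALL / PL_SUB).
    """
    if assignments.empty:
        raise InputError("no assignments to summarize")
    total = len(assignments)
    rows = []
    for group, n in assignments["primary"].value_counts().sort_index().items():
        rows.append(
            {"group": group, "kind": "primary", "n_contigs": int(n),
             "fraction": n / total}
        )
    for tag in TREND_TAGS:
        n = int((assignments["trend"] == tag).sum())
        rows.append(
            {"group": tag, "kind": "overlay", "n_contigs": n, "fraction": n / total}
        )
    return pd.DataFrame(rows)
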