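"""KEGG-Module abundance in a MAG-centric view.

Each MAG is an independent unit whose contigs carry KO-annotated genes, and
normalized coverage stands in for gene abundance.  Within a MAG, a KO's
weight is the average of the contig weights over all of its gene hits
(multiple hits of the same KO in one MAG are averaged).  A module — treated
as a plain set of KOs — has abundance

    sum of the weights of its KOs present in the MAG  /  module size

so a module with KOs K1..K3 on contigs of weight w1, w2 scores
``(AVG(w1, w2) + w1 + w2) / 3`` when K1 sits on both contigs, K2 on the
first and K3 on the second; a 4-KO module with a single detected KO on the
second contig scores ``w2 / 4``.

Group-level abundance aggregates over the MAGs present in a coverage-pattern
group.  Because a contig's normalized coverage is a per-sample vector, a
*weight policy* reduces it to the scalar contig weight:

``group-mean`` (default)
    mean over the samples whose presence the group requires (AL → the AL
    sample; BO → all samples; PL_ALL / KI / KD → all PL samples; PL_Pi →
    that PL sample; PL_SUB → the contig's supra-threshold PL samples;
    LO / UN → all samples).
``max``
    maximum over all samples.
``per-sample``
    no reduction — one output column per (group, sample).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .model import (
    CoverageMatrix,
    GeneAnnotation,
    MagRecord,
    ModuleDefinition,
    SampleMeta,
    order_samples,
)

logger = logging.getLogger(__name__)

WEIGHT_POLICIES = ("group-mean", "max", "per-sample")


def ko_weights_in_mag(
    mag_contig_ids: Iterable[str],
    annotations: Sequence[GeneAnnotation],
    contig_weights: Mapping[str, float],
    per_hit: bool = True,
) -> dict[str, float]:
    """KO → weight table for one MAG.

    Each annotated gene hit contributes its contig's weight; the KO weight
    is the mean over hits.  With ``per_hit=False`` several hits of one KO on
    the same contig collapse to a single contribution.  Annotations whose
    contig is outside the MAG are skipped with a warning.
    """
    mag_contigs = set(mag_contig_ids)
    hits: dict[str, list[float]] = defaultdict(list)
    seen_pairs: set[tuple[str, str]] = set()
    for ann in annotations:
        if ann.ko_id is None:
            continue
        if ann.contig_id not in mag_contigs:
            logger.warning(
                "gene %s references contig %s outside the MAG; skipped",
                ann.gene_id, ann.contig_id,
            )
            continue
        if ann.contig_id not in contig_weights:
            raise InputError(f"no weight for contig {ann.contig_id!r}")
        if not per_hit:
            pair = (ann.ko_id, ann.contig_id)
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
        hits[ann.ko_id].append(float(contig_weights[ann.contig_id]))
    return {ko: float(np.mean(ws)) for ko, ws in hits.items()}


def module_abundance_in_mag(
    ko_weights: Mapping[str, float], module: ModuleDefinition
) -> float:
    """Sum of present-KO weights divided by module size (absent KOs count 0)."""
    present = [ko_weights[ko] for ko in module.ko_ids if ko in ko_weights]
    return float(sum(present)) / module.size


def _group_members(assignments: pd.DataFrame, group: str) -> pd.Index:
    if group in ("KI", "KD"):
        return assignments.index[assignments["trend"] == group]
    return assignments.index[assignments["primary"] == group]


def _contig_scalar(
    profile: pd.Series,
    group: str,
    al_id: str,
    pl_ids: list[str],
    presence: pd.Series,
) -> float:
    """Reduce a per-sample coverage profile to one scalar (group-mean policy)."""
    if group == "AL":
        return float(profile[al_id])
    if group in ("PL_ALL", "KI", "KD"):
        return float(profile[pl_ids].mean())
    if group.startswith("PL_P"):
        i = int(group[4:]) - 1
        return float(profile[pl_ids[i]])
    if group == "PL_SUB":
        supra = [s for s in pl_ids if bool(presence[f"present_{s}"])]
        if not supra:  # degenerate: fall back to all PL samples
            supra = pl_ids
        return float(profile[supra].mean())
    # BO, LO, UN: mean over every sample
    return float(profile[[al_id] + pl_ids].mean())


def _as_mag_map(mags: Iterable[MagRecord] | Mapping[str, set[str]]) -> dict[str, set[str]]:
    if isinstance(mags, Mapping):
        mag_map = {m: set(cs) for m, cs in mags.items()}
    else:
        mag_map = {m.mag_id: set(m.contig_ids) for m in mags}
    claimed: dict[str, str] = {}
    for mag, cs in mag_map.items():
        for c in cs:
            if c in claimed:
                raise InputError(
                    f"contig {c!r} belongs to both MAG {claimed[c]!r} and {mag!r}"
                )
            claimed[c] = mag
    return mag_map


def module_abundance_by_group(
    assignments: pd.DataFrame,
    mags: Iterable[MagRecord] | Mapping[str, set[str]],
    annotations: Sequence[GeneAnnotation],
    modules: Sequence[ModuleDefinition],
    matrix: CoverageMatrix,
    samples: list[SampleMeta],
    policy: str = "group-mean",
    group_scoped: bool = True,
    per_hit: bool = True,
) -> pd.DataFrame:
    """Module × group abundance matrix.

    For each group, every MAG with ≥ 1 contig assigned to the group is
    "present"; its module abundance is computed from KO weights over its
    group-assigned contigs (``group_scoped=True``, default) or over all of
    its contigs (``group_scoped=False``), each contig reduced to a scalar
    weight by the named policy.  The group value is the sum over present
    MAGs.  Under the ``per-sample`` policy columns are ``<group>:<sample>``.
    """
    if policy not in WEIGHT_POLICIES:
        raise InputError(f"unknown weight policy {policy!r}; known: {WEIGHT_POLICIES}")
    if matrix.state != "normalized":
        raise InputError("module abundance requires normalized coverage")
    al, pl = order_samples(samples)
    al_id, pl_ids = al.sample_id, [s.sample_id for s in pl]
    all_ids = [al_id] + pl_ids
    mag_map = _as_mag_map(mags)
    ann_by_contig: dict[str, list[GeneAnnotation]] = defaultdict(list)
    for a in annotations:
        if a.ko_id is not None:
            ann_by_contig[a.contig_id].append(a)

    groups = sorted(assignments["primary"].unique())
    groups += [t for t in ("KI", "KD") if (assignments["trend"] == t).any()]

    if policy == "per-sample":
        columns = [f"{g}:{s}" for g in groups for s in all_ids]
    else:
        columns = list(groups)
    out = pd.DataFrame(
        0.0, index=[m.module_id for m in modules], columns=columns
    )
    out.index.name = "module_id"

    for group in groups:
        members = set(_group_members(assignments, group))
        for mag_id, mag_contigs in mag_map.items():
            in_group = mag_contigs & members
            if not in_group:
                continue
            eval_contigs = in_group if group_scoped else (mag_contigs & set(assignments.index))
            mag_anns = [a for c in sorted(eval_contigs) for a in ann_by_contig.get(c, [])]
            scalar_columns: list[tuple[str, dict[str, float]]] = []
            if policy == "per-sample":
                for s in all_ids:
                    weights = {
                        c: float(matrix.values.at[c, s]) for c in eval_contigs
                    }
                    scalar_columns.append((f"{group}:{s}", weights))
            else:
                weights = {}
                for c in eval_contigs:
                    profile = matrix.values.loc[c]
                    if policy == "max":
                        weights[c] = float(profile[all_ids].max())
                    else:
                        scope = group if group_scoped else str(
                            assignments.at[c, "primary"]
                        )
                        weights[c] = _contig_scalar(
                            profile, scope, al_id, pl_ids, assignments.loc[c]
                        )
                scalar_columns.append((group, weights))
            for col, weights in scalar_columns:
                kw = ko_weights_in_mag(eval_contigs, mag_anns, weights, per_hit=per_hit)
                for module in modules:
                    out.at[module.module_id, col] += module_abundance_in_mag(kw, module)
    return out


def module_abundance_per_mag(
    mags: Iterable[MagRecord] | Mapping[str, set[str]],
    annotations: Sequence[GeneAnnotation],
    modules: Sequence[ModuleDefinition],
    contig_weights: Mapping[str, float],
    per_hit: bool = True,
) -> pd.DataFrame:
    """Module × MAG abundance for pre-reduced scalar contig weights."""
    mag_map = _as_mag_map(mags)
    ann_by_contig: dict[str, list[GeneAnnotation]] = defaultdict(list)
    for a in annotations:
        if a.ko_id is not None:
            ann_by_contig[a.contig_id].append(a)
    out = pd.DataFrame(
        0.0, index=[m.module_id for m in modules], columns=sorted(mag_map)
    )
    out.index.name = "module_id"
    for mag_id, mag_contigs in mag_map.items():
        usable = {c for c in mag_contigs if c in contig_weights}
        mag_anns = [a for c in sorted(usable) for a in ann_by_contig.get(c, [])]
        kw = ko_weights_in_mag(usable, mag_anns, contig_weights, per_hit=per_hit)
        for module in modules:
            out.at[module.module_id, mag_id] = module_abundance_in_mag(kw, module)
    return out
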