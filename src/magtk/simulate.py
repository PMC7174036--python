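"""Synthetic metagenome communities with machine-readable ground truth.

The generator emulates the external inputs the toolkit consumes — per-bin
contig FASTA, per-contig lineage tables with planted contamination, raw
contig × sample coverage with planted coverage-pattern groups and depth
trends, sample metadata, gene → KO annotations and module definitions — so
that every pipeline stage can be checked against a known truth table with
no downloads.

Coverage profiles are planted on the *normalized* scale in two well
separated strata (a supra-threshold "high" level and a sub-threshold "low"
level, each with bounded multiplicative jitter) and then multiplied by each
sample's per-million scaling factor to produce the emitted raw table.  The
number of sub- and supra-threshold matrix entries is balanced so that the
global median — the grouping threshold — always lands in the gap between
the strata, guaranteeing that the planted presence patterns binarize
exactly.  When a user design is unbalanced, filler BO/LO/UN/PL_SUB contigs
are appended (and recorded in the truth tables) to restore balance; set
``auto_balance=False`` to get a hard error instead.

Depth-trend contigs (KI/KD) receive exactly affine-in-depth PL profiles
(Pearson r = ±1); trend-free PL_ALL/PL_SUB contigs are re-jittered until
|r| ≤ 0.8, keeping a margin below the 0.9 tagging threshold.

Sequences are random nucleotides (content never affects any computation)
and kept short for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .errors import InputError
from .model import (
    NA_TOKEN,
    RANKS,
    ContigRecord,
    CoverageMatrix,
    GeneAnnotation,
    MagRecord,
    ModuleDefinition,
    SampleMeta,
)

#: Planted contig counts per group for the default community.  Chosen so the
#: numbers of sub- and supra-threshold matrix entries balance exactly (no
#: filler contigs) over 1 AL + 4 PL samples, with every group and both depth
#: trends represented.
DEFAULT_GROUP_DESIGN: dict[str, int] = {
    "AL": 6, "BO": 6, "LO": 7, "PL_ALL": 6, "PL_SUB": 6,
    "PL_P1": 2, "PL_P2": 2, "PL_P3": 2, "PL_P4": 2, "UN": 5,
    "KI": 4, "KD": 4,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_mags: int = 3
    depths_cm: tuple[float, ...] = (110.0, 122.0, 135.0, 170.0)
    al_depth_cm: float = 7.0
    group_design: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_DESIGN)
    )
    contamination_fraction: float = 0.2
    n_modules: int = 6
    kos_per_module: int = 4
    genes_per_contig: int = 2
    ko_assignment_prob: float = 0.8
    high_coverage: float = 5.0
    low_coverage: float = 0.05
    noise_scale: float = 0.15
    contig_length_range: tuple[int, int] = (500, 2000)
    total_reads_range: tuple[int, int] = (5_000_000, 20_000_000)
    auto_balance: bool = True
    write_sequences: bool = True

    @property
    def n_pl(self) -> int:
        return len(self.depths_cm)

    def validate(self) -> None:
        if self.n_pl < 2:
            raise InputError("need at least 2 PL samples")
        if not 0.0 <= self.contamination_fraction < 0.5:
            raise InputError("contamination_fraction must be in [0, 0.5)")
        lo_max = self.low_coverage * (1 + self.noise_scale)
        hi_min = self.high_coverage * (1 - self.noise_scale)
        if lo_max >= hi_min:
            raise InputError(
                "unrealizable design: low and high coverage strata overlap "
                f"(low ≤ {lo_max:g} vs high ≥ {hi_min:g}); shrink noise_scale "
                "or separate the levels"
            )
        valid = {"AL", "BO", "LO", "PL_ALL", "PL_SUB", "UN", "KI", "KD"}
        valid |= {f"PL_P{i}" for i in range(1, self.n_pl + 1)}
        for g in self.group_design:
            if g not in valid:
                raise InputError(f"unrealizable design: unknown group {g!r}")
        if any(n < 0 for n in self.group_design.values()):
            raise InputError("unrealizable design: negative contig count")
        if sum(self.group_design.values()) == 0:
            raise InputError("unrealizable design: zero contigs")


@dataclass
class SimulatedCommunity:
    """All in-memory pieces of one synthetic community plus its truth."""

    config: SimulationConfig
    samples: list[SampleMeta]
    contigs: dict[str, ContigRecord]
    mags: list[MagRecord]
    lineages: dict[str, tuple[str, ...]]
    raw_matrix: CoverageMatrix
    normalized_truth: pd.DataFrame  # planted normalized profiles
    annotations: list[GeneAnnotation]
    modules: list[ModuleDefinition]
    truth: pd.DataFrame  # per contig: bin, group, trend, contaminant flag
    paths: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# presence-pattern planning
# ---------------------------------------------------------------------------

def _pattern_for(group: str, n_pl: int, rng: np.random.Generator,
                 sub_size: int | None = None) -> tuple[bool, tuple[bool, ...]]:
    """(AL present, PL presence tuple) realizing one group label."""
    if group == "AL":
        return True, (False,) * n_pl
    if group == "BO":
        return True, (True,) * n_pl
    if group == "LO":
        return False, (False,) * n_pl
    if group in ("PL_ALL", "KI", "KD"):
        return False, (True,) * n_pl
    if group.startswith("PL_P"):
        i = int(group[4:]) - 1
        if not 0 <= i < n_pl:
            raise InputError(f"unrealizable design: {group} with {n_pl} PL samples")
        pl = [False] * n_pl
        pl[i] = True
        return False, tuple(pl)
    if group == "PL_SUB":
        if n_pl < 3:
            raise InputError("unrealizable design: PL_SUB needs ≥ 3 PL samples")
        k = sub_size if sub_size is not None else 2
        idx = rng.choice(n_pl, size=k, replace=False)
        pl = [i in set(idx.tolist()) for i in range(n_pl)]
        return False, tuple(pl)
    if group == "UN":
        if n_pl < 2:
            raise InputError("unrealizable design: UN needs ≥ 2 PL samples")
        k = min(2, n_pl - 1)
        idx = rng.choice(n_pl, size=k, replace=False)
        pl = [i in set(idx.tolist()) for i in range(n_pl)]
        return True, tuple(pl)
    raise InputError(f"unknown group {group!r}")


def _plan_contigs(config: SimulationConfig, rng: np.random.Generator):
    """Expand the group design into one planned record per contig."""
    n_pl = config.n_pl
    plan: list[dict] = []
    sub_sizes = list(range(2, n_pl)) or [2]
    sub_i = 0
    for group in sorted(config.group_design):
        for _ in range(config.group_design[group]):
            sub_size = None
            if group == "PL_SUB":
                sub_size = sub_sizes[sub_i % len(sub_sizes)]
                sub_i += 1
            al_p, pl_p = _pattern_for(group, n_pl, rng, sub_size)
            primary = "PL_ALL" if group in ("KI", "KD") else group
            trend = group if group in ("KI", "KD") else ""
            plan.append(
                {"group": primary, "trend": trend, "al_present": al_p,
                 "pl_present": pl_p, "planted_as": group}
            )
    _balance(plan, config, rng)
    return plan


_FILLERS = ("LO", "BO", "PL_ALL", "AL", "PL_SUB", "UN")


def _balance(plan: list[dict], config: SimulationConfig, rng: np.random.Generator) -> None:
    """Append filler contigs until #present entries == #absent entries."""
    n_pl = config.n_pl

    def delta(al_p: bool, pl_p: Sequence[bool]) -> int:
        p = int(al_p) + sum(pl_p)
        return 2 * p - (n_pl + 1)

    d = sum(delta(c["al_present"], c["pl_present"]) for c in plan)
    if d == 0:
        return
    if not config.auto_balance:
        raise InputError(
            "unrealizable design: sub- and supra-threshold entry counts "
            f"differ by {d}, so the global median cannot be guaranteed to "
            "fall between the coverage strata; enable auto_balance or "
            "adjust the group counts"
        )
    # candidate fillers with their entry-count contributions
    candidates: list[tuple[str, bool, tuple[bool, ...], int]] = []
    for g in _FILLERS:
        if g == "PL_SUB" and n_pl < 3:
            continue
        for size in (range(2, n_pl) if g == "PL_SUB" else [None]):
            al_p, pl_p = _pattern_for(g, n_pl, rng, size)
            candidates.append((g, al_p, pl_p, delta(al_p, pl_p)))
    for _ in range(10 * (abs(d) + 1)):
        if d == 0:
            return
        g, al_p, pl_p, c = min(candidates, key=lambda t: (abs(d + t[3]), t[0]))
        if abs(d + c) >= abs(d):  # no candidate helps: cannot converge
            break
        plan.append(
            {"group": g, "trend": "", "al_present": al_p,
             "pl_present": pl_p, "planted_as": f"{g}(filler)"}
        )
        d += c
    if d != 0:
        raise InputError(
            "unrealizable design: could not balance coverage strata entries"
        )


# ---------------------------------------------------------------------------
# profile generation
# ---------------------------------------------------------------------------

def _jitter(level: float, config: SimulationConfig, rng: np.random.Generator) -> float:
    return level * (1.0 + rng.uniform(-config.noise_scale, config.noise_scale))


def _pl_profile(contig: dict, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Planted normalized PL coverages honouring presence and trend truth."""
    depths = np.asarray(config.depths_cm, dtype=float)
    n_pl = config.n_pl
    hi, lo = config.high_coverage, config.low_coverage
    if contig["trend"] in ("KI", "KD"):
        # exactly affine in depth, r = ±1, all values supra-threshold
        t = (depths - depths.min()) / (depths.max() - depths.min())
        values = hi * (1.0 + t) if contig["trend"] == "KI" else hi * (2.0 - t)
        return values
    for attempt in range(1000):
        if attempt and contig["group"] == "PL_SUB":
            # a depth-monotone presence subset is inherently correlated with
            # depth; re-draw the subset (same size, so balance is unchanged)
            k = sum(contig["pl_present"])
            idx = set(rng.choice(n_pl, size=k, replace=False).tolist())
            contig["pl_present"] = tuple(i in idx for i in range(n_pl))
        values = np.array(
            [_jitter(hi if p else lo, config, rng) for p in contig["pl_present"]]
        )
        if contig["group"] not in ("PL_ALL", "PL_SUB"):
            return values
        # trend-free eligible contigs must stay clearly below the 0.9 tag
        if np.ptp(values) == 0:
            return values
        r = float(np.corrcoef(values, depths)[0, 1])
        if abs(r) <= 0.8:
            return values
    raise InputError("unrealizable design: cannot draw a trend-free PL profile")


RANDOM_BASES = np.array(list("ACGT"))


def build_community(config: SimulationConfig) -> SimulatedCommunity:
    """Construct a synthetic community in memory (no files written)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pl = config.n_pl

    samples = [
        SampleMeta(
            sample_id="AL1", role="AL", depth_cm=config.al_depth_cm,
            total_mapped_reads=int(rng.integers(*config.total_reads_range)),
        )
    ]
    for i, depth in enumerate(config.depths_cm, start=1):
        samples.append(
            SampleMeta(
                sample_id=f"PL{i}", role="PL", depth_cm=float(depth),
                total_mapped_reads=int(rng.integers(*config.total_reads_range)),
            )
        )
    sample_ids = [s.sample_id for s in samples]

    plan = _plan_contigs(config, rng)
    n_contigs = len(plan)

    # normalized-scale profiles
    norm = np.zeros((n_contigs, n_pl + 1))
    for i, contig in enumerate(plan):
        al_level = config.high_coverage if contig["al_present"] else config.low_coverage
        norm[i, 0] = _jitter(al_level, config, rng)
        norm[i, 1:] = _pl_profile(contig, config, rng)

    contig_ids = [f"C{i + 1:04d}" for i in range(n_contigs)]
    # round-robin membership keeps every group represented in every bin
    bin_of = {cid: f"bin{(i % config.n_mags) + 1}" for i, cid in enumerate(contig_ids)}
    bin_ids = sorted({bin_of[c] for c in contig_ids})

    # lineages: one cohesive majority lineage per bin; contaminants carry a
    # foreign lineage with NA at genus/species to exercise label propagation
    majority = {
        b: tuple(f"{rank.capitalize()}_{b}" for rank in RANKS) for b in bin_ids
    }
    foreign = {
        b: tuple(
            [f"X{rank.capitalize()}_{b}" for rank in RANKS[:4]] + [NA_TOKEN, NA_TOKEN]
        )
        for b in bin_ids
    }
    lineages: dict[str, tuple[str, ...]] = {}
    contaminant: dict[str, bool] = {}
    for b in bin_ids:
        members = [c for c in contig_ids if bin_of[c] == b]
        n_cont = int(round(config.contamination_fraction * len(members)))
        n_cont = min(n_cont, max(0, (len(members) - 1) // 2))
        picked = set(
            rng.choice(len(members), size=n_cont, replace=False).tolist()
        ) if n_cont else set()
        for j, c in enumerate(members):
            is_cont = j in picked
            contaminant[c] = is_cont
            lineages[c] = foreign[b] if is_cont else majority[b]

    # sequences
    contigs: dict[str, ContigRecord] = {}
    for cid in contig_ids:
        length = int(rng.integers(*config.contig_length_range))
        seq = (
            "".join(rng.choice(RANDOM_BASES, size=length))
            if config.write_sequences else None
        )
        contigs[cid] = ContigRecord(
            contig_id=cid, length_bp=length, sequence=seq, bin_id=bin_of[cid]
        )

    mags = [
        MagRecord(mag_id=b, contig_ids={c for c in contig_ids if bin_of[c] == b})
        for b in bin_ids
    ]

    # KO / module annotation
    modules = []
    ko_pool: list[str] = []
    ko_counter = 1
    for m in range(1, config.n_modules + 1):
        kos = [f"K{ko_counter + j:05d}" for j in range(config.kos_per_module)]
        ko_counter += config.kos_per_module
        modules.append(ModuleDefinition(module_id=f"M{m:05d}", ko_ids=frozenset(kos)))
        ko_pool.extend(kos)
    annotations: list[GeneAnnotation] = []
    for cid in contig_ids:
        for g in range(1, config.genes_per_contig + 1):
            gene_id = f"{cid}_{g}"
            if rng.uniform() < config.ko_assignment_prob:
                ko = ko_pool[int(rng.integers(len(ko_pool)))]
            else:
                ko = None
            annotations.append(
                GeneAnnotation(gene_id=gene_id, contig_id=cid, ko_id=ko)
            )

    normalized_truth = pd.DataFrame(norm, index=contig_ids, columns=sample_ids)
    normalized_truth.index.name = "contig_id"
    factors = np.array([s.total_mapped_reads / 1e6 for s in samples])
    raw = pd.DataFrame(norm * factors, index=contig_ids, columns=sample_ids)
    raw.index.name = "contig_id"

    truth = pd.DataFrame(
        {
            "contig_id": contig_ids,
            "bin_id": [bin_of[c] for c in contig_ids],
            "group": [p["group"] for p in plan],
            "trend": [p["trend"] for p in plan],
            "planted_as": [p["planted_as"] for p in plan],
            "is_contaminant": [contaminant[c] for c in contig_ids],
        }
    ).set_index("contig_id")

    return SimulatedCommunity(
        config=config,
        samples=samples,
        contigs=contigs,
        mags=mags,
        lineages=lineages,
        raw_matrix=CoverageMatrix(values=raw, state="raw"),
        normalized_truth=normalized_truth,
        annotations=annotations,
        modules=modules,
        truth=truth,
    )


def simulate_community(config: SimulationConfig, out_dir: str | Path) -> SimulatedCommunity:
    """Build a community and write every fixture file plus truth tables."""
    community = build_community(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": out_dir / "samples.tsv",
        "coverage": out_dir / "coverage.tsv",
        "lineages": out_dir / "lineages.tsv",
        "ko": out_dir / "ko.tsv",
        "modules": out_dir / "modules.tsv",
        "mags": out_dir / "mags.tsv",
        "truth_contigs": out_dir / "truth_contigs.tsv",
        "bins_dir": out_dir / "bins",
    }
    mio.write_sample_table(community.samples, paths["samples"])
    mio.write_coverage_table(community.raw_matrix, paths["coverage"])
    mio.write_lineage_table(community.lineages, paths["lineages"], dialect="plain")
    mio.write_ko_table(community.annotations, paths["ko"])
    mio.write_module_definitions(community.modules, paths["modules"])
    mio.write_mag_table(
        {c: m.mag_id for m in community.mags for c in sorted(m.contig_ids)},
        paths["mags"],
    )
    community.truth.to_csv(paths["truth_contigs"], sep="\t")
    if community.config.write_sequences:
        paths["bins_dir"].mkdir(exist_ok=True)
        for mag in community.mags:
            mio.write_fasta(
                [community.contigs[c] for c in sorted(mag.contig_ids)],
                paths["bins_dir"] / f"{mag.mag_id}.fasta",
            )
    community.paths = paths
    return community


def demo_two_contig_bin(
    w1: float = 2.0, w2: float = 4.0
) -> tuple[MagRecord, list[GeneAnnotation], dict[str, float], list[ModuleDefinition]]:
    """The two-contig micro-example used throughout the docs.

    Bin_1 holds contig C1 (genes hitting K1, K2; weight ``w1``) and contig
    C2 (genes hitting K1, K3, K6; weight ``w2``).  Module M1 = {K1, K2, K3};
    module M2 has four KOs of which only K6 is present.  Hence

        abundance(M1) = (AVG(w1, w2) + w1 + w2) / 3
        abundance(M2) = w2 / 4

    — e.g. 3.0 and 1.0 for w1=2, w2=4.
    """
    mag = MagRecord(mag_id="Bin_1", contig_ids={"C1", "C2"})
    annotations = [
        GeneAnnotation("C1_1", "C1", "K1"),
        GeneAnnotation("C1_2", "C1", "K2"),
        GeneAnnotation("C2_1", "C2", "K1"),
        GeneAnnotation("C2_2", "C2", "K3"),
        GeneAnnotation("C2_3", "C2", "K6"),
    ]
    weights = {"C1": float(w1), "C2": float(w2)}
    modules = [
        ModuleDefinition("M1", frozenset({"K1", "K2", "K3"})),
        ModuleDefinition("M2", frozenset({"K4", "K5", "K6", "K7"})),
    ]
    return mag, annotations, weights, modules
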