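import logging

import numpy as np
import pandas as pd
import pytest

from magtk.errors import InputError
from magtk.model import (
    CoverageMatrix,
    GeneAnnotation,
    ModuleDefinition,
    SampleMeta,
)
from magtk.modules import (
    ko_weights_in_mag,
    module_abundance_by_group,
    module_abundance_in_mag,
    module_abundance_per_mag,
)
from magtk.simulate import demo_two_contig_bin

SAMPLES = [
    SampleMeta("AL1", "AL", 7, 1_000_000),
    SampleMeta("PL1", "PL", 110, 1_000_000),
    SampleMeta("PL2", "PL", 122, 1_000_000),
    SampleMeta("PL3", "PL", 135, 1_000_000),
    SampleMeta("PL4", "PL", 170, 1_000_000),
]
SAMPLE_IDS = [s.sample_id for s in SAMPLES]


# ---------------------------------------------------------------------------
# independent brute-force oracle (plain nested loops, no magtk internals)
# ---------------------------------------------------------------------------

def brute_scalar(profile, group, presence_row):
    pl_ids = SAMPLE_IDS[1:]
    if group == "AL":
        return profile["AL1"]
    if group in ("PL_ALL", "KI", "KD"):
        return sum(profile[s] for s in pl_ids) / len(pl_ids)
    if group.startswith("PL_P"):
        return profile[pl_ids[int(group[4:]) - 1]]
    if group == "PL_SUB":
        supra = [s for s in pl_ids if presence_row[f"present_{s}"]]
        supra = supra or pl_ids
        return sum(profile[s] for s in supra) / len(supra)
    return sum(profile[s] for s in SAMPLE_IDS) / len(SAMPLE_IDS)


def brute_module_abundance_by_group(assignments, mags, annotations, modules,
                                    norm_df, policy, group_scoped, per_hit=True):
    groups = sorted(set(assignments["primary"]))
    for tag in ("KI", "KD"):
        if (assignments["trend"] == tag).any():
            groups.append(tag)
    out = {}
    for g in groups:
        for module in modules:
            total = 0.0
            for mag_id, mag_contigs in mags.items():
                if g in ("KI", "KD"):
                    in_group = [c for c in sorted(mag_contigs)
                                if c in assignments.index
                                and assignments.at[c, "trend"] == g]
                else:
                    in_group = [c for c in sorted(mag_contigs)
                                if c in assignments.index
                                and assignments.at[c, "primary"] == g]
                if not in_group:
                    continue
                eval_contigs = in_group if group_scoped else [
                    c for c in sorted(mag_contigs) if c in assignments.index
                ]
                contributions = {}
                for c in eval_contigs:
                    profile = norm_df.loc[c]
                    if policy == "max":
                        w = max(profile[s] for s in SAMPLE_IDS)
                    else:
                        scope = g if group_scoped else assignments.at[c, "primary"]
                        w = brute_scalar(profile, scope, assignments.loc[c])
                    seen_on_contig = set()
                    for a in annotations:
                        if a.contig_id != c or a.ko_id is None:
                            continue
                        if not per_hit and a.ko_id in seen_on_contig:
                            continue
                        seen_on_contig.add(a.ko_id)
                        contributions.setdefault(a.ko_id, []).append(w)
                acc = 0.0
                for ko in module.ko_ids:
                    if ko in contributions:
                        ws = contributions[ko]
                        acc += sum(ws) / len(ws)
                total += acc / module.size
            out[(module.module_id, g)] = total
    return out


# ---------------------------------------------------------------------------
# KO weights and per-MAG module abundance
# ---------------------------------------------------------------------------

class TestKoWeights:
    def test_shared_ko_averages_contig_weights(self):
        mag, ann, weights, _ = demo_two_contig_bin(2.0, 4.0)
        kw = ko_weights_in_mag(mag.contig_ids, ann, weights)
        assert kw["K1"] == pytest.approx(3.0)  # AVG(w1, w2)
        assert kw["K2"] == 2.0
        assert kw["K3"] == 4.0
        assert kw["K6"] == 4.0
        assert "K4" not in kw

    def test_foreign_contig_annotation_skipped_with_warning(self, caplog):
        ann = [GeneAnnotation("X1_1", "X1", "K1")]
        with caplog.at_level(logging.WARNING, logger="magtk.modules"):
            kw = ko_weights_in_mag({"C1"}, ann, {"C1": 1.0})
        assert kw == {} and "X1" in caplog.text

    def test_per_hit_vs_per_contig_averaging(self):
        ann = [
            GeneAnnotation("C1_1", "C1", "K1"),
            GeneAnnotation("C1_2", "C1", "K1"),
            GeneAnnotation("C2_1", "C2", "K1"),
        ]
        weights = {"C1": 1.0, "C2": 4.0}
        per_hit = ko_weights_in_mag({"C1", "C2"}, ann, weights, per_hit=True)
        per_contig = ko_weights_in_mag({"C1", "C2"}, ann, weights, per_hit=False)
        assert per_hit["K1"] == pytest.approx(2.0)     # (1 + 1 + 4) / 3
        assert per_contig["K1"] == pytest.approx(2.5)  # (1 + 4) / 2


class TestModuleAbundanceInMag:
    @pytest.mark.parametrize("w1,w2,m1,m2", [(2.0, 4.0, 3.0, 1.0),
                                             (1.0, 1.0, 1.0, 0.25),
                                             (2.0, 0.0, 1.0, 0.0)])
    def test_demo_arithmetic(self, w1, w2, m1, m2):
        mag, ann, weights, modules = demo_two_contig_bin(w1, w2)
        kw = ko_weights_in_mag(mag.contig_ids, ann, weights)
        assert module_abundance_in_mag(kw, modules[0]) == pytest.approx(m1)
        assert module_abundance_in_mag(kw, modules[1]) == pytest.approx(m2)

    def test_absent_module_scores_zero(self):
        assert module_abundance_in_mag({}, ModuleDefinition("M", frozenset({"K9"}))) == 0.0

    def test_saturation_identity_and_bounds(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            w = float(rng.uniform(0.1, 9))
            kos = [f"K{i}" for i in range(int(rng.integers(1, 6)))] or ["K0"]
            module = ModuleDefinition("M", frozenset(kos))
            kw = {k: w for k in kos}
            assert module_abundance_in_mag(kw, module) == pytest.approx(w)
            mixed = {k: float(rng.uniform(0, w)) for k in kos}
            val = module_abundance_in_mag(mixed, module)
            assert 0.0 <= val <= max(mixed.values())


# ---------------------------------------------------------------------------
# group-level aggregation
# ---------------------------------------------------------------------------

def _mini_assignments(rows):
    df = pd.DataFrame(rows).set_index("contig_id")
    for s in SAMPLE_IDS:
        col = f"present_{s}"
        if col not in df.columns:
            df[col] = False
    return df


def _mini_matrix(profiles):
    df = pd.DataFrame(profiles, columns=SAMPLE_IDS, dtype=float)
    df.index = list(profiles.keys()) if isinstance(profiles, dict) else df.index
    return CoverageMatrix(values=df, state="normalized")


class TestWeightPolicies:
    def _setup(self, primary="PL_ALL", presence=None):
        assignments = _mini_assignments(
            [{"contig_id": "C1", "primary": primary, "trend": ""}]
        )
        if presence:
            for s, flag in presence.items():
                assignments.loc["C1", f"present_{s}"] = flag
        profiles = pd.DataFrame(
            [[9.0, 1.0, 2.0, 3.0, 4.0]], index=["C1"], columns=SAMPLE_IDS
        )
        matrix = CoverageMatrix(values=profiles, state="normalized")
        ann = [GeneAnnotation("C1_1", "C1", "K1")]
        modules = [ModuleDefinition("M1", frozenset({"K1"}))]
        return assignments, ann, modules, matrix

    def test_group_mean_over_pl_samples(self):
        assignments, ann, modules, matrix = self._setup("PL_ALL")
        out = module_abundance_by_group(
            assignments, {"mag": {"C1"}}, ann, modules, matrix, SAMPLES
        )
        assert out.at["M1", "PL_ALL"] == pytest.approx(2.5)  # mean of 1..4

    def test_unique_pl_group_uses_its_sample(self):
        assignments, ann, modules, matrix = self._setup("PL_P2")
        out = module_abundance_by_group(
            assignments, {"mag": {"C1"}}, ann, modules, matrix, SAMPLES
        )
        assert out.at["M1", "PL_P2"] == pytest.approx(2.0)

    def test_pl_sub_uses_supra_threshold_samples(self):
        assignments, ann, modules, matrix = self._setup(
            "PL_SUB", presence={"PL3": True, "PL4": True}
        )
        out = module_abundance_by_group(
            assignments, {"mag": {"C1"}}, ann, modules, matrix, SAMPLES
        )
        assert out.at["M1", "PL_SUB"] == pytest.approx(3.5)  # mean of PL3, PL4

    def test_max_policy(self):
        assignments, ann, modules, matrix = self._setup("PL_ALL")
        out = module_abundance_by_group(
            assignments, {"mag": {"C1"}}, ann, modules, matrix, SAMPLES,
            policy="max",
        )
        assert out.at["M1", "PL_ALL"] == pytest.approx(9.0)

    def test_per_sample_policy_emits_sample_columns(self):
        assignments, ann, modules, matrix = self._setup("PL_ALL")
        out = module_abundance_by_group(
            assignments, {"mag": {"C1"}}, ann, modules, matrix, SAMPLES,
            policy="per-sample",
        )
        assert out.at["M1", "PL_ALL:PL4"] == pytest.approx(4.0)
        assert out.at["M1", "PL_ALL:AL1"] == pytest.approx(9.0)

    def test_unknown_policy_rejected(self):
        assignments, ann, modules, matrix = self._setup("PL_ALL")
        with pytest.raises(InputError, match="policy"):
            module_abundance_by_group(
                assignments, {"mag": {"C1"}}, ann, modules, matrix, SAMPLES,
                policy="median",
            )


class TestGroupAggregation:
    def test_two_mags_add(self):
        assignments = _mini_assignments(
            [{"contig_id": c, "primary": "BO", "trend": ""} for c in ("C1", "C2")]
        )
        profiles = pd.DataFrame(
            [[2.0] * 5, [6.0] * 5], index=["C1", "C2"], columns=SAMPLE_IDS
        )
        matrix = CoverageMatrix(values=profiles, state="normalized")
        ann = [GeneAnnotation("C1_1", "C1", "K1"), GeneAnnotation("C2_1", "C2", "K1")]
        modules = [ModuleDefinition("M1", frozenset({"K1"}))]
        single = module_abundance_by_group(
            assignments.loc[["C1"]], {"m1": {"C1"}}, ann, modules, matrix, SAMPLES
        )
        combined = module_abundance_by_group(
            assignments, {"m1": {"C1"}, "m2": {"C2"}}, ann, modules, matrix, SAMPLES
        )
        assert single.at["M1", "BO"] == pytest.approx(2.0)
        assert combined.at["M1", "BO"] == pytest.approx(2.0 + 6.0)

    def test_overlapping_mags_rejected(self):
        assignments = _mini_assignments(
            [{"contig_id": "C1", "primary": "BO", "trend": ""}]
        )
        matrix = CoverageMatrix(
            values=pd.DataFrame([[1.0] * 5], index=["C1"], columns=SAMPLE_IDS),
            state="normalized",
        )
        with pytest.raises(InputError, match="C1"):
            module_abundance_by_group(
                assignments, {"m1": {"C1"}, "m2": {"C1"}}, [],
                [ModuleDefinition("M1", frozenset({"K1"}))], matrix, SAMPLES,
            )

    @pytest.mark.parametrize("policy", ["group-mean", "max"])
    @pytest.mark.parametrize("group_scoped", [True, False])
    def test_matches_bruteforce_oracle(self, policy, group_scoped):
        """Random communities up to 5 MAGs × 30 contigs × 20 modules."""
        from magtk.coverage import normalize as cov_normalize
        from magtk.grouping import assign_groups
        from magtk.simulate import SimulationConfig, build_community

        for seed in (1, 2):
            config = SimulationConfig(seed=seed, n_mags=5, n_modules=20,
                                      kos_per_module=3, genes_per_contig=3)
            community = build_community(config)
            norm = cov_normalize(community.raw_matrix, community.samples)
            assignments = assign_groups(norm, community.samples)
            mags = {m.mag_id: set(m.contig_ids) for m in community.mags}
            result = module_abundance_by_group(
                assignments, mags, community.annotations, community.modules,
                norm, community.samples, policy=policy, group_scoped=group_scoped,
            )
            expected = brute_module_abundance_by_group(
                assignments, mags, community.annotations, community.modules,
                norm.values, policy, group_scoped,
            )
            for (module_id, group), value in expected.items():
                assert result.at[module_id, group] == pytest.approx(
                    value, abs=1e-9
                ), (module_id, group)


def test_module_abundance_per_mag_matches_demo():
    mag, ann, weights, modules = demo_two_contig_bin(2.0, 4.0)
    out = module_abundance_per_mag([mag], ann, modules, weights)
    assert out.at["M1", "Bin_1"] == pytest.approx(3.0)
    assert out.at["M2", "Bin_1"] == pytest.approx(1.0)
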