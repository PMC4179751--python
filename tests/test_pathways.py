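"""Pathway-active compound selection and transcriptional-coherence tests."""

import math

import numpy as np
import pandas as pd
import pytest

from persig import pathways as pw
from persig.io_formats import PathwayCollection


def profile_frame(rows, kinases):
    return pd.DataFrame(rows, index=[f"C{i}" for i in range(len(rows))],
                        columns=kinases).astype(bool)


def pair_table(records):
    return pd.DataFrame(records, columns=["compound_a", "compound_b", "similarity",
                                          "space_id"])


def all_pairs(values_by_pair):
    return pair_table([(a, b, s, "transcript:A") for (a, b), s in values_by_pair.items()])


class TestActiveCompounds:
    def test_single_kinase_rule(self):
        profiles_ = profile_frame(
            [[0, 0], [1, 0], [0, 1], [1, 1]], ["K1", "K2"]
        )
        active = pw.pathway_active_compounds(frozenset({"K1"}), profiles_)
        assert active == frozenset({"C1", "C3"})

    def test_all_kinase_pathway_superset(self):
        profiles_ = profile_frame([[0, 0], [1, 0], [0, 1]], ["K1", "K2"])
        active = pw.pathway_active_compounds(frozenset({"K1", "K2"}), profiles_)
        assert active == frozenset({"C1", "C2"})

    def test_source_choice_changes_membership(self):
        """Measured and predicted profiles differing in one bit disagree."""
        measured = profile_frame([[1], [0]], ["K1"])
        predicted = profile_frame([[0], [0]], ["K1"])
        assert pw.pathway_active_compounds(frozenset({"K1"}), measured) == frozenset({"C0"})
        assert pw.pathway_active_compounds(frozenset({"K1"}), predicted) == frozenset()

    def test_kinase_map_intersects_universe(self):
        col = PathwayCollection({"P1": ("d", frozenset({"K1", "PROTX"})),
                                 "P2": ("d", frozenset({"PROTY"}))})
        kmap = pw.pathway_kinase_map(col, ["K1", "K2"])
        assert kmap == {"P1": frozenset({"K1"}), "P2": frozenset()}


class TestTranscriptTest:
    def test_extreme_separation(self):
        compounds = [f"C{i}" for i in range(6)]
        active = frozenset(compounds[:3])
        values = {}
        for i in range(6):
            for j in range(i + 1, 6):
                a, b = compounds[i], compounds[j]
                values[(a, b)] = 1.0 if {a, b} <= active else 0.0
        result, counts = pw.pathway_transcript_test(active, all_pairs(values))
        assert counts["n_active_pairs"] == 3
        assert result.mean_high == 1.0 and result.mean_low == 0.0
        assert result.p < 1e-6

    def test_exactly_three_actives_three_pairs(self):
        compounds = [f"C{i}" for i in range(10)]
        rng = np.random.default_rng(0)
        values = {}
        for i in range(10):
            for j in range(i + 1, 10):
                values[(compounds[i], compounds[j])] = float(rng.random())
        result, counts = pw.pathway_transcript_test(
            frozenset(compounds[:3]), all_pairs(values)
        )
        assert counts["n_active_pairs"] == 3
        assert result is not None

    def test_below_minimum_not_computable(self):
        compounds = [f"C{i}" for i in range(5)]
        values = {(compounds[i], compounds[j]): 0.5
                  for i in range(5) for j in range(i + 1, 5)}
        result, _ = pw.pathway_transcript_test(frozenset(compounds[:2]), all_pairs(values))
        assert result is None

    def test_groups_partition_all_pairs(self, rng):
        compounds = [f"C{i}" for i in range(12)]
        values = {(compounds[i], compounds[j]): float(rng.random())
                  for i in range(12) for j in range(i + 1, 12)}
        active = frozenset(compounds[:5])
        _, counts = pw.pathway_transcript_test(active, all_pairs(values))
        n_active, n_rest = counts["n_active_pairs"], counts["n_rest_pairs"]
        assert n_active == math.comb(5, 2)
        assert n_active + n_rest == math.comb(12, 2)

    def test_pure_inactive_mode_excludes_mixed_pairs(self, rng):
        compounds = [f"C{i}" for i in range(10)]
        values = {(compounds[i], compounds[j]): float(rng.random())
                  for i in range(10) for j in range(i + 1, 10)}
        active = frozenset(compounds[:4])
        _, mixed = pw.pathway_transcript_test(active, all_pairs(values))
        _, pure = pw.pathway_transcript_test(active, all_pairs(values),
                                             pure_inactive_pairs=True)
        assert pure["n_rest_pairs"] == math.comb(6, 2)
        assert mixed["n_rest_pairs"] == math.comb(10, 2) - math.comb(4, 2)


class TestScreen:
    def make_screen_inputs(self, rng, order=None):
        kinases = ["K1", "K2", "K3"]
        profiles_ = profile_frame(rng.random((12, 3)) < 0.4, kinases)
        items = {
            "P1": ("d", frozenset({"K1"})),
            "P2": ("d", frozenset({"K2", "K3"})),
            "P3": ("d", frozenset({"PROT1"})),  # no kinase -> not computable
        }
        if order:
            items = {k: items[k] for k in order}
        col = PathwayCollection(items)
        compounds = list(profiles_.index)
        values = {(compounds[i], compounds[j]): float(rng.random())
                  for i in range(12) for j in range(i + 1, 12)}
        return col, profiles_, {"A": all_pairs(values)}

    def test_not_computable_excluded_from_denominator(self, rng):
        col, profiles_, tpairs = self.make_screen_inputs(rng)
        summary, results = pw.pathway_screen(col, profiles_, tpairs)
        p3 = results[results["pathway_id"] == "P3"].iloc[0]
        assert not p3["computable"] and "no kinase" in p3["reason"]
        assert summary.n_pathways_tested == int(results["computable"].sum())

    def test_screen_independent_of_pathway_order(self, rng):
        col1, profiles_, tpairs = self.make_screen_inputs(rng, order=["P1", "P2", "P3"])
        rng2 = np.random.default_rng(12345)
        col2, profiles2, tpairs2 = self.make_screen_inputs(rng2, order=["P3", "P2", "P1"])
        _, res1 = pw.pathway_screen(col1, profiles_, tpairs)
        _, res2 = pw.pathway_screen(col2, profiles2, tpairs2)
        res1s = res1.sort_values("pathway_id", ignore_index=True)
        res2s = res2.sort_values("pathway_id", ignore_index=True)
        pd.testing.assert_frame_equal(res1s, res2s)


def test_effect_size_dose_response():
    """Stronger planted kinase→gene effects give smaller pathway p-values."""
    from persig import profiles as pr, synthetic

    # effect sizes chosen below discretization saturation: with a ±2σ call
    # threshold and unit noise, effects ≳ 2 turn essentially every effect
    # gene into an ON bit and the p-values plateau
    medians = []
    for effect_mean in (0.5, 1.0, 2.0):
        cfg = synthetic.SimulationConfig(seed=5, n_cell_lines=1,
                                         effect_mean=effect_mean)
        data = synthetic.simulate(cfg)
        line = sorted(data.zscores)[0]
        fps = pr.transcript_fingerprints(data.zscores[line], cell_line=line)
        tpairs = pr.pairwise_similarity(fps)
        # use ground-truth targets as the activity profile: isolates the
        # transcriptional response from model quality
        kinases = data.kinome.col_ids
        frame = pd.DataFrame(
            [[k in data.ground_truth.targets[c] for k in kinases]
             for c in sorted(data.ground_truth.targets)],
            index=sorted(data.ground_truth.targets), columns=kinases,
        )
        summary, results = pw.pathway_screen(data.pathways, frame, {line: tpairs})
        pvals = results.loc[results["computable"], "p"]
        medians.append(float(np.median(-np.log10(np.maximum(pvals, 1e-300)))))
    assert medians[0] < medians[1] < medians[2]
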