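"""Fingerprint constructions and Tanimoto similarity properties."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from persig import profiles
from persig.profiles import (
    BinaryFingerprint,
    SpaceMismatchError,
    cross_cellline_similarity,
    kinome_fingerprint,
    pairwise_similarity,
    selectivity_annotation,
    tanimoto,
    transcript_fingerprint,
)

from conftest import make_matrix, random_fingerprints


def fp(*bits, space="s"):
    return BinaryFingerprint(space_id=space, bits=frozenset(bits))


bitsets = st.frozensets(st.sampled_from([f"f{i}" for i in range(12)]), max_size=12)


class TestTanimoto:
    def test_identity_nonempty(self):
        assert tanimoto(fp("a", "b"), fp("a", "b")) == 1.0

    def test_manual_count(self):
        assert tanimoto(fp("1", "2", "3"), fp("2", "3", "4")) == 0.5

    def test_empty_empty_convention(self):
        assert tanimoto(fp(), fp()) == 0.0

    def test_space_mismatch(self):
        with pytest.raises(SpaceMismatchError):
            tanimoto(fp("a", space="x"), fp("a", space="y"))

    @settings(max_examples=200, deadline=None)
    @given(a=bitsets, b=bitsets, c=bitsets)
    def test_metric_properties(self, a, b, c):
        """Symmetry, bounds, identity-of-indiscernibles, triangle inequality."""
        fa, fb, fc = fp(*a), fp(*b), fp(*c)
        sab = tanimoto(fa, fb)
        assert 0.0 <= sab <= 1.0
        assert sab == tanimoto(fb, fa)
        if a and a == b:
            assert sab == 1.0
        if sab == 1.0 and a:
            assert a == b
        # 1 - Tanimoto (Jaccard distance) satisfies the triangle inequality
        dab, dbc, dac = 1 - sab, 1 - tanimoto(fb, fc), 1 - tanimoto(fa, fc)
        assert dac <= dab + dbc + 1e-12


class TestChemFingerprint:
    def test_equivalent_smiles_identical(self):
        assert profiles.chem_fingerprint("OCC") == profiles.chem_fingerprint("CCO")

    def test_distinct_structures_differ(self):
        a = profiles.chem_fingerprint("C")
        b = profiles.chem_fingerprint("CCCC")
        assert tanimoto(a, b) < 1.0

    def test_unparseable_smiles_names_compound(self):
        with pytest.raises(ValueError, match="C9999"):
            profiles.chem_fingerprint("not_a_smiles(", compound_id="C9999")

    def test_self_similarity_one(self):
        smiles = ["CCO", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O", "CCN(CC)CC",
                  "C1CCCCC1", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"]
        for s in smiles:
            f = profiles.chem_fingerprint(s)
            assert tanimoto(f, f) == 1.0


class TestKinomeFingerprint:
    def test_threshold_strict_and_missing_off(self):
        panel = make_matrix(
            [[90.0, 95.0, np.nan]], ["C1"], ["K1", "K2", "K3"]
        )
        fps = kinome_fingerprint(panel, threshold=90.0)
        assert fps["C1"].bits == frozenset({"K2"})  # 90.0 exactly is OFF

    def test_all_missing_row_empty_and_zero_similarity(self):
        panel = make_matrix(
            [[np.nan, np.nan], [95.0, 99.0]], ["C1", "C2"], ["K1", "K2"]
        )
        fps = kinome_fingerprint(panel)
        assert len(fps["C1"]) == 0
        assert tanimoto(fps["C1"], fps["C2"]) == 0.0


class TestTranscriptFingerprint:
    def test_rule_application(self):
        sig = pd.Series([2.5, -3.1, 0.2], index=["g1", "g2", "g3"])
        f = transcript_fingerprint(sig, z_threshold=2.0)
        assert f.bits == frozenset({"g1_up", "g2_down"})

    def test_subthreshold_empty(self):
        sig = pd.Series([1.9, -1.9, 0.0], index=["g1", "g2", "g3"])
        assert len(transcript_fingerprint(sig, z_threshold=2.0)) == 0

    def test_negation_swaps_up_down(self):
        rng = np.random.default_rng(0)
        sig = pd.Series(rng.normal(0, 2, 50), index=[f"g{i}" for i in range(50)])
        f_pos = transcript_fingerprint(sig)
        f_neg = transcript_fingerprint(-sig)
        swap = {b.replace("_up", "_DOWN").replace("_down", "_up").replace("_DOWN", "_down")
                for b in f_pos.bits}
        assert f_neg.bits == frozenset(swap)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-6, 6, allow_nan=False), min_size=1, max_size=30))
    def test_up_down_exclusive_and_bounded(self, zs):
        sig = pd.Series(zs, index=[f"g{i}" for i in range(len(zs))])
        f = transcript_fingerprint(sig)
        genes_up = {b[:-3] for b in f.bits if b.endswith("_up")}
        genes_down = {b[:-5] for b in f.bits if b.endswith("_down")}
        assert not genes_up & genes_down
        assert len(f) <= len(zs)


class TestPairwise:
    def test_pair_count(self, rng):
        fps = random_fingerprints(rng, 3)
        assert len(pairwise_similarity(fps)) == 3

    def test_matches_brute_force_oracle(self, rng):
        fps = random_fingerprints(rng, 50)
        table = pairwise_similarity(fps)
        got = {(r.compound_a, r.compound_b): r.similarity
               for r in table.itertuples(index=False)}
        for a, b in itertools.combinations(sorted(fps), 2):
            assert got[(a, b)] == pytest.approx(tanimoto(fps[a], fps[b]), abs=0)

    def test_input_order_invariance(self, rng):
        fps = random_fingerprints(rng, 10)
        shuffled = {k: fps[k] for k in reversed(sorted(fps))}
        pd.testing.assert_frame_equal(pairwise_similarity(fps), pairwise_similarity(shuffled))


class TestCrossCellLine:
    def make_line_fps(self, rng, n, cell):
        out = {}
        for i in range(n):
            genes = rng.choice(30, size=8, replace=False)
            bits = {f"g{g}_up" if rng.random() < 0.5 else f"g{g}_down" for g in genes}
            out[f"C{i:03d}"] = BinaryFingerprint(
                space_id=f"transcript:{cell}", bits=frozenset(bits)
            )
        return out

    def test_identical_lines_reduce_to_within_line(self, rng):
        fps_a = self.make_line_fps(rng, 8, "A")
        fps_b = {
            c: BinaryFingerprint(space_id="transcript:B", bits=f.bits)
            for c, f in fps_a.items()
        }
        cross = cross_cellline_similarity(fps_a, fps_b)
        within = pairwise_similarity(fps_a)
        assert np.allclose(cross["similarity"], within["similarity"])

    def test_symmetric_in_cell_lines(self, rng):
        fps_a = self.make_line_fps(rng, 8, "A")
        fps_b = self.make_line_fps(rng, 8, "B")
        ab = cross_cellline_similarity(fps_a, fps_b)
        ba = cross_cellline_similarity(fps_b, fps_a)
        assert np.allclose(ab["similarity"], ba["similarity"])

    def test_matches_brute_force_oracle(self, rng):
        fps_a = self.make_line_fps(rng, 20, "A")
        fps_b = self.make_line_fps(rng, 20, "B")
        table = cross_cellline_similarity(fps_a, fps_b)
        got = {(r.compound_a, r.compound_b): r.similarity
               for r in table.itertuples(index=False)}
        def raw(x, y):
            u = len(x | y)
            return len(x & y) / u if u else 0.0
        for i, j in itertools.combinations(sorted(fps_a), 2):
            expected = 0.5 * (raw(fps_a[i].bits, fps_b[j].bits)
                              + raw(fps_a[j].bits, fps_b[i].bits))
            assert got[(i, j)] == pytest.approx(expected, abs=1e-12)

    def test_disjoint_compounds_warns_empty(self, rng):
        fps_a = self.make_line_fps(rng, 3, "A")
        fps_b = {f"X{i}": f for i, (_, f) in enumerate(self.make_line_fps(rng, 3, "B").items())}
        with pytest.warns(UserWarning):
            table = cross_cellline_similarity(fps_a, fps_b)
        assert table.empty


class TestSelectivity:
    GROUPS = {"K1": "TK", "K2": "TK", "K3": "TK", "K4": "CMGC", "K5": "AGC",
              "K6": "TK", "K7": "CMGC", "K8": "AGC"}

    @pytest.mark.parametrize(
        "bits,expected",
        [
            ((), "inactive"),
            (("K1",), "selective"),
            (("K1", "K2", "K3"), "group_selective"),
            (("K1", "K2", "K3", "K4", "K5", "K6"), "promiscuous"),
            (("K1", "K4"), "multi"),
            (("K1", "K2", "K3", "K4"), "multi"),
        ],
    )
    def test_classification_rules(self, bits, expected):
        assert selectivity_annotation(fp(*bits, space="kinome"), self.GROUPS) == expected

    def test_five_actives_single_group_is_group_selective(self):
        groups = dict(self.GROUPS, K9="TK", K10="TK")
        f = fp("K1", "K2", "K3", "K6", "K9", space="kinome")
        assert selectivity_annotation(f, groups) == "group_selective"

    def test_unannotated_kinase_errors(self):
        with pytest.raises(KeyError, match="K99"):
            selectivity_annotation(fp("K99", space="kinome"), self.GROUPS)
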