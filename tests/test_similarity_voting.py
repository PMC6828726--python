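"""Homolog-set construction, template matching and squared-overlap voting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glysite import synthetic as syn
from glysite import voting as vt
from glysite.io import GLYCOPROTEIN, NON_GLYCOPROTEIN


def _hs(pid, members):
    return vt.HomologSet(protein_id=pid, members={m: 0.9 for m in members})


def _index(entries):
    index = vt.TemplateIndex()
    for pid, members, label in entries:
        index.add(_hs(pid, members), label)
    return index


class TestParseHitList:
    def test_threshold_self_hit_and_percent_units(self, tmp_path):
        path = tmp_path / "Q1.tsv"
        path.write_text("A\t0.99\nB\t0.49\nQ1\t1.00\nC\t97.1\n")
        hs = vt.parse_hit_list(path)
        assert hs.protein_id == "Q1"
        assert set(hs.members) == {"A", "C"}
        assert hs.members["C"] == pytest.approx(0.971)

    def test_ranked_summary_format(self, tmp_path):
        path = tmp_path / "Q2.hhr"
        path.write_text(
            "No Hit Prob E-value\n"
            "1 H1 99.9 1e-30\n"
            "2 H2 45.0 0.5\n"
        )
        hs = vt.parse_hit_list(path, query_id="Q2")
        assert set(hs.members) == {"H1"}

    def test_unparseable_line_reports_line_number(self, tmp_path):
        path = tmp_path / "Q3.tsv"
        path.write_text("A\t0.9\nnot-a-number\tNaN?\n")
        with pytest.raises(ValueError, match=":2"):
            vt.parse_hit_list(path)


class TestTemplatesAndVoting:
    def test_overlap_boundary_at_k_min(self):
        query = _hs("Q", "ABCDE")  # 5 members
        index = _index([
            ("P1", "ABCD" + "Z", GLYCOPROTEIN),   # overlap 4 -> not a template
            ("P2", "ABCDE", GLYCOPROTEIN),          # overlap 5 -> template
        ])
        templates = vt.find_templates(query, index, k_min=5)
        assert [t[0] for t in templates] == ["P2"]

    def test_leave_self_out(self):
        query = _hs("P1", "ABCDE")
        index = _index([("P1", "ABCDE", GLYCOPROTEIN), ("P2", "ABCDE", GLYCOPROTEIN)])
        templates = vt.find_templates(query, index, k_min=5)
        assert [t[0] for t in templates] == ["P2"]

    def test_empty_query_has_no_templates(self):
        index = _index([("P1", "ABCDE", GLYCOPROTEIN)])
        assert vt.find_templates(_hs("Q", ""), index) == []

    def test_squared_overlap_hand_case(self):
        # glyco overlaps {6, 5}, non-glyco {5}: V_G=61, V_NG=25, score=61/86
        templates = [("P1", 6, GLYCOPROTEIN), ("P2", 5, GLYCOPROTEIN),
                     ("P3", 5, NON_GLYCOPROTEIN)]
        result = vt.voting_score(_hs("Q", "ABCDEF"), templates)
        assert result.v_g == 61 and result.v_ng == 25
        assert result.score == pytest.approx(61 / 86)

    def test_symmetric_overlaps_score_half(self):
        templates = [("P1", 5, GLYCOPROTEIN), ("P2", 5, NON_GLYCOPROTEIN)]
        assert vt.voting_score(_hs("Q", "ABCDE"), templates).score == 0.5

    def test_only_glyco_templates_score_one(self):
        templates = [("P1", 7, GLYCOPROTEIN)]
        assert vt.voting_score(_hs("Q", "ABCDEFG"), templates).score == 1.0

    def test_no_templates_scores_nan(self):
        assert math.isnan(vt.voting_score(_hs("Q", "AB"), []).score)

    def test_adding_glyco_template_increases_score(self):
        base = [("P1", 5, GLYCOPROTEIN), ("P2", 6, NON_GLYCOPROTEIN)]
        s0 = vt.voting_score(_hs("Q", "ABCDEF"), base).score
        s1 = vt.voting_score(_hs("Q", "ABCDEF"), base + [("P3", 5, GLYCOPROTEIN)]).score
        assert s1 > s0

    def test_label_swap_maps_score_to_complement(self):
        templates = [("P1", 6, GLYCOPROTEIN), ("P2", 5, NON_GLYCOPROTEIN),
                     ("P3", 7, NON_GLYCOPROTEIN)]
        swapped = [
            (pid, o, GLYCOPROTEIN if lab == NON_GLYCOPROTEIN else NON_GLYCOPROTEIN)
            for pid, o, lab in templates
        ]
        q = _hs("Q", "ABCDEFG")
        assert vt.voting_score(q, swapped).score == pytest.approx(
            1 - vt.voting_score(q, templates).score
        )

    @given(data=st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_naive_oracle_on_random_universes(self, data):
        """Exact agreement with an independent brute-force implementation on
        random universes of up to 30 proteins."""
        universe = [f"U{i}" for i in range(20)]
        n_train = data.draw(st.integers(min_value=1, max_value=29))
        entries = []
        for i in range(n_train):
            members = data.draw(st.sets(st.sampled_from(universe), max_size=15))
            label = data.draw(st.sampled_from([GLYCOPROTEIN, NON_GLYCOPROTEIN]))
            entries.append((f"P{i}", members, label))
        q_members = data.draw(st.sets(st.sampled_from(universe), max_size=15))
        k_min = data.draw(st.integers(min_value=1, max_value=6))
        query = _hs("Q", q_members)
        index = _index(entries)
        result = vt.voting_score(query, vt.find_templates(query, index, k_min=k_min))
        # naive re-computation from first principles
        v_g = v_ng = 0.0
        for pid, members, label in entries:
            overlap = len(set(q_members) & set(members))
            if overlap >= k_min:
                if label == GLYCOPROTEIN:
                    v_g += overlap**2
                else:
                    v_ng += overlap**2
        assert result.v_g == v_g and result.v_ng == v_ng
        if v_g + v_ng > 0:
            assert result.score == pytest.approx(v_g / (v_g + v_ng))
        else:
            assert math.isnan(result.score)


class TestIntervalSummary:
    def test_top_interval_all_glycoproteins(self):
        df = vt.score_interval_summary([0.9, 0.95, 1.0], [True, True, True])
        assert df.iloc[4]["n"] == 3 and df.iloc[4]["p"] == 1.0

    def test_counts_conserve_defined_scores(self):
        scores = [0.05, 0.3, 0.5, 0.7, 0.99, float("nan")]
        df = vt.score_interval_summary(scores, [False, False, True, True, True, False])
        assert df["n"].sum() == 5

    def test_homology_structure_gives_monotone_intervals(self, signal_config):
        """Strong within-class overlap: the glycoprotein fraction rises with
        the voting score across intervals."""
        labels = {f"G{i}": True for i in range(50)}
        labels.update({f"N{i}": False for i in range(50)})
        sets = syn.generate_homolog_universe(signal_config, labels)
        clf = vt.SimilarityVotingClassifier().fit(
            list(sets.values()), [int(labels[p]) for p in sets]
        )
        test_labels = {f"T{i}": i % 2 == 0 for i in range(100)}
        test_cfg = syn.replace(signal_config, seed=signal_config.seed + 1)
        test_sets = syn.generate_homolog_universe(test_cfg, test_labels)
        scores = clf.score_proteins(list(test_sets.values()))
        truth = [test_labels[p] for p in test_sets]
        df = vt.score_interval_summary(scores, truth)
        ps = df["p"].dropna().to_numpy()
        assert (np.diff(ps) >= 0).all()


class TestClassifierAndRoundTrip:
    def test_hit_list_roundtrip_through_files(self, tmp_path, signal_config):
        labels = {f"G{i}": True for i in range(5)}
        sets = syn.generate_homolog_universe(signal_config, labels)
        syn.write_hit_lists(sets, tmp_path, signal_config)
        for pid, hs in sets.items():
            parsed = vt.parse_hit_list(tmp_path / f"{pid}.tsv", query_id=pid)
            assert parsed.ids == hs.ids  # decoys and self-hit are dropped

    def test_heldout_glycoproteins_score_high_under_strong_boost(self, signal_config):
        labels = {f"G{i}": True for i in range(60)}
        labels.update({f"N{i}": False for i in range(60)})
        sets = syn.generate_homolog_universe(signal_config, labels)
        clf = vt.SimilarityVotingClassifier().fit(
            list(sets.values()), [int(labels[p]) for p in sets]
        )
        held_labels = {f"H{i}": True for i in range(100)}
        held_cfg = syn.replace(signal_config, seed=signal_config.seed + 7)
        held = syn.generate_homolog_universe(held_cfg, held_labels)
        scores = clf.score_proteins(list(held.values()))
        assert np.mean(scores[~np.isnan(scores)] > 0.8) >= 0.8

    def test_null_boost_scores_near_half(self, null_config):
        labels = {f"G{i}": True for i in range(40)}
        labels.update({f"N{i}": False for i in range(40)})
        sets = syn.generate_homolog_universe(null_config, labels)
        clf = vt.SimilarityVotingClassifier().fit(
            list(sets.values()), [int(labels[p]) for p in sets]
        )
        held_cfg = syn.replace(null_config, seed=null_config.seed + 7)
        held = syn.generate_homolog_universe(held_cfg, {f"H{i}": i % 2 == 0 for i in range(80)})
        scores = clf.score_proteins(list(held.values()))
        defined = scores[~np.isnan(scores)]
        assert len(defined) > 0
        assert abs(np.mean(defined) - 0.5) < 0.12
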