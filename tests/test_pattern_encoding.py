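"""Pattern vocabularies, the APD_w statistic and one-hot encoding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glysite import patterns as pt
from glysite import synthetic as syn
from glysite import io as gio


class TestRegionSlicing:
    def test_sequon_region_slice(self):
        sa = "BBBBBBBBBBEE" + "EEE" + "EEBBBBBBBB"
        assert pt.extract_region_pattern(sa, pt.SEQUON, 3) == "EEE"

    def test_terminal_anchors(self):
        ann = "ABCDEFGHIJKL" + "MNO" + "PQRSTUVWXY"
        # N-terminal length 6 ends at window position 12
        assert pt.extract_region_pattern(ann, pt.N_TERMINAL, 6) == "GHIJKL"
        # C-terminal length 9 starts at window position 16
        assert pt.extract_region_pattern(ann, pt.C_TERMINAL, 9) == "PQRSTUVWX"

    @pytest.mark.parametrize("w", [2, 12])
    def test_w_outside_range_rejected(self, w):
        with pytest.raises(ValueError):
            pt.extract_region_pattern("E" * 25, pt.N_TERMINAL, w)

    def test_sequon_region_w_fixed(self):
        with pytest.raises(ValueError):
            pt.extract_region_pattern("E" * 25, pt.SEQUON, 4)


def _apd_oracle(counts, other, z):
    """Literal transcription of the average-pattern-deviation formula."""
    items = list(counts.values())
    if other != (0, 0) and other[1] > 0:
        items.append(other)
    num = sum(abs(e / n - z) * (e + n) for e, n in items)
    den = sum(e + n for e, n in items)
    return num / den


class TestVocabularyAndAPD:
    def test_rare_pattern_floor_boundary(self):
        # 200 windows -> floor = ceil(0.01 * 200) = 2: a pattern with total
        # count exactly at the floor (one occurrence per class) is retained;
        # a single-occurrence pattern is pooled into the bucket
        anns = (["E" * 25] * 197
                + ["B" * 25] * 2
                + ["E" * 9 + "EBE" + "E" * 13])
        y = [1] * 99 + [0] * 98 + [1, 0] + [0]
        vocab = pt.build_vocabulary(anns, y, pt.SA, pt.N_TERMINAL, 3)
        assert "BBB" in vocab.patterns  # 2 >= 2, one in each class
        assert "EBE" not in vocab.patterns  # 1 < 2 -> bucket
        assert vocab.other_e + vocab.other_n == 1

    def test_conservation_of_window_count(self, signal_dataset):
        _, labelled, y = signal_dataset
        sas = [a.sa for a in labelled]
        for region in pt.REGIONS:
            w = 3 if region == pt.SEQUON else 6
            vocab = pt.build_vocabulary(sas, y, pt.SA, region, w)
            total = sum(e + n for e, n in vocab.counts.values())
            total += vocab.other_e + vocab.other_n
            assert total == len(labelled)

    def test_sequon_sa_vocabulary_has_at_most_8_patterns(self, signal_dataset):
        _, labelled, y = signal_dataset
        vocab = pt.build_vocabulary([a.sa for a in labelled], y, pt.SA, pt.SEQUON, 3)
        assert len(vocab.patterns) <= 8  # |{E,B}^3|

    def test_apd_zero_at_exact_balance(self):
        vocab = pt.PatternVocabulary(
            pt.SA, pt.N_TERMINAL, 3,
            counts={"EEE": (10, 10), "EBB": (5, 5)},
            other_e=0, other_n=0, z=1.0, n_windows=30,
        )
        assert pt.compute_apd(vocab) == pytest.approx(0.0)

    def test_apd_hand_case(self):
        # two patterns (e=30,n=10) and (e=10,n=30) at z=1:
        # (|3-1|*40 + |1/3-1|*40) / 80 = 4/3
        vocab = pt.PatternVocabulary(
            pt.SA, pt.N_TERMINAL, 3,
            counts={"EEE": (30, 10), "BBB": (10, 30)},
            other_e=0, other_n=0, z=1.0, n_windows=80,
        )
        assert pt.compute_apd(vocab) == pytest.approx(4.0 / 3.0, abs=1e-12)

    @given(
        data=st.data(),
        n_patterns=st.integers(min_value=1, max_value=6),
        z_num=st.integers(min_value=1, max_value=50),
        z_den=st.integers(min_value=1, max_value=50),
    )
    @settings(max_examples=200, deadline=None)
    def test_apd_matches_independent_transcription(self, data, n_patterns, z_num, z_den):
        """Oracle equivalence on random small vocabularies, to 1e-12."""
        counts = {}
        for i in range(n_patterns):
            e = data.draw(st.integers(min_value=0, max_value=50))
            n = data.draw(st.integers(min_value=1, max_value=50))
            counts[f"P{i}"] = (e, n)
        other = (
            data.draw(st.integers(min_value=0, max_value=50)),
            data.draw(st.integers(min_value=0, max_value=50)),
        )
        z = z_num / z_den
        vocab = pt.PatternVocabulary(
            pt.SA, pt.N_TERMINAL, 3, counts=dict(counts),
            other_e=other[0], other_n=other[1], z=z,
            n_windows=sum(e + n for e, n in counts.values()) + sum(other),
        )
        assert pt.compute_apd(vocab) == pytest.approx(
            _apd_oracle(counts, other, z), abs=1e-12
        )

    def test_apd_nonnegative(self, signal_dataset):
        _, labelled, y = signal_dataset
        sas = [a.sa for a in labelled]
        for w in range(3, 12):
            vocab = pt.build_vocabulary(sas, y, pt.SA, pt.C_TERMINAL, w)
            assert pt.compute_apd(vocab) >= 0.0


class TestWindowLengthSelection:
    def test_signal_concentrated_near_sequon_prefers_small_w(self):
        """Effect confined to the 4 sequon-adjacent residues: short patterns
        carry all the contrast, long ones dilute it."""
        config = syn.GeneratorConfig(
            seed=5, n_glycoproteins=120, n_non_glycoproteins=120,
            sa_effect=0.45, ss_effect=0.0, effect_width=4,
        )
        proteins, annotations = syn.generate_proteins(config)
        sa, ss = syn.generate_residue_annotations(proteins, annotations, config)
        windows = gio.build_dataset(proteins, annotations)
        annotated = gio.annotate_windows(windows, sa, ss)
        labelled = [a for a in annotated if a.window.label != gio.UNLABELED]
        y = [1 if a.window.label == gio.POSITIVE else 0 for a in labelled]
        sas = [a.sa for a in labelled]
        # brute-force APD sweep as the oracle
        apd = {
            w: pt.compute_apd(pt.build_vocabulary(sas, y, pt.SA, pt.N_TERMINAL, w))
            for w in range(3, 12)
        }
        assert apd[4] > apd[11]
        w_star, _ = pt.select_window_length(sas, y, pt.SA, pt.N_TERMINAL)
        assert w_star == max(apd, key=apd.get)

    def test_null_effect_shrinks_apd_towards_zero(self, null_dataset, signal_dataset):
        """With no class-conditional effect the deviations are sampling noise;
        the planted-signal condition dominates the null at every length."""
        _, null_lab, y0 = null_dataset
        _, sig_lab, y1 = signal_dataset
        null_sas = [a.sa for a in null_lab]
        sig_sas = [a.sa for a in sig_lab]
        for w in (3, 4):
            v0 = pt.build_vocabulary(null_sas, y0, pt.SA, pt.N_TERMINAL, w)
            v1 = pt.build_vocabulary(sig_sas, y1, pt.SA, pt.N_TERMINAL, w)
            apd0 = pt.compute_apd(v0)
            apd1 = pt.compute_apd(v1)
            assert apd0 < apd1 / 3
            assert apd0 < 0.5 * v0.z


class TestEncoding:
    def test_one_hot_per_region_block(self, signal_dataset):
        _, labelled, y = signal_dataset
        sas = [a.sa for a in labelled]
        sss = [a.ss for a in labelled]
        vocabs = {}
        for ft, strings in ((pt.SA, sas), (pt.SS, sss)):
            for region in pt.REGIONS:
                _, vocab = pt.select_window_length(strings, y, ft, region)
                vocabs[(ft, region)] = vocab
        lengths = [vocabs[k].block_length for k in vocabs]
        for a in labelled[:50]:
            vec = pt.encode_patterns(a.sa, a.ss, vocabs)
            assert vec.shape == (sum(lengths),)
            assert vec.sum() == 6.0  # exactly one hit in each of 6 blocks
            offset = 0
            for k in vocabs:
                block = vec[offset : offset + vocabs[k].block_length]
                assert block.sum() == 1.0
                offset += vocabs[k].block_length

    def test_unknown_pattern_routes_to_bucket(self):
        vocab = pt.PatternVocabulary(
            pt.SA, pt.SEQUON, 3, counts={"EEE": (30, 10)},
            other_e=3, other_n=2, z=1.0, n_windows=45,
        )
        vec = pt.encode_patterns("B" * 25, None, {(pt.SA, pt.SEQUON): vocab})
        assert vec.tolist() == [0.0, 1.0]
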