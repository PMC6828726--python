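"""Pattern-based encoding of predicted surface accessibility and secondary structure.

Each 25-mer sequon window is split into three regions of its per-residue
class strings: the N-terminal region (everything upstream of the sequon N,
ending at window position 12), the three-residue sequon region (positions
13-15) and the C-terminal region (starting at position 16).  Region
substrings of length w (3 <= w <= 11 for the terminal regions, fixed 3 for
the sequon) are treated as categorical patterns.

Patterns occurring in fewer than 1% of training windows are grouped into a
single rare-pattern bucket.  For each candidate length w the average pattern
deviation

    APD_w = sum_i |e_i/n_i - z| * (e_i + n_i) / sum_i (e_i + n_i)

is computed, where e_i / n_i count pattern i in glycosite / non-glycosite
windows and z is the background glycosite:non-glycosite ratio; the length w*
maximizing APD_w is selected per region.  Windows are then encoded one-hot
against the retained patterns (the bucket catches unmatched patterns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

SA = "SA"
SS = "SS"
N_TERMINAL = "N_terminal"
SEQUON = "sequon"
C_TERMINAL = "C_terminal"

REGIONS = (N_TERMINAL, SEQUON, C_TERMINAL)
ALPHABETS = {SA: "EB", SS: "HEC"}
PAD_CHAR = "-"
OTHER = "<other>"

W_MIN, W_MAX = 3, 11
SEQUON_W = 3


def extract_region_pattern(annotation: str, region: str, w: int, l: int = 25) -> str:
    """Slice the region pattern of length ``w`` out of a window-level class string.

    Terminal regions are anchored at the sequon-proximal end: the N-terminal
    pattern ends at window position 12 (1-based) and the C-terminal pattern
    starts at position 16; the sequon region is positions 13-15 (w fixed at 3).
    """
    if len(annotation) != l:
        raise ValueError(f"annotation length {len(annotation)} != l = {l}")
    c = l // 2  # 0-based index of the sequon N
    if region == SEQUON:
        if w != SEQUON_W:
            raise ValueError(f"sequon region has fixed w = {SEQUON_W}, got {w}")
        return annotation[c : c + 3]
    if not (W_MIN <= w <= W_MAX):
        raise ValueError(f"w must be in [{W_MIN}, {W_MAX}], got {w}")
    if region == N_TERMINAL:
        return annotation[c - w : c]
    if region == C_TERMINAL:
        return annotation[c + 3 : c + 3 + w]
    raise ValueError(f"unknown region {region!r}")


@dataclass
class PatternVocabulary:
    """Retained patterns for one (feature type, region) at length ``w``.

    ``counts`` maps each retained pattern to its (e_i, n_i) glycosite /
    non-glycosite occurrence counts; rare patterns (below the 1% floor),
    patterns containing the padding character and patterns never seen in
    negatives are pooled into a single rare-pattern bucket with counts
    (other_e, other_n).  ``z`` is the background positives:negatives ratio.
    """

    feature_type: str
    region: str
    w: int
    counts: dict[str, tuple[int, int]]
    other_e: int
    other_n: int
    z: float
    n_windows: int

    @property
    def patterns(self) -> list[str]:
        return list(self.counts)

    @property
    def has_bucket(self) -> bool:
        # The bucket slot is dropped only when nothing can ever fall through:
        # the sequon region is never padded, so full coverage of the class
        # alphabet suffices there; terminal regions can always meet padded
        # patterns at prediction time and keep the bucket unconditionally.
        if self.other_e + self.other_n > 0 or self.region != SEQUON:
            return True
        alphabet = ALPHABETS[self.feature_type]
        return len(self.counts) < len(alphabet) ** self.w

    @property
    def block_length(self) -> int:
        return len(self.counts) + (1 if self.has_bucket else 0)

    def index_of(self, pattern: str) -> int:
        """Slot index of a pattern within this region's one-hot block."""
        try:
            return list(self.counts).index(pattern)
        except ValueError:
            if not self.has_bucket:
                raise ValueError(
                    f"pattern {pattern!r} unmatched and vocabulary has no bucket"
                )
            return len(self.counts)


def build_vocabulary(
    annotations: Sequence[str],
    y: Sequence[int],
    feature_type: str,
    region: str,
    w: int,
    rare_threshold: float = 0.01,
    l: int = 25,
) -> PatternVocabulary:
    """Count region patterns by class and pool the rare ones.

    A pattern is retained when its total occurrence count reaches
    ``ceil(rare_threshold * n_windows)`` (counts exactly at the floor are
    retained), contains no padding character, and occurs at least once in
    negatives (otherwise e_i/n_i would be infinite in the APD sum); all other
    patterns merge into the bucket.  Retained patterns are ordered by
    decreasing total count (ties lexicographic) for stable serialization.
    """
    labels = np.asarray(y).astype(int)
    if len(annotations) != len(labels):
        raise ValueError("annotations and labels differ in length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes to build a pattern vocabulary")

    e_counts: dict[str, int] = {}
    n_counts: dict[str, int] = {}
    for ann, lab in zip(annotations, labels):
        pat = extract_region_pattern(ann, region, w, l=l)
        if lab == 1:
            e_counts[pat] = e_counts.get(pat, 0) + 1
            n_counts.setdefault(pat, 0)
        else:
            n_counts[pat] = n_counts.get(pat, 0) + 1
            e_counts.setdefault(pat, 0)

    floor = math.ceil(rare_threshold * len(annotations))
    retained: dict[str, tuple[int, int]] = {}
    other_e = other_n = 0
    for pat in e_counts:
        e, n = e_counts[pat], n_counts[pat]
        if (e + n) >= floor and PAD_CHAR not in pat and n > 0:
            retained[pat] = (e, n)
        else:
            other_e += e
            other_n += n
    ordered = dict(
        sorted(retained.items(), key=lambda kv: (-(kv[1][0] + kv[1][1]), kv[0]))
    )
    return PatternVocabulary(
        feature_type=feature_type,
        region=region,
        w=w,
        counts=ordered,
        other_e=other_e,
        other_n=other_n,
        z=n_pos / n_neg,
        n_windows=len(annotations),
    )


def compute_apd(vocab: PatternVocabulary) -> float:
    """Average pattern deviation of a vocabulary.

    Occurrence-weighted mean of |e_i/n_i - z| over the retained patterns and
    the rare-pattern bucket.  The bucket enters the sum as a single pattern;
    if its negative count is zero (its ratio would be infinite) it is left
    out of both sums.
    """
    items = list(vocab.counts.values())
    if vocab.other_e + vocab.other_n > 0 and vocab.other_n > 0:
        items.append((vocab.other_e, vocab.other_n))
    if not items:
        raise ValueError("empty vocabulary: no patterns with defined ratios")
    num = sum(abs(e / n - vocab.z) * (e + n) for e, n in items)
    den = sum(e + n for e, n in items)
    return num / den


def select_window_length(
    annotations: Sequence[str],
    y: Sequence[int],
    feature_type: str,
    region: str,
    rare_threshold: float = 0.01,
    l: int = 25,
) -> tuple[int, PatternVocabulary]:
    """Pick the terminal-region pattern length w* maximizing APD_w.

    Sweeps w = 3..11, ties broken toward smaller w.  The sequon region is
    fixed at w = 3 and returned directly.
    """
    if region == SEQUON:
        vocab = build_vocabulary(
            annotations, y, feature_type, region, SEQUON_W,
            rare_threshold=rare_threshold, l=l,
        )
        return SEQUON_W, vocab
    best: tuple[int, PatternVocabulary] | None = None
    best_apd = -np.inf
    for w in range(W_MIN, min(W_MAX, l // 2) + 1):
        vocab = build_vocabulary(
            annotations, y, feature_type, region, w,
            rare_threshold=rare_threshold, l=l,
        )
        apd = compute_apd(vocab)
        if apd > best_apd:
            best, best_apd = (w, vocab), apd
    assert best is not None
    return best


def encode_patterns(
    sa: str | None,
    ss: str | None,
    vocabs: dict[tuple[str, str], PatternVocabulary],
    l: int = 25,
) -> np.ndarray:
    """One-hot encode a window's SA and SS strings against fitted vocabularies.

    Blocks are concatenated per feature type in region order N-terminal,
    sequon, C-terminal (SA first, then SS).  Exactly one position is set per
    region block: the matched pattern, or the rare-pattern bucket.
    """
    blocks: list[np.ndarray] = []
    for feature_type, ann in ((SA, sa), (SS, ss)):
        for region in REGIONS:
            vocab = vocabs.get((feature_type, region))
            if vocab is None:
                continue
            if ann is None:
                raise ValueError(f"{feature_type} annotation required but missing")
            pat = extract_region_pattern(ann, region, vocab.w, l=l)
            block = np.zeros(vocab.block_length)
            block[vocab.index_of(pat)] = 1.0
            blocks.append(block)
    if not blocks:
        return np.zeros(0)
    return np.concatenate(blocks)
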