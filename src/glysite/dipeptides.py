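"""Gapped-dipeptide features for sequon windows.

A gapped dipeptide (GD) pairs the sequon asparagine with one flank residue A
at gap k: written ``A{k}N`` when A lies k residues upstream (N-terminal side)
and ``N{k}A`` when A lies k residues downstream (C-terminal side).  For a
25-mer window k runs from 0 to 11.  The C-terminal gap-1 position is the S/T
of the sequon itself, so N1S and N1T carry no discriminative power and are
excluded; each window therefore yields exactly 23 gapped dipeptides, and the
realizable feature space over the 20 standard residues has
12*20 + 11*20 = 460 types.

Each GD type gets a gapped dipeptide ratio (GDR): the fraction of its
occurrences among glycosite windows divided by the fraction among
non-glycosite windows (an odds-ratio-style statistic).  GDRs are min-max
normalized within each (gap, side) class to [0, 1] and the 23 normalized
values of a window form its GD feature vector.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import STANDARD_AA, NEGATIVE, POSITIVE, SequonWindow

N_SIDE = "N_terminal"
C_SIDE = "C_terminal"

NEUTRAL_GDR = 0.5  # encoded value for undefined / unseen / X-containing GDs


def max_gap(l: int = 25) -> int:
    """Largest gap representable in an l-mer window ((l-3)/2; 11 for l=25)."""
    return (l - 3) // 2


def _window_str(window: SequonWindow | str) -> str:
    return window.window if isinstance(window, SequonWindow) else window


def gd_slots(l: int = 25) -> list[tuple[str, int]]:
    """Canonical (side, gap) order: N-terminal gaps 11..0, then C-terminal
    gaps 0, 2..11.  Fixed so serialized models are stable."""
    m = max_gap(l)
    slots = [(N_SIDE, k) for k in range(m, -1, -1)]
    slots.append((C_SIDE, 0))
    slots.extend((C_SIDE, k) for k in range(2, m + 1))
    return slots


def gd_name(residue: str, side: str, gap: int) -> str:
    """Canonical string form: ``A{k}N`` upstream, ``N{k}A`` downstream.

    When the flank residue is itself an asparagine the two sides would
    collide as plain strings (the printed convention distinguishes them by
    marking the sequon N typographically); the downstream form carries a
    ``_c`` suffix so every one of the 460 types has a unique key.
    """
    if side == N_SIDE:
        return f"{residue}{gap}N"
    name = f"N{gap}{residue}"
    return name + "_c" if residue == "N" else name


def enumerate_window_gds(window: SequonWindow | str) -> list[str]:
    """The 23 gapped dipeptides of a 25-mer window, in canonical slot order."""
    w = _window_str(window)
    if len(w) % 2 == 0 or len(w) < 5:
        raise ValueError(f"window length must be odd and >= 5, got {len(w)}")
    c = len(w) // 2
    out = []
    for side, k in gd_slots(len(w)):
        residue = w[c - 1 - k] if side == N_SIDE else w[c + 1 + k]
        out.append(gd_name(residue, side, k))
    return out


def enumerate_feature_space(l: int = 25) -> list[str]:
    """All realizable GD types over the 20 standard residues, canonical order.

    The C-terminal gap-1 slot is constrained to S/T by the sequon motif and
    both are excluded, so it contributes no types: 460 for l = 25.
    """
    return [
        gd_name(a, side, k) for side, k in gd_slots(l) for a in STANDARD_AA
    ]


@dataclass
class GDRTable:
    """Fitted gapped-dipeptide-ratio table.

    ``df`` is indexed by GD type (all 460 for l=25) with columns side, gap,
    pos_count, neg_count, gdr, normalized_gdr.  ``gdr`` is NaN where undefined
    (zero negative count without pseudocount, or never observed); undefined
    entries take the neutral value at encoding time and are excluded from the
    per-(gap, side) min-max ranking.
    """

    df: pd.DataFrame
    l: int
    total_pos: float
    total_neg: float
    pseudocount: float = 0.0

    def _norm_map(self) -> dict[str, float]:
        cached = getattr(self, "_norm_cache", None)
        if cached is None:
            s = self.df["normalized_gdr"].dropna()
            cached = dict(zip(s.index, s.to_numpy()))
            object.__setattr__(self, "_norm_cache", cached)
        return cached

    def encode(self, window: SequonWindow | str) -> np.ndarray:
        """23-vector of normalized GDRs for a window (neutral 0.5 fallback)."""
        lookup = self._norm_map()
        return np.array(
            [
                lookup.get(gd, NEUTRAL_GDR)
                for gd in enumerate_window_gds(_window_str(window))
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="dipeptide")

    @classmethod
    def from_tsv(cls, path: str | Path, l: int = 25) -> "GDRTable":
        df = pd.read_csv(path, sep="\t", index_col="dipeptide")
        return cls(df=df, l=l, total_pos=float(df["pos_count"].sum()),
                   total_neg=float(df["neg_count"].sum()))


def _labels_of(windows: Sequence, y: Sequence | None) -> np.ndarray:
    if y is not None:
        return np.asarray(y).astype(int)
    labels = []
    for w in windows:
        if w.label == POSITIVE:
            labels.append(1)
        elif w.label == NEGATIVE:
            labels.append(0)
        else:
            raise ValueError("unlabeled window in training data and no y given")
    return np.asarray(labels)


def fit_gdr(
    windows: Sequence[SequonWindow | str],
    y: Sequence[int] | None = None,
    l: int = 25,
    pseudocount: float = 0.0,
    denominator: str = "occurrences",
) -> GDRTable:
    """Count GD occurrences per class and compute raw GDRs.

    GDR = (pos_count / total positive occurrences) /
          (neg_count / total negative occurrences).
    With ``denominator="windows"`` the class totals are window counts instead;
    the two definitions differ by a constant factor per table, which cancels
    in min-max normalization.  GDs containing X or ambiguity letters carry no
    statistic and are not counted.  With the default zero pseudocount, a GD
    absent from negatives has an undefined GDR (NaN).
    """
    labels = _labels_of(windows, y)
    n_pos_windows = int((labels == 1).sum())
    n_neg_windows = int((labels == 0).sum())
    if n_pos_windows == 0 or n_neg_windows == 0:
        raise ValueError("need at least one positive and one negative window")
    if denominator not in ("occurrences", "windows"):
        raise ValueError(f"unknown denominator {denominator!r}")

    space = enumerate_feature_space(l)
    index = pd.Index(space, name="dipeptide")
    valid = set(space)
    pos_counter: Counter[str] = Counter()
    neg_counter: Counter[str] = Counter()
    for w, lab in zip(windows, labels):
        counter = pos_counter if lab == 1 else neg_counter
        for gd in enumerate_window_gds(_window_str(w)):
            if gd in valid:  # X / ambiguity letters in the flank carry no statistic
                counter[gd] += 1
    pos_count = pd.Series([float(pos_counter.get(gd, 0)) for gd in space], index=index)
    neg_count = pd.Series([float(neg_counter.get(gd, 0)) for gd in space], index=index)

    if denominator == "occurrences":
        total_pos = float(pos_count.sum())
        total_neg = float(neg_count.sum())
    else:
        total_pos = float(n_pos_windows)
        total_neg = float(n_neg_windows)

    eps = pseudocount
    pc, nc = pos_count + eps, neg_count + eps
    with np.errstate(divide="ignore", invalid="ignore"):
        gdr = (pc / total_pos) / (nc / total_neg)
    gdr = gdr.where(nc > 0)  # zero negatives -> undefined
    gdr = gdr.where((pos_count + neg_count + eps) > 0)  # never observed -> undefined

    sides = [s for s, k in gd_slots(l) for _ in STANDARD_AA]
    gaps = [k for s, k in gd_slots(l) for _ in STANDARD_AA]
    df = pd.DataFrame(
        {
            "side": sides,
            "gap": gaps,
            "pos_count": pos_count,
            "neg_count": neg_count,
            "gdr": gdr,
            "normalized_gdr": np.nan,
        },
        index=index,
    )
    return GDRTable(df=df, l=l, total_pos=total_pos, total_neg=total_neg,
                    pseudocount=pseudocount)


def normalize_gdr(table: GDRTable) -> GDRTable:
    """Min-max normalize GDRs within each (gap, side) class to [0, 1].

    Undefined GDRs stay NaN.  A degenerate class (all defined GDRs equal)
    maps to the neutral midpoint 0.5.
    """
    df = table.df.copy()
    norm = pd.Series(np.nan, index=df.index)
    for (_, _), grp in df.groupby(["side", "gap"], sort=False):
        defined = grp["gdr"].dropna()
        if defined.empty:
            continue
        lo, hi = defined.min(), defined.max()
        if hi > lo:
            norm.loc[defined.index] = (defined - lo) / (hi - lo)
        else:
            norm.loc[defined.index] = NEUTRAL_GDR
    df["normalized_gdr"] = norm
    return GDRTable(df=df, l=table.l, total_pos=table.total_pos,
                    total_neg=table.total_neg, pseudocount=table.pseudocount)


def encode_gd(window: SequonWindow | str, table: GDRTable) -> np.ndarray:
    """Thin wrapper over :meth:`GDRTable.encode`."""
    return table.encode(window)


class GappedDipeptideEncoder(BaseEstimator, TransformerMixin):
    """Transformer: sequon windows -> 23-dimensional normalized-GDR vectors.

    Parameters
    ----------
    l : window length (odd), default 25.
    pseudocount : additive count smoothing, default 0 (ratios reproduce the
        raw odds ratios exactly; absent-from-negatives GDs stay undefined).
    """

    def __init__(self, l: int = 25, pseudocount: float = 0.0):
        self.l = l
        self.pseudocount = pseudocount

    def fit(self, X: Sequence[SequonWindow | str], y: Sequence[int] | None = None):
        table = fit_gdr(list(X), y=y, l=self.l, pseudocount=self.pseudocount)
        self.table_ = normalize_gdr(table)
        self.n_features_out_ = len(gd_slots(self.l))
        return self

    def transform(self, X: Sequence[SequonWindow | str]) -> np.ndarray:
        if not hasattr(self, "table_"):
            raise RuntimeError("GappedDipeptideEncoder is not fitted")
        return np.vstack([self.table_.encode(w) for w in X])
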