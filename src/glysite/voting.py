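"""Protein-level similarity voting from homology-search hit lists.

Stage one of the predictor scores whole proteins.  For each protein P a
profile-HMM homology search (run externally) yields a hit list; hits with
reported probability >= 0.5 form the similar-protein set S(P).  A training
protein P becomes a *template* for a query Q when |S(Q) ∩ S(P)| >= k
(default 5).  Templates vote with weight overlap^2:

    V_G  = sum over glycoprotein templates of |S(Q) ∩ S(P_i)|^2
    V_NG = sum over non-glycoprotein templates of |S(Q) ∩ S(P_j)|^2

and the protein score is V_G / (V_G + V_NG), in [0, 1].  A query with no
templates has an undefined score (NaN), which downstream integration treats
as "no adjustment".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import GLYCOPROTEIN, NON_GLYCOPROTEIN

PROB_THRESHOLD = 0.5
K_MIN = 5

#: header tokens that may legitimately start a non-data line in a hit list
_HEADER_STARTS = ("#", "no ", "hit_id", "query", "rank")


@dataclass(frozen=True)
class HomologSet:
    """Similar-protein set S(P): retained hits with their probabilities."""

    protein_id: str
    members: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.protein_id in self.members:
            raise ValueError(f"{self.protein_id}: self-hit retained in members")
        bad = {m: p for m, p in self.members.items() if not (0.0 <= p <= 1.0)}
        if bad:
            raise ValueError(f"{self.protein_id}: probabilities outside [0,1]: {bad}")

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass
class TemplateIndex:
    """Training-side lookup: protein id -> (similar-protein set, binary label)."""

    entries: dict[str, tuple[HomologSet, str]] = field(default_factory=dict)

    def add(self, homolog_set: HomologSet, label: str) -> None:
        if label not in (GLYCOPROTEIN, NON_GLYCOPROTEIN):
            raise ValueError(f"template label must be binary, got {label!r}")
        if homolog_set.protein_id in self.entries:
            raise ValueError(f"duplicate template id {homolog_set.protein_id!r}")
        self.entries[homolog_set.protein_id] = (homolog_set, label)

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for pid, (hs, label) in self.entries.items():
            members = ",".join(f"{m}:{p:.4f}" for m, p in sorted(hs.members.items()))
            rows.append((pid, label, members))
        pd.DataFrame(rows, columns=["protein_id", "label", "members"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TemplateIndex":
        df = pd.read_csv(path, sep="\t", dtype=str)
        index = cls()
        for row in df.itertuples(index=False):
            members = {}
            if isinstance(row.members, str) and row.members:
                for item in row.members.split(","):
                    mid, prob = item.rsplit(":", 1)
                    members[mid] = float(prob)
            index.add(HomologSet(protein_id=row.protein_id, members=members), row.label)
        return index


def parse_hit_list(
    path: str | Path,
    query_id: str | None = None,
    prob_threshold: float = PROB_THRESHOLD,
) -> HomologSet:
    """Parse a homology-search hit list into a HomologSet.

    Accepts either a simplified two-column table (hit id, probability) or the
    profile-search tool's ranked summary lines (rank, hit id, probability, ...).
    Probabilities above 1 are interpreted as percentages and divided by 100.
    Hits below ``prob_threshold`` and self-hits (hit id == query id) are
    dropped.  ``query_id`` defaults to the file's stem.
    """
    path = Path(path)
    if query_id is None:
        query_id = path.stem
    members: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.lower().startswith(_HEADER_STARTS):
                continue
            fields = line.split()
            try:
                if len(fields) >= 3 and fields[0].isdigit():
                    hit_id, prob = fields[1], float(fields[2])
                elif len(fields) >= 2:
                    hit_id, prob = fields[0], float(fields[1])
                else:
                    raise ValueError("too few columns")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable hit line ({exc})")
            if prob > 1.0:
                prob /= 100.0
            if hit_id == query_id or prob < prob_threshold:
                continue
            members[hit_id] = prob
    return HomologSet(protein_id=query_id, members=members)


def find_templates(
    query: HomologSet, index: TemplateIndex, k_min: int = K_MIN
) -> list[tuple[str, int, str]]:
    """Templates of a query: index entries sharing >= k_min similar proteins.

    Returns (template id, overlap size, label) triples.  The query's own id,
    if present in the index, is skipped (leave-self-out).
    """
    q = query.ids
    out = []
    for pid, (hs, label) in index.entries.items():
        if pid == query.protein_id:
            continue
        overlap = len(q & hs.ids)
        if overlap >= k_min:
            out.append((pid, overlap, label))
    return out


@dataclass
class VotingResult:
    protein_id: str
    v_g: float
    v_ng: float
    templates: list[tuple[str, int, str]]

    @property
    def score(self) -> float:
        """V_G / (V_G + V_NG); NaN when the query has no templates."""
        total = self.v_g + self.v_ng
        return self.v_g / total if total > 0 else float("nan")


def voting_score(query: HomologSet, templates: Sequence[tuple[str, int, str]]) -> VotingResult:
    """Squared-overlap vote over the query's templates."""
    v_g = float(sum(o * o for _, o, lab in templates if lab == GLYCOPROTEIN))
    v_ng = float(sum(o * o for _, o, lab in templates if lab == NON_GLYCOPROTEIN))
    return VotingResult(protein_id=query.protein_id, v_g=v_g, v_ng=v_ng,
                        templates=list(templates))


def score_interval_summary(
    scores: Sequence[float], is_glycoprotein: Sequence[bool]
) -> pd.DataFrame:
    """Bin defined protein scores into five intervals and report the
    glycoprotein fraction p_i per interval.

    Intervals are [0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8), [0.8,1.0]; the
    last is closed so a score of exactly 1 is counted.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(is_glycoprotein, dtype=bool)
    defined = ~np.isnan(scores)
    scores, labels = scores[defined], labels[defined]
    edges = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
    rows = []
    for i in range(5):
        lo, hi = edges[i], edges[i + 1]
        mask = (scores >= lo) & ((scores < hi) | (i == 4) & (scores <= hi))
        n = int(mask.sum())
        n_glyco = int(labels[mask].sum())
        rows.append(
            {
                "interval": f"[{lo:.1f},{hi:.1f}" + ("]" if i == 4 else ")"),
                "n": n,
                "n_glycoproteins": n_glyco,
                "p": n_glyco / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


class SimilarityVotingClassifier(BaseEstimator, ClassifierMixin):
    """Protein-level glycoprotein classifier by homolog-set similarity voting.

    fit(X, y) with X a sequence of HomologSet and y binary labels
    (1 = glycoprotein) builds the template index; ``score_proteins`` returns
    the voting score per query (NaN when no template matches), ``predict``
    thresholds the score at 0.5.
    """

    def __init__(self, k_min: int = K_MIN):
        self.k_min = k_min

    def fit(self, X: Sequence[HomologSet], y: Sequence[int]):
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        index = TemplateIndex()
        for hs, lab in zip(X, y):
            index.add(hs, GLYCOPROTEIN if lab == 1 else NON_GLYCOPROTEIN)
        self.index_ = index
        self.classes_ = np.array([0, 1])
        return self

    def vote(self, homolog_set: HomologSet) -> VotingResult:
        if not hasattr(self, "index_"):
            raise RuntimeError("SimilarityVotingClassifier is not fitted")
        templates = find_templates(homolog_set, self.index_, k_min=self.k_min)
        return voting_score(homolog_set, templates)

    def score_proteins(self, X: Sequence[HomologSet]) -> np.ndarray:
        return np.array([self.vote(hs).score for hs in X])

    def predict(self, X: Sequence[HomologSet]) -> np.ndarray:
        scores = self.score_proteins(X)
        with np.errstate(invalid="ignore"):
            return (scores > 0.5).astype(int)
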