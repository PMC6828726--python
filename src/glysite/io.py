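"""Sequence and annotation input: FASTA parsing, sequon location, window extraction.

N-linked glycosylation occurs almost exclusively at the asparagine of
N-X-S/T sequons (X any residue except proline).  This module locates those
sequons, extracts fixed-length sequence windows centred on the sequon
asparagine, and joins them with site-level annotations (experimentally
validated glycosite / non-glycosite / excluded evidence) to build labelled
datasets for the downstream classifiers.

Coordinates are 1-based and inclusive throughout, matching UniProt site
numbering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

# protein labels
GLYCOPROTEIN = "glycoprotein"
NON_GLYCOPROTEIN = "non_glycoprotein"
UNKNOWN = "unknown"

# site annotation statuses
VALIDATED = "validated_glycosite"
NON_SITE = "non_glycosite"
EXCLUDED = "excluded_evidence"

# window labels
POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: letters carrying no residue identity usable by the featurizers; 'X' is also
#: the padding character for positions outside the protein.
AMBIGUOUS_AA = frozenset("XBZUO")

_STATUS_ALIASES = {
    "validated_glycosite": VALIDATED,
    "glycosite": VALIDATED,
    "validated": VALIDATED,
    "experimental": VALIDATED,
    "positive": VALIDATED,
    "non_glycosite": NON_SITE,
    "non-glycosite": NON_SITE,
    "negative": NON_SITE,
    "excluded_evidence": EXCLUDED,
    "excluded": EXCLUDED,
    "probable": EXCLUDED,
    "potential": EXCLUDED,
    "by sequence similarity": EXCLUDED,
    "by similarity": EXCLUDED,
}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an optional protein-level glycosylation label."""

    id: str
    sequence: str
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        if self.label not in (GLYCOPROTEIN, NON_GLYCOPROTEIN, UNKNOWN):
            raise ValueError(f"protein {self.id!r}: unknown label {self.label!r}")


@dataclass(frozen=True)
class SiteAnnotation:
    """Evidence status of one asparagine (1-based position) in a protein."""

    protein_id: str
    position: int
    status: str

    def __post_init__(self) -> None:
        if self.status not in (VALIDATED, NON_SITE, EXCLUDED):
            raise ValueError(f"unknown annotation status {self.status!r}")


@dataclass(frozen=True)
class SequonWindow:
    """An l-mer centred on a sequon asparagine (default l = 25).

    Positions outside the protein are padded with 'X'.  The centre residue is
    the sequon N and the residue two positions downstream is S or T.
    """

    protein_id: str
    position: int
    window: str
    label: str = UNLABELED

    def __post_init__(self) -> None:
        l = len(self.window)
        if l % 2 == 0 or l < 5:
            raise ValueError(f"window length must be odd and >= 5, got {l}")
        c = l // 2
        if self.window[c] != "N":
            raise ValueError(f"window centre must be 'N', got {self.window[c]!r}")
        if self.window[c + 2] not in "ST":
            raise ValueError(
                f"residue two downstream of the sequon N must be S/T, got "
                f"{self.window[c + 2]!r}"
            )
        if self.label not in (POSITIVE, NEGATIVE, UNLABELED):
            raise ValueError(f"unknown window label {self.label!r}")

    @property
    def l(self) -> int:
        return len(self.window)


@dataclass(frozen=True)
class AnnotatedWindow:
    """A sequon window together with per-residue predicted surface
    accessibility (E/B) and secondary structure (H/E/C) strings.

    Padding positions (outside the protein) carry '-' in both strings.
    Either string may be None when the corresponding predictor output is
    unavailable; featurizers then fall back to sequence-only features.
    """

    window: SequonWindow
    sa: str | None = None
    ss: str | None = None

    def __post_init__(self) -> None:
        for name, s in (("sa", self.sa), ("ss", self.ss)):
            if s is not None and len(s) != self.window.l:
                raise ValueError(
                    f"{name} string length {len(s)} != window length {self.window.l}"
                )


def parse_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into ProteinRecords.

    Sequences are uppercased and '*' stop characters stripped.  Raises on an
    empty sequence or a duplicated id, naming the offending entry.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().replace("*", "")
        if not entry.id:
            raise ValueError(f"{path}: FASTA entry with empty header")
        if not seq:
            raise ValueError(f"{path}: entry {entry.id!r} has an empty sequence")
        if entry.id in seen:
            raise ValueError(f"{path}: duplicated id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    return records


def find_sequons(
    sequence: str,
    exclude_center_proline: bool = True,
    include_ambiguous_middle: bool = False,
) -> list[int]:
    """Return 1-based positions of sequon asparagines (N-X-S/T).

    N-X-C sequons are never reported.  With ``exclude_center_proline`` (the
    default) N-P-S/T is skipped, following the motif definition.  Middle
    residues that carry no identity (X and the ambiguity letters B/Z/U/O) are
    skipped by default as well, since the proline exclusion cannot be checked
    for them.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    positions: list[int] = []
    for i in range(len(sequence) - 2):
        if sequence[i] != "N" or sequence[i + 2] not in "ST":
            continue
        mid = sequence[i + 1]
        if exclude_center_proline and mid == "P":
            continue
        if not include_ambiguous_middle and mid in AMBIGUOUS_AA:
            continue
        positions.append(i + 1)
    return positions


def extract_window(
    sequence: str,
    position: int,
    l: int = 25,
    protein_id: str = "",
    label: str = UNLABELED,
) -> SequonWindow:
    """Extract the l-mer centred on the sequon N at ``position`` (1-based).

    Flanks outside the protein are padded with 'X'.
    """
    if l % 2 == 0 or l < 5:
        raise ValueError(f"l must be odd and >= 5, got {l}")
    if not (1 <= position <= len(sequence)):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    if sequence[position - 1] != "N":
        raise ValueError(f"position {position} is {sequence[position - 1]!r}, not 'N'")
    if position + 1 > len(sequence) - 1 or sequence[position + 1] not in "ST":
        raise ValueError(f"position {position} is not an N-X-S/T sequon")
    half = l // 2
    start = position - 1 - half
    chars = []
    for i in range(start, start + l):
        chars.append(sequence[i] if 0 <= i < len(sequence) else "X")
    return SequonWindow(protein_id=protein_id, position=position, window="".join(chars), label=label)


def load_annotations(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> list[SiteAnnotation]:
    """Read a site-annotation table (TSV or CSV, header protein_id,position,status).

    Evidence statuses such as 'Probable', 'Potential' or 'By sequence
    similarity' map to ``excluded_evidence``: such sites are retained in the
    returned list but never enter training or evaluation datasets.  Every row
    is validated against the sequences (the annotated residue must be N).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"protein_id", "position", "status"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: annotation table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    by_id = {p.id: p for p in proteins}
    out: list[SiteAnnotation] = []
    for row in df.itertuples(index=False):
        pid = str(row.protein_id)
        pos = int(row.position)
        raw = str(row.status).strip().lower()
        status = _STATUS_ALIASES.get(raw)
        if status is None:
            raise ValueError(f"{path}: unknown status {row.status!r} for {pid}:{pos}")
        if pid not in by_id:
            raise ValueError(f"{path}: annotation for unknown protein {pid!r}")
        seq = by_id[pid].sequence
        if not (1 <= pos <= len(seq)) or seq[pos - 1] != "N":
            residue = seq[pos - 1] if 1 <= pos <= len(seq) else "<out of range>"
            raise ValueError(
                f"{path}: {pid} position {pos} is {residue!r}, not an asparagine"
            )
        out.append(SiteAnnotation(protein_id=pid, position=pos, status=status))
    return out


def build_dataset(
    proteins: Sequence[ProteinRecord],
    annotations: Iterable[SiteAnnotation],
    l: int = 25,
    exclude_center_proline: bool = True,
    include_ambiguous_middle: bool = False,
) -> list[SequonWindow]:
    """Assemble labelled sequon windows from proteins and site annotations.

    Positives are experimentally validated glycosites.  Negatives are the
    unannotated (or explicitly negative) sequons of glycoproteins plus all
    sequons of non-glycoproteins.  Excluded-evidence sequons are omitted
    entirely.  Sequons of proteins with an ``unknown`` label and no annotation
    are emitted unlabeled (prediction inputs).
    """
    status_at = {(a.protein_id, a.position): a.status for a in annotations}
    windows: list[SequonWindow] = []
    for protein in proteins:
        for pos in find_sequons(
            protein.sequence,
            exclude_center_proline=exclude_center_proline,
            include_ambiguous_middle=include_ambiguous_middle,
        ):
            status = status_at.get((protein.id, pos))
            if status == EXCLUDED:
                continue
            if status == VALIDATED:
                label = POSITIVE
            elif status == NON_SITE:
                label = NEGATIVE
            elif protein.label in (GLYCOPROTEIN, NON_GLYCOPROTEIN):
                label = NEGATIVE
            else:
                label = UNLABELED
            windows.append(
                extract_window(protein.sequence, pos, l=l, protein_id=protein.id, label=label)
            )
    return windows


def annotate_windows(
    windows: Sequence[SequonWindow],
    sa_by_protein: Mapping[str, str] | None,
    ss_by_protein: Mapping[str, str] | None,
) -> list[AnnotatedWindow]:
    """Attach per-residue SA/SS strings (protein-level) to sequon windows.

    The protein-level strings are sliced with the same coordinates as the
    windows; positions outside the protein are padded with '-'.
    """

    def _slice(full: str | None, pos: int, l: int) -> str | None:
        if full is None:
            return None
        half = l // 2
        start = pos - 1 - half
        return "".join(
            full[i] if 0 <= i < len(full) else "-" for i in range(start, start + l)
        )

    out = []
    for w in windows:
        sa_full = sa_by_protein.get(w.protein_id) if sa_by_protein else None
        ss_full = ss_by_protein.get(w.protein_id) if ss_by_protein else None
        out.append(
            AnnotatedWindow(
                window=w,
                sa=_slice(sa_full, w.position, w.l),
                ss=_slice(ss_full, w.position, w.l),
            )
        )
    return out


def read_residue_classes(path: str | Path) -> tuple[str, str]:
    """Parse a whitespace-delimited per-residue class table into (sa, ss) strings.

    Adapter for external surface-accessibility / secondary-structure
    predictors.  The table must carry columns named ``position``, ``residue``
    and at least one of ``sa`` (classes E/B) and ``ss`` (classes H/E/C); rows
    must cover positions 1..L.  Any tool producing per-residue class calls can
    be exported to this form.
    """
    df = pd.read_csv(path, sep=r"\s+", engine="python")
    cols = {c.lower(): c for c in df.columns}
    if "position" not in cols or "residue" not in cols:
        raise ValueError(f"{path}: need 'position' and 'residue' columns")
    df = df.sort_values(cols["position"])
    positions = df[cols["position"]].to_numpy()
    if positions[0] != 1 or not (positions == range(1, len(df) + 1)).all():
        raise ValueError(f"{path}: positions must be contiguous from 1")

    def _col(name: str, allowed: str) -> str:
        if name not in cols:
            return ""
        s = "".join(df[cols[name]].astype(str).str.upper())
        bad = set(s) - set(allowed)
        if bad:
            raise ValueError(f"{path}: invalid {name} classes {sorted(bad)}")
        return s

    return _col("sa", "EB-"), _col("ss", "HEC-")
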