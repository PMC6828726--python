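"""Deterministic synthetic data for the full two-stage pipeline.

Generates every input the pipeline consumes — protein FASTA records with
planted N-X-S/T sequons and site annotations, per-residue surface
accessibility / secondary-structure class strings, and homolog-set universes
with controllable within-class overlap — in the exact file formats the real
pipeline reads.

What the generator emulates: labelled sequon windows whose flanks sample
chosen gapped dipeptides at an enriched rate in glycosites; SA/SS strings
whose sequon-adjacent classes differ between glycosites and non-glycosites
by a configurable effect; and homology universes in which same-label
proteins share more similar-protein-set members.  What it does not emulate:
real amino-acid composition, sequence evolution, or profile-HMM alignment
statistics — passing tests on this data demonstrate correct mechanics and
signal recovery, not field performance on real proteomes.

Each generator operation draws from its own stream derived from the master
seed with a fixed per-operation tag, so adding an operation never shifts
another operation's draws.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import (
    GLYCOPROTEIN,
    NON_GLYCOPROTEIN,
    NON_SITE,
    STANDARD_AA,
    VALIDATED,
    ProteinRecord,
    SiteAnnotation,
)
from .voting import HomologSet, TemplateIndex

_STREAMS = {"proteins": 1, "annotations": 2, "homologs": 3}

_GD_RE = re.compile(r"^([A-Z])(\d+)N$|^N(\d+)([A-Z])$")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic pipeline inputs.

    Protein counts and the two-thirds glycosite fraction mirror the scale of
    curated human glycoprotein training sets (about two glycosylated sequons
    for every non-glycosylated one within glycoproteins); lengths follow a
    lognormal around 400 residues, typical of secreted human proteins.
    Effect parameters default to null (no planted signal) — tests and
    simulations state their planted conditions explicitly.
    """

    seed: int = 0
    n_glycoproteins: int = 80
    n_non_glycoproteins: int = 80
    mean_length: float = 400.0
    length_sigma: float = 0.35
    min_length: int = 80
    max_length: int = 1200
    sequons_per_protein: float = 4.0
    positive_fraction: float = 2.0 / 3.0
    l: int = 25
    #: (gapped dipeptide, positive enrichment factor) pairs, e.g. ("W5N", 3.0);
    #: factor f plants the residue at rate f/20 in glycosite flanks vs the
    #: uniform 1/20 background elsewhere.
    planted_dipeptides: tuple[tuple[str, float], ...] = ()
    #: added exposure probability at sequon-adjacent positions of glycosites
    sa_effect: float = 0.0
    #: added coil probability at sequon-adjacent positions of glycosites
    ss_effect: float = 0.0
    #: how many residues on each side of the sequon carry the SA/SS effect
    effect_width: int = 4
    sa_exposed_base: float = 0.5
    ss_base: tuple[float, float, float] = (0.30, 0.20, 0.50)  # H, E, C
    n_universe: int = 300
    mean_set_size: float = 40.0
    overlap_boost: float = 0.6

    def __post_init__(self) -> None:
        if self.n_glycoproteins <= 0 or self.n_non_glycoproteins <= 0:
            raise ValueError("protein counts must be positive")
        for gd, f in self.planted_dipeptides:
            if f <= 0:
                raise ValueError(f"enrichment factor for {gd} must be > 0")
            if not _GD_RE.match(gd):
                raise ValueError(f"malformed gapped dipeptide {gd!r}")
        if not (0.0 <= self.overlap_boost <= 1.0):
            raise ValueError("overlap_boost must lie in [0, 1]")


def _rng(config: GeneratorConfig, op: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[op]])


def _gd_offset(gd: str) -> int:
    """Signed offset of a gapped dipeptide's flank residue from the sequon N."""
    m = _GD_RE.match(gd)
    assert m is not None
    if m.group(1) is not None:  # AkN, upstream
        return -(int(m.group(2)) + 1)
    return int(m.group(3)) + 1  # NkA, downstream


def _gd_residue(gd: str) -> str:
    m = _GD_RE.match(gd)
    assert m is not None
    return m.group(1) or m.group(4)


def generate_proteins(
    config: GeneratorConfig,
) -> tuple[list[ProteinRecord], list[SiteAnnotation]]:
    """Synthesize labelled proteins with planted, annotated sequons.

    Every planted sequon is annotated (validated glycosite or non-glycosite);
    sequons arising by chance in the random background are left unannotated
    and become negatives downstream, as in real datasets.  Glycosite flanks
    sample the configured planted dipeptides at enriched rates.
    """
    rng = _rng(config, "proteins")
    aa = np.array(list(STANDARD_AA))
    proteins: list[ProteinRecord] = []
    annotations: list[SiteAnnotation] = []
    half = config.l // 2
    n_total = config.n_glycoproteins + config.n_non_glycoproteins
    for i in range(n_total):
        is_glyco = i < config.n_glycoproteins
        pid = f"{'G' if is_glyco else 'NG'}{i:04d}"
        mu = np.log(config.mean_length) - config.length_sigma**2 / 2
        length = int(np.clip(rng.lognormal(mu, config.length_sigma),
                             config.min_length, config.max_length))
        seq = rng.choice(aa, size=length)
        # plant sequons at well-separated slots so windows never overlap
        slots = np.arange(half + 1, length - half - 1, config.l + 3)
        n_seq = min(len(slots), max(1, rng.poisson(config.sequons_per_protein)))
        positions = np.sort(rng.choice(slots, size=n_seq, replace=False))
        for pos in positions:  # pos is 1-based
            j = pos - 1
            seq[j] = "N"
            seq[j + 1] = rng.choice([a for a in STANDARD_AA if a not in "PNST"])
            seq[j + 2] = rng.choice(["S", "T"])
            positive = bool(is_glyco and rng.random() < config.positive_fraction)
            if positive:
                for gd, factor in config.planted_dipeptides:
                    off = _gd_offset(gd)
                    k = j + off
                    # never overwrite the sequon triplet (offsets 0..+2)
                    if not (0 <= k < length) or 0 <= off <= 2:
                        continue
                    p = min(factor / 20.0, 0.95)
                    if rng.random() < p:
                        seq[k] = _gd_residue(gd)
                    else:
                        seq[k] = rng.choice([a for a in STANDARD_AA if a != _gd_residue(gd)])
            annotations.append(
                SiteAnnotation(
                    protein_id=pid,
                    position=int(pos),
                    status=VALIDATED if positive else NON_SITE,
                )
            )
        proteins.append(
            ProteinRecord(
                id=pid,
                sequence="".join(seq),
                label=GLYCOPROTEIN if is_glyco else NON_GLYCOPROTEIN,
            )
        )
    return proteins, annotations


def generate_residue_annotations(
    proteins: Sequence[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    config: GeneratorConfig,
) -> tuple[dict[str, str], dict[str, str]]:
    """Protein-level SA (E/B) and SS (H/E/C) strings with class-conditional
    effects at glycosite-adjacent positions.

    Returns (sa_by_protein, ss_by_protein).  With both effects at zero the
    strings are label-independent (null model).
    """
    rng = _rng(config, "annotations")
    positives = {
        (a.protein_id, a.position) for a in annotations if a.status == VALIDATED
    }
    sa_map: dict[str, str] = {}
    ss_map: dict[str, str] = {}
    h, e, c = config.ss_base
    for protein in proteins:
        length = len(protein.sequence)
        p_exposed = np.full(length, config.sa_exposed_base)
        p_coil = np.tile([h, e, c], (length, 1))
        for (pid, pos) in positives:
            if pid != protein.id:
                continue
            j = pos - 1
            lo = max(0, j - config.effect_width)
            hi = min(length, j + 3 + config.effect_width)
            p_exposed[lo:hi] = np.clip(
                p_exposed[lo:hi] + config.sa_effect, 0.0, 0.98
            )
            shifted = np.array(
                [h - config.ss_effect / 2, e - config.ss_effect / 2, c + config.ss_effect]
            )
            shifted = np.clip(shifted, 0.01, None)
            p_coil[lo:hi] = shifted / shifted.sum()
        sa = np.where(rng.random(length) < p_exposed, "E", "B")
        ss_draws = rng.random(length)
        cum = np.cumsum(p_coil, axis=1)
        ss = np.where(
            ss_draws < cum[:, 0], "H", np.where(ss_draws < cum[:, 1], "E", "C")
        )
        sa_map[protein.id] = "".join(sa)
        ss_map[protein.id] = "".join(ss)
    return sa_map, ss_map


def generate_homolog_universe(
    config: GeneratorConfig,
    labels: Mapping[str, bool],
) -> dict[str, HomologSet]:
    """Similar-protein sets over a synthetic universe of member ids.

    The universe is split into two halves; a protein draws each member from
    its own label's half with probability 0.5 + overlap_boost/2, so
    same-label proteins overlap more.  With boost 0 membership is
    label-blind.  Hit probabilities are uniform on [0.5, 1].
    """
    rng = _rng(config, "homologs")
    universe = np.array([f"U{i:05d}" for i in range(config.n_universe)])
    half = config.n_universe // 2
    halves = {True: universe[:half], False: universe[half:]}
    p_own = 0.5 + config.overlap_boost / 2.0
    sets: dict[str, HomologSet] = {}
    for pid, is_glyco in labels.items():
        size = max(1, rng.poisson(config.mean_set_size))
        n_own = rng.binomial(size, p_own)
        own = halves[bool(is_glyco)]
        other = halves[not bool(is_glyco)]
        members = np.concatenate(
            [
                rng.choice(own, size=min(n_own, len(own)), replace=False),
                rng.choice(other, size=min(size - n_own, len(other)), replace=False),
            ]
        )
        probs = rng.uniform(0.5, 1.0, size=len(members))
        sets[pid] = HomologSet(
            protein_id=pid, members=dict(zip(members.tolist(), probs.tolist()))
        )
    return sets


def build_template_index(
    sets: Mapping[str, HomologSet], labels: Mapping[str, bool]
) -> TemplateIndex:
    index = TemplateIndex()
    for pid, hs in sets.items():
        index.add(hs, GLYCOPROTEIN if labels[pid] else NON_GLYCOPROTEIN)
    return index


def write_hit_lists(
    sets: Mapping[str, HomologSet],
    directory: str | Path,
    config: GeneratorConfig | None = None,
) -> None:
    """Write one hit-list TSV per protein (hit_id, probability).

    Each file also carries a self-hit and a couple of sub-threshold decoy
    hits, which a correct parser must drop.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed if config else 0, 4])
    for pid, hs in sets.items():
        lines = [f"{pid}\t1.000"]  # self-hit
        for mid, prob in sorted(hs.members.items()):
            lines.append(f"{mid}\t{prob:.4f}")
        for d in range(2):  # decoys below the 0.5 probability floor
            lines.append(f"DECOY{d:02d}\t{rng.uniform(0.05, 0.45):.4f}")
        (directory / f"{pid}.tsv").write_text("\n".join(lines) + "\n")


def write_fasta(proteins: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def write_annotations(annotations: Sequence[SiteAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tstatus\n")
        for a in annotations:
            fh.write(f"{a.protein_id}\t{a.position}\t{a.status}\n")


def write_protein_labels(proteins: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tlabel\n")
        for p in proteins:
            fh.write(f"{p.id}\t{p.label}\n")


def write_residue_classes(
    proteins: Sequence[ProteinRecord],
    sa_map: Mapping[str, str],
    ss_map: Mapping[str, str],
    directory: str | Path,
) -> None:
    """Write per-protein per-residue class tables (position residue sa ss)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for p in proteins:
        sa, ss = sa_map[p.id], ss_map[p.id]
        with open(directory / f"{p.id}.tsv", "w") as fh:
            fh.write("position\tresidue\tsa\tss\n")
            for i, residue in enumerate(p.sequence, start=1):
                fh.write(f"{i}\t{residue}\t{sa[i - 1]}\t{ss[i - 1]}\n")
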