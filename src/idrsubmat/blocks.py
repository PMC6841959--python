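"""Disorder labeling, alignment-block extraction, clustering and binning.

A residue is called disordered only when two independent annotations agree:
its disorder score reaches the threshold (default 0.5) *and* its predicted
secondary structure is coil. Alignment columns in which every residue is
disordered and no row is gapped become the counting substrate ("disordered
blocks") for substitution-matrix estimation; columns with gaps or mixed
structural states are discarded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align

from .io import (
    CANONICAL_ALPHABET,
    GAP,
    Alignment,
    ProteinSequence,
    ResidueAnnotation,
)


class ResidueLabel(enum.Enum):
    DISORDERED = "D"
    ORDERED = "O"
    GAP = "-"


@dataclass(frozen=True)
class ResidueLabelTrack:
    """Per-residue DISORDERED/ORDERED calls for one (ungapped) sequence."""

    seq_id: str
    labels: tuple[ResidueLabel, ...]

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class DisorderedBlockSet:
    """Gap-free, all-disordered alignment columns pooled for pair counting."""

    columns: tuple[tuple[str, ...], ...]
    source_family: str = ""

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def __iter__(self):
        return iter(self.columns)


@dataclass(frozen=True)
class ClusterSet:
    """Greedy identity clustering result: a partition with one centroid each."""

    identity_threshold: float
    clusters: tuple[tuple[str, ...], ...]
    centroids: tuple[str, ...]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


class DisorderBin(enum.Enum):
    """Disorder-content bins: LD (0-20%], MD (20-40%], HD (40-100%]."""

    LD = (0.0, 20.0)
    MD = (20.0, 40.0)
    HD = (40.0, 100.0)


DEFAULT_DISORDER_THRESHOLD = 0.5
MIN_SEQUENCE_LENGTH = 100


def label_residues(
    ann: ResidueAnnotation, threshold: float = DEFAULT_DISORDER_THRESHOLD
) -> ResidueLabelTrack:
    """Call each residue DISORDERED iff score >= threshold and state is coil."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    labels = tuple(
        ResidueLabel.DISORDERED
        if score >= threshold and state == "C"
        else ResidueLabel.ORDERED
        for score, state in zip(ann.disorder_scores, ann.ss_states)
    )
    return ResidueLabelTrack(seq_id=ann.seq_id, labels=labels)


def project_labels(
    alignment: Alignment, tracks: Sequence[ResidueLabelTrack]
) -> list[list[ResidueLabel]]:
    """Spread each row's residue labels across its gapped alignment row.

    Returns a grid indexed [row][column]; gap cells carry ``ResidueLabel.GAP``.
    """
    by_id = {t.seq_id: t for t in tracks}
    grid: list[list[ResidueLabel]] = []
    for rid, row in alignment.rows:
        track = by_id.get(rid)
        if track is None:
            raise KeyError(f"no label track for alignment row {rid!r}")
        ungapped_len = len(row) - row.count(GAP)
        if len(track) != ungapped_len:
            raise ValueError(
                f"{rid}: track length {len(track)} != ungapped length {ungapped_len}"
            )
        cells: list[ResidueLabel] = []
        k = 0
        for c in row:
            if c == GAP:
                cells.append(ResidueLabel.GAP)
            else:
                cells.append(track.labels[k])
                k += 1
        grid.append(cells)
    return grid


def extract_disordered_columns(
    grid: Sequence[Sequence[ResidueLabel]],
    alignment: Alignment,
    which: ResidueLabel = ResidueLabel.DISORDERED,
) -> DisorderedBlockSet:
    """Keep columns that are gap-free and uniformly ``which``-labeled.

    Columns containing any gap, any residue of the opposite structural state,
    or any non-canonical residue are dropped. ``which=ResidueLabel.ORDERED``
    extracts the ordered-column counterpart used for control matrices.
    """
    kept: list[tuple[str, ...]] = []
    for j in range(alignment.n_columns):
        ok = True
        for i in range(alignment.n_rows):
            if grid[i][j] is not which:
                ok = False
                break
        if not ok:
            continue
        column = alignment.column(j)
        if all(r in CANONICAL_ALPHABET for r in column):
            kept.append(column)
    return DisorderedBlockSet(columns=tuple(kept))


def pool_blocks(per_family: Iterable[DisorderedBlockSet]) -> DisorderedBlockSet:
    """Concatenate block sets from several families into one counting pool."""
    columns: list[tuple[str, ...]] = []
    for bs in per_family:
        columns.extend(bs.columns)
    return DisorderedBlockSet(columns=tuple(columns), source_family="pooled")


def write_blocks_tsv(
    blocks: DisorderedBlockSet, path: str | Path, family_id: str | None = None
) -> None:
    """One column per line: concatenated residues, then the family id."""
    fid = family_id if family_id is not None else blocks.source_family
    with open(path, "w") as fh:
        for col in blocks.columns:
            fh.write("".join(col) + "\t" + fid + "\n")


def read_blocks_tsv(path: str | Path) -> DisorderedBlockSet:
    columns: list[tuple[str, ...]] = []
    family = ""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            columns.append(tuple(parts[0]))
            if len(parts) > 1:
                family = parts[1]
    return DisorderedBlockSet(columns=tuple(columns), source_family=family)


def _make_global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def pairwise_identity(
    a: str, b: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Fraction of identical columns in a global alignment of ``a`` and ``b``.

    The denominator is the number of alignment columns after terminal gap
    columns are excluded ("internal identity").
    """
    if aligner is None:
        aligner = _make_global_aligner()
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    # trim terminal gap columns on either end
    lo, hi = 0, len(sa)
    while lo < hi and (sa[lo] == GAP or sb[lo] == GAP):
        lo += 1
    while hi > lo and (sa[hi - 1] == GAP or sb[hi - 1] == GAP):
        hi -= 1
    if hi <= lo:
        return 0.0
    matches = sum(1 for x, y in zip(sa[lo:hi], sb[lo:hi]) if x == y and x != GAP)
    return matches / (hi - lo)


def cluster_sequences(
    seqs: Sequence[ProteinSequence],
    identity: float,
    min_length: int | None = None,
) -> ClusterSet:
    """Greedy centroid clustering at an identity threshold (UCLUST-style).

    Sequences are visited in order of decreasing length (input order breaks
    ties); each joins the first cluster whose centroid it matches at
    ``>= identity``, otherwise it founds a new cluster. ``min_length``
    drops shorter sequences before clustering (the family-database filter
    uses 100).
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    if not (0.0 < identity <= 1.0):
        raise ValueError(f"identity {identity} outside (0, 1]")
    pool = list(seqs)
    if min_length is not None:
        pool = [s for s in pool if len(s) >= min_length]
        if not pool:
            raise ValueError(f"no sequences of length >= {min_length}")
    order = sorted(range(len(pool)), key=lambda i: (-len(pool[i]), i))
    aligner = _make_global_aligner()
    centroids: list[ProteinSequence] = []
    members: list[list[str]] = []
    for i in order:
        seq = pool[i]
        placed = False
        for c, centroid in enumerate(centroids):
            if pairwise_identity(seq.residues, centroid.residues, aligner) >= identity:
                members[c].append(seq.id)
                placed = True
                break
        if not placed:
            centroids.append(seq)
            members.append([seq.id])
    return ClusterSet(
        identity_threshold=identity,
        clusters=tuple(tuple(m) for m in members),
        centroids=tuple(c.id for c in centroids),
    )


def write_clusters_tsv(clusters: ClusterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for centroid, members in zip(clusters.centroids, clusters.clusters):
            for m in members:
                fh.write(f"{m}\t{centroid}\n")


def percent_disorderedness(track: ResidueLabelTrack) -> float:
    """Percentage of residues labeled DISORDERED, in [0, 100]."""
    if len(track) == 0:
        raise ValueError(f"{track.seq_id}: empty label track")
    n_dis = sum(1 for lab in track.labels if lab is ResidueLabel.DISORDERED)
    return 100.0 * n_dis / len(track)


def assign_bin(percent: float) -> DisorderBin:
    """Bin a disorder percentage: LD = [0,20], MD = (20,40], HD = (40,100]."""
    if not (0.0 <= percent <= 100.0):
        raise ValueError(f"percent disorderedness {percent} outside [0, 100]")
    if percent <= 20.0:
        return DisorderBin.LD
    if percent <= 40.0:
        return DisorderBin.MD
    return DisorderBin.HD
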