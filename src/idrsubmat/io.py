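"""Readers and writers for the external formats the pipeline consumes.

Sequence data travels as FASTA / aligned FASTA; per-residue disorder scores
as IUPred-style three-column TSV (1-based position, residue letter, score in
[0, 1]); secondary structure as flat or FASTA-style strings over the 3-state
alphabet {H, E, C}; family membership as a two-column TSV; and search hits in
12-column blast-tabular format. On-disk coordinates are 1-based inclusive;
everything in memory is 0-based half-open.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted in lenient mode on top of the canonical twenty
EXTENDED_RESIDUES = "BZXU*-"
SS_STATES = "HEC"
GAP = "-"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence with identifier and optional description."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def noncanonical_positions(self) -> tuple[int, ...]:
        """0-based positions holding residues outside the canonical twenty."""
        return tuple(
            i for i, r in enumerate(self.residues) if r not in CANONICAL_ALPHABET
        )


@dataclass(frozen=True)
class Alignment:
    """A gapped multiple sequence alignment; rows are (id, gapped string)."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        n = len(self.rows[0][1])
        for rid, row in self.rows:
            if len(row) != n:
                raise FormatError(
                    f"row {rid!r} has length {len(row)}, expected {n}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ungapped(self, row_index: int) -> ProteinSequence:
        rid, row = self.rows[row_index]
        return ProteinSequence(id=rid, residues=row.replace(GAP, ""))

    def column(self, j: int) -> tuple[str, ...]:
        return tuple(row[j] for _, row in self.rows)


@dataclass(frozen=True)
class ResidueAnnotation:
    """Per-residue disorder scores and 3-state secondary structure for one sequence."""

    seq_id: str
    disorder_scores: tuple[float, ...]
    ss_states: str

    def __post_init__(self) -> None:
        if len(self.disorder_scores) != len(self.ss_states):
            raise ValueError(
                f"{self.seq_id}: score track length {len(self.disorder_scores)} "
                f"!= ss track length {len(self.ss_states)}"
            )
        for s in self.disorder_scores:
            if not (0.0 <= s <= 1.0) or math.isnan(s):
                raise ValueError(f"{self.seq_id}: disorder score {s} outside [0, 1]")
        for c in self.ss_states:
            if c not in SS_STATES:
                raise ValueError(f"{self.seq_id}: secondary-structure state {c!r}")

    def __len__(self) -> int:
        return len(self.ss_states)


@dataclass(frozen=True)
class FamilyTable:
    """Mapping of sequence ids to family ids and the induced partition."""

    membership: Mapping[str, str]

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for sid, fid in self.membership.items():
            out.setdefault(fid, []).append(sid)
        return {fid: tuple(m) for fid, m in out.items()}

    def family_of(self, seq_id: str) -> str:
        try:
            return self.membership[seq_id]
        except KeyError:
            raise KeyError(f"sequence id {seq_id!r} not in family table") from None

    def sizes(self) -> dict[str, int]:
        return {fid: len(m) for fid, m in self.families.items()}


@dataclass(frozen=True)
class HitRecord:
    """One line of 12-column blast-tabular output (1-based inclusive coords)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_or_raw_score: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValueError(
                f"{self.query_id}/{self.subject_id}: inverted coordinates"
            )
        if self.e_value < 0:
            raise ValueError(f"negative E-value {self.e_value}")


def _check_residues(seq: ProteinSequence, strict: bool) -> None:
    allowed = CANONICAL_ALPHABET if strict else CANONICAL_ALPHABET + EXTENDED_RESIDUES
    for i, r in enumerate(seq.residues):
        if r not in allowed:
            raise FormatError(
                f"{seq.id}: illegal residue {r!r} at position {i + 1}"
            )


def read_fasta(path: str | Path, strict: bool = True) -> list[ProteinSequence]:
    """Read a protein FASTA file.

    In strict mode any residue outside the canonical 20-letter alphabet and
    any duplicated identifier raise :class:`FormatError`; lenient mode keeps
    ambiguity codes (they are excluded from counting downstream) and warns on
    duplicates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = ProteinSequence(
            id=rec.id, residues=str(rec.seq).upper(), description=rec.description
        )
        if seq.id in seen:
            msg = f"duplicate sequence id {seq.id!r} in {path}"
            if strict:
                raise FormatError(msg)
            warnings.warn(msg, stacklevel=2)
        seen.add(seq.id)
        _check_residues(seq, strict)
        records.append(seq)
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description or "")
        for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; '.' gaps are normalized to '-'."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rows.append((rec.id, str(rec.seq).upper().replace(".", GAP)))
    if not rows:
        raise FormatError(f"{path}: empty alignment")
    return Alignment(rows=tuple(rows))


def write_alignment(aln: Alignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, row in aln.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


#: column meanings of the disorder-score TSV (override for other dialects)
DEFAULT_SCORE_COLUMNS = {"position": 0, "residue": 1, "score": 2}


def read_annotations(
    score_path: str | Path,
    ss_path: str | Path,
    seq: ProteinSequence,
    score_columns: Mapping[str, int] = DEFAULT_SCORE_COLUMNS,
) -> ResidueAnnotation:
    """Read disorder scores and secondary-structure states for ``seq``.

    The score file is cross-checked residue by residue against ``seq``;
    positions must run contiguously from 1 to the sequence length.
    """
    pos_col = score_columns["position"]
    res_col = score_columns["residue"]
    sco_col = score_columns["score"]
    scores: list[float] = []
    with open(score_path) as fh:
        expected_pos = 1
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                pos = int(parts[pos_col])
                residue = parts[res_col]
                score = float(parts[sco_col])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{score_path}: bad line {line!r}") from exc
            if pos != expected_pos:
                raise FormatError(
                    f"{score_path}: position {pos}, expected {expected_pos}"
                )
            if pos > len(seq):
                raise FormatError(
                    f"{score_path}: position {pos} beyond sequence length {len(seq)}"
                )
            if residue != seq.residues[pos - 1]:
                raise FormatError(
                    f"{score_path}: residue {residue!r} at position {pos} does not "
                    f"match sequence residue {seq.residues[pos - 1]!r}"
                )
            if not (0.0 <= score <= 1.0):
                raise FormatError(f"{score_path}: score {score} outside [0, 1]")
            scores.append(score)
            expected_pos += 1
    if len(scores) != len(seq):
        raise FormatError(
            f"{score_path}: {len(scores)} scores for sequence of length {len(seq)}"
        )

    ss = _read_ss_string(ss_path)
    if len(ss) != len(seq):
        raise FormatError(
            f"{ss_path}: state string length {len(ss)} != sequence length {len(seq)}"
        )
    return ResidueAnnotation(
        seq_id=seq.id, disorder_scores=tuple(scores), ss_states=ss
    )


def _read_ss_string(path: str | Path) -> str:
    """Read a 3-state string, flat or FASTA-style (headers ignored)."""
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith((">", "#")):
                continue
            chunks.append(line)
    return "".join(chunks).upper()


def write_annotations(
    ann: ResidueAnnotation, seq: ProteinSequence, score_path: str | Path, ss_path: str | Path
) -> None:
    with open(score_path, "w") as fh:
        for i, score in enumerate(ann.disorder_scores):
            fh.write(f"{i + 1}\t{seq.residues[i]}\t{score:.4f}\n")
    with open(ss_path, "w") as fh:
        fh.write(f">{ann.seq_id}\n{ann.ss_states}\n")


def read_family_table(path: str | Path) -> FamilyTable:
    """Read a two-column TSV mapping sequence id to family id."""
    membership: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: expected 2 columns, got {line!r}")
            sid, fid = parts[0], parts[1]
            if sid in membership and membership[sid] != fid:
                raise FormatError(f"{path}: {sid!r} assigned to two families")
            membership[sid] = fid
    if not membership:
        raise FormatError(f"{path}: empty family table")
    return FamilyTable(membership=membership)


def write_family_table(table: FamilyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, fid in table.membership.items():
            fh.write(f"{sid}\t{fid}\n")


_HIT_FIELDS = 12


def read_hits_tabular(path: str | Path) -> list[HitRecord]:
    """Read 12-column blast-tabular ('-m 8' style) hits; '#' lines skipped."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _HIT_FIELDS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_HIT_FIELDS} columns, got {len(parts)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=parts[0],
                        subject_id=parts[1],
                        percent_identity=float(parts[2]),
                        alignment_length=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        q_start=int(parts[6]),
                        q_end=int(parts[7]),
                        s_start=int(parts[8]),
                        s_end=int(parts[9]),
                        e_value=float(parts[10]),
                        bit_or_raw_score=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def format_hit(hit: HitRecord) -> str:
    """Serialize one hit back to its tabular line (loss-free for parsed files)."""
    return "\t".join(
        [
            hit.query_id,
            hit.subject_id,
            f"{hit.percent_identity:.2f}",
            str(hit.alignment_length),
            str(hit.mismatches),
            str(hit.gap_opens),
            str(hit.q_start),
            str(hit.q_end),
            str(hit.s_start),
            str(hit.s_end),
            f"{hit.e_value:.3g}",
            f"{hit.bit_or_raw_score:g}",
        ]
    )


def write_hits_tabular(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for hit in hits:
            fh.write(format_hit(hit) + "\n")
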