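"""Substrate recognition site (SRS) mapping for cytochrome P450 sequences.

All P450s share six sequence regions, SRS1-SRS6, that line the catalytic
pocket around the heme and govern substrate binding and regio-specificity.
SRS boundaries are published for a handful of reference enzymes (e.g. rat
CYP2A1, Hyoscyamus muticus CYP71D55, Thapsia villosa CYP71AJ6); for any
other P450 they are obtained by globally aligning the query to an annotated
reference and projecting the reference intervals through the alignment
columns.

This module implements that projection, per-region percent-identity
profiling between homologs, and a scanner for the conserved K-helix ExxR
motif that anchors the SRS5 mutagenesis hotspots.

Coordinates are 1-based inclusive throughout, matching the residue
numbering convention of variant names such as A99I or G362V.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
SRS_LABELS = ("SRS1", "SRS2", "SRS3", "SRS4", "SRS5", "SRS6")

Interval = tuple[int, int]


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence; positions are 1-based."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = sorted(set(self.residues) - AMINO_ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-amino-acid symbols: "
                + ", ".join(repr(c) for c in bad)
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} outside {self.id} (length {len(self)})")
        return self.residues[position - 1]

    def segment(self, start: int, end: int) -> str:
        """Residues of the closed interval [start, end]."""
        if not (1 <= start <= end <= len(self.residues)):
            raise IndexError(f"interval {start}-{end} outside {self.id}")
        return self.residues[start - 1 : end]


@dataclass(frozen=True)
class SrsAnnotation:
    """The six SRS intervals (closed, 1-based) on a named sequence."""

    sequence_id: str
    intervals: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if len(self.intervals) != len(SRS_LABELS):
            raise ValueError(
                f"{self.sequence_id}: expected {len(SRS_LABELS)} SRS intervals, "
                f"got {len(self.intervals)}"
            )
        prev_end = 0
        for label, (start, end) in zip(SRS_LABELS, self.intervals):
            if start > end:
                raise ValueError(f"{self.sequence_id} {label}: start {start} > end {end}")
            if start <= prev_end:
                raise ValueError(
                    f"{self.sequence_id} {label}: overlaps or is out of order "
                    f"(starts at {start}, previous region ends at {prev_end})"
                )
            prev_end = end

    def validate_against(self, record: ProteinRecord) -> None:
        last_end = self.intervals[-1][1]
        if last_end > len(record):
            raise ValueError(
                f"{self.sequence_id} SRS6 ends at {last_end} beyond sequence "
                f"length {len(record)}"
            )

    @property
    def residue_counts(self) -> tuple[int, ...]:
        return tuple(end - start + 1 for start, end in self.intervals)

    @property
    def total_residues(self) -> int:
        return sum(self.residue_counts)


@dataclass(frozen=True)
class AlignmentParams:
    """Substitution matrix and affine gap penalties for global alignment.

    Defaults (BLOSUM62, open 10, extend 0.5, end gaps penalized) are the
    standard protein-alignment settings; per-region identities of close
    homologs are insensitive to moderate changes.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment as an explicit column list.

    Each column is a pair of 1-based positions, ``None`` marking a gap on
    that side. Non-gap positions are strictly increasing on each side and
    every residue of both sequences appears in exactly one column.
    """

    id_a: str
    id_b: str
    columns: tuple[tuple[Optional[int], Optional[int]], ...]
    score: float
    params: AlignmentParams

    def side_of(self, sequence_id: str) -> int:
        if sequence_id == self.id_a:
            return 0
        if sequence_id == self.id_b:
            return 1
        raise KeyError(
            f"sequence {sequence_id!r} is not part of alignment "
            f"({self.id_a}, {self.id_b})"
        )

    def position_map(self, from_id: str, to_id: str) -> dict[int, Optional[int]]:
        """Map every residue position of one sequence to its aligned partner."""
        src, dst = self.side_of(from_id), self.side_of(to_id)
        out: dict[int, Optional[int]] = {}
        for col in self.columns:
            if col[src] is not None:
                out[col[src]] = col[dst]
        return out


@dataclass(frozen=True)
class SrsProjection:
    """SRS intervals carried from an annotated reference onto a query.

    An interval may be ``None`` when every reference column of that region
    is gapped in the query.
    """

    query_id: str
    reference_id: str
    intervals: tuple[Optional[Interval], ...]

    @property
    def residue_counts(self) -> tuple[int, ...]:
        return tuple(0 if iv is None else iv[1] - iv[0] + 1 for iv in self.intervals)

    @property
    def total_residues(self) -> int:
        return sum(self.residue_counts)


@dataclass(frozen=True)
class IdentityProfile:
    """Per-SRS, pooled-SRS and full-length percent identity of a pair.

    Unrounded percentages are stored; :meth:`rounded` gives the
    nearest-integer report form.
    """

    id_a: str
    id_b: str
    per_srs: tuple[float, ...]
    total_srs: float
    full_length: float

    def rounded(self) -> dict[str, int]:
        out = {label: round(v) for label, v in zip(SRS_LABELS, self.per_srs)}
        out["Total SRS"] = round(self.total_srs)
        out["Total sequence"] = round(self.full_length)
        return out

    def swapped(self) -> "IdentityProfile":
        return IdentityProfile(self.id_b, self.id_a, self.per_srs, self.total_srs, self.full_length)


@dataclass(frozen=True)
class MotifHit:
    """A located sequence motif (e.g. the K-helix ExxR)."""

    sequence_id: str
    pattern: str
    start: int
    matched: str


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from FASTA; validates alphabet and id uniqueness."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, str(rec.seq).strip().upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_srs_annotations(path: str | Path) -> list[SrsAnnotation]:
    """Read SRS annotations from TSV (sequence_id, srs_label, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str, "srs_label": str})
    required = {"sequence_id", "srs_label", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    annotations = []
    for seq_id, group in df.groupby("sequence_id", sort=False):
        by_label = {row.srs_label: (int(row.start), int(row.end)) for row in group.itertuples()}
        for label in SRS_LABELS:
            if label not in by_label:
                raise ValueError(f"{seq_id}: missing {label}")
        extra = set(by_label) - set(SRS_LABELS)
        if extra:
            raise ValueError(f"{seq_id}: unknown SRS labels {sorted(extra)}")
        annotations.append(SrsAnnotation(str(seq_id), tuple(by_label[l] for l in SRS_LABELS)))
    return annotations


def write_srs_annotations(annotations: Iterable[SrsAnnotation], path: str | Path) -> None:
    rows = [
        {"sequence_id": ann.sequence_id, "srs_label": label, "start": start, "end": end}
        for ann in annotations
        for label, (start, end) in zip(SRS_LABELS, ann.intervals)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignment


def _make_aligner(params: AlignmentParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_align(
    a: ProteinRecord, b: ProteinRecord, params: AlignmentParams | None = None
) -> PairwiseAlignment:
    """Optimal global alignment under affine gap penalties.

    Among co-optimal alignments the engine's first traceback is returned,
    which is deterministic for fixed inputs and parameters.
    """
    params = params or AlignmentParams()
    aligner = _make_aligner(params)
    aln = aligner.align(a.residues, b.residues)[0]
    indices = aln.indices  # (2, n_columns); -1 marks a gap
    columns = tuple(
        (int(i) + 1 if i >= 0 else None, int(j) + 1 if j >= 0 else None)
        for i, j in indices.T
    )
    return PairwiseAlignment(a.id, b.id, columns, float(aln.score), params)


# ---------------------------------------------------------------------------
# Projection and identity


def project_srs(
    reference_annotation: SrsAnnotation,
    alignment: PairwiseAlignment,
    query: ProteinRecord,
) -> SrsProjection:
    """Carry reference SRS intervals onto the query through alignment columns.

    A reference boundary aligned to a query gap shrinks inward to the nearest
    aligned query residue; an interval gapped along its whole length becomes
    empty. Query insertions falling inside a region are included (the
    projected interval is the closed span of aligned query residues).
    """
    ref_side = alignment.side_of(reference_annotation.sequence_id)
    qry_side = 1 - ref_side
    if alignment.columns and (alignment.id_a, alignment.id_b)[qry_side] != query.id:
        raise KeyError(
            f"query {query.id!r} is not the other side of the alignment"
        )
    intervals: list[Optional[Interval]] = []
    for start, end in reference_annotation.intervals:
        qpos = [
            col[qry_side]
            for col in alignment.columns
            if col[ref_side] is not None
            and start <= col[ref_side] <= end
            and col[qry_side] is not None
        ]
        intervals.append((min(qpos), max(qpos)) if qpos else None)
    return SrsProjection(query.id, reference_annotation.sequence_id, tuple(intervals))


def consensus_projection(
    query: ProteinRecord,
    references: Sequence[tuple[ProteinRecord, SrsAnnotation]],
    params: AlignmentParams | None = None,
) -> tuple[tuple[Optional[Interval], ...], list[SrsProjection]]:
    """Project SRS intervals from several annotated references.

    Returns the consensus (per-region intersection across references; empty
    regions drop out) together with the individual projections.
    """
    projections = []
    for ref_record, ref_ann in references:
        aln = global_align(ref_record, query, params)
        projections.append(project_srs(ref_ann, aln, query))
    consensus: list[Optional[Interval]] = []
    for k in range(len(SRS_LABELS)):
        ivs = [p.intervals[k] for p in projections if p.intervals[k] is not None]
        if not ivs:
            consensus.append(None)
            continue
        start = max(iv[0] for iv in ivs)
        end = min(iv[1] for iv in ivs)
        consensus.append((start, end) if start <= end else None)
    return tuple(consensus), projections


def _in_interval(pos: Optional[int], interval: Optional[Interval]) -> bool:
    return pos is not None and interval is not None and interval[0] <= pos <= interval[1]


def srs_identity(
    a: ProteinRecord,
    b: ProteinRecord,
    alignment: PairwiseAlignment,
    intervals_a: Sequence[Optional[Interval]],
    intervals_b: Sequence[Optional[Interval]],
) -> IdentityProfile:
    """Percent identity per SRS, pooled over SRS, and over the full alignment.

    A column belongs to region *k* when either side's residue lies in that
    side's interval. Identity is identical-residue columns over all columns
    of the region; gap-containing columns count as mismatches. A region with
    no columns on either side reports 0.
    """
    side_a, side_b = alignment.side_of(a.id), alignment.side_of(b.id)
    per_srs: list[float] = []
    pooled_cols = 0
    pooled_ident = 0
    total_ident = 0
    for k in range(len(SRS_LABELS)):
        n_cols = 0
        n_ident = 0
        for col in alignment.columns:
            pa, pb = col[side_a], col[side_b]
            if _in_interval(pa, intervals_a[k]) or _in_interval(pb, intervals_b[k]):
                n_cols += 1
                if pa is not None and pb is not None and a.residue(pa) == b.residue(pb):
                    n_ident += 1
        per_srs.append(100.0 * n_ident / n_cols if n_cols else 0.0)
        pooled_cols += n_cols
        pooled_ident += n_ident
    for col in alignment.columns:
        pa, pb = col[side_a], col[side_b]
        if pa is not None and pb is not None and a.residue(pa) == b.residue(pb):
            total_ident += 1
    total_srs = 100.0 * pooled_ident / pooled_cols if pooled_cols else 0.0
    full_length = 100.0 * total_ident / len(alignment.columns)
    return IdentityProfile(a.id, b.id, tuple(per_srs), total_srs, full_length)


def assign_srs_intervals(
    records: Mapping[str, ProteinRecord],
    annotations: Sequence[SrsAnnotation],
    params: AlignmentParams | None = None,
) -> dict[str, tuple[Optional[Interval], ...]]:
    """SRS intervals for every record: native where annotated, otherwise the
    consensus projection from all annotated references."""
    annotated = {ann.sequence_id: ann for ann in annotations}
    for seq_id, ann in annotated.items():
        if seq_id not in records:
            raise KeyError(f"annotated sequence {seq_id!r} not among the records")
        ann.validate_against(records[seq_id])
    references = [(records[i], annotated[i]) for i in annotated]
    out: dict[str, tuple[Optional[Interval], ...]] = {}
    for seq_id, record in records.items():
        if seq_id in annotated:
            out[seq_id] = tuple(annotated[seq_id].intervals)
        else:
            if not references:
                raise ValueError("no annotated reference available for projection")
            out[seq_id], _ = consensus_projection(record, references, params)
    return out


def identity_matrix(
    records: Sequence[ProteinRecord],
    annotations: Sequence[SrsAnnotation],
    pairs: Sequence[tuple[str, str]],
    params: AlignmentParams | None = None,
) -> list[IdentityProfile]:
    """Identity profiles for requested sequence pairs (self-pairs allowed).

    Pairs are aligned in a canonical id order so that reversing a pair yields
    the same numbers (the profile is re-oriented to the requested order).
    """
    by_id = {r.id: r for r in records}
    for x, y in pairs:
        for seq_id in (x, y):
            if seq_id not in by_id:
                raise KeyError(f"unknown sequence id {seq_id!r}")
    intervals = assign_srs_intervals(by_id, annotations, params)
    profiles: list[IdentityProfile] = []
    cache: dict[tuple[str, str], IdentityProfile] = {}
    for x, y in pairs:
        key = tuple(sorted((x, y)))
        if key not in cache:
            a, b = by_id[key[0]], by_id[key[1]]
            aln = global_align(a, b, params)
            cache[key] = srs_identity(a, b, aln, intervals[key[0]], intervals[key[1]])
        profile = cache[key]
        profiles.append(profile if profile.id_a == x else profile.swapped())
    return profiles


def write_identity_report(
    profiles: Sequence[IdentityProfile],
    tsv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Write rounded identity profiles as TSV; optionally unrounded JSON."""
    rows = []
    for p in profiles:
        row = {"pair": f"{p.id_a} and {p.id_b}"}
        row.update({f"{label} (%)": v for label, v in zip(SRS_LABELS, (round(x) for x in p.per_srs))})
        row["Total SRS (%)"] = round(p.total_srs)
        row["Total sequence (%)"] = round(p.full_length)
        rows.append(row)
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = [
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "per_srs": list(p.per_srs),
                "total_srs": p.total_srs,
                "full_length": p.full_length,
            }
            for p in profiles
        ]
        Path(json_path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Motif scan

_EXXR = re.compile(r"E..R")


def find_exxr(
    record: ProteinRecord,
    start: int = 1,
    end: int | None = None,
) -> Optional[MotifHit]:
    """First E-x-x-R match within [start, end]; ``None`` when absent.

    The K-helix ExxR of P450s follows the I-helix, so callers mapping SRS5
    hotspots typically pass ``start`` just after the projected SRS4 end.
    """
    end = len(record) if end is None else end
    if not (1 <= start <= end <= len(record)):
        raise IndexError(f"search interval {start}-{end} outside {record.id}")
    # the E must start within [start, end]; the motif may run up to 3 residues past end
    m = _EXXR.search(record.residues, start - 1, min(len(record), end + 3))
    if m is None or m.start() + 1 > end:
        return None
    return MotifHit(record.id, "ExxR", m.start() + 1, m.group())
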