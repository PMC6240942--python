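"""Mutagenesis candidate enumeration and variant notation for P450 engineering.

Three semi-rational selection rules are implemented:

* **SRS5 hotspots** — the residues at fixed offsets (by default 5 and 9)
  from the glutamate of the conserved K-helix ExxR motif, known mutational
  hotspots that point toward the heme;
* **reciprocal mutagenesis** — at every SRS position where two homologs
  differ, substitute the target residue with the donor's, to transfer or
  dissect their catalytic differences (alignment gaps become segment-swap
  candidates, merged into maximal runs);
* **equivalent positions** — carry a position known to matter in one enzyme
  onto another through their pairwise alignment.

Variants are written in the field's notation: ``A99I`` substitutes A at
position 99 with I; ``473DDP::EL`` replaces the segment DDP starting at 473
with EL (a net deletion). ``parse_variant``/``render`` round-trip this
grammar exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from cypsrs.srs_mapping import (
    AMINO_ALPHABET,
    Interval,
    MotifHit,
    PairwiseAlignment,
    ProteinRecord,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Substitution:
    position: int
    ref: str
    new: str

    def render(self) -> str:
        return f"{self.ref}{self.position}{self.new}"

    @property
    def span(self) -> tuple[int, int]:
        return (self.position, self.position)


@dataclass(frozen=True)
class SegmentSwap:
    """Replace ``ref_segment`` starting at ``position`` with ``new_segment``.

    Segments may differ in length (net insertion or deletion). An empty
    ``ref_segment`` inserts ``new_segment`` before ``position``.
    """

    position: int
    ref_segment: str
    new_segment: str

    def render(self) -> str:
        return f"{self.position}{self.ref_segment}::{self.new_segment}"

    @property
    def span(self) -> tuple[int, int]:
        end = self.position + max(len(self.ref_segment), 1) - 1
        return (self.position, end)


Edit = Union[Substitution, SegmentSwap]


@dataclass(frozen=True)
class VariantSpec:
    """An ordered, non-overlapping set of edits on one protein sequence."""

    edits: tuple[Edit, ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for edit in self.edits:
            start, end = edit.span
            if start <= prev_end:
                raise ValueError(
                    f"edit {edit.render()!r} overlaps or duplicates position "
                    f"{start} (previous edit ends at {prev_end})"
                )
            prev_end = end

    def render(self) -> str:
        return " ".join(edit.render() for edit in self.edits)


@dataclass(frozen=True)
class MutationCandidate:
    """A proposed variant with the rule and evidence that produced it."""

    target_id: str
    spec: VariantSpec
    rule: str  # hotspot_srs5 | reciprocal | equivalent_position | indel_swap
    provenance: str

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("candidate provenance must be non-empty")


@dataclass(frozen=True)
class EquivalentPosition:
    """A homolog position carried onto a query through an alignment."""

    query_id: str
    query_position: int
    query_residue: str
    homolog_id: str
    homolog_position: int
    homolog_residue: str


# ---------------------------------------------------------------------------
# Variant grammar

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_SWAP_RE = re.compile(r"^(\d+)([A-Z]*)::([A-Z]*)$")


def _check_letters(token: str, letters: str) -> None:
    bad = sorted(set(letters) - AMINO_ALPHABET)
    if bad:
        raise ValueError(f"malformed variant token {token!r}: non-residue {bad}")


def parse_variant(text: str) -> VariantSpec:
    """Parse whitespace-separated edits in the A99I / 473DDP::EL notation."""
    tokens = text.split()
    if not tokens:
        raise ValueError("empty variant text")
    edits: list[Edit] = []
    for token in tokens:
        m = _SUB_RE.match(token)
        if m:
            ref, pos, new = m.group(1), int(m.group(2)), m.group(3)
            _check_letters(token, ref + new)
            edits.append(Substitution(pos, ref, new))
            continue
        m = _SWAP_RE.match(token)
        if m:
            pos, ref_seg, new_seg = int(m.group(1)), m.group(2), m.group(3)
            if not ref_seg and not new_seg:
                raise ValueError(f"malformed variant token {token!r}: empty swap")
            _check_letters(token, ref_seg + new_seg)
            edits.append(SegmentSwap(pos, ref_seg, new_seg))
            continue
        raise ValueError(f"malformed variant token {token!r}")
    edits.sort(key=lambda e: e.span[0])
    return VariantSpec(tuple(edits))


def apply_variant(record: ProteinRecord, spec: VariantSpec) -> ProteinRecord:
    """Apply edits to a sequence; the new id carries the canonical variant text.

    Positions refer to the unedited sequence, so edits are applied from the
    C-terminal end to keep earlier coordinates valid.
    """
    residues = record.residues
    for edit in spec.edits:
        start, _ = edit.span
        if isinstance(edit, Substitution):
            if start > len(record):
                raise ValueError(f"{edit.render()}: position beyond {record.id}")
            found = record.residue(start)
            if found != edit.ref:
                raise ValueError(
                    f"{edit.render()}: expected {edit.ref} found {found} at {start}"
                )
        else:
            seg_end = start + len(edit.ref_segment) - 1
            if edit.ref_segment:
                found = record.segment(start, seg_end)
                if found != edit.ref_segment:
                    raise ValueError(
                        f"{edit.render()}: expected {edit.ref_segment} found {found} at {start}"
                    )
    for edit in reversed(spec.edits):
        i = edit.span[0] - 1
        if isinstance(edit, Substitution):
            residues = residues[:i] + edit.new + residues[i + 1 :]
        else:
            residues = residues[:i] + edit.new_segment + residues[i + len(edit.ref_segment) :]
    return ProteinRecord(f"{record.id}_{spec.render().replace(' ', '_')}", residues)


# ---------------------------------------------------------------------------
# Selection rules


def srs5_hotspots(
    record: ProteinRecord,
    exxr: MotifHit,
    offsets: Sequence[int] = (5, 9),
    replacements: Optional[Sequence[str]] = None,
) -> list[MutationCandidate]:
    """Hotspot candidates at fixed offsets downstream of the ExxR glutamate.

    Without a replacement panel each candidate carries the placeholder X for
    the caller to saturate. Offsets landing beyond the sequence are skipped
    with a warning.
    """
    candidates: list[MutationCandidate] = []
    for offset in sorted(set(offsets)):
        if offset < 0:
            raise ValueError(f"hotspot offset must be non-negative, got {offset}")
        position = exxr.start + offset
        if position > len(record):
            logger.warning(
                "hotspot offset %d lands at %d beyond %s (length %d); skipped",
                offset, position, record.id, len(record),
            )
            continue
        wild_type = record.residue(position)
        provenance = f"ExxR at {exxr.start} + {offset}"
        for new in replacements or ("X",):
            candidates.append(
                MutationCandidate(
                    record.id,
                    VariantSpec((Substitution(position, wild_type, new),)),
                    "hotspot_srs5",
                    provenance,
                )
            )
    return candidates


def reciprocal_candidates(
    target: ProteinRecord,
    target_intervals: Sequence[Optional[Interval]],
    donor: ProteinRecord,
    donor_intervals: Sequence[Optional[Interval]],
    alignment: PairwiseAlignment,
) -> list[MutationCandidate]:
    """Candidates transferring donor residues onto the target within the SRS.

    Mismatch columns give one substitution each; runs of columns containing a
    gap (extended over contiguous adjacent mismatches) give one segment-swap
    candidate in the 473DDP::EL style.
    """
    t_side = alignment.side_of(target.id)
    d_side = 1 - t_side

    def in_srs(col: tuple[Optional[int], Optional[int]]) -> bool:
        pt, pd_ = col[t_side], col[d_side]
        for iv_t, iv_d in zip(target_intervals, donor_intervals):
            if (iv_t and pt is not None and iv_t[0] <= pt <= iv_t[1]) or (
                iv_d and pd_ is not None and iv_d[0] <= pd_ <= iv_d[1]
            ):
                return True
        return False

    # group contiguous non-identical SRS columns; a group with any gap becomes
    # one segment swap, otherwise each column is an independent substitution
    candidates: list[MutationCandidate] = []
    group: list[tuple[Optional[int], Optional[int]]] = []
    last_target_pos = 0

    def flush() -> None:
        nonlocal group
        if not group:
            return
        has_gap = any(c[t_side] is None or c[d_side] is None for c in group)
        if has_gap:
            t_pos = [c[t_side] for c in group if c[t_side] is not None]
            ref_seg = "".join(target.residue(p) for p in t_pos)
            new_seg = "".join(
                donor.residue(c[d_side]) for c in group if c[d_side] is not None
            )
            position = t_pos[0] if t_pos else last_target_pos + 1
            candidates.append(
                MutationCandidate(
                    target.id,
                    VariantSpec((SegmentSwap(position, ref_seg, new_seg),)),
                    "indel_swap",
                    f"{donor.id} segment {new_seg or '-'} vs {target.id} {ref_seg or '-'}",
                )
            )
        else:
            for c in group:
                pt, pd_ = c[t_side], c[d_side]
                candidates.append(
                    MutationCandidate(
                        target.id,
                        VariantSpec(
                            (Substitution(pt, target.residue(pt), donor.residue(pd_)),)
                        ),
                        "reciprocal",
                        f"{donor.id} position {pd_}",
                    )
                )
        group = []

    for col in alignment.columns:
        pt, pd_ = col[t_side], col[d_side]
        if not in_srs(col):
            flush()
            if pt is not None:
                last_target_pos = pt
            continue
        identical = (
            pt is not None and pd_ is not None and target.residue(pt) == donor.residue(pd_)
        )
        if identical:
            flush()
        else:
            group.append(col)
        if pt is not None:
            last_target_pos = pt
    flush()
    candidates.sort(key=lambda c: (c.rule, c.spec.edits[0].span[0]))
    return candidates


def map_equivalent_position(
    query: ProteinRecord,
    homolog: ProteinRecord,
    homolog_position: int,
    alignment: PairwiseAlignment,
) -> Optional[EquivalentPosition]:
    """The query position aligned to ``homolog_position``, or ``None`` on a gap."""
    if not 1 <= homolog_position <= len(homolog):
        raise IndexError(
            f"position {homolog_position} outside {homolog.id} (length {len(homolog)})"
        )
    query_position = alignment.position_map(homolog.id, query.id)[homolog_position]
    if query_position is None:
        return None
    return EquivalentPosition(
        query.id,
        query_position,
        query.residue(query_position),
        homolog.id,
        homolog_position,
        homolog.residue(homolog_position),
    )
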