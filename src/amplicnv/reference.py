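"""Construction of the artificial (reduced) mapping reference.

The mapping target for copy-number estimation is a short artificial
chromosome holding exactly one copy of each repeat unit plus one
single-copy control segment.  Reads from all copies of an ampliconic gene
pile up on its single unit, so per-base depth there is proportional to
total copy number, while depth on the control tracks the per-chromosome
sequencing depth.

Two layouts are supported: one FASTA record per segment (the default,
which keeps depth bookkeeping trivial) or a single concatenated record.
Both carry an invertible coordinate map back to the source assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .repeats import RepeatUnit


@dataclass(frozen=True)
class Segment:
    seg_id: str
    source_chrom: str
    source_start: int
    source_end: int
    offset: int  # start position in the concatenated coordinate system

    @property
    def length(self) -> int:
        return self.source_end - self.source_start


@dataclass
class ArtificialReference:
    """Ordered segments (units first, control last) with a coordinate map."""

    segments: list[Segment]
    control_id: str
    mode: str = "multi"  # "multi": one record per segment; "concat": one record
    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def unit_ids(self) -> list[str]:
        return [s.seg_id for s in self.segments if s.seg_id != self.control_id]

    def segment(self, seg_id: str) -> Segment:
        for s in self.segments:
            if s.seg_id == seg_id:
                return s
        raise KeyError(seg_id)

    def coordinate_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.seg_id, s.source_chrom, s.source_start, s.source_end, s.offset, s.length)
             for s in self.segments],
            columns=["segment", "source_chrom", "source_start", "source_end", "offset", "length"],
        )


def unit_from_gene(gene_start: int, gene_end: int, flank: int = 2000) -> tuple[int, int]:
    """Expand a gene interval by symmetric flanks to form a repeat unit.

    This is the convention used for palindromic arrays where the unit
    cannot be read off a dotplot: one copy of the gene +/- ``flank`` bp.
    """
    if gene_end <= gene_start:
        raise ValueError("empty gene interval")
    return max(0, gene_start - flank), gene_end + flank


def build_reference(
    units: list[RepeatUnit],
    control: tuple[str, int, int, str],
    sources: dict[str, str],
    mode: str = "multi",
) -> tuple[ArtificialReference, dict[str, str]]:
    """Assemble the artificial reference from unit intervals plus a control.

    ``control`` is (source_chrom, start, end, control_id).  Returns the
    reference description and its FASTA records ({record_name: sequence}).
    Unit intervals must be unique, within their source sequence, and
    non-overlapping on a shared source.
    """
    if mode not in ("multi", "concat"):
        raise ValueError(f"unknown mode {mode!r}")
    c_chrom, c_start, c_end, c_id = control
    if c_end <= c_start:
        raise ValueError("control interval is empty")

    intervals: list[tuple[str, int, int, str]] = []
    for u in units:
        uid = u.gene_name or u.region_id
        intervals.append((u.region_id, u.start, u.end, uid))
    intervals.append((c_chrom, c_start, c_end, c_id))

    seen_ids: set[str] = set()
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, seg_id in intervals:
        if seg_id in seen_ids:
            raise ValueError(f"duplicate segment id {seg_id!r}")
        seen_ids.add(seg_id)
        if chrom not in sources:
            raise ValueError(f"source sequence {chrom!r} not provided")
        if start < 0 or end > len(sources[chrom]):
            raise ValueError(f"segment {seg_id!r} outside source {chrom!r} bounds")
        by_chrom.setdefault(chrom, []).append((start, end, seg_id))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1, id1), (s2, e2, id2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"segments {id1!r} and {id2!r} overlap on {chrom!r}")

    segments: list[Segment] = []
    offset = 0
    for chrom, start, end, seg_id in intervals:
        segments.append(Segment(seg_id, chrom, start, end, offset))
        offset += end - start

    ref = ArtificialReference(segments=segments, control_id=c_id, mode=mode)
    if mode == "multi":
        records = {s.seg_id: sources[s.source_chrom][s.source_start:s.source_end] for s in segments}
    else:
        records = {"artificial_chromosome": "".join(
            sources[s.source_chrom][s.source_start:s.source_end] for s in segments)}
    ref.sequences = records
    return ref, records


def lift_coordinates(ref: ArtificialReference, position: int, segment: str | None = None) -> tuple[str, int]:
    """Map a position on the artificial reference back to the source assembly.

    In "concat" mode ``position`` indexes the single concatenated record;
    in "multi" mode pass the record's ``segment`` id and a position within
    it.  Returns (source_chrom, source_position), 0-based.
    """
    if segment is not None:
        s = ref.segment(segment)
        if not 0 <= position < s.length:
            raise ValueError(f"position {position} outside segment {segment!r}")
        return s.source_chrom, s.source_start + position
    if not 0 <= position < ref.total_length:
        raise ValueError(f"position {position} outside reference of length {ref.total_length}")
    for s in ref.segments:
        if s.offset <= position < s.offset + s.length:
            return s.source_chrom, s.source_start + (position - s.offset)
    raise AssertionError("unreachable: gap-free segments cover the reference")


def unlift_coordinates(ref: ArtificialReference, chrom: str, source_position: int) -> tuple[str, int]:
    """Inverse of :func:`lift_coordinates`: source -> (segment_id, position)."""
    for s in ref.segments:
        if s.source_chrom == chrom and s.source_start <= source_position < s.source_end:
            return s.seg_id, source_position - s.source_start
    raise ValueError(f"{chrom}:{source_position} not covered by any segment")
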