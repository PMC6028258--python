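"""Per-base read depth over reference segments.

Depth can come straight from a coordinate-sorted, indexed BAM/CRAM (with
the read filters the copy-number method assumes: mapping quality, edit
distance, no duplicates) or from a plain per-base depth table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam


@dataclass
class DepthProfile:
    """Per-base depth arrays for one individual, keyed by segment id."""

    individual_id: str
    depths: dict[str, np.ndarray]
    source: str = "tsv"

    def __post_init__(self):
        for seg, arr in self.depths.items():
            arr = np.asarray(arr)
            if arr.ndim != 1:
                raise ValueError(f"depth array for {seg!r} must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"negative depth in segment {seg!r}")
            self.depths[seg] = arr


def _read_passes(read: pysam.AlignedSegment, mapq_min: int, max_mismatches: int) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if read.is_duplicate or read.is_qcfail:
        return False
    if read.mapping_quality < mapq_min:
        return False
    nm = read.get_tag("NM") if read.has_tag("NM") else 0
    return nm <= max_mismatches


def depth_from_alignments(
    alignment_path: str | os.PathLike,
    segments: dict[str, tuple[str, int, int]],
    individual_id: str | None = None,
    mapq_min: int = 50,
    max_mismatches: int = 2,
) -> DepthProfile:
    """Per-base depth over ``segments`` from an indexed alignment file.

    ``segments`` maps segment id -> (contig, start, end), 0-based
    half-open.  Reads are excluded when unmapped, secondary/supplementary,
    flagged duplicate or QC-fail, mapping quality < ``mapq_min``, or edit
    distance (NM tag) > ``max_mismatches``; depth counts aligned reference
    bases only (deletions and skips in a read do not add depth).
    """
    af = pysam.AlignmentFile(str(alignment_path))
    try:
        if not af.has_index():
            raise ValueError(f"{alignment_path}: alignment file must be indexed")
        refs = set(af.references)
        depths: dict[str, np.ndarray] = {}
        for seg_id, (contig, start, end) in segments.items():
            if contig not in refs:
                raise ValueError(f"segment contig {contig!r} absent from alignment header")
            arr = np.zeros(end - start, dtype=np.int64)
            for read in af.fetch(contig, start, end):
                if not _read_passes(read, mapq_min, max_mismatches):
                    continue
                for pos in read.get_reference_positions():
                    if start <= pos < end:
                        arr[pos - start] += 1
            depths[seg_id] = arr
    finally:
        af.close()
    name = individual_id or os.path.splitext(os.path.basename(str(alignment_path)))[0]
    return DepthProfile(individual_id=name, depths=depths, source="alignment")


def profiles_to_table(profiles: dict[str, DepthProfile]) -> pd.DataFrame:
    """Flatten profiles to a long table (individual, segment, pos, depth)."""
    frames = []
    for ind, prof in profiles.items():
        for seg, arr in prof.depths.items():
            frames.append(pd.DataFrame({
                "individual": ind, "segment": seg,
                "pos": np.arange(arr.size), "depth": arr}))
    return pd.concat(frames, ignore_index=True)


def table_to_profiles(table: pd.DataFrame) -> dict[str, DepthProfile]:
    """Inverse of :func:`profiles_to_table`; positions must be 0..len-1."""
    profiles = {}
    for ind, sub in table.groupby("individual", sort=False):
        depths = {}
        for seg, seg_df in sub.groupby("segment", sort=False):
            seg_df = seg_df.sort_values("pos")
            if not np.array_equal(seg_df["pos"].to_numpy(), np.arange(len(seg_df))):
                raise ValueError(f"depth table for {ind}/{seg} is not contiguous from 0")
            depths[seg] = seg_df["depth"].to_numpy()
        profiles[ind] = DepthProfile(individual_id=ind, depths=depths, source="tsv")
    return profiles


def read_depth_table(path: str | os.PathLike) -> dict[str, DepthProfile]:
    return table_to_profiles(pd.read_csv(path, sep="\t"))


def write_depth_table(profiles: dict[str, DepthProfile], path: str | os.PathLike) -> None:
    profiles_to_table(profiles).to_csv(path, sep="\t", index=False)
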