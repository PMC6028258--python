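"""Depth-ratio copy-number estimation.

The copy number of an ampliconic gene is estimated as

    CN = median(per-base depth over its repeat unit)
         / median(per-base depth over the single-copy control)

because reads from every copy of the gene co-pile on the single unit kept
in the artificial reference.  The median makes the estimate robust to
local coverage artefacts; zero-depth positions are *included* (a unit
absent from an individual must yield CN 0, not a division artefact), and
the median of an even number of values is the midpoint of the two central
ones.  The ratio cancels the individual's overall sequencing depth, so CN
is invariant to global depth rescaling.  With the control measuring depth
per chromosome copy, female X values are averages of the two haplotypes
and need not be integers.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .depth import DepthProfile


def estimate_copy_number(
    profile: DepthProfile,
    units: Iterable[str],
    control: str = "control",
) -> pd.DataFrame:
    """Copy-number rows (one per unit) for a single individual's profile.

    Returns columns individual, gene, unit_median, control_median, cn.
    A zero control median makes CN missing (NaN) with a warning rather
    than infinite.
    """
    if control not in profile.depths:
        raise ValueError(f"control segment {control!r} missing from profile")
    control_median = float(np.median(profile.depths[control]))
    rows = []
    for unit in units:
        if unit not in profile.depths:
            raise ValueError(f"unit segment {unit!r} missing from profile")
        unit_median = float(np.median(profile.depths[unit]))
        if control_median > 0:
            cn = unit_median / control_median
        else:
            warnings.warn(
                f"{profile.individual_id}: control median is 0, CN undefined for {unit!r}")
            cn = np.nan
        rows.append((profile.individual_id, unit, unit_median, control_median, cn))
    return pd.DataFrame(rows, columns=["individual", "gene", "unit_median", "control_median", "cn"])


def build_cn_table(
    profiles: Mapping[str, DepthProfile],
    units: Iterable[str],
    control: str = "control",
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stack per-individual estimates; optionally join sample metadata."""
    units = list(units)
    table = pd.concat(
        [estimate_copy_number(p, units, control) for p in profiles.values()],
        ignore_index=True)
    if metadata is not None:
        table = table.merge(metadata, on="individual", how="left")
    return table


def duplicate_concordance(cn_a: pd.DataFrame, cn_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene spread of |CN difference| between duplicate sequencing runs.

    The two tables are matched on (individual, gene); sequencing noise
    alone should put the median difference at ~0 for every gene.
    """
    merged = cn_a.merge(cn_b, on=["individual", "gene"], suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no shared (individual, gene) pairs between the two tables")
    merged["abs_diff"] = (merged["cn_a"] - merged["cn_b"]).abs()
    out = merged.groupby("gene")["abs_diff"].agg(
        median_diff="median", max_diff="max", n_pairs="size").reset_index()
    return out


def cn_summary(cn_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene min, max, delta (max - min) and median copy number."""
    g = cn_table.groupby("gene")["cn"]
    out = g.agg(min_cn="min", max_cn="max", median_cn="median", n="size").reset_index()
    out["delta_cn"] = out["max_cn"] - out["min_cn"]
    return out[["gene", "min_cn", "max_cn", "delta_cn", "median_cn", "n"]]
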