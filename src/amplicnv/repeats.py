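"""Tandem-repeat discovery by exact self-matching.

Ampliconic regions consist of near-identical (>99.9%) copies of a repeat
unit laid out in tandem.  On a dotplot of the region against itself such an
array shows up as off-diagonal lines at vertical offsets equal to integer
multiples of the unit length.  This module automates that inspection: it
finds maximal exact self-matches seeded by shared k-mers (the analogue of an
exact-seed self-alignment), then infers the unit of repetition from the
spacing of the off-diagonal matches.

Because copies within an array are so similar, exact seeds of 100 bp are
expected to survive between copies (a 0.1% per-base divergence breaks an
exact run roughly every kilobase), so a full gapped aligner is not needed.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class SelfMatch:
    """A maximal exact match of a sequence against itself.

    Coordinates are 0-based half-open on the same (forward) sequence;
    matches are stored canonically with ``query_start < target_start`` so
    each repeat is reported once.  ``offset`` is the dotplot diagonal
    (vertical distance from the main diagonal).
    """

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.query_end - self.query_start

    @property
    def offset(self) -> int:
        return self.target_start - self.query_start


@dataclass
class RepeatUnit:
    """One unit of repetition of an ampliconic region.

    ``start``/``end`` delimit a single copy on the source sequence;
    ``copy_count_estimate`` is the number of copies the self-matches
    support.  ``ambiguous`` is set when the observed match offsets are not
    all multiples of a single period.
    """

    region_id: str
    start: int
    end: int
    copy_count_estimate: int = 1
    gene_name: str | None = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty unit interval [{self.start}, {self.end})")
        if self.copy_count_estimate < 1:
            raise ValueError("copy_count_estimate must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


def find_self_matches(
    sequence: str,
    min_exact: int = 100,
    step: int = 100,
    include_reverse: bool = True,
) -> list[SelfMatch]:
    """Find maximal exact repeats of length >= ``min_exact`` within a sequence.

    Seeds are k-mers of length ``min_exact`` taken at query positions on a
    grid of spacing ``step`` and looked up at every position of the
    sequence; each seed hit is extended to a maximal exact match.  The
    trivial main-diagonal self-match is excluded, and forward matches are
    deduplicated to canonical order (query before target).  Reverse-strand
    matches (against the reverse complement) are reported with strand "-".
    """
    if min_exact < 1 or step < 1:
        raise ValueError("min_exact and step must be >= 1")
    seq = sequence.upper()
    n = len(seq)
    if n < min_exact:
        return []

    k = min_exact
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        index[seq[i : i + k]].append(i)

    matches: set[SelfMatch] = set()
    for q in range(0, n - k + 1, step):
        for t in index.get(seq[q : q + k], ()):
            if t == q:
                continue
            lo_q, lo_t = (q, t) if q < t else (t, q)
            # extend the seed to a maximal exact match on this diagonal
            while lo_q > 0 and seq[lo_q - 1] == seq[lo_t - 1]:
                lo_q -= 1
                lo_t -= 1
            hi_q, hi_t = lo_q + k, lo_t + k
            while hi_t < n and seq[hi_q] == seq[hi_t]:
                hi_q += 1
                hi_t += 1
            if hi_q - lo_q >= min_exact:
                matches.add(SelfMatch(lo_q, hi_q, lo_t, hi_t, "+"))

    if include_reverse:
        rc = _revcomp(seq)
        rc_index: dict[str, list[int]] = defaultdict(list)
        for i in range(n - k + 1):
            rc_index[rc[i : i + k]].append(i)
        for q in range(0, n - k + 1, step):
            for t in rc_index.get(seq[q : q + k], ()):
                lo_q, lo_t = q, t
                while lo_q > 0 and lo_t > 0 and seq[lo_q - 1] == rc[lo_t - 1]:
                    lo_q -= 1
                    lo_t -= 1
                hi_q, hi_t = lo_q + k, lo_t + k
                while hi_q < n and hi_t < n and seq[hi_q] == rc[hi_t]:
                    hi_q += 1
                    hi_t += 1
                # map the reverse-complement interval back to forward coords
                f_start, f_end = n - hi_t, n - lo_t
                if hi_q - lo_q < min_exact:
                    continue
                if (f_start, f_end) == (lo_q, hi_q):
                    continue  # a palindrome matching itself
                a = (lo_q, hi_q)
                b = (f_start, f_end)
                if a > b:
                    a, b = b, a
                matches.add(SelfMatch(a[0], a[1], b[0], b[1], "-"))

    return sorted(matches)


def infer_unit(
    matches: list[SelfMatch],
    region: tuple[str, int, int],
    gene_name: str | None = None,
    override: tuple[int, int] | None = None,
    rel_tol: float = 0.02,
) -> RepeatUnit:
    """Infer the repeat unit from the spacing of off-diagonal self-matches.

    The unit length is the fundamental period of the forward off-diagonal
    offsets: when every offset is (within ``rel_tol``) an integer multiple
    of the smallest one, that smallest offset is the period and the copy
    count is one more than the number of distinct multiples observed.
    Offsets that do not fit a single period set the ``ambiguous`` flag and
    the smallest candidate period is used.  A user-supplied ``override``
    interval (curated unit boundaries) always wins over inference.
    Reverse-strand matches (palindrome arms) never inform the period.
    """
    region_id, r_start, r_end = region
    if override is not None:
        return RepeatUnit(region_id, override[0], override[1], gene_name=gene_name,
                          copy_count_estimate=max(1, _count_copies(matches, override[1] - override[0], rel_tol)))

    offsets = sorted({m.offset for m in matches if m.strand == "+" and m.offset > 0})
    if not offsets:
        return RepeatUnit(region_id, r_start, r_end, copy_count_estimate=1, gene_name=gene_name)

    period = offsets[0]
    multiples = set()
    ambiguous = False
    for off in offsets:
        ratio = off / period
        nearest = round(ratio)
        if nearest >= 1 and abs(ratio - nearest) <= rel_tol * nearest:
            multiples.add(nearest)
        else:
            ambiguous = True
    if ambiguous:
        # no single period explains every offset; fall back to the most
        # frequent offset if one dominates, else keep the smallest
        counts = Counter(m.offset for m in matches if m.strand == "+" and m.offset > 0)
        top = counts.most_common(2)
        if len(top) == 1 or top[0][1] > top[1][1]:
            period = min(period, top[0][0]) if top[0][0] % period == 0 else top[0][0]
        multiples = {round(off / period) for off in offsets
                     if abs(off / period - round(off / period)) <= rel_tol * max(1, round(off / period))}
        multiples.discard(0)

    copies = 1 + len(multiples)
    return RepeatUnit(region_id, r_start, r_start + period,
                      copy_count_estimate=copies, gene_name=gene_name, ambiguous=ambiguous)


def _count_copies(matches: list[SelfMatch], period: int, rel_tol: float) -> int:
    multiples = set()
    for m in matches:
        if m.strand != "+" or m.offset <= 0:
            continue
        nearest = round(m.offset / period)
        if nearest >= 1 and abs(m.offset / period - nearest) <= rel_tol * nearest:
            multiples.add(nearest)
    return 1 + len(multiples)


def matches_to_segments(matches: list[SelfMatch]) -> list[tuple[int, int, int, int]]:
    """Export matches as dotplot segment endpoints (x1, y1, x2, y2)."""
    return [(m.query_start, m.target_start, m.query_end, m.target_end) for m in matches]
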