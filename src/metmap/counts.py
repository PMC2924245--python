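"""From mapped reads to observed fragment states.

HpaII digestion leaves fragment ends that read "CGG" on the sequenced
strand, so read filtering, end assignment and the single-end approximation
of paired-end fragment counts all key off the cut coordinates. Counts are
finally capped into the ten observed states using a dataset-specific value
``k_max`` estimated from a low-bias reference set of fragments.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

from .genome import Fragment
from .params import poisson_cap

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "KmaxEstimate",
    "filter_reads",
    "fragment_read_counts",
    "site_end_counts",
    "estimate_kmax",
    "cap_count",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentRecord:
    """A mapped single-end read, reduced to what end assignment needs.

    ``prefix`` is the first three bases *as sequenced* (for a reverse-strand
    alignment this is the reverse complement of the last three aligned
    reference bases). ``start``/``end`` are 0-based half-open reference
    coordinates of the alignment.
    """

    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    prefix: str | None = None  # first 3 sequenced bases, if known

    @property
    def five_prime(self) -> int:
        """0-based reference coordinate of the sequenced 5' base."""
        return self.start if self.strand == "+" else self.end - 1


def filter_reads(alignments) -> tuple[list[AlignmentRecord], dict]:
    """Retain only reads whose sequenced 5' prefix is "CGG".

    Records without a known prefix are dropped and counted separately;
    returns (retained, stats) with stats keys ``n_input``, ``n_retained``,
    ``n_dropped_prefix``, ``n_no_prefix``.
    """
    retained = []
    n_input = n_bad = n_none = 0
    for rec in alignments:
        n_input += 1
        if rec.prefix is None:
            n_none += 1
            continue
        if rec.prefix.upper() == "CGG":
            retained.append(rec)
        else:
            n_bad += 1
    stats = {
        "n_input": n_input,
        "n_retained": len(retained),
        "n_dropped_prefix": n_bad,
        "n_no_prefix": n_none,
    }
    if n_none:
        logger.info("dropped %d alignments with unknown read prefix", n_none)
    return retained, stats


def _end_counters(alignments) -> tuple[Counter, Counter]:
    """Per-position 5'-end counters for forward and reverse reads.

    Forward reads representing a fragment's left end start exactly at the
    cut coordinate L. Reverse reads representing the right end start (5')
    at R+1: the antisense strand of the CCGG at the right cut is cleaved two
    bases downstream, leaving the 2-nt CG overhang, so the sequenced 5' base
    sits one base past the sense-strand cut.
    """
    fwd: Counter = Counter()
    rev: Counter = Counter()
    for rec in alignments:
        if rec.strand == "+":
            fwd[(rec.chrom, rec.start)] += 1
        else:
            rev[(rec.chrom, rec.end - 1)] += 1
    return fwd, rev


def _window_count(counter: Counter, chrom: str, pos: int, slack: int) -> int:
    if slack == 0:
        return counter[(chrom, pos)]
    return sum(counter[(chrom, p)] for p in range(pos - slack, pos + slack + 1))


def fragment_read_counts(
    alignments,
    fragments: list[Fragment],
    slack: int = 0,
    paired_counts: dict | None = None,
) -> dict:
    """Assign reads to fragment ends and set each fragment's ``read_count``.

    Single-end data cannot pair the two ends of one fragment copy, so the
    paired count is approximated by the symmetric mean of the two end
    counts, rounded half-up. When true pair counts are available pass them
    as ``paired_counts`` keyed by (chrom, left_cut, right_cut).

    ``slack`` widens end matching by +-slack bp for aligner off-by-one
    dialects. Returns orphan/assignment statistics; fragments are modified
    in place.
    """
    fwd, rev = _end_counters(alignments)
    left_ends = {(f.chrom, f.left.cut_pos) for f in fragments}
    right_ends = {(f.chrom, f.right.cut_pos + 1) for f in fragments}
    for f in fragments:
        if paired_counts is not None:
            f.read_count = paired_counts.get(
                (f.chrom, f.left.cut_pos, f.right.cut_pos), 0
            )
            continue
        r_left = _window_count(fwd, f.chrom, f.left.cut_pos, slack)
        r_right = _window_count(rev, f.chrom, f.right.cut_pos + 1, slack)
        f.read_count = math.floor((r_left + r_right) / 2 + 0.5)
    n_orphan_fwd = sum(c for k, c in fwd.items() if k not in left_ends)
    n_orphan_rev = sum(c for k, c in rev.items() if k not in right_ends)
    stats = {
        "n_forward": sum(fwd.values()),
        "n_reverse": sum(rev.values()),
        "n_orphans": n_orphan_fwd + n_orphan_rev,
    }
    if stats["n_orphans"]:
        logger.info("%d reads matched no candidate fragment end", stats["n_orphans"])
    return stats


def site_end_counts(alignments, hpaii_sites) -> dict[tuple[str, int], int]:
    """Total reads whose 5' end marks a given HpaII cut (either strand).

    This is the naive per-site read-count signal that the model corrects;
    it is kept for raw-count baselines and validation plots.
    """
    fwd, rev = _end_counters(alignments)
    out = {}
    for s in hpaii_sites:
        key = (s.chrom, s.cut_pos)
        out[key] = fwd[(s.chrom, s.cut_pos)] + rev[(s.chrom, s.cut_pos + 1)]
    return out


@dataclass(frozen=True)
class KmaxEstimate:
    k_max: float
    n_reference_fragments: int
    mean_count: float

    @property
    def degenerate(self) -> bool:
        return self.k_max <= 0


def estimate_kmax(
    fragments: list[Fragment],
    islands: dict[str, list[tuple[int, int]]],
    min_len: int = 50,
    max_len: int = 80,
) -> KmaxEstimate:
    """Estimate the capping value from a low-bias reference fragment set.

    Reference fragments are 50–80 bp, hold no interior restriction site,
    and lie fully inside a CpG island — short enough to be insensitive to
    size selection, interior-free so neighborhood methylation cannot
    suppress them, and island-located so they are presumed unmethylated.
    Their counts are modeled as Poisson; k_max is the mean plus two standard
    deviations (sqrt of the mean).
    """
    ref = []
    for f in fragments:
        if not min_len <= f.length <= max_len or f.interior_sites:
            continue
        for a, b in islands.get(f.chrom, ()):
            if a <= f.start and f.end <= b:
                ref.append(f.read_count)
                break
    if not ref:
        raise ValueError(
            "empty k_max reference set: no interior-free 50-80 bp fragment lies "
            "fully inside a provided island; supply a different island set or "
            "relax the length thresholds"
        )
    mean = sum(ref) / len(ref)
    est = KmaxEstimate(poisson_cap(mean), len(ref), mean)
    if est.degenerate:
        logger.warning("degenerate k_max=0 (all reference counts zero)")
    return est


def cap_count(r: int, k_max: float) -> int:
    """Cap a fragment read count into the ten observed states.

    ``f = min(9, floor(10 r / k_max))``: monotone in r, uniform bins below
    the cap, saturating at 9 for counts at or above k_max.
    """
    if k_max <= 0:
        raise ValueError("k_max must be positive")
    if r < 0:
        raise ValueError("read count must be non-negative")
    return min(9, math.floor(10.0 * r / k_max))
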