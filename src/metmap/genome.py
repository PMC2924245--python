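"""Reference-genome side of the assay: CG/CCGG sites, candidate fragments,
experiment scope and span, and sequence-only CpG islands.

Coordinates are 0-based, half-open throughout. HpaII cleaves C^CGG, so the
cut coordinate of a CCGG at position ``p-1`` is ``p``, the position of the
CG's C; a fragment bounded by cuts L < R occupies [L, R) and has length R-L.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

__all__ = [
    "CGSite",
    "Fragment",
    "SpanReport",
    "GGIsland",
    "scan_cg_sites",
    "enumerate_fragments",
    "sites_in_scope",
    "compute_span",
    "neighbor_exclusion_fraction",
    "call_gg_islands",
]


@dataclass(frozen=True)
class CGSite:
    """A CG dinucleotide; ``is_hpaii`` when it is the middle of a CCGG."""

    chrom: str
    pos: int  # 0-based position of the C of the CG
    is_hpaii: bool

    @property
    def cut_pos(self) -> int:
        """HpaII cut coordinate (C^CGG): the position of the CG's C."""
        if not self.is_hpaii:
            raise AttributeError("cut_pos is defined only for HpaII sites")
        return self.pos


@dataclass
class Fragment:
    """A candidate HpaII–HpaII fragment inside the size-selection window."""

    chrom: str
    left: CGSite
    right: CGSite
    interior_sites: tuple[CGSite, ...] = ()
    read_count: int = 0
    f_state: int | None = None

    @property
    def length(self) -> int:
        return self.right.cut_pos - self.left.cut_pos

    @property
    def start(self) -> int:
        return self.left.cut_pos

    @property
    def end(self) -> int:
        return self.right.cut_pos

    def __post_init__(self) -> None:
        if self.left.cut_pos >= self.right.cut_pos:
            raise ValueError("fragment ends out of order")


@dataclass(frozen=True)
class SpanReport:
    method: str
    genome_bp_spanned: int
    fraction_of_genome: float
    n_informative_ccgg: int
    fraction_of_islands: float | None = None
    island_bp_spanned: int | None = None


@dataclass(frozen=True)
class GGIsland:
    """A sequence-only CpG island (maximal +17/−1 segment passing filters)."""

    chrom: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_cg: float


def scan_cg_sites(sequence: str, chrom: str = "seq") -> list[CGSite]:
    """Locate every CG on the forward strand, flagging CCGG membership.

    CG is its own reverse complement, so forward-strand scanning is
    exhaustive. Matches containing N are skipped implicitly (they cannot
    spell CG).
    """
    seq = sequence.upper()
    sites: list[CGSite] = []
    i = seq.find("CG")
    n = len(seq)
    while i != -1:
        is_hpaii = i >= 1 and i + 2 < n and seq[i - 1] == "C" and seq[i + 2] == "G"
        sites.append(CGSite(chrom, i, is_hpaii))
        i = seq.find("CG", i + 1)
    return sites


def _gap_intervals(sequence: str, min_run: int) -> list[tuple[int, int]]:
    """Intervals of >= min_run consecutive N (assembly gaps)."""
    gaps = []
    seq = sequence.upper()
    i = seq.find("N")
    while i != -1:
        j = i
        while j < len(seq) and seq[j] == "N":
            j += 1
        if j - i >= min_run:
            gaps.append((i, j))
        i = seq.find("N", j)
    return gaps


def enumerate_fragments(
    hpaii_sites: list[CGSite],
    l_min: int,
    l_max: int,
    sequence: str | None = None,
    max_gap_run: int = 10,
) -> list[Fragment]:
    """All HpaII–HpaII fragments whose cut-to-cut length is in [l_min, l_max].

    Ends need not be adjacent sites (methylated sites are not cleaved, so
    any pair can bound a real fragment); interior HpaII sites are recorded.
    When ``sequence`` is supplied, fragments spanning an assembly gap
    (> ``max_gap_run`` consecutive N) are dropped.
    """
    if not 0 < l_min <= l_max:
        raise ValueError(f"invalid size window [{l_min}, {l_max}]")
    sites = sorted(hpaii_sites, key=lambda s: s.cut_pos)
    cuts = [s.cut_pos for s in sites]
    gaps = _gap_intervals(sequence, max_gap_run + 1) if sequence else []
    frags: list[Fragment] = []
    for i, left in enumerate(sites):
        lo = bisect.bisect_left(cuts, left.cut_pos + l_min, lo=i + 1)
        hi = bisect.bisect_right(cuts, left.cut_pos + l_max, lo=lo)
        for j in range(lo, hi):
            right = sites[j]
            if any(g0 < right.cut_pos and g1 > left.cut_pos for g0, g1 in gaps):
                continue
            frags.append(
                Fragment(
                    left.chrom, left, right, interior_sites=tuple(sites[i + 1 : j])
                )
            )
    return frags


def sites_in_scope(
    hpaii_sites: list[CGSite], fragments: list[Fragment]
) -> list[CGSite]:
    """HpaII sites lying on at least one size-passing fragment.

    Membership as an interior site counts even though at most three interior
    variables are retained in the fragment's factor downstream.
    """
    member = set()
    for f in fragments:
        member.add((f.chrom, f.left.pos))
        member.add((f.chrom, f.right.pos))
        for s in f.interior_sites:
            member.add((s.chrom, s.pos))
    return [s for s in hpaii_sites if (s.chrom, s.pos) in member]


def _informative_flags(
    hpaii_sites: list[CGSite], l_min: int, l_max: int, method: str
) -> dict[tuple[str, int], bool]:
    """1/0 flag per CCGG: can the method report its methylation state?

    MethylSeq: the site lies on some (not necessarily adjacent-ended)
    size-passing fragment. RRBS: complete methylation-insensitive digestion
    yields only adjacent-site fragments, so the site must bound an adjacent
    gap inside the window.
    """
    flags: dict[tuple[str, int], bool] = {}
    by_chrom: dict[str, list[CGSite]] = {}
    for s in hpaii_sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, sites in by_chrom.items():
        sites = sorted(sites, key=lambda s: s.cut_pos)
        if method == "methylseq":
            frags = enumerate_fragments(sites, l_min, l_max)
            in_scope = {(s.chrom, s.pos) for s in sites_in_scope(sites, frags)}
            for s in sites:
                flags[(chrom, s.pos)] = (chrom, s.pos) in in_scope
        elif method == "rrbs":
            cuts = [s.cut_pos for s in sites]
            for k, s in enumerate(sites):
                ok = False
                if k > 0 and l_min <= cuts[k] - cuts[k - 1] <= l_max:
                    ok = True
                if k + 1 < len(cuts) and l_min <= cuts[k + 1] - cuts[k] <= l_max:
                    ok = True
                flags[(chrom, s.pos)] = ok
        else:
            raise ValueError(f"unknown method {method!r}")
    return flags


def _spanned_intervals(
    sites: list[CGSite], flags: dict[tuple[str, int], bool]
) -> list[tuple[int, int]]:
    """Maximal regions bounded by consecutive informative CCGGs (one chrom)."""
    sites = sorted(sites, key=lambda s: s.cut_pos)
    out: list[tuple[int, int]] = []
    run_start = None
    prev = None
    for s in sites:
        if flags[(s.chrom, s.pos)]:
            if run_start is None:
                run_start = s.cut_pos
            prev = s.cut_pos
        else:
            if run_start is not None and prev is not None and prev > run_start:
                out.append((run_start, prev))
            run_start = None
            prev = None
    if run_start is not None and prev is not None and prev > run_start:
        out.append((run_start, prev))
    return out


def compute_span(
    hpaii_sites: list[CGSite],
    l_min: int,
    l_max: int,
    method: str = "methylseq",
    genome_length: int | None = None,
    islands: dict[str, list[tuple[int, int]]] | None = None,
) -> SpanReport:
    """Span of a methyltyping method: total length of maximal regions whose
    bounding CCGGs are all informative.

    With ``islands`` given, the island span additionally extends to an island
    edge when the CCGG nearest to that edge is informative (applied at both
    edges independently).
    """
    flags = _informative_flags(hpaii_sites, l_min, l_max, method)
    by_chrom: dict[str, list[CGSite]] = {}
    for s in hpaii_sites:
        by_chrom.setdefault(s.chrom, []).append(s)

    spanned: dict[str, list[tuple[int, int]]] = {
        chrom: _spanned_intervals(sites, flags) for chrom, sites in by_chrom.items()
    }
    total = sum(e - s for ivs in spanned.values() for s, e in ivs)
    n_inf = sum(flags.values())
    frac_genome = total / genome_length if genome_length else 0.0

    frac_islands = island_bp = None
    if islands is not None:
        island_bp = 0
        island_total = 0
        for chrom, ivs in islands.items():
            sites = sorted(by_chrom.get(chrom, []), key=lambda s: s.cut_pos)
            cuts = [s.cut_pos for s in sites]
            sp = spanned.get(chrom, [])
            for a, b in ivs:
                island_total += b - a
                covered = _clip_intervals(sp, a, b)
                # edge extension: nearest CCGG to each island edge
                for edge, side in ((a, "left"), (b, "right")):
                    idx = _nearest_site(cuts, edge)
                    if idx is None:
                        continue
                    s = sites[idx]
                    if flags[(chrom, s.pos)]:
                        if side == "left":
                            covered.append((a, min(max(s.cut_pos, a), b)))
                        else:
                            covered.append((max(min(s.cut_pos, b), a), b))
                island_bp += sum(e0 - s0 for s0, e0 in merge_intervals(covered))
        frac_islands = island_bp / island_total if island_total else 0.0

    return SpanReport(
        method=method,
        genome_bp_spanned=total,
        fraction_of_genome=frac_genome,
        n_informative_ccgg=n_inf,
        fraction_of_islands=frac_islands,
        island_bp_spanned=island_bp,
    )


def _nearest_site(cuts: list[int], edge: int) -> int | None:
    if not cuts:
        return None
    i = bisect.bisect_left(cuts, edge)
    best, dist = None, None
    for j in (i - 1, i):
        if 0 <= j < len(cuts):
            d = abs(cuts[j] - edge)
            if dist is None or d < dist:
                best, dist = j, d
    return best


def _clip_intervals(
    intervals: list[tuple[int, int]], a: int, b: int
) -> list[tuple[int, int]]:
    out = []
    for s, e in intervals:
        s2, e2 = max(s, a), min(e, b)
        if e2 > s2:
            out.append((s2, e2))
    return out


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping (not merely touching) half-open intervals."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s < out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def neighbor_exclusion_fraction(hpaii_sites: list[CGSite], min_dist: int = 40) -> float:
    """Fraction of HpaII sites whose two neighbors are both closer than
    ``min_dist`` bp (the sites a hard distance filter would discard).

    Terminal sites of a chromosome have a single neighbor and never qualify;
    the denominator is all HpaII sites.
    """
    by_chrom: dict[str, list[int]] = {}
    for s in hpaii_sites:
        by_chrom.setdefault(s.chrom, []).append(s.cut_pos)
    n_total = sum(len(v) for v in by_chrom.values())
    if n_total < 3:
        return 0.0
    n_excluded = 0
    for cuts in by_chrom.values():
        cuts.sort()
        for k in range(1, len(cuts) - 1):
            if cuts[k] - cuts[k - 1] < min_dist and cuts[k + 1] - cuts[k] < min_dist:
                n_excluded += 1
    return n_excluded / n_total


# --- Gardiner-Garden sequence-only CpG islands ---------------------------

_CG_SCORE = 17
_OTHER_SCORE = -1


def _maximal_scoring_segments(scores: list[int]) -> list[tuple[int, int]]:
    """All maximal-scoring segments of a score sequence (Ruzzo–Tompa).

    Returns half-open index intervals into ``scores``, disjoint, in left
    order; ties resolve leftmost-longest by construction.
    """
    # stack entries: [start, end, L, R] with L = cumulative before start,
    # R = cumulative through end
    stack: list[list[int]] = []
    cum = 0
    for i, s in enumerate(scores):
        prev_cum = cum
        cum += s
        if s <= 0:
            continue
        k = [i, i + 1, prev_cum, cum]
        while True:
            j = None
            for t in range(len(stack) - 1, -1, -1):
                if stack[t][2] < k[2]:
                    j = t
                    break
            if j is None or stack[j][3] >= k[3]:
                stack.append(k)
                break
            k = [stack[j][0], k[1], stack[j][2], k[3]]
            del stack[j:]
    return [(a, b) for a, b, _, _ in stack]


def call_gg_islands(sequence: str, chrom: str = "seq") -> list[GGIsland]:
    """Sequence-only CpG islands: maximal segments under +17 per CG / −1 per
    other dinucleotide (overlapping dinucleotides, step 1), filtered by
    length > 200 bp, GC fraction >= 0.5 and obs/exp CG > 0.6, where
    obs/exp = (#CG × L) / (#C × #G).
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 2:
        return []
    scores = [
        _CG_SCORE if seq[i] == "C" and seq[i + 1] == "G" else _OTHER_SCORE
        for i in range(n - 1)
    ]
    islands = []
    for a, b in _maximal_scoring_segments(scores):
        start, end = a, b + 1  # dinucleotide [a, b) covers bases [a, b+1)
        length = end - start
        if length <= 200:
            continue
        sub = seq[start:end]
        n_c = sub.count("C")
        n_g = sub.count("G")
        gc = (n_c + n_g) / length
        if gc < 0.5:
            continue
        n_cg = sum(
            1 for i in range(length - 1) if sub[i] == "C" and sub[i + 1] == "G"
        )
        obs_exp = (n_cg * length) / (n_c * n_g) if n_c and n_g else 0.0
        if obs_exp <= 0.6:
            continue
        islands.append(GGIsland(chrom, start, end, gc, obs_exp))
    return islands
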