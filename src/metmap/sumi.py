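"""Strongly Unmethylated Island (SUMI) annotation.

SUMIs are experiment-specific unmethylated regions, the union of two sets:

* Set 1 — maximal runs of consecutive CG variables (HpaII or not) whose
  posterior island probability exceeds 0.1, kept when the read data
  directly supports at least two fragments inside the run (strong sequence
  evidence, possibly weak direct evidence);
* Set 2 — 600 bp windows centered on HpaII sites that are *not* called
  island-like (p_island < 0.1) but whose score exceeds the outside-island
  prior score (0.1663); overlapping windows merge, and a merged region is
  kept when at least 30% of its HpaII sites beat the score threshold and at
  least two supported fragments lie inside (strong direct evidence, weak
  sequence evidence).

Each SUMI is scored by the mean score of the HpaII sites it contains.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import Fragment, merge_intervals
from .model import PosteriorTable
from .params import ModelParameters

__all__ = ["SUMI", "annotate_sumis", "compare_sumi_sets"]


@dataclass(frozen=True)
class SUMI:
    chrom: str
    start: int
    end: int
    score: float
    provenance: str  # "set1" | "set2" | "both"
    n_sites: int
    n_supported_fragments: int


def _supported_inside(
    fragments: list[Fragment], chrom: str, start: int, end: int, min_count: int
) -> int:
    return sum(
        1
        for f in fragments
        if f.chrom == chrom
        and f.read_count >= min_count
        and f.start >= start
        and f.end <= end
    )


def annotate_sumis(
    posteriors: PosteriorTable,
    fragments: list[Fragment],
    params: ModelParameters,
    p_island_threshold: float = 0.1,
    score_threshold: float | None = None,
    min_supported_fragments: int = 2,
    min_site_fraction: float = 0.3,
    window: int = 600,
    min_fragment_count: int = 1,
) -> list[SUMI]:
    """Annotate scored SUMIs from posteriors and direct fragment support.

    ``score_threshold`` defaults to the model's outside-island prior score.
    Direct support means a candidate fragment with raw read count >=
    ``min_fragment_count`` lying fully inside the region. Overlapping
    regions from the two sets are merged; merged regions are rescored.
    """
    if score_threshold is None:
        score_threshold = params.unmeth_prior_outside_score
    by_chrom: dict[str, list] = {}
    for r in posteriors.records:
        by_chrom.setdefault(r.site.chrom, []).append(r)

    candidates: list[tuple[str, int, int, str]] = []
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: r.site.pos)
        # --- set 1: island-probability runs
        run: list = []
        for r in recs + [None]:
            if r is not None and r.p_island > p_island_threshold:
                run.append(r)
                continue
            if run:
                start, end = run[0].site.pos, run[-1].site.pos + 2
                if (
                    _supported_inside(fragments, chrom, start, end, min_fragment_count)
                    >= min_supported_fragments
                ):
                    candidates.append((chrom, start, end, "set1"))
            run = []
        # --- set 2: windows on confidently-scored non-island sites
        windows = [
            (r.site.cut_pos - window // 2, r.site.cut_pos + window // 2)
            for r in recs
            if r.site.is_hpaii
            and r.p_island < p_island_threshold
            and r.score is not None
            and r.score > score_threshold
        ]
        for start, end in merge_intervals(windows):
            region_sites = [
                r
                for r in recs
                if r.site.is_hpaii and start <= r.site.pos < end
            ]
            n_above = sum(1 for r in region_sites if r.score > score_threshold)
            if not region_sites or n_above / len(region_sites) < min_site_fraction:
                continue
            if (
                _supported_inside(fragments, chrom, start, end, min_fragment_count)
                >= min_supported_fragments
            ):
                candidates.append((chrom, start, end, "set2"))

    # union of both sets, merged, rescored
    out: list[SUMI] = []
    for chrom in sorted({c for c, *_ in candidates}):
        ivs = [(s, e, tag) for c, s, e, tag in candidates if c == chrom]
        merged: list[tuple[int, int, set]] = []
        for s, e, tag in sorted(ivs):
            if merged and s < merged[-1][1]:
                ms, me, tags = merged[-1]
                merged[-1] = (ms, max(me, e), tags | {tag})
            else:
                merged.append((s, e, {tag}))
        recs = by_chrom.get(chrom, [])
        for s, e, tags in merged:
            scores = [
                r.score
                for r in recs
                if r.site.is_hpaii and s <= r.site.pos < e and r.score is not None
            ]
            out.append(
                SUMI(
                    chrom,
                    s,
                    e,
                    score=sum(scores) / len(scores) if scores else float("nan"),
                    provenance="both" if len(tags) > 1 else tags.pop(),
                    n_sites=len(scores),
                    n_supported_fragments=_supported_inside(
                        fragments, chrom, s, e, min_fragment_count
                    ),
                )
            )
    return out


def compare_sumi_sets(sumis_a: list[SUMI], sumis_b: list[SUMI]) -> dict:
    """Overlap bookkeeping between two SUMI annotations on one assembly.

    Returns counts of a-only, b-only and overlapping (>= 1 bp) calls plus
    interval union and intersection lists.
    """
    chroms_a = {s.chrom for s in sumis_a}
    chroms_b = {s.chrom for s in sumis_b}
    if chroms_a and chroms_b and not chroms_a & chroms_b:
        raise ValueError(
            f"chromosome namespaces do not overlap: {sorted(chroms_a)} vs "
            f"{sorted(chroms_b)}"
        )

    def overlaps(x: SUMI, y: SUMI) -> bool:
        return x.chrom == y.chrom and x.start < y.end and y.start < x.end

    a_overlap = [s for s in sumis_a if any(overlaps(s, t) for t in sumis_b)]
    b_overlap = [s for s in sumis_b if any(overlaps(t, s) for t in sumis_a)]

    union: list[tuple[str, int, int]] = []
    inter: list[tuple[str, int, int]] = []
    for chrom in sorted(chroms_a | chroms_b):
        ia = [(s.start, s.end) for s in sumis_a if s.chrom == chrom]
        ib = [(s.start, s.end) for s in sumis_b if s.chrom == chrom]
        union.extend((chrom, s, e) for s, e in merge_intervals(ia + ib))
        ma, mb = merge_intervals(ia), merge_intervals(ib)
        for s1, e1 in ma:
            for s2, e2 in mb:
                s, e = max(s1, s2), min(e1, e2)
                if e > s:
                    inter.append((chrom, s, e))
    return {
        "n_a": len(sumis_a),
        "n_b": len(sumis_b),
        "n_a_only": len(sumis_a) - len(a_overlap),
        "n_b_only": len(sumis_b) - len(b_overlap),
        "n_a_overlapping": len(a_overlap),
        "n_b_overlapping": len(b_overlap),
        "union": union,
        "intersection": inter,
    }


def jaccard(
    intervals_a: list[tuple[int, int]], intervals_b: list[tuple[int, int]]
) -> float:
    """Base-level Jaccard index between two interval sets on one sequence."""
    ma, mb = merge_intervals(list(intervals_a)), merge_intervals(list(intervals_b))
    inter = 0
    for s1, e1 in ma:
        for s2, e2 in mb:
            inter += max(0, min(e1, e2) - max(s1, s2))
    total_a = sum(e - s for s, e in ma)
    total_b = sum(e - s for s, e in mb)
    union = total_a + total_b - inter
    return inter / union if union else 1.0
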