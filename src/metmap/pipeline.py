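"""End-to-end orchestration: read filtering, counting, capping, per-region
inference with overlap context, merging, and SUMI annotation.

Chromosomes are segmented into non-overlapping core regions (default
0.5 Mbp) extended by ``l_max`` bp of context on each side; fragments and
sites are owned by exactly one core region (by the left cut / site
position), and the context makes boundary posteriors match a whole-
chromosome run to numerical precision because observations farther than a
few fragment lengths away carry no information about a site.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .counts import cap_count, estimate_kmax, filter_reads, fragment_read_counts
from .genome import CGSite, call_gg_islands, enumerate_fragments, scan_cg_sites
from .model import PosteriorTable, build_model, infer_posteriors
from .params import ModelParameters
from .sumi import annotate_sumis

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "Region", "segment_genome", "run_pipeline", "score_chromosome"]


@dataclass(frozen=True)
class Region:
    chrom: str
    core_start: int
    core_end: int
    ctx_start: int
    ctx_end: int

    def owns_site(self, site: CGSite) -> bool:
        return self.core_start <= site.pos < self.core_end


@dataclass
class RunConfig:
    genome: str | Path
    alignments: str | Path | None = None
    l_min: int = 50
    l_max: int = 300
    region_size: int = 500_000
    islands: str | Path | None = None  # BED for k_max; None -> GG caller
    k_max: float | None = None  # explicit override of the estimate
    seed: int = 0
    out_dir: str | Path = "metmap_out"
    params: ModelParameters = field(default_factory=ModelParameters)
    end_match_slack: int = 0

    def validate(self) -> None:
        if not 0 < self.l_min <= self.l_max:
            raise ValueError(f"invalid size window [{self.l_min}, {self.l_max}]")
        if self.region_size <= self.l_max:
            raise ValueError("region_size must exceed l_max")


def segment_genome(
    chrom_lengths: dict[str, int],
    region_size: int = 500_000,
    l_max: int = 300,
    context_factor: int = 2,
) -> list[Region]:
    """Non-overlapping core regions of ``region_size`` bp, each with
    ``context_factor * l_max`` bp of context on both sides (clipped at
    chromosome ends).

    Two fragment lengths of context guarantee that every fragment whose
    evidence could measurably touch a core site lies fully inside the
    context window: excluded fragments end at least ``l_max`` bp from the
    core, and the conditioned island chain forgets evidence at a per-base
    rate that makes influence at that distance far below numerical noise.
    """
    if region_size <= l_max:
        raise ValueError("region_size must exceed l_max")
    ctx = context_factor * l_max
    regions = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            end = min(start + region_size, length)
            regions.append(
                Region(chrom, start, end, max(0, start - ctx), min(length, end + ctx))
            )
            start = end
    return regions


def score_chromosome(
    cg_sites: list[CGSite],
    fragments,
    params: ModelParameters,
    k_max: float,
    region_size: int = 500_000,
    seed: int = 0,
    chrom_length: int | None = None,
) -> PosteriorTable:
    """Per-region exact inference over one chromosome, merged in order.

    ``fragments`` must already carry read counts; their observed states are
    capped here with ``k_max``. Fragments whose context region does not
    fully contain them are never split: ownership is by left cut, and the
    context window of ``l_max`` guarantees containment.
    """
    for f in fragments:
        f.f_state = cap_count(f.read_count, k_max)
    if not cg_sites:
        return PosteriorTable([], params, seed)
    chrom = cg_sites[0].chrom
    length = chrom_length or (max(s.pos for s in cg_sites) + 2)
    regions = segment_genome({chrom: length}, region_size, params.l_max)
    merged = PosteriorTable([], params, seed)
    for region in regions:
        sites = [s for s in cg_sites if region.ctx_start <= s.pos < region.ctx_end]
        frags = [
            f
            for f in fragments
            if region.ctx_start <= f.start and f.end <= region.ctx_end
        ]
        if not sites:
            continue
        graph = build_model(sites, frags, params, seed)
        post = infer_posteriors(graph)
        merged.records.extend(r for r in post.records if region.owns_site(r.site))
    return merged


def run_pipeline(config: RunConfig) -> dict:
    """Filter -> count -> k_max -> per-region inference -> SUMIs -> outputs.

    Writes per-site scores, SUMI BED/TSV and a run report under
    ``config.out_dir`` and returns the report dictionary.
    """
    from . import io as mio

    config.validate()
    genome_path = Path(config.genome)
    if not genome_path.exists():
        raise FileNotFoundError(f"genome FASTA not found: {genome_path}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = dataclasses.replace(config.params, l_min=config.l_min, l_max=config.l_max)

    genome = mio.read_fasta(genome_path)
    report: dict = {"version": __version__, "seed": config.seed}

    alignments = []
    if config.alignments is not None:
        aln_path = Path(config.alignments)
        if not aln_path.exists():
            raise FileNotFoundError(f"alignments not found: {aln_path}")
        alignments, filter_stats = filter_reads(mio.read_alignments(aln_path))
        report["read_filter"] = filter_stats

    all_sites: dict[str, list[CGSite]] = {}
    all_frags: dict[str, list] = {}
    for chrom, seq in genome.items():
        sites = scan_cg_sites(seq, chrom)
        hpaii = [s for s in sites if s.is_hpaii]
        frags = enumerate_fragments(hpaii, config.l_min, config.l_max, sequence=seq)
        all_sites[chrom] = sites
        all_frags[chrom] = frags
    flat_frags = [f for frags in all_frags.values() for f in frags]
    report["n_candidate_fragments"] = len(flat_frags)

    count_stats = fragment_read_counts(
        alignments, flat_frags, slack=config.end_match_slack
    )
    report["counting"] = count_stats

    if config.k_max is not None:
        k_max = float(config.k_max)
        report["k_max"] = {"k_max": k_max, "source": "explicit"}
    else:
        if config.islands is not None:
            islands = mio.read_bed_intervals(config.islands)
            source = "bed"
        else:
            islands = {
                chrom: [(i.start, i.end) for i in call_gg_islands(seq, chrom)]
                for chrom, seq in genome.items()
            }
            source = "gg-caller"
        est = estimate_kmax(flat_frags, islands)
        if est.degenerate:
            raise RuntimeError(
                "degenerate k_max = 0: reference fragments received no reads; "
                "check read filtering and end-matching, or pass an explicit k_max"
            )
        k_max = est.k_max
        report["k_max"] = {
            "k_max": k_max,
            "source": source,
            "n_reference_fragments": est.n_reference_fragments,
            "mean_count": est.mean_count,
        }

    header = [
        f"metmap {__version__}",
        f"seed={config.seed} l_min={config.l_min} l_max={config.l_max} "
        f"k_max={k_max:.4f} region_size={config.region_size}",
    ]
    all_posteriors = PosteriorTable([], params, config.seed)
    sumis = []
    for chrom, seq in genome.items():
        post = score_chromosome(
            all_sites[chrom],
            all_frags[chrom],
            params,
            k_max,
            region_size=config.region_size,
            seed=config.seed,
            chrom_length=len(seq),
        )
        all_posteriors.records.extend(post.records)
        sumis.extend(annotate_sumis(post, all_frags[chrom], params))

    in_scope = all_posteriors.hpaii()
    scope_member = set()
    for f in flat_frags:
        scope_member.add((f.chrom, f.left.pos))
        scope_member.add((f.chrom, f.right.pos))
        scope_member.update((s.chrom, s.pos) for s in f.interior_sites)
    in_scope = [r for r in in_scope if (r.site.chrom, r.site.pos) in scope_member]

    mio.write_site_scores(out_dir / "site_scores.tsv", in_scope, header)
    mio.write_sumi_bed(out_dir / "sumis.bed", sumis)
    mio.write_sumi_tsv(out_dir / "sumis.tsv", sumis, header)
    report["n_sites_in_scope"] = len(in_scope)
    report["n_sumis"] = len(sumis)
    with open(out_dir / "report.txt", "w") as fh:
        for k, v in sorted(report.items()):
            fh.write(f"{k}\t{v}\n")
    logger.info("wrote %s", out_dir)
    return report
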