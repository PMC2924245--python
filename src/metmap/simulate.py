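"""Synthetic MethylSeq experiments with known ground truth.

The generator mirrors the model's own generative story so that every other
module can be tested against planted truth: a per-base two-state island
chain lays out unmethylated islands; CG dinucleotides are planted with
island-dependent density and a configurable fraction become CCGG (HpaII)
sites; each HpaII site draws a methylation value and an unmethylated-allele
fraction ``u``; candidate fragments are produced per allele when both ends
are cleaved and no interior site is, size-selected, and sampled with
Poisson read counts.

Sequence assembly guarantees that CG/CCGG occurrences are exactly the
planted ones (background bases are patched where they would create a
spurious CG or extend a planted CG into CCGG), so scanning the simulated
FASTA recovers the planted sites bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .counts import AlignmentRecord
from .genome import CGSite, Fragment, enumerate_fragments
from .params import ModelParameters

__all__ = [
    "SimParams",
    "SimTruth",
    "simulate_genome",
    "simulate_methylome",
    "simulate_reads",
    "simulate_experiment",
    "calibration_summary",
]


@dataclass(frozen=True)
class SimParams:
    """Knobs of the generator that the model parameters do not fix.

    ``gc_in``/``gc_out``: background GC fraction inside/outside islands
    (vertebrate-like defaults). ``hpaii_fraction``: fraction of planted CGs
    extended to CCGG (between the genome-wide and island-local CCGG/CG
    ratios observed in human sequence). ``partial_u_low/high``: the
    unmethylated-allele fraction of a partially methylated site is uniform
    on this interval. Island geometry defaults to the model's own chain;
    ``island_mean_length``/``island_spacing`` override it with realistic
    CpG-island geometry (hundreds of bp) for island-recovery studies.
    """

    gc_in: float = 0.65
    gc_out: float = 0.38
    hpaii_fraction: float = 0.15
    partial_u_low: float = 0.1
    partial_u_high: float = 0.9
    island_mean_length: float | None = None  # bp; None -> 1/b_leave
    island_spacing: float | None = None  # bp between islands; None -> 1/a_enter


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    chrom: str
    sequence: str
    islands: list[tuple[int, int]]
    cg_sites: list[CGSite]
    site_island: dict[int, bool]  # CG pos -> planted island status
    site_u: dict[int, float] = field(default_factory=dict)  # HpaII pos -> u
    fragments: list[Fragment] = field(default_factory=list)
    fragment_rho: dict[tuple[int, int], float] = field(default_factory=dict)
    seed: int | None = None
    n_eligible_island: int = 0
    n_eligible_outside: int = 0

    @property
    def hpaii_sites(self) -> list[CGSite]:
        return [s for s in self.cg_sites if s.is_hpaii]


def _island_state_runs(
    length: int, a: float, b: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-base island indicator from alternating geometric sojourns,
    started from the stationary distribution."""
    state = rng.random() < a / (a + b)  # True = island
    out = np.empty(length, dtype=bool)
    i = 0
    while i < length:
        run = rng.geometric(b if state else a)
        j = min(length, i + run)
        out[i:j] = state
        state = not state
        i = j
    return out


def _runs_to_intervals(flags: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(flags.astype(np.int8)))
    bounds = np.concatenate(([0], idx + 1, [len(flags)]))
    return [
        (int(bounds[k]), int(bounds[k + 1]))
        for k in range(len(bounds) - 1)
        if flags[bounds[k]]
    ]


def simulate_genome(
    length: int,
    params: ModelParameters,
    seed: int,
    sim: SimParams = SimParams(),
    chrom: str = "sim1",
) -> SimTruth:
    """Generate an island-structured genome of ``length`` bp.

    Island sojourns follow the model's per-base chain (a_enter, b_leave)
    unless ``sim`` overrides the geometry; CGs are planted per eligible
    position with probability p_cg_in/p_cg_out and a ``hpaii_fraction``
    subset becomes CCGG.
    """
    if length < 10**4:
        raise ValueError("simulated genomes should be at least 10 kb")
    rng = np.random.default_rng(seed)
    a = 1.0 / sim.island_spacing if sim.island_spacing else params.a_enter
    b = 1.0 / sim.island_mean_length if sim.island_mean_length else params.b_leave
    island = _island_state_runs(length, a, b, rng)
    p_cg = np.where(island, params.p_cg_in, params.p_cg_out)
    cand = rng.random(length) < p_cg
    hpa = rng.random(length) < sim.hpaii_fraction

    # resolve token placement left to right (tokens: CG=2bp, CCGG=4bp with
    # the CG at offset 1)
    seq = np.empty(length, dtype="<U1")
    gc = np.where(island, sim.gc_in, sim.gc_out)
    u01 = rng.random(length)
    # background bases: split GC mass between C/G, AT mass between A/T
    u2 = rng.random(length)
    bg = np.where(
        u01 < gc,
        np.where(u2 < 0.5, "C", "G"),
        np.where(u2 < 0.5, "A", "T"),
    )
    seq[:] = bg

    cg_pos: list[int] = []
    hpaii_flag: list[bool] = []
    site_island: dict[int, bool] = {}
    n_elig = np.zeros(2, dtype=np.int64)  # [outside, island]
    n_token_bases = 0
    next_free = 0
    for j in np.flatnonzero(cand):
        if j < next_free:
            continue  # inside a previous token: not an eligible position
        if hpa[j] and j + 4 <= length:
            seq[j : j + 4] = ["C", "C", "G", "G"]
            cg_pos.append(j + 1)
            hpaii_flag.append(True)
            site_island[j + 1] = bool(island[j])
            token_len = 4
        elif j + 2 <= length:
            seq[j : j + 2] = ["C", "G"]
            cg_pos.append(j)
            hpaii_flag.append(False)
            site_island[j] = bool(island[j])
            token_len = 2
        else:
            continue
        # positions consumed by the token interior were never decisions
        n_token_bases += token_len - 1
        next_free = j + token_len

    # eligible decision positions per island state (token starts count,
    # token interiors do not)
    covered = np.zeros(length, dtype=bool)
    for pos, is_h in zip(cg_pos, hpaii_flag):
        start = pos - 1 if is_h else pos
        token_len = 4 if is_h else 2
        covered[start + 1 : start + token_len] = True
    n_elig[1] = int(np.sum(island & ~covered))
    n_elig[0] = int(np.sum(~island & ~covered))

    _patch_spurious_cg(seq, cg_pos, hpaii_flag, rng)

    sites = [
        CGSite(chrom, pos, bool(flag)) for pos, flag in zip(cg_pos, hpaii_flag)
    ]
    return SimTruth(
        chrom=chrom,
        sequence="".join(seq),
        islands=_runs_to_intervals(island),
        cg_sites=sites,
        site_island=site_island,
        seed=seed,
        n_eligible_island=int(n_elig[1]),
        n_eligible_outside=int(n_elig[0]),
    )


def _patch_spurious_cg(
    seq: np.ndarray, cg_pos: list[int], hpaii_flag: list[bool], rng
) -> None:
    """Replace background bases that would create unplanted CGs or extend a
    planted plain CG into CCGG. Replacements are A/T, which can neither seed
    a CG nor extend one, so a single pass suffices."""
    planted = set(cg_pos)
    s = seq  # mutate in place
    n = len(s)
    joined = "".join(s)
    i = joined.find("CG")
    while i != -1:
        if i not in planted:
            s[i + 1] = "A" if rng.random() < 0.5 else "T"
        i = joined.find("CG", i + 1)
    # patching may leave stale matches in `joined`; re-scan once on the
    # patched sequence to catch CGs formed of untouched bases
    joined = "".join(s)
    i = joined.find("CG")
    while i != -1:
        if i not in planted:
            s[i + 1] = "A" if rng.random() < 0.5 else "T"
        i = joined.find("CG", i + 1)
    for pos, is_h in zip(cg_pos, hpaii_flag):
        if is_h:
            continue
        if pos >= 1 and pos + 2 < n and s[pos - 1] == "C" and s[pos + 2] == "G":
            s[pos + 2] = "A" if rng.random() < 0.5 else "T"


def simulate_methylome(
    truth: SimTruth,
    params: ModelParameters,
    seed: int,
    sim: SimParams = SimParams(),
) -> dict[int, float]:
    """Draw per-HpaII-site methylation and unmethylated-allele fraction u.

    Sites draw (U, P, M) from the island-conditional methylation
    distribution; U gives u=1, M gives u=0, and P draws u uniformly on the
    heterogeneity interval. Returns {CG position: u} and stores it on
    ``truth``.
    """
    rng = np.random.default_rng(seed)
    site_u: dict[int, float] = {}
    for s in truth.hpaii_sites:
        dist = params.meth_cpd(0 if truth.site_island[s.pos] else 1)
        m = rng.choice(3, p=dist)
        if m == 0:
            u = 1.0
        elif m == 2:
            u = 0.0
        else:
            u = rng.uniform(sim.partial_u_low, sim.partial_u_high)
        site_u[s.pos] = float(u)
    truth.site_u = site_u
    return site_u


def fragment_production_rate(f: Fragment, site_u: dict[int, float]) -> float:
    """Per-allele production rate: both ends cleaved, no interior cleaved."""
    rho = site_u[f.left.pos] * site_u[f.right.pos]
    for q in f.interior_sites:
        rho *= 1.0 - site_u[q.pos]
    return rho


def simulate_reads(
    truth: SimTruth,
    l_min: int,
    l_max: int,
    depth: float,
    seed: int,
    emit_alignments: bool = False,
    jackpot: bool = False,
    contaminant_fraction: float = 0.0,
) -> tuple[list[Fragment], list[AlignmentRecord]]:
    """Sample per-fragment Poisson read counts for the size-passing
    candidate fragments, optionally emitting single-end alignments (one
    forward read at the left cut and one reverse read at the right end per
    sequenced fragment copy — a paired-end run collapsed to single-end).

    ``jackpot`` multiplies one random nonzero count by 100, emulating a PCR
    amplification artifact. ``contaminant_fraction`` adds that expected
    fraction of extra reads with non-HpaII prefixes at random positions
    (material that survived the gel without a restriction end).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not truth.site_u:
        raise ValueError("run simulate_methylome first")
    rng = np.random.default_rng(seed)
    frags = enumerate_fragments(truth.hpaii_sites, l_min, l_max)
    for f in frags:
        rho = fragment_production_rate(f, truth.site_u)
        truth.fragment_rho[(f.start, f.end)] = rho
        f.read_count = int(rng.poisson(depth * rho))
    if jackpot:
        nonzero = [f for f in frags if f.read_count > 0]
        if nonzero:
            victim = nonzero[int(rng.integers(len(nonzero)))]
            victim.read_count *= 100
    truth.fragments = frags
    alignments: list[AlignmentRecord] = []
    if emit_alignments:
        read_len = 32
        for f in frags:
            for _ in range(f.read_count):
                alignments.append(
                    AlignmentRecord(
                        truth.chrom,
                        f.start,
                        min(f.start + read_len, len(truth.sequence)),
                        "+",
                        "CGG",
                    )
                )
                # antisense 5' end one base past the sense-strand cut
                alignments.append(
                    AlignmentRecord(
                        truth.chrom,
                        max(f.end + 2 - read_len, 0),
                        f.end + 2,
                        "-",
                        "CGG",
                    )
                )
        if contaminant_fraction > 0 and alignments:
            n_cont = int(rng.poisson(contaminant_fraction * len(alignments)))
            prefixes = ["ACG", "TGG", "AAA", "GCG"]
            for _ in range(n_cont):
                start = int(rng.integers(0, max(1, len(truth.sequence) - read_len)))
                alignments.append(
                    AlignmentRecord(
                        truth.chrom,
                        start,
                        start + read_len,
                        "+",
                        prefixes[int(rng.integers(len(prefixes)))],
                    )
                )
    return frags, alignments


def simulate_experiment(
    length: int,
    params: ModelParameters,
    depth: float,
    seed: int,
    sim: SimParams = SimParams(),
    chrom: str = "sim1",
) -> SimTruth:
    """Genome + methylome + reads in one call, with derived sub-seeds."""
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    truth = simulate_genome(length, params, seeds[0], sim, chrom)
    simulate_methylome(truth, params, seeds[1], sim)
    simulate_reads(truth, params.l_min, params.l_max, depth, seeds[2])
    return truth


def calibration_summary(truth: SimTruth, params: ModelParameters) -> dict:
    """Estimates of the generative parameters from one simulated genome,
    with standard errors.

    Island fraction: mean island indicator, SE from the two-state chain
    (lag-1 autocorrelation 1-a-b). In-island CG frequency: planted CG
    decisions per eligible island position (binomial SE).
    """
    length = len(truth.sequence)
    island_bp = sum(e - s for s, e in truth.islands)
    frac = island_bp / length
    a, b = params.a_enter, params.b_leave
    pi = a / (a + b)
    rho = 1.0 - a - b
    se_frac = math.sqrt(pi * (1 - pi) * (1 + rho) / ((1 - rho) * length))
    n_cg_in = sum(1 for v in truth.site_island.values() if v)
    p_in = n_cg_in / truth.n_eligible_island if truth.n_eligible_island else 0.0
    se_p_in = (
        math.sqrt(p_in * (1 - p_in) / truth.n_eligible_island)
        if truth.n_eligible_island
        else float("nan")
    )
    return {
        "island_fraction": frac,
        "island_fraction_expected": pi,
        "island_fraction_se": se_frac,
        "cg_freq_island": p_in,
        "cg_freq_island_expected": params.p_cg_in,
        "cg_freq_island_se": se_p_in,
    }
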