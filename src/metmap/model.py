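"""The directed graphical model and its exact inference.

Hidden variables form a genomic chain over every CG dinucleotide of a
region. Each HpaII site contributes six joint states — methylation
(U, P, M) crossed with island status (I, O) — and each plain CG
contributes the two island states. Distance-dependent transition factors
couple consecutive CG positions through a per-base two-state island chain
with CG emissions; a site's methylation value depends on its own island
status. Each candidate size-passing fragment is an observed variable whose
ten states are the capped read counts; its factor ties the methylation
values of the fragment's two bounding sites and up to three randomly
chosen interior sites through the per-allele production rate (both ends
cleaved, no interior cleaved).

Internally every HpaII site is represented by *two* chained variables — a
2-state island variable followed by a 3-state methylation variable tied to
it by the methylation CPD — so that fragment factors touch only 3-state
axes. This factored representation is exactly equivalent to the 6-state
formulation (posteriors are reported jointly over the pair) but keeps the
cliques of the elimination order exponentially smaller in CG-dense
regions, where many overlapping fragments are pending at once.

Posteriors are exact: two-pass message passing over the clique chain
induced by eliminating variables in genomic order, with messages
renormalized at every step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome import CGSite, Fragment
from .params import ModelParameters

__all__ = [
    "island_transition",
    "initial_island_distribution",
    "methylation_cpd",
    "fragment_class",
    "fragment_cpd",
    "build_model",
    "infer_posteriors",
    "metmap_score",
    "ModelGraph",
    "PosteriorTable",
    "SitePosterior",
]


def _scaled_matrix_power(m: np.ndarray, n: int) -> np.ndarray:
    """m**n up to a positive scalar, by squaring with rescaling.

    Entries of the per-base chain matrix decay geometrically with distance;
    rescaling by the max entry at each squaring keeps the computation in
    range for arbitrary distances. Only row ratios matter downstream.
    """
    result = np.eye(m.shape[0])
    base = m.copy()
    while n:
        if n & 1:
            result = result @ base
            result /= result.max()
        base = base @ base
        base /= base.max()
        n >>= 1
    return result


def island_transition(d: int, params: ModelParameters) -> np.ndarray:
    """2x2 row-stochastic island transition over a gap of ``d`` bp.

    Conditions the per-base island chain on a CG being observed at the far
    end and no CG starting over the intervening ``d-1`` bases:
    ``N(d) ∝ (T·D)^(d-1) · T · E`` with T the per-base island transitions,
    D = diag(1-p_cg_in, 1-p_cg_out) and E = diag(p_cg_in, p_cg_out),
    rows then normalized. Rows/columns are ordered (I, O).
    """
    if d < 1:
        raise ValueError("distance between CG starts must be >= 1")
    a, b = params.a_enter, params.b_leave
    t = np.array([[1.0 - b, b], [a, 1.0 - a]])
    d_no = np.diag([1.0 - params.p_cg_in, 1.0 - params.p_cg_out])
    e_cg = np.diag([params.p_cg_in, params.p_cg_out])
    m = _scaled_matrix_power(t @ d_no, d - 1) @ t @ e_cg
    return m / m.sum(axis=1, keepdims=True)


def initial_island_distribution(params: ModelParameters) -> np.ndarray:
    """Island distribution of a region's first CG variable: the initial
    per-position island probability reweighted by the CG emission."""
    w = np.array(
        [
            params.pi_island * params.p_cg_in,
            (1.0 - params.pi_island) * params.p_cg_out,
        ]
    )
    return w / w.sum()


def methylation_cpd(island_state: int, params: ModelParameters) -> np.ndarray:
    """(U, P, M) distribution of a HpaII site given island status
    (0 = inside, 1 = outside)."""
    return params.meth_cpd(island_state)


def fragment_class(
    end_states: tuple[int, int],
    interior_states,
    params: ModelParameters,
) -> int:
    """Equivalence class (0..4) of a methylation configuration.

    Configurations with equal per-allele production-rate bins are
    observationally equivalent; rate 0 is class 0 and classes 1..4 bin
    (0, .25], (.25, .5], (.5, .75], (.75, 1].
    """
    rho = params.production_rate(end_states, interior_states)
    if rho <= 0.0:
        return 0
    return 1 + min(3, int(np.floor(4.0 * rho - 1e-12)))


def fragment_cpd(cls: int, params: ModelParameters) -> np.ndarray:
    """Distribution over the ten observed states for an equivalence class."""
    if not 0 <= cls <= 4:
        raise ValueError(f"class must be 0..4, got {cls}")
    return np.asarray(params.fragment_table)[cls]


# --- graph construction ---------------------------------------------------


@dataclass
class _Factor:
    vars: tuple[int, ...]  # ascending variable indices
    table: np.ndarray  # shape = domains of vars, in that order
    fragment: Fragment | None = None  # set for fragment factors


@dataclass
class ModelGraph:
    """Factored chain representation of one region.

    ``site_vars`` maps each CG site (chain order) to its variable indices:
    ``(island_var,)`` for plain CGs, ``(island_var, meth_var)`` for HpaII
    sites. ``domains[v]`` is 2 for island variables, 3 for methylation
    variables.
    """

    sites: list[CGSite]
    site_vars: list[tuple[int, ...]]
    domains: list[int]
    factors: list[_Factor]
    params: ModelParameters
    seed: int | None = None

    @property
    def n_hidden(self) -> int:
        return len(self.domains)


def _fragment_factor_table(
    n_members: int, f_state: int, params: ModelParameters
) -> np.ndarray:
    """Factor over member methylation variables (first two axes = ends)."""
    shape = (3,) * n_members
    table = np.empty(shape)
    for idx in np.ndindex(*shape):
        cls = fragment_class((idx[0], idx[1]), idx[2:], params)
        table[idx] = params.fragment_table[cls, f_state]
    return table


def build_model(
    region_sites: list[CGSite],
    fragments: list[Fragment],
    params: ModelParameters,
    seed: int | None = 0,
) -> ModelGraph:
    """Assemble the factor graph for one region.

    ``region_sites`` are all CG dinucleotides of the region in position
    order (HpaII or not); ``fragments`` must carry an observed ``f_state``.
    Interior sites beyond ``params.interior_cap`` are subsampled uniformly
    with the given seed, so graphs are reproducible run to run.
    """
    sites = sorted(region_sites, key=lambda s: s.pos)
    domains: list[int] = []
    site_vars: list[tuple[int, ...]] = []
    meth_var: dict[tuple[str, int], int] = {}
    factors: list[_Factor] = []

    prev_island_var: int | None = None
    prev_pos: int | None = None
    for s in sites:
        iv = len(domains)
        domains.append(2)
        if prev_island_var is None:
            factors.append(_Factor((iv,), initial_island_distribution(params)))
        else:
            trans = island_transition(s.pos - prev_pos, params)
            factors.append(_Factor((prev_island_var, iv), trans.copy()))
        if s.is_hpaii:
            mv = len(domains)
            domains.append(3)
            emission = np.vstack([params.meth_cpd(0), params.meth_cpd(1)])
            factors.append(_Factor((iv, mv), emission))
            meth_var[(s.chrom, s.pos)] = mv
            site_vars.append((iv, mv))
        else:
            site_vars.append((iv,))
        prev_island_var, prev_pos = iv, s.pos

    rng = np.random.default_rng(seed)
    for f in sorted(fragments, key=lambda f: (f.chrom, f.start, f.end)):
        if f.f_state is None:
            raise ValueError("fragments must carry an observed f_state")
        interior = list(f.interior_sites)
        if len(interior) > params.interior_cap:
            chosen = rng.choice(len(interior), size=params.interior_cap, replace=False)
            interior = [interior[int(c)] for c in sorted(chosen)]
        members = [f.left, f.right] + interior
        try:
            var_ids = [meth_var[(s.chrom, s.pos)] for s in members]
        except KeyError as exc:
            raise ValueError(
                f"fragment {f.chrom}:{f.start}-{f.end} references a site outside "
                "the region"
            ) from exc
        table = _fragment_factor_table(len(members), f.f_state, params)
        order = np.argsort(var_ids)
        factors.append(
            _Factor(
                tuple(var_ids[int(o)] for o in order),
                np.transpose(table, axes=tuple(int(o) for o in order)),
                fragment=f,
            )
        )
    return ModelGraph(sites, site_vars, domains, factors, params, seed)


# --- exact inference ------------------------------------------------------


def _multiply_into(
    acc: np.ndarray,
    acc_vars: tuple[int, ...],
    table: np.ndarray,
    tvars: tuple[int, ...],
) -> np.ndarray:
    """Multiply ``table`` (over tvars, a subset of acc_vars) into ``acc``."""
    pos = {v: k for k, v in enumerate(acc_vars)}
    src_axes = sorted(range(len(tvars)), key=lambda k: pos[tvars[k]])
    t = np.transpose(table, axes=src_axes)
    shape = [1] * len(acc_vars)
    for axis, v in zip(t.shape, sorted(tvars, key=lambda v: pos[v])):
        shape[pos[v]] = axis
    return acc * t.reshape(shape)


def _marginalize(
    acc: np.ndarray, acc_vars: tuple[int, ...], keep: tuple[int, ...]
) -> np.ndarray:
    axes = tuple(k for k, v in enumerate(acc_vars) if v not in set(keep))
    return acc.sum(axis=axes) if axes else acc


@dataclass
class _Plan:
    buckets: list[list[_Factor]]
    frontiers: list[tuple[int, ...]]  # frontier after each step
    cliques: list[tuple[int, ...]]
    max_clique_states: int


def _elimination_plan(domains: list[int], factors: list[_Factor]) -> _Plan:
    n = len(domains)
    need_until = list(range(n))
    for f in factors:
        last = f.vars[-1]
        for v in f.vars:
            need_until[v] = max(need_until[v], last)
    buckets: list[list[_Factor]] = [[] for _ in range(n)]
    for f in factors:
        buckets[f.vars[-1]].append(f)
    frontiers: list[tuple[int, ...]] = []
    cliques: list[tuple[int, ...]] = []
    frontier: list[int] = []
    max_states = 1
    for t in range(n):
        clique = tuple(sorted(set(frontier) | {t}))
        cliques.append(clique)
        states = int(np.prod([domains[v] for v in clique], dtype=np.int64))
        max_states = max(max_states, states)
        frontier = [v for v in clique if need_until[v] > t]
        frontiers.append(tuple(frontier))
    return _Plan(buckets, frontiers, cliques, max_states)


def infer_posteriors(graph: ModelGraph, clique_cap: int = 2**20) -> "PosteriorTable":
    """Exact marginal posteriors for every CG site.

    Variables are eliminated in chain order; the frontier after step t
    holds every variable still referenced by a factor anchored further
    right, so each clique is the previous frontier plus one variable.
    Forward and backward passes over this clique chain give exact
    marginals; for HpaII sites the joint (island, methylation) pair
    marginal is read off the clique that introduces the methylation
    variable.

    If a clique would exceed ``clique_cap`` joint states, the interior
    links of the widest offending fragments are dropped (their factors
    rebuilt end-only) with a warning; inference remains exact for the
    reduced model. If the cap still cannot be met, an error is raised
    rather than approximating silently.
    """
    factors = list(graph.factors)
    while True:
        plan = _elimination_plan(graph.domains, factors)
        if plan.max_clique_states <= clique_cap:
            break
        hot_vars: set[int] = set()
        for t, clique in enumerate(plan.cliques):
            states = int(
                np.prod([graph.domains[v] for v in clique], dtype=np.int64)
            )
            if states > clique_cap:
                hot_vars.update(clique)
        reducible = sorted(
            (
                f
                for f in factors
                if f.fragment is not None
                and len(f.vars) > 2
                and hot_vars.intersection(f.vars)
            ),
            key=lambda f: -f.fragment.length,
        )
        if not reducible:
            raise RuntimeError(
                f"clique of {plan.max_clique_states} states exceeds cap "
                f"{clique_cap} and no interior links remain to drop"
            )
        # drop the widest offenders in batches to limit replanning
        batch = reducible[: max(1, len(reducible) // 4)]
        warnings.warn(
            f"dropping interior links of {len(batch)} wide fragment factor(s) "
            "to respect the clique-size cap",
            stacklevel=2,
        )
        dropped = set(map(id, batch))
        factors = [f for f in factors if id(f) not in dropped]
        for old in batch:
            ends = (old.vars[0], old.vars[-1])  # extremes are the fragment ends
            table = _fragment_factor_table(2, old.fragment.f_state, graph.params)
            factors.append(_Factor(ends, table, fragment=old.fragment))

    return _run_clique_chain(graph, factors, plan)


def _run_clique_chain(
    graph: ModelGraph, factors: list[_Factor], plan: _Plan
) -> "PosteriorTable":
    n = len(graph.domains)
    domains = graph.domains

    def clique_potential(t: int) -> tuple[np.ndarray, tuple[int, ...]]:
        cvars = plan.cliques[t]
        acc = np.ones(tuple(domains[v] for v in cvars))
        for f in plan.buckets[t]:
            acc = _multiply_into(acc, cvars, f.table, f.vars)
        return acc, cvars

    fwd: list[np.ndarray | None] = [None] * n
    for t in range(n):
        acc, cvars = clique_potential(t)
        if t > 0 and plan.frontiers[t - 1]:
            acc = _multiply_into(acc, cvars, fwd[t - 1], plan.frontiers[t - 1])
        msg = _marginalize(acc, cvars, plan.frontiers[t])
        z = msg.sum()
        if z <= 0:
            raise ZeroDivisionError(
                "all joint configurations have zero probability "
                "(inconsistent evidence)"
            )
        fwd[t] = msg / z

    # variables whose joint pair marginal is wanted: meth var -> island var
    pair_of: dict[int, int] = {
        sv[1]: sv[0] for sv in graph.site_vars if len(sv) == 2
    }
    marginals: dict[int, np.ndarray] = {}
    pair_marginals: dict[int, np.ndarray] = {}

    bwd: list[np.ndarray | None] = [None] * n  # message into clique t over frontier t
    for t in range(n - 1, -1, -1):
        acc, cvars = clique_potential(t)
        if t > 0 and plan.frontiers[t - 1]:
            belief = _multiply_into(acc, cvars, fwd[t - 1], plan.frontiers[t - 1])
        else:
            belief = acc
        if bwd[t] is not None and plan.frontiers[t]:
            belief = _multiply_into(belief, cvars, bwd[t], plan.frontiers[t])
        if t in pair_of:
            pm = _marginalize(belief, cvars, (pair_of[t], t))
            pair_marginals[t] = pm / pm.sum()
        marg = _marginalize(belief, cvars, (t,))
        marginals[t] = marg / marg.sum()
        if t > 0:
            if bwd[t] is not None and plan.frontiers[t]:
                acc = _multiply_into(acc, cvars, bwd[t], plan.frontiers[t])
            msg = _marginalize(acc, cvars, plan.frontiers[t - 1])
            z = msg.sum()
            bwd[t - 1] = msg / z if z > 0 else msg

    records = []
    for site, sv in zip(graph.sites, graph.site_vars):
        if len(sv) == 1:
            records.append(SitePosterior(site, p_island=float(marginals[sv[0]][0])))
        else:
            pm = pair_marginals[sv[1]]  # axes (island, meth)
            records.append(
                SitePosterior(
                    site,
                    p_island=float(pm[0].sum()),
                    p_u=float(pm[:, 0].sum()),
                    p_p=float(pm[:, 1].sum()),
                    p_m=float(pm[:, 2].sum()),
                    joint=pm.copy(),
                )
            )
    return PosteriorTable(records, graph.params, graph.seed)


# --- posterior bookkeeping ------------------------------------------------


def metmap_score(posterior) -> float:
    """Inferred unmethylated-allele fraction from a methylation posterior.

    Accepts a (U, P, M) triple or a 2x3 (island x methylation) joint;
    partially methylated alleles contribute half their mass.
    """
    p = np.asarray(posterior, dtype=float)
    if p.shape == (2, 3):
        p = p.sum(axis=0)
    if p.shape != (3,):
        raise ValueError("posterior must be a (U,P,M) triple or 2x3 joint")
    return float(p[0] + 0.5 * p[1])


@dataclass(frozen=True)
class SitePosterior:
    site: CGSite
    p_island: float
    p_u: float | None = None  # None for non-HpaII CG variables
    p_p: float | None = None
    p_m: float | None = None
    joint: np.ndarray | None = None  # 2x3 (island, methylation), HpaII only

    @property
    def score(self) -> float | None:
        if self.p_u is None:
            return None
        return self.p_u + 0.5 * self.p_p


@dataclass
class PosteriorTable:
    records: list[SitePosterior]
    params: ModelParameters
    seed: int | None = None

    def hpaii(self) -> list[SitePosterior]:
        return [r for r in self.records if r.site.is_hpaii]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": [r.site.chrom for r in self.records],
                "start": [r.site.pos for r in self.records],
                "end": [r.site.pos + 2 for r in self.records],
                "is_hpaii": [r.site.is_hpaii for r in self.records],
                "p_island": [r.p_island for r in self.records],
                "p_U": [r.p_u for r in self.records],
                "p_P": [r.p_p for r in self.records],
                "p_M": [r.p_m for r in self.records],
                "metmap_score": [r.score for r in self.records],
            }
        )
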