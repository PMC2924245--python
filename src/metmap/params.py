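"""Fixed parameters of the MetMap graphical model.

The model couples three families of conditional distributions:

* a two-state per-base chain over "unmethylated island" (I) vs "outside" (O),
  with per-base entry/exit probabilities and state-dependent CG emission
  probabilities, which together yield distance-dependent transitions between
  consecutive CG dinucleotides;
* per-site methylation distributions over (U, P, M) — fully unmethylated,
  partially (heterogeneously) methylated, fully methylated — conditioned on
  island status;
* a 5x10 lookup table mapping equivalence classes of fragment-end/interior
  methylation configurations to the ten observed (capped) read-count states.

All values are probabilities; distances are in base pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModelParameters", "default_fragment_table", "DEFAULT_PARAMS"]

#: Mean per-allele fragment-production rate assigned to each of the five
#: equivalence classes when building the default observation table.
_CLASS_RATES = (0.0, 0.125, 0.375, 0.625, 0.875)


def default_fragment_table() -> np.ndarray:
    """Default 5x10 fragment observation table.

    Row ``k`` is the Binomial(9, rho_k) probability mass over the ten
    observed states 0..9, with ``rho_k`` the midpoint production rate of
    equivalence class ``k`` (0 for the impossible class). Any row-stochastic
    5x10 table (e.g. one fit by linear programming) may be substituted via
    :class:`ModelParameters`.
    """
    from scipy.stats import binom

    ks = np.arange(10)
    table = np.vstack([binom.pmf(ks, 9, rho) for rho in _CLASS_RATES])
    return table / table.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class ModelParameters:
    """All fixed probabilities of the model, with their published defaults."""

    #: per-base probability of entering an unmethylated island (O -> I)
    a_enter: float = 0.00031434
    #: per-base probability of leaving an unmethylated island (I -> O)
    b_leave: float = 0.0257
    #: probability of a CG starting at a base inside an island
    p_cg_in: float = 0.10178
    #: probability of a CG starting at a base outside an island
    p_cg_out: float = 0.01298
    #: initial probability that a genomic position is inside an island
    pi_island: float = 0.013
    #: P(U), P(P), P(M) given island status I
    meth_given_island: tuple[float, float, float] = (0.7231, 0.05, 0.2269)
    #: P(U), P(P), P(M) given island status O
    meth_given_outside: tuple[float, float, float] = (0.1413, 0.05, 0.8087)
    #: per-allele probability that HpaII cleaves a site in state U, P, M
    cut_prob: tuple[float, float, float] = (1.0, 0.5, 0.0)
    #: maximum number of interior site variables retained per fragment factor
    interior_cap: int = 3
    #: size-selection window (bp)
    l_min: int = 50
    l_max: int = 300
    #: 5x10 row-stochastic observation table (class -> capped count state)
    fragment_table: np.ndarray = field(default_factory=default_fragment_table)

    def __post_init__(self) -> None:
        for name in ("a_enter", "b_leave", "p_cg_in", "p_cg_out", "pi_island"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} not in (0,1)")
        for name in ("meth_given_island", "meth_given_outside"):
            dist = getattr(self, name)
            if abs(sum(dist) - 1.0) > 1e-12 or min(dist) < 0:
                raise ValueError(f"{name} is not a distribution: {dist}")
        table = np.asarray(self.fragment_table, dtype=float)
        if table.shape != (5, 10):
            raise ValueError(f"fragment_table must be 5x10, got {table.shape}")
        if np.any(table < 0) or np.max(np.abs(table.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("fragment_table rows must be non-negative and sum to 1")
        if not 0 < self.l_min <= self.l_max:
            raise ValueError(f"invalid size window [{self.l_min}, {self.l_max}]")
        if self.interior_cap < 0:
            raise ValueError("interior_cap must be non-negative")

    @property
    def unmeth_prior_outside_score(self) -> float:
        """Prior unmethylated-allele fraction (MetMap score) outside islands.

        Equals P(U|O) + 0.5*P(P|O); with the default parameters this is the
        published 0.1663 threshold used for unmethylated-region annotation.
        """
        u, p, _ = self.meth_given_outside
        return u + 0.5 * p

    @property
    def stationary_island_fraction(self) -> float:
        """Long-run fraction of bases inside islands, a/(a+b)."""
        return self.a_enter / (self.a_enter + self.b_leave)

    def meth_cpd(self, island_state: int) -> np.ndarray:
        """(U,P,M) distribution given island axis index (0 = I, 1 = O)."""
        dist = self.meth_given_island if island_state == 0 else self.meth_given_outside
        return np.asarray(dist, dtype=float)

    def production_rate(self, end_m: tuple[int, int], interior_m) -> float:
        """Per-allele fragment production rate for a methylation configuration.

        A fragment copy is produced when both bounding sites are cleaved and
        no interior site is; states index (U, P, M) = (0, 1, 2).
        """
        c = self.cut_prob
        rho = c[end_m[0]] * c[end_m[1]]
        for m in interior_m:
            rho *= 1.0 - c[m]
        return rho


#: Module-level instance with the published defaults.
DEFAULT_PARAMS = ModelParameters()


def load_fragment_table(path) -> np.ndarray:
    """Load a replacement 5x10 observation table from a whitespace TSV."""
    table = np.loadtxt(path, dtype=float)
    if table.shape != (5, 10):
        raise ValueError(f"expected a 5x10 table in {path}, got {table.shape}")
    rows = table.sum(axis=1)
    if np.any(table < 0) or np.max(np.abs(rows - 1.0)) > 1e-9:
        raise ValueError(f"table in {path} is not row-stochastic")
    return table


def _require_unit_interval(x: float, name: str) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name}={x} outside [0,1]")


def poisson_cap(mean_count: float) -> float:
    """Capping value two Poisson standard deviations above a mean count."""
    if mean_count < 0:
        raise ValueError("mean_count must be non-negative")
    return mean_count + 2.0 * math.sqrt(mean_count)
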