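"""Validation utilities: bisulfite-style five-point scoring, the
tolerance-window ("adjusted") comparison, and correlation reporting."""

from __future__ import annotations

import math

__all__ = [
    "BISULFITE_GRID",
    "FEASIBLE_RANGES",
    "bisulfite_bin",
    "adjusted_bisulfite",
    "pearson",
    "raw_count_score",
]

#: The five-point unmethylation scale read off Sanger C/T peak heights.
BISULFITE_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)

#: Tolerance window for each bisulfite score, reflecting that mid-scale
#: assignments are the least precise. Treated as closed intervals for
#: clamping (a prediction of 0 against a 0.25 score adjusts to 0.15).
FEASIBLE_RANGES = {
    0.0: (0.0, 0.15),
    0.25: (0.15, 0.35),
    0.5: (0.35, 0.65),
    0.75: (0.65, 0.85),
    1.0: (0.85, 1.0),
}


def bisulfite_bin(u: float) -> float:
    """Nearest five-point bisulfite score for a continuous unmethylated
    fraction; ties round up (0.375 -> 0.5)."""
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"u={u} outside [0,1]")
    best = None
    for g in BISULFITE_GRID:
        d = abs(u - g)
        if best is None or d < best[0] - 1e-15 or (abs(d - best[0]) <= 1e-15 and g > best[1]):
            best = (d, g)
    return best[1]


def adjusted_bisulfite(bis_score: float, prediction: float) -> float:
    """Clamp a prediction into the feasible range of its bisulfite score.

    The adjusted value is the point of the score's tolerance window closest
    to the prediction, so a prediction consistent with the window is
    returned unchanged.
    """
    if bis_score not in FEASIBLE_RANGES:
        raise ValueError(f"bisulfite score {bis_score} not on the five-point scale")
    if not 0.0 <= prediction <= 1.0:
        raise ValueError(f"prediction={prediction} outside [0,1]")
    lo, hi = FEASIBLE_RANGES[bis_score]
    return min(max(prediction, lo), hi)


def pearson(x, y) -> float:
    """Product-moment correlation, computed from first principles."""
    xs = [float(v) for v in x]
    ys = [float(v) for v in y]
    if len(xs) != len(ys):
        raise ValueError("x and y must have equal length")
    n = len(xs)
    if n < 2:
        raise ValueError("need at least two points")
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((v - mx) ** 2 for v in xs)
    syy = sum((v - my) ** 2 for v in ys)
    if sxx <= 0 or syy <= 0:
        raise ValueError("correlation undefined for a constant vector")
    sxy = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
    return sxy / math.sqrt(sxx * syy)


def raw_count_score(r: float, k_max: float) -> float:
    """Normalized per-site read count in [0, 1] using the capping value —
    the naive unmethylation estimate the model is compared against."""
    if k_max <= 0:
        raise ValueError("k_max must be positive")
    return min(r / k_max, 1.0)
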