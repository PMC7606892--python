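"""F0-referenced binomial testing of cross-generational IRS transitions.

For each locus the parental (F0) counts define a two-sided confidence
interval on the F0 retention proportion (default: 75% Clopper-Pearson).
The interval bounds serve as reference null proportions for one-sided
exact binomial tests on the filial (F1) counts:

* upward:   P(X >= k1 | n1, p_upper)  — retention increased,
* downward: P(X <= k1 | n1, p_lower)  — retention decreased.

A locus is called "up" when its F1 IRS lies strictly above the upper
reference bound and the upward test survives multiple-testing
adjustment (Benjamini-Hochberg by default, applied per direction over
all tested loci); symmetrically for "down".  An F1 IRS exactly on a
bound is direction "none".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .io_formats import ValidationError
from .irs import IRSRecord

__all__ = [
    "ReferenceBounds",
    "TransitionCall",
    "reference_bounds",
    "test_transition",
    "call_transitions",
    "summarize_transitions",
]


@dataclass(frozen=True)
class ReferenceBounds:
    ies_id: str
    p_lower: float
    p_upper: float
    level: float
    k0: int
    n0: int


@dataclass
class TransitionCall:
    ies_id: str
    direction: Literal["up", "down", "none"]
    p_value_up: float
    p_value_down: float
    p_adjusted: float
    significant: bool
    f0_irs: float
    f1_irs: float


def reference_bounds(
    k0: int,
    n0: int,
    level: float = 0.75,
    ies_id: str = "",
    method: str = "clopper-pearson",
) -> ReferenceBounds:
    """Two-sided CI on the F0 retention proportion, used as reference nulls.

    ``clopper-pearson`` gives the exact (conservative) interval, with the
    conventional closed forms at k0 = 0 and k0 = n0; ``wilson`` is the
    score interval alternative.
    """
    if n0 < 1:
        raise ValidationError("n0 must be >= 1 (locus should be coverage-filtered)")
    if not 0 <= k0 <= n0:
        raise ValidationError(f"k0={k0} outside [0, n0={n0}]")
    if not 0 < level < 1:
        raise ValidationError(f"confidence level {level} outside (0, 1)")
    if method == "clopper-pearson":
        ci = stats.binomtest(k0, n0).proportion_ci(confidence_level=level, method="exact")
    elif method == "wilson":
        ci = stats.binomtest(k0, n0).proportion_ci(confidence_level=level, method="wilson")
    else:
        raise ValidationError(f"unknown CI method {method!r}")
    return ReferenceBounds(
        ies_id=ies_id, p_lower=float(ci.low), p_upper=float(ci.high), level=level, k0=k0, n0=n0
    )


def _tail_pvalues(k1: int, n1: int, bounds: ReferenceBounds) -> tuple[float, float]:
    p_up = float(stats.binom.sf(k1 - 1, n1, bounds.p_upper))
    p_down = float(stats.binom.cdf(k1, n1, bounds.p_lower))
    return p_up, p_down


def test_transition(k1: int, n1: int, bounds: ReferenceBounds, alpha: float = 0.05) -> TransitionCall:
    """Single-locus transition test without multiple-testing adjustment."""
    if n1 < 1:
        raise ValidationError("n1 must be >= 1")
    p_up, p_down = _tail_pvalues(k1, n1, bounds)
    f1_irs = k1 / n1
    if f1_irs > bounds.p_upper:
        direction, p_dir = "up", p_up
    elif f1_irs < bounds.p_lower:
        direction, p_dir = "down", p_down
    else:
        direction, p_dir = "none", min(p_up, p_down)
    return TransitionCall(
        ies_id=bounds.ies_id,
        direction=direction,
        p_value_up=p_up,
        p_value_down=p_down,
        p_adjusted=p_dir,
        significant=direction != "none" and p_dir <= alpha,
        f0_irs=bounds.k0 / bounds.n0,
        f1_irs=f1_irs,
    )


def call_transitions(
    f0_counts: Sequence,
    f1_counts: Sequence,
    level: float = 0.75,
    alpha: float = 0.05,
    adjust: str = "bh",
    ci_method: str = "clopper-pearson",
) -> list[TransitionCall]:
    """Call per-locus transitions between an F0 and an F1 count table.

    Both inputs are sequences of JunctionCounts (or anything exposing
    ``ies_id``, ``k_ies``, and either ``n_total`` or ``k_mac``); only loci
    present in both are tested.  ``adjust``: "bh" (Benjamini-Hochberg,
    per direction over all tested loci) or "none" (raw P-values).
    """
    if adjust not in ("bh", "none"):
        raise ValidationError(f"unknown adjustment {adjust!r}")

    def as_kn(c):
        n = c.n_total if hasattr(c, "n_total") else c.k_ies + c.k_mac
        return int(c.k_ies), int(n)

    f0 = {c.ies_id: as_kn(c) for c in f0_counts}
    f1 = {c.ies_id: as_kn(c) for c in f1_counts}
    shared = [i for i in f0 if i in f1 and f0[i][1] >= 1 and f1[i][1] >= 1]
    if not shared:
        raise ValidationError("no shared loci between F0 and F1 tables")

    k0 = np.array([f0[i][0] for i in shared])
    n0 = np.array([f0[i][1] for i in shared])
    k1 = np.array([f1[i][0] for i in shared])
    n1 = np.array([f1[i][1] for i in shared])

    alpha_ci = 1.0 - level
    if ci_method == "clopper-pearson":
        lower = np.where(k0 > 0, stats.beta.ppf(alpha_ci / 2, k0, n0 - k0 + 1), 0.0)
        upper = np.where(
            k0 < n0, stats.beta.ppf(1 - alpha_ci / 2, k0 + 1, np.maximum(n0 - k0, 1)), 1.0
        )
    else:
        bnds = [reference_bounds(int(a), int(b), level, method=ci_method) for a, b in zip(k0, n0)]
        lower = np.array([b.p_lower for b in bnds])
        upper = np.array([b.p_upper for b in bnds])

    p_ups = stats.binom.sf(k1 - 1, n1, upper)
    p_downs = stats.binom.cdf(k1, n1, lower)
    f1_irs = k1 / n1
    directions = np.where(f1_irs > upper, "up", np.where(f1_irs < lower, "down", "none"))

    calls = [
        TransitionCall(
            ies_id=ies_id,
            direction=str(directions[idx]),
            p_value_up=float(p_ups[idx]),
            p_value_down=float(p_downs[idx]),
            p_adjusted=np.nan,
            significant=False,
            f0_irs=float(k0[idx] / n0[idx]),
            f1_irs=float(f1_irs[idx]),
        )
        for idx, ies_id in enumerate(shared)
    ]

    if adjust == "bh":
        adj_up = stats.false_discovery_control(p_ups)
        adj_down = stats.false_discovery_control(p_downs)
    else:
        adj_up, adj_down = p_ups, p_downs

    for idx, call in enumerate(calls):
        if call.direction == "up":
            call.p_adjusted = float(adj_up[idx])
        elif call.direction == "down":
            call.p_adjusted = float(adj_down[idx])
        else:
            call.p_adjusted = float(min(adj_up[idx], adj_down[idx]))
        call.significant = call.direction != "none" and call.p_adjusted <= alpha
    return calls


def summarize_transitions(calls: Sequence[TransitionCall]) -> dict:
    """Counts of tested/called loci by direction."""
    sig = [c for c in calls if c.significant]
    return {
        "n_tested": len(calls),
        "n_significant": len(sig),
        "n_up": sum(1 for c in sig if c.direction == "up"),
        "n_down": sum(1 for c in sig if c.direction == "down"),
    }
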