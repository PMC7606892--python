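"""Stratification of IES loci and the contingency/correlation statistics
computed on the strata.

Strata are built from four independent labellings:

* expression class of the host gene — HEG (top quartile of the log2
  expression distribution), WEG (bottom quartile), mid, or unexpressed;
* IES size class — the frequent Paramecium size classes
  26-30, 44-45, 46-50, 54-60, 64-70, 74-80, 84-90, 94-100 nt
  (lengths between classes are "unbinned");
* small vs large, split at ``small_max_length`` (default 32, the end of
  the first size class; the boundary is a package choice, see docs);
* genomic location (exon / intergenic / other) and epigenetic-control
  class (DCL2/3-sensitive, DCL5-sensitive, none, unknown).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import ExpressionTable, IESLocus, ValidationError
from .irs import DEFAULT_IRS_THRESHOLD, IRSRecord

__all__ = [
    "SIZE_CLASSES",
    "DEFAULT_SMALL_MAX_LENGTH",
    "StratumLabel",
    "classify_expression",
    "assign_size_class",
    "label_strata",
    "two_proportion_test",
    "fisher_one_tail",
    "count_ratio_by_size_class",
    "median_irs_by_size_class",
    "kendall_tau",
    "wilcoxon_rank_sum",
    "epi_enrichment",
    "ptc_fold",
    "exclusive_overlap",
    "TerminalPWM",
]

#: the frequent IES size classes, inclusive bounds in nt
SIZE_CLASSES: tuple[tuple[int, int], ...] = (
    (26, 30),
    (44, 45),
    (46, 50),
    (54, 60),
    (64, 70),
    (74, 80),
    (84, 90),
    (94, 100),
)
DEFAULT_SMALL_MAX_LENGTH = 32


@dataclass(frozen=True)
class StratumLabel:
    ies_id: str
    expression_class: str  # HEG | WEG | mid | unexpressed
    size_class: str  # "26-30" ... or "unbinned"
    small_or_large: str  # small | large
    location_class: str
    epi_class: str


def classify_expression(expr_table: ExpressionTable) -> dict[str, str]:
    """HEG / WEG / mid labels from the log2 expression distribution.

    Quartile boundaries use linear-interpolation quantiles over genes
    with positive expression; genes exactly on a boundary go to "mid".
    Zero-expression genes are not labelled here (they are "unexpressed").
    """
    log2 = expr_table.positive_log2
    if len(log2) < 8:
        raise ValidationError(f"need >= 8 positively expressed genes, got {len(log2)}")
    vals = np.fromiter(log2.values(), dtype=float)
    if np.ptp(vals) == 0:
        raise ValidationError("all expression values identical; quartiles undefined")
    q25, q75 = np.quantile(vals, [0.25, 0.75])
    out = {}
    for gid, v in log2.items():
        if v > q75:
            out[gid] = "HEG"
        elif v < q25:
            out[gid] = "WEG"
        else:
            out[gid] = "mid"
    return out


def assign_size_class(length: int) -> str:
    """Inclusive-bound size class label, or "unbinned" between classes."""
    if length < 26:
        raise ValidationError(f"length {length} below the study-wide 26 nt minimum")
    for lo, hi in SIZE_CLASSES:
        if lo <= length <= hi:
            return f"{lo}-{hi}"
    return "unbinned"


def label_strata(
    loci: Iterable[IESLocus],
    expr_table: ExpressionTable | None = None,
    small_max_length: int = DEFAULT_SMALL_MAX_LENGTH,
) -> dict[str, StratumLabel]:
    """Attach every stratum label to each locus.

    HEG/WEG labels apply only to exon-mapping IESs whose host gene has an
    expression value; hosts with zero expression are "unexpressed".
    """
    expr_classes = classify_expression(expr_table) if expr_table is not None else {}
    labels = {}
    for locus in loci:
        expr = "unexpressed"
        gid = locus.host_gene_id
        if locus.location_class == "exon" and gid is not None and expr_table is not None:
            if gid in expr_classes:
                expr = expr_classes[gid]
            elif gid in expr_table:
                expr = "unexpressed"  # present but zero expression
        labels[locus.ies_id] = StratumLabel(
            ies_id=locus.ies_id,
            expression_class=expr,
            size_class=assign_size_class(locus.length),
            small_or_large="small" if locus.length <= small_max_length else "large",
            location_class=locus.location_class,
            epi_class=locus.epi_class,
        )
    return labels


# ---------------------------------------------------------------------------
# tests and correlations


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, alternative: str = "two-sided"
) -> float:
    """Equality-of-proportions test on a 2x2 table.

    Two-sided: chi-squared with Yates continuity correction.  One-sided
    ("greater": p1 > p2; "less"): the signed square root of the corrected
    chi-squared statistic referred to the normal tail.
    """
    if n1 < 1 or n2 < 1:
        raise ValidationError("group sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValidationError("counts outside [0, n]")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if table.sum(axis=0).min() == 0:  # a margin is empty: no information
        return 1.0
    chi2, p_two, _, _ = stats.chi2_contingency(table, correction=True)
    if alternative == "two-sided":
        return float(p_two)
    z = np.sqrt(chi2) * np.sign(k1 / n1 - k2 / n2)
    if alternative == "greater":
        return float(stats.norm.sf(z))
    if alternative == "less":
        return float(stats.norm.cdf(z))
    raise ValidationError(f"unknown alternative {alternative!r}")


def fisher_one_tail(a: int, b: int, c: int, d: int) -> float:
    """One-tailed Fisher exact test for enrichment of cell ``a``.

    The table is [[a, b], [c, d]] and the alternative is "greater":
    the odds of the first row favouring the first column exceed those of
    the second row.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("negative cell count")
    if a + b + c + d == 0:
        raise ValidationError("all-zero contingency table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall's tau-b with tie correction; normal-approximation P-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant vector: tau undefined")
    res = stats.kendalltau(x, y, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney U) P-value, normal approximation
    with continuity correction and tie handling."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("both samples must have >= 3 observations")
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# size-class procedures


def _retained_by_class(
    records: Sequence[IRSRecord],
    labels: Mapping[str, StratumLabel],
    location: str,
    irs_threshold: float,
) -> dict[str, list[float]]:
    """IRS values above threshold, grouped by size class, for one location."""
    out: dict[str, list[float]] = {}
    for r in records:
        if r.irs is None or not r.passed_filters:
            continue
        lab = labels.get(r.ies_id)
        if lab is None or lab.location_class != location:
            continue
        if lab.size_class == "unbinned":
            continue
        if r.irs > irs_threshold:
            out.setdefault(lab.size_class, []).append(r.irs)
    return out


def _class_is_small(size_class: str, small_max_length: int) -> bool:
    hi = int(size_class.split("-")[1])
    return hi <= small_max_length


def count_ratio_by_size_class(
    f0_records: Sequence[IRSRecord],
    f1_records: Sequence[IRSRecord],
    labels: Mapping[str, StratumLabel],
    location: str = "exon",
    irs_threshold: float = DEFAULT_IRS_THRESHOLD,
    min_per_class: int = 3,
    small_max_length: int = DEFAULT_SMALL_MAX_LENGTH,
) -> dict:
    """F1/F0 ratios of incompletely excised IES counts per size class.

    Counts IESs with IRS above the threshold per frequent size class;
    classes with fewer than ``min_per_class`` such IESs in either
    condition are dropped.  Pooled small and large ratios sum counts over
    the surviving classes on each side of the small/large boundary.
    """
    f0 = {k: len(v) for k, v in _retained_by_class(f0_records, labels, location, irs_threshold).items()}
    f1 = {k: len(v) for k, v in _retained_by_class(f1_records, labels, location, irs_threshold).items()}
    per_class = {}
    kept = []
    for lo, hi in SIZE_CLASSES:
        cls = f"{lo}-{hi}"
        c0, c1 = f0.get(cls, 0), f1.get(cls, 0)
        if c0 < min_per_class or c1 < min_per_class:
            continue
        kept.append(cls)
        per_class[cls] = {"f0": c0, "f1": c1, "ratio": c1 / c0}

    def pooled(small: bool):
        classes = [c for c in kept if _class_is_small(c, small_max_length) == small]
        c0 = sum(per_class[c]["f0"] for c in classes)
        c1 = sum(per_class[c]["f1"] for c in classes)
        if c0 == 0:
            return {"f0": c0, "f1": c1, "ratio": None, "undefined": True}
        return {"f0": c0, "f1": c1, "ratio": c1 / c0}

    return {"per_class": per_class, "pooled_small": pooled(True), "pooled_large": pooled(False)}


def median_irs_by_size_class(
    records: Sequence[IRSRecord],
    labels: Mapping[str, StratumLabel],
    location: str = "exon",
    irs_threshold: float = DEFAULT_IRS_THRESHOLD,
    min_per_class: int = 3,
) -> dict[str, float]:
    """Median IRS of incompletely excised IESs per frequent size class."""
    by_class = _retained_by_class(records, labels, location, irs_threshold)
    return {
        cls: float(np.median(v))
        for cls, v in sorted(by_class.items(), key=lambda kv: int(kv[0].split("-")[0]))
        if len(v) >= min_per_class
    }


# ---------------------------------------------------------------------------
# enrichment and overlap


def epi_enrichment(
    retained_ids: Iterable[str],
    background_ids: Iterable[str],
    labels: Mapping[str, StratumLabel],
    epi_class: str,
) -> tuple[float, float, float]:
    """Epi-IES fraction among retained loci vs the underlying background.

    Returns (observed fraction, expected fraction, one-tailed Fisher P
    for enrichment of the epi class among retained loci).  The Fisher
    table contrasts retained loci with the rest of the background.
    """
    retained = set(retained_ids)
    background = set(background_ids)
    if not retained:
        raise ValidationError("empty retained set")
    if not retained <= background:
        raise ValidationError("retained set not contained in background")

    def is_epi(i: str) -> bool:
        return labels[i].epi_class == epi_class

    a = sum(1 for i in retained if is_epi(i))
    b = len(retained) - a
    rest = background - retained
    c = sum(1 for i in rest if is_epi(i))
    d = len(rest) - c
    observed = a / len(retained)
    expected = (a + c) / len(background)
    return observed, expected, fisher_one_tail(a, b, c, d)


def ptc_fold(ptc_inducing_count: int, ptc_free_count: int) -> dict:
    """How many-fold more likely retention is to introduce a PTC than not."""
    if ptc_inducing_count < 0 or ptc_free_count < 0:
        raise ValidationError("negative count")
    if ptc_free_count == 0:
        return {"fold": math_inf(), "rounded": math_inf(), "infinite": True}
    fold = ptc_inducing_count / ptc_free_count
    return {"fold": fold, "rounded": round(fold, 1), "infinite": False}


def math_inf() -> float:
    return float("inf")


def exclusive_overlap(
    named_sets: Mapping[str, Iterable[str]],
    excluded_sets: Mapping[str, Iterable[str]] | None = None,
    labels: Mapping[str, StratumLabel] | None = None,
) -> dict:
    """IESs present in every named set and absent from every excluded set.

    With stratum labels supplied, small/large and intragenic/intergenic
    tallies of the shared loci are attached.
    """
    named = {k: set(v) for k, v in named_sets.items()}
    excluded = {k: set(v) for k, v in (excluded_sets or {}).items()}
    if len(named) < 2:
        raise ValidationError("need at least two named sets")
    clash = set(named) & set(excluded)
    if clash:
        raise ValidationError(f"sets named in both roles: {sorted(clash)}")
    shared = set.intersection(*named.values())
    for s in excluded.values():
        shared -= s
    out: dict = {"shared_ids": sorted(shared), "n_shared": len(shared)}
    if labels is not None:
        out["n_small"] = sum(1 for i in shared if labels[i].small_or_large == "small")
        out["n_large"] = out["n_shared"] - out["n_small"]
        out["n_intragenic"] = sum(1 for i in shared if labels[i].location_class == "exon")
        out["n_intergenic"] = sum(
            1 for i in shared if labels[i].location_class == "intergenic"
        )
    return out


# ---------------------------------------------------------------------------
# cis-acting splicing-signal score


class TerminalPWM:
    """Position frequency profile over the terminal ``w`` nt of each IES end.

    The score of a sequence is the mean, over the 2*w terminal positions,
    of the observed-base frequency normalized by the per-position maximum
    frequency — 1.0 means the sequence matches the training consensus at
    every terminal position.
    """

    BASES = "ACGT"

    def __init__(self, left_freqs: np.ndarray, right_freqs: np.ndarray, w: int):
        self.left_freqs = left_freqs
        self.right_freqs = right_freqs
        self.w = w

    @classmethod
    def fit(cls, sequences: Iterable[str], w: int = 8) -> "TerminalPWM":
        seqs = list(sequences)
        if not seqs:
            raise ValidationError("empty training set")
        left = np.zeros((w, 4))
        right = np.zeros((w, 4))
        for seq in seqs:
            if len(seq) < 2 * w:
                raise ValidationError(f"IES shorter than 2w={2 * w} nt")
            for i, base in enumerate(seq[:w]):
                left[i, cls.BASES.index(base)] += 1
            for i, base in enumerate(seq[-w:]):
                right[i, cls.BASES.index(base)] += 1
        return cls(left / len(seqs), right / len(seqs), w)

    def score(self, ies_sequence: str) -> float:
        w = self.w
        if len(ies_sequence) < 2 * w:
            raise ValidationError(f"IES shorter than 2w={2 * w} nt")
        vals = []
        for freqs, window in (
            (self.left_freqs, ies_sequence[:w]),
            (self.right_freqs, ies_sequence[-w:]),
        ):
            for i, base in enumerate(window):
                col = freqs[i]
                m = col.max()
                vals.append(col[self.BASES.index(base)] / m if m > 0 else 0.0)
        return float(np.mean(vals))
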