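"""Ground-truth simulator for the IES retention analysis.

The generator emulates the structure the analysis assumes: an AT-rich
somatic (MAC) reference carrying single-CDS genes, TA-bounded IES
insertion points inside coding exons and intergenic spacers, a peaked
IES size distribution over the frequent Paramecium size classes,
log-scale gene expression, and per-condition true retention
probabilities with planted multiplicative effects.

Conditions mirror the cross-generational temperature design: a parental
line at 25°C (``F0_25C``), a control filial line at the same
temperature (``F1_25C``), two temperature-shifted filial lines
(``F1_18C``, ``F1_32C``) and a filial line whose parents received daily
heat shocks (``F1_25C_HS``).  In the shifted conditions, small
exon-mapping IESs (preferentially DCL2/3-sensitive and in highly
expressed genes) have their retention probability multiplied up, and
large exon-mapping IESs (preferentially DCL5-sensitive and in weakly
expressed genes) multiplied down.

Planted-effect ("responsive") loci draw their baseline retention from a
scale-free (reciprocal) distribution over the incompletely excised
regime — the loci the cross-generational effects act on — while the
non-responsive background is mostly fully excised (point mass at zero
plus a thin Beta tail).  Four effect roles are planted:

* ``up``            — small exon IESs: retention strongly increased in
  shifted conditions (preferentially DCL2/3-sensitive, HEG hosts);
* ``up_large``      — large exon IESs: retention mildly increased, so
  the count of incompletely excised large IESs rises less than the
  small-IES count;
* ``down``          — large exon IESs (preferentially DCL5-sensitive,
  WEG hosts): retention reduced, shrinking the magnitude of incomplete
  excision for large IESs;
* ``up_intergenic`` — intergenic IESs of any size: a uniform mild
  increase, so no size-dependent pattern appears outside genes.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from Bio.Seq import Seq

from .io_formats import (
    ExpressionTable,
    GeneModel,
    IESLocus,
    ValidationError,
    write_epi_classes,
    write_expression,
    write_fasta,
    write_gene_models,
    write_ies_annotation,
)
from .irs import JunctionCounts
from .strata import classify_expression

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate_truth", "simulate_counts", "simulate_reads"]

DEFAULT_CONDITIONS = ("F0_25C", "F1_25C", "F1_18C", "F1_32C", "F1_25C_HS")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort; defaults are the
    package's scaled-down emulation of the experimental design."""

    seed: int = 0
    n_genes: int = 600
    n_ies: int = 3000
    genes_per_scaffold: int = 25
    gene_codons_min: int = 250
    gene_codons_max: int = 450
    intergenic_min: int = 500
    intergenic_max: int = 1100
    at_content: float = 0.70
    exon_fraction: float = 0.70
    #: weights over the frequent size classes (eliminated-segment length, nt)
    size_class_weights: dict = field(
        default_factory=lambda: {
            "26-30": 0.30,
            "44-45": 0.08,
            "46-50": 0.10,
            "54-60": 0.12,
            "64-70": 0.10,
            "74-80": 0.08,
            "84-90": 0.06,
            "94-100": 0.06,
        }
    )
    #: residual weight spread uniformly over 26..100 (exercises "unbinned")
    size_background_weight: float = 0.10
    expr_log2_mean: float = 6.0
    expr_log2_sd: float = 2.0
    zero_expression_fraction: float = 0.05
    #: baseline retention: point mass at 0 + Beta tail (non-responsive loci)
    baseline_zero_fraction: float = 0.90
    baseline_beta: tuple = (0.5, 20.0)
    #: responsive loci are incompletely excised at baseline: retention
    #: drawn as 1/Uniform(1/max, 1/min) — density proportional to 1/p^2,
    #: so counts above a threshold scale roughly with the multiplier
    responsive_retention_min: float = 0.02
    responsive_retention_max: float = 0.30
    #: epi-class assignment rates
    dcl23_prob_small: float = 0.20
    dcl5_prob_large: float = 0.20
    #: responsiveness: base rate per role, boosted for epi-sensitive loci
    #: and by host expression class (HEG for up, WEG for down), capped
    up_small_base_prob: float = 0.20
    down_large_base_prob: float = 0.15
    up_large_prob: float = 0.25
    up_intergenic_prob: float = 0.15
    responsive_epi_boost: float = 4.0
    responsive_expr_boost: float = 2.0
    responsive_max_prob: float = 0.90
    #: per-condition multiplicative retention shifts by role
    up_multipliers: dict = field(
        default_factory=lambda: {"F1_18C": 4.0, "F1_32C": 5.0, "F1_25C_HS": 2.5}
    )
    up_large_multipliers: dict = field(
        default_factory=lambda: {"F1_18C": 2.0, "F1_32C": 2.5, "F1_25C_HS": 1.2}
    )
    down_multipliers: dict = field(
        default_factory=lambda: {"F1_18C": 0.25, "F1_32C": 0.20, "F1_25C_HS": 0.50}
    )
    intergenic_multipliers: dict = field(
        default_factory=lambda: {"F1_18C": 2.5, "F1_32C": 2.5, "F1_25C_HS": 1.5}
    )
    #: fraction of IESs with a stop codon planted in the retained frame;
    #: responsive small exon IESs carry planted stops more often, so the
    #: retained fraction shows a PTC excess over its stratum background
    ptc_seed_rate: float = 0.45
    ptc_seed_rate_responsive: float = 0.85
    small_max_length: int = 32
    min_ies_separation: int = 40
    #: beta-binomial overdispersion for read counts; None = pure binomial
    overdispersion: float | None = None
    conditions: tuple = DEFAULT_CONDITIONS

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValidationError("simulation config must set a seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("baseline_beta", "conditions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.n_ies < 16:
            raise ValidationError("n_ies too small to populate the strata")
        if not 0 <= self.exon_fraction <= 1:
            raise ValidationError("exon_fraction outside [0, 1]")
        if self.gene_codons_min < 40:
            raise ValidationError("genes must be >= 40 codons to host IESs")
        w = sum(self.size_class_weights.values()) + self.size_background_weight
        if w <= 0:
            raise ValidationError("size-class weights sum to zero")


@dataclass
class SyntheticTruth:
    """Full generative ground truth for one simulated cohort."""

    mac_genome: dict
    ies_loci: list
    genes: list
    expression: ExpressionTable
    conditions: tuple
    true_retention: dict  # (ies_id, condition) -> probability
    planted_effects: dict  # ies_id -> role record; plus "_summary"
    config: SimulationConfig
    clamp_warnings: int = 0

    def retention(self, ies_id: str, condition: str) -> float:
        return self.true_retention[(ies_id, condition)]

    def loci_by_role(self, role: str) -> list[str]:
        return [
            i for i, rec in self.planted_effects.items()
            if not i.startswith("_") and rec["role"] == role
        ]

    def write_fixtures(self, outdir) -> dict[str, Path]:
        """Write the FASTA/GFF3/TSV fixture set plus a truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mac_fasta": outdir / "mac_genome.fasta",
            "ies_gff3": outdir / "ies.gff3",
            "genes_gff3": outdir / "genes.gff3",
            "expression_tsv": outdir / "expression.tsv",
            "epi_tsv": outdir / "epi_classes.tsv",
            "truth_json": outdir / "truth.json",
        }
        write_fasta(self.mac_genome, paths["mac_fasta"])
        write_ies_annotation(self.ies_loci, paths["ies_gff3"])
        write_gene_models(self.genes, paths["genes_gff3"])
        write_expression(self.expression, paths["expression_tsv"])
        write_epi_classes(
            {l.ies_id: l.epi_class for l in self.ies_loci}, paths["epi_tsv"]
        )
        truth = {
            "conditions": list(self.conditions),
            "true_retention": {
                f"{i}|{c}": p for (i, c), p in sorted(self.true_retention.items())
            },
            "planted_effects": self.planted_effects,
            "clamp_warnings": self.clamp_warnings,
        }
        with open(paths["truth_json"], "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


# ---------------------------------------------------------------------------
# sequence construction helpers


def _base_probs(at: float) -> np.ndarray:
    return np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])  # A C G T


_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, n: int, at: float) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=_base_probs(at))])


def _codon_pool(at: float) -> tuple[list[str], np.ndarray]:
    """All codons except TGA (the ciliate stop), weighted by base content."""
    probs = dict(zip("ACGT", _base_probs(at)))
    codons, weights = [], []
    for c in itertools.product("ACGT", repeat=3):
        codon = "".join(c)
        if codon == "TGA":
            continue
        codons.append(codon)
        weights.append(probs[c[0]] * probs[c[1]] * probs[c[2]])
    w = np.array(weights)
    return codons, w / w.sum()


def _sample_lengths(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    """Eliminated-segment lengths from the peaked class mixture."""
    labels = list(config.size_class_weights)
    weights = np.array([config.size_class_weights[l] for l in labels], dtype=float)
    weights = np.append(weights, config.size_background_weight)
    weights /= weights.sum()
    choices = rng.choice(len(weights), size=n, p=weights)
    lengths = np.empty(n, dtype=int)
    for i, c in enumerate(choices):
        if c == len(labels):  # uniform background
            lengths[i] = rng.integers(26, 101)
        else:
            lo, hi = (int(x) for x in labels[c].split("-"))
            lengths[i] = rng.integers(lo, hi + 1)
    return lengths


def _spaced_ta_sites(seq: str, lo: int, hi: int, min_sep: int) -> list[int]:
    """TA positions in seq[lo:hi], greedily spaced >= min_sep apart."""
    sites, last = [], -(10**9)
    pos = seq.find("TA", lo)
    while 0 <= pos < hi:
        if pos - last >= min_sep:
            sites.append(pos)
            last = pos
        pos = seq.find("TA", pos + 1)
    return sites


def _plant_inframe_stop(
    rng: np.random.Generator, eliminated: str, q: int, mac_len: int, strand: str
) -> str:
    """Place a stop codon in ``eliminated`` so it is in frame once retained.

    ``q`` is the coding-strand nucleotide offset of the insertion in the
    + strand CDS; for - strand genes the eliminated segment appears
    reverse-complemented at coding offset ``mac_len - q``, so a TCA on
    the + strand reads TGA in the coding frame.
    """
    L = len(eliminated)
    if strand == "+":
        f0 = (3 - (q % 3)) % 3
        starts = [t for t in range(f0, L - 2, 3) if t >= 2]
        if not starts:
            return eliminated
        t = int(rng.choice(starts))
        return eliminated[:t] + "TGA" + eliminated[t + 3 :]
    qq = mac_len - q
    f0 = (3 - (qq % 3)) % 3
    # position t in the revcomp segment maps to eliminated index L - 3 - t
    starts = [L - 3 - t for t in range(f0, L - 2, 3) if 2 <= L - 3 - t <= L - 3]
    if not starts:
        return eliminated
    t = int(rng.choice(starts))
    return eliminated[:t] + "TCA" + eliminated[t + 3 :]


# ---------------------------------------------------------------------------
# main generator


def simulate_truth(config: SimulationConfig, seed: int | None = None) -> SyntheticTruth:
    """Generate a deterministic ground-truth cohort from the config."""
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    codons, codon_w = _codon_pool(config.at_content)
    codon_arr = np.array(codons)

    # --- genes and scaffolds -------------------------------------------------
    genes: list[GeneModel] = []
    scaffolds: dict[str, str] = {}
    gene_coding: dict[str, str] = {}
    n_scaffolds = -(-config.n_genes // config.genes_per_scaffold)
    gene_idx = 0
    for s_idx in range(n_scaffolds):
        name = f"scaffold_{s_idx + 1:03d}"
        parts: list[str] = []
        pos = 0
        spacer = _random_dna(
            rng, int(rng.integers(config.intergenic_min, config.intergenic_max + 1)), config.at_content
        )
        parts.append(spacer)
        pos += len(spacer)
        for _ in range(config.genes_per_scaffold):
            if gene_idx >= config.n_genes:
                break
            n_codons = int(rng.integers(config.gene_codons_min, config.gene_codons_max + 1))
            body = "".join(codon_arr[rng.choice(len(codon_arr), size=n_codons, p=codon_w)])
            coding = body + "TGA"
            strand = "+" if rng.random() < 0.5 else "-"
            on_plus = coding if strand == "+" else str(Seq(coding).reverse_complement())
            gid = f"gene_{gene_idx + 1:04d}"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    scaffold=name,
                    strand=strand,
                    cds_segments=[(pos, pos + len(on_plus))],
                )
            )
            gene_coding[gid] = coding
            parts.append(on_plus)
            pos += len(on_plus)
            spacer = _random_dna(
                rng,
                int(rng.integers(config.intergenic_min, config.intergenic_max + 1)),
                config.at_content,
            )
            parts.append(spacer)
            pos += len(spacer)
            gene_idx += 1
        scaffolds[name] = "".join(parts)

    # --- insertion sites -----------------------------------------------------
    margin = 150  # stay clear of scaffold edges and region boundaries
    exon_pool: list[tuple[str, int, str]] = []  # (scaffold, pos, gene_id)
    for gene in genes:
        s, e = gene.cds_segments[0]
        for p in _spaced_ta_sites(scaffolds[gene.scaffold], s + 3, e - 5, config.min_ies_separation):
            exon_pool.append((gene.scaffold, p, gene.gene_id))
    intergenic_pool: list[tuple[str, int]] = []
    for name, seq in scaffolds.items():
        gene_spans = sorted(
            g.cds_segments[0] for g in genes if g.scaffold == name
        )
        bounds = [0] + [x for span in gene_spans for x in span] + [len(seq)]
        for lo, hi in zip(bounds[::2], bounds[1::2]):
            for p in _spaced_ta_sites(seq, lo + margin, hi - margin, config.min_ies_separation):
                intergenic_pool.append((name, p))

    n_exon = int(round(config.n_ies * config.exon_fraction))
    n_inter = config.n_ies - n_exon
    if len(exon_pool) < n_exon or len(intergenic_pool) < n_inter:
        raise ValidationError(
            f"not enough TA insertion sites (exon {len(exon_pool)}/{n_exon}, "
            f"intergenic {len(intergenic_pool)}/{n_inter}); increase genome size"
        )
    exon_sites = [exon_pool[i] for i in rng.choice(len(exon_pool), size=n_exon, replace=False)]
    inter_sites = [
        intergenic_pool[i] for i in rng.choice(len(intergenic_pool), size=n_inter, replace=False)
    ]

    # --- expression ----------------------------------------------------------
    expr_vals = {}
    for gene in genes:
        if rng.random() < config.zero_expression_fraction:
            expr_vals[gene.gene_id] = 0.0
        else:
            expr_vals[gene.gene_id] = float(
                2 ** rng.normal(config.expr_log2_mean, config.expr_log2_sd)
            )
    expression = ExpressionTable(expr_vals)
    expr_classes = classify_expression(expression)

    # --- IES loci: epi class, planted role, sequence ---------------------------
    gene_by_id = {g.gene_id: g for g in genes}
    lengths = _sample_lengths(rng, config.n_ies, config)
    small_max = config.small_max_length
    loci: list[IESLocus] = []
    planted: dict[str, dict] = {}
    clamp_count = 0
    records = [("exon",) + site for site in exon_sites] + [
        ("intergenic",) + site + (None,) for site in inter_sites
    ]
    for i, rec in enumerate(records):
        loc_class, scaffold, ip, host = rec[0], rec[1], rec[2], rec[3]
        L = int(lengths[i])
        small = L <= small_max

        if small and rng.random() < config.dcl23_prob_small:
            epi = "DCL2/3"
        elif not small and rng.random() < config.dcl5_prob_large:
            epi = "DCL5"
        else:
            epi = "none"

        role = "background"
        if loc_class == "exon":
            expr = expr_classes.get(host, "unexpressed")
            if small:
                p = config.up_small_base_prob
                if epi == "DCL2/3":
                    p *= config.responsive_epi_boost
                if expr == "HEG":
                    p *= config.responsive_expr_boost
                if rng.random() < min(p, config.responsive_max_prob):
                    role = "up"
            else:
                p = config.down_large_base_prob
                if epi == "DCL5":
                    p *= config.responsive_epi_boost
                if expr == "WEG":
                    p *= config.responsive_expr_boost
                if rng.random() < min(p, config.responsive_max_prob):
                    role = "down"
                elif rng.random() < config.up_large_prob:
                    role = "up_large"
        elif rng.random() < config.up_intergenic_prob:
            role = "up_intergenic"

        interior = _random_dna(rng, L - 2, config.at_content)
        eliminated = "TA" + interior
        strand = None
        if loc_class == "exon":
            gene = gene_by_id[host]
            strand = gene.strand
            seed_rate = (
                config.ptc_seed_rate_responsive if role == "up" else config.ptc_seed_rate
            )
            if rng.random() < seed_rate:
                q = ip - gene.cds_segments[0][0]
                eliminated = _plant_inframe_stop(
                    rng, eliminated, q, gene.cds_length, gene.strand
                )
        ies_id = f"IES_{i + 1:05d}"
        loci.append(
            IESLocus(
                ies_id=ies_id,
                scaffold=scaffold,
                mac_insertion_point=int(ip),
                ies_sequence=eliminated + "TA",
                location_class=loc_class,
                host_gene_id=host,
                strand_of_host=strand,
                epi_class=epi,
            )
        )
        planted[ies_id] = {"role": role}

    role_multipliers = {
        "up": config.up_multipliers,
        "up_large": config.up_large_multipliers,
        "down": config.down_multipliers,
        "up_intergenic": config.intergenic_multipliers,
    }

    # --- baseline and per-condition retention ---------------------------------
    true_retention: dict[tuple[str, str], float] = {}
    a_b, b_b = config.baseline_beta
    r_lo, r_hi = config.responsive_retention_min, config.responsive_retention_max
    for locus in loci:
        role = planted[locus.ies_id]["role"]
        if role != "background":
            base = float(1.0 / rng.uniform(1.0 / r_hi, 1.0 / r_lo))
        elif rng.random() < config.baseline_zero_fraction:
            base = 0.0
        else:
            base = float(rng.beta(a_b, b_b))
        planted[locus.ies_id]["baseline"] = base
        mults = role_multipliers.get(role, {})
        for cond in config.conditions:
            p = base * mults.get(cond, 1.0)
            if p > 1.0:
                p = 1.0
                clamp_count += 1
            true_retention[(locus.ies_id, cond)] = p
    if clamp_count:
        warnings.warn(f"{clamp_count} retention probabilities clamped to [0, 1]")

    strata_desc = {
        "up": "small exon IESs (DCL2/3- and HEG-boosted)",
        "up_large": "large exon IESs, mild count increase",
        "down": "large exon IESs (DCL5- and WEG-boosted), retention reduced",
        "up_intergenic": "intergenic IESs, size-independent mild increase",
    }
    planted["_summary"] = {
        role: {
            "stratum": desc,
            "multipliers": dict(role_multipliers[role]),
            "n_loci": sum(
                1 for v in planted.values() if isinstance(v, dict) and v.get("role") == role
            ),
        }
        for role, desc in strata_desc.items()
    }

    return SyntheticTruth(
        mac_genome=scaffolds,
        ies_loci=loci,
        genes=genes,
        expression=expression,
        conditions=tuple(config.conditions),
        true_retention=true_retention,
        planted_effects=planted,
        config=config,
        clamp_warnings=clamp_count,
    )


# ---------------------------------------------------------------------------
# read-count and read simulation


def simulate_counts(
    truth: SyntheticTruth,
    condition: str,
    mean_coverage: float,
    seed: int | np.random.Generator = 0,
) -> list[JunctionCounts]:
    """Per-locus junction counts: n ~ Poisson(coverage), IES+ ~ Binomial(n, p).

    With ``config.overdispersion`` set to a concentration ``c``, the
    per-locus success probability is drawn from Beta(p*c, (1-p)*c)
    (beta-binomial counts).
    """
    if condition not in truth.conditions:
        raise ValidationError(f"unknown condition {condition!r}")
    if mean_coverage <= 0:
        raise ValidationError("mean_coverage must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([truth.retention(l.ies_id, condition) for l in truth.ies_loci])
    n = rng.poisson(mean_coverage, size=len(p))
    c = truth.config.overdispersion
    if c is not None:
        pos = (p > 0) & (p < 1)
        p = p.copy()
        p[pos] = rng.beta(p[pos] * c, (1 - p[pos]) * c)
    k = rng.binomial(n, p)
    return [
        JunctionCounts(ies_id=l.ies_id, k_ies=int(k[i]), k_mac=int(n[i] - k[i]))
        for i, l in enumerate(truth.ies_loci)
    ]


def simulate_reads(
    truth: SyntheticTruth,
    condition: str,
    read_length: int,
    mean_coverage: float,
    seed: int | np.random.Generator = 0,
    min_flank: int = 10,
    fastq_path=None,
) -> list[tuple[str, str]]:
    """Reads drawn from the MAC (excised) or IES+ (retained) form per locus.

    Each read name encodes its origin (``<ies_id>|IES|i`` or
    ``<ies_id>|MAC|i``) so classifier output can be checked against the
    generative truth.  Reads start uniformly within the local form, so a
    read may cover no junction (NO_MATCH) — as in real data.
    """
    if read_length < 2 * min_flank:
        raise ValidationError(
            f"read_length {read_length} < 2 x min_flank {min_flank}"
        )
    if condition not in truth.conditions:
        raise ValidationError(f"unknown condition {condition!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    for locus in truth.ies_loci:
        scaf = truth.mac_genome[locus.scaffold]
        ip = locus.mac_insertion_point
        ctx = read_length
        left = scaf[max(0, ip - ctx) : ip]
        right = scaf[ip + 2 : ip + 2 + ctx]
        mac_form = left + scaf[ip : ip + 2] + right
        ies_form = left + locus.ies_sequence + right
        p = truth.retention(locus.ies_id, condition)
        n = int(rng.poisson(mean_coverage))
        origins = rng.random(n) < p
        for i in range(n):
            form, tag = (ies_form, "IES") if origins[i] else (mac_form, "MAC")
            start = int(rng.integers(0, len(form) - read_length + 1))
            seq = form[start : start + read_length]
            if rng.random() < 0.5:  # either sequencing orientation
                seq = str(Seq(seq).reverse_complement())
            reads.append((f"{locus.ies_id}|{tag}|{i}", seq))
    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            for name, seq in reads:
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return reads
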