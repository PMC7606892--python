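"""Premature-termination-codon consequences of IES retention.

Paramecium tetraurelia uses the ciliate nuclear genetic code (NCBI
translation table 6): TGA is the only stop codon, while TAA and TAG
encode glutamine.  Calling PTCs with the standard table would therefore
be biologically wrong; the standard code remains available for
contrast.

Retention of an exon-mapping IES splices the eliminated segment back
into the host CDS.  The consequence is one of:

* ``PTC_INDUCING``     — translation of the retained CDS stops strictly
  upstream of the native stop codon;
* ``ORF_INTACT``       — the eliminated length is a multiple of 3 and no
  stop appears before the native one;
* ``FRAMESHIFT_NO_STOP`` — the reading frame downstream is shifted but
  no premature stop is created.

The native stop is located by coordinate arithmetic (the insertion is
internal, so its nucleotide offset in the retained CDS is
``cds_length - 3 + inserted_length``), never by sequence search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io_formats import GeneModel, IESLocus, ValidationError

__all__ = [
    "PTCAnnotation",
    "GENETIC_CODES",
    "build_retained_cds",
    "translate",
    "classify_ptc",
    "ptc_enrichment",
]

#: name -> NCBI translation table id
GENETIC_CODES = {"ciliate": 6, "standard": 1}


@dataclass(frozen=True)
class PTCAnnotation:
    ies_id: str
    host_gene_id: str
    consequence: Literal["PTC_INDUCING", "ORF_INTACT", "FRAMESHIFT_NO_STOP"]
    first_stop_codon_index: int | None
    frame_shift: int  # eliminated-segment length mod 3

    @property
    def ptc_inducing(self) -> bool:
        return self.consequence == "PTC_INDUCING"


def _containing_segment(gene: GeneModel, ip: int) -> tuple[int, int]:
    for s, e in gene.cds_segments:
        # strictly inside: the retained TA and the spliced segment stay
        # within one segment, away from both boundaries
        if s < ip and ip + 2 < e:
            return s, e
    raise ValidationError(
        f"insertion point {ip} not strictly inside a CDS segment of {gene.gene_id}"
    )


def build_retained_cds(gene: GeneModel, ies: IESLocus, mac_genome: Mapping[str, str]) -> str:
    """The host CDS with the eliminated segment spliced back in, coding strand.

    Splicing happens in genome (+ strand) space in front of the retained
    TA; for ``-`` strand genes the result is the reverse complement of
    the + strand construction.  Removing the segment again restores the
    MAC CDS exactly.
    """
    if gene.scaffold != ies.scaffold:
        raise ValidationError(
            f"gene {gene.gene_id} on {gene.scaffold} but IES {ies.ies_id} on {ies.scaffold}"
        )
    scaf = mac_genome[gene.scaffold]
    ip = ies.mac_insertion_point
    _containing_segment(gene, ip)
    parts = []
    for s, e in gene.cds_segments:
        seg = scaf[s:e]
        if s < ip and ip + 2 < e:
            seg = scaf[s:ip] + ies.eliminated_segment + scaf[ip:e]
        parts.append(seg)
    plus = "".join(parts)
    if gene.strand == "-":
        return str(Seq(plus).reverse_complement())
    return plus


def translate(cds: str, genetic_code: str = "ciliate") -> tuple[str, list[int]]:
    """Codon-by-codon translation; returns (protein, stop codon indices).

    Stops are rendered as ``*`` in the protein string; trailing bases that
    do not form a complete codon are ignored.
    """
    if genetic_code not in GENETIC_CODES:
        raise ValidationError(f"unknown genetic code {genetic_code!r}")
    if len(cds) < 3:
        raise ValidationError("CDS shorter than one codon")
    if set(cds) - set("ACGT"):
        raise ValidationError("non-ACGT character in CDS")
    table_id = GENETIC_CODES[genetic_code]
    # sanity anchor on the Biopython table rather than hand-rolled codons
    CodonTable.unambiguous_dna_by_id[table_id]
    n_codons = len(cds) // 3
    protein = str(Seq(cds[: 3 * n_codons]).translate(table=table_id))
    stops = [i for i, aa in enumerate(protein) if aa == "*"]
    return protein, stops


def classify_ptc(
    gene: GeneModel,
    ies: IESLocus,
    mac_genome: Mapping[str, str],
    genetic_code: str = "ciliate",
) -> PTCAnnotation:
    """Consequence of retaining one exon-mapping IES in its host CDS."""
    retained = build_retained_cds(gene, ies, mac_genome)
    ins_len = ies.length
    frame_shift = ins_len % 3
    _, stops = translate(retained, genetic_code)
    mac_len = gene.cds_length
    # nucleotide offset of the native stop codon in the retained CDS
    native_stop_nt = mac_len - 3 + ins_len

    first_premature = next((i for i in stops if 3 * i < native_stop_nt), None)
    if first_premature is not None:
        consequence = "PTC_INDUCING"
    elif frame_shift == 0:
        consequence = "ORF_INTACT"
    else:
        consequence = "FRAMESHIFT_NO_STOP"
    return PTCAnnotation(
        ies_id=ies.ies_id,
        host_gene_id=gene.gene_id,
        consequence=consequence,
        first_stop_codon_index=first_premature,
        frame_shift=frame_shift,
    )


def ptc_enrichment(
    observed_ids: Sequence[str],
    background_ids: Sequence[str],
    annotations: Mapping[str, PTCAnnotation],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Permutation test for PTC-inducing excess in an observed IES set.

    The null draws ``len(observed)`` loci from the background stratum
    ``n_perm`` times; the expected fraction is the mean PTC-inducing
    fraction over draws and the one-sided empirical P-value carries the
    standard +1 correction.
    """
    observed = list(observed_ids)
    background = list(background_ids)
    if len(background) < len(observed):
        raise ValidationError("background smaller than observed set")
    missing = [i for i in observed + background if i not in annotations]
    if missing:
        raise ValidationError(f"loci without PTC annotation: {missing[:5]}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    is_ptc = np.array([annotations[i].ptc_inducing for i in background])
    obs_frac = float(np.mean([annotations[i].ptc_inducing for i in observed]))
    m = len(observed)
    draws = np.empty(n_perm)
    for p in range(n_perm):
        draws[p] = is_ptc[rng.choice(len(background), size=m, replace=False)].mean()
    expected = float(draws.mean())
    p_emp = float((np.sum(draws >= obs_frac) + 1) / (n_perm + 1))
    return obs_frac, expected, p_emp
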