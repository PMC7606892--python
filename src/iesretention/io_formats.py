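"""Readers and writers for the on-disk formats the pipeline touches.

All coordinates are 0-based half-open inside the package and 1-based
inclusive in GFF3; the conversion happens here and nowhere else.

An IES is stored with *both* flanking TA dinucleotides, and the somatic
(MAC) reference retains a single TA at the insertion point::

    MIC locus :  left_flank  [TA ... interior ... TA]  right_flank
    MAC locus :  left_flank   TA                       right_flank

The eliminated segment is the stored sequence minus its final TA, so the
reported IES length is ``len(ies_sequence) - 2`` and splicing the
eliminated segment back in front of the retained TA reconstitutes the
germline form exactly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils.feature
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ParseError",
    "ValidationError",
    "IESLocus",
    "GeneModel",
    "ExpressionTable",
    "read_fasta",
    "write_fasta",
    "read_ies_annotation",
    "write_ies_annotation",
    "read_gene_models",
    "write_gene_models",
    "read_expression",
    "write_expression",
    "read_epi_classes",
    "write_epi_classes",
    "read_counts",
    "write_counts",
    "write_report",
    "read_report",
]

IES_FEATURE_TYPE = "internal_eliminated_sequence"
VALID_EPI_CLASSES = ("DCL2/3", "DCL5", "none", "unknown")
VALID_LOCATION_CLASSES = ("exon", "intergenic", "other")

#: attributes this package writes; anything else on a feature is preserved.
_KNOWN_IES_ATTRS = ("ID", "sequence", "location_class", "host_gene", "epi_class")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass
class IESLocus:
    """One germline Internal Eliminated Sequence.

    ``mac_insertion_point`` is the 0-based position on the MAC scaffold
    where the retained TA begins.  ``length`` is the eliminated-segment
    length, ``len(ies_sequence) - 2``.
    """

    ies_id: str
    scaffold: str
    mac_insertion_point: int
    ies_sequence: str
    location_class: str = "other"
    host_gene_id: str | None = None
    strand_of_host: str | None = None
    epi_class: str = "unknown"
    extra_attributes: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.ies_sequence) - 2

    @property
    def eliminated_segment(self) -> str:
        """The DNA removed on excision: everything but the final TA."""
        return self.ies_sequence[:-2]

    def validate(self, min_length: int = 26) -> None:
        seq = self.ies_sequence
        if not (seq.startswith("TA") and seq.endswith("TA")):
            raise ValidationError(
                f"IES {self.ies_id}: sequence is not TA-bounded "
                f"({seq[:4]}...{seq[-4:]})"
            )
        if set(seq) - set("ACGT"):
            raise ValidationError(
                f"IES {self.ies_id}: non-ACGT characters in sequence"
            )
        if self.length < min_length:
            raise ValidationError(
                f"IES {self.ies_id}: length {self.length} < {min_length}"
            )
        if self.location_class == "exon" and not self.host_gene_id:
            raise ValidationError(
                f"IES {self.ies_id}: exon-mapping but no host gene"
            )
        if self.location_class not in VALID_LOCATION_CLASSES:
            raise ValidationError(
                f"IES {self.ies_id}: bad location_class {self.location_class!r}"
            )
        if self.epi_class not in VALID_EPI_CLASSES:
            raise ValidationError(
                f"IES {self.ies_id}: bad epi_class {self.epi_class!r}"
            )


@dataclass
class GeneModel:
    """A protein-coding gene on the MAC reference.

    ``cds_segments`` are sorted, non-overlapping half-open 0-based
    intervals in genomic order; for ``-`` strand genes the coding sequence
    is the reverse complement of their concatenation.
    """

    gene_id: str
    scaffold: str
    strand: str
    cds_segments: list[tuple[int, int]]

    def __post_init__(self) -> None:
        segs = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if e1 > s2:
                raise ValidationError(
                    f"gene {self.gene_id}: overlapping CDS segments"
                )
        self.cds_segments = [(int(s), int(e)) for s, e in segs]
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    def mac_cds_sequence(self, mac_genome: Mapping[str, str]) -> str:
        """Coding-strand CDS extracted from the MAC genome."""
        scaf = mac_genome[self.scaffold]
        plus = "".join(scaf[s:e] for s, e in self.cds_segments)
        if self.strand == "-":
            return str(Seq(plus).reverse_complement())
        return plus


class ExpressionTable:
    """Per-gene expression values with log2 transform on positive entries.

    Zero-expression genes are retained but carry no log2 value and are
    excluded from any quartile computation downstream.
    """

    def __init__(self, values: Mapping[str, float]):
        for gid, v in values.items():
            if v < 0:
                raise ValidationError(f"gene {gid}: negative expression {v}")
        self.values: dict[str, float] = dict(values)

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values

    def log2_value(self, gene_id: str) -> float | None:
        v = self.values[gene_id]
        return math.log2(v) if v > 0 else None

    @property
    def positive_log2(self) -> dict[str, float]:
        return {g: math.log2(v) for g, v in self.values.items() if v > 0}


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3


def _iter_gff3_features(path):
    """Yield (line_number, gffutils.Feature), raising ParseError with the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # gffutils raises several types
                raise ParseError(f"{path}: malformed GFF3 at line {lineno}: {exc}") from exc
            if len(line.split("\t")) != 9:
                raise ParseError(
                    f"{path}: malformed GFF3 at line {lineno}: expected 9 columns"
                )
            yield lineno, feat


def _attr(feat, key: str) -> str | None:
    vals = feat.attributes.get(key)
    return vals[0] if vals else None


def read_ies_annotation(path_gff3, path_fasta=None, min_length: int = 26) -> list[IESLocus]:
    """Read IES loci from GFF3, resolving sequences from an attribute or FASTA.

    The GFF3 feature spans the retained TA on the MAC reference
    (1-based inclusive start..start+1); internally the insertion point is
    the 0-based ``start - 1``.
    """
    companion = read_fasta(path_fasta) if path_fasta is not None else {}
    loci: list[IESLocus] = []
    for lineno, feat in _iter_gff3_features(path_gff3):
        if feat.featuretype != IES_FEATURE_TYPE:
            continue
        ies_id = _attr(feat, "ID")
        if ies_id is None:
            raise ParseError(f"{path_gff3}: line {lineno}: IES feature without ID")
        seq = _attr(feat, "sequence")
        if seq is None:
            if ies_id not in companion:
                raise ValidationError(
                    f"IES {ies_id}: no sequence attribute and no FASTA entry"
                )
            seq = companion[ies_id]
        extra = {
            k: list(v)
            for k, v in feat.attributes.items()
            if k not in _KNOWN_IES_ATTRS
        }
        locus = IESLocus(
            ies_id=ies_id,
            scaffold=feat.seqid,
            mac_insertion_point=feat.start - 1,
            ies_sequence=seq.upper(),
            location_class=_attr(feat, "location_class") or "other",
            host_gene_id=_attr(feat, "host_gene"),
            strand_of_host=feat.strand if feat.strand in "+-" else None,
            epi_class=_attr(feat, "epi_class") or "unknown",
            extra_attributes=extra,
        )
        locus.validate(min_length=min_length)
        loci.append(locus)
    return loci


def write_ies_annotation(loci: Iterable[IESLocus], path_gff3) -> None:
    with open(path_gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            attrs = [
                f"ID={locus.ies_id}",
                f"sequence={locus.ies_sequence}",
                f"location_class={locus.location_class}",
            ]
            if locus.host_gene_id:
                attrs.append(f"host_gene={locus.host_gene_id}")
            attrs.append(f"epi_class={locus.epi_class}")
            for k, vals in locus.extra_attributes.items():
                attrs.append(f"{k}={','.join(vals)}")
            start = locus.mac_insertion_point + 1  # 1-based inclusive
            strand = locus.strand_of_host or "."
            fh.write(
                "\t".join(
                    [
                        locus.scaffold,
                        "iesretention",
                        IES_FEATURE_TYPE,
                        str(start),
                        str(start + 1),
                        ".",
                        strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gene_models(path_gff3) -> list[GeneModel]:
    """Read gene models from GFF3 CDS features grouped by Parent."""
    segs: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for lineno, feat in _iter_gff3_features(path_gff3):
        if feat.featuretype != "CDS":
            continue
        parent = _attr(feat, "Parent") or _attr(feat, "ID")
        if parent is None:
            raise ParseError(f"{path_gff3}: line {lineno}: CDS without Parent/ID")
        segs.setdefault(parent, []).append((feat.start - 1, feat.end))
        meta[parent] = (feat.seqid, feat.strand)
    genes = []
    for gid, intervals in segs.items():
        scaffold, strand = meta[gid]
        genes.append(
            GeneModel(gene_id=gid, scaffold=scaffold, strand=strand, cds_segments=intervals)
        )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path_gff3) -> None:
    with open(path_gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            gstart = min(s for s, _ in gene.cds_segments) + 1
            gend = max(e for _, e in gene.cds_segments)
            fh.write(
                "\t".join(
                    [
                        gene.scaffold,
                        "iesretention",
                        "gene",
                        str(gstart),
                        str(gend),
                        ".",
                        gene.strand,
                        ".",
                        f"ID={gene.gene_id}",
                    ]
                )
                + "\n"
            )
            for s, e in gene.cds_segments:
                fh.write(
                    "\t".join(
                        [
                            gene.scaffold,
                            "iesretention",
                            "CDS",
                            str(s + 1),
                            str(e),
                            ".",
                            gene.strand,
                            "0",
                            f"Parent={gene.gene_id}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# TSV tables


def _iter_tsv_rows(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_expression(path_tsv) -> ExpressionTable:
    """Two-column TSV ``gene_id<TAB>value``; a header row is tolerated."""
    values: dict[str, float] = {}
    for lineno, fields in _iter_tsv_rows(path_tsv):
        if len(fields) < 2:
            raise ParseError(f"{path_tsv}: line {lineno}: expected 2 columns")
        gid, raw = fields[0], fields[1]
        try:
            value = float(raw)
        except ValueError:
            if lineno == 1:  # header
                continue
            raise ParseError(f"{path_tsv}: line {lineno}: non-numeric value {raw!r}")
        if gid in values:
            raise ValidationError(f"duplicate gene_id {gid!r} in {path_tsv}")
        if value < 0:
            raise ValidationError(
                f"{path_tsv}: line {lineno}: negative expression for {gid}"
            )
        values[gid] = value
    return ExpressionTable(values)


def write_expression(table: ExpressionTable, path_tsv) -> None:
    with open(path_tsv, "w") as fh:
        fh.write("gene_id\texpression\n")
        for gid, v in table.values.items():
            fh.write(f"{gid}\t{v:g}\n")


def read_epi_classes(path_tsv) -> dict[str, str]:
    """TSV ``ies_id<TAB>epi_class`` emulating ParameciumDB epi-IES lists."""
    classes: dict[str, str] = {}
    for lineno, fields in _iter_tsv_rows(path_tsv):
        if len(fields) < 2:
            raise ParseError(f"{path_tsv}: line {lineno}: expected 2 columns")
        ies_id, cls = fields[0], fields[1]
        if cls == "epi_class":  # header
            continue
        if cls not in VALID_EPI_CLASSES:
            raise ValidationError(
                f"{path_tsv}: line {lineno}: unknown epi_class {cls!r}"
            )
        classes[ies_id] = cls
    return classes


def write_epi_classes(classes: Mapping[str, str], path_tsv) -> None:
    with open(path_tsv, "w") as fh:
        fh.write("ies_id\tepi_class\n")
        for ies_id, cls in classes.items():
            fh.write(f"{ies_id}\t{cls}\n")


def read_counts(path_tsv):
    """Read a junction-count table (ies_id, k_ies, k_mac[, n_ambiguous])."""
    from .irs import JunctionCounts  # local import to avoid a cycle

    counts = []
    for lineno, fields in _iter_tsv_rows(path_tsv):
        if fields[0] == "ies_id":
            continue
        if len(fields) < 3:
            raise ParseError(f"{path_tsv}: line {lineno}: expected >= 3 columns")
        try:
            k_ies, k_mac = int(fields[1]), int(fields[2])
            n_amb = int(fields[3]) if len(fields) > 3 else 0
        except ValueError as exc:
            raise ParseError(f"{path_tsv}: line {lineno}: {exc}") from exc
        counts.append(
            JunctionCounts(ies_id=fields[0], k_ies=k_ies, k_mac=k_mac, n_ambiguous=n_amb)
        )
    return counts


def write_counts(counts, path_tsv) -> None:
    with open(path_tsv, "w") as fh:
        fh.write("ies_id\tk_ies\tk_mac\tn_ambiguous\n")
        for c in counts:
            fh.write(f"{c.ies_id}\t{c.k_ies}\t{c.k_mac}\t{c.n_ambiguous}\n")


# ---------------------------------------------------------------------------
# JSON reports


def _sanitize(obj, path="results"):
    """Make ``obj`` JSON-safe; NaN/inf become null with a warning."""
    if isinstance(obj, Mapping):
        return {str(k): _sanitize(v, f"{path}.{k}") for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v, f"{path}[{i}]") for i, v in enumerate(obj)]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float) and not math.isfinite(obj):
        warnings.warn(f"non-finite value at {path} serialized as null")
        return None
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    if isinstance(obj, set):
        return sorted(_sanitize(v, path) for v in obj)
    raise ValidationError(f"unserializable field at {path}: {type(obj).__name__}")


def write_report(results: Mapping, path_json, metadata: Mapping | None = None) -> None:
    """Write a JSON report with run metadata; round-trippable via read_report."""
    payload = {
        "metadata": _sanitize(dict(metadata or {}), "metadata"),
        "results": _sanitize(dict(results)),
    }
    with open(path_json, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def read_report(path_json) -> dict:
    with open(path_json) as fh:
        return json.load(fh)
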