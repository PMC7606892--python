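"""Junction-read classification, counting and IES Retention Scores.

The IES Retention Score (IRS) of a locus is the fraction of
junction-informative reads that contain the IES: ``k_ies / (k_ies +
k_mac)``.  An IRS of 0 means complete excision from every sequenced
somatic copy; 1 means full retention.

Read classification is by exact substring match against three junction
strings per locus, each spanning the breakpoint with ``min_flank`` bases
of context on both sides:

* the MAC junction (excised form: left flank | retained TA + right flank),
* the IES+ left boundary (left flank | IES start),
* the IES+ right boundary (eliminated segment | retained TA + right flank).

A read (or its reverse complement) containing an IES+ boundary is
IES_PLUS; containing the MAC junction, MAC; containing evidence of both
forms — or junctions of two different loci — AMBIGUOUS and never
counted as support anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .io_formats import IESLocus, ValidationError

__all__ = [
    "ReadClass",
    "JunctionCounts",
    "IRSRecord",
    "LocusJunctions",
    "junctions_for_locus",
    "classify_read",
    "count_reads",
    "compute_irs",
    "apply_filters",
    "DEFAULT_MIN_READS",
    "DEFAULT_MIN_LENGTH",
    "DEFAULT_MIN_FLANK",
    "DEFAULT_IRS_THRESHOLD",
]

DEFAULT_MIN_READS = 20
DEFAULT_MIN_LENGTH = 26
DEFAULT_MIN_FLANK = 10
#: an IES with IRS above this is called "incompletely excised" / somatic
DEFAULT_IRS_THRESHOLD = 0.1


class ReadClass(Enum):
    IES_PLUS = "IES_PLUS"
    MAC = "MAC"
    AMBIGUOUS = "AMBIGUOUS"
    NO_MATCH = "NO_MATCH"


@dataclass
class JunctionCounts:
    ies_id: str
    k_ies: int
    k_mac: int
    n_ambiguous: int = 0

    def __post_init__(self) -> None:
        if min(self.k_ies, self.k_mac, self.n_ambiguous) < 0:
            raise ValidationError(f"{self.ies_id}: negative read count")

    @property
    def n_total(self) -> int:
        return self.k_ies + self.k_mac


@dataclass
class IRSRecord:
    ies_id: str
    irs: float | None
    n_total: int
    passed_filters: bool = True
    filter_reasons: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class LocusJunctions:
    """The three 2*min_flank junction strings of one locus."""

    ies_id: str
    mac_junction: str
    ies_left: str
    ies_right: str


def junctions_for_locus(
    locus: IESLocus, mac_genome: Mapping[str, str], min_flank: int = DEFAULT_MIN_FLANK
) -> LocusJunctions:
    """Derive the three junction strings from the MAC genome + IES sequence.

    Each string has exactly ``min_flank`` bases on either side of its
    breakpoint.  The locus must not sit closer than ``min_flank`` to a
    scaffold edge.
    """
    if min_flank < 1:
        raise ValidationError("min_flank must be >= 1")
    scaf = mac_genome[locus.scaffold]
    ip = locus.mac_insertion_point
    if scaf[ip : ip + 2] != "TA":
        raise ValidationError(
            f"IES {locus.ies_id}: MAC reference lacks TA at insertion point {ip}"
        )
    if ip < min_flank or ip + min_flank > len(scaf):
        raise ValidationError(
            f"IES {locus.ies_id}: insertion point within {min_flank} nt of scaffold edge"
        )
    left = scaf[ip - min_flank : ip]
    # retained (IES+) local form: left flank + full IES sequence + right flank,
    # where the IES's final TA coincides with the MAC's retained TA.
    retained = locus.ies_sequence + scaf[ip + 2 : ip + 2 + min_flank]
    return LocusJunctions(
        ies_id=locus.ies_id,
        mac_junction=left + scaf[ip : ip + min_flank],
        ies_left=left + retained[:min_flank],
        ies_right=retained[len(locus.ies_sequence) - 2 - min_flank : len(locus.ies_sequence) - 2 + min_flank],
    )


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def classify_read(
    read_sequence: str, locus_junctions: LocusJunctions, min_flank: int = DEFAULT_MIN_FLANK
) -> ReadClass:
    """Classify one read against one locus by exact junction matching."""
    if min_flank < 1:
        raise ValidationError("min_flank must be >= 1")
    read = read_sequence.upper()
    rc = _revcomp(read)

    def hits(j: str) -> bool:
        return j in read or j in rc

    ies_hit = hits(locus_junctions.ies_left) or hits(locus_junctions.ies_right)
    mac_hit = hits(locus_junctions.mac_junction)
    if ies_hit and mac_hit:
        return ReadClass.AMBIGUOUS
    if ies_hit:
        return ReadClass.IES_PLUS
    if mac_hit:
        return ReadClass.MAC
    return ReadClass.NO_MATCH


def _iter_reads(fastq) -> Iterable[tuple[str, str]]:
    if isinstance(fastq, (str,)) or hasattr(fastq, "__fspath__"):
        seen = set()
        for rec in SeqIO.parse(str(fastq), "fastq"):
            if rec.id in seen:
                import warnings

                warnings.warn(f"duplicate read identifier {rec.id}; both processed")
            seen.add(rec.id)
            yield rec.id, str(rec.seq).upper()
    else:
        yield from fastq


def count_reads(
    fastq,
    loci: Sequence[IESLocus],
    mac_genome: Mapping[str, str],
    min_flank: int = DEFAULT_MIN_FLANK,
) -> list[JunctionCounts]:
    """Tally IES+/MAC support per locus from a FASTQ (path or (id, seq) pairs).

    Each read contributes to at most one locus category; a read whose
    junction matches span two different loci is AMBIGUOUS at both.
    A k-mer index over the fixed-length junction strings keeps the scan
    linear in total read length.
    """
    junctions = [junctions_for_locus(l, mac_genome, min_flank) for l in loci]
    k = 2 * min_flank
    index: dict[str, list[tuple[int, str]]] = {}
    for i, j in enumerate(junctions):
        index.setdefault(j.mac_junction, []).append((i, "mac"))
        index.setdefault(j.ies_left, []).append((i, "ies"))
        index.setdefault(j.ies_right, []).append((i, "ies"))

    k_ies = [0] * len(loci)
    k_mac = [0] * len(loci)
    n_amb = [0] * len(loci)

    for _read_id, seq in _iter_reads(fastq):
        per_locus: dict[int, set[str]] = {}
        for s in (seq, _revcomp(seq)):
            for pos in range(len(s) - k + 1):
                for i, kind in index.get(s[pos : pos + k], ()):
                    per_locus.setdefault(i, set()).add(kind)
        if not per_locus:
            continue
        if len(per_locus) > 1:  # junction evidence at two loci: never double-count
            for i in per_locus:
                n_amb[i] += 1
            continue
        (i, kinds), = per_locus.items()
        if kinds == {"ies"}:
            k_ies[i] += 1
        elif kinds == {"mac"}:
            k_mac[i] += 1
        else:
            n_amb[i] += 1

    return [
        JunctionCounts(ies_id=loci[i].ies_id, k_ies=k_ies[i], k_mac=k_mac[i], n_ambiguous=n_amb[i])
        for i in range(len(loci))
    ]


def compute_irs(counts: JunctionCounts) -> IRSRecord:
    """IRS = k_ies / (k_ies + k_mac); undefined (flagged) when no reads."""
    n = counts.n_total
    if n == 0:
        return IRSRecord(
            ies_id=counts.ies_id,
            irs=None,
            n_total=0,
            passed_filters=False,
            filter_reasons=["no_reads"],
        )
    return IRSRecord(ies_id=counts.ies_id, irs=counts.k_ies / n, n_total=n)


def apply_filters(
    records: Sequence[IRSRecord],
    loci: Sequence[IESLocus],
    min_reads: int = DEFAULT_MIN_READS,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[IRSRecord]:
    """Apply the study-wide locus filters (coverage >= 20, length > 25 nt).

    Excluded records are retained with their reasons for audit; the
    returned list covers every input record.
    """
    lengths = {l.ies_id: l.length for l in loci}
    orphans = [r.ies_id for r in records if r.ies_id not in lengths]
    if orphans:
        raise ValidationError(
            f"records without matching loci: {', '.join(orphans[:5])}"
            + ("..." if len(orphans) > 5 else "")
        )
    out = []
    for r in records:
        reasons = [x for x in r.filter_reasons if x == "no_reads"]
        if r.n_total < min_reads:
            reasons.append("low_coverage")
        if lengths[r.ies_id] < min_length:
            reasons.append("short_ies")
        out.append(
            IRSRecord(
                ies_id=r.ies_id,
                irs=r.irs,
                n_total=r.n_total,
                passed_filters=not reasons,
                filter_reasons=sorted(set(reasons)),
            )
        )
    return out
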