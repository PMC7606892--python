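"""Shared fixtures: a hand-built toy locus and small simulated cohorts."""

import numpy as np
import pytest

from iesretention import (
    GeneModel,
    IESLocus,
    SimulationConfig,
    simulate_truth,
)


def make_locus(
    ies_id="IES_T1",
    scaffold="scaf",
    ip=30,
    interior="GGGCCGGTCAGTCAGGTACGTCAG",
    **kw,
):
    """A TA-bounded locus; eliminated length = len(interior) + 2."""
    return IESLocus(
        ies_id=ies_id,
        scaffold=scaffold,
        mac_insertion_point=ip,
        ies_sequence="TA" + interior + "TA",
        **kw,
    )


@pytest.fixture
def toy_locus():
    """One + strand gene with a 26-nt IES strictly inside its CDS.

    The scaffold is 30 nt of flank, a 60-nt CDS, 30 nt of flank; the
    insertion point sits at a TA inside the CDS.
    """
    rng = np.random.default_rng(42)
    # 20 codons, no internal TGA, codon 4 = TAC puts a TA at offset 12
    codons = (
        "ATG GCA GCT GAC TAC GGA CTT CCG GAG CAC "
        "CTT GAA CCG GGG CTT AAG CAT CTC GAG TGA"
    ).split()
    cds = "".join(codons)
    assert len(cds) % 3 == 0 and cds[12:14] == "TA"
    left = "".join(rng.choice(list("ACGT"), size=30))
    right = "".join(rng.choice(list("ACGT"), size=30))
    scaffold_seq = left + cds + right
    gene = GeneModel(
        gene_id="gene_T1",
        scaffold="scaf",
        strand="+",
        cds_segments=[(30, 30 + len(cds))],
    )
    ip = 30 + 12  # the TA inside the CDS
    locus = make_locus(
        ip=ip, location_class="exon", host_gene_id="gene_T1", strand_of_host="+"
    )
    genome = {"scaf": scaffold_seq}
    return genome, gene, locus


@pytest.fixture(scope="session")
def small_truth():
    """A small deterministic cohort reused across read-level tests."""
    cfg = SimulationConfig(seed=7, n_genes=40, n_ies=200, genes_per_scaffold=10)
    return simulate_truth(cfg)


@pytest.fixture(scope="session")
def default_truth():
    """The default study-condition cohort (session-scoped for speed)."""
    return simulate_truth(SimulationConfig(seed=7))
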