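"""Annotate the coding consequence of retaining each exon-mapping IES.

Paramecium uses the ciliate nuclear genetic code: only TGA terminates
translation, while TAA and TAG encode glutamine.  Retention splices the
eliminated segment back into the host CDS; a stop upstream of the
native one marks the IES as PTC-inducing.
"""

from collections import Counter

from iesretention import SimulationConfig, classify_ptc, simulate_truth, translate

protein, stops = translate("ATGTAAGGGTGA", genetic_code="ciliate")
print(f"ATGTAAGGGTGA -> {protein} (TAA read as Q; the only stop is the TGA)")

truth = simulate_truth(SimulationConfig(seed=11, n_genes=60, n_ies=300, genes_per_scaffold=15))
genes = {g.gene_id: g for g in truth.genes}
annotations = [
    classify_ptc(genes[l.host_gene_id], l, truth.mac_genome)
    for l in truth.ies_loci
    if l.location_class == "exon"
]
print(Counter(a.consequence for a in annotations))
# PTC_INDUCING transcripts are expected targets of nonsense-mediated
# decay, so retention of such an IES removes a productive gene copy.
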