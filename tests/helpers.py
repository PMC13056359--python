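"""Shared test utilities: a brute-force operon oracle independent of the
chain-walking implementation."""

from operonscan.model import GeneRecord, OperonParams
from operonscan.operon_caller import intergenic_distance


def brute_force_operon(genes, target, params: OperonParams):
    """Enumerate every contiguous window containing the target, check all
    rules on each, and return the member accessions of the maximal valid
    window. Independent of the greedy chain walk it cross-checks."""
    t = next(i for i, g in enumerate(genes) if g is target or g == target)

    def junction_ok(a, b):
        d = intergenic_distance(a, b)
        return -params.max_overlap_bp <= d <= params.max_intergenic_bp

    best = (t, t)
    for i in range(len(genes)):
        for j in range(i, len(genes)):
            if not i <= t <= j:
                continue
            if t - i > params.max_genes_each_side:
                continue
            if j - t > params.max_genes_each_side:
                continue
            if params.require_same_strand and any(
                genes[k].strand != target.strand for k in range(i, j + 1)
            ):
                continue
            if any(
                not junction_ok(genes[k], genes[k + 1]) for k in range(i, j)
            ):
                continue
            if (j - i) > (best[1] - best[0]):
                best = (i, j)
    return tuple(g.protein_accession for g in genes[best[0] : best[1] + 1])


def make_contig(
    gaps,
    strands=None,
    name="T",
    length=500,
    assembly="ASM",
):
    """Build a contig of len(gaps)+1 genes with the given junction gaps."""
    n = len(gaps) + 1
    strands = strands or ["+"] * n
    genes = []
    pos = 1000
    for i in range(n):
        if i > 0:
            pos = genes[-1].end + 1 + gaps[i - 1]
        genes.append(
            GeneRecord(
                assembly_id=assembly,
                contig_id=f"ctg_{name}",
                gene_index=i,
                start=pos,
                end=pos + length - 1,
                strand=strands[i],
                protein_accession=f"{name}_{i:02d}",
                product="hypothetical protein",
            )
        )
    return genes
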