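#!/usr/bin/env python
"""Genome-wide SNP structure: pairwise Fst, PCA and an NJ population tree.

Computes the Weir-Cockerham pairwise multilocus theta matrix across the
four populations, a Patterson-scaled genotype PCA, and a neighbor-joining
tree on allele-sharing distances.  Reads results/sim/, writes
results/structure/ (tables + a PCA scatter).
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from bemisia_delim import io as bio_io
from bemisia_delim.structure import nj_tree, pairwise_fst_matrix, pca_genotypes

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sim = BASE / "sim"
    out = BASE / "structure"
    out.mkdir(parents=True, exist_ok=True)
    matrix, dropped = bio_io.read_vcf(sim / "genotypes.vcf")
    popmap = bio_io.read_popmap(sim / "popmap.tsv")

    theta, pops = pairwise_fst_matrix(matrix, popmap)
    bio_io.write_fst_matrix_tsv(theta, pops, out / "fst_matrix.tsv")
    print("pairwise multilocus Fst (Weir-Cockerham):")
    for i, a in enumerate(pops):
        for j in range(i + 1, len(pops)):
            print(f"  {a} vs {pops[j]}: {theta[i, j]:.3f}")

    pca = pca_genotypes(matrix)
    bio_io.write_pca_tsv(pca, out / "pca_coordinates.tsv")
    print(f"PCA on {pca.n_loci_used} loci: PC1 {pca.variance_explained[0]:.1%}, "
          f"PC2 {pca.variance_explained[1]:.1%} of variance")

    fig, ax = plt.subplots(figsize=(6, 5))
    for pop in pops:
        idx = [pca.individual_ids.index(i) for i in popmap.members(pop)]
        ax.scatter(pca.coordinates[idx, 0], pca.coordinates[idx, 1],
                   label=pop, s=24)
    ax.set_xlabel(f"PC1 ({pca.variance_explained[0]:.1%})")
    ax.set_ylabel(f"PC2 ({pca.variance_explained[1]:.1%})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "pca.png", dpi=120)

    newick = nj_tree(matrix, popmap)
    (out / "nj_tree.nwk").write_text(newick + "\n")
    print(f"NJ population tree: {newick}")


if __name__ == "__main__":
    main()
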