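#!/usr/bin/env python
"""Generate the synthetic study dataset all later steps analyse.

Emulates the study design: 62 whitefly individuals in four populations
(SSA2/SSA4, SSA1-NW, SSA1-SE and the SSA-CA contact zone) typed at 3,000
genome-wide SNPs, each carrying one partial mtCOI barcode; five SSA2
individuals carry NUMT barcodes descended from an "SSA4" nuclear copy of
the SSA2 mitochondrial sequence, and three individuals are planted
inter-specific hybrids.  Writes FASTA/VCF/TSV inputs plus truth tables
under results/sim/.
"""

from pathlib import Path

from bemisia_delim import io as bio_io
from bemisia_delim.sim import simulate_study_mimic

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mimic = simulate_study_mimic(seed=SEED, n_loci=3000)

    bio_io.write_fasta(mimic.barcodes, OUT / "barcodes.fasta")
    bio_io.write_fasta([mimic.reference], OUT / "reference.fasta")
    bio_io.write_fasta(mimic.panel, OUT / "panel.fasta")
    bio_io.write_vcf(mimic.genotypes, OUT / "genotypes.vcf")
    bio_io.write_popmap(mimic.popmap, OUT / "popmap.tsv")
    with open(OUT / "barcode_truth.tsv", "w") as fh:
        fh.write("barcode_id\tindividual\torigin\n")
        for bid, ind in mimic.barcode_individual.items():
            fh.write(f"{bid}\t{ind}\t{mimic.mtcoi_truth[bid]}\n")
    with open(OUT / "planted.tsv", "w") as fh:
        fh.write("individual\trole\n")
        for ind in mimic.hybrid_ids:
            fh.write(f"{ind}\tinter_specific_hybrid\n")
        for ind in mimic.numt_individual_ids:
            fh.write(f"{ind}\tnumt_barcode_carrier\n")

    n_numt = sum(1 for v in mimic.mtcoi_truth.values() if v == "NUMT")
    print(f"seed {SEED}: wrote {mimic.genotypes.n_individuals} individuals x "
          f"{mimic.genotypes.n_loci} SNPs, {len(mimic.barcodes)} barcodes "
          f"({n_numt} NUMTs), {len(mimic.hybrid_ids)} planted hybrids -> {OUT}")


if __name__ == "__main__":
    main()
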