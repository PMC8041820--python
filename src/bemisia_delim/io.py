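"""Readers and writers for the pipeline's interchange formats.

FASTA via Bio.SeqIO (headers may carry ``|species=LABEL`` metadata), VCF
via cyvcf2 (biallelic SNPs only; multiallelic and indel records are
counted and dropped), and TSV for everything tabular (tab-separated, no
quoting, UTF-8, '.' for missing).  VCF coordinates are 1-based as standard;
internal locus indexing is 0-based half-open.  All writers emit files in a
deterministic byte order so reruns under the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .curation import HaplotypeSet, NucSequence, PseudogeneReport, SpeciesCall
from .sim import MISSING
from .structure import AncestryModel, CvReport, GenotypeMatrix, PcaResult, PopulationMap

log = logging.getLogger("bemisia_delim")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, on_invalid: str = "map_to_n") -> list[NucSequence]:
    """Read (possibly wrapped) FASTA records.

    Duplicate ids are rejected.  ``|species=LABEL`` in a header populates
    the taxon field.  Characters outside {A,C,G,T,N} are mapped to N by
    default or rejected with ``on_invalid='error'``.
    """
    records: list[NucSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        taxon = None
        if "|" in rec.description:
            for part in rec.description.split("|")[1:]:
                if part.startswith("species="):
                    taxon = part[len("species="):].strip()
        rid = header.split("|")[0]
        if rid in seen:
            raise ValueError(f"duplicate FASTA id {rid!r} in {path}")
        seen.add(rid)
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            if on_invalid == "error":
                raise ValueError(f"record {rid!r} has invalid characters {sorted(bad)}")
            for ch in bad:
                seq = seq.replace(ch, "N")
        records.append(NucSequence(rid, seq, taxon=taxon))
    if not records:
        log.warning("no records read from %s", path)
    return records


def write_fasta(records: list[NucSequence], path: str | Path, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if rec.taxon is None else f"{rec.id}|species={rec.taxon}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path, ploidy: int = 2) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Biallelic-SNP dosage matrix from a VCF with GT calls.

    Multiallelic and non-SNP records are dropped with counts; missing calls
    ('./.' or '.') become the missing sentinel; phased separators are
    accepted.  Returns (matrix, dropped-record counts).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} has no samples")
    rows: list[np.ndarray] = []
    locus_ids: list[str] = []
    dropped = {"multiallelic": 0, "non_snp": 0}
    for rec in vcf:
        if len(rec.ALT) != 1:
            dropped["multiallelic"] += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            dropped["non_snp"] += 1
            continue
        dos = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            alleles = [a for a in gt[:-1] if a != -2][:ploidy]
            if any(a < 0 for a in alleles) or len(alleles) < ploidy:
                dos[i] = MISSING
            else:
                dos[i] = sum(alleles)
        rows.append(dos)
        locus_ids.append(f"{rec.CHROM}:{rec.POS}")
    if not rows:
        raise ValueError(f"no biallelic SNPs retained from {path}")
    matrix = GenotypeMatrix(
        np.vstack(rows).T, samples, locus_ids, ploidy=ploidy
    )
    return matrix, dropped


def write_vcf(matrix: GenotypeMatrix, path: str | Path, chrom: str = "sim1") -> None:
    """Minimal biallelic-SNP VCF (GT only, A>G placeholder alleles)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.individual_ids)
            + "\n"
        )
        for l in range(matrix.n_loci):
            fields = [chrom, str(l + 1), matrix.locus_ids[l], "A", "G", ".", "PASS", ".", "GT"]
            for g in matrix.dosages[:, l]:
                if g == MISSING:
                    fields.append("./." if matrix.ploidy == 2 else ".")
                elif matrix.ploidy == 2:
                    fields.append(["0/0", "0/1", "1/1"][g])
                else:
                    fields.append(str(int(g)))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# TSV tables


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tpopulation\n")
        for ind, pop in popmap.population_of.items():
            fh.write(f"{ind}\t{pop}\n")


def read_popmap(path: str | Path) -> PopulationMap:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("individual"):
            raise ValueError(f"popmap {path} must have an 'individual<TAB>population' header")
        for line in fh:
            if not line.strip():
                continue
            ind, pop = line.rstrip("\n").split("\t")
            mapping[ind] = pop
    return PopulationMap(mapping)


def write_dosage_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Individuals x loci dosage table; '.' marks a missing call."""
    with open(path, "w") as fh:
        fh.write("individual\t" + "\t".join(matrix.locus_ids) + "\n")
        for i, ind in enumerate(matrix.individual_ids):
            row = [
                "." if g == MISSING else str(int(g)) for g in matrix.dosages[i]
            ]
            fh.write(ind + "\t" + "\t".join(row) + "\n")


def read_dosage_tsv(path: str | Path, ploidy: int = 2) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "individual":
            raise ValueError(f"dosage table {path} must start with an 'individual' column")
        locus_ids = header[1:]
        ids, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([MISSING if v == "." else int(v) for v in parts[1:]])
    return GenotypeMatrix(np.array(rows, dtype=np.int8), ids, locus_ids, ploidy)


def write_truth_labels_tsv(truth_origin: dict[str, str], source: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\torigin\tsource_haplotype\n")
        for rid in truth_origin:
            fh.write(f"{rid}\t{truth_origin[rid]}\t{source.get(rid, '.')}\n")


def write_pseudogene_reports_tsv(reports: list[PseudogeneReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tn_indels\tframeshift\tn_stops\tn_deviations\tverdict\treasons\n")
        for r in reports:
            fh.write(
                f"{r.sequence_id}\t{len(r.indels)}\t{str(r.frameshift).lower()}\t"
                f"{len(r.premature_stops)}\t{len(r.conserved_deviations)}\t"
                f"{r.verdict}\t{','.join(r.reasons) or '.'}\n"
            )


def write_haplotypes_tsv(hs: HaplotypeSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("representative\tn_members\tmembers\n")
        for rep, members in hs.groups:
            fh.write(f"{rep}\t{len(members)}\t{','.join(members)}\n")


def write_species_calls_tsv(calls: dict[str, SpeciesCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tspecies\tnearest_reference\tdistance\treliable\n")
        for qid, c in calls.items():
            fh.write(
                f"{qid}\t{c.species}\t{c.nearest_id}\t{c.distance:.6f}\t"
                f"{str(c.reliable).lower()}\n"
            )


def write_fst_matrix_tsv(theta: np.ndarray, pops: list[str], path) -> None:
    """Lower-triangular pairwise theta table in the popmap's label order."""
    with open(path, "w") as fh:
        fh.write("population\t" + "\t".join(pops[:-1]) + "\n")
        for i in range(1, len(pops)):
            vals = [f"{theta[i, j]:.6f}" for j in range(i)]
            fh.write(pops[i] + "\t" + "\t".join(vals) + "\n")


def write_pca_tsv(res: PcaResult, path) -> None:
    k = res.coordinates.shape[1]
    with open(path, "w") as fh:
        fh.write("individual\t" + "\t".join(f"PC{i + 1}" for i in range(k)) + "\n")
        for i, ind in enumerate(res.individual_ids):
            fh.write(ind + "\t" + "\t".join(f"{v:.6f}" for v in res.coordinates[i]) + "\n")


def write_q_tsv(model: AncestryModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\t" + "\t".join(f"Q{k + 1}" for k in range(model.K)) + "\n")
        for i, ind in enumerate(model.individual_ids):
            fh.write(ind + "\t" + "\t".join(f"{v:.6f}" for v in model.Q[i]) + "\n")


def write_p_tsv(model: AncestryModel, locus_ids: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\t" + "\t".join(f"P{k + 1}" for k in range(model.K)) + "\n")
        for l, lid in enumerate(locus_ids):
            fh.write(lid + "\t" + "\t".join(f"{model.P[k, l]:.6f}" for k in range(model.K)) + "\n")


def write_cv_tsv(report: CvReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("K\tmean_error\tsd_error\tchosen\n")
        for k, m, s in zip(report.k_values, report.mean_error, report.sd_error):
            fh.write(f"{k}\t{m:.6f}\t{s:.6f}\t{'*' if k == report.chosen_k else '.'}\n")


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def file_checksum(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def ensure_outdir(outdir: str | Path) -> Path:
    p = Path(outdir)
    os.makedirs(p, exist_ok=True)
    return p
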