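"""End-to-end driver: curate -> structure -> ancestry -> integrate.

``run_pipeline`` executes the whole species-delimitation analysis on real
inputs (FASTA barcodes + VCF genotypes + popmap) or on the built-in
synthetic study mimic, writing every stage's table plus a JSON summary.
All randomness flows from the single configured seed, so a rerun with the
same configuration is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

from . import io as bio_io
from .curation import (
    NucSequence,
    assign_mtcoi_species,
    build_conservation_profile,
    collapse_haplotypes,
    screen_sequence,
    translate,
)
from .delimit import (
    ClusterSpeciesMap,
    classify_hybrids,
    derive_cluster_species_map,
    integrate_assignments,
)
from .sim import simulate_study_mimic
from .structure import admixture_em, choose_k_cv, nj_tree, pairwise_fst_matrix, pca_genotypes

log = logging.getLogger("bemisia_delim")


@dataclass
class PipelineConfig:
    """Every tunable of the integrated analysis, with its default."""

    seed: int = 0
    outdir: str = "pipeline_out"
    simulate: bool = False
    n_loci: int = 3000  # simulate mode only
    # curation
    queries: str | None = None
    reference: str | None = None
    panel: str | None = None
    code: int = 5
    frame: int = 0
    min_conservation: float = 1.0
    max_distance: float = 0.035
    min_query_length: int = 100
    # nuclear inputs
    vcf: str | None = None
    popmap: str | None = None
    ploidy: int = 2
    # structure
    k_min: int = 1
    k_max: int = 5
    cv_folds: int = 3
    cv_mask_fraction: float = 0.1
    cv_restarts: int = 1
    n_restarts: int = 10
    em_tol: float = 1e-6
    em_max_iter: int = 2000
    # delimitation
    tau: float = 0.10

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat key=value config file; unknown keys are rejected."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                default = getattr(cls(), key)
                if isinstance(default, bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    kwargs[key] = int(value)
                elif isinstance(default, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)


def _stage(name: str):
    """Tag stage errors so failures name the stage that raised them."""

    class _Ctx:
        def __enter__(self):
            log.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also written).

    Stages: barcode curation and species diagnosis; pairwise Fst; PCA;
    cross-validated choice of K; ancestry model; cluster-to-species
    anchoring; hybrid classification; cytonuclear integration.
    """
    outdir = bio_io.ensure_outdir(config.outdir)
    rng = np.random.default_rng(config.seed)
    sub_seeds = rng.integers(0, 2**31, size=8)
    log.info("effective config: %s", config)

    with _stage("inputs"):
        if config.simulate:
            mimic = simulate_study_mimic(seed=config.seed, n_loci=config.n_loci)
            queries = mimic.barcodes
            reference = mimic.reference
            panel = mimic.panel
            matrix = mimic.genotypes
            popmap = mimic.popmap
            barcode_of = {v: k for k, v in mimic.barcode_individual.items()}
        else:
            for name in ("queries", "reference", "panel", "vcf", "popmap"):
                if getattr(config, name) is None:
                    raise ValueError(f"missing required input: --{name}")
                if not Path(getattr(config, name)).exists():
                    raise FileNotFoundError(
                        f"{name} file not found: {getattr(config, name)}"
                    )
            queries = bio_io.read_fasta(config.queries)
            reference = bio_io.read_fasta(config.reference)[0]
            panel = bio_io.read_fasta(config.panel)
            matrix, dropped = bio_io.read_vcf(config.vcf, ploidy=config.ploidy)
            log.info("VCF records dropped: %s", dropped)
            popmap = bio_io.read_popmap(config.popmap)
            # barcode id convention: query id == individual id, or 'bc_<ind>'
            barcode_of = {}
            for q in queries:
                ind = q.id[3:] if q.id.startswith("bc_") else q.id
                if ind in matrix.individual_ids:
                    barcode_of[ind] = q.id

    with _stage("curation"):
        profile = build_conservation_profile(
            [translate(p.residues, frame=config.frame, code=config.code) for p in panel]
        )
        reports = {}
        for q in queries:
            reports[q.id] = screen_sequence(
                q,
                reference,
                profile=profile,
                min_conservation=config.min_conservation,
                code=config.code,
                frame=config.frame,
                min_query_length=config.min_query_length,
            )
        species_calls = {
            q.id: assign_mtcoi_species(
                q,
                panel,
                max_distance=config.max_distance,
                verdict=reports[q.id].verdict,
                allow_numt=True,
            )
            for q in queries
        }
        clean = [q for q in queries if reports[q.id].verdict == "plausible_mtDNA"]
        haplotypes = collapse_haplotypes(clean) if clean else None
        bio_io.write_pseudogene_reports_tsv(
            sorted(reports.values(), key=lambda r: r.sequence_id),
            outdir / "pseudogene_reports.tsv",
        )
        bio_io.write_species_calls_tsv(
            dict(sorted(species_calls.items())), outdir / "mtcoi_species.tsv"
        )
        if haplotypes:
            bio_io.write_haplotypes_tsv(haplotypes, outdir / "haplotypes.tsv")

    with _stage("fst"):
        theta, pops = pairwise_fst_matrix(matrix, popmap)
        bio_io.write_fst_matrix_tsv(theta, pops, outdir / "fst_matrix.tsv")

    with _stage("pca"):
        pca = pca_genotypes(matrix)
        bio_io.write_pca_tsv(pca, outdir / "pca_coordinates.tsv")

    with _stage("choose-k"):
        cv = choose_k_cv(
            matrix,
            list(range(config.k_min, config.k_max + 1)),
            mask_fraction=config.cv_mask_fraction,
            n_folds=config.cv_folds,
            seed=int(sub_seeds[0]),
            n_restarts=config.cv_restarts,
        )
        bio_io.write_cv_tsv(cv, outdir / "cv_report.tsv")

    with _stage("ancestry"):
        model = admixture_em(
            matrix,
            cv.chosen_k,
            seed=int(sub_seeds[1]),
            tol=config.em_tol,
            max_iter=config.em_max_iter,
            n_restarts=config.n_restarts,
        )
        bio_io.write_q_tsv(model, outdir / "ancestry_Q.tsv")
        bio_io.write_p_tsv(model, matrix.locus_ids, outdir / "ancestry_P.tsv")

    with _stage("tree"):
        newick = nj_tree(matrix, popmap)
        (outdir / "nj_tree.nwk").write_text(newick + "\n")

    with _stage("integration"):
        mt_species = {}
        mt_verdicts = {}
        for ind in matrix.individual_ids:
            bid = barcode_of.get(ind)
            if bid is None:
                continue
            mt_species[ind] = species_calls[bid].species
            mt_verdicts[ind] = reports[bid].verdict
        cluster_map = derive_cluster_species_map(model, mt_species, mt_verdicts)
        hybrids = classify_hybrids(model, cluster_map, tau=config.tau)
        assignments = integrate_assignments(hybrids, cluster_map, mt_species, mt_verdicts)
        with open(outdir / "hybrids.tsv", "w") as fh:
            fh.write("individual\tmajor_cluster\tmajor_fraction\tcall\ttau\n")
            for h in hybrids:
                fh.write(
                    f"{h.individual_id}\t{h.major_cluster}\t{h.major_fraction:.6f}\t"
                    f"{h.call}\t{h.tau}\n"
                )
        with open(outdir / "assignments.tsv", "w") as fh:
            fh.write("individual\tmtcoi_species\tnuclear_species\tfinal\tconcordance\n")
            for a in assignments:
                fh.write(
                    f"{a.individual_id}\t{a.mtcoi_species}\t{a.nuclear_species}\t"
                    f"{a.final}\t{a.concordance}\n"
                )

    verdict_counts: dict[str, int] = {}
    for a in assignments:
        verdict_counts[a.concordance] = verdict_counts.get(a.concordance, 0) + 1
    call_counts: dict[str, int] = {}
    for h in hybrids:
        call_counts[h.call] = call_counts.get(h.call, 0) + 1
    summary = {
        "seed": config.seed,
        "n_individuals": matrix.n_individuals,
        "n_loci": matrix.n_loci,
        "n_barcodes": len(queries),
        "n_numt_suspects": sum(
            1 for r in reports.values() if r.verdict == "NUMT_suspect"
        ),
        "n_unique_haplotypes": haplotypes.n_unique if haplotypes else 0,
        "chosen_k": cv.chosen_k,
        "cluster_species_map": {str(k): v for k, v in cluster_map.labels.items()},
        "hybrid_call_counts": dict(sorted(call_counts.items())),
        "concordance_counts": dict(sorted(verdict_counts.items())),
        "inter_specific_hybrids": sorted(
            h.individual_id for h in hybrids if h.call == "inter_specific_hybrid"
        ),
        "pairwise_fst": {
            f"{pops[i]}|{pops[j]}": round(float(theta[i, j]), 6)
            for i in range(len(pops))
            for j in range(i + 1, len(pops))
        },
        "tau": config.tau,
        "outputs": sorted(
            {p.name for p in outdir.iterdir() if p.is_file()} | {"summary.json"}
        ),
    }
    bio_io.write_json(summary, outdir / "summary.json")
    return summary
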