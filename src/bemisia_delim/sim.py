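"""Synthetic data with the statistical structure the analyses assume.

Two generators:

* an mtCOI barcode panel: clean species haplotypes evolved from a stop-free
  ancestral coding sequence, plus NUMT copies mutated without coding
  constraint (extra substitutions and indels) — the contamination scenario
  that produces spurious "species" in barcode surveys;
* a structured genotype matrix under the Balding–Nichols model: per-locus
  ancestral allele frequencies, per-cluster frequencies drawn from a Beta
  distribution parameterised by a differentiation parameter F, binomial
  genotypes, optionally admixed individuals drawn from Q-weighted mixture
  frequencies.

Both are deterministic given their seed, and both return truth labels so
every downstream stage can be scored against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curation import AlignedPair, NucSequence, detect_indels, translate

MISSING = -1  # sentinel dosage for a missing genotype call

_BASES = "ACGT"


@dataclass
class MtCoiSimConfig:
    """Parameters of the barcode + NUMT panel generator.

    Defaults emulate a 657 bp partial mtCOI barcode region with a few
    percent divergence between cryptic species, sub-percent within-species
    variation, and NUMT copies carrying both substitutions and short indels
    (lengths 1-3, mixing frameshifting and in-frame events).
    """

    region_length: int = 657
    n_species: int = 3
    n_haplotypes_per_species: int = 5
    interspecies_divergence: float = 0.08
    intraspecies_divergence: float = 0.01
    numt_fraction: float = 0.3
    numt_sub_rate: float = 0.05
    numt_indel_rate: float = 0.01
    indel_length_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.25, 3: 0.15}
    )
    code: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "interspecies_divergence",
            "intraspecies_divergence",
            "numt_fraction",
            "numt_sub_rate",
            "numt_indel_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.interspecies_divergence > 0.75 or self.intraspecies_divergence > 0.75:
            raise ValueError(
                "divergence > 0.75 cannot be realised by random substitution"
            )
        if self.region_length < 3:
            raise ValueError("region_length must be >= 3")
        if self.n_species < 1 or self.n_haplotypes_per_species < 1:
            raise ValueError("need >= 1 species and >= 1 haplotype per species")
        if self.numt_fraction >= 1.0 and self.numt_fraction != 0.0:
            raise ValueError("numt_fraction must be < 1")
        probs = self.indel_length_distribution
        if not probs or any(l < 1 for l in probs) or any(p < 0 for p in probs.values()):
            raise ValueError("invalid indel length distribution")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("indel length probabilities must sum to 1")


@dataclass
class PopSimConfig:
    """Parameters of the Balding–Nichols structured-genotype generator."""

    n_clusters: int = 3
    F_per_cluster: tuple[float, ...] = (0.4, 0.12, 0.15)
    n_individuals_per_cluster: tuple[int, ...] = (8, 34, 12)
    n_loci: int = 3000
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    n_admixed: int = 0
    admixed_Q_truth: tuple[tuple[float, ...], ...] = ()
    admixed_pop_labels: tuple[str, ...] = ()
    missing_rate: float = 0.0
    ploidy: int = 2
    seed: int = 0

    def validate(self) -> None:
        K = self.n_clusters
        if K < 1:
            raise ValueError("need >= 1 cluster")
        if len(self.F_per_cluster) != K or len(self.n_individuals_per_cluster) != K:
            raise ValueError("per-cluster parameter lengths must equal n_clusters")
        for f in self.F_per_cluster:
            if not 0.0 <= f < 1.0:
                raise ValueError(f"F={f} outside [0, 1); F=1 is a degenerate Beta")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate outside [0, 1]")
        if self.missing_rate >= 1.0:
            raise ValueError("missing_rate=1 leaves no callable genotypes")
        if self.n_admixed != len(self.admixed_Q_truth):
            raise ValueError("need one Q row per admixed individual")
        for row in self.admixed_Q_truth:
            if len(row) != K:
                raise ValueError("admixed Q rows must have n_clusters entries")
            if abs(sum(row) - 1.0) > 1e-9 or any(q < 0 for q in row):
                raise ValueError("admixed Q rows must be non-negative and sum to 1")
        if self.admixed_pop_labels and len(self.admixed_pop_labels) != self.n_admixed:
            raise ValueError("need one population label per admixed individual")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral_freq_range must satisfy 0 < lo < hi < 1")


@dataclass
class MtCoiTruth:
    """Per-record ground truth for a simulated barcode panel."""

    origin: dict[str, str]  # record id -> "mtDNA" | "NUMT"
    source_haplotype: dict[str, str]  # record id -> progenitor haplotype id
    species: dict[str, str]  # record id -> species of the progenitor
    true_alignment: dict[str, AlignedPair]  # NUMT id -> planted alignment vs progenitor
    frameshift: dict[str, bool]  # NUMT id -> planted frameshift status
    premature_stop: dict[str, bool]  # NUMT id -> internal stop in realised frame


@dataclass
class PopTruth:
    """Per-individual ground truth for a simulated genotype matrix."""

    cluster: dict[str, int | None]  # individual -> source cluster (None if admixed)
    Q: np.ndarray  # individuals x K true ancestry proportions


# ---------------------------------------------------------------------------
# mtCOI panel


def _random_stopfree_cds(rng: np.random.Generator, length: int, code: int) -> str:
    """Random coding sequence of ``length`` nt with no internal stop in frame 0."""
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[code]
    codons = sorted(set(table.forward_table) - set(table.stop_codons))
    n_codons = length // 3
    seq = "".join(codons[i] for i in rng.integers(0, len(codons), size=n_codons))
    # pad the trailing partial codon (never translated) with random bases
    seq += "".join(_BASES[i] for i in rng.integers(0, 4, size=length - 3 * n_codons))
    return seq


def _substitute(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    avoid_stops: bool,
    code: int,
    max_tries: int = 200,
) -> str:
    """Apply ~rate substitutions/site uniformly (Jukes–Cantor-like).

    With ``avoid_stops`` each substitution is rejection-sampled so the
    frame-0 translation stays internally stop-free (truth labels for clean
    mtDNA records must be clean by construction).
    """
    n_sub = rng.binomial(len(seq), rate)
    bases = list(seq)
    positions = rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False)
    for pos in positions:
        for _ in range(max_tries):
            new = _BASES[rng.integers(0, 4)]
            if new == bases[pos]:
                continue
            old = bases[pos]
            bases[pos] = new
            if not avoid_stops:
                break
            prot = translate("".join(bases), frame=0, code=code)
            if "*" not in prot[:-1]:
                break
            bases[pos] = old
        else:
            raise ValueError(
                "could not place a stop-free substitution; divergence too high"
            )
    return "".join(bases)


def _substitute_synonymous(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    code: int,
    max_tries: int = 400,
) -> str:
    """Apply ~rate synonymous substitutions/site.

    Within-species mtCOI variation is overwhelmingly synonymous (purifying
    selection on the protein), so clean intra-species haplotypes should
    differ at silent sites; positions are rejection-sampled until the
    translation is unchanged.
    """
    n_sub = rng.binomial(len(seq), rate)
    bases = list(seq)
    prot = translate("".join(bases), frame=0, code=code)
    placed = 0
    tries = 0
    while placed < n_sub and tries < max_tries * (n_sub + 1):
        tries += 1
        pos = int(rng.integers(0, len(bases)))
        new = _BASES[rng.integers(0, 4)]
        if new == bases[pos]:
            continue
        old = bases[pos]
        bases[pos] = new
        if translate("".join(bases), frame=0, code=code) == prot:
            placed += 1
        else:
            bases[pos] = old
    return "".join(bases)


def _apply_indels(
    rng: np.random.Generator,
    seq: str,
    indel_rate: float,
    length_dist: dict[int, float],
) -> tuple[str, AlignedPair]:
    """Plant indels and return (mutated sequence, true alignment vs input)."""
    n_indels = rng.binomial(len(seq), indel_rate)
    # identity alignment as mutable columns: (query_char, ref_char)
    cols = [[c, c] for c in seq]
    lengths = sorted(length_dist)
    probs = np.array([length_dist[l] for l in lengths])
    for _ in range(n_indels):
        length = int(rng.choice(lengths, p=probs))
        kind = "deletion" if rng.random() < 0.5 else "insertion"
        ref_cols = [i for i, (q, r) in enumerate(cols) if r != "-"]
        if kind == "deletion":
            if len(ref_cols) <= length:
                continue
            start = int(rng.integers(0, len(ref_cols) - length + 1))
            for i in ref_cols[start : start + length]:
                cols[i][0] = "-"
        else:
            at = int(rng.integers(0, len(ref_cols) + 1))
            col_at = ref_cols[at] if at < len(ref_cols) else len(cols)
            ins = [[_BASES[rng.integers(0, 4)], "-"] for _ in range(length)]
            cols[col_at:col_at] = ins
    # a base both deleted and never inserted-over leaves q='-', r=base: fine;
    # drop columns where a deletion hit an inserted column (q and r both '-')
    cols = [c for c in cols if not (c[0] == "-" and c[1] == "-")]
    query = "".join(q for q, _ in cols if q != "-")
    pair = AlignedPair(
        query_row="".join(q for q, _ in cols),
        reference_row="".join(r for _, r in cols),
        frame=0,
    )
    return query, pair


def simulate_mtcoi_panel(
    config: MtCoiSimConfig,
) -> tuple[list[NucSequence], MtCoiTruth]:
    """Generate species haplotypes and NUMT copies with truth labels.

    True-mtDNA records translate internally stop-free in frame 0 by
    construction.  NUMT records are copies of a random haplotype mutated at
    ``numt_sub_rate``/``numt_indel_rate`` with no coding constraint; the
    planted alignment is kept so detector calls can be scored exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ancestral = _random_stopfree_cds(rng, config.region_length, config.code)

    records: list[NucSequence] = []
    origin: dict[str, str] = {}
    source: dict[str, str] = {}
    species_of: dict[str, str] = {}
    for s in range(config.n_species):
        sp = f"SSA{s + 1}"
        sp_ancestor = _substitute(
            rng, ancestral, config.interspecies_divergence, True, config.code
        )
        for h in range(config.n_haplotypes_per_species):
            hap = _substitute(
                rng, sp_ancestor, config.intraspecies_divergence, True, config.code
            )
            rid = f"{sp}_h{h + 1}"
            records.append(NucSequence(rid, hap, taxon=sp))
            origin[rid] = "mtDNA"
            source[rid] = rid
            species_of[rid] = sp

    n_clean = len(records)
    f = config.numt_fraction
    n_numt = int(round(f * n_clean / (1.0 - f))) if f > 0 else 0
    true_aln: dict[str, AlignedPair] = {}
    fs_truth: dict[str, bool] = {}
    stop_truth: dict[str, bool] = {}
    clean = list(records)
    for j in range(n_numt):
        src = clean[rng.integers(0, n_clean)]
        mutated = _substitute(rng, src.residues, config.numt_sub_rate, False, config.code)
        final, pair = _apply_indels(
            rng, mutated, config.numt_indel_rate, config.indel_length_distribution
        )
        rid = f"NUMT_{j + 1}"
        records.append(NucSequence(rid, final))
        origin[rid] = "NUMT"
        source[rid] = src.id
        species_of[rid] = src.taxon
        true_aln[rid] = pair
        _, fs = detect_indels(pair)
        fs_truth[rid] = fs
        prot = translate(final, frame=0, code=config.code)
        stop_truth[rid] = "*" in prot[:-1]

    truth = MtCoiTruth(
        origin=origin,
        source_haplotype=source,
        species=species_of,
        true_alignment=true_aln,
        frameshift=fs_truth,
        premature_stop=stop_truth,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Balding–Nichols genotypes


def simulate_genotypes_bn(config: PopSimConfig):
    """Structured genotypes under the Balding–Nichols model.

    Per locus an ancestral frequency p is drawn uniformly on the configured
    range; cluster k's frequency comes from Beta(p(1-F_k)/F_k,
    (1-p)(1-F_k)/F_k) (equal to p when F_k = 0); genotypes are binomial with
    ``ploidy`` trials.  Admixed individuals draw from their Q-weighted
    mixture frequency.  Missing calls are planted uniformly at random.

    Returns (GenotypeMatrix, PopulationMap, PopTruth); imported lazily from
    :mod:`.structure` to keep module dependencies one-way.
    """
    from .structure import GenotypeMatrix, PopulationMap

    config.validate()
    rng = np.random.default_rng(config.seed)
    K = config.n_clusters
    L = config.n_loci
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=L)

    P = np.empty((K, L))
    for k, F in enumerate(config.F_per_cluster):
        if F == 0.0:
            P[k] = p_anc
        else:
            ratio = (1.0 - F) / F
            P[k] = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio)
    P = np.clip(P, 1e-12, 1.0 - 1e-12)

    ids: list[str] = []
    pops: list[str] = []
    clusters: list[int | None] = []
    Q_rows: list[np.ndarray] = []
    freq_rows: list[np.ndarray] = []
    for k, n_k in enumerate(config.n_individuals_per_cluster):
        for i in range(n_k):
            ids.append(f"c{k + 1}_{i + 1:02d}")
            pops.append(f"pop{k + 1}")
            clusters.append(k)
            q = np.zeros(K)
            q[k] = 1.0
            Q_rows.append(q)
            freq_rows.append(P[k])
    for j, qrow in enumerate(config.admixed_Q_truth):
        q = np.asarray(qrow, dtype=float)
        ids.append(f"adm_{j + 1:02d}")
        pops.append(
            config.admixed_pop_labels[j] if config.admixed_pop_labels else "admixed"
        )
        clusters.append(None)
        Q_rows.append(q)
        freq_rows.append(q @ P)

    freqs = np.vstack(freq_rows)  # N x L individual-level alt-allele frequencies
    G = rng.binomial(config.ploidy, freqs).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(G.shape) < config.missing_rate
        G[mask] = MISSING

    matrix = GenotypeMatrix(
        dosages=G,
        individual_ids=ids,
        locus_ids=[f"L{l + 1}" for l in range(L)],
        ploidy=config.ploidy,
    )
    popmap = PopulationMap(dict(zip(ids, pops)))
    truth = PopTruth(cluster=dict(zip(ids, clusters)), Q=np.vstack(Q_rows))
    return matrix, popmap, truth


# ---------------------------------------------------------------------------
# the default study mimic


@dataclass
class StudyMimic:
    """The default synthetic stand-in for the 62-individual study design."""

    genotypes: object  # GenotypeMatrix
    popmap: object  # PopulationMap
    pop_truth: PopTruth
    barcodes: list[NucSequence]  # one per individual that has a barcode
    barcode_individual: dict[str, str]  # barcode id -> individual id
    reference: NucSequence  # alignment/translation reference (clean mtCOI)
    panel: list[NucSequence]  # species-labelled diagnosis panel
    mtcoi_truth: dict[str, str]  # barcode id -> "mtDNA" | "NUMT"
    hybrid_ids: list[str]  # planted inter-specific hybrid individuals
    numt_individual_ids: list[str]  # individuals carrying NUMT barcodes
    cluster_species: dict[int, str]  # true cluster index -> species label


def default_mimic_config(seed: int = 0, n_loci: int = 3000) -> PopSimConfig:
    """62 individuals in the study's population layout.

    Three ancestral clusters (SSA2-like, SSA1-NW, SSA1-SE) with
    differentiation F = (0.40, 0.12, 0.15): the species-level split is much
    deeper than the within-SSA1 sub-clusters, as in the observed pairwise
    Fst pattern.  Populations: 10 SSA2/SSA4 (two of them SSA2 x SSA1-NW
    hybrids), 34 SSA1-NW, 12 SSA1-SE, and 6 contact-zone SSA-CA individuals
    with mixed SSA1-NW/SSA1-SE ancestry (one also carrying an SSA2
    component — the three-way hybrid).
    """
    admixed_Q = (
        # five contact-zone individuals, balanced NW/SE ancestry
        (0.0, 0.5, 0.5),
        (0.0, 0.5, 0.5),
        (0.0, 0.5, 0.5),
        (0.0, 0.5, 0.5),
        (0.0, 0.5, 0.5),
        # three-way contact-zone hybrid with an SSA2 component
        (0.15, 0.35, 0.5),
        # two SSA2 x SSA1-NW inter-specific hybrids
        (0.70, 0.30, 0.0),
        (0.80, 0.20, 0.0),
    )
    labels = ("SSA-CA",) * 6 + ("SSA2/SSA4",) * 2
    return PopSimConfig(
        n_clusters=3,
        F_per_cluster=(0.40, 0.12, 0.15),
        n_individuals_per_cluster=(8, 34, 12),
        n_loci=n_loci,
        n_admixed=8,
        admixed_Q_truth=admixed_Q,
        admixed_pop_labels=labels,
        missing_rate=0.05,
        ploidy=2,
        seed=seed,
    )


def simulate_study_mimic(seed: int = 0, n_loci: int = 3000) -> StudyMimic:
    """Generate the full cytonuclear study mimic.

    Nuclear side: :func:`default_mimic_config`.  Barcode side: each
    individual carries one mtCOI record from its species; five SSA2
    individuals instead carry NUMT barcodes descended from a divergent
    nuclear copy of the SSA2 mitochondrial sequence ("SSA4"), each planted
    with a frameshifting indel — the misleading barcodes that created the
    spurious SSA4 species.  The diagnosis panel carries SSA1, SSA2 and the
    SSA4 NUMT progenitor, so NUMT barcodes diagnose as SSA4 while their
    nuclear genomes cluster with SSA2.
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31, size=4)

    pop_cfg = default_mimic_config(seed=int(sub_seeds[0]), n_loci=n_loci)
    genotypes, popmap, pop_truth = simulate_genotypes_bn(pop_cfg)
    # rename individuals to study-style ids
    new_ids = []
    k_counts = {"SSA2/SSA4": 0, "pop2": 0, "pop3": 0, "SSA-CA": 0}
    rename = {"pop1": "SSA2/SSA4", "pop2": "SSA1-NW", "pop3": "SSA1-SE"}
    pops = {}
    for ind in genotypes.individual_ids:
        pop = popmap.population_of[ind]
        pop = rename.get(pop, pop)
        tag = {"SSA2/SSA4": "ssa2", "SSA1-NW": "nw", "SSA1-SE": "se", "SSA-CA": "ca"}[pop]
        k_counts.setdefault(pop, 0)
        k_counts[pop] += 1
        nid = f"{tag}_{k_counts[pop]:02d}"
        new_ids.append(nid)
        pops[nid] = pop
    id_map = dict(zip(genotypes.individual_ids, new_ids))
    genotypes.individual_ids = new_ids
    popmap.population_of = pops
    pop_truth.cluster = {id_map[i]: c for i, c in pop_truth.cluster.items()}
    hybrid_ids = [id_map[f"adm_{j:02d}"] for j in (6, 7, 8)]

    # barcode side: 2 species (SSA1, SSA2) with enough haplotype diversity
    mt_rng = np.random.default_rng(int(sub_seeds[1]))
    code = 5
    ancestral = _random_stopfree_cds(mt_rng, 657, code)
    ssa1_ref = _substitute(mt_rng, ancestral, 0.04, True, code)
    ssa2_ref = _substitute(mt_rng, ancestral, 0.04, True, code)
    # the SSA4 NUMT progenitor: an old nuclear copy of the SSA2 barcode
    ssa4_progenitor = _substitute(mt_rng, ssa2_ref, 0.06, False, code)
    reference = NucSequence("REF_SSA1", ssa1_ref, taxon="SSA1")
    panel = [
        NucSequence("PANEL_SSA1", ssa1_ref, taxon="SSA1"),
        NucSequence("PANEL_SSA2", ssa2_ref, taxon="SSA2"),
        NucSequence("PANEL_SSA4", ssa4_progenitor, taxon="SSA4"),
    ]

    barcodes: list[NucSequence] = []
    barcode_individual: dict[str, str] = {}
    mtcoi_truth: dict[str, str] = {}
    numt_carriers: list[str] = []
    ssa2_inds = [i for i in new_ids if pops[i] == "SSA2/SSA4"]
    numt_set = set(ssa2_inds[:3] + hybrid_ids[1:])  # 3 pure SSA2 + both SSA2 hybrids
    for ind in new_ids:
        pop = pops[ind]
        bid = f"bc_{ind}"
        if ind in numt_set:
            # NUMT barcode: progenitor + recent substitutions + a 1 nt indel
            seq = _substitute(mt_rng, ssa4_progenitor, 0.005, False, code)
            final, _ = _apply_indels(mt_rng, seq, 0.0, {1: 1.0})
            # force exactly one frameshifting deletion at a random position
            pos = int(mt_rng.integers(30, len(final) - 30))
            final = final[:pos] + final[pos + 1 :]
            barcodes.append(NucSequence(bid, final))
            mtcoi_truth[bid] = "NUMT"
            numt_carriers.append(ind)
        else:
            base = ssa2_ref if pop == "SSA2/SSA4" else ssa1_ref
            seq = _substitute_synonymous(mt_rng, base, 0.004, code)
            barcodes.append(NucSequence(bid, seq))
            mtcoi_truth[bid] = "mtDNA"
        barcode_individual[bid] = ind

    return StudyMimic(
        genotypes=genotypes,
        popmap=popmap,
        pop_truth=pop_truth,
        barcodes=barcodes,
        barcode_individual=barcode_individual,
        reference=reference,
        panel=panel,
        mtcoi_truth=mtcoi_truth,
        hybrid_ids=hybrid_ids,
        numt_individual_ids=numt_carriers,
        cluster_species={0: "SSA2", 1: "SSA1-NW", 2: "SSA1-SE"},
    )
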