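"""Cytonuclear integration: species verdicts, NUMT resolution, hybrid calls.

The barcode marker and the genome-wide SNP clusters can disagree for two
very different reasons: a NUMT barcode (a pseudogene masquerading as a
divergent species — the "SSA4" case, which nuclear data places inside
SSA2), or genuine cytonuclear discordance.  This module keeps the two
apart: a barcode verdict is only overridden when there is positive NUMT
evidence; a plausible-but-discordant barcode is flagged, never silently
corrected.  It also classifies admixed individuals into within-species
introgression versus inter-specific hybrids from their ancestry vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import AncestryModel


def species_of(label: str) -> str:
    """Species-level component of a cluster label (e.g. 'SSA1-NW' -> 'SSA1')."""
    return label.split("-")[0].split("/")[0]


@dataclass
class ClusterSpeciesMap:
    """Ancestry cluster index -> species/sub-species label; total over K."""

    labels: dict[int, str]

    def check_total(self, K: int) -> None:
        missing = [k for k in range(K) if k not in self.labels]
        if missing:
            raise ValueError(f"clusters missing from species map: {missing}")

    def label(self, k: int) -> str:
        if k not in self.labels:
            raise ValueError(f"cluster {k} missing from species map")
        return self.labels[k]


@dataclass
class HybridCall:
    individual_id: str
    major_cluster: int
    major_fraction: float
    minor_fractions: dict[int, float]
    call: str  # "pure" | "intra_specific_admixed" | "inter_specific_hybrid"
    tau: float


@dataclass
class SpeciesAssignment:
    individual_id: str
    mtcoi_species: str  # species label | "NUMT_invalidated(<label>)" | "absent"
    nuclear_species: str
    final: str
    concordance: str  # concordant | resolved_numt | cytonuclear_discordant | nuclear_only


def classify_hybrids(
    model: AncestryModel,
    cluster_map: ClusterSpeciesMap,
    tau: float = 0.10,
) -> list[HybridCall]:
    """Per-individual hybrid status from ancestry fractions.

    pure: all minor fractions < tau.  inter_specific_hybrid: some minor
    fraction >= tau belongs to a cluster of a different species than the
    major cluster.  Otherwise intra_specific_admixed (introgression between
    sub-clusters of one species).
    """
    if not 0.0 < tau <= 0.5:
        raise ValueError("tau must be in (0, 0.5]")
    cluster_map.check_total(model.K)
    calls = []
    for i, ind in enumerate(model.individual_ids):
        q = model.Q[i]
        major = int(np.argmax(q))
        minors = {k: float(q[k]) for k in range(model.K) if k != major}
        major_sp = species_of(cluster_map.label(major))
        big_minors = [k for k, f in minors.items() if f >= tau]
        if not big_minors:
            call = "pure"
        elif any(species_of(cluster_map.label(k)) != major_sp for k in big_minors):
            call = "inter_specific_hybrid"
        else:
            call = "intra_specific_admixed"
        calls.append(
            HybridCall(
                individual_id=ind,
                major_cluster=major,
                major_fraction=float(q[major]),
                minor_fractions=minors,
                call=call,
                tau=tau,
            )
        )
    return calls


def integrate_assignments(
    hybrid_calls: list[HybridCall],
    cluster_map: ClusterSpeciesMap,
    mtcoi_species: dict[str, str] | None = None,
    mtcoi_verdicts: dict[str, str] | None = None,
) -> list[SpeciesAssignment]:
    """Reconcile barcode diagnoses with nuclear cluster assignments.

    Per individual with nuclear data: (a) agreement -> concordant; (b)
    barcode flagged NUMT_suspect and disagreeing -> the nuclear species
    stands, concordance resolved_numt; (c) plausible barcode disagreeing ->
    nuclear species with a cytonuclear_discordant flag; (d) no barcode ->
    nuclear_only.  Species are compared at species level, so an SSA1
    barcode agrees with either SSA1 sub-cluster.
    """
    mtcoi_species = mtcoi_species or {}
    mtcoi_verdicts = mtcoi_verdicts or {}
    out = []
    for call in hybrid_calls:
        ind = call.individual_id
        nuclear_label = cluster_map.label(call.major_cluster)
        nuclear_sp = species_of(nuclear_label)
        mt_sp = mtcoi_species.get(ind)
        verdict = mtcoi_verdicts.get(ind)
        if mt_sp is None:
            out.append(
                SpeciesAssignment(ind, "absent", nuclear_label, nuclear_label, "nuclear_only")
            )
            continue
        if species_of(mt_sp) == nuclear_sp:
            concordance = "concordant"
            mt_field = mt_sp
        elif verdict == "NUMT_suspect":
            concordance = "resolved_numt"
            mt_field = f"NUMT_invalidated({mt_sp})"
        else:
            concordance = "cytonuclear_discordant"
            mt_field = mt_sp
        out.append(
            SpeciesAssignment(ind, mt_field, nuclear_label, nuclear_label, concordance)
        )
    return out


def derive_cluster_species_map(
    model: AncestryModel,
    mtcoi_species: dict[str, str],
    mtcoi_verdicts: dict[str, str],
) -> ClusterSpeciesMap:
    """Anchor nuclear clusters to species by majority vote of reliable barcodes.

    Each individual with a plausible (non-NUMT) barcode votes its barcode
    species for its major cluster.  Clusters sharing a species vote are
    disambiguated with a deterministic sub-cluster suffix; a cluster with
    no votes is labelled 'cluster<k>'.
    """
    votes: dict[int, dict[str, int]] = {k: {} for k in range(model.K)}
    for i, ind in enumerate(model.individual_ids):
        sp = mtcoi_species.get(ind)
        if sp is None or sp in ("unassigned", "ambiguous"):
            continue
        if mtcoi_verdicts.get(ind) == "NUMT_suspect":
            continue
        major = int(np.argmax(model.Q[i]))
        votes[major][sp] = votes[major].get(sp, 0) + 1
    labels: dict[int, str] = {}
    for k in range(model.K):
        if votes[k]:
            labels[k] = max(sorted(votes[k]), key=lambda s: votes[k][s])
        else:
            labels[k] = f"cluster{k}"
    # disambiguate clusters that share a species label
    by_label: dict[str, list[int]] = {}
    for k, lab in labels.items():
        by_label.setdefault(lab, []).append(k)
    for lab, ks in by_label.items():
        if len(ks) > 1:
            for j, k in enumerate(sorted(ks), start=1):
                labels[k] = f"{lab}-{j}"
    return ClusterSpeciesMap(labels)
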