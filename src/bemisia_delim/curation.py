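"""mtCOI barcode integrity screening and species diagnosis.

Nuclear copies of mitochondrial genes (NUMTs) evolve free of coding
constraint and accumulate indels, premature stop codons and substitutions at
otherwise conserved residues.  When a PCR primer pair amplifies a NUMT
instead of the true mitochondrial cytochrome oxidase I (mtCOI) locus, the
resulting "barcode" can be misdiagnosed as a distinct species.  This module
screens partial mtCOI sequences against a trusted reference for the three
classic pseudogene signatures:

(i)   indels, in particular those that shift the reading frame;
(ii)  premature stop codons in the conceptual translation;
(iii) amino-acid replacements at residues conserved across a reference panel.

It also provides haplotype collapsing, pairwise p-distance, and
nearest-reference species assignment for sequences that pass the screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner
from Bio.Data import CodonTable

VALID_BASES = set("ACGTN")
GAP = "-"

CRITERION_INDEL_FRAMESHIFT = "INDEL_FRAMESHIFT"
CRITERION_PREMATURE_STOP = "PREMATURE_STOP"
CRITERION_CONSERVED_DEVIATION = "CONSERVED_DEVIATION"


@dataclass
class NucSequence:
    """A nucleotide sequence over {A,C,G,T,N} with an optional taxon label."""

    id: str
    residues: str
    taxon: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        self.residues = self.residues.upper()
        bad = set(self.residues) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignedPair:
    """A gapped global alignment of a query against a reference.

    Rows are equal-length strings over {A,C,G,T,N,-}; ``frame`` is the
    reference reading-frame offset (0, 1 or 2).
    """

    query_row: str
    reference_row: str
    frame: int = 0
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.query_row) != len(self.reference_row):
            raise ValueError("alignment rows differ in length")
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")
        for q, r in zip(self.query_row, self.reference_row):
            if q == GAP and r == GAP:
                raise ValueError("column gapped in both rows")


@dataclass
class IndelEvent:
    """A maximal gap run, positioned on the ungapped reference (1-based).

    For deletions ``position`` is the first deleted reference base; for
    insertions it is the reference base immediately preceding the inserted
    run (0 if the insertion precedes the reference).
    """

    position: int
    length: int
    kind: str  # "insertion" | "deletion"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"unknown indel kind {self.kind!r}")


@dataclass
class ConservationProfile:
    """Per-column residue frequencies over a reference protein panel.

    ``conservation[j]`` is the maximum residue frequency in column j, or
    ``None`` for uninformative (all-gap) columns.
    """

    frequencies: list[dict[str, float]]
    conservation: list[float | None]
    n_reference_sequences: int

    def __len__(self) -> int:
        return len(self.conservation)


@dataclass
class PseudogeneReport:
    sequence_id: str
    indels: list[IndelEvent] = field(default_factory=list)
    frameshift: bool = False
    premature_stops: list[int] = field(default_factory=list)
    conserved_deviations: list[tuple] = field(default_factory=list)
    verdict: str = "plausible_mtDNA"
    reasons: list[str] = field(default_factory=list)


@dataclass
class HaplotypeSet:
    """Partition of input sequences into exact-match haplotype groups."""

    groups: list[tuple[str, list[str]]]  # (representative id, member ids)
    n_input: int
    n_unique: int


@dataclass
class SpeciesCall:
    species: str  # label | "unassigned" | "ambiguous"
    nearest_id: str
    distance: float
    reliable: bool = True


# ---------------------------------------------------------------------------
# alignment


def align_to_reference(
    query: NucSequence,
    reference: NucSequence,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = 5.0,
    gap_extend: float = 1.0,
    min_query_length: int = 100,
    frame: int = 0,
) -> AlignedPair:
    """Globally align a query barcode to the reference with affine gaps.

    ``gap_open`` is the cost of the first gapped position and ``gap_extend``
    of each subsequent one (both positive costs).  The first optimal
    alignment reported by the aligner is returned, which is deterministic.
    Queries shorter than ``min_query_length`` are refused: fragments too
    short to place reliably produce spurious pseudogene signatures.
    """
    if len(query) < min_query_length:
        raise ValueError(
            f"fragment too short: query {query.id!r} has {len(query)} nt "
            f"(< {min_query_length})"
        )
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(reference.residues, query.residues)[0]
    return AlignedPair(
        query_row=str(aln[1]),
        reference_row=str(aln[0]),
        frame=frame,
        score=float(aln.score),
    )


# ---------------------------------------------------------------------------
# criterion (i): indels and frameshifts


def detect_indels(pair: AlignedPair) -> tuple[list[IndelEvent], bool]:
    """Report maximal gap runs and whether any codon boundary is shifted.

    The query is frameshifted if the cumulative signed indel length
    (insertions positive, deletions negative) is not a multiple of three at
    any reference codon boundary downstream of an indel, or at the end of
    the alignment.
    """
    events: list[IndelEvent] = []
    frameshift = False
    shift = 0  # cumulative signed indel length
    ref_pos = 0  # ungapped reference bases consumed
    run_kind: str | None = None
    run_len = 0
    run_start = 0

    def close_run() -> None:
        nonlocal run_kind, run_len
        if run_kind is not None:
            events.append(IndelEvent(position=run_start, length=run_len, kind=run_kind))
            run_kind = None
            run_len = 0

    for q, r in zip(pair.query_row, pair.reference_row):
        if q == GAP:  # deletion relative to reference
            if run_kind != "deletion":
                close_run()
                run_kind = "deletion"
                run_start = ref_pos + 1
            run_len += 1
            shift -= 1
            ref_pos += 1
        elif r == GAP:  # insertion relative to reference
            if run_kind != "insertion":
                close_run()
                run_kind = "insertion"
                run_start = ref_pos
            run_len += 1
            shift += 1
        else:
            close_run()
            ref_pos += 1
        # codon boundary on the reference frame grid
        if r != GAP and ref_pos > pair.frame and (ref_pos - pair.frame) % 3 == 0:
            if shift % 3 != 0:
                frameshift = True
    close_run()
    if shift % 3 != 0:
        frameshift = True
    return events, frameshift


# ---------------------------------------------------------------------------
# criterion (ii): translation and premature stops


def translate(seq: str, frame: int = 0, code: int = 5) -> str:
    """Translate a (possibly gapped) nucleotide string.

    Gaps are stripped first.  The default genetic code is NCBI table 5
    (invertebrate mitochondrial), under which AGA/AGG encode serine and TGA
    tryptophan.  Codons containing N translate to 'X'; stops render '*';
    the trailing partial codon is ignored.
    """
    try:
        table = CodonTable.unambiguous_dna_by_id[code]
    except KeyError:
        raise ValueError(f"unknown genetic code table id {code}") from None
    s = seq.replace(GAP, "").upper()[frame:]
    out = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in table.stop_codons:
            out.append("*")
        else:
            out.append(table.forward_table[codon])
    return "".join(out)


def detect_premature_stops(protein: str, terminal_window: int = 1) -> list[int]:
    """1-based codon indices of '*' strictly before the last ``terminal_window`` residues.

    A stop at the very end of the amplicon is legitimate (the barcode may
    run up to the gene's terminus); internal stops are pseudogene evidence.
    """
    cutoff = len(protein) - terminal_window
    return [i + 1 for i, aa in enumerate(protein) if aa == "*" and i < cutoff]


# ---------------------------------------------------------------------------
# criterion (iii): conserved-residue deviations


def build_conservation_profile(reference_proteins: list[str]) -> ConservationProfile:
    """Column-wise residue frequencies across aligned reference proteins.

    Conservation per column is the maximum residue frequency over non-gap
    entries; columns with only gaps are uninformative and never flag.
    """
    if len(reference_proteins) < 2:
        raise ValueError("need >= 2 reference proteins for a conservation profile")
    lengths = {len(p) for p in reference_proteins}
    if len(lengths) != 1:
        raise ValueError("reference proteins must have equal aligned length")
    ncol = lengths.pop()
    freqs: list[dict[str, float]] = []
    cons: list[float | None] = []
    for j in range(ncol):
        counts: dict[str, int] = {}
        for p in reference_proteins:
            aa = p[j]
            if aa != GAP:
                counts[aa] = counts.get(aa, 0) + 1
        total = sum(counts.values())
        if total == 0:
            freqs.append({})
            cons.append(None)
        else:
            f = {aa: c / total for aa, c in counts.items()}
            freqs.append(f)
            cons.append(max(f.values()))
    return ConservationProfile(
        frequencies=freqs, conservation=cons, n_reference_sequences=len(reference_proteins)
    )


def score_conserved_deviations(
    query_protein: str,
    profile: ConservationProfile,
    min_conservation: float = 1.0,
) -> list[tuple]:
    """Residue replacements at columns conserved at >= ``min_conservation``.

    Returns tuples (1-based column, expected residue set, observed residue,
    conservation).  Gap and 'X' query residues never flag.
    """
    if len(query_protein) != len(profile):
        raise ValueError(
            f"query protein length {len(query_protein)} != profile length {len(profile)}"
        )
    out = []
    for j, aa in enumerate(query_protein):
        c = profile.conservation[j]
        if c is None or c < min_conservation:
            continue
        if aa in (GAP, "X"):
            continue
        observed = set(profile.frequencies[j])
        if aa not in observed:
            out.append((j + 1, frozenset(observed), aa, c))
    return out


# ---------------------------------------------------------------------------
# verdict


def classify_sequence(
    sequence_id: str,
    indels: list[IndelEvent],
    frameshift: bool,
    premature_stops: list[int],
    conserved_deviations: list[tuple],
    min_deviations: int = 1,
) -> PseudogeneReport:
    """Combine the three pseudogene criteria into a verdict.

    NUMT_suspect iff a frameshift, any premature stop, or at least
    ``min_deviations`` conserved-residue deviations is present.
    """
    reasons = []
    if frameshift:
        reasons.append(CRITERION_INDEL_FRAMESHIFT)
    if premature_stops:
        reasons.append(CRITERION_PREMATURE_STOP)
    if len(conserved_deviations) >= min_deviations:
        reasons.append(CRITERION_CONSERVED_DEVIATION)
    return PseudogeneReport(
        sequence_id=sequence_id,
        indels=indels,
        frameshift=frameshift,
        premature_stops=premature_stops,
        conserved_deviations=conserved_deviations,
        verdict="NUMT_suspect" if reasons else "plausible_mtDNA",
        reasons=reasons,
    )


def project_query_codons(pair: AlignedPair) -> str:
    """Query residues in reference-codon coordinates.

    For each reference codon (on the frame grid) the query bases occupying
    those alignment columns are translated; insertions are skipped and any
    deleted base renders the codon as '-'.  This yields a query protein row
    directly comparable to a profile built on the same reference.
    """
    codon: list[str] = []
    ref_pos = 0
    out = []
    for q, r in zip(pair.query_row, pair.reference_row):
        if r == GAP:
            continue  # insertion: not a reference coordinate
        ref_pos += 1
        if ref_pos <= pair.frame:
            continue
        codon.append(q)
        if len(codon) == 3:
            if GAP in codon:
                out.append(GAP)
            else:
                out.append(translate("".join(codon)))
            codon = []
    return "".join(out)


def screen_sequence(
    query: NucSequence,
    reference: NucSequence,
    profile: ConservationProfile | None = None,
    min_conservation: float = 1.0,
    min_deviations: int = 1,
    terminal_window: int = 1,
    code: int = 5,
    frame: int = 0,
    min_query_length: int = 100,
) -> PseudogeneReport:
    """Run the full pseudogene screen for one query against the reference.

    The reference must itself translate stop-free in the configured frame;
    otherwise the frame is wrong and every verdict would be meaningless.
    """
    ref_protein = translate(reference.residues, frame=frame, code=code)
    if detect_premature_stops(ref_protein, terminal_window):
        raise ValueError(
            "reference translates with internal stops in the configured frame; "
            "check --frame/--code"
        )
    pair = align_to_reference(
        query, reference, frame=frame, min_query_length=min_query_length
    )
    indels, frameshift = detect_indels(pair)
    # translate the query itself, on the reference codon grid from where it
    # first aligns, so frameshifted downstream stops are visible
    qrow = pair.query_row
    rrow = pair.reference_row
    lead_ref = 0
    for q, r in zip(qrow, rrow):
        if q != GAP:
            break
        if r != GAP:
            lead_ref += 1
    offset = (3 - (lead_ref - frame) % 3) % 3
    protein = translate(qrow, frame=offset, code=code)
    stops = detect_premature_stops(protein, terminal_window)
    deviations: list[tuple] = []
    if profile is not None:
        projected = project_query_codons(pair)
        deviations = score_conserved_deviations(projected, profile, min_conservation)
    return classify_sequence(query.id, indels, frameshift, stops, deviations, min_deviations)


# ---------------------------------------------------------------------------
# haplotypes and distances


def collapse_haplotypes(
    sequences: list[NucSequence],
    window: tuple[int, int] | None = None,
    n_is_wildcard: bool = False,
) -> HaplotypeSet:
    """Group sequences identical over a common coordinate window.

    ``window`` is a 0-based half-open slice; by default the mutual overlap
    of all inputs (``[0, min length)``) is used.  With ``n_is_wildcard`` an
    N matches anything (greedy grouping in input order, so the relation need
    not be transitive); otherwise N is an ordinary mismatch.
    """
    if not sequences:
        raise ValueError("no sequences to collapse")
    if window is None:
        window = (0, min(len(s) for s in sequences))
    start, end = window
    if not 0 <= start < end:
        raise ValueError(f"invalid window {window}")
    trimmed = [(s.id, s.residues[start:end]) for s in sequences]

    def matches(a: str, b: str) -> bool:
        if not n_is_wildcard:
            return a == b
        return all(x == y or x == "N" or y == "N" for x, y in zip(a, b))

    groups: list[tuple[str, str, list[str]]] = []  # (rep id, rep seq, members)
    for sid, seq in trimmed:
        for i, (rep_id, rep_seq, members) in enumerate(groups):
            if matches(seq, rep_seq):
                members.append(sid)
                break
        else:
            groups.append((sid, seq, [sid]))
    return HaplotypeSet(
        groups=[(rep_id, members) for rep_id, _, members in groups],
        n_input=len(sequences),
        n_unique=len(groups),
    )


def p_distance(
    a: NucSequence | str,
    b: NucSequence | str,
    aligned: bool = False,
) -> tuple[int, int, float]:
    """Proportion of differing nucleotides over comparable aligned sites.

    Sites with a gap or N in either row are excluded.  With ``aligned`` the
    two strings are used column-by-column as given; otherwise the pair is
    globally aligned first.
    """
    sa = a.residues if isinstance(a, NucSequence) else a.upper()
    sb = b.residues if isinstance(b, NucSequence) else b.upper()
    if aligned:
        if len(sa) != len(sb):
            raise ValueError("pre-aligned rows differ in length")
        rows = (sa, sb)
    else:
        qa = a if isinstance(a, NucSequence) else NucSequence("a", sa)
        qb = b if isinstance(b, NucSequence) else NucSequence("b", sb)
        pair = align_to_reference(qa, qb, min_query_length=1)
        rows = (pair.query_row, pair.reference_row)
    ndiff = ncomp = 0
    for x, y in zip(*rows):
        if x in (GAP, "N") or y in (GAP, "N"):
            continue
        ncomp += 1
        if x != y:
            ndiff += 1
    if ncomp == 0:
        raise ValueError("no comparable sites between the two sequences")
    return ndiff, ncomp, ndiff / ncomp


def assign_mtcoi_species(
    query: NucSequence,
    panel: list[NucSequence],
    max_distance: float = 0.035,
    verdict: str | None = None,
    allow_numt: bool = False,
) -> SpeciesCall:
    """Nearest-reference species diagnosis by p-distance.

    The query is assigned the species of its nearest labelled reference if
    the distance is at most ``max_distance`` (default 0.035, the whitefly
    mtCOI species-boundary convention); ties between different species give
    "ambiguous", and distances beyond the cutoff "unassigned".  Queries
    flagged as NUMT suspects are refused unless ``allow_numt``, in which
    case the call is marked unreliable.
    """
    if not panel:
        raise ValueError("empty reference panel")
    reliable = True
    if verdict == "NUMT_suspect":
        if not allow_numt:
            raise ValueError(
                f"query {query.id!r} is a NUMT suspect; pass allow_numt=True to "
                "diagnose anyway (result will be marked unreliable)"
            )
        reliable = False
    dists = []
    for ref in panel:
        if ref.taxon is None:
            raise ValueError(f"panel sequence {ref.id!r} lacks a species label")
        _, _, d = p_distance(query, ref)
        dists.append((d, ref))
    dmin = min(d for d, _ in dists)
    nearest = [(d, ref) for d, ref in dists if math.isclose(d, dmin, abs_tol=1e-12)]
    species = {ref.taxon for _, ref in nearest}
    _, nearest_ref = nearest[0]
    if dmin > max_distance:
        label = "unassigned"
    elif len(species) > 1:
        label = "ambiguous"
    else:
        label = nearest_ref.taxon
    return SpeciesCall(
        species=label, nearest_id=nearest_ref.id, distance=dmin, reliable=reliable
    )
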