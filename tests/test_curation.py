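"""mtCOI pseudogene screen: alignment, indels, translation, verdicts."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bemisia_delim.curation import (
    AlignedPair,
    NucSequence,
    align_to_reference,
    assign_mtcoi_species,
    build_conservation_profile,
    classify_sequence,
    collapse_haplotypes,
    detect_indels,
    detect_premature_stops,
    p_distance,
    score_conserved_deviations,
    screen_sequence,
    translate,
)

# ---------------------------------------------------------------------------
# alignment


def brute_force_align(a: str, b: str, match=2.0, mismatch=-1.0, open_=5.0, ext=1.0):
    """Independent three-state global alignment DP, coded with plain loops.

    Affine gap cost = open_ for the first gapped position of a run, ext for
    each subsequent one.  Returns the optimal score only; written apart
    from the production aligner as an oracle for its scores.
    """
    NEG = -1e18
    n, m = len(a), len(b)
    # M[i][j]: best ending in a match/mismatch; X: gap in b (a consumed); Y: gap in a
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(open_ + (i - 1) * ext)
    for j in range(1, m + 1):
        Y[0][j] = -(open_ + (j - 1) * ext)
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = match if a[i - 1] == b[j - 1] else mismatch
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            if i > 0 and j >= 0 and not (i == 1 and j == 0):
                X[i][j] = max(
                    X[i][j],
                    M[i - 1][j] - open_ if M[i - 1][j] > NEG else NEG,
                    X[i - 1][j] - ext if X[i - 1][j] > NEG else NEG,
                    Y[i - 1][j] - open_ if Y[i - 1][j] > NEG else NEG,
                )
            if j > 0 and i >= 0 and not (j == 1 and i == 0):
                Y[i][j] = max(
                    Y[i][j],
                    M[i][j - 1] - open_ if M[i][j - 1] > NEG else NEG,
                    Y[i][j - 1] - ext if Y[i][j - 1] > NEG else NEG,
                    X[i][j - 1] - open_ if X[i][j - 1] > NEG else NEG,
                )
    return max(M[n][m], X[n][m], Y[n][m])


def test_identity_alignment_is_gap_free():
    ref = NucSequence("r", "ATGACGTTACGA")
    pair = align_to_reference(ref, ref, min_query_length=1)
    assert pair.query_row == pair.reference_row == ref.residues


@pytest.mark.parametrize("del_at", [0, 3, 7, 11])
def test_single_deletion_recovered_and_score_optimal(del_at):
    ref = "ATGACGTTACGA"
    query = ref[:del_at] + ref[del_at + 1 :]
    pair = align_to_reference(
        NucSequence("q", query), NucSequence("r", ref), min_query_length=1
    )
    events, frameshift = detect_indels(pair)
    assert [(e.kind, e.length) for e in events] == [("deletion", 1)]
    assert frameshift
    assert pair.score == pytest.approx(brute_force_align(ref, query))


def test_random_short_pairs_match_bruteforce_score():
    import random

    rng = random.Random(0)
    for _ in range(15):
        ref = "".join(rng.choice("ACGT") for _ in range(rng.randint(6, 10)))
        query = "".join(rng.choice("ACGT") for _ in range(rng.randint(6, 10)))
        pair = align_to_reference(
            NucSequence("q", query), NucSequence("r", ref), min_query_length=1
        )
        assert pair.score == pytest.approx(brute_force_align(ref, query))


def test_short_fragment_refused():
    with pytest.raises(ValueError, match="fragment too short"):
        align_to_reference(NucSequence("q", "ACGT"), NucSequence("r", "ACGT" * 50))


def test_empty_query_rejected_at_construction():
    with pytest.raises(ValueError):
        NucSequence("q", "")


# ---------------------------------------------------------------------------
# indels / frameshift


def test_gap_free_pair_has_no_events():
    pair = AlignedPair("ACGTAC", "ACGTAC")
    assert detect_indels(pair) == ([], False)


def test_in_frame_deletion_is_not_a_frameshift():
    # codon-aligned 3 nt deletion
    pair = AlignedPair("ATG---ACGTAA", "ATGAAAACGTAA")
    events, frameshift = detect_indels(pair)
    assert [(e.kind, e.length, e.position) for e in events] == [("deletion", 3, 4)]
    assert not frameshift


def test_single_nt_deletion_shifts_frame():
    pair = AlignedPair("ATG-AAACGTAA", "ATGAAAACGTAA")
    events, frameshift = detect_indels(pair)
    assert len(events) == 1 and events[0].length == 1
    assert frameshift


def test_compensating_indels_shift_frame_only_in_between():
    # +1 insertion then -1 deletion: out of frame across the middle codons
    pair = AlignedPair("ATGTAAACGT-ACGA", "ATG-AAACGTAACGA")
    events, frameshift = detect_indels(pair)
    assert len(events) == 2
    assert frameshift


# ---------------------------------------------------------------------------
# translation (invertebrate mitochondrial code, NCBI table 5)


@pytest.mark.parametrize(
    "codon,expected",
    [("ATG", "M"), ("AGA", "S"), ("TGA", "W"), ("TAA", "*"), ("ANG", "X")],
)
def test_table5_codon_facts(codon, expected):
    assert translate(codon, frame=0, code=5) == expected


def test_translation_strips_gaps_and_partial_codon():
    assert translate("AT-GAC-GA", 0, 5) == translate("ATGACGA", 0, 5)
    assert translate("ATGAC", 0, 5) == "M"


def test_unknown_code_table_rejected():
    with pytest.raises(ValueError, match="unknown genetic code"):
        translate("ATG", 0, code=999)


def test_premature_stop_positions():
    assert detect_premature_stops("MSTW" * 10) == []
    protein = "M" + "A" * 48 + "*" + "A" * 168 + "*"
    assert detect_premature_stops(protein) == [50]
    assert detect_premature_stops("MAA*", terminal_window=1) == []


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=3, max_size=120))
def test_stop_free_translation_roundtrip(seq):
    """Any sequence without internal stops yields no premature-stop calls."""
    protein = translate(seq, 0, 5)
    if "*" not in protein[:-1]:
        assert detect_premature_stops(protein) == []


# ---------------------------------------------------------------------------
# conservation profile


def test_identical_references_fully_conserved():
    profile = build_conservation_profile(["MSTW", "MSTW", "MSTW"])
    assert profile.conservation == [1.0, 1.0, 1.0, 1.0]


def test_split_column_half_conserved():
    profile = build_conservation_profile(["MA", "MV"])
    assert profile.conservation == [1.0, 0.5]


def test_all_gap_column_uninformative_and_never_flags():
    profile = build_conservation_profile(["M-T", "M-T"])
    assert profile.conservation[1] is None
    # the uninformative column never flags, even with a residue present
    assert score_conserved_deviations("MAT", profile, min_conservation=1.0) == []


def test_deviation_at_fully_conserved_column():
    profile = build_conservation_profile(["MSTW", "MSTW"])
    devs = score_conserved_deviations("MSAW", profile)
    assert len(devs) == 1 and devs[0][0] == 3 and devs[0][2] == "A"
    assert score_conserved_deviations("MSTW", profile) == []


def test_low_conservation_column_does_not_flag_below_threshold():
    profile = build_conservation_profile(["MA", "MV"])
    assert score_conserved_deviations("MW", profile, min_conservation=0.95) == []


def test_profile_needs_two_references_and_equal_lengths():
    with pytest.raises(ValueError):
        build_conservation_profile(["MSTW"])
    with pytest.raises(ValueError):
        build_conservation_profile(["MSTW", "MST"])


def test_length_mismatch_with_profile_rejected():
    profile = build_conservation_profile(["MSTW", "MSTW"])
    with pytest.raises(ValueError):
        score_conserved_deviations("MST", profile)


# ---------------------------------------------------------------------------
# verdicts


def test_frameshift_alone_gives_numt_verdict():
    report = classify_sequence("x", [], True, [], [])
    assert report.verdict == "NUMT_suspect"
    assert report.reasons == ["INDEL_FRAMESHIFT"]


def test_single_conserved_deviation_gives_numt_verdict():
    report = classify_sequence("x", [], False, [], [(10, frozenset("L"), "P", 1.0)])
    assert report.verdict == "NUMT_suspect"
    assert report.reasons == ["CONSERVED_DEVIATION"]


def test_clean_sequence_is_plausible():
    report = classify_sequence("x", [], False, [], [])
    assert report.verdict == "plausible_mtDNA"
    assert report.reasons == []


def test_screen_refuses_reference_with_internal_stops():
    bad_ref = NucSequence("r", "ATGTAA" + "ATG" * 40)  # stop at codon 2
    q = NucSequence("q", "ATG" * 41)
    with pytest.raises(ValueError, match="internal stops"):
        screen_sequence(q, bad_ref, min_query_length=1)


# ---------------------------------------------------------------------------
# haplotypes


def test_identical_sequences_collapse_to_one():
    seqs = [NucSequence(f"s{i}", "ACGTACGT") for i in range(3)]
    hs = collapse_haplotypes(seqs)
    assert hs.n_unique == 1 and hs.groups[0][1] == ["s0", "s1", "s2"]


def test_twenty_five_records_eleven_haplotypes():
    """25 records over 11 distinct residue strings collapse to 11 groups."""
    base = "ACGTACGTACGTACGTACGT"
    swap = {"A": "T", "C": "G", "G": "C", "T": "A"}
    variants = [base[:i] + swap[base[i]] + base[i + 1 :] for i in range(11)]
    members = [variants[i % 11] for i in range(25)]
    seqs = [NucSequence(f"s{i}", m) for i, m in enumerate(members)]
    hs = collapse_haplotypes(seqs)
    assert hs.n_input == 25 and hs.n_unique == 11
    # the groups partition the input
    all_members = sorted(m for _, ms in hs.groups for m in ms)
    assert all_members == sorted(s.id for s in seqs)


def test_n_wildcard_vs_mismatch_modes():
    a = NucSequence("a", "ACGTACGT")
    b = NucSequence("b", "ACGTACGN")
    assert collapse_haplotypes([a, b], n_is_wildcard=True).n_unique == 1
    assert collapse_haplotypes([a, b], n_is_wildcard=False).n_unique == 2


def test_collapse_empty_input_rejected():
    with pytest.raises(ValueError):
        collapse_haplotypes([])


# ---------------------------------------------------------------------------
# p-distance


def test_p_distance_identical_is_zero():
    a = NucSequence("a", "ACGTACGTACGTACG")
    n, L, p = p_distance(a, a)
    assert (n, L, p) == (0, 15, 0.0)


def test_p_distance_three_mismatches_over_536_sites():
    """Three substitutions over 536 compared sites give 0.56% difference."""
    import random

    rng = random.Random(1)
    a = "".join(rng.choice("ACGT") for _ in range(536))
    b = list(a)
    for pos in (10, 200, 400):
        b[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[pos]]
    n, L, p = p_distance(a, "".join(b), aligned=True)
    assert (n, L) == (3, 536)
    assert p == pytest.approx(0.005597, abs=1e-6)


def test_p_distance_excludes_gap_and_n_columns():
    n, L, p = p_distance("AC-TN", "ACGTA", aligned=True)
    assert (n, L, p) == (0, 3, 0.0)


def test_p_distance_no_comparable_sites_is_error():
    with pytest.raises(ValueError, match="comparable"):
        p_distance("NNNN", "ACGT", aligned=True)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.text(alphabet="ACGTN", min_size=10, max_size=40),
    st.text(alphabet="ACGTN", min_size=10, max_size=40),
)
def test_p_distance_symmetric_and_bounded(a, b):
    L = min(len(a), len(b))
    a, b = a[:L], b[:L]
    try:
        n1, c1, p1 = p_distance(a, b, aligned=True)
        n2, c2, p2 = p_distance(b, a, aligned=True)
    except ValueError:
        return  # no comparable sites
    assert (n1, c1, p1) == (n2, c2, p2)
    assert 0.0 <= p1 <= 1.0
    # independent column count
    direct = sum(
        1 for x, y in zip(a, b) if "N" not in (x, y) and x != y
    )
    assert n1 == direct


# ---------------------------------------------------------------------------
# species assignment


def _panel():
    return [
        NucSequence("ref1", "ATGACGTTACGAATGACGTTACGAATGACGTTACGA" * 3, taxon="SSA1"),
        NucSequence("ref2", "ATGACGTTACGAATGACGTTACGAATGACGTTACGA".replace("ACG", "GCA") * 3, taxon="SSA2"),
    ]


def test_identical_query_assigned_at_distance_zero():
    panel = _panel()
    q = NucSequence("q", panel[0].residues)
    call = assign_mtcoi_species(q, panel)
    assert call.species == "SSA1" and call.distance == 0.0 and call.reliable


def test_distant_query_unassigned():
    panel = _panel()
    q = NucSequence("q", panel[0].residues)
    call = assign_mtcoi_species(q, panel, max_distance=0.035)
    assert call.species == "SSA1"
    far = NucSequence(
        "far", "".join({"A": "C", "C": "G", "G": "T", "T": "A"}[c] for c in panel[0].residues)
    )
    assert assign_mtcoi_species(far, panel).species == "unassigned"


def test_equidistant_between_species_is_ambiguous():
    a = "ATGACGTTACGA" * 9
    panel = [
        NucSequence("r1", a, taxon="SSA1"),
        NucSequence("r2", a, taxon="SSA2"),
    ]
    call = assign_mtcoi_species(NucSequence("q", a), panel)
    assert call.species == "ambiguous"


def test_numt_suspect_query_needs_override():
    panel = _panel()
    q = NucSequence("q", panel[0].residues)
    with pytest.raises(ValueError, match="NUMT suspect"):
        assign_mtcoi_species(q, panel, verdict="NUMT_suspect")
    call = assign_mtcoi_species(q, panel, verdict="NUMT_suspect", allow_numt=True)
    assert not call.reliable


def test_empty_panel_rejected():
    with pytest.raises(ValueError, match="empty"):
        assign_mtcoi_species(NucSequence("q", "ACGT" * 30), [])
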