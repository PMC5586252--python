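"""Window finding, N-score arithmetic, anchor classes and Plk1 prediction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from b56tools.errors import FormatError, ParameterError
from b56tools.motif import (
    B56_CONSENSUS,
    FLANK_POSITIONS,
    MotifPattern,
    anchor_class,
    classify_window,
    find_motif_windows,
    predict_plk1_sites,
    scan_sequence,
    score_window,
)
from b56tools.sequences import parse_phospho

AA = "ACDEFGHIKLMNPQRSTVWY"


# --- independent oracle: literal per-window constraint check -----------------

def brute_force_windows(residues, phospho=frozenset()):
    """Re-derives consensus matches from the constraint definitions alone."""
    hits = []
    for i in range(len(residues) - 8):
        w = residues[i : i + 9]
        if any(c in "BJOUXZ" for c in w):
            continue
        flagged = {p - i for p in phospho if i + 1 <= p <= i + 9}  # 1-based in window
        if (
            w[0] in "LMFI" and 1 not in flagged
            and w[3] in "ILV" and 4 not in flagged
            and w[5] == "E" and 6 not in flagged
        ):
            hits.append((i + 1, w))
    return hits


sequences = st.text(alphabet=AA + "X", min_size=0, max_size=60)


@settings(max_examples=300, derandomize=True)
@given(sequences)
def test_find_windows_matches_brute_force(seq):
    assert find_motif_windows(seq) == brute_force_windows(seq)


def test_phospho_marks_block_constrained_positions():
    # pS at position 6 of an otherwise perfect frame must not pass
    assert find_motif_windows("LAAIApSAAA") == []
    # same window with E at 6 passes, and a flank pS counts toward numST
    matches = scan_sequence("x", "LpSAIAEAAA")
    assert len(matches) == 1
    assert matches[0].numST == 1 and matches[0].phospho_positions == (2,)


def test_empty_and_short_sequences():
    assert find_motif_windows("") == []
    assert find_motif_windows("LAAIAEAA") == []  # 8 residues: frame cannot fit


def test_nonstandard_residue_invalidates_only_that_window():
    # X inside the first frame kills it; a clean frame later still matches
    seq = "LXAIAEAAA" + "LAAIAEAAA"
    hits = find_motif_windows(seq)
    assert (10, "LAAIAEAAA") in hits
    assert all(start != 1 for start, _ in hits)


@pytest.mark.parametrize(
    "window,numDE,numST,numKR,n",
    [
        ("LESIAEHVD", 2, 0, 0, 2),   # flanks E,H,V,D; the S at position 3 is ignored
        ("LESVAEEHE", 3, 0, 0, 3),
        ("LAAIAEAAA", 0, 0, 0, 0),
        ("LKAIAEAKK", 0, 0, 3, -3),
        ("LSQVDESER", 1, 2, 1, 2),
    ],
)
def test_score_window_examples(window, numDE, numST, numKR, n):
    de, st_, kr, N, n_intr = score_window(window)
    assert (de, st_, kr, N) == (numDE, numST, numKR, n)
    assert n_intr == de - kr


def test_score_window_counts_only_flank_positions():
    # acidic residues at non-flank positions 3 and 5 contribute nothing
    de, st_, kr, N, _ = score_window("LAEIDEAAA")
    assert (de, st_, kr, N) == (0, 0, 0, 0)


def test_score_window_rejects_wrong_length():
    with pytest.raises(ParameterError):
        score_window("LAAIAE")


@pytest.mark.parametrize(
    "window,cls,min_n",
    [
        ("LAAIAEAAA", "best_best", 1),
        ("LAAVAEAAA", "one_similar", 2),
        ("MAAIAEAAA", "one_similar", 2),
        ("MAAVAEAAA", "both_similar", 4),
        ("FAALAEAAA", "both_similar", 4),
    ],
)
def test_anchor_classes(window, cls, min_n):
    assert anchor_class(window) == (cls, min_n)


@pytest.mark.parametrize(
    "window,label",
    [
        ("LESIAEHVD", "intrinsic"),          # N_intrinsic 2 >= 1
        ("LSQVDESER", "phospho_responsive"), # L/V anchors, N 2 >= 2 > N_intrinsic 0
        ("LAAIAEAAA", "fail"),
        ("LEAVAEAAA", "fail"),               # one_similar needs N >= 2, has 1
    ],
)
def test_classification(window, label):
    assert classify_window(window).classification == label


windows9 = st.tuples(
    st.sampled_from("LMFI"),
    st.text(alphabet=AA, min_size=2, max_size=2),
    st.sampled_from("ILV"),
    st.text(alphabet=AA, min_size=1, max_size=1),
    st.text(alphabet=AA, min_size=3, max_size=3),
).map(lambda t: t[0] + t[1] + t[2] + t[3] + "E" + t[4])

_ORDER = {"fail": 0, "phospho_responsive": 1, "intrinsic": 2}


@settings(max_examples=200, derandomize=True)
@given(windows9, st.sampled_from(FLANK_POSITIONS))
def test_classification_monotone_under_flank_improvement(window, pos):
    """Replacing a flank K/R by A, or A by E, never demotes a window."""
    before = _ORDER[classify_window(window).classification]
    res = window[pos - 1]
    if res in "KR":
        improved = window[: pos - 1] + "A" + window[pos:]
    else:
        improved = window[: pos - 1] + "E" + window[pos:]
    after = _ORDER[classify_window(improved).classification]
    assert after >= before


@settings(max_examples=200, derandomize=True)
@given(windows9)
def test_score_identity_and_bounds(window):
    de, st_, kr, N, n_intr = score_window(window)
    assert N == de + st_ - kr
    assert -4 <= N <= 4
    assert n_intr <= N


def test_pattern_validation():
    with pytest.raises(ParameterError):
        MotifPattern((frozenset("L"),) * 9)  # position 6 not {E}
    bad = [frozenset("L"), None, None, frozenset("ILV"), None,
           frozenset("D"), None, None, None]
    with pytest.raises(ParameterError):
        MotifPattern(tuple(bad))


# --- Plk1 -2 rule ------------------------------------------------------------

def brute_force_plk1(residues, offset):
    return [
        offset + i
        for i in range(2, len(residues))
        if residues[i] in "ST" and residues[i - 2] in "DEN"
    ]


@settings(max_examples=300, derandomize=True)
@given(st.text(alphabet=AA, min_size=0, max_size=50), st.integers(1, 1000))
def test_plk1_sites_match_brute_force(seq, offset):
    got = [s.position for s in predict_plk1_sites(seq, offset)]
    assert got == brute_force_plk1(seq, offset)
    assert got == sorted(got)


def test_plk1_examples():
    assert [s.position for s in predict_plk1_sites("AAAAAA")] == []
    assert [s.position for s in predict_plk1_sites("ADASDNTA", offset=1)] == [4, 7]
    sites = predict_plk1_sites("NKRLSTIDESGSIL", offset=140)
    assert [(s.position, s.residue, s.minus2) for s in sites] == [(149, "S", "D")]


def test_parse_phospho_grammar():
    assert parse_phospho("LEPVRpSEE") == ("LEPVRSEE", frozenset({6}))
    with pytest.raises(FormatError):
        parse_phospho("ApGA")
    with pytest.raises(FormatError):
        parse_phospho("AAp")
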