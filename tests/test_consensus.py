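"""Consensus matching, mismatch accounting and sequence plumbing."""

import pytest

from p53recode import (
    ConsensusPattern,
    ResponseElement,
    count_mismatches,
    iupac_admits,
    locate_core,
    reference_re,
    reverse_complement,
)
from p53recode.consensus import AlphabetError, MECHANISM_ANNOTATIONS

from conftest import random_re

# independent rule table (not derived from the package's symbol sets)
ORACLE_SETS = {
    "R": {"A", "G"}, "W": {"A", "T"}, "Y": {"C", "T"}, "N": {"A", "C", "G", "T"},
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
}


def oracle_admits(symbol, base):
    if base == "I":
        return "G" in ORACLE_SETS[symbol]
    if base == "N":
        return False
    return base in ORACLE_SETS[symbol]


@pytest.mark.parametrize(
    "symbol,base,expected",
    [
        ("R", "A", True),
        ("R", "G", True),
        ("Y", "A", False),
        ("W", "T", True),
        ("C", "I", False),  # I admitted only where G is
        ("R", "I", True),
        ("G", "I", True),
        ("N", "I", True),
        ("W", "I", False),
        ("C", "N", False),
        ("N", "N", False),  # genomic ambiguity never matches
    ],
)
def test_iupac_admits_rule_table(symbol, base, expected):
    assert iupac_admits(symbol, base) is expected


def test_iupac_admits_rejects_unknown():
    with pytest.raises(AlphabetError):
        iupac_admits("X", "A")
    with pytest.raises(AlphabetError):
        iupac_admits("R", "Z")


@pytest.mark.parametrize(
    "name,positions,core",
    [
        ("p21", (11, 20), 0),
        ("MDM2", (10, 17, 18), 1),
        ("NOXA", (5, 16, 20), 2),
    ],
)
def test_count_mismatches_printed_res(name, positions, core):
    rep = count_mismatches(reference_re(name))
    assert rep.positions == positions
    assert rep.total == len(positions)
    assert rep.core_mismatches == core


def test_exact_consensus_instance_has_zero_mismatches():
    re = ResponseElement(name="ideal", sequence="GGGCATGTCCGGGCATGTCC")
    assert count_mismatches(re).total == 0


def test_mismatch_report_invariants_and_bruteforce_oracle(rng):
    """total = 20 - admitted positions, per an independent per-position check."""
    pattern = ConsensusPattern()
    full = pattern.full_site
    for _ in range(1000):
        re = random_re(rng, alphabet="ACGTI")
        rep = count_mismatches(re)
        admitted = sum(
            1 for p in range(1, 21) if oracle_admits(full[p - 1], re.base(p))
        )
        expect = tuple(
            p for p in range(1, 21) if not oracle_admits(full[p - 1], re.base(p))
        )
        assert rep.positions == expect
        assert rep.total == 20 - admitted
        assert rep.core_mismatches <= rep.total
        assert rep.invariant_position_mismatches <= rep.core_mismatches


def test_uniform_consensus_expansion_never_mismatches(rng):
    full = ConsensusPattern().full_site
    for _ in range(200):
        seq = "".join(
            sorted(ORACLE_SETS[s])[rng.integers(len(ORACLE_SETS[s]))] for s in full
        )
        assert count_mismatches(ResponseElement(name="x", sequence=seq)).total == 0


def test_mismatch_count_invariant_under_reverse_complement(rng):
    """The consensus is its own reverse complement (spacer 0)."""
    for _ in range(1000):
        re = random_re(rng)
        assert (
            count_mismatches(re).total
            == count_mismatches(re.reverse_complement()).total
        )


@pytest.mark.parametrize(
    "name,core1,core2,m1,m2",
    [
        ("BAX", "CAGG", "CTTG", False, True),
        ("p21", "CATG", "CATG", True, True),
        ("NOXA", "CGTG", "CAGG", False, False),
    ],
)
def test_locate_core(name, core1, core2, m1, m2):
    rep = locate_core(reference_re(name))
    assert (rep.core1, rep.core2) == (core1, core2)
    assert (rep.core1_matches, rep.core2_matches) == (m1, m2)


def test_locate_core_mismatch_positions():
    assert locate_core(reference_re("NOXA")).mismatch_positions == (5, 16)
    assert locate_core(reference_re("BAX")).mismatch_positions == (6,)


@pytest.mark.parametrize(
    "seq,expected",
    [("ACGT", "ACGT"), ("GGI", "CCC"), ("AAAA", "TTTT")],
)
def test_reverse_complement(seq, expected):
    assert reverse_complement(seq) == expected


def test_reverse_complement_rejects_unknown():
    with pytest.raises(AlphabetError):
        reverse_complement("ACGU")


def test_consensus_closed_under_reverse_complement(rng):
    """RC of any exact-consensus 20-mer still matches the consensus."""
    full = ConsensusPattern().full_site
    for _ in range(100):
        seq = "".join(
            sorted(ORACLE_SETS[s])[rng.integers(len(ORACLE_SETS[s]))] for s in full
        )
        rc = reverse_complement(seq)
        assert count_mismatches(ResponseElement(name="rc", sequence=rc)).total == 0


from hypothesis import given, settings
from hypothesis import strategies as st

seq20 = st.text(alphabet="ACGTI", min_size=20, max_size=20)


@settings(derandomize=True, max_examples=200)
@given(seq20)
def test_reverse_complement_is_involution_on_inosine_free(seq):
    if "I" in seq:
        # I pairs C, so RC is not an involution when inosine is present
        seq = seq.replace("I", "G")
    assert reverse_complement(reverse_complement(seq)) == seq


@settings(derandomize=True, max_examples=200)
@given(seq20)
def test_mismatch_positions_sorted_and_bounded(seq):
    rep = count_mismatches(ResponseElement(name="h", sequence=seq))
    assert list(rep.positions) == sorted(rep.positions)
    assert all(1 <= p <= 20 for p in rep.positions)
    assert rep.invariant_position_mismatches <= rep.core_mismatches <= rep.total


def test_response_element_validation():
    with pytest.raises(ValueError):
        ResponseElement(name="short", sequence="ACGT")
    with pytest.raises(AlphabetError):
        ResponseElement(name="bad", sequence="Z" * 20)
    # lower-case folded, not treated as mismatch annotation
    re = ResponseElement(name="lc", sequence="gaacatgtcccaacatgttg")
    assert re.sequence == "GAACATGTCCCAACATGTTG"


def test_mechanism_annotations():
    assert MECHANISM_ANNOTATIONS["Arg280"].contacted_positions == {4, 7, 14, 17}
    assert MECHANISM_ANNOTATIONS["Lys120"].contacted_positions == {2, 3, 12, 13}
    assert MECHANISM_ANNOTATIONS["Arg248"].groove == "minor"
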