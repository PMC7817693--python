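"""Edit design: applying substitutions and proposing mode flips."""

from itertools import product

import pytest

from p53recode import (
    ResponseElement,
    apply_edits,
    classify,
    propose_ic_variant,
    propose_mode_flip,
    reference_re,
    replace_range,
)
from p53recode.classify import DEFAULT_THRESHOLDS
from p53recode.consensus import CODE_POSITIONS
from p53recode.edits import Edit, EditConsistencyError

from conftest import random_re


def test_apply_edits_reproduces_printed_bax_8_13(bax):
    edited = apply_edits(bax, (Edit(8, "C", "T"), Edit(13, "G", "A")))
    assert edited.sequence == reference_re("BAX_8/13").sequence


def test_replace_range_reproduces_bax_4bp(bax):
    edited = replace_range(bax, 8, "TCCCAA")  # positions 8-13 CCCGGG -> TCCCAA
    diff = [p for p in range(1, 21) if edited.base(p) != bax.base(p)]
    assert diff == [8, 11, 12, 13]


def test_empty_edit_list_is_identity(bax):
    assert apply_edits(bax, ()).sequence == bax.sequence


def test_from_base_mismatch_raises(bax):
    with pytest.raises(EditConsistencyError):
        apply_edits(bax, (Edit(8, "G", "T"),))  # position 8 holds C, not G


def test_edits_are_reversible(rng):
    for _ in range(100):
        re = random_re(rng)
        edits = tuple(
            Edit(p, re.base(p), b)
            for p, b in zip((3, 8, 13), "GCG")
            if re.base(p) != b
        )
        fwd = apply_edits(re, edits)
        back = apply_edits(fwd, tuple(Edit(e.position, e.to_base, e.from_base)
                                      for e in edits))
        assert back.sequence == re.sequence


def brute_force_min_edits(re, target_mode, thresholds=DEFAULT_THRESHOLDS):
    """Smallest number of code-position substitutions reaching target_mode,
    over all 4^4 base assignments at the code positions (A/C/G/T)."""
    best = None
    for combo in product("ACGT", repeat=4):
        seq = list(re.sequence)
        n_edit = 0
        for p, b in zip(CODE_POSITIONS, combo):
            if seq[p - 1] != b:
                seq[p - 1] = b
                n_edit += 1
        if n_edit == 0:
            continue
        mutant = ResponseElement(name="m", sequence="".join(seq))
        if classify(mutant, thresholds).mode_label == target_mode:
            best = n_edit if best is None else min(best, n_edit)
    return best


def test_bax_flip_to_hydrophobic_includes_printed_plan(bax):
    plans = propose_mode_flip(bax, "hydrophobic")
    assert all(p.edit_count == 2 for p in plans)
    printed = {(8, 13)}
    assert printed <= {tuple(e.position for e in p.edits) for p in plans}
    for p in plans:
        assert p.profile_after.mode_label == "hydrophobic"


def test_p21_flip_to_electrostatic_needs_three_edits(p21):
    plans = propose_mode_flip(p21, "electrostatic")
    assert plans and all(p.edit_count == 3 for p in plans)


def test_already_at_target_raises(p21):
    with pytest.raises(ValueError):
        propose_mode_flip(p21, "hydrophobic")


def test_plans_are_ranked_deterministically(bax):
    plans = propose_mode_flip(bax, "hydrophobic")
    keys = [tuple(e.position for e in p.edits) for p in plans]
    assert keys == sorted(keys)


def test_minimal_plan_size_matches_brute_force(rng):
    """Closed loop on random REs: plan size equals exhaustive minimum and
    every plan achieves the target on reclassification."""
    checked = 0
    for _ in range(200):
        re = random_re(rng)
        current = classify(re).mode_label
        for target in ("hydrophobic", "electrostatic"):
            if current == target:
                continue
            plans = propose_mode_flip(re, target)
            oracle = brute_force_min_edits(re, target)
            if not plans:
                # transition-convention plans may be impossible only if even
                # arbitrary substitutions cannot reach the target in <= 4
                assert oracle is None
                continue
            assert plans[0].edit_count == oracle
            for p in plans:
                assert classify(p.result).mode_label == target
            checked += 1
    assert checked > 100


def test_ic_variant_bax_style(bax):
    plan = propose_ic_variant(bax, (8, 13))
    assert plan.profile_before.k120r_label == "unbound"
    assert plan.profile_after.k120r_label == "unbound"  # major channel untouched
    assert plan.profile_after.mode_label == "hydrophobic"
    assert plan.profile_after.minor_channel_count == plan.profile_before.minor_channel_count - 2
    assert plan.profile_after.major_channel_count == plan.profile_before.major_channel_count


def test_ic_variant_6fj5_style():
    plan = propose_ic_variant(reference_re("6FJ5"), (8, 18))
    assert plan.result.sequence == reference_re("6FJ5_8/18 I/C").sequence
    assert plan.profile_after.major_channel_count == 4
    assert plan.profile_after.minor_channel_count == 2


def test_ic_variant_zero_positions_is_identity(bax):
    plan = propose_ic_variant(bax, ())
    assert plan.edit_count == 0
    assert plan.result.sequence == bax.sequence


def test_ic_variant_requires_gc_pair(p21):
    with pytest.raises(EditConsistencyError):
        propose_ic_variant(p21, (3,))  # p21 position 3 is A
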