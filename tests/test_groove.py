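"""Groove-width geometry: ideal duplexes, invariances, closed-form oracle."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from p53recode import build_ideal_duplex, compare_profiles, groove_widths
from p53recode.groove import (
    DuplexStructure,
    PHOSPHATE_CORRECTION,
    StructureError,
    ideal_width_oracle,
    read_duplex_pdb,
)

SEQ = "GGGCATGTCCGGGCATGTCC"


@pytest.fixture(scope="module")
def ideal():
    return build_ideal_duplex(SEQ)


def test_uniform_duplex_profile_is_constant(ideal):
    prof = groove_widths(ideal)
    assert len(prof.levels) > 8
    assert prof.minor_width_raw.std() < 1e-6
    assert prof.major_width_raw.std() < 1e-6
    assert prof.minor_width_raw.mean() < prof.major_width_raw.mean()


def test_correction_is_exactly_5_8(ideal):
    prof = groove_widths(ideal)
    assert np.allclose(prof.minor_width, prof.minor_width_raw - 5.8)
    assert np.allclose(prof.major_width, prof.major_width_raw - 5.8)
    assert PHOSPHATE_CORRECTION == 5.8


def test_widths_match_closed_form_helix_oracle(ideal):
    """Min over the candidate separations of the coaxial-helix chord formula."""
    prof = groove_widths(ideal)
    minor_expect = min(ideal_width_oracle(s) for s in range(0, 6))
    major_expect = min(ideal_width_oracle(s) for s in range(-5, 0))
    assert prof.minor_width_raw == pytest.approx(minor_expect, abs=1e-6)
    assert prof.major_width_raw == pytest.approx(major_expect, abs=1e-6)


def test_rigid_body_invariance(ideal, rng):
    R = Rotation.random(random_state=np.random.RandomState(4)).as_matrix()
    t = np.array([12.3, -45.6, 7.89])
    moved = ideal.transformed(R, t)
    a, b = groove_widths(ideal), groove_widths(moved)
    assert np.allclose(a.minor_width_raw, b.minor_width_raw, atol=1e-9)
    assert np.allclose(a.major_width_raw, b.major_width_raw, atol=1e-9)


def test_strand_swap_preserves_groove_identity(ideal):
    swapped = ideal.swap_strands()
    a, b = groove_widths(ideal), groove_widths(swapped)
    assert np.allclose(np.sort(a.minor_width_raw), np.sort(b.minor_width_raw))
    assert np.allclose(np.sort(a.major_width_raw), np.sort(b.major_width_raw))


def test_straight_parallel_strands_give_separation_distance():
    """P atoms on two parallel lines d apart, in register: minor raw = d."""
    n, d, h = 12, 14.0, 3.4
    s1 = tuple((0.0, 0.0, m * h) for m in range(n))
    s2 = tuple((d, 0.0, (n - 1 - m) * h) for m in range(n))  # antiparallel order
    duplex = DuplexStructure(sequences=("A" * n, "T" * n), p_coords=(s1, s2))
    prof = groove_widths(duplex)
    assert np.allclose(prof.minor_width_raw, d, atol=1e-12)


def test_groove_phase_sweep_is_monotone():
    """Over 145-175 deg, minor widens while major narrows, per brute force."""
    minors, majors = [], []
    for phase in range(145, 176, 5):
        prof = groove_widths(build_ideal_duplex(SEQ, groove_phase_deg=phase))
        minors.append(prof.minor_width_raw.mean())
        majors.append(prof.major_width_raw.mean())
    assert np.all(np.diff(minors) > 0)
    assert np.all(np.diff(majors) < 0)


def test_too_short_duplex_rejected():
    with pytest.raises(StructureError):
        build_ideal_duplex("ACGT")
    with pytest.raises(ValueError):
        build_ideal_duplex(SEQ, twist_deg=-1)


def test_missing_terminal_phosphates_skip_edge_levels(ideal):
    coords = (
        (None,) + ideal.p_coords[0][1:],
        ideal.p_coords[1][:-1] + (None,),
    )
    trimmed = DuplexStructure(sequences=ideal.sequences, p_coords=coords)
    full = groove_widths(ideal)
    part = groove_widths(trimmed)
    assert len(part.levels) < len(full.levels)
    assert set(part.levels) <= set(full.levels)
    keep = np.isin(full.levels, part.levels)
    assert np.allclose(part.minor_width_raw, full.minor_width_raw[keep])
    assert np.allclose(part.major_width_raw, full.major_width_raw[keep])


def test_compare_profiles_self_is_zero(ideal):
    prof = groove_widths(ideal)
    df = compare_profiles(prof, prof)
    assert np.allclose(df["minor_diff"], 0.0)
    assert np.allclose(df["major_diff"], 0.0)


def test_compare_profiles_sign_matches_generator_truth():
    narrow = groove_widths(build_ideal_duplex(SEQ, groove_phase_deg=150))
    wide = groove_widths(build_ideal_duplex(SEQ, groove_phase_deg=170))
    df = compare_profiles(wide, narrow)
    assert (df["minor_diff"] > 0).all()  # larger phase -> wider minor groove
    assert (df["major_diff"] < 0).all()
    assert df["arg248_zone"].any()


def test_compare_profiles_overlap_and_disjoint(ideal):
    prof = groove_widths(ideal)
    import dataclasses

    shifted = dataclasses.replace(prof, levels=prof.levels + 3)
    df = compare_profiles(prof, shifted)
    assert len(df) == len(set(prof.levels) & set(shifted.levels))
    far = dataclasses.replace(prof, levels=prof.levels + 1000)
    with pytest.raises(ValueError):
        compare_profiles(prof, far)


def test_single_strand_rejected():
    with pytest.raises(StructureError):
        DuplexStructure(sequences=("ACGTAA",), p_coords=((None,) * 6,))


def _duplex_to_pdb(duplex, path):
    """Minimal PDB writer for test fixtures (chains A and B, P atoms only)."""
    names = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
    lines = []
    serial = 1
    for chain_id, (seq, coords) in zip("AB", zip(duplex.sequences, duplex.p_coords)):
        for i, (base, c) in enumerate(zip(seq, coords), start=1):
            if c is None:
                continue
            x, y, z = c
            lines.append(
                f"ATOM  {serial:5d}  P   {names[base]:>3s} {chain_id}{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           P"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def test_pdb_round_trip(tmp_path, ideal):
    pdb = tmp_path / "ideal.pdb"
    _duplex_to_pdb(ideal, pdb)
    back = read_duplex_pdb(pdb)
    assert back.sequences == ideal.sequences
    a, b = groove_widths(ideal), groove_widths(back)
    assert np.allclose(a.minor_width_raw, b.minor_width_raw, atol=1e-3)
    assert np.allclose(a.major_width_raw, b.major_width_raw, atol=1e-3)
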