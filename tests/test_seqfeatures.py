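import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbsmine.errors import ClassificationError
from pbsmine.records import GeneFamily, MotifPattern, ProteinRecord
from pbsmine.refpanel import APCE_PHYTOCHROME_CYS, FAR_RED_MOTIF
from pbsmine.seqfeatures import (
    classify_apcE,
    classify_cpcG_cpcL,
    conserved_residue_check,
    hydropathy_profile,
    identity_matrix,
    scan_motif,
)
from pbsmine.simulate import mutate_to_identity


def _protein(seq, pid="p"):
    return ProteinRecord(pid, "test", seq)


# --- motif scanning --------------------------------------------------------


@pytest.mark.parametrize(
    "sequence,expected",
    [
        ("GGGVIPEDVGGG", [(3, 9, "VIPEDV")]),  # literal far-red motif
        ("ILPEDL", [(0, 6, "ILPEDL")]),  # class members at flank positions
        ("AIPEDV", [(0, 6, "AIPEDV")]),  # one tolerated mismatch
        ("AAPEDA", []),  # three mismatches at class positions
        ("VIGEDV", []),  # anchored proline violated
        ("AAAAAAAAAA", []),
    ],
)
def test_far_red_motif_scan(sequence, expected):
    assert scan_motif(_protein(sequence), FAR_RED_MOTIF) == expected


def test_scan_motif_reports_all_windows_left_to_right():
    hits = scan_motif(_protein("VIPEDVXXVIPEDV"), FAR_RED_MOTIF)
    assert [h[0] for h in hits] == [0, 8]


def test_scan_motif_rejects_empty_pattern():
    empty = MotifPattern.from_strings("empty", [])
    with pytest.raises(ValueError):
        scan_motif(_protein("AAAA"), empty)


# --- conserved residues ----------------------------------------------------


def _toy_family(rng):
    sequence = "".join(rng.choice(list("ADEFGHIKLMNPQRSTVWY"), size=40))
    sequence = sequence[:19] + "C" + sequence[20:]  # Cys at position 20
    canonical = _protein(sequence, "ref")
    return GeneFamily(
        family_name="cpcA",
        category="PBP",
        reference_members=[canonical],
        canonical_reference=canonical,
        conserved_sites=[(20, "C")],
    )


def test_conserved_fraction_counts_substitution(scheme, rng):
    family = _toy_family(rng)
    members = [
        mutate_to_identity(
            family.canonical_reference, 0.9, {19}, rng,
            protein_id=f"m{i}", strain_id="s",
        )
        for i in range(9)
    ]
    mutated = list(family.canonical_reference.sequence)
    mutated[19] = "S"
    members.append(_protein("".join(mutated), "m9"))
    result = conserved_residue_check(family, members, (20, "C"), scheme)
    assert result.conserved_fraction == pytest.approx(0.9)
    assert result.presence["m9"] is False


def test_conserved_fraction_order_invariant(scheme, rng):
    family = _toy_family(rng)
    members = [
        mutate_to_identity(
            family.canonical_reference, 0.85, {19}, rng,
            protein_id=f"m{i}", strain_id="s",
        )
        for i in range(6)
    ]
    forward = conserved_residue_check(family, members, (20, "C"), scheme)
    backward = conserved_residue_check(family, members[::-1], (20, "C"), scheme)
    assert forward.conserved_fraction == backward.conserved_fraction


def test_gap_at_site_counts_as_absent(scheme, rng):
    family = _toy_family(rng)
    # member missing residues 18-22 entirely: site cannot map
    sequence = family.canonical_reference.sequence
    member = _protein(sequence[:17] + sequence[22:], "gapped")
    result = conserved_residue_check(family, [member], (20, "C"), scheme)
    assert result.presence["gapped"] is False


def test_short_member_excluded_from_denominator(scheme, rng):
    family = _toy_family(rng)
    intact = _protein(family.canonical_reference.sequence, "ok")
    stub = _protein("MKTAY", "stub")
    result = conserved_residue_check(family, [intact, stub], (20, "C"), scheme)
    assert "stub" not in result.presence
    assert result.conserved_fraction == 1.0


def test_unannotated_site_rejected(scheme, rng):
    family = _toy_family(rng)
    with pytest.raises(ValueError):
        conserved_residue_check(family, [], (7, "C"), scheme)


# --- apcE classification ---------------------------------------------------


def _apcE_variant(panel_by_name, motif: bool, cys: bool):
    family = panel_by_name["apcE"]
    chars = list(family.canonical_reference.sequence)
    if motif:
        chars[299:305] = list("VIPEDV")
    if not cys:
        chars[APCE_PHYTOCHROME_CYS - 1] = "S"
    return _protein("".join(chars), "apcE_test"), family


@pytest.mark.parametrize(
    "motif,cys,expected",
    [
        (True, False, "far_red"),
        (False, True, "conventional"),
        (True, True, "ambiguous"),  # conflicting evidence is never coerced
        (False, False, "ambiguous"),
    ],
)
def test_apcE_classification(panel_by_name, scheme, motif, cys, expected):
    protein, family = _apcE_variant(panel_by_name, motif, cys)
    result = classify_apcE(protein, family, scheme)
    assert result.klass == expected
    assert result.phytochrome_cys_present is cys
    assert (result.motif_hit is not None) is motif


def test_apcE_never_far_red_with_cysteine(panel_by_name, scheme):
    protein, family = _apcE_variant(panel_by_name, motif=True, cys=True)
    assert classify_apcE(protein, family, scheme).klass != "far_red"


# --- hydropathy ------------------------------------------------------------


@pytest.mark.parametrize(
    "sequence,expected",
    [
        ("I" * 19, 4.5),
        ("R" * 19, -4.5),
        ("I" * 10 + "R" * 9, (10 * 4.5 + 9 * -4.5) / 19),
    ],
)
def test_hydropathy_single_window(sequence, expected):
    profile = hydropathy_profile(_protein(sequence), window=19)
    assert len(profile) == 1
    assert profile[0] == pytest.approx(expected)


@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", min_size=19, max_size=80))
@settings(derandomize=True, max_examples=50)
def test_hydropathy_profile_length_and_bounds(sequence):
    profile = hydropathy_profile(_protein(sequence), window=19)
    assert len(profile) == len(sequence) - 18
    assert np.all(profile >= -4.5 - 1e-12)
    assert np.all(profile <= 4.5 + 1e-12)


def test_hydropathy_window_longer_than_sequence_rejected():
    with pytest.raises(ValueError):
        hydropathy_profile(_protein("MKT"), window=19)


# --- cpcG / cpcL discrimination --------------------------------------------


def test_hydrophobic_tail_classified_cpcL():
    body = "DENQKRST" * 25
    tail = "ILVFAILVFAILVFAILVFAI"  # 21 hydrophobic residues
    klass, score = classify_cpcG_cpcL(_protein(body + tail))
    assert klass == "cpcL"
    assert score >= 1.6


def test_hydrophilic_sequence_classified_cpcG():
    klass, _ = classify_cpcG_cpcL(_protein("DENQKRSTGH" * 25))
    assert klass == "cpcG"


def test_n_terminal_hydrophobic_stretch_is_not_cpcL():
    sequence = "ILVFA" * 10 + "DENQKRSTGH" * 20
    klass, _ = classify_cpcG_cpcL(_protein(sequence))
    assert klass == "cpcG"


def test_too_short_sequence_raises_classification_error():
    with pytest.raises(ClassificationError):
        classify_cpcG_cpcL(_protein("MKTAYIAK"))


# --- identity matrices -----------------------------------------------------


def test_identity_matrix_identical_pair(scheme):
    members = [_protein("MKTAYIAKQRQISFVK", f"m{i}") for i in range(2)]
    matrix = identity_matrix(members, scheme)
    assert matrix[0, 1] == 1.0


def test_identity_matrix_symmetric_with_unit_diagonal(scheme, panel_by_name, rng):
    reference = panel_by_name["apcA"].canonical_reference
    members = [
        mutate_to_identity(reference, 0.85, set(), rng,
                           protein_id=f"m{i}", strain_id="s")
        for i in range(4)
    ]
    matrix = identity_matrix(members, scheme)
    assert np.allclose(matrix, matrix.T)
    assert np.allclose(np.diag(matrix), 1.0)
    # members built at >=85% identity to one reference stay mutually similar
    assert matrix.min() > 0.70


def test_identity_matrix_needs_two_members(scheme):
    with pytest.raises(ValueError):
        identity_matrix([_protein("MKT")], scheme)
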