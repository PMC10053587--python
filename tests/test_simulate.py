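import json

import numpy as np
import pytest

from pbsmine.align import global_align
from pbsmine.errors import SpecError
from pbsmine.refpanel import APCA_GLUTAMATE_POSITIONS
from pbsmine.simulate import (
    APCA_GLUTAMATE_SHIFT,
    StrainSpec,
    build_dataset,
    build_strain,
    default_strain_specs,
    mutate_to_identity,
)

SPECS = {s.strain_id: s for s in default_strain_specs()}


# --- mutate_to_identity ----------------------------------------------------


def test_target_identity_one_is_identity(panel_by_name, rng):
    reference = panel_by_name["apcA"].canonical_reference
    mutant = mutate_to_identity(reference, 1.0, set(), rng,
                                protein_id="m", strain_id="s")
    assert mutant.sequence == reference.sequence


def test_realized_identity_within_band(panel_by_name, scheme):
    reference = panel_by_name["apcA"].canonical_reference  # length 161
    rng = np.random.default_rng(1)
    mutant = mutate_to_identity(reference, 0.85, set(), rng,
                                protein_id="m", strain_id="s")
    result, _ = global_align(mutant, reference, scheme)
    assert 0.82 <= result.identity <= 0.88


@pytest.mark.parametrize("seed", range(1, 6))
def test_frozen_positions_never_mutated(panel_by_name, seed):
    family = panel_by_name["cpcA"]
    reference = family.canonical_reference
    frozen = {pos - 1 for pos, _ in family.conserved_sites}
    rng = np.random.default_rng(seed)
    mutant = mutate_to_identity(reference, 0.6, frozen, rng,
                                protein_id="m", strain_id="s")
    for pos, residue in family.conserved_sites:
        assert mutant.sequence[pos - 1] == residue


def test_frozen_budget_overflow_is_spec_error(panel_by_name, rng):
    reference = panel_by_name["apcC"].canonical_reference  # length 67
    frozen = set(range(50))
    with pytest.raises(SpecError):
        mutate_to_identity(reference, 0.4, frozen, rng,
                           protein_id="m", strain_id="s")


def test_out_of_range_target_is_spec_error(panel_by_name, rng):
    reference = panel_by_name["apcA"].canonical_reference
    with pytest.raises(SpecError):
        mutate_to_identity(reference, 0.2, set(), rng,
                           protein_id="m", strain_id="s")


def test_planted_substitutions_shift_composition(panel_by_name):
    reference = panel_by_name["apcA"].canonical_reference
    baseline = reference.sequence.count("E")
    rng = np.random.default_rng(9)
    mutant = mutate_to_identity(
        reference, 0.85, {p - 1 for p in APCA_GLUTAMATE_POSITIONS}, rng,
        protein_id="m", strain_id="s",
        planted={"E": APCA_GLUTAMATE_SHIFT}, pool_exclude=frozenset("E"),
    )
    assert mutant.sequence.count("E") == baseline + APCA_GLUTAMATE_SHIFT


# --- strain specifications (transcribed complement tables) ------------------


def test_nineteen_thermophiles_and_two_mesophiles():
    groups = [s.group for s in SPECS.values()]
    assert groups.count("thermophile") == 19
    assert groups.count("mesophile") == 2


def test_jsc1_complement_row():
    complement = SPECS["Leptolyngbya_JSC-1"].complement()
    expected = dict(apcA=1, apcB=1, cpcA=2, cpcB=2, cpeA=1, cpeB=1,
                    pcyA=1, pebA=1, pebB=1)
    for family, copies in expected.items():
        assert complement[family] == copies, family
    assert complement["apcE"] == 2
    assert complement["cpcL"] == 2


def test_pigment_types_seventeen_T1_two_T2():
    thermophiles = [s for s in SPECS.values() if s.group == "thermophile"]
    types = [s.pigment_type() for s in thermophiles]
    assert types.count("T1") == 17
    assert types.count("T2") == 2


def test_thermosynechococcus_cpcG_three_cpcL_zero():
    complement = SPECS["Thermosynechococcus_CL-1"].complement()
    assert complement["cpcG"] == 3
    assert complement.get("cpcL", 0) == 0


def test_thermostichus_lyase_copy_numbers():
    complement = SPECS["Thermostichus_60AY4M2"].complement()
    assert (complement["cpcE"], complement["cpcF"],
            complement["cpcS"], complement["cpcT"]) == (2, 2, 1, 2)


def test_pcc6715_lacks_cpcS():
    assert "cpcS" not in SPECS["Thermosynechococcus_PCC6715"].complement()


def test_six_putative_cpcL_homologs_total():
    total = sum(s.complement().get("cpcL", 0) for s in SPECS.values())
    assert total == 6


def test_three_far_red_strains():
    far_red = [s.strain_id for s in SPECS.values() if "far_red" in s.apcE_classes]
    assert sorted(far_red) == [
        "Leptolyngbya_JSC-1", "Leptothermofonsia_E412", "Ocullathermofonsia_A174",
    ]


def test_cluster_layout_templates():
    labels = SPECS["Thermosynechococcus_BP-1"].cluster_labels()
    assert "cpcB-A-C-D-E-F-G" in labels
    assert "apcA-B-C" in labels
    labels = SPECS["Ocullathermofonsia_A174"].cluster_labels()
    assert "cpcG-G-L-G" in labels
    labels = SPECS["Thermostichus_JA-2-3Ba"].cluster_labels()
    assert "cpcB-A-C-E-T" in labels


def test_mismatched_apcE_classes_is_spec_error():
    spec = SPECS["Leptolyngbya_JSC-1"]
    with pytest.raises(SpecError):
        StrainSpec(
            strain_id="x", morphology=spec.morphology, group=spec.group,
            layouts=spec.layouts, apcE_classes=("conventional",),
        )


# --- strain construction ---------------------------------------------------


def test_build_strain_layout_geometry(panel):
    spec = SPECS["Thermosynechococcus_BP-1"]
    proteins, features, truth = build_strain(
        spec, panel, np.random.default_rng(5)
    )
    pbs = [f for f in features if not f.protein_id.startswith("decoy")]
    assert len(pbs) == sum(truth["complement"].values())
    # clusters: consecutive genes <= 200 bp apart, cluster breaks >= 5000 bp
    sizes = [len(layout) for layout in spec.layouts]
    index = 0
    for size in sizes:
        run = pbs[index : index + size]
        for a, b in zip(run, run[1:]):
            assert 0 < b.start - a.end - 1 <= 200
        index += size
    boundaries = [pbs[i] for i in np.cumsum(sizes)[:-1]]
    starts = [pbs[i - 1] for i in np.cumsum(sizes)[:-1]]
    for prev, nxt in zip(starts, boundaries):
        assert nxt.start - prev.end - 1 >= 5000
    # opposite-strand template members carried through
    assert {f.strand for f in features} == {"+", "-"}


def test_build_strain_decoy_count(panel):
    spec = SPECS["Synechocystis_PCC6803"]
    proteins, _, truth = build_strain(spec, panel, np.random.default_rng(3))
    decoys = [p for p in proteins if p.protein_id.startswith("decoy")]
    assert len(decoys) == truth["n_decoys"] == 10


def test_duplicate_strain_id_rejected(tmp_path):
    spec = SPECS["Synechococcus_PCC7942"]
    with pytest.raises(SpecError, match="duplicate"):
        build_dataset(str(tmp_path / "d"), seed=1, specs=[spec, spec])


def test_dataset_deterministic_and_seed_sensitive(tmp_path):
    specs = [SPECS["Thermosynechococcus_BP-1"]]
    a = tmp_path / "a"
    b = tmp_path / "b"
    c = tmp_path / "c"
    manifest_a = build_dataset(str(a), seed=1, specs=specs)
    manifest_b = build_dataset(str(b), seed=1, specs=specs)
    manifest_c = build_dataset(str(c), seed=2, specs=specs)
    fa = (a / "Thermosynechococcus_BP-1" / "proteins.faa").read_bytes()
    fb = (b / "Thermosynechococcus_BP-1" / "proteins.faa").read_bytes()
    fc = (c / "Thermosynechococcus_BP-1" / "proteins.faa").read_bytes()
    assert fa == fb
    assert fa != fc  # different bytes ...
    assert manifest_a["strains"] == manifest_c["strains"]  # ... same truth


def test_manifest_matches_written_files(full_dataset):
    dataset_dir, manifest = full_dataset
    on_disk = json.load(open(f"{dataset_dir}/manifest.json"))
    assert on_disk["strains"] == manifest["strains"]
    assert len(manifest["strains"]) == 21
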