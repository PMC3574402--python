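"""Rare-locally vs rare-throughout classification and the definition nesting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from varzea import (
    DEFINITIONS,
    HABITATS,
    CommonRarePartition,
    RarityDefinition,
    ReferenceHabitatTable,
    ValidationError,
    check_definition_nesting,
    classify_all_definitions,
    classify_rarity_status,
)


def make_reference(presence: dict[str, dict[str, float | None]]) -> ReferenceHabitatTable:
    """presence: species -> {habitat: share or None}; habitats absent -> absent rows."""
    rows = []
    for sp, habs in presence.items():
        for h in HABITATS:
            if h in habs:
                rows.append((sp, h, True, habs[h]))
            else:
                rows.append((sp, h, False, np.nan))
    return ReferenceHabitatTable(
        table=pd.DataFrame(rows, columns=["species", "habitat", "present", "rel_abund"])
    )


def make_partition(common, rare):
    return CommonRarePartition(
        threshold=0.01, common=frozenset(common), rare=frozenset(rare)
    )


def test_habitat_count_rule():
    ref = make_reference({"r1": {HABITATS[0]: 0.001, HABITATS[1]: 0.002, HABITATS[2]: None}})
    part = make_partition(common=["c1"], rare=["r1"])
    for label in ("i", "ii"):
        out = classify_rarity_status(part, ref, label)
        assert out.status["r1"] == "rare_locally"
        assert out.status["c1"] == "common"


def test_share_threshold_rule_between_half_and_one_percent():
    # present in a single habitat at share 0.007: rare locally under (iii)
    # (threshold 0.5%), rare throughout under (iv) (threshold 1%)
    ref = make_reference({"r1": {HABITATS[3]: 0.007}})
    part = make_partition(common=[], rare=["r1"])
    assert classify_rarity_status(part, ref, "iii").status["r1"] == "rare_locally"
    assert classify_rarity_status(part, ref, "iv").status["r1"] == "rare_throughout"
    assert classify_rarity_status(part, ref, "i").status["r1"] == "rare_throughout"


def test_absent_everywhere_is_rare_throughout_under_all_definitions():
    ref = make_reference({"r1": {}})
    part = make_partition(common=[], rare=["r1"])
    for label in DEFINITIONS:
        assert classify_rarity_status(part, ref, label).status["r1"] == "rare_throughout"


def test_missing_reference_information_excludes():
    ref = make_reference({"r1": {HABITATS[0]: 0.1, HABITATS[1]: 0.1}})
    part = make_partition(common=[], rare=["r1", "r2"])
    out = classify_rarity_status(part, ref, "i")
    assert out.status["r2"] == "excluded"
    assert out.status["r1"] == "rare_locally"


def test_reference_table_validation():
    bad = pd.DataFrame(
        [("a", HABITATS[0], False, 0.2)],
        columns=["species", "habitat", "present", "rel_abund"],
    )
    with pytest.raises(ValidationError, match="absent rows"):
        ReferenceHabitatTable(table=bad)
    bad = pd.DataFrame(
        [("a", "moon crater", True, 0.2)],
        columns=["species", "habitat", "present", "rel_abund"],
    )
    with pytest.raises(ValidationError, match="outside the declared set"):
        ReferenceHabitatTable(table=bad)


def test_classification_ignores_row_order_and_absent_habitats():
    presence = {"r1": {HABITATS[0]: 0.004, HABITATS[4]: 0.006}}
    ref = make_reference(presence)
    shuffled = ReferenceHabitatTable(
        table=ref.table.sample(frac=1.0, random_state=3).reset_index(drop=True)
    )
    present_only = ReferenceHabitatTable(table=ref.table[ref.table["present"]].copy())
    part = make_partition(common=[], rare=["r1"])
    for r in (ref, shuffled, present_only):
        assert classify_rarity_status(part, r, "iii").status["r1"] == "rare_locally"


def test_monotonicity_in_definition_parameters():
    rng = np.random.default_rng(5)
    presence = {}
    for i in range(40):
        habs = rng.choice(len(HABITATS), size=rng.integers(0, 5), replace=False)
        presence[f"r{i:02d}"] = {HABITATS[h]: float(rng.uniform(0, 0.02)) for h in habs}
    ref = make_reference(presence)
    part = make_partition(common=[], rare=list(presence))

    def rl(min_habitats, threshold):
        d = RarityDefinition("x", min_habitats=min_habitats, abundance_threshold=threshold)
        return classify_rarity_status(part, ref, d).species_with("rare_locally")

    assert rl(3, 0.005) <= rl(2, 0.005)  # more habitats required -> never grows
    assert rl(2, 0.01) <= rl(2, 0.005)  # higher share threshold -> never grows


reference_strategy = st.dictionaries(
    keys=st.integers(0, 30).map(lambda i: f"r{i:02d}"),
    values=st.dictionaries(
        keys=st.sampled_from(HABITATS),
        values=st.one_of(st.none(), st.floats(0.0, 0.05)),
        max_size=6,
    ),
    min_size=1,
    max_size=25,
)


@given(reference_strategy, st.floats(0.0, 1.0))
@settings(max_examples=120, deadline=None, derandomize=True)
def test_nesting_holds_universally(presence, missing_frac):
    """RL(ii) ⊆ RL(i) ⊆ RL(iv) ⊆ RL(iii) on every generated dataset."""
    species = sorted(presence)
    n_missing = int(missing_frac * len(species) * 0.3)
    rare = species + [f"m{i}" for i in range(n_missing)]  # some lack reference rows
    ref = make_reference(presence)
    part = make_partition(common=["common1"], rare=rare)
    assignments = classify_all_definitions(part, ref)
    report = check_definition_nesting(assignments)
    assert report["ok"], report
    sizes = report["sizes"]
    assert sizes["ii"] <= sizes["i"] <= sizes["iv"] <= sizes["iii"]


def test_nesting_collapses_without_share_evidence():
    """With no species meeting any share threshold, RL(iii) = RL(iv) = RL(i)."""
    presence = {
        "r1": {HABITATS[0]: 0.001, HABITATS[1]: 0.002},
        "r2": {HABITATS[2]: 0.001},
        "r3": {},
    }
    ref = make_reference(presence)
    part = make_partition(common=[], rare=list(presence))
    a = classify_all_definitions(part, ref)
    assert (
        a["i"].species_with("rare_locally")
        == a["iii"].species_with("rare_locally")
        == a["iv"].species_with("rare_locally")
        == {"r1"}
    )


def test_pooled_share_mode_uses_regional_denominator():
    # share 0.012 in one of six habitats: pooled share 0.002 misses the 0.5%
    # threshold that the per-habitat reading meets
    ref = make_reference({"r1": {HABITATS[0]: 0.012}})
    part = make_partition(common=[], rare=["r1"])
    per = classify_rarity_status(part, ref, "iii", share_mode="per_habitat")
    pooled = classify_rarity_status(part, ref, "iii", share_mode="pooled")
    assert per.status["r1"] == "rare_locally"
    assert pooled.status["r1"] == "rare_throughout"
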