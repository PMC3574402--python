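"""Classify low-abundance species as rare locally versus rare throughout.

A species that is rare in the focal habitat may still be widespread or
abundant in other habitat types of the region ("rare locally"), or it may be
scarce everywhere ("rare throughout").  The distinction is drawn from an
independent reference table recording, for each species and each of several
other habitat types, presence and within-habitat relative abundance.

Four operational definitions of "rare locally" are supported:

===  ============================  =====================================
def  habitat criterion             abundance criterion (OR)
===  ============================  =====================================
i    present in >= 2 habitats      —
ii   present in >= 3 habitats      —
iii  present in >= 2 habitats      share >= 0.5% where present
iv   present in >= 2 habitats      share >= 1% where present
===  ============================  =====================================

The OR structure makes the four rare-locally sets nested:
RL(ii) ⊆ RL(i) ⊆ RL(iv) ⊆ RL(iii) for every dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .abundance import CommonRarePartition
from .data import ValidationError

__all__ = [
    "HABITATS",
    "RarityDefinition",
    "DEFINITIONS",
    "ReferenceHabitatTable",
    "parse_reference_table",
    "StatusAssignment",
    "classify_rarity_status",
    "classify_all_definitions",
    "check_definition_nesting",
]

#: canonical reference habitat types of the reserve (the focal lake
#: floating-meadow habitat itself is never part of this set)
HABITATS = (
    "open water",
    "banks and margins",
    "flooded forest",
    "floating meadow within channels",
    "forest temporary pools",
    "submerged dead trees",
)

STATUS_LEVELS = ("common", "rare_locally", "rare_throughout", "excluded")


@dataclass(frozen=True)
class RarityDefinition:
    """One operational definition of "rare locally"."""

    label: str
    min_habitats: int
    abundance_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.min_habitats < 1:
            raise ValueError("min_habitats must be >= 1")
        if self.abundance_threshold is not None and not 0 < self.abundance_threshold < 1:
            raise ValueError("abundance_threshold must lie in (0, 1)")


DEFINITIONS: dict[str, RarityDefinition] = {
    "i": RarityDefinition("i", min_habitats=2),
    "ii": RarityDefinition("ii", min_habitats=3),
    "iii": RarityDefinition("iii", min_habitats=2, abundance_threshold=0.005),
    "iv": RarityDefinition("iv", min_habitats=2, abundance_threshold=0.01),
}


@dataclass
class ReferenceHabitatTable:
    """Per-(species, habitat) presence and within-habitat relative abundance.

    ``rel_abund`` is the species' share of the habitat's own total abundance;
    it may be missing (NaN) for present species when only presence was
    recorded, and must be missing or zero where the species is absent.
    """

    table: pd.DataFrame
    habitats: tuple[str, ...] = HABITATS

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = ["species", "habitat", "present"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"reference table lacks columns {missing}")
        if "rel_abund" not in t.columns:
            t["rel_abund"] = np.nan
        t["species"] = t["species"].astype(str)
        t["habitat"] = t["habitat"].astype(str)
        if t["present"].dtype != bool:
            t["present"] = (
                t["present"].astype(str).str.strip().str.lower().map(
                    {"true": True, "false": False, "1": True, "0": False,
                     "yes": True, "no": False}
                )
            )
            if t["present"].isna().any():
                raise ValidationError("present column must be boolean")
        t["rel_abund"] = pd.to_numeric(t["rel_abund"], errors="coerce")
        unknown = sorted(set(t["habitat"]) - set(self.habitats))
        if unknown:
            raise ValidationError(f"habitats outside the declared set: {unknown}")
        bad = t["rel_abund"].notna() & ((t["rel_abund"] < 0) | (t["rel_abund"] > 1))
        if bad.any():
            raise ValidationError(f"rel_abund outside [0, 1]; rows {list(t.index[bad][:10])}")
        inconsistent = (~t["present"]) & t["rel_abund"].notna() & (t["rel_abund"] > 0)
        if inconsistent.any():
            raise ValidationError(
                f"positive rel_abund on absent rows {list(t.index[inconsistent][:10])}"
            )
        if t.duplicated(subset=["species", "habitat"]).any():
            raise ValidationError("duplicate (species, habitat) rows in reference table")
        self.table = t.sort_values(["species", "habitat"], kind="mergesort").reset_index(drop=True)

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())


def parse_reference_table(path: str | Path, habitats: Iterable[str] | None = None) -> ReferenceHabitatTable:
    frame = pd.read_csv(path, encoding="utf-8")
    habs = tuple(habitats) if habitats is not None else HABITATS
    return ReferenceHabitatTable(table=frame, habitats=habs)


@dataclass(frozen=True)
class StatusAssignment:
    """Per-species rarity status under one definition."""

    definition: RarityDefinition
    status: pd.Series  # species -> one of STATUS_LEVELS
    share_mode: str = "per_habitat"

    def species_with(self, label: str) -> frozenset:
        return frozenset(self.status.index[self.status == label])

    @property
    def counts(self) -> dict[str, int]:
        return {lvl: int((self.status == lvl).sum()) for lvl in STATUS_LEVELS}


def _habitat_evidence(
    reference: ReferenceHabitatTable,
    exclude_habitats: Iterable[str],
    share_mode: str,
) -> pd.DataFrame:
    """Per-species number of habitats present and best abundance share."""
    t = reference.table
    keep = ~t["habitat"].isin(set(exclude_habitats))
    t = t[keep]
    present = t[t["present"]]
    n_habitats = present.groupby("species").size()
    if share_mode == "per_habitat":
        # share within the single habitat where the species does best
        share = present.groupby("species")["rel_abund"].max()
    elif share_mode == "pooled":
        # share of the pooled regional total, assuming equal habitat totals
        n_declared = len([h for h in reference.habitats if h not in set(exclude_habitats)])
        share = present.groupby("species")["rel_abund"].sum() / max(n_declared, 1)
    else:
        raise ValueError("share_mode must be 'per_habitat' or 'pooled'")
    species = t["species"].unique()
    out = pd.DataFrame(index=pd.Index(sorted(species), name="species"))
    out["n_habitats"] = n_habitats.reindex(out.index).fillna(0).astype(int)
    out["best_share"] = share.reindex(out.index).fillna(0.0)
    return out


def classify_rarity_status(
    partition: CommonRarePartition,
    reference: ReferenceHabitatTable,
    definition: RarityDefinition | str = "i",
    share_mode: str = "per_habitat",
    exclude_habitats: Iterable[str] = (),
) -> StatusAssignment:
    """Label every species common / rare_locally / rare_throughout / excluded.

    A rare species is *rare locally* when it is present in at least
    ``min_habitats`` other habitat types, or — for definitions carrying an
    abundance criterion — when its relative-abundance share in some habitat
    where it is present reaches the threshold.  Rare species with no row in
    the reference table carry no regional information and are *excluded*.
    Common species keep status *common* under every definition.
    """
    if isinstance(definition, str):
        definition = DEFINITIONS[definition]
    evidence = _habitat_evidence(reference, exclude_habitats, share_mode)
    status = pd.Series("common", index=pd.Index(sorted(partition.species), name="species"))
    for sp in partition.rare:
        if sp not in evidence.index:
            status[sp] = "excluded"
            continue
        n_hab = evidence.at[sp, "n_habitats"]
        share = evidence.at[sp, "best_share"]
        locally = n_hab >= definition.min_habitats
        if definition.abundance_threshold is not None and n_hab >= 1:
            locally = locally or share >= definition.abundance_threshold
        status[sp] = "rare_locally" if locally else "rare_throughout"
    return StatusAssignment(definition=definition, status=status, share_mode=share_mode)


def classify_all_definitions(
    partition: CommonRarePartition,
    reference: ReferenceHabitatTable,
    definitions: Mapping[str, RarityDefinition] | None = None,
    **kwargs,
) -> dict[str, StatusAssignment]:
    defs = definitions if definitions is not None else DEFINITIONS
    return {label: classify_rarity_status(partition, reference, d, **kwargs) for label, d in defs.items()}


#: expected subset chain of the rare-locally sets, a logical consequence of
#: the OR structure and of 0.01 >= 0.005
NESTING_CHAIN = (("ii", "i"), ("i", "iv"), ("iv", "iii"))


def check_definition_nesting(assignments: Mapping[str, StatusAssignment]) -> dict:
    """Verify RL(ii) ⊆ RL(i) ⊆ RL(iv) ⊆ RL(iii) and report set sizes.

    A violation indicates an implementation bug, never a data property.
    """
    needed = {"i", "ii", "iii", "iv"}
    if not needed <= set(assignments):
        raise ValueError(f"need assignments for definitions {sorted(needed)}")
    rl = {lbl: assignments[lbl].species_with("rare_locally") for lbl in needed}
    relations = []
    ok = True
    for inner, outer in NESTING_CHAIN:
        offenders = sorted(rl[inner] - rl[outer])
        holds = not offenders
        ok = ok and holds
        relations.append(
            {"subset": inner, "superset": outer, "holds": holds, "offenders": offenders}
        )
    return {
        "ok": ok,
        "relations": relations,
        "sizes": {lbl: len(rl[lbl]) for lbl in sorted(needed)},
    }
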