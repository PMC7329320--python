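"""The functional-gene panel.

Sixteen marker genes proxy the microbial populations carrying out the major
soil C, N and P transformations (cellulose/starch/xylan degradation,
nitrification, N fixation, nitrate reduction, denitrification, organic-P
mineralization and inorganic-P dissolution), plus two whole-community biomass
markers (bacterial 16S rRNA and fungal ITS) used as covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

C_CYCLING = "C_cycling"
N_CYCLING = "N_cycling"
P_CYCLING = "P_cycling"
BIOMASS = "biomass_marker"

FUNCTIONAL_GROUPS = (C_CYCLING, N_CYCLING, P_CYCLING)

#: gene -> (group, functional process)
_PANEL = {
    "fungcbhIR": (C_CYCLING, "cellulose degradation"),
    "GH74": (C_CYCLING, "cellulose degradation"),
    "GH31": (C_CYCLING, "starch degradation"),
    "GH51": (C_CYCLING, "xylan/arabinan degradation"),
    "amoA-a": (N_CYCLING, "nitrification (archaeal)"),
    "amoA-b": (N_CYCLING, "nitrification (bacterial)"),
    "nifH": (N_CYCLING, "nitrogen fixation"),
    "narG": (N_CYCLING, "nitrate reduction"),
    "nirK": (N_CYCLING, "denitrification"),
    "nirS": (N_CYCLING, "denitrification"),
    "norB": (N_CYCLING, "denitrification"),
    "nosZ": (N_CYCLING, "denitrification"),
    "phoD": (P_CYCLING, "organic P mineralization"),
    "phoC": (P_CYCLING, "organic P mineralization"),
    "BPP": (P_CYCLING, "phytic acid mineralization"),
    "pqqC": (P_CYCLING, "inorganic P dissolution"),
    "bact_16S": (BIOMASS, "bacterial biomass"),
    "fungal_ITS": (BIOMASS, "fungal biomass"),
}

FUNCTIONAL_GENES = tuple(g for g, (grp, _) in _PANEL.items() if grp != BIOMASS)
BIOMASS_MARKERS = tuple(g for g, (grp, _) in _PANEL.items() if grp == BIOMASS)
ALL_GENES = FUNCTIONAL_GENES + BIOMASS_MARKERS

TREATMENTS = ("control", "drying_wetting", "warming", "n_deposition")
STRESSORS = ("drying_wetting", "warming", "n_deposition")


@dataclass(frozen=True)
class GenePanel:
    """The marker-gene panel: gene name -> functional group and process."""

    genes: dict = field(default_factory=lambda: dict(_PANEL))

    @property
    def functional_genes(self) -> list[str]:
        return [g for g, (grp, _) in self.genes.items() if grp != BIOMASS]

    @property
    def biomass_markers(self) -> list[str]:
        return [g for g, (grp, _) in self.genes.items() if grp == BIOMASS]

    def group_of(self, gene: str) -> str:
        return self.genes[gene][0]

    def members(self, group: str) -> list[str]:
        return [g for g, (grp, _) in self.genes.items() if grp == group]


def default_panel() -> GenePanel:
    return GenePanel()


def group_genes(group: str, panel: GenePanel | None = None) -> list[str]:
    """Member genes of a functional group (C_cycling, N_cycling, P_cycling)."""
    panel = panel or default_panel()
    if group not in (FUNCTIONAL_GROUPS + (BIOMASS,)):
        raise KeyError(f"unknown functional group: {group!r}")
    return panel.members(group)
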