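"""Anatomical region sets used throughout the analysis.

Two fixed AAL-atlas region sets are analysed: a 24-ROI parieto-occipital
set (10 parietal, 12 occipital, 2 posterior cingulate) and the left/right
hippocampi. Synthetic cohorts may use arbitrary custom region sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field


_PARIETAL = [
    "Parietal_Sup_L", "Parietal_Sup_R",
    "Parietal_Inf_L", "Parietal_Inf_R",
    "SupraMarginal_L", "SupraMarginal_R",
    "Angular_L", "Angular_R",
    "Precuneus_L", "Precuneus_R",
]

_OCCIPITAL = [
    "Calcarine_L", "Calcarine_R",
    "Cuneus_L", "Cuneus_R",
    "Lingual_L", "Lingual_R",
    "Occipital_Sup_L", "Occipital_Sup_R",
    "Occipital_Mid_L", "Occipital_Mid_R",
    "Occipital_Inf_L", "Occipital_Inf_R",
]

_POST_CINGULATE = ["Cingulum_Post_L", "Cingulum_Post_R"]

PARIETO_OCCIPITAL_LABELS = tuple(_PARIETAL + _OCCIPITAL + _POST_CINGULATE)
HIPPOCAMPUS_LABELS = ("Hippocampus_L", "Hippocampus_R")


@dataclass(frozen=True)
class RegionSet:
    """A named set of ROI labels over which measures are averaged.

    The two canonical sets are :data:`PARIETO_OCCIPITAL` (exactly 24
    members) and :data:`HIPPOCAMPI` (exactly 2 members); custom sets of
    any size are allowed for synthetic data.
    """

    name: str
    members: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate ROI labels in region set {self.name!r}")
        if self.name == "parieto_occipital" and len(self.members) != 24:
            raise ValueError("parieto_occipital region set must have exactly 24 members")
        if self.name == "hippocampi" and len(self.members) != 2:
            raise ValueError("hippocampi region set must have exactly 2 members")

    def __len__(self) -> int:
        return len(self.members)


PARIETO_OCCIPITAL = RegionSet("parieto_occipital", PARIETO_OCCIPITAL_LABELS)
HIPPOCAMPI = RegionSet("hippocampi", HIPPOCAMPUS_LABELS)
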