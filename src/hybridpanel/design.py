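"""Constants describing the published hybrid-panel study design.

The panel was built from 18 wild-type parent strains. Mating-competent
derivatives (31 MATa and 33 MATalpha) were crossed in all MATa x MATalpha
combinations, and every hybrid was grown in six media (a control plus five
stress supplements). The numbers below are design inputs, not results: all
derived quantities (hybrid counts, pair counts, assay combinations) are
computed by enumeration from them.
"""

from __future__ import annotations

import itertools

import pandas as pd

__all__ = [
    "PARENT_STRAINS",
    "MEDIA",
    "N_MATA",
    "N_MATALPHA",
    "parent_table",
    "enumerate_crosses",
    "count_parent_pairs",
    "count_assay_combinations",
]

# strain code, ploidy (N), domestication status, clade
PARENT_STRAINS: list[tuple[str, int, str, str]] = [
    ("A2", 2, "domesticated", "Wine European"),
    ("B11", 2, "domesticated", "French dairy"),
    ("B5", 2, "domesticated", "Brazilian bioethanol"),
    ("B8", 2, "domesticated", "Mosaic beer"),
    ("C11", 4, "domesticated", "Mixed origin"),
    ("C2", 4, "domesticated", "African beer"),
    ("C6", 2, "domesticated", "French Guiana human"),
    ("C9", 2, "domesticated", "Mexican agave"),
    ("E1", 2, "domesticated", "Sake"),
    ("E10", 2, "domesticated", "African palm wine"),
    ("E4", 2, "wild", "Asian fermentation"),
    ("F12", 2, "wild", "Malaysian"),
    ("F3", 2, "wild", "Asian islands"),
    ("F6", 2, "wild", "American oak"),
    ("G6", 2, "wild", "Far East Asian"),
    ("G8", 2, "wild", "CHN II"),
    ("H6", 4, "domesticated", "Ale beer"),
    ("H9", 4, "domesticated", "Farmhouse beer"),
]

#: Growth media: minimal control plus five stress supplements.
MEDIA: list[str] = [
    "control",
    "ethanol_14pct",
    "nacl_1.5M",
    "lactic_0.15M",
    "acetic_0.05M",
    "hmf_0.05M",
]

#: Mating-competent roster sizes actually obtained in the study
#: (three parents were sterile; two spore-derived MATa clones were lost).
N_MATA: int = 31
N_MATALPHA: int = 33


def parent_table() -> pd.DataFrame:
    """Return the 18-parent design table as a DataFrame."""
    return pd.DataFrame(
        PARENT_STRAINS,
        columns=["strain_id", "ploidy", "domestication", "clade"],
    )


def enumerate_crosses(mata_ids: list[str], matalpha_ids: list[str]) -> list[tuple[str, str]]:
    """All MATa x MATalpha crosses between two rosters of mating-competent strains."""
    return [(a, b) for a in mata_ids for b in matalpha_ids]


def count_parent_pairs(parent_ids: list[str]) -> int:
    """Number of unordered pairs of distinct parents (no self-pairs)."""
    return sum(1 for _ in itertools.combinations(sorted(set(parent_ids)), 2))


def count_assay_combinations(n_hybrids: int, media: list[str] | None = None) -> int:
    """Hybrid x medium combinations in the growth assay design."""
    media = MEDIA if media is None else media
    return n_hybrids * len(media)
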