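"""Published community-level reference tables for the Yongxing Island
plant-pollinator community (South China Sea oceanic island; 29 plant
species, 45 flower-visitor species surveyed in one flowering season).

The raw per-stigma and per-visit records of that survey are not publicly
deposited; what is available are the printed per-species summary tables and
community totals.  This module ships those numbers so the package's
statistics can be recomputed from them: the floral-trait table (symmetry,
flower size in mm^2, heterospecific-pollen percentage) and the per-species
CP-HP pattern classification (pattern label, stigma count, and the chosen
fit's adjusted R^2, coefficient, F and p).  Species codes abbreviate Latin
binomials (e.g. Tri.cis = Tribulus cistoides).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "flower_trait_table",
    "pattern_table",
    "community_totals",
]

# species, symmetry (R radial / B bilateral), flower size mm^2, HP %
_TRAITS = [
    ("Bid.pil", "R", 488.5, 0.5),
    ("Can.mar", "B", 861.3, 11.3),
    ("Cle.vis", "B", 204.0, 0.9),
    ("Cor.sub", "R", 2235.1, 4.1),
    ("Eup.ato", "R", 188.0, 0.0),
    ("Eup.cya", "R", 2333.9, 3.9),
    ("Gue.spe", "R", 1069.4, 0.0),
    ("Ipo.pes", "R", 4454.6, 25.4),
    ("Ipo.vio", "R", 9415.9, 6.4),
    ("Mac.atr", "B", 427.6, 0.2),
    ("Mes.arg", "R", 22.9, 38.1),
    ("Mor.cit", "R", 260.7, 33.3),
    ("Pas.foe", "R", 1073.7, 2.3),
    ("Phy.nod", "B", 4.2, 1.9),
    ("Phy.min", "R", 142.1, 1.5),
    ("Sca.tac", "B", 405.7, 3.3),
    ("Ses.can", "B", 147.6, 1.1),
    ("Ses.por", "R", 148.0, 1.9),
    ("Sid.aln", "R", 136.7, 1.6),
    ("Sol.pho", "R", 47.4, 10.0),
    ("Sta.jam", "B", 177.1, 0.6),
    ("Sur.mar", "R", 102.7, 11.6),
    ("Ter.cat", "R", 45.5, 0.6),
    ("Tri.por", "B", 54.8, 0.2),
    ("Tri.cis", "R", 577.8, 41.8),
    ("Tri.pro", "R", 158.5, 0.5),
    ("Vig.mar", "B", 396.7, 10.3),
    ("Wed.bif", "R", 590.5, 1.2),
    ("Wed.tri", "R", 843.5, 4.2),
]

# species, n stigmas, pattern group, adjusted R^2, b, F, p (None = printed slash)
_PATTERNS = [
    ("Bid.pil", 54, "linear", 0.221, 0.008, 15.71, 0.001),
    ("Can.mar", 50, "linear", 0.388, 0.142, 22.52, 0.001),
    ("Cle.vis", 54, "linear", 0.511, 0.042, 16.66, 0.001),
    ("Cor.sub", 52, "exponential", 0.364, 0.003, 19.92, 0.001),
    ("Eup.ato", 50, "no_pattern", None, None, None, None),
    ("Eup.cya", 51, "no_pattern", -0.074, -0.012, 0.24, 0.636),
    ("Gue.spe", 51, "no_pattern", None, None, None, None),
    ("Ipo.pes", 50, "exponential", 0.175, 0.012, 10.53, 0.002),
    ("Ipo.vio", 58, "linear", 0.08, 0.048, 5.94, 0.018),
    ("Mac.atr", 52, "no_pattern", -0.021, 0.00001, 0.00, 0.962),
    ("Mes.arg", 50, "no_pattern", -0.041, 0.13, 0.06, 0.803),
    ("Mor.cit", 50, "no_pattern", 0.022, 0.01, 1.89, 0.177),
    ("Pas.foe", 54, "no_pattern", -0.01, 0.006, 0.47, 0.494),
    ("Phy.min", 50, "no_pattern", 0.036, 0.011, 2.85, 0.098),
    ("Phy.nod", 51, "no_pattern", -0.024, 0.002, 0.08, 0.778),
    ("Sca.tac", 52, "no_pattern", -0.015, 0.002, 0.26, 0.614),
    ("Ses.can", 52, "no_pattern", 0.005, 0.004, 1.26, 0.267),
    ("Ses.por", 52, "no_pattern", 0.002, -0.005, 1.13, 0.293),
    ("Sid.aln", 50, "no_pattern", -0.006, 0.017, 0.71, 0.404),
    ("Sol.pho", 50, "linear", 0.606, 0.417, 22.52, 0.001),
    ("Sta.jam", 50, "linear", 0.145, 0.034, 7.96, 0.007),
    ("Sur.mar", 50, "no_pattern", -0.039, -0.002, 0.26, 0.617),
    ("Ter.cat", 50, "no_pattern", -0.03, 0.00007, 0.01, 0.928),
    ("Tri.cis", 52, "exponential", 0.092, 0.007, 5.84, 0.02),
    ("Tri.por", 52, "no_pattern", -0.011, 0.001, 0.43, 0.517),
    ("Tri.pro", 54, "no_pattern", -0.017, 0.001, 0.11, 0.746),
    ("Vig.mar", 50, "no_pattern", -0.053, 0.035, 0.10, 0.754),
    ("Wed.bif", 53, "no_pattern", -0.018, 0.004, 0.07, 0.788),
    ("Wed.tri", 51, "exponential", 0.367, 0.004, 18.42, 0.001),
]

#: community-scale totals reported alongside the per-species tables
community_totals = {
    "n_plants": 29,
    "n_pollinators": 45,
    "n_links": 494,
    "n_stigmas_reported": 1494,
    "n_empty_stigmas": 84,
    "total_grains": 203865,
    "total_cp": 183244,
    "total_hp": 20621,
}


def flower_trait_table() -> pd.DataFrame:
    """Per-species floral symmetry, flower size (mm^2) and HP percentage."""
    df = pd.DataFrame(_TRAITS, columns=["species", "symmetry", "flower_size", "hp_pct"])
    return df.set_index("species")


def pattern_table() -> pd.DataFrame:
    """Per-species CP-HP pattern classification with the chosen-fit statistics.

    ``n_stigmas`` is the number of stigmas collected per species; species
    that received no HP grains carry NaN fit statistics (printed as
    slashes in the source table).
    """
    df = pd.DataFrame(
        _PATTERNS,
        columns=["species", "n_stigmas", "pattern_group", "adj_r_squared", "b", "F", "p"],
    )
    return df.set_index("species")
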