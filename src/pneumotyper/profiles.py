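"""Shipped default genus profiles for the murine lung/URT scenario.

The three tissue profiles (URT, lung_aspirate, lung_unique) are the published
mean relative abundances (percent) of genera present at >1% in at least one
group in the BALB/cJ study this package models; each is normalized to sum to
one when turned into a :class:`~pneumotyper.synth.GenusProfile`.  The murine
URT is dominated by *Streptococcus* (~75%) with a handful of oropharyngeal
genera; lung_aspirate mirrors the URT with traces of lung_unique genera;
lung_unique is diverse with no single dominant genus.

The contaminant profile carries the reagent/no-template-control signature
(*Pseudomonas* 53%, *Escherichia* 15%) padded with genera commonly reported
as kit/water contaminants.  The environmental profiles (cage bedding, rodent
chow, drinking water) are synthetic: they are constructed so bedding and chow
share community mass with lung_unique (and bedding additionally with URT via
*Streptococcus*) while drinking water is essentially disjoint from all tissue
groups, which is the qualitative structure the study reports.
"""

from __future__ import annotations

# Percent composition; "-" cells in the source table are simply absent here.
URT_PERCENT: dict[str, float] = {
    "Actinobacillus": 14.96,
    "Aggregatibacter": 3.83,
    "Candidatus": 0.01,
    "Flavobacterium": 0.01,
    "Haemophilus": 2.86,
    "Lactobacillus": 1.02,
    "Mannheimia": 1.89,
    "Streptococcus": 74.80,
}

LUNG_ASPIRATE_PERCENT: dict[str, float] = {
    "Actinobacillus": 11.18,
    "Aggregatibacter": 1.13,
    "Brevundimonas": 0.08,
    "Candidatus": 0.21,
    "Flavobacterium": 0.30,
    "Haemophilus": 2.00,
    "Lactobacillus": 0.78,
    "Mannheimia": 3.00,
    "Stenotrophomonas": 0.16,
    "Streptococcus": 72.21,
}

LUNG_UNIQUE_PERCENT: dict[str, float] = {
    "Acinetobacter": 3.01,
    "Actinobacillus": 1.84,
    "Aggregatibacter": 0.72,
    "Brevundimonas": 1.06,
    "Candidatus": 7.03,
    "Chryseobacterium": 1.42,
    "Desulfotomaculum": 1.44,
    "Eubacterium": 1.73,
    "Flavobacterium": 6.28,
    "Fluviicola": 1.32,
    "Geobacillus": 2.05,
    "Haemophilus": 0.18,
    "Lactobacillus": 0.60,
    "Legionella": 1.50,
    "Mannheimia": 0.12,
    "Methylobacterium": 1.84,
    "Paludibacter": 1.83,
    "Parvularcula": 2.58,
    "Povalibacter": 1.10,
    "Pseudomonas": 2.31,
    "Simiduia": 2.27,
    "Sphingomonas": 1.32,
    "Stenotrophomonas": 1.91,
    "Streptococcus": 14.49,
    "Variovorax": 1.53,
}

# Reagent / no-template-control signature.  Pseudomonas and Escherichia carry
# the published shares; the remainder is split over well-known kit contaminants.
CONTAMINANT_PERCENT: dict[str, float] = {
    "Pseudomonas": 53.0,
    "Escherichia": 15.0,
    "Ralstonia": 12.0,
    "Bradyrhizobium": 8.0,
    "Delftia": 7.0,
    "Herbaspirillum": 5.0,
}

# Synthetic environmental sources (see module docstring).
BEDDING_PERCENT: dict[str, float] = {
    "Streptococcus": 30.0,
    "Acinetobacter": 14.0,
    "Flavobacterium": 14.0,
    "Bacillus": 12.0,
    "Lactobacillus": 8.0,
    "Chryseobacterium": 6.0,
    "Candidatus": 6.0,
    "Paenibacillus": 6.0,
    "Corynebacterium": 4.0,
}

CHOW_PERCENT: dict[str, float] = {
    "Acinetobacter": 18.0,
    "Flavobacterium": 18.0,
    "Pantoea": 14.0,
    "Bacillus": 14.0,
    "Candidatus": 12.0,
    "Chryseobacterium": 9.0,
    "Paenibacillus": 8.0,
    "Methylobacterium": 7.0,
}

WATER_PERCENT: dict[str, float] = {
    "Ralstonia": 40.0,
    "Sphingobium": 30.0,
    "Limnohabitans": 30.0,
}


def genus_universe() -> list[str]:
    """Sorted union of all genera appearing in any shipped profile."""
    names: set[str] = set()
    for prof in (
        URT_PERCENT,
        LUNG_ASPIRATE_PERCENT,
        LUNG_UNIQUE_PERCENT,
        CONTAMINANT_PERCENT,
        BEDDING_PERCENT,
        CHOW_PERCENT,
        WATER_PERCENT,
    ):
        names.update(prof)
    return sorted(names)
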