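"""Reference constants and study-design defaults.

``PUBLISHED_GH2AX_RATES`` carries the published per-species rates of
γH2AX increase (% positive cells per year) as a downstream fixture: the
underlying per-individual figure data were never deposited, so these
slopes are inputs to cross-species analyses, not quantities this package
recomputes from raw data.

``study_cohort_configs`` returns the synthetic-cohort defaults emulating
the reported study design: the published per-species sample sizes and age
ranges, with the published rates as the generative truth.
"""

from __future__ import annotations

from .simulate import SpeciesSimConfig

__all__ = ["PUBLISHED_GH2AX_RATES", "STUDY_DESIGN", "study_cohort_configs"]

# Rate of γH2AX increase, % positive cells per year, as reported per species.
PUBLISHED_GH2AX_RATES: dict[str, float] = {
    "bottlenose dolphin": 0.115,
    "goat": 0.668,
    "reindeer": 1.24,
    "american flamingo": 0.180,
    "griffon vulture": 0.427,
    "loggerhead sea turtle": 0.137,
}

# Reported cohort design: (n individuals, (min age, max age) in years).
STUDY_DESIGN: dict[str, tuple[int, tuple[float, float]]] = {
    "bottlenose dolphin": (9, (8.6, 50.1)),
    "goat": (15, (0.85, 10.1)),
    "reindeer": (8, (1.44, 10.5)),
    "american flamingo": (15, (0.79, 50.1)),
    "griffon vulture": (6, (8.06, 21.4)),
    "loggerhead sea turtle": (3, (8.35, 43.7)),
}


def study_cohort_configs(cells_per_individual: int = 5000) -> list[SpeciesSimConfig]:
    """Synthetic-cohort configurations mirroring the reported study design.

    One config per species with the reported number of individuals and age
    range, the published γH2AX rate as the true damaged-fraction rate
    (converted from % to fraction per year), and a baseline damaged
    fraction of 0.5 so the young-reference median threshold splits the
    reference sample evenly.  The per-individual cell count is
    configurable because the source reports none for the damage assay.
    """
    configs = []
    for species, (n, age_range) in STUDY_DESIGN.items():
        configs.append(
            SpeciesSimConfig(
                species_name=species,
                baseline_positive_fraction=0.5,
                true_damage_rate=PUBLISHED_GH2AX_RATES[species] / 100.0,
                n_individuals=n,
                age_range=age_range,
                cells_per_individual=cells_per_individual,
            )
        )
    return configs
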