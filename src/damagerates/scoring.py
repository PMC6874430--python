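"""Young-reference percentile thresholds and per-individual percentages.

Two headline statistics are computed per individual:

* **% γH2AX-positive cells** — a cell is damage-positive when its
  pan-nuclear intensity is *strictly above* a threshold set at the 50th
  percentile of the intensities of a young reference sample of the same
  species.
* **% short telomeres** — a cell has short telomeres when its telomere
  fluorescence is *strictly below* a threshold set at the 25th percentile
  of the young reference sample's telomere fluorescence.

The percentile is computed by linear interpolation between closest order
statistics (with ``n`` sorted values the threshold sits at fractional rank
``(p/100)·(n−1)``), so a continuous even-sized reference scored against its
own median is 50.0% positive by construction.  Ties go to
negative/not-short.  The reference is, by default, the youngest individual
of each species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceThreshold",
    "percentile_threshold",
    "pct_positive",
    "pct_short_telomeres",
    "compute_reference_thresholds",
    "summarize_individuals",
]

DAMAGE_PERCENTILE = 50.0
SHORT_TELOMERE_PERCENTILE = 25.0


@dataclass(frozen=True)
class ReferenceThreshold:
    """A young-reference percentile threshold for one species and statistic."""

    species: str
    statistic: str  # "gh2ax_positivity" | "short_telomere"
    percentile: float
    threshold_value: float
    reference_individual: str
    n_reference_cells: int


def percentile_threshold(values, percentile: float) -> float:
    """Percentile by linear interpolation between closest order statistics.

    With sorted values ``v_0 … v_{n-1}`` the returned value is
    ``v_⌊h⌋ + (h−⌊h⌋)·(v_{⌊h⌋+1} − v_⌊h⌋)`` at ``h = (percentile/100)·(n−1)``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to set a threshold")
    if not np.all(np.isfinite(arr)):
        raise ValueError("threshold values must be finite")
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie strictly between 0 and 100")
    return float(np.percentile(arr, percentile, method="linear"))


def pct_positive(cell_intensities, threshold: float) -> float:
    """Percent of cells whose intensity is strictly greater than ``threshold``."""
    arr = np.asarray(cell_intensities, dtype=float)
    if arr.size == 0:
        raise ValueError("empty cell list")
    return 100.0 * float(np.count_nonzero(arr > threshold)) / arr.size


def pct_short_telomeres(cell_values, threshold: float) -> float:
    """Percent of cells whose telomere fluorescence is strictly below ``threshold``."""
    arr = np.asarray(cell_values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty cell list")
    return 100.0 * float(np.count_nonzero(arr < threshold)) / arr.size


def _reference_individual(group: pd.DataFrame, rule: str | dict) -> str:
    """Pick the reference individual: youngest by default, or an explicit mapping."""
    species = group["species"].iloc[0]
    if isinstance(rule, dict):
        if species not in rule:
            raise ValueError(f"no reference individual configured for species {species!r}")
        return rule[species]
    if rule != "youngest":
        raise ValueError(f"unknown reference rule {rule!r}")
    per_ind = group.groupby("individual_id")["age"].first().sort_values(kind="stable")
    return str(per_ind.index[0])


def compute_reference_thresholds(
    cells: pd.DataFrame,
    damage_percentile: float = DAMAGE_PERCENTILE,
    telomere_percentile: float = SHORT_TELOMERE_PERCENTILE,
    reference: str | dict = "youngest",
) -> dict[tuple[str, str], ReferenceThreshold]:
    """Per-species thresholds from the young reference individual's cells.

    ``cells`` must carry columns ``species``, ``individual_id``, ``age``
    and at least one of ``gh2ax_intensity`` / ``telomere_fluorescence``.
    Returns a dict keyed by ``(species, statistic)``.
    """
    thresholds: dict[tuple[str, str], ReferenceThreshold] = {}
    for species, group in cells.groupby("species", sort=True):
        ref_id = _reference_individual(group, reference)
        ref_cells = group[group["individual_id"] == ref_id]
        if ref_cells.empty:
            raise ValueError(f"reference individual {ref_id!r} not found for {species!r}")
        if "gh2ax_intensity" in group.columns:
            thresholds[(species, "gh2ax_positivity")] = ReferenceThreshold(
                species=str(species),
                statistic="gh2ax_positivity",
                percentile=damage_percentile,
                threshold_value=percentile_threshold(
                    ref_cells["gh2ax_intensity"], damage_percentile
                ),
                reference_individual=ref_id,
                n_reference_cells=len(ref_cells),
            )
        if "telomere_fluorescence" in group.columns:
            thresholds[(species, "short_telomere")] = ReferenceThreshold(
                species=str(species),
                statistic="short_telomere",
                percentile=telomere_percentile,
                threshold_value=percentile_threshold(
                    ref_cells["telomere_fluorescence"], telomere_percentile
                ),
                reference_individual=ref_id,
                n_reference_cells=len(ref_cells),
            )
    return thresholds


def summarize_individuals(
    cells: pd.DataFrame,
    thresholds: dict[tuple[str, str], ReferenceThreshold],
    tif_percentages: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score every individual against its species' fixed reference thresholds.

    The thresholds are computed once from the reference individual and
    reused for every individual of the species, including the reference
    itself.  Returns one row per individual with columns ``species``,
    ``individual_id``, ``age``, ``pct_gh2ax_positive``,
    ``pct_short_telomeres``, ``n_cells`` (and ``pct_cells_with_tif`` when
    ``tif_percentages`` is supplied with columns ``species``,
    ``individual_id``, ``pct_cells_with_tif``).
    """
    rows = []
    for (species, ind), group in cells.groupby(["species", "individual_id"], sort=True):
        row: dict = {
            "species": species,
            "individual_id": ind,
            "age": float(group["age"].iloc[0]),
            "n_cells": len(group),
        }
        if "gh2ax_intensity" in group.columns:
            key = (species, "gh2ax_positivity")
            if key not in thresholds:
                raise ValueError(f"species {species!r} has no damage threshold")
            row["pct_gh2ax_positive"] = pct_positive(
                group["gh2ax_intensity"], thresholds[key].threshold_value
            )
        if "telomere_fluorescence" in group.columns:
            key = (species, "short_telomere")
            if key not in thresholds:
                raise ValueError(f"species {species!r} has no short-telomere threshold")
            row["pct_short_telomeres"] = pct_short_telomeres(
                group["telomere_fluorescence"], thresholds[key].threshold_value
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    if tif_percentages is not None:
        out = out.merge(
            tif_percentages[["species", "individual_id", "pct_cells_with_tif"]],
            on=["species", "individual_id"],
            how="left",
        )
    return out


def thresholds_to_records(thresholds: dict[tuple[str, str], ReferenceThreshold]) -> list[dict]:
    """JSON-serialisable records for a thresholds mapping."""
    return [vars(t) for _, t in sorted(thresholds.items())]
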