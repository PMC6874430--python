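"""Synthetic cohorts and synthetic fluorescence microscopy fields.

The generator emulates the statistical structure of a cross-sectional
leukocyte aging study: each individual is sampled at a single age, each of
its cells carries a pan-nuclear DNA-damage (γH2AX) intensity drawn from a
two-component lognormal mixture whose damaged fraction rises linearly with
age, and a per-cell telomere fluorescence that declines exponentially with
age.  Image rendering produces 2D high-content-screening-like fields
(nuclear stain + damage stain) and 3D confocal-like stacks (nuclear stain +
telomere spots + 53BP1 foci) with full ground truth, so every downstream
quantification step can be validated against known inputs.

All randomness flows from a single master seed; per-individual and
per-field substreams are derived by fixed arithmetic on ``(seed, index)``
so that tables and images are reproducible regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SpeciesSimConfig",
    "SyntheticImageSpec",
    "generate_cohort",
    "render_field_2d",
    "render_stack_3d",
    "write_cohort_csv",
    "read_cohort_csv",
]

# Columns of a cohort table.  The last two are ground truth: they exist only
# because the cohort is simulated, and are never consumed by the analysis.
COHORT_COLUMNS = [
    "species",
    "individual_id",
    "age",
    "cell_id",
    "gh2ax_intensity",
    "telomere_fluorescence",
    "is_damaged",
    "true_positive_fraction",
]


@dataclass(frozen=True)
class SpeciesSimConfig:
    """Generative parameters for one species' cross-sectional cohort.

    Parameters
    ----------
    species_name
        Label used in the output tables.
    baseline_positive_fraction
        Damaged-cell fraction at age 0 (``p0``), in [0, 1].
    true_damage_rate
        Increase of the damaged fraction per year (``r``); the fraction at
        age ``a`` is ``clip(p0 + r * a, 0, 1)``.
    intensity_neg, intensity_pos
        ``(log-mean, log-sd)`` of the lognormal γH2AX intensity of
        undamaged and damaged cells (arbitrary units).  The damaged
        component must sit above the undamaged one.
    telomere_log_mean_at_birth
        Log-mean of per-cell telomere fluorescence at age 0 (a.u.).
    telomere_decline_per_year
        Decline of the telomere log-mean per year of age.
    telomere_log_sd
        Log-sd of per-cell telomere fluorescence.
    n_individuals, age_range, cells_per_individual
        Cohort design: number of animals, (min, max) ages in years from
        which individual ages are drawn uniformly, and cells measured per
        animal.
    """

    species_name: str
    baseline_positive_fraction: float = 0.5
    true_damage_rate: float = 0.005
    intensity_neg: tuple[float, float] = (4.0, 0.3)
    intensity_pos: tuple[float, float] = (5.5, 0.3)
    telomere_log_mean_at_birth: float = 8.0
    telomere_decline_per_year: float = 0.01
    telomere_log_sd: float = 0.5
    n_individuals: int = 10
    age_range: tuple[float, float] = (0.0, 20.0)
    cells_per_individual: int = 5000

    def __post_init__(self) -> None:
        values = [
            self.baseline_positive_fraction,
            self.true_damage_rate,
            *self.intensity_neg,
            *self.intensity_pos,
            self.telomere_log_mean_at_birth,
            self.telomere_decline_per_year,
            self.telomere_log_sd,
            *self.age_range,
        ]
        if not all(math.isfinite(v) for v in values):
            raise ValueError("SpeciesSimConfig contains non-finite values")
        if not 0.0 <= self.baseline_positive_fraction <= 1.0:
            raise ValueError("baseline_positive_fraction must lie in [0, 1]")
        if self.intensity_pos[0] <= self.intensity_neg[0]:
            raise ValueError(
                "damaged-cell log-mean intensity must exceed the undamaged one"
            )
        if self.intensity_neg[1] <= 0 or self.intensity_pos[1] <= 0:
            raise ValueError("intensity log-sd values must be positive")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range is inverted")
        if self.age_range[0] < 0:
            raise ValueError("ages must be non-negative")
        if self.n_individuals < 1 or self.cells_per_individual < 1:
            raise ValueError("counts must be >= 1")


def _substream(seed: int, *indices: int) -> np.random.Generator:
    """Deterministic child stream for (seed, index...) independent of call order."""
    return np.random.default_rng([int(seed)] + [int(i) for i in indices])


def generate_cohort(config: SpeciesSimConfig, seed: int) -> pd.DataFrame:
    """Simulate one species' cross-sectional cohort as a per-cell table.

    Each individual gets a single uniformly drawn age (cross-sectional: one
    timepoint per animal).  Each cell is damaged with probability
    ``clip(p0 + r * age, 0, 1)``; its γH2AX intensity is drawn from the
    damaged or undamaged lognormal component accordingly, and its telomere
    fluorescence from a lognormal whose log-mean declines linearly with
    age.  Ground-truth columns (``is_damaged``, ``true_positive_fraction``)
    are included.  Identical ``(config, seed)`` yields an identical table.
    """
    cfg = config
    age_rng = _substream(seed, 0)
    ages = age_rng.uniform(cfg.age_range[0], cfg.age_range[1], cfg.n_individuals)

    frames = []
    n = cfg.cells_per_individual
    for i, age in enumerate(ages):
        rng = _substream(seed, i + 1)
        p = float(np.clip(cfg.baseline_positive_fraction + cfg.true_damage_rate * age, 0.0, 1.0))
        damaged = rng.random(n) < p
        log_mu = np.where(damaged, cfg.intensity_pos[0], cfg.intensity_neg[0])
        log_sd = np.where(damaged, cfg.intensity_pos[1], cfg.intensity_neg[1])
        gh2ax = np.exp(rng.normal(log_mu, log_sd))
        tel_mu = cfg.telomere_log_mean_at_birth - cfg.telomere_decline_per_year * age
        telomere = np.exp(rng.normal(tel_mu, cfg.telomere_log_sd, n))
        frames.append(
            pd.DataFrame(
                {
                    "species": cfg.species_name,
                    "individual_id": f"{cfg.species_name}_{i:03d}",
                    "age": age,
                    "cell_id": np.arange(n),
                    "gh2ax_intensity": gh2ax,
                    "telomere_fluorescence": telomere,
                    "is_damaged": damaged,
                    "true_positive_fraction": p,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Layout and noise parameters of a synthetic microscopy field.

    ``field_shape`` is ``(y, x)`` pixels for a 2D field or ``(z, y, x)``
    voxels for a confocal-like stack.  ``nucleus_axes`` gives one
    ``(min, max)`` radius range per axis.  Foci (3D only) are rendered as
    Gaussian blobs; ``tif_pairs`` telomere/53BP1 centroid pairs are made
    exactly coincident and ``edge_spots`` extra 53BP1 spots are dropped
    into the rim band (distance-to-boundary ≤ ``rim_margin``) of nuclei.
    """

    field_shape: tuple[int, ...] = (512, 512)
    n_nuclei: int = 20
    nucleus_axes: tuple[tuple[float, float], ...] = ((8.0, 13.0), (6.0, 10.0))
    psf_sigma: float = 1.0
    background_level: float = 10.0
    shot_noise: bool = True
    gain: float = 1.0
    nuclear_level: float = 500.0
    foci_per_nucleus: dict = field(default_factory=lambda: {"telomere": 3, "53bp1": 2})
    spot_amplitude: dict = field(default_factory=lambda: {"telomere": 1000.0, "53bp1": 800.0})
    spot_sigma: float = 0.8
    tif_pairs: int = 0
    edge_spots: int = 0
    rim_margin: float = 2.0
    min_spot_separation: float = 7.0
    border_margin: float = 2.0
    seed: int = 0

    @property
    def is_3d(self) -> bool:
        return len(self.field_shape) == 3

    def __post_init__(self) -> None:
        if len(self.field_shape) not in (2, 3):
            raise ValueError("field_shape must be 2D or 3D")
        if len(self.nucleus_axes) != len(self.field_shape):
            raise ValueError("nucleus_axes must give one (min, max) range per axis")
        if self.n_nuclei < 0 or self.tif_pairs < 0 or self.edge_spots < 0:
            raise ValueError("counts must be non-negative")
        for lo, hi in self.nucleus_axes:
            if lo <= 0 or hi < lo:
                raise ValueError("nucleus axis ranges must be positive and ordered")


def _place_nuclei(
    spec: SyntheticImageSpec, rng: np.random.Generator, max_attempts_per_nucleus: int = 500
) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Rejection-sample non-overlapping nucleus (center, radii, rotation) triples.

    Overlap is checked on bounding spheres; nuclei are kept at least
    ``border_margin`` inside the field so blur does not clip them.
    """
    shape = np.asarray(spec.field_shape, dtype=float)
    placed: list[tuple[np.ndarray, np.ndarray, float]] = []
    attempts = 0
    budget = max(1, spec.n_nuclei) * max_attempts_per_nucleus
    while len(placed) < spec.n_nuclei:
        if attempts > budget:
            raise RuntimeError(
                f"could not place {spec.n_nuclei} non-overlapping nuclei in "
                f"{spec.field_shape} after {budget} attempts"
            )
        attempts += 1
        radii = np.array([rng.uniform(lo, hi) for lo, hi in spec.nucleus_axes])
        bound = radii.max()
        lo = radii + spec.border_margin
        hi = shape - radii - spec.border_margin
        if np.any(hi <= lo):
            raise RuntimeError("field too small for the configured nucleus radii")
        center = rng.uniform(lo, hi)
        ok = True
        for c2, r2, _ in placed:
            if np.linalg.norm(center - c2) <= bound + r2.max() + 1.0:
                ok = False
                break
        if ok:
            rotation = float(rng.uniform(0, np.pi)) if not spec.is_3d else 0.0
            placed.append((center, radii, rotation))
    return placed


def _ellipse_mask_2d(shape, center, radii, rotation) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of an axis-rotated filled ellipse, clipped to ``shape``."""
    from skimage.draw import ellipse

    rr, cc = ellipse(center[0], center[1], radii[0], radii[1], shape=shape, rotation=rotation)
    return rr, cc


def _ellipsoid_mask_3d(shape, center, radii) -> tuple[np.ndarray, ...]:
    lo = np.maximum(np.floor(center - radii).astype(int), 0)
    hi = np.minimum(np.ceil(center + radii).astype(int) + 1, shape)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    dist = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    inside = dist <= 1.0
    return tuple(g[inside] for g in grids)


def _apply_optics(channels: np.ndarray, spec: SyntheticImageSpec, rng: np.random.Generator) -> np.ndarray:
    """Gaussian PSF blur then (optionally) Poisson shot noise, per channel."""
    out = np.empty_like(channels, dtype=float)
    for c in range(channels.shape[0]):
        img = channels[c]
        if spec.psf_sigma > 0:
            img = ndimage.gaussian_filter(img, spec.psf_sigma, mode="constant", cval=spec.background_level)
        if spec.shot_noise:
            img = rng.poisson(np.maximum(img * spec.gain, 0.0)) / spec.gain
        out[c] = img
    return out


def render_field_2d(
    spec: SyntheticImageSpec, cell_assignments: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Render a two-channel 2D field (nuclear stain, damage stain).

    Nucleus ``i`` is a filled ellipse whose damage-channel value, before
    blur and noise, is ``background_level + cell_assignments[i]``.  Returns
    ``(image, labels)`` where ``image`` has shape ``(2, y, x)`` and
    ``labels`` is the unblurred ground-truth label map (0 = background,
    nuclei labelled 1..n in placement order).
    """
    if spec.is_3d:
        raise ValueError("render_field_2d requires a 2D field_shape")
    if len(cell_assignments) != spec.n_nuclei:
        raise ValueError("need one damage intensity per nucleus")
    rng = _substream(spec.seed, 101)
    nuclei = _place_nuclei(spec, rng)

    labels = np.zeros(spec.field_shape, dtype=np.int32)
    nuclear = np.full(spec.field_shape, float(spec.background_level))
    damage = np.full(spec.field_shape, float(spec.background_level))
    for i, (center, radii, rotation) in enumerate(nuclei):
        rr, cc = _ellipse_mask_2d(spec.field_shape, center, radii, rotation)
        labels[rr, cc] = i + 1
        nuclear[rr, cc] = spec.background_level + spec.nuclear_level
        damage[rr, cc] = spec.background_level + float(cell_assignments[i])

    image = _apply_optics(np.stack([nuclear, damage]), spec, _substream(spec.seed, 102))
    return image, labels


def render_stack_3d(spec: SyntheticImageSpec) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Render a three-channel 3D stack (nuclear, telomere, 53BP1) with ground truth.

    Telomere and 53BP1 foci are Gaussian blobs at recorded voxel centroids.
    Exactly ``spec.tif_pairs`` 53BP1 centroids coincide with telomere
    centroids (constructed TIFs), and ``spec.edge_spots`` extra 53BP1
    centroids are placed in the nuclear rim band.  Returns
    ``(stack, labels, foci)`` where ``stack`` has shape ``(3, z, y, x)``,
    ``labels`` is the ground-truth nucleus label map and ``foci`` is a list
    of dicts with keys ``channel``, ``centroid`` (z, y, x), ``nucleus``,
    ``intensity`` (sum of the rendered blob before blur/noise),
    ``is_tif_pair`` and ``near_rim``.
    """
    if not spec.is_3d:
        raise ValueError("render_stack_3d requires a 3D field_shape")
    n_tel = int(spec.foci_per_nucleus.get("telomere", 0))
    n_53 = int(spec.foci_per_nucleus.get("53bp1", 0))
    if spec.n_nuclei > 0 and spec.tif_pairs > spec.n_nuclei * min(n_tel, n_53):
        raise ValueError("tif_pairs exceeds the available foci per channel")

    rng = _substream(spec.seed, 201)
    nuclei = _place_nuclei(spec, rng)
    shape = spec.field_shape

    labels = np.zeros(shape, dtype=np.int32)
    for i, (center, radii, _) in enumerate(nuclei):
        idx = _ellipsoid_mask_3d(np.asarray(shape), center, radii)
        labels[idx] = i + 1

    nuclear = np.full(shape, float(spec.background_level))
    nuclear[labels > 0] += spec.nuclear_level
    telomere_ch = np.full(shape, float(spec.background_level))
    bp1_ch = np.full(shape, float(spec.background_level))

    # Candidate voxels per nucleus: the interior (safely away from the rim,
    # so detected spots are not rim-flagged) and the rim band itself.
    interior: dict[int, np.ndarray] = {}
    rim_band: dict[int, np.ndarray] = {}
    for lab in range(1, spec.n_nuclei + 1):
        mask = labels == lab
        edt = ndimage.distance_transform_edt(mask)
        interior[lab] = np.argwhere(edt >= spec.rim_margin + 2.0)
        rim_band[lab] = np.argwhere((edt > 0) & (edt <= spec.rim_margin))

    spot_rng = _substream(spec.seed, 202)
    foci: list[dict] = []
    positions: list[np.ndarray] = []

    def _pick(candidates: np.ndarray) -> np.ndarray:
        """Draw a candidate voxel at least min_spot_separation from all spots."""
        order = spot_rng.permutation(len(candidates))
        for j in order:
            p = candidates[j].astype(float)
            if all(np.linalg.norm(p - q) >= spec.min_spot_separation for q in positions):
                return p
        raise RuntimeError(
            "could not place a focus with the required separation; "
            "reduce foci counts or enlarge nuclei"
        )

    def _render_blob(channel: np.ndarray, center: np.ndarray, amplitude: float) -> float:
        r = int(math.ceil(5 * spec.spot_sigma))
        lo = np.maximum(np.floor(center).astype(int) - r, 0)
        hi = np.minimum(np.floor(center).astype(int) + r + 1, shape)
        grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        blob = amplitude * np.exp(-d2 / (2 * spec.spot_sigma**2))
        channel[tuple(g for g in grids)] += blob
        return float(blob.sum())

    # Interior telomere foci, then 53BP1: the first `tif_pairs` 53BP1 spots
    # (spread round-robin over nuclei) reuse a telomere centroid.
    tel_by_nucleus: dict[int, list[int]] = {}
    for lab in range(1, spec.n_nuclei + 1):
        tel_by_nucleus[lab] = []
        if len(interior[lab]) == 0 and n_tel > 0:
            raise RuntimeError("nucleus too small for interior foci; enlarge nucleus_axes")
        for _ in range(n_tel):
            p = _pick(interior[lab])
            positions.append(p)
            total = _render_blob(telomere_ch, p, spec.spot_amplitude["telomere"])
            foci.append(
                {
                    "channel": "telomere",
                    "centroid": tuple(float(v) for v in p),
                    "nucleus": lab,
                    "intensity": total,
                    "is_tif_pair": False,
                    "near_rim": False,
                }
            )
            tel_by_nucleus[lab].append(len(foci) - 1)

    pairs_left = spec.tif_pairs
    for lab in range(1, spec.n_nuclei + 1):
        n_pairs_here = 0
        for k in range(n_53):
            if pairs_left > 0 and k < len(tel_by_nucleus[lab]):
                tel_idx = tel_by_nucleus[lab][k]
                p = np.asarray(foci[tel_idx]["centroid"])
                foci[tel_idx]["is_tif_pair"] = True
                pairs_left -= 1
                n_pairs_here += 1
                is_pair = True
            else:
                p = _pick(interior[lab])
                positions.append(p)
                is_pair = False
            total = _render_blob(bp1_ch, p, spec.spot_amplitude["53bp1"])
            foci.append(
                {
                    "channel": "53bp1",
                    "centroid": tuple(float(v) for v in p),
                    "nucleus": lab,
                    "intensity": total,
                    "is_tif_pair": is_pair,
                    "near_rim": False,
                }
            )
    if pairs_left > 0:
        raise RuntimeError("failed to construct the requested number of TIF pairs")

    for k in range(spec.edge_spots):
        lab = 1 + k % max(spec.n_nuclei, 1)
        if len(rim_band[lab]) == 0:
            raise RuntimeError("nucleus rim band is empty; enlarge nucleus_axes")
        p = _pick(rim_band[lab])
        positions.append(p)
        total = _render_blob(bp1_ch, p, spec.spot_amplitude["53bp1"])
        foci.append(
            {
                "channel": "53bp1",
                "centroid": tuple(float(v) for v in p),
                "nucleus": lab,
                "intensity": total,
                "is_tif_pair": False,
                "near_rim": True,
            }
        )

    stack = _apply_optics(
        np.stack([nuclear, telomere_ch, bp1_ch]), spec, _substream(spec.seed, 203)
    )
    return stack, labels, foci


def write_tiff(image: np.ndarray, path) -> None:
    """Write a (channel, [z,] y, x) float image as 16-bit unsigned TIFF."""
    import tifffile

    clipped = np.clip(np.round(image), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, clipped)


def read_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path).astype(float)
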