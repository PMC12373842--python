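"""Synthetic 3D-colony drug screen generator.

Emulates the structure of a 384-well morphology screen: ~1000 compounds at
three doses spread over nine plates, 14 vehicle (DMSO) and 14 positive
(re-epithelializing) control wells per plate, multiplicative plate-to-plate
variation, additive row/column positional artifacts, planted hit compounds
(larger, lumen-forming colonies) and cytotoxic compounds (reduced colony
counts). Also renders idealized fluorescence well images of cystic
(hollow, annular) and spiky (star-shaped, solid) colonies with noise-free
ground-truth label masks.

Noise model: per-well median colony area is log-normal (mean-preserving)
around baseline x plate effect x hit multiplier, plus additive positional
effects; the lumen-bearing colony fraction is beta-binomial given the
well's colony count; colony counts are Poisson. ``cv_noise = 0`` switches
the generator to a fully deterministic, noise-free mode.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .analytics import FeatureMatrix
from .layout import PlateLayout, default_384_layout, parse_well, well_name

GATING_FEATURES = ("median_colony_area", "pct_colonies_with_lumens")

#: Extra per-well morphology features (name -> (baseline, cystic slope, noise SD)).
#: They carry the same cystic/spiky signal as the gating metrics and give the
#: PCA morphospace more than two dimensions to work with.
EXTRA_FEATURE_MODEL: Mapping[str, Tuple[float, float, float]] = {
    "median_circularity": (0.45, 0.35, 0.04),
    "mean_intensity": (5000.0, 1000.0, 500.0),
    "texture_energy": (0.20, 0.10, 0.03),
    "texture_entropy": (4.0, -0.8, 0.30),
}


@dataclass(frozen=True)
class HitSpec:
    """A planted hit: multiplies median area and shifts the lumen fraction."""

    compound_id: str
    area_multiplier: float = 3.0
    lumen_shift: float = 0.4
    concentrations: Optional[Tuple[float, ...]] = None  # None = all doses

    def __post_init__(self) -> None:
        if self.area_multiplier <= 0:
            raise ValueError("effect multiplier must be > 0")


@dataclass(frozen=True)
class DeadSpec:
    """A planted cytotoxic compound: scales the expected colony count."""

    compound_id: str
    survival_fraction: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.survival_fraction <= 1.0:
            raise ValueError("survival fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticScreenConfig:
    n_compounds: int = 1059
    concentrations: Tuple[float, ...] = (0.1, 1.0, 10.0)
    seed: int = 0
    baseline_median_area: float = 2500.0  # px^2
    baseline_pct_lumens: float = 0.10  # fraction of colonies with a lumen
    baseline_colony_count: float = 60.0
    cv_noise: float = 0.10
    plate_effect_sd: float = 0.05  # log-scale multiplicative SD
    # additive positional amplitudes, per metric (peak of a +/-amp gradient)
    row_effect_amp: Mapping[str, float] = field(
        default_factory=lambda: {"median_colony_area": 250.0, "pct_colonies_with_lumens": 0.015}
    )
    col_effect_amp: Mapping[str, float] = field(
        default_factory=lambda: {"median_colony_area": 250.0, "pct_colonies_with_lumens": 0.015}
    )
    hit_compounds: Tuple[HitSpec, ...] = ()
    dead_compounds: Tuple[DeadSpec, ...] = ()
    positive_area_multiplier: float = 3.0
    positive_lumen_shift: float = 0.40
    lumen_overdispersion: float = 0.02  # beta-binomial rho
    extra_features: Tuple[str, ...] = tuple(EXTRA_FEATURE_MODEL)

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_pct_lumens <= 1.0:
            raise ValueError("baseline_pct_lumens must be in [0, 1]")
        if self.cv_noise < 0:
            raise ValueError("cv_noise must be >= 0")
        if not 0.0 <= self.lumen_overdispersion < 1.0:
            raise ValueError("lumen_overdispersion must be in [0, 1)")
        for name in self.extra_features:
            if name not in EXTRA_FEATURE_MODEL:
                raise ValueError(f"unknown extra feature: {name}")
        for specs, kind in ((self.hit_compounds, "hit"), (self.dead_compounds, "dead")):
            ids = [s.compound_id for s in specs]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicated {kind} compound ids")

    def compound_ids(self) -> List[str]:
        return [f"C{i + 1:04d}" for i in range(self.n_compounds)]


@dataclass
class SyntheticGroundTruth:
    """Planted structure of a simulated screen, for recovery testing."""

    hit_wells: List[dict]  # plate_id, well, compound_id, concentration, effects
    dead_wells: List[dict]
    plate_effects: Dict[str, float]
    row_effects: Dict[str, Dict[str, List[float]]]  # plate -> metric -> vector
    col_effects: Dict[str, Dict[str, List[float]]]
    seed: int = 0

    def hit_well_keys(self) -> set:
        return {(h["plate_id"], h["well"]) for h in self.hit_wells}

    def dead_well_keys(self) -> set:
        return {(d["plate_id"], d["well"]) for d in self.dead_wells}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticGroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


def _beta_binomial_fraction(
    rng: np.random.Generator, p: float, n: int, rho: float
) -> float:
    """Fraction k/n with k ~ BetaBinomial(n, p, rho); degenerate p handled."""
    if n <= 0:
        return float("nan")
    if p <= 0.0:
        return 0.0
    if p >= 1.0:
        return 1.0
    if rho > 0:
        a = p * (1.0 - rho) / rho
        b = (1.0 - p) * (1.0 - rho) / rho
        q = rng.beta(a, b)
    else:
        q = p
    return rng.binomial(n, q) / n


def simulate_screen(
    config: SyntheticScreenConfig, layout: Optional[PlateLayout] = None
) -> Tuple[FeatureMatrix, SyntheticGroundTruth]:
    """Generate the per-well feature table of a synthetic screen.

    Compounds are laid out one well per compound x concentration, filling
    plates in row-major order while skipping control positions; the final
    plate's unused positions are marked ``empty``. Identical config (and
    seed) yields an identical table.
    """
    layout = layout or default_384_layout()
    if layout.compound_capacity <= 0:
        raise ValueError("layout has no compound capacity")
    doses = list(config.concentrations)
    assignments = [(cid, c) for cid in config.compound_ids() for c in doses]
    n_plates = math.ceil(len(assignments) / layout.compound_capacity)
    hits = {h.compound_id: h for h in config.hit_compounds}
    dead = {d.compound_id: d for d in config.dead_compounds}
    known = set(config.compound_ids())
    for cid in list(hits) + list(dead):
        if cid not in known:
            raise ValueError(f"planted compound id not in screen: {cid}")

    ss = np.random.SeedSequence(config.seed)
    plate_seeds = ss.spawn(n_plates)
    noise_free = config.cv_noise == 0

    rows_out: List[dict] = []
    gt = SyntheticGroundTruth([], [], {}, {}, {}, seed=config.seed)
    cursor = 0
    for p in range(n_plates):
        rng = np.random.default_rng(plate_seeds[p])
        plate_id = f"P{p + 1:02d}"
        plate_eff = 1.0 if noise_free and config.plate_effect_sd == 0 else float(
            np.exp(rng.normal(0.0, config.plate_effect_sd))
        )
        gt.plate_effects[plate_id] = plate_eff

        def gradient(n: int, amp: float) -> np.ndarray:
            if amp == 0:
                return np.zeros(n)
            return amp * np.linspace(-1.0, 1.0, n) * rng.choice([-1.0, 1.0])

        row_eff = {m: gradient(layout.n_rows, config.row_effect_amp.get(m, 0.0)) for m in GATING_FEATURES}
        col_eff = {m: gradient(layout.n_cols, config.col_effect_amp.get(m, 0.0)) for m in GATING_FEATURES}
        gt.row_effects[plate_id] = {m: row_eff[m].tolist() for m in GATING_FEATURES}
        gt.col_effects[plate_id] = {m: col_eff[m].tolist() for m in GATING_FEATURES}

        for well in layout.iter_wells():
            role = layout.role_of(well)
            compound_id: Optional[str] = None
            conc = float("nan")
            if role == "compound":
                if cursor < len(assignments):
                    compound_id, conc = assignments[cursor]
                    cursor += 1
                else:
                    role = "empty"

            area_mult, lumen_shift, survival = 1.0, 0.0, 1.0
            if role == "positive":
                area_mult = config.positive_area_multiplier
                lumen_shift = config.positive_lumen_shift
            elif role == "compound" and compound_id is not None:
                h = hits.get(compound_id)
                if h is not None and (h.concentrations is None or conc in h.concentrations):
                    area_mult, lumen_shift = h.area_multiplier, h.lumen_shift
                d = dead.get(compound_id)
                if d is not None:
                    survival = d.survival_fraction

            r_idx, c_num = parse_well(well)
            if role == "empty":
                rec = dict.fromkeys(
                    ("median_colony_area", "pct_colonies_with_lumens", "colony_count"),
                    float("nan"),
                )
                rec.update({name: float("nan") for name in config.extra_features})
            else:
                lam = config.baseline_colony_count * survival
                count = int(round(lam)) if noise_free else int(rng.poisson(lam))
                area = (
                    config.baseline_median_area
                    * plate_eff
                    * area_mult
                    * _lognormal_factor(rng, config.cv_noise, 1)[0]
                )
                area += row_eff["median_colony_area"][r_idx]
                area += col_eff["median_colony_area"][c_num - 1]
                area = max(area, 0.0)
                p_lumen = float(
                    np.clip(
                        config.baseline_pct_lumens
                        + lumen_shift
                        + row_eff["pct_colonies_with_lumens"][r_idx]
                        + col_eff["pct_colonies_with_lumens"][c_num - 1],
                        0.0,
                        1.0,
                    )
                )
                if noise_free:
                    pct = p_lumen
                else:
                    pct = _beta_binomial_fraction(rng, p_lumen, count, config.lumen_overdispersion)
                if count == 0:
                    area, pct = float("nan"), float("nan")
                rec = {
                    "median_colony_area": area,
                    "pct_colonies_with_lumens": pct,
                    "colony_count": count,
                }
                # cystic score in [0,1]: how strongly this well is pushed
                # toward the cystic phenotype, drives the extra features
                s = float(
                    np.clip(
                        0.5 * math.log(max(area_mult, 1e-9)) / math.log(3.0)
                        + 0.5 * min(lumen_shift / 0.4, 1.0) if (area_mult != 1.0 or lumen_shift != 0.0) else 0.0,
                        0.0,
                        1.0,
                    )
                )
                for name in config.extra_features:
                    base, slope, sd = EXTRA_FEATURE_MODEL[name]
                    val = base + slope * s
                    if not noise_free:
                        val += float(rng.normal(0.0, sd))
                    if name == "median_circularity":
                        val = float(np.clip(val, 0.0, 1.0))
                    rec[name] = val

            rows_out.append(
                {
                    "plate_id": plate_id,
                    "well": well,
                    "row": well[0],
                    "col": c_num,
                    "role": role,
                    "compound_id": compound_id,
                    "concentration_um": conc,
                    **rec,
                }
            )
            if role == "compound" and compound_id in hits:
                h = hits[compound_id]
                if h.concentrations is None or conc in h.concentrations:
                    gt.hit_wells.append(
                        {
                            "plate_id": plate_id,
                            "well": well,
                            "compound_id": compound_id,
                            "concentration_um": conc,
                            "area_multiplier": h.area_multiplier,
                            "lumen_shift": h.lumen_shift,
                        }
                    )
            if role == "compound" and compound_id in dead:
                gt.dead_wells.append(
                    {
                        "plate_id": plate_id,
                        "well": well,
                        "compound_id": compound_id,
                        "concentration_um": conc,
                        "survival_fraction": dead[compound_id].survival_fraction,
                    }
                )

    fm = FeatureMatrix(pd.DataFrame(rows_out))
    return fm, gt


def example_screen_config(
    seed: int = 0,
    n_hit_compounds: int = 6,
    n_dead_compounds: int = 20,
    area_multiplier: float = 3.0,
    lumen_shift: float = 0.4,
    survival_fraction: float = 0.15,
    **overrides,
) -> SyntheticScreenConfig:
    """Default screen conditions with planted hits and cytotoxic compounds.

    Hit and dead compound ids are drawn (disjointly, reproducibly from
    ``seed``) from the compound list.
    """
    base = SyntheticScreenConfig(seed=seed, **overrides)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    picks = rng.choice(base.n_compounds, size=n_hit_compounds + n_dead_compounds, replace=False)
    ids = base.compound_ids()
    hits = tuple(
        HitSpec(ids[i], area_multiplier=area_multiplier, lumen_shift=lumen_shift)
        for i in sorted(picks[:n_hit_compounds])
    )
    dead = tuple(
        DeadSpec(ids[i], survival_fraction=survival_fraction)
        for i in sorted(picks[n_hit_compounds:])
    )
    return SyntheticScreenConfig(
        seed=seed, hit_compounds=hits, dead_compounds=dead, **overrides
    )


def simulate_gradient_plates(
    n_plates: int = 3,
    seed: int = 0,
    area_gradient: float = 750.0,
    lumen_gradient: float = 0.045,
    cv_noise: float = 0.05,
    baseline_median_area: float = 2500.0,
    baseline_pct_lumens: float = 0.10,
    baseline_colony_count: float = 60.0,
    layout: Optional[PlateLayout] = None,
) -> FeatureMatrix:
    """Plates with strong spatially co-oriented row/column gradients, no hits.

    Both gating metrics drift along the same plate directions (as edge and
    evaporation artifacts do), so wells in the drifted corner look extreme
    on every uncorrected score at once. This is the stress case positional
    correction exists for: fold change and naive per-plate z-scores chase
    the gradient while B-scores remove it.
    """
    layout = layout or default_384_layout()
    ss = np.random.SeedSequence([seed, 0x6AD])
    rng = np.random.default_rng(ss)
    rows_out: List[dict] = []
    compound_counter = 0
    for p in range(n_plates):
        plate_id = f"G{p + 1:02d}"
        orient_r = rng.choice([-1.0, 1.0])
        orient_c = rng.choice([-1.0, 1.0])
        gr = np.linspace(-1.0, 1.0, layout.n_rows) * orient_r
        gc = np.linspace(-1.0, 1.0, layout.n_cols) * orient_c
        for well in layout.iter_wells():
            role = layout.role_of(well)
            r_idx, c_num = parse_well(well)
            pos = gr[r_idx] + gc[c_num - 1]
            area = baseline_median_area * _lognormal_factor(rng, cv_noise, 1)[0]
            area += area_gradient * pos
            count = int(rng.poisson(baseline_colony_count))
            p_lumen = float(np.clip(baseline_pct_lumens + lumen_gradient * pos, 0.0, 1.0))
            pct = _beta_binomial_fraction(rng, p_lumen, max(count, 1), 0.0)
            if role == "compound":
                compound_counter += 1
            rows_out.append(
                {
                    "plate_id": plate_id,
                    "well": well,
                    "row": well[0],
                    "col": c_num,
                    "role": role,
                    "compound_id": f"G{compound_counter:04d}" if role == "compound" else None,
                    "concentration_um": 1.0 if role == "compound" else float("nan"),
                    "median_colony_area": max(area, 0.0),
                    "pct_colonies_with_lumens": pct,
                    "colony_count": count,
                }
            )
    return FeatureMatrix(pd.DataFrame(rows_out))


# ---------------------------------------------------------------------------
# well-image rendering


@dataclass(frozen=True)
class ColonyImageSpec:
    """Parameters of an idealized single-channel fluorescence well image.

    Cystic colonies render as bright annuli with a dim (background-level)
    lumen; spiky colonies as solid star polygons with radial profile
    r(theta) = R * (1 + amplitude * cos(n_spikes * theta)).
    """

    image_size: Tuple[int, int] = (520, 696)  # (rows, cols); 4x-field stand-in
    bit_depth: int = 16
    background_level: float = 100.0
    colony_intensity: float = 3000.0
    noise_sd: float = 0.0
    colony_shape: str = "cystic"  # cystic | spiky | mixed
    outer_radius: float = 30.0
    lumen_radius: float = 10.0
    n_spikes: int = 8
    spike_amplitude: float = 0.3
    n_colonies: int = 1
    min_separation: float = 80.0
    cystic_fraction: Optional[float] = None  # used when colony_shape == "mixed"
    allow_border: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bit_depth != 16:
            raise ValueError("only 16-bit images are generated")
        if self.colony_shape not in ("cystic", "spiky", "mixed"):
            raise ValueError(f"unknown colony_shape: {self.colony_shape}")
        if self.lumen_radius >= self.outer_radius:
            raise ValueError("lumen_radius must be < outer_radius")
        if not 0.0 <= self.spike_amplitude < 1.0:
            raise ValueError("spike_amplitude must be in [0, 1)")
        if self.colony_shape == "mixed" and self.cystic_fraction is None:
            raise ValueError("mixed shape requires cystic_fraction")
        if self.cystic_fraction is not None and not 0.0 <= self.cystic_fraction <= 1.0:
            raise ValueError("cystic_fraction must be in [0, 1]")


class PlacementError(RuntimeError):
    """Raised when colonies cannot be placed at the requested separation."""


def _place_centers(spec: ColonyImageSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_size
    amp = 0.0 if spec.colony_shape == "cystic" else spec.spike_amplitude
    margin = 0.0 if spec.allow_border else spec.outer_radius * (1.0 + amp) + 1
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PlacementError("image too small for colony radius")
    centers: List[Tuple[float, float]] = []
    attempts = 0
    max_attempts = 200 * max(spec.n_colonies, 1)
    while len(centers) < spec.n_colonies:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {spec.n_colonies} colonies with "
                f"min_separation={spec.min_separation}"
            )
        attempts += 1
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if all(math.hypot(cy - y, cx - x) >= spec.min_separation for y, x in centers):
            centers.append((cy, cx))
    return np.asarray(centers)


def _paint_colony(
    shape_kind: str,
    center: Tuple[float, float],
    spec: ColonyImageSpec,
    phase: float,
    label: int,
    image: np.ndarray,
    colony_mask: np.ndarray,
    lumen_mask: np.ndarray,
    next_lumen_label: int,
) -> int:
    h, w = spec.image_size
    rmax = spec.outer_radius * (1.0 + spec.spike_amplitude) + 2
    cy, cx = center
    y0, y1 = max(int(cy - rmax), 0), min(int(cy + rmax) + 1, h)
    x0, x1 = max(int(cx - rmax), 0), min(int(cx + rmax) + 1, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    rho = np.hypot(dy, dx)
    if shape_kind == "cystic":
        inside = rho <= spec.outer_radius
        lumen = rho <= spec.lumen_radius
    else:
        theta = np.arctan2(dy, dx)
        boundary = spec.outer_radius * (
            1.0 + spec.spike_amplitude * np.cos(spec.n_spikes * (theta - phase))
        )
        inside = rho <= boundary
        lumen = np.zeros_like(inside)
    image[y0:y1, x0:x1][inside] = spec.colony_intensity
    image[y0:y1, x0:x1][lumen] = spec.background_level
    colony_mask[y0:y1, x0:x1][inside] = label
    if lumen.any():
        lumen_mask[y0:y1, x0:x1][lumen] = next_lumen_label
        next_lumen_label += 1
    return next_lumen_label


def simulate_well_image(
    spec: ColonyImageSpec,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a well image plus noise-free colony and lumen label masks.

    Returns ``(image uint16, colony_mask uint16, lumen_mask uint16)``;
    colony labels run 1..n in placement order, lumen labels likewise.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(spec, rng)
    h, w = spec.image_size
    image = np.full((h, w), float(spec.background_level))
    colony_mask = np.zeros((h, w), np.uint16)
    lumen_mask = np.zeros((h, w), np.uint16)

    if spec.colony_shape == "mixed":
        n_cystic = int(round(spec.cystic_fraction * spec.n_colonies))
        kinds = ["cystic"] * n_cystic + ["spiky"] * (spec.n_colonies - n_cystic)
    else:
        kinds = [spec.colony_shape] * spec.n_colonies

    next_lumen = 1
    for i, (center, kind) in enumerate(zip(centers, kinds), start=1):
        phase = rng.uniform(0.0, 2.0 * math.pi)
        next_lumen = _paint_colony(
            kind, tuple(center), spec, phase, i, image, colony_mask, lumen_mask, next_lumen
        )

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, image.shape)
    image = np.clip(np.rint(image), 0, 2**16 - 1).astype(np.uint16)
    return image, colony_mask, lumen_mask
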