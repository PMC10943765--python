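"""Seeded generator of month-labelled FTIR spectra, traits and environment.

The generator emulates the statistical structure the analysis pipeline
assumes for a year-round harvest study of a medicinal orchid:

* absorbance fingerprints on the 4000-452 cm^-1 grid (4 cm^-1 steps) built
  from Gaussian carbohydrate/protein bands (O-H stretch near 3417, C-H
  near 2920/2850, C=O near 1702, carboxylate near 1595, C-H bending near
  1440/1380, amide III / C-O-C near 1322/1260, pyran-ring near 1027 cm^-1);
* a month amplitude profile with the November-March harvest window elevated
  and December maximal;
* a distinct (zero-mean) per-month band signature providing class
  separability, scaled by ``class_separation``;
* per-plant latent polysaccharide levels that drive both the carbohydrate
  band amplitudes and the dry matter content, so a spectra -> DMC
  calibration is learnable by construction;
* replicate scans with multiplicative/additive scatter artefacts and white
  noise;
* a trait table (X1-X9) with a shared per-plant size latent for X1-X5,
  exact water-content complements X8 = 100 - X6 and X9 = 100 - X7, and a
  configurable monotone link from solar radiation to fresh stem weight.

Every draw flows from one seed; identical configs give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SpectraSet

__all__ = ["SimConfig", "generate_spectra", "generate_traits", "generate_linked_dataset"]



def default_month_profile() -> dict[int, float]:
    """Relative fingerprint intensity per month: harvest window (Nov-Mar)
    elevated, December maximal."""
    return {1: 1.20, 2: 1.15, 3: 1.10, 4: 1.05, 5: 0.95, 6: 0.90,
            7: 0.85, 8: 0.90, 9: 0.95, 10: 1.00, 11: 1.25, 12: 1.35}


def default_environment() -> pd.DataFrame:
    """Monthly solar radiation (KJ m-2 day-1) and precipitation (mm) on the
    scale of a subtropical highland site: radiation peaking in late spring,
    rain concentrated in the summer monsoon."""
    months = np.arange(1, 13)
    sard = np.array([12780, 15601, 17831, 19063, 20100, 18400,
                     16800, 16200, 15100, 13900, 12533, 11527], float)
    pre = np.array([13, 14, 148, 448, 520, 690, 810, 760, 430, 190, 11, 88], float)
    return pd.DataFrame({"month": months, "sard": sard, "pre": pre})


@dataclass
class SimConfig:
    """Study-design and noise parameters for the simulator.

    Defaults encode the study conditions: 12 months, 12 plants per month,
    3 replicate scans, the band set above, and scatter/noise at the scale of
    a bench ATR instrument.  ``class_separation`` scales every between-month
    difference (band signature and amplitude profile); at 0 the months are
    statistically identical up to plant-level variation.
    """

    months: tuple = tuple(range(1, 13))
    plants_per_month: int = 12
    replicates: int = 3
    parts: tuple = ("stem", "leaf")

    band_centers: tuple = (3417, 2920, 2850, 1702, 1595, 1440, 1380, 1322, 1260, 1027)
    band_widths: tuple = (160, 35, 30, 28, 45, 28, 22, 24, 28, 50)
    band_amplitudes: tuple = (0.45, 0.22, 0.18, 0.25, 0.35, 0.18, 0.15, 0.16, 0.20, 0.60)
    carbo_bands: tuple = (0, 7, 8, 9)  # indices tied to the polysaccharide latent

    month_profile: dict = field(default_factory=default_month_profile)
    class_separation: float = 1.0
    signature_scale: float = 0.2

    grid_start: float = 4000.0
    grid_stop: float = 450.0
    grid_step: float = 4.0

    plant_level_sd: float = 0.12       # latent polysaccharide spread per plant
    band_jitter_sd: float = 0.03       # per-plant per-band amplitude jitter
    scatter_slope: tuple = (0.98, 1.02)
    scatter_offset: tuple = (0.0, 0.01)
    noise_sd: float = 0.002

    # DMC (%) = intercept + slope * dmc level + N(0, linkage_noise), where the
    # dmc level is the part's month pattern times the plant deviation
    dmc_stem_coeff: tuple = (4.0, 13.0)
    dmc_leaf_coeff: tuple = (5.0, 8.0)
    linkage_noise: float = 0.3
    # seasonal DMC patterns: stem accumulates towards April and December,
    # leaf peaks sharply in December (the planted "optimal harvest month")
    dmc_stem_month: dict = field(default_factory=lambda: {
        1: 1.02, 2: 1.05, 3: 1.15, 4: 1.35, 5: 1.00, 6: 0.92,
        7: 0.85, 8: 0.88, 9: 0.92, 10: 0.96, 11: 1.00, 12: 1.18})
    dmc_leaf_month: dict = field(default_factory=lambda: {
        1: 1.12, 2: 1.08, 3: 1.05, 4: 1.02, 5: 0.95, 6: 0.90,
        7: 0.85, 8: 0.90, 9: 0.95, 10: 1.00, 11: 1.20, 12: 1.45})

    size_latent_sd: float = 0.25       # shared lognormal spread of X1-X5
    trait_own_sd: float = 0.10
    trait_base: dict = field(default_factory=lambda: {
        "X1": 18.0, "X2": 5.0, "X3": 3.2})  # cm, g, g; X4/X5 derive from DMC
    sard_x2_link: float = -0.5         # fractional drop in X2 from min to max sard

    environment: pd.DataFrame = field(default_factory=default_environment)
    seed: int = 0

    def __post_init__(self):
        if self.plants_per_month < 1 or self.replicates < 1:
            raise ValueError("plants_per_month and replicates must be >= 1")
        if self.noise_sd < 0 or self.linkage_noise < 0:
            raise ValueError("noise levels must be >= 0")
        if any(p <= 0 for p in self.month_profile.values()):
            raise ValueError("month profile must be positive")
        grid = self.grid()
        for c in self.band_centers:
            if not (grid.min() <= c <= grid.max()):
                raise ValueError(f"band center {c} cm^-1 outside the grid")

    def grid(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_stop - 1e-9, -self.grid_step)

    def signature(self) -> np.ndarray:
        """Zero-mean per-month band signature, fixed across seeds.

        A Fourier design over the prime modulus 13 (cosine/sine characters
        at frequencies 1-5 across the band index) gives every month a
        distinct band-ratio pattern with near-uniform pairwise separation —
        no two months are accidentally collinear, which a random signature
        does not guarantee.
        """
        n_bands = len(self.band_centers)
        m = np.arange(1, 13)[:, None]
        cols = []
        for k in range(1, n_bands // 2 + 1):
            cols.append(np.sqrt(2) * np.cos(2 * np.pi * m * k / 13))
            cols.append(np.sqrt(2) * np.sin(2 * np.pi * m * k / 13))
        sig = np.hstack(cols)[:, :n_bands]
        return sig - sig.mean(axis=1, keepdims=True)


def _effective_profile(cfg: SimConfig, month: int) -> float:
    base = cfg.month_profile[month]
    return 1.0 + cfg.class_separation * (base - 1.0)


def _latents(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-plant latent draws shared by the spectra and trait generators."""
    rows = []
    for month in cfg.months:
        for plant in range(1, cfg.plants_per_month + 1):
            rows.append({
                "month": month,
                "sample_id": f"M{month:02d}P{plant:02d}",
                "u_stem": rng.normal(), "u_leaf": rng.normal(),
                "v_size": rng.normal(),
            })
    return pd.DataFrame(rows)


def _dmc_level(cfg: SimConfig, month: int, part: str, u: float) -> float:
    """Latent DMC level: the part's seasonal pattern (scaled by
    class_separation like every between-month difference) times the plant
    deviation shared with the carbohydrate bands."""
    pattern = (cfg.dmc_stem_month if part == "stem" else cfg.dmc_leaf_month)[month]
    eff = 1.0 + cfg.class_separation * (pattern - 1.0)
    return eff * (1.0 + cfg.plant_level_sd * u)


def _clean_spectrum(cfg: SimConfig, grid: np.ndarray, month: int, part: str,
                    u: float, jitter: np.ndarray) -> np.ndarray:
    """Band amplitudes for one plant.

    Carbohydrate bands are proportional to the plant's latent DMC level (so
    the spectra -> DMC map is linear up to the per-band jitter); the
    remaining bands carry the month profile and the zero-mean month
    signature that makes harvest periods distinguishable.
    """
    sig = cfg.signature()[month - 1]
    prof = _effective_profile(cfg, month)
    poly = _dmc_level(cfg, month, part, u)
    base = np.asarray(cfg.band_amplitudes)
    carbo = np.zeros(len(base), bool)
    carbo[list(cfg.carbo_bands)] = True
    # additive signature keeps low-intensity months as distinguishable as
    # high-intensity ones
    month_gain = prof + cfg.class_separation * cfg.signature_scale * sig
    amps = np.where(carbo, base * poly, base * month_gain) * (1.0 + jitter)
    centers = np.asarray(cfg.band_centers, float)
    widths = np.asarray(cfg.band_widths, float)
    return (amps[None, :] * np.exp(
        -0.5 * ((grid[:, None] - centers[None, :]) / widths[None, :]) ** 2
    )).sum(axis=1)


def generate_linked_dataset(cfg: SimConfig) -> tuple[SpectraSet, pd.DataFrame, pd.DataFrame]:
    """Joint draw of (spectra, trait table, environment table).

    The same per-plant latent polysaccharide level drives both the
    carbohydrate band amplitudes and X6/X7, so the spectra -> DMC map is
    linear up to ``linkage_noise``.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid()
    latents = _latents(cfg, rng)
    env = cfg.environment.copy()

    sard = env.set_index("month")["sard"]
    s_lo, s_hi = sard.min(), sard.max()

    spec_rows, spec_meta, trait_rows = [], [], []
    for _, row in latents.iterrows():
        month = int(row["month"])
        for part in cfg.parts:
            u = row["u_stem"] if part == "stem" else row["u_leaf"]
            jitter = rng.normal(0.0, cfg.band_jitter_sd, size=len(cfg.band_centers))
            clean = _clean_spectrum(cfg, grid, month, part, u, jitter)
            for rep in range(1, cfg.replicates + 1):
                slope = rng.uniform(*cfg.scatter_slope)
                offset = rng.uniform(*cfg.scatter_offset)
                noise = rng.normal(0.0, cfg.noise_sd, size=len(grid))
                spec_rows.append(slope * clean + offset + noise)
                spec_meta.append({"sample_id": row["sample_id"], "month": month,
                                  "part": part, "replicate": rep})

        # traits: DMC from the same latents, sizes from the shared size latent
        a_s, b_s = cfg.dmc_stem_coeff
        a_l, b_l = cfg.dmc_leaf_coeff
        x6 = a_s + b_s * _dmc_level(cfg, month, "stem", row["u_stem"]) \
            + rng.normal(0.0, cfg.linkage_noise)
        x7 = a_l + b_l * _dmc_level(cfg, month, "leaf", row["u_leaf"]) \
            + rng.normal(0.0, cfg.linkage_noise)
        x6, x7 = float(np.clip(x6, 1.0, 99.0)), float(np.clip(x7, 1.0, 99.0))

        season = _effective_profile(cfg, month)
        sard_frac = (sard[month] - s_lo) / (s_hi - s_lo) if s_hi > s_lo else 0.0
        size = np.exp(cfg.size_latent_sd * row["v_size"])
        x1 = cfg.trait_base["X1"] * season * size * np.exp(
            rng.normal(0.0, cfg.trait_own_sd))
        x2 = cfg.trait_base["X2"] * season * size * np.exp(
            rng.normal(0.0, cfg.trait_own_sd)) * (1.0 + cfg.sard_x2_link * sard_frac)
        x3 = cfg.trait_base["X3"] * season * size * np.exp(
            rng.normal(0.0, cfg.trait_own_sd))
        x4 = x2 * x6 / 100.0  # dry weights consistent with DMC by construction
        x5 = x3 * x7 / 100.0
        trait_rows.append({
            "month": month, "sample_id": row["sample_id"],
            "X1": x1, "X2": x2, "X3": x3, "X4": x4, "X5": x5,
            "X6": x6, "X7": x7, "X8": 100.0 - x6, "X9": 100.0 - x7,
        })

    spectra = SpectraSet(grid, np.vstack(spec_rows), pd.DataFrame(spec_meta))
    traits = pd.DataFrame(trait_rows)
    traits.attrs["seed"] = cfg.seed
    spectra.meta.attrs["seed"] = cfg.seed
    env.attrs["seed"] = cfg.seed
    return spectra, traits, env


def generate_spectra(cfg: SimConfig) -> SpectraSet:
    """Spectra only (replicate scans included); see generate_linked_dataset."""
    spectra, _, _ = generate_linked_dataset(cfg)
    return spectra


def generate_traits(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trait and environment tables only; see generate_linked_dataset."""
    _, traits, env = generate_linked_dataset(cfg)
    return traits, env
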