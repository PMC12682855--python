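"""Generators for every input of the pipeline, with known ground truth.

Four generators, all driven by one seeded :class:`numpy.random.Generator`
(sub-streams are spawned deterministically per generator):

* :func:`simulate_trial` — a factorial genotype x P-level Rhizotube trial
  with genotype, treatment and interaction effects on biomass and tissue P,
  multiplicative (log-normal) residual noise, and a noise-free ground-truth
  metric table computed in closed form.
* :func:`simulate_paired_platforms` — genotype-mean metric tables for two
  platforms sharing a latent genotype-efficiency vector with correlation
  ``rho_true``, plus platform-specific scale/offset distortions.
* :func:`simulate_growth_series` — logistic root-area growth curves per
  tube with genotype-specific asymptote/rate and a treatment multiplier.
* :func:`render_root_scene` — a rendered root image (branching downward
  random walk, dilated to a stroke width, darker than background) with its
  true mask, true pixel area, and a six-view stack with known offsets.

Biomass noise is multiplicative because biomass is positive and replicate
scatter in such trials is naturally expressed as a coefficient of
variation.  Default effect sizes and scales were chosen so that the
simulated metric ranges bracket the ranges observed in real 26-genotype
wheat trials (PAE roughly 10-90 %, PUE tens to hundreds).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .trial_io import (
    METRIC_COLUMNS,
    P_MINUS,
    P_PLUS,
    HarvestRecord,
    MetricTable,
    TrialDesign,
)
from .root_imaging import DEFAULT_PIXEL_COEFF, RootAreaSeries, ViewStack

__all__ = [
    "SimulationConfig",
    "TrialTruth",
    "PairedTruth",
    "RootScene",
    "make_design",
    "simulate_trial",
    "simulate_paired_platforms",
    "simulate_growth_series",
    "render_root_scene",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the emulated trial.

    The factorial layout mirrors the two real trials: 26 genotypes x 2 P
    levels with 6 tubes per cell on one platform (312 tubes) and 4 on the
    other (208).  ``p_applied`` is grams of P available per tube, derived
    from the two Hoagland phosphate concentrations (0.3 mM vs 0.0032 mM,
    31 g/mol P) at a common reference solution volume.

    Effect structure (log scale): ``genotype_effect_sd`` scales a latent
    standard-normal genotype efficiency that is expressed fully under P-
    and at ``latent_pplus_weight`` under P+; ``treatment_effect`` is the
    log biomass lift of optimal P; ``interaction_sd`` adds genotype x level
    wobble; ``residual_cv`` is the replicate-level coefficient of
    variation.  ``rho_true`` is the cross-platform latent correlation used
    by the paired-platform generator.
    """

    n_genotypes: int = 26
    replicates: int = 6
    replicates_alt: int = 4
    p_applied: dict[str, float] = field(
        default_factory=lambda: {P_PLUS: 5.0e-3, P_MINUS: 5.3e-5}
    )
    genotype_effect_sd: float = 0.25
    treatment_effect: float = 1.41
    interaction_sd: float = 0.08
    residual_cv: float = 0.10
    rho_true: float = 0.45
    seed: int = 0
    # scale parameters of the response model
    dw_pminus: float = 0.11            # mean whole-plant DW at P- (g)
    conc: dict[str, float] = field(
        default_factory=lambda: {P_PLUS: 2.2e-3, P_MINUS: 2.0e-4}
    )                                  # tissue P concentration by level
    root_shoot: dict[str, float] = field(
        default_factory=lambda: {P_PLUS: 0.25, P_MINUS: 0.35}
    )                                  # baseline root/shoot ratio by level
    root_latent_slope: float = 0.30    # extra root allocation per latent unit at P-
    conc_latent_slope: float = 0.05    # tissue P response to latent at P-
    latent_pplus_weight: float = 0.40
    platform_noise_sd: float = 0.15    # genotype-mean noise in the paired generator

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("genotype_effect_sd", "interaction_sd", "residual_cv",
                     "platform_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.rho_true <= 1:
            raise ValueError("rho_true must lie in [0, 1]")
        if self.n_genotypes < 2 or self.replicates < 1:
            raise ValueError("need >=2 genotypes and >=1 replicate")


def _rng(cfg: SimulationConfig, stream: str) -> np.random.Generator:
    """Deterministic per-generator sub-stream derived from the run seed."""
    tag = zlib.crc32(stream.encode()) % 2**31
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, tag]))


def make_design(cfg: SimulationConfig, platform_label: str = "SIM",
                replicates: int | None = None) -> TrialDesign:
    genotypes = tuple(f"G{i + 1:02d}" for i in range(cfg.n_genotypes))
    return TrialDesign(
        genotypes=genotypes,
        p_applied=dict(cfg.p_applied),
        replicates_per_cell=replicates or cfg.replicates,
        platform_label=platform_label,
    )


@dataclass
class TrialTruth:
    """Noise-free state of one simulated trial."""

    latent: pd.Series                 # genotype -> latent efficiency
    metric_table: MetricTable         # closed-form metrics of the noise-free trial
    design: TrialDesign


def _log_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def simulate_trial(
    cfg: SimulationConfig, replicates: int | None = None, platform_label: str = "SIM"
) -> tuple[list[HarvestRecord], TrialTruth]:
    """Simulate one platform's harvest and return records plus ground truth.

    The deterministic back-bone per genotype i and level l is

    ``log DW_il = log(dw_pminus) + tau_l + w_l * sd_g * e_i + gamma_il``

    with ``tau_{P-}=0``, ``tau_{P+}=treatment_effect``, ``w_{P-}=1``,
    ``w_{P+}=latent_pplus_weight`` and ``e_i ~ N(0,1)`` the latent genotype
    efficiency.  Root allocation rises with ``e_i`` under P- (efficient
    genotypes forage), tissue P concentration is lower under P- and rises
    weakly with ``e_i``, and P uptake is exactly DW x concentration.
    Replicates multiply every response by independent log-normal noise
    matched to ``residual_cv``.  The ground-truth metric table is computed
    in closed form from the noise-free backbone.
    """
    design = make_design(cfg, platform_label=platform_label, replicates=replicates)
    n_rep = design.replicates_per_cell
    rng = _rng(cfg, f"trial-{platform_label}-{n_rep}")
    g = cfg.n_genotypes
    levels = (design.p_plus, design.p_minus)

    e = rng.standard_normal(g)
    gamma = rng.normal(0.0, cfg.interaction_sd, size=(g, 2))
    sigma = _log_sigma(cfg.residual_cv)

    # deterministic per-cell backbone
    truth_rows = {}
    cell_values = {}
    for j, level in enumerate(levels):
        tau = cfg.treatment_effect if level == design.p_plus else 0.0
        w = cfg.latent_pplus_weight if level == design.p_plus else 1.0
        at_minus = level == design.p_minus
        dw = cfg.dw_pminus * np.exp(tau + w * cfg.genotype_effect_sd * e + gamma[:, j])
        ratio = cfg.root_shoot[level] * np.exp(cfg.root_latent_slope * e * at_minus)
        conc = cfg.conc[level] * np.exp(cfg.conc_latent_slope * e * at_minus)
        root = dw * ratio / (1.0 + ratio)
        shoot = dw - root
        uptake = dw * conc
        cell_values[level] = (dw, shoot, root, conc, uptake)
        truth_rows[level] = {
            "pae": uptake / design.p_applied_for(level) * 100.0,
            "prae": uptake / root,
            "pue": dw * dw / conc,
            "dw": dw,
        }

    records: list[HarvestRecord] = []
    for j, level in enumerate(levels):
        dw0, shoot0, root0, conc0, _ = cell_values[level]
        for rep in range(1, n_rep + 1):
            noise_dw = np.exp(rng.normal(0.0, sigma, size=g))
            noise_rt = np.exp(rng.normal(0.0, sigma / 2.0, size=g))
            noise_cc = np.exp(rng.normal(0.0, sigma, size=g))
            dw = dw0 * noise_dw
            ratio = (root0 / shoot0) * noise_rt
            root = dw * ratio / (1.0 + ratio)
            shoot = dw - root
            conc = conc0 * noise_cc
            uptake = dw * conc
            for i, geno in enumerate(design.genotypes):
                records.append(
                    HarvestRecord(
                        genotype=geno,
                        p_level=level,
                        replicate=rep,
                        shoot_dw=float(shoot[i]),
                        root_dw=float(root[i]),
                        plant_p_concentration=float(conc[i]),
                        p_uptake=float(uptake[i]),
                    )
                )

    # closed-form ground-truth metric table (sample SD of a noise-free cell is 0)
    avail_hi = design.p_applied_for(design.p_plus)
    avail_lo = design.p_applied_for(design.p_minus)
    dw_hi = truth_rows[design.p_plus]["dw"]
    dw_lo = truth_rows[design.p_minus]["dw"]
    frame = pd.DataFrame(index=pd.Index(design.genotypes, name="genotype"),
                         columns=list(METRIC_COLUMNS), dtype=float)
    for level, suffix in ((design.p_minus, "pminus"), (design.p_plus, "pplus")):
        for m in ("pae", "prae", "pue"):
            frame[f"{m}_{suffix}_mean"] = truth_rows[level][m]
            frame[f"{m}_{suffix}_sd"] = 0.0
    frame["apue"] = (dw_hi - dw_lo) / (avail_hi - avail_lo)
    frame["relative_efficiency"] = dw_lo / dw_hi * 100.0
    truth = TrialTruth(
        latent=pd.Series(e, index=list(design.genotypes), name="latent"),
        metric_table=MetricTable(frame, platform_label=platform_label, n_per_cell=n_rep),
        design=design,
    )
    return records, truth


@dataclass
class PairedTruth:
    """Latent efficiencies underlying a paired-platform simulation."""

    latent_a: pd.Series
    latent_b: pd.Series
    rho_true: float


# affine maps (intercept, slope) from latent efficiency to each metric column;
# PRAE slopes are negative: efficient genotypes spread uptake over more root.
_PAIRED_MAPS = {
    "pae_pminus_mean": (45.0, 14.0),
    "prae_pminus_mean": (0.006, -0.0012),
    "pue_pminus_mean": (55.0, 16.0),
    "pae_pplus_mean": (30.0, 5.0),
    "prae_pplus_mean": (0.06, -0.008),
    "pue_pplus_mean": (150.0, 25.0),
    "relative_efficiency": (55.0, 12.0),
    "apue": (50.0, 18.0),
}


def simulate_paired_platforms(
    cfg: SimulationConfig,
) -> tuple[MetricTable, MetricTable, PairedTruth]:
    """Two genotype-mean metric tables sharing a latent efficiency vector.

    Platform latents are standard normal with correlation ``rho_true``;
    each metric column is an affine map of the platform latent plus
    independent genotype-level noise (``platform_noise_sd``) and a
    platform-specific scale/offset distortion.  Min-max normalization
    removes the distortion, so recovered cross-platform correlation of the
    composite indicator tracks ``rho_true``.
    """
    rng = _rng(cfg, "paired-platforms")
    g = cfg.n_genotypes
    genotypes = [f"G{i + 1:02d}" for i in range(g)]
    e_a = rng.standard_normal(g)
    eta = rng.standard_normal(g)
    e_b = cfg.rho_true * e_a + np.sqrt(1.0 - cfg.rho_true**2) * eta

    tables = []
    for label, latent in (("PLATFORM-A", e_a), ("PLATFORM-B", e_b)):
        scale = float(rng.uniform(0.8, 1.25))
        offset = float(rng.uniform(-0.1, 0.1))
        frame = pd.DataFrame(index=pd.Index(genotypes, name="genotype"),
                             columns=list(METRIC_COLUMNS), dtype=float)
        for col, (a, b) in _PAIRED_MAPS.items():
            noisy = latent + rng.normal(0.0, cfg.platform_noise_sd, size=g)
            values = a + b * (scale * noisy + offset)
            if col.startswith(("pae", "pue", "prae")):
                values = np.maximum(values, 0.01 * abs(a))  # keep metrics positive
            frame[col] = values
            if col.endswith("_mean"):
                frame[col.replace("_mean", "_sd")] = 0.1 * abs(b)
        tables.append(MetricTable(frame, platform_label=label, n_per_cell=cfg.replicates))
    truth = PairedTruth(
        latent_a=pd.Series(e_a, index=genotypes, name="latent_a"),
        latent_b=pd.Series(e_b, index=genotypes, name="latent_b"),
        rho_true=cfg.rho_true,
    )
    return tables[0], tables[1], truth


def simulate_growth_series(
    cfg: SimulationConfig,
    times=None,
    area_max: float = 30000.0,
    treatment_multiplier: float = 0.55,
    noise_sd: float = 300.0,
    replicates: int | None = None,
) -> tuple[list[RootAreaSeries], pd.DataFrame]:
    """Per-tube logistic root-area growth curves with known parameters.

    ``area(t) = A / (1 + exp(-k (t - t0)))`` with genotype-specific
    asymptote ``A`` and rate ``k``; under P- the asymptote is multiplied
    by ``treatment_multiplier``.  Each tube adds a log-normal random
    intercept on the asymptote and i.i.d. additive noise per time point
    (areas clipped at zero).  Returns the series plus a truth table of
    (genotype, level, tube, A, k, t0).
    """
    if times is None:
        times = np.arange(7.0, 97.0, 7.0)  # twice-weekly-ish scans to day ~96
    times = np.asarray(times, dtype=float)
    if times.size < 4:
        raise ValueError("need at least four time points")
    rng = _rng(cfg, "growth")
    n_rep = replicates or cfg.replicates
    genotypes = [f"G{i + 1:02d}" for i in range(cfg.n_genotypes)]

    series: list[RootAreaSeries] = []
    truth_rows = []
    for i, geno in enumerate(genotypes):
        a_geno = area_max * float(np.exp(rng.normal(0.0, 0.25)))
        k_geno = float(rng.uniform(0.08, 0.16))
        t0_geno = float(rng.uniform(30.0, 55.0))
        for level, mult in ((P_PLUS, 1.0), (P_MINUS, treatment_multiplier)):
            for rep in range(1, n_rep + 1):
                a_tube = a_geno * mult * float(np.exp(rng.normal(0.0, 0.10)))
                clean = a_tube / (1.0 + np.exp(-k_geno * (times - t0_geno)))
                noisy = np.clip(clean + rng.normal(0.0, noise_sd, size=times.size), 0.0, None)
                tube_id = f"{geno}-{level}-{rep}"
                series.append(RootAreaSeries(tube_id=tube_id, times=times,
                                             areas_px=noisy))
                truth_rows.append({"tube_id": tube_id, "genotype": geno,
                                   "p_level": level, "replicate": rep,
                                   "asymptote": a_tube, "rate": k_geno,
                                   "midpoint": t0_geno})
    return series, pd.DataFrame(truth_rows).set_index("tube_id")


@dataclass
class RootScene:
    """A rendered root image with its ground truth and view stack."""

    image: np.ndarray
    mask: np.ndarray
    area_px: int
    stack: ViewStack
    offsets: np.ndarray


def _disk(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1), dtype=bool)
    yy, xx = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    return yy * yy + xx * xx <= radius * radius


def render_root_scene(
    width: int = 480,
    height: int = 240,
    n_branches: int = 4,
    stroke_width: int = 3,
    noise_sigma: float = 0.02,
    seed: int = 0,
    view_overlap: int = 24,
) -> RootScene:
    """Render a root-like scene: trunk plus side branches, dark on bright.

    A single trunk starts at the top of the image and random-walks
    downward; ``n_branches`` side branches split off at random depths, so
    the whole skeleton stays one connected component hanging from the top
    (as a real root system does).  The skeleton is dilated to
    ``stroke_width`` and drawn dark (0.2) on a bright background (0.85);
    additive Gaussian noise of ``noise_sigma`` completes the image.  The
    true mask/area are recorded before noise.  Six views of equal width
    with ``view_overlap`` shared columns are cut at known offsets.
    """
    if stroke_width < 1:
        raise ValueError("stroke_width must be >= 1")
    if width % 6:
        raise ValueError("width must be divisible by 6")
    rng = np.random.default_rng(seed)
    skel = np.zeros((height, width), dtype=bool)

    def walk(row: int, col: float, drift_sd: float) -> list[tuple[int, int]]:
        path = []
        drift = rng.normal(0.0, drift_sd)
        while row < height and 0 <= col < width:
            path.append((row, int(col)))
            skel[row, int(col)] = True
            drift = 0.8 * drift + rng.normal(0.0, drift_sd)
            col += drift
            row += 1
        return path

    if n_branches > 0:
        trunk = walk(0, width * 0.5 + rng.uniform(-width * 0.1, width * 0.1), 0.6)
        for _ in range(max(0, n_branches - 1)):
            if len(trunk) < 10:
                break
            r0, c0 = trunk[rng.integers(5, len(trunk) // 2 + 5)]
            walk(r0, float(c0), 1.2)

    mask = ndimage.binary_dilation(skel, structure=_disk(stroke_width // 2))
    image = np.where(mask, 0.20, 0.85)
    # smooth substrate texture: far below root contrast, but it gives every
    # column a registration signal for the view-stitching cross-correlation
    texture = ndimage.gaussian_filter(rng.standard_normal(image.shape), sigma=3.0)
    image = image + 0.04 * texture / max(texture.std(), 1e-12)
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    view_w = width // 6 + view_overlap
    step = width // 6
    offsets = np.arange(6) * step
    pad = np.hstack([image, image[:, :view_overlap]])  # cylinder wraps around
    views = tuple(pad[:, o:o + view_w].copy() for o in offsets)
    stack = ViewStack(views=views, tube_id="scene", pixel_coeff=DEFAULT_PIXEL_COEFF)
    return RootScene(image=image, mask=mask, area_px=int(mask.sum()),
                     stack=stack, offsets=offsets)
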