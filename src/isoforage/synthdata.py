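"""Synthetic datasets with the statistical structure the pipeline assumes.

Every generator is deterministic under its seed and emits tables that
pass core_io validation. "Truth sidecar" tables record the generating
parameters (true diet proportions, true trophic positions) in separate
files that no analysis stage ever reads — blinding by construction.

The default scenario mirrors a three-site paired natural/disturbed
design: a C3/C4-separated source menu (upland groups present only at
natural locations), ~5 consumers per site × status cell, and 45 feeding
crabs in 3 trials of 15 offered five plant prey plus a fully consumed
animal prey.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (CONSUMER_COLUMNS, IsotopeSample, SourceGroup,
                      TRIAL_COLUMNS, TrophicEnrichment, consumers_to_frame,
                      sources_to_frame)


@dataclass
class SourceSpec:
    name: str
    mu_d13C: float
    mu_d15N: float
    sigma_d13C: float = 0.8
    sigma_d15N: float = 0.6
    pctC: float = 40.0
    pctN: float = 2.0
    upland: bool = False        # absent from disturbed locations
    n_reps: int = 4


@dataclass
class FeedingScenario:
    n_crabs: int = 45
    n_trials: int = 3
    prey: tuple[str, ...] = ("Avicennia", "Iva", "Grass", "Borrichia",
                             "Fern", "Cricket")
    consumption_fraction: dict = field(default_factory=lambda: {
        "Avicennia": 0.45, "Iva": 0.5, "Grass": 0.1, "Borrichia": 0.1,
        "Fern": 0.1, "Cricket": 1.0,
    })
    wet_mass_range: tuple[float, float] = (0.8, 1.6)
    dry_ratio: dict = field(default_factory=lambda: {
        "Avicennia": 0.32, "Iva": 0.22, "Grass": 0.30, "Borrichia": 0.20,
        "Fern": 0.25, "Cricket": 0.35,
    })
    autogenic_factor: float = 0.93      # control final dry / true initial dry
    mass_noise_sd: float = 0.004


@dataclass
class TrophicScenario:
    baseline_d15N: dict = field(default_factory=lambda: {
        "S1": 4.0, "S2": 5.5, "S3": 3.2,
    })
    true_tp: dict = field(default_factory=lambda: {
        ("S1", "natural"): 2.4, ("S1", "disturbed"): 2.8,
        ("S2", "natural"): 2.35, ("S2", "disturbed"): 2.75,
        ("S3", "natural"): 2.45, ("S3", "disturbed"): 2.85,
    })
    noise_sd: dict = field(default_factory=lambda: {
        "natural": 0.25, "disturbed": 0.12,
    })   # sd of consumer d15N around the cell mean, in TP units x TEF
    n_baseline: int = 5
    n_crabs_per_cell: int = 5


def _default_sources() -> list[SourceSpec]:
    return [
        SourceSpec("HerbArthropods", -20.0, 6.5, 1.0, 0.8, 45.0, 9.0),
        SourceSpec("SecArthropods", -19.0, 8.0, 1.2, 1.0, 45.0, 10.0),
        SourceSpec("Uca", -16.5, 7.5, 0.8, 0.7, 38.0, 11.0),
        SourceSpec("Gastropods", -18.0, 5.5, 0.9, 0.7, 40.0, 9.5),
        SourceSpec("MangroveDetritus", -26.5, 4.5, 1.0, 0.8, 42.0, 1.4),
        SourceSpec("SeagrassWrack", -14.5, 4.0, 1.2, 0.9, 35.0, 1.8),
        SourceSpec("HighIntertidalVeg", -27.0, 6.0, 1.1, 0.9, 42.0, 2.4),
        SourceSpec("Grasses", -13.0, 4.5, 0.8, 0.8, 43.0, 1.2),
        SourceSpec("UplandDetritus", -27.5, 2.5, 1.0, 0.8, 46.0, 0.9,
                   upland=True),
        SourceSpec("UplandPlants", -28.0, 3.5, 1.0, 0.8, 44.0, 1.6,
                   upland=True),
    ]


def _default_proportions(menu: list[str]) -> dict:
    # mild preference structure; renormalized per menu
    base = {
        "HerbArthropods": 0.15, "SecArthropods": 0.05, "Uca": 0.08,
        "Gastropods": 0.12, "MangroveDetritus": 0.18, "SeagrassWrack": 0.04,
        "HighIntertidalVeg": 0.14, "Grasses": 0.04, "UplandDetritus": 0.10,
        "UplandPlants": 0.10,
    }
    w = np.array([base[m] for m in menu])
    w = w / w.sum()
    return dict(zip(menu, w))


@dataclass
class ScenarioConfig:
    sites: tuple[str, ...] = ("S1", "S2", "S3")
    statuses: tuple[str, ...] = ("natural", "disturbed")
    sources: list[SourceSpec] = field(default_factory=_default_sources)
    true_proportions: dict | None = None    # (site, status) -> {source: p}
    n_consumers: int = 5
    consumer_noise_sd: tuple[float, float] = (0.5, 0.4)   # per tracer
    tef: TrophicEnrichment = field(default_factory=TrophicEnrichment)
    feeding: FeedingScenario = field(default_factory=FeedingScenario)
    trophic: TrophicScenario = field(default_factory=TrophicScenario)
    seed: int = 0

    def menu(self, status: str) -> list[str]:
        return [s.name for s in self.sources
                if status == "natural" or not s.upland]

    def proportions(self, site: str, status: str) -> dict:
        if self.true_proportions is not None:
            p = self.true_proportions[(site, status)]
        else:
            p = _default_proportions(self.menu(status))
        total = sum(p.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"true proportions for {(site, status)} sum to {total}")
        return p


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_sources(cfg: ScenarioConfig,
                seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Source-group table plus raw per-replicate source samples.

    Returns (source_groups, source_replicates): the group table carries the
    true generating parameters; the replicate table draws ``n_reps``
    Normal(mu, sigma) samples per group per site × status location so that
    aggregation can be exercised against the truth.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    group_rows = []
    reps = []
    for site in cfg.sites:
        for status in cfg.statuses:
            loc = f"{site}-{status[0].upper()}"
            for s in cfg.sources:
                if s.upland and status == "disturbed":
                    continue
                group_rows.append({
                    "name": s.name, "site": loc,
                    "mu_d13C": s.mu_d13C, "sigma_d13C": s.sigma_d13C,
                    "mu_d15N": s.mu_d15N, "sigma_d15N": s.sigma_d15N,
                    "conc_C": s.pctC, "conc_N": s.pctN, "n": s.n_reps,
                })
                for r in range(s.n_reps):
                    reps.append(IsotopeSample(
                        sample_id=f"{loc}-{s.name}-{r + 1}",
                        site=loc, habitat_status=status, category=s.name,
                        d13C=float(rng.normal(s.mu_d13C, s.sigma_d13C)),
                        d15N=float(rng.normal(s.mu_d15N, s.sigma_d15N)),
                        pctC=s.pctC, pctN=s.pctN,
                    ))
    groups = pd.DataFrame(group_rows)
    return groups, consumers_to_frame(reps)


def gen_consumers(cfg: ScenarioConfig,
                  seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Consumer isotope table plus the truth sidecar of generating proportions.

    Consumer tracer values are the concentration-weighted mixture mean of
    the (TEF-shifted) true sources under the cell's true proportions, plus
    Normal noise.
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    specs = {s.name: s for s in cfg.sources}
    rows = []
    truth = []
    for site in cfg.sites:
        for status in cfg.statuses:
            loc = f"{site}-{status[0].upper()}"
            menu = cfg.menu(status)
            p = cfg.proportions(site, status)
            pv = np.array([p[m] for m in menu])
            mu = np.array([[specs[m].mu_d13C, specs[m].mu_d15N] for m in menu])
            conc = np.array([[specs[m].pctC, specs[m].pctN] for m in menu])
            tefm = np.array(cfg.tef.mean)
            w = pv[:, None] * conc
            w = w / w.sum(axis=0, keepdims=True)
            mix_mean = np.sum(w * (mu + tefm), axis=0)
            for j in range(cfg.n_consumers):
                noise = rng.normal(0.0, cfg.consumer_noise_sd, size=2)
                rows.append({
                    "sample_id": f"{loc}-crab-{j + 1}", "site": loc,
                    "habitat_status": status, "category": "Armases",
                    "d13C": float(mix_mean[0] + noise[0]),
                    "d15N": float(mix_mean[1] + noise[1]),
                    "pctC": 40.0, "pctN": 11.0,
                })
            for m in menu:
                truth.append({"site": loc, "habitat_status": status,
                              "source": m, "true_proportion": p[m]})
    return (pd.DataFrame(rows, columns=CONSUMER_COLUMNS),
            pd.DataFrame(truth))


def gen_feeding_trials(cfg: ScenarioConfig,
                       seed: int | None = None) -> pd.DataFrame:
    """Multi-choice feeding-trial table with paired no-consumer controls.

    Per crab and prey: initial wet mass ~ Uniform(range); the true initial
    dry mass is wet × species dry ratio; the control half loses mass by the
    autogenic factor; the offered half additionally loses the consumed
    fraction. Gaussian weighing noise applies to final dry masses. A
    fraction of 1.0 (the animal-prey analog) exercises the fully consumed
    path downstream.
    """
    fs = cfg.feeding
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 2)
    rows = []
    per_trial = fs.n_crabs // fs.n_trials
    for i in range(fs.n_crabs):
        crab = f"crab-{i + 1:03d}"
        trial = min(i // per_trial, fs.n_trials - 1) + 1
        sex = "M" if (i % per_trial) < (per_trial + 1) // 2 else "F"
        for prey in fs.prey:
            frac = fs.consumption_fraction[prey]
            ratio = fs.dry_ratio[prey]
            for is_control in (False, True):
                wet = rng.uniform(*fs.wet_mass_range)
                init_dry = wet * ratio
                after_autogenic = init_dry * fs.autogenic_factor
                final = after_autogenic if is_control \
                    else after_autogenic * (1.0 - frac)
                final = max(0.0, final + rng.normal(0.0, fs.mass_noise_sd)) \
                    if frac < 1.0 or is_control else 0.0
                rows.append({
                    "crab_id": crab, "sex": sex, "trial": trial, "prey": prey,
                    "initial_wet_mass": wet, "final_dry_mass": final,
                    "is_control": is_control,
                })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def gen_trophic_dataset(cfg: ScenarioConfig,
                        seed: int | None = None) -> tuple[pd.DataFrame,
                                                          pd.DataFrame]:
    """Crab + baseline-snail isotope table with a true-TP sidecar.

    Baseline snails sit at the site's baseline δ15N plus noise; crabs at
    baseline + (tp_true − 2) × Δδ15N plus status-specific noise.
    """
    ts = cfg.trophic
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 3)
    delta = cfg.tef.delta_d15N_mean
    rows = []
    truth = []
    for site in cfg.sites:
        base = ts.baseline_d15N[site]
        for status in cfg.statuses:
            loc = f"{site}-{status[0].upper()}"
            for j in range(ts.n_baseline):
                rows.append({
                    "sample_id": f"{loc}-snail-{j + 1}", "site": loc,
                    "habitat_status": status, "category": "Melampus",
                    "d13C": float(rng.normal(-22.0, 0.5)),
                    "d15N": float(rng.normal(base, 0.3)),
                    "pctC": 38.0, "pctN": 10.0,
                })
            tp_true = ts.true_tp[(site, status)]
            sd = ts.noise_sd[status]
            for j in range(ts.n_crabs_per_cell):
                d15 = base + (tp_true - 2.0) * delta + rng.normal(0.0, sd * delta)
                rows.append({
                    "sample_id": f"{loc}-crab-{j + 1}", "site": loc,
                    "habitat_status": status, "category": "Armases",
                    "d13C": float(rng.normal(-20.0, 1.0)),
                    "d15N": float(d15),
                    "pctC": 40.0, "pctN": 11.0,
                })
            truth.append({"site": loc, "habitat_status": status,
                          "true_tp": tp_true, "baseline_d15N": base})
    return pd.DataFrame(rows, columns=CONSUMER_COLUMNS), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Scenario writer
# ---------------------------------------------------------------------------

def write_scenario(cfg: ScenarioConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every table of the scenario into ``outdir``; returns paths.

    Files are byte-identical across runs with the same config and seed
    (fixed column order and float formatting).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.17g"
    paths: dict[str, Path] = {}

    groups, reps = gen_sources(cfg)
    consumers, p_truth = gen_consumers(cfg)
    trials = gen_feeding_trials(cfg)
    trophic_tbl, tp_truth = gen_trophic_dataset(cfg)

    for key, frame in [
        ("sources", groups), ("source_replicates", reps),
        ("consumers", consumers), ("truth_proportions", p_truth),
        ("feeding_trials", trials), ("trophic_samples", trophic_tbl),
        ("truth_tp", tp_truth),
    ]:
        path = outdir / f"{key}.csv"
        frame.to_csv(path, index=False, float_format=fmt)
        paths[key] = path
    return paths
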