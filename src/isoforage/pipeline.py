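"""End-to-end orchestration: selectivity → trophic → polygon → simm.

Consumers flagged outside the mixing region are warned about but not
dropped by default (a config switch enables exclusion). All stage
outputs are CSV; the manifest records seeds, effective parameters,
stage statuses and the output inventory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import core_io, polygon as polygon_mod, selectivity as sel_mod
from . import simm as simm_mod, synthdata, trophic as trophic_mod
from .core_io import AnalysisConfig

logger = logging.getLogger("isoforage")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)       # stage -> "ok"/"failed"/...
    outputs: dict = field(default_factory=dict)      # label -> path
    warnings: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "config_hash": self.config_hash, "seed": self.seed,
                "stages": self.stages,
                "outputs": {k: str(v) for k, v in self.outputs.items()},
                "warnings": self.warnings,
            }, fh, indent=2)

    @property
    def all_ok(self) -> bool:
        return all(v == "ok" for v in self.stages.values())


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _hash_config(cfg: AnalysisConfig) -> str:
    blob = json.dumps({
        "tef": [cfg.tef.delta_d13C_mean, cfg.tef.delta_d13C_sd,
                cfg.tef.delta_d15N_mean, cfg.tef.delta_d15N_sd],
        "lambda": cfg.lambda_baseline,
        "mcmc": vars(cfg.mcmc), "polygon": vars(cfg.polygon),
        "concentration_dependent": cfg.concentration_dependent,
    }, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(
    cfg: AnalysisConfig,
    outdir: str | Path,
    scenario: synthdata.ScenarioConfig | None = None,
    data_dir: str | Path | None = None,
    drop_outside_consumers: bool = False,
) -> RunManifest:
    """Execute every stage on a synthetic scenario or pre-generated tables.

    When ``data_dir`` is given it must contain the tables written by
    :func:`isoforage.synthdata.write_scenario` (or externally prepared
    files with the same names/schemas); otherwise ``scenario`` (default
    scenario if omitted) is generated under ``outdir/data``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_hash_config(cfg), seed=cfg.mcmc.seed)

    fmt = "%.17g"

    # -- stage 0: data ------------------------------------------------------
    try:
        if data_dir is None:
            scenario = scenario or synthdata.ScenarioConfig(seed=cfg.mcmc.seed)
            data_paths = synthdata.write_scenario(scenario, outdir / "data")
        else:
            data_dir = Path(data_dir)
            data_paths = {k: data_dir / f"{k}.csv" for k in
                          ("sources", "source_replicates", "consumers",
                           "feeding_trials", "trophic_samples")}
            for key in ("sources", "consumers", "feeding_trials",
                        "trophic_samples"):
                if not data_paths[key].exists():
                    raise FileNotFoundError(
                        f"required input table missing: {data_paths[key]}")
        manifest.stages["data"] = "ok"
        manifest.outputs.update({f"data/{k}": p for k, p in data_paths.items()})
    except Exception as exc:
        manifest.stages["data"] = "failed"
        raise StageError("data", exc) from exc
    logger.info("stage data: ok")

    # -- stage 1: selectivity ----------------------------------------------
    try:
        trials = sel_mod.read_feeding_trials(data_paths["feeding_trials"])
        alpha_tbl = sel_mod.selectivity_per_crab(trials)
        tests = sel_mod.selectivity_group_tests(alpha_tbl)
        alpha_path = outdir / "selectivity_alpha.csv"
        alpha_tbl.to_csv(alpha_path, index=False, float_format=fmt)
        fr = tests["friedman"]
        summary = pd.DataFrame([{
            "test": "friedman", "statistic": fr.statistic, "df": fr.df,
            "p": fr.pvalue,
            "dropped_prey": ";".join(tests["dropped_prey"]),
        }])
        test_path = outdir / "selectivity_tests.csv"
        summary.to_csv(test_path, index=False, float_format=fmt)
        nem_path = outdir / "selectivity_nemenyi.csv"
        tests["nemenyi"].to_csv(nem_path, float_format=fmt)
        manifest.outputs.update({"selectivity_alpha": alpha_path,
                                 "selectivity_tests": test_path,
                                 "selectivity_nemenyi": nem_path})
        manifest.stages["selectivity"] = "ok"
    except Exception as exc:
        manifest.stages["selectivity"] = "failed"
        raise StageError("selectivity", exc) from exc
    logger.info("stage selectivity: ok")

    # -- stage 2: trophic ---------------------------------------------------
    try:
        samples = core_io.read_isotope_table(data_paths["trophic_samples"],
                                             "consumer")
        records = trophic_mod.compute_trophic_positions(
            samples, "Armases", cfg.baseline_category, cfg.tef,
            cfg.lambda_baseline)
        tp_frame = trophic_mod.records_to_frame(records)
        tp_path = outdir / "trophic_positions.csv"
        tp_frame.to_csv(tp_path, index=False, float_format=fmt)
        anova = trophic_mod.nested_anova(tp_frame)
        anova_path = outdir / "trophic_anova.csv"
        anova.rename(columns={
            "effect": "Source", "SS": "Sum of Squares", "df": "DF",
            "MS": "Mean Square", "F": "F value", "p": "P",
        }).to_csv(anova_path, index=False, float_format=fmt)
        pw = trophic_mod.pairwise_site_tests(tp_frame)
        pw_path = outdir / "trophic_pairwise.csv"
        pw.to_csv(pw_path, index=False, float_format=fmt)
        ranges = trophic_mod.tp_range_summary(tp_frame)
        rng_path = outdir / "trophic_ranges.csv"
        ranges.to_csv(rng_path, index=False, float_format=fmt)
        manifest.outputs.update({
            "trophic_positions": tp_path, "trophic_anova": anova_path,
            "trophic_pairwise": pw_path, "trophic_ranges": rng_path})
        manifest.stages["trophic"] = "ok"
    except Exception as exc:
        manifest.stages["trophic"] = "failed"
        raise StageError("trophic", exc) from exc
    logger.info("stage trophic: ok")

    # -- stage 3: mixing polygon -------------------------------------------
    try:
        sources = core_io.read_isotope_table(data_paths["sources"], "source")
        consumers = core_io.read_isotope_table(data_paths["consumers"],
                                               "consumer")
        frames = []
        outside_ids: list[str] = []
        for site in sorted({c.site for c in consumers}):
            site_sources = [s for s in sources if s.site == site]
            site_consumers = [c for c in consumers if c.site == site]
            res = polygon_mod.simulate_mixing_region(
                site_sources, site_consumers, cfg.tef,
                n_iterations=cfg.polygon.n_iterations,
                seed=cfg.polygon.seed,
                inclusion_alpha=cfg.polygon.inclusion_alpha)
            frame = res.to_frame()
            frame.insert(0, "site", site)
            frames.append(frame)
            outside_ids.extend(
                res.outside_flags.index[res.outside_flags].tolist())
        poly_tbl = pd.concat(frames, ignore_index=True)
        poly_path = outdir / "polygon_inclusion.csv"
        poly_tbl.to_csv(poly_path, index=False, float_format=fmt)
        manifest.outputs["polygon_inclusion"] = poly_path
        if outside_ids:
            msg = (f"{len(outside_ids)} consumer(s) outside the "
                   f"{(1 - cfg.polygon.inclusion_alpha) * 100:.0f}% mixing "
                   f"region: {outside_ids}")
            manifest.warnings.append(msg)
            logger.warning(msg)
            if drop_outside_consumers:
                consumers = [c for c in consumers
                             if c.sample_id not in set(outside_ids)]
        manifest.stages["polygon"] = "ok"
    except Exception as exc:
        manifest.stages["polygon"] = "failed"
        raise StageError("polygon", exc) from exc
    logger.info("stage polygon: ok")

    # -- stage 4: mixing model ---------------------------------------------
    try:
        posts = {}
        for status in ("natural", "disturbed"):
            sub_cons = [c for c in consumers if c.habitat_status == status]
            sub_sites = {c.site for c in sub_cons}
            sub_src = [s for s in sources if s.site in sub_sites]
            if not sub_cons:
                continue
            spec = simm_mod.MixingModelSpec(
                sources=sub_src, consumers=sub_cons, tef=cfg.tef,
                concentration_dependent=cfg.concentration_dependent)
            posts[status] = simm_mod.sample_posterior(spec, cfg.mcmc)
        for status, post in posts.items():
            summary = simm_mod.summarize_posterior(post)
            spath = outdir / f"simm_summary_{status}.csv"
            summary.to_csv(spath, index=False, float_format=fmt)
            dpath = outdir / f"simm_diagnostics_{status}.csv"
            post.diagnostics.to_csv(dpath, index=False, float_format=fmt)
            draws_path = outdir / f"simm_draws_{status}.csv"
            post.to_long_frame().to_csv(draws_path, index=False,
                                        float_format="%.8g")
            manifest.outputs.update({
                f"simm_summary_{status}": spath,
                f"simm_diagnostics_{status}": dpath,
                f"simm_draws_{status}": draws_path})
            if post.max_rhat > 1.05:
                manifest.warnings.append(
                    f"{status}: max rhat {post.max_rhat:.3f} > 1.05")
        manifest.stages["simm"] = "ok"
    except Exception as exc:
        manifest.stages["simm"] = "failed"
        raise StageError("simm", exc) from exc
    logger.info("stage simm: ok")

    manifest.to_json(outdir / "manifest.json")
    manifest.outputs["manifest"] = outdir / "manifest.json"
    return manifest


def make_report(manifest: RunManifest, outdir: str | Path) -> str:
    """Render a markdown run report from the manifest's output tables.

    Sections: selectivity ranking, trophic position tests, polygon
    inclusion, posterior diet proportions. Incomplete manifests yield a
    partial report with the missing stages flagged. Regeneration from the
    same manifest is idempotent.
    """
    outdir = Path(outdir)
    lines = ["# isoforage run report", ""]
    lines.append(f"Config hash: `{manifest.config_hash}`; seed: {manifest.seed}")
    lines.append("")
    if not manifest.all_ok:
        failed = [k for k, v in manifest.stages.items() if v != "ok"]
        lines.append(f"**PARTIAL REPORT** — stage(s) not ok: {failed}")
        lines.append("")
    if manifest.warnings:
        lines.append("## Warnings")
        for w in manifest.warnings:
            lines.append(f"- {w}")
        lines.append("")

    def _table(df: pd.DataFrame) -> list[str]:
        try:
            return [df.to_markdown(index=False, floatfmt=".4g"), ""]
        except ImportError:   # tabulate not installed
            return ["```", df.to_string(index=False), "```", ""]

    if "selectivity_alpha" in manifest.outputs:
        lines.append("## Feeding selectivity (mean alpha per prey)")
        alpha = pd.read_csv(manifest.outputs["selectivity_alpha"])
        prey_cols = [c for c in alpha.columns if c.startswith("alpha_")]
        ranking = (alpha[prey_cols].mean()
                   .rename(lambda c: c.removeprefix("alpha_"))
                   .sort_values(ascending=False))
        rank_df = ranking.reset_index()
        rank_df.columns = ["prey", "mean_alpha"]
        lines += _table(rank_df)
        tests = pd.read_csv(manifest.outputs["selectivity_tests"])
        lines += _table(tests)
    if "trophic_anova" in manifest.outputs:
        lines.append("## Trophic position")
        lines += _table(pd.read_csv(manifest.outputs["trophic_anova"]))
        lines += _table(pd.read_csv(manifest.outputs["trophic_ranges"]))
    if "polygon_inclusion" in manifest.outputs:
        lines.append("## Mixing-polygon inclusion")
        poly = pd.read_csv(manifest.outputs["polygon_inclusion"])
        n_out = int(poly["outside_region"].sum())
        lines.append(f"{len(poly)} consumers tested; {n_out} outside the "
                     "mixing region.")
        lines.append("")
    simm_keys = [k for k in manifest.outputs if k.startswith("simm_summary")]
    if simm_keys:
        lines.append("## Posterior diet proportions")
        for k in sorted(simm_keys):
            lines.append(f"### {k.removeprefix('simm_summary_')}")
            lines += _table(pd.read_csv(manifest.outputs[k]))
    text = "\n".join(lines)
    (outdir / "report.md").write_text(text)
    return text
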