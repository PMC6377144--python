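"""Trophic position from δ15N against a site-specific baseline organism.

TP = lambda + (δ15N_consumer − δ15N_baseline) / Δδ15N, with lambda the
assumed trophic level of the baseline (a long-lived primary consumer,
default 2) and Δδ15N the per-step enrichment factor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import IsotopeSample, TrophicEnrichment, ValidationError

logger = logging.getLogger("isoforage")


@dataclass(frozen=True)
class BaselineEstimate:
    site: str
    mean_d15N: float
    sd_d15N: float      # NaN when n == 1
    n: int


@dataclass(frozen=True)
class TrophicPositionRecord:
    sample_id: str
    site: str
    habitat_status: str
    tp: float
    baseline_d15N: float
    lam: float


def compute_baseline(
    samples: Sequence[IsotopeSample],
    baseline_category: str,
    site: str,
) -> BaselineEstimate:
    """Arithmetic mean ± sd of the baseline organism's δ15N at one site."""
    vals = [s.d15N for s in samples
            if s.category == baseline_category and s.site == site]
    if not vals:
        raise ValidationError(
            f"no {baseline_category!r} baseline samples at site {site!r}")
    arr = np.asarray(vals, dtype=float)
    if len(arr) == 1:
        sd = math.nan
        logger.warning("single baseline sample at site %r; sd undefined", site)
    else:
        sd = float(np.std(arr, ddof=1))
    return BaselineEstimate(site=site, mean_d15N=float(arr.mean()), sd_d15N=sd,
                            n=len(arr))


def trophic_position(
    consumer_d15N: float | np.ndarray,
    baseline_d15N: float,
    tef: TrophicEnrichment,
    lam: float = 2.0,
):
    """tp = lam + (consumer − baseline) / Δδ15N."""
    if not tef.delta_d15N_mean > 0:
        raise ValueError(
            f"Δδ15N must be > 0, got {tef.delta_d15N_mean}")
    return lam + (np.asarray(consumer_d15N, dtype=float) - baseline_d15N) \
        / tef.delta_d15N_mean


def compute_trophic_positions(
    samples: Sequence[IsotopeSample],
    consumer_category: str,
    baseline_category: str,
    tef: TrophicEnrichment,
    lam: float = 2.0,
) -> list[TrophicPositionRecord]:
    """Per-individual TP for every consumer, using its site's baseline mean."""
    sites = sorted({s.site for s in samples if s.category == consumer_category})
    baselines = {site: compute_baseline(samples, baseline_category, site)
                 for site in sites}
    out = []
    for s in samples:
        if s.category != consumer_category:
            continue
        base = baselines[s.site]
        tp = float(trophic_position(s.d15N, base.mean_d15N, tef, lam))
        out.append(TrophicPositionRecord(
            sample_id=s.sample_id, site=s.site, habitat_status=s.habitat_status,
            tp=tp, baseline_d15N=base.mean_d15N, lam=lam,
        ))
    return out


def records_to_frame(records: Sequence[TrophicPositionRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": r.sample_id, "site": r.site,
        "habitat_status": r.habitat_status, "tp": r.tp,
        "baseline_d15N": r.baseline_d15N, "lambda": r.lam,
    } for r in records])


def propagate_baseline_uncertainty(
    samples: Sequence[IsotopeSample],
    consumer_category: str,
    baseline_category: str,
    tef: TrophicEnrichment,
    lam: float = 2.0,
    n_draws: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo TP uncertainty from baseline and enrichment resampling.

    Each draw resamples the site baseline mean (normal, se of the mean) and
    the enrichment factor (normal, its sd); returns per-consumer mean, sd
    and a 95% interval of the propagated TP.
    """
    rng = np.random.default_rng(seed)
    sites = sorted({s.site for s in samples if s.category == consumer_category})
    baselines = {site: compute_baseline(samples, baseline_category, site)
                 for site in sites}
    rows = []
    for s in samples:
        if s.category != consumer_category:
            continue
        b = baselines[s.site]
        se = (b.sd_d15N / math.sqrt(b.n)) if b.n > 1 else 0.0
        base_draws = rng.normal(b.mean_d15N, se, size=n_draws)
        tef_draws = rng.normal(tef.delta_d15N_mean, tef.delta_d15N_sd,
                               size=n_draws)
        tef_draws = np.clip(tef_draws, 1e-6, None)
        tps = lam + (s.d15N - base_draws) / tef_draws
        rows.append({
            "sample_id": s.sample_id, "site": s.site,
            "habitat_status": s.habitat_status,
            "tp_mean": float(tps.mean()), "tp_sd": float(tps.std(ddof=1)),
            "tp_lo95": float(np.percentile(tps, 2.5)),
            "tp_hi95": float(np.percentile(tps, 97.5)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nested ANOVA (treatment fixed, site nested within treatment)
# ---------------------------------------------------------------------------

def nested_anova(
    records: Sequence[TrophicPositionRecord] | pd.DataFrame,
    response: str = "tp",
    treatment: str = "habitat_status",
    site: str = "site",
    denominator: str = "residual",
) -> pd.DataFrame:
    """Two-stratum nested ANOVA of TP on treatment with site nested within.

    Sequential sums of squares: SS_treat between treatment means,
    SS_site(treat) between site means within treatment, SS_resid within
    sites; they add to SS_total.

    ``denominator`` selects the error stratum for the treatment F:
    ``"residual"`` tests both effects over the residual mean square (the
    fixed-site reading); ``"site"`` tests treatment over the
    site-within-treatment mean square (the conventional random-site test).

    Returns a table with rows Treatment, Site within Treatment, Residuals
    and columns effect, SS, df, MS, F, p.
    """
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    df = records[[response, treatment, site]].dropna()
    if df[treatment].nunique() < 2:
        raise ValueError("need >= 2 treatment levels")
    cell_sizes = df.groupby([treatment, site], observed=True).size()
    if (cell_sizes < 2).any():
        bad = cell_sizes[cell_sizes < 2].index.tolist()
        raise ValueError(f"unreplicated cell(s): {bad}")
    sites_per_treat = df.groupby(treatment, observed=True)[site].nunique()
    if (sites_per_treat < 2).any():
        raise ValueError("need >= 2 sites per treatment")

    y = df[response].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    treat_means = df.groupby(treatment, observed=True)[response].agg(["mean", "size"])
    ss_treat = float((treat_means["size"] * (treat_means["mean"] - grand) ** 2).sum())
    df_treat = len(treat_means) - 1

    cell = df.groupby([treatment, site], observed=True)[response].agg(["mean", "size"])
    cell = cell.join(treat_means["mean"].rename("treat_mean"), on=treatment)
    ss_site = float((cell["size"] * (cell["mean"] - cell["treat_mean"]) ** 2).sum())
    df_site = len(cell) - len(treat_means)

    ss_resid = ss_total - ss_treat - ss_site
    df_resid = len(df) - len(cell)

    ms_treat = ss_treat / df_treat
    ms_site = ss_site / df_site if df_site > 0 else math.nan
    ms_resid = ss_resid / df_resid

    if denominator == "residual":
        denom_ms, denom_df = ms_resid, df_resid
    elif denominator == "site":
        denom_ms, denom_df = ms_site, df_site
    else:
        raise ValueError(f"denominator must be 'residual' or 'site', "
                         f"got {denominator!r}")

    def _f_p(ms, dfn, dms, dfd):
        if dms == 0 or not math.isfinite(dms):
            return (0.0, 1.0) if ms == 0 else (math.inf, 0.0)
        f = ms / dms
        return f, float(stats.f.sf(f, dfn, dfd))

    f_treat, p_treat = _f_p(ms_treat, df_treat, denom_ms, denom_df)
    f_site, p_site = _f_p(ms_site, df_site, ms_resid, df_resid)

    return pd.DataFrame([
        {"effect": "Treatment", "SS": ss_treat, "df": df_treat, "MS": ms_treat,
         "F": f_treat, "p": p_treat},
        {"effect": "Site within Treatment", "SS": ss_site, "df": df_site,
         "MS": ms_site, "F": f_site, "p": p_site},
        {"effect": "Residuals", "SS": ss_resid, "df": df_resid, "MS": ms_resid,
         "F": math.nan, "p": math.nan},
    ])


def pairwise_site_tests(
    records: Sequence[TrophicPositionRecord] | pd.DataFrame,
    method: str = "tukey",
) -> pd.DataFrame:
    """Per-site two-sample comparison of TP between habitat statuses.

    ``method`` is ``"tukey"`` (Tukey HSD, default) or ``"welch"``
    (Welch two-sample t). Sites missing one status are skipped with a
    warning.
    """
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    rows = []
    for site_name, grp in records.groupby("site", sort=True):
        statuses = sorted(grp["habitat_status"].unique())
        if len(statuses) < 2:
            logger.warning("site %r has a single habitat status; skipped",
                           site_name)
            continue
        a = grp.loc[grp["habitat_status"] == statuses[0], "tp"].to_numpy()
        b = grp.loc[grp["habitat_status"] == statuses[1], "tp"].to_numpy()
        if method == "welch":
            res = stats.ttest_ind(a, b, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
            label = "t"
        elif method == "tukey":
            res = stats.tukey_hsd(a, b)
            stat = float(res.statistic[0, 1])
            p = float(res.pvalue[0, 1])
            label = "diff"
        else:
            raise ValueError(f"method must be 'tukey' or 'welch', got {method!r}")
        rows.append({
            "site": site_name, "group_a": statuses[0], "group_b": statuses[1],
            "statistic": stat, "stat_type": label, "p": p,
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
        })
    return pd.DataFrame(rows)


def tp_range_summary(
    records: Sequence[TrophicPositionRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Per (site, habitat_status): min, max, range, mean ± sd, n of TP.

    Cells with fewer than 2 records are skipped with a warning.
    """
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    rows = []
    for (site_name, status), grp in records.groupby(
            ["site", "habitat_status"], sort=True):
        if len(grp) < 2:
            logger.warning("cell (%r, %r) has < 2 records; skipped",
                           site_name, status)
            continue
        tp = grp["tp"].to_numpy(dtype=float)
        rows.append({
            "site": site_name, "habitat_status": status,
            "n": len(tp), "min": float(tp.min()), "max": float(tp.max()),
            "range": float(tp.max() - tp.min()),
            "mean": float(tp.mean()), "sd": float(tp.std(ddof=1)),
        })
    return pd.DataFrame(rows)
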