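"""Feeding preference from multi-choice trials.

Workflow: estimate initial dry mass from a wet→dry regression, correct
for autogenic mass change using paired no-consumer controls, convert
remaining proportions to the Manly–Chesson selectivity index for
depleting prey, and compare prey with Friedman / Nemenyi rank tests.

The selectivity index for depleting (non-replaced) prey is

    alpha_i = ln(p_i) / sum_j ln(p_j)

where p_i is the proportion of prey i remaining (remaining mass over
initial mass when masses substitute for counts). Equal depletion gives
alpha = 1/m for every prey; alpha_i < 0 flags avoidance (autogenic mass
gain, p_i > 1); a fully consumed prey (p_i = 0) has no defined alpha and
is excluded from the normalising sum with a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import TRIAL_COLUMNS, ValidationError, _require_columns

logger = logging.getLogger("isoforage")


@dataclass(frozen=True)
class PreyMass:
    prey: str
    initial_wet_mass: float
    final_dry_mass: float


@dataclass
class FeedingTrial:
    """One crab's multi-choice record with its paired no-consumer control."""

    crab_id: str
    sex: str
    trial: int
    offered: list[PreyMass]
    controls: list[PreyMass]

    def validate(self) -> None:
        offered_prey = sorted(p.prey for p in self.offered)
        control_prey = sorted(p.prey for p in self.controls)
        if offered_prey != control_prey:
            raise ValidationError(
                f"crab {self.crab_id!r}: treatment prey {offered_prey} != "
                f"control prey {control_prey}"
            )
        for rec in list(self.offered) + list(self.controls):
            if not (math.isfinite(rec.initial_wet_mass) and rec.initial_wet_mass > 0):
                raise ValidationError(
                    f"crab {self.crab_id!r}, prey {rec.prey!r}: initial wet mass "
                    f"must be > 0, got {rec.initial_wet_mass}"
                )
            if not (math.isfinite(rec.final_dry_mass) and rec.final_dry_mass >= 0):
                raise ValidationError(
                    f"crab {self.crab_id!r}, prey {rec.prey!r}: final dry mass "
                    f"must be >= 0, got {rec.final_dry_mass}"
                )


@dataclass
class WetDryRegression:
    """OLS fit of dry mass on wet mass: dry = slope * wet + intercept."""

    slope: float
    intercept: float
    r2: float
    n: int

    def predict(self, wet: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(wet, dtype=float) + self.intercept


@dataclass
class SelectivityResult:
    alpha: dict[str, float]            # NaN for undefined prey
    p_remaining: dict[str, float]
    consumed_mass: dict[str, float]
    undefined: set[str] = field(default_factory=set)
    negative_consumption: set[str] = field(default_factory=set)

    @property
    def m_effective(self) -> int:
        return sum(1 for a in self.alpha.values() if not math.isnan(a))


def read_feeding_trials(path: str | Path) -> list[FeedingTrial]:
    """Read the feeding-trial CSV (one row per crab × prey × treatment/control)."""
    df = pd.read_csv(path)
    _require_columns(df, TRIAL_COLUMNS, path)
    trials = []
    for (crab_id, sex, trial), grp in df.groupby(["crab_id", "sex", "trial"],
                                                 sort=True):
        is_ctrl = grp["is_control"].astype(bool)
        make = lambda sub: [
            PreyMass(str(r.prey), float(r.initial_wet_mass), float(r.final_dry_mass))
            for r in sub.itertuples(index=False)
        ]
        ft = FeedingTrial(
            crab_id=str(crab_id), sex=str(sex), trial=int(trial),
            offered=make(grp[~is_ctrl]), controls=make(grp[is_ctrl]),
        )
        ft.validate()
        trials.append(ft)
    return trials


def write_feeding_trials(trials: Sequence[FeedingTrial], path: str | Path) -> None:
    rows = []
    for t in trials:
        for rec, ctrl in ((t.offered, False), (t.controls, True)):
            for p in rec:
                rows.append({
                    "crab_id": t.crab_id, "sex": t.sex, "trial": t.trial,
                    "prey": p.prey, "initial_wet_mass": p.initial_wet_mass,
                    "final_dry_mass": p.final_dry_mass, "is_control": ctrl,
                })
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Dry-mass estimation and autogenic correction
# ---------------------------------------------------------------------------

def fit_wet_dry_regression(pairs: Sequence[tuple[float, float]]) -> WetDryRegression:
    """Ordinary least squares of dry mass on wet mass.

    Requires >= 3 pairs and non-degenerate wet masses.
    """
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 (wet, dry) pairs, got {len(pairs)}")
    wet = np.array([p[0] for p in pairs], dtype=float)
    dry = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(wet) == 0 or np.var(wet) == 0:
        raise ValueError("wet masses have zero variance; cannot fit regression")
    res = stats.linregress(wet, dry)
    return WetDryRegression(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue ** 2), n=len(pairs),
    )


def fit_regressions_per_prey(
    trials: Sequence[FeedingTrial],
) -> dict[str, WetDryRegression]:
    """Fit one wet→dry regression per prey from pooled control leaves.

    Control halves carry both an initial wet and a final dry mass, so they
    supply the (wet, dry) pairs; water content is species-specific, hence
    the per-prey fit.
    """
    pairs: dict[str, list[tuple[float, float]]] = {}
    for t in trials:
        for c in t.controls:
            pairs.setdefault(c.prey, []).append(
                (c.initial_wet_mass, c.final_dry_mass))
    return {prey: fit_wet_dry_regression(pp) for prey, pp in sorted(pairs.items())}


def estimate_consumption(
    trial: FeedingTrial,
    regressions: Mapping[str, WetDryRegression] | WetDryRegression,
) -> dict[str, float]:
    """Consumed dry mass per prey, corrected for autogenic change.

    est_init_dry = reg(initial_wet); the matched control supplies a
    multiplicative autogenic factor g = control_final_dry /
    reg(control_initial_wet); consumed = est_init_dry * g - final_dry.
    Negative values (autogenic gain or measurement noise) are retained.
    """
    controls = {c.prey: c for c in trial.controls}
    consumed = {}
    for rec in trial.offered:
        reg = (regressions[rec.prey] if isinstance(regressions, Mapping)
               else regressions)
        ctrl = controls[rec.prey]
        ctrl_pred = float(reg.predict(ctrl.initial_wet_mass))
        if ctrl_pred <= 0:
            raise ValueError(
                f"crab {trial.crab_id!r}, prey {rec.prey!r}: predicted control "
                f"dry mass {ctrl_pred:.4g} <= 0"
            )
        g = ctrl.final_dry_mass / ctrl_pred
        est_init_dry = float(reg.predict(rec.initial_wet_mass))
        consumed[rec.prey] = est_init_dry * g - rec.final_dry_mass
    return consumed


def estimate_initial_dry(
    trial: FeedingTrial,
    regressions: Mapping[str, WetDryRegression] | WetDryRegression,
) -> dict[str, float]:
    """Autogenic-adjusted initial dry mass per offered prey."""
    controls = {c.prey: c for c in trial.controls}
    out = {}
    for rec in trial.offered:
        reg = (regressions[rec.prey] if isinstance(regressions, Mapping)
               else regressions)
        ctrl = controls[rec.prey]
        g = ctrl.final_dry_mass / float(reg.predict(ctrl.initial_wet_mass))
        out[rec.prey] = float(reg.predict(rec.initial_wet_mass)) * g
    return out


# ---------------------------------------------------------------------------
# Manly–Chesson index
# ---------------------------------------------------------------------------

def manly_alpha(
    initial_dry: Mapping[str, float],
    consumed: Mapping[str, float],
    epsilon_floor: float | None = None,
) -> SelectivityResult:
    """Selectivity index for depleting prey from remaining proportions.

    Parameters
    ----------
    initial_dry : per-prey offered dry mass (g), all > 0.
    consumed : per-prey consumed dry mass (g); may be negative.
    epsilon_floor : optional floor substituted for p = 0 (sensitivity
        analysis); by default fully consumed prey are flagged undefined
        and excluded from the normalising sum.

    Raises
    ------
    ValueError when any p_i < 0 (consumption exceeding the offer is a data
    fault), when every prey is fully consumed, or when the log-sum
    denominator vanishes (no net feeding signal).
    """
    if set(initial_dry) != set(consumed):
        raise ValueError("initial_dry and consumed must cover the same prey")
    p: dict[str, float] = {}
    negative = set()
    for prey, n_i in initial_dry.items():
        if not (math.isfinite(n_i) and n_i > 0):
            raise ValueError(f"prey {prey!r}: initial dry mass must be > 0, got {n_i}")
        c_i = consumed[prey]
        p_i = 1.0 - c_i / n_i
        if p_i < 0:
            if p_i > -1e-9:  # fully consumed up to rounding
                p_i = 0.0
            else:
                raise ValueError(
                    f"prey {prey!r}: remaining proportion {p_i:.4g} < 0 "
                    "(consumed exceeds offered)"
                )
        if c_i < 0:
            negative.add(prey)
        p[prey] = p_i

    undefined = set()
    logs: dict[str, float] = {}
    for prey, p_i in p.items():
        if p_i == 0.0:
            if epsilon_floor is not None:
                logs[prey] = math.log(epsilon_floor)
            else:
                undefined.add(prey)
        else:
            logs[prey] = math.log(p_i)
    if not logs:
        raise ValueError("all prey fully consumed: selectivity index undefined")
    denom = sum(logs.values())
    if denom == 0.0 or abs(denom) < 1e-300:
        raise ValueError("zero log-sum denominator: no net consumption signal")
    alpha = {prey: math.nan for prey in p}
    for prey, lg in logs.items():
        alpha[prey] = lg / denom
    return SelectivityResult(
        alpha=alpha, p_remaining=p,
        consumed_mass=dict(consumed),
        undefined=undefined, negative_consumption=negative,
    )


def selectivity_per_crab(
    trials: Sequence[FeedingTrial],
    regressions: Mapping[str, WetDryRegression] | None = None,
    epsilon_floor: float | None = None,
) -> pd.DataFrame:
    """Per-crab alpha table: one row per crab, one column per prey.

    NaN marks undefined alpha (fully consumed prey). Regressions default to
    per-prey fits pooled over all control leaves.
    """
    if regressions is None:
        regressions = fit_regressions_per_prey(trials)
    rows = []
    for t in trials:
        consumed = estimate_consumption(t, regressions)
        init = estimate_initial_dry(t, regressions)
        res = manly_alpha(init, consumed, epsilon_floor=epsilon_floor)
        row = {"crab_id": t.crab_id, "sex": t.sex, "trial": t.trial}
        row.update({f"alpha_{prey}": a for prey, a in res.alpha.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rank-based group tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    pvalue: float


def friedman_test(block_matrix: np.ndarray | pd.DataFrame) -> FriedmanResult:
    """Friedman rank-sum test over a blocks × prey matrix (mid-rank ties).

    Requires >= 2 prey (columns), >= 2 blocks (rows) and no missing cells;
    no imputation is attempted.
    """
    m = np.asarray(block_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError(f"need a 2-D matrix with >= 2 rows and columns, "
                         f"got shape {m.shape}")
    if np.isnan(m).any():
        raise ValueError("block matrix contains missing cells; no imputation")
    if np.all(m == m[0, 0]):
        return FriedmanResult(statistic=0.0, df=m.shape[1] - 1, pvalue=1.0)
    stat, p = stats.friedmanchisquare(*(m[:, j] for j in range(m.shape[1])))
    return FriedmanResult(statistic=float(stat), df=m.shape[1] - 1,
                          pvalue=float(p))


def nemenyi_posthoc(block_matrix: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """All-pairs Nemenyi test on Friedman mean ranks.

    p_ij = P(studentized range_{k, inf} >= |Rbar_i - Rbar_j| /
    sqrt(k (k+1) / (12 n))). Returns a symmetric k × k matrix with unit
    diagonal; column labels follow the input when it is a DataFrame.
    """
    if isinstance(block_matrix, pd.DataFrame):
        labels = list(block_matrix.columns)
        m = block_matrix.to_numpy(dtype=float)
    else:
        m = np.asarray(block_matrix, dtype=float)
        labels = list(range(m.shape[1]))
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError(f"need a 2-D matrix with >= 2 rows and columns, "
                         f"got shape {m.shape}")
    if np.isnan(m).any():
        raise ValueError("block matrix contains missing cells; no imputation")
    n, k = m.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (12.0 * n))
    diff = np.abs(mean_ranks[:, None] - mean_ranks[None, :])
    q = diff / se
    pvals = stats.studentized_range.sf(q, k, np.inf)
    np.fill_diagonal(pvals, 1.0)
    return pd.DataFrame(np.clip(pvals, 0.0, 1.0), index=labels, columns=labels)


def selectivity_group_tests(alpha_table: pd.DataFrame) -> dict:
    """Friedman + Nemenyi over the per-crab alpha table (defined prey only).

    Prey columns with any undefined alpha (NaN) are dropped from the rank
    tests, mirroring the exclusion of fully consumed prey.
    """
    prey_cols = [c for c in alpha_table.columns if c.startswith("alpha_")]
    block = alpha_table[prey_cols]
    keep = [c for c in prey_cols if not block[c].isna().any()]
    dropped = sorted(set(prey_cols) - set(keep))
    if dropped:
        logger.warning("dropping prey with undefined alpha from rank tests: %s",
                       [c.removeprefix("alpha_") for c in dropped])
    block = block[keep]
    block.columns = [c.removeprefix("alpha_") for c in keep]
    fr = friedman_test(block)
    nem = nemenyi_posthoc(block)
    return {"friedman": fr, "nemenyi": nem, "dropped_prey":
            [c.removeprefix("alpha_") for c in dropped]}
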