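"""Domain types, CSV readers/writers, configuration and validation.

All tracer values are stored as plain decimals in per-mil (‰) units:
d13C relative to VPDB, d15N relative to air N2. No internal rescaling
is performed anywhere in the pipeline.

Canonical interchange format is CSV. An XLSX import shim with a
configurable column mapping is provided for externally supplied
spreadsheets, but it maps onto the same validated schemas.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("isoforage")

TRACERS = ("d13C", "d15N")

HABITAT_STATUSES = ("natural", "disturbed")

CONSUMER_COLUMNS = [
    "sample_id", "site", "habitat_status", "category", "d13C", "d15N", "pctC", "pctN",
]
SOURCE_COLUMNS = [
    "name", "site", "mu_d13C", "sigma_d13C", "mu_d15N", "sigma_d15N",
    "conc_C", "conc_N", "n",
]
TRIAL_COLUMNS = [
    "crab_id", "sex", "trial", "prey", "initial_wet_mass", "final_dry_mass",
    "is_control",
]


class ValidationError(ValueError):
    """A record violates a schema invariant."""


class SchemaError(ValueError):
    """A table is missing required columns or has the wrong layout."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopeSample:
    """One organism/tissue measurement in two-tracer isotope space.

    ``category`` names either a consumer taxon or a source group; ``pctC``
    and ``pctN`` are elemental content by mass (percent), and may be NaN
    when concentration dependence is not used downstream.
    """

    sample_id: str
    site: str
    habitat_status: str
    category: str
    d13C: float
    d15N: float
    pctC: float = math.nan
    pctN: float = math.nan

    def validate(self) -> None:
        if self.habitat_status not in HABITAT_STATUSES:
            raise ValidationError(
                f"sample {self.sample_id!r}: habitat_status must be one of "
                f"{HABITAT_STATUSES}, got {self.habitat_status!r}"
            )
        for tracer in TRACERS:
            v = getattr(self, tracer)
            if not math.isfinite(v):
                raise ValidationError(
                    f"sample {self.sample_id!r}: {tracer} must be finite, got {v!r}"
                )
        if not math.isnan(self.pctC) and not 0.0 <= self.pctC <= 100.0:
            raise ValidationError(
                f"sample {self.sample_id!r}: pctC must lie in [0, 100], got {self.pctC}"
            )
        if not math.isnan(self.pctN) and not 0.0 < self.pctN <= 100.0:
            raise ValidationError(
                f"sample {self.sample_id!r}: pctN must lie in (0, 100], got {self.pctN}"
            )


@dataclass(frozen=True)
class SourceGroup:
    """Per-site aggregated source (prey) category.

    ``mu``/``sigma``/``conc`` are per-tracer in the order (d13C, d15N);
    ``conc`` holds %C for the carbon tracer and %N for nitrogen.
    """

    name: str
    site: str
    mu: tuple[float, float]
    sigma: tuple[float, float]
    conc: tuple[float, float]
    n: int
    sd_undefined: bool = False

    def validate(self, require_conc: bool = True) -> None:
        if any(s < 0 or not math.isfinite(s) for s in self.sigma):
            raise ValidationError(
                f"source {self.name!r} at {self.site!r}: sigma must be >= 0, "
                f"got {self.sigma}"
            )
        if any(not math.isfinite(m) for m in self.mu):
            raise ValidationError(
                f"source {self.name!r} at {self.site!r}: non-finite mean {self.mu}"
            )
        if require_conc and any(not (c > 0) for c in self.conc):
            raise ValidationError(
                f"source {self.name!r} at {self.site!r}: concentrations must be "
                f"> 0, got {self.conc}"
            )
        if self.n < 1:
            raise ValidationError(
                f"source {self.name!r} at {self.site!r}: n must be >= 1, got {self.n}"
            )


@dataclass(frozen=True)
class TrophicEnrichment:
    """Per-tracer trophic discrimination factor, mean ± sd (‰)."""

    delta_d15N_mean: float = 5.2
    delta_d15N_sd: float = 0.28
    delta_d13C_mean: float = 4.6
    delta_d13C_sd: float = 0.71

    def validate(self) -> None:
        if self.delta_d15N_sd < 0 or self.delta_d13C_sd < 0:
            raise ValidationError("trophic enrichment sds must be >= 0")

    @property
    def mean(self) -> tuple[float, float]:
        """(d13C, d15N) enrichment means, tracer order matching TRACERS."""
        return (self.delta_d13C_mean, self.delta_d15N_mean)

    @property
    def sd(self) -> tuple[float, float]:
        return (self.delta_d13C_sd, self.delta_d15N_sd)


@dataclass
class McmcConfig:
    chains: int = 3
    iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.chains < 2:
            raise ValidationError("mcmc.chains must be >= 2 for diagnostics")
        if not self.burn_in < self.iterations:
            raise ValidationError("mcmc.burn_in must be < mcmc.iterations")
        if self.thin < 1:
            raise ValidationError("mcmc.thin must be >= 1")


@dataclass
class PolygonConfig:
    n_iterations: int = 1500
    seed: int = 0
    inclusion_alpha: float = 0.05

    def validate(self) -> None:
        if not 0.0 < self.inclusion_alpha < 1.0:
            raise ValidationError("polygon.inclusion_alpha must lie in (0, 1)")
        if self.n_iterations < 100:
            raise ValidationError("polygon.n_iterations must be >= 100")


@dataclass
class AnalysisConfig:
    """Run-level configuration shared by every pipeline stage."""

    tef: TrophicEnrichment = field(default_factory=TrophicEnrichment)
    lambda_baseline: float = 2.0
    baseline_category: str = "Melampus"
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    polygon: PolygonConfig = field(default_factory=PolygonConfig)
    paths: dict = field(default_factory=dict)
    concentration_dependent: bool = True

    def validate(self) -> None:
        self.tef.validate()
        self.mcmc.validate()
        self.polygon.validate()


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file (nested sections)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = AnalysisConfig()
    if "tef" in raw:
        cfg.tef = TrophicEnrichment(**raw["tef"])
    if "mcmc" in raw:
        cfg.mcmc = McmcConfig(**raw["mcmc"])
    if "polygon" in raw:
        cfg.polygon = PolygonConfig(**raw["polygon"])
    for key in ("lambda_baseline", "baseline_category", "paths",
                "concentration_dependent"):
        if key in raw:
            setattr(cfg, key, raw[key])
    cfg.validate()
    return cfg


def save_config(cfg: AnalysisConfig, path: str | Path) -> None:
    raw = {
        "tef": vars(cfg.tef).copy() if not isinstance(cfg.tef, dict) else cfg.tef,
        "lambda_baseline": cfg.lambda_baseline,
        "baseline_category": cfg.baseline_category,
        "mcmc": vars(cfg.mcmc),
        "polygon": vars(cfg.polygon),
        "paths": cfg.paths,
        "concentration_dependent": cfg.concentration_dependent,
    }
    raw["tef"] = {
        "delta_d15N_mean": cfg.tef.delta_d15N_mean,
        "delta_d15N_sd": cfg.tef.delta_d15N_sd,
        "delta_d13C_mean": cfg.tef.delta_d13C_mean,
        "delta_d13C_sd": cfg.tef.delta_d13C_sd,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _parse_float(value, row: int, column: str, path) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    if isinstance(value, str) and value.strip() == "":
        return math.nan
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"{path}: non-numeric value {value!r} in column {column!r} at row {row}"
        ) from None


def read_isotope_table(path: str | Path, schema: str):
    """Read a consumer or source CSV into validated domain records.

    Parameters
    ----------
    path : file path
    schema : {"consumer", "source"}

    Returns
    -------
    list of IsotopeSample (consumer) or SourceGroup (source).

    Raises
    ------
    SchemaError if required columns are absent; ValidationError naming the
    offending row for non-numeric or invariant-violating values.
    """
    df = pd.read_csv(path)
    if schema == "consumer":
        _require_columns(df, CONSUMER_COLUMNS, path)
        out: list[IsotopeSample] = []
        for i, row in enumerate(df.itertuples(index=False), start=2):
            rec = IsotopeSample(
                sample_id=str(row.sample_id),
                site=str(row.site),
                habitat_status=str(row.habitat_status),
                category=str(row.category),
                d13C=_parse_float(row.d13C, i, "d13C", path),
                d15N=_parse_float(row.d15N, i, "d15N", path),
                pctC=_parse_float(row.pctC, i, "pctC", path),
                pctN=_parse_float(row.pctN, i, "pctN", path),
            )
            try:
                rec.validate()
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {i}: {exc}") from None
            out.append(rec)
        return out
    if schema == "source":
        _require_columns(df, SOURCE_COLUMNS, path)
        groups: list[SourceGroup] = []
        for i, row in enumerate(df.itertuples(index=False), start=2):
            grp = SourceGroup(
                name=str(row.name),
                site=str(row.site),
                mu=(_parse_float(row.mu_d13C, i, "mu_d13C", path),
                    _parse_float(row.mu_d15N, i, "mu_d15N", path)),
                sigma=(_parse_float(row.sigma_d13C, i, "sigma_d13C", path),
                       _parse_float(row.sigma_d15N, i, "sigma_d15N", path)),
                conc=(_parse_float(row.conc_C, i, "conc_C", path),
                      _parse_float(row.conc_N, i, "conc_N", path)),
                n=int(row.n),
            )
            try:
                grp.validate(require_conc=False)
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {i}: {exc}") from None
            groups.append(grp)
        return groups
    raise ValueError(f"unknown schema {schema!r}; expected 'consumer' or 'source'")


def consumers_to_frame(samples: Iterable[IsotopeSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(s, c) for c in CONSUMER_COLUMNS} for s in samples],
        columns=CONSUMER_COLUMNS,
    )


def sources_to_frame(groups: Iterable[SourceGroup]) -> pd.DataFrame:
    rows = []
    for g in groups:
        rows.append({
            "name": g.name, "site": g.site,
            "mu_d13C": g.mu[0], "sigma_d13C": g.sigma[0],
            "mu_d15N": g.mu[1], "sigma_d15N": g.sigma[1],
            "conc_C": g.conc[0], "conc_N": g.conc[1], "n": g.n,
        })
    return pd.DataFrame(rows, columns=SOURCE_COLUMNS)


def write_isotope_table(records, path: str | Path, schema: str) -> None:
    """Write records back to the canonical CSV schema (17 sig. digits)."""
    if schema == "consumer":
        df = consumers_to_frame(records)
    elif schema == "source":
        df = sources_to_frame(records)
    else:
        raise ValueError(f"unknown schema {schema!r}")
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Source aggregation
# ---------------------------------------------------------------------------

def aggregate_sources(
    samples: Sequence[IsotopeSample],
    grouping: Mapping[str, str] | None = None,
) -> list[SourceGroup]:
    """Aggregate raw source replicates into per-(group, site) SourceGroups.

    ``grouping`` maps raw categories to group names (identity when omitted).
    For each group at each site the per-tracer mean and sample sd (ddof=1)
    and the mean %C/%N are computed; a single-replicate group gets sd = 0
    with ``sd_undefined`` flagged and a logged warning.
    """
    if grouping is None:
        grouping = {}
    keyed: dict[tuple[str, str], list[IsotopeSample]] = {}
    for s in samples:
        group = grouping.get(s.category, s.category)
        keyed.setdefault((group, s.site), []).append(s)
    if grouping:
        wanted = set(grouping.values())
        produced = {g for g, _ in keyed}
        empty = wanted - produced
        if empty:
            raise ValidationError(f"no samples for group(s): {sorted(empty)}")
    out = []
    for (group, site), members in sorted(keyed.items()):
        d13 = np.array([m.d13C for m in members], dtype=float)
        d15 = np.array([m.d15N for m in members], dtype=float)
        pc = np.array([m.pctC for m in members], dtype=float)
        pn = np.array([m.pctN for m in members], dtype=float)
        n = len(members)
        if n == 1:
            sd = (0.0, 0.0)
            flagged = True
            logger.warning("source group %r at site %r has a single replicate; "
                           "sd set to 0", group, site)
        else:
            sd = (float(np.std(d13, ddof=1)), float(np.std(d15, ddof=1)))
            flagged = False
        out.append(SourceGroup(
            name=group, site=site,
            mu=(float(d13.mean()), float(d15.mean())),
            sigma=sd,
            conc=(float(np.nanmean(pc)) if not np.all(np.isnan(pc)) else math.nan,
                  float(np.nanmean(pn)) if not np.all(np.isnan(pn)) else math.nan),
            n=n, sd_undefined=flagged,
        ))
    return out


# ---------------------------------------------------------------------------
# XLSX shim
# ---------------------------------------------------------------------------

def read_isotope_xlsx(
    path: str | Path,
    schema: str,
    column_map: Mapping[str, str],
    sheet: str | int = 0,
    defaults: Mapping[str, object] | None = None,
) -> list:
    """Import an XLSX sheet whose layout is declared by ``column_map``.

    ``column_map`` maps canonical column names (see CONSUMER_COLUMNS /
    SOURCE_COLUMNS) to the spreadsheet's own headers. Canonical columns
    absent from the map are filled from ``defaults`` (or NaN). The sheet is
    normalized to the canonical CSV schema and run through the same
    validation as :func:`read_isotope_table`.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    canonical = CONSUMER_COLUMNS if schema == "consumer" else SOURCE_COLUMNS
    defaults = dict(defaults or {})
    out = pd.DataFrame()
    for col in canonical:
        if col in column_map:
            src = column_map[col]
            if src not in df.columns:
                raise SchemaError(f"{path}: mapped column {src!r} not found")
            out[col] = df[src]
        elif col in defaults:
            out[col] = defaults[col]
        else:
            out[col] = math.nan
    import io as _io

    buf = _io.StringIO()
    out.to_csv(buf, index=False)
    buf.seek(0)
    return read_isotope_table(buf, schema)  # type: ignore[arg-type]
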