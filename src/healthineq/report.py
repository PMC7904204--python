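"""Descriptive study outputs: sample profile, stratified prevalence and mean
z-score tables, concentration summaries, and the end-to-end report bundle.

Rounding conventions follow the usual presentation of such studies:
percentages and prevalences at 1 decimal place, mean z-scores at 2, indices
and contributions at 3.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .decomposition import format_decomposition_table, round_half_away, wagstaff_decompose
from .errors import ConfigurationError, DomainError
from .inequality import concentration
from .models import FactorSpec
from .synthetic import CovariateSpec, SimulationConfig, generate_population

__all__ = [
    "sample_profile",
    "prevalence_by_strata",
    "meanz_by_strata",
    "concentration_summary",
    "run_report",
    "default_factor_specs",
]

logger = logging.getLogger(__name__)

OUTCOMES = ("thinness", "stunting", "both")
Z_COLUMNS = ("z_bmi_age", "z_height_age")


def default_factor_specs() -> list[FactorSpec]:
    """Factor coding used by the default report: reference category first."""
    return [
        FactorSpec("age_group", ("early", "late")),
        FactorSpec("education", ("no_schooling", "1-7", "8-9", "10+")),
        FactorSpec("working", ("yes", "no")),
        FactorSpec("media", ("no_exposure", "rare", "frequent")),
        FactorSpec("wealth_quintile", ("1", "2", "3", "4", "5")),
        FactorSpec("caste", ("sc_st", "non_sc_st")),
        FactorSpec("religion", ("hindu", "non_hindu")),
        FactorSpec("residence", ("urban", "rural")),
        FactorSpec("state", ("uttar_pradesh", "bihar")),
    ]


def _require_columns(records: pd.DataFrame, names) -> None:
    missing = [n for n in names if n not in records.columns]
    if missing:
        raise DomainError(f"records table missing column(s): {missing}")


def sample_profile(
    records: pd.DataFrame,
    factor_specs: Sequence[FactorSpec],
    by: str | None = None,
) -> pd.DataFrame:
    """Counts and percentages per category, optionally within groups.

    Percentages are of the (group) column total, rounded half away from zero
    to 1 decimal place; raw counts are reported alongside.
    """
    if records.empty:
        raise DomainError("cannot profile an empty records table")
    _require_columns(records, [s.name for s in factor_specs] + ([by] if by else []))
    groups = records.groupby(by, sort=True) if by else [(None, records)]
    rows = []
    for gval, sub in groups:
        total = len(sub)
        for spec in factor_specs:
            values = sub[spec.name].astype(str)
            for cat in spec.categories:
                count = int((values == str(cat)).sum())
                row = {
                    "stratifier": spec.name,
                    "category": cat,
                    "count": count,
                    "pct": round_half_away(100.0 * count / total, 1),
                    "denominator": total,
                }
                if by:
                    row[by] = gval
                rows.append(row)
        row = {
            "stratifier": "total",
            "category": "total",
            "count": total,
            "pct": 100.0,
            "denominator": total,
        }
        if by:
            row[by] = gval
        rows.append(row)
    return pd.DataFrame(rows)


def _weighted_stat(
    records: pd.DataFrame,
    value_col: str,
    factor_specs: Sequence[FactorSpec],
    weight_col: str | None,
    by: str | None,
    *,
    scale: float,
    decimals: int,
    stat_name: str,
) -> pd.DataFrame:
    _require_columns(
        records,
        [value_col]
        + [s.name for s in factor_specs]
        + ([weight_col] if weight_col else [])
        + ([by] if by else []),
    )
    groups = records.groupby(by, sort=True) if by else [(None, records)]
    rows = []
    for gval, sub in groups:
        valid = sub[sub[value_col].notna()]
        for spec in list(factor_specs) + [None]:
            if spec is None:
                cats = [("total", valid)]
                strat = "total"
            else:
                values = valid[spec.name].astype(str)
                cats = [(c, valid[values == str(c)]) for c in spec.categories]
                strat = spec.name
            for cat, cell in cats:
                n_cell = len(cell)
                if n_cell == 0:
                    rows.append(
                        {
                            "stratifier": strat,
                            "category": cat,
                            stat_name: np.nan,
                            "denominator": 0,
                            "flag": "empty",
                            **({by: gval} if by else {}),
                        }
                    )
                    continue
                w = (
                    cell[weight_col].to_numpy(dtype=float)
                    if weight_col
                    else np.ones(n_cell)
                )
                val = float(np.average(cell[value_col].to_numpy(dtype=float), weights=w))
                rows.append(
                    {
                        "stratifier": strat,
                        "category": cat,
                        stat_name: round_half_away(val * scale, decimals),
                        "denominator": n_cell,
                        "flag": "",
                        **({by: gval} if by else {}),
                    }
                )
    return pd.DataFrame(rows)


def prevalence_by_strata(
    records: pd.DataFrame,
    outcome: str,
    factor_specs: Sequence[FactorSpec],
    weight_col: str | None = None,
    by: str | None = None,
) -> pd.DataFrame:
    """Weighted prevalence (percent, 1 d.p.) of a binary outcome per category.

    Records with a missing outcome are excluded and the per-cell denominator
    reported; empty cells are flagged rather than shown as zero.
    """
    return _weighted_stat(
        records, outcome, factor_specs, weight_col, by,
        scale=100.0, decimals=1, stat_name="prevalence",
    )


def meanz_by_strata(
    records: pd.DataFrame,
    z_column: str,
    factor_specs: Sequence[FactorSpec],
    weight_col: str | None = None,
    by: str | None = None,
) -> pd.DataFrame:
    """Weighted mean z-score (2 d.p.) per category, with denominators."""
    return _weighted_stat(
        records, z_column, factor_specs, weight_col, by,
        scale=1.0, decimals=2, stat_name="mean_z",
    )


def concentration_summary(
    records: pd.DataFrame,
    outcomes: Sequence[str],
    score_col: str,
    weight_col: str | None = None,
    by: str | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Concentration index per outcome (and group), plus curve coordinates."""
    groups = records.groupby(by, sort=True) if by else [(None, records)]
    rows = []
    curves: dict[str, pd.DataFrame] = {}
    for gval, sub in groups:
        for outcome in outcomes:
            valid = sub[sub[outcome].notna()]
            res = concentration(
                valid[outcome].to_numpy(dtype=float),
                valid[score_col].to_numpy(dtype=float),
                valid[weight_col].to_numpy(dtype=float) if weight_col else None,
            )
            key = f"{outcome}" if gval is None else f"{gval}_{outcome}"
            curves[key] = res.curve_points
            rows.append(
                {
                    **({by: gval} if by else {}),
                    "outcome": outcome,
                    "index": round_half_away(res.index, 3),
                    "orientation": res.orientation,
                    "n": res.n_effective,
                    "mean_outcome": round_half_away(res.mean_outcome, 4),
                }
            )
    return pd.DataFrame(rows), curves


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        return yaml.safe_load(text)
    return dict(config)


def _build_simulation_config(block: Mapping) -> SimulationConfig:
    block = dict(block)
    if "covariate_specs" in block:
        block["covariate_specs"] = {
            sex: tuple(
                CovariateSpec(
                    name=s["name"],
                    categories=tuple(s["categories"]),
                    base_logits=tuple(s["base_logits"]),
                    rank_slopes=tuple(s["rank_slopes"]),
                )
                for s in specs
            )
            for sex, specs in block["covariate_specs"].items()
        }
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(block) - valid
    if unknown:
        raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(**block)


def run_report(config, out_dir: str | Path | None = None) -> dict:
    """Run the full descriptive + inequality analysis and write a CSV bundle.

    ``config`` is a mapping (or YAML path) with keys:

    * ``data``: CSV path of survey records, or ``simulate``: a
      SimulationConfig block (one of the two is required);
    * ``score``: ranking column (default ``wealth_score``);
    * ``weight``: optional weight column;
    * ``outcomes``: binary outcome columns (default thinness/stunting/both);
    * ``out_dir``: output directory (overridden by the argument).

    Writes one CSV per table — profile, prevalence per outcome, mean-z per
    indicator, concentration summary and curves, and one decomposition per
    sex per outcome — plus ``manifest.json`` listing every output with its
    row count.  Returns the manifest as a dict.  Reruns with the same config
    and seed are byte-identical.
    """
    cfg = _load_config(config)
    out_dir = Path(out_dir if out_dir is not None else cfg.get("out_dir", "report_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    if "data" in cfg:
        records = pd.read_csv(cfg["data"])
        logger.info("loaded %d records from %s", len(records), cfg["data"])
    elif "simulate" in cfg:
        sim = _build_simulation_config(cfg["simulate"])
        records = generate_population(sim)
        logger.info("simulated %d records (seed %d)", len(records), sim.seed)
    else:
        raise ConfigurationError("config needs either a 'data' path or a 'simulate' block")

    score_col = cfg.get("score", "wealth_score")
    weight_col = cfg.get("weight")
    outcomes = tuple(cfg.get("outcomes", OUTCOMES))
    _require_columns(records, [score_col, "sex", *outcomes])
    if "wealth_quintile" in records.columns:
        records = records.assign(wealth_quintile=records["wealth_quintile"].astype(str))

    specs = default_factor_specs()
    specs = [s for s in specs if s.name in records.columns]
    # wealth enters the decomposition as quintile dummies against the poorest,
    # while ranking uses the continuous score
    decomp_specs = specs

    manifest: dict[str, dict] = {}

    def _write(name: str, frame: pd.DataFrame):
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        manifest[name] = {"path": path.name, "rows": int(len(frame))}
        logger.info("wrote %s (%d rows)", path.name, len(frame))

    profile = sample_profile(records, specs, by="sex")
    _write("profile", profile)

    for outcome in outcomes:
        n_valid = int(records[outcome].notna().sum())
        logger.info("outcome %s: %d of %d records non-missing", outcome, n_valid, len(records))
        _write(
            f"prevalence_{outcome}",
            prevalence_by_strata(records, outcome, specs, weight_col, by="sex"),
        )

    for z_col in Z_COLUMNS:
        if z_col in records.columns:
            _write(
                f"meanz_{z_col.removeprefix('z_')}",
                meanz_by_strata(records, z_col, specs, weight_col, by="sex"),
            )

    summary, curves = concentration_summary(records, outcomes, score_col, weight_col, by="sex")
    _write("concentration_summary", summary)
    for key, curve in curves.items():
        _write(f"curve_{key}", curve)

    for sex in sorted(records["sex"].astype(str).unique()):
        sub = records[records["sex"].astype(str) == sex]
        for outcome in outcomes:
            valid = sub[sub[outcome].notna()]
            try:
                result = wagstaff_decompose(
                    valid[outcome].to_numpy(dtype=float),
                    valid,
                    decomp_specs,
                    valid[score_col].to_numpy(dtype=float),
                    valid[weight_col].to_numpy(dtype=float) if weight_col else None,
                )
            except Exception as exc:  # abort naming the stage
                raise RuntimeError(
                    f"decomposition stage failed for sex={sex}, outcome={outcome}: {exc}"
                ) from exc
            _write(f"decomposition_{sex}_{outcome}", format_decomposition_table(result, decomp_specs))

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
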