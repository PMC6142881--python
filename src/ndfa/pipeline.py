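"""End-to-end orchestration: CSV inputs → symbiosis tables, ANOVA, SSR scans.

Reads the three tabular inputs (per-plot field samples, non-fixing
reference plant δ¹⁵N values, glasshouse B-value organ measurements),
computes %Ndfa and the N budget per plot, aggregates treatment-cell means
± SE, runs the two-way landrace × inoculation ANOVA per site with Duncan
letter separation, builds a correlation panel, and optionally scans FASTA
sequences for SSRs. Per-plot values are computed first and averaged
afterwards — cell summaries are means of plot-level quantities, not
quantities of cell means.

Packaged reference fixtures (``ndfa.pipeline.packaged_fixture``) carry the
published per-site reference δ¹⁵N values, the glasshouse shoot/root δ¹⁵N,
and the per-landrace treatment means of the field trial, so the whole
pipeline can be exercised without external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import isotopes, ssr, trial_stats
from .isotopes import (
    BValueExperiment,
    OrganMeasurement,
    TrialDesign,
    b_value,
    plant_density,
    symbiosis_result,
    whole_plant_delta15n,
)
from .trial_stats import FactorialDataset, duncan_mrt, factorial_anova

__all__ = [
    "SAMPLES_COLUMNS",
    "RunConfig",
    "ReportBundle",
    "SchemaError",
    "packaged_fixture",
    "read_samples_csv",
    "read_references_csv",
    "read_bvalue_csv",
    "reference_mean_table",
    "bvalue_table",
    "per_plot_symbiosis",
    "cell_summary",
    "site_anova",
    "letter_table",
    "correlation_panel",
    "run_full_analysis",
]

logger = logging.getLogger("ndfa")

SAMPLES_COLUMNS = (
    "site",
    "landrace",
    "inoculation",
    "replicate",
    "shoot_dm_g",
    "nodule_dm_mg",
    "n_pct",
    "c_pct",
    "delta15n",
)

RESPONSES = (
    "shoot_dm_g",
    "nodule_dm_mg",
    "n_pct",
    "n_content_mg",
    "cn_ratio",
    "delta15n",
    "ndfa_pct",
    "n_fixed_kg_ha",
    "soil_n_kg_ha",
)


class SchemaError(ValueError):
    """An input table violates its schema; the message carries row numbers."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything one full analysis run needs.

    Exactly one B-value source must be given: either ``bvalue_path`` (organ
    measurements, shoots averaged) or an explicit ``b_value``.
    """

    samples_path: str | Path
    references_path: str | Path
    bvalue_path: str | Path | None = None
    b_value: float | None = None
    design: TrialDesign = field(default_factory=TrialDesign)
    density: float | None = None  # overrides design when given
    r_atm: float = isotopes.ATM_15N_14N_RATIO
    alpha: float = 0.05
    clamp_ndfa: bool = False
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.bvalue_path is None) == (self.b_value is None):
            raise ValueError("exactly one of bvalue_path / b_value must be set")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def plants_per_ha(self) -> float:
        return self.density if self.density is not None else plant_density(self.design)


def packaged_fixture(name: str) -> Path:
    """Path of a packaged fixture table (reference_plants, bvalue_glasshouse, field_trial_means)."""
    return Path(str(resources.files("ndfa").joinpath("data", f"{name}.csv")))


# ---------------------------------------------------------------------------
# Readers with per-row diagnostics
# ---------------------------------------------------------------------------


def _require_columns(frame: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = set(required) - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")


def read_samples_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-plot samples table."""
    frame = pd.read_csv(path)
    _require_columns(frame, SAMPLES_COLUMNS, path)
    problems = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        if row[["shoot_dm_g", "nodule_dm_mg"]].lt(0).any():
            problems.append(f"line {line}: negative dry matter")
        for col in ("n_pct", "c_pct"):
            if not 0 <= row[col] <= 100:
                problems.append(f"line {line}: {col}={row[col]} outside [0, 100]")
        if pd.isna(row["delta15n"]):
            problems.append(f"line {line}: missing delta15n")
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    return frame


def read_references_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, ("site", "species", "delta15n"), path)
    if frame["delta15n"].isna().any():
        bad = [str(i + 2) for i in frame.index[frame["delta15n"].isna()]]
        raise SchemaError(f"{path}: missing delta15n at lines {', '.join(bad)}")
    return frame


def read_bvalue_csv(path: str | Path) -> BValueExperiment:
    """Read the glasshouse organ table into a B-value experiment.

    Organ N contents may be absent (the B value needs shoot δ¹⁵N only);
    missing contents are stored as zero and whole-plant δ¹⁵N is then
    reported as not computable.
    """
    frame = pd.read_csv(path)
    _require_columns(frame, ("landrace", "organ", "delta15n"), path)
    entries = []
    for landrace, grp in frame.groupby("landrace", sort=False):
        organs = {}
        for _, row in grp.iterrows():
            content = row.get("n_content_mg", np.nan)
            organs[row["organ"]] = OrganMeasurement(
                organ=row["organ"],
                delta15n=float(row["delta15n"]),
                n_content=0.0 if pd.isna(content) else float(content),
            )
        if "shoot" not in organs:
            raise SchemaError(f"{path}: landrace {landrace!r} lacks a shoot row")
        root = organs.get("root", OrganMeasurement("root", organs["shoot"].delta15n, 0.0))
        entries.append((str(landrace), organs["shoot"], root))
    return BValueExperiment(landraces=tuple(entries))


# ---------------------------------------------------------------------------
# Analysis stages
# ---------------------------------------------------------------------------


def reference_mean_table(references: pd.DataFrame) -> pd.DataFrame:
    """Per-site mean ± SE of reference-plant δ¹⁵N (the δ¹⁵N_ref values)."""
    g = references.groupby("site")["delta15n"]
    return pd.DataFrame(
        {"mean_delta15n": g.mean(), "se": g.sem(ddof=1), "n_species": g.count()}
    )


def bvalue_table(experiment: BValueExperiment) -> tuple[pd.DataFrame, float]:
    """Per-landrace organ and whole-plant δ¹⁵N plus the pooled B value."""
    rows = []
    for landrace, shoot, root in experiment.landraces:
        total_n = shoot.n_content + root.n_content
        whole = whole_plant_delta15n(shoot, root) if total_n > 0 else np.nan
        rows.append(
            {
                "landrace": landrace,
                "shoot_delta15n": shoot.delta15n,
                "root_delta15n": root.delta15n,
                "whole_plant_delta15n": whole,
            }
        )
    return pd.DataFrame(rows).set_index("landrace"), b_value(experiment)


def per_plot_symbiosis(
    samples: pd.DataFrame,
    reference_means: pd.Series | dict,
    b: float,
    density: float,
    clamp_ndfa: bool = False,
) -> pd.DataFrame:
    """Symbiosis budget for every plot (replicate), before any averaging."""
    ref = dict(reference_means)
    out = samples.copy()
    results = [
        symbiosis_result(
            delta_ref=ref[row.site],
            delta_leg=row.delta15n,
            b=b,
            shoot_dm=row.shoot_dm_g,
            n_pct=row.n_pct,
            c_pct=row.c_pct,
            density=density,
            clamp_ndfa=clamp_ndfa,
        )
        for row in samples.itertuples()
    ]
    out["n_content_mg"] = [r.shoot_n_content for r in results]
    out["cn_ratio"] = [r.cn_ratio for r in results]
    out["ndfa_pct"] = [r.ndfa_pct for r in results]
    out["total_n_kg_ha"] = [r.total_n for r in results]
    out["n_fixed_kg_ha"] = [r.n_fixed for r in results]
    out["soil_n_kg_ha"] = [r.soil_n_uptake for r in results]
    out["ndfa_out_of_range"] = [r.out_of_range for r in results]
    return out


def cell_summary(
    per_plot: pd.DataFrame, by: tuple[str, ...] = ("site", "landrace", "inoculation")
) -> pd.DataFrame:
    """Mean ± SE (SD/√n over replicates) per treatment cell."""
    g = per_plot.groupby(list(by), sort=False)
    pieces = {}
    for col in RESPONSES + ("total_n_kg_ha",):
        pieces[f"{col}_mean"] = g[col].mean()
        pieces[f"{col}_se"] = g[col].sem(ddof=1)
    summary = pd.DataFrame(pieces)
    summary["n_plots"] = g.size()
    return summary


def site_anova(
    per_plot: pd.DataFrame, response: str, factors: tuple[str, ...] = ("landrace", "inoculation")
) -> trial_stats.AnovaTable:
    """Two-way (or n-way) fixed-effects ANOVA of one response at one site."""
    data = FactorialDataset.from_frame(per_plot, response, factors)
    return factorial_anova(data)


def letter_table(
    per_plot: pd.DataFrame,
    response: str,
    factor: str,
    anova: trial_stats.AnovaTable,
    alpha: float = 0.05,
) -> trial_stats.LetterGrouping:
    """Duncan letters for one factor's means, protected by the omnibus F.

    When the factor's omnibus test is not significant at ``alpha``, no
    separation is attempted and every level shares the letter "a".
    """
    g = per_plot.groupby(factor, sort=False)[response]
    means = g.mean().to_dict()
    n_per_level = int(g.count().iloc[0])
    resid = anova["Residual"]
    if anova.p_value(factor) > alpha:
        order = sorted(means, key=lambda lvl: (-means[lvl], str(lvl)))
        se = float(np.sqrt(resid["mean_sq"] / n_per_level))
        return trial_stats.LetterGrouping(
            tuple(order), tuple(means[lvl] for lvl in order), se, ("a",) * len(order)
        )
    return duncan_mrt(
        means,
        n_per_level=n_per_level,
        ms_error=float(resid["mean_sq"]),
        df_error=int(resid["df"]),
        alpha=alpha,
    )


def correlation_panel(per_plot: pd.DataFrame, columns: tuple[str, ...] = RESPONSES) -> pd.DataFrame:
    """Pairwise Pearson r and p for the measured parameters."""
    rows = []
    for i, a in enumerate(columns):
        for b_col in columns[i + 1 :]:
            r, p = trial_stats.pearson_correlation(per_plot[a], per_plot[b_col])
            rows.append({"x": a, "y": b_col, "r": r, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


@dataclass
class ReportBundle:
    """All products of one full analysis run."""

    reference_table: pd.DataFrame
    bvalue_table: pd.DataFrame | None
    b: float
    per_plot: pd.DataFrame
    cell_table: pd.DataFrame
    landrace_tables: dict
    anova_tables: dict
    letters: dict
    correlations: pd.DataFrame
    warnings: list[str]
    summary: dict


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Execute the complete pipeline described by ``config``.

    The conservation identity (N-fixed + soil N uptake = total shoot N) is
    asserted for every plot; any %Ndfa outside [0, 100] is recorded in both
    the log and the JSON summary.
    """
    samples = read_samples_csv(config.samples_path)
    references = read_references_csv(config.references_path)
    ref_table = reference_mean_table(references)

    if config.b_value is not None:
        b, bval_table = config.b_value, None
    else:
        experiment = read_bvalue_csv(config.bvalue_path)
        bval_table, b = bvalue_table(experiment)

    ref_means = ref_table["mean_delta15n"]
    for site, mean in ref_means.items():
        if mean == b:
            raise isotopes.DegenerateInputError(
                f"site {site!r}: reference mean δ¹⁵N equals the B value; "
                "%Ndfa is undefined"
            )

    density = config.plants_per_ha
    per_plot = per_plot_symbiosis(samples, ref_means, b, density, config.clamp_ndfa)

    closure = per_plot["n_fixed_kg_ha"] + per_plot["soil_n_kg_ha"] - per_plot["total_n_kg_ha"]
    assert np.allclose(closure, 0.0, atol=1e-9), "N budget failed to close"
    logger.info("N budget closed for all %d plots", len(per_plot))

    warnings_list = []
    for row in per_plot[per_plot["ndfa_out_of_range"]].itertuples():
        msg = (
            f"%Ndfa outside [0, 100] for {row.site}/{row.landrace}/"
            f"{row.inoculation} rep {row.replicate}: {row.ndfa_pct:.2f}"
        )
        warnings_list.append(msg)
        logger.warning(msg)

    cells = cell_summary(per_plot)
    landrace_cells = cell_summary(per_plot, by=("site", "landrace"))

    anova_tables: dict[tuple[str, str], trial_stats.AnovaTable] = {}
    letters: dict[tuple[str, str], dict[str, str]] = {}
    for site, site_plots in per_plot.groupby("site", sort=False):
        for response in RESPONSES:
            table = site_anova(site_plots, response)
            anova_tables[(site, response)] = table
            letters[(site, response)] = letter_table(
                site_plots, response, "landrace", table, config.alpha
            ).as_dict()

    correlations = correlation_panel(per_plot)

    summary = {
        "b_value": b,
        "plant_density_per_ha": density,
        "reference_means": {s: float(v) for s, v in ref_means.items()},
        "sites": sorted(per_plot["site"].unique()),
        "n_plots": int(len(per_plot)),
        "ndfa_warnings": warnings_list,
        "cells": {
            "/".join(map(str, key)): {
                "ndfa_pct": round(float(row["ndfa_pct_mean"]), 6),
                "n_fixed_kg_ha": round(float(row["n_fixed_kg_ha_mean"]), 6),
                "soil_n_kg_ha": round(float(row["soil_n_kg_ha_mean"]), 6),
                "total_n_kg_ha": round(float(row["total_n_kg_ha_mean"]), 6),
            }
            for key, row in cells.iterrows()
        },
        "duncan_letters": {
            f"{site}:{response}": letters[(site, response)]
            for (site, response) in letters
        },
        "anova_F": {
            f"{site}:{response}": {
                term: (None if not np.isfinite(table[term]["F"]) else round(float(table[term]["F"]), 6))
                for term in table.terms
            }
            for (site, response), table in anova_tables.items()
        },
    }

    bundle = ReportBundle(
        reference_table=ref_table,
        bvalue_table=bval_table,
        b=b,
        per_plot=per_plot,
        cell_table=cells,
        landrace_tables={"by_site_landrace": landrace_cells},
        anova_tables=anova_tables,
        letters=letters,
        correlations=correlations,
        warnings=warnings_list,
        summary=summary,
    )
    if config.out_dir is not None:
        write_outputs(bundle, config.out_dir)
    return bundle


def write_outputs(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write the report bundle as CSV tables plus a JSON summary.

    The JSON summary is serialized with sorted keys so identical inputs
    yield byte-identical output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.reference_table.to_csv(out / "reference_means.csv")
    if bundle.bvalue_table is not None:
        bundle.bvalue_table.to_csv(out / "bvalue.csv")
    bundle.per_plot.to_csv(out / "per_plot.csv", index=False)
    bundle.cell_table.to_csv(out / "cell_summary.csv")
    bundle.landrace_tables["by_site_landrace"].to_csv(out / "landrace_summary.csv")
    bundle.correlations.to_csv(out / "correlations.csv", index=False)
    anova_frames = []
    for (site, response), table in bundle.anova_tables.items():
        frame = table.table.reset_index()
        frame.insert(0, "site", site)
        frame.insert(1, "response", response)
        anova_frames.append(frame)
    pd.concat(anova_frames, ignore_index=True).to_csv(out / "anova.csv", index=False)
    letter_rows = [
        {"site": site, "response": response, "level": level, "letters": letters}
        for (site, response), groups in bundle.letters.items()
        for level, letters in groups.items()
    ]
    pd.DataFrame(letter_rows).to_csv(out / "duncan_letters.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps(bundle.summary, sort_keys=True, indent=2) + "\n"
    )


def scan_fasta(
    fasta_path: str | Path, min_repeats: dict[int, int] | None = None
) -> dict[str, list[ssr.SsrHit]]:
    """Scan every record of a FASTA file for SSRs."""
    return {
        record.id: ssr.scan_ssrs(record, min_repeats=min_repeats)
        for record in ssr.read_fasta(fasta_path)
    }
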