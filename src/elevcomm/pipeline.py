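"""End-to-end analysis pipeline.

Orchestrates the full workflow from a single configuration: synthetic
data generation (or loading of delimited input tables), predictor
screening, per-subregion rarefaction, richness/abundance trend models,
dissimilarity / NMDS / environmental vectors, sequential PERMANOVA, and
univariate plus multivariate model averaging.  Every stage writes a
delimited table into the output directory and the run is summarised in
a JSON manifest (seed, config hash, package version, stage seeds).

The master seed is split into per-stage child seeds with a seed
sequence, so individual stages are reproducible independently of the
order in which other stages consume randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, StageError
from .averaging import model_averaging
from .dissimilarity import bray_curtis_matrix, fit_env_vectors, nmds, nonempty_plots
from .glm import MixedFitResult, fit_nb_glmm
from .permanova import Term, permanova_sequential
from .rarefaction import pool_abundances, rarefaction_curve
from .screening import screen_predictors
from .simulate import (
    DEFAULT_PRIORITY,
    PREDICTOR_GROUPS,
    SimConfig,
    generate_community,
    generate_design,
    generate_environment,
)

log = logging.getLogger("elevcomm")

FLOAT_FORMAT = "%.6g"

STAGES = (
    "simulate", "screen", "rarefy", "trend",
    "ordinate", "permanova", "average",
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "elevcomm_out"
    # input tables; None means generate synthetically
    plots_path: str | None = None
    community_path: str | None = None
    env_path: str | None = None
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    groups: dict = field(default_factory=lambda: dict(PREDICTOR_GROUPS))
    priority: list = field(default_factory=lambda: list(DEFAULT_PRIORITY))
    r_max: float = 0.90
    n_perm: int = 4999
    n_null: int = 999
    nmds_dims: int = 2
    nmds_restarts: int = 20
    rarefaction_factor: float = 2.0
    averaging_predictors: list | None = None  # None: all screened
    min_prevalence: int = 0  # multivariate mode: drop rarer species

    def __post_init__(self):
        for name in ("n_perm", "n_null", "nmds_dims", "nmds_restarts"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        child = np.random.SeedSequence(
            [int(self.seed), STAGES.index(stage)]
        ).generate_state(1)[0]
        return int(child % (2**31))


def richness_abundance_trend(
    counts: pd.DataFrame, plots: pd.DataFrame
) -> tuple[MixedFitResult, MixedFitResult]:
    """Mixed-model elevation trends of richness and total abundance.

    Per-plot observed richness (species with count > 0) and total
    abundance — zeros included, empty plots are data — are each
    modelled as negative-binomial counts on actual elevation (km) with
    a random subregion intercept.
    """
    richness = (counts > 0).sum(axis=1).to_numpy()
    abundance = counts.sum(axis=1).to_numpy()
    if abundance.sum() == 0:
        raise ConfigurationError("all plots are empty: degenerate trend model")
    elev_km = plots["actual_elev"].to_numpy(dtype=float) / 1000.0
    X = np.column_stack([np.ones(len(plots)), elev_km])
    names = ["intercept", "elev_km"]
    group = plots["subregion"].to_numpy()
    rich = fit_nb_glmm(richness, X, group, names=names)
    abun = fit_nb_glmm(abundance, X, group, names=names)
    return rich, abun


def _trend_frame(fit: MixedFitResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": fit.names,
            "estimate": fit.coef,
            "se": fit.se,
            "t": fit.tvalues,
            "P": fit.pvalues,
        }
    )


def _write(df: pd.DataFrame, path: Path, **kw):
    df.to_csv(path, float_format=FLOAT_FORMAT, **kw)


def load_tables(config: RunConfig):
    """Load or synthesise the three input tables."""
    if config.plots_path:
        plots = pd.read_csv(config.plots_path, index_col="plot_id")
        counts = pd.read_csv(config.community_path, index_col=0)
        env = pd.read_csv(config.env_path, index_col=0)
        return plots, env, counts
    sim = SimConfig(seed=config.stage_seed("simulate"), **config.sim)
    plots = generate_design(sim)
    env = generate_environment(plots, sim)
    counts = generate_community(plots, env, sim)
    return plots, env, counts


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns a dict of in-memory results.

    On stage failure a ``FAILED`` marker naming the stage is written and
    a :class:`StageError` raised; tables from completed stages remain.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest = {
        "package": "elevcomm",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "outputs": [],
    }

    def record(name: str):
        manifest["outputs"].append(name)

    stage = "simulate"
    try:
        plots, env, counts = load_tables(config)
        _write(plots, out / "design.csv")
        _write(env, out / "environment.csv")
        _write(counts, out / "community.csv")
        record("design.csv"); record("environment.csv"); record("community.csv")
        results["plots"], results["env"], results["counts"] = plots, env, counts

        stage = "screen"
        reduced, report = screen_predictors(
            env, config.groups, config.r_max, config.priority
        )
        _write(report.correlations, out / "screening_correlations.csv")
        with open(out / "screening_log.txt", "w") as fh:
            fh.write("retained: " + ", ".join(report.retained) + "\n")
            for drop, keep, r in report.removed:
                fh.write(f"removed {drop} (r={r:.4f} with {keep})\n")
        record("screening_correlations.csv"); record("screening_log.txt")
        results["screened_env"], results["screening"] = reduced, report

        stage = "rarefy"
        pooled = pool_abundances(counts, plots["subregion"])
        curves = []
        for sub, vec in sorted(pooled.items()):
            if vec.n == 0:
                log.warning("subregion %s has no individuals; skipped", sub)
                continue
            c = rarefaction_curve(vec, factor=config.rarefaction_factor)
            c.insert(0, "subregion", sub)
            curves.append(c)
        curves = pd.concat(curves, ignore_index=True)
        _write(curves, out / "rarefaction.csv", index=False)
        record("rarefaction.csv")
        results["rarefaction"] = curves

        stage = "trend"
        rich, abun = richness_abundance_trend(counts, plots)
        _write(_trend_frame(rich), out / "trend_richness.csv", index=False)
        _write(_trend_frame(abun), out / "trend_abundance.csv", index=False)
        record("trend_richness.csv"); record("trend_abundance.csv")
        results["trend_richness"], results["trend_abundance"] = rich, abun

        stage = "ordinate"
        d = bray_curtis_matrix(counts)
        _write(d, out / "dissimilarity.csv")
        keep = nonempty_plots(counts)
        ord_seed = config.stage_seed("ordinate")
        ordination = nmds(
            d.loc[keep, keep],
            k=config.nmds_dims,
            restarts=config.nmds_restarts,
            seed=ord_seed,
        )
        coords = ordination.coords.copy()
        _write(coords, out / "ordination.csv")
        with open(out / "ordination_stress.txt", "w") as fh:
            fh.write(
                f"stress-1 = {ordination.stress:.6g} "
                f"({ordination.n_restarts} restarts, "
                f"converged={ordination.converged})\n"
            )
        vectors = fit_env_vectors(
            ordination, env.loc[keep], n_perm=999, seed=ord_seed
        )
        _write(vectors, out / "vector_fits.csv", index=False)
        record("dissimilarity.csv"); record("ordination.csv")
        record("ordination_stress.txt"); record("vector_fits.csv")
        results["dissimilarity"] = d
        results["ordination"] = ordination
        results["vector_fits"] = vectors

        stage = "permanova"
        terms = [
            Term("subregion", plots["subregion"].to_numpy(), "factor"),
            Term("actual_elev", plots["actual_elev"].to_numpy(), "covariate"),
        ]
        perm = permanova_sequential(
            d, terms, n_perm=config.n_perm, seed=config.stage_seed("permanova")
        )
        table = perm.table.copy()
        table.loc[len(table)] = ["residual", perm.residual_df,
                                 perm.residual_ss, np.nan, np.nan]
        table.loc[len(table)] = ["total", len(plots) - 1,
                                 perm.total_ss, np.nan, np.nan]
        _write(table, out / "permanova.csv", index=False)
        record("permanova.csv")
        results["permanova"] = perm

        stage = "average"
        pool = reduced
        if config.averaging_predictors:
            pool = reduced[list(config.averaging_predictors)]
        richness = (counts > 0).sum(axis=1).to_numpy()
        avg_seed = config.stage_seed("average")
        uni = model_averaging(
            richness, pool, "univariate", n_null=config.n_null, seed=avg_seed
        )
        comm = counts
        if config.min_prevalence > 0:
            keep_sp = (counts > 0).sum(axis=0) >= config.min_prevalence
            comm = counts.loc[:, keep_sp]
        multi = model_averaging(
            comm.to_numpy(dtype=float), pool, "multivariate",
            n_null=config.n_null, seed=avg_seed,
        )
        _write(uni.table, out / "averaging_richness.csv", index=False)
        _write(multi.table, out / "averaging_composition.csv", index=False)
        record("averaging_richness.csv"); record("averaging_composition.csv")
        results["averaging_richness"] = uni
        results["averaging_composition"] = multi

    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results
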