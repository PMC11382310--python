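"""End-to-end orchestration: simulate/load -> screen -> match -> compare ->
mediate -> report, driven by one YAML (or JSON) config with seeded
reproducibility.

Artifacts written to the output directory:

* ``cohort_summary.tsv``         per-arm baseline table, full cohort
* ``screening.tsv``              univariate confounder screen
* ``matches.tsv``                treated/control id pairs with distances
* ``balance.tsv``                standardized mean differences before/after
* ``matched_summary.tsv``        per-arm baseline table, matched cohort
* ``or_table.tsv``               mediator odds ratios on the matched cohort
* ``hr_table.tsv``               overall-survival hazard ratios (Cox)
* ``km_<name>.tsv``              Kaplan-Meier step functions per arm and
                                 per arm x mediator, plus log-rank p-values
* ``mediation.json``             the effect decomposition
* ``subgroups.json``             per-stratum decompositions (surgery)
* ``manifest.txt``               seed, config hash, per-file checksums

Every stage draws from a named substream of the single global seed, so the
same config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import cohort_io, propensity, survival_core as sc
from .mediation import MediationConfig, mediate, subgroup_mediation
from .synthetic_cohort import SimulationParams, default_paper_params, simulate_cohort

log = logging.getLogger("ril_mediation")

DEFAULT_CANDIDATES = list(propensity.CANDIDATE_FEATURES)


@dataclass
class PipelineConfig:
    """One input source, stage options, output directory, global seed."""

    csv: str | None = None
    simulate: SimulationParams | None = None
    candidates: list = field(default_factory=lambda: list(DEFAULT_CANDIDATES))
    screen_alpha: float = 0.05
    forced: tuple = propensity.DEFAULT_FORCED
    criterion: str = "wald_p"
    distance_scale: str = "logit"
    caliper: float | None = None
    mediation: MediationConfig = field(default_factory=MediationConfig)
    subgroup_by: str = "surgery"
    output_dir: str = "ril_mediation_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.csv is None) == (self.simulate is None):
            raise ValueError("config must name exactly one input: csv or simulate")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulate" in d and d["simulate"] is not None:
            d["simulate"] = SimulationParams.from_dict(d["simulate"])
        if "mediation" in d and d["mediation"] is not None:
            d["mediation"] = MediationConfig(**d["mediation"])
        if "forced" in d:
            d["forced"] = tuple(d["forced"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def canonical(self) -> str:
        d = {
            "csv": self.csv,
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "candidates": list(self.candidates),
            "screen_alpha": self.screen_alpha,
            "forced": list(self.forced),
            "criterion": self.criterion,
            "distance_scale": self.distance_scale,
            "caliper": self.caliper,
            "mediation": {
                k: v for k, v in vars(self.mediation).items()
            },
            "subgroup_by": self.subgroup_by,
            "seed": self.seed,
        }
        return json.dumps(d, sort_keys=True, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _km_table(df: pd.DataFrame, group_cols: list) -> pd.DataFrame:
    rows = []
    for key, sub in df.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        curve = sc.km_estimate(sub["os_months"], sub["event"])
        part = pd.DataFrame({"time": curve.times, "surv": curve.surv})
        for col, val in zip(group_cols, key):
            part.insert(0, col, val)
        part["median"] = curve.median
        rows.append(part)
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns a run report (paths + headline
    numbers). Any stage failure aborts with the stage name; artifacts
    produced so far are left on disk."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level.upper())
    report = {"stages": {}, "artifacts": {}}
    stage = "input"
    t_start = time.perf_counter()
    try:
        if config.csv is not None:
            cohort = cohort_io.read_cohort(config.csv)
        else:
            params = config.simulate
            if params.seed != config.seed:
                from dataclasses import replace
                params = replace(params, seed=config.seed)
            cohort = simulate_cohort(params)
        report["stages"][stage] = {"n": len(cohort),
                                   "rejected": cohort.n_rejected}

        stage = "summary"
        summary = cohort_io.summarize_cohort(cohort, by="modality")
        _write_tsv(summary, out / "cohort_summary.tsv")

        stage = "screening"
        screen = propensity.univariate_screen(
            cohort, config.candidates, alpha=config.screen_alpha)
        _write_tsv(screen, out / "screening.tsv")
        selected = screen.loc[screen["significant"], "candidate"].tolist()
        candidates = sorted(set(selected) | set(config.forced),
                            key=config.candidates.index)

        stage = "propensity"
        ps = propensity.fit_ps_model(cohort, candidates, forced=config.forced,
                                     criterion=config.criterion)
        report["stages"][stage] = {"selected": ps.selected_covariates}

        stage = "matching"
        matches = propensity.optimal_match(
            ps, cohort, distance_scale=config.distance_scale,
            caliper=config.caliper)
        pair_df = matches.to_frame()
        pair_df["distance"] = [
            abs(float(ps.scores[t]) - float(ps.scores[c]))
            for t, c in matches.pairs
        ]
        _write_tsv(pair_df, out / "matches.tsv")
        balance = propensity.match_diagnostics(cohort, matches, candidates)
        _write_tsv(balance, out / "balance.tsv", index=True)
        mcohort = propensity.matched_cohort(cohort, matches)
        _write_tsv(cohort_io.summarize_cohort(mcohort, by="modality"),
                   out / "matched_summary.tsv")
        report["stages"][stage] = {"pairs": len(matches.pairs),
                                   "total_distance": matches.total_distance}

        stage = "comparison"
        mdf = mcohort.df
        ps_m = ps.scores.reindex(mdf["id"]).to_numpy()
        or_rows, hr_rows = [], []
        med = config.mediation
        for cov, X in [
            ("modality", pd.DataFrame({"modality": mdf["modality"].astype(float)})),
            ("modality+ps", pd.DataFrame(
                {"modality": mdf["modality"].astype(float), "ps": ps_m})),
        ]:
            lfit = sc.fit_logistic(mdf[med.mediator], X)
            row = lfit.summary().loc["modality"]
            or_rows.append({"model": cov, **row.to_dict()})
            cfit = sc.fit_cox(mdf["os_months"], mdf["event"], X)
            crow = cfit.summary().loc["modality"]
            hr_rows.append({"model": cov, **crow.to_dict()})
        _write_tsv(pd.DataFrame(or_rows), out / "or_table.tsv")
        _write_tsv(pd.DataFrame(hr_rows), out / "hr_table.tsv")

        stage = "km"
        km_arm = _km_table(mdf, ["modality"])
        _write_tsv(km_arm, out / "km_by_modality.tsv")
        km_both = _km_table(mdf, ["modality", med.mediator])
        _write_tsv(km_both, out / "km_by_modality_mediator.tsv")
        lr_stat, lr_p = sc.logrank_test(mdf["os_months"], mdf["event"],
                                        mdf["modality"])
        report["stages"][stage] = {"logrank_chi2": lr_stat, "logrank_p": lr_p}

        stage = "mediation"
        result = mediate(mcohort, ps.scores, med)
        (out / "mediation.json").write_text(result.to_json(indent=2))
        report["stages"][stage] = {
            "hr_nie": result.hr_nie, "hr_nde": result.hr_nde,
            "hr_te": result.hr_te, "pm": result.pm,
            "median_diff": result.median_diff,
        }

        stage = "subgroups"
        subs = subgroup_mediation(mcohort, ps.scores, config.subgroup_by, med)
        (out / "subgroups.json").write_text(json.dumps(
            {str(k): v.to_dict() for k, v in subs.items()}, indent=2))
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        log.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = [f"seed\t{config.seed}",
                f"config_sha256\t{hashlib.sha256(config.canonical().encode()).hexdigest()}"]
    for p in sorted(out.iterdir()):
        if p.name not in ("manifest.txt", "run.log"):
            manifest.append(f"sha256:{p.name}\t{_sha256(p)}")
    (out / "manifest.txt").write_text("\n".join(manifest) + "\n")
    report["artifacts"] = {p.name: str(p) for p in sorted(out.iterdir())}
    report["elapsed_s"] = time.perf_counter() - t_start
    log.removeHandler(handler)
    handler.close()
    return report


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

def _setup_logging(level: str) -> None:
    logging.basicConfig(stream=sys.stderr, level=level.upper(),
                        format="%(levelname)s %(name)s: %(message)s")


@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def cli(log_level):
    """Propensity-matched causal mediation analysis for censored survival."""
    _setup_logging(log_level)


@cli.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--n", type=int, default=734, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def simulate(seed, n, out):
    """Write a synthetic confounded cohort CSV at the default calibration."""
    cohort = simulate_cohort(default_paper_params(n=n, seed=seed))
    cohort_io.write_cohort(cohort, out)
    click.echo(f"wrote {len(cohort)} patients to {out}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True),
              required=True)
@click.option("--seed", type=int, default=None)
@click.option("--out", "out_dir", type=click.Path(), default=None)
def run(config_path, seed, out_dir):
    """Run the full pipeline from a YAML config."""
    config = PipelineConfig.from_yaml(config_path)
    if seed is not None:
        config.seed = seed
    if out_dir is not None:
        config.output_dir = out_dir
    report = run_pipeline(config)
    click.echo(json.dumps(report["stages"], indent=2, default=str))


@cli.command()
@click.option("--csv", "csv_path", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--distance-scale", default="logit", show_default=True)
def match(csv_path, out, distance_scale):
    """Fit the propensity model and write optimal 1:1 match pairs (TSV)."""
    cohort = cohort_io.read_cohort(csv_path)
    ps = propensity.fit_ps_model(cohort, DEFAULT_CANDIDATES)
    matches = propensity.optimal_match(ps, cohort,
                                       distance_scale=distance_scale)
    df = matches.to_frame()
    df["distance"] = [abs(float(ps.scores[t]) - float(ps.scores[c]))
                      for t, c in matches.pairs]
    df.to_csv(out, sep="\t", index=False)
    click.echo(f"{len(matches.pairs)} pairs, total {matches.distance_scale} "
               f"distance {matches.total_distance:.4f}")


@cli.command(name="mediate")
@click.option("--csv", "csv_path", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--interaction/--no-interaction", default=False)
def mediate_cmd(csv_path, out, interaction):
    """Propensity-adjusted mediation analysis on a cohort CSV (no matching)."""
    cohort = cohort_io.read_cohort(csv_path)
    ps = propensity.fit_ps_model(cohort, DEFAULT_CANDIDATES)
    result = mediate(cohort, ps.scores,
                     MediationConfig(interaction=interaction))
    Path(out).write_text(result.to_json(indent=2))
    click.echo(f"NIE HR {result.hr_nie:.3f}  NDE HR {result.hr_nde:.3f}  "
               f"TE HR {result.hr_te:.3f}  PM {result.pm:.3f}")


@cli.command()
@click.option("--results", type=click.Path(exists=True), required=True,
              help="mediation.json from a previous run")
def report(results):
    """Render a human-readable summary of a saved mediation result."""
    d = json.loads(Path(results).read_text())
    lines = [
        "Effect decomposition (hazard-ratio scale):",
        f"  total effect   HR {d['hr_te']:.3f}  CI {d['ci']['te']}",
        f"  direct effect  HR {d['hr_nde']:.3f}  CI {d['ci']['nde']}",
        f"  indirect (mediated) HR {d['hr_nie']:.3f}  CI {d['ci']['nie']}",
        f"  proportion mediated {d['pm']:.3f}"
        + ("" if d["pm_valid"] else "  [flagged: outside valid range]"),
        f"  median survival gain via mediator {d['median_diff']:.2f} months",
    ]
    click.echo("\n".join(lines))


if __name__ == "__main__":
    cli()
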