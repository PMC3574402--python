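"""One-call orchestration of the full rarity-profiling analysis.

A run takes either real input files (survey, traits, reference) or a
simulation config, executes every stage — season assignment, abundance
structure in both currencies, occurrence profiling and deconstruction,
rarity classification under the selected definitions, and the persistence
logistic regressions — and writes a reproducible report bundle: delimited
text and JSON artifacts plus a manifest with a SHA-256 hash per file.  The
manifest is written last, so a partial failure never leaves a manifest
pointing at truncated outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import abundance, data, glm, occurrence, rarity
from .simulate import SimulationConfig, simulate_reference_habitats, simulate_survey

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``survey_path`` and ``simulation`` must be set.  With
    ``survey_path``, ``reference_path`` is required for classification and
    ``traits_path`` is optional (mean weights then derive from the survey).
    """

    outdir: str | Path = "varzea_run"
    survey_path: str | Path | None = None
    traits_path: str | Path | None = None
    reference_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    definitions: tuple[str, ...] = ("i", "ii", "iii", "iv")
    factors: tuple[str, ...] = ("lakes", "seasons")
    threshold: float = 0.01
    share_mode: str = "per_habitat"
    seed: int = 0

    def validate(self) -> None:
        if (self.survey_path is None) == (self.simulation is None):
            raise ValueError("set exactly one of survey_path and simulation")
        if not self.definitions or not self.factors:
            raise ValueError("select at least one definition and one factor")
        unknown = [d for d in self.definitions if d not in rarity.DEFINITIONS]
        if unknown:
            raise ValueError(f"unknown definitions {unknown}")
        unknown = [f for f in self.factors if f not in ("lakes", "seasons")]
        if unknown:
            raise ValueError(f"unknown factors {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = raw["simulation"]
            if "months" in sim:
                sim["months"] = tuple(sim["months"])
            if "habitats" in sim:
                sim["habitats"] = tuple(sim["habitats"])
            raw["simulation"] = SimulationConfig(**sim)
        for key in ("definitions", "factors"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path, **kwargs) -> None:
    frame.to_csv(path, float_format="%.10g", **kwargs)


def _fit_report(fit: glm.LogisticFit, design: glm.DesignInfo, wald: glm.WaldResult) -> dict:
    return {
        "factor": design.factor,
        "levels_observed": [int(v) for v in design.levels_observed],
        "reference_level": int(design.reference_level),
        "n_obs": fit.n_obs,
        "converged": fit.converged,
        "separation_flag": fit.separation_flag,
        "iterations": fit.n_iter,
        "log_likelihood": fit.loglik,
        "coefficients": {k: float(v) for k, v in fit.params.items()},
        "standard_errors": {k: float(v) for k, v in fit.bse.items()},
        "covariance": {
            row: {col: float(fit.cov.at[row, col]) for col in fit.cov.columns}
            for row in fit.cov.index
        },
        "wald": {"statistic": wald.statistic, "df": wald.df, "p": wald.p},
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    artifacts: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        artifacts.append(path)
        return path

    try:
        # --- inputs -------------------------------------------------------
        if config.simulation is not None:
            table, truth = simulate_survey(config.simulation, seed=config.seed)
            reference = simulate_reference_habitats(
                config.simulation, truth, seed=config.seed + 1
            )
            emit("truth.csv", lambda p: _write_csv(truth.table, p))
            log.append(f"simulate: {len(table.records)} records, {table.n_species} species")
        else:
            traits = (
                data.parse_traits_table(config.traits_path)
                if config.traits_path
                else None
            )
            table = data.parse_survey_table(config.survey_path, traits=traits)
            if config.reference_path is None:
                raise data.ValidationError("reference_path is required for classification")
            reference = rarity.parse_reference_table(config.reference_path)
            log.append(f"parse: {len(table.records)} records, {table.n_species} species")

        table = data.assign_seasons(table)
        emit("survey.csv", lambda p: data.write_survey_table(table, p))

        # --- abundance structure -----------------------------------------
        summaries = data.species_summaries(table)
        emit("species_summaries.csv", lambda p: _write_csv(summaries, p))
        counts = abundance.abundance_vector(table, "individuals")
        proportions = abundance.relative_abundance(counts)
        partition = abundance.partition_common_rare(proportions, config.threshold)
        emit(
            "partition.json",
            lambda p: p.write_text(
                json.dumps(
                    {
                        "threshold": partition.threshold,
                        "currency": partition.currency,
                        "n_common": len(partition.common),
                        "n_rare": len(partition.rare),
                        "common": sorted(partition.common),
                        "rare": sorted(partition.rare),
                    },
                    indent=2,
                )
            ),
        )
        curve = abundance.rank_abundance_curve(proportions)
        emit("rank_abundance.csv", lambda p: _write_csv(curve, p, index=False))
        histograms = {}
        for currency in abundance.CURRENCIES:
            vec = abundance.abundance_vector(table, currency)
            hist = abundance.log10_class_histogram(vec, currency)
            histograms[currency] = hist
            emit(
                f"sad_{currency}.csv", lambda p, h=hist: _write_csv(h.to_frame(), p, index=False)
            )
        log.append(
            f"abundance: {len(partition.common)} common, {len(partition.rare)} rare "
            f"at threshold {config.threshold}"
        )

        # --- occurrence ---------------------------------------------------
        profiles = occurrence.occurrence_profiles(table)
        emit("occurrence_profiles.csv", lambda p: _write_csv(profiles, p))
        joint = occurrence.joint_occurrence_distribution(profiles)
        emit("joint_occurrence.csv", lambda p: _write_csv(joint.matrix, p))
        for currency, hist in histograms.items():
            for group_by in ("lakes", "seasons"):
                tidy = occurrence.deconstruct_sad(hist, profiles, group_by)
                emit(
                    f"deconstructed_sad_{currency}_{group_by}.csv",
                    lambda p, t=tidy: _write_csv(t, p, index=False),
                )
        log.append(f"occurrence: joint distribution over {joint.matrix.shape} grid")

        # --- rarity classification ---------------------------------------
        assignments = {
            label: rarity.classify_rarity_status(
                partition, reference, label, share_mode=config.share_mode
            )
            for label in config.definitions
        }
        wide = pd.DataFrame({f"def_{k}": a.status for k, a in assignments.items()})
        emit("status_assignments.csv", lambda p: _write_csv(wide, p))
        if set(config.definitions) >= {"i", "ii", "iii", "iv"}:
            nesting = rarity.check_definition_nesting(assignments)
            emit(
                "nesting_report.json",
                lambda p: p.write_text(json.dumps(nesting, indent=2)),
            )
            log.append(f"nesting: ok={nesting['ok']} sizes={nesting['sizes']}")

        # --- persistence models ------------------------------------------
        for label in config.definitions:
            for factor in config.factors:
                design = glm.encode_design(
                    assignments[label], summaries, profiles, factor=factor
                )
                fit = glm.fit_logistic_irls(design.X, design.y)
                wald = glm.wald_factor_test(fit, list(design.dummy_names))
                report = _fit_report(fit, design, wald)
                emit(
                    f"model_def_{label}_{factor}.json",
                    lambda p, r=report: p.write_text(json.dumps(r, indent=2)),
                )
                log.append(
                    f"glm def {label} {factor}: chi2={wald.statistic:.3f} "
                    f"df={wald.df} p={wald.p:.4f}"
                )
    except Exception:
        # deliberately skip the manifest: its absence marks a failed run
        (outdir / "log.txt").write_text("\n".join(log) + "\nFAILED\n")
        raise

    emit("log.txt", lambda p: p.write_text("\n".join(log) + "\n"))
    manifest = {
        "seed": config.seed,
        "definitions": list(config.definitions),
        "factors": list(config.factors),
        "threshold": config.threshold,
        "outputs": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
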