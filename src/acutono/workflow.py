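"""End-to-end study orchestration with fixed-seed reproducibility.

A single master seed fans out deterministically to the simulation and the
training stage via ``numpy.random.SeedSequence([master, stage_tag])``, so a
repeated run with the same configuration produces byte-identical numeric
artifacts.  All rule constants (7 zero crossings, the 350-570 Hz band, 3
valid pulses, k_p = 2, the 5 s pre-evaluation phase) live in the run
configuration rather than in the operations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import agreement, calibration, pipeline, quality, simulate
from .quality import ValidityRules
from .types import ForwardModelCoefficients, SimulationConfig

__all__ = ["RunConfig", "run_study", "make_table2", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full simulate-process-gate-calibrate-report run needs."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    rules: ValidityRules = field(default_factory=ValidityRules)
    architecture: Tuple[int, int] = calibration.DEFAULT_ARCHITECTURE
    n_trials: int = 200
    keep_fraction: float = 0.1
    split_fractions: Tuple[float, float, float] = calibration.DEFAULT_FRACTIONS
    feature_columns: Optional[List[str]] = None
    k_p: float = 2.0
    master_seed: int = 0
    touchdown_threshold: float = 50.0
    pressure_dev_threshold: float = 300.0
    make_plots: bool = True


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML document (missing keys take defaults)."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    sim_doc = doc.pop("simulation", {})
    coeff_doc = sim_doc.pop("coefficients", {})
    sim = SimulationConfig(**sim_doc, coefficients=ForwardModelCoefficients(**coeff_doc))
    rules = ValidityRules(**doc.pop("rules", {}))
    if "architecture" in doc:
        doc["architecture"] = tuple(doc["architecture"])
    if "split_fractions" in doc:
        doc["split_fractions"] = tuple(doc["split_fractions"])
    return RunConfig(simulation=sim, rules=rules, **doc)


def _training_seed(master_seed: int) -> int:
    return int(np.random.SeedSequence([int(master_seed), 11]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: RunConfig, outdir) -> Path:
    """Run the whole pipeline and write its artifacts into ``outdir``.

    Artifacts: cohort table, per-measurement features, the success-rate
    summary, the agreement report (JSON), the selected calibration models,
    optional plots, and a manifest listing every file with a content hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate ---
    sim = dataclasses.replace(config.simulation, rng_seed=int(config.master_seed))
    eyes, recordings = simulate.simulate_cohort(sim)
    cohort = simulate.cohort_to_frame(eyes)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    logger.info("simulated %d eyes, %d recordings", len(eyes), len(recordings))

    # --- process + gate ---
    features, categories = pipeline.build_feature_table(eyes, recordings, config.rules)
    features.to_csv(outdir / "measurement_features.csv", index=False)
    cat_frame = pd.DataFrame(
        [
            {
                "measurement_id": c.measurement_id,
                "category": c.category,
                "self_administered": c.self_administered,
            }
            for c in categories
        ]
    )
    cat_frame.to_csv(outdir / "categories.csv", index=False)
    summary = quality.summarize_cohort(categories)
    quality.summary_to_frame(summary).to_csv(outdir / "success_rate.csv", index=False)
    logger.info(
        "usable measurements: %d of %d (%.1f%%)",
        summary.counts["expectancy_compliant"],
        summary.total,
        summary.shares["expectancy_compliant"],
    )

    # --- calibrate ---
    ensemble = calibration.run_trials(
        features,
        architecture=config.architecture,
        n_trials=config.n_trials,
        keep_fraction=config.keep_fraction,
        seed=_training_seed(config.master_seed),
        fractions=config.split_fractions,
        feature_columns=config.feature_columns,
    )
    ensemble.assert_test_isolation()
    models_dir = outdir / "models"
    models_dir.mkdir(exist_ok=True)
    for rank, idx in enumerate(ensemble.selected):
        ensemble.models[idx].to_json(models_dir / f"model_{rank:03d}.json")

    # --- agreement on the untouched test split ---
    test = features.loc[ensemble.test_index]
    summary_agr = agreement.ensemble_agreement(ensemble, test, k_p=config.k_p)
    report = summary_agr["ensemble_report"]
    report_doc = {
        "ensemble": report.to_dict(),
        "mean_slope_over_selected": summary_agr["mean_slope"],
        "sd_slope_over_selected": summary_agr["sd_slope"],
        "mean_expanded_uncertainty_over_selected": summary_agr["mean_expanded_uncertainty"],
        "n_selected_models": len(ensemble.selected),
        "n_trials": len(ensemble.models),
        "n_training_failures": ensemble.n_failures,
    }
    (outdir / "agreement.json").write_text(json.dumps(report_doc, indent=2))
    if config.make_plots:
        ref = test["reference_iop"].to_numpy()
        agreement.plot_agreement(ref, ensemble.predict(test), report,
                                 path=outdir / "agreement.png")

    # --- manifest ---
    artifacts = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "master_seed": int(config.master_seed),
        "simulation_seed": int(sim.rng_seed),
        "training_seed": _training_seed(config.master_seed),
        "numpy_version": np.__version__,
        "artifacts": {str(p.relative_to(outdir)): _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def make_table2(categories: "pd.DataFrame | str | Path") -> pd.DataFrame:
    """Success-rate summary (counts + one-decimal shares + self-run success).

    Accepts either a per-measurement category table (columns
    ``measurement_id``, ``category``, optional ``self_administered``) or a
    pre-counted table (columns ``category``, ``count``), e.g. a published
    count column to reproduce its share arithmetic.
    """
    if not isinstance(categories, pd.DataFrame):
        categories = pd.read_csv(categories)
    if "count" in categories.columns:
        by_cat = dict(zip(categories["category"], categories["count"]))
        unknown = set(by_cat) - set(quality.CATEGORIES) - {"total"}
        if unknown:
            raise ValueError(f"format error: unknown categories {sorted(unknown)}")
        cats = quality.categories_from_counts(
            [int(by_cat.get(c, 0)) for c in quality.CATEGORIES]
        )
    elif "category" in categories.columns:
        bad = set(categories["category"]) - set(quality.CATEGORIES)
        if bad:
            raise ValueError(f"format error: unknown categories {sorted(bad)}")
        self_col = (
            categories["self_administered"]
            if "self_administered" in categories.columns
            else [True] * len(categories)
        )
        cats = [
            quality.MeasurementCategory(
                measurement_id=str(row.get("measurement_id", i)),
                category=row["category"],
                self_administered=bool(s),
            )
            for (i, row), s in zip(categories.iterrows(), self_col)
        ]
    else:
        raise ValueError("format error: need a 'category' (and 'count' or per-row) column")
    if not cats:
        raise ValueError("empty category table")
    summary = quality.summarize_cohort(cats)
    frame = quality.summary_to_frame(summary)
    frame.attrs["self_administered_success_rate"] = summary.self_administered_success_rate
    return frame
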