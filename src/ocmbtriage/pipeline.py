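"""End-to-end orchestration: ingest or simulate, analyse, write artifacts.

``run_pipeline`` executes the stages in order — cohort ingest or simulation,
index panels, correlation + ROC + cutoff selection, model-grid evaluation,
optimal-model selection — and writes a reproducible artifact set.  Every
machine-readable artifact embeds the configuration and seed (and a config
hash), and the run is deterministic given config + seed: running twice with
the same inputs produces byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ._exceptions import InvalidValueError
from .decision import DecisionModel, round_half_away
from .indices import attach_panels, read_cohort_csv, samples_to_frame, write_cohort_csv
from .model import OcmbTriage
from .simulate import CohortParams, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "cohort_summary", "load_config"]


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of ``input_csv``/``simulate`` is set."""

    input_csv: Optional[str] = None
    simulate: Optional[dict] = None  # CohortParams field overrides
    min_specificity: float = 0.85
    snap_igmi: float = 0.05
    snap_fklci: float = 25.0
    level: float = 0.95
    ci_method: str = "clopper-pearson"
    models: Optional[list] = None  # list of {name, igmi_cutoff, fklci_cutoff}
    output_dir: str = "ocmbtriage_run"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self):
        if (self.input_csv is None) == (self.simulate is None):
            raise InvalidValueError("set exactly one of input_csv or simulate")
        if not 0 < self.level < 1:
            raise InvalidValueError("level must be in (0, 1)")

    def digest(self) -> str:
        # hash only what affects the results: where and how verbosely we
        # write them must not change the provenance fingerprint
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        payload.pop("verbosity")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Read a YAML key-value config file into a :class:`RunConfig`."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def cohort_summary(cohort: pd.DataFrame, rounding=round_half_away) -> dict:
    """Counts, percentages, and median (IQR) of the indices for one cohort.

    Percentages are rounded half away from zero by default (configurable);
    quantiles use linear interpolation (NumPy default, type 7).
    """
    if len(cohort) == 0:
        raise InvalidValueError("empty cohort")
    df = cohort
    if not {"igmi", "fklci", "qalb"}.issubset(df.columns):
        df = attach_panels(df)
    out: dict = {"n": int(len(df))}

    def count_pct(mask) -> dict:
        k = int(mask.sum())
        return {"count": k, "percent": rounding(100 * k / len(df))}

    for col, key in (("ocmb_status", "ocmb_positive"), ("ocmb", "ocmb_positive"),
                     ("activity", "active_disease"), ("sex", "male")):
        if col in df.columns and df[col].notna().any():
            known = df[col].dropna()
            if col == "sex":
                mask = known.astype(str).str.upper().isin(("M", "MALE", "1"))
            else:
                mask = known.astype(bool)
            k = int(mask.sum())
            out[key] = {
                "count": k,
                "n_known": int(len(known)),
                "percent": rounding(100 * k / len(known)),
            }
    for col in ("qalb", "igmi", "fklci"):
        q1, med, q3 = np.quantile(df[col], [0.25, 0.5, 0.75])
        out[col] = {"median": float(med), "iqr": [float(q1), float(q3)]}
    return out


def _models_from_config(entries) -> Optional[list[DecisionModel]]:
    if entries is None:
        return None
    return [
        DecisionModel(
            name=e.get("name", f"Model {i + 1}"),
            igmi_cutoff=float(e["igmi_cutoff"]),
            fklci_cutoff=float(e["fklci_cutoff"]),
        )
        for i, e in enumerate(entries)
    ]


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the paths of the written artifacts.

    Artifacts: ``cohort.csv`` (simulated runs only), ``summary.json``,
    ``roc.json``, ``models.csv``/``models.txt`` (the metric table),
    ``optimal.json`` and ``run.log``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ocmbtriage")
    root.addHandler(handler)
    root.setLevel(config.verbosity)
    provenance = {"seed": config.seed, "config_hash": config.digest(),
                  "config": dataclasses.asdict(config)}
    artifacts: dict[str, str] = {}
    try:
        logger.info("stage=ingest config_hash=%s seed=%d", config.digest(), config.seed)
        if config.simulate is not None:
            params = CohortParams(**{**config.simulate, "seed": config.seed})
            samples = generate_cohort(params)
            write_cohort_csv(samples, outdir / "cohort.csv")
            artifacts["cohort"] = str(outdir / "cohort.csv")
            frame = samples_to_frame(samples)
        else:
            frame = samples_to_frame(read_cohort_csv(config.input_csv))
        frame = attach_panels(frame)

        logger.info("stage=summary n=%d", len(frame))
        _write_json(outdir / "summary.json",
                    {**provenance, "summary": cohort_summary(frame)})
        artifacts["summary"] = str(outdir / "summary.json")

        logger.info("stage=fit")
        triage = OcmbTriage.from_dataframe(frame)
        results = triage.fit(
            min_specificity=config.min_specificity,
            snap_igmi=config.snap_igmi,
            snap_fklci=config.snap_fklci,
            level=config.level,
            ci_method=config.ci_method,
            models=_models_from_config(config.models),
        )

        digest = results.to_dict()
        _write_json(outdir / "roc.json", {**provenance, **{
            k: digest[k] for k in ("correlation", "auc", "auc_comparison", "cutoffs")
        }})
        artifacts["roc"] = str(outdir / "roc.json")

        results.table.to_csv(outdir / "models.csv", index=False)
        (outdir / "models.txt").write_text(results.summary() + "\n", encoding="utf-8")
        artifacts["models"] = str(outdir / "models.csv")
        artifacts["summary_text"] = str(outdir / "models.txt")

        _write_json(outdir / "optimal.json",
                    {**provenance, "optimal_model": digest["optimal_model"]})
        artifacts["optimal"] = str(outdir / "optimal.json")
        logger.info("stage=done optimal=%s", results.optimal_model.name)
    finally:
        root.removeHandler(handler)
        handler.close()
    artifacts["log"] = str(outdir / "run.log")
    return artifacts
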