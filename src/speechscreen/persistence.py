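"""Model artifact directory: a JSON manifest plus serialized estimators.

The manifest records the schema version, per-task feature columns, the
hyperparameters chosen by cross-validation, the decision threshold and the
training seed, so a scoring run can refuse inputs produced under a
different feature schema.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib

from .models import TASK_ORDER, ScreeningModel

SCHEMA_VERSION = 1


class ArtifactError(ValueError):
    """Raised when a model artifact is missing, corrupt or incompatible."""


def save_model(model: ScreeningModel, out_dir, seed: int | None = None,
               extra: dict | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "tasks": list(TASK_ORDER),
        "feature_columns": {t: list(c) for t, c in model.feature_columns_.items()},
        "chosen": {
            t: {
                "family": m.best_family_,
                "params": m.best_params_,
                "k": m.best_k_,
            }
            for t, m in model.task_models_.items()
        },
        "ensemble": {
            "family": model.ensemble_.best_family_,
            "params": model.ensemble_.best_params_,
        },
        "threshold": model.threshold_,
        "seed": seed,
    }
    if extra:
        manifest.update(extra)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    joblib.dump(model, out / "model.joblib")


def load_model(model_dir) -> tuple[ScreeningModel, dict]:
    d = Path(model_dir)
    manifest_path = d / "manifest.json"
    if not manifest_path.exists():
        raise ArtifactError(f"no manifest.json in {d}")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ArtifactError(
            f"artifact schema version {manifest.get('schema_version')} "
            f"incompatible with supported version {SCHEMA_VERSION}"
        )
    model = joblib.load(d / "model.joblib")
    return model, manifest
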