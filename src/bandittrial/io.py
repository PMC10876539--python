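"""File I/O for trial logs and run manifests.

All event streams are plain CSV with header rows; missing adherence/reward
values are written as the string ``NA``.  Latent profiles and bandit state
checkpoints are JSON.  A run manifest records the config, master seed, and a
content hash of every output file so a rerun can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import FACTOR_NAMES
from .cohort import COHORT_COLUMNS, LatentProfile
from .config import TrialConfig
from .trial import MESSAGE_COLUMNS, TrialLog

_NA = "NA"

_REQUIRED = {
    "cohort.csv": list(COHORT_COLUMNS),
    "assignments.csv": ["patient_id", "arm", "stratum"],
    "messages.csv": MESSAGE_COLUMNS,
    "adherence.csv": ["patient_id", "study_day", "fraction_taken"],
    "rewards.csv": ["patient_id", "decision_day", "reward"],
}

_BOOL_COHORT = [
    "married_partnered", "activation", "automaticity", "insulin_use",
    "employment", "physicians_3plus", "class_metformin",
    "class_sulfonylurea", "class_sglt2",
]


class SchemaError(ValueError):
    """A log file does not match the expected column schema."""


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, na_rep=_NA)


def _read_csv(path: Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[_NA], keep_default_na=False)
    missing = [c for c in _REQUIRED[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")
    return df[_REQUIRED[name]]


def _profiles_to_json(profiles: dict[str, LatentProfile]) -> str:
    return json.dumps(
        [
            {
                "patient_id": p.patient_id,
                "baseline_propensity": p.baseline_propensity,
                "factor_effects": p.factor_effects.tolist(),
                "carryover_effects": p.carryover_effects.tolist(),
                "cluster_label": p.cluster_label,
                "disconnect_rate": p.disconnect_rate,
            }
            for p in profiles.values()
        ],
        indent=1,
    )


def _profiles_from_json(payload: str) -> dict[str, LatentProfile]:
    return {
        d["patient_id"]: LatentProfile(
            patient_id=d["patient_id"],
            baseline_propensity=d["baseline_propensity"],
            factor_effects=np.array(d["factor_effects"]),
            carryover_effects=np.array(d["carryover_effects"]),
            cluster_label=d["cluster_label"],
            disconnect_rate=d["disconnect_rate"],
        )
        for d in json.loads(payload)
    }


def write_logs(log: TrialLog, outdir: str | Path) -> dict[str, str]:
    """Write all log streams to ``outdir``; returns file -> sha256 hashes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_csv(log.cohort, out / "cohort.csv")
    _write_csv(log.assignments, out / "assignments.csv")
    _write_csv(log.messages, out / "messages.csv")
    _write_csv(log.adherence, out / "adherence.csv")
    _write_csv(log.rewards, out / "rewards.csv")
    (out / "profiles.json").write_text(_profiles_to_json(log.profiles))
    if log.final_state is not None:
        (out / "bandit_state.json").write_text(log.final_state.to_json())
    if log.config is not None:
        (out / "config.json").write_text(log.config.model_dump_json(indent=1))
    return {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(out.iterdir()) if f.suffix in (".csv", ".json")
    }


def read_logs(indir: str | Path) -> TrialLog:
    """Read a log directory written by :func:`write_logs`."""
    src = Path(indir)
    cohort = _read_csv(src / "cohort.csv", "cohort.csv")
    for c in _BOOL_COHORT:
        cohort[c] = cohort[c].astype(bool)
    messages = _read_csv(src / "messages.csv", "messages.csv")
    for c in ("history", "social", "reflective"):
        messages[c] = messages[c].astype(bool)
    config = None
    cfg_path = src / "config.json"
    if cfg_path.exists():
        config = TrialConfig(**json.loads(cfg_path.read_text()))
    from .bandit import BanditState

    state = None
    state_path = src / "bandit_state.json"
    if state_path.exists():
        state = BanditState.from_json(state_path.read_text())
    return TrialLog(
        cohort=cohort,
        profiles=_profiles_from_json((src / "profiles.json").read_text()),
        assignments=_read_csv(src / "assignments.csv", "assignments.csv"),
        messages=messages,
        adherence=_read_csv(src / "adherence.csv", "adherence.csv"),
        rewards=_read_csv(src / "rewards.csv", "rewards.csv"),
        config=config,
        final_state=state,
    )


def roundtrip_logs(log: TrialLog, outdir: str | Path) -> TrialLog:
    """Write then re-read a log; the result is value-identical to the input."""
    write_logs(log, outdir)
    return read_logs(outdir)


@dataclass
class RunManifest:
    """Reproducibility record: config + seed + output content hashes."""

    config: dict
    seed: int
    package_version: str
    file_hashes: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "seed": self.seed,
             "package_version": self.package_version, "file_hashes": self.file_hashes},
            indent=1, sort_keys=True,
        )

    @classmethod
    def from_json(cls, payload: str) -> "RunManifest":
        return cls(**json.loads(payload))


def write_manifest(log: TrialLog, outdir: str | Path, hashes: dict[str, str]) -> RunManifest:
    from . import __version__

    manifest = RunManifest(
        config=json.loads(log.config.model_dump_json()) if log.config else {},
        seed=log.config.seed if log.config else 0,
        package_version=__version__,
        file_hashes=hashes,
    )
    (Path(outdir) / "manifest.json").write_text(manifest.to_json())
    return manifest
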