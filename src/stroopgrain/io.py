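"""Readers, writers and run configuration.

Trial tables are comma-separated UTF-8 text with a header row; overtime
is an explicit ``outcome`` value, never a sentinel RT.  Every result
written through :func:`write_results` gets a sidecar metadata record
(config hash, seeds, package version) so outputs are traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "TRIAL_SCHEMA",
    "schema_text",
    "read_trials",
    "write_trials",
    "write_results",
    "RunConfig",
    "config_hash",
]

#: column -> (required-for, description)
TRIAL_SCHEMA = {
    "pid": ("always", "participant identifier"),
    "cb": ("always", "counterbalancing group, 1 (standard Stroop first) or 2"),
    "task": ("always", "'standard' or 'emotional'"),
    "block": ("always", "block number within task"),
    "trial": ("always", "trial index within block"),
    "congruency": ("standard", "'congruent' or 'incongruent' (standard task)"),
    "word": ("emotional", "stimulus word (emotional task)"),
    "valence_score": ("emotional", "continuous word valence in [-1, 1]"),
    "rt_ms": ("always", "reaction time in ms; empty for overtime trials"),
    "outcome": ("always", "'correct', 'incorrect' or 'overtime'"),
    "sex": ("always", "sex assigned at birth, male=1"),
    "age": ("always", "age in years"),
    "esl": ("optional", "English as a second language flag"),
    "brooding": ("always", "ruminative-brooding sum score (constant per pid)"),
}


def schema_text() -> str:
    lines = ["Trial table columns (CSV, UTF-8, header row):"]
    for col, (req, desc) in TRIAL_SCHEMA.items():
        lines.append(f"  {col:14s} [{req}] {desc}")
    return "\n".join(lines)


def read_trials(path, task: str | None = None) -> pd.DataFrame:
    """Read and schema-validate a trial table.

    ``task`` tightens validation: a standard-task analysis requires the
    congruency column, an emotional-task analysis the word and valence
    columns.  Unknown columns are preserved.  Malformed RT values
    produce a row-level error report.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = [c for c, (req, _) in TRIAL_SCHEMA.items() if req == "always"]
    if task == "standard":
        required.append("congruency")
    elif task == "emotional":
        required += ["word", "valence_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing required column(s): {missing}")
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad = df.index[rt.isna() & (df["outcome"] != "overtime")]
    if len(bad):
        raise ValueError(
            f"malformed rt_ms on {len(bad)} non-overtime row(s), e.g. rows "
            f"{list(bad[:5])}"
        )
    df["rt_ms"] = rt
    logger.info(
        "read %d trials for %d participants from %s",
        len(df), df["pid"].nunique(), path,
    )
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    cols = [c for c in TRIAL_SCHEMA if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, index=False, columns=cols)


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serialisable configuration object."""
    canon = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


def write_results(results, path, config=None, seed=None) -> None:
    """Write a results table/record plus a sidecar metadata file.

    DataFrames become CSV (deterministic column order and float
    formatting); dicts become JSON.  The sidecar ``<path>.meta.json``
    records the config hash, master seed and package version.
    """
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(results, pd.DataFrame):
        out = results.reset_index() if results.index.name else results
        out.to_csv(path, index=False)
        attrs = dict(results.attrs)
    elif isinstance(results, dict):
        path.write_text(
            json.dumps(results, indent=2, sort_keys=True, default=str) + "\n",
            encoding="utf-8",
        )
        attrs = {}
    else:
        raise TypeError(f"cannot write results of type {type(results)}")
    meta = {
        "config_hash": config_hash(config) if config is not None else None,
        "seed": seed,
        "version": __version__,
        "attrs": {k: v for k, v in attrs.items() if _jsonable(v)},
    }
    Path(str(path) + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )


def _jsonable(v) -> bool:
    try:
        json.dumps(v, default=str)
        return True
    except TypeError:
        return False


@dataclass
class RunConfig:
    """End-to-end run settings; round-trips losslessly through YAML."""

    network_path: str | None = None
    trials_path: str | None = None
    output_dir: str = "results"
    stages: list[str] = field(default_factory=lambda: ["fit", "select", "stats"])
    master_seed: int = 0
    alpha_tasks: float = 0.025
    alpha_params: float = 0.05
    apply_stoplist: bool = True
    correct_only: bool = True
    ea: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            cfg = cls.from_dict(yaml.safe_load(fh))
        for p in (cfg.network_path, cfg.trials_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())
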