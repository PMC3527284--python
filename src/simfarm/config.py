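"""Global configuration and task-document loading.

The global configuration (one YAML document) carries the administrator-set
load-balancing target *t*, backend settings, the work directory, the
notification sink and the SD divisor convention.  Task descriptions are one
YAML document per task, resolving to a :class:`~simfarm.tasks.TaskSpec`.
Unknown keys are rejected in both, so typos fail at startup rather than
silently running with defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .backend import BackendConfig
from .balance import LoadBalanceConfig
from .fixtures import get_model
from .model import read_native_model, read_sbml_model
from .tasks import TaskSpec

__all__ = ["GlobalConfig", "load_global_config", "load_task_spec", "setup_logging"]

_GLOBAL_KEYS = {"t_target", "override_one_per_job", "benchmark_cap", "backend",
                "work_dir", "notification", "sd_divisor", "log_path"}
_BACKEND_KEYS = {"backend", "max_parallel", "eviction_rate", "poll_interval", "seed"}
_TASK_KEYS = {
    "task_type", "name", "model", "model_file", "model_fixture", "sbml_file",
    "t_end", "n_points", "target_spec", "target_mode", "direction",
    "algorithm", "algorithm_settings", "sensitivity_parameters",
    "optimization_parameters", "repeat_count", "scan_parameters", "scan_grid",
    "scan_subtask", "algorithms", "raw_args", "raw_executable",
    "dataset_file", "dataset_tsv", "base_seed",
}


@dataclass
class GlobalConfig:
    balance: LoadBalanceConfig = field(default_factory=LoadBalanceConfig)
    backend: BackendConfig = field(default_factory=BackendConfig)
    work_dir: Path = Path("simfarm_work")
    notification: str = "log"  # "log" or a file path
    sd_divisor: str = "sample"
    log_path: Path | None = None  # defaults to work_dir/activity.log

    def resolved_log_path(self) -> Path:
        return Path(self.log_path) if self.log_path else Path(self.work_dir) / "activity.log"


def load_global_config(source) -> GlobalConfig:
    """Load the global configuration from a YAML file path, text, or dict."""
    raw = _as_mapping(source)
    unknown = set(raw) - _GLOBAL_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    backend_raw = dict(raw.get("backend", {}))
    unknown = set(backend_raw) - _BACKEND_KEYS
    if unknown:
        raise ValueError(f"unknown backend keys: {sorted(unknown)}")
    balance = LoadBalanceConfig(
        t_target=float(raw.get("t_target", 900.0)),
        override_one_per_job=bool(raw.get("override_one_per_job", False)),
        benchmark_cap=raw.get("benchmark_cap"),
    )
    cfg = GlobalConfig(
        balance=balance,
        backend=BackendConfig(**backend_raw),
        work_dir=Path(raw.get("work_dir", "simfarm_work")),
        notification=raw.get("notification", "log"),
        sd_divisor=raw.get("sd_divisor", "sample"),
        log_path=Path(raw["log_path"]) if raw.get("log_path") else None,
    )
    if cfg.sd_divisor not in ("sample", "population"):
        raise ValueError(f"sd_divisor must be 'sample' or 'population', got {cfg.sd_divisor!r}")
    return cfg


def _as_mapping(source) -> dict:
    if isinstance(source, dict):
        return source
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text = Path(source).read_text()
    else:
        text = str(source)
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration document must be a mapping")
    return data


def load_task_spec(source, base_dir: Path | None = None) -> TaskSpec:
    """Load a TaskSpec from a YAML task document (path, text, or dict)."""
    raw = _as_mapping(source)
    unknown = set(raw) - _TASK_KEYS
    if unknown:
        raise ValueError(f"unknown task keys: {sorted(unknown)}")
    base_dir = Path(base_dir) if base_dir else Path(".")

    model = None
    if "model_fixture" in raw:
        model = get_model(raw["model_fixture"])
    elif "model" in raw:
        model = read_native_model(raw["model"])
    elif "model_file" in raw:
        model = read_native_model((base_dir / raw["model_file"]).read_text())
    elif "sbml_file" in raw:
        model = read_sbml_model(str(base_dir / raw["sbml_file"]))

    dataset_tsv = raw.get("dataset_tsv", "")
    if "dataset_file" in raw:
        dataset_tsv = (base_dir / raw["dataset_file"]).read_text()

    spec = TaskSpec(
        task_type=raw["task_type"],
        model=model,
        name=raw.get("name", "task"),
        t_end=float(raw.get("t_end", 10.0)),
        n_points=int(raw.get("n_points", 101)),
        target_spec=raw.get("target_spec", ""),
        target_mode=raw.get("target_mode", "final_time"),
        direction=raw.get("direction", "minimize"),
        algorithm=raw.get("algorithm", "particle_swarm"),
        algorithm_settings=dict(raw.get("algorithm_settings", {})),
        sensitivity_parameters=[tuple(p) for p in raw.get("sensitivity_parameters", [])],
        optimization_parameters=[tuple(p) for p in raw.get("optimization_parameters", [])],
        repeat_count=int(raw.get("repeat_count", 1)),
        scan_parameters=list(raw.get("scan_parameters", [])),
        scan_grid=raw.get("scan_grid"),
        scan_subtask=dict(raw.get("scan_subtask", {"type": "time_course"})),
        algorithms=[(a["algorithm"], dict(a.get("settings", {})))
                    for a in raw.get("algorithms", [])],
        raw_args=raw.get("raw_args", ""),
        raw_executable=raw.get("raw_executable", ""),
        dataset_tsv=dataset_tsv,
        base_seed=int(raw.get("base_seed", 0)),
    )
    spec.validate()
    return spec


def setup_logging(log_path: Path, level=logging.INFO) -> logging.Logger:
    """Route all package activity (including errors) to one text log file."""
    log_path = Path(log_path)
    log_path.parent.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger("simfarm")
    logger.setLevel(level)
    have = any(isinstance(h, logging.FileHandler)
               and Path(getattr(h, "baseFilename", "")) == log_path.resolve()
               for h in logger.handlers)
    if not have:
        handler = logging.FileHandler(log_path)
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    return logger
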