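"""Run configuration: dialect, solver tolerances, output and seeding."""

from __future__ import annotations

import difflib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .model import SolverSettings
from .params import DIALECTS

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    The seed is recorded in every output artifact; solver tolerances and
    the reporting step feed :class:`~pias3net.model.SolverSettings`.
    """

    dialect: str = "methods"
    rtol: float = 1e-6
    atol: float = 1e-8
    report_step: float = 1.0
    out_dir: str = "results"
    seed: int = 0
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}; choose from {DIALECTS}")
        if self.rtol <= 0 or self.atol <= 0 or self.report_step <= 0:
            raise ValueError("tolerances and report_step must be > 0")

    def solver_settings(self) -> SolverSettings:
        return SolverSettings(rtol=self.rtol, atol=self.atol,
                              report_step=self.report_step)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read a JSON or YAML config; absent keys default, unknown keys error.

    Unknown keys raise with a nearest-valid-key suggestion so that typos
    like ``rtoll`` do not silently fall back to a default.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        try:
            data = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ValueError(f"cannot parse {path}: {exc}") from exc
    else:
        try:
            data = json.loads(text) if text.strip() else {}
        except json.JSONDecodeError as exc:
            raise ValueError(
                f"cannot parse {path} (line {exc.lineno}): {exc.msg}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(data).__name__}")
    valid = set(RunConfig.__dataclass_fields__)
    for key in data:
        if key not in valid:
            hint = difflib.get_close_matches(key, sorted(valid), n=1)
            extra = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {key!r}{extra}")
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    else:
        path.write_text(json.dumps(config.to_dict(), indent=2) + "\n")
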