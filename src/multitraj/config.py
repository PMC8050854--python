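"""Run configuration, validation, and manifest writing for the CLI pipeline."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .core import ValidationError

logger = logging.getLogger("multitraj")

__all__ = ["RunConfig", "load_config", "parse_grid", "write_manifest", "setup_logging"]


@dataclass
class RunConfig:
    """All knobs of the pipeline in one structured object.

    Paths are optional until the subcommand that needs them runs; `validate`
    checks only the paths a command actually uses.
    """

    network: str | None = None
    cohort: str | None = None
    labels: str | None = None
    entity_map: str | None = None
    out_dir: str = "multitraj_out"
    # resolution sweep
    grid: list[float] = field(default_factory=lambda: [float(g) for g in range(1, 51)])
    weighted: bool = False
    # selection / optimization
    theta_grid: list[int] = field(default_factory=lambda: [0, 1, 2, 3])
    lambda_grid: list[int] = field(default_factory=lambda: list(range(2, 11)))
    smin: int = 2
    kmax: int = 8
    pam_direct: bool = False
    normalized_hamming: bool = False
    linkage_method: str = "average"
    terminal_death: bool = False
    # stochastic procedure sizes
    seed: int = 0
    n_shuffles: int = 10_000
    n_bootstrap: int = 1000
    n_null: int = 1000
    alpha: float = 0.05

    def validate(self, require: tuple[str, ...] = ()) -> None:
        problems = []
        for name in require:
            value = getattr(self, name)
            if value is None:
                problems.append(f"missing required path: {name}")
            elif not Path(value).exists():
                problems.append(f"{name} path does not exist: {value}")
        if not self.grid or any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            problems.append("grid must be non-empty and strictly increasing")
        if self.smin < 1 or self.kmax < 2:
            problems.append("smin must be >= 1 and kmax >= 2")
        if not 0 < self.alpha <= 1:
            problems.append("alpha must be in (0, 1]")
        if problems:
            raise ValidationError("invalid configuration: " + "; ".join(problems))


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Read a YAML config file (optional) and apply command-line overrides."""
    data = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def parse_grid(text: str) -> list[float]:
    """Parse '1:12' (inclusive integer range) or '0.5,1,2' into a grid."""
    if ":" in text:
        lo, hi = text.split(":")
        return [float(g) for g in range(int(lo), int(hi) + 1)]
    return [float(x) for x in text.split(",") if x.strip()]


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(out_dir: str | Path, command: str, config: RunConfig, inputs: list[str | Path]) -> Path:
    from . import __version__

    payload = {
        "command": command,
        "version": __version__,
        "config": asdict(config),
        "inputs": {str(p): _checksum(p) for p in inputs if p and Path(p).exists()},
    }
    out = Path(out_dir) / f"manifest_{command}.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return out


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING if verbosity <= 0 else logging.INFO if verbosity == 1 else logging.DEBUG
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)
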