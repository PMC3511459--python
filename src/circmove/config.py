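"""Plain-text (key=value) serialization of model specs and run configs.

A heading-model spec line looks like ``car(kj)``, optionally with a
constraint: ``car(kj)[lambda=1.234]``, ``car(vm)[alpha=0.5]``,
``car(kj)[fp=100,2000]``.  A run config file holds one ``key = value`` pair
per line (``#`` comments allowed); list values are comma-separated.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .heading import (
    Family,
    FixedAlpha,
    FixedLambda,
    FocalPoint,
    HeadingModelSpec,
    Noise,
)

__all__ = ["spec_to_string", "spec_from_string", "RunConfig", "read_config",
           "config_hash"]

_SPEC_RE = re.compile(
    r"^\s*(crw|car)\s*\(\s*(vm|wc|kj)\s*\)\s*(?:\[\s*(\w+)\s*=\s*([^\]]+)\]\s*)?$",
    re.IGNORECASE)


def spec_to_string(spec: HeadingModelSpec) -> str:
    s = f"{spec.family.value}({spec.noise.value})"
    c = spec.constraint
    if isinstance(c, FixedLambda):
        s += f"[lambda={c.value:g}]"
    elif isinstance(c, FixedAlpha):
        s += f"[alpha={c.value:g}]"
    elif isinstance(c, FocalPoint):
        s += f"[fp={c.x:g},{c.y:g}]"
    return s


def spec_from_string(text: str) -> HeadingModelSpec:
    m = _SPEC_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse model spec {text!r} "
                         "(expected e.g. 'car(kj)' or 'car(kj)[lambda=1.2]')")
    family, noise, key, val = m.groups()
    constraint = None
    if key is not None:
        key = key.lower()
        if key == "lambda":
            constraint = FixedLambda(float(val))
        elif key == "alpha":
            constraint = FixedAlpha(float(val))
        elif key == "fp":
            x, y = (float(v) for v in val.split(","))
            constraint = FocalPoint(x, y)
        else:
            raise ValueError(f"unknown constraint {key!r} in {text!r}")
    return HeadingModelSpec(Family(family.lower()), Noise(noise.lower()), constraint)


@dataclass(frozen=True)
class RunConfig:
    """Everything a selection run needs; serializable so the run is
    reproducible from the config alone."""

    fixes: str
    time_units: Tuple[float, ...] = (1.0,)
    models: Tuple[str, ...] = ("crw(vm)", "car(vm)", "car(wc)", "car(kj)")
    n_starts: int = 8
    seed: int = 0
    n_sim: int = 500
    out: Optional[str] = None

    def specs(self) -> List[HeadingModelSpec]:
        return [spec_from_string(m) for m in self.models]

    def to_text(self) -> str:
        lines = [
            f"fixes = {self.fixes}",
            "time_units = " + ",".join(f"{t:g}" for t in self.time_units),
            "models = " + ",".join(self.models),
            f"n_starts = {self.n_starts}",
            f"seed = {self.seed}",
            f"n_sim = {self.n_sim}",
        ]
        if self.out:
            lines.append(f"out = {self.out}")
        return "\n".join(lines) + "\n"


def read_config(path) -> RunConfig:
    kv: Dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        kv[key.lower()] = val
    if "fixes" not in kv:
        raise ValueError("config must set 'fixes'")
    cfg = RunConfig(
        fixes=kv["fixes"],
        time_units=tuple(float(t) for t in kv.get("time_units", "1").split(",")),
        models=tuple(m.strip() for m in kv.get(
            "models", "crw(vm),car(vm),car(wc),car(kj)").split(",")),
        n_starts=int(kv.get("n_starts", 8)),
        seed=int(kv.get("seed", 0)),
        n_sim=int(kv.get("n_sim", 500)),
        out=kv.get("out"),
    )
    for m in cfg.models:            # validate early, before any computation
        spec_from_string(m)
    return cfg


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(cfg.to_text().encode()).hexdigest()[:12]
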