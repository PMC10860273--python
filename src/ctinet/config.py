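"""Run configuration: the handful of knobs the pipeline exposes.

Defaults follow the method's stated conventions: networks are built only
for cell types with at least 100 cells, edges are kept at BH q <= 0.05,
random-walk restart probability is 0.5 with an L1 convergence tolerance
of 1e-10, and permutation nulls use 1000 draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .core import ValidationError


@dataclass
class RunConfig:
    alpha_edge_q: float = 0.05
    min_cells: int = 100
    n_permutations: int = 1000
    n_null_networks: int = 20
    rwr_gamma: float = 0.5
    rwr_tol: float = 1e-10
    rng_seed: int = 0

    def validate(self) -> "RunConfig":
        if not (0.0 < self.alpha_edge_q <= 1.0):
            raise ValidationError(f"alpha_edge_q must be in (0, 1], got {self.alpha_edge_q}")
        if self.min_cells < 1:
            raise ValidationError(f"min_cells must be positive, got {self.min_cells}")
        if self.n_permutations < 1:
            raise ValidationError(f"n_permutations must be positive, got {self.n_permutations}")
        if self.n_null_networks < 1:
            raise ValidationError(f"n_null_networks must be positive, got {self.n_null_networks}")
        if not (0.0 < self.rwr_gamma <= 1.0):
            raise ValidationError(f"rwr_gamma must be in (0, 1], got {self.rwr_gamma}")
        if self.rwr_tol <= 0:
            raise ValidationError(f"rwr_tol must be positive, got {self.rwr_tol}")
        self.rng_seed = int(self.rng_seed)
        return self


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a flat key=value config file, then apply keyword overrides.

    Blank lines and ``#`` comments are ignored. Unknown keys and
    unparsable values are errors, never silently dropped.
    """
    values: dict = {}
    if path is not None:
        text = Path(path).read_text()
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
    values.update(overrides)

    kwargs = {}
    for key, val in values.items():
        if key not in _FIELD_TYPES:
            raise ValidationError(f"unknown config key {key!r}")
        caster = int if "int" in str(_FIELD_TYPES[key]) else float
        try:
            kwargs[key] = caster(val)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"config key {key!r}: cannot parse {val!r}") from exc
    return RunConfig(**kwargs).validate()
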