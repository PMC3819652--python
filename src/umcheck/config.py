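"""Run-wide numerical and solver configuration.

All analyses accept an optional :class:`RunConfig`; the module-level
:data:`DEFAULT_CONFIG` is used when none is given.  Tolerances are absolute.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path


@dataclasses.dataclass
class RunConfig:
    """Numerical parameters shared by every analysis.

    Attributes
    ----------
    big_bound:
        Finite surrogate ``M`` for unbounded fluxes (flux units).  Infinite
        bounds found in inputs are clamped to ``[-M, M]`` so every linear
        program has a finite optimum.
    zero_tol:
        Threshold below which a flux magnitude is treated as zero; the
        numeric surrogate for the "zero flux in every steady state"
        definition of a blocked reaction.
    feasibility_tol:
        Absolute tolerance on mass-balance residuals accepted from the
        solver.
    lethal_threshold_fraction:
        A gene knockout is lethal when the mutant biomass optimum falls
        below this fraction of the wild-type optimum.
    biomass_lb_fraction:
        Default biomass lower bound for minimal-medium prediction, as a
        fraction of the wild-type optimum.
    solver_name:
        LP/MILP backend; only ``"highs"`` (scipy) is built in.
    max_rays:
        Cap on enumerated extreme rays in conservation-relation analysis.
    dd_max_cols:
        Largest column count for which exact double-description
        enumeration is attempted; larger systems fall back to a rational
        nullspace basis with a nonnegativity check.
    time_limit_s:
        Per-solve time limit passed to the MILP backend.
    """

    big_bound: float = 1000.0
    zero_tol: float = 1e-9
    feasibility_tol: float = 1e-9
    lethal_threshold_fraction: float = 0.01
    biomass_lb_fraction: float = 0.1
    solver_name: str = "highs"
    max_rays: int = 10000
    dd_max_cols: int = 120
    time_limit_s: float = 300.0

    def __post_init__(self) -> None:
        if self.zero_tol <= 0 or self.feasibility_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 < self.lethal_threshold_fraction <= 1:
            raise ValueError("lethal_threshold_fraction must be in (0, 1]")
        if not 0 < self.biomass_lb_fraction <= 1:
            raise ValueError("biomass_lb_fraction must be in (0, 1]")
        if self.big_bound <= 0:
            raise ValueError("big_bound must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from JSON or flat ``key=value`` text."""
        text = Path(path).read_text()
        stripped = text.lstrip()
        if stripped.startswith("{"):
            data = json.loads(text)
        else:
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = value.strip()
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in data.items():
            if key not in fields:
                raise ValueError(f"unknown config key: {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                kwargs[key] = str(value).lower() in ("1", "true", "yes")
            elif isinstance(default, int) and not isinstance(value, float):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = str(value)
        return cls(**kwargs)


DEFAULT_CONFIG = RunConfig()
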