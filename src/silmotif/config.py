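"""Run configuration: every tunable default in one place.

The config file format is a flat ``key = value`` document (``#`` comments
allowed).  Ramachandran regions are configured as semicolon-separated
rectangles ``phi_lo,phi_hi,psi_lo,psi_hi`` under keys ``rama_alphaR``,
``rama_alphaL`` and ``rama_beta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import InputError
from .geometry import DEFAULT_RAMA_REGIONS, RamaClass
from .motifs import MotifConfig


@dataclass(frozen=True)
class RunConfig:
    """Defaults shared by the CLI and the library entry points."""

    min_run: int = 4
    flank_min: int = 3
    antiparallel_filter: bool = False
    axis_min_angle: float = 120.0
    max_planarity: float | None = None
    saltbridge_cutoff: float = 4.0
    polar_cutoff: float = 3.5
    consensus_denominator: str = "all20"
    degrees_per_residue: float = 100.0
    break_distance: float = 4.5
    seed: int = 0
    rama_regions: dict = field(default_factory=lambda: dict(DEFAULT_RAMA_REGIONS))

    def __post_init__(self) -> None:
        for name in ("saltbridge_cutoff", "polar_cutoff", "degrees_per_residue",
                     "break_distance"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.consensus_denominator not in ("all20", "observed"):
            raise InputError(f"bad consensus denominator {self.consensus_denominator!r}")

    def motif_config(self) -> MotifConfig:
        return MotifConfig(
            flank_min=self.flank_min,
            min_run=self.min_run,
            antiparallel_filter=self.antiparallel_filter,
            axis_min_angle=self.axis_min_angle,
            max_planarity=self.max_planarity,
            rama_regions=self.rama_regions,
            break_distance=self.break_distance,
        )


_RAMA_KEYS = {
    "rama_alphaR": RamaClass.ALPHA_R,
    "rama_alphaL": RamaClass.ALPHA_L,
    "rama_beta": RamaClass.BETA,
}

_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def load_config(path) -> RunConfig:
    """Parse a flat key=value config file into a :class:`RunConfig`."""
    cfg = RunConfig()
    overrides: dict = {}
    regions = dict(cfg.rama_regions)
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InputError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in _RAMA_KEYS:
            rects = []
            for rect in value.split(";"):
                parts = [float(x) for x in rect.split(",")]
                if len(parts) != 4:
                    raise InputError(f"{path}:{lineno}: rectangle needs 4 numbers")
                rects.append(tuple(parts))
            regions[_RAMA_KEYS[key]] = tuple(rects)
        elif key in ("min_run", "flank_min", "seed"):
            overrides[key] = int(value)
        elif key in ("axis_min_angle", "saltbridge_cutoff", "polar_cutoff",
                     "degrees_per_residue", "break_distance", "max_planarity"):
            overrides[key] = float(value)
        elif key == "antiparallel_filter":
            overrides[key] = _BOOL[value.lower()]
        elif key == "consensus_denominator":
            overrides[key] = value
        else:
            raise InputError(f"{path}:{lineno}: unknown key {key!r}")
    return replace(cfg, rama_regions=regions, **overrides)
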