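"""Simulation parameters, presets and plain-text (YAML) config files.

Two presets ship with the package: ``frog`` — the quasi-2D small-organ
parameter set (support radius 10 mm, boundary pressures 10.6 / 1.60 kPa,
gamma 0.01e-12 m^3) — and ``brain`` — the whole-brain 3D set (support
radius 30 mm, boundary pressures 13.3 / 0.66 kPa, gamma 0.20e-12 m^3,
grey-matter alpha 1.6x the white-matter base).

Config files are YAML mappings; every physical key may be written either as
a bare number (canonical unit assumed) or as ``{value: ..., unit: "..."}``
in which case the unit string is validated against the canonical one.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, replace

import yaml

log = logging.getLogger("perfusim")

#: canonical unit per physical parameter
UNITS = {
    "mu": "Pa s",
    "epsilon_mm": "mm",
    "hct": "-",
    "alpha": "m s kg^-1",
    "k_a": "m^2",
    "k_v": "m^2",
    "phi_a": "-",
    "phi_v": "-",
    "p_a0": "Pa",
    "p_v0": "Pa",
    "gamma_a": "m^3",
    "gamma_v": "m^3",
    "alpha_grey_ratio": "-",
    "smoothing_radius_mm": "mm",
    "smoothing_sigma_mm": "mm",
    "t0_s": "s",
    "c0": "mol m^-3",
    "t_sim_s": "s",
    "sample_dt_s": "s",
    "solver_tol": "-",
    "cfl_factor": "-",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Scalar physical and numerical parameters of one simulation."""

    name: str = "frog"
    mu: float = 3.00e-3            # blood viscosity [Pa s]
    epsilon_mm: float = 10.0       # support radius of the terminal kernels
    hct: float = 0.40              # hematocrit [-]
    alpha: float = 1.00e-6         # perfusion proportionality [m s kg^-1]
    k_a: float = 1.00e-12          # arterial permeability [m^2]
    k_v: float = 5.00e-12          # venous permeability [m^2]
    phi_a: float = 0.05            # arterial porosity (CBV fraction) [-]
    phi_v: float = 0.10            # venous porosity [-]
    p_a0: float = 10.6e3           # arterial root pressure [Pa]
    p_v0: float = 1.60e3           # venous root pressure [Pa]
    gamma_a: float = 0.01e-12      # terminal pressure-drop parameter [m^3]
    gamma_v: float = 0.01e-12
    alpha_grey_ratio: float = 1.6  # grey/white alpha contrast [-]
    smoothing_radius_mm: float = 2.5
    smoothing_sigma_mm: float = 1.5
    t0_s: float = 7.5              # AIF bolus delay [s]
    c0: float = 1.0                # AIF amplitude [mol m^-3]
    t_sim_s: float = 120.0
    sample_dt_s: float = 5.0
    solver_tol: float = 1e-6
    cfl_factor: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for key in ("mu", "epsilon_mm", "k_a", "k_v", "phi_a", "phi_v",
                    "p_a0", "p_v0", "gamma_a", "gamma_v", "t_sim_s",
                    "sample_dt_s", "solver_tol", "cfl_factor", "c0",
                    "alpha_grey_ratio"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be strictly positive")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if not 0.0 <= self.hct < 1.0:
            raise ValueError("hematocrit must lie in [0, 1)")
        if not (0 <= self.phi_a <= 1 and 0 <= self.phi_v <= 1):
            raise ValueError("porosities must lie in [0, 1]")

    def with_factors(self, factors: dict[str, float]) -> "SimulationConfig":
        """Multiplicatively perturbed copy (sensitivity analysis)."""
        changes = {}
        for key, f in factors.items():
            if not hasattr(self, key):
                raise KeyError(f"unknown parameter {key!r}")
            changes[key] = getattr(self, key) * f
        return replace(self, **changes)

    def to_yaml(self, path):
        doc = {}
        for key, val in asdict(self).items():
            if key in UNITS:
                doc[key] = {"value": val, "unit": UNITS[key]}
            else:
                doc[key] = val
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


_PRESETS = {
    "frog": SimulationConfig(name="frog"),
    "brain": SimulationConfig(
        name="brain", epsilon_mm=30.0, alpha=1.00e-5, k_a=12.5e-12,
        k_v=25.0e-12, p_a0=13.3e3, p_v0=0.66e3, gamma_a=0.20e-12,
        gamma_v=0.20e-12),
}


def preset(name: str) -> SimulationConfig:
    """Return the named parameter preset ('frog' or 'brain')."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(_PRESETS)}")
    return _PRESETS[name]


def load_config(path, base: str = "frog") -> SimulationConfig:
    """Load a YAML config on top of a preset, validating keys and units."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    base_name = doc.pop("preset", base)
    cfg = preset(base_name)
    known = set(asdict(cfg))
    changes = {}
    for key, val in doc.items():
        if key not in known:
            raise KeyError(f"unknown config key {key!r}")
        if isinstance(val, dict):
            unit = val.get("unit")
            if unit is not None and key in UNITS and unit != UNITS[key]:
                raise ValueError(f"unit mismatch for {key!r}: got {unit!r}, "
                                 f"expected {UNITS[key]!r}")
            val = val["value"]
        changes[key] = val
    missing = known - set(doc) - {"name"}
    if missing:
        log.debug("config %s: defaults used for %s", path, sorted(missing))
    return replace(cfg, **changes)
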