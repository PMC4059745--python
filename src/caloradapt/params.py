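"""Model parameters and their plain-text serialization.

All rate constants are expressed per minute (the model's internal time
unit); the two memory windows are expressed in days and converted at
1440 min/day where needed.  Energy is in kJ, masses in g, leptin in ng,
ghrelin in pg/mL, glucose in g.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

MIN_PER_DAY = 1440.0

#: Metabolizable energy density of the chow diet, kJ per gram.
DIET_ENERGY_DENSITY = 12.6


@dataclass(frozen=True)
class ModelParameters:
    """The 21 constants of the energy-balance model.

    Grouped as: energy densities and intake kinetics (fixed from the
    literature / diet composition), the four energy-partition constants
    plus the baseline rate of energy expenditure (fit step 1), the four
    hunger coefficients (fit step 2), and the three memory constants
    (fit step 3).
    """

    # -- fixed constants -------------------------------------------------
    rho_F: float = 39.3           #: fat energy density, kJ/g
    rho_FFM: float = 7.5          #: fat-free energy density, kJ/g
    intake_rate_coeff: float = 1.52   #: time to ingest 1 kJ, min/kJ
    ghrelin_prod: float = 0.4025  #: pg/mL/min
    ghrelin_clear: float = 0.007  #: /min
    glucose_yield: float = 0.039  #: g of plasma glucose per kJ eaten
    glucose_clear: float = 0.007  #: /min
    leptin_prod: float = 0.126    #: ng per g fat per min
    leptin_clear: float = 0.074   #: /min

    # -- energy partition + baseline expenditure (fit step 1) ------------
    maintenance_offset: float = 1964.4    #: K, mass-independent caloric content, kJ
    partition_juvenile_amp: float = 2.2      #: a, dimensionless
    partition_baseline: float = 0.16         #: b, dimensionless
    partition_fat_decay: float = 0.269       #: d, /g
    lambda0: float = 2.525e-5                #: baseline expenditure rate, /min

    # -- hunger coefficients (fit step 2) --------------------------------
    hunger_ghrelin_coeff: float = 4.02e-3    #: mL.kJ/min/pg
    hunger_leptin_coeff: float = 1.66e-3     #: /ng
    hunger_glucose_scale: float = 5.03       #: g
    hunger_relax: float = 5.99e-4            #: /min/g

    # -- memory of past intake (fit step 3) ------------------------------
    mem_gain: float = 9.05e-4                #: k, /kJ
    tau1: float = 1.0                        #: short window, day
    tau2: float = 8.0                        #: long window, day

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0.0) and f.name != "mem_gain":
                raise ValueError(f"parameter {f.name} must be strictly positive, got {v}")
        if self.mem_gain < 0.0:
            raise ValueError("mem_gain must be non-negative")
        if not self.tau1 < self.tau2:
            raise ValueError(f"tau1 ({self.tau1}) must be smaller than tau2 ({self.tau2})")
        if not self.rho_F > self.rho_FFM:
            raise ValueError("fat energy density must exceed fat-free energy density")

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Reference parameter set (defaults above).
DEFAULT_PARAMS = ModelParameters()

_UNITS = {
    "rho_F": "kJ/g", "rho_FFM": "kJ/g", "intake_rate_coeff": "min/kJ",
    "ghrelin_prod": "pg/mL/min", "ghrelin_clear": "/min",
    "glucose_yield": "g/kJ", "glucose_clear": "/min",
    "leptin_prod": "ng/g/min", "leptin_clear": "/min",
    "maintenance_offset": "kJ", "partition_juvenile_amp": "-",
    "partition_baseline": "-", "partition_fat_decay": "/g",
    "lambda0": "/min", "hunger_ghrelin_coeff": "mL.kJ/min/pg",
    "hunger_leptin_coeff": "/ng", "hunger_glucose_scale": "g",
    "hunger_relax": "/min/g", "mem_gain": "/kJ", "tau1": "day", "tau2": "day",
}


def write_params(params: ModelParameters, path: str | Path) -> None:
    """Write parameters to a ``key = value  # unit`` text file."""
    lines = ["# caloradapt model parameters (internal time unit: minute)"]
    for name, value in params.as_dict().items():
        lines.append(f"{name} = {value!r}  # {_UNITS[name]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path: str | Path) -> ModelParameters:
    """Read a parameter file written by :func:`write_params`."""
    values: dict[str, float] = {}
    known = {f.name for f in fields(ModelParameters)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        values[key] = float(val)
    return ModelParameters(**values)
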