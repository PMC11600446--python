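"""Configuration loading and patient parameter vectors.

The model is driven by a single YAML configuration (see
``config/defaults.yaml``).  A *patient* is the nominal configuration plus a
vector of per-parameter perturbation multipliers; a *population* is a batch
of such vectors held as numpy arrays so the whole cohort can be stepped
through the simulator at once.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "load_config",
    "default_config",
    "ParameterSpace",
    "PatientParameters",
    "ParameterSet",
]

NARROW_FRACTION = 0.05


def load_config(path=None) -> dict:
    """Load a model configuration; ``None`` loads the packaged defaults."""
    if path is None:
        ref = importlib.resources.files("virtualckd.config").joinpath("defaults.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


_DEFAULT_CACHE: dict = {}


def default_config() -> dict:
    """Packaged default configuration (cached, returned as a fresh copy)."""
    if "cfg" not in _DEFAULT_CACHE:
        _DEFAULT_CACHE["cfg"] = load_config(None)
    import copy

    return copy.deepcopy(_DEFAULT_CACHE["cfg"])


@dataclass(frozen=True)
class SpaceEntry:
    name: str
    perturb_class: str  # "narrow" | "wide"
    fraction: float     # half-width of the uniform multiplier range

    @property
    def lower(self) -> float:
        return max(0.05, 1.0 - self.fraction)

    @property
    def upper(self) -> float:
        return 1.0 + self.fraction


class ParameterSpace:
    """The set of perturbable parameters and their multiplier ranges.

    Narrow-class entries move +/-5% around nominal; wide-class entries move
    up to 100% above nominal (per-entry fraction) and are bounded below so
    every physical parameter stays strictly positive.
    """

    def __init__(self, entries: list[SpaceEntry]):
        if not entries:
            raise ValueError("parameter space must contain at least one entry")
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in space")
        for e in entries:
            if e.lower <= 0:
                raise ValueError(f"{e.name}: lower bound must stay positive")
        self.entries = list(entries)

    @classmethod
    def from_config(cls, config: dict | None = None) -> "ParameterSpace":
        config = config if config is not None else default_config()
        entries = []
        for row in config["parameters"]:
            klass = row["class"]
            frac = NARROW_FRACTION if klass == "narrow" else float(row["fraction"])
            entries.append(SpaceEntry(row["name"], klass, frac))
        return cls(entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def sample(self, rng: np.random.Generator, n: int = 1) -> dict[str, np.ndarray]:
        """Draw ``n`` multiplier vectors, uniform per entry within its range."""
        return {
            e.name: rng.uniform(e.lower, e.upper, size=n) for e in self.entries
        }

    def unit(self, n: int = 1) -> dict[str, np.ndarray]:
        """All-ones multipliers (the nominal model)."""
        return {e.name: np.ones(n) for e in self.entries}


@dataclass
class ParameterSet:
    """A batch of patient parameter vectors (vectorized over patients).

    ``multipliers`` maps parameter name to an array of shape ``(n,)``;
    missing names default to 1.  ``nominal`` values come from the attached
    configuration.
    """

    multipliers: dict[str, np.ndarray]
    config: dict = field(default_factory=default_config)

    def __post_init__(self) -> None:
        sizes = {np.asarray(v).size for v in self.multipliers.values()}
        if len(sizes) > 1:
            raise ValueError(f"inconsistent multiplier lengths: {sizes}")
        self._n = sizes.pop() if sizes else 1
        self.multipliers = {
            k: np.asarray(v, dtype=float).reshape(self._n)
            for k, v in self.multipliers.items()
        }
        for k, v in self.multipliers.items():
            if not np.all(np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"multiplier {k!r} must be finite and positive")

    @property
    def n(self) -> int:
        return self._n

    def mult(self, name: str) -> np.ndarray:
        return self.multipliers.get(name, np.ones(self._n))

    def subset(self, idx) -> "ParameterSet":
        return ParameterSet(
            {k: v[idx] for k, v in self.multipliers.items()}, config=self.config
        )

    @classmethod
    def nominal(cls, n: int = 1, config: dict | None = None) -> "ParameterSet":
        return cls({}, config=config if config is not None else default_config())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({k: v for k, v in self.multipliers.items()})


class PatientParameters(ParameterSet):
    """Single-patient view of :class:`ParameterSet` (n == 1).

    Exposes ``nominal`` (name -> nominal value) for the headline structural
    parameters alongside the perturbation multipliers.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if self._n != 1:
            raise ValueError("PatientParameters holds exactly one patient")

    @property
    def nominal(self) -> dict[str, float]:
        cfg = self.config
        op = cfg["operating_point"]
        return {
            "salt_intake": op["salt_intake"],
            "nephron_number": op["nephron_number"],
            "damage_threshold": cfg["damage"]["threshold_mmhg"],
            "damage_delay": float(cfg["damage"]["delay_days"]),
            "damage_gain": cfg["damage"]["gain"],
            "amlodipine_clearance": 1.0,
            "renin_gain": 1.0,
            "aldo_gain": 1.0,
            "sympathetic_tone": 1.0,
            "heart_rate": 1.0,
            "baroreceptor_gain": 1.0,
            "myogenic_gain": 1.0,
            "renal_resistance": 1.0,
            "proximal_reabsorption": cfg["constants"]["fp0"],
            "distal_reabsorption": 1.0,
        }
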