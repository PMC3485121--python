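"""Trajectory container and simulation protocols shared by both simulators."""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import SiteGraph


@dataclass
class Trajectory:
    """Sampled observable counts on a fixed time grid.

    ``values`` has shape (len(times), len(observable_names)); counts are
    nonnegative integers.  ``metadata`` records seed, method and model hash
    so runs are attributable.
    """

    times: np.ndarray
    values: np.ndarray
    observable_names: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.values.shape != (len(self.times), len(self.observable_names)):
            raise ValueError("values shape does not match grid/observables")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.observable_names)
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)

    def observable(self, name: str) -> np.ndarray:
        return self.values[:, self.observable_names.index(name)]


@dataclass
class Addition:
    """Add copies of a concrete species at a protocol time (ligand dosing)."""

    time: float
    species: Union[SiteGraph, str]
    copies: int


@dataclass
class ParamSwitch:
    time: float
    name: str
    value: float


@dataclass
class Protocol:
    """Simulation protocol: optional pre-equilibration, then timed
    interventions on [0, t_end].

    ``equilibrate`` seconds are simulated before t=0 (no sampling, no
    interventions); steady state is not auto-detected — the duration is the
    caller's choice.
    """

    equilibrate: float = 0.0
    additions: list[Addition] = field(default_factory=list)
    param_switches: list[ParamSwitch] = field(default_factory=list)

    def events(self) -> list[tuple[float, object]]:
        evs: list[tuple[float, object]] = []
        evs.extend((a.time, a) for a in self.additions)
        evs.extend((s.time, s) for s in self.param_switches)
        evs.sort(key=lambda p: p[0])
        return evs


def sample_grid(t_end: float, sample_dt: float) -> np.ndarray:
    if t_end <= 0 or sample_dt <= 0:
        raise ValueError("t_end and sample_dt must be positive")
    n = int(round(t_end / sample_dt))
    return np.linspace(0.0, n * sample_dt, n + 1)
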