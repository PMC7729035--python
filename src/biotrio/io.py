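"""Configuration, result serialization and fixture generation.

Trajectory and scan tables are CSV (columns ``time_h,R,P,M,ratio``,
17-significant-digit floats, so round trips are lossless); structured
results are JSON with a ``schema_version`` field.  Run configuration is
a flat key-value file (YAML subset).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import BifurcationScan
from .games import BimatrixGame
from .model import ModelParameters, PopulationState
from .simulate import SimulationSettings, Trajectory

__all__ = [
    "RunConfig",
    "SCHEMA_VERSION",
    "trajectory_to_frame",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_scan_csv",
    "write_results_json",
    "generate_fixtures",
]

SCHEMA_VERSION = "1.0"

_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run, round-trippable through a
    flat key-value config file.

    The model itself is deterministic; ``seed`` only controls fixture
    generation for tests.
    """

    params: ModelParameters = field(default_factory=ModelParameters)
    t_end: float = 25.0
    dt_out: float = 0.025
    initial_state: tuple[float, float, float] = (1.0, 1.0, 1.0)
    scan_k3_min: float = 0.2
    scan_k3_max: float = 3.0
    scan_k3_step: float = 0.1
    game_condition: str = "moderate"
    seed: int = 0

    def settings(self) -> SimulationSettings:
        return SimulationSettings(
            t_end=self.t_end,
            dt_out=self.dt_out,
            initial_state=PopulationState(*self.initial_state),
        )

    def scan_grid(self) -> np.ndarray:
        n = int(round((self.scan_k3_max - self.scan_k3_min) / self.scan_k3_step))
        return self.scan_k3_min + self.scan_k3_step * np.arange(n + 1)

    def to_flat_dict(self) -> dict:
        d = {f"params.{k}": v for k, v in self.params.to_dict().items()}
        d.update(
            t_end=self.t_end,
            dt_out=self.dt_out,
            initial_R=self.initial_state[0],
            initial_P=self.initial_state[1],
            initial_M=self.initial_state[2],
            scan_k3_min=self.scan_k3_min,
            scan_k3_max=self.scan_k3_max,
            scan_k3_step=self.scan_k3_step,
            game_condition=self.game_condition,
            seed=self.seed,
        )
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_flat_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        params = ModelParameters(
            **{k.split(".", 1)[1]: float(v) for k, v in d.items() if k.startswith("params.")}
        )
        return cls(
            params=params,
            t_end=float(d["t_end"]),
            dt_out=float(d["dt_out"]),
            initial_state=(float(d["initial_R"]), float(d["initial_P"]), float(d["initial_M"])),
            scan_k3_min=float(d["scan_k3_min"]),
            scan_k3_max=float(d["scan_k3_max"]),
            scan_k3_step=float(d["scan_k3_step"]),
            game_condition=str(d["game_condition"]),
            seed=int(d["seed"]),
        )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_h": traj.times,
            "R": traj.states[:, 0],
            "P": traj.states[:, 1],
            "M": traj.states[:, 2],
            "ratio": traj.ratio,
        }
    )


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    trajectory_to_frame(traj).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    return Trajectory(
        times=df["time_h"].to_numpy(),
        states=df[["R", "P", "M"]].to_numpy(),
        ratio=df["ratio"].to_numpy(),
    )


def write_scan_csv(scan: BifurcationScan, path: str | Path) -> None:
    pd.DataFrame(
        {"k3": scan.k3_values, "env_max": scan.env_max, "env_min": scan.env_min}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_results_json(payload: dict, path: str | Path) -> None:
    """Structured results with a schema-version stamp."""
    out = {"schema_version": SCHEMA_VERSION}
    out.update(payload)
    Path(path).write_text(json.dumps(out, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    if isinstance(obj, (ModelParameters, PopulationState)):
        return asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def generate_fixtures(seed: int, n_games: int = 10) -> dict:
    """Reproducible test fixtures: regime-stratified parameter sets plus
    random bimatrices for equilibrium-oracle property tests.

    The parameter family covers the four dynamic regimes at the reference
    parameterisation (k3 = 0.1, 1, 10, 1000 with every other constant 1
    and N = 4).  Random 2x2 and 3x3 bimatrices (payoffs uniform in
    [-2, 2]) and zero-sum 3x3 matrices exercise the Nash solvers.  The
    same seed yields identical fixtures.
    """
    rng = np.random.default_rng(seed)
    regime_params = [ModelParameters(k3=k3) for k3 in (0.1, 1.0, 10.0, 1000.0)]
    random_bimatrices = []
    for _ in range(n_games):
        shape = rng.choice([2, 3], size=2)
        a = np.round(rng.uniform(-2, 2, size=tuple(shape)), 3)
        b = np.round(rng.uniform(-2, 2, size=tuple(shape)), 3)
        labels1 = tuple(f"s{i}" for i in range(shape[0]))
        labels2 = tuple(f"t{j}" for j in range(shape[1]))
        random_bimatrices.append(BimatrixGame(labels1, labels2, a, b))
    zero_sum = []
    for _ in range(n_games):
        a = np.round(rng.uniform(-2, 2, size=(3, 3)), 3)
        labels = ("s0", "s1", "s2")
        zero_sum.append(BimatrixGame(labels, labels, a, -a))
    return {
        "regime_params": regime_params,
        "random_bimatrices": random_bimatrices,
        "zero_sum_bimatrices": zero_sum,
    }
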