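"""Pipeline configuration: a single TOML file drives a full run.

The resolved configuration is written alongside every run's outputs and
round-trips losslessly through :func:`dump_toml` / :func:`load_config`.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .design import BOTH, DEFAULT_NODE_LABELS
from .exceptions import ConfigError
from .synth import (
    CouplingSpec,
    CovariateModel,
    EdgeLink,
    GompertzGroupParams,
    default_group_specs,
)

# ---------------------------------------------------------------------------
# minimal TOML emitter (stdlib only reads TOML)


def _fmt_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        s = repr(float(v))
        return s if any(c in s for c in ".einf") else s + ".0"
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_fmt_value(x) for x in v) + "]"
    raise ConfigError(f"cannot serialize {type(v).__name__} to TOML")


def dump_toml(data: dict, path: str | Path | None = None) -> str:
    """Serialize a nested dict (tables, arrays of tables, scalars, lists)."""

    def emit(table: dict, prefix: str) -> list[str]:
        lines = []
        scalars = {
            k: v
            for k, v in table.items()
            if not isinstance(v, dict)
            and not (isinstance(v, list) and v and isinstance(v[0], dict))
        }
        if prefix and (scalars or not table):
            lines.append(f"[{prefix}]")
        for k, v in scalars.items():
            if v is None:
                continue
            lines.append(f"{k} = {_fmt_value(v)}")
        for k, v in table.items():
            if isinstance(v, dict):
                sub = f"{prefix}.{k}" if prefix else k
                lines.append("")
                lines.extend(emit(v, sub))
            elif isinstance(v, list) and v and isinstance(v[0], dict):
                sub = f"{prefix}.{k}" if prefix else k
                for item in v:
                    lines.append("")
                    lines.append(f"[[{sub}]]")
                    for ik, iv in item.items():
                        if iv is None:
                            continue
                        lines.append(f"{ik} = {_fmt_value(iv)}")
        return lines

    text = "\n".join(emit(data, "")).lstrip("\n") + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# configuration schema


@dataclass(frozen=True)
class DesignConfig:
    tr_s: float = 3.0
    epoch_len_s: float = 27.0
    n_cycles: int = 8


@dataclass(frozen=True)
class SimulationConfig:
    n_hc: int = 24
    n_scz: int = 31
    seed: int = 0
    noise_sd: float = 1.0
    strong_coupling: float = 0.35
    weak_coupling: float = 0.05
    #: optional exponential-smoothing stress filter time constant (s)
    smoothing_tau_s: float | None = None
    #: optional explicit coupling tables; when empty the default
    #: ground-truth scheme is used
    coupling: tuple[dict, ...] = ()


@dataclass(frozen=True)
class BehaviorConfig:
    n_items: int = 9
    noise: str = "binomial"
    gompertz: dict[str, GompertzGroupParams] = field(
        default_factory=lambda: {
            "HC": GompertzGroupParams(0.90, 1.0, 0.9, 0.08, 0.3, 0.15),
            "SCZ": GompertzGroupParams(0.75, 1.2, 0.6, 0.08, 0.3, 0.15),
        }
    )


@dataclass(frozen=True)
class EstimationConfig:
    mode: str = "bivariate"
    p: int = 1
    include_intercept: bool = True
    demean: bool = False
    hemodynamic_offset: int = 0


@dataclass(frozen=True)
class InferenceConfig:
    q_threshold: float = 0.05
    #: "per-cell" = BH within each condition x phase family of 30 edges;
    #: "global" = one family across all cells
    family: str = "per-cell"


@dataclass(frozen=True)
class PipelineConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    node_labels: tuple[str, ...] = DEFAULT_NODE_LABELS
    covariates: CovariateModel = field(default_factory=CovariateModel)
    output_dir: str = "dfclearn_out"

    def group_specs(self) -> dict[str, list[CouplingSpec]]:
        """Resolve coupling specs: explicit tables, else the defaults."""
        if not self.simulation.coupling:
            return default_group_specs(
                noise_sd=self.simulation.noise_sd,
                strong=self.simulation.strong_coupling,
                weak=self.simulation.weak_coupling,
            )
        specs: dict[str, list[CouplingSpec]] = {}
        for entry in self.simulation.coupling:
            try:
                group = entry["group"]
                spec = CouplingSpec(
                    condition=entry["condition"],
                    phase=entry.get("phase", BOTH),
                    B=np.asarray(entry["B"], dtype=float),
                    intercept=entry.get("intercept"),
                    noise_sd=float(entry.get("noise_sd", self.simulation.noise_sd)),
                )
            except KeyError as e:
                raise ConfigError(f"coupling table missing key {e}") from e
            specs.setdefault(group, []).append(spec)
        return specs

    def to_dict(self) -> dict:
        d = {
            "design": asdict(self.design),
            "simulation": {
                **{k: v for k, v in asdict(self.simulation).items() if k != "coupling"},
                **(
                    {"coupling": [dict(c) for c in self.simulation.coupling]}
                    if self.simulation.coupling
                    else {}
                ),
            },
            "behavior": {
                "n_items": self.behavior.n_items,
                "noise": self.behavior.noise,
                "gompertz": {
                    g: asdict(p) for g, p in self.behavior.gompertz.items()
                },
            },
            "estimation": asdict(self.estimation),
            "inference": asdict(self.inference),
            "nodes": {"labels": list(self.node_labels)},
            "covariates": {
                "age_mean": dict(self.covariates.age_mean),
                "age_sd": dict(self.covariates.age_sd),
                "fsiq_mean": dict(self.covariates.fsiq_mean),
                "fsiq_sd": dict(self.covariates.fsiq_sd),
                "dosage_log_mean": self.covariates.dosage_log_mean,
                "dosage_log_sd": self.covariates.dosage_log_sd,
                **(
                    {"edge_links": [asdict(l) for l in self.covariates.edge_links]}
                    if self.covariates.edge_links
                    else {}
                ),
            },
            "output": {"dir": self.output_dir},
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            sim = dict(d.get("simulation", {}))
            coupling = tuple(sim.pop("coupling", ()))
            beh = dict(d.get("behavior", {}))
            gompertz = {
                g: GompertzGroupParams(**p)
                for g, p in beh.pop("gompertz", {}).items()
            } or BehaviorConfig().gompertz
            cov = dict(d.get("covariates", {}))
            links = tuple(EdgeLink(**l) for l in cov.pop("edge_links", ()))
            cov_model = (
                CovariateModel(**cov, edge_links=links) if cov or links else CovariateModel()
            )
            return cls(
                design=DesignConfig(**d.get("design", {})),
                simulation=SimulationConfig(**sim, coupling=coupling),
                behavior=BehaviorConfig(**beh, gompertz=gompertz),
                estimation=EstimationConfig(**d.get("estimation", {})),
                inference=InferenceConfig(**d.get("inference", {})),
                node_labels=tuple(d.get("nodes", {}).get("labels", DEFAULT_NODE_LABELS)),
                covariates=cov_model,
                output_dir=d.get("output", {}).get("dir", "dfclearn_out"),
            )
        except TypeError as e:
            raise ConfigError(f"invalid configuration: {e}") from e

    def dump(self, path: str | Path | None = None) -> str:
        return dump_toml(self.to_dict(), path)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a TOML config file."""
    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    except FileNotFoundError as e:
        raise ConfigError(f"config file not found: {path}") from e
    except tomllib.TOMLDecodeError as e:
        raise ConfigError(f"malformed TOML in {path}: {e}") from e
    return PipelineConfig.from_dict(data)
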