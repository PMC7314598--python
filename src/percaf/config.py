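"""YAML run configuration: schema validation, defaults, round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .dynamics import SimConfig
from .fiber_network import LatticeSpec

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """A configuration file failed schema validation."""


_LATTICE_KEYS = {"L_x", "L_y", "L_z"}
_PROFILE_KEYS = {"mode", "nu_par", "nu_perp", "nu_bar", "theta_endo", "theta_epi"}
_DYNAMICS_KEYS = {
    "T",
    "tau",
    "eps",
    "delta",
    "n_steps",
    "burn_in",
    "dynamics_seed",
    "stop_at_circuits",
    "snapshot_times",
}
_DETECTION_KEYS = {"af_alpha", "af_window"}
_SEED_KEYS = {"structure_seed", "block_seed"}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a single simulation run."""

    spec: LatticeSpec
    profile: dict
    sim: SimConfig
    structure_seed: int = 0
    block_seed: int = 1

    def to_dict(self) -> dict:
        sim = asdict(self.sim)
        snapshot_times = list(sim.pop("snapshot_times"))
        af_alpha = sim.pop("af_alpha")
        af_window = sim.pop("af_window")
        sim.pop("max_circuits")
        if snapshot_times:
            sim["snapshot_times"] = snapshot_times
        return {
            "lattice": {"L_x": self.spec.L_x, "L_y": self.spec.L_y, "L_z": self.spec.L_z},
            "profile": dict(self.profile),
            "dynamics": sim,
            "detection": {"af_alpha": af_alpha, "af_window": af_window},
            "seeds": {
                "structure_seed": self.structure_seed,
                "block_seed": self.block_seed,
            },
        }


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section '{section}': {', '.join(sorted(unknown))}"
        )


def _from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("top level of the config must be a mapping")
    _check_keys(
        "<top>", data, {"lattice", "profile", "dynamics", "detection", "seeds"}
    )
    lat = data.get("lattice") or {}
    _check_keys("lattice", lat, _LATTICE_KEYS)
    try:
        spec = LatticeSpec(
            L_x=int(lat.get("L_x", 200)),
            L_y=int(lat.get("L_y", 200)),
            L_z=int(lat.get("L_z", 25)),
        )
    except ValueError as e:
        raise ConfigError(f"lattice: {e}") from e

    prof = dict(data.get("profile") or {})
    _check_keys("profile", prof, _PROFILE_KEYS)
    prof.setdefault("mode", "inhomogeneous")
    if prof["mode"] == "inhomogeneous":
        prof.setdefault("nu_bar", 0.33)
        prof.setdefault("theta_endo", 24.0)
        prof.setdefault("theta_epi", 42.0)
    elif prof["mode"] == "homogeneous":
        if "nu_par" not in prof or "nu_perp" not in prof:
            raise ConfigError("profile: homogeneous mode requires nu_par and nu_perp")
    else:
        raise ConfigError(f"profile: unknown mode {prof['mode']!r}")

    dyn = data.get("dynamics") or {}
    _check_keys("dynamics", dyn, _DYNAMICS_KEYS)
    det = data.get("detection") or {}
    _check_keys("detection", det, _DETECTION_KEYS)
    seeds = data.get("seeds") or {}
    _check_keys("seeds", seeds, _SEED_KEYS)
    try:
        sim = SimConfig(
            T=int(dyn.get("T", 220)),
            tau=int(dyn.get("tau", 50)),
            eps=float(dyn.get("eps", 0.05)),
            delta=float(dyn.get("delta", 0.05)),
            n_steps=int(dyn.get("n_steps", 22000)),
            burn_in=int(dyn.get("burn_in", 0)),
            dynamics_seed=int(dyn.get("dynamics_seed", 2)),
            stop_at_circuits=int(dyn.get("stop_at_circuits", 0)),
            snapshot_times=tuple(int(t) for t in dyn.get("snapshot_times", ())),
            af_alpha=float(det.get("af_alpha", 1.1)),
            af_window=None if det.get("af_window") is None else int(det["af_window"]),
        )
    except ValueError as e:
        raise ConfigError(f"dynamics: {e}") from e
    return RunConfig(
        spec=spec,
        profile=prof,
        sim=sim,
        structure_seed=int(seeds.get("structure_seed", 0)),
        block_seed=int(seeds.get("block_seed", 1)),
    )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML config; absent sections fall back to the
    standard parameters (200 x 200 x 25, T = 220, tau = 50)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    data = yaml.safe_load(p.read_text()) or {}
    return _from_dict(data)


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
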