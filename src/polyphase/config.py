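"""Run configuration: a validated YAML key/value schema that round-trips
losslessly and expands into system specs, engine parameters, interaction
tables and ladders."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .builder import default_chain_roles, three_bead_roles
from .model import (
    BeadRole,
    ChainSpec,
    EngineParams,
    InteractionTable,
    SystemSpec,
    build_interaction_table,
)

__all__ = ["ConfigError", "RunConfig", "read_config", "write_config"]


class ConfigError(ValueError):
    """Schema violation; the message names the offending field."""


@dataclass
class RunConfig:
    # system
    system_kind: str = "default"  # default | system1 | system2 | three_bead
    n_chains: int = 2
    chain_length: int = 80
    patch_len: int = 7
    roles: str | None = None  # run-length override, e.g. "36B-7R-37B"
    n_frac: float | None = None  # percent, three_bead only
    concentration: float | None = 200e-6  # mol/L
    box_edge: float | None = None  # Å; overrides concentration if set
    # interactions (k_B T at T_ref)
    eps_sp: float = 1.2
    eps_ns: float = 0.5
    T_ref: float = 310.0
    # engine
    engine: EngineParams = field(default_factory=EngineParams)
    # run
    n_steps: int = 100_000
    report_every: int = 1_000
    seed: int = 0
    # optional replica-exchange ladder
    ladder_t_min: float | None = None
    ladder_t_max: float | None = None
    ladder_dt: float | None = None
    swap_interval: float = 500400.0  # fs (16680 x 30 fs steps, ~0.5 ns)
    # analysis switches
    analyze_contacts: bool = True
    analyze_kinetics: bool = False
    analyze_shells: bool = False
    cutoff_sigma: float = 2.5  # contact cutoff in units of σ
    # output
    output_dir: str = "."

    # -------------------------------------------------- construction

    _SCHEMA = {
        "system": {
            "kind": "system_kind",
            "n_chains": "n_chains",
            "chain_length": "chain_length",
            "patch_len": "patch_len",
            "roles": "roles",
            "n_frac": "n_frac",
            "concentration": "concentration",
            "box_edge": "box_edge",
        },
        "interactions": {
            "eps_sp": "eps_sp",
            "eps_ns": "eps_ns",
            "T_ref": "T_ref",
        },
        "engine": {
            "k_s": None,
            "r0": None,
            "kappa": None,
            "sigma": None,
            "dt": None,
            "T": None,
            "damping_time": None,
            "bead_mass": None,
        },
        "run": {
            "n_steps": "n_steps",
            "report_every": "report_every",
            "seed": "seed",
        },
        "ladder": {
            "t_min": "ladder_t_min",
            "t_max": "ladder_t_max",
            "dt": "ladder_dt",
            "swap_interval": "swap_interval",
        },
        "analysis": {
            "contacts": "analyze_contacts",
            "kinetics": "analyze_kinetics",
            "shells": "analyze_shells",
            "cutoff_sigma": "cutoff_sigma",
        },
        "output": {"dir": "output_dir"},
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        kwargs: dict = {}
        engine_kwargs: dict = {}
        for section, content in data.items():
            if section not in cls._SCHEMA:
                raise ConfigError(f"unknown config section: {section!r}")
            if content is None:
                continue
            if not isinstance(content, dict):
                raise ConfigError(f"config section {section!r} must be a mapping")
            for key, value in content.items():
                if key not in cls._SCHEMA[section]:
                    raise ConfigError(f"unknown config key: {section}.{key}")
                if section == "engine":
                    engine_kwargs[key] = value
                else:
                    kwargs[cls._SCHEMA[section][key]] = value
        try:
            engine = EngineParams(**engine_kwargs)
        except ValueError as exc:
            raise ConfigError(f"engine: {exc}") from exc
        cfg = cls(engine=engine, **kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.system_kind not in ("default", "system1", "system2", "three_bead"):
            raise ConfigError(f"system.kind: unknown kind {self.system_kind!r}")
        if self.n_chains < 1:
            raise ConfigError("system.n_chains must be >= 1")
        if self.patch_len > self.chain_length:
            raise ConfigError("system.patch_len cannot exceed system.chain_length")
        if self.system_kind == "three_bead" and self.n_frac is None:
            raise ConfigError("system.n_frac is required for the three_bead kind")
        if self.box_edge is None and self.concentration is None:
            raise ConfigError("system needs either box_edge or concentration")
        if not self.eps_sp > self.eps_ns:
            raise ConfigError(
                "interactions: eps_sp must exceed eps_ns "
                f"(got eps_sp={self.eps_sp}, eps_ns={self.eps_ns})"
            )
        if self.n_steps < 1:
            raise ConfigError("run.n_steps must be >= 1")
        if self.report_every < 1:
            raise ConfigError("run.report_every must be >= 1")
        ladder_bits = (self.ladder_t_min, self.ladder_t_max, self.ladder_dt)
        if any(b is not None for b in ladder_bits) and None in ladder_bits:
            raise ConfigError("ladder requires t_min, t_max and dt together")

    def to_dict(self) -> dict:
        data: dict = {}
        for section, mapping in self._SCHEMA.items():
            content = {}
            for key, attr in mapping.items():
                if section == "engine":
                    content[key] = getattr(self.engine, key)
                else:
                    content[key] = getattr(self, attr)
            data[section] = content
        return data

    # ------------------------------------------------------ expansion

    def chain_spec(self) -> ChainSpec:
        if self.roles is not None:
            return ChainSpec.from_role_string(self.roles, n_frac=self.n_frac)
        if self.system_kind == "three_bead":
            roles = three_bead_roles(
                self.chain_length, self.patch_len, self.n_frac, seed=self.seed
            )
            return ChainSpec(roles=roles, n_frac=self.n_frac)
        return ChainSpec(roles=default_chain_roles(self.chain_length, self.patch_len))

    def system_spec(self) -> SystemSpec:
        type1 = self.chain_spec()
        if self.system_kind in ("system1", "system2"):
            partner_role = (
                BeadRole.INERT if self.system_kind == "system1" else BeadRole.ALT_NONSPECIFIC
            )
            partner = ChainSpec(
                roles=tuple(
                    r if r == BeadRole.SPECIFIC else partner_role for r in type1.roles
                )
            )
            half = self.n_chains // 2
            chains = ((type1, self.n_chains - half), (partner, half))
        else:
            chains = ((type1, self.n_chains),)
        kwargs = (
            {"box_edge": self.box_edge}
            if self.box_edge is not None
            else {"concentration": self.concentration}
        )
        return SystemSpec(chains=chains, seed=self.seed, **kwargs)

    def interaction_table(self) -> InteractionTable:
        kind = self.system_kind if self.system_kind in ("system1", "system2") else "default"
        return build_interaction_table(self.eps_sp, self.eps_ns, kind, T_ref=self.T_ref)

    def ladder(self):
        from .remd import temperature_ladder

        if self.ladder_t_min is None:
            return None
        return temperature_ladder(
            self.ladder_t_min,
            self.ladder_dt,
            self.ladder_t_max,
            swap_interval=self.swap_interval,
            seed=self.seed,
        )

    @property
    def cutoff(self) -> float:
        """Contact cutoff in Å."""
        return self.cutoff_sigma * self.engine.sigma


def read_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
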