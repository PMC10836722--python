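"""Pipeline configuration: flat key=value sections, one per stage.

The config file format is INI-style (stdlib ``configparser``): every
parameter has a documented default below, and unknown sections or keys are
rejected rather than ignored.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field

from .errors import ParameterError

DEFAULTS: dict[str, dict[str, float | int | str]] = {
    "simulate": {
        "n_clonotypes": 1000,
        "abundance_exponent": 1.2,
        "n_responders": 20,
        "expansion_fold": 10.0,
        "n_convergent_groups": 2,
        "convergent_group_size": 3,
        "dual_alpha_rate": 0.1,
        "noise_sd": 0.3,
        "depth": 100000,
    },
    "expansion": {
        "min_log2_ratio": 1.0,
        "min_freq": 1e-4,
        "top_n": 100,
    },
    "convergence": {
        "min_read_support": 2,
        "min_umi_support": 2,
    },
    "segments": {
        "min_match": 5,
        "central_fraction": 1.0 / 3.0,
    },
    "reactivity": {
        "min_gfp": 3.0,
        "min_ha": 20.0,
        "max_wt_gfp": 2.0,
    },
    "hla": {
        "min_pct": 10.0,
        "panel_lines": 20,
        "panel_noise": 0.05,
    },
    "bcr": {
        "min_junction_identity": 0.85,
        "shm_rate": 0.02,
        "lineage_sizes": "10,1,1,1,1,1",
    },
}


@dataclass
class PipelineConfig:
    """Typed view over the per-stage parameter sections, plus the global seed."""

    seed: int = 0
    sections: dict[str, dict] = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULTS.items()})

    def get(self, section: str, key: str):
        return self.sections[section][key]

    @classmethod
    def from_file(cls, path, seed: int | None = None) -> "PipelineConfig":
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise ParameterError(f"config file {path} not found or unreadable")
        config = cls()
        for section in parser.sections():
            if section == "global":
                for key, value in parser.items(section):
                    if key != "seed":
                        raise ParameterError(f"unknown key {key!r} in [global]")
                    config.seed = int(value)
                continue
            if section not in DEFAULTS:
                raise ParameterError(f"unknown config section [{section}]")
            for key, value in parser.items(section):
                if key not in DEFAULTS[section]:
                    raise ParameterError(f"unknown key {key!r} in [{section}]")
                default = DEFAULTS[section][key]
                caster = type(default)
                config.sections[section][key] = caster(value)
        if seed is not None:
            config.seed = seed
        return config

    def write(self, path) -> None:
        parser = configparser.ConfigParser()
        parser["global"] = {"seed": str(self.seed)}
        for section, values in self.sections.items():
            parser[section] = {k: str(v) for k, v in values.items()}
        with open(path, "w") as handle:
            parser.write(handle)
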