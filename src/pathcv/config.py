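"""Run configuration and manifests.

One YAML document configures a whole run: the system, the CV
definitions, per-stage parameters, seeds and the output directory.
Unknown keys are rejected with an error naming the key, every stochastic
stage requires a seed (a global ``seed`` suffices), and the effective
configuration — defaults included — is logged at run start.  At the end
of a run a :class:`RunManifest` is written atomically; it records the
package version, a hash of the effective configuration, the seeds and
the per-stage output files, which is sufficient to re-execute the run
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from .errors import SpecError

__all__ = ["RunConfig", "RunManifest", "load_config"]

log = logging.getLogger("pathcv")

_TOP_KEYS = {
    "seed", "output_dir", "log_level", "stages", "system", "cvs",
    "synth", "zts", "string", "metad", "fes", "cluster", "network",
    "classify", "density", "rmsf", "drive",
}
_STOCHASTIC_STAGES = {"synth", "string", "metad", "rmsf"}

_STAGE_KEYS = {
    "system": {"kind", "params", "temperature", "friction", "timestep", "mass", "seed"},
    "synth": {"n_beads", "n_frames", "noise_amplitude", "basin_depths", "seed",
              "bond_length", "strand_gap"},
    "zts": {"descent_steps", "iterations", "start_images", "final_images",
            "extract_count", "extract_start", "middle_extra", "descent_step",
            "endpoints"},
    "string": {"force_constant", "friction", "mass", "dt", "stride", "max_updates",
               "burn_in", "conv_window", "conv_tolerance", "pmf_steps",
               "pmf_burn_in", "fixed_endpoints", "seed", "reparam_every"},
    "metad": {"height", "sigma", "stride", "bias_temperature", "temperature",
              "n_walkers", "n_steps", "seed", "grid_min", "grid_max",
              "grid_spacing", "convention", "system"},
    "fes": {"grid_min", "grid_max", "grid_spacing", "hills_file"},
    "cluster": {"threshold", "superpose", "input"},
    "network": {"link_threshold", "mode"},
    "classify": {"rules", "default"},
    "density": {"bins", "contour_interval"},
    "rmsf": {"mode", "n_steps", "seed", "superpose"},
    "drive": {"targets", "force_constant", "n_targets", "rc_pairs",
              "max_iterations", "gradient_tolerance"},
}


@dataclass
class RunConfig:
    """Validated run configuration."""

    raw: dict
    path: str | None = None

    def __post_init__(self):
        unknown = set(self.raw) - _TOP_KEYS
        if unknown:
            raise SpecError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        for stage, keys in _STAGE_KEYS.items():
            section = self.raw.get(stage)
            if section is None:
                continue
            if not isinstance(section, dict):
                raise SpecError(f"config section {stage!r} must be a mapping")
            bad = set(section) - keys
            if bad:
                raise SpecError(
                    f"unknown key(s) in section {stage!r}: {', '.join(sorted(bad))}"
                )
        for stage in self.raw.get("stages", []):
            if stage in _STOCHASTIC_STAGES and self.seed_for(stage) is None:
                raise SpecError(f"stochastic stage {stage!r} requires a seed "
                                "(set a global 'seed' or a per-stage one)")

    @property
    def seed(self):
        return self.raw.get("seed")

    @property
    def output_dir(self) -> str:
        return str(self.raw.get("output_dir", "pathcv_out"))

    @property
    def stages(self) -> list:
        return list(self.raw.get("stages", []))

    def seed_for(self, stage: str):
        section = self.raw.get(stage) or {}
        return section.get("seed", self.raw.get("seed"))

    def section(self, stage: str) -> dict:
        return dict(self.raw.get(stage) or {})

    def require(self, stage: str, key: str):
        section = self.raw.get(stage) or {}
        if key not in section:
            raise SpecError(f"missing required config key {stage}.{key}")
        return section[key]

    def digest(self) -> str:
        canonical = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()

    def log_effective(self):
        log.info("effective configuration: %s",
                 json.dumps(self.raw, sort_keys=True, default=str))


def load_config(path) -> RunConfig:
    if not os.path.exists(path):
        raise SpecError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SpecError(f"{path}: config must be a YAML mapping")
    return RunConfig(raw=raw, path=str(path))


@dataclass
class RunManifest:
    """Record of a completed run, written atomically as JSON."""

    config_digest: str
    seeds: dict
    outputs: dict = field(default_factory=dict)
    version: str = __version__

    def add_output(self, stage: str, path: str):
        self.outputs.setdefault(stage, []).append(str(path))

    def checksums(self) -> dict:
        sums = {}
        for paths in self.outputs.values():
            for p in paths:
                if os.path.exists(p):
                    with open(p, "rb") as fh:
                        sums[p] = hashlib.sha256(fh.read()).hexdigest()
        return sums

    def write(self, path):
        payload = {
            "version": self.version,
            "config_digest": self.config_digest,
            "seeds": self.seeds,
            "outputs": self.outputs,
            "checksums": self.checksums(),
        }
        tmp = f"{path}.tmp"
        with open(tmp, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        os.replace(tmp, path)

    @classmethod
    def read(cls, path) -> dict:
        with open(path) as fh:
            return json.load(fh)
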