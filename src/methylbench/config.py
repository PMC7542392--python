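"""YAML run configuration shared by the command-line entry points.

A run config ties together a simulated (or provided) genome, one or two
conversion protocols, the truth-methylome rules and the DMR thresholds, with
a single top-level seed feeding every stage.  Validation collects *all*
violations before raising so a bad config fails with one complete message.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .simulate import LevelRule, MethylationParams, ProtocolParams
from .dmr import (
    DEFAULT_MIN_COV,
    DEFAULT_MIN_SITES,
    DEFAULT_P_MAX,
    DEFAULT_STEP,
    DEFAULT_WINDOW,
    DIFF_PRESETS,
)

GENOME_DEFAULTS = dict(
    n_nuclear_contigs=2,
    contig_length=150_000,
    pericentromere_fraction=0.3,
    gene_density=0.35,
    te_density=0.5,
    gc_gradient=0.07,
    organelle_length=30_000,
)

PROTOCOL_PRESETS = {
    "emseq": ProtocolParams.emseq_preset,
    "wgbs": ProtocolParams.wgbs_preset,
}


@dataclass
class DmrConfig:
    preset: str = "protocol_compare"
    p_max: float = DEFAULT_P_MAX
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP
    min_sites: int = DEFAULT_MIN_SITES
    min_cov: int = DEFAULT_MIN_COV


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "methylbench_out"
    genome: dict = field(default_factory=lambda: dict(GENOME_DEFAULTS))
    methylome: str | dict = "arabidopsis_like"
    protocols: dict = field(
        default_factory=lambda: {"a": {"preset": "emseq"}, "b": {"preset": "wgbs"}}
    )
    dmr: DmrConfig = field(default_factory=DmrConfig)
    organelle_contigs: list[str] = field(default_factory=lambda: ["organelle"])
    log_level: str = "INFO"

    def protocol_params(self, label: str, seed_offset: int = 0) -> ProtocolParams:
        block = dict(self.protocols[label])
        preset = block.pop("preset", None)
        block.setdefault("seed", self.seed + seed_offset)
        if preset is not None:
            if preset not in PROTOCOL_PRESETS:
                raise ConfigurationError(f"unknown protocol preset {preset!r}")
            return PROTOCOL_PRESETS[preset](**block)
        return ProtocolParams(**block)

    def methylation_params(self) -> MethylationParams:
        if self.methylome == "arabidopsis_like":
            return MethylationParams.arabidopsis_like()
        if isinstance(self.methylome, dict):
            rules = {
                comp: {ctx: _rule_from_spec(spec) for ctx, spec in by_ctx.items()}
                for comp, by_ctx in self.methylome.items()
            }
            return MethylationParams(rules=rules)
        raise ConfigurationError(f"unknown methylome spec {self.methylome!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _rule_from_spec(spec) -> LevelRule:
    if isinstance(spec, (int, float)):
        return LevelRule.fixed(float(spec))
    if isinstance(spec, dict):
        return LevelRule.bimodal(
            float(spec["frac_high"]), float(spec["level_high"]), float(spec["level_low"])
        )
    raise ConfigurationError(f"bad methylation rule spec {spec!r}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    problems: list[str] = []
    known = {
        "seed",
        "output_dir",
        "genome",
        "methylome",
        "protocols",
        "dmr",
        "organelle_contigs",
        "log_level",
    }
    for key in raw:
        if key not in known:
            problems.append(f"unknown config key {key!r}")
    genome = dict(GENOME_DEFAULTS)
    genome.update(raw.get("genome", {}) or {})
    for key in genome:
        if key not in GENOME_DEFAULTS and key not in ("seed", "base_gc"):
            problems.append(f"unknown genome key {key!r}")
    dmr_raw = raw.get("dmr", {}) or {}
    dmr_cfg = DmrConfig()
    for key, val in dmr_raw.items():
        if not hasattr(dmr_cfg, key):
            problems.append(f"unknown dmr key {key!r}")
        else:
            setattr(dmr_cfg, key, val)
    if dmr_cfg.preset not in DIFF_PRESETS:
        problems.append(f"unknown dmr preset {dmr_cfg.preset!r}")
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "methylbench_out")),
        genome=genome,
        methylome=raw.get("methylome", "arabidopsis_like"),
        protocols=raw.get("protocols", RunConfig().protocols),
        dmr=dmr_cfg,
        organelle_contigs=list(raw.get("organelle_contigs", ["organelle"])),
        log_level=str(raw.get("log_level", "INFO")),
    )
    # validate protocol blocks eagerly so all violations surface together
    for label in cfg.protocols:
        try:
            cfg.protocol_params(label)
        except (ConfigurationError, TypeError) as exc:
            problems.append(f"protocol {label!r}: {exc}")
    try:
        cfg.methylation_params()
    except ConfigurationError as exc:
        problems.append(f"methylome: {exc}")
    if problems:
        raise ConfigurationError("invalid configuration:\n  " + "\n  ".join(problems))
    return cfg
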