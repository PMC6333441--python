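"""Run configuration: YAML schema, validation, and system assembly.

A run configuration collects everything a simulation needs — morphology
(generator parameters or an SWC file), passive and channel biophysics,
synapse/release parameters and the protocol block — plus the seed.  Every
output artifact records the configuration hash and seed so a run can be
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from piriform.biophysics import ChannelSet, PassiveParams
from piriform.engine import CompartmentalSystem
from piriform.morphology import (
    DEFAULT_MAX_SEG_LEN,
    GeneratorParams,
    discretize,
    generate_synthetic_morphology,
    read_swc,
)

__all__ = ["ConfigError", "RunConfig", "load_config", "build_system", "config_hash"]


class ConfigError(ValueError):
    """Schema violation; the message names the offending keys."""


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    dt: float = 0.025  # ms
    output_dir: str = "piriform_out"
    swc_path: str | None = None
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    max_seg_len: float = DEFAULT_MAX_SEG_LEN
    passive: PassiveParams = field(default_factory=PassiveParams)
    channels: ChannelSet = field(default_factory=ChannelSet.passive)
    lot_band_start: float = 250.0
    excitatory_scale: float | None = None  # None = run the unitary calibration
    g_unit_per_vesicle: bool = False
    ohmic_nmda: bool = False
    protocol: dict = field(default_factory=dict)


def _coerce_block(cls, block: dict, where: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    bad = sorted(set(block) - valid)
    if bad:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(bad)}")
    for key in ("total_length_range", "diam_by_order", "level_weights", "branching"):
        if key in block and isinstance(block[key], list):
            block[key] = tuple(block[key])
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {where} block: {exc}") from None


_TOP_KEYS = {
    "seed", "dt", "output_dir", "morphology", "biophysics", "synapses",
    "protocol", "ohmic_nmda",
}


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    bad = sorted(set(raw) - _TOP_KEYS)
    if bad:
        raise ConfigError(f"unknown top-level key(s): {', '.join(bad)}")

    morph = dict(raw.get("morphology") or {})
    bio = dict(raw.get("biophysics") or {})
    syn = dict(raw.get("synapses") or {})

    swc_path = morph.pop("swc_path", None)
    max_seg_len = morph.pop("max_seg_len", DEFAULT_MAX_SEG_LEN)
    lot_band_start = morph.pop("lot_band_start", 250.0)
    gen = _coerce_block(GeneratorParams, morph.pop("generator", {}) or {}, "morphology.generator")
    if morph:
        raise ConfigError(
            f"unknown key(s) in morphology: {', '.join(sorted(morph))}"
        )

    ch_block = bio.pop("channels", {}) or {}
    ch_passive = ch_block.pop("passive", True)
    channels = (
        ChannelSet.passive() if ch_passive and not ch_block
        else _coerce_block(ChannelSet, ch_block, "biophysics.channels")
    )
    passive = _coerce_block(PassiveParams, bio, "biophysics")

    known_syn = {"excitatory_scale", "g_unit_per_vesicle"}
    bad = sorted(set(syn) - known_syn)
    if bad:
        raise ConfigError(f"unknown key(s) in synapses: {', '.join(bad)}")

    return RunConfig(
        seed=int(raw.get("seed", 0)),
        dt=float(raw.get("dt", 0.025)),
        output_dir=str(raw.get("output_dir", "piriform_out")),
        swc_path=swc_path,
        generator=gen,
        max_seg_len=float(max_seg_len),
        passive=passive,
        channels=channels,
        lot_band_start=float(lot_band_start),
        excitatory_scale=syn.get("excitatory_scale"),
        g_unit_per_vesicle=bool(syn.get("g_unit_per_vesicle", False)),
        ohmic_nmda=bool(raw.get("ohmic_nmda", False)),
        protocol=dict(raw.get("protocol") or {}),
    )


def build_system(cfg: RunConfig) -> CompartmentalSystem:
    """Morphology → grid → empty compartmental system per the configuration."""
    if cfg.swc_path:
        morph = read_swc(cfg.swc_path)
    else:
        morph = generate_synthetic_morphology(cfg.generator, seed=cfg.seed)
    grid = discretize(morph, cfg.max_seg_len)
    return CompartmentalSystem(
        grid=grid,
        passive=cfg.passive,
        channels=cfg.channels,
        ohmic_nmda=cfg.ohmic_nmda,
        g_unit_per_vesicle=cfg.g_unit_per_vesicle,
    )


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration."""
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [enc(x) for x in obj]
        return obj

    blob = json.dumps(enc(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
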