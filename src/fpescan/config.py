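"""Plain-text (key = value) configuration for presets and scenarios.

The shipped ``data/presets.cfg`` is the declarative counterpart of the
in-code presets: every acceptance-relevant scenario (model calibration,
headline power cohort, discovery cohort shape) is expressible and diffable
as configuration.  User config files use the same INI dialect.
"""

from __future__ import annotations

import configparser
from importlib import resources

from .model import (
    FpeModelParams,
    attenuated_conditions,
    calibrated_conditions,
    ideal_conditions,
)

__all__ = ["load_config", "preset_from_config", "default_config"]


def default_config() -> configparser.ConfigParser:
    """The shipped presets/constants configuration."""
    cfg = configparser.ConfigParser()
    with resources.files("fpescan.data").joinpath("presets.cfg").open() as fh:
        cfg.read_file(fh)
    return cfg


def load_config(path) -> configparser.ConfigParser:
    """Read a key = value config file (INI sections)."""
    cfg = configparser.ConfigParser()
    with open(path) as fh:
        cfg.read_file(fh)
    return cfg


def preset_from_config(cfg: configparser.ConfigParser, name: str) -> FpeModelParams:
    """Build model parameters from a config section.

    The ``derivation`` key selects how the allele frequency and efficacy
    are fixed: ``ideal`` (full attribution, complete protection),
    ``attenuated`` (ideal-frequency allele, efficacy scaled to the
    attributed share) or ``calibrated`` (3%-failure contrast behind the
    predicted case/control row).
    """
    if name not in cfg:
        raise KeyError(f"no preset section [{name}] in config")
    sec = cfg[name]
    ratio = sec.getfloat("sex_bias_ratio")
    derivation = sec.get("derivation", "ideal")
    if derivation == "ideal":
        return ideal_conditions(ratio)
    if derivation == "attenuated":
        return attenuated_conditions(ratio, sec.getfloat("fpe_share", 0.5))
    if derivation == "calibrated":
        return calibrated_conditions(
            ratio, sec.getfloat("affected_risk_share", 0.97)
        )
    raise ValueError(f"unknown derivation {derivation!r} in [{name}]")
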