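"""YAML configuration: one file carries matching thresholds, ensemble
settings and simulator parameters.

Documented keys (all optional; defaults in parentheses):

* ``min_reciprocal_overlap`` (0.5) — deletion reciprocal-overlap threshold
* ``ins_delta`` (500) — insertion breakpoint distance in bp
* ``require_same_type`` (true), ``strict_overlap`` (false)
* ``min_callers`` (2) — corroboration threshold of the generalized ensemble
* ``min_support`` (2) — read-support filter for call sets
* ``min_sv_len`` (200) — benchmark / truth-set size floor in bp
* ``simulator:`` — mapping with ``chrom_sizes``, ``n_del``, ``n_ins``,
  ``del_len_median``, ``del_len_sigma``, ``ins_len_median``,
  ``ins_len_sigma``, ``allele_fraction``, ``min_gap``, ``seed``,
  ``coverage``, ``coverages``, ``replicates`` and a ``callers`` list of
  profile mappings (``label``, ``min_support``, ``breakpoint_sd``,
  ``fp_rate``, ``type_bias``).
"""

from __future__ import annotations

from typing import List, Mapping, Optional

import yaml

from .errors import ValidationError
from .model import MatchConfig
from .simulator import CallerProfile, LengthDist, SimConfig, default_profiles


def load_config(path) -> dict:
    """Load a YAML config file; an empty file yields an empty mapping."""
    with open(path, "rt") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ValidationError(f"config {path} must be a key-value mapping")
    return dict(data)


def match_config_from(cfg: Mapping) -> MatchConfig:
    return MatchConfig(
        min_reciprocal_overlap=float(cfg.get("min_reciprocal_overlap", 0.5)),
        ins_delta=int(cfg.get("ins_delta", 500)),
        require_same_type=bool(cfg.get("require_same_type", True)),
        strict_overlap=bool(cfg.get("strict_overlap", False)),
    )


def sim_config_from(cfg: Mapping, seed: Optional[int] = None) -> SimConfig:
    sim = cfg.get("simulator", {}) or {}
    kwargs = {}
    if "chrom_sizes" in sim:
        kwargs["chrom_sizes"] = {str(k): int(v) for k, v in sim["chrom_sizes"].items()}
    for key in ("n_del", "n_ins", "min_gap", "seed"):
        if key in sim:
            kwargs[key] = int(sim[key])
    if "allele_fraction" in sim:
        kwargs["allele_fraction"] = float(sim["allele_fraction"])
    if "sample" in sim:
        kwargs["sample"] = str(sim["sample"])
    if "del_len_median" in sim or "del_len_sigma" in sim:
        kwargs["del_len"] = LengthDist(float(sim.get("del_len_median", 500.0)),
                                       float(sim.get("del_len_sigma", 0.9)))
    if "ins_len_median" in sim or "ins_len_sigma" in sim:
        kwargs["ins_len"] = LengthDist(float(sim.get("ins_len_median", 400.0)),
                                       float(sim.get("ins_len_sigma", 0.8)))
    if seed is not None:
        kwargs["seed"] = int(seed)
    return SimConfig(**kwargs)


def profiles_from(cfg: Mapping) -> List[CallerProfile]:
    sim = cfg.get("simulator", {}) or {}
    specs = sim.get("callers")
    if not specs:
        return default_profiles()
    profiles = []
    for spec in specs:
        profiles.append(CallerProfile(
            label=str(spec["label"]),
            min_support=int(spec.get("min_support", 2)),
            breakpoint_sd=float(spec.get("breakpoint_sd", 20.0)),
            fp_rate=float(spec.get("fp_rate", 0.0)),
            type_bias={str(k): float(v)
                       for k, v in (spec.get("type_bias") or {}).items()},
        ))
    return profiles
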