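"""Flat ``KEY=VALUE`` configuration files.

Primer keys use Primer3's names (PRIMER_OPT_SIZE, PRIMER_MIN_TM,
PRIMER_PRODUCT_SIZE_RANGE, ...) so existing Primer3 settings files port
directly; scan thresholds use SSR_* keys. Lines starting with ``#`` and
blank lines are ignored; an unknown key is an error (silent typos in
threshold names would quietly change results).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, Tuple, Union

from ssrforge.errors import ConfigError
from ssrforge.primer_design import PrimerConstraints
from ssrforge.ssr_scanner import DEFAULT_MIN_LENGTHS, ScanConfig

# Primer3 key -> PrimerConstraints field (plain numeric keys)
_PRIMER_KEYS: Dict[str, Tuple[str, type]] = {
    "PRIMER_MIN_SIZE": ("size_min", int),
    "PRIMER_OPT_SIZE": ("size_opt", int),
    "PRIMER_MAX_SIZE": ("size_max", int),
    "PRIMER_MIN_TM": ("tm_min", float),
    "PRIMER_OPT_TM": ("tm_opt", float),
    "PRIMER_MAX_TM": ("tm_max", float),
    "PRIMER_MIN_GC": ("gc_min", float),
    "PRIMER_OPT_GC_PERCENT": ("gc_opt", float),
    "PRIMER_MAX_GC": ("gc_max", float),
    "PRIMER_MAX_POLY_X": ("max_poly_x", int),
    "PRIMER_MAX_SELF_ANY": ("max_self_any", int),
    "PRIMER_MAX_SELF_END": ("max_self_end", int),
    "PRIMER_PAIR_MAX_DIFF_TM": ("max_pair_tm_diff", float),
    "PRIMER_SALT_MONOVALENT": ("monovalent_mM", float),
    "PRIMER_DNA_CONC": ("oligo_nM", float),
    "PRIMER_NUM_RETURN": ("max_pairs_returned", int),
    "PRIMER_WT_SIZE": ("weight_size", float),
    "PRIMER_WT_TM": ("weight_tm", float),
    "PRIMER_WT_GC_PERCENT": ("weight_gc", float),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs: scan thresholds plus primer constraints."""

    scan: ScanConfig = field(default_factory=ScanConfig)
    primers: PrimerConstraints = field(default_factory=PrimerConstraints)
    motif_min: int = 1
    motif_max: int = 5


def _parse_lines(text: str, source: str) -> Dict[str, str]:
    kv: Dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{source}:{lineno}: expected KEY=VALUE, got {line!r}")
        key, value = line.split("=", 1)
        key = key.strip()
        if key in kv:
            raise ConfigError(f"{source}:{lineno}: duplicate key {key}")
        kv[key] = value.strip()
    return kv


def parse_config_text(text: str, source: str = "<config>") -> PipelineConfig:
    kv = _parse_lines(text, source)

    primer_updates: Dict[str, Union[int, float]] = {}
    min_lengths = dict(DEFAULT_MIN_LENGTHS)
    scan_masked = True
    motif_min, motif_max = 1, 5

    for key, value in kv.items():
        try:
            if key in _PRIMER_KEYS:
                attr, typ = _PRIMER_KEYS[key]
                primer_updates[attr] = typ(value)
            elif key == "PRIMER_PRODUCT_SIZE_RANGE":
                lo, hi = value.split("-")
                primer_updates["product_min"] = int(lo)
                primer_updates["product_max"] = int(hi)
            elif key.startswith("SSR_MIN_LENGTH_"):
                k = int(key.rsplit("_", 1)[1])
                min_lengths[k] = int(value)
            elif key == "SSR_MOTIF_MIN":
                motif_min = int(value)
            elif key == "SSR_MOTIF_MAX":
                motif_max = int(value)
            elif key == "SSR_SCAN_MASKED":
                scan_masked = value not in ("0", "false", "False", "no")
            else:
                raise ConfigError(f"{source}: unknown configuration key {key!r}")
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"{source}: bad value for {key}: {value!r} ({exc})")

    if not (1 <= motif_min <= motif_max):
        raise ConfigError(
            f"{source}: SSR_MOTIF_MIN/MAX must satisfy 1 <= min <= max, "
            f"got {motif_min}/{motif_max}"
        )
    min_lengths = {k: v for k, v in min_lengths.items()
                   if motif_min <= k <= motif_max}

    valid_attrs = {f.name for f in fields(PrimerConstraints)}
    assert set(a for a in primer_updates) <= valid_attrs
    return PipelineConfig(
        scan=ScanConfig(min_total_length_by_k=min_lengths, scan_masked=scan_masked),
        primers=replace(PrimerConstraints(), **primer_updates),
        motif_min=motif_min,
        motif_max=motif_max,
    )


def load_config(path: Union[str, Path, None]) -> PipelineConfig:
    """Load a configuration file; ``None`` yields all defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    return parse_config_text(path.read_text(), str(path))
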