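"""Run configuration: YAML loading, validation and defaults.

A config names the species set, the chain file of every species pair, the
projection/classification thresholds and a global seed::

    species: [mm, gg]
    chains:
      - {a: mm, b: gg, path: chains/mm.gg.chain}
    thresholds: {dc: 300, ic: 2500, max_hops: 4, min_block_size: 10,
                 window: 0, min_shared: 6}
    seed: 42

Paths are resolved relative to the config file.  Unknown keys are rejected;
absent thresholds default to dc=300, ic=2500, max_hops=4, min_shared=6.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from .core import ProjectionParams

_TOP_KEYS = {"species", "chains", "thresholds", "seed", "out_dir", "log_level"}
_THRESHOLD_KEYS = {"dc", "ic", "max_hops", "min_block_size", "window", "min_shared"}


class ConfigError(ValueError):
    """Raised for invalid or incomplete run configurations."""


@dataclass(frozen=True)
class RunConfig:
    species: Tuple[str, ...]
    chain_paths: Dict[Tuple[str, str], Path]
    params: ProjectionParams
    window: int = 0
    min_shared: int = 6
    seed: int = 0
    out_dir: Optional[Path] = None
    log_level: str = "INFO"

    def config_hash(self) -> str:
        """Stable short hash of the configuration (for output headers)."""
        parts = [
            ",".join(self.species),
            ";".join(
                f"{a}|{b}|{p.name}" for (a, b), p in sorted(self.chain_paths.items())
            ),
            f"{self.params.dc_threshold},{self.params.ic_threshold},"
            f"{self.params.max_hops},{self.params.min_block_size}",
            f"{self.window},{self.min_shared},{self.seed}",
        ]
        return hashlib.sha256("\n".join(parts).encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    species = raw.get("species")
    if not species or not isinstance(species, list):
        raise ConfigError(f"{path}: 'species' must be a nonempty list")
    if len(set(species)) != len(species):
        raise ConfigError(f"{path}: duplicate species ids")

    thresholds = raw.get("thresholds") or {}
    unknown = set(thresholds) - _THRESHOLD_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown threshold keys: {sorted(unknown)}")
    dc = int(thresholds.get("dc", 300))
    ic = int(thresholds.get("ic", 2500))
    if dc > ic:
        raise ConfigError(f"{path}: dc threshold ({dc}) exceeds ic threshold ({ic})")
    try:
        params = ProjectionParams(
            dc_threshold=dc,
            ic_threshold=ic,
            max_hops=int(thresholds.get("max_hops", 4)),
            min_block_size=int(thresholds.get("min_block_size", 10)),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc

    base = path.parent
    chain_paths: Dict[Tuple[str, str], Path] = {}
    for entry in raw.get("chains") or []:
        if not isinstance(entry, dict) or set(entry) != {"a", "b", "path"}:
            raise ConfigError(
                f"{path}: each chain entry needs exactly the keys a, b, path"
            )
        a, b = entry["a"], entry["b"]
        for sp in (a, b):
            if sp not in species:
                raise ConfigError(
                    f"{path}: chain pair ({a}, {b}) references unknown species {sp!r}"
                )
        cpath = Path(entry["path"])
        if not cpath.is_absolute():
            cpath = base / cpath
        if not cpath.exists():
            raise ConfigError(
                f"{path}: chain file for pair ({a}, {b}) not found: {cpath}"
            )
        chain_paths[(a, b)] = cpath

    out_dir = raw.get("out_dir")
    return RunConfig(
        species=tuple(species),
        chain_paths=chain_paths,
        params=params,
        window=int(thresholds.get("window", 0)),
        min_shared=int(thresholds.get("min_shared", 6)),
        seed=int(raw.get("seed", 0)),
        out_dir=Path(out_dir) if out_dir else None,
        log_level=str(raw.get("log_level", "INFO")),
    )


def load_indexes(config: RunConfig):
    """Build an AnchorIndex per configured chain file."""
    from .anchor_index import build_index
    from .chain_io import extract_anchor_blocks, read_chain

    indexes = {}
    for (a, b), cpath in config.chain_paths.items():
        anchors = []
        for chain in read_chain(cpath, a, b):
            anchors.extend(
                extract_anchor_blocks(chain, config.params.min_block_size)
            )
        indexes[(a, b)] = build_index(anchors)
    return indexes
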