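"""Run configuration: defaults, YAML loading with strict keys, serialization.

Defaults encode the pipeline's processing constants: 4-nt end trim, 23-nt
minimum read length after trimming, the 26-32 nt footprint window, MAPQ
cutoff 5, and 0.05 alphas for the ANOVA/BH and t-test gates. The resolved
configuration (defaults plus overrides) is serialized next to the outputs
of every run for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .annotation import AnnotationConfig, ConfigurationError
from .simulate import NEXTFLEX_ADAPTER, RiboseqParams, TmtParams


@dataclass
class TrimConfig:
    adapter: str = NEXTFLEX_ADAPTER
    end_trim: int = 4
    min_length: int = 23
    min_overlap: int = 3


@dataclass
class SizeSelectConfig:
    min_len: int = 26
    max_len: int = 32


@dataclass
class StatsConfig:
    occ_alpha: float = 0.05
    fdr_alpha: float = 0.05
    t_alpha: float = 0.05
    occupancy_mode: str = "raw"   # raw | cpm
    ttest: str = "welch"          # welch | student
    dunnett_method: str = "mvt"   # mvt | mc
    # upstream identification thresholds, recorded for provenance only
    peptide_probability: float = 0.99
    protein_probability: float = 0.93


@dataclass
class PathsConfig:
    annotation_fasta: str = ""
    cds_bed: str = ""
    contaminants_fasta: str = ""
    samples_tsv: str = ""
    peptides_tsv: str = ""
    plex_tsv: str = ""
    impurity_csv: str = ""
    mito_list_tsv: str = ""


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "mitoribo_run"
    n_replicates: int = 3
    mapq_min: int = 5
    kmer_size: int = 12
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    riboseq: RiboseqParams = field(default_factory=RiboseqParams)
    tmt: TmtParams = field(default_factory=TmtParams)
    trim: TrimConfig = field(default_factory=TrimConfig)
    size_select: SizeSelectConfig = field(default_factory=SizeSelectConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)


def _build(cls: type, data: dict[str, Any], context: str) -> Any:
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigurationError(
            f"unknown config key(s) under {context}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        current = known[name]
        if dataclasses.is_dataclass(_field_class(current)):
            if not isinstance(value, dict):
                raise ConfigurationError(f"{context}.{name} must be a mapping")
            kwargs[name] = _build(_field_class(current), value, f"{context}.{name}")
        else:
            if isinstance(value, list):
                value = tuple(value)
            kwargs[name] = value
    return cls(**kwargs)


def _field_class(f: dataclasses.Field) -> type | None:
    if f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
        made = f.default_factory()  # type: ignore[misc]
        if dataclasses.is_dataclass(made):
            return type(made)
    return None


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None) -> RunConfig:
    """Build a RunConfig from defaults + optional YAML + optional overrides.

    Unknown keys anywhere in the document are rejected.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("config file must contain a mapping")
        data.update(loaded)
    for key, value in (overrides or {}).items():
        data[key] = value
    return _build(RunConfig, data, "config")


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Serialize the fully resolved configuration (defaults + overrides)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)
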