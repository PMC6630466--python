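"""Run configuration: the filter cascade constants and input paths.

Serialized as flat ``key=value`` text; a copy is written into every
output directory so a run can be reproduced bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

from .association import DEFAULT_EXCLUDED_POPULATIONS
from .errors import InvalidInputError


@dataclass(frozen=True)
class RunConfig:
    # input paths
    mirna_fasta: str = ""
    utr_fasta: str = ""
    vcf: str = ""
    panel: str = ""
    latitude: str = ""
    expression: str = ""
    interactions: str = ""
    null_fst: str = ""
    # filter cascade
    target_site_types: tuple[str, ...] = ("8mer", "7mer-m8", "7mer-A1")
    expression_threshold: float = -1.0  # < 0 means "top 50% of the table"
    freq_lower: float = 0.01
    freq_upper: float = 0.99
    fst_estimator: str = "hudson"
    fst_threshold: float = 0.7
    pfst_threshold: float = 0.05
    excluded_populations: tuple[str, ...] = tuple(sorted(DEFAULT_EXCLUDED_POPULATIONS))
    # empirical-null settings when no genome-wide Fst file is supplied
    null_size: int = 999
    null_F: float = 0.15
    rng_seed: int = 0
    out_dir: str = "mirvar_out"

    def __post_init__(self):
        for name in ("fst_threshold", "pfst_threshold", "freq_lower", "freq_upper"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1], got {v}")
        if self.freq_lower >= self.freq_upper:
            raise InvalidInputError("frequency window lower bound must be < upper bound")


_TUPLE_FIELDS = {"target_site_types", "excluded_populations"}
_INT_FIELDS = {"null_size", "rng_seed"}
_FLOAT_FIELDS = {
    "expression_threshold", "freq_lower", "freq_upper",
    "fst_threshold", "pfst_threshold", "null_F",
}


def write_config(config: RunConfig, path: str | Path) -> None:
    lines = []
    for f in fields(config):
        value = getattr(config, f.name)
        if f.name in _TUPLE_FIELDS:
            value = ",".join(value)
        lines.append(f"{f.name}={value}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> RunConfig:
    known = {f.name for f in fields(RunConfig)}
    kwargs: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, value = line.partition("=")
        key = key.strip()
        if not sep or key not in known:
            raise InvalidInputError(f"{path}: bad config line {lineno}: {line!r}")
        value = value.strip()
        if key in _TUPLE_FIELDS:
            kwargs[key] = tuple(v for v in value.split(",") if v)
        elif key in _INT_FIELDS:
            kwargs[key] = int(value)
        elif key in _FLOAT_FIELDS:
            kwargs[key] = float(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def with_fixture_paths(config: RunConfig, paths: dict) -> RunConfig:
    """Point a config at the files emitted by the synthetic generator."""
    return replace(
        config,
        mirna_fasta=str(paths["mirnas"]),
        utr_fasta=str(paths["utrs"]),
        vcf=str(paths["vcf"]),
        panel=str(paths["panel"]),
        latitude=str(paths["latitude"]),
        expression=str(paths["expression"]),
        interactions=str(paths["interactions"]),
    )
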