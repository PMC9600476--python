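"""Run configuration: thresholds, inputs, and the resolved-config echo.

Thresholds default to the study conventions (detection prevalence 0.20,
core prevalence 0.50, MAF 0.05, call rate 0.90, heritable SE-ratio 2 with
p < 0.05, GWAS FDR tiers 0.01/0.05, network |rho| 0.2).  Configuration is
plain TOML; CLI flags override the file, the file overrides defaults, and
every run writes the resolved configuration next to its outputs.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .genomics import InputError

__all__ = ["Thresholds", "RunConfig"]


@dataclass
class Thresholds:
    detection_prevalence: float = 0.20
    core_prevalence: float = 0.50
    maf_min: float = 0.05
    call_rate_min: float = 0.90
    heritable_se_ratio: float = 2.0
    heritable_p: float = 0.05
    fdr_significant: float = 0.01
    fdr_suggestive: float = 0.05
    edge_rho: float = 0.2
    edge_p_adj: float = 0.05
    mantel_permutations: int = 9999


@dataclass
class RunConfig:
    """Inputs (paths or a simulation block), thresholds, seed, output dir."""

    out_dir: str = "results/run"
    seed: int = 0
    # either all three paths, or simulate=True with simulation settings
    genotype_path: str | None = None
    variant_map_path: str | None = None
    taxa_path: str | None = None
    phenotype_path: str | None = None
    simulate: bool = True
    n_individuals: int = 400
    n_snps: int = 2000
    n_taxa_per_h2: int = 20
    sim_h2_levels: list[float] = field(default_factory=lambda: [0.0, 0.3, 0.6])
    sim_m2: float = 0.30
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        thr = Thresholds(**raw.pop("thresholds", {}))
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(thresholds=thr, **raw)

    def to_toml_text(self) -> str:
        """Serialize the resolved configuration (echoed into every run dir)."""
        lines = []
        d = asdict(self)
        thr = d.pop("thresholds")
        for k, v in d.items():
            if v is None:
                continue
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
        lines.append("[thresholds]")
        for k, v in thr.items():
            lines.append(f"{k} = {_toml_value(v)}")
        return "\n".join(lines) + "\n"

    def validate(self) -> None:
        if not self.simulate:
            for name in ("genotype_path", "taxa_path", "phenotype_path"):
                if getattr(self, name) is None:
                    raise InputError(f"{name} required when simulate = false")


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, list):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    return repr(v)
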