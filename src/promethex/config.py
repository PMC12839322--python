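"""Analysis configuration.

All thresholds of the pipeline live in a single :class:`Config` object so a
run is a pure function of (inputs, config, seed).  Defaults follow the
published analysis: Δβ ≥ 0.2 and |log2FC| ≥ 1.3 for the integrated
differential step, β ≥ 0.3 for calling a CpG "methylated", |ρ| > 0.4 and
adjusted R² > 0.5 for the association scorers, α = 0.05 throughout, and the
external silencing definition (≥1% of samples methylated, mean z < −1.65,
FDR < 0.001).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


class ConfigError(ValueError):
    """Invalid configuration value or unknown key."""


@dataclass
class Config:
    #: minimum group-mean promoter Δβ for differential methylation
    delta_beta_min: float = 0.2
    #: minimum |log2 fold change| for differential expression
    abs_log2fc_min: float = 1.3
    #: beta at or above which a CpG counts as methylated (ratio metric)
    meth_cpg_beta_min: float = 0.3
    #: minimum |Spearman rho| for selection by the Spearman scorers
    spearman_abs_min: float = 0.4
    #: minimum adjusted R^2 for selection by the regression scorers
    adj_r2_min: float = 0.5
    #: significance level for adjusted (differential) and model p-values
    alpha: float = 0.05
    #: standardized CIMP-index at or above which a sample is CIMP-H
    cimp_index_hi: float = 0.5
    #: standardized CIMP-index at or below which a sample is Non-CIMP
    cimp_index_lo: float = -0.5
    #: minimum fraction of samples methylated for a probe silencing call
    silencing_sample_frac: float = 0.01
    #: maximum mean expression z-score of the methylated group (strictly below)
    silencing_z_max: float = -1.65
    #: FDR level for the silencing one-sided test
    silencing_alpha: float = 0.001
    #: seed for every stochastic component
    rng_seed: int = 0

    _PROB_FIELDS = (
        "meth_cpg_beta_min",
        "alpha",
        "silencing_sample_frac",
        "silencing_alpha",
    )

    def __post_init__(self) -> None:
        for name in self._PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1), got {v!r}")
        if not self.cimp_index_lo < self.cimp_index_hi:
            raise ConfigError(
                f"cimp_index_lo ({self.cimp_index_lo}) must be below "
                f"cimp_index_hi ({self.cimp_index_hi})"
            )

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in dataclasses.fields(cls)]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "Config":
        """Read ``key = value`` lines; ``#`` starts a comment; blank lines ok.

        Keyword arguments override file values (CLI precedence).
        """
        values: dict[str, object] = {}
        known = set(cls.field_names())
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = int(val) if key == "rng_seed" else float(val)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    def replace(self, **kw) -> "Config":
        return dataclasses.replace(self, **kw)
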