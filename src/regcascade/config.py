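"""Pipeline configuration and sample metadata.

All numeric thresholds used anywhere in the pipeline live in
:class:`PipelineConfig`, so that a run is fully described by one config
object plus one seed.  The defaults are the study conditions of the
neurodevelopmental ASD analysis this package implements: genes with a
median read count below 20 are treated as unexpressed, differential
expression is called at |log2FC| > 1 and FDR < 0.05, regulator-target
pairs are considered coordinately expressed at |r| >= 0.75, cascades are
grown with a strict r > 0.8 gate up to three layers, and TF motifs are
matched in lncRNA promoters (-1000 bp to +200 bp around the TSS) at an
exact match p-value of 5e-5.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
import yaml

log = logging.getLogger("regcascade")

CELL_TYPES = ("iPSC", "NPC", "neuron")
CONDITIONS = ("normal", "ASD")

BASES = "ACGT"


class ConfigError(ValueError):
    """Malformed or out-of-range configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    min_median_count: int = 20          # reads; genes with median below this are unexpressed
    lfc_threshold: float = 1.0          # log2 units, strict ">" when calling DEGs
    fdr_threshold: float = 0.05
    pair_corr_cutoff: float = 0.75      # coordinate-expression gate, |r| >= cutoff
    cascade_corr_cutoff: float = 0.8    # cascade growth gate, strict |r| > cutoff
    max_layers: int = 3                 # regulation radius below the root TF
    motif_pvalue: float = 5e-5
    promoter_upstream: int = 1000       # bp upstream of the TSS
    promoter_downstream: int = 200      # bp downstream of the TSS
    pwm_pseudocount: float = 0.8        # total pseudocount, split by background
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for key in ("min_median_count", "lfc_threshold", "pair_corr_cutoff",
                    "cascade_corr_cutoff", "promoter_upstream",
                    "promoter_downstream", "pwm_pseudocount"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be strictly positive, got {getattr(self, key)}")
        for key in ("fdr_threshold", "motif_pvalue"):
            v = getattr(self, key)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{key} must lie in (0, 1), got {v}")
        if self.max_layers < 1:
            raise ConfigError(f"max_layers must be >= 1, got {self.max_layers}")
        bg = self.background
        if len(bg) != 4 or any(b <= 0 for b in bg):
            raise ConfigError(f"background must be 4 positive probabilities, got {bg}")
        if abs(sum(bg) - 1.0) > 1e-12:
            raise ConfigError(f"background must sum to 1, got sum {sum(bg)!r}")
        if int(self.seed) != self.seed:
            raise ConfigError(f"seed must be an integer, got {self.seed}")


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}


def load_config(path) -> PipelineConfig:
    """Read a flat key: value document and return a validated config.

    Omitted keys take the defaults above; unknown keys are warned about
    and ignored (forward compatibility), out-of-range values raise
    :class:`ConfigError` naming the offending key.
    """
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must be a flat key: value mapping")
    known = {}
    for key, value in raw.items():
        if key not in _FIELD_TYPES:
            log.warning("config: ignoring unknown key %r", key)
            continue
        if key == "background":
            if not isinstance(value, (list, tuple)):
                raise ConfigError(f"background must be a list of 4 probabilities, got {value!r}")
            value = tuple(float(v) for v in value)
        elif key in ("min_median_count", "max_layers", "promoter_upstream",
                     "promoter_downstream", "seed"):
            if isinstance(value, bool) or not isinstance(value, int):
                raise ConfigError(f"{key} must be an integer, got {value!r}")
        else:
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ConfigError(f"{key} must be numeric, got {value!r}")
            value = float(value)
        known[key] = value
    cfg = PipelineConfig(**known)
    for f in dataclasses.fields(cfg):
        log.info("config: %s = %r", f.name, getattr(cfg, f.name))
    return cfg


@dataclass
class SampleSheet:
    """Per-sample metadata: sample id, cell type, condition."""

    frame: pd.DataFrame  # columns sample_id, cell_type, condition

    def __post_init__(self) -> None:
        required = ["sample_id", "cell_type", "condition"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ConfigError(f"sample sheet missing columns {missing}")
        self.frame = self.frame[required].astype(str).reset_index(drop=True)
        ids = self.frame["sample_id"]
        if ids.duplicated().any():
            dup = sorted(ids[ids.duplicated()].unique())
            raise ConfigError(f"duplicate sample ids: {dup}")
        bad_ct = sorted(set(self.frame["cell_type"]) - set(CELL_TYPES))
        if bad_ct:
            raise ConfigError(f"unknown cell types {bad_ct}; expected one of {CELL_TYPES}")
        bad_cond = sorted(set(self.frame["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise ConfigError(f"unknown conditions {bad_cond}; expected one of {CONDITIONS}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples(self, cell_type: str | None = None,
                condition: str | None = None) -> list[str]:
        sel = self.frame
        if cell_type is not None:
            sel = sel[sel["cell_type"] == cell_type]
        if condition is not None:
            sel = sel[sel["condition"] == condition]
        return list(sel["sample_id"])

    def groups(self) -> list[tuple[str, str]]:
        """Non-empty (cell_type, condition) groups in canonical order."""
        present = set(zip(self.frame["cell_type"], self.frame["condition"]))
        return [(ct, cond) for ct in CELL_TYPES for cond in CONDITIONS
                if (ct, cond) in present]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "SampleSheet":
        return cls(pd.DataFrame(records, columns=["sample_id", "cell_type", "condition"]))

    @classmethod
    def read_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)
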