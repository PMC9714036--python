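"""Readers, writers and run configuration.

All tabular formats are UTF-8 CSV/TSV with a header row, "." decimal and
no index column, so outputs are bit-stable across runs with the same
config and seed. Gene symbols are uppercased on read to match TCGA-style
matrices.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .immuno import ExpressionMatrix
from .timecourse import MID_COLUMNS, LabelTimeCourse

_FLOAT_FMT = "%.10g"


def read_mid_csv(path: str | Path) -> LabelTimeCourse:
    """Read a long-format MID CSV into a validated time course.

    MIDs whose fractions sum within 1e-3 of 1 are renormalized; larger
    deviations are rejected with the offending row reported.
    """
    df = pd.read_csv(path)
    missing = [c for c in MID_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return LabelTimeCourse(df, renorm_tol=1e-3)


def write_mid_csv(tc: LabelTimeCourse, path: str | Path) -> None:
    tc.frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Genes x samples TSV: first column gene symbols, header = sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    frame = expr.frame
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_covariate_csv(path: str | Path, column: str = "leukocyte_fraction") -> pd.Series:
    df = pd.read_csv(path)
    for col in ("sample_id", column):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return df.set_index("sample_id")[column].astype(float)


def read_gene_set(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s.upper())
    return out


@dataclass(frozen=True)
class RunConfig:
    """Stage parameters plus a provenance block echoed into every output."""

    params: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        cfg_seed = int(raw.pop("seed", 0))
        return cls(params=raw, seed=cfg_seed if seed is None else seed)

    def get(self, key: str, default: Any = None) -> Any:
        return self.params.get(key, default)

    @property
    def digest(self) -> str:
        payload = json.dumps(
            {"params": self.params, "seed": self.seed}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance(self) -> dict[str, str]:
        return {"config_hash": self.digest, "package_version": __version__}


def write_results_csv(df: pd.DataFrame, path: str | Path, config: RunConfig) -> None:
    """Write a tidy results table with provenance columns appended."""
    out = df.copy()
    for key, val in config.provenance().items():
        out[key] = val
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_run_summary(payload: dict, path: str | Path, config: RunConfig) -> None:
    data = {**payload, "provenance": config.provenance()}
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True, default=float) + "\n")
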