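"""Long-format container for labeled time courses.

A :class:`LabelTimeCourse` holds MIDVectors indexed by condition, tracer,
metabolite, time and replicate, backed by a tidy pandas DataFrame with one
row per (measurement, mass shift). This is the in-memory mirror of the MID
CSV dialect written by the simulator and read back by the analysis stages.
"""

from __future__ import annotations

from collections.abc import Callable, Iterator

import numpy as np
import pandas as pd

from . import mid as _mid
from .errors import DataError, ValidationError

#: Canonical column order of the long-format MID table.
MID_COLUMNS = [
    "sample_id",
    "condition",
    "tracer",
    "metabolite",
    "time_min",
    "replicate",
    "mass_shift",
    "fraction",
]

_KEY = ["sample_id", "condition", "tracer", "metabolite", "time_min", "replicate"]


class LabelTimeCourse:
    """MIDVectors indexed by metabolite, time, replicate, condition, tracer."""

    def __init__(self, frame: pd.DataFrame, renorm_tol: float = 0.0):
        missing = [c for c in MID_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"MID table missing columns: {', '.join(missing)}")
        df = frame.loc[:, MID_COLUMNS].copy()
        df["time_min"] = df["time_min"].astype(float)
        df["mass_shift"] = df["mass_shift"].astype(int)
        df["fraction"] = df["fraction"].astype(float)
        df["replicate"] = df["replicate"].astype(int)
        if (df["fraction"] < -1e-12).any():
            row = int(df.index[df["fraction"] < -1e-12][0])
            raise ValidationError(f"negative isotopologue fraction at row {row}")
        sums = df.groupby(_KEY, sort=False)["fraction"].transform("sum")
        bad = (sums - 1.0).abs() > max(renorm_tol, 1e-6)
        if bad.any():
            row = int(df.index[bad][0])
            raise ValidationError(
                f"MID does not sum to 1 (got {sums[bad].iloc[0]:.6f}) at row {row}"
            )
        if renorm_tol > 0:
            df["fraction"] = df["fraction"] / sums
        self._df = df.sort_values(_KEY + ["mass_shift"], kind="stable").reset_index(
            drop=True
        )

    # -- construction -------------------------------------------------

    @classmethod
    def from_mids(
        cls, records: list[tuple[dict, _mid.MIDVector]]
    ) -> "LabelTimeCourse":
        """Build from (metadata, MIDVector) pairs.

        Metadata must provide condition, tracer, time_min and replicate;
        sample_id defaults to ``{condition}_r{replicate}``.
        """
        rows = []
        for meta, m in records:
            sample = meta.get(
                "sample_id", f"{meta['condition']}_r{meta['replicate']}"
            )
            for shift, frac in enumerate(m.fractions):
                rows.append(
                    {
                        "sample_id": sample,
                        "condition": meta["condition"],
                        "tracer": meta["tracer"],
                        "metabolite": m.metabolite,
                        "time_min": meta["time_min"],
                        "replicate": meta["replicate"],
                        "mass_shift": shift,
                        "fraction": float(frac),
                    }
                )
        if not rows:
            raise DataError("no MID records supplied")
        return cls(pd.DataFrame(rows))

    # -- accessors ----------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying tidy table (copy)."""
        return self._df.copy()

    @property
    def conditions(self) -> list[str]:
        return sorted(self._df["condition"].unique())

    @property
    def metabolites(self) -> list[str]:
        return sorted(self._df["metabolite"].unique())

    @property
    def times(self) -> np.ndarray:
        return np.sort(self._df["time_min"].unique())

    def subset(self, **criteria) -> "LabelTimeCourse":
        """Filter by equality on any MID column (e.g. condition='tumor_a')."""
        df = self._df
        for col, val in criteria.items():
            if col not in MID_COLUMNS:
                raise DataError(f"unknown column {col!r}")
            df = df[df[col] == val]
        if df.empty:
            raise DataError(f"no rows match {criteria!r}")
        return LabelTimeCourse(df)

    def iter_mids(self) -> Iterator[tuple[dict, _mid.MIDVector]]:
        for key, grp in self._df.groupby(_KEY, sort=True):
            meta = dict(zip(_KEY, key))
            grp = grp.sort_values("mass_shift")
            shifts = grp["mass_shift"].to_numpy()
            if not np.array_equal(shifts, np.arange(len(shifts))):
                raise ValidationError(
                    f"non-contiguous mass shifts for {meta['metabolite']}"
                )
            yield meta, _mid.MIDVector(meta["metabolite"], grp["fraction"].to_numpy())

    def mid(
        self, metabolite: str, time_min: float, replicate: int = 0, **criteria
    ) -> _mid.MIDVector:
        """Fetch one MIDVector; extra criteria disambiguate condition/tracer."""
        sub = self.subset(
            metabolite=metabolite, time_min=float(time_min), replicate=replicate,
            **criteria,
        )
        metas = list(sub.iter_mids())
        if len(metas) > 1:
            raise DataError(
                f"{len(metas)} measurements match; add condition/tracer criteria"
            )
        return metas[0][1]

    # -- transforms ---------------------------------------------------

    def map_mids(
        self, fn: Callable[[_mid.MIDVector], _mid.MIDVector]
    ) -> "LabelTimeCourse":
        """Apply a per-MID transform (e.g. natural-abundance correction)."""
        return LabelTimeCourse.from_mids(
            [(meta, fn(m)) for meta, m in self.iter_mids()]
        )

    def enrichments(self, mode: str = "atom_fraction") -> pd.DataFrame:
        """Per-measurement scalar enrichment table."""
        rows = [
            {**meta, "enrichment": _mid.enrichment(m, mode)}
            for meta, m in self.iter_mids()
        ]
        return pd.DataFrame(rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelTimeCourse):
            return NotImplemented
        a = self._df.reset_index(drop=True)
        b = other._df.reset_index(drop=True)
        if a.shape != b.shape:
            return False
        try:
            pd.testing.assert_frame_equal(a, b, check_exact=False, atol=1e-12)
        except AssertionError:
            return False
        return True

    def __len__(self) -> int:
        return len(self._df.groupby(_KEY))
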