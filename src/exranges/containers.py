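"""In-memory containers for multi-series time-course expression data.

The central object is :class:`ExpressionMatrix`: a genes x samples table of
non-negative expression values together with a *design* assigning each sample
to a time series (a tissue, a subject, a growth condition, ...) and a numeric
time within that series.  All downstream feature engineering (slopes, rate
significance, ExRANGES) is driven by this design: slopes are only ever taken
between consecutive samples of the same series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "StepMatrix",
    "GoldStandard",
    "step_label",
    "parse_step_label",
]

DESIGN_COLUMNS = ("series_id", "time")


class ValidationError(ValueError):
    """Raised when an input table violates the data-model invariants."""


def step_label(series_id: object, from_time: float) -> str:
    """Column label for the step leaving ``from_time`` in ``series_id``.

    Uses ``repr`` of the float so the label parses back losslessly.
    """
    return f"{series_id}:{float(from_time)!r}"


def parse_step_label(label: str) -> tuple[str, float]:
    series_id, _, t = label.rpartition(":")
    return series_id, float(t)


class ExpressionMatrix:
    """Genes x samples expression values with per-sample (series, time) design.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene identifier, columns by sample identifier,
        entries finite non-negative reals (platform-dependent units).
    design : pandas.DataFrame
        Indexed by sample identifier with columns ``series_id`` and ``time``
        and optionally ``cyclic`` (boolean, constant within a series).
    """

    def __init__(self, values: pd.DataFrame, design: pd.DataFrame, *, validate: bool = True):
        design = design.copy()
        if "cyclic" not in design.columns:
            design["cyclic"] = False
        self.values = values
        self.design = design
        if validate:
            self._validate()

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        v, d = self.values, self.design
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dup}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        if d.index.duplicated().any():
            dup = d.index[d.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate design rows for samples: {dup}")
        for col in DESIGN_COLUMNS:
            if col not in d.columns:
                raise ValidationError(f"design is missing required column {col!r}")
        missing = [s for s in v.columns if s not in d.index]
        if missing:
            raise ValidationError(f"samples absent from design: {missing}")
        extra = [s for s in d.index if s not in v.columns]
        if extra:
            raise ValidationError(f"design rows without matrix columns: {extra}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        times = pd.to_numeric(d["time"], errors="coerce")
        if times.isna().any():
            bad = d.index[times.isna()].tolist()
            raise ValidationError(f"non-numeric time for samples: {bad}")
        self.design["time"] = times.astype(float)
        for series_id, grp in d.groupby("series_id", sort=False):
            if grp["time"].duplicated().any():
                t = grp["time"][grp["time"].duplicated()].iloc[0]
                raise ValidationError(
                    f"duplicate time {t} within series {series_id!r}"
                )
            if grp["cyclic"].nunique() > 1:
                raise ValidationError(
                    f"inconsistent cyclic flag within series {series_id!r}"
                )

    # -- accessors -------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values.columns)

    def series_ids(self) -> list:
        seen = dict.fromkeys(self.design.loc[self.samples, "series_id"])
        return list(seen)

    def series_samples(self, series_id) -> pd.DataFrame:
        """Design rows of one series, sorted by time."""
        d = self.design.loc[self.samples]
        grp = d[d["series_id"] == series_id]
        return grp.sort_values("time")

    def is_cyclic(self, series_id) -> bool:
        return bool(self.series_samples(series_id)["cyclic"].iloc[0])

    def subset(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[genes], self.design, validate=False)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ExpressionMatrix {self.n_genes} genes x {self.n_samples} samples, "
            f"{len(self.series_ids())} series>"
        )


@dataclass
class StepMatrix:
    """Genes x steps values with per-step metadata.

    ``steps`` is indexed by the step label (``series:from_time``) and carries
    ``series_id``, ``from_time``, ``to_time`` and ``from_sample`` (the sample
    id the step value is attached to).  Used for slope, RANGES and ExRANGES
    matrices, which all share the same step geometry.
    """

    values: pd.DataFrame
    steps: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.steps.index):
            raise ValidationError("step metadata does not match value columns")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def signs(self) -> pd.DataFrame:
        return np.sign(self.values)

    def gene_steps(self, gene) -> pd.DataFrame:
        """One gene's steps as a tidy table (series, from/to time, value)."""
        out = self.steps.copy()
        out["value"] = self.values.loc[gene].to_numpy()
        return out


@dataclass
class GoldStandard:
    """Experimentally supported regulator->target positives for evaluation.

    ``positives`` maps each regulator to its positive target set; ``universe``
    is the full list of evaluated targets (defaults to the union of targets
    seen, but is normally the inference run's target list).
    """

    positives: dict
    universe: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positives = {r: set(t) for r, t in self.positives.items()}
        if not self.universe:
            self.universe = sorted({t for ts in self.positives.values() for t in ts})
        uni = set(self.universe)
        for reg, ts in self.positives.items():
            stray = ts - uni
            if stray:
                raise ValidationError(
                    f"gold-standard targets of {reg!r} outside universe: {sorted(stray)}"
                )

    @property
    def regulators(self) -> list:
        return list(self.positives)

    def positives_for(self, regulator) -> set:
        return set(self.positives.get(regulator, set()))

    def pairs(self) -> set:
        return {(r, t) for r, ts in self.positives.items() for t in ts}

    def __len__(self) -> int:
        return sum(len(t) for t in self.positives.values())
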