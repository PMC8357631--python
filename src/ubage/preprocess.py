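"""Raw intensities to analysis-ready log2 matrices.

Three steps, in the fixed order the pipeline applies them: log2
transformation, minimum-valid filtering within sample groups, and
downshifted-normal imputation of the remaining missing values. Filtering
precedes imputation on purpose — imputing a feature that is absent from a
whole group would fabricate a group difference out of the imputation
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import stream
from .io_tables import LOG2, RAW, QuantTable, ValidationError


class StateError(RuntimeError):
    """A scale transition was requested from the wrong state."""


@dataclass
class ImputationParams:
    """Downshifted-normal imputation constants (Perseus convention).

    Per sample column with observed mean ``m`` and standard deviation
    ``s``, missing cells draw independently from
    ``Normal(m - shift * s, (width * s)**2)`` — a narrow distribution
    placed below the detection range, encoding the assumption that
    missing LFQ values are missing because the peptide was near or below
    the detection limit.
    """

    width: float = 0.3
    shift: float = 1.8
    seed: int = 0

    def validate(self) -> None:
        if self.width <= 0:
            raise ValidationError("imputation width must be > 0")
        if self.shift < 0:
            raise ValidationError("imputation shift must be >= 0")


def log2_transform(table: QuantTable) -> QuantTable:
    """log2-transform every observed cell; missing cells stay missing."""
    if table.scale != RAW:
        raise StateError("table is already log2-scaled")
    return QuantTable(
        table.level, table.features.copy(), np.log2(table.intensities), LOG2
    )


def filter_min_valid(
    table: QuantTable,
    groups: Mapping[str, Sequence[str]],
    min_valid: int | None = None,
) -> QuantTable:
    """Keep features quantified in >= min_valid samples of some group.

    ``groups`` maps a group label to its sample ids (a partition of a
    subset of the table's columns). The default ``min_valid`` is the
    group size minus one, evaluated per group, which tolerates a single
    dropout per condition.
    """
    if not groups:
        raise ValidationError("no sample groups supplied")
    for label, ids in groups.items():
        missing = [s for s in ids if s not in table.intensities.columns]
        if missing:
            raise ValidationError(f"group {label!r} references unknown samples {missing}")
    thresholds = {
        label: (len(ids) - 1 if min_valid is None else min_valid)
        for label, ids in groups.items()
    }
    if all(thr > len(ids) for (label, ids), thr in zip(groups.items(), thresholds.values())):
        raise ValidationError("min_valid exceeds every group size")
    keep = pd.Series(False, index=table.intensities.index)
    for label, ids in groups.items():
        valid = table.intensities[list(ids)].notna().sum(axis=1)
        keep |= valid >= thresholds[label]
    return QuantTable(
        table.level,
        table.features.loc[keep],
        table.intensities.loc[keep],
        table.scale,
    )


def impute_missing(table: QuantTable, params: ImputationParams) -> QuantTable:
    """Replace missing cells by draws from a per-column downshifted normal.

    Observed cells are never modified; the result has no missing cells.
    Deterministic under a fixed ``params.seed``.
    """
    params.validate()
    if table.scale != LOG2:
        raise StateError("imputation operates on log2-scaled tables")
    intens = table.intensities.copy()
    rng = stream(params.seed, "imputation")
    for col in intens.columns:
        column = intens[col]
        observed = column.dropna()
        n_missing = int(column.isna().sum())
        if n_missing == 0:
            continue
        if len(observed) < 2:
            raise ValidationError(
                f"sample {col!r} has {len(observed)} observed values; "
                "cannot estimate an imputation distribution"
            )
        m, s = float(observed.mean()), float(observed.std(ddof=1))
        draws = rng.normal(m - params.shift * s, params.width * s, size=n_missing)
        intens.loc[column.isna(), col] = draws
    return QuantTable(table.level, table.features.copy(), intens, table.scale)


def preprocess(
    table: QuantTable,
    groups: Mapping[str, Sequence[str]],
    imputation: ImputationParams,
    min_valid: int | None = None,
) -> QuantTable:
    """log2-transform, min-valid filter, then impute, in that order."""
    return impute_missing(
        filter_min_valid(log2_transform(table), groups, min_valid), imputation
    )
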