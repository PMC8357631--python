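"""Per-feature two-group testing with permutation-based FDR.

The test is the pooled-variance (Student) two-sample t-test on log2
intensities, optionally with an ``s0`` fudge constant added to the
standard error (the SAM / Perseus convention that damps significance of
tiny absolute changes). Multiple testing is controlled by a
permutation-based false-discovery-rate estimate: group labels are
shuffled, the |t| distribution under relabelling is accumulated, and for
every observed |t| threshold ``c``

    FDR(c) = (mean permuted count of |t| >= c) / (observed count of |t| >= c),

capped at 1; the per-feature q-value is the monotone step-down envelope
of FDR over decreasing |t|, so q never increases with |t|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stream
from .io_tables import LOG2, QuantTable, ValidationError

logger = logging.getLogger(__name__)

EXHAUSTIVE = "exhaustive"
#: above this many distinct label assignments, exhaustive enumeration is refused
MAX_EXHAUSTIVE = 10_000


@dataclass
class ContrastSpec:
    """A two-group comparison: ``group_a`` (test) minus ``group_b`` (reference)."""

    name: str
    group_a: Sequence[str]
    group_b: Sequence[str]
    fdr_threshold: float = 0.05
    n_permutations: int | str = 250
    s0: float = 0.0
    seed: int = 0

    def validate(self, available: Sequence[str] | None = None) -> None:
        a, b = set(self.group_a), set(self.group_b)
        if a & b:
            raise ValidationError(f"contrast {self.name!r}: groups overlap: {sorted(a & b)}")
        if len(a) < 2 or len(b) < 2:
            raise ValidationError(f"contrast {self.name!r}: each group needs >= 2 samples")
        if not 0 < self.fdr_threshold < 1:
            raise ValidationError("fdr_threshold must lie in (0, 1)")
        if self.s0 < 0:
            raise ValidationError("s0 must be >= 0")
        if self.n_permutations != EXHAUSTIVE and int(self.n_permutations) < 1:
            raise ValidationError("n_permutations must be >= 1 or 'exhaustive'")
        if available is not None:
            unknown = (a | b) - set(available)
            if unknown:
                raise ValidationError(
                    f"contrast {self.name!r}: samples not in table: {sorted(unknown)}"
                )


# ---------------------------------------------------------------------------
# the t statistic
# ---------------------------------------------------------------------------


def _t_matrix(values_a: np.ndarray, values_b: np.ndarray, s0: float) -> np.ndarray:
    """Pooled-variance t statistic per row of two (features x reps) blocks."""
    na, nb = values_a.shape[1], values_b.shape[1]
    mean_a, mean_b = values_a.mean(axis=1), values_b.mean(axis=1)
    var_a = values_a.var(axis=1, ddof=1)
    var_b = values_b.var(axis=1, ddof=1)
    sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb)) + s0
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    # zero pooled variance with s0 = 0: identical means -> t = 0;
    # different means -> perfect separation, t = +/- infinity
    degenerate = (se == 0) & (diff != 0)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.sign(diff) * np.inf, t)
    return t


def two_sample_t(
    values_a: Sequence[float], values_b: Sequence[float], s0: float = 0.0
) -> tuple[float, float, float]:
    """Pooled-variance Student t-test of ``a`` versus ``b``.

    Returns ``(log2_fc, t_stat, p_value)`` with ``log2_fc = mean(a) -
    mean(b)`` and a two-sided p from the t distribution with
    ``len(a) + len(b) - 2`` degrees of freedom. With zero pooled variance
    and ``s0 = 0``, identical means give ``(0, 0, 1)`` and different
    means give p = 0 (a degenerate, perfectly separated feature).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least two values")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("missing values must be imputed before testing")
    t = float(_t_matrix(a[None, :], b[None, :], s0)[0])
    df = len(a) + len(b) - 2
    if np.isinf(t):
        p = 0.0
    else:
        p = float(2.0 * stats.t.sf(abs(t), df))
    return float(a.mean() - b.mean()), t, p


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------


def _assignment_masks(
    n: int, k: int, observed: np.ndarray, spec: ContrastSpec
) -> tuple[np.ndarray, int]:
    """Boolean masks (n_perm x n) assigning k of n samples to one group.

    The mask always selects the *smaller* group, so a contrast and its
    role-swapped twin enumerate or sample identical |t| distributions.
    The observed assignment (``observed``, and its complement in a
    balanced design) is never part of the null: it reproduces the
    observed statistics exactly and would otherwise floor the FDR
    estimate at 1 / n_permutations, making significance unattainable for
    small designs such as 3 versus 3. Exhaustive mode enumerates all
    remaining distinct assignments; integer mode samples that many
    uniformly (seeded), falling back to exhaustive when fewer distinct
    assignments exist than requested.
    """
    total = comb(n, k)

    def is_observed(mask: np.ndarray) -> bool:
        return bool(np.array_equal(mask, observed) or (2 * k == n and np.array_equal(mask, ~observed)))

    available = total - (2 if 2 * k == n else 1)
    want = spec.n_permutations
    if want == EXHAUSTIVE:
        if total > MAX_EXHAUSTIVE:
            raise ValidationError(
                f"{total} distinct assignments exceed the exhaustive cap {MAX_EXHAUSTIVE}"
            )
        exhaustive = True
        n_perm = available
    else:
        want = int(want)
        exhaustive = available <= want
        n_perm = available if exhaustive else want
        if exhaustive and available < want:
            logger.info(
                "only %d distinct label shuffles (requested %d); using all",
                available,
                want,
            )
    masks = np.zeros((n_perm, n), dtype=bool)
    if exhaustive:
        i = 0
        for idx in combinations(range(n), k):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            if is_observed(mask):
                continue
            masks[i] = mask
            i += 1
    else:
        rng = stream(spec.seed, "permutation_fdr")
        i = 0
        while i < n_perm:
            mask = np.zeros(n, dtype=bool)
            mask[rng.permutation(n)[:k]] = True
            if is_observed(mask):
                continue
            masks[i] = mask
            i += 1
    return masks, n_perm


def permutation_fdr(matrix: pd.DataFrame, spec: ContrastSpec) -> pd.Series:
    """Per-feature q-values for ``spec`` on a complete log2 matrix.

    ``matrix`` is features x samples and must contain every sample of the
    contrast with no missing values. Deterministic under ``spec.seed``.
    """
    spec.validate(matrix.columns)
    combined = sorted(set(spec.group_a) | set(spec.group_b))
    values = matrix[combined].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError("matrix has missing values; impute first")
    na, nb = len(spec.group_a), len(spec.group_b)
    obs_t = np.abs(
        _t_matrix(
            matrix[list(spec.group_a)].to_numpy(dtype=float),
            matrix[list(spec.group_b)].to_numpy(dtype=float),
            spec.s0,
        )
    )

    k = min(na, nb)
    small_group = spec.group_a if na <= nb else spec.group_b
    observed_mask = np.array([s in set(small_group) for s in combined])
    masks, n_perm = _assignment_masks(len(combined), k, observed_mask, spec)
    perm_t = np.empty((n_perm, len(matrix)))
    for i, mask in enumerate(masks):
        perm_t[i] = np.abs(_t_matrix(values[:, mask], values[:, ~mask], spec.s0))

    perm_sorted = np.sort(perm_t.ravel())
    obs_sorted = np.sort(obs_t)
    n_total = perm_sorted.size
    # count of permuted |t| >= c, averaged over permutations
    numerator = (n_total - np.searchsorted(perm_sorted, obs_t, side="left")) / n_perm
    denominator = len(obs_t) - np.searchsorted(obs_sorted, obs_t, side="left")
    fdr = np.minimum(1.0, numerator / np.maximum(denominator, 1))

    # step-down envelope: walk thresholds from the most significant |t|
    # downward, carrying the running maximum of the FDR estimate, so q is
    # monotone non-increasing in |t| and no feature borrows a luckily low
    # estimate from a more lenient threshold
    order = np.argsort(-obs_t, kind="mergesort")
    q_desc = np.maximum.accumulate(fdr[order])
    q = np.empty_like(q_desc)
    q[order] = q_desc
    return pd.Series(q, index=matrix.index, name="q_value")


def run_contrast(
    table: QuantTable,
    spec: ContrastSpec,
    observed_counts: pd.DataFrame | None = None,
    min_valid_test: int = 2,
) -> pd.DataFrame:
    """One differential row per feature for a two-group contrast.

    The table must be log2-scaled and complete (imputed) for the
    contrast's samples. ``log2_fc`` is oriented ``group_a - group_b``;
    ``significant`` means ``q_value < spec.fdr_threshold``.

    ``observed_counts`` (columns ``n_valid_a`` / ``n_valid_b``) carries
    the pre-imputation number of observed values per group. A group that
    is (almost) wholly imputed has no real within-group evidence — the
    downshifted imputer fabricates a tight cluster at the detection
    floor, which the permutation null cannot reproduce — so features
    with fewer than ``min_valid_test`` observed values in either group
    keep their fold change and statistic but are reported with q = 1 and
    never called significant.
    """
    if table.scale != LOG2:
        raise ValidationError("run_contrast needs a log2-scaled table")
    spec.validate(table.samples)
    sub = table.intensities[list(spec.group_a) + list(spec.group_b)]
    if sub.isna().to_numpy().any():
        raise ValidationError("contrast samples contain missing values; impute first")
    a = sub[list(spec.group_a)].to_numpy(dtype=float)
    b = sub[list(spec.group_b)].to_numpy(dtype=float)
    t = _t_matrix(a, b, spec.s0)
    df = a.shape[1] + b.shape[1] - 2
    with np.errstate(invalid="ignore"):
        p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    q = permutation_fdr(sub, spec)
    out = pd.DataFrame(index=table.intensities.index)
    out["protein_id"] = table.features["protein_id"]
    out["site_position"] = table.features["site_position"]
    out["log2_fc"] = a.mean(axis=1) - b.mean(axis=1)
    out["t_stat"] = t
    out["p_value"] = p
    out["q_value"] = q
    if observed_counts is not None:
        out["n_valid_a"] = observed_counts["n_valid_a"].reindex(out.index)
        out["n_valid_b"] = observed_counts["n_valid_b"].reindex(out.index)
        weak = (out["n_valid_a"] < min_valid_test) | (out["n_valid_b"] < min_valid_test)
        out.loc[weak, "q_value"] = 1.0
    else:
        out["n_valid_a"] = int(a.shape[1])
        out["n_valid_b"] = int(b.shape[1])
    out["significant"] = out["q_value"] < spec.fdr_threshold
    return out


def summarize_counts(diff_tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Counts and percentages of up/down significant features per contrast.

    ``up`` counts significant features with positive log2 fold change,
    ``down`` negative; percentages are over up + down and reported as NaN
    when no feature is significant.
    """
    rows = []
    for name, table in diff_tables.items():
        if table.empty:
            raise ValidationError(f"differential table {name!r} is empty")
        sig = table[table["significant"]]
        up = int((sig["log2_fc"] > 0).sum())
        down = int((sig["log2_fc"] < 0).sum())
        total = up + down
        rows.append(
            {
                "contrast": name,
                "up": up,
                "down": down,
                "total_significant": total,
                "up_pct": 100.0 * up / total if total else np.nan,
                "down_pct": 100.0 * down / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("contrast")
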