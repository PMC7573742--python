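"""Behavioral table handling and residual dependent measures.

Both mapping analyses (voxel- and edge-level) operate on *residual* scores:
the primary measure regressed, by ordinary least squares with an intercept,
on one or more control measures.  For tool-use gesturing the hand-posture
error proportion is residualized against meaningless-imitation performance;
for grip strength the right (contralesional) hand is residualized against
the left.  Negative residuals mean worse-than-predicted performance on the
primary measure, which is the tail of interest throughout.

The packaged cohort table (57 left-hemisphere stroke participants: scores,
demographics, lesion volumes) ships as a TSV fixture and is validated by
checksum on load.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BEHAVIOR_COLUMNS",
    "ResidualScores",
    "average_grip_trials",
    "residualize",
    "pearson_r",
    "load_table1_fixture",
    "validate_behavior_table",
    "read_behavior_table",
    "write_behavior_table",
]

#: Canonical column order for a behavior table.
BEHAVIOR_COLUMNS = (
    "subject_id",
    "gts_hp",
    "imi_hp",
    "lh_grip",
    "rh_grip",
    "months_post",
    "lesion_volume",
    "age",
    "education",
    "gender",
)

#: Columns in which missing values are permitted (grip testing was skipped
#: for participants with contralesional weakness).
_MISSING_ALLOWED = {"lh_grip", "rh_grip"}

_TABLE1_SHA256 = "e2bef227ca30e8e953d3c5e9880b563cf01720c19db1ead6a885980af81986bd"


@dataclass
class ResidualScores:
    """OLS residuals of a behavioral measure, one value per retained subject.

    Residuals are zero-mean and orthogonal to every (centered) regressor
    that was removed; ``formula_terms`` records the regressor names.
    """

    subject_ids: list
    values: np.ndarray
    formula_terms: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.subject_ids)} subject ids but "
                f"{self.values.shape[0]} residual values"
            )

    def __len__(self) -> int:
        return self.values.shape[0]


def average_grip_trials(trials) -> float:
    """Average force across repeated dynamometer trials for one hand."""
    arr = np.asarray(trials, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no finite grip trial values to average")
    return float(arr.mean())


def _design_matrix(regressors, names, n: int) -> tuple[np.ndarray, list]:
    cols = [np.ones(n)]
    for k, reg in enumerate(regressors):
        reg = np.asarray(reg, dtype=float)
        if reg.shape != (n,):
            raise ValueError(f"regressor {names[k]!r} has shape {reg.shape}, expected ({n},)")
        if not np.all(np.isfinite(reg)):
            raise ValueError(f"regressor {names[k]!r} contains non-finite values")
        cols.append(reg)
    return np.column_stack(cols), names


def _check_full_rank(design: np.ndarray, names) -> None:
    """Reject mutually collinear regressors, naming an offender.

    A constant regressor is allowed (it is absorbed by the intercept and the
    residuals stay well defined); only collinearity among the centered
    non-constant columns makes the fit ill-conditioned enough to refuse.
    """
    centered = design[:, 1:] - design[:, 1:].mean(axis=0)
    keep = [j for j in range(centered.shape[1])
            if np.linalg.norm(centered[:, j]) > 1e-12]
    if not keep:
        return
    sub = centered[:, keep]
    rank = np.linalg.matrix_rank(sub)
    if rank == sub.shape[1]:
        return
    for j in range(sub.shape[1]):
        reduced = np.delete(sub, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            raise ValueError(
                f"rank-deficient design: regressor {names[keep[j]]!r} is "
                "collinear with another regressor"
            )
    raise ValueError("rank-deficient design matrix")


def residualize(y, *regressors, subject_ids=None, names=None) -> ResidualScores:
    """OLS residuals of ``y`` on the given regressors (intercept included).

    Missing values are the caller's problem: filter to complete rows first.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if not regressors:
        raise ValueError("at least one regressor is required")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if n <= len(regressors) + 1:
        raise ValueError(
            f"need more than {len(regressors) + 1} observations, got {n}"
        )
    if names is None:
        names = [f"x{k + 1}" for k in range(len(regressors))]
    design, names = _design_matrix(regressors, list(names), n)
    _check_full_rank(design, names)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    if subject_ids is None:
        subject_ids = list(range(n))
    return ResidualScores(list(subject_ids), resid, formula_terms=list(names))


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation.

    Invariant under positive affine rescaling of either variable, so error
    proportions and accuracy proportions yield the same value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def one_tailed_p_negative(r: float, n: int) -> float:
    """One-tailed p-value for the hypothesis r < 0 (t distribution, n-2 df)."""
    if n < 3:
        raise ValueError("need at least 3 observations")
    r = float(np.clip(r, -0.999999999, 0.999999999))
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(stats.t.cdf(t, df=n - 2))


def validate_behavior_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants of a behavior table; returns the table."""
    missing_cols = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"behavior table missing columns: {missing_cols}")
    for col in ("gts_hp", "imi_hp"):
        vals = df[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"missing values not allowed in {col!r}")
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col!r} must be proportions in [0, 1]")
    for col in ("months_post", "lesion_volume", "age", "education"):
        vals = df[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"missing values not allowed in {col!r}")
    if (df["months_post"].to_numpy(dtype=float) <= 0).any():
        raise ValueError("months_post must be positive")
    if (df["lesion_volume"].to_numpy(dtype=float) < 0).any():
        raise ValueError("lesion_volume must be non-negative")
    return df


def read_behavior_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA", "_"], dtype={"subject_id": str})
    return validate_behavior_table(df)


def write_behavior_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def load_table1_fixture() -> pd.DataFrame:
    """Load the packaged 57-participant cohort table.

    Grip columns carry NA exactly where the source prints a missing marker
    (16 participants without right-hand testing, 5 of whom also lack
    left-hand scores). The file is checksum-verified to guard against
    accidental edits.
    """
    ref = resources.files("svrlsm.data").joinpath("table1.tsv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise ValueError(
            f"cohort fixture checksum mismatch: {digest} != {_TABLE1_SHA256}"
        )
    import io as _io

    df = pd.read_csv(_io.BytesIO(raw), sep="\t", na_values=["NA"], dtype={"subject_id": str})
    return validate_behavior_table(df)
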