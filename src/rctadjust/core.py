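"""Domain types and delimited-text I/O for two-arm trial data.

A trial is one row per participant: an identifier, a 0/1 treatment
indicator ``z`` (1 = treatment, 0 = control), a continuous outcome ``y``,
and named baseline covariates (continuous, or binary coded 0/1).  The
on-disk interchange format is plain comma-separated text with a header row
and ``.`` as the decimal mark; the treatment column must contain literal
0/1 integers — no label coercion, so arms can never be silently swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "TrialDataset",
    "AdjustedEstimate",
    "read_trial_csv",
    "write_trial_csv",
    "write_results_table",
    "RESULTS_COLUMNS",
]

#: Column order of the aggregated simulation results table
#: (one row per scenario x method).
RESULTS_COLUMNS = [
    "scenario",
    "n",
    "method",
    "n_covariates",
    "mean_theta",
    "pct_bias",
    "mean_se",
    "empirical_se",
    "se_ratio",
    "coverage_pct",
    "n_failed_reps",
]


@dataclass(frozen=True)
class TrialDataset:
    """One two-arm trial, validated on construction.

    Parameters
    ----------
    subject_id : array of str
        Participant labels.
    treatment : int array
        0/1 allocation indicator (1 = treatment arm).
    outcome : float array
        Continuous outcome, one per participant.
    covariates : float 2-d array, shape (n, p)
        Baseline covariate matrix; binary covariates are coded 0/1.
    covariate_names : tuple of str
        Unique names, one per covariate column.
    """

    subject_id: np.ndarray
    treatment: np.ndarray
    outcome: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subject_id", np.asarray(self.subject_id))
        object.__setattr__(
            self, "treatment", np.asarray(self.treatment, dtype=np.int64)
        )
        object.__setattr__(self, "outcome", np.asarray(self.outcome, dtype=float))
        cov = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if cov.size == 0:
            cov = cov.reshape(len(self.outcome), 0)
        object.__setattr__(self, "covariates", cov)
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        self._validate()

    def _validate(self) -> None:
        n = len(self.outcome)
        if not (len(self.subject_id) == len(self.treatment) == n == self.covariates.shape[0]):
            raise ValidationError(
                "row count mismatch: subject_id=%d treatment=%d outcome=%d covariates=%d"
                % (len(self.subject_id), len(self.treatment), n, self.covariates.shape[0])
            )
        if self.covariates.shape[1] != len(self.covariate_names):
            raise ValidationError(
                f"{self.covariates.shape[1]} covariate columns but "
                f"{len(self.covariate_names)} names"
            )
        if len(set(self.covariate_names)) != len(self.covariate_names):
            raise ValidationError("covariate names are not unique")
        bad_z = np.flatnonzero(~np.isin(self.treatment, (0, 1)))
        if bad_z.size:
            raise ValidationError(
                f"treatment must be 0 or 1; offending rows (0-based): {bad_z[:10].tolist()}"
            )
        bad_y = np.flatnonzero(~np.isfinite(self.outcome))
        if bad_y.size:
            raise ValidationError(
                f"missing/non-finite outcome; rows (0-based): {bad_y[:10].tolist()}"
            )
        bad_x = np.flatnonzero(~np.all(np.isfinite(self.covariates), axis=1))
        if bad_x.size:
            raise ValidationError(
                f"missing/non-finite covariates; rows (0-based): {bad_x[:10].tolist()}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.outcome)

    @property
    def n_treated(self) -> int:
        return int(self.treatment.sum())

    @property
    def n_control(self) -> int:
        return self.n - self.n_treated

    def require_two_per_arm(self) -> None:
        """Raise unless both arms contain at least 2 participants."""
        if self.n_treated < 2 or self.n_control < 2:
            raise ValidationError(
                f"need >= 2 participants per arm, got {self.n_treated} treated / "
                f"{self.n_control} control"
            )

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Columns for ``names`` in the requested order, shape (n, len(names))."""
        idx = []
        for name in names:
            try:
                idx.append(self.covariate_names.index(name))
            except ValueError:
                raise ConfigurationError(
                    f"unknown covariate {name!r}; available: {list(self.covariate_names)}"
                ) from None
        return self.covariates[:, idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.subject_id, "z": self.treatment, "y": self.outcome})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        return df


@dataclass(frozen=True)
class AdjustedEstimate:
    """A treatment-effect estimate with its uncertainty.

    ``theta_hat`` is on the outcome scale; ``se_hat`` is the primary
    analytic SE (model-based for regression, sandwich for IPTW) and
    ``se_boot`` the optional nonparametric bootstrap SE.  The CI is
    symmetric about ``theta_hat`` under ``reference_distribution``
    (``"normal"`` for IPTW, ``"t"`` with ``residual_df`` for regression)
    and ``p_value`` is the matching two-sided Wald tail probability.
    """

    theta_hat: float
    se_hat: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    reference_distribution: str
    adjusted_covariates: tuple[str, ...] = ()
    residual_df: int | None = None
    se_boot: float | None = None
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.method not in ("unadjusted", "regression", "iptw"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.reference_distribution not in ("normal", "t"):
            raise ConfigurationError(
                f"unknown reference distribution {self.reference_distribution!r}"
            )
        if self.reference_distribution == "t" and (
            self.residual_df is None or self.residual_df <= 0
        ):
            raise ConfigurationError("t reference requires a positive residual_df")
        if not self.se_hat > 0:
            raise ValidationError(f"se_hat must be positive, got {self.se_hat}")
        # equality only in the degenerate zero-residual limit (se underflows
        # against theta's magnitude); intervals are treated as closed
        if not self.ci_low <= self.ci_high:
            raise ValidationError("ci_low must not exceed ci_high")


# -- CSV I/O ------------------------------------------------------------------


def read_trial_csv(
    path,
    column_map: Mapping[str, object] | None = None,
) -> TrialDataset:
    """Read a trial dataset from comma-separated text.

    ``column_map`` maps the roles ``id``, ``treatment``, ``outcome`` and
    ``covariates`` (a list of names) onto columns of the file.  Default:
    ``id``/``z``/``y`` with every remaining column treated as a covariate.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cmap = dict(column_map or {})
    id_col = cmap.get("id", "id")
    z_col = cmap.get("treatment", "z")
    y_col = cmap.get("outcome", "y")
    for role, col in (("id", id_col), ("treatment", z_col), ("outcome", y_col)):
        if col not in df.columns:
            raise ConfigurationError(f"column {col!r} (role {role}) not found in {path}")
    cov_cols = cmap.get("covariates")
    if cov_cols is None:
        cov_cols = [c for c in df.columns if c not in (id_col, z_col, y_col)]
    else:
        missing = [c for c in cov_cols if c not in df.columns]
        if missing:
            raise ConfigurationError(f"covariate column(s) {missing} not found in {path}")
    z_raw = df[z_col]
    if not (pd.api.types.is_integer_dtype(z_raw) or set(z_raw.dropna().unique()) <= {0, 1, 0.0, 1.0}):
        bad = df.index[~z_raw.isin([0, 1])].tolist()
        raise ValidationError(
            f"treatment column {z_col!r} must contain 0/1 only; offending rows: {bad[:10]}"
        )
    na_rows = df.index[df[[z_col, y_col, *cov_cols]].isna().any(axis=1)].tolist()
    if na_rows:
        raise ValidationError(f"missing values in rows {na_rows[:10]}")
    return TrialDataset(
        subject_id=df[id_col].astype(str).to_numpy(),
        treatment=df[z_col].to_numpy(),
        outcome=df[y_col].to_numpy(dtype=float),
        covariates=df[list(cov_cols)].to_numpy(dtype=float)
        if cov_cols
        else np.empty((len(df), 0)),
        covariate_names=tuple(cov_cols),
    )


def write_trial_csv(data: TrialDataset, path) -> None:
    """Write a dataset in the canonical ``id,z,y,<covariates...>`` layout.

    Floats are written with 17 significant digits, enough for every float64
    to survive a write/read cycle bit-exactly.
    """
    data.to_frame().to_csv(path, index=False, float_format="%.17g")


def write_results_table(rows: Iterable[Mapping[str, object]], path) -> None:
    """Write labelled metric records as CSV with a stable column order.

    All records must share one schema.  Columns in :data:`RESULTS_COLUMNS`
    come first (those present), then any extras in first-seen order; an
    empty collection yields a header-only file with the canonical columns.
    """
    rows = list(rows)
    if not rows:
        pd.DataFrame(columns=RESULTS_COLUMNS).to_csv(path, index=False)
        return
    schema = set(rows[0])
    for i, r in enumerate(rows[1:], start=1):
        if set(r) != schema:
            raise ConfigurationError(f"record {i} does not share the schema of record 0")
    ordered = [c for c in RESULTS_COLUMNS if c in schema]
    ordered += [c for c in rows[0] if c not in ordered]
    pd.DataFrame(rows)[ordered].to_csv(path, index=False)
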