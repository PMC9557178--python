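"""Covariate standardization and pairwise collinearity screening."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_COLLINEARITY_THRESHOLD = 0.8


@dataclass
class DesignMatrix:
    """Z-scored design matrix with its standardization constants.

    ``means``/``sds`` use the population (divide-by-n) convention and must be
    reused verbatim when standardizing prediction-grid covariates.  Constant
    columns are left at zero and listed in ``constant_columns``.
    """

    columns: list[str]
    values: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    constant_columns: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Apply the stored constants to new raw covariate rows."""
        raw = np.asarray(raw, dtype=float)
        safe_sds = np.where(self.sds == 0, 1.0, self.sds)
        out = (raw - self.means) / safe_sds
        out[:, self.sds == 0] = 0.0
        return out

    def select(self, names: list[str]) -> "DesignMatrix":
        idx = [self.columns.index(n) for n in names]
        return DesignMatrix(
            columns=list(names),
            values=self.values[:, idx],
            means=self.means[idx],
            sds=self.sds[idx],
            constant_columns=[n for n in self.constant_columns if n in names],
        )


def standardize(
    raw: np.ndarray, columns: list[str] | None = None
) -> DesignMatrix:
    """Per-column population z-scoring; constant columns become 0 + a flag."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw design matrix must be 2-D")
    if np.isnan(raw).any():
        raise ValueError("missing values in design matrix")
    if columns is None:
        columns = [f"x{k}" for k in range(raw.shape[1])]
    if len(columns) != raw.shape[1]:
        raise ValueError("column names must match matrix width")
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)  # population convention (ddof=0)
    constant = sds == 0
    if constant.any():
        bad = [c for c, flag in zip(columns, constant) if flag]
        warnings.warn(
            f"zero-variance column(s) left at 0: {', '.join(bad)}",
            RuntimeWarning,
        )
    safe_sds = np.where(constant, 1.0, sds)
    values = (raw - means) / safe_sds
    values[:, constant] = 0.0
    return DesignMatrix(
        columns=list(columns),
        values=values,
        means=means,
        sds=sds,
        constant_columns=[c for c, flag in zip(columns, constant) if flag],
    )


def correlation_screen(
    design: DesignMatrix,
    threshold: float = DEFAULT_COLLINEARITY_THRESHOLD,
    priority: list[str] | None = None,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy pairwise collinearity screen.

    Pairs with |Pearson r| >= threshold lose their lower-priority member
    (priority defaults to column order).  Returns the retained names and the
    list of (kept, dropped, r) decisions.
    """
    if len(design.columns) < 2:
        raise ValueError("need at least 2 columns to screen")
    if priority is None:
        priority = list(design.columns)
    ordered = [c for c in priority if c in design.columns] + [
        c for c in design.columns if c not in priority
    ]
    idx = {c: design.columns.index(c) for c in ordered}
    corr = np.corrcoef(design.values, rowvar=False)
    retained = list(ordered)
    dropped: list[tuple[str, str, float]] = []
    for i, hi in enumerate(ordered):
        if hi not in retained:
            continue
        for lo in ordered[i + 1:]:
            if lo not in retained:
                continue
            r = float(corr[idx[hi], idx[lo]])
            if abs(r) >= threshold:
                retained.remove(lo)
                dropped.append((hi, lo, r))
    # report in original column order
    retained = [c for c in design.columns if c in retained]
    return retained, dropped
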