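"""lncRNA-mRNA Pearson co-expression screen.

Every differentially expressed lncRNA is correlated against every
differentially expressed mRNA across the selected samples. A pair is kept
when |r| > 0.7 (strict) and its two-sided p-value, from the exact
t-transform t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom, is
below 0.05. The screen also returns the full pre-filter correlation grid
(the heat-map table).

The sample scope is configurable: correlations can be computed over all
samples of both groups (default) or over the case group only. With a case
group of five samples the p < 0.05 filter at df = 3 only admits
|r| >~ 0.878, which substantially restricts what can pass; this is a
property of the design, not of the implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .diffexpr import DEResult
from .errors import DegenerateInputError, ValidationError
from .io_formats import ExpressionMatrix

DEFAULT_R_THRESHOLD = 0.7
DEFAULT_ALPHA = 0.05

PAIR_TABLE_COLUMNS = (
    "lnc_probe",
    "lnc_symbol",
    "mrna_probe",
    "mrna_symbol",
    "r",
    "p_value",
    "n",
)


@dataclass
class CoexprPair:
    """One significant lncRNA-mRNA correlation."""

    lnc_probe: str
    lnc_symbol: str
    mrna_probe: str
    mrna_symbol: str
    r: float
    p_value: float
    n: int


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValidationError("correlation requires at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.sqrt(xc @ xc), np.sqrt(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        raise DegenerateInputError("zero-variance vector has no defined correlation")
    return float(np.clip((xc @ yc) / (nx * ny), -1.0, 1.0))


def corr_p_value(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation under the null rho = 0."""
    if n < 3:
        raise ValidationError("correlation p-value requires n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValidationError("|r| must not exceed 1")
    denom = 1.0 - r * r
    if denom <= 0.0:
        return 0.0
    t = r * np.sqrt((n - 2) / denom)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def passes_coexpression_filter(
    r: float,
    p: float,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> bool:
    """Retention rule: |r| strictly above the threshold and p strictly below
    alpha; a pair at |r| = 0.7 exactly is rejected."""
    return abs(r) > r_threshold and p < alpha


def _row_standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; zero-variance rows are flagged."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc * Xc).sum(axis=1))
    degenerate = norms == 0.0
    safe = np.where(degenerate, 1.0, norms)
    return Xc / safe[:, None], degenerate


def correlation_grid(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between every row of A and every row of B (same columns).

    Returns the r grid and its two-sided p-values; zero-variance rows yield
    NaN entries.
    """
    A = np.ascontiguousarray(A, dtype=float)
    B = np.ascontiguousarray(B, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValidationError("A and B must share the sample axis")
    n = A.shape[1]
    if n < 3:
        raise ValidationError("correlation requires at least 3 samples")
    Za, bad_a = _row_standardize(A)
    Zb, bad_b = _row_standardize(B)
    r = np.clip(Za @ Zb.T, -1.0, 1.0)
    r[bad_a, :] = np.nan
    r[:, bad_b] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 - r * r
        t = r * np.sqrt((n - 2) / np.where(denom <= 0, np.nan, denom))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(denom <= 0, 0.0, p))
    return r, p


def coexpression_screen(
    m: ExpressionMatrix,
    de: Sequence[DEResult],
    sample_scope: str = "all",
    case_label: str | None = None,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[list[CoexprPair], pd.DataFrame]:
    """Correlate every DE lncRNA against every DE mRNA.

    Returns the retained pairs (sorted by |r| descending, then lncRNA and
    mRNA symbol) and the full lncRNA x mRNA correlation grid indexed by
    probe ID.
    """
    if sample_scope not in ("all", "case_only"):
        raise ValidationError(f"unknown sample_scope {sample_scope!r}")
    if sample_scope == "case_only":
        if case_label is None:
            raise ValidationError("case_only scope requires case_label")
        samples = m.samples_in_group(case_label)
    else:
        samples = m.sample_ids
    if len(samples) < 3:
        raise ValidationError("fewer than 3 samples in the selected scope")
    de_lnc = [r for r in de if r.status != "ns" and r.biotype == "lncRNA"]
    de_mrna = [r for r in de if r.status != "ns" and r.biotype == "mRNA"]
    if not de_lnc or not de_mrna:
        raise ValidationError(
            "need at least one differentially expressed lncRNA and mRNA"
        )
    lnc_probes = [r.probe_id for r in de_lnc]
    mrna_probes = [r.probe_id for r in de_mrna]
    sub = m.data.loc[:, samples]
    A = sub.loc[lnc_probes].to_numpy(dtype=float)
    B = sub.loc[mrna_probes].to_numpy(dtype=float)
    r_grid, p_grid = correlation_grid(A, B)
    n_degenerate = int(np.isnan(r_grid).all(axis=1).sum() + np.isnan(r_grid).all(axis=0).sum())
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} zero-variance probes skipped in the co-expression screen",
            stacklevel=2,
        )
    n = len(samples)
    pairs: list[CoexprPair] = []
    keep = ~np.isnan(r_grid) & (np.abs(r_grid) > r_threshold) & (p_grid < alpha)
    for i, j in zip(*np.nonzero(keep)):
        pairs.append(
            CoexprPair(
                lnc_probe=de_lnc[i].probe_id,
                lnc_symbol=de_lnc[i].gene_symbol,
                mrna_probe=de_mrna[j].probe_id,
                mrna_symbol=de_mrna[j].gene_symbol,
                r=float(r_grid[i, j]),
                p_value=float(p_grid[i, j]),
                n=n,
            )
        )
    pairs.sort(key=lambda p: (-abs(p.r), p.lnc_symbol, p.mrna_symbol))
    grid = pd.DataFrame(r_grid, index=lnc_probes, columns=mrna_probes)
    grid.index.name = "lnc_probe"
    return pairs, grid


def pairs_to_frame(pairs: Sequence[CoexprPair]) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in pairs], columns=PAIR_TABLE_COLUMNS)


def write_pairs_table(pairs: Sequence[CoexprPair], path: str | Path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def read_pairs_table(path: str | Path) -> list[CoexprPair]:
    df = pd.read_csv(
        path, sep="\t", dtype={c: str for c in PAIR_TABLE_COLUMNS[:4]},
        float_precision="round_trip",
    )
    return [
        CoexprPair(
            lnc_probe=row.lnc_probe,
            lnc_symbol=row.lnc_symbol,
            mrna_probe=row.mrna_probe,
            mrna_symbol=row.mrna_symbol,
            r=float(row.r),
            p_value=float(row.p_value),
            n=int(row.n),
        )
        for row in df.itertuples(index=False)
    ]


class CoexpressionScreen(BaseEstimator):
    """Scikit-learn style pairwise correlation screen between two feature
    groups of one samples x features matrix.

    Parameters give the column indices of the two groups (lncRNA-like rows
    of the grid vs mRNA-like columns); ``fit`` computes the correlation and
    p-value grids and the boolean retention mask.
    """

    def __init__(
        self,
        row_features: Sequence[int],
        col_features: Sequence[int],
        r_threshold: float = DEFAULT_R_THRESHOLD,
        alpha: float = DEFAULT_ALPHA,
    ):
        self.row_features = row_features
        self.col_features = col_features
        self.r_threshold = r_threshold
        self.alpha = alpha

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=3)
        A = X[:, np.asarray(self.row_features, dtype=int)].T
        B = X[:, np.asarray(self.col_features, dtype=int)].T
        self.r_grid_, self.p_grid_ = correlation_grid(A, B)
        self.retained_ = (
            ~np.isnan(self.r_grid_)
            & (np.abs(self.r_grid_) > self.r_threshold)
            & (self.p_grid_ < self.alpha)
        )
        self.n_features_in_ = X.shape[1]
        return self

    def pairs(self) -> pd.DataFrame:
        check_is_fitted(self, "r_grid_")
        i, j = np.nonzero(self.retained_)
        return pd.DataFrame(
            {
                "row_feature": np.asarray(self.row_features)[i],
                "col_feature": np.asarray(self.col_features)[j],
                "r": self.r_grid_[i, j],
                "p_value": self.p_grid_[i, j],
            }
        )
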