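"""Two-group differential expression on log2 intensities.

The test is the classical pooled-variance Student's t with
df = n1 + n2 - 2; a probe is called ``up`` when log2FC > 1 (fold change
strictly greater than 2) and p < 0.05, ``down`` for log2FC < -1 and
p < 0.05, otherwise ``ns``. Both inequalities are strict. Fold change is
oriented case minus control, so ``up`` means higher in the case group.
Benjamini-Hochberg adjusted p-values are reported alongside and can replace
the raw-p criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted
from statsmodels.stats.multitest import multipletests

from .errors import StateError, ValidationError
from .io_formats import ExpressionMatrix, ProbeAnnotation

DEFAULT_LOG2FC_THRESHOLD = 1.0
DEFAULT_ALPHA = 0.05

DE_TABLE_COLUMNS = (
    "probe_id",
    "gene_symbol",
    "biotype",
    "mean_case",
    "mean_control",
    "log2fc",
    "t_stat",
    "p_value",
    "adj_p",
    "status",
    "degenerate_flag",
)


@dataclass
class DEResult:
    """Per-probe differential-expression summary."""

    probe_id: str
    gene_symbol: str
    biotype: str
    mean_case: float
    mean_control: float
    log2fc: float
    t_stat: float
    p_value: float
    adj_p: float
    status: str
    degenerate_flag: bool


def _t_test_arrays(
    case: np.ndarray, control: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sided t-test over the rows of two probes x samples
    blocks. Zero pooled variance is flagged: equal means give (t=0, p=1),
    unequal means the signed-infinity sentinel with p=0."""
    case = np.ascontiguousarray(case, dtype=float)
    control = np.ascontiguousarray(control, dtype=float)
    n1, n2 = case.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least 2 samples")
    m1, m2 = case.mean(axis=1), control.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = control.var(axis=1, ddof=1)
    diff = m1 - m2
    if equal_var:
        df = np.full(m1.shape, float(n1 + n2 - 2))
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    else:
        a, b = v1 / n1, v2 / n2
        se = np.sqrt(a + b)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    degenerate = se == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, diff / np.where(degenerate, 1.0, se))
        p = 2.0 * stats.t.sf(np.abs(t), np.where(degenerate, 1.0, df))
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate & (diff != 0), np.sign(diff) * np.inf, t)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    return t, p, degenerate


def t_test_two_group(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> tuple[float, float, bool]:
    """Pooled-variance Student's t for one probe.

    Returns ``(t, p, degenerate_flag)``; see `_t_test_arrays` for the
    zero-variance conventions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValidationError("expected 1-D value vectors")
    t, p, flag = _t_test_arrays(x[None, :], y[None, :], equal_var=equal_var)
    return float(t[0]), float(p[0]), bool(flag[0])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_status(
    log2fc: np.ndarray,
    p: np.ndarray,
    fc_log2: float = DEFAULT_LOG2FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    """Volcano classification with strict thresholds on both axes."""
    log2fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p, dtype=float)
    status = np.full(log2fc.shape, "ns", dtype=object)
    status[(log2fc > fc_log2) & (p < alpha)] = "up"
    status[(log2fc < -fc_log2) & (p < alpha)] = "down"
    return status


def differential_expression(
    m: ExpressionMatrix,
    ann: ProbeAnnotation,
    case_label: str,
    control_label: str,
    fc_log2: float = DEFAULT_LOG2FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    use_adjusted: bool = False,
    equal_var: bool = True,
) -> list[DEResult]:
    """Test every probe for a case-vs-control shift on the log2 scale."""
    if m.scale != "log2":
        raise StateError("differential expression expects a log2-scale matrix")
    for label in (case_label, control_label):
        if label not in m.groups.values():
            raise ValidationError(f"group label {label!r} absent from sample groups")
    unannotated = [p for p in m.probe_ids if p not in ann]
    if unannotated:
        raise ValidationError(
            f"{len(unannotated)} probes missing from the annotation "
            f"(first: {unannotated[0]!r})"
        )
    case_cols = m.samples_in_group(case_label)
    control_cols = m.samples_in_group(control_label)
    case = m.data[case_cols].to_numpy(dtype=float)
    control = m.data[control_cols].to_numpy(dtype=float)
    t, p, degenerate = _t_test_arrays(case, control, equal_var=equal_var)
    mean_case = case.mean(axis=1)
    mean_control = control.mean(axis=1)
    log2fc = mean_case - mean_control
    adj_p = bh_adjust(p)
    status = classify_status(log2fc, adj_p if use_adjusted else p, fc_log2, alpha)
    ann_table = ann.table
    symbols = ann_table.loc[m.probe_ids, "gene_symbol"].to_numpy()
    biotypes = ann_table.loc[m.probe_ids, "biotype"].to_numpy()
    return [
        DEResult(
            probe_id=pid,
            gene_symbol=symbols[i],
            biotype=biotypes[i],
            mean_case=float(mean_case[i]),
            mean_control=float(mean_control[i]),
            log2fc=float(log2fc[i]),
            t_stat=float(t[i]),
            p_value=float(p[i]),
            adj_p=float(adj_p[i]),
            status=str(status[i]),
            degenerate_flag=bool(degenerate[i]),
        )
        for i, pid in enumerate(m.probe_ids)
    ]


def volcano_table(results: Sequence[DEResult], cap: float = 350.0) -> pd.DataFrame:
    """Per-probe (log2fc, -log10 p, status) table for volcano plotting.

    Exact-zero p-values (the degenerate sentinel) are capped at ``cap``.
    """
    rows = []
    for r in results:
        if r.p_value == 0.0:
            y = cap
        else:
            y = min(-np.log10(r.p_value), cap)
        rows.append((r.probe_id, r.biotype, r.log2fc, y, r.status))
    return pd.DataFrame(
        rows, columns=["probe_id", "biotype", "log2fc", "neg_log10_p", "status"]
    )


def de_counts(results: Sequence[DEResult]) -> dict[str, int]:
    """Up/down counts split by biotype, as reported in the run manifest."""
    counts = {
        "up_lncRNA": 0,
        "down_lncRNA": 0,
        "up_mRNA": 0,
        "down_mRNA": 0,
    }
    for r in results:
        if r.status in ("up", "down"):
            counts[f"{r.status}_{r.biotype}"] += 1
    return counts


def results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in results], columns=DE_TABLE_COLUMNS)
    return df


def write_de_table(results: Sequence[DEResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> list[DEResult]:
    df = pd.read_csv(
        path, sep="\t", dtype={"probe_id": str, "gene_symbol": str},
        float_precision="round_trip",
    )
    return [
        DEResult(
            probe_id=row.probe_id,
            gene_symbol=row.gene_symbol,
            biotype=row.biotype,
            mean_case=float(row.mean_case),
            mean_control=float(row.mean_control),
            log2fc=float(row.log2fc),
            t_stat=float(row.t_stat),
            p_value=float(row.p_value),
            adj_p=float(row.adj_p),
            status=row.status,
            degenerate_flag=bool(row.degenerate_flag),
        )
        for row in df.itertuples(index=False)
    ]


class PooledTTestDE(BaseEstimator):
    """Scikit-learn style two-group differential-expression selector.

    ``fit(X, y)`` takes a samples x probes matrix and a vector of group
    labels, computes per-feature pooled-t statistics and the volcano status,
    and exposes them as fitted attributes; ``transform`` keeps the
    differentially expressed features.
    """

    def __init__(
        self,
        case_label: str,
        control_label: str,
        fc_log2: float = DEFAULT_LOG2FC_THRESHOLD,
        alpha: float = DEFAULT_ALPHA,
        use_adjusted: bool = False,
        equal_var: bool = True,
    ):
        self.case_label = case_label
        self.control_label = control_label
        self.fc_log2 = fc_log2
        self.alpha = alpha
        self.use_adjusted = use_adjusted
        self.equal_var = equal_var

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValidationError("y must have one label per sample (row)")
        case_mask = y == self.case_label
        control_mask = y == self.control_label
        if not case_mask.any() or not control_mask.any():
            raise ValidationError("both group labels must be present in y")
        case = X[case_mask].T
        control = X[control_mask].T
        t, p, degenerate = _t_test_arrays(case, control, equal_var=self.equal_var)
        self.log2fc_ = case.mean(axis=1) - control.mean(axis=1)
        self.t_stat_ = t
        self.p_value_ = p
        self.adj_p_ = bh_adjust(p)
        self.degenerate_ = degenerate
        self.status_ = classify_status(
            self.log2fc_,
            self.adj_p_ if self.use_adjusted else self.p_value_,
            self.fc_log2,
            self.alpha,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "status_")
        return self.status_ != "ns"

    def transform(self, X):
        check_is_fitted(self, "status_")
        X = check_array(X, dtype=float)
        return X[:, self.get_support()]
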