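"""Group statistics: epoch averaging, Mann-Whitney U tests with signed z,
Benjamini-Hochberg FDR, and per-node metric correlations between layers.

Feature tables are pandas DataFrames with one row per epoch (or subject)
and columns ``subject``, ``group``, ``epoch`` plus named features; tests
compare the ``patient`` group against ``control`` (positive z means
patients > controls).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, StructureError

ID_COLUMNS = ("subject", "group", "epoch")


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in ID_COLUMNS]


def average_epochs(df: pd.DataFrame) -> pd.DataFrame:
    """Average per-epoch features into one row per subject."""
    if "subject" not in df.columns or "group" not in df.columns:
        raise StructureError("feature table needs 'subject' and 'group' columns")
    if df.empty:
        raise InsufficientDataError("empty feature table")
    feats = feature_columns(df)
    grouped = df.groupby("subject", sort=False)
    out = grouped[feats].mean()
    out.insert(0, "group", grouped["group"].first())
    out = out.reset_index()
    return out


@dataclass
class GroupTestResult:
    U: float
    z: float
    p: float


def group_test(values: np.ndarray, labels: np.ndarray) -> GroupTestResult:
    """Two-sided Mann-Whitney U test of patients vs controls.

    U is the statistic for the patient sample; the p-value is exact for
    small untied samples (scipy's automatic policy), while z uses the
    tie-corrected normal approximation and is signed so that positive
    means patients > controls.  A constant feature is degenerate: p = 1,
    z = 0, with a warning."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    x = values[labels == "patient"]
    y = values[labels != "patient"]
    if x.size == 0 or y.size == 0:
        raise StructureError("both groups must be nonempty")
    if np.ptp(values) == 0:
        warnings.warn("degenerate (constant) feature; returning p = 1", stacklevel=2)
        return GroupTestResult(U=x.size * y.size / 2.0, z=0.0, p=1.0)
    res = mannwhitneyu(x, y, alternative="two-sided", method="auto")
    u = float(res.statistic)
    n1, n2 = x.size, y.size
    mu = n1 * n2 / 2.0
    # tie-corrected variance of U
    ranks = rankdata(values)
    n = n1 + n2
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    z = (u - mu) / np.sqrt(sigma2) if sigma2 > 0 else 0.0
    return GroupTestResult(U=u, z=float(z), p=float(res.pvalue))


def fdr_adjust(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (adjusted p, reject flags)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return p_adj, reject


def node_group_stats(
    df: pd.DataFrame,
    features: list[str] | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-feature group tests with FDR correction within this family.

    ``df`` must be subject-level (use :func:`average_epochs` first)."""
    if features is None:
        features = feature_columns(df)
    labels = df["group"].to_numpy()
    rows = []
    for f in features:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = group_test(df[f].to_numpy(), labels)
        rows.append((f, r.U, r.z, r.p))
    out = pd.DataFrame(rows, columns=["feature", "U", "z", "p"])
    p_adj, reject = fdr_adjust(out["p"].to_numpy(), q=q)
    out["p_adj"] = p_adj
    out["significant"] = reject
    return out


def layer_metric_correlation(sequences: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pearson r between per-node metric sequences (e.g. each band's
    clustering profile and the multiplex profile).  Zero-variance
    sequences yield NaN entries, flagged with a warning."""
    names = list(sequences)
    arrays = [np.asarray(sequences[k], dtype=float) for k in names]
    lengths = {a.size for a in arrays}
    if len(lengths) != 1:
        raise StructureError("sequences must share one node count")
    n = len(names)
    r = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            a, b = arrays[i], arrays[j]
            if a.std() == 0 or b.std() == 0:
                if i == j and a.std() == 0:
                    pass
                warnings.warn(
                    f"zero-variance sequence in correlation ({names[i]}, {names[j]})",
                    stacklevel=2,
                )
                continue
            r[i, j] = np.corrcoef(a, b)[0, 1]
    return pd.DataFrame(r, index=names, columns=names)
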