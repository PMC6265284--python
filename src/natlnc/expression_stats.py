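"""FPKM-based differential expression, fraction-enrichment and heatmap ordering.

Differential calls use a Welch two-sample t-test on log2(FPKM + eps) with the
printed gates P < alpha and fold-change >= fc_min applied to pseudo-count-
stabilised FPKM ratios.  This is a documented stand-in for count-based
differential testing: the calls are threshold-driven, and only the gates are
part of the contract.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .errors import ConfigurationError, ValidationError
from .formats_io import ExpressionTable


@dataclass(frozen=True)
class Contrast:
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValidationError(f"contrast {self.label!r}: groups overlap")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValidationError(
                f"contrast {self.label!r}: each group needs >= 2 samples"
            )


def fpkm_max(expr: ExpressionTable, feature_id: str) -> float:
    """Maximum FPKM of a feature over all samples."""
    if feature_id not in expr.values.index:
        raise KeyError(f"feature {feature_id!r} not in expression table")
    return float(expr.values.loc[feature_id].max())


def _welch_p(la: np.ndarray, lb: np.ndarray) -> np.ndarray:
    """Two-sided Welch p-values per row, with the zero-variance convention:
    both groups constant -> p = 1 if the means agree else p = 0."""
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trigger a precision warning; handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    va = la.var(axis=1, ddof=1)
    vb = lb.var(axis=1, ddof=1)
    degenerate = (va == 0) & (vb == 0)
    if degenerate.any():
        same = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
    return p


def differential_call(
    expr: ExpressionTable,
    contrast: Contrast,
    alpha: float = 0.05,
    fc_min: float = 2.0,
    eps: float = 1.0,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-feature enrichment calls for one contrast.

    Returns a DataFrame (index feature_id) with mean_a, mean_b, log2fc =
    log2((mean_a+eps)/(mean_b+eps)), pvalue (two-sided Welch on
    log2(FPKM+eps)) and status in {enriched_a, enriched_b, ns}.  With
    ``fdr=True`` the gate is applied to Benjamini-Hochberg-adjusted p-values.
    """
    missing = [s for s in (*contrast.group_a, *contrast.group_b)
               if s not in expr.values.columns]
    if missing:
        raise ConfigurationError(f"samples not in matrix: {missing}")
    a = expr.values[list(contrast.group_a)].to_numpy(dtype=float)
    b = expr.values[list(contrast.group_b)].to_numpy(dtype=float)
    p = _welch_p(np.log2(a + eps), np.log2(b + eps))
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_a + eps) / (mean_b + eps))

    p_gate = p
    if fdr:
        p_gate = stats.false_discovery_control(p, method="bh")
    thr = np.log2(fc_min)
    status = np.where(
        (p_gate < alpha) & (log2fc >= thr), "enriched_a",
        np.where((p_gate < alpha) & (log2fc <= -thr), "enriched_b", "ns"),
    )
    return pd.DataFrame(
        dict(mean_a=mean_a, mean_b=mean_b, log2fc=log2fc, pvalue=p, status=status),
        index=expr.values.index,
    )


def fraction_enrichment(
    expr: ExpressionTable,
    fraction_a: str,
    fraction_b: str,
    alpha: float = 0.05,
    fc_min: float = 2.0,
    eps: float = 1.0,
    fdr: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Enrichment calls between two fraction sample groups (e.g. poly(A)+/-).

    Returns the per-feature call table and summary counts per status.
    """
    group_a = expr.samples_where(fraction=fraction_a)
    group_b = expr.samples_where(fraction=fraction_b)
    for name, group in ((fraction_a, group_a), (fraction_b, group_b)):
        if not group:
            raise ConfigurationError(f"no samples with fraction {name!r}")
    contrast = Contrast(tuple(group_a), tuple(group_b),
                        label=f"{fraction_a}_vs_{fraction_b}")
    calls = differential_call(expr, contrast, alpha, fc_min, eps, fdr)
    counts = calls["status"].value_counts().to_dict()
    summary = {
        "enriched_a": counts.get("enriched_a", 0),
        "enriched_b": counts.get("enriched_b", 0),
        "ns": counts.get("ns", 0),
    }
    return calls, summary


@dataclass
class ClusteringResult:
    order: list[str]
    labels: pd.Series  # cluster label (1..k) per feature
    k: int
    seed: int


def kmeans_order(
    expr_subset: pd.DataFrame, k: int, seed: int
) -> ClusteringResult:
    """Heatmap row ordering: k-means on row-fractional densities.

    Rows are scaled to fractional density (row / row max, all-zero rows stay
    zero), clustered with k-means (k-means++ init, 10 restarts, best inertia),
    and ordered by cluster profile peak position, then by each feature's own
    peak position, then feature id.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if k > len(expr_subset):
        raise ConfigurationError(
            f"k={k} exceeds number of features {len(expr_subset)}"
        )
    mat = expr_subset.to_numpy(dtype=float)
    rowmax = mat.max(axis=1, keepdims=True)
    scaled = np.divide(mat, rowmax, out=np.zeros_like(mat), where=rowmax > 0)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw_labels = km.fit_predict(scaled)

    positions = np.arange(scaled.shape[1])

    def centre_of_mass(profile: np.ndarray) -> float:
        tot = profile.sum()
        return float((profile * positions).sum() / tot) if tot > 0 else 0.0

    cluster_pos = {
        c: centre_of_mass(km.cluster_centers_[c]) for c in range(k)
    }
    feature_pos = [centre_of_mass(row) for row in scaled]
    cluster_rank = {
        c: r for r, c in enumerate(sorted(range(k), key=lambda c: (cluster_pos[c], c)))
    }
    ids = list(expr_subset.index)
    order = sorted(
        range(len(ids)),
        key=lambda i: (cluster_rank[raw_labels[i]], feature_pos[i], ids[i]),
    )
    labels = pd.Series(
        [cluster_rank[raw_labels[i]] + 1 for i in range(len(ids))],
        index=expr_subset.index, name="cluster",
    )
    return ClusteringResult(
        order=[ids[i] for i in order], labels=labels, k=k, seed=seed
    )
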