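"""Lipidome statistics: log10 transform, autoscaling, Welch tests with
BH-FDR, volcano classification, Ward clustering and essentiality-
metabolite correlation.

The processing chain mirrors a one-factor metabolomics workflow:
raw intensities -> log10 (zeros replaced by one fifth of each feature's
minimum positive value, flagged) -> per-feature autoscaling (mean 0,
sample s.d. 1).  Tests run on the processed matrix while fold changes
are always computed on raw group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.cluster import hierarchy as _h
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .tables import LipidomeTable

__all__ = [
    "LipidomeTable",
    "log10_transform",
    "autoscale",
    "differential_test",
    "volcano_classify",
    "hierarchical_cluster",
    "essentiality_correlation",
    "ClusterResult",
]


def log10_transform(table: LipidomeTable) -> LipidomeTable:
    """Elementwise log10 of a raw table.

    Zeros/missing values are replaced by one fifth of the feature's
    minimum positive value before taking logs (a feature with no
    positive value at all is left as NaN); replaced cells are flagged.
    """
    if table.state != "raw":
        raise ValueError(f"log10_transform expects a raw table, got {table.state!r}")
    x = table.values.copy()
    flags = pd.DataFrame(False, index=x.index, columns=x.columns)
    for feat in x.index:
        row = x.loc[feat]
        bad = (row <= 0) | row.isna()
        if bad.any():
            pos = row[row > 0]
            if pos.empty:
                x.loc[feat] = np.nan
                continue
            x.loc[feat, bad] = pos.min() / 5.0
            flags.loc[feat, bad] = True
    return table.advanced(np.log10(x), "log10", flags=flags)


def autoscale(table: LipidomeTable) -> LipidomeTable:
    """Per-feature centring and unit-variance scaling (n-1 s.d.).
    Constant features map to all-zero rows."""
    if table.state != "log10":
        raise ValueError(f"autoscale expects a log10 table, got {table.state!r}")
    x = table.values
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    scaled = x.sub(mu, axis=0).div(sd.where(sd > 0, np.inf), axis=0)
    return table.advanced(scaled, "autoscaled")


def differential_test(
    table: LipidomeTable, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-feature Welch two-sided t-test (group_a vs group_b) on the
    processed matrix, BH q-values, and log2 fold change of raw group
    means (a over b).

    Returns a DataFrame with columns ``log2_fc``, ``fold_change``,
    ``t``, ``p``, ``q`` indexed by feature.
    """
    cols_a = table.samples_in_group(group_a)
    cols_b = table.samples_in_group(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    xa = table.values[cols_a].values
    xb = table.values[cols_b].values
    t, p = _sps.ttest_ind(xa, xb, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")

    raw = table.raw if table.raw is not None else table.values
    mean_a = raw[cols_a].mean(axis=1).values
    mean_b = raw[cols_b].mean(axis=1).values
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_a / mean_b
        log2fc = np.log2(fc)
    return pd.DataFrame(
        {"log2_fc": log2fc, "fold_change": fc, "t": t, "p": p, "q": q},
        index=table.features,
    )


def volcano_classify(
    results: pd.DataFrame, fc_threshold: float = 2.0, q_threshold: float = 0.05
) -> pd.Series:
    """Label features up/down/ns by the |fold change| > threshold and
    q < threshold rules (strict inequalities)."""
    fc = results["fold_change"]
    sig = results["q"] < q_threshold
    up = sig & (fc > fc_threshold)
    down = sig & (fc < 1.0 / fc_threshold)
    labels = pd.Series("ns", index=results.index)
    labels[up] = "up"
    labels[down] = "down"
    return labels


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: pd.Series
    leaf_order: list[str]


def hierarchical_cluster(
    table: LipidomeTable, n_clusters: int = 2,
    metric: str = "euclidean", method: str = "ward",
) -> ClusterResult:
    """Agglomerative clustering of features (Ward linkage on Euclidean
    distances by default); deterministic, with a stable leaf order."""
    x = table.values.values
    z = _h.linkage(pdist(x, metric=metric), method=method)
    labels = pd.Series(
        _h.fcluster(z, t=n_clusters, criterion="maxclust"), index=table.features
    )
    order = [table.features[i] for i in _h.leaves_list(z)]
    return ClusterResult(linkage=z, labels=labels, leaf_order=order)


def essentiality_correlation(
    metabolites: pd.DataFrame, essentiality: pd.Series
) -> pd.DataFrame:
    """Pearson correlation of each metabolite (row) with a per-sample
    essentiality score, with two-sided p-values and BH q-values.

    NaNs are handled pairwise-complete per metabolite; metabolites with
    fewer than 3 complete pairs or zero variance get NaN r and are
    flagged in the ``flag`` column.
    """
    essentiality = essentiality.reindex(metabolites.columns)
    rows = []
    for feat in metabolites.index:
        x = metabolites.loc[feat]
        ok = x.notna() & essentiality.notna()
        n = int(ok.sum())
        xi, yi = x[ok].values, essentiality[ok].values
        if n < 3 or np.std(xi) == 0 or np.std(yi) == 0:
            rows.append({"feature": feat, "r": np.nan, "p": np.nan,
                         "n": n, "flag": "undefined"})
            continue
        r, p = _sps.pearsonr(xi, yi)
        rows.append({"feature": feat, "r": r, "p": p, "n": n, "flag": ""})
    out = pd.DataFrame(rows).set_index("feature")
    mask = out["p"].notna()
    q = pd.Series(np.nan, index=out.index)
    if mask.any():
        _, qv, _, _ = multipletests(out.loc[mask, "p"].values, method="fdr_bh")
        q[mask] = qv
    out["q"] = q
    return out
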