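"""Connectivity-biomarker association with FDR control.

Spearman rank correlations (Pearson behind a flag) between per-subject
connectivity — the network average and every single directed connection,
self-connections included — and a per-subject covariate such as serum
neurofilament light chain. p-values are Benjamini-Hochberg adjusted within
each (condition, measure) family of single connections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ncreann import network_average


def rank_correlation(x, y, method: str = "spearman") -> tuple[float, float]:
    """Correlation coefficient and two-sided p.

    Spearman uses average ranks for ties and the t approximation for p.
    Raises on zero variance in either vector.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return float(r), float(p)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def associate(connectivity: pd.DataFrame, covariate: pd.DataFrame,
              method: str = "spearman", value_col: str = "raw",
              include_network_average: bool = True) -> pd.DataFrame:
    """Correlate connectivity with a covariate, FDR within each family.

    Parameters
    ----------
    connectivity
        Tidy per-subject table with columns ``subject, condition, measure,
        source, target`` and the value column (default ``raw``) — one row
        per subject per directed connection per measure per condition.
    covariate
        Table with columns ``subject, value`` (e.g. the biomarker).

    Returns a report with one row per (condition, measure, connection) plus,
    optionally, a ``network`` row per (condition, measure) averaging the
    non-self connections. Single-connection p-values are BH-adjusted within
    each (condition, measure) family (self-connections included, matching a
    16-row family for four nodes); network rows are adjusted within the
    network-row family per condition. Subjects missing from either table are
    dropped pairwise; fewer than 5 complete pairs is an error.
    """
    cov = covariate.set_index("subject")["value"]
    rows = []
    for (cond, measure), g in connectivity.groupby(["condition", "measure"],
                                                   sort=True):
        wide = g.pivot_table(index="subject", columns=["source", "target"],
                             values=value_col)
        common = wide.index.intersection(cov.index)
        if len(common) < 5:
            raise ValueError(
                f"fewer than 5 complete subject pairs for ({cond}, {measure})")
        wide = wide.loc[common]
        cv = cov.loc[common].to_numpy()
        conn_rows = []
        for (src, tgt) in wide.columns:
            r, p = rank_correlation(wide[(src, tgt)].to_numpy(), cv, method)
            conn_rows.append({"condition": cond, "measure": measure,
                              "connection": f"{src} -> {tgt}",
                              "rho": r, "p": p, "n": len(common)})
        padj = fdr_adjust([r["p"] for r in conn_rows])
        for row, pa in zip(conn_rows, padj):
            row["p_fdr"] = float(pa)
        rows.extend(conn_rows)
        if include_network_average:
            nodes = sorted({s for s, _ in wide.columns})
            net = []
            for subj in common:
                mat = np.array([[wide.loc[subj, (i, j)] for j in nodes]
                                for i in nodes])
                net.append(network_average(mat))
            r, p = rank_correlation(np.asarray(net), cv, method)
            rows.append({"condition": cond, "measure": measure,
                         "connection": "network", "rho": r, "p": p,
                         "n": len(common), "p_fdr": np.nan})
    report = pd.DataFrame(rows)
    net_mask = report.connection == "network"
    if net_mask.any():
        for cond, g in report[net_mask].groupby("condition"):
            report.loc[g.index, "p_fdr"] = fdr_adjust(g.p.to_numpy())
    report["method"] = method
    return report.reset_index(drop=True)


def connectivity_long_table(per_subject: dict, node_names=None) -> pd.DataFrame:
    """Stack per-subject :class:`ConnectivityMatrices` into the tidy format
    consumed by :func:`associate`.

    ``per_subject`` maps subject id -> ConnectivityMatrices or
    {condition -> ConnectivityMatrices}.
    """
    frames = []
    for subject, cms in per_subject.items():
        if not isinstance(cms, dict):
            cms = {cms.condition or "all": cms}
        for cond, cm in cms.items():
            df = cm.to_frame()
            df["condition"] = cond
            df["subject"] = subject
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
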