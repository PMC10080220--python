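"""Differential expression via edge scores on the global graph.

The selection of differentially expressed genes (DEGs) here is statistical
rather than cutoff-based: every undirected edge (X, Y) of the global
interaction graph receives the score

    EdgeScore_XY = |FC_X| * (1 - pX) + |FC_Y| * (1 - pY)

where FC is the log2 fold-change of the knockout-vs-control contrast and p
its moderated-t p-value.  Sorting all edge scores in descending order yields
a curve with a sharp elevated head followed by a long flat tail; a single
mean-shift change point separates the two regimes and defines three
high-edge-score (HES) thresholds:

* HES1 - the last score of the elevated segment (change-point lower
  boundary), the default, most inclusive threshold;
* HES2 - the score at rank ceil(0.75 k) of the k elevated scores, i.e. a
  25% safety margin that drops the weakest quartile of elevated edges;
* HES3 - the maximal edge score (the single strongest edge; its two
  endpoints are the top-ranked gene pair).

DEGs are the endpoints of edges at or above the chosen threshold, ranked by
their best incident edge score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats

from .kgml import GlobalGraph

__all__ = [
    "ExpressionDataset",
    "HESThresholds",
    "read_expression",
    "fit_gene_stats",
    "compute_edge_scores",
    "detect_changepoint",
    "derive_hes_thresholds",
    "select_degs",
    "extract_ko_subnetwork",
    "trigamma_inverse",
]


@dataclass
class ExpressionDataset:
    """A log2 expression matrix with a two-group knockout design.

    ``matrix`` is genes x samples; ``groups`` maps each sample name to
    ``"KO"`` or ``"CTRL"``; ``ko_genes`` names the knocked-out gene(s) in
    organism-prefixed Entrez form.
    """

    matrix: pd.DataFrame
    groups: pd.Series
    ko_genes: frozenset[str]
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        self.ko_genes = frozenset(self.ko_genes)
        if not self.ko_genes:
            raise ValueError("ko_genes must be non-empty")
        if self.matrix.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        self.groups = self.groups.reindex(self.matrix.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        bad = set(self.groups.unique()) - {"KO", "CTRL"}
        if bad:
            raise ValueError(f"group labels must be KO/CTRL, got {bad}")
        counts = self.groups.value_counts()
        if counts.get("KO", 0) < 2 or counts.get("CTRL", 0) < 2:
            raise ValueError("need at least 2 samples per group")
        missing = self.ko_genes - set(self.matrix.index)
        if missing:
            warnings.warn(
                f"{self.dataset_id}: KO gene(s) not in expression matrix: "
                f"{sorted(missing)}",
                stacklevel=2,
            )

    @property
    def ko_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "KO"])

    @property
    def ctrl_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "CTRL"])


def read_expression(
    matrix_path: str | Path,
    design_path: str | Path,
    ko_genes: Iterable[str],
    dataset_id: str = "dataset",
) -> ExpressionDataset:
    """Read a tab-delimited expression matrix plus (sample, group) design."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t")
    groups = pd.Series(design["group"].values, index=design["sample"].values)
    return ExpressionDataset(
        matrix=matrix,
        groups=groups,
        ko_genes=frozenset(ko_genes),
        dataset_id=dataset_id,
    )


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma_inverse requires x > 0")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def _estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (d0, s0^2) on log variances.

    Matches the first two moments of log(s^2) against the theoretical
    log-F distribution: e = log(s2) - digamma(df/2) + log(df/2) has mean
    log(s0^2) + digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2).
    """
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_2 = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_2 = math.exp(e_mean)
    return d0, s0_2


def fit_gene_stats(
    dataset: ExpressionDataset,
    *,
    moderation: bool = True,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene log2 fold-change and (moderated) two-sample t statistics.

    With ``moderation`` on, gene-wise pooled variances are shrunk toward an
    empirical-Bayes prior: s2_post = (d0*s0^2 + d*s2) / (d0 + d) with
    (d0, s0^2) estimated across genes by moment matching on log variances;
    the t statistic then has d0 + d degrees of freedom.  With moderation
    off this is exactly the ordinary pooled-variance two-sample t-test.
    ``prior_df`` overrides the estimated d0 (``math.inf`` forces complete
    shrinkage to s0^2).

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``t``,
    ``p``, ``df_resid``, ``df_prior``, ``s2_post``; hyperparameters and the
    number of dropped (missing-value) genes are in ``.attrs``.
    """
    X = dataset.matrix
    complete = ~X.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(
            f"{dataset.dataset_id}: dropping {n_dropped} gene(s) with missing values",
            stacklevel=2,
        )
        X = X.loc[complete]
    if X.empty:
        raise ValueError("no genes with complete data")

    ko = X[dataset.ko_samples].to_numpy(float)
    ct = X[dataset.ctrl_samples].to_numpy(float)
    n1, n2 = ko.shape[1], ct.shape[1]
    df_resid = float(n1 + n2 - 2)

    m1, m2 = ko.mean(axis=1), ct.mean(axis=1)
    v1, v2 = ko.var(axis=1, ddof=1), ct.var(axis=1, ddof=1)
    if np.all(v1 == 0) or np.all(v2 == 0):
        raise ValueError("a group has zero variance for every gene")
    log2fc = m1 - m2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid

    if moderation and len(X) < 2:
        warnings.warn(
            "moderation needs >= 2 genes; falling back to ordinary t",
            stacklevel=2,
        )
        moderation = False

    if moderation:
        positive = s2[s2 > 0]
        if len(positive) < 2:
            warnings.warn(
                "too few positive variances for moderation; ordinary t used",
                stacklevel=2,
            )
            moderation = False

    if moderation:
        d0, s0_2 = _estimate_variance_prior(s2[s2 > 0], df_resid)
        if prior_df is not None:
            d0 = float(prior_df)
        if math.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid
    else:
        d0, s0_2 = 0.0, float("nan")
        s2_post = s2
        df_total = df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (log2fc != 0), np.sign(log2fc) * np.inf, t)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "df_resid": df_resid,
            "df_prior": d0,
            "s2_post": s2_post,
        },
        index=X.index,
    )
    out.attrs.update(
        {
            "moderation": moderation,
            "df_prior": d0,
            "s2_prior": s0_2,
            "n_dropped": n_dropped,
            "dataset_id": dataset.dataset_id,
        }
    )
    return out


def compute_edge_scores(stats_df: pd.DataFrame, graph: GlobalGraph) -> pd.DataFrame:
    """Score every measured undirected global-graph edge.

    score = |FC_X|(1 - pX) + |FC_Y|(1 - pY); edges with an unmeasured
    endpoint are skipped (count in ``.attrs['n_skipped']``).  Rows are
    sorted by descending score, ties broken by the canonical gene pair.
    """
    measured = stats_df.index
    keys = sorted(graph.undirected_edge_keys)
    mask = [a in measured and b in measured for a, b in keys]
    scored = [k for k, m in zip(keys, mask) if m]
    n_skipped = len(keys) - len(scored)
    if not scored:
        raise ValueError("no scorable edges: graph and measured genes are disjoint")
    gx = [a for a, _ in scored]
    gy = [b for _, b in scored]
    fc = stats_df["log2fc"]
    p = stats_df["p"]
    score = (
        fc.loc[gx].abs().to_numpy() * (1.0 - p.loc[gx].to_numpy())
        + fc.loc[gy].abs().to_numpy() * (1.0 - p.loc[gy].to_numpy())
    )
    table = pd.DataFrame({"gene_x": gx, "gene_y": gy, "score": score})
    table = table.sort_values(
        ["score", "gene_x", "gene_y"], ascending=[False, True, True]
    ).reset_index(drop=True)
    table.attrs["n_skipped"] = n_skipped
    return table


def detect_changepoint(scores: np.ndarray | Iterable[float]) -> int:
    """Single mean-shift change point of a descending score sequence.

    Exact at-most-one-change segmentation: the split index k minimising the
    total within-segment sum of squared deviations over both segments.  The
    returned index is the first position of the flat (right) segment
    (0-based, in [1, n-1]); ties resolve to the smallest index.
    """
    s = np.asarray(list(scores) if not isinstance(scores, np.ndarray) else scores, float)
    n = s.size
    if n < 4:
        raise ValueError("need at least 4 scores for change-point detection")
    if np.ptp(s) == 0:
        raise ValueError("degenerate distribution: all scores equal")
    c1 = np.cumsum(s)
    c2 = np.cumsum(s * s)
    total1, total2 = c1[-1], c2[-1]
    k = np.arange(1, n)  # split: left = s[:k], right = s[k:]
    left = c2[k - 1] - c1[k - 1] ** 2 / k
    right = (total2 - c2[k - 1]) - (total1 - c1[k - 1]) ** 2 / (n - k)
    cost = left + right
    return int(k[np.argmin(cost)])


@dataclass(frozen=True)
class HESThresholds:
    """The three high-edge-score thresholds derived from the change point."""

    hes1: float
    hes2: float
    hes3: float
    changepoint_index: int

    def get(self, which: str) -> float:
        which = which.upper().replace("HES", "")
        return {"1": self.hes1, "2": self.hes2, "3": self.hes3}[which]

    def to_dict(self) -> dict[str, float | int]:
        return {
            "hes1": self.hes1,
            "hes2": self.hes2,
            "hes3": self.hes3,
            "changepoint_index": self.changepoint_index,
        }


def derive_hes_thresholds(
    scores: pd.DataFrame | np.ndarray | Iterable[float],
    changepoint_index: int,
) -> HESThresholds:
    """HES1/HES2/HES3 from the descending score sequence and its change point.

    The k = changepoint_index scores before the change point form the
    elevated segment: HES1 is its last (smallest) score, HES3 the maximal
    score, and HES2 the score at 1-based rank ceil(0.75 k) — excluding the
    weakest quartile of elevated edges as a safety margin.
    """
    if isinstance(scores, pd.DataFrame):
        s = scores["score"].to_numpy(float)
    else:
        s = np.asarray(list(scores) if not isinstance(scores, np.ndarray) else scores, float)
    n = s.size
    if not 1 <= changepoint_index <= n - 1:
        raise ValueError(f"changepoint_index {changepoint_index} outside [1, {n - 1}]")
    k = changepoint_index
    hes3 = float(s[0])
    hes1 = float(s[k - 1])
    if k == 1:
        warnings.warn(
            "single elevated edge: HES1 = HES2 = HES3", stacklevel=2
        )
        hes2 = hes1
    else:
        hes2 = float(s[math.ceil(0.75 * k) - 1])
    return HESThresholds(hes1=hes1, hes2=hes2, hes3=hes3, changepoint_index=k)


def select_degs(
    edge_scores: pd.DataFrame,
    threshold: float,
    stats_df: pd.DataFrame,
    *,
    threshold_label: str | None = None,
) -> pd.DataFrame:
    """DEGs = endpoints of edges scoring at or above the threshold.

    Genes are ranked by their best qualifying incident edge score
    (descending, ties broken by gene id).  Returns a DataFrame indexed by
    gene with ``best_edge_score``, ``log2fc``, ``p`` and 1-based ``rank``.
    """
    qualifying = edge_scores[edge_scores["score"] >= threshold]
    long = pd.concat(
        [
            qualifying[["gene_x", "score"]].rename(columns={"gene_x": "gene"}),
            qualifying[["gene_y", "score"]].rename(columns={"gene_y": "gene"}),
        ]
    )
    if long.empty:
        out = pd.DataFrame(
            columns=["best_edge_score", "log2fc", "p", "rank"]
        ).rename_axis("gene")
    else:
        best = (
            long.groupby("gene")["score"]
            .max()
            .rename("best_edge_score")
            .reset_index()
            .sort_values(
                ["best_edge_score", "gene"], ascending=[False, True]
            )
            .set_index("gene")
        )
        out = best
        out["log2fc"] = stats_df["log2fc"].reindex(out.index)
        out["p"] = stats_df["p"].reindex(out.index)
        out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["threshold"] = float(threshold)
    out.attrs["threshold_used"] = threshold_label or f"score>={threshold:g}"
    return out


def extract_ko_subnetwork(degs: pd.DataFrame, graph: GlobalGraph) -> nx.MultiDiGraph:
    """Induced subgraph of the global graph on the DEG set.

    Nodes carry log2fc, p and rank annotations; all global-graph edges with
    both endpoints in the DEG set are retained.
    """
    g = nx.MultiDiGraph()
    deg_set = set(degs.index)
    for gene in sorted(deg_set):
        row = degs.loc[gene]
        g.add_node(
            gene,
            log2fc=float(row["log2fc"]),
            p=float(row["p"]),
            rank=int(row["rank"]),
            best_edge_score=float(row["best_edge_score"]),
        )
    for e in graph.edges:
        if e.source in deg_set and e.target in deg_set:
            g.add_edge(
                e.source,
                e.target,
                relation=e.relation,
                sign=e.sign,
                pathway_ids=",".join(sorted(e.pathway_ids)),
            )
    return g
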