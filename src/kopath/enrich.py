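"""Pathway enrichment methods behind a uniform interface.

Three methods are implemented natively:

* **ORA** — upper-tail hypergeometric over-representation of the DEG set in
  each pathway's gene set;
* **GSEA_PERM** — weighted Kolmogorov-Smirnov enrichment score on the
  signed moderated-t ranking with gene-label permutation p-values;
* **SPIA** — signaling pathway impact analysis combining over-representation
  evidence (pNDE) with topological perturbation evidence (pPERT).  The
  perturbation factor of each gene solves PF = dE + B.PF where B is the
  out-degree-normalised signed adjacency matrix, i.e. (I - B) PF = dE;
  tA = sum(PF - dE) is the total net accumulated perturbation, its
  significance assessed by a bootstrap that reassigns observed DE
  fold-changes to random pathway genes.  pNDE and pPERT combine by the
  adjusted Fisher product pG = c - c ln c with c = pNDE * pPERT.

Externally produced per-pathway p-value tables plug in through the
``EXTERNAL:<name>`` method id, so methods not re-implemented here (SAFE,
GSA, PADOG, impact-analysis variants, ...) can still be benchmarked.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .kgml import DEFAULT_BETA, GlobalGraph, PathwayGraph, pathway_beta_matrices

__all__ = [
    "MethodSpec",
    "run_ora",
    "run_gsea_perm",
    "spia_pnde",
    "spia_perturbation",
    "spia_ppert_bootstrap",
    "combine_fisher",
    "adjust_pvalues",
    "run_method",
    "run_spia",
    "format_deg_pct",
    "write_results",
]

RESULT_COLUMNS = [
    "pathway_id",
    "name",
    "pSize",
    "pSize_all",
    "NDE",
    "pNDE",
    "tA",
    "pPERT",
    "status",
    "pG",
    "pGFdr",
    "pGBonf",
    "method_id",
]


@dataclass
class MethodSpec:
    """Which enrichment method to run and with what parameters."""

    method_id: str = "SPIA"
    permutations: int = 999
    reps: int = 2000
    seed: int = 0
    alpha: float = 0.05
    beta_map: Mapping[str, float] | None = None
    external_table: str | Path | None = None

    def to_dict(self) -> dict:
        return {
            "method_id": self.method_id,
            "permutations": self.permutations,
            "reps": self.reps,
            "seed": self.seed,
            "alpha": self.alpha,
            "beta_map": dict(self.beta_map) if self.beta_map else None,
            "external_table": str(self.external_table)
            if self.external_table
            else None,
        }


def run_ora(
    deg_genes: Iterable[str],
    pathway_genes: Iterable[str],
    universe: Iterable[str],
) -> float:
    """Upper-tail hypergeometric p-value P(X >= overlap).

    Population N = |universe|, successes K = |pathway ∩ universe|,
    draws n = |DEGs ∩ universe|.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    degs = set(deg_genes) & universe
    pw = set(pathway_genes) & universe
    overlap = len(degs & pw)
    N, K, n = len(universe), len(pw), len(degs)
    return float(stats.hypergeom.sf(overlap - 1, N, K, n))


def _es_profiles(
    abs_r: np.ndarray, hit_matrix: np.ndarray
) -> np.ndarray:
    """Weighted-KS enrichment scores for one or many hit indicator rows."""
    hit = hit_matrix.astype(float)
    n = abs_r.size
    nh = hit.sum(axis=1)
    nr = hit @ abs_r
    # guard degenerate rows (no hits / all hits) — callers exclude them
    nr = np.where(nr > 0, nr, 1.0)
    miss_w = np.where(n - nh > 0, 1.0 / np.maximum(n - nh, 1), 0.0)
    inc = hit * (abs_r / nr[:, None]) - (1.0 - hit) * miss_w[:, None]
    running = np.cumsum(inc, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(running.shape[0]), idx]


def run_gsea_perm(
    stats_df: pd.DataFrame,
    pathway_genes: Iterable[str],
    *,
    permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float] | None:
    """Gene-permutation GSEA on the signed moderated-t ranking.

    Weighted Kolmogorov-Smirnov enrichment score with weight exponent 1;
    the p-value is the add-one-smoothed fraction of random same-size gene
    sets whose |ES| meets or exceeds the observed |ES|.  Returns
    ``(ES, p)``, or ``None`` when the pathway has no measured genes.
    """
    if permutations < 100:
        raise ValueError("need at least 100 permutations")
    ranking = stats_df.assign(_gene=stats_df.index).sort_values(
        ["t", "_gene"], ascending=[False, True]
    )
    genes = ranking.index.to_numpy()
    abs_r = np.abs(ranking["t"].to_numpy(float))
    hits = np.isin(genes, list(set(pathway_genes)))
    nh = int(hits.sum())
    n = genes.size
    if nh == 0 or nh == n:
        warnings.warn("pathway has no informative measured genes for GSEA")
        return None
    es = float(_es_profiles(abs_r, hits[None, :])[0])

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((permutations, n)), axis=1)
    hit_perm = order < nh  # each row: nh random hit positions
    es_perm = _es_profiles(abs_r, hit_perm)
    exceed = int(np.sum(np.abs(es_perm) >= abs(es)))
    p = (exceed + 1) / (permutations + 1)
    return es, float(p)


def spia_pnde(
    nde: int, psize_measured: int, total_de: int, universe_size: int
) -> float:
    """Hypergeometric over-representation component of the combined evidence."""
    if universe_size <= 0:
        raise ValueError("empty universe")
    return float(stats.hypergeom.sf(nde - 1, universe_size, psize_measured, total_de))


def spia_perturbation(
    beta: "BetaMatrices",
    de_log2fc: Mapping[str, float],
) -> tuple[np.ndarray, float] | None:
    """Solve the linear perturbation propagation for one pathway.

    dE(g) is the log2 fold-change of pathway DEGs (0 for non-DEGs);
    PF solves (I - B) PF = dE and tA = sum(PF - dE).  Returns ``None``
    when I - B is (numerically) singular, mirroring the convention of
    skipping such pathways.
    """
    n = len(beta.genes)
    de = np.zeros(n)
    idx = beta.index
    for g, fc in de_log2fc.items():
        if g in idx:
            de[idx[g]] = fc
    a = np.eye(n) - beta.combined
    det = np.linalg.det(a)
    if abs(det) < 1e-10:
        return None
    pf = np.linalg.solve(a, de)
    ta = float(np.sum(pf - de))
    return pf, ta


def spia_ppert_bootstrap(
    beta: "BetaMatrices",
    de_log2fc: Mapping[str, float],
    all_de_values: Sequence[float],
    *,
    reps: int = 2000,
    seed: int = 0,
) -> tuple[float, str, float] | None:
    """Bootstrap p-value for the total net accumulated perturbation tA.

    The null draws, ``reps`` times, NDE fold-change values (with
    replacement) from the dataset-wide DE pool and assigns them to NDE
    random pathway genes; pPERT is the add-one-smoothed two-sided tail
    probability of |tA_obs - median(tA_null)|.  Status is Activated when
    tA_obs exceeds the null median, Inhibited otherwise.

    Returns ``(pPERT, status, tA_obs)``; ``None`` if I - B is singular.
    """
    if reps < 200:
        raise ValueError("need at least 200 bootstrap reps")
    de_in = {g: v for g, v in de_log2fc.items() if g in beta.index}
    nde = len(de_in)
    if nde == 0:
        return 1.0, "NA", 0.0
    obs = spia_perturbation(beta, de_in)
    if obs is None:
        return None
    _, ta_obs = obs

    n = len(beta.genes)
    a = np.eye(n) - beta.combined
    lu, piv = linalg.lu_factor(a)
    rng = np.random.default_rng(seed)
    pool = np.asarray(list(all_de_values), float)
    if pool.size == 0:
        pool = np.asarray(list(de_in.values()), float)
    values = rng.choice(pool, size=(reps, nde), replace=True)
    # nde distinct random positions per rep
    positions = np.argsort(rng.random((reps, n)), axis=1)[:, :nde]
    de_null = np.zeros((n, reps))
    rows = positions.T  # (nde, reps)
    cols = np.broadcast_to(np.arange(reps), rows.shape)
    de_null[rows, cols] = values.T
    pf_null = linalg.lu_solve((lu, piv), de_null)
    ta_null = (pf_null - de_null).sum(axis=0)

    med = float(np.median(ta_null))
    exceed = int(np.sum(np.abs(ta_null - med) >= abs(ta_obs - med)))
    ppert = (exceed + 1) / (reps + 1)
    status = "Activated" if ta_obs > med else "Inhibited"
    return float(ppert), status, ta_obs


def combine_fisher(pnde: float, ppert: float) -> float:
    """Adjusted Fisher product pG = c - c ln c with c = pNDE * pPERT.

    Equals the chi-square(4 df) survival function at -2 ln c.  Zero inputs
    are clamped to the smallest positive float with a warning.
    """
    tiny = float(np.finfo(float).tiny)  # smallest normal float
    if pnde <= 0 or ppert <= 0:
        warnings.warn("zero p-value clamped before Fisher combination")
        pnde = max(pnde, tiny)
        ppert = max(ppert, tiny)
    c = max(pnde * ppert, tiny)  # guard underflow of the product
    if c >= 1.0:
        return 1.0
    return float(c - c * math.log(c))


def adjust_pvalues(pvalues: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: BH step-up or Bonferroni."""
    p = np.asarray(list(pvalues), float)
    if p.size == 0:
        return p
    key = {"BH": "fdr_bh", "BONFERRONI": "bonferroni"}[method.upper()]
    return multipletests(p, method=key)[1]


def format_deg_pct(nde: int, psize: int) -> str:
    """Render the "NDE (pct)" cell: percent = round(100*NDE/pSize, 2)."""
    pct = 0.0 if psize == 0 else 100.0 * nde / psize
    # round half away from zero, as sprintf-style reporting does
    q = math.floor(pct * 100 + 0.5) / 100
    return f"{nde} ({q:.2f})"


def _induced_pathway(pw: PathwayGraph, genes: set[str]) -> PathwayGraph:
    kept = frozenset(pw.genes & genes)
    edges = tuple(
        e for e in pw.edges if e.source in kept and e.target in kept
    )
    return PathwayGraph(
        pathway_id=pw.pathway_id,
        name=pw.name,
        organism=pw.organism,
        genes=kept,
        edges=edges,
    )


def run_spia(
    degs: pd.DataFrame,
    stats_df: pd.DataFrame,
    collection: Sequence[PathwayGraph],
    *,
    reps: int = 2000,
    seed: int = 0,
    beta_map: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """SPIA over a pathway collection; one row per pathway with measured genes."""
    measured = set(stats_df.index)
    universe = sorted(set().union(*(pw.genes for pw in collection)) & measured)
    universe_size = len(universe)
    deg_set = set(degs.index) & set(universe)
    total_de = len(deg_set)
    de_pool = degs.loc[sorted(deg_set), "log2fc"].to_numpy(float)

    rows = []
    for i, pw in enumerate(sorted(collection, key=lambda p: p.pathway_id)):
        pm = pw.genes & measured
        if not pm:
            warnings.warn(f"pathway {pw.pathway_id} has no measured genes; skipped")
            continue
        sub = _induced_pathway(pw, pm)
        beta = pathway_beta_matrices(sub, beta_map)
        de_in = {
            g: float(stats_df.loc[g, "log2fc"]) for g in sorted(deg_set & pm)
        }
        nde = len(de_in)
        pnde = spia_pnde(nde, len(pm), total_de, universe_size)
        boot = spia_ppert_bootstrap(
            beta, de_in, de_pool, reps=reps, seed=seed + i
        )
        if boot is None:  # singular I - B: pathway unassessable, logged
            warnings.warn(
                f"pathway {pw.pathway_id}: singular perturbation system; NA"
            )
            ppert, status, ta, pg = np.nan, "NA", np.nan, np.nan
        else:
            ppert, status, ta = boot
            pg = combine_fisher(pnde, ppert)
        rows.append(
            {
                "pathway_id": pw.pathway_id,
                "name": pw.name,
                "pSize": len(pm),
                "pSize_all": pw.psize,
                "NDE": nde,
                "pNDE": pnde,
                "tA": ta,
                "pPERT": ppert,
                "status": status,
                "pG": pg,
            }
        )
    return pd.DataFrame(rows)


def _finalise(df: pd.DataFrame, method_id: str) -> pd.DataFrame:
    if df.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    valid = df["pG"].notna()
    df = df.copy()
    df["pGFdr"] = np.nan
    df["pGBonf"] = np.nan
    if valid.any():
        df.loc[valid, "pGFdr"] = adjust_pvalues(df.loc[valid, "pG"], "BH")
        df.loc[valid, "pGBonf"] = adjust_pvalues(df.loc[valid, "pG"], "Bonferroni")
    df["method_id"] = method_id
    df = df.sort_values(["pG", "pathway_id"], na_position="last").reset_index(
        drop=True
    )
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[RESULT_COLUMNS]


def run_method(
    spec: MethodSpec,
    *,
    collection: Sequence[PathwayGraph],
    stats_df: pd.DataFrame | None = None,
    degs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Dispatch one enrichment method over a pathway collection.

    Returns one row per pathway with measured genes, sorted by ascending
    pG, with BH and Bonferroni adjustments; the MethodSpec (seed included)
    is embedded in ``.attrs['method_spec']``.  Non-topology methods carry
    their single per-pathway p in the ``pG`` column; pNDE/tA/pPERT stay NA.
    """
    method = spec.method_id
    rows: list[dict] = []
    if method == "SPIA":
        if stats_df is None or degs is None:
            raise ValueError("SPIA needs stats_df and degs")
        df = run_spia(
            degs,
            stats_df,
            collection,
            reps=spec.reps,
            seed=spec.seed,
            beta_map=spec.beta_map,
        )
    elif method == "ORA":
        if stats_df is None or degs is None:
            raise ValueError("ORA needs stats_df and degs")
        measured = set(stats_df.index)
        universe = set().union(*(pw.genes for pw in collection)) & measured
        deg_set = set(degs.index) & universe
        for pw in sorted(collection, key=lambda p: p.pathway_id):
            pm = pw.genes & measured
            if not pm:
                continue
            p = run_ora(deg_set, pw.genes, universe)
            rows.append(
                {
                    "pathway_id": pw.pathway_id,
                    "name": pw.name,
                    "pSize": len(pm),
                    "pSize_all": pw.psize,
                    "NDE": len(deg_set & pm),
                    "pG": p,
                }
            )
        df = pd.DataFrame(rows)
    elif method == "GSEA_PERM":
        if stats_df is None:
            raise ValueError("GSEA needs stats_df")
        measured = set(stats_df.index)
        for i, pw in enumerate(sorted(collection, key=lambda p: p.pathway_id)):
            pm = pw.genes & measured
            if not pm:
                continue
            res = run_gsea_perm(
                stats_df,
                pw.genes,
                permutations=spec.permutations,
                seed=spec.seed + i,
            )
            if res is None:
                continue
            es, p = res
            rows.append(
                {
                    "pathway_id": pw.pathway_id,
                    "name": pw.name,
                    "pSize": len(pm),
                    "pSize_all": pw.psize,
                    "NDE": len((set(degs.index) if degs is not None else set()) & pm),
                    "tA": es,
                    "pG": p,
                }
            )
        df = pd.DataFrame(rows)
    elif method.startswith("EXTERNAL"):
        if spec.external_table is None:
            raise ValueError("EXTERNAL method needs an external_table file")
        ext = pd.read_csv(spec.external_table, sep="\t")
        if not {"pathway_id", "p"} <= set(ext.columns):
            raise ValueError("external table needs pathway_id and p columns")
        by_id = {pw.pathway_id: pw for pw in collection}
        missing = [pid for pid in by_id if pid not in set(ext["pathway_id"])]
        if missing:
            warnings.warn(
                f"external table lacks {len(missing)} collection pathway(s)"
            )
        for _, row in ext.iterrows():
            pw = by_id.get(row["pathway_id"])
            rows.append(
                {
                    "pathway_id": row["pathway_id"],
                    "name": pw.name if pw else row["pathway_id"],
                    "pSize": pw.psize if pw else np.nan,
                    "pSize_all": pw.psize if pw else np.nan,
                    "pG": float(row["p"]),
                }
            )
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown method_id {method!r}")

    out = _finalise(df, method)
    out.attrs["method_spec"] = spec.to_dict()
    return out


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a results table plus a JSON sidecar with the MethodSpec."""
    import json

    path = Path(path)
    results.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(results.attrs.get("method_spec", {}), indent=2, sort_keys=True)
        + "\n"
    )
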