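"""Shared fixtures: hand-built KGML files and the default synthetic study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kopath import (
    ExpressionDataset,
    build_global_graph,
    compute_edge_scores,
    derive_hes_thresholds,
    detect_changepoint,
    fit_gene_stats,
    select_degs,
)
from kopath.simulate import FixtureSpec, build_collection, simulate_ko_dataset

TINY_KGML = """<?xml version="1.0"?>
<pathway name="path:tst00001" org="tst" number="00001" title="tiny test pathway">
  <entry id="1" name="tst:1" type="gene"/>
  <entry id="2" name="tst:2" type="gene"/>
  <entry id="3" name="tst:3" type="gene"/>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="2" entry2="3" type="PPrel">
    <subtype name="inhibition" value="--|"/>
  </relation>
</pathway>
"""

MULTIGENE_KGML = """<?xml version="1.0"?>
<pathway name="path:tst00002" org="tst" number="00002" title="multi-gene entry">
  <entry id="1" name="tst:10 tst:11" type="gene"/>
  <entry id="2" name="tst:20" type="gene"/>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
</pathway>
"""

GROUP_KGML = """<?xml version="1.0"?>
<pathway name="path:tst00003" org="tst" number="00003" title="group entry">
  <entry id="1" name="tst:1" type="gene"/>
  <entry id="2" name="tst:2" type="gene"/>
  <entry id="3" name="tst:3" type="gene"/>
  <entry id="4" name="undefined" type="group">
    <component id="1"/>
    <component id="2"/>
  </entry>
  <relation entry1="4" entry2="3" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
</pathway>
"""

EMPTY_KGML = """<?xml version="1.0"?>
<pathway name="path:tst00004" org="tst" number="00004" title="compounds only">
  <entry id="1" name="cpd:C00076" type="compound"/>
</pathway>
"""


@pytest.fixture()
def tiny_kgml(tmp_path):
    path = tmp_path / "tst00001.xml"
    path.write_text(TINY_KGML)
    return path


@pytest.fixture(scope="session")
def default_study():
    """The default-spec synthetic study at seed 1, run through DEG selection."""
    spec = FixtureSpec(seed=1)
    collection = build_collection(spec)
    dataset = simulate_ko_dataset(spec, collection)
    stats = fit_gene_stats(dataset)
    graph = build_global_graph(collection)
    scores = compute_edge_scores(stats, graph)
    cp = detect_changepoint(scores["score"].to_numpy())
    hes = derive_hes_thresholds(scores, cp)
    degs = select_degs(scores, hes.hes1, stats, threshold_label="HES1")
    return {
        "spec": spec,
        "collection": collection,
        "dataset": dataset,
        "stats": stats,
        "graph": graph,
        "scores": scores,
        "changepoint": cp,
        "hes": hes,
        "degs": degs,
    }


def make_two_group_dataset(
    data: np.ndarray, genes: list[str], n_ko: int, n_ctrl: int, ko_genes=("g0",)
) -> ExpressionDataset:
    cols = [f"KO_{i}" for i in range(n_ko)] + [f"CTRL_{i}" for i in range(n_ctrl)]
    matrix = pd.DataFrame(data, index=genes, columns=cols)
    groups = pd.Series(["KO"] * n_ko + ["CTRL"] * n_ctrl, index=cols)
    return ExpressionDataset(
        matrix=matrix, groups=groups, ko_genes=frozenset(ko_genes), dataset_id="test"
    )
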