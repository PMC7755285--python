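import numpy as np
import pandas as pd
import pytest

from coexmod import (
    ExpressionMatrix,
    SyntheticDesign,
    simulate_expression,
)


@pytest.fixture(scope="session")
def default_design():
    """The study design every recovery test runs on: 7 stages × 3 replicates,
    5 planted modules of 200 genes, 500 background genes, kME ∈ [0.6, 0.95]."""
    return SyntheticDesign()


@pytest.fixture(scope="session")
def default_dataset(default_design):
    return simulate_expression(default_design)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, default_design):
    """One full pipeline run on the default synthetic bundle, shared by the
    integration and acceptance tests."""
    from coexmod import write_fixture_bundle
    from coexmod.pipeline import PipelineConfig, run_pipeline

    root = tmp_path_factory.mktemp("pipeline")
    paths = write_fixture_bundle(default_design, root / "fixture")
    cfg = PipelineConfig(
        expression=paths["expression"],
        sample_sheet=paths["samples"],
        out_dir=str(root / "out"),
        gmt_files=[
            (paths["modules_gmt"], "BP"),
            (paths["go_gmt"], "BP"),
            (paths["pathway_gmt"], "pathway"),
        ],
        select_go=["GO_TARGET0", "GO_TARGET1", "GO_TARGET2"],
        select_pathway=["PATHWAY0", "PATHWAY1", "PATHWAY2"],
        k_quantile=None,
        k_min=0.0,  # synthetic scale: screen on kME; quantile variant tested separately
        seed=7,
    )
    manifest = run_pipeline(cfg)
    return {"config": cfg, "manifest": manifest, "paths": paths}


def make_expression(values: np.ndarray, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n_g, n_s = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_g)]
    sample_ids = sample_ids or [f"d{10 + 10 * (j // 3)}_r{j % 3 + 1}" for j in range(n_s)]
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {"stage_day": [10 + 10 * (j // 3) for j in range(n_s)],
         "replicate": [j % 3 + 1 for j in range(n_s)]},
        index=df.columns,
    )
    return ExpressionMatrix(df, meta)
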