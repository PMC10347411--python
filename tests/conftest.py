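import numpy as np
import pytest

from brainage import (
    ModelConfig,
    TrainingConfig,
    build_graph,
    cross_validate,
    evaluate_group,
    harmonize_matrices,
    pearson_fc,
)
from brainage.connectivity import edge_table
from brainage.combat import site_f_statistics
from brainage.synthetic import default_cohort_spec, generate_cohort


def make_random_fc(R: int, seed: int = 0):
    """A valid random connectivity matrix (sample correlation of noise)."""
    from brainage.connectivity import ROITimeSeries

    rng = np.random.default_rng(seed)
    X = rng.normal(size=(4 * R, R))
    return pearson_fc(ROITimeSeries(f"rand-{seed}", X))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast low-dimensional cohort with planted signal and site effects."""
    from brainage.synthetic import CohortSpec, GroupSpec

    spec = CohortSpec(
        groups=(
            GroupSpec("HC", 0.0, 60),
            GroupSpec("AD", 5.0, 20),
        ),
        n_regions=16,
        n_sites=4,
        n_signal_edges=10,
        timeseries_length_range=(150, 250),
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_pipeline_run():
    """Full pipeline on the default synthetic cohort.

    One shared run: generation, Pearson FC, ComBat, graph construction,
    10-fold cross-validated GNN training, and patient-group evaluation.
    """
    spec = default_cohort_spec(seed=1)
    cohort = generate_cohort(spec)
    pheno = cohort.phenotypes()
    fcs = [pearson_fc(ts) for ts in cohort.timeseries]

    raw_edges = edge_table(fcs)
    f_before = site_f_statistics(
        raw_edges.drop(columns="subject_id").to_numpy(),
        pheno.set_index("subject_id").loc[raw_edges.subject_id, "site"],
    )

    harmonized, combat_model = harmonize_matrices(fcs, pheno)
    harm_edges = edge_table(harmonized)
    f_after = site_f_statistics(
        harm_edges.drop(columns="subject_id").to_numpy(),
        pheno.set_index("subject_id").loc[harm_edges.subject_id, "site"],
    )

    info = pheno.set_index("subject_id")
    groups: dict[str, list] = {}
    for fc in harmonized:
        g = build_graph(fc, threshold=0.0, age=float(info.loc[fc.subject_id, "age"]))
        groups.setdefault(str(info.loc[fc.subject_id, "group"]), []).append(g)

    model_cfg = ModelConfig(in_dim=spec.n_regions, seed=0)
    train_cfg = TrainingConfig(n_epochs=50, k_folds=10, split_seed=0)
    fold_results, summary = cross_validate(groups["HC"], model_cfg, train_cfg)
    ad_report = evaluate_group(fold_results, groups["AD"], "AD")

    return {
        "spec": spec,
        "cohort": cohort,
        "pheno": pheno,
        "raw_edge_table": raw_edges,
        "harmonized_edge_table": harm_edges,
        "site_f_before": f_before,
        "site_f_after": f_after,
        "groups": groups,
        "fold_results": fold_results,
        "cv_summary": summary,
        "ad_report": ad_report,
    }
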