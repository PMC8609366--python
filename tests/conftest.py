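import numpy as np
import pytest

from ofmri_states import (
    CohortSpec,
    GaussianHMMVB,
    StimulationParadigm,
    concatenate,
    default_ground_truth,
    pca_reduce,
    simulate_cohort,
    standardize_run,
)


def reduced_paradigm(n_blocks: int = 5, n_volumes: int = 360) -> StimulationParadigm:
    """A half-length run: 50 s baseline + 5 blocks of 10 on / 50 off + 10 s
    tail = 360 volumes, preserving the window geometry of the full design."""
    return StimulationParadigm(n_blocks=n_blocks, tail_s=10.0, n_volumes=n_volumes)


def reduced_cohort_spec() -> CohortSpec:
    """A desk-scale cohort: 6 subjects per group (vs the study's 9/10/12),
    half-length runs, same session structure as the full design."""
    return CohortSpec(
        groups={"WT-mCherry": [6], "WT-ChR2": [6, 6], "3xTgAD-ChR2": [6, 6]},
        paradigm=reduced_paradigm(),
    )


@pytest.fixture(scope="session")
def default_gt():
    return default_ground_truth()


@pytest.fixture(scope="session")
def small_gt():
    """Ground truth on 30 regions: identical planted structure, faster."""
    return default_ground_truth(n_regions=30)


@pytest.fixture(scope="session")
def fitted_reduced_cohort(default_gt):
    """Simulate a reduced cohort, preprocess, and fit a K=5 HMM (3
    repetitions, lowest free energy kept — the study's procedure) once for
    all recovery tests."""
    spec = reduced_cohort_spec()
    manifest, runs, truth = simulate_cohort(spec, default_gt, seed=11)
    std = [standardize_run(r) for r in runs]
    concat = concatenate(manifest, std)
    pca, scores = pca_reduce(concat, 0.5)
    model = None
    for rep in range(3):
        m = GaussianHMMVB(
            n_states=default_gt.K_true, random_state=100 + rep, max_iter=100
        ).fit(scores, lengths=concat.lengths)
        if model is None or m.free_energy_ < model.free_energy_:
            model = m
    return dict(
        spec=spec,
        gt=default_gt,
        manifest=manifest,
        runs=runs,
        truth=truth,
        concat=concat,
        pca=pca,
        scores=scores,
        model=model,
    )
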