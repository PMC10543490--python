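"""Shared fixtures: tiny phantom cohorts and the reduced end-to-end run.

The reduced cross-validation fixture is session-scoped and shared by the
end-to-end segmentation and cross-modality agreement tests, since the three
contrast models reuse the same cohort and fold splits.
"""

from __future__ import annotations

import pandas as pd
import pytest

from plexus_seg.experiment import (
    TrainSpec,
    cases_from_subjects,
    make_cv_splits,
    run_cross_validation,
)
from plexus_seg.phantom import PhantomParams, generate_cohort

# fixed study seed for the reduced end-to-end runs
E2E_SEED = 0
E2E_N = 20


def reduced_params() -> PhantomParams:
    """64-cube phantom grid at 1.5 mm: same anatomy, smaller volumes."""
    return PhantomParams(grid_shape=(64, 64, 64), spacing=(1.5, 1.5, 1.5))


@pytest.fixture(scope="session")
def small_cohort():
    """Six 64-cube phantoms for unit-level experiment tests."""
    params = reduced_params()
    subjects, manifest = generate_cohort(params, n=6, seed=42)
    return params, subjects, manifest


@pytest.fixture(scope="session")
def reduced_cv_results():
    """Reduced cross-validated segmentation on 20 phantoms, three contrasts.

    FLAIR runs the full 5-fold design; T1 and T2 run the first two folds
    (8 of the 20 subjects tested), which is enough overlap for the
    cross-modality volume agreement check at desk scale.
    """
    params = reduced_params()
    subjects, _ = generate_cohort(params, n=E2E_N, seed=E2E_SEED)
    ids = sorted(s.subject_id for s in subjects)
    split = make_cv_splits(ids, n_folds=5, seed=E2E_SEED)
    spec = TrainSpec.reduced(seed=E2E_SEED)
    scores = {}
    for modality, folds in (("flair", 5), ("t1", 2), ("t2", 2)):
        cases = cases_from_subjects(subjects, modality)
        sub_split = split if folds == 5 else type(split)(
            folds=split.folds[:folds], seed=split.seed)
        scores[modality] = run_cross_validation(cases, spec, split=sub_split)
    lvv = pd.DataFrame(
        {"subject_id": [s.subject_id for s in subjects],
         "lvv_cm3": [s.lvv_cm3 for s in subjects]}
    )
    return scores, split, lvv
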