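"""Shared fixtures: small synthetic studies and matrix builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import t1screen as t
from t1screen.interactions import InteractionMatrix
from t1screen.pipeline import design_from_assignment
from t1screen.tables import MetabolitePeakList

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def quantify_generated(study, thresholds=None):
    """Compile windows from a study's mix assignment and quantify it."""
    design = design_from_assignment(study.mix_of, study.peak_lists)
    windows, _ = t.compile_peak_windows(design, study.peak_lists)
    return t.quantify_study(
        study.measurements, windows, thresholds or t.Thresholds()
    )


def matrix_from_scores(scores: dict, proteins=None, metabolites=None) -> InteractionMatrix:
    """Interaction matrix from a {(protein, metabolite): delta_rf} dict
    (None values become missing cells)."""
    if proteins is None:
        proteins = sorted({p for p, _ in scores})
    if metabolites is None:
        metabolites = sorted({m for _, m in scores})
    dr = pd.DataFrame(np.nan, index=list(proteins), columns=list(metabolites))
    for (p, m), v in scores.items():
        if v is not None:
            dr.at[p, m] = v
    npk = pd.DataFrame(1, index=list(proteins), columns=list(metabolites), dtype=int)
    return InteractionMatrix(delta_rf=dr, n_peaks=npk)


def clashfree_library(n_mets=20, n_mixes=4, n_clusters=8, seed=0):
    """Library with a known zero-overlap partition: base peaks far apart,
    plus planted clash pairs between metabolites of different planned
    mixes, so a correct colouring always exists."""
    rng = np.random.default_rng(seed)
    mets = [f"met{i:02d}" for i in range(n_mets)]
    planned = {m: i % n_mixes for i, m in enumerate(mets)}
    peaks = {m: [(round(0.6 + i * 0.4, 3), 1.0)] for i, m in enumerate(mets)}
    base = 0.6 + n_mets * 0.4 + 0.5
    for c in range(n_clusters):
        g1, g2 = rng.choice(n_mixes, size=2, replace=False)
        m1 = str(rng.choice([m for m in mets if planned[m] == g1]))
        m2 = str(rng.choice([m for m in mets if planned[m] == g2]))
        pos = base + 0.2 * c
        peaks[m1].append((round(pos, 3), 0.8))
        peaks[m2].append((round(pos + 0.01, 3), 0.8))
    return {m: MetabolitePeakList(m, tuple(p)) for m, p in peaks.items()}


@pytest.fixture(scope="session")
def noiseless_binder_study():
    """3 proteins x 4 metabolites, three binders, no noise/offset: the
    closed-form regime."""
    return t.simulate_screen(
        n_proteins=3,
        n_metabolites=4,
        binder_fraction=0.25,
        noise_sd=0.0,
        shift_offset_sd=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def noiseless_quantified(noiseless_binder_study):
    matrix, quants = quantify_generated(noiseless_binder_study)
    return noiseless_binder_study, matrix, quants


@pytest.fixture(scope="session")
def recovery_study_quantified():
    """The 20x20 parameter-recovery study: 10% binders, KD ~ U[10, 500] uM,
    noise 0.01, fixed seed."""
    study = t.simulate_screen(seed=1)
    matrix, quants = quantify_generated(study)
    return study, matrix, quants
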