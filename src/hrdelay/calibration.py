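"""Calibration experiments: null decoding, test size, permutation specificity.

These routines re-run the analysis machinery under global-null synthetic
conditions (all three stimulus conditions share identical generative
parameters) to verify that the pipeline is unbiased: cross-validated
AUC centred on chance, the stage-B intercept test rejecting at its
nominal rate, and the permutation significance rule with ~95%
specificity.  They are used both by the test suite and by the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from .design import StudyDesign
from .inference import permutation_null_auc, permutation_test
from .pipeline import all_condition_pairs, analyze_participant, decode_participant
from .selection import hotelling_intercept
from .synth import GeneratorParams, build_ground_truth, simulate_study

__all__ = [
    "intercept_test_rejection_rate",
    "simulate_null_participant",
    "null_decoding_aucs",
    "permutation_specificity",
    "DESK_DESIGN",
]

#: desk-scale design: the study timing with the minimum per-session
#: repetition count used in the study (5 triplets)
DESK_DESIGN = StudyDesign(n_triplets_per_session=5)


def intercept_test_rejection_rate(
    n_voxels: int = 10_000,
    n_runs: int = 15,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical size of the stage-B Hotelling intercept test.

    Each voxel gets ``n_runs`` response vectors drawn from a zero-mean
    standard bivariate normal; the returned fraction of voxels declared
    significant should match ``alpha``.
    """
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_runs, n_voxels, 2))
    vectors = draws[..., 0] + 1j * draws[..., 1]
    _, p = hotelling_intercept(vectors)
    return float(np.mean(p < alpha))


def simulate_null_participant(
    design: StudyDesign = DESK_DESIGN,
    n_voxels: int = 60,
    seed: int = 0,
):
    """Sessions + fitted selectors for one zero-effect participant."""
    params = GeneratorParams.null()
    ss = np.random.SeedSequence(entropy=(int(seed), 0x5EED))
    s1, s2 = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    truth, meta = build_ground_truth(design, n_voxels, params, seed=s1)
    sessions = simulate_study(design, truth, seed=s2, params=params, meta=meta)
    return analyze_participant(sessions)


def null_decoding_aucs(
    n_studies: int = 100,
    design: StudyDesign = DESK_DESIGN,
    n_voxels: int = 60,
    seed: int = 0,
    encodings: tuple[str, ...] = ("delay", "amplitude", "both"),
) -> np.ndarray:
    """Per-study mean cross-validated AUC over many null studies.

    Each study runs the full cascade (selection per session, SVM per
    condition pair and encoding, both train/test directions); the
    returned array holds one mean AUC per study and should centre on
    chance (0.5).
    """
    out = np.empty(n_studies)
    children = np.random.SeedSequence(seed).spawn(n_studies)
    for i, child in enumerate(children):
        s = int(child.generate_state(1)[0] % (2**31))
        selectors = simulate_null_participant(design, n_voxels, seed=s)
        dec = decode_participant(
            selectors, all_condition_pairs(design), encodings
        )
        out[i] = dec["auc"].mean()
    return out


def permutation_specificity(
    n_datasets: int = 400,
    n_permutations: int = 512,
    design: StudyDesign = DESK_DESIGN,
    n_voxels: int = 40,
    seed: int = 0,
    encoding: str = "both",
) -> float:
    """Fraction of null datasets NOT declared significant (target ~0.95).

    For each null dataset the observed between-session AUC of one
    condition pair is compared against its within-triplet permutation
    null; the significance rule requires the observed AUC to exceed 95%
    of the permuted AUCs.
    """
    pair = all_condition_pairs(design)[0]
    children = np.random.SeedSequence(entropy=(seed, 0xA11CE)).spawn(n_datasets)
    not_significant = 0
    for child in children:
        s1, s2 = [int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(2)]
        selectors = simulate_null_participant(design, n_voxels, seed=s1)
        labels = [sel.labels_ for sel in selectors]
        null = permutation_null_auc(
            selectors,
            labels,
            pair,
            encoding,
            n_permutations=n_permutations,
            seed=s2,
        )
        if not null.significant:
            not_significant += 1
    return not_significant / n_datasets
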