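"""Desk-scale validation experiments: recovery, calibration, dissociation.

Because the study this package models is defined on neuroimaging data,
correctness is established by simulation instead: ground-truth kernels must
be recovered from synthetic sessions, the permutation machinery must reject
at its nominal rate on null data, and the end-to-end pipeline must recover
a built-in entropy/surprisal dissociation.  The experiments here run at
deliberately reduced problem sizes (short sessions, small groups, small
source grids) so a full validation sweep completes on one CPU in minutes;
the statistical structure of the full-scale study is preserved.
"""

from __future__ import annotations

import numpy as np

from .mtrf import boost, cross_validate, predict
from .predictors import build_predictor_set, standardize
from .stats import paired_permutation_test, signflip_test
from .synth import (
    GroupSpec,
    SimConfig,
    generate_lexicon,
    generate_session,
    ground_truth_trfs,
    simulate_recording,
)

__all__ = [
    "recovery_experiment",
    "dissociation_replicate",
    "dissociation_config",
    "paired_test_null_rejection",
    "signflip_null_rejection",
    "cv_permutation_control",
]


def recovery_experiment(
    seed: int = 0,
    snr: float = 10.0,
    duration_minutes: float = 5.0,
    step: float = 0.01,
    max_iter: int = 4000,
) -> dict:
    """Kernel recovery from one synthetic session at a given SNR.

    Simulates a continuous session of roughly ``duration_minutes`` of
    speech and scores, at every ROI source, how well boosting (single
    train/validation split) recovers the generating two-peak kernels of
    the value-scaled channels:

    * run A drives the response with surprisal and entropy kernels (both
      gain 1.0) -> per-channel correlation with the truth;
    * run B sets the entropy gain to 0 -> the recovered entropy kernel's
      norm relative to the recovered unit-gain surprisal kernel's norm.

    The binary onset covariates are deliberately excluded here: their
    impulses coincide with the scaled surprisal/entropy impulses, so under
    greedy l1 boosting the covariates' shared variance is reassigned and
    individual kernels of the collinear set are not identifiable at finite
    data -- recovery is scored on the well-posed two-channel design.

    Returns worst-case (over ROI sources) correlations and norm ratio.
    """
    rng = np.random.default_rng(seed)
    n_words = int(duration_minutes * 60 * 8.0 / 3.5)  # ~8 phon/s, ~3.5 phon/word
    cfg = SimConfig(seed=seed, lexicon_size=300, grid_shape=(3, 3),
                    roi_box=(1, 1, 1, 2), snr=snr)
    lexicon = generate_lexicon(cfg, rng)
    session = generate_session(lexicon, cfg, "continuous", rng, n_words=n_words)
    ps = build_predictor_set(session, lexicon).subset(["surprisal", "entropy"])
    basis = cfg.basis()
    geometry = cfg.geometry()
    roi = np.flatnonzero(geometry.roi_mask)
    psz = standardize(ps)
    n = ps.n_samples
    train = np.arange(0, int(n * 2 / 3))
    val = np.arange(int(n * 2 / 3), n)
    i_ent = ps.feature_names.index("entropy")
    i_sur = ps.feature_names.index("surprisal")

    def _fit_all(gains):
        truth = ground_truth_trfs(gains, basis, ps.feature_names)
        recording, _ = simulate_recording(ps, truth, geometry, snr, rng)
        return truth, [
            boost(psz, standardize(recording[src]), train, val, step=step,
                  max_iter=max_iter, basis=basis)
            for src in roi
        ]

    truth_a, models_a = _fit_all({"surprisal": 1.0, "entropy": 1.0})
    correlations: dict[str, float] = {}
    for model in models_a:
        for i, name in ((i_sur, "surprisal"), (i_ent, "entropy")):
            r = float(np.corrcoef(model.kernels[i], truth_a.kernels[i])[0, 1])
            correlations[name] = min(correlations.get(name, 1.0), r)

    _, models_b = _fit_all({"surprisal": 1.0, "entropy": 0.0})
    norm_ratio = max(
        float(np.linalg.norm(m.kernels[i_ent]) / np.linalg.norm(m.kernels[i_sur]))
        for m in models_b
    )
    return {
        "kernel_correlations": correlations,
        "min_correlation": min(correlations.values()),
        "zero_gain_norm_ratio": norm_ratio,
        "n_words": n_words,
        "n_samples": n,
        "n_roi_sources": len(roi),
    }


def dissociation_config(
    seed: int,
    n_subjects: int = 6,
    n_words: int = 80,
    snr: float = 2.0,
    matched_gains: bool = False,
) -> SimConfig:
    """Scaled-down two-group study config for dissociation experiments.

    The dissociation design gives entropy zero gain in the single-word
    group; ``matched_gains`` instead gives both groups the full entropy
    gain (the interaction null).
    """
    g_ent_single = 1.0 if matched_gains else 0.0
    base = {"surprisal": 1.0, "word_onset": 0.5, "phoneme_onset": 0.5}
    return SimConfig(
        seed=seed,
        lexicon_size=300,
        n_words=n_words,
        snr=snr,
        grid_shape=(2, 2),
        roi_box=(0, 0, 0, 0),
        groups=(
            GroupSpec("single_word", "single_word", n_subjects,
                      {**base, "entropy": g_ent_single}),
            GroupSpec("continuous", "continuous", n_subjects,
                      {**base, "entropy": 1.0}),
        ),
    )


def dissociation_replicate(
    seed: int,
    n_subjects: int = 6,
    n_words: int = 80,
    snr: float = 2.0,
    matched_gains: bool = False,
    k: int = 3,
    step: float = 0.02,
    max_iter: int = 500,
    n_permutations: int = 200,
) -> dict:
    """One end-to-end run of the scaled-down model-comparison pipeline.

    Simulates the two-group study, fits full / minus-entropy /
    minus-surprisal models per subject, and returns the report (including
    the entropy/surprisal ratio interaction p-value and per-group
    significance flags).
    """
    from .pipeline import StudyConfig, run_model_comparison

    cfg = StudyConfig(
        sim=dissociation_config(seed, n_subjects, n_words, snr, matched_gains),
        k=k,
        step=step,
        max_iter=max_iter,
        n_permutations=n_permutations,
        roi_only=True,
        seed=seed,
    )
    return run_model_comparison(cfg)


def paired_test_null_rejection(
    n_replicates: int = 200,
    n_perm: int = 500,
    n_subjects: int = 10,
    grid_shape: tuple[int, int] = (4, 4),
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise rejection rate of the paired TFCE test on null maps."""
    from .stats import SourceGeometry

    geometry = SourceGeometry.grid(*grid_shape)
    rng = np.random.default_rng(seed)
    rejections = 0
    V = geometry.n_sources
    for rep in range(n_replicates):
        a = rng.normal(size=(n_subjects, V))
        b = rng.normal(size=(n_subjects, V))
        res = paired_permutation_test(
            a, b, geometry.edges, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        rejections += bool((res.p <= alpha).any())
    return rejections / n_replicates


def signflip_null_rejection(
    n_replicates: int = 200,
    n_perm: int = 500,
    n_subjects: int = 10,
    n_points: int = 30,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise rejection rate of the sign-flip TFCE test on pure noise."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for rep in range(n_replicates):
        x = rng.normal(size=(n_subjects, n_points))
        res = signflip_test(x, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rejections += bool((res.p <= alpha).any())
    return rejections / n_replicates


def cv_permutation_control(
    n_replicates: int = 40,
    seed: int = 0,
    n_words: int = 60,
    snr: float = 2.0,
    k: int = 3,
    step: float = 0.02,
    max_iter: int = 500,
) -> dict:
    """Held-out power of the true surprisal predictor vs an event-permuted one.

    For each replicate a session is simulated, the response is generated
    from the surprisal kernel, and two cross-validated fits are compared:
    one with the true surprisal values and one in which the values are
    randomly permuted across phoneme events (preserving timing and
    marginals).  Returns the fraction of replicates in which the true
    predictor's held-out power is at least that of the permuted one.
    """
    base_cfg = SimConfig(seed=seed, lexicon_size=300, n_words=n_words, snr=snr)
    basis = base_cfg.basis()
    wins = 0
    n_calls = None
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed * 100003 + rep)
        lexicon = generate_lexicon(base_cfg, rng)
        session = generate_session(lexicon, base_cfg, "continuous", rng,
                                   n_words=n_words)
        ps = build_predictor_set(session, lexicon).subset(
            ["word_onset", "surprisal"]
        )
        truth = ground_truth_trfs(
            {"surprisal": 1.0, "word_onset": 0.5}, basis, ps.feature_names
        )
        y = predict(truth, ps)
        noise_sd = np.sqrt((y**2).mean()) / snr
        y = standardize(y + rng.normal(0, noise_sd, len(y)))
        psz = standardize(ps)
        fit = cross_validate(psz, y, k=k, step=step, max_iter=max_iter,
                             basis=basis)
        perm = ps.channels["surprisal"].copy()
        nz = np.flatnonzero(perm[0])
        perm[0, nz] = perm[0, nz][rng.permutation(len(nz))]
        ps_perm = standardize(
            type(ps)({"word_onset": ps.channels["word_onset"],
                      "surprisal": perm}, ps.rate)
        )
        fit_perm = cross_validate(ps_perm, y, k=k, step=step, max_iter=max_iter,
                                  basis=basis)
        wins += bool(fit.power[0] >= fit_perm.power[0])
        n_calls = fit.n_boost_calls
    return {
        "win_fraction": wins / n_replicates,
        "n_boost_calls_per_fit": n_calls,
    }
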