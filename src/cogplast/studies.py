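"""Simulation studies validating the inference machinery.

These are the package's own calibration checks, run on synthetic cohorts:
the family-wise false-positive rate of the TFCE-FWE permutation GLM under
the null, recovery of the planted hub cluster and indirect effect by the
full pipeline, and parameter recovery for the mediation paths at large n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mediation import MediationData, fit_paths
from .permutation import DesignSpec, PermutationScheme, TFCEParams, run_glm_permutation
from .pipeline import delta_centrality_maps, residualize_on_baseline, run_mediation_pipeline
from .synthetic import CohortConfig, generate_cohort
from .volgrid import Mask

__all__ = [
    "type_one_error_study",
    "recovery_study",
    "simulate_mediation_data",
    "mediation_parameter_recovery",
]


def _null_config(grid_shape, seed, n_frames):
    return CohortConfig(grid_shape=grid_shape, n_frames=n_frames,
                        effect_a=0.0, effect_b=0.0, direct_effect_c=0.0,
                        seed=seed)


def type_one_error_study(n_replicates: int = 200, n_flips: int = 500,
                         grid_shape=(12, 12, 12), n_frames: int = 200,
                         alpha: float = 0.05, seed: int = 0):
    """Family-wise false-positive rate of the TFCE-FWE GLM under the null.

    Each replicate generates a cohort with all planted effects at zero,
    computes Delta EC maps, residualizes on baseline and runs the
    sign-flip permutation GLM (age/sex nuisance).  Returns (rate,
    per-replicate flags): the share of replicates whose FWE-corrected
    minimum p falls below ``alpha``.
    """
    root = np.random.SeedSequence(seed)
    rep_seeds = root.generate_state(n_replicates, dtype=np.uint32) >> 1
    flags = np.zeros(n_replicates, dtype=bool)
    mask = Mask(np.ones(grid_shape, dtype=bool))
    for r in range(n_replicates):
        cfg = _null_config(grid_shape, int(rep_seeds[r]), n_frames)
        subjects, _ = generate_cohort(cfg, modalities=("bold",))
        delta, baseline = delta_centrality_maps(subjects, mask)
        delta_res = residualize_on_baseline(delta, baseline)
        group = np.array([1 if s.is_exercise else 0 for s in subjects])
        covs = np.column_stack([[s.age for s in subjects],
                                [float(s.sex) for s in subjects]])
        design = DesignSpec(group=group, covariates=covs, contrast=1)
        scheme = PermutationScheme.build(group, n_flips=n_flips,
                                         seed=int(rep_seeds[r]))
        res = run_glm_permutation(delta_res, mask, design, scheme=scheme)
        flags[r] = res.min_p() < alpha
    return float(flags.mean()), flags


def recovery_study(n_seeds: int = 25, n_flips: int = 500, B: int = 2000,
                   dice_threshold: float = 0.3, seed: int = 0,
                   config_kwargs: dict = None):
    """Hub-cluster and indirect-effect recovery on planted-effect cohorts.

    Runs the full pipeline on ``n_seeds`` default cohorts and reports the
    share of seeds where (i) the NPC screen returns a significant cluster
    overlapping the hub mask with Dice > ``dice_threshold`` and (ii) the
    downstream bootstrap mediation CI excludes zero.
    """
    root = np.random.SeedSequence(seed)
    run_seeds = root.generate_state(n_seeds, dtype=np.uint32) >> 1
    cluster_hits = np.zeros(n_seeds, dtype=bool)
    mediation_hits = np.zeros(n_seeds, dtype=bool)
    dices = np.zeros(n_seeds)
    for i in range(n_seeds):
        cfg = CohortConfig(seed=int(run_seeds[i]), **(config_kwargs or {}))
        res = run_mediation_pipeline(cfg, n_flips=n_flips, B=B)
        dices[i] = res.hub_dice
        cluster_hits[i] = res.found_cluster and res.hub_dice > dice_threshold
        mediation_hits[i] = res.mediation_significant
    return {
        "cluster_rate": float(cluster_hits.mean()),
        "mediation_rate": float(mediation_hits.mean()),
        "dice": dices,
        "cluster_hits": cluster_hits,
        "mediation_hits": mediation_hits,
    }


def simulate_mediation_data(n: int, a: float = 0.5, b: float = 0.6,
                            c_prime: float = 0.3, noise_m: float = 1.0,
                            noise_y: float = 1.0, seed: int = 0) -> MediationData:
    """Single-mediator linear model with known paths for recovery checks."""
    rng = np.random.default_rng(seed)
    X = (rng.random(n) < 0.5).astype(float)
    M = a * X + rng.normal(0, noise_m, n)
    Y = c_prime * X + b * M + rng.normal(0, noise_y, n)
    return MediationData(X=X, M=M, Y=Y)


def mediation_parameter_recovery(n: int = 5000, a: float = 0.5, b: float = 0.6,
                                 c_prime: float = 0.3, seed: int = 0) -> dict:
    """Point-estimate recovery of (a, b, ab) at large n."""
    data = simulate_mediation_data(n, a=a, b=b, c_prime=c_prime, seed=seed)
    res = fit_paths(data)
    return {"a_hat": float(res.a[0]), "b_hat": float(res.b[0]),
            "ab_hat": float(res.ab[0]), "c_prime_hat": res.c_prime,
            "a_true": a, "b_true": b, "ab_true": a * b, "n": n}
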