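"""End-to-end analysis chain on a synthetic cohort.

Mirrors the study workflow: eigenvector-centrality maps per subject and
session, percentage-change images, voxel-wise residualization on baseline,
the NPC mediation screen over voxels, cluster extraction, and bootstrap
mediation on the cluster-mean mediator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .centrality import eigenvector_centrality
from .cognition import percent_gain, score_d2r
from .mediation import MediationData, MediationResult, percentile_bootstrap
from .permutation import (DesignSpec, NPCResult, PermutationScheme, TFCEParams,
                          npc_fisher_screen)
from .synthetic import CohortConfig, GroundTruth, generate_cohort
from .volgrid import Mask, residualize

__all__ = [
    "PipelineResult",
    "residualize_on_baseline",
    "delta_centrality_maps",
    "dice",
    "run_mediation_pipeline",
]


def residualize_on_baseline(delta: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Voxel-wise residualized change: regress each column of ``delta``
    (subjects x voxels) on the matching column of ``baseline`` plus an
    intercept, vectorized over voxels."""
    d = delta - delta.mean(axis=0, keepdims=True)
    b = baseline - baseline.mean(axis=0, keepdims=True)
    denom = (b ** 2).sum(axis=0)
    denom[denom == 0] = np.inf
    beta = (b * d).sum(axis=0) / denom
    return d - beta[None, :] * b


def delta_centrality_maps(subjects, mask: Mask, drop_timeseries: bool = True):
    """Per-subject EC percentage-change and baseline maps over ``mask``.

    Returns (delta (n, V), baseline (n, V)) over the masked voxels.  BOLD
    timeseries are released after use by default to bound memory.
    """
    m = mask.membership
    delta_rows, base_rows = [], []
    for s in subjects:
        ec_pre = eigenvector_centrality(s.bold_pre, mask)
        ec_post = eigenvector_centrality(s.bold_post, mask)
        pre = ec_pre.values[m]
        post = ec_post.values[m]
        delta_rows.append(100.0 * (post - pre) / pre)
        base_rows.append(pre)
        if drop_timeseries:
            s.bold_pre = s.bold_post = None
    return np.vstack(delta_rows), np.vstack(base_rows)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A & B| / (|A| + |B|) of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / denom if denom else 0.0


@dataclass
class PipelineResult:
    npc: NPCResult
    hub_dice: float
    mediation: Optional[MediationResult]
    behavior_resid: np.ndarray
    mediator: Optional[np.ndarray]
    truth: GroundTruth
    config: CohortConfig

    @property
    def found_cluster(self) -> bool:
        return len(self.npc.clusters) > 0

    @property
    def mediation_significant(self) -> bool:
        if self.mediation is None:
            return False
        lo, hi = self.mediation.ci95[0]
        return lo > 0 or hi < 0


def run_mediation_pipeline(config: CohortConfig, n_flips: int = 500,
                           B: int = 2000, alpha: float = 0.05,
                           tfce_params: TFCEParams = None,
                           seed: Optional[int] = None) -> PipelineResult:
    """Full chain: cohort -> Delta EC -> NPC screen -> bootstrap mediation.

    The analysis mask is the whole grid (the synthetic stand-in for a
    study-specific gray-matter mask).  Behavior is the d2-R concentration
    performance gain in percent, scored from the generated line records and
    residualized on its baseline; Delta EC maps are residualized voxel-wise
    on baseline EC.  The mediator entering the bootstrap mediation is the
    mean residualized Delta EC over the significant NPC cluster(s).
    """
    seed = config.seed if seed is None else seed
    subjects, truth = generate_cohort(config, modalities=("bold", "cognition"))
    mask = Mask(np.ones(config.grid_shape, dtype=bool))

    delta, baseline = delta_centrality_maps(subjects, mask)
    delta_res = residualize_on_baseline(delta, baseline)

    group = np.array([1 if s.is_exercise else 0 for s in subjects])
    age = np.array([s.age for s in subjects])
    sex = np.array([s.sex for s in subjects], dtype=float)

    cp_pre = np.array([score_d2r(s.d2r_pre) for s in subjects], dtype=float)
    cp_post = np.array([score_d2r(s.d2r_post) for s in subjects], dtype=float)
    gain = percent_gain(cp_pre, cp_post)
    gain_res = residualize(gain, cp_pre)

    design = DesignSpec(group=group, covariates=np.column_stack([age, sex]), contrast=1)
    scheme = PermutationScheme.build(group, n_flips=n_flips, seed=seed)
    npc = npc_fisher_screen(delta_res, mask, design, gain_res, scheme=scheme,
                            tfce_params=tfce_params, alpha=alpha)

    sig = npc.cluster_labels > 0
    hub_dice = dice(sig, truth.hub_mask.membership)

    mediation = mediator = None
    if sig.any():
        sig_masked = sig[mask.membership]
        mediator = delta_res[:, sig_masked].mean(axis=1)
        data = MediationData(X=group, M=mediator, Y=gain_res,
                             covariates=np.column_stack([age, sex]))
        mediation = percentile_bootstrap(data, B=B, seed=seed)
    return PipelineResult(npc=npc, hub_dice=hub_dice, mediation=mediation,
                          behavior_resid=gain_res, mediator=mediator,
                          truth=truth, config=config)
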