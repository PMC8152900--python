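"""Synthetic cohorts with planted ground truth.

The generator emulates a two-group longitudinal exercise study (32 exercise
vs 16 control subjects, two sessions) with exactly the statistical structure
the analysis pipeline assumes:

* resting-state-like 4D timeseries in which a set of network voxels shares
  one latent signal g(t); hub voxels gain mixing weight after the
  intervention in exercise subjects only, so their connectivity centrality
  increases (x_v(t) = w_{v,s} g(t) + sigma eps_v(t));
* a behavioral gain score driven partly by the *latent* connectivity change
  (a planted indirect effect: group -> latent -> behavior), so measurement
  noise attenuates the observable mediator path realistically;
* diffusion eigenvalue maps whose minor eigenvalues decrease
  post-intervention inside a white-matter region, exercise group only;
* graded-exercise-test records with a linear heart-rate curve and cubic
  lactate curve, plus training-session lactate samples above the anaerobic
  threshold for exercise subjects.

All randomness flows from one root seed via numpy SeedSequence spawning
(cohort-level stream first, then one child per subject, split again per
modality), so every fixture is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .cognition import D2RLine
from .fitness import GXTRecord
from .volgrid import Mask, Timeseries4D

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SyntheticSubject",
    "default_masks",
    "generate_cohort",
    "generate_gxt",
    "write_cohort",
]

ALL_MODALITIES = ("bold", "diffusion", "cognition", "gxt")


def _block(shape, lo_frac, hi_frac) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    sl = tuple(slice(int(round(lo * s)), max(int(round(lo * s)) + 1, int(round(hi * s))))
               for lo, hi, s in zip(lo_frac, hi_frac, shape))
    m[sl] = True
    return m


def default_masks(shape=(16, 16, 16)):
    """Hub, network and white-matter effect masks for a given grid.

    The hub is a small central-frontal block; two further network blocks
    share the hub's latent signal; the white-matter block is disjoint from
    all of them.  Fractional placement keeps the layout valid on any grid
    of at least 8 voxels per axis.
    """
    hub = Mask(_block(shape, (0.25, 0.25, 0.25), (0.44, 0.44, 0.44)))
    net1 = Mask(_block(shape, (0.56, 0.19, 0.19), (0.81, 0.44, 0.44)))
    net2 = Mask(_block(shape, (0.19, 0.56, 0.56), (0.44, 0.81, 0.81)))
    wm = Mask(_block(shape, (0.62, 0.62, 0.19), (0.88, 0.88, 0.44)))
    return hub, [net1, net2], wm


@dataclass
class CohortConfig:
    """Study conditions for cohort generation.

    Effect sizes: ``effect_a`` is the hub mixing-weight increase per unit of
    the subject's positive latent delta (delta ~ Exp(1), mean 1, so
    the mean group difference in the latent mediator is ``effect_a``);
    ``effect_b`` is the behavioral gain (percent) per unit latent;
    ``direct_effect_c`` the group direct path (percent).  ``noise_sd`` holds
    the per-source noise scales: BOLD noise relative to the unit-variance
    latent signal, behavioral gain noise in percent, lognormal sigma of the
    diffusion eigenvalue noise, GXT heart-rate (bpm) and lactate (mmol/L)
    noise.
    """

    n_exercise: int = 32
    n_control: int = 16
    grid_shape: tuple = (16, 16, 16)
    n_frames: int = 200
    frame_interval: float = 1.4
    hub_mask: Optional[Mask] = None
    network_masks: Optional[List[Mask]] = None
    wm_effect_mask: Optional[Mask] = None
    effect_a: float = 1.0
    effect_b: float = 6.0
    direct_effect_c: float = 1.0
    wm_effect: float = 0.05
    baseline_coupling: float = -0.05
    behavior_intercept: float = 5.0
    noise_sd: dict = field(default_factory=lambda: {
        "bold": 0.8, "behavior": 4.0, "diffusion": 0.03,
        "gxt_hr": 2.0, "gxt_lactate": 0.15,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exercise < 2 or self.n_control < 2:
            raise ValueError("each group needs >= 2 subjects")
        if self.hub_mask is None or self.network_masks is None or self.wm_effect_mask is None:
            hub, nets, wm = default_masks(self.grid_shape)
            self.hub_mask = self.hub_mask or hub
            self.network_masks = self.network_masks or nets
            self.wm_effect_mask = self.wm_effect_mask or wm
        for m in [self.hub_mask, self.wm_effect_mask, *self.network_masks]:
            if tuple(m.shape) != tuple(self.grid_shape):
                raise ValueError("mask shape exceeds or mismatches the grid")
        net_union = np.zeros(self.grid_shape, dtype=bool)
        for m in self.network_masks:
            net_union |= m.membership
        if (self.hub_mask.membership & net_union).any():
            raise ValueError("hub and network masks must be disjoint")
        for name in ("effect_a", "effect_b", "direct_effect_c"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def n_subjects(self) -> int:
        return self.n_exercise + self.n_control

    def signal_mask(self) -> np.ndarray:
        out = self.hub_mask.membership.copy()
        for m in self.network_masks:
            out |= m.membership
        return out


@dataclass
class GroundTruth:
    true_a: float
    true_b: float
    true_ab: float
    true_c_prime: float
    hub_mask: Mask
    wm_effect_mask: Mask
    latent: np.ndarray      # planted latent connectivity change per subject
    delta: np.ndarray       # positive latent delta per subject (hub weight units)
    true_gain: np.ndarray   # noise-free part of the behavioral gain


@dataclass
class SyntheticSubject:
    id: str
    group: str              # "exercise" | "control"
    age: float
    sex: int                # 1 = female, 0 = male
    latent: float
    bold_pre: Optional[Timeseries4D] = None
    bold_post: Optional[Timeseries4D] = None
    eig_pre: Optional[np.ndarray] = None     # (x, y, z, 3) descending eigenvalues
    eig_post: Optional[np.ndarray] = None
    d2r_pre: Optional[list] = None
    d2r_post: Optional[list] = None
    cp_pre: Optional[int] = None
    cp_post: Optional[int] = None
    zvt_pre: Optional[np.ndarray] = None
    zvt_post: Optional[np.ndarray] = None
    digit_pre: Optional[list] = None
    digit_post: Optional[list] = None
    gxt: Optional[GXTRecord] = None
    gxt_truth: Optional[dict] = None
    training_lactate: Optional[list] = None  # per-session sample lists

    @property
    def is_exercise(self) -> bool:
        return self.group == "exercise"


# ---------------------------------------------------------------------------
# GXT generation
# ---------------------------------------------------------------------------

def generate_gxt(seed, start_w: float = 25.0, step_w: float = 25.0,
                 hr0: float = 70.0, hr_slope: float = 0.5,
                 lactate_base: float = 1.0, lactate_scale: float = 120.0,
                 body_mass: float = 70.0, hr_stop: float = 170.0,
                 hr_noise_sd: float = 0.0, lactate_noise_sd: float = 0.0,
                 max_stages: int = 24):
    """One graded exercise test: 25 W stages, linear HR, cubic lactate.

    HR(W) = hr0 + hr_slope * W (+ noise); the test terminates after the
    stage in which HR reaches ``hr_stop``.  Lactate follows
    lactate_base + (W / lactate_scale)^3 (+ noise, floored at 0.2 mmol/L).
    Returns (GXTRecord, truth) where truth carries the generating curve
    parameters for recovery tests.
    """
    rng = np.random.default_rng(seed)
    stages, hr, lac = [], [], []
    w = start_w
    for _ in range(max_stages):
        h = hr0 + hr_slope * w + (rng.normal(0, hr_noise_sd) if hr_noise_sd else 0.0)
        l_true = lactate_base + (w / lactate_scale) ** 3
        l = l_true + (rng.normal(0, lactate_noise_sd) if lactate_noise_sd else 0.0)
        stages.append(w)
        hr.append(h)
        lac.append(max(l, 0.2))
        if h >= hr_stop:
            break
        w += step_w
    if len(stages) < 4:
        raise ValueError("GXT protocol produced fewer than 4 stages")
    record = GXTRecord(stages=np.array(stages), hr=np.array(hr),
                       lactate=np.array(lac), body_mass=body_mass)
    truth = {"hr0": hr0, "hr_slope": hr_slope, "lactate_base": lactate_base,
             "lactate_scale": lactate_scale,
             "lactate_coeffs": np.array([lactate_base, 0.0, 0.0, lactate_scale ** -3])}
    return record, truth


# ---------------------------------------------------------------------------
# Per-modality subject pieces
# ---------------------------------------------------------------------------

def _bold_session(rng, config: CohortConfig, weights: np.ndarray) -> Timeseries4D:
    shape = tuple(config.grid_shape)
    T = config.n_frames
    g = rng.standard_normal(T)
    x = rng.standard_normal(size=shape + (T,), dtype=np.float32)
    x *= config.noise_sd["bold"]
    sig = weights > 0
    x[sig] += (weights[sig, None] * g[None, :]).astype(np.float32)
    return Timeseries4D(values=x, frame_interval=config.frame_interval)


def _diffusion_session(rng, config: CohortConfig, post_exercise: bool) -> np.ndarray:
    shape = tuple(config.grid_shape)
    base = np.empty(shape + (3,))
    base[..., 0], base[..., 1], base[..., 2] = 1.0e-3, 0.8e-3, 0.6e-3
    wm = config.wm_effect_mask.membership
    base[wm] = np.array([1.5e-3, 0.5e-3, 0.5e-3])
    if post_exercise:
        shrink = 1.0 - config.wm_effect
        base[wm, 1] *= shrink
        base[wm, 2] *= shrink
    noise = np.exp(rng.normal(0.0, config.noise_sd["diffusion"], size=base.shape))
    eig = base * noise
    eig = np.sort(eig, axis=-1)[..., ::-1]   # enforce l1 >= l2 >= l3 > 0
    return eig


def _d2r_lines(rng, cp: int, n_lines: int = 14, error_rate: float = 0.03):
    """Line records whose literal-convention CP score equals ``cp``."""
    total_targets = int(round(cp / (1.0 - 2 * error_rate)))
    errors = total_targets - cp
    base = total_targets // n_lines
    targets = np.full(n_lines, base, dtype=int)
    targets[: total_targets - base * n_lines] += 1
    commission = np.zeros(n_lines, dtype=int)
    overlooked = np.zeros(n_lines, dtype=int)
    for _ in range(errors):
        ln = int(rng.integers(0, n_lines))
        if rng.random() < 0.5 and overlooked[ln] < targets[ln]:
            overlooked[ln] += 1
        else:
            commission[ln] += 1
    lines = []
    for ln in range(n_lines):
        processed = min(47, int(targets[ln] * 2 + 4))
        processed = max(processed, targets[ln] + commission[ln])
        lines.append(D2RLine(processed=processed, processed_targets=int(targets[ln]),
                             commission_errors=int(commission[ln]),
                             overlooked_targets=int(overlooked[ln])))
    return lines


def _digit_trials(rng, k: int, n_trials: int = 14):
    k = int(np.clip(k, 0, n_trials))
    out = np.zeros(n_trials, dtype=bool)
    out[:k] = True
    rng.shuffle(out)
    return list(out)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig, modalities: Sequence[str] = ALL_MODALITIES):
    """Generate a full synthetic cohort and its ground truth.

    ``modalities`` selects which raw materials are generated ("bold",
    "diffusion", "cognition", "gxt"); the latent mediator, demographics and
    true behavioral gains are always produced.  Deterministic given
    ``config.seed``.
    """
    modalities = tuple(modalities)
    unknown = set(modalities) - set(ALL_MODALITIES)
    if unknown:
        raise ValueError(f"unknown modalities {sorted(unknown)}")
    root = np.random.SeedSequence(config.seed)
    cohort_ss, *subj_ss = root.spawn(1 + config.n_subjects)
    crng = np.random.default_rng(cohort_ss)

    n = config.n_subjects
    groups = np.array(["exercise"] * config.n_exercise + ["control"] * config.n_control)
    ages = crng.uniform(18.0, 35.0, size=n)
    sexes = (crng.random(n) < 0.6).astype(int)      # 1 = female
    delta = crng.gamma(shape=1.0, scale=1.0, size=n)   # positive, mean 1, sd 1
    is_ex = (groups == "exercise").astype(float)
    latent = config.effect_a * delta * is_ex

    cp_pre = np.clip(np.round(crng.normal(180.0, 20.0, size=n)), 120, 260).astype(int)
    true_gain = (config.behavior_intercept
                 + config.baseline_coupling * (cp_pre - 180.0)
                 + config.direct_effect_c * is_ex
                 + config.effect_b * latent)
    gain = true_gain + crng.normal(0.0, config.noise_sd["behavior"], size=n)

    weights_pre = config.signal_mask().astype(np.float64)
    hub = config.hub_mask.membership

    subjects = []
    for i in range(n):
        streams = subj_ss[i].spawn(5)
        s = SyntheticSubject(id=f"sub-{i + 1:03d}", group=str(groups[i]),
                             age=float(ages[i]), sex=int(sexes[i]),
                             latent=float(latent[i]))
        if "bold" in modalities:
            rng_pre = np.random.default_rng(streams[0])
            rng_post = np.random.default_rng(streams[1])
            w_post = weights_pre.copy()
            if s.is_exercise:
                w_post[hub] += config.effect_a * delta[i]
            s.bold_pre = _bold_session(rng_pre, config, weights_pre)
            s.bold_post = _bold_session(rng_post, config, w_post)
        if "diffusion" in modalities:
            rng_d = np.random.default_rng(streams[2])
            s.eig_pre = _diffusion_session(rng_d, config, post_exercise=False)
            s.eig_post = _diffusion_session(rng_d, config,
                                            post_exercise=s.is_exercise)
        if "cognition" in modalities:
            rng_c = np.random.default_rng(streams[3])
            cp_post = int(round(cp_pre[i] * (1.0 + gain[i] / 100.0)))
            s.cp_pre, s.cp_post = int(cp_pre[i]), cp_post
            s.d2r_pre = _d2r_lines(rng_c, int(cp_pre[i]))
            s.d2r_post = _d2r_lines(rng_c, cp_post)
            zvt_mean = rng_c.normal(65.0, 7.0)
            s.zvt_pre = zvt_mean + rng_c.normal(0, 2.0, size=4)
            s.zvt_post = s.zvt_pre * (1.0 + rng_c.normal(0, 0.03)) \
                + rng_c.normal(0, 1.0, size=4)
            k = int(np.clip(round(rng_c.normal(10.0, 2.0)), 2, 14))
            s.digit_pre = _digit_trials(rng_c, k)
            s.digit_post = _digit_trials(rng_c, int(np.clip(round(k + rng_c.normal(0, 1.5)), 2, 14)))
        if "gxt" in modalities:
            rng_g = np.random.default_rng(streams[4])
            hr0 = rng_g.normal(70.0, 7.0)
            slope = float(np.clip(rng_g.normal(0.5, 0.06), 0.35, 0.7))
            l0 = float(np.clip(rng_g.normal(1.0, 0.15), 0.5, 1.6))
            scale = float(np.clip(rng_g.normal(120.0, 15.0), 90.0, 160.0))
            mass = float(np.clip(rng_g.normal(68.0, 10.0), 45.0, 110.0))
            s.gxt, s.gxt_truth = generate_gxt(
                streams[4].spawn(1)[0], hr0=hr0, hr_slope=slope,
                lactate_base=l0, lactate_scale=scale, body_mass=mass,
                hr_noise_sd=config.noise_sd["gxt_hr"],
                lactate_noise_sd=config.noise_sd["gxt_lactate"])
            if s.is_exercise:
                w_obs = s.gxt.stages
                curve_min = l0 + (w_obs.min() / scale) ** 3
                iat_lac = curve_min + 1.5
                ratio = float(np.clip(rng_g.normal(1.4, 0.4), 0.6, 2.8))
                s.training_lactate = [
                    list(ratio * iat_lac * np.exp(rng_g.normal(0, 0.08, size=5)))
                    for _ in range(2)
                ]
        subjects.append(s)

    truth = GroundTruth(true_a=config.effect_a, true_b=config.effect_b,
                        true_ab=config.effect_a * config.effect_b,
                        true_c_prime=config.direct_effect_c,
                        hub_mask=config.hub_mask,
                        wm_effect_mask=config.wm_effect_mask,
                        latent=latent, delta=delta, true_gain=true_gain)
    return subjects, truth


# ---------------------------------------------------------------------------
# Cohort directory writer
# ---------------------------------------------------------------------------

def write_cohort(subjects, truth: GroundTruth, outdir, write_bold: bool = True) -> None:
    """Write a cohort directory: cohort.csv, per-subject NIfTI volumes,
    gxt/<id>.csv and a plain-text ground_truth.json."""
    import json
    from pathlib import Path

    import pandas as pd

    from .cognition import percent_gain, score_d2r, score_digit_span, score_zvt
    from .volgrid import VolumeGrid, write_mask, write_timeseries, write_volume

    out = Path(outdir)
    (out / "gxt").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        row = {"id": s.id, "group": s.group, "age": s.age, "sex": s.sex}
        if s.d2r_pre is not None:
            row["d2r_cp_pre"] = score_d2r(s.d2r_pre)
            row["d2r_cp_post"] = score_d2r(s.d2r_post)
            row["d2r_gain_pct"] = percent_gain(row["d2r_cp_pre"], row["d2r_cp_post"])
            row["zvt_pre_s"] = score_zvt(s.zvt_pre)
            row["zvt_post_s"] = score_zvt(s.zvt_post)
            row["digit_pre"] = score_digit_span(s.digit_pre)
            row["digit_post"] = score_digit_span(s.digit_post)
        rows.append(row)
        if write_bold and s.bold_pre is not None:
            write_timeseries(s.bold_pre, out / f"{s.id}_pre_bold.nii.gz")
            write_timeseries(s.bold_post, out / f"{s.id}_post_bold.nii.gz")
        if s.eig_pre is not None:
            for tag, eig in (("pre", s.eig_pre), ("post", s.eig_post)):
                for j, name in enumerate(("l1", "l2", "l3")):
                    write_volume(VolumeGrid(eig[..., j]), out / f"{s.id}_{tag}_{name}.nii.gz")
        if s.gxt is not None:
            pd.DataFrame({"stage_w": s.gxt.stages, "hr_bpm": s.gxt.hr,
                          "lactate_mmol": s.gxt.lactate}).to_csv(
                out / "gxt" / f"{s.id}.csv", index=False)
    pd.DataFrame(rows).to_csv(out / "cohort.csv", index=False)
    write_mask(truth.hub_mask, out / "hub_mask.nii.gz")
    write_mask(truth.wm_effect_mask, out / "wm_effect_mask.nii.gz")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({"true_a": truth.true_a, "true_b": truth.true_b,
                   "true_ab": truth.true_ab, "true_c_prime": truth.true_c_prime,
                   "latent": truth.latent.tolist(), "delta": truth.delta.tolist(),
                   "true_gain": truth.true_gain.tolist()}, fh, indent=1)
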