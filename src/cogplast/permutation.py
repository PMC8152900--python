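"""Permutation GLM inference on voxel-wise change maps.

Group inference on per-subject change images uses a two-sample design with
nuisance covariates (age, sex, baseline), the Aspin-Welch v statistic
(unpooled variances, so unequal group sizes and variances are handled),
within-group sign-flipping of Freedman-Lane residuals to build the null,
threshold-free cluster enhancement (TFCE) of the statistic maps, and
family-wise error (FWE) correction from the permutation distribution of the
image-wide maximum TFCE value.

A nonparametric-combination (NPC) screen tests a mediation-consistent
pattern jointly: partial test 1 is the directional group effect on the map,
partial test 2 the directional slope of behavior on the map; both submodels
are permuted with the same sign-flip draws (synchronized permutations), each
partial statistic is converted to a p value by its rank within that voxel's
own permutation distribution, and the two are aggregated with Fisher's
combining function T = -2 (ln p1 + ln p2) before TFCE and max-statistic FWE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy import ndimage

from .centrality import connectivity_structure
from .volgrid import DimensionalityError, Mask, VolumeGrid

__all__ = [
    "DesignSpec",
    "PermutationScheme",
    "TFCEParams",
    "PermutationGLMResult",
    "NPCResult",
    "aspin_welch_v",
    "tfce",
    "fisher_combine",
    "run_glm_permutation",
    "npc_fisher_screen",
    "stack_maps",
    "label_clusters",
]


@dataclass
class DesignSpec:
    """Two-group design with optional nuisance covariates.

    group: 0 = control, 1 = exercise, per subject.  contrast +1 tests for
    greater values in the exercise group (-1 for smaller, e.g. diffusivity
    decreases).  Covariates are nuisance only (an intercept is always
    included).
    """

    group: np.ndarray
    covariates: Optional[np.ndarray] = None
    contrast: int = 1

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group).astype(int)
        if set(np.unique(self.group)) - {0, 1}:
            raise ValueError("group must be coded 0/1")
        if self.group.min() == self.group.max():
            raise ValueError("both groups must be represented")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=np.float64))
            if self.covariates.shape[0] != len(self.group):
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != len(self.group):
                raise ValueError("covariate rows must match subjects")
            if not np.all(np.isfinite(self.covariates)):
                raise ValueError("covariates must be complete")
        if self.contrast not in (-1, 1):
            raise ValueError("contrast must be +1 or -1")

    def nuisance_matrix(self) -> np.ndarray:
        n = len(self.group)
        if self.covariates is None:
            return np.ones((n, 1))
        return np.column_stack([np.ones(n), self.covariates])


@dataclass
class PermutationScheme:
    """Sign-flip draws for within-group permutation inference.

    ``flips`` has shape (n_draws, n_subjects) with the first row the
    identity (all +1).  Flips are drawn i.i.d. per subject; the group labels
    act as the variance groups of the v statistic (exchangeability blocks),
    not as flip-constraint units.  With ``exhaustive`` all 2^n distinct sign
    patterns are enumerated instead of sampled.
    """

    flips: np.ndarray
    blocks: np.ndarray
    seed: int
    exhaustive: bool = False

    @property
    def n_draws(self) -> int:
        return self.flips.shape[0]

    @classmethod
    def build(cls, groups, n_flips: int = 5000, seed: int = 0,
              exhaustive: bool = False) -> "PermutationScheme":
        groups = np.asarray(groups)
        n = len(groups)
        if exhaustive:
            if n > 20:
                raise ValueError("exhaustive enumeration is limited to n <= 20")
            bits = np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]
            flips = 1.0 - 2.0 * (bits & 1)  # row 0 is the identity
        else:
            rng = np.random.default_rng(seed)
            rand = rng.choice([-1.0, 1.0], size=(n_flips, n))
            flips = np.vstack([np.ones((1, n)), rand])
        return cls(flips=flips, blocks=groups.copy(), seed=seed, exhaustive=exhaustive)


@dataclass
class TFCEParams:
    """TFCE enhancement parameters (extent exponent E, height exponent H)."""

    E: float = 0.5
    H: float = 2.0
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be >= 0")
        if self.n_steps < 10:
            raise ValueError("n_steps must be >= 10")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def aspin_welch_v(y: np.ndarray, groups: np.ndarray, contrast: int = 1) -> np.ndarray:
    """Aspin-Welch v statistic (unpooled two-sample t) per voxel.

    ``y`` is (n_subjects,) or (n_subjects, V); groups coded 0/1.  v =
    contrast * (mean_1 - mean_0) / sqrt(s1^2/n1 + s0^2/n0).  Voxels with
    zero variance in both groups yield NaN (flagged, not enhanced).
    """
    y = np.asarray(y, dtype=np.float64)
    scalar = y.ndim == 1
    if scalar:
        y = y[:, None]
    g = np.asarray(groups).astype(bool)
    n1, n0 = int(g.sum()), int((~g).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs n >= 2")
    m1 = y[g].mean(axis=0)
    m0 = y[~g].mean(axis=0)
    v1 = y[g].var(axis=0, ddof=1)
    v0 = y[~g].var(axis=0, ddof=1)
    se2 = v1 / n1 + v0 / n0
    with np.errstate(invalid="ignore", divide="ignore"):
        v = contrast * (m1 - m0) / np.sqrt(se2)
    v = np.where(se2 == 0, np.nan, v)
    return float(v[0]) if scalar else v


def fisher_combine(*pvalues) -> np.ndarray:
    """Fisher's combining function T = -2 sum ln p over partial tests."""
    acc = 0.0
    for p in pvalues:
        acc = acc + np.log(np.asarray(p, dtype=np.float64))
    return -2.0 * acc


# ---------------------------------------------------------------------------
# TFCE (union-find fast path)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _uf_find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@njit(cache=True)
def _tfce_kernel(flat_vals, order, neighbors, thresholds, E, H, dh, out):
    """Accumulate TFCE scores processing thresholds in descending order.

    Voxels activate as the threshold drops below their value; connected
    components are maintained with a union-find, so each threshold costs
    O(active voxels) instead of a full relabeling.
    """
    nv = flat_vals.size
    parent = np.full(nv, -1, dtype=np.int64)
    size = np.zeros(nv, dtype=np.int64)
    m = order.size
    j = 0
    for ti in range(thresholds.size):
        h = thresholds[ti]
        while j < m and flat_vals[order[j]] >= h:
            v = order[j]
            parent[v] = v
            size[v] = 1
            for k in range(neighbors.shape[1]):
                u = neighbors[v, k]
                if u >= 0 and parent[u] >= 0:
                    ru = _uf_find(parent, u)
                    rv = _uf_find(parent, v)
                    if ru != rv:
                        if size[ru] < size[rv]:
                            ru, rv = rv, ru
                        parent[rv] = ru
                        size[ru] += size[rv]
            j += 1
        inc = (h ** H) * dh
        for idx in range(j):
            v = order[idx]
            r = _uf_find(parent, v)
            out[v] += (size[r] ** E) * inc


_NEIGHBOR_CACHE: dict = {}


def _neighbor_table(shape, connectivity: int) -> np.ndarray:
    key = (tuple(shape), connectivity)
    cached = _NEIGHBOR_CACHE.get(key)
    if cached is not None:
        return cached
    struct = connectivity_structure(connectivity)
    offsets = [tuple(o - 1 for o in idx) for idx in zip(*np.nonzero(struct))
               if tuple(o - 1 for o in idx) != (0, 0, 0)]
    nv = int(np.prod(shape))
    grid = np.arange(nv, dtype=np.int64).reshape(shape)
    nb = np.full((nv, len(offsets)), -1, dtype=np.int64)
    for k, (dx, dy, dz) in enumerate(offsets):
        shifted = np.full(shape, -1, dtype=np.int64)
        src = tuple(slice(max(d, 0), s + min(d, 0)) for d, s in zip((dx, dy, dz), shape))
        dst = tuple(slice(max(-d, 0), s + min(-d, 0)) for d, s in zip((dx, dy, dz), shape))
        shifted[dst] = grid[src]
        nb[:, k] = shifted.ravel()
    _NEIGHBOR_CACHE[key] = nb
    return nb


def tfce(values: np.ndarray, params: TFCEParams = None, dh: float = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3D statistic map.

    TFCE(p) = sum_h e_h(p)^E * h^H * dh over thresholds h = dh, 2dh, ...,
    where e_h(p) is the voxel count of p's connected suprathreshold
    component at height h.  Only positive values are enhanced (one-sided
    contrasts); NaN values are treated as 0.  ``dh`` defaults to
    max(values) / n_steps; pass the observed map's dh when enhancing
    permuted maps so enhancement is comparable across draws.
    """
    params = params or TFCEParams()
    vals = np.asarray(values, dtype=np.float64)
    if vals.ndim != 3:
        raise DimensionalityError(f"TFCE expects a 3D map, got {vals.ndim}D")
    flat = np.where(np.isfinite(vals) & (vals > 0), vals, 0.0).ravel()
    out = np.zeros_like(flat)
    mx = flat.max() if flat.size else 0.0
    if mx <= 0:
        return out.reshape(vals.shape)
    if dh is None:
        dh = mx / params.n_steps
    # generous epsilon: a spurious empty top threshold adds nothing, while
    # dropping a populated one (mx/dh a few ulps under an integer) would
    # change the enhancement of the peak
    n_thr = int(np.floor(mx / dh + 1e-6))
    if n_thr < 1:
        return out.reshape(vals.shape)
    thresholds = dh * np.arange(1, n_thr + 1, dtype=np.float64)
    # the top threshold may exceed the map maximum by rounding when dh was
    # derived from an equal-to-ulp copy of this map; clamp so the peak's top
    # slab is never silently dropped
    thresholds[-1] = min(thresholds[-1], mx)
    pos = np.flatnonzero(flat > 0)
    order = pos[np.argsort(flat[pos])[::-1]].astype(np.int64)
    nb = _neighbor_table(vals.shape, params.connectivity)
    _tfce_kernel(flat, order, nb, thresholds[::-1].copy(), params.E, params.H,
                 float(dh), out)
    return out.reshape(vals.shape)


# ---------------------------------------------------------------------------
# Freedman-Lane sign-flip GLM
# ---------------------------------------------------------------------------

def stack_maps(maps, mask: Mask):
    """Stack per-subject maps to (n_subjects, V) over the analyzable voxels.

    ``maps`` may be a sequence of VolumeGrids/arrays or an (n, V) array.
    Voxels missing (NaN) in any subject are excluded; returns (Y,
    analysis_mask) where analysis_mask marks the retained voxels in 3D.
    """
    if isinstance(maps, np.ndarray) and maps.ndim == 2:
        Y = maps
        valid = np.all(np.isfinite(Y), axis=0)
        am = np.zeros(mask.shape, dtype=bool)
        am[mask.membership] = valid
        return Y[:, valid], Mask(am)
    rows = []
    for m in maps:
        arr = m.values if hasattr(m, "values") else np.asarray(m, dtype=np.float64)
        rows.append(arr[mask.membership])
    Y = np.vstack(rows)
    valid = np.all(np.isfinite(Y), axis=0)
    am = np.zeros(mask.shape, dtype=bool)
    am[mask.membership] = valid
    if not valid.any():
        raise ValueError("no voxel is complete across subjects")
    return Y[:, valid], Mask(am)


def _residual_projector(Z: np.ndarray):
    """Return a function applying I - Z (Z'Z)^{-1} Z' to (n, V) data."""
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("nuisance design is rank deficient")
    pinv = np.linalg.pinv(Z)

    def apply(Y):
        return Y - Z @ (pinv @ Y)

    return apply


def freedman_lane_flip(y: np.ndarray, design: DesignSpec, flip: np.ndarray):
    """Reconstructed data for one sign-flip draw under Freedman-Lane.

    Residuals of ``y`` on the nuisance-only model (intercept + covariates)
    are sign-flipped per subject and the nuisance fit re-added.  With the
    identity flip the data are returned unchanged.
    """
    y = np.asarray(y, dtype=np.float64)
    Z = design.nuisance_matrix()
    proj = _residual_projector(Z)
    Y = y[:, None] if y.ndim == 1 else y
    E = proj(Y)
    F = Y - E
    out = F + np.asarray(flip, dtype=np.float64)[:, None] * E
    return out[:, 0] if y.ndim == 1 else out


def _scatter(vec: np.ndarray, mask: Mask) -> np.ndarray:
    out = np.zeros(mask.shape)
    out[mask.membership] = vec
    return out


@dataclass
class PermutationGLMResult:
    v_map: VolumeGrid
    tfce_map: VolumeGrid
    fwe_p: VolumeGrid
    analysis_mask: Mask
    max_distribution: np.ndarray
    scheme: PermutationScheme
    dh: float

    def min_p(self) -> float:
        return float(np.nanmin(self.fwe_p.values[self.analysis_mask.membership]))


def _fwe_p_from_max(obs_tfce_masked: np.ndarray, max_dist: np.ndarray) -> np.ndarray:
    """FWE p per voxel: share of draws (identity included) whose spatial
    maximum reaches the voxel's observed TFCE score; never 0."""
    # max_dist[0] is the identity draw
    counts = (max_dist[None, :] >= obs_tfce_masked[:, None]).sum(axis=1)
    return counts / max_dist.size


def run_glm_permutation(maps, mask: Mask, design: DesignSpec,
                        scheme: PermutationScheme = None,
                        tfce_params: TFCEParams = None) -> PermutationGLMResult:
    """Voxel-wise group inference with sign-flip permutations, TFCE and
    max-statistic FWE correction.

    The observed Aspin-Welch v map is TFCE-enhanced; each flip draw
    reconstructs the data Freedman-Lane style, recomputes the v map and its
    TFCE enhancement (reusing the observed dh) and records the spatial
    maximum.  FWE p at a voxel is (1 + #{non-identity draws with max >=
    observed TFCE}) / (1 + n_flips).
    """
    tfce_params = tfce_params or TFCEParams()
    Y, amask = stack_maps(maps, mask)
    n = Y.shape[0]
    if len(design.group) != n:
        raise ValueError("design rows do not match number of subject maps")
    g = design.group
    if (g == 1).sum() < 3 or (g == 0).sum() < 3:
        raise ValueError("need >= 3 subjects per group")
    scheme = scheme or PermutationScheme.build(g)
    if scheme.flips.shape[1] != n:
        raise ValueError("scheme subject count does not match maps")

    Z = design.nuisance_matrix()
    proj = _residual_projector(Z)
    E = proj(Y)                      # Freedman-Lane residuals; P E = E

    v_obs = aspin_welch_v(E, g, design.contrast)
    t_obs3 = tfce(_scatter(np.nan_to_num(v_obs), amask), tfce_params)
    dh = np.nanmax(np.where(np.isfinite(v_obs) & (v_obs > 0), v_obs, 0.0))
    dh = dh / tfce_params.n_steps if dh > 0 else 1.0

    max_dist = np.empty(scheme.n_draws)
    max_dist[0] = t_obs3.max()
    for d in range(1, scheme.n_draws):
        s = scheme.flips[d]
        v_d = aspin_welch_v(proj(s[:, None] * E), g, design.contrast)
        t_d = tfce(_scatter(np.nan_to_num(v_d), amask), tfce_params, dh=dh)
        max_dist[d] = t_d.max()

    obs_masked = t_obs3[amask.membership]
    p_masked = _fwe_p_from_max(obs_masked, max_dist)
    vs = maps[0].voxel_size if hasattr(maps[0], "voxel_size") else (1.0, 1.0, 1.0)
    return PermutationGLMResult(
        v_map=VolumeGrid(_scatter(v_obs, amask), vs),
        tfce_map=VolumeGrid(t_obs3, vs),
        fwe_p=VolumeGrid(np.where(amask.membership, _scatter(p_masked, amask), np.nan), vs),
        analysis_mask=amask, max_distribution=max_dist, scheme=scheme, dh=float(dh),
    )


# ---------------------------------------------------------------------------
# Nonparametric combination
# ---------------------------------------------------------------------------

def _rank_p(stats_matrix: np.ndarray) -> np.ndarray:
    """Per-voxel permutation p of every draw's statistic (larger = more
    extreme): p[d, v] = #{d' : S[d', v] >= S[d, v]} / n_draws (self counted,
    so p >= 1/n_draws; ties share the larger count)."""
    from scipy.stats import rankdata

    D = stats_matrix.shape[0]
    return rankdata(-stats_matrix, axis=0, method="max") / D


@dataclass
class NPCResult:
    combined_map: VolumeGrid       # observed Fisher T map
    tfce_map: VolumeGrid
    fwe_p: VolumeGrid
    analysis_mask: Mask
    max_distribution: np.ndarray
    clusters: list                 # dicts: label, extent, peak_index, peak_p
    cluster_labels: np.ndarray
    partial_p_observed: tuple      # (p1, p2) maps over analysis mask


def label_clusters(sig: np.ndarray, score: np.ndarray, p: np.ndarray,
                   connectivity: int = 26):
    """Connected components of a significance mask with extent and peak."""
    labels, n = ndimage.label(sig, structure=connectivity_structure(connectivity))
    out = []
    relabeled = np.zeros_like(labels)
    comps = []
    for lab in range(1, n + 1):
        comp = labels == lab
        comps.append((int(comp.sum()), lab, comp))
    comps.sort(reverse=True, key=lambda t: t[0])
    for new, (extent, lab, comp) in enumerate(comps, start=1):
        relabeled[comp] = new
        masked_score = np.where(comp, score, -np.inf)
        peak = np.unravel_index(int(np.argmax(masked_score)), sig.shape)
        out.append({"label": new, "extent": extent, "peak_index": tuple(int(i) for i in peak),
                    "peak_p": float(p[peak])})
    return out, relabeled


def npc_fisher_screen(maps, mask: Mask, design: DesignSpec, behavior,
                      scheme: PermutationScheme = None,
                      tfce_params: TFCEParams = None,
                      alpha: float = 0.05,
                      behavior_contrast: int = None) -> NPCResult:
    """Joint (NPC) mediation screen over voxels.

    Partial test 1: directional group effect on the map, age/sex-adjusted
    (Aspin-Welch v on Freedman-Lane residuals).  Partial test 2: directional
    slope of behavior on the map, adjusting for age, sex and group.  The
    same sign-flip vector drives both submodels at every draw; per voxel,
    each partial statistic becomes a p value by rank within that voxel's own
    permutation distribution, the two are combined with Fisher's T =
    -2(ln p1 + ln p2), T maps are TFCE-enhanced and FWE-corrected with the
    maximum statistic.  Suprathreshold voxels at ``alpha`` are returned as
    labeled clusters.
    """
    tfce_params = tfce_params or TFCEParams()
    behavior = np.asarray(behavior, dtype=np.float64)
    if not np.all(np.isfinite(behavior)):
        raise ValueError("behavior scores must be complete")
    Y, amask = stack_maps(maps, mask)
    n, V = Y.shape
    g = design.group
    scheme = scheme or PermutationScheme.build(g)
    D = scheme.n_draws
    bc = design.contrast if behavior_contrast is None else behavior_contrast

    # submodel 1: group effect on maps, nuisance = intercept + covariates
    proj1 = _residual_projector(design.nuisance_matrix())
    E1 = proj1(Y)

    # submodel 2: slope of behavior on each voxel, nuisance = intercept +
    # covariates + group; Freedman-Lane flips the behavior residuals
    Z2 = np.column_stack([design.nuisance_matrix(), g.astype(float)])
    proj2 = _residual_projector(Z2)
    e2 = proj2(behavior[:, None])[:, 0]
    My = proj2(Y)                                   # voxel maps, nuisance removed
    My_norm = np.linalg.norm(My, axis=0)
    My_norm[My_norm == 0] = np.nan
    df2 = n - Z2.shape[1] - 1

    S1 = np.empty((D, V))
    S2 = np.empty((D, V))
    for d in range(D):
        s = scheme.flips[d]
        S1[d] = aspin_welch_v(proj1(s[:, None] * E1), g, design.contrast)
        bt = proj2((s * e2)[:, None])[:, 0]
        bn = np.linalg.norm(bt)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (My.T @ bt) / (My_norm * bn) if bn > 0 else np.full(V, np.nan)
            r = np.clip(r, -1.0, 1.0)
            S2[d] = bc * r * np.sqrt(df2 / np.maximum(1e-300, 1.0 - r ** 2))
    S1 = np.nan_to_num(S1, nan=-np.inf)
    S2 = np.nan_to_num(S2, nan=-np.inf)

    p1 = _rank_p(S1)
    p2 = _rank_p(S2)
    T = fisher_combine(p1, p2)                      # (D, V)

    t_obs3 = tfce(_scatter(T[0], amask), tfce_params)
    mx = T[0].max()
    dh = mx / tfce_params.n_steps if mx > 0 else 1.0
    max_dist = np.empty(D)
    max_dist[0] = t_obs3.max()
    for d in range(1, D):
        max_dist[d] = tfce(_scatter(T[d], amask), tfce_params, dh=dh).max()

    obs_masked = t_obs3[amask.membership]
    p_masked = _fwe_p_from_max(obs_masked, max_dist)
    p3 = np.where(amask.membership, _scatter(p_masked, amask), np.nan)
    sig = amask.membership & (p3 <= alpha)
    clusters, labels = label_clusters(sig, t_obs3, p3, tfce_params.connectivity)

    vs = maps[0].voxel_size if hasattr(maps[0], "voxel_size") else (1.0, 1.0, 1.0)
    return NPCResult(
        combined_map=VolumeGrid(_scatter(T[0], amask), vs),
        tfce_map=VolumeGrid(t_obs3, vs),
        fwe_p=VolumeGrid(p3, vs),
        analysis_mask=amask, max_distribution=max_dist,
        clusters=clusters, cluster_labels=labels,
        partial_p_observed=(p1[0], p2[0]),
    )
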