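"""Group-level inference on per-source maps.

Model-comparison statistics for encoding models: Gaussian smoothing of
per-source maps, threshold-free cluster enhancement (TFCE), max-statistic
permutation tests (paired condition-label and one-sample sign-flip),
region-of-interest summaries with Cohen's d, the entropy/surprisal ratio
interaction test between participant groups, and sign-aligned principal
component analysis of TRFs.

TFCE integrates cluster extent and height over all thresholds,

    tfce(v) = sum_h extent_h(v)^E * h^H * dh   for h = dh, 2dh, ... <= stat(v)

where ``extent_h(v)`` is the size of the connected suprathreshold component
containing source ``v``.  Negative statistics are enhanced by applying the
same integral to the negated map and negating the result, so two-tailed
max-|TFCE| null distributions are well defined.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from scipy import stats as _sps

__all__ = [
    "SourceGeometry",
    "StatMap",
    "TestResult",
    "ROISummary",
    "smooth_map",
    "tfce",
    "paired_permutation_test",
    "signflip_test",
    "roi_summary",
    "cohens_d",
    "ratio_interaction_test",
    "trf_pca_align",
    "chain_adjacency",
]


@dataclass
class SourceGeometry:
    """Source-space geometry: coordinates, adjacency, orientations, labels."""

    coordinates: np.ndarray  # (V, 3) mm
    edges: np.ndarray  # (E, 2) int, undirected unique pairs
    orientations: np.ndarray | None = None  # (V, 3) unit vectors
    roi_mask: np.ndarray | None = None  # (V,) bool
    hemisphere: np.ndarray | None = None  # (V,) int in {0, 1}

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, float)
        self.edges = np.asarray(self.edges, np.int64).reshape(-1, 2)
        V = self.n_sources
        if self.edges.size and self.edges.max() >= V:
            raise ValueError("edge index out of range")
        if self.orientations is not None:
            self.orientations = np.asarray(self.orientations, float)
            norms = np.linalg.norm(self.orientations, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("orientation vectors must be unit norm")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, bool)
        if self.hemisphere is not None:
            self.hemisphere = np.asarray(self.hemisphere, int)

    @property
    def n_sources(self) -> int:
        return self.coordinates.shape[0]

    @classmethod
    def grid(
        cls,
        nx: int,
        ny: int,
        spacing: float = 5.0,
        roi: tuple[int, int, int, int] | None = None,
        split_hemispheres: bool = False,
    ) -> "SourceGeometry":
        """A 2-D grid of sources with 4-neighbour adjacency.

        ``roi`` is an inclusive ``(x0, x1, y0, y1)`` index box.  With
        ``split_hemispheres`` the grid's left/right halves (x index) receive
        hemisphere labels 0/1.  Orientations all point "up" (+z), which is
        sufficient for sign-alignment of PCA components.
        """
        xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        coords = np.column_stack(
            [xs.ravel() * spacing, ys.ravel() * spacing, np.zeros(nx * ny)]
        )
        edges = []
        for i in range(nx):
            for j in range(ny):
                v = i * ny + j
                if i + 1 < nx:
                    edges.append((v, (i + 1) * ny + j))
                if j + 1 < ny:
                    edges.append((v, v + 1))
        orient = np.tile([0.0, 0.0, 1.0], (nx * ny, 1))
        roi_mask = None
        if roi is not None:
            x0, x1, y0, y1 = roi
            roi_mask = ((xs >= x0) & (xs <= x1) & (ys >= y0) & (ys <= y1)).ravel()
        hemi = (xs >= nx / 2).ravel().astype(int) if split_hemispheres else None
        return cls(coords, np.asarray(edges), orient, roi_mask, hemi)


def chain_adjacency(n: int) -> np.ndarray:
    """Edges of a 1-D chain (for TFCE over a time axis)."""
    i = np.arange(n - 1)
    return np.column_stack([i, i + 1])


@dataclass
class StatMap:
    """Per-subject, per-source scalar values."""

    values: np.ndarray  # (n_subjects, n_sources)
    geometry: SourceGeometry | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite values in StatMap")
        if self.geometry is not None and (
            self.values.shape[1] != self.geometry.n_sources
        ):
            raise ValueError("StatMap does not match geometry source count")


@dataclass
class TestResult:
    """Observed statistic, TFCE enhancement, p-values and null summary."""

    statistic: np.ndarray
    tfce_map: np.ndarray
    p: np.ndarray
    null_max: np.ndarray
    n_permutations: int
    seed: int | None = None
    tail: str = "two"

    def __post_init__(self) -> None:
        lo = 1.0 / (self.n_permutations + 1)
        if ((self.p < lo - 1e-12) | (self.p > 1 + 1e-12)).any():
            raise ValueError("p-values outside [1/(n_perm+1), 1]")

    @property
    def significant(self) -> np.ndarray:
        return self.p <= 0.05


# ---------------------------------------------------------------------------
# smoothing


def smooth_map(
    values: np.ndarray | StatMap,
    geometry: SourceGeometry,
    sd: float = 5.0,
    truncate: float = 3.0,
):
    """Gaussian-kernel smoothing over the source space.

    Weights ``exp(-d^2 / 2 sd^2)`` from inter-source Euclidean distance
    (mm), truncated at ``truncate * sd`` and normalized to sum 1 per source,
    so constant maps are preserved.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    vals = values.values if isinstance(values, StatMap) else np.atleast_2d(
        np.asarray(values, float)
    )
    xyz = geometry.coordinates
    d2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(-1)
    W = np.exp(-d2 / (2 * sd**2))
    W[d2 > (truncate * sd) ** 2] = 0.0
    W /= W.sum(axis=1, keepdims=True)
    out = vals @ W.T
    if isinstance(values, StatMap):
        return StatMap(out, geometry)
    return out if np.asarray(values).ndim == 2 else out[0]


# ---------------------------------------------------------------------------
# TFCE


@njit(cache=True)
def _tfce_onesided(stat, edges, dh, E, H, out):
    """Accumulate the TFCE integral for nonnegative ``stat`` into ``out``."""
    V = stat.shape[0]
    n_edges = edges.shape[0]
    m = 0.0
    for v in range(V):
        if stat[v] > m:
            m = stat[v]
    if m <= 0.0:
        return
    n_steps = int(np.floor(m / dh + 1e-9))
    parent = np.empty(V, np.int64)
    size = np.empty(V, np.int64)
    for s in range(1, n_steps + 1):
        h = s * dh
        # union-find over suprathreshold sources
        for v in range(V):
            parent[v] = v
            size[v] = 1
        above = stat >= h
        for e in range(n_edges):
            a = edges[e, 0]
            b = edges[e, 1]
            if above[a] and above[b]:
                ra = a
                while parent[ra] != ra:
                    ra = parent[ra]
                rb = b
                while parent[rb] != rb:
                    rb = parent[rb]
                if ra != rb:
                    if size[ra] < size[rb]:
                        ra, rb = rb, ra
                    parent[rb] = ra
                    size[ra] += size[rb]
        hterm = h**H * dh
        for v in range(V):
            if above[v]:
                r = v
                while parent[r] != r:
                    r = parent[r]
                out[v] += size[r] ** E * hterm


def tfce(
    stat_map: np.ndarray,
    edges: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a per-source statistic map.

    ``dh`` defaults to ``max(|stat|) / 100``.  Output carries the sign of
    the input (negative clusters enhanced on the negated map).
    """
    stat = np.asarray(stat_map, float)
    if stat.size == 0:
        raise ValueError("empty statistic map")
    if not np.isfinite(stat).all():
        raise ValueError("non-finite statistic")
    edges = np.asarray(edges, np.int64).reshape(-1, 2)
    m = np.abs(stat).max()
    if m == 0:
        return np.zeros_like(stat)
    if dh is None:
        dh = m / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    out = np.zeros_like(stat)
    pos = np.maximum(stat, 0.0)
    neg = np.maximum(-stat, 0.0)
    _tfce_onesided(pos, edges, dh, E, H, out)
    if (neg > 0).any():
        nout = np.zeros_like(stat)
        _tfce_onesided(neg, edges, dh, E, H, nout)
        out -= nout
    return out


# ---------------------------------------------------------------------------
# permutation tests

_T_CAP = 1e6  # zero-variance t statistics are capped, keeping TFCE finite


def _t_onesample(x: np.ndarray) -> np.ndarray:
    """One-sample t over axis 0, with zero-variance values capped."""
    n = x.shape[0]
    mean = x.mean(0)
    sd = x.std(0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(sd == 0, np.sign(mean) * _T_CAP, t)
    return np.clip(t, -_T_CAP, _T_CAP)


def paired_permutation_test(
    maps_a: StatMap | np.ndarray,
    maps_b: StatMap | np.ndarray,
    edges: np.ndarray | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
    tail: str = "two",
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    exhaustive: bool | str = "auto",
    geometry: SourceGeometry | None = None,
) -> TestResult:
    """Mass-univariate paired t test with TFCE and a max-statistic null.

    The observed statistic is the per-source paired t on ``a - b``; the null
    distribution is built from the maximum TFCE statistic over sources under
    random within-subject condition swaps (sign flips of the differences).
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``, or the exact
    enumeration fraction in ``exhaustive`` mode (all ``2^n`` flips).
    """
    a = maps_a.values if isinstance(maps_a, StatMap) else np.atleast_2d(maps_a)
    b = maps_b.values if isinstance(maps_b, StatMap) else np.atleast_2d(maps_b)
    if a.shape != b.shape:
        raise ValueError("maps must share subjects and sources")
    if a.shape[0] < 2:
        raise ValueError("paired test needs at least 2 subjects")
    if edges is None:
        if geometry is None and isinstance(maps_a, StatMap):
            geometry = maps_a.geometry
        if geometry is None:
            raise ValueError("provide adjacency edges or a geometry")
        edges = geometry.edges
    d = a - b
    return _signflip_max_test(d, edges, n_perm, seed, tail, E, H, dh, exhaustive)


def signflip_test(
    timecourses: np.ndarray,
    edges: np.ndarray | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
    tail: str = "two",
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    exhaustive: bool | str = "auto",
) -> TestResult:
    """Mass-univariate one-sample t test vs 0 with TFCE sign-flip null.

    ``timecourses`` is ``(n_subjects, n_points)``; adjacency defaults to the
    1-D chain along the second axis (a time axis).
    """
    x = np.atleast_2d(np.asarray(timecourses, float))
    if x.shape[0] < 2:
        raise ValueError("sign-flip test needs at least 2 subjects")
    if (x.std(0) == 0).all():
        raise ValueError("input constant across subjects; test degenerate")
    if edges is None:
        edges = chain_adjacency(x.shape[1])
    return _signflip_max_test(x, edges, n_perm, seed, tail, E, H, dh, exhaustive)


def _signflip_max_test(d, edges, n_perm, seed, tail, E, H, dh, exhaustive):
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in ("two", "greater"):
        raise ValueError("tail must be 'two' or 'greater'")
    n_subj = d.shape[0]
    if exhaustive == "auto":
        # exact test whenever the full sign-flip orbit is affordable
        exhaustive = 2**n_subj <= n_perm
    t_obs = _t_onesample(d)
    # common dh across permutations keeps enhanced values comparable
    if dh is None:
        m = np.abs(t_obs).max()
        dh = (m if m > 0 else 1.0) / 100.0
    tfce_obs = tfce(t_obs, edges, E, H, dh)

    if exhaustive:
        signs_iter = (
            np.asarray(s, float) for s in itertools.product((1.0, -1.0), repeat=n_subj)
        )
        n_null = 2**n_subj
    else:
        rng = np.random.default_rng(seed)
        signs_iter = (
            rng.choice((1.0, -1.0), size=n_subj) for _ in range(n_perm)
        )
        n_null = n_perm

    null_max = np.empty(n_null)
    for i, s in enumerate(signs_iter):
        t_p = _t_onesample(d * s[:, None])
        tf = tfce(t_p, edges, E, H, dh)
        null_max[i] = np.abs(tf).max() if tail == "two" else tf.max()

    obs_stat = np.abs(tfce_obs) if tail == "two" else tfce_obs
    if exhaustive:
        p = (null_max[None, :] >= obs_stat[:, None] - 1e-12).mean(axis=1)
        n_eff = n_null - 1  # identity permutation is part of the orbit
    else:
        p = (1.0 + (null_max[None, :] >= obs_stat[:, None] - 1e-12).sum(axis=1)) / (
            n_perm + 1.0
        )
        n_eff = n_perm
    p = np.clip(p, 1.0 / (n_eff + 1.0), 1.0)
    return TestResult(
        statistic=t_obs,
        tfce_map=tfce_obs,
        p=p,
        null_max=null_max,
        n_permutations=n_eff,
        seed=seed,
        tail=tail,
    )


# ---------------------------------------------------------------------------
# ROI summaries and effect sizes


def cohens_d(values: np.ndarray) -> float:
    """One-sample Cohen's d: mean / SD (sample SD, ddof=1)."""
    values = np.asarray(values, float)
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation; Cohen's d undefined")
    return float(values.mean() / sd)


@dataclass
class ROISummary:
    per_subject: np.ndarray  # (n_subjects,)
    mean: float
    d: float
    hemisphere_t: float | None = None
    hemisphere_p: float | None = None
    hemispheres_averaged: bool = True
    per_hemisphere: np.ndarray | None = None  # (n_subjects, 2)


def roi_summary(
    stat_map: StatMap | np.ndarray,
    roi_mask: np.ndarray | None = None,
    hemisphere_labels: np.ndarray | None = None,
    test_hemispheres: bool = False,
    alpha: float = 0.05,
) -> ROISummary:
    """Per-subject ROI mean and Cohen's d.

    With ``test_hemispheres`` and hemisphere labels, the left/right ROI
    means are first compared with a paired t test; hemispheres are averaged
    (the default summary) when the difference is not significant, mirroring
    the practice of collapsing symmetric ROIs absent lateralization.
    """
    if isinstance(stat_map, StatMap):
        vals = stat_map.values
        if roi_mask is None and stat_map.geometry is not None:
            roi_mask = stat_map.geometry.roi_mask
        if hemisphere_labels is None and stat_map.geometry is not None:
            hemisphere_labels = stat_map.geometry.hemisphere
    else:
        vals = np.atleast_2d(np.asarray(stat_map, float))
    if roi_mask is None:
        roi_mask = np.ones(vals.shape[1], bool)
    roi_mask = np.asarray(roi_mask, bool)
    if not roi_mask.any():
        raise ValueError("empty ROI mask")

    hemi_t = hemi_p = None
    per_hemi = None
    averaged = True
    if test_hemispheres:
        if hemisphere_labels is None:
            raise ValueError("hemisphere labels required for hemisphere test")
        labels = np.asarray(hemisphere_labels, int)
        m0 = roi_mask & (labels == 0)
        m1 = roi_mask & (labels == 1)
        if not (m0.any() and m1.any()):
            raise ValueError("ROI empty in one hemisphere")
        per_hemi = np.column_stack([vals[:, m0].mean(1), vals[:, m1].mean(1)])
        hemi_t, hemi_p = _sps.ttest_rel(per_hemi[:, 0], per_hemi[:, 1])
        hemi_t, hemi_p = float(hemi_t), float(hemi_p)
        averaged = hemi_p > alpha
        per_subject = per_hemi.mean(1) if averaged else vals[:, roi_mask].mean(1)
    else:
        per_subject = vals[:, roi_mask].mean(1)

    return ROISummary(
        per_subject=per_subject,
        mean=float(per_subject.mean()),
        d=cohens_d(per_subject),
        hemisphere_t=hemi_t,
        hemisphere_p=hemi_p,
        hemispheres_averaged=averaged,
        per_hemisphere=per_hemi,
    )


def ratio_interaction_test(
    entropy_deltas_g1: np.ndarray,
    surprisal_deltas_g1: np.ndarray,
    entropy_deltas_g2: np.ndarray,
    surprisal_deltas_g2: np.ndarray,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Between-group t test on the per-subject entropy/surprisal power ratio.

    Each subject contributes ``ratio = (unique entropy power) / (unique
    surprisal power)``; the two groups' ratios are compared with a pooled-
    variance two-sample t test (``df = n1 + n2 - 2``), or Welch's variant.
    Returns ``(t, df, p)`` (two-tailed).
    """
    e1 = np.asarray(entropy_deltas_g1, float)
    s1 = np.asarray(surprisal_deltas_g1, float)
    e2 = np.asarray(entropy_deltas_g2, float)
    s2 = np.asarray(surprisal_deltas_g2, float)
    if e1.shape != s1.shape or e2.shape != s2.shape:
        raise ValueError("entropy/surprisal delta shape mismatch")
    if len(e1) < 2 or len(e2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    for name, s in (("group 1", s1), ("group 2", s2)):
        zero = np.flatnonzero(s == 0)
        if zero.size:
            raise ValueError(
                f"zero surprisal delta for {name} subject(s) {zero.tolist()}; "
                "ratio undefined"
            )
    r1 = e1 / s1
    r2 = e2 / s2
    if welch:
        t, p = _sps.ttest_ind(r1, r2, equal_var=False)
        df = _welch_df(r1, r2)
    else:
        t, p = _sps.ttest_ind(r1, r2, equal_var=True)
        df = len(r1) + len(r2) - 2
    return float(t), float(df), float(p)


def _welch_df(x, y):
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    return float(
        (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    )


# ---------------------------------------------------------------------------
# TRF PCA with sign alignment


def trf_pca_align(
    trfs: np.ndarray,
    geometry: SourceGeometry,
    mask: np.ndarray | None = None,
    up: Sequence[float] = (0.0, 0.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """First principal component of each subject's sources-by-time TRF.

    For every subject the ``(V, T)`` TRF (restricted to ``mask``) is
    decomposed by SVD; the first spatial component (unit norm) and its time
    course (carrying the singular value) are returned.  Because a principal
    component's sign is arbitrary, each subject's component is flipped so
    that its orientation-weighted mean current vector has a positive
    projection on ``up``; negating a subject's entire TRF therefore leaves
    the aligned outputs unchanged.

    Returns ``(maps, timecourses)`` with shapes ``(n_subj, V_mask)`` and
    ``(n_subj, T)``.
    """
    trfs = np.asarray(trfs, float)
    if trfs.ndim == 2:
        trfs = trfs[None]
    n_subj, V, T = trfs.shape
    if mask is None:
        mask = np.ones(V, bool)
    mask = np.asarray(mask, bool)
    if geometry.orientations is None:
        raise ValueError("geometry lacks orientation vectors")
    orient = geometry.orientations[mask]
    up = np.asarray(up, float)

    maps = np.empty((n_subj, mask.sum()))
    courses = np.empty((n_subj, T))
    for s in range(n_subj):
        X = trfs[s][mask]
        if not X.any():
            raise ValueError(f"subject {s}: TRF is identically zero (rank 0)")
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        comp = U[:, 0]
        course = S[0] * Vt[0]
        mean_current = (comp[:, None] * orient).mean(0)
        if mean_current @ up < 0:
            comp = -comp
            course = -course
        maps[s] = comp
        courses[s] = course
    return maps, courses
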