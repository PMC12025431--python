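"""Polarity-invariant modified k-means over GFP-peak topographies.

The modified k-means treats a map and its negation as the same state: cluster
membership maximizes the squared normalized inner product between an observed
map and a template, and the template update is the dominant eigenvector of the
scatter matrix of its assigned maps (the polarity-invariant analog of the
cluster mean). Model quality is summarized by the global explained variance
(GEV, GFP-weighted fraction of topographic variance captured by the assigned
templates) and by a small-sample-corrected cross-validation criterion used to
choose the number of classes k; lower CV is better.

All map comparisons operate on spatially centered maps (the spatial mean of
each topography is removed), so inner products coincide with Pearson spatial
correlations up to norms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment



class ClusteringError(ValueError):
    """Raised on degenerate clustering inputs."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class TopographySet:
    """Observed maps to cluster: (n_observations, n_channels) in µV."""

    maps: np.ndarray
    channels: list[str]

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ClusteringError("maps must be (observations, channels)")
        if not np.all(np.isfinite(self.maps)):
            raise ClusteringError("maps contain non-finite values")
        if self.maps.shape[1] != len(self.channels):
            raise ClusteringError("channel label count mismatch")

    @property
    def n_obs(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class TemplateSet:
    """K zero-mean, unit-norm template maps with class labels and fit metrics."""

    templates: np.ndarray
    channels: list[str]
    labels: list[str]
    gev: float | None = None
    cv: float | None = None

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        if self.templates.ndim != 2:
            raise ClusteringError("templates must be (K, channels)")
        means = np.abs(self.templates.mean(axis=1))
        norms = np.abs(np.linalg.norm(self.templates, axis=1) - 1.0)
        if np.any(means > 1e-9) or np.any(norms > 1e-9):
            raise ClusteringError("template rows must be zero-mean, unit-norm")
        if len(self.labels) != self.templates.shape[0]:
            raise ClusteringError("one label per template required")
        if len(set(self.labels)) != len(self.labels):
            raise ClusteringError("template labels must be unique")
        if self.gev is not None and not (0.0 <= self.gev <= 1.0 + 1e-12):
            raise ClusteringError(f"GEV out of [0,1]: {self.gev}")

    @property
    def k(self) -> int:
        return self.templates.shape[0]

    def to_files(self, path: str | Path) -> None:
        """Delimited matrix (rows = classes) plus key=value metadata sidecar."""
        path = Path(path)
        header = "\t".join(self.channels)
        np.savetxt(path, self.templates, delimiter="\t", header=header,
                   comments="", fmt="%.10e")
        meta = [f"labels = {','.join(self.labels)}", f"k = {self.k}"]
        if self.gev is not None:
            meta.append(f"gev = {self.gev!r}")
        if self.cv is not None:
            meta.append(f"cv = {self.cv!r}")
        path.with_suffix(path.suffix + ".meta").write_text("\n".join(meta) + "\n")


@dataclass
class ClusterDiagnostics:
    """Per-restart and per-k bookkeeping for a clustering run."""

    restart_gev: list[float] = field(default_factory=list)
    restart_iterations: list[int] = field(default_factory=list)
    chosen_restart: int = 0
    k_table: dict[int, tuple[float, float]] = field(default_factory=dict)
    # k -> (gev, cv)


# ---------------------------------------------------------------------------
# Map-space primitives
# ---------------------------------------------------------------------------

def _center(maps: np.ndarray) -> np.ndarray:
    """Remove each map's spatial mean (last axis)."""
    return maps - maps.mean(axis=-1, keepdims=True)


def _center_norm(v: np.ndarray) -> np.ndarray:
    vc = _center(v)
    n = np.linalg.norm(vc)
    if n == 0:
        raise ClusteringError("zero-variance map")
    return vc / n


def spatial_correlation(u: np.ndarray, v: np.ndarray,
                        polarity_invariant: bool = True) -> float:
    """Pearson correlation between two maps after removing spatial means.

    With ``polarity_invariant`` the absolute value is returned, so a map and
    its negation correlate perfectly.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size or u.size < 2:
        raise ClusteringError("maps must share the same channel count >= 2")
    r = float(_center_norm(u) @ _center_norm(v))
    r = max(-1.0, min(1.0, r))
    return abs(r) if polarity_invariant else r


def gmd(u: np.ndarray, v: np.ndarray, polarity_invariant: bool = True) -> float:
    """Global map dissimilarity between two maps.

    RMS difference of the GFP-normalized, zero-mean maps; 0 for identical
    shapes, with the polarity chosen to minimize the dissimilarity when
    ``polarity_invariant``. Related to spatial correlation r by
    GMD = sqrt(2 * (1 - r)) on the unit-GFP scale.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    c = u.size
    uc, vc = _center(u), _center(v)
    ugfp = np.sqrt(np.mean(uc**2))
    vgfp = np.sqrt(np.mean(vc**2))
    if ugfp == 0 or vgfp == 0:
        raise ClusteringError("zero-variance map in GMD")
    uh, vh = uc / ugfp, vc / vgfp
    d_plus = np.sqrt(np.mean((uh - vh) ** 2))
    if not polarity_invariant:
        return float(d_plus)
    d_minus = np.sqrt(np.mean((uh + vh) ** 2))
    return float(min(d_plus, d_minus))


# ---------------------------------------------------------------------------
# Fit metrics
# ---------------------------------------------------------------------------

def compute_gev(obs: TopographySet, templates: TemplateSet,
                assignment: np.ndarray) -> float:
    """Global explained variance of an assignment.

    GEV = sum_t (GFP_t * r_t)^2 / sum_t GFP_t^2 with GFP_t the observation's
    spatial SD and r_t its polarity-invariant spatial correlation with the
    assigned template. Equals sum (x_c . T_a)^2 / sum ||x_c||^2 on centered
    maps with unit-norm templates.
    """
    assignment = np.asarray(assignment, dtype=int)
    if assignment.size != obs.n_obs:
        raise ClusteringError("assignment length mismatch")
    x = _center(obs.maps)
    norms2 = np.einsum("ij,ij->i", x, x)
    total = norms2.sum()
    if total == 0:
        raise ClusteringError("all-zero observations")
    proj = np.einsum("ij,ij->i", x, templates.templates[assignment])
    return float(np.sum(proj**2) / total)


def cv_criterion(obs: TopographySet, templates: TemplateSet,
                 assignment: np.ndarray) -> float:
    """Cross-validation criterion with the small-sample correction.

    CV = sigma^2 * ((C-1)/(C-1-k))^2 where sigma^2 is the mean residual
    variance per spatial degree of freedom after projecting each map on its
    assigned template. Lower is better; 0 for a noise-free fit. Requires
    C > k + 1.
    """
    k = templates.k
    c = obs.n_channels
    if c <= k + 1:
        raise ClusteringError(f"CV undefined: {c} channels for k={k}")
    assignment = np.asarray(assignment, dtype=int)
    x = _center(obs.maps)
    norms2 = np.einsum("ij,ij->i", x, x)
    proj = np.einsum("ij,ij->i", x, templates.templates[assignment])
    sigma2 = np.sum(norms2 - proj**2) / (obs.n_obs * (c - 1))
    return float(sigma2 * ((c - 1) / (c - 1 - k)) ** 2)


# ---------------------------------------------------------------------------
# Modified k-means
# ---------------------------------------------------------------------------

def _dominant_map(x_assigned: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of the scatter matrix of the assigned maps,
    re-centered to zero spatial mean and unit norm."""
    scatter = x_assigned.T @ x_assigned
    eigvals, eigvecs = np.linalg.eigh(scatter)
    t = eigvecs[:, -1]
    t = t - t.mean()
    n = np.linalg.norm(t)
    if n == 0:
        raise ClusteringError("degenerate template update (constant maps)")
    return t / n


def modified_kmeans(obs: TopographySet, k: int, n_restarts: int = 50,
                    max_iter: int = 1000, tol: float = 1e-6,
                    seed: int | np.random.Generator | None = 0,
                    ) -> tuple[TemplateSet, np.ndarray, ClusterDiagnostics]:
    """Cluster topographies into k polarity-invariant classes.

    Each restart initializes the templates as k distinct observed maps chosen
    uniformly at random, then alternates polarity-invariant assignment with
    dominant-eigenvector template updates until the assignment stabilizes,
    the relative GEV change drops below ``tol``, or ``max_iter`` is reached.
    The restart with the highest GEV wins. Empty clusters are re-seeded with
    the observation worst fit by the current templates.

    Returns the fitted :class:`TemplateSet` (labels "0".."k-1", to be renamed
    by :func:`align_labels`), the per-observation class assignment, and
    per-restart diagnostics.
    """
    if k < 2:
        raise ClusteringError("k must be >= 2")
    if obs.n_obs < k:
        raise ClusteringError(f"{obs.n_obs} observations < k={k}")
    x = _center(obs.maps)
    norms2 = np.einsum("ij,ij->i", x, x)
    if np.all(norms2 == 0):
        raise ClusteringError("all observations spatially constant")
    total = norms2.sum()
    # degenerate: all maps identical in shape but k > 1
    shapes = x[norms2 > 0] / np.sqrt(norms2[norms2 > 0])[:, None]
    if np.all(np.abs(np.abs(shapes @ shapes[0]) - 1.0) < 1e-12) and k > 1:
        raise ClusteringError("all observations share one topography; k > 1 "
                              "is degenerate")

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    diag = ClusterDiagnostics()
    best_gev = -np.inf
    best_templates: np.ndarray | None = None
    best_assign: np.ndarray | None = None

    for restart in range(n_restarts):
        init_idx = rng.choice(obs.n_obs, size=k, replace=False)
        templates = np.empty((k, obs.n_channels))
        for j, i in enumerate(init_idx):
            xi = x[i]
            n = np.linalg.norm(xi)
            if n == 0:  # replace a flat init map by the strongest observation
                xi = x[np.argmax(norms2)]
                n = np.linalg.norm(xi)
            templates[j] = xi / n

        assign = np.full(obs.n_obs, -1, dtype=int)
        prev_gev = -np.inf
        iterations = max_iter
        for it in range(1, max_iter + 1):
            proj = x @ templates.T                       # (N, k)
            fit = proj**2
            new_assign = np.argmax(fit, axis=1)          # ties -> lowest index
            # re-seed empty clusters with the worst-fit observation
            for j in range(k):
                if not np.any(new_assign == j):
                    best_fit = fit[np.arange(obs.n_obs), new_assign]
                    worst = int(np.argmin(best_fit / np.where(norms2 > 0,
                                                              norms2, 1.0)))
                    new_assign[worst] = j
                    xw = x[worst]
                    n = np.linalg.norm(xw)
                    if n > 0:
                        templates[j] = xw / n
            for j in range(k):
                members = x[new_assign == j]
                templates[j] = _dominant_map(members)
            proj = np.einsum("ij,ij->i", x, templates[new_assign])
            gev = float(np.sum(proj**2) / total)
            converged = np.array_equal(new_assign, assign)
            assign = new_assign
            if converged or (prev_gev > -np.inf
                             and abs(gev - prev_gev) < tol * max(prev_gev, 1e-300)):
                iterations = it
                break
            prev_gev = gev
        diag.restart_gev.append(gev)
        diag.restart_iterations.append(iterations)
        if gev > best_gev:
            best_gev = gev
            best_templates = templates.copy()
            best_assign = assign.copy()
            diag.chosen_restart = restart

    ts = TemplateSet(templates=best_templates, channels=list(obs.channels),
                     labels=[str(j) for j in range(k)], gev=best_gev)
    ts.cv = (cv_criterion(obs, ts, best_assign)
             if obs.n_channels > k + 1 else None)
    return ts, best_assign, diag


def select_k(obs: TopographySet, k_range=(4, 5, 6, 7), n_restarts: int = 50,
             max_iter: int = 1000, tol: float = 1e-6,
             seed: int | np.random.Generator | None = 0,
             ) -> tuple[int, ClusterDiagnostics]:
    """Scan candidate class counts and pick the CV-criterion argmin.

    Ties within a relative tolerance of the minimum CV (measured on the
    per-degree-of-freedom power scale, so noise-free data with CV ~ 0 at
    every k resolves deterministically) go to the smallest k. Full GEV/CV
    tables are returned so a caller may override the choice.
    """
    k_range = tuple(int(k) for k in k_range)
    if not k_range:
        raise ClusteringError("empty k_range")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    diag = ClusterDiagnostics()
    cvs = []
    for k in k_range:
        ts, assign, _ = modified_kmeans(obs, k, n_restarts=n_restarts,
                                        max_iter=max_iter, tol=tol, seed=rng)
        cv = cv_criterion(obs, ts, assign)
        diag.k_table[k] = (ts.gev, cv)
        cvs.append(cv)
    cvs = np.asarray(cvs)
    x = _center(obs.maps)
    power_scale = float(np.einsum("ij,ij->i", x, x).sum()
                        / (obs.n_obs * (obs.n_channels - 1)))
    thresh = cvs.min() + 1e-9 * max(power_scale, cvs.min())
    k_opt = int(min(k for k, cv in zip(k_range, cvs) if cv <= thresh))
    return k_opt, diag


# ---------------------------------------------------------------------------
# Canonical-class alignment
# ---------------------------------------------------------------------------

def align_labels(ts: TemplateSet, canonical: TemplateSet) -> TemplateSet:
    """Relabel templates to the canonical classes (A, B, C, D, ...).

    Finds the one-to-one matching that maximizes the total absolute spatial
    correlation with the canonical maps (optimal assignment), reorders the
    template rows into canonical order, and flips signs so each row
    correlates positively with its canonical map (cosmetic; all downstream
    operations are polarity-invariant).
    """
    if ts.k != canonical.k:
        raise ClusteringError(f"k mismatch: {ts.k} vs {canonical.k}")
    if list(ts.channels) != list(canonical.channels):
        raise ClusteringError("channel label mismatch")
    corr = np.array([[spatial_correlation(c_map, t_map, polarity_invariant=False)
                      for t_map in ts.templates]
                     for c_map in canonical.templates])
    rows, cols = linear_sum_assignment(-np.abs(corr))
    order = cols[np.argsort(rows)]
    aligned = ts.templates[order].copy()
    for i in range(ts.k):
        if corr[i, order[i]] < 0:
            aligned[i] = -aligned[i]
    return TemplateSet(templates=aligned, channels=list(ts.channels),
                       labels=list(canonical.labels), gev=ts.gev, cv=ts.cv)


def brute_force_alignment(ts: TemplateSet, canonical: TemplateSet) -> list[int]:
    """Exhaustive permutation search for the alignment (test oracle)."""
    k = ts.k
    best, best_perm = -np.inf, None
    for perm in itertools.permutations(range(k)):
        score = sum(spatial_correlation(canonical.templates[i],
                                        ts.templates[perm[i]])
                    for i in range(k))
        if score > best:
            best, best_perm = score, perm
    return list(best_perm)
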