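"""Population-structure inference.

Three complementary views of structure in a SNP dosage matrix:

* PCA with Patterson scaling (centre by 2p, scale by sqrt(2p(1-p)));
* DAPC: k-means on retained principal components with the number of
  clusters chosen by BIC, followed by linear discriminant axes;
* sNMF-style admixture: least-squares factorisation of the dosage/2
  matrix into ancestry proportions Q (rows on the simplex) and
  ancestral allele frequencies F (entries in [0,1]), with the number
  of ancestral populations K chosen by a masked-entry cross-entropy
  criterion.

The admixture solver is an alternating projected-gradient scheme with
exact Lipschitz step sizes, so the least-squares objective on observed
entries is non-increasing across sweeps; missing entries are excluded
from the objective by an EM-style fill with the current prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ovitherm.io import GenotypeMatrix


class ValidationError(ValueError):
    pass


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

def _imputed_scaled(geno: GenotypeMatrix) -> np.ndarray:
    """Mean-imputed dosages, centred by 2p and scaled by sqrt(2p(1-p))."""
    g = geno.calls_float()
    p = np.nanmean(g, axis=0) / 2.0
    g = np.where(np.isnan(g), 2.0 * p, g)
    scale = np.sqrt(2.0 * p * (1.0 - p))
    keep = scale > 0
    return (g[:, keep] - 2.0 * p[keep]) / scale[keep]


def pca_genotypes(geno: GenotypeMatrix, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the scaled dosage matrix.

    Returns per-sample scores (n x n_components) and the percentage of
    total variance carried by each axis.
    """
    x = _imputed_scaled(geno)
    if x.shape[1] == 0:
        raise ValidationError("all markers monomorphic; nothing to decompose")
    if n_components >= min(x.shape):
        raise ValidationError("n_components must be < min(n_samples, n_markers)")
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    ev = s ** 2
    total = ev.sum()
    if total == 0:
        raise ValidationError("zero-variance matrix")
    scores = u[:, :n_components] * s[:n_components]
    pct = 100.0 * ev[:n_components] / total
    return scores, pct


# ----------------------------------------------------------------------
# k-means + BIC (cluster identification step of DAPC)
# ----------------------------------------------------------------------

@dataclass
class ClusterScan:
    bic_by_k: dict[int, float]
    assignments_by_k: dict[int, np.ndarray]
    chosen_k: int


def _elbow_k(bic: dict[int, float]) -> int:
    """K at maximum curvature (second difference) of the BIC curve."""
    ks = sorted(bic)
    if len(ks) < 3:
        return min(bic, key=bic.get)
    curv = {ks[i]: (bic[ks[i - 1]] - bic[ks[i]]) - (bic[ks[i]] - bic[ks[i + 1]])
            for i in range(1, len(ks) - 1)}
    return max(curv, key=curv.get)


def find_clusters_bic(pc_scores: np.ndarray, k_max: int, seed: int = 0,
                      n_restarts: int = 10, selection: str = "auto") -> ClusterScan:
    """k-means over K = 1..k_max on PC scores, scored by BIC.

    ``BIC(K) = n * ln(WSS_K / n) + K * ln(n)``.  With ``selection
    ="argmin"`` the chosen K minimises BIC; with ``"elbow"`` it sits at
    the point of maximum curvature of the BIC curve.  The default
    ``"auto"`` uses the argmin when the curve has an interior minimum
    and falls back to the elbow when BIC is still decreasing at k_max
    (on tight Gaussian-like clusters this BIC keeps decreasing past
    the true K, exactly the situation where practitioners read the
    elbow of the curve).  Deterministic given (data, seed).
    """
    x = np.asarray(pc_scores, dtype=float)
    n = x.shape[0]
    if k_max >= n:
        raise ValidationError("k_max must be < n_samples")
    if selection not in {"auto", "argmin", "elbow"}:
        raise ValidationError(f"unknown selection rule {selection!r}")
    bic, assign = {}, {}
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(x)
        wss = float(km.inertia_)
        bic[k] = n * np.log(max(wss, 1e-300) / n) + k * np.log(n)
        assign[k] = labels
    argmin = min(bic, key=bic.get)
    if selection == "argmin":
        chosen = argmin
    elif selection == "elbow":
        chosen = _elbow_k(bic)
    else:
        chosen = argmin if argmin != k_max else _elbow_k(bic)
    return ClusterScan(bic, assign, chosen)


# ----------------------------------------------------------------------
# DAPC
# ----------------------------------------------------------------------

@dataclass
class DapcResult:
    bic_by_k: dict[int, float] | None
    chosen_k: int
    assignments: np.ndarray
    discriminant_coords: np.ndarray
    pct_variance_by_axis: np.ndarray
    model: LinearDiscriminantAnalysis


def _n_pcs_for_variance(pct: np.ndarray, target: float = 90.0) -> int:
    cum = np.cumsum(pct)
    return int(np.searchsorted(cum, target) + 1)


def dapc(geno: GenotypeMatrix, groups: list | None = None,
         n_pcs: int | None = None, k_max: int = 10, seed: int = 0) -> DapcResult:
    """Discriminant analysis of principal components.

    When ``groups`` is None the clusters come from k-means with BIC
    selection (no prior population information).  ``n_pcs`` defaults to
    the number of axes explaining 90% of variance, capped so that the
    within-group scatter stays estimable.
    """
    max_axes = min(geno.n_samples, geno.n_markers) - 1
    scores, pct = pca_genotypes(geno, max_axes)
    if n_pcs is None:
        n_pcs = _n_pcs_for_variance(pct)
    bic_by_k = None
    if groups is None:
        scan = find_clusters_bic(scores[:, :n_pcs], min(k_max, geno.n_samples - 1),
                                 seed=seed)
        labels = scan.assignments_by_k[scan.chosen_k]
        bic_by_k = scan.bic_by_k
        chosen_k = scan.chosen_k
    else:
        labels = np.asarray(groups, dtype=object)
        chosen_k = len(set(labels))
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("DAPC needs >= 2 groups")
    if (counts < 2).any():
        raise ValidationError("every group needs >= 2 members")
    n_pcs = min(n_pcs, geno.n_samples - len(uniq))
    x = scores[:, :n_pcs]
    lda = LinearDiscriminantAnalysis(solver="eigen")
    try:
        lda.fit(x, labels.astype(str))
    except np.linalg.LinAlgError:
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=1e-6)
        lda.fit(x, labels.astype(str))
    coords = lda.transform(x)
    evr = lda.explained_variance_ratio_[: coords.shape[1]]
    pct_axes = 100.0 * evr / evr.sum()
    return DapcResult(bic_by_k, chosen_k, labels, coords, pct_axes, lda)


# ----------------------------------------------------------------------
# Least-squares admixture
# ----------------------------------------------------------------------

@dataclass
class StructureResult:
    k: int
    q: np.ndarray
    f: np.ndarray
    cross_entropy: float
    iterations_run: int
    seed: int
    objective_path: np.ndarray


def _project_rows_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = v.shape
    u = np.sort(v, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    idx = np.arange(1, k + 1)
    cond = u - css / idx > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.clip(v - theta[:, None], 0.0, None)


def _init_qf(m: np.ndarray, obs: np.ndarray, k: int,
             rng: np.random.Generator, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Warm start: k-means clusters on the leading singular vectors.

    Q starts near the cluster indicator (softened so no entry is on the
    simplex boundary); F starts at the per-cluster observed frequency.
    Falls back to a Dirichlet draw for degenerate inputs.
    """
    n, mm = m.shape
    counts = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        base = np.where(counts > 0, m.sum(axis=0) / counts, 0.5)
    filled = np.where(obs, m, base[None, :])
    centred = filled - filled.mean(axis=0)
    try:
        u, s, _ = np.linalg.svd(centred, full_matrices=False)
        top = u[:, :max(k - 1, 1)] * s[:max(k - 1, 1)]
        labels = KMeans(n_clusters=k, n_init=5,
                        random_state=seed % (2**32)).fit_predict(top)
        q = np.full((n, k), 0.1 / max(k - 1, 1))
        q[np.arange(n), labels] = 0.9
        f = np.empty((k, mm))
        for c in range(k):
            members = labels == c
            if members.any():
                cnt = obs[members].sum(axis=0).astype(float)
                with np.errstate(invalid="ignore", divide="ignore"):
                    f[c] = np.where(cnt > 0, m[members].sum(axis=0) / cnt, base)
            else:
                f[c] = base
    except np.linalg.LinAlgError:
        q = rng.dirichlet(np.ones(k), size=n)
        f = np.clip(base[None, :] + rng.normal(0.0, 0.05, (k, mm)), 0.0, 1.0)
    return q, np.clip(f, 0.0, 1.0)


def _observed_objective(m: np.ndarray, obs: np.ndarray, q: np.ndarray,
                        f: np.ndarray) -> float:
    resid = np.where(obs, m - q @ f, 0.0)
    return float((resid ** 2).sum())


def admixture_lsq(geno: GenotypeMatrix, k: int, seed: int = 0,
                  max_iter: int = 500, tol: float = 1e-7,
                  _mask: np.ndarray | None = None) -> StructureResult:
    """Least-squares admixture estimate for K ancestral populations.

    Minimises ``sum over observed entries of (dosage/2 - (Q F))^2``
    subject to Q rows on the simplex and F in [0,1], by alternating
    projected-gradient sweeps with exact Lipschitz steps.  The objective
    is non-increasing across sweeps.  ``_mask`` marks entries to exclude
    from the fit in addition to missing data (used by the cross-entropy
    criterion).
    """
    if k < 1:
        raise ValidationError("K must be >= 1")
    if k > geno.n_samples:
        raise ValidationError("K must be <= n_samples")
    g = geno.calls_float()
    obs = ~np.isnan(g)
    if _mask is not None:
        obs = obs & ~_mask
    m = np.where(obs, g / 2.0, 0.0)
    n, mm = m.shape

    if k == 1:
        counts = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(counts > 0, m.sum(axis=0) / counts, 0.5)
        q = np.ones((n, 1))
        objv = _observed_objective(m, obs, q, f[None, :])
        return StructureResult(1, q, f[None, :], np.nan, 0, seed,
                               np.array([objv]))

    rng = np.random.default_rng(seed)
    q, f = _init_qf(m, obs, k, rng, seed)

    path = [_observed_objective(m, obs, q, f)]
    it = 0
    for it in range(1, max_iter + 1):
        # EM fill: surrogate objective with current predictions at
        # unobserved entries majorises the observed-entry objective
        pred = q @ f
        m_fill = np.where(obs, m, pred)
        # Q sweep: projected gradient with step 1/L, L = 2*lmax(F F^T);
        # the data term M F^T is constant within the sweep, so inner
        # iterations cost only O(n K^2)
        ff = f @ f.T
        g0 = m_fill @ f.T
        l_q = 2.0 * max(np.linalg.eigvalsh(ff)[-1], 1e-12)
        for _ in range(25):
            q = _project_rows_to_simplex(q - 2.0 * (q @ ff - g0) / l_q)
        # F sweep: projected gradient with step 1/L, L = 2*lmax(Q^T Q)
        qq = q.T @ q
        h0 = q.T @ m_fill
        l_f = 2.0 * max(np.linalg.eigvalsh(qq)[-1], 1e-12)
        for _ in range(25):
            f = np.clip(f - 2.0 * (qq @ f - h0) / l_f, 0.0, 1.0)
        objv = _observed_objective(m, obs, q, f)
        path.append(objv)
        prev = path[-2]
        if prev > 0 and (prev - objv) / prev < tol:
            break
    return StructureResult(k, q, f, np.nan, it, seed, np.asarray(path))


def predicted_frequencies(result: StructureResult, eps: float = 1e-6) -> np.ndarray:
    """Model Alt-allele frequencies Q F, clipped away from {0,1}."""
    return np.clip(result.q @ result.f, eps, 1.0 - eps)


def genotype_cross_entropy(g: np.ndarray, pi: np.ndarray, where: np.ndarray) -> float:
    """Mean binomial cross-entropy of dosages against model frequencies."""
    if not where.any():
        raise ValidationError("empty evaluation mask")
    h = g / 2.0
    ll = h * np.log(pi) + (1.0 - h) * np.log(1.0 - pi)
    return float(-ll[where].mean())


@dataclass
class CrossEntropyScan:
    ce_by_k: dict[int, float]
    best_k: int
    results: dict[int, StructureResult]


def cross_entropy_select(geno: GenotypeMatrix, k_range=range(1, 11),
                         mask_fraction: float = 0.05, seed: int = 0,
                         max_iter: int = 500, tol: float = 1e-7) -> CrossEntropyScan:
    """Choose K by cross-entropy on a held-out mask of observed entries.

    A seeded random ``mask_fraction`` of the observed genotypes is
    hidden from the fit; the criterion is the binomial cross-entropy of
    the hidden dosages against the fitted Q F frequencies.  Lower is
    better; ``best_k`` is the argmin.
    """
    if not 0.0 < mask_fraction < 0.5:
        raise ValidationError("mask_fraction must be in (0, 0.5)")
    g = geno.calls_float()
    obs = ~np.isnan(g)
    rng = np.random.default_rng(seed)
    mask = obs & (rng.random(g.shape) < mask_fraction)
    if not mask.any():
        raise ValidationError("held-out mask is empty")
    ce, results = {}, {}
    for k in k_range:
        res = admixture_lsq(geno, k, seed=seed + k, max_iter=max_iter,
                            tol=tol, _mask=mask)
        pi = predicted_frequencies(res)
        value = genotype_cross_entropy(np.where(obs, g, 0.0), pi, mask)
        results[k] = StructureResult(res.k, res.q, res.f, value,
                                     res.iterations_run, res.seed,
                                     res.objective_path)
        ce[k] = value
    best = min(ce, key=ce.get)
    return CrossEntropyScan(ce, best, results)


def match_ancestry_columns(q_est: np.ndarray, q_true: np.ndarray) -> np.ndarray:
    """Permute estimated ancestry columns to best match a reference Q.

    Uses Hungarian assignment on column-wise absolute-error cost;
    ancestral components are only identified up to relabeling.
    """
    k = q_true.shape[1]
    cost = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            cost[i, j] = np.abs(q_est[:, i] - q_true[:, j]).mean()
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(k, dtype=int)
    perm[cols] = rows
    return q_est[:, perm]
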