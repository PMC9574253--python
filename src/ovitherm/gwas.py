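"""Mixed-model genome-wide association for the heat-tolerance score.

The model is ``y = G a + X b + Z u + e`` with a vanRaden genomic
relationship matrix behind the polygenic term: Var(u) = sg2 * K,
Var(e) = se2 * I.  Variance components are estimated once on the
marker-free null model by EMMA-style spectral REML and then held fixed
for every marker test (the P3D / EMMAX approximation); an exact
per-marker REML is available behind a flag.  Marker effects are in
phenotype units per Alt allele.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from ovitherm.io import UNPLACED, GenotypeMatrix


class ValidationError(ValueError):
    pass


# ----------------------------------------------------------------------
# Kinship
# ----------------------------------------------------------------------

def vanraden_kinship(geno: GenotypeMatrix) -> np.ndarray:
    """vanRaden genomic relationship matrix.

    ``K = W W' / (2 * sum_j p_j (1 - p_j))`` with W the dosage matrix
    centred by twice the Alt frequency; missing dosages are mean-imputed
    per marker.  On Hardy-Weinberg data the mean diagonal is near 1.
    """
    g = geno.calls_float()
    p = np.nanmean(g, axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom == 0.0:
        raise ValidationError("all markers monomorphic; kinship undefined")
    w = np.where(np.isnan(g), 0.0, g - 2.0 * p)
    k = (w @ w.T) / denom
    return (k + k.T) / 2.0


# ----------------------------------------------------------------------
# EMMA-style REML on the null model
# ----------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    delta: float            # se2 / sg2
    reml_loglik: float
    profile: pd.DataFrame   # grid of (delta, restricted log-likelihood)

    @property
    def heritability(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


def _reml_loglik(log_delta: float, lam: np.ndarray, eta2: np.ndarray) -> float:
    delta = np.exp(log_delta)
    denom = lam + delta
    nq = lam.size
    return 0.5 * (nq * (np.log(nq / (2 * np.pi)) - 1.0
                        - np.log(np.sum(eta2 / denom)))
                  - np.sum(np.log(denom)))


def reml_null(y: np.ndarray, x: np.ndarray, kinship: np.ndarray,
              n_grid: int = 100) -> VarianceComponents:
    """REML variance components of the marker-free mixed model.

    Uses the spectral trick: eigendecompose the kinship projected off
    the fixed-effect space, profile the restricted likelihood over
    ``delta = se2/sg2`` on a log grid (1e-5..1e5) and refine the best
    grid point by bounded scalar optimisation.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != y.size:
        x = x.T
    n = y.size
    q = np.linalg.matrix_rank(x)
    if n < q + 2:
        raise ValidationError("too few samples for REML")
    # projection off the fixed effects; +I stabilises the eigenproblem
    xtx_inv = np.linalg.pinv(x.T @ x)
    s = np.eye(n) - x @ xtx_inv @ x.T
    skso = s @ (kinship + np.eye(n)) @ s
    vals, vecs = np.linalg.eigh((skso + skso.T) / 2.0)
    lam = vals[q:] - 1.0                 # n-q informative eigenvalues of SKS
    lam = np.clip(lam, 0.0, None)
    u = vecs[:, q:]
    eta2 = (u.T @ y) ** 2

    grid = np.linspace(np.log(1e-5), np.log(1e5), n_grid)
    ll = np.array([_reml_loglik(g, lam, eta2) for g in grid])
    if not np.isfinite(ll).all():
        raise FloatingPointError("non-finite restricted likelihood on grid")
    best = int(np.argmax(ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, n_grid - 1)]
    res = minimize_scalar(lambda g: -_reml_loglik(g, lam, eta2),
                          bounds=(lo, hi), method="bounded")
    log_delta = float(res.x)
    if -res.fun < ll[best]:
        log_delta = float(grid[best])
    delta = float(np.exp(log_delta))
    sg2 = float(np.sum(eta2 / (lam + delta)) / lam.size)
    se2 = delta * sg2
    profile = pd.DataFrame({"delta": np.exp(grid), "reml_loglik": ll})
    return VarianceComponents(sg2, se2, delta,
                              _reml_loglik(log_delta, lam, eta2), profile)


# ----------------------------------------------------------------------
# P3D marker scan
# ----------------------------------------------------------------------

@dataclass
class GwasRecord:
    marker_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    effect: float
    se: float
    pvalue: float
    lod: float
    qvalue: float = np.nan
    status: str = "NS"
    gene: str = "-"
    monomorphic: bool = False


def _rotate(kinship: np.ndarray, sg2: float, se2: float):
    vals, vecs = np.linalg.eigh((kinship + kinship.T) / 2.0)
    w = sg2 * np.clip(vals, 0.0, None) + se2
    return vecs, 1.0 / np.sqrt(w)


def marker_scan(geno: GenotypeMatrix, y: np.ndarray, x: np.ndarray | None,
                kinship: np.ndarray, vc: VarianceComponents,
                exact_reml: bool = False) -> list[GwasRecord]:
    """Per-marker generalized least squares with fixed variance components.

    Missing dosages are mean-imputed per marker.  Each marker is tested
    by a two-sided t test on its GLS coefficient with
    ``n - rank(X) - 1`` degrees of freedom; p-values for monomorphic
    markers are 1 with a flag.  With ``exact_reml`` the variance
    components are re-estimated under each marker's fixed-effect design
    (slow; P3D is the default).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n != geno.n_samples:
        raise ValidationError("phenotype length must match sample count")
    if x is None:
        x = np.ones((n, 1))
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != n:
        x = x.T
    qrank = np.linalg.matrix_rank(x)

    g = geno.calls_float()
    p_hat = np.nanmean(g, axis=0) / 2.0
    g = np.where(np.isnan(g), 2.0 * p_hat, g)
    mono = np.nanstd(g, axis=0) == 0.0

    records: list[GwasRecord] = []
    df = n - qrank - 1
    if df <= 0:
        raise ValidationError("not enough residual degrees of freedom")

    def scan_with(vc_local: VarianceComponents, cols: np.ndarray):
        vecs, wsqrt = _rotate(kinship, vc_local.sigma_g2, vc_local.sigma_e2)
        yt = wsqrt * (vecs.T @ y)
        xt = wsqrt[:, None] * (vecs.T @ x)
        gt = wsqrt[:, None] * (vecs.T @ cols)
        # residualise on covariates
        qx, _ = np.linalg.qr(xt)
        ry = yt - qx @ (qx.T @ yt)
        rg = gt - qx @ (qx.T @ gt)
        gss = (rg ** 2).sum(axis=0)
        gy = rg.T @ ry
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = gy / gss
            rss = (ry ** 2).sum() - beta * gy
            sigma2 = rss / df
            se = np.sqrt(sigma2 / gss)
            tstat = beta / se
        pval = 2.0 * stats.t.sf(np.abs(tstat), df)
        return beta, se, pval

    if exact_reml:
        beta = np.zeros(geno.n_markers)
        se = np.zeros(geno.n_markers)
        pval = np.ones(geno.n_markers)
        for j in range(geno.n_markers):
            if mono[j]:
                continue
            vc_j = reml_null(y, np.column_stack([x, g[:, j]]), kinship)
            b, s, p = scan_with(vc_j, g[:, [j]])
            beta[j], se[j], pval[j] = b[0], s[0], p[0]
    else:
        beta, se, pval = scan_with(vc, g)

    beta = np.where(mono, 0.0, beta)
    se = np.where(mono, np.nan, se)
    pval = np.where(mono, 1.0, np.clip(pval, np.finfo(float).tiny, 1.0))
    for j in range(geno.n_markers):
        records.append(GwasRecord(
            marker_id=geno.marker_ids[j],
            chrom=str(geno.chrom[j]),
            pos=int(geno.pos[j]),
            ref=str(geno.ref[j]),
            alt=str(geno.alt[j]),
            effect=float(beta[j]),
            se=float(se[j]),
            pvalue=float(pval[j]),
            lod=float(-np.log10(pval[j])),
            monomorphic=bool(mono[j]),
        ))
    return records


# ----------------------------------------------------------------------
# Significance status with LD linkage
# ----------------------------------------------------------------------

def _composite_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        return 0.0
    av, bv = a[ok], b[ok]
    if av.std() == 0 or bv.std() == 0:
        return 0.0
    return float(np.corrcoef(av, bv)[0, 1] ** 2)


def significance_status(records: list[GwasRecord], geno: GenotypeMatrix,
                        p_threshold: float = 1e-3, ld_r2: float = 0.8,
                        ld_window_bp: int = 1_000_000) -> list[GwasRecord]:
    """Assign Sig / SigLD / NS status and BH q-values.

    ``Sig``: raw p <= p_threshold.  ``SigLD``: p <= 2 * p_threshold and
    composite-dosage r^2 >= ld_r2 with a Sig marker on the same
    chromosome within the window.  Unplaced markers never enter LD
    pairs.  BH q-values are computed across all tested markers.
    """
    if not records:
        return []
    for thr, name in ((p_threshold, "p_threshold"), (ld_r2, "ld_r2")):
        if not 0.0 < thr < 1.0:
            raise ValidationError(f"{name} must be in (0, 1)")
    pvals = np.array([r.pvalue for r in records])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    col = {mid: j for j, mid in enumerate(geno.marker_ids)}
    g = geno.calls_float()

    out = [replace(r, qvalue=float(qv)) for r, qv in zip(records, qvals)]
    sig = [r for r in out if r.pvalue <= p_threshold]
    for j, r in enumerate(out):
        if r.pvalue <= p_threshold:
            out[j] = replace(r, status="Sig")
    placed_sig = [r for r in sig if r.pos != UNPLACED and r.marker_id in col]
    for j, r in enumerate(out):
        if out[j].status == "Sig" or r.pos == UNPLACED:
            continue
        if r.pvalue > 2.0 * p_threshold or r.marker_id not in col:
            continue
        for s in placed_sig:
            if s.chrom != r.chrom or abs(s.pos - r.pos) > ld_window_bp:
                continue
            if _composite_r2(g[:, col[r.marker_id]], g[:, col[s.marker_id]]) >= ld_r2:
                out[j] = replace(r, status="SigLD")
                break
    return out


# ----------------------------------------------------------------------
# Plot-ready tables
# ----------------------------------------------------------------------

def manhattan_qq_data(records: list[GwasRecord]) -> dict[str, object]:
    """Manhattan and QQ tables plus the genomic inflation factor lambda.

    Manhattan: cumulative genome coordinate, lod and a chromosome
    colour index (unplaced markers appended after the last chromosome).
    QQ: expected vs observed -log10 p under the uniform null.  Lambda
    is the median chi-square ratio.
    """
    man_rows = []
    chroms: list[str] = []
    for r in records:
        c = r.chrom if r.pos != UNPLACED else "NA"
        if c not in chroms:
            chroms.append(c)
    offset = {}
    running = 0
    for c in chroms:
        offset[c] = running
        span = [r.pos for r in records if r.chrom == c and r.pos != UNPLACED]
        running += (max(span) if span else 1) + 1
    for r in records:
        c = r.chrom if r.pos != UNPLACED else "NA"
        pos = r.pos if r.pos != UNPLACED else 1
        man_rows.append({
            "marker_id": r.marker_id, "chrom": c,
            "cum_pos": offset[c] + pos, "lod": r.lod,
            "color_index": chroms.index(c) % 2,
        })
    manhattan = pd.DataFrame(man_rows)

    pvals = np.sort(np.array([r.pvalue for r in records]))
    m = pvals.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(pvals)
    qq = pd.DataFrame({"expected": expected, "observed": observed})
    chi2 = stats.chi2.isf(pvals, df=1)
    lam = float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
    return {"manhattan": manhattan, "qq": qq, "lambda": lam}
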