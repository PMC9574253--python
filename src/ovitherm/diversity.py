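"""Multilocus diversity and differentiation statistics.

Covers Nei's unbiased gene diversity (Hexp), the index of association
Ia and its standardised form rbarD (multilocus association; expectation
zero under random mating), Weir-Cockerham pairwise Fst (theta) and a
neighbour-joining tree over the resulting distance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from ovitherm.io import GenotypeMatrix


class ValidationError(ValueError):
    pass


# ----------------------------------------------------------------------
# Gene diversity
# ----------------------------------------------------------------------

def nei_gene_diversity(geno: GenotypeMatrix) -> float:
    """Mean unbiased expected heterozygosity over markers.

    Per marker, ``h = N/(N-1) * (1 - p^2 - q^2)`` with N the number of
    observed allele copies.  Markers with fewer than two observed
    copies are excluded.
    """
    if geno.n_markers == 0:
        raise ValidationError("empty marker set")
    g = geno.calls_float()
    n_obs = np.sum(~np.isnan(g), axis=0)
    copies = 2.0 * n_obs
    with np.errstate(invalid="ignore"):
        p = np.nansum(g, axis=0) / copies
    ok = copies >= 2
    if not ok.any():
        raise ValidationError("no marker with >= 2 observed allele copies")
    p, copies = p[ok], copies[ok]
    h = copies / (copies - 1.0) * (1.0 - p ** 2 - (1.0 - p) ** 2)
    return float(np.mean(h))


# ----------------------------------------------------------------------
# Index of association
# ----------------------------------------------------------------------

def _pair_distance_matrix(g: np.ndarray) -> np.ndarray:
    """Per-locus distances for all sample pairs: |dose_a - dose_b| / 2.

    Returns a (n_pairs, n_loci) array with NaN where either genotype is
    missing (pairwise-complete convention).
    """
    n = g.shape[0]
    iu = np.triu_indices(n, k=1)
    return np.abs(g[iu[0], :] - g[iu[1], :]) / 2.0


def index_of_association(geno: GenotypeMatrix) -> tuple[float, float]:
    """Index of association Ia and its standardised form rbarD.

    For every pair of individuals, the per-locus distance is
    ``|dosage_a - dosage_b| / 2`` and the multilocus distance D is the
    sum over loci.  ``Ia = V_O / V_E - 1`` where V_O is the observed
    variance of D over pairs and V_E the sum of per-locus variances;
    ``rbarD = (V_O - V_E) / (2 * sum_{j<k} sqrt(var_j var_k))``.
    Variances over pairs use the population (divide-by-N) convention
    throughout, which makes the duplicated-locus identity
    (Ia = rbarD = 1) exact.  Pairs missing a genotype at a locus are
    dropped from that locus only.
    """
    n, m = geno.n_samples, geno.n_markers
    if n < 2:
        raise ValidationError("need >= 2 samples")
    if m < 1:
        raise ValidationError("need >= 1 marker")
    g = geno.calls_float()
    n_pairs = n * (n - 1) // 2
    iu = np.triu_indices(n, k=1)
    # chunk over loci: V_O is the variance over pairs of the multilocus
    # distance D (sum of per-locus d), so only D row sums and per-locus
    # moments are needed -- never an m x m covariance matrix
    d_sum = np.zeros(n_pairs)
    var = np.zeros(m)
    chunk = max(1, int(2e7) // max(n_pairs, 1))
    for lo in range(0, m, chunk):
        gc = g[:, lo:lo + chunk]
        d = np.abs(gc[iu[0], :] - gc[iu[1], :]) / 2.0
        obs = ~np.isnan(d)
        counts = obs.sum(axis=0).astype(float)
        if (counts < 2).any():
            raise ValidationError("a locus has fewer than 2 complete pairs")
        d0 = np.where(obs, d, 0.0)
        means = d0.sum(axis=0) / counts
        var[lo:lo + chunk] = (d0 ** 2).sum(axis=0) / counts - means ** 2
        # dropped (missing) entries contribute the locus mean to D so
        # that pairs with missing genotypes stay on a comparable scale
        d_sum += np.where(obs, d, means[np.newaxis, :]).sum(axis=1)
    if np.all(var == 0):
        raise ValidationError(
            "all individuals identical at every locus; Ia undefined (V_E = 0)")
    v_e = float(var.sum())
    v_o = float(np.mean(d_sum ** 2) - np.mean(d_sum) ** 2)
    ia = v_o / v_e - 1.0
    if m < 2:
        warnings.warn("single marker: Ia fixed at 0, rbarD undefined")
        raise ValidationError("rbarD undefined for a single marker")
    sq = np.sqrt(np.clip(var, 0.0, None))
    denom = float(sq.sum() ** 2 - (sq ** 2).sum())  # 2 * sum_{j<k} sqrt(vj vk)
    if denom == 0.0:
        raise ValidationError("rbarD denominator is zero")
    rbar_d = (v_o - v_e) / denom
    return ia, rbar_d


# ----------------------------------------------------------------------
# Weir-Cockerham Fst
# ----------------------------------------------------------------------

def _wc_components(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components for two samples.

    Biallelic loci, r = 2 populations of unequal size, including the
    heterozygosity terms.  Returns (a, a+b+c) per locus; loci without
    at least two genotyped individuals in each group are NaN.
    """
    r = 2.0
    stats = []
    for g in (g1, g2):
        obs = ~np.isnan(g)
        n_i = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.nansum(g, axis=0) / (2.0 * n_i)
            h_i = np.nansum(g == 1, axis=0) / n_i
        stats.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = stats
    valid = (n1 >= 2) & (n2 >= 2)
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
                           / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    a = np.where(valid, a, np.nan)
    abc = np.where(valid, a + b + c, np.nan)
    return a, abc


def weir_cockerham_theta(g1: np.ndarray, g2: np.ndarray) -> float:
    """Multilocus theta between two dosage matrices (NaN = missing)."""
    a, abc = _wc_components(g1, g2)
    num = np.nansum(a)
    den = np.nansum(abc)
    if den == 0:
        return 0.0
    return float(num / den)


@dataclass
class FstMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        assert v.shape == (len(self.labels), len(self.labels))
        assert np.allclose(v, v.T)
        self.values = v


def weir_cockerham_fst(geno: GenotypeMatrix, grouping: list[str]) -> FstMatrix:
    """Pairwise multilocus Weir-Cockerham theta between groups.

    Groups with fewer than two samples are excluded with a warning.
    Small negative estimates are kept (property of the estimator).
    """
    if len(grouping) != geno.n_samples:
        raise ValidationError("grouping length must equal sample count")
    grouping = np.asarray(grouping, dtype=object)
    labels = [g for g in dict.fromkeys(grouping)]
    sizes = {lab: int((grouping == lab).sum()) for lab in labels}
    dropped = [lab for lab in labels if sizes[lab] < 2]
    if dropped:
        warnings.warn(f"groups with < 2 samples excluded: {dropped}")
        labels = [lab for lab in labels if sizes[lab] >= 2]
    if len(labels) < 2:
        raise ValidationError("need >= 2 groups with >= 2 samples")
    g = geno.calls_float()
    mats = {lab: g[grouping == lab] for lab in labels}
    k = len(labels)
    theta = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            t = weir_cockerham_theta(mats[labels[i]], mats[labels[j]])
            theta[i, j] = theta[j, i] = t
    return FstMatrix(labels, theta)


# ----------------------------------------------------------------------
# Neighbour joining
# ----------------------------------------------------------------------

def nj_tree(dist: FstMatrix) -> str:
    """Unrooted neighbour-joining Newick string from a distance matrix.

    Negative input entries are clamped to zero before agglomeration and
    negative branch lengths are clamped to zero in the result.
    """
    if len(dist.labels) < 3:
        raise ValidationError("neighbour joining needs >= 3 taxa")
    vals = np.clip(dist.values, 0.0, None)
    np.fill_diagonal(vals, 0.0)
    dm = DistanceMatrix(vals, ids=dist.labels)
    tree = _skbio_nj(dm, neg_as_zero=True)
    return str(tree).strip()


# ----------------------------------------------------------------------
# Table of diversity summaries
# ----------------------------------------------------------------------

@dataclass
class DiversitySummary:
    group: str
    n: int
    hexp: float
    ia: float
    rbar_d: float


def diversity_table(geno: GenotypeMatrix, grouping: str = "breed") -> list[DiversitySummary]:
    """Hexp / Ia / rbarD per group plus a Total row over all samples.

    ``grouping`` selects the ``breed`` or ``location`` sample metadata.
    """
    if grouping == "breed":
        labels = geno.breed
    elif grouping == "location":
        labels = geno.location
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")
    if labels is None:
        raise ValidationError(f"genotype matrix has no {grouping} metadata")
    labels = np.asarray(labels, dtype=object)
    out = []
    for lab in dict.fromkeys(labels):
        sub = geno.take_samples(np.flatnonzero(labels == lab))
        ia, rbar = index_of_association(sub)
        out.append(DiversitySummary(str(lab), sub.n_samples,
                                    nei_gene_diversity(sub), ia, rbar))
    ia, rbar = index_of_association(geno)
    out.append(DiversitySummary("Total", geno.n_samples,
                                nei_gene_diversity(geno), ia, rbar))
    return out
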