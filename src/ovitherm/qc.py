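"""SNP quality control: allele frequency, call rate and exact HWE filters.

Defaults mirror a single-pass chip QC: drop markers with minor allele
frequency < 0.01, genotyping call rate < 90%, or an exact
Hardy-Weinberg test p-value < 1e-6.  The exact (conditional) test is
used rather than a chi-square because the 1e-6 tail is exactly where
the chi-square approximation breaks down at cohort sizes of a few
hundred.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from ovitherm.io import MISSING, GenotypeMatrix


class ValidationError(ValueError):
    pass


def allele_stats(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker Alt frequency, MAF and call rate.

    Markers with no non-missing calls get call_rate 0 and maf 0 with
    ``degenerate=True`` rather than raising.
    """
    calls = geno.calls
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    alt_counts = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_obs > 0, alt_counts / (2.0 * n_obs), np.nan)
    maf = np.where(np.isnan(alt_freq), 0.0, np.minimum(alt_freq, 1.0 - alt_freq))
    call_rate = n_obs / geno.n_samples if geno.n_samples else n_obs * 0.0
    return pd.DataFrame({
        "marker_id": geno.marker_ids,
        "alt_freq": np.where(np.isnan(alt_freq), 0.0, alt_freq),
        "maf": maf,
        "call_rate": call_rate,
        "degenerate": n_obs == 0,
    })


@lru_cache(maxsize=200_000)
def _hwe_exact_cached(n_het: int, n_rare: int, n: int) -> float:
    """Exact two-sided HWE p given het count, rare-allele count, sample size.

    Conditional distribution of the heterozygote count given the allele
    counts; p is the summed probability of all heterozygote counts at
    most as probable as the observed one.  Probabilities are built by
    the standard stable recurrence from the modal het count.
    """
    if n == 0:
        return 1.0
    # possible het counts share parity with the rare allele count
    het_min = n_rare % 2
    n_common = 2 * n - n_rare
    hets = list(range(het_min, min(n_rare, 2 * n - n_rare) + 1, 2))
    if len(hets) <= 1:
        return 1.0
    # start from the mode to avoid under/overflow
    mode = int(round(n_rare * n_common / (2.0 * n - 1.0)))
    if (mode - het_min) % 2:
        mode += 1 if mode < hets[-1] else -1
    mode = min(max(mode, hets[0]), hets[-1])
    probs = {mode: 1.0}
    # going down: P(h-2)/P(h) = h*(h-1) / ((nr-h+2)*(nc-h+2))
    h = mode
    while h - 2 >= hets[0]:
        probs[h - 2] = probs[h] * h * (h - 1) / (
            (n_rare - h + 2.0) * (n_common - h + 2.0))
        h -= 2
    h = mode
    while h + 2 <= hets[-1]:
        probs[h + 2] = probs[h] * (n_rare - h) * (n_common - h) / (
            (h + 2.0) * (h + 1.0))
        h += 2
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def hwe_exact_test(n_aa_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Exact test of Hardy-Weinberg proportions for one biallelic marker.

    Parameters are the three genotype counts (either homozygote class
    may be passed first; the test is symmetric in allele labels).
    """
    for c in (n_aa_hom, n_het, n_alt_hom):
        if c < 0:
            raise ValidationError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_alt_hom
    if n < 1:
        raise ValidationError("need at least one genotype")
    n_alt = n_het + 2 * n_alt_hom
    n_rare = min(n_alt, 2 * n - n_alt)
    return _hwe_exact_cached(n_het, n_rare, n)


def hwe_pvalues(geno: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p-value per marker (1.0 for markers with no calls)."""
    calls = geno.calls
    out = np.ones(geno.n_markers)
    for j in range(geno.n_markers):
        col = calls[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        out[j] = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()),
                                int((col == 2).sum()))
    return out


@dataclass
class QcReport:
    n_input: int
    n_removed_maf: int
    n_removed_callrate: int
    n_removed_hwe: int
    n_retained: int
    table: pd.DataFrame  # marker_id, maf, call_rate, hwe_p, verdict

    def __post_init__(self) -> None:
        removed = self.n_removed_maf + self.n_removed_callrate + self.n_removed_hwe
        assert self.n_input == self.n_retained + removed


def filter_snps(geno: GenotypeMatrix, maf_min: float = 0.01,
                callrate_min: float = 0.90,
                hwe_alpha: float = 1e-6) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the MAF / call-rate / HWE filters to a genotype matrix.

    A marker is removed if it fails any criterion; in the report its
    removal is attributed to the first failing rule in the order
    MAF -> call rate -> HWE (each criterion is evaluated on the full
    input matrix, so the retained set is order-independent).
    """
    for thr, name in ((maf_min, "maf_min"), (callrate_min, "callrate_min"),
                      (hwe_alpha, "hwe_alpha")):
        if not 0.0 <= thr <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1]")
    stats = allele_stats(geno)
    hwe_p = hwe_pvalues(geno)
    fail_maf = stats["maf"].to_numpy() < maf_min
    fail_cr = stats["call_rate"].to_numpy() < callrate_min
    fail_hwe = hwe_p < hwe_alpha

    verdict = np.full(geno.n_markers, "pass", dtype=object)
    verdict[fail_hwe] = "fail_hwe"
    verdict[fail_cr] = "fail_callrate"
    verdict[fail_maf] = "fail_maf"

    keep = ~(fail_maf | fail_cr | fail_hwe)
    table = pd.DataFrame({
        "marker_id": geno.marker_ids,
        "maf": stats["maf"],
        "call_rate": stats["call_rate"],
        "hwe_p": hwe_p,
        "verdict": verdict,
    })
    report = QcReport(
        n_input=geno.n_markers,
        n_removed_maf=int((verdict == "fail_maf").sum()),
        n_removed_callrate=int((verdict == "fail_callrate").sum()),
        n_removed_hwe=int((verdict == "fail_hwe").sum()),
        n_retained=int(keep.sum()),
        table=table,
    )
    return geno.take_markers(np.flatnonzero(keep)), report
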