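"""Synthetic cohorts with known ground truth.

Genotypes follow the Balding-Nichols drift model: each marker has an
ancestral Alt frequency p0 ~ Uniform(0.05, 0.95); each of K ancestral
populations draws its frequency from Beta(p0(1-F)/F, (1-p0)(1-F)/F)
with F the target Fst, so the simulated differentiation is directly
checkable with the package's own Weir-Cockerham estimator.  Individual
ancestry proportions are Dirichlet(alpha); dosages are Binomial(2, q)
with q the ancestry-weighted Alt frequency; markers are independent
given ancestry (no linkage disequilibrium is simulated).

The physiology generator emulates paired rest (07:00) / stress (14:00)
measurements of the five AHTI parameters.  The stress response is
scaled by a standardized genetic score built from a handful of causal
SNPs plus a polygenic term drawn with covariance proportional to the
realized vanRaden kinship, so the mixed-model assumptions of the GWAS
hold exactly under simulation.

All randomness flows from one integer seed through named generators;
no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ovitherm.io import MISSING, GenotypeMatrix
from ovitherm.gwas import vanraden_kinship


class ValidationError(ValueError):
    pass


N_AUTOSOMES = 26  # sheep karyotype

#: per-parameter (rest mean, rest SD) for an adult desert ewe
DEFAULT_BASELINES = {
    "RT": (38.8, 0.30),    # deg C
    "ET": (35.5, 0.60),    # deg C
    "RR": (35.0, 6.0),     # breaths/min
    "GV": (7.0, 1.2),      # L/min
    "VO2": (0.055, 0.008),  # L/min
    "VCO2": (0.045, 0.007),  # L/min
    "BW": (45.0, 5.0),     # kg
}

#: mean rest-to-stress change under severe heat load (THI > 100)
DEFAULT_DELTA_MEANS = {
    "RT": 1.0, "ET": 2.5, "RR": 55.0, "GV": 5.0,
    "VO2": 0.020, "VCO2": 0.018, "BW": 0.0,
}


@dataclass
class SyntheticTruth:
    q_true: np.ndarray                  # n x K ancestry proportions
    f_true: np.ndarray                  # K x m ancestral Alt frequencies
    fst_target: float
    causal_markers: list[tuple[str, float]] = field(default_factory=list)
    h2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.allclose(self.q_true.sum(axis=1), 1.0, atol=1e-12):
            raise ValidationError("Q rows must sum to 1")
        if ((self.f_true < 0) | (self.f_true > 1)).any():
            raise ValidationError("F entries must lie in [0,1]")


def simulate_admixed_genotypes(
    n_samples: int = 200,
    n_markers: int = 20_000,
    k: int = 3,
    fst_target: float = 0.05,
    alpha: float | np.ndarray = 0.2,
    missing_rate: float = 0.02,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Draw an admixed cohort under the Balding-Nichols model.

    ``alpha`` is the Dirichlet concentration of individual ancestry
    (small values give nearly unadmixed individuals; ``alpha -> 0`` is
    handled by assigning each individual wholly to one population).
    Breed and location labels are the argmax ancestry component, which
    emulates a cohort of K discrete breeds sampled at K sites.
    """
    if n_samples < 2 or n_markers < 2:
        raise ValidationError("need n_samples >= 2 and n_markers >= 2")
    if k < 1:
        raise ValidationError("K must be >= 1")
    if not 0.0 < fst_target < 1.0:
        raise ValidationError("fst_target must be in (0, 1)")
    if not 0.0 <= missing_rate < 1.0:
        raise ValidationError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    p0 = rng.uniform(0.05, 0.95, size=n_markers)
    f = fst_target
    shape1 = p0 * (1.0 - f) / f
    shape2 = (1.0 - p0) * (1.0 - f) / f
    f_true = rng.beta(shape1, shape2, size=(k, n_markers))

    alpha_vec = np.broadcast_to(np.asarray(alpha, dtype=float), (k,))
    if (alpha_vec <= 0).any():
        # degenerate concentration: unadmixed individuals, balanced pops
        q_true = np.zeros((n_samples, k))
        q_true[np.arange(n_samples), rng.integers(0, k, n_samples)] = 1.0
    else:
        q_true = rng.dirichlet(alpha_vec, size=n_samples)

    q_ind = q_true @ f_true                       # individual Alt frequency
    calls = rng.binomial(2, q_ind).astype(np.int16)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING

    chrom_of = rng.integers(1, N_AUTOSOMES + 1, size=n_markers)
    pos = np.zeros(n_markers, dtype=np.int64)
    for c in range(1, N_AUTOSOMES + 1):
        idx = np.flatnonzero(chrom_of == c)
        draw = np.unique(rng.integers(1, 100_000_000, size=2 * idx.size + 8))
        while draw.size < idx.size:  # vanishingly rare at chip densities
            extra = rng.integers(1, 100_000_000, size=idx.size)
            draw = np.unique(np.concatenate([draw, extra]))
        pos[idx] = np.sort(rng.choice(draw, size=idx.size, replace=False))
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=n_markers)
    alt_i = (ref_i + rng.integers(1, 4, size=n_markers)) % 4

    width = len(str(n_markers))
    marker_ids = [f"SNP{j + 1:0{width}d}" for j in range(n_markers)]
    sample_ids = [f"ind{i + 1:04d}" for i in range(n_samples)]
    pop = q_true.argmax(axis=1)
    breed = [f"breed{p + 1}" for p in pop]
    location = [f"site{p + 1}" for p in pop]

    geno = GenotypeMatrix(
        sample_ids, marker_ids, calls,
        chrom=np.array([str(c) for c in chrom_of], dtype=object),
        pos=pos, ref=bases[ref_i].astype(object), alt=bases[alt_i].astype(object),
        breed=breed, location=location,
    )
    truth = SyntheticTruth(q_true, f_true, fst_target, [], 0.0, seed)
    return geno, truth


# ----------------------------------------------------------------------
# Genetic scores and phenotypes
# ----------------------------------------------------------------------

def _kinship_sqrt(kin: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((kin + kin.T) / 2.0)
    return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))


def genetic_scores(geno: GenotypeMatrix, truth: SyntheticTruth,
                   rng: np.random.Generator) -> np.ndarray:
    """Standardized genetic+environmental stress-response score s.

    s = genetic part (causal effects x centred dosage + polygenic term
    with covariance proportional to the vanRaden kinship, jointly
    rescaled to variance h2) + Gaussian noise of variance 1 - h2.
    """
    n = geno.n_samples
    h2 = truth.h2
    gen = np.zeros(n)
    if h2 > 0:
        col = {mid: j for j, mid in enumerate(geno.marker_ids)}
        g = geno.calls_float()
        g = np.where(np.isnan(g), np.nanmean(g, axis=0), g)
        for mid, eff in truth.causal_markers:
            if mid not in col:
                raise ValidationError(f"causal marker {mid} not in matrix")
            d = g[:, col[mid]]
            gen = gen + eff * (d - d.mean())
        kin = vanraden_kinship(geno)
        gen = gen + _kinship_sqrt(kin) @ rng.standard_normal(n)
        sd = gen.std()
        if sd > 0:
            gen = gen / sd * np.sqrt(h2)
    env_sd = np.sqrt(max(1.0 - h2, 0.0))
    return gen + rng.normal(0.0, env_sd, size=n)


def simulate_physiology(
    geno: GenotypeMatrix,
    truth: SyntheticTruth,
    baselines: dict[str, tuple[float, float]] | None = None,
    delta_means: dict[str, float] | None = None,
    seed: int = 0,
    noise_frac: float = 0.25,
) -> pd.DataFrame:
    """Paired rest/stress physiology driven by a genetic stress response.

    Rest values are Normal(baseline mean, baseline SD) per animal; the
    stress value is ``rest + delta_mean * (1 + s_i) + eps`` with s the
    standardized score from :func:`genetic_scores` and eps Gaussian
    measurement noise of SD ``noise_frac * |delta_mean|``.  GV, VO2,
    VCO2 and BW are generated directly so tidal volume (GV/RR) and
    metabolic rate derive consistently downstream.
    """
    baselines = dict(DEFAULT_BASELINES, **(baselines or {}))
    delta_means = dict(DEFAULT_DELTA_MEANS, **(delta_means or {}))
    rng = np.random.default_rng(seed)
    n = geno.n_samples
    s = genetic_scores(geno, truth, rng)

    rows = []
    rest_vals = {p: rng.normal(mu, sd, size=n) for p, (mu, sd) in baselines.items()}
    rest_vals["RR"] = np.clip(rest_vals["RR"], 5.0, None)
    rest_vals["BW"] = np.clip(rest_vals["BW"], 20.0, None)
    rest_vals["GV"] = np.clip(rest_vals["GV"], 0.5, None)
    for p in ("VO2", "VCO2"):
        rest_vals[p] = np.clip(rest_vals[p], 1e-3, None)
    stress_vals = {}
    for p, delta in delta_means.items():
        eps = rng.normal(0.0, noise_frac * abs(delta), size=n) if delta else 0.0
        stress_vals[p] = rest_vals[p] + delta * (1.0 + s) + eps
    stress_vals["RR"] = np.clip(stress_vals["RR"], 5.0, None)
    stress_vals["BW"] = np.clip(stress_vals["BW"], 20.0, None)
    stress_vals["GV"] = np.clip(stress_vals["GV"], 0.5, None)
    for p in ("VO2", "VCO2"):
        stress_vals[p] = np.clip(stress_vals[p], 1e-3, None)

    for i, aid in enumerate(geno.sample_ids):
        for tp, vals in (("rest", rest_vals), ("stress", stress_vals)):
            rows.append({"animal_id": aid, "timepoint": tp,
                         **{p: float(vals[p][i]) for p in baselines}})
    return pd.DataFrame(rows)


def simulate_gwas_phenotype(geno: GenotypeMatrix,
                            causal: list[tuple[str, float]],
                            h2_poly: float, seed: int = 0) -> np.ndarray:
    """Continuous phenotype y = sum(beta * dosage) + polygenic + noise.

    The polygenic and residual terms have total variance 1 split as
    ``h2_poly`` : ``1 - h2_poly``; causal effects are in phenotype
    units per Alt allele.  Used for association power and type-I
    studies where an integer score would only coarsen the signal.
    """
    if not 0.0 <= h2_poly < 1.0:
        raise ValidationError("h2_poly must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = geno.n_samples
    col = {mid: j for j, mid in enumerate(geno.marker_ids)}
    g = geno.calls_float()
    g = np.where(np.isnan(g), np.nanmean(g, axis=0), g)
    y = np.zeros(n)
    for mid, eff in causal:
        if mid not in col:
            raise ValidationError(f"causal marker {mid} not in matrix")
        y = y + eff * g[:, col[mid]]
    if h2_poly > 0:
        kin = vanraden_kinship(geno)
        u = _kinship_sqrt(kin) @ rng.standard_normal(n)
        sd = u.std()
        if sd > 0:
            u = u / sd * np.sqrt(h2_poly)
        y = y + u
    return y + rng.normal(0.0, np.sqrt(1.0 - h2_poly), size=n)


# ----------------------------------------------------------------------
# Meteorology
# ----------------------------------------------------------------------

def simulate_meteo(site_params: list[tuple[str, float, float, float, float]]) -> pd.DataFrame:
    """Build a meteorological table from per-site (DBT, RH) pairs.

    ``site_params`` rows are (label, DBT_am, RH_am, DBT_pm, RH_pm);
    the output has one row per site and clock time, ready for THI
    computation.
    """
    labels = [row[0] for row in site_params]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate site labels")
    rows = []
    for label, dbt_am, rh_am, dbt_pm, rh_pm in site_params:
        for clock, dbt, rh in (("07:00", dbt_am, rh_am), ("14:00", dbt_pm, rh_pm)):
            if not -20.0 <= dbt <= 60.0:
                raise ValidationError(f"DBT {dbt} out of plausible range")
            if not 0.0 <= rh <= 100.0:
                raise ValidationError(f"RH {rh} outside [0, 100]")
            rows.append({"location": label, "clock_time": clock,
                         "DBT": dbt, "RH": rh})
    return pd.DataFrame(rows, columns=["location", "clock_time", "DBT", "RH"])
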