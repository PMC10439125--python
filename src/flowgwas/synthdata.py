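"""Synthetic cohorts with known ground truth.

Every downstream stage of the pipeline (adjustment, association,
conditional selection, clumping, fine-mapping, colocalisation,
enrichment) is exercised on cohorts produced here, because the real
cohorts such analyses run on are access-controlled.  The generator
injects

* LD-blocked genotypes (Gaussian copula per block: a latent exchangeable
  multivariate normal thresholded to hard genotypes at Hardy-Weinberg
  allele frequencies, which gives tunable within-block correlation with
  exact marginal MAF),
* additive genetic effects on the transformed trait scale,
* the technical structure the stage-1 adjustment model targets
  (between-analyser offsets, slow machine drift, an annual seasonal
  cycle, a time-since-venipuncture trend, day-of-week shifts), and
* the physiological covariate structure the stage-2 model targets,

and records exactly what it injected in a :class:`TrueModel` so tests can
compare recovered quantities against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

# Fixed calendar conventions: timestamps are seconds since the Unix
# epoch; the seasonal term uses a 365.25-day year.
SECONDS_PER_DAY = 86_400
SECONDS_PER_YEAR = int(365.25 * SECONDS_PER_DAY)
STUDY_START = int(pd.Timestamp("2012-06-11", tz="UTC").timestamp())
STUDY_SPAN = 2 * SECONDS_PER_YEAR

MENO_LEVELS = ("post", "pre", "hysterectomy", "male", "NA")
DRK_LEVELS = ("never", "previous", "current", "NA")
ALC_LEVELS = ("never", "rarely", "1_to_3_months", "1_to_2_weeks", "3_to_5_weeks", "most_days")
SMK_LEVELS = ("never", "previous", "current", "NA")
SFRQ_LEVELS = ("never", "special_occasions", "rarely", "occasional", "most_days", "every_day")
ARM_LEVELS = ("M8", "M10", "M12", "F12", "F14", "F16")


@dataclass
class Block:
    """One LD block: variants mutually correlated, independent of other blocks."""

    chrom: str
    n_variants: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    within_block_corr: float = 0.7

    def validate(self) -> None:
        lo, hi = self.maf_range
        if self.n_variants <= 0:
            raise ValueError(f"block on {self.chrom}: n_variants must be positive")
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"block on {self.chrom}: maf_range must lie in (0, 0.5]")
        if not (0.0 <= self.within_block_corr < 1.0):
            raise ValueError(f"block on {self.chrom}: within_block_corr must lie in [0, 1)")


@dataclass
class TechEffects:
    """Amplitudes of the injected technical terms, in trait-SD units."""

    machine_offset: float = 0.0
    drift_amplitude: float = 0.0
    seasonal_amplitude: float = 0.0
    venipuncture_slope: float = 0.0  # SD units per hour since venipuncture


@dataclass
class SimConfig:
    n_samples: int = 1000
    blocks: list[Block] = field(default_factory=lambda: [Block("1", 20)])
    causal_effects: list[tuple[str, str, float]] = field(default_factory=list)
    tech_effects: TechEffects = field(default_factory=TechEffects)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0
    trait_supports: dict[str, str] = field(default_factory=dict)  # trait -> support class

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for b in self.blocks:
            b.validate()


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    ``dosages`` holds alternate-allele dose in [0, 2] (hard genotypes
    {0, 1, 2} unless imputation noise was added); ``variants`` carries
    id, chrom, pos, ref, alt, maf (empirical), info and block columns.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in genotype matrix")
        return self.dosages[:, idx[0]]


@dataclass
class TrueModel:
    """Record of everything a simulation injected."""

    causal: dict[str, list[tuple[str, float]]]  # trait -> [(variant id, beta)]
    technical: dict[str, np.ndarray]  # term name -> per-sample contribution
    covariate: dict[str, np.ndarray]
    noise_sd: float
    protein_shift: float = 0.0


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw LD-blocked hard genotypes via a per-block Gaussian copula.

    Each haplotype's latent value is sqrt(rho)*u_block + sqrt(1-rho)*e,
    thresholded at the normal quantile of the variant's allele frequency,
    so marginal allele frequencies are exact Hardy-Weinberg binomials
    while within-block dosage correlation is governed by ``rho``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    sizes = [b.n_variants for b in config.blocks]
    total = sum(sizes)
    block_of = np.repeat(np.arange(len(sizes)), sizes)
    rho = np.repeat([b.within_block_corr for b in config.blocks], sizes)
    mafs = np.concatenate([rng.uniform(*b.maf_range, size=b.n_variants) for b in config.blocks])
    thresholds = norm.ppf(mafs)  # latent < threshold -> alt allele

    # one shared factor per block; latents drawn in float32 and built in
    # place, block by block, to keep the working set cache-sized at
    # genome-scan widths
    thresholds32 = thresholds.astype(np.float32)
    dosages = np.zeros((n, total), dtype=np.float64)
    offset = 0
    for b in config.blocks:
        m = b.n_variants
        w_u = np.float32(np.sqrt(b.within_block_corr))
        w_e = np.float32(np.sqrt(1.0 - b.within_block_corr))
        th = thresholds32[offset : offset + m]
        out = dosages[:, offset : offset + m]
        for _hap in range(2):
            u = rng.standard_normal((n, 1), dtype=np.float32)
            z = rng.standard_normal((n, m), dtype=np.float32)
            z *= w_e
            z += w_u * u
            out += z < th
        offset += m
    del block_of

    meta: list[pd.DataFrame] = []
    pos_counter: dict[str, int] = {}
    offset = 0
    for bi, block in enumerate(config.blocks):
        m = block.n_variants
        start = pos_counter.get(block.chrom, 1_000_000)
        pos = start + 10_000 * np.arange(m)
        freq = dosages[:, offset : offset + m].mean(axis=0) / 2.0
        meta.append(
            pd.DataFrame(
                {
                    "id": [f"{block.chrom}:{p}:A:G" for p in pos],
                    "chrom": block.chrom,
                    "pos": pos,
                    "ref": "A",
                    "alt": "G",
                    "maf": np.minimum(freq, 1 - freq),
                    "info": 1.0,
                    "block": bi,
                }
            )
        )
        pos_counter[block.chrom] = start + m * 10_000 + 20_000_000  # blocks far apart
        offset += m

    variants = pd.concat(meta, ignore_index=True)
    samples = [f"S{i:05d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


def simulate_covariates(n: int, seed: int = 0) -> pd.DataFrame:
    """Per-sample technical and baseline covariates.

    Emits every field the two adjustment models consume: measurement
    timestamp (and the derived day-of-week, seconds-since-new-year and
    time-of-day), analyser label, venipuncture interval with a
    missingness indicator (missing values imputed by the observed
    median), age, sex, menopause status consistent with sex, weight and
    height with missingness flags, drinking/alcohol/smoking covariates,
    trial arm and clinic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)

    t = STUDY_START + rng.integers(0, STUDY_SPAN, size=n)
    # working-hours time of day so t_day is informative
    ts = pd.to_datetime(t, unit="s", utc=True)
    day_start = ts.normalize()
    t = (day_start + pd.to_timedelta(rng.uniform(8 * 3600, 20 * 3600, size=n), unit="s")).astype(
        "int64"
    ) // 10**9
    ts = pd.to_datetime(t, unit="s", utc=True)

    analyser = np.where(rng.random(n) < 0.5, "A", "B")
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    age = rng.uniform(18, 75, size=n).round(1)

    meno = np.full(n, "male", dtype=object)
    female = sex == "F"
    u = rng.random(n)
    meno[female & (age < 48)] = "pre"
    meno[female & (age >= 48)] = "post"
    meno[female & (u < 0.05)] = "hysterectomy"
    meno[female & (u >= 0.05) & (u < 0.08)] = "NA"

    # venipuncture -> analysis interval, hours; some clinics post samples
    t_ven_h = rng.uniform(2, 36, size=n)
    t_ven_missing = rng.random(n) < 0.05
    t_ven_obs = np.where(t_ven_missing, np.nan, t_ven_h)
    median_ven = float(np.nanmedian(t_ven_obs))
    t_ven_imputed = np.where(t_ven_missing, median_ven, t_ven_obs)

    wgt = rng.normal(78, 14, size=n).clip(40)
    hgt = rng.normal(172, 9, size=n).clip(140)
    wgt_na = rng.random(n) < 0.02
    hgt_na = rng.random(n) < 0.02
    wgt_v = np.where(wgt_na, np.nan, wgt)
    hgt_v = np.where(hgt_na, np.nan, hgt)
    wgt_v = np.where(np.isnan(wgt_v), np.nanmean(wgt_v), wgt_v)
    hgt_v = np.where(np.isnan(hgt_v), np.nanmean(hgt_v), hgt_v)

    pckyrs = np.where(rng.random(n) < 0.6, 0.0, rng.gamma(2.0, 6.0, size=n))
    pckyrs_na = rng.random(n) < 0.03
    pckyrs_v = np.where(pckyrs_na, np.nan, pckyrs)
    pckyrs_v = np.where(np.isnan(pckyrs_v), np.nanmean(pckyrs_v), pckyrs_v)

    arm = np.where(
        sex == "M",
        rng.choice(["M8", "M10", "M12"], size=n),
        rng.choice(["F12", "F14", "F16"], size=n),
    )

    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n)],
            "timestamp": t,
            "t": t - STUDY_START,
            "analyser": analyser,
            "t_year": (
                (
                    ts.tz_localize(None).to_numpy()
                    - pd.to_datetime({"year": ts.year, "month": 1, "day": 1}).to_numpy()
                )
                / np.timedelta64(1, "s")
            ).astype(np.int64),
            "t_day": (t % SECONDS_PER_DAY).astype(np.int64),
            "t_ven": (t_ven_imputed * 3600).astype(np.int64),
            "t_ven_imputed": t_ven_missing,
            "day_of_week": ts.day_name().str.lower(),
            "sex": sex,
            "age": age,
            "meno": meno,
            "wgt": wgt_v.round(1),
            "wgt_na": wgt_na,
            "hgt": hgt_v.round(1),
            "hgt_na": hgt_na,
            "drk": rng.choice(DRK_LEVELS, size=n, p=[0.2, 0.15, 0.6, 0.05]),
            "alc": rng.choice(ALC_LEVELS, size=n),
            "smk": rng.choice(SMK_LEVELS, size=n, p=[0.55, 0.25, 0.15, 0.05]),
            "sfrq": rng.choice(SFRQ_LEVELS, size=n),
            "pckyrs": pckyrs_v.round(2),
            "pckyrs_na": pckyrs_na,
            "arm": arm,
            "clinic": rng.choice(["C1", "C2", "C3", "C4"], size=n),
        }
    )
    return df


def _technical_terms(cov: pd.DataFrame, te: TechEffects) -> dict[str, np.ndarray]:
    """Per-sample technical contributions, each centred over the cohort."""
    out: dict[str, np.ndarray] = {}
    m_ind = (cov["analyser"].to_numpy() == "B").astype(float)
    out["machine"] = te.machine_offset * (m_ind - m_ind.mean())
    tfrac = cov["t"].to_numpy() / STUDY_SPAN
    drift = np.sin(2 * np.pi * tfrac)  # one slow cycle over the study
    out["drift"] = te.drift_amplitude * (drift - drift.mean())
    seas = np.sin(2 * np.pi * cov["t_year"].to_numpy() / SECONDS_PER_YEAR)
    out["seasonal"] = te.seasonal_amplitude * (seas - seas.mean())
    ven_h = cov["t_ven"].to_numpy() / 3600.0
    out["venipuncture"] = te.venipuncture_slope * (ven_h - ven_h.mean())
    return out


_COVARIATE_DESIGNS = {
    "age": lambda c: c["age"].to_numpy(float),
    "male": lambda c: (c["sex"].to_numpy() == "M").astype(float),
    "wgt": lambda c: c["wgt"].to_numpy(float),
    "hgt": lambda c: c["hgt"].to_numpy(float),
    "pckyrs": lambda c: c["pckyrs"].to_numpy(float),
    "current_smoker": lambda c: (c["smk"].to_numpy() == "current").astype(float),
}


def simulate_phenotypes(
    g: GenotypeMatrix, cov: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, TrueModel]:
    """Measured traits = a^-1(genetics + technical + covariates + noise).

    The additive model is built on the transformed (analysis) scale and
    mapped back through the inverse pre-transform of each trait's
    support class, so the adjustment stages see exactly the structure
    they are designed to remove.  Technical terms are functions of the
    covariate table only, hence independent of genotype by construction.
    """
    config.validate()
    if len(cov) != g.n_samples:
        raise ValueError("sample sets of genotypes and covariates do not match")
    rng = np.random.default_rng(config.seed + 1)
    n = g.n_samples

    traits = sorted({t for _, t, _ in config.causal_effects}) or ["trait1"]
    known_ids = set(g.variants["id"])
    for vid, _, _ in config.causal_effects:
        if vid not in known_ids:
            raise ValueError(f"causal variant {vid!r} absent from genotype matrix")

    tech = _technical_terms(cov, config.tech_effects)
    tech_total = sum(tech.values(), np.zeros(n))

    cov_terms: dict[str, np.ndarray] = {}
    for name, coef in config.covariate_effects.items():
        if name not in _COVARIATE_DESIGNS:
            raise ValueError(f"unknown covariate effect {name!r}")
        x = _COVARIATE_DESIGNS[name](cov)
        cov_terms[name] = coef * (x - x.mean())
    cov_total = sum(cov_terms.values(), np.zeros(n))

    causal: dict[str, list[tuple[str, float]]] = {t: [] for t in traits}
    values: dict[str, np.ndarray] = {}
    from .phenoadjust import inverse_pre_transform  # local import avoids cycle

    for trait in traits:
        eta = np.zeros(n)
        for vid, tname, beta in config.causal_effects:
            if tname == trait:
                eta += beta * g.column(vid)
                causal[trait].append((vid, beta))
        y = eta + tech_total + cov_total + rng.normal(0.0, config.noise_sd, size=n)
        support = config.trait_supports.get(trait, "unbounded")
        values[trait] = inverse_pre_transform(y, support)

    pheno = pd.DataFrame(values)
    pheno.insert(0, "sample_id", cov["sample_id"].to_numpy())
    truth = TrueModel(
        causal=causal, technical=tech, covariate=cov_terms, noise_sd=config.noise_sd
    )
    return pheno, truth


def simulate_protein_table(
    n_proteins: int,
    n_granule: int,
    delta: float,
    seed: int = 0,
    effect_sd: float = 0.05,
    se_scale: float = 0.012,
    fpkm_confounded: bool = False,
) -> pd.DataFrame:
    """Per-protein allelic effect estimates with an alpha-granule shift.

    Effect estimates are drawn around a mean shifted by ``-delta`` for
    granule-labelled proteins; each protein gets an estimation standard
    error and a Wald p-value, plus a megakaryocyte expression value
    (log2 FPKM), drawn independently of the label unless
    ``fpkm_confounded`` is set.
    """
    if n_granule > n_proteins:
        raise ValueError("n_granule cannot exceed n_proteins")
    rng = np.random.default_rng(seed)
    granule = np.zeros(n_proteins, dtype=bool)
    granule[:n_granule] = True

    fpkm = rng.normal(4.0, 2.0, size=n_proteins)
    mean = np.where(granule, -delta, 0.0)
    if fpkm_confounded:
        # expression itself shifts the effect, and granule proteins are
        # more highly expressed -- the classic confounding pattern
        fpkm = fpkm + np.where(granule, 2.0, 0.0)
        mean = mean - 0.01 * (fpkm - fpkm.mean())
    true_effect = mean + rng.normal(0.0, effect_sd, size=n_proteins)
    se = se_scale * rng.uniform(0.8, 1.25, size=n_proteins)
    beta = true_effect + rng.normal(0.0, se)
    p = 2 * norm.sf(np.abs(beta / se))

    return pd.DataFrame(
        {
            "protein_id": [f"P{i:04d}" for i in range(n_proteins)],
            "beta": beta,
            "se": se,
            "p": p,
            "alpha_granule": granule,
            "log2_fpkm": fpkm,
        }
    )
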