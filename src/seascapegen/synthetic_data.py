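"""Synthetic genotype + depth + environment datasets with per-locus truth.

The generator emulates a fjord-seascape RAD-seq study design: ~10 sampling
locations with unequal sample sizes, thousands of biallelic SNPs, six
environmental variables summarised per location, adaptive allele-frequency
clines along those variables, merged-paralog contamination, and missing
genotypes.  Every locus carries a truth-table row (neutral / adaptive /
paralog) so downstream detection stages can be scored.

Model summary
-------------
* Neutral loci: per-deme alternate-allele frequencies follow the
  Balding–Nichols model, ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with ancestral
  frequency ``p`` and differentiation parameter ``F`` (the expected
  Weir–Cockerham FST among demes).
* Adaptive loci: deme frequency is a logistic cline on the z-scored value of
  one environmental variable, ``expit(alpha + beta * z(env))``.
* Genotypes: ``Binomial(2, p_deme)`` per individual; read depths are
  negative-binomial with a 50:50 binomial allele split in heterozygotes.
* Paralogs: two independent diploid copies whose reads merge; the apparent
  genotype is heterozygous whenever the four underlying allele copies carry
  both alleles, and the alt-read fraction in apparent heterozygotes is
  ``alt_copies / 4`` — the signature HDplot detects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_core import (
    MISSING,
    DepthTable,
    EnvTable,
    GenotypeMatrix,
    write_popmap,
    write_vcf,
)

#: Default location labels and rough fjord-region coordinates (decimal deg).
DEFAULT_LOCATIONS = (
    ("REL", -41.70, -72.40),
    ("MAN", -41.90, -73.45),
    ("HOR", -41.95, -72.45),
    ("CHE", -42.05, -74.05),
    ("CHA", -42.92, -72.75),
    ("RMB", -43.78, -72.95),
    ("MEL", -43.90, -73.75),
    ("PUY", -44.32, -72.56),
    ("CIS", -44.74, -72.70),
    ("AYS", -45.40, -72.83),
)

#: Per-variable (deme profile over 10 locations, half-spread) defaults.
#: Profiles are deliberately correlated but not collinear, mimicking the
#: joint latitudinal / estuarine structure of fjord water masses.
DEFAULT_ENV_PROFILES = {
    "temperature": (np.array([13.0, 12.6, 12.4, 12.0, 11.6, 11.2, 11.0, 10.6, 10.3, 10.0]), 3.0),
    "salinity": (np.array([26.0, 31.5, 28.0, 33.0, 30.5, 30.0, 32.5, 29.0, 29.5, 28.5]), 2.5),
    "oxygen": (np.array([6.4, 6.0, 6.1, 5.9, 5.4, 5.0, 5.2, 4.6, 4.4, 4.2]), 1.5),
    "nitrate": (np.array([8.0, 10.0, 9.0, 12.0, 11.0, 13.0, 14.0, 15.0, 15.5, 16.0]), 4.0),
    "phosphate": (np.array([1.0, 0.9, 1.2, 1.0, 1.4, 1.2, 1.5, 1.4, 1.7, 1.6]), 0.5),
    "silicate": (np.array([20.0, 10.0, 16.0, 6.0, 12.0, 14.0, 8.0, 17.0, 15.0, 13.0]), 5.0),
}


@dataclass
class SimulationParams:
    """Knobs of the synthetic study; defaults mirror the emulated design.

    ``n_per_deme`` defaults to the retained per-location sample sizes of a
    10-location fjord survey (202 individuals total, 12–27 per site).
    ``fst_drift`` is the Balding–Nichols F; ``beta_env`` the logistic cline
    slope per unit z-scored environment for adaptive loci.
    """

    n_demes: int = 10
    n_per_deme: list[int] = field(
        default_factory=lambda: [17, 23, 24, 12, 15, 22, 20, 22, 20, 27]
    )
    n_neutral_loci: int = 2000
    n_adaptive_loci: int = 100
    n_paralog_loci: int = 50
    p_lo: float = 0.1
    p_hi: float = 0.9
    fst_drift: float = 0.05
    beta_env: float = 1.5
    alpha_range: float = 0.5
    adaptive_variables: tuple[str, ...] = ("temperature", "salinity", "oxygen")
    #: "logistic": expit(alpha + beta z); "linear": 0.5 + 0.15 beta z clipped
    #: to [0.02, 0.98] (frequency linear in the gradient, the textbook
    #: directional-selection cline for power studies).
    cline_model: str = "logistic"
    env_summary_for_cline: str = "mean"
    missing_rate_locus: float = 0.03
    missing_rate_sample: float = 0.02
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.adaptive_variables = tuple(self.adaptive_variables)
        self.n_per_deme = list(self.n_per_deme)
        if not 0 < self.fst_drift < 1:
            raise ValueError("fst_drift must be in (0, 1)")
        for r in (self.missing_rate_locus, self.missing_rate_sample):
            if not 0 <= r <= 1:
                raise ValueError("missing rates must be in [0, 1]")
        if len(self.n_per_deme) != self.n_demes:
            raise ValueError("n_per_deme length must equal n_demes")
        if not 0 < self.p_lo <= self.p_hi < 1:
            raise ValueError("require 0 < p_lo <= p_hi < 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["adaptive_variables"] = list(self.adaptive_variables)
        return d


def simulate_environment(params: SimulationParams) -> EnvTable:
    """Build the per-location environment table from the deme profiles.

    Each variable's mean follows its profile; min/max are mean -/+ the
    profile's half-spread, so min <= mean <= max holds by construction and
    the z-scores of mean, min and max coincide across demes.
    """
    if params.n_demes < 2:
        raise ValueError("need at least two demes")
    rows = {}
    labels, lats, lons = [], [], []
    for d in range(params.n_demes):
        base = DEFAULT_LOCATIONS[d % len(DEFAULT_LOCATIONS)]
        suffix = "" if d < len(DEFAULT_LOCATIONS) else f"{d // len(DEFAULT_LOCATIONS)}"
        labels.append(base[0] + suffix)
        lats.append(base[1])
        lons.append(base[2])
    rows["latitude"] = lats
    rows["longitude"] = lons
    for var, (profile, spread) in DEFAULT_ENV_PROFILES.items():
        if not np.all(np.isfinite(profile)):
            raise ValueError(f"non-finite gradient specification for {var}")
        vals = np.interp(
            np.linspace(0, len(profile) - 1, params.n_demes),
            np.arange(len(profile)),
            profile,
        )
        rows[f"{var}_mean"] = vals
        rows[f"{var}_min"] = vals - spread
        rows[f"{var}_max"] = vals + spread
        rows[f"{var}_range"] = np.full(params.n_demes, 2 * spread)
    return EnvTable(pd.DataFrame(rows, index=pd.Index(labels, name="location")))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("environmental variable constant across demes")
    return (x - x.mean()) / sd


def simulate_allele_freqs(
    params: SimulationParams, env: EnvTable, rng: np.random.Generator
):
    """Per-deme allele frequencies for neutral and adaptive loci.

    Returns ``(freqs, truth)`` where ``freqs`` is (n_demes, n_loci) and
    ``truth`` a DataFrame with class / variable / beta per locus (paralogs
    are appended later by :func:`simulate_paralog_loci`).
    """
    F = params.fst_drift
    n_d = params.n_demes
    p_anc = rng.uniform(params.p_lo, params.p_hi, size=params.n_neutral_loci)
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    neutral = rng.beta(a[None, :], b[None, :], size=(n_d, params.n_neutral_loci))

    n_ad = params.n_adaptive_loci
    variables = [
        params.adaptive_variables[j % len(params.adaptive_variables)] for j in range(n_ad)
    ]
    alphas = rng.uniform(-params.alpha_range, params.alpha_range, size=n_ad)
    betas = rng.choice([-1.0, 1.0], size=n_ad) * params.beta_env
    cols = np.empty((n_d, n_ad))
    for j, var in enumerate(variables):
        z = _zscore(env.value(var, params.env_summary_for_cline).to_numpy())
        if params.cline_model == "logistic":
            cols[:, j] = expit(alphas[j] + betas[j] * z)
        elif params.cline_model == "linear":
            cols[:, j] = np.clip(0.5 + 0.15 * betas[j] * z, 0.02, 0.98)
        else:
            raise ValueError("cline_model must be 'logistic' or 'linear'")
    freqs = np.clip(np.hstack([neutral, cols]), 1e-9, 1 - 1e-9)
    truth = pd.DataFrame(
        {
            "class": ["neutral"] * params.n_neutral_loci + ["adaptive"] * n_ad,
            "variable": [""] * params.n_neutral_loci + variables,
            "beta": np.concatenate([np.zeros(params.n_neutral_loci), betas]),
        }
    )
    return freqs, truth


def simulate_genotypes(
    freqs: np.ndarray, params: SimulationParams, rng: np.random.Generator
):
    """Draw genotypes and allele-specific depths given deme frequencies.

    Genotypes are Binomial(2, p_deme); total depth per called genotype is
    negative-binomial (mean ``depth_mean``, shape ``depth_dispersion``) and
    alt reads are Binomial(depth, 0.5) for heterozygotes, all-ref/all-alt
    for homozygotes.  Missingness is entrywise Bernoulli with combined rate
    ``1 - (1-r_locus)(1-r_sample)``.
    """
    if np.any(freqs < 0) or np.any(freqs > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    n_demes, n_loci = freqs.shape
    sizes = params.n_per_deme
    n_total = int(sum(sizes))
    deme_of = np.repeat(np.arange(n_demes), sizes)
    p_ind = freqs[deme_of, :]  # (n_total, n_loci)
    geno = rng.binomial(2, p_ind).astype(np.int8)

    depth = _negbin(rng, params.depth_mean, params.depth_dispersion, geno.shape)
    depth = np.maximum(depth, 1)  # a called genotype implies >= 1 read
    alt = np.where(
        geno == 1,
        rng.binomial(depth, 0.5),
        np.where(geno == 2, depth, 0),
    )
    ref = depth - alt

    miss_rate = 1 - (1 - params.missing_rate_locus) * (1 - params.missing_rate_sample)
    miss = rng.random(geno.shape) < miss_rate
    geno = np.where(miss, MISSING, geno).astype(np.int8)
    ref = np.where(miss, 0, ref)
    alt = np.where(miss, 0, alt)
    return geno, DepthTable(ref=ref, alt=alt), deme_of


def _negbin(rng: np.random.Generator, mean: float, shape: float, size) -> np.ndarray:
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p, size=size).astype(np.int32)


def simulate_paralog_loci(
    params: SimulationParams, rng: np.random.Generator, n_individuals: int
):
    """Merged-duplicate loci: two independent copies observed as one.

    Each paralog is two independent loci (deme-free, ancestral frequency
    drawn per copy).  Per individual the four allele copies give the apparent
    genotype (het iff both alleles present); merged depth is drawn at twice
    the per-copy mean and alt reads follow ``Binomial(depth, copies/4)``.
    """
    n_p = params.n_paralog_loci
    geno = np.zeros((n_individuals, n_p), dtype=np.int8)
    ref = np.zeros((n_individuals, n_p), dtype=np.int32)
    alt = np.zeros((n_individuals, n_p), dtype=np.int32)
    for j in range(n_p):
        p1, p2 = rng.uniform(params.p_lo, params.p_hi, size=2)
        copies = rng.binomial(2, p1, size=n_individuals) + rng.binomial(
            2, p2, size=n_individuals
        )
        geno[:, j] = np.select([copies == 0, copies == 4], [0, 2], default=1)
        depth = _negbin(rng, 2 * params.depth_mean, params.depth_dispersion, n_individuals)
        depth = np.maximum(depth, 1)
        alt[:, j] = rng.binomial(depth, copies / 4.0)
        ref[:, j] = depth - alt[:, j]
    truth = pd.DataFrame(
        {"class": ["paralog"] * n_p, "variable": [""] * n_p, "beta": np.zeros(n_p)}
    )
    return geno, DepthTable(ref=ref, alt=alt), truth


@dataclass
class SyntheticDataset:
    gm: GenotypeMatrix
    depths: DepthTable
    env: EnvTable
    truth: pd.DataFrame  # indexed by locus_id
    params: SimulationParams


def simulate_dataset(params: SimulationParams) -> SyntheticDataset:
    """Full in-memory dataset: genotypes, depths, environment, truth table.

    Loci are laid out as RAD tags with 1–3 SNPs per tag so the one-SNP-per-tag
    filter has work to do; paralog columns are appended as their own tags.
    The same seed always returns an identical dataset.
    """
    rng = np.random.default_rng(params.seed)
    env = simulate_environment(params)
    freqs, truth = simulate_allele_freqs(params, env, rng)
    geno, depths, deme_of = simulate_genotypes(freqs, params, rng)
    n_individuals = geno.shape[0]
    if params.n_paralog_loci > 0:
        pg, pdep, ptruth = simulate_paralog_loci(params, rng, n_individuals)
        geno = np.hstack([geno, pg])
        depths = DepthTable(
            ref=np.hstack([depths.ref, pdep.ref]),
            alt=np.hstack([depths.alt, pdep.alt]),
        )
        truth = pd.concat([truth, ptruth], ignore_index=True)

    n_loci = geno.shape[1]
    # group singleton loci into tags of 1-3 SNPs; paralog loci get own tags
    tags = np.empty(n_loci, dtype=object)
    positions = np.empty(n_loci, dtype=np.int64)
    tag_no, j = 0, 0
    n_main = n_loci - params.n_paralog_loci
    while j < n_main:
        k = int(rng.integers(1, 4))
        k = min(k, n_main - j)
        pos = np.sort(rng.choice(np.arange(5, 140), size=k, replace=False))
        for m in range(k):
            tags[j + m] = f"tag{tag_no:06d}"
            positions[j + m] = int(pos[m])
        tag_no += 1
        j += k
    for m in range(params.n_paralog_loci):
        tags[n_main + m] = f"tag{tag_no:06d}"
        positions[n_main + m] = int(rng.integers(5, 140))
        tag_no += 1

    labels = env.locations
    samples, popmap = [], {}
    counters = {}
    for d, lab in zip(deme_of, [labels[d] for d in deme_of]):
        counters[lab] = counters.get(lab, 0) + 1
        s = f"{lab}_{counters[lab]:03d}"
        samples.append(s)
        popmap[s] = lab
    gm = GenotypeMatrix(
        samples=samples,
        tags=tags,
        positions=positions,
        calls=geno,
        popmap=pd.Series(popmap),
    )
    truth.index = pd.Index(gm.locus_ids, name="locus")
    return SyntheticDataset(gm=gm, depths=depths, env=env, truth=truth, params=params)


def generate_dataset(params: SimulationParams, outdir) -> dict[str, Path]:
    """Simulate and write VCF + popmap + environment CSV + truth TSV.

    Identical parameters (including seed) produce byte-identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(params)
    paths = {
        "vcf": out / "genotypes.vcf",
        "popmap": out / "popmap.tsv",
        "env": out / "environment.csv",
        "truth": out / "truth.tsv",
    }
    write_vcf(ds.gm, paths["vcf"], depths=ds.depths)
    write_popmap(ds.gm.popmap, paths["popmap"])
    ds.env.to_csv(paths["env"])
    ds.truth.to_csv(paths["truth"], sep="\t")
    return paths
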