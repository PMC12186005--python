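"""Iterative SNP/sample filter cascade with paralog and HWE screening.

The cascade mirrors the study design for RAD-seq notothenioid data:
per-location MAF at 0.05 -> 50% call-rate tier (loci then samples) -> 90%
tier -> per-location MAF at 0.1 -> HDplot paralog removal (H < 0.6, |D| < 5)
-> Hardy-Weinberg exact-test filter -> one SNP per RAD tag (highest FST).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_core import MISSING, DepthTable, FilterReport, GenotypeMatrix
from .popgen_stats import theta_per_locus


# ----------------------------------------------------------------------
# MAF and call rate
# ----------------------------------------------------------------------

def maf_per_location(gm: GenotypeMatrix) -> pd.DataFrame:
    """Minor-allele frequency per locus x location; NaN where no calls."""
    pop_idx, locs = gm.location_indices()
    called = gm.called_mask()
    geno = np.where(called, gm.calls, 0).astype(float)
    onehot = np.zeros((len(locs), gm.n_samples))
    onehot[pop_idx, np.arange(gm.n_samples)] = 1.0
    n_il = onehot @ called
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (onehot @ geno) / (2 * n_il)
    maf = np.minimum(f, 1 - f)
    maf[n_il == 0] = np.nan
    return pd.DataFrame(maf.T, index=gm.locus_ids, columns=locs)


def filter_maf(
    gm: GenotypeMatrix, threshold: float, rule: str = "any"
) -> GenotypeMatrix:
    """Retain loci whose per-location MAF meets the threshold.

    ``rule="any"`` keeps a locus if MAF >= threshold in at least one
    location (preserves locally common variants); ``rule="all"`` requires
    every location with data to meet it.
    """
    if not 0 < threshold < 0.5:
        raise ValueError("MAF threshold must be in (0, 0.5)")
    if rule not in ("any", "all"):
        raise ValueError("rule must be 'any' or 'all'")
    maf = maf_per_location(gm).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if rule == "any":
            keep = np.nanmax(maf, axis=1) >= threshold
        else:
            keep = np.nanmin(maf, axis=1) >= threshold
    keep = np.where(np.isnan(np.nanmax(maf, axis=1)), False, keep)
    return gm.subset(locus_idx=keep)


def filter_call_rate(
    gm: GenotypeMatrix,
    locus_min: float,
    sample_min: float,
    depths: DepthTable | None = None,
):
    """Drop loci below ``locus_min`` call rate, then samples below ``sample_min``.

    Loci are filtered before samples within the tier.  Returns
    ``(gm, depths)`` with the depth table subset alongside when given.
    """
    for t in (locus_min, sample_min):
        if not 0 < t <= 1:
            raise ValueError("call-rate thresholds must be in (0, 1]")
    called = gm.called_mask()
    locus_rate = called.mean(axis=0)
    keep_loci = locus_rate >= locus_min
    if not keep_loci.any():
        warnings.warn("all loci removed by locus call-rate filter")
    gm = gm.subset(locus_idx=keep_loci)
    if depths is not None:
        depths = depths.subset(locus_idx=keep_loci)
    called = gm.called_mask()
    if gm.n_loci == 0:
        return gm, depths
    sample_rate = called.mean(axis=1)
    keep_samples = sample_rate >= sample_min
    gm = gm.subset(sample_idx=keep_samples)
    if depths is not None:
        depths = depths.subset(sample_idx=keep_samples)
    return gm, depths


# ----------------------------------------------------------------------
# HDplot
# ----------------------------------------------------------------------

@dataclass
class HDplotStats:
    """Per-locus heterozygote proportion H and read-ratio deviation D.

    H is the fraction of called individuals that are heterozygous.  D is the
    z-score of the designated-allele (reference) read count among all reads
    in heterozygotes: ``D = (x - n/2) / sqrt(n/4)`` with n total reads and x
    reference reads.  A true single-copy locus has D near 0; merged paralogs
    show |D| well beyond the binomial expectation.
    """

    h: np.ndarray
    d: np.ndarray
    locus_ids: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"H": self.h, "D": self.d}, index=self.locus_ids)


def hdplot_stats(gm: GenotypeMatrix, depths: DepthTable) -> HDplotStats:
    if (depths.ref < 0).any() or (depths.alt < 0).any():
        raise ValueError("negative depths")
    called = gm.called_mask()
    het = gm.calls == 1
    n_called = called.sum(axis=0)
    n_het = het.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(n_called > 0, n_het / n_called, 0.0)
    x = np.where(het, depths.ref, 0).sum(axis=0).astype(float)  # designated allele
    n = np.where(het, depths.ref + depths.alt, 0).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (x - n / 2) / np.sqrt(n / 4)
    d = np.where(n > 0, d, 0.0)
    h = np.where(n_het > 0, h, 0.0)
    return HDplotStats(h=h, d=d, locus_ids=gm.locus_ids)


def filter_paralogs(
    gm: GenotypeMatrix,
    stats: HDplotStats,
    h_max: float = 0.6,
    d_max: float = 5.0,
):
    """Retain singleton-like loci: H < h_max and |D| < d_max.

    Returns ``(retained_gm, removed_locus_ids)``.
    """
    if len(stats.h) != gm.n_loci:
        raise ValueError("HDplot stats not aligned with genotype matrix")
    keep = (stats.h < h_max) & (np.abs(stats.d) < d_max)
    removed = gm.locus_ids[~keep]
    return gm.subset(locus_idx=keep), removed


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact HWE p-value for biallelic genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (same parity) whose conditional probability
    P(n_ab | n_a, n) = n! / (n_AA! n_ab! n_bb!) * 2^n_ab / C(2n, n_a)
    does not exceed that of the observed count.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_ab  # minor-or-major allele count; symmetric below
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = (
        gammaln(n + 1)
        - gammaln((rare - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln(n - (rare + hets) / 2 + 1)
        + hets * np.log(2.0)
        - (gammaln(2 * n + 1) - gammaln(rare + 1) - gammaln(2 * n - rare + 1))
    )
    probs = np.exp(logp)
    probs /= probs.sum()  # guard tiny numerical drift
    obs = probs[hets == n_ab][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def hwe_per_location(gm: GenotypeMatrix) -> pd.DataFrame:
    """Exact-test p-value per locus x location (p = 1 where monomorphic)."""
    pop_idx, locs = gm.location_indices()
    out = np.ones((gm.n_loci, len(locs)))
    for li, loc in enumerate(locs):
        sel = pop_idx == li
        calls = gm.calls[sel]
        n0 = (calls == 0).sum(axis=0)
        n1 = (calls == 1).sum(axis=0)
        n2 = (calls == 2).sum(axis=0)
        for j in range(gm.n_loci):
            tot = n0[j] + n1[j] + n2[j]
            if tot >= 1:
                out[j, li] = hwe_exact_test(int(n0[j]), int(n1[j]), int(n2[j]))
    return pd.DataFrame(out, index=gm.locus_ids, columns=locs)


def filter_hwe(
    gm: GenotypeMatrix,
    alpha: float = 0.05,
    min_deviating_locations: int = 3,
) -> GenotypeMatrix:
    """Remove loci out of HWE (p < alpha) in >= min_deviating_locations sites.

    Set ``min_deviating_locations`` to the number of locations to require
    deviation everywhere before removal.
    """
    p = hwe_per_location(gm).to_numpy()
    n_dev = (p < alpha).sum(axis=1)
    keep = n_dev < min_deviating_locations
    return gm.subset(locus_idx=keep)


# ----------------------------------------------------------------------
# One SNP per tag
# ----------------------------------------------------------------------

def select_one_snp_per_tag(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep the SNP with the highest multi-population theta per RAD tag.

    Ties (including all-NaN tags) break to the smallest position.
    """
    theta = theta_per_locus(gm)
    score = np.where(np.isfinite(theta), theta, -np.inf)
    order = pd.DataFrame(
        {"tag": gm.tags, "pos": gm.positions, "score": score, "idx": np.arange(gm.n_loci)}
    )
    # highest score wins; ties -> smallest position
    order = order.sort_values(["tag", "score", "pos"], ascending=[True, False, True])
    keep_idx = order.groupby("tag", sort=False).head(1)["idx"].to_numpy()
    keep_idx.sort()
    return gm.subset(locus_idx=keep_idx)


# ----------------------------------------------------------------------
# Cascade
# ----------------------------------------------------------------------

@dataclass
class FilterConfig:
    maf_initial: float = 0.05
    maf_strict: float = 0.1
    maf_rule: str = "any"
    call_rate_tiers: tuple[tuple[float, float], ...] = ((0.5, 0.5), (0.9, 0.9))
    hdplot_h_max: float = 0.6
    hdplot_d_max: float = 5.0
    hwe_alpha: float = 0.05
    hwe_min_deviating: int = 3
    one_snp_per_tag: bool = True


def run_filter_cascade(
    gm: GenotypeMatrix,
    depths: DepthTable | None,
    config: FilterConfig | None = None,
):
    """Run the full iterative cascade; returns (GenotypeMatrix, FilterReport).

    Steps follow the tiered design: initial MAF, 50% locus/sample call rate,
    90% locus/sample call rate, strict MAF, HDplot (skipped without depths),
    HWE, one SNP per tag.  The report row order mirrors that cascade.
    """
    cfg = config or FilterConfig()
    report = FilterReport()
    report.add("input", gm.n_samples, gm.n_loci)
    if gm.n_loci == 0 or gm.n_samples == 0:
        return gm, report

    def _track(name, new_gm):
        report.add(name, new_gm.n_samples, new_gm.n_loci)
        return new_gm

    def _subset_depths(old_gm, new_gm, dep):
        if dep is None:
            return None
        keep = set(new_gm.locus_ids)
        locus_idx = np.array([lid in keep for lid in old_gm.locus_ids])
        keep_s = set(new_gm.samples)
        sample_idx = np.array([s in keep_s for s in old_gm.samples])
        return dep.subset(sample_idx=sample_idx, locus_idx=locus_idx)

    prev = gm
    gm = _track(f"MAF >= {cfg.maf_initial}", filter_maf(gm, cfg.maf_initial, cfg.maf_rule))
    depths = _subset_depths(prev, gm, depths)

    for locus_min, sample_min in cfg.call_rate_tiers:
        before = gm
        gm_l, depths = filter_call_rate(gm, locus_min, 1e-12, depths)  # loci only
        report.add(f"call rate per locus >= {locus_min:.0%}", gm_l.n_samples, gm_l.n_loci)
        gm_s, depths = filter_call_rate(gm_l, 1e-12, sample_min, depths)  # samples only
        report.add(f"call rate per sample >= {sample_min:.0%}", gm_s.n_samples, gm_s.n_loci)
        gm = gm_s
        del before

    prev = gm
    gm = _track(f"MAF >= {cfg.maf_strict}", filter_maf(gm, cfg.maf_strict, cfg.maf_rule))
    depths = _subset_depths(prev, gm, depths)

    if depths is not None:
        stats = hdplot_stats(gm, depths)
        prev = gm
        filtered, _removed = filter_paralogs(gm, stats, cfg.hdplot_h_max, cfg.hdplot_d_max)
        gm = _track(
            f"HDplot singletons (H < {cfg.hdplot_h_max}, |D| < {cfg.hdplot_d_max})",
            filtered,
        )
        depths = _subset_depths(prev, gm, depths)
    else:
        report.add("HDplot (skipped: no depths)", gm.n_samples, gm.n_loci)

    gm = _track(
        f"HWE exact p >= {cfg.hwe_alpha} in > {cfg.hwe_min_deviating - 1} locations",
        filter_hwe(gm, cfg.hwe_alpha, cfg.hwe_min_deviating),
    )
    if cfg.one_snp_per_tag:
        gm = _track("one SNP per tag (highest FST)", select_one_snp_per_tag(gm))
    return gm, report
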