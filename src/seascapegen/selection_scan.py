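"""Outlier scans for putative adaptive loci and the consensus rule.

Two population-genetic-differentiation (PGD) scans and two genotype-
environment-association (GEA) scans represent their method classes:

* ``fsthet_scan`` — empirical FST-vs-heterozygosity quantile envelope.
* ``pca_outlier_scan`` — Mahalanobis distance of per-locus z-scores on the
  top principal components, with median-based genomic-inflation correction.
* ``gea_lfmm_lite`` — per-locus regression of genotype on one environmental
  variable with latent population structure absorbed by K genotype PCs.
* ``rda_scan`` — constrained ordination (redundancy analysis) of genotypes
  on all environmental variables; extreme axis loadings flag loci.

A locus becomes a consensus (putative adaptive) outlier when flagged
divergent by at least ``min_methods`` scans; loci flagged as balancing are
excluded from both the adaptive and the neutral set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io_core import MISSING, EnvTable, GenotypeMatrix
from .popgen_stats import theta_per_locus, wc_components

PGD_METHODS = ("fsthet", "pcadapt")
GEA_METHODS = ("lfmm", "rda")


@dataclass
class ScanResult:
    method: str
    table: pd.DataFrame  # index locus_id; columns stat, p, q, flag[, variable]

    @property
    def divergent(self) -> set[str]:
        return set(self.table.index[self.table["flag"] == "divergent"])

    @property
    def balancing(self) -> set[str]:
        return set(self.table.index[self.table["flag"] == "balancing"])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------

def _imputed_standardized(gm: GenotypeMatrix, scale: bool = True) -> np.ndarray:
    """Float genotypes, locus-mean imputed, centered (and scaled)."""
    g = gm.calls_float()
    mu = np.nanmean(g, axis=0)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(mu, inds[1])
    g = g - mu
    if scale:
        sd = g.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        g = g / sd
    return g


def _genotype_pcs(gm: GenotypeMatrix, k: int, seed: int | None = 0) -> np.ndarray:
    g = _imputed_standardized(gm)
    if not 1 <= k < min(gm.n_samples, gm.n_loci):
        raise ValueError(f"K={k} out of range for {gm.n_samples} x {gm.n_loci}")
    pca = PCA(n_components=k, svd_solver="full")
    return pca.fit_transform(g)


def genomic_inflation_factor(chisq: np.ndarray, df: int) -> float:
    """Median-based lambda: median observed chi-square / theoretical median."""
    return float(np.median(chisq) / sstats.chi2.ppf(0.5, df))


# ----------------------------------------------------------------------
# PGD scans
# ----------------------------------------------------------------------

def fsthet_scan(
    gm: GenotypeMatrix,
    n_bins: int = 25,
    quantile: float = 0.95,
    min_bin: int = 20,
) -> ScanResult:
    """Empirical FST-heterozygosity envelope outliers.

    Loci are binned by overall expected heterozygosity; within each bin the
    empirical (1-q)/2 and (1+q)/2 quantiles of theta form an envelope after a
    3-bin moving-average smoothing.  Loci above the upper bound are flagged
    divergent, below the lower bound balancing.  No p-values are produced —
    the envelope itself is the decision rule, as in quantile-based
    FST-heterozygosity scans.
    """
    theta = theta_per_locus(gm)
    pop_idx, locs = gm.location_indices()
    called = gm.called_mask()
    geno = np.where(called, gm.calls, 0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pbar = geno.sum(axis=0) / (2 * called.sum(axis=0))
    ht = 2 * pbar * (1 - pbar)

    ok = np.isfinite(theta) & np.isfinite(ht)
    edges = np.quantile(ht[ok], np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    bins = np.clip(np.searchsorted(edges, ht, side="right") - 1, 0, len(edges) - 2)

    # merge undersized bins with their left neighbour
    counts = np.bincount(bins[ok], minlength=len(edges) - 1)
    remap = np.arange(len(counts))
    for b in range(1, len(counts)):
        if counts[b] < min_bin:
            remap[b] = remap[b - 1]
            counts[remap[b]] += counts[b]
            counts[b] = 0
    if counts[0] < min_bin and len(counts) > 1:
        nxt = np.flatnonzero(counts > 0)
        if len(nxt) > 0 and nxt[0] != 0:
            remap[remap == 0] = nxt[0]
    bins = remap[bins]

    lo_q, hi_q = (1 - quantile) / 2, (1 + quantile) / 2
    uniq = np.unique(bins[ok])
    # smooth the envelope over 3 adjacent bins by pooling their loci before
    # taking the quantile: pooling keeps the per-bin exceedance pinned at the
    # nominal tail, where averaging three noisy quantiles would inflate it
    bound_lo, bound_hi = {}, {}
    for i, b in enumerate(uniq):
        window = uniq[max(0, i - 1) : i + 2]
        vals = theta[ok & np.isin(bins, window)]
        bound_lo[b] = np.quantile(vals, lo_q)
        bound_hi[b] = np.quantile(vals, hi_q)

    flag = np.array(["neutral"] * gm.n_loci, dtype=object)
    for j in range(gm.n_loci):
        if not ok[j]:
            continue
        b = bins[j]
        if theta[j] > bound_hi[b]:
            flag[j] = "divergent"
        elif theta[j] < bound_lo[b]:
            flag[j] = "balancing"
    table = pd.DataFrame(
        {"stat": theta, "het": ht, "p": np.nan, "q": np.nan, "flag": flag},
        index=gm.locus_ids,
    )
    return ScanResult(method="fsthet", table=table)


def pca_outlier_scan(gm: GenotypeMatrix, k: int, fdr: float = 0.05) -> ScanResult:
    """Mahalanobis outliers on per-locus PC regression z-scores.

    Each standardized locus is regressed on the top-K genotype PCs; the K
    coefficient z-scores per locus feed a Mahalanobis distance whose null is
    chi-square(K) after dividing by the median-based genomic inflation
    factor.  BH q < ``fdr`` flags a locus divergent.
    """
    g = _imputed_standardized(gm)
    pcs = _genotype_pcs(gm, k)
    n = gm.n_samples
    q_mat, _ = np.linalg.qr(pcs - pcs.mean(axis=0))  # orthonormal basis
    coef = q_mat.T @ g  # (k, L) projections
    resid = g - q_mat @ coef
    dof = n - k - 1
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2, 1e-300))
    z = coef / se  # coefficient z-scores in the orthonormal basis
    zc = z.T - z.T.mean(axis=0)
    cov = np.cov(zc, rowvar=False)
    cov = np.atleast_2d(cov)
    d2 = np.einsum("ij,jk,ik->i", zc, np.linalg.pinv(cov), zc)
    gif = genomic_inflation_factor(d2, k)
    p = sstats.chi2.sf(d2 / gif, k)
    q = bh_fdr(p)
    flag = np.where(q < fdr, "divergent", "neutral")
    table = pd.DataFrame(
        {"stat": d2, "p": p, "q": q, "flag": flag}, index=gm.locus_ids
    )
    table.attrs["gif"] = gif
    return ScanResult(method="pcadapt", table=table)


# ----------------------------------------------------------------------
# GEA scans
# ----------------------------------------------------------------------

def gea_lfmm_lite(
    gm: GenotypeMatrix,
    env: EnvTable,
    variable: str,
    k: int,
    summary: str = "mean",
    fdr: float = 0.05,
) -> ScanResult:
    """Latent-factor-corrected genotype~environment regression scan.

    Genotype (imputed dosage) is regressed on the individual-level
    environmental value plus K latent factors; the environment coefficient's
    z-score, genomic-inflation corrected, gives chi-square(1) p-values and
    BH q-values.  q < ``fdr`` associates the locus with the variable.

    The latent factors are the top-K PCs of the genotype matrix after
    regressing out the environmental variable.  Taking PCs of the raw
    genotypes instead would let the factors absorb the very gradient being
    tested (the environment is constant within demes, so it lies inside the
    structure subspace) and drive power to zero; residualizing first is the
    cheap analogue of the joint factor/effect estimation in latent-factor
    mixed models.
    """
    e = env.per_individual(gm, variable, summary)
    if np.allclose(e, e[0]):
        raise ValueError(f"environmental variable {variable!r} constant across demes")
    g = _imputed_standardized(gm, scale=False)
    n = gm.n_samples
    ez = (e - e.mean()) / e.std()
    if not 1 <= k < min(n, gm.n_loci):
        raise ValueError(f"K={k} out of range for {n} x {gm.n_loci}")
    env_design = np.column_stack([np.ones(n), ez])
    beta_env, *_ = np.linalg.lstsq(env_design, g, rcond=None)
    pca = PCA(n_components=k, svd_solver="full")
    pcs = pca.fit_transform(g - env_design @ beta_env)
    X = np.column_stack([np.ones(n), ez, pcs])
    beta, *_ = np.linalg.lstsq(X, g, rcond=None)
    resid = g - X @ beta
    dof = n - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    z = beta[1] / se
    chi = z**2
    gif = genomic_inflation_factor(chi, 1)
    p = sstats.chi2.sf(chi / gif, 1)
    q = bh_fdr(p)
    flag = np.where(q < fdr, "divergent", "neutral")
    table = pd.DataFrame(
        {"stat": z, "p": p, "q": q, "flag": flag, "variable": variable},
        index=gm.locus_ids,
    )
    table.attrs["gif"] = gif
    return ScanResult(method="lfmm", table=table)


def rda_scan(
    gm: GenotypeMatrix,
    env: EnvTable,
    loading_sd: float = 3.0,
    summary: str = "mean",
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int | None = 0,
    max_corr: float = 0.99,
) -> ScanResult:
    """Redundancy-analysis loading outliers across all environmental variables.

    Centers imputed genotypes, regresses them on the (z-scored, collinearity-
    pruned) environment matrix, and takes the SVD of the fitted values as the
    constrained axes.  Axis significance comes from permuting which location
    receives which environment row — the location is the exchangeable unit
    when the environment is measured per location, and free individual-level
    permutation would let residual drift structure masquerade as constrained
    variance.  On each significant axis, loci whose loading deviates from
    the loading mean by more than ``loading_sd`` standard deviations are
    flagged divergent and annotated with the environmental variable most
    correlated with their genotypes.
    """
    variables = list(env.variables)
    if len(variables) < 2:
        raise ValueError("RDA needs >= 2 environmental variables")
    pop_idx, locs = gm.location_indices()
    cols, kept = [], []
    for v in variables:
        vals = env.value(v, summary).loc[locs].to_numpy(float)
        if vals.std() == 0:
            continue
        z = (vals - vals.mean()) / vals.std()
        drop = any(abs(np.corrcoef(z, c)[0, 1]) > max_corr for c in cols)
        if drop:
            import warnings

            warnings.warn(f"dropping collinear environmental variable {v!r}")
            continue
        cols.append(z)
        kept.append(v)
    E = np.column_stack(cols)  # (n_locations, n_variables)
    X = E[pop_idx]
    g = _imputed_standardized(gm, scale=False)
    n, L = g.shape

    n_axes = E.shape[1]  # constrained rank; later SVD axes are numerical noise

    def _axis_var(Xm):
        beta, *_ = np.linalg.lstsq(Xm, g, rcond=None)
        fitted = Xm @ beta
        _, s, vt = np.linalg.svd(fitted, full_matrices=False)
        return (s**2)[:n_axes], vt[:n_axes]

    s2_obs, vt = _axis_var(X)
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_axes)
    for _ in range(n_perm):
        perm = rng.permutation(len(locs))  # shuffle env rows across locations
        s2_p, _ = _axis_var(E[perm][pop_idx])
        counts += s2_p >= s2_obs
    p_axis = (counts + 1) / (n_perm + 1)
    # sequential convention: once an axis fails, later (smaller) axes are
    # not interpreted either
    sig_axes = []
    for ax in range(n_axes):
        if p_axis[ax] < alpha:
            sig_axes.append(ax)
        else:
            break
    sig_axes = np.array(sig_axes, dtype=int)

    flag = np.array(["neutral"] * L, dtype=object)
    var_assign = np.array([""] * L, dtype=object)
    max_stat = np.zeros(L)
    for ax in sig_axes:
        load = vt[ax]
        zdev = np.abs(load - load.mean()) / load.std(ddof=0)
        max_stat = np.maximum(max_stat, zdev)
        flag[zdev > loading_sd] = "divergent"
    if len(sig_axes) > 0 and (flag == "divergent").any():
        idx = np.flatnonzero(flag == "divergent")
        for j in idx:
            cors = [abs(np.corrcoef(g[:, j], X[:, m])[0, 1]) for m in range(X.shape[1])]
            var_assign[j] = kept[int(np.argmax(cors))]
    table = pd.DataFrame(
        {"stat": max_stat, "p": np.nan, "q": np.nan, "flag": flag, "variable": var_assign},
        index=gm.locus_ids,
    )
    table.attrs["axis_p"] = p_axis.tolist()
    return ScanResult(method="rda", table=table)


# ----------------------------------------------------------------------
# Consensus
# ----------------------------------------------------------------------

@dataclass
class ConsensusSets:
    pgd_set: set[str]
    gea_set: set[str]
    shared_set: set[str]
    adaptive_set: set[str]
    neutral_set: set[str]
    balancing_set: set[str]
    per_method: dict[str, set[str]]
    per_variable: dict[str, set[str]]

    def intersection_counts(self) -> pd.DataFrame:
        """UpSet-style counts of loci per method-combination."""
        rows = {}
        methods = sorted(self.per_method)
        all_loci = set().union(*self.per_method.values()) if self.per_method else set()
        for locus in all_loci:
            key = tuple(m for m in methods if locus in self.per_method[m])
            rows[key] = rows.get(key, 0) + 1
        return pd.DataFrame(
            [{"methods": "+".join(k), "count": v} for k, v in sorted(rows.items())]
        )


def consensus_outliers(
    scan_results: list[ScanResult],
    min_methods: int = 2,
    mode: str = "union",
) -> ConsensusSets:
    """Combine scans into putative-adaptive consensus sets.

    ``mode="union"`` counts flagging methods across both approaches (a
    PGD+GEA pair qualifies at min_methods=2); ``mode="within"`` requires
    ``min_methods`` flags within the same approach class for membership in
    that class's set.  ``shared_set`` is always the PGD/GEA intersection of
    qualifying loci; balancing-flagged loci are excluded from both the
    adaptive and neutral sets.
    """
    if len(scan_results) < 2:
        raise ValueError("need at least two scan results")
    universes = [set(sr.table.index) for sr in scan_results]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("scan results cover different locus sets")
    if mode not in ("union", "within"):
        raise ValueError("mode must be 'union' or 'within'")
    all_loci = universes[0]

    per_method = {sr.method: sr.divergent for sr in scan_results}
    balancing = set().union(*(sr.balancing for sr in scan_results))
    counts: dict[str, int] = {}
    pgd_flags: dict[str, int] = {}
    gea_flags: dict[str, int] = {}
    for sr in scan_results:
        is_pgd = sr.method in PGD_METHODS
        for locus in sr.divergent:
            counts[locus] = counts.get(locus, 0) + 1
            if is_pgd:
                pgd_flags[locus] = pgd_flags.get(locus, 0) + 1
            else:
                gea_flags[locus] = gea_flags.get(locus, 0) + 1

    if mode == "union":
        qualifying = {l for l, c in counts.items() if c >= min_methods}
        pgd_set = {l for l in qualifying if pgd_flags.get(l, 0) >= 1}
        gea_set = {l for l in qualifying if gea_flags.get(l, 0) >= 1}
    else:
        pgd_set = {l for l, c in pgd_flags.items() if c >= min_methods}
        gea_set = {l for l, c in gea_flags.items() if c >= min_methods}
        qualifying = pgd_set | gea_set
    shared = pgd_set & gea_set
    adaptive = qualifying - balancing
    neutral = all_loci - qualifying - balancing

    per_variable: dict[str, set[str]] = {}
    for sr in scan_results:
        if "variable" not in sr.table.columns:
            continue
        sub = sr.table[sr.table["flag"] == "divergent"]
        for locus, var in sub["variable"].items():
            for v in str(var).split(","):  # loci may associate with several variables
                if v:
                    per_variable.setdefault(v, set()).add(locus)
    return ConsensusSets(
        pgd_set=pgd_set,
        gea_set=gea_set,
        shared_set=shared,
        adaptive_set=adaptive,
        neutral_set=neutral,
        balancing_set=balancing,
        per_method=per_method,
        per_variable=per_variable,
    )
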