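"""Diversity, Weir–Cockerham differentiation, and isolation by distance.

The differentiation estimator is the Weir & Cockerham (1984) theta, built
from the among-population (a), among-individual-within-population (b) and
within-individual (c) variance components.  Multi-locus estimates pool as a
ratio of sums, Sum(a) / Sum(a+b+c), never as a mean of per-locus ratios.
Missing genotypes are excluded pairwise per locus.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix


# ----------------------------------------------------------------------
# Weir-Cockerham variance components
# ----------------------------------------------------------------------

def wc_components(calls: np.ndarray, pop_idx: np.ndarray, n_pops: int):
    """Per-locus W&C variance components (a, b, c) for 0/1/2 genotype calls.

    Parameters
    ----------
    calls
        (n_samples, n_loci) alt-allele counts with :data:`MISSING` sentinel.
    pop_idx
        Per-sample integer population index in ``[0, n_pops)``.
    n_pops
        Number of populations.

    Returns
    -------
    (a, b, c) float arrays of length n_loci.  Loci observed in fewer than two
    populations, or where the mean sample size is 1, get NaN components.
    """
    calls = np.asarray(calls)
    called = calls != MISSING
    geno = np.where(called, calls, 0).astype(float)
    het = (calls == 1).astype(float)

    onehot = np.zeros((n_pops, calls.shape[0]))
    onehot[pop_idx, np.arange(calls.shape[0])] = 1.0

    n_il = onehot @ called  # (n_pops, n_loci) called individuals
    alt_il = onehot @ geno
    het_il = onehot @ het

    with np.errstate(divide="ignore", invalid="ignore"):
        p_il = alt_il / (2 * n_il)
        h_il = het_il / n_il

    present = n_il > 0
    r = present.sum(axis=0).astype(float)  # populations observed per locus
    n_sum = n_il.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = n_sum / r
        nc = (n_sum - (n_il**2).sum(axis=0) / n_sum) / (r - 1)
        pbar = alt_il.sum(axis=0) / (2 * n_sum)
        s2 = np.where(present, n_il * (np.nan_to_num(p_il) - pbar) ** 2, 0.0).sum(
            axis=0
        ) / ((r - 1) * nbar)
        hbar = het_il.sum(axis=0) / n_sum

        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2

    bad = (r < 2) | (nbar <= 1)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def theta_per_locus(gm: GenotypeMatrix) -> np.ndarray:
    """Per-locus theta-hat = a / (a + b + c); NaN where undefined."""
    pop_idx, locs = gm.location_indices()
    a, b, c = wc_components(gm.calls, pop_idx, len(locs))
    with np.errstate(divide="ignore", invalid="ignore"):
        return a / (a + b + c)


def pooled_theta(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Ratio-of-sums multi-locus theta over loci with finite components."""
    tot = a + b + c
    ok = np.isfinite(tot) & (tot != 0)
    denom = tot[ok].sum()
    if denom == 0 or not ok.any():
        return float("nan")
    return float(a[ok].sum() / denom)


# ----------------------------------------------------------------------
# Diversity
# ----------------------------------------------------------------------

@dataclass
class DiversityStats:
    """Per locus x location Ho / unbiased He / FIS plus dataset summaries."""

    ho: pd.DataFrame  # loci x locations
    he: pd.DataFrame
    fis: pd.DataFrame
    summary: pd.DataFrame  # rows Ho/He/FIS with mean and 95% CI half-width


def diversity(gm: GenotypeMatrix) -> DiversityStats:
    """Observed / unbiased expected heterozygosity and FIS per locus+location.

    He uses the small-sample correction ``2n/(2n-1) * 2p(1-p)`` with n the
    called individuals in the cell; FIS = 1 - Ho/He, undefined (NaN) where
    He = 0.  Dataset summaries are means over locus x location cells with a
    normal-approximation 95% CI.
    """
    pop_idx, locs = gm.location_indices()
    called = gm.called_mask()
    geno = np.where(called, gm.calls, 0).astype(float)
    het = (gm.calls == 1).astype(float)

    onehot = np.zeros((len(locs), gm.n_samples))
    onehot[pop_idx, np.arange(gm.n_samples)] = 1.0
    n_il = onehot @ called
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (onehot @ geno) / (2 * n_il)
        ho = (onehot @ het) / n_il
        he = (2 * n_il) / (2 * n_il - 1) * 2 * p * (1 - p)
        fis = 1 - ho / he
    he[n_il == 0] = np.nan
    ho[n_il == 0] = np.nan
    fis[~np.isfinite(fis)] = np.nan

    ids = gm.locus_ids
    frames = {
        "Ho": pd.DataFrame(ho.T, index=ids, columns=locs),
        "He": pd.DataFrame(he.T, index=ids, columns=locs),
        "FIS": pd.DataFrame(fis.T, index=ids, columns=locs),
    }
    rows = []
    for name, df in frames.items():
        vals = df.to_numpy().ravel()
        vals = vals[np.isfinite(vals)]
        mean = vals.mean() if len(vals) else np.nan
        half = 1.96 * vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else np.nan
        rows.append((name, mean, half))
    summary = pd.DataFrame(rows, columns=["statistic", "mean", "ci95_half"]).set_index(
        "statistic"
    )
    return DiversityStats(ho=frames["Ho"], he=frames["He"], fis=frames["FIS"], summary=summary)


# ----------------------------------------------------------------------
# Pairwise / global FST
# ----------------------------------------------------------------------

@dataclass
class FstResult:
    theta: float | None = None
    ci95: tuple[float, float] | None = None
    per_locus: np.ndarray | None = None
    pairwise: pd.DataFrame | None = None  # lower triangle theta, upper p
    pairwise_theta: pd.DataFrame | None = None
    pairwise_p: pd.DataFrame | None = None
    n_permutations: int = 0


def _pair_theta(calls: np.ndarray, labels: np.ndarray) -> float:
    a, b, c = wc_components(calls, labels, 2)
    return pooled_theta(a, b, c)


def pairwise_fst(
    gm: GenotypeMatrix, n_perm: int = 10000, seed: int | None = None
) -> FstResult:
    """Pairwise multi-locus theta with permutation p-values.

    p-value per pair = (#{permuted theta >= observed} + 1) / (n_perm + 1),
    permuting individuals between the two locations.
    """
    pop_idx, locs = gm.location_indices()
    if len(locs) < 2:
        raise ValueError("pairwise FST requires at least two locations")
    rng = np.random.default_rng(seed)
    k = len(locs)
    theta_m = pd.DataFrame(np.full((k, k), np.nan), index=locs, columns=locs)
    p_m = pd.DataFrame(np.full((k, k), np.nan), index=locs, columns=locs)
    for i, j in itertools.combinations(range(k), 2):
        sel = np.flatnonzero((pop_idx == i) | (pop_idx == j))
        calls = gm.calls[sel]
        labels = (pop_idx[sel] == j).astype(int)
        if np.bincount(labels, minlength=2).min() < 2:
            raise ValueError(f"location pair ({locs[i]}, {locs[j]}) has < 2 individuals")
        obs = _pair_theta(calls, labels)
        theta_m.iloc[j, i] = obs
        if n_perm > 0:
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(labels)
                if _pair_theta(calls, perm) >= obs:
                    count += 1
            p_m.iloc[i, j] = (count + 1) / (n_perm + 1)
    combined = theta_m.where(~theta_m.isna(), p_m)
    return FstResult(
        pairwise=combined,
        pairwise_theta=theta_m,
        pairwise_p=p_m,
        n_permutations=n_perm,
    )


def global_fst(gm: GenotypeMatrix, n_boot: int = 1000, seed: int | None = None) -> FstResult:
    """Pooled multi-population theta with a bootstrap-over-loci 95% CI."""
    pop_idx, locs = gm.location_indices()
    if len(locs) < 2:
        raise ValueError("global FST requires at least two locations")
    a, b, c = wc_components(gm.calls, pop_idx, len(locs))
    theta = pooled_theta(a, b, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_locus = a / (a + b + c)
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        tot = a + b + c
        ok = np.isfinite(tot) & (tot != 0)
        a_ok, tot_ok = a[ok], tot[ok]
        L = len(a_ok)
        boots = np.empty(n_boot)
        for m in range(n_boot):
            idx = rng.integers(0, L, size=L)
            boots[m] = a_ok[idx].sum() / tot_ok[idx].sum()
        ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
    return FstResult(theta=theta, ci95=ci, per_locus=per_locus)


# ----------------------------------------------------------------------
# Mantel isolation by distance
# ----------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    method: str = "permutation"


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def linearize_fst(fst: np.ndarray) -> np.ndarray:
    """Rousset linearization theta/(1-theta); errors on theta = 1."""
    fst = np.asarray(fst, dtype=float)
    if np.any(np.isclose(fst, 1.0)):
        raise ValueError(
            "theta = 1 entry: linearization theta/(1-theta) is infinite; "
            "remove fixed pairs or use raw distances"
        )
    return fst / (1 - fst)


def mantel_ibd(
    fst_matrix: np.ndarray,
    coords: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    linearize: bool = True,
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel correlation of linearized FST against Euclidean distance.

    One-sided (greater) permutation test with simultaneous row/column
    permutation of the geographic matrix; ``exhaustive=True`` enumerates all
    n! permutations (tiny n only) and reports p = #{r_perm >= r_obs} / n!.
    """
    fst_matrix = np.asarray(fst_matrix, dtype=float)
    n = fst_matrix.shape[0]
    if fst_matrix.shape != (n, n):
        raise ValueError("fst_matrix must be square")
    if not np.allclose(fst_matrix, fst_matrix.T, equal_nan=True):
        raise ValueError("fst_matrix must be symmetric")
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != n:
        raise ValueError("coords rows must match fst_matrix")
    if n < 4:
        raise ValueError("need >= 4 locations for a meaningful Mantel test")
    gen = linearize_fst(fst_matrix) if linearize else fst_matrix
    geo = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))

    x = _upper(gen)
    r_obs = _mantel_r(x, geo)
    if exhaustive:
        if n > 7:
            raise ValueError("exhaustive mode limited to n <= 7")
        perms = list(itertools.permutations(range(n)))
        count = sum(1 for p in perms if _mantel_r(x, geo[np.ix_(p, p)]) >= r_obs - 1e-12)
        return MantelResult(
            r=float(r_obs),
            p_value=count / len(perms),
            n_permutations=len(perms),
            method="exhaustive",
        )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if _mantel_r(x, geo[np.ix_(p, p)]) >= r_obs:
            count += 1
    return MantelResult(
        r=float(r_obs), p_value=(count + 1) / (n_perm + 1), n_permutations=n_perm
    )


def _mantel_r(x_upper: np.ndarray, mat_y: np.ndarray) -> float:
    y = _upper(mat_y)
    xc = x_upper - x_upper.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)
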