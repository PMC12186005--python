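"""Additive polygenic scores along environmental gradients.

For each adaptive locus the favored allele is oriented by the sign of the
OLS slope of genotype (0/1/2) on the environmental variable: a positive
slope scores the genotype as-is, a negative slope scores ``2 - genotype``.
The additive polygenic score (APS) of an individual is the sum of these
per-locus scores, so APS lies in [0, 2L] for L scored loci.  The
APS-environment relationship is then compared across null / linear /
quadratic OLS models by AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io_core import MISSING, EnvTable, GenotypeMatrix
from .selection_scan import ConsensusSets

#: Environmental (variable, summary) pairs scored by default: annual maximum
#: temperature and salinity plus annual minimum oxygen — the biologically
#: prioritized stressors for a eurythermal, euryhaline estuarine fish.
DEFAULT_APS_VARIABLES = (
    ("temperature", "max"),
    ("salinity", "max"),
    ("oxygen", "min"),
)


@dataclass
class Orientation:
    locus_ids: np.ndarray
    sign: np.ndarray  # +1 (score = g) or -1 (score = 2 - g)
    slope: np.ndarray


def favored_allele_orientation(
    gm: GenotypeMatrix,
    env: EnvTable,
    variable: str,
    loci: list[str],
    summary: str = "mean",
) -> Orientation:
    """Per-locus favored-allele orientation from the genotype~environment slope.

    Monomorphic loci are excluded with a warning; an exactly zero slope
    orients positive by convention.
    """
    e = env.per_individual(gm, variable, summary)
    sub = gm.subset_loci_by_id(loci)
    g = sub.calls_float()
    keep, signs, slopes = [], [], []
    ec = e - e.mean()
    for j, lid in enumerate(sub.locus_ids):
        gj = g[:, j]
        m = np.isfinite(gj)
        if len(np.unique(gj[m])) < 2:
            warnings.warn(f"monomorphic locus {lid} excluded from orientation")
            continue
        ej = e[m] - e[m].mean()
        denom = (ej**2).sum()
        slope = float((ej * (gj[m] - gj[m].mean())).sum() / denom) if denom > 0 else 0.0
        keep.append(lid)
        slopes.append(slope)
        signs.append(1 if slope >= 0 else -1)
    return Orientation(
        locus_ids=np.array(keep, dtype=object),
        sign=np.array(signs, dtype=int),
        slope=np.array(slopes, dtype=float),
    )


def compute_aps(
    gm: GenotypeMatrix,
    orientation: Orientation,
    missing: str = "expected",
) -> np.ndarray:
    """Per-individual APS = sum of oriented scores over the scored loci.

    ``missing="expected"`` replaces a missing genotype's contribution by the
    orientation-consistent expectation from its location's allele frequency
    (2*f for +, 2-2*f for -); ``missing="zero_locus"`` drops the
    contribution (scores the locus 0 for that individual).
    """
    sub = gm.subset_loci_by_id(list(orientation.locus_ids))
    order = {lid: i for i, lid in enumerate(sub.locus_ids)}
    col = np.array([order[lid] for lid in orientation.locus_ids])
    calls = sub.calls[:, col].astype(float)
    mask = calls == MISSING
    score = np.where(orientation.sign[None, :] > 0, calls, 2 - calls)
    if mask.any():
        if missing == "expected":
            pop_idx, locs = sub.location_indices()
            called = ~mask
            onehot = np.zeros((len(locs), sub.n_samples))
            onehot[pop_idx, np.arange(sub.n_samples)] = 1.0
            geno = np.where(called, calls, 0.0)
            n_il = onehot @ called
            with np.errstate(divide="ignore", invalid="ignore"):
                f = (onehot @ geno) / (2 * n_il)
            f = np.nan_to_num(f, nan=0.5)
            exp_g = 2 * f[pop_idx, :]  # per individual via its location
            exp_score = np.where(orientation.sign[None, :] > 0, exp_g, 2 - exp_g)
            score = np.where(mask, exp_score, score)
        elif missing == "zero_locus":
            score = np.where(mask, 0.0, score)
        else:
            raise ValueError("missing must be 'expected' or 'zero_locus'")
    return score.sum(axis=1)


@dataclass
class ModelFit:
    name: str
    aic: float
    r2: float
    p_value: float
    coef: np.ndarray
    degenerate: bool = False


def _gaussian_aic(rss: float, n: int, k: int) -> float:
    """AIC = 2k - 2 lnL with lnL = -n/2 (ln(2 pi RSS/n) + 1); k counts sigma."""
    if rss <= 0:
        rss = 1e-300
    loglik = -n / 2 * (np.log(2 * np.pi * rss / n) + 1)
    return 2 * k - 2 * loglik


def fit_aps_models(aps: np.ndarray, env_values: np.ndarray) -> dict[str, ModelFit]:
    """Compare null / linear / quadratic OLS models of APS on environment.

    Returns a dict with fits for the three models plus key ``"best"``
    (lowest AIC).  R^2 and the F-test p-value are relative to the null
    (intercept-only) model.
    """
    aps = np.asarray(aps, dtype=float)
    e = np.asarray(env_values, dtype=float)
    n = len(aps)
    if aps.std() == 0:
        null = ModelFit("null", _gaussian_aic(0.0, n, 2), 0.0, 1.0, np.array([aps[0]]))
        deg = ModelFit("linear", np.inf, 0.0, 1.0, np.zeros(2), degenerate=True)
        deg2 = ModelFit("quadratic", np.inf, 0.0, 1.0, np.zeros(3), degenerate=True)
        return {"null": null, "linear": deg, "quadratic": deg2, "best": null}
    if len(np.unique(e)) < 3:
        raise ValueError("need >= 3 distinct environmental values for the quadratic fit")

    designs = {
        "null": np.ones((n, 1)),
        "linear": np.column_stack([np.ones(n), e]),
        "quadratic": np.column_stack([np.ones(n), e, e**2]),
    }
    tss = ((aps - aps.mean()) ** 2).sum()
    fits: dict[str, ModelFit] = {}
    for name, X in designs.items():
        coef, *_ = np.linalg.lstsq(X, aps, rcond=None)
        rss = ((aps - X @ coef) ** 2).sum()
        k = X.shape[1] + 1  # slopes + intercept + residual variance
        aic = _gaussian_aic(rss, n, k)
        r2 = 1 - rss / tss
        if name == "null":
            p = 1.0
        else:
            df1 = X.shape[1] - 1
            df2 = n - X.shape[1]
            f = ((tss - rss) / df1) / (rss / df2) if rss > 0 else np.inf
            p = float(sstats.f.sf(f, df1, df2))
        fits[name] = ModelFit(name, aic, r2, p, coef)
    fits["best"] = min((fits[m] for m in designs), key=lambda f: f.aic)
    return fits


@dataclass
class APSResult:
    per_variable: dict[str, pd.DataFrame]  # individual APS + env value
    orientations: dict[str, Orientation]
    models: dict[str, dict[str, ModelFit]]
    direction: dict[str, int]  # sign of the best linear slope


def aps_pipeline(
    gm: GenotypeMatrix,
    env: EnvTable,
    consensus: ConsensusSets,
    variables=DEFAULT_APS_VARIABLES,
    locus_rule: str = "per_variable",
    missing: str = "expected",
) -> APSResult:
    """Score shared consensus loci against the prioritized variables.

    ``locus_rule="per_variable"`` scores, for each variable, the shared loci
    the GEA scans associated with that variable (falling back to all shared
    loci when no per-variable assignment exists); ``"all_shared"`` always
    scores the full shared set.
    """
    if not consensus.shared_set:
        raise ValueError("consensus shared_set is empty; nothing to score")
    per_variable, orients, models, direction = {}, {}, {}, {}
    for variable, summary in variables:
        e = env.per_individual(gm, variable, summary)
        if np.allclose(e, e[0]):
            raise ValueError(f"variable {variable!r} ({summary}) constant across demes")
        loci = sorted(consensus.shared_set)
        if locus_rule == "per_variable":
            assigned = consensus.per_variable.get(variable, set()) & consensus.shared_set
            if assigned:
                loci = sorted(assigned)
        elif locus_rule != "all_shared":
            raise ValueError("locus_rule must be 'per_variable' or 'all_shared'")
        orient = favored_allele_orientation(gm, env, variable, loci, summary)
        if len(orient.locus_ids) == 0:
            raise ValueError(f"no polymorphic loci to score for {variable!r}")
        aps = compute_aps(gm, orient, missing=missing)
        fits = fit_aps_models(aps, e)
        key = f"{variable}_{summary}"
        per_variable[key] = pd.DataFrame(
            {"aps": aps, "env": e, "location": list(gm.popmap.values)},
            index=gm.samples,
        )
        orients[key] = orient
        models[key] = fits
        lin = fits["linear"]
        direction[key] = int(np.sign(lin.coef[1])) if not lin.degenerate else 0
    return APSResult(
        per_variable=per_variable, orientations=orients, models=models, direction=direction
    )
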