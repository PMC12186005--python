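"""End-to-end orchestration: simulate -> filter -> popgen -> scan -> aps.

A single :class:`RunConfig` (serializable to/from YAML) plus its seed fully
determines every numeric output.  The master seed fans out to per-stage
child seeds through ``numpy.random.SeedSequence.spawn`` so stages can be
re-run in isolation and still reproduce the full run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import polygenic_scores, popgen_stats, qc_filtering, selection_scan
from .io_core import EnvTable, GenotypeMatrix
from .qc_filtering import FilterConfig
from .synthetic_data import SimulationParams, simulate_dataset, generate_dataset


@dataclass
class RunConfig:
    sim: SimulationParams = field(default_factory=SimulationParams)
    filter: FilterConfig = field(default_factory=FilterConfig)
    scan_k: int = 2
    scan_fdr: float = 0.05
    gea_summary: str = "mean"
    consensus_min_methods: int = 2
    consensus_mode: str = "union"
    fst_permutations: int = 199
    fst_bootstrap: int = 200
    mantel_permutations: int = 999
    aps_variables: tuple = polygenic_scores.DEFAULT_APS_VARIABLES
    aps_locus_rule: str = "per_variable"
    run_scans: bool = True
    run_popgen: bool = True
    run_aps: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["aps_variables"] = [list(v) for v in self.aps_variables]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimulationParams(**d["sim"])
        if "filter" in d:
            fc = d["filter"]
            if isinstance(fc, dict):
                if "call_rate_tiers" in fc:
                    fc["call_rate_tiers"] = tuple(tuple(t) for t in fc["call_rate_tiers"])
                d["filter"] = FilterConfig(**fc)
        if "aps_variables" in d:
            d["aps_variables"] = tuple(tuple(v) for v in d["aps_variables"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in children]


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the full pipeline into ``outdir``; returns the run directory.

    Writes: simulated inputs, filter report, diversity/FST/Mantel tables,
    per-method scan tables, consensus sets, APS tables and model comparison,
    and a manifest with the config hash and SHA-256 of every artifact.
    Re-running with the same config reproduces every file byte-for-byte.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {"config_hash": config.config_hash(), "stages": {}}

    sim_params = dataclasses.replace(config.sim, seed=seeds[0])
    ds = simulate_dataset(sim_params)
    generate_dataset(sim_params, out / "input")
    manifest["stages"]["simulate"] = {
        "seed": seeds[0],
        "n_samples": ds.gm.n_samples,
        "n_loci": ds.gm.n_loci,
    }

    try:
        gm, report = qc_filtering.run_filter_cascade(ds.gm, ds.depths, config.filter)
    except Exception as err:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"stage 'filter' failed: {err}") from err
    report.to_tsv(out / "filter_report.tsv")
    report.to_json(out / "filter_report.json")
    manifest["stages"]["filter"] = {
        "n_samples": gm.n_samples,
        "n_loci": gm.n_loci,
        "steps": report.steps,
    }

    consensus = None
    if config.run_scans:
        try:
            scans = [
                selection_scan.fsthet_scan(gm),
                selection_scan.pca_outlier_scan(gm, k=config.scan_k, fdr=config.scan_fdr),
                selection_scan.rda_scan(
                    gm, ds.env, summary=config.gea_summary, seed=seeds[2]
                ),
            ]
            for var in ds.env.variables:
                scans.append(
                    selection_scan.gea_lfmm_lite(
                        gm, ds.env, var, k=config.scan_k,
                        summary=config.gea_summary, fdr=config.scan_fdr,
                    )
                )
        except Exception as err:
            raise RuntimeError(f"stage 'scan' failed: {err}") from err
        # merge the per-variable LFMM scans into one method-level result
        lfmm_tables = [s.table for s in scans if s.method == "lfmm"]
        merged = _merge_lfmm(lfmm_tables)
        scans = [s for s in scans if s.method != "lfmm"] + [merged]
        for sr in scans:
            sr.table.to_csv(out / f"scan_{sr.method}.tsv", sep="\t")
        consensus = selection_scan.consensus_outliers(
            scans, min_methods=config.consensus_min_methods, mode=config.consensus_mode
        )
        _write_sets(consensus, out / "consensus_sets.tsv")
        consensus.intersection_counts().to_csv(
            out / "consensus_intersections.tsv", sep="\t", index=False
        )
        manifest["stages"]["scan"] = {
            "seed": seeds[2],
            "pgd": len(consensus.pgd_set),
            "gea": len(consensus.gea_set),
            "shared": len(consensus.shared_set),
        }

    if config.run_popgen:
        try:
            div = popgen_stats.diversity(gm)
            div.summary.to_csv(out / "diversity_summary.tsv", sep="\t")
            fst = popgen_stats.pairwise_fst(
                gm, n_perm=config.fst_permutations, seed=seeds[1]
            )
            fst.pairwise.to_csv(out / "pairwise_fst.tsv", sep="\t", float_format="%.6g")
            glob = popgen_stats.global_fst(gm, n_boot=config.fst_bootstrap, seed=seeds[1])
            theta_lower = np.nan_to_num(fst.pairwise_theta.to_numpy())
            mantel = popgen_stats.mantel_ibd(
                theta_lower + theta_lower.T,
                ds.env.coords(),
                n_perm=config.mantel_permutations,
                seed=seeds[3],
            )
            (out / "popgen.json").write_text(
                json.dumps(
                    {
                        "global_fst": glob.theta,
                        "global_fst_ci95": glob.ci95,
                        "mantel_r": mantel.r,
                        "mantel_p": mantel.p_value,
                        "mantel_permutations": mantel.n_permutations,
                    },
                    indent=2,
                )
                + "\n"
            )
        except Exception as err:
            raise RuntimeError(f"stage 'popgen' failed: {err}") from err
        manifest["stages"]["popgen"] = {
            "seed": seeds[1],
            "global_fst": glob.theta,
            "mantel_r": mantel.r,
        }

    if config.run_aps:
        if consensus is None or not consensus.shared_set:
            raise RuntimeError(
                "stage 'aps' failed: no consensus set (scans disabled or empty)"
            )
        try:
            aps = polygenic_scores.aps_pipeline(
                gm, ds.env, consensus,
                variables=config.aps_variables,
                locus_rule=config.aps_locus_rule,
            )
        except Exception as err:
            raise RuntimeError(f"stage 'aps' failed: {err}") from err
        model_json = {}
        for key, df in aps.per_variable.items():
            df.to_csv(out / f"aps_{key}.tsv", sep="\t", float_format="%.6g")
            fits = aps.models[key]
            model_json[key] = {
                name: {
                    "aic": round(fits[name].aic, 6),
                    "r2": round(fits[name].r2, 6),
                    "p": fits[name].p_value,
                }
                for name in ("null", "linear", "quadratic")
            }
            model_json[key]["best"] = fits["best"].name
            model_json[key]["direction"] = aps.direction[key]
        (out / "aps_models.json").write_text(json.dumps(model_json, indent=2) + "\n")
        manifest["stages"]["aps"] = {
            k: model_json[k]["best"] for k in model_json
        }

    manifest["artifacts"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _merge_lfmm(tables: list[pd.DataFrame]):
    """Combine per-variable LFMM scans: a locus is divergent if any variable
    flags it; it keeps the variable of its smallest q-value."""
    from .selection_scan import ScanResult

    idx = tables[0].index
    q = np.column_stack([t["q"].to_numpy() for t in tables])
    p = np.column_stack([t["p"].to_numpy() for t in tables])
    z = np.column_stack([t["stat"].to_numpy() for t in tables])
    variables = [t["variable"].iloc[0] for t in tables]
    best = np.argmin(q, axis=1)
    rows = np.arange(len(idx))
    div = np.array([t["flag"].to_numpy() == "divergent" for t in tables])  # (V, L)
    flag = np.where(div.any(axis=0), "divergent", "neutral")
    # a locus may associate with several variables; keep all flagged ones
    var_col = [
        ",".join(variables[v] for v in np.flatnonzero(div[:, j])) or variables[best[j]]
        for j in rows
    ]
    merged = pd.DataFrame(
        {
            "stat": z[rows, best],
            "p": p[rows, best],
            "q": q[rows, best],
            "flag": flag,
            "variable": var_col,
        },
        index=idx,
    )
    return ScanResult(method="lfmm", table=merged)


def _write_sets(consensus, path) -> None:
    rows = []
    for name in ("pgd_set", "gea_set", "shared_set", "adaptive_set", "neutral_set", "balancing_set"):
        for locus in sorted(getattr(consensus, name)):
            rows.append((name.removesuffix("_set"), locus))
    pd.DataFrame(rows, columns=["set", "locus"]).to_csv(path, sep="\t", index=False)
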