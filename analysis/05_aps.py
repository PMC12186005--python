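#!/usr/bin/env python
"""Additive polygenic scores along the prioritized environmental gradients.

For maximum temperature, maximum salinity, and minimum oxygen, orients each
shared consensus locus by the sign of its genotype-on-environment slope,
sums favored-allele counts per individual, and compares null / linear /
quadratic models of APS on the environment by AIC.
"""

import json
from pathlib import Path

import pandas as pd

from seascapegen.io_core import read_env_table, read_vcf
from seascapegen.pipeline import _merge_lfmm
from seascapegen.polygenic_scores import aps_pipeline
from seascapegen.selection_scan import (
    consensus_outliers,
    fsthet_scan,
    gea_lfmm_lite,
    pca_outlier_scan,
    rda_scan,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    gm, _ = read_vcf(OUT / "filtered.vcf", OUT / "input" / "popmap.tsv")
    env = read_env_table(OUT / "input" / "environment.csv")
    # rebuild the consensus object (sets on disk lack per-variable detail)
    scans = [fsthet_scan(gm), pca_outlier_scan(gm, k=2), rda_scan(gm, env, seed=1)]
    lfmm = [gea_lfmm_lite(gm, env, v, k=2) for v in env.variables]
    scans.append(_merge_lfmm([s.table for s in lfmm]))
    cons = consensus_outliers(scans)

    res = aps_pipeline(gm, env, cons)
    out = {}
    for key, fits in res.models.items():
        res.per_variable[key].to_csv(OUT / f"aps_{key}.tsv", sep="\t", float_format="%.6g")
        out[key] = {
            m: {"aic": round(fits[m].aic, 2), "r2": round(fits[m].r2, 4)}
            for m in ("null", "linear", "quadratic")
        }
        out[key]["best"] = fits["best"].name
        n_loci = len(res.orientations[key].locus_ids)
        print(
            f"{key:18s} loci={n_loci:3d}  best={fits['best'].name:9s} "
            f"linear R2={fits['linear'].r2:.3f} (AIC {fits['linear'].aic:.1f} "
            f"vs null {fits['null'].aic:.1f})"
        )
    (OUT / "aps_models.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
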