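#!/usr/bin/env python
"""Detect putative adaptive loci and build the PGD/GEA consensus sets.

Runs two population-genetic-differentiation scans (FST-heterozygosity
quantile envelope; PCA/Mahalanobis with genomic-inflation correction) and
two genotype-environment-association scans (latent-factor-corrected
regression per variable; redundancy-analysis loadings), then intersects:
a locus flagged divergent by at least two methods is a consensus outlier,
and the shared set is the PGD/GEA intersection.  Scores recovery against
the simulation truth and writes per-method tables plus the consensus sets.
"""

from pathlib import Path

import pandas as pd

from seascapegen.io_core import read_env_table, read_vcf
from seascapegen.pipeline import _merge_lfmm, _write_sets
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
    truth = pd.read_csv(OUT / "input" / "truth.tsv", sep="\t", index_col="locus")

    scans = [
        fsthet_scan(gm),
        pca_outlier_scan(gm, k=2),
        rda_scan(gm, env, seed=1),
    ]
    lfmm = [gea_lfmm_lite(gm, env, v, k=2) for v in env.variables]
    scans.append(_merge_lfmm([s.table for s in lfmm]))
    for sr in scans:
        sr.table.to_csv(OUT / f"scan_{sr.method}.tsv", sep="\t")
        n_div = len(sr.divergent)
        n_bal = len(sr.balancing)
        print(f"{sr.method:8s} divergent={n_div:4d}  balancing={n_bal:4d}")

    cons = consensus_outliers(scans)
    _write_sets(cons, OUT / "consensus_sets.tsv")
    cons.intersection_counts().to_csv(
        OUT / "consensus_intersections.tsv", sep="\t", index=False
    )
    print(
        f"\nconsensus: PGD={len(cons.pgd_set)}  GEA={len(cons.gea_set)}  "
        f"shared={len(cons.shared_set)}"
    )
    truth_ad = set(truth.index[truth["class"] == "adaptive"]) & set(gm.locus_ids)
    recall = len(cons.adaptive_set & truth_ad) / max(len(truth_ad), 1)
    fdp = len(cons.adaptive_set - truth_ad) / max(len(cons.adaptive_set), 1)
    print(f"recovery vs truth: recall={recall:.0%}  false-discovery={fdp:.1%}")


if __name__ == "__main__":
    main()
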