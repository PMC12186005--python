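"""Shared data model and file I/O for the pipeline.

Genotypes are coded as counts of the alternate allele (0/1/2) with a
dedicated sentinel for missing calls.  Loci are RAD-tag SNPs identified by a
(tag, position) pair; the locus identifier string is ``"<tag>_<pos>"`` with
the 1-based VCF position kept verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Dedicated code for an uncalled genotype.  Never used in arithmetic; always
#: compare against this constant (or use :meth:`GenotypeMatrix.called_mask`).
MISSING: int = -9

ENV_VARIABLES = ("temperature", "salinity", "oxygen", "nitrate", "phosphate", "silicate")
ENV_SUMMARIES = ("mean", "min", "max", "range")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be converted to the data model."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of alternate-allele counts with a popmap.

    Parameters
    ----------
    samples
        Ordered sample identifiers (rows).
    tags, positions
        Per-locus RAD-tag identifier and 1-based SNP position within the tag
        (columns); ``(tag, position)`` pairs must be unique.
    calls
        ``(n_samples, n_loci)`` int array with entries in {0, 1, 2, MISSING}.
    popmap
        Mapping sample -> sampling-location label covering every sample.
    """

    samples: list[str]
    tags: np.ndarray
    positions: np.ndarray
    calls: np.ndarray
    popmap: pd.Series

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.tags = np.asarray(self.tags)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.tags)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.tags)} loci"
            )
        if self.tags.shape != self.positions.shape:
            raise ValueError("tags and positions must align")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"calls contain invalid codes: {np.unique(self.calls[bad])}")
        if not isinstance(self.popmap, pd.Series):
            self.popmap = pd.Series(dict(self.popmap))
        missing_samples = [s for s in self.samples if s not in self.popmap.index]
        if missing_samples:
            raise ValueError(f"samples absent from popmap: {missing_samples[:5]}")
        self.popmap = self.popmap.loc[self.samples]
        pairs = list(zip(self.tags.tolist(), self.positions.tolist()))
        if len(set(pairs)) != len(pairs):
            raise ValueError("(tag, position) pairs must be unique")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.tags)

    @property
    def locus_ids(self) -> np.ndarray:
        return np.array([f"{t}_{p}" for t, p in zip(self.tags, self.positions)])

    @property
    def locations(self) -> list[str]:
        """Location labels in order of first appearance in the popmap."""
        return list(dict.fromkeys(self.popmap.values))

    def location_indices(self) -> tuple[np.ndarray, list[str]]:
        """Per-sample integer location index and the location label list."""
        locs = self.locations
        lut = {l: i for i, l in enumerate(locs)}
        return np.array([lut[self.popmap[s]] for s in self.samples]), locs

    def called_mask(self) -> np.ndarray:
        return self.calls != MISSING

    def calls_float(self) -> np.ndarray:
        """Calls as float with NaN at missing entries (for numeric work)."""
        out = self.calls.astype(float)
        out[self.calls == MISSING] = np.nan
        return out

    # -- subsetting -----------------------------------------------------
    def subset(self, sample_idx=None, locus_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if li.dtype == bool:
            li = np.flatnonzero(li)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            tags=self.tags[li],
            positions=self.positions[li],
            calls=self.calls[np.ix_(si, li)],
            popmap=self.popmap.iloc[si],
        )

    def subset_loci_by_id(self, locus_ids) -> "GenotypeMatrix":
        wanted = set(locus_ids)
        idx = [i for i, lid in enumerate(self.locus_ids) if lid in wanted]
        return self.subset(locus_idx=np.array(idx, dtype=int))


@dataclass
class DepthTable:
    """Allele-specific read depths aligned 1:1 with a GenotypeMatrix."""

    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=np.int32)
        self.alt = np.asarray(self.alt, dtype=np.int32)
        if self.ref.shape != self.alt.shape:
            raise ValueError("ref and alt depth arrays must have the same shape")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("depths must be non-negative")

    def subset(self, sample_idx=None, locus_idx=None) -> "DepthTable":
        si = slice(None) if sample_idx is None else np.asarray(sample_idx)
        li = slice(None) if locus_idx is None else np.asarray(locus_idx)
        if isinstance(si, np.ndarray) and si.dtype == bool:
            si = np.flatnonzero(si)
        if isinstance(li, np.ndarray) and li.dtype == bool:
            li = np.flatnonzero(li)
        if isinstance(si, slice) and isinstance(li, slice):
            return DepthTable(self.ref.copy(), self.alt.copy())
        if isinstance(si, slice):
            return DepthTable(self.ref[:, li], self.alt[:, li])
        if isinstance(li, slice):
            return DepthTable(self.ref[si, :], self.alt[si, :])
        return DepthTable(self.ref[np.ix_(si, li)], self.alt[np.ix_(si, li)])


class EnvTable:
    """Per-location environmental summaries plus coordinates.

    Wraps a DataFrame indexed by location with columns ``latitude``,
    ``longitude`` and ``<variable>_<summary>`` for each variable in
    :data:`ENV_VARIABLES` (or a user subset) and each summary in
    :data:`ENV_SUMMARIES`.  Validates min <= mean <= max and recomputes the
    range column as max - min when absent.
    """

    def __init__(self, df: pd.DataFrame, variables=None):
        df = df.copy()
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicated locations: {dupes}")
        for col in ("latitude", "longitude"):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        if variables is None:
            variables = [v for v in ENV_VARIABLES if f"{v}_mean" in df.columns]
            if not variables:
                # accept arbitrary variable names ending in _mean
                variables = sorted(
                    c[: -len("_mean")] for c in df.columns if c.endswith("_mean")
                )
        self.variables = list(variables)
        for v in self.variables:
            for s in ("mean", "min", "max"):
                if f"{v}_{s}" not in df.columns:
                    raise ValueError(f"missing required column {v}_{s}")
            rng = df[f"{v}_max"] - df[f"{v}_min"]
            if f"{v}_range" not in df.columns:
                df[f"{v}_range"] = rng
            elif not np.allclose(df[f"{v}_range"], rng, atol=1e-6):
                raise ValueError(f"{v}_range inconsistent with max - min")
            if (df[f"{v}_min"] - df[f"{v}_mean"] > 1e-9).any() or (
                df[f"{v}_mean"] - df[f"{v}_max"] > 1e-9
            ).any():
                raise ValueError(f"min <= mean <= max violated for {v}")
        self.df = df

    @property
    def locations(self) -> list[str]:
        return list(self.df.index)

    def value(self, variable: str, summary: str = "mean") -> pd.Series:
        col = f"{variable}_{summary}"
        if col not in self.df.columns:
            raise KeyError(col)
        return self.df[col]

    def coords(self) -> np.ndarray:
        return self.df[["latitude", "longitude"]].to_numpy(float)

    def per_individual(self, gm: GenotypeMatrix, variable: str, summary: str = "mean") -> np.ndarray:
        """Assign each individual its location's environmental value."""
        vals = self.value(variable, summary)
        return np.array([vals[gm.popmap[s]] for s in gm.samples], dtype=float)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index_label="location", float_format="%.6g")

    @classmethod
    def from_csv(cls, path) -> "EnvTable":
        return cls(pd.read_csv(path, index_col="location"))


@dataclass
class FilterReport:
    """Ordered record of (step, samples retained, loci retained)."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_samples: int, n_loci: int) -> None:
        if self.steps:
            _, s_prev, l_prev = self.steps[-1]
            if n_samples > s_prev or n_loci > l_prev:
                raise ValueError(
                    f"filter cascade must be non-increasing at step {name!r}"
                )
        self.steps.append((name, int(n_samples), int(n_loci)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "samples", "loci"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                [{"step": s, "samples": n, "loci": m} for s, n, m in self.steps],
                indent=2,
            )
            + "\n"
        )


# ----------------------------------------------------------------------
# VCF / popmap I/O
# ----------------------------------------------------------------------

def read_popmap(path) -> pd.Series:
    """Read a two-column (sample, location) whitespace/tab-delimited popmap."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["sample", "location"], dtype=str)
    if df["sample"].duplicated().any():
        raise ValueError("popmap contains duplicated samples")
    return df.set_index("sample")["location"]


def read_vcf(path, popmap_path, multiallelic: str = "reject", unmapped: str = "drop"):
    """Read a biallelic-SNP VCF plus popmap into the data model.

    Returns ``(GenotypeMatrix, DepthTable | None)``; the depth table is
    present when the VCF carries AD fields.

    Parameters
    ----------
    multiallelic
        ``"reject"`` raises on any record with more than one ALT allele;
        ``"drop"`` silently skips such records.
    unmapped
        ``"drop"`` removes VCF samples absent from the popmap; ``"error"``
        raises instead.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("reject", "drop"):
        raise ValueError("multiallelic must be 'reject' or 'drop'")
    popmap = read_popmap(popmap_path)
    vcf = VCF(str(path))
    header_has_ad = "ID=AD" in vcf.raw_header
    vcf_samples = list(vcf.samples)
    keep = [i for i, s in enumerate(vcf_samples) if s in popmap.index]
    if len(keep) < len(vcf_samples) and unmapped == "error":
        extra = sorted(set(vcf_samples) - set(popmap.index))
        raise ValueError(f"VCF samples absent from popmap: {extra[:5]}")
    samples = [vcf_samples[i] for i in keep]

    tags, positions = [], []
    call_rows, ref_rows, alt_rows = [], [], []
    has_ad = False
    for v in vcf:
        if len(v.ALT) != 1:
            if multiallelic == "reject":
                raise VcfParseError(
                    f"multi-allelic record at {v.CHROM}:{v.POS} (ALT={v.ALT})"
                )
            continue
        tags.append(v.CHROM)
        positions.append(v.POS)
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(v.gt_types)[keep]
        row = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        call_rows.append(row.astype(np.int8))
        ad = v.format("AD") if header_has_ad else None
        if ad is not None:
            has_ad = True
            ad = np.asarray(ad)[keep]
            ref_rows.append(np.where(ad[:, 0] < 0, 0, ad[:, 0]))
            alt_rows.append(np.where(ad[:, 1] < 0, 0, ad[:, 1]))
        else:
            ref_rows.append(np.zeros(len(keep), dtype=np.int32))
            alt_rows.append(np.zeros(len(keep), dtype=np.int32))

    calls = (
        np.column_stack(call_rows) if call_rows else np.zeros((len(samples), 0), np.int8)
    )
    gm = GenotypeMatrix(
        samples=samples,
        tags=np.array(tags, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        calls=calls,
        popmap=popmap,
    )
    depths = None
    if has_ad:
        depths = DepthTable(
            ref=np.column_stack(ref_rows) if ref_rows else np.zeros_like(calls, np.int32),
            alt=np.column_stack(alt_rows) if alt_rows else np.zeros_like(calls, np.int32),
        )
    return gm, depths


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, depths: DepthTable | None = None) -> None:
    """Write a VCFv4.2 file; byte-stable (no run-dependent header lines)."""
    lines = ["##fileformat=VCFv4.2", '##source=seascapegen']
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if depths is not None:
        lines.append(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
        )
    for tag in dict.fromkeys(gm.tags.tolist()):
        lines.append(f"##contig=<ID={tag}>")
    header = [
        "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
    ] + gm.samples
    lines.append("\t".join(header))
    fmt = "GT:AD" if depths is not None else "GT"
    for j in range(gm.n_loci):
        fields = [
            str(gm.tags[j]),
            str(gm.positions[j]),
            f"{gm.tags[j]}_{gm.positions[j]}",
            "A",
            "T",
            ".",
            "PASS",
            ".",
            fmt,
        ]
        for i in range(gm.n_samples):
            g = _GT_STR[int(gm.calls[i, j])]
            if depths is not None:
                g = f"{g}:{depths.ref[i, j]},{depths.alt[i, j]}"
            fields.append(g)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def write_popmap(popmap: pd.Series, path) -> None:
    with open(path, "w") as fh:
        for sample, loc in popmap.items():
            fh.write(f"{sample}\t{loc}\n")


def read_env_table(path) -> EnvTable:
    return EnvTable.from_csv(path)
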