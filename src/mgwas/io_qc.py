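"""Genotype and abundance containers, standard-format I/O, and QC filters.

Genotypes are held as a samples x variants ALT-dosage matrix (``np.nan`` for
missing calls) with per-variant metadata (position, alleles, MAF, exact-test
HWE p, call rate).  Microbial features are held as a samples x features
relative-abundance table.  QC mirrors common GWAS practice: variants are kept
when MAF >= 1%, HWE exact p > 1e-6 and call rate > 98%; microbial features are
kept when prevalence and mean relative abundance strictly exceed 10% and 1e-4.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]
STAT_COLUMNS = ["maf", "hwe_p", "call_rate"]


@dataclasses.dataclass
class GenotypeMatrix:
    """Samples x variants ALT-allele dosage matrix with variant metadata.

    ``dosages[i, j]`` counts ALT alleles of variant ``j`` in sample ``i``
    (0/1/2 for hard calls, fractional for DS dosages, ``np.nan`` if missing).
    ``variants`` has one row per variant with columns chrom/pos/id/ref/alt and,
    once :meth:`compute_stats` has run, maf/hwe_p/call_rate.
    """

    samples: list
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def compute_stats(self) -> "GenotypeMatrix":
        """Populate maf / hwe_p / call_rate columns in ``variants`` (in place)."""
        d = self.dosages
        n = self.n_samples
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            called = ~np.isnan(d)
            n_called = called.sum(axis=0)
            alt_freq = np.nanmean(d, axis=0) / 2.0
        alt_freq = np.where(n_called > 0, alt_freq, np.nan)
        maf = np.minimum(alt_freq, 1.0 - alt_freq)
        hwe = np.ones(self.n_variants)
        hard = np.round(d)
        for j in range(self.n_variants):
            col = hard[called[:, j], j]
            if col.size == 0:
                hwe[j] = np.nan
                continue
            n_aa = int((col == 0).sum())
            n_het = int((col == 1).sum())
            n_bb = int((col == 2).sum())
            if n_aa + n_het + n_bb == 0:  # fractional dosages only
                hwe[j] = np.nan
            else:
                hwe[j] = hwe_exact_test(n_aa, n_het, n_bb)
        self.variants["maf"] = maf
        self.variants["hwe_p"] = hwe
        self.variants["call_rate"] = n_called / n
        return self

    def imputed(self) -> "GenotypeMatrix":
        """Return a copy with missing dosages mean-imputed per variant."""
        d = self.dosages.copy()
        if np.isnan(d).any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                col_mean = np.nanmean(d, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(d))
            d[idx] = col_mean[idx[1]]
        return GenotypeMatrix(list(self.samples), self.variants.copy(), d)

    def subset_variants(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.where(mask)[0]
        else:
            idx = mask
        return GenotypeMatrix(
            list(self.samples),
            self.variants.iloc[idx].reset_index(drop=True),
            self.dosages[:, idx],
        )

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.samples, columns=self.variants["id"]
        )


@dataclasses.dataclass
class AbundanceTable:
    """Samples x features relative-abundance table (fractions, rows sum <= 1)."""

    values: pd.DataFrame

    def __post_init__(self):
        if (self.values.values < -1e-12).any():
            raise ValueError("abundances must be non-negative")

    @property
    def samples(self) -> list:
        return list(self.values.index)

    @property
    def features(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def prevalence(self) -> pd.Series:
        """Per-feature fraction of samples with a strictly positive value."""
        return (self.values > 0).mean(axis=0)

    @property
    def mean_abundance(self) -> pd.Series:
        return self.values.mean(axis=0)

    def subset_features(self, names) -> "AbundanceTable":
        return AbundanceTable(self.values.loc[:, list(names)])


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed count (no mid-p adjustment).  Returns a value in (0, 1].
    """
    counts = (n_hom1, n_het, n_hom2)
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative, got {counts}")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_hom1 + n_het
    rare = min(n_a, 2 * n - n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # conditional P(het | n, rare) = n! / (hr! het! hc!) * 2^het * rare! common! / (2n)!
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


def variant_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_min: float = 1e-6,
    call_rate_min: float = 0.98,
) -> tuple[GenotypeMatrix, dict]:
    """Keep variants with MAF >= maf_min, HWE p > hwe_min, call rate > call_rate_min.

    Returns the filtered matrix and a per-filter removal report.
    """
    if not set(STAT_COLUMNS) <= set(g.variants.columns):
        g.compute_stats()
    v = g.variants
    pass_maf = v["maf"].to_numpy() >= maf_min
    pass_hwe = v["hwe_p"].to_numpy() > hwe_min
    pass_cr = v["call_rate"].to_numpy() > call_rate_min
    keep = pass_maf & pass_hwe & pass_cr
    report = {
        "n_in": g.n_variants,
        "fail_maf": int((~pass_maf).sum()),
        "fail_hwe": int((~pass_hwe).sum()),
        "fail_call_rate": int((~pass_cr).sum()),
        "n_kept": int(keep.sum()),
    }
    return g.subset_variants(keep), report


def feature_qc(
    a: AbundanceTable,
    prevalence_min: float = 0.10,
    mean_abund_min: float = 1e-4,
) -> tuple[AbundanceTable, dict]:
    """Keep features whose prevalence and mean abundance strictly exceed the cutoffs."""
    prev = a.prevalence
    mean = a.mean_abundance
    keep = (prev > prevalence_min) & (mean > mean_abund_min)
    report = {
        "n_in": a.n_features,
        "fail_prevalence": int((~(prev > prevalence_min)).sum()),
        "fail_mean_abundance": int((~(mean > mean_abund_min)).sum()),
        "n_kept": int(keep.sum()),
    }
    return AbundanceTable(a.values.loc[:, keep[keep].index]), report


# ---------------------------------------------------------------------------
# genotype I/O


def read_genotypes(path, fmt: str | None = None, multiallelic: str = "skip") -> GenotypeMatrix:
    """Read genotypes from VCF (GT or DS) or a dosage TSV.

    ``fmt`` is inferred from the extension when None.  Multiallelic VCF records
    are skipped or raise, per ``multiallelic`` ("skip" | "error").
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "dosage_tsv"
    if fmt == "vcf":
        g = _read_vcf(path, multiallelic=multiallelic)
    elif fmt == "dosage_tsv":
        g = read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    return g.compute_stats()


def _read_vcf(path, multiallelic: str = "skip") -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    cols = []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            if multiallelic == "error":
                raise ValueError(
                    f"multiallelic record at line for {var.CHROM}:{var.POS}"
                )
            continue
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = var.gt_types.astype(float)
            dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
        cols.append(dos)
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    dosages = np.column_stack(cols)
    return GenotypeMatrix(samples, pd.DataFrame(rows), dosages)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write hard-called genotypes as a minimal VCF v4.2 (GT field)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in pd.unique(g.variants["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(str(s) for s in g.samples)
    )
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    hard = np.round(g.dosages)
    for j, rec in g.variants.iterrows():
        calls = [
            "./." if np.isnan(hard[i, j]) else gt_map[int(hard[i, j])]
            for i in range(g.n_samples)
        ]
        lines.append(
            f"{rec['chrom']}\t{rec['pos']}\t{rec['id']}\t{rec['ref']}\t"
            f"{rec['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    """Dosage TSV: one row per variant, metadata columns then one column per sample."""
    df = g.variants[VARIANT_COLUMNS].copy()
    dos = pd.DataFrame(g.dosages.T, columns=[str(s) for s in g.samples])
    pd.concat([df.reset_index(drop=True), dos], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV missing columns {missing}")
    df["chrom"] = df["chrom"].astype(str)
    samples = [c for c in df.columns if c not in VARIANT_COLUMNS]
    dosages = df[samples].to_numpy(dtype=float).T
    return GenotypeMatrix(samples, df[VARIANT_COLUMNS].copy(), dosages)


# ---------------------------------------------------------------------------
# abundance / covariate I/O


def read_abundance(path, clade_col: str = "clade_name") -> AbundanceTable:
    """Read a MetaPhlAn-style abundance TSV (clade rows, sample columns).

    Values in percent are auto-detected by column sums and rescaled to fractions.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if clade_col not in df.columns:
        clade_col = df.columns[0]
    df = df.set_index(clade_col)
    values = df.T.astype(float)  # samples x features
    if np.nanmedian(values.sum(axis=1)) > 1.5:  # percent scale
        values = values / 100.0
    values.index.name = "sample_id"
    return AbundanceTable(values)


def write_abundance(a: AbundanceTable, path, clade_col: str = "clade_name") -> None:
    out = a.values.T
    out.index.name = clade_col
    out.to_csv(path, sep="\t")


def read_table(path, index_col: str = "sample_id") -> pd.DataFrame:
    """Read a covariate / trait TSV keyed by sample_id."""
    df = pd.read_csv(path, sep="\t")
    if index_col not in df.columns:
        index_col = df.columns[0]
    df = df.set_index(index_col)
    df.index = df.index.astype(str)
    return df


def read_covariates(path) -> pd.DataFrame:
    df = read_table(path)
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"covariate columns with missing values: {bad}")
    if "sex" in df.columns and not set(df["sex"].unique()) <= {0, 1}:
        raise ValueError("sex must be coded {0,1}")
    return df


def align_samples(*objs):
    """Inner-join sample IDs across GenotypeMatrix / AbundanceTable / DataFrame."""
    ids = None
    for o in objs:
        cur = (
            [str(s) for s in o.samples]
            if isinstance(o, (GenotypeMatrix, AbundanceTable))
            else [str(s) for s in o.index]
        )
        ids = cur if ids is None else [s for s in ids if s in set(cur)]
    if not ids:
        raise KeyError("no shared sample IDs across inputs")
    out = []
    for o in objs:
        if isinstance(o, GenotypeMatrix):
            pos = {str(s): i for i, s in enumerate(o.samples)}
            idx = [pos[s] for s in ids]
            out.append(GenotypeMatrix(ids, o.variants.copy(), o.dosages[idx]))
        elif isinstance(o, AbundanceTable):
            v = o.values.copy()
            v.index = v.index.astype(str)
            out.append(AbundanceTable(v.loc[ids]))
        else:
            d = o.copy()
            d.index = d.index.astype(str)
            out.append(d.loc[ids])
    return out
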