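"""External formats, genotype QC and the univariate cis-eQTL pre-screen.

Containers
----------
:class:`GenotypeMatrix`
    allele dosages (samples x SNPs, values {0,1,2}; NaN allowed pre-QC) with
    per-SNP chromosome/position, minor-allele frequency and LD-block id.
:class:`ExpressionMatrix`
    genes x samples real matrix with gene TSS coordinates.
:class:`FeatureTable`
    per-SNP epigenetic features plus per SNP-gene-pair interaction features.

Coordinates are 1-based inclusive internally (VCF convention); BED inputs are
converted from 0-based half-open at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("eqtel")

MISSING = np.nan


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    dosages: np.ndarray          # (n_samples, p) float; {0,1,2} or NaN pre-QC
    snp_ids: np.ndarray          # (p,) str
    chrom: np.ndarray            # (p,) str
    pos: np.ndarray              # (p,) int, 1-based
    maf: np.ndarray              # (p,) float in [0, 0.5]
    block_id: np.ndarray         # (p,) int
    sample_ids: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def validate(self, require_complete: bool = False) -> None:
        p = self.n_snps
        for name in ("snp_ids", "chrom", "pos", "maf", "block_id"):
            if len(getattr(self, name)) != p:
                raise ValueError(f"{name} length != number of SNPs")
        if require_complete and np.isnan(self.dosages).any():
            raise ValueError("missing dosages present after QC")
        got = compute_maf(self.dosages)
        ok = np.isnan(got) | (np.abs(got - self.maf) <= 1e-12)
        if not ok.all():
            bad = self.snp_ids[~ok][:5]
            raise ValueError(f"stored maf inconsistent with dosages: {list(bad)}")

    def subset(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[:, keep],
            snp_ids=self.snp_ids[keep],
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            maf=self.maf[keep],
            block_id=self.block_id[keep],
            sample_ids=self.sample_ids,
        )


@dataclass
class ExpressionMatrix:
    values: np.ndarray           # (n_genes, n_samples)
    gene_ids: np.ndarray         # (n_genes,) str
    tss_chrom: np.ndarray        # (n_genes,) str
    tss_pos: np.ndarray          # (n_genes,) int
    sample_ids: np.ndarray | None = None

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureTable:
    """Epigenetic features per SNP and interaction features per cis pair.

    ``pair_snp_idx`` / ``pair_gene_idx`` index into the companion
    GenotypeMatrix / ExpressionMatrix and define the candidate SNP-gene pair
    universe.
    """

    epigenetic: np.ndarray       # (p, R1)
    interaction: np.ndarray      # (n_pairs, R2)
    epigenetic_names: list[str]
    interaction_names: list[str]
    pair_snp_idx: np.ndarray     # (n_pairs,) int
    pair_gene_idx: np.ndarray    # (n_pairs,) int

    @property
    def n_pairs(self) -> int:
        return len(self.pair_snp_idx)

    def standardize(self) -> "FeatureTable":
        """Standardize every feature column to mean 0, sd 1."""

        def _std(m):
            m = np.asarray(m, dtype=float)
            mu = m.mean(axis=0)
            sd = m.std(axis=0)
            sd[sd == 0] = 1.0
            return (m - mu) / sd

        return replace(self, epigenetic=_std(self.epigenetic),
                       interaction=_std(self.interaction))

    def design_matrix(self) -> np.ndarray:
        """Pairs x (1 + R1 + R2) design with leading bias column."""
        n = self.n_pairs
        return np.column_stack(
            [np.ones(n), self.epigenetic[self.pair_snp_idx], self.interaction]
        )


# ---------------------------------------------------------------------------
# helpers


def compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per SNP from dosages, ignoring missing."""
    with np.errstate(invalid="ignore"):
        p_alt = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(p_alt, 1.0 - p_alt)


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test P value.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of all configurations no more likely
    than the observed one (the standard exact SNP-HWE formulation).
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_aa, n_bb) + n_ab  # minor allele count
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(n_het | allele counts) up to a constant, via gammaln
    from scipy.special import gammaln

    n_hom_rare = (n_rare - het_values) // 2
    n_hom_common = n - het_values - n_hom_rare
    logp = (
        het_values * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(n_hom_rare + 1)
        - gammaln(het_values + 1)
        - gammaln(n_hom_common + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[het_values == n_ab][0]
    return float(prob[prob <= p_obs * (1 + 1e-12)].sum())


# ---------------------------------------------------------------------------
# readers / writers


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read genotypes as samples x SNPs dosages.

    Supported dialects: ``vcf`` (GT field, diploid, bi-allelic), ``plink-text``
    (.raw-style dosage table) and ``tsv`` (this package's own text format,
    the only one carrying block ids and MAF explicitly).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink-text":
        return _read_plink_raw(path)
    if format == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.array(vcf.samples)
    dosages, snp_ids, chroms, poss = [], [], [], []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at line for {var.CHROM}:{var.POS} "
                f"(ALT={var.ALT}); only bi-allelic SNPs are supported"
            )
        gts = np.array(var.genotypes, dtype=object)
        row = np.empty(len(sample_ids))
        for s, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"ploidy {len(alleles)} != 2 at {var.CHROM}:{var.POS}"
                )
            if any(a < 0 for a in alleles):
                row[s] = MISSING
            else:
                row[s] = sum(alleles)
        dosages.append(row)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(var.POS)
    X = np.array(dosages).T if dosages else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(
        dosages=X,
        snp_ids=np.array(snp_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=int),
        maf=compute_maf(X),
        block_id=np.zeros(X.shape[1], dtype=int),
        sample_ids=sample_ids,
    )


def _read_plink_raw(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df]
    snp_cols = [c for c in df.columns if c not in meta]
    X = df[snp_cols].to_numpy(dtype=float)
    if np.nanmax(X, initial=0) > 2 or np.nanmin(X, initial=0) < 0:
        raise ValueError("dosages outside [0, 2]; not a diploid .raw table")
    # .raw columns are SNP_countedallele; strip the allele suffix
    snp_ids = np.array([c.rsplit("_", 1)[0] for c in snp_cols], dtype=object)
    return GenotypeMatrix(
        dosages=X,
        snp_ids=snp_ids,
        chrom=np.array(["NA"] * len(snp_ids), dtype=object),
        pos=np.zeros(len(snp_ids), dtype=int),
        maf=compute_maf(X),
        block_id=np.zeros(len(snp_ids), dtype=int),
        sample_ids=df["IID"].astype(str).to_numpy() if "IID" in df else None,
    )


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = ["snp_id", "chrom", "pos", "maf", "block_id"]
    for col in meta:
        if col not in df.columns:
            raise ValueError(f"genotype tsv missing column {col!r} in {path}")
    sample_cols = [c for c in df.columns if c not in meta]
    X = df[sample_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(
        dosages=X,
        snp_ids=df["snp_id"].to_numpy(dtype=object),
        chrom=df["chrom"].astype(str).to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=int),
        maf=df["maf"].to_numpy(dtype=float),
        block_id=df["block_id"].to_numpy(dtype=int),
        sample_ids=np.array(sample_cols),
    )


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the package's own genotype TSV dialect (round-trip exact)."""
    samples = (
        g.sample_ids
        if g.sample_ids is not None
        else [f"S{i}" for i in range(g.n_samples)]
    )
    df = pd.DataFrame(
        {
            "snp_id": g.snp_ids,
            "chrom": g.chrom,
            "pos": g.pos,
            "maf": g.maf,
            "block_id": g.block_id,
        }
    )
    dos = pd.DataFrame(g.dosages.T, columns=list(samples))
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False,
                                        float_format="%.17g")


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Minimal diploid GT-only VCF writer for the package's genotypes."""
    samples = (
        list(g.sample_ids)
        if g.sample_ids is not None
        else [f"S{i}" for i in range(g.n_samples)]
    )
    code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in range(g.n_snps):
            gts = [
                "./." if np.isnan(d) else code[int(round(d))]
                for d in g.dosages[:, j]
            ]
            fh.write(
                f"{g.chrom[j]}\t{g.pos[j]}\t{g.snp_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def read_blocks(path: str | Path, snp_ids: np.ndarray) -> np.ndarray:
    """PLINK .blocks-style text -> per-SNP block index.

    Each line lists whitespace-separated SNP ids (optionally prefixed '*').
    SNPs absent from every line each get their own singleton block.
    """
    index = {s: i for i, s in enumerate(snp_ids)}
    block_id = np.full(len(snp_ids), -1, dtype=int)
    b = 0
    with open(path) as fh:
        for line in fh:
            toks = [t for t in line.split() if t != "*"]
            if not toks:
                continue
            hit = False
            for t in toks:
                if t in index:
                    if block_id[index[t]] != -1:
                        raise ValueError(f"SNP {t} listed in more than one block")
                    block_id[index[t]] = b
                    hit = True
            if hit:
                b += 1
    for i in np.flatnonzero(block_id == -1):
        block_id[i] = b
        b += 1
    return block_id


def write_blocks(g: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in np.unique(g.block_id):
            fh.write("* " + " ".join(map(str, g.snp_ids[g.block_id == b])) + "\n")


def read_expression(path: str | Path, tss: pd.DataFrame | None = None) -> ExpressionMatrix:
    """TSV expression (genes x samples, first column gene_id).

    ``tss`` optionally maps gene_id -> (chrom, pos); genes without an entry
    get chrom 'NA', pos 0.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    gene_ids = df.iloc[:, 0].to_numpy(dtype=object)
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    chrom = np.array(["NA"] * len(gene_ids), dtype=object)
    pos = np.zeros(len(gene_ids), dtype=int)
    if tss is not None:
        lut = tss.set_index("gene_id")
        for i, gid in enumerate(gene_ids):
            if gid in lut.index:
                chrom[i] = str(lut.loc[gid, "chrom"])
                pos[i] = int(lut.loc[gid, "pos"])
    return ExpressionMatrix(values, gene_ids, chrom, pos,
                            sample_ids=np.array(df.columns[1:]))


def write_expression(e: ExpressionMatrix, path: str | Path) -> None:
    samples = (
        e.sample_ids if e.sample_ids is not None
        else [f"S{i}" for i in range(e.n_samples)]
    )
    df = pd.DataFrame(e.values, columns=list(samples))
    df.insert(0, "gene_id", e.gene_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ -> DataFrame with 1-based inclusive (start, end)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    df["start"] = df["start"].astype(int) + 1  # 0-based half-open -> 1-based incl.
    df["end"] = df["end"].astype(int)
    df["chrom"] = df["chrom"].astype(str)
    return df


# ---------------------------------------------------------------------------
# QC and pre-screen


def qc_filter(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.15,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, dict]:
    """Remove SNPs failing call-rate, MAF or exact-HWE filters.

    Each filter is assessed on the original matrix (so the result is
    independent of filter order). Survivors have remaining missing dosages
    mean-imputed. Returns the filtered matrix and a QC report dict.
    """
    for name, v in (("call_rate_min", call_rate_min), ("maf_min", maf_min),
                    ("hwe_p_min", hwe_p_min)):
        if not (0 < v < 1):
            raise ValueError(f"{name} must be in (0, 1), got {v}")
    X = g.dosages
    n = X.shape[0]
    call_rate = 1.0 - np.isnan(X).sum(axis=0) / n
    maf = compute_maf(X)
    maf = np.where(np.isnan(maf), 0.0, maf)
    hwe_p = np.ones(g.n_snps)
    for j in range(g.n_snps):
        col = X[:, j]
        col = col[~np.isnan(col)]
        counts = [(col == k).sum() for k in (0, 1, 2)]
        hwe_p[j] = hwe_exact_test(*counts)
    fail_cr = call_rate < call_rate_min
    fail_maf = maf < maf_min
    fail_hwe = hwe_p < hwe_p_min
    keep = ~(fail_cr | fail_maf | fail_hwe)
    report = {
        "n_input": int(g.n_snps),
        "n_removed_call_rate": int(fail_cr.sum()),
        "n_removed_maf": int(fail_maf.sum()),
        "n_removed_hwe": int(fail_hwe.sum()),
        "n_kept": int(keep.sum()),
    }
    if not keep.any():
        raise ValueError(f"QC removed every SNP: {report}")
    out = g.subset(keep)
    # mean-impute residual missing dosages (preserves per-SNP mean/MAF)
    X = out.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    out.dosages = X
    out.maf = compute_maf(X)
    log.info("QC: %s", report)
    return out, report


def normalize_expression(e: ExpressionMatrix) -> ExpressionMatrix:
    """Rank-based inverse-normal transform per gene, then unit variance.

    Ranks use Blom offsets, z = ndtri((rank - 3/8) / (n + 1/4)), ties
    averaged; each row is then scaled to sample variance exactly 1. The
    transform is idempotent (ranks are preserved by monotone maps).
    """
    vals = np.asarray(e.values, dtype=float)
    n = vals.shape[1]
    out = np.empty_like(vals)
    for i in range(vals.shape[0]):
        row = vals[i]
        if np.ptp(row) == 0:
            raise ValueError(f"constant expression row for gene {e.gene_ids[i]}")
        ranks = stats.rankdata(row, method="average")
        z = ndtri((ranks - 0.375) / (n + 0.25))
        z = z - z.mean()
        z /= z.std()
        out[i] = z
    return replace(e, values=out)


def univariate_screen(
    g: GenotypeMatrix,
    e: ExpressionMatrix,
    window_bp: int = 1_000_000,
    fdr: float = 1e-6,
) -> list[str]:
    """Genes with at least one cis SNP significant by simple regression.

    For every gene, SNPs within ``window_bp`` of the TSS are tested by
    single-SNP linear regression; P values are pooled over all cis pairs and
    Benjamini-Hochberg corrected at ``fdr``. Genes with an empty candidate
    window are excluded with a warning.
    """
    Y = e.values
    n = Y.shape[1]
    pvals, gene_of_test = [], []
    for j in range(e.n_genes):
        cis = cis_window(g, e.tss_chrom[j], e.tss_pos[j], window_bp)
        if cis.size == 0:
            log.warning("gene %s has no cis SNPs within %d bp; excluded",
                        e.gene_ids[j], window_bp)
            continue
        X = g.dosages[:, cis]
        y = Y[j]
        yc = y - y.mean()
        Xc = X - X.mean(axis=0)
        sx = Xc.std(axis=0)
        sx[sx == 0] = np.inf  # monomorphic: r = 0
        r = (Xc.T @ yc) / (n * sx * yc.std())
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        pvals.extend(p)
        gene_of_test.extend([j] * len(p))
    if not pvals:
        return []
    reject, *_ = multipletests(np.array(pvals), alpha=fdr, method="fdr_bh")
    hit_genes = sorted({gene_of_test[k] for k in np.flatnonzero(reject)})
    return [str(e.gene_ids[j]) for j in hit_genes]


def cis_window(
    g: GenotypeMatrix, chrom: str, tss: int, window_bp: int = 1_000_000
) -> np.ndarray:
    """Indices of SNPs within window_bp of a TSS (strand ignored)."""
    return np.flatnonzero(
        (g.chrom == str(chrom)) & (np.abs(g.pos - int(tss)) <= window_bp)
    )
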