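"""Semi-synthetic benchmark generator with known causal ground truth.

The generator emulates the statistical design of the benchmark used to
evaluate the method: block-LD genotypes (default 313 samples, 874 candidate
SNPs per gene, MAF uniform on [0.15, 0.5]), 1% of SNPs flagged as
interacting-regulator loci, a per-gene number of expression-regulators drawn
from a zero-truncated Poisson, standard-normal effect sizes on standardized
dosages, residual noise calibrated so the true predictor explains exactly a
drawn fraction of expression variance, and seven enhancer-derived epigenetic
features whose distribution is mean-shifted (activating marks up, repressive
marks down) at regulator loci.

Genotypes use a Gaussian-copula threshold scheme: two latent haplotype draws
per sample from an equicorrelated normal within each LD block, thresholded
at the allele-frequency quantile and summed to a diploid dosage. The
``within_block_r`` parameter is the latent copula correlation; realized
dosage correlation is attenuated by thresholding.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

from eqtel.config import SimulationConfig
from eqtel.io_formats import ExpressionMatrix, FeatureTable, GenotypeMatrix

log = logging.getLogger("eqtel")


@dataclass
class SimulationTruth:
    regulator_flags: np.ndarray          # (p,) bool
    expression_regulators: dict[str, list[tuple[str, float]]]  # gene -> [(snp, effect)]
    target_r2: np.ndarray                # (n_genes,)
    noise_sd: np.ndarray                 # (n_genes,)

    def pair_frame(self, gene_ids: np.ndarray) -> pd.DataFrame:
        rows = []
        for gid in gene_ids:
            for snp, eff in self.expression_regulators.get(str(gid), []):
                rows.append((snp, str(gid), eff))
        return pd.DataFrame(rows, columns=["snp_id", "gene_id", "effect"])

    def write(self, path: str | Path, g: GenotypeMatrix, gene_ids: np.ndarray) -> None:
        """Serialize truth as TSV: snp_id, gene_id, effect, regulator_flag."""
        flag = dict(zip(g.snp_ids, self.regulator_flags))
        df = self.pair_frame(gene_ids)
        df["regulator_flag"] = [bool(flag[s]) for s in df["snp_id"]]
        df.to_csv(path, sep="\t", index=False)


def simulate_genotypes(
    n_samples: int = 313,
    n_genes: int = 200,
    snps_per_gene: int = 874,
    maf_range: tuple[float, float] = (0.15, 0.5),
    block_size_mean: float = 10.0,
    within_block_r: float = 0.8,
    seed: int = 0,
    snp_spacing_bp: int = 2000,
    gene_spacing_bp: int = 4_000_000,
) -> GenotypeMatrix:
    """Block-LD genotype dosages with uniform MAFs.

    SNPs are laid out in per-gene segments (``snps_per_gene`` consecutive
    SNPs, all within 1 Mb of the gene's TSS) and partitioned into LD blocks
    with geometric-distributed sizes. Blocks never span genes.
    """
    if not (0.0 <= within_block_r < 1.0):
        raise ValueError(f"within_block_r must be in [0, 1), got {within_block_r}")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"invalid maf_range {maf_range}")
    rng = np.random.default_rng(seed)
    p = n_genes * snps_per_gene
    maf = rng.uniform(lo, hi, size=p)
    thresh = ndtri(1.0 - maf)  # latent > thresh  <=>  alt allele

    dosages = np.empty((n_samples, p), dtype=np.float64)
    block_id = np.empty(p, dtype=int)
    rho = within_block_r
    b = 0
    for gidx in range(n_genes):
        start = gidx * snps_per_gene
        done = 0
        while done < snps_per_gene:
            size = min(rng.geometric(1.0 / block_size_mean), snps_per_gene - done)
            sl = slice(start + done, start + done + size)
            # equicorrelated latent normals via shared factor, two haplotypes
            for hap in range(2):
                shared = rng.standard_normal(n_samples)[:, None]
                own = rng.standard_normal((n_samples, size))
                z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
                alt = z > thresh[sl][None, :]
                if hap == 0:
                    dosages[:, sl] = alt
                else:
                    dosages[:, sl] += alt
            block_id[sl] = b
            b += 1
            done += size

    pos = np.empty(p, dtype=int)
    chrom = np.array(["1"] * p, dtype=object)
    for gidx in range(n_genes):
        base = (gidx + 1) * gene_spacing_bp
        pos[gidx * snps_per_gene:(gidx + 1) * snps_per_gene] = (
            base + snp_spacing_bp * np.arange(snps_per_gene)
        )
    snp_ids = np.array([f"snp{j}" for j in range(p)], dtype=object)
    from eqtel.io_formats import compute_maf

    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=snp_ids,
        chrom=chrom,
        pos=pos,
        maf=compute_maf(dosages),
        block_id=block_id,
        sample_ids=np.array([f"S{i}" for i in range(n_samples)]),
    )


def gene_annotation(
    n_genes: int,
    snps_per_gene: int,
    snp_spacing_bp: int = 2000,
    gene_spacing_bp: int = 4_000_000,
) -> ExpressionMatrix:
    """Gene ids and TSS coordinates matching :func:`simulate_genotypes`.

    The TSS sits at the centre of the gene's SNP segment, so every one of the
    gene's SNPs lies within 1 Mb of it and no other gene's SNPs do.
    """
    gene_ids = np.array([f"gene{j}" for j in range(n_genes)], dtype=object)
    tss = np.array(
        [
            (j + 1) * gene_spacing_bp + snp_spacing_bp * snps_per_gene // 2
            for j in range(n_genes)
        ],
        dtype=int,
    )
    return ExpressionMatrix(
        values=np.zeros((n_genes, 0)),
        gene_ids=gene_ids,
        tss_chrom=np.array(["1"] * n_genes, dtype=object),
        tss_pos=tss,
    )


def assign_regulators(
    g: GenotypeMatrix, fraction: float = 0.01, seed: int = 0
) -> np.ndarray:
    """Flag exactly round(fraction * p) SNPs as interacting-regulator loci."""
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    p = g.n_snps
    k = int(round(fraction * p))
    if k < 1:
        raise ValueError(f"fraction {fraction} yields no regulators for p={p}")
    rng = np.random.default_rng(seed)
    flags = np.zeros(p, dtype=bool)
    flags[rng.choice(p, size=k, replace=False)] = True
    return flags


def zero_truncated_poisson(lam: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated Poisson via inverse CDF on the truncated support."""
    u = rng.uniform(size=size)
    from scipy.stats import poisson

    # P(K = k | K >= 1) cdf inversion, k capped generously
    kmax = max(20, int(lam + 10 * np.sqrt(lam) + 10))
    ks = np.arange(1, kmax + 1)
    pmf = poisson.pmf(ks, lam) / (1.0 - np.exp(-lam))
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0
    return ks[np.searchsorted(cdf, u)]


def simulate_expression(
    g: GenotypeMatrix,
    flags: np.ndarray,
    cfg: SimulationConfig | None = None,
    seed: int = 0,
    gene_ann: ExpressionMatrix | None = None,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Per-gene linear expression from flagged cis SNPs plus calibrated noise.

    For each gene: draw k ~ zero-truncated Poisson(lambda), pick k causal
    SNPs among the gene's regulator-flagged cis set (redraw k with a warning
    if the set is smaller), draw effects N(0, effect_sd^2) applied to
    standardized dosages, then set noise_sd so that on the realized genotypes
    var(predictor) / (var(predictor) + noise_sd^2) equals the drawn target
    R^2 from Beta(r2_beta_a, r2_beta_b).
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    if gene_ann is None:
        gene_ann = gene_annotation(cfg.n_genes, cfg.snps_per_gene,
                                   cfg.snp_spacing_bp, cfg.gene_spacing_bp)
    n_genes = gene_ann.n_genes
    n = g.n_samples
    values = np.empty((n_genes, n))
    target_r2 = np.empty(n_genes)
    noise_sd = np.empty(n_genes)
    regulators: dict[str, list[tuple[str, float]]] = {}

    from eqtel.io_formats import cis_window

    for j in range(n_genes):
        cis = cis_window(g, gene_ann.tss_chrom[j], gene_ann.tss_pos[j])
        flagged = cis[flags[cis]]
        # monomorphic SNPs carry no effect variance and cannot be causal
        flagged = flagged[g.dosages[:, flagged].std(axis=0) > 0]
        if flagged.size == 0:
            raise ValueError(
                f"gene {gene_ann.gene_ids[j]} has no regulator-flagged cis SNP"
            )
        k = int(zero_truncated_poisson(cfg.causal_count_lambda, 1, rng)[0])
        while k > flagged.size:
            log.warning(
                "gene %s: drew %d causal SNPs but only %d flagged cis SNPs; redrawing",
                gene_ann.gene_ids[j], k, flagged.size,
            )
            k = int(zero_truncated_poisson(cfg.causal_count_lambda, 1, rng)[0])
        chosen = rng.choice(flagged, size=k, replace=False)
        effects = rng.normal(0.0, cfg.effect_sd, size=k)
        while np.any(effects == 0.0):  # effect_dist excludes exact zero
            effects[effects == 0.0] = rng.normal(0.0, cfg.effect_sd,
                                                 size=(effects == 0.0).sum())
        X = g.dosages[:, chosen]
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        predictor = Xs @ effects
        v = predictor.var()
        r2 = rng.beta(cfg.r2_beta_a, cfg.r2_beta_b)
        target_r2[j] = r2
        noise_sd[j] = np.sqrt(v * (1.0 - r2) / r2)
        values[j] = predictor + rng.normal(0.0, noise_sd[j], size=n)
        regulators[str(gene_ann.gene_ids[j])] = [
            (str(g.snp_ids[s]), float(b)) for s, b in zip(chosen, effects)
        ]

    expr = ExpressionMatrix(
        values=values,
        gene_ids=gene_ann.gene_ids,
        tss_chrom=gene_ann.tss_chrom,
        tss_pos=gene_ann.tss_pos,
        sample_ids=g.sample_ids,
    )
    truth = SimulationTruth(
        regulator_flags=flags.copy(),
        expression_regulators=regulators,
        target_r2=target_r2,
        noise_sd=noise_sd,
    )
    return expr, truth


def simulate_features(
    flags: np.ndarray,
    truth: SimulationTruth | None = None,
    g: GenotypeMatrix | None = None,
    gene_ann: ExpressionMatrix | None = None,
    cfg: SimulationConfig | None = None,
    enhancer_shift: np.ndarray | None = None,
    seed: int = 0,
) -> FeatureTable:
    """Epigenetic + interaction features separating regulator loci.

    Background SNPs draw each epigenetic feature from N(0, 1); regulator
    SNPs from N(shift_r, 1) where the shift vector is ``enhancer_shift``
    (default ``enhancer_shift_sd`` times the activating/repressive sign
    pattern). Interaction features are N(0, 1) for background pairs and
    mean-shifted for true expression-regulator pairs.
    """
    cfg = cfg or SimulationConfig()
    p = len(flags)
    rng = np.random.default_rng(seed)
    if enhancer_shift is None:
        enhancer_shift = cfg.enhancer_shift_sd * np.asarray(cfg.epigenetic_signs, float)
    enhancer_shift = np.asarray(enhancer_shift, dtype=float)
    if len(enhancer_shift) != cfg.n_epigenetic:
        raise ValueError(
            f"enhancer_shift length {len(enhancer_shift)} != "
            f"n_epigenetic {cfg.n_epigenetic}"
        )
    E = rng.standard_normal((p, cfg.n_epigenetic))
    E[flags] += enhancer_shift[None, :]

    if gene_ann is None:
        gene_ann = gene_annotation(cfg.n_genes, cfg.snps_per_gene,
                                   cfg.snp_spacing_bp, cfg.gene_spacing_bp)
    from eqtel.io_formats import cis_window

    pair_snp, pair_gene = [], []
    if g is not None:
        for j in range(gene_ann.n_genes):
            cis = cis_window(g, gene_ann.tss_chrom[j], gene_ann.tss_pos[j])
            pair_snp.append(cis)
            pair_gene.append(np.full(cis.size, j))
        pair_snp = np.concatenate(pair_snp) if pair_snp else np.empty(0, int)
        pair_gene = np.concatenate(pair_gene) if pair_gene else np.empty(0, int)
    else:
        pair_snp = np.arange(p)
        pair_gene = np.zeros(p, dtype=int)

    P = rng.standard_normal((len(pair_snp), cfg.n_interaction))
    if truth is not None and g is not None:
        snp_index = {s: i for i, s in enumerate(g.snp_ids)}
        gene_index = {str(gid): j for j, gid in enumerate(gene_ann.gene_ids)}
        true_pairs = {
            (snp_index[s], gene_index[gid])
            for gid, lst in truth.expression_regulators.items()
            for s, _ in lst
        }
        hit = np.array(
            [(s, gj) in true_pairs for s, gj in zip(pair_snp, pair_gene)]
        )
        P[hit] += cfg.interaction_shift_sd
    return FeatureTable(
        epigenetic=E,
        interaction=P,
        epigenetic_names=list(cfg.epigenetic_names),
        interaction_names=[f"interaction{k}" for k in range(cfg.n_interaction)],
        pair_snp_idx=np.asarray(pair_snp, dtype=int),
        pair_gene_idx=np.asarray(pair_gene, dtype=int),
    )


def simulate_dataset(
    cfg: SimulationConfig | None = None,
    seed: int = 0,
    enhancer_shift: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, ExpressionMatrix, FeatureTable, SimulationTruth]:
    """Full benchmark dataset: genotypes, expression, features, truth."""
    cfg = cfg or SimulationConfig()
    seeds = np.random.SeedSequence(seed).generate_state(4)
    g = simulate_genotypes(
        cfg.n_samples, cfg.n_genes, cfg.snps_per_gene, cfg.maf_range,
        cfg.block_size_mean, cfg.within_block_r, seed=int(seeds[0]),
        snp_spacing_bp=cfg.snp_spacing_bp, gene_spacing_bp=cfg.gene_spacing_bp,
    )
    flags = assign_regulators(g, cfg.regulator_fraction, seed=int(seeds[1]))
    gene_ann = gene_annotation(cfg.n_genes, cfg.snps_per_gene,
                               cfg.snp_spacing_bp, cfg.gene_spacing_bp)
    expr, truth = simulate_expression(g, flags, cfg, seed=int(seeds[2]),
                                      gene_ann=gene_ann)
    feats = simulate_features(flags, truth, g, gene_ann, cfg,
                              enhancer_shift=enhancer_shift, seed=int(seeds[3]))
    return g, expr, feats, truth


def write_dataset(
    out_dir: str | Path,
    g: GenotypeMatrix,
    e: ExpressionMatrix,
    f: FeatureTable,
    truth: SimulationTruth,
) -> None:
    """Serialize a dataset in the package's text dialects plus truth TSV."""
    from eqtel.io_formats import write_blocks, write_expression, write_genotypes

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genotypes(g, out / "genotypes.tsv")
    write_blocks(g, out / "ld.blocks")
    write_expression(e, out / "expression.tsv")
    epi = pd.DataFrame(f.epigenetic, columns=f.epigenetic_names)
    epi.insert(0, "snp_id", g.snp_ids)
    epi.to_csv(out / "epigenetic_features.tsv", sep="\t", index=False)
    inter = pd.DataFrame(f.interaction, columns=f.interaction_names)
    inter.insert(0, "snp_id", g.snp_ids[f.pair_snp_idx])
    inter.insert(1, "gene_id", e.gene_ids[f.pair_gene_idx])
    inter.to_csv(out / "interaction_features.tsv", sep="\t", index=False)
    truth.write(out / "truth.tsv", g, e.gene_ids)
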