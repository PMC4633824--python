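"""Downstream functional validation statistics.

Covers the post-hoc evidence used to judge reported regulatory SNPs:
allele-differential motif disruption with exact match P values, enrichment
of disruption among reported SNPs over control SNPs, DNase-footprint
overlap fractions, allelic read imbalance at heterozygous sites, and the
excess-enrichment estimator of the proportion of reported SNPs that are
causal.

Match P values are exact with respect to a discretized score lattice: the
per-position log-odds scores are rounded to an integer grid (granularity
``scale``) and the full null score distribution under the background base
frequencies is computed by dynamic programming over that grid, so for small
widths the DP equals brute-force enumeration over all background words.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

log = logging.getLogger("eqtel")

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# PWM machinery


class PWM:
    """Position weight matrix with integer-lattice log-odds scoring.

    ``probs`` is a (width, 4) probability matrix (columns A, C, G, T, rows
    sum to 1 after pseudocount). Scores are natural-log odds against the
    background, rounded to an integer lattice of ``scale`` steps per nat;
    both scanning and P values use the lattice, so they are mutually exact.
    """

    def __init__(self, probs: np.ndarray, motif_id: str = "motif",
                 background: np.ndarray | None = None, scale: int = 1000):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("PWM probs must be (width, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")
        self.motif_id = motif_id
        self.probs = probs
        self.background = (
            np.full(4, 0.25) if background is None
            else np.asarray(background, dtype=float)
        )
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")
        self.scale = int(scale)
        logodds = np.log(np.clip(probs, 1e-12, None) / self.background)
        self.iscores = np.rint(logodds * self.scale).astype(np.int64)
        self._dist_cache: dict[bool, tuple[np.ndarray, np.ndarray, int]] = {}

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, counts: np.ndarray, motif_id: str = "motif",
                    pseudocount: float = 0.01,
                    background: np.ndarray | None = None,
                    scale: int = 1000) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(counts / counts.sum(axis=1, keepdims=True), motif_id,
                   background, scale)

    def _matrix(self, reverse: bool) -> np.ndarray:
        if not reverse:
            return self.iscores
        # reverse complement: flip positions and swap A<->T, C<->G
        return self.iscores[::-1, ::-1]

    def score_word(self, word: str, reverse: bool = False) -> int | None:
        """Integer lattice score of a width-length word (None if ambiguous)."""
        m = self._matrix(reverse)
        total = 0
        for k, ch in enumerate(word.upper()):
            b = _BASES.find(ch)
            if b < 0:
                return None
            total += m[k, b]
        return int(total)

    def score_distribution(self, reverse: bool = False):
        """(support offset, survival probabilities) of the null score by DP."""
        if reverse in self._dist_cache:
            return self._dist_cache[reverse]
        m = self._matrix(reverse)
        # DP as array convolution over positions on the integer lattice
        dist = np.array([1.0])
        offset = 0
        for k in range(m.shape[0]):
            row = m[k]
            rlo, rhi = int(row.min()), int(row.max())
            new = np.zeros(len(dist) + rhi - rlo)
            for b in range(4):
                new[int(row[b]) - rlo: int(row[b]) - rlo + len(dist)] += (
                    self.background[b] * dist
                )
            dist = new
            offset += rlo
        sf = dist[::-1].cumsum()[::-1]  # P(S >= s) for s = offset + index
        self._dist_cache[reverse] = (offset, sf, len(dist))
        return self._dist_cache[reverse]

    def match_pvalue(self, score: int, reverse: bool = False) -> float:
        """Exact P(null score >= score) under the background model."""
        offset, sf, length = self.score_distribution(reverse)
        idx = score - offset
        if idx <= 0:
            return 1.0
        if idx >= length:
            return 0.0
        return float(sf[idx])


def read_pwms(path: str | Path, format: str = "transfac",
              pseudocount: float = 0.01,
              background: np.ndarray | None = None) -> list[PWM]:
    """Parse TRANSFAC-like or MEME-minimal PWM text via Bio.motifs."""
    from Bio import motifs as bio_motifs

    fmt = {"transfac": "transfac", "meme": "minimal"}[format]
    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, fmt):
            counts = np.array([[m.counts[b][k] for b in _BASES]
                               for k in range(m.length)], dtype=float)
            name = getattr(m, "name", None) or getattr(m, "base_id", None)
            out.append(PWM.from_counts(counts, motif_id=str(name or f"m{len(out)}"),
                                       pseudocount=pseudocount,
                                       background=background))
    return out


@dataclass
class MotifDisruption:
    motif_id: str
    snp_id: str
    score_major: float            # best-match -log10 P for the major allele
    score_minor: float
    differential: float           # score_major - score_minor
    passes_hit_threshold: bool    # max score >= -log10(hit P cutoff)


def scan_alleles(
    sequence: str,
    alleles: tuple[str, str],
    pwm: PWM,
    snp_id: str = "snp",
    hit_p: float = 2e-4,
    flank: int | None = None,
) -> MotifDisruption:
    """Best motif match around a SNP, separately per allele.

    ``sequence`` is the window with the variant base at the centre (odd
    length, default 50 bp flanks). For each allele the best
    log-odds match over both strands and every offset overlapping the SNP
    is converted to -log10 of its exact match P; the differential is the
    difference in log10 P between major and minor allele. Offsets
    containing ambiguous bases are skipped.
    """
    seq = sequence.upper()
    if len(seq) % 2 != 1:
        raise ValueError("window length must be odd (SNP centred)")
    center = len(seq) // 2
    if flank is not None and len(seq) != 2 * flank + 1:
        raise ValueError(f"window length {len(seq)} != 2*{flank}+1")
    w = pwm.width
    if w > len(seq):
        raise ValueError(f"PWM width {w} exceeds window {len(seq)}")
    scores = []
    for allele in alleles:
        if len(allele) != 1:
            raise ValueError("only single-base alleles supported")
        s = seq[:center] + allele.upper() + seq[center + 1:]
        best_p = 1.0
        for start in range(max(0, center - w + 1), min(center + 1, len(s) - w + 1)):
            word = s[start: start + w]
            for reverse in (False, True):
                isc = pwm.score_word(word, reverse)
                if isc is None:
                    continue
                p = pwm.match_pvalue(isc, reverse)
                best_p = min(best_p, p)
        scores.append(-math.log10(max(best_p, 1e-300)))
    score_major, score_minor = scores
    return MotifDisruption(
        motif_id=pwm.motif_id,
        snp_id=snp_id,
        score_major=score_major,
        score_minor=score_minor,
        differential=score_major - score_minor,
        passes_hit_threshold=max(scores) >= -math.log10(hit_p),
    )


def motif_enrichment(
    case_diffs: dict[str, np.ndarray],
    control_diffs: dict[str, np.ndarray],
    fold_min: float = 1.5,
    p_max: float = 0.05,
    use_absolute: bool = True,
    min_case: int = 5,
) -> pd.DataFrame:
    """Motifs whose disruption is enriched among case SNPs.

    Per motif: ratio of mean absolute differentials (case/control) and a
    two-sided Wilcoxon rank-sum P (exact for small samples); motifs passing
    both filters are returned ordered by decreasing ratio.
    """
    rows = []
    for motif, case in case_diffs.items():
        case = np.asarray(case, dtype=float)
        ctrl = np.asarray(control_diffs.get(motif, []), dtype=float)
        if len(case) < min_case:
            log.warning("motif %s: only %d scored case SNPs; excluded",
                        motif, len(case))
            continue
        if len(ctrl) == 0:
            continue
        a = np.abs(case) if use_absolute else case
        b = np.abs(ctrl) if use_absolute else ctrl
        denom = b.mean()
        ratio = a.mean() / denom if denom > 0 else np.inf
        method = "exact" if max(len(a), len(b)) <= 25 else "asymptotic"
        p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        rows.append((motif, ratio, float(p), len(a), len(b)))
    df = pd.DataFrame(rows, columns=["motif_id", "ratio", "p_value",
                                     "n_case", "n_control"])
    hits = df[(df["ratio"] >= fold_min) & (df["p_value"] < p_max)]
    return hits.sort_values("ratio", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# footprints and allelic imbalance


def footprint_fraction(
    snps: pd.DataFrame,
    interval_sets: dict[str, pd.DataFrame] | pd.DataFrame,
    flank: int = 25,
) -> dict[str, float]:
    """Fraction of SNPs whose +-flank window hits an interval, per set.

    ``snps`` needs columns chrom, pos (1-based). Interval frames use
    1-based inclusive (start, end) as produced by ``read_bed``. The pooled
    fraction over all sets is reported under "pooled".
    """
    if len(snps) == 0:
        raise ValueError("zero SNPs supplied")
    if isinstance(interval_sets, pd.DataFrame):
        interval_sets = {"intervals": interval_sets}

    def build_trees(df):
        trees: dict[str, IntervalTree] = {}
        for chrom, sub in df.groupby("chrom"):
            # half-open tree coordinates: [start, end+1)
            trees[str(chrom)] = IntervalTree.from_tuples(
                (int(s), int(e) + 1) for s, e in zip(sub["start"], sub["end"])
                if e >= s
            )
        return trees

    per_set_trees = {name: build_trees(df) for name, df in interval_sets.items()}
    out = {}
    pooled_hit = np.zeros(len(snps), dtype=bool)
    for name, trees in per_set_trees.items():
        hit = np.zeros(len(snps), dtype=bool)
        for i, (chrom, pos) in enumerate(zip(snps["chrom"], snps["pos"])):
            tree = trees.get(str(chrom))
            if tree is not None and tree.overlap(int(pos) - flank,
                                                 int(pos) + flank + 1):
                hit[i] = True
        out[name] = float(hit.mean())
        pooled_hit |= hit
    out["pooled"] = float(pooled_hit.mean())
    return out


def allelic_imbalance(
    counts: pd.DataFrame,
    min_minor_fraction: float = 0.02,
    min_minor_reads: int = 2,
) -> pd.DataFrame:
    """Allelic-imbalance statistics at heterozygous SNPs.

    ``counts`` needs columns snp_id, ref_count, alt_count (pooled reads).
    A SNP is treated as heterozygous when the minor allele reaches both a
    read fraction >= min_minor_fraction and >= min_minor_reads reads; other
    SNPs (including zero-coverage ones) are excluded. Returns the read
    difference, the absolute log-ratio with a +1 pseudo-count, and the
    max/min fold ratio.
    """
    df = counts.copy()
    df["total"] = df["ref_count"] + df["alt_count"]
    df = df[df["total"] > 0]
    minor = df[["ref_count", "alt_count"]].min(axis=1)
    het = (minor / df["total"] >= min_minor_fraction) & (minor >= min_minor_reads)
    df = df[het].copy()
    df["difference"] = (df["ref_count"] - df["alt_count"]).abs()
    df["abs_log_ratio"] = np.abs(
        np.log((df["ref_count"] + 1.0) / (df["alt_count"] + 1.0))
    )
    big = df[["ref_count", "alt_count"]].max(axis=1)
    small = df[["ref_count", "alt_count"]].min(axis=1)
    df["fold"] = big / small
    return df.drop(columns="total").reset_index(drop=True)


# ---------------------------------------------------------------------------
# causal-fraction estimator


def select_reference_causal(
    assoc: pd.DataFrame, gap_min: float = 2.5, score_min: float | None = None
) -> list[str]:
    """High-confidence causal SNPs from univariate association scores.

    ``assoc`` needs columns gene_id, snp_id, score (-log10 P). Per gene the
    best SNP is deemed causal when its score exceeds the second best by more
    than ``gap_min`` (and passes ``score_min`` if given).
    """
    out = []
    for gid, sub in assoc.groupby("gene_id"):
        sub = sub.sort_values("score", ascending=False)
        if len(sub) < 2:
            continue
        best, second = sub.iloc[0], sub.iloc[1]
        if score_min is not None and best["score"] < score_min:
            continue
        if best["score"] - second["score"] > gap_min:
            out.append(str(best["snp_id"]))
    return out


def causal_fraction(
    c_case: dict[str, float], c_ref: dict[str, float]
) -> tuple[dict[str, float], float]:
    """Per-motif causal fraction (c_case-1)/(c_ref-1), clipped to [0, 1].

    ``c_case`` are per-motif disruption enrichments of the reported SNPs
    over background; ``c_ref`` the same for the high-confidence causal
    reference set. Motifs without reference signal (c_ref <= 1) are
    excluded. Returns (per-motif fractions, their mean).
    """
    fracs = {}
    for motif, cc in c_case.items():
        if motif not in c_ref:
            continue
        cr = c_ref[motif]
        if cc <= 0 or cr <= 0:
            raise ValueError(f"enrichments must be > 0 (motif {motif})")
        if cr <= 1.0:
            log.warning("motif %s: reference enrichment %.3g <= 1; excluded",
                        motif, cr)
            continue
        fracs[motif] = float(np.clip((cc - 1.0) / (cr - 1.0), 0.0, 1.0))
    mean = float(np.mean(list(fracs.values()))) if fracs else float("nan")
    return fracs, mean
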