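"""Imputation accuracy metrics and mask generators for evaluation.

All statistics are computed over the *mask*: the set of entries that were
deliberately hidden before imputation, so the truth is known. A genotype
is concordant only when both alleles match; allelic concordance credits a
half-right heterozygote with one of its two alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "MetricsReport",
    "mask_genotypes",
    "genotype_cr",
    "allelic_cr",
    "genotype_r2",
    "maf_binned_metrics",
    "het_cr",
    "evaluate",
    "DEFAULT_MAF_BINS",
]

# half-open (low, high] intervals over the minor-allele-frequency range
DEFAULT_MAF_BINS = (0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


def mask_genotypes(
    g: GenotypeMatrix, rate: float, pattern: str, seed: int | np.random.Generator
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Hide a fraction of a missing-free matrix to create an evaluation task.

    systematic: round(rate * p) uniformly chosen marker columns are set to
    0 in every sample (markers off-chip for the whole population);
    sporadic: per sample, round(rate * p) uniformly chosen entries are set
    to 0 (assay dropouts). Rounding is to nearest, ties to even. Returns
    the masked matrix and the boolean truth mask of hidden coordinates.
    """
    if not 0.0 < rate < 1.0:
        raise ValueError("masking rate must be in (0, 1)")
    if g.has_missing():
        raise ValueError("matrix to be masked must be missing-free")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, p = g.shape
    k = int(np.round(rate * p))
    mask = np.zeros((n, p), dtype=bool)
    if pattern == "systematic":
        cols = rng.choice(p, size=k, replace=False)
        mask[:, cols] = True
    elif pattern == "sporadic":
        for i in range(n):
            mask[i, rng.choice(p, size=k, replace=False)] = True
    else:
        raise ValueError(f"unknown missing pattern {pattern!r}")
    codes = g.codes.copy()
    codes[mask] = MISSING
    return GenotypeMatrix(g.sample_ids, g.markers, codes, validate=False), mask


def _as_codes(x) -> np.ndarray:
    return x.codes if isinstance(x, GenotypeMatrix) else np.asarray(x)


def _check(imputed, truth, mask) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    imputed, truth = _as_codes(imputed), _as_codes(truth)
    mask = np.asarray(mask, dtype=bool)
    if imputed.shape != truth.shape or mask.shape != truth.shape:
        raise ValueError("imputed/truth/mask shapes differ")
    return imputed, truth, mask


def genotype_cr(imputed, truth, mask) -> float:
    """Fraction of masked entries whose imputed code equals the true code."""
    imputed, truth, mask = _check(imputed, truth, mask)
    if not mask.any():
        raise ValueError("empty evaluation mask")
    return float((imputed[mask] == truth[mask]).mean())


def allelic_cr(imputed, truth, mask, scope: str = "all") -> float:
    """Per-allele concordance over masked diploid entries.

    Each entry contributes two allele comparisons: with alternate-allele
    dosages c = code - 1, the number of matching alleles is 2 - |c_true -
    c_imp|. scope='minor' counts only copies of the locus's true minor
    allele in the denominator (monomorphic loci carry none and drop out).
    """
    imputed, truth, mask = _check(imputed, truth, mask)
    if not mask.any():
        raise ValueError("empty evaluation mask")
    dt = truth.astype(int) - 1
    di = imputed.astype(int) - 1
    if scope == "all":
        matches = 2 - np.abs(dt[mask] - di[mask])
        return float(matches.sum() / (2 * mask.sum()))
    if scope != "minor":
        raise ValueError(f"unknown scope {scope!r}")
    # per-locus minor allele from the truth genotypes
    p_alt = dt.mean(axis=0) / 2.0
    minor_is_alt = p_alt <= 0.5
    # dosage of the minor allele per entry
    md_t = np.where(minor_is_alt, dt, 2 - dt)
    md_i = np.where(minor_is_alt, di, 2 - di)
    denom = md_t[mask].sum()
    if denom == 0:
        raise ValueError("no true minor-allele copies among masked entries")
    correct = np.minimum(md_t, md_i)[mask].sum()
    return float(correct / denom)


def genotype_r2(imputed, truth, mask) -> float | None:
    """Squared Pearson correlation of integer codes over masked entries;
    None (undefined, not zero) when either vector is constant."""
    imputed, truth, mask = _check(imputed, truth, mask)
    if not mask.any():
        raise ValueError("empty evaluation mask")
    a = imputed[mask].astype(float)
    b = truth[mask].astype(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    r = stats.pearsonr(a, b).statistic
    return float(r * r)


def het_cr(imputed, truth, mask) -> float | None:
    """Genotype concordance restricted to masked entries that are truly
    heterozygous (code 2); None if the mask holds no heterozygotes."""
    imputed, truth, mask = _check(imputed, truth, mask)
    het = mask & (truth == 2)
    if not het.any():
        return None
    return float((imputed[het] == truth[het]).mean())


def truth_maf(truth) -> np.ndarray:
    """Per-locus minor allele frequency from the truth genotype codes."""
    truth = _as_codes(truth)
    p_alt = (truth.astype(float) - 1).mean(axis=0) / 2.0
    return np.minimum(p_alt, 1.0 - p_alt)


def maf_binned_metrics(
    imputed, truth, mask, bins: tuple[float, ...] = DEFAULT_MAF_BINS
) -> pd.DataFrame:
    """Accuracy broken down by truth minor-allele-frequency interval.

    Loci fall into half-open bins (low, high]; per bin the minor-allele CR,
    all-allele CR and genotype r2 are computed over that bin's masked
    entries. Empty bins are reported with missing values.
    """
    imputed, truth, mask = _check(imputed, truth, mask)
    maf = truth_maf(truth)
    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        in_bin = (maf > lo) & (maf <= hi)
        sub = mask & in_bin[None, :]
        row = {
            "maf_low": lo,
            "maf_high": hi,
            "n_masked": int(sub.sum()),
            "minor_cr": np.nan,
            "all_cr": np.nan,
            "r2": np.nan,
        }
        if sub.any():
            row["all_cr"] = allelic_cr(imputed, truth, sub, scope="all")
            try:
                row["minor_cr"] = allelic_cr(imputed, truth, sub, scope="minor")
            except ValueError:
                pass
            r2 = genotype_r2(imputed, truth, sub)
            row["r2"] = np.nan if r2 is None else r2
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class MetricsReport:
    """Summary of imputation accuracy against held-out truth."""

    genotype_cr: float
    allelic_cr: float
    genotype_r2: float | None
    het_cr: float | None
    per_maf_bin: pd.DataFrame
    n_masked: int

    def to_text(self) -> str:
        lines = [
            f"masked entries evaluated : {self.n_masked}",
            f"genotype CR              : {self.genotype_cr:.4f}",
            f"allelic CR (all alleles) : {self.allelic_cr:.4f}",
            "genotype r2              : "
            + ("undefined" if self.genotype_r2 is None else f"{self.genotype_r2:.4f}"),
            "heterozygous-locus CR    : "
            + ("undefined" if self.het_cr is None else f"{self.het_cr:.4f}"),
            "",
            self.per_maf_bin.to_string(index=False),
        ]
        return "\n".join(lines)

    def to_csv(self, path: str) -> None:
        self.per_maf_bin.to_csv(path, index=False)


def evaluate(imputed, truth, mask, bins: tuple[float, ...] = DEFAULT_MAF_BINS) -> MetricsReport:
    """Compute the full accuracy report for one imputation run."""
    imputed_c, truth_c, mask_b = _check(imputed, truth, mask)
    return MetricsReport(
        genotype_cr=genotype_cr(imputed_c, truth_c, mask_b),
        allelic_cr=allelic_cr(imputed_c, truth_c, mask_b, scope="all"),
        genotype_r2=genotype_r2(imputed_c, truth_c, mask_b),
        het_cr=het_cr(imputed_c, truth_c, mask_b),
        per_maf_bin=maf_binned_metrics(imputed_c, truth_c, mask_b, bins),
        n_masked=int(mask_b.sum()),
    )
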