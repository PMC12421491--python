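"""Hardy-Weinberg chi-square testing and filtering power.

A sex-determined artifact locus where males are called AA and females Aa
violates Hardy-Weinberg proportions — but a chi-square HWE filter only
catches it if enough heterozygotes are sampled. :func:`min_het_to_reject`
computes the smallest heterozygote count k among n individuals (the rest
homozygous AA, no aa) at which the test becomes significant; at n = 30 and
alpha = 0.05 with df = 2 this threshold is 19 heterozygous individuals.

On degrees of freedom: the textbook HWE test uses df = 1 (three genotype
classes, one estimated allele frequency); df = 2 treats the expected
proportions as fixed and is the more conservative variant. Both are
supported; the package default is df = 2, which is what the n=30 threshold
of 19 corresponds to (df = 1 gives 16). Plain Pearson chi-square, no
continuity correction and no exact test.

:func:`sex_aware_hwe_filter` runs the test pooled and within each sex: a
locus failing pooled HWE while conforming (or being monomorphic) within each
sex is the signature of a sex-linked artifact, not of genotyping error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class HweResult:
    n_aa: int  # homozygous reference
    n_ab: int  # heterozygous
    n_bb: int  # homozygous alternate
    p_hat: float  # estimated allele frequency of A
    chi2: float
    df: int
    p_value: float
    alpha: float = 0.05

    @property
    def n(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class PowerCurve:
    """p-value of the HWE test as a function of heterozygote count k.

    The sweep fixes n individuals with counts (n-k AA, k Aa, 0 aa) for
    k = 0..n; ``k_min`` is the smallest significant k (None if no k is).
    """

    n: int
    df: int
    alpha: float
    k: np.ndarray
    p_values: np.ndarray
    k_min: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "p_value": self.p_values})


def _chisq_stat(n_aa, n_ab, n_bb):
    """Pearson chi-square against HWE expectations; vectorized.

    Classes with zero expected count contribute 0 when the observed count is
    also 0 (monomorphic sites give chi2 = 0).
    """
    n_aa = np.asarray(n_aa, dtype=float)
    n_ab = np.asarray(n_ab, dtype=float)
    n_bb = np.asarray(n_bb, dtype=float)
    n = n_aa + n_ab + n_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n_aa + n_ab) / (2 * n)
        exp = np.stack([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        obs = np.stack([n_aa, n_ab, n_bb])
        terms = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
        chi2 = terms.sum(axis=0)
    return p, chi2


def hwe_chisq(n_aa: int, n_ab: int, n_bb: int, df: int = 2, alpha: float = 0.05) -> HweResult:
    """Chi-square HWE test from genotype counts."""
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    if n_aa + n_ab + n_bb < 1:
        raise ValueError("need at least one individual")
    if df not in (1, 2):
        raise ValueError("df must be 1 or 2")
    p, chi2 = _chisq_stat(n_aa, n_ab, n_bb)
    pval = float(stats.chi2.sf(chi2, df))
    return HweResult(int(n_aa), int(n_ab), int(n_bb), float(p), float(chi2), df, pval, alpha)


def power_curve(n: int, df: int = 2, alpha: float = 0.05) -> PowerCurve:
    """Full k = 0..n sweep of the AA/Aa-only configuration."""
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.arange(n + 1)
    _, chi2 = _chisq_stat(n - k, k, np.zeros_like(k))
    pvals = stats.chi2.sf(chi2, df)
    sig = np.flatnonzero(pvals < alpha)
    k_min = int(sig[0]) if sig.size else None
    return PowerCurve(n, df, alpha, k, pvals, k_min)


def min_het_to_reject(n: int, alpha: float = 0.05, df: int = 2) -> int | None:
    """Smallest heterozygote count among n rejecting HWE at level alpha.

    Genotype counts are (n-k AA, k Aa, 0 aa); returns None when no k in
    0..n reaches significance.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return power_curve(n, df=df, alpha=alpha).k_min


def _counts_by_locus(calls: np.ndarray):
    """(nAA, nAa, naa) per locus, missing calls excluded; dosage 0 = AA."""
    return (calls == 0).sum(axis=0), (calls == 1).sum(axis=0), (calls == 2).sum(axis=0)


def sex_aware_hwe_filter(
    matrix: GenotypeMatrix,
    sexes,
    alpha: float = 0.05,
    df: int = 2,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """HWE flags per locus, pooled and within each sex.

    Flags:

    - ``pass`` — no significant departure (loci monomorphic everywhere are
      untestable and pass);
    - ``fail_pooled_only`` — fails pooled HWE but conforms, or is
      monomorphic, within each sex: candidate sex-linked artifact;
    - ``fail_within_sex`` — departs from HWE inside at least one sex.

    ``sexes`` is an iterable of 'M'/'F'/'U' aligned to matrix samples;
    unknowns enter the pooled test only. ``bonferroni`` divides alpha by the
    locus count.
    """
    sexes = np.asarray(list(sexes))
    if sexes.shape[0] != matrix.n_samples:
        raise ValueError("sexes length does not match matrix samples")
    for sex in ("M", "F"):
        if (sexes == sex).sum() < 2:
            raise ValueError(f"need at least 2 individuals of sex {sex}")
    alpha_eff = alpha / matrix.n_loci if bonferroni else alpha

    def pvals(sub: np.ndarray):
        n_aa, n_ab, n_bb = _counts_by_locus(sub)
        n = n_aa + n_ab + n_bb
        _, chi2 = _chisq_stat(n_aa, n_ab, n_bb)
        p = stats.chi2.sf(chi2, df)
        # monomorphic = a single allele observed (all-het sites are testable)
        mono = (n_aa == n) | (n_bb == n) | (n == 0)
        return p, mono

    p_pool, mono_pool = pvals(matrix.calls)
    p_m, mono_m = pvals(matrix.calls[sexes == "M", :])
    p_f, mono_f = pvals(matrix.calls[sexes == "F", :])

    fail_pool = ~mono_pool & (p_pool < alpha_eff)
    fail_m = ~mono_m & (p_m < alpha_eff)
    fail_f = ~mono_f & (p_f < alpha_eff)

    flag = np.where(
        fail_m | fail_f,
        "fail_within_sex",
        np.where(fail_pool, "fail_pooled_only", "pass"),
    )
    n_untestable = int(mono_pool.sum())
    if n_untestable:
        logger.info("sex_aware_hwe_filter: %d untestable (monomorphic) loci pass", n_untestable)
    return pd.DataFrame(
        {
            "chrom": matrix.loci["chrom"],
            "pos": matrix.loci["pos"],
            "id": matrix.loci["id"],
            "p_pooled": p_pool,
            "p_male": p_m,
            "p_female": p_f,
            "flag": flag,
        }
    )
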