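"""Sex inference from Z-chromosome heterozygosity.

In a ZW system the homogametic males (ZZ) are ordinarily heterozygous at
polymorphic Z loci, while the hemizygous females (ZW) carry a single Z allele
that diploid callers record as a homozygous genotype. The per-individual
inbreeding coefficient on the Z,

    F = (ObsHom - ExpHom) / (L - ExpHom),

therefore clusters near 0 for males and near 1 for females (this is the
statistic PLINK's ``--check-sex`` computes; a frequently quoted variant
divides by ExpHom instead, but that form does not cluster at 1 for the
heterogametic sex). Expected homozygosity per locus uses the cohort allele
frequency with the A/(A-1) small-sample correction, A being the non-missing
allele count.

Classification uses two thresholds: F <= lower -> male, F >= upper ->
female, in between -> unknown (defaults 0.2 / 0.8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .fst import VariantFilter, filter_variants

logger = logging.getLogger(__name__)


@dataclass
class SexThresholds:
    lower: float = 0.2
    upper: float = 0.8

    def __post_init__(self) -> None:
        if not (0 <= self.lower < self.upper <= 1):
            raise ValueError(f"need 0 <= lower < upper <= 1, got {self.lower}, {self.upper}")


@dataclass
class SexEstimate:
    """Per-individual Z-heterozygosity summary and inferred label."""

    individual: str
    obs_hom: int
    exp_hom: float
    n_used: int  # non-missing Z calls entering the statistic
    F: float  # NaN when undetermined
    label: str  # 'M', 'F' or 'U'


def expected_hom(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus expected homozygosity across the cohort.

    For each locus with sample alt frequency p and non-missing allele count
    A >= 2, returns 1 - 2 p (1-p) * A/(A-1). Loci with fewer than two
    observed alleles are unusable; the second return value is the usability
    mask.

    Parameters
    ----------
    calls : (n_samples, n_loci) dosage matrix (-1 = missing)
    """
    calls = np.atleast_2d(np.asarray(calls))
    ok = calls >= 0
    A = 2 * ok.sum(axis=0)
    usable = A >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, calls, 0).sum(axis=0) / A
        exp = 1 - 2 * p * (1 - p) * A / (A - 1)
    exp = np.where(usable, exp, np.nan)
    return exp, usable


def inbreeding_f(
    ind_calls: np.ndarray, exp_hom_per_locus: np.ndarray, individual: str = ""
) -> SexEstimate:
    """F statistic for one individual from its Z calls.

    Missing calls are dropped together with their expected-homozygosity
    contribution. Degenerate cases (no usable calls, or L <= ExpHom) yield
    F = NaN and label 'U'.
    """
    ind_calls = np.asarray(ind_calls)
    exp_hom_per_locus = np.asarray(exp_hom_per_locus, dtype=float)
    keep = (ind_calls >= 0) & np.isfinite(exp_hom_per_locus)
    L = int(keep.sum())
    obs = int(np.count_nonzero(ind_calls[keep] != 1))
    e = float(exp_hom_per_locus[keep].sum())
    if L == 0 or L <= e:
        if L > 0:
            logger.warning("degenerate F for %s: L=%d <= ExpHom=%.3f", individual, L, e)
        return SexEstimate(individual, obs, e, L, float("nan"), "U")
    f = (obs - e) / (L - e)
    return SexEstimate(individual, obs, e, L, f, "U")


def classify_sex(F: float, thresholds: SexThresholds | None = None) -> str:
    """Map an F value to 'M', 'F' or 'U' (boundary values are decisive)."""
    t = thresholds or SexThresholds()
    if not np.isfinite(F):
        return "U"
    if F <= t.lower:
        return "M"
    if F >= t.upper:
        return "F"
    return "U"


def infer_sexes(
    matrix: GenotypeMatrix,
    z_chrom: str,
    thresholds: SexThresholds | None = None,
    vfilter: VariantFilter | None = None,
) -> pd.DataFrame:
    """Infer sex for every individual from Z-linked loci.

    Z loci are pre-filtered with the same MAF/missingness filters as the
    genome scan before computing F. Returns a DataFrame with columns
    ``id, obs_hom, exp_hom, n_z, F, sex_inferred`` in matrix sample order;
    per-label counts are logged.
    """
    thresholds = thresholds or SexThresholds()
    z_idx = matrix.loci_on(z_chrom)
    if z_idx.size == 0:
        available = sorted(matrix.loci["chrom"].astype(str).unique())
        raise ValueError(f"no loci on chromosome {z_chrom!r}; available: {available}")

    zmat = filter_variants(matrix.subset_loci(z_idx), vfilter or VariantFilter())
    if zmat.n_loci == 0:
        logger.warning("all Z loci removed by filters; every individual labeled U")
        return pd.DataFrame(
            {"id": matrix.samples, "obs_hom": 0, "exp_hom": 0.0, "n_z": 0,
             "F": np.nan, "sex_inferred": "U"}
        )

    exp, _usable = expected_hom(zmat.calls)
    rows = []
    for i, sample in enumerate(zmat.samples):
        est = inbreeding_f(zmat.calls[i], exp, sample)
        est.label = classify_sex(est.F, thresholds)
        rows.append((sample, est.obs_hom, est.exp_hom, est.n_used, est.F, est.label))
    out = pd.DataFrame(rows, columns=["id", "obs_hom", "exp_hom", "n_z", "F", "sex_inferred"])
    counts = out["sex_inferred"].value_counts()
    logger.info(
        "sex inference over %d Z loci: %d male, %d female, %d unknown",
        zmat.n_loci, counts.get("M", 0), counts.get("F", 0), counts.get("U", 0),
    )
    return out
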