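"""Per-SNP Weir & Cockerham (1984) differentiation for arbitrary contrasts.

The estimator decomposes allele-frequency variance at a single biallelic
locus into three components:

    a — variance between groups,
    b — variance between individuals within groups,
    c — variance within individuals (heterozygosity),

and reports theta = a / (a + b + c). Groups can be anything — male vs female,
population vs population — which is exactly what makes the estimator
vulnerable to sex-determined artifact loci: contrasting 54 males against 54
females at a locus where sexes are fixed for opposite alleles yields
theta = 1, and a male-homozygous/female-heterozygous locus yields 0.5.

Semantics mirror per-site ``vcftools --weir-fst-pop`` (window size 1):
missing genotypes reduce the per-group sample size, negative theta values
are reported as computed, and monomorphic sites give NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class VariantFilter:
    """PLINK-style variant filters: ``--maf`` and ``--geno``.

    ``geno_max_missing`` is the largest tolerated missing-call fraction per
    locus; ``maf_min`` the smallest tolerated minor-allele frequency,
    computed on retained individuals.
    """

    maf_min: float = 0.01
    geno_max_missing: float = 0.8

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must be in [0, 0.5]")
        if not (0 <= self.geno_max_missing <= 1):
            raise ValueError("geno_max_missing must be in [0, 1]")


@dataclass
class GroupAlleleStats:
    """Per-group sample sizes, alt-allele frequencies and het proportions.

    Arrays are aligned over groups; entries may be 2-D ``(r, L)`` when a
    whole scan is evaluated at once.
    """

    n: np.ndarray  # non-missing diploid individuals per group
    p: np.ndarray  # alt-allele frequency per group
    h: np.ndarray  # observed heterozygote proportion per group

    @property
    def r(self) -> int:
        return self.n.shape[0]


@dataclass
class FstRecord:
    """Variance components and theta for one locus under one grouping."""

    locus_id: str
    nbar: float
    nc: float
    pbar: float
    s2: float
    hbar: float
    a: float
    b: float
    c: float
    theta: float


def allele_stats(calls: np.ndarray, groups: Sequence[np.ndarray]) -> GroupAlleleStats:
    """Per-group allele statistics at one locus from dosage calls.

    ``groups`` are index arrays into ``calls``; missing calls (−1) are
    dropped per group. Raises if fewer than two groups retain data.
    """
    calls = np.asarray(calls)
    n, p, h = [], [], []
    for g in groups:
        sub = calls[np.asarray(g, dtype=np.intp)]
        sub = sub[sub >= 0]
        n_i = sub.size
        n.append(n_i)
        p.append(sub.sum() / (2 * n_i) if n_i else np.nan)
        h.append(np.count_nonzero(sub == 1) / n_i if n_i else np.nan)
    n = np.asarray(n, dtype=float)
    if np.count_nonzero(n > 0) < 2:
        raise ValueError("need non-missing calls in at least 2 groups")
    return GroupAlleleStats(n=n, p=np.asarray(p), h=np.asarray(h))


def _components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Weir-Cockerham a, b, c from per-group (n, p, h); group axis first.

    Broadcasts over any trailing axes, so a whole locus table can be
    evaluated in one call. Returns (nbar, nc, pbar, s2, hbar, a, b, c,
    theta); undefined entries (nbar <= 1, zero total variance) are NaN.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[0]
    if r < 2:
        raise ValueError("need at least 2 groups")
    squeeze = n.ndim == 1
    if squeeze:
        n, p, h = n[:, None], p[:, None], h[:, None]

    with np.errstate(invalid="ignore", divide="ignore"):
        nsum = n.sum(axis=0)
        nbar = nsum / r
        nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n * p).sum(axis=0) / nsum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / nsum

        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2

        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
        undefined = ~(nbar > 1)
        for arr in (a, b, c, theta):
            arr[...] = np.where(undefined, np.nan, arr)
    out = (nbar, nc, pbar, s2, hbar, a, b, c, theta)
    if squeeze:
        out = tuple(np.squeeze(x, axis=-1) for x in out)
    return out


def wc_components(stats: GroupAlleleStats, locus_id: str = "") -> FstRecord:
    """Evaluate the variance components for one locus."""
    nbar, nc, pbar, s2, hbar, a, b, c, theta = _components(
        stats.n.astype(float), stats.p, stats.h
    )
    return FstRecord(
        locus_id, float(nbar), float(nc), float(pbar), float(s2), float(hbar),
        float(a), float(b), float(c), float(theta),
    )


def _group_stats_matrix(calls: np.ndarray, groups: Sequence[np.ndarray]):
    """(r, L) arrays of n, p, h over all loci for the given sample groups."""
    ns, ps, hs = [], [], []
    for g in groups:
        sub = calls[np.asarray(g, dtype=np.intp), :]
        ok = sub >= 0
        n_i = ok.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(ok, sub, 0).sum(axis=0) / (2 * n_i)
            h_i = (sub == 1).sum(axis=0) / n_i
        ns.append(n_i)
        ps.append(p_i)
        hs.append(h_i)
    return np.stack(ns), np.stack(ps), np.stack(hs)


def theta_at(matrix_or_calls, groups: Sequence[Sequence[str]] | Sequence[np.ndarray], locus=None) -> float:
    """Convenience: theta for one locus.

    With a :class:`GenotypeMatrix`, ``groups`` are id lists and ``locus`` a
    ``(chrom, pos)`` pair or integer index; with a raw call vector, ``groups``
    are index arrays.
    """
    if isinstance(matrix_or_calls, GenotypeMatrix):
        m = matrix_or_calls
        if locus is None:
            raise ValueError("locus required with a GenotypeMatrix")
        j = locus if isinstance(locus, (int, np.integer)) else m.locus_index(*locus)
        calls = m.calls[:, j]
        groups = [m.sample_indices(g) for g in groups]
    else:
        calls = np.asarray(matrix_or_calls)
    try:
        stats = allele_stats(calls, groups)
    except ValueError:
        return float("nan")
    return wc_components(stats).theta


def filter_variants(matrix: GenotypeMatrix, vfilter: VariantFilter | None = None) -> GenotypeMatrix:
    """Drop loci failing the missingness filter, then the MAF filter."""
    vfilter = vfilter or VariantFilter()
    calls = matrix.calls
    miss_frac = (calls < 0).mean(axis=0)
    keep = miss_frac <= vfilter.geno_max_missing

    ok = calls >= 0
    n_alleles = 2 * ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, calls, 0).sum(axis=0) / n_alleles
    maf = np.minimum(p, 1 - p)
    keep &= np.where(n_alleles > 0, maf >= vfilter.maf_min, False)

    dropped = matrix.n_loci - int(keep.sum())
    if dropped:
        logger.info("filter_variants: dropped %d of %d loci", dropped, matrix.n_loci)
    return matrix.subset_loci(keep)


def fst_scan(
    matrix: GenotypeMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    vfilter: VariantFilter | None = None,
    clamp_zero: bool = False,
) -> pd.DataFrame:
    """Per-site Weir-Cockerham scan between two sample groups.

    Returns one row per locus passing the variant filters, sorted by
    chromosome then position, with columns mirroring per-site
    ``vcftools --weir-fst-pop`` output: CHROM, POS, ID, N_A, N_B, A, B, C,
    THETA. Loci where either group has no data are skipped (counted in the
    log). Negative theta is reported as computed unless ``clamp_zero``.
    """
    a_set, b_set = set(group_a), set(group_b)
    overlap = a_set & b_set
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if not a_set or not b_set:
        raise ValueError("both groups must be non-empty")

    sub = filter_variants(matrix, vfilter) if vfilter is not False else matrix
    if sub.n_loci == 0:
        logger.warning("fst_scan: no loci pass filters")
        return _empty_scan_table()

    idx_a = sub.sample_indices(group_a)
    idx_b = sub.sample_indices(group_b)
    n, p, h = _group_stats_matrix(sub.calls, [idx_a, idx_b])
    *_, a_comp, b_comp, c_comp, theta = _components(n, p, h)

    usable = (n > 0).sum(axis=0) >= 2
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("fst_scan: skipped %d loci with data in < 2 groups", n_skipped)

    if clamp_zero:
        theta = np.maximum(theta, 0.0)

    out = pd.DataFrame(
        {
            "CHROM": sub.loci["chrom"].astype(str),
            "POS": sub.loci["pos"].astype(int),
            "ID": sub.loci["id"],
            "N_A": n[0].astype(int),
            "N_B": n[1].astype(int),
            "A": a_comp,
            "B": b_comp,
            "C": c_comp,
            "THETA": theta,
        }
    )[usable]
    return out.sort_values(["CHROM", "POS"], kind="stable").reset_index(drop=True)


def weighted_fst(scan: pd.DataFrame) -> float:
    """Genome-wide Weir-Cockerham estimate from a scan table.

    The ratio of summed variance components sum(a) / sum(a+b+c) — the
    "weighted FST" of vcftools. Unlike the per-locus average of theta
    ratios, its expectation equals the model differentiation parameter, so
    it is the quantity to compare against a simulation's generating value.
    """
    num = scan["A"].sum()
    den = (scan["A"] + scan["B"] + scan["C"]).sum()
    if den == 0:
        return float("nan")
    return float(num / den)


def _empty_scan_table() -> pd.DataFrame:
    return pd.DataFrame(
        {c: pd.Series(dtype=t) for c, t in [
            ("CHROM", str), ("POS", int), ("ID", str), ("N_A", int), ("N_B", int),
            ("A", float), ("B", float), ("C", float), ("THETA", float),
        ]}
    )
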