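"""Mechanistic classification of sex-differentiated loci.

A locus that separates males from females in a genome scan can do so for
several reasons, each with a distinct genotype signature:

- ``fixed_between_sex_paralog`` — both sexes (nearly) fixed for *different*
  alleles with male-vs-female theta near 1: a diverged W-linked homologue
  whose reads/probes overwrite the autosomal signal in females entirely.
  Action: exclude the locus and validate it molecularly.
- ``sex_limited_het_paralog`` — one sex (nearly) all heterozygous, the other
  homozygous, theta near 0.5: the W (or Z) copy adds a second "allele" in
  the heterogametic sex only. Same action.
- ``z_linked_dosage`` — a locus on the Z chromosome where females show no
  heterozygosity: ordinary hemizygosity, not an artifact. Analyze the sexes
  separately rather than discarding the locus.
- ``unremarkable`` — everything else; keep.

A female/male coverage ratio >= 1.5, when depth data are supplied, is
recorded as corroborating evidence for the paralog categories (mis-mapped
W reads pile up extra female coverage); it never changes the category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .fst import _components, _group_stats_matrix, allele_stats, wc_components

logger = logging.getLogger(__name__)

CATEGORY_ACTIONS = {
    "fixed_between_sex_paralog": "exclude_and_validate",
    "sex_limited_het_paralog": "exclude_and_validate",
    "z_linked_dosage": "analyze_by_sex",
    "unremarkable": "keep",
}


@dataclass
class ClassifyThresholds:
    """Fuzzy rule thresholds; defaults tolerate real-data noise where
    observed theta at fixed-difference artifacts is ~0.96 rather than 1."""

    fixed_frac: float = 0.95  # fraction of a sex fixed for its modal homozygote
    het_frac: float = 0.90  # fraction heterozygous / homozygous for rule 2
    theta_fixed_min: float = 0.9
    theta_het_band: tuple[float, float] = (0.3, 0.7)
    female_het_max: float = 0.05  # "no heterozygosity" for the Z dosage rule
    coverage_ratio_min: float = 1.5
    min_per_sex: int = 5


@dataclass
class SexGenotypeProfile:
    """Per-sex genotype summary of one locus."""

    locus_id: str
    chrom: str
    pos: int
    counts_m: tuple[int, int, int]  # (AA, Aa, aa) among males
    counts_f: tuple[int, int, int]
    het_m: float
    het_f: float
    theta_mf: float
    coverage_ratio: float | None = None  # female/male mean depth
    testable: bool = True

    def _fixation(self, counts: tuple[int, int, int]) -> tuple[int, float]:
        """(modal homozygote dosage, its fraction of non-missing calls)."""
        n = sum(counts)
        if n == 0:
            return -1, 0.0
        dosage = 0 if counts[0] >= counts[2] else 2
        frac = counts[0] / n if dosage == 0 else counts[2] / n
        return dosage, frac


def sex_genotype_profile(
    calls: np.ndarray,
    sexes,
    locus_id: str = "",
    chrom: str = "",
    pos: int = 0,
    depth: np.ndarray | None = None,
    min_per_sex: int = 5,
) -> SexGenotypeProfile:
    """Build the per-sex profile for one locus.

    ``sexes`` aligns to ``calls``; 'U' individuals are ignored. A locus with
    fewer than ``min_per_sex`` non-missing calls in either sex is marked
    untestable (theta and heterozygosities NaN).
    """
    calls = np.asarray(calls)
    sexes = np.asarray(list(sexes))
    idx_m = np.flatnonzero(sexes == "M")
    idx_f = np.flatnonzero(sexes == "F")

    def counts(idx):
        sub = calls[idx]
        sub = sub[sub >= 0]
        return (int((sub == 0).sum()), int((sub == 1).sum()), int((sub == 2).sum()))

    cm, cf = counts(idx_m), counts(idx_f)
    n_m, n_f = sum(cm), sum(cf)
    testable = n_m >= min_per_sex and n_f >= min_per_sex

    het_m = cm[1] / n_m if n_m else np.nan
    het_f = cf[1] / n_f if n_f else np.nan
    theta = np.nan
    if testable:
        theta = wc_components(allele_stats(calls, [idx_m, idx_f])).theta

    cov = None
    if depth is not None:
        depth = np.asarray(depth, dtype=float)
        mean_m = depth[idx_m].mean() if idx_m.size else np.nan
        mean_f = depth[idx_f].mean() if idx_f.size else np.nan
        cov = float(mean_f / mean_m) if mean_m and np.isfinite(mean_m) else None

    return SexGenotypeProfile(
        locus_id, str(chrom), int(pos), cm, cf, het_m, het_f, float(theta), cov, testable
    )


@dataclass
class LocusCall:
    category: str
    action: str
    evidence: list[str] = field(default_factory=list)


def classify_locus(
    profile: SexGenotypeProfile,
    thresholds: ClassifyThresholds | None = None,
    z_chrom: str | None = None,
) -> LocusCall:
    """Apply the diagnostic rules, in order of decreasing specificity."""
    t = thresholds or ClassifyThresholds()
    if not profile.testable:
        return LocusCall("unremarkable", "keep", ["untestable: insufficient per-sex data"])

    dos_m, fix_m = profile._fixation(profile.counts_m)
    dos_f, fix_f = profile._fixation(profile.counts_f)
    evidence: list[str] = []
    category = "unremarkable"

    # rule 1: fixed difference between the sexes
    if (
        fix_m >= t.fixed_frac
        and fix_f >= t.fixed_frac
        and dos_m != dos_f
        and dos_m >= 0
        and dos_f >= 0
        and profile.theta_mf >= t.theta_fixed_min
    ):
        category = "fixed_between_sex_paralog"
        evidence.append(
            f"sexes fixed for opposite alleles ({fix_m:.2f}/{fix_f:.2f}), "
            f"theta_mf={profile.theta_mf:.3f}"
        )
    else:
        # rule 2: one sex heterozygous, the other homozygous
        hom_m = 1 - profile.het_m
        hom_f = 1 - profile.het_f
        lo, hi = t.theta_het_band
        if lo <= profile.theta_mf <= hi and (
            (profile.het_f >= t.het_frac and hom_m >= t.het_frac)
            or (profile.het_m >= t.het_frac and hom_f >= t.het_frac)
        ):
            category = "sex_limited_het_paralog"
            which = "females" if profile.het_f >= t.het_frac else "males"
            evidence.append(
                f"{which} heterozygous, other sex homozygous, theta_mf={profile.theta_mf:.3f}"
            )
        elif (
            z_chrom is not None
            and profile.chrom == str(z_chrom)
            and np.isfinite(profile.het_f)
            and profile.het_f <= t.female_het_max
        ):
            category = "z_linked_dosage"
            evidence.append(f"Z-linked locus, female heterozygosity {profile.het_f:.3f}")

    if (
        category in ("fixed_between_sex_paralog", "sex_limited_het_paralog")
        and profile.coverage_ratio is not None
        and profile.coverage_ratio >= t.coverage_ratio_min
    ):
        evidence.append(f"female/male coverage ratio {profile.coverage_ratio:.1f} (corroborating)")

    return LocusCall(category, CATEGORY_ACTIONS[category], evidence)


def scan_report(
    matrix: GenotypeMatrix,
    sexes,
    depth: np.ndarray | None = None,
    report_threshold: float = 0.4,
    thresholds: ClassifyThresholds | None = None,
    z_chrom: str | None = None,
) -> pd.DataFrame:
    """Classify every locus with male-vs-female theta above the threshold.

    Returns a table (CHROM, POS, ID, THETA_MF, CATEGORY, ACTION, EVIDENCE)
    of elevated loci; per-category counts are logged. ``depth`` is an
    optional matrix aligned to ``matrix.calls``.
    """
    t = thresholds or ClassifyThresholds()
    sexes = np.asarray(list(sexes))
    idx_m = np.flatnonzero(sexes == "M")
    idx_f = np.flatnonzero(sexes == "F")
    n, p, h = _group_stats_matrix(matrix.calls, [idx_m, idx_f])
    *_, theta = _components(n, p, h)

    with np.errstate(invalid="ignore"):
        elevated = np.flatnonzero(np.nan_to_num(theta, nan=-np.inf) > report_threshold)

    rows = []
    for j in elevated:
        prof = sex_genotype_profile(
            matrix.calls[:, j],
            sexes,
            locus_id=str(matrix.loci["id"].iloc[j]),
            chrom=str(matrix.loci["chrom"].iloc[j]),
            pos=int(matrix.loci["pos"].iloc[j]),
            depth=None if depth is None else depth[:, j],
            min_per_sex=t.min_per_sex,
        )
        call = classify_locus(prof, t, z_chrom=z_chrom)
        rows.append(
            (prof.chrom, prof.pos, prof.locus_id, prof.theta_mf,
             call.category, call.action, "; ".join(call.evidence))
        )
    out = pd.DataFrame(
        rows, columns=["CHROM", "POS", "ID", "THETA_MF", "CATEGORY", "ACTION", "EVIDENCE"]
    ).sort_values(["CHROM", "POS"], kind="stable").reset_index(drop=True)
    if len(out):
        logger.info(
            "scan_report: %d loci above theta %.2f — %s",
            len(out), report_threshold, out["CATEGORY"].value_counts().to_dict(),
        )
    return out
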