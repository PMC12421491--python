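"""Synthetic ZW cohorts with planted sex-linked artifact loci.

Birds (and other ZW taxa) have heterogametic females: a female carries one Z
and one W, a male two Z copies. Diploid genotype callers do not know this, so
a female's single Z allele is recorded as a homozygous diploid call. When the
W chromosome is absent from the reference assembly, reads or probes from a
W-linked paralog collapse onto its autosomal or Z counterpart and produce
"artifact" loci whose calls are a deterministic function of sex:

``het_call``
    every female appears heterozygous (her autosomal allele plus the diverged
    W copy), every male homozygous reference — the male-vs-female FST ~ 0.5
    class.
``split_call``
    the two sexes appear fixed for opposite alleles — the FST ~ 1 class.

Background differentiation between populations follows the Balding-Nichols
model: per-population allele frequencies are Beta-distributed around an
ancestral frequency with differentiation parameter ``F_bg``, which gives the
simulator a closed-form expected FST to test against.

Artifact loci are simulated at the call level; read depth is a separate
Poisson overlay (:func:`simulate_depth`) with female-specific inflation at
artifact loci, mimicking the pile-up of mis-mapped W reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, make_sample_table

logger = logging.getLogger(__name__)

ARTIFACT_REGIMES = ("het_call", "split_call")
LOCUS_CLASSES = ("autosomal", "z_linked", "artifact_het", "artifact_split")


@dataclass
class ArtifactSpec:
    """A planted sex-determined locus.

    ``coverage_multiplier`` is the female/male mean-depth ratio at the locus
    (>= 1); it only affects :func:`simulate_depth`, never the calls.
    """

    chrom: str
    pos: int
    regime: str
    coverage_multiplier: float = 6.0

    def __post_init__(self) -> None:
        if self.regime not in ARTIFACT_REGIMES:
            raise ValueError(f"regime must be one of {ARTIFACT_REGIMES}, got {self.regime!r}")
        if self.coverage_multiplier < 1:
            raise ValueError("coverage_multiplier must be >= 1")
        self.pos = int(self.pos)
        self.chrom = str(self.chrom)


@dataclass
class LocusTruth:
    """Simulator ground truth for one locus.

    ``p_pop`` maps population name to the generating alt-allele frequency;
    it is ``None`` for artifact classes, whose calls are sex-determined.
    """

    locus_id: str
    locus_class: str
    p_pop: dict[str, float] | None
    coverage_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.locus_class not in LOCUS_CLASSES:
            raise ValueError(f"unknown locus class {self.locus_class!r}")
        if self.locus_class.startswith("artifact") and self.p_pop is not None:
            raise ValueError("artifact loci have no generating frequency")


@dataclass
class SimConfig:
    """Cohort simulation parameters.

    populations : list of (name, n_males, n_females)
    L_auto, L_z : numbers of autosomal and Z-linked background loci
    artifact_loci : planted sex-determined loci
    maf_range : interval in (0, 0.5] for the ancestral allele frequency draw
    F_bg : Balding-Nichols between-population differentiation in [0, 1);
        0 means all populations share the ancestral frequency exactly
    missing_rate : i.i.d. probability a call is dropped to missing
    error_rate : optional per-call error probability (a called genotype is
        replaced by one of the other two dosages, uniformly); defaults to 0
    """

    populations: list[tuple[str, int, int]]
    L_auto: int = 1000
    L_z: int = 200
    artifact_loci: list[ArtifactSpec] = field(default_factory=list)
    maf_range: tuple[float, float] = (0.05, 0.5)
    F_bg: float = 0.0
    missing_rate: float = 0.0
    error_rate: float = 0.0
    auto_chrom: str = "1"
    z_chrom: str = "Z"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("at least one population required")
        self.populations = [(str(n), int(m), int(f)) for n, m, f in self.populations]
        for name, m, f in self.populations:
            if m < 0 or f < 0:
                raise ValueError(f"negative count in population {name!r}")
        if self.L_auto < 0 or self.L_z < 0:
            raise ValueError("locus counts must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0 <= self.F_bg < 1):
            raise ValueError("F_bg must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")

    @property
    def n_individuals(self) -> int:
        return sum(m + f for _, m, f in self.populations)


def _population_frequencies(
    p_anc: np.ndarray, F: float, n_pops: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_pops, L) Balding-Nichols frequencies around ancestral p_anc."""
    if F == 0:
        return np.broadcast_to(p_anc, (n_pops, p_anc.size)).copy()
    scale = (1 - F) / F
    return rng.beta(p_anc * scale, (1 - p_anc) * scale, size=(n_pops, p_anc.size))


def simulate_cohort(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame, list[LocusTruth]]:
    """Simulate genotype calls for a ZW cohort.

    Returns the genotype matrix, a sample table carrying true sexes, and the
    per-locus ground truth. Locus order is: autosomal, artifact, Z-linked.
    Deterministic for a fixed ``config.seed``; sub-streams are derived per
    stage (frequencies, genotypes, errors, missingness) so each stage is
    independently reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_freq, rng_geno, rng_err, rng_miss = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    pop_names = [name for name, _, _ in config.populations]
    ids, pops, sexes = [], [], []
    for name, n_m, n_f in config.populations:
        for i in range(n_m):
            ids.append(f"{name}_M{i:03d}")
            pops.append(name)
            sexes.append("M")
        for i in range(n_f):
            ids.append(f"{name}_F{i:03d}")
            pops.append(name)
            sexes.append("F")
    samples = make_sample_table(ids, pops, sexes)
    n_ind = len(ids)
    is_female = np.asarray([s == "F" for s in sexes])
    pop_index = np.asarray([pop_names.index(p) for p in pops])

    lo, hi = config.maf_range
    L_bg = config.L_auto + config.L_z
    p_anc = rng_freq.uniform(lo, hi, size=L_bg)
    p_pops = _population_frequencies(p_anc, config.F_bg, len(pop_names), rng_freq)
    p_auto, p_z = p_pops[:, : config.L_auto], p_pops[:, config.L_auto :]

    # per-individual generating frequency rows
    calls_auto = rng_geno.binomial(2, p_auto[pop_index, :]).astype(np.int8)

    # Z: males draw two alleles; hemizygous females draw one, recorded as the
    # corresponding homozygote (diploid coding) — never heterozygous
    calls_z = rng_geno.binomial(2, p_z[pop_index, :]).astype(np.int8)
    female_z = 2 * rng_geno.binomial(1, p_z[pop_index, :][is_female]).astype(np.int8)
    calls_z[is_female] = female_z

    art_cols = []
    for spec in config.artifact_loci:
        col = np.zeros(n_ind, dtype=np.int8)
        col[is_female] = 1 if spec.regime == "het_call" else 2
        art_cols.append(col)
    calls_art = (
        np.stack(art_cols, axis=1) if art_cols else np.empty((n_ind, 0), dtype=np.int8)
    )

    calls = np.concatenate([calls_auto, calls_art, calls_z], axis=1)

    loci = _locus_table(config)
    truth = _truth_list(config, loci, p_auto, p_z, pop_names)

    if config.error_rate > 0:
        flip = rng_err.random(calls.shape) < config.error_rate
        # replace by one of the two other dosages, uniformly
        shift = rng_err.integers(1, 3, size=calls.shape)
        calls = np.where(flip, (calls + shift) % 3, calls).astype(np.int8)

    if config.missing_rate > 0:
        drop = rng_miss.random(calls.shape) < config.missing_rate
        calls = np.where(drop, MISSING, calls).astype(np.int8)

    matrix = GenotypeMatrix(calls, loci, ids)
    logger.info(
        "simulated cohort: %d individuals (%d populations), %d loci "
        "(%d autosomal, %d artifact, %d Z-linked), seed=%d",
        n_ind, len(pop_names), matrix.n_loci, config.L_auto,
        len(config.artifact_loci), config.L_z, config.seed,
    )
    return matrix, samples, truth


def _locus_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.L_auto):
        pos = 1000 * (i + 1)
        rows.append((config.auto_chrom, pos, f"auto_{i:05d}", "A", "G"))
    for spec in config.artifact_loci:
        rows.append((spec.chrom, spec.pos, f"artifact_{spec.chrom}_{spec.pos}", "A", "G"))
    for i in range(config.L_z):
        pos = 1000 * (i + 1)
        rows.append((config.z_chrom, pos, f"z_{i:05d}", "A", "G"))
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])


def _truth_list(
    config: SimConfig,
    loci: pd.DataFrame,
    p_auto: np.ndarray,
    p_z: np.ndarray,
    pop_names: list[str],
) -> list[LocusTruth]:
    truth: list[LocusTruth] = []
    ids = loci["id"].tolist()
    j = 0
    for i in range(config.L_auto):
        truth.append(
            LocusTruth(ids[j], "autosomal", dict(zip(pop_names, p_auto[:, i].tolist())))
        )
        j += 1
    for spec in config.artifact_loci:
        cls = "artifact_het" if spec.regime == "het_call" else "artifact_split"
        truth.append(LocusTruth(ids[j], cls, None, spec.coverage_multiplier))
        j += 1
    for i in range(config.L_z):
        truth.append(
            LocusTruth(ids[j], "z_linked", dict(zip(pop_names, p_z[:, i].tolist())))
        )
        j += 1
    return truth


def simulate_depth(
    truth: list[LocusTruth],
    samples: pd.DataFrame,
    d0: float,
    seed: int,
) -> np.ndarray:
    """Per-cell Poisson read depths, female-inflated at artifact loci.

    Depth is Poisson(d0) everywhere except that a female's mean at an
    artifact locus is ``d0 * coverage_multiplier`` — mis-mapped W-linked
    reads add coverage in the sex that carries the W.
    """
    if d0 <= 0:
        raise ValueError("d0 must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    is_female = (samples["sex"] == "F").to_numpy()
    mult = np.asarray(
        [t.coverage_multiplier if t.locus_class.startswith("artifact") else 1.0 for t in truth]
    )
    lam = np.where(is_female[:, None], d0 * mult[None, :], d0)
    return rng.poisson(lam)
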