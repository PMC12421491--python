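"""Balanced subsampling and the sex-ratio subsampling grid.

Contrasting two population samples of fixed size but varying male:female
composition shows how strongly FST at a sex-determined locus depends on who
was sampled rather than on any biological differentiation: across the
default 5x5 grid of ratios (0:12, 3:9, 6:6, 9:3, 12:0 in each sample) the
per-site theta at a split-call artifact locus ranges over the full [0, 1]
interval.

Subsampling streams are keyed by (seed, pool content, ratio) rather than by
argument position, so swapping the two pools transposes the grid exactly,
and each ratio reuses one fixed draw of individuals across the grid (one
draw per ratio, as in a single-panel figure; use ``replicates`` to average
over redraws).
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .fst import allele_stats, wc_components

logger = logging.getLogger(__name__)

#: the canonical male:female ratio sweep for 12-individual samples
DEFAULT_RATIOS: tuple[tuple[int, int], ...] = ((0, 12), (3, 9), (6, 6), (9, 3), (12, 0))


@dataclass
class RatioSpec:
    """(n_males, n_females) compositions to sweep in each sample."""

    ratios: tuple[tuple[int, int], ...] = DEFAULT_RATIOS

    def __post_init__(self) -> None:
        self.ratios = tuple((int(m), int(f)) for m, f in self.ratios)
        if not self.ratios:
            raise ValueError("need at least one ratio")
        for m, f in self.ratios:
            if m < 0 or f < 0:
                raise ValueError("counts must be >= 0")
            if m + f == 0:
                raise ValueError("each ratio needs at least one individual")

    @property
    def max_males(self) -> int:
        return max(m for m, _ in self.ratios)

    @property
    def max_females(self) -> int:
        return max(f for _, f in self.ratios)


@dataclass
class RatioGrid:
    """Theta values over all (ratio_A, ratio_B) cells at one focal locus.

    Cells where theta is undefined (monomorphic in both subsamples, e.g. the
    all-male vs all-male corner of a split-call locus) are NaN — untestable,
    which is not the same as undifferentiated.
    """

    locus: str
    ratios: tuple[tuple[int, int], ...]
    thetas: np.ndarray  # (len(ratios), len(ratios)); rows = sample A
    pool_a: str = "A"
    pool_b: str = "B"

    def labels(self, pool: str) -> list[str]:
        # Figure-style labels: "<pool>.03f09m" = 3 females + 9 males
        return [f"{pool}.{f:02d}f{m:02d}m" for m, f in self.ratios]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.thetas, index=self.labels(self.pool_a), columns=self.labels(self.pool_b)
        )


def select_balanced(
    samples: pd.DataFrame, population: str, n_per_sex: int, seed: int
) -> list[str]:
    """Draw n males and n females from one population, without replacement.

    Raises with the available per-sex counts when the population cannot
    supply the requested numbers (such populations are excluded from
    balanced designs).
    """
    pop = samples[samples["population"] == population]
    males = pop.loc[pop["sex"] == "M", "id"].tolist()
    females = pop.loc[pop["sex"] == "F", "id"].tolist()
    if len(males) < n_per_sex or len(females) < n_per_sex:
        raise ValueError(
            f"population {population!r} has {len(males)} males / {len(females)} females; "
            f"need {n_per_sex} of each — excluded"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pick_m = rng.choice(len(males), size=n_per_sex, replace=False)
    pick_f = rng.choice(len(females), size=n_per_sex, replace=False)
    return [males[i] for i in sorted(pick_m)] + [females[i] for i in sorted(pick_f)]


def _pool_stream(seed: int, pool_ids: list[str], ratio: tuple[int, int], replicate: int):
    """RNG keyed by pool content (not argument position) for transposability."""
    digest = zlib.crc32("\n".join(sorted(pool_ids)).encode())
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), digest, ratio[0], ratio[1], replicate])
    )


def _draw(pool: pd.DataFrame, ratio: tuple[int, int], rng) -> list[str]:
    n_m, n_f = ratio
    males = sorted(pool.loc[pool["sex"] == "M", "id"])
    females = sorted(pool.loc[pool["sex"] == "F", "id"])
    pick_m = rng.choice(len(males), size=n_m, replace=False) if n_m else []
    pick_f = rng.choice(len(females), size=n_f, replace=False) if n_f else []
    return [males[i] for i in pick_m] + [females[i] for i in pick_f]


def sexratio_grid(
    matrix: GenotypeMatrix,
    pool_a: pd.DataFrame,
    pool_b: pd.DataFrame,
    locus: tuple[str, int] | int,
    ratios: RatioSpec | None = None,
    seed: int = 0,
    replicates: int = 1,
    pool_a_name: str = "A",
    pool_b_name: str = "B",
) -> RatioGrid:
    """Per-site theta at one locus over all pairs of sex-ratio compositions.

    ``pool_a`` / ``pool_b`` are sample-table slices (columns id, sex) of the
    two pools; each must contain at least the maximum requested number of
    males and of females. With ``replicates > 1`` each cell averages theta
    over independent seeded redraws (NaN draws ignored).
    """
    ratios = ratios or RatioSpec()
    for name, pool in ((pool_a_name, pool_a), (pool_b_name, pool_b)):
        n_m = int((pool["sex"] == "M").sum())
        n_f = int((pool["sex"] == "F").sum())
        if n_m < ratios.max_males or n_f < ratios.max_females:
            raise ValueError(
                f"pool {name!r} has {n_m} males / {n_f} females; grid needs "
                f"{ratios.max_males} males and {ratios.max_females} females"
            )

    j = locus if isinstance(locus, (int, np.integer)) else matrix.locus_index(*locus)
    calls = matrix.calls[:, j]
    locus_id = str(matrix.loci["id"].iloc[j])

    n_r = len(ratios.ratios)
    per_rep = np.full((replicates, n_r, n_r), np.nan)
    for rep in range(replicates):
        draws_a = [
            matrix.sample_indices(_draw(pool_a, r, _pool_stream(seed, list(pool_a["id"]), r, rep)))
            for r in ratios.ratios
        ]
        draws_b = [
            matrix.sample_indices(_draw(pool_b, r, _pool_stream(seed, list(pool_b["id"]), r, rep)))
            for r in ratios.ratios
        ]
        for ia in range(n_r):
            for ib in range(n_r):
                try:
                    stats = allele_stats(calls, [draws_a[ia], draws_b[ib]])
                    per_rep[rep, ia, ib] = wc_components(stats).theta
                except ValueError:
                    pass  # < 2 groups with data: cell stays NaN
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        thetas = np.nanmean(per_rep, axis=0)
    return RatioGrid(locus_id, ratios.ratios, thetas, pool_a_name, pool_b_name)


def grid_summary(grid: RatioGrid, clamp_zero: bool = False) -> dict:
    """Extremes over defined (non-NaN) cells plus the labeled table.

    ``clamp_zero`` floors negative theta estimates at 0 for the summary
    (the usual display convention); cell values in the table are untouched.
    """
    defined = grid.thetas[np.isfinite(grid.thetas)]
    if defined.size == 0:
        raise ValueError("all grid cells are undefined")
    if clamp_zero:
        defined = np.maximum(defined, 0.0)
    lo, hi = float(defined.min()), float(defined.max())
    return {"min": lo, "max": hi, "range": hi - lo, "table": grid.to_frame()}
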