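"""In-memory containers shared by all analysis stages.

The central object is :class:`GenotypeMatrix`: diploid biallelic calls for a
cohort, coded as alternate-allele dosage (0, 1, 2) with ``-1`` for missing.
Sample metadata travels as a plain :class:`pandas.DataFrame` with columns
``id``, ``population`` and ``sex`` (``M``/``F``/``U``), the same layout the
TSV readers and writers use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: columns every locus table must carry; positions are 1-based (VCF convention)
LOCUS_COLUMNS = ("chrom", "pos", "id", "ref", "alt")

SAMPLE_COLUMNS = ("id", "population", "sex")
VALID_SEXES = ("M", "F", "U")


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci genotype calls.

    Parameters
    ----------
    calls
        ``(n_samples, n_loci)`` integer array of alt-allele dosages; ``-1``
        marks a missing call.
    loci
        Per-locus table with columns ``chrom, pos, id, ref, alt``.
    samples
        Sample identifiers in row order of ``calls``.
    """

    calls: np.ndarray
    loci: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.samples = [str(s) for s in self.samples]
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D (samples x loci) array")
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        missing_cols = set(LOCUS_COLUMNS) - set(self.loci.columns)
        if missing_cols:
            raise ValueError(f"loci table lacks columns: {sorted(missing_cols)}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("calls must be in {-1, 0, 1, 2}")
        self.loci = self.loci.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_indices(self, ids: Iterable[str]) -> np.ndarray:
        """Row indices for the given sample ids (order preserved)."""
        lookup = {s: i for i, s in enumerate(self.samples)}
        ids = list(ids)
        unknown = [s for s in ids if s not in lookup]
        if unknown:
            raise KeyError(f"unknown sample ids: {unknown}")
        return np.asarray([lookup[s] for s in ids], dtype=np.intp)

    def subset_samples(self, ids: Iterable[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(ids)
        return GenotypeMatrix(self.calls[idx], self.loci.copy(), [self.samples[i] for i in idx])

    def subset_loci(self, which: np.ndarray) -> "GenotypeMatrix":
        """Subset loci by boolean mask or integer index array."""
        which = np.asarray(which)
        if which.dtype == bool:
            which = np.flatnonzero(which)
        return GenotypeMatrix(
            self.calls[:, which], self.loci.iloc[which].reset_index(drop=True), list(self.samples)
        )

    def loci_on(self, chrom: str) -> np.ndarray:
        """Integer indices of loci on the named chromosome."""
        return np.flatnonzero((self.loci["chrom"].astype(str) == str(chrom)).to_numpy())

    def locus_index(self, chrom: str, pos: int) -> int:
        hit = np.flatnonzero(
            (self.loci["chrom"].astype(str) == str(chrom)).to_numpy()
            & (self.loci["pos"].to_numpy() == int(pos))
        )
        if hit.size == 0:
            raise KeyError(f"no locus at {chrom}:{pos}")
        return int(hit[0])


def make_sample_table(
    ids: Sequence[str],
    populations: Sequence[str],
    sexes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build a valid sample table; sexes default to ``U`` (unknown)."""
    if sexes is None:
        sexes = ["U"] * len(ids)
    df = pd.DataFrame({"id": list(ids), "population": list(populations), "sex": list(sexes)})
    validate_sample_table(df)
    return df


def validate_sample_table(df: pd.DataFrame) -> None:
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample table lacks columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    bad = ~df["sex"].isin(VALID_SEXES)
    if bad.any():
        raise ValueError(f"sex must be one of {VALID_SEXES}; got {sorted(df.loc[bad, 'sex'].unique())}")


@dataclass
class CohortBundle:
    """A genotype matrix plus aligned metadata and provenance.

    Provenance records source files, applied filters and seeds so any output
    can be regenerated from the log alone.
    """

    matrix: GenotypeMatrix
    samples: pd.DataFrame
    depth: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_sample_table(self.samples)
        if list(self.samples["id"]) != list(self.matrix.samples):
            raise ValueError("sample table order does not match genotype matrix")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.matrix.calls.shape:
                raise ValueError("depth matrix shape does not match genotype matrix")
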