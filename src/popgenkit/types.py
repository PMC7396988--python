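"""Shared domain types.

The central data structure is :class:`HaplotypeMatrix`, a phased,
ancestral/derived-polarized haplotype-by-site 0/1 matrix with physical
coordinates and per-haplotype population labels.  Every statistic in the
package consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "HaplotypeMatrix",
    "SiteFreq",
    "FstRecord",
    "LDBlock",
    "DiversityResult",
    "NeutralityTestResult",
    "Region",
]


@dataclass(frozen=True)
class Region:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    @classmethod
    def parse(cls, text: str) -> "Region":
        """Parse ``chrom:start-end``; thousands separators are tolerated."""
        try:
            chrom, span = text.split(":")
            lo, hi = span.replace(",", "").split("-")
            return cls(chrom, int(lo), int(hi))
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"cannot parse region string {text!r}") from exc


class HaplotypeMatrix:
    """Phased binary haplotype matrix (haplotypes x sites).

    Alleles are coded 0 = ancestral, 1 = derived.  Positions are 1-based
    physical coordinates and must be strictly increasing; every haplotype
    carries a population label.  No missing data is allowed — unpolarized
    or incomplete sites are expected to be dropped at ingest.
    """

    def __init__(
        self,
        alleles: np.ndarray,
        positions: Sequence[int],
        site_ids: Sequence[str] | None = None,
        pop_labels: Sequence[str] | None = None,
        chrom: str = "1",
    ) -> None:
        alleles = np.asarray(alleles, dtype=np.int8)
        if alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        positions = np.asarray(positions, dtype=np.int64)
        if positions.shape[0] != alleles.shape[1]:
            raise ValueError("positions length must equal number of sites")
        if positions.size > 1 and not np.all(np.diff(positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(alleles, (0, 1)).all():
            raise ValueError("alleles must be 0 (ancestral) or 1 (derived)")
        if site_ids is None:
            site_ids = [f"site{p}" for p in positions]
        if len(site_ids) != alleles.shape[1]:
            raise ValueError("site_ids length must equal number of sites")
        if pop_labels is None:
            pop_labels = ["pop0"] * alleles.shape[0]
        if len(pop_labels) != alleles.shape[0]:
            raise ValueError("pop_labels length must equal number of haplotypes")
        self.alleles = alleles
        self.positions = positions
        self.site_ids = list(site_ids)
        self.pop_labels = np.asarray(pop_labels, dtype=object)
        self.chrom = chrom

    # -- basic introspection -------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def derived_counts(self) -> np.ndarray:
        """Derived-allele count per site."""
        return self.alleles.sum(axis=0)

    def derived_freqs(self) -> np.ndarray:
        return self.derived_counts() / self.n_haplotypes

    def segregating_mask(self) -> np.ndarray:
        c = self.derived_counts()
        return (c > 0) & (c < self.n_haplotypes)

    def site_index(self, site_id: str) -> int:
        try:
            return self.site_ids.index(site_id)
        except ValueError as exc:
            raise KeyError(f"site {site_id!r} not present") from exc

    # -- subsetting ----------------------------------------------------------
    def take_sites(self, idx: np.ndarray | Sequence[int]) -> "HaplotypeMatrix":
        idx = np.asarray(idx)
        return HaplotypeMatrix(
            self.alleles[:, idx],
            self.positions[idx],
            [self.site_ids[i] for i in np.atleast_1d(idx)],
            self.pop_labels,
            self.chrom,
        )

    def take_haplotypes(self, idx: np.ndarray | Sequence[int]) -> "HaplotypeMatrix":
        idx = np.asarray(idx)
        return HaplotypeMatrix(
            self.alleles[idx, :],
            self.positions,
            self.site_ids,
            self.pop_labels[idx],
            self.chrom,
        )

    def subset_region(self, region: Region) -> "HaplotypeMatrix":
        if region.chrom != self.chrom:
            raise ValueError(f"region chrom {region.chrom} != matrix chrom {self.chrom}")
        mask = (self.positions >= region.start) & (self.positions <= region.end)
        return self.take_sites(np.flatnonzero(mask))

    def subset_population(self, pop: str) -> "HaplotypeMatrix":
        idx = np.flatnonzero(self.pop_labels == pop)
        if idx.size == 0:
            raise ValueError(f"no haplotypes labeled {pop!r}")
        return self.take_haplotypes(idx)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.positions, other.positions)
            and self.site_ids == other.site_ids
            and np.array_equal(self.pop_labels, other.pop_labels)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"HaplotypeMatrix({self.n_haplotypes} haplotypes x {self.n_sites} sites, "
            f"chrom={self.chrom})"
        )


@dataclass(frozen=True)
class SiteFreq:
    """Derived-allele count at one site in one population sample."""

    derived_count: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"sample size must be >= 2, got {self.n}")
        if not 0 <= self.derived_count <= self.n:
            raise ValueError("derived_count must be in [0, n]")

    @property
    def freq(self) -> float:
        return self.derived_count / self.n


@dataclass
class FstRecord:
    site_id: str
    fst: float  # clamped value when clamping requested
    raw: float = float("nan")  # unclamped estimate
    clamped: bool = False
    defined: bool = True


@dataclass
class LDBlock:
    start_index: int
    end_index: int  # inclusive
    start_bp: int
    end_bp: int
    n_sites: int


@dataclass
class DiversityResult:
    pi: float
    var_pi: float
    n: int
    L: int


@dataclass
class NeutralityTestResult:
    statistic: float
    p_value: float
    method: str
    q_value: float | None = None
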