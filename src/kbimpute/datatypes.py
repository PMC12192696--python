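"""Core containers shared by every stage of the imputation pipeline.

Genotypes are additively coded per marker: 0 = homozygous for the major
allele, 1 = heterozygous, 2 = homozygous for the minor allele.  Missing
calls are stored as the sentinel :data:`MISSING` (-1) in an int8 array so
that a full resequencing panel stays compact in memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

#: Sentinel for a missing genotype call inside ``GenotypeMatrix.calls``.
MISSING: int = -1

VALID_CALLS = frozenset({0, 1, 2, MISSING})


class ValidationError(ValueError):
    """A container or operation precondition was violated."""


class ParseError(ValueError):
    """A file could not be interpreted as the declared format."""


@dataclass(frozen=True)
class MarkerInfo:
    """Metadata for one biallelic SNP.

    Parameters
    ----------
    name : str
        Marker identifier, unique within a panel.
    chrom : str
        Chromosome label.
    pos : int
        1-based physical position in bp.
    alleles : tuple of (str, str), optional
        Ordered (major, minor) single-character nucleotide codes.  ``None``
        when the source format (numeric 0/1/2) carries no allele labels; the
        surrogate A/G coding is then used on export.
    """

    name: str
    chrom: str = "1"
    pos: int = 1
    alleles: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"marker {self.name!r}: pos must be >= 1, got {self.pos}")
        if self.alleles is not None:
            major, minor = self.alleles
            if major == minor:
                raise ValidationError(
                    f"marker {self.name!r}: major and minor alleles must differ ({major!r})"
                )


@dataclass
class GenotypeMatrix:
    """Individuals x markers matrix of additively coded genotype calls.

    Attributes
    ----------
    taxa : list of str
        Ordered individual identifiers (rows).
    markers : list of MarkerInfo
        Ordered marker metadata (columns).
    calls : ndarray of int8, shape (n_individuals, n_markers)
        Values in {0, 1, 2, MISSING}.
    """

    taxa: list[str]
    markers: list[MarkerInfo]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValidationError(f"calls must be 2-D, got shape {self.calls.shape}")
        n, m = self.calls.shape
        if n != len(self.taxa):
            raise ValidationError(f"{len(self.taxa)} taxa but {n} call rows")
        if m != len(self.markers):
            raise ValidationError(f"{len(self.markers)} markers but {m} call columns")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValidationError(f"duplicate taxa: {dupes}")
        names = [mk.name for mk in self.markers]
        if len(set(names)) != len(names):
            dupes = sorted({x for x in names if names.count(x) > 1})
            raise ValidationError(f"duplicate marker names: {dupes}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid call {int(self.calls[i, j])} at row {i}, col {j} "
                "(expected 0, 1, 2 or MISSING)"
            )

    # -- basic introspection -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, m) mask of missing calls."""
        return self.calls == MISSING

    def is_complete(self) -> bool:
        return not (self.calls == MISSING).any()

    # -- construction helpers ------------------------------------------------

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.taxa), list(self.markers), self.calls.copy())

    def take_individuals(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            [self.taxa[i] for i in idx], list(self.markers), self.calls[idx, :].copy()
        )

    def take_markers(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            list(self.taxa), [self.markers[j] for j in idx], self.calls[:, idx].copy()
        )

    def with_calls(self, calls: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.taxa), list(self.markers), calls)


def default_markers(n: int, prefix: str = "snp") -> list[MarkerInfo]:
    """Fabricate marker metadata for sources that carry none.

    Numeric 0/1/2 files have no positions, so markers are placed on a single
    pseudo-chromosome "1" at pos = column index + 1.
    """
    return [MarkerInfo(name=f"{prefix}{j + 1}", chrom="1", pos=j + 1) for j in range(n)]
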