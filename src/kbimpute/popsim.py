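"""Synthetic structured-population genotype simulator and masking utilities.

The simulator emulates the two data regimes an imputation benchmark needs:

* a **homogeneous** panel (``n_subpops=1``): one haplotype pool, long
  shared haplotype blocks, no allele-frequency stratification;
* a **structured** multi-breed panel (``n_subpops>1``): subpopulation
  allele frequencies drawn around a shared ancestral frequency with a
  Balding-Nichols Beta model, so ``divergence`` plays the role of F_ST.

Each subpopulation owns a small pool of founder haplotypes; every
individual's two haplotypes are recombinant mosaics of that pool, which
keeps long haplotype blocks shared within (but not between)
subpopulations -- the structural property a cluster-then-impute strategy
exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import MISSING, GenotypeMatrix, ValidationError, default_markers


@dataclass
class PopSimConfig:
    """Parameters of the structured-population generator.

    Attributes
    ----------
    n_subpops : int
        Number of diverged subpopulations (K_true).
    n_per_subpop : int
        Individuals sampled per subpopulation.
    n_markers : int
        Biallelic marker count.
    pool_size : int
        Founder haplotypes per subpopulation; smaller pools mean stronger
        haplotype sharing.
    divergence : float
        Between-subpopulation allele-frequency divergence in [0, 1]
        (Balding-Nichols F, an F_ST analogue).  0 = panmictic.
    recomb_rate : float
        Per-adjacent-marker probability that a mosaic haplotype switches
        to a different founder, in [0, 0.5].
    seed : int
        Random seed; simulation is deterministic given the config.
    """

    n_subpops: int = 3
    n_per_subpop: int = 30
    n_markers: int = 2000
    pool_size: int = 12
    divergence: float = 0.3
    recomb_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subpops", "n_per_subpop", "n_markers", "pool_size"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValidationError(f"divergence must be in [0, 1], got {self.divergence}")
        if not 0.0 <= self.recomb_rate <= 0.5:
            raise ValidationError(f"recomb_rate must be in [0, 0.5], got {self.recomb_rate}")


@dataclass
class SimulatedPopulation:
    """A complete simulated panel with its generating truth."""

    genotypes: GenotypeMatrix
    true_haplotypes: np.ndarray  # (n_individuals, 2, n_markers) uint8
    subpop_labels: np.ndarray  # (n_individuals,) int

    def __post_init__(self) -> None:
        sums = self.true_haplotypes.sum(axis=1).astype(np.int8)
        if not np.array_equal(sums, self.genotypes.calls):
            raise ValidationError("genotypes must equal element-wise haplotype sums")


@dataclass
class MaskSpec:
    """The cells hidden for a masking benchmark, with their true values."""

    rate: float
    cells: np.ndarray  # (n_cells, 2) int: (individual index, marker index)
    truth: np.ndarray  # (n_cells,) int8 in {0,1,2}
    seed: int

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64).reshape(-1, 2)
        self.truth = np.asarray(self.truth, dtype=np.int8)
        if len(self.cells) != len(self.truth):
            raise ValidationError("cells and truth must have equal length")
        if not np.isin(self.truth, (0, 1, 2)).all():
            raise ValidationError("truth values must be complete genotypes in {0,1,2}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _mosaic_haplotype(pool: np.ndarray, recomb_rate: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant mosaic of the founder pool."""
    n_pool, m = pool.shape
    if n_pool == 1 or recomb_rate == 0.0:
        return pool[rng.integers(n_pool)].copy()
    switches = rng.random(m - 1) < recomb_rate
    segment = np.concatenate(([0], np.cumsum(switches)))
    founders = rng.integers(n_pool, size=segment[-1] + 1)
    return pool[founders[segment], np.arange(m)].copy()


def simulate_population(cfg: PopSimConfig) -> SimulatedPopulation:
    """Simulate a structured diploid panel under ``cfg``.

    Ancestral allele frequencies are Uniform(0.05, 0.95); subpopulation
    frequencies come from Beta(p(1-F)/F, (1-p)(1-F)/F) so their expected
    F_ST equals ``divergence``.  Founder haplotypes are per-site Bernoulli
    draws from the subpopulation frequencies; individuals receive two
    mosaic copies of the founder pool.
    """
    rng = np.random.default_rng(cfg.seed)
    k, m = cfg.n_subpops, cfg.n_markers
    p_anc = rng.uniform(0.05, 0.95, size=m)
    if cfg.divergence == 0.0:
        p_sub = np.tile(p_anc, (k, 1))
    else:
        f = cfg.divergence
        a = p_anc * (1.0 - f) / f
        b = (1.0 - p_anc) * (1.0 - f) / f
        p_sub = rng.beta(np.tile(a, (k, 1)), np.tile(b, (k, 1)))

    n_total = k * cfg.n_per_subpop
    haps = np.empty((n_total, 2, m), dtype=np.uint8)
    labels = np.repeat(np.arange(k), cfg.n_per_subpop)
    for s in range(k):
        pool = (rng.random((cfg.pool_size, m)) < p_sub[s]).astype(np.uint8)
        start = s * cfg.n_per_subpop
        for i in range(cfg.n_per_subpop):
            haps[start + i, 0] = _mosaic_haplotype(pool, cfg.recomb_rate, rng)
            haps[start + i, 1] = _mosaic_haplotype(pool, cfg.recomb_rate, rng)

    calls = haps.sum(axis=1).astype(np.int8)
    taxa = [f"ind{str(i + 1).zfill(4)}" for i in range(n_total)]
    gm = GenotypeMatrix(taxa, default_markers(m), calls)
    return SimulatedPopulation(genotypes=gm, true_haplotypes=haps, subpop_labels=labels)


# ---------------------------------------------------------------------------
# marker subsetting and masking
# ---------------------------------------------------------------------------

def subset_markers(gm: GenotypeMatrix, n: int, seed: int) -> GenotypeMatrix:
    """Uniform random marker subset of size ``n``, original order preserved."""
    if n > gm.n_markers:
        raise ValidationError(f"cannot subset {n} markers from {gm.n_markers}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(gm.n_markers, size=n, replace=False))
    return gm.take_markers(idx)


def apply_mask(gm: GenotypeMatrix, rate: float, seed: int) -> tuple[GenotypeMatrix, MaskSpec]:
    """Hide ``round(rate * cells)`` uniformly chosen calls.

    The input must be complete.  A re-draw rule guarantees no marker ends
    up entirely missing (an all-missing column carries no frequency
    information for any imputation engine).
    """
    if not gm.is_complete():
        raise ValidationError("apply_mask requires a complete genotype matrix")
    if not 0.0 < rate < 1.0:
        raise ValidationError(f"mask rate must be in (0, 1), got {rate}")
    n, m = gm.calls.shape
    total = n * m
    n_mask = int(round(rate * total))
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=n_mask, replace=False)
    chosen = np.zeros(total, dtype=bool)
    chosen[flat] = True
    grid = chosen.reshape(n, m)

    # re-draw rule: no column may be fully masked
    if n_mask >= n:
        full_cols = np.flatnonzero(grid.sum(axis=0) == n)
        for col in full_cols:
            keep_row = rng.integers(n)
            grid[keep_row, col] = False
            # move the freed mask to a random unmasked cell that would not
            # complete another column
            while True:
                cand = rng.integers(total)
                ci, cj = divmod(cand, m)
                if grid[ci, cj]:
                    continue
                if grid[:, cj].sum() + 1 == n:
                    continue
                grid[ci, cj] = True
                break

    cells = np.argwhere(grid)
    truth = gm.calls[grid].copy()
    masked = gm.copy()
    masked.calls[grid] = MISSING
    spec = MaskSpec(rate=rate, cells=cells, truth=truth, seed=seed)
    return masked, spec


def unmask(masked: GenotypeMatrix, spec: MaskSpec) -> GenotypeMatrix:
    """Restore the hidden truth values; inverse of :func:`apply_mask`."""
    restored = masked.copy()
    restored.calls[spec.cells[:, 0], spec.cells[:, 1]] = spec.truth
    return restored
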