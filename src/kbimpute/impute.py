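"""Haplotype-copying HMM imputation engine.

The engine follows the Li-Stephens mosaic model: a target individual's two
haplotypes are imperfect copies of haplotypes in a reference panel.  The
hidden state at each marker is the ordered pair of copied panel haplotypes;
each copy independently switches to a uniformly chosen haplotype with
probability ``switch_prob`` between adjacent markers (the recombination
analogue), and each emitted allele differs from the copied allele with
probability ``mismatch_prob`` (the mutation/genotyping-error analogue).
Genotype posteriors at missing markers come from the forward-backward
algorithm over this pair chain; the state space is quadratic in panel size,
which is exactly why clustering individuals into subpopulations with fewer,
longer shared haplotypes pays off.

Because the transition kernel factorizes over the two copies and is
"stay or jump uniformly", one forward step costs O(H^2) rather than
O(H^4).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import MISSING, GenotypeMatrix, ValidationError

#: Genotype preference on exact posterior ties: heterozygote, then major
#: homozygote, then minor homozygote.
_TIE_ORDER = np.array([1, 0, 2])


@dataclass
class HMMParams:
    """Tunable parameters of the copying model.

    Attributes
    ----------
    switch_prob : float
        Per-adjacent-marker probability that a copied haplotype switches to
        a uniformly chosen panel haplotype.  No genetic map is used: the
        marker panel lives on a single pseudo-chromosome, so the rate is
        uniform per interval.
    mismatch_prob : float
        Per-allele probability that the emitted allele differs from the
        copied haplotype's allele.
    em_iters : int
        Maximum sweeps of iterative conditional phasing when building the
        panel.
    tol : float
        Convergence tolerance reserved for likelihood-based stopping.
    max_panel : int
        Cap on reference haplotypes per target (the pair state space is
        H^2); larger panels are randomly subsampled.
    """

    switch_prob: float = 0.01
    mismatch_prob: float = 0.005
    em_iters: int = 10
    tol: float = 1e-6
    max_panel: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.switch_prob < 1.0:
            raise ValidationError(f"switch_prob must be in (0,1), got {self.switch_prob}")
        if not 0.0 < self.mismatch_prob < 0.5:
            raise ValidationError(f"mismatch_prob must be in (0,0.5), got {self.mismatch_prob}")


@dataclass
class HaplotypePanel:
    """Reference haplotypes over a marker window; the HMM state space.

    ``haplotypes`` is H x M binary (one row per haplotype, one column per
    marker); ``owners`` maps each haplotype row to the individual it was
    phased from (-1 for external panels).
    """

    haplotypes: np.ndarray
    owners: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] < 1:
            raise ValidationError("panel must be a non-empty H x M matrix")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValidationError("panel entries must be binary alleles")
        if self.owners is None:
            self.owners = np.full(self.haplotypes.shape[0], -1, dtype=int)
        else:
            self.owners = np.asarray(self.owners, dtype=int)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class ImputationResult:
    """A completed genotype matrix plus per-cell posteriors.

    ``posteriors`` maps each originally missing (individual, marker) cell
    to its probability triple over genotypes {0, 1, 2}.
    """

    completed: GenotypeMatrix
    posteriors: dict[tuple[int, int], np.ndarray]
    engine: str
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.completed.calls == MISSING).any():
            raise ValidationError("completed matrix must contain no missing calls")
        for cell, p in self.posteriors.items():
            s = float(np.sum(p))
            if abs(s - 1.0) > 1e-9:
                raise ValidationError(f"posterior at {cell} sums to {s}, not 1")


# ---------------------------------------------------------------------------
# haploid Viterbi (panel construction)
# ---------------------------------------------------------------------------

def _viterbi_template(
    obs: np.ndarray, known: np.ndarray, haps: np.ndarray, switch: float, mismatch: float
) -> np.ndarray:
    """Most likely copied-allele sequence for one haplotype observation.

    ``obs`` is the current allele assignment (0/1), ``known`` flags markers
    where the underlying genotype was observed (unknown markers emit 1).
    Returns the allele carried by the Viterbi copying path at each marker.
    """
    H, M = haps.shape
    log_stay = np.log1p(-switch + switch / H)
    log_jump = np.log(switch / H)
    le_match = np.log1p(-mismatch)
    le_miss = np.log(mismatch)
    v = np.zeros(H)
    ptr = np.zeros((M, H), dtype=np.int32)
    for m in range(M):
        if m > 0:
            best = int(np.argmax(v))
            jump_score = v[best] + log_jump
            stay_score = v + log_stay
            take_stay = stay_score >= jump_score
            ptr[m] = np.where(take_stay, np.arange(H), best)
            v = np.where(take_stay, stay_score, jump_score)
        if known[m]:
            v = v + np.where(haps[:, m] == obs[m], le_match, le_miss)
        v -= v.max()  # rescale; path-relative scores only
    state = int(np.argmax(v))
    template = np.empty(M, dtype=np.uint8)
    for m in range(M - 1, -1, -1):
        template[m] = haps[state, m]
        state = int(ptr[m, state])
    return template


def build_panel(gm: GenotypeMatrix, params: HMMParams | None = None, seed: int = 0) -> HaplotypePanel:
    """Phase all individuals into a 2N-haplotype reference panel.

    Heterozygote phases start random and are refined by iterative
    conditional phasing: each individual's two haplotypes are matched
    against the panel of all other haplotypes by Viterbi copying, and het
    (and missing) sites are re-assigned to agree with the copied templates.
    Sweeps stop after ``em_iters`` or when no site changes.
    """
    params = params or HMMParams()
    n, m = gm.calls.shape
    if n < 2:
        raise ValidationError("panel construction needs >= 2 individuals")
    rng = np.random.default_rng(seed)
    calls = gm.calls
    obs_mask = calls != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(
            obs_mask.any(axis=0),
            np.where(obs_mask, calls, 0).sum(axis=0) / (2.0 * np.maximum(obs_mask.sum(axis=0), 1)),
            0.5,
        )

    haps = np.zeros((2 * n, m), dtype=np.uint8)
    for i in range(n):
        row = calls[i]
        a = np.zeros(m, dtype=np.uint8)
        b = np.zeros(m, dtype=np.uint8)
        hom2 = row == 2
        a[hom2] = b[hom2] = 1
        het = row == 1
        flip = rng.random(het.sum()) < 0.5
        a_het = np.zeros(het.sum(), dtype=np.uint8)
        a_het[flip] = 1
        a[het] = a_het
        b[het] = 1 - a_het
        miss = row == MISSING
        a[miss] = rng.random(miss.sum()) < freq[miss]
        b[miss] = rng.random(miss.sum()) < freq[miss]
        haps[2 * i] = a
        haps[2 * i + 1] = b

    if n >= 2 and m >= 1:
        all_idx = np.arange(2 * n)
        for _ in range(params.em_iters):
            changes = 0
            for i in range(n):
                ref_idx = np.concatenate([all_idx[: 2 * i], all_idx[2 * i + 2 :]])
                ref = haps[ref_idx]
                known = obs_mask[i]
                het = calls[i] == 1
                miss = ~known
                if not het.any() and not miss.any():
                    continue
                # conditional re-phase: the first haplotype copies its Viterbi
                # template at ambiguous sites, the second is forced to the
                # genotype complement at het sites and then follows its own
                # template at missing sites
                t_a = _viterbi_template(haps[2 * i], known, ref, params.switch_prob, params.mismatch_prob)
                new_a = np.where(het | miss, t_a, haps[2 * i])
                new_b = np.where(het, 1 - new_a, haps[2 * i + 1])
                t_b = _viterbi_template(new_b, known, ref, params.switch_prob, params.mismatch_prob)
                new_b = np.where(miss, t_b, new_b)
                changes += int((new_a != haps[2 * i]).sum() + (new_b != haps[2 * i + 1]).sum())
                haps[2 * i] = new_a
                haps[2 * i + 1] = new_b
            if changes == 0:
                break

    owners = np.repeat(np.arange(n), 2)
    return HaplotypePanel(haplotypes=haps, owners=owners)


# ---------------------------------------------------------------------------
# forward-backward over the haplotype-pair chain
# ---------------------------------------------------------------------------

def _pair_transition(f: np.ndarray, switch: float) -> np.ndarray:
    """Apply the pair transition kernel in O(H^2).

    Each copy independently stays with probability (1 - s) or jumps to a
    uniform haplotype with probability s, so the kernel factorizes into two
    rank-one updates.
    """
    H = f.shape[0]
    s = switch
    g = (1.0 - s) * f + (s / H) * f.sum(axis=1, keepdims=True)
    return (1.0 - s) * g + (s / H) * g.sum(axis=0, keepdims=True)


def _emission_matrices(p1: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genotype emission probabilities for every state pair at one marker.

    ``p1`` is the per-haplotype probability of emitting allele 1 (copied
    allele passed through the symmetric flip channel).
    """
    q = 1.0 - p1
    e0 = np.outer(q, q)
    e2 = np.outer(p1, p1)
    e1 = np.outer(p1, q) + np.outer(q, p1)
    return e0, e1, e2


def forward_backward(
    obs: np.ndarray, panel: HaplotypePanel, params: HMMParams
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior genotype triples at every missing marker of one individual.

    Parameters
    ----------
    obs : (M,) int array with values in {0, 1, 2, MISSING}
    panel : HaplotypePanel aligned to the same markers
    params : HMMParams

    Returns
    -------
    missing_idx : (k,) int array of marker indices that were missing
    posteriors : (k, 3) array; each row sums to 1
    """
    obs = np.asarray(obs)
    if panel.n_haplotypes < 1:
        raise ValidationError("empty reference panel")
    H, M = panel.haplotypes.shape
    if obs.shape[0] != M:
        raise ValidationError(f"observation length {obs.shape[0]} != panel markers {M}")
    known = obs != MISSING
    if not known.any():
        raise ValidationError("observation has no non-missing markers")
    missing_idx = np.flatnonzero(~known)
    if len(missing_idx) == 0:
        return missing_idx, np.empty((0, 3))

    e = params.mismatch_prob
    # P(emit allele 1 | copied haplotype), per haplotype and marker
    p1 = e + (1.0 - 2.0 * e) * panel.haplotypes.astype(np.float64)

    def emission(m: int) -> np.ndarray | None:
        if not known[m]:
            return None
        e0, e1, e2 = _emission_matrices(p1[:, m])
        return (e0, e1, e2)[int(obs[m])]

    # forward pass, storing the (normalized) forward matrix at missing markers
    f = np.full((H, H), 1.0 / (H * H))
    em = emission(0)
    if em is not None:
        f = f * em
        f /= f.sum()
    fwd_at: dict[int, np.ndarray] = {}
    if not known[0]:
        fwd_at[0] = f.copy()
    for m in range(1, M):
        f = _pair_transition(f, params.switch_prob)
        em = emission(m)
        if em is not None:
            f = f * em
        f /= f.sum()
        if not known[m]:
            fwd_at[m] = f.copy()

    # backward pass, emitting posteriors as missing markers are reached
    posteriors = np.empty((len(missing_idx), 3))
    slot = {m: i for i, m in enumerate(missing_idx)}
    b = np.ones((H, H))
    for m in range(M - 1, -1, -1):
        if not known[m]:
            post = fwd_at[m] * b
            post /= post.sum()
            e0, e1, e2 = _emission_matrices(p1[:, m])
            posteriors[slot[m]] = [
                float((post * e0).sum()),
                float((post * e1).sum()),
                float((post * e2).sum()),
            ]
        if m > 0:
            em = emission(m)
            bb = b * em if em is not None else b
            b = _pair_transition(bb, params.switch_prob)
            b /= b.sum()
    # guard tiny numerical drift
    posteriors /= posteriors.sum(axis=1, keepdims=True)
    return missing_idx, posteriors


def _call_from_posterior(p: np.ndarray) -> int:
    """Argmax genotype; exact ties prefer het, then the major homozygote."""
    return int(_TIE_ORDER[int(np.argmax(p[_TIE_ORDER]))])


def _check_markers_observed(gm: GenotypeMatrix) -> None:
    all_missing = (gm.calls == MISSING).all(axis=0)
    if all_missing.any():
        j = int(np.flatnonzero(all_missing)[0])
        raise ValidationError(
            f"marker {gm.markers[j].name!r} (column {j}) has no observed calls"
        )


def _loo_panel_indices(
    panel: HaplotypePanel, individual: int, max_panel: int, rng: np.random.Generator
) -> np.ndarray:
    idx = np.flatnonzero(panel.owners != individual)
    if len(idx) > max_panel:
        idx = np.sort(rng.choice(idx, size=max_panel, replace=False))
    return idx


def impute_hmm(
    gm: GenotypeMatrix, params: HMMParams | None = None, seed: int = 0
) -> ImputationResult:
    """Impute all missing calls with the haplotype-copying HMM.

    The panel is phased from all individuals; each individual with missing
    calls is then decoded against the panel *excluding its own two
    haplotypes* (leave-one-out), so its posteriors never condition on a
    circular copy of itself.  Panels above ``max_panel`` haplotypes are
    subsampled deterministically per individual.
    """
    params = params or HMMParams()
    _check_markers_observed(gm)
    completed = gm.copy()
    posteriors: dict[tuple[int, int], np.ndarray] = {}
    rows_missing = np.flatnonzero((gm.calls == MISSING).any(axis=1))
    if len(rows_missing) == 0:
        return ImputationResult(completed=completed, posteriors=posteriors, engine="hmm")
    if gm.n_individuals < 2:
        raise ValidationError("HMM imputation needs >= 2 individuals")

    panel = build_panel(gm, params, seed=seed)
    for i in rows_missing:
        sub_rng = np.random.default_rng(np.random.SeedSequence([seed, int(i), 7]))
        idx = _loo_panel_indices(panel, int(i), params.max_panel, sub_rng)
        sub = HaplotypePanel(haplotypes=panel.haplotypes[idx], owners=panel.owners[idx])
        missing_idx, post = forward_backward(gm.calls[i], sub, params)
        for mi, p in zip(missing_idx, post):
            completed.calls[i, mi] = _call_from_posterior(p)
            posteriors[(int(i), int(mi))] = p
    return ImputationResult(completed=completed, posteriors=posteriors, engine="hmm")


def impute_baseline(gm: GenotypeMatrix) -> ImputationResult:
    """Fill each missing call with the modal genotype of its marker.

    A deliberately naive control: posteriors are the empirical genotype
    frequencies among observed calls; modal ties take the lower code.
    """
    _check_markers_observed(gm)
    completed = gm.copy()
    posteriors: dict[tuple[int, int], np.ndarray] = {}
    counts = np.stack([(gm.calls == g).sum(axis=0) for g in (0, 1, 2)], axis=0).astype(float)
    freqs = counts / counts.sum(axis=0, keepdims=True)
    modal = np.argmax(counts, axis=0)  # np.argmax takes the first (lowest) on ties
    for i, j in np.argwhere(gm.calls == MISSING):
        completed.calls[i, j] = modal[j]
        posteriors[(int(i), int(j))] = freqs[:, j].copy()
    return ImputationResult(completed=completed, posteriors=posteriors, engine="baseline")


def impute_external_beagle(
    gm: GenotypeMatrix, beagle_jar: str | Path, workdir: str | Path | None = None
) -> ImputationResult:
    """Impute by shelling out to an external Beagle jar (optional backend).

    Requires a Java runtime and the jar on disk; raises an environment
    error otherwise.  Round-trips through VCF via :mod:`genotype_io` and
    restores the input taxa order.
    """
    from . import genotype_io

    beagle_jar = Path(beagle_jar)
    java = shutil.which("java")
    if java is None:
        raise EnvironmentError("no Java runtime found on PATH for external Beagle")
    if not beagle_jar.exists():
        raise EnvironmentError(f"Beagle jar not found: {beagle_jar}")
    _check_markers_observed(gm)
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp = Path(tmp)
        in_vcf = tmp / "input.vcf"
        out_prefix = tmp / "imputed"
        genotype_io.to_vcf(gm, in_vcf)
        proc = subprocess.run(
            [java, "-jar", str(beagle_jar), f"gt={in_vcf}", f"out={out_prefix}"],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise RuntimeError(f"Beagle failed (exit {proc.returncode}):\n{proc.stderr}")
        out = genotype_io.from_vcf(out_prefix.with_suffix(".vcf.gz"))
    out = genotype_io.reorder_to_taxa(out, gm.taxa)
    posteriors = {
        (int(i), int(j)): _one_hot(out.calls[i, j])
        for i, j in np.argwhere(gm.calls == MISSING)
    }
    return ImputationResult(completed=out, posteriors=posteriors, engine="beagle-external")


def _one_hot(g: int) -> np.ndarray:
    p = np.zeros(3)
    p[int(g)] = 1.0
    return p


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------

class LiStephensImputer(BaseEstimator, TransformerMixin):
    """Haplotype-copying HMM imputer with a scikit-learn transformer API.

    ``X`` is an (n_individuals, n_markers) array of additive genotype
    dosages 0/1/2 with ``np.nan`` marking missing calls.  ``fit(X)``
    phases the panel; ``transform(X)`` returns a completed integer matrix.
    When transforming the same data the estimator was fitted on, each row
    is decoded against the panel excluding its own two haplotypes.

    Parameters mirror :class:`HMMParams`; ``random_state`` seeds phase
    initialization and panel subsampling.
    """

    def __init__(
        self,
        switch_prob: float = 0.01,
        mismatch_prob: float = 0.005,
        em_iters: int = 10,
        max_panel: int = 200,
        random_state: int = 0,
    ):
        self.switch_prob = switch_prob
        self.mismatch_prob = mismatch_prob
        self.em_iters = em_iters
        self.max_panel = max_panel
        self.random_state = random_state

    def _params(self) -> HMMParams:
        return HMMParams(
            switch_prob=self.switch_prob,
            mismatch_prob=self.mismatch_prob,
            em_iters=self.em_iters,
            max_panel=self.max_panel,
        )

    @staticmethod
    def _to_gm(X: np.ndarray) -> GenotypeMatrix:
        from .datatypes import default_markers

        X = np.asarray(X, dtype=float)
        calls = np.full(X.shape, np.int8(MISSING), dtype=np.int8)
        ok = ~np.isnan(X)
        calls[ok] = X[ok].astype(np.int8)
        taxa = [f"s{i}" for i in range(X.shape[0])]
        return GenotypeMatrix(taxa, default_markers(X.shape[1]), calls)

    def fit(self, X, y=None):
        gm = self._to_gm(X)
        self._fit_calls_ = gm.calls.copy()
        self.panel_ = build_panel(gm, self._params(), seed=self.random_state)
        self.n_features_in_ = gm.n_markers
        return self

    def transform(self, X) -> np.ndarray:
        gm = self._to_gm(X)
        if gm.n_markers != self.n_features_in_:
            raise ValidationError("marker count differs from fitted panel")
        params = self._params()
        same = gm.calls.shape == self._fit_calls_.shape and np.array_equal(
            gm.calls, self._fit_calls_
        )
        out = gm.calls.astype(np.int8).copy()
        for i in range(gm.n_individuals):
            if not (gm.calls[i] == MISSING).any():
                continue
            if same:
                rng = np.random.default_rng(np.random.SeedSequence([self.random_state, int(i), 7]))
                idx = _loo_panel_indices(self.panel_, int(i), params.max_panel, rng)
                sub = HaplotypePanel(self.panel_.haplotypes[idx], self.panel_.owners[idx])
            else:
                sub = self.panel_
            missing_idx, post = forward_backward(gm.calls[i], sub, params)
            for mi, p in zip(missing_idx, post):
                out[i, mi] = _call_from_posterior(p)
        return out
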