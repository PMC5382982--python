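"""Synthetic cohorts and toy graphs with the structure the analysis assumes.

Emulates a two-group small-animal resting-state acquisition: each
subject's ROI signal is drawn from a modular block correlation matrix
(bilaterally mirrored modules, higher correlation within modules than
between), on top of which the generator layers slow scanner drift, a
CSF-like nuisance signal mixed into every ROI, smooth random-walk motion
traces, and large-amplitude spike artifacts on a flagged subset of
volumes. Lesion-group subjects get a planted connectivity effect: the
within-block covariance of a designated "ipsilesional cortical" node
block is scaled down and that of a bilateral "thalamic" block scaled up,
giving every downstream stage a known ground truth to recover.

Also provides ring-lattice and Erdos-Renyi G(n, m) toy graphs used as
fixtures for small-world and randomization checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sps

from .graphs import BinaryGraph
from .preprocess import NuisanceSet, RoiTimeSeriesSet

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "SimulatedSubject",
    "default_effect_blocks",
    "generate_cohort",
    "make_lattice_graph",
    "make_random_graph",
]

NUISANCE_NAMES = ["mot1", "mot2", "mot3", "mot4", "mot5", "mot6", "csf"]


@dataclass(frozen=True)
class EffectSpec:
    """Planted group effect: block-wise covariance scaling in the lesion group.

    ``reduction_factor`` in (0, 1] multiplies the off-diagonal
    correlations among ``reduced_block`` nodes (the "ipsilesional
    cortex" analog); ``increase_factor`` >= 1 multiplies those among
    ``increased_block`` nodes (the bilateral "thalamus" analog).
    ``null_flag`` forces both factors to 1, making both groups share one
    generating distribution.
    """

    reduced_block: frozenset[int] = frozenset()
    increased_block: frozenset[int] = frozenset()
    reduction_factor: float = 1.0
    increase_factor: float = 1.0
    null_flag: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "reduced_block", frozenset(self.reduced_block))
        object.__setattr__(self, "increased_block", frozenset(self.increased_block))
        if self.reduced_block & self.increased_block:
            raise ValueError("reduced and increased blocks must be disjoint")
        if not 0 < self.reduction_factor <= 1:
            raise ValueError("reduction_factor must lie in (0, 1]")
        if self.increase_factor < 1:
            raise ValueError("increase_factor must be >= 1")

    def effective_factors(self) -> tuple[float, float]:
        if self.null_flag:
            return 1.0, 1.0
        return self.reduction_factor, self.increase_factor


@dataclass(frozen=True)
class CohortSpec:
    """Acquisition and covariance parameters of a simulated cohort.

    Defaults mirror the emulated protocol: 900 one-second volumes over
    150 ROIs (75 per hemisphere), six bilaterally mirrored covariance
    modules, and mild drift/spike artifact levels.
    """

    n_lesion: int = 13
    n_sham: int = 11
    n_nodes: int = 150
    n_hemisphere: int = 75
    n_volumes: int = 900
    tr_seconds: float = 1.0
    n_modules: int = 6
    within_corr: float = 0.7
    between_corr: float = 0.25
    signal_cutoff_hz: float = 0.12
    drift_amplitude: float = 0.5
    spike_fraction: float = 0.02
    csf_mix: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesion < 1 or self.n_sham < 1:
            raise ValueError("both groups need at least one subject")
        if self.n_nodes != 2 * self.n_hemisphere:
            raise ValueError("n_nodes must equal 2 * n_hemisphere")
        if not 0 <= self.between_corr < self.within_corr < 1:
            raise ValueError("need 0 <= between_corr < within_corr < 1")
        if not 0 <= self.spike_fraction < 1:
            raise ValueError("spike_fraction must lie in [0, 1)")
        if self.n_volumes < 60:
            raise ValueError("n_volumes must be at least 60")
        if self.n_modules < 1 or self.n_modules > self.n_hemisphere:
            raise ValueError("n_modules must lie in [1, n_hemisphere]")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not 0 < self.signal_cutoff_hz < 0.5 / self.tr_seconds:
            raise ValueError("signal_cutoff_hz must lie in (0, Nyquist)")

    def module_assignment(self) -> np.ndarray:
        """Module index per node; mirror nodes share a module across hemispheres."""
        local = np.arange(self.n_nodes) % self.n_hemisphere
        return local * self.n_modules // self.n_hemisphere


@dataclass
class SimulatedSubject:
    """One simulated subject: signal series plus its nuisance regressors."""

    ts: RoiTimeSeriesSet
    nuisance: NuisanceSet
    spike_volumes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def default_effect_blocks(
    cohort: CohortSpec, n_reduced: int = 10, n_increased: int = 6
) -> tuple[frozenset[int], frozenset[int]]:
    """Canonical effect-block placement for a cohort.

    The reduced block takes up to ``n_reduced`` leading ipsilesional
    nodes of the first covariance module ("lesioned cortex" analog); the
    increased block takes up to ``n_increased`` nodes split evenly
    across hemispheres within one mid-parcellation module, emulating a
    bilateral deep-brain structure. Sizes are clipped to what fits in a
    single module so every cohort geometry gets valid blocks.
    """
    h = cohort.n_hemisphere
    module = cohort.module_assignment()
    m0_ipsi = [i for i in range(h) if module[i] == module[0]]
    reduced = frozenset(m0_ipsi[: min(n_reduced, len(m0_ipsi))])
    mid = module[int(h * 0.55)]
    mid_ipsi = [i for i in range(h) if module[i] == mid and i not in reduced]
    half = min(max(1, n_increased // 2), len(mid_ipsi))
    left = mid_ipsi[:half]
    increased = frozenset(left + [i + h for i in left])
    if len(reduced) < 2 or len(increased) < 2:
        raise ValueError("cohort too small for default effect blocks")
    return reduced, increased


def _block_correlation(cohort: CohortSpec, factors: tuple[float, float], effect: EffectSpec) -> np.ndarray:
    """Target correlation with planted effects, guaranteed positive definite.

    The connectivity increase multiplies within-block off-diagonal
    entries directly. The reduction is applied as a node-level
    connectivity loss: every reduced-block node's couplings are scaled
    by sqrt(reduction_factor), so within-block correlations shrink by
    exactly the requested factor and block-to-outside correlations by
    its square root -- the pattern a node losing signal coupling
    produces, and positive definite by congruence (the variance freed by
    the scaling returns to the diagonal as node-private noise). A
    shrinkage-toward-identity fallback covers targets the direct
    construction cannot certify.
    """
    module = cohort.module_assignment()
    same = module[:, None] == module[None, :]
    corr = np.where(same, cohort.within_corr, cohort.between_corr).astype(float)
    np.fill_diagonal(corr, 1.0)
    red, inc = factors
    for block in (effect.reduced_block, effect.increased_block):
        if block and (min(block) < 0 or max(block) >= cohort.n_nodes):
            raise ValueError("effect block indices out of range")
    if effect.increased_block and inc != 1.0:
        idx = np.fromiter(sorted(effect.increased_block), dtype=int)
        sub = corr[np.ix_(idx, idx)] * inc
        np.fill_diagonal(sub, 1.0)
        corr[np.ix_(idx, idx)] = sub
    if effect.reduced_block and red != 1.0:
        scale = np.ones(cohort.n_nodes)
        scale[np.fromiter(sorted(effect.reduced_block), dtype=int)] = math.sqrt(red)
        corr = scale[:, None] * corr * scale[None, :]
        np.fill_diagonal(corr, 1.0)
    off = corr[~np.eye(cohort.n_nodes, dtype=bool)]
    if np.any(np.abs(off) >= 1.0):
        raise ValueError("requested correlations reach |r| >= 1; infeasible target")
    base = corr.copy()
    for alpha in np.arange(0.0, 1.0, 0.05):
        corr = (1 - alpha) * base + alpha * np.eye(cohort.n_nodes)
        try:
            np.linalg.cholesky(corr)
            return corr
        except np.linalg.LinAlgError:
            continue
    raise ValueError("within/between correlation combination is not positive definite")


def _lowpass_noise(rng: np.random.Generator, t: int, cutoff_bins: int) -> np.ndarray:
    """Unit-variance noise restricted to the lowest Fourier bins."""
    spec = np.zeros(t // 2 + 1, dtype=complex)
    k = max(2, cutoff_bins)
    spec[1:k] = rng.standard_normal(k - 1) + 1j * rng.standard_normal(k - 1)
    x = np.fft.irfft(spec, n=t)
    sd = x.std()
    return x / sd if sd > 0 else x


def _simulate_subject(
    cohort: CohortSpec,
    chol: np.ndarray,
    subject_id: str,
    group: str,
    rng: np.random.Generator,
) -> SimulatedSubject:
    t, r = cohort.n_volumes, cohort.n_nodes
    data = rng.standard_normal((t, r)) @ chol.T
    # BOLD-like fluctuations are slow: band-limit the correlated signal.
    # A common linear filter preserves the correlation structure exactly;
    # one global scalar restores unit-scale variance.
    sos = _sps.butter(4, cohort.signal_cutoff_hz, btype="low", fs=1.0 / cohort.tr_seconds, output="sos")
    data = _sps.sosfiltfilt(sos, data, axis=0)
    data = data / data.std(axis=0).mean()

    # CSF-like nuisance: low-pass noise partially mixed into every ROI
    duration = t * cohort.tr_seconds
    csf = _lowpass_noise(rng, t, cutoff_bins=int(duration * 0.05) + 1)
    data = data + cohort.csf_mix * csf[:, None]

    # slow scanner drift below 0.01 Hz, independent phase/frequency per ROI
    tt = np.arange(t) * cohort.tr_seconds
    freqs = rng.uniform(0.002, 0.008, size=r)
    phases = rng.uniform(0, 2 * np.pi, size=r)
    data = data + cohort.drift_amplitude * np.sin(2 * np.pi * freqs[None, :] * tt[:, None] + phases[None, :])

    # motion traces: smoothed random walks (translations mm, rotations deg)
    steps = rng.normal(0.0, 0.02, size=(t, 6))
    kernel = np.ones(9) / 9.0
    motion = np.cumsum(steps, axis=0)
    motion = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, motion)

    # spike artifacts after the settle-in window, flagged invalid
    valid = np.ones(t, dtype=bool)
    n_spikes = math.ceil(cohort.spike_fraction * t)
    spike_volumes = np.empty(0, dtype=int)
    if n_spikes > 0:
        candidates = np.arange(50, t)
        if n_spikes > candidates.size:
            raise ValueError("spike_fraction too high for the post-settle window")
        spike_volumes = np.sort(rng.choice(candidates, size=n_spikes, replace=False))
        # offsets drawn independently per ROI so a spike is not a shared signal
        amp = rng.uniform(6.0, 10.0, size=(n_spikes, r)) * rng.choice([-1.0, 1.0], size=(n_spikes, r))
        data[spike_volumes] += amp
        valid[spike_volumes] = False

    ts = RoiTimeSeriesSet(
        subject_id=subject_id,
        group=group,
        data=data,
        tr_seconds=cohort.tr_seconds,
        valid=valid,
    )
    nuis = NuisanceSet(np.column_stack([motion, csf]), names=list(NUISANCE_NAMES))
    return SimulatedSubject(ts=ts, nuisance=nuis, spike_volumes=spike_volumes)


def generate_cohort(cohort: CohortSpec, effect: EffectSpec | None = None) -> list[SimulatedSubject]:
    """Draw a full two-group cohort; deterministic given ``cohort.seed``.

    Sham subjects sample the baseline modular correlation; lesion
    subjects sample the effect-modified one (identical under
    ``null_flag``). Returns subjects ordered lesion first, then sham.
    """
    if effect is None:
        effect = EffectSpec(null_flag=True)
    factors = effect.effective_factors()
    chol_sham = np.linalg.cholesky(_block_correlation(cohort, (1.0, 1.0), EffectSpec(null_flag=True)))
    if factors == (1.0, 1.0):
        chol_lesion = chol_sham
    else:
        chol_lesion = np.linalg.cholesky(_block_correlation(cohort, factors, effect))
    seeds = np.random.SeedSequence(cohort.seed).spawn(cohort.n_lesion + cohort.n_sham)
    subjects = []
    for i in range(cohort.n_lesion):
        subjects.append(
            _simulate_subject(
                cohort, chol_lesion, f"lesion{i + 1:02d}", "lesion", np.random.default_rng(seeds[i])
            )
        )
    for i in range(cohort.n_sham):
        subjects.append(
            _simulate_subject(
                cohort,
                chol_sham,
                f"sham{i + 1:02d}",
                "sham",
                np.random.default_rng(seeds[cohort.n_lesion + i]),
            )
        )
    return subjects


def make_lattice_graph(n: int, k: int) -> BinaryGraph:
    """Ring lattice: each node joined to its k nearest neighbours (k even)."""
    if k % 2 != 0:
        raise ValueError("k must be even")
    if k >= n:
        raise ValueError("k must be smaller than n")
    if k < 2:
        raise ValueError("k must be at least 2")
    adj = np.zeros((n, n), dtype=np.int8)
    for d in range(1, k // 2 + 1):
        idx = np.arange(n)
        adj[idx, (idx + d) % n] = 1
        adj[(idx + d) % n, idx] = 1
    m = int(np.triu(adj, 1).sum())
    return BinaryGraph(adjacency=adj, sparsity=m / (n * (n - 1) / 2))


def make_random_graph(n: int, m: int, seed: int | None = None) -> BinaryGraph:
    """Erdos-Renyi G(n, m): m distinct edges sampled uniformly, no loops."""
    total = n * (n - 1) // 2
    if not 0 <= m <= total:
        raise ValueError(f"m must lie in [0, {total}] for n={n}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(total, size=m, replace=False)
    ii, jj = np.triu_indices(n, 1)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[ii[chosen], jj[chosen]] = 1
    adj = adj + adj.T
    return BinaryGraph(adjacency=adj, sparsity=max(m, 1) / total if total else 1.0)
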