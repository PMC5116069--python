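"""Wright-Fisher machinery for the selection-shift analysis.

The question: the focal immune allele is essentially fixed in the
ancient panel (60 generations ago) yet at frequency ~0.37 in the modern
sample.  Could drift explain that, or is a shift from positive to
negative selection at European contact required?

The machinery is a discrete Wright-Fisher model: each generation a
deterministic selection update on genotype fitnesses (1, 1+hs, 1+s) is
followed by binomial resampling of 2N chromosomes.  Pieces:

* :func:`wf_backward_neutral` — reverse-time neutral sampling of the
  allele frequency at the East Asian / Native American split (605
  generations ago), conditioned on the modern CHB frequency 0.475 with
  a growth-equivalent constant size of 8,250 diploids.
* :func:`wf_forward` — forward simulation with a per-generation size
  and selection schedule.
* :func:`simulate_shift_models` — the three post-contact regimes
  (neutral / negative / positive) applied 12 generations ago to
  trajectories accepted on the ancient condition (frequency > 0.8 at
  generation 60), reporting the fraction whose binomially sampled
  modern frequency reaches the observed value.
* :func:`sample_posterior_ts` — rejection-sampling posterior for the
  time of the selection shift t ~ U(0, 30) and post-shift coefficient
  s ~ U(-0.5, 0), accepting on the ancient condition plus an exact
  match of the modern derived count (19 of 50 chromosomes).
* :func:`drift_only_null` — the no-selection control: the distribution
  of the allele frequency at generation 60 under pure drift.

All simulations are vectorized across replicates and deterministic
given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import logger, rng_from_seed

__all__ = [
    "ShiftSimConfig",
    "Trajectory",
    "PosteriorSamples",
    "ShiftResult",
    "DriftNull",
    "wf_forward",
    "wf_forward_batch",
    "wf_backward_neutral",
    "simulate_shift_models",
    "sample_posterior_ts",
    "drift_only_null",
]

REGIMES = ("neutral", "negative", "positive")


@dataclass
class ShiftSimConfig:
    """Study conditions for the selection-shift simulations.

    Defaults are the analysis conditions: modern CHB frequency 0.475
    with constant-equivalent size 8,250 diploids over the 605
    generations since the split; ancestral Native American size 13,975
    diploids dropping to 6,006 at the bottleneck 7 generations ago;
    ancient panel at generation 60 with acceptance threshold 0.8;
    European contact 12 generations ago; original selection coefficient
    ~ U(0, 0.1); negative-shift prior U(-0.3, 0); posterior priors
    t ~ U(0, 30) and s ~ U(-0.5, 0); 19 derived of 50 modern
    chromosomes observed, with 0.37 as the modern frequency threshold.
    Dominance is additive (h = 0.5) by default — the shift fractions
    are somewhat sensitive to it, so it is exposed.
    """

    chb_present_freq: float = 0.475
    chb_const_ne: float = 8_250.0
    split_gen: int = 605
    ancestral_ne: float = 13_975.0
    bottleneck_gen: int = 7
    bottleneck_ne: float = 6_006.0
    ancient_sample_gen: int = 60
    ancient_accept_threshold: float = 0.8
    contact_gen: int = 12
    s_original_prior: tuple[float, float] = (0.0, 0.1)
    negative_prior: tuple[float, float] = (-0.3, 0.0)
    posterior_t_prior: tuple[float, float] = (0.0, 30.0)
    posterior_s_prior: tuple[float, float] = (-0.5, 0.0)
    modern_chromosomes: int = 50
    observed_derived: int = 19
    modern_freq_threshold: float = 0.37
    dominance: float = 0.5
    n_reps: int = 10_000
    seed: int | None = None
    max_proposal_factor: int = 200

    def __post_init__(self):
        if not 0 < self.ancient_accept_threshold <= 1:
            raise ValueError("ancient_accept_threshold must lie in (0, 1]")
        if not (self.split_gen > self.ancient_sample_gen > self.contact_gen
                > self.bottleneck_gen >= 0):
            raise ValueError("need split > ancient_sample > contact > bottleneck >= 0")
        for lo, hi in (self.s_original_prior, self.posterior_t_prior):
            if lo > hi:
                raise ValueError("prior bounds must be ordered")
        for lo, hi in (self.negative_prior, self.posterior_s_prior):
            if lo > hi or hi > 0:
                raise ValueError("negative-selection priors must lie at or below 0")
        if not 0 <= self.chb_present_freq <= 1:
            raise ValueError("chb_present_freq must lie in [0, 1]")

    @property
    def observed_count_max(self) -> int:
        """Largest modern derived count counted as reaching the observed
        frequency (the allele is declining, so 'reach or surpass' means
        count/n at or below the threshold)."""
        return int(np.floor(self.modern_chromosomes * self.modern_freq_threshold + 1e-9))

    def native_size_at(self, gen: np.ndarray | int) -> np.ndarray:
        """Diploid size of the Native lineage at a generation before
        present (bottleneck applies from ``bottleneck_gen`` onward)."""
        gen = np.asarray(gen)
        return np.where(gen > self.bottleneck_gen, self.ancestral_ne, self.bottleneck_ne)


@dataclass
class Trajectory:
    """A per-generation derived-allele frequency path, oldest first.

    ``freqs[i]`` is the frequency ``n_gens - i`` generations before the
    end of the simulated span; ``s`` holds the selection coefficient
    applied at each of the ``n_gens`` transitions.
    """

    freqs: np.ndarray
    s: np.ndarray
    absorbed: bool = field(init=False)

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, float)
        self.s = np.asarray(self.s, float)
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("trajectory frequencies must lie in [0, 1]")
        if self.s.size != max(self.freqs.size - 1, 0):
            raise ValueError("need one selection coefficient per transition")
        self.absorbed = bool(self.freqs[-1] in (0.0, 1.0)) if self.freqs.size else False

    @property
    def n_gens(self) -> int:
        return self.freqs.size - 1

    def freq_at(self, gens_before_end: int) -> float:
        """Frequency ``gens_before_end`` generations before the end of
        the trajectory (0 = final frequency)."""
        return float(self.freqs[self.n_gens - gens_before_end])


def _selection_update(p: np.ndarray, s, h) -> np.ndarray:
    """Deterministic one-generation update on fitnesses (1, 1+hs, 1+s)."""
    w11, w01 = 1.0 + np.asarray(s, float), 1.0 + np.asarray(h, float) * np.asarray(s, float)
    q = 1.0 - p
    num = p * p * w11 + p * q * w01
    den = p * p * w11 + 2.0 * p * q * w01 + q * q
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), p)
    return out


def _check_fitness(s, h):
    s = np.asarray(s, float)
    if np.any(1.0 + s <= 0) or np.any(1.0 + h * s <= 0):
        raise ValueError("fitnesses 1+s and 1+hs must be positive")


def _wf_step(p: np.ndarray, n_dip, s, h, rng: np.random.Generator) -> np.ndarray:
    """Selection then binomial resampling of 2N chromosomes."""
    p_sel = _selection_update(p, s, h)
    two_n = np.broadcast_to(np.asarray(np.round(2 * np.asarray(n_dip)), dtype=np.int64), p_sel.shape)
    return rng.binomial(two_n, p_sel) / two_n


def wf_forward(f0: float, sizes, s, h: float = 0.5, n_gens: int | None = None,
               seed=None) -> Trajectory:
    """Forward Wright-Fisher simulation of one allele.

    ``sizes`` and ``s`` may be scalars or per-generation arrays (length
    ``n_gens``); each generation applies the deterministic selection
    update followed by binomial sampling of 2N chromosomes.
    """
    if not 0 <= f0 <= 1:
        raise ValueError("f0 must lie in [0, 1]")
    sizes = np.atleast_1d(np.asarray(sizes, float))
    s_arr = np.atleast_1d(np.asarray(s, float))
    if n_gens is None:
        n_gens = max(sizes.size, s_arr.size)
    sizes = np.broadcast_to(sizes, (n_gens,)) if sizes.size != n_gens else sizes
    s_arr = np.broadcast_to(s_arr, (n_gens,)) if s_arr.size != n_gens else s_arr
    if np.any(sizes < 1):
        raise ValueError("population sizes must be >= 1 diploid")
    _check_fitness(s_arr, h)
    rng = rng_from_seed(seed)
    freqs = np.empty(n_gens + 1)
    freqs[0] = f0
    p = np.asarray(f0, float)
    for g in range(n_gens):
        p = _wf_step(p, sizes[g], s_arr[g], h, rng)
        freqs[g + 1] = p
    return Trajectory(freqs=freqs, s=s_arr.copy())


def wf_forward_batch(f0, sizes, s, h: float = 0.5, n_gens: int | None = None,
                     seed=None) -> np.ndarray:
    """Final frequencies of many independent forward Wright-Fisher
    replicates (vectorized across replicates).

    ``f0`` is an array of starting frequencies, one per replicate;
    ``sizes`` and ``s`` are scalars or per-generation schedules shared
    by all replicates.  Returns the frequency after ``n_gens``
    generations for each replicate.
    """
    f = np.atleast_1d(np.asarray(f0, float)).copy()
    if np.any((f < 0) | (f > 1)):
        raise ValueError("f0 must lie in [0, 1]")
    sizes = np.atleast_1d(np.asarray(sizes, float))
    s_arr = np.atleast_1d(np.asarray(s, float))
    if n_gens is None:
        n_gens = max(sizes.size, s_arr.size)
    sizes = np.broadcast_to(sizes, (n_gens,)) if sizes.size != n_gens else sizes
    s_arr = np.broadcast_to(s_arr, (n_gens,)) if s_arr.size != n_gens else s_arr
    _check_fitness(s_arr, h)
    rng = rng_from_seed(seed)
    for g in range(n_gens):
        f = _wf_step(f, sizes[g], s_arr[g], h, rng)
    return f


def wf_backward_neutral(f_present, n_diploid: float, n_gens: int, seed=None):
    """Reverse-time neutral Wright-Fisher sampling.

    Applies the neutral binomial kernel backward — the previous
    generation's count is drawn as Binomial(2N, f_current) — which is
    the standard approximate time-reversal of neutral drift.  Returns
    the frequency ``n_gens`` generations before the present, as a
    scalar for scalar input or elementwise for an array of present
    frequencies.  Paths absorbed at 0 stay absorbed; downstream
    acceptance conditions remove them where appropriate.
    """
    f = np.atleast_1d(np.asarray(f_present, float))
    if np.any((f < 0) | (f > 1)):
        raise ValueError("f_present must lie in [0, 1]")
    rng = rng_from_seed(seed)
    two_n = int(round(2 * n_diploid))
    for _ in range(n_gens):
        f = rng.binomial(two_n, f) / two_n
    return float(f[0]) if np.isscalar(f_present) else f


# ---------------------------------------------------------------------
# the three post-contact regimes
# ---------------------------------------------------------------------

@dataclass
class ShiftResult:
    fractions: dict[str, float]
    final_freqs: dict[str, np.ndarray]
    sampled_counts: dict[str, np.ndarray]
    n_accepted: int
    n_proposed: int
    n_rejected: int
    config: ShiftSimConfig


def _propose_accepted_trajectories(cfg: ShiftSimConfig, n_needed: int,
                                   rng: np.random.Generator,
                                   s_shift_sampler=None):
    """Vectorized rejection sampling of pre-contact trajectories.

    Returns per-replicate (f at contact generation, s_original, extras)
    for ``n_needed`` trajectories passing the ancient condition
    (frequency above the acceptance threshold at the ancient sampling
    generation).  Raises after ``max_proposal_factor * n_needed``
    proposals with diagnostics if nothing is accepted.
    """
    cap = cfg.max_proposal_factor * n_needed
    batch = int(min(max(2 * n_needed, 1000), 200_000))
    got_f, got_s = [], []
    n_proposed = n_accepted = 0
    while n_accepted < n_needed:
        if n_proposed >= cap:
            if n_accepted == 0:
                raise RuntimeError(
                    f"no trajectory accepted after {n_proposed} proposals; "
                    f"threshold={cfg.ancient_accept_threshold}, "
                    f"s_original~U{cfg.s_original_prior}"
                )
            break
        f = np.full(batch, cfg.chb_present_freq)
        f = wf_backward_neutral(f, cfg.chb_const_ne, cfg.split_gen, rng)
        s_orig = rng.uniform(*cfg.s_original_prior, size=batch)
        # forward from the split to the ancient sampling generation
        for _ in range(cfg.split_gen - cfg.ancient_sample_gen):
            f = _wf_step(f, cfg.ancestral_ne, s_orig, cfg.dominance, rng)
        ok = f > cfg.ancient_accept_threshold
        f, s_orig = f[ok], s_orig[ok]
        # ancient sampling generation down to contact
        for g in range(cfg.ancient_sample_gen, cfg.contact_gen, -1):
            f = _wf_step(f, cfg.native_size_at(g), s_orig, cfg.dominance, rng)
        got_f.append(f)
        got_s.append(s_orig)
        n_proposed += batch
        n_accepted += f.size
    f = np.concatenate(got_f)[:n_needed]
    s_orig = np.concatenate(got_s)[:n_needed]
    n_accepted = min(n_accepted, n_needed)
    return f, s_orig, n_proposed, n_accepted


def simulate_shift_models(config: ShiftSimConfig | None = None, seed=None) -> ShiftResult:
    """Fractions of simulations reaching the observed modern frequency
    under the three post-contact selection regimes.

    Accepted pre-contact trajectories (positive selection with
    s_original ~ U(0, 0.1), frequency above 0.8 at the ancient sampling
    generation) are continued from the contact generation under each
    regime — s = 0 (neutral), s ~ U(-0.3, 0) (negative) or
    s = s_original (positive) — down to the present through the
    bottleneck.  The modern sample is a Binomial(50, f_present) draw;
    a replicate "reaches" the observed frequency when its sampled
    frequency is at or below the observed 0.37 (the allele declined).
    """
    cfg = config or ShiftSimConfig()
    rng = rng_from_seed(cfg.seed if seed is None else seed)
    if cfg.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    f12, s_orig, n_prop, n_acc = _propose_accepted_trajectories(cfg, cfg.n_reps, rng)
    fractions, finals, counts = {}, {}, {}
    for regime in REGIMES:
        if regime == "neutral":
            s_post = np.zeros(n_acc)
        elif regime == "negative":
            s_post = rng.uniform(*cfg.negative_prior, size=n_acc)
        else:
            s_post = s_orig
        f = f12.copy()
        for g in range(cfg.contact_gen, 0, -1):
            f = _wf_step(f, cfg.native_size_at(g), s_post, cfg.dominance, rng)
        k = rng.binomial(cfg.modern_chromosomes, f)
        fractions[regime] = float(np.mean(k <= cfg.observed_count_max))
        finals[regime] = f
        counts[regime] = k
    n_rej = n_prop - n_acc
    logger.info("shift simulations: %d accepted of %d proposed (%d rejected)",
                n_acc, n_prop, n_rej)
    return ShiftResult(fractions=fractions, final_freqs=finals, sampled_counts=counts,
                       n_accepted=n_acc, n_proposed=n_prop, n_rejected=n_rej, config=cfg)


# ---------------------------------------------------------------------
# (t, s) posterior
# ---------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Accepted (t, s) pairs from the rejection sampler."""

    t: np.ndarray
    s: np.ndarray
    s_original: np.ndarray
    n_proposed: int
    n_accepted: int
    n_ancient_ok: int
    n_modern_ok: int = 0

    def __post_init__(self):
        if self.n_accepted != self.t.size or self.t.size != self.s.size:
            raise ValueError("n_accepted must equal the number of (t, s) pairs")


def sample_posterior_ts(config: ShiftSimConfig | None = None, n_accept: int = 10_000,
                        seed=None, tolerance: int = 0) -> PosteriorSamples:
    """Rejection-sampling joint posterior of the shift time t and the
    post-shift selection coefficient s.

    Proposals: s_original ~ U(0, 0.1), t ~ U(0, 30) generations before
    present, s ~ U(-0.5, 0).  A proposal is accepted when the ancient
    condition holds (frequency at least 0.8 at generation 60) and the
    binomially sampled modern derived count matches the observed 19 of
    50 chromosomes to within ``tolerance`` (0 = exact match, the
    default).  Runs until ``n_accept`` pairs are collected or the
    proposal cap is reached, in which case a partial result is returned
    with a warning.
    """
    cfg = config or ShiftSimConfig()
    if n_accept < 1:
        raise ValueError("n_accept must be >= 1")
    rng = rng_from_seed(cfg.seed if seed is None else seed)
    cap = cfg.max_proposal_factor * max(n_accept, 100)
    batch = int(min(max(4 * n_accept, 2000), 200_000))
    acc_t, acc_s, acc_so = [], [], []
    n_proposed = n_ancient_ok = n_accepted = n_modern_ok = 0
    while n_accepted < n_accept and n_proposed < cap:
        f = np.full(batch, cfg.chb_present_freq)
        f = wf_backward_neutral(f, cfg.chb_const_ne, cfg.split_gen, rng)
        s_orig = rng.uniform(*cfg.s_original_prior, size=batch)
        t = rng.uniform(*cfg.posterior_t_prior, size=batch)
        s_neg = rng.uniform(*cfg.posterior_s_prior, size=batch)
        for _ in range(cfg.split_gen - cfg.ancient_sample_gen):
            f = _wf_step(f, cfg.ancestral_ne, s_orig, cfg.dominance, rng)
        ok = f >= cfg.ancient_accept_threshold
        n_ancient_ok += int(ok.sum())
        f, s_orig, t, s_neg = f[ok], s_orig[ok], t[ok], s_neg[ok]
        for g in range(cfg.ancient_sample_gen, 0, -1):
            s_eff = np.where(g <= t, s_neg, s_orig)
            f = _wf_step(f, cfg.native_size_at(g), s_eff, cfg.dominance, rng)
        k = rng.binomial(cfg.modern_chromosomes, f)
        hit = np.abs(k - cfg.observed_derived) <= tolerance
        n_modern_ok += int(hit.sum())
        acc_t.append(t[hit])
        acc_s.append(s_neg[hit])
        acc_so.append(s_orig[hit])
        n_accepted += int(hit.sum())
        n_proposed += batch
    t = np.concatenate(acc_t)[:n_accept] if acc_t else np.empty(0)
    s = np.concatenate(acc_s)[:n_accept] if acc_s else np.empty(0)
    so = np.concatenate(acc_so)[:n_accept] if acc_so else np.empty(0)
    if t.size < n_accept:
        warnings.warn(
            f"proposal cap reached: returning {t.size} of {n_accept} requested samples"
        )
    return PosteriorSamples(t=t, s=s, s_original=so, n_proposed=n_proposed,
                            n_accepted=t.size, n_ancient_ok=n_ancient_ok,
                            n_modern_ok=n_modern_ok)


# ---------------------------------------------------------------------
# drift-only null
# ---------------------------------------------------------------------

@dataclass
class DriftNull:
    freqs_at_ancient: np.ndarray
    tail_probability: float
    threshold: float
    n_reps: int


def drift_only_null(config: ShiftSimConfig | None = None, n_reps: int = 10_000,
                    seed=None) -> DriftNull:
    """Distribution of the allele frequency at the ancient sampling
    generation under pure drift.

    Split frequencies are sampled by the neutral backward simulation
    conditioned on the modern CHB frequency, then evolved forward
    neutrally in the ancestral Native American population to generation
    60.  Reports P(f_60 >= acceptance threshold): if this is small, the
    near-fixed ancient frequency is an outlier under drift alone.
    """
    cfg = config or ShiftSimConfig()
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = rng_from_seed(cfg.seed if seed is None else seed)
    f = np.full(n_reps, cfg.chb_present_freq)
    f = wf_backward_neutral(f, cfg.chb_const_ne, cfg.split_gen, rng)
    for _ in range(cfg.split_gen - cfg.ancient_sample_gen):
        f = _wf_step(f, cfg.ancestral_ne, 0.0, cfg.dominance, rng)
    tail = float(np.mean(f >= cfg.ancient_accept_threshold))
    return DriftNull(freqs_at_ancient=f, tail_probability=tail,
                     threshold=cfg.ancient_accept_threshold, n_reps=n_reps)
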