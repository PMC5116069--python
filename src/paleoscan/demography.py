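"""Demographic model of an ancient/modern exome time transect.

The default model (:func:`prh_model`) describes a Northwest Coast Native
American population sampled at two time points: an ancient panel drawn 60
generations before present and its modern descendants.  The history is a
four-population tree with an African root, an out-of-Africa bottleneck, an
East Asian (CHB) / European (GBR) split with exponential growth, a Native
American lineage splitting from the East Asian branch, a severe
post-contact bottleneck seven generations ago, and a recent European
admixture pulse (fraction 0.33, four generations ago) into the modern
population.  The European population acts as a "ghost": it is never part
of the fitted site-frequency spectrum but supplies admixed ancestry.

The module provides

* model containers with validation (:class:`Epoch`, :class:`PopulationSpec`,
  :class:`DemographicModel`) and conversion to an msprime demography,
* joint derived site-frequency-spectrum simulation with ancient sampling
  (:func:`simulate_joint_sfs`), monomorphic cell included,
* a multinomial composite likelihood over SFS cells
  (:func:`composite_loglik`) and simulation-based fitting with random
  restarts (:func:`fit_demography`) plus parametric-bootstrap confidence
  intervals (:func:`parametric_bootstrap`),
* growth-equivalent constant population sizes
  (:func:`equivalent_constant_ne`), defined through elapsed coalescent
  time (the harmonic-mean size over an epoch).

Time is handled in integer-ish generations internally; years appear only
at the interface and are converted with :func:`years_to_generations`
(generation time 25 years by default).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import msprime
import numpy as np
import pandas as pd
from scipy import integrate, optimize

from ._util import logger, rng_from_seed, spawn_seeds

__all__ = [
    "Epoch",
    "PopulationSpec",
    "Admixture",
    "Split",
    "DemographicModel",
    "JointSFS",
    "FitResult",
    "prh_model",
    "rescale_model",
    "equivalent_constant_ne",
    "years_to_generations",
    "size_reduction",
    "simulate_joint_sfs",
    "simulate_region",
    "RegionSample",
    "composite_loglik",
    "fit_demography",
    "parametric_bootstrap",
]

GENERATION_TIME = 25.0


class ModelValidationError(ValueError):
    """Raised when a demographic model violates its structural invariants."""


@dataclass(frozen=True)
class Epoch:
    """A span of a population's history, looking backward in time.

    ``size`` is the diploid effective size at ``start_gen`` (the recent
    edge of the epoch); with ``growth_rate`` r the size at time t within
    the epoch is ``size * exp(-r * (t - start_gen))`` — the msprime
    convention, so r > 0 means the population grew forward in time.
    """

    start_gen: float
    end_gen: float
    size: float
    growth_rate: float = 0.0

    def __post_init__(self):
        if self.size <= 0:
            raise ModelValidationError(f"epoch size must be > 0, got {self.size}")
        if self.end_gen <= self.start_gen:
            raise ModelValidationError("epoch end must be after (older than) start")

    def size_at(self, t: float) -> float:
        return self.size * math.exp(-self.growth_rate * (t - self.start_gen))


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    epochs: tuple[Epoch, ...]
    sampling_time: float = 0.0
    sample_size: int = 0  # haploid count

    def __post_init__(self):
        object.__setattr__(self, "epochs", tuple(self.epochs))
        if self.sampling_time < 0:
            raise ModelValidationError("sampling_time must be >= 0")
        if self.sample_size < 0:
            raise ModelValidationError("sample_size must be >= 0")
        eps = sorted(self.epochs, key=lambda e: e.start_gen)
        if tuple(eps) != self.epochs:
            raise ModelValidationError(f"epochs of {self.name} must be ordered by start_gen")
        for a, b in zip(eps, eps[1:]):
            if not math.isclose(a.end_gen, b.start_gen):
                raise ModelValidationError(
                    f"epochs of {self.name} must be contiguous and non-overlapping"
                )


@dataclass(frozen=True)
class Admixture:
    """A single instantaneous admixture pulse: ``target`` receives a
    ``fraction`` of its ancestry from ``source`` at ``time_gen``."""

    time_gen: float
    source: str
    target: str
    fraction: float

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ModelValidationError("admixture fraction must be in [0, 1]")


@dataclass(frozen=True)
class Split:
    time_gen: float
    derived: tuple[str, ...]
    ancestral: str

    def __post_init__(self):
        der = (self.derived,) if isinstance(self.derived, str) else tuple(self.derived)
        object.__setattr__(self, "derived", der)


@dataclass
class DemographicModel:
    populations: list[PopulationSpec]
    splits: list[Split] = field(default_factory=list)
    admixture: Admixture | None = None
    generation_time: float = GENERATION_TIME
    mutation_rate: float = 2.5e-8
    recombination_rate: float = 2.5e-8
    sequence_length: float = 7.4e6

    def __post_init__(self):
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ModelValidationError("duplicate population names")
        if self.mutation_rate <= 0 or self.recombination_rate < 0:
            raise ModelValidationError("rates must be positive")
        byname = {p.name: p for p in self.populations}
        for s in self.splits:
            for nm in (*s.derived, s.ancestral):
                if nm not in byname:
                    raise ModelValidationError(f"split references unknown population {nm!r}")
        # split times strictly ordered along each lineage
        parent = {}
        t_of = {}
        for s in self.splits:
            for d in s.derived:
                if d in parent:
                    raise ModelValidationError(f"population {d!r} splits twice")
                parent[d] = s.ancestral
                t_of[d] = s.time_gen
        for d in parent:
            node, t = d, t_of[d]
            while node in parent:
                nxt = parent[node]
                if nxt in t_of and not t_of[node] < t_of.get(nxt, math.inf):
                    raise ModelValidationError(
                        f"split times not strictly ordered along lineage through {node!r}"
                    )
                node = nxt
        if self.admixture is not None:
            for nm in (self.admixture.source, self.admixture.target):
                if nm not in byname:
                    raise ModelValidationError(f"admixture references unknown population {nm!r}")
        # ancient samples must predate... i.e. be more recent than the split
        for p in self.populations:
            if p.sample_size and p.name in t_of and p.sampling_time > t_of[p.name]:
                raise ModelValidationError(
                    f"{p.name} sampled at {p.sampling_time} after its split at {t_of[p.name]}"
                )

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def sampled_populations(self) -> list[str]:
        return [p.name for p in self.populations if p.sample_size > 0]

    # -- msprime bridge ------------------------------------------------
    def to_msprime(self) -> msprime.Demography:
        dem = msprime.Demography()
        # populations that are the ancestral side of a split are inactive
        # until the split by msprime default; sampled ones (e.g. an
        # outgroup that continues to the present) must be active from 0
        ancestral_of = {s.ancestral for s in self.splits}
        for p in self.populations:
            first = p.epochs[0]
            kw = {}
            if p.name in ancestral_of and (p.sample_size > 0 or first.start_gen == 0):
                kw["initially_active"] = True
            dem.add_population(
                name=p.name,
                initial_size=first.size,
                growth_rate=first.growth_rate if first.start_gen == 0 else 0.0,
                **kw,
            )
            for ep in p.epochs:
                if ep.start_gen > 0:
                    dem.add_population_parameters_change(
                        time=ep.start_gen,
                        population=p.name,
                        initial_size=ep.size,
                        growth_rate=ep.growth_rate,
                    )
        if self.admixture is not None and self.admixture.fraction > 0:
            adm = self.admixture
            # backward in time: lineages in target jump to source; a
            # zero-fraction pulse is a null event and is dropped so it
            # cannot perturb the random stream
            dem.add_mass_migration(
                time=adm.time_gen, source=adm.target, dest=adm.source, proportion=adm.fraction
            )
        for s in sorted(self.splits, key=lambda s: s.time_gen):
            dem.add_population_split(
                time=s.time_gen, derived=list(s.derived), ancestral=s.ancestral
            )
        dem.sort_events()
        return dem

    def sample_sets(self, pops: Sequence[str] | None = None) -> list[msprime.SampleSet]:
        pops = list(pops) if pops is not None else self.sampled_populations
        out = []
        for nm in pops:
            p = self.population(nm)
            if p.sample_size % 2:
                raise ModelValidationError("haploid sample sizes must be even (diploid samples)")
            out.append(
                msprime.SampleSet(p.sample_size // 2, population=nm,
                                  time=p.sampling_time, ploidy=2)
            )
        return out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        pops = [
            PopulationSpec(
                name=p["name"],
                epochs=tuple(Epoch(**e) for e in p["epochs"]),
                sampling_time=p.get("sampling_time", 0.0),
                sample_size=p.get("sample_size", 0),
            )
            for p in d["populations"]
        ]
        splits = [Split(s["time_gen"], tuple(s["derived"]), s["ancestral"]) for s in d.get("splits", [])]
        adm = d.get("admixture")
        admixture = Admixture(**adm) if adm else None
        kw = {
            k: d[k]
            for k in ("generation_time", "mutation_rate", "recombination_rate", "sequence_length")
            if k in d
        }
        return cls(populations=pops, splits=splits, admixture=admixture, **kw)


# ---------------------------------------------------------------------
# the default time-transect model
# ---------------------------------------------------------------------

def prh_model(
    *,
    n_prh: float = 13_975.0,
    n_tsim: float = 6_006.0,
    t_na: float = 605.0,
    t_bcol: float = 7.0,
    ancient_sample_gen: float = 60.0,
    admixture_fraction: float = 0.33,
    admixture_gen: float = 4.0,
    n_chb0: float = 550.0,
    chb_growth_rate: float = 0.0048,
    n_gbr0: float = 1_032.0,
    gbr_growth_rate: float = 0.0038,
    t_eur_asn: float = 920.0,
    n_ooa: float = 1_861.0,
    t_ooa: float = 2_040.0,
    n_af: float = 14_474.0,
    n_ancestral: float = 7_310.0,
    t_af_expansion: float = 5_920.0,
    sample_size: int = 50,
    mutation_rate: float = 2.5e-8,
    recombination_rate: float = 2.5e-8,
    sequence_length: float = 7.4e6,
) -> DemographicModel:
    """Best-fitting time-transect demography, in generations.

    Free (fitted) quantities are the bottleneck parameters ``n_prh``,
    ``n_tsim``, the split ``t_na`` and the bottleneck time ``t_bcol``
    (defaults are the point estimates: 13,975 and 6,006 diploids, 605 and
    7 generations).  The remaining structure is fixed: out-of-Africa
    bottleneck (N=1,861 at 51 kya), CHB/GBR split at 23 kya with
    exponential growth from 550 and 1,032 diploids, and a European
    admixture pulse of 0.33 into the modern population 100 years ago.
    The CHB and GBR growth rates since their split are not part of the
    fitted model and are accepted as inputs (defaults 0.48%/0.38% per
    generation, the commonly used continental-expansion values).

    Populations named ``PRH`` (ancient panel, sampled ``ancient_sample_gen``
    generations ago), ``TSIM`` (modern descendants), ``CHB`` (outgroup)
    and ``GBR`` (European reference / admixture source).
    """
    if not t_bcol < ancient_sample_gen < t_na < t_eur_asn < t_ooa:
        raise ModelValidationError("event times must satisfy t_bcol < ancient < t_na < t_eur_asn < t_ooa")
    chb_present = n_chb0 * math.exp(chb_growth_rate * t_eur_asn)
    gbr_present = n_gbr0 * math.exp(gbr_growth_rate * t_eur_asn)
    pops = [
        PopulationSpec(
            "TSIM",
            (
                Epoch(0.0, t_bcol, n_tsim),
                Epoch(t_bcol, ancient_sample_gen, n_prh),
            ),
            sampling_time=0.0,
            sample_size=sample_size,
        ),
        PopulationSpec(
            "PRH",
            (Epoch(ancient_sample_gen, t_na, n_prh),),
            sampling_time=ancient_sample_gen,
            sample_size=sample_size,
        ),
        PopulationSpec(
            "CHB",
            (Epoch(0.0, t_eur_asn, chb_present, chb_growth_rate),),
            sampling_time=0.0,
            sample_size=sample_size,
        ),
        PopulationSpec(
            "GBR",
            (Epoch(0.0, t_eur_asn, gbr_present, gbr_growth_rate),),
            sampling_time=0.0,
            sample_size=sample_size,
        ),
        PopulationSpec("OOA", (Epoch(t_eur_asn, t_ooa, n_ooa),)),
        PopulationSpec(
            "AF",
            (Epoch(0.0, t_af_expansion, n_af), Epoch(t_af_expansion, math.inf, n_ancestral)),
        ),
    ]
    splits = [
        Split(ancient_sample_gen, ("TSIM",), "PRH"),
        Split(t_na, ("PRH",), "CHB"),
        Split(t_eur_asn, ("CHB", "GBR"), "OOA"),
        Split(t_ooa, ("OOA",), "AF"),
    ]
    admixture = (
        Admixture(admixture_gen, source="GBR", target="TSIM", fraction=admixture_fraction)
        if admixture_fraction > 0
        else None
    )
    return DemographicModel(
        populations=pops,
        splits=splits,
        admixture=admixture,
        mutation_rate=mutation_rate,
        recombination_rate=recombination_rate,
        sequence_length=sequence_length,
    )


def rescale_model(model: DemographicModel, factor: float) -> DemographicModel:
    """Rescale a model for desk-scale runs: sizes and times divided by
    ``factor``, mutation and recombination rates multiplied by it.
    Population-genetic compound parameters (theta, rho, drift per unit
    of scaled time) are preserved; outputs computed under a rescaled
    model should be flagged as such."""
    if factor < 1:
        raise ValueError("rescale factor must be >= 1")
    f = float(factor)

    def ep(e: Epoch) -> Epoch:
        return Epoch(e.start_gen / f, e.end_gen / f, e.size / f, e.growth_rate * f)

    pops = [
        PopulationSpec(p.name, tuple(ep(e) for e in p.epochs), p.sampling_time / f, p.sample_size)
        for p in model.populations
    ]
    splits = [Split(s.time_gen / f, s.derived, s.ancestral) for s in model.splits]
    adm = model.admixture
    admixture = Admixture(adm.time_gen / f, adm.source, adm.target, adm.fraction) if adm else None
    return DemographicModel(
        populations=pops,
        splits=splits,
        admixture=admixture,
        generation_time=model.generation_time,
        mutation_rate=model.mutation_rate * f,
        recombination_rate=model.recombination_rate * f,
        sequence_length=model.sequence_length,
    )


# ---------------------------------------------------------------------
# small closed-form helpers
# ---------------------------------------------------------------------

def years_to_generations(years: float, generation_time: float = GENERATION_TIME) -> int:
    """Convert years before present to (rounded) generations."""
    if years < 0:
        raise ValueError("years must be >= 0")
    return int(round(years / generation_time))


def size_reduction(n_before: float, n_after: float) -> float:
    """Fractional effective-size reduction across a bottleneck, e.g.
    13,975 -> 6,006 diploids gives 0.57."""
    if n_before <= 0 or n_after < 0:
        raise ValueError("sizes must be positive")
    return 1.0 - n_after / n_before


def equivalent_constant_ne(epoch_length: float, size_history: Callable[[float], float]) -> float:
    """Constant diploid size with the same elapsed coalescent time as a
    varying history over an epoch.

    Solves ``integral_0^L dt / (2 N(t)) = L / (2 Nc)`` for Nc, i.e. the
    harmonic-mean size.  ``size_history(t)`` gives the diploid size t
    time units into the epoch and must be strictly positive.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be > 0")
    for t in np.linspace(0.0, epoch_length, 7):
        if size_history(float(t)) <= 0:
            raise ValueError("size_history must be strictly positive over the epoch")
    val, _ = integrate.quad(lambda t: 1.0 / size_history(t), 0.0, epoch_length, limit=200)
    return float(epoch_length / val)


# ---------------------------------------------------------------------
# joint SFS
# ---------------------------------------------------------------------

@dataclass
class JointSFS:
    """Joint derived site-frequency spectrum, monomorphic cell included.

    ``counts[i, j, ...]`` is the number of sites with i derived copies in
    the first population's sample, j in the second, etc.  The all-zero
    cell holds the monomorphic (ancestral in every sample) sites so that
    ``counts.sum()`` equals the total number of surveyed sites.
    """

    pops: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        self.pops = tuple(self.pops)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != len(self.pops):
            raise ValueError("counts dimensionality must match number of populations")
        if np.any(self.counts < 0):
            raise ValueError("SFS counts must be non-negative")

    @property
    def sample_sizes(self) -> tuple[int, ...]:
        return tuple(s - 1 for s in self.counts.shape)

    @property
    def total_sites(self) -> float:
        return float(self.counts.sum())

    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def marginal(self, pop: str) -> np.ndarray:
        ax = tuple(i for i, p in enumerate(self.pops) if p != pop)
        return self.counts.sum(axis=ax)

    def to_frame(self) -> pd.DataFrame:
        idx = np.indices(self.counts.shape).reshape(len(self.pops), -1)
        df = pd.DataFrame({p: idx[i] for i, p in enumerate(self.pops)})
        df["n_sites"] = self.counts.ravel()
        return df[df["n_sites"] > 0].reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, pops: Sequence[str], shape: Sequence[int]) -> "JointSFS":
        counts = np.zeros(tuple(shape))
        counts[tuple(df[p].to_numpy(dtype=int) for p in pops)] = df["n_sites"].to_numpy()
        return cls(tuple(pops), counts)


@dataclass
class RegionSample:
    """Haplotypes simulated for one genomic region."""

    positions: np.ndarray            # float positions in [0, L)
    genotypes: np.ndarray            # (n_sites, n_haplotypes) 0/1 derived
    pop_slices: dict[str, slice]     # haplotype columns per population
    sequence_length: float

    def derived_counts(self, pop: str) -> np.ndarray:
        return self.genotypes[:, self.pop_slices[pop]].sum(axis=1)

    def n_haploid(self, pop: str) -> int:
        sl = self.pop_slices[pop]
        return sl.stop - sl.start

    def frequencies(self, pop: str) -> np.ndarray:
        return self.derived_counts(pop) / self.n_haploid(pop)


def _sim_ancestry(model, length, seed, pops, num_replicates=None):
    return msprime.sim_ancestry(
        samples=model.sample_sets(pops),
        demography=model.to_msprime(),
        sequence_length=length,
        recombination_rate=model.recombination_rate,
        ploidy=2,
        random_seed=seed,
        num_replicates=num_replicates,
        discrete_genome=False,
    )


def _sample_index_sets(ts, model, pops):
    """Sample node IDs per requested population, in request order."""
    name_to_id = {p.metadata["name"]: p.id for p in ts.populations()}
    return [ts.samples(population=name_to_id[nm]) for nm in pops]


def simulate_region(model: DemographicModel, *, sequence_length: float | None = None,
                    seed: int | None = None, pops: Sequence[str] | None = None) -> RegionSample:
    """Simulate haplotypes for a single region under the model.

    Used by the selection-scan null, the synthetic exome generator and
    tests.  Sites are polarized derived/ancestral (infinite-sites
    mutations on the simulated genealogy).
    """
    pops = list(pops) if pops is not None else model.sampled_populations
    L = float(sequence_length if sequence_length is not None else model.sequence_length)
    s1, s2 = spawn_seeds(seed, 2)
    ts = _sim_ancestry(model, L, s1, pops)
    ts = msprime.sim_mutations(ts, rate=model.mutation_rate, random_seed=s2,
                               discrete_genome=False)
    sets = _sample_index_sets(ts, model, pops)
    order = np.concatenate(sets) if sets and ts.num_samples else np.array([], dtype=int)
    G = ts.genotype_matrix()
    if order.size:
        G = G[:, order]
    G = (G > 0).astype(np.int8)
    slices, at = {}, 0
    for nm, s in zip(pops, sets):
        slices[nm] = slice(at, at + len(s))
        at += len(s)
    pos = np.array([v.position for v in ts.variants()]) if ts.num_sites else np.empty(0)
    return RegionSample(positions=pos, genotypes=G, pop_slices=slices, sequence_length=L)


def simulate_joint_sfs(model: DemographicModel, seed: int | None = None, *,
                       pops: Sequence[str] | None = None,
                       num_chunks: int = 1) -> JointSFS:
    """Simulate the joint derived SFS under the model.

    The monomorphic cell is filled so that the total equals the model's
    ``sequence_length`` in sites.  With ``num_chunks`` > 1 the sequence
    is simulated as that many independent replicates of equal length and
    the spectra summed — the composite-likelihood machinery treats cells
    as independent anyway, and replicates are far cheaper than one long
    recombining sequence.
    """
    pops = list(pops) if pops is not None else model.sampled_populations
    if not pops:
        raise ModelValidationError("no sampled populations")
    s1, s2 = spawn_seeds(seed, 2)
    chunk_len = model.sequence_length / num_chunks
    reps = _sim_ancestry(model, chunk_len, s1, pops,
                         num_replicates=num_chunks if num_chunks > 1 else None)
    if num_chunks == 1:
        reps = [reps]
    counts = None
    n_sites = 0.0
    mut_seeds = spawn_seeds(s2, num_chunks)
    for ts, ms in zip(reps, mut_seeds):
        ts = msprime.sim_mutations(ts, rate=model.mutation_rate, random_seed=ms,
                                   discrete_genome=False)
        sets = _sample_index_sets(ts, model, pops)
        afs = ts.allele_frequency_spectrum(sample_sets=sets, polarised=True,
                                           span_normalise=False)
        counts = afs if counts is None else counts + afs
        n_sites += ts.num_sites
    zero = (0,) * len(pops)
    counts[zero] += max(0.0, round(model.sequence_length) - n_sites)
    return JointSFS(tuple(pops), counts)


# ---------------------------------------------------------------------
# composite likelihood and fitting
# ---------------------------------------------------------------------

def composite_loglik(observed: JointSFS, expected: JointSFS, floor: float | None = None) -> float:
    """Multinomial composite log-likelihood of ``observed`` SFS counts
    under the cell proportions of ``expected``.

    Empty expected cells are floored at ``1 / (2 * total expected sites)``
    (configurable) before taking logs, so a single unobserved-in-expected
    cell cannot send the likelihood to -inf.
    """
    if observed.pops != expected.pops or observed.counts.shape != expected.counts.shape:
        raise ValueError("observed and expected SFS axes do not match")
    total = expected.counts.sum()
    if total <= 0:
        raise ValueError("expected SFS is empty")
    if floor is None:
        floor = 1.0 / (2.0 * total)
    p = np.maximum(expected.counts / total, floor)
    return float(np.sum(observed.counts * np.log(p)))


@dataclass
class FitResult:
    params: dict[str, float]
    loglik: float
    ci: dict[str, tuple[float, float]] | None = None
    n_optimizations: int = 0
    n_failures: int = 0
    rescaled: bool = False

    def __post_init__(self):
        if not math.isfinite(self.loglik):
            raise ValueError("fitted log-likelihood must be finite")
        if self.ci:
            for k, (lo, hi) in self.ci.items():
                if not lo <= self.params[k] <= hi:
                    raise ValueError(f"CI for {k} does not bracket the point estimate")


def _expected_sfs(builder, params, pops, eval_seed, sim_chunks, expected_factor=1.0):
    model = builder(**params)
    if expected_factor != 1.0:
        model = dataclasses.replace(
            model, sequence_length=model.sequence_length * expected_factor)
    return simulate_joint_sfs(model, seed=eval_seed, pops=pops, num_chunks=sim_chunks)


def fit_demography(
    observed: JointSFS,
    builder: Callable[..., DemographicModel],
    free_params: dict[str, tuple[float, float]],
    *,
    n_optimizations: int = 100,
    seed: int | None = None,
    sim_chunks: int = 100,
    expected_factor: float = 10.0,
    fixed_params: dict | None = None,
    bootstrap_reps: int = 0,
    maxiter: int = 80,
    rescaled: bool = False,
) -> FitResult:
    """Fit free demographic parameters by maximum composite likelihood.

    ``builder(**params)`` must return a :class:`DemographicModel`; the
    expected SFS for each likelihood evaluation is estimated from
    ``sim_chunks`` simulation replicates using a seed held fixed across
    evaluations (common random numbers), so the noisy likelihood surface
    is at least a fixed surface and the fit is deterministic given
    ``seed``; the expected genome is ``expected_factor`` times longer
    than the model's, which keeps Monte-Carlo noise in the expected cell
    proportions well below the observed-data sampling noise.  ``n_optimizations`` bounded Nelder–Mead searches are run
    from uniform random starting points (in log space) and the best
    likelihood wins.  Optimizer excursions beyond the bounds are clamped
    with a warning.

    With ``bootstrap_reps`` > 0 a parametric bootstrap is run at the
    fitted values to attach percentile 95% confidence intervals.
    """
    fixed_params = dict(fixed_params or {})
    names = list(free_params)
    if not names:
        model = builder(**fixed_params)
        ll = composite_loglik(
            observed, simulate_joint_sfs(model, seed=seed, pops=list(observed.pops),
                                         num_chunks=sim_chunks)
        )
        return FitResult(params=dict(fixed_params), loglik=ll, n_optimizations=0,
                         rescaled=rescaled)
    lo = np.array([free_params[n][0] for n in names], dtype=float)
    hi = np.array([free_params[n][1] for n in names], dtype=float)
    if np.any(lo <= 0):
        raise ValueError("parameter bounds must be positive")
    log_lo, log_hi = np.log(lo), np.log(hi)
    eval_seed, start_seed = spawn_seeds(seed, 2)
    rng = rng_from_seed(start_seed)
    pops = list(observed.pops)

    clamped = [False]

    def negloglik(x_log: np.ndarray) -> float:
        x = np.exp(np.asarray(x_log, dtype=float))
        if np.any(x < lo) or np.any(x > hi):
            clamped[0] = True
            x = np.clip(x, lo, hi)
        params = dict(fixed_params)
        params.update(dict(zip(names, x)))
        expected = _expected_sfs(builder, params, pops, eval_seed, sim_chunks,
                                 expected_factor)
        return -composite_loglik(observed, expected)

    best_x, best_nll = None, math.inf
    for _ in range(n_optimizations):
        x0 = rng.uniform(log_lo, log_hi)
        res = optimize.minimize(
            negloglik, x0, method="Nelder-Mead",
            bounds=list(zip(log_lo, log_hi)),
            options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-2},
        )
        if res.fun < best_nll:
            best_nll, best_x = res.fun, res.x
    if clamped[0]:
        warnings.warn("optimizer left the parameter bounds; values were clamped")
    fitted = dict(fixed_params)
    fitted.update(dict(zip(names, np.clip(np.exp(best_x), lo, hi))))
    result = FitResult(params=fitted, loglik=-best_nll, n_optimizations=n_optimizations,
                       rescaled=rescaled)
    if bootstrap_reps > 0:
        boot_seed = spawn_seeds(seed, 3)[2]
        ci = parametric_bootstrap(
            builder, fitted, free_params, observed_pops=pops,
            observed_chunks=1, n_reps=bootstrap_reps, seed=boot_seed,
            sim_chunks=sim_chunks, expected_factor=expected_factor,
            fixed_params=fixed_params, maxiter=maxiter,
        )
        result.ci = {k: ci[k] for k in names}
        # re-validate bracket invariant
        result.__post_init__()
    return result


def parametric_bootstrap(
    builder: Callable[..., DemographicModel],
    fitted_params: dict[str, float],
    free_params: dict[str, tuple[float, float]],
    *,
    observed_pops: Sequence[str],
    n_reps: int,
    seed: int | None = None,
    sim_chunks: int = 100,
    expected_factor: float = 10.0,
    observed_chunks: int = 1,
    n_optimizations: int = 1,
    fixed_params: dict | None = None,
    maxiter: int = 80,
) -> dict[str, tuple[float, float]]:
    """Percentile 95% confidence intervals from refits to SFS replicates
    simulated at the fitted parameter values.

    Individual refit failures are logged and skipped; only a complete
    failure is fatal.  The point estimate is included in the percentile
    sample so that reported intervals always bracket it, which matters
    at the small replicate counts used for desk-scale runs.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    names = list(free_params)
    seeds = spawn_seeds(seed, 2 * n_reps)
    estimates = {n: [fitted_params[n]] for n in names}
    n_fail = 0
    for r in range(n_reps):
        try:
            model = builder(**fitted_params)
            rep = simulate_joint_sfs(model, seed=seeds[2 * r], pops=list(observed_pops),
                                     num_chunks=observed_chunks)
            fit = fit_demography(
                rep, builder, free_params, n_optimizations=n_optimizations,
                seed=seeds[2 * r + 1], sim_chunks=sim_chunks,
                expected_factor=expected_factor,
                fixed_params=fixed_params, maxiter=maxiter,
            )
            for n in names:
                estimates[n].append(fit.params[n])
        except Exception as exc:  # refit failures recorded, not fatal
            n_fail += 1
            logger.warning("bootstrap replicate %d failed: %s", r, exc)
    if n_fail == n_reps:
        raise RuntimeError("all bootstrap replicates failed")
    ci = {}
    for n in names:
        vals = np.array(estimates[n])
        lo_q, hi_q = np.percentile(vals, [2.5, 97.5])
        ci[n] = (min(lo_q, fitted_params[n]), max(hi_q, fitted_params[n]))
    return ci
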