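"""Synthetic exome datasets emulating the time-transect study design.

Every pipeline stage is testable without any download: this module
generates gene annotations, haplotypes, true allele frequencies and
genotype likelihoods for four populations under the time-transect
demography, with the ancient panel drawn 60 generations before present.

The design emulated: 25 diploid individuals per population (50
haplotypes), gene transcripts with 10 kb flanks laid on a synthetic
chromosome, mean sequencing depth 7.97x for the ancient panel and
9.66x for the modern ones, per-base error and missingness, an optional
positively selected gene injected with a prescribed allele-frequency
trajectory, and European admixture (fraction 0.33) in the modern
population.  Genotype likelihoods are emitted directly from simulated
genotypes through the depth/error model; read-level artefacts (mapping,
end-trimming, post-mortem damage) are not emulated, though a C/T-G/A
site mask is available downstream for the structure-analysis filter.

A truth record (true sample frequencies, generative admixture fraction,
selected gene and trajectory) is retained for every dataset so tests
can score recovery.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from ._util import rng_from_seed, spawn_seeds
from .demography import DemographicModel, prh_model, simulate_region
from .freqs import FrequencyTable, GenotypeLikelihoodMatrix, SITE_COLUMNS
from .pbs import GeneAnnotation
from .trajectory import Trajectory

__all__ = [
    "SyntheticExomeConfig",
    "SyntheticDataset",
    "generate_exome_dataset",
    "inject_selected_gene",
    "generate_gene_lengths",
]

_BASES = np.array(list("ACGT"))
ANCIENT_POP = "PRH"
FLANK_ADDED = 20_000  # 10 kb upstream + 10 kb downstream


@dataclass
class SyntheticExomeConfig:
    """Study-design parameters of the generator.

    ``length_dist`` describes transcript lengths: ``("lognormal", mu,
    sigma)`` on the log scale (default median ~2.5 kb, a realistic
    transcript-length spread), ``("fixed", L)``, or an explicit array
    resampled with replacement.
    """

    model: DemographicModel | None = None
    n_genes: int = 200
    length_dist: tuple = ("lognormal", math.log(2_500.0), 0.8)
    depth_ancient: float = 7.97
    depth_modern: float = 9.66
    base_error: float = 0.002
    missingness: float = 0.05
    flank: int = 10_000
    gene_spacing: int = 1_000
    min_transcript: int = 200
    seed: int | None = None

    def __post_init__(self):
        if self.depth_ancient <= 0 or self.depth_modern <= 0:
            raise ValueError("depths must be > 0")
        for r in (self.base_error, self.missingness):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.model is None:
            self.model = prh_model()


@dataclass
class SyntheticDataset:
    config: SyntheticExomeConfig
    genes: list[GeneAnnotation]
    sites: pd.DataFrame                      # chrom,pos,ancestral,derived,gene_id
    haplotypes: dict[str, np.ndarray]        # pop -> (n_hap, n_sites) 0/1
    frequency_table: FrequencyTable          # true sample frequencies
    genotype_likelihoods: dict[str, GenotypeLikelihoodMatrix]
    truth: dict

    @property
    def pops(self) -> list[str]:
        return list(self.haplotypes)


def generate_gene_lengths(dist, n: int, seed=None, add: int = FLANK_ADDED) -> np.ndarray:
    """Draw ``n`` positive gene-scan lengths and add 20 kb of flanks,
    mirroring how transcript lengths feed the neutral null."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng_from_seed(seed)
    if isinstance(dist, tuple) and dist and dist[0] == "lognormal":
        _, mu, sigma = dist
        lengths = rng.lognormal(mu, sigma, size=n)
    elif isinstance(dist, tuple) and dist and dist[0] == "fixed":
        lengths = np.full(n, float(dist[1]))
    else:
        pool = np.asarray(dist, float)
        lengths = rng.choice(pool, size=n, replace=True)
    lengths = np.maximum(np.round(lengths), 1.0)
    return lengths + add


def _draw_alleles(n_sites: int, rng) -> tuple[np.ndarray, np.ndarray]:
    anc = rng.integers(0, 4, size=n_sites)
    der = (anc + rng.integers(1, 4, size=n_sites)) % 4
    return _BASES[anc], _BASES[der]


def _genotype_likelihoods(genotypes: np.ndarray, depth: float, base_error: float,
                          missingness: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Likelihoods from a per-individual depth/error read model.

    Per (site, individual): depth ~ Poisson(mean depth); derived-read
    count ~ Binomial(depth, p_g) with p_g = e, 1/2, 1-e for genotypes
    0, 1, 2; GL(g) is the binomial likelihood of the observed counts,
    normalized to max 1.  Individuals with zero reads (or hit by the
    extra missingness rate) are flagged missing.
    """
    S, I = genotypes.shape
    d = rng.poisson(depth, size=(S, I))
    missing = (d == 0) | (rng.random((S, I)) < missingness)
    p_read = np.array([base_error, 0.5, 1.0 - base_error])
    k = rng.binomial(d, p_read[genotypes])
    gl = np.empty((S, I, 3))
    for g in range(3):
        gl[:, :, g] = _stats.binom.pmf(k, d, p_read[g])
    m = gl.max(axis=2, keepdims=True)
    gl = np.divide(gl, m, out=np.zeros_like(gl), where=m > 0)
    gl[missing] = 0.0
    gl[missing, 0] = 1.0  # placeholder; masked by the missing flag
    return gl, missing


def generate_exome_dataset(config: SyntheticExomeConfig | None = None,
                           seed=None) -> SyntheticDataset:
    """Simulate a full synthetic exome dataset.

    Each gene region (transcript + flanks) is simulated independently
    under the demographic model; true per-population sample frequencies
    come straight from the simulated haplotypes, and genotype
    likelihoods are layered on top through the depth/error model.
    Byte-identical given the same config and seed.
    """
    cfg = config or SyntheticExomeConfig()
    master = cfg.seed if seed is None else seed
    s_len, s_regions, s_alleles, s_gl = spawn_seeds(master, 4)
    rng_alleles = rng_from_seed(s_alleles)
    transcripts = generate_gene_lengths(cfg.length_dist, cfg.n_genes, seed=s_len, add=0)
    transcripts = np.maximum(transcripts, cfg.min_transcript)
    region_seeds = spawn_seeds(s_regions, cfg.n_genes)
    pops = cfg.model.sampled_populations
    genes, site_frames = [], []
    haps = {p: [] for p in pops}
    offset = 0
    for g in range(cfg.n_genes):
        t_len = int(transcripts[g])
        region_len = t_len + 2 * cfg.flank
        region = simulate_region(cfg.model, sequence_length=region_len,
                                 seed=region_seeds[g], pops=pops)
        start = offset + cfg.flank + 1
        genes.append(GeneAnnotation(gene_id=f"G{g}", chrom="chr1", start=start,
                                    end=start + t_len - 1, flank=cfg.flank))
        n_sites = region.genotypes.shape[0]
        pos = offset + 1 + np.floor(region.positions).astype(int)
        # flooring continuous coordinates can collide; keep positions
        # strictly increasing so (chrom, pos) is a unique site key
        if n_sites > 1:
            for i in range(1, n_sites):
                if pos[i] <= pos[i - 1]:
                    pos[i] = pos[i - 1] + 1
        anc, der = _draw_alleles(n_sites, rng_alleles)
        site_frames.append(pd.DataFrame({
            "chrom": "chr1", "pos": pos, "ancestral": anc, "derived": der,
            "gene_id": f"G{g}",
        }))
        for p in pops:
            haps[p].append(region.genotypes[:, region.pop_slices[p]].T)
        offset += region_len + cfg.gene_spacing
    sites = pd.concat(site_frames, ignore_index=True)
    haplotypes = {p: np.concatenate(haps[p], axis=1) for p in pops}
    ds = _assemble_dataset(cfg, genes, sites, haplotypes, gl_seed=s_gl)
    ds.truth["seed"] = master
    return ds


def _assemble_dataset(cfg, genes, sites, haplotypes, gl_seed,
                      selected=None, trajectory=None) -> SyntheticDataset:
    """Build frequency table and genotype likelihoods from haplotypes."""
    pops = list(haplotypes)
    rng_gl = rng_from_seed(gl_seed)
    freq_frames, glms = [], {}
    for p in pops:
        H = haplotypes[p]
        n_hap = H.shape[0]
        counts = H.sum(axis=0)
        df = sites[SITE_COLUMNS].copy()
        df["pop"] = p
        df["freq"] = counts / n_hap
        df["n_haploid"] = n_hap
        df["n_nonmissing"] = n_hap // 2
        freq_frames.append(df)
        genotypes = H[0::2] + H[1::2]  # consecutive haplotypes pair into diploids
        depth = cfg.depth_ancient if p == ANCIENT_POP else cfg.depth_modern
        gl, missing = _genotype_likelihoods(genotypes.T, depth, cfg.base_error,
                                            cfg.missingness, rng_gl)
        glms[p] = GenotypeLikelihoodMatrix(sites[SITE_COLUMNS].copy(), gl, missing)
    table = FrequencyTable(pd.concat(freq_frames, ignore_index=True))
    adm = cfg.model.admixture
    truth = {
        "true_frequencies": table.df[["chrom", "pos", "pop", "freq"]].copy(),
        "alpha": adm.fraction if adm else 0.0,
        "selected_gene": selected,
        "trajectory": trajectory,
    }
    return SyntheticDataset(config=cfg, genes=genes, sites=sites,
                            haplotypes=haplotypes, frequency_table=table,
                            genotype_likelihoods=glms, truth=truth)


def inject_selected_gene(dataset: SyntheticDataset, trajectory: Trajectory,
                         gene_id: str, seed=None, *, kernel_bp: float = 5_000.0,
                         ancient_gen: int = 60) -> SyntheticDataset:
    """Overwrite one gene with a selected-allele signal.

    The focal SNP (nearest the transcript midpoint) has its ancient and
    modern panel frequencies redrawn binomially from the trajectory at
    the ancient sampling generation and at present; linked sites in the
    gene are pulled toward the focal frequency with an exponentially
    distance-decaying hitchhiking kernel.  Haplotypes, frequencies and
    genotype likelihoods are regenerated consistently for the affected
    sites; the truth record is updated.
    """
    genes = {g.gene_id: g for g in dataset.genes}
    if gene_id not in genes:
        raise KeyError(f"unknown gene {gene_id!r}")
    if trajectory.n_gens < ancient_gen:
        raise ValueError("trajectory must span the ancient sampling time")
    gene = genes[gene_id]
    rng = rng_from_seed(seed)
    new = copy.deepcopy(dataset)
    in_gene = (new.sites["gene_id"] == gene_id).to_numpy()
    idx = np.flatnonzero(in_gene)
    if idx.size == 0:
        raise ValueError(f"gene {gene_id!r} has no segregating sites to inject into")
    pos = new.sites["pos"].to_numpy()[idx]
    mid = (gene.start + gene.end) / 2.0
    focal = idx[np.argmin(np.abs(pos - mid))]
    target = {ANCIENT_POP: trajectory.freq_at(ancient_gen), "TSIM": trajectory.freq_at(0)}
    w = np.exp(-np.abs(pos - pos[np.argmin(np.abs(pos - mid))]) / kernel_bp)
    for p, f_target in target.items():
        H = new.haplotypes[p]
        n_hap = H.shape[0]
        f_focal = rng.binomial(n_hap, f_target) / n_hap
        f_old = H[:, idx].mean(axis=0)
        f_new = (1 - w) * f_old + w * f_focal
        f_new[idx == focal] = f_focal
        counts = np.round(f_new * n_hap).astype(int)
        for j, site in enumerate(idx):
            col = np.zeros(n_hap, dtype=np.int8)
            col[rng.permutation(n_hap)[: counts[j]]] = 1
            H[:, site] = col
    sub = new.sites.iloc[idx]
    for p in (ANCIENT_POP, "TSIM"):
        H = new.haplotypes[p]
        counts = H[:, idx].sum(axis=0)
        n_hap = H.shape[0]
        mask = (new.frequency_table.df["pop"] == p).to_numpy() & np.tile(
            in_gene, len(new.frequency_table.df) // len(in_gene))
        new.frequency_table.df.loc[mask, "freq"] = counts / n_hap
        genotypes = (H[0::2] + H[1::2])[:, idx]
        depth = new.config.depth_ancient if p == ANCIENT_POP else new.config.depth_modern
        gl, missing = _genotype_likelihoods(genotypes.T, depth, new.config.base_error,
                                            new.config.missingness, rng)
        new.genotype_likelihoods[p].gl[idx] = gl
        new.genotype_likelihoods[p].missing[idx] = missing
    new.truth["selected_gene"] = gene_id
    new.truth["trajectory"] = trajectory
    new.truth["focal_site"] = (str(sub.iloc[np.argmin(np.abs(pos - mid))]["chrom"]),
                               int(pos[np.argmin(np.abs(pos - mid))]))
    new.truth["true_frequencies"] = new.frequency_table.df[
        ["chrom", "pos", "pop", "freq"]].copy()
    return new
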