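"""Population branch statistic (PBS) selection scan.

For three populations X, Y, Z the statistic transforms each pairwise
F_ST into an estimated branch length T = -log(1 - F_ST) and allocates
differentiation to the branch leading to X:

    PBS_X = (T_XY + T_XZ - T_YZ) / 2,

and cyclically for Y and Z.  Large PBS_X flags loci that changed
frequency specifically along X's history — here the branch leading to
the ancient panel.  Per-gene values aggregate per-site F_ST variance
components as a ratio of averages over the transcript plus 10 kb flanks
before transforming, which keeps low-frequency sites from dominating.

The module also implements the per-locus admixture correction
f_pre = (f_post - a * f_EUR) / (1 - a) with a chosen per locus to
minimize F_ST between the corrected modern population and the outgroup,
the neutral-simulation null for empirical p-values, the ancient-vs-
modern frequency-change outlier scan, and haplotype pairwise-difference
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import logger, rng_from_seed, spawn_seeds
from .demography import DemographicModel, simulate_region
from .freqs import FrequencyTable

__all__ = [
    "GeneAnnotation",
    "PBSRecord",
    "NeutralNull",
    "fst",
    "fst_components",
    "branch_length",
    "pbs_from_fst",
    "pbs_per_snp",
    "pbs_per_gene",
    "pbs_scan_genes",
    "correct_frequency",
    "estimate_alpha",
    "admixture_correct_table",
    "neutral_pbs_null",
    "pbs_pvalue",
    "format_pvalue",
    "freq_change_scan",
    "haplotype_diff_profile",
]

_FST_CAP = 1.0 - 1e-9
ESTIMATORS = ("reynolds", "hudson")


@dataclass(frozen=True)
class GeneAnnotation:
    """A transcript span (1-based inclusive) scanned with symmetric flanks."""

    gene_id: str
    chrom: str
    start: int
    end: int
    flank: int = 10_000

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start must be <= end")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    @property
    def window(self) -> tuple[int, int]:
        return max(1, self.start - self.flank), self.end + self.flank


@dataclass
class PBSRecord:
    unit_id: str
    fst_xy: float
    fst_xz: float
    fst_yz: float
    t_xy: float = field(init=False)
    t_xz: float = field(init=False)
    t_yz: float = field(init=False)
    pbs_x: float = field(init=False)
    pbs_y: float = field(init=False)
    pbs_z: float = field(init=False)
    n_sites: int = 1
    pvalue: float | None = None

    def __post_init__(self):
        for f in (self.fst_xy, self.fst_xz, self.fst_yz):
            if not 0.0 <= f <= 1.0:
                raise ValueError("F_ST values must lie in [0, 1]")
        self.t_xy = branch_length(self.fst_xy)
        self.t_xz = branch_length(self.fst_xz)
        self.t_yz = branch_length(self.fst_yz)
        self.pbs_x, self.pbs_y, self.pbs_z = pbs_from_fst(self.fst_xy, self.fst_xz, self.fst_yz)


# ---------------------------------------------------------------------
# F_ST estimators
# ---------------------------------------------------------------------

def _check_freq_n(p1, n1, p2, n2):
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    n1, n2 = np.asarray(n1, float), np.asarray(n2, float)
    if np.any((p1 < 0) | (p1 > 1)) or np.any((p2 < 0) | (p2 > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("haploid sample sizes must be >= 2")
    return p1, n1, p2, n2


def fst_components(p1, n1, p2, n2, estimator: str = "reynolds"):
    """Per-site numerator / denominator variance components.

    ``estimator`` is ``"reynolds"`` (coancestry-based; the default,
    following the original PBS formulation) or ``"hudson"`` (with its
    sample-size-corrected numerator).  Sample sizes are haploid counts.
    Sites monomorphic in both populations return (0, 0) and thus drop
    out of ratio-of-averages aggregation while still counting as sites.
    """
    p1, n1, p2, n2 = _check_freq_n(p1, n1, p2, n2)
    d2 = (p1 - p2) ** 2
    if estimator == "reynolds":
        h1 = 2 * p1 * (1 - p1)
        h2 = 2 * p2 * (1 - p2)
        shared = (n1 * h1 + n2 * h2) / (n1 + n2 - 2)
        num = d2 - (n1 + n2) * shared / (4 * n1 * n2)
        den = d2 + (4 * n1 * n2 - n1 - n2) * shared / (4 * n1 * n2)
    elif estimator == "hudson":
        num = d2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    else:
        raise ValueError(f"unknown F_ST estimator {estimator!r}")
    return num, den


def fst(p1, n1, p2, n2, estimator: str = "reynolds"):
    """Pairwise F_ST estimate in [0, 1]; negative estimates truncate to 0
    (single-site unbiased estimators go negative for similar
    frequencies), and monomorphic pairs are reported as 0."""
    num, den = fst_components(p1, n1, p2, n2, estimator)
    num, den = np.asarray(num, float), np.asarray(den, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    n_trunc = int(np.sum(f < 0))
    if n_trunc:
        logger.debug("truncated %d negative F_ST estimates at 0", n_trunc)
    f = np.clip(f, 0.0, 1.0)
    return float(f) if f.ndim == 0 else f


def branch_length(f):
    """Yi-style branch-length transform T = -log(1 - F_ST), with F_ST
    capped at 1 - 1e-9 so fixed differences stay finite (T ~ 20.72)."""
    f = np.asarray(f, float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("F_ST must lie in [0, 1]")
    t = -np.log1p(-np.minimum(f, _FST_CAP))
    return float(t) if t.ndim == 0 else t


def pbs_from_fst(f_xy, f_xz, f_yz):
    t_xy, t_xz, t_yz = branch_length(f_xy), branch_length(f_xz), branch_length(f_yz)
    pbs_x = (t_xy + t_xz - t_yz) / 2.0
    pbs_y = (t_xy + t_yz - t_xz) / 2.0
    pbs_z = (t_xz + t_yz - t_xy) / 2.0
    return pbs_x, pbs_y, pbs_z


def pbs_per_snp(p_x, p_y, p_z, n_x, n_y, n_z, *, estimator: str = "reynolds",
                unit_id: str = "snp") -> PBSRecord:
    """Per-SNP PBS record for populations (X, Y, Z)."""
    for p in (p_x, p_y, p_z):
        if p is None or (np.isscalar(p) and np.isnan(p)):
            raise ValueError("all three population frequencies must be present")
    return PBSRecord(
        unit_id=unit_id,
        fst_xy=fst(p_x, n_x, p_y, n_y, estimator),
        fst_xz=fst(p_x, n_x, p_z, n_z, estimator),
        fst_yz=fst(p_y, n_y, p_z, n_z, estimator),
        n_sites=1,
    )


def pbs_per_gene(p_x, p_y, p_z, n_x, n_y, n_z, *, estimator: str = "reynolds",
                 aggregate: str = "ratio", unit_id: str = "gene") -> PBSRecord:
    """Per-gene PBS from arrays of per-site frequencies in a window.

    ``aggregate="ratio"`` (default) sums per-site F_ST numerator and
    denominator components across the window before taking the ratio
    (ratio of averages), then transforms; ``"mean"`` averages per-site
    PBS values instead.
    """
    arrs = [np.atleast_1d(np.asarray(a, float)) for a in (p_x, p_y, p_z, n_x, n_y, n_z)]
    p_x, p_y, p_z, n_x, n_y, n_z = np.broadcast_arrays(*arrs)
    if p_x.size == 0:
        raise ValueError("gene window contains no sites")
    if aggregate == "ratio":
        fsts = []
        for (pa, na, pb, nb) in (((p_x), n_x, p_y, n_y), (p_x, n_x, p_z, n_z), (p_y, n_y, p_z, n_z)):
            num, den = fst_components(pa, na, pb, nb, estimator)
            dsum = float(np.sum(den))
            f = max(0.0, min(1.0, float(np.sum(num)) / dsum)) if dsum > 0 else 0.0
            fsts.append(f)
        rec = PBSRecord(unit_id, *fsts, n_sites=int(p_x.size))
        return rec
    if aggregate == "mean":
        recs = [
            pbs_per_snp(p_x[i], p_y[i], p_z[i], n_x[i], n_y[i], n_z[i], estimator=estimator)
            for i in range(p_x.size)
        ]
        rec = PBSRecord(unit_id, 0.0, 0.0, 0.0, n_sites=int(p_x.size))
        rec.pbs_x = float(np.mean([r.pbs_x for r in recs]))
        rec.pbs_y = float(np.mean([r.pbs_y for r in recs]))
        rec.pbs_z = float(np.mean([r.pbs_z for r in recs]))
        rec.fst_xy = rec.fst_xz = rec.fst_yz = float("nan")
        rec.t_xy = rec.t_xz = rec.t_yz = float("nan")
        return rec
    raise ValueError(f"unknown aggregate {aggregate!r}")


# ---------------------------------------------------------------------
# admixture correction
# ---------------------------------------------------------------------

def correct_frequency(f_post, f_eur, alpha):
    """Remove a fraction ``alpha`` of European ancestry from an observed
    frequency: f_pre = (f_post - alpha * f_eur) / (1 - alpha), clamped
    to [0, 1]."""
    f_post = np.asarray(f_post, float)
    f_eur = np.asarray(f_eur, float)
    alpha = np.asarray(alpha, float)
    if np.any((alpha < 0) | (alpha >= 1)):
        raise ValueError("alpha must lie in [0, 1)")
    raw = (f_post - alpha * f_eur) / (1.0 - alpha)
    n_clamped = int(np.sum((raw < 0) | (raw > 1)))
    if n_clamped:
        logger.debug("admixture correction clamped %d frequencies", n_clamped)
    out = np.clip(raw, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def estimate_alpha(f_tsim, n_tsim, f_eur, f_chb, n_chb, *, step: float = 0.01,
                   max_alpha: float = 0.99, estimator: str = "reynolds"):
    """Per-locus admixture fraction: the grid value in [0, max_alpha]
    (step 0.01) minimizing F_ST between the admixture-corrected modern
    population and the outgroup; ties resolve to the smallest alpha.

    Minimization uses the untruncated estimator (which is monotone in
    the squared frequency difference), so the minimum is unique at the
    best-matching alpha; truncation at 0 would create a tie plateau and
    bias the recovered fraction downward.
    """
    f_tsim = np.atleast_1d(np.asarray(f_tsim, float))
    f_eur = np.broadcast_to(np.asarray(f_eur, float), f_tsim.shape)
    f_chb = np.broadcast_to(np.asarray(f_chb, float), f_tsim.shape)
    n_t = np.broadcast_to(np.asarray(n_tsim, float), f_tsim.shape)
    n_c = np.broadcast_to(np.asarray(n_chb, float), f_tsim.shape)
    grid = np.round(np.arange(0.0, max_alpha + step / 2, step), 10)
    corr = correct_frequency(f_tsim[None, :], f_eur[None, :], grid[:, None])
    num, den = fst_components(corr, n_t[None, :], f_chb[None, :], n_c[None, :], estimator)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(den != 0, num / np.where(den != 0, den, 1.0), 0.0)
    best = np.argmin(f, axis=0)  # first minimum -> smallest alpha on ties
    alpha = grid[best]
    return float(alpha[0]) if np.isscalar(n_tsim) and alpha.size == 1 else alpha


def admixture_correct_table(f_tsim, n_tsim, f_eur, f_chb, n_chb, **kw) -> pd.DataFrame:
    """Per-locus correction report: alpha, observed (post), reference and
    corrected (pre) frequencies."""
    alpha = np.atleast_1d(estimate_alpha(f_tsim, n_tsim, f_eur, f_chb, n_chb, **kw))
    f_pre = correct_frequency(f_tsim, f_eur, alpha)
    return pd.DataFrame({
        "alpha": alpha,
        "f_post": np.atleast_1d(np.asarray(f_tsim, float)),
        "f_eur": np.atleast_1d(np.asarray(f_eur, float)),
        "f_pre": np.atleast_1d(f_pre),
    })


# ---------------------------------------------------------------------
# gene scan over a frequency table
# ---------------------------------------------------------------------

def _window_mask(sites: pd.DataFrame, gene: GeneAnnotation) -> np.ndarray:
    lo, hi = gene.window
    return ((sites["chrom"] == gene.chrom) & (sites["pos"] >= lo) & (sites["pos"] <= hi)).to_numpy()


def pbs_scan_genes(table: FrequencyTable, genes: Sequence[GeneAnnotation],
                   roles: Sequence[str] = ("PRH", "TSIM", "CHB"), *,
                   estimator: str = "reynolds", aggregate: str = "ratio",
                   correct: bool = False, eur: str = "GBR") -> pd.DataFrame:
    """Per-gene PBS over transcript+flank windows of a frequency table.

    ``roles`` orders the populations as (X, Y, Z) = (focal/ancient,
    modern, outgroup).  With ``correct=True`` the modern population's
    frequencies are admixture-corrected against ``eur`` before the scan.
    Genes with no retained sites are skipped with a log message.
    """
    pops = list(roles) + ([eur] if correct else [])
    sites, freq, n = table.wide(pops)
    keep = ~np.isnan(freq).any(axis=1)
    sites, freq, n = sites[keep].reset_index(drop=True), freq[keep], n[keep]
    fx, fy, fz = freq[:, 0], freq[:, 1].copy(), freq[:, 2]
    nx, ny, nz = n[:, 0], n[:, 1], n[:, 2]
    alpha = None
    if correct:
        feur = freq[:, 3]
        alpha = estimate_alpha(fy, ny, feur, fz, nz, estimator=estimator)
        fy = correct_frequency(fy, feur, alpha)
    rows = []
    for gene in genes:
        m = _window_mask(sites, gene)
        if not m.any():
            logger.info("gene %s skipped: no retained sites in window", gene.gene_id)
            continue
        rec = pbs_per_gene(fx[m], fy[m], fz[m], nx[m], ny[m], nz[m],
                           estimator=estimator, aggregate=aggregate, unit_id=gene.gene_id)
        rows.append({
            "gene_id": gene.gene_id, "chrom": gene.chrom,
            "start": gene.start, "end": gene.end,
            "fst_xy": rec.fst_xy, "fst_xz": rec.fst_xz, "fst_yz": rec.fst_yz,
            "pbs_x": rec.pbs_x, "pbs_y": rec.pbs_y, "pbs_z": rec.pbs_z,
            "n_sites": rec.n_sites,
        })
    df = pd.DataFrame(rows)
    df.attrs["estimator"] = estimator
    df.attrs["aggregate"] = aggregate
    df.attrs["admixture_corrected"] = bool(correct)
    return df


# ---------------------------------------------------------------------
# neutral null and p-values
# ---------------------------------------------------------------------

@dataclass
class NeutralNull:
    """Per-gene PBS values from neutral gene-scale simulations."""

    values: np.ndarray
    lengths: np.ndarray
    n_reps: int
    seed: int | None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.lengths = np.asarray(self.lengths, float)
        if len(self.values) != self.n_reps:
            raise ValueError("n_reps must equal the number of null values")


def region_pbs(region, roles=("PRH", "TSIM", "CHB"), *, estimator="reynolds",
               aggregate="ratio", correct=False, eur="GBR") -> float:
    """Ancient-branch per-gene PBS for one simulated region; a region
    with no segregating sites contributes PBS = 0."""
    if region.genotypes.shape[0] == 0:
        return 0.0
    fx, fy, fz = (region.frequencies(p) for p in roles)
    nx, ny, nz = (region.n_haploid(p) for p in roles)
    if correct:
        feur = region.frequencies(eur)
        alpha = estimate_alpha(fy, ny, feur, fz, nz, estimator=estimator)
        fy = correct_frequency(fy, feur, alpha)
    rec = pbs_per_gene(fx, fy, fz, nx, ny, nz, estimator=estimator, aggregate=aggregate)
    return rec.pbs_x


def neutral_pbs_null(model: DemographicModel, lengths, n_reps: int, seed=None, *,
                     admixture_correct: bool = False,
                     roles: Sequence[str] = ("PRH", "TSIM", "CHB"), eur: str = "GBR",
                     estimator: str = "reynolds", aggregate: str = "ratio") -> NeutralNull:
    """Neutral per-gene PBS null distribution.

    Each replicate draws a region length uniformly at random from
    ``lengths`` (an array, e.g. transcript lengths + 20 kb, or a
    callable ``lengths(rng, n)``), simulates the four-population model,
    and computes the ancient-branch per-gene PBS through the same
    aggregation path as the observed scan, with the admixture correction
    applied when flagged.  Replicates with no segregating sites
    contribute PBS = 0 (logged), mirroring how an invariant gene would
    scan.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = rng_from_seed(seed)
    if callable(lengths):
        ls = np.asarray(lengths(rng, n_reps), float)
    else:
        lengths = np.asarray(lengths, float)
        ls = rng.choice(lengths, size=n_reps, replace=True)
    pops = list(roles) + ([eur] if admixture_correct else [])
    seeds = spawn_seeds(int(rng.integers(2**31 - 1)), n_reps)
    vals = np.empty(n_reps)
    n_empty = 0
    for i in range(n_reps):
        region = simulate_region(model, sequence_length=ls[i], seed=seeds[i], pops=pops)
        if region.genotypes.shape[0] == 0:
            n_empty += 1
        vals[i] = region_pbs(region, roles, estimator=estimator, aggregate=aggregate,
                             correct=admixture_correct, eur=eur)
    if n_empty:
        logger.info("%d null replicates had no segregating sites (PBS = 0)", n_empty)
    meta = {
        "estimator": estimator, "aggregate": aggregate,
        "admixture_corrected": admixture_correct,
        "length_source": "callable" if callable(lengths) else "array",
    }
    return NeutralNull(values=vals, lengths=ls, n_reps=n_reps, seed=seed, metadata=meta)


def pbs_pvalue(observed: float, null) -> float:
    """Empirical upper-tail p-value: the proportion of null PBS values at
    least as extreme (selection inflates PBS, so "more extreme" is the
    upper tail)."""
    vals = null.values if isinstance(null, NeutralNull) else np.asarray(null, float)
    if vals.size == 0:
        raise ValueError("null distribution is empty")
    return float(np.count_nonzero(vals >= observed) / vals.size)


def format_pvalue(p: float, n_reps: int) -> str:
    """Human-readable p-value; an observed value beyond every null
    replicate reports the resolution bound, e.g. "< 0.001" at 1,000."""
    if p == 0.0:
        return f"< {1.0 / n_reps:g}"
    return f"{p:g}"


# ---------------------------------------------------------------------
# frequency-change outlier scan and haplotype profiles
# ---------------------------------------------------------------------

def freq_change_scan(ancient: FrequencyTable, modern: FrequencyTable,
                     ancient_pop: str | None = None,
                     modern_pop: str | None = None) -> pd.DataFrame:
    """Per-SNP derived-allele frequency change, ancient minus modern,
    with each site's quantile in the exome-wide empirical distribution
    of changes (1.0 = most extreme decline since ancient times)."""
    a = ancient.df if ancient_pop is None else ancient.df[ancient.df["pop"] == ancient_pop]
    m = modern.df if modern_pop is None else modern.df[modern.df["pop"] == modern_pop]
    merged = a.merge(m, on=["chrom", "pos"], suffixes=("_ancient", "_modern"))
    if merged.empty:
        raise ValueError("no shared sites between the two tables")
    merged["delta"] = merged["freq_ancient"] - merged["freq_modern"]
    merged["quantile"] = stats.rankdata(merged["delta"], method="average") / len(merged)
    cols = ["chrom", "pos", "freq_ancient", "freq_modern", "delta", "quantile"]
    return merged[cols].reset_index(drop=True)


def haplotype_diff_profile(haplotypes: dict[str, np.ndarray],
                           reference: np.ndarray) -> pd.DataFrame:
    """Hamming distances of each haplotype to a reference haplotype,
    sorted ascending within each population.

    ``haplotypes`` maps population name to an (n_haplotypes, L) binary
    array; ``reference`` is a length-L binary haplotype.
    """
    reference = np.asarray(reference)
    rows = []
    for pop, haps in haplotypes.items():
        haps = np.asarray(haps)
        if haps.shape[1] != reference.shape[0]:
            raise ValueError(f"haplotype length mismatch in population {pop!r}")
        d = (haps != reference[None, :]).sum(axis=1)
        order = np.argsort(d, kind="stable")
        for rank, idx in enumerate(order):
            rows.append({"pop": pop, "rank": rank, "haplotype": int(idx),
                         "differences": int(d[idx])})
    return pd.DataFrame(rows)
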