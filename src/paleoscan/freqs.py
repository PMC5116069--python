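"""Allele-frequency estimation from genotype likelihoods, plus site filters.

Low-coverage exomes (ancient ones especially) do not support hard
genotype calls, so per-population derived-allele frequencies are
estimated directly from per-individual genotype likelihoods by an EM
algorithm: given a frequency f, genotypes are Binomial(2, f) a priori;
the E-step computes posterior mean genotypes and the M-step sets
f to half their average.  This is the classical likelihood-based
frequency estimator used by ANGSD-style pipelines.

Sites are retained only where at least ``min_nonmissing`` individuals
have data in every scanned population, and (for SFS construction) where
a likelihood-ratio test rejects monomorphism at p < 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import logger

__all__ = [
    "GenotypeLikelihoodMatrix",
    "FrequencyTable",
    "ml_allele_frequency",
    "ml_allele_frequencies",
    "frequency_table",
    "apply_site_filters",
    "frequencies_from_counts",
    "polymorphism_pvalue",
    "transversion_mask",
]

_GENOTYPES = np.array([0.0, 1.0, 2.0])

SITE_COLUMNS = ["chrom", "pos", "ancestral", "derived"]


@dataclass
class GenotypeLikelihoodMatrix:
    """Per-site, per-individual genotype likelihoods for one population.

    ``gl[s, i, g]`` is the likelihood of the data for individual i at
    site s given g copies of the derived allele (g = 0, 1, 2), scaled so
    the per-(site, individual) maximum is 1.  ``missing[s, i]`` marks
    individuals with no data at the site.
    """

    sites: pd.DataFrame
    gl: np.ndarray
    missing: np.ndarray = field(default=None)

    def __post_init__(self):
        self.gl = np.asarray(self.gl, dtype=float)
        if self.gl.ndim != 3 or self.gl.shape[2] != 3:
            raise ValueError("gl must have shape (n_sites, n_individuals, 3)")
        if self.missing is None:
            self.missing = np.zeros(self.gl.shape[:2], dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.gl.shape[:2]:
            raise ValueError("missing mask shape mismatch")
        if np.any(self.gl < 0):
            raise ValueError("genotype likelihoods must be >= 0")
        ok = self.gl.max(axis=2) > 0
        if np.any(~ok & ~self.missing):
            raise ValueError("non-missing entries need at least one positive likelihood")
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"sites frame lacks columns {missing_cols}")
        if (self.sites["ancestral"] == self.sites["derived"]).any():
            raise ValueError("ancestral and derived alleles must differ")
        if (self.sites["pos"] < 1).any():
            raise ValueError("positions are 1-based and must be >= 1")

    @property
    def n_sites(self) -> int:
        return self.gl.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.gl.shape[1]

    def normalized(self) -> "GenotypeLikelihoodMatrix":
        m = self.gl.max(axis=2, keepdims=True)
        gl = np.divide(self.gl, m, out=np.zeros_like(self.gl), where=m > 0)
        return GenotypeLikelihoodMatrix(self.sites, gl, self.missing)


def _em_update(gl: np.ndarray, use: np.ndarray, f: np.ndarray):
    """One EM step for a batch of sites; returns (f_new, loglik)."""
    f = np.clip(f, 1e-12, 1 - 1e-12)
    prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)  # (S, 3)
    w = gl * prior[:, None, :]  # (S, I, 3)
    tot = w.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        post = w / tot[:, :, None]
        ll = np.where(use, np.log(tot), 0.0).sum(axis=1)
    eg = np.where(use, (post * _GENOTYPES).sum(axis=2), 0.0)
    n = use.sum(axis=1)
    f_new = eg.sum(axis=1) / (2 * np.maximum(n, 1))
    return f_new, ll


def ml_allele_frequencies(gl: np.ndarray, missing: np.ndarray | None = None, *,
                          tol: float = 1e-8, max_iter: int = 2000,
                          f0: float = 0.25) -> np.ndarray:
    """Vectorized EM maximum-likelihood derived-allele frequencies.

    ``gl`` has shape (n_sites, n_individuals, 3).  Sites where every
    individual is missing come back as NaN.  The EM log-likelihood is
    monotonically non-decreasing; a decrease beyond numerical noise
    raises, as it would indicate a broken update.
    """
    gl = np.asarray(gl, dtype=float)
    if missing is None:
        missing = np.zeros(gl.shape[:2], dtype=bool)
    use = ~np.asarray(missing, dtype=bool)
    n_use = use.sum(axis=1)
    f = np.full(gl.shape[0], f0, dtype=float)
    last_ll = np.full(gl.shape[0], -np.inf)
    active = n_use > 0
    for _ in range(max_iter):
        f_new, ll = _em_update(gl, use, f)
        if np.any(ll[active] < last_ll[active] - 1e-9):
            raise RuntimeError("EM log-likelihood decreased")
        delta = np.abs(f_new - f)[active].max(initial=0.0)
        f, last_ll = np.where(active, f_new, f), ll
        if delta < tol:
            break
    f = np.where(n_use > 0, f, np.nan)
    return f


def ml_allele_frequency(gl: np.ndarray, missing: np.ndarray | None = None, **kw) -> float:
    """EM maximum-likelihood frequency for a single site.

    Raises if every individual is missing (an undefined frequency); the
    table-level estimator instead records NaN and lets the site filters
    remove such sites.
    """
    gl = np.asarray(gl, dtype=float)
    if gl.ndim != 2 or gl.shape[1] != 3:
        raise ValueError("site gl must have shape (n_individuals, 3)")
    if missing is not None and bool(np.all(missing)):
        raise ValueError("all individuals missing: frequency undefined")
    m = None if missing is None else np.asarray(missing, bool)[None, :]
    return float(ml_allele_frequencies(gl[None], m, **kw)[0])


def polymorphism_pvalue(gl: np.ndarray, missing: np.ndarray | None = None) -> np.ndarray:
    """Likelihood-ratio test of polymorphism per site.

    Compares the maximized likelihood over f in [0, 1] against the best
    monomorphic model (f = 0 or f = 1).  Because the null pins f to the
    boundary, the LR statistic is referred to the 50:50 mixture of a
    point mass at zero and a chi-square with one degree of freedom.
    Sites pass the SNP-calling filter at p < 1e-6.
    """
    gl = np.asarray(gl, dtype=float)
    if gl.ndim == 2:
        gl = gl[None]
    if missing is None:
        missing = np.zeros(gl.shape[:2], dtype=bool)
    use = ~np.asarray(missing, dtype=bool)
    f_hat = ml_allele_frequencies(gl, missing)
    _, ll_hat = _em_update(gl, use, np.nan_to_num(f_hat, nan=0.5))
    with np.errstate(divide="ignore"):
        ll0 = np.where(use, np.log(np.maximum(gl[:, :, 0], 1e-300)), 0.0).sum(axis=1)
        ll1 = np.where(use, np.log(np.maximum(gl[:, :, 2], 1e-300)), 0.0).sum(axis=1)
    lr = 2.0 * (ll_hat - np.maximum(ll0, ll1))
    lr = np.maximum(lr, 0.0)
    p = 0.5 * stats.chi2.sf(lr, df=1)
    p = np.where(lr == 0.0, 1.0, p)
    return p


def transversion_mask(sites: pd.DataFrame) -> np.ndarray:
    """True for C/T or G/A polymorphisms (either orientation).

    These are the site classes affected by post-mortem deamination;
    structure-style analyses drop them.  The mask marks the sites to
    *remove*.
    """
    pairs = set(map(tuple, sites[["ancestral", "derived"]].to_numpy()))
    damage = {("C", "T"), ("T", "C"), ("G", "A"), ("A", "G")}
    flagged = [tuple(x) in damage for x in sites[["ancestral", "derived"]].to_numpy()]
    del pairs
    return np.asarray(flagged, dtype=bool)


def frequencies_from_counts(count, total):
    """Derived-allele frequency from (count, haploid total)."""
    count = np.asarray(count, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(total <= 0):
        raise ValueError("haploid total must be > 0: frequency undefined")
    if np.any(count < 0) or np.any(count > total):
        raise ValueError("count must satisfy 0 <= count <= total")
    out = count / total
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------
# the frequency table
# ---------------------------------------------------------------------

class FrequencyTable:
    """Long-format per-site, per-population derived-allele frequencies.

    Wraps a DataFrame with columns chrom, pos, ancestral, derived, pop,
    freq, n_haploid, n_nonmissing.  ``n_haploid`` is the effective
    haploid sample size behind the frequency (2 x non-missing diploids
    for likelihood-based estimates).
    """

    COLUMNS = SITE_COLUMNS + ["pop", "freq", "n_haploid", "n_nonmissing"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"frequency table lacks columns {missing}")
        bad = df["freq"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def pops(self) -> list[str]:
        return sorted(self.df["pop"].unique())

    def wide(self, pops=None):
        """Return (site frame, freq matrix, n_haploid matrix) with one
        row per site and one column per population; sites absent from a
        population come back NaN."""
        pops = list(pops) if pops is not None else self.pops
        piv = self.df.pivot_table(index=["chrom", "pos"], columns="pop",
                                  values=["freq", "n_haploid"], aggfunc="first")
        sites = (
            self.df[SITE_COLUMNS].drop_duplicates(["chrom", "pos"]).set_index(["chrom", "pos"])
        )
        sites = sites.loc[piv.index].reset_index()
        freq = np.column_stack([piv[("freq", p)].to_numpy() for p in pops])
        n = np.column_stack([piv[("n_haploid", p)].to_numpy() for p in pops])
        return sites, freq, n

    def to_tsv(self, path, seed=None, params=None) -> None:
        from ._util import header_lines

        with open(path, "w") as fh:
            for line in header_lines(seed, params):
                fh.write(line + "\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FrequencyTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


def frequency_table(glms: dict[str, GenotypeLikelihoodMatrix]) -> FrequencyTable:
    """Estimate a :class:`FrequencyTable` from per-population genotype
    likelihoods via the EM estimator."""
    frames = []
    for pop, glm in glms.items():
        freq = ml_allele_frequencies(glm.gl, glm.missing)
        nonmiss = (~glm.missing).sum(axis=1)
        df = glm.sites[SITE_COLUMNS].copy()
        df["pop"] = pop
        df["freq"] = freq
        df["n_haploid"] = 2 * nonmiss
        df["n_nonmissing"] = nonmiss
        frames.append(df)
    return FrequencyTable(pd.concat(frames, ignore_index=True))


def apply_site_filters(table: FrequencyTable, min_nonmissing: int = 5,
                       pops=None) -> FrequencyTable:
    """Drop sites with fewer than ``min_nonmissing`` non-missing
    individuals in any scanned population (default five, the standard
    frequency-calling threshold).  Filtering is idempotent."""
    df = table.df
    pops = list(pops) if pops is not None else table.pops
    sub = df[df["pop"].isin(pops)]
    ok = sub.groupby(["chrom", "pos"])["n_nonmissing"].min() >= min_nonmissing
    has_all = sub.groupby(["chrom", "pos"])["pop"].nunique() >= len(pops)
    keep = ok & has_all
    keep_idx = keep[keep].index
    mask = df.set_index(["chrom", "pos"]).index.isin(keep_idx)
    removed = df.loc[~mask, ["chrom", "pos"]].drop_duplicates().shape[0]
    if removed:
        logger.info("site filter removed %d sites (< %d non-missing individuals)",
                    removed, min_nonmissing)
    return FrequencyTable(df[mask].reset_index(drop=True))
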