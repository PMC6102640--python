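"""Tagging-SNP association scans for insertion presence/absence.

For every insertion site and continental population, each biallelic SNP
dosage is regressed on the binary carrier status with a logistic model
adjusted for ancestry (the first k = 6 classical-MDS coordinates of the
identity-by-state distance matrix).  *hiSNPs* for a site are the SNPs
inside a 1 Mb window centered on the insertion whose association p-value
passes the window-wise Bonferroni threshold 0.05 / (SNPs in window).

The maximum-likelihood fit is a Newton/IRLS iteration with a Wald test
on the dosage coefficient.  A perfectly tagging SNP separates the
outcome completely (carrier <=> dosage >= 1), where the MLE diverges; in
that case the fit falls back to Firth's bias-reduced likelihood and the
p-value comes from the penalized likelihood-ratio test, flagged with
``method="firth"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

from .errors import DegenerateStatisticError, InputError

logger = logging.getLogger(__name__)

_SEPARATION_BETA = 15.0  # |log-odds| beyond which the MLE is treated as divergent


@dataclass
class GenotypeTable:
    """Biallelic SNP dosages (rows) for a cohort (columns); -1 = missing."""

    snps: pd.DataFrame  # columns: id, chrom, pos, ref, alt
    dosage: np.ndarray  # (n_snps, n_individuals) int8
    individual_ids: list[str]
    populations: dict[str, str] | None = None

    def __post_init__(self):
        if self.dosage.shape != (len(self.snps), len(self.individual_ids)):
            raise InputError("genotype dosage matrix shape mismatch")

    @classmethod
    def from_vcf(cls, path, populations: dict[str, str] | None = None) -> "GenotypeTable":
        from .io import read_vcf_genotypes

        samples, snps, dosage = read_vcf_genotypes(path)
        return cls(snps=snps, dosage=dosage, individual_ids=samples, populations=populations)

    def subset_snps(self, index: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            self.snps.iloc[index].reset_index(drop=True),
            self.dosage[index],
            self.individual_ids,
            self.populations,
        )

    def subset_individuals(self, keep_ids: list[str]) -> "GenotypeTable":
        idx = [self.individual_ids.index(i) for i in keep_ids]
        pops = {i: self.populations[i] for i in keep_ids} if self.populations else None
        return GenotypeTable(self.snps, self.dosage[:, idx], list(keep_ids), pops)


@dataclass(frozen=True)
class AssociationRecord:
    snp_id: str
    site_id: str
    population: str
    beta: float
    odds_ratio: float
    p_value: float
    converged: bool
    method: str = "mle"  # mle | firth | failed


@dataclass
class HiSNPSet:
    """Bonferroni-significant tagging SNPs for one site in one population."""

    site_id: str
    population: str
    window_start: int
    window_end: int
    bonferroni_threshold: float  # nan when no SNP lies in the window
    members: pd.DataFrame

    @property
    def member_ids(self) -> set[str]:
        return set(self.members["snp_id"])


# ----------------------------------------------------------- genotype pruning


def allele_frequency(dosage: np.ndarray) -> np.ndarray:
    """ALT allele frequency per SNP, ignoring missing entries."""
    d = np.ma.masked_less(dosage.astype(float), 0)
    return np.asarray(d.mean(axis=1) / 2.0)


def prune_and_thin(
    genotypes: GenotypeTable,
    maf_min: float = 0.05,
    ld_window: int = 50,
    ld_step: int = 5,
    ld_r2_max: float = 0.2,
    thin_fraction: float = 0.10,
    seed: int = 0,
) -> GenotypeTable:
    """Common-SNP filter, greedy LD pruning, then seeded random thinning.

    Mirrors the usual preparation of markers for ancestry estimation:
    keep MAF > ``maf_min``, drop one of any pair with r² > ``ld_r2_max``
    inside a sliding window of ``ld_window`` SNPs advanced by
    ``ld_step``, then retain a uniform random ``thin_fraction`` subset.
    """
    freq = allele_frequency(genotypes.dosage)
    maf = np.minimum(freq, 1 - freq)
    idx = np.nonzero(maf > maf_min)[0]
    if idx.size == 0:
        raise InputError("no SNPs pass the MAF filter; relax maf_min")
    keep = np.ones(idx.size, dtype=bool)
    filled = _mean_imputed(genotypes.dosage[idx])
    for start in range(0, idx.size, ld_step):
        win = np.arange(start, min(start + ld_window, idx.size))
        win = win[keep[win]]
        if win.size < 2:
            continue
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(filled[win])
        r2 = np.nan_to_num(corr) ** 2
        for a in range(win.size):
            if not keep[win[a]]:
                continue
            hits = np.nonzero(r2[a, a + 1 :] > ld_r2_max)[0]
            for b in hits:
                keep[win[a + 1 + b]] = False
    pruned = idx[keep]
    if pruned.size == 0:
        raise InputError("all SNPs removed by LD pruning; relax ld_r2_max")
    n_keep = int(round(thin_fraction * pruned.size))
    if n_keep == 0:
        raise InputError("thinning removed every SNP; increase thin_fraction")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(pruned, size=n_keep, replace=False))
    return genotypes.subset_snps(chosen)


def _mean_imputed(dosage: np.ndarray) -> np.ndarray:
    out = dosage.astype(np.float64)
    missing = out < 0
    if missing.any():
        means = np.where(
            (~missing).sum(axis=1) > 0,
            np.where(missing, 0, out).sum(axis=1) / np.maximum((~missing).sum(axis=1), 1),
            0.0,
        )
        out[missing] = np.broadcast_to(means[:, None], out.shape)[missing]
    return out


# -------------------------------------------------------------- ancestry MDS


def ibs_distance(dosage: np.ndarray) -> np.ndarray:
    """Pairwise 1 - identity-by-state similarity between individuals.

    d_ij = mean(|g_i - g_j|) / 2 over SNPs non-missing in both.
    """
    valid = (dosage >= 0)
    ind = [(dosage == v) & valid for v in (0, 1, 2)]
    ind_f = [m.astype(np.float32) for m in ind]
    p01 = ind_f[0].T @ ind_f[1]
    p02 = ind_f[0].T @ ind_f[2]
    p12 = ind_f[1].T @ ind_f[2]
    total = (p01 + p01.T) + 2.0 * (p02 + p02.T) + (p12 + p12.T)
    counts = valid.astype(np.float32).T @ valid.astype(np.float32)
    if (counts == 0).any():
        raise DegenerateStatisticError("individual pair with no shared genotyped SNPs")
    d = total / (2.0 * counts)
    np.fill_diagonal(d, 0.0)
    return d.astype(np.float64)


def compute_mds(genotypes: GenotypeTable, k: int = 6) -> np.ndarray:
    """First ``k`` classical-MDS (principal coordinate) axes of IBS distance.

    Signs are fixed so the largest-|loading| entry of each axis is
    positive; axes whose eigenvalue is numerically zero are returned as
    zero columns (e.g. identical individuals).
    """
    n = len(genotypes.individual_ids)
    if k >= n:
        raise InputError(f"k = {k} must be smaller than the number of individuals ({n})")
    d = ibs_distance(genotypes.dosage)
    d2 = d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    coords = np.zeros((n, k))
    scale = max(vals.max(), 1.0)
    for out_col, ev_col in enumerate(order):
        lam = vals[ev_col]
        if lam <= 1e-12 * scale:
            continue
        col = vecs[:, ev_col] * np.sqrt(lam)
        pivot = int(np.argmax(np.abs(col)))
        if col[pivot] < 0:
            col = -col
        coords[:, out_col] = col
    return coords


# --------------------------------------------------------- logistic regression


def _irls(x: np.ndarray, y: np.ndarray, max_iter: int = 25, tol: float = 1e-10):
    """Newton/IRLS for logistic ML. Returns (beta, cov, converged).

    Iteration stops early (non-converged) once the dosage coefficient
    diverges past the separation bound, rather than grinding to the
    iteration cap.
    """
    beta = np.zeros(x.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -35, 35)
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = x.T @ (y - mu)
        h = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(h, grad)
        except np.linalg.LinAlgError:
            return beta, None, False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 2 * _SEPARATION_BETA:
            return beta, None, False
    eta = np.clip(x @ beta, -35, 35)
    mu = expit(eta)
    w = mu * (1 - mu)
    h = (x * w[:, None]).T @ x
    try:
        cov = np.linalg.inv(h)
    except np.linalg.LinAlgError:
        return beta, None, False
    return beta, cov, converged


def _penalized_loglik(x: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(x @ beta, -35, 35)
    mu = expit(eta)
    w = np.maximum(mu * (1 - mu), 1e-12)
    h = (x * w[:, None]).T @ x
    loglik = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    _, logdet = np.linalg.slogdet(h)
    return loglik + 0.5 * logdet


def _firth(x: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-7):
    """Firth bias-reduced logistic fit; returns (beta, penalized loglik).

    Newton steps on the Jeffreys-penalized score with step-halving to
    keep the penalized likelihood monotone (the logistf convention).
    """
    beta = np.zeros(x.shape[1])
    pll = _penalized_loglik(x, y, beta)
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -35, 35)
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-12)
        xw = x * w[:, None]
        h = xw.T @ x
        try:
            hinv = np.linalg.inv(h)
        except np.linalg.LinAlgError:
            hinv = np.linalg.pinv(h)
        hat = np.einsum("ij,jk,ik->i", x, hinv, xw)
        score = x.T @ (y - mu + hat * (0.5 - mu))
        step = hinv @ score
        new_beta = beta + step
        new_pll = _penalized_loglik(x, y, new_beta)
        halvings = 0
        while new_pll < pll - 1e-12 and halvings < 12:
            step *= 0.5
            new_beta = beta + step
            new_pll = _penalized_loglik(x, y, new_beta)
            halvings += 1
        beta, pll = new_beta, new_pll
        if np.max(np.abs(step)) < tol:
            break
    return beta, pll


def _separates_marginally(y: np.ndarray, d: np.ndarray) -> bool:
    """Complete separation along the dosage axis alone (cheap pre-check)."""
    d1, d0 = d[y == 1], d[y == 0]
    return bool(d1.min() > d0.max() or d0.min() > d1.max())


def fit_logistic(
    presence: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | None = None,
    snp_id: str = "",
    site_id: str = "",
    population: str = "",
) -> AssociationRecord:
    """Logistic regression of carrier status on SNP dosage.

    Missing dosages are dropped pairwise.  Complete (or quasi-complete)
    separation triggers the Firth fallback with a penalized-LRT p-value.
    Raises :class:`DegenerateStatisticError` when the outcome has a
    single class.
    """
    y = np.asarray(presence, dtype=np.float64)
    d = np.asarray(dosage, dtype=np.float64)
    mask = ~(np.isnan(d) | (d < 0))
    y, d = y[mask], d[mask]
    cov = None if covariates is None else np.asarray(covariates, float)[mask]
    if y.size == 0 or len(np.unique(y)) < 2:
        raise DegenerateStatisticError("outcome has a single class")
    cols = [np.ones_like(d), d]
    if cov is not None:
        keep = cov.std(axis=0) > 1e-12  # drop within-population constants
        cols.extend(cov[:, i] for i in np.nonzero(keep)[0])
    x = np.column_stack(cols)
    return _fit(x, y, snp_id=snp_id, site_id=site_id, population=population)


def _fit(
    x: np.ndarray,
    y: np.ndarray,
    reduced_pll: float | None = None,
    snp_id: str = "",
    site_id: str = "",
    population: str = "",
) -> AssociationRecord:
    """Core fit on an assembled design matrix (dosage in column 1).

    ``reduced_pll`` optionally carries the cached penalized log-likelihood
    of the dosage-free Firth model (identical for every SNP of a scan
    with no missing genotypes).
    """
    d = x[:, 1]
    if d.std() < 1e-12:
        return AssociationRecord(snp_id, site_id, population,
                                 float("nan"), float("nan"), float("nan"),
                                 False, "failed")
    if not _separates_marginally(y, d):
        beta, covmat, converged = _irls(x, y)
        if converged and covmat is not None and abs(beta[1]) < _SEPARATION_BETA:
            se = np.sqrt(covmat[1, 1])
            z = beta[1] / se
            p = float(2 * norm.sf(abs(z)))
            return AssociationRecord(snp_id, site_id, population,
                                     float(beta[1]), float(np.exp(beta[1])),
                                     p, True, "mle")
    # separation or non-convergence: Firth fit, penalized-LRT p-value
    beta_f, pll_full = _firth(x, y)
    if reduced_pll is None:
        _, reduced_pll = _firth(np.delete(x, 1, axis=1), y)
    lr = max(2.0 * (pll_full - reduced_pll), 0.0)
    p = float(chi2.sf(lr, 1))
    b = float(beta_f[1])
    return AssociationRecord(snp_id, site_id, population, b,
                             float(np.exp(min(b, 700.0))), p, True, "firth")


# --------------------------------------------------------------- site scanning


def scan_site(
    site_id: str,
    presence_row: np.ndarray,
    genotypes: GenotypeTable,
    mds: np.ndarray,
    populations: dict[str, str] | None = None,
) -> list[AssociationRecord]:
    """Genome-wide per-population association scan for one insertion site.

    ``presence_row`` must be aligned to ``genotypes.individual_ids``.
    Populations where the site is fixed or absent are skipped; small
    populations (< 20) are scanned with a warning.
    """
    populations = populations or genotypes.populations or {
        i: "ALL" for i in genotypes.individual_ids
    }
    labels = np.asarray([populations[i] for i in genotypes.individual_ids])
    records: list[AssociationRecord] = []
    for pop in sorted(set(labels)):
        sel = labels == pop
        y = presence_row[sel]
        if len(np.unique(y)) < 2:
            logger.info("site %s fixed or absent in %s; skipped", site_id, pop)
            continue
        if sel.sum() < 20:
            warnings.warn(f"population {pop} has only {int(sel.sum())} individuals", stacklevel=2)
        cov = mds[sel]
        keep_cov = cov.std(axis=0) > 1e-12
        cov = cov[:, keep_cov]
        dos = genotypes.dosage[:, sel]
        n = int(sel.sum())
        x = np.empty((n, 2 + cov.shape[1]))
        x[:, 0] = 1.0
        x[:, 2:] = cov
        yf = y.astype(np.float64)
        # dosage-free Firth loglik is shared by every complete-data SNP fit
        _, reduced_pll = _firth(np.delete(x, 1, axis=1), yf)
        for j, snp_id in enumerate(genotypes.snps["id"]):
            d = dos[j].astype(np.float64)
            if (d < 0).any():  # pairwise deletion of missing genotypes
                try:
                    rec = fit_logistic(yf, d, cov, snp_id=snp_id,
                                       site_id=site_id, population=pop)
                except DegenerateStatisticError:
                    continue
            else:
                x[:, 1] = d
                rec = _fit(x, yf, reduced_pll=reduced_pll, snp_id=snp_id,
                           site_id=site_id, population=pop)
            records.append(rec)
    return records


def records_to_frame(records: list[AssociationRecord], genotypes: GenotypeTable) -> pd.DataFrame:
    """Long-format association table with SNP coordinates attached."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        return pd.DataFrame(columns=["snp_id", "site_id", "population", "beta",
                                     "odds_ratio", "p_value", "converged", "method",
                                     "chrom", "pos"])
    coords = genotypes.snps.set_index("id")[["chrom", "pos"]]
    df = df.join(coords, on="snp_id")
    return df


def define_hisnps(
    records: pd.DataFrame,
    site_id: str,
    site_chrom: str,
    site_pos: int,
    population: str,
    window_size: int = 1_000_000,
    alpha: float = 0.05,
) -> HiSNPSet:
    """Bonferroni hiSNP set within the window centered on the insertion.

    The threshold is ``alpha / N`` with N the number of SNPs tested in
    the window (converged or not); members are the converged records at
    or below it.  An empty window yields an empty set with an undefined
    (NaN) threshold.
    """
    half = window_size // 2
    start, end = site_pos - half, site_pos + half
    sub = records[(records["site_id"] == site_id) & (records["population"] == population)]
    in_win = sub[(sub["chrom"] == site_chrom) & (sub["pos"] >= start) & (sub["pos"] < end)]
    n = len(in_win)
    if n == 0:
        return HiSNPSet(site_id, population, start, end, float("nan"),
                        in_win.reset_index(drop=True))
    threshold = alpha / n
    members = in_win[in_win["converged"] & (in_win["p_value"] <= threshold)]
    members = members.sort_values(["p_value", "snp_id"], kind="stable").reset_index(drop=True)
    return HiSNPSet(site_id, population, start, end, threshold, members)


# ------------------------------------------------------- linkage disequilibrium


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of unphased dosages.

    Missing entries are dropped pairwise; zero variance in either vector
    returns NaN (undefined).
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    mask = ~(np.isnan(a) | np.isnan(b) | (a < 0) | (b < 0))
    a, b = a[mask], b[mask]
    if a.size < 2 or a.std() < 1e-12 or b.std() < 1e-12:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def tag_snps_by_ld(
    presence_row: np.ndarray, genotypes: GenotypeTable, threshold: float = 0.2
) -> pd.DataFrame:
    """SNPs tagging the insertion by r² > threshold against carrier status."""
    rows = []
    for j, snp_id in enumerate(genotypes.snps["id"]):
        r2 = ld_r2(presence_row, genotypes.dosage[j])
        if np.isfinite(r2) and r2 > threshold:
            rows.append((snp_id, r2))
    return pd.DataFrame(rows, columns=["snp_id", "r_squared"])


def compare_hisnp_sets(set_a: set[str], set_b: set[str]) -> dict[str, float]:
    """Directed overlap fractions and Jaccard index of two hiSNP sets."""
    inter = len(set_a & set_b)
    union = len(set_a | set_b)
    return {
        "overlap_a_in_b": inter / len(set_a) if set_a else float("nan"),
        "overlap_b_in_a": inter / len(set_b) if set_b else float("nan"),
        "jaccard": inter / union if union else float("nan"),
    }
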