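"""Weighted mixed-linear-model association scan with LD-window QTL grouping.

The model for a vector of daughter yield deviations (DYD) y is

    y = 1 mu + x beta + u + e,   u ~ N(0, G sigma_u^2),  e ~ N(0, D sigma_e^2)

where x holds 0/1/2 dosages of the tested allele, G is the genomic
relationship matrix (VanRaden method 1 from SNP dosages) and D is a
diagonal matrix of inverse per-animal accuracy weights, accounting for
heterogeneous DYD reliability.  Variance components are estimated once by
REML on the null model (no marker) and held fixed during the scan.

Computation whitens by D^(-1/2) and eigendecomposes the whitened GRM, so
the per-marker generalized least squares solves reduce to weighted inner
products — no per-marker matrix inversion.  Each marker gets a Wald
chi-square test with 1 df; genome-wide significance uses the Bonferroni
threshold alpha / m.

Significant markers are grouped into QTL regions iteratively: the most
significant unassigned marker becomes a peak, and every significant marker
within the window (default 10 Mb, peak-centered) whose r^2 with the peak
exceeds the threshold (default 0.7) joins its region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger("pangraphsv")


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def _impute_mean(dosages: np.ndarray) -> np.ndarray:
    X = np.asarray(dosages, dtype=float).copy()
    col_mean = np.nanmean(X, axis=0)
    r, c = np.where(np.isnan(X))
    X[r, c] = col_mean[c]
    return X

def compute_grm(snp_dosages: np.ndarray) -> np.ndarray:
    """VanRaden method-1 GRM with observed allele frequencies.

    G = Z Z' / (2 sum_j p_j (1 - p_j)) with Z = dosages - 2p.  Missing
    dosages are mean-imputed; monomorphic markers carry no information and
    are dropped.  diag(G) averages ~1 for a population in HWE.
    """
    X = _impute_mean(snp_dosages)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers monomorphic; GRM undefined")
    X = X[:, poly]
    p = p[poly]
    Z = X - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    return (Z @ Z.T) / denom


# ---------------------------------------------------------------------------
# Null-model REML
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    mu: float
    sigma_u2: float
    sigma_e2: float
    loglik: float               # residual log-likelihood (constant dropped)
    lam: float                  # variance ratio sigma_u2 / sigma_e2
    boundary: bool              # estimate pinned at the search boundary
    n: int


def _whiten(G: np.ndarray, D: np.ndarray | None, n: int
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (w_half_inv, eigvals, eigvecs) of D^(-1/2) G D^(-1/2)."""
    if D is None:
        d = np.ones(n)
    else:
        d = np.diag(D) if D.ndim == 2 else np.asarray(D, dtype=float)
    if np.any(d <= 0):
        raise ValueError("D must be diagonal positive")
    w = 1.0 / np.sqrt(d)
    Gt = (G * w).T * w          # W G W for diagonal W
    s, U = np.linalg.eigh((Gt + Gt.T) / 2.0)
    s = np.clip(s, 0.0, None)
    return w, s, U


def _reml_neg_loglik(log_lam: float, s: np.ndarray, z: np.ndarray,
                     x0: np.ndarray) -> float:
    lam = np.exp(log_lam)
    h = lam * s + 1.0
    wt = 1.0 / h
    xtx = float(np.sum(wt * x0 * x0))
    mu = float(np.sum(wt * x0 * z)) / xtx
    r = z - x0 * mu
    n_p = z.size - 1
    rss = float(np.sum(wt * r * r))
    if rss <= 0 or xtx <= 0:
        return np.inf
    return 0.5 * (float(np.sum(np.log(h))) + np.log(xtx)
                  + n_p * np.log(rss / n_p) + n_p)


def fit_null_reml(y: np.ndarray, G: np.ndarray,
                  D: np.ndarray | None = None,
                  log_lam_bounds: tuple[float, float] = (-8.0, 8.0)
                  ) -> NullModel:
    """REML variance components of the null model y = 1 mu + u + e.

    One-dimensional optimization over log(lambda), lambda = sigma_u2 /
    sigma_e2, after whitening by D^(-1/2) and eigendecomposition of the
    whitened GRM.  Estimates pinned near a search boundary (heritability
    ~0 or ~1, e.g. G = I where only sigma_u2 + sigma_e2 is identified) are
    flagged.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 records for variance estimation")
    w, s, U = _whiten(G, D, n)
    z = U.T @ (w * y)
    x0 = U.T @ w                # U' W 1

    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=log_lam_bounds, args=(s, z, x0),
        method="bounded", options={"xatol": 1e-8})
    log_lam = float(res.x)
    lam = float(np.exp(log_lam))
    h = lam * s + 1.0
    wt = 1.0 / h
    xtx = float(np.sum(wt * x0 * x0))
    mu = float(np.sum(wt * x0 * z)) / xtx
    r = z - x0 * mu
    sigma_e2 = float(np.sum(wt * r * r)) / (n - 1)
    sigma_u2 = lam * sigma_e2
    # near a bound, or a profile so flat the ratio is not identified
    # (e.g. G = I, where only sigma_u2 + sigma_e2 has likelihood support)
    at_edge = (log_lam - log_lam_bounds[0] < 1e-3
               or log_lam_bounds[1] - log_lam < 1e-3)
    edge_gap = min(_reml_neg_loglik(b, s, z, x0) for b in log_lam_bounds) \
        - float(res.fun)
    boundary = at_edge or edge_gap < 1e-4
    if boundary:
        logger.warning("REML variance ratio at search boundary "
                       "(lambda = %.3g); components weakly identified", lam)
    return NullModel(mu=mu, sigma_u2=sigma_u2, sigma_e2=sigma_e2,
                     loglik=-float(res.fun), lam=lam, boundary=boundary, n=n)


def reml_loglik_grid(y: np.ndarray, G: np.ndarray, D: np.ndarray | None,
                     log_lams: np.ndarray) -> np.ndarray:
    """Residual log-likelihood on a grid of log(lambda) values."""
    y = np.asarray(y, dtype=float)
    w, s, U = _whiten(G, D, y.size)
    z = U.T @ (w * y)
    x0 = U.T @ w
    return np.array([-_reml_neg_loglik(ll, s, z, x0) for ll in log_lams])


# ---------------------------------------------------------------------------
# Association scan
# ---------------------------------------------------------------------------

@dataclass
class AssocResult:
    marker_id: str
    beta: float
    se: float
    p_value: float
    chromosome: str = "ref"
    position: int = 0
    monomorphic: bool = False

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p_value))


def mlma_scan(y: np.ndarray, markers: np.ndarray, G: np.ndarray,
              sigma_u2: float, sigma_e2: float,
              D: np.ndarray | None = None,
              marker_ids: list[str] | None = None,
              chromosomes: list[str] | None = None,
              positions: np.ndarray | None = None) -> list[AssocResult]:
    """Per-marker GLS scan with variance components held fixed.

    For each dosage column x, beta is the generalized least squares
    estimate under V = G sigma_u2 + D sigma_e2 with an intercept, and the
    Wald statistic beta^2 / var(beta) is referred to chi-square(1).  All
    markers are solved through one eigendecomposition of the whitened GRM.
    Monomorphic markers get p = 1 and a flag.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = _impute_mean(markers)
    m = X.shape[1]
    if marker_ids is None:
        marker_ids = [f"m{j + 1}" for j in range(m)]
    if chromosomes is None:
        chromosomes = ["ref"] * m
    if positions is None:
        positions = np.arange(m)

    lam = sigma_u2 / sigma_e2
    w, s, U = _whiten(G, D, n)
    wt = 1.0 / (sigma_e2 * (lam * s + 1.0))     # 1 / eigenvalues of whitened V
    t1 = U.T @ w
    ty = U.T @ (w * y)
    TX = U.T @ (w[:, None] * X)

    a11 = float(np.sum(wt * t1 * t1))
    b1 = float(np.sum(wt * t1 * ty))
    a12 = (wt * t1) @ TX
    a22 = wt @ (TX * TX)
    b2 = (wt * ty) @ TX

    det = a11 * a22 - a12 * a12
    mono = X.std(axis=0) == 0
    results: list[AssocResult] = []
    for j in range(m):
        if mono[j] or det[j] <= 0:
            results.append(AssocResult(
                marker_id=marker_ids[j], beta=0.0, se=np.inf, p_value=1.0,
                chromosome=chromosomes[j], position=int(positions[j]),
                monomorphic=True))
            continue
        beta = (a11 * b2[j] - a12[j] * b1) / det[j]
        var_b = a11 / det[j]
        chi2 = beta * beta / var_b
        p = float(stats.chi2.sf(chi2, df=1))
        results.append(AssocResult(
            marker_id=marker_ids[j], beta=float(beta), se=float(np.sqrt(var_b)),
            p_value=max(p, np.nextafter(0, 1)),
            chromosome=chromosomes[j], position=int(positions[j])))
    return results


def gls_single_marker(y: np.ndarray, x: np.ndarray, V: np.ndarray
                      ) -> tuple[float, float, float]:
    """Explicit-inverse GLS for one marker (brute-force reference route).

    Returns (beta, se, p).  O(n^3) per call; used as the numerical oracle
    for :func:`mlma_scan`, not in production scans.
    """
    Vi = np.linalg.inv(V)
    Xd = np.column_stack([np.ones_like(y), x])
    A = Xd.T @ Vi @ Xd
    b = Xd.T @ Vi @ y
    Ainv = np.linalg.inv(A)
    est = Ainv @ b
    beta = float(est[1])
    var_b = float(Ainv[1, 1])
    chi2 = beta * beta / var_b
    return beta, float(np.sqrt(var_b)), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Thresholds and trait transforms
# ---------------------------------------------------------------------------

def bonferroni(alpha: float, m: int) -> tuple[float, float]:
    """Genome-wide threshold alpha/m and its -log10."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    thr = alpha / m
    return thr, float(-np.log10(thr))


def scs_transform(scc: float | np.ndarray) -> float | np.ndarray:
    """Somatic cell score: SCS = 3 + log2(SCC / 100,000), SCC in cells/mL."""
    scc = np.asarray(scc, dtype=float)
    if np.any(scc <= 0):
        raise ValueError("somatic cell count must be positive")
    out = 3.0 + np.log2(scc / 100_000.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# QTL grouping
# ---------------------------------------------------------------------------

@dataclass
class QTLRegion:
    chromosome: str
    peak: AssocResult
    members: list[AssocResult] = field(default_factory=list)

    @property
    def interval(self) -> tuple[int, int]:
        pos = [r.position for r in self.members]
        return min(pos), max(pos)


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    x = _impute_mean(np.asarray(x, float)[:, None])[:, 0]
    y = _impute_mean(np.asarray(y, float)[:, None])[:, 0]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def group_qtl(results: list[AssocResult], dosages: np.ndarray,
              threshold_neglogp: float, window_bp: float = 10e6,
              r2_threshold: float = 0.7) -> list[QTLRegion]:
    """Iterative LD-window grouping of significant markers into QTL regions.

    Repeat until no significant marker is unassigned: the most significant
    one (ties: smaller p, then smaller position) becomes a peak; every
    unassigned significant marker on the same chromosome within the
    peak-centered window whose r^2 with the peak exceeds the threshold
    joins its region.  The output partitions the significant markers.
    """
    col = {r.marker_id: j for j, r in enumerate(results)}
    sig = [r for r in results if r.neg_log10_p >= threshold_neglogp]
    X = _impute_mean(np.asarray(dosages, float))
    half = window_bp / 2.0
    regions: list[QTLRegion] = []
    remaining = sorted(sig, key=lambda r: (r.p_value, r.position))
    while remaining:
        peak = remaining[0]
        members = [peak]
        rest = []
        for r in remaining[1:]:
            if (r.chromosome == peak.chromosome
                    and abs(r.position - peak.position) <= half
                    and ld_r2(X[:, col[peak.marker_id]],
                              X[:, col[r.marker_id]]) > r2_threshold):
                members.append(r)
            else:
                rest.append(r)
        regions.append(QTLRegion(chromosome=peak.chromosome, peak=peak,
                                 members=members))
        remaining = rest
    return regions
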