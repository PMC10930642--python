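"""Association scans for quantitative traits: GLM and kinship mixed model.

The GLM scan fits, per marker, ordinary least squares
``y ~ intercept + covariates + dosage`` with a two-sided t-test on the dosage
coefficient.  The MLM scan fits the single-locus mixed model
``y = Xb + g beta + u + e`` with ``u ~ N(0, sigma_g^2 K)`` and
``e ~ N(0, sigma_e^2 I)``: variance components are estimated once on the null
model by REML through the eigendecomposition of K with a 1-D search over the
variance ratio delta = sigma_e^2/sigma_g^2 (grid + bounded refinement), and
every marker is then tested by generalized least squares with the components
held fixed (the P3D/EMMAX approximation).  Exact per-marker REML is available
behind a flag for small problems.

Population structure enters through the VanRaden genomic relationship matrix
and the leading principal components of the standardized genotypes, which are
fitted as fixed covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import MISSING, GenotypeMatrix, MarkerMap

#: Smallest positive p-value reported (never exactly zero).
P_FLOOR = np.nextafter(0.0, 1.0)

_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, df=1)


@dataclass
class KinshipMatrix:
    samples: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape does not match sample count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric")

    def take(self, idx) -> "KinshipMatrix":
        idx = np.asarray(idx)
        return KinshipMatrix(
            [self.samples[i] for i in idx], self.values[np.ix_(idx, idx)]
        )


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


@dataclass
class AssocResult:
    table: pd.DataFrame  # marker_id, chrom, pos_bp, maf, beta, se, p, testable
    model: str
    lambda_gc: float
    bonferroni_alpha: float
    bonferroni_threshold: float

    @property
    def significant_markers(self) -> list:
        t = self.table
        return list(t.loc[t["p"] < self.bonferroni_threshold, "marker_id"])


def compute_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Columns are centered by twice the allele frequency and the cross-product
    is scaled by ``2 sum p(1-p)``; missing dosages are mean-imputed and
    monomorphic markers are excluded.
    """
    d = g.mean_imputed()
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers for kinship")
    z = d[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return KinshipMatrix(list(g.samples), (z @ z.T) / denom)


def compute_pcs(g: GenotypeMatrix, k: int = 3) -> np.ndarray:
    """Top-k principal component scores of the standardized genotype matrix.

    Sign is fixed so each component's largest-magnitude marker loading is
    positive; ``k=0`` returns an empty covariate block.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= g.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    if k == 0:
        return np.zeros((g.n_samples, 0))
    d = g.mean_imputed()
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    x = (d[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] *= -1.0
    return scores


def bonferroni_threshold(m_tested: int, alpha: float = 0.01) -> float:
    """Per-test significance cut-off alpha / m under Bonferroni adjustment."""
    if m_tested < 1:
        raise ValueError("m_tested must be >= 1")
    return alpha / m_tested


def lambda_gc(p_values) -> float:
    """Genomic inflation factor: median chi-square quantile over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValueError("no valid p-values")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_MEDIAN_1DF)


def _design(n: int, covariates) -> np.ndarray:
    if covariates is None:
        covariates = np.zeros((n, 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    X = np.column_stack([np.ones(n), covariates])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify an offending column for the error message
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                raise ValueError(
                    f"collinear covariates: column {j - 1} is linearly "
                    "dependent on the intercept/preceding columns"
                )
        raise ValueError("collinear covariates")
    return X


def _ols_scan(X0: np.ndarray, G: np.ndarray, y: np.ndarray):
    """Vectorized per-marker OLS of y on [X0, g_j]; returns beta, se, p, testable."""
    n, q = X0.shape
    Q, _ = np.linalg.qr(X0)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)
    gss = np.einsum("ij,ij->j", G_r, G_r)
    yss = float(y_r @ y_r)
    df = n - q - 1
    if df <= 0:
        raise ValueError("not enough samples for the design")
    testable = gss > 1e-12 * max(1.0, np.abs(G).max()) ** 2 * n
    beta = np.zeros(G.shape[1])
    se = np.full(G.shape[1], np.nan)
    p = np.ones(G.shape[1])
    bt = (G_r[:, testable].T @ y_r) / gss[testable]
    rss = np.maximum(yss - bt**2 * gss[testable], 0.0)
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se_t = np.sqrt(sigma2 / gss[testable])
        tstat = np.where(se_t > 0, bt / se_t, np.inf * np.sign(bt))
    p_t = 2.0 * stats.t.sf(np.abs(tstat), df)
    beta[testable] = bt
    se[testable] = se_t
    p[testable] = np.clip(p_t, P_FLOOR, 1.0)
    return beta, se, p, testable


def _prepare(g: GenotypeMatrix, y, covariates):
    y = np.asarray(y, dtype=float)
    if len(y) != g.n_samples:
        raise ValueError("phenotype length does not match sample count")
    mask = np.isfinite(y)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 phenotyped samples")
    idx = np.flatnonzero(mask)
    y = y[idx]
    if np.allclose(y, y[0]):
        raise ValueError("phenotype is constant")
    gsub = g.take_samples(idx)
    G = gsub.mean_imputed()
    cov = None if covariates is None else np.asarray(covariates, dtype=float)[idx]
    return idx, gsub, G, y, cov


def _result_table(m: MarkerMap | None, g: GenotypeMatrix, beta, se, p, testable):
    if m is not None:
        base = {"marker_id": m.marker_id, "chrom": m.chrom, "pos_bp": m.pos_bp}
    else:
        base = {
            "marker_id": [f"m{j}" for j in range(g.n_markers)],
            "chrom": ["0"] * g.n_markers,
            "pos_bp": np.zeros(g.n_markers, dtype=np.int64),
        }
    return pd.DataFrame(
        {**base, "maf": g.maf(), "beta": beta, "se": se, "p": p, "testable": testable}
    )


def glm_scan(
    g: GenotypeMatrix,
    y,
    covariates=None,
    m: MarkerMap | None = None,
    alpha: float = 0.01,
) -> AssocResult:
    """Fixed-effects scan: per-marker OLS with a t-test on the dosage term.

    Samples with a missing phenotype are dropped; missing dosages are
    mean-imputed per marker.  Constant-dosage markers are flagged untestable
    (beta 0, p 1).
    """
    _, gsub, G, y, cov = _prepare(g, y, covariates)
    X0 = _design(len(y), cov)
    beta, se, p, testable = _ols_scan(X0, G, y)
    table = _result_table(m, gsub, beta, se, p, testable)
    n_tested = int(testable.sum())
    return AssocResult(
        table=table,
        model="glm",
        lambda_gc=lambda_gc(p[testable]) if n_tested else np.nan,
        bonferroni_alpha=alpha,
        bonferroni_threshold=bonferroni_threshold(max(n_tested, 1), alpha),
    )


def _reml_loglik(delta, d, Xt, yt, logdet_xx):
    """Restricted log-likelihood of the null mixed model at variance ratio delta."""
    n, q = Xt.shape
    w = 1.0 / (d + delta)
    XtW = Xt * w[:, None]
    A = XtW.T @ Xt
    beta = np.linalg.solve(A, XtW.T @ yt)
    r = yt - Xt @ beta
    rwr = float(np.sum(w * r * r))
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0 or rwr <= 0:
        return -np.inf
    nq = n - q
    return -0.5 * (
        nq * np.log(2 * np.pi * rwr / nq)
        + nq
        + np.sum(np.log(d + delta))
        + logdet_a
        - logdet_xx
    )


def reml_null(
    y: np.ndarray, K: np.ndarray, X0: np.ndarray, log10_bounds=(-5.0, 5.0)
) -> tuple[VarianceComponents, float, np.ndarray, np.ndarray]:
    """REML variance components of ``y = X0 b + u + e`` via eigen-rotation.

    Returns (components, delta, eigenvalues, eigenvectors).  The search runs a
    coarse grid over log10 delta followed by bounded scalar refinement.
    """
    dvals, U = np.linalg.eigh(K)
    dvals = np.maximum(dvals, 0.0)  # PSD bending at 1e-8 tolerance
    yt = U.T @ y
    Xt = U.T @ X0
    sign, logdet_xx = np.linalg.slogdet(X0.T @ X0)
    grid = np.logspace(log10_bounds[0], log10_bounds[1], 61)
    ll = np.array([_reml_loglik(dl, dvals, Xt, yt, logdet_xx) for dl in grid])
    if not np.isfinite(ll).any():
        raise RuntimeError(f"REML failed on the whole grid; loglik trace: {ll}")
    best = int(np.nanargmax(ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda x: -_reml_loglik(10.0**x, dvals, Xt, yt, logdet_xx),
        bounds=(np.log10(lo), np.log10(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"REML refinement did not converge: {res.message}")
    delta = float(10.0**res.x)
    n, q = Xt.shape
    w = 1.0 / (dvals + delta)
    XtW = Xt * w[:, None]
    beta = np.linalg.solve(XtW.T @ Xt, XtW.T @ yt)
    r = yt - Xt @ beta
    sigma_g2 = float(np.sum(w * r * r) / (n - q))
    vc = VarianceComponents(sigma_g2=sigma_g2, sigma_e2=sigma_g2 * delta)
    return vc, delta, dvals, U


def mlm_scan(
    g: GenotypeMatrix,
    y,
    K: KinshipMatrix,
    covariates=None,
    m: MarkerMap | None = None,
    alpha: float = 0.01,
    exact_reml: bool = False,
) -> tuple[AssocResult, VarianceComponents]:
    """Kinship mixed-model scan (P3D by default, exact per-marker REML on request).

    When REML pushes the polygenic share to the boundary (h2 < 1e-6) the scan
    falls back to the exact OLS path, so the sigma_g2 = 0 limit reproduces the
    GLM to machine precision.
    """
    idx, gsub, G, y, cov = _prepare(g, y, covariates)
    Ksub = K.take(idx) if len(idx) != len(K.samples) else K
    eig = np.linalg.eigvalsh(Ksub.values)
    if eig.min() < -1e-8 * max(1.0, abs(eig.max())):
        raise ValueError("kinship matrix not positive semidefinite")
    X0 = _design(len(y), cov)
    vc, delta, dvals, U = reml_null(y, Ksub.values, X0)

    # REML at (or pinned against) the upper delta bound means no detectable
    # polygenic variance: collapse to the exact OLS path so the sigma_g2 = 0
    # limit reproduces the GLM to machine precision.
    if vc.h2 < 1e-6 or delta >= 0.99e5:
        res = glm_scan(g, _reinflate(y, idx, g.n_samples),
                       covariates=covariates, m=m, alpha=alpha)
        res.model = "mlm"
        return res, VarianceComponents(sigma_g2=0.0, sigma_e2=float(np.var(y, ddof=1)))

    w = 1.0 / (dvals + delta)
    sw = np.sqrt(w)
    yt = sw * (U.T @ y)
    X0t = sw[:, None] * (U.T @ X0)
    Gt = sw[:, None] * (U.T @ G)
    beta, se, p, testable = _ols_scan(X0t, Gt, yt)

    if exact_reml:
        for j in np.flatnonzero(testable):
            Xj = np.column_stack([X0, G[:, j]])
            vcj, dj, _, _ = reml_null(y, Ksub.values, Xj)
            wj = 1.0 / (dvals + dj)
            Xjt = np.sqrt(wj)[:, None] * (U.T @ Xj)
            yjt = np.sqrt(wj) * (U.T @ y)
            bj, sej, pj, tj = _ols_scan(Xjt[:, :-1], Xjt[:, -1:], yjt)
            beta[j], se[j], p[j] = bj[0], sej[0], pj[0]

    table = _result_table(m, gsub, beta, se, p, testable)
    n_tested = int(testable.sum())
    result = AssocResult(
        table=table,
        model="mlm",
        lambda_gc=lambda_gc(p[testable]) if n_tested else np.nan,
        bonferroni_alpha=alpha,
        bonferroni_threshold=bonferroni_threshold(max(n_tested, 1), alpha),
    )
    return result, vc


def _reinflate(y_sub: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Scatter a phenotype subset back to full sample length (NaN elsewhere)."""
    out = np.full(n, np.nan)
    out[idx] = y_sub
    return out


def genotype_trait_summary(
    dosage, alleles: tuple[str, str], y
) -> pd.DataFrame:
    """Trait mean/SD/count per genotype group of one biallelic marker.

    Groups are keyed by allele-pair labels (e.g. TT / CT / CC for alleles
    (T, C)); samples with a missing dosage form an ``undefined`` group and
    samples with a missing trait value are excluded from the statistics.
    """
    dosage = np.asarray(dosage)
    y = np.asarray(y, dtype=float)
    a, b = alleles
    labels = {0: f"{a}{a}", 1: f"{a}{b}", 2: f"{b}{b}", MISSING: "undefined"}
    rows = []
    for dose in (0, 1, 2, MISSING):
        sel = (dosage == dose) & np.isfinite(y)
        if not sel.any():
            continue
        v = y[sel]
        rows.append(
            {
                "genotype": labels[dose],
                "n": int(sel.sum()),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("genotype")
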