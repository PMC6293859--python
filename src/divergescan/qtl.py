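"""Mixed-model QTL mapping with a stepwise major-QTL scan.

The per-trait model decomposes a phenotype vector y over n fish as

    y = X b + S c + Z g + W q + e

with b the fixed effects (population mean and selection-line contrast),
c ~ N(0, I sigma_c^2) the random cage effect, g ~ N(0, K sigma_g^2) the
polygenic effect with K the realized genomic relationship matrix,
q the fixed allele-substitution effects of the currently selected major
QTL (dosage regressions), and e ~ N(0, I sigma_e^2). The phenotypic
covariance is V = sigma_c^2 SS' + sigma_g^2 ZKZ' + sigma_e^2 I.

Effects are solved from Henderson's mixed model equations, blocks ordered
(b, q, c, g) with lambda1 = sigma_e^2/sigma_c^2 on the cage block and
lambda2 * K^-1 on the polygenic block. Variance components are estimated
by REML: the residual variance is profiled out and the restricted
log-likelihood is maximized over log variance ratios with a
derivative-free simplex search (multi-start, so zero-boundary solutions
are reachable).

The genome scan tests one marker at a time as an extra fixed column with
variance components held fixed (EMMAX-style); stepwise selection adds the
best marker under a Bonferroni threshold, re-estimates variance
components, applies a backward check, and excludes markers within a
configurable distance of accepted QTL from later rounds.

Breeding values are GEBV = Z g_hat + W q_hat; trait heritability is
h^2 = (sigma_q^2 + sigma_g^2) / (sigma_q^2 + sigma_g^2 + sigma_c^2 + sigma_e^2),
where sigma_q^2 is the realized variance of the fitted fixed-QTL term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats
from scipy.linalg import LinAlgWarning

from .io import GenotypeMatrix
from .relationship import Grm

__all__ = [
    "VarianceComponents",
    "ModelMatrices",
    "MmeSystem",
    "FitResult",
    "QtlHit",
    "ConvergenceError",
    "build_model_matrices",
    "assemble_mme",
    "solve_mme",
    "fit_mme",
    "estimate_varcomp",
    "scan_snps",
    "stepwise_select",
    "heritability",
    "qtl_contribution",
]

_BOUNDARY_RATIO = 1e-8  # variance ratios below this collapse to the zero boundary


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the likelihood trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class VarianceComponents:
    """(sigma_c^2, sigma_g^2, sigma_e^2) plus post-hoc sigma_q^2."""

    cage: float = 0.0
    polygenic: float = 0.0
    residual: float = 1.0
    qtl: float = 0.0

    def __post_init__(self):
        for name in ("cage", "polygenic", "residual", "qtl"):
            if getattr(self, name) < 0:
                raise ValueError(f"variance {name} must be >= 0")

    @property
    def lambda1(self) -> float:
        """sigma_e^2 / sigma_c^2 (cage shrinkage); requires cage variance > 0."""
        if self.cage <= 0:
            raise ValueError("lambda1 undefined for zero cage variance")
        return self.residual / self.cage

    @property
    def lambda2(self) -> float:
        """sigma_e^2 / sigma_g^2 (polygenic shrinkage); requires polygenic > 0."""
        if self.polygenic <= 0:
            raise ValueError("lambda2 undefined for zero polygenic variance")
        return self.residual / self.polygenic

    @property
    def total(self) -> float:
        return self.qtl + self.polygenic + self.cage + self.residual


def heritability(v: VarianceComponents) -> float:
    """h^2 = (sigma_q^2 + sigma_g^2) / (sigma_q^2 + sigma_g^2 + sigma_c^2 + sigma_e^2)."""
    if v.total <= 0:
        raise ValueError("total variance is zero")
    return (v.qtl + v.polygenic) / v.total


@dataclass
class ModelMatrices:
    """Design matrices for one trait, complete-case over phenotyped samples."""

    y: np.ndarray
    X: np.ndarray
    S: np.ndarray | None  # cage incidence, None when a cage term is absent
    Z: np.ndarray  # maps phenotyped samples onto rows of K
    W: np.ndarray  # dosage columns of currently selected QTL (may be n x 0)
    K: np.ndarray | None
    sample_ids: list[str] = field(default_factory=list)
    qtl_markers: list[str] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.y)
        for name in ("X", "Z", "W"):
            mat = getattr(self, name)
            if mat.shape[0] != n:
                raise ValueError(f"{name} has {mat.shape[0]} rows, expected {n}")
        if self.S is not None and self.S.shape[0] != n:
            raise ValueError("S row count mismatch")
        if self.K is not None and self.Z.shape[1] != self.K.shape[0]:
            raise ValueError("Z columns must match K dimension")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def fixed(self) -> np.ndarray:
        """All fixed-effect columns [X | W]."""
        return np.hstack([self.X, self.W]) if self.W.shape[1] else self.X

    def with_qtl(self, w_cols: np.ndarray, marker_ids: list[str]) -> "ModelMatrices":
        w = np.hstack([self.W, w_cols]) if self.W.shape[1] else np.atleast_2d(w_cols)
        if w.ndim == 1:
            w = w[:, None]
        return replace(self, W=w, qtl_markers=self.qtl_markers + marker_ids)


def build_model_matrices(
    g: GenotypeMatrix,
    samples: pd.DataFrame,
    trait: str,
    grm: Grm,
    include_parents: bool = True,
) -> ModelMatrices:
    """Assemble y, X, S, Z for one trait (complete-case; W starts empty).

    X holds the intercept and, when both lines are present, a selection-line
    contrast. S is the cage incidence (omitted if a single cage). Z selects
    the phenotyped samples' rows of K.
    """
    meta = samples.set_index("sample_id").loc[g.samples]
    mask = meta[trait].notna().to_numpy()
    if not include_parents and "role" in meta.columns:
        mask &= (meta["role"] != "parent").to_numpy()
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError(f"no phenotyped samples for trait {trait!r}")
    sub = meta.iloc[idx]
    y = sub[trait].to_numpy(dtype=float)
    n = len(y)

    x_cols = [np.ones(n)]
    lines = sub["line"].to_numpy()
    if len(pd.unique(lines)) > 1:
        x_cols.append((lines == "selection").astype(float))
    X = np.column_stack(x_cols)

    S = None
    if "cage_id" in sub.columns:
        cages = pd.unique(sub["cage_id"])
        if len(cages) > 1:
            S = (sub["cage_id"].to_numpy()[:, None] == cages[None, :]).astype(float)

    if grm.samples != g.samples:
        raise ValueError("GRM sample order must match genotype matrix")
    Z = np.zeros((n, len(g.samples)))
    Z[np.arange(n), idx] = 1.0

    return ModelMatrices(
        y=y, X=X, S=S, Z=Z, W=np.empty((n, 0)), K=grm.matrix,
        sample_ids=[g.samples[i] for i in idx],
    )


@dataclass
class MmeSystem:
    """Assembled mixed-model-equation blocks: C @ sol = rhs."""

    coeff: np.ndarray
    rhs: np.ndarray
    slices: dict[str, slice]
    model: ModelMatrices
    varcomp: VarianceComponents


def assemble_mme(
    m: ModelMatrices, v: VarianceComponents, ridge: float = 0.0
) -> MmeSystem:
    """Build Henderson's equations with blocks ordered (b, q, c, g).

    The cage block carries S'S + lambda1*I; the polygenic block carries
    Z'Z + lambda2*K^-1. A random term with zero variance is dropped
    (the infinite-lambda limit). A singular K raises with advice to pass a
    ridge delta, added to K's diagonal before inversion.
    """
    use_cage = m.S is not None and v.cage > 0
    use_poly = m.K is not None and v.polygenic > 0

    parts = [("b", m.X), ("q", m.W)]
    if use_cage:
        parts.append(("c", m.S))
    if use_poly:
        parts.append(("g", m.Z))
    names = [nm for nm, mat in parts if mat.shape[1] > 0]
    mats = [mat for nm, mat in parts if mat.shape[1] > 0]

    sizes = [mat.shape[1] for mat in mats]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    slices = {nm: slice(offsets[i], offsets[i + 1]) for i, nm in enumerate(names)}
    dim = offsets[-1]

    coeff = np.empty((dim, dim))
    rhs = np.empty(dim)
    for i, a in enumerate(mats):
        rhs[slices[names[i]]] = a.T @ m.y
        for j, b in enumerate(mats):
            coeff[slices[names[i]], slices[names[j]]] = a.T @ b
    if use_cage:
        s = slices["c"]
        coeff[s, s] += v.lambda1 * np.eye(s.stop - s.start)
    if use_poly:
        k = m.K + ridge * np.eye(m.K.shape[0])
        try:
            cho = sla.cho_factor(k)
            k_inv = sla.cho_solve(cho, np.eye(k.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "K is singular; pass a ridge delta (e.g. ridge=1e-6) to regularize"
            ) from exc
        s = slices["g"]
        coeff[s, s] += v.lambda2 * k_inv
    return MmeSystem(coeff=coeff, rhs=rhs, slices=slices, model=m, varcomp=v)


@dataclass
class FitResult:
    """Solved model: effect estimates, GEBV, variances, h^2."""

    b_hat: np.ndarray
    q_hat: np.ndarray
    c_hat: np.ndarray
    g_hat: np.ndarray
    gebv: np.ndarray
    varcomp: VarianceComponents
    h2: float
    loglik: float | None = None
    qtl_markers: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)


def solve_mme(system: MmeSystem) -> FitResult:
    """Solve the symmetric block system and unpack effects.

    GEBV = Z g_hat + W q_hat holds exactly by construction.
    """
    if not np.all(np.isfinite(system.coeff)) or not np.all(np.isfinite(system.rhs)):
        raise ValueError("non-finite entries in the mixed model equations")
    with warnings.catch_warnings():
        # near-singular K is ridge-regularized at assembly; the K^-1 block
        # can still be extreme for small family cohorts, which scipy flags
        # even though the symmetric solve stays finite (checked below)
        warnings.simplefilter("ignore", LinAlgWarning)
        sol = sla.solve(system.coeff, system.rhs, assume_a="sym")
    if not np.all(np.isfinite(sol)):
        raise ValueError("mixed model equations produced non-finite solution")
    m, v = system.model, system.varcomp
    sl = system.slices
    b_hat = sol[sl["b"]]
    q_hat = sol[sl["q"]] if "q" in sl else np.empty(0)
    c_hat = sol[sl["c"]] if "c" in sl else np.zeros(m.S.shape[1] if m.S is not None else 0)
    g_hat = sol[sl["g"]] if "g" in sl else np.zeros(m.Z.shape[1])
    gebv = m.Z @ g_hat + (m.W @ q_hat if len(q_hat) else 0.0)
    sigma_q = float(np.var(m.W @ q_hat, ddof=1)) if len(q_hat) and m.n > 1 else 0.0
    v = replace(v, qtl=sigma_q)
    return FitResult(
        b_hat=b_hat, q_hat=q_hat, c_hat=c_hat, g_hat=g_hat, gebv=np.asarray(gebv),
        varcomp=v, h2=heritability(v), qtl_markers=list(m.qtl_markers),
        sample_ids=list(m.sample_ids),
    )


def fit_mme(m: ModelMatrices, v: VarianceComponents, ridge: float = 0.0) -> FitResult:
    return solve_mme(assemble_mme(m, v, ridge=ridge))


def _phenotypic_covariance_parts(m: ModelMatrices) -> list[np.ndarray]:
    """Covariance contributions per variance ratio: [SS', ZKZ'] as applicable."""
    parts = []
    if m.S is not None:
        parts.append(m.S @ m.S.T)
    if m.K is not None:
        parts.append(m.Z @ m.K @ m.Z.T)
    return parts


def _reml_negloglik(
    log_gamma: np.ndarray, parts: list[np.ndarray], y: np.ndarray, xf: np.ndarray
) -> tuple[float, float]:
    """Profile REML: returns (-restricted loglik, profiled sigma_e^2)."""
    n, p = xf.shape
    h = np.eye(n)
    for lg, part in zip(log_gamma, parts):
        h = h + np.exp(lg) * part
    try:
        cho = sla.cho_factor(h, lower=True)
    except np.linalg.LinAlgError:
        return np.inf, np.nan
    logdet_h = 2.0 * np.sum(np.log(np.diag(cho[0])))
    hi_y = sla.cho_solve(cho, y)
    hi_x = sla.cho_solve(cho, xf)
    xtx = xf.T @ hi_x
    xty = xf.T @ hi_y
    try:
        # extreme variance ratios visited by the optimizer make this
        # ill-conditioned; such points score poorly on their own
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", LinAlgWarning)
            beta = sla.solve(xtx, xty, assume_a="sym")
    except np.linalg.LinAlgError:
        return np.inf, np.nan
    rss = float(y @ hi_y - xty @ beta)
    if rss <= 0:
        return np.inf, np.nan
    sigma_e2 = rss / (n - p)
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0:
        return np.inf, np.nan
    nll = 0.5 * ((n - p) * np.log(sigma_e2) + logdet_h + logdet_xtx + (n - p))
    return nll, sigma_e2


def estimate_varcomp(
    m: ModelMatrices,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> VarianceComponents:
    """REML estimates of (sigma_c^2, sigma_g^2, sigma_e^2).

    The QTL columns in W are treated as fixed covariates. The residual
    variance is profiled out and the restricted log-likelihood is maximized
    over log variance ratios by Nelder-Mead from several starting points
    (covering interior and near-boundary regimes); ratios converging below
    the boundary tolerance are reported as exactly zero.
    """
    xf = m.fixed
    n, p = xf.shape
    if n < p + 2:
        raise ValueError(f"need n >= {p + 2} phenotyped samples, have {n}")
    parts = _phenotypic_covariance_parts(m)
    has_cage = m.S is not None
    n_ratio = len(parts)

    if n_ratio == 0:
        resid = m.y - xf @ np.linalg.lstsq(xf, m.y, rcond=None)[0]
        return VarianceComponents(residual=float(resid @ resid / (n - p)))

    from scipy.optimize import minimize

    trace: list[float] = []

    def objective(lg):
        nll, _ = _reml_negloglik(np.asarray(lg), parts, m.y, xf)
        trace.append(-nll)
        return nll

    starts = [np.full(n_ratio, s) for s in (-2.0, 0.0, 2.0, -8.0)]
    if n_ratio == 2:
        starts += [np.array([-8.0, 0.0]), np.array([0.0, -8.0])]
    best = None
    for x0 in starts:
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": tol, "maxiter": max_iter},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("REML optimization failed", trace)

    _, sigma_e2 = _reml_negloglik(best.x, parts, m.y, xf)
    gammas = np.exp(best.x)
    gammas[gammas < _BOUNDARY_RATIO] = 0.0
    if has_cage:
        cage = gammas[0] * sigma_e2
        poly = gammas[1] * sigma_e2 if n_ratio > 1 else 0.0
    else:
        cage = 0.0
        poly = gammas[0] * sigma_e2
    return VarianceComponents(cage=float(cage), polygenic=float(poly),
                              residual=float(sigma_e2))


def reml_loglik(m: ModelMatrices, v: VarianceComponents) -> float:
    """Restricted log-likelihood of the model at given variance components."""
    parts = _phenotypic_covariance_parts(m)
    gammas = []
    if m.S is not None:
        gammas.append(v.cage / v.residual if v.cage > 0 else 0.0)
    if m.K is not None:
        gammas.append(v.polygenic / v.residual if v.polygenic > 0 else 0.0)
    n, p = m.fixed.shape
    h = np.eye(n)
    for gam, part in zip(gammas, parts):
        h = h + gam * part
    v_mat = v.residual * h
    cho = sla.cho_factor(v_mat, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(cho[0])))
    xf = m.fixed
    vi_y = sla.cho_solve(cho, m.y)
    vi_x = sla.cho_solve(cho, xf)
    xtx = xf.T @ vi_x
    beta = sla.solve(xtx, xf.T @ vi_y, assume_a="sym")
    resid_form = float(m.y @ vi_y - (xf.T @ vi_y) @ beta)
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    return -0.5 * (logdet_v + logdet_xtx + resid_form)


def _whitener(m: ModelMatrices, v: VarianceComponents) -> np.ndarray:
    """Lower Cholesky factor of V = sigma_c^2 SS' + sigma_g^2 ZKZ' + sigma_e^2 I."""
    vm = v.residual * np.eye(m.n)
    if m.S is not None and v.cage > 0:
        vm += v.cage * (m.S @ m.S.T)
    if m.K is not None and v.polygenic > 0:
        vm += v.polygenic * (m.Z @ m.K @ m.Z.T)
    return np.linalg.cholesky(vm)


def scan_snps(
    m: ModelMatrices,
    g: GenotypeMatrix,
    v: VarianceComponents,
    candidates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Single-marker association scan with variance components held fixed.

    Each candidate marker enters as one extra fixed dosage column; after
    whitening by the Cholesky factor of V, its Wald test is an OLS t-test
    with n - p - 1 degrees of freedom. Monomorphic or collinear markers are
    flagged ``skipped`` with NaN statistics.

    Parameters
    ----------
    candidates : bool mask over markers, optional; default all.
    """
    L = _whitener(m, v)
    y_t = sla.solve_triangular(L, m.y, lower=True)
    x_t = sla.solve_triangular(L, m.fixed, lower=True)
    n, p = x_t.shape

    # dosages of phenotyped samples, mean-imputed per marker
    row_idx = m.Z.argmax(axis=1)
    dos = g.dosages[row_idx, :].copy()
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(dos, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nr, nc = np.nonzero(np.isnan(dos))
    dos[nr, nc] = col_mean[nc]
    w_t = sla.solve_triangular(L, dos, lower=True)

    q, _ = np.linalg.qr(x_t)
    y_perp = y_t - q @ (q.T @ y_t)
    w_perp = w_t - q @ (q.T @ w_t)
    rss0 = float(y_perp @ y_perp)

    num = w_perp.T @ y_perp
    den = np.einsum("ij,ij->j", w_perp, w_perp)
    scale = np.einsum("ij,ij->j", w_t, w_t) + 1e-30
    skipped = den / scale < 1e-10
    if candidates is not None:
        skipped = skipped | ~np.asarray(candidates, dtype=bool)
    den_safe = np.where(skipped | (den <= 0), np.nan, den)
    beta = num / den_safe
    rss = rss0 - num**2 / den_safe
    df = n - p - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom for the scan")
    sigma2 = rss / df
    se = np.sqrt(sigma2 / den_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    out = g.markers[["chrom", "pos"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["stat"] = tstat
    out["pvalue"] = pval
    out["skipped"] = skipped
    return out


@dataclass
class QtlHit:
    """One accepted major QTL for one trait."""

    trait: str
    marker_id: str
    chrom: str
    pos: int
    effect: float
    stat: float
    pvalue: float
    cp: float  # contribution to phenotypic variance


def qtl_contribution(
    w_col: np.ndarray, effect: float, v: VarianceComponents
) -> float:
    """Cp = Var(w_j * q_hat_j) / (sigma_q^2 + sigma_g^2 + sigma_c^2 + sigma_e^2)."""
    vp = v.total
    if vp <= 0:
        raise ValueError("phenotypic variance is zero")
    return float(np.var(w_col * effect, ddof=1)) / vp


def _imputed_column(g: GenotypeMatrix, m: ModelMatrices, j: int) -> np.ndarray:
    row_idx = m.Z.argmax(axis=1)
    col = g.dosages[row_idx, j].copy()
    mean = np.nanmean(col) if np.any(~np.isnan(col)) else 0.0
    col[np.isnan(col)] = mean
    return col


def stepwise_select(
    g: GenotypeMatrix,
    samples: pd.DataFrame,
    trait: str,
    grm: Grm,
    alpha: float = 0.05,
    min_distance_bp: int = 1_000_000,
    max_qtl: int = 20,
    include_parents: bool = True,
    ridge: float = 1e-6,
) -> tuple[list[QtlHit], FitResult]:
    """Forward-backward stepwise scan for major QTL on one trait.

    Forward: include the most significant marker while its p-value clears
    the Bonferroni threshold alpha / (markers tested); variance components
    are re-estimated after each inclusion. Backward: any included marker
    whose conditional p-value (given the others) rises above the threshold
    is removed. Markers within ``min_distance_bp`` of an accepted QTL are
    excluded from later rounds. Returns the accepted hits (with effects and
    Cp from the final joint fit) and the final model fit.
    """
    m = build_model_matrices(g, samples, trait, grm, include_parents=include_parents)
    chroms = g.markers["chrom"].to_numpy()
    positions = g.markers["pos"].to_numpy()
    marker_ids = list(g.markers.index)
    included: list[int] = []

    def eligible() -> np.ndarray:
        mask = np.ones(g.n_markers, dtype=bool)
        for j in included:
            near = (chroms == chroms[j]) & (
                np.abs(positions - positions[j]) <= min_distance_bp
            )
            mask &= ~near
        return mask

    while len(included) < max_qtl:
        v = estimate_varcomp(m)
        mask = eligible()
        if not mask.any():
            break
        scan = scan_snps(m, g, v, candidates=mask)
        tested = int((~scan["skipped"]).sum())
        if tested == 0:
            break
        threshold = alpha / tested
        pvals = scan["pvalue"].to_numpy()
        j = int(np.nanargmin(np.where(scan["skipped"], np.nan, pvals))) if np.any(
            ~scan["skipped"] & np.isfinite(pvals)
        ) else -1
        if j < 0 or not (pvals[j] < threshold):
            break
        m = m.with_qtl(_imputed_column(g, m, j)[:, None], [marker_ids[j]])
        included.append(j)

        # backward check on the enlarged model
        v = estimate_varcomp(m)
        drop: list[int] = []
        for k_pos, j_k in enumerate(included):
            others = [jj for jj in included if jj != j_k]
            m_red = replace(
                m,
                W=np.column_stack([_imputed_column(g, m, jj) for jj in others])
                if others
                else np.empty((m.n, 0)),
                qtl_markers=[marker_ids[jj] for jj in others],
            )
            single = np.zeros(g.n_markers, dtype=bool)
            single[j_k] = True
            cond = scan_snps(m_red, g, v, candidates=single)
            p_k = cond["pvalue"].iloc[j_k]
            if not (p_k < threshold):
                drop.append(j_k)
        if drop:
            included = [jj for jj in included if jj not in drop]
            m = replace(
                m,
                W=np.column_stack([_imputed_column(g, m, jj) for jj in included])
                if included
                else np.empty((m.n, 0)),
                qtl_markers=[marker_ids[jj] for jj in included],
            )

    v = estimate_varcomp(m)
    fit = fit_mme(m, v, ridge=ridge)
    hits: list[QtlHit] = []
    if included:
        final_scan_v = fit.varcomp
        for pos_idx, j in enumerate(included):
            others = [jj for jj in included if jj != j]
            m_red = replace(
                m,
                W=np.column_stack([_imputed_column(g, m, jj) for jj in others])
                if others
                else np.empty((m.n, 0)),
                qtl_markers=[marker_ids[jj] for jj in others],
            )
            single = np.zeros(g.n_markers, dtype=bool)
            single[j] = True
            cond = scan_snps(m_red, g, v, candidates=single)
            w_col = _imputed_column(g, m, j)
            effect = float(fit.q_hat[pos_idx])
            hits.append(
                QtlHit(
                    trait=trait,
                    marker_id=marker_ids[j],
                    chrom=str(chroms[j]),
                    pos=int(positions[j]),
                    effect=effect,
                    stat=float(cond["stat"].iloc[j]),
                    pvalue=float(cond["pvalue"].iloc[j]),
                    cp=qtl_contribution(w_col, effect, final_scan_v),
                )
            )
        hits.sort(key=lambda h: h.pvalue)
    return hits, fit
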