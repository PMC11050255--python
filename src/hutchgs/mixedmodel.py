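"""REML variance components and GBLUP breeding-value prediction.

Univariate model (one record per animal per trait):

    y = X b + Z a + e,   a ~ N(0, G sigma_a^2),   e ~ N(0, I sigma_e^2)

with G the genomic relationship matrix.  The restricted likelihood is
maximised by rotating into the eigenbasis of Z G Z' and profiling the
residual variance, leaving a one-dimensional Brent search over the variance
ratio.

Multivariate model (t traits, possibly different record sets per trait):

    vec(a) ~ N(0, M (x) G),   residuals per animal ~ N(0, R)

where M and R are the t x t genetic and residual covariance matrices and
records of different animals are residually independent.  Estimation is
EM-REML with average-information (AI) acceleration: EM steps are monotone in
the restricted likelihood and guarantee progress; AI steps are attempted once
the EM phase stabilises and are step-halved back toward the EM update
whenever they would decrease the likelihood or leave the PSD cone.

Two interchangeable computational backends evaluate the likelihood and the
EM/AI quantities: a fast one for "balanced" data (all traits recorded on the
same animals with the same fixed-effect design), which block-diagonalises
everything in the eigenbasis of G, and a dense one for arbitrary per-trait
missingness.

Prediction solves Henderson's mixed-model equations at fixed variance
components; GEBVs are returned for every individual in the GRM, including
unphenotyped or masked ones, whose information flows through G.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import minimize_scalar

from .grm import GRM, bend_grm

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# model specification and design construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which traits (1 = univariate, >=2 = multivariate) and which
    categorical fixed factors enter the model."""

    traits: tuple[str, ...]
    fixed_factors: tuple[str, ...] = ()
    grm_ref: str | None = None

    def __post_init__(self) -> None:
        if len(self.traits) == 0 or len(set(self.traits)) != len(self.traits):
            raise ValueError("traits must be non-empty and unique")
        object.__setattr__(self, "traits", tuple(self.traits))
        object.__setattr__(self, "fixed_factors", tuple(self.fixed_factors))


@dataclass
class TraitData:
    """Design pieces for one trait: response over its non-missing records,
    full-rank fixed-effect matrix, and record-to-GRM-row indices."""

    name: str
    y: np.ndarray           # (n_rec,)
    X: np.ndarray           # (n_rec, p) full column rank, intercept first
    idx: np.ndarray         # (n_rec,) indices into the GRM sample order
    x_columns: list[str]


@dataclass
class MixedModelData:
    """Per-trait design data plus the shared GRM."""

    traits: list[TraitData]
    grm: GRM

    @property
    def n_traits(self) -> int:
        return len(self.traits)


def _code_factors(sub: pd.DataFrame, factors: tuple[str, ...],
                  declared_levels: dict[str, list]) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment (first-level-reference) contrasts."""
    n = len(sub)
    cols = [np.ones(n)]
    names = ["intercept"]
    for f in factors:
        vals = sub[f].astype(str)
        present = [lv for lv in declared_levels[f] if lv in set(vals)]
        missing = [lv for lv in declared_levels[f] if lv not in set(vals)]
        if missing:
            warnings.warn(
                f"factor '{f}': level(s) {missing} have zero records after "
                f"missingness filtering and were dropped", stacklevel=3)
        for lv in present[1:]:
            cols.append((vals == lv).to_numpy(dtype=float))
            names.append(f"{f}[{lv}]")
    X = np.column_stack(cols)
    return X, names


def build_design(phenotypes: pd.DataFrame, spec: ModelSpec, grm: GRM) -> MixedModelData:
    """Assemble per-trait response vectors and full-rank fixed-effect designs.

    Records with a missing response are dropped trait by trait; factors are
    coded with an intercept and treatment contrasts (first observed level as
    reference), the coding being recorded in ``x_columns``.  Raises if a
    phenotyped individual is absent from the GRM or if the coded design is
    column-rank deficient (naming the aliased columns).
    """
    id_to_row = {s: i for i, s in enumerate(grm.sample_ids)}
    for f in spec.fixed_factors:
        if f not in phenotypes.columns:
            raise ValueError(f"fixed factor '{f}' not found in the phenotype table")
    declared_levels = {
        f: sorted(phenotypes[f].astype(str).unique()) for f in spec.fixed_factors
    }
    traits = []
    for trait in spec.traits:
        if trait not in phenotypes.columns:
            raise ValueError(f"trait '{trait}' not found in the phenotype table")
        sub = phenotypes.loc[phenotypes[trait].notna()]
        unknown = [s for s in sub["id"] if s not in id_to_row]
        if unknown:
            raise ValueError(
                f"{len(unknown)} phenotyped individual(s) missing from the GRM "
                f"(first: {unknown[0]})")
        y = sub[trait].to_numpy(dtype=float)
        X, names = _code_factors(sub, spec.fixed_factors, declared_levels)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, _, piv = scipy.linalg.qr(X, pivoting=True, mode="economic")
            aliased = [names[j] for j in piv[rank:]]
            raise ValueError(f"singular fixed-effect design for trait '{trait}': "
                             f"aliased columns {aliased}")
        idx = np.array([id_to_row[s] for s in sub["id"]], dtype=np.int64)
        traits.append(TraitData(name=trait, y=y, X=X, idx=idx, x_columns=names))
    return MixedModelData(traits=traits, grm=grm)


# ---------------------------------------------------------------------------
# variance-component results
# ---------------------------------------------------------------------------

@dataclass
class VarCompUV:
    """Univariate REML estimates: additive and residual variances,
    heritability, asymptotic standard errors (inverse AI matrix), restricted
    log-likelihood and convergence information."""

    sigma2_a: float
    sigma2_e: float
    h2: float
    se_sigma2_a: float
    se_sigma2_e: float
    se_h2: float
    loglik: float
    n_iter: int
    converged: bool
    boundary: bool = False


@dataclass
class VarCompMV:
    """Multivariate REML estimates: genetic (M) and residual (R) covariance
    matrices, the derived genetic correlations with delta-method standard
    errors, and the EM/AI iteration history."""

    trait_names: list[str]
    M: np.ndarray
    R: np.ndarray
    genetic_corr: np.ndarray
    se_M: np.ndarray
    se_R: np.ndarray
    se_genetic_corr: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    loglik_history: list[float] = field(default_factory=list)

    @property
    def h2(self) -> np.ndarray:
        va = np.diag(self.M)
        ve = np.diag(self.R)
        return va / (va + ve)


# ---------------------------------------------------------------------------
# univariate REML (eigen-rotation + profiled Brent search)
# ---------------------------------------------------------------------------

def _prepare_uv(data: MixedModelData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    td = data.traits[0]
    K = data.grm.matrix[np.ix_(td.idx, td.idx)]
    d, U = np.linalg.eigh(K)
    if d[0] < -1e-8 * max(d[-1], 1.0):
        K = bend_grm(K)
        d, U = np.linalg.eigh(K)
    d = np.maximum(d, 0.0)
    return d, U.T @ td.y, U.T @ td.X


def _uv_profile_loglik(log_delta: float, d: np.ndarray, yr: np.ndarray,
                       Xr: np.ndarray) -> tuple[float, float, float]:
    """Restricted log-likelihood profiled over sigma_e^2 at a fixed variance
    ratio delta = sigma_a^2 / sigma_e^2.  Returns (logL, sigma2_e, sigma2_a)."""
    n, p = Xr.shape
    delta = np.exp(log_delta)
    w = delta * d + 1.0
    Xw = Xr / w[:, None]
    B = Xr.T @ Xw
    beta = np.linalg.solve(B, Xw.T @ yr)
    r = yr - Xr @ beta
    quad = float(np.sum(r * r / w))
    sigma2_e = quad / (n - p)
    _, logdetB = np.linalg.slogdet(B)
    ll = -0.5 * ((n - p) * (_LOG2PI + np.log(sigma2_e) + 1.0)
                 + float(np.sum(np.log(w))) + logdetB)
    return ll, sigma2_e, delta * sigma2_e


def reml_uv(data: MixedModelData, *, max_iter: int = 200, tol: float = 1e-8) -> VarCompUV:
    """Univariate REML by profiled one-dimensional optimisation.

    Z G Z' is eigendecomposed once; y and X are rotated; the restricted
    likelihood is then separable and maximised over the log variance ratio by
    bounded Brent search.  A ratio driven to the search boundary is reported
    as a boundary estimate (h2 ~ 0 or ~ 1) with ``boundary=True`` rather
    than as an error.  Standard errors come from the inverse AI matrix.
    """
    if data.n_traits != 1:
        raise ValueError("reml_uv requires single-trait data")
    d, yr, Xr = _prepare_uv(data)
    n, p = Xr.shape
    if n <= p:
        raise ValueError("more fixed-effect columns than records")

    lo, hi = -25.0, 25.0
    res = minimize_scalar(lambda t: -_uv_profile_loglik(t, d, yr, Xr)[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10, "maxiter": max_iter})
    ll, sigma2_e, sigma2_a = _uv_profile_loglik(res.x, d, yr, Xr)
    boundary = bool(res.x < lo + 0.5 or res.x > hi - 0.5)
    pheno_var = float(np.var(yr, ddof=1))
    floor = 1e-10 * pheno_var
    if sigma2_a < floor:
        sigma2_a = floor
        boundary = True
    h2 = sigma2_a / (sigma2_a + sigma2_e)

    # asymptotic covariance of (sigma2_a, sigma2_e) from the AI matrix
    v = sigma2_a * d + sigma2_e
    Xv = Xr / v[:, None]
    Bv = Xr.T @ Xv

    def applyP(u: np.ndarray) -> np.ndarray:
        t1 = u / v
        return t1 - Xv @ np.linalg.solve(Bv, Xr.T @ t1)

    Py = applyP(yr)
    u_a, u_e = d * Py, Py
    AI = 0.5 * np.array([
        [u_a @ applyP(u_a), u_a @ applyP(u_e)],
        [u_e @ applyP(u_a), u_e @ applyP(u_e)],
    ])
    try:
        cov = np.linalg.inv(AI)
        if np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError
        se_a, se_e = np.sqrt(np.diag(cov))
        g = np.array([sigma2_e, -sigma2_a]) / (sigma2_a + sigma2_e) ** 2
        se_h2 = float(np.sqrt(max(g @ cov @ g, 0.0)))
    except np.linalg.LinAlgError:
        se_a = se_e = se_h2 = float("nan")

    return VarCompUV(sigma2_a=float(sigma2_a), sigma2_e=float(sigma2_e), h2=float(h2),
                     se_sigma2_a=float(se_a), se_sigma2_e=float(se_e), se_h2=se_h2,
                     loglik=float(ll), n_iter=int(res.nfev), converged=bool(res.success),
                     boundary=boundary)


# ---------------------------------------------------------------------------
# multivariate REML backends
# ---------------------------------------------------------------------------

def _vech_indices(t: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(t) for j in range(i, t)]


def _sym_basis(t: int, i: int, j: int) -> np.ndarray:
    J = np.zeros((t, t))
    J[i, j] = J[j, i] = 1.0
    return J


def _clip_psd(A: np.ndarray, *, rel_floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue clipping at rel_floor * trace: keeps iterates inside the
    PSD cone without collapsing them to singularity."""
    A = (A + A.T) / 2.0
    w, V = np.linalg.eigh(A)
    floor = rel_floor * max(np.trace(A), 1e-300)
    if w[0] >= floor:
        return A
    w = np.maximum(w, floor)
    return (V * w) @ V.T


class _BalancedBackend:
    """All traits observed on the same animals with the same fixed-effect
    design: rotate into the eigenbasis of G and everything factorises into
    q independent t x t blocks (plus a low-rank fixed-effect correction)."""

    def __init__(self, data: MixedModelData):
        td0 = data.traits[0]
        self.t = data.n_traits
        self.q = len(td0.idx)
        self.p = td0.X.shape[1]
        K = data.grm.matrix[np.ix_(td0.idx, td0.idx)]
        d, U = np.linalg.eigh(K)
        if d[0] < -1e-8 * max(d[-1], 1.0):
            K = bend_grm(K)
            d, U = np.linalg.eigh(K)
        self.d = np.maximum(d, 0.0)
        self.Ys = U.T @ np.column_stack([td.y for td in data.traits])   # (q, t)
        self.Xs = U.T @ td0.X                                           # (q, p)
        self.N = self.q * self.t
        self.n_fixed = self.t * self.p

    # -- per-(M,R) state ----------------------------------------------------
    def _state(self, M: np.ndarray, R: np.ndarray) -> dict:
        d, Ys, Xs, t, p = self.d, self.Ys, self.Xs, self.t, self.p
        Vk = d[:, None, None] * M[None] + R[None]
        Vinv = np.linalg.inv(Vk)
        sign, logdet = np.linalg.slogdet(Vk)
        if np.any(sign <= 0):
            return {"ok": False}
        XtViX = np.einsum("kij,ka,kb->iajb", Vinv, Xs, Xs,
                          optimize=True).reshape(t * p, t * p)
        XtViy = np.einsum("kij,kj,ka->ia", Vinv, Ys, Xs, optimize=True).reshape(-1)
        sB, logdetB = np.linalg.slogdet(XtViX)
        if sB <= 0:
            return {"ok": False}
        beta = np.linalg.solve(XtViX, XtViy).reshape(t, p)
        r = Ys - Xs @ beta.T
        Py = np.einsum("kij,kj->ki", Vinv, r)
        quad = float(np.sum(r * Py))
        ll = -0.5 * (float(logdet.sum()) + logdetB + quad
                     + (self.N - self.n_fixed) * _LOG2PI)
        C = np.linalg.inv(XtViX)
        Cx = np.einsum("ka,iajb,kb->kij", Xs, C.reshape(t, p, t, p), Xs, optimize=True)
        return {"ok": True, "Vinv": Vinv, "Py": Py, "ll": ll, "C": C, "Cx": Cx}

    def loglik(self, M: np.ndarray, R: np.ndarray) -> float:
        st = self._state(M, R)
        return st["ll"] if st["ok"] else -np.inf

    def em_update(self, M: np.ndarray, R: np.ndarray,
                  st: dict) -> tuple[np.ndarray, np.ndarray]:
        d, q = self.d, self.q
        Vinv, Py, Cx = st["Vinv"], st["Py"], st["Cx"]
        # genetic covariance: E[A' G^-1 A | y] / q
        Sa = np.einsum("k,ki,kj->ij", d, Py, Py, optimize=True)
        E1 = M @ Sa @ M
        MVM = np.einsum("ab,kbc,cd->kad", M, Vinv, M, optimize=True)
        F = np.einsum("ab,kbc->kac", M, Vinv, optimize=True)
        term2 = np.einsum("k,kij->ij", d, MVM, optimize=True)
        term3 = np.einsum("k,kab,kbc,kdc->ad", d, F, Cx, F, optimize=True)
        M_new = (E1 + q * M - term2 + term3) / q
        # residual covariance: E[E' E | y] / q
        Se = Py.T @ Py
        E1e = R @ Se @ R
        RVR = np.einsum("ab,kbc,cd->kad", R, Vinv, R, optimize=True)
        Fr = np.einsum("ab,kbc->kac", R, Vinv, optimize=True)
        term3e = np.einsum("kab,kbc,kdc->ad", Fr, Cx, Fr, optimize=True)
        R_new = (E1e + q * R - RVR.sum(axis=0) + term3e) / q
        return (M_new + M_new.T) / 2.0, (R_new + R_new.T) / 2.0

    def _applyP(self, u: np.ndarray, st: dict) -> np.ndarray:
        Vinv, C = st["Vinv"], st["C"]
        Xs, t, p = self.Xs, self.t, self.p
        t1 = np.einsum("kij,kj->ki", Vinv, u)
        g = np.einsum("ki,ka->ia", t1, Xs).reshape(-1)
        h = (C @ g).reshape(t, p)
        t2 = np.einsum("kij,kj->ki", Vinv, Xs @ h.T)
        return t1 - t2

    def score_and_ai(self, M: np.ndarray, R: np.ndarray,
                     st: dict) -> tuple[np.ndarray, np.ndarray]:
        t = self.t
        d, Vinv, Py, Cx = self.d, st["Vinv"], st["Py"], st["Cx"]
        params = [("g", i, j) for i, j in _vech_indices(t)] + \
                 [("e", i, j) for i, j in _vech_indices(t)]
        us, scores = [], []
        ones = np.ones_like(d)
        for kind, i, j in params:
            J = _sym_basis(t, i, j)
            w = d if kind == "g" else ones
            u = w[:, None] * (Py @ J)
            tr1 = np.einsum("k,kij,ji->", w, Vinv, J, optimize=True)
            tr2 = np.einsum("k,kij,jl,klm,kmi->", w, Vinv, J, Vinv, Cx, optimize=True)
            scores.append(-0.5 * (tr1 - tr2 - float(np.sum(u * Py))))
            us.append(u)
        Pus = [self._applyP(u, st) for u in us]
        nr = len(params)
        AI = np.empty((nr, nr))
        for a in range(nr):
            for b in range(a, nr):
                AI[a, b] = AI[b, a] = 0.5 * float(np.sum(us[a] * Pus[b]))
        return np.array(scores), AI


class _DenseBackend:
    """Arbitrary per-trait record sets: build the full record-level V and
    work with dense matrices.  Intended for moderate problem sizes."""

    def __init__(self, data: MixedModelData):
        self.t = len(data.traits)
        self.q = data.grm.n_individuals
        G = data.grm.matrix
        if np.linalg.eigvalsh(G).min() < -1e-8 * max(np.abs(G).max(), 1.0):
            G = bend_grm(G)
        self.G = G
        self.y = np.concatenate([td.y for td in data.traits])
        self.X = scipy.linalg.block_diag(*[td.X for td in data.traits])
        self.cells = np.concatenate([
            i * self.q + td.idx for i, td in enumerate(data.traits)])
        self.N = len(self.y)
        self.n_fixed = self.X.shape[1]

    def _kron_cells(self, T: np.ndarray, genetic: bool) -> np.ndarray:
        """(T (x) G)[cells, cells] or (T (x) I)[cells, cells] without forming
        the full Kronecker product."""
        t, q, cells = self.t, self.q, self.cells
        trait_of = cells // q
        ind_of = cells % q
        base = self.G if genetic else np.eye(q)
        return T[np.ix_(trait_of, trait_of)] * base[np.ix_(ind_of, ind_of)]

    def _state(self, M: np.ndarray, R: np.ndarray) -> dict:
        V = self._kron_cells(M, True) + self._kron_cells(R, False)
        try:
            cf = scipy.linalg.cho_factor(V)
        except np.linalg.LinAlgError:
            return {"ok": False}
        logdetV = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        Vinv = scipy.linalg.cho_solve(cf, np.eye(self.N))
        XtViX = self.X.T @ Vinv @ self.X
        sB, logdetB = np.linalg.slogdet(XtViX)
        if sB <= 0:
            return {"ok": False}
        beta = np.linalg.solve(XtViX, self.X.T @ (Vinv @ self.y))
        r = self.y - self.X @ beta
        Py = Vinv @ r
        ll = -0.5 * (logdetV + logdetB + float(r @ Py)
                     + (self.N - self.n_fixed) * _LOG2PI)
        ViX = Vinv @ self.X
        P = Vinv - ViX @ np.linalg.solve(XtViX, ViX.T)
        return {"ok": True, "P": P, "Py": Py, "ll": ll}

    def loglik(self, M: np.ndarray, R: np.ndarray) -> float:
        st = self._state(M, R)
        return st["ll"] if st["ok"] else -np.inf

    def _cov_a_y(self, M: np.ndarray) -> np.ndarray:
        """Cov(vec(A), y) with A trait-major: (t*q, N)."""
        t, q, cells = self.t, self.q, self.cells
        trait_of = cells // q
        ind_of = cells % q
        out = np.empty((t * q, self.N))
        for i in range(t):
            out[i * q:(i + 1) * q, :] = M[i, trait_of] * self.G[:, ind_of]
        return out

    def _selection(self, T: np.ndarray) -> np.ndarray:
        """(T (x) I_q) restricted to record columns: Sel[i*q+k, r] =
        T[i, trait(r)] * delta(k, individual(r)).  Equals Cov(e_complete, y)
        for T = R, and G^-1 Cov(a, y) for T = M (no inverse required)."""
        t, q, cells = self.t, self.q, self.cells
        trait_of = cells // q
        ind_of = cells % q
        out = np.zeros((t * q, self.N))
        for i in range(t):
            block = np.zeros((q, self.N))
            block[ind_of, np.arange(self.N)] = T[i, trait_of]
            out[i * q:(i + 1) * q, :] = block
        return out

    def em_update(self, M: np.ndarray, R: np.ndarray,
                  st: dict) -> tuple[np.ndarray, np.ndarray]:
        t, q = self.t, self.q
        P, Py = st["P"], st["Py"]
        # genetic: E[A' G^-1 A | y]_ij = w_i' G w_j + q M_ij - tr(Sel_i P Ca_j')
        # with w_i = Sel_i(M) Py; the selection identity keeps G^-1 out of it,
        # so singular or bent G is handled the same way as in the fast path
        Sa = self._selection(M)
        Ca = self._cov_a_y(M)
        w = (Sa @ Py).reshape(t, q)
        wGw = w @ self.G @ w.T
        CaP = Ca @ P
        M_new = np.empty((t, t))
        for i in range(t):
            for j in range(i, t):
                trace_term = float(np.sum(Sa[i * q:(i + 1) * q] * CaP[j * q:(j + 1) * q]))
                M_new[i, j] = M_new[j, i] = (wGw[i, j] + q * M[i, j] - trace_term) / q
        Ce = self._selection(R)
        ehat = (Ce @ Py).reshape(t, q)
        CeP = Ce @ P
        R_new = np.empty((t, t))
        for i in range(t):
            for j in range(i, t):
                cond_tr = R[i, j] * q - float(np.sum(
                    CeP[i * q:(i + 1) * q] * Ce[j * q:(j + 1) * q]))
                R_new[i, j] = R_new[j, i] = (ehat[i] @ ehat[j] + cond_tr) / q
        return M_new, R_new

    def score_and_ai(self, M: np.ndarray, R: np.ndarray,
                     st: dict) -> tuple[np.ndarray, np.ndarray]:
        t = self.t
        P, Py = st["P"], st["Py"]
        params = [("g", i, j) for i, j in _vech_indices(t)] + \
                 [("e", i, j) for i, j in _vech_indices(t)]
        us, scores = [], []
        for kind, i, j in params:
            J = _sym_basis(t, i, j)
            Vr = self._kron_cells(J, kind == "g")
            u = Vr @ Py
            scores.append(-0.5 * (float(np.sum(P * Vr)) - float(Py @ u)))
            us.append(u)
        Pus = [P @ u for u in us]
        nr = len(params)
        AI = np.empty((nr, nr))
        for a in range(nr):
            for b in range(a, nr):
                AI[a, b] = AI[b, a] = 0.5 * float(us[a] @ Pus[b])
        return np.array(scores), AI


def _is_balanced(data: MixedModelData) -> bool:
    td0 = data.traits[0]
    for td in data.traits[1:]:
        if len(td.idx) != len(td0.idx) or not np.array_equal(td.idx, td0.idx):
            return False
        if td.X.shape != td0.X.shape or not np.array_equal(td.X, td0.X):
            return False
    return True


def _theta_to_mats(theta: np.ndarray, t: int) -> tuple[np.ndarray, np.ndarray]:
    nv = t * (t + 1) // 2
    M = np.zeros((t, t))
    R = np.zeros((t, t))
    for k, (i, j) in enumerate(_vech_indices(t)):
        M[i, j] = M[j, i] = theta[k]
        R[i, j] = R[j, i] = theta[nv + k]
    return M, R


def _mats_to_theta(M: np.ndarray, R: np.ndarray) -> np.ndarray:
    t = M.shape[0]
    return np.array([M[i, j] for i, j in _vech_indices(t)]
                    + [R[i, j] for i, j in _vech_indices(t)])


def reml_mv(
    data: MixedModelData,
    *,
    max_iter: int = 200,
    tol: float = 1e-8,
    em_steps_before_ai: int = 5,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarCompMV:
    """Multivariate EM-REML with average-information acceleration.

    Starting values come from per-trait univariate fits (zero covariances)
    unless ``init`` supplies a warm start.  Every accepted step is checked
    against the restricted likelihood: EM updates are monotone by
    construction, AI steps are halved back toward the EM update whenever
    they would decrease the likelihood or leave the PSD cone (eigenvalues
    are clipped at 1e-8 x trace).  Convergence: relative log-likelihood
    change below ``tol``.  Reports genetic correlations with delta-method
    standard errors from the inverse AI matrix.
    """
    t = data.n_traits
    if t < 1:
        raise ValueError("no traits")
    for td in data.traits:
        if len(td.y) == 0:
            raise ValueError(f"trait '{td.name}' has no records")

    backend = _BalancedBackend(data) if _is_balanced(data) else _DenseBackend(data)

    if init is not None:
        M = _clip_psd(np.asarray(init[0], dtype=float))
        R = _clip_psd(np.asarray(init[1], dtype=float))
    else:
        M = np.zeros((t, t))
        R = np.zeros((t, t))
        for i, td in enumerate(data.traits):
            uv = reml_uv(MixedModelData(traits=[td], grm=data.grm))
            pv = float(np.var(td.y, ddof=1))
            M[i, i] = max(uv.sigma2_a, 1e-4 * pv)
            R[i, i] = max(uv.sigma2_e, 1e-4 * pv)

    pheno_var = np.array([float(np.var(td.y, ddof=1)) for td in data.traits])
    floor = 1e-10 * pheno_var

    st = backend._state(M, R)
    if not st.get("ok", False):
        M, R = _clip_psd(M, rel_floor=1e-6), _clip_psd(R, rel_floor=1e-6)
        st = backend._state(M, R)
        if not st.get("ok", False):
            raise ValueError("restricted likelihood undefined at the starting values")
    ll = st["ll"]
    history = [ll]
    converged = False
    n_iter = 0
    ai_active = False

    for it in range(1, max_iter + 1):
        n_iter = it
        M_em, R_em = backend.em_update(M, R, st)
        M_em = _clip_psd(M_em)
        R_em = _clip_psd(R_em)
        np.fill_diagonal(M_em, np.maximum(np.diag(M_em), floor))
        np.fill_diagonal(R_em, np.maximum(np.diag(R_em), floor))

        accepted = False
        if ai_active or it > em_steps_before_ai:
            ai_active = True
            try:
                s, AI = backend.score_and_ai(M, R, st)
                dtheta = np.linalg.solve(AI + 1e-10 * np.eye(len(s)) * max(np.trace(AI), 1.0), s)
                theta = _mats_to_theta(M, R)
                frac = 1.0
                for _ in range(6):
                    Mc, Rc = _theta_to_mats(theta + frac * dtheta, t)
                    Mc, Rc = _clip_psd(Mc), _clip_psd(Rc)
                    st_c = backend._state(Mc, Rc)
                    if st_c.get("ok", False) and st_c["ll"] >= ll - 1e-12:
                        M, R, st = Mc, Rc, st_c
                        accepted = True
                        break
                    frac *= 0.5
            except np.linalg.LinAlgError:
                pass
        if not accepted:
            st_em = backend._state(M_em, R_em)
            if not st_em.get("ok", False):
                warnings.warn("EM update left the feasible region; stopping early")
                break
            M, R, st = M_em, R_em, st_em

        ll_new = st["ll"]
        history.append(ll_new)
        if not ai_active and abs(ll_new - ll) / max(abs(ll_new), 1.0) < 1e-3:
            ai_active = True
        if abs(ll_new - ll) / max(abs(ll_new), 1.0) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    if not converged:
        warnings.warn(f"multivariate REML did not converge in {n_iter} iterations "
                      f"(last relative change above {tol:g})")

    # standard errors from the inverse AI matrix at the optimum
    nv = t * (t + 1) // 2
    se_M = np.full((t, t), np.nan)
    se_R = np.full((t, t), np.nan)
    se_rg = np.full((t, t), np.nan)
    cov = None
    try:
        s, AI = backend.score_and_ai(M, R, st)
        cov = np.linalg.inv(AI)
        for k, (i, j) in enumerate(_vech_indices(t)):
            if cov[k, k] >= 0:
                se_M[i, j] = se_M[j, i] = np.sqrt(cov[k, k])
            if cov[nv + k, nv + k] >= 0:
                se_R[i, j] = se_R[j, i] = np.sqrt(cov[nv + k, nv + k])
    except np.linalg.LinAlgError:
        pass

    va = np.diag(M)
    denom = np.sqrt(np.outer(va, va))
    with np.errstate(invalid="ignore", divide="ignore"):
        rg = np.clip(M / denom, -1.0, 1.0)
    np.fill_diagonal(rg, 1.0)

    if cov is not None:
        vech = _vech_indices(t)
        pos = {ij: k for k, ij in enumerate(vech)}
        for i in range(t):
            for j in range(i + 1, t):
                g = np.zeros(2 * nv)
                denom_ij = np.sqrt(va[i] * va[j])
                if denom_ij <= 0:
                    continue
                g[pos[(i, i)]] = -M[i, j] / (2.0 * va[i] * denom_ij)
                g[pos[(i, j)]] = 1.0 / denom_ij
                g[pos[(j, j)]] = -M[i, j] / (2.0 * va[j] * denom_ij)
                var_rg = float(g @ cov @ g)
                if var_rg >= 0:
                    se_rg[i, j] = se_rg[j, i] = np.sqrt(var_rg)

    return VarCompMV(
        trait_names=[td.name for td in data.traits],
        M=M, R=R, genetic_corr=rg, se_M=se_M, se_R=se_R, se_genetic_corr=se_rg,
        loglik=float(st["ll"]), n_iter=n_iter, converged=converged,
        loglik_history=history,
    )


# ---------------------------------------------------------------------------
# BLUP via Henderson's mixed-model equations
# ---------------------------------------------------------------------------

def _masked_traits(data: MixedModelData,
                   mask: dict[str, set[str]] | None) -> list[TraitData]:
    if not mask:
        return data.traits
    id_of = data.grm.sample_ids
    out = []
    for td in data.traits:
        masked_ids = mask.get(td.name)
        if not masked_ids:
            out.append(td)
            continue
        keep = np.array([id_of[i] not in masked_ids for i in td.idx])
        out.append(TraitData(name=td.name, y=td.y[keep], X=td.X[keep],
                             idx=td.idx[keep], x_columns=td.x_columns))
    return out


def solve_blup(
    data: MixedModelData,
    vc: VarCompUV | VarCompMV,
    mask: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Solve the mixed-model equations at fixed variance components.

    Henderson's equations are solved in their equivalent variance form,
    which never inverts G: with V = Z (M (x) G) Z' + Sigma_e over the kept
    records,

        b = (X' V^-1 X)^-1 X' V^-1 y,
        a = (M (x) G) Z' V^-1 (y - X b).

    This matters because the VanRaden G is always singular (centering gives
    it the all-ones null vector), so the G^-1 form of the equations would
    require bending that perturbs the solution; the variance form is exact
    for singular G and singular M alike.

    ``mask`` maps trait name -> set of individual ids whose records for that
    trait are treated as unobserved (removed from y, X and Z).  Fixed effects
    are estimated jointly with the breeding values; GEBVs are returned for
    every individual in the GRM -- masked and unphenotyped individuals are
    predicted through their genomic relationships.

    Returns a table with one row per GRM individual: ``id``, one
    ``gebv_<trait>`` column per trait and one ``observed_<trait>`` flag
    (True when the phenotype entered the equations).
    """
    t = data.n_traits
    q = data.grm.n_individuals
    if isinstance(vc, VarCompUV):
        if t != 1:
            raise ValueError("univariate variance components with multi-trait data")
        M = np.array([[vc.sigma2_a]])
        R = np.array([[vc.sigma2_e]])
    else:
        M = vc.M
        R = vc.R
    traits = _masked_traits(data, mask)

    G = data.grm.matrix
    y = np.concatenate([td.y for td in traits])
    X = scipy.linalg.block_diag(*[td.X for td in traits])
    p_tot = X.shape[1]
    cells = np.concatenate([i * q + td.idx for i, td in enumerate(traits)])
    trait_of = cells // q
    ind_of = cells % q

    V = (M[np.ix_(trait_of, trait_of)] * G[np.ix_(ind_of, ind_of)]
         + R[np.ix_(trait_of, trait_of)] * (ind_of[:, None] == ind_of[None, :]))
    try:
        cf = scipy.linalg.cho_factor(V)
    except np.linalg.LinAlgError:
        ridge = 1e-10 * float(np.mean(np.diag(V)))
        logger.warning("record covariance singular; retrying with ridge %.3e", ridge)
        try:
            cf = scipy.linalg.cho_factor(V + ridge * np.eye(V.shape[0]))
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "mixed-model equations singular even after bending") from err
    ViX = scipy.linalg.cho_solve(cf, X)
    Viy = scipy.linalg.cho_solve(cf, y)
    bhat = np.linalg.solve(X.T @ ViX, X.T @ Viy)
    Pr = Viy - ViX @ bhat          # V^-1 (y - X bhat)

    ahat = np.empty((t, q))
    for i in range(t):
        acc = np.zeros(q)
        offset = 0
        for j, td in enumerate(traits):
            nj = len(td.y)
            if M[i, j] != 0.0:
                acc += M[i, j] * (G[:, td.idx] @ Pr[offset:offset + nj])
            offset += nj
        ahat[i] = acc
    out = pd.DataFrame({"id": data.grm.sample_ids})
    for i, td in enumerate(traits):
        out[f"gebv_{td.name}"] = ahat[i]
        flag = np.zeros(q, dtype=bool)
        flag[td.idx] = True
        out[f"observed_{td.name}"] = flag
    return out
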