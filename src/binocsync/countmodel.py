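"""Poisson count models for fixation-pair counts.

The modeling unit is one cell of the count table: the number of binocular
fixation pairs a participant produced on one page in one screen region (for
one asynchrony type).  Two nested models are fitted per analysis:

* a **null model** — intercept plus random intercepts for participant,
  article, and page (page order within article), capturing between-unit
  rate heterogeneity;
* a **screen-region model** — the same plus fixed effects for the left and
  right screen regions, with *middle as the reference level*, so the two
  coefficients are log rate ratios versus the middle of the line.

Counts get a Poisson error distribution with a log link.  The plain GLM is
fitted by iteratively reweighted least squares; the mixed model maximizes a
Laplace approximation to the marginal likelihood over crossed independent
random intercepts (maximum likelihood, not REML-like, so likelihood-ratio
tests on fixed effects between nested fits are valid).  Variance components
are optimized on the standard-deviation scale with a lower bound at zero;
boundary solutions are reported as zero variances, not errors.

The parameter count ``k`` used by AIC/BIC is the number of fixed
coefficients plus the number of variance components.

Usage::

    model = PoissonCountModel(counts, region_effect=True,
                              random_factors=("participant", "article", "page"))
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

REGION_REFERENCE = "middle"
REGION_TERMS = ("left", "right")
FACTOR_COLUMNS = {
    "participant": "participant_id",
    "article": "article_id",
    "page": "page_id",
}

_ETA_CLIP = 30.0


def information_criteria(loglik: float, k: int, nobs: int) -> tuple[float, float]:
    """AIC and BIC from a maximized log-likelihood.

    ``aic = -2*loglik + 2*k``; ``bic = -2*loglik + k*ln(nobs)``.
    """
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * np.log(nobs)
    return float(aic), float(bic)


@dataclasses.dataclass(frozen=True)
class Factor:
    """A grouping factor: integer level codes plus level labels."""

    name: str
    codes: np.ndarray
    n_levels: int
    labels: tuple


@dataclasses.dataclass
class Design:
    y: np.ndarray
    X: np.ndarray
    xnames: list[str]
    factors: list[Factor]

    @property
    def nobs(self) -> int:
        return len(self.y)


def build_design(
    counts: pd.DataFrame,
    region_effect: bool = True,
    random_factors: tuple[str, ...] = ("participant", "article", "page"),
    page_within_article: bool = True,
) -> Design:
    """Response vector, treatment-coded fixed design, grouping structure.

    Region is treatment-coded with ``middle`` as the reference; the fixed
    columns are (intercept, region[left], region[right]) in that order.  A
    requested region level absent from the data is an error.  The ``page``
    factor is keyed by (article, page) by default — page order within
    article — or by the bare page label with ``page_within_article=False``.
    """
    if len(counts) == 0:
        raise ValueError("empty count table")
    y = counts["count"].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y % 1 != 0):
        raise ValueError("counts must be non-negative integers")
    n = len(y)
    cols = [np.ones(n)]
    xnames = ["intercept"]
    if region_effect:
        region = counts["region"].astype(str).to_numpy()
        present = set(region)
        for level in (REGION_REFERENCE, *REGION_TERMS):
            if level not in present:
                raise ValueError(f"region level {level!r} absent from the data")
        for level in REGION_TERMS:
            cols.append((region == level).astype(float))
            xnames.append(f"region[{level}]")
    X = np.column_stack(cols)
    factors = []
    for fac in random_factors:
        if fac not in FACTOR_COLUMNS:
            raise ValueError(f"unknown random factor {fac!r}")
        if fac == "page" and page_within_article:
            key = (
                counts["article_id"].astype(str) + "/" + counts["page_id"].astype(str)
            )
        else:
            key = counts[FACTOR_COLUMNS[fac]].astype(str)
        codes, labels = pd.factorize(key, sort=True)
        factors.append(
            Factor(name=fac, codes=codes.astype(np.int64), n_levels=len(labels),
                   labels=tuple(labels))
        )
    return Design(y=y, X=X, xnames=xnames, factors=factors)


# ---------------------------------------------------------------------------
# GLM by IRLS


def _poisson_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    return float(np.sum(y * eta - mu) - special.gammaln(y + 1.0).sum())


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _fit_irls(y, X, tol=1e-12, max_iter=100):
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-8))
    dev_hist = []
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        dev_hist.append(_poisson_deviance(y, mu))
        z = eta + (y - mu) / mu
        XtW = X.T * mu
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    dev_hist.append(_poisson_deviance(y, mu))
    cov = np.linalg.inv((X.T * mu) @ X)
    return beta, cov, _poisson_loglik(y, eta), dev_hist, converged


# ---------------------------------------------------------------------------
# GLMM by Laplace approximation

_SD_FLOOR = 1e-6  # below this an SD is treated as a zero-variance boundary


class _LaplaceEngine:
    """Laplace machinery: random-effect mode and approximate marginal loglik.

    Follows the nAGQ = 1 convention of mixed-model practice: the inner
    Newton solves only for the random-effect mode b̂(β, σ); the fixed
    effects are optimized in the *outer* problem against the full Laplace
    objective, log-determinant term included (the determinant depends on β
    through the IRLS weights, so profiling β at the joint penalized mode
    would bias the intercept).
    """

    def __init__(self, y, X, factors: list[Factor]):
        self.y = y
        self.X = X
        self.factors = factors
        self.p = X.shape[1]
        self.sizes = [f.n_levels for f in factors]
        self.q = sum(self.sizes)
        self.offsets = np.concatenate([[0], np.cumsum(self.sizes)])[:-1]
        self._b = np.zeros(self.q)  # warm start across outer evaluations

    def _eta(self, beta, b, active):
        eta = self.X @ beta
        for fi in active:
            off = self.offsets[fi]
            eta = eta + b[off : off + self.sizes[fi]][self.factors[fi].codes]
        return np.clip(eta, -_ETA_CLIP, _ETA_CLIP)

    def _hbb(self, mu, active):
        """Random-effect block of the negative Hessian (Z'WZ), dense."""
        dims = [self.sizes[fi] for fi in active]
        pos = np.concatenate([[0], np.cumsum(dims)])
        H = np.zeros((int(pos[-1]), int(pos[-1])))
        for ai, fi in enumerate(active):
            c = self.factors[fi].codes
            nf = self.sizes[fi]
            a0 = pos[ai]
            H[a0 : a0 + nf, a0 : a0 + nf] = np.diag(
                np.bincount(c, weights=mu, minlength=nf)
            )
            for bi in range(ai + 1, len(active)):
                gi = active[bi]
                cg = self.factors[gi].codes
                ng = self.sizes[gi]
                b0 = pos[bi]
                C = np.bincount(c * ng + cg, weights=mu, minlength=nf * ng).reshape(
                    nf, ng
                )
                H[a0 : a0 + nf, b0 : b0 + ng] = C
                H[b0 : b0 + ng, a0 : a0 + nf] = C.T
        return H, pos

    def mode(self, beta, sigmas, max_iter=100, gtol=1e-9):
        """Newton ascent over b of the penalized conditional loglik."""
        active = [i for i, s in enumerate(sigmas) if s > _SD_FLOOR]
        b = self._b.copy()
        for fi in range(len(self.factors)):
            if fi not in active:
                off = self.offsets[fi]
                b[off : off + self.sizes[fi]] = 0.0
        if not active:
            return b, np.exp(np.clip(self.X @ beta, -_ETA_CLIP, _ETA_CLIP)), active

        def penalty(b):
            pen = 0.0
            for fi in active:
                off = self.offsets[fi]
                bb = b[off : off + self.sizes[fi]]
                pen += float(bb @ bb) / sigmas[fi] ** 2
            return pen

        def objective(b):
            eta = self._eta(beta, b, active)
            return float(self.y @ eta - np.exp(eta).sum()) - 0.5 * penalty(b)

        def pack(b):
            return np.concatenate(
                [b[self.offsets[fi] : self.offsets[fi] + self.sizes[fi]] for fi in active]
            )

        def unpack(v):
            out = np.zeros(self.q)
            pos = 0
            for fi in active:
                nf = self.sizes[fi]
                out[self.offsets[fi] : self.offsets[fi] + nf] = v[pos : pos + nf]
                pos += nf
            return out

        obj = objective(b)
        for _ in range(max_iter):
            eta = self._eta(beta, b, active)
            mu = np.exp(eta)
            resid = self.y - mu
            g = []
            for fi in active:
                off = self.offsets[fi]
                bb = b[off : off + self.sizes[fi]]
                g.append(
                    np.bincount(
                        self.factors[fi].codes, weights=resid,
                        minlength=self.sizes[fi],
                    )
                    - bb / sigmas[fi] ** 2
                )
            grad = np.concatenate(g)
            if np.max(np.abs(grad)) < gtol * (1.0 + abs(obj)):
                break
            H, pos = self._hbb(mu, active)
            for ai, fi in enumerate(active):
                a0, nf = pos[ai], self.sizes[fi]
                H[a0 : a0 + nf, a0 : a0 + nf] += np.eye(nf) / sigmas[fi] ** 2
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            t = 1.0
            packed = pack(b)
            for _ls in range(30):
                cand = unpack(packed + t * step)
                cand_obj = objective(cand)
                if cand_obj >= obj - 1e-12:
                    break
                t *= 0.5
            b, obj = cand, cand_obj
        self._b = b.copy()
        eta = self._eta(beta, b, active)
        return b, np.exp(eta), active

    def laplace_loglik(self, beta, sigmas):
        """Laplace-approximate marginal log-likelihood at (β, σ)."""
        b, mu, active = self.mode(beta, sigmas)
        eta = self._eta(beta, b, active)
        ll_cond = _poisson_loglik(self.y, eta)
        if not active:
            return ll_cond, b
        pen = 0.0
        for fi in active:
            off = self.offsets[fi]
            bb = b[off : off + self.sizes[fi]]
            pen += float(bb @ bb) / sigmas[fi] ** 2
        Hbb, _ = self._hbb(mu, active)
        # logdet(D) + logdet(Hbb + D^-1) = logdet(I + S Hbb S), S = diag(σ)
        s_diag = np.concatenate(
            [np.full(self.sizes[fi], sigmas[fi]) for fi in active]
        )
        M = np.eye(len(s_diag)) + (s_diag[:, None] * Hbb) * s_diag[None, :]
        sign, logdet = np.linalg.slogdet(M)
        if sign <= 0:
            return -np.inf, b
        return ll_cond - 0.5 * pen - 0.5 * logdet, b

    def beta_cov(self, beta, sigmas):
        """Approximate covariance of β̂: Schur complement of the joint Hessian."""
        b, mu, active = self.mode(beta, sigmas)
        A = (self.X.T * mu) @ self.X
        if not active:
            return np.linalg.inv(A)
        Hbb, pos = self._hbb(mu, active)
        for ai, fi in enumerate(active):
            a0, nf = pos[ai], self.sizes[fi]
            Hbb[a0 : a0 + nf, a0 : a0 + nf] += np.eye(nf) / sigmas[fi] ** 2
        B = np.zeros((self.p, Hbb.shape[0]))
        for ai, fi in enumerate(active):
            c = self.factors[fi].codes
            nf = self.sizes[fi]
            for j in range(self.p):
                B[j, pos[ai] : pos[ai] + nf] = np.bincount(
                    c, weights=self.X[:, j] * mu, minlength=nf
                )
        return np.linalg.inv(A - B @ np.linalg.solve(Hbb, B.T))


# ---------------------------------------------------------------------------
# Model / Results objects


class PoissonCountModel:
    """Poisson model for fixation-pair counts, GLM or mixed.

    Parameters
    ----------
    counts
        Count table with columns participant_id, article_id, page_id,
        region, count (plus anything else, ignored).
    region_effect
        Include fixed effects for the left/right screen regions (treatment
        coding, middle as reference).  ``False`` gives the null model.
    random_factors
        Subset of {"participant", "article", "page"} to receive independent
        random intercepts; empty for a plain GLM.
    page_within_article
        Key the page factor by (article, page-order) rather than the bare
        page label.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        region_effect: bool = True,
        random_factors: tuple[str, ...] = ("participant", "article", "page"),
        page_within_article: bool = True,
    ):
        self.counts = counts
        self.region_effect = bool(region_effect)
        self.page_within_article = bool(page_within_article)
        requested = tuple(random_factors)
        design = build_design(
            counts, region_effect, requested, page_within_article
        )
        # a factor with a single level is unidentifiable alongside the
        # intercept: drop it with a warning
        kept = []
        for fac in design.factors:
            if fac.n_levels < 2:
                import warnings

                warnings.warn(
                    f"random factor {fac.name!r} has a single level; dropped",
                    stacklevel=2,
                )
            else:
                kept.append(fac)
        design.factors = kept
        self.random_factors = tuple(f.name for f in kept)
        self.design = design

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, **kwargs) -> "PoissonCountModel":
        return cls(counts, **kwargs)

    @property
    def k_params(self) -> int:
        return self.design.X.shape[1] + len(self.design.factors)

    def fit(self, start_sd: float = 0.3, maxiter: int = 200) -> "PoissonCountResults":
        d = self.design
        if not d.factors:
            beta, cov, ll, dev_hist, converged = _fit_irls(d.y, d.X)
            return PoissonCountResults(
                model=self,
                params=pd.Series(beta, index=d.xnames),
                cov_params=cov,
                loglik=ll,
                random_variances={},
                converged=converged,
                method="glm-irls",
                deviance_history=dev_hist,
            )
        engine = _LaplaceEngine(d.y, d.X, d.factors)
        nfac = len(d.factors)
        p = d.X.shape[1]
        beta0, _, _, _, _ = _fit_irls(d.y, d.X)  # GLM start for β

        def nll(x):
            ll, _ = engine.laplace_loglik(x[:p], x[p:])
            return -ll

        x0 = np.concatenate([beta0, np.full(nfac, start_sd)])
        bounds = [(None, None)] * p + [(0.0, 10.0)] * nfac
        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7, "eps": 1e-6},
        )
        beta = res.x[:p]
        sigmas = np.where(res.x[p:] > _SD_FLOOR, res.x[p:], 0.0)
        ll, b = engine.laplace_loglik(beta, sigmas)
        cov = engine.beta_cov(beta, sigmas)
        variances = {
            fac.name: float(s**2) for fac, s in zip(d.factors, sigmas)
        }
        return PoissonCountResults(
            model=self,
            params=pd.Series(beta, index=d.xnames),
            cov_params=cov,
            loglik=float(ll),
            random_variances=variances,
            converged=bool(res.success),
            method="glmm-laplace",
            random_effects=b,
        )


@dataclasses.dataclass
class PoissonCountResults:
    """Estimates, uncertainties and information criteria for one fit."""

    model: PoissonCountModel
    params: pd.Series
    cov_params: np.ndarray
    loglik: float
    random_variances: dict[str, float]
    converged: bool
    method: str
    deviance_history: list[float] | None = None
    random_effects: np.ndarray | None = None

    # -- derived quantities -------------------------------------------------
    @property
    def nobs(self) -> int:
        return self.model.design.nobs

    @property
    def k_params(self) -> int:
        return len(self.params) + len(self.random_variances)

    @property
    def aic(self) -> float:
        return information_criteria(self.loglik, self.k_params, self.nobs)[0]

    @property
    def bic(self) -> float:
        return information_criteria(self.loglik, self.k_params, self.nobs)[1]

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues.to_numpy())),
            index=self.params.index,
        )

    @property
    def random_sds(self) -> dict[str, float]:
        return {k: float(np.sqrt(v)) for k, v in self.random_variances.items()}

    @property
    def n_groups(self) -> dict[str, int]:
        return {f.name: f.n_levels for f in self.model.design.factors}

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimates": {
                name: {
                    "est": float(self.params[name]),
                    "se": float(self.bse[name]),
                    "z": float(self.zvalues[name]),
                    "p": float(self.pvalues[name]),
                }
                for name in self.params.index
            },
            "random_effects": {
                name: {"variance": v, "sd": float(np.sqrt(v))}
                for name, v in self.random_variances.items()
            },
            "n_groups": self.n_groups,
            "loglik": float(self.loglik),
            "k": self.k_params,
            "n_obs": self.nobs,
            "aic": float(self.aic),
            "bic": float(self.bic),
            "converged": bool(self.converged),
        }

    def summary(self) -> str:
        lines = [
            "Poisson count model" + (" (Laplace GLMM)" if self.random_variances else " (GLM)"),
            "=" * 58,
            f"{'term':<16}{'Est':>10}{'SE':>10}{'z':>9}{'p':>11}",
            "-" * 58,
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<16}{self.params[name]:>10.3f}{self.bse[name]:>10.3f}"
                f"{self.zvalues[name]:>9.2f}{self.pvalues[name]:>11.3g}"
            )
        if self.random_variances:
            lines.append("-" * 58)
            lines.append(f"{'random intercept':<22}{'Variance':>12}{'SD':>12}")
            for name, v in self.random_variances.items():
                ng = self.n_groups.get(name, 0)
                lines.append(
                    f"{name + f' ({ng})':<22}{v:>12.4f}{np.sqrt(v):>12.4f}"
                )
            if all(v == 0.0 for v in self.random_variances.values()):
                lines.append("All random intercepts were equal to zero.")
        lines.append("-" * 58)
        lines.append(
            f"Observations {self.nobs}   Log likelihood {self.loglik:,.3f}"
        )
        lines.append(f"AIC {self.aic:,.3f}   BIC {self.bic:,.3f}   k {self.k_params}")
        if not self.converged:
            lines.append("WARNING: optimizer did not report convergence")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model comparison


@dataclasses.dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test between two nested fits."""

    chisq: float
    df: int
    p: float


def _is_nested(null: PoissonCountResults, full: PoissonCountResults) -> bool:
    if null.nobs != full.nobs:
        return False
    if not set(null.params.index) <= set(full.params.index):
        return False
    return set(null.random_variances) == set(full.random_variances)


def lrt_compare(null: PoissonCountResults, full: PoissonCountResults) -> LRTResult:
    """Compare nested fits on the same data by likelihood ratio.

    ``chisq = 2 (loglik_full − loglik_null)``, df is the difference in
    parameter count, p is the upper-tail chi-square probability.
    """
    if not _is_nested(null, full):
        raise ValueError("models are not nested on the same data")
    chisq = 2.0 * (full.loglik - null.loglik)
    if -1e-6 < chisq < 0:  # optimizer tolerance on identical fits
        chisq = 0.0
    df = full.k_params - null.k_params
    if df <= 0:
        raise ValueError("full model has no extra parameters")
    return LRTResult(chisq=float(chisq), df=int(df), p=float(stats.chi2.sf(chisq, df)))


def likelihood_ratio(loglik_null: float, loglik_full: float, df: int) -> LRTResult:
    """LRT from raw log-likelihoods (e.g. published table values)."""
    chisq = 2.0 * (loglik_full - loglik_null)
    return LRTResult(chisq=float(chisq), df=int(df), p=float(stats.chi2.sf(chisq, df)))


def format_table(
    null: PoissonCountResults, full: PoissonCountResults, title: str = ""
) -> str:
    """Two-column report table: null model vs sides-of-screen model."""
    if null.nobs != full.nobs:
        raise ValueError("fits are not on the same data")
    w = 14

    def cell(res, name):
        if name in res.params.index:
            return f"{res.params[name]:.3f} ({res.pvalues[name]:.3g})"
        return ""

    lines = []
    if title:
        lines.append(title)
    lines.append(f"{'':<22}{'null model':>{w + 8}}{'sides of screen':>{w + 8}}")
    lines.append(f"{'':<22}{'(1)':>{w + 8}}{'(2)':>{w + 8}}")
    for name in ("region[left]", "region[right]"):
        lines.append(
            f"{name:<22}{cell(null, name):>{w + 8}}{cell(full, name):>{w + 8}}"
        )
    lines.append(
        f"{'Constant':<22}{cell(null, 'intercept'):>{w + 8}}{cell(full, 'intercept'):>{w + 8}}"
    )
    lines.append("Random effects" + f"{'Variance':>{w + 8}}{'SD':>{w + 8}}".rjust(52))
    for name, v in full.random_variances.items():
        ng = full.n_groups.get(name, 0)
        lines.append(
            f"{name.capitalize() + f' ({ng})':<22}{v:>{w + 8}.4f}{np.sqrt(v):>{w + 8}.4f}"
        )
    if full.random_variances and all(
        v == 0.0 for v in full.random_variances.values()
    ):
        lines.append("All random intercepts were equal to zero.")
    lines.append(f"{'Observations':<22}{null.nobs:>{w + 8},}{full.nobs:>{w + 8},}")
    lines.append(
        f"{'Log likelihood':<22}{null.loglik:>{w + 8},.3f}{full.loglik:>{w + 8},.3f}"
    )
    lines.append(f"{'Akaike inf. crit.':<22}{null.aic:>{w + 8},.3f}{full.aic:>{w + 8},.3f}")
    lines.append(
        f"{'Bayesian inf. crit.':<22}{null.bic:>{w + 8},.3f}{full.bic:>{w + 8},.3f}"
    )
    lines.append("Note: p value in brackets.")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers over the model objects


def fit_poisson_glm(counts: pd.DataFrame, region_effect: bool = True) -> PoissonCountResults:
    """Plain Poisson GLM (no random intercepts) on a count table."""
    return PoissonCountModel(counts, region_effect, random_factors=()).fit()


def fit_poisson_glmm(
    counts: pd.DataFrame,
    region_effect: bool = True,
    random_factors: tuple[str, ...] = ("participant", "article", "page"),
    page_within_article: bool = True,
) -> PoissonCountResults:
    """Laplace-approximate Poisson GLMM with crossed random intercepts."""
    return PoissonCountModel(
        counts, region_effect, random_factors, page_within_article
    ).fit()
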