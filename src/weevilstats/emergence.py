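"""Negative-binomial emergence modelling with control-versus-treatment contrasts.

Per-stump season totals of emerging adult weevils are overdispersed counts;
the model is NB2 (variance mu + mu^2/theta) with a log link, treatment as a
fixed factor coded against the control, and the replicate block entering
either as fixed indicator coefficients (default: exact maximum likelihood,
fully deterministic) or as a Gaussian random intercept integrated out by a
Laplace approximation (mirroring the GLMM formulation). The treatment
effect is tested by a likelihood-ratio test against the no-treatment model;
effects are reported as relative emergence ratios (treatment/control on the
response scale) with Dunnett-style many-to-one adjusted p-values computed
by Monte-Carlo integration of the maximum-|Z| null distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

from .vocab import TREATMENTS


class ConvergenceError(RuntimeError):
    """The likelihood optimizer failed to converge."""


@dataclass(frozen=True)
class ContrastResult:
    """One treatment-vs-control contrast on the response scale."""

    contrast: str
    ratio: float
    se: float
    z: float
    p_unadjusted: float
    p_adjusted: float


def _ordered_levels(values, preferred) -> list:
    present = list(dict.fromkeys(values))
    ordered = [lv for lv in preferred if lv in present]
    ordered += [lv for lv in sorted(present) if lv not in ordered]
    return ordered


class EmergenceModel:
    """Negative-binomial model of per-stump emergence counts.

    Parameters
    ----------
    data : DataFrame with columns ``block``, ``treatment``, ``emerged``.
    include_treatment : drop the treatment factor to obtain the null model
        for the likelihood-ratio test.
    block_mode : ``"fixed"`` (indicator coefficients, default),
        ``"random"`` (Gaussian intercept, Laplace approximation) or
        ``"none"`` (intercept only).
    control : reference treatment level.
    theta : fix the NB2 dispersion at this value instead of estimating it
        (large values recover a Poisson log-linear model).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        include_treatment: bool = True,
        block_mode: str = "fixed",
        control: str = "control",
        theta: float | None = None,
    ):
        for col in ("block", "treatment", "emerged"):
            if col not in data.columns:
                raise KeyError(f"data lacks column {col!r}")
        if (data["emerged"] < 0).any():
            raise ValueError("emergence counts must be non-negative")
        if block_mode not in ("fixed", "random", "none"):
            raise ValueError(f"unknown block_mode {block_mode!r}")
        self.data = data.reset_index(drop=True)
        self.include_treatment = include_treatment
        self.block_mode = block_mode
        self.control = control
        self.theta = theta
        self.treatment_levels = _ordered_levels(self.data["treatment"], (control,) + tuple(TREATMENTS))
        if include_treatment:
            if control not in self.treatment_levels:
                raise ValueError(f"control level {control!r} absent from data")
            if len(self.treatment_levels) < 2:
                raise ValueError("need >= 2 treatments when include_treatment")
            self.treatment_levels = [control] + [t for t in self.treatment_levels if t != control]
        self.block_levels = sorted(self.data["block"].unique())
        if block_mode != "none" and len(self.block_levels) < 2:
            raise ValueError("need >= 2 blocks")
        zero_groups = [
            t for t, g in self.data.groupby("treatment")["emerged"] if (g == 0).all()
        ]
        if zero_groups and include_treatment:
            warnings.warn(
                f"treatment group(s) {zero_groups} have all-zero counts; the fit "
                "proceeds but their coefficients may diverge (infinite-SE flags)",
                stacklevel=2,
            )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "EmergenceModel":
        return cls(data, **kwargs)

    # -- design ----------------------------------------------------------

    def _design(self) -> pd.DataFrame:
        n = len(self.data)
        cols = {"Intercept": np.ones(n)}
        if self.block_mode == "fixed":
            for b in self.block_levels[1:]:
                cols[f"block[{b}]"] = (self.data["block"] == b).to_numpy(float)
        if self.include_treatment:
            for t in self.treatment_levels[1:]:
                cols[f"treatment[{t}]"] = (self.data["treatment"] == t).to_numpy(float)
        return pd.DataFrame(cols, index=self.data.index)

    def _treatment_names(self) -> list[str]:
        return [f"treatment[{t}]" for t in self.treatment_levels[1:]] if self.include_treatment else []

    # -- fitting ---------------------------------------------------------

    def fit(self, maxiter: int = 200, start_params=None) -> "EmergenceResults":
        if self.block_mode == "random":
            return self._fit_laplace(maxiter=maxiter)
        y = self.data["emerged"].to_numpy(float)
        x = self._design()
        if self.theta is not None:
            glm = sm.GLM(y, x, family=sm.families.NegativeBinomial(alpha=1.0 / self.theta))
            res = glm.fit(maxiter=maxiter)
            params = res.params
            vcov = res.cov_params()
            theta = float(self.theta)
            llf = float(res.llf)
            converged = bool(res.converged)
            k = x.shape[1]
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if start_params is None:
                    poisson = sm.GLM(y, x, family=sm.families.Poisson()).fit()
                    start_params = np.r_[poisson.params.to_numpy(), 0.2]
                nb = sm.NegativeBinomial(y, x, loglike_method="nb2")

                def _ok(r):
                    # the optimizer's flag is pessimistic near the alpha -> 0
                    # boundary; a vanished score is convergence
                    if not np.isfinite(np.asarray(r.params)).all():
                        return False
                    if r.mle_retvals.get("converged", True):
                        return True
                    gopt = r.mle_retvals.get("gopt")
                    return gopt is not None and np.max(np.abs(gopt)) < 1e-4

                res = nb.fit(start_params=start_params, method="bfgs",
                             maxiter=maxiter, gtol=1e-8, disp=0)
                if not _ok(res):
                    # hard instances: simplex from the original start, then a
                    # gradient polish
                    nm = nb.fit(start_params=start_params, method="nm",
                                maxiter=50 * maxiter, disp=0)
                    res = nb.fit(start_params=np.asarray(nm.params), method="bfgs",
                                 maxiter=maxiter, gtol=1e-8, disp=0)
                    if not (_ok(res) or nm.mle_retvals.get("converged", False)
                            or np.asarray(nm.params)[-1] <= 1e-6):
                        raise ConvergenceError(
                            f"NB2 fit failed to converge: {res.mle_retvals}"
                        )
            converged = True
            params = np.asarray(res.params)[:-1]
            alpha = float(np.asarray(res.params)[-1])
            theta = 1.0 / max(alpha, 1e-12)
            try:
                cov = np.asarray(res.cov_params())
            except ValueError:
                # no optimizer Hessian available (simplex path): numeric one
                h = numdiff.approx_hess1(np.asarray(res.params), nb.loglike)
                cov = np.linalg.pinv(-h)
            vcov = pd.DataFrame(cov)
            vcov = vcov.iloc[:-1, :-1]
            vcov.index = vcov.columns = x.columns
            llf = float(res.llf)
            k = x.shape[1] + 1
        params = pd.Series(np.asarray(params, dtype=float), index=x.columns)
        vcov = pd.DataFrame(np.asarray(vcov, dtype=float), index=x.columns, columns=x.columns)
        return EmergenceResults(
            model=self, params=params, theta=theta, llf=llf, vcov=vcov,
            converged=converged, k_params=k, sigma_block=None,
        )

    # -- Laplace-approximated random-intercept fit -----------------------

    def _block_data(self):
        x = self._design()
        out = []
        for b in self.block_levels:
            idx = self.data.index[self.data["block"] == b]
            out.append((self.data.loc[idx, "emerged"].to_numpy(float), x.loc[idx].to_numpy(float)))
        return out, list(x.columns)

    @staticmethod
    def _block_laplace_ll(y, eta0, theta, sigma2) -> float:
        # Newton in the scalar random intercept b, then Laplace.
        b = 0.0
        for _ in range(50):
            mu = np.exp(eta0 + b)
            g1 = np.sum(y - (y + theta) * mu / (mu + theta)) - b / sigma2
            g2 = -np.sum((y + theta) * theta * mu / (mu + theta) ** 2) - 1.0 / sigma2
            step = g1 / g2
            b -= step
            if abs(step) < 1e-10:
                break
        mu = np.exp(eta0 + b)
        ll = np.sum(
            special.gammaln(y + theta) - special.gammaln(theta) - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
        ll += -0.5 * b * b / sigma2 - 0.5 * np.log(2 * np.pi * sigma2)
        g2 = -np.sum((y + theta) * theta * mu / (mu + theta) ** 2) - 1.0 / sigma2
        return ll + 0.5 * np.log(2 * np.pi) - 0.5 * np.log(-g2)

    def _fit_laplace(self, maxiter: int = 200) -> "EmergenceResults":
        blocks, colnames = self._block_data()
        p = len(colnames)

        def nll(par):
            beta, log_theta, log_sigma = par[:p], par[p], par[p + 1]
            theta = np.exp(log_theta)
            sigma2 = np.exp(2 * log_sigma)
            total = 0.0
            for y, xb in blocks:
                eta0 = xb @ beta
                total += self._block_laplace_ll(y, eta0, theta, sigma2)
            return -total

        pooled = EmergenceModel(
            self.data, include_treatment=self.include_treatment,
            block_mode="none", control=self.control,
        ).fit()
        start = np.r_[pooled.params.to_numpy(), np.log(pooled.theta), np.log(0.3)]
        opt = optimize.minimize(
            nll, start, method="L-BFGS-B",
            bounds=[(None, None)] * p + [(np.log(1e-3), np.log(1e6)), (np.log(1e-4), np.log(10.0))],
            options={"maxiter": maxiter},
        )
        if not opt.success:
            raise ConvergenceError(f"Laplace NB fit failed: {opt.message}")
        beta = pd.Series(opt.x[:p], index=colnames)
        theta = float(np.exp(opt.x[p]))
        sigma = float(np.exp(opt.x[p + 1]))
        hess = numdiff.approx_hess1(opt.x, nll)
        try:
            vcov_all = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            vcov_all = np.linalg.pinv(hess)
        vcov = pd.DataFrame(vcov_all[:p, :p], index=colnames, columns=colnames)
        return EmergenceResults(
            model=self, params=beta, theta=theta, llf=float(-opt.fun), vcov=vcov,
            converged=True, k_params=p + 2, sigma_block=sigma,
        )


@dataclass
class EmergenceResults:
    """Fitted emergence model: coefficients, dispersion, covariance.

    ``llf`` values are comparable across nested fits sharing a
    ``block_mode``; ``k_params`` counts every estimated parameter
    (dispersion and random-effect SD included).
    """

    model: EmergenceModel
    params: pd.Series
    theta: float
    llf: float
    vcov: pd.DataFrame
    converged: bool
    k_params: int
    sigma_block: float | None = None

    @property
    def block_mode(self) -> str:
        return self.model.block_mode

    def treatment_ratios(self) -> pd.Series:
        """Relative emergence ratio exp(beta_t) per non-control treatment."""
        names = self.model._treatment_names()
        return np.exp(self.params[names]).rename(lambda s: s[len("treatment["):-1])

    # -- estimated marginal means ----------------------------------------

    def marginal_means(self) -> pd.DataFrame:
        """Response-scale predicted mean per treatment with delta-method SE.

        With fixed block effects the prediction averages over the observed
        blocks; with a random intercept it is evaluated at a block effect
        of 0 (the median block, not the mean of the response distribution).
        """
        model = self.model
        names = list(self.params.index)
        v = self.vcov.to_numpy()
        levels = model.treatment_levels if model.include_treatment else ["(all)"]
        rows = []
        for t in levels:
            etas, grads = [], []
            block_cols = (
                [None] if model.block_mode != "fixed" else [None] + model.block_levels[1:]
            )
            for b in block_cols:
                x = np.zeros(len(names))
                x[names.index("Intercept")] = 1.0
                if b is not None:
                    x[names.index(f"block[{b}]")] = 1.0
                if model.include_treatment and t != model.treatment_levels[0]:
                    x[names.index(f"treatment[{t}]")] = 1.0
                etas.append(float(x @ self.params.to_numpy()))
                grads.append(x)
            mus = np.exp(etas)
            mu = float(mus.mean())
            grad = np.average(np.asarray(grads) * mus[:, None], axis=0)
            se = float(np.sqrt(grad @ v @ grad))
            rows.append({"treatment": t, "mean": mu, "se": se})
        return pd.DataFrame(rows).set_index("treatment")

    # -- Dunnett many-to-one contrasts -----------------------------------

    def dunnett_contrasts(self, n_mc: int = 100_000, seed: int | None = 0) -> list[ContrastResult]:
        """Each treatment vs control, Dunnett-adjusted by Monte Carlo.

        The adjusted p-value is the probability that the maximum absolute
        component of a zero-mean multivariate normal with the contrasts'
        estimated correlation matrix exceeds the observed |z|, estimated
        from ``n_mc`` draws with a fixed seed; it is floored at the
        unadjusted p so adjustment never appears anti-conservative.
        """
        names = self.model._treatment_names()
        if not names:
            raise ValueError("model has no treatment contrasts")
        beta = self.params[names].to_numpy()
        v = self.vcov.loc[names, names].to_numpy()
        se = np.sqrt(np.diag(v))
        if not np.isfinite(se).all() or (se == 0).any():
            raise ValueError("degenerate contrast covariance")
        z = beta / se
        corr = v / np.outer(se, se)
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular contrast correlation matrix") from exc
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((n_mc, len(names))) @ chol.T
        maxabs = np.abs(draws).max(axis=1)
        out = []
        for j, name in enumerate(names):
            p_un = float(2 * stats.norm.sf(abs(z[j])))
            p_adj = float((maxabs >= abs(z[j])).mean())
            p_adj = min(1.0, max(p_adj, p_un))
            label = name[len("treatment["):-1]
            out.append(
                ContrastResult(
                    contrast=f"{label} vs {self.model.treatment_levels[0]}",
                    ratio=float(np.exp(beta[j])),
                    se=float(np.exp(beta[j]) * se[j]),
                    z=float(z[j]),
                    p_unadjusted=p_un,
                    p_adjusted=p_adj,
                )
            )
        return out

    def summary(self) -> str:
        from .report import format_p

        lines = [
            f"Negative-binomial emergence model (block_mode = {self.block_mode})",
            f"  n = {len(self.model.data)}, loglik = {self.llf:.3f}, theta = {self.theta:.3f}"
            + (f", block SD = {self.sigma_block:.3f}" if self.sigma_block is not None else ""),
        ]
        if self.model.include_treatment:
            lines.append("  Relative emergence ratios (vs control):")
            for c in self.dunnett_contrasts():
                lines.append(
                    f"    {c.contrast}: ratio = {c.ratio:.3f} (SE {c.se:.3f}), "
                    f"adj. p = {format_p(c.p_adjusted)}"
                )
        return "\n".join(lines)


def fit_nb(
    data: pd.DataFrame,
    include_treatment: bool = True,
    block_mode: str = "fixed",
    **kwargs,
) -> EmergenceResults:
    """One-call NB2 fit (see :class:`EmergenceModel`)."""
    return EmergenceModel(
        data, include_treatment=include_treatment, block_mode=block_mode, **kwargs
    ).fit()


def lrt_treatment(full: EmergenceResults, null: EmergenceResults) -> tuple[float, int, float]:
    """Likelihood-ratio test of the treatment factor.

    ``null`` must be the same data and block handling without the treatment
    factor. Returns (chi2, df, p).
    """
    if full.block_mode != null.block_mode:
        raise ValueError("fits use different block modes; log-likelihoods not comparable")
    if len(full.model.data) != len(null.model.data):
        raise ValueError("fits use different data")
    chi2 = 2.0 * (full.llf - null.llf)
    if chi2 < -1e-6:
        raise ConvergenceError(
            f"negative LRT statistic ({chi2:.3g}); refit with better starting values"
        )
    chi2 = max(chi2, 0.0)
    df = full.k_params - null.k_params
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p


def marginal_means(fit: EmergenceResults) -> pd.DataFrame:
    """Functional alias for :meth:`EmergenceResults.marginal_means`."""
    return fit.marginal_means()


def dunnett_contrasts(
    fit: EmergenceResults, control: str = "control", n_mc: int = 100_000, seed: int | None = 0
) -> list[ContrastResult]:
    """Functional alias for :meth:`EmergenceResults.dunnett_contrasts`."""
    if fit.model.treatment_levels[0] != control:
        raise ValueError(f"fit was coded against {fit.model.treatment_levels[0]!r}")
    return fit.dunnett_contrasts(n_mc=n_mc, seed=seed)
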