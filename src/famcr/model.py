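"""Model / Results interface for fitting the family-unit model.

``FamilyUnitModel`` wraps a :class:`~famcr.data.Dataset` together with a
:class:`~famcr.params.ConstraintMap`; ``fit`` maximises the forward-
algorithm likelihood over the unconstrained (logit) parameterisation
with a multi-start quasi-Newton search, and ``fit_mcmc`` samples the
posterior under uniform priors with an affine-invariant ensemble
sampler. Both return a :class:`FamilyUnitResults` carrying estimates,
uncertainties and a summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import CompiledData, Dataset
from .derived import (LitterSurvival, ThreeYearOutcome, litter_survival,
                      three_year_outcomes)
from .likelihood import DEFAULT_NONCAPTURE_DATE, compiled_loglik
from .params import (ConstraintMap, ParameterSet, default_parameters,
                     expit, inverse_transform, transform_parameters)

_PI_LABELS = tuple(f"pi{i}" for i in range(1, 12))


class FamilyUnitModel:
    """Hidden-Markov multievent model for family-unit encounter histories.

    Parameters
    ----------
    data : Dataset
        Encounter histories (first record of each family is a capture).
    constraints : ConstraintMap, optional
        Sharing/fixing structure; default leaves every scalar free.
    template : ParameterSet, optional
        Supplies fixed values, the departure model and (when it is not
        estimated) the initial mixture. Defaults to mid-range values
        with a constant departure rate of 0.5.
    noncapture_date : float
        Expected capture date used for nonobservation emission columns
        when detection is class-specific.
    """

    def __init__(self, data: Dataset, constraints: ConstraintMap | None = None,
                 template: ParameterSet | None = None,
                 noncapture_date: float = DEFAULT_NONCAPTURE_DATE):
        self.data = data
        self.constraints = constraints if constraints is not None else ConstraintMap()
        self.template = template if template is not None else default_parameters()
        self.noncapture_date = noncapture_date
        self._cd = CompiledData(data)
        self.free_names: list[str] = list(self.constraints.group_labels())
        if self.constraints.pi_free:
            self.free_names += [f"logit_{n}" for n in _PI_LABELS[:10]]
        self.n_free = len(self.free_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, T: int | None = None,
                       **kwargs) -> "FamilyUnitModel":
        """Build the model from a long-format encounter-history table."""
        return cls(Dataset.from_frame(df, T=T), **kwargs)

    # -- likelihood ------------------------------------------------------

    def params_from_free(self, x: np.ndarray) -> ParameterSet:
        return inverse_transform(x, self.constraints, self.template)

    def free_from_params(self, params: ParameterSet) -> np.ndarray:
        return transform_parameters(params, self.constraints)

    def loglike(self, x: np.ndarray) -> float:
        """Dataset log-likelihood at a free (transformed-scale) vector."""
        return compiled_loglik(self._cd, self.params_from_free(x),
                               self.noncapture_date)[0]

    def loglike_params(self, params: ParameterSet) -> float:
        """Dataset log-likelihood at a full ParameterSet."""
        return compiled_loglik(self._cd, params, self.noncapture_date)[0]

    def _nll(self, x: np.ndarray) -> float:
        ll = self.loglike(x)
        return 1e12 if not np.isfinite(ll) else -ll

    # -- maximum likelihood ----------------------------------------------

    def fit(self, starts: int = 5, start_params: ParameterSet | None = None,
            seed: int = 0, maxiter: int = 1000, compute_se: bool = True
            ) -> "FamilyUnitResults":
        """Maximum-likelihood fit with multi-start L-BFGS-B.

        The first start is the template (or ``start_params``); the rest
        are overdispersed draws on the transformed scale. Ties between
        starts break by highest log-likelihood then smallest gradient
        norm. Standard errors come from the inverse observed information
        mapped to the probability scale by the delta method.
        """
        rng = np.random.default_rng(seed)
        x0_list = []
        base = self.free_from_params(start_params) if start_params is not None \
            else np.zeros(self.n_free)
        x0_list.append(base)
        for _ in range(max(0, starts - 1)):
            x0_list.append(base + rng.normal(0.0, 1.25, self.n_free))
        best = None
        trace = []
        for x0 in x0_list:
            res = minimize(self._nll, x0, method="L-BFGS-B",
                           options={"maxiter": maxiter, "ftol": 1e-11,
                                    "gtol": 1e-6, "maxfun": 200000})
            gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
            trace.append((-res.fun, gnorm, bool(res.success)))
            if best is None or (-res.fun, -gnorm) > (-best.fun, -best_gnorm):
                best, best_gnorm = res, gnorm
        llf = -best.fun
        converged = bool(best.success) and np.isfinite(llf)
        x = best.x
        cov_x = None
        if compute_se:
            cov_x = self._covariance(x)
        return FamilyUnitResults(model=self, x=x, llf=llf,
                                 converged=converged, backend="mle",
                                 cov_x=cov_x, start_trace=trace)

    def _covariance(self, x: np.ndarray) -> np.ndarray | None:
        from statsmodels.tools.numdiff import approx_hess

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            H = approx_hess(x, self._nll)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        d = np.diag(cov)
        if np.any(d < 0):
            # boundary / weakly identified directions: salvage what we can
            cov = np.where(np.isfinite(cov), cov, np.nan)
        return cov

    # -- MCMC -------------------------------------------------------------

    def log_posterior(self, x: np.ndarray, ordering: bool = False) -> float:
        """Log posterior on the transformed scale under uniform priors.

        Uniform(0,1) on every free probability (logit Jacobian) and a
        flat Dirichlet on the initial mixture. ``ordering`` truncates the
        prior to cub survival below yearling survival (s1<s3, s2<s4), the
        biologically motivated constraint used for sparse data.
        """
        params = self.params_from_free(x)
        if ordering and (params.s[0] >= params.s[2] or params.s[1] >= params.s[3]):
            return -np.inf
        ll = compiled_loglik(self._cd, params, self.noncapture_date)[0]
        if not np.isfinite(ll):
            return -np.inf
        n_scalar = len(self.constraints.free_groups())
        th = expit(x[:n_scalar])
        logjac = float(np.sum(np.log(th) + np.log1p(-th)))
        if self.constraints.pi_free:
            logjac += float(np.sum(np.log(np.clip(params.pi, 1e-300, None))))
        return ll + logjac

    def fit_mcmc(self, draws: int = 1500, burn: int = 1000,
                 walkers: int | None = None, seed: int = 0,
                 ordering: bool = False,
                 start_params: ParameterSet | None = None,
                 thin: int = 5) -> "FamilyUnitResults":
        """Posterior sampling with the emcee ensemble sampler.

        Walkers start in a tight ball around the template (or
        ``start_params``, typically an MLE); convergence is flagged by
        split-R-hat < 1.05 over the retained draws.
        """
        import emcee

        nw = walkers if walkers is not None else max(2 * self.n_free + 2, 32)
        rng = np.random.default_rng(seed)
        base = self.free_from_params(start_params) if start_params is not None \
            else np.zeros(self.n_free)
        p0 = base + rng.normal(0.0, 0.05, (nw, self.n_free))
        if ordering:
            # nudge starts into the truncated region
            for i in range(nw):
                par = self.params_from_free(p0[i])
                if par.s[0] >= par.s[2] or par.s[1] >= par.s[3]:
                    p0[i, :] = base
        sampler = emcee.EnsembleSampler(
            nw, self.n_free, self.log_posterior, kwargs={"ordering": ordering})
        sampler.random_state = np.random.RandomState(seed).get_state()
        sampler.run_mcmc(p0, burn + draws, progress=False)
        chain = sampler.get_chain(discard=burn, thin=thin)  # (n, nw, k)
        rhat = _split_rhat(chain)
        flat = chain.reshape(-1, self.n_free)
        x_mean = flat.mean(axis=0)
        res = FamilyUnitResults(model=self, x=x_mean,
                                llf=self.loglike(x_mean),
                                converged=bool(np.nanmax(rhat) < 1.05),
                                backend="mcmc", cov_x=np.cov(flat.T),
                                posterior=flat, rhat=rhat)
        return res


def _split_rhat(chain: np.ndarray) -> np.ndarray:
    """Split-R-hat per parameter from an (n, chains, k) sample array."""
    import arviz as az

    n = chain.shape[0] - chain.shape[0] % 2
    c = chain[:n]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = az.rhat(az.convert_to_dataset(np.moveaxis(c, 1, 0)))
    return np.asarray(r["x"]) if "x" in r else np.asarray(
        r.to_array()).ravel()


@dataclass
class FamilyUnitResults:
    """Estimates, uncertainty and diagnostics from a model fit."""

    model: FamilyUnitModel
    x: np.ndarray
    llf: float
    converged: bool
    backend: str
    cov_x: np.ndarray | None = None
    posterior: np.ndarray | None = None
    rhat: np.ndarray | None = None
    start_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.params: ParameterSet = self.model.params_from_free(self.x)
        self.n_free: int = self.model.n_free
        self.nobs: int = len(self.model.data)

    # -- labelled estimates ----------------------------------------------

    def _labels(self) -> list[str]:
        labels = list(self.model.constraints.group_labels())
        if self.model.constraints.pi_free:
            labels += list(_PI_LABELS)
        return labels

    def _theta_of_x(self, x: np.ndarray) -> np.ndarray:
        """Probability-scale estimate vector for the labels."""
        n_scalar = len(self.model.constraints.free_groups())
        params = self.model.params_from_free(x)
        th = list(expit(x[:n_scalar]))
        if self.model.constraints.pi_free:
            th += list(params.pi)
        return np.asarray(th)

    @property
    def estimates(self) -> dict[str, float]:
        if self.backend == "mcmc" and self.posterior is not None:
            th = np.array([self._theta_of_x(xx) for xx in self.posterior])
            return dict(zip(self._labels(), th.mean(axis=0)))
        return dict(zip(self._labels(), self._theta_of_x(self.x)))

    @property
    def bse(self) -> dict[str, float]:
        """Standard errors on the probability scale (delta method)."""
        if self.backend == "mcmc" and self.posterior is not None:
            th = np.array([self._theta_of_x(xx) for xx in self.posterior])
            return dict(zip(self._labels(), th.std(axis=0, ddof=1)))
        if self.cov_x is None:
            return {k: np.nan for k in self._labels()}
        J = self._jacobian()
        var = np.einsum("ij,jk,ik->i", J, self.cov_x, J)
        return dict(zip(self._labels(), np.sqrt(np.clip(var, 0.0, None))))

    def _jacobian(self, eps: float = 1e-6) -> np.ndarray:
        k = self.x.shape[0]
        f0 = self._theta_of_x(self.x)
        J = np.empty((f0.shape[0], k))
        for j in range(k):
            xp, xm = self.x.copy(), self.x.copy()
            xp[j] += eps
            xm[j] -= eps
            J[:, j] = (self._theta_of_x(xp) - self._theta_of_x(xm)) / (2 * eps)
        return J

    @property
    def conf_int(self) -> dict[str, tuple[float, float]]:
        """95% intervals: logit-scale Wald for scalars (MLE) or posterior
        2.5/97.5 percentiles (MCMC); always inside [0, 1]."""
        labels = self._labels()
        if self.backend == "mcmc" and self.posterior is not None:
            th = np.array([self._theta_of_x(xx) for xx in self.posterior])
            lo = np.percentile(th, 2.5, axis=0)
            hi = np.percentile(th, 97.5, axis=0)
            return {k: (float(a), float(b)) for k, a, b in zip(labels, lo, hi)}
        out: dict[str, tuple[float, float]] = {}
        n_scalar = len(self.model.constraints.free_groups())
        sd_x = np.sqrt(np.clip(np.diag(self.cov_x), 0.0, None)) \
            if self.cov_x is not None else np.full(self.n_free, np.nan)
        theta = self._theta_of_x(self.x)
        bse = self.bse
        for i, k in enumerate(labels):
            if i < n_scalar:
                lo = float(expit(self.x[i] - 1.96 * sd_x[i]))
                hi = float(expit(self.x[i] + 1.96 * sd_x[i]))
            else:  # pi components: normal on probability scale, clipped
                se = bse[k]
                lo = float(np.clip(theta[i] - 1.96 * se, 0.0, 1.0))
                hi = float(np.clip(theta[i] + 1.96 * se, 0.0, 1.0))
            out[k] = (lo, hi)
        return out

    # -- presentation -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        est, se, ci = self.estimates, self.bse, self.conf_int
        rows = [(k, est[k], se[k], ci[k][0], ci[k][1]) for k in est]
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se",
                                           "lo95", "hi95"])

    def summary(self) -> str:
        df = self.to_frame()
        head = (f"Family-unit multievent model ({self.backend.upper()})\n"
                f"families: {self.nobs}   occasions: {self.model.data.T}   "
                f"free parameters: {self.n_free}\n"
                f"log-likelihood: {self.llf:.3f}   converged: {self.converged}\n")
        if self.backend == "mcmc" and self.rhat is not None:
            head += f"max split-R-hat: {float(np.nanmax(self.rhat)):.3f}\n"
        with pd.option_context("display.float_format", "{:0.4f}".format):
            return head + df.to_string(index=False)

    # -- derived quantities ----------------------------------------------

    def litter_survival(self) -> LitterSurvival:
        return litter_survival(self.params)

    def three_year_outcomes(self) -> ThreeYearOutcome:
        """Plug-in 3-year reproductive outcome probabilities."""
        return three_year_outcomes(self.params)

    def three_year_outcomes_posterior(self) -> pd.DataFrame | None:
        """Posterior-propagated outcome probabilities (MCMC backend).

        Applies the closed forms to every retained draw; the posterior
        mean of a nonlinear function differs from its plug-in value.
        """
        if self.posterior is None:
            return None
        vals = []
        for xx in self.posterior:
            o = three_year_outcomes(self.model.params_from_free(xx))
            vals.append((o.pr0, o.pr1, o.pr2))
        arr = np.asarray(vals)
        return pd.DataFrame({
            "outcome": ["pr0", "pr1", "pr2"],
            "mean": arr.mean(axis=0),
            "lo95": np.percentile(arr, 2.5, axis=0),
            "hi95": np.percentile(arr, 97.5, axis=0),
        })
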