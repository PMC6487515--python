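"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by re-sampling every model input:
transition-matrix rows from Dirichlet distributions whose concentrations are
the observed transition counts (plus a unit prior, so sparse rows carry more
uncertainty), and state utilities / healthcare costs / sick days from
parametric families (normal, gamma, logistic, beta, Poisson) fitted to the
patient-level samples by maximum likelihood and selected by the
Anderson-Darling statistic (with chi-squared and skewness/kurtosis
diagnostics recorded).

:func:`run_psa` performs the two-level simulation: ``n_outer`` parameter
draws, each evaluated for *both* strategies on the same realisation with
``n_inner`` simulated patients per strategy, yielding a paired incremental
sample cloud, percentile intervals and the ICER of the pooled means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .economics import CEComparison, icer
from .engine import ModelConfig, simulate_cohort
from .estimation import TransitionModel, dirichlet_params
from .states import N_STATES, HealthState, StrategySpec
from .valuation import MissingParameterError, StateValues, Tariff

DEFAULT_CANDIDATES = ("normal", "gamma", "logistic", "beta", "poisson")


@dataclass(frozen=True)
class DistributionFit:
    """A fitted parametric family with goodness-of-fit diagnostics."""

    family: str
    params: dict
    ad_stat: float = np.nan
    chi2_stat: float = np.nan
    chi2_pvalue: float = np.nan
    skewness: float = np.nan
    kurtosis: float = np.nan
    n: int = 0
    flagged: bool = False
    note: str = ""

    def mean(self) -> float:
        p = self.params
        if self.family == "normal":
            return p["loc"]
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        if self.family == "logistic":
            return p["loc"]
        if self.family == "beta":
            return p["a"] / (p["a"] + p["b"])
        if self.family == "poisson":
            return p["mu"]
        if self.family == "point_mass":
            return p["value"]
        raise ValueError(f"unknown family {self.family!r}")

    def rvs(self, rng: np.random.Generator, size=None):
        p = self.params
        if self.family == "normal":
            return rng.normal(p["loc"], p["scale"], size)
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], size)
        if self.family == "logistic":
            return rng.logistic(p["loc"], p["scale"], size)
        if self.family == "beta":
            return rng.beta(p["a"], p["b"], size)
        if self.family == "poisson":
            draw = rng.poisson(p["mu"], size)
            return float(draw) if size is None else draw.astype(float)
        if self.family == "point_mass":
            if size is None:
                return p["value"]
            return np.full(size, p["value"])
        raise ValueError(f"unknown family {self.family!r}")

    def cdf(self, x):
        p = self.params
        if self.family == "normal":
            return stats.norm.cdf(x, p["loc"], p["scale"])
        if self.family == "gamma":
            return stats.gamma.cdf(x, p["shape"], scale=p["scale"])
        if self.family == "logistic":
            return stats.logistic.cdf(x, p["loc"], p["scale"])
        if self.family == "beta":
            return stats.beta.cdf(x, p["a"], p["b"])
        if self.family == "poisson":
            return stats.poisson.cdf(x, p["mu"])
        raise ValueError(f"no cdf for family {self.family!r}")

    def to_dict(self) -> dict:
        def _clean(v):
            return None if isinstance(v, float) and np.isnan(v) else v
        return {
            "family": self.family,
            "params": {k: float(v) for k, v in self.params.items()},
            "ad_stat": _clean(float(self.ad_stat)),
            "chi2_stat": _clean(float(self.chi2_stat)),
            "chi2_pvalue": _clean(float(self.chi2_pvalue)),
            "skewness": _clean(float(self.skewness)),
            "kurtosis": _clean(float(self.kurtosis)),
            "n": int(self.n),
            "flagged": bool(self.flagged),
            "note": self.note,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionFit":
        def _num(v):
            return np.nan if v is None else float(v)
        return cls(
            family=d["family"], params=dict(d["params"]),
            ad_stat=_num(d.get("ad_stat")), chi2_stat=_num(d.get("chi2_stat")),
            chi2_pvalue=_num(d.get("chi2_pvalue")),
            skewness=_num(d.get("skewness")), kurtosis=_num(d.get("kurtosis")),
            n=int(d.get("n", 0)), flagged=bool(d.get("flagged", False)),
            note=d.get("note", ""),
        )


def _anderson_darling(x: np.ndarray, fit: DistributionFit) -> float:
    """A-squared statistic of the sample against the fitted CDF.

    For discrete families the probability integral transform uses the
    midpoint CDF ``F(x) - p(x)/2`` (continuity correction), so statistics
    remain comparable with continuous candidates on tied count data.
    """
    x = np.sort(x)
    n = x.size
    f = fit.cdf(x)
    if fit.family == "poisson":
        f = f - 0.5 * stats.poisson.pmf(x, fit.params["mu"])
    f = np.clip(f, 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(f) + np.log(1 - f[::-1]))))


def _chi2_gof(x: np.ndarray, fit: DistributionFit,
              n_params: int) -> tuple[float, float]:
    """Chi-squared goodness of fit on equal-probability bins."""
    n = x.size
    if fit.family == "poisson":
        kmax = int(np.quantile(x, 0.99)) + 1
        edges = np.arange(-0.5, kmax + 1.5)
        observed, _ = np.histogram(x, bins=np.append(edges, np.inf))
        cdf_vals = stats.poisson.cdf(
            np.append(edges[1:], np.inf), fit.params["mu"])
        expected = n * np.diff(np.append(fit.cdf(edges[0]), cdf_vals))
    else:
        k = max(5, min(20, n // 20))
        qs = np.linspace(0, 1, k + 1)[1:-1]
        edges = np.quantile(x, qs)
        observed, _ = np.histogram(
            x, bins=np.concatenate(([-np.inf], edges, [np.inf])))
        cdf_edges = np.concatenate(([0.0], fit.cdf(edges), [1.0]))
        expected = n * np.diff(cdf_edges)
    keep = expected > 1e-9
    observed, expected = observed[keep], expected[keep]
    expected = expected * observed.sum() / expected.sum()
    statistic = float(np.sum((observed - expected) ** 2 / expected))
    dof = max(len(observed) - 1 - n_params, 1)
    return statistic, float(stats.chi2.sf(statistic, dof))


def _fit_family(x: np.ndarray, family: str) -> DistributionFit | None:
    """MLE fit of one candidate family, or None if inapplicable."""
    n = x.size
    if family == "normal":
        loc, scale = stats.norm.fit(x)
        if scale <= 0:
            return None
        return DistributionFit("normal", {"loc": loc, "scale": scale}, n=n)
    if family == "gamma":
        if np.any(x <= 0):
            return None
        shape, _, scale = stats.gamma.fit(x, floc=0)
        if shape <= 0 or scale <= 0:
            return None
        return DistributionFit("gamma", {"shape": shape, "scale": scale}, n=n)
    if family == "logistic":
        loc, scale = stats.logistic.fit(x)
        if scale <= 0:
            return None
        return DistributionFit("logistic", {"loc": loc, "scale": scale}, n=n)
    if family == "beta":
        if np.any((x <= 0) | (x >= 1)):
            return None
        a, b, _, _ = stats.beta.fit(x, floc=0, fscale=1)
        if a <= 0 or b <= 0:
            return None
        return DistributionFit("beta", {"a": a, "b": b}, n=n)
    if family == "poisson":
        if np.any(x < 0) or not np.allclose(x, np.round(x)):
            return None
        mu = float(np.mean(x))
        if mu <= 0:
            return None
        return DistributionFit("poisson", {"mu": mu}, n=n)
    raise ValueError(f"unknown candidate family {family!r}")


_N_PARAMS = {"normal": 2, "gamma": 2, "logistic": 2, "beta": 2, "poisson": 1}


def fit_distribution(
    samples: Sequence[float],
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
) -> DistributionFit:
    """Fit candidate families to a sample and select by Anderson-Darling.

    Inapplicable candidates (e.g. gamma for non-positive data) are skipped.
    Zero-variance samples degrade to a flagged point mass.  Requires at least
    8 observations.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 8:
        raise ValueError(f"need >= 8 samples to fit, got {x.size}")
    if not candidates:
        raise ValueError("candidate family set is empty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x))
    if np.ptp(x) == 0 or np.std(x) == 0:
        warnings.warn("degenerate (zero-variance) sample; using point mass",
                      stacklevel=2)
        return DistributionFit(
            "point_mass", {"value": float(x[0])}, n=x.size,
            skewness=skew, kurtosis=kurt, flagged=True,
            note="zero-variance sample",
        )
    fits: list[DistributionFit] = []
    for family in candidates:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = _fit_family(x, family)
            except stats.FitError:
                fit = None
        if fit is None:
            continue
        ad = _anderson_darling(x, fit)
        chi2_stat, chi2_p = _chi2_gof(x, fit, _N_PARAMS[family])
        fits.append(replace(fit, ad_stat=ad, chi2_stat=chi2_stat,
                            chi2_pvalue=chi2_p, skewness=skew, kurtosis=kurt))
    if not fits:
        raise ValueError("no candidate family applicable to the sample")
    return min(fits, key=lambda f: f.ad_stat)


@dataclass
class FittedParameterDistributions:
    """Complete parameter-uncertainty specification for the PSA.

    ``transition_concentrations`` maps each treatment key to a 4x4 array of
    per-row Dirichlet concentrations; the per-state fits cover utilities
    (annual), healthcare cost per cycle and sick days per cycle.  Workforce
    participation, the day-of-absence cost and drug costs are treated as
    fixed configuration.
    """

    transition_concentrations: dict[str, np.ndarray]
    utility_fits: dict[HealthState, DistributionFit]
    hc_cost_fits: dict[HealthState, DistributionFit]
    sick_day_fits: dict[HealthState, DistributionFit]
    workforce_participation: float = 0.7
    day_cost: float = 230.0

    def require_complete(self, keys: Iterable[str]) -> None:
        missing = [k for k in keys if k not in self.transition_concentrations]
        if missing:
            raise MissingParameterError(
                f"no Dirichlet concentrations for treatment keys: {missing}"
            )
        for name, d in [("utility", self.utility_fits),
                        ("hc_cost", self.hc_cost_fits),
                        ("sick_day", self.sick_day_fits)]:
            absent = [s.name for s in HealthState if s not in d]
            if absent:
                raise MissingParameterError(
                    f"no {name} fit for states: {absent}"
                )

    @classmethod
    def from_data(
        cls,
        visits: pd.DataFrame,
        tariff: Tariff,
        transition_model: TransitionModel,
        dirichlet_prior: float = 1.0,
        workforce_participation: float = 0.7,
        day_cost: float = 230.0,
        candidates: Sequence[str] = DEFAULT_CANDIDATES,
    ) -> "FittedParameterDistributions":
        """Fit all parameter distributions from visit records and counts."""
        from .valuation import EQ5D_DIMENSIONS
        from .states import classify_das28

        conc = {
            key: dirichlet_params(c, dirichlet_prior)
            for key, c in transition_model.counts.items()
        }
        states = visits["das28"].map(classify_das28)
        utils = visits.apply(
            lambda row: tariff.utility([row[d] for d in EQ5D_DIMENSIONS]),
            axis=1,
        )
        utility_fits = {}
        hc_fits = {}
        sick_fits = {}
        for hs in HealthState:
            mask = states == hs
            if mask.sum() < 8:
                raise MissingParameterError(
                    f"fewer than 8 visits in state {hs.name}; cannot fit"
                )
            utility_fits[hs] = fit_distribution(utils[mask], candidates)
            hc_fits[hs] = fit_distribution(
                visits.loc[mask, "interval_cost"], candidates)
            sick_fits[hs] = fit_distribution(
                visits.loc[mask, "sick_days"], candidates)
        return cls(
            transition_concentrations=conc,
            utility_fits=utility_fits,
            hc_cost_fits=hc_fits,
            sick_day_fits=sick_fits,
            workforce_participation=workforce_participation,
            day_cost=day_cost,
        )

    @classmethod
    def point_mass(
        cls,
        transition_model: TransitionModel,
        state_values: StateValues,
        concentration_scale: float = 1e12,
    ) -> "FittedParameterDistributions":
        """Degenerate (zero-uncertainty) fits collapsing the PSA onto the
        base case: Dirichlet concentrations scaled to near-point-mass rows
        and point-mass utility/cost fits."""
        conc = {
            k: p * concentration_scale
            for k, p in transition_model.probs.items()
        }
        def _pm(d):
            return {s: DistributionFit("point_mass", {"value": float(v)},
                                       n=0, flagged=False)
                    for s, v in d.items()}
        return cls(
            transition_concentrations=conc,
            utility_fits=_pm(state_values.utilities),
            hc_cost_fits=_pm(state_values.hc_cost_per_cycle),
            sick_day_fits=_pm(state_values.sick_days_per_cycle),
            workforce_participation=state_values.workforce_participation,
            day_cost=state_values.day_cost,
        )

    def to_dict(self) -> dict:
        return {
            "transition_concentrations": {
                k: np.asarray(v).tolist()
                for k, v in self.transition_concentrations.items()
            },
            "utility_fits": {s.name: f.to_dict()
                             for s, f in self.utility_fits.items()},
            "hc_cost_fits": {s.name: f.to_dict()
                             for s, f in self.hc_cost_fits.items()},
            "sick_day_fits": {s.name: f.to_dict()
                              for s, f in self.sick_day_fits.items()},
            "workforce_participation": self.workforce_participation,
            "day_cost": self.day_cost,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FittedParameterDistributions":
        return cls(
            transition_concentrations={
                k: np.asarray(v, dtype=float)
                for k, v in d["transition_concentrations"].items()
            },
            utility_fits={HealthState[s]: DistributionFit.from_dict(f)
                          for s, f in d["utility_fits"].items()},
            hc_cost_fits={HealthState[s]: DistributionFit.from_dict(f)
                          for s, f in d["hc_cost_fits"].items()},
            sick_day_fits={HealthState[s]: DistributionFit.from_dict(f)
                           for s, f in d["sick_day_fits"].items()},
            workforce_participation=float(d["workforce_participation"]),
            day_cost=float(d["day_cost"]),
        )


def _dirichlet_row(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet draw via gamma normalisation; zero concentrations yield
    exact zeros (a degenerate Dirichlet on the face of the simplex)."""
    g = np.array([rng.gamma(a, 1.0) if a > 0 else 0.0 for a in alpha])
    total = g.sum()
    if total == 0:
        raise ValueError("all-zero Dirichlet concentration row")
    return g / total


def draw_parameter_set(
    fits: FittedParameterDistributions,
    rng: np.random.Generator,
) -> tuple[TransitionModel, StateValues]:
    """Draw one coherent model-parameter realisation.

    Transition rows come from their Dirichlets (rows sum to 1); utilities
    from their fitted family, truncated at 1 by resampling; costs and sick
    days are clipped at 0 (gamma/Poisson draws need no clipping).
    """
    probs = {}
    for key, conc in fits.transition_concentrations.items():
        conc = np.asarray(conc, dtype=float)
        probs[key] = np.stack(
            [_dirichlet_row(conc[r], rng) for r in range(N_STATES)])
    tm = TransitionModel.from_probs(probs)

    utilities = {}
    for s, fit in fits.utility_fits.items():
        u = float(fit.rvs(rng))
        for _ in range(100):
            if u <= 1.0:
                break
            u = float(fit.rvs(rng))
        utilities[s] = min(u, 1.0)
    hc = {s: max(float(f.rvs(rng)), 0.0)
          for s, f in fits.hc_cost_fits.items()}
    sick = {s: max(float(f.rvs(rng)), 0.0)
            for s, f in fits.sick_day_fits.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vals = StateValues(
            utilities=utilities, sick_days_per_cycle=sick,
            hc_cost_per_cycle=hc,
            workforce_participation=fits.workforce_participation,
            day_cost=fits.day_cost,
        )
    return tm, vals


@dataclass
class PSAResult:
    """Two-level PSA output.

    ``outer_means`` has one row per outer parameter draw with each strategy's
    inner-cohort mean cost/QALY; ``delta_cost``/``delta_effect`` are the
    paired incremental samples (II minus I).  Percentile intervals are
    reported on two bases: over outer-draw means (parameter uncertainty) and
    over pooled individual patients (parameter plus patient-level
    variability).
    """

    strategy_i: str
    strategy_ii: str
    outer_means: pd.DataFrame
    pooled_patient_quantiles: dict
    comparison: CEComparison
    n_outer: int
    n_inner: int
    seed: int

    @property
    def delta_cost(self) -> np.ndarray:
        return (self.outer_means["cost_ii"] - self.outer_means["cost_i"]
                ).to_numpy()

    @property
    def delta_effect(self) -> np.ndarray:
        return (self.outer_means["qaly_ii"] - self.outer_means["qaly_i"]
                ).to_numpy()

    def incremental_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_effect,
        })

    def summary(self) -> dict:
        out = {"n_outer": self.n_outer, "n_inner": self.n_inner,
               "seed": self.seed, "strategies": {}}
        for label, name in [("I", self.strategy_i), ("II", self.strategy_ii)]:
            suffix = "i" if label == "I" else "ii"
            cost = self.outer_means[f"cost_{suffix}"]
            qaly = self.outer_means[f"qaly_{suffix}"]
            out["strategies"][name] = {
                "mean_cost": round(float(cost.mean()), 2),
                "cost_interval_outer": [
                    round(float(cost.quantile(0.025)), 2),
                    round(float(cost.quantile(0.975)), 2),
                ],
                "cost_interval_pooled":
                    self.pooled_patient_quantiles[f"cost_{suffix}"],
                "mean_qaly": round(float(qaly.mean()), 3),
                "qaly_interval_outer": [
                    round(float(qaly.quantile(0.025)), 3),
                    round(float(qaly.quantile(0.975)), 3),
                ],
                "qaly_interval_pooled":
                    self.pooled_patient_quantiles[f"qaly_{suffix}"],
            }
        out["icer"] = self.comparison.summary()
        return out


def run_psa(
    strategy_i: StrategySpec,
    strategy_ii: StrategySpec,
    fits: FittedParameterDistributions,
    n_outer: int = 2000,
    n_inner: int = 200,
    seed: int = 0,
    base_cfg: ModelConfig | None = None,
) -> PSAResult:
    """Two-level probabilistic sensitivity analysis.

    For each of ``n_outer`` outer iterations one parameter set is drawn and
    *both* strategies are simulated on that same realisation with ``n_inner``
    patients each (common parameter draws pair the strategies, so the
    incremental cloud reflects parameter uncertainty, not mismatched draws).
    """
    if n_outer < 1 or n_inner < 1:
        raise ValueError("n_outer and n_inner must be >= 1")
    fits.require_complete(
        set(strategy_i.transition_keys) | set(strategy_ii.transition_keys))
    base_cfg = base_cfg if base_cfg is not None else ModelConfig()

    root = np.random.SeedSequence(seed)
    param_seeds, sim_seeds = root.spawn(2)
    param_rngs = [np.random.default_rng(s)
                  for s in param_seeds.spawn(n_outer)]
    inner_seeds = sim_seeds.generate_state(2 * n_outer) % (2**31)

    rows = []
    pooled = {"cost_i": [], "qaly_i": [], "cost_ii": [], "qaly_ii": []}
    for j in range(n_outer):
        tm, vals = draw_parameter_set(fits, param_rngs[j])
        rec = {}
        for suffix, strat, s_off in [("i", strategy_i, 0),
                                     ("ii", strategy_ii, 1)]:
            cfg = replace(base_cfg, n_patients=n_inner,
                          seed=int(inner_seeds[2 * j + s_off]))
            res = simulate_cohort(strat, tm, vals, cfg)
            rec[f"cost_{suffix}"] = res.mean_cost
            rec[f"qaly_{suffix}"] = res.mean_qaly
            pooled[f"cost_{suffix}"].append(
                res.per_patient["total_cost"].to_numpy())
            pooled[f"qaly_{suffix}"].append(
                res.per_patient["total_qaly"].to_numpy())
        rows.append(rec)

    outer_means = pd.DataFrame(rows)
    pooled_q = {}
    for key, chunks in pooled.items():
        allv = np.concatenate(chunks)
        digits = 2 if key.startswith("cost") else 3
        pooled_q[key] = [round(float(np.quantile(allv, 0.025)), digits),
                         round(float(np.quantile(allv, 0.975)), digits)]
    comparison = icer(
        float(outer_means["cost_i"].mean()),
        float(outer_means["qaly_i"].mean()),
        float(outer_means["cost_ii"].mean()),
        float(outer_means["qaly_ii"].mean()),
    )
    return PSAResult(
        strategy_i=strategy_i.name, strategy_ii=strategy_ii.name,
        outer_means=outer_means, pooled_patient_quantiles=pooled_q,
        comparison=comparison, n_outer=n_outer, n_inner=n_inner, seed=seed,
    )
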