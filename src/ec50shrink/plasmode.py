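"""Plasmode-style simulation and evaluation of the shrinkage estimators.

Each simulated dataset is generated from per-gene 4pLL truth curves
evaluated on the experimental design, with i.i.d. Gaussian noise added
(default sd 0.1; six control replicates plus three per treated
concentration, 27 observations on the default design).  Per run, every gene
is re-fitted, the empirical priors are re-estimated from that run's direct
estimates, and the posterior means serve as the Bayesian estimates.

Evaluation follows the study's conventions: per-gene mean squared error
against the true log-EC50 over each method's non-missing runs, a four-way
MSE comparison category (low / better / similar / worse), credible- and
confidence-interval coverage probabilities, and MA-type coordinates
(log product, log ratio of the two MSEs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import (
    VPA_DESIGN,
    ConcentrationDesign,
    LL4Params,
    LL4Results,
    confidence_interval,
    fit_ll4,
    predict_ll4,
)
from .empirical_bayes import (
    estimate_prior_ml,
    estimate_prior_robust,
    fit_mixture_em,
    posterior_mixture,
    posterior_normal,
    posterior_point_and_interval,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate_dataset",
    "run_plasmode",
    "evaluate_mse",
    "classify_gene",
    "coverage_probability",
    "ma_transform",
    "restrict_by_truth",
    "summarize_categories",
    "evaluate_all",
    "MAX_CONC_LOG_CUTOFF",
    "METHODS",
]

METHODS = ("direct", "ml", "robust", "mixture")

#: log of the highest tested concentration (1000 uM): true log-EC50 values
#: above this correspond to inflection points outside the tested range.
MAX_CONC_LOG_CUTOFF = math.log(1000.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one plasmode simulation study."""

    n_runs: int = 1000
    noise_sd: float = 0.1
    design: ConcentrationDesign = VPA_DESIGN
    missing_cap: int | None = None
    seed: int = 0
    methods: tuple = METHODS
    level: float = 0.95
    em_options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.missing_cap is None:
            # 20% of runs: the study's cap of 200 out of 1000
            object.__setattr__(self, "missing_cap", self.n_runs // 5)
        if not 0 <= self.missing_cap < self.n_runs:
            raise ValueError("missing_cap must be in [0, n_runs)")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if "direct" not in self.methods:
            object.__setattr__(self, "methods", ("direct", *self.methods))


def simulate_dataset(
    truth: LL4Params,
    design: ConcentrationDesign,
    noise_sd: float,
    rng: np.random.Generator,
) -> tuple:
    """One simulated (x, y) dataset: truth curve plus N(0, noise_sd^2) noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    x = design.expand()
    y = predict_ll4(truth, x)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.size)
    else:
        y = y.copy()
    return x, y


@dataclass
class SimulationResult:
    """Estimates and intervals for every gene x run x method.

    Arrays are shaped (n_genes, n_runs, n_methods) with NaN marking missing
    values (failed fits, failed prior estimation, EM non-convergence).
    ``retained`` flags genes whose union-over-methods missing-run count is
    within the configured cap.
    """

    gene_ids: list
    methods: tuple
    truth: list
    estimates: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    config: SimulationConfig

    def method_index(self, method: str) -> int:
        return self.methods.index(method)

    @property
    def n_missing(self) -> np.ndarray:
        """Per-gene count of runs where any requested method is missing."""
        return np.isnan(self.estimates).any(axis=2).sum(axis=1)

    @property
    def retained(self) -> np.ndarray:
        return self.n_missing <= self.config.missing_cap

    @property
    def retained_genes(self) -> list:
        return [g for g, keep in zip(self.gene_ids, self.retained) if keep]

    def true_e_tilde(self) -> np.ndarray:
        return np.array([t.e_tilde for t in self.truth])


def _gene_rng(seed: int, run: int, gene: int) -> np.random.Generator:
    # per-run, per-gene substream: adding genes never perturbs existing ones
    return np.random.default_rng([seed, run, gene])


def run_plasmode(truths, config: SimulationConfig) -> SimulationResult:
    """Run the full simulate -> refit -> re-estimate-prior -> shrink loop.

    ``truths`` is a sequence of :class:`LL4Params` or a DataFrame with
    columns ``gene, b, c, d, e_tilde``.  Per-gene or per-run failures are
    recorded as NaN, never raised.  Deterministic given ``config.seed``.
    """
    if isinstance(truths, pd.DataFrame):
        gene_ids = (
            truths["gene"].astype(str).tolist()
            if "gene" in truths
            else [f"g{i}" for i in range(len(truths))]
        )
        truth_params = [
            LL4Params(r.b, r.c, r.d, r.e_tilde) for r in truths.itertuples()
        ]
    else:
        truth_params = list(truths)
        gene_ids = [f"g{i}" for i in range(len(truth_params))]
    n_genes = len(truth_params)
    if n_genes < 2:
        raise ValueError("prior estimation needs at least 2 genes")

    methods = tuple(config.methods)
    n_methods = len(methods)
    shape = (n_genes, config.n_runs, n_methods)
    estimates = np.full(shape, np.nan)
    lower = np.full(shape, np.nan)
    upper = np.full(shape, np.nan)
    i_direct = methods.index("direct")

    for run in range(config.n_runs):
        e_hat = np.full(n_genes, np.nan)
        se = np.full(n_genes, np.nan)
        fits: list[LL4Results | None] = [None] * n_genes
        for g, truth in enumerate(truth_params):
            rng = _gene_rng(config.seed, run, g)
            x, y = simulate_dataset(truth, config.design, config.noise_sd, rng)
            fit = fit_ll4(x, y)
            if fit.converged and np.isfinite(fit.se("e_tilde")) and fit.se("e_tilde") > 0:
                fits[g] = fit
                e_hat[g] = fit.params.e_tilde
                se[g] = fit.se("e_tilde")

        ok = np.isfinite(e_hat)
        for g in np.flatnonzero(ok):
            estimates[g, run, i_direct] = e_hat[g]
            lo, up = confidence_interval(fits[g], "e_tilde", config.level)
            lower[g, run, i_direct] = lo
            upper[g, run, i_direct] = up

        values = e_hat[ok]
        priors = {}
        for method in methods:
            if method == "direct":
                continue
            try:
                if method == "ml":
                    priors[method] = estimate_prior_ml(values)
                elif method == "robust":
                    priors[method] = estimate_prior_robust(values)
                else:
                    mix = fit_mixture_em(values, **config.em_options)
                    if mix.success:
                        priors[method] = mix
            except ValueError:
                pass  # degenerate prior: this method stays missing for the run

        for method, prior in priors.items():
            j = methods.index(method)
            for g in np.flatnonzero(ok):
                s2 = se[g] ** 2
                if method == "mixture":
                    post = posterior_mixture(e_hat[g], s2, prior)
                else:
                    post = posterior_normal(e_hat[g], s2, prior)
                pt, lo, up = posterior_point_and_interval(post, config.level)
                estimates[g, run, j] = pt
                lower[g, run, j] = lo
                upper[g, run, j] = up

    return SimulationResult(
        gene_ids=gene_ids,
        methods=methods,
        truth=truth_params,
        estimates=estimates,
        lower=lower,
        upper=upper,
        config=config,
    )


def evaluate_mse(result: SimulationResult, method: str) -> pd.DataFrame:
    """Per-gene MSE of the direct and of one Bayes method vs the true log-EC50.

    Each method's MSE averages over its own non-missing runs; a gene with no
    non-missing run for a method gets NaN there and is excluded downstream.
    """
    if method not in result.methods:
        raise ValueError(f"method {method!r} was not simulated")
    truth = result.true_e_tilde()

    def _mse(idx):
        err2 = (result.estimates[:, :, idx] - truth[:, None]) ** 2
        with np.errstate(invalid="ignore"):
            return np.nanmean(err2, axis=1)

    return pd.DataFrame(
        {
            "gene": result.gene_ids,
            "mse_direct": _mse(result.method_index("direct")),
            "mse_bayes": _mse(result.method_index(method)),
        }
    )


def classify_gene(
    mse_direct: float,
    mse_bayes: float,
    low_cut: float = 0.1,
    ratio_cut: float = 1.1,
) -> str:
    """Four-way MSE comparison category.

    Evaluated in order: ``low`` (orange) when both MSEs are below
    ``low_cut``; ``better`` (green) when the Bayes MSE beats the direct MSE
    by at least the factor ``ratio_cut``; ``worse`` (black) in the opposite
    case; otherwise ``similar`` (blue).
    """
    for v in (mse_direct, mse_bayes):
        if not (np.isfinite(v) and v >= 0):
            raise ValueError(f"MSEs must be finite and >= 0, got {v}")
    if mse_direct < low_cut and mse_bayes < low_cut:
        return "low"
    if mse_direct >= ratio_cut * mse_bayes:
        return "better"
    if mse_bayes >= ratio_cut * mse_direct:
        return "worse"
    return "similar"


def coverage_probability(result: SimulationResult, method: str) -> pd.DataFrame:
    """Per-gene fraction of non-missing runs whose interval covers the truth."""
    j = result.method_index(method)
    truth = result.true_e_tilde()[:, None]
    lo, up = result.lower[:, :, j], result.upper[:, :, j]
    present = np.isfinite(result.estimates[:, :, j])
    covered = (lo <= truth) & (truth <= up) & present
    n_ok = present.sum(axis=1)
    with np.errstate(invalid="ignore"):
        cp = np.where(n_ok > 0, covered.sum(axis=1) / np.maximum(n_ok, 1), np.nan)
    return pd.DataFrame({"gene": result.gene_ids, "cp": cp, "n_runs_used": n_ok})


def ma_transform(mse_direct: float, mse_bayes: float) -> tuple:
    """MA-type coordinates: (log product, log ratio) of the two MSEs.

    Natural log; a negative y coordinate means the Bayes method improved
    on the direct estimate.
    """
    if not (mse_direct > 0 and mse_bayes > 0):
        raise ValueError("MA transform requires strictly positive MSEs")
    return (
        math.log(mse_direct * mse_bayes),
        math.log(mse_bayes / mse_direct),
    )


def restrict_by_truth(
    evaluations: pd.DataFrame,
    truths,
    cutoff: float = MAX_CONC_LOG_CUTOFF,
) -> pd.DataFrame:
    """Keep genes whose TRUE log-EC50 is below the cutoff.

    Curves with an inflection point beyond the highest tested concentration
    are implausible fits; restricting the evaluation (not the shrinkage,
    which always uses all genes) to true log-EC50 < log(max concentration)
    mirrors the study's sensitivity analysis.
    """
    if isinstance(truths, pd.DataFrame):
        true_e = truths.set_index(truths["gene"].astype(str))["e_tilde"]
        keep = evaluations["gene"].astype(str).map(true_e) < cutoff
    else:
        e_map = {f"g{i}": t.e_tilde for i, t in enumerate(truths)}
        keep = evaluations["gene"].map(e_map) < cutoff
    return evaluations.loc[keep.fillna(False)].reset_index(drop=True)


def summarize_categories(per_gene: pd.DataFrame, category_col: str = "category") -> pd.Series:
    """Counts of low / better / similar / worse genes (table-of-effects shape)."""
    counts = per_gene[category_col].value_counts()
    return counts.reindex(["low", "better", "similar", "worse"], fill_value=0)


def evaluate_all(result: SimulationResult, restrict_retained: bool = True) -> dict:
    """Full evaluation: per-method per-gene table plus category summaries.

    Returns ``{"per_gene": {method: DataFrame}, "summary": DataFrame}`` where
    each per-gene table carries MSEs, category, coverage probabilities and
    MA coordinates, computed over retained genes (missing cap rule) unless
    ``restrict_retained`` is False.
    """
    keep = result.retained if restrict_retained else np.ones(len(result.gene_ids), bool)
    cp_direct = coverage_probability(result, "direct").set_index("gene")["cp"]
    per_gene = {}
    summary_rows = {}
    for method in result.methods:
        if method == "direct":
            continue
        tab = evaluate_mse(result, method)
        tab = tab.loc[keep].reset_index(drop=True)
        defined = tab["mse_direct"].notna() & tab["mse_bayes"].notna()
        tab["category"] = [
            classify_gene(r.mse_direct, r.mse_bayes) if ok else None
            for r, ok in zip(tab.itertuples(), defined)
        ]
        ma = [
            ma_transform(r.mse_direct, r.mse_bayes)
            if ok and r.mse_direct > 0 and r.mse_bayes > 0
            else (np.nan, np.nan)
            for r, ok in zip(tab.itertuples(), defined)
        ]
        tab["ma_x"] = [m[0] for m in ma]
        tab["ma_y"] = [m[1] for m in ma]
        tab["cp_direct"] = tab["gene"].map(cp_direct)
        tab["cp_bayes"] = tab["gene"].map(
            coverage_probability(result, method).set_index("gene")["cp"]
        )
        per_gene[method] = tab
        summary_rows[method] = summarize_categories(tab.dropna(subset=["category"]))
    summary = pd.DataFrame(summary_rows).T
    summary.index.name = "method"
    return {"per_gene": per_gene, "summary": summary}
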