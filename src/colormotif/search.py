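"""Random search over (alpha, beta) hyperparameters maximizing the ELBO.

The search draws the DP concentration alpha log-uniformly and a single shared
Beta shape beta = beta1 = beta2 uniformly on (0, 1), runs one fit per trial
and ranks trials by final ELBO.  The shipped operating point is alpha = 1000,
beta = 0.9: the fitted ELBO is far more sensitive to the emission prior shape
than to the DP concentration, and larger beta (a flatter Beta over the
near-deterministic agreement attributes) is generally favored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .model import BBDPConfig, fit

#: Operating point selected by ELBO random search.
DEFAULT_ALPHA = 1000.0
DEFAULT_BETA = 0.9
#: Default log10 range for the concentration draw; contains the operating point.
DEFAULT_ALPHA_RANGE = (0.0, 4.0)


@dataclass(frozen=True)
class HyperparamTrial:
    trial_index: int
    alpha: float
    beta: float
    elbo: float
    seed: int
    k_star: int
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None and np.isfinite(self.elbo)


class SelectionError(RuntimeError):
    """No successful trial to select from."""


def random_search(
    X,
    n_trials: int,
    cfg_template: BBDPConfig | None = None,
    alpha_range: tuple[float, float] = DEFAULT_ALPHA_RANGE,
    seed: int = 0,
) -> list[HyperparamTrial]:
    """Run ``n_trials`` independent fits at randomly drawn hyperparameters.

    alpha is log-uniform over ``10**alpha_range``; beta is uniform strictly
    inside (0, 1) and used for both Beta shapes.  Trials come back sorted by
    descending ELBO (failed trials last); the draw order is recorded in
    ``trial_index`` and everything is reproducible from ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    template = cfg_template or BBDPConfig()
    rng = np.random.default_rng(seed)
    trials: list[HyperparamTrial] = []
    for t in range(n_trials):
        alpha = float(10.0 ** rng.uniform(*alpha_range))
        beta = float(rng.uniform(np.nextafter(0.0, 1.0), 1.0))
        fit_seed = int(rng.integers(0, 2**31))
        cfg = replace(template, alpha=alpha, beta1=beta, beta2=beta, seed=fit_seed)
        try:
            _, result = fit(X, cfg)
            trials.append(
                HyperparamTrial(
                    trial_index=t,
                    alpha=alpha,
                    beta=beta,
                    elbo=result.final_elbo,
                    seed=fit_seed,
                    k_star=result.effective_K,
                )
            )
        except Exception as exc:  # a failed trial is recorded, never fatal
            trials.append(
                HyperparamTrial(
                    trial_index=t,
                    alpha=alpha,
                    beta=beta,
                    elbo=float("nan"),
                    seed=fit_seed,
                    k_star=0,
                    error=str(exc),
                )
            )
    return sorted(
        trials,
        key=lambda tr: (-(tr.elbo if tr.ok else -np.inf), tr.trial_index),
    )


def select_best(trials: Sequence[HyperparamTrial]) -> HyperparamTrial:
    """Max-ELBO trial; exact ties resolve to the lower draw index."""
    ok = [t for t in trials if t.ok]
    if not ok:
        raise SelectionError("no successful trials")
    return min(ok, key=lambda t: (-t.elbo, t.trial_index))


@dataclass(frozen=True)
class SensitivityReport:
    """Binned ELBO means and rank correlations against beta and log10(alpha)."""

    beta_table: pd.DataFrame   # columns: bin, n, mean_elbo
    alpha_table: pd.DataFrame
    corr_beta: float           # Spearman rank correlation (nan if undefined)
    corr_log_alpha: float


def _binned_means(values: np.ndarray, elbos: np.ndarray, n_bins: int = 10) -> pd.DataFrame:
    bins = pd.cut(pd.Series(values), bins=n_bins)
    df = pd.DataFrame({"bin": bins, "elbo": elbos})
    out = (
        df.groupby("bin", observed=True)["elbo"]
        .agg(n="size", mean_elbo="mean")
        .reset_index()
    )
    return out[out["n"] > 0]


def beta_sensitivity_report(
    trials: Sequence[HyperparamTrial], n_bins: int = 10
) -> SensitivityReport:
    """Decile tables of mean ELBO against beta and against log10(alpha),
    plus Spearman rank correlations.  Degenerate inputs (all trials at one
    hyperparameter value) yield NaN correlations, reported as such."""
    ok = [t for t in trials if t.ok]
    if len(ok) < 10:
        raise ValueError("need at least 10 successful trials")
    betas = np.array([t.beta for t in ok])
    log_alphas = np.log10([t.alpha for t in ok])
    elbos = np.array([t.elbo for t in ok])

    def corr(x):
        if np.ptp(x) == 0 or np.ptp(elbos) == 0:
            return float("nan")
        return float(spearmanr(x, elbos).statistic)

    return SensitivityReport(
        beta_table=_binned_means(betas, elbos, n_bins),
        alpha_table=_binned_means(log_alphas, elbos, n_bins),
        corr_beta=corr(betas),
        corr_log_alpha=corr(log_alphas),
    )


def trials_to_frame(trials: Sequence[HyperparamTrial]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in trials],
            "alpha": [t.alpha for t in trials],
            "beta": [t.beta for t in trials],
            "elbo": [t.elbo for t in trials],
            "k_star": [t.k_star for t in trials],
            "seed": [t.seed for t in trials],
            "error": [t.error or "" for t in trials],
        }
    )


def write_trials(trials: Sequence[HyperparamTrial], path) -> None:
    trials_to_frame(trials).to_csv(path, sep="\t", index=False)
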