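"""End-to-end glue: dataset -> model -> chain -> validation summaries.

These helpers wire the synthetic (or file-loaded) data bundle into the
inference machinery with the data-derived initial state, and run the
bootstrap / hypothetical-series / importance-resampling validation loop.
"""

from __future__ import annotations

import numpy as np

from .inference import (
    BLOCKS,
    Chain,
    IPMModel,
    MCMCConfig,
    PriorSpec,
    irmcmc_fit,
    posterior_summary,
    run_mcmc,
)
from .states import initial_state_means
from .synthetic import (
    Dataset,
    initial_total_from_ground,
    june_proportions_from_ground,
)
from .observation import AerialObservation
from .validation import (
    bootstrap_population_series,
    credible_coverage,
    generate_hypothetical_ground_series,
    interpolated_truth,
    observed_class_profile,
)


def build_model(
    ds: Dataset,
    free_blocks=BLOCKS,
    prior: PriorSpec | None = None,
    ground: np.ndarray | None = None,
    aerial=None,
) -> IPMModel:
    """An IPMModel bound to the bundle (optionally overriding the data).

    The initial-state means come from the data itself: average June class
    shares applied to the early ground-count total.
    """
    ground = ds.ground if ground is None else ground
    aerial = ds.aerial if aerial is None else aerial
    tab = ds.covariate_table()
    init_means = initial_state_means(
        june_proportions_from_ground(ground, ds.config.month0),
        initial_total_from_ground(ground),
    )
    return IPMModel(
        ground, aerial, tab, ds.truth.predation,
        prior or PriorSpec(), init_means, free_blocks=free_blocks,
    )


def fit_dataset(
    ds: Dataset, cfg: MCMCConfig, free_blocks=BLOCKS, start_coeffs=None
) -> tuple[IPMModel, Chain]:
    model = build_model(ds, free_blocks=free_blocks)
    coeffs = start_coeffs if start_coeffs is not None else ds.truth.coeffs
    return model, run_mcmc(model, cfg, coeffs)


def ecosystem_prediction(chain: Chain, aerial_months=None) -> np.ndarray:
    """(n_kept, T+1) draws of the ecosystem-scale total K(t) * B(t).

    The survey ratio K is defined (and sampled) only at aerial months; the
    ratio is time-varying, so each draw's K values are linearly interpolated
    across months (constant beyond the first/last survey) before scaling
    that draw's reserve trajectory.
    """
    if chain.K.size == 0:
        raise ValueError("chain has no aerial ratio draws")
    if aerial_months is None:
        aerial_months = chain.aerial_months
    months = np.asarray(aerial_months, dtype=float)
    T1 = chain.B.shape[1]
    ts = np.arange(T1, dtype=float)
    out = np.empty_like(chain.B, dtype=float)
    for i in range(chain.n_kept):
        k_t = np.interp(ts, months, chain.K[i])
        out[i] = k_t * chain.B[i]
    return out


def validation_coverage(
    ds: Dataset,
    reference_model: IPMModel,
    reference_chain: Chain,
    n_series: int,
    cfg: MCMCConfig,
    seed: int,
) -> list[float]:
    """Bootstrap -> hypothetical series -> IRMCMC refit -> coverage.

    Returns one per-series percentage: how often the bootstrap ecosystem
    totals fall inside the refitted 95% credible limits of K * B.
    """
    T = ds.config.T
    series_list = bootstrap_population_series(ds.transects, n_series, seed)
    props = observed_class_profile(ds.ground)
    coverages = []
    for b, series in enumerate(series_list):
        ground_b = generate_hypothetical_ground_series(
            series, props, ds.truth.variances, K=ds.truth.k_ratio,
            T=T, seed=seed + 1000 + b, month0=ds.config.month0,
        )
        aerial_b = [
            AerialObservation(
                month_index=int(m), psi=float(est),
                se=float(np.sqrt(max(v, 1.0))) if np.isfinite(v) else 200.0,
            )
            for m, est, v in zip(series.months, series.estimates,
                                 series.variances)
        ]
        model_b = build_model(ds, free_blocks=reference_model.free_blocks,
                              ground=ground_b, aerial=aerial_b)
        cfg_b = MCMCConfig(
            n_iter=cfg.n_iter, n_burnin=cfg.n_burnin, thin=cfg.thin,
            seed=cfg.seed + b, tmcmc_scales=dict(cfg.tmcmc_scales),
            latent_step_mean=cfg.latent_step_mean,
            adapt_interval=cfg.adapt_interval, pool_size=cfg.pool_size,
        )
        chain_b = irmcmc_fit(reference_chain, model_b, cfg_b)
        eco = ecosystem_prediction(chain_b)
        _, lo, hi = posterior_summary(eco)
        truth = interpolated_truth(series, T)
        coverages.append(credible_coverage(truth, lo[1:], hi[1:]))
    return coverages
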