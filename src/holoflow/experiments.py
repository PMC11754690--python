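"""The desk-scale multi-view classification experiment.

One call renders the two standard datasets (rolling and non-rolling cells)
and trains fresh fusion models over a grid of K (projections fused), seeds,
and input domains, reproducing the three headline comparisons:

* rolling, hologram domain, K in ``k_rolling`` — accuracy should *rise*
  with K (each projection is a genuinely new view of the rolling cell);
* rolling, OPD domain, K in ``k_domain`` — compared against the hologram
  domain at the same K: holograms carry amplitude as well as phase, so they
  should classify at least as well;
* non-rolling, hologram domain, K in ``k_domain`` — the control: repeated
  near-identical views, so extra projections should bring no real benefit.

Everything is deterministic for fixed seeds.  Runtime is dominated by
training: roughly ``epochs`` x (sum of K) x seeds backbone passes.
"""

from __future__ import annotations

import logging

import pandas as pd

from .datasets import ProjectionDatasetConfig, make_projection_dataset
from .fusionnet import TrainConfig, projection_sweep

__all__ = ["multiview_experiment"]

logger = logging.getLogger("holoflow")


def multiview_experiment(
    n_per_class: int = 150,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    epochs: int = 15,
    k_rolling: tuple[int, ...] = (1, 3, 5),
    k_domain: tuple[int, ...] = (1, 5),
    rolling_dataset_seed: int = 11,
    fixed_dataset_seed: int = 12,
    center_crop: int = 96,
) -> dict[str, pd.DataFrame]:
    """Run the three sweeps; returns DataFrames keyed ``rolling_hologram``,
    ``rolling_opd`` and ``nonrolling_hologram`` (one row per K x seed run,
    with held-out test accuracy)."""
    n_proj = max(max(k_rolling), max(k_domain))
    train_config = TrainConfig(epochs=epochs)

    logger.info("rendering rolling dataset (%d cells)", 3 * n_per_class)
    rolling = make_projection_dataset(
        ProjectionDatasetConfig(
            n_per_class=n_per_class, n_projections=n_proj, rolling=True,
            seed=rolling_dataset_seed,
        )
    )
    logger.info("rendering non-rolling dataset (%d cells)", 3 * n_per_class)
    fixed = make_projection_dataset(
        ProjectionDatasetConfig(
            n_per_class=n_per_class, n_projections=n_proj, rolling=False,
            seed=fixed_dataset_seed,
        )
    )

    results: dict[str, pd.DataFrame] = {}
    logger.info("sweep: rolling cells, hologram domain, K=%s", list(k_rolling))
    results["rolling_hologram"] = projection_sweep(
        rolling, k_values=k_rolling, domain="hologram", seeds=seeds,
        train_config=train_config, center_crop=center_crop,
    )
    logger.info("sweep: rolling cells, OPD domain, K=%s", list(k_domain))
    results["rolling_opd"] = projection_sweep(
        rolling, k_values=k_domain, domain="opd", seeds=seeds,
        train_config=train_config, center_crop=center_crop,
    )
    logger.info("sweep: non-rolling cells, hologram domain, K=%s", list(k_domain))
    results["nonrolling_hologram"] = projection_sweep(
        fixed, k_values=k_domain, domain="hologram", seeds=seeds,
        train_config=train_config, center_crop=center_crop,
    )
    return results
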