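"""Reference benchmark runs used by the acceptance script and tests."""

from __future__ import annotations

import numpy as np

from . import bayes, segment
from .evaluate import propagate_scores, ranking_metrics
from .pipeline import groups_from_design, segment_dataset
from .simulate import SimConfig, simulate_confounded_dataset


def confounded_benchmark(
    seed: int,
    n_cpgs: int = 20000,
    n_dmrs: int = 170,
    depth_mean: float = 30.0,
    method: str = "advi",
    advi_steps: int = 10000,
) -> dict[str, float]:
    """Confounded-covariate benchmark at desk scale.

    Simulates the multi-covariate dataset, segments it with the default
    3-state model, scores regions with the Bayesian GLM, and returns
    per-cytosine AUROC/AP for both region inputs:

    - ``auroc_all`` / ``ap_all``: every decoded region is fitted;
    - ``auroc_hypo_hyper`` / ``ap_hypo_hyper``: only candidate hypo/hyper
      regions are fitted, all other CpGs score zero.
    """
    cfg = SimConfig(n_cpgs=n_cpgs, n_dmrs=n_dmrs, depth_mean=depth_mean, seed=seed)
    dataset, design, truth = simulate_confounded_dataset(cfg)
    g1, g2 = groups_from_design(design, dataset.sample_ids)
    seg = segment_dataset(dataset, g1, g2)

    rng = np.random.default_rng(seed)
    out: dict[str, float] = {"n_cpgs": float(n_cpgs),
                             "positive_fraction": truth.positive_fraction}
    for tag, mode in (("all", "all"), ("hypo_hyper", "hypo_hyper")):
        candidates = segment.select_candidate_regions(seg.regions, mode=mode)
        results = bayes.call_dmrs(candidates, design, method=method,
                                  seed=int(rng.integers(2**31)),
                                  advi_steps=advi_steps)
        metrics = ranking_metrics(propagate_scores(results, truth.labels))
        out[f"auroc_{tag}"] = metrics["auroc"]
        out[f"ap_{tag}"] = metrics["average_precision"]
    return out
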