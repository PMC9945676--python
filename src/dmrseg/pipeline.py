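"""High-level glue: dataset -> segmentation -> candidate regions -> DMR calls."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import bayes, segment
from .io import DesignMatrix, MethylationDataset


@dataclass
class SegmentationResult:
    model: segment.HMMModel
    tracks: list[segment.ObservationTrack]
    state_paths: list[list[str]]
    regions: list[segment.Region]
    log_likelihood_trace: list[float] = field(default_factory=list)


def groups_from_design(design: DesignMatrix,
                       sample_ids: Sequence[str]) -> tuple[list[str], list[str]]:
    """Split samples by the binary covariate of interest (1 = group1/case)."""
    col = design.matrix[:, design.interest_index]
    vals = np.unique(col)
    if len(vals) != 2:
        raise ValueError("covariate of interest is not binary; pass groups explicitly")
    ids = list(sample_ids)
    g1 = [s for s, v in zip(ids, col) if v == vals.max()]
    g2 = [s for s, v in zip(ids, col) if v == vals.min()]
    return g1, g2


def segment_dataset(
    dataset: MethylationDataset,
    group1: Sequence[str],
    group2: Sequence[str],
    scale: str = "beta",
    n_states: int = 3,
    max_iter: int = 50,
    tol: float = 1e-4,
    learn_emissions: bool = False,
    seed: int = 0,
) -> SegmentationResult:
    """Build observation tracks, fit transitions, decode and merge into regions."""
    tracks = segment.build_observation_tracks(dataset, group1, group2, scale=scale)
    if learn_emissions:
        model = segment.fit_unspecified_emissions(tracks, n_states=n_states, seed=seed,
                                                  max_iter=max_iter, tol=tol)
        trace: list[float] = []
    else:
        model = segment.default_model(n_states=n_states, scale=scale)
        model, trace = segment.fit_transitions_baum_welch(
            model, tracks, max_iter=max_iter, tol=tol)
    paths = [segment.viterbi_decode(model, tr) for tr in tracks]
    regions = []
    for tr, path in zip(tracks, paths):
        regions.extend(segment.merge_state_runs(dataset, tr, path))
    return SegmentationResult(model=model, tracks=tracks, state_paths=paths,
                              regions=regions, log_likelihood_trace=trace)


def run_dmr_pipeline(
    dataset: MethylationDataset,
    design: DesignMatrix,
    params: bayes.ExperimentalParams | None = None,
    hyper: bayes.GLMHyperparams | None = None,
    groups: tuple[Sequence[str], Sequence[str]] | None = None,
    scale: str = "beta",
    n_states: int = 3,
    mode: str = "all",
    min_cpgs: int = 1,
    method: str = "advi",
    seed: int = 0,
    **fit_kwargs,
) -> tuple[SegmentationResult, list[bayes.DMRResult]]:
    """Full pipeline: segmentation, candidate selection and Bayesian scoring."""
    if groups is None:
        groups = groups_from_design(design, dataset.sample_ids)
    seg = segment_dataset(dataset, groups[0], groups[1], scale=scale,
                          n_states=n_states, seed=seed)
    candidates = segment.select_candidate_regions(seg.regions, mode=mode,
                                                  min_cpgs=min_cpgs)
    results = bayes.call_dmrs(candidates, design, params=params, hyper=hyper,
                              method=method, seed=seed, **fit_kwargs)
    return seg, results
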