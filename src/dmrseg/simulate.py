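"""Synthetic BS-seq datasets with known DMR truth.

Two protocols:

* :func:`simulate_confounded_dataset` - a general-experimental-design genome:
  the CpG axis is partitioned into regions of length L ~ ceil(Gamma(shape=4,
  rate=0.2)); each region gets covariate coefficients b ~ N(0, 5) (the
  coefficient of interest forced to 0 for null regions and to |b| > 3 for
  DMRs), noise sigma_E^2 ~ Gamma(shape=0.5, scale=1), latent logits
  Y ~ N(D b, sigma_E^2) and methylation fractions theta = sigmoid(Y) shared
  by every CpG in the region; counts are binomial at a Poisson read depth.

* :func:`simulate_spikein_dataset` - a two-group benchmark in the spirit of
  spike-in studies on real CpG-island data: bimodal region-level baseline
  methylation, replicate-level beta variability, and DMRs realized by adding
  or subtracting a fixed methylation difference (0.1-0.4) from the case
  group's success probability before counts are drawn.

Coordinates are synthetic (fixed 50-bp stride on one chromosome): the
segmentation model is distance-blind, so only CpG order matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import DesignMatrix, MethylationDataset

#: Default 6-sample confounded design: intercept, binary case/control (the
#: covariate of interest), an arbitrary binary covariate and an arbitrary
#: continuous covariate.
DEFAULT_DESIGN_ROWS = np.array([
    [1, 0, 0, 0.3],
    [1, 0, 1, 0.5],
    [1, 0, 0, 0.7],
    [1, 1, 1, 0.3],
    [1, 1, 0, 0.5],
    [1, 1, 1, 0.7],
])
DEFAULT_COVARIATE_NAMES = ["intercept", "case_control", "binary", "continuous"]


def default_design(n_samples: int = 6) -> DesignMatrix:
    if n_samples != 6:
        raise ValueError("the default confounded design has 6 samples")
    return DesignMatrix(
        matrix=DEFAULT_DESIGN_ROWS.copy(),
        covariate_names=list(DEFAULT_COVARIATE_NAMES),
        interest_index=1,
        sample_ids=[f"sample{i + 1}" for i in range(6)],
    )


@dataclass
class SimConfig:
    """Settings for the confounded-covariate protocol.

    Defaults reproduce the protocol at genome scale (~215k CpGs, 1700 DMRs);
    pass smaller ``n_cpgs``/``n_dmrs`` for desk-scale runs.
    """

    n_cpgs: int = 215000
    n_dmrs: int = 1700
    region_length_shape: float = 4.0
    region_length_rate: float = 0.2
    coef_var: float = 5.0          # variance of b entries
    effect_threshold: float = 3.0  # |b[interest]| must exceed this in DMRs
    noise_shape: float = 0.5       # Gamma shape of sigma_E^2
    noise_scale: float = 1.0       # Gamma scale of sigma_E^2
    depth_mean: float = 30.0       # Poisson read depth, truncated at >= 1
    position_stride: int = 50
    chrom: str = "chr1"
    design: DesignMatrix | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cpgs <= 0 or self.n_dmrs < 0:
            raise ValueError("n_cpgs must be positive and n_dmrs non-negative")
        expected_len = self.region_length_shape / self.region_length_rate
        if self.n_dmrs * expected_len >= self.n_cpgs:
            raise ValueError("expected DMR span exceeds the genome "
                             f"({self.n_dmrs} x E[L]={expected_len:.1f} >= {self.n_cpgs})")
        for v in (self.region_length_shape, self.region_length_rate, self.coef_var,
                  self.effect_threshold, self.noise_shape, self.noise_scale,
                  self.depth_mean):
            if v <= 0:
                raise ValueError("all simulation parameters must be positive")


@dataclass
class SimTruth:
    """Ground truth: per-CpG DMR labels plus the generating region structure."""

    labels: np.ndarray          # (T,) 0/1 per CpG: inside a DMR w.r.t. interest
    region_id: np.ndarray       # (T,) region index per CpG
    region_is_dmr: np.ndarray   # (R,) bool
    region_b: np.ndarray        # (R, Np) true coefficients (confounded protocol)
    region_theta: np.ndarray    # (R, N) true methylation fractions per sample

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.region_id):
            raise ValueError("labels and region_id lengths differ")
        expected = self.region_is_dmr[self.region_id].astype(np.int8)
        if not np.array_equal(expected, self.labels.astype(np.int8)):
            raise ValueError("labels inconsistent with region DMR flags")
        if ((self.region_theta <= 0) | (self.region_theta >= 1)).any():
            raise ValueError("true theta must lie in (0, 1)")

    @property
    def positive_fraction(self) -> float:
        return float(self.labels.mean())


def sample_region_lengths(n_total_cpgs: int, shape: float, rate: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Region lengths L ~ ceil(Gamma(shape, rate)) until they tile n_total_cpgs.

    The last region is truncated so lengths sum exactly to ``n_total_cpgs``.
    """
    lengths: list[int] = []
    total = 0
    mean_len = shape / rate
    while total < n_total_cpgs:
        block = max(int((n_total_cpgs - total) / mean_len * 1.2) + 16, 16)
        draw = np.ceil(rng.gamma(shape, 1.0 / rate, size=block)).astype(np.int64)
        for L in draw:
            lengths.append(int(L))
            total += int(L)
            if total >= n_total_cpgs:
                break
    lengths[-1] -= total - n_total_cpgs
    if lengths[-1] == 0:
        lengths.pop()
    return np.asarray(lengths, dtype=np.int64)


def _truncated_poisson(lam: float, size, rng: np.random.Generator) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1 (every CpG has at least one read)."""
    d = rng.poisson(lam, size=size)
    zero = d == 0
    while zero.any():
        d[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = d == 0
    return d


def _sites_frame(n_cpgs: int, chrom: str, stride: int) -> pd.DataFrame:
    pos = (np.arange(n_cpgs, dtype=np.int64) * stride) + 1
    return pd.DataFrame({"chrom": chrom, "pos": pos})


def simulate_confounded_dataset(
    config: SimConfig,
) -> tuple[MethylationDataset, DesignMatrix, SimTruth]:
    """Generate the confounded-covariate benchmark (see module docstring).

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    design = config.design or default_design()
    D = design.matrix
    n, npar = D.shape
    k = design.interest_index

    lengths = sample_region_lengths(config.n_cpgs, config.region_length_shape,
                                    config.region_length_rate, rng)
    n_regions = len(lengths)
    if config.n_dmrs > n_regions:
        raise ValueError(f"n_dmrs={config.n_dmrs} exceeds {n_regions} regions")
    dmr_idx = rng.choice(n_regions, size=config.n_dmrs, replace=False)
    is_dmr = np.zeros(n_regions, dtype=bool)
    is_dmr[dmr_idx] = True

    b = rng.normal(0.0, np.sqrt(config.coef_var), size=(n_regions, npar))
    b[~is_dmr, k] = 0.0
    # rejection-sample the interest coefficient of DMRs from N(0, coef_var)
    # truncated to |b| > effect_threshold
    need = np.where(is_dmr)[0]
    while len(need):
        cand = rng.normal(0.0, np.sqrt(config.coef_var), size=len(need))
        ok = np.abs(cand) > config.effect_threshold
        b[need[ok], k] = cand[ok]
        need = need[~ok]

    sigma_e2 = rng.gamma(config.noise_shape, config.noise_scale, size=n_regions)
    Y = b @ D.T + rng.standard_normal((n_regions, n)) * np.sqrt(sigma_e2)[:, None]
    theta = expit(Y)
    theta = np.clip(theta, 1e-12, 1 - 1e-12)

    region_id = np.repeat(np.arange(n_regions), lengths)
    theta_per_cpg = theta[region_id]  # (T, n)
    nbs = _truncated_poisson(config.depth_mean, (config.n_cpgs, n), rng)
    nc = rng.binomial(nbs, theta_per_cpg)

    sample_ids = design.sample_ids or [f"sample{i + 1}" for i in range(n)]
    dataset = MethylationDataset(
        sample_ids=list(sample_ids),
        sites=_sites_frame(config.n_cpgs, config.chrom, config.position_stride),
        nbs=nbs, nc=nc)
    truth = SimTruth(labels=is_dmr[region_id].astype(np.int8), region_id=region_id,
                     region_is_dmr=is_dmr, region_b=b, region_theta=theta)
    return dataset, design, truth


def simulate_spikein_dataset(
    n_cpgs: int,
    n_dmrs: int,
    n_samples_per_group: int = 6,
    diffs: Sequence[float] = (0.1, 0.2, 0.3, 0.4),
    depth_mean: float = 30.0,
    seed: int = 0,
    region_length_shape: float = 4.0,
    region_length_rate: float = 0.2,
    baseline_alpha: float = 0.5,
    baseline_beta: float = 0.5,
    replicate_concentration: float = 50.0,
    position_stride: int = 50,
    chrom: str = "chr1",
    margin: float = 0.02,
) -> tuple[MethylationDataset, tuple[list[str], list[str]], SimTruth]:
    """Two-group benchmark with fixed spiked methylation differences.

    Baseline region methylation is drawn from a bimodal Beta mixture
    (low/high, emulating CpG-island data); per sample and region a replicate
    level is drawn from a Beta centred on the baseline
    (``replicate_concentration`` controls spread), giving spatial correlation
    within regions.  In DMRs the case group's success probability is shifted
    by a difference drawn uniformly from ``diffs`` with random sign; baselines
    too close to the boundary for the chosen shift are re-drawn.

    Returns the dataset, the (case, control) sample-id lists, and the truth.
    """
    diffs = np.asarray(list(diffs), dtype=float)
    if ((diffs <= 0) | (diffs >= 1)).any():
        raise ValueError("diffs must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_cases = n_controls = n_samples_per_group
    n = n_cases + n_controls

    lengths = sample_region_lengths(n_cpgs, region_length_shape, region_length_rate, rng)
    n_regions = len(lengths)
    if n_dmrs > n_regions:
        raise ValueError(f"n_dmrs={n_dmrs} exceeds {n_regions} regions")
    dmr_idx = rng.choice(n_regions, size=n_dmrs, replace=False)
    is_dmr = np.zeros(n_regions, dtype=bool)
    is_dmr[dmr_idx] = True

    baseline = rng.beta(baseline_alpha, baseline_beta, size=n_regions)
    baseline = np.clip(baseline, margin, 1.0 - margin)
    shift = np.zeros(n_regions)
    for r in dmr_idx:
        d = float(rng.choice(diffs))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        # re-draw the baseline until the shifted probability stays inside (0,1)
        while not margin <= baseline[r] + sign * d <= 1.0 - margin:
            baseline[r] = float(np.clip(rng.beta(baseline_alpha, baseline_beta),
                                        margin, 1.0 - margin))
        shift[r] = sign * d

    kappa = replicate_concentration
    p_rep = rng.beta(baseline[:, None] * kappa, (1.0 - baseline[:, None]) * kappa,
                     size=(n_regions, n))
    p_rep = np.clip(p_rep, 1e-6, 1.0 - 1e-6)
    p_rep[:, :n_cases] = np.clip(p_rep[:, :n_cases] + shift[:, None], 1e-6, 1.0 - 1e-6)

    region_id = np.repeat(np.arange(n_regions), lengths)
    nbs = _truncated_poisson(depth_mean, (n_cpgs, n), rng)
    nc = rng.binomial(nbs, p_rep[region_id])

    case_ids = [f"case{i + 1}" for i in range(n_cases)]
    control_ids = [f"control{i + 1}" for i in range(n_controls)]
    dataset = MethylationDataset(
        sample_ids=case_ids + control_ids,
        sites=_sites_frame(n_cpgs, chrom, position_stride),
        nbs=nbs, nc=nc)
    b = np.zeros((n_regions, 1))
    b[:, 0] = shift
    truth = SimTruth(labels=is_dmr[region_id].astype(np.int8), region_id=region_id,
                     region_is_dmr=is_dmr, region_b=b, region_theta=p_rep)
    return dataset, (case_ids, control_ids), truth


def write_simulation(
    dataset: MethylationDataset,
    truth: SimTruth,
    outdir: str | Path,
    design: DesignMatrix | None = None,
) -> dict[str, Path]:
    """Write a simulated dataset as bismark-coverage files + design TSV + truth BED.

    Round-trips through :func:`dmrseg.io.read_count_tables`.  Returns the
    written paths keyed by role.
    """
    if dataset.n_sites == 0:
        raise ValueError("empty dataset")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    chrom = dataset.sites["chrom"].to_numpy()
    pos = dataset.sites["pos"].to_numpy()
    for j, sample in enumerate(dataset.sample_ids):
        nbs = dataset.nbs[:, j]
        nc = dataset.nc[:, j]
        with np.errstate(invalid="ignore"):
            pct = np.where(nbs > 0, 100.0 * nc / np.maximum(nbs, 1), 0.0)
        df = pd.DataFrame({"chrom": chrom, "start": pos, "end": pos,
                           "pct": np.round(pct, 6), "meth": nc, "unmeth": nbs - nc})
        p = outdir / f"{sample}.cov"
        df.to_csv(p, sep="\t", header=False, index=False)
        paths[sample] = p

    if design is not None:
        df = pd.DataFrame(design.matrix, columns=design.covariate_names)
        df.insert(0, "sample", design.sample_ids or dataset.sample_ids)
        p = outdir / "design.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths["design"] = p

    # truth BED: one line per true DMR (0-based half-open over CpG positions)
    rows = []
    for r in np.where(truth.region_is_dmr)[0]:
        member = np.where(truth.region_id == r)[0]
        rows.append({"chrom": chrom[member[0]], "start": int(pos[member[0]]) - 1,
                     "end": int(pos[member[-1]]), "n_cpgs": len(member)})
    p = outdir / "truth.bed"
    pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpgs"]).to_csv(
        p, sep="\t", index=False)
    paths["truth"] = p
    return paths
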