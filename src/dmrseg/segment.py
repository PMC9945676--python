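"""Genome segmentation of CpG methylation differences with a Gaussian-emission HMM.

The observation at each CpG is the difference in mean methylation level
between two sample groups, y = mean(mu, group1) - mean(mu, group2) with
mu = N_BS,C / N_BS.  Hidden states are methylation states (equal, hypo-,
hypermethylated between the groups).  Transitions (and optionally emissions)
are learned by Baum-Welch; the most likely state path comes from the Viterbi
algorithm; maximal runs of the same decoded state become candidate regions
whose read counts are aggregated over member CpGs.

All forward/backward/Viterbi work is done with per-step rescaling or in log
space; the model has no notion of genomic distance between CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import MethylationDataset

_LOG_FLOOR = np.log(1e-300)  # emission density floor, keeps -inf off Viterbi paths


@dataclass
class ObservationTrack:
    """Per-chromosome sequence of between-group methylation differences."""

    chrom: str
    site_index: np.ndarray  # indices into MethylationDataset.sites
    y: np.ndarray
    scale: str = "beta"  # "beta" or "M"

    def __post_init__(self) -> None:
        self.site_index = np.asarray(self.site_index, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.site_index) != len(self.y):
            raise ValueError("site_index and y lengths differ")
        if self.scale == "beta" and len(self.y) and (np.abs(self.y) > 1 + 1e-12).any():
            raise ValueError("beta-scale differences must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class EmissionSpec:
    """One hidden state: a name and a Gaussian N(mean, sd) over y."""

    name: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"state '{self.name}': sd must be > 0")


HYPO_HYPER_FAMILIES = ("hypo", "hyper")


def is_candidate_state(name: str) -> bool:
    """True for states in the hypo/hyper families (hypo, hypo1, hyper2, ...)."""
    return any(name.startswith(fam) for fam in HYPO_HYPER_FAMILIES)


@dataclass
class HMMModel:
    """Gaussian-emission HMM: states, transition matrix A and initial distribution pi."""

    states: list[EmissionSpec]
    A: np.ndarray
    pi: np.ndarray
    trained: bool = False

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        k = len(self.states)
        if len(set(s.name for s in self.states)) != k:
            raise ValueError("state names must be unique")
        if self.A.shape != (k, k):
            raise ValueError(f"A must be {k}x{k}")
        if self.pi.shape != (k,):
            raise ValueError(f"pi must have length {k}")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of A must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-9):
            raise ValueError("pi must sum to 1")
        if (self.A < 0).any() or (self.pi < 0).any():
            raise ValueError("probabilities must be non-negative")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    def log_emission(self, y: np.ndarray) -> np.ndarray:
        """Log emission densities, shape (T, n_states), floored at log 1e-300."""
        y = np.asarray(y, dtype=float)[:, None]
        mu = np.array([s.mean for s in self.states])
        sd = np.array([s.sd for s in self.states])
        logp = -0.5 * np.log(2 * np.pi * sd**2) - (y - mu) ** 2 / (2 * sd**2)
        return np.maximum(logp, _LOG_FLOOR)


def methylation_ratio(n_bs_c, n_bs):
    """Methylation level mu = N_BS,C / N_BS; NaN where coverage is zero.

    Accepts scalars or arrays; raises if counts are negative or
    N_BS,C > N_BS anywhere.
    """
    n_bs_c = np.asarray(n_bs_c, dtype=float)
    n_bs = np.asarray(n_bs, dtype=float)
    if (n_bs_c < 0).any() or (n_bs < 0).any():
        raise ValueError("negative counts")
    if (n_bs_c > n_bs).any():
        raise ValueError("methylated count exceeds total count")
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(n_bs > 0, n_bs_c / np.maximum(n_bs, 1), np.nan)
    if mu.ndim == 0:
        return float(mu)
    return mu


def m_transform(mu: np.ndarray, n_bs: np.ndarray | None = None) -> np.ndarray:
    """Map beta-values onto the real line: M = log2(mu / (1 - mu)).

    mu is clipped to [eps, 1-eps] with eps = max(1/(N_BS+2), 1e-3) so that
    fully (un)methylated sites at finite depth stay finite.
    """
    mu = np.asarray(mu, dtype=float)
    if n_bs is None:
        eps = np.full_like(mu, 1e-3)
    else:
        eps = np.maximum(1.0 / (np.asarray(n_bs, dtype=float) + 2.0), 1e-3)
    clipped = np.clip(mu, eps, 1.0 - eps)
    return np.log2(clipped / (1.0 - clipped))


def build_observation_tracks(
    dataset: MethylationDataset,
    group1_samples: Sequence[str],
    group2_samples: Sequence[str],
    scale: str = "beta",
) -> list[ObservationTrack]:
    """Per-chromosome tracks of y = mean(mu, group1) - mean(mu, group2).

    Group means are unweighted over samples with non-zero coverage; CpGs where
    either group has no covered sample are dropped (their indices simply do
    not appear in any track).  ``scale="M"`` applies the M-value transform to
    each sample's mu before averaging.
    """
    if scale not in ("beta", "M"):
        raise ValueError(f"unknown scale '{scale}'")
    g1 = list(group1_samples)
    g2 = list(group2_samples)
    if not g1 or not g2:
        raise ValueError("both groups must be non-empty")
    if set(g1) & set(g2):
        raise ValueError("groups must be disjoint")
    unknown = (set(g1) | set(g2)) - set(dataset.sample_ids)
    if unknown:
        raise ValueError(f"unknown samples: {sorted(unknown)}")
    col = {s: j for j, s in enumerate(dataset.sample_ids)}
    i1 = [col[s] for s in g1]
    i2 = [col[s] for s in g2]

    mu = methylation_ratio(dataset.nc, dataset.nbs)
    if scale == "M":
        vals = m_transform(mu, dataset.nbs)
        vals = np.where(np.isnan(mu), np.nan, vals)
    else:
        vals = mu

    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # all-NaN groups (whole group uncovered) legitimately yield NaN means
        warnings.simplefilter("ignore", RuntimeWarning)
        mean1 = np.nanmean(vals[:, i1], axis=1)
        mean2 = np.nanmean(vals[:, i2], axis=1)
    y_all = mean1 - mean2
    keep = np.isfinite(y_all)

    tracks = []
    for chrom, idx in dataset.chrom_slices():
        sel = idx[keep[idx]]
        if len(sel) == 0:
            continue
        tracks.append(ObservationTrack(chrom=chrom, site_index=sel, y=y_all[sel], scale=scale))
    return tracks


def default_emissions(n_states: int = 3, scale: str = "beta") -> list[EmissionSpec]:
    """Default Gaussian emission parameters per hidden state.

    3-state beta scale: equal N(0, 0.08), hyper N(0.3, 0.06), hypo N(-0.3, 0.06).
    5-state beta scale adds a second, stronger hypo/hyper level at +-0.5.
    3-state M scale: equal N(0, 0.5), hyper N(1.7, 0.5), hypo N(-1.7, 0.5).
    """
    if scale == "beta":
        if n_states == 3:
            return [
                EmissionSpec("equal", 0.0, 0.08),
                EmissionSpec("hypo", -0.3, 0.06),
                EmissionSpec("hyper", 0.3, 0.06),
            ]
        if n_states == 5:
            return [
                EmissionSpec("equal", 0.0, 0.08),
                EmissionSpec("hypo1", -0.25, 0.06),
                EmissionSpec("hypo2", -0.5, 0.06),
                EmissionSpec("hyper1", 0.25, 0.06),
                EmissionSpec("hyper2", 0.5, 0.06),
            ]
    elif scale == "M":
        if n_states == 3:
            return [
                EmissionSpec("equal", 0.0, 0.5),
                EmissionSpec("hypo", -1.7, 0.5),
                EmissionSpec("hyper", 1.7, 0.5),
            ]
    raise ValueError(f"unsupported (n_states={n_states}, scale='{scale}')")


def default_model(n_states: int = 3, scale: str = "beta",
                  self_transition: float = 0.9) -> HMMModel:
    """HMM with default emissions, persistent transitions and uniform pi.

    The initial transition matrix puts ``self_transition`` on the diagonal and
    splits the rest evenly, encoding persistence of methylation state along
    the chromosome; Baum-Welch then refines it.
    """
    states = default_emissions(n_states, scale)
    k = len(states)
    off = (1.0 - self_transition) / (k - 1)
    A = np.full((k, k), off)
    np.fill_diagonal(A, self_transition)
    pi = np.full(k, 1.0 / k)
    return HMMModel(states=states, A=A, pi=pi)


def _forward_backward(model: HMMModel, y: np.ndarray):
    """Scaled forward-backward. Returns (log_lik, gamma, xi_sum, alpha1)."""
    T = len(y)
    K = model.n_states
    logB = model.log_emission(y)
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    logoff = logB.max(axis=1)
    A = model.A

    alpha = np.empty((T, K))
    c = np.empty(T)
    a = model.pi * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]

    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        xi = alpha[t][:, None] * A * (B[t + 1] * beta[t + 1])[None, :] / c[t + 1]
        xi_sum += xi

    log_lik = np.log(c).sum() + logoff.sum()
    return log_lik, gamma, xi_sum


def log_likelihood(model: HMMModel, tracks: Sequence[ObservationTrack]) -> float:
    """Total observation log-likelihood over tracks."""
    total = 0.0
    for tr in tracks:
        if len(tr) == 0:
            continue
        ll, _, _ = _forward_backward(model, tr.y)
        total += ll
    return total


def fit_transitions_baum_welch(
    model: HMMModel,
    tracks: Sequence[ObservationTrack],
    max_iter: int = 50,
    tol: float = 1e-4,
    learn_emissions: bool = False,
    min_sd: float = 1e-3,
) -> tuple[HMMModel, list[float]]:
    """Baum-Welch EM over (A, pi), optionally also the Gaussian emissions.

    With ``learn_emissions=False`` (the default) the emission parameters are
    left untouched and only the transition matrix and initial distribution are
    re-estimated.  Returns the fitted model and the per-iteration total
    log-likelihood trace (non-decreasing up to the stopping tolerance).
    """
    tracks = [tr for tr in tracks if len(tr) >= 1]
    if not tracks:
        raise ValueError("all tracks are empty")
    model = replace(model, states=[replace(s) for s in model.states],
                    A=model.A.copy(), pi=model.pi.copy())
    K = model.n_states
    ll_trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        xi_tot = np.zeros((K, K))
        gamma_from = np.zeros(K)
        pi_acc = np.zeros(K)
        m1 = np.zeros(K)
        my = np.zeros(K)
        my2 = np.zeros(K)
        total_ll = 0.0
        for tr in tracks:
            ll, gamma, xi_sum = _forward_backward(model, tr.y)
            total_ll += ll
            xi_tot += xi_sum
            gamma_from += gamma[:-1].sum(axis=0)
            pi_acc += gamma[0]
            if learn_emissions:
                m1 += gamma.sum(axis=0)
                my += gamma.T @ tr.y
                my2 += gamma.T @ (tr.y**2)
        ll_trace.append(total_ll)

        with np.errstate(invalid="ignore", divide="ignore"):
            A_new = xi_tot / np.maximum(gamma_from[:, None], 1e-300)
        # rows never visited keep their old transitions
        dead = gamma_from < 1e-12
        A_new[dead] = model.A[dead]
        A_new /= A_new.sum(axis=1, keepdims=True)
        pi_new = pi_acc / pi_acc.sum()
        states = model.states
        if learn_emissions:
            means = my / np.maximum(m1, 1e-300)
            var = my2 / np.maximum(m1, 1e-300) - means**2
            sds = np.sqrt(np.maximum(var, min_sd**2))
            states = [replace(s, mean=float(m), sd=float(sd))
                      for s, m, sd in zip(model.states, means, sds)]
        model = HMMModel(states=states, A=A_new, pi=pi_new, trained=True)

        if np.isfinite(prev_ll) and abs(total_ll - prev_ll) < tol:
            break
        prev_ll = total_ll
    return model, ll_trace


def fit_unspecified_emissions(
    tracks: Sequence[ObservationTrack],
    n_states: int = 3,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 1e-4,
    self_transition: float = 0.9,
) -> HMMModel:
    """Fit an HMM without prescribing the emission distributions.

    Gaussian emissions are initialised by k-means on the pooled y values
    (seeded), then jointly re-estimated with (A, pi) by Baum-Welch.  Fitted
    states are relabelled by the sign/magnitude of their means: the state with
    mean closest to zero becomes ``equal`` and the rest become
    ``hypo``/``hyper`` (numbered by magnitude when more than one per side).
    """
    tracks = [tr for tr in tracks if len(tr) >= 1]
    if not tracks:
        raise ValueError("all tracks are empty")
    y_all = np.concatenate([tr.y for tr in tracks])
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_states, n_init=5, random_state=seed)
    lab = km.fit_predict(y_all[:, None])
    means = km.cluster_centers_.ravel()
    sds = np.array([max(y_all[lab == j].std(), 1e-2) for j in range(n_states)])
    states = [EmissionSpec(f"s{j}", float(means[j]), float(sds[j])) for j in range(n_states)]
    k = n_states
    off = (1.0 - self_transition) / (k - 1)
    A = np.full((k, k), off)
    np.fill_diagonal(A, self_transition)
    model = HMMModel(states=states, A=A, pi=np.full(k, 1.0 / k))
    model, _ = fit_transitions_baum_welch(model, tracks, max_iter=max_iter, tol=tol,
                                          learn_emissions=True)
    return relabel_states_by_mean(model)


def relabel_states_by_mean(model: HMMModel) -> HMMModel:
    """Name states by their fitted means: near-zero -> equal, signed -> hypo/hyper."""
    means = np.array([s.mean for s in model.states])
    equal_idx = int(np.argmin(np.abs(means)))
    names = [""] * len(means)
    names[equal_idx] = "equal"
    for fam, side in (("hypo", means < means[equal_idx]), ("hyper", means > means[equal_idx])):
        idx = [i for i in np.argsort(np.abs(means)) if side[i] and i != equal_idx]
        if len(idx) == 1:
            names[idx[0]] = fam
        else:
            for rank, i in enumerate(idx, start=1):
                names[i] = f"{fam}{rank}"
    # degenerate fits can leave unnamed states; keep them distinct
    for i, n in enumerate(names):
        if not n:
            names[i] = f"equal{i}"
    seen: dict[str, int] = {}
    for i, n in enumerate(names):
        if n in seen:
            names[i] = f"{n}_{i}"
        seen[n] = i
    states = [replace(s, name=n) for s, n in zip(model.states, names)]
    return replace(model, states=states)


def viterbi_decode(model: HMMModel, track: ObservationTrack) -> list[str]:
    """Most probable hidden-state path (log-space Viterbi), one label per CpG.

    Ties are broken toward the lower state index in the model's state order.
    """
    y = np.asarray(track.y, dtype=float)
    if len(y) == 0:
        raise ValueError("empty track")
    if not np.isfinite(y).all():
        raise ValueError("non-finite observation in track")
    logB = model.log_emission(y)
    with np.errstate(divide="ignore"):
        logA = np.log(model.A)
        logpi = np.log(model.pi)
    T, K = logB.shape
    v = logpi + logB[0]
    back = np.empty((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = v[:, None] + logA  # cand[i, j]
        back[t] = np.argmax(cand, axis=0)  # first max -> lowest index wins ties
        v = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(v))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    names = model.state_names
    return [names[j] for j in path]


@dataclass
class Region:
    """Maximal run of same-state CpGs with per-sample aggregated counts."""

    chrom: str
    start_pos: int  # 1-based inclusive
    end_pos: int    # 1-based inclusive
    state: str
    site_indices: np.ndarray  # indices into the dataset
    nbs: np.ndarray  # per-sample aggregated totals, shape (n_samples,)
    nc: np.ndarray   # per-sample aggregated methylated counts

    def __post_init__(self) -> None:
        self.site_indices = np.asarray(self.site_indices, dtype=np.int64)
        self.nbs = np.asarray(self.nbs, dtype=np.int64)
        self.nc = np.asarray(self.nc, dtype=np.int64)
        if len(self.site_indices) < 1:
            raise ValueError("region must contain at least one CpG")

    @property
    def n_cpgs(self) -> int:
        """W: number of member CpGs."""
        return len(self.site_indices)


def merge_state_runs(
    dataset: MethylationDataset,
    track: ObservationTrack,
    state_sequence: Sequence[str],
) -> list[Region]:
    """Combine adjacent CpGs with the same decoded state into regions.

    Aggregates each sample's read counts over member CpGs.  Regions never
    span chromosomes because tracks are per-chromosome.
    """
    states = list(state_sequence)
    if len(states) != len(track):
        raise ValueError("state sequence length does not match track")
    pos = dataset.sites["pos"].to_numpy()
    regions: list[Region] = []
    start = 0
    for t in range(1, len(states) + 1):
        if t == len(states) or states[t] != states[start]:
            idx = track.site_index[start:t]
            regions.append(Region(
                chrom=track.chrom,
                start_pos=int(pos[idx[0]]),
                end_pos=int(pos[idx[-1]]),
                state=states[start],
                site_indices=idx,
                nbs=dataset.nbs[idx].sum(axis=0),
                nc=dataset.nc[idx].sum(axis=0),
            ))
            start = t
    return regions


def select_candidate_regions(
    regions: Sequence[Region],
    mode: str = "all",
    min_cpgs: int = 1,
    candidate_states: Sequence[str] | None = None,
) -> list[Region]:
    """Filter regions by state family and minimum CpG count.

    ``mode="hypo_hyper"`` keeps states in the hypo/hyper families (all levels
    in 5-state mode); for unspecified-emission models pass the candidate state
    names explicitly via ``candidate_states``.  ``min_cpgs=26`` reproduces the
    "> 25 CpGs" filter used for real data.
    """
    if mode not in ("all", "hypo_hyper"):
        raise ValueError(f"unknown mode '{mode}'")
    out = list(regions)
    if mode == "hypo_hyper":
        if candidate_states is not None:
            keep = set(candidate_states)
            out = [r for r in out if r.state in keep]
        else:
            out = [r for r in out if is_candidate_state(r.state)]
    return [r for r in out if r.n_cpgs >= min_cpgs]
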