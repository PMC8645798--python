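"""Synthetic longitudinal cohorts of ICA-like component time courses.

The generator emulates the kind of data a dynamic functional network
connectivity (dFNC) study consumes: per-session component time-course
matrices whose instantaneous covariance switches among a small set of
block-modular "state" correlation patterns under a Markov chain, plus
rigid-body motion traces, scanner-like nuisance (drift, spikes, noise),
and a two-visit longitudinal design with planted age and sex effects on
state dwell dynamics.  Ground truth (state paths, per-session transition
matrices, planted coefficients) is recorded so downstream estimation
stages can be validated by parameter recovery.

Covariate effects act on the log-odds of each state's self-transition
probability: positive slopes lengthen dwell times and reduce the number
of transitions, monotonically, while keeping transition rows stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .states import dwell_metrics

__all__ = [
    "StateSpec",
    "CohortDesign",
    "SimulatedSession",
    "GroundTruth",
    "build_state_covariances",
    "simulate_state_sequence",
    "simulate_session",
    "simulate_cohort",
    "default_partition",
    "default_state_specs",
    "default_design",
]

#: Canonical intrinsic-network names used for the default component partition.
NETWORK_NAMES = ("SC", "AUD", "SM", "VIS", "DMN", "CC", "CB")


@dataclass(frozen=True)
class StateSpec:
    """One recurring connectivity configuration ("dynamic state").

    Attributes
    ----------
    label : int
        State identifier, 1..K.
    correlation : ndarray, shape (C, C)
        Symmetric positive-definite correlation matrix with unit diagonal.
    partition : ndarray of int, shape (C,)
        Component -> network assignment used to build the block pattern.
    """

    label: int
    correlation: np.ndarray
    partition: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.correlation, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("correlation must be square")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("correlation must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-8):
            raise ValueError("correlation must have unit diagonal")
        w = np.linalg.eigvalsh(R)
        if w.min() <= 0:
            raise ValueError(
                f"state {self.label}: correlation not positive definite "
                f"(min eigenvalue {w.min():.3g})"
            )
        if np.abs(R - np.diag(np.diag(R))).max() >= 1.0:
            raise ValueError("off-diagonal correlation magnitude must be < 1")
        if len(self.partition) != R.shape[0]:
            raise ValueError("partition size must equal number of components")

    @property
    def n_components(self) -> int:
        return self.correlation.shape[0]


@dataclass
class CohortDesign:
    """Parameters of a two-visit longitudinal synthetic cohort.

    Ages are in years; `age_dwell_slopes` and `female_age_slopes` are per
    year of centered age on the log-odds of each state's self-transition
    probability; `sex_dwell_offsets` are additive log-odds shifts for
    girls.  `T` volumes are emitted at repetition time `TR` seconds.
    """

    n_subjects: int = 100
    visit_ages: tuple = ((10.1, 0.6), (13.9, 0.5))  # (mean, sd) per visit
    retention: float = 0.45
    sex_ratio: float = 0.5  # fraction girls
    T: int = 200
    TR: float = 1.76
    K: int = 5
    transition_base: np.ndarray | None = None
    age_dwell_slopes: np.ndarray | None = None
    sex_dwell_offsets: np.ndarray | None = None
    female_age_slopes: np.ndarray | None = None
    noise_sd: float = 0.2
    spike_rate: float = 0.002
    spike_amp: float = 4.0
    drift_slope: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if self.transition_base is None:
            self.transition_base = uniform_sticky_transitions(self.K, 0.98)
        self.transition_base = np.asarray(self.transition_base, dtype=float)
        K = self.transition_base.shape[0]
        self.K = K
        for name in ("age_dwell_slopes", "sex_dwell_offsets", "female_age_slopes"):
            v = getattr(self, name)
            v = np.zeros(K) if v is None else np.asarray(v, dtype=float)
            if v.shape != (K,):
                raise ValueError(f"{name} must have length K={K}")
            setattr(self, name, v)
        P = self.transition_base
        if (P < 0).any():
            raise ValueError("transition_base entries must be nonnegative")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition_base rows must sum to 1")
        if not (0.0 <= self.retention <= 1.0 and 0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("retention and sex_ratio must lie in [0, 1]")
        if self.T <= 0 or self.TR <= 0:
            raise ValueError("T and TR must be positive")

    @property
    def mean_age_visit1(self) -> float:
        return float(self.visit_ages[0][0])


@dataclass
class SimulatedSession:
    subject_id: str
    visit: int
    age: float
    sex: str  # "M" or "F"
    timecourses: np.ndarray  # T x C
    motion6: np.ndarray  # T x 6 (3 translations mm, 3 rotations rad)
    true_states: np.ndarray  # length T, values 1..K
    true_metrics: "object"  # SessionStateMetrics at TR resolution


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must estimate."""

    age_dwell_slopes: np.ndarray
    sex_dwell_offsets: np.ndarray
    female_age_slopes: np.ndarray
    mean_age_visit1: float
    transition_matrices: dict = field(default_factory=dict)  # (subject, visit) -> K x K


def uniform_sticky_transitions(K: int, p_stay: float) -> np.ndarray:
    """Row-stochastic matrix with constant self-transition probability."""
    if not 0.0 < p_stay < 1.0:
        raise ValueError("p_stay must be in (0, 1)")
    P = np.full((K, K), (1.0 - p_stay) / (K - 1))
    np.fill_diagonal(P, p_stay)
    return P


def default_partition(C: int = 20) -> np.ndarray:
    """Assign C components to the seven canonical networks, round-robin sizes."""
    sizes = np.full(len(NETWORK_NAMES), C // len(NETWORK_NAMES))
    sizes[: C % len(NETWORK_NAMES)] += 1
    return np.repeat(np.arange(len(NETWORK_NAMES)), sizes)


def _project_correlation(R: np.ndarray, min_eig: float = 1e-3) -> np.ndarray:
    """Clip eigenvalues at ``min_eig`` and rescale to unit diagonal."""
    R = 0.5 * (R + R.T)
    w, V = np.linalg.eigh(R)
    if w.min() < min_eig:
        w = np.clip(w, min_eig, None)
        R = (V * w) @ V.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def build_state_covariances(
    C: int,
    partition,
    within_r,
    between_r,
    seed: int | None = None,
    network_signs=None,
    network_weights=None,
    nonmodular=(),
    nonmodular_scale: float = 0.15,
    min_eig: float = 1e-3,
) -> list[StateSpec]:
    """Build K block-modular state correlation matrices.

    Parameters
    ----------
    C : int
        Number of components (>= 2).
    partition : array-like of int, length C
        Component -> network assignment.
    within_r, between_r : float or sequence of float
        Within-network and between-network correlation per state.  Scalars
        build a single state.
    network_signs : sequence of arrays, optional
        Per-state +/-1 polarity per network; the correlation between
        networks a and b is ``between_r * s[a] * s[b]``.  Distinct sign
        patterns give states distinct modular configurations (which
        networks anti-correlate), the feature that separates states under
        correlation distance.  Default: all +1.
    network_weights : sequence of arrays, optional
        Per-state participation weight in [0, 1] per network: within-block
        correlation of network a scales by w[a], between-block by
        sqrt(w[a] w[b]).  Lets each state engage a different subset of
        networks.  Default: all 1.
    nonmodular : sequence of int
        State indices (0-based) built instead as identity plus weak random
        structure of scale ``nonmodular_scale`` — the "non-modularized"
        configuration.
    min_eig : float
        Eigenvalue floor for the positive-definiteness repair
        (clip then renormalize to unit diagonal).
    """
    if C < 2:
        raise ValueError("C must be >= 2")
    partition = np.asarray(partition)
    if partition.shape != (C,):
        raise ValueError(f"partition has size {partition.size}, expected {C}")
    within_r = np.atleast_1d(np.asarray(within_r, dtype=float))
    between_r = np.atleast_1d(np.asarray(between_r, dtype=float))
    if within_r.shape != between_r.shape:
        raise ValueError("within_r and between_r must have the same length")
    if (np.abs(within_r) >= 1).any() or (np.abs(between_r) >= 1).any():
        raise ValueError("|within_r| and |between_r| must be < 1")
    K = within_r.size
    rng = np.random.default_rng(seed)
    n_networks = int(partition.max()) + 1
    same = partition[:, None] == partition[None, :]

    specs = []
    for k in range(K):
        if k in set(nonmodular):
            A = rng.uniform(-nonmodular_scale, nonmodular_scale, size=(C, C))
            R = np.eye(C) + 0.5 * (A + A.T)
            np.fill_diagonal(R, 1.0)
        else:
            if network_signs is not None:
                s = np.asarray(network_signs[k], dtype=float)
                if s.shape != (n_networks,):
                    raise ValueError("network_signs entries must have one sign per network")
            else:
                s = np.ones(n_networks)
            if network_weights is not None:
                w = np.asarray(network_weights[k], dtype=float)
                if w.shape != (n_networks,):
                    raise ValueError("network_weights entries must have one weight per network")
            else:
                w = np.ones(n_networks)
            sign = s[partition][:, None] * s[partition][None, :]
            wc = w[partition]
            within = within_r[k] * wc[:, None] * same
            between = between_r[k] * sign * np.sqrt(wc[:, None] * wc[None, :])
            R = np.where(same, within, between)
            np.fill_diagonal(R, 1.0)
        R = _project_correlation(R, min_eig=min_eig)
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError(f"state {k + 1}: projection failed to reach positive definiteness")
        specs.append(StateSpec(label=k + 1, correlation=R, partition=partition))
    return specs


def _hub_state_correlation(
    C: int,
    seed: int,
    neg_hubs=(0, 5, 12, 19),
    pos_hubs=(7,),
    hub_r: float = 0.32,
    background: float = 0.04,
) -> np.ndarray:
    """Non-modularized state: no block organization, but a few hub
    components globally anti-correlated with everything (and one globally
    positively coupled), over a weak random background — the
    configuration typically labeled "non-modularized" when such states
    are inspected."""
    rng = np.random.default_rng(seed)
    neg_hubs = [h for h in neg_hubs if h < C]
    pos_hubs = [h for h in pos_hubs if h < C]
    A = rng.uniform(-background, background, size=(C, C))
    R = np.eye(C) + 0.5 * (A + A.T)
    for i in neg_hubs:
        R[i, :] = R[:, i] = -hub_r
    for i in neg_hubs:
        for j in neg_hubs:
            R[i, j] = hub_r
    for i in pos_hubs:
        R[i, :] = R[:, i] = 0.8 * hub_r
        for j in neg_hubs:
            R[i, j] = R[j, i] = -hub_r
    np.fill_diagonal(R, 1.0)
    return _project_correlation(R)


def default_state_specs(C: int = 20, seed: int = 12345) -> list[StateSpec]:
    """The five default planted states.

    States 1-3 are fully modularized (within-network 0.5, between-network
    -0.25) and state 5 partially modularized (between -0.2); each engages
    its own subset of the seven networks with its own polarity pattern,
    so the states disagree on WHICH networks participate and
    anti-correlate (pairwise pattern correlations < 0.25), the feature
    that separates recovered states — states differing only in block
    strength would be collinear under correlation distance.  State 4 is
    non-modularized: hub components globally anti-correlated with the
    rest over a weak random background.  Columns: SC AUD SM VIS DMN CC CB.
    """
    partition = default_partition(C)
    n_net = int(partition.max()) + 1
    signs = np.array(
        [
            [-1, -1, -1, +1, +1, +1, +1],
            [-1, -1, -1, -1, +1, -1, -1],
            [+1, -1, -1, -1, +1, -1, -1],
            [+1, -1, +1, +1, -1, -1, -1],
        ],
        dtype=float,
    )
    weights = np.array(
        [
            [1.0, 1.0, 0.0, 0.0, 0.0, 1.0, 1.0],
            [0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 1.0],
            [1.0, 0.0, 0.0, 1.0, 1.0, 0.0, 1.0],
            [0.0, 1.0, 1.0, 1.0, 0.0, 1.0, 0.0],
        ]
    )
    if n_net != signs.shape[1]:  # non-default partitions: recycle columns
        idx = np.arange(n_net) % signs.shape[1]
        signs, weights = signs[:, idx], weights[:, idx]
    ones = np.ones(n_net)
    specs = build_state_covariances(
        C,
        partition,
        within_r=[0.5, 0.5, 0.5, 0.0, 0.5],
        between_r=[-0.25, -0.25, -0.25, 0.0, -0.2],
        seed=seed,
        network_signs=[signs[0], signs[1], signs[2], ones, signs[3]],
        network_weights=[weights[0], weights[1], weights[2], ones, weights[3]],
        nonmodular=(3,),
    )
    specs[3] = StateSpec(4, _hub_state_correlation(C, seed + 1), partition)
    return specs


def default_design(**overrides) -> CohortDesign:
    """Cohort design with the study-condition defaults.

    Planted effects mirror the directions reported for this age range:
    state-1 dwell time rises with age, states 3-5 fall, transitions fall,
    and girls dwell longer in state 2, shorter in states 3-4, with a
    steeper age decline in transitions.
    """
    base = dict(
        age_dwell_slopes=np.array([0.16, 0.02, -0.04, -0.04, -0.04]),
        sex_dwell_offsets=np.array([0.0, 0.20, -0.15, -0.15, 0.10]),
        female_age_slopes=np.array([0.06, 0.04, 0.0, -0.04, 0.04]),
    )
    base.update(overrides)
    return CohortDesign(**base)


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (uniform if not unique)."""
    w, V = np.linalg.eig(P.T)
    idx = np.where(np.isclose(w, 1.0, atol=1e-8))[0]
    if len(idx) != 1:
        return np.full(P.shape[0], 1.0 / P.shape[0])
    pi = np.real(V[:, idx[0]])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_state_sequence(transition: np.ndarray, T: int, seed=None) -> np.ndarray:
    """Sample a length-T Markov state path (labels 1..K).

    The first state is drawn from the stationary distribution (uniform if
    not unique).
    """
    P = np.asarray(transition, dtype=float)
    if (P < 0).any():
        raise ValueError("transition probabilities must be nonnegative")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition rows must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = P.shape[0]
    cum = np.cumsum(P, axis=1)
    u = rng.random(T)
    path = np.empty(T, dtype=np.int64)
    s = int(np.searchsorted(np.cumsum(stationary_distribution(P)), u[0], side="right"))
    s = min(s, K - 1)
    path[0] = s
    for t in range(1, T):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        s = min(s, K - 1)
        path[t] = s
    return path + 1


def simulate_session(
    specs: list[StateSpec],
    path: np.ndarray,
    design: CohortDesign,
    seed=None,
    subject_id: str = "sub-000",
    visit: int = 1,
    age: float = 10.0,
    sex: str = "M",
) -> SimulatedSession:
    """Emit one scan session following a given state path.

    At each volume the observation is a zero-mean multivariate Gaussian
    draw with the correlation of the current state; linear drift, sparse
    spikes, and white observation noise are then added.  Motion is a
    smoothed random walk at sub-QC-threshold amplitude.
    """
    path = np.asarray(path)
    K = len(specs)
    if path.min() < 1 or path.max() > K:
        raise ValueError("path entries must index into specs (1..K)")
    C = specs[0].n_components
    T = len(path)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    chol = [np.linalg.cholesky(s.correlation) for s in specs]
    Z = rng.standard_normal((T, C))
    X = np.empty_like(Z)
    for k in range(K):
        mask = path == k + 1
        if mask.any():
            X[mask] = Z[mask] @ chol[k].T

    t = np.arange(T)[:, None]
    X = X + design.drift_slope * t
    if design.spike_rate > 0:
        spikes = rng.random((T, C)) < design.spike_rate
        X = X + spikes * rng.choice([-1.0, 1.0], size=(T, C)) * design.spike_amp
    if design.noise_sd > 0:
        X = X + design.noise_sd * rng.standard_normal((T, C))

    # Smooth random walk: translations ~hundredths of mm, rotations ~1e-4 rad.
    steps = rng.standard_normal((T, 6)) * np.r_[0.02, 0.02, 0.02, 2e-4, 2e-4, 2e-4]
    from scipy.ndimage import gaussian_filter1d

    motion6 = gaussian_filter1d(np.cumsum(steps, axis=0), sigma=3.0, axis=0, mode="nearest")

    return SimulatedSession(
        subject_id=subject_id,
        visit=visit,
        age=float(age),
        sex=sex,
        timecourses=X,
        motion6=motion6,
        true_states=path,
        true_metrics=dwell_metrics(path, K),
    )


def session_transition_matrix(design: CohortDesign, age: float, sex: str) -> np.ndarray:
    """Shift self-transition log-odds by the planted covariate effects.

    Off-diagonal mass in each row is rescaled proportionally so rows stay
    stochastic.
    """
    P = design.transition_base.copy()
    age_c = age - design.mean_age_visit1
    female = 1.0 if sex == "F" else 0.0
    shift = (
        design.age_dwell_slopes * age_c
        + design.sex_dwell_offsets * female
        + design.female_age_slopes * age_c * female
    )
    K = P.shape[0]
    for k in range(K):
        p_new = float(expit(logit(P[k, k]) + shift[k]))
        off = P[k].copy()
        off[k] = 0.0
        total = off.sum()
        if total > 0:
            off *= (1.0 - p_new) / total
        P[k] = off
        P[k, k] = p_new
    return P


def simulate_cohort(
    design: CohortDesign, specs: list[StateSpec] | None = None
) -> tuple[list[SimulatedSession], GroundTruth]:
    """Simulate a two-visit longitudinal cohort with planted effects.

    Every subject has a visit-1 session; a second visit occurs with
    probability ``design.retention``.  The per-session transition matrix
    is the base matrix with each state's self-transition log-odds shifted
    by age (centered at the design's visit-1 mean age) and sex.
    """
    if specs is None:
        specs = default_state_specs(seed=design.seed + 1)
    rng = np.random.default_rng(design.seed)
    truth = GroundTruth(
        age_dwell_slopes=design.age_dwell_slopes.copy(),
        sex_dwell_offsets=design.sex_dwell_offsets.copy(),
        female_age_slopes=design.female_age_slopes.copy(),
        mean_age_visit1=design.mean_age_visit1,
    )
    sessions = []
    width = max(3, len(str(design.n_subjects)))
    for i in range(design.n_subjects):
        sid = f"sub-{i:0{width}d}"
        sex = "F" if rng.random() < design.sex_ratio else "M"
        (m1, s1), (m2, s2) = design.visit_ages
        age1 = float(rng.normal(m1, s1))
        visits = [(1, age1)]
        if rng.random() < design.retention:
            visits.append((2, float(rng.normal(m2, s2))))
        for visit, age in visits:
            P = session_transition_matrix(design, age, sex)
            truth.transition_matrices[(sid, visit)] = P
            path = simulate_state_sequence(P, design.T, seed=rng)
            sessions.append(
                simulate_session(
                    specs, path, design, seed=rng,
                    subject_id=sid, visit=visit, age=age, sex=sex,
                )
            )
    return sessions, truth
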