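"""Dynamic states: correlation-distance k-means over pooled FNC windows,
state assignment, dwell-time/transition metrics, and occurrence profiles.

Windows from every session and visit are pooled and clustered into k
recurring connectivity configurations.  The distance between a window and
a centroid is one minus the Pearson correlation of their pair-space
vectors; rows are therefore centered and unit-scaled before distance
computation, and centroids are renormalized means of their members'
normalized rows (the standard correlation-distance k-means convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClusteringConfig",
    "StatePartition",
    "SessionStateMetrics",
    "OccurrenceProfile",
    "kmeans_correlation",
    "assign_to_states",
    "dwell_metrics",
    "occurrence_profile",
]


@dataclass
class ClusteringConfig:
    k: int = 5
    n_init: int = 500
    max_iter: int = 100
    seed: int = 0
    tol: float = 1e-8

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")


@dataclass
class StatePartition:
    """Result of pooled clustering: centroids, assignments, occupancy."""

    centroids: np.ndarray  # k x n_pairs
    labels: np.ndarray  # pooled window labels, values 1..k
    inertia: float
    occupancy_global: np.ndarray  # fraction of all windows per state
    session_slices: list = field(default_factory=list)  # (session key, slice)
    inertia_trace: np.ndarray | None = None  # per-iteration inertia of best run
    kept: np.ndarray | None = None  # mask of non-constant rows actually clustered

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def assignments(self) -> dict:
        """Per-session state sequences (session key -> labels)."""
        return {key: self.labels[sl] for key, sl in self.session_slices}


@dataclass
class SessionStateMetrics:
    """Per-session state summaries: mean dwell time, transitions, occupancy."""

    mdt: np.ndarray  # mean dwell time per state, in sequence units (windows/TR)
    visited: np.ndarray  # boolean per state
    nt: int  # number of transitions
    occupancy: np.ndarray  # fraction of sequence per state


@dataclass
class OccurrenceProfile:
    freq: np.ndarray  # k x n_windows
    lo: np.ndarray | None  # bootstrap envelope (min)
    hi: np.ndarray | None  # bootstrap envelope (max)
    pct_lo: np.ndarray | None  # 2.5 percentile
    pct_hi: np.ndarray | None  # 97.5 percentile
    n_boot: int


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    """Center and unit-scale rows; raises on constant rows."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("constant rows have undefined correlation distance")
    return Xc / norms


def _constant_row_mask(X: np.ndarray) -> np.ndarray:
    return np.ptp(X, axis=1) == 0


def _lloyd(Xn: np.ndarray, init_idx: np.ndarray, max_iter: int, tol: float):
    """One correlation-distance k-means run on pre-normalized rows.

    Returns (centroids, labels, inertia, inertia_trace).  For normalized
    rows d(x, c) = 1 - x.c, so assignment is an argmax of a matrix product.
    """
    N = Xn.shape[0]
    k = len(init_idx)
    Cn = Xn[init_idx].copy()
    labels = np.zeros(N, dtype=np.int64)
    trace = []
    prev = np.inf
    for _ in range(max_iter):
        sim = Xn @ Cn.T
        labels = np.argmax(sim, axis=1)
        inertia = float(N - sim[np.arange(N), labels].sum())
        trace.append(inertia)
        # centroid update: renormalized mean of members' normalized rows
        for j in range(k):
            members = labels == j
            if not members.any():
                # seize the point farthest from its own centroid
                worst = np.argmin(sim[np.arange(N), labels])
                labels[worst] = j
                members = labels == j
            m = Xn[members].mean(axis=0)
            m = m - m.mean()
            n = np.linalg.norm(m)
            Cn[j] = Xn[members][0] if n == 0 else m / n
        if prev - inertia <= tol:
            break
        prev = inertia
    sim = Xn @ Cn.T
    labels = np.argmax(sim, axis=1)
    inertia = float(N - sim[np.arange(N), labels].sum())
    trace.append(inertia)
    return Cn, labels, inertia, np.asarray(trace)


def _exemplar_indices(X: np.ndarray, session_slices) -> np.ndarray:
    """Per-session exemplar windows: local maxima of across-pair variance.

    The variance of a window's connectivity vector peaks when the window
    sits inside a strongly patterned episode, so its local maxima over
    time are good state exemplars."""
    idx = []
    for _, sl in session_slices:
        v = X[sl].var(axis=1)
        interior = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])
        local = np.flatnonzero(interior) + 1
        if local.size == 0:
            local = np.array([int(np.argmax(v))])
        idx.extend(np.arange(sl.start, sl.stop)[local])
    return np.asarray(idx)


def kmeans_correlation(
    windows: np.ndarray,
    cfg: ClusteringConfig | None = None,
    session_slices=None,
    exemplar_init: bool = False,
) -> StatePartition:
    """Cluster pooled FNC windows into k states with correlation distance.

    The best of ``cfg.n_init`` random restarts (centroids initialized as k
    distinct rows) by total within-cluster correlation distance is kept.
    States are relabeled in descending global occupancy (state 1 most
    frequent).  Constant rows, whose correlation distance is undefined,
    are pre-filtered with a warning and assigned to the nearest state by
    Euclidean distance afterwards.

    With ``exemplar_init=True`` (requires ``session_slices``) the restarts
    run on per-session exemplar windows only (local maxima of across-pair
    variance) and the winning exemplar centroids seed a single full-data
    pass — a memory-scale shortcut; the default is the exhaustive pooled
    clustering.
    """
    cfg = cfg or ClusteringConfig()
    X = np.asarray(windows, dtype=float)
    if X.ndim != 2:
        raise ValueError("windows must be a 2-D pooled matrix")
    const = _constant_row_mask(X)
    if const.any():
        warnings.warn(f"{const.sum()} constant window rows excluded from clustering")
    kept = ~const
    Xk = X[kept]
    if Xk.shape[0] < cfg.k:
        raise ValueError(f"need at least k={cfg.k} non-constant windows, got {Xk.shape[0]}")
    Xn = _normalize_rows(Xk)

    rng = np.random.default_rng(cfg.seed)
    if exemplar_init:
        if not session_slices:
            raise ValueError("exemplar_init requires session_slices")
        ex = _exemplar_indices(X, session_slices)
        ex = ex[kept[ex]]
        # exemplar positions within the kept/normalized row set
        pos_in_kept = np.cumsum(kept) - 1
        Xe = Xn[pos_in_kept[ex]]
        if Xe.shape[0] < cfg.k:
            raise ValueError("fewer exemplars than clusters")
        best_ex = None
        for _ in range(cfg.n_init):
            init_idx = rng.choice(Xe.shape[0], size=cfg.k, replace=False)
            out = _lloyd(Xe, init_idx, cfg.max_iter, cfg.tol)
            if best_ex is None or out[2] < best_ex[2]:
                best_ex = out
        # one full pass seeded by the exemplar centroids
        seeds = np.argmax(Xn @ best_ex[0].T, axis=0)
        best = _lloyd(Xn, seeds, cfg.max_iter, cfg.tol)
    else:
        best = None
        for _ in range(cfg.n_init):
            init_idx = rng.choice(Xn.shape[0], size=cfg.k, replace=False)
            out = _lloyd(Xn, init_idx, cfg.max_iter, cfg.tol)
            if best is None or out[2] < best[2]:
                best = out
    Cn, labels_kept, inertia, trace = best

    labels = np.empty(X.shape[0], dtype=np.int64)
    labels[kept] = labels_kept
    if const.any():
        d = ((X[const][:, None, :] - Cn[None, :, :]) ** 2).sum(axis=2)
        labels[const] = np.argmin(d, axis=1)

    counts = np.bincount(labels, minlength=cfg.k)
    order = np.argsort(-counts, kind="stable")  # descending occupancy
    relabel = np.empty(cfg.k, dtype=np.int64)
    relabel[order] = np.arange(cfg.k)
    labels = relabel[labels] + 1
    centroids = Cn[order]
    occupancy = np.bincount(labels - 1, minlength=cfg.k) / len(labels)

    slices = []
    if session_slices is not None:
        slices = list(session_slices)
    return StatePartition(
        centroids=centroids,
        labels=labels,
        inertia=inertia,
        occupancy_global=occupancy,
        session_slices=slices,
        inertia_trace=trace,
        kept=kept,
    )


def assign_to_states(z: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Assign windows to the nearest centroid by correlation distance.

    Ties break toward the lower state label.  Accepts a SessionFNC-like
    object with a ``z`` attribute or a raw windows x pairs matrix.
    """
    z = np.asarray(getattr(z, "z", z), dtype=float)
    if z.ndim == 1:
        z = z[None, :]
    if z.shape[1] != centroids.shape[1]:
        raise ValueError(
            f"window dimension {z.shape[1]} does not match centroids {centroids.shape[1]}"
        )
    Xn = _normalize_rows(z)
    Cn = _normalize_rows(centroids)
    sim = Xn @ Cn.T
    return np.argmax(sim, axis=1) + 1  # argmax takes the first (lowest label) on ties


def dwell_metrics(seq, k: int) -> SessionStateMetrics:
    """Run-length summaries of one state sequence.

    mdt[s] is the mean length of maximal runs of state s (0 if unvisited);
    nt counts adjacent unequal pairs; occupancy is the fraction of the
    sequence spent in each state.
    """
    seq = np.asarray(seq)
    if seq.size == 0:
        raise ValueError("empty state sequence")
    if seq.min() < 1 or seq.max() > k:
        raise ValueError(f"state labels must lie in 1..{k}")
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.r_[0, change + 1]
    ends = np.r_[change, seq.size - 1]
    run_states = seq[starts]
    run_lengths = ends - starts + 1
    mdt = np.zeros(k)
    visited = np.zeros(k, dtype=bool)
    for s in range(1, k + 1):
        lens = run_lengths[run_states == s]
        if lens.size:
            visited[s - 1] = True
            mdt[s - 1] = lens.mean()
    occupancy = np.bincount(seq - 1, minlength=k) / seq.size
    return SessionStateMetrics(
        mdt=mdt, visited=visited, nt=int(len(starts) - 1), occupancy=occupancy
    )


def occurrence_profile(
    assignments: dict,
    subject_ids: dict,
    k: int,
    n_boot: int = 100,
    seed: int = 0,
) -> OccurrenceProfile:
    """Across-session state frequency at each window position, with a
    subject-level bootstrap (resampling subjects with all their sessions).

    ``assignments`` maps session key -> length-n_windows label sequence;
    ``subject_ids`` maps session key -> subject.  Bands are both the
    resample envelope (min/max, the spaghetti display) and 2.5/97.5
    percentiles.
    """
    keys = list(assignments)
    seqs = np.asarray([assignments[key] for key in keys])
    if seqs.ndim != 2:
        raise ValueError("all sessions must share the same number of windows")
    n_windows = seqs.shape[1]

    def freq_of(rows: np.ndarray) -> np.ndarray:
        out = np.empty((k, n_windows))
        for s in range(1, k + 1):
            out[s - 1] = (rows == s).mean(axis=0)
        return out

    freq = freq_of(seqs)
    if n_boot <= 0:
        return OccurrenceProfile(freq, None, None, None, None, 0)

    subjects = np.asarray([subject_ids[key] for key in keys])
    uniq = np.unique(subjects)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, k, n_windows))
    for b in range(n_boot):
        chosen = rng.choice(uniq, size=len(uniq), replace=True)
        rows = np.concatenate([seqs[subjects == s] for s in chosen], axis=0)
        boots[b] = freq_of(rows)
    return OccurrenceProfile(
        freq=freq,
        lo=boots.min(axis=0),
        hi=boots.max(axis=0),
        pct_lo=np.percentile(boots, 2.5, axis=0),
        pct_hi=np.percentile(boots, 97.5, axis=0),
        n_boot=n_boot,
    )
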