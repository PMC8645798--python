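"""The end-to-end analysis as a Model/Results pair.

``DynamicFNCAnalysis`` is constructed from session data (a manifest of
time-course and motion files, a list of in-memory sessions, or a fully
synthetic cohort); ``fit()`` executes motion QC, time-course cleanup,
per-session tapered-window graphical-lasso connectivity, pooled
correlation-distance k-means, per-session state metrics, and the
longitudinal mixed-model suite, returning a ``DynamicFNCResults`` that
carries every intermediate product, a ``summary()`` table, plotting
helpers, and writers for the delimited-text output bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fnc as fnc_mod
from . import io as io_mod
from . import preprocess as pp
from . import simulate as sim
from . import states as st
from . import stats as lstats

__all__ = ["SessionData", "DynamicFNCAnalysis", "DynamicFNCResults"]


@dataclass
class SessionData:
    subject_id: str
    visit: int
    age: float
    sex: str
    timecourses: np.ndarray
    motion6: np.ndarray


@dataclass
class DynamicFNCResults:
    """Fitted dynamic-state analysis.

    Attributes map to the pipeline stages: ``qc_table`` (per-session
    inclusion decisions), ``session_fnc`` (per included session, the
    windows x pairs Fisher-Z matrix and its selected penalty),
    ``partition`` (pooled k-means states), ``metrics_table`` (long outcome
    table of dwell times and transition counts), ``occurrence``
    (state-frequency-by-window-position profiles), and ``suite`` (the
    mixed-model results over outcomes).
    """

    model: "DynamicFNCAnalysis"
    qc_table: pd.DataFrame
    session_fnc: dict  # (subject, visit) -> SessionFNC
    partition: st.StatePartition
    metrics: dict  # (subject, visit) -> SessionStateMetrics
    metrics_table: pd.DataFrame
    occurrence: st.OccurrenceProfile
    suite: lstats.SuiteResults | None
    descriptives: pd.DataFrame | None
    pair_sd: dict = field(default_factory=dict)  # (subject, visit) -> PairVariability

    @property
    def k(self) -> int:
        return self.partition.k

    def summary(self) -> str:
        n_in = int(self.qc_table["include"].sum())
        lines = [
            "Dynamic functional network connectivity analysis",
            "=" * 48,
            f"Sessions: {len(self.qc_table)} scanned, {n_in} passed motion QC",
            f"States: k={self.k}, global occupancy "
            + ", ".join(
                f"state {i + 1}: {100 * o:.1f}%"
                for i, o in enumerate(self.partition.occupancy_global)
            ),
            f"Windows per session: {next(iter(self.session_fnc.values())).n_windows}"
            if self.session_fnc
            else "",
            "",
        ]
        if self.suite is not None:
            lines.append(self.suite.summary())
        return "\n".join(lines)

    def temporal_sd_table(self) -> pd.DataFrame:
        """Long per-session per-pair SD table for edgewise models."""
        rows = []
        for (sid, visit), pv in self.pair_sd.items():
            meta = self.qc_table.set_index(["subject_id", "visit"]).loc[(sid, visit)]
            for p, (i, j) in enumerate(pv.pair_index):
                rows.append((sid, visit, float(meta["age"]), meta["sex"],
                             f"{i}-{j}", float(pv.sd[p])))
        df = pd.DataFrame(rows, columns=["subject_id", "visit", "age", "sex", "pair", "value"])
        mean_age_v1 = df.loc[df["visit"] == df["visit"].min(), "age"].mean()
        df["age_c"] = df["age"] - mean_age_v1
        df["female"] = (df["sex"] == "F").astype(float)
        return df

    def bootstrap_curves(self, outcome: str, n_boot: int | None = None, seed: int = 0):
        cfg = self.model.config
        return lstats.bootstrap_curves(
            self.metrics_table,
            outcome,
            transform=self.suite.transforms.get(outcome) if self.suite else None,
            n_boot=n_boot if n_boot is not None else cfg.stats["n_boot"],
            seed=seed,
        )

    def plot_occurrence(self, ax=None):
        """State frequency over window position, bootstrap spaghetti as bands."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        x = np.arange(self.occurrence.freq.shape[1])
        for s in range(self.k):
            (line,) = ax.plot(x, self.occurrence.freq[s], label=f"state {s + 1}")
            if self.occurrence.lo is not None:
                ax.fill_between(x, self.occurrence.lo[s], self.occurrence.hi[s],
                                alpha=0.15, color=line.get_color())
        ax.set_xlabel("window position")
        ax.set_ylabel("frequency of occurrence")
        ax.legend(fontsize=8)
        return ax

    def plot_centroids(self, axes=None):
        """Centroid connectivity patterns as component x component matrices."""
        import matplotlib.pyplot as plt

        C = int((1 + np.sqrt(1 + 8 * self.partition.centroids.shape[1])) / 2)
        iu = np.triu_indices(C, k=1)
        if axes is None:
            _, axes = plt.subplots(1, self.k, figsize=(3 * self.k, 3))
        for s, ax in zip(range(self.k), np.atleast_1d(axes)):
            M = np.zeros((C, C))
            M[iu] = self.partition.centroids[s]
            M = M + M.T
            vmax = np.abs(M).max() or 1.0
            ax.imshow(M, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
            ax.set_title(f"state {s + 1}", fontsize=9)
        return axes

    def save(self, outdir, seed: int = 0) -> None:
        """Write the delimited-text output bundle and the run log."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.qc_table.to_csv(outdir / "qc_table.tsv", sep="\t", index=False)
        fnc_dir = outdir / "session_fnc"
        fnc_dir.mkdir(exist_ok=True)
        lam_rows = []
        for (sid, visit), f in self.session_fnc.items():
            io_mod.write_timecourse_matrix(
                fnc_dir / f"{sid}_visit{visit}_fnc_z.tsv",
                f.z,
                [f"pair_{i}_{j}" for i, j in f.pair_index],
            )
            lam_rows.append((sid, visit, f.lambda_selected))
        pd.DataFrame(lam_rows, columns=["subject_id", "visit", "lambda_selected"]).to_csv(
            outdir / "session_lambda.tsv", sep="\t", index=False
        )
        if self.session_fnc:
            any_fnc = next(iter(self.session_fnc.values()))
            pd.DataFrame(any_fnc.pair_index, columns=["component_i", "component_j"]).to_csv(
                outdir / "pair_index.tsv", sep="\t", index=False
            )
            io_mod.write_timecourse_matrix(
                outdir / "state_centroids.tsv",
                self.partition.centroids,
                [f"pair_{i}_{j}" for i, j in any_fnc.pair_index],
            )
        self.metrics_table.to_csv(outdir / "metrics_table.tsv", sep="\t", index=False)
        occ_rows = []
        for s in range(self.k):
            for w in range(self.occurrence.freq.shape[1]):
                occ_rows.append(
                    (s + 1, w, self.occurrence.freq[s, w],
                     self.occurrence.pct_lo[s, w] if self.occurrence.pct_lo is not None else np.nan,
                     self.occurrence.pct_hi[s, w] if self.occurrence.pct_hi is not None else np.nan)
                )
        pd.DataFrame(occ_rows, columns=["state", "window", "freq", "lo", "hi"]).to_csv(
            outdir / "occurrence_profile.tsv", sep="\t", index=False
        )
        if self.suite is not None:
            self.suite.base_table.to_csv(outdir / "stats_base_models.tsv", sep="\t", index=False)
            self.suite.interaction_table.to_csv(
                outdir / "stats_interaction_models.tsv", sep="\t", index=False
            )
            self.suite.stratified_table.to_csv(
                outdir / "stats_stratified_models.tsv", sep="\t", index=False
            )
            self.suite.lr_tests.to_csv(outdir / "stats_lr_tests.tsv", sep="\t", index=False)
        if self.descriptives is not None:
            self.descriptives.to_csv(outdir / "stats_descriptive_tests.tsv", sep="\t", index=False)
        io_mod.write_run_log(
            outdir / "run_log.yaml",
            self.model.config,
            seed,
            {
                "sessions_scanned": len(self.qc_table),
                "sessions_included": int(self.qc_table["include"].sum()),
                "sessions_excluded_motion": int((~self.qc_table["include"]).sum()),
                "windows_per_session": next(iter(self.session_fnc.values())).n_windows
                if self.session_fnc else 0,
            },
        )


class DynamicFNCAnalysis:
    """Dynamic-state analysis model over a cohort of scan sessions.

    Parameters
    ----------
    sessions : list of SessionData
        Component time courses and motion traces per (subject, visit).
    config : PipelineConfig, optional
        Study parameters; defaults reproduce the reference conditions.
    """

    def __init__(self, sessions, config: io_mod.PipelineConfig | None = None):
        self.sessions = list(sessions)
        self.config = config or io_mod.PipelineConfig()
        self.truth = None  # populated by from_synthetic

    @classmethod
    def from_manifest(cls, manifest_path, config=None) -> "DynamicFNCAnalysis":
        manifest = io_mod.read_manifest(manifest_path)
        root = Path(manifest_path).parent
        sessions = []
        for row in manifest.itertuples(index=False):
            ts, _ = io_mod.read_timecourse_matrix(root / row.timecourse_path)
            motion = io_mod.read_motion(root / row.motion_path)
            sessions.append(
                SessionData(str(row.subject_id), int(row.visit), float(row.age_years),
                            str(row.sex), ts, motion)
            )
        return cls(sessions, config)

    @classmethod
    def from_synthetic(cls, design: sim.CohortDesign | None = None, specs=None,
                       config=None, seed: int | None = None) -> "DynamicFNCAnalysis":
        design = design or sim.default_design()
        if seed is not None:
            design.seed = seed
        sim_sessions, truth = sim.simulate_cohort(design, specs)
        sessions = [
            SessionData(s.subject_id, s.visit, s.age, s.sex, s.timecourses, s.motion6)
            for s in sim_sessions
        ]
        obj = cls(sessions, config)
        if obj.config.TR != design.TR:
            obj.config.TR = design.TR
        obj.truth = truth
        obj._sim_sessions = sim_sessions
        return obj

    # -- pipeline stages ----------------------------------------------------

    def run_qc(self) -> pd.DataFrame:
        qc_cfg = self.config.qc_config()
        rows = []
        for s in self.sessions:
            fd = pp.framewise_displacement(s.motion6, qc_cfg.head_radius)
            d = pp.motion_qc(fd, qc_cfg)
            rows.append((s.subject_id, s.visit, s.age, s.sex, d.mean_fd, d.frac_above,
                         d.include, d.reason))
        return pd.DataFrame(
            rows,
            columns=["subject_id", "visit", "age", "sex", "mean_fd", "frac_above",
                     "include", "reason"],
        )

    def preprocess_session(self, s: SessionData) -> np.ndarray:
        conf = pp.expand_confounds(s.motion6)
        return pp.preprocess_timecourses(
            s.timecourses, conf, self.config.filter_spec(),
            n_drop=self.config.preprocess["n_drop"],
            despike_k=self.config.preprocess["despike_k"],
        )

    def fit(self, seed: int | None = None, run_stats: bool = True,
            occurrence_boot: int = 100, progress: bool = False) -> DynamicFNCResults:
        """Run the full pipeline and fit the longitudinal models."""
        cfg = self.config
        if seed is not None:
            cfg.clustering["seed"] = int(seed)
        qc_table = self.run_qc()
        included = [
            s for s, ok in zip(self.sessions, qc_table["include"]) if ok
        ]

        glasso_cfg = cfg.glasso_config()
        session_fnc, pair_sd, slices, subj_of = {}, {}, [], {}
        pooled, pos = [], 0
        spec = None
        for s in included:
            clean = self.preprocess_session(s)
            if spec is None:
                spec = cfg.taper(T_prime=clean.shape[0])
            lam = fnc_mod.select_lambda(clean, glasso_cfg)
            f = fnc_mod.compute_session_fnc(
                clean, spec, lam, glasso_tol=glasso_cfg.tol,
                glasso_max_iter=glasso_cfg.max_iter,
            )
            key = (s.subject_id, s.visit)
            session_fnc[key] = f
            pair_sd[key] = fnc_mod.temporal_sd(f)
            pooled.append(f.z)
            slices.append((key, slice(pos, pos + f.n_windows)))
            subj_of[key] = s.subject_id
            pos += f.n_windows
            if progress:
                print(f"  fnc {key}: lambda={lam:.3g}")

        partition = st.kmeans_correlation(
            np.vstack(pooled), cfg.clustering_config(), session_slices=slices
        )
        assignments = partition.assignments
        metrics = {key: st.dwell_metrics(seq, partition.k)
                   for key, seq in assignments.items()}
        occurrence = st.occurrence_profile(
            assignments, subj_of, partition.k, n_boot=occurrence_boot,
            seed=cfg.clustering["seed"],
        )

        meta = [(s.subject_id, s.visit, s.age, s.sex) for s in included]
        metrics_table = lstats.outcome_table_from_metrics(
            meta, [metrics[(m[0], m[1])] for m in meta], partition.k
        )
        suite = descr = None
        if run_stats:
            outcomes = [f"mdt_state{i + 1}" for i in range(partition.k)] + ["n_transitions"]
            suite = lstats.model_suite(
                metrics_table, outcomes, alpha=cfg.stats["fdr_alpha"],
                boxcox=cfg.stats["boxcox"],
            )
            descr = lstats.descriptive_tests(metrics_table)
        return DynamicFNCResults(
            model=self,
            qc_table=qc_table,
            session_fnc=session_fnc,
            partition=partition,
            metrics=metrics,
            metrics_table=metrics_table,
            occurrence=occurrence,
            suite=suite,
            descriptives=descr,
            pair_sd=pair_sd,
        )
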