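"""Delimited-text formats, pipeline configuration, and the run log.

Every artifact the pipeline reads or writes is plain delimited text
(tab-separated with a header row) so downstream use is language
agnostic: component time-course matrices, motion files, the cohort
manifest, QC tables, per-session FNC matrices, centroids, metrics and
statistics tables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fnc import GlassoConfig, TaperedWindowSpec, build_taper
from .preprocess import FilterSpec, QCConfig
from .states import ClusteringConfig

__all__ = [
    "read_timecourse_matrix",
    "write_timecourse_matrix",
    "read_motion",
    "write_motion",
    "read_manifest",
    "write_manifest",
    "write_cohort",
    "PipelineConfig",
    "write_run_log",
    "read_run_log",
]


def read_timecourse_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a T x C delimited text matrix with a header of component labels.

    Raises a parse error naming the offending row/column for ragged rows
    or non-numeric cells; rejects non-finite values.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        labels = header.split("\t")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(labels):
                raise ValueError(
                    f"{path.name}:{lineno}: expected {len(labels)} columns, got {len(cells)}"
                )
            row = []
            for ci, cell in enumerate(cells):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path.name}:{lineno}: non-numeric value {cell!r} "
                        f"in column {ci + 1} ({labels[ci]})"
                    ) from None
            rows.append(row)
    X = np.asarray(rows, dtype=float)
    if X.size == 0:
        raise ValueError(f"{path.name}: empty matrix body")
    if not np.isfinite(X).all():
        raise ValueError(f"{path.name}: non-finite entries")
    return X, labels


def write_timecourse_matrix(path, X: np.ndarray, labels=None) -> None:
    X = np.asarray(X)
    if labels is None:
        labels = [f"IC{i + 1}" for i in range(X.shape[1])]
    with open(path, "w") as fh:
        fh.write("\t".join(labels) + "\n")
        np.savetxt(fh, X, fmt="%.10g", delimiter="\t")


MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def read_motion(path) -> np.ndarray:
    X, labels = read_timecourse_matrix(path)
    if X.shape[1] != 6:
        raise ValueError(f"{Path(path).name}: motion file must have 6 columns")
    return X


def write_motion(path, motion6: np.ndarray) -> None:
    write_timecourse_matrix(path, motion6, MOTION_COLUMNS)


MANIFEST_COLUMNS = ["subject_id", "visit", "age_years", "sex", "timecourse_path", "motion_path"]


def read_manifest(path, check_paths: bool = True) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df.duplicated(["subject_id", "visit"]).any():
        raise ValueError("manifest has duplicate (subject, visit) rows")
    if (df["age_years"] <= 0).any():
        raise ValueError("ages must be positive")
    if check_paths:
        for col in ("timecourse_path", "motion_path"):
            for p in df[col]:
                full = path.parent / p
                if not full.exists():
                    raise FileNotFoundError(f"manifest references missing file: {p}")
    return df


def write_manifest(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_cohort(sessions, truth, outdir) -> Path:
    """Write a simulated cohort as text files plus manifest and truth tables."""
    outdir = Path(outdir)
    (outdir / "timecourses").mkdir(parents=True, exist_ok=True)
    (outdir / "motion").mkdir(exist_ok=True)
    rows, truth_rows = [], []
    for s in sessions:
        stem = f"{s.subject_id}_visit{s.visit}"
        tc = f"timecourses/{stem}_timecourses.tsv"
        mo = f"motion/{stem}_motion.tsv"
        write_timecourse_matrix(outdir / tc, s.timecourses)
        write_motion(outdir / mo, s.motion6)
        rows.append((s.subject_id, s.visit, s.age, s.sex, tc, mo))
        m = s.true_metrics
        for k in range(len(m.mdt)):
            truth_rows.append((s.subject_id, s.visit, f"true_mdt_state{k + 1}", m.mdt[k]))
        truth_rows.append((s.subject_id, s.visit, "true_n_transitions", m.nt))
    write_manifest(outdir / "manifest.tsv", pd.DataFrame(rows, columns=MANIFEST_COLUMNS))
    pd.DataFrame(truth_rows, columns=["subject_id", "visit", "quantity", "value"]).to_csv(
        outdir / "ground_truth_metrics.tsv", sep="\t", index=False
    )
    coef = pd.DataFrame(
        {
            "state": np.arange(1, len(truth.age_dwell_slopes) + 1),
            "age_dwell_slope": truth.age_dwell_slopes,
            "sex_dwell_offset": truth.sex_dwell_offsets,
            "female_age_slope": truth.female_age_slopes,
        }
    )
    coef.to_csv(outdir / "ground_truth_coefficients.tsv", sep="\t", index=False)
    return outdir / "manifest.tsv"


@dataclass
class PipelineConfig:
    """One structured configuration for the whole pipeline.

    Defaults are the study conditions: W=25 TR windows in steps of 1 with
    a sigma=3 TR taper, per-session cross-validated graphical-lasso
    penalty, k=5 states with 500 k-means restarts, 0.15 Hz fifth-order
    low-pass at TR=1.76 s, first 4 volumes dropped, FD exclusion at
    0.25 mm mean / 20% of volumes above 0.2 mm.
    """

    window: dict = field(default_factory=lambda: dict(W=25, step=1, sigma=3.0))
    glasso: dict = field(
        default_factory=lambda: dict(
            grid_min=0.01, grid_max=0.5, grid_size=12, n_folds=5, tol=1e-3, max_iter=200
        )
    )
    clustering: dict = field(default_factory=lambda: dict(k=5, n_init=500, seed=0))
    preprocess: dict = field(
        default_factory=lambda: dict(n_drop=4, cutoff_hz=0.15, order=5, despike_k=5.0)
    )
    qc: dict = field(
        default_factory=lambda: dict(
            mean_fd_max=0.25, fd_spike_thresh=0.2, spike_frac_max=0.20, head_radius=50.0
        )
    )
    stats: dict = field(
        default_factory=lambda: dict(boxcox=True, fdr_alpha=0.05, n_boot=2000)
    )
    TR: float = 1.76

    def qc_config(self) -> QCConfig:
        return QCConfig(**self.qc)

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(order=self.preprocess["order"],
                          cutoff_hz=self.preprocess["cutoff_hz"], TR=self.TR)

    def glasso_config(self) -> GlassoConfig:
        g = self.glasso
        return GlassoConfig(
            lambda_grid=np.geomspace(g["grid_min"], g["grid_max"], g["grid_size"]),
            n_folds=g["n_folds"], tol=g["tol"], max_iter=g["max_iter"],
        )

    def clustering_config(self) -> ClusteringConfig:
        return ClusteringConfig(**self.clustering)

    def taper(self, T_prime: int) -> TaperedWindowSpec:
        return build_taper(W=self.window["W"], sigma=self.window["sigma"],
                           step=self.window["step"], T_prime=T_prime)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def write_run_log(path, config: PipelineConfig, seed: int, stage_counts: dict) -> None:
    """Record everything needed to reconstruct the run: full config, seed,
    package version, and per-stage session accounting."""
    from . import __version__

    payload = {
        "dfnckit_version": __version__,
        "seed": int(seed),
        "config": config.to_dict(),
        "stage_counts": {k: int(v) for k, v in stage_counts.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_run_log(path) -> dict:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    payload["config"] = PipelineConfig.from_dict(payload["config"])
    return payload
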