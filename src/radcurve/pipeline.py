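"""End-to-end orchestration: TPS input -> sliding GPA -> relative warps ->
group tests -> tables, plots and a reproducible run manifest.

Two built-in presets mirror the study design: an extant-only scheme (taxon
groups of living species) and a terrestrial scheme (sprawled/parasagittal
extant groups plus extinct clades).  They differ only in which group-table
column is used and which groups are excluded (e.g. marine and winged taxa
for the terrestrial analysis); exclusions are a config list, not hard-coded
taxonomy.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inference import (
    PairwiseMatrix,
    kruskal_wallis_mc,
    multivariate_k,
    pairwise_shape_tests,
)
from .superimposition import GeneralizedProcrustesAnalysis
from .tps_io import (
    LandmarkConfiguration,
    SpecimenRecord,
    load_dataset,
    stack_configurations,
    write_tps,
)
from .warps import RelativeWarps, broken_stick

logger = logging.getLogger("radcurve")

__all__ = ["RunConfig", "run_full_analysis", "make_tables", "parse_table"]

FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    tps_path: str
    group_csv: str
    scheme_column: str
    seed: int
    output_dir: str
    angle_csv: str | None = None
    angle_column: str = "angle_deg"
    angle_group_column: str | None = None  # defaults to scheme_column
    tree_path: str | None = None
    slide: bool = True
    include_uniform: bool = True
    n_permutations: int = 1999
    alpha: float = 0.05
    exclude_groups: list = field(default_factory=list)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def validate(self) -> None:
        for p in (self.tps_path, self.group_csv, self.angle_csv, self.tree_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _stage(name, manifest):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is not None:
                manifest["failed_stage"] = name
                logger.error("stage %s: FAILED after %.2fs", name, dt)
                raise RuntimeError(f"pipeline stage {name!r} failed") from exc
            manifest["stages"].append({"name": name, "seconds": round(dt, 3)})
            logger.info("stage %s: done in %.2fs", name, dt)

    return _Ctx()


def run_full_analysis(config: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle.

    Outputs (all under ``config.output_dir``): aligned TPS, relative-warp
    score CSV, variance table with broken-stick expectations, pairwise shape
    and angle test matrices, an ordination plot with per-group convex hulls,
    and a JSON manifest (versions, seed, config hash, warnings).
    Bit-identical numeric outputs under identical config + seed.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "radcurve_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "stages": [],
        "warnings": [],
        "outputs": {},
    }
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        with _stage("load", manifest):
            records, table = load_dataset(config.tps_path, config.group_csv)
            if table is None or config.scheme_column not in table.columns:
                raise ValueError(f"scheme column {config.scheme_column!r} missing")
            groups = table[config.scheme_column]
            keep = [
                r
                for r in records
                if r.specimen_id in groups.index
                and pd.notna(groups.loc[r.specimen_id])
                and groups.loc[r.specimen_id] not in config.exclude_groups
            ]
            if len(keep) < 3:
                raise ValueError("fewer than 3 usable specimens after filtering")
            X = stack_configurations(keep)
            labels = np.array([groups.loc[r.specimen_id] for r in keep])
            ids = [r.specimen_id for r in keep]

        with _stage("superimposition", manifest):
            gpa_est = GeneralizedProcrustesAnalysis(slide=config.slide)
            gpa_est.fit(X)
            aligned_recs = [
                SpecimenRecord(
                    specimen_id=i, configuration=LandmarkConfiguration(a)
                )
                for i, a in zip(ids, gpa_est.aligned_)
            ]
            write_tps(aligned_recs, out / "aligned.tps")
            long = pd.DataFrame(
                {
                    "specimen_id": np.repeat(ids, X.shape[1]),
                    "landmark_index": np.tile(np.arange(X.shape[1]), len(ids)),
                    "x": gpa_est.aligned_[:, :, 0].ravel(),
                    "y": gpa_est.aligned_[:, :, 1].ravel(),
                }
            )
            long.to_csv(out / "aligned_long.csv", index=False, float_format=FLOAT_FMT)
            pd.DataFrame(
                {
                    "specimen_id": ids,
                    "distance_to_consensus": gpa_est.distances_,
                    "iterations": gpa_est.n_iter_,
                    "converged": gpa_est.converged_,
                }
            ).to_csv(out / "gpa_summary.csv", index=False, float_format=FLOAT_FMT)

        with _stage("relative_warps", manifest):
            rw = RelativeWarps(include_uniform=config.include_uniform)
            rw.fit(gpa_est.aligned_, consensus=gpa_est.consensus_)
            n_axes = min(len(ids) - 1, rw.scores_.shape[1])
            score_df = pd.DataFrame(
                rw.scores_[:, :n_axes],
                index=pd.Index(ids, name="specimen_id"),
                columns=[f"RW{i + 1}" for i in range(n_axes)],
            )
            score_df.to_csv(out / "rw_scores.csv", float_format=FLOAT_FMT)
            bs = rw.broken_stick_expectation()
            var_df = pd.DataFrame(
                {
                    "axis": [f"RW{i + 1}" for i in range(n_axes)],
                    "proportion": rw.explained_variance_ratio_[:n_axes],
                    "percent": 100 * rw.explained_variance_ratio_[:n_axes],
                    "broken_stick_expectation": bs[:n_axes],
                }
            )
            var_df.to_csv(out / "variance_table.csv", index=False, float_format=FLOAT_FMT)

        with _stage("pairwise_shape_tests", manifest):
            battery = pairwise_shape_tests(
                X,
                labels,
                n_permutations=config.n_permutations,
                seed=config.seed,
                base_alpha=config.alpha,
                slide=False,
            )
            battery.statistic_frame().to_csv(out / "pairwise_F.csv", float_format=FLOAT_FMT)
            battery.p_frame().to_csv(out / "pairwise_p.csv", float_format=FLOAT_FMT)
            (out / "pairwise_table.txt").write_text(make_tables(battery))

        angle_battery = None
        if config.angle_csv is not None:
            with _stage("angle_tests", manifest):
                from .curvature import read_angle_table

                adf = read_angle_table(config.angle_csv)
                gcol = config.angle_group_column or "group"
                angle_battery = kruskal_wallis_mc(
                    adf[config.angle_column].to_numpy(),
                    adf[gcol].to_numpy(),
                    alpha=config.alpha,
                )
                angle_battery.p_frame().to_csv(out / "angle_pairwise_p.csv", float_format=FLOAT_FMT)
                (out / "angle_table.txt").write_text(make_tables(angle_battery))

        signal = None
        if config.tree_path is not None:
            with _stage("phylogenetic_signal", manifest):
                taxa = [r.taxon or r.specimen_id for r in keep]
                sig_scores = score_df.copy()
                sig_scores.index = taxa
                signal = multivariate_k(
                    config.tree_path,
                    sig_scores.iloc[:, : min(5, n_axes)],
                    n_permutations=min(config.n_permutations, 999),
                    seed=config.seed,
                )
                pd.DataFrame(
                    {
                        "axis": list(signal["per_axis"].keys()),
                        "K": [r.statistic for r in signal["per_axis"].values()],
                        "p": [r.p_value for r in signal["per_axis"].values()],
                    }
                ).to_csv(out / "phylo_signal.csv", index=False, float_format=FLOAT_FMT)

        with _stage("plots", manifest):
            _hull_plot(score_df, labels, out / "rw_scatter.svg")

        caught = sorted({str(w.message) for w in wrec})

    manifest["warnings"] = caught
    manifest["outputs"] = {p.name: p.name for p in sorted(out.iterdir())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "gpa": gpa_est,
        "relative_warps": rw,
        "pairwise": battery,
        "angles": angle_battery,
        "signal": signal,
        "scores": score_df,
        "variance_table": var_df,
        "output_dir": out,
        "manifest": manifest,
    }


def _hull_plot(score_df: pd.DataFrame, labels: np.ndarray, path: Path) -> None:
    """RW1 vs RW2 scatter with per-group convex hulls (SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.spatial import ConvexHull, QhullError

    fig, ax = plt.subplots(figsize=(6, 5))
    if score_df.shape[1] >= 2:
        for g in pd.unique(labels):
            pts = score_df.loc[labels == g, ["RW1", "RW2"]].to_numpy()
            (line,) = ax.plot(pts[:, 0], pts[:, 1], "o", label=str(g), ms=4)
            if len(pts) >= 3:
                try:
                    hull = ConvexHull(pts)
                    cyc = np.append(hull.vertices, hull.vertices[0])
                    ax.plot(pts[cyc, 0], pts[cyc, 1], "-", color=line.get_color(), lw=1, alpha=0.5)
                except QhullError:
                    pass
        ax.set_xlabel("RW1")
        ax.set_ylabel("RW2")
        ax.legend(fontsize=8)
    fig.savefig(path, format="svg")
    plt.close(fig)


def make_tables(matrix: PairwiseMatrix) -> str:
    """Lower-triangle CSV-style text table: F values with '*' on cells
    significant at the shared Bonferroni alpha, blanks elsewhere on the
    diagonal and upper triangle.
    """
    labels = matrix.labels
    lines = ["," + ",".join(str(l) for l in labels)]
    for i, a in enumerate(labels):
        cells = [str(a)]
        for j, b in enumerate(labels):
            if j >= i:
                cells.append("")
                continue
            res = matrix.get(a, b)
            if res is None:
                cells.append("NA")
                continue
            star = "*" if res.p_value < matrix.alpha_corrected else ""
            cells.append(f"{res.statistic:.12g}{star}")
        lines.append(",".join(cells))
    return "\n".join(lines) + "\n"


def parse_table(text: str) -> pd.DataFrame:
    """Parse a table emitted by :func:`make_tables` back to a numeric frame.

    Returns a DataFrame of F values (NaN off the lower triangle) with a
    boolean companion column convention: '*' suffixes are stripped.
    """
    lines = [ln for ln in text.strip().splitlines()]
    header = lines[0].split(",")[1:]
    data = np.full((len(header), len(header)), np.nan)
    for i, ln in enumerate(lines[1:]):
        cells = ln.split(",")[1:]
        for j, cell in enumerate(cells):
            cell = cell.strip().rstrip("*")
            if cell and cell != "NA":
                data[i, j] = float(cell)
    return pd.DataFrame(data, index=header, columns=header)
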