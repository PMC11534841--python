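"""End-to-end analysis: one call from annotation table to full report bundle."""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .agreement import LoamAgreement, subject_stats
from .data import AnnotationMatrix, read_annotations, write_table
from .regression import build_regression_frame, regression_table
from .strata import stratify_quartiles, stratum_report
from .synthetic import SyntheticConfig, generate
from .window import SlidingWindowLoam
from .plots import plot_agreement, plot_window_curve

__all__ = ["RunConfig", "ReportBundle", "run_full_analysis"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run needs; recorded in the provenance log."""

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    alpha: float = 0.05
    window_width: int = 26
    threshold_pct: float = 20.0
    crossing_bound: str = "upper"
    n_boot: int = 10_000
    exclude_cysts: bool = True  # also emit the cyst-excluded sensitivity tables
    finite_observer_correction: bool = True
    seed: int = 0
    out_dir: str = "volagree_report"
    make_figures: bool = True

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of input_path or synthetic config")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha out of range")
        if self.window_width < 4:
            raise ValueError("window width must be ≥ 4")
        if self.threshold_pct <= 0:
            raise ValueError("threshold must be positive")

    def provenance(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return {
            "config": d,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "volagree_version": __version__,
        }


@dataclass
class ReportBundle:
    """In-memory results of one full run (tables also written to out_dir)."""

    subject_stats: pd.DataFrame
    overall: pd.DataFrame
    strata: pd.DataFrame
    strata_excluded: pd.DataFrame | None
    curve: pd.DataFrame
    crossing_volume: float | None
    regression: pd.DataFrame
    out_dir: Path
    files: list[str] = field(default_factory=list)


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Run every analysis stage and write the report bundle to disk.

    Stages: cohort input (read or simulate) → per-subject statistics →
    whole-cohort and per-quartile agreement tables (inclusive and
    cyst-excluded) → sliding-window curve with threshold crossing →
    covariate regression → figures → provenance log.  Any stage failure
    aborts with the stage named and the partially written bundle removed.
    """
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if config.input_path is not None:
            matrix = read_annotations(config.input_path)
        else:
            matrix, truth = generate(config.synthetic, seed=config.seed)
            write_table(matrix.to_long(), out / "annotations.csv")
            truth_df = pd.DataFrame(
                {"subject": list(matrix.subject_ids), "true_volume": truth["V"],
                 "cyst": truth["cyst"]}
            )
            write_table(truth_df, out / "annotations_truth.csv")

        stage = "subject_stats"
        stats_df = subject_stats(matrix)
        write_table(stats_df.rename_axis("subject").reset_index(), out / "subject_stats.csv")

        stage = "agreement"
        loam_kwargs = dict(
            alpha=config.alpha,
            n_boot=config.n_boot,
            finite_observer_correction=config.finite_observer_correction,
        )
        overall = LoamAgreement(random_state=config.seed, **loam_kwargs).fit(matrix)
        overall_df = pd.DataFrame([{"stratum": "all", "n_subjects": matrix.n_subjects,
                                    **overall.to_result().to_dict()}])
        assignment = stratify_quartiles(stats_df["mean_volume"])
        strata_df = stratum_report(matrix, assignment, exclude_cysts=False,
                                   random_state=config.seed, **loam_kwargs)
        write_table(pd.concat([overall_df, strata_df], ignore_index=True),
                    out / "loam_quartiles.csv")
        strata_excl = None
        if config.exclude_cysts:
            strata_excl = stratum_report(matrix, assignment, exclude_cysts=True,
                                         random_state=config.seed, **loam_kwargs)
            write_table(strata_excl, out / "loam_quartiles_excluding_cysts.csv")

        stage = "sliding_window"
        sw = SlidingWindowLoam(
            width=config.window_width,
            threshold_pct=config.threshold_pct,
            bound=config.crossing_bound,
            alpha=config.alpha,
            n_boot=min(config.n_boot, 2000),
            random_state=config.seed,
        ).fit(matrix)
        write_table(sw.curve_.table, out / "window_curve.csv")

        stage = "regression"
        frame = build_regression_frame(matrix, stats_df)
        reg = regression_table(frame, alpha=config.alpha, selection_alpha=config.alpha)
        write_table(reg, out / "regression.csv")

        files = ["subject_stats.csv", "loam_quartiles.csv", "window_curve.csv",
                 "regression.csv"]
        if config.exclude_cysts:
            files.append("loam_quartiles_excluding_cysts.csv")

        if config.make_figures:
            stage = "figures"
            fig = plot_agreement(matrix, assignment, strata_df, config.threshold_pct)
            fig.savefig(out / "agreement_quartiles.png", dpi=150)
            fig2 = plot_window_curve(sw.curve_, config.threshold_pct, sw.crossing_volume_)
            fig2.savefig(out / "window_curve.png", dpi=150)
            files += ["agreement_quartiles.png", "window_curve.png"]

        stage = "provenance"
        prov = config.provenance()
        prov["crossing_volume_mm3"] = sw.crossing_volume_
        prov["n_subjects"] = matrix.n_subjects
        prov["n_observers"] = matrix.n_observers
        with open(out / "provenance.json", "w") as fh:
            json.dump(prov, fh, indent=2, default=str)
        files.append("provenance.json")
    except Exception as exc:
        # remove partial outputs so a failed run leaves no half-written bundle
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"analysis stage {stage!r} failed: {exc}") from exc

    return ReportBundle(
        subject_stats=stats_df,
        overall=overall_df,
        strata=strata_df,
        strata_excluded=strata_excl,
        curve=sw.curve_.table,
        crossing_volume=sw.crossing_volume_,
        regression=reg,
        out_dir=out,
        files=files,
    )
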