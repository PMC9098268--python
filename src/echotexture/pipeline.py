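"""End-to-end orchestration: simulate -> extract -> screen -> rank ->
evaluate, with one master seed fanned out to per-stage child seeds so that
every run is bit-reproducible and stages can be re-run independently.

Artifacts written to the output directory:

* ``images/``        PNG rasters plus ``manifest.csv``
* ``features_R.csv`` / ``features_T.csv``  feature tables (one row per image)
* ``screening_R.csv`` / ``screening_T.csv``  per-feature screen statistics
* ``ranked_R.csv`` / ``ranked_T.csv``  top-10 Relief-F rankings
* ``sweep_R.csv`` / ``sweep_T.csv``  accuracy-vs-k sweep rows
* ``report.csv``     per-classifier training/test metrics at the best k
* ``sweep_R.png`` / ``sweep_T.png``  accuracy-vs-k curves
* ``scatter.png``    2-feature scatter of the two top-ranked features
* ``summary.json``   machine-readable metrics + resolved config + seeds
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureConfig, extract_all
from .harness import ProtocolResult, run_full_protocol
from .registry import FEATURE_NAMES
from .synthetic import CohortSpec, SpeckleParams

__all__ = ["RunConfig", "extract_table", "run"]


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one pipeline run."""

    out_dir: str = "echotexture_run"
    master_seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    speckle: SpeckleParams = field(default_factory=SpeckleParams)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    alpha: float = 0.05
    relieff_k: int = 5
    top_n: int = 10
    k_max: int = 10
    train_counts: tuple[int, int] = (50, 38)
    include_loocv: bool = True
    write_images: bool = True
    write_plots: bool = True

    def child_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds derived from the master seed."""
        ss = np.random.SeedSequence(self.master_seed)
        cohort, split, clf = (int(s.generate_state(1)[0]) % (2**31) for s in ss.spawn(3))
        return {"cohort": cohort, "split": split, "classifier": clf}

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["seeds"] = self.child_seeds()
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("seeds", None)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortSpec(**d["cohort"])
        if "speckle" in d and isinstance(d["speckle"], dict):
            d["speckle"] = SpeckleParams(**d["speckle"])
        if "features" in d and isinstance(d["features"], dict):
            f = dict(d["features"])
            if "gabor_sizes" in f:
                f["gabor_sizes"] = tuple(f["gabor_sizes"])
            d["features"] = FeatureConfig(**f)
        if "train_counts" in d:
            d["train_counts"] = tuple(d["train_counts"])
        return cls(**d)


def extract_table(
    manifest: pd.DataFrame,
    images: dict[tuple[str, str], np.ndarray],
    phase: str,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Feature table for one phase: columns subject_id, phase, class, then
    the 250 registry feature names in order; one row per image."""
    rows = []
    sub = manifest[manifest["phase"] == phase]
    for sid, ph, cls in zip(sub["subject_id"], sub["phase"], sub["class"]):
        vec = extract_all(images[(sid, ph)], config)
        rows.append({"subject_id": sid, "phase": ph, "class": int(cls), **vec})
    table = pd.DataFrame(rows)
    return table[["subject_id", "phase", "class", *FEATURE_NAMES]]


def _plot_sweep(sweep: pd.DataFrame, phase: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True, sharey=True)
    for ax, name in zip(axes.ravel(), sweep["classifier"].unique()):
        for stage, marker in (("training", "o"), ("test", "s")):
            sub = sweep[(sweep["classifier"] == name) & (sweep["stage"] == stage)]
            if len(sub):
                ax.plot(sub["k"], sub["accuracy"], marker=marker, label=stage)
        ax.set_title(name)
        ax.set_xlabel("number of selected features k")
        ax.set_ylabel("accuracy (%)")
        ax.legend()
    fig.suptitle(f"Accuracy vs. selected features, {phase}-phase")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_scatter(table: pd.DataFrame, feats: list[str], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for cls, label, color in ((1, "patient", "tab:red"), (0, "control", "tab:blue")):
        sub = table[table["class"] == cls]
        ax.scatter(sub[feats[0]], sub[feats[1]], s=18, alpha=0.7,
                   label=label, color=color)
    ax.set_xlabel(feats[0])
    ax.set_ylabel(feats[1])
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run(config: RunConfig) -> ProtocolResult:
    """Execute the full pipeline and write all artifacts to
    ``config.out_dir``."""
    from .synthetic import generate_cohort

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.child_seeds()
    (out / "config.json").write_text(config.to_json())

    cohort = dataclasses.replace(config.cohort, seed=seeds["cohort"])
    manifest, images = generate_cohort(
        cohort, config.speckle,
        out_dir=(out / "images") if config.write_images else None,
    )

    tables = {
        phase: extract_table(manifest, images, phase, config.features)
        for phase in ("R", "T")
    }
    for phase, table in tables.items():
        table.to_csv(out / f"features_{phase}.csv", index=False)

    result = run_full_protocol(
        tables,
        train_counts=config.train_counts,
        alpha=config.alpha,
        relieff_k=config.relieff_k,
        top_n=config.top_n,
        k_max=config.k_max,
        split_seed=seeds["split"],
        clf_seed=seeds["classifier"],
        include_loocv=config.include_loocv,
    )

    for phase in ("R", "T"):
        result.screening[phase].to_csv(out / f"screening_{phase}.csv", index=False)
        result.ranked[phase].to_csv(out / f"ranked_{phase}.csv", index=False)
        result.sweep[phase].to_csv(out / f"sweep_{phase}.csv", index=False)
        if config.write_plots:
            _plot_sweep(result.sweep[phase], phase, out / f"sweep_{phase}.png")
    result.report.to_csv(out / "report.csv", index=False)
    if config.write_plots and len(result.ranked["R"]) >= 2:
        _plot_scatter(
            tables["R"], result.ranked["R"]["Feature"].tolist()[:2],
            out / "scatter.png",
        )

    summary = {
        "seeds": seeds,
        "split": {
            "train": result.split.train_counts,
            "test": result.split.test_counts,
        },
        "metrics": result.report.to_dict(orient="records"),
        "best": result.best,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True,
                   default=lambda o: o.item())  # numpy scalars
    )
    return result
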