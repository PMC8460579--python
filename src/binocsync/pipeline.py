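"""End-to-end orchestration: simulate/read → pair → classify → count → fit.

``run_pipeline`` drives the full analysis and writes every artifact (pairs
CSV, counts CSV, type-distribution table, per-type model reports, manifest)
into an output directory.  Rerunning with an identical configuration
reproduces byte-identical CSV/JSON outputs; the manifest records the config
hash, seed, package version, and per-stage record counts so the
conservation numbers can be reconciled after the fact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .countmodel import PoissonCountModel, format_table, lrt_compare
from .events import (
    ScreenGeometry,
    read_fixation_csv,
    write_counts_csv,
    write_fit_json,
    write_pairs_csv,
)
from .pairing import pair_streams
from .simulate import SimConfig, simulate_reading_session
from .spatial import assign_regions, count_table
from .typology import DEFAULT_RULE, ToleranceRule, classify_pairs, type_distribution

logger = logging.getLogger("binocsync")

#: types modeled by default; T4 and T8 mix early- and late-priority for
#: opposite eyes, so their directional predictions are ambiguous
DEFAULT_MODEL_TYPES = ("Syn", "T1", "T2", "T3", "T5", "T6", "T7")


@dataclasses.dataclass
class PipelineConfig:
    """Everything one pipeline run needs."""

    sim: SimConfig | None = None
    input_csv: str | None = None
    screen: ScreenGeometry = dataclasses.field(default_factory=ScreenGeometry)
    tolerance: ToleranceRule = DEFAULT_RULE
    model_types: tuple[str, ...] = DEFAULT_MODEL_TYPES
    random_factors: tuple[str, ...] = ("participant", "article", "page")
    out_dir: str = "binocsync_out"
    seed: int = 0
    fit_models: bool = True
    make_figures: bool = False

    def __post_init__(self) -> None:
        from .typology import LABELS

        bad = set(self.model_types) - set(LABELS)
        if bad:
            raise ValueError(f"unknown type labels in model_types: {sorted(bad)}")
        if self.sim is None and self.input_csv is None:
            raise ValueError("either a SimConfig or an input CSV is required")

    def digest(self) -> str:
        payload = {
            "sim": self.sim.to_dict() if self.sim else None,
            "input_csv": self.input_csv,
            "screen": [self.screen.width_px, self.screen.height_px,
                       list(self.screen.region_bounds)],
            "tol_ms": self.tolerance.tol_ms,
            "model_types": list(self.model_types),
            "random_factors": list(self.random_factors),
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle.

    Returns the manifest dictionary (also written to ``manifest.json``).
    Any stage failure is re-raised annotated with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    stage = "input"
    try:
        if config.sim is not None:
            sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
            session = simulate_reading_session(sim_cfg)
            fixations = session.fixations
            session.write(out / "fixations.csv", out / "sim_truth.json")
        else:
            fixations, rejections = read_fixation_csv(
                config.input_csv, screen=config.screen
            )
            manifest["stages"]["rejected_rows"] = rejections.reasons
        manifest["stages"]["fixations"] = int(len(fixations))

        stage = "pair"
        pairs, unpaired = pair_streams(fixations)
        manifest["stages"]["pairs"] = int(len(pairs))
        manifest["stages"]["unpaired"] = unpaired

        stage = "classify"
        pairs = classify_pairs(pairs, config.tolerance)
        manifest["stages"]["classified"] = int(len(pairs))

        stage = "spatial"
        pairs = assign_regions(pairs, config.screen)
        manifest["stages"]["spatialized"] = int(len(pairs))
        write_pairs_csv(pairs, out / "pairs.csv")

        dist = type_distribution(pairs)
        dist_frame = dist.to_frame()
        dist_frame.to_csv(out / "type_distribution.csv", index=False)
        with open(out / "type_aggregates.json", "w") as fh:
            json.dump(dist.aggregates, fh, indent=2)
            fh.write("\n")

        stage = "counts"
        counts = count_table(pairs)
        write_counts_csv(counts, out / "counts.csv")
        manifest["stages"]["count_total"] = int(counts["count"].sum())

        if config.fit_models:
            stage = "fit"
            fits_dir = out / "fits"
            fits_dir.mkdir(exist_ok=True)
            for label in config.model_types:
                sub = counts[counts["type"] == label]
                if sub.empty or sub["region"].nunique() < 3:
                    logger.warning("skipping model for %s: insufficient data", label)
                    continue
                null = PoissonCountModel(
                    sub, region_effect=False, random_factors=config.random_factors
                ).fit()
                full = PoissonCountModel(
                    sub, region_effect=True, random_factors=config.random_factors
                ).fit()
                lrt = lrt_compare(null, full)
                write_fit_json(
                    {
                        "type": label,
                        "null": null.to_dict(),
                        "sides_of_screen": full.to_dict(),
                        "lrt": dataclasses.asdict(lrt),
                    },
                    fits_dir / f"{label}.json",
                )
                (fits_dir / f"{label}.txt").write_text(
                    format_table(null, full, title=f"Screen differences in {label}")
                    + "\n"
                )

        if config.make_figures:
            stage = "figures"
            _make_figures(pairs, config, out)
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _make_figures(pairs: pd.DataFrame, config: PipelineConfig, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .spatial import hexbin_counts, plot_hexbin
    from .typology import LABELS

    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    dist = type_distribution(pairs)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(dist.proportions.index, 100 * dist.proportions.values)
    ax.set_ylabel("% of binocular fixations")
    fig.savefig(fig_dir / "type_distribution.png", dpi=120)
    plt.close(fig)
    for label in LABELS:
        sub = pairs[pairs["type"] == label]
        if len(sub) == 0:
            continue
        grid = hexbin_counts(sub, hex_radius_px=25.0)
        ax = plot_hexbin(grid, title=f"{label} (n={len(sub)})")
        ax.figure.savefig(fig_dir / f"hexbin_{label}.png", dpi=120)
        plt.close(ax.figure)
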