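"""Synthetic binocular reading sessions with planted ground truth.

The raw data this pipeline was designed for cannot be redistributed, so the
generator emulates their statistical structure: multi-line page reading on
a 1024 × 768 screen sampled at 500 Hz (a 2 ms time lattice), with each
conceptual fixation realised as one left-eye and one right-eye event whose
onsets and offsets differ by small, long-tailed lags.

The lag model plants the spatial asymmetry the analysis is built to detect.
The signed start offset (right minus left, ms) of a fixation at normalized
horizontal position x̃ = 2·x/width − 1 is drawn from a Laplace distribution

    start_offset ~ Laplace(loc = −start_bias_slope · x̃,  scale = lag_scale_ms)

so with a positive slope the right eye tends to *start earlier* (negative
offset) at the right of the screen, where the abducting right eye arrives
first after a left-to-right saccade.  End offsets use
``loc = +end_bias_slope · x̃``: the right eye tends to *end later* at the
right.  The first fixation after a return sweep additionally shifts the
start-offset location by ``+sweep_advantage_ms`` (left eye arrives earlier
at line beginnings).  All event times are rounded half-away-from-zero to
the 2 ms grid, which is what makes the offset lattice {…, −4, −2, 0, 2, 4, …}.

A second, fast path generates Poisson count tables directly with planted
region effects and random-intercept SDs, for exercising the count models
without running the full event pipeline.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .events import FIXATION_COLUMNS, ScreenGeometry


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic reading session.

    Defaults reflect the study conditions being emulated: 36 participants,
    21 articles of ~5 pages, up to five left-justified lines per page on a
    1024 × 768 screen, mean fixation durations around 200 ms, and per-eye
    lags forming a long-tailed (Laplace) distribution with single-digit-
    millisecond typical magnitudes on the 2 ms sampling lattice.
    """

    n_participants: int = 36
    n_articles: int = 21
    pages_per_article: int = 5
    lines_per_page: int = 5
    line_length_px: float = 920.0  # 64 monospaced characters at 14.4 px
    screen: ScreenGeometry = dataclasses.field(default_factory=ScreenGeometry)
    fixdur_log_mean: float = 5.3  # ln ms; exp(5.3) ≈ 200 ms
    fixdur_log_sd: float = 0.35
    saccade_ms: float = 30.0
    lag_scale_ms: float = 1.5
    start_bias_slope: float = 2.0  # ms per unit normalized x
    end_bias_slope: float = 1.5
    sweep_advantage_ms: float = 2.0  # extra left-eye start advantage after return sweeps
    quantum_ms: float = 2.0
    degenerate_tol: float = 1e-3
    group: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_articles", "pages_per_article", "lines_per_page"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.lines_per_page > 5:
            raise ValueError("at most five lines per page")
        if self.lag_scale_ms <= 0 or self.quantum_ms <= 0:
            raise ValueError("lag_scale_ms and quantum_ms must be positive")
        if self.line_length_px > self.screen.width_px:
            raise ValueError("line_length_px exceeds screen width")
        # degenerate-parameter guard: a lag perturbation must almost never
        # consume a plausible short fixation (1st-percentile duration)
        d_low = float(np.exp(self.fixdur_log_mean - 2.326 * self.fixdur_log_sd))
        p_bad = float(np.exp(-max(d_low / 2.0, 1e-9) / self.lag_scale_ms))
        if p_bad > self.degenerate_tol:
            raise ValueError(
                "degenerate config: lag perturbations of scale "
                f"{self.lag_scale_ms} ms would consume short fixations "
                f"(P ≈ {p_bad:.2g} > {self.degenerate_tol})"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["screen"] = {
            "width_px": self.screen.width_px,
            "height_px": self.screen.height_px,
            "region_bounds": list(self.screen.region_bounds),
        }
        return d


@dataclasses.dataclass(frozen=True)
class SimTruth:
    """Ground truth planted by a generator run, for recovery tests."""

    start_bias_slope: float = 0.0
    end_bias_slope: float = 0.0
    sweep_advantage_ms: float = 0.0
    lag_scale_ms: float = 0.0
    region_effects: dict | None = None  # log rate ratios vs middle
    grouping_sds: dict | None = None
    intercept: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class SimulatedSession:
    """A generated session: both eyes' event streams plus the ground truth."""

    fixations: pd.DataFrame  # canonical columns, both eyes
    truth: SimTruth
    config: SimConfig

    @property
    def left(self) -> pd.DataFrame:
        return self.fixations[self.fixations["eye"] == "L"].reset_index(drop=True)

    @property
    def right(self) -> pd.DataFrame:
        return self.fixations[self.fixations["eye"] == "R"].reset_index(drop=True)

    def write(self, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        from .events import write_fixations_csv

        write_fixations_csv(self.fixations, csv_path)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {"config": self.config.to_dict(), "truth": self.truth.to_dict()},
                    fh,
                    indent=2,
                )
                fh.write("\n")


def _quantize(t: np.ndarray, q: float) -> np.ndarray:
    """Round half away from zero onto the q-ms grid."""
    return np.sign(t) * np.floor(np.abs(t) / q + 0.5) * q


def _simulate_page(
    rng: np.random.Generator, cfg: SimConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One page: base fixation times/positions for the conceptual scanpath."""
    width = cfg.screen.width_px
    height = cfg.screen.height_px
    top = height * 0.15
    line_gap = (height * 0.7) / max(cfg.lines_per_page, 1)
    xs, ys, sweep = [], [], []
    for li in range(cfg.lines_per_page):
        x = 30.0 + rng.uniform(0, 20)
        y0 = top + li * line_gap
        first = True
        while x < cfg.line_length_px:
            xs.append(min(x, width - 1))
            ys.append(min(max(y0 + rng.normal(0, 4), 0), height - 1))
            sweep.append(first and li > 0)
            first = False
            x += max(rng.normal(60, 20), 14)
    n = len(xs)
    durs = np.exp(rng.normal(cfg.fixdur_log_mean, cfg.fixdur_log_sd, n))
    min_dur = 2 * (cfg.saccade_ms / 2) + 2 * cfg.quantum_ms
    durs = np.maximum(durs, min_dur)
    return np.array(xs), np.array(ys), durs, np.array(sweep, bool)


def simulate_reading_session(config: SimConfig) -> SimulatedSession:
    """Generate left- and right-eye fixation streams for a full session.

    Deterministic given ``config.seed``; per-(participant, article, page)
    substreams are independently seeded, so regenerating a subset of the
    session reproduces identical events.
    """
    cfg = config
    q = cfg.quantum_ms
    # clip lags to half the inter-fixation gap so each eye's stream stays
    # strictly ordered; symmetric clipping far beyond the median of the
    # Laplace leaves the offset median untouched
    clip = cfg.saccade_ms / 2.0 - q
    frames: list[pd.DataFrame] = []
    for pi in range(cfg.n_participants):
        pid = f"P{pi + 1:02d}"
        for ai in range(cfg.n_articles):
            aid = f"A{ai + 1:02d}"
            for gi in range(cfg.pages_per_article):
                rng = np.random.default_rng([cfg.seed, pi, ai, gi])
                xs, ys, durs, sweep = _simulate_page(rng, cfg)
                n = len(xs)
                starts = np.empty(n)
                t = 500.0 + rng.uniform(0, 50)
                for i in range(n):
                    starts[i] = t
                    t += durs[i] + cfg.saccade_ms
                xnorm = 2.0 * xs / cfg.screen.width_px - 1.0
                loc_start = -cfg.start_bias_slope * xnorm + np.where(
                    sweep, cfg.sweep_advantage_ms, 0.0
                )
                loc_end = cfg.end_bias_slope * xnorm
                off_start = np.clip(
                    rng.laplace(loc_start, cfg.lag_scale_ms), -clip, clip
                )
                off_end = np.clip(
                    rng.laplace(loc_end, cfg.lag_scale_ms), -clip, clip
                )
                l_start = _quantize(starts, q)
                l_end = _quantize(starts + durs, q)
                r_start = _quantize(starts + off_start, q)
                r_end = _quantize(starts + durs + off_end, q)
                base = {
                    "participant_id": pid,
                    "group": cfg.group,
                    "article_id": aid,
                    "page_id": f"{gi + 1}",
                }
                for eye, s, e in (("L", l_start, l_end), ("R", r_start, r_end)):
                    frames.append(
                        pd.DataFrame(
                            {
                                **base,
                                "eye": eye,
                                "start_ms": s.astype(np.int64),
                                "end_ms": e.astype(np.int64),
                                "x_px": np.round(xs, 1),
                                "y_px": np.round(ys, 1),
                            }
                        )
                    )
    fixations = pd.concat(frames, ignore_index=True)[FIXATION_COLUMNS]
    fixations = fixations.sort_values(
        ["participant_id", "article_id", "page_id", "eye", "start_ms"],
        kind="mergesort",
    ).reset_index(drop=True)
    _assert_stream_sanity(fixations, q)
    truth = SimTruth(
        start_bias_slope=cfg.start_bias_slope,
        end_bias_slope=cfg.end_bias_slope,
        sweep_advantage_ms=cfg.sweep_advantage_ms,
        lag_scale_ms=cfg.lag_scale_ms,
    )
    return SimulatedSession(fixations=fixations, truth=truth, config=cfg)


def _assert_stream_sanity(fixations: pd.DataFrame, q: float) -> None:
    t = fixations[["start_ms", "end_ms"]].to_numpy(float)
    if np.any(t < 0) or np.any(t % q != 0):
        raise AssertionError("generated times off the sampling grid")
    for _, grp in fixations.groupby(
        ["participant_id", "article_id", "page_id", "eye"], sort=False
    ):
        s = grp["start_ms"].to_numpy()
        e = grp["end_ms"].to_numpy()
        if np.any(e <= s) or (len(s) > 1 and np.any(s[1:] < e[:-1])):
            raise AssertionError("generated stream overlaps or is unordered")


def simulate_count_table(
    planted_effects: dict[str, float] | None = None,
    grouping_sds: dict[str, float] | None = None,
    n_participants: int = 36,
    n_articles: int = 1,
    n_pages: int = 5,
    intercept: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Directly generate a Poisson count table with planted structure.

    One row per (participant, article, page, region); counts are drawn
    Poisson with log-mean = intercept + region effect + the summed random
    intercepts of the requested grouping factors, each level drawn normal
    with the planted SD.  ``planted_effects`` maps "left"/"right" to log
    rate ratios versus the middle region; ``grouping_sds`` maps
    "participant"/"article"/"page" to non-negative SDs.
    """
    effects = {"left": 0.0, "right": 0.0}
    effects.update(planted_effects or {})
    sds = {"participant": 0.0, "article": 0.0, "page": 0.0}
    sds.update(grouping_sds or {})
    if any(s < 0 for s in sds.values()):
        raise ValueError("grouping SDs must be >= 0")
    if not all(np.isfinite(list(effects.values()))):
        raise ValueError("planted effects must be finite")
    rng = np.random.default_rng(seed)
    b_part = rng.normal(0.0, sds["participant"], n_participants)
    b_art = rng.normal(0.0, sds["article"], n_articles)
    b_page = rng.normal(0.0, sds["page"], (n_articles, n_pages))
    regions = ("left", "middle", "right")
    reg_eff = np.array([effects["left"], 0.0, effects["right"]])
    rows = []
    for pi in range(n_participants):
        for ai in range(n_articles):
            for gi in range(n_pages):
                logmu = intercept + b_part[pi] + b_art[ai] + b_page[ai, gi] + reg_eff
                counts = rng.poisson(np.exp(logmu))
                for ri, reg in enumerate(regions):
                    rows.append(
                        (
                            f"P{pi + 1:02d}",
                            "sim",
                            f"A{ai + 1:02d}",
                            f"{gi + 1}",
                            reg,
                            int(counts[ri]),
                        )
                    )
    df = pd.DataFrame(
        rows,
        columns=["participant_id", "group", "article_id", "page_id", "region", "count"],
    )
    truth = SimTruth(
        region_effects=dict(effects),
        grouping_sds=dict(sds),
        intercept=float(intercept),
    )
    return df, truth
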