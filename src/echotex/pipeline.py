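"""End-to-end orchestration: synthetic study out, summary tables back in.

``run_simulate`` writes a complete synthetic study (speckle PNGs, image
manifest, spot table, trait table) from one master seed; ``run_analyze``
consumes those files — or any real study laid out the same way — and writes
the echotexture records, the group summary, the ANOVA tables and the
within-group / pooled correlation screens as CSV, plus a ``run.log``.

Seed streams, in fixed order: stream 0 drives the trait/echotexture table,
stream 1 is split per image in bird-major, plane-minor order.  A rerun with
the same seed produces byte-identical CSVs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, defaults
from .echotexture import (
    DEFAULT_SPOT_DIAMETER,
    analyze_batch,
    default_spot_layout,
    group_summary,
    read_spots_csv,
)
from .image_io import read_manifest, write_png
from .stats import anova_oneway_tukey, anova_twoway_lsd, correlation_screen
from .synthetic import (
    PLANE_ANISOTROPY,
    SpeckleParams,
    TraitModel,
    calibrate_sigma,
    simulate_speckle_image,
    simulate_trait_table,
)

__all__ = ["RunConfig", "RunReport", "run_simulate", "run_analyze", "load_config"]

logger = logging.getLogger(__name__)

_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


@dataclass
class RunConfig:
    """Configuration of one simulate or analyze run."""

    out_dir: str = "echotex_run"
    manifest: str | None = None
    spots: str | None = None
    traits: str | None = None
    alpha: float = 0.05
    spot_diameter: float = DEFAULT_SPOT_DIAMETER
    n_traits_bookkeeping: int = defaults.N_TRAITS_BOOKKEEPING
    seed: int = 0
    pooled: bool = True
    mph_mode: str = "per-spot"
    bh_annotation: bool = False
    n_per_group: int = defaults.N_PER_GROUP
    image_rows: int = 480
    image_cols: int = 640
    smooth_sigma: float = 0.8
    target_correlations: list = field(default_factory=list)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3 (the screen needs n >= 3)")
        if self.mph_mode not in ("per-spot", "across-spots"):
            raise ValueError(f"unknown mph_mode {self.mph_mode!r}")
        if self.spot_diameter < 3:
            raise ValueError("spot_diameter must be >= 3")


def load_config(path: str | Path) -> RunConfig:
    """Read a declarative ``key = value`` config file (# starts a comment)."""
    cfg = RunConfig()
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if not hasattr(cfg, key):
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        current = getattr(cfg, key)
        if isinstance(current, bool):
            if val.lower() not in _BOOL:
                raise ValueError(f"{path}:{lineno}: bad boolean {val!r}")
            setattr(cfg, key, _BOOL[val.lower()])
        elif isinstance(current, int) and not isinstance(current, bool):
            setattr(cfg, key, int(val))
        elif isinstance(current, float):
            setattr(cfg, key, float(val))
        elif key == "target_correlations":
            # x:y:r triples separated by ';'
            triples = []
            for part in val.split(";"):
                x, y, r = (s.strip() for s in part.split(":"))
                triples.append((x, y, float(r)))
            cfg.target_correlations = triples
        else:
            setattr(cfg, key, val)
    cfg.validate()
    return cfg


@dataclass
class RunReport:
    """What a run produced: output paths, per-row failures, timings."""

    outputs: dict
    failures: list
    timings: dict
    ok: bool


def _setup_run_logging(out_dir: Path) -> logging.Handler:
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("echotex")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    return handler


def _log_versions(seed: int) -> None:
    import scipy
    logger.info("echotex %s | numpy %s | scipy %s | pandas %s | seed %d",
                __version__, np.__version__, scipy.__version__, pd.__version__, seed)


def run_simulate(cfg: RunConfig) -> RunReport:
    """Write a full synthetic study ready for ``run_analyze``.

    Per bird and plane, the speckle scale is calibrated so the image's
    pre-normalization envelope mean equals that bird's latent MPI; the
    scene frame pins the extrema at 0/255 so byte-scale normalization in
    the analysis step is (near-)neutral over the parenchyma.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    handler = _setup_run_logging(out)
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    try:
        _log_versions(cfg.seed)
        ss = np.random.SeedSequence(cfg.seed)
        traits_ss, images_ss = ss.spawn(2)
        model = TraitModel(target_correlations=list(cfg.target_correlations))
        traits_df, echo_df = simulate_trait_table(
            model, cfg.n_per_group, seed=int(traits_ss.generate_state(1)[0]))
        timings["traits"] = time.perf_counter() - t0

        img_dir = out / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        latent = echo_df.set_index(["bird_id", "plane"])["mpi"]
        birds = traits_df[["bird_id", "group"]]
        n_images = len(birds) * len(defaults.PLANES)
        child_seeds = images_ss.spawn(n_images)
        manifest_rows, spot_rows = [], []
        k = 0
        t1 = time.perf_counter()
        for bird, group in birds.itertuples(index=False):
            for plane in defaults.PLANES:
                target = float(np.clip(latent.loc[(bird, plane)], 1.0, 254.0))
                params = SpeckleParams(
                    sigma=calibrate_sigma(target),
                    size=(cfg.image_rows, cfg.image_cols),
                    smooth_sigma=cfg.smooth_sigma,
                    anisotropy=PLANE_ANISOTROPY[plane],
                    scene=True,
                    seed=int(child_seeds[k].generate_state(1)[0]),
                )
                k += 1
                img = simulate_speckle_image(params, plane=plane)
                path = img_dir / f"{bird}_{plane}.png"
                write_png(img, path)
                manifest_rows.append({"bird_id": bird, "group": group,
                                      "plane": plane, "path": str(path)})
                layout = default_spot_layout(img, diameter=cfg.spot_diameter,
                                             spacing=max(40.0, cfg.spot_diameter + 7))
                for idx, spot in enumerate(layout.spots, start=1):
                    spot_rows.append({"bird_id": bird, "plane": plane,
                                      "spot_index": idx,
                                      "center_row": spot.center[0],
                                      "center_col": spot.center[1],
                                      "diameter": spot.diameter})
        timings["images"] = time.perf_counter() - t1

        manifest_path = out / "manifest.csv"
        spots_path = out / "spots.csv"
        traits_path = out / "traits.csv"
        pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
        pd.DataFrame(spot_rows).to_csv(spots_path, index=False)
        traits_df.to_csv(traits_path, index=False)
        for stage, dt in timings.items():
            logger.info("stage %s: %.2f s", stage, dt)
        return RunReport(
            outputs={"manifest": manifest_path, "spots": spots_path,
                     "traits": traits_path, "images": img_dir},
            failures=[], timings=timings, ok=True,
        )
    except Exception:
        logger.exception("simulate run failed")
        raise
    finally:
        logging.getLogger("echotex").removeHandler(handler)
        handler.close()


def _anova_rows(result, analysis: str, variable: str, data: pd.DataFrame,
                value: str) -> list[dict]:
    rows = []
    for factor in result.factors:
        for level in sorted(data[factor].unique()):
            vals = data.loc[data[factor] == level, value].to_numpy(dtype=float)
            rows.append({
                "analysis": analysis, "variable": variable, "factor": factor,
                "level": level, "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0,
                "letters": result.letters[factor][level],
                "f": result.f[factor], "p_value": result.p[factor],
                "method": result.method,
            })
    return rows


def run_analyze(cfg: RunConfig) -> RunReport:
    """Run the full analysis chain and write the six output files."""
    cfg.validate()
    out = Path(cfg.out_dir)
    handler = _setup_run_logging(out)
    timings: dict[str, float] = {}
    try:
        _log_versions(cfg.seed)
        if cfg.manifest is None or cfg.traits is None:
            raise ValueError("analyze needs 'manifest' and 'traits' paths")
        manifest = read_manifest(cfg.manifest)
        spots = read_spots_csv(cfg.spots) if cfg.spots else None
        traits = pd.read_csv(cfg.traits, dtype={"bird_id": str, "group": str})

        t0 = time.perf_counter()
        batch = analyze_batch(manifest, spots, mph_mode=cfg.mph_mode,
                              spot_diameter=cfg.spot_diameter)
        timings["echotexture"] = time.perf_counter() - t0
        records = batch.records
        if records.empty:
            raise RuntimeError("no image could be analyzed; see run.log")
        records_path = out / "echotexture.csv"
        records.to_csv(records_path, index=False, float_format="%.6g")
        summary = group_summary(records)
        summary_path = out / "group_summary.csv"
        summary.to_csv(summary_path, index=False, float_format="%.6g")

        t0 = time.perf_counter()
        anova_rows: list[dict] = []
        for stat in ("mpi", "mph"):
            res = anova_twoway_lsd(records, value=stat, factor_a="group",
                                   factor_b="plane", alpha=cfg.alpha)
            anova_rows += _anova_rows(res, "echotexture-two-way", stat.upper(),
                                      records, stat)
        trait_cols = [c for c in traits.columns if c not in ("bird_id", "group")]
        for trait in trait_cols:
            samples = {g: sub[trait].to_numpy(dtype=float)
                       for g, sub in traits.groupby("group")}
            try:
                res = anova_oneway_tukey(samples, alpha=cfg.alpha)
            except ValueError as exc:
                logger.warning("skipping one-way ANOVA for %s: %s", trait, exc)
                continue
            tdf = traits[["group", trait]].rename(columns={trait: "value"})
            anova_rows += _anova_rows(res, "trait-one-way", trait, tdf, "value")
        anova_path = out / "anova.csv"
        pd.DataFrame(anova_rows).to_csv(anova_path, index=False, float_format="%.6g")
        timings["anova"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        screen = correlation_screen(records, traits, alpha=cfg.alpha,
                                    pooled=cfg.pooled,
                                    n_traits_bookkeeping=cfg.n_traits_bookkeeping,
                                    bh_annotation=cfg.bh_annotation)
        within_path = out / "screen_within.csv"
        screen.within.results.to_csv(within_path, index=False, float_format="%.6g")
        outputs = {"echotexture": records_path, "group_summary": summary_path,
                   "anova": anova_path, "screen_within": within_path}
        logger.info("within screen: %d significant of %d possible (%.1f%%), %d tested",
                    screen.within.significant, screen.within.possible,
                    screen.within.percentage, screen.within.n_tested)
        if screen.pooled is not None:
            pooled_path = out / "screen_pooled.csv"
            screen.pooled.results.to_csv(pooled_path, index=False, float_format="%.6g")
            outputs["screen_pooled"] = pooled_path
            logger.info("pooled screen: %d significant of %d possible (%.1f%%), %d tested",
                        screen.pooled.significant, screen.pooled.possible,
                        screen.pooled.percentage, screen.pooled.n_tested)
        timings["screen"] = time.perf_counter() - t0

        for row in batch.failures:
            logger.warning("image failure: %s", row)
        for stage, dt in timings.items():
            logger.info("stage %s: %.2f s", stage, dt)
        return RunReport(outputs=outputs, failures=batch.failures,
                         timings=timings, ok=True)
    except Exception:
        logger.exception("analyze run failed")
        raise
    finally:
        logging.getLogger("echotex").removeHandler(handler)
        handler.close()
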