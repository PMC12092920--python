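"""End-to-end orchestration: images + ratings -> features -> difficulty -> model.

A run consumes either a directory of real images (with a manifest and a
ratings table) or a synthetic-generation block, and writes per-image and
per-case feature tables, difficulty records, a model report (JSON + text
summary), and a provenance file, all under one run directory.
"""
from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .difficulty import (EASIEST, HARDEST, build_difficulty_records,
                         density_difficulty_test)
from .images import GrayImage
from .model import BoostConfig, ModelReport, evaluate
from .preprocess import preprocess_image, read_image
from .radiomics import RadiomicsConfig, case_features, extract_image_features, zscore_table
from .synthetic import GeneratorConfig, make_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticBlock:
    n_cases: int = 140
    n_readers: int = 137
    balanced: bool = True  # hardest/easiest only, mirroring quartile retention
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)


@dataclass(frozen=True)
class InputBlock:
    image_dir: str = ""
    manifest: str = "manifest.csv"
    ratings: str = "ratings.csv"
    density: str | None = None  # csv: case_id, density_class


@dataclass(frozen=True)
class PipelineConfig:
    """Exactly one of ``inputs`` / ``synthetic`` must be set."""

    out_dir: str = "run"
    seed: int = 0
    inputs: InputBlock | None = None
    synthetic: SyntheticBlock | None = None
    threshold: int = 100
    threshold_overrides: dict[str, int] = field(default_factory=dict)
    radiomics: RadiomicsConfig = field(default_factory=RadiomicsConfig)
    boost: BoostConfig = field(default_factory=BoostConfig)
    normalize_in_fold: bool = True
    resume: bool = False

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("exactly one of inputs/synthetic must be configured")

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        """Build a config from a plain dict (e.g. parsed JSON).

        Nested blocks (`inputs`, `synthetic`, `radiomics`, `boost`, and
        `synthetic.generator` with its texture presets) may be given as
        dicts of overrides on the defaults.
        """
        from .synthetic import TextureParams

        payload = dict(payload)
        if isinstance(payload.get("inputs"), dict):
            payload["inputs"] = InputBlock(**payload["inputs"])
        if isinstance(payload.get("synthetic"), dict):
            blk = dict(payload["synthetic"])
            if isinstance(blk.get("generator"), dict):
                gen = dict(blk["generator"])
                for key in ("easiest_texture", "hardest_texture"):
                    if isinstance(gen.get(key), dict):
                        gen[key] = TextureParams(**gen[key])
                blk["generator"] = GeneratorConfig(**gen)
            payload["synthetic"] = SyntheticBlock(**blk)
        if isinstance(payload.get("radiomics"), dict):
            payload["radiomics"] = RadiomicsConfig(**payload["radiomics"])
        if isinstance(payload.get("boost"), dict):
            payload["boost"] = BoostConfig(**payload["boost"])
        return cls(**payload)


def _load_images(cfg: PipelineConfig, out: Path) -> tuple[dict, pd.DataFrame, pd.Series | None]:
    """Returns (case_id -> list of GrayImage, rating matrix, density series)."""
    if cfg.synthetic is not None:
        blk = cfg.synthetic
        gen = blk.generator
        if blk.balanced:
            from dataclasses import replace

            gen = replace(gen, class_proportions=(0.5, 0.5, 0.0))
        ds = make_dataset(blk.n_cases, blk.n_readers, gen, cfg.seed)
        ds.truth.to_csv(out / "truth.csv")
        by_case = {
            cid: [img for img, _ in views.values()] for cid, views in ds.images.items()
        }
        density = ds.truth["density_class"]
        return by_case, ds.ratings, density

    blk = cfg.inputs
    root = Path(blk.image_dir)
    try:
        manifest = pd.read_csv(root / blk.manifest)
        tidy = pd.read_csv(root / blk.ratings)
    except OSError as exc:
        raise OSError(f"input stage: cannot read manifest/ratings: {exc}") from exc
    by_case: dict[str, list[GrayImage]] = {}
    for row in manifest.itertuples():
        img = read_image(root / row.path)
        img.view = str(row.view)
        img.laterality = str(row.laterality)
        by_case.setdefault(str(row.case_id), []).append(img)
    ratings = tidy.pivot(index="reader_id", columns="case_id", values="score")
    density = None
    if blk.density:
        density = pd.read_csv(root / blk.density).set_index("case_id")["density_class"]
    return by_case, ratings, density


def extract_features(
    by_case: dict[str, list[GrayImage]],
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-image and per-case (4-view-averaged) feature tables.

    Cases without exactly 4 views are dropped with a warning.
    """
    image_rows = {}
    case_rows = {}
    for case_id, images in sorted(by_case.items()):
        if len(images) != 4:
            logger.warning("case %s has %d views (expected 4): dropped", case_id, len(images))
            continue
        vecs = []
        for img in images:
            key = f"{case_id}_{img.laterality[-1]}{img.view}".replace("flipped-R", "R")
            img8, mask = preprocess_image(
                img, cfg.threshold, cfg.threshold_overrides.get(key)
            )
            try:
                vecs.append(extract_image_features(img8, mask, cfg.radiomics))
            except Exception as exc:
                raise type(exc)(f"feature extraction failed for {key}: {exc}") from exc
            image_rows[key] = vecs[-1]
        case_rows[case_id] = case_features(vecs, case_id)
    image_table = pd.DataFrame(image_rows).T
    case_table = pd.DataFrame(case_rows).T
    case_table.index.name = image_table.index.name = None
    return image_table, case_table


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage and write the run directory. Returns its path."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mammodiff")
    root.addHandler(handler)
    try:
        return _run_pipeline(cfg, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_pipeline(cfg: PipelineConfig, out: Path) -> Path:

    feats_path = out / "case_features.csv"
    img_feats_path = out / "image_features.csv"
    if cfg.resume and feats_path.is_file():
        logger.info("resume: reusing cached feature tables in %s", out)
        case_table = pd.read_csv(feats_path, index_col=0)
        ratings, density = _load_ratings(cfg, out)
    else:
        by_case, ratings, density = _load_images(cfg, out)
        image_table, case_table = extract_features(by_case, cfg)
        image_table.to_csv(img_feats_path)
        case_table.to_csv(feats_path)

    normalized, zparams = zscore_table(case_table)
    normalized.to_csv(out / "case_features_normalized.csv")

    records = build_difficulty_records(ratings, density)
    diff_table = pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "score": r.score,
                "n_readers": r.n_readers,
                "label": r.label,
                "density_group": r.density_group,
            }
            for r in records
        ]
    ).set_index("case_id")
    diff_table.to_csv(out / "difficulty.csv")

    density_test = None
    groups = {r.density_group for r in records}
    if {"low", "high"} <= groups:
        density_test = density_difficulty_test(records)

    retained = diff_table[diff_table["label"].isin([HARDEST, EASIEST])]
    retained = retained[retained.index.isin(case_table.index)]
    X = case_table.loc[retained.index]
    y = (retained["label"] == HARDEST).to_numpy(dtype=float)
    report = evaluate(X, y, cfg.boost, normalize_in_fold=cfg.normalize_in_fold)

    _write_report(out, cfg, report, diff_table, density_test)
    return out


def _load_ratings(cfg: PipelineConfig, out: Path) -> tuple[pd.DataFrame, pd.Series | None]:
    """Rating matrix + density without touching pixel data (resume path)."""
    if cfg.synthetic is not None:
        from dataclasses import replace

        blk = cfg.synthetic
        gen = (
            replace(blk.generator, class_proportions=(0.5, 0.5, 0.0))
            if blk.balanced
            else blk.generator
        )
        ds = make_dataset(blk.n_cases, blk.n_readers, gen, cfg.seed, generate_images=False)
        return ds.ratings, ds.truth["density_class"]
    blk = cfg.inputs
    root = Path(blk.image_dir)
    tidy = pd.read_csv(root / blk.ratings)
    ratings = tidy.pivot(index="reader_id", columns="case_id", values="score")
    density = None
    if blk.density:
        density = pd.read_csv(root / blk.density).set_index("case_id")["density_class"]
    return ratings, density


def _write_report(
    out: Path,
    cfg: PipelineConfig,
    report: ModelReport,
    diff_table: pd.DataFrame,
    density_test: tuple[float, float] | None,
) -> None:
    payload = report.to_dict()
    if density_test is not None:
        payload["density_difficulty_test"] = {"H": density_test[0], "p": density_test[1]}
    payload["n_hardest"] = int((diff_table["label"] == HARDEST).sum())
    payload["n_easiest"] = int((diff_table["label"] == EASIEST).sum())
    (out / "model_report.json").write_text(json.dumps(payload, indent=2))

    lines = [
        "mammodiff run summary",
        "=====================",
        f"cases scored: {len(diff_table)} "
        f"(hardest {payload['n_hardest']}, easiest {payload['n_easiest']})",
        f"LOOCV AUC: {report.auc:.3f} "
        f"(95% CI {report.auc_ci[0]:.3f}-{report.auc_ci[1]:.3f}, DeLong)",
        f"scree-selected features: {', '.join(report.selected_features) or '(none)'}",
        f"significant features (Kruskal-Wallis, p<0.05, unadjusted): "
        f"{payload['n_significant']}/{len(report.kw_table)}",
    ]
    if density_test is not None:
        lines.append(
            f"density comparison (low vs high): H={density_test[0]:.3f}, p={density_test[1]:.3g}"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")

    provenance = {
        "mammodiff_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))


__all__ = [
    "PipelineConfig",
    "SyntheticBlock",
    "InputBlock",
    "run_pipeline",
    "extract_features",
    "write_dataset",
]
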