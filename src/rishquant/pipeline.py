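"""End-to-end demo pipeline: synth -> train -> segment -> quantify -> score.

``run_pipeline`` executes every stage on a synthetic cohort and leaves a
run directory containing the generated fields, two model checkpoints
(blue/wild-type and red/truncated), per-field counts, per-sample means,
rubric scores, group summaries and a manifest listing every artifact
with the config hash and the derived per-stage seeds. Reruns with the
same config and seed reproduce all CSV/JSON outputs bit-exactly.

The single global seed fans out to stage seeds through
``numpy.random.SeedSequence(seed).generate_state(3) % 2**31``
(synthesis, blue model, red model, in that order).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import save_cohort
from .postprocess import MorphConfig, binarize, count_dots, morph_clean, quantify_counts
from .preprocess import PreprocessConfig, extract_patches, preprocess_field
from .scoring import positivity_filter, score_counts, summarize_groups
from .segmenter import DoubleUNetSegmenter
from .synthetic import CohortSpec, SyntheticFieldSpec, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "build_patch_dataset"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthSection:
    n_samples: int = 3
    fields_per_sample: int = 10
    height: int = 256
    width: int = 256
    blue_mean_range: tuple[float, float] = (10.0, 90.0)
    red_mean_range: tuple[float, float] = (5.0, 45.0)


@dataclass(frozen=True)
class NetSection:
    depth: int = 3
    base_filters: int = 16
    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 32
    train_fraction: float = 0.8
    dice_smooth: float = 1.0
    bridge: str = "multiply"


@dataclass(frozen=True)
class ScoringSection:
    wt_min: int = 4
    tr_min: int = 3
    group_by: tuple[str, ...] = ("race", "stage", "gleason")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "rishquant_run"
    verbosity: int = 0
    synth: SynthSection = field(default_factory=SynthSection)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    net: NetSection = field(default_factory=NetSection)
    morph: MorphConfig = field(default_factory=MorphConfig)
    scoring: ScoringSection = field(default_factory=ScoringSection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sections = {
            "synth": SynthSection,
            "preprocess": PreprocessConfig,
            "net": NetSection,
            "morph": MorphConfig,
            "scoring": ScoringSection,
        }
        kwargs: dict = {}
        for key, val in raw.items():
            if key in sections:
                known = {f.name for f in dataclasses.fields(sections[key])}
                bad = set(val) - known
                if bad:
                    raise ValueError(
                        f"invalid config key(s) {sorted(bad)} in section {key!r}"
                    )
                val = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in val.items()
                }
                kwargs[key] = sections[key](**val)
            elif key in ("seed", "out_dir", "verbosity"):
                kwargs[key] = val
            else:
                raise ValueError(f"invalid config key {key!r}")
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seeds(seed: int) -> tuple[int, int, int]:
    synth, blue, red = (
        int(s) for s in np.random.SeedSequence(seed).generate_state(3) % 2**31
    )
    return synth, blue, red


def build_patch_dataset(
    fields, cfg: PreprocessConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Preprocess fields and tile them into (patches, blue masks, red masks)."""
    X, yb, yr = [], [], []
    for f in fields:
        pre = preprocess_field(f.image, cfg)
        X.extend(extract_patches(pre, cfg).patches)
        yb.extend(extract_patches(f.blue_mask, cfg).patches)
        yr.extend(extract_patches(f.red_mask, cfg).patches)
    return (
        np.asarray(X, dtype=np.float32),
        np.asarray(yb, dtype=np.uint8),
        np.asarray(yr, dtype=np.uint8),
    )


def _count_field(model, image, pre_cfg, morph_cfg) -> int:
    prob = model.predict_field(image, pre_cfg)
    return count_dots(morph_clean(binarize(prob, morph_cfg), morph_cfg), morph_cfg)


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage; returns the run directory. See the module docstring."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synth_seed, blue_seed, red_seed = _stage_seeds(cfg.seed)
    if cfg.verbosity:
        logging.basicConfig(level=logging.INFO)

    def fail(stage: str, err: Exception) -> RuntimeError:
        return RuntimeError(f"pipeline stage {stage!r} failed [{type(err).__name__}]: {err}")

    # synth ------------------------------------------------------------
    try:
        cohort = CohortSpec(
            n_samples=cfg.synth.n_samples,
            fields_per_sample=cfg.synth.fields_per_sample,
            blue_mean_range=cfg.synth.blue_mean_range,
            red_mean_range=cfg.synth.red_mean_range,
            field=SyntheticFieldSpec(height=cfg.synth.height, width=cfg.synth.width),
            seed=synth_seed,
        )
        fields, meta = generate_cohort(cohort)
        field_meta = save_cohort(fields, meta, out / "cohort")
        logger.info("generated %d fields for %d samples", len(fields), len(meta))
    except Exception as e:  # noqa: BLE001 - stage label requested by contract
        raise fail("synth", e) from e

    # train ------------------------------------------------------------
    try:
        X, yb, yr = build_patch_dataset(fields, cfg.preprocess)
        models = {}
        for channel, y, seed in (
            ("blue_WT", yb, blue_seed),
            ("red_TR", yr, red_seed),
        ):
            est = DoubleUNetSegmenter(
                channel=channel,
                depth=cfg.net.depth,
                base_filters=cfg.net.base_filters,
                learning_rate=cfg.net.learning_rate,
                epochs=cfg.net.epochs,
                batch_size=cfg.net.batch_size,
                train_fraction=cfg.net.train_fraction,
                dice_smooth=cfg.net.dice_smooth,
                bridge=cfg.net.bridge,
                patch_size=cfg.preprocess.patch_size,
                seed=seed,
                verbose=cfg.verbosity,
            )
            est.fit(X, y)
            est.save(out / f"model_{channel}.ckpt")
            models[channel] = est
            logger.info(
                "%s model: held-out DSC %.4f", channel, est.report_.test_metrics.dsc
            )
    except Exception as e:  # noqa: BLE001
        raise fail("train", e) from e

    # segment + quantify ------------------------------------------------
    try:
        rows = []
        for f in fields:
            rows.append(
                {
                    "sample_id": f.sample_id,
                    "field_index": f.field_index,
                    "blue_count": _count_field(
                        models["blue_WT"], f.image, cfg.preprocess, cfg.morph
                    ),
                    "red_count": _count_field(
                        models["red_TR"], f.image, cfg.preprocess, cfg.morph
                    ),
                }
            )
        counts = pd.DataFrame(rows)
        counts.to_csv(out / "counts.csv", index=False)
        samples = quantify_counts(counts)
        samples.round(2).to_csv(out / "samples.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise fail("quantify", e) from e

    # score + report -----------------------------------------------------
    try:
        scores = score_counts(counts)
        sample_meta = field_meta.drop_duplicates("sample_id")[
            ["sample_id", "race", "stage", "gleason"]
        ]
        scores = scores.merge(sample_meta, on="sample_id")
        scores.to_csv(out / "scores.csv", index=False)
        positive, n_pos = positivity_filter(
            scores, cfg.scoring.wt_min, cfg.scoring.tr_min
        )
        summaries = []
        for key in cfg.scoring.group_by:
            s = summarize_groups(positive, key)
            s.insert(0, "group_by", key)
            s.rename(columns={key: "group"}, inplace=True)
            summaries.append(s)
        pd.concat(summaries, ignore_index=True).to_csv(
            out / "cohort_summary.csv", index=False
        )
    except Exception as e:  # noqa: BLE001
        raise fail("score", e) from e

    # manifest -----------------------------------------------------------
    files = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seeds": {"global": cfg.seed, "synth": synth_seed, "blue": blue_seed, "red": red_seed},
        "n_fields": len(fields),
        "n_positive_samples": n_pos,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
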