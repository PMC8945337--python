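"""End-to-end study orchestration: synth → preprocess → features → classify.

``run_study`` drives the whole analysis from one :class:`StudyConfig`:
it simulates (or loads) a cohort, filters and normalizes every record,
builds per-modality caffeine/placebo group energy profiles, jointly
z-scores them, runs the classifier bank with leave-one-out
cross-validation, and optionally persists profiles, the results table, a
log and a provenance JSON under ``output_dir``. One master seed governs
every random draw, so re-running an identical config reproduces the
result bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import features as _features
from . import preprocess as _preprocess
from . import synth as _synth
from .io import SignalRecord

logger = logging.getLogger(__name__)


@dataclass
class FeatureSettings:
    segment_min: float = 5.0
    window_s: float = 5.0
    window_step_s: float | None = None  # None: contiguous (step = width)
    zscore_scope: str = "joint"  # pooled across both groups
    #: minutes skipped before segmentation (pre-intake baseline);
    #: None means "use the cohort config's baseline_min"
    analysis_start_min: float | None = None


@dataclass
class ClassifySettings:
    sample_unit: str = "group_point"  # or "subject_point"
    seed: int = 0


@dataclass
class StudyConfig:
    """Everything one study run needs; ``seed`` cascades to all stages."""

    cohort: _synth.CohortConfig = field(default_factory=_synth.CohortConfig)
    filters: dict[str, _preprocess.FilterSpec] = field(
        default_factory=lambda: dict(_preprocess.DEFAULT_FILTERS)
    )
    normalization: str = "unit-energy"
    features: FeatureSettings = field(default_factory=FeatureSettings)
    classify: ClassifySettings = field(default_factory=ClassifySettings)
    output_dir: Path | None = None


@dataclass
class StudyResult:
    """Profiles, classifier table and provenance of one study run."""

    profiles: dict[str, dict[str, _features.GroupProfile]]  # modality -> group -> raw
    zscored: dict[str, dict[str, _features.GroupProfile]]
    table: pd.DataFrame
    provenance: dict


def _config_to_jsonable(config: StudyConfig) -> dict:
    d = asdict(config)
    d["filters"] = {k: asdict(v) for k, v in config.filters.items()}
    if d.get("output_dir") is not None:
        d["output_dir"] = str(d["output_dir"])
    return d


def config_hash(config: StudyConfig) -> str:
    """Stable SHA-256 over the canonical JSON form of a config."""
    payload = json.dumps(_config_to_jsonable(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def config_from_yaml(path: str | Path) -> StudyConfig:
    """Build a StudyConfig from a YAML file (missing keys take defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort_kw = dict(raw.get("cohort", {}))
    if "pk" in cohort_kw:
        cohort_kw["pk"] = _synth.PKProfile(**cohort_kw["pk"])
    cohort = _synth.CohortConfig(**cohort_kw)
    filters = dict(_preprocess.DEFAULT_FILTERS)
    for modality, spec in raw.get("filters", {}).items():
        mod = modality.upper()
        filters[mod] = _preprocess.FilterSpec(
            modality=mod,
            kind=spec.get("kind", filters[mod].kind),
            cutoffs=tuple(spec.get("cutoffs_hz", filters[mod].cutoffs)),
            order=spec.get("order"),
            phase_mode=spec.get("phase_mode", "zero-phase"),
        )
    return StudyConfig(
        cohort=cohort,
        filters=filters,
        normalization=raw.get("normalization", {}).get("mode", "unit-energy"),
        features=FeatureSettings(**raw.get("features", {})),
        classify=ClassifySettings(**raw.get("classify", {})),
        output_dir=Path(raw["output_dir"]) if raw.get("output_dir") else None,
    )


def preprocess_cohort(
    records: list[SignalRecord], config: StudyConfig
) -> list[SignalRecord]:
    """Filter and normalize every record with its modality's spec."""
    return [
        _preprocess.preprocess_record(
            rec, config.filters[rec.modality], config.normalization
        )
        for rec in records
    ]


def cohort_energy_points(
    processed: list[SignalRecord], config: StudyConfig
) -> tuple[dict, dict, dict[str, _classify.LabeledPoints]]:
    """Group energy profiles and z-scored labeled points per modality.

    Returns ``(raw_profiles, zscored_profiles, labeled_points)``; the
    labeled points are the classifier inputs — by default the 2 × n_segment
    z-scored group-mean energies (one dimension per point).
    """
    fset = config.features
    start_min = (
        fset.analysis_start_min
        if fset.analysis_start_min is not None
        else config.cohort.baseline_min
    )
    by_key: dict[tuple[str, str], list[np.ndarray]] = {}
    for rec in processed:
        skip = int(round(start_min * 60.0 * rec.fs))
        analyzed = rec.with_samples(rec.samples[skip:]) if skip else rec
        means = _features.subject_segment_means(
            analyzed, fset.segment_min, fset.window_s, fset.window_step_s
        )
        by_key.setdefault((rec.modality, rec.condition), []).append(means)

    raw: dict[str, dict[str, _features.GroupProfile]] = {}
    zscored: dict[str, dict[str, _features.GroupProfile]] = {}
    points: dict[str, _classify.LabeledPoints] = {}
    modalities = sorted({m for m, _ in by_key})
    for modality in modalities:
        mats = {
            cond: _features.stack_common_segments(by_key[(modality, cond)])
            for cond in ("caffeine", "placebo")
        }
        n_common = min(m.shape[1] for m in mats.values())
        mats = {c: m[:, :n_common] for c, m in mats.items()}
        prof = {
            cond: _features.group_mean_profile(mats[cond], cond, modality)
            for cond in mats
        }
        z_caf, z_pla = _features.zscore_joint(prof["caffeine"], prof["placebo"])
        raw[modality] = prof
        zscored[modality] = {"caffeine": z_caf, "placebo": z_pla}

        if config.classify.sample_unit == "group_point":
            feats = np.concatenate([z_caf.points, z_pla.points])
            labels = np.array(
                ["caffeine"] * z_caf.points.size + ["placebo"] * z_pla.points.size
            )
        elif config.classify.sample_unit == "subject_point":
            pooled = np.concatenate([mats["caffeine"].ravel(), mats["placebo"].ravel()])
            mu, sd = pooled.mean(), pooled.std()
            if sd == 0:
                raise ValueError("zero pooled sd for subject-level points")
            feats = (pooled - mu) / sd
            labels = np.array(
                ["caffeine"] * mats["caffeine"].size + ["placebo"] * mats["placebo"].size
            )
        else:
            raise ValueError(f"unknown sample_unit {config.classify.sample_unit!r}")
        points[modality] = _classify.LabeledPoints(feats, labels)
    return raw, zscored, points


def run_study(
    config: StudyConfig, records: list[SignalRecord] | None = None,
    persist_signals: bool = False,
) -> StudyResult:
    """Execute the full study and return (and optionally persist) results.

    ``records`` may carry a pre-generated or loaded cohort; by default the
    cohort is simulated from ``config.cohort``.
    """
    stages: list[tuple[str, float]] = []
    t0 = time.perf_counter()

    def mark(stage: str) -> None:
        stages.append((stage, time.perf_counter() - t0))
        logger.info("stage %-12s done at %.2f s", stage, stages[-1][1])

    try:
        if records is None:
            records = _synth.generate_cohort(config.cohort)
        mark("synth")
        processed = preprocess_cohort(records, config)
        mark("preprocess")
        raw, zscored, points = cohort_energy_points(processed, config)
        mark("features")
        table = _classify.run_classifier_bank(points, seed=config.classify.seed)
        mark("classify")
    except Exception as exc:
        failed = ("synth", "preprocess", "features", "classify")[len(stages)]
        raise RuntimeError(f"study failed in stage {failed!r}: {exc}") from exc

    provenance = {
        "config": _config_to_jsonable(config),
        "config_hash": config_hash(config),
        "seed": config.cohort.seed,
        "n_records": len(records),
        "stage_seconds": {name: round(t, 3) for name, t in stages},
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    result = StudyResult(profiles=raw, zscored=zscored, table=table, provenance=provenance)

    if config.output_dir is not None:
        _persist(result, records, config, persist_signals)
    return result


def _persist(
    result: StudyResult, records: list[SignalRecord], config: StudyConfig,
    persist_signals: bool,
) -> None:
    out = Path(config.output_dir)
    for sub in ("signals", "features", "profiles", "results"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    if persist_signals:
        _synth.write_cohort(records, out / "signals")
    for modality in result.profiles:
        frame = _features.profiles_to_frame(
            {c: p for c, p in result.profiles[modality].items()},
            {c: p for c, p in result.zscored[modality].items()},
        )
        frame.to_csv(out / "profiles" / f"profile_{modality}.csv", index=False)
        frame.to_csv(out / "features" / f"features_{modality}.csv", index=False)
    result.table.to_csv(out / "results" / "classifier_accuracy.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=2))
    logger.info("results persisted under %s", out)
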