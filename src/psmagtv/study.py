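"""End-to-end study orchestration.

``run_study`` chains phantom simulation -> pre-processing -> the full
semi-automatic segmentation battery -> observer simulation and STAPLE
fusion (the "Manual" method) -> exclusion-aware metrics -> the Table-1
style summary, for a configurable number of synthetic cases. Per-case seeds
are derived deterministically from one master seed, so a repeated run with
the same configuration reproduces every output bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import volume_ml
from .metrics import evaluate_case
from .phantom import ObserverModel, PhantomSpec, generate_phantom, simulate_observers
from .preprocess import crop_to_prostate, embed_mask, remove_bladder
from .report import build_summary, render_markdown
from .segment import SegmentationConfig, segment_all
from .staple import interobserver_dsc, staple

__all__ = ["StudyConfig", "StudyResult", "run_study", "load_config", "save_config"]

log = logging.getLogger("psmagtv")


@dataclass(frozen=True)
class StudyConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    observers: ObserverModel = field(default_factory=ObserverModel)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    n_cases: int = 20
    master_seed: int = 1234
    margin_voxels: int = 2
    #: write per-case NIfTI artifacts (slower, larger output)
    save_volumes: bool = True

    def __post_init__(self):
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")


@dataclass
class StudyResult:
    summary: pd.DataFrame
    records: list
    interobserver: list          # per-case pooled pairwise Dice of the observers
    reference_volumes: dict
    output_dir: Path | None


def _case_seeds(master_seed: int, n_cases: int) -> np.ndarray:
    """Two deterministic sub-2^31 seeds (phantom, observers) per case."""
    ss = np.random.SeedSequence(int(master_seed))
    state = ss.generate_state(2 * n_cases, dtype=np.uint64)
    return (state % (2**31)).astype(np.int64).reshape(n_cases, 2)


def _config_to_dict(config: StudyConfig) -> dict:
    return {
        "phantom": dataclasses.asdict(config.phantom),
        "observers": dataclasses.asdict(config.observers),
        "segmentation": dataclasses.asdict(config.segmentation),
        "n_cases": config.n_cases,
        "master_seed": config.master_seed,
        "margin_voxels": config.margin_voxels,
        "save_volumes": config.save_volumes,
    }


def load_config(path) -> StudyConfig:
    """Read a :class:`StudyConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "phantom" in kwargs:
        kwargs["phantom"] = PhantomSpec(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in kwargs["phantom"].items()
        })
    if "observers" in kwargs:
        kwargs["observers"] = ObserverModel(**kwargs["observers"])
    if "segmentation" in kwargs:
        kwargs["segmentation"] = SegmentationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in kwargs["segmentation"].items()
        })
    return StudyConfig(**kwargs)


def save_config(config: StudyConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=True)


def run_case(config: StudyConfig, phantom_seed: int, observer_seed: int, case_id: str):
    """Run one synthetic case; returns (records, interobserver_dsc, ref_ml,
    artifacts) where artifacts maps names to images for optional saving."""
    spec = dataclasses.replace(config.phantom, seed=int(phantom_seed))
    obs_model = dataclasses.replace(config.observers, seed=int(observer_seed))

    suv, prostate, bladder, reference = generate_phantom(spec)
    region = crop_to_prostate(suv, prostate, config.margin_voxels)
    region = remove_bladder(region, bladder)

    records = []

    observers = simulate_observers(reference.positive, prostate, obs_model)
    fusion = staple(observers)
    records.append(evaluate_case(fusion.consensus, reference, case_id, "Manual"))
    iod = interobserver_dsc(observers)

    for result in segment_all(region, config.segmentation):
        pred = embed_mask(region, result.gtv)
        records.append(evaluate_case(pred, reference, case_id, result.method_label))
        if result.empty:
            log.info("case %s: no GTV generated by %s", case_id, result.method_label)

    artifacts = {
        "suv": suv,
        "prostate": prostate,
        "bladder": bladder,
        "positive": reference.positive,
        "exclusion": reference.exclusion,
        "manual_consensus": fusion.consensus,
        **{f"observer_{j}": m for j, m in enumerate(observers)},
    }
    return records, iod, volume_ml(reference.positive), artifacts


def _records_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "case_id": r.case_id,
            "method_label": r.method_label,
            "dsc": r.dsc,
            "hd95_mm": np.nan if r.hd95_mm is None else r.hd95_mm,
            "coverage": r.coverage,
            "fdr": np.nan if r.fdr is None else r.fdr,
            "volume_ratio": r.volume_ratio,
            "gtv_ml": r.gtv_ml,
            "reference_ml": r.reference_ml,
            "empty_gtv": r.empty_gtv,
        }
        for r in records
    )


def run_study(config: StudyConfig, output_dir=None) -> StudyResult:
    """Run the full multi-case study.

    When ``output_dir`` is given, writes per-case NIfTI artifacts (if
    ``config.save_volumes``), ``metrics.csv``, ``summary.csv``,
    ``summary.md`` and a JSON manifest with the configuration, package
    version and all derived seeds.
    """
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    seeds = _case_seeds(config.master_seed, config.n_cases)
    all_records = []
    interobs = []
    ref_volumes = {}
    for i in range(config.n_cases):
        case_id = f"case{i:03d}"
        log.info("running %s (phantom seed %d)", case_id, seeds[i, 0])
        records, iod, ref_ml, artifacts = run_case(
            config, seeds[i, 0], seeds[i, 1], case_id
        )
        all_records.extend(records)
        interobs.append(iod)
        ref_volumes[case_id] = ref_ml
        if out is not None and config.save_volumes:
            from .nifti import write_mask, write_suv

            case_dir = out / case_id
            case_dir.mkdir(exist_ok=True)
            for name, img in artifacts.items():
                writer = write_suv if name == "suv" else write_mask
                writer(img, case_dir / f"{name}.nii.gz")

    summary = build_summary(all_records, ref_volumes)

    if out is not None:
        _records_frame(all_records).to_csv(out / "metrics.csv", index=False, float_format="%.8g")
        summary.to_csv(out / "summary.csv", index=False, float_format="%.8g")
        (out / "summary.md").write_text(render_markdown(summary) + "\n")
        manifest = {
            "package_version": __version__,
            "config": _config_to_dict(config),
            "case_seeds": seeds.tolist(),
            "interobserver_dsc": interobs,
            "reference_volumes_ml": ref_volumes,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return StudyResult(
        summary=summary,
        records=all_records,
        interobserver=interobs,
        reference_volumes=ref_volumes,
        output_dir=out,
    )
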