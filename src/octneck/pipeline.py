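"""Per-case and whole-study orchestration.

``run_case`` executes the imaging pipeline end to end for one aneurysm:
polar remap -> three-class segmentation -> neck-coverage map -> gap areas ->
occlusion prediction.  ``run_study`` aggregates case results and runs the
study statistics; it also works from the case table alone (no volumes), so
the tabulated analyses are reproducible without imaging data.

Reports are plain dicts serialised with sorted keys and no timestamps, so a
re-run on identical inputs is byte-identical; every report embeds the
configuration hash and any seeds used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import coverage as cov
from . import stats as st
from .exceptions import InputError, StageError
from .geometry import build_neck_surface
from .io import CaseRecord, read_annotation, read_case_table, read_volume
from .segmentation import SegmentationParams, classify_volume

log = logging.getLogger("octneck")

__all__ = ["PipelineConfig", "CaseResult", "run_case", "run_study"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the imaging pipeline and the threshold rule."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    band_halfwidth_um: float = 100.0
    include_tissue: bool = False
    threshold_mm2: float = 1.0
    n_radii: int | None = None  # polar radial samples; None -> half frame size

    def to_dict(self) -> dict:
        return {
            "segmentation": self.segmentation.to_dict(),
            "band_halfwidth_um": self.band_halfwidth_um,
            "include_tissue": self.include_tissue,
            "threshold_mm2": self.threshold_mm2,
            "n_radii": self.n_radii,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        seg = d.pop("segmentation", {})
        return cls(segmentation=SegmentationParams.from_dict(seg), **d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CaseResult:
    """Outcome of the imaging pipeline for one aneurysm."""

    case_id: str
    largest_gap_mm2: float
    gap_areas_mm2: list[float]
    prediction: cov.Occlusion
    covered_fraction: float
    total_neck_area_mm2: float
    artifacts: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "largest_gap_mm2": self.largest_gap_mm2,
            "gap_areas_mm2": self.gap_areas_mm2,
            "prediction": self.prediction.value,
            "covered_fraction": self.covered_fraction,
            "total_neck_area_mm2": self.total_neck_area_mm2,
            "artifacts": self.artifacts,
        }


def _stage(stage: str, case_id: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                log.error("stage %s failed for case %s: %s", stage, case_id, exc)
                raise StageError(stage, case_id, exc) from exc
            return False

    return _Ctx()


def run_case(
    volume_path,
    annotation_path,
    config: PipelineConfig | None = None,
    meta_path=None,
    out_dir=None,
    case_id: str = "case",
) -> CaseResult:
    """Run remap -> classify -> coverage -> gaps -> prediction for one case.

    ``meta_path`` defaults to the volume path with a ``.json`` suffix.
    Deterministic for fixed inputs and config.
    """
    config = config or PipelineConfig()
    if meta_path is None:
        meta_path = Path(volume_path).with_suffix(".json")

    with _stage("io", case_id):
        volume = read_volume(volume_path, meta_path)
    with _stage("geometry", case_id):
        annotation = read_annotation(annotation_path)
        neck = build_neck_surface(annotation, volume.geometry)
    with _stage("segmentation", case_id):
        labels = classify_volume(volume, config.segmentation, n_radii=config.n_radii)
    with _stage("coverage", case_id):
        cmap = cov.build_coverage_map(
            labels, neck, config.band_halfwidth_um, config.include_tissue
        )
        gaps = cov.find_gaps(cmap)
        largest = gaps[0].area_mm2 if gaps else 0.0
        prediction = cov.predict_occlusion(largest, config.threshold_mm2)

    result = CaseResult(
        case_id=case_id,
        largest_gap_mm2=largest,
        gap_areas_mm2=[g.area_mm2 for g in gaps],
        prediction=prediction,
        covered_fraction=cmap.covered_fraction,
        total_neck_area_mm2=neck.total_area_mm2,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        grid_path = out / f"{case_id}_coverage.csv"
        summary_path = out / f"{case_id}_result.json"
        cov.write_coverage_csv(cmap, grid_path)
        result.artifacts = {"coverage_csv": str(grid_path), "result_json": str(summary_path)}
        payload = result.to_dict()
        payload["config_hash"] = config.config_hash()
        with open(summary_path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    log.info("case %s: largest gap %.4f mm^2 -> %s", case_id, largest, prediction.value)
    return result


def _case_id(record: CaseRecord) -> str:
    return f"{record.animal_id}_{record.location}"


def run_study(
    cases: Sequence[CaseRecord] | str | Path,
    volumes: dict[str, tuple] | None = None,
    config: PipelineConfig | None = None,
    out_dir=None,
    agreement_pairs: Sequence[tuple[float, float]] | None = None,
    seed: int | None = None,
) -> dict:
    """Aggregate per-case results and run the study statistics.

    ``cases`` is a list of :class:`CaseRecord` or a case-table CSV path.
    ``volumes`` optionally maps case ids (``animal_location``) to
    ``(volume_path, annotation_path)``; failing cases are flagged, not fatal.
    ``agreement_pairs`` are optional paired gap measurements from two
    modalities for Bland-Altman agreement.
    """
    config = config or PipelineConfig()
    if not isinstance(cases, (list, tuple)):
        cases = read_case_table(cases)
    if not cases:
        raise InputError("study needs at least one case")

    report: dict = {
        "config_hash": config.config_hash(),
        "threshold_mm2": config.threshold_mm2,
        "seed": seed,
        "n_cases": len(cases),
    }

    if volumes:
        imaging: dict[str, dict] = {}
        for cid, (vol_path, ann_path) in sorted(volumes.items()):
            try:
                res = run_case(vol_path, ann_path, config, out_dir=out_dir, case_id=cid)
                imaging[cid] = res.to_dict()
            except StageError as exc:  # isolate per-case failures
                log.warning("case %s flagged: %s", cid, exc)
                imaging[cid] = {"case_id": cid, "error": str(exc), "stage": exc.stage}
        report["imaging"] = imaging

    summary = st.group_summary(cases)
    report["group_summary"] = summary

    devices = sorted({c.device for c in cases})
    if set(devices) == {"NGID", "coils"}:
        hern = np.array(
            [
                [sum(c.herniation for c in cases if c.device == "NGID"),
                 sum(not c.herniation for c in cases if c.device == "NGID")],
                [sum(c.herniation for c in cases if c.device == "coils"),
                 sum(not c.herniation for c in cases if c.device == "coils")],
            ]
        )
        hern_table = st.ContingencyTable2x2(*hern.ravel().tolist())
        report["herniation"] = {
            "table": hern.tolist(),
            "proportion_coils": summary["coils"]["herniation_proportion"],
            "fisher_p": st.fisher_exact_2x2(hern_table),
        }

        a = [float(c.n_implants) for c in cases if c.device == "NGID"]
        b = [float(c.n_implants) for c in cases if c.device == "coils"]
        method = "exact_permutation" if len(a) + len(b) <= 12 else "normal_approx"
        u, p = st.mann_whitney_u(a, b, method=method)
        report["implants_mann_whitney"] = {"U": u, "p": p, "method": method}

        occ = np.array(
            [
                [sum(st.dichotomize_dsa(c.dsa_180d) is st.Outcome.BAD for c in cases if c.device == d),
                 sum(st.dichotomize_dsa(c.dsa_180d) is st.Outcome.GOOD for c in cases if c.device == d)]
                for d in ("NGID", "coils")
            ]
        )
        report["occlusion_180d"] = {
            "table": occ.tolist(),
            "fisher_p": st.fisher_exact_2x2(st.ContingencyTable2x2(*occ.ravel().tolist())),
        }

    if any(c.largest_gap_mm2 is not None for c in cases):
        thr = st.threshold_predictivity(cases, config.threshold_mm2)
        report["threshold"] = {
            "value_mm2": config.threshold_mm2,
            "table": thr.table.as_array().tolist(),
            "fisher_p": thr.fisher_p,
            "misclassified": thr.misclassified,
            "n": thr.n,
        }

    if agreement_pairs is not None:
        ba = st.bland_altman(agreement_pairs)
        report["agreement"] = {
            "bias_mm2": ba.bias,
            "loa_low_mm2": ba.loa_low,
            "loa_high_mm2": ba.loa_high,
            "n_pairs": ba.n_pairs,
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "study_report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report


def summarize_report(report: dict) -> str:
    """Human-readable study summary."""
    lines = [f"Study of {report['n_cases']} aneurysms (config {report['config_hash']})"]
    gs = report.get("group_summary", {})
    for device, s in gs.items():
        lines.append(
            f"  {device}: n={s['n']}, mean implants {s['mean_implants']:.2f}, "
            f"herniation {100 * s['herniation_proportion']:.0f}%"
        )
    if "herniation" in report:
        lines.append(f"  herniation Fisher p = {report['herniation']['fisher_p']:.3f}")
    if "implants_mann_whitney" in report:
        mw = report["implants_mann_whitney"]
        lines.append(f"  implant counts: U = {mw['U']:.1f}, p = {mw['p']:.4f} ({mw['method']})")
    if "threshold" in report:
        t = report["threshold"]
        lines.append(
            f"  gap > {t['value_mm2']} mm^2 rule: Fisher p = {t['fisher_p']:.4f}, "
            f"{t['misclassified']}/{t['n']} misclassified"
        )
    if "agreement" in report:
        a = report["agreement"]
        lines.append(
            f"  agreement: bias {a['bias_mm2']:.4f} mm^2, "
            f"LoA ({a['loa_low_mm2']:.4f}, {a['loa_high_mm2']:.4f})"
        )
    return "\n".join(lines)
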