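"""End-to-end pipeline: load volumes, section, measure, compare, report.

A run is described by a :class:`RunConfig` (YAML or JSON): a manifest of
patients (id, group, volume/mask/landmark paths, optionally a predicted mask
and predicted landmarks for agreement evaluation), densitometry parameter
overrides, a seed, and an output directory.  ``run_pipeline`` writes

* ``measurements.csv`` — one row per patient per section, full precision;
* ``summary.csv`` — group means ± SD at one-decimal precision;
* ``comparisons.json`` — the inter-/intra-individual t-tests per marker;
* ``agreement.json`` — Dice / ICC / bootstrap mean difference / end
  deviations, when predicted segmentations are supplied;
* ``run.json`` — every parameter used, exclusions with reasons, library
  versions, so no setting is silently defaulted.

Two runs with the same config and seed produce identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import agreement_summary, compare_inter, compare_intra, dice
from .densitometry import DensitometryParams, measure_patient
from .geometry import (
    AAA_REQUIRED,
    CONTROL_REQUIRED,
    LandmarkSet,
    end_deviation,
    extract_centerline,
    section_aorta,
)
from .io import CTVolume, load_landmarks, load_mask, load_mask_raw, load_volume

log = logging.getLogger("pvat")


@dataclass
class PatientEntry:
    patient_id: str
    group: str  # "AAA" | "control"
    volume: str
    mask: str
    landmarks: str
    predicted_mask: str | None = None
    predicted_landmarks: str | None = None

    def __post_init__(self) -> None:
        if self.group not in ("AAA", "control"):
            raise ValueError(f"group must be 'AAA' or 'control', got {self.group!r}")


@dataclass
class RunConfig:
    manifest: list[PatientEntry]
    output_dir: str = "pvat_out"
    seed: int = 0
    log_level: str = "INFO"
    params: DensitometryParams = field(default_factory=DensitometryParams)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        entries = [PatientEntry(**row) for row in d["manifest"]]
        p = d.get("params", {})
        params = DensitometryParams(
            **{k: tuple(v) if isinstance(v, list) else v for k, v in p.items()}
        )
        return cls(
            manifest=entries,
            output_dir=d.get("output_dir", "pvat_out"),
            seed=int(d.get("seed", 0)),
            log_level=d.get("log_level", "INFO"),
            params=params,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)


def _required_roles(group: str):
    return AAA_REQUIRED if group == "AAA" else CONTROL_REQUIRED


def validate_inputs(config: RunConfig) -> list[dict]:
    """Non-mutating consistency report over every manifest entry.

    Checks file existence, NIfTI grid consistency (shape, spacing, affine),
    mask binarity, and landmark completeness for the patient's group.
    Returns a machine-readable list of issues; empty means clean.
    """
    issues: list[dict] = []

    def add(pid: str, issue: str) -> None:
        issues.append({"patient_id": pid, "issue": issue})

    for entry in config.manifest:
        pid = entry.patient_id
        missing = [p for p in (entry.volume, entry.mask, entry.landmarks) if not Path(p).exists()]
        if missing:
            add(pid, f"missing files: {missing}")
            continue
        vol = load_volume(entry.volume)
        mask_data, mask_spacing, mask_affine = load_mask_raw(entry.mask)
        if vol.shape != mask_data.shape:
            add(pid, f"grid mismatch: volume shape {vol.shape} vs mask shape {mask_data.shape}")
        if not np.allclose(vol.spacing, mask_spacing, rtol=1e-4):
            add(pid, f"grid mismatch: volume spacing {vol.spacing} vs mask spacing {mask_spacing}")
        offdiag = mask_affine[:3, :3] - np.diag(np.diag(mask_affine[:3, :3]))
        if not np.allclose(offdiag, 0.0, atol=1e-6):
            add(pid, "non-diagonal affine: oblique grids are not supported")
        extra = set(np.unique(mask_data)) - {0, 1}
        if extra:
            add(pid, f"non-binary mask: values {sorted(int(v) for v in extra)} present")
        lms = load_landmarks(entry.landmarks)
        missing_roles = sorted(_required_roles(entry.group) - set(lms))
        if missing_roles:
            add(pid, f"missing landmarks for {entry.group} patient: {missing_roles}")
    return issues


def _analyze_patient(entry: PatientEntry, params: DensitometryParams):
    volume = load_volume(entry.volume)
    mask, mask_spacing = load_mask(entry.mask)
    if volume.shape != mask.shape or not np.allclose(volume.spacing, mask_spacing, rtol=1e-4):
        raise ValueError(
            f"{entry.patient_id}: grid mismatch between volume "
            f"(shape {volume.shape}, spacing {volume.spacing}) and mask "
            f"(shape {mask.shape}, spacing {mask_spacing})"
        )
    lms = LandmarkSet(load_landmarks(entry.landmarks))
    required = _required_roles(entry.group)
    missing = sorted(required - set(lms.points))
    if missing:
        raise ValueError(
            f"{entry.patient_id}: {entry.group} patient is missing landmark roles {missing}"
        )
    cl = extract_centerline(mask, volume.spacing)
    sections = section_aorta(mask, volume.spacing, cl, lms)
    measurements = measure_patient(
        volume, mask, sections, params, patient_id=entry.patient_id
    )
    return volume, mask, lms, sections, measurements


def _summary_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    order = [
        ("AAA", "aneurysmal"),
        ("control", "infrarenal"),
        ("AAA", "non_aneurysmal_abdominal"),
    ]
    for group, section in order:
        sub = df[(df["group"] == group) & (df["section"] == section) & df["valid"]]
        if sub.empty:
            continue
        row = {"cohort": group, "section": section, "n": len(sub)}
        for col, name in (
            ("hu_close", "hu_close"),
            ("hu_distant", "hu_distant"),
            ("hu_delta", "hu_delta"),
            ("hu_ratio_pct", "hu_ratio_pct"),
        ):
            row[name] = f"{sub[col].mean():.1f} ± {sub[col].std(ddof=1):.1f}"
        rows.append(row)
    return pd.DataFrame(rows)


def _agreement_block(config: RunConfig, per_patient: dict):
    dice_per_case: dict[str, float] = {}
    marker_pairs: dict[str, list[list[float]]] = {"hu_delta": [], "hu_ratio": []}
    end_devs = []
    for entry in config.manifest:
        if entry.predicted_mask is None:
            continue
        volume, mask, lms, sections, measurements = per_patient[entry.patient_id]
        pred_mask, _ = load_mask(entry.predicted_mask)
        dice_per_case[entry.patient_id] = dice(mask, pred_mask)

        # evaluation section: aneurysmal for AAA patients, infrarenal for controls
        target = "aneurysmal" if entry.group == "AAA" else "infrarenal"
        ref = next((m for m in measurements if m.section == target), None)
        try:
            cl = extract_centerline(pred_mask, volume.spacing)
            pred_sections = section_aorta(pred_mask, volume.spacing, cl, lms)
            pred_meas = measure_patient(
                volume, pred_mask, pred_sections, config.params, patient_id=entry.patient_id
            )
            pred = next((m for m in pred_meas if m.section == target), None)
        except ValueError as exc:
            log.warning("%s: predicted mask unusable (%s)", entry.patient_id, exc)
            pred = None
        if ref is not None and pred is not None and ref.valid and pred.valid:
            marker_pairs["hu_delta"].append([ref.hu_delta, pred.hu_delta])
            marker_pairs["hu_ratio"].append([ref.hu_ratio_pct, pred.hu_ratio_pct])

        if entry.predicted_landmarks is not None and entry.group == "AAA":
            pred_lms = LandmarkSet(load_landmarks(entry.predicted_landmarks))
            end_devs.append(end_deviation(sections.centerline, pred_lms, lms))

    pairs = {
        m: np.asarray(v) for m, v in marker_pairs.items() if len(v) >= 5
    }
    if not dice_per_case:
        return None
    return agreement_summary(
        dice_per_case, pairs, end_deviations=end_devs or None, seed=config.seed
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the paths of the written artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    rows = []
    per_patient = {}
    for entry in config.manifest:
        volume, mask, lms, sections, measurements = _analyze_patient(entry, config.params)
        per_patient[entry.patient_id] = (volume, mask, lms, sections, measurements)
        for m in measurements:
            rows.append({"group": entry.group, **m.to_dict()})
        log.info("%s: measured sections %s", entry.patient_id, sections.section_names())
    df = pd.DataFrame(rows)
    measurements_csv = out / "measurements.csv"
    df.to_csv(measurements_csv, index=False)
    _summary_table(df).to_csv(out / "summary.csv", index=False)

    all_meas = [m for (_, _, _, _, ms) in per_patient.values() for m in ms]
    aaa_ids = {e.patient_id for e in config.manifest if e.group == "AAA"}
    aneurysmal = [m for m in all_meas if m.section == "aneurysmal"]
    infrarenal = [m for m in all_meas if m.section == "infrarenal"]
    aaa_sections = [m for m in all_meas if m.patient_id in aaa_ids]

    comparisons = {}
    for marker in ("hu_delta", "hu_ratio"):
        if len(aneurysmal) >= 2 and len(infrarenal) >= 2:
            try:
                comparisons[f"inter_{marker}"] = compare_inter(
                    aneurysmal, infrarenal, marker
                ).to_dict()
            except ValueError as exc:
                log.warning("inter comparison (%s) skipped: %s", marker, exc)
        if len(aaa_sections) >= 4:
            try:
                comparisons[f"intra_{marker}"] = compare_intra(aaa_sections, marker).to_dict()
            except ValueError as exc:
                log.warning("intra comparison (%s) skipped: %s", marker, exc)
    comparisons_json = out / "comparisons.json"
    comparisons_json.write_text(json.dumps(comparisons, indent=2, sort_keys=True) + "\n")

    agreement = _agreement_block(config, per_patient)
    artifacts = {
        "measurements": str(measurements_csv),
        "summary": str(out / "summary.csv"),
        "comparisons": str(comparisons_json),
    }
    if agreement is not None:
        agreement_json = out / "agreement.json"
        agreement_json.write_text(
            json.dumps(agreement.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        artifacts["agreement"] = str(agreement_json)

    exclusions = sorted(
        {
            (pid, reason)
            for comp in comparisons.values()
            for pid, reason in (tuple(e) for e in comp["excluded"])
        }
    )
    run_log = {
        "pvat_version": __version__,
        "seed": config.seed,
        "params": asdict(config.params),
        "n_patients": len(config.manifest),
        "groups": {
            "AAA": sum(1 for e in config.manifest if e.group == "AAA"),
            "control": sum(1 for e in config.manifest if e.group == "control"),
        },
        "exclusions": [{"patient_id": p, "reason": r} for p, r in exclusions],
        "versions": _versions(),
        "artifacts": artifacts,
    }
    (out / "run.json").write_text(json.dumps(run_log, indent=2, sort_keys=True) + "\n")
    artifacts["run_log"] = str(out / "run.json")
    return artifacts


def _versions() -> dict[str, str]:
    import nibabel
    import scipy

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "nibabel": nibabel.__version__,
        "pandas": pd.__version__,
    }
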