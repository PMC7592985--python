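"""End-to-end pipeline orchestration.

Ties the stages together: median filtering and reference-tissue intensity
standardization -> per-channel feature extraction and matrix assembly ->
leave-one-patient-out selection/training/calibration -> voxel-wise binary
and probability maps.  Also defines the on-disk per-patient layout used by
the command line.
"""

from __future__ import annotations

import json
import os
from dataclasses import replace as dc_replace

import numpy as np
import pandas as pd
import yaml

from . import model as mdl
from .config import RunConfig
from .dti_features import compute_dti_maps
from .preprocess import (
    build_reference_stats,
    median_filter,
    reference_summary,
    standardize_intensity,
)
from .texture_features import extract_channel_features, assemble_feature_matrix
from .volume_io import (
    MISSING,
    DtiEigenvalues,
    PatientCase,
    ROIMask,
    VoxelVolume,
    read_mask,
    read_volume,
    write_mask,
    write_volume,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and patient."""


def preprocess_case(case: PatientCase, config: RunConfig) -> PatientCase:
    """Median-filter and standardize the configured channels of one case.

    Standardization divides each configured channel by the median + IQR of
    that patient's reference tissue, measured on the filtered volume, so
    the standardized reference summary is 1.
    """
    updates: dict[str, VoxelVolume] = {}
    for name in ("t2w", "dwi_highb", "adc"):
        vol = getattr(case, name)
        if name in config.median_filter_channels:
            vol = median_filter(vol, config.median_window)
        if name in config.standardize_channels:
            divisor = reference_summary(vol, case.reference_tissue)
            vol = standardize_intensity(vol, divisor)
        if vol is not getattr(case, name):
            updates[name] = vol
    return dc_replace(case, **updates) if updates else case


def preprocess_cohort(
    cases: list[PatientCase], config: RunConfig
) -> tuple[list[PatientCase], dict]:
    """Preprocess every case; report the reference-tissue reproducibility."""
    stats = build_reference_stats(
        "reference_tissue",
        [(c.patient_id, c.t2w, c.reference_tissue) for c in cases],
    ) if len(cases) >= 2 else None
    out = [preprocess_case(c, config) for c in cases]
    report = {
        "reference_tissue": {
            "inter_cv_percent": stats.inter_cv_percent if stats else None,
            "per_patient_summary": dict(stats.per_patient_summary) if stats else {},
        }
    }
    return out, report


def case_labels(case: PatientCase, config: RunConfig):
    """Consensus cancer/noncancer masks for one case."""
    r1 = [p[0] for p in case.rater_masks]
    r2 = [p[1] for p in case.rater_masks]
    return mdl.curate_reference_labels(
        r1, r2, case.pz, config.min_lesion_volume_cc
    )


def extract_case_matrix(
    case: PatientCase,
    config: RunConfig,
    cancer: ROIMask | None = None,
    noncancer: ROIMask | None = None,
) -> pd.DataFrame:
    """Assemble the labeled voxel-feature matrix for one (preprocessed) case."""
    if cancer is None or noncancer is None:
        cancer, noncancer, _ = case_labels(case, config)
    featsets = [
        extract_channel_features(
            getattr(case, name), case.pz, name,
            window=config.window, levels=config.glcm_levels,
            bins=config.first_order_bins,
        )
        for name in config.scalar_channels
    ]
    dti = (
        compute_dti_maps(case.eigenvalues, case.pz) if config.include_dti else None
    )
    df = assemble_feature_matrix(featsets, dti, cancer, noncancer, case.patient_id)
    n_feat = len([c for c in df.columns if c not in
                  ("patient_id", "slice", "row", "col", "label")])
    if n_feat != config.expected_feature_count:
        raise PipelineError(
            f"extract[{case.patient_id}]: {n_feat} feature columns, expected "
            f"{config.expected_feature_count} for {config.channel_config}"
        )
    return df


def extract_cohort_matrices(
    cases: list[PatientCase], config: RunConfig, preprocessed: bool = False
) -> dict[str, pd.DataFrame]:
    if not preprocessed:
        cases, _ = preprocess_cohort(cases, config)
    out = {}
    for case in cases:
        try:
            out[case.patient_id] = extract_case_matrix(case, config)
        except Exception as exc:
            raise PipelineError(f"extract[{case.patient_id}]: {exc}") from exc
    return out


def predict_maps(
    model: "mdl.TrainedModel", case: PatientCase, config: RunConfig
) -> tuple[VoxelVolume, VoxelVolume]:
    """Voxel-wise cancer probability and binary maps over the PZ.

    The case must be preprocessed with the same configuration the model was
    trained under.  Outside the PZ both maps carry the missing value; the
    binary map is 1 where the decision function is positive, which is also
    where the calibrated probability crosses the sigmoid midpoint.
    """
    empty = ROIMask(np.zeros(case.pz.shape, dtype=bool), case.pz.spacing, "cancer")
    allpz = ROIMask(case.pz.data.copy(), case.pz.spacing, "noncancer")
    df = extract_case_matrix(case, config, cancer=empty, noncancer=allpz)
    try:
        f = model.decision_values(df)
    except ValueError as exc:
        raise PipelineError(
            f"predict[{case.patient_id}]: channel configuration mismatch: {exc}"
        ) from exc
    A, B = model.platt
    prob_vals = mdl.platt_probability(f, A, B)
    prob = np.full(case.pz.shape, MISSING)
    binary = np.full(case.pz.shape, MISSING)
    ss = df["slice"].to_numpy()
    rr = df["row"].to_numpy()
    cc = df["col"].to_numpy()
    prob[ss, rr, cc] = prob_vals
    binary[ss, rr, cc] = (f > 0).astype(np.float64)
    return VoxelVolume(prob, case.pz.spacing), VoxelVolume(binary, case.pz.spacing)


def run_pipeline(
    config: RunConfig,
    cases: list[PatientCase] | None = None,
    output_dir: str | None = None,
) -> mdl.EvalReport:
    """Full workflow: preprocess -> extract -> LOPO train/validate -> maps.

    When ``cases`` is None they are loaded from ``config.input_dir``.  When
    an output directory is given, the evaluation report, the preprocessing
    report, the configuration, and each held-out patient's probability and
    binary maps are written there.
    """
    if cases is None:
        if not config.input_dir:
            raise PipelineError("run: no cases given and no input_dir configured")
        cases = load_cohort(config.input_dir)
    cases, pre_report = preprocess_cohort(cases, config)
    matrices = extract_cohort_matrices(cases, config, preprocessed=True)
    report, models = mdl.lopo_run(cases, config, matrices=matrices)

    out = output_dir or config.output_dir
    if out:
        import hashlib

        from sklearn.metrics import roc_curve

        os.makedirs(out, exist_ok=True)
        cfg_hash = hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
        report.config["config_hash"] = cfg_hash
        report.to_json(os.path.join(out, "eval_report.json"))
        with open(os.path.join(out, "preprocess_report.json"), "w") as fh:
            json.dump(pre_report, fh, indent=2, default=float)
        config.save_yaml(os.path.join(out, "config.yaml"))
        for pid, model in models.items():
            case = next(c for c in cases if c.patient_id == pid)
            prob, binary = predict_maps(model, case, config)
            write_volume(prob, os.path.join(out, f"{pid}_probability.nii"))
            write_volume(binary, os.path.join(out, f"{pid}_binary.nii"))
            test_df = matrices[pid]
            if test_df["label"].nunique() == 2:
                f = model.decision_values(test_df)
                fpr, tpr, thr = roc_curve(test_df["label"] == 1, f)
                pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(
                    os.path.join(out, f"{pid}_roc.csv"), index=False
                )
    return report


# ---------------------------------------------------------------------------
# On-disk case layout
# ---------------------------------------------------------------------------

_CHANNEL_FILES = ("t2w", "dwi_highb", "adc", "lambda1", "lambda2", "lambda3")


def write_case(case: PatientCase, directory: str, ext: str = ".nii.gz") -> None:
    """Write one case as NIfTI volumes plus a YAML manifest."""
    os.makedirs(directory, exist_ok=True)
    manifest: dict = {"patient_id": case.patient_id, "channels": {}, "masks": {},
                      "rater_masks": []}
    vols = {
        "t2w": case.t2w, "dwi_highb": case.dwi_highb, "adc": case.adc,
        "lambda1": case.eigenvalues.lambda1,
        "lambda2": case.eigenvalues.lambda2,
        "lambda3": case.eigenvalues.lambda3,
    }
    for name, vol in vols.items():
        fname = name + ext
        write_volume(vol, os.path.join(directory, fname))
        manifest["channels"][name] = fname
    for name, mask in (("pz", case.pz), ("reference_tissue", case.reference_tissue)):
        fname = name + ext
        write_mask(mask, os.path.join(directory, fname))
        manifest["masks"][name] = fname
    for i, (r1, r2) in enumerate(case.rater_masks):
        f1, f2 = f"rater1_{i:03d}{ext}", f"rater2_{i:03d}{ext}"
        write_mask(r1, os.path.join(directory, f1))
        write_mask(r2, os.path.join(directory, f2))
        manifest["rater_masks"].append([f1, f2])
    with open(os.path.join(directory, "case.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def load_case(directory: str) -> PatientCase:
    with open(os.path.join(directory, "case.yaml")) as fh:
        manifest = yaml.safe_load(fh)
    ch = {
        name: read_volume(os.path.join(directory, fname))
        for name, fname in manifest["channels"].items()
    }
    eig = DtiEigenvalues(ch["lambda1"], ch["lambda2"], ch["lambda3"])
    pz = read_mask(os.path.join(directory, manifest["masks"]["pz"]), "PZ")
    ref = read_mask(
        os.path.join(directory, manifest["masks"]["reference_tissue"]),
        "reference_tissue",
    )
    raters = [
        (read_mask(os.path.join(directory, f1), "rater1"),
         read_mask(os.path.join(directory, f2), "rater2"))
        for f1, f2 in manifest["rater_masks"]
    ]
    return PatientCase(
        patient_id=manifest["patient_id"], t2w=ch["t2w"],
        dwi_highb=ch["dwi_highb"], adc=ch["adc"], eigenvalues=eig,
        pz=pz, reference_tissue=ref, rater_masks=raters,
    )


def write_cohort(cases: list[PatientCase], directory: str) -> None:
    for case in cases:
        write_case(case, os.path.join(directory, case.patient_id))


def load_cohort(directory: str) -> list[PatientCase]:
    subdirs = sorted(
        d for d in os.listdir(directory)
        if os.path.isfile(os.path.join(directory, d, "case.yaml"))
    )
    if not subdirs:
        raise PipelineError(f"no cases found under {directory}")
    return [load_case(os.path.join(directory, d)) for d in subdirs]
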