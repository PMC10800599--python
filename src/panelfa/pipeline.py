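"""End-to-end orchestration of the panel → FA workflow.

Two study-shaped variants share the code path:

* "rat" mode — two groups with repeated panel timepoints; group comparison
  uses BKY FDR at Q < 0.1, and the PCA/voxel-wise stages run on the
  injured group's panel at a chosen timepoint against its FA volumes.
* "human" mode — a single timepoint; the group comparison flags raw
  p < 0.05 without FDR, and the PCA/voxel-wise stages run on the patient
  group.

Each run writes a manifest (input hashes, seed, versions, permutation
count, exhaustive flag) sufficient to reproduce every output bit for bit.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from . import panel_stats, pca
from .roi_pcr import extract_roi_fa, pcr_fit
from .voxelwise import Design, TFCEParams, extract_rois, permutation_fwe

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    panel_csv: str
    volumes: list | str
    mask: str
    out_dir: str
    mode: str = "rat"                # "rat" (BKY FDR) or "human" (raw p)
    predict_group: str = "B"         # group whose panel predicts FA
    timepoint: str | None = None     # panel timepoint for PCA (default: last)
    control_group: str | None = "A"  # None skips the group comparison
    max_pcs: int = 3
    n_perm: int = 10_000
    alpha: float = 0.05
    fdr_q: float = 0.1
    tfce: TFCEParams = field(default_factory=TFCEParams)
    contrast: str = "f"
    roi_summary: str = "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("rat", "human"):
            raise ValueError("mode must be 'rat' or 'human'")
        if isinstance(self.tfce, dict):
            self.tfce = TFCEParams(**self.tfce)
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate_paths(self) -> None:
        paths = [self.panel_csv, self.mask]
        if isinstance(self.volumes, str):
            paths.append(self.volumes)
        else:
            paths.extend(self.volumes)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the populated run directory.

    Stage order: group comparison (if a control group is configured) →
    PCA reduction → voxel-wise permutation inference → ROI extraction →
    per-ROI PCR.  An empty significant mask ends the run with an explicit
    "no ROI" report rather than an error.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "read inputs"
    try:
        panel = pio.read_panel(config.panel_csv)
        vol_paths = (config.volumes if isinstance(config.volumes, str)
                     else sorted(config.volumes))
        volumes = pio.read_volumes(vol_paths, config.mask)

        stage = "panel_stats"
        if config.control_group is not None:
            panel_ctrl = panel.select(group=config.control_group)
            panel_case = panel.select(group=config.predict_group)
            comp = panel_stats.compare_panel(
                panel_case, panel_ctrl, q=config.fdr_q,
                per_timepoint=True, fdr=(config.mode == "rat"),
                alpha=config.alpha)
            comp.to_csv(out / "marker_comparison.csv", index=False)
            logger.info("panel_stats: %d comparisons, %d discoveries",
                        len(comp), int(comp["discovery"].sum()))

        stage = "pca_reduction"
        tp = config.timepoint or panel.timepoints()[-1]
        case_tp = panel.select(group=config.predict_group, timepoint=tp)
        model = pca.fit(case_tp, max_components=config.max_pcs)
        model.to_json(out / "pca_model.json")
        model.summary().to_csv(out / "pca_summary.csv")
        logger.info("pca: timepoint=%s K=%d eigenvalues=%s", tp,
                    model.n_components,
                    np.round(model.eigenvalues[:model.n_components], 2))

        stage = "align subjects"
        case_vols = _subset_volumes(volumes, case_tp.subject_id)
        aligned = pio.align_panel_to_volumes(case_tp, case_vols)
        scores = pca.transform(model, aligned)

        stage = "voxelwise_inference"
        design = Design.from_scores(scores)
        result = permutation_fwe(case_vols, design, params=config.tfce,
                                 n_perm_requested=config.n_perm,
                                 alpha=config.alpha, seed=config.seed,
                                 contrast=config.contrast)
        for key, vol in result.stat_maps.items():
            pio.write_nifti(vol, case_vols.affine, out / f"stat_{key}.nii.gz")
        for key, vol in result.corrp_maps.items():
            pio.write_nifti(vol, case_vols.affine, out / f"corrp_{key}.nii.gz")
        pio.write_nifti(result.sig_mask.astype(np.int8), case_vols.affine,
                        out / "sig_mask.nii.gz", dtype=np.int8)

        stage = "extract_rois"
        labels = extract_rois(result.sig_mask, config.tfce.connectivity)
        pio.write_nifti(labels, case_vols.affine, out / "roi_labels.nii.gz",
                        dtype=np.int32)
        n_rois = int(labels.max())

        stage = "roi_pcr"
        roi_reports = []
        for lab in range(1, n_rois + 1):
            y = extract_roi_fa(case_vols, labels == lab,
                               summary=config.roi_summary)
            res = pcr_fit(y, model)
            res.to_json(out / f"roi_{lab}_pcr.json")
            res.coefficients.to_csv(out / f"roi_{lab}_coefficients.csv",
                                    index=False)
            roi_reports.append({"roi": lab,
                                "n_voxels": int((labels == lab).sum()),
                                "F": res.anova["F"], "p": res.anova["p"],
                                "adjusted_r_squared": res.adjusted_r_squared,
                                "shapiro_p": res.shapiro["p"]})
        if n_rois == 0:
            pio.write_json({"n_rois": 0,
                            "message": "no significant voxels at the "
                                       "configured alpha; no ROI analysis "
                                       "performed"},
                           out / "no_roi_report.json")
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") \
            from err

    manifest = {
        "config": _config_dict(config),
        "inputs": {"panel_csv": pio.sha256_file(config.panel_csv),
                   "mask": pio.sha256_file(config.mask)},
        "n_permutations": result.n_perm,
        "exhaustive": result.exhaustive,
        "n_rois": n_rois,
        "rois": roi_reports,
        "timepoint": str(tp),
        "runtime_s": round(time.time() - t0, 2),
        "versions": _versions(),
    }
    if not isinstance(config.volumes, str):
        manifest["inputs"]["volumes"] = {
            str(p): pio.sha256_file(p) for p in sorted(config.volumes)}
    pio.write_json(manifest, out / "manifest.json")
    logger.info("pipeline complete: %d ROI(s), outputs in %s", n_rois, out)
    return out


def _subset_volumes(volumes, subject_ids):
    ids = [str(s) for s in volumes.subject_ids]
    wanted = list(dict.fromkeys(str(s) for s in subject_ids))
    idx = [ids.index(s) for s in wanted if s in ids]
    if len(idx) != len(wanted):
        missing = sorted(set(wanted) - set(ids))
        raise ValueError(f"volumes missing subjects: {missing}")
    from .voxelwise import VolumeStack
    return VolumeStack(volumes.data[idx], volumes.mask, volumes.affine,
                       volumes.subject_ids[idx])


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["tfce"] = asdict(config.tfce) if not isinstance(config.tfce, dict) \
        else config.tfce
    return d


def _versions() -> dict:
    import nibabel
    import scipy

    from . import __version__
    return {"panelfa": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "nibabel": nibabel.__version__}
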