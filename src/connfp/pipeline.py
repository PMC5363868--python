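"""End-to-end pipeline orchestration.

Sequences the full analysis: (synthetic cohort generation or data loading)
-> ROI time-series preprocessing -> correlation / Fisher-z networks ->
minimum-connectedness sparsity search -> binarization -> eigenvector
centrality -> permutation tests on both modalities (volume, centrality) ->
feature selection -> LOOCV random-forest classification -> per-group
fingerprint profiles.  Every stage output is persisted, a hash manifest
written, and the machine-readable run report is byte-reproducible given the
same configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import centrality as _centrality
from . import classify as _classify
from . import fingerprint as _fingerprint
from . import network as _network
from . import preprocess as _preprocess
from . import stats as _stats
from .synthetic import Cohort, CohortConfig, SubjectRecord, generate_cohort

log = logging.getLogger("connfp")


@dataclass
class PreprocessConfig:
    n_discard: int = 4
    poly_order: int = 3
    apply_bandpass: bool | None = None  # None: on for real data, off for synthetic
    low_hz: float = 0.009
    high_hz: float = 0.08


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one input mode applies: ``synthetic`` (generate a cohort from
    ``cohort``), ``tables`` (load a serialized cohort directory from
    ``cohort_dir``: manifest + per-subject time-series CSVs + volumes CSV),
    or ``images`` (extract time series and volumes from per-subject NIfTI
    functional and label images listed in ``image_manifest``).
    """

    mode: str = "synthetic"
    out_dir: str = "connfp_run"
    seed: int = 0
    cohort: CohortConfig | None = None
    cohort_dir: str | None = None
    # images mode: manifest CSV (subject_id, group, func, labels), the atlas
    # labels defining network nodes, and the subset scored volumetrically
    image_manifest: str | None = None
    roi_labels: Sequence[int] | None = None
    target_labels: Sequence[int] | None = None
    tr_seconds: float = 3.0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sparsity: float | None = None  # None = minimum-connectedness search
    grid: _network.SparsityGrid = field(default_factory=_network.SparsityGrid)
    ranking: str = "signed"
    normalization: str = "unit_euclidean"
    n_permutations: int = 5000
    alpha: float = 0.05
    correction: str = "maxT"
    n_trees: int = 500
    nested_selection: bool = False
    write_intermediates: bool = True

    def validate(self) -> None:
        if self.mode not in ("synthetic", "tables", "images"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "tables":
            if not self.cohort_dir:
                raise ValueError("tables mode requires cohort_dir")
            if not Path(self.cohort_dir).exists():
                raise ValueError(f"cohort_dir {self.cohort_dir} does not exist")
        if self.mode == "images":
            if not (self.image_manifest and self.roi_labels and self.target_labels):
                raise ValueError("images mode requires image_manifest, "
                                 "roi_labels and target_labels")
            if not set(self.target_labels) <= set(self.roi_labels):
                raise ValueError("target_labels must be a subset of roi_labels")
            if not Path(self.image_manifest).exists():
                raise ValueError(f"image_manifest {self.image_manifest} "
                                 "does not exist")


def compute_volume(labels: np.ndarray, label_id: int,
                   voxel_dims_mm: Sequence[float]) -> float:
    """Region volume in cc by voxel counting: count * voxel volume / 1000."""
    labels = np.asarray(labels)
    count = int((labels == label_id).sum())
    if count == 0:
        raise ValueError(f"label {label_id} absent from label volume")
    return count * float(np.prod(np.asarray(voxel_dims_mm, dtype=float))) / 1000.0


def _load_image_cohort(cfg: RunConfig) -> Cohort:
    """Assemble a cohort from NIfTI functional images and label volumes.

    Volumes are computed by voxel counting in each subject's label image
    (voxel dimensions from the NIfTI header); ROI time series are mean
    signals over each atlas label. Images must already share a common space.
    """
    import nibabel as nib

    manifest = pd.read_csv(cfg.image_manifest)
    roi_labels = list(cfg.roi_labels)
    roi_names = [f"ROI_{lab}" for lab in roi_labels]
    target_idx = [roi_labels.index(lab) for lab in cfg.target_labels]
    subjects = []
    for row in manifest.itertuples():
        func = nib.load(row.func)
        label_img = nib.load(row.labels)
        label_data = np.rint(np.asanyarray(label_img.dataobj)).astype(int)
        ts = _preprocess.extract_roi_timeseries(func, label_data, roi_labels,
                                                cfg.tr_seconds, roi_names)
        zooms = label_img.header.get_zooms()[:3]
        vols = [compute_volume(label_data, lab, zooms) for lab in cfg.target_labels]
        subjects.append(SubjectRecord(str(row.subject_id), str(row.group),
                                      ts.data, np.asarray(vols)))
    return Cohort(subjects, roi_names, target_idx)


def _preprocess_subject(sub: SubjectRecord, tr: float, roi_names: list[str],
                        cfg: PreprocessConfig, synthetic: bool) -> _preprocess.RoiTimeSeries:
    ts = _preprocess.RoiTimeSeries(sub.timeseries, tr, roi_names)
    ts = _preprocess.discard_initial_volumes(ts, cfg.n_discard)
    ts = _preprocess.regress_nuisance(ts, poly_order=cfg.poly_order)
    do_bp = cfg.apply_bandpass if cfg.apply_bandpass is not None else not synthetic
    if do_bp:
        ts = _preprocess.bandpass(ts, _preprocess.BandpassConfig(cfg.low_hz, cfg.high_hz))
    return ts


def _json_bytes(obj) -> bytes:
    return json.dumps(obj, indent=2, sort_keys=True).encode()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    The run directory contains the cohort (synthetic mode), per-modality
    permutation tables (CSV + JSON), the selected feature list, the
    classification result, fingerprint profiles, a ``report.json`` with every
    headline number, and ``manifest.sha256`` hashing all written artifacts.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synthetic = cfg.mode == "synthetic"

    if synthetic:
        cohort_cfg = cfg.cohort if cfg.cohort is not None else CohortConfig(seed=cfg.seed)
        log.info("generating synthetic cohort (seed %d)", cohort_cfg.seed)
        cohort = generate_cohort(cohort_cfg)
        if cfg.write_intermediates:
            cohort.to_dir(out / "cohort")
    elif cfg.mode == "tables":
        log.info("loading cohort from %s", cfg.cohort_dir)
        cohort = Cohort.from_dir(cfg.cohort_dir)
    else:
        log.info("extracting cohort from images in %s", cfg.image_manifest)
        cohort = _load_image_cohort(cfg)
    tr = cohort.config.tr_seconds if cohort.config else cfg.tr_seconds

    # preprocessing + networks
    zs: list[_network.ZMatrix] = []
    for sub in cohort.subjects:
        try:
            ts = _preprocess_subject(sub, tr, cohort.roi_names, cfg.preprocess,
                                     synthetic)
            zs.append(_network.fisher_z(_network.correlation_matrix(ts)))
        except Exception as exc:
            raise RuntimeError(f"stage network failed for subject "
                               f"{sub.subject_id}: {exc}") from exc

    if cfg.sparsity is not None:
        sparsity = float(cfg.sparsity)
        log.info("using forced sparsity %.2f", sparsity)
    else:
        sparsity = _network.minimum_common_sparsity(zs, cfg.grid, cfg.ranking)
        log.info("minimum common sparsity: %.2f", sparsity)
    networks = [_network.binarize_at_sparsity(z, sparsity, cfg.ranking) for z in zs]

    cent = _centrality.subject_centrality_features(
        networks, cohort.target_roi_indices, cfg.normalization)
    vols = cohort.volumes_matrix()
    labels = cohort.labels
    region_names = cohort.target_roi_names

    # permutation tests per modality
    perm_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in np.random.SeedSequence([cfg.seed, 101]).spawn(2)]
    tables = {}
    for modality, feats, pseed in (("volume", vols, perm_seeds[0]),
                                   ("centrality", cent, perm_seeds[1])):
        pcfg = _stats.PermutationConfig(n_permutations=cfg.n_permutations,
                                        alpha=cfg.alpha, correction=cfg.correction,
                                        seed=pseed)
        tables[modality] = _stats.permutation_test(feats, labels, pcfg,
                                                   region_names, modality)
        log.info("%s permutation test done (B=%d)", modality, cfg.n_permutations)

    selection = _stats.select_features(tables, cfg.alpha)
    col_of = {("volume", r): j for j, r in enumerate(region_names)}
    col_of.update({("centrality", r): j + len(region_names)
                   for j, r in enumerate(region_names)})
    all_features = np.hstack([vols, cent])
    feature_names = ([f"volume:{r}" for r in region_names]
                     + [f"centrality:{r}" for r in region_names])

    clf_result = None
    if selection.selected:
        cols = [col_of[key] for key in selection.selected]
        ccfg = _classify.ClassifierConfig(
            n_trees=cfg.n_trees, seed=int(
                np.random.SeedSequence([cfg.seed, 202]).generate_state(1)[0] % (2 ** 31)),
            nested_selection=cfg.nested_selection)
        selector = None
        if cfg.nested_selection:
            def selector(x_tr, y_tr, _names=feature_names):
                sub_tables = {}
                for modality, offset in (("volume", 0), ("centrality", len(region_names))):
                    sub = x_tr[:, offset:offset + len(region_names)]
                    pcfg = _stats.PermutationConfig(
                        n_permutations=max(500, cfg.n_permutations // 5),
                        alpha=cfg.alpha, correction=cfg.correction, seed=perm_seeds[0])
                    sub_tables[modality] = _stats.permutation_test(
                        sub, y_tr, pcfg, region_names, modality)
                sel = _stats.select_features(sub_tables, cfg.alpha)
                return [col_of[key] for key in sel.selected]
            clf_features = all_features
        else:
            clf_features = all_features[:, cols]
        clf_result = _classify.loocv_rf(clf_features, labels, ccfg,
                                        cohort.subject_ids, selector)
        log.info("LOOCV accuracy: %.2f%%", clf_result.accuracy_percent)
    else:
        log.warning("empty feature selection; classification skipped")

    fingerprints = {
        "volume": _fingerprint.fingerprint_summary(vols, labels, region_names),
        "centrality": _fingerprint.fingerprint_summary(cent, labels, region_names),
    }

    # ---- persist artifacts ----
    written: list[Path] = []

    def _write(rel: str, data: bytes) -> None:
        p = out / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_bytes(data)
        written.append(p)

    if cfg.write_intermediates:
        for modality, feats in (("volume", vols), ("centrality", cent)):
            df = pd.DataFrame(feats, index=cohort.subject_ids, columns=region_names)
            _write(f"features_{modality}.csv",
                   df.rename_axis("subject_id").to_csv().encode())
        for modality, table in tables.items():
            _write(f"permutation_{modality}.csv", table.to_dataframe().to_csv().encode())
            _write(f"permutation_{modality}.json", _json_bytes(table.to_dict()))

    report = {
        "package_version": _pkg_version("connfp"),
        "seed": cfg.seed,
        "mode": cfg.mode,
        "n_subjects": len(cohort.subjects),
        "groups": {g: int((labels == g).sum()) for g in sorted(set(labels))},
        "chosen_sparsity": sparsity,
        "sparsity_forced": cfg.sparsity is not None,
        "ranking": cfg.ranking,
        "normalization": cfg.normalization,
        "n_permutations": cfg.n_permutations,
        "correction": cfg.correction,
        "alpha": cfg.alpha,
        "permutation_tables": {m: t.to_dict() for m, t in tables.items()},
        "selected_features": [list(t) for t in selection.selected],
        "classification": clf_result.to_dict() if clf_result else None,
        "baseline_accuracy_percent": _classify.baseline_accuracy(3),
        "fingerprints": {m: {g: p.to_dict() for g, p in profs.items()}
                         for m, profs in fingerprints.items()},
        "cohort_config": (cohort.config.to_dict() if cohort.config else None),
    }
    _write("report.json", _json_bytes(report))

    manifest_lines = []
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.sha256":
            digest = hashlib.sha256(p.read_bytes()).hexdigest()
            manifest_lines.append(f"{digest}  {p.relative_to(out)}")
    (out / "manifest.sha256").write_text("\n".join(manifest_lines) + "\n")
    return out
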