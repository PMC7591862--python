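"""End-to-end study orchestration: simulate -> connectome -> anomaly ->
attribution -> symmetry -> trajectory/recurrence -> report.

Every stage writes deterministic TSV/NIfTI outputs derived only from the
configuration and its seed, so re-running a config reproduces every table
byte-identically.  Stages abort with the stage name and offending subject
on failure.
"""

from __future__ import annotations

import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .anomaly import cohort_anomaly, smooth_tumour_mask
from .attribution import attribute_patient, attribution_summary
from .config import LongitudinalConfig, StudyConfig, load_config
from .connectome import compute_connectome, mean_reference
from .grid import VoxelMask
from .images import SegmentationVolume
from .phantom import Phantom, build_phantom, network_tumour, spatial_tumour
from .recurrence import (
    align_trajectories,
    fit_quadratic_trend,
    new_tumour_voxels,
    recurrence_test,
    tumour_vicinity,
    volume_filter,
)
from .simulate import (
    LesionSpec,
    LongitudinalSchedule,
    SessionSpec,
    segmentation_from_mask,
    simulate_control,
    simulate_longitudinal,
    simulate_patient,
)
from .symmetry import lesion_anomaly_overlap, lesion_map, network_median_anomaly

log = logging.getLogger("canomap")

STAGES = (
    "simulate",
    "connectome",
    "anomaly",
    "attribute",
    "symmetry",
    "trajectory",
    "recurrence",
    "report",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, subject: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject!r}: {cause}")
        self.stage, self.subject = stage, subject


class Study:
    """Lazily computed study state shared by the CLI subcommands."""

    def __init__(self, config: StudyConfig, output_dir: str | Path | None = None):
        self.config = config
        self.out = Path(output_dir if output_dir is not None else config.output_dir)
        self._cache: dict = {}
        ss = np.random.SeedSequence(config.seed)
        # fixed seed channels so adding patients never reshuffles controls
        self._seeds = ss.generate_state(4096) % (2**31)

    def _seed(self, channel: int) -> int:
        return int(self._seeds[channel])

    # -- simulate ---------------------------------------------------------
    @property
    def phantom(self) -> Phantom:
        if "phantom" not in self._cache:
            self._cache["phantom"] = build_phantom(self.config.phantom)
        return self._cache["phantom"]

    @property
    def controls(self):
        if "controls" not in self._cache:
            self._cache["controls"] = [
                simulate_control(
                    self.phantom, self.config.signal, self._seed(i),
                    subject_id=f"control{i:02d}",
                )
                for i in range(self.config.n_controls)
            ]
        return self._cache["controls"]

    def _tumour_mask(self, pat) -> VoxelMask:
        if pat.mode == "functional":
            return network_tumour(
                self.phantom, pat.network, pat.n_blocks,
                seed=self._seed(1000 + zlib.crc32(pat.id.encode()) % 1000),
            )
        if pat.centre is None:
            raise StageError("simulate", pat.id, ValueError("spatial mode needs centre"))
        return spatial_tumour(self.phantom, pat.centre, pat.radius_mm)

    @property
    def patients(self):
        """{id: (TimeSeriesImage, SegmentationVolume, PatientConfig)}"""
        if "patients" not in self._cache:
            out = {}
            for i, pat in enumerate(self.config.patients):
                try:
                    tum = self._tumour_mask(pat)
                    lesion = LesionSpec(tum, pat.mode, pat.gamma, pat.tau_mm)
                    ts, seg = simulate_patient(
                        self.phantom, self.config.signal, lesion,
                        self._seed(2000 + i), subject_id=pat.id,
                    )
                    out[pat.id] = (ts, seg, pat)
                except StageError:
                    raise
                except Exception as exc:
                    raise StageError("simulate", pat.id, exc) from exc
            self._cache["patients"] = out
        return self._cache["patients"]

    # -- connectome -------------------------------------------------------
    @property
    def reference(self):
        if "reference" not in self._cache:
            try:
                conns = [compute_connectome(c) for c in self.controls]
                self._cache["reference"] = mean_reference(conns)
            except Exception as exc:
                raise StageError("connectome", "controls", exc) from exc
        return self._cache["reference"]

    # -- anomaly ----------------------------------------------------------
    def exclusion_for(self, seg: SegmentationVolume) -> VoxelMask:
        a = self.config.analysis
        return smooth_tumour_mask(seg, a.fwhm_mm, a.smooth_rel_threshold).intersect(
            self.phantom.mask
        )

    @property
    def anomaly_maps(self):
        if "anomaly" not in self._cache:
            a = self.config.analysis
            maps = {}
            for pid, (ts, seg, pat) in self.patients.items():
                try:
                    excl = self.exclusion_for(seg)
                    ms, _ = cohort_anomaly(
                        self.controls, [ts], exclude=excl,
                        mad_consistency=a.mad_consistency,
                        use_fisher_z=a.use_fisher_z,
                    )
                    ms[0].subject_id = pid
                    maps[pid] = ms[0]
                except Exception as exc:
                    raise StageError("anomaly", pid, exc) from exc
            self._cache["anomaly"] = maps
        return self._cache["anomaly"]

    # -- longitudinal -----------------------------------------------------
    def _longitudinal_schedule(self) -> tuple[LongitudinalSchedule, VoxelMask]:
        lc: LongitudinalConfig = self.config.longitudinal
        ph = self.phantom
        half = ph.spec.shape[0] // 4
        centre = (half, ph.spec.shape[1] // 2, (ph.spec.shape[2] + 3) // 2)
        prim = spatial_tumour(ph, centre, radius_mm=4.0)
        rec_centre = (centre[0], min(centre[1] + 3, ph.spec.shape[1] - 1), centre[2])
        rec = spatial_tumour(ph, rec_centre, radius_mm=5.5).difference(prim)
        seg_pre = segmentation_from_mask(ph.grid, prim, code=2)
        cavity = np.zeros(ph.grid.shape, np.int16)
        cavity[prim.volume] = 5
        seg_post = SegmentationVolume(ph.grid, cavity)
        with_rec = cavity.copy()
        with_rec[rec.volume] = 2
        seg_rec = SegmentationVolume(ph.grid, with_rec)

        def lesion(g):
            return LesionSpec(prim, lc.mode, g, lc.tau_mm)

        sessions = (
            SessionSpec("pre", seg_pre, lesion(lc.pre_gamma)),
            SessionSpec("post", seg_post, lesion(lc.post_gamma)),
            SessionSpec("followup-1", seg_post, lesion(lc.followup_gamma)),
            SessionSpec(
                "followup-2", seg_post, lesion(lc.followup_gamma),
                recurrence_site=rec, recurrence_gamma=lc.recurrence_gamma,
                recurrence_silent=True,
            ),
            SessionSpec(
                "followup-3", seg_rec, lesion(lc.followup_gamma),
                recurrence_site=rec, recurrence_gamma=lc.recurrence_gamma,
                recurrence_silent=False,
            ),
        )
        return LongitudinalSchedule(sessions), rec

    @property
    def longitudinal_sessions(self):
        if "longitudinal" not in self._cache:
            lc = self.config.longitudinal
            if not lc.enabled:
                self._cache["longitudinal"] = None
            else:
                schedule, _ = self._longitudinal_schedule()
                self._cache["longitudinal"] = simulate_longitudinal(
                    self.phantom, self.config.signal, schedule,
                    self._seed(3000), subject_id=lc.patient_id,
                )
        return self._cache["longitudinal"]

    @property
    def longitudinal_anomaly(self):
        if "long_anomaly" not in self._cache:
            sessions = self.longitudinal_sessions
            if sessions is None:
                self._cache["long_anomaly"] = None
            else:
                a = self.config.analysis
                maps = []
                for ts, seg in sessions:
                    excl = self.exclusion_for(seg)
                    ms, _ = cohort_anomaly(
                        self.controls, [ts], exclude=excl,
                        mad_consistency=a.mad_consistency,
                        use_fisher_z=a.use_fisher_z,
                    )
                    ms[0].session_label = ts.session_label
                    ms[0].session_index = ts.session_index
                    ms[0].subject_id = ts.subject_id
                    maps.append(ms[0])
                self._cache["long_anomaly"] = maps
        return self._cache["long_anomaly"]


def run_pipeline(
    config, output_dir: str | Path | None = None, stages=STAGES
) -> dict[str, Path]:
    """Run the requested stages and return the paths written per stage."""
    if not isinstance(config, StudyConfig):
        config = load_config(config)
    study = Study(config, output_dir)
    out = study.out
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    a = config.analysis
    ph = study.phantom

    if "simulate" in stages:
        d = out / "simulated"
        d.mkdir(exist_ok=True)
        io.write_mask(ph.mask, d / "mask.nii.gz")
        io.write_parcellation(ph.parcellation, d / "parcellation.nii.gz", d / "labels.tsv")
        rows = []
        for c in study.controls:
            io.write_timeseries(c, d / f"{c.subject_id}_bold.nii.gz")
            rows.append({"subject": c.subject_id, "role": "control", "session": 0})
        for pid, (ts, seg, pat) in study.patients.items():
            io.write_timeseries(ts, d / f"{pid}_bold.nii.gz")
            io.write_segmentation(seg, d / f"{pid}_seg.nii.gz")
            rows.append({"subject": pid, "role": "patient", "session": 0})
        if study.longitudinal_sessions is not None:
            for ts, seg in study.longitudinal_sessions:
                tag = f"{ts.subject_id}_ses-{ts.session_index}"
                io.write_timeseries(ts, d / f"{tag}_bold.nii.gz")
                io.write_segmentation(seg, d / f"{tag}_seg.nii.gz")
                rows.append(
                    {"subject": ts.subject_id, "role": "longitudinal",
                     "session": ts.session_index}
                )
        io.write_table(pd.DataFrame(rows), d / "manifest.tsv")
        written["simulate"] = d

    if "connectome" in stages:
        d = out / "connectome"
        d.mkdir(exist_ok=True)
        io.save_connectome_array(
            study.reference.values, ph.mask, d / "reference",
            n_controls=study.reference.n_controls,
        )
        written["connectome"] = d

    if {"anomaly", "attribute", "symmetry"} & set(stages) and study.patients:
        maps = study.anomaly_maps

    if "anomaly" in stages and study.patients:
        d = out / "anomaly"
        d.mkdir(exist_ok=True)
        rows = []
        for pid, amap in maps.items():
            io.write_scalar_map(amap.scores, amap.mask, d / f"{pid}_anomaly.nii.gz")
            valid = amap.scores[amap.valid]
            rows.append(
                {
                    "patient": pid,
                    "n_valid": int(valid.size),
                    "median_score": float(np.median(valid)),
                    "frac_below_thr": float(np.mean(valid < a.anomaly_threshold)),
                }
            )
        io.write_table(pd.DataFrame(rows), d / "anomaly_summary.tsv")
        written["anomaly"] = d

    if "attribute" in stages and study.patients:
        d = out / "attribution"
        d.mkdir(exist_ok=True)
        tables = []
        for pid, amap in maps.items():
            try:
                _, seg, pat = study.patients[pid]
                tum = seg.enhancing_necrotic_mask().intersect(ph.mask)
                tables.append(
                    attribute_patient(
                        amap, study.reference, tum, ph.grid, ph.network,
                        anomaly_threshold=a.anomaly_threshold,
                        restrict_to_anomalous=a.restrict_attribution_to_anomalous,
                        subject_id=pid,
                    )
                )
            except Exception as exc:
                raise StageError("attribute", pid, exc) from exc
        if tables:
            io.write_table(pd.concat(tables, ignore_index=True), d / "attribution_voxels.tsv")
            io.write_table(attribution_summary(tables), d / "attribution_summary.tsv")
        written["attribute"] = d

    if "symmetry" in stages and study.patients:
        d = out / "symmetry"
        d.mkdir(exist_ok=True)
        net_tables, lmaps, amaps = [], [], []
        for pid, amap in maps.items():
            _, seg, pat = study.patients[pid]
            net_tables.append(
                network_median_anomaly(amap, ph.parcellation, pat.tumour_hemisphere)
            )
            tum = seg.enhancing_necrotic_mask().intersect(ph.mask)
            if not tum.empty():
                lmaps.append(
                    lesion_map(tum, study.reference, np.arctanh(a.connectivity_threshold_r))
                )
                amaps.append(amap)
        table = pd.concat(net_tables, ignore_index=True)
        io.write_table(table, d / "network_medians.tsv")
        if len(table["patient"].unique()) >= 3:
            from .symmetry import symmetry_correlation

            for comp in ("cerebrum", "cerebellum"):
                r, r2 = symmetry_correlation(table, comp)
                io.write_table(
                    pd.DataFrame(r2, columns=list(range(7))), d / f"r2_{comp}.tsv"
                )
        if len(lmaps) >= 2:
            io.write_table(
                lesion_anomaly_overlap(lmaps, amaps, ph.parcellation, a.anomaly_thresholds),
                d / "overlap_curves.tsv",
            )
        written["symmetry"] = d

    if "trajectory" in stages and study.longitudinal_anomaly is not None:
        d = out / "trajectory"
        d.mkdir(exist_ok=True)
        lc = config.longitudinal
        tabs = [
            network_median_anomaly(m, ph.parcellation, "L")
            for m in study.longitudinal_anomaly[:3]
        ]
        for i, t in enumerate(tabs):
            t["session"] = i
        aligned = align_trajectories(tabs)
        io.write_table(aligned, d / "trajectories.tsv")
        fits = []
        for (net, side, comp), g in aligned.groupby(["network", "side", "compartment"]):
            try:
                fit = fit_quadratic_trend(g["session"], g["delta_anomaly"])
                fits.append(
                    {"network": net, "side": side, "compartment": comp,
                     "a": fit.intercept, "b": fit.linear, "c": fit.quadratic,
                     "r_squared": fit.r_squared, "rmse": fit.rmse}
                )
            except ValueError:
                continue
        io.write_table(pd.DataFrame(fits), d / "quadratic_fits.tsv")
        written["trajectory"] = d

    if "recurrence" in stages and study.longitudinal_anomaly is not None:
        d = out / "recurrence"
        d.mkdir(exist_ok=True)
        sessions = study.longitudinal_sessions
        amaps_l = study.longitudinal_anomaly
        rows = []
        for t0 in range(len(sessions) - 1):
            seg0, seg1 = sessions[t0][1], sessions[t0 + 1][1]
            fut = new_tumour_voxels(seg0, seg1).intersect(ph.mask)
            if fut.empty():
                continue
            passes = volume_filter(fut, ph.grid, a.min_new_cm3)
            vic = tumour_vicinity(seg0, ph.mask, a.vicinity_mm)
            rc = recurrence_test(
                amaps_l[t0], fut, vic, n_perm=a.n_perm,
                seed=Study(config)._seed(3500 + t0), session_pair=(t0, t0 + 1),
            )
            row = rc.as_row()
            row["volume_mm3"] = fut.n_voxels * ph.grid.voxel_volume_mm3()
            row["passes_volume_filter"] = int(passes)
            rows.append(row)
            io.write_mask(fut, d / f"future_t{t0}-t{t0+1}.nii.gz")
            io.write_mask(vic, d / f"vicinity_t{t0}.nii.gz")
        io.write_table(pd.DataFrame(rows), d / "recurrence_tests.tsv")
        written["recurrence"] = d

    if "report" in stages:
        rows = [
            {"item": "phantom_voxels", "value": ph.n_voxels},
            {"item": "n_controls", "value": config.n_controls},
            {"item": "n_patients", "value": len(config.patients)},
            {"item": "seed", "value": config.seed},
        ]
        io.write_table(pd.DataFrame(rows), out / "report.tsv")
        written["report"] = out / "report.tsv"

    return written
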