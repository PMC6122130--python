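"""End-to-end experiment orchestration.

One configuration drives the full chain: simulate phantom "subjects"
(independent noise realizations of one geometry) -> median-b0 normalization
-> tensor fit and scalar maps -> study-averaged response and CSD -> tracking
with the four algorithms -> track-density images thresholded at the density
cutoffs -> Overlap Fraction against the probabilistic-CSD reference ->
tract-based ROI statistics -> radial-ratio intra-axonal fraction sweep over
the FA cutoffs -> FA-vs-AFD linear/cubic model selection.  All randomness
derives from one master seed through named per-stage substreams; outputs are
CSV tables plus a JSON manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import afd as afd_mod
from . import csd as csd_mod
from . import density_overlap as dov
from . import dti as dti_mod
from . import dwio, phantom, stats, tracking

log = logging.getLogger("lowbafd")

DENSITY_CUTOFFS = (0.0, 1.0, 5.0, 10.0)
FA_CUTOFFS = (0.7, 0.75, 0.8, 0.85)
REFERENCE_ALGORITHM = "prob_csd"


@dataclass
class ExperimentConfig:
    # phantom geometry: two straight bundles crossing at 90 degrees
    grid: int = 40
    bundle_radius_vox: float = 2.5
    f_ic: float = 0.7
    # acquisition
    n_directions: int = 30
    b_value: float = 1000.0
    snr: float = 30.0
    # cohort: independent noise realizations of the one geometry
    n_subjects: int = 13
    # tracking
    seeds_per_voxel_prob: int = 100
    det_step_mm: float = 0.5
    csd_step_mm: float = 0.2
    angle_max_deg: float = 60.0
    fa_min: float = 0.2
    fodf_amp_min: float = 0.15
    min_length_mm: float = 10.0
    # analysis
    density_cutoffs: tuple = DENSITY_CUTOFFS
    fa_cutoffs: tuple = FA_CUTOFFS
    alpha: float = 0.05
    tensor_method: str = "constrained"
    master_seed: int = 42

    @classmethod
    def small(cls, n_subjects: int = 2, master_seed: int = 42) -> "ExperimentConfig":
        """Desk-scale configuration: small grid, sparse probabilistic seeding."""
        return cls(grid=20, n_subjects=n_subjects, seeds_per_voxel_prob=6,
                   master_seed=master_seed)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("density_cutoffs", "fa_cutoffs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def substream_seed(master_seed: int, stage: str, subject: int = 0) -> int:
    """Deterministic per-stage, per-subject seed below 2^31."""
    stage_id = int.from_bytes(stage.encode()[:8].ljust(8, b"\0"), "little")
    ss = np.random.SeedSequence([int(master_seed), stage_id % (2**31), int(subject)])
    return int(ss.generate_state(1)[0] % (2**31))


def _seed_voxels(truth: phantom.PhantomGroundTruth) -> np.ndarray:
    """Seed ROI: a transverse slab at the low-z end of bundle 1."""
    vox = np.argwhere(truth.bundle_labels == 1)
    z0 = vox[:, 2].min()
    return vox[vox[:, 2] <= z0 + 1]


def run_experiment(config: ExperimentConfig, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    scheme = phantom.make_half_sphere_scheme(
        config.n_directions, config.b_value, seed=substream_seed(config.master_seed, "scheme")
    )
    geom = phantom.crossing_config(
        grid=config.grid, radius_vox=config.bundle_radius_vox, f_ic=config.f_ic
    )

    of_rows, tbra_rows, afd_rows, fit_rows = [], [], [], []
    responses = []
    subjects = []
    for subj in range(config.n_subjects):
        t0 = time.time()
        ds, truth = phantom.build_phantom(
            geom, scheme, snr=config.snr, seed=substream_seed(config.master_seed, "noise", subj)
        )
        ds = dwio.normalize_by_median_b0(ds)
        tensor_field, maps = dti_mod.compute_scalar_maps(ds, method=config.tensor_method)
        resp = csd_mod.estimate_response(ds, tensor_field, maps, fa_select=min(config.fa_cutoffs))
        responses.append(resp)
        subjects.append((ds, truth, tensor_field, maps))
        log.info("subject %d: simulated + fitted in %.1fs", subj, time.time() - t0)

    study_response = csd_mod.average_responses(responses)

    for subj, (ds, truth, tensor_field, maps) in enumerate(subjects):
        t0 = time.time()
        fodf = csd_mod.fit_csd_field(ds, study_response)
        seeds = _seed_voxels(truth)
        tdis: dict[str, dov.TDIMap] = {}
        tractograms: dict[str, dwio.Tractogram] = {}
        for algo in tracking.ALGORITHMS:
            is_prob = algo.startswith("prob")
            cfg = tracking.TrackingConfig(
                algorithm=algo,
                step_mm=config.csd_step_mm if algo.endswith("csd") else config.det_step_mm,
                angle_max_deg=config.angle_max_deg,
                fa_min=config.fa_min,
                fodf_amp_min=config.fodf_amp_min,
                seeds_per_voxel=config.seeds_per_voxel_prob if is_prob else 1,
                min_length_mm=config.min_length_mm,
                seed=substream_seed(config.master_seed, f"track_{algo}", subj),
            )
            field_in = fodf if algo.endswith("csd") else tensor_field
            tg = tracking.track(field_in, maps, seeds, None, cfg, ds.affine)
            tractograms[algo] = tg
            tdis[algo] = dov.compute_tdi(tg, ds.spatial_shape, ds.affine, ds.voxel_size, algo)

        # Overlap Fraction: p-CSD as the reference reconstruction
        for cutoff in config.density_cutoffs:
            ref_mask = dov.threshold_tdi(tdis[REFERENCE_ALGORITHM], cutoff)
            for algo in tracking.ALGORITHMS:
                if algo == REFERENCE_ALGORITHM:
                    continue
                tgt_mask = dov.threshold_tdi(tdis[algo], cutoff)
                if not ref_mask.any():
                    continue
                res = dov.overlap_fraction(tgt_mask, ref_mask, cutoff, algo, REFERENCE_ALGORITHM)
                of_rows.append(
                    {"subject": subj, "method": algo, "cutoff_percent": cutoff,
                     "of_percent": res.of_percent, "n_target": res.n_target,
                     "n_reference": res.n_reference, "n_intersection": res.n_intersection}
                )
            # tract-based ROI statistics per method and cutoff
            for algo in tracking.ALGORITHMS:
                mask = dov.threshold_tdi(tdis[algo], cutoff)
                if not mask.any():
                    continue
                row = dov.tract_roi_stats(maps, mask)
                row.update({"subject": subj, "method": algo, "cutoff_percent": cutoff})
                tbra_rows.append(row)

        # intra-axonal volume fraction sweep
        for est in afd_mod.intra_axonal_fraction_sweep(
            ds, fodf, maps.FA, config.fa_cutoffs, brain_mask=truth.brain_mask
        ):
            afd_rows.append(
                {"subject": subj, "fa_cutoff": est.fa_cutoff, "mean_fraction": est.mean_fraction,
                 "sd_fraction": est.sd_fraction, "n_voxels": est.n_voxels,
                 "voxel_percent_of_brain": est.voxel_percent_of_brain}
            )

        # FA vs AFD model selection on the reference tractogram
        tg_ref = tractograms[REFERENCE_ALGORITHM]
        if len(tg_ref):
            vals, _dirs, _fl = afd_mod.afd_along_tract(fodf, tg_ref, ds.affine, ds.voxel_size)
            vox = [v for v, a in vals.items() if a > 0 and maps.valid[v]]
            fa = np.array([maps.FA[v] for v in vox])
            afd_vals = np.array([vals[v] for v in vox])
            if len(vox) > 10 and np.ptp(fa) > 0:
                small, big, cmp = stats.compare_linear_cubic(fa, afd_vals, alpha=config.alpha)
                fit_rows.append(
                    {"subject": subj, "tract": "bundle1", "n_voxels": len(vox),
                     "F": cmp.F, "p_value": cmp.p_value, "preferred": cmp.preferred,
                     "ss_linear": small.ss, "ss_cubic": big.ss}
                )
        log.info("subject %d: analysis in %.1fs", subj, time.time() - t0)

    of_table = pd.DataFrame(of_rows)
    tbra_table = pd.DataFrame(tbra_rows)
    afd_table = pd.DataFrame(afd_rows)
    fit_table = pd.DataFrame(fit_rows)

    of_summary = (
        of_table.groupby(["method", "cutoff_percent"])["of_percent"]
        .agg(["mean", "std"]).reset_index()
        if len(of_table) else pd.DataFrame()
    )
    afd_summary = (
        afd_table.groupby("fa_cutoff")[["mean_fraction", "sd_fraction", "voxel_percent_of_brain"]]
        .mean().reset_index()
        if len(afd_table) else pd.DataFrame()
    )

    # repeated-measures tests across subjects (need n > k - 1)
    stats_rows = []
    for factor, levels in (("cutoff_percent", config.density_cutoffs), ("method", tracking.ALGORITHMS)):
        if len(tbra_rows) == 0:
            break
        k = len(levels)
        if config.n_subjects <= k - 1:
            continue
        for scalar in ("FA", "MD"):
            other = "method" if factor == "cutoff_percent" else "cutoff_percent"
            # average over the other factor to isolate one within-subject factor
            wide = tbra_table.pivot_table(index="subject", columns=factor, values=scalar)
            if wide.shape != (config.n_subjects, k) or wide.isna().any().any():
                continue
            res = stats.wilks_lambda_repeated(wide.to_numpy())
            stats_rows.append(
                {"factor": factor, "scalar": scalar, "wilks_lambda": res.wilks_lambda,
                 "F": res.F, "hypothesis_df": res.hypothesis_df, "error_df": res.error_df,
                 "p_value": res.p_value}
            )
    stats_table = pd.DataFrame(stats_rows)

    tables = {
        "of_table": of_table, "of_summary": of_summary, "tbra_table": tbra_table,
        "afd_table": afd_table, "afd_summary": afd_summary,
        "fit_comparison": fit_table, "rm_tests": stats_table,
    }
    for name, tbl in tables.items():
        tbl.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
    manifest = {
        "config": asdict(config),
        "stage_seeds": {
            "scheme": substream_seed(config.master_seed, "scheme"),
            "noise": [substream_seed(config.master_seed, "noise", s) for s in range(config.n_subjects)],
        },
        "runtime_s": round(time.time() - t_start, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return tables
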