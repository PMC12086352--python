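"""End-to-end reproducible experiment driver.

Runs synthetic generation -> acquisition -> reconstruction -> spectral
fitting -> quantitative maps -> oxygen models -> VDP and regional
statistics for a cohort of animals at two inspired-oxygen levels, and
writes every product (tables, maps, models, log) plus a content-hash
manifest under one experiment directory.  Identical config and seed give
a byte-identical manifest.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as xio
from .config import ExperimentConfig, HeterogeneityConfig
from .fitting import PriorKnowledge, fit_volume
from .maps import make_maps, summarize
from .oxygen import fit_log_model, fit_mlr, fit_slr, predict_pao2, save_model
from .recon import reconstruct
from .regional import (LobeAtlas, paired_t, regional_summaries, two_way_anova,
                       vdp_from_volumes)
from .sampling import (build_spherical_pattern, dummy_scan_residual,
                       scan_duration_s, spectral_axis)
from .synthetic import (generate_phantom, kspace_noise_for_snr,
                        simulate_acquisition, simulate_blood_gas,
                        simulate_ventilation)

__all__ = ["run_pipeline"]

log = logging.getLogger("xemrsi.pipeline")

# cohort VDP means +- SD at each oxygen level, used by the ventilation stage
VDP_DEFAULTS = {0.40: (0.0690, 0.0390), 1.00: (0.0502, 0.0434)}


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: ExperimentConfig, out_dir=None) -> dict:
    """Execute all stages; returns a result bundle of key tables/paths."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO if config.verbosity else logging.WARNING)
    # snapshot with a normalized output path so identical experiments give
    # identical manifests regardless of where they are written
    snapshot = ExperimentConfig.from_dict(config.to_dict())
    snapshot.out_dir = "."
    snapshot.save(out / "config.yaml")

    acq = config.acq
    rng = np.random.default_rng(config.seed)
    het = (HeterogeneityConfig.default() if config.heterogeneity == "default"
           else HeterogeneityConfig.none())
    stage_t0 = time.time()
    result: dict = {}

    def done(stage):
        nonlocal stage_t0
        log.info("stage %-12s %6.1f s", stage, time.time() - stage_t0)
        stage_t0 = time.time()

    try:
        # -- protocol arithmetic ------------------------------------------
        pattern = build_spherical_pattern(acq.matrix)
        ppm = spectral_axis(acq)
        protocol = {
            "n_excitations": len(pattern),
            "scan_time_s": scan_duration_s(pattern, acq, round_to_s=False),
            "scan_time_rounded_s": scan_duration_s(pattern, acq),
            "hz_per_bin": acq.bandwidth_hz / acq.n_spectral_zf,
            "ppm_per_bin": float(ppm[1] - ppm[0]),
            "dummy_residual": dummy_scan_residual(acq.n_dummy, acq.dummy_flip_deg),
            "voxel_mm": list(acq.voxel_mm),
        }
        (out / "protocol.json").write_text(json.dumps(protocol, indent=2))
        result["protocol"] = protocol
        done("protocol")

        # -- blood gas -----------------------------------------------------
        records = simulate_blood_gas(
            config.n_animals, config.fio2_levels,
            seed=np.random.default_rng(rng.integers(2**31)),
        )
        xio.save_blood_gas(records, out / "bloodgas.csv")
        bg = xio.blood_gas_to_frame(records)
        result["blood_gas"] = bg
        done("bloodgas")

        # -- image cohort: simulate, recon, fit, maps ---------------------
        summaries, regionals, vdp_rows = [], [], []
        atlas = None
        example_maps = {}
        for level in config.fio2_levels:
            prior = PriorKnowledge.default(level)
            for i in range(config.n_animals):
                animal = f"pig{i + 1}"
                pao2 = float(
                    bg.loc[(bg.animal == animal) & (bg.fio2 == level), "pao2_mmHg"].iloc[0]
                )
                phantom = generate_phantom(
                    acq.matrix, level, het,
                    seed=np.random.default_rng(rng.integers(2**31)),
                    pao2=pao2, animal=animal,
                )
                if atlas is None:
                    atlas = LobeAtlas(phantom.lobe_labels, phantom.label_map)
                if config.noise_sd is not None:
                    noise_sd = config.noise_sd
                elif config.noise_rbc_snr:
                    noise_sd = kspace_noise_for_snr(
                        phantom, acq, pattern, config.noise_rbc_snr, "rbc"
                    )
                else:
                    noise_sd = 0.0
                ksp = simulate_acquisition(
                    phantom, acq, pattern, noise_sd,
                    seed=np.random.default_rng(rng.integers(2**31)),
                )
                img = reconstruct(ksp)
                fits = fit_volume(img, prior, acq)
                qmaps = make_maps(fits, acq,
                                  t2star_ms={"gas": phantom.gas_t2star_ms})
                ident = {"animal": animal, "fio2": level}
                summaries.append(summarize(qmaps, extra=ident))
                lab = atlas.labels
                if qmaps.mask.shape != lab.shape:
                    reps = tuple(qs // ls for qs, ls in zip(qmaps.mask.shape, lab.shape))
                    lab = np.kron(lab, np.ones(reps, dtype=lab.dtype))
                regionals.append(
                    regional_summaries(qmaps, LobeAtlas(lab, atlas.label_map),
                                       extra=ident)
                )
                if i == 0:
                    example_maps[level] = qmaps
                mu, sd = VDP_DEFAULTS.get(round(level, 2), (0.06, 0.03))
                frac = float(np.clip(rng.normal(mu, sd), 0.0, 0.5))
                vent, tcv = simulate_ventilation(
                    defect_frac=frac,
                    seed=np.random.default_rng(rng.integers(2**31)),
                )
                vdp_rows.append({**ident, "vdp_percent": vdp_from_volumes(vent, tcv)})
        summary = pd.concat(summaries, ignore_index=True)
        regional = pd.concat(regionals, ignore_index=True)
        vdp = pd.DataFrame(vdp_rows)
        summary.to_csv(out / "summary.csv", index=False)
        regional.to_csv(out / "regional.csv", index=False)
        vdp.to_csv(out / "vdp.csv", index=False)
        result.update(summary=summary, regional=regional, vdp=vdp)
        done("cohort")

        # -- oxygen models -------------------------------------------------
        wide = summary.pivot_table(index=["animal", "fio2"], columns="metric",
                                   values="mean").reset_index()
        cal = wide.merge(bg[["animal", "fio2", "pao2_mmHg"]], on=["animal", "fio2"])
        slr_cs = fit_slr(cal.pao2_mmHg, cal.cs_rbc, "rbc_cs_ppm")
        slr_lw = fit_slr(cal.pao2_mmHg, cal.lw_rbc, "rbc_lw_hz")
        try:
            mlr = fit_mlr(cal.cs_rbc, cal.lw_rbc, cal.pao2_mmHg)
        except (np.linalg.LinAlgError, ValueError) as e:
            # noiseless calibrations make cs and lw exactly collinear
            log.warning("MLR calibration degenerate, skipped: %s", e)
            mlr = None
        logm = fit_log_model(cal.pao2_mmHg, cal.cs_rbc)
        for name, model in (("slr_cs", slr_cs), ("slr_lw", slr_lw),
                            ("mlr", mlr), ("log", logm)):
            if model is not None:
                save_model(model, out / f"model_{name}.json")
        result.update(slr_cs=slr_cs, slr_lw=slr_lw, mlr=mlr, log=logm,
                      calibration=cal)
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        for level, qmaps in example_maps.items():
            for mode, model in (("slr", slr_cs), ("mlr", mlr)):
                if model is None:
                    continue
                pao2_map = predict_pao2(qmaps, model, mode)
                xio.save_volume(pao2_map, maps_dir / f"pao2_{mode}_fio2{int(level*100)}.nii.gz",
                                acq.voxel_mm)
            for metric in ("rbc_m", "cs_rbc", "lw_rbc", "cs_diff"):
                xio.save_volume(qmaps.maps[metric],
                                maps_dir / f"{metric}_fio2{int(level*100)}.nii.gz",
                                acq.voxel_mm)
        done("oxygen")

        # -- statistics ----------------------------------------------------
        stats_rows = []
        lo, hi = sorted(config.fio2_levels)[:2]
        for metric in summary.metric.unique():
            w = summary[summary.metric == metric].pivot(index="animal",
                                                        columns="fio2",
                                                        values="mean")
            t, p, dfree = paired_t(w[lo], w[hi])
            stats_rows.append(dict(metric=metric, test="paired_t", t=t, p=p,
                                   df=dfree))
        anova_rows = []
        for metric in regional.metric.unique():
            sub = regional[regional.metric == metric]
            try:
                res = two_way_anova(sub)
            except ValueError as e:
                anova_rows.append(dict(metric=metric, error=str(e)))
                continue
            anova_rows.append(dict(metric=metric,
                                   p_region=res["p_region"],
                                   p_oxygen=res["p_oxygen"],
                                   p_interaction=res["p_interaction"]))
        t_vdp, p_vdp, df_vdp = paired_t(
            vdp[vdp.fio2 == lo].sort_values("animal").vdp_percent,
            vdp[vdp.fio2 == hi].sort_values("animal").vdp_percent,
        )
        stats_rows.append(dict(metric="vdp_percent", test="paired_t",
                               t=t_vdp, p=p_vdp, df=df_vdp))
        stats = pd.DataFrame(stats_rows)
        anova = pd.DataFrame(anova_rows)
        stats.to_csv(out / "paired_tests.csv", index=False)
        anova.to_csv(out / "anova.csv", index=False)
        result.update(paired_tests=stats, anova=anova)
        done("statistics")

    except Exception as e:
        (out / "FAILED.txt").write_text(f"pipeline aborted: {e}")
        raise

    # -- manifest ----------------------------------------------------------
    manifest = {
        str(p.relative_to(out)): _hash_file(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    result["manifest"] = manifest
    result["out_dir"] = out
    done("manifest")
    return result
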