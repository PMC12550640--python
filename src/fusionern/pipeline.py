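"""End-to-end orchestration and parameter-recovery studies.

``run_pipeline`` executes simulate -> score -> fit -> incremental -> report
with reproducible seeds, writing every artifact as a new file under the
output directory and finishing with a run report (config hash, seeds,
record counts, convergence summaries, file manifest with checksums).

``recovery_study`` repeats generate -> fit for one of the named studies
(anxiety LCS, neural LCS, incremental blocks, final path model) with seeds
``base_seed + replicate`` and aggregates the estimates against their
generating values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .config import MODALITIES, REGIONS, GeneratorConfig
from .cohort import (apply_missingness, generate_cohort,
                     generate_incremental_cohort, generate_path_cohort,
                     generate_roi_scores, incremental_blocks)
from .erp import CORRECT, ERROR, average_erp, baseline_correct, \
    difference_wave, find_ern_peak
from .fusion import build_roi_score_table
from .incremental import IncrementalValidityModel, build_interaction_terms
from .lcs import AnxietyLCS, NeuralLCS, estimate_change_scores
from .neuralgen import build_geometry, generate_neural_data
from .pathmodel import FinalPathModel

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "recovery_study",
           "null_gamma_calibration", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str = "fusionern_run"
    seed: int = 0
    stages: tuple = ("simulate", "score", "fit", "incremental", "report")
    baseline_window: tuple = (-100.0, 0.0)
    search_window: tuple = (0.0, 100.0)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        neural = d["generator"].pop("neural")
        d["generator"]["neural"] = {f"{m}.{r}": v
                                    for (m, r), v in neural.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = dict(d.pop("generator", {}))
        from .config import (AnxietyParams, EpochParams, FinalPathParams,
                             GeometryParams, IncrementalGenParams,
                             IndicatorParams, MissingParams,
                             NeuralCorrParams, NeuralRegionParams)
        sub = {"anxiety": AnxietyParams, "indicators": IndicatorParams,
               "neural_corr": NeuralCorrParams, "missing": MissingParams,
               "incremental": IncrementalGenParams, "path": FinalPathParams,
               "geometry": GeometryParams, "epochs": EpochParams}
        kwargs = {}
        for key, val in gen.items():
            if key == "neural":
                kwargs["neural"] = {
                    tuple(k.split(".")): NeuralRegionParams(**v)
                    for k, v in val.items()}
            elif key in sub:
                if key == "geometry":
                    val = {k: (tuple(tuple(x) for x in v)
                               if k in ("dacc_box", "pcc_box")
                               else tuple(v) if k == "grid_shape" else v)
                           for k, v in val.items()}
                if key == "epochs":
                    val = {k: tuple(v) if isinstance(v, list) else v
                           for k, v in val.items()}
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        cfg = cls(**{**d, "generator": GeneratorConfig(**kwargs)})
        cfg.stages = tuple(cfg.stages)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    stages: list
    record_counts: dict
    convergence: dict
    manifest: dict  # path -> sha256

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = config.generator.validate()
    counts, convergence = {}, {}
    stages = list(config.stages)
    if "report" not in stages:
        stages.append("report")

    for stage in stages:
        try:
            if stage == "simulate":
                _stage_simulate(out, config, gen, counts)
            elif stage == "score":
                _stage_score(out, config, gen, counts)
            elif stage == "fit":
                _stage_fit(out, counts, convergence)
            elif stage == "incremental":
                _stage_incremental(out, counts, convergence)
            elif stage == "report":
                pass
            else:
                raise PipelineError(f"unknown stage {stage!r}")
        except PipelineError:
            raise
        except FileNotFoundError as err:
            raise PipelineError(
                f"stage {stage!r}: missing input {err.filename}") from err
        except Exception as err:
            raise PipelineError(f"stage {stage!r}: {err}") from err

    manifest = {str(p.relative_to(out)): _checksum(p)
                for p in sorted(out.rglob("*")) if p.is_file()
                and p.name != "run_report.json"}
    report = RunReport(config.config_hash(), config.seed, stages, counts,
                       convergence, manifest)
    report.to_json(out / "run_report.json")
    return report


def _stage_simulate(out, config, gen, counts):
    seed = config.seed
    cohort, truth = generate_cohort(gen, seed=seed)
    fio.write_table(cohort, out / "cohort.csv")
    fio.write_table(truth, out / "truth.csv")
    geometry = build_geometry(gen.geometry)
    fio.write_mesh(geometry.mesh, out / "geometry" / "nodes.csv",
                   out / "geometry" / "elements.csv")
    fio.write_mask(geometry.mask, out / "geometry" / "roi_mask.nii")
    ndir = out / "neural"
    ndir.mkdir(parents=True, exist_ok=True)
    n_art = 0
    with fio.EpochWriter(out / "epochs.h5") as ew:
        for sid, wave, mesh, vol, epochs in generate_neural_data(
                truth, gen, seed=seed + 1, geometry=geometry):
            fio.write_table(pd.DataFrame({
                "id": np.arange(mesh.n_elements),
                "cdr_error": mesh.cdr_error,
                "cdr_correct": mesh.cdr_correct,
            }), ndir / f"{sid}_{wave}_cdr.csv")
            fio.write_volume(vol, ndir / f"{sid}_{wave}_contrast.nii")
            ew.write(sid, wave, epochs)
            n_art += 1
    counts["simulate"] = {"subjects": len(cohort),
                          "neural_artifacts": n_art}


def _stage_score(out, config, gen, counts):
    cohort = fio.read_table(out / "cohort.csv")
    geometry_mesh = fio.read_mesh(out / "geometry" / "nodes.csv",
                                  out / "geometry" / "elements.csv")
    mask = fio.read_mask(out / "geometry" / "roi_mask.nii")
    epochs_path = out / "epochs.h5"
    if not epochs_path.exists():
        raise PipelineError("stage 'score': missing input epochs.h5")

    vmap = None
    peak_rows, entries = [], []
    for sid, wave in fio.list_epoch_keys(epochs_path):
        ep = fio.read_epochs(epochs_path, sid, wave)
        ep = baseline_correct(ep, config.baseline_window)
        err = average_erp(ep, ERROR)
        corr = average_erp(ep, CORRECT)
        diff = difference_wave(err, corr)
        lat, amp = find_ern_peak(diff, gen.epochs.frontocentral,
                                 config.search_window)
        peak_rows.append({"subject": sid, "wave": wave, "latency_ms": lat,
                          "amplitude_uv": amp,
                          "n_error_trials": err.n_trials,
                          "n_correct_trials": corr.n_trials})
        cdr = fio.read_table(out / "neural" / f"{sid}_{wave}_cdr.csv")
        mesh = type(geometry_mesh)(geometry_mesh.nodes,
                                   geometry_mesh.elements,
                                   cdr_error=cdr["cdr_error"].to_numpy(),
                                   cdr_correct=cdr["cdr_correct"].to_numpy())
        vol = fio.read_volume(out / "neural" / f"{sid}_{wave}_contrast.nii")
        if vmap is None:
            from .fusion import map_voxels_to_elements
            vmap = map_voxels_to_elements(vol, mesh)
        entries.append({"subject": sid, "wave": wave, "mesh": mesh,
                        "volume": vol, "mask": mask, "vmap": vmap,
                        "ern_latency_ms": lat})
    fio.write_table(pd.DataFrame(peak_rows), out / "ern_peaks.csv")
    tidy = build_roi_score_table(entries)
    fio.write_table(tidy, out / "scores_tidy.csv")
    wide = fio.tidy_to_wide(tidy)
    cohort2, wide2 = apply_missingness(cohort, wide, gen,
                                       seed=config.seed + 2)
    fio.write_table(cohort2, out / "cohort_observed.csv")
    fio.write_table(wide2, out / "scores_wide.csv")
    counts["score"] = {"peaks": len(peak_rows), "scores": len(tidy)}


def _stage_fit(out, counts, convergence):
    cohort = fio.read_table(out / "cohort_observed.csv")
    wide = fio.read_table(out / "scores_wide.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anx = AnxietyLCS.from_dataframe(cohort).fit()
        rows = anx.params.reset_index()
        fio.write_table(rows, out / "anxiety_lcs_params.csv")
        convergence["anxiety_lcs"] = bool(anx.converged)
        change, fits = estimate_change_scores(wide)
    for (mod, reg), res in fits.items():
        convergence[f"neural_lcs_{mod}_{reg}"] = bool(res.converged)
    table = change.copy()
    fio.write_table(table, out / "change_scores.csv")
    counts["fit"] = {"neural_models": len(fits)}


def _stage_incremental(out, counts, convergence):
    cohort = fio.read_table(out / "cohort_observed.csv")
    change = fio.read_table(out / "change_scores.csv")
    frame = cohort.merge(change, on="subject_id", how="left")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        frame = build_interaction_terms(frame)
        inc = IncrementalValidityModel(frame, incremental_blocks()).fit()
        fio.write_table(inc.increments().reset_index(),
                        out / "incremental_blocks.csv")
        convergence["incremental"] = bool(inc.converged)
        sig = inc.significant_blocks()
        # carry significant neural blocks into the focused model; fall back
        # to fusion when no neural block clears the gate
        mod_by_block = {"block2": "eeg", "block3": "fmri", "block4": "fusion"}
        chosen = [mod_by_block[b] for b in sig if b in mod_by_block] \
            or ["fusion"]
        slopes_rows = []
        for modality in chosen:
            fp = FinalPathModel(frame, modality=modality).fit()
            convergence[f"path_{modality}"] = bool(fp.converged)
            fio.write_table(fp.coefficients().reset_index(),
                            out / f"path_{modality}_coefficients.csv")
            for focal in (f"{modality}_dacc_13", f"{modality}_pcc_change"):
                tab = fp.simple_slopes(focal).reset_index()
                tab.insert(0, "focal", focal)
                tab.insert(0, "modality", modality)
                slopes_rows.append(tab)
        fio.write_table(pd.concat(slopes_rows, ignore_index=True),
                        out / "simple_slopes.csv")
    counts["incremental"] = {"significant_blocks": sig,
                             "final_models": chosen}


# ---------------------------------------------------------------------------
# recovery studies
# ---------------------------------------------------------------------------

def _rep_anxiety(gen: GeneratorConfig, seed: int, compute_se: bool) -> dict:
    cohort, _ = generate_cohort(gen, seed=seed)
    res = AnxietyLCS.from_dataframe(cohort).fit(compute_se=compute_se)
    out = {"converged": res.converged,
           "mean_delta": res.get("delta~1"),
           "var_delta": res.get("delta~~delta")}
    if compute_se:
        for par, key in (("delta~1", "mean_delta"),
                         ("delta~~delta", "var_delta")):
            out[f"{key}_lo"] = res.get(par, "ci_low")
            out[f"{key}_hi"] = res.get(par, "ci_high")
    return out


def _rep_neural(gen: GeneratorConfig, seed: int, compute_se: bool,
                modality="fusion", region="dacc") -> dict:
    cohort, truth = generate_cohort(gen, seed=seed)
    scores = generate_roi_scores(truth, gen, seed=seed + 500_000)
    _, scores = apply_missingness(cohort, scores, gen, seed=seed + 900_000)
    res = NeuralLCS.from_dataframe(scores, modality, region).fit(
        compute_se=compute_se)
    return {"converged": res.converged,
            "std_change": res.get("change~1", "std_est"),
            "mean_change": res.get("change~1"),
            "var_change": res.get("change~~change")}


def _rep_incremental(gen: GeneratorConfig, seed: int,
                     compute_se: bool) -> dict:
    frame, _ = generate_incremental_cohort(gen, seed=seed)
    res = IncrementalValidityModel(frame, incremental_blocks()).fit(
        compute_se=compute_se)
    dr2 = res.delta_r2
    return {"converged": res.converged,
            **{f"block{k + 1}_delta_r2": dr2[k] for k in range(4)}}


def _rep_path(gen: GeneratorConfig, seed: int, compute_se: bool) -> dict:
    frame, _ = generate_path_cohort(gen, seed=seed)
    res = FinalPathModel(frame).fit(compute_se=compute_se)
    coefs = res.coefficients()
    out = {"converged": res.converged}
    for pred in coefs.index:
        out[pred] = coefs.loc[pred, "B"]
    out["slope_dacc13_hi_bi"] = out["fusion_dacc_13"] \
        + out["fusion_dacc_13_x_bi"]
    out["slope_dacc13_lo_bi"] = out["fusion_dacc_13"] \
        - out["fusion_dacc_13_x_bi"]
    return out


_STUDIES = {"anxiety": _rep_anxiety, "neural": _rep_neural,
            "incremental": _rep_incremental, "path": _rep_path}


def recovery_study(config: GeneratorConfig, replicates: int = 200,
                   study: str = "anxiety", base_seed: Optional[int] = None,
                   compute_se: bool = False):
    """Repeated generate -> fit; returns ``(summary, per_replicate)``.

    Replicate r uses seed ``base_seed + r`` (r = 1..replicates).
    Non-converged replicates are excluded from the summary and counted.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    fn = _STUDIES[study]
    base = config.seed if base_seed is None else base_seed
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(1, replicates + 1):
            row = fn(config, base + r, compute_se)
            row["replicate"] = r
            rows.append(row)
    reps = pd.DataFrame(rows).set_index("replicate")
    ok = reps[reps["converged"].astype(bool)]
    summary_rows = []
    generating = _generating_values(config, study)
    for col in ok.columns:
        if col == "converged" or col.endswith("_lo") or col.endswith("_hi"):
            continue
        row = {"parameter": col,
               "generating": generating.get(col, np.nan),
               "mean_estimate": float(ok[col].mean()),
               "empirical_se": float(ok[col].std()),
               "n_converged": int(len(ok)),
               "n_excluded": int(len(reps) - len(ok))}
        if f"{col}_lo" in ok.columns and col in generating:
            cover = ((ok[f"{col}_lo"] <= generating[col])
                     & (generating[col] <= ok[f"{col}_hi"]))
            row["coverage"] = float(cover.mean())
        summary_rows.append(row)
    return pd.DataFrame(summary_rows).set_index("parameter"), reps


def _generating_values(gen: GeneratorConfig, study: str) -> dict:
    if study == "anxiety":
        return {"mean_delta": gen.anxiety.mean_delta,
                "var_delta": gen.anxiety.var_delta}
    if study == "neural":
        p = gen.neural[("fusion", "dacc")]
        return {"mean_change": p.mean_change,
                "var_change": p.var_change,
                "std_change": p.mean_change / np.sqrt(p.var_change)}
    if study == "incremental":
        return {f"block{k + 1}_delta_r2": v
                for k, v in enumerate(gen.incremental.delta_r2)}
    if study == "path":
        pp = gen.path
        out = {"sex": pp.sex, "minority": pp.minority, "bi": pp.bi,
               "eta13": pp.anxiety13,
               "fusion_dacc_13": pp.dacc_13, "fusion_pcc_13": pp.pcc_13,
               "fusion_dacc_change": pp.dacc_change,
               "fusion_pcc_change": pp.pcc_change,
               "fusion_dacc_13_x_bi": pp.bi_x_dacc_13,
               "fusion_pcc_13_x_bi": pp.bi_x_pcc_13,
               "fusion_dacc_change_x_bi": pp.bi_x_dacc_change,
               "fusion_pcc_change_x_bi": pp.bi_x_pcc_change}
        out["slope_dacc13_hi_bi"] = pp.dacc_13 + pp.bi_x_dacc_13
        out["slope_dacc13_lo_bi"] = pp.dacc_13 - pp.bi_x_dacc_13
        return out
    raise ValueError(f"unknown study {study!r}")


def null_gamma_calibration(replicates: int = 400, n: int = 176,
                           base_seed: int = 0,
                           block_sizes=(4, 4, 4, 4),
                           signal_r2: float = 0.3) -> pd.DataFrame:
    """Type-I error of the block Wald test under null later blocks.

    Generates standard-normal predictors in ``len(block_sizes)`` blocks with
    outcome signal only in block 1, fits the blockwise model (observed
    outcome, complete data) and records each later block's p-value.  Returns
    a per-block rejection-rate table at alpha = 0.05.
    """
    pcols = {k: [] for k in range(1, len(block_sizes))}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(1, replicates + 1):
            rng = np.random.default_rng(base_seed + r)
            p = sum(block_sizes)
            x = rng.standard_normal((n, p))
            w = rng.standard_normal(block_sizes[0])
            w *= np.sqrt(signal_r2) / np.linalg.norm(w)
            y = x[:, :block_sizes[0]] @ w \
                + np.sqrt(1 - signal_r2) * rng.standard_normal(n)
            cols = [f"x{i}" for i in range(p)]
            frame = pd.DataFrame(x, columns=cols)
            frame["y"] = y
            blocks, stop = [], 0
            for m in block_sizes:
                blocks.append(cols[stop:stop + m])
                stop += m
            res = IncrementalValidityModel(frame, blocks, outcome="y").fit()
            pv = res.increments()["pvalue"].to_numpy()
            for k in pcols:
                pcols[k].append(pv[k])
    rows = [{"block": f"block{k + 1}",
             "rejection_rate": float(np.mean(np.asarray(v) < 0.05)),
             "replicates": len(v)} for k, v in pcols.items()]
    return pd.DataFrame(rows).set_index("block")
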