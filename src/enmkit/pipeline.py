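"""End-to-end analysis pipeline: thin -> screen -> tune -> fit -> grade -> change.

:func:`run` executes the full presence-only workflow on a directory of
co-registered ``.asc`` layers and an occurrence CSV, with optional extra
scenario layer directories (past/future climates). Replicated fitting
follows the bootstrap convention: each replicate resamples the presence
set with replacement, splits it 75/25 into training and test records,
fits the selected model on the training share, and the analysis surface
is the mean of the replicate logistic rasters. The MTSPS threshold is
computed on the pooled held-out presence predictions against the
background, then drives grading, binarization, change mapping, and the
centroid trajectory.

Every stage writes plain-text artifacts (CSV / .asc / JSON) into the
output directory and appends a line to ``run_log.jsonl``; a rerun with
the same configuration is bit-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import change as change_mod
from . import suitability as suit_mod
from .evaluation import auc, auc_band, percent_contribution, tss
from .features import FC_CODES
from .grids import RasterStack, write_ascii_grid
from .model import MaxEnt, sample_background
from .occurrences import OccurrenceSet, load_and_clean, thin
from .selection import pearson_matrix, screen_variables
from .tuning import DEFAULT_RMS, tune

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (flat key/value document)."""

    occurrences_csv: str = ""
    layer_dir: str = ""
    out_dir: str = "enmkit_run"
    scenarios: dict[str, str] = field(default_factory=dict)  # name -> layer dir
    min_km: float = 2.5
    corr_threshold: float = 0.8
    baseline_fc: str = "LQHPT"
    fcs: tuple[str, ...] = FC_CODES
    rms: tuple[float, ...] = tuple(DEFAULT_RMS)
    n_background: int = 10_000
    replicates: int = 10
    train_fraction: float = 0.75
    years_between: float = 20.0
    n_knots: int = 50
    max_iter: int = 5000
    tol: float = 1e-5
    seed: int = 0
    mtsps: str | float = "auto"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for k, v in doc.items():
            if not hasattr(cfg, k):
                raise KeyError(f"unknown config key {k!r}")
            setattr(cfg, k, v)
        cfg.fcs = tuple(cfg.fcs)
        cfg.rms = tuple(float(r) for r in cfg.rms)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = asdict(self)
        d["fcs"] = list(self.fcs)
        d["rms"] = [float(r) for r in self.rms]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.t0 = time.time()
        path.write_text("")

    def stage(self, name: str, **fields) -> None:
        rec = {"stage": name, "elapsed_s": round(time.time() - self.t0, 3), **fields}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run_log.jsonl")
    config.to_yaml(out / "config.yaml")

    # ---- load inputs -----------------------------------------------------
    stack = RasterStack.from_dir(config.layer_dir)
    mask_layer = stack[stack.names[0]]
    occ = load_and_clean(config.occurrences_csv, raster_mask=mask_layer)
    cleaning = asdict(occ.report) if occ.report else {}
    log.stage("load", n_layers=len(stack), **cleaning)

    # ---- thinning --------------------------------------------------------
    occ_thin = thin(occ, min_km=config.min_km, seed=config.seed)
    occ_thin.to_csv(out / "occurrences_thinned.csv")
    log.stage("thin", seed=config.seed, min_km=config.min_km,
              n_in=len(occ), n_out=len(occ_thin))

    # ---- baseline contributions + collinearity screening -----------------
    baseline = MaxEnt.from_stack(
        stack, occ_thin, fc=config.baseline_fc, rm=1.0,
        n_background=config.n_background, seed=config.seed, n_knots=config.n_knots,
    ).fit(max_iter=config.max_iter, tol=config.tol)
    contrib = percent_contribution(baseline)
    contrib.to_csv(out / "baseline_contribution.csv")
    corr = pearson_matrix(stack, max_cells=20_000, seed=config.seed)
    corr.to_csv(out / "correlation_matrix.csv")
    kept, dropped = screen_variables(corr, contrib.to_dict(), threshold=config.corr_threshold)
    (out / "variable_screening.txt").write_text(
        "kept: " + ", ".join(kept) + "\n"
        + "".join(f"dropped {d} (|r|={abs(r):.3f} with {k})\n" for d, k, r in dropped)
    )
    log.stage("screen", kept=kept, dropped=[d for d, _, _ in dropped])
    stack_kept = stack.subset(kept)

    # ---- tuning ----------------------------------------------------------
    tr = tune(
        stack_kept, occ_thin, fcs=config.fcs, rms=config.rms,
        n_background=config.n_background, seed=config.seed,
        n_knots=config.n_knots, max_iter=config.max_iter, tol=config.tol,
    )
    tr.to_csv(out / "tuning.csv")
    fc_sel, rm_sel = tr.selected
    log.stage("tune", n_records=len(tr.records), selected_fc=fc_sel, selected_rm=rm_sel)

    # ---- replicated fits and mean logistic surfaces ----------------------
    h = stack_kept.header
    mask = stack_kept.joint_mask()
    inside = h.contains(occ_thin.lon, occ_thin.lat)
    prow, pcol = h.lonlat_to_rowcol(occ_thin.lon[inside], occ_thin.lat[inside])
    ok = mask[prow, pcol]
    prow, pcol = prow[ok], pcol[ok]
    X_p = stack_kept.values_at_cells(prow, pcol)
    brow, bcol = sample_background(stack_kept, n=config.n_background, seed=config.seed)
    X_b = stack_kept.values_at_cells(brow, bcol)

    scen_stacks: dict[str, RasterStack] = {"current": stack_kept}
    for name, d in config.scenarios.items():
        scen_stacks[name] = RasterStack.from_dir(d).subset(kept)

    n = X_p.shape[0]
    n_train = max(5, int(round(config.train_fraction * n)))
    surface_sum = {name: None for name in scen_stacks}
    test_preds: list[np.ndarray] = []
    bg_preds: list[np.ndarray] = []
    results_last = None
    for rep in range(config.replicates):
        rep_rng = np.random.default_rng(config.seed * 1000 + rep)
        boot = rep_rng.choice(n, size=n, replace=True)
        perm = rep_rng.permutation(n)
        train_idx, test_idx = boot[perm[:n_train]], boot[perm[n_train:]]
        mdl = MaxEnt(
            X_p[train_idx], X_b, stack_kept.names,
            fc=fc_sel, rm=rm_sel, n_knots=config.n_knots,
        )
        res = mdl.fit(max_iter=config.max_iter, tol=config.tol)
        results_last = res
        for name, s in scen_stacks.items():
            r = res.predict(s, output="logistic")
            surface_sum[name] = r.values if surface_sum[name] is None else surface_sum[name] + r.values
        if test_idx.size:
            test_preds.append(res.predict_points(X_p[test_idx], output="logistic"))
        bg_preds.append(res.predict_points(X_b, output="logistic"))
        log.stage("fit_replicate", replicate=rep, gain=round(res.gain, 4),
                  k_nonzero=res.k_nonzero, converged=res.converged)
    results_last.to_json(out / "model_last_replicate.json")

    mean_surface = {}
    for name, s in scen_stacks.items():
        vals = surface_sum[name] / config.replicates
        r = s[s.names[0]].with_values(vals, s.joint_mask())
        mean_surface[name] = r
        write_ascii_grid(r, out / f"logistic_{name}.asc", fmt="%.6f")

    # ---- evaluation + MTSPS ---------------------------------------------
    pooled_test = np.concatenate(test_preds) if test_preds else np.empty(0)
    pooled_bg = np.concatenate(bg_preds)
    if config.mtsps == "auto":
        mtsps = suit_mod.mtsps_threshold(pooled_test, pooled_bg)
    else:
        mtsps = float(config.mtsps)
    a_test = auc(pooled_test, pooled_bg) if pooled_test.size else float("nan")
    report = {
        "mtsps": mtsps,
        "auc_test": a_test,
        "auc_band": auc_band(a_test) if np.isfinite(a_test) else "undefined",
        "tss": tss(pooled_test, pooled_bg, mtsps) if pooled_test.size else float("nan"),
    }
    (out / "evaluation.json").write_text(json.dumps(report, indent=2))
    log.stage("mtsps", value=mtsps)

    # ---- grading + areas -------------------------------------------------
    scheme = suit_mod.GradeScheme(mtsps)
    area_rows = {}
    binaries = {}
    for name, surf in mean_surface.items():
        grades = suit_mod.classify(surf, scheme)
        write_ascii_grid(grades, out / f"grades_{name}.asc", fmt="%d")
        rep_a = suit_mod.area_report(grades)
        area_rows[name] = rep_a.to_frame()["area_1e4_km2"]
        binaries[name] = change_mod.binarize(surf, mtsps)
        write_ascii_grid(binaries[name], out / f"binary_{name}.asc", fmt="%d")
    pd.DataFrame(area_rows).to_csv(out / "areas.csv")
    log.stage("grade", scenarios=list(mean_surface))

    # ---- occurrence distribution proportions ------------------------------
    grades_cur = suit_mod.classify(mean_surface["current"], scheme)
    gvals = grades_cur.values[prow, pcol]
    counts = {g: int(np.sum(gvals == i)) for i, g in enumerate(suit_mod.GRADE_NAMES)}
    props = suit_mod.distribution_proportion(counts)
    pd.DataFrame({"count": counts, "proportion_pct": props}).to_csv(
        out / "occurrence_proportions.csv"
    )

    # ---- change maps + centroid trajectory -------------------------------
    scen_names = [s for s in scen_stacks if s != "current"]
    if not scen_names:
        log.stage("change", skipped=True, reason="single scenario")
    else:
        rows = {}
        for name in scen_names:
            cm = change_mod.change_map(binaries["current"], binaries[name])
            write_ascii_grid(cm.codes, out / f"change_{name}.asc", fmt="%d")
            st = change_mod.change_stats(cm)
            rows[name] = {k: round(v / 1e4, 2) if "pct" not in k else round(v, 2)
                          for k, v in st.to_row().items()}
        pd.DataFrame(rows).T.to_csv(out / "change_stats.csv")
        log.stage("change", scenarios=scen_names)

        traj = []
        order = ["current"] + scen_names
        cents = {name: change_mod.centroid(binaries[name]) for name in order}
        for a, b in zip(order[:-1], order[1:]):
            sh = change_mod.centroid_shift(cents[a], cents[b], config.years_between)
            traj.append({"from": a, "to": b, **sh.to_row()})
        pd.DataFrame(traj).to_csv(out / "centroid_trajectory.csv", index=False)
        log.stage("centroid", periods=order)

    log.stage("done")
    return out
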