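"""End-to-end orchestration of the synthetic volatilomics study.

``run_all`` sequences both detector branches — simulate (or load) paired
IMS/MS cube sets, run the branch preprocessing chains, then PCA, Ward
clustering on the first five PC scores, and PLSR calibration of the
alpha-acid content with an external test split — and writes a report bundle:
merit reports as JSON, score plots with group ellipses, dendrograms,
refolded loading maps and a provenance log.  The two branches share all
stage code and differ only by configuration (drift-time handling and the
log transform), and a rerun with an identical configuration produces
byte-identical JSON reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import chemometrics as chem
from . import preprocess as pp
from . import synthetic_data as sd


class SimSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_samples: int = 65
    n_replicates: int = 2
    seed: int = 0
    rt_step: float = 0.02
    n_dt: int = 256
    noise_sd_additive: float = 0.1
    noise_sd_multiplicative: float = 0.01
    rt_jitter_sd: float = 0.03
    dt_jitter_sd: float = 0.8
    conc_noise_sd: float = 0.06


class BranchSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sg_window: int = 7
    sg_polyorder: int = 2
    rt_lo: float = 1.3
    rt_hi: float = 15.0
    marker_rt: float = 0.5
    marker_window: float = 0.3
    pareto: bool = True  # Pareto scaling for the PLSR features
    n_lv: int | None = 5  # None -> stepwise selection up to lv_max
    lv_max: int = 10


class ChemSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_pcs_hca: int = 5
    n_pcs_plot: int = 2
    n_test: int = 10
    split_seed: int = 0
    ellipse_level: float = 0.975


class RunConfig(BaseModel):
    """Validated configuration of a full run; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    out_dir: str = "volatilo_run"
    sim: SimSection = Field(default_factory=SimSection)
    ims: BranchSection = Field(default_factory=BranchSection)
    ms: BranchSection = Field(default_factory=lambda: BranchSection(pareto=False, n_lv=2))
    chem: ChemSection = Field(default_factory=ChemSection)
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _branch_analysis(
    matrix: pp.UnfoldedMatrix,
    alpha: np.ndarray,
    branch_cfg: BranchSection,
    chem_cfg: ChemSection,
) -> dict:
    """PCA + HCA + PLSR for one detector branch on the unfolded matrix."""
    Xc, _ = pp.mean_center(matrix.X)
    n_pcs = min(chem_cfg.n_pcs_hca, matrix.X.shape[0] - 1)
    pca = chem.pca_fit(Xc, n_components=n_pcs, center=False)
    dendro = chem.hca_ward(pca.scores, k=n_pcs)

    train, test = chem.split_train_test(alpha, n_test=chem_cfg.n_test,
                                        seed=chem_cfg.split_seed)
    X_tr, X_te = matrix.X[train], matrix.X[test]
    y_tr, y_te = alpha[train], alpha[test]
    if branch_cfg.n_lv is None:
        sel = chem.select_lv(X_tr, y_tr, X_te, y_te, lv_max=branch_cfg.lv_max,
                             pareto=branch_cfg.pareto)
        n_lv = sel.n_lv
    else:
        n_lv = branch_cfg.n_lv
    model = chem.plsr_fit(X_tr, y_tr, n_lv, pareto=branch_cfg.pareto)
    merits = chem.figures_of_merit(y_tr, model.predict(X_tr),
                                   y_te, model.predict(X_te))
    return {"pca": pca, "dendrogram": dendro, "model": model, "merits": merits,
            "train": train, "test": test, "matrix": matrix, "alpha": alpha}


def _figures(result: dict, groups: np.ndarray, out: Path, tag: str,
             level: float) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    pca = result["pca"]
    fig, ax = plt.subplots(figsize=(5, 4))
    palette = {"low": "tab:blue", "middle": "tab:orange", "high": "tab:red"}
    for grp in ("low", "middle", "high"):
        sel = groups == grp
        if not np.any(sel):
            continue
        pts = pca.scores[sel, :2]
        ax.scatter(pts[:, 0], pts[:, 1], s=18, color=palette[grp], label=grp)
        if sel.sum() >= 3:
            try:
                ell = chem.mahalanobis_ellipse(pts, level=level)
            except np.linalg.LinAlgError:
                continue
            ax.add_patch(MplEllipse(ell.center, 2 * ell.semi_axes[0],
                                    2 * ell.semi_axes[1], angle=ell.angle_deg,
                                    fill=False, color=palette[grp], lw=1.2))
    ax.set_xlabel(f"PC1 ({pca.explained_variance_pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({pca.explained_variance_pct[1]:.1f}%)")
    ax.legend(title="alpha-acid group", fontsize=8)
    fig.tight_layout()
    fig.savefig(out / f"scores_{tag}.png", dpi=120)
    plt.close(fig)

    from scipy.cluster import hierarchy as h

    fig, ax = plt.subplots(figsize=(7, 3.5))
    h.dendrogram(result["dendrogram"].merges, ax=ax, no_labels=True,
                 color_threshold=0)
    ax.set_ylabel("Ward merge height")
    fig.tight_layout()
    fig.savefig(out / f"dendrogram_{tag}.png", dpi=120)
    plt.close(fig)

    lv1 = result["matrix"].refold(result["model"].weights[:, 0])
    fig, ax = plt.subplots(figsize=(5.5, 4))
    m = result["matrix"]
    im = ax.imshow(lv1.T, aspect="auto", origin="lower", cmap="coolwarm",
                   extent=[m.rt_axis[0], m.rt_axis[-1],
                           m.second_axis[0], m.second_axis[-1]],
                   vmin=-np.abs(lv1).max(), vmax=np.abs(lv1).max())
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("drift time (RIP-relative)" if m.second_name == "dt_rel" else "m/z")
    fig.colorbar(im, ax=ax, label="LV1 weight")
    fig.tight_layout()
    fig.savefig(out / f"loadings_lv1_{tag}.png", dpi=120)
    plt.close(fig)


def run_all(config: RunConfig) -> dict:
    """Run the full synthetic study for both branches; returns the bundle.

    Writes under ``config.out_dir``: merit_{ims,ms}.json, report.json,
    provenance_{ims,ms}.jsonl and (optionally) score/dendrogram/loading
    figures.  Any stage failure aborts with the failing stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        sim = config.sim
        sc = sd.SimConfig(
            n_samples=sim.n_samples, n_replicates=sim.n_replicates,
            rt_step=sim.rt_step, n_dt=sim.n_dt,
            seed=sim.seed, noise_sd_additive=sim.noise_sd_additive,
            noise_sd_multiplicative=sim.noise_sd_multiplicative,
            rt_jitter_sd=sim.rt_jitter_sd, dt_jitter_sd=sim.dt_jitter_sd,
        )
        samples, ims_cubes, ms_cubes = sd.simulate_study(
            sc, conc_noise_sd=sim.conc_noise_sd)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    alpha = np.array([s.alpha_acid for s in samples])
    groups = np.array([s.group for s in samples])
    results = {}
    for tag, cubes, branch_cfg in (("ims", ims_cubes, config.ims),
                                   ("ms", ms_cubes, config.ms)):
        try:
            if tag == "ims":
                proc = pp.preprocess_ims(
                    cubes, sg_window=branch_cfg.sg_window,
                    sg_polyorder=branch_cfg.sg_polyorder,
                    marker_rt=branch_cfg.marker_rt,
                    marker_window=branch_cfg.marker_window,
                    rt_lo=branch_cfg.rt_lo, rt_hi=branch_cfg.rt_hi)
            else:
                proc = pp.preprocess_ms(
                    cubes, sg_window=branch_cfg.sg_window,
                    sg_polyorder=branch_cfg.sg_polyorder,
                    marker_rt=branch_cfg.marker_rt,
                    marker_window=branch_cfg.marker_window,
                    rt_lo=branch_cfg.rt_lo, rt_hi=branch_cfg.rt_hi)
            averaged = pp.average_by_sample(proc)
            pp.write_provenance(averaged, out / f"provenance_{tag}.jsonl")
            matrix = pp.unfold(averaged)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"preprocess_{tag}", e) from e
        try:
            res = _branch_analysis(matrix, alpha, branch_cfg, config.chem)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"chemometrics_{tag}", e) from e
        results[tag] = res
        with open(out / f"merit_{tag}.json", "w") as fh:
            json.dump({**res["merits"].to_dict(),
                       "n_lv": res["model"].n_lv,
                       "pareto": branch_cfg.pareto}, fh, indent=2, sort_keys=True)
        if config.make_figures:
            try:
                _figures(res, groups, out, tag, config.chem.ellipse_level)
            except Exception as e:  # noqa: BLE001
                raise StageError(f"figures_{tag}", e) from e

    report = {
        "n_samples": len(samples),
        "branches": {
            tag: {
                "merits": results[tag]["merits"].to_dict(),
                "n_lv": results[tag]["model"].n_lv,
                "explained_variance_pct":
                    [round(float(v), 4)
                     for v in results[tag]["pca"].explained_variance_pct],
            }
            for tag in results
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    sd.metadata_frame(samples).to_csv(out / "samples.csv", index=False)
    return {"samples": samples, "report": report, **results}
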