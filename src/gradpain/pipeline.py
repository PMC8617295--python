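"""Orchestration: subject-level and group-level runs from one JSON config.

The config is a single declarative document::

    {
      "tr": 2.5, "highpass_hz": 0.01, "n_maps": 3, "tsm_order": 3,
      "graph_k": null, "n_perm": 10000, "seed": 42,
      "output_dir": "out",
      "qst_table": "cohort.csv",
      "subjects": [
        {"id": "sub-001", "bold": "...", "roi": "...", "brain": "...",
         "confounds": "..."},
        ...
      ]
    }

Every default and the config hash are recorded in a provenance sidecar next
to each output, and outputs are written atomically (temp file + rename).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import gradpain
from gradpain.connectopy import extract_connectopies, average_connectopy
from gradpain.errors import ConfigError, DataError
from gradpain.preprocess import ConfoundSet, clean
from gradpain.qst import score_cohort
from gradpain.stats import permutation_test, per_coefficient_association, sex_comparison, quintile_gradient_curves
from gradpain.synthetic import nuisance_design
from gradpain.trend_surface import fit_tsm
from gradpain.volume import load_confounds, load_mask, load_volume, save_volume, BoldVolume, Mask

log = logging.getLogger(__name__)


@dataclass
class SubjectPaths:
    id: str
    bold: str
    roi: str
    brain: str
    confounds: str | None = None


@dataclass
class RunConfig:
    subjects: list[SubjectPaths]
    qst_table: str | None = None
    tr: float | None = None
    highpass_hz: float = 0.01
    n_maps: int = 3
    tsm_order: int = 3
    graph_k: int | None = None
    n_perm: int = 10000
    seed: int = 0
    output_dir: str = "gradpain_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        try:
            doc = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        subjects = [SubjectPaths(**s) for s in doc.pop("subjects", [])]
        known = {f.name for f in dataclasses.fields(cls)} - {"subjects"}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(subjects=subjects, **doc)

    def validate(self) -> None:
        if not self.subjects:
            raise ConfigError("config lists no subjects")
        for s in self.subjects:
            for role in ("bold", "roi", "brain"):
                p = getattr(s, role)
                if not Path(p).exists():
                    raise ConfigError(f"subject {s.id}: missing {role} file {p}")
            if s.confounds and not Path(s.confounds).exists():
                raise ConfigError(f"subject {s.id}: missing confound file {s.confounds}")
        if self.qst_table and not Path(self.qst_table).exists():
            raise ConfigError(f"missing QST table {self.qst_table}")

    def provenance(self) -> dict:
        doc = dataclasses.asdict(self)
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return {
            "software": f"gradpain {gradpain.__version__}",
            "config_hash": hashlib.sha256(blob).hexdigest()[:16],
            "settings": doc,
        }


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def run_subject(config: RunConfig, subject_id: str) -> dict:
    """Preprocess → connectopy → trend surface for one subject.

    Writes one 3D NIfTI per connectopy plus a JSON sidecar with eigenvalues,
    TSM coefficients and provenance; returns the sidecar document.
    """
    config.validate()
    sub = next((s for s in config.subjects if s.id == subject_id), None)
    if sub is None:
        raise ConfigError(f"subject '{subject_id}' not in config")
    outdir = Path(config.output_dir) / subject_id
    outdir.mkdir(parents=True, exist_ok=True)

    vol = load_volume(sub.bold, tr=config.tr)
    roi = load_mask(sub.roi, "roi")
    brain = load_mask(sub.brain, "brain")
    conf = ConfoundSet(load_confounds(sub.confounds)) if sub.confounds else None
    log.info("[%s] preprocess: %d brain voxels, %d ROI voxels", subject_id, brain.n_voxels, roi.n_voxels)
    cvol, cbrain = clean(vol, brain, conf, cutoff_hz=config.highpass_hz)
    res = extract_connectopies(cvol, roi, cbrain, n_maps=config.n_maps, k=config.graph_k)

    cmap_grid = np.zeros((*roi.data.shape, config.n_maps), dtype=np.float32)
    tsm_docs = []
    for c in res.connectopies:
        cmap_grid[roi.data, c.rank - 1] = c.values
        fit = fit_tsm(c.values, res.roi_coordinates, order=config.tsm_order)
        tsm_docs.append(
            {
                "rank": c.rank,
                "eigenvalue": c.eigenvalue,
                "coefficients": fit.coefficients.tolist(),
                "intercept": fit.intercept,
                "r2_spatial": fit.r2_spatial,
                "prior_precision": fit.prior_precision,
            }
        )
    save_volume(BoldVolume(cmap_grid, vol.affine, vol.tr), outdir / "connectopies.nii.gz")
    doc = {
        "subject": subject_id,
        "n_target_components": res.n_components,
        "graph_k": res.graph.k,
        "graph_bridges": res.graph.n_bridges,
        "tsm": tsm_docs,
        "provenance": config.provenance(),
    }
    _atomic_write_text(outdir / "tsm.json", json.dumps(doc, indent=2, sort_keys=True))
    return doc


def run_group(config: RunConfig, n_bins: int = 10) -> dict:
    """Group statistics over completed subject runs.

    Requires every subject's sidecar and the QST table; computes per-outcome
    (cold, heat, mechanical, composite) partial R² of the dominant-gradient
    TSM block with Freedman–Lane permutation p-values, the per-parameter
    associations, the sex comparison, and quintile gradient curves.
    """
    config.validate()
    if len(config.subjects) < 8:
        raise DataError(f"group analysis needs >= 8 subjects, got {len(config.subjects)}")
    if not config.qst_table:
        raise ConfigError("group analysis needs qst_table in the config")
    rows, cmaps = [], []
    for s in config.subjects:
        side = Path(config.output_dir) / s.id / "tsm.json"
        if not side.exists():
            raise DataError(f"missing subject output {side}; run the subject level first")
        doc = json.loads(side.read_text())
        dom = next(t for t in doc["tsm"] if t["rank"] == 1)
        rows.append({"subject_id": s.id, **{f"tsm_{i}": v for i, v in enumerate(dom["coefficients"])}})
        import nibabel as nib

        img = nib.load(str(Path(config.output_dir) / s.id / "connectopies.nii.gz"))
        roi = load_mask(s.roi, "roi")
        cmaps.append(np.asanyarray(img.dataobj)[..., 0][roi.data])
    tsm_table = pd.DataFrame(rows)

    qst = pd.read_csv(config.qst_table)
    qst = score_cohort(qst)
    merged = tsm_table.merge(qst, on="subject_id")
    if len(merged) < 8:
        raise DataError("fewer than 8 subjects with both imaging and QST data")
    X = merged[[f"tsm_{i}" for i in range(3 * config.tsm_order)]].to_numpy()
    Z = nuisance_design(merged)

    outcomes = {}
    for name in ("z_cold", "z_heat", "z_mech", "composite"):
        res = permutation_test(merged[name].to_numpy(), X, Z, n_perm=config.n_perm, seed=config.seed)
        outcomes[name] = {
            "partial_r2": res.observed,
            "p_value": res.p_value,
            "n_perm": res.n_perm,
            "null_mean": float(res.null.mean()),
            "null_q95": float(np.quantile(res.null, 0.95)),
        }
    assoc = per_coefficient_association(
        merged["composite"].to_numpy(), X, Z, n_perm=min(config.n_perm, 1000), seed=config.seed
    )
    sexes = sex_comparison(X, merged["sex"].to_numpy())

    roi0 = load_mask(config.subjects[0].roi, "roi")
    coords = roi0.indices()[:, 1].astype(float)  # posteroanterior voxel axis
    curves = quintile_gradient_curves(
        np.array(cmaps), merged["composite"].to_numpy(), coords, n_bins=n_bins, seed=config.seed
    ) if len(merged) >= 25 else None

    results = {
        "n_subjects": int(len(merged)),
        "outcomes": outcomes,
        "per_parameter_composite": assoc.to_dict(orient="list"),
        "sex_comparison": sexes.to_dict(orient="list"),
        "quintile_curves": _curves_doc(curves),
        "average_connectopy": average_connectopy(cmaps).tolist(),
        "provenance": config.provenance(),
    }
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _atomic_write_text(out / "group_results.json", json.dumps(results, indent=2, sort_keys=True))
    return results


def write_group_figures(results: dict, outdir: str | Path) -> list[Path]:
    """Render the group-level summary figures (average dominant connectopy
    profile, quintile gradient curves with CI bands, per-parameter partial
    correlations) from a run_group results document."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(np.sort(results["average_connectopy"]))
    ax.set_xlabel("ROI voxel (sorted)")
    ax.set_ylabel("average dominant connectopy")
    fig.tight_layout()
    p = outdir / "average_connectopy.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    curves = results.get("quintile_curves")
    if curves:
        fig, ax = plt.subplots(figsize=(5, 3))
        x = curves["bin_centers"]
        for grp, color in (("low", "tab:blue"), ("high", "tab:red")):
            ax.plot(x, curves[grp]["curve"], color=color, label=f"{grp} sensitivity")
            ax.fill_between(x, curves[grp]["ci_low"], curves[grp]["ci_high"], color=color, alpha=0.25)
        ax.set_xlabel("normalized posteroanterior position")
        ax.set_ylabel("connectopy value")
        ax.legend()
        fig.tight_layout()
        p = outdir / "quintile_curves.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    assoc = results.get("per_parameter_composite")
    if assoc:
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(assoc["parameter"], assoc["partial_r"])
        ax.set_xlabel("trend-surface parameter")
        ax.set_ylabel("partial r with composite")
        fig.tight_layout()
        p = outdir / "per_parameter.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written


def _curves_doc(curves: dict | None):
    if curves is None:
        return None
    doc = {"bin_centers": curves["bin_centers"].tolist()}
    for grp in ("low", "high"):
        doc[grp] = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in curves[grp].items()}
    return doc
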