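"""End-to-end study workflow.

``run_study`` chains the whole analysis: read landmarks and tree → mirror
left elements → generalized Procrustes superimposition → semilandmark
sliding → bilateral symmetrization → shape PCA → Procrustes ANOVA
(shape ~ genus * log size), centroid-size ANOVA with Tukey HSD, multivariate
phylogenetic signal → CVA with leave-one-out cross-validation → projection
and classification of unknown (subfossil) specimens — and writes every
result surface as TSV/JSON plus a run manifest sufficient to re-run
identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    classify_unknowns,
    cva_fit,
    loo_crossvalidate,
    retained_pcs,
)
from .core import AlignedDataset, Configuration
from .io import save_aligned_dataset
from .morphospace import ancestral_states, pca_fit, shape_at_score
from .procrustes import gpa, mirror_configuration, slide_semilandmarks, symmetrize_pairs
from .stats import kmult, pairwise_group_tests, procrustes_anova, size_anova_tukey

__all__ = ["StudyOptions", "StudyResult", "run_study", "prepare_dataset"]


@dataclass
class StudyOptions:
    """Stage parameters for a full study run; all logged to the manifest."""

    n_permutations: int = 1000
    seed: int = 0
    sliding_cycles: int = 5
    pc_retention_variance: float = 0.90
    typicality_variant: str = "chisq"
    typicality_threshold: float = 0.20
    gpa_tol: float = 1e-10
    warp_axes: int = 2


@dataclass
class StudyResult:
    dataset: AlignedDataset
    space: object
    anova: object
    pairwise: pd.DataFrame
    size_anova: pd.DataFrame
    tukey: pd.DataFrame
    size_summary: pd.DataFrame
    signal: object | None
    cva: object
    loo_accuracy: float
    confusion: pd.DataFrame
    n_retained_pcs: int
    report: object | None
    manifest: dict = field(default_factory=dict)


def prepare_dataset(
    configs: list[Configuration],
    scheme,
    sliding_cycles: int = 5,
    gpa_tol: float = 1e-10,
) -> AlignedDataset:
    """Mirror lefts, superimpose, slide semilandmarks, symmetrize pairs."""
    prepared = [
        mirror_configuration(c) if c.side == "left" else c for c in configs
    ]
    ds = gpa(prepared, scheme, tol=gpa_tol)
    ds = slide_semilandmarks(ds, scheme, max_cycles=sliding_cycles)
    return symmetrize_pairs(ds)


def run_study(
    modern: list[Configuration],
    scheme,
    tree: dendropy.Tree | None = None,
    unknowns: list[Configuration] | None = None,
    options: StudyOptions | None = None,
    out_dir: str | Path | None = None,
) -> StudyResult:
    """Execute the full analysis chain on modern configurations, optionally
    classifying unknown specimens against the fitted reference.

    Writes (when ``out_dir`` is given): aligned dataset, PC scores and
    variance table, ANOVA/Tukey/pairwise tables, phylogenetic-signal result,
    LOO confusion table, a Table-1-style classification report, PC/CV
    scatter data and per-axis warp landmark sets, plus ``manifest.json``.
    """
    opt = options or StudyOptions()
    manifest: dict = {
        "package_version": __version__,
        "options": asdict(opt),
        "n_modern_configurations": len(modern),
        "n_unknowns": 0 if unknowns is None else len(unknowns),
        "stages_completed": [],
    }

    def _done(stage: str) -> None:
        manifest["stages_completed"].append(stage)

    try:
        ds = prepare_dataset(
            modern, scheme, sliding_cycles=opt.sliding_cycles, gpa_tol=opt.gpa_tol
        )
        _done("superimposition")

        space = pca_fit(ds)
        _done("pca")

        anova = procrustes_anova(
            ds, n_perm=opt.n_permutations, seed=opt.seed
        )
        pairwise = pairwise_group_tests(
            ds, n_perm=opt.n_permutations, seed=opt.seed + 1
        )
        size_tbl, tukey, size_summary = size_anova_tukey(ds)
        _done("group_stats")

        signal = None
        anc = None
        if tree is not None:
            species = ds.column("species").astype(str)
            species_scores = {
                sp: space.scores_[species == sp].mean(axis=0)
                for sp in sorted(set(species))
            }
            signal = kmult(
                species_scores, tree, n_perm=opt.n_permutations, seed=opt.seed + 2
            )
            anc = ancestral_states(
                {sp: v[:2] for sp, v in species_scores.items()}, tree
            )
            _done("phylogenetic_signal")

        genera = ds.column("genus").astype(str)
        n_groups = len(set(genera))
        cap = ds.n_specimens - n_groups - 1
        k = retained_pcs(space, opt.pc_retention_variance, cap=cap)
        scores_k = space.scores_[:, :k]
        model = cva_fit(scores_k, genera, typicality=opt.typicality_variant)
        loo_acc, confusion = loo_crossvalidate(scores_k, genera)
        _done("cva")

        report = None
        if unknowns:
            report = classify_unknowns(
                model,
                space,
                ds,
                unknowns,
                n_retained=k,
                typicality_threshold=opt.typicality_threshold,
            )
            _done("classification")

        manifest["n_retained_pcs"] = k
        manifest["loo_accuracy"] = loo_acc

        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            save_aligned_dataset(out / "aligned.json", ds, provenance=asdict(opt))
            ids = ds.column("specimen_id").astype(str)
            score_df = pd.DataFrame(
                space.scores_, columns=[f"PC{i+1}" for i in range(space.scores_.shape[1])]
            )
            score_df.insert(0, "specimen_id", ids)
            score_df.insert(1, "genus", genera)
            score_df.insert(2, "species", ds.column("species").astype(str))
            score_df.to_csv(out / "pc_scores.tsv", sep="\t", index=False)
            pd.DataFrame(
                {
                    "axis": [f"PC{i+1}" for i in range(len(space.eigenvalues_))],
                    "eigenvalue": space.eigenvalues_,
                    "variance_fraction": space.variance_fractions_,
                }
            ).to_csv(out / "pc_variance.tsv", sep="\t", index=False)
            anova.to_frame().to_csv(out / "procrustes_anova.tsv", sep="\t", index=False)
            pairwise.to_csv(out / "pairwise_shape_tests.tsv", sep="\t", index=False)
            size_tbl.to_csv(out / "size_anova.tsv", sep="\t", index=False)
            tukey.to_csv(out / "size_tukey_hsd.tsv", sep="\t", index=False)
            size_summary.to_csv(out / "size_summary.tsv", sep="\t", index=False)
            confusion.to_csv(out / "loo_confusion.tsv", sep="\t")
            cv_scores = model.canonical_scores(scores_k)[:, : model.n_canonical_axes_]
            cv_df = pd.DataFrame(
                cv_scores, columns=[f"CV{i+1}" for i in range(cv_scores.shape[1])]
            )
            cv_df.insert(0, "specimen_id", ids)
            cv_df.insert(1, "genus", genera)
            cv_df.to_csv(out / "cv_scores.tsv", sep="\t", index=False)
            if signal is not None:
                (out / "phylogenetic_signal.json").write_text(
                    json.dumps(
                        {
                            "k_mult": signal.k_mult,
                            "p_value": signal.p_value,
                            "n_permutations": signal.n_permutations,
                        },
                        indent=2,
                    )
                )
            if anc is not None:
                rows = []
                for nd, v in anc.items():
                    label = nd.taxon.label if nd.taxon else f"node_{id(nd) % 10**6}"
                    rows.append((label, nd.is_leaf(), *v[:2]))
                pd.DataFrame(rows, columns=["node", "is_tip", "PC1", "PC2"]).to_csv(
                    out / "phylomorphospace_nodes.tsv", sep="\t", index=False
                )
            for axis in range(min(opt.warp_axes, space.components_.shape[0])):
                lo = float(space.scores_[:, axis].min())
                hi = float(space.scores_[:, axis].max())
                for tag, val in (("min", lo), ("max", hi)):
                    warped = shape_at_score(space, axis, val)
                    np.savetxt(
                        out / f"warp_PC{axis+1}_{tag}.csv",
                        warped,
                        delimiter=",",
                        header="x,y,z",
                        comments="",
                    )
            if report is not None:
                report.table.to_csv(out / "classification_report.tsv", sep="\t", index=False)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return StudyResult(
            dataset=ds,
            space=space,
            anova=anova,
            pairwise=pairwise,
            size_anova=size_tbl,
            tukey=tukey,
            size_summary=size_summary,
            signal=signal,
            cva=model,
            loo_accuracy=loo_acc,
            confusion=confusion,
            n_retained_pcs=k,
            report=report,
            manifest=manifest,
        )
    except Exception as e:
        stage = manifest["stages_completed"][-1] if manifest["stages_completed"] else "input"
        raise RuntimeError(
            f"study failed after stage {stage!r}: {e}; completed stages: "
            f"{manifest['stages_completed']}"
        ) from e
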