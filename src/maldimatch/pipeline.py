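"""End-to-end orchestration: read -> normalize -> bin -> segment ->
discriminative m/z -> deisotope -> (impute -> moderated test -> classify)
-> tau-search -> MLP assignment -> cluster reports -> ORA.

Every stage writes a plain tabular file into the run directory so any
stage can be replaced by external software (e.g. a commercial segmentation
export), and a manifest records input hashes, parameters, seeds and the
package version — the manifest alone suffices to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .deisotope import DeisotopeParams, deisotope_all, export_monoisotopic_list
from .diffstats import (
    PeptideTable,
    fold_change_classify,
    impute_missing,
    moderated_ttest,
    ora_hypergeometric,
    protein_intensity_table,
    read_peptides_table,
    validate_proteins,
)
from .ims import bin_spectra, read_ims, tic_normalize
from .mlp import assign_proteins, assignments_frame, cluster_report, tau_search
from .segmentation import discriminative_mz, export_mass_list, segment
from .synthdata import GroundTruth, SimConfig, generate_ims_dataset, generate_lcms_table, write_peptides_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs, outputs and stage parameters of one pipeline run.

    Stage parameters default to the study's stated values: 0.1 Da bin
    width, ROC threshold 0.7, deisotoping tolerances 0.15 Da / 50%
    intensity, co-localization 0.7, imputation downshift 1.8 / width 0.3,
    and tau = 0.1 Da.  ``cluster_conditions`` maps each cluster id to the
    condition ("control"/"case" group name) whose tissue it occupies —
    a user declaration mirroring the manual histology step.
    """

    ims_path: str
    peptides_path: str
    out_dir: str
    ims_format: str = "imzml"
    bin_width: float = 0.1
    n_clusters: int = 3
    auc_threshold: float = 0.7
    mz_tol: float = 0.15
    intensity_tol: float = 0.5
    coloc_min: float = 0.7
    downshift: float = 1.8
    width: float = 0.3
    tau: float = 0.1
    ambiguity_ratio: float = 2.0
    seed: int = 0
    cluster_conditions: dict[int, str] = field(default_factory=dict)
    group_names: tuple[str, str] | None = None
    term_sets_path: str | None = None

    def validate(self) -> None:
        for name in ("ims_path", "peptides_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ValueError(f"{name}: no such file {p!r}")
        if self.n_clusters < 2:
            raise ValueError(f"n_clusters must be >= 2, got {self.n_clusters}")
        if self.tau <= 0 or self.bin_width <= 0:
            raise ValueError("tau and bin_width must be positive")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_term_sets(path) -> dict[str, set[str]]:
    """Read term membership as a two-column TSV (term <tab> member)."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("term\t"):
                continue
            term, member = line.split("\t")[:2]
            terms.setdefault(term, set()).add(member)
    return terms


def run_all(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory.

    On stage failure, a FAILED marker naming the stage is written and the
    exception re-raised; partial outputs are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "init"
    timings: dict[str, float] = {}
    try:
        t0 = time.perf_counter()

        def tick(name):
            nonlocal t0
            timings[name] = time.perf_counter() - t0
            logger.info("stage %s done in %.2fs", name, timings[name])
            t0 = time.perf_counter()

        stage = "read"
        ds = read_ims(config.ims_path, format=config.ims_format)
        table = read_peptides_table(config.peptides_path, group_names=config.group_names)
        tick(stage)

        stage = "normalize"
        ds = tic_normalize(ds)
        tick(stage)

        stage = "bin"
        binned = bin_spectra(ds, width=config.bin_width)
        tick(stage)

        stage = "segment"
        seg = segment(binned, k=config.n_clusters, seed=config.seed)
        labels = seg.labels_at(config.n_clusters)
        np.savetxt(out / "segmentation_labels.txt", labels.reshape(ds.grid_shape), fmt="%d")
        tick(stage)

        stage = "discriminative_mz"
        for c in np.unique(labels):
            entries = discriminative_mz(binned, labels, int(c), config.auc_threshold)
            if entries:
                export_mass_list(entries, out / f"discriminative_mz_cluster{c}.tsv")
        tick(stage)

        stage = "deisotope"
        params = DeisotopeParams(
            mz_tol=config.mz_tol, intensity_tol=config.intensity_tol, coloc_min=config.coloc_min
        )
        per_cluster, pooled = deisotope_all(ds, labels, params=params)
        for c, ml in per_cluster.items():
            export_monoisotopic_list(ml, out / f"monoisotopic_cluster{c}.tsv")
        export_monoisotopic_list(pooled, out / "monoisotopic_pooled.tsv")
        tick(stage)

        stage = "impute"
        table = impute_missing(table, downshift=config.downshift, width=config.width, seed=config.seed)
        tick(stage)

        stage = "moderated_test"
        table, test_params = moderated_ttest(table)
        tick(stage)

        stage = "classify"
        table = fold_change_classify(table)
        stats_out = pd.concat([table.meta.reset_index(drop=True), table.stats.reset_index(drop=True)], axis=1)
        stats_out.to_csv(out / "peptide_stats.tsv", sep="\t", index=False)
        g0, g1 = table.group_names
        volcano = stats_out[["Sequence", "Protein", "log2fc", "p"]].copy()
        volcano["neg_log10_p"] = -np.log10(volcano["p"])
        volcano.to_csv(out / "volcano.tsv", sep="\t", index=False)
        presence = validate_proteins(table)
        presence.to_csv(out / "protein_presence.tsv", sep="\t")
        tick(stage)

        stage = "match"
        assignments = []
        for c, ml in per_cluster.items():
            condition = config.cluster_conditions.get(int(c))
            if condition is None:
                logger.warning("cluster %d has no condition declaration; skipped in matching", c)
                continue
            cands = tau_search(ml, table, tau=config.tau, cluster_condition=condition)
            assignments.extend(
                assign_proteins(cands, cluster=int(c), ambiguity_ratio=config.ambiguity_ratio)
            )
        assignments_frame(assignments).to_csv(out / "assignments.tsv", sep="\t", index=False)
        tick(stage)

        stage = "report"
        reports = cluster_report(assignments)
        for c, rep in reports.items():
            rep.to_csv(out / f"proteins_cluster{c}.tsv", sep="\t", index=False)
        tick(stage)

        stage = "ora"
        if config.term_sets_path:
            terms = read_term_sets(config.term_sets_path)
            universe = set(table.meta["Protein"])
            for c, rep in reports.items():
                sel = set(rep["protein"]) & universe
                if sel:
                    res = ora_hypergeometric(sel, terms, universe)
                    res.to_csv(out / f"ora_cluster{c}.tsv", sep="\t", index=False)
        tick(stage)

        stage = "manifest"
        manifest = {
            "package": "maldimatch",
            "version": __version__,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            "inputs": {
                "ims": _sha256(config.ims_path),
                "peptides": _sha256(config.peptides_path),
            },
            "moderated_test": {
                "prior_df": None if np.isinf(test_params.prior_df) else test_params.prior_df,
                "prior_var": test_params.prior_var,
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.info("stage timings: %s", {k: round(v, 2) for k, v in timings.items()})
    except Exception as exc:
        (out / "FAILED").write_text(f"{stage}: {type(exc).__name__}: {exc}\n")
        raise
    return out


# ---------------------------------------------------------------------------
# Simulation harness

def _match_clusters_to_regions(labels: np.ndarray, truth: GroundTruth, grid_shape) -> dict[int, int]:
    """Map each segmentation label to the planted region it mostly overlaps."""
    region = truth.region_map.ravel()
    mapping = {}
    for c in np.unique(labels):
        regs, counts = np.unique(region[labels == c], return_counts=True)
        mapping[int(c)] = int(regs[counts.argmax()])
    return mapping


def simulate_and_run(
    sim_config: SimConfig, out_dir, run_overrides: dict | None = None
) -> tuple[Path, dict]:
    """Generate synthetic data, run the pipeline, score against the truth.

    Cluster condition declarations are derived from the ground truth by
    majority overlap of segmentation labels with planted regions (the
    stand-in for the manual histology judgment).  Returns the run directory
    and a metrics dict: segmentation ARI, envelope recovery, top-1
    parent-protein recovery, per-cluster report precision, and the observed
    type-I error of the moderated test on null peptides at alpha = 0.05.
    """
    from sklearn.metrics import adjusted_rand_score

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table_df, truth = generate_lcms_table(sim_config)
    ds = generate_ims_dataset(sim_config, truth)
    pep_path = out / "peptides.tsv"
    ims_path = out / "ims.tsv"
    write_peptides_table(table_df, pep_path)
    from .ims import write_ims

    write_ims(ds, ims_path, format="tabular")
    truth.save(out)

    # first segmentation pass to derive the cluster->condition declaration
    binned = bin_spectra(tic_normalize(ds), width=0.1)
    seg = segment(binned, k=sim_config.n_regions, seed=sim_config.seed)
    labels = seg.labels_at(sim_config.n_regions)
    cluster_region = _match_clusters_to_regions(labels, truth, sim_config.grid_shape)
    cluster_conditions = {c: truth.region_condition[r] for c, r in cluster_region.items()}

    cfg = RunConfig(
        ims_path=str(ims_path),
        peptides_path=str(pep_path),
        out_dir=str(out / "run"),
        ims_format="tabular",
        n_clusters=sim_config.n_regions,
        seed=sim_config.seed,
        cluster_conditions=cluster_conditions,
        group_names=sim_config.group_names,
    )
    if run_overrides:
        for k, v in run_overrides.items():
            setattr(cfg, k, v)
    run_dir = run_all(cfg)

    metrics = score_run(run_dir, truth, sim_config)
    with open(out / "truth_comparison.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    return run_dir, metrics


def score_run(run_dir, truth: GroundTruth, sim_config: SimConfig) -> dict:
    """Compare a finished run directory against the generator's ground truth."""
    from sklearn.metrics import adjusted_rand_score

    run_dir = Path(run_dir)
    labels = np.loadtxt(run_dir / "segmentation_labels.txt", dtype=int).ravel()
    ari = float(adjusted_rand_score(truth.region_map.ravel(), labels))
    cluster_region = _match_clusters_to_regions(labels, truth, sim_config.grid_shape)

    from .isotopes import PROTON_MASS

    imaged = truth.imaged().copy()
    imaged["mh"] = imaged["mass"] + PROTON_MASS  # observed monoisotopic m/z
    # envelope recovery: planted mono m/z found in the matched cluster's list
    recovered = 0
    mono_by_cluster = {}
    for c, r in cluster_region.items():
        path = run_dir / f"monoisotopic_cluster{c}.tsv"
        mono_by_cluster[c] = (
            pd.read_csv(path, sep="\t")["mono_mz"].to_numpy() if path.exists() else np.zeros(0)
        )
    for _, row in imaged.iterrows():
        for c, r in cluster_region.items():
            if r == row["ims_region"] and len(mono_by_cluster[c]):
                if np.min(np.abs(mono_by_cluster[c] - row["mh"])) <= 0.05:
                    recovered += 1
                    break
    envelope_recovery = recovered / max(len(imaged), 1)

    # top-1 protein recovery and report precision
    assignments = pd.read_csv(run_dir / "assignments.tsv", sep="\t")
    n_top1 = n_scored = 0
    precisions = []
    for c, r in cluster_region.items():
        planted = imaged[imaged["ims_region"] == r]
        planted_proteins = set(planted["protein"])
        sub = assignments[(assignments["cluster"] == c) & (assignments["status"] == "assigned")]
        for _, a in sub.iterrows():
            d = np.abs(planted["mh"].to_numpy() - a["ims_mz"])
            if len(d) and d.min() <= 0.1:
                n_scored += 1
                if planted["protein"].to_numpy()[d.argmin()] == a["protein"]:
                    n_top1 += 1
        rep_path = run_dir / f"proteins_cluster{c}.tsv"
        if rep_path.exists():
            rep = pd.read_csv(rep_path, sep="\t")
            if len(rep):
                precisions.append(
                    sum(p in planted_proteins for p in rep["protein"]) / len(rep)
                )
    top1 = n_top1 / max(n_scored, 1)

    # moderated-test type-I error on null (fold change 0) peptides
    stats_tab = pd.read_csv(run_dir / "peptide_stats.tsv", sep="\t")
    null_mask = np.isclose(truth.peptides["log2fc"].to_numpy(), 0.0)
    typeI = float((stats_tab.loc[null_mask, "p"] < 0.05).mean()) if null_mask.any() else np.nan

    return {
        "segmentation_ari": ari,
        "envelope_recovery": float(envelope_recovery),
        "top1_protein_recovery": float(top1),
        "n_matched_masses": int(n_scored),
        "report_precision": float(np.mean(precisions)) if precisions else np.nan,
        "type_I_error_alpha_05": typeI,
    }
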