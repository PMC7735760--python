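"""Stage orchestration: simulate -> call -> footprint -> cluster -> enrich.

Each stage reads and writes plain-text artifacts in a run directory, so
stages can be re-run individually; ``run_pipeline`` executes the stages
present in a :class:`~samosa.config.RunConfig` in order and writes a
machine-readable manifest (parameters, seeds, input digests, file digests)
for provenance.  All outputs are deterministic under a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cluster, enrich, footprint, methylation, sim
from .config import RunConfig
from .io import (
    FeatureSet,
    ModificationTrack,
    read_kinetics,
    read_tracks,
    write_bed,
    write_dyads,
    write_kinetics,
    write_tracks,
)

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_simulate(cfg, outdir: Path) -> dict:
    mixture = [
        (
            sim.FibreSpec(
                pattern_id=p.pattern_id,
                pattern_type=p.pattern_type,
                n_nucleosomes=p.n_nucleosomes,
                nrl=p.nrl,
                footprint=p.footprint,
                dyad_jitter_sd=p.dyad_jitter_sd,
                linker_meth_prob=p.linker_meth_prob,
                occluded_meth_prob=p.occluded_meth_prob,
                flank5=p.flank5,
                flank3=p.flank3,
                seq_mode=p.seq_mode,
            ),
            p.weight,
        )
        for p in cfg.patterns
    ]
    total = sum(w for _, w in mixture)
    mixture = [(s, w / total) for s, w in mixture]
    ipd_model = sim.IPDModel(**cfg.ipd.model_dump())
    molecules, truths, labels = sim.simulate_sample(
        mixture, cfg.n_molecules, ipd_model, cfg.seed
    )
    write_kinetics(molecules, outdir / "kinetics.tsv")
    write_bed(sim.truth_features(truths), outdir / "truth_dyads.bed")
    sim.write_labels(labels, outdir / "labels.tsv")
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)
    return {"n_molecules": len(molecules)}


def stage_call(cfg, outdir: Path, kinetics: Path) -> dict:
    molecules = list(read_kinetics(kinetics))
    z, flagged = methylation.pooled_z(
        molecules, min_at=cfg.min_at, anchor=cfg.anchor
    )
    fit = methylation.fit_mixture(
        z, max_iter=cfg.max_iter, tol=cfg.tol, seed=cfg.seed
    )
    fit.model.to_json(outdir / "model.json")
    tracks, flagged2 = methylation.call_sample(
        molecules,
        fit.model,
        per_molecule=cfg.per_molecule,
        min_at=cfg.min_at,
        anchor=cfg.anchor,
        score=cfg.score,
    )
    write_tracks(tracks, outdir / "tracks.tsv")
    (outdir / "flagged_molecules.txt").write_text(
        "".join(f"{mid}\n" for mid in sorted(set(flagged) | set(flagged2)))
    )
    return {
        "n_molecules": len(molecules),
        "n_tracks": len(tracks),
        "n_flagged": len(set(flagged) | set(flagged2)),
        "mixture_flags": list(fit.flags),
    }


def stage_footprint(cfg, outdir: Path, tracks_path: Path, kinetics: Path) -> dict:
    tracks = list(read_tracks(tracks_path))
    smooth = cfg.smooth_window or (
        footprint.IN_VITRO_SMOOTH if cfg.mode == "invitro" else footprint.IN_VIVO_SMOOTH
    )
    nrl_rows = []
    if cfg.mode == "invitro":
        molecules = {m.molecule_id: m for m in read_kinetics(kinetics)}
        callsets = []
        for t in tracks:
            sm = footprint.rolling_mean_nan(t.prob, smooth)
            if sm.size < cfg.dyad_window:
                continue
            cs = footprint.call_dyads(
                sm,
                window=cfg.dyad_window,
                min_separation=cfg.min_separation,
                edge_margin=cfg.edge_margin,
                molecule_id=t.molecule_id,
            )
            callsets.append(cs)
            nrl_rows.append(
                {
                    "molecule_id": t.molecule_id,
                    "nrl_lag": np.nan,
                    "peak_found": False,
                    "averaged_nrl": cs.averaged_nrl,
                    "n_dyads": cs.dyads.size,
                }
            )
        write_dyads(callsets, molecules, outdir / "dyads.bed")
        n_out = len(callsets)
    else:
        acg_rows = []
        for t in tracks:
            sm = footprint.rolling_mean_nan(t.prob, smooth)[: cfg.max_len_used]
            try:
                acg = footprint.autocorrelogram(sm, molecule_id=t.molecule_id)
            except ValueError:
                continue
            call = footprint.find_nrl_peak(
                acg, lag_range=(cfg.lag_min, cfg.lag_max),
                prominence=cfg.prominence, height=cfg.peak_height,
            )
            acg_rows.append(
                (t.molecule_id, ",".join("" if not np.isfinite(v) else f"{v:.6f}"
                                         for v in acg.values))
            )
            nrl_rows.append(
                {
                    "molecule_id": t.molecule_id,
                    "nrl_lag": call.nrl_lag if call.peak_found else np.nan,
                    "peak_found": call.peak_found,
                    "averaged_nrl": np.nan,
                    "n_dyads": 0,
                }
            )
        with open(outdir / "acg.tsv", "w") as fh:
            fh.write("molecule_id\tacg\n")
            for mid, vals in acg_rows:
                fh.write(f"{mid}\t{vals}\n")
        n_out = len(acg_rows)
    pd.DataFrame(nrl_rows).to_csv(outdir / "nrl.csv", index=False)
    return {"n_tracks": len(tracks), "n_out": n_out, "mode": cfg.mode}


def read_acg_matrix(path: Path) -> list[footprint.Autocorrelogram]:
    acgs = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "molecule_id\tacg":
            raise ValueError(f"{path}: unexpected header")
        for line in fh:
            mid, _, vals = line.rstrip("\n").partition("\t")
            arr = np.array(
                [float(v) if v else np.nan for v in vals.split(",")], dtype=float
            )
            acgs.append(footprint.Autocorrelogram(mid, arr, np.zeros(arr.size, int)))
    return acgs


def stage_cluster(cfg, outdir: Path, acg_path: Path, nrl_path: Path,
                  tracks_path: Path) -> dict:
    acgs = read_acg_matrix(acg_path)
    matrix = cluster.build_matrix(acgs, min_len=cfg.min_len,
                                  max_len_used=cfg.max_len_used)
    assignment = cluster.leiden_cluster(
        matrix, k_neighbors=cfg.k_neighbors, resolution=cfg.resolution,
        seed=cfg.seed,
    )
    nrl_df = pd.read_csv(nrl_path)
    calls = [
        footprint.NrlCall(
            r.molecule_id,
            int(r.nrl_lag) if r.peak_found and np.isfinite(r.nrl_lag) else None,
            bool(r.peak_found),
        )
        for r in nrl_df.itertuples(index=False)
    ]
    tracks = list(read_tracks(tracks_path))
    summary = cluster.summarize_clusters(
        assignment, calls, tracks, fibre_matrix=matrix
    )
    assignment.to_frame().to_csv(outdir / "assignment.csv", index=False)
    summary.table.to_csv(outdir / "summary.csv", index=False)
    np.savetxt(outdir / "profiles_modification.tsv", summary.mod_profiles,
               delimiter="\t", fmt="%.6g")
    if summary.mean_acg is not None:
        np.savetxt(outdir / "profiles_acg.tsv", summary.mean_acg,
                   delimiter="\t", fmt="%.6g")
    with open(outdir / "cluster_params.json", "w") as fh:
        json.dump(assignment.params, fh, indent=2)
    return {"n_clustered": len(assignment.molecule_ids),
            "n_clusters": assignment.n_clusters}


def stage_enrich(cfg, outdir: Path, assignment_path: Path, labels_path: Path) -> dict:
    adf = pd.read_csv(assignment_path)
    assignment = cluster.ClusterAssignment(
        list(adf["molecule_id"].astype(str)), adf["cluster"].to_numpy()
    )
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    categories = labels.rename(columns={"pattern_id": "category"})
    table = enrich.enrichment_scan(assignment, categories, fdr=cfg.fdr)
    table.to_csv(outdir / "enrichment.csv", index=False)
    return {"n_tests": len(table),
            "n_significant": int(table["significant"].sum()) if len(table) else 0}


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run all configured stages in order and write a provenance manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = config.model_dump_json()
    manifest: dict = {
        "package_version": __version__,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stages": {},
    }

    kinetics = outdir / "kinetics.tsv"
    tracks = outdir / "tracks.tsv"
    if config.simulate is not None:
        manifest["stages"]["simulate"] = stage_simulate(config.simulate, outdir)
    if config.call is not None:
        if not kinetics.exists():
            raise FileNotFoundError(f"call stage: missing input {kinetics}")
        manifest["stages"]["call"] = stage_call(config.call, outdir, kinetics)
    if config.footprint is not None:
        if not tracks.exists():
            raise FileNotFoundError(f"footprint stage: missing input {tracks}")
        manifest["stages"]["footprint"] = stage_footprint(
            config.footprint, outdir, tracks, kinetics
        )
    if config.cluster is not None:
        acg = outdir / "acg.tsv"
        if not acg.exists():
            raise FileNotFoundError(f"cluster stage: missing input {acg}")
        manifest["stages"]["cluster"] = stage_cluster(
            config.cluster, outdir, acg, outdir / "nrl.csv", tracks
        )
    if config.enrich is not None:
        assignment = outdir / "assignment.csv"
        labels = outdir / "labels.tsv"
        for p in (assignment, labels):
            if not p.exists():
                raise FileNotFoundError(f"enrich stage: missing input {p}")
        manifest["stages"]["enrich"] = stage_enrich(
            config.enrich, outdir, assignment, labels
        )

    manifest["outputs"] = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", outdir)
    return outdir
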