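"""Pipeline orchestration: configuration, seeding, stage chaining, provenance.

A single declarative YAML config drives the full analysis
(features -> eigenposture -> {motifs, hmm, map} -> stats); every random stage
receives a sub-seed derived from the global seed, all outputs are CSV/JSON
tables, and a provenance record (config hash, package version, input hashes)
makes any output reproducible. Stages can be toggled; a rerun with the same
config and inputs is deterministic.

Console entry point::

    cionaswim run --config run.yaml [--seed N] [--out DIR]
    cionaswim simulate --out DIR [--seed N] [--n N] [--duration S]
"""

from __future__ import annotations

import argparse
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import behavior_map, eigenposture, features, hmm_states, io_model, motifs, stats_stimulus


@dataclass
class RunConfig:
    manifest: str
    out_dir: str = "run"
    seed: int = 0
    min_valid_fraction: float = 0.8
    eigen_k: int = 6
    stages: dict = field(
        default_factory=lambda: {"features": True, "eigen": True, "motifs": True, "hmm": True, "map": True, "stats": True}
    )
    motif_window: int = 30
    motif_threshold: float = 8.0
    motif_clusters: int = 15
    hmm_states: int = 10
    hmm_covariance: str = "full"
    map_sample: int = 5000
    map_eps: float | None = None
    map_min_samples: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def sub_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class DependencyError(RuntimeError):
    pass


def run(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(config.manifest)
    if not manifest_path.exists():
        raise DependencyError(f"stage 'load': missing input manifest {manifest_path}")
    ds = io_model.read_manifest(manifest_path)
    ds = io_model.filter_recordings(ds, config.min_valid_fraction)
    recordings = ds.all_recordings()
    if not recordings:
        raise DependencyError("stage 'load': no recordings pass the validity filter")
    provenance = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": hashlib.sha256(json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16],
        "inputs": {str(manifest_path): _hash_file(manifest_path)},
        "stages_run": [],
    }

    parts = {r.animal_id: features.partition_recording(r) for r in recordings}
    kappa = {
        r.animal_id: np.where(
            r.valid[:, None], features.curvature(np.nan_to_num(r.points)), np.nan
        )
        for r in recordings
    }

    basis = None
    if config.stages.get("eigen", True):
        pooled = np.concatenate([k[np.isfinite(k).all(axis=1)] for k in kappa.values()])
        basis = eigenposture.fit_eigenbasis(pooled, k=config.eigen_k)
        eigenposture.save_eigenbasis(basis, out / "eigenbasis.csv")
        provenance["stages_run"].append("eigen")

    panels = {}
    if config.stages.get("features", True):
        if basis is None:
            raise DependencyError("stage 'features': requires stage 'eigen' for EC columns")
        for r in recordings:
            ec = eigenposture.project(kappa[r.animal_id], basis)
            panels[r.animal_id] = features.feature_panel(r, ec[:, :6], parts[r.animal_id])
        pd.concat(panels.values()).to_csv(out / "feature_panel.csv", index=False)
        provenance["stages_run"].append("features")

    if config.stages.get("motifs", True):
        cfg = motifs.MotifConfig(
            m=config.motif_window, profile_threshold=config.motif_threshold, n_clusters=config.motif_clusters
        )
        by_condition: dict[str, list] = {}
        for cond, recs in ds.recordings.items():
            found = []
            for r in recs:
                seg = features.segment_curvature(kappa[r.animal_id], parts[r.animal_id]).T
                seg = np.nan_to_num(seg)
                if seg.shape[1] >= 2 * cfg.m:
                    found.extend(motifs.mine_recording(seg, r.animal_id, cfg, valid=r.valid))
            by_condition[cond] = found
        all_motifs = [m for ms in by_condition.values() for m in ms]
        if len(all_motifs) >= cfg.n_clusters:
            model = motifs.cluster_motifs(all_motifs, k=cfg.n_clusters, seed=config.sub_seed("motifs"))
            catalog = pd.DataFrame(
                {
                    "recording_id": [m.recording_id for m in all_motifs],
                    "start_frame": [m.start_frame for m in all_motifs],
                    "window": [m.m for m in all_motifs],
                    "cluster": [m.cluster_label for m in all_motifs],
                }
            )
            catalog.to_csv(out / "motif_catalog.csv", index=False)
            if ds.control_map:
                usage, fold = motifs.motif_usage(by_condition, ds.control_map, k=cfg.n_clusters)
                usage.to_csv(out / "motif_usage.csv")
                fold.to_csv(out / "motif_fold_change.csv")
        provenance["stages_run"].append("motifs")

    decoded_by_condition: dict[str, list] = {}
    hmm_model = None
    if config.stages.get("hmm", True):
        if not panels:
            raise DependencyError("stage 'hmm': requires stage 'features'")
        feat_cols = [f"EC{i}" for i in range(1, 7)] + ["quirkiness"]
        sequences = []
        for r in recordings:
            segs = hmm_states.split_at_gaps(panels[r.animal_id][feat_cols].to_numpy(), min_length=config.hmm_states)
            sequences.extend(segs)
        hmm_model = hmm_states.fit_ghmm(
            sequences, n_states=config.hmm_states, covariance_type=config.hmm_covariance, seed=config.sub_seed("hmm")
        )
        hmm_states.save_model(hmm_model, out / "hmm_model.json")
        rows = []
        for cond, recs in ds.recordings.items():
            decoded_by_condition[cond] = []
            for r in recs:
                X = panels[r.animal_id][feat_cols].to_numpy()
                ok = np.isfinite(X).all(axis=1)
                if ok.sum() < 2:
                    continue
                seq = hmm_states.decode(X[ok], hmm_model, r.animal_id, frame_index=r.frame_index[ok])
                decoded_by_condition[cond].append(seq)
                rows.append(
                    pd.DataFrame({"recording_id": r.animal_id, "frame": seq.frame_index, "state": seq.states})
                )
        pd.concat(rows).to_csv(out / "hmm_states.csv", index=False)
        usage, _ = hmm_states.state_usage(decoded_by_condition, config.hmm_states, ds.control_map)
        usage.to_csv(out / "hmm_state_usage.csv")
        for cond, seqs in decoded_by_condition.items():
            matrix, _ = hmm_states.empirical_transitions(seqs, config.hmm_states)
            np.savetxt(out / f"transitions_{cond}.csv", matrix, delimiter=",")
        provenance["stages_run"].append("hmm")

    if config.stages.get("map", True):
        if not panels:
            raise DependencyError("stage 'map': requires stage 'features'")
        feats, speeds = [], []
        for r in recordings:
            panel = panels[r.animal_id]
            ec = panel[[f"EC{i}" for i in range(1, 7)]].to_numpy().T
            if np.isfinite(ec).all() and ec.shape[1] >= 64:
                wf = behavior_map.wavelet_features(ec, fps=r.fps)
                feats.append(wf.T)
                speeds.append(panel[[f"s{s}" for s in features.TAIL_SEGMENT_NAMES]].to_numpy())
        if feats:
            F = np.concatenate(feats)
            S = np.concatenate(speeds)
            n = min(config.map_sample, len(F))
            idx, _ = behavior_map.speed_weighted_sample(S, n=n, seed=config.sub_seed("map"))
            emb = behavior_map.fit_embedding(F[idx], seed=config.sub_seed("map"))
            coords = pd.DataFrame(emb.composite, columns=["e1x", "e1y", "e2x", "e3y"])
            coords.to_csv(out / "embedding_coords.csv", index=False)
            if config.map_eps is not None:
                cl = behavior_map.cluster_map(emb, eps=config.map_eps, min_samples=config.map_min_samples)
                pd.DataFrame({"label": cl.labels}).to_csv(out / "map_labels.csv", index=False)
            density, _ = behavior_map.occupancy_density(emb.composite[:, :2])
            np.savetxt(out / "map_density.csv", density, delimiter=",")
        provenance["stages_run"].append("map")

    if config.stages.get("stats", True):
        if not panels:
            raise DependencyError("stage 'stats': requires stage 'features'")
        panels_by_cond = {
            cond: pd.concat([panels[r.animal_id] for r in recs]) for cond, recs in ds.recordings.items()
        }
        if ds.control_map:
            barcode = stats_stimulus.smd_barcode(panels_by_cond, ds.control_map)
            barcode.to_csv(out / "smd_barcode.csv")
            rows = []
            for cond, ctrl in ds.control_map.items():
                for col in features.PANEL_COLUMNS:
                    res = stats_stimulus.drug_vs_control_test(
                        panels_by_cond[cond][col].dropna().to_numpy(),
                        panels_by_cond[ctrl][col].dropna().to_numpy(),
                        name=f"{cond}:{col}",
                    )
                    rows.append(asdict(res))
            pd.DataFrame(rows).to_csv(out / "drug_tests.csv", index=False)
        provenance["stages_run"].append("stats")

    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return out


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(prog="cionaswim", description=__doc__)
    sub = parser.add_subparsers(dest="command", required=True)
    p_run = sub.add_parser("run", help="run the configured pipeline")
    p_run.add_argument("--config", required=True)
    p_run.add_argument("--seed", type=int, default=None)
    p_run.add_argument("--out", default=None)
    p_sim = sub.add_parser("simulate", help="emit a simulated dataset + manifest")
    p_sim.add_argument("--out", required=True)
    p_sim.add_argument("--seed", type=int, default=0)
    p_sim.add_argument("--n", type=int, default=4)
    p_sim.add_argument("--duration", type=float, default=60.0)
    args = parser.parse_args(argv)
    if args.command == "run":
        config = RunConfig.from_yaml(args.config)
        if args.seed is not None:
            config.seed = args.seed
        if args.out is not None:
            config.out_dir = args.out
        out = run(config)
        print(f"pipeline outputs written to {out}")
    elif args.command == "simulate":
        from .synthetic_data import simulate_dataset

        ds, _ = simulate_dataset({"wild_type": args.n}, duration_s=args.duration, seed=args.seed)
        manifest = io_model.write_manifest(ds, args.out)
        print(f"simulated dataset manifest: {manifest}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
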