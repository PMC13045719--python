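"""End-to-end experiment orchestration.

A single :class:`ExperimentConfig` drives the whole chain — phantoms → RF
scan → 7-stage processing → CT → paired dataset → per-stage translation
training → metric evaluation — with every phase cached on disk (HDF5 /
npz / CSV) and resumable: a rerun with an identical config reuses any
completed phase untouched.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from us2ct import io as us2ct_io
from us2ct.ct_sim import simulate_ct
from us2ct.metrics import aggregate_records, evaluate_testset, records_to_frame
from us2ct.pairs import align_and_resample, aligned_masks, make_split
from us2ct.phantoms import PhantomConfig, realize_phantom, sample_inclusions
from us2ct.pix2pix import ModelState, TrainConfig, load_model, save_model, train
from us2ct.rf_chain import STAGES, StageMatrix, run_chain
from us2ct.us_sim import ProbeConfig, desk_probe, scan


@dataclass
class ExperimentConfig:
    flavour: str = "ct_invisible"
    n_phantoms: int = 120
    scale_preset: str = "desk_64"       # desk_64 | full_256
    stages: tuple = ("upsampling",)
    grid_spacing: float = 0.4           # mm/pixel of the phantom raster
    n_angles: int = 100
    sirt_iterations: int = 40
    ct_noise_frac: float = 0.01
    train_steps: int = 3000
    train_ratio: float = 0.8
    seed_phantom: int = 10
    seed_split: int = 20
    seed_train: int = 30
    output_dir: str = "experiment_out"
    max_inclusions: int = 3

    @property
    def out_size(self) -> int:
        return 256 if self.scale_preset == "full_256" else 64

    def probe(self) -> ProbeConfig:
        return ProbeConfig() if self.scale_preset == "full_256" else desk_probe()

    def phantom_config(self) -> PhantomConfig:
        return PhantomConfig(
            grid_spacing=self.grid_spacing,
            flavour=self.flavour,
            max_inclusions=self.max_inclusions,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["stages"] = tuple(raw.get("stages", ("upsampling",)))
        return cls(**raw)


def _phantom_seed(base: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([base, index]))


def simulate_dataset(config: ExperimentConfig, log=print) -> Path:
    """Phase 1-3: phantoms, RF stages and CT into one HDF5 container.

    Each phantom id is independently seeded from ``seed_phantom`` so the
    phase is resumable and order-independent.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    h5path = outdir / "dataset.h5"
    pcfg = config.phantom_config()
    probe = config.probe()
    t0 = time.time()
    with h5py.File(h5path, "a") as f:
        root = f.require_group("phantoms")
        for i in range(config.n_phantoms):
            pid = f"p{i:04d}"
            if pid in root and root[pid].attrs.get("complete", False):
                continue
            if pid in root:
                del root[pid]
            rng = _phantom_seed(config.seed_phantom, i)
            inclusions = sample_inclusions(pcfg, rng)
            phantom = realize_phantom(pcfg, inclusions, rng)
            g = root.create_group(pid)
            us2ct_io.save_phantom(g, phantom)
            rf = scan(phantom, probe, rng)
            rf.phantom_id = pid
            for stage in run_chain(rf):
                if stage.stage in config.stages or stage.stage == "upsampling":
                    us2ct_io.save_stage(g, stage.stage, stage.data, stage.dt, stage.c_bar)
            ct = simulate_ct(
                phantom, rng,
                n_angles=config.n_angles,
                n_iterations=config.sirt_iterations,
                noise_sigma_frac=config.ct_noise_frac,
            )
            us2ct_io.save_ct(g, ct)
            g.attrs["complete"] = True
        f.attrs["flavour"] = config.flavour
        f.attrs["seed_phantom"] = config.seed_phantom
    log(f"[simulate] {config.n_phantoms} phantoms ready in {time.time()-t0:.1f}s")
    return h5path


def build_pairs(config: ExperimentConfig, stage: str, log=print):
    """Phase 4 for one stage: aligned pairs plus evaluation masks."""
    h5path = Path(config.output_dir) / "dataset.h5"
    pcfg = config.phantom_config()
    probe = config.probe()
    pairs, masks = {}, {}
    with h5py.File(h5path, "r") as f:
        for pid in sorted(f["phantoms"].keys()):
            g = f["phantoms"][pid]
            phantom = us2ct_io.load_phantom(g)
            ct = us2ct_io.load_ct(g)
            d = g["stages"][stage]
            sm = StageMatrix(
                stage=stage, data=d[...].astype(np.float64), probe=probe,
                c_bar=float(d.attrs["c_bar"]), dt=float(d.attrs["dt"]),
                phantom_id=pid, flavour=config.flavour,
            )
            pairs[pid] = align_and_resample(sm, ct, pcfg, probe, config.out_size)
            masks[pid] = aligned_masks(phantom, probe, config.out_size)
    return pairs, masks


def split_manifest(config: ExperimentConfig, ids):
    outdir = Path(config.output_dir)
    path = outdir / "split.json"
    if path.exists():
        raw = json.loads(path.read_text())
        return raw["train"], raw["test"]
    manifest = make_split(sorted(ids), ratio=config.train_ratio, seed=config.seed_split)
    path.write_text(json.dumps({"train": list(manifest.train_ids),
                                "test": list(manifest.test_ids),
                                "seed": config.seed_split}))
    return list(manifest.train_ids), list(manifest.test_ids)


def train_stage(config: ExperimentConfig, stage: str, train_pairs, log=print) -> ModelState:
    """Phase 5 for one stage, cached as models/<stage>.npz."""
    outdir = Path(config.output_dir) / "models"
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{stage}.npz"
    if path.exists():
        log(f"[train] reusing cached model for {stage}")
        return load_model(path)
    tcfg = TrainConfig(
        steps=config.train_steps,
        seed=config.seed_train,
        scale_preset=config.scale_preset,
    )
    t0 = time.time()
    state = train(train_pairs, tcfg, np.random.default_rng(config.seed_train))
    log(f"[train] {stage}: {tcfg.steps} steps in {time.time()-t0:.1f}s "
        f"(final L1 {np.mean(state.loss_history['g_l1'][-50:]):.4f})")
    save_model(state, path)
    return state


def run_experiment(config: ExperimentConfig, log=print) -> dict:
    """Run (or resume) the full experiment; returns a report dict and
    writes metrics CSVs plus a JSON provenance manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    simulate_dataset(config, log=log)

    models, test_pairs_by_stage, masks_all = {}, {}, {}
    for stage in config.stages:
        pairs, masks = build_pairs(config, stage, log=log)
        masks_all.update(masks)
        train_ids, test_ids = split_manifest(config, pairs.keys())
        models[stage] = train_stage(config, stage, [pairs[i] for i in train_ids], log=log)
        test_pairs_by_stage[stage] = [pairs[i] for i in test_ids]

    records = evaluate_testset(models, test_pairs_by_stage, masks_all, config.flavour)
    df = records_to_frame(records)
    df.to_csv(outdir / "metrics.csv", index=False)
    agg = aggregate_records(records)
    agg.to_csv(outdir / "metrics_aggregated.csv", index=False)
    manifest = {
        "config": asdict(config),
        "n_records": len(records),
        "stages": list(config.stages),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log(f"[evaluate] {len(records)} metric records written")
    return {"records": records, "aggregate": agg, "models": models,
            "test_pairs": test_pairs_by_stage, "masks": masks_all}


def make_fixtures(seed: int, path, n_per_flavour: int = 4) -> Path:
    """Miniature deterministic dataset bundle (coarse grid, all stages)
    used by the test suite."""
    path = Path(path)
    probe = desk_probe()
    with h5py.File(path, "w") as f:
        for fi, flavour in enumerate(("ct_invisible", "ct_visible")):
            pcfg = PhantomConfig(grid_spacing=0.4, flavour=flavour)
            root = f.require_group(f"{flavour}/phantoms")
            for i in range(n_per_flavour):
                rng = np.random.default_rng(np.random.SeedSequence([seed, fi, i]))
                phantom = realize_phantom(pcfg, sample_inclusions(pcfg, rng), rng)
                g = root.create_group(f"p{i:04d}")
                us2ct_io.save_phantom(g, phantom)
                rf = scan(phantom, probe, rng)
                for stage in run_chain(rf):
                    us2ct_io.save_stage(g, stage.stage, stage.data, stage.dt, stage.c_bar)
                ct = simulate_ct(phantom, rng, n_iterations=20)
                us2ct_io.save_ct(g, ct)
        f.attrs["seed"] = seed
    return path
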