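"""End-to-end workflow: generate/split/encode/(evolve)/train/evaluate/explain.

Every stage draws its randomness from named substreams of the single config
seed; two runs with the same config and inputs produce identical artifacts.
The artifacts directory holds a split audit, optional evolution histories,
the serialized encoder state, trained members, metrics and attribution
tables, plus a structured log recording seeds and stage checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .attribution import attribute_ensemble, global_importance
from .dataio import RunConfig, write_dataset
from .datasets import GeneratorConfig, generate_dataset, write_ground_truth
from .encoding import EncoderState, SprayFeatureEncoder
from .evolve import evolve_hyperparameters
from .modeling import ModelSpec, make_ensemble, rmse, train_final
from .splitting import cluster_apis, split_by_api

log = logging.getLogger("spraydry")


def _substream(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def save_pipeline(outdir, state: EncoderState, members: dict, specs: dict) -> None:
    """Persist a trained pipeline: encoder state (flat text), members
    (joblib), and a manifest tying them together."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state.save(outdir / "encoder_state.txt")
    manifest = {"members": {}, "specs": {}}
    for name, model in members.items():
        fname = f"member_{name}.joblib"
        joblib.dump(model, outdir / fname)
        manifest["members"][name] = fname
    for name, spec in specs.items():
        manifest["specs"][name] = {"family": spec.family, "hyperparams": spec.hyperparams}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_pipeline(outdir) -> tuple[EncoderState, "EnsembleRegressor"]:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    state = EncoderState.load(outdir / "encoder_state.txt")
    members = [joblib.load(outdir / f) for f in manifest["members"].values()]
    return state, make_ensemble(members, encoder=state)


def run_pipeline(
    config: RunConfig,
    dataset: pd.DataFrame | None = None,
    generator: GeneratorConfig | None = None,
    outdir="artifacts",
) -> dict:
    """Run the full workflow; returns the metrics dict it also writes."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    try:
        return _run(config, dataset, generator, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _stage(name):
    log.info("stage=%s", name)


def _run(config, dataset, generator, outdir: Path) -> dict:
    if dataset is None:
        _stage("generate")
        generator = generator or GeneratorConfig(seed=_substream(config.seed, "generate"))
        dataset, truth = generate_dataset(generator)
        write_dataset(dataset, outdir / "dataset.csv")
        write_ground_truth(truth, outdir / "ground_truth.txt")
        log.info("generated dataset checksum=%s", _checksum(outdir / "dataset.csv"))

    _stage("split")
    split_seed = _substream(config.seed, "split")
    clusters = cluster_apis(dataset, config.n_clusters, seed=split_seed)
    split = split_by_api(clusters, config.test_fraction, seed=split_seed, dataset=dataset)
    split.to_frame().to_csv(outdir / "split_audit.csv", index=False)
    train = dataset.loc[split.train_rows]
    test = dataset.loc[split.test_rows]
    log.info(
        "split seed=%s train_apis=%d test_apis=%d checksum=%s",
        split_seed, len(split.train_apis), len(split.test_apis),
        _checksum(outdir / "split_audit.csv"),
    )

    _stage("encode")
    encoder = SprayFeatureEncoder(
        smoothing_k=config.smoothing_k,
        smoothing_f=config.smoothing_f,
        use_target_encoding=config.use_target_encoding,
        include_orifice_diameter=config.include_orifice_diameter,
    )
    encoder.fit(train)
    X_train = encoder.transform(train)
    X_test = encoder.transform(test)

    specs = {f: ModelSpec(f) for f in config.ensemble}
    if config.evolve_families:
        _stage("evolve")
        template = SprayFeatureEncoder(
            smoothing_k=config.smoothing_k,
            smoothing_f=config.smoothing_f,
            use_target_encoding=config.use_target_encoding,
            include_orifice_diameter=config.include_orifice_diameter,
        )
        for family in config.evolve_families:
            evo_seed = _substream(config.seed, f"evolve:{family}")
            spec, result = evolve_hyperparameters(
                family, train,
                population=config.population,
                tournament=config.tournament,
                iterations=config.iterations,
                seed=evo_seed,
                encoder=template,
            )
            specs[family] = spec
            pd.DataFrame(
                {"iteration": range(1, len(result.history) + 1),
                 "best_cv_rmse": result.history}
            ).to_csv(outdir / f"evolution_{family}.csv", index=False)
            log.info(
                "evolved family=%s seed=%s best_cv_rmse=%.4f evaluations=%d",
                family, evo_seed, result.best_fitness, result.evaluations,
            )

    _stage("train")
    train_seed = _substream(config.seed, "train")
    members = {
        name: train_final(spec, X_train, train["d50"], seed=train_seed)
        for name, spec in specs.items()
    }
    ensemble = make_ensemble(list(members.values()), encoder=encoder.state_)
    save_pipeline(outdir / "model", encoder.state_, members, specs)

    _stage("evaluate")
    metrics = {
        "train_rmse": rmse(ensemble.predict(X_train), train["d50"]),
        "test_rmse": rmse(ensemble.predict(X_test), test["d50"]),
        "test_d50_std": float(test["d50"].std(ddof=1)),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    log.info("metrics %s", metrics)

    _stage("explain")
    attr_seed = _substream(config.seed, "explain")
    rng = np.random.default_rng(attr_seed)
    sample = X_train.iloc[rng.choice(len(X_train), size=min(40, len(X_train)), replace=False)]
    attributions = [
        attribute_ensemble(ensemble, sample.iloc[i], X_train, seed=attr_seed)
        for i in range(len(sample))
    ]
    table = global_importance(attributions, sample)
    table.to_csv(outdir / "global_importance.csv")
    log.info("attribution sample=%d checksum=%s", len(sample),
             _checksum(outdir / "global_importance.csv"))
    return metrics
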