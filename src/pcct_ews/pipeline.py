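"""End-to-end orchestration: simulate -> label -> window -> train -> evaluate
-> explain, with content-hash provenance and up-to-date stage skipping."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import attribution, evaluation, labelling, models, preprocess, schema, simulate, windows


DEFAULT_CONFIG = {
    "seed": 0,
    "sim": {"n_episodes": 20},
    "bands": {},
    "window": {"input_hz": 0.2, "no_context": False},
    "train": {
        "arch": "combined_transformer_vector_reduced",
        "task": "respiratory",
        "hp": {"epochs": 2},
    },
    "evaluate": {"max_fpr": 0.20, "bootstrap_iterations": 200},
    "explain": {"steps": 50, "n_windows": 5},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base.get(k, {}), v) if isinstance(v, dict) else v
    return out


def _hash_bytes(b: bytes) -> str:
    return hashlib.sha256(b).hexdigest()[:16]


def _hash_path(path: Path) -> str:
    """Content hash of a file or directory tree."""
    if path.is_file():
        return _hash_bytes(path.read_bytes())
    parts = []
    for f in sorted(path.rglob("*")):
        if f.is_file():
            parts.append(f"{f.relative_to(path)}:{_hash_bytes(f.read_bytes())}")
    return _hash_bytes("\n".join(parts).encode())


def _hash_obj(obj) -> str:
    return _hash_bytes(json.dumps(obj, sort_keys=True, default=str).encode())


class Pipeline:
    """Runs the staged workflow under one output directory.

    Each stage records a hash of its configuration and inputs in
    ``manifest.json``; a stage re-runs only when that hash changes or its
    outputs are missing, so deleting an intermediate artifact re-runs exactly
    that stage and everything downstream.
    """

    STAGES = ("simulate", "label", "window", "train", "evaluate", "explain")

    def __init__(self, config: dict, out_dir: str | Path):
        self.config = _merge(DEFAULT_CONFIG, config or {})
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text())
            if self.manifest_path.exists()
            else {"stages": {}, "config": self.config}
        )
        self.log: list[str] = []

    # -- plumbing -----------------------------------------------------------

    def _stage_dir(self, name: str) -> Path:
        return self.out / name

    def _up_to_date(self, name: str, key: str) -> bool:
        rec = self.manifest["stages"].get(name)
        return (
            rec is not None
            and rec.get("key") == key
            and self._stage_dir(name).exists()
        )

    def _record(self, name: str, key: str, t0: float):
        self.manifest["stages"][name] = {
            "key": key,
            "output_hash": _hash_path(self._stage_dir(name)),
            "seconds": round(time.time() - t0, 3),
        }
        self.manifest["config"] = self.config
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))

    def _run_stage(self, name: str, key: str, fn) -> bool:
        if self._up_to_date(name, key):
            self.log.append(f"{name}: up to date, skipped")
            return False
        t0 = time.time()
        try:
            self._stage_dir(name).mkdir(parents=True, exist_ok=True)
            fn()
        except Exception as exc:
            raise RuntimeError(
                f"stage {name!r} failed (artifacts under {self._stage_dir(name)}): {exc}"
            ) from exc
        self._record(name, key, t0)
        self.log.append(f"{name}: ran")
        return True

    # -- stages ---------------------------------------------------------------

    def run(self) -> dict:
        """Execute all stages in order; returns the manifest."""
        cfg = self.config
        seed = cfg["seed"]

        sim_key = _hash_obj({"sim": cfg["sim"], "seed": seed})
        self._run_stage("simulate", sim_key, self._simulate)

        label_key = _hash_obj(
            {"bands": cfg["bands"], "in": self.manifest["stages"]["simulate"]["output_hash"]}
        )
        self._run_stage("label", label_key, self._label)

        window_key = _hash_obj(
            {
                "window": cfg["window"],
                "seed": seed,
                "in": self.manifest["stages"]["label"]["output_hash"],
            }
        )
        self._run_stage("window", window_key, self._window)

        train_key = _hash_obj(
            {
                "train": cfg["train"],
                "seed": seed,
                "in": self.manifest["stages"]["window"]["output_hash"],
            }
        )
        self._run_stage("train", train_key, self._train)

        eval_key = _hash_obj(
            {
                "evaluate": cfg["evaluate"],
                "in": self.manifest["stages"]["train"]["output_hash"],
            }
        )
        self._run_stage("evaluate", eval_key, self._evaluate)

        explain_key = _hash_obj(
            {
                "explain": cfg["explain"],
                "in": self.manifest["stages"]["train"]["output_hash"],
            }
        )
        self._run_stage("explain", explain_key, self._explain)
        return self.manifest

    def _simulate(self):
        cfg = simulate.SimulationConfig(seed=self.config["seed"], **self.config["sim"])
        episodes, _ = simulate.generate_cohort(cfg)
        d = self._stage_dir("simulate")
        for ep in episodes:
            schema.write_episode(ep, d)
        schema.write_cohort_manifest(
            d / "cohort.json", [ep.episode_id for ep in episodes]
        )

    def _episodes(self) -> list[schema.Episode]:
        d = self._stage_dir("simulate")
        ids = schema.read_cohort_manifest(d / "cohort.json")["episodes"]
        return [schema.read_episode(d / i) for i in ids]

    def _label(self):
        params = labelling.BandParams(**self.config["bands"])
        d = self._stage_dir("label")
        for ep in self._episodes():
            ep.series = preprocess.clean_vitals(ep.series)
            detected = labelling.label_episode(ep, params)
            doc = {
                k: [e.to_dict() for e in v] for k, v in detected.items()
            }
            (d / f"{ep.episode_id}.json").write_text(json.dumps(doc, indent=1))

    def _load_events(self, episode_id: str) -> list[schema.EventInterval]:
        doc = json.loads(
            (self._stage_dir("label") / f"{episode_id}.json").read_text()
        )
        return [schema.EventInterval(**e) for kind in doc.values() for e in kind]

    def _window(self):
        wcfg = self.config["window"]
        episodes = self._episodes()
        provider = preprocess.HashingEmbeddingProvider()
        all_samples: list[windows.WindowSample] = []
        for ep in episodes:
            ep.events += self._load_events(ep.episode_id)
            base = preprocess.encode_baseline(ep.meta, "reduced")
            dx = provider.embed(ep.meta.diagnosis_text)
            all_samples.extend(
                windows.make_windows(
                    ep, base, dx,
                    input_hz=wcfg.get("input_hz", 1.0),
                    no_context=wcfg.get("no_context", False),
                )
            )
        split = windows.stratify_and_split(episodes, seed=self.config["seed"])
        d = self._stage_dir("window")
        data = windows.stack_samples(all_samples)
        split_of = np.array([split.assignment[e] for e in data["episode_id"]])
        np.savez_compressed(d / "windows.npz", **data, split=split_of)
        (d / "split.json").write_text(json.dumps(split.assignment, indent=1))

    def _load_windows(self) -> dict:
        z = np.load(self._stage_dir("window") / "windows.npz", allow_pickle=False)
        return {k: z[k] for k in z.files}

    def _subset(self, data: dict, split: str) -> dict:
        m = data["split"] == split
        return {k: v[m] for k, v in data.items()}

    def _train(self):
        tcfg = self.config["train"]
        data = self._load_windows()
        tr = self._subset(data, "train")
        tu = self._subset(data, "tune")
        hp = models.HyperParams(seed=self.config["seed"], **tcfg.get("hp", {}))
        dims = models.FeatureDims(baseline=tr["baseline"].shape[1])
        model = models.build_model(tcfg["arch"], hp, dims)
        models.train(model, tr, tu, tcfg["task"])
        d = self._stage_dir("train")
        np.savez_compressed(d / "model.npz", **model.state_dict())
        (d / "model.json").write_text(
            json.dumps(
                {
                    "arch": tcfg["arch"],
                    "task": tcfg["task"],
                    "hp": asdict(hp),
                    "baseline_dim": dims.baseline,
                    "parameter_count": models.count_parameters(model),
                },
                indent=1,
            )
        )
        with open(d / "history.csv", "w") as f:
            f.write("epoch,loss,tune_auroc\n")
            for h in model.history:
                f.write(f"{h['epoch']},{h['loss']},{h['tune_auroc']}\n")

    def load_model(self) -> models.Model:
        d = self._stage_dir("train")
        doc = json.loads((d / "model.json").read_text())
        hp = models.HyperParams(**doc["hp"])
        model = models.build_model(
            doc["arch"], hp, models.FeatureDims(baseline=doc["baseline_dim"])
        )
        z = np.load(d / "model.npz")
        model.load_state_dict({k: z[k] for k in z.files})
        return model

    def _evaluate(self):
        ecfg = self.config["evaluate"]
        task = self.config["train"]["task"]
        data = self._load_windows()
        model = self.load_model()
        tune = self._subset(data, "tune")
        test = self._subset(data, "test")
        thr = evaluation.select_threshold(
            model.predict(tune), tune[f"y_{task}"], ecfg["max_fpr"]
        )
        report = evaluation.evaluate(
            model.predict(test), test[f"y_{task}"], thr,
            iterations=ecfg["bootstrap_iterations"], seed=self.config["seed"],
        )
        (self._stage_dir("evaluate") / "report.json").write_text(
            json.dumps(report.as_dict(), indent=1)
        )

    def _explain(self):
        xcfg = self.config["explain"]
        data = self._load_windows()
        test = self._subset(data, "test")
        model = self.load_model()
        n = min(xcfg["n_windows"], len(test["fine"]))
        results = []
        for i in range(n):
            w = {k: test[k][i] for k in ("fine", "context", "baseline", "dx")}
            results.append(
                attribution.integrated_gradients(model, w, steps=xcfg["steps"])
            )
        preds = model.predict({k: test[k][:n] for k in test}) >= 0.5
        grouping = attribution.default_grouping(test["baseline"].shape[1])
        imp = attribution.aggregate_cohort(results, grouping, preds)
        d = self._stage_dir("explain")
        with open(d / "group_importance.csv", "w") as f:
            f.write("group,overall,predicted_positive,predicted_negative\n")
            for g in imp.overall:
                f.write(
                    f"{g},{imp.overall[g]},{imp.predicted_positive[g]},"
                    f"{imp.predicted_negative[g]}\n"
                )


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the staged workflow; returns the run manifest."""
    return Pipeline(config, out_dir).run()


def benchmark_inference(model: models.Model, n_windows: int = 20,
                        seq_len: int = 180, baseline_dim: int = 43) -> dict:
    """Per-window inference latency on local hardware (reported, never
    asserted: no pass/fail)."""
    rng = np.random.default_rng(0)
    lat = []
    for _ in range(n_windows):
        batch = {
            "fine": rng.normal(size=(1, seq_len, 36)),
            "context": rng.normal(size=(1, 24, 21)),
            "baseline": rng.normal(size=(1, baseline_dim)),
            "dx": rng.normal(size=(1, 768)),
        }
        t0 = time.perf_counter()
        model.forward(batch)
        lat.append((time.perf_counter() - t0) * 1000)
    lat = np.array(lat)
    return {
        "n": n_windows,
        "median_ms": float(np.median(lat)),
        "p90_ms": float(np.percentile(lat, 90)),
        "mean_ms": float(lat.mean()),
        "latencies_ms": lat.tolist(),
    }
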