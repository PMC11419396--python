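"""Reproducible experiment runner.

An :class:`ExperimentConfig` (YAML-serializable) ties together stimulus
generation, training, simulation and analysis.  Named presets reproduce the
package's standard experiments end to end; every output directory gets a
manifest recording parameters, the config hash and output file hashes, and
rerunning an identical config reproduces byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, stimuli
from .dynamic_network import NetworkSimConfig, run_bottleneck, simulate_network, sweep_phase_delay
from .static_network import TrainConfig, evaluate, forward_static, train_network
from .unit_dynamics import InhibitionParams, NodeParams, Z_GRID_DEFAULT, parameter_sweep

_SCHEMA = {
    "name",
    "seed",
    "stimulus",
    "train",
    "dynamics",
    "analysis",
    "out_dir",
}


@dataclass
class ExperimentConfig:
    name: str = "experiment"
    seed: int = 0
    stimulus: dict = field(default_factory=dict)   # e.g. {"attended": "A", "others": ["E"]}
    train: dict = field(default_factory=dict)      # TrainConfig overrides
    dynamics: dict = field(default_factory=dict)   # m, f, duration, delays_ms, ...
    analysis: dict = field(default_factory=dict)   # threshold, transient
    out_dir: str = "runs"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        bad = set(data) - _SCHEMA
        if bad:
            raise ValueError(
                f"unknown config keys {sorted(bad)}; valid keys are {sorted(_SCHEMA)}"
            )
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(out: Path, config: ExperimentConfig, files: list[Path]) -> Path:
    manifest = {
        "name": config.name,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "outputs": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest()[:16] for f in files
        },
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _trained_weights(config: ExperimentConfig):
    ds = stimuli.build_training_set(config.seed)
    tc = TrainConfig(seed=config.seed, **config.train)
    weights, trace = train_network(ds, tc)
    return ds, weights, trace


def _inh(config: ExperimentConfig, default_m=0.5, default_f=10.0) -> InhibitionParams:
    d = config.dynamics
    return InhibitionParams(m=d.get("m", default_m), f=d.get("f", default_f))


def _sim_config(config: ExperimentConfig, **overrides) -> NetworkSimConfig:
    inh = _inh(config)
    kwargs = dict(
        inh_layer1=inh,
        inh_layer2=inh,
        duration=config.dynamics.get("duration", 1.0),
    )
    kwargs.update(overrides)
    return NetworkSimConfig(**kwargs)


def _save(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def _competition_image(config: ExperimentConfig, attended="A", others=("E",)):
    s = config.stimulus
    return stimuli.build_competition_image(
        s.get("attended", attended),
        list(s.get("others", others)),
        noise_sd=s.get("noise_sd", 0.10),
        seed=config.seed,
    )


# ---------------------------------------------------------------- presets


def _preset_train(config: ExperimentConfig, out: Path) -> list[Path]:
    ds, weights, trace = _trained_weights(config)
    rows = []
    for epoch, loss in enumerate(trace, start=1):
        rows.append({"epoch": epoch, "mean_loss": loss})
    acc, final_loss = evaluate(weights, ds)
    test = stimuli.build_training_set(config.seed + 10_000)
    test_acc, test_loss = evaluate(weights, test)
    files = [_save(pd.DataFrame(rows), out / "loss_trace.csv")]
    summary = pd.DataFrame(
        [
            {
                "train_accuracy": acc,
                "train_loss": final_loss,
                "test_accuracy": test_acc,
                "test_loss": test_loss,
            }
        ]
    )
    files.append(_save(summary, out / "train_summary.csv"))
    np.savez(out / "weights.npz", kernels1=weights.kernels1, W2=weights.W2, W3=weights.W3)
    files.append(out / "weights.npz")
    return files


def _preset_sweep(config: ExperimentConfig, out: Path) -> list[Path]:
    z_grid = config.dynamics.get("z_grid", list(Z_GRID_DEFAULT))
    c_grid = config.dynamics.get("c_grid", list(np.arange(2.0, 16.0, 1.0)))
    s_grid = config.dynamics.get("s_grid", [0.1])
    files = []
    for label, inh in (
        ("free", InhibitionParams(m=0.0)),
        ("inhibited", _inh(config)),
    ):
        df = parameter_sweep(c_grid, s_grid, z_grid, inh)
        files.append(_save(df, out / f"sweep_{label}.csv"))
    return files


def _preset_stability(config: ExperimentConfig, out: Path) -> list[Path]:
    _, weights, _ = _trained_weights(config)
    img = stimuli.make_image(
        [stimuli.Placement(config.stimulus.get("letter", "A"), 0)],
        config.stimulus.get("noise_sd", 0.10),
        config.seed,
    )
    files = []
    for label, m in (("free", 0.0), ("inhibited", config.dynamics.get("m", 0.5))):
        inh = InhibitionParams(m=m, f=config.dynamics.get("f", 10.0))
        res = simulate_network(
            img, weights, _sim_config(config, inh_layer1=inh, inh_layer2=inh)
        )
        files.append(_save(res.to_frame(), out / f"run_{label}.csv"))
    return files


def _preset_bottleneck(config: ExperimentConfig, out: Path) -> list[Path]:
    _, weights, _ = _trained_weights(config)
    files = []
    pairs = [("A", "E"), ("E", "T"), ("A", "T")]
    rows = []
    for first, second in pairs:
        img = stimuli.make_image(
            [stimuli.Placement(first, 0), stimuli.Placement(second, 1)],
            config.stimulus.get("noise_sd", 0.10),
            config.seed,
        )
        res = run_bottleneck(img, weights, config.dynamics.get("duration", 1.0))
        files.append(_save(res.to_frame(), out / f"bottleneck_{first}{second}.csv"))
        steady = dict(zip(["p_A", "p_E", "p_T"], res.probs[-1]))
        rows.append({"pair": first + second, **steady})
    files.append(_save(pd.DataFrame(rows), out / "bottleneck_steady.csv"))
    return files


def _temporal_code_run(config: ExperimentConfig, out: Path, pairs, **dyn) -> list[Path]:
    _, weights, _ = _trained_weights(config)
    threshold = config.analysis.get("threshold", analysis.EVENT_THRESHOLD)
    files, rows = [], []
    for attended, *others in pairs:
        img = stimuli.build_competition_image(
            attended, list(others), noise_sd=config.stimulus.get("noise_sd", 0.10),
            seed=config.seed,
        )
        sim_cfg = _sim_config(config, **dyn)
        res = simulate_network(img, weights, sim_cfg)
        tag = attended + "".join(others)
        files.append(_save(res.to_frame(), out / f"run_{tag}.csv"))
        code = analysis.detect_events(res.probs, res.dt, sim_cfg.inh_layer2, threshold)
        files.append(_save(code.to_frame(), out / f"events_{tag}.csv"))
        row = {"pair": tag, "items_per_cycle": json.dumps(analysis.items_per_cycle(code))}
        for letter in stimuli.LETTERS:
            row[f"readout_{letter}"] = analysis.readout_accuracy(
                res.probs, letter, config.analysis.get("transient", 0.1), res.dt
            )
        rows.append(row)
    files.append(_save(pd.DataFrame(rows), out / "metrics.csv"))
    return files


def _preset_temporal_code(config: ExperimentConfig, out: Path) -> list[Path]:
    return _temporal_code_run(config, out, [("A", "E"), ("E", "T"), ("A", "T")])


def _preset_similarity(config: ExperimentConfig, out: Path) -> list[Path]:
    _, weights, _ = _trained_weights(config)
    attended = config.stimulus.get("attended", "E")
    others = config.stimulus.get("others", ["T"])
    img = stimuli.build_competition_image(
        attended, list(others), noise_sd=config.stimulus.get("noise_sd", 0.10),
        seed=config.seed,
    )
    res = simulate_network(img, weights, _sim_config(config))
    files = []
    for layer, h_t in ((1, res.h1), (2, res.h2)):
        cols = {"t": res.t}
        for letter in stimuli.LETTERS:
            ref_img = stimuli.make_image([stimuli.Placement(letter, 0)], 0.0, 0)
            rec = forward_static(ref_img, weights)
            ref = rec.h1 if layer == 1 else rec.h2
            cols[f"s_{letter}"] = analysis.similarity_trace(h_t, ref, letter).values
        files.append(_save(pd.DataFrame(cols), out / f"similarity_layer{layer}.csv"))
    return files


def _preset_phase_delay(config: ExperimentConfig, out: Path) -> list[Path]:
    _, weights, _ = _trained_weights(config)
    img = _competition_image(config)
    delays_ms = config.dynamics.get("delays_ms", [0.0, 16.4, 32.7, 49.1, 57.3, 65.5, 81.8])
    layer = config.dynamics.get("layer", 2)
    sim_cfg = _sim_config(config)
    results = sweep_phase_delay(img, weights, sim_cfg, layer, [d / 1000 for d in delays_ms])
    files, rows = [], []
    for d, res in zip(delays_ms, results):
        inh = sim_cfg.inh_layer2 if layer == 2 else sim_cfg.inh_layer1
        code = analysis.detect_events(res.probs, res.dt, sim_cfg.inh_layer1)
        rows.append(
            {
                "delay_ms": d,
                "layer": layer,
                "n_events": len(code.events),
                "items_per_cycle": json.dumps(analysis.items_per_cycle(code)),
            }
        )
        files.append(_save(res.to_frame(), out / f"delay_{d:05.1f}ms.csv"))
    files.append(_save(pd.DataFrame(rows), out / "phase_delay_metrics.csv"))
    return files


def _preset_fast_refraction(config: ExperimentConfig, out: Path) -> list[Path]:
    params = NodeParams(tau_r=0.05)
    return _temporal_code_run(config, out, [("A", "E")], params=params)


def _preset_slow_inhibition(config: ExperimentConfig, out: Path) -> list[Path]:
    inh = InhibitionParams(m=config.dynamics.get("m", 0.5), f=5.0)
    return _temporal_code_run(
        config, out, [("A", "E")], inh_layer1=inh, inh_layer2=inh,
        duration=config.dynamics.get("duration", 2.0),
    )


def _preset_three_letters(config: ExperimentConfig, out: Path) -> list[Path]:
    files = _temporal_code_run(config, out, [("E", "T", "A")])
    inh6 = InhibitionParams(m=config.dynamics.get("m", 0.5), f=6.0)
    sub = out / "inhibition_6hz"
    sub.mkdir(exist_ok=True)
    files += _temporal_code_run(
        config, sub, [("E", "T", "A")], inh_layer1=inh6, inh_layer2=inh6,
        duration=config.dynamics.get("duration", 2.0),
    )
    return files


PRESETS = {
    "fig2-train": _preset_train,
    "fig3-sweep": _preset_sweep,
    "fig4-stability": _preset_stability,
    "fig5-bottleneck": _preset_bottleneck,
    "fig6-temporal-code": _preset_temporal_code,
    "fig7-similarity": _preset_similarity,
    "fig8-phase-delay": _preset_phase_delay,
    "s2-fast-refraction": _preset_fast_refraction,
    "s3-slow-inhibition": _preset_slow_inhibition,
    "s4-three-letters": _preset_three_letters,
}


def run_experiment(config: ExperimentConfig) -> Path:
    """Run a named preset; returns the path of the manifest written.

    The preset name is ``config.name``; outputs land in
    ``out_dir/name-confighash/``.
    """
    if config.name not in PRESETS:
        raise ValueError(
            f"unknown experiment {config.name!r}; presets: {sorted(PRESETS)}"
        )
    out = Path(config.out_dir) / f"{config.name}-{config.config_hash()}"
    out.mkdir(parents=True, exist_ok=True)
    files = PRESETS[config.name](config, out)
    return _write_manifest(out, config, [f for f in files if f.suffix == ".csv"])
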