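"""Orchestration: simulate -> gate -> estimate -> fit -> report, reproducibly.

A run is driven by a single config (YAML or constructed in code) with one
global seed; per-stage seeds are derived from it with a fixed key-derivation
rule (`numpy.random.SeedSequence(global_seed).spawn` in a documented, fixed
order), so re-running the same config reproduces every stochastic artifact
bit-exactly.  Each stage writes delimited-text/JSON artifacts and the run
ends with a manifest recording parameters, seeds, warnings and artifact
hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biosensor_stats import detection_ladder
from .cytometry import derive_gate_from_control, estimate_fluorescent_fraction
from .rate_inference import (ensemble_summary, fit_exponential,
                             fit_logistic_mcmc, select_model)
from .synthetic_data import (CytometryModel, DoseModel, SimulationConfig,
                             SwitchingTrajectory, simulate_stochastic_switching,
                             synthesize_cytometry_events)

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "SCENARIOS"]

SCENARIOS = ("cumate_dose_response", "arsenite_endpoint", "anoxic_memory",
             "stability_passaging")


@dataclass
class RunConfig:
    """Experiment layout plus module parameter blocks for one pipeline run."""

    concentrations: list = field(default_factory=lambda: [0.0, 1e-6, 5e-6, 1e-5])
    n_biological: int = 3
    n_technical: int = 3
    t_grid: list = field(default_factory=lambda: [float(t) for t in
                                                  np.linspace(0.0, 8.0, 7)])
    n_cells: int = 20_000
    n_events_per_sample: int = 20_000
    f0_true: float = 1e-3
    fmax_true: float = 0.9
    dose: dict = field(default_factory=dict)        # DoseModel kwargs
    cytometry: dict = field(default_factory=dict)   # CytometryModel kwargs
    gate_quantile: float = 0.999
    mcmc_steps: int = 1000
    mcmc_burn: int = 250
    seed: int = 0
    outdir: str = "results/run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = json.loads(json.dumps(asdict(self), default=float))
        Path(path).write_text(yaml.safe_dump(payload))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _spawn_seeds(global_seed: int, n: int) -> list[int]:
    """Fixed key-derivation rule: SeedSequence(global_seed).spawn in order."""
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(global_seed).spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return the run manifest.

    Stage order: simulate trajectories per (concentration, biological,
    technical) cell; synthesize and gate cytometry events; estimate gated
    fractions; fit and select rate models; summarize the dose-response and
    run the detection ladder on endpoint fractions.  A stage failure halts
    the run with the stage named; artifacts already written are retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    dose = DoseModel(**config.dose)
    cyto = CytometryModel(**config.cytometry)
    t_grid = np.asarray(config.t_grid, dtype=float)
    warnings_log: list[str] = []
    artifacts: dict[str, str] = {}

    seeds = _spawn_seeds(config.seed, 4)
    stage_seeds = dict(zip(("simulate", "events", "gate", "fit"), seeds))

    stage = "simulate"
    try:
        truth = {"k_by_concentration": {str(c): float(dose.rate(c))
                                        for c in config.concentrations}}
        sim_root = np.random.SeedSequence(stage_seeds["simulate"])
        trajectories = {}
        for c in config.concentrations:
            k_c = float(dose.rate(c))
            for b in range(config.n_biological):
                for r in range(config.n_technical):
                    s = int(sim_root.spawn(1)[0].generate_state(1)[0] % (2**31))
                    cfg = SimulationConfig(
                        n_cells=config.n_cells, f0_true=config.f0_true,
                        k_true=k_c, fmax_true=config.fmax_true,
                        mechanism="logistic_mean", t_grid=t_grid, rng_seed=s)
                    traj = simulate_stochastic_switching(cfg)
                    trajectories[(c, b, r)] = traj

        stage = "events+gate+estimate"
        ev_root = np.random.SeedSequence(stage_seeds["events"])
        gate_rng = np.random.default_rng(stage_seeds["gate"])
        control = synthesize_cytometry_events(0.0, 50_000, cyto, seed=gate_rng,
                                              sample_id="control")
        gate = derive_gate_from_control(control, q=config.gate_quantile)
        gate_path = out / "gate.json"
        gate.to_json(gate_path)
        artifacts["gate"] = str(gate_path)

        rows = []
        for (c, b, r), traj in trajectories.items():
            rng = np.random.default_rng(ev_root.spawn(1)[0])
            for i, t in enumerate(traj.times):
                events = synthesize_cytometry_events(
                    traj.fractions[i], config.n_events_per_sample, cyto,
                    seed=rng, sample_id=f"c{c}-b{b}-r{r}-t{t}")
                est = estimate_fluorescent_fraction(events, gate)
                if est.smoothed:
                    warnings_log.append(
                        f"boundary count smoothed for sample {est.sample_id}")
                rows.append({"concentration": c, "biological": b,
                             "technical": r, "time_h": t, "x": est.x,
                             "n": est.n, "fraction": est.p_hat})
        frac_table = pd.DataFrame(rows)
        frac_path = out / "gated_fractions.csv"
        frac_table.to_csv(frac_path, index=False)
        artifacts["gated_fractions"] = str(frac_path)

        stage = "fit"
        fit_root = np.random.SeedSequence(stage_seeds["fit"])
        dose_rows = []
        fit_records = []
        for c in config.concentrations:
            for b in range(config.n_biological):
                selected = []
                for r in range(config.n_technical):
                    sub = frac_table[(frac_table.concentration == c)
                                     & (frac_table.biological == b)
                                     & (frac_table.technical == r)].sort_values("time_h")
                    traj = SwitchingTrajectory(
                        times=sub["time_h"].to_numpy(),
                        fractions=(sub["x"] / sub["n"]).to_numpy(),
                        counts=(sub["x"].to_numpy(), sub["n"].to_numpy()),
                        replicate_id=f"c{c}-b{b}-r{r}", treatment=c)
                    exp_fit = fit_exponential(traj)
                    log_fit = None
                    if c > 0:
                        s = int(fit_root.spawn(1)[0].generate_state(1)[0] % (2**31))
                        log_fit = fit_logistic_mcmc(
                            traj, seed=s, n_steps=config.mcmc_steps,
                            n_burn=config.mcmc_burn)
                        if not log_fit.identifiable:
                            warnings_log.append(
                                f"non-identifiable logistic fit at c={c}, "
                                f"bio={b}, tech={r}")
                    sel = select_model(exp_fit, log_fit, concentration=c)
                    selected.append(sel)
                    fit_records.append({
                        "concentration": c, "biological": b, "technical": r,
                        "model": sel.model, "k": sel.k, "aicc": sel.aicc,
                        "max_loglik": sel.max_loglik,
                        "identifiable": sel.identifiable})
                ens = ensemble_summary(selected, t_grid)
                dose_rows.append({"concentration": c, "biological": b,
                                  "k_min": ens.k_min, "k_mean": ens.k_mean,
                                  "k_max": ens.k_max})
        fits_path = out / "fit_results.csv"
        pd.DataFrame(fit_records).to_csv(fits_path, index=False)
        artifacts["fit_results"] = str(fits_path)

        dose_df = (pd.DataFrame(dose_rows)
                   .groupby("concentration", as_index=False)
                   .agg(k_min=("k_min", "min"), k_mean=("k_mean", "mean"),
                        k_max=("k_max", "max")))
        dose_path = out / "dose_response.csv"
        dose_df.to_csv(dose_path, index=False)
        artifacts["dose_response"] = str(dose_path)

        stage = "report"
        t_end = t_grid[-1]
        endpoint = frac_table[frac_table.time_h == t_end]
        readouts = endpoint.rename(columns={"biological": "experiment",
                                            "fraction": "value"})
        ladder = detection_ladder(readouts[["experiment", "concentration",
                                            "value"]], alpha=0.05)
        ladder_path = out / "detection_ladder.csv"
        ladder.steps.to_csv(ladder_path, index=False)
        artifacts["detection_ladder"] = str(ladder_path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the stage named
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "config": asdict(config),
        "stage_seeds": stage_seeds,
        "ground_truth": truth,
        "lowest_detected_concentration": ladder.lowest_detected,
        "warnings": warnings_log,
        "artifacts": {k: {"path": v, "sha256": _sha256(Path(v))}
                      for k, v in artifacts.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def make_fixtures(scenario: str, seed: int, outdir: str | Path) -> dict:
    """Write synthetic inputs + ground-truth sidecars for a study scenario.

    cumate_dose_response — 7 time points x 4 concentrations of gated-fraction
    trajectories with Hill-map ground-truth rates; arsenite_endpoint —
    endpoint fraction readouts for 3 experiments x 3 technical replicates on
    a 0/15/30/60 nM ladder; anoxic_memory — exposure trajectory plus a
    post-transfer maturation shift (the immature dim subpopulation decaying
    over 0/6/24 h oxic readouts); stability_passaging — 4 serial-passage
    cycles of 1e4-fold dilution with a configurable selection coefficient
    against recombined cells.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario '{scenario}'; options: {SCENARIOS}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth: dict = {"scenario": scenario, "seed": seed}

    if scenario == "cumate_dose_response":
        concentrations = [0.0, 1e-6, 5e-6, 1e-5]
        dose = DoseModel(k_max=1.5, K_half=3e-6, hill_n=2.0, k_leak=0.0)
        t_grid = np.linspace(0.0, 8.0, 7)
        rows = []
        for c in concentrations:
            k_c = float(dose.rate(c))
            for r in range(3):
                cfg = SimulationConfig(n_cells=20_000, f0_true=1e-3, k_true=k_c,
                                       fmax_true=0.9, t_grid=t_grid,
                                       rng_seed=int(rng.integers(2**31)))
                traj = simulate_stochastic_switching(cfg)
                x, n = traj.counts
                for i, t in enumerate(t_grid):
                    rows.append({"concentration": c, "replicate": r,
                                 "time_h": t, "x": int(x[i]), "n": int(n[i])})
        pd.DataFrame(rows).to_csv(out / "trajectories.csv", index=False)
        truth["k_by_concentration"] = {str(c): float(dose.rate(c))
                                       for c in concentrations}

    elif scenario == "arsenite_endpoint":
        concentrations = [0.0, 15e-9, 30e-9, 60e-9]
        # endpoint added fractions rising with concentration; baseline ~0.1%
        effect = {0.0: 0.0011, 15e-9: 0.0017, 30e-9: 0.0035, 60e-9: 0.0066}
        rows = []
        n_events = 150_000
        for b in range(3):
            baseline = 0.001 * (1 + 0.2 * rng.standard_normal())
            for c in concentrations:
                for r in range(3):
                    f = max(baseline + effect[c] * (1 + 0.1 * rng.standard_normal()),
                            1e-5)
                    x = rng.binomial(n_events, f)
                    rows.append({"experiment": f"E{b + 1}", "concentration": c,
                                 "replicate": r, "x": int(x), "n": n_events,
                                 "value": x / n_events})
        pd.DataFrame(rows).to_csv(out / "endpoint_fractions.csv", index=False)
        truth["added_fraction_by_concentration"] = {str(c): v
                                                    for c, v in effect.items()}

    elif scenario == "anoxic_memory":
        # exposure-phase switching then oxic readouts at 0/6/24 h while the
        # immature (dim) recombined subpopulation matures
        cfg = SimulationConfig(n_cells=50_000, f0_true=2e-3, k_true=0.01,
                               fmax_true=0.9,
                               t_grid=np.array([0.0, 20.0, 40.0, 61.0]),
                               rng_seed=int(rng.integers(2**31)))
        traj = simulate_stochastic_switching(cfg)
        final_fraction = float(traj.fractions[-1])
        immature_by_readout = {0.0: 0.3, 6.0: 0.05, 24.0: 0.01}
        for t_readout, iota in immature_by_readout.items():
            model = CytometryModel(immature_fraction=iota)
            events = synthesize_cytometry_events(
                final_fraction, 20_000, model,
                seed=int(rng.integers(2**31)),
                sample_id=f"oxic_{t_readout:g}h")
            events.to_csv(out / f"events_oxic_{t_readout:g}h.csv")
        x, n = traj.counts
        pd.DataFrame({"time_h": traj.times, "x": x, "n": n}).to_csv(
            out / "exposure_trajectory.csv", index=False)
        truth["final_recombined_fraction"] = final_fraction
        truth["immature_fraction_by_readout_h"] = immature_by_readout

    else:  # stability_passaging
        selection = 0.02  # per-generation disadvantage of recombined cells
        dilution = 1e4
        gens_per_cycle = float(np.log2(dilution))
        f = 0.4
        rows = [{"cycle": 0, "generations": 0.0, "fraction": f,
                 "x": int(f * 200_000), "n": 200_000}]
        total_g = 0.0
        for cycle in range(1, 5):
            for _ in range(int(round(gens_per_cycle))):
                f = f * (1 - selection) / (1 - selection * f)
            total_g += gens_per_cycle
            n = 200_000
            x = int(rng.binomial(n, f))
            rows.append({"cycle": cycle, "generations": total_g,
                         "fraction": x / n, "x": x, "n": n})
        pd.DataFrame(rows).to_csv(out / "passaging_fractions.csv", index=False)
        truth.update({"selection_coefficient": selection,
                      "dilution_factor": dilution,
                      "generations_per_cycle": gens_per_cycle})

    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return truth
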