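# hystnet

Simulation and analysis of **workload-transition (hysteresis) effects** in
multitasking, at two coupled levels:

* **brain networks** — directed ("effective") connectivity between cortical
  sources inferred from multichannel EEG-like time series, and
* **behavior** — reaction times and tracking error of a cognitive agent
  performing a flight-deck-style multitasking battery under a
  Low → High → Low demand schedule.

A hysteresis effect is the carryover of a *previous* demand level into the
current one: after a high-demand block, operators respond faster and report
lower workload in a low-demand block than they did in an identical block
before it, and the directed brain network reorganizes (prefrontal cortex
becomes the dominant causal source). `hystnet` makes this phenomenon fully
simulable: a ground-truth generator produces source-level EEG from *known*
condition-dependent directed networks, so every stage of the inference
pipeline can be scored by parameter and structure recovery rather than by
eyeballing, and an ACT-R-style agent reproduces (or, with one switch,
abolishes) the behavioral hysteresis.

It is written for computational/cognitive-neuroscience researchers and
methodologists who need a transparent, fully seeded testbed for
frequency-domain Granger-causality pipelines and workload-transition
modeling.

## What is inside

**Ground truth and environments**

* `networks` / `synth` — six cortical nodes (visual cortex VC, dorsal and
  ventral anterior cingulate dACC/vACC, dorsal posterior cingulate dPCC,
  prefrontal cortex PFC, parietal cortex PC, with their Brodmann areas and
  cognitive-architecture module assignments). Condition-dependent directed
  networks are realized as stable MVAR processes — each node an AR(2)
  resonator with a 7–30 Hz spectral peak, each edge a nonzero off-diagonal
  coefficient — and simulated at 128 Hz in the fixed L1 → H2 → L3 order.
* `matb` — Poisson event schedules for the four multitasking subtasks
  (system monitoring, communications, tracking, resource management), with
  per-minute rates drawn from published low/high ranges.

**Inference pipeline**

Given `k` channels, the order-`p` multivariate autoregressive model is

    X(t) = Σₙ A(n) X(t−n) + E(t),  n = 1..p

* `mvar` — ensemble normalization across trials, windowed fits (350 ms
  windows, 30-sample steps) via a multichannel lattice with geometric-mean
  (Vieira–Morf) reflection-coefficient normalization (plain least squares is
  kept as an independent cross-check), and Hannan–Quinn order selection over
  1–40.
* `validation` — residual whiteness (autocorrelation band test and the
  Li–McLeod Portmanteau statistic), the stability index
  (log largest companion-matrix eigenvalue modulus, negative for stationary
  models), and percent consistency (> 85% of the data's correlation
  structure must be reproduced by data regenerated from the fitted model).
* `connectivity` — from the transfer matrix
  `H(f) = [I − Σₙ A(n) e^{−i2πfn/fs}]⁻¹`: the directed transfer function
  (DTF), partial coherence from the inverse spectral matrix, and their
  product, the **direct DTF (dDTF)** — direct, directed, frequency-specific
  information flow over 2–32 Hz — with per-frequency 97.5th-percentile edge
  thresholding.
* `metrics` — per-node outflow/inflow, the asymmetry ratio
  `(out − in)/(out + in)` (+1 pure causal source, −1 pure causal sink), hub
  identification, per-edge connectivity magnitude, and the L3-vs-L1
  hysteresis contrast.

**Cognitive agent**

* `actr` — a discrete-event agent built on the ACT-R sub-symbolic equations:
  base-level learning `B(t) = ln Σₖ (t−tₖ)^−d`, activation
  `A = B + Σⱼ WⱼSⱼ + ε`, retrieval probability `1/(1+e^{(τ−A)/s})` and
  retrieval latency `F e^{−A}`, under the architectural constraints of a
  50 ms production cycle and a single-chunk (serialized) declarative buffer.
  The `carryover` switch controls whether presentation histories persist
  across demand blocks — the mechanism that carries practice from the
  high-demand block into the final low-demand block.
* `pipeline` / `cli` — end-to-end orchestration with YAML configs, seeded
  reproducibility, and a `hystnet` command-line entry point.

## Worked example

Recover each condition's network from synthetic data and quantify the
transition:

```python
import hystnet as hn
from hystnet.metrics import compute_report, condition_contrast

reports = {}
for cond in ["L1", "H2", "L3"]:
    net = hn.make_ground_truth_network(cond)          # known directed graph
    model = hn.network_to_mvar(net)                   # stable MVAR realization
    eeg = hn.simulate_source_eeg(model, 120.0, fs=128.0, n_trials=8, seed=7)
    fit = hn.fit_window(hn.ensemble_normalize(eeg), p=16)
    print(f"{cond}: stability {hn.stability_index(fit):+.3f}, "
          f"consistency {hn.percent_consistency(eeg.data, fit, seed=7):.1f}%")
    reports[cond] = compute_report(hn.ddtf(fit), condition=cond)

for cond, rep in reports.items():
    hub = rep.hub()
    print(f"{cond}: hub {hub} (outflow {rep.outflow[hub]:.3f}, "
          f"asymmetry {rep.asymmetry[hub]:+.2f})")

for flip in condition_contrast(reports)["role_changes"]:
    print(f"{flip['node']}: {flip['from']} -> {flip['to']}")
```

prints

```
L1: stability -0.117, consistency 93.9%
H2: stability -0.011, consistency 96.7%
L3: stability -0.116, consistency 94.5%
L1: hub VC (outflow 0.115, asymmetry +0.94)
H2: hub dACC (outflow 0.080, asymmetry +0.15)
L3: hub PFC (outflow 0.100, asymmetry +0.94)
VC: source -> balanced
vACC: balanced -> sink
dPCC: sink -> balanced
PFC: balanced -> source
```

Every fitted model is stable (index < 0) and reproduces > 85% of the data's
correlation structure. The recovered transition mirrors the hysteresis
narrative: in the first low-demand block the visual cortex drives the
network; after the high-demand block the prefrontal cortex has become the
dominant causal source and the ventral cingulate its sink.

The behavioral side of the same phenomenon:

```python
from hystnet.pipeline import PipelineConfig, run_behavioral_pipeline

cfg = PipelineConfig(seed=1, condition_minutes=4.0, n_behavioral_runs=25)
res = run_behavioral_pipeline(cfg)
for mode in ("carryover", "no_carryover"):
    c = res["contrast"][mode]
    print(f"{mode}: L3-L1 mean RT {c['mean']:+.3f} s  [{c['lo']:+.3f}, {c['hi']:+.3f}]")
```

prints

```
carryover: L3-L1 mean RT -0.329 s  [-0.551, -0.133]
no_carryover: L3-L1 mean RT -0.018 s  [-0.242, +0.270]
```

With declarative carryover the final low-demand block is reliably faster
than the first (the interval excludes zero — hysteresis); with memory reset
at each block the difference vanishes, reproducing the characteristic gap
between human operators and memory-reset cognitive models.

## Command line

```bash
hystnet synth-eeg --preset default --minutes 4 --trials 8 --seed 1 --out eeg.csv
hystnet matb-events --condition lhl --minutes 4 --seed 1 --out events.csv
hystnet actr-run --events events.csv --carryover on --seed 1 --out responses.csv
hystnet connectivity --in eeg.csv --order 16 --band 7:30 --out ddtf.csv
hystnet pipeline neural --config cfg.yaml
hystnet pipeline behavioral --config cfg.yaml
```
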