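# chcq — a cortico-hippocampal qubit-network model of classical conditioning

`chcq` simulates classical-conditioning experiments (acquisition, extinction,
stimulus discrimination, reversal, blocking, overshadowing, latent
inhibition, sensory/compound preconditioning, context shifts) with a pair of
coupled *qubit-neuron* networks, and compares **intact** against
**hippocampal-lesioned** systems by the number of training trials each needs
to reach a steady conditioned response.  It is aimed at computational
modelers of cortico-hippocampal function who want a small, fully
reproducible trials-to-criterion battery.

## The model

Every unit is a qubit neuron: its state is a phase angle *y*, and its
observable activation is the excited-state probability

&nbsp;&nbsp;&nbsp;&nbsp;a = sin²(y),&nbsp;&nbsp;&nbsp;
y = (π/2)·S(ε) − Arg(v),&nbsp;&nbsp;&nbsp;
v = Σᵢ wᵢ e^{i p̃ᵢ} − e^{iϑ},

where S is the logistic sigmoid, ε a reversal parameter, ϑ a phase
threshold, and p̃ᵢ = (π/2)pᵢ the phase encoding of real cue amplitudes
pᵢ ∈ [0, 1].  Two such networks are coupled:

* **Hippocampus** — an autoencoder (R=5 cue inputs, Q hidden qubits, R
  outputs) trained by the unsupervised **instar** rule on its input layer
  (incoming parameters drift toward the cue, gated by activation) and the
  **outstar** rule on its output layer.
* **Cortex** — a feedforward network (R → Q → 1) whose scalar output is the
  conditioned response CR ∈ [0, 1]; its hidden layer drifts slowly by
  instar, its output layer learns by the **Widrow–Hoff** (delta) rule
  against the reinforcement target (US present d=1, absent d=0).

In the intact system, an adaptive signal carries the hippocampal
hidden-layer parameters into the cortical hidden layer (per-trial blending)
and gates cortical output plasticity by **cue novelty** — the distance
between the cue and the hippocampal instar weights.  Lesioning removes the
whole link; a lesioned run depends only on the cortical seed and the cue
sequence.  Cues are vectors `[amp_A, amp_B, X, Y, Z]` (two stimuli, three
one-hot contexts); a phase of training ends when the CR stays above 0.85
(paired) or below 0.18 (unpaired) for 3 consecutive sweeps.

## Worked example

Latent inhibition: 50 unreinforced pre-exposures to the cue, then pairing
with the US until criterion.

```console
$ chcq run --task latent_inhibition --system intact --seed 3
phase 1: 50 trials
phase 2: 19 trials
$ chcq run --task latent_inhibition --system lesioned --seed 3
phase 1: 50 trials
phase 2: 16 trials
```

Phase 1 is the fixed 50-trial pre-exposure.  Phase 2 is the number of
reinforced trials until the CR stays ≥ 0.85: the intact system (19) is
slowed by the pre-exposure because the hippocampus has already encoded the
cue and reports low novelty, while the lesioned system (16) re-acquires at
its usual speed — latent inhibition depends on the hippocampal link.

Other entry points:

```bash
chcq battery --out battery_out          # full battery, summary.csv
chcq baseline --task a_minus --seed 0   # generic feedforward comparison net
chcq calibrate --grid '{"mu": [0.1, 0.16]}' --out calibrated.yaml
```

Library use mirrors the CLI: `build_model`, `make_paradigm`, `run_paradigm`
in `chcq`, battery and calibration in `chcq.battery`.

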