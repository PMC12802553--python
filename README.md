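# neoqpt

Quantum-simulation pipeline for proton-transfer kinetics with a quantum
proton: coupled electron–proton second-quantized Hamiltonians, exact
sector diagonalization (CASCI), adaptive variational state preparation
(ADAPT-VQE), adaptive approximate quantum compiling (AQC) into two-qubit
blocks, device-style noisy emulation with zero-noise extrapolation
(ZNE), and transition-state-theory rate constants.

Everything runs on plain numpy/scipy — the Pauli algebra, Jordan–Wigner
mapping and statevector simulator are part of the package, sized for
desk-scale registers (≤ 12 qubits).

## Layout

| module | contents |
| --- | --- |
| `neoqpt.hamiltonian` | `OrbitalSpace`, `NEOHamiltonian`, LMR interpolation, Löwdin orthogonalization, natural-orbital truncation, Jordan–Wigner mapping |
| `neoqpt.io` | `neo-json` and `neo-fcidump` (FCIDUMP + extension blocks) serialization |
| `neoqpt.exact` | CASCI sector diagonalization, product-state references, barrier heights, reduced density matrices, entanglement entropy, proton densities |
| `neoqpt.adapt` | excitation pools (fermionic and qubit-string), commutator gradients, ADAPT-VQE |
| `neoqpt.aqc` | two-qubit-block approximate compiling with high/low presets, prefix factorization, circuit metrics |
| `neoqpt.noise` | device tables → noise models, local gate folding, trajectory-sampled noisy expectations, fit-first / difference-first ZNE with bootstrap |
| `neoqpt.kinetics` | Eyring-style TST rates, rate suppression, barrier-tolerance sensitivity |
| `neoqpt.synthetic` | seeded random Hamiltonians, the Left/Middle/Right double-well triple with closed-form limits, Gaussian orbital grids |
| `neoqpt.pipeline` / `neoqpt.cli` | end-to-end orchestration and the `neoqpt` command |

## CLI

```sh
neoqpt generate --seed 1 --out triple/          # synthetic L/M/R triple
neoqpt solve triple/middle.json                 # CASCI + HF reference
neoqpt vqe triple/left.json --preset shallow
neoqpt aqc triple/left.json --preset low --out circ.json
neoqpt kinetics --barrier-mha 13.427 --ref-barrier-mha 11.857 -T 120
neoqpt pipeline --seed 0 --out report/          # full workflow, 7 labels
```

`neoqpt pipeline` accepts `--config config.json` with the fields of
`neoqpt.pipeline.PipelineConfig` (trajectory labels, presets, ZNE
settings, seeds). Reports land in `summary.csv`, `trajectory.csv` and
`report.json`.

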