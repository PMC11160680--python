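# cyclekin

Exact symbolic steady-state analysis of kinetic diagrams.

`cyclekin` implements the classical diagram method for discrete-state
kinetic networks: from a connected graph of states with reversible,
rate-labelled transitions it enumerates the auxiliary diagram families
(spanning-tree *partial diagrams*, target-oriented *directional
diagrams*, and cycle-feeding *flux diagrams*) and assembles exact
symbolic expressions for steady-state state probabilities, net cycle
fluxes, net transition fluxes, and observable *operational* fluxes.
Expressions are plain SymPy objects, so they can be substituted,
simplified, proven equivalent, or compiled into fast numeric evaluators.

The package also ships numerical cross-validation solvers (matrix and
stiff-ODE), thermodynamic-consistency tooling (cycle closure residuals,
driving forces, a detailed-balanced random-rate generator), and three
built-in membrane-transporter models:

* a 4-state antiporter with a leak transition (fully symbolic),
* a 6-state Na+/H+ antiporter ring with an optional leak transition,
* an 8-state drug/proton free-exchange transporter on a cube topology,

together with parameter sweeps over the leak rate, the
alternating-access bias ratio, and the substrate off-rate bias ratio.

## Library quick start

```python
import numpy as np
from cyclekin import (
    load_diagram, enumerate_partial_diagrams, enumerate_cycles,
    state_probability_expressions, net_cycle_flux_expression,
    operational_flux, steady_state_matrix,
)

# 4 states, edges declared by the nonzero pattern of a rate matrix
K = np.array([
    [0, 1, 0, 1],
    [1, 0, 1, 1],
    [0, 1, 0, 1],
    [1, 1, 1, 0],
])
diagram = load_diagram(K)

trees = enumerate_partial_diagrams(diagram)      # 8 spanning trees
cycles = enumerate_cycles(diagram)               # 3 simple cycles
probs = state_probability_expressions(diagram)   # p_i = omega_i / sigma
flux = net_cycle_flux_expression(diagram, cycles[-1], probs)
print(flux.numerator)   # (pi+ - pi-) * feeder sum, over rate symbols k_i_j
```

The built-in transporter fixtures live in `cyclekin.models`:

```python
from cyclekin.models import build_emre, sweep_roff
result = sweep_roff(np.logspace(-10, 10, 21), kAA=100.0)
print(result.fluxes["D"], result.stoichiometry)
```

## Command line

The `cyclekin` entry point exposes the same functionality:

```sh
cyclekin count four_state          # diagram/cycle counts
cyclekin cycles emre               # cycles + transport signatures (TSV)
cyclekin probs four_state --format latex
cyclekin cycleflux four_state --cycle 1-2-3-4
cyclekin opflux emre H --route transitions --direction int_to_ext
cyclekin solve six_state_leak      # numeric steady state + net fluxes
cyclekin validate --n 50 --max-states 8 --seed 7
cyclekin model emre --sweep roff --kaa 100 --grid log:-10:10:41 --out sweep.tsv
```

Model files are accepted as JSON edge lists (with per-edge process /
ligand / side / order / concentration annotations) or CSV rate matrices;
see `cyclekin.io` for the schemas.

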