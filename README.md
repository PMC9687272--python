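# ulkswitch

A tested implementation of the bistable mTORC1–ULK1–PP2A switch that
governs autophagy induction, for systems biologists who want to simulate
pharmacological and genetic perturbations of the triangle, analyse its
phase plane, and estimate its kinetics from immunoblot densitometry time
courses.

## The model

mTORC1 phosphorylates and inactivates ULK1 (Ser757) and PP2A; active ULK1
inhibits mTORC1 and stimulates PP2A; PP2A dephosphorylates and activates
ULK1 and suppresses mTORC1.  With `m`, `u`, `p` the active concentrations
and `MT`, `UT`, `PT` the conserved totals (1 in the untreated cell),
mass-action kinetics give three ODEs with twelve rate constants:

```
dm/dt = ka_m (MT − m) − (ki_m + k_b u + k_e p) m
du/dt = (ka_u + k_c p)(UT − u) − (ki_u + k_a m) u
dp/dt = (ka_p + k_d u)(PT − p) − (ki_p + k_f m) p
```

The two double-negative loops and the ULK1→PP2A→ULK1 positive loop make
the system a toggle: a *non-autophagy* state (mTORC1 high, ULK1
phosphorylated) and an *autophagy* state (ULK1 active, mTORC1 low)
coexist under physiological conditions, separated by a saddle.
Treatments are levers on the totals — rapamycin `MT = 0.1`, okadaic acid
`PT = 0.1`–`0.3`, siRNA a pre-equilibrated reduced total — and the
package simulates them, enumerates and classifies the resulting
equilibria, traces ULK1/mTORC1 balance curves (with PP2A at quasi-steady
state), fits the twelve constants to densitometry series, and generates
realistic synthetic densitometry for testing all of it.  Details:
[docs/methods.md](docs/methods.md).

## Worked example

Enumerate the equilibria of the untreated cell:

```
$ ulkswitch phaseplane --outdir pp_out
lever_name  lever_value    m_act    u_act    p_act stability         label  max_re_eigenvalue
                    NaN 0.822263 0.008934 0.002682    stable non-autophagy          -0.007137
                    NaN 0.665235 0.030371 0.009952  unstable non-autophagy           0.010402
                    NaN 0.063708 0.906925 0.552738    stable     autophagy          -0.123615
```

Three intersections of the balance curves: the resting state (82% of
mTORC1 active, ULK1 almost fully phosphorylated), a saddle, and the
autophagy state (91% of ULK1 active).  Under rapamycin the landscape
collapses to the autophagy state alone:

```python
from ulkswitch import default_rates, find_equilibria, TotalLevels

for eq in find_equilibria(default_rates(), TotalLevels(mTORT=0.1)):
    print(eq.label, eq.stability, round(eq.state.u_act, 3))
# autophagy stable 0.959
```

Simulate a figure-level condition, or the whole pipeline
(synthetic densitometry → 12-constant fit → all catalog experiments):

```
ulkswitch simulate --experiment fig6c --out fig6c.csv
ulkswitch pipeline --seed 1 --outdir pipeline_out
```

`fig6c` (okadaic acid + rapamycin) ends with ULK1 active
(`final_label: autophagy`), while `fig6d` (PP2A siRNA + rapamycin) keeps
ULK1 phosphorylated — the small residual phosphatase pool is what decides
whether mTORC1 inhibition can trigger autophagy.

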